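"""Reading and writing weight matrices and reports.

Formats are deliberately minimal and text-only:

- dense CSV: ``N`` rows of ``N`` comma-separated reals, no header, 0-based
  implicit ids;
- edge TSV: header ``src\\tdst\\tweight``, one directed edge per line,
  0-based integer ids, absent edges are zero;
- reports: structured JSON with stable keys, floats at 12 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from netsym.core import ValidationError, WeightMatrix

PathLike = Union[str, Path]

_DIAG_TOL = 1e-12


def read_matrix(
    path: PathLike,
    format: Optional[str] = None,
    n_neurons: Optional[int] = None,
) -> WeightMatrix:
    """Read a weight matrix from dense CSV or a TSV edge list.

    ``format`` is ``"dense_csv"`` or ``"edge_tsv"``; if omitted it is
    inferred from the suffix (``.csv`` vs ``.tsv``).  For edge lists,
    ``n_neurons`` declares the network size (default: 1 + largest id).
    Diagonal entries below 1e-12 are forced to exact zero; anything larger is
    rejected.
    """
    path = Path(path)
    if format is None:
        format = {"csv": "dense_csv", "tsv": "edge_tsv"}.get(
            path.suffix.lstrip(".").lower()
        )
        if format is None:
            raise ValidationError(
                f"cannot infer format from suffix {path.suffix!r}; pass format="
            )
    if format == "dense_csv":
        rows = [
            [float(x) for x in line.split(",")]
            for line in path.read_text().strip().splitlines()
            if line.strip()
        ]
        lengths = {len(r) for r in rows}
        if len(lengths) != 1 or lengths.pop() != len(rows):
            raise ValidationError(
                f"matrix not square: {len(rows)} rows, widths {sorted({len(r) for r in rows})}"
            )
        w = np.asarray(rows, dtype=float)
    elif format == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        expected = ["src", "dst", "weight"]
        if list(df.columns[:3]) != expected:
            raise ValidationError(
                f"edge list must have header {expected}, got {list(df.columns)}"
            )
        if df.duplicated(subset=["src", "dst"]).any():
            dup = df[df.duplicated(subset=["src", "dst"])].iloc[0]
            raise ValidationError(
                f"duplicate edge ({int(dup.src)}, {int(dup.dst)})"
            )
        n = n_neurons if n_neurons is not None else int(df[["src", "dst"]].to_numpy().max()) + 1
        w = np.zeros((n, n))
        for _, row in df.iterrows():
            src, dst = int(row.src), int(row.dst)
            if not (0 <= src < n and 0 <= dst < n):
                raise ValidationError(f"edge ({src}, {dst}) outside declared size {n}")
            # edge src -> dst lands at row dst (postsynaptic), column src
            w[dst, src] = float(row.weight)
    else:
        raise ValidationError(f"unknown format {format!r}")
    near_diag = np.abs(np.diag(w)) <= _DIAG_TOL
    w[np.diag_indices_from(w)] = np.where(near_diag, 0.0, np.diag(w))
    return WeightMatrix.from_array(w)


def write_matrix(W: WeightMatrix, path: PathLike) -> None:
    """Write a weight matrix as headerless dense CSV."""
    np.savetxt(path, W.weights, delimiter=",", fmt="%.12g")


def _round_floats(obj):
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, np.floating):
        return float(f"{float(obj):.12g}")
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def write_report(obj, path: PathLike) -> None:
    """Write a report/statistics/summary object (anything with to_dict) as JSON."""
    d = obj.to_dict() if hasattr(obj, "to_dict") else dict(obj)
    Path(path).write_text(json.dumps(_round_floats(d), indent=2) + "\n")


def read_report(path: PathLike) -> dict:
    """Read back a JSON report as a plain dict."""
    return json.loads(Path(path).read_text())
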