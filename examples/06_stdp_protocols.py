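"""Watch learning drive a spiking network towards symmetry or asymmetry.

A small leaky integrate-and-fire network with triplet STDP is stimulated
either with a frequency protocol (each neuron driven at its own rate, which
builds reciprocal connections and pushes s up) or a sequential protocol
(neurons driven in a fixed order, which carves one-way connections and
pushes s down).  Kept short here (N=8, 30 simulated seconds) so it runs in a
few seconds; the trend continues to saturation on longer runs.
"""

from netsym import NullModelSpec, SimulationConfig, moments_s, run_simulation

null = moments_s(NullModelSpec(family="uniform"), 8)
print(f"random-network null mean for N=8: mu_s = {null.mu_s:.3f}\n")

for protocol in ("frequency", "sequential"):
    cfg = SimulationConfig(
        n_neurons=8,
        duration_ms=30_000.0,
        protocol=protocol,
        record_interval_ms=10_000.0,
    )
    r = run_simulation(cfg, seed=1)
    traj = ", ".join(f"{s:.3f}" for s in r.s_trajectory)
    print(f"{protocol:10s}: s over time [{traj}]")

print("\nFrequency stimulation raises s above the null mean; sequential "
      "stimulation lowers it.")
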