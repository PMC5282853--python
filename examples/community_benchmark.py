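"""Multiplex community benchmark: recovery vs noise.

Two 256-node networks with eight planted 32-node clusters and every node
of degree exactly 32.  The first network keeps mixing 0.1; the second's
mixing parameter (fraction of each node's edges leaving its cluster)
grows, and recovery is scored by normalized mutual information against
the planted partition.
"""

from emdn.benchmarks import multiplex_nmi_sweep

sweep = multiplex_nmi_sweep(mixings=(0.1, 0.3, 0.6), n_seeds=5, rng_seed=0)
print(sweep.round(4))
print(
    "\nmean NMI of 1.0 would be perfect recovery of the eight planted"
    "\nclusters; values should stay high at low mixing and degrade as the"
    "\nsecond network's cluster structure dissolves."
)
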