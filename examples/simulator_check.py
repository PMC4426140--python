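"""Validate the branching-process theory against the exact Moran simulator.

The analytic machinery approximates the early fate of the migrant haplotype
by a multitype branching process.  This script runs the individual-based
Moran model (the ground truth the approximation targets) on two settings and
reports the z-scores of the discrepancies.

Run:  python examples/simulator_check.py          (about a minute)
"""

import introgress as ig

CASES = [
    # (fixture, replicates, stop_fraction, seed)
    ("fig4a", 200_000, 0.05, 99),   # one linked deleterious allele, N=10^4
    ("fig2", 100_000, 0.05, 23),    # four unlinked deleterious alleles
]

print(f"{'fixture':<10} {'theory':>10} {'simulated':>10} {'SE':>8} {'z':>6}")
for name, reps, stop, seed in CASES:
    scn = ig.get_fixture(name).scenario
    pred = ig.introgression_probability(scn)
    est = ig.estimate(scn, replicates=reps, seed=seed, stop_fraction=stop)
    z = (est.introgression_prob - pred) / est.introgression_se
    print(f"{name:<10} {pred:>10.5f} {est.introgression_prob:>10.5f} "
          f"{est.introgression_se:>8.5f} {z:>6.2f}")

print("\n|z| < 3 means the simulator and the theory agree within Monte-Carlo "
      "noise.")
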