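"""Walk through the single-hitchhiker analysis end to end.

A beneficial allele (Malthusian fitness 0.012) enters a resident population
of size N = 500 linked to one deleterious allele (haplotype fitness 0.01,
recombination probability 0.003 per generation).  We compute, step by step:

1. the probability the migrant haplotype introgresses at all,
2. the distribution of the rescue type (which haplotype establishes first),
3. the deterministic-phase retention probability of the deleterious allele,
4. the final fixation distribution, i.e. the hitchhiking probability.

Run:  python examples/single_hitchhiker.py
"""

import introgress as ig

scenario = ig.get_fixture("worked_example_10_2").scenario
print(f"scenario: N={scenario.N}, classes={sorted(scenario.selection.sigma)}")

# 1. establishment of anything at all
table = ig.extinction_table(scenario)
p_intro = ig.introgression_probability(scenario)
print(f"\n1. introgression probability 1 - Q_(0,1) = {p_intro:.7f}")
print(f"   (closed form check: {ig.closed_form_single_linked(0.012, 0.01, 0.003):.7f}"
      " = Q_(0,1))")

# 2. which haplotype founds the permanent lineage?
rescue = ig.rescue_distribution(scenario)
for (i, j), p in sorted(rescue.P.items()):
    print(f"2. P(rescue type = ({i},{j})) = {p:.5f}")

# 3. the loaded haplotype still has to survive its own sweep: recombination
#    during the deterministic phase can free the beneficial allele
nu_bar = ig.effective_initial_size(sigma_est=0.01, r_total=0.003)
model = ig.SweepModel(
    N=500, sigma_est=0.01, sigma_targets=[0.012], r_targets=[0.003], nu_bar=nu_bar
)
p_det = ig.retention_probability_single(model)
print(f"\n3. effective initial size nu_bar = {nu_bar:.3f}")
print(f"   deterministic-phase retention  = {p_det:.6f}")

# 4. concatenate both phases
dist = ig.fixation_distribution(scenario)
print("\n4. conditional fixation distribution (given introgression):")
for cls, p in sorted(dist.conditional.items()):
    print(f"   P(fix {cls}) = {p:.6f}   [{dist.method[cls]}]")
print(f"   hitchhiking probability of the deleterious allele = "
      f"{ig.hitchhiking_probability(scenario, (0, 1)):.6f}")

# cross-check against the exact Moran simulator (a few seconds)
est = ig.estimate(scenario, replicates=500, seed=42, condition_on_success=True)
p_sim = est.fixation_dist.get((0, 1), 0.0)
print(f"\nMoran simulator, 500 conditioned replicates: "
      f"P(fix (0,1)) = {p_sim:.4f} +- {est.fixation_se[(0, 1)]:.4f}")
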