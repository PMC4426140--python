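"""Introgression through a wall of linked deleterious alleles.

The beneficial migrant allele sits between I deleterious alleles on its left
and J = 2 on its right; only the haplotypes (0,0) and (0,1) have positive
fitness, so introgression must proceed by stochastic tunneling: recombination
has to strip the load before the lineage dies.  Two things happen as I grows:

* the introgression probability collapses roughly geometrically, and
* the hitchhiking probability of the mildly deleterious right-hand allele
  dips at I = 1, because the first recombination event then usually creates
  the doomed-but-slowly-dying (1,0) haplotype instead of a fit one.

Writes a TSV table and prints it.  Run:  python examples/many_linked_alleles.py
"""

import introgress as ig

rows = []
for I in range(0, 11):
    scn = ig.fig9_scenario(I=I, J=2)
    p_intro = ig.introgression_probability(scn)
    p_hh = ig.hitchhiking_probability(scn, (0, 1))
    rows.append({"I": I, "introgression_prob": p_intro, "hitchhike_01": p_hh})

ig.write_results(
    rows,
    "many_linked_alleles.tsv",
    header_comment="sigma_(0,0)=0.08, sigma_(0,1)=0.07, all pairwise r=1e-4, J=2",
)

print(f"{'I':>2}  {'P(introgression)':>18}  {'P(fix (0,1) | success)':>24}")
for row in rows:
    print(f"{row['I']:>2}  {row['introgression_prob']:>18.6e}  "
          f"{row['hitchhike_01']:>24.6f}")
print("\nwrote many_linked_alleles.tsv")
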