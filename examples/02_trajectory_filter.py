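"""Allele-frequency trajectories and the monotone sweep filter.

Builds the canonical selected-allele sweep (per-generation alternate
allele counts 0, 1, 2, 2, 4 over the six chromosomes of three diploid
mice) and applies the trajectory filter.
"""

from clonaltraj import per_generation_maf, trajectory_filter
from clonaltraj.simgen import CANONICAL_SWEEP_COUNTS, sweep_genotypes

genotypes = sweep_genotypes(CANONICAL_SWEEP_COUNTS)
(trajectory,) = per_generation_maf(genotypes)

print("generation   alt alleles / chromosomes   frequency")
for g, (a, c, f) in enumerate(
    zip(trajectory.alt_counts, trajectory.callable_chromosomes, trajectory.freqs), 1
):
    print(f"        g{g}   {a} / {c}                       {f:.6f}")

verdict = trajectory_filter(trajectory)
print(f"\nfilter verdict: passes={verdict.passes}, direction={verdict.direction}")

# The allele rises monotonically (ties allowed) from <= 1/3 in g1 to
# >= 2/3 in g5 — the signature of an allele sweeping through the tumor
# across passages, which is what the filter keeps.  Frequencies are
# exact sixths because each passage carries 2 x 3 chromosomes.
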