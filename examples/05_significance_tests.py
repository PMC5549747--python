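"""Assess scale-vs-scale correlations against the uniform random null.

Compares the codon-content purine scale with (a) an optimized scale from a
short Monte Carlo run and (b) a random scale, reporting randomization
p-values (fraction of 1e5 uniform-null scales correlating at least as
extremely) and the Fisher-combined significance of the two comparisons.
"""

from scalescape import (
    CodonUsage,
    MCConfig,
    NucleobaseTarget,
    ProfileCache,
    SyntheticSpec,
    codon_content_scale,
    fisher_combine,
    generate_proteome,
    randomization_p,
    run_mc,
    sample_random_scales,
    scale_correlation,
)
from scalescape.significance import floored

reference = codon_content_scale(CodonUsage.uniform(), NucleobaseTarget.PUR, "affinity")
proteome = generate_proteome(
    SyntheticSpec(n_pairs=200, length_distribution=("fixed", 300), seed=5)
)
optimized = run_mc(ProfileCache(proteome), MCConfig(n_steps=1500, seed=30)).final_scale
(random_scale,) = sample_random_scales(1, seed=31)

pvals = []
for label, other in [("optimized", optimized), ("random", random_scale)]:
    r = scale_correlation(other, reference)
    result = randomization_p(reference, r, n_random=100_000, seed=32)
    pvals.append(floored(result))
    print(
        f"{label:10s} vs codon scale: R = {r:+.3f}, "
        f"one-tailed p = {result.p_one_tailed:.3g}, two-tailed p = {result.p_two_tailed:.3g}"
    )

print(f"Fisher-combined two-tailed p: {fisher_combine(pvals):.3g}")
# The optimized scale's correlation is far outside the null (p at the Monte
# Carlo resolution floor); the random scale's is not; the combined p is
# dominated by the strong comparison.
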