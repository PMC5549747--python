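"""Optimize an affinity scale by the zero-temperature Monte Carlo search.

Runs three independent seeded searches on one synthetic proteome, reports
their convergence, and shows that all runs land on essentially the same
scale (the funnel property) — which in turn matches the codon-content scale
that the data were generated from (parameter recovery).
"""

from scalescape import (
    CodonUsage,
    MCConfig,
    NucleobaseTarget,
    ProfileCache,
    SyntheticSpec,
    codon_content_scale,
    generate_proteome,
    mean_scale,
    moves_to_threshold,
    run_independent,
    scale_correlation,
)

proteome = generate_proteome(
    SyntheticSpec(n_pairs=300, length_distribution=("lognormal", 300, 0.4), seed=3)
)
cache = ProfileCache(proteome)

trajectories = run_independent(cache, MCConfig(n_steps=1500), n_runs=3, base_seed=10)
for traj in trajectories:
    moves = moves_to_threshold(traj, -0.8)
    print(
        f"seed {traj.config.seed}: final <R> = {traj.final_R:.4f}, "
        f"reached -0.80 after {moves} attempted moves"
    )

finals = [t.final_scale for t in trajectories]
print(f"pairwise scale correlation (runs 0,1): {scale_correlation(finals[0], finals[1]):.4f}")
print(f"pairwise scale correlation (runs 0,2): {scale_correlation(finals[0], finals[2]):.4f}")

codon = codon_content_scale(CodonUsage.uniform(), NucleobaseTarget.PUR, "affinity")
recovery = scale_correlation(mean_scale(finals), codon)
print(f"mean optimized scale vs generating codon scale: R = {recovery:.4f}")
# R > 0.99: the search recovers the genetic-code-determined scale from the
# sequence data alone, without being told anything about the code.
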