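"""Map the diversity of suboptimal scales across matching levels.

Selects, from an ensemble of independent searches, the scale each run had
when it passed a given matching level, clusters each ensemble under the
1 - R correlation distance, and prints cluster counts per (level, cutoff).
Many clusters at weak matching collapsing to one near the optimum is the
signature of a funnel-shaped fitness landscape.
"""

import numpy as np

from scalescape import (
    MCConfig,
    ProfileCache,
    SyntheticSpec,
    generate_proteome,
    landscape_table,
    run_independent,
)

proteome = generate_proteome(
    SyntheticSpec(n_pairs=300, length_distribution=("lognormal", 300, 0.4), seed=4)
)
trajectories = run_independent(
    ProfileCache(proteome), MCConfig(n_steps=1500), n_runs=20, base_seed=20
)

converged = float(np.mean([t.final_R for t in trajectories]))
table = landscape_table(
    trajectories,
    levels=[-0.3, -0.5, -0.7, converged],
    cutoffs=[0.1, 0.2, 0.4],
    n_required=2,
)
print(table.to_string(index=False))
# n_clusters shrinks both with looser cutoffs (nesting) and toward stronger
# matching levels: weakly matching scales are diverse, optimal ones unique.
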