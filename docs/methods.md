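# Methods

## Profiles and the fitness function

Each cognate pair consists of a coding sequence of length 3L+3 (trailing
stop codon) and its protein of length L. Profiles are evaluated at codon
resolution: entry i of the mRNA profile is the fraction of target
nucleobases among the 63 nucleotides of codons i..i+20, and entry i of the
protein profile is the mean scale weight of residues i..i+20. Both profiles
therefore have exactly L−20 points in one-to-one register, which is the
natural correspondence for a 63-nt/21-residue window pair (63 = 3×21).
Only full windows are used — shrunken edge windows would contribute
high-variance points at the termini — and the stop codon is excluded
because it has no cognate residue. Window size is a parameter
(`window`, default 21 codons/residues); published window-size insensitivity
means results change little for nearby values.

The fitness of a scale w is the unweighted proteome mean `<R>` of per-pair
Pearson correlations between the two profiles. Two conventions matter:

- **Zero variance → R = 0.** A flat profile (constant mRNA composition, or a
  degenerate scale such as the all-equal starting scale) carries no
  positional signal; its correlation is defined as 0 ("no matching"). This
  makes the search's starting fitness well-defined.
- **Linear invariance.** Window averaging and Pearson correlation are
  invariant under w → αw+β (α>0), and anti-symmetric for α<0. Scales are
  therefore reported unit-rescaled (min→0, max→1); an all-equal scale has no
  shape to preserve and maps to all 0.5 with a `degenerate` flag.

### Fast evaluation

`ProfileCache` compresses pair p into sufficient statistics: with m the
centered mRNA profile (per target), s its SD, and Wc the column-centered
window-composition matrix,

    R_p(w) = (a_p·w) / (s_p · sqrt(wᵀ C_p w)),   a_p = Wcᵀm/n,  C_p = WcᵀWc/n.

Evaluating `<R>` for a new scale is then one (N×20) mat-vec plus one batched
quadratic form, independent of sequence lengths — about 0.5 ms for 1000
pairs — which is what makes ensemble Monte Carlo campaigns cheap. The cached
path agrees with the from-scratch profile computation to ~1e−12 (tested
against an independent brute-force window counter).

## Monte Carlo search

Zero-temperature downhill Metropolis, deliberately minimal: no finite
temperature, restarts, or gradients. Per attempted move, k ~ U{1..4}
distinct weights are perturbed; the perturbation amplitude ramps linearly
from 0.1 to 0.01 over the run (simulated annealing of the step size, not of
an acceptance temperature); a move is accepted iff it strictly lowers `<R>`
(ties rejected, keeping accepted fitness strictly decreasing). The search
starts from the all-equal scale with fitness 0 by the zero-variance
convention. Runs are driven by a single PCG64 generator seeded explicitly,
making trajectories bitwise reproducible; campaigns derive run i's seed as
`base_seed + i`.

Two readings of the algorithm's looser phrasing are exposed as options:
offsets are independent per perturbed weight by default
(`shared_offset=True` applies one common offset), and `moves_to_threshold`
counts attempted moves by default (`count="accepted"` counts acceptances).
Defaults: `n_steps=1500`, roughly 5× the ~300 moves a whole-proteome-sized
problem needs to converge, honoring the rule of running several times longer
than the time to a stable minimum.

## Codon-content reference scales

For amino acid a, the raw content is Σ_c usage(c|a)·n_target(c)/3 over its
sense codons, with usage computed from the analyzed dataset's own CDS
(organism-specific usage is exactly what distinguishes otherwise-identical
genetic codes; amino acids absent from a dataset fall back to uniform usage
with a warning). The default `affinity` orientation negates the content
before unit rescaling so that base-rich amino acids get low weights; this is
the binding-affinity sign convention under which matching `<R>` is negative.
The `content` orientation (no negation) is the physically transparent
variant; the two are exactly anti-correlated. Negating before or after usage
weighting is equivalent since rescaling absorbs affine maps.

## Landscape clustering

Scales selected at a matching level (per independent run, the accepted scale
with `<R>` closest to the level, within ±0.01 by default) are clustered
agglomeratively under the correlation distance 1−R ∈ [0,2]. Cutting the
dendrogram at a distance cutoff counts flat clusters; counts are nested
(non-increasing in the cutoff). Average linkage is the default — the funnel
narrative is robust to linkage but absolute counts are not, so the linkage
is recorded in every output table and single/complete are available. Levels
represented by fewer than `n_required` runs are dropped rather than
reported from thin ensembles; note that fast-converging searches may skip a
weak level entirely between two accepted moves, so weak levels are
systematically harder to populate. Cluster counts grow with ensemble size;
comparisons are only meaningful at fixed ensemble size.

## Significance

The null for scale-vs-scale correlation draws 20 i.i.d. weights uniform on
[0,1] — matching the unit-rescaling convention, and the distribution whose
weight SD is 1/√12 ≈ 0.289. The one-tailed p is the fraction of null scales
correlating at least as extremely as observed; the default `toward-observed`
direction picks the tail on the observed side so that both strong negative
and strong positive correlations can be significant, while
`direction="negative"` gives the strict lower-tail test. Two-tailed
conversion is 2p if p<0.5 else 1−p; Fisher combination refers
−2Σln pᵢ to χ² with 2k degrees of freedom. An empirical p of exactly 0 is
an artifact of finite sampling: it is floored at the Monte Carlo resolution
1/n_random (`significance.floored`) before combination.

## Synthetic proteomes

The generator draws protein lengths (fixed, uniform, or lognormal
parametrized by mean and log-SD; default study condition: 1000 pairs,
lognormal mean 300, σ=0.4, roughly a bacterial proteome's size and length
spread), residues i.i.d. from a configurable composition (default uniform;
a rough E. coli-like composition ships as a labeled preset), and codons from
a configurable within-family usage (default uniform), appending a random
stop codon. Every generated pair passes strict validation including the
translation check.

Residues being i.i.d. is a deliberate modeling choice, not a limitation to
be fixed: with no positional autocorrelation, any profile complementarity in
the generated data comes only from the genetic code plus codon usage, which
is precisely the null needed to test that the search recovers the
codon-content scale rather than sequence-order artifacts. Consequently the
synthetic data do not emulate real gene content, GC gradients, codon
autocorrelation, or amino-acid clustering — so passing synthetic tests
demonstrates correctness of the machinery and code-driven matching, but not
the magnitude of complementarity in any real organism, for which real
paired datasets must be supplied.

## Numerical choices and problem sizes

- Variances below 1e−24 are treated as exactly zero (flat-profile guard).
- Scale TSVs are written at 17 significant digits, making write→read
  round trips exact.
- Codon-usage families validate to 1 within 1e−9; window-matrix rows to 1
  within 1e−12.
- Dataset pairs require protein length ≥ 22 so profiles have ≥ 2 points and
  Pearson R is defined; profile functions themselves accept length ≥ 21
  (single window) for inspection.
- Test-suite and reproduction-script problem sizes (1000-pair proteomes,
  10–40 run ensembles, 1e5–1e6 null draws) were chosen as the smallest sizes
  at which the ensemble statistics stabilize; the full-scale analogue of the
  published campaigns (1000 runs per organism/target) runs through
  `scalescape campaign` or `run_independent` unchanged, just longer.

## Known limitations

- The search is strictly downhill; on a non-funnel fitness surface it would
  stop in local minima. The diversity analysis relies on many independent
  runs rather than within-run tempering.
- Whole-proteome caches hold a 20×20 covariance per pair (~3 MB per 1000
  pairs) — fine for proteomes, not designed for metagenome-scale inputs.
- The correlation-distance clustering deduplicates nothing: near-identical
  converged scales appear as one tight cluster, by design.
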