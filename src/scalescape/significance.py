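"""Randomization tests for scale-vs-scale correlations and Fisher combination.

The null model draws scales with 20 i.i.d. weights uniform on [0, 1] (the
same unit interval scales are rescaled to) and asks how often a random scale
correlates with the reference scale at least as extremely as the observed
one. One-tailed empirical p-values are converted to two-tailed ones by the
rule 2p if p < 0.5 else 1 - p, and independent two-tailed p-values are
combined with Fisher's method (X^2 = -2 sum ln p, chi-square with 2k df).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .scales import AffinityScale

DIRECTIONS = ("negative", "positive", "toward-observed")

_CHUNK = 100_000


@dataclass(frozen=True)
class SignificanceResult:
    """Empirical significance of one observed scale-vs-scale correlation."""

    observed_R: float
    p_one_tailed: float
    p_two_tailed: float
    n_random: int
    seed: int
    direction: str

    @property
    def resolution(self) -> float:
        """Monte-Carlo resolution of the p estimate."""
        return 1.0 / self.n_random


def null_correlations(
    reference: AffinityScale, n_random: int, rng: np.random.Generator
) -> np.ndarray:
    """Pearson correlations of ``n_random`` uniform-null scales with a reference."""
    ref = reference.vector
    refc = ref - ref.mean()
    norm = np.sqrt(refc @ refc)
    if norm < 1e-12:
        raise ValueError("degenerate (constant) reference scale")
    refu = refc / norm
    out = np.empty(n_random)
    for start in range(0, n_random, _CHUNK):
        block = rng.random((min(_CHUNK, n_random - start), 20))
        bc = block - block.mean(axis=1, keepdims=True)
        norms = np.sqrt((bc * bc).sum(axis=1))
        norms[norms < 1e-15] = np.inf  # constant random scale: R = 0
        out[start : start + block.shape[0]] = (bc @ refu) / norms
    return out


def randomization_p(
    reference_scale: AffinityScale,
    observed_R: float,
    n_random: int = 1_000_000,
    direction: str = "toward-observed",
    seed: int = 0,
) -> SignificanceResult:
    """Empirical p-value of an observed correlation against the uniform null.

    ``direction`` chooses the tail: ``negative`` counts null correlations
    <= observed, ``positive`` counts >= observed, and ``toward-observed``
    (default) picks the tail on the side of the observed value — the
    convention that makes both strong negative and strong positive observed
    correlations significant.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    rng = np.random.Generator(np.random.PCG64(seed))
    null = null_correlations(reference_scale, n_random, rng)
    if direction == "toward-observed":
        tail = "negative" if observed_R < 0 else "positive"
    else:
        tail = direction
    if tail == "negative":
        p_one = float((null <= observed_R).mean())
    else:
        p_one = float((null >= observed_R).mean())
    return SignificanceResult(
        observed_R=observed_R,
        p_one_tailed=p_one,
        p_two_tailed=two_tailed(p_one),
        n_random=n_random,
        seed=seed,
        direction=direction,
    )


def two_tailed(p_one: float) -> float:
    """Two-tailed conversion of a one-tailed p: 2p if p < 0.5, else 1 - p."""
    if not 0.0 <= p_one <= 1.0:
        raise ValueError(f"p-value {p_one} outside [0, 1]")
    return 2.0 * p_one if p_one < 0.5 else 1.0 - p_one


def fisher_combine(p_values: list[float] | np.ndarray) -> float:
    """Fisher's method: X^2 = -2 sum ln p_i on chi-square with 2k df (upper tail).

    p = 0 is an error (infinite statistic): empirical p-values of 0 must be
    floored at their Monte-Carlo resolution 1/n_random by the caller.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("all p-values must be in (0, 1]")
    x2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x2, df=2 * p.size))


def floored(result: SignificanceResult) -> float:
    """Two-tailed p floored at the Monte-Carlo resolution, safe for Fisher combination."""
    return max(result.p_two_tailed, result.resolution)
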