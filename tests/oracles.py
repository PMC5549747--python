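"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's matrix machinery: profiles are
computed by literal per-window counting/averaging over the raw strings, and
correlations go through scipy. They serve as oracles for the fast paths.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def naive_mrna_profile(cds: str, bases: tuple[str, ...], window: int = 21) -> np.ndarray:
    """Per-window target-base fraction by direct counting over the nucleotide string."""
    coding = cds[: len(cds) - 3]  # drop stop codon
    n_codons = len(coding) // 3
    values = []
    for i in range(n_codons - window + 1):
        chunk = coding[3 * i : 3 * (i + window)]
        values.append(sum(chunk.count(b) for b in bases) / (3 * window))
    return np.array(values)


def naive_protein_profile(protein: str, weights: dict[str, float], window: int = 21) -> np.ndarray:
    """Per-window mean of per-residue weights by direct slicing."""
    per_residue = [weights[aa] for aa in protein]
    return np.array(
        [
            sum(per_residue[i : i + window]) / window
            for i in range(len(protein) - window + 1)
        ]
    )


def naive_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """scipy Pearson R with the flat-profile -> 0 convention."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(stats.pearsonr(x, y).statistic)


def naive_mean_R(proteome, bases: tuple[str, ...], weights: dict[str, float], window: int = 21) -> float:
    return float(
        np.mean(
            [
                naive_pearson(
                    naive_mrna_profile(p.cds, bases, window),
                    naive_protein_profile(p.protein, weights, window),
                )
                for p in proteome
            ]
        )
    )


def naive_codon_counts(proteome) -> dict[str, int]:
    """Single-pass sense-codon counter over all CDS (stop codons skipped)."""
    counts: dict[str, int] = {}
    for pair in proteome:
        for i in range(0, len(pair.cds) - 3, 3):
            codon = pair.cds[i : i + 3]
            if codon not in ("TAA", "TAG", "TGA"):
                counts[codon] = counts.get(codon, 0) + 1
    return counts


def components_under_cutoff(dist: np.ndarray, cutoff: float) -> int:
    """Single-linkage flat clusters as graph components under distance <= cutoff."""
    n = dist.shape[0]
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= cutoff:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})
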