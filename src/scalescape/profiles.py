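"""Windowed sequence profiles and the proteome-average correlation fitness.

An mRNA nucleobase-density profile is the sliding-window fraction of a target
base (or base class) along a coding sequence; a protein affinity profile is
the sliding-window mean of per-residue weights under a 20-element amino-acid
scale. Profiles are evaluated at codon resolution: the mRNA window covers 63
nucleotides (21 codons) and the protein window 21 residues, centered on the
same codon/residue, so both profiles of a length-L protein have exactly
L - 20 points in register. Only full windows are used and the trailing stop
codon is excluded (it has no cognate residue).

The fitness of a scale is the proteome-average Pearson correlation <R>
between cognate profile pairs. :class:`ProfileCache` compresses each pair
into sufficient statistics (a 20-vector and a 20x20 window-covariance matrix)
so that <R> for any scale is a few small matrix products — this is what makes
the Monte Carlo search over scale space fast.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .dataset import Proteome, SequencePair
from .genetic_code import AA_INDEX, AMINO_ACIDS

if TYPE_CHECKING:  # pragma: no cover
    from .scales import AffinityScale

WINDOW_CODONS = 21  # 63-nt mRNA window == 21 codons == 21-residue protein window

#: variance below this is treated as exactly zero (flat profile -> R = 0)
_VAR_EPS = 1e-24


class NucleobaseTarget(Enum):
    """A nucleobase (or the purine class) whose mRNA density is profiled.

    Pyrimidine density is by definition ``1 - PUR`` and is therefore never a
    search target; :func:`pyr_density_profile` exposes it as a helper.
    """

    URA = ("T",)
    CYT = ("C",)
    ADE = ("A",)
    GUA = ("G",)
    PUR = ("A", "G")

    @property
    def bases(self) -> tuple[str, ...]:
        return self.value

    @classmethod
    def parse(cls, name: str) -> "NucleobaseTarget":
        try:
            return cls[name.upper()]
        except KeyError:
            raise ValueError(
                f"unknown target {name!r}; expected one of "
                f"{', '.join(t.name for t in cls)}"
            ) from None


@dataclass(frozen=True)
class FitnessResult:
    """Proteome-average Pearson correlation and its per-pair breakdown."""

    mean_R: float
    per_pair_R: np.ndarray
    n_pairs: int


def _codon_base_counts(cds: str) -> np.ndarray:
    """Per-codon counts of A, C, G, T over the L sense codons (stop dropped)."""
    arr = np.frombuffer(cds[: len(cds) - 3].encode(), dtype=np.uint8)
    codons = arr.reshape(-1, 3)
    counts = np.empty((codons.shape[0], 4), dtype=np.float64)
    for col, base in enumerate(b"ACGT"):
        counts[:, col] = (codons == base).sum(axis=1)
    return counts


_BASE_COL = {"A": 0, "C": 1, "G": 2, "T": 3}


def _window_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Means over all full sliding windows; len(values) - window + 1 points."""
    c = np.concatenate(([0.0], np.cumsum(values, dtype=np.float64)))
    return (c[window:] - c[:-window]) / window


def mrna_density_profile(
    cds: str, target: NucleobaseTarget, window: int = WINDOW_CODONS
) -> np.ndarray:
    """Window-averaged density of the target base(s) along a CDS.

    Entry i is the fraction of target bases among the ``3 * window``
    nucleotides of codons i..i+window-1; the stop codon is excluded.
    """
    n_codons = len(cds) // 3 - 1
    if n_codons < window:
        raise ValueError(
            f"CDS encodes {n_codons} residues; need at least {window} for one full window"
        )
    counts = _codon_base_counts(cds)
    per_codon = sum(counts[:, _BASE_COL[b]] for b in target.bases) / 3.0
    return _window_mean(per_codon, window)


def pyr_density_profile(cds: str, window: int = WINDOW_CODONS) -> np.ndarray:
    """Pyrimidine density: elementwise ``1 - PUR`` density (never a search target)."""
    return 1.0 - mrna_density_profile(cds, NucleobaseTarget.PUR, window)


def protein_window_matrix(protein: str, window: int = WINDOW_CODONS) -> np.ndarray:
    """(L - window + 1) x 20 matrix of windowed amino-acid frequencies.

    Row i holds the frequencies of the 20 amino acids among residues
    i..i+window-1, so the affinity profile under scale w is ``matrix @ w``:
    the matrix factorizes sequence weighting from window smoothing.
    """
    L = len(protein)
    if L < window:
        raise ValueError(f"protein length {L} < window {window}")
    idx = np.fromiter((AA_INDEX[aa] for aa in protein), count=L, dtype=np.intp)
    onehot = np.zeros((L, 20), dtype=np.float64)
    onehot[np.arange(L), idx] = 1.0
    c = np.concatenate((np.zeros((1, 20)), np.cumsum(onehot, axis=0)))
    return (c[window:] - c[:-window]) / window


def protein_profile(
    source: str | np.ndarray, scale: "AffinityScale | np.ndarray", window: int = WINDOW_CODONS
) -> np.ndarray:
    """Window-averaged per-residue weights for a protein under a scale.

    ``source`` may be a protein string or a precomputed window matrix.
    """
    w = scale if isinstance(scale, np.ndarray) else scale.vector
    matrix = source if isinstance(source, np.ndarray) else protein_window_matrix(source, window)
    return matrix @ w


def pair_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson R with the zero-variance convention.

    A flat profile carries no positional signal, so if either input has zero
    variance the correlation is defined as 0 ("no matching"); this also gives
    the all-equal starting scale of the Monte Carlo search a fitness of 0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    xc = x - x.mean()
    yc = y - y.mean()
    vx = xc @ xc
    vy = yc @ yc
    if vx <= _VAR_EPS or vy <= _VAR_EPS:
        return 0.0
    return float((xc @ yc) / np.sqrt(vx * vy))


class ProfileCache:
    """Precomputed per-pair statistics for fast evaluation of any scale.

    For pair p with n windows, let m be its centered mRNA density profile
    (for a given target) with standard deviation s, and W its window matrix
    with centered columns Wc. Then for a scale w::

        R_p(w) = (a_p . w) / (s_p * sqrt(w' C_p w)),
        a_p = Wc' m / n,   C_p = Wc' Wc / n

    so <R> over the proteome is one matvec plus one quadratic form per pair,
    independent of sequence length. Statistics for each target are built
    lazily on first use.
    """

    def __init__(self, proteome: Proteome, window: int = WINDOW_CODONS):
        if len(proteome) == 0:
            raise ValueError("empty proteome")
        self.proteome = proteome
        self.window = window
        self.ids = [p.id for p in proteome]
        self._counts = [_codon_base_counts(p.cds) for p in proteome]
        self._matrices = [protein_window_matrix(p.protein, window) for p in proteome]
        # centered window matrices and their covariance, shared by all targets
        n = len(proteome)
        self._cov = np.empty((n, 20, 20))
        self._centered = []
        for i, W in enumerate(self._matrices):
            Wc = W - W.mean(axis=0)
            self._centered.append(Wc)
            self._cov[i] = Wc.T @ Wc / W.shape[0]
        self._target_stats: dict[NucleobaseTarget, tuple[np.ndarray, np.ndarray]] = {}

    def __len__(self) -> int:
        return len(self.ids)

    def window_matrix(self, i: int) -> np.ndarray:
        return self._matrices[i]

    def mrna_profile(self, i: int, target: NucleobaseTarget) -> np.ndarray:
        per_codon = sum(
            self._counts[i][:, _BASE_COL[b]] for b in target.bases
        ) / 3.0
        return _window_mean(per_codon, self.window)

    def _stats(self, target: NucleobaseTarget) -> tuple[np.ndarray, np.ndarray]:
        """(A, s): per-pair cross vectors a_p stacked (n_pairs x 20) and mRNA SDs."""
        if target not in self._target_stats:
            n = len(self.ids)
            A = np.empty((n, 20))
            s = np.empty(n)
            for i in range(n):
                m = self.mrna_profile(i, target)
                mc = m - m.mean()
                nwin = m.size
                A[i] = self._centered[i].T @ mc / nwin
                s[i] = np.sqrt(mc @ mc / nwin)
            self._target_stats[target] = (A, s)
        return self._target_stats[target]

    def mean_R(self, scale: "AffinityScale | np.ndarray", target: NucleobaseTarget) -> float:
        return self.fitness(scale, target).mean_R

    def fitness(
        self, scale: "AffinityScale | np.ndarray", target: NucleobaseTarget
    ) -> FitnessResult:
        """Per-pair and proteome-average Pearson R for one scale."""
        w = scale if isinstance(scale, np.ndarray) else scale.vector
        A, s = self._stats(target)
        num = A @ w
        var_p = np.einsum("pij,i,j->p", self._cov, w, w)
        per_pair = np.zeros(len(self.ids))
        ok = (var_p > _VAR_EPS) & (s > np.sqrt(_VAR_EPS))
        per_pair[ok] = num[ok] / (s[ok] * np.sqrt(var_p[ok]))
        return FitnessResult(
            mean_R=float(per_pair.mean()), per_pair_R=per_pair, n_pairs=len(self.ids)
        )


def proteome_mean_R(
    source: Proteome | ProfileCache,
    scale: "AffinityScale | np.ndarray",
    target: NucleobaseTarget,
    window: int = WINDOW_CODONS,
) -> FitnessResult:
    """Unweighted proteome-average Pearson R between cognate profile pairs.

    Accepts either a raw proteome (profiles computed from scratch) or a
    :class:`ProfileCache` (fast path); the two agree to ~1e-12.
    """
    if isinstance(source, ProfileCache):
        return source.fitness(scale, target)
    if len(source) == 0:
        raise ValueError("empty proteome")
    w = scale if isinstance(scale, np.ndarray) else scale.vector
    per_pair = np.array(
        [
            pair_correlation(
                mrna_density_profile(p.cds, target, window),
                protein_profile(p.protein, w, window),
            )
            for p in source
        ]
    )
    return FitnessResult(
        mean_R=float(per_pair.mean()), per_pair_R=per_pair, n_pairs=len(source)
    )
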