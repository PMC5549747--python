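"""Synthetic paired proteomes with controlled codon usage and lengths.

Generated proteins draw residues i.i.d. from a configurable amino-acid
composition; each residue's codon is drawn from a configurable within-family
codon usage, and a stop codon is appended. Every generated pair is valid by
construction (translation-consistent, length rule satisfied).

Residues being i.i.d. means profile structure comes only from sampling
noise: this is exactly the null in which any observed mRNA/protein profile
complementarity is driven by the genetic code and codon usage rather than by
sequence order, which is what makes these proteomes the right substrate for
parameter-recovery experiments on the Monte Carlo search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import MIN_PROTEIN_LENGTH, Proteome, SequencePair
from .genetic_code import AA_TO_CODONS, AMINO_ACIDS
from .scales import AffinityScale, CodonUsage

#: rough E. coli amino-acid composition (mole fractions), offered as a
#: labeled preset — the default composition is uniform
ECOLI_LIKE_AA_FREQUENCIES: dict[str, float] = {
    "A": 0.095, "C": 0.012, "D": 0.054, "E": 0.058, "F": 0.039,
    "G": 0.074, "H": 0.022, "I": 0.060, "K": 0.044, "L": 0.106,
    "M": 0.028, "N": 0.040, "P": 0.044, "Q": 0.044, "R": 0.055,
    "S": 0.058, "T": 0.054, "V": 0.071, "W": 0.015, "Y": 0.027,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic proteome.

    ``length_distribution`` is one of ``("fixed", L)``,
    ``("uniform", Lmin, Lmax)`` or ``("lognormal", mean, sigma)`` over
    protein lengths; lognormal lengths are parametrized by the distribution
    *mean* and log-space sigma, then rounded and clipped at the 22-residue
    minimum. Codon usage defaults to uniform within each synonymous family;
    amino-acid frequencies default to uniform over the 20.
    """

    n_pairs: int
    length_distribution: tuple = ("fixed", 300)
    codon_usage: CodonUsage | None = None
    amino_acid_frequencies: dict[str, float] | None = None
    seed: int = 0
    id_prefix: str = "syn"

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        kind = self.length_distribution[0]
        if kind == "fixed":
            (_, L) = self.length_distribution
            if L < MIN_PROTEIN_LENGTH:
                raise ValueError(f"fixed length {L} < {MIN_PROTEIN_LENGTH}")
        elif kind == "uniform":
            (_, lo, hi) = self.length_distribution
            if not (MIN_PROTEIN_LENGTH <= lo <= hi):
                raise ValueError("need 22 <= Lmin <= Lmax")
        elif kind == "lognormal":
            (_, mean, sigma) = self.length_distribution
            if mean < MIN_PROTEIN_LENGTH or sigma <= 0:
                raise ValueError("need mean >= 22 and sigma > 0")
        else:
            raise ValueError(f"unknown length distribution {kind!r}")
        if self.amino_acid_frequencies is not None:
            if set(self.amino_acid_frequencies) != set(AMINO_ACIDS):
                raise ValueError("amino_acid_frequencies must cover the 20 amino acids")
            total = sum(self.amino_acid_frequencies.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"amino-acid frequencies sum to {total}, not 1")


def _draw_lengths(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    kind = spec.length_distribution[0]
    if kind == "fixed":
        return np.full(spec.n_pairs, spec.length_distribution[1], dtype=np.int64)
    if kind == "uniform":
        _, lo, hi = spec.length_distribution
        return rng.integers(lo, hi + 1, size=spec.n_pairs)
    _, mean, sigma = spec.length_distribution
    mu = np.log(mean) - sigma**2 / 2.0  # log-space mean giving E[L] = mean
    lengths = np.rint(rng.lognormal(mu, sigma, size=spec.n_pairs)).astype(np.int64)
    return np.maximum(lengths, MIN_PROTEIN_LENGTH)


def generate_proteome(spec: SyntheticSpec) -> Proteome:
    """Generate a synthetic proteome; bit-reproducible for a fixed seed."""
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    usage = spec.codon_usage or CodonUsage.uniform()
    if spec.amino_acid_frequencies is None:
        aa_p = np.full(20, 1.0 / 20.0)
    else:
        aa_p = np.array([spec.amino_acid_frequencies[aa] for aa in AMINO_ACIDS])
        aa_p = aa_p / aa_p.sum()
    codon_lists = [AA_TO_CODONS[aa] for aa in AMINO_ACIDS]
    max_codons = max(len(c) for c in codon_lists)
    # per-amino-acid cumulative codon probabilities, padded to a rectangle so
    # codon indices for a whole protein come from one vectorized comparison
    cum = np.ones((20, max_codons))
    for r, codons in enumerate(codon_lists):
        cum[r, : len(codons)] = np.cumsum([usage[c] for c in codons])
        cum[r, len(codons) - 1] = 1.0  # guard against cumsum rounding
    stop_codons = ("TAA", "TAG", "TGA")
    lengths = _draw_lengths(spec, rng)
    pairs: list[SequencePair] = []
    for i, L in enumerate(lengths):
        residues = rng.choice(20, size=int(L), p=aa_p)
        u = rng.random(int(L))
        codon_idx = (u[:, None] > cum[residues]).sum(axis=1)
        codons = [codon_lists[r][j] for r, j in zip(residues, codon_idx)]
        codons.append(stop_codons[rng.integers(3)])
        pairs.append(
            SequencePair(
                id=f"{spec.id_prefix}{i:05d}",
                cds="".join(codons),
                protein="".join(AMINO_ACIDS[r] for r in residues),
            )
        )
    return Proteome(organism=f"synthetic(seed={spec.seed})", pairs=pairs)


def sample_random_scales(n: int, seed: int = 0) -> list[AffinityScale]:
    """n scales with 20 i.i.d. uniform-[0,1] weights: the shared null sampler."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.Generator(np.random.PCG64(seed))
    block = rng.random((n, 20))
    return [
        AffinityScale.from_vector(row, meta=f"random seed={seed} i={i}")
        for i, row in enumerate(block)
    ]
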