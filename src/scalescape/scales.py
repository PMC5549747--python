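"""Amino-acid affinity scales: representation, rescaling, codon-derived
reference scales, comparison and TSV/AAindex I/O.

An affinity scale assigns one real weight to each of the 20 canonical amino
acids. By the binding-free-energy convention lower weight = stronger
affinity, so a scale that "matches" an mRNA density profile produces a
*negative* proteome-average correlation. Scales are compared after linear
rescaling to the unit interval (min -> 0, max -> 1), which leaves all profile
correlations unchanged.

The genetic code itself defines a natural reference scale for every
nucleobase target: the usage-weighted average fraction of that base in each
amino acid's codons (:func:`codon_content_scale`). With the affinity
orientation (negated content) this scale is a near-optimum of the matching
problem.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .dataset import Proteome
from .genetic_code import AA_INDEX, AA_TO_CODONS, AMINO_ACIDS, CODON_TO_AA, STOP_CODONS
from .profiles import NucleobaseTarget

logger = logging.getLogger(__name__)

_WEIGHT_EPS = 1e-12


@dataclass(frozen=True)
class AffinityScale:
    """20 amino-acid weights for one nucleobase target (the MC state)."""

    weights: Mapping[str, float]
    target: str = ""
    meta: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        keys = set(self.weights)
        if keys != set(AMINO_ACIDS):
            missing = sorted(set(AMINO_ACIDS) - keys)
            extra = sorted(keys - set(AMINO_ACIDS))
            raise ValueError(f"bad amino-acid set (missing={missing}, extra={extra})")
        vec = np.array([float(self.weights[aa]) for aa in AMINO_ACIDS])
        if not np.all(np.isfinite(vec)):
            raise ValueError("non-finite weight")
        object.__setattr__(self, "weights", dict(zip(AMINO_ACIDS, vec.tolist())))
        object.__setattr__(self, "_vector", vec)

    @property
    def vector(self) -> np.ndarray:
        """Weights as a 20-vector in alphabetical amino-acid order."""
        return self._vector  # type: ignore[attr-defined]

    @classmethod
    def from_vector(
        cls, vector: Iterable[float], target: str = "", meta: str = "", degenerate: bool = False
    ) -> "AffinityScale":
        vec = list(vector)
        if len(vec) != 20:
            raise ValueError(f"expected 20 weights, got {len(vec)}")
        return cls(dict(zip(AMINO_ACIDS, map(float, vec))), target, meta, degenerate)

    @classmethod
    def uniform(cls, value: float = 0.0, target: str = "") -> "AffinityScale":
        return cls.from_vector([value] * 20, target=target, meta="uniform")

    def __getitem__(self, aa: str) -> float:
        return self.weights[aa]


def rescale_unit(scale: AffinityScale) -> AffinityScale:
    """Map weights linearly onto [0, 1] (min -> 0, max -> 1).

    Window averaging and Pearson correlation are invariant under this, so
    rescaling distinguishes genuinely different scales from linear copies.
    A degenerate all-equal scale has no shape to preserve; it maps to all 0.5
    and is flagged.
    """
    v = scale.vector
    span = v.max() - v.min()
    if span <= _WEIGHT_EPS:
        warnings.warn("rescaling a constant scale; returning all-0.5", stacklevel=2)
        return replace(
            scale,
            weights=dict(zip(AMINO_ACIDS, [0.5] * 20)),
            degenerate=True,
        )
    out = (v - v.min()) / span
    return AffinityScale.from_vector(out, target=scale.target, meta=scale.meta)


def scale_correlation(s1: AffinityScale, s2: AffinityScale) -> float:
    """Pearson R over the 20 paired weights (amino acids matched by identity).

    Returns 0 for a zero-variance (degenerate) scale, the same convention
    used for flat profiles.
    """
    from .profiles import pair_correlation

    return pair_correlation(s1.vector, s2.vector)


@dataclass(frozen=True)
class CodonUsage:
    """Relative codon frequencies within each synonymous-codon family."""

    usage: Mapping[str, float]

    def __post_init__(self) -> None:
        usage = {c: float(f) for c, f in self.usage.items()}
        if set(usage) != set(CODON_TO_AA):
            raise ValueError("usage must cover exactly the 61 sense codons")
        for aa in AMINO_ACIDS:
            total = sum(usage[c] for c in AA_TO_CODONS[aa])
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{aa} codon frequencies sum to {total}, not 1")
        object.__setattr__(self, "usage", usage)

    def __getitem__(self, codon: str) -> float:
        return self.usage[codon]

    @classmethod
    def uniform(cls) -> "CodonUsage":
        return cls(
            {
                c: 1.0 / len(AA_TO_CODONS[aa])
                for aa in AMINO_ACIDS
                for c in AA_TO_CODONS[aa]
            }
        )


def codon_usage_from(proteome: Proteome) -> CodonUsage:
    """Empirical within-family codon usage counted from a dataset's own CDS.

    Stop codons are excluded. An amino acid absent from the dataset gets
    uniform usage over its codons, with a warning.
    """
    if len(proteome) == 0:
        raise ValueError("empty proteome")
    counts = {c: 0 for c in CODON_TO_AA}
    for pair in proteome:
        cds = pair.cds
        for i in range(0, len(cds) - 3, 3):
            codon = cds[i : i + 3]
            if codon not in STOP_CODONS:
                counts[codon] += 1
    usage: dict[str, float] = {}
    for aa in AMINO_ACIDS:
        codons = AA_TO_CODONS[aa]
        total = sum(counts[c] for c in codons)
        if total == 0:
            warnings.warn(f"amino acid {aa} absent from dataset; using uniform usage")
            usage.update({c: 1.0 / len(codons) for c in codons})
        else:
            usage.update({c: counts[c] / total for c in codons})
    return CodonUsage(usage)


def codon_content_scale(
    usage: CodonUsage,
    target: NucleobaseTarget,
    orientation: str = "affinity",
) -> AffinityScale:
    """Usage-weighted target-base fraction of each amino acid's codons.

    The raw content of amino acid a is ``sum_c usage(c|a) * n_target(c) / 3``
    over its sense codons. ``orientation="content"`` returns that directly;
    ``orientation="affinity"`` (default) negates it before unit rescaling so
    that base-rich amino acids get LOW weights — the binding-affinity sign
    convention under which matching proteome correlations are negative.
    The result is unit-rescaled either way.
    """
    if orientation not in ("affinity", "content"):
        raise ValueError(f"orientation must be 'affinity' or 'content', got {orientation!r}")
    content = np.empty(20)
    for i, aa in enumerate(AMINO_ACIDS):
        content[i] = sum(
            usage[c] * sum(c.count(b) for b in target.bases) / 3.0
            for c in AA_TO_CODONS[aa]
        )
    raw = -content if orientation == "affinity" else content
    return rescale_unit(
        AffinityScale.from_vector(
            raw, target=target.name, meta=f"codon-{orientation}"
        )
    )


# --- scale file I/O ---------------------------------------------------------


def write_scale(scale: AffinityScale, path: str | Path) -> None:
    """Write a 2-column TSV ``aa<TAB>weight`` with one header comment line."""
    with open(Path(path), "w") as handle:
        handle.write(f"# target={scale.target or 'NA'} meta={scale.meta or 'NA'}\n")
        for aa in AMINO_ACIDS:
            handle.write(f"{aa}\t{scale.weights[aa]:.17g}\n")


def read_scale(path: str | Path) -> AffinityScale:
    """Read a 2-column scale TSV; exactly the 20 canonical amino acids required."""
    target = ""
    meta = ""
    weights: dict[str, float] = {}
    with open(Path(path)) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("target="):
                        target = tok[7:].replace("NA", "")
                    elif tok.startswith("meta="):
                        meta = tok[5:].replace("NA", "")
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'aa weight'")
            aa, value = fields
            if aa in weights:
                raise ValueError(f"{path}:{lineno}: duplicate entry for {aa}")
            weights[aa] = float(value)
    return AffinityScale(weights, target=target, meta=meta)


def read_aaindex(path: str | Path, accession: str | None = None) -> AffinityScale:
    """Read one index from an AAindex1-format file.

    AAindex entries start with ``H <accession>`` and carry the 20 values
    under the ``I`` line in the fixed order
    A/L R/K N/M D/F C/P Q/S E/T G/W H/Y I/V (two rows of ten).
    If ``accession`` is None the first entry is returned.
    """
    order = ["A", "R", "N", "D", "C", "Q", "E", "G", "H", "I",
             "L", "K", "M", "F", "P", "S", "T", "W", "Y", "V"]
    entries: dict[str, tuple[str, list[float]]] = {}
    acc = desc = None
    values: list[float] = []
    in_values = False
    with open(Path(path)) as handle:
        for line in handle:
            if line.startswith("H "):
                acc = line[2:].strip()
                desc = ""
                values = []
                in_values = False
            elif line.startswith("D ") and acc is not None:
                desc = line[2:].strip()
            elif line.startswith("I "):
                in_values = True
            elif line.startswith("//"):
                if acc is not None:
                    entries[acc] = (desc or "", values)
                acc = None
                in_values = False
            elif in_values:
                values.extend(float(x) if x != "NA" else np.nan for x in line.split())
    if not entries:
        raise ValueError(f"{path}: no AAindex entries found")
    if accession is None:
        accession = next(iter(entries))
    if accession not in entries:
        raise ValueError(f"{path}: accession {accession!r} not found")
    desc, values = entries[accession]
    if len(values) != 20 or any(np.isnan(values)):
        raise ValueError(f"{path}: {accession}: need 20 numeric values")
    return AffinityScale(
        dict(zip(order, values)), meta=f"{accession} {desc}".strip()
    )
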