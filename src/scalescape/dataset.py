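"""Paired CDS/protein datasets: domain types, validation, reading, writing.

A :class:`SequencePair` couples one coding sequence with its cognate protein.
Pairs are selected by the length rule ``len(cds) == 3 * len(protein) + 3``
(trailing stop codon present), restricted to canonical alphabets, and must be
long enough (protein length >= 22) for the 21-residue windowed profiles to
have at least two points. Two on-disk formats are supported:

* ``fasta-pair`` — two FASTA files (CDS and protein) with identical ID sets;
* ``s1-dialect`` — whitespace-separated text, one ``id cds protein`` record
  per line.

RNA-alphabet CDS input (U instead of T) is normalized to DNA on read so a
single internal nucleotide alphabet exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import AMINO_ACIDS, NUCLEOTIDES, TranslationError, translate_cds

logger = logging.getLogger(__name__)

MIN_PROTEIN_LENGTH = 22

_AA_SET = frozenset(AMINO_ACIDS)

DatasetFormat = Literal["fasta-pair", "s1-dialect"]


class DatasetError(ValueError):
    """Raised for unreadable, empty or structurally invalid datasets."""


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of validating one CDS/protein pair.

    ``reasons`` holds machine-readable failure codes:
    ``length-rule``, ``non-canonical-nucleotide``, ``non-canonical-amino-acid``,
    ``protein-too-short``, ``translation-mismatch``.
    """

    passed: bool
    reasons: tuple[str, ...] = ()

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def validate_pair(
    cds: str,
    protein: str,
    check_translation: bool = False,
    min_protein_length: int = MIN_PROTEIN_LENGTH,
) -> ValidationReport:
    """Check one CDS/protein pair against the selection rules.

    The translation check is off by default: record selection uses the
    length criterion only, with translation consistency available as an
    opt-in stricter filter.
    """
    reasons: list[str] = []
    cds = cds.upper().replace("U", "T")
    protein = protein.upper()
    if len(cds) != 3 * len(protein) + 3:
        reasons.append("length-rule")
    if not NUCLEOTIDES.issuperset(cds):
        reasons.append("non-canonical-nucleotide")
    if not _AA_SET.issuperset(protein):
        reasons.append("non-canonical-amino-acid")
    if len(protein) < min_protein_length:
        reasons.append("protein-too-short")
    if check_translation and not reasons:
        try:
            if translate_cds(cds) != protein:
                reasons.append("translation-mismatch")
        except TranslationError:
            reasons.append("translation-mismatch")
    return ValidationReport(passed=not reasons, reasons=tuple(reasons))


@dataclass(frozen=True)
class SequencePair:
    """One cognate CDS/protein pair; the unit the proteome fitness averages over."""

    id: str
    cds: str
    protein: str

    def __post_init__(self) -> None:
        report = validate_pair(self.cds, self.protein)
        if not report.passed:
            raise DatasetError(
                f"invalid pair {self.id!r}: {', '.join(report.reasons)}"
            )
        object.__setattr__(self, "cds", self.cds.upper().replace("U", "T"))
        object.__setattr__(self, "protein", self.protein.upper())

    @property
    def length(self) -> int:
        """Protein length L (the CDS has 3L + 3 nucleotides)."""
        return len(self.protein)


@dataclass
class Proteome:
    """An ordered collection of valid sequence pairs with unique IDs."""

    organism: str
    pairs: list[SequencePair] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.pairs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate pair IDs: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[SequencePair]:
        return iter(self.pairs)

    def __getitem__(self, key: int | str) -> SequencePair:
        if isinstance(key, str):
            for p in self.pairs:
                if p.id == key:
                    return p
            raise KeyError(key)
        return self.pairs[key]


def _filter_records(
    records: Iterable[tuple[str, str, str]],
    organism: str,
    min_protein_length: int,
    check_translation: bool,
) -> Proteome:
    pairs: list[SequencePair] = []
    n_rejected = 0
    reason_counts: dict[str, int] = {}
    for rec_id, cds, protein in records:
        report = validate_pair(
            cds, protein,
            check_translation=check_translation,
            min_protein_length=min_protein_length,
        )
        if report.passed:
            pairs.append(SequencePair(rec_id, cds, protein))
        else:
            n_rejected += 1
            for reason in report.reasons:
                reason_counts[reason] = reason_counts.get(reason, 0) + 1
            logger.debug("rejected %s: %s", rec_id, ", ".join(report.reasons))
    if n_rejected:
        logger.info(
            "%s: rejected %d records (%s)",
            organism,
            n_rejected,
            ", ".join(f"{k}={v}" for k, v in sorted(reason_counts.items())),
        )
    if not pairs:
        raise DatasetError(f"{organism}: no valid pairs after filtering")
    return Proteome(organism=organism, pairs=pairs)


def _read_s1(path: Path) -> Iterator[tuple[str, str, str]]:
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 3:
                raise DatasetError(f"{path}:{lineno}: expected 'id cds protein'")
            if len(fields) > 3:
                logger.warning(
                    "%s:%d: ignoring %d extra columns", path, lineno, len(fields) - 3
                )
            yield fields[0], fields[1], fields[2]


def _read_fasta_pair(cds_path: Path, protein_path: Path) -> Iterator[tuple[str, str, str]]:
    cds_records = {r.id: str(r.seq) for r in SeqIO.parse(str(cds_path), "fasta")}
    protein_records = {r.id: str(r.seq) for r in SeqIO.parse(str(protein_path), "fasta")}
    if set(cds_records) != set(protein_records):
        only_cds = sorted(set(cds_records) - set(protein_records))
        only_prot = sorted(set(protein_records) - set(cds_records))
        raise DatasetError(
            f"ID sets differ between {cds_path} and {protein_path} "
            f"(CDS-only: {only_cds[:3]}, protein-only: {only_prot[:3]})"
        )
    for rec_id in cds_records:
        yield rec_id, cds_records[rec_id], protein_records[rec_id]


def read_dataset(
    path: str | Path | Sequence[str | Path],
    format: DatasetFormat = "s1-dialect",
    min_protein_length: int = MIN_PROTEIN_LENGTH,
    check_translation: bool = False,
    organism: str | None = None,
) -> Proteome:
    """Read and filter a paired CDS/protein dataset.

    For ``s1-dialect``, ``path`` is a single text file. For ``fasta-pair``,
    ``path`` is a ``(cds_path, protein_path)`` pair. Records failing any
    selection rule are dropped and counted via logging; duplicate IDs are a
    hard error (silent deduplication would corrupt proteome averages).
    """
    if format == "s1-dialect":
        p = Path(path)  # type: ignore[arg-type]
        if not p.exists():
            raise DatasetError(f"no such file: {p}")
        records: Iterable[tuple[str, str, str]] = _read_s1(p)
        name = organism or p.stem
    elif format == "fasta-pair":
        if isinstance(path, (str, Path)):
            raise DatasetError("fasta-pair needs a (cds_path, protein_path) pair")
        cds_path, protein_path = (Path(x) for x in path)
        for p in (cds_path, protein_path):
            if not p.exists():
                raise DatasetError(f"no such file: {p}")
        records = _read_fasta_pair(cds_path, protein_path)
        name = organism or cds_path.stem
    else:
        raise DatasetError(f"unknown format {format!r}")
    return _filter_records(records, name, min_protein_length, check_translation)


def write_dataset(
    proteome: Proteome,
    path: str | Path | Sequence[str | Path],
    format: DatasetFormat = "s1-dialect",
) -> None:
    """Write a proteome so that re-reading reproduces it exactly."""
    if len(proteome) == 0:
        raise DatasetError("refusing to write an empty proteome")
    if format == "s1-dialect":
        with open(Path(path), "w") as handle:  # type: ignore[arg-type]
            for pair in proteome:
                handle.write(f"{pair.id} {pair.cds} {pair.protein}\n")
    elif format == "fasta-pair":
        cds_path, protein_path = (Path(x) for x in path)  # type: ignore[misc]
        SeqIO.write(
            (SeqRecord(Seq(p.cds), id=p.id, description="") for p in proteome),
            str(cds_path),
            "fasta",
        )
        SeqIO.write(
            (SeqRecord(Seq(p.protein), id=p.id, description="") for p in proteome),
            str(protein_path),
            "fasta",
        )
    else:
        raise DatasetError(f"unknown format {format!r}")
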