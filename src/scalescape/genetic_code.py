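"""Standard genetic code tables and CDS translation.

The package works on the 20 canonical amino acids (one-letter codes, kept in
alphabetical order in :data:`AMINO_ACIDS`) and DNA-alphabet coding sequences;
RNA input is normalized to DNA (U -> T) at the I/O boundary.
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

NUCLEOTIDES: frozenset[str] = frozenset("ACGT")

_table = unambiguous_dna_by_id[1]

#: codon -> amino acid, 61 sense codons of the standard genetic code
CODON_TO_AA: dict[str, str] = dict(_table.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_table.stop_codons)

#: amino acid -> tuple of its sense codons (synonymous codon family)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in AMINO_ACIDS
}

SENSE_CODONS: tuple[str, ...] = tuple(
    c for aa in AMINO_ACIDS for c in AA_TO_CODONS[aa]
)


class TranslationError(ValueError):
    """Raised when a CDS cannot be translated by the standard genetic code."""


def translate_cds(cds: str) -> str:
    """Translate a coding sequence with the standard genetic code.

    The final codon may be a stop codon; it is excluded from the returned
    protein. Internal stop codons, non-canonical nucleotides and lengths not
    divisible by 3 raise :class:`TranslationError`.
    """
    if len(cds) % 3 != 0:
        raise TranslationError(f"CDS length {len(cds)} not divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    residues = []
    for pos, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise TranslationError(f"internal stop codon {codon} at codon {pos}")
        try:
            residues.append(CODON_TO_AA[codon])
        except KeyError:
            raise TranslationError(f"non-canonical codon {codon!r} at codon {pos}") from None
    return "".join(residues)
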