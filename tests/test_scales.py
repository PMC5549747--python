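import numpy as np
import pytest

from scalescape import (
    AffinityScale,
    CodonUsage,
    NucleobaseTarget,
    SyntheticSpec,
    codon_content_scale,
    codon_usage_from,
    generate_proteome,
    read_aaindex,
    read_scale,
    rescale_unit,
    scale_correlation,
    write_scale,
)
from scalescape.genetic_code import AA_TO_CODONS, AMINO_ACIDS

PUR = NucleobaseTarget.PUR


def make_scale(**overrides):
    weights = {aa: 0.0 for aa in AMINO_ACIDS}
    weights.update(overrides)
    return AffinityScale(weights)


class TestAffinityScale:
    def test_requires_exactly_the_20_canonical(self):
        with pytest.raises(ValueError, match="missing"):
            AffinityScale({aa: 0.0 for aa in AMINO_ACIDS[:-1]})
        with pytest.raises(ValueError):
            AffinityScale({**{aa: 0.0 for aa in AMINO_ACIDS}, "X": 1.0})

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            make_scale(A=np.nan)

    def test_vector_in_alphabetical_order(self):
        scale = make_scale(A=1.0, Y=2.0)
        assert scale.vector[0] == 1.0 and scale.vector[-1] == 2.0


class TestRescaleUnit:
    def test_min_max_mapping(self):
        scale = rescale_unit(make_scale(A=2.0, C=6.0, D=4.0, **{aa: 2.0 for aa in "EFGHIKLMNPQRSTVWY"}))
        assert scale["A"] == 0.0 and scale["C"] == 1.0 and scale["D"] == 0.5

    def test_idempotent_on_unit_scale(self):
        scale = rescale_unit(make_scale(A=5.0, C=-3.0))
        again = rescale_unit(scale)
        np.testing.assert_allclose(again.vector, scale.vector, atol=1e-15)

    def test_constant_scale_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            scale = rescale_unit(AffinityScale.uniform(7.0))
        assert scale.degenerate
        np.testing.assert_allclose(scale.vector, 0.5)


class TestScaleCorrelation:
    def test_self_and_mirror(self):
        scale = rescale_unit(make_scale(A=1.0, C=2.0, D=5.0))
        mirror = AffinityScale.from_vector(1.0 - scale.vector)
        assert scale_correlation(scale, scale) == pytest.approx(1.0)
        assert scale_correlation(scale, mirror) == pytest.approx(-1.0)

    def test_degenerate_scale_gives_zero(self):
        assert scale_correlation(AffinityScale.uniform(1.0), make_scale(A=1.0)) == 0.0


class TestCodonUsage:
    def test_uniform_within_family(self):
        usage = CodonUsage.uniform()
        assert usage["ATG"] == 1.0  # Met: single codon
        assert usage["AAA"] == 0.5 and usage["AAG"] == 0.5  # Lys: two codons

    def test_frequencies_must_sum_to_one_per_family(self):
        usage = {c: 1.0 / len(AA_TO_CODONS[aa]) for aa in AMINO_ACIDS for c in AA_TO_CODONS[aa]}
        usage["AAA"] = 0.9  # breaks the Lys family
        with pytest.raises(ValueError, match="sum"):
            CodonUsage(usage)

    def test_counting_single_cds(self):
        from scalescape import Proteome, SequencePair

        proteome = Proteome("x", [SequencePair("p1", "AAA" * 22 + "TAA", "K" * 22)])
        with pytest.warns(UserWarning, match="absent"):
            usage = codon_usage_from(proteome)
        assert usage["AAA"] == 1.0 and usage["AAG"] == 0.0
        assert usage["TTT"] == 0.5  # Phe absent -> uniform fallback

    def test_mixed_codon_counting(self):
        from scalescape import Proteome, SequencePair

        cds = "AAA" * 3 + "AAG" + "AAA" * 18 + "TAA"
        with pytest.warns(UserWarning):
            usage = codon_usage_from(Proteome("x", [SequencePair("p", cds, "K" * 22)]))
        # 21 AAA + 1 AAG among the 22 Lys codons
        assert usage["AAA"] == pytest.approx(21 / 22)
        assert usage["AAG"] == pytest.approx(1 / 22)

    def test_empirical_usage_matches_independent_counter(self, small_proteome):
        from oracles import naive_codon_counts

        usage = codon_usage_from(small_proteome)
        counts = naive_codon_counts(small_proteome)
        for aa in AMINO_ACIDS:
            family_total = sum(counts.get(c, 0) for c in AA_TO_CODONS[aa])
            for codon in AA_TO_CODONS[aa]:
                assert usage[codon] == pytest.approx(counts.get(codon, 0) / family_total)


class TestCodonContentScale:
    def test_known_contents_under_uniform_usage(self):
        content = codon_content_scale(CodonUsage.uniform(), PUR, orientation="content")
        # raw contents: Lys (AAA/AAG) = 1, Glu (GAA/GAG) = 1, Phe (TTT/TTC) = 0;
        # after unit rescaling these stay at the extremes
        assert content["K"] == 1.0 and content["E"] == 1.0 and content["F"] == 0.0
        affinity = codon_content_scale(CodonUsage.uniform(), PUR, orientation="affinity")
        assert affinity["F"] == 1.0 and affinity["K"] == 0.0 and affinity["E"] == 0.0

    def test_met_content_is_two_thirds_regardless_of_usage(self):
        # ATG is Met's only codon: 2 purines of 3 bases, so its raw content
        # is 2/3 under any usage; check via the unrescaled arithmetic
        from scalescape.genetic_code import AA_TO_CODONS

        assert AA_TO_CODONS["M"] == ("ATG",)
        assert sum("ATG".count(b) for b in ("A", "G")) / 3 == pytest.approx(2 / 3)

    def test_phe_cyt_raw_content(self):
        # Phe codons TTT/TTC under uniform usage: CYT content (0 + 1/3)/2 = 1/6.
        # Check on the unrescaled arithmetic the scale builder uses.
        usage = CodonUsage.uniform()
        raw_phe = sum(usage[c] * c.count("C") / 3 for c in AA_TO_CODONS["F"])
        assert raw_phe == pytest.approx(1 / 6)
        content = codon_content_scale(usage, NucleobaseTarget.CYT, "content")
        assert 0.0 < content["F"] < 1.0

    def test_orientations_anticorrelate_exactly(self, uniform_usage):
        content = codon_content_scale(uniform_usage, PUR, "content")
        affinity = codon_content_scale(uniform_usage, PUR, "affinity")
        assert scale_correlation(content, affinity) == pytest.approx(-1.0)

    def test_affinity_scale_matches_negatively_on_synthetic_proteomes(self, uniform_usage):
        """<R> under the affinity-oriented codon scale is <= 0 on any proteome
        generated by the standard genetic code."""
        from scalescape import proteome_mean_R

        scale = codon_content_scale(uniform_usage, PUR, "affinity")
        for seed in range(20):
            proteome = generate_proteome(
                SyntheticSpec(n_pairs=3, length_distribution=("fixed", 60), seed=seed)
            )
            assert proteome_mean_R(proteome, scale, PUR).mean_R <= 0.0

    def test_usage_recovery_from_large_synthetic_proteome(self):
        """Empirical codon usage of a generated proteome recovers the
        generating usage within +/-0.02 per codon (>= 1e5 codons)."""
        rng = np.random.default_rng(123)
        usage = {}
        for aa in AMINO_ACIDS:
            codons = AA_TO_CODONS[aa]
            p = rng.dirichlet(np.ones(len(codons)) * 5.0)
            usage.update(dict(zip(codons, p)))
        truth = CodonUsage(usage)
        proteome = generate_proteome(
            SyntheticSpec(
                n_pairs=400, length_distribution=("fixed", 300),
                codon_usage=truth, seed=99,
            )
        )  # 120k codons
        estimated = codon_usage_from(proteome)
        for codon, freq in truth.usage.items():
            assert abs(estimated[codon] - freq) < 0.02


class TestScaleIO:
    def test_roundtrip_exact(self, tmp_path):
        scale = AffinityScale.from_vector(
            np.linspace(-1.23456789, 2.3456789, 20), target="PUR", meta="demo"
        )
        path = tmp_path / "s.tsv"
        write_scale(scale, path)
        back = read_scale(path)
        np.testing.assert_allclose(back.vector, scale.vector, rtol=1e-12)
        assert back.target == "PUR"

    def test_missing_amino_acid_rejected(self, tmp_path):
        path = tmp_path / "s.tsv"
        lines = [f"{aa}\t1.0" for aa in AMINO_ACIDS if aa != "W"]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="missing"):
            read_scale(path)

    def test_non_canonical_entry_rejected(self, tmp_path):
        path = tmp_path / "s.tsv"
        lines = [f"{aa}\t1.0" for aa in AMINO_ACIDS] + ["X\t0.5"]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError):
            read_scale(path)

    def test_duplicate_entry_rejected(self, tmp_path):
        path = tmp_path / "s.tsv"
        lines = [f"{aa}\t1.0" for aa in AMINO_ACIDS] + ["A\t0.5"]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_scale(path)


class TestAAindexReader:
    AAINDEX_ENTRY = (
        "H TEST010101\n"
        "D A synthetic test index (alanine-high)\n"
        "R\n"
        "A Nobody\n"
        "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V\n"
        "     1.0     0.2     0.3     0.4     0.5     0.6     0.7     0.8     0.9     1.1\n"
        "     1.2     1.3     1.4     1.5     1.6     1.7     1.8     1.9     2.0     2.1\n"
        "//\n"
    )

    def test_reads_values_in_aaindex_order(self, tmp_path):
        path = tmp_path / "idx.txt"
        path.write_text(self.AAINDEX_ENTRY)
        scale = read_aaindex(path)
        assert scale["A"] == 1.0 and scale["R"] == 0.2 and scale["V"] == 2.1
        assert scale["L"] == 1.2 and scale["K"] == 1.3
        assert "TEST010101" in scale.meta

    def test_unknown_accession_rejected(self, tmp_path):
        path = tmp_path / "idx.txt"
        path.write_text(self.AAINDEX_ENTRY)
        with pytest.raises(ValueError, match="not found"):
            read_aaindex(path, accession="NOPE")
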