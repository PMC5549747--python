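"""Compute cognate profile pairs and their proteome-average matching <R>.

For one mRNA/protein pair, prints the first few points of the purine-density
profile (63-nt windows) and the protein affinity profile (21-residue windows)
under the codon-content reference scale, then the per-pair and proteome-wide
Pearson correlations. Negative <R> means the profiles are complementary:
purine-rich mRNA stretches align with low-weight (purine-avid) protein
stretches under the binding-affinity sign convention.
"""

from scalescape import (
    CodonUsage,
    NucleobaseTarget,
    SyntheticSpec,
    codon_content_scale,
    generate_proteome,
    mrna_density_profile,
    pair_correlation,
    protein_profile,
    proteome_mean_R,
)

proteome = generate_proteome(
    SyntheticSpec(n_pairs=200, length_distribution=("lognormal", 300, 0.4), seed=2)
)
scale = codon_content_scale(CodonUsage.uniform(), NucleobaseTarget.PUR, "affinity")

pair = proteome[0]
mrna = mrna_density_profile(pair.cds, NucleobaseTarget.PUR)
prot = protein_profile(pair.protein, scale)
print(f"pair {pair.id}: {pair.length} residues -> {len(mrna)} profile points")
print("mRNA PUR density  :", " ".join(f"{x:.3f}" for x in mrna[:6]), "...")
print("protein profile   :", " ".join(f"{x:.3f}" for x in prot[:6]), "...")
print(f"per-pair Pearson R: {pair_correlation(mrna, prot):+.3f}")

result = proteome_mean_R(proteome, scale, NucleobaseTarget.PUR)
print(f"proteome-average <R> over {result.n_pairs} pairs: {result.mean_R:+.3f}")
# <R> near -0.9 on this synthetic proteome: the codon-content scale is the
# genetic-code-determined near-optimum of the matching problem.
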