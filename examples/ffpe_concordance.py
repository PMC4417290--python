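"""Per-gene concordance between frozen and FFPE aliquots.

Formalin fixation degrades RNA, so a signature measured on archival FFPE
blocks is only trustworthy if each gene's expression tracks its frozen
counterpart. This example simulates 34 paired samples with a known
degradation model (signal attenuation plus extra noise) and prints the
per-gene Pearson r between frozen and FFPE measurements next to the
analytic value the degradation model implies.
"""

from her2sig import (
    GeneratorConfig,
    concordance_by_gene,
    expected_ffpe_correlation,
    make_cohort,
    make_ffpe_pairs,
)

cfg = GeneratorConfig(seed=5, n_tumors=34, panel_size=8, n_informative=4,
                      ffpe_attenuation=0.7, ffpe_extra_sd=1.0)
frozen, _ = make_cohort(cfg)
ffpe = make_ffpe_pairs(frozen, cfg)

observed = concordance_by_gene(frozen, ffpe)
expected = expected_ffpe_correlation(cfg)

print(f"{'gene':8s} {'observed r':>10s} {'model r':>8s}   (n pairs)")
for gene, gc in observed.items():
    print(f"{gene:8s} {gc.r:10.2f} {expected[gene]:8.2f}   ({gc.n_shared})")
print("\nPositive r across genes means paraffin treatment preserved the "
      "expression ranking; r near 0 flags a gene unusable on FFPE.")
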