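"""Simulate a synthetic GG1 prostate cohort and run quality control.

Generates the default cohort (34 African cancer, 26 African non-cancer,
47 European cancer samples; 2000 genes), applies the sample and gene QC
filters, normalises to log2 expression and derives ancestry-specific PSA
groups.
"""

from gg1tx import (
    SimulationConfig,
    assign_psa_groups,
    filter_genes_prevalence,
    filter_samples,
    normalize_log2,
    simulate_cohort,
)

cfg = SimulationConfig(seed=1)
counts, metadata, truth = simulate_cohort(cfg)
print(f"cohort: {counts.shape[0]} genes x {counts.shape[1]} samples")
print(metadata.groupby(["ancestry", "cancer_status"]).size().to_string(), "\n")

# library-size rule at the standard 15M; the expressed-genes rule scaled to
# the simulated gene count (the 10,000-gene default presumes a full
# transcriptome-sized matrix)
counts, report = filter_samples(counts, min_expressed_genes=int(0.75 * cfg.n_genes))
counts, n_genes_removed = filter_genes_prevalence(counts)
print(f"QC: removed {report.n_removed} samples "
      f"({report.n_failed_library} low library, {report.n_failed_genes} few genes, "
      f"{report.n_failed_both} both) and {n_genes_removed} low-prevalence genes")

expr = normalize_log2(counts)
metadata, medians = assign_psa_groups(metadata)
print(f"PSA medians by ancestry (ng/mL): "
      f"{ {k: round(v, 2) for k, v in medians.items()} }")
print(metadata["psa_group"].value_counts().to_string())
print("\nSamples above their own ancestry's PSA median are 'high'; these "
      "groups drive the PSA-stratified analyses downstream.")
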