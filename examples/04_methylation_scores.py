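"""Healthy-control-standardized gene-set methylation scores, the IFN
membership breakdown, and the PASI-correlation-filtered score on a
treatment series."""

from methylpso import (
    SimConfig, beta_to_m, call_dmps, classify_ifn, correlation_filter_score,
    fit_score_model, generate_cohort, generate_gene_sets, generate_manifest,
    generate_treatment_series, score_samples,
)

cfg = SimConfig(n_probes=5000, n_planted_dmp=200, seed=4)
manifest = generate_manifest(cfg)
cohort = generate_cohort(cfg)
sheet, beta, truth = cohort
gene_sets = generate_gene_sets(cfg)

dmps = call_dmps(beta_to_m(beta), beta, sheet, ("HC", "PsO+PsA"),
                 manifest=manifest)
dmp_genes = {g for genes in dmps["genes"] for g in genes}
cls = classify_ifn(dmp_genes, gene_sets["IFN_I"], gene_sets["IFN_II"])
print("IFN membership of differentially methylated genes:")
print(cls.table().to_string())

model = fit_score_model(beta, sheet, dmps, gene_sets["IFN_I"], "IFN_I")
res = score_samples(model, beta, sheet)
by_group = res.total.groupby(sheet.group).mean()
print("\nmean IFN_I total score per group (HC is 0 by construction):")
print(by_group.round(2).to_string())
print("HC vs patients Mann-Whitney p:",
      f"{res.group_test('HC', 'PsO').p:.3g} (PsO)")

# treatment series: activity-linked probes recover toward the HC mean
tsheet, tbeta = generate_treatment_series(cfg, cohort)
fs = correlation_filter_score(tbeta, tsheet, dmps, gene_sets["IL17_TNF"])
print(f"\nPASI-filtered IL17/TNF score: kept {len(fs.kept_probes)} probes "
      f"with |r|>0.7")
print(f"score vs PASI: r = {fs.r_score_vs_pasi:.2f} "
      f"(p = {fs.p_score_vs_pasi:.2g})")
post = [s for s in tsheet.sample_ids if s.endswith("_post1")]
pre = [s.removesuffix("_post1") for s in post]
print(f"mean score before treatment {fs.result.total[pre].mean():.1f}, "
      f"after {fs.result.total[post].mean():.1f} (0 = healthy level)")
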