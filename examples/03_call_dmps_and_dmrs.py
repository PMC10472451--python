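"""Call differentially methylated positions and regions and check the calls
against the planted ground truth."""

from methylpso import (
    SimConfig, beta_to_m, call_dmps, call_dmrs, dmp_statistics,
    generate_cohort, generate_manifest, promoter_subset, summarize_dmps,
)

cfg = SimConfig(n_probes=20_000, n_planted_dmp=500, seed=3)
manifest = generate_manifest(cfg)
sheet, beta, truth = generate_cohort(cfg)
m = beta_to_m(beta)

dmps = call_dmps(m, beta, sheet, ("HC", "PsO+PsA"), manifest=manifest,
                 q_threshold=0.05, delta_beta_threshold=0.1)
n_hypo, n_hyper, n_total, n_genes = summarize_dmps(dmps)
print(f"DMPs (FDR<0.05, |dbeta|>0.1): {n_hypo} hypo + {n_hyper} hyper "
      f"= {n_total}, affecting {n_genes} genes")

planted = set(truth.planted_delta.index)
tp = len(set(dmps.index) & planted)
print(f"true positives: {tp}/{len(dmps)} calls "
      f"(sensitivity {tp / len(planted):.2f}, "
      f"FDP {(len(dmps) - tp) / max(1, len(dmps)):.3f})")

hypo, hyper = promoter_subset(dmps, manifest)
print(f"promoter DMPs: {len(hypo)} hypo, {len(hyper)} hyper")

stats, _ = dmp_statistics(m, beta, sheet, ("HC", "PsO+PsA"))
dmrs = call_dmrs(stats, manifest, min_cpg=5, max_gap_bp=1000)
print(f"DMRs (>=5 CpGs, gap <=1 kb): {len(dmrs)}")
# Single qualifying CpGs rarely cluster at realistic EPIC spacing, so region
# counts are far below position counts, as on real arrays.
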