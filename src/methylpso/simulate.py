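"""Synthetic EPIC-like methylation cohorts with planted effects.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage of the pipeline can be verified against a known
ground truth without external data:

* a probe manifest with region classes, QC flags and gene annotation;
* a three-group cohort (healthy controls HC, skin psoriasis PsO, psoriatic
  arthritis PsA) whose baseline per-probe methylation follows the canonical
  bimodal array β distribution (three-component Beta mixture);
* planted differentially methylated positions: a signed Δβ shift applied on
  the β scale in patient groups (hypermethylated probes start in the
  low-methylation mode, hypomethylated ones in the high mode, so the realized
  group-mean Δβ matches the configured effect);
* per-sample technical noise and slide (batch) location/scale effects on the
  variance-stabilized M scale, plus an age trend on a probe subset;
* a per-patient disease-activity latent that drives both the PASI score and
  the methylation of "score-gene" promoter CpGs, with negative sign —
  methylation falls as activity rises;
* gene-set collections (IFN_I, IFN_II, IL17_TNF) built from planted genes
  plus background genes, for score and enrichment testing;
* an optional post-treatment series in which planted and activity-coupled
  deviations shrink toward the HC mean by a configurable recovery fraction
  and PASI falls accordingly.

All randomness flows from one master seed through per-artifact
``numpy.random.SeedSequence`` streams (layout / manifest / cohort /
treatment), so regenerating one artifact never perturbs the others and a
fixed seed yields byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import (
    BETA_EPS,
    BetaMatrix,
    ConfigError,
    GeneSetCollection,
    ProbeManifest,
    PROMOTER_REGIONS,
    REGIONS,
    SampleSheet,
)

logger = logging.getLogger(__name__)

#: SD of the half-normal(+0.2) disease-activity latent
_LATENT_SD = float(np.sqrt(1.0 - 2.0 / np.pi))


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort; defaults mirror the study design
    (8 HC / 12 PsO / 8 PsA) and an EPIC-like probe universe."""

    n_probes: int = 20_000
    n_hc: int = 8
    n_pso: int = 12
    n_psa: int = 8
    n_planted_dmp: int = 500
    delta_beta_effect: float = 0.2
    frac_hyper: float = 0.5
    psa_specific_fraction: float = 0.0
    noise_sd_m: float = 0.8
    n_slides: int = 2
    slide_shift_m: float = 0.0
    slide_scale: float = 1.0
    age_effect_m: float = 0.01
    age_probe_fraction: float = 0.05
    score_gene_fraction: float = 0.25
    pasi_link_r: float = 0.8
    activity_shared_sd: float = 0.8
    n_treated: int = 8
    recovery: float = 0.9
    region_proportions: dict = field(default_factory=lambda: {
        "TSS1500": 0.13, "TSS200": 0.10, "5'UTR": 0.12,
        "Body": 0.35, "3'UTR": 0.05, "IGR": 0.25})
    snp_rate: float = 0.03
    ch_rate: float = 0.02
    xreactive_rate: float = 0.015
    detection_fail_rate: float = 0.002
    mixture_props: tuple = (0.55, 0.10, 0.35)
    mixture_shapes: tuple = ((2, 18), (10, 10), (18, 2))
    n_chromosomes: int = 22
    epsilon: float = BETA_EPS
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_probes", "n_hc", "n_pso", "n_psa", "n_slides"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_planted_dmp < 0:
            raise ConfigError("n_planted_dmp must be non-negative")
        if not 0.0 <= self.frac_hyper <= 1.0:
            raise ConfigError("frac_hyper must lie in [0, 1]")
        if abs(self.delta_beta_effect) > 0.5:
            raise ConfigError("|delta_beta_effect| must be <= 0.5")
        if self.noise_sd_m <= 0:
            raise ConfigError("noise_sd_m must be positive")
        if not 0.0 <= self.pasi_link_r < 1.0:
            raise ConfigError("pasi_link_r must lie in [0, 1)")
        if not 0.0 <= self.recovery <= 1.0:
            raise ConfigError("recovery must lie in [0, 1]")
        props = sum(self.region_proportions.values())
        if abs(props - 1.0) > 1e-9:
            raise ConfigError("region proportions must sum to 1")

    @property
    def n_patients(self) -> int:
        return self.n_pso + self.n_psa

    @property
    def n_samples(self) -> int:
        return self.n_hc + self.n_patients

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """What was planted, for downstream verification."""

    planted_delta: pd.Series            # probe_id -> signed beta shift
    planted_genes: set
    psa_specific: list
    score_sets: dict                    # set name -> gene list
    coupled_probes: list                # probes tied to the activity latent
    batch_assignments: dict             # sample -> slide
    latent_activity: pd.Series          # per patient sample

    def to_dict(self) -> dict:
        return {
            "planted_delta": self.planted_delta.to_dict(),
            "planted_genes": sorted(self.planted_genes),
            "psa_specific": list(self.psa_specific),
            "score_sets": {k: sorted(v) for k, v in self.score_sets.items()},
            "coupled_probes": list(self.coupled_probes),
            "batch_assignments": dict(self.batch_assignments),
            "latent_activity": self.latent_activity.to_dict(),
        }


@dataclass
class _Internals:
    """Per-sample draws retained so the treatment series can reuse them."""

    m0: np.ndarray                  # per-probe baseline M
    eps: np.ndarray                 # probes x samples noise (unscaled)
    shared: np.ndarray              # per-sample shared activity-block noise
    pasi_noise: pd.Series           # per patient sample
    coupling_k: float
    aging_idx: np.ndarray
    age_center: float


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("layout", "manifest", "cohort", "treatment")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _logit2(b: np.ndarray, eps: float) -> np.ndarray:
    b = np.clip(b, eps, 1.0 - eps)
    return np.log2(b / (1.0 - b))


def _sigmoid2(m: np.ndarray) -> np.ndarray:
    e = np.exp2(m)
    return e / (1.0 + e)


def _largest_remainder_counts(n: int, proportions: dict) -> dict:
    raw = {k: n * v for k, v in proportions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:short]:
        counts[k] += 1
    return counts


@dataclass
class _Layout:
    regions: np.ndarray
    planted_idx: np.ndarray
    planted_sign: np.ndarray
    psa_specific_idx: np.ndarray
    probe_gene: list                # list[list[str]] per probe
    planted_genes: set
    score_sets: dict
    coupled_idx: np.ndarray
    aging_idx: np.ndarray


def _build_layout(config: SimConfig) -> _Layout:
    """Shared structural choices (regions, planted probes, gene map, score
    sets) drawn from the layout stream so manifest and cohort agree."""
    rng = _streams(config.seed)["layout"]
    n = config.n_probes

    counts = _largest_remainder_counts(n, config.region_proportions)
    region_pool = np.concatenate([np.full(c, r) for r, c in counts.items()])
    regions = rng.permutation(region_pool)

    promoter_idx = np.flatnonzero(np.isin(regions, PROMOTER_REGIONS))
    if config.n_planted_dmp > promoter_idx.size:
        raise ConfigError("not enough promoter probes to plant DMPs")
    planted_idx = np.sort(rng.choice(promoter_idx, config.n_planted_dmp,
                                     replace=False))
    n_hyper = int(round(config.frac_hyper * config.n_planted_dmp))
    sign = np.full(config.n_planted_dmp, -1.0)
    hyper_pick = rng.choice(config.n_planted_dmp, n_hyper, replace=False)
    sign[hyper_pick] = 1.0
    n_psa_specific = int(round(config.psa_specific_fraction
                               * config.n_planted_dmp))
    psa_specific_pos = rng.choice(config.n_planted_dmp, n_psa_specific,
                                  replace=False)
    psa_specific_idx = planted_idx[np.sort(psa_specific_pos)]

    # planted genes: ~2 promoter probes per gene, hypo and hyper kept apart
    probe_gene: list[list[str]] = [[] for _ in range(n)]
    planted_genes: set[str] = set()
    gene_of_planted: dict[int, str] = {}
    counter = 0
    for s in (-1.0, 1.0):
        members = planted_idx[sign == s]
        for j in range(0, members.size, 2):
            counter += 1
            gname = f"PSGENE{counter:04d}"
            planted_genes.add(gname)
            for idx in members[j:j + 2]:
                probe_gene[idx] = [gname]
                gene_of_planted[int(idx)] = gname

    # background genes on a subset of the remaining annotated probes
    n_bg_genes = max(50, n // 40)
    bg_names = np.array([f"GENE{i:05d}" for i in range(1, n_bg_genes + 1)])
    unplanted = np.setdiff1d(np.arange(n), planted_idx)
    annotatable = unplanted[regions[unplanted] != "IGR"]
    with_gene = annotatable[rng.random(annotatable.size) < 0.7]
    for idx, g in zip(with_gene, rng.choice(bg_names, with_gene.size)):
        probe_gene[idx] = [str(g)]

    # score sets drawn from hypomethylated planted genes (+ background)
    hypo_genes = sorted({gene_of_planted[int(i)]
                         for i in planted_idx[sign == -1.0]})
    k = int(round(config.score_gene_fraction * len(hypo_genes)))
    score_sets: dict[str, list[str]] = {}
    for name in ("IFN_I", "IFN_II", "IL17_TNF"):
        chosen = list(rng.choice(hypo_genes, k, replace=False)) if k else []
        bg = list(rng.choice(bg_names, max(k, 5), replace=False))
        score_sets[name] = sorted(set(chosen) | set(bg))
    score_gene_union = set().union(*(score_sets[s] for s in score_sets))
    coupled_idx = np.array(sorted(
        int(i) for i in planted_idx
        if probe_gene[i] and probe_gene[i][0] in score_gene_union), dtype=int)

    n_aging = int(round(config.age_probe_fraction * n))
    aging_pool = np.setdiff1d(unplanted, coupled_idx)
    aging_idx = np.sort(rng.choice(aging_pool, min(n_aging, aging_pool.size),
                                   replace=False))

    return _Layout(regions=regions, planted_idx=planted_idx,
                   planted_sign=sign, psa_specific_idx=psa_specific_idx,
                   probe_gene=probe_gene, planted_genes=planted_genes,
                   score_sets=score_sets, coupled_idx=coupled_idx,
                   aging_idx=aging_idx)


def probe_ids(config: SimConfig) -> pd.Index:
    return pd.Index([f"cg{i:08d}" for i in range(1, config.n_probes + 1)],
                    name="probe_id")


def generate_manifest(config: SimConfig) -> ProbeManifest:
    """EPIC-like probe manifest consistent with the cohort's ground truth."""
    config.validate()
    layout = _build_layout(config)
    rng = _streams(config.seed)["manifest"]
    n = config.n_probes
    ids = probe_ids(config)

    block = int(np.ceil(n / config.n_chromosomes))
    chroms = np.array([f"chr{min(i // block + 1, config.n_chromosomes)}"
                       for i in range(n)])
    pos = np.empty(n, dtype=int)
    for c in pd.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        gaps = rng.integers(100, 5000, idx.size)
        pos[idx] = 10_000 + np.cumsum(gaps)

    planted_mask = np.zeros(n, dtype=bool)
    planted_mask[layout.planted_idx] = True
    flags = {}
    for name, rate in (("flag_snp", config.snp_rate),
                       ("flag_ch", config.ch_rate),
                       ("flag_xreactive", config.xreactive_rate)):
        f = rng.random(n) < rate
        f[planted_mask] = False      # planted effects must survive QC
        flags[name] = f
    cgi = rng.random(n) < 0.3

    df = pd.DataFrame({
        "chrom": chroms, "pos": pos, "genes": layout.probe_gene,
        "region": layout.regions, "cgi": cgi, **flags}, index=ids)
    return ProbeManifest(df)


def generate_gene_sets(config: SimConfig) -> GeneSetCollection:
    """IFN_I / IFN_II / IL17_TNF collections matching the cohort's planting."""
    config.validate()
    layout = _build_layout(config)
    return GeneSetCollection(layout.score_sets)


def _sample_frame(config: SimConfig, rng) -> pd.DataFrame:
    rows = []
    subject = 0
    age_params = {"HC": (29.0, 5.0), "PsO": (41.0, 10.0), "PsA": (55.0, 12.0)}
    for group, count in (("HC", config.n_hc), ("PsO", config.n_pso),
                         ("PsA", config.n_psa)):
        mu, sd = age_params[group]
        for i in range(count):
            subject += 1
            rows.append({
                "sample_id": f"{group}{i + 1:02d}",
                "subject_id": f"S{subject:03d}",
                "group": group,
                "age": float(np.round(np.clip(rng.normal(mu, sd), 18, 80), 1)),
                "sex": "M" if i % 2 == 0 else "F",
                # pair-blocked so slides are sex- and group-balanced
                "slide": f"slide{(i // 2) % config.n_slides + 1}",
                "timepoint": np.nan if group == "HC" else "naive",
            })
    return pd.DataFrame(rows).set_index("sample_id")


def _pasi_from_latent(latent: np.ndarray, noise: np.ndarray) -> np.ndarray:
    """Monotone noisy map from activity to a 0–40 PASI scale."""
    return np.round(np.clip(1.0 + 12.0 * latent + 0.5 * noise, 0.0, 40.0), 1)


def _coupling_strength(config: SimConfig) -> float:
    r = config.pasi_link_r
    if r == 0:
        return 0.0
    total_noise = np.hypot(config.activity_shared_sd, config.noise_sd_m)
    return float(total_noise * r / np.sqrt(1.0 - r ** 2) / _LATENT_SD)


def generate_cohort(config: SimConfig):
    """Generate (SampleSheet, BetaMatrix, GroundTruth) under `config`."""
    config.validate()
    layout = _build_layout(config)
    rng = _streams(config.seed)["cohort"]
    n, eps = config.n_probes, config.epsilon
    ids = probe_ids(config)

    sheet_df = _sample_frame(config, rng)
    n_samples = len(sheet_df)
    patient_mask = (sheet_df["group"] != "HC").to_numpy()
    patient_ids = sheet_df.index[patient_mask]

    latent = np.abs(rng.normal(size=patient_mask.sum())) + 0.2
    pasi_noise = rng.normal(size=patient_mask.sum())
    pasi = np.full(n_samples, np.nan)
    pasi[patient_mask] = _pasi_from_latent(latent, pasi_noise)
    sheet_df["pasi"] = pasi

    # baseline methylation: bimodal mixture, planted probes in shiftable range
    comp = rng.choice(len(config.mixture_props), n, p=config.mixture_props)
    baseline = np.empty(n)
    for c, (a, b) in enumerate(config.mixture_shapes):
        mask = comp == c
        baseline[mask] = rng.beta(a, b, mask.sum())
    hyper = layout.planted_idx[layout.planted_sign > 0]
    hypo = layout.planted_idx[layout.planted_sign < 0]
    baseline[hyper] = rng.uniform(0.10, 0.40, hyper.size)
    baseline[hypo] = rng.uniform(0.60, 0.90, hypo.size)
    if layout.coupled_idx.size:
        baseline[layout.coupled_idx] = rng.uniform(
            0.55, 0.80, layout.coupled_idx.size)
    m0 = _logit2(baseline, eps)

    eps_mat = rng.normal(0.0, config.noise_sd_m, (n, n_samples))
    shared = rng.normal(0.0, config.activity_shared_sd, n_samples)
    k_couple = _coupling_strength(config)
    age = sheet_df["age"].to_numpy(float)
    age_center = float(age.mean())

    slide_idx = np.array([int(s.removeprefix("slide")) - 1
                          for s in sheet_df["slide"]])
    shift = config.slide_shift_m * slide_idx
    scale = np.where(slide_idx > 0, config.slide_scale, 1.0)

    M = m0[:, None] + eps_mat * scale[None, :] + shift[None, :]
    if layout.aging_idx.size and config.age_effect_m:
        M[layout.aging_idx, :] += config.age_effect_m * (age - age_center)[None, :]
    if layout.coupled_idx.size and k_couple:
        M[np.ix_(layout.coupled_idx, np.arange(n_samples))] += shared[None, :]
        M[np.ix_(layout.coupled_idx, np.flatnonzero(patient_mask))] += \
            -k_couple * latent[None, :]

    beta = _sigmoid2(M)
    delta = config.delta_beta_effect * layout.planted_sign
    psa_mask = (sheet_df["group"] == "PsA").to_numpy()
    psa_specific = set(int(i) for i in layout.psa_specific_idx)
    for j, (idx, d) in enumerate(zip(layout.planted_idx, delta)):
        cols = psa_mask if int(idx) in psa_specific else patient_mask
        beta[idx, cols] += d
    n_clipped = int(((beta < eps) | (beta > 1 - eps)).sum())
    if n_clipped:
        logger.info("clipped %d beta value(s) to [%g, %g]", n_clipped, eps,
                    1 - eps)
    beta = np.clip(beta, eps, 1.0 - eps)

    fail = np.zeros((n, n_samples), dtype=bool)
    failing = np.flatnonzero(rng.random(n) < config.detection_fail_rate)
    failing = np.setdiff1d(failing, layout.planted_idx)
    for idx in failing:
        cols = rng.choice(n_samples, rng.integers(1, 4), replace=False)
        fail[idx, cols] = True

    beta_df = pd.DataFrame(beta, index=ids, columns=sheet_df.index)
    fail_df = pd.DataFrame(fail, index=ids, columns=sheet_df.index)
    truth = GroundTruth(
        planted_delta=pd.Series(delta, index=ids[layout.planted_idx]),
        planted_genes=layout.planted_genes,
        psa_specific=[str(ids[i]) for i in layout.psa_specific_idx],
        score_sets=layout.score_sets,
        coupled_probes=[str(ids[i]) for i in layout.coupled_idx],
        batch_assignments=sheet_df["slide"].to_dict(),
        latent_activity=pd.Series(latent, index=patient_ids),
    )
    truth._internals = _Internals(
        m0=m0, eps=eps_mat, shared=shared,
        pasi_noise=pd.Series(pasi_noise, index=patient_ids),
        coupling_k=k_couple, aging_idx=layout.aging_idx,
        age_center=age_center)
    truth._layout = layout
    return SampleSheet(sheet_df), BetaMatrix(beta_df, fail_df), truth


def generate_treatment_series(config: SimConfig, cohort,
                              treated: list[str] | None = None,
                              recovery: float | None = None):
    """Append post-treatment samples for a patient subset.

    Planted-DMP and activity-coupled deviations shrink toward the HC mean by
    `recovery` (default from config, 0.9), and PASI falls with the shrunken
    latent. The pre-treatment noise realization is reused for the post
    sample, so recovery=0 reproduces the pre-treatment values and recovery=1
    leaves only baseline-plus-noise.
    """
    config.validate()
    sheet, beta, truth = cohort
    recovery = config.recovery if recovery is None else recovery
    internals: _Internals = truth._internals
    layout: _Layout = truth._layout
    rng = _streams(config.seed)["treatment"]
    eps = config.epsilon

    patients = list(sheet.df.index[sheet.df["group"] != "HC"])
    if treated is None:
        if config.n_treated > len(patients):
            raise ConfigError("n_treated exceeds number of patients")
        treated = sorted(rng.choice(patients, config.n_treated, replace=False))
    else:
        unknown = [t for t in treated if t not in set(patients)]
        if unknown:
            raise ConfigError(f"treated sample(s) not in cohort: {unknown}")

    ids = beta.df.index
    n = len(ids)
    col_of = {s: j for j, s in enumerate(sheet.df.index)}
    shrink = 1.0 - recovery
    slide_idx_all = np.array([int(s.removeprefix("slide")) - 1
                              for s in sheet.df["slide"]])
    psa_specific = {str(p) for p in truth.psa_specific}

    post_cols = {}
    post_rows = []
    for sid in treated:
        j = col_of[sid]
        row = sheet.df.loc[sid]
        lat = float(truth.latent_activity[sid]) * shrink
        scale = config.slide_scale if slide_idx_all[j] > 0 else 1.0
        M = (internals.m0
             + internals.eps[:, j] * scale
             + config.slide_shift_m * slide_idx_all[j])
        if internals.aging_idx.size and config.age_effect_m:
            M[internals.aging_idx] += config.age_effect_m * (
                float(row["age"]) - internals.age_center)
        if layout.coupled_idx.size and internals.coupling_k:
            M[layout.coupled_idx] += internals.shared[j] \
                - internals.coupling_k * lat
        b = _sigmoid2(M)
        is_psa = row["group"] == "PsA"
        for pid, d in truth.planted_delta.items():
            if pid in psa_specific and not is_psa:
                continue
            b[ids.get_loc(pid)] += d * shrink
        b = np.clip(b, eps, 1.0 - eps)
        post_id = f"{sid}_post1"
        post_cols[post_id] = b
        pasi_after = _pasi_from_latent(
            np.array([lat]), np.array([internals.pasi_noise[sid]]))[0]
        post_rows.append({
            "sample_id": post_id, "subject_id": row["subject_id"],
            "group": row["group"], "age": row["age"], "sex": row["sex"],
            "slide": row["slide"], "timepoint": "post1",
            "pasi": pasi_after})

    post_sheet = pd.DataFrame(post_rows).set_index("sample_id")
    combined_sheet = pd.concat([sheet.df, post_sheet])
    post_beta = pd.DataFrame(post_cols, index=ids)
    combined_beta = pd.concat([beta.df, post_beta], axis=1)
    fail = None
    if beta.detection_fail is not None:
        post_fail = pd.DataFrame(False, index=ids, columns=post_beta.columns)
        fail = pd.concat([beta.detection_fail, post_fail], axis=1)
    return SampleSheet(combined_sheet), BetaMatrix(combined_beta, fail)
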