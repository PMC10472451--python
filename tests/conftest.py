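import numpy as np
import pandas as pd
import pytest

from methylpso import (
    BetaMatrix,
    ProbeManifest,
    SampleSheet,
    SimConfig,
    generate_cohort,
    generate_gene_sets,
    generate_manifest,
)


def make_manifest(n, chrom="chr1", start=1000, step=100, region="TSS200",
                  genes=None, **flag_overrides):
    """Hand-built manifest with evenly spaced probes."""
    ids = [f"cg{i:05d}" for i in range(n)]
    df = pd.DataFrame({
        "chrom": chrom,
        "pos": np.arange(start, start + n * step, step)[:n],
        "genes": genes if genes is not None else [[] for _ in range(n)],
        "region": region,
        "cgi": False,
        "flag_snp": False,
        "flag_ch": False,
        "flag_xreactive": False,
    }, index=pd.Index(ids, name="probe_id"))
    for col, values in flag_overrides.items():
        df[col] = values
    return ProbeManifest(df)


def make_sheet(groups, slides=None, ages=None, sexes=None, pasi=None):
    n = len(groups)
    ids = [f"S{i:02d}" for i in range(n)]
    df = pd.DataFrame({
        "subject_id": ids,
        "group": list(groups),
        "age": ages if ages is not None else np.linspace(25, 55, n).round(1),
        "sex": sexes if sexes is not None else ["M", "F"][:1] * n,
        "slide": slides if slides is not None else ["slide1"] * n,
        "pasi": pasi if pasi is not None else [np.nan] * n,
    }, index=pd.Index(ids, name="sample_id"))
    return SampleSheet(df)


def make_beta(values, probe_ids=None, sample_ids=None):
    arr = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"cg{i:05d}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"S{j:02d}" for j in range(arr.shape[1])]
    return BetaMatrix(pd.DataFrame(arr, index=probe_ids, columns=sample_ids))


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_probes=4000, n_planted_dmp=150, delta_beta_effect=0.2,
                     slide_shift_m=0.4, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    manifest = generate_manifest(small_cfg)
    sheet, beta, truth = generate_cohort(small_cfg)
    gene_sets = generate_gene_sets(small_cfg)
    return {"cfg": small_cfg, "manifest": manifest, "sheet": sheet,
            "beta": beta, "truth": truth, "gene_sets": gene_sets}
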