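"""Over-representation analysis (ORA) of gene lists against GMT collections.

The test is the one-sided hypergeometric upper tail: with a universe of N
genes, a set of K, a query of n and an overlap of k, the enrichment p-value
is P(X >= k) for X ~ Hypergeom(N, K, n) — identical to the one-sided Fisher
exact test on the 2x2 overlap table. Correction across sets is Bonferroni,
over the sets actually tested (overlap >= 1). The universe should be the
genes with at least one probe surviving preprocessing (array-design
background), not the whole genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats as sps

from .datatypes import ConfigError, GeneSetCollection


@dataclass
class EnrichmentRow:
    set_name: str
    k: int          # overlap
    n: int          # query size (within universe)
    K: int          # set size (within universe)
    N: int          # universe size
    p: float
    p_adj: float
    overlap_genes: list[str]
    significant: bool = False


def ora(query_genes, collection: GeneSetCollection, universe) -> list[EnrichmentRow]:
    """One row per gene set overlapping the query, sorted by adjusted p
    (ties broken by larger overlap, then name)."""
    if len(collection) == 0:
        raise ConfigError("empty gene-set collection")
    universe = {g.upper() for g in universe}
    if not universe:
        raise ConfigError("empty universe")
    query = {g.upper() for g in query_genes}
    if not query:
        raise ConfigError("empty query gene list")
    outside = query - universe
    if outside:
        warnings.warn(f"dropping {len(outside)} query gene(s) outside the "
                      f"universe: {sorted(outside)[:5]}")
        query &= universe
        if not query:
            raise ConfigError("no query gene inside the universe")
    N, n = len(universe), len(query)
    tested = []
    for name in collection.names:
        members = collection[name] & universe
        overlap = sorted(query & members)
        if not overlap:
            continue
        k, K = len(overlap), len(members)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        tested.append(EnrichmentRow(set_name=name, k=k, n=n, K=K, N=N,
                                    p=p, p_adj=p, overlap_genes=overlap))
    m = len(tested)
    for row in tested:
        row.p_adj = min(1.0, row.p * m)
    tested.sort(key=lambda r: (r.p_adj, -r.k, r.set_name))
    return tested


def report_top(rows: list[EnrichmentRow], top_n: int = 10,
               alpha: float = 0.05) -> pd.DataFrame:
    """Top `top_n` sets by adjusted p; rows below `alpha` flagged significant."""
    ordered = sorted(rows, key=lambda r: (r.p_adj, -r.k, r.set_name))[:top_n]
    return pd.DataFrame(
        [{"set_name": r.set_name, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
          "p": r.p, "p_adj": r.p_adj, "significant": r.p_adj < alpha,
          "overlap_genes": ";".join(r.overlap_genes)} for r in ordered]
    )
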