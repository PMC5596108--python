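"""Cross-domain (16S-18S) co-occurrence network.

For every bacterial x eukaryote OTU pair sharing enough samples, Spearman
rank correlation is computed across samples; significance comes from a
permutation null (sample labels of one table shuffled, the same permutation
applied to all OTUs so each permuted statistic is a draw from the pairwise
null), and Benjamini-Hochberg FDR controls the edge set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import RelAbundTable, ValidationError

MIN_SHARED_SAMPLES = 8


@dataclass
class EdgeList:
    edges: pd.DataFrame  # source, target, rho, p, q, sign
    method: str
    n_permutations: int
    fdr_alpha: float
    min_prevalence: float
    min_abs_rho: float
    seed: int
    n_tested: int
    shared_samples: list[str] = field(default_factory=list)
    skipped_constant: list[str] = field(default_factory=list)
    all_pairs: pd.DataFrame | None = None  # every tested pair, for diagnostics


def _rank_z(frac: pd.DataFrame, samples: list[str], min_prevalence: float):
    """Prevalence-filter OTUs, drop constant vectors, return mean-centred
    unit-norm rank rows (so Z @ Z.T gives Spearman rho with ties handled)."""
    x = frac[samples]
    prevalence = (x > 0).mean(axis=1)
    keep = x.loc[prevalence >= min_prevalence]
    const = keep.index[keep.nunique(axis=1) <= 1].tolist()
    keep = keep.drop(index=const)
    if keep.empty:
        return keep.index.tolist(), np.empty((0, len(samples))), const
    ranks = np.apply_along_axis(stats.rankdata, 1, keep.to_numpy(dtype=float))
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    ranks /= norms
    return keep.index.tolist(), ranks, const


def cooccurrence_network(
    tableA: RelAbundTable,
    tableB: RelAbundTable,
    method: str = "spearman",
    n_permutations: int = 999,
    fdr_alpha: float = 0.05,
    min_prevalence: float = 0.2,
    min_abs_rho: float = 0.0,
    seed: int = 0,
) -> EdgeList:
    """Build the cross-table co-occurrence edge list.

    Edges are retained when the BH q-value is at most ``fdr_alpha`` and
    |rho| is at least ``min_abs_rho``. Deterministic for a fixed seed.
    """
    if method != "spearman":
        raise ValueError(f"unsupported method {method!r}")
    from statsmodels.stats.multitest import multipletests

    shared = [s for s in tableA.sample_ids if s in set(tableB.sample_ids)]
    if len(shared) < MIN_SHARED_SAMPLES:
        raise ValidationError(
            f"only {len(shared)} shared samples; need >= {MIN_SHARED_SAMPLES}"
        )
    ids_a, za, const_a = _rank_z(tableA.fractions, shared, min_prevalence)
    ids_b, zb, const_b = _rank_z(tableB.fractions, shared, min_prevalence)
    skipped = const_a + const_b
    if not ids_a or not ids_b:
        empty = pd.DataFrame(columns=["source", "target", "rho", "p", "q", "sign"])
        return EdgeList(
            edges=empty, method=method, n_permutations=n_permutations,
            fdr_alpha=fdr_alpha, min_prevalence=min_prevalence,
            min_abs_rho=min_abs_rho, seed=seed, n_tested=0,
            shared_samples=shared, skipped_constant=skipped, all_pairs=empty,
        )

    rho = za @ zb.T
    rng = np.random.default_rng(seed)
    hits = np.ones_like(rho)  # +1 convention numerator
    abs_obs = np.abs(rho) - 1e-12
    n = len(shared)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        rho_p = za[:, perm] @ zb.T
        hits += np.abs(rho_p) >= abs_obs
    p = hits / (n_permutations + 1)

    pairs = pd.DataFrame(
        {
            "source": np.repeat(ids_a, len(ids_b)),
            "target": np.tile(ids_b, len(ids_a)),
            "rho": rho.ravel(),
            "p": p.ravel(),
        }
    )
    _, q, _, _ = multipletests(pairs["p"].to_numpy(), method="fdr_bh")
    pairs["q"] = q
    pairs["sign"] = np.where(pairs["rho"] >= 0, "positive", "negative")
    edges = pairs[(pairs["q"] <= fdr_alpha) & (pairs["rho"].abs() >= min_abs_rho)]
    edges = edges.sort_values(["q", "p", "source", "target"]).reset_index(drop=True)
    return EdgeList(
        edges=edges,
        method=method,
        n_permutations=n_permutations,
        fdr_alpha=fdr_alpha,
        min_prevalence=min_prevalence,
        min_abs_rho=min_abs_rho,
        seed=seed,
        n_tested=len(pairs),
        shared_samples=shared,
        skipped_constant=skipped,
        all_pairs=pairs,
    )


def write_edgelist_tsv(edge_list: EdgeList, path) -> None:
    edge_list.edges.to_csv(path, sep="\t", index=False)


def write_edgelist_graphml(edge_list: EdgeList, path) -> None:
    import networkx as nx

    g = nx.Graph(
        method=edge_list.method,
        n_permutations=edge_list.n_permutations,
        fdr_alpha=edge_list.fdr_alpha,
        seed=edge_list.seed,
    )
    for row in edge_list.edges.itertuples(index=False):
        g.add_node(row.source, domain="bacteria")
        g.add_node(row.target, domain="eukaryote")
        g.add_edge(row.source, row.target, rho=float(row.rho), p=float(row.p),
                   q=float(row.q), sign=row.sign)
    nx.write_graphml(g, path)
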