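"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately re-derive each statistic from its
definition with explicit loops, independent of the package's vectorised
implementations, so tests can compare the two routes.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from nodulebiome import SimParams, generate_community
from nodulebiome.containers import Stratum, StratumScheme


# ---------------------------------------------------------------------------
# oracles


def brute_shannon(counts) -> float:
    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * math.log(p)
    return h


def brute_chao1(counts) -> float:
    s_obs = sum(1 for c in counts if c > 0)
    f1 = sum(1 for c in counts if c == 1)
    f2 = sum(1 for c in counts if c == 2)
    return s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))


def brute_bray(x, y) -> float:
    num = 0.0
    den = 0.0
    for a, b in zip(x, y):
        num += min(a, b)
        den += a + b
    return 1.0 - 2.0 * num / den


def brute_permanova_F(d: np.ndarray, labels) -> float:
    labels = list(labels)
    n = len(labels)
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d[i, j] ** 2
    ss_total /= n
    groups = sorted(set(labels))
    ss_within = 0.0
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        s = 0.0
        for ii in range(len(idx)):
            for jj in range(ii + 1, len(idx)):
                s += d[idx[ii], idx[jj]] ** 2
        ss_within += s / len(idx)
    ss_between = ss_total - ss_within
    a = len(groups)
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def brute_permanova_exact(d: np.ndarray, labels):
    """Exhaustive relabeling: returns (F_obs, exact p)."""
    f_obs = brute_permanova_F(d, labels)
    seen = set()
    hits = 0
    total = 0
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if brute_permanova_F(d, perm) >= f_obs - 1e-12:
            hits += 1
    return f_obs, hits / total


def brute_presence(counts: pd.DataFrame, sample_strata: dict, strata: list,
                   min_count=1, min_samples=1) -> pd.DataFrame:
    out = {}
    for st in strata:
        samples = [s for s, lab in sample_strata.items() if lab == st]
        col = {}
        for otu in counts.index:
            hits = sum(1 for s in samples if counts.loc[otu, s] >= min_count)
            col[otu] = hits >= min_samples
        out[st] = pd.Series(col)
    return pd.DataFrame(out)


def brute_ols(x, y):
    """Closed-form simple OLS: slope, intercept, R^2."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxx = sum((a - mx) ** 2 for a in x)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    syy = sum((b - my) ** 2 for b in y)
    slope = sxy / sxx
    intercept = my - slope * mx
    r2 = sxy**2 / (sxx * syy)
    return slope, intercept, r2


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def tiny_scheme() -> StratumScheme:
    """Minimal three-habitat scheme: one water zone, one sediment layer, nodules."""
    return StratumScheme(
        (
            Stratum("epipelagic", "water", 0, 200),
            Stratum("sed_0_5", "sediment", 0, 5),
            Stratum("nodule", "nodule"),
        )
    )


@pytest.fixture(scope="session")
def small_params() -> SimParams:
    return SimParams(
        n_areas=2,
        samples_per_stratum_per_area=3,
        n_specialist_otus_per_stratum=8,
        n_moderate_otus=30,
        n_generalist_otus=8,
        n_contaminant_otus=4,
        n_decoy_otus=4,
        depth_mean=3000,
        depth_sd=300,
        n_euk_otus=30,
        n_planted_pairs=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_community(small_params):
    return generate_community(small_params)
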