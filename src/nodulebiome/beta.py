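"""Beta diversity and group inference: Bray-Curtis dissimilarity,
non-metric multidimensional scaling (Kruskal stress-1), one-way PERMANOVA
with permutation p-values, and two-way ANOVA with Tukey HSD.

Bray-Curtis, nMDS, and PERMANOVA are implemented from their defining
formulas; the two-way ANOVA/Tukey comparison is an ordinary linear-model
fit and goes through statsmodels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DistanceMatrix, RelAbundTable, ValidationError


# ---------------------------------------------------------------------------
# Bray-Curtis


def bray_curtis(table: RelAbundTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample profiles:
    d(x, y) = 1 - 2 sum_i min(x_i, y_i) / sum_i (x_i + y_i)."""
    x = table.fractions.to_numpy(dtype=float)
    n = x.shape[1]
    if n < 2:
        raise ValidationError("Bray-Curtis requires at least 2 samples")
    if (x.sum(axis=0) == 0).any():
        raise ValidationError("sample with all-zero profile")
    d = np.zeros((n, n))
    for i in range(n):
        xi = x[:, i]
        mins = np.minimum(xi[:, None], x[:, i + 1 :]).sum(axis=0)
        sums = (xi[:, None] + x[:, i + 1 :]).sum(axis=0)
        d[i, i + 1 :] = 1.0 - 2.0 * mins / sums
    d = d + d.T
    return DistanceMatrix(table.sample_ids, d)


# ---------------------------------------------------------------------------
# non-metric MDS


def _pava(y: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    """Weighted pool-adjacent-violators: least-squares non-decreasing fit."""
    n = len(y)
    if w is None:
        w = np.ones(n)
    level_mean = []
    level_weight = []
    level_len = []
    for i in range(n):
        m, wt, ln = y[i], w[i], 1
        while level_mean and level_mean[-1] > m:
            pm, pw, pl = level_mean.pop(), level_weight.pop(), level_len.pop()
            m = (m * wt + pm * pw) / (wt + pw)
            wt += pw
            ln += pl
        level_mean.append(m)
        level_weight.append(wt)
        level_len.append(ln)
    out = np.empty(n)
    pos = 0
    for m, ln in zip(level_mean, level_len):
        out[pos : pos + ln] = m
        pos += ln
    return out


def _disparities(d_obs: np.ndarray, d_conf: np.ndarray) -> np.ndarray:
    """Monotone-regressed disparities for Kruskal stress.

    Ties in the observed dissimilarities are handled by the primary (weak)
    approach: within a tie block the configuration distances are free to
    order themselves, achieved by breaking ties in favour of the current
    configuration before pooling.
    """
    order = np.lexsort((d_conf, d_obs))
    dhat = np.empty_like(d_conf)
    dhat[order] = _pava(d_conf[order])
    return dhat


def kruskal_stress(dist: DistanceMatrix, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against observed dissimilarities:
    sqrt( sum (dhat_ij - d_ij)^2 / sum d_ij^2 ) with d the configuration
    distances and dhat their isotonic disparities."""
    d_obs = dist.condensed()
    d_conf = _config_distances(np.asarray(coords, dtype=float))
    denom = (d_conf**2).sum()
    if denom == 0:
        return np.inf
    dhat = _disparities(d_obs, d_conf)
    return float(np.sqrt(((dhat - d_conf) ** 2).sum() / denom))


def _config_distances(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)
    diff = x[iu[0]] - x[iu[1]]
    return np.sqrt((diff**2).sum(axis=1))


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # sample x k
    stress: float
    n_restarts: int
    best_restart_seed: int
    converged: bool


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1.

    Each restart starts from a random Gaussian configuration and alternates
    isotonic regression (disparities) with a Guttman-transform update;
    iterations that fail to decrease stress end the restart, so accepted
    stress is monotone within a restart. The best configuration over all
    restarts is returned; non-convergence is reported via ``converged``,
    never raised.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    d_obs = dist.condensed()
    n = len(dist.sample_ids)
    iu = np.triu_indices(n, k=1)
    ss = np.random.SeedSequence(seed)
    restart_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_restarts)]

    best_stress = np.inf
    best_x = None
    best_seed = restart_seeds[0]
    best_converged = False
    for rseed in restart_seeds:
        rng = np.random.default_rng(rseed)
        x = rng.normal(size=(n, k))
        prev = np.inf
        converged = False
        for _ in range(max_iter):
            d_conf = _config_distances(x)
            denom = (d_conf**2).sum()
            if denom == 0:
                break
            dhat = _disparities(d_obs, d_conf)
            stress = np.sqrt(((dhat - d_conf) ** 2).sum() / denom)
            if stress > prev:  # reject uphill step, keep previous config
                x = x_prev
                stress = prev
                converged = True
                break
            if prev - stress < tol:
                prev = stress
                converged = True
                break
            prev = stress
            x_prev = x
            # Guttman transform with disparities
            ratio = np.zeros_like(d_conf)
            nz = d_conf > 0
            ratio[nz] = dhat[nz] / d_conf[nz]
            b = np.zeros((n, n))
            b[iu] = -ratio
            b = b + b.T
            np.fill_diagonal(b, -b.sum(axis=1))
            x = b @ x / n
        final = kruskal_stress(dist, x)
        if final < best_stress:
            best_stress = final
            best_x = x - x.mean(axis=0)
            best_seed = rseed
            best_converged = converged
    coords = pd.DataFrame(
        best_x, index=dist.sample_ids, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(
        coordinates=coords,
        stress=float(best_stress),
        n_restarts=n_restarts,
        best_restart_seed=best_seed,
        converged=best_converged,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    df_between: int
    df_within: int
    seed: int | None


def _permanova_F(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances and integer group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    df_b = n_groups - 1
    df_w = n - n_groups
    f = (ss_between / df_b) / (ss_within / df_w)
    r2 = ss_between / ss_total
    return f, r2


def permanova(
    dist: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
    exact: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA (Anderson's pseudo-F) on a distance matrix.

    SS_total = (1/N) sum_{i<j} d_ij^2, SS_within = sum_g (1/n_g)
    sum_{i<j in g} d_ij^2, pseudo-F = (SS_between/(a-1)) / (SS_within/(N-a)).
    The p-value permutes group labels with the +1 convention; with
    ``exact=True`` every distinct relabeling is enumerated instead (small N
    only) and p is the exact tail fraction including the identity.
    """
    labels = np.asarray(pd.Index(groups))
    n = len(dist.sample_ids)
    if len(labels) != n:
        raise ValidationError("groups length must match distance matrix")
    if n < 3:
        raise ValidationError("PERMANOVA needs at least 3 samples")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    if a == n:
        raise ValidationError("every sample in its own group leaves no residual")
    if n_permutations < 1 and not exact:
        raise ValueError("n_permutations must be >= 1")
    d2 = dist.values**2
    f_obs, r2 = _permanova_F(d2, codes, a)

    if exact:
        seen = set()
        hits = 0
        total = 0
        for perm in itertools.permutations(codes):
            if perm in seen:
                continue
            seen.add(perm)
            total += 1
            f_p, _ = _permanova_F(d2, np.asarray(perm), a)
            if f_p >= f_obs - 1e-12:
                hits += 1
        p = hits / total
        n_perm_rec = total
        used_seed = None
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            f_p, _ = _permanova_F(d2, rng.permutation(codes), a)
            if f_p >= f_obs - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
        n_perm_rec = n_permutations
        used_seed = int(seed)

    return PermanovaResult(
        pseudo_F=float(f_obs),
        R2=float(r2),
        p_value=float(p),
        n_permutations=int(n_perm_rec),
        df_between=a - 1,
        df_within=n - a,
        seed=used_seed,
    )


# ---------------------------------------------------------------------------
# two-way ANOVA + Tukey


@dataclass
class AnovaTukeyResult:
    anova_table: pd.DataFrame  # rows: factor_a, factor_b, interaction, residual
    residual_df: int
    tukey_table: pd.DataFrame  # pairwise comparisons on factor_a


def anova_tukey(values, factor_a, factor_b, interaction: bool = True) -> AnovaTukeyResult:
    """Two-way fixed-effects ANOVA (Type II sums of squares, suited to
    unbalanced designs) with Tukey HSD on the first factor's marginal means.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.DataFrame(
        {"y": np.asarray(values, dtype=float), "a": np.asarray(factor_a), "b": np.asarray(factor_b)}
    )
    for col in ("a", "b"):
        if df[col].nunique() < 2:
            raise ValidationError(f"factor {col!r} has a single level")
    formula = "y ~ C(a) + C(b)" + (" + C(a):C(b)" if interaction else "")
    fit = smf.ols(formula, data=df).fit()
    if fit.df_resid <= 0:
        raise ValidationError("zero residual degrees of freedom")
    table = sm.stats.anova_lm(fit, typ=2)
    tukey = pairwise_tukeyhsd(df["y"], df["a"])
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return AnovaTukeyResult(
        anova_table=table,
        residual_df=int(fit.df_resid),
        tukey_table=tukey_df,
    )
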