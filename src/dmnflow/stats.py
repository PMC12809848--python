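"""Group-level and symptom-association statistics.

Covers the summary-statistic demographics tests (pooled two-sample t,
one-way ANOVA from group summaries, Pearson chi-square), the covariate-
adjusted group comparison (ANCOVA partial F with Tukey-HSD or Fisher-LSD
post hoc tests on adjusted means), the eta-squared -> Cohen's d effect-size
convention, voxel-wise inference by TFCE with Freedman-Lane permutation
FWE correction, and covariate-adjusted multiple regression of symptoms on
a network metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

__all__ = [
    "StatResult",
    "VoxelStatMap",
    "t_from_summary",
    "anova_from_summary",
    "chi_square_counts",
    "AncovaResult",
    "ancova_f",
    "posthoc_pairwise",
    "cohens_d_from_f",
    "tfce_enhance",
    "permutation_fwe",
    "regress_symptoms",
]


@dataclass
class StatResult:
    test: str
    statistic: float
    df: tuple
    p_value: float
    effect_size: float | None = None
    notes: str = ""


# ---------------------------------------------------------------------------
# summary-statistic tests (demographics tables)


def t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> StatResult:
    """Student pooled-variance two-sample t from group summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return StatResult("two-sample t", float(t), (n1 + n2 - 2,), float(p))


def anova_from_summary(groups: list[tuple[float, float, int]]) -> StatResult:
    """One-way ANOVA F reconstructed from (mean, sd, n) per group."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    means = np.array([g[0] for g in groups], dtype=float)
    sds = np.array([g[1] for g in groups], dtype=float)
    ns = np.array([g[2] for g in groups], dtype=float)
    if (ns < 2).any() or (sds <= 0).any():
        raise ValueError("each group needs n >= 2 and sd > 0")
    N, k = ns.sum(), len(groups)
    grand = (ns * means).sum() / N
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds**2).sum()
    df1, df2 = k - 1, N - k
    F = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(F, df1, df2))
    return StatResult("one-way ANOVA", float(F), (int(df1), int(df2)), p)


def chi_square_counts(table: np.ndarray) -> StatResult:
    """Pearson chi-square on a contingency table (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    res = sps.chi2_contingency(table, correction=False)
    return StatResult("chi-square", float(res.statistic), (int(res.dof),), float(res.pvalue))


# ---------------------------------------------------------------------------
# ANCOVA with covariates


@dataclass
class AncovaResult:
    result: StatResult
    adjusted_means: dict[str, float]
    groups: list[str]
    # fitted-model internals reused by the post hoc tests
    params: np.ndarray = field(repr=False, default=None)
    cov_params: np.ndarray = field(repr=False, default=None)
    mse: float = 0.0
    df_resid: int = 0
    contrasts: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


def _group_design(group: np.ndarray, covariates: np.ndarray | None):
    """Intercept + dummy-coded groups (first level = reference) + covariates."""
    levels = list(pd.unique(group))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    n = len(group)
    dummies = np.zeros((n, len(levels) - 1))
    for j, lev in enumerate(levels[1:]):
        dummies[:, j] = group == lev
    cols = [np.ones(n), *dummies.T]
    if covariates is not None and covariates.size:
        cols.extend(np.asarray(covariates, dtype=float).T)
    X = np.column_stack(cols)
    return X, levels


def ancova_f(
    response: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
) -> AncovaResult:
    """Partial F test for the group factor adjusting for covariates.

    Fits the full linear model (intercept + group dummies + covariates) and
    the reduced model (intercept + covariates); F = partial F for group with
    df1 = k - 1 and df2 = N - k - c. Also returns covariate-adjusted group
    means (predictions at the covariate grand means).
    """
    y = np.asarray(response, dtype=float)
    group = np.asarray(group)
    n = y.size
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
    X_full, levels = _group_design(group, covariates)
    k = len(levels)
    if covariates is not None:
        c = covariates.shape[1]
        X_red = np.column_stack([np.ones(n), covariates])
    else:
        c = 0
        X_red = np.ones((n, 1))
    if n <= k + c + 1:
        raise ValueError("not enough subjects for the model")
    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        raise ValueError("collinear design: group dummies/covariates are rank deficient")

    XtX = X_full.T @ X_full
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ X_full.T @ y
    resid_full = y - X_full @ beta
    rss_full = resid_full @ resid_full

    beta_r, *_ = np.linalg.lstsq(X_red, y, rcond=None)
    resid_red = y - X_red @ beta_r
    rss_red = resid_red @ resid_red

    df1 = k - 1
    df2 = n - k - c
    mse = rss_full / df2
    F = ((rss_red - rss_full) / df1) / mse
    p = float(sps.f.sf(F, df1, df2))

    # adjusted means: prediction at covariate grand means per group
    cov_means = covariates.mean(axis=0) if c else np.empty(0)
    contrasts: dict[str, np.ndarray] = {}
    adj = {}
    for i, lev in enumerate(levels):
        L = np.zeros(X_full.shape[1])
        L[0] = 1.0
        if i > 0:
            L[i] = 1.0
        L[k:] = cov_means
        contrasts[str(lev)] = L
        adj[str(lev)] = float(L @ beta)

    res = StatResult("ANCOVA partial F", float(F), (df1, int(df2)), p)
    return AncovaResult(
        result=res,
        adjusted_means=adj,
        groups=[str(l) for l in levels],
        params=beta,
        cov_params=XtX_inv * mse,
        mse=float(mse),
        df_resid=int(df2),
        contrasts=contrasts,
    )


def posthoc_pairwise(fit: AncovaResult, method: str = "tukey") -> pd.DataFrame:
    """Pairwise comparisons of covariate-adjusted group means.

    ``tukey``: p from the studentized range distribution with k groups and the
    model's residual df (Tukey HSD on adjusted means). ``lsd``: unadjusted
    two-sided t (Fisher LSD). Returns one row per pair.
    """
    if method not in ("tukey", "lsd"):
        raise ValueError("method must be 'tukey' or 'lsd'")
    k = len(fit.groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = fit.groups[i], fit.groups[j]
            L = fit.contrasts[gi] - fit.contrasts[gj]
            diff = float(L @ fit.params)
            se = float(np.sqrt(L @ fit.cov_params @ L))
            t = diff / se
            if method == "tukey":
                q = abs(t) * np.sqrt(2.0)
                p = float(sps.studentized_range.sf(q, k, fit.df_resid))
            else:
                p = float(2.0 * sps.t.sf(abs(t), fit.df_resid))
            rows.append(
                {"group1": gi, "group2": gj, "diff": diff, "se": se,
                 "t": t, "p_adj": min(p, 1.0), "method": method}
            )
    return pd.DataFrame(rows)


def cohens_d_from_f(F: float, df1: float, df2: float) -> float:
    """Effect size d via partial eta squared:

    eta_p^2 = F df1 / (F df1 + df2);  d = 2 sqrt(eta_p^2 / (1 - eta_p^2)).
    """
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise ValueError("require F >= 0 and positive dfs")
    eta2 = F * df1 / (F * df1 + df2)
    return float(2.0 * np.sqrt(eta2 / (1.0 - eta2)))


# ---------------------------------------------------------------------------
# TFCE and permutation inference


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def tfce_enhance(
    stat_map: np.ndarray,
    mask: np.ndarray,
    H: float = 2.0,
    E: float = 0.5,
    dh: float | None = None,
    n_steps: int = 100,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a 3D statistic map.

        TFCE(v) = sum_{h = dh, 2dh, ...} e(h, v)^E * h^H * dh

    where e(h, v) is the voxel count of the 26-connected suprathreshold
    (>= h) component containing v. ``dh`` defaults to max/n_steps. Only
    positive values are enhanced.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if H <= 0 or E <= 0:
        raise ValueError("H and E must be > 0")
    sm = np.where(mask, stat_map, 0.0)
    vmax = float(sm.max())
    out = np.zeros_like(sm, dtype=float)
    if vmax <= 0:
        return out
    if dh is None:
        dh = vmax / n_steps
    if dh <= 0:
        raise ValueError("dh must be > 0")
    h = dh
    while h <= vmax + 1e-12:
        bw = sm >= h
        labels, n = ndimage.label(bw, structure=_STRUCT26)
        if n == 0:
            break
        sizes = np.bincount(labels.reshape(-1))
        contrib = (sizes[labels[bw]] ** E) * (h**H) * dh
        out[bw] += contrib
        h += dh
    return out


@dataclass
class VoxelStatMap:
    stat: np.ndarray  # 3D F map
    tfce: np.ndarray  # 3D enhanced map
    p_fwe: np.ndarray  # 3D corrected p (1 outside mask)
    cluster_labels: np.ndarray  # 3D int labels of surviving clusters
    cluster_sizes: dict[int, int]
    null_max: np.ndarray  # permutation distribution of max TFCE


def _partial_f_maps(Y: np.ndarray, X_full: np.ndarray, X_red: np.ndarray,
                    df1: int, df2: int) -> np.ndarray:
    """Vectorized partial F across voxels. Y is (N, V)."""
    R_full = np.eye(len(Y)) - X_full @ np.linalg.pinv(X_full)
    R_red = np.eye(len(Y)) - X_red @ np.linalg.pinv(X_red)
    rss_full = np.einsum("ij,ij->j", R_full @ Y, R_full @ Y)
    rss_red = np.einsum("ij,ij->j", R_red @ Y, R_red @ Y)
    rss_full = np.maximum(rss_full, 1e-300)
    return ((rss_red - rss_full) / df1) / (rss_full / df2)


def permutation_fwe(
    voxel_responses: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None,
    mask: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    min_cluster: int = 10,
    alpha: float = 0.05,
    tfce_kwargs: dict | None = None,
) -> VoxelStatMap:
    """Voxel-wise group inference: partial-F maps, TFCE, permutation FWE.

    Permutation follows Freedman-Lane: the covariate-only model is fitted,
    its residuals permuted and added back to the covariate fit, and the
    group partial F recomputed on each permuted dataset. The null
    distribution is the maximum TFCE value per permutation; corrected
    p(v) = (1 + #{max_null >= TFCE_obs(v)}) / (n_perm + 1). Voxels with
    p < alpha are reported only within connected clusters of at least
    ``min_cluster`` voxels.

    ``voxel_responses`` is (N_subjects, V_mask) with columns in mask order.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if n_perm < 1.0 / alpha * 2:
        warnings.warn("few permutations for the requested alpha", stacklevel=2)
    mask = np.asarray(mask, dtype=bool)
    Y = np.asarray(voxel_responses, dtype=float)
    N, V = Y.shape
    if V != int(mask.sum()):
        raise ValueError("voxel_responses columns must match mask voxel count")
    tfce_kwargs = dict(tfce_kwargs or {})

    X_full, levels = _group_design(np.asarray(group), covariates)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        X_red = np.column_stack([np.ones(N), covariates])
    else:
        X_red = np.ones((N, 1))
    k = len(levels)
    c = X_red.shape[1] - 1
    df1, df2 = k - 1, N - k - c

    def unflatten(v):
        out = np.zeros(mask.shape)
        out[mask] = v
        return out

    f_obs = _partial_f_maps(Y, X_full, X_red, df1, df2)
    stat3d = unflatten(f_obs)
    obs_enh = tfce_enhance(stat3d, mask, **tfce_kwargs)

    # Freedman-Lane: permute reduced-model residuals
    P_red = X_red @ np.linalg.pinv(X_red)
    fitted_red = P_red @ Y
    resid_red = Y - fitted_red
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(N)
        Yb = fitted_red + resid_red[perm]
        fb = _partial_f_maps(Yb, X_full, X_red, df1, df2)
        enh = tfce_enhance(unflatten(fb), mask, **tfce_kwargs)
        null_max[b] = enh[mask].max()

    obs_vals = obs_enh[mask]
    exceed = (null_max[None, :] >= obs_vals[:, None]).sum(axis=1)
    p_vals = (1.0 + exceed) / (n_perm + 1.0)
    p3d = np.ones(mask.shape)
    p3d[mask] = p_vals

    sig = (p3d < alpha) & mask
    labels, n_lab = ndimage.label(sig, structure=_STRUCT26)
    sizes = {}
    for lab in range(1, n_lab + 1):
        size = int((labels == lab).sum())
        if size < min_cluster:
            labels[labels == lab] = 0
        else:
            sizes[lab] = size
    return VoxelStatMap(
        stat=stat3d, tfce=obs_enh, p_fwe=p3d,
        cluster_labels=labels, cluster_sizes=sizes, null_max=null_max,
    )


# ---------------------------------------------------------------------------
# symptom regression


def regress_symptoms(
    symptom: np.ndarray,
    predictor: np.ndarray,
    covariates: np.ndarray | None = None,
) -> StatResult:
    """OLS of a symptom score on a network metric plus covariates.

    Returns the predictor's coefficient B as the statistic, with its SE, t,
    two-sided p, and 95% CI in the notes fields.
    """
    import statsmodels.api as sm

    y = np.asarray(symptom, dtype=float)
    x = np.asarray(predictor, dtype=float).reshape(-1, 1)
    cols = [x]
    if covariates is not None and np.size(covariates):
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cols.append(cov)
    X = sm.add_constant(np.hstack(cols))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design in symptom regression")
    if len(y) <= X.shape[1] + 1:
        raise ValueError("not enough subjects for the regression")
    fit = sm.OLS(y, X).fit()
    B = float(fit.params[1])
    se = float(fit.bse[1])
    t = float(fit.tvalues[1])
    p = float(fit.pvalues[1])
    lo, hi = fit.conf_int()[1]
    res = StatResult(
        "multiple regression", B, (int(fit.df_resid),), p,
        notes=f"se={se:.6g}; t={t:.6g}; ci95=({lo:.6g}, {hi:.6g})",
    )
    res.ci95 = (float(lo), float(hi))  # type: ignore[attr-defined]
    res.se = se  # type: ignore[attr-defined]
    return res
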