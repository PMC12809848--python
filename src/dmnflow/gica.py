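"""Group spatial ICA: order selection, reduction, unmixing, stability, dual regression.

The decomposition follows the temporal-concatenation group-ICA scheme: each
subject's (time x voxel) matrix is PCA-reduced in the temporal dimension,
subjects are stacked along time, and extended Infomax ICA unmixes the stack
into spatial components. Model order is chosen by the Wax-Kailath minimum
description length criterion on the covariance eigenvalues. Stability is
assessed ICASSO-style: repeated runs are pooled, clustered by absolute
spatial correlation, and each cluster's quality index Iq is the mean
intra-cluster minus mean extra-cluster similarity. Subject-specific time
courses, maps, and scalar loading coefficients come from spatial-temporal
(dual) regression against the group maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import skew

__all__ = [
    "ComponentSet",
    "SubjectComponent",
    "TemplateMatch",
    "PCAReduction",
    "estimate_order_mdl",
    "pca_reduce",
    "concat_group",
    "infomax_unmix",
    "icasso_aggregate",
    "back_reconstruct",
    "match_template",
    "zscore_map",
]


@dataclass
class ComponentSet:
    """Group-level decomposition result."""

    spatial_maps: np.ndarray  # (n_components, V) z-scored over the mask
    group_timecourses: np.ndarray  # (concat_time, n_components)
    stability_iq: np.ndarray  # (n_components,)
    order: int
    run_count: int


@dataclass
class SubjectComponent:
    """One subject x one component from back-reconstruction."""

    map: np.ndarray  # (V,)
    timecourse: np.ndarray  # (T,)
    loading: float


@dataclass
class TemplateMatch:
    component_index: int
    spatial_correlation: float


@dataclass
class PCAReduction:
    reduced: np.ndarray  # (target_dim, V)
    basis: np.ndarray  # (original_dim, target_dim)
    row_means: np.ndarray  # (original_dim,)
    explained_variance_ratio: float

    def back_project(self) -> np.ndarray:
        return self.basis @ self.reduced + self.row_means[:, None]


# ---------------------------------------------------------------------------
# order selection


def estimate_order_mdl(data: np.ndarray) -> int:
    """Wax-Kailath MDL order on the temporal covariance eigenvalues.

    ``data`` is (time, voxel): the p = time dimensions are the observed
    channels, the N = voxel columns the samples. Returns the k minimizing

        MDL(k) = -N (p-k) ln( GM(l_{k+1..p}) / AM(l_{k+1..p}) )
                 + 0.5 k (2p - k) ln N.
    """
    data = np.asarray(data, dtype=float)
    p, N = data.shape
    xc = data - data.mean(axis=1, keepdims=True)
    cov = xc @ xc.T / N
    lam = np.linalg.eigvalsh(cov)[::-1]
    lam = np.clip(lam, 1e-12, None)
    if lam[0] / lam[-1] > 1e12:
        raise ValueError("degenerate covariance: eigenvalue spread too large for MDL")
    mdl = np.empty(p)
    for k in range(p):
        tail = lam[k:]
        m = tail.size
        gm = np.exp(np.mean(np.log(tail)))
        am = np.mean(tail)
        mdl[k] = -N * m * np.log(gm / am) + 0.5 * k * (2 * p - k) * np.log(N)
    return int(np.argmin(mdl))


# ---------------------------------------------------------------------------
# reduction and concatenation


def pca_reduce(data: np.ndarray, target_dim: int) -> PCAReduction:
    """Reduce the temporal dimension of a (time, voxel) matrix by PCA.

    Rows are centered over voxels; the retained subspace and the row means are
    stored so the reduction is invertible on that subspace.
    """
    data = np.asarray(data, dtype=float)
    p, N = data.shape
    if not 1 <= target_dim <= min(p, N):
        raise ValueError(f"target_dim must be in [1, {min(p, N)}]")
    means = data.mean(axis=1)
    xc = data - means[:, None]
    cov = xc @ xc.T / N
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    basis = vec[:, :target_dim]
    reduced = basis.T @ xc
    total = lam.sum()
    evr = float(lam[:target_dim].sum() / total) if total > 0 else 1.0
    return PCAReduction(reduced=reduced, basis=basis, row_means=means,
                        explained_variance_ratio=evr)


def concat_group(
    reduced_list: list[np.ndarray], subject_ids: list[str] | None = None
) -> tuple[np.ndarray, list[tuple[int, int, str]]]:
    """Stack per-subject reduced matrices along the (reduced) time axis.

    Returns the group matrix and a boundary table of (start, stop, subject_id)
    row slices for back-reconstruction bookkeeping.
    """
    if not reduced_list:
        raise ValueError("no subjects to concatenate")
    V = reduced_list[0].shape[1]
    if any(r.shape[1] != V for r in reduced_list):
        raise ValueError("voxel dimension differs across subjects")
    if subject_ids is None:
        subject_ids = [f"sub-{i:03d}" for i in range(len(reduced_list))]
    boundaries = []
    start = 0
    for r, sid in zip(reduced_list, subject_ids):
        boundaries.append((start, start + r.shape[0], sid))
        start += r.shape[0]
    return np.vstack(reduced_list), boundaries


# ---------------------------------------------------------------------------
# extended Infomax


@dataclass
class InfomaxResult:
    sources: np.ndarray  # (n_components, V)
    unmixing: np.ndarray  # (n_components, m) including whitening
    mixing: np.ndarray  # (m, n_components)
    converged: bool
    n_iter: int


def _whiten(x: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = x.mean(axis=1, keepdims=True)
    xc = x - means
    cov = xc @ xc.T / x.shape[1]
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1][:n_components]
    lam, vec = np.clip(lam[order], 1e-12, None), vec[:, order]
    K = (vec / np.sqrt(lam)).T  # (n_comp, m)
    return K @ xc, K, means[:, 0]


def infomax_unmix(
    data: np.ndarray,
    n_components: int,
    seed: int | np.random.Generator = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    lrate: float = 0.2,
) -> InfomaxResult:
    """Extended Infomax ICA (natural gradient, sub/super-Gaussian switching).

    ``data`` is (m, V) with V voxel samples; returns spatial sources. The
    update is the full-batch natural-gradient rule

        W <- W + lr * ( I - K tanh(u) u^T / V - u u^T / V ) W

    with K = diag(+1 super-Gaussian, -1 sub-Gaussian) re-estimated each
    iteration from the sign of E[sech^2 u] E[u^2] - E[u tanh u]. The learning
    rate is annealed when an update diverges; convergence is declared when
    the weight change's Frobenius norm drops below ``tol``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = np.asarray(data, dtype=float)
    m, V = data.shape
    if n_components > m:
        raise ValueError("n_components exceeds data dimension")
    xw, K_white, _ = _whiten(data, n_components)

    n = n_components
    # random orthonormal start
    A0 = rng.standard_normal((n, n))
    W, _ = np.linalg.qr(A0)
    eye = np.eye(n)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        u = W @ xw
        tu = np.tanh(u)
        # sub/super-Gaussian switching signs
        sign = np.sign(
            np.mean(1.0 - tu**2, axis=1) * np.mean(u**2, axis=1)
            - np.mean(tu * u, axis=1)
        )
        sign[sign == 0] = 1.0
        grad = eye - (sign[:, None] * tu) @ u.T / V - u @ u.T / V
        dW = lrate * grad @ W
        if not np.isfinite(dW).all() or np.linalg.norm(dW) > 1e3:
            lrate *= 0.5
            if lrate < 1e-12:
                break
            continue
        W = W + dW
        if np.linalg.norm(dW) < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"Infomax did not reach tol={tol:g} in {it} iterations; "
            "returning best iterate",
            stacklevel=2,
        )
    sources = W @ xw
    unmixing = W @ K_white
    mixing = np.linalg.pinv(unmixing)
    return InfomaxResult(sources=sources, unmixing=unmixing, mixing=mixing,
                         converged=converged, n_iter=it)


# ---------------------------------------------------------------------------
# ICASSO stability


def icasso_aggregate(
    data: np.ndarray,
    n_components: int,
    n_runs: int = 20,
    seed: int = 0,
    bootstrap: bool = False,
    max_iter: int = 2000,
) -> ComponentSet:
    """Repeated-run ICA with ICASSO-style clustering and stability index.

    Each run restarts Infomax from a fresh random state (and optionally
    bootstraps voxels). All run x component estimates are pooled, their
    pairwise similarity |Pearson r| computed, and average-linkage clustering
    cuts the pool into ``n_components`` clusters. The returned map per
    cluster is the centrotype (the member most similar to its cluster), and

        Iq = mean intra-cluster similarity - mean extra-cluster similarity.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    data = np.asarray(data, dtype=float)
    m, V = data.shape
    rng = np.random.default_rng(seed)

    estimates = []
    for _ in range(n_runs):
        run_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        x = data
        if bootstrap:
            cols = run_rng.integers(0, V, size=V)
            x = data[:, cols]
        res = infomax_unmix(x, n_components, seed=run_rng, max_iter=max_iter)
        if bootstrap:
            # re-express sources on the original voxels
            src = res.unmixing @ (data - data.mean(axis=1, keepdims=True))
        else:
            src = res.sources
        estimates.append(src)
    pool = np.vstack(estimates)  # (n_runs * n_components, V)

    sim = np.abs(np.corrcoef(pool))
    np.fill_diagonal(sim, 1.0)
    dist = squareform(1.0 - sim, checks=False)
    Z = linkage(dist, method="average")
    labels = fcluster(Z, t=n_components, criterion="maxclust")
    if len(np.unique(labels)) < n_components:
        raise ValueError("could not form the requested number of clusters")

    maps, iqs, tc_cols = [], [], []
    for c in range(1, n_components + 1):
        members = np.flatnonzero(labels == c)
        others = np.flatnonzero(labels != c)
        sub = sim[np.ix_(members, members)]
        if members.size > 1:
            intra = (sub.sum() - members.size) / (members.size * (members.size - 1))
        else:
            intra = 1.0
        extra = sim[np.ix_(members, others)].mean() if others.size else 0.0
        iqs.append(intra - extra)
        # centrotype: member with maximal total similarity to its cluster
        centro = members[np.argmax(sub.sum(axis=1))]
        cmap = pool[centro].copy()
        if skew(cmap) < 0:
            cmap = -cmap
        maps.append(cmap)

    maps = np.array(maps)
    maps_z = np.array([zscore_map(mp) for mp in maps])
    # group time courses by least squares against the aggregate maps
    xc = data - data.mean(axis=1, keepdims=True)
    tcs, *_ = np.linalg.lstsq(maps_z.T, xc.T, rcond=None)
    order = np.argsort(iqs)[::-1]
    return ComponentSet(
        spatial_maps=maps_z[order],
        group_timecourses=tcs.T[:, order],
        stability_iq=np.asarray(iqs)[order],
        order=n_components,
        run_count=n_runs,
    )


# ---------------------------------------------------------------------------
# back-reconstruction (dual regression)


def back_reconstruct(
    data: np.ndarray, group_maps: np.ndarray, ridge_cond: float = 1e8
) -> list[SubjectComponent]:
    """Dual regression of one subject against the group spatial maps.

    Stage 1: each volume's voxel vector is regressed jointly on all group maps
    (plus intercept), giving component time courses; the scalar loading is the
    root-mean-square of a component's time course (the RMS amplitude of its
    fitted contribution). Stage 2: each voxel's time series is regressed on
    the time courses, giving the subject-specific maps.

    ``data`` is (V, T) masked voxel time series; ``group_maps`` is (K, V).
    """
    data = np.asarray(data, dtype=float)
    group_maps = np.asarray(group_maps, dtype=float)
    if data.shape[0] != group_maps.shape[1]:
        raise ValueError("subject voxels not aligned with group maps")
    # voxel-wise temporal demeaning: guarantees zero-mean component time
    # courses, so the loading is not inflated by DC offsets
    data = data - data.mean(axis=1, keepdims=True)
    V, T = data.shape
    K = group_maps.shape[0]

    X1 = np.column_stack([np.ones(V), group_maps.T])  # (V, K+1)
    if np.linalg.cond(X1) > ridge_cond:
        warnings.warn("collinear group maps; using ridge fallback", stacklevel=2)
        lam = 1e-6 * np.trace(X1.T @ X1) / X1.shape[1]
        beta = np.linalg.solve(X1.T @ X1 + lam * np.eye(K + 1), X1.T @ data)
    else:
        beta, *_ = np.linalg.lstsq(X1, data, rcond=None)
    tcs = beta[1:]  # (K, T)

    X2 = np.column_stack([np.ones(T), tcs.T])  # (T, K+1)
    bmap, *_ = np.linalg.lstsq(X2, data.T, rcond=None)
    smaps = bmap[1:]  # (K, V)

    out = []
    for k in range(K):
        loading = float(np.sqrt(np.mean(tcs[k] ** 2)))
        out.append(SubjectComponent(map=smaps[k], timecourse=tcs[k], loading=loading))
    return out


# ---------------------------------------------------------------------------
# identification and scaling


def match_template(component_maps: np.ndarray, template: np.ndarray) -> TemplateMatch:
    """Pick the component whose map best correlates with the template."""
    template = np.asarray(template, dtype=float).reshape(-1)
    if template.std() == 0:
        raise ValueError("template map is constant")
    best_idx, best_r = -1, -np.inf
    for k, mp in enumerate(component_maps):
        if np.std(mp) == 0:
            continue  # undefined correlation
        r = float(np.corrcoef(mp, template)[0, 1])
        if r > best_r:
            best_idx, best_r = k, r
    if best_idx < 0:
        raise ValueError("no component with nonzero variance to match")
    return TemplateMatch(component_index=best_idx, spatial_correlation=best_r)


def zscore_map(map_values: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Z-score a map within the mask; voxels outside the mask are set to 0."""
    map_values = np.asarray(map_values, dtype=float)
    if mask is None:
        vals = map_values
        sd = vals.std()
        if sd == 0:
            raise ValueError("map has zero variance")
        return (vals - vals.mean()) / sd
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vals = map_values[mask]
    sd = vals.std()
    if sd == 0:
        raise ValueError("map has zero variance within mask")
    out = np.zeros_like(map_values, dtype=float)
    out[mask] = (vals - vals.mean()) / sd
    return out
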