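"""Polarity-invariant modified k-means for microstate template extraction.

Topographies of opposite polarity count as the same microstate (the
oscillatory generators flip sign), so similarity is the absolute Pearson
spatial correlation and the cluster "centroid" is the dominant eigenvector
of the assigned maps' outer-product sum — the polarity-invariant analogue
of the mean. Clustering runs on the topographies at GFP peaks; the fit is
scored by global explained variance (GEV), the GFP^2-weighted fraction of
variance the templates account for.

Cluster-number selection uses an ensemble of validity criteria whose
per-criterion optima are aggregated by their median (a meta-criterion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import silhouette_score

from .core import TemplateSet


@dataclass
class ClusterConfig:
    """Settings for the modified k-means and the k scan.

    ``n_restarts`` random restarts are run per k and the solution with the
    highest GEV kept; restart seeds derive from ``rng_seed`` so results are
    reproducible given (seed, n_restarts). ``convergence_tol`` is on the
    change of GEV between iterations.
    """

    k_range: Sequence[int] = tuple(range(2, 11))
    n_restarts: int = 50
    max_iter: int = 100
    convergence_tol: float = 1e-7
    rng_seed: int = 0
    silhouette_subsample: int = 1000

    def __post_init__(self) -> None:
        ks = sorted(set(int(k) for k in self.k_range))
        if not ks or ks[0] < 2:
            raise ValueError("k_range must be nonempty with min >= 2")
        self.k_range = tuple(ks)
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass
class ClusterSolution:
    """Result of one k-means fit (or of a k scan at the chosen k)."""

    templates: TemplateSet
    gev_total: float
    assignments: np.ndarray
    corrs: np.ndarray = field(default_factory=lambda: np.array([]))
    criteria_scores: pd.DataFrame | None = None


def spatial_corr(u: np.ndarray, v: np.ndarray, ignore_polarity: bool = True) -> float:
    """Pearson spatial correlation between two topographies.

    Mean-centers across channels; takes the absolute value when polarity is
    ignored, so a map and its sign-flip correlate at 1.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.size < 2:
        raise ValueError("topographies must have equal length >= 2")
    uc = u - u.mean()
    vc = v - v.mean()
    nu, nv = np.linalg.norm(uc), np.linalg.norm(vc)
    if nu == 0 or nv == 0:
        raise ValueError("zero-variance map: correlation undefined")
    r = float(uc @ vc / (nu * nv))
    return abs(r) if ignore_polarity else r


def _center_normalize(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-center each map across channels; return unit-norm rows and the
    spatial GFP (population SD across channels) of each map."""
    X = np.asarray(maps, dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        raise ValueError("zero-variance map among inputs")
    gfp = norms / np.sqrt(X.shape[1])
    return X / norms[:, None], gfp


def _abs_corr(Xn: np.ndarray, T: np.ndarray) -> np.ndarray:
    """|Pearson| between unit-norm mean-zero rows of Xn and templates T."""
    return np.abs(Xn @ T.T)


def _principal_map(Xn: np.ndarray) -> np.ndarray:
    """Dominant eigenvector of Xn^T Xn: the polarity-invariant centroid."""
    C = Xn.shape[1]
    if Xn.shape[0] == 1:
        return Xn[0].copy()
    S = Xn.T @ Xn
    _, vec = eigh(S, subset_by_index=[C - 1, C - 1])
    v = vec[:, 0]
    v = v - v.mean()  # mean-zero up to roundoff (ones is in the null space)
    return v / np.linalg.norm(v)


def modified_kmeans(peak_maps: np.ndarray, k: int,
                    cfg: ClusterConfig | None = None) -> ClusterSolution:
    """Polarity-invariant k-means on a set of topographies.

    Iterates (a) assignment of each map to the template of maximal absolute
    spatial correlation and (b) template update as the first principal
    component of the assigned maps, until the GEV change falls below the
    tolerance. The best of ``n_restarts`` random initializations by total
    GEV is returned. Maps enter unweighted (one vote per GFP peak); GEV is
    GFP^2-weighted:

        GEV = sum_i GFP_i^2 corr_i^2 / sum_i GFP_i^2 .

    An emptied cluster is re-seeded from the currently worst-fit map.
    """
    cfg = cfg or ClusterConfig()
    X = np.asarray(peak_maps, dtype=float)
    n = X.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k={k} out of range for {n} maps")
    Xn, gfp = _center_normalize(X)
    w = gfp**2
    w_sum = w.sum()
    rng = np.random.default_rng(cfg.rng_seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=cfg.n_restarts)

    best: tuple[float, np.ndarray, np.ndarray, np.ndarray] | None = None
    for seed in restart_seeds:
        r = np.random.default_rng(seed)
        T = Xn[r.choice(n, size=k, replace=False)].copy()
        prev_gev = -np.inf
        for _ in range(cfg.max_iter):
            C = _abs_corr(Xn, T)
            assign = C.argmax(axis=1)
            best_corr = C[np.arange(n), assign]
            for j in range(k):
                members = assign == j
                if not members.any():
                    worst = int(best_corr.argmin())
                    T[j] = Xn[worst]
                    assign[worst] = j
                    members = assign == j
                T[j] = _principal_map(Xn[members])
            C = _abs_corr(Xn, T)
            assign = C.argmax(axis=1)
            best_corr = C[np.arange(n), assign]
            gev = float((w * best_corr**2).sum() / w_sum)
            if abs(gev - prev_gev) < cfg.convergence_tol:
                break
            prev_gev = gev
        if best is None or gev > best[0]:
            best = (gev, T.copy(), assign.copy(), best_corr.copy())

    gev, T, assign, best_corr = best
    templates = TemplateSet(maps=T, level="subject")
    return ClusterSolution(templates=templates, gev_total=gev,
                           assignments=assign, corrs=best_corr)


# ---------------------------------------------------------------------------
# cluster-number selection


def _dispersion(sol: ClusterSolution, gfp: np.ndarray) -> float:
    """GFP^2-weighted unexplained variance of a solution."""
    w = gfp**2
    return float((w * (1.0 - sol.corrs**2)).sum())


def _elbow_k(ks: np.ndarray, values: np.ndarray) -> int:
    """k at maximal perpendicular distance from the chord through the first
    and last points of the curve (a kneedle-style elbow)."""
    x = (ks - ks[0]) / max(ks[-1] - ks[0], 1)
    span = values[-1] - values[0]
    y = (values - values[0]) / (span if span != 0 else 1.0)
    dist = np.abs(y - x)
    return int(ks[dist.argmax()])


def select_optimal_k(peak_maps: np.ndarray, cfg: ClusterConfig | None = None
                     ) -> tuple[int, dict[int, ClusterSolution]]:
    """Scan k over ``cfg.k_range`` and pick the meta-criterion optimum.

    Five cluster-validity criteria are evaluated per k — Krzanowski-Lai,
    the predictive-residual cross-validation criterion, silhouette on the
    ``1 - |corr|`` distance, a polarity-invariant Davies-Bouldin index, and
    a GEV elbow — and the meta-criterion is the median of the per-criterion
    optimal k values, ties broken downward.

    Returns ``(k_star, solutions)``; ``solutions[k_star].criteria_scores``
    holds the per-criterion score table.
    """
    cfg = cfg or ClusterConfig()
    X = np.asarray(peak_maps, dtype=float)
    Xn, gfp = _center_normalize(X)
    n, C = Xn.shape

    # degenerate data: every map identical up to sign
    if _abs_corr(Xn, Xn[:1]).min() > 1.0 - 1e-12:
        warnings.warn("all input maps are identical up to polarity; "
                      "returning min(k_range)")
        k0 = cfg.k_range[0]
        sol = modified_kmeans(X, k0, cfg)
        return k0, {k0: sol}

    ks = list(cfg.k_range)
    # extend by one k on each side for the Krzanowski-Lai differences
    k_lo = max(1, ks[0] - 1)
    k_hi = min(n, ks[-1] + 1)
    scan = sorted(set([k_lo, *ks, k_hi]))
    sols: dict[int, ClusterSolution] = {}
    for k in scan:
        sols[k] = modified_kmeans(X, k, cfg)

    W = {k: _dispersion(sols[k], gfp) for k in scan}
    gev = np.array([sols[k].gev_total for k in ks])
    ks_arr = np.array(ks)

    # cross-validation criterion: residual variance with a dof penalty
    sigma2 = np.array([W[k] / (n * (C - 1)) for k in ks])
    cv = sigma2 * ((C - 1) / (C - 1 - ks_arr)) ** 2
    k_cv = int(ks_arr[cv.argmin()])

    # Krzanowski-Lai
    def diff(k: int) -> float:
        return (k - 1) ** (2.0 / C) * W[k - 1] - k ** (2.0 / C) * W[k]

    kl_scores = []
    for k in ks:
        if k - 1 in W and k + 1 in W and k >= 2:
            d_k, d_k1 = diff(k), diff(k + 1)
            kl_scores.append(abs(d_k) / abs(d_k1) if d_k1 != 0 else 0.0)
        else:
            kl_scores.append(np.nan)
    kl_scores = np.array(kl_scores)
    k_kl = int(ks_arr[np.nanargmax(kl_scores)]) if np.isfinite(kl_scores).any() else ks[0]

    # silhouette on 1 - |corr| distance (subsampled for large inputs)
    rng = np.random.default_rng(cfg.rng_seed + 1)
    if n > cfg.silhouette_subsample:
        idx = rng.choice(n, size=cfg.silhouette_subsample, replace=False)
    else:
        idx = np.arange(n)
    D = 1.0 - _abs_corr(Xn[idx], Xn[idx])
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    sil = []
    for k in ks:
        labels = sols[k].assignments[idx]
        if len(np.unique(labels)) < 2:
            sil.append(np.nan)
        else:
            sil.append(silhouette_score(D, labels, metric="precomputed"))
    sil = np.array(sil)
    k_sil = int(ks_arr[np.nanargmax(sil)]) if np.isfinite(sil).any() else ks[0]

    # Davies-Bouldin with the polarity-invariant distance
    db = []
    for k in ks:
        sol = sols[k]
        T = sol.templates.maps
        S = np.array([np.mean(1.0 - sol.corrs[sol.assignments == j])
                      if (sol.assignments == j).any() else 0.0 for j in range(k)])
        M = 1.0 - _abs_corr(T, T)
        ratio = np.zeros(k)
        for i in range(k):
            others = [(S[i] + S[j]) / M[i, j] for j in range(k)
                      if j != i and M[i, j] > 1e-12]
            ratio[i] = max(others) if others else np.inf
        db.append(ratio.mean())
    db = np.array(db)
    k_db = int(ks_arr[db.argmin()])

    # GEV elbow
    k_elbow = _elbow_k(ks_arr, gev)

    optima = sorted([k_cv, k_kl, k_sil, k_db, k_elbow])
    k_star = int(optima[(len(optima) - 1) // 2])  # lower median: ties downward

    scores = pd.DataFrame({
        "k": ks, "gev": gev, "cv": cv, "kl": kl_scores,
        "silhouette": sil, "davies_bouldin": db,
    }).set_index("k")
    scores.attrs["criterion_optima"] = {
        "cv": k_cv, "kl": k_kl, "silhouette": k_sil,
        "davies_bouldin": k_db, "gev_elbow": k_elbow,
    }
    sols[k_star].criteria_scores = scores
    return k_star, {k: sols[k] for k in ks}


# ---------------------------------------------------------------------------
# group-level clustering and template matching


def group_templates(subject_sets: Sequence[TemplateSet], k: int,
                    cfg: ClusterConfig | None = None) -> ClusterSolution:
    """Second-stage clustering: pool all subject-level template maps (one
    vote per map, every subject contributing equally) and run the
    polarity-invariant k-means on the pool."""
    if len(subject_sets) < 2:
        raise ValueError("need at least 2 subjects for group clustering")
    n_ch = subject_sets[0].n_channels
    if any(s.n_channels != n_ch for s in subject_sets):
        raise ValueError("heterogeneous channel counts across subjects")
    pool = np.vstack([s.maps for s in subject_sets])
    sol = modified_kmeans(pool, k, cfg)
    sol.templates.level = "group"
    return sol


def match_templates(set_a: TemplateSet, set_b: TemplateSet
                    ) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Optimal one-to-one pairing of two template sets.

    Solves the assignment problem maximizing total absolute spatial
    correlation; returns the matched label pairs (ordered by set_a) and the
    correlation per pair.
    """
    if set_a.k != set_b.k:
        raise ValueError("template sets must have equal k")
    if set_a.n_channels != set_b.n_channels:
        raise ValueError("template sets must share the channel count")
    C = np.abs(set_a.maps @ set_b.maps.T)
    rows, cols = linear_sum_assignment(-C)
    pairs = [(set_a.labels[i], set_b.labels[j]) for i, j in zip(rows, cols)]
    return pairs, C[rows, cols]


def canonical_templates(n_channels: int) -> TemplateSet:
    """Five idealized topographies on a spherical sensor layout, used only
    to assign the conventional letters A-E to group templates.

    A: left-posterior to right-anterior gradient; B: right-posterior to
    left-anterior; C: symmetric anterior-posterior; D: fronto-central
    focal; E: occipito-central focal. Purely cosmetic — label assignment
    never affects any numeric result.
    """
    from .simulate import fibonacci_hemisphere

    pos = fibonacci_hemisphere(n_channels)
    x, y, z = pos.T  # x: right, y: anterior, z: up

    def blob(center: np.ndarray) -> np.ndarray:
        return np.exp(-np.sum((pos - center) ** 2, axis=1) / 0.3)

    maps = np.vstack([
        -x + y,                      # A
        x + y,                       # B
        y,                           # C
        blob(np.array([0.0, 0.55, 0.83])),   # D
        blob(np.array([0.0, -0.55, 0.83])),  # E
    ])
    return TemplateSet(maps=maps, labels=list("ABCDE"), level="cohort")


def assign_canonical_labels(templates: TemplateSet) -> TemplateSet:
    """Relabel (and reorder) a 5-template set by best match against the
    canonical A-E topographies. For other k, labels are left untouched."""
    if templates.k != 5:
        return templates
    canon = canonical_templates(templates.n_channels)
    C = np.abs(canon.maps @ templates.maps.T)
    rows, cols = linear_sum_assignment(-C)
    order = cols[np.argsort(rows)]
    return TemplateSet(maps=templates.maps[order], labels=list("ABCDE"),
                       level=templates.level)
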