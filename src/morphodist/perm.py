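"""Distance-matrix permutation inference.

PERMANOVA partitions the total sum of squared inter-object distances into
between- and within-group components and compares them with a pseudo-F
statistic; significance comes from permuting group labels.  PERMDISP (a
multivariate analog of Levene's test) embeds the distance matrix by
principal coordinates analysis, measures each object's distance to its group
centroid with the usual imaginary-axis correction, and applies a one-way
F test to those distances, again with permutation significance.  Sampled
permutation p-values use the (b+1)/(m+1) convention with ties counted as
exceedances; tiny problems can be enumerated exhaustively.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PermTestResult",
    "PCoAResult",
    "DispersionProfile",
    "permanova",
    "pcoa",
    "permdisp",
    "balanced_downsample",
    "pairwise_tests",
    "dist_to_group_centroid",
]

_EXACT_LIMIT = 12  # enumerate all label arrangements only below this n


@dataclass
class PermTestResult:
    """One PERMANOVA or PERMDISP contrast."""

    test: str
    n: int
    df_model: int
    df_resid: int
    F: float
    R2: float
    p: float
    n_perm: int
    method: str = "sampled"          # 'sampled' or 'exact'
    significant_bonferroni: bool | None = None

    def __post_init__(self) -> None:
        if not (np.isnan(self.R2) or -1e-12 <= self.R2 <= 1 + 1e-12):
            raise ValueError("R2 must lie in [0, 1]")


@dataclass
class PCoAResult:
    """Principal coordinates of a distance matrix, keeping imaginary axes."""

    coordinates: np.ndarray      # (n, k) axis scores scaled by sqrt(|eigenvalue|)
    eigenvalues: np.ndarray      # (k,) sorted descending (may be negative)
    axis_class: np.ndarray       # 'real'/'imaginary' per retained axis
    neg_eigenvalue_mass: float   # sum |negative eigenvalues| / sum |eigenvalues|


@dataclass
class DispersionProfile:
    """Per-object distances to the own-group centroid plus group summaries."""

    distances: pd.DataFrame      # object, group, distance
    group_summary: pd.DataFrame  # group, n, median, lower, upper (2.5/97.5%)


def _check_distance_matrix(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    return D


def _group_codes(labels) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    uniq, codes = np.unique(labels, return_inverse=True)
    return uniq, codes


def _permanova_stats(Dsq: np.ndarray, codes: np.ndarray, a: int) -> tuple[float, float]:
    N = Dsq.shape[0]
    ss_t = Dsq.sum() / (2.0 * N)
    ss_w = 0.0
    for g in range(a):
        idx = np.flatnonzero(codes == g)
        ss_w += Dsq[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_a = ss_t - ss_w
    tol = 1e-12 * max(ss_t, 1e-300)
    if ss_w <= tol:
        F = np.inf if ss_a > tol else 0.0
    else:
        F = (ss_a / (a - 1)) / (ss_w / (N - a))
    R2 = ss_a / ss_t if ss_t > 0 else np.nan
    return F, R2


def _distinct_arrangements(codes: np.ndarray):
    """All distinct permutations of a small label multiset."""
    seen = set()
    for perm in itertools.permutations(codes.tolist()):
        if perm not in seen:
            seen.add(perm)
            yield np.asarray(perm)


def permanova(
    D: np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    exact: bool = False,
) -> PermTestResult:
    """Permutational multivariate analysis of variance on a distance matrix.

    With ``exact=True`` (small n only) every distinct label arrangement is
    enumerated and ``p = #(F_perm >= F_obs) / #arrangements``.
    """
    D = _check_distance_matrix(D)
    uniq, codes = _group_codes(labels)
    a = len(uniq)
    N = len(codes)
    if a < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        raise ValueError("every group needs at least 2 objects")
    Dsq = D * D
    F_obs, R2 = _permanova_stats(Dsq, codes, a)

    if exact:
        if N > _EXACT_LIMIT:
            raise ValueError(f"exact enumeration limited to n <= {_EXACT_LIMIT}")
        fs = np.array([_permanova_stats(Dsq, arr, a)[0] for arr in _distinct_arrangements(codes)])
        p = float(np.mean(fs >= F_obs - 1e-12))
        return PermTestResult("permanova", N, a - 1, N - a, F_obs, R2, p,
                              n_perm=len(fs), method="exact")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        F_p, _ = _permanova_stats(Dsq, perm, a)
        if F_p >= F_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return PermTestResult("permanova", N, a - 1, N - a, F_obs, R2, p, n_perm=n_perm)


def pcoa(D: np.ndarray, tol: float = 1e-9) -> PCoAResult:
    """Principal coordinates analysis keeping negative-eigenvalue axes flagged."""
    D = _check_distance_matrix(D)
    n = D.shape[0]
    A = -0.5 * D * D
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = J @ A @ J
    B = (B + B.T) / 2.0
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    scale = np.abs(w).max() if n > 1 else 1.0
    keep = np.abs(w) > tol * max(scale, 1.0)
    wk, Vk = w[keep], V[:, keep]
    coords = Vk * np.sqrt(np.abs(wk))
    axis_class = np.where(wk >= 0, "real", "imaginary")
    neg = float(np.abs(w[w < 0]).sum())
    tot = float(np.abs(w).sum())
    return PCoAResult(
        coordinates=coords,
        eigenvalues=wk,
        axis_class=axis_class,
        neg_eigenvalue_mass=neg / tot if tot > 0 else 0.0,
    )


def _geometric_median(X: np.ndarray, tol: float = 1e-10, max_iter: int = 500) -> np.ndarray:
    """Weiszfeld iteration for the spatial median."""
    y = X.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(X - y, axis=1)
        if np.any(d < 1e-12):
            return y
        w = 1.0 / d
        y_new = (X * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y


def _disp_distances(Xr: np.ndarray, Xi: np.ndarray, codes: np.ndarray, a: int,
                    center: str) -> tuple[np.ndarray, int]:
    """Distance of each object to its group centroid with imaginary correction."""
    z = np.empty(len(codes))
    clamped = 0
    for g in range(a):
        idx = np.flatnonzero(codes == g)
        if center == "median":
            cr = _geometric_median(Xr[idx])
        else:
            cr = Xr[idx].mean(axis=0)
        dr2 = ((Xr[idx] - cr) ** 2).sum(axis=1)
        if Xi.shape[1]:
            ci = Xi[idx].mean(axis=0)
            di2 = ((Xi[idx] - ci) ** 2).sum(axis=1)
        else:
            di2 = 0.0
        d2 = dr2 - di2
        neg = d2 < 0
        clamped += int(np.count_nonzero(neg))
        z[idx] = np.sqrt(np.clip(d2, 0.0, None))
    return z, clamped


def _anova_f(z: np.ndarray, codes: np.ndarray, a: int) -> tuple[float, float]:
    N = len(z)
    grand = z.mean()
    ssb = 0.0
    ssw = 0.0
    for g in range(a):
        zg = z[codes == g]
        ssb += len(zg) * (zg.mean() - grand) ** 2
        ssw += ((zg - zg.mean()) ** 2).sum()
    tol = 1e-12 * max(float((z * z).sum()), 1e-300)
    if ssw <= tol:
        F = np.inf if ssb > tol else 0.0
    else:
        F = (ssb / (a - 1)) / (ssw / (N - a))
    sst = ssb + ssw
    R2 = ssb / sst if sst > 0 else 0.0
    return F, R2


def permdisp(
    D: np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    center: str = "mean",
    permute: str = "assignments",
    exact: bool = False,
) -> tuple[PermTestResult, DispersionProfile]:
    """Permutation test of multivariate homogeneity of group dispersions.

    ``center`` selects the group centroid in PCoA space: coordinate mean
    (default) or spatial median.  ``permute='assignments'`` recomputes
    distances-to-centroid under each permuted grouping; ``permute='z'``
    permutes the observed distances (faster, classical residual shuffle).
    """
    D = _check_distance_matrix(D)
    uniq, codes = _group_codes(labels)
    a = len(uniq)
    N = len(codes)
    if a < 2:
        raise ValueError("need at least 2 groups")
    if np.bincount(codes).min() < 2:
        raise ValueError("every group needs at least 2 objects")
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    emb = pcoa(D)
    real = emb.axis_class == "real"
    Xr = emb.coordinates[:, real]
    Xi = emb.coordinates[:, ~real]
    z_obs, clamped = _disp_distances(Xr, Xi, codes, a, center)
    if clamped:
        logger.info("permdisp: clamped %d negative corrected squared distance(s)", clamped)
    F_obs, R2 = _anova_f(z_obs, codes, a)

    if permute == "assignments":
        def perm_stat(perm: np.ndarray) -> float:
            zp, _ = _disp_distances(Xr, Xi, perm, a, center)
            return _anova_f(zp, perm, a)[0]
    elif permute == "z":
        def perm_stat(perm: np.ndarray) -> float:
            return _anova_f(z_obs[perm], codes, a)[0]
    else:
        raise ValueError("permute must be 'assignments' or 'z'")

    if exact:
        if N > _EXACT_LIMIT:
            raise ValueError(f"exact enumeration limited to n <= {_EXACT_LIMIT}")
        if permute == "z":
            raise ValueError("exact mode requires permute='assignments'")
        fs = np.array([perm_stat(arr) for arr in _distinct_arrangements(codes)])
        p = float(np.mean(fs >= F_obs - 1e-12))
        res = PermTestResult("permdisp", N, a - 1, N - a, F_obs, R2, p,
                             n_perm=len(fs), method="exact")
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            if permute == "assignments":
                stat = perm_stat(rng.permutation(codes))
            else:
                stat = perm_stat(rng.permutation(N))
            if stat >= F_obs - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        res = PermTestResult("permdisp", N, a - 1, N - a, F_obs, R2, p, n_perm=n_perm)

    prof = _profile_from_distances(z_obs, np.asarray(labels))
    return res, prof


def _profile_from_distances(z: np.ndarray, labels: np.ndarray) -> DispersionProfile:
    df = pd.DataFrame({"object": np.arange(len(z)), "group": labels, "distance": z})
    rows = []
    for g, sub in df.groupby("group", sort=False, observed=True):
        d = sub["distance"].to_numpy()
        rows.append(
            {
                "group": g,
                "n": len(d),
                "median": float(np.median(d)),
                "lower": float(np.percentile(d, 2.5)),
                "upper": float(np.percentile(d, 97.5)),
            }
        )
    return DispersionProfile(distances=df, group_summary=pd.DataFrame(rows))


def dist_to_group_centroid(D: np.ndarray, labels) -> DispersionProfile:
    """Distance of each object to its own group centroid via the Gower identity.

    d^2(i, c_G) = (1/n_G) sum_{j in G} d_ij^2 - (1/n_G^2) sum_{j<k in G} d_jk^2,
    clamped at zero.  Exact for Euclidean-embeddable distances.
    """
    D = _check_distance_matrix(D)
    labels = np.asarray(labels)
    uniq, codes = _group_codes(labels)
    Dsq = D * D
    z = np.empty(len(codes))
    for g in range(len(uniq)):
        idx = np.flatnonzero(codes == g)
        ng = len(idx)
        sub = Dsq[np.ix_(idx, idx)]
        within = sub.sum() / 2.0
        d2 = sub.mean(axis=1) - within / (ng * ng)
        z[idx] = np.sqrt(np.clip(d2, 0.0, None))
    return _profile_from_distances(z, labels)


def balanced_downsample(labels, seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Indices balancing exactly two groups by down-sampling the larger one."""
    labels = np.asarray(labels)
    uniq, codes = _group_codes(labels)
    if len(uniq) != 2:
        raise ValueError("balanced_downsample expects exactly 2 groups")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx0 = np.flatnonzero(codes == 0)
    idx1 = np.flatnonzero(codes == 1)
    small, large = (idx0, idx1) if len(idx0) <= len(idx1) else (idx1, idx0)
    pick = rng.choice(large, size=len(small), replace=False)
    return np.sort(np.concatenate([small, pick]))


def pairwise_tests(
    D: np.ndarray,
    labels,
    n_perm: int = 999,
    seed: int | None = 1,
    alpha: float = 0.05,
    center: str = "mean",
    permute: str = "assignments",
) -> pd.DataFrame:
    """Balanced pairwise PERMANOVA and PERMDISP over all group pairs.

    Each unordered pair is first balanced by random down-sampling, then both
    tests run on the restricted distance matrix.  Significance is starred at
    the Bonferroni-corrected level alpha / (number of pairs).
    """
    D = _check_distance_matrix(D)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    pairs = list(itertools.combinations(uniq.tolist(), 2))
    alpha_corr = alpha / len(pairs)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(pairs))
    rows = []
    for (ga, gb), child in zip(pairs, children):
        rng = np.random.default_rng(child)
        mask = np.isin(labels, [ga, gb])
        sub_idx = np.flatnonzero(mask)
        sub_labels = labels[sub_idx]
        bal = balanced_downsample(sub_labels, rng)
        idx = sub_idx[bal]
        Dp = D[np.ix_(idx, idx)]
        lp = labels[idx]
        res_a = permanova(Dp, lp, n_perm=n_perm, seed=rng)
        res_d, _ = permdisp(Dp, lp, n_perm=n_perm, seed=rng, center=center, permute=permute)
        for res in (res_a, res_d):
            res.significant_bonferroni = bool(res.p < alpha_corr)
            rows.append(
                {
                    "pair": f"{ga} vs. {gb}",
                    "test": res.test,
                    "n": res.n,
                    "df_model": res.df_model,
                    "df_resid": res.df_resid,
                    "F": res.F,
                    "R2": res.R2,
                    "p": res.p,
                    "n_perm": res.n_perm,
                    "bonferroni_alpha": alpha_corr,
                    "significant": res.significant_bonferroni,
                }
            )
    return pd.DataFrame(rows)
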