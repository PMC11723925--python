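"""Resemblance under missing data: imputation, repeated mixed PCA, and
median/interval combination of Mahalanobis-type distance matrices.

The procedure has four steps.  (1) Missing cells are filled by resampling
each variable's observed empirical distribution, independently per
iteration, giving m completed tables.  (2) Each completed table is submitted
to a mixed-data PCA and an inter-individual Mahalanobis-type distance matrix
is computed over the retained components.  (3) The m distance matrices are
combined per pair into a median matrix and percentile confidence bounds.
(4) Each object's m first-two-PC positions (sign- and rotation-aligned to a
reference iteration) are averaged into a centroid with a 95% confidence
ellipse; group centroids, dispersion ellipses, the eigenvalue spectrum and
variable-PC correlation arrows summarise the ordination.

Distances are rotation- and sign-invariant, so only the plotted coordinates
need alignment.  Per-pair medians are computed over pair blocks from the
stored per-iteration score matrices, never materialising m full distance
matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.stats import chi2

from .pca import PCModel, correlation_circle, mixed_pca, standardized_scores, variance_explained
from .schema_io import FlakeTable, Schema

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "DistanceSummary",
    "OrdinationSummary",
    "impute_once",
    "run_flexdist",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the resemblance analysis."""

    n_iterations: int = 1000
    ci_level: float = 0.95
    min_rel_eig: float = 1e-8
    n_components: int | None = None      # fixed PC count; None = all non-degenerate
    imputation: str = "marginal"         # or "within_group" hot-deck
    pair_block_size: int = 200_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.imputation not in ("marginal", "within_group"):
            raise ValueError("imputation must be 'marginal' or 'within_group'")


@dataclass
class DistanceSummary:
    """Per-pair median and confidence bounds across imputations."""

    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    ci_level: float
    n_iterations: int

    def __post_init__(self) -> None:
        for name in ("median", "lower", "upper"):
            M = getattr(self, name)
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} matrix must be symmetric")
            if np.any(np.diag(M) != 0):
                raise ValueError(f"{name} matrix must have a zero diagonal")
        if np.any(self.lower > self.median + 1e-12) or np.any(self.median > self.upper + 1e-12):
            raise ValueError("interval ordering lower <= median <= upper violated")

    @property
    def n(self) -> int:
        return self.median.shape[0]

    def to_long(self) -> pd.DataFrame:
        i, j = np.triu_indices(self.n, 1)
        return pd.DataFrame(
            {
                "i": i,
                "j": j,
                "median": self.median[i, j],
                "lower": self.lower[i, j],
                "upper": self.upper[i, j],
            }
        )

    def mean_ci_width(self) -> float:
        i, j = np.triu_indices(self.n, 1)
        return float((self.upper - self.lower)[i, j].mean())


@dataclass
class OrdinationSummary:
    """Plot-ready content for the two-dimensional ordination."""

    object_centroids: pd.DataFrame   # object, group, pc1, pc2
    object_ellipses: pd.DataFrame    # object, semi_major, semi_minor, angle_deg
    group_centroids: pd.DataFrame    # group, pc1, pc2
    group_ellipses: pd.DataFrame     # group, semi_major, semi_minor, angle_deg
    variance_pct: np.ndarray         # percent variance per PC (sums to 100)
    arrows: pd.DataFrame             # column, variable, pc1_corr, pc2_corr
    ci_level: float


def impute_once(
    table: FlakeTable,
    seed: int | np.random.Generator | None = None,
    mode: str = "marginal",
) -> FlakeTable:
    """Fill every missing cell with a draw from that variable's observed values.

    ``mode='within_group'`` draws from the same group's observed values when
    any exist (hot-deck), falling back to the pooled observed values.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = table.copy()
    groups = table.group.to_numpy()
    for name in table.schema.names:
        col = out.data[name]
        is_cat = isinstance(col.dtype, pd.CategoricalDtype)
        vals = col.cat.codes.to_numpy().astype(float) if is_cat else col.to_numpy(dtype=float)
        if is_cat:
            vals[vals < 0] = np.nan
        miss = np.isnan(vals)
        if not miss.any():
            continue
        obs_all = vals[~miss]
        if len(obs_all) == 0:
            raise ValueError(f"variable {name} has no observed values to impute from")
        fill = np.empty(int(miss.sum()))
        if mode == "within_group":
            rows = np.flatnonzero(miss)
            for t, r in enumerate(rows):
                pool = vals[(groups == groups[r]) & ~miss]
                if len(pool) == 0:
                    pool = obs_all
                fill[t] = pool[rng.integers(len(pool))]
        else:
            fill = obs_all[rng.integers(len(obs_all), size=int(miss.sum()))]
        vals[miss] = fill
        if is_cat:
            out.data[name] = pd.Categorical.from_codes(
                vals.astype(int), categories=col.cat.categories, ordered=col.cat.ordered
            )
        else:
            out.data[name] = vals
    return out


def _sign_align(model: PCModel, ref: PCModel) -> None:
    """Flip PC signs in-place to maximise loading agreement with the reference."""
    k = min(model.loadings.shape[1], ref.loadings.shape[1])
    for j in range(k):
        if np.dot(model.loadings[:, j], ref.loadings[:, j]) < 0:
            model.loadings[:, j] = -model.loadings[:, j]
            model.scores[:, j] = -model.scores[:, j]


def _planar_rotation(model: PCModel, ref: PCModel) -> np.ndarray:
    """Orthogonal Procrustes rotation mapping the model's first-two-PC plane
    onto the reference's, estimated from loadings."""
    A = model.loadings[:, :2]
    B = ref.loadings[:, :2]
    R, _ = orthogonal_procrustes(A, B)
    return R


def _ellipse_params(cov: np.ndarray, quantile: float) -> tuple[float, float, float]:
    w, V = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)[::-1]
    V = V[:, ::-1]
    a = float(np.sqrt(w[0] * quantile))
    b = float(np.sqrt(w[1] * quantile))
    angle = float(np.degrees(np.arctan2(V[1, 0], V[0, 0])))
    return a, b, angle


def _pair_quantiles(score_list: list[np.ndarray], n: int, ci: float,
                    block: int) -> DistanceSummary:
    m = len(score_list)
    iu, ju = np.triu_indices(n, 1)
    n_pairs = len(iu)
    med = np.zeros((n, n))
    lo = np.zeros((n, n))
    hi = np.zeros((n, n))
    alpha = (1.0 - ci) / 2.0
    for start in range(0, n_pairs, block):
        sl = slice(start, min(start + block, n_pairs))
        ib, jb = iu[sl], ju[sl]
        vals = np.empty((m, len(ib)))
        for t, S in enumerate(score_list):
            diff = S[ib] - S[jb]
            vals[t] = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        q = np.quantile(vals, [alpha, 0.5, 1.0 - alpha], axis=0)
        lo[ib, jb] = lo[jb, ib] = q[0]
        med[ib, jb] = med[jb, ib] = q[1]
        hi[ib, jb] = hi[jb, ib] = q[2]
    return DistanceSummary(median=med, lower=lo, upper=hi, ci_level=ci, n_iterations=m)


def _ordination_from_runs(
    scores2_list: list[np.ndarray],
    arrows_list: list[pd.DataFrame],
    var_pct_list: list[np.ndarray],
    group: pd.Series,
    ci: float,
) -> OrdinationSummary:
    m = len(scores2_list)
    stack = np.stack(scores2_list)             # (m, n, 2)
    cent = stack.mean(axis=0)                  # (n, 2)
    q = chi2.ppf(ci, df=2)
    n = cent.shape[0]
    ell = np.zeros((n, 3))
    if m > 1:
        for i in range(n):
            cov = np.cov(stack[:, i, :].T)
            ell[i] = _ellipse_params(np.atleast_2d(cov), q)
    obj_cent = pd.DataFrame(
        {"object": np.arange(n), "group": group.to_numpy(), "pc1": cent[:, 0], "pc2": cent[:, 1]}
    )
    obj_ell = pd.DataFrame(
        {"object": np.arange(n), "semi_major": ell[:, 0], "semi_minor": ell[:, 1],
         "angle_deg": ell[:, 2]}
    )
    grows, gell = [], []
    for g, sub in obj_cent.groupby("group", sort=False, observed=True):
        xy = sub[["pc1", "pc2"]].to_numpy()
        grows.append({"group": g, "pc1": xy[:, 0].mean(), "pc2": xy[:, 1].mean()})
        if len(xy) > 2:
            a, b, ang = _ellipse_params(np.cov(xy.T), q)
        else:
            a = b = ang = 0.0
        gell.append({"group": g, "semi_major": a, "semi_minor": b, "angle_deg": ang})
    # average arrows and spectra across iterations
    arrows = arrows_list[0].copy()
    arrows[["pc1_corr", "pc2_corr"]] = np.mean(
        [a[["pc1_corr", "pc2_corr"]].to_numpy() for a in arrows_list], axis=0
    )
    k = min(len(v) for v in var_pct_list)
    var_pct = np.mean([v[:k] for v in var_pct_list], axis=0)
    var_pct = 100.0 * var_pct / var_pct.sum()
    return OrdinationSummary(
        object_centroids=obj_cent,
        object_ellipses=obj_ell,
        group_centroids=pd.DataFrame(grows),
        group_ellipses=pd.DataFrame(gell),
        variance_pct=var_pct,
        arrows=arrows,
        ci_level=ci,
    )


def _rotated_arrows(model: PCModel, R: np.ndarray) -> pd.DataFrame:
    """Variable-PC correlations against the rotated first-two-PC scores."""
    S2 = model.scores[:, :2] @ R
    Z = model.encoded
    zsd = Z.std(axis=0, ddof=1)
    out = np.zeros((Z.shape[1], 2))
    for c in range(2):
        s = S2[:, c]
        ssd = s.std(ddof=1)
        if ssd > 0:
            out[:, c] = ((Z - Z.mean(axis=0)) * (s - s.mean())[:, None]).sum(axis=0) / (
                (Z.shape[0] - 1) * zsd * ssd
            )
    return pd.DataFrame(
        {"column": model.columns, "variable": model.column_vars,
         "pc1_corr": out[:, 0], "pc2_corr": out[:, 1]}
    )


def run_flexdist(
    table: FlakeTable,
    schema: Schema | None = None,
    cfg: AnalysisConfig | None = None,
) -> tuple[DistanceSummary, OrdinationSummary]:
    """Run the full multiple-imputation resemblance procedure."""
    schema = schema or table.schema
    cfg = cfg or AnalysisConfig()
    n_missing = int(table.data.isna().sum().sum())

    if n_missing == 0:
        model = mixed_pca(table, schema)
        U = standardized_scores(model, cfg.min_rel_eig, cfg.n_components)
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(U))
        dist = DistanceSummary(median=D, lower=D.copy(), upper=D.copy(),
                               ci_level=cfg.ci_level, n_iterations=1)
        arrows = correlation_circle(model)
        ordn = _ordination_from_runs(
            [model.scores[:, :2]], [arrows], [variance_explained(model)],
            table.group, cfg.ci_level,
        )
        return dist, ordn

    m = cfg.n_iterations
    if m < 2:
        raise ValueError("n_iterations must be >= 2 when the table has missing cells")
    child_seeds = np.random.SeedSequence(cfg.seed).spawn(m)
    score_list: list[np.ndarray] = []
    scores2_list: list[np.ndarray] = []
    arrows_list: list[pd.DataFrame] = []
    var_pct_list: list[np.ndarray] = []
    ref: PCModel | None = None
    for t in range(m):
        rng = np.random.default_rng(child_seeds[t])
        completed = impute_once(table, rng, mode=cfg.imputation)
        model = mixed_pca(completed, schema)
        if ref is None:
            ref = model
            R = np.eye(2)
        else:
            _sign_align(model, ref)
            R = _planar_rotation(model, ref)
        score_list.append(standardized_scores(model, cfg.min_rel_eig, cfg.n_components))
        scores2_list.append(model.scores[:, :2] @ R)
        arrows_list.append(_rotated_arrows(model, R))
        var_pct_list.append(variance_explained(model))

    dist = _pair_quantiles(score_list, table.n, cfg.ci_level, cfg.pair_block_size)
    ordn = _ordination_from_runs(scores2_list, arrows_list, var_pct_list,
                                 table.group, cfg.ci_level)
    return dist, ordn
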