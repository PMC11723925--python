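"""Heterogeneous correlations among mixed-scale variables.

Correlations are dispatched by the scales of each pair under a latent
Gaussian model: Pearson for continuous pairs, polychoric for ordinal pairs
(tetrachoric in the binary case), and polyserial for continuous-categorical
pairs (biserial in the binary case).  Polychoric and polyserial use the
standard two-step estimator: thresholds are fixed at the inverse-normal
cumulative marginals, then the latent correlation maximises the
bivariate-normal likelihood by bounded scalar search on [-0.999, 0.999].
Missing values are handled by pairwise deletion.  Nominal variables with
more than two categories enter the matrix as per-category binary indicators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal, norm

from .schema_io import FlakeTable, Schema

__all__ = [
    "DegenerateError",
    "HetCorMatrix",
    "pearson_pairwise",
    "polychoric",
    "tetrachoric",
    "polyserial",
    "hetero_corr_matrix",
]

RHO_BOUND = 0.999
#: thresholds beyond +-8 SD are numerically at the marginal boundary
_INF = 8.0


class DegenerateError(ValueError):
    """A correlation is undefined for this pair (zero variance / degenerate margin)."""


def _bvn_cdf_grid(a: np.ndarray, b: np.ndarray, rho: float) -> np.ndarray:
    """Standard bivariate normal CDF on the grid a x b (1-D threshold arrays)."""
    A, B = np.meshgrid(a, b, indexing="ij")
    pts = np.column_stack([A.ravel(), B.ravel()])
    cov = np.array([[1.0, rho], [rho, 1.0]])
    vals = multivariate_normal.cdf(
        pts, mean=np.zeros(2), cov=cov, abseps=1e-10, releps=0.0
    )
    return np.asarray(vals).reshape(len(a), len(b))


def _cell_probs(a: np.ndarray, b: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities for cut points a (rows) and b (columns)."""
    aa = np.concatenate([[-_INF], np.clip(a, -_INF, _INF), [_INF]])
    bb = np.concatenate([[-_INF], np.clip(b, -_INF, _INF), [_INF]])
    F = _bvn_cdf_grid(aa, bb, rho)
    P = F[1:, 1:] - F[:-1, 1:] - F[1:, :-1] + F[:-1, :-1]
    return np.clip(P, 1e-12, 1.0)


def pearson_pairwise(x, y) -> float:
    """Product-moment correlation over pairwise-complete cases."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    n = int(ok.sum())
    if n < 3:
        raise DegenerateError(f"fewer than 3 pairwise-complete observations (n={n})")
    xs, ys = x[ok], y[ok]
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise DegenerateError("zero variance in a pairwise-complete margin")
    return float(np.corrcoef(xs, ys)[0, 1])


def _marginal_thresholds(margin: np.ndarray) -> np.ndarray:
    total = margin.sum()
    if total <= 0:
        raise DegenerateError("empty contingency margin")
    cum = np.cumsum(margin)[:-1] / total
    return norm.ppf(cum)


def polychoric(ctab) -> float:
    """Two-step polychoric correlation from a two-way table of level counts.

    Levels with zero marginal counts are dropped; if fewer than two levels
    remain on either margin the correlation is undefined.
    """
    T = np.asarray(ctab, dtype=float)
    if T.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if np.any(T < 0):
        raise ValueError("counts must be nonnegative")
    T = T[T.sum(axis=1) > 0][:, T.sum(axis=0) > 0]
    if T.shape[0] < 2 or T.shape[1] < 2:
        raise DegenerateError("a margin has all mass in one level")
    a = _marginal_thresholds(T.sum(axis=1))
    b = _marginal_thresholds(T.sum(axis=0))

    def nll(rho: float) -> float:
        return -float(np.sum(T * np.log(_cell_probs(a, b, rho))))

    res = minimize_scalar(nll, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def tetrachoric(ctab) -> float:
    """Tetrachoric correlation: the 2x2 case of the polychoric estimator."""
    T = np.asarray(ctab, dtype=float)
    if T.shape != (2, 2):
        raise ValueError("tetrachoric requires a 2x2 table")
    return polychoric(T)


def polyserial(x, y_codes, n_levels: int | None = None) -> float:
    """Two-step polyserial correlation between a continuous x and ordinal codes y.

    ``y_codes`` are integer level indices (0..K-1; negative or NaN = missing).
    The biserial correlation is the two-level case.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y_codes, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y) | (y < 0))
    xs = x[ok]
    ys = y[ok].astype(int)
    n = len(xs)
    if n < 10:
        raise DegenerateError(f"fewer than 10 pairwise-complete observations (n={n})")
    levels, ys = np.unique(ys, return_inverse=True)
    K = len(levels)
    if K < 2:
        raise DegenerateError("only one observed ordinal level")
    sd = xs.std(ddof=1)
    if sd == 0:
        raise DegenerateError("zero variance in the continuous margin")
    z = (xs - xs.mean()) / sd
    counts = np.bincount(ys, minlength=K).astype(float)
    tau = np.concatenate([[-_INF], np.clip(_marginal_thresholds(counts), -_INF, _INF), [_INF]])
    lo = tau[ys]
    hi = tau[ys + 1]

    def nll(rho: float) -> float:
        s = np.sqrt(1.0 - rho * rho)
        p = norm.cdf((hi - rho * z) / s) - norm.cdf((lo - rho * z) / s)
        return -float(np.sum(np.log(np.clip(p, 1e-12, 1.0))))

    res = minimize_scalar(nll, bounds=(-RHO_BOUND, RHO_BOUND), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


# ---------------------------------------------------------------------------
# full matrix


@dataclass
class HetCorMatrix:
    """Heterogeneous correlation matrix with per-pair estimator bookkeeping."""

    matrix: pd.DataFrame          # symmetric, unit diagonal, entries in [-1, 1]
    method: pd.DataFrame          # estimator label per pair
    n_effective: pd.DataFrame     # pairwise-complete counts
    psd_repaired: bool
    diagnostics: list[str]

    def to_long(self) -> pd.DataFrame:
        """Long format (var1, var2, rho, method, n) over the upper triangle."""
        cols = list(self.matrix.columns)
        rows = []
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                rows.append(
                    {
                        "var1": a,
                        "var2": b,
                        "rho": self.matrix.loc[a, b],
                        "method": self.method.loc[a, b],
                        "n": self.n_effective.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def _working_columns(table: FlakeTable, schema: Schema):
    """Expand the table into correlation-ready columns.

    Returns a list of (name, kind, values) with kind in {'cont', 'ord', 'bin'};
    categorical values are float level codes with NaN for missing.  Nominal
    variables with more than two categories become one indicator column per
    observed category.
    """
    cols = []
    for var in schema.variables:
        s = table.data[var.name]
        if var.scale == "continuous":
            cols.append((var.name, "cont", s.to_numpy(dtype=float)))
        elif var.scale == "ordinal":
            codes = s.cat.codes.to_numpy().astype(float)
            codes[codes < 0] = np.nan
            cols.append((var.name, "ord", codes))
        else:
            codes = s.cat.codes.to_numpy().astype(float)
            codes[codes < 0] = np.nan
            if len(var.levels) == 2:  # type: ignore[arg-type]
                cols.append((var.name, "bin", codes))
            else:
                for k, lev in enumerate(var.levels):  # type: ignore[arg-type]
                    lab = (var.level_labels[k] if var.level_labels else lev)
                    ind = np.where(np.isnan(codes), np.nan, (codes == k).astype(float))
                    cols.append((f"{var.name}.{lab}", "bin", ind))
    return cols


def _pair_corr(kind_a: str, xa: np.ndarray, kind_b: str, xb: np.ndarray) -> tuple[float, str, int]:
    ok = ~(np.isnan(xa) | np.isnan(xb))
    n = int(ok.sum())
    ka, kb = kind_a, kind_b
    if ka == "cont" and kb == "cont":
        return pearson_pairwise(xa, xb), "pearson", n
    if ka == "cont" or kb == "cont":
        if ka == "cont":
            x, y, ky = xa, xb, kb
        else:
            x, y, ky = xb, xa, ka
        label = "biserial" if ky == "bin" else "polyserial"
        return polyserial(x, y), label, n
    # categorical-categorical
    a = xa[ok].astype(int)
    b = xb[ok].astype(int)
    ka_lev = int(a.max()) + 1 if len(a) else 0
    kb_lev = int(b.max()) + 1 if len(b) else 0
    T = np.zeros((ka_lev, kb_lev))
    np.add.at(T, (a, b), 1.0)
    Tn = T[T.sum(axis=1) > 0][:, T.sum(axis=0) > 0]
    label = "tetrachoric" if Tn.shape == (2, 2) else "polychoric"
    return polychoric(T), label, n


def hetero_corr_matrix(
    table: FlakeTable,
    schema: Schema | None = None,
    psd_repair: bool = True,
) -> HetCorMatrix:
    """Pairwise heterogeneous correlation matrix over correlation-ready columns.

    Undefined pairs are recorded as NaN with a diagnostic rather than
    silently zeroed.  If requested and possible, an eigenvalue-clipping
    repair restores positive semi-definiteness; whether repair ran is flagged.
    """
    schema = schema or table.schema
    cols = _working_columns(table, schema)
    names = [c[0] for c in cols]
    p = len(cols)
    R = np.eye(p)
    M = np.full((p, p), "", dtype=object)
    Nf = np.zeros((p, p), dtype=int)
    diags: list[str] = []
    for i in range(p):
        Nf[i, i] = int((~np.isnan(cols[i][2])).sum())
        for j in range(i + 1, p):
            try:
                rho, label, n = _pair_corr(cols[i][1], cols[i][2], cols[j][1], cols[j][2])
            except DegenerateError as exc:
                rho, label = np.nan, "undefined"
                n = int((~(np.isnan(cols[i][2]) | np.isnan(cols[j][2]))).sum())
                diags.append(f"{names[i]} vs {names[j]}: {exc}")
            R[i, j] = R[j, i] = rho
            M[i, j] = M[j, i] = label
            Nf[i, j] = Nf[j, i] = n

    repaired = False
    if psd_repair:
        if np.isnan(R).any():
            diags.append("PSD repair skipped: matrix contains undefined entries")
        else:
            w, V = np.linalg.eigh(R)
            if w.min() < -1e-8:
                w = np.clip(w, 0.0, None)
                R = (V * w) @ V.T
                d = np.sqrt(np.diag(R))
                R = R / np.outer(d, d)
                np.fill_diagonal(R, 1.0)
                repaired = True
    R = np.clip(R, -1.0, 1.0)
    idx = pd.Index(names)
    return HetCorMatrix(
        matrix=pd.DataFrame(R, index=idx, columns=idx),
        method=pd.DataFrame(M, index=idx, columns=idx),
        n_effective=pd.DataFrame(Nf, index=idx, columns=idx),
        psd_repaired=repaired,
        diagnostics=diags,
    )
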