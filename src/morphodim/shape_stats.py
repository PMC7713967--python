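"""Permutation-based linear models on multivariate shape.

Implements Procrustes ANOVA/ANCOVA with Type II sums of squares and
residual-randomization permutation (RRPP) inference, pairwise
phenotype-vector angle/magnitude comparisons, Mantel tests, 2D-3D
distance correlations and disparity models.

Type II convention: a term is tested after all other terms that do not
contain it (main effects exclude their interactions; interactions are
tested against the additive model).  Significance comes from permuting
the residuals of the corresponding reduced model and recomputing the
statistic; the observed arrangement counts as one permutation, so
p >= 1/(n_perm + 1) and ties are counted as exceedances (conservative).
Effect sizes (Z) are standard-normal positions of log F in the
permutation distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "RrppFit",
    "VectorComparison",
    "rrpp_fit",
    "pairwise_vectors",
    "compare_vectors_across_spaces",
    "mantel",
    "distance_correlation_2d3d",
    "disparity_ancova",
]

_CHUNK_ELEMS = 4_000_000  # max B*N*p elements materialized at once


# ----------------------------------------------------------------------
# design matrices
# ----------------------------------------------------------------------

def _is_factor(col: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(col)

def _block_for(data: pd.DataFrame, var: str) -> np.ndarray:
    col = data[var]
    if _is_factor(col):
        dummies = pd.get_dummies(col.astype(str), drop_first=True)
        dummies = dummies[sorted(dummies.columns)]
        return dummies.to_numpy(dtype=float)
    return col.to_numpy(dtype=float)[:, None]

def _term_block(data: pd.DataFrame, term: str) -> np.ndarray:
    parts = term.split(":")
    for v in parts:
        if v not in data.columns:
            raise KeyError(f"term {term!r} references unknown column {v!r}")
    block = _block_for(data, parts[0])
    for v in parts[1:]:
        nxt = _block_for(data, v)
        block = np.einsum("ni,nj->nij", block, nxt).reshape(len(data), -1)
    return block

def _term_vars(term: str) -> frozenset[str]:
    return frozenset(term.split(":"))

def _orth(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (SVD, rank-tolerant)."""
    if x.size == 0:
        return np.zeros((x.shape[0], 0))
    return linalg.orth(x)


# ----------------------------------------------------------------------
# fit container
# ----------------------------------------------------------------------

@dataclass
class RrppFit:
    """An RRPP linear-model fit on an (N, p) response.

    ``table`` has one row per term plus ``Residual`` and ``Total`` rows,
    with columns ``df, SS, MS, R2, F, Z, p_perm``; SS are Type II.
    """

    y: np.ndarray
    data: pd.DataFrame
    terms: list[str]
    table: pd.DataFrame
    coefficients: np.ndarray        # full-model OLS coefficients
    coef_names: list[str]
    n_perm: int
    seed: int | None
    ss_total: float
    df_residual: int
    _blocks: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    @property
    def r2(self) -> pd.Series:
        return self.table["R2"]


def _perm_indices(rng: np.random.Generator, n_perm: int, n: int) -> np.ndarray:
    idx = np.empty((n_perm, n), dtype=np.intp)
    for b in range(n_perm):
        idx[b] = rng.permutation(n)
    return idx


def rrpp_fit(
    y: np.ndarray,
    data: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> RrppFit:
    """Fit an OLS linear model to a multivariate response with RRPP tests.

    Parameters
    ----------
    y
        ``(N,)`` or ``(N, p)`` response (e.g. vectorized aligned shapes).
    data
        Metadata frame; non-numeric columns are treated as factors.
    terms
        Model terms, e.g. ``["watershed", "diet_ld", "watershed:diet_ld"]``.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n, p = y.shape
    if len(data) != n:
        raise ValueError("response and data lengths differ")
    data = data.reset_index(drop=True)

    blocks = {t: _term_block(data, t) for t in terms}
    ones = np.ones((n, 1))

    # aliasing check: every block must add its own rank on top of the rest
    x_all = np.hstack([ones] + [blocks[t] for t in terms])
    rank_full = np.linalg.matrix_rank(x_all)
    for t in terms:
        others = np.hstack([ones] + [blocks[s] for s in terms if s != t])
        if np.linalg.matrix_rank(others) == rank_full:
            raise ValueError(f"rank-deficient design: term {t!r} is aliased "
                             "with the remaining terms")
    df_res = n - rank_full
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom (N <= model df)")

    q_full = _orth(x_all)
    yc = y - y.mean(axis=0)
    ss_total = float((yc ** 2).sum())
    rss_full = float((y ** 2).sum() - ((q_full.T @ y) ** 2).sum())
    ms_res = rss_full / df_res
    # saturated / degenerate responses: F defined as 0 when both the term
    # SS and the residual vanish, +inf when only the residual does
    zero_tol = 1e-12 * max(ss_total, 1.0)

    def _f(ss_term, df_t, rss):
        ss_term = np.asarray(ss_term, dtype=float)
        rss = np.asarray(rss, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_term / df_t) / (rss / df_res)
        return np.where(rss <= zero_tol,
                        np.where(ss_term <= zero_tol, 0.0, np.inf), f)

    rng = np.random.default_rng(seed)
    perm_idx = _perm_indices(rng, n_perm, n)

    rows = []
    for t in terms:
        tv = _term_vars(t)
        reduced = [s for s in terms
                   if s != t and not (_term_vars(s) > tv)]
        x_red = np.hstack([ones] + [blocks[s] for s in reduced])
        q_red = _orth(x_red)
        z = blocks[t] - q_red @ (q_red.T @ blocks[t])
        q_t = _orth(z)
        df_t = q_t.shape[1]
        if df_t == 0:
            raise ValueError(f"term {t!r} contributes no estimable contrast")

        fitted = q_red @ (q_red.T @ y)
        resid = y - fitted
        ss_obs = float(((q_t.T @ y) ** 2).sum())
        f_obs = float(_f(ss_obs, df_t, rss_full))

        f_perm = np.empty(n_perm)
        chunk = max(1, _CHUNK_ELEMS // max(1, n * p))
        for start in range(0, n_perm, chunk):
            idx = perm_idx[start:start + chunk]
            yp = fitted[None, :, :] + resid[idx, :]
            a = np.einsum("nk,bnp->bkp", q_t, yp)
            ss_b = (a ** 2).sum(axis=(1, 2))
            g = np.einsum("nk,bnp->bkp", q_full, yp)
            rss_b = (yp ** 2).sum(axis=(1, 2)) - (g ** 2).sum(axis=(1, 2))
            f_perm[start:start + len(idx)] = _f(ss_b, df_t, rss_b)

        p_val = (1 + np.count_nonzero(f_perm >= f_obs)) / (n_perm + 1)
        f_dist = np.concatenate([[f_obs], f_perm])
        pos = (f_dist > 0) & np.isfinite(f_dist)
        if not np.isfinite(f_obs):
            z_eff = np.inf
        elif f_obs > 0 and pos.sum() > 2:
            logs = np.log(f_dist[pos])
            sd = logs.std()
            z_eff = (np.log(f_obs) - logs.mean()) / sd if sd > 0 else 0.0
        else:
            z_eff = 0.0
        rows.append({"term": t, "df": df_t, "SS": ss_obs, "MS": ss_obs / df_t,
                     "R2": ss_obs / ss_total if ss_total > 0 else 0.0,
                     "F": f_obs, "Z": z_eff, "p_perm": p_val})

    rows.append({"term": "Residual", "df": df_res, "SS": rss_full,
                 "MS": ms_res, "R2": rss_full / ss_total if ss_total else 0.0,
                 "F": np.nan, "Z": np.nan, "p_perm": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total,
                 "MS": np.nan, "R2": 1.0, "F": np.nan, "Z": np.nan,
                 "p_perm": np.nan})
    table = pd.DataFrame(rows).set_index("term")

    coef, *_ = np.linalg.lstsq(x_all, y, rcond=None)
    coef_names = ["(Intercept)"]
    for t in terms:
        coef_names += [f"{t}[{j}]" for j in range(blocks[t].shape[1])]

    return RrppFit(y=y, data=data, terms=list(terms), table=table,
                   coefficients=coef, coef_names=coef_names, n_perm=n_perm,
                   seed=seed, ss_total=ss_total, df_residual=df_res,
                   _blocks=blocks)


# ----------------------------------------------------------------------
# phenotype vectors
# ----------------------------------------------------------------------

@dataclass
class VectorComparison:
    """Pairwise comparison of per-group covariate slope vectors."""

    vectors: pd.DataFrame          # groups x p slope vectors
    angles: pd.DataFrame           # degrees, [0, 180], zero diagonal
    magnitude_diff: pd.DataFrame   # | |u| - |v| |
    p_angles: pd.DataFrame
    p_magnitude: pd.DataFrame
    magnitudes: pd.Series
    n_perm: int
    seed: int | None
    unstable_groups: list[str] = field(default_factory=list)


def _angles_deg(v: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(v, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = v / safe[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    ang = np.degrees(np.arccos(cos))
    np.fill_diagonal(ang, 0.0)
    return ang


def _batched_pair_stats(vecs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(B, G, p) slope vectors -> (B, G, G) angle and |Δmagnitude| arrays."""
    norms = np.linalg.norm(vecs, axis=2)
    safe = np.where(norms > 0, norms, 1.0)
    unit = vecs / safe[..., None]
    cos = np.clip(np.einsum("bgp,bhp->bgh", unit, unit), -1.0, 1.0)
    ang = np.degrees(np.arccos(cos))
    dmag = np.abs(norms[:, :, None] - norms[:, None, :])
    return ang, dmag


def _group_slope_weights(groups: pd.Series, x: np.ndarray
                         ) -> tuple[np.ndarray, list[str], list[str]]:
    """Weights W with slopes = W @ Y for per-group within-group regression."""
    levels = sorted(map(str, groups.unique()))
    n = len(groups)
    w = np.zeros((len(levels), n))
    unstable = []
    for gi, g in enumerate(levels):
        rows = np.flatnonzero((groups.astype(str) == g).to_numpy())
        xg = x[rows]
        sxx = ((xg - xg.mean()) ** 2).sum()
        if len(rows) < 3 or sxx == 0:
            unstable.append(g)
            if sxx == 0:
                continue
        w[gi, rows] = (xg - xg.mean()) / sxx
    return w, levels, unstable


def _pairwise_core(
    y: np.ndarray,
    groups: pd.Series,
    x: np.ndarray,
    n_perm: int,
    seed: int | None,
) -> VectorComparison:
    n, p = y.shape
    w, levels, unstable = _group_slope_weights(groups, x)
    if unstable:
        warnings.warn(f"groups {unstable} have < 3 specimens spanning the "
                      "covariate; their vectors are unstable", RuntimeWarning)
    slopes = w @ y
    ang_obs, dmag_obs = _batched_pair_stats(slopes[None])
    ang_obs, dmag_obs = ang_obs[0], dmag_obs[0]

    # null model: common slope (no group x covariate interaction)
    dummies = pd.get_dummies(groups.astype(str), drop_first=True)
    x_red = np.hstack([np.ones((n, 1)),
                       dummies.to_numpy(dtype=float), x[:, None]])
    q_red = _orth(x_red)
    fitted = q_red @ (q_red.T @ y)
    resid = y - fitted

    rng = np.random.default_rng(seed)
    ge_ang = np.zeros_like(ang_obs)
    ge_mag = np.zeros_like(dmag_obs)
    chunk = max(1, _CHUNK_ELEMS // max(1, n * p))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        idx = np.stack([rng.permutation(n) for _ in range(b)])
        yp = fitted[None] + resid[idx]
        sl = np.einsum("gn,bnp->bgp", w, yp)
        ang_b, dmag_b = _batched_pair_stats(sl)
        ge_ang += (ang_b >= ang_obs[None]).sum(axis=0)
        ge_mag += (dmag_b >= dmag_obs[None]).sum(axis=0)
        done += b
    p_ang = (1 + ge_ang) / (n_perm + 1)
    p_mag = (1 + ge_mag) / (n_perm + 1)
    np.fill_diagonal(p_ang, np.nan)
    np.fill_diagonal(p_mag, np.nan)

    def df(a: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(a, index=levels, columns=levels)

    return VectorComparison(
        vectors=pd.DataFrame(slopes, index=levels),
        angles=df(ang_obs),
        magnitude_diff=df(dmag_obs),
        p_angles=df(p_ang),
        p_magnitude=df(p_mag),
        magnitudes=pd.Series(np.linalg.norm(slopes, axis=1), index=levels),
        n_perm=n_perm,
        seed=seed,
        unstable_groups=unstable,
    )


def pairwise_vectors(
    fit: RrppFit,
    group: str,
    covariate: str,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> VectorComparison:
    """Pairwise angles and magnitude differences of per-group slope vectors.

    Per-group slope vectors are the trends through multivariate phenotype
    space per unit of the covariate; under perfectly parallel responses all
    pairwise angles are 0 deg.  p-values are RRPP permutations of the
    reduced (common-slope) model residuals.
    """
    if f"{group}:{covariate}" not in fit.terms and \
            f"{covariate}:{group}" not in fit.terms:
        raise ValueError(
            f"fit must contain the {group}:{covariate} interaction")
    groups = fit.data[group]
    x = fit.data[covariate].to_numpy(dtype=float)
    return _pairwise_core(fit.y, groups, x, n_perm, seed)


def compare_vectors_across_spaces(
    fit: RrppFit,
    covariate: str,
    dim: str = "space",
    within: str | None = None,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Angles/magnitudes between 2D and 3D trend vectors in a common space.

    ``fit`` is an RRPP fit on common-space responses whose data frame has a
    dimensionality factor (``dim``, e.g. ``"from_2d"``/``"from_3d"``).
    Returns the across-all-specimens comparison and, when ``within`` is
    given (e.g. watershed), a per-group table of 2D-vs-3D angles.
    """
    if dim not in fit.data.columns:
        raise ValueError(f"fit data lacks dimensionality column {dim!r}")
    x = fit.data[covariate].to_numpy(dtype=float)
    overall = _pairwise_core(fit.y, fit.data[dim], x, n_perm, seed)
    out = {"overall": overall}
    if within is not None:
        recs = []
        for gi, g in enumerate(sorted(fit.data[within].astype(str).unique())):
            rows = np.flatnonzero(
                (fit.data[within].astype(str) == g).to_numpy())
            sub = _pairwise_core(
                fit.y[rows], fit.data[dim].iloc[rows].reset_index(drop=True),
                x[rows], n_perm,
                None if seed is None else seed + 1 + gi)
            lv = sub.angles.index
            if len(lv) == 2:
                recs.append({
                    within: g,
                    "angle_deg": sub.angles.iloc[0, 1],
                    "p_angle": sub.p_angles.iloc[0, 1],
                    "magnitude_diff": sub.magnitude_diff.iloc[0, 1],
                    "p_magnitude": sub.p_magnitude.iloc[0, 1],
                })
        out["per_group"] = pd.DataFrame(recs)
    return out


# ----------------------------------------------------------------------
# distance-matrix statistics
# ----------------------------------------------------------------------

def mantel(
    d1: np.ndarray,
    d2: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the strictly-lower-triangle entries;
    p comes from jointly permuting row/column labels of ``d2``
    (one-sided, r* >= r).
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    for name, d in (("d1", d1), ("d2", d2)):
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError(f"{name} is not square")
        if not np.allclose(d, d.T):
            raise ValueError(f"{name} is not symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError(f"{name} does not have a zero diagonal")
    if d1.shape != d2.shape:
        raise ValueError("distance matrices differ in size")
    n = d1.shape[0]
    il = np.tril_indices(n, k=-1)
    v1 = d1[il]
    r_obs = float(np.corrcoef(v1, d2[il])[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = np.corrcoef(v1, d2[np.ix_(perm, perm)][il])[0, 1]
        if r_p >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return r_obs, p


def distance_correlation_2d3d(aligned2d, aligned3d) -> tuple[float, float]:
    """Pearson r of log10 per-specimen distances to the consensus shape.

    Each specimen's Procrustes distance from the consensus is computed in
    the 2D and the 3D space, log10-transformed and correlated.  The
    two-sided t-based p-value is returned but is not meaningful when the
    two datasets are derived from the same specimens.
    """
    d2 = np.linalg.norm(
        (aligned2d.coords - aligned2d.consensus[None]).reshape(
            aligned2d.coords.shape[0], -1), axis=1)
    d3 = np.linalg.norm(
        (aligned3d.coords - aligned3d.consensus[None]).reshape(
            aligned3d.coords.shape[0], -1), axis=1)
    if d2.shape != d3.shape:
        raise ValueError("samples have different specimen counts")
    keep = (d2 > 0) & (d3 > 0)
    if not keep.all():
        warnings.warn("dropping specimens identical to the consensus "
                      "(zero distance)", RuntimeWarning)
    r, p = stats.pearsonr(np.log10(d2[keep]), np.log10(d3[keep]))
    return float(r), float(p)


def disparity_ancova(
    distances: np.ndarray,
    data: pd.DataFrame,
    covariate: str,
    group: str = "watershed",
    n_perm: int = 999,
    seed: int | None = None,
) -> RrppFit:
    """ANCOVA of per-specimen 2D-3D disparity on a group and a covariate."""
    distances = np.asarray(distances, dtype=float)
    if distances.ndim != 1:
        raise ValueError("one distance per specimen expected")
    return rrpp_fit(distances[:, None], data, [group, covariate],
                    n_perm=n_perm, seed=seed)
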