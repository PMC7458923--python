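"""Distance-based multivariate tests: PERMANOVA and dispersion homogeneity.

PERMANOVA partitions the total sum of squared dissimilarities
(sum_{i<j} d_ij^2 / n = tr(G), with G the Gower-centered matrix) over an
ordered list of model terms using sequential (Type I) sums of squares:
ss_k = tr(H_k G) - tr(H_{k-1} G), where H_k is the hat matrix of the design
containing terms 1..k.  The pseudo-F for each term is tested by permuting
whole samples (raw rows, as adonis2 does by default), optionally restricted
within the levels of a ``strata`` factor, with the +1-corrected p-value
p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).

The dispersion test (Anderson's PERMDISP/betadisper idea) embeds the
dissimilarity matrix by PCoA keeping both real and imaginary axes, computes
each sample's distance to its group centroid with the imaginary correction
(squared distance = real part - imaginary part, clamped at zero), and runs a
one-way ANOVA on those distances, followed by Tukey HSD to count which group
pairs actually differ in spread.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .dissimilarity import DissimilarityMatrix
from .ordination import gower_center, pcoa
from .profile_io import ProfileError, SampleMetadata

logger = logging.getLogger(__name__)

_RANK_TOL = 1e-8


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaTable:
    terms: list[str]
    df: np.ndarray
    ss: np.ndarray
    r2: np.ndarray
    f: np.ndarray
    p: np.ndarray
    residual_df: int
    residual_ss: float
    total_df: int
    total_ss: float
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t, "Df": int(self.df[i]), "SumOfSqs": self.ss[i],
             "R2": self.r2[i], "F": self.f[i], "p": self.p[i]}
            for i, t in enumerate(self.terms)
        ]
        rows.append({"term": "Residual", "Df": self.residual_df,
                     "SumOfSqs": self.residual_ss,
                     "R2": self.residual_ss / self.total_ss,
                     "F": np.nan, "p": np.nan})
        rows.append({"term": "Total", "Df": self.total_df,
                     "SumOfSqs": self.total_ss, "R2": 1.0,
                     "F": np.nan, "p": np.nan})
        return pd.DataFrame(rows)


def _main_columns(meta: pd.DataFrame, factor: str, numeric: bool) -> np.ndarray:
    """Full-rank treatment-coded columns (no intercept) for one factor."""
    values = meta[factor]
    if numeric:
        return values.to_numpy(dtype=float)[:, None]
    levels = sorted(pd.unique(values))
    # drop the first level: treatment coding against the reference
    return np.column_stack([(values == lv).to_numpy(float) for lv in levels[1:]]) \
        if len(levels) > 1 else np.zeros((len(values), 0))


def build_design(
    meta: pd.DataFrame,
    terms: Sequence[str],
    numeric_factors: Sequence[str] = (),
) -> dict[str, np.ndarray]:
    """Design columns per term.  Interaction terms use ':' between factors and
    are products of the treatment-coded main-effect columns."""
    numeric = set(numeric_factors)
    mains: dict[str, np.ndarray] = {}
    blocks: dict[str, np.ndarray] = {}
    for term in terms:
        factors = term.split(":")
        for f in factors:
            if f not in meta.columns:
                raise ProfileError(f"unknown factor {f!r} in term {term!r}")
            if f not in mains:
                mains[f] = _main_columns(meta, f, f in numeric)
        cols = mains[factors[0]]
        for f in factors[1:]:
            cols = np.einsum("ni,nj->nij", cols, mains[f]).reshape(len(meta), -1)
        blocks[term] = cols
    return blocks


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection onto the column space of x, and its rank."""
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    keep = diag > _RANK_TOL * max(diag.max(), 1.0)
    q = q[:, keep]
    return q @ q.T, int(keep.sum())


def _strata_permutation(
    rng: np.random.Generator, strata_codes: Optional[np.ndarray], n: int
) -> np.ndarray:
    if strata_codes is None:
        return rng.permutation(n)
    perm = np.arange(n)
    for code in np.unique(strata_codes):
        idx = np.nonzero(strata_codes == code)[0]
        perm[idx] = idx[rng.permutation(len(idx))]
    return perm


def permanova(
    d: DissimilarityMatrix,
    meta: SampleMetadata,
    terms: Sequence[str] = (
        "year", "species", "sex",
        "year:species", "year:sex", "species:sex", "year:species:sex",
    ),
    n_perm: int = 9999,
    strata: Optional[str] = "year",
    numeric_factors: Sequence[str] = (),
    seed: int = 0,
    permutations: Optional[np.ndarray] = None,
) -> PermanovaTable:
    """Sequential-SS multi-factor PERMANOVA on a dissimilarity matrix.

    ``terms`` is an ordered list of mains and interactions (Type I SS is
    order-dependent, and the order used is reported).  ``strata`` restricts
    permutations within the levels of that metadata factor; ``numeric_factors``
    lists factors to code as a single numeric column (df = 1) instead of
    categorically.  ``permutations`` may supply an explicit (n_perm, n) array
    of row permutations, e.g. for exhaustive enumeration.
    """
    if list(meta.sample_ids) != list(d.sample_ids):
        raise ProfileError("metadata sample ids do not match dissimilarity matrix")
    n = d.n
    g = gower_center(d.values)
    total_ss = float(np.trace(g))
    blocks = build_design(meta.frame, terms, numeric_factors)

    if strata is not None:
        codes = meta.frame[strata].to_numpy()
        sizes = pd.Series(codes).value_counts()
        if (sizes == 1).any():
            warnings.warn(f"strata {strata!r} has singleton levels (unpermutable samples)")
    else:
        codes = None

    # nested hat matrices H_0 (intercept) .. H_K
    ones = np.ones((n, 1))
    hats = [ones @ ones.T / n]
    ranks = [1]
    x = ones
    for term in terms:
        x = np.hstack([x, blocks[term]])
        h, r = _hat(x)
        if r == ranks[-1]:
            raise ProfileError(f"term {term!r} is aliased with earlier terms (singular design)")
        hats.append(h)
        ranks.append(r)
    df = np.diff(ranks)
    residual_df = n - ranks[-1]
    if residual_df < 1:
        raise ProfileError("no residual degrees of freedom")

    eps = 1e-12 * max(total_ss, 1.0)

    def term_stats(g_mat: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
        traces = np.array([float(np.sum(h * g_mat)) for h in hats])  # tr(H G), H symmetric
        ss = np.diff(traces)
        ss_res = total_ss - traces[-1]
        if ss_res > eps:
            f_vals = (ss / df) / (ss_res / residual_df)
        else:  # no residual variation: define F = 0 so p comes out 1
            f_vals = np.zeros(len(ss))
        return ss, ss_res, f_vals

    ss, ss_res, f_obs = term_stats(g)

    if permutations is not None:
        perms = np.asarray(permutations, dtype=int)
        n_perm = perms.shape[0]
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([_strata_permutation(rng, codes, n) for _ in range(n_perm)])

    exceed = np.zeros(len(terms))
    for perm in perms:
        g_perm = g[np.ix_(perm, perm)]
        _, _, f_perm = term_stats(g_perm)
        exceed += f_perm >= f_obs
    p = (1.0 + exceed) / (1.0 + n_perm)

    return PermanovaTable(
        terms=list(terms), df=df.astype(int), ss=ss,
        r2=ss / total_ss if total_ss > eps else np.zeros(len(ss)),
        f=f_obs, p=p, residual_df=int(residual_df), residual_ss=float(ss_res),
        total_df=n - 1, total_ss=total_ss, n_perm=int(n_perm),
    )


# ---------------------------------------------------------------------------
# PERMDISP + Tukey


@dataclass
class DispersionResult:
    sample_ids: list[str]
    groups: np.ndarray                 # group label per retained sample
    distances: np.ndarray              # distance to own group centroid
    anova_f: float
    anova_p: float
    degenerate: bool = False
    excluded_samples: list[str] = None  # singleton-group samples, if any
    tukey_table: Optional[pd.DataFrame] = None
    percent_homogeneous: Optional[float] = None


def permdisp(d: DissimilarityMatrix, groups: Sequence) -> DispersionResult:
    """Distance-to-centroid dispersion analysis in full PCoA space.

    Squared distances are corrected by the imaginary axes
    (real-part squared distance minus imaginary-part squared distance) and
    clamped at zero with a warning when the correction overshoots.  Groups of
    size 1 are excluded with a warning.  Returns the one-way ANOVA F and its
    classical F-distribution p-value on the distances.
    """
    groups = np.asarray(groups)
    if len(groups) != d.n:
        raise ProfileError("group labels do not match matrix size")
    labels, counts = np.unique(groups, return_counts=True)
    small = labels[counts < 2]
    excluded: list[str] = []
    keep = np.ones(d.n, dtype=bool)
    if small.size:
        keep = ~np.isin(groups, small)
        excluded = [sid for sid, k in zip(d.sample_ids, keep) if not k]
        warnings.warn(f"excluding singleton groups: {list(small)}")
    labels = [lv for lv in labels if lv not in set(small)]
    if len(labels) < 2:
        raise ProfileError("need at least 2 groups of size >= 2")

    res = pcoa(d)
    real = res.coordinates
    imag = res.imaginary_coordinates
    dist2 = np.full(d.n, np.nan)
    n_clamped = 0
    for lv in labels:
        idx = np.nonzero((groups == lv) & keep)[0]
        c_real = real[idx].mean(axis=0)
        c_imag = imag[idx].mean(axis=0) if imag.shape[1] else np.zeros(0)
        sq = ((real[idx] - c_real) ** 2).sum(axis=1)
        if imag.shape[1]:
            sq = sq - ((imag[idx] - c_imag) ** 2).sum(axis=1)
        n_clamped += int((sq < 0).sum())
        dist2[idx] = np.maximum(sq, 0.0)
    if n_clamped:
        warnings.warn(f"{n_clamped} negative corrected squared distances clamped to 0")

    mask = keep
    dists = np.sqrt(dist2[mask])
    glab = groups[mask]
    by_group = [dists[glab == lv] for lv in labels]
    if all(np.allclose(v, 0) for v in by_group):
        return DispersionResult(
            [s for s, k in zip(d.sample_ids, keep) if k], glab, dists,
            anova_f=np.nan, anova_p=np.nan, degenerate=True,
            excluded_samples=excluded,
        )
    f_stat, p_val = stats.f_oneway(*by_group)
    return DispersionResult(
        [s for s, k in zip(d.sample_ids, keep) if k], glab, dists,
        anova_f=float(f_stat), anova_p=float(p_val),
        excluded_samples=excluded,
    )


def tukey_hsd_dispersion(
    disp: DispersionResult, alpha: float = 0.05
) -> tuple[pd.DataFrame, float]:
    """Studentized-range (Tukey HSD) pairwise comparison of mean
    distance-to-centroid; returns the pair table and the fraction of pairs
    NOT significantly different at ``alpha`` (the homogeneity percentage)."""
    labels = np.unique(disp.groups)
    if len(labels) < 2:
        raise ProfileError("need at least 2 groups for Tukey HSD")
    res = pairwise_tukeyhsd(disp.distances, disp.groups.astype(str), alpha=alpha)
    table = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    table["p-adj"] = res.pvalues
    n_pairs = len(table)
    assert n_pairs == len(labels) * (len(labels) - 1) // 2
    percent_homogeneous = float((res.pvalues > alpha).mean())
    return table, percent_homogeneous


def exhaustive_permutations(n: int) -> np.ndarray:
    """All n! row permutations (for small-n enumeration oracles)."""
    return np.array(list(itertools.permutations(range(n))), dtype=int)
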