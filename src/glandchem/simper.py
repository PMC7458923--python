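"""SIMPER: decomposition of between-group Bray-Curtis dissimilarity.

For every between-group sample pair (j, k), compound i contributes

    c_ijk = |x_ij - x_ik| / sum_i (x_ij + x_ik),

and summing c_ijk over compounds gives exactly the pair's Bray-Curtis
dissimilarity.  The per-compound average contribution over all between-group
pairs therefore sums to the mean between-group dissimilarity — the key
conservation identity this module asserts.  Significance of each compound's
contribution is assessed by permuting group labels (one-sided, "contributes
more than expected by chance"), with a Bonferroni flag at
alpha = 0.05 / p_total over the total number of identified compounds.

Markers consistently significant in every analyzed season are intersected
into a consistent set, and a PCA on the marker submatrix ranks which marker
carries the most variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .profile_io import CompoundTable, ProfileError

logger = logging.getLogger(__name__)


@dataclass
class SimperResult:
    compound_ids: list[str]
    average_contribution: np.ndarray   # fraction of dissimilarity, >= 0
    contribution_sd: np.ndarray        # SD over between-group pairs
    p_perm: np.ndarray
    p_bonferroni_significant: np.ndarray  # bool at alpha = 0.05 / p_total
    mean_between_dissimilarity: float
    n_perm: int
    p_total: int

    def to_frame(self) -> pd.DataFrame:
        order = np.argsort(self.average_contribution)[::-1]
        cum = np.cumsum(self.average_contribution[order])
        total = self.mean_between_dissimilarity
        return pd.DataFrame(
            {
                "compound_id": [self.compound_ids[i] for i in order],
                "average_contribution": self.average_contribution[order],
                "contribution_pct": 100 * self.average_contribution[order] / total
                if total > 0 else 0.0,
                "contribution_sd": self.contribution_sd[order],
                "cumulative_fraction": cum / total if total > 0 else cum,
                "p_perm": self.p_perm[order],
                "bonferroni_significant": self.p_bonferroni_significant[order],
            }
        )

    def significant(self, alpha: float) -> list[str]:
        return [c for c, p in zip(self.compound_ids, self.p_perm) if p < alpha]


@dataclass
class ConsistentMarkerSet:
    compound_ids: list[str]                 # significant in every season
    per_season_p: pd.DataFrame              # seasons x compounds p-values
    bonferroni_consistent: list[str]        # same intersection under Bonferroni
    alpha: float


@dataclass
class PCASelection:
    compound_ids: list[str]
    loadings: pd.DataFrame        # compounds x retained components
    variance_explained: np.ndarray
    n_retained: int
    top_variance_compound: str


def _mean_contributions(x_a: np.ndarray, x_b: np.ndarray) -> np.ndarray:
    """Per-compound mean contribution over all between-group pairs."""
    denom = x_a.sum(axis=1)[:, None] + x_b.sum(axis=1)[None, :]  # (nA, nB)
    diff = np.abs(x_a[:, None, :] - x_b[None, :, :])             # (nA, nB, p)
    return (diff / denom[:, :, None]).mean(axis=(0, 1))


def simper(
    table: CompoundTable,
    groups: Sequence,
    n_perm: int = 999,
    seed: int = 0,
    p_total: Optional[int] = None,
) -> SimperResult:
    """SIMPER between the two levels of ``groups``.

    ``p_total`` is the Bonferroni divisor (defaults to the table's compound
    count — the total number of identified molecules, not the number tested).
    """
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ProfileError(f"SIMPER needs exactly two groups, got {list(levels)}")
    idx_a = np.nonzero(groups == levels[0])[0]
    idx_b = np.nonzero(groups == levels[1])[0]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ProfileError("each group needs at least 2 samples")
    x = table.abundances
    sums = x.sum(axis=1)
    if np.any(sums <= 0):
        raise ProfileError("all-zero sample row")

    def oriented(mask: np.ndarray) -> np.ndarray:
        # fix the orientation to the side holding sample 0 so that relabeling
        # A<->B reproduces bit-identical floating-point sums
        if not mask[0]:
            mask = ~mask
        return mask

    mask_obs = oriented(groups == levels[0])
    x_a, x_b = x[mask_obs], x[~mask_obs]
    denom = x_a.sum(axis=1)[:, None] + x_b.sum(axis=1)[None, :]
    contrib = np.abs(x_a[:, None, :] - x_b[None, :, :]) / denom[:, :, None]
    avg = contrib.mean(axis=(0, 1))
    sd = contrib.reshape(-1, x.shape[1]).std(axis=0, ddof=1)
    mean_bc = float(avg.sum())

    rng = np.random.default_rng(seed)
    exceed = np.zeros(x.shape[1])
    n = len(groups)
    for _ in range(n_perm):
        # permute the labels over samples; the statistic is symmetric in the
        # two groups, so every permutation draw survives relabeling intact
        mask = oriented((groups == levels[0])[rng.permutation(n)])
        avg_perm = _mean_contributions(x[mask], x[~mask])
        exceed += avg_perm >= avg
    p_perm = (1.0 + exceed) / (1.0 + n_perm)

    p_total = table.n_compounds if p_total is None else int(p_total)
    bonf = p_perm < (0.05 / p_total)
    return SimperResult(
        compound_ids=table.compound_ids,
        average_contribution=avg,
        contribution_sd=sd,
        p_perm=p_perm,
        p_bonferroni_significant=bonf,
        mean_between_dissimilarity=mean_bc,
        n_perm=int(n_perm),
        p_total=p_total,
    )


def consistent_markers(
    per_season_results: Mapping, alpha: float = 0.01
) -> ConsistentMarkerSet:
    """Compounds with permutation p < ``alpha`` in every season, plus the same
    intersection under the Bonferroni flags (both views are reported because
    either convention is defensible)."""
    if len(per_season_results) < 2:
        raise ProfileError("need results from at least 2 seasons")
    seasons = list(per_season_results)
    sig_sets = [set(per_season_results[s].significant(alpha)) for s in seasons]
    consistent = set.intersection(*sig_sets)
    bonf_sets = [
        {
            c
            for c, flag in zip(r.compound_ids, r.p_bonferroni_significant)
            if flag
        }
        for r in per_season_results.values()
    ]
    bonf_consistent = set.intersection(*bonf_sets)
    if not consistent:
        warnings.warn("no compound is significant in every season")
    first = per_season_results[seasons[0]]
    p_frame = pd.DataFrame(
        {s: per_season_results[s].p_perm for s in seasons},
        index=first.compound_ids,
    ).T
    order = first.compound_ids
    return ConsistentMarkerSet(
        compound_ids=[c for c in order if c in consistent],
        per_season_p=p_frame,
        bonferroni_consistent=[c for c in order if c in bonf_consistent],
        alpha=alpha,
    )


def pca_select(
    table: CompoundTable,
    marker_ids: Sequence[str],
    cumulative_threshold: float = 0.75,
    correlation_mode: bool = True,
) -> PCASelection:
    """PCA of the marker-compound submatrix.

    Correlation mode (default) standardizes columns to unit variance because
    abundances span scales; covariance mode is available.  Components are
    retained while their cumulative variance stays <= the threshold (at least
    one).  ``top_variance_compound`` is the compound with the largest absolute
    loading on the first component.
    """
    marker_ids = list(marker_ids)
    if len(marker_ids) < 2:
        raise ProfileError("PCA selection needs at least 2 marker compounds")
    if table.n_samples < 3:
        raise ProfileError("PCA selection needs at least 3 samples")
    col_idx = {c: j for j, c in enumerate(table.compound_ids)}
    missing = [c for c in marker_ids if c not in col_idx]
    if missing:
        raise ProfileError(f"markers not in table: {missing}")
    x = table.abundances[:, [col_idx[c] for c in marker_ids]]
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(marker_ids, keep) if not k]
        warnings.warn(f"dropping constant marker columns: {dropped}")
        marker_ids = [c for c, k in zip(marker_ids, keep) if k]
        x, sd = x[:, keep], sd[keep]
    if x.shape[1] < 2:
        raise ProfileError("fewer than 2 non-constant marker compounds")
    xc = x - x.mean(axis=0)
    if correlation_mode:
        xc = xc / sd
    model = PCA()
    model.fit(xc)
    var = model.explained_variance_ratio_
    cum = np.cumsum(var)
    n_keep = max(1, int((cum <= cumulative_threshold + 1e-12).sum()))
    loadings = pd.DataFrame(
        model.components_[:n_keep].T,
        index=marker_ids,
        columns=[f"PC{i + 1}" for i in range(n_keep)],
    )
    top = marker_ids[int(np.argmax(np.abs(model.components_[0])))]
    return PCASelection(
        compound_ids=marker_ids,
        loadings=loadings,
        variance_explained=var[:n_keep],
        n_retained=n_keep,
        top_variance_compound=top,
    )
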