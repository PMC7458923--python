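"""Chemical richness and per-individual chemical diversity.

Chemical richness R_chem of a sample set is the number of compounds detected
(strictly positive abundance) in at least one sample.  Chemical diversity
H_chem of one profile is the Shannon entropy of its compound relative
abundances, H = -sum p_i ln(p_i) with p_i = value / row sum, using the
natural log and the convention 0 * ln(0) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .profile_io import CompoundTable, ProfileError, SampleMetadata


@dataclass(frozen=True)
class DiversitySummary:
    group: tuple
    n: int
    r_chem: int
    h_mean: float
    h_sd: Optional[float]  # None when n == 1 (sample SD undefined)


def h_chem(profile: np.ndarray) -> float:
    """Shannon diversity of one abundance row (percent or proportion —
    invariant under rescaling)."""
    x = np.asarray(profile, dtype=float)
    if np.any(x < 0):
        raise ProfileError("negative abundance in profile")
    total = x.sum()
    if total <= 0:
        raise ProfileError("all-zero profile has undefined diversity")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def h_chem_rows(table: CompoundTable) -> np.ndarray:
    return np.array([h_chem(row) for row in table.abundances])


def r_chem(table: CompoundTable) -> int:
    """Number of compounds with positive abundance in at least one sample."""
    if table.n_samples == 0:
        raise ProfileError("empty sample set has no richness")
    return int(np.any(table.abundances > 0, axis=0).sum())


def summarize_by_group(
    table: CompoundTable,
    meta: SampleMetadata,
    keys: Sequence[str] = ("year", "species", "sex"),
) -> list[DiversitySummary]:
    """Per-group richness and mean +/- SD (n-1 denominator) of H_chem.

    Groups are the distinct key combinations present in the metadata, in
    sorted order; empty groups cannot occur by construction.
    """
    meta.check_aligned(table)
    h = h_chem_rows(table)
    key_frame = meta.frame[list(keys)]
    out: list[DiversitySummary] = []
    for group, idx in sorted(key_frame.groupby(list(keys), sort=True).groups.items()):
        pos = key_frame.index.get_indexer(idx)
        sub = CompoundTable(
            [table.sample_ids[i] for i in pos],
            list(table.annotations),
            table.abundances[pos],
        )
        hv = h[pos]
        group_key = group if isinstance(group, tuple) else (group,)
        out.append(
            DiversitySummary(
                group=group_key,
                n=len(pos),
                r_chem=r_chem(sub),
                h_mean=float(hv.mean()),
                h_sd=float(hv.std(ddof=1)) if len(pos) > 1 else None,
            )
        )
    return out


def summary_frame(summaries: list[DiversitySummary], keys=("year", "species", "sex")) -> pd.DataFrame:
    """Tabular view (one row per group, H reported to 2 decimals alongside
    full-precision columns)."""
    rows = []
    for s in summaries:
        row = dict(zip(keys, s.group))
        row.update(
            n=s.n,
            r_chem=s.r_chem,
            h_mean=s.h_mean,
            h_sd=s.h_sd,
            h_display=f"{s.h_mean:.2f}" + (f" (± {s.h_sd:.2f})" if s.h_sd is not None else " (NA)"),
        )
        rows.append(row)
    return pd.DataFrame(rows)
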