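"""Shared data model and I/O for compound relative-abundance tables.

A study dataset consists of a samples x compounds matrix of percent relative
abundances (each row of an identified gland-secretion profile sums to 100),
optional per-compound annotations (name, PubChem ChemID, molecular class,
spectral match score), and a per-sample metadata table carrying the design
factors ``species``, ``sex``, ``year`` and ``season``.

Rows are samples; values are percentages, not proportions.  Proportions
``p_i = value / 100`` are derived where a formula needs them.  Missing cells
in an input matrix are read as zeros (absence of a compound in a profile)
with a logged warning count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Controlled vocabulary of molecular classes.
MOL_CLASSES = (
    "fatty acid",
    "fatty alcohol",
    "alkane",
    "alkene",
    "sterol",
    "pregnane steroid",
    "aldehyde",
    "other",
)

SPECIES_LEVELS = ("marthae", "subcristatus")
SEX_LEVELS = ("F", "M")
SEASON_LEVELS = ("rs", "nrs")

ROW_SUM_TOL = 1e-6


class ProfileError(ValueError):
    """Raised for invalid compound tables or metadata."""


@dataclass(frozen=True)
class CompoundAnnotation:
    """Identity and provenance of one compound column.

    ``compound_id`` is the identity token used everywhere; ``chem_id`` (a
    PubChem identifier) is annotation only, since distinct compounds can share
    names across classes.  ``match_score`` is the spectral-library similarity
    in percent, when known.
    """

    compound_id: str
    name: str = ""
    chem_id: Optional[int] = None
    mol_class: str = "other"
    match_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mol_class not in MOL_CLASSES:
            raise ProfileError(
                f"unknown molecular class {self.mol_class!r} for "
                f"{self.compound_id!r}; expected one of {MOL_CLASSES}"
            )
        if self.match_score is not None and not (0.0 <= self.match_score <= 100.0):
            raise ProfileError(
                f"match_score {self.match_score} for {self.compound_id!r} "
                "outside [0, 100]"
            )


@dataclass
class CompoundTable:
    """Samples x compounds matrix of non-negative percent relative abundances."""

    sample_ids: list[str]
    annotations: list[CompoundAnnotation]
    abundances: np.ndarray  # shape (n_samples, n_compounds)

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        n, p = self.abundances.shape
        if len(self.sample_ids) != n:
            raise ProfileError(
                f"{len(self.sample_ids)} sample ids for {n} matrix rows"
            )
        if len(self.annotations) != p:
            raise ProfileError(
                f"{len(self.annotations)} annotations for {p} matrix columns"
            )
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ProfileError(f"duplicate sample ids: {sorted(dup)}")
        dup = _duplicates(self.compound_ids)
        if dup:
            raise ProfileError(f"duplicate compound ids: {sorted(dup)}")
        if np.any(self.abundances < 0):
            i, j = np.argwhere(self.abundances < 0)[0]
            raise ProfileError(
                f"negative abundance at sample {self.sample_ids[i]!r}, "
                f"compound {self.compound_ids[j]!r}"
            )
        if not np.all(np.isfinite(self.abundances)):
            raise ProfileError("non-finite abundance values")

    @property
    def compound_ids(self) -> list[str]:
        return [a.compound_id for a in self.annotations]

    @property
    def n_samples(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_compounds(self) -> int:
        return self.abundances.shape[1]

    def is_normalized(self, tol: float = ROW_SUM_TOL) -> bool:
        return bool(np.all(np.abs(self.abundances.sum(axis=1) - 100.0) <= tol))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.abundances, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.compound_ids,
        )


@dataclass
class SampleMetadata:
    """Per-sample design factors aligned with a :class:`CompoundTable`."""

    frame: pd.DataFrame  # index sample_id; columns species, sex, year, season

    def __post_init__(self) -> None:
        required = {"species", "sex", "year", "season"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ProfileError(f"metadata missing columns: {sorted(missing)}")
        if self.frame.index.has_duplicates:
            raise ProfileError("duplicate sample ids in metadata")
        self.frame = self.frame.copy()
        self.frame["year"] = self.frame["year"].astype(int)
        for col, levels in (
            ("species", SPECIES_LEVELS),
            ("sex", SEX_LEVELS),
            ("season", SEASON_LEVELS),
        ):
            bad = set(self.frame[col]) - set(levels)
            if bad:
                raise ProfileError(
                    f"metadata column {col!r} has values {sorted(bad)} outside "
                    f"{levels}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def check_aligned(self, table: CompoundTable) -> None:
        if self.sample_ids != table.sample_ids:
            raise ProfileError("metadata sample ids do not match table")

    def __getitem__(self, col: str) -> pd.Series:
        return self.frame[col]


def _duplicates(items: Sequence) -> set:
    seen, dup = set(), set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _sep_for(path: Union[str, Path]) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


# ---------------------------------------------------------------------------
# readers / writers


def read_compound_table(
    matrix_path: Union[str, Path],
    annotation_path: Optional[Union[str, Path]] = None,
) -> CompoundTable:
    """Read a compound matrix (CSV/TSV; header = compound ids, first column =
    sample id) and optional annotation CSV into a validated table.

    Missing cells are read as 0 with a logged warning count.  Duplicate ids or
    negative values are hard errors.
    """
    sep = _sep_for(matrix_path)
    with open(matrix_path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dup_cols = _duplicates(header)
    if dup_cols:
        raise ProfileError(f"duplicate compound ids in header: {sorted(dup_cols)}")
    df = pd.read_csv(matrix_path, sep=sep, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    dup_rows = _duplicates(list(df.index))
    if dup_rows:
        raise ProfileError(f"duplicate sample ids: {sorted(dup_rows)}")
    n_missing = int(df.isna().sum().sum())
    if n_missing:
        logger.warning("read %d missing cells as 0 from %s", n_missing, matrix_path)
        df = df.fillna(0.0)
    values = df.to_numpy(dtype=float)
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise ProfileError(
            f"negative value at sample {df.index[i]!r}, compound "
            f"{df.columns[j]!r} in {matrix_path}"
        )
    annotations = _read_annotations(annotation_path, list(df.columns))
    return CompoundTable(list(df.index), annotations, values)


def _read_annotations(
    annotation_path: Optional[Union[str, Path]], compound_ids: list[str]
) -> list[CompoundAnnotation]:
    if annotation_path is None:
        return [CompoundAnnotation(cid) for cid in compound_ids]
    ann = pd.read_csv(annotation_path, sep=_sep_for(annotation_path))
    ann["compound_id"] = ann["compound_id"].astype(str)
    by_id = {}
    for _, row in ann.iterrows():
        chem = row.get("chem_id")
        score = row.get("match_score")
        by_id[row["compound_id"]] = CompoundAnnotation(
            compound_id=row["compound_id"],
            name=str(row.get("name", "") or ""),
            chem_id=None if pd.isna(chem) else int(chem),
            mol_class=row.get("mol_class", "other") or "other",
            match_score=None if pd.isna(score) else float(score),
        )
    missing = [c for c in compound_ids if c not in by_id]
    if missing:
        raise ProfileError(f"annotations missing for compounds: {missing}")
    return [by_id[c] for c in compound_ids]


def write_compound_table(
    table: CompoundTable,
    matrix_path: Union[str, Path],
    annotation_path: Optional[Union[str, Path]] = None,
) -> None:
    """Write matrix (and optionally annotations) at full precision so that
    read -> write -> read round-trips bit-identically."""
    df = table.to_frame()
    df.to_csv(matrix_path, sep=_sep_for(matrix_path), float_format="%.17g")
    if annotation_path is not None:
        rows = [
            {
                "compound_id": a.compound_id,
                "name": a.name,
                "chem_id": a.chem_id,
                "mol_class": a.mol_class,
                "match_score": a.match_score,
            }
            for a in table.annotations
        ]
        pd.DataFrame(rows).to_csv(annotation_path, index=False)


def read_metadata(path: Union[str, Path]) -> SampleMetadata:
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ProfileError("metadata file lacks a sample_id column")
    return SampleMetadata(df.set_index("sample_id"))


def write_metadata(meta: SampleMetadata, path: Union[str, Path]) -> None:
    meta.frame.to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# transformations


def normalize_rows(table: CompoundTable) -> CompoundTable:
    """Rescale every row to sum to 100 percent.  All-zero rows are an error."""
    sums = table.abundances.sum(axis=1)
    zero = np.nonzero(sums <= 0)[0]
    if zero.size:
        raise ProfileError(
            f"all-zero abundance row for sample {table.sample_ids[zero[0]]!r}"
        )
    values = table.abundances * (100.0 / sums[:, None])
    return CompoundTable(list(table.sample_ids), list(table.annotations), values)


def filter_by_match_score(table: CompoundTable, threshold: float) -> CompoundTable:
    """Drop compounds whose spectral match score is strictly below
    ``threshold`` percent; compounds without a score are retained.  Rows are
    re-normalized afterwards."""
    if not (0.0 <= threshold <= 100.0):
        raise ProfileError(f"threshold {threshold} outside [0, 100]")
    keep = [
        j
        for j, a in enumerate(table.annotations)
        if a.match_score is None or a.match_score >= threshold
    ]
    dropped = [a.compound_id for j, a in enumerate(table.annotations) if j not in set(keep)]
    if not keep:
        raise ProfileError("no compounds retained by match-score filter")
    if dropped:
        logger.info("match-score filter dropped %d compounds: %s", len(dropped), dropped)
    out = CompoundTable(
        list(table.sample_ids),
        [table.annotations[j] for j in keep],
        table.abundances[:, keep],
    )
    return normalize_rows(out)


Predicate = Union[str, Callable[[pd.DataFrame], "pd.Series"]]


def subset(
    table: CompoundTable, meta: SampleMetadata, predicate: Predicate
) -> tuple[CompoundTable, SampleMetadata]:
    """Select samples by a metadata predicate (a pandas query string such as
    ``"year in (2012, 2014)"`` or a callable returning a boolean mask).

    Matched rows keep their original order.  Compound columns that become
    all-zero in the subset are retained so compound indices stay aligned
    across subsets.
    """
    meta.check_aligned(table)
    if callable(predicate):
        mask = np.asarray(predicate(meta.frame), dtype=bool)
    else:
        mask = meta.frame.eval(predicate).to_numpy(dtype=bool)
    if mask.shape != (table.n_samples,):
        raise ProfileError("predicate did not produce one boolean per sample")
    if not mask.any():
        raise ProfileError("subset predicate matched no samples")
    idx = np.nonzero(mask)[0]
    sub_table = CompoundTable(
        [table.sample_ids[i] for i in idx],
        list(table.annotations),
        table.abundances[idx],
    )
    sub_meta = SampleMetadata(meta.frame.iloc[idx])
    return sub_table, sub_meta
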