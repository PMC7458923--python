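"""Synthetic compound-profile generator.

Emulates the statistical structure of a two-species femoral-gland secretion
study: a fixed year x species x sex sampling design (227 individuals in 11
non-empty cells across three field seasons), ~113 GC-MS compounds spanning
the usual lipophilic classes, sparse presence/absence, compositional rows
(percent relative abundance closed to 100), and planted multiplicative
species/sex/year effects on small sets of discriminatory compounds.

The generative model per sample s (in design cell g) and compound i is

    latent intensity  y = exp(m_i + effects(g, i) + eps),  eps ~ N(0, sigma^2)
    presence          z ~ Bernoulli(pi_i(g))
    raw amount        z * y,   then the row is closed to percent (sum 100).

Effects act on the log-intensity *before* closure, so a planted marker
perturbs the relative abundance of every compound (compositional leakage),
as in real closed data.  Factor levels carry half the log-effect with
opposite signs (e.g. marthae +delta/2, subcristatus -delta/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .profile_io import (
    MOL_CLASSES,
    CompoundAnnotation,
    CompoundTable,
    SampleMetadata,
)

#: Sampling design: (year, species, sex) -> number of individuals.
STUDY_CELL_COUNTS: dict[tuple[int, str, str], int] = {
    (2012, "marthae", "F"): 24,
    (2012, "marthae", "M"): 54,
    (2012, "subcristatus", "F"): 31,
    (2012, "subcristatus", "M"): 41,
    (2014, "marthae", "F"): 15,
    (2014, "marthae", "M"): 15,
    (2014, "subcristatus", "F"): 13,
    (2014, "subcristatus", "M"): 17,
    (2015, "marthae", "F"): 3,
    (2015, "marthae", "M"): 5,
    (2015, "subcristatus", "M"): 9,
}

#: Years 2012/2014 were reproductive-season collections, 2015 was not.
SEASON_BY_YEAR = {2012: "rs", 2014: "rs", 2015: "nrs"}

#: Rough molecular-class composition of a secretion profile (fractions of
#: compounds per class; lipids dominate).
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "fatty acid": 0.34,
    "fatty alcohol": 0.16,
    "alkane": 0.12,
    "alkene": 0.10,
    "sterol": 0.10,
    "pregnane steroid": 0.06,
    "aldehyde": 0.05,
    "other": 0.07,
}

_MAX_REDRAWS = 100


@dataclass
class SyntheticSpec:
    """Full parameterization of one synthetic study dataset.

    Effect sets hold compound indices; the matching ``delta_*`` is the full
    between-level difference in log-intensity (a level gets +delta/2 or
    -delta/2).  ``presence_prob`` is the per-compound base detection
    probability; ``presence_year_shift`` optionally moves all of them on the
    logit scale per year.
    """

    cell_counts: Mapping[tuple[int, str, str], int]
    n_compounds: int
    class_proportions: Mapping[str, float]
    baseline_log_mean: np.ndarray  # (p,) per-compound m_i
    species_effect: tuple[int, ...] = ()
    delta_species: float = 0.0
    sex_effect: tuple[int, ...] = ()
    delta_sex: float = 0.0
    year_effect: tuple[int, ...] = ()
    delta_year: float = 0.0
    presence_prob: np.ndarray = field(default_factory=lambda: np.array([]))
    presence_year_shift: Mapping[int, float] = field(default_factory=dict)
    noise_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        self.baseline_log_mean = np.asarray(self.baseline_log_mean, dtype=float)
        self.presence_prob = np.asarray(self.presence_prob, dtype=float)
        if any(c < 0 for c in self.cell_counts.values()):
            raise ValueError("negative cell count")
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        if self.baseline_log_mean.shape != (self.n_compounds,):
            raise ValueError("baseline_log_mean length != n_compounds")
        if self.presence_prob.shape != (self.n_compounds,):
            raise ValueError("presence_prob length != n_compounds")
        if np.any((self.presence_prob < 0) | (self.presence_prob > 1)):
            raise ValueError("presence probabilities outside [0, 1]")
        for idx_set in (self.species_effect, self.sex_effect, self.year_effect):
            if any(i < 0 or i >= self.n_compounds for i in idx_set):
                raise ValueError("effect index out of range")

    @property
    def n_samples(self) -> int:
        return sum(self.cell_counts.values())


def default_study_spec(seed: int) -> SyntheticSpec:
    """Spec mirroring the study design: 227 samples over the 11 non-empty
    year x species x sex cells, 113 compounds, with a 7-compound planted
    species signal plus weaker sex and year signals."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    p = 113
    baseline = rng.normal(loc=0.0, scale=1.0, size=p)
    # Bimodal detection probabilities: a common core plus a tail of
    # occasionally-detected compounds, so per-group richness varies with
    # group size while every compound is still seen somewhere in the full
    # sample (the floor keeps total absence over ~227 samples negligible).
    common = rng.beta(4.0, 1.2, size=p)
    rare = np.clip(rng.beta(0.6, 1.8, size=p), 0.04, 1.0)
    presence = np.where(rng.random(p) < 0.4, rare, common)
    return SyntheticSpec(
        cell_counts=dict(STUDY_CELL_COUNTS),
        n_compounds=p,
        class_proportions=dict(DEFAULT_CLASS_PROPORTIONS),
        baseline_log_mean=baseline,
        species_effect=tuple(range(0, 7)),
        delta_species=2.0,
        sex_effect=tuple(range(7, 11)),
        delta_sex=1.0,
        year_effect=tuple(range(11, 16)),
        delta_year=1.0,
        presence_prob=presence,
        noise_sd=0.6,
        seed=int(seed),
    )


def null_spec(spec: SyntheticSpec) -> SyntheticSpec:
    """Copy of ``spec`` with every effect magnitude and group-dependent
    presence shift zeroed, so all group labels are exchangeable."""
    return replace(
        spec,
        delta_species=0.0,
        delta_sex=0.0,
        delta_year=0.0,
        presence_year_shift={},
    )


def _level_sign(value, levels) -> float:
    """+1 for the first level, -1 for the last, interior levels spaced evenly."""
    levels = list(levels)
    if len(levels) == 1:
        return 0.0
    k = levels.index(value)
    return 1.0 - 2.0 * k / (len(levels) - 1)


def _assign_classes(spec: SyntheticSpec, rng: np.random.Generator) -> list[str]:
    classes = [c for c in MOL_CLASSES if c in spec.class_proportions]
    counts = {c: int(np.floor(spec.class_proportions[c] * spec.n_compounds)) for c in classes}
    # distribute the rounding remainder deterministically by largest fraction
    rem = spec.n_compounds - sum(counts.values())
    fracs = sorted(
        classes,
        key=lambda c: spec.class_proportions[c] * spec.n_compounds - counts[c],
        reverse=True,
    )
    for c in fracs[:rem]:
        counts[c] += 1
    labels = [c for c in classes for _ in range(counts[c])]
    rng.shuffle(labels)
    return labels


def generate(spec: SyntheticSpec) -> tuple[CompoundTable, SampleMetadata]:
    """Draw one dataset from the spec.  Deterministic for a fixed seed; a
    sample drawing all-zero presence is redrawn (bounded retries)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    p = spec.n_compounds
    years = sorted({y for (y, _, _) in spec.cell_counts})
    classes = _assign_classes(spec, rng)
    annotations = [
        CompoundAnnotation(compound_id=f"c{i + 1:03d}", name=f"compound-{i + 1}", mol_class=classes[i])
        for i in range(p)
    ]

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    rows: list[np.ndarray] = []
    counter = 0
    for (year, species, sex) in sorted(spec.cell_counts):
        count = spec.cell_counts[(year, species, sex)]
        mu = spec.baseline_log_mean.copy()
        if spec.species_effect:
            mu[list(spec.species_effect)] += (
                0.5 * spec.delta_species * _level_sign(species, ("marthae", "subcristatus"))
            )
        if spec.sex_effect:
            mu[list(spec.sex_effect)] += 0.5 * spec.delta_sex * _level_sign(sex, ("F", "M"))
        if spec.year_effect:
            mu[list(spec.year_effect)] += 0.5 * spec.delta_year * _level_sign(year, years)
        pi = spec.presence_prob
        shift = spec.presence_year_shift.get(year, 0.0)
        if shift:
            with np.errstate(divide="ignore"):
                logit = np.log(pi) - np.log1p(-pi)
            pi = 1.0 / (1.0 + np.exp(-(logit + shift)))
            pi = np.nan_to_num(pi, nan=1.0)  # pi==1 maps through inf logit
        for _ in range(count):
            counter += 1
            for attempt in range(_MAX_REDRAWS):
                z = rng.random(p) < pi
                if z.any():
                    break
            else:
                raise RuntimeError(
                    f"sample {counter} drew all-zero presence {_MAX_REDRAWS} times"
                )
            eps = rng.normal(0.0, spec.noise_sd, size=p)
            raw = z * np.exp(mu + eps)
            rows.append(100.0 * raw / raw.sum())
            sid = f"s{counter:03d}"
            sample_ids.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "species": species,
                    "sex": sex,
                    "year": year,
                    "season": SEASON_BY_YEAR.get(year, "rs"),
                }
            )

    table = CompoundTable(sample_ids, annotations, np.vstack(rows))
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    return table, meta


def spec_to_dict(spec: SyntheticSpec) -> dict:
    """YAML-serializable form of a spec."""
    return {
        "cell_counts": [
            {"year": y, "species": sp, "sex": sx, "n": n}
            for (y, sp, sx), n in sorted(spec.cell_counts.items())
        ],
        "n_compounds": spec.n_compounds,
        "class_proportions": dict(spec.class_proportions),
        "baseline_log_mean": spec.baseline_log_mean.tolist(),
        "species_effect": list(spec.species_effect),
        "delta_species": spec.delta_species,
        "sex_effect": list(spec.sex_effect),
        "delta_sex": spec.delta_sex,
        "year_effect": list(spec.year_effect),
        "delta_year": spec.delta_year,
        "presence_prob": spec.presence_prob.tolist(),
        "presence_year_shift": {int(k): float(v) for k, v in spec.presence_year_shift.items()},
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
    }


def spec_from_dict(d: dict) -> SyntheticSpec:
    return SyntheticSpec(
        cell_counts={
            (int(c["year"]), c["species"], c["sex"]): int(c["n"]) for c in d["cell_counts"]
        },
        n_compounds=int(d["n_compounds"]),
        class_proportions=d["class_proportions"],
        baseline_log_mean=np.asarray(d["baseline_log_mean"], dtype=float),
        species_effect=tuple(d.get("species_effect", ())),
        delta_species=float(d.get("delta_species", 0.0)),
        sex_effect=tuple(d.get("sex_effect", ())),
        delta_sex=float(d.get("delta_sex", 0.0)),
        year_effect=tuple(d.get("year_effect", ())),
        delta_year=float(d.get("delta_year", 0.0)),
        presence_prob=np.asarray(d["presence_prob"], dtype=float),
        presence_year_shift={int(k): float(v) for k, v in d.get("presence_year_shift", {}).items()},
        noise_sd=float(d.get("noise_sd", 0.6)),
        seed=int(d.get("seed", 0)),
    )
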