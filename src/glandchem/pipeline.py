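"""End-to-end study workflow.

Runs, on one compound table (user-supplied or synthetic): group diversity
summaries -> Bray-Curtis matrix -> nMDS + dispersion homogeneity with Tukey
screening -> multi-factor PERMANOVA -> per-season SIMPER with consistent
marker intersection -> PCA of the markers -> the random-forest stability
protocol.  All stages read the same in-memory objects (no re-parsing between
sections), every stage seed fans out deterministically from one master seed,
and each report section is either present or explicitly marked skipped with
the error that stopped it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dissimilarity import bray_curtis_matrix
from .diversity import summarize_by_group, summary_frame
from .multivariate import permanova, permdisp, tukey_hsd_dispersion
from .ordination import nmds
from .profile_io import (
    CompoundTable,
    SampleMetadata,
    normalize_rows,
    read_compound_table,
    read_metadata,
    subset,
)
from .rf_stability import RFProtocolConfig, run_protocol
from .simper import consistent_markers, pca_select, simper
from .synthetic import SyntheticSpec, default_study_spec, generate

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    matrix_path: Optional[str] = None
    annotation_path: Optional[str] = None
    metadata_path: Optional[str] = None
    synthetic_spec: Optional[SyntheticSpec] = None
    simper_years: tuple[int, ...] = (2012, 2014)
    permanova_terms: tuple[str, ...] = (
        "year", "species", "sex",
        "year:species", "year:sex", "species:sex", "year:species:sex",
    )
    permanova_n_perm: int = 9999
    strata: Optional[str] = "year"
    simper_alpha: float = 0.01
    simper_n_perm: int = 999
    pca_threshold: float = 0.75
    nmds_dimensions: int = 3
    nmds_starts: int = 4
    rf: RFProtocolConfig = field(default_factory=lambda: RFProtocolConfig(n_runs=100))
    out_dir: Optional[str] = None
    master_seed: int = 0


@dataclass
class StudyReport:
    sections: dict
    skipped: dict  # stage -> error message
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(
            {"sections": self.sections, "skipped": self.skipped,
             "provenance": self.provenance},
            indent=2, sort_keys=True, default=_jsonify,
        )


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _stage_seeds(master_seed: int, names: Sequence[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(master_seed)
    states = np.random.default_rng(ss).integers(2**31, size=len(names))
    return {name: int(s) for name, s in zip(names, states)}


def load_inputs(config: PipelineConfig) -> tuple[CompoundTable, SampleMetadata]:
    if config.synthetic_spec is not None:
        return generate(config.synthetic_spec)
    if config.matrix_path is None or config.metadata_path is None:
        raise FileNotFoundError(
            "config needs either a synthetic spec or matrix + metadata paths"
        )
    for p in (config.matrix_path, config.metadata_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    table = read_compound_table(config.matrix_path, config.annotation_path)
    table = normalize_rows(table)
    meta = read_metadata(config.metadata_path)
    meta.check_aligned(table)
    return table, meta


def run_pipeline(config: PipelineConfig) -> StudyReport:
    table, meta = load_inputs(config)
    seeds = _stage_seeds(
        config.master_seed, ["nmds", "permanova", "simper", "rf"]
    )
    sections: dict = {}
    skipped: dict = {}

    def stage(name: str, fn):
        try:
            sections[name] = fn()
            logger.info("stage %s done", name)
        except Exception as exc:  # report and continue with independent stages
            logger.error("stage %s failed: %s", name, exc)
            skipped[name] = f"{type(exc).__name__}: {exc}"

    stage("diversity", lambda: summary_frame(summarize_by_group(table, meta)))

    d = bray_curtis_matrix(table)

    nmds_coords: list[np.ndarray] = []

    def _nmds():
        res = nmds(d, k=config.nmds_dimensions, n_starts=config.nmds_starts,
                   seed=seeds["nmds"])
        nmds_coords.append(res.coordinates)
        return {"stress": res.stress, "converged": res.converged,
                "n_iterations": res.n_iterations, "best_of": res.best_of}
    stage("nmds", _nmds)

    def _dispersion():
        groups = (
            meta.frame["year"].astype(str) + "/" + meta.frame["species"]
            + "/" + meta.frame["sex"]
        ).to_numpy()
        disp = permdisp(d, groups)
        out = {"anova_f": disp.anova_f, "anova_p": disp.anova_p,
               "degenerate": disp.degenerate}
        if not disp.degenerate:
            tukey, pct = tukey_hsd_dispersion(disp)
            out["percent_homogeneous"] = pct
            out["n_pairs"] = len(tukey)
        return out
    stage("dispersion", _dispersion)

    stage("permanova", lambda: permanova(
        d, meta, terms=config.permanova_terms, n_perm=config.permanova_n_perm,
        strata=config.strata, seed=seeds["permanova"],
    ).to_frame())

    simper_results = {}

    def _simper():
        for i, year in enumerate(config.simper_years):
            sub_t, sub_m = subset(table, meta, f"year == {year}")
            simper_results[year] = simper(
                sub_t, sub_m["species"].to_numpy(),
                n_perm=config.simper_n_perm, seed=seeds["simper"] + i,
            )
        return {str(y): r.to_frame() for y, r in simper_results.items()}
    stage("simper", _simper)

    def _markers():
        markers = consistent_markers(simper_results, alpha=config.simper_alpha)
        out = {"consistent": markers.compound_ids,
               "bonferroni_consistent": markers.bonferroni_consistent,
               "alpha": markers.alpha}
        if len(markers.compound_ids) >= 2:
            sel = pca_select(table, markers.compound_ids,
                             cumulative_threshold=config.pca_threshold)
            out["pca"] = {
                "top_variance_compound": sel.top_variance_compound,
                "variance_explained": sel.variance_explained,
                "n_retained": sel.n_retained,
            }
        return out
    if simper_results:
        stage("markers", _markers)
    else:
        skipped["markers"] = "skipped: SIMPER stage unavailable"

    def _rf():
        cfg = RFProtocolConfig(
            n_runs=config.rf.n_runs, train_fraction=config.rf.train_fraction,
            n_trees=config.rf.n_trees, mtry=min(config.rf.mtry, table.n_compounds),
            positive_class=config.rf.positive_class, master_seed=seeds["rf"],
        )
        res = run_protocol(table, meta["species"].to_numpy(), cfg)
        return {
            "frequency": res.frequency, "chi2_stat": res.chi2_stat,
            "chi2_df": res.chi2_df, "chi2_p": res.chi2_p,
            "mean_metrics": res.mean_metrics, "auc": res.auc,
            "n_discarded": res.n_discarded,
        }
    stage("rf_stability", _rf)

    provenance = {
        "package_version": __version__,
        "master_seed": config.master_seed,
        "stage_seeds": seeds,
        "n_samples": table.n_samples,
        "n_compounds": table.n_compounds,
        "config_hash": hashlib.sha256(
            repr(sorted(asdict(config).items(), key=lambda kv: kv[0])).encode()
        ).hexdigest()[:16],
    }
    report = StudyReport(sections=sections, skipped=skipped, provenance=provenance)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        for name, value in sections.items():
            if isinstance(value, pd.DataFrame):
                value.to_csv(out / f"{name}.csv", index=False)
        if nmds_coords:
            from .plots import plot_ordination

            plot_ordination(nmds_coords[0], meta, out / "nmds.png",
                            axis_labels=("nMDS 1", "nMDS 2"))
        if "rf_stability" in sections:
            from .plots import plot_importance_frequency

            plot_importance_frequency(
                sections["rf_stability"]["frequency"],
                out / "importance_frequency.png",
            )
    return report


def synth_demo(seed: int, **overrides) -> StudyReport:
    """Generate the default synthetic study design and run everything at
    desk-scale defaults (n_perm = 999, 100 forest runs)."""
    spec = default_study_spec(seed)
    config = PipelineConfig(
        synthetic_spec=spec, permanova_n_perm=999, master_seed=seed, **overrides
    )
    return run_pipeline(config)
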