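from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from glandchem.profile_io import CompoundAnnotation, CompoundTable, SampleMetadata
from glandchem.synthetic import SyntheticSpec, default_study_spec


def make_table(values, sample_ids=None, compound_ids=None, mol_classes=None,
               match_scores=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    compound_ids = compound_ids or [f"c{j}" for j in range(p)]
    annotations = [
        CompoundAnnotation(
            compound_id=cid,
            mol_class=(mol_classes[j] if mol_classes else "other"),
            match_score=(match_scores[j] if match_scores else None),
        )
        for j, cid in enumerate(compound_ids)
    ]
    return CompoundTable(sample_ids, annotations, values)


def make_metadata(table, species=None, sex=None, year=None, season=None):
    n = table.n_samples
    frame = pd.DataFrame(
        {
            "species": species or ["marthae"] * (n // 2) + ["subcristatus"] * (n - n // 2),
            "sex": sex or ["F", "M"] * (n // 2) + ["F"] * (n % 2),
            "year": year or [2012] * n,
            "season": season or ["rs"] * n,
        },
        index=pd.Index(table.sample_ids, name="sample_id"),
    )
    return SampleMetadata(frame)


def small_spec(seed, n_per_group=15, n_compounds=15, delta_species=0.0,
               noise_sd=0.6, presence=0.9):
    """Two-cell (one factor) design for fast simulations."""
    rng = np.random.default_rng(seed)
    return SyntheticSpec(
        cell_counts={
            (2012, "marthae", "M"): n_per_group,
            (2012, "subcristatus", "M"): n_per_group,
        },
        n_compounds=n_compounds,
        class_proportions={"fatty acid": 0.5, "alkene": 0.5},
        baseline_log_mean=rng.normal(size=n_compounds),
        species_effect=tuple(range(3)),
        delta_species=delta_species,
        presence_prob=np.full(n_compounds, presence),
        noise_sd=noise_sd,
        seed=seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study_data():
    """One draw of the full synthetic study design, shared across tests."""
    from glandchem.synthetic import generate

    return generate(default_study_spec(1))
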