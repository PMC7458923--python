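import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from glandchem.dissimilarity import DissimilarityMatrix, bray_curtis_matrix
from glandchem.multivariate import (
    exhaustive_permutations,
    permanova,
    permdisp,
    tukey_hsd_dispersion,
)
from glandchem.profile_io import ProfileError, SampleMetadata

from conftest import make_metadata, make_table


def euclid_dm(points):
    points = np.asarray(points, float)
    d = squareform(pdist(points))
    d = d / max(d.max(), 1.0)
    return DissimilarityMatrix([f"s{i}" for i in range(len(points))], d)


def meta_from(**columns):
    n = len(next(iter(columns.values())))
    frame = pd.DataFrame(
        {
            "species": columns.get("species", ["marthae"] * n),
            "sex": columns.get("sex", ["F"] * n),
            "year": columns.get("year", [2012] * n),
            "season": columns.get("season", ["rs"] * n),
        },
        index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
    )
    return SampleMetadata(frame)


class TestPermanova:
    def test_no_signal_gives_unit_p(self):
        values = np.tile([40.0, 35.0, 25.0], (6, 1))
        d = bray_curtis_matrix(make_table(values))
        meta = meta_from(species=["marthae"] * 3 + ["subcristatus"] * 3)
        res = permanova(d, meta, terms=["species"], n_perm=99, strata=None, seed=0)
        assert res.p[0] == 1.0
        assert abs(res.ss[0]) < 1e-12

    def test_additivity_and_total(self, study_data):
        table, meta = study_data
        d = bray_curtis_matrix(table)
        res = permanova(d, meta, n_perm=9, seed=0)
        assert res.ss.sum() + res.residual_ss == pytest.approx(res.total_ss, abs=1e-8)
        # total SS identity: sum_{i<j} d_ij^2 / n
        n = d.n
        expected_total = (d.values[np.triu_indices(n, 1)] ** 2).sum() / n
        assert res.total_ss == pytest.approx(expected_total, abs=1e-8)
        assert res.r2.sum() + res.residual_ss / res.total_ss == pytest.approx(1.0)
        assert res.df.sum() + res.residual_df == res.total_df

    def test_euclidean_matches_coordinate_anova(self, rng):
        # on Euclidean distances the trace machinery must reproduce the
        # classical sequential ANOVA sums of squares summed over coordinates
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        n = 24
        points = rng.normal(size=(n, 3))
        species = rng.permutation(["marthae"] * 12 + ["subcristatus"] * 12)
        sex = rng.permutation(["F"] * 12 + ["M"] * 12)
        meta = meta_from(species=list(species), sex=list(sex))
        d = DissimilarityMatrix(
            [f"s{i}" for i in range(n)], squareform(pdist(points)) / 10.0
        )
        res = permanova(
            d, meta, terms=["species", "sex", "species:sex"], n_perm=9,
            strata=None, seed=0,
        )
        expected = np.zeros(3)
        for coord in range(3):
            frame = pd.DataFrame(
                {"y": points[:, coord] / 10.0, "species": species, "sex": sex}
            )
            fit = ols("y ~ C(species) + C(sex) + C(species):C(sex)", frame).fit()
            anova = sm.stats.anova_lm(fit, typ=1)
            expected += anova["sum_sq"].to_numpy()[:3]
        np.testing.assert_allclose(res.ss, expected, atol=1e-8)

    def test_sampled_p_matches_exhaustive_enumeration(self, rng):
        values = rng.random((6, 4)) * 50 + 1
        d = bray_curtis_matrix(make_table(values))
        meta = meta_from(species=["marthae"] * 3 + ["subcristatus"] * 3)
        exact = permanova(
            d, meta, terms=["species"], strata=None,
            permutations=exhaustive_permutations(6),
        )
        sampled = permanova(
            d, meta, terms=["species"], n_perm=9999, strata=None, seed=1
        )
        p = exact.p[0]
        mc_se = np.sqrt(p * (1 - p) / 9999)
        assert abs(sampled.p[0] - p) <= 3 * mc_se + 1e-4

    def test_p_invariant_to_level_relabeling(self, rng):
        values = rng.random((12, 5)) + 0.1
        d = bray_curtis_matrix(make_table(values))
        species = ["marthae"] * 6 + ["subcristatus"] * 6
        flipped = ["subcristatus"] * 6 + ["marthae"] * 6
        r1 = permanova(d, meta_from(species=species), terms=["species"],
                       n_perm=199, strata=None, seed=5)
        r2 = permanova(d, meta_from(species=flipped), terms=["species"],
                       n_perm=199, strata=None, seed=5)
        assert r1.p[0] == r2.p[0]
        assert r1.f[0] == pytest.approx(r2.f[0], abs=1e-12)

    def test_strata_never_cross_years(self, rng):
        from glandchem.multivariate import _strata_permutation

        years = np.repeat([2012, 2014, 2015], [8, 6, 4])
        g = np.random.default_rng(0)
        for _ in range(50):
            perm = _strata_permutation(g, years, len(years))
            assert np.array_equal(years[perm], years)

    def test_numeric_year_coding_has_one_df(self, study_data):
        table, meta = study_data
        d = bray_curtis_matrix(table)
        res = permanova(d, meta, terms=["year", "species"], n_perm=9,
                        numeric_factors=["year"], seed=0)
        assert res.df[0] == 1

    def test_aliased_term_is_error(self, rng):
        values = rng.random((8, 4)) + 0.1
        d = bray_curtis_matrix(make_table(values))
        meta = meta_from(species=["marthae"] * 4 + ["subcristatus"] * 4,
                         season=["rs"] * 4 + ["nrs"] * 4)  # season == species
        with pytest.raises(ProfileError, match="aliased"):
            permanova(d, meta, terms=["species", "season"], n_perm=9,
                      strata=None, seed=0)

    def test_one_way_pseudo_f_matches_reference_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova

        values = rng.random((14, 6)) + 0.05
        table = make_table(values)
        d = bray_curtis_matrix(table)
        species = ["marthae"] * 7 + ["subcristatus"] * 7
        res = permanova(d, meta_from(species=species), terms=["species"],
                        n_perm=99, strata=None, seed=0)
        sk = sk_permanova(
            DistanceMatrix(d.values, ids=d.sample_ids), np.array(species),
            permutations=99,
        )
        assert res.f[0] == pytest.approx(sk["test statistic"], abs=1e-10)


class TestPermdisp:
    def test_hand_geometry_mean_distances(self):
        points = [(0, 0), (2, 0), (0, 0), (6, 0)]
        d = euclid_dm(points)
        groups = np.array(["A", "A", "B", "B"])
        disp = permdisp(d, groups)
        scale = 6.0  # euclid_dm normalizes by the max distance
        np.testing.assert_allclose(
            np.sort(disp.distances * scale), [1, 1, 3, 3], atol=1e-8
        )

    def test_coincident_points_flagged_degenerate(self):
        # each group is a pair of coincident points: all centroid distances 0
        values = np.array(
            [[0, 0, 0.5, 0.5], [0, 0, 0.5, 0.5], [0.5, 0.5, 0, 0], [0.5, 0.5, 0, 0]]
        )
        d = DissimilarityMatrix(["a", "b", "c", "d"], values)
        disp = permdisp(d, np.array(["A", "A", "B", "B"]))
        assert disp.degenerate
        assert np.allclose(disp.distances, 0)

    def test_singleton_group_excluded_with_warning(self, rng):
        points = rng.normal(size=(9, 2))
        d = euclid_dm(points)
        groups = np.array(["A"] * 4 + ["B"] * 4 + ["C"])
        with pytest.warns(UserWarning, match="singleton"):
            disp = permdisp(d, groups)
        assert len(disp.distances) == 8

    def test_detects_inflated_dispersion(self, rng):
        pts = np.vstack([
            rng.normal(scale=1.0, size=(20, 2)),
            rng.normal(scale=5.0, size=(20, 2)),
        ])
        disp = permdisp(euclid_dm(pts), np.array(["A"] * 20 + ["B"] * 20))
        assert disp.anova_p < 0.01


class TestTukey:
    def test_pair_count_for_study_groups(self, study_data):
        table, meta = study_data
        d = bray_curtis_matrix(table)
        groups = (
            meta.frame["year"].astype(str) + "/" + meta.frame["species"]
            + "/" + meta.frame["sex"]
        ).to_numpy()
        disp = permdisp(d, groups)
        tukey, pct = tukey_hsd_dispersion(disp)
        assert len(tukey) == 55  # C(11, 2)
        assert 0 <= pct <= 1

    def test_inflated_group_significant_in_all_its_pairs(self, rng):
        pts = np.vstack([
            rng.normal(scale=1.0, size=(30, 2)) for _ in range(3)
        ] + [rng.normal(scale=5.0, size=(30, 2))])
        groups = np.repeat(["A", "B", "C", "D"], 30)
        disp = permdisp(euclid_dm(pts), groups)
        tukey, pct = tukey_hsd_dispersion(disp)
        d_pairs = tukey[(tukey["group1"] == "D") | (tukey["group2"] == "D")]
        assert (d_pairs["p-adj"] < 0.05).all()
        assert pct == pytest.approx(3 / 6)
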