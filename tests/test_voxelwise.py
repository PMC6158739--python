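"""Design construction, voxel-wise GLM, TFCE and permutation inference."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import t as t_dist

from mdcascade import (
    DesignMatrix,
    TFCEParams,
    build_design,
    fit_glm_tmap,
    glm_tstats,
    group_contrast_maps,
    intersect_binarized_maps,
    permutation_fwe,
    tfce_enhance,
)

from oracles import simple_regression_t, tfce_oracle


def _subjects(n_car=6, n_non=5):
    rows = []
    for i in range(n_car + n_non):
        rows.append(
            {
                "subject_id": f"s{i}",
                "mutation_carrier": i < n_car,
                "eyo": -20.0 + 3 * i,
                "sex": i % 2,
                "education": 12 + (i % 5),
                "cdr_positive": False,
            }
        )
    return pd.DataFrame(rows)


class TestBuildDesign:
    def test_carrier_row_coding(self):
        df = pd.DataFrame(
            [
                {"subject_id": "a", "mutation_carrier": True, "eyo": -10.0,
                 "sex": 0, "education": 14},
                {"subject_id": "b", "mutation_carrier": False, "eyo": 3.0,
                 "sex": 1, "education": 16},
                {"subject_id": "c", "mutation_carrier": False, "eyo": -1.0,
                 "sex": 0, "education": 10},
                {"subject_id": "d", "mutation_carrier": True, "eyo": 2.0,
                 "sex": 1, "education": 12},
                {"subject_id": "e", "mutation_carrier": True, "eyo": -7.0,
                 "sex": 1, "education": 18},
                {"subject_id": "f", "mutation_carrier": False, "eyo": 6.0,
                 "sex": 0, "education": 13},
                {"subject_id": "g", "mutation_carrier": True, "eyo": 1.0,
                 "sex": 0, "education": 15},
            ]
        )
        design = build_design(df)
        assert design.column_names == (
            "intercept", "eyo", "mutation", "eyo_x_mutation", "sex", "education"
        )
        np.testing.assert_allclose(design.X[0], [1, -10, 1, -10, 0, 14])
        # non-carriers have a zero interaction column entry
        assert design.X[1, 3] == 0 and design.X[2, 3] == 0

    def test_single_group_is_rank_deficient(self):
        df = _subjects(n_car=8, n_non=0)
        with pytest.raises(ValueError, match="rank"):
            build_design(df)

    def test_missing_covariate_rejected(self):
        df = _subjects()
        df.loc[2, "education"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            build_design(df)


class TestGLM:
    def test_matches_simple_regression_oracle(self, rng):
        n = 200
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        Y = (2 + 3 * x + rng.normal(size=n))[:, None] * np.ones((1, 7))
        Y += rng.normal(size=(n, 7)) * 0.3
        t, dof = glm_tstats(Y, X, np.array([0.0, 1.0]))
        assert dof == n - 2
        for j in range(7):
            assert t[j] == pytest.approx(simple_regression_t(x, Y[:, j]), rel=1e-8)

    def test_null_tstats_calibrated(self, rng):
        n, v = 100, 4000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Y = rng.normal(size=(n, v))
        t, dof = glm_tstats(Y, X, np.array([0.0, 1.0]))
        crit = t_dist.ppf(0.975, dof)
        rate = np.mean(np.abs(t) > crit)
        # binomial 3-sigma band around 0.05 for 4000 voxels
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / v)

    def test_zero_contrast_rejected(self, rng):
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        with pytest.raises(ValueError, match="zero"):
            glm_tstats(rng.normal(size=(10, 3)), X, np.zeros(2))

    def test_zero_variance_voxel_gets_t_zero(self, rng):
        n = 30
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Y = np.column_stack([np.ones(n) * 5.0, rng.normal(size=n)])
        t, _ = glm_tstats(Y, X, np.array([0.0, 1.0]))
        assert t[0] == 0.0 and t[1] != 0.0


class TestTFCE:
    def test_all_zero_map(self):
        out = tfce_enhance(np.zeros((4, 4, 4)), np.ones((4, 4, 4), bool))
        assert np.all(out == 0)

    def test_single_voxel_closed_form(self):
        # value 1.0, H=2, E=0.5, dh=0.1: 0.1 * sum_{h=0.1..1.0} h^2 = 0.385
        tmap = np.zeros((5, 5, 5))
        tmap[2, 2, 2] = 1.0
        params = TFCEParams(H=2.0, E=0.5, dh=0.1, connectivity=26)
        out = tfce_enhance(tmap, np.ones((5, 5, 5), bool), params)
        assert out[2, 2, 2] == pytest.approx(0.385, rel=1e-10)

    def test_adjacent_voxels_enhance_more_than_isolated(self):
        params = TFCEParams(H=2.0, E=0.5, dh=0.1)
        together = np.zeros((4, 4, 4))
        together[1, 1, 1] = together[1, 1, 2] = 1.0
        apart = np.zeros((4, 4, 4))
        apart[0, 0, 0] = apart[3, 3, 3] = 1.0
        mask = np.ones((4, 4, 4), bool)
        a = tfce_enhance(together, mask, params)
        b = tfce_enhance(apart, mask, params)
        assert a[1, 1, 1] > b[0, 0, 0]

    def test_negative_map_is_antisymmetric(self, rng):
        tmap = rng.normal(size=(5, 5, 5))
        mask = rng.random((5, 5, 5)) < 0.7
        mask[2, 2, 2] = True
        params = TFCEParams(dh=0.05)
        np.testing.assert_allclose(
            tfce_enhance(-tmap, mask, params), -tfce_enhance(tmap, mask, params),
            atol=1e-12,
        )

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_bfs_oracle(self, connectivity, rng):
        for _ in range(10):
            tmap = rng.normal(size=(6, 6, 6))
            mask = rng.random((6, 6, 6)) < 0.6
            mask[3, 3, 3] = True
            params = TFCEParams(H=2.0, E=0.5, dh=0.1, connectivity=connectivity)
            got = tfce_enhance(tmap, mask, params)
            want = tfce_oracle(tmap, mask, H=2.0, E=0.5, dh=0.1, connectivity=connectivity)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_monotone_in_statistic_map(self, rng):
        base = np.abs(rng.normal(size=(5, 5, 5)))
        mask = np.ones((5, 5, 5), bool)
        params = TFCEParams(dh=0.05)
        bigger = base + 0.5
        a = tfce_enhance(base, mask, params)
        b = tfce_enhance(bigger, mask, params)
        assert np.all(b >= a - 1e-12)

    def test_bad_dh_rejected(self):
        with pytest.raises(ValueError, match="dh"):
            TFCEParams(dh=-0.1)


class TestPermutationFWE:
    def _data(self, rng, n=24, shape=(6, 6, 4), effect=0.0):
        mask = np.ones(shape, bool)
        subjects = _subjects(n_car=n // 2, n_non=n - n // 2)
        design = build_design(subjects)
        nvox = int(mask.sum())
        Y = rng.normal(size=(n, nvox))
        if effect:
            carrier = subjects["mutation_carrier"].to_numpy(float)
            eyo = subjects["eyo"].to_numpy()
            Y[:, :8] += effect * (carrier * eyo)[:, None]
        return Y, design, mask, subjects

    def test_single_permutation_gives_p_one(self, rng):
        Y, design, mask, _ = self._data(rng)
        res = permutation_fwe(Y, design, design.contrast("eyo_x_mutation"),
                              mask, n_perm=1, seed=0)
        assert np.all(res.fwe_p[mask] == 1.0)
        assert res.max_stat_null.shape == (1,)

    def test_planted_interaction_detected_background_clean(self, rng):
        Y, design, mask, _ = self._data(rng, n=60, effect=0.5)
        res = permutation_fwe(Y, design, design.contrast("eyo_x_mutation"),
                              mask, n_perm=100, seed=3)
        p = res.fwe_p[mask]
        assert np.all(p[:8] <= 0.05)
        assert np.all(p[50:] > 0.05)

    def test_p_bounds_and_determinism(self, rng):
        Y, design, mask, _ = self._data(rng)
        c = design.contrast("eyo_x_mutation")
        a = permutation_fwe(Y, design, c, mask, n_perm=50, seed=9)
        b = permutation_fwe(Y, design, c, mask, n_perm=50, seed=9)
        assert np.array_equal(a.fwe_p, b.fwe_p)
        assert np.all(a.fwe_p[mask] >= 1 / 50) and np.all(a.fwe_p[mask] <= 1)


class TestGroupContrasts:
    def test_planted_symptomatic_effect_localised(self, rng):
        n = 60
        subjects = _subjects(n_car=30, n_non=30)
        subjects["cdr_positive"] = subjects["mutation_carrier"] & (subjects["eyo"] > 0)
        mask = np.ones((4, 4, 2), bool)
        Y = rng.normal(size=(n, 32))
        sym = (subjects["mutation_carrier"] & subjects["cdr_positive"]).to_numpy()
        Y[sym, :6] += 3.0
        maps = group_contrast_maps(Y, subjects, mask)
        assert set(maps) == {
            "symptomatic_vs_noncarrier",
            "asymptomatic_vs_noncarrier",
            "symptomatic_vs_asymptomatic",
        }
        tmap = maps["symptomatic_vs_noncarrier"].tmap[mask]
        assert tmap[:6].min() > 3.0
        null_tmap = maps["asymptomatic_vs_noncarrier"].tmap[mask]
        assert np.abs(null_tmap).max() < 4.0

    def test_tiny_group_rejected(self):
        subjects = _subjects(n_car=4, n_non=4)
        subjects["cdr_positive"] = [True] + [False] * 7
        with pytest.raises(ValueError, match="fewer than 2"):
            group_contrast_maps(np.zeros((8, 4)), subjects, np.ones((2, 2, 1), bool))


class TestIntersection:
    def test_identity_disjoint_subset(self):
        a = np.zeros((3, 3, 3), bool)
        a[0] = True
        b = np.zeros((3, 3, 3), bool)
        b[0, 0] = True
        assert np.array_equal(intersect_binarized_maps([a, a]), a)
        c = np.zeros((3, 3, 3), bool)
        c[2] = True
        assert not intersect_binarized_maps([a, c]).any()
        assert np.array_equal(intersect_binarized_maps([a, b]), b)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            intersect_binarized_maps([np.ones((2, 2, 2), bool), np.ones((3, 2, 2), bool)])
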