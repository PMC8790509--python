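"""Calibration engine: quadrature oracles, EM ascent, reductions, invariances."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import norm

from trtequate import (
    CalibrationConfig,
    ConcurrentCalibrator,
    DichotomousItemParams,
    ResponseMatrix,
    eap_score,
    marginal_loglik,
)
from trtequate.calibrate import CalibrationResult
from trtequate.models import MISSING
from trtequate.simulate import PersonSample, generate_responses


def _matrix(codes, item_ids, groups=None):
    codes = np.asarray(codes, dtype=np.int16)
    groups = np.asarray(groups if groups is not None else ["base"] * len(codes))
    return ResponseMatrix(codes=codes, item_ids=tuple(item_ids), groups=groups)


@pytest.fixture(scope="module")
def fitted_pair(small_dich_data):
    """2PLM and 2PTM fits of the shared small dataset."""
    matrix, pair = small_dich_data["matrix"], small_dich_data["pair"]
    c1 = ConcurrentCalibrator("2PLM", convergence_tol=1e-3).fit(matrix, structure=pair)
    c2 = ConcurrentCalibrator("2PTM", convergence_tol=1e-3).fit(
        matrix, structure=pair, init_items=c1.item_estimates_
    )
    return c1, c2


class TestMarginalLoglik:
    def test_matches_hand_computed_quadrature(self):
        # 3 persons x 2 items; 5-point rectangular grid computed independently
        items = {
            "i1": DichotomousItemParams("i1", 1.2, 0.3),
            "i2": DichotomousItemParams("i2", 0.8, -0.5),
        }
        codes = [[1, 0], [0, 1], [1, 1]]
        mat = _matrix(codes, ["i1", "i2"])
        config = CalibrationConfig(model_family="2PLM", quad_points_theta=5)
        got = marginal_loglik(mat, items, {}, {}, config)

        theta = np.linspace(-5, 5, 5)
        w = norm.pdf(theta) * (theta[1] - theta[0])
        expected = 0.0
        for row in codes:
            like = np.ones_like(theta)
            for iid, y in zip(["i1", "i2"], row):
                p = expit(items[iid].a * (theta - items[iid].b))
                like *= p if y == 1 else (1 - p)
            expected += np.log((w * like).sum())
        assert got == pytest.approx(expected, abs=1e-10)

    def test_all_missing_person_contributes_nothing(self):
        items = {
            "i1": DichotomousItemParams("i1", 1.2, 0.3),
            "i2": DichotomousItemParams("i2", 0.8, -0.5),
        }
        config = CalibrationConfig(model_family="2PLM")
        base = marginal_loglik(_matrix([[1, 0], [0, 1]], ["i1", "i2"]), items, {}, {}, config)
        extra = marginal_loglik(
            _matrix([[1, 0], [0, 1], [MISSING, MISSING]], ["i1", "i2"]),
            items, {}, {}, config,
        )
        assert extra - base == pytest.approx(0.0, abs=1e-5)


class TestEAPScoring:
    def _result(self, items, family="2PLM", variances=None):
        return CalibrationResult(
            model_family=family, item_estimates=items,
            testlet_variances=variances or {}, group_params={"new_mean": 0.0, "new_var": 1.0},
            log_likelihood=0.0, n_cycles=0, converged=True,
        )

    def test_single_item_matches_dense_trapezoid_posterior(self):
        item = DichotomousItemParams("i1", 1.5, 0.4)
        result = self._result({"i1": item, "i2": DichotomousItemParams("i2", 1.0, 0.0)})
        mat = _matrix([[1, MISSING], [0, MISSING], [1, 0], [0, 1]], ["i1", "i2"])
        config = CalibrationConfig(model_family="2PLM", quad_points_theta=201)
        scores = eap_score(mat, result, config)

        grid = np.linspace(-5, 5, 10_001)
        for row, got in zip([1, 0], scores[:2]):
            p = expit(item.a * (grid - item.b))
            like = p if row == 1 else 1 - p
            post = like * norm.pdf(grid)
            expected = np.trapezoid(post * grid, grid) / np.trapezoid(post, grid)
            assert got == pytest.approx(expected, abs=1e-4)

    def test_all_missing_person_scores_at_prior_mean(self):
        items = {
            "i1": DichotomousItemParams("i1", 1.0, 0.0),
            "i2": DichotomousItemParams("i2", 1.0, 0.5),
        }
        mat = _matrix([[1, 0], [0, 1], [MISSING, MISSING]], ["i1", "i2"])
        scores = eap_score(mat, self._result(items))
        assert scores[2] == pytest.approx(0.0, abs=1e-10)

    def test_additional_correct_response_never_lowers_score(self):
        items = {
            f"i{j}": DichotomousItemParams(f"i{j}", 1.0 + 0.1 * j, 0.2 * j - 0.5)
            for j in range(4)
        }
        ids = list(items)
        result = self._result(items)
        patterns = [[1, 0, MISSING, MISSING], [0, 0, 1, MISSING], [1, 1, 1, MISSING]]
        with_extra = [p[:3] + [1] for p in patterns]
        base_scores = eap_score(_matrix(patterns, ids), result)
        more_scores = eap_score(_matrix(with_extra, ids), result)
        assert np.all(more_scores >= base_scores)


class TestFitProperties:
    def test_em_ascent_on_both_families(self, fitted_pair):
        for cal in fitted_pair:
            diffs = np.diff(cal.loglik_path_)
            assert diffs.min() > -1e-6

    def test_new_group_shift_recovered(self, fitted_pair):
        for cal in fitted_pair:
            assert cal.group_params_["new_mean"] == pytest.approx(0.5, abs=0.15)
            assert cal.group_params_["new_var"] == pytest.approx(1.0, abs=0.3)

    def test_anchor_items_single_shared_estimate(self, fitted_pair, small_dich_data):
        # concurrent linking: one estimate per anchor item, informed by both groups
        pair = small_dich_data["pair"]
        for cal in fitted_pair:
            for iid in pair.anchor_ids:
                assert iid in cal.item_estimates_
        assert len(fitted_pair[0].item_estimates_) == 100

    def test_sigma2_nonnegative_and_bounded(self, fitted_pair):
        for sig2 in fitted_pair[1].testlet_variances_.values():
            assert 0.0 <= sig2 <= 9.0

    def test_column_permutation_invariance(self, small_dich_data, rng):
        matrix = small_dich_data["matrix"]
        sub_cols = list(range(0, 30))
        codes = matrix.codes[:, sub_cols]
        ids = [matrix.item_ids[j] for j in sub_cols]
        m1 = _matrix(codes, ids, matrix.groups)
        perm = rng.permutation(len(ids))
        m2 = _matrix(codes[:, perm], [ids[j] for j in perm], matrix.groups)
        f1 = ConcurrentCalibrator("2PLM", convergence_tol=1e-5).fit(m1)
        f2 = ConcurrentCalibrator("2PLM", convergence_tol=1e-5).fit(m2)
        for iid in ids:
            assert f1.item_estimates_[iid].a == pytest.approx(
                f2.item_estimates_[iid].a, abs=1e-4
            )
            assert f1.item_estimates_[iid].b == pytest.approx(
                f2.item_estimates_[iid].b, abs=1e-4
            )

    def test_zero_variance_item_excluded_with_flag(self):
        rng = np.random.default_rng(8)
        n = 300
        theta = rng.normal(0, 1, n)
        codes = np.column_stack(
            [
                (expit(1.2 * (theta - 0.2)) > rng.uniform(size=n)).astype(np.int16),
                (expit(0.9 * (theta + 0.4)) > rng.uniform(size=n)).astype(np.int16),
                np.ones(n, dtype=np.int16),  # constant column
            ]
        )
        cal = ConcurrentCalibrator("2PLM", convergence_tol=1e-3).fit(
            _matrix(codes, ["i1", "i2", "konst"])
        )
        assert cal.excluded_items_ == ("konst",)
        assert set(cal.item_estimates_) == {"i1", "i2"}

    def test_singleton_testlets_degenerate_to_plain_model(self):
        # every "testlet" has one item: the 2PTM must collapse onto the 2PLM
        rng = np.random.default_rng(15)
        n = 1500
        items = tuple(
            DichotomousItemParams(f"i{j:02d}", 0.8 + 0.1 * j, 0.3 * j - 1.5, None)
            for j in range(10)
        )
        persons = PersonSample("base", rng.normal(0, 1, n), {})
        codes = generate_responses(items, persons, rng)
        mat = _matrix(codes, [it.item_id for it in items])
        tmap = {f"i{j:02d}": f"t{j}" for j in range(4)}  # 4 singleton testlets
        f_plain = ConcurrentCalibrator("2PLM", convergence_tol=1e-5).fit(mat)
        f_testlet = ConcurrentCalibrator("2PTM", convergence_tol=1e-5).fit(
            mat, structure=tmap, init_items=f_plain.item_estimates_
        )
        for iid in tmap:
            assert f_testlet.item_estimates_[iid].a == pytest.approx(
                f_plain.item_estimates_[iid].a, abs=0.02
            )
            assert f_testlet.item_estimates_[iid].b == pytest.approx(
                f_plain.item_estimates_[iid].b, abs=0.02
            )

    def test_dominant_testlet_inflates_discrimination_under_plain_fit(self):
        # when a single strong testlet carries half the test, ignoring its
        # random effect inflates the testlet items' discriminations and
        # attenuates the independent items' — direction depends on the
        # testlet's share of the form
        rng = np.random.default_rng(3)
        items = []
        for j in range(12):
            a = float(np.exp(rng.normal(0, 0.3))) + 0.3
            b = float(rng.normal(0, 1))
            items.append(DichotomousItemParams(f"i{j:02d}", a, b, "t1" if j >= 6 else None))
        n = 4000
        theta = rng.normal(0, 1, n)
        gam = rng.normal(0, np.sqrt(2.0), n)
        codes = np.empty((n, 12), dtype=np.int16)
        for j, it in enumerate(items):
            t = theta - (gam if it.testlet_id else 0.0)
            codes[:, j] = (expit(it.a * (t - it.b)) > rng.uniform(size=n)).astype(np.int16)
        mat = _matrix(codes, [it.item_id for it in items])
        cal = ConcurrentCalibrator("2PLM", convergence_tol=1e-4).fit(mat)
        err = np.array([cal.item_estimates_[it.item_id].a - it.a for it in items])
        assert err[6:].mean() > 0.3   # testlet items inflated
        assert err[:6].mean() < -0.2  # independent items attenuated

    def test_eap_rmse_floor_reflects_test_information(self):
        from dataclasses import replace

        from trtequate import eap_rmse_floor, printed_form_pair

        items = printed_form_pair("dichotomous", 5).new_items
        floor = eap_rmse_floor(items, n=20_000)
        # 60 pure-logistic items with these slopes cannot score better than ~0.23
        assert 0.21 < floor < 0.25
        steeper = tuple(replace(it, a=2 * it.a) for it in items)
        assert eap_rmse_floor(steeper, n=20_000) < floor

    def test_result_json_round_trip(self, fitted_pair, tmp_path):
        import json

        res = fitted_pair[1].result()
        payload = json.loads(res.to_json())
        assert payload["model_family"] == "2PTM"
        assert len(payload["items"]) == 100
        assert set(payload["testlet_variances"]) == set(res.testlet_variances)
        assert payload["converged"] is True
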