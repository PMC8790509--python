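"""Generator: truncation bounds, form layout, fixtures, responses, determinism."""

import numpy as np
import pytest

from trtequate import (
    MISSING,
    DichotomousItemParams,
    SimulationCondition,
    assemble_concurrent_matrix,
    assign_testlet_variances,
    build_form_pair,
    draw_testlet_variances,
    generate_responses,
    load_printed_forms,
    load_printed_table,
    printed_form_pair,
    replication_rng,
    sample_persons,
)
from trtequate.models import PolytomousItemParams, prob_dichotomous, PersonState
from trtequate.simulate import (
    sample_dichotomous_params,
    sample_discriminations,
    sample_polytomous_params,
)


class TestParameterSampling:
    def test_truncation_bounds_hold(self, rng):
        a = sample_discriminations("non_anchor", rng, 10_000)
        assert a.min() > 0 and a.max() < 2.5
        a_anchor = sample_discriminations("anchor", rng, 10_000)
        assert a_anchor.min() > 1.0 and a_anchor.max() < 2.0
        bs = np.array([sample_dichotomous_params("non_anchor", rng)[1] for _ in range(2_000)])
        assert bs.min() > -3 and bs.max() < 3

    def test_anchor_matches_rejection_oracle(self, rng):
        # independent large-sample rejection sampler for the truncated lognormal
        z = rng.standard_normal(400_000)
        oracle = np.exp(z)
        oracle = oracle[(oracle > 1.0) & (oracle < 2.0)]
        draws = sample_discriminations("anchor", rng, 10_000)
        se = oracle.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - oracle.mean()) < 3 * se

    def test_polytomous_boundaries_sorted_and_match_order_statistics(self, rng):
        n = 10_000
        draws = np.array([sample_polytomous_params("non_anchor", rng)[1] for _ in range(n)])
        assert np.all(np.diff(draws, axis=1) > 0)
        # Monte-Carlo order-statistic oracle: sorted truncated-normal 4-tuples
        z = rng.standard_normal((200_000, 4))
        z = z[np.all(np.abs(z) < 3, axis=1)]
        oracle = np.sort(z, axis=1)
        se = oracle.std(axis=0) / np.sqrt(n)
        assert np.all(np.abs(draws.mean(axis=0) - oracle.mean(axis=0)) < 3 * se)

    def test_two_category_item_gives_single_boundary(self, rng):
        a, bs = sample_polytomous_params("non_anchor", rng, n_categories=2)
        assert len(bs) == 1 and -3 < bs[0] < 3

    def test_variance_levels(self, rng):
        lo = draw_testlet_variances("low", 10_000, rng)
        assert lo.min() >= 0.1 and lo.max() <= 0.5
        hi = draw_testlet_variances("high", 10_000, rng)
        se = (2.0 - 1.1) / np.sqrt(12) / np.sqrt(len(hi))
        assert abs(hi.mean() - 1.55) < 3 * se
        assert draw_testlet_variances("moderate", 0, rng).size == 0
        with pytest.raises(ValueError):
            draw_testlet_variances("extreme", 5, rng)


class TestFormLayout:
    @pytest.mark.parametrize("length,n_nonanchor,n_anchor", [(5, 4, 2), (10, 2, 1)])
    def test_testlet_counts_by_length(self, length, n_nonanchor, n_anchor):
        cond = SimulationCondition(testlet_length=length, sample_size=100, seed=1)
        pair = build_form_pair(cond, replication_rng(1, 0, 99))
        base = pair.testlets_for("base")
        anchors = [t for t in base if t.testlet_id.startswith("anchor")]
        others = [t for t in base if not t.testlet_id.startswith("anchor")]
        assert len(others) == n_nonanchor and len(anchors) == n_anchor
        assert all(len(t.item_ids) == length for t in base)
        assert len(pair.base_items) == 60 and len(pair.new_items) == 60
        assert len(pair.anchor_ids) == 20

    def test_anchor_parameters_shared_exactly(self):
        cond = SimulationCondition(sample_size=100, seed=3)
        pair = build_form_pair(cond, replication_rng(3, 0, 99))
        base = {it.item_id: it for it in pair.base_items}
        new = {it.item_id: it for it in pair.new_items}
        for iid in pair.anchor_ids:
            assert base[iid] == new[iid]

    def test_same_seed_is_bit_identical(self):
        cond = SimulationCondition(sample_size=50, seed=11)
        p1 = build_form_pair(cond, replication_rng(11, 2, 5))
        p2 = build_form_pair(cond, replication_rng(11, 2, 5))
        assert p1 == p2

    def test_assigned_variances_respect_level(self, rng):
        pair = printed_form_pair("dichotomous", 5)
        pair = assign_testlet_variances(pair, "high", rng)
        for spec in pair.all_testlets().values():
            assert 1.1 <= spec.sigma2 <= 2.0


class TestPrintedFixtures:
    def test_dichotomous_reference_values(self):
        df = load_printed_table("dichotomous")
        ref = df[df["form"] == "reference"].set_index("item")
        assert ref.loc[2, "a"] == pytest.approx(2.32)
        assert ref.loc[2, "b"] == pytest.approx(-1.49)
        assert round(ref["a"].mean(), 2) == 1.51
        assert round(ref["a"].std(ddof=1), 2) == 0.36

    def test_polytomous_reference_values(self):
        df = load_printed_table("polytomous")
        ref = df[df["form"] == "reference"].set_index("item")
        assert ref.loc[41, "a"] == pytest.approx(1.21)
        np.testing.assert_allclose(
            ref.loc[41, ["b1", "b2", "b3", "b4"]].to_numpy(dtype=float),
            [-1.40, -1.17, -0.24, 0.80],
        )
        assert round(ref["a"].mean(), 2) == 1.10

    def test_linked_form_pair_shares_reference_anchor_block(self):
        pair = load_printed_forms("dichotomous")
        base = {it.item_id: it for it in pair.base_items}
        new = {it.item_id: it for it in pair.new_items}
        assert len(pair.anchor_ids) == 20
        for iid in pair.anchor_ids:
            assert base[iid] == new[iid]

    def test_printed_pair_with_imposed_layout_validates(self):
        for length in (5, 10):
            pair = printed_form_pair("dichotomous", length)
            pair.validate(testlet_length=length)
        poly = printed_form_pair("polytomous", 5)
        for it in poly.all_items().values():
            assert np.all(np.diff(it.boundaries) > 0)


class TestPersonsAndResponses:
    def test_group_shift_and_gamma_variance(self, small_dich_data, rng):
        pair = small_dich_data["pair"]
        big = sample_persons(100_000, "new", pair.testlets_for("new"), rng, 0.5)
        assert abs(big.thetas.mean() - 0.5) < 3 / np.sqrt(len(big.thetas))
        spec = pair.testlets_for("new")[0]
        g = big.gammas[spec.testlet_id]
        # chi-square sampling error of a variance estimate
        se = spec.sigma2 * np.sqrt(2.0 / len(g))
        assert abs(g.var() - spec.sigma2) < 3 * se
        zero_shift = sample_persons(100, "new", (), rng, 0.0)
        assert zero_shift.thetas.shape == (100,)
        with pytest.raises(ValueError):
            sample_persons(0, "base", (), rng)

    def test_degenerate_item_always_correct(self, rng):
        items = (DichotomousItemParams("easy", 1.0, -30.0),)
        persons = sample_persons(500, "base", (), rng)
        codes = generate_responses(items, persons, rng)
        assert np.all(codes == 1)

    def test_dichotomous_proportions_match_probability(self, rng):
        item = DichotomousItemParams("i", 1.4, -0.3, "t")
        from trtequate import PersonSample

        n = 50_000
        persons = PersonSample("base", np.full(n, 0.7), {"t": np.full(n, 0.4)})
        codes = generate_responses((item,), persons, rng)
        p = prob_dichotomous(item, PersonState(0.7, {"t": 0.4}), use_testlet=True)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(codes.mean() - p) < 3 * se

    def test_polytomous_frequencies_match_category_probs(self, rng):
        from trtequate import PersonSample, grm_category_probs

        item = PolytomousItemParams("p", 1.2, (-1.1, -0.2, 0.5, 1.4), "t")
        n = 50_000
        persons = PersonSample("base", np.full(n, 0.2), {"t": np.full(n, -0.6)})
        codes = generate_responses((item,), persons, rng)[:, 0]
        expected = grm_category_probs(
            item, PersonState(0.2, {"t": -0.6}), use_testlet=True
        )
        freq = np.bincount(codes, minlength=5) / n
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(freq - expected) < 3 * se + 1e-9)

    def test_within_testlet_correlation_exceeds_cross_under_high_effect(self):
        cond = SimulationCondition(
            testlet_effect="high", sample_size=2000, seed=9,
        )
        gen = replication_rng(9, 0, 0)
        pair = build_form_pair(cond, gen)
        persons = sample_persons(2000, "base", pair.testlets_for("base"), gen)
        codes = generate_responses(pair.base_items, persons, gen)
        cols = {it.item_id: j for j, it in enumerate(pair.base_items)}
        corr = np.corrcoef(codes.T)
        within, cross = [], []
        testlets = pair.testlets_for("base")
        for t in testlets:
            idx = [cols[i] for i in t.item_ids]
            for i, ci in enumerate(idx):
                for cj in idx[i + 1:]:
                    within.append(corr[ci, cj])
            other = [
                cols[i] for u in testlets if u.testlet_id != t.testlet_id
                for i in u.item_ids
            ]
            cross.extend(corr[ci, cj] for ci in idx for cj in other[:10])
        assert np.mean(within) > np.mean(cross)


class TestConcurrentAssembly:
    def test_shapes_and_missingness(self, small_dich_data):
        matrix = small_dich_data["matrix"]
        assert len(matrix.item_ids) == 100  # 60 + 60 - 20 shared
        base_rows = matrix.codes[matrix.groups == "base"]
        new_rows = matrix.codes[matrix.groups == "new"]
        assert np.all((base_rows == MISSING).sum(axis=1) == 40)
        assert np.all((new_rows == MISSING).sum(axis=1) == 40)
        anchor_cols = [matrix.column(i) for i in small_dich_data["pair"].anchor_ids]
        assert not np.any(matrix.codes[:, anchor_cols] == MISSING)

    def test_regeneration_is_bit_identical(self, small_dich_data):
        cond = small_dich_data["condition"]
        gen = replication_rng(42, 0, 0)
        pair = build_form_pair(cond, gen)
        pb = sample_persons(cond.sample_size, "base", pair.testlets_for("base"), gen)
        pn = sample_persons(cond.sample_size, "new", pair.testlets_for("new"), gen, 0.5)
        matrix = assemble_concurrent_matrix(
            generate_responses(pair.base_items, pb, gen),
            generate_responses(pair.new_items, pn, gen),
            pair,
        )
        np.testing.assert_array_equal(matrix.codes, small_dich_data["matrix"].codes)
        assert pair == small_dich_data["pair"]


class TestIO:
    def test_matrix_and_form_round_trip(self, small_dich_data, tmp_path):
        from trtequate.io import (
            read_form_pair,
            read_response_matrix,
            write_form_pair,
            write_response_matrix,
        )

        matrix = small_dich_data["matrix"]
        write_response_matrix(matrix, tmp_path / "m.tsv")
        back = read_response_matrix(tmp_path / "m.tsv")
        np.testing.assert_array_equal(back.codes, matrix.codes)
        assert back.item_ids == matrix.item_ids

        pair = small_dich_data["pair"]
        write_form_pair(pair, tmp_path / "i.tsv", tmp_path / "t.tsv")
        back_pair = read_form_pair(tmp_path / "i.tsv", tmp_path / "t.tsv")
        assert {i.item_id for i in back_pair.base_items} == {
            i.item_id for i in pair.base_items
        }
        orig = pair.all_items()
        for iid, item in back_pair.all_items().items():
            assert item.a == pytest.approx(orig[iid].a)
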