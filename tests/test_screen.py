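import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from fgrscreen.cohort_types import AbundanceMatrix
from fgrscreen.data import CANDIDATE_DIRECTIONS, CANDIDATE_IDS, candidate_annotations
from fgrscreen.screen import (
    BrainAnnotation,
    CandidateSet,
    QvalueConfig,
    ScreenRow,
    brain_expression_filter,
    concordant_candidates,
    estimate_pi0,
    rank_transform,
    screen_day,
    spearman_pvalue,
    spearman_rho,
    storey_qvalues,
    union_report,
)


class TestRanksAndRho:
    @pytest.mark.parametrize(
        "values, expected",
        [([3, 1, 2], [3, 1, 2]), ([5, 5, 1], [2.5, 2.5, 1]), ([7], [1])],
    )
    def test_midrank_transform(self, values, expected):
        assert rank_transform(values).tolist() == expected

    def test_rank_transform_rejects_nan(self):
        with pytest.raises(ValueError, match="index 1"):
            rank_transform([1.0, np.nan, 2.0])

    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [10, 20, 30], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4, 5], [2, 1, 4, 3, 5], 0.8),  # 1 - 6*4/(5*24)
        ],
    )
    def test_spearman_examples(self, x, y, expected):
        assert spearman_rho(x, y) == pytest.approx(expected)

    def test_constant_vector_is_undefined(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_matches_scipy_and_is_rank_invariant(self, rng):
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            rho = spearman_rho(x, y)
            assert rho == pytest.approx(spearmanr(x, y).statistic)
            # invariant under strictly increasing transforms; negation flips sign
            assert spearman_rho(np.exp(x), y**3 + 2 * y) == pytest.approx(rho)
            assert spearman_rho(x, -y) == pytest.approx(-rho)


class TestSpearmanPvalue:
    def test_zero_rho_gives_one(self):
        assert spearman_pvalue(0.0, 10) == 1.0

    def test_t_approx_small_sample_value(self):
        # t = 0.8 * sqrt(3 / 0.36) = 2.3094 on 3 df
        assert spearman_pvalue(0.8, 5) == pytest.approx(0.1041, abs=2e-4)

    def test_perfect_correlation(self):
        assert 0 < spearman_pvalue(1.0, 8) < 1e-12
        assert spearman_pvalue(1.0, 5, method="exact_perm") == pytest.approx(2 / 120)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            spearman_pvalue(0.5, 3)
        with pytest.raises(ValueError):
            spearman_pvalue(1.2, 10)
        with pytest.raises(ValueError):
            spearman_pvalue(0.5, 10, method="exact_perm")

    def test_t_approx_close_to_exact_at_n8(self, rng):
        """The t approximation tracks the exact permutation null within 0.02
        (against the mid-p of the discrete null, whose atoms the continuous
        approximation splits)."""
        import itertools

        base = np.arange(1, 9, dtype=float)
        perms = np.array(list(itertools.permutations(base)))
        c = base - base.mean()
        null = np.abs(((perms - base.mean()) * c).sum(axis=1) / (c * c).sum())
        worst = 0.0
        for _ in range(200):
            x, y = rng.normal(size=8), rng.normal(size=8)
            rho = spearman_rho(x, y)
            mid = 0.5 * ((null >= abs(rho) - 1e-12).mean() + (null > abs(rho) + 1e-12).mean())
            worst = max(worst, abs(spearman_pvalue(rho, 8) - mid))
            # the implementation's exact_perm mode is the P(>= obs) convention
            assert spearman_pvalue(rho, 8, method="exact_perm") == pytest.approx(
                (null >= abs(rho) - 1e-12).mean()
            )
        assert worst <= 0.02


class TestStoreyQ:
    def test_pi0_on_uniform_null(self, rng):
        p = rng.uniform(size=10_000)
        assert 0.95 <= estimate_pi0(p) <= 1.0

    def test_pi0_fixed_mode(self):
        cfg = QvalueConfig(pi0_mode="fixed", pi0_fixed=1.0)
        assert estimate_pi0([0.2, 0.8, 0.5], cfg) == 1.0

    def test_pi0_clamps_to_floor_when_all_small(self):
        p = np.full(100, 0.001)
        assert estimate_pi0(p) == pytest.approx(1 / 100)

    def test_pi0_smoother_falls_back_below_m10(self, caplog):
        with caplog.at_level("WARNING"):
            assert estimate_pi0([0.5] * 5) == 1.0
        assert "m >= 10" in caplog.text

    @pytest.mark.parametrize(
        "p, expected",
        [
            ([1, 1, 1, 1], [1, 1, 1, 1]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.001, 0.5, 0.9], [0.003, 0.75, 0.9]),
        ],
    )
    def test_qvalue_examples(self, p, expected):
        assert storey_qvalues(p, pi0=1.0) == pytest.approx(expected)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    @settings(max_examples=150, deadline=None)
    def test_qvalues_with_unit_pi0_equal_benjamini_hochberg(self, p):
        q = storey_qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        assert q == pytest.approx(bh, abs=1e-12)

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=50),
        st.floats(min_value=0.1, max_value=1.0),
    )
    @settings(max_examples=150, deadline=None)
    def test_qvalue_order_and_bounds(self, p, pi0):
        q = storey_qvalues(p, pi0=pi0)
        assert np.all(q <= 1.0) and np.all(q >= 0.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= pi0 + 1e-12)


class TestScreenDay:
    def _matrix(self, values, samples, day="PND4"):
        return AbundanceMatrix(day, pd.DataFrame(values, columns=samples))

    def test_protein_tracking_weight_is_significant(self, rng):
        weights = {f"s{i}": w for i, w in enumerate(rng.normal(6.5, 0.7, 20))}
        samples = list(weights)
        vals = rng.lognormal(1, 0.3, size=(30, 20))
        vals[0] = [weights[s] for s in samples]  # protein 0 equals birth weight
        rows = screen_day(self._matrix(vals, samples), weights)
        assert rows[0].rho == pytest.approx(1.0)
        assert rows[0].significant

    def test_missing_weight_raises_with_ids(self, rng):
        vals = rng.lognormal(1, 0.3, size=(5, 6))
        mat = self._matrix(vals, [f"s{i}" for i in range(6)])
        with pytest.raises(ValueError, match="s5"):
            screen_day(mat, {f"s{i}": 6.0 + i for i in range(5)})

    def test_nan_rows_use_complete_pairs_and_low_n_excluded(self, rng):
        weights = {f"s{i}": 6.0 + 0.1 * i for i in range(10)}
        vals = rng.lognormal(1, 0.3, size=(4, 10))
        vals[1, :3] = np.nan  # 7 complete pairs
        vals[2, :8] = np.nan  # 2 complete pairs -> excluded
        frame = pd.DataFrame(vals, columns=list(weights))
        rows = screen_day(frame, weights)
        assert rows[1].n == 7 and np.isfinite(rows[1].p_value)
        assert rows[2].n == 2 and not rows[2].significant and np.isnan(rows[2].q_value)

    def test_screen_recovers_planted_directions(self, config):
        from fgrscreen.cohort_sim import gen_cohort, gen_proteome

        cohort = gen_cohort(config)
        a4, _, truth = gen_proteome(cohort, config)
        rows = screen_day(a4, {p.pup_id: p.birth_weight_g for p in cohort})
        by_id = {r.protein_id: r for r in rows}
        for pid, direction in truth.directions.items():
            assert np.sign(by_id[pid].rho) == direction


def _row(pid, day, rho, sig):
    p = 0.01 if sig else 0.5
    return ScreenRow(pid, day, 20, rho, p, p, sig)


class TestConcordance:
    def test_direction_consistency(self):
        day4 = [_row("A", "PND4", -0.8, True), _row("B", "PND4", -0.8, True),
                _row("C", "PND4", 0.7, True), _row("D", "PND4", 0.9, False)]
        day5 = [_row("A", "PND5", -0.6, True), _row("B", "PND5", 0.6, True),
                _row("C", "PND5", 0.5, True), _row("D", "PND5", 0.9, True)]
        cs = concordant_candidates(day4, day5)
        assert cs.overlap == {"A", "B", "C"}
        assert cs.consistent_direction == {"A", "C"}
        assert cs.directions == {"A": -1, "C": 1}

    def test_single_day_proteins_dropped(self):
        day4 = [_row("A", "PND4", -0.8, True), _row("X", "PND4", -0.8, True)]
        day5 = [_row("A", "PND5", -0.8, True)]
        cs = concordant_candidates(day4, day5)
        assert cs.overlap == {"A"}

    def test_nesting_invariant_enforced(self):
        with pytest.raises(ValueError):
            CandidateSet(
                sig_day4=frozenset("A"), sig_day5=frozenset("A"),
                overlap=frozenset("A"), consistent_direction=frozenset("AB"),
                brain_filtered=frozenset(), directions={},
            )


class TestBrainFilter:
    def _candidates(self, ids):
        s = frozenset(ids)
        return CandidateSet(s, s, s, s, frozenset(),
                            {i: CANDIDATE_DIRECTIONS.get(i, 1) for i in ids})

    def test_reference_panel_retains_exactly_six(self):
        """The >=Medium neuronal/glial/Purkinje rule keeps 6 of the 15
        reference candidates."""
        out = brain_expression_filter(
            self._candidates(CANDIDATE_IDS), candidate_annotations()
        )
        assert out.brain_filtered == {"Cd200", "A2m", "Ubb", "Serpini1", "Otub1", "Ube1"}

    def test_low_endothelial_only_is_excluded(self):
        ann = BrainAnnotation("X", (("cerebral_cortex", "endothelial", "low"),))
        out = brain_expression_filter(self._candidates(["X"]), [ann])
        assert not out.brain_filtered

    def test_empty_annotation_entries_excluded(self):
        out = brain_expression_filter(
            self._candidates(["X"]), [BrainAnnotation("X", ())]
        )
        assert not out.brain_filtered and not out.needs_review

    def test_missing_record_goes_to_needs_review(self):
        out = brain_expression_filter(self._candidates(["X"]), [])
        assert out.needs_review == {"X"} and not out.brain_filtered

    def test_rule_is_configurable(self):
        ann = BrainAnnotation("X", (("hippocampus", "endothelial", "high"),))
        strict = brain_expression_filter(self._candidates(["X"]), [ann])
        loose = brain_expression_filter(
            self._candidates(["X"]), [ann],
            cell_classes={"neuronal", "glial", "purkinje", "endothelial"},
        )
        assert not strict.brain_filtered and loose.brain_filtered == {"X"}

    def test_filtered_subset_of_consistent(self):
        out = brain_expression_filter(
            self._candidates(CANDIDATE_IDS), candidate_annotations()
        )
        assert out.brain_filtered <= out.consistent_direction


class TestUnion:
    @pytest.mark.parametrize(
        "n4, n5, nov, expected", [(140, 123, 51, 212), (10, 10, 10, 10), (3, 4, 0, 7)]
    )
    def test_union_arithmetic(self, n4, n5, nov, expected):
        assert union_report(n4, n5, nov) == expected

    def test_invalid_overlap(self):
        with pytest.raises(ValueError):
            union_report(5, 4, 5)
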