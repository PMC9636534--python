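"""Gold-code collapsing, discretization, and agreement statistics."""

import math

import numpy as np
import pytest

from flashmobile import (
    AgreementClass,
    GoldCode,
    GoldSegment,
    GoldTimeline,
    UserLabel,
    cohen_kappa,
    collapse_gold,
    dyad_agreement_report,
    icc_absolute_agreement,
    pabak,
)
from flashmobile.agreement import (
    confusion_matrix,
    discretize_device,
    discretize_gold,
)
from flashmobile.attribution import AttributedInterval

S = 1000


class TestCollapseGold:
    @pytest.mark.parametrize(
        "code,expected",
        [
            (GoldCode.CHILD_SCREEN, AgreementClass.CHILD_USE),
            (GoldCode.BOTH_SCREEN, AgreementClass.CHILD_USE),
            (GoldCode.CHILD_MULTITASK, AgreementClass.CHILD_USE),
            (GoldCode.PARENT_SCREEN, AgreementClass.OTHER_USE),
            (GoldCode.CHILD_AUDIO, AgreementClass.NO_USE),
            (GoldCode.PARENT_AUDIO, AgreementClass.NO_USE),
            (GoldCode.BOTH_AUDIO, AgreementClass.NO_USE),
            (GoldCode.NO_USE, AgreementClass.NO_USE),
            (GoldCode.UNCERTAIN, AgreementClass.EXCLUDED),
            (GoldCode.OUT_OF_FRAME, AgreementClass.EXCLUDED),
        ],
    )
    def test_ten_code_collapse(self, code, expected):
        assert collapse_gold(code) is expected

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            collapse_gold("scrolling")


class TestDiscretize:
    def test_single_segment_gives_constant_sequence(self):
        tl = GoldTimeline([GoldSegment(0, 10 * S, GoldCode.CHILD_SCREEN)], (0, 10 * S))
        assert discretize_gold(tl, (0, 10 * S)) == [AgreementClass.CHILD_USE] * 10

    def test_boundary_on_grid_line_labels_each_cell_once(self):
        tl = GoldTimeline(
            [GoldSegment(0, 5 * S, GoldCode.CHILD_SCREEN),
             GoldSegment(5 * S, 10 * S, GoldCode.NO_USE)],
            (0, 10 * S),
        )
        seq = discretize_gold(tl, (0, 10 * S))
        assert seq == [AgreementClass.CHILD_USE] * 5 + [AgreementClass.NO_USE] * 5

    def test_majority_rule_with_tie_to_earlier_segment(self):
        # cell [0,1s): 500 ms child vs 500 ms parent -> earlier segment wins
        tl = GoldTimeline(
            [GoldSegment(0, 500, GoldCode.CHILD_SCREEN),
             GoldSegment(500, 1000, GoldCode.PARENT_SCREEN)],
            (0, 1000),
        )
        assert discretize_gold(tl, (0, 1000)) == [AgreementClass.CHILD_USE]

    def test_device_uncovered_cells_are_no_use(self):
        att = [AttributedInterval("a", 2 * S, 4 * S, UserLabel.CHILD)]
        seq = discretize_device(att, (0, 6 * S))
        assert seq == [AgreementClass.NO_USE] * 2 + [AgreementClass.CHILD_USE] * 2 + [
            AgreementClass.NO_USE
        ] * 2

    def test_refinement_changes_totals_by_at_most_one_cell_per_boundary(self):
        rng = np.random.default_rng(4)
        cuts = np.sort(rng.integers(1, 600_000, size=8))
        bounds = [0, *cuts.tolist(), 600_000]
        codes = [
            [GoldCode.CHILD_SCREEN, GoldCode.PARENT_SCREEN, GoldCode.NO_USE][i % 3]
            for i in range(len(bounds) - 1)
        ]
        tl = GoldTimeline(
            [GoldSegment(a, b, c) for a, b, c in zip(bounds, bounds[1:], codes) if b > a],
            (0, 600_000),
        )
        coarse = discretize_gold(tl, (0, 600_000), resolution_s=1.0)
        fine = discretize_gold(tl, (0, 600_000), resolution_s=0.1)
        for cls in (AgreementClass.CHILD_USE, AgreementClass.OTHER_USE,
                    AgreementClass.NO_USE):
            c_s = coarse.count(cls) * 1.0
            f_s = fine.count(cls) * 0.1
            assert abs(c_s - f_s) <= len(bounds)  # one coarse cell per boundary


class TestConfusionMatrix:
    def test_identical_sequences_po_one(self):
        seq = [AgreementClass.CHILD_USE] * 5 + [AgreementClass.NO_USE] * 5
        res = confusion_matrix(seq, seq)
        assert res.overall_po == 1.0
        assert res.per_class_gold_conditional[AgreementClass.CHILD_USE] == 1.0

    def test_total_disagreement_po_zero(self):
        gold = [AgreementClass.CHILD_USE] * 4
        dev = [AgreementClass.OTHER_USE] * 4
        assert confusion_matrix(gold, dev).overall_po == 0.0

    def test_hand_built_matrix_po(self):
        """Counts (50,5,3,2 / 4,30,1,0 / 0,0,0,0 / 2,1,0,52): Po = 132/150."""
        rows = [
            (AgreementClass.CHILD_USE, [50, 5, 3, 2]),
            (AgreementClass.OTHER_USE, [4, 30, 1, 0]),
            (AgreementClass.UNIDENTIFIED, [0, 0, 0, 0]),
            (AgreementClass.NO_USE, [2, 1, 0, 52]),
        ]
        order = [AgreementClass.CHILD_USE, AgreementClass.OTHER_USE,
                 AgreementClass.UNIDENTIFIED, AgreementClass.NO_USE]
        gold, dev = [], []
        for g, counts in rows:
            for d, c in zip(order, counts):
                gold += [g] * c
                dev += [d] * c
        res = confusion_matrix(gold, dev)
        assert res.overall_po == pytest.approx(132 / 150, abs=1e-15)
        assert math.isnan(res.per_class_gold_conditional[AgreementClass.UNIDENTIFIED])

    def test_excluded_gold_cells_dropped_without_touching_others(self):
        gold = [AgreementClass.CHILD_USE, AgreementClass.EXCLUDED, AgreementClass.NO_USE]
        dev = [AgreementClass.CHILD_USE, AgreementClass.CHILD_USE, AgreementClass.NO_USE]
        res = confusion_matrix(gold, dev)
        assert res.n_scored_cells == 2 and res.overall_po == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([AgreementClass.NO_USE], [])


class TestCohenKappa:
    def test_perfect_diagonal_is_one(self):
        assert cohen_kappa(np.diag([10, 20, 5, 7])) == 1.0

    def test_outer_product_margins_give_zero(self):
        p = np.array([0.5, 0.2, 0.2, 0.1])
        q = np.array([0.25, 0.25, 0.3, 0.2])
        conf = np.outer(p, q) * 1000
        assert cohen_kappa(conf) == pytest.approx(0.0, abs=1e-12)

    def test_two_by_two_closed_form(self):
        """[[40,10],[10,40]]: Po=0.8, Pe=0.5, kappa = 0.6."""
        assert cohen_kappa(np.array([[40, 10], [10, 40]])) == pytest.approx(0.6, abs=1e-12)

    def test_matches_sklearn_on_random_labelings(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 4, size=300)
            b = np.where(rng.random(300) < 0.6, a, rng.integers(0, 4, size=300))
            conf = np.zeros((4, 4))
            np.add.at(conf, (a, b), 1)
            assert cohen_kappa(conf) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12
            )


class TestPabak:
    @pytest.mark.parametrize("k", [2, 3, 4, 10])
    def test_perfect_agreement_is_one(self, k):
        assert pabak(1.0, k) == 1.0

    def test_k2_is_2po_minus_1(self):
        assert pabak(0.8, 2) == pytest.approx(0.6, abs=1e-15)

    def test_k4_example(self):
        assert pabak(0.7, 4) == pytest.approx((2.8 - 1) / 3, abs=1e-15)

    def test_strictly_increasing_in_po(self):
        vals = [pabak(po, 4) for po in np.linspace(0, 1, 50)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            pabak(0.5, 1)

    def test_kappa_equals_pabak_on_uniform_marginals(self):
        # uniform margins with constant off-diagonal: kappa == PABAK
        conf = np.full((4, 4), 5.0)
        np.fill_diagonal(conf, 50.0)
        po = np.trace(conf) / conf.sum()
        assert cohen_kappa(conf) == pytest.approx(pabak(po, 4), abs=1e-12)


class TestICC:
    def test_identical_pairs_give_one(self):
        pairs = [(3, 3), (7, 7), (12, 12), (20, 20)]
        assert icc_absolute_agreement(pairs) == pytest.approx(1.0, abs=1e-12)

    def test_constant_offset_penalized_below_one(self):
        pairs = [(x, x + 50) for x in (3, 7, 12, 20)]
        assert icc_absolute_agreement(pairs) < 1.0

    def test_six_dyad_fixture_matches_hand_anova(self):
        """Six dyads; expected value from the two-way ANOVA table done by
        hand (mean squares MSR, MSC, MSE -> ICC(2,1))."""
        pairs = [(10, 12), (20, 19), (15, 18), (30, 26), (8, 9), (25, 28)]
        arr = np.array(pairs, float)
        n, k = arr.shape
        grand = arr.mean()
        msr = k * ((arr.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((arr.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (
            ((arr - grand) ** 2).sum()
            - k * ((arr.mean(1) - grand) ** 2).sum()
            - n * ((arr.mean(0) - grand) ** 2).sum()
        ) / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc_absolute_agreement(pairs) == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin_icc2(self):
        import pandas as pd
        import pingouin as pg

        pairs = [(10, 12), (20, 19), (15, 18), (30, 26), (8, 9), (25, 28)]
        df = pd.DataFrame(
            {
                "targets": list(range(6)) * 2,
                "raters": ["gold"] * 6 + ["device"] * 6,
                "score": [p[0] for p in pairs] + [p[1] for p in pairs],
            }
        )
        icc = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="score")
        # absolute-agreement single-measures row; label varies across versions
        mask = icc["Type"].isin(["ICC2", "ICC(A,1)"])
        ref = float(icc.loc[mask, "ICC"].iloc[0])
        assert icc_absolute_agreement(pairs) == pytest.approx(ref, abs=1e-10)

    def test_permuting_dyads_leaves_icc_unchanged(self):
        pairs = [(10, 12), (20, 19), (15, 18), (30, 26)]
        assert icc_absolute_agreement(pairs) == pytest.approx(
            icc_absolute_agreement(list(reversed(pairs))), abs=1e-12
        )

    def test_zero_variance_not_applicable(self):
        assert math.isnan(icc_absolute_agreement([(5, 5), (5, 5), (5, 5)]))


class TestDyadReport:
    def test_perfect_compliance_limit_full_agreement(self, perfect_config):
        from flashmobile import measure, render_gold_codes, simulate_household

        gt, log = simulate_household(perfect_config)
        att, _, _ = measure(log)
        res = dyad_agreement_report(render_gold_codes(gt), att)
        assert res.overall_po == 1.0 and res.pabak == 1.0 and res.kappa == 1.0
        assert res.per_class_gold_conditional[AgreementClass.CHILD_USE] == 1.0

    def test_zero_compliance_limit_unidentified_dominates(self):
        from flashmobile import measure, render_gold_codes, simulate_household
        from conftest import small_config

        gt, log = simulate_household(small_config(seed=2, p_comply=0.0))
        att, _, _ = measure(log)
        res = dyad_agreement_report(render_gold_codes(gt), att)
        unid_col = res.confusion[:, 2].sum()
        use_cols = res.confusion[:, :2].sum()
        assert unid_col > 0 and use_cols == 0  # all use unidentified
        gc = res.per_class_gold_conditional[AgreementClass.CHILD_USE]
        assert math.isnan(gc) or gc == 0.0

    def test_disjoint_spans_rejected(self):
        tl = GoldTimeline([GoldSegment(0, 10 * S, GoldCode.NO_USE)], (0, 10 * S))
        att = [AttributedInterval("a", 20 * S, 30 * S, UserLabel.CHILD)]
        with pytest.raises(ValueError):
            dyad_agreement_report(tl, att)
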