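"""Expert-panel protocol: distribution, summaries, consolidation, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irgdose import (
    IRG,
    CalibrationOffsets,
    CellScore,
    ExpertScore,
    ScoreSummary,
    StrategyAssignment,
    apply_calibration,
    build_score_sets,
    compute_group_offsets,
    consolidate_cell,
    distribute_irgs,
    flag_for_debate,
    summarize_cell,
)
from irgdose.errors import (
    IncompleteCalibrationError,
    InconsistentCellError,
    InsufficientRatersError,
    MissingOffsetError,
    ProtocolViolationError,
    ScoreRangeError,
)
from irgdose.scoring import FICTITIOUS_SETTING


def make_scores(values, round=1, setting="s1", group="G1", domain="delivery",
                declension="quantity", period="p1", activity_class="NPDA"):
    return [
        ExpertScore(
            expert_id=f"E{k}", group_id=group, setting=setting, intervention="int1",
            activity_class=activity_class, period=period, domain=domain,
            declension=declension, round=round, value=v,
        )
        for k, v in enumerate(values)
    ]


scores_in_range = st.lists(
    st.floats(0, 20, allow_nan=False, width=32), min_size=2, max_size=8
)


class TestDistributeIrgs:
    def test_balanced_partition(self, pralimap):
        _, assignment = pralimap
        from irgdose import enumerate_irgs

        irgs = enumerate_irgs(assignment)
        allocation = distribute_irgs(irgs, ["G1", "G2", "G3"], seed=7)
        assert sorted(len(v) for v in allocation.values()) == [24, 24, 24]
        allocated = [irg for group in allocation.values() for irg in group]
        assert sorted(map(str, allocated)) == sorted(map(str, irgs))

    def test_single_group_gets_all(self):
        irgs = [IRG(f"s{k}", "i", "control") for k in range(5)]
        assert len(distribute_irgs(irgs, ["G1"], seed=0)["G1"]) == 5

    def test_seed_determinism(self):
        irgs = [IRG(f"s{k}", "i", "control") for k in range(7)]
        a = distribute_irgs(irgs, ["G1", "G2"], seed=42)
        b = distribute_irgs(irgs, ["G1", "G2"], seed=42)
        assert a == b

    @given(n=st.integers(0, 30), g=st.integers(1, 5), seed=st.integers(0, 100))
    @settings(max_examples=40, derandomize=True)
    def test_fairness_invariant(self, n, g, seed):
        irgs = [IRG(f"s{k}", "i", "control") for k in range(n)]
        allocation = distribute_irgs(irgs, [f"G{k}" for k in range(g)], seed=seed)
        sizes = [len(v) for v in allocation.values()]
        assert sum(sizes) == n
        assert max(sizes) - min(sizes) <= 1


class TestSummarizeCell:
    def test_hand_computed_statistics(self):
        summary = summarize_cell(make_scores([10, 12, 14, 16, 18, 20]))
        assert summary.mean == pytest.approx(15.0)
        assert summary.sd == pytest.approx(math.sqrt(14), abs=5e-4)  # 3.742 at 3 d.p.
        assert round(summary.sd, 3) == 3.742
        assert summary.range == pytest.approx(10.0)
        assert summary.n_experts == 6

    def test_identical_scores(self):
        summary = summarize_cell(make_scores([13.0] * 6))
        assert (summary.mean, summary.sd, summary.range) == (13.0, 0.0, 0.0)
        assert not summary.flagged

    def test_full_scale_range(self):
        assert summarize_cell(make_scores([0.0, 20.0])).range == 20.0

    def test_insufficient_raters(self):
        with pytest.raises(InsufficientRatersError):
            summarize_cell(make_scores([10.0]))

    def test_mixed_cells_rejected(self):
        mixed = make_scores([10.0], setting="s1") + make_scores([11.0], setting="s2")
        with pytest.raises(InconsistentCellError):
            summarize_cell(mixed)
        rounds = make_scores([10.0], round=1) + make_scores([11.0], round=2)
        with pytest.raises(InconsistentCellError):
            summarize_cell(rounds)


class TestFlagForDebate:
    @pytest.mark.parametrize(
        "sd, rng, expected",
        [
            (2.6, 5.0, True),   # SD alone triggers
            (2.5, 6.0, False),  # thresholds are strict: at the boundary, no debate
            (0.0, 7.0, True),   # range alone triggers (disjunction)
            (2.49, 5.99, False),
            (2.51, 0.0, True),
        ],
    )
    def test_threshold_rule(self, sd, rng, expected):
        summary = ScoreSummary(("s", "i", "NPDA", "p", "delivery", "quantity"),
                               round=1, n_experts=6, mean=10.0, sd=sd, range=rng)
        assert flag_for_debate(summary) is expected

    @given(values=scores_in_range, scale=st.floats(1.0, 3.0))
    @settings(max_examples=60, derandomize=True)
    def test_flagging_is_monotone_in_dispersion(self, values, scale):
        """Moving every score further from the cell mean never unflags."""
        base = summarize_cell(make_scores(values))
        mean = float(np.mean(values))
        widened = [min(max(mean + scale * (v - mean), 0.0), 20.0) for v in values]
        # clamping may shrink extreme deviations back; skip those cases
        if max(abs(v - mean) for v in widened) >= max(abs(v - mean) for v in values):
            wide = summarize_cell(make_scores(widened))
            if base.flagged:
                assert wide.flagged


class TestConsolidateCell:
    def test_unflagged_round1_mean(self):
        assert consolidate_cell(make_scores([8, 10, 12])) == pytest.approx(10.0)

    def test_round2_replaces_round1(self):
        round1 = make_scores([8, 18, 10])  # range 10 -> flagged
        round2 = make_scores([14, 14, 14], round=2)
        assert consolidate_cell(round1, round2) == pytest.approx(14.0)

    def test_discrepant_round2_mean_preserved(self):
        round1 = make_scores([8, 18, 10])
        round2 = make_scores([10, 18], round=2)  # still no consensus
        assert consolidate_cell(round1, round2) == pytest.approx(14.0)

    def test_round2_for_unflagged_cell_is_protocol_violation(self):
        round1 = make_scores([10, 11, 12])
        round2 = make_scores([11, 11], round=2)
        with pytest.raises(ProtocolViolationError):
            consolidate_cell(round1, round2)

    @given(r1=scores_in_range, r2=scores_in_range)
    @settings(max_examples=60, derandomize=True)
    def test_final_within_contributing_round_bounds(self, r1, r2):
        round1 = make_scores(r1)
        flagged = summarize_cell(round1).flagged
        if flagged:
            final = consolidate_cell(round1, make_scores(r2, round=2))
            lo, hi = min(r2), max(r2)
        else:
            final = consolidate_cell(round1)
            lo, hi = min(r1), max(r1)
        assert lo - 1e-9 <= final <= hi + 1e-9


def fictitious_scores(group_values):
    """group_values: mapping group -> list of scores on the fictitious IRG."""
    out = []
    for group, values in group_values.items():
        out.extend(
            make_scores(values, setting=FICTITIOUS_SETTING, group=group)
        )
    return out


class TestCalibration:
    def test_offsets_from_group_means(self):
        offsets = compute_group_offsets(
            fictitious_scores({"G1": [12, 12], "G2": [14, 14], "G3": [16, 16]})
        )
        assert offsets.offsets == pytest.approx({"G1": -2.0, "G2": 0.0, "G3": 2.0})
        assert offsets.grand_mean == pytest.approx(14.0)

    def test_identical_groups_zero_offsets(self):
        offsets = compute_group_offsets(
            fictitious_scores({"G1": [13, 13], "G2": [13, 13]})
        )
        assert all(o == pytest.approx(0.0) for o in offsets.offsets.values())

    def test_two_groups(self):
        offsets = compute_group_offsets(
            fictitious_scores({"G1": [10, 10], "G2": [13, 13]})
        )
        assert offsets.offsets == pytest.approx({"G1": -1.5, "G2": 1.5})

    def test_missing_group_raises(self):
        scores = fictitious_scores({"G1": [10, 10], "G2": [12, 12]})
        with pytest.raises(IncompleteCalibrationError, match="G3"):
            compute_group_offsets(scores, group_ids=["G1", "G2", "G3"])

    def test_single_group_raises(self):
        with pytest.raises(IncompleteCalibrationError):
            compute_group_offsets(fictitious_scores({"G1": [10, 10]}))

    def test_non_fictitious_input_rejected(self):
        with pytest.raises(InconsistentCellError):
            compute_group_offsets(make_scores([10, 11]))

    @given(
        means=st.lists(st.floats(2, 18, allow_nan=False), min_size=2, max_size=5)
    )
    @settings(max_examples=50, derandomize=True)
    def test_offsets_sum_to_zero_and_equalize(self, means):
        groups = {f"G{k}": [m, m] for k, m in enumerate(means)}
        offsets = compute_group_offsets(fictitious_scores(groups))
        assert sum(offsets.offsets.values()) == pytest.approx(0.0, abs=1e-9)
        # subtracting each group's offset equalises the fictitious means exactly
        adjusted = {g: np.mean(v) - offsets.offsets[g] for g, v in groups.items()}
        assert np.ptp(list(adjusted.values())) == pytest.approx(0.0, abs=1e-9)


def cell(value, group="G1", setting="s1", domain="delivery", declension="quantity"):
    return CellScore(setting, "int1", "NPDA", "p1", domain, declension,
                     group_id=group, value=value)


class TestApplyCalibration:
    def test_subtracts_offset(self):
        offsets = CalibrationOffsets({"G1": 2.0}, grand_mean=12.0)
        out = apply_calibration([cell(12.0)], offsets)
        assert out[0].value == pytest.approx(10.0)

    def test_clamps_to_scale(self):
        offsets = CalibrationOffsets({"G1": 2.0}, grand_mean=12.0)
        assert apply_calibration([cell(1.0)], offsets)[0].value == 0.0
        low = CalibrationOffsets({"G1": -2.0}, grand_mean=12.0)
        assert apply_calibration([cell(19.5)], low, mas=20.0)[0].value == 20.0

    def test_zero_offset_is_identity(self):
        offsets = CalibrationOffsets({"G1": 0.0}, grand_mean=12.0)
        assert apply_calibration([cell(7.3)], offsets)[0].value == 7.3

    def test_fictitious_scores_excluded(self):
        offsets = CalibrationOffsets({"G1": 0.0}, grand_mean=12.0)
        out = apply_calibration([cell(7.0), cell(9.0, setting=FICTITIOUS_SETTING)], offsets)
        assert len(out) == 1 and out[0].setting == "s1"

    def test_unknown_group_raises(self):
        offsets = CalibrationOffsets({"G1": 0.0}, grand_mean=12.0)
        with pytest.raises(MissingOffsetError):
            apply_calibration([cell(7.0, group="G9")], offsets)


class TestBuildScoreSets:
    def _assignment(self):
        return StrategyAssignment.from_active_sets(("s1",), ("int1",), {"int1": ["s1"]})

    def _four_cells(self, values=(13.6, 12.2, 12.2, 11.4)):
        keys = [("delivery", "quantity"), ("delivery", "quality"),
                ("participation", "quantity"), ("participation", "quality")]
        return [cell(v, domain=d, declension=q) for (d, q), v in zip(keys, values)]

    def test_complete_triple(self):
        sets, incomplete = build_score_sets(self._four_cells(), self._assignment())
        assert incomplete == []
        (ss,) = sets
        assert (ss.dqt, ss.dql, ss.pqt, ss.pql) == (13.6, 12.2, 12.2, 11.4)
        assert ss.irg.is_active

    def test_incomplete_triple_reported_not_built(self):
        sets, incomplete = build_score_sets(self._four_cells()[:3], self._assignment())
        assert sets == []
        (rec,) = incomplete
        assert rec.missing == (("participation", "quality"),)

    def test_study_scale_triples(self):
        """72 NPDA + 36 PDA triples per period -> 108 score sets per period."""
        from irgdose import SimulationConfig, generate_true_scores, true_score_sets

        config = SimulationConfig(n_periods=1, score_sd=0.0, seed=0)
        from irgdose import pralimap_programme

        programme, assignment = pralimap_programme(n_periods=1)
        truth = generate_true_scores(programme, assignment, config, seed=0)
        assert len(true_score_sets(truth)) == 108

    def test_out_of_range_score_rejected(self):
        bad = self._four_cells(values=(25.0, 12.0, 12.0, 12.0))
        with pytest.raises(ScoreRangeError):
            build_score_sets(bad, self._assignment())
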