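"""End-to-end wiring: expert scores -> consolidated cells -> calibrated doses."""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass

from .dose import Dose, compute_all_doses
from .programme import Programme, StrategyAssignment
from .scoring import (
    DEFAULT_RANGE_THRESHOLD,
    DEFAULT_SD_THRESHOLD,
    CalibrationOffsets,
    CellScore,
    ExpertScore,
    IncompleteTriple,
    ScoreSet,
    apply_calibration,
    build_score_sets,
    compute_group_offsets,
    consolidate_scores,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineResult:
    doses: list[Dose]
    score_sets: list[ScoreSet]
    cell_scores: list[CellScore]
    offsets: CalibrationOffsets
    incomplete: list[IncompleteTriple]

    @property
    def flagged_cells(self) -> list[CellScore]:
        return [c for c in self.cell_scores if c.flagged]


def scores_to_doses(
    scores: Sequence[ExpertScore],
    programme: Programme,
    assignment: StrategyAssignment,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    range_threshold: float = DEFAULT_RANGE_THRESHOLD,
    calibrate: bool = True,
) -> PipelineResult:
    """Run the full scoring-to-dose pipeline.

    Consolidates every cell (flagging and round-2 handling included),
    estimates group offsets from the fictitious IRG when ``calibrate`` is
    true and at least two groups scored it, applies the calibration, then
    assembles score sets and computes doses.  Without fictitious scores (or
    with a single group) offsets are zero and a note is logged.
    """
    cell_scores = consolidate_scores(scores, sd_threshold, range_threshold)
    group_ids = sorted({c.group_id for c in cell_scores})
    fictitious_raw = [s for s in scores if s.is_fictitious]
    if calibrate and fictitious_raw and len({s.group_id for s in fictitious_raw}) >= 2:
        offsets = compute_group_offsets(fictitious_raw, group_ids=group_ids)
    else:
        if calibrate:
            logger.info("no usable fictitious-IRG scores; calibration offsets set to 0")
        offsets = CalibrationOffsets.zero(group_ids)
    calibrated = apply_calibration(cell_scores, offsets, mas=programme.mas)
    score_sets, incomplete = build_score_sets(calibrated, assignment, mas=programme.mas)
    doses = compute_all_doses(score_sets)
    return PipelineResult(
        doses=doses,
        score_sets=score_sets,
        cell_scores=cell_scores,
        offsets=offsets,
        incomplete=incomplete,
    )
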