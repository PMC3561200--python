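"""Expert-panel scoring: distribution, consensus summaries and calibration.

The scoring protocol follows the nominal group technique.  Each IRG's
indicator report sheet is scored independently by the experts of one group
on a 0..mas scale, one score per (period × domain × declension) cell.  For
each cell the mean, sample standard deviation and range are computed; when
the SD exceeds 2.5 or the range exceeds 6 (strictly), the experts debate
and score a second round.  The round-2 mean then replaces the round-1 mean;
mean scores are preserved even without consensus.

When several expert groups are used, a *fictitious IRG* scored by every
group estimates between-group scoring offsets; each group's offset (its
fictitious mean minus the across-group grand mean) is subtracted from its
scores, clamping to [0, mas].
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    ConfigError,
    ConsistencyError,
    IncompleteCalibrationError,
    InconsistentCellError,
    InsufficientRatersError,
    MissingOffsetError,
    ProtocolViolationError,
    ScoreRangeError,
)
from .programme import (
    ACTIVITY_CLASSES,
    DECLENSIONS,
    DELIVERY,
    DOMAINS,
    IRG,
    PARTICIPATION,
    PDA,
    QUALITY,
    QUANTITY,
    StrategyAssignment,
)

logger = logging.getLogger(__name__)

#: Reserved setting id marking the fictitious (calibration) IRG.
FICTITIOUS_SETTING = "__FICTITIOUS__"

DEFAULT_SD_THRESHOLD = 2.5
DEFAULT_RANGE_THRESHOLD = 6.0

#: Cell key: (setting, intervention, activity_class, period, domain, declension)
CellKey = tuple[str, str, str, str, str, str]


@dataclass(frozen=True)
class ExpertScore:
    """One rater's mark on one score cell.

    ``group_id`` carries the expert-group identity used for calibration;
    the fictitious IRG is encoded by ``setting == FICTITIOUS_SETTING``.
    """

    expert_id: str
    group_id: str
    setting: str
    intervention: str
    activity_class: str
    period: str
    domain: str
    declension: str
    round: int
    value: float

    def __post_init__(self) -> None:
        if self.activity_class not in ACTIVITY_CLASSES:
            raise ConfigError(f"bad activity class {self.activity_class!r}")
        if self.domain not in DOMAINS:
            raise ConfigError(f"bad domain {self.domain!r}")
        if self.declension not in DECLENSIONS:
            raise ConfigError(f"bad declension {self.declension!r}")
        if self.round not in (1, 2):
            raise ConfigError(f"round must be 1 or 2, got {self.round}")

    @property
    def cell(self) -> CellKey:
        return (
            self.setting,
            self.intervention,
            self.activity_class,
            self.period,
            self.domain,
            self.declension,
        )

    @property
    def is_fictitious(self) -> bool:
        return self.setting == FICTITIOUS_SETTING


@dataclass(frozen=True)
class ScoreSummary:
    """Consensus statistics for one cell and round."""

    cell: CellKey
    round: int
    n_experts: int
    mean: float
    sd: float
    range: float
    flagged: bool = False


@dataclass(frozen=True)
class CalibrationOffsets:
    """Per-group additive offsets; they sum to zero across groups."""

    offsets: Mapping[str, float]
    grand_mean: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "offsets", dict(self.offsets))

    def __getitem__(self, group_id: str) -> float:
        try:
            return self.offsets[group_id]
        except KeyError:
            raise MissingOffsetError(f"no calibration offset for group {group_id!r}") from None

    @classmethod
    def zero(cls, group_ids: Iterable[str]) -> "CalibrationOffsets":
        return cls({g: 0.0 for g in group_ids}, grand_mean=math.nan)


@dataclass(frozen=True)
class CellScore:
    """A consolidated (and possibly calibrated) score for one cell."""

    setting: str
    intervention: str
    activity_class: str
    period: str
    domain: str
    declension: str
    group_id: str
    value: float
    flagged: bool = False

    @property
    def cell(self) -> CellKey:
        return (
            self.setting,
            self.intervention,
            self.activity_class,
            self.period,
            self.domain,
            self.declension,
        )

    @property
    def is_fictitious(self) -> bool:
        return self.setting == FICTITIOUS_SETTING


@dataclass(frozen=True)
class ScoreSet:
    """The four consolidated scores feeding one dose.

    DQt/DQl are delivery quantity/quality, PQt/PQl participation
    quantity/quality, all on the common 0..mas scale.
    """

    irg: IRG
    activity_class: str
    period: str
    dqt: float
    dql: float
    pqt: float
    pql: float
    mas: float = 20.0

    def __post_init__(self) -> None:
        for name, v in self.scores.items():
            if not 0.0 <= v <= self.mas:
                raise ScoreRangeError(
                    f"{name}={v} outside [0, {self.mas}] for IRG "
                    f"({self.irg.setting}, {self.irg.intervention})"
                )

    @property
    def scores(self) -> dict[str, float]:
        return {"DQt": self.dqt, "DQl": self.dql, "PQt": self.pqt, "PQl": self.pql}


@dataclass(frozen=True)
class IncompleteTriple:
    """A (irg, activity class, period) triple missing some of its four cells."""

    setting: str
    intervention: str
    activity_class: str
    period: str
    missing: tuple[tuple[str, str], ...]  # (domain, declension) pairs


# Operations ----------------------------------------------------------------


def distribute_irgs(
    irgs: Sequence[IRG], group_ids: Sequence[str], seed: int | None = None
) -> dict[str, list[IRG]]:
    """Partition IRGs fairly among expert groups (sizes differ by at most 1).

    The order is randomised (seeded, reproducible) and IRGs dealt
    round-robin to the groups.
    """
    if not group_ids:
        raise ConfigError("at least one expert group is required")
    if len(set(group_ids)) != len(group_ids):
        raise ConfigError("duplicate group ids")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(irgs))
    allocation: dict[str, list[IRG]] = {g: [] for g in group_ids}
    for pos, idx in enumerate(order):
        allocation[group_ids[pos % len(group_ids)]].append(irgs[idx])
    return allocation


def summarize_cell(
    scores: Sequence[ExpertScore],
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    range_threshold: float = DEFAULT_RANGE_THRESHOLD,
) -> ScoreSummary:
    """Mean, sample SD and range of one cell's scores from one round.

    All scores must address the same cell and round, with at least two
    raters.  The resulting summary carries the debate flag per
    :func:`flag_for_debate`.
    """
    if len(scores) < 2:
        raise InsufficientRatersError(
            f"need >= 2 expert scores to summarise a cell, got {len(scores)}"
        )
    cells = {s.cell for s in scores}
    rounds = {s.round for s in scores}
    if len(cells) > 1 or len(rounds) > 1:
        raise InconsistentCellError(
            f"scores mix {len(cells)} cell(s) and {len(rounds)} round(s)"
        )
    values = np.asarray([s.value for s in scores], dtype=float)
    summary = ScoreSummary(
        cell=scores[0].cell,
        round=scores[0].round,
        n_experts=len(scores),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        range=float(values.max() - values.min()),
    )
    return replace(summary, flagged=flag_for_debate(summary, sd_threshold, range_threshold))


def flag_for_debate(
    summary: ScoreSummary,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    range_threshold: float = DEFAULT_RANGE_THRESHOLD,
) -> bool:
    """True iff the cell's SD or range strictly exceeds its threshold."""
    if not (sd_threshold > 0 and range_threshold > 0):
        raise ConfigError("thresholds must be > 0")
    return summary.sd > sd_threshold or summary.range > range_threshold


def consolidate_cell(
    round1: Sequence[ExpertScore],
    round2: Sequence[ExpertScore] | None = None,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    range_threshold: float = DEFAULT_RANGE_THRESHOLD,
) -> float:
    """Final score for one cell: the round-2 mean when the cell was flagged
    and re-scored, else the round-1 mean.

    Mean scores are preserved even when round 2 remains discrepant.  Round-2
    scores for an unflagged cell violate the protocol.
    """
    summary1 = summarize_cell(round1, sd_threshold, range_threshold)
    if round2:
        if not summary1.flagged:
            raise ProtocolViolationError(
                f"round-2 scores supplied for unflagged cell {summary1.cell}"
            )
        summary2 = summarize_cell(round2, sd_threshold, range_threshold)
        if summary2.round != 2 or summary1.round != 1:
            raise InconsistentCellError("rounds mislabelled in consolidate_cell input")
        if summary2.cell != summary1.cell:
            raise InconsistentCellError("round-1 and round-2 scores address different cells")
        return summary2.mean
    return summary1.mean


def consolidate_scores(
    scores: Sequence[ExpertScore],
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    range_threshold: float = DEFAULT_RANGE_THRESHOLD,
) -> list[CellScore]:
    """Consolidate a full table of expert scores cell by cell.

    Scores are grouped by (cell, group); each group's rounds are consolidated
    with :func:`consolidate_cell`.  Flagged cells are logged.
    """
    by_cell: dict[tuple[CellKey, str], dict[int, list[ExpertScore]]] = {}
    for s in scores:
        by_cell.setdefault((s.cell, s.group_id), {1: [], 2: []})[s.round].append(s)
    out: list[CellScore] = []
    for (cell, group_id), rounds in sorted(by_cell.items()):
        if not rounds[1]:
            raise ProtocolViolationError(
                f"cell {cell} (group {group_id}) has round-2 scores but no round 1"
            )
        summary1 = summarize_cell(rounds[1], sd_threshold, range_threshold)
        if summary1.flagged:
            logger.info(
                "cell %s (group %s) flagged for debate: sd=%.2f range=%.1f",
                cell, group_id, summary1.sd, summary1.range,
            )
        value = consolidate_cell(rounds[1], rounds[2] or None, sd_threshold, range_threshold)
        setting, intervention, activity_class, period, domain, declension = cell
        out.append(
            CellScore(
                setting, intervention, activity_class, period, domain, declension,
                group_id=group_id, value=value, flagged=summary1.flagged,
            )
        )
    return out


def compute_group_offsets(
    fictitious_scores: Sequence[ExpertScore | CellScore],
    group_ids: Sequence[str] | None = None,
) -> CalibrationOffsets:
    """Estimate each group's scoring offset from the fictitious IRG.

    A group's offset is its mean over all fictitious cells minus the
    (unweighted) grand mean of the group means; offsets sum to zero.  At
    least two groups must have scored the fictitious IRG.
    """
    by_group: dict[str, list[float]] = {}
    for s in fictitious_scores:
        if not s.is_fictitious:
            raise InconsistentCellError(
                f"non-fictitious score (setting {s.setting!r}) passed to calibration"
            )
        by_group.setdefault(s.group_id, []).append(s.value)
    if group_ids is not None:
        missing = set(group_ids) - set(by_group)
        if missing:
            raise IncompleteCalibrationError(
                f"group(s) missing fictitious-IRG scores: {sorted(missing)}"
            )
    if len(by_group) < 2:
        raise IncompleteCalibrationError(
            f"calibration needs >= 2 groups scoring the fictitious IRG, got {len(by_group)}"
        )
    group_means = {g: float(np.mean(v)) for g, v in sorted(by_group.items())}
    grand = float(np.mean(list(group_means.values())))
    offsets = {g: m - grand for g, m in group_means.items()}
    for g, o in offsets.items():
        logger.info("calibration offset for group %s: %+.3f", g, o)
    return CalibrationOffsets(offsets, grand_mean=grand)


def apply_calibration(
    cell_scores: Sequence[CellScore],
    offsets: CalibrationOffsets,
    mas: float = 20.0,
) -> list[CellScore]:
    """Subtract each group's offset from its scores, clamping to [0, mas].

    Fictitious-IRG scores are dropped from the output: they exist only to
    estimate the offsets.
    """
    out: list[CellScore] = []
    for cs in cell_scores:
        if cs.is_fictitious:
            continue
        calibrated = min(max(cs.value - offsets[cs.group_id], 0.0), mas)
        out.append(replace(cs, value=calibrated))
    return out


_SCORE_NAMES: dict[tuple[str, str], str] = {
    (DELIVERY, QUANTITY): "dqt",
    (DELIVERY, QUALITY): "dql",
    (PARTICIPATION, QUANTITY): "pqt",
    (PARTICIPATION, QUALITY): "pql",
}


def build_score_sets(
    cell_scores: Sequence[CellScore],
    assignment: StrategyAssignment,
    mas: float = 20.0,
) -> tuple[list[ScoreSet], list[IncompleteTriple]]:
    """Assemble per-(IRG, activity class, period) score sets from cell scores.

    Each complete triple (all four domain × declension cells present) yields
    one :class:`ScoreSet`; incomplete triples are skipped and reported.
    """
    by_triple: dict[tuple[str, str, str, str], dict[tuple[str, str], float]] = {}
    for cs in cell_scores:
        if cs.is_fictitious:
            raise ConsistencyError("fictitious scores must be calibrated away before assembly")
        key = (cs.setting, cs.intervention, cs.activity_class, cs.period)
        slot = by_triple.setdefault(key, {})
        if (cs.domain, cs.declension) in slot:
            raise InconsistentCellError(
                f"duplicate cell ({cs.domain}, {cs.declension}) for triple {key}"
            )
        slot[(cs.domain, cs.declension)] = cs.value
    score_sets: list[ScoreSet] = []
    incomplete: list[IncompleteTriple] = []
    for key, cells in sorted(by_triple.items()):
        setting, intervention, activity_class, period = key
        missing = tuple(sorted(set(_SCORE_NAMES) - set(cells)))
        if missing:
            logger.warning("triple %s incomplete; missing cells %s", key, missing)
            incomplete.append(IncompleteTriple(setting, intervention, activity_class, period, missing))
            continue
        irg = IRG(setting, intervention, assignment.status[(setting, intervention)])
        kwargs = {_SCORE_NAMES[dd]: v for dd, v in cells.items()}
        score_sets.append(ScoreSet(irg, activity_class, period, mas=mas, **kwargs))
    return score_sets, incomplete
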