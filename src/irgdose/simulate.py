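"""Synthetic programmes, true scores, expert panels and target rosters.

The generator emulates the statistical structure the dose framework
assumes so that every stage is testable without study data:

* each scored cell of an IRG has a latent *true* score drawn from a normal
  distribution with a class-specific mean (clamped to the 0..mas scale);
* NPDA cells of active IRGs are shifted upwards (active settings also do
  more freelance activity relevant to their strategy);
* later periods decay (fatigue, staff turnover);
* settings active for both strategies of a designated pair receive an
  additive interaction shift (negative = antagonism) on those two
  strategies' active IRG cells; strategies outside the pair stay
  independent;
* each expert scores truth + a group-level offset + independent normal
  rater noise, clamped to [0, mas]; round-2 scores (for flagged cells)
  are re-drawn with half the rater SD, emulating the debate's convergence;
* a fictitious IRG, scored by every group, carries the group offsets and
  nothing else, enabling calibration.

The ``pralimap`` preset reproduces the source study's structure: 24
settings x 3 strategies with 12 active settings each (the published
allocation pattern), 2 periods, scores on 0..20, and 3 groups of 6
experts.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .programme import (
    DECLENSIONS,
    DOMAINS,
    NPDA,
    PDA,
    IRG,
    Programme,
    StrategyAssignment,
    enumerate_irgs,
)
from .scoring import (
    DEFAULT_RANGE_THRESHOLD,
    DEFAULT_SD_THRESHOLD,
    FICTITIOUS_SETTING,
    CellKey,
    ExpertScore,
    ScoreSet,
    distribute_irgs,
    summarize_cell,
)

#: Active settings per strategy in the source study's published allocation
#: (24 schools, strategies education / screening / environment).
_PRALIMAP_ACTIVE: dict[str, tuple[int, ...]] = {
    "education": (2, 3, 4, 5, 6, 7, 9, 11, 14, 17, 18, 23),
    "screening": (2, 3, 6, 7, 8, 9, 10, 12, 15, 17, 22, 24),
    "environment": (3, 4, 6, 9, 10, 14, 15, 16, 18, 19, 21, 22),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the source study's design (24 settings, 3 strategies
    with 12 active settings each, 2 periods, 0..20 scale, 3 groups of 6
    experts).  True-score means are set so that the implied mean doses
    (roughly mean^2 / mas) land mid-range of the study's printed dose
    tables; rater noise and group offsets straddle the reported 0.8-2.8
    point between-group adjustments.
    """

    n_settings: int = 24
    interventions: Mapping[str, int] = field(
        default_factory=lambda: {"education": 12, "screening": 12, "environment": 12}
    )
    n_periods: int = 2
    mas: float = 20.0
    n_groups: int = 3
    experts_per_group: int = 6
    rater_sd: float = 2.0
    group_offsets: tuple[float, ...] = (-2.0, 0.0, 2.0)
    npda_mean: float = 11.0
    pda_mean: float = 12.5
    score_sd: float = 2.0
    period2_decay: float = 1.0
    active_effect: float = 2.0
    interaction: float = -2.0
    interaction_pair: tuple[str, str] | None = None  # default: first two interventions
    sd_threshold: float = DEFAULT_SD_THRESHOLD
    range_threshold: float = DEFAULT_RANGE_THRESHOLD
    preset: str | None = "pralimap"
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "interventions", dict(self.interventions))
        object.__setattr__(self, "group_offsets", tuple(self.group_offsets))
        if self.n_settings < 1:
            raise ConfigError("n_settings must be >= 1")
        if self.n_periods < 1:
            raise ConfigError("n_periods must be >= 1")
        if not self.mas > 0:
            raise ConfigError("mas must be > 0")
        if self.experts_per_group < 2:
            raise ConfigError("experts_per_group must be >= 2")
        if self.rater_sd < 0 or self.score_sd < 0:
            raise ConfigError("rater_sd and score_sd must be >= 0")
        if len(self.group_offsets) != self.n_groups:
            raise ConfigError(
                f"group_offsets has length {len(self.group_offsets)}, expected n_groups={self.n_groups}"
            )
        if abs(sum(self.group_offsets)) > 1e-9:
            raise ConfigError(f"group_offsets must sum to 0, got {sum(self.group_offsets)}")
        for name, n_active in self.interventions.items():
            if not 0 <= n_active <= self.n_settings:
                raise ConfigError(
                    f"intervention {name!r} requests {n_active} active settings "
                    f"but the programme has {self.n_settings}"
                )
        if self.preset not in (None, "pralimap"):
            raise ConfigError(f"unknown preset {self.preset!r}")
        if self.interaction_pair is not None:
            object.__setattr__(self, "interaction_pair", tuple(self.interaction_pair))
            unknown = set(self.interaction_pair) - set(self.interventions)
            if len(self.interaction_pair) != 2 or unknown:
                raise ConfigError(
                    f"interaction_pair must name two known interventions, got {self.interaction_pair}"
                )

    def resolved_interaction_pair(self) -> tuple[str, str] | None:
        """The strategy pair the interaction shift applies to.

        Defaults to the first two interventions; None when the interaction
        is zero or fewer than two interventions exist.
        """
        if self.interaction == 0:
            return None
        if self.interaction_pair is not None:
            return self.interaction_pair
        if self.preset == "pralimap":
            return ("education", "environment")
        names = tuple(self.interventions)
        return names[:2] if len(names) >= 2 else None

    @property
    def group_ids(self) -> tuple[str, ...]:
        return tuple(f"G{k + 1}" for k in range(self.n_groups))


@dataclass(frozen=True)
class SyntheticTruth:
    """Generated true scores plus everything needed to recover them.

    ``combined_settings`` are the settings active for both strategies of
    the interaction pair — the ones whose pair IRGs carry the shift.
    """

    programme: Programme
    assignment: StrategyAssignment
    config: SimulationConfig
    scores: Mapping[CellKey, float]
    combined_settings: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", dict(self.scores))


def _spawn(seed: int | None) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_programme(
    config: SimulationConfig, seed: int | None = None
) -> tuple[Programme, StrategyAssignment]:
    """A programme and assignment matching the config.

    The ``pralimap`` preset returns the study's fixed allocation; otherwise
    the requested number of active settings per intervention is drawn
    uniformly without replacement (seeded, reproducible).
    """
    if config.preset == "pralimap":
        return pralimap_programme(
            n_periods=config.n_periods, mas=config.mas
        )
    settings = tuple(f"s{k + 1:02d}" for k in range(config.n_settings))
    periods = tuple(f"period{k + 1}" for k in range(config.n_periods))
    rng = _spawn(config.seed if seed is None else seed)
    active: dict[str, list[str]] = {}
    for name, n_active in config.interventions.items():
        chosen = rng.choice(config.n_settings, size=n_active, replace=False)
        active[name] = [settings[j] for j in sorted(chosen)]
    programme = Programme(settings, tuple(config.interventions), periods, mas=config.mas)
    assignment = StrategyAssignment.from_active_sets(settings, tuple(config.interventions), active)
    return programme, assignment


def pralimap_programme(
    n_periods: int = 2, mas: float = 20.0
) -> tuple[Programme, StrategyAssignment]:
    """The source study's configuration: 24 schools x 3 strategies, 12 active each."""
    settings = tuple(f"school{k:02d}" for k in range(1, 25))
    interventions = tuple(_PRALIMAP_ACTIVE)
    periods = tuple(f"year{k + 1}" for k in range(n_periods))
    active = {
        name: [f"school{k:02d}" for k in rows] for name, rows in _PRALIMAP_ACTIVE.items()
    }
    programme = Programme(settings, interventions, periods, mas=mas)
    assignment = StrategyAssignment.from_active_sets(settings, interventions, active)
    return programme, assignment


def _cell_mean(
    config: SimulationConfig,
    irg: IRG,
    activity_class: str,
    period_index: int,
    combined: bool,
) -> float:
    mean = config.pda_mean if activity_class == PDA else config.npda_mean
    if activity_class == NPDA and irg.is_active:
        mean += config.active_effect
    mean -= config.period2_decay * period_index
    if combined and irg.is_active:
        mean += config.interaction
    return mean


def generate_true_scores(
    programme: Programme,
    assignment: StrategyAssignment,
    config: SimulationConfig,
    seed: int | None = None,
) -> SyntheticTruth:
    """Draw the latent true score of every scored cell.

    Cells exist for every IRG's NPDA sheet and for active IRGs' PDA sheets,
    over all periods, domains and declensions.  Values are normal around
    the structured mean (class + active effect - decay + interaction),
    clamped to [0, mas].
    """
    rng = _spawn(config.seed if seed is None else seed)
    pair = config.resolved_interaction_pair()
    if pair is None:
        combined: frozenset[str] = frozenset()
    else:
        combined = frozenset(
            s
            for s in programme.settings
            if assignment.is_active(s, pair[0]) and assignment.is_active(s, pair[1])
        )
    scores: dict[CellKey, float] = {}
    for irg in enumerate_irgs(assignment):
        classes = (NPDA, PDA) if irg.is_active else (NPDA,)
        for activity_class in classes:
            for p_idx, period in enumerate(programme.periods):
                shifted = (
                    pair is not None
                    and irg.intervention in pair
                    and irg.setting in combined
                )
                mean = _cell_mean(config, irg, activity_class, p_idx, shifted)
                for domain in DOMAINS:
                    for declension in DECLENSIONS:
                        value = mean + rng.normal(0.0, config.score_sd) if config.score_sd else mean
                        scores[
                            (irg.setting, irg.intervention, activity_class, period, domain, declension)
                        ] = float(np.clip(value, 0.0, config.mas))
    return SyntheticTruth(programme, assignment, config, scores, combined)


def true_score_sets(truth: SyntheticTruth) -> list[ScoreSet]:
    """Score sets built directly from the truth (bypassing the expert layer)."""
    by_triple: dict[tuple[str, str, str, str], dict[tuple[str, str], float]] = {}
    for (setting, intervention, ac, period, domain, declension), v in truth.scores.items():
        by_triple.setdefault((setting, intervention, ac, period), {})[(domain, declension)] = v
    sets = []
    for (setting, intervention, ac, period), cells in sorted(by_triple.items()):
        irg = IRG(setting, intervention, truth.assignment.status[(setting, intervention)])
        sets.append(
            ScoreSet(
                irg, ac, period,
                dqt=cells[("delivery", "quantity")],
                dql=cells[("delivery", "quality")],
                pqt=cells[("participation", "quantity")],
                pql=cells[("participation", "quality")],
                mas=truth.config.mas,
            )
        )
    return sets


def _fictitious_cells(truth: SyntheticTruth) -> dict[CellKey, float]:
    # The fictitious IRG is an NPDA sheet at the plain class mean: it carries
    # group offsets and rater noise only, which is all calibration needs.
    cfg = truth.config
    return {
        (FICTITIOUS_SETTING, FICTITIOUS_SETTING, NPDA, period, domain, declension): cfg.npda_mean
        for period in truth.programme.periods
        for domain in DOMAINS
        for declension in DECLENSIONS
    }


def generate_expert_scores(
    truth: SyntheticTruth, seed: int | None = None
) -> list[ExpertScore]:
    """Round-1 (and, for flagged cells, round-2) scores for the whole panel.

    IRGs are distributed fairly among the groups; every group additionally
    scores the fictitious IRG.  Round-1 scores are truth + group offset +
    N(0, rater_sd); flagged cells get round-2 scores with rater SD halved.
    All scores are clamped to [0, mas].
    """
    cfg = truth.config
    rng = _spawn(cfg.seed if seed is None else seed)
    offsets = dict(zip(cfg.group_ids, cfg.group_offsets))

    irgs = enumerate_irgs(truth.assignment)
    allocation = distribute_irgs(irgs, list(cfg.group_ids), seed=int(rng.integers(2**31)))
    group_of: dict[tuple[str, str], list[str]] = {}
    for gid, items in allocation.items():
        for irg in items:
            group_of[(irg.setting, irg.intervention)] = [gid]

    cells: list[tuple[CellKey, float, list[str]]] = []
    for key, value in sorted(truth.scores.items()):
        cells.append((key, value, group_of[(key[0], key[1])]))
    for key, value in sorted(_fictitious_cells(truth).items()):
        cells.append((key, value, list(cfg.group_ids)))

    out: list[ExpertScore] = []
    for key, true_value, gids in cells:
        setting, intervention, ac, period, domain, declension = key
        for gid in gids:
            centre = true_value + offsets[gid]
            round1 = []
            for e in range(cfg.experts_per_group):
                noise = rng.normal(0.0, cfg.rater_sd) if cfg.rater_sd else 0.0
                round1.append(
                    ExpertScore(
                        expert_id=f"{gid}-E{e + 1}",
                        group_id=gid,
                        setting=setting,
                        intervention=intervention,
                        activity_class=ac,
                        period=period,
                        domain=domain,
                        declension=declension,
                        round=1,
                        value=float(np.clip(centre + noise, 0.0, cfg.mas)),
                    )
                )
            out.extend(round1)
            summary = summarize_cell(round1, cfg.sd_threshold, cfg.range_threshold)
            if summary.flagged:
                half_sd = cfg.rater_sd / 2.0
                for s in round1:
                    noise = rng.normal(0.0, half_sd) if half_sd else 0.0
                    out.append(
                        ExpertScore(
                            expert_id=s.expert_id,
                            group_id=gid,
                            setting=setting,
                            intervention=intervention,
                            activity_class=ac,
                            period=period,
                            domain=domain,
                            declension=declension,
                            round=2,
                            value=float(np.clip(centre + noise, 0.0, cfg.mas)),
                        )
                    )
    return out


def generate_roster(
    programme: Programme, targets_per_setting: int, seed: int | None = None
) -> dict[str, str]:
    """Unique target ids mapped to their setting, in a seeded random order."""
    if targets_per_setting < 0:
        raise ConfigError("targets_per_setting must be >= 0")
    rng = _spawn(seed)
    pairs = [
        (f"t{k:05d}", setting)
        for k, setting in enumerate(
            (s for s in programme.settings for _ in range(targets_per_setting)), start=1
        )
    ]
    rng.shuffle(pairs)
    return dict(pairs)


@dataclass(frozen=True)
class StudyBundle:
    """Everything one simulated study produces."""

    programme: Programme
    assignment: StrategyAssignment
    truth: SyntheticTruth
    expert_scores: list[ExpertScore]
    roster: dict[str, str]


def simulate_study(
    config: SimulationConfig,
    targets_per_setting: int = 0,
    seed: int | None = None,
) -> StudyBundle:
    """Generate a full study: programme, truth, expert panel and roster."""
    root = _spawn(config.seed if seed is None else seed)
    programme, assignment = generate_programme(config, seed=int(root.integers(2**31)))
    truth = generate_true_scores(programme, assignment, config, seed=int(root.integers(2**31)))
    scores = generate_expert_scores(truth, seed=int(root.integers(2**31)))
    roster = generate_roster(programme, targets_per_setting, seed=int(root.integers(2**31)))
    return StudyBundle(programme, assignment, truth, scores, roster)
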