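"""Intervention dose computation and assignment to target persons.

The four consolidated scores of an IRG are nested, not independent:
participation is subject to delivery, quality to quantity.  The delivery
quantity score is therefore weighted down by the mean of the other three,
normalised by the common maximal assignable score::

    dose = DQt * mean(DQl, PQt, PQl) / mas

The weighting factor lies in [0, 1], so 0 <= dose <= DQt <= mas.  Per
period, every IRG yields one non-programme-driven (NPDA) dose and every
active IRG additionally one programme-driven (PDA) dose.  Doses are
collective: every target person of a setting inherits, verbatim, every
dose of that setting's IRGs.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError, ConsistencyError, RosterError, ScoreRangeError
from .programme import PDA
from .scoring import ScoreSet


@dataclass(frozen=True)
class Dose:
    """One computed intervention dose, on the same 0..mas scale as scores."""

    setting: str
    intervention: str
    status: str
    activity_class: str
    period: str
    value: float


@dataclass(frozen=True)
class TargetDoseRecord:
    """All IRG doses inherited by one target person (keyed by
    (intervention, activity_class, period))."""

    target_id: str
    setting: str
    doses: Mapping[tuple[str, str, str], float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", dict(self.doses))


def dose_value(
    dqt: float,
    dql: float,
    pqt: float,
    pql: float,
    mas: float = 20.0,
    weights: Sequence[float] | None = None,
) -> float:
    """Scalar dose formula: ``DQt * mean(DQl, PQt, PQl) / mas``.

    ``weights`` is a configuration hook replacing the unweighted mean of
    (DQl, PQt, PQl) with a weighted one; weights are normalised to sum 1.
    """
    if not mas > 0:
        raise ConfigError(f"mas must be > 0, got {mas}")
    for name, v in (("DQt", dqt), ("DQl", dql), ("PQt", pqt), ("PQl", pql)):
        if not 0.0 <= v <= mas:
            raise ScoreRangeError(f"{name}={v} outside [0, {mas}]")
    if weights is None:
        weighting = (dql + pqt + pql) / 3.0
    else:
        if len(weights) != 3 or any(w < 0 for w in weights) or sum(weights) <= 0:
            raise ConfigError("weights must be 3 non-negative numbers with positive sum")
        total = sum(weights)
        weighting = (weights[0] * dql + weights[1] * pqt + weights[2] * pql) / total
    return dqt * weighting / mas


def compute_dose(score_set: ScoreSet, weights: Sequence[float] | None = None) -> Dose:
    """Apply the dose formula to one score set."""
    value = dose_value(
        score_set.dqt, score_set.dql, score_set.pqt, score_set.pql,
        mas=score_set.mas, weights=weights,
    )
    return Dose(
        setting=score_set.irg.setting,
        intervention=score_set.irg.intervention,
        status=score_set.irg.status,
        activity_class=score_set.activity_class,
        period=score_set.period,
        value=value,
    )


def compute_all_doses(
    score_sets: Sequence[ScoreSet], weights: Sequence[float] | None = None
) -> list[Dose]:
    """One dose per score set; PDA score sets must belong to active IRGs."""
    doses: list[Dose] = []
    for ss in score_sets:
        if ss.activity_class == PDA and not ss.irg.is_active:
            raise ConsistencyError(
                f"PDA score set for control IRG ({ss.irg.setting}, {ss.irg.intervention})"
            )
        doses.append(compute_dose(ss, weights=weights))
    return doses


def assign_doses_to_targets(
    doses: Sequence[Dose],
    roster: Mapping[str, str],
    settings: Sequence[str] | None = None,
) -> list[TargetDoseRecord]:
    """Assign every IRG dose to every target person of its setting.

    ``roster`` maps target id -> setting.  When ``settings`` (the
    programme's setting list) is given, roster settings are validated
    against it; otherwise against the settings present in ``doses``.
    """
    known = set(settings) if settings is not None else {d.setting for d in doses}
    by_setting: dict[str, dict[tuple[str, str, str], float]] = {}
    for d in doses:
        by_setting.setdefault(d.setting, {})[(d.intervention, d.activity_class, d.period)] = d.value
    records: list[TargetDoseRecord] = []
    for target_id, setting in roster.items():
        if setting not in known:
            raise RosterError(f"target {target_id!r} names unknown setting {setting!r}")
        records.append(TargetDoseRecord(target_id, setting, by_setting.get(setting, {})))
    return records


def doses_to_frame(doses: Sequence[Dose]) -> pd.DataFrame:
    """Tidy dose table: one row per dose, columns matching the dose CSV."""
    return pd.DataFrame(
        [
            {
                "setting": d.setting,
                "intervention": d.intervention,
                "status": d.status,
                "activity_class": d.activity_class,
                "period": d.period,
                "dose": d.value,
            }
            for d in doses
        ],
        columns=["setting", "intervention", "status", "activity_class", "period", "dose"],
    )
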