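"""Programme structure: settings, interventions, IRGs and the evaluation grid.

An *intervention-related group* (IRG) is one (setting, intervention) cell —
the basic unit in which an intervention is planned and in which its
implementation may vary.  A setting assigned an intervention forms an
*active* IRG (IRG-A); every other setting is a *control* IRG (IRG-C) for
that intervention.  Process evaluation crosses two domains (delivery,
participation) with two declensions (quantity, quality) for four actor
roles, giving a 16-cell evaluation grid of which 12 cells are eligible:
targets do not deliver interventions, and supervisors do not take part in
the field.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from typing import NamedTuple

from .errors import ConfigError, IncompleteAssignmentError

# Controlled vocabularies ---------------------------------------------------

ACTIVE = "active"
CONTROL = "control"
STATUSES = (ACTIVE, CONTROL)

PDA = "PDA"  # programme-driven activities
NPDA = "NPDA"  # non-programme-driven activities
ACTIVITY_CLASSES = (NPDA, PDA)

DELIVERY = "delivery"
PARTICIPATION = "participation"
DOMAINS = (DELIVERY, PARTICIPATION)

QUANTITY = "quantity"
QUALITY = "quality"
DECLENSIONS = (QUANTITY, QUALITY)

ROLES = ("supervisor", "anchor_receiver", "anchor_provider", "target")

DEFAULT_MAS = 20.0

#: (role, domain) pairs excluded from the evaluation grid: targets do not
#: perform interventions and supervisors do not work in the field.
DEFAULT_INELIGIBLE = frozenset(
    {("target", DELIVERY), ("supervisor", PARTICIPATION)}
)


# Domain types --------------------------------------------------------------


@dataclass(frozen=True)
class Programme:
    """A programme: its settings, interventions, periods and score scale.

    Parameters
    ----------
    settings
        Unique setting identifiers (schools, hospitals, districts ...).
    interventions
        Unique intervention/strategy identifiers.
    periods
        Ordered, non-empty list of intervention-period identifiers.
    mas
        Common maximal assignable score — the top of the 0..mas scale every
        expert scores on and the normalising denominator of the dose formula.
    """

    settings: tuple[str, ...]
    interventions: tuple[str, ...]
    periods: tuple[str, ...]
    mas: float = DEFAULT_MAS

    def __post_init__(self) -> None:
        object.__setattr__(self, "settings", tuple(self.settings))
        object.__setattr__(self, "interventions", tuple(self.interventions))
        object.__setattr__(self, "periods", tuple(self.periods))
        for name, ids in (("settings", self.settings), ("interventions", self.interventions)):
            dupes = _duplicates(ids)
            if dupes:
                raise ConfigError(f"duplicate {name[:-1]} identifier(s): {sorted(dupes)}")
        if not self.periods:
            raise ConfigError("periods must be non-empty")
        if _duplicates(self.periods):
            raise ConfigError(f"duplicate period identifier(s): {sorted(_duplicates(self.periods))}")
        if not self.mas > 0:
            raise ConfigError(f"mas must be > 0, got {self.mas}")

    @property
    def n_periods(self) -> int:
        return len(self.periods)


def _duplicates(ids: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dupes: set[str] = set()
    for i in ids:
        (dupes if i in seen else seen).add(i)
    return dupes


@dataclass(frozen=True)
class StrategyAssignment:
    """Complete active/control map over settings × interventions.

    ``status[(setting, intervention)]`` is ``"active"`` when the setting is
    assigned the intervention, else ``"control"``.  Every pair must be
    present exactly once.
    """

    settings: tuple[str, ...]
    interventions: tuple[str, ...]
    status: Mapping[tuple[str, str], str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "settings", tuple(self.settings))
        object.__setattr__(self, "interventions", tuple(self.interventions))
        object.__setattr__(self, "status", dict(self.status))
        expected = {(s, i) for s in self.settings for i in self.interventions}
        missing = expected - set(self.status)
        if missing:
            raise IncompleteAssignmentError(
                f"assignment missing {len(missing)} (setting, intervention) pair(s), "
                f"e.g. {sorted(missing)[0]}"
            )
        extra = set(self.status) - expected
        if extra:
            raise ConfigError(f"assignment has unknown pair(s), e.g. {sorted(extra)[0]}")
        for pair, st in self.status.items():
            if st not in STATUSES:
                raise ConfigError(
                    f"bad status token {st!r} for pair {pair}; expected one of {STATUSES}"
                )

    @classmethod
    def from_active_sets(
        cls,
        settings: Sequence[str],
        interventions: Sequence[str],
        active: Mapping[str, Iterable[str]],
    ) -> "StrategyAssignment":
        """Build an assignment from per-intervention sets of active settings."""
        unknown = set(active) - set(interventions)
        if unknown:
            raise ConfigError(f"active map names unknown intervention(s): {sorted(unknown)}")
        status: dict[tuple[str, str], str] = {}
        for i in interventions:
            act = set(active.get(i, ()))
            bad = act - set(settings)
            if bad:
                raise ConfigError(
                    f"active settings for {i!r} include unknown setting(s): {sorted(bad)}"
                )
            for s in settings:
                status[(s, i)] = ACTIVE if s in act else CONTROL
        return cls(tuple(settings), tuple(interventions), status)

    def is_active(self, setting: str, intervention: str) -> bool:
        try:
            return self.status[(setting, intervention)] == ACTIVE
        except KeyError:
            raise IncompleteAssignmentError(
                f"no assignment for pair ({setting!r}, {intervention!r})"
            ) from None

    def active_settings(self, intervention: str) -> tuple[str, ...]:
        return tuple(s for s in self.settings if self.is_active(s, intervention))

    def active_interventions(self, setting: str) -> tuple[str, ...]:
        return tuple(i for i in self.interventions if self.is_active(setting, i))


@dataclass(frozen=True)
class IRG:
    """One (setting, intervention) cell with its active/control status."""

    setting: str
    intervention: str
    status: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ConfigError(f"bad IRG status {self.status!r}; expected one of {STATUSES}")

    @property
    def is_active(self) -> bool:
        return self.status == ACTIVE


@dataclass(frozen=True)
class EvaluationObject:
    """One (actor role × domain × declension) cell of the evaluation grid."""

    actor_role: str
    domain: str
    declension: str
    eligible: bool


@dataclass(frozen=True)
class SheetTemplate:
    """Plan for one indicator report sheet: an IRG × activity class, all periods.

    Every IRG gets one sheet of non-programme-driven activity (NPDA)
    indicators; active IRGs additionally get a programme-driven (PDA) sheet.
    """

    irg: IRG
    activity_class: str
    periods: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "periods", tuple(self.periods))
        if self.activity_class not in ACTIVITY_CLASSES:
            raise ConfigError(
                f"bad activity class {self.activity_class!r}; expected one of {ACTIVITY_CLASSES}"
            )
        if self.activity_class == PDA and not self.irg.is_active:
            raise ConfigError(
                f"PDA sheet planned for control IRG ({self.irg.setting}, {self.irg.intervention})"
            )


class DoseCount(NamedTuple):
    total: int
    per_period: int


# Operations ----------------------------------------------------------------


def enumerate_irgs(assignment: StrategyAssignment) -> list[IRG]:
    """List every IRG of the programme, statuses copied from the assignment.

    Returns one IRG per (setting, intervention) pair, in setting-major order;
    the count is ``|settings| × |interventions|``.
    """
    return [
        IRG(s, i, assignment.status[(s, i)])
        for s in assignment.settings
        for i in assignment.interventions
    ]


def evaluation_grid(
    ineligible: Iterable[tuple[str, str]] = DEFAULT_INELIGIBLE,
) -> list[EvaluationObject]:
    """The 16-cell evaluation grid (4 roles × 2 domains × 2 declensions).

    ``ineligible`` is a set of (role, domain) pairs whose two declension
    cells are excluded from process evaluation; the default realises
    "targets do not perform interventions and supervisors do not work in
    the field" and leaves 12 eligible cells.
    """
    mask = set(ineligible)
    bad = {p for p in mask if p[0] not in ROLES or p[1] not in DOMAINS}
    if bad:
        raise ConfigError(f"bad (role, domain) pair(s) in ineligibility mask: {sorted(bad)}")
    return [
        EvaluationObject(role, domain, declension, eligible=(role, domain) not in mask)
        for role in ROLES
        for domain in DOMAINS
        for declension in DECLENSIONS
    ]


def plan_report_sheets(
    irgs: Sequence[IRG], periods: Sequence[str] = ()
) -> list[SheetTemplate]:
    """One NPDA sheet per IRG plus one PDA sheet per active IRG."""
    sheets = [SheetTemplate(irg, NPDA, tuple(periods)) for irg in irgs]
    sheets += [SheetTemplate(irg, PDA, tuple(periods)) for irg in irgs if irg.is_active]
    return sheets


def sheet_counts_by_setting(sheets: Sequence[SheetTemplate]) -> dict[str, int]:
    """Number of planned sheets per setting (|interventions| + #active there)."""
    counts: dict[str, int] = {}
    for sheet in sheets:
        counts[sheet.irg.setting] = counts.get(sheet.irg.setting, 0) + 1
    return counts


def expected_dose_count(irgs: Sequence[IRG], n_periods: int) -> DoseCount:
    """Doses the design implies: per period, two per active IRG and one per control.

    Active IRGs yield an NPDA and a PDA dose each period; control IRGs only
    an NPDA dose.
    """
    if n_periods < 1:
        raise ConfigError(f"n_periods must be >= 1, got {n_periods}")
    n_active = sum(irg.is_active for irg in irgs)
    n_control = len(irgs) - n_active
    per_period = 2 * n_active + n_control
    return DoseCount(total=n_periods * per_period, per_period=per_period)
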