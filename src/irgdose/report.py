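"""Indicator report sheets rendered as deterministic markdown documents.

A report sheet collects, for one IRG and one activity class, the valued
indicators ordered by domain, then declension, then the actor pair
(object of evaluation / source of information), then period.  Quantitative
indicators are shown with their unit; qualitative indicators verbatim.
Missing sections are rendered as explicit gaps so reviewers can see what
was never collected.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

from .errors import ConfigError
from .programme import DECLENSIONS, DOMAINS, SheetTemplate


@dataclass(frozen=True)
class Indicator:
    """One valued indicator destined for a report sheet."""

    domain: str
    declension: str
    object_role: str
    source_role: str
    period: str
    label: str
    value: object
    unit: str | None = None
    kind: str = "quantitative"  # or "qualitative"

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ConfigError(f"bad domain {self.domain!r}")
        if self.declension not in DECLENSIONS:
            raise ConfigError(f"bad declension {self.declension!r}")
        if self.kind not in ("quantitative", "qualitative"):
            raise ConfigError(f"bad indicator kind {self.kind!r}")


def _render_indicator(ind: Indicator) -> str:
    if ind.kind == "quantitative":
        unit = f" {ind.unit}" if ind.unit else ""
        return f"- {ind.label}: {ind.value}{unit}"
    return f'- {ind.label}: "{ind.value}"'


def render_report_sheet(
    sheet: SheetTemplate,
    indicators: Sequence[Indicator] = (),
    scores: Mapping[tuple[str, str, str], float] | None = None,
) -> str:
    """Render one sheet to markdown; same input gives byte-identical output.

    ``scores`` optionally maps (period, domain, declension) to the
    consolidated score, shown under the matching declension heading.
    """
    irg = sheet.irg
    lines = [
        f"# Indicator report sheet — {irg.setting} / {irg.intervention}",
        "",
        f"Activity class: {sheet.activity_class}   Status: IRG-{'A' if irg.is_active else 'C'}",
        "",
    ]
    periods = list(sheet.periods) or sorted({i.period for i in indicators})
    for domain in DOMAINS:
        lines.append(f"## {domain.capitalize()}")
        for declension in DECLENSIONS:
            lines.append(f"### {declension.capitalize()}")
            selected = [
                i for i in indicators if i.domain == domain and i.declension == declension
            ]
            if scores:
                for period in periods:
                    key = (period, domain, declension)
                    if key in scores:
                        lines.append(f"Consolidated score ({period}): {scores[key]:.1f}")
            if not selected:
                lines.append("_no indicators recorded_")
                lines.append("")
                continue
            by_actor: dict[tuple[str, str], list[Indicator]] = {}
            for ind in selected:
                by_actor.setdefault((ind.object_role, ind.source_role), []).append(ind)
            for (obj, src) in sorted(by_actor):
                lines.append(f"#### Object: {obj} — source: {src}")
                group = by_actor[(obj, src)]
                ordered_periods = periods or sorted({i.period for i in group})
                for period in ordered_periods:
                    in_period = [i for i in group if i.period == period]
                    lines.append(f"Period {period}:")
                    if not in_period:
                        lines.append("- _gap: nothing recorded_")
                    else:
                        lines.extend(
                            _render_indicator(i) for i in sorted(in_period, key=lambda i: i.label)
                        )
            lines.append("")
    return "\n".join(lines).rstrip() + "\n"
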