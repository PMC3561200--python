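"""File interchange: programme configs, score / roster / dose tables.

Formats are deliberately plain: the programme definition is one JSON or
YAML document; scores, rosters, doses and summaries are comma-separated
UTF-8 CSV with a header row and "." as the decimal mark (locale decimals
are rejected, not guessed).  All write -> read round-trips are lossless.
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from pathlib import Path

import pandas as pd
import yaml

from .dose import Dose, TargetDoseRecord
from .errors import ConfigError, ScoreRangeError
from .programme import Programme, SheetTemplate, StrategyAssignment
from .scoring import ExpertScore

SCORE_COLUMNS = [
    "expert_id", "group_id", "setting", "intervention", "activity_class",
    "period", "domain", "declension", "round", "value",
]
DOSE_COLUMNS = ["setting", "intervention", "status", "activity_class", "period", "dose"]


# Programme config ----------------------------------------------------------


def read_programme(path: str | Path) -> tuple[Programme, StrategyAssignment]:
    """Load a programme definition (JSON or YAML) and validate it.

    Expected document::

        settings: [school01, ...]
        interventions: [education, ...]
        periods: [year1, year2]
        mas: 20            # optional, default 20
        assignment:
          school01: {education: active, ...}
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{path}: expected a mapping at top level")
    for key in ("settings", "interventions", "periods", "assignment"):
        if key not in doc:
            raise ConfigError(f"{path}: missing required field {key!r}")
    programme = Programme(
        settings=tuple(str(s) for s in doc["settings"]),
        interventions=tuple(str(i) for i in doc["interventions"]),
        periods=tuple(str(p) for p in doc["periods"]),
        mas=float(doc.get("mas", 20.0)),
    )
    table = doc["assignment"]
    if not isinstance(table, Mapping):
        raise ConfigError(f"{path}: 'assignment' must map setting -> {{intervention: status}}")
    status: dict[tuple[str, str], str] = {}
    for setting, row in table.items():
        if not isinstance(row, Mapping):
            raise ConfigError(f"{path}: assignment for setting {setting!r} must be a mapping")
        for intervention, token in row.items():
            status[(str(setting), str(intervention))] = str(token)
    assignment = StrategyAssignment(programme.settings, programme.interventions, status)
    return programme, assignment


def write_programme(
    path: str | Path, programme: Programme, assignment: StrategyAssignment
) -> None:
    path = Path(path)
    doc = {
        "settings": list(programme.settings),
        "interventions": list(programme.interventions),
        "periods": list(programme.periods),
        "mas": programme.mas,
        "assignment": {
            s: {i: assignment.status[(s, i)] for i in programme.interventions}
            for s in programme.settings
        },
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


# Expert scores -------------------------------------------------------------


def read_scores(path: str | Path, mas: float = 20.0) -> list[ExpertScore]:
    """Read an expert-score CSV, validating values against [0, mas].

    Errors cite the offending data row (1-based, excluding the header).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing column(s) {missing}")
    out: list[ExpertScore] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            value = float(row.value)
            rnd = int(row.round)
        except ValueError as exc:
            raise ConfigError(f"{path}: row {row_no}: malformed number ({exc})") from None
        if not 0.0 <= value <= mas:
            raise ScoreRangeError(
                f"{path}: row {row_no}: value {value} outside [0, {mas}]"
            )
        try:
            out.append(
                ExpertScore(
                    expert_id=row.expert_id, group_id=row.group_id,
                    setting=row.setting, intervention=row.intervention,
                    activity_class=row.activity_class, period=row.period,
                    domain=row.domain, declension=row.declension,
                    round=rnd, value=value,
                )
            )
        except ConfigError as exc:
            raise ConfigError(f"{path}: row {row_no}: {exc}") from None
    return out


def write_scores(path: str | Path, scores: Sequence[ExpertScore]) -> None:
    pd.DataFrame(
        [
            {
                "expert_id": s.expert_id, "group_id": s.group_id,
                "setting": s.setting, "intervention": s.intervention,
                "activity_class": s.activity_class, "period": s.period,
                "domain": s.domain, "declension": s.declension,
                "round": s.round, "value": repr(s.value),
            }
            for s in scores
        ],
        columns=SCORE_COLUMNS,
    ).to_csv(path, index=False)


# Rosters and doses ---------------------------------------------------------


def read_roster(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, dtype=str)
    for col in ("target_id", "setting"):
        if col not in df.columns:
            raise ConfigError(f"{path}: missing column {col!r}")
    if df["target_id"].duplicated().any():
        dup = df.loc[df["target_id"].duplicated(), "target_id"].iloc[0]
        raise ConfigError(f"{path}: duplicate target id {dup!r}")
    return dict(zip(df["target_id"], df["setting"]))


def write_roster(path: str | Path, roster: Mapping[str, str]) -> None:
    pd.DataFrame(
        [{"target_id": t, "setting": s} for t, s in roster.items()],
        columns=["target_id", "setting"],
    ).to_csv(path, index=False)


def read_doses(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={c: str for c in DOSE_COLUMNS[:-1]})
    missing = [c for c in DOSE_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing column(s) {missing}")
    df["dose"] = df["dose"].astype(float)
    return df[DOSE_COLUMNS]


def write_doses(path: str | Path, dose_df: pd.DataFrame) -> None:
    dose_df[DOSE_COLUMNS].to_csv(path, index=False)


def write_sheet_plan(path: str | Path, sheets: Sequence[SheetTemplate]) -> None:
    pd.DataFrame(
        [
            {
                "setting": sh.irg.setting,
                "intervention": sh.irg.intervention,
                "status": sh.irg.status,
                "activity_class": sh.activity_class,
            }
            for sh in sheets
        ],
        columns=["setting", "intervention", "status", "activity_class"],
    ).to_csv(path, index=False)


def write_target_doses(path: str | Path, records: Sequence[TargetDoseRecord]) -> None:
    """Wide target-dose CSV: one column per (intervention, class, period)."""
    keys = sorted({k for r in records for k in r.doses})
    rows = []
    for r in sorted(records, key=lambda r: r.target_id):
        row: dict[str, object] = {"target_id": r.target_id, "setting": r.setting}
        for k in keys:
            row["|".join(k)] = r.doses.get(k, float("nan"))
        rows.append(row)
    cols = ["target_id", "setting", *("|".join(k) for k in keys)]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_truth(path: str | Path, truth_scores: Mapping, extra: Mapping | None = None) -> None:
    """Dump generated true scores (JSON) for test assertions."""
    doc = {
        "scores": {"|".join(key): value for key, value in sorted(truth_scores.items())},
        **(dict(extra) if extra else {}),
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n", encoding="utf-8")
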