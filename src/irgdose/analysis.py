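"""Dose description, active-vs-control contrasts and strategy interactions.

The unit of analysis is the setting (the cluster of the trial design).
Contrasts and interactions use permutation inference: with a dozen
settings per arm no distributional assumption is warranted, so assignment
labels are shuffled at the setting level and two-sided p-values are
estimated with the add-one rule (b + 1) / (n_perm + 1), which can never
return zero.

The interaction of two strategies is measured against the additive
expectation on the 2x2 factorial of their assignments::

    interaction = mean(both) - (mean(A only) + mean(B only) - mean(neither))

A negative value means sub-additivity (antagonism) when the strategies are
combined.  Its null distribution is obtained by shuffling one strategy's
labels within the strata of the other.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateDesignError, InsufficientGroupError
from .programme import ACTIVE, NPDA

MIN_PERMUTATIONS = 99

DESCRIBE_COLUMNS = ["n", "mean", "sd", "median", "q1", "q3", "min", "max"]


@dataclass(frozen=True)
class ContrastResult:
    """Active-vs-control contrast of one strategy's doses in one period."""

    strategy: str
    activity_class: str
    period: str
    n_active: int
    n_control: int
    mean_active: float
    mean_control: float
    difference: float
    p_value: float
    n_perm: int


@dataclass(frozen=True)
class InteractionResult:
    """Deviation from additivity of two strategies on one dose outcome.

    ``cell_means`` holds the mean outcome dose in the four assignment cells
    'neither', 'a_only', 'b_only', 'both' (cells partition the settings).
    """

    strategy_a: str
    strategy_b: str
    activity_class: str
    period: str
    cell_means: dict[str, float]
    cell_sizes: dict[str, int]
    interaction: float
    p_value: float
    n_perm: int


def describe_doses(
    dose_df: pd.DataFrame,
    group_keys: Sequence[str] = ("intervention", "activity_class", "period"),
) -> pd.DataFrame:
    """Distribution summary per group: N, mean, SD, median, quartiles, extremes.

    Quartiles use linear interpolation between order statistics (numpy's
    default).  The SD is the sample SD; a singleton group reports 0.0 (its
    N column flags the degenerate case).  Output order is invariant to the
    input row order.
    """
    if dose_df.empty:
        return pd.DataFrame(columns=[*group_keys, *DESCRIBE_COLUMNS])

    def _one(values: pd.Series) -> pd.Series:
        v = values.to_numpy(dtype=float)
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
        return pd.Series(
            {
                "n": len(v),
                "mean": v.mean(),
                "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                "median": med,
                "q1": q1,
                "q3": q3,
                "min": v.min(),
                "max": v.max(),
            }
        )

    out = (
        dose_df.groupby(list(group_keys), sort=True)["dose"]
        .apply(_one)
        .unstack()
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out[[*group_keys, *DESCRIBE_COLUMNS]]


def _one_value_per_setting(
    dose_df: pd.DataFrame, strategy: str, activity_class: str, period: str
) -> pd.DataFrame:
    sub = dose_df[
        (dose_df["intervention"] == strategy)
        & (dose_df["activity_class"] == activity_class)
        & (dose_df["period"] == period)
    ]
    if sub["setting"].duplicated().any():
        dup = sub.loc[sub["setting"].duplicated(), "setting"].iloc[0]
        raise ConfigError(
            f"multiple ({strategy}, {activity_class}, {period}) doses for setting {dup!r}"
        )
    return sub.sort_values("setting").reset_index(drop=True)


def compare_active_control(
    dose_df: pd.DataFrame,
    strategy: str,
    period: str,
    activity_class: str = NPDA,
    n_perm: int = 9999,
    seed: int | None = None,
) -> ContrastResult:
    """Two-sided permutation contrast of active vs control settings.

    Works on one dose per setting (NPDA doses by default, the only class
    defined on both arms); assignment labels are shuffled at the setting
    level.  Seeded runs are reproducible.
    """
    if n_perm < MIN_PERMUTATIONS:
        raise ConfigError(f"n_perm must be >= {MIN_PERMUTATIONS}, got {n_perm}")
    sub = _one_value_per_setting(dose_df, strategy, activity_class, period)
    values = sub["dose"].to_numpy(dtype=float)
    active = (sub["status"] == ACTIVE).to_numpy()
    n_a, n_c = int(active.sum()), int((~active).sum())
    if n_a == 0 or n_c == 0:
        raise InsufficientGroupError(
            f"contrast needs both arms non-empty, got {n_a} active / {n_c} control "
            f"for ({strategy}, {activity_class}, {period})"
        )
    mean_a = float(values[active].mean())
    mean_c = float(values[~active].mean())
    observed = mean_a - mean_c

    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(values, (n_perm, 1)), axis=1)
    diffs = perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1)
    b = int(np.count_nonzero(np.abs(diffs) >= abs(observed)))
    p = (b + 1) / (n_perm + 1)
    return ContrastResult(
        strategy=strategy,
        activity_class=activity_class,
        period=period,
        n_active=n_a,
        n_control=n_c,
        mean_active=mean_a,
        mean_control=mean_c,
        difference=observed,
        p_value=p,
        n_perm=n_perm,
    )


def _interaction_stat(
    values: np.ndarray, a: np.ndarray, b: np.ndarray
) -> tuple[float, dict[str, float], dict[str, int]]:
    cells = {
        "neither": ~a & ~b,
        "a_only": a & ~b,
        "b_only": ~a & b,
        "both": a & b,
    }
    sizes = {k: int(m.sum()) for k, m in cells.items()}
    empty = [k for k, n in sizes.items() if n == 0]
    if empty:
        raise DegenerateDesignError(f"empty factorial cell(s): {empty}")
    means = {k: float(values[m].mean()) for k, m in cells.items()}
    stat = means["both"] - (means["a_only"] + means["b_only"] - means["neither"])
    return stat, means, sizes


def interaction_analysis(
    dose_df: pd.DataFrame,
    strategy_a: str,
    strategy_b: str,
    period: str,
    activity_class: str = NPDA,
    n_perm: int = 9999,
    seed: int | None = None,
) -> InteractionResult:
    """Between-strategy interaction on strategy A's doses.

    The outcome is strategy A's dose (of ``activity_class``, in ``period``)
    per setting; the factors are the active/control assignments of A and B.
    The permutation null shuffles A's labels within B's strata, preserving
    B's marginal structure.
    """
    if n_perm < MIN_PERMUTATIONS:
        raise ConfigError(f"n_perm must be >= {MIN_PERMUTATIONS}, got {n_perm}")
    sub = _one_value_per_setting(dose_df, strategy_a, activity_class, period)
    values = sub["dose"].to_numpy(dtype=float)
    a = (sub["status"] == ACTIVE).to_numpy()

    status_b = (
        dose_df[dose_df["intervention"] == strategy_b]
        .drop_duplicates("setting")
        .set_index("setting")["status"]
    )
    missing = set(sub["setting"]) - set(status_b.index)
    if missing:
        raise ConfigError(
            f"no {strategy_b!r} assignment for setting(s) {sorted(missing)}"
        )
    b_mask = (status_b.reindex(sub["setting"]).to_numpy() == ACTIVE)

    observed, means, sizes = _interaction_stat(values, a, b_mask)

    rng = np.random.default_rng(seed)
    perm_vals = np.tile(values, (n_perm, 1))
    # Shuffling A's labels within a B stratum is equivalent to shuffling the
    # outcome values within that stratum while keeping both label vectors fixed.
    for stratum in (b_mask, ~b_mask):
        idx = np.flatnonzero(stratum)
        perm_vals[:, idx] = rng.permuted(perm_vals[:, idx], axis=1)
    cell_masks = [~a & ~b_mask, a & ~b_mask, ~a & b_mask, a & b_mask]
    m00, m10, m01, m11 = (perm_vals[:, m].mean(axis=1) for m in cell_masks)
    stats = m11 - (m10 + m01 - m00)
    count = int(np.count_nonzero(np.abs(stats) >= abs(observed)))
    p = (count + 1) / (n_perm + 1)
    return InteractionResult(
        strategy_a=strategy_a,
        strategy_b=strategy_b,
        activity_class=activity_class,
        period=period,
        cell_means=means,
        cell_sizes=sizes,
        interaction=observed,
        p_value=p,
        n_perm=n_perm,
    )


def compare_pda_npda(
    dose_df: pd.DataFrame,
    strategy: str,
    period: str,
    n_perm: int = 9999,
    seed: int | None = None,
) -> ContrastResult:
    """Secondary paired contrast: PDA vs NPDA dose within active settings.

    Uses a sign-flip permutation of the within-setting differences.
    """
    if n_perm < MIN_PERMUTATIONS:
        raise ConfigError(f"n_perm must be >= {MIN_PERMUTATIONS}, got {n_perm}")
    sub = dose_df[
        (dose_df["intervention"] == strategy)
        & (dose_df["period"] == period)
        & (dose_df["status"] == ACTIVE)
    ]
    wide = sub.pivot_table(index="setting", columns="activity_class", values="dose")
    if "PDA" not in wide.columns or "NPDA" not in wide.columns or wide.empty:
        raise InsufficientGroupError(
            f"need paired PDA and NPDA doses in active settings for ({strategy}, {period})"
        )
    wide = wide.dropna(subset=["PDA", "NPDA"])
    if wide.empty:
        raise InsufficientGroupError("no setting has both a PDA and an NPDA dose")
    diffs = (wide["PDA"] - wide["NPDA"]).to_numpy(dtype=float)
    observed = float(diffs.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, diffs.size))
    perm_means = (signs * diffs).mean(axis=1)
    b = int(np.count_nonzero(np.abs(perm_means) >= abs(observed)))
    return ContrastResult(
        strategy=strategy,
        activity_class="PDA-NPDA",
        period=period,
        n_active=int(len(diffs)),
        n_control=int(len(diffs)),
        mean_active=float(wide["PDA"].mean()),
        mean_control=float(wide["NPDA"].mean()),
        difference=observed,
        p_value=(b + 1) / (n_perm + 1),
        n_perm=n_perm,
    )
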