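# Methods

## The dose model

An intervention-related group (IRG) is one (setting, intervention) cell of
a programme; it is *active* when the setting is assigned the intervention
and *control* otherwise. Implementation is evaluated per IRG, activity
class (programme-driven, PDA, for active IRGs; non-programme-driven,
NPDA, for all IRGs) and intervention period, on two domains (delivery,
participation) in two declensions (quantity, quality). Crossing domains
and declensions with the four actor roles (supervisor, anchor as
receiver, anchor as provider, target) gives a 16-cell evaluation grid of
which 12 cells are eligible: targets do not deliver interventions and
supervisors do not take part in the field. The exact four excluded cells
are configurable data (`evaluation_grid(ineligible=...)`); the default
mask excludes target × delivery and supervisor × participation, which
realises both exclusion reasons and yields exactly 12 eligible cells.

Each scored sheet yields four consolidated scores `DQt, DQl, PQt, PQl`
on a common 0..`mas` scale, and

```
dose = DQt × mean(DQl, PQt, PQl) / mas.
```

The facets are nested (participation presupposes delivery, quality
presupposes quantity), so delivery quantity is discounted by the mean of
the other three. Properties relied on throughout: the weighting factor is
in [0, 1], hence `0 ≤ dose ≤ DQt ≤ mas`; the dose is nondecreasing in
every score; scaling all four scores and `mas` by `c > 0` scales the dose
by `c`. The unweighted mean of exactly three scores is the reference
definition; `dose_value(..., weights=)` exposes an alternative-weighting
hook but no alternative is endorsed (this weighting tends to compress
between-IRG variability — a known limitation, see below). Doses are
stored unrounded; tables round for display only.

Per period the design implies `2·|active| + |control|` doses (an NPDA
dose for every IRG, plus a PDA dose for every active IRG); report-sheet
planning implies one NPDA sheet per IRG plus one PDA sheet per active
IRG.

## Scoring protocol

Consensus follows the nominal group technique. Per cell (IRG × class ×
period × domain × declension) and expert group:

- **Summary.** Mean, *sample* SD (n−1 denominator; panels are small — six
  experts by default — so the conservative estimator is used) and range
  (max − min), requiring ≥ 2 raters.
- **Debate flag.** The cell is flagged iff `sd > 2.5` **or**
  `range > 6`, both strict ("higher than"); at exactly 2.5 / 6 no debate
  is triggered.
- **Consolidation.** The round-2 mean, when a flagged cell was re-scored,
  *replaces* the round-1 mean entirely (it is not averaged with it);
  without a round 2, the round-1 mean stands. Means are preserved even
  when round 2 remains discrepant. Round-2 scores for an unflagged cell
  are a protocol violation and raise.

**Calibration.** With several expert groups, a fictitious IRG scored by
every group estimates group effects. Each group's offset is its mean over
all fictitious cells minus the unweighted grand mean of the group means;
offsets sum to zero by construction. The grand mean is the anchor because
no external reference exists for the "true" level — this preserves the
overall score level while removing between-group differences. The offset
is applied uniformly across a group's cells (additive-per-group); the
alternative, per-cell offsets, is structurally possible by computing
offsets per cell subset but is not the default, as a handful of
fictitious cells cannot support cell-specific estimates. Calibrated
scores are clamped to [0, `mas`] after subtraction; fictitious scores are
dropped from all downstream output.

Score sets are assembled only from complete (IRG, class, period) triples
(all four domain × declension cells present); incomplete triples are
skipped and reported, never silently imputed.

## Analysis

The unit of analysis is the setting (the trial's cluster). Summaries
report N, mean, sample SD, median, quartiles (linear interpolation
between order statistics, numpy's default — the most common convention),
min and max per (strategy × activity class × period); a singleton group
reports SD 0 with its N column flagging the degenerate case.

Contrasts and interactions use permutation inference rather than t or
rank tests: with about a dozen settings per arm no distributional claim
is defensible, and permutation of assignment labels at the setting level
respects the clustered design. P-values use the add-one rule
`(b + 1)/(n_perm + 1)`, which is never zero and keeps the test valid
(slightly conservative). The active-vs-control contrast defaults to NPDA
doses, the only class defined on both arms; a paired PDA-vs-NPDA
contrast within active settings (sign-flip permutation) is available as
a secondary analysis.

The interaction of strategies A and B on A's dose is measured on the 2×2
factorial of their assignments:

```
interaction = mean(both) − (mean(A only) + mean(B only) − mean(neither))
```

Negative values mean sub-additivity (antagonism). The permutation null
shuffles A's labels within B's strata (equivalently, permutes outcomes
within each stratum), preserving B's marginal structure. All four cells
must be non-empty. On any exactly additive cell-mean configuration with
zero noise the statistic is identically 0.

## Synthetic generator

`irgdose.simulate` draws, per scored cell, a latent true score
`N(μ_cell, score_sd)` clamped to [0, `mas`], with

```
μ_cell = class mean (+ active_effect if NPDA of an active IRG)
         − period2_decay × (period index)
         (+ interaction if the IRG belongs to the interaction pair
            and its setting is active for both pair strategies)
```

Experts score `truth + group offset + N(0, rater_sd)`, clamped; flagged
cells receive round-2 scores re-drawn with `rater_sd / 2`, a simple
convergence model of the debate (the protocol reports that debates seek
consensus but prescribes no model). The fictitious IRG is an NPDA sheet
fixed at the NPDA class mean — it carries offsets and rater noise only,
which is all calibration needs.

Defaults (score units on the 0..20 scale) and their provenance:

| parameter | default | rationale |
|---|---|---|
| `n_settings`, `interventions`, `n_periods` | 24, 3×12 active, 2 | the preset study configuration |
| `mas` | 20 | the study's common maximal assignable score |
| `n_groups`, `experts_per_group` | 3, 6 | the study's panel structure |
| `npda_mean`, `pda_mean` | 11.0, 12.5 | the implied mean dose ≈ μ²/mas lands mid-range of the study's printed mean doses (5.2–9.0 NPDA, 6.3–8.2 PDA) |
| `score_sd` | 2.0 | printed between-IRG score SDs 1.5–2.6 |
| `period2_decay` | 1.0 | year-2 doses printed ~1–2.7 lower |
| `active_effect` | 2.0 | printed active-vs-control NPDA gaps ~1–5 dose units |
| `interaction` | −2.0 | the reported negative education × environment interaction; applies to a designated pair (default education × environment in the preset), other strategies stay independent |
| `rater_sd`, `group_offsets` | 2.0, (−2, 0, +2) | chosen to straddle the reported 0.8–2.8-point between-group adjustments |

**Nonlinearity note.** The dose is quadratic in the scores: when all four
cell means equal μ, the expected dose is μ²/`mas` (plus a σ²-term under
noise). A score-scale interaction γ applied to the "both" cell of a
factorial with no main effects therefore maps to a dose-scale interaction
of `γ(2μ + γ)/mas`; at μ = 11, γ = −2, `mas` = 20 this is −2.0. Parameter
recovery of the interaction is asserted on that dose scale. The
interaction-recovery study uses a 24-setting, two-strategy balanced
factorial with `active_effect = 0` (isolating the interaction, the
standard recovery design) and true-score SD 0.5.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: expert behaviour beyond additive offsets
plus i.i.d. normal noise (no halo effects, anchoring on the first sheet,
or cell-specific group biases); indicator-level raw data below the score
level; missingness mechanisms (incomplete triples must be injected
explicitly); correlation between the four facets within a sheet (true
scores are drawn independently per cell, whereas real delivery and
participation are correlated); and non-normal, boundary-inflated score
distributions beyond what clamping induces.

## Numerical choices

- Scores, offsets and doses are double precision; clamping uses
  `min(max(x, 0), mas)`.
- "Exact" end-to-end recovery (zero rater noise, zero offsets) is
  asserted at 1e-10 absolute on the dose scale: means of identical
  floating-point scores can differ from the score by an ulp-level
  rounding in the summation.
- Permutation tests are vectorised (an `n_perm × n` value matrix);
  two-sided p-values compare `|stat|` with `≥`, so the degenerate
  identical-arms case correctly yields p = 1.
- Seeds: every stochastic operation takes a seed; composite operations
  derive child seeds below 2³¹ from one root generator, so a single seed
  reproduces a whole study.
- Problem sizes in the statistical test suites — 200 replicates for
  offset recovery, 100 for interaction recovery, 500 × 999 permutations
  for the null type-I studies — give Monte-Carlo SEs comfortably below
  the asserted margins while keeping the suite quick.

## Known limitations

- The dose weighting compresses between-IRG variability; validating
  alternative weightings requires outcome ("in-treatment") data and is
  out of scope.
- Doses are collective: every target of a setting inherits its IRG doses
  verbatim; no individual-level exposure is modelled.
- The significance procedure used in the source study's dose contrasts is
  unreported; the permutation tests here are a principled replacement,
  not a replication, and the study's printed dose tables (derived from
  unpublished per-IRG expert scores) are not reproducible — only
  structural counts and the dose formula itself are checked against them.
- Covariate-adjusted (multivariate) dose analysis is deliberately not
  included; standard regression tooling applies directly to the tidy dose
  table.
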