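# Methods

## The tasks and what is measured

**Model reconstruction.** A trial presents a target model of `set_size ∈
{1, 2, 4}` colored squares (side 0.85°) inside a 13.47° × 13.47° frame;
hues come from 256 evenly spaced HSV hues at full saturation and value
(spacing 360/256 = 1.40625°). The observer reconstructs the array by
clicking positions and picking hues on a color wheel, and may re-view the
model freely; the log is an ordered sequence of `view` and `place` events
with strictly increasing timestamps, starting with the initial view and
ending when all items are placed.

Derived per trial:

- **utilization** = set_size / n_views. The *non-empty* variant divides by
  only those views followed by at least one placement; at set size 1 it is
  identically 1, which serves as an analytic self-check of the whole
  event-log path (the acceptance script recomputes it on a fresh cohort).
- **correspondence matching**: each placement is assigned the target item
  nearest by Euclidean center distance. When the per-placement nearest
  neighbors are all distinct, this equals the global minimum-total-distance
  one-to-one assignment (each term is individually minimal), which the tests
  verify against exhaustive search. Duplicate assignments (collisions) make
  error attribution ambiguous; the trial is excluded. Set-size-1 trials
  cannot collide. Exact distance ties are broken by the lowest target index
  and logged; they have probability zero under continuous noise.
- **position error**: Euclidean distance placed→target center, degrees.
- **color error**: minimal circular hue difference in radians, in [0, π].
  A non-circular option (`scoring.circular_color: false`) reproduces
  analyses that took raw absolute differences without the wrap.

**Change detection.** 150 trials, set sizes N ∈ {4, 8} (half change, half
no-change). Capacity is Cowan's K = N·(H − FA) per set size, averaged over
the two set sizes. RTs outside a subject's mean ± 3 SD are trimmed first
(single pass, pooled over set sizes; per-subject pooling is configurable).
Subjects with mean K below 0 are flagged for exclusion (below-chance
responding makes the estimate uninterpretable); threshold and switch are
config options.

## Exclusion rules

Order of operations: collisions are removed first; then, within a trimming
population, a trial is excluded when its trial-mean position error *or*
trial-mean color error exceeds the population mean + 3 SD of that measure.
The population defaults to subject × set size and is selectable
(`subject_x_ss`, `subject`, `pooled`) because published analyses do not
always state the convention; zero-variance populations trim nothing. The
exclusion report gives per-set-size removal percentages for collisions and
outliers separately, both pooled and averaged over per-subject percentages.
Every excluded trial carries exactly one reason (collision XOR outlier; RT
trimming applies only to change detection).

## Statistics

- **Split-half reliability**: per subject, means over odd- vs
  even-positioned trials (1-based position within the subject × set-size
  sequence after exclusions), Pearson-correlated across subjects and
  Spearman–Brown corrected, r_SB = 2r/(1+r). For K, the odd/even split is
  taken within each set-size × change cell so both halves retain all cells.
  A zero-variance half makes reliability undefined (reported missing). The
  `first_n` option (default 15) reports the shortened-task reliability.
- **Within-subject CIs**: Cousineau normalization (cell − subject mean +
  grand mean), Morey correction √(C/(C−1)), t-based 95% interval,
  complete cases only.
- **RM-ANOVA**: one-way repeated measures, df = (C−1, (C−1)(n−1)); F/p
  come from pingouin, effect sizes from the package's own sums-of-squares
  decomposition. η² is partial (SS_effect/(SS_effect+SS_error)) by default
  with a classical (SS_effect/SS_total) option, since reports often write
  η² without qualifier. df are always computed from the data actually
  analyzed. The degenerate all-equal matrix (0/0) is defined as F = 0,
  p = 1. Contrasts are paired t-tests with η² = t²/(t²+df); the default
  scheme compares the smallest set size against the within-subject mean of
  the larger two, then the larger two against each other; a fully pairwise
  scheme is available because "pooled" comparisons are describable both ways.
- **Correlations**: Pearson r between per-subject capacity, utilization and
  the two error measures at the largest set size (where between-subject
  variance in utilization is greatest), Bonferroni-adjusted over the six
  off-diagonal pairs; the matrix diagonal carries each measure's split-half
  reliability.

## The synthetic observers

The simulator exists for parameter recovery, not psychological realism. Per
agent: slot capacity `capacity_k`, items encoded per view `utilization_u`
(non-integer values via stochastic rounding), isotropic Gaussian placement
noise `sigma_pos_deg`, von Mises hue noise `kappa_color`, empty-review
probability `p_empty_review`, and a change-detection guess rate. In change
detection the probed item is in memory with probability min(capacity_k/N, 1);
correct if so, otherwise "change" with the guess rate — so E[K̂] =
capacity_k for capacity_k ≤ N, independent of the guess rate. RTs and
viewing durations are log-normal placeholders that exist to exercise the
trimming and viewing-time paths.

Cohort defaults emulate the standard study conditions: 30 subjects, 30
reconstruction trials at each set size in {1, 2, 4}, a 150-trial
change-detection block at N ∈ {4, 8}. Parameter defaults are chosen as
field-typical values: capacity ~ truncated N(2.8, 0.9) on [0.5, 6] (the
canonical "around three items"), utilization ~ truncated N(1.5, 0.7) on
[1, 4] (observers load roughly one to two items per view when free to
choose), sigma_pos ~ truncated N(0.5°, 0.15°), kappa_color ~ truncated
N(8, 3) (≈23° circular SD), p_empty_review = 0.05, guess rate 0.5.
Between-subject spread in the noise parameters is included because real
observers differ in precision — without it, error reliabilities are
meaningless. Sampling enforces capacity ≥ utilization by raising capacity
when needed.

Three labeled strategy variants formalize informal accounts of
under-utilization as generative options (they are not fitted or compared):
`item_selection` encodes only u items but at high precision;
`narrow_resource` encodes everything in one view with one high-precision
item and the rest low; `partial_report` encodes everything but reports only
the most precise u items per view. The baseline is `fixed_utilization`.

What the simulator does **not** emulate: exposure-duration effects (a brief
first view is a timing option only, with no behavioral consequence), swap /
mis-binding errors, fatigue or learning, guessing distributions in the
reconstruction response, or any strategic adaptation across trials. Passing
recovery tests therefore validates the *estimators*, not claims about human
mechanisms.

## Numerical and design choices

- Coordinates are degrees of visual angle, origin at frame center, y up;
  `geometry.ppd` converts pixel logs. The wheel's zero angle and direction
  are config parameters (defaults: 0° at +x, counterclockwise) since wheel
  orientation is display-specific.
- Square non-overlap is enforced with the Chebyshev metric
  (max(|dx|, |dy|) ≥ side + gap), the exact condition for axis-aligned
  squares; it implies the weaker Euclidean-center-distance criterion.
  Placement of items uses rejection sampling with an attempt budget;
  impossible geometries raise rather than loop.
- Matching uses final placement coordinates only; placement order is
  irrelevant to assignment.
- The change-detection stimulus set carries nine named RGB colors
  (`CHANGE_DETECTION_COLORS`): task descriptions commonly announce "eight
  highly distinguishable colors" yet enumerate nine; the enumerated list is
  kept verbatim and the discrepancy documented at the constant.
- `p_empty_review = 1` is rejected at simulation time (the trial would
  never terminate); stochastic rounding guarantees at least one placement
  per counted view for u ≥ 1.
- Problem sizes in the tests (500 seeds per set size for geometry
  invariants, 50 subjects × 150 trials for K recovery, 1,000 instances for
  the matching oracle, 30-subject cohorts for reliability behavior) were
  chosen so Monte-Carlo tolerances (±0.15 on K, r_SB > 0.9) sit at ≥ 2
  binomial standard errors from their thresholds while the suite stays
  desk-scale.

## Known limitations

- Reliability of error measures in synthetic cohorts is driven entirely by
  the spread of noise parameters; it cannot speak to trait stability in
  humans.
- The 3-SD trim is single-pass by contract; iterating it would remove more
  trials because the SD shrinks after each pass.
- Spearman–Brown correction is only monotone/bounded on r ∈ [0, 1];
  negative half-correlations (small samples, no true signal) can map below
  −1 and should be read as "unreliable", not as a correlation.
- Scoring real deposited logs requires a column mapping and choosing the
  trimming-population convention to match the original analysis scripts;
  both are config, not code changes.
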