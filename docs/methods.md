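# Methods

## Data model and cleaning

One row per time-loss injury, following the football consensus-statement
coding style: player identifier, injury date, season label (derivable from
the date given a season start month, default July, since professional
seasons span calendar years), body part, side, tissue nature, optional
specific diagnosis category, onset, severity in days lost, contact flag,
activity context and recurrence class. Ingest is row-validated; rows whose
date, enum or severity fields do not parse are rejected with a logged
reason, never silently dropped.

Cleaning applies five rules in a fixed order:

1. **Label normalization** — exact-match mapping from raw spellings to
   canonical labels, supplied as a config file. No fuzzy matching: a
   surveillance audit trail needs deterministic replacements. Unmapped
   labels warn (or abort in strict mode).
2. **Missing core fields** — records with an empty player id or body part
   are removed; those two fields are the minimum needed to place an injury
   in a player's history. A missing side is *not* grounds for removal.
3. **Contact exclusion** — injuries positively caused by contact are
   removed. Records with an *unknown* contact mechanism are retained by
   default: the exclusion targets injuries caused by contact, not injuries
   of unknown mechanism. A flag enables the strict reading. Exacerbations
   (recurrence before return to play) are retained as ordinary records by
   default, with an optional flag to drop them.
4. **Side merging** — laterality is folded into the body part
   (`Thigh|L`, `Thigh|R`), so the same part on different sides becomes a
   different anatomical token. Bilateral maps to its own token `B` rather
   than duplicating the record (no duplication rule is defensible without
   more information), unspecified to `U`. The pre-merge label is kept for
   audit.
5. **Single-injury player-seasons** — a player-season with one injury has
   no within-season predecessor and is removed. This rule runs *last* and
   is iterated to a fixed point, because the earlier exclusions can reduce
   a player-season to a single record; running it earlier would
   misattribute removals.

The removal report attributes every dropped record to exactly one rule
(before − after = Σ removals), and the whole pipeline is idempotent.

## Sequences and transitions

Within each (player, season) group, injuries are sorted by date; same-day
ties fall back to input row order (the source data define no order for
them; the choice is stable and is flagged with a warning). Seasons are
independent: no pair crosses a season or player boundary, because the
off-season plausibly breaks any causal link and pooling across it would
confound the estimates.

Under **chain semantics** (default) a sequence *I₁…I_k* contributes the
k−1 consecutive pairs — each initial injury's *first* subsequent injury —
so |transitions| = Σ(length − 1) and the transition count equals the
subsequent-injury count. This is the only reading under which a cohort's
subsequent-injury total can exceed its multi-injury player count several
times over. **Star semantics** (only the season's first injury emits its
one pair) is provided behind a flag for sensitivity analysis. The gap in
days between paired injuries is recorded but unused in estimation (the
model is first-order and time-homogeneous); it is available to the report
layer and to future sojourn-time extensions.

## Estimation

States are formed at one of two granularities: side-qualified body part ×
nature, or diagnosis category (records with category "Unsure"/"Others" are
excluded from the categorization-level analysis; the list is
configurable). Pairs are tallied into a count matrix and converted to
probabilities under an explicit denominator convention:

* **global** — count over the cohort-wide transition total; all cells sum
  to 1. This is the convention under which reported matrix cells and their
  confidence intervals are mutually consistent, and is the default.
* **row** — count over the from-state's outgoing total; each occupied row
  sums to 1. This is the conditional next-injury law — what "transition
  matrix" means in the Markov-chain sense — and the convention used in the
  kernel-recovery experiments.

Both are first-class because the two definitions genuinely coexist in
surveillance reporting; every estimate records which denominator and which
n produced it.

Confidence intervals default to the Wald interval `p ± z·√(p(1−p)/n)`,
clipped to [0, 1], z = 1.959964 at 95%. Wald is the convention whose
half-widths reproduce matrix-style reports exactly at the global
denominator; the Wilson score interval (statsmodels) is offered for small
counts, where Wald under-covers. One known caveat is documented rather
than matched: a worked interval of (0.098, 0.102) around p = 0.10 would
imply n ≈ 86,000, inconsistent with any cohort of this scale; the package
reproduces interval arithmetic only at the actual transition count. No
multiple-testing correction is applied across cells.

Scenario classification is anatomical: same part & same nature
(re-injury, scenario 1), same part & different nature (scenario 2), and
the all-inclusive "any" (scenario 3). Scenarios 1 and 2 are disjoint and
partition the same-body-part pairs; every pair belongs to "any".

The reporting threshold (default p ≥ 0.002, strictly-below removal)
affects presentation only — counts, totals and denominators always use
the unfiltered data.

## Synthetic cohort generator

The generator emulates the scale and shape of a private professional-
league cohort, so that every stage is testable without real data:

* **Scale** — 1,250 players × 8 seasons (July–May windows), mean 0.47
  injuries per player-season ⇒ ≈ 4,700 injuries.
* **Counts** — Negative Binomial with dispersion r = 0.6. Injury counts
  in team sports are strongly overdispersed (a minority of players carry
  most recurrences); a Poisson with the same mean would make the
  subsequent-injury share ≈ 20%, while the NB choice puts it near the
  ~1/3 observed in elite football cohorts. This follows from
  E[(N−1)⁺]/E[N] in closed form, so the parameter was fixed analytically,
  not fitted.
* **States** — 14 part-nature states whose marginal approximates the
  reported body-part distribution (thigh .324, knee .157, ankle .143,
  hip & groin .129, lower leg .097, remainder spread), each mapped to a
  diagnosis category label.
* **Kernel** — `K = 0.83·marginal + 0.12·I + 0.05·SamePart` by default
  (re-injury excess on the diagonal, a smaller same-part excess),
  row-stochastic by construction; any explicit row-stochastic kernel can
  be supplied. The first injury of a player-season is drawn from the
  marginal, each later one from the kernel row of its predecessor — the
  generating process matches the model being estimated, deliberately, so
  parameter recovery is a clean test. A misspecification mode
  (`second_order_weight` > 0 mixes in the grand-predecessor's kernel row)
  demonstrates estimator behaviour when the first-order assumption fails;
  it is beyond the emulated design.
* **Noise** — contact injuries (10%, plus 2% unknown mechanism), blanked
  core fields (2%), raw label variants (15%, case/suffix noise undone by
  the shipped exact-match normalization map), "Unsure"/"Others" categories
  (4%). Dates are uniform within the season window (no within-season
  seasonality is modelled); severity is geometric (mean ≈ 6.7 days) and
  decorative.

Determinism: a single `numpy.random.Generator` (PCG64) seeded from the
config; field draws occur in a fixed order, so a fixed seed reproduces the
cohort byte-for-byte across platforms.

What the generator does **not** emulate: exposure (match/training hours),
severity-dependent return-to-play gaps, workload, calendar congestion,
club-level reporting heterogeneity, or any real per-player injury-count
distribution (unpublished). Passing tests therefore demonstrate that the
pipeline recovers the truth *of this generating process* — correctness of
the machinery and calibration of the intervals — not that real injury data
are first-order Markov.

## Verification design

* **Independent oracle** — `reference_statistics` recomputes expected
  counts and both probability conventions from the latent states by plain
  loops (group → sort → pair → tally → divide), sharing no code with the
  estimator; pipeline output must match it exactly on 50 small cohorts.
* **Parameter recovery** — 200 replicate cohorts of 5,000 players ×
  8 seasons from the default kernel; for every cell with expected count
  ≥ 25, the row-denominator estimate must lie within 3 true standard
  errors ≥ 95% of the time, and empirical 95% Wald coverage must fall in
  [0.92, 0.97]. The experiment runs in ≈ 20 s because generation and
  estimation are fully vectorized.
* **Invariants** — probability normalization under both conventions,
  scenario partition, preprocessing idempotence and removal accounting,
  transition-count conservation, round-trip I/O identity, and a χ²
  goodness-of-fit check of the generator's marginal draws at n > 10,000.

Problem sizes in the default test run (cohorts of a few hundred players
for exactness checks, 5,000 × 8 for recovery) were chosen as the smallest
sizes at which the statistical assertions are stable.

## Known limitations

* First-order and time-homogeneous only: no sojourn times, no higher-order
  history, no across-season linkage, no Bayesian smoothing.
* Exact-match normalization: misspellings outside the map pass through
  (with a warning) rather than being fuzzily corrected.
* The Wald default is kept for reporting consistency even though Wilson is
  preferable for cells with counts below ~10; both are one parameter away.
* Same-day injury ordering is an artifact convention (input row order),
  not a property of the data.
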