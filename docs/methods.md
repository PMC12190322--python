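# Methods

This note documents the models, statistics, numerical choices and
limitations of `schema_mux`, in the order of the analysis chain.

## Task model and data model

A session is a sequence of go/no-go trials on eight odors.  Two orthogonal
reward rules can be in effect: the **non-match rule** (a 'go' is rewarded
iff the current odor differs from the previous completed trial's odor) and
the **cue-identity rule** (a 'go' is rewarded iff the odor is one of the
cue-rewarded odors 1–4).  Each trial's *configuration* (match / non-match)
is a pure function of the completed-trial odor sequence: the first completed
trial of a session is `undefined`, and aborted trials neither receive a
configuration nor advance the comparison — the rule compares with the last
odor that was actually sampled to completion.  `undefined`-configuration
trials are excluded from every rule-conditioned analysis, so both rules are
always scored on identical trial sets.

Times are session-relative seconds.  All alignment windows are half-open
`[start, end)`; a spike exactly at an event time falls in the first bin at
or after the event.  Sessions are stored as plain CSV (`trials.csv` with a
fixed 17-column header, `spikes.csv` in long `unit_id,spike_time` format);
floats are serialized with 17 significant digits and parsed with the
round-trip parser, so write→read is exact.

## Synthetic generator

The generator stands in for the recorded dataset; every analysis is
validated against its planted ground truth.

**Trial sequences.** At each step the previous odor repeats with probability
`p_repeat` (default 0.5), otherwise a uniformly random *different* odor is
drawn.  The 0.5 default balances match and non-match trials and populates
all 16 trial types, which the decoding analyses need; real sessions may
differ, and the rate is configurable.  Event timing mirrors the behavioral
apparatus: nose-poke after a drawn latency, a 500 ms delay before odor
onset, 0.5–0.8 s of sampling (above the 300 ms minimum hold), and a
4-second light-off inter-trial interval plus jitter.

**Agent.** Choices are drawn from a logistic policy mixing the two rule
evidences, go-probability = lapse/2 + (1−lapse)·σ(bias + w_nm·x_nm +
w_ci·x_ci) with x_nm = ±1 for non-match/match (0 when undefined) and
x_ci = ±1 for cue-rewarded/non-rewarded odors.  This is the simplest family
that reproduces the graded error biases of interest: a residual positive
w_nm under the cue-identity rule produces exactly the "errs more on
non-match trials" signature.  With learning enabled, weights follow a delta
rule toward the action rewarded under the rule in effect,
w ← w + lr·(target − p_go)·x.

**Population.** Each unit is Poisson with a log-normal baseline (default
8 Hz, σ=0.3) and multiplicative gains applied during the odor-sampling
period only: an 8-vector of odor gains (log-normal, σ=0.15 by default), and
scalar non-match, cue-reward and choice gains that multiply the rate when
the condition is "on" (non-match configuration, cue-rewarded odor, go
choice) and are 1 otherwise.  Gains combine multiplicatively, which keeps
rates nonnegative and makes planted standardized effects predictable (a
planted gain g on half the trials yields Δz with the sign of log g).
Planted selective subpopulations mix enhanced (gain g) and suppressed
(gain 1/g) units half-and-half.  Spikes are drawn as an inhomogeneous
Poisson process on the piecewise-constant rate, exactly (per-segment Poisson
counts with uniform placement), with no spike-history dependence, drift, or
correlated noise — so the generator validates the statistics, not the
biophysics.  Test conclusions transfer to real data only insofar as real
deviations (non-Poisson variance, correlated noise, instability) are
absent here; the permutation framework is distribution-free, but power
numbers are generator-specific.

**Scenarios.** `naive` (go-biased agent, odor tuning only), `nm_expert`
(saturating non-match agent; 25% of units non-match-selective at gain 2.2),
`switch` (cue-identity rule; cue-identity agent with residual non-match
weight; 25% cue-identity-selective units plus a non-match-selective
fraction whose gain fades across sessions but persists), `control_cueid`
(cue-identity only; non-match gains identically 1).  Defaults: 3 sessions ×
300 trials × 40 units.

## Behavior metrics

Accuracy under a rule is the fraction of eligible trials where the choice
matches the rule's prescription (go on rule-rewarded, no-go otherwise).
`trials_to_criterion` uses a *trailing* 30-trial window ending at trial t
(the standard online reading of "cross 80% correct across 30 trials") and
returns the smallest t ≥ 30 whose window accuracy reaches the threshold.
Go-probability tables flag empty (odor, configuration) cells as absent
(NaN), never 0.  The configuration error bias conditions on cue-nonrewarded
odors under the cue-identity rule, where any 'go' is an error, and compares
non-match against match configurations.

## Single-unit statistics

PSTHs are mean counts per 50 ms bin divided by the bin width, smoothed with
a 5-bin uniform moving average whose edge bins average only their available
support (a constant trace is a fixed point).  Z-scores normalize the mean
response-window rate (0.5 s ending at odor un-poke) per reward condition
against baseline activity (1.0 s ending at trial start): z_c = (r̄_c − b̄)/σ_b,
with b̄ and σ_b computed across **all** completed trials so both conditions
share one normalizer — this is what makes Δz = z_rew − z_nonrew exactly
antisymmetric under condition swap.  Baseline SDs below 10⁻⁹ Hz mark the
unit degenerate (z absent).

The responsiveness and selectivity tests are **ZETA-style
temporal-deviation permutation tests**: the statistic is a maximum absolute
deviation of a cumulative spike count, and the null is built by permutation
rather than by the asymptotic machinery of the original ZETA procedure —
permutation keeps the test exact at any trial count and matches the
trial-shuffling null the analyses are defined by.  Responsiveness: T = max
over bins of |pooled cumulative spike fraction − uniform-rate line|; null by
independent circular shifts of each trial's bin vector (preserves per-trial
counts, destroys trial-locked timing).  Selectivity: D = max over bins of
|F_rew − F_nonrew| where F_c is the condition's cumulative count normalized
by its trial count (so rate and timing differences both register); null by
permuting condition labels, with an exhaustive-enumeration mode for small
trial counts.  P-values use p = (1 + #{T_perm ≥ T_obs})/(1 + n_perm), so
the smallest attainable p is 1/(n_perm+1); n_perm defaults to 1000.  A unit
is *selective for a rule* when both its responsiveness p and that rule's
selectivity p are ≤ α (default 0.05); no multiple-testing correction is
applied across units, since the exported quantity is the population
proportion at fixed α.

Because the responsiveness statistic detects temporal structure within the
analyzed window, the default alignment window (−1.5 s to 0 relative to
un-poke) deliberately spans both pre-odor and odor-sampling epochs: a
sustained response appears as a step in the cumulative and is detected.

## Population geometry

Pseudo-ensembles align trials of the same type across sessions: per
session, `n_per_type` trials of each type populated everywhere are
subsampled (each session's subsample is drawn from a generator seeded with
the same ensemble seed, so identical sessions contribute identical blocks),
unit columns are concatenated, and each column is standardized over the
included trials.  Standardization happens after subsampling so the
mean-0/SD-1 invariant holds exactly on the ensemble that downstream code
sees.  Zero-variance units are dropped.

The default embedding is the **linear fallback**: projection onto the top
three principal directions with a deterministic sign convention — it is the
test and acceptance surface because it is exactly reproducible.  UMAP
(`neighbor-embedding`, seeded) is available for figures; all quantitative
claims are routed through the permutation framework, which absorbs the
choice of embedding.

Centroid distances are normalized Euclidean,
d(a,b) = √Σ_k (μ_a,k − μ_b,k)²/s²_k, with s²_k the *pooled* within-type
variance per embedding dimension (floor 10⁻¹²) — the simplest reading of
"accounts for variance within each trial type"; a per-pair variant would
weight each pair differently and break the single-matrix dendrogram input.
Ward linkage on that matrix gives the dendrogram (exported as newick).
Contrasts: `nm_config` averages, over odors, the distance between the
odor's match and non-match centroids; `ci_reward` averages centroid
distances over cross-group odor pairs with configurations collapsed.  The
permutation null shuffles trial labels (within sessions when session ids
are supplied) and recomputes the contrast.

## Decoding and templates

Trial types are decoded with a linear SVM (C = 1,
inverse-class-frequency weights, one-vs-one voting with ties broken toward
the lowest label index), leave-one-out cross-validated; features are
per-unit z-scored response-window rates.  Class weights are computed once
on the full sample and held fixed across folds: this keeps the exact
leave-one-out shortcut valid — a point with zero dual coefficient can be
removed without changing the optimum, so only support vectors need refits.
The binary per-rule decoders additionally run their hot loop through
scikit-learn's low-level libsvm binding (same optimization problem;
verified prediction-equivalent to the public API), because the permutation
null refits the whole leave-one-out loop per label shuffle.

Confusion matrices are 16×16 and row-stochastic, ordered odors 1–8 in match
configuration then 1–8 in non-match.  Template similarity scores the
off-diagonal cells +1 inside the template and −1 outside:
S = (mean in-template − mean out-of-template off-diagonal probability),
normalized by the maximum contrast a row-stochastic matrix can attain (all
off-diagonal mass inside the template), so S ∈ [−1, 1] with S = 0 for both
the identity and the uniform matrix — the unique linear scoring with that
property, which is what makes S evidence of block structure rather than of
overall accuracy.  The permutation null draws one random relabeling of the
16 types and applies it **jointly** to rows and columns: independent row
and column shuffles would destroy the row-column identity and make the
diagonal meaningless.  The diagonal ratio R divides the mean main-diagonal
probability by the mean probability on the ±8 side diagonals (same odor,
opposite configuration); R ≈ 1 when configuration is ignored and R > 1 when
configuration coding separates the partners (denominator floor 10⁻⁹,
reported as +∞ when the side diagonal is empty).

Choice residualization regresses each unit's response on {intercept, go
indicator} by OLS and keeps the residuals (zero-mean, orthogonal to the
choice indicator); with a single choice present, features are only
centered, with a warning.

## Brain–behavior coupling

Session-level couplings correlate (Pearson; rank correlation available as
an option matters only for the linear plots) decoder accuracy with
behavioral accuracy per rule.  The ignore-probability is computed on
*incongruent* trials — non-match configuration with a cue-nonrewarded odor,
where the two rules prescribe opposite actions; on such trials "labeled
rewarded by the non-match decoder" and "correctly labeled rewarded" are the
same event, which fixes the denominator as decoder-positive incongruent
trials.  P(ignore) = withheld / decoder-positive, with held-out predictions
only (the decoder result carries a provenance flag).  Couplings pool
sessions; per-rat analyses are a grouping of the same per-session rows.

## Pipeline and reproducibility

The orchestrator derives each stage's seed from the master seed by fixed
offsets (simulate +0, selectivity +10000, geometry +20000, decoding
+30000, coupling +40000) and records them in `manifest.json`; a run is
byte-identical for a fixed configuration.  Any stage failure aborts with
the stage name and session id.

## Validation studies and problem sizes

`schema_mux.validation` holds the studies that the acceptance suite asserts
and `scripts/acceptance.py` reports:

- **Calibration** — each permutation test's false-positive rate at α = 0.05
  under its planted null, at n_perm = 200 with per-test replicate counts
  (1000 for the vectorized unit tests, 800/600 for the geometry and
  template tests, 400 for the binary decoder, whose null refits a
  leave-one-out SVM per permutation).  Replicate counts are set so the
  binomial Monte-Carlo error of the estimate is small against the 7%
  acceptance bound.
- **Template recovery** — 10 seeds × one 250-trial, 40-unit session per
  scenario; the confusion matrix must align (p ≤ 0.01 at 1000 permutations)
  with exactly the planted rule's template, with both under mixed coding;
  the same confusions give the diagonal-ratio direction (mixed > cue-only).
- **Selectivity recovery** — two 300-trial, 40-unit sessions with 25%
  planted non-match-selective units (gain 2.2, half suppressed); recovered
  fraction within 5 percentage points, Δz signs matching planted gain signs
  for ≥ 95% of recovered planted units.
- **Behavioral closed forms** — exact equalities for saturated and
  always-go agents; `trials_to_criterion` against a naive sliding-window
  loop on 1000 random correctness sequences.
- **Geometry** — two-session pseudo-ensemble of planted non-match coding:
  contrast permutation p ≤ 0.01 and a first dendrogram split separating
  match from non-match types.
- **Brain–behavior** — with every unit configuration-coding (near-perfect
  decoder), P(ignore) must recover the agent's closed-form
  incongruent-withhold rate within the 95% binomial interval; across
  sessions with coupled gain and compliance, the fidelity-ignore
  correlation must come out positive in ≥ 9/10 seeds.
- **Oracle equivalence** — the exhaustive selectivity mode against direct
  enumeration, and the shortcut leave-one-out confusion against a plain
  per-trial refit loop.

These sizes keep the full validation run in a few minutes on one core.

## Known limitations

- The generator's Poisson independence means calibration and power results
  do not speak to correlated-noise or non-stationary recordings.
- The ZETA-style tests share the permutation null of the original analyses
  but do not reproduce the original algorithm's interpolation or
  asymptotic approximation; p-values are exchangeable-null exact, not
  numerically identical to the reference implementation's.
- The linear-fallback embedding is a faithful geometry-preserving stand-in
  for testing; UMAP outputs will differ point-wise, and only
  permutation-test conclusions should be compared across embeddings.
- Leave-one-out with full-sample class weights and full-sample feature
  scaling involves the held-out trial in those two global statistics; this
  follows common practice for small-trial neural decoding and is applied
  identically under the permutation null, so test levels are unaffected.
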