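# Methods

`pausemix` models the latencies between keystrokes during essay writing
as draws from a finite mixture of lognormal distributions, one mixture
per essay, and relates the fitted mixture parameters to human essay
scores. This note documents the model, the estimation choices, the
synthetic data the package validates itself on, and the limits of both.

## The model

A pause event is the latency y > 0 (milliseconds) between two
consecutive editor events, labeled with the linguistic context at which
it occurred (within a word, between words/sentences/paragraphs, around
deletions, before edit operations). One context — by default
`WithinWord`, the most frequent — is analyzed per run.

Within an essay, log-latencies x = log y are modeled as a K-component
Gaussian mixture

    g(x | θ) = Σ_{k=1..K} π_k · N(x; μ_k, σ_k),   Σ π_k = 1,

equivalently a lognormal mixture on the raw scale. The latent indicator
z ∈ {1..K} with P(z = k) = π_k attaches each pause to one component.
Components ordered by mean are interpreted against the multi-layer
cognitive account of writing: the smallest-mean component collects
fast, low-level processing (orthographic/motor fluency), larger-mean
components progressively slower, higher-level processing (planning,
revision). π_1, the share of pauses in the fast component, is the
headline per-essay feature.

The log-likelihood (and hence AIC/BIC) is computed on the log scale.
The Jacobian of the log transform contributes the same additive
constant to every K fit on the same data, so model comparison is
unaffected by working with N(x) rather than the raw lognormal density.

## Estimation

Parameters are estimated per essay by expectation–maximization:

- E-step: responsibilities r_ik ∝ π_k N(x_i; μ_k, σ_k), rows
  normalized; computed with a per-observation max shift (log-sum-exp),
  so extreme latencies cannot underflow.
- M-step: π_k = mean_i r_ik; μ_k = Σ r_ik x_i / Σ r_ik; σ_k² the
  r-weighted variance about μ_k.

Convergence is declared when the relative log-likelihood improvement
falls below `tol` (default 1e-8) before `max_iter` (default 1,000)
iterations. The mixture likelihood is unbounded (a component can
collapse onto a point), so σ_k is floored at 1e-3 log-ms and component
weights at 1/n; a run that terminates at either floor is reported
`converged = False` and excluded from model selection. Label switching
is resolved by sorting components by mean, ties kept in original order.

**Initialization and multistart.** The first initialization slices the
sorted data into K contiguous quantile blocks (deterministic);
subsequent initializations jitter the block boundaries with seeded
uniform noise. Multistart is run short-EM style: each of `n_restarts`
(default 10) initializations is advanced only `short_iter` (default 50)
iterations, and only the most promising basin is refined to full
tolerance. This retains the basin coverage of full multistart at a
fraction of the cost; `short_iter = 0` restores full multistart. The
data are sorted once at entry, making results exactly invariant to
input order. All arithmetic in the inner loop is compiled (numba) and
deterministic.

**Estimator behavior worth knowing.** At moderate component overlap the
mixture likelihood is multimodal, and with a few hundred observations
the *global* maximizer occasionally sits in an unequal-variance mode
away from the generating parameters, with a correspondingly large
π error. This is a property of the likelihood, not of the optimizer:
short-EM, full 10-restart multistart, and truth-initialized EM agree on
the optimum on such datasets, and an independent implementation
(R mclust) attains only equal or lower likelihoods on identical data.
Per-essay π̂ should therefore be treated as a noisy feature at realistic
essay lengths; corpus-level analyses (correlations over hundreds of
essays) average this noise out.

## Model selection

Fits for K = 2..5 are compared per essay by

    AIC = −2·loglik + 2p,    BIC = −2·loglik + p·ln N,

with p = 3K − 1 free parameters (K means, K SDs, K − 1 free weights)
and N the essay's pause count. Lower is better; the argmin is taken
over converged fits only, ties to the smaller K. Since the BIC penalty
exceeds AIC's whenever ln N > 2, AIC never chooses a smaller K than BIC
on the same fits. A corpus-level census reports how many essays
converged for K=2, K=2–3, K=2–4, K=2–5 (nested, non-increasing).

Information criteria reward extra components even when the added means
are nearly coincident and thus poorly estimated, so selection is
supplemented by a separation screen: all pairwise distances
|μ_i − μ_j| of the ordered means (3 quantities at K=3, 6 at K=4),
graded against cut-points on the log scale — ≥ 1 "well separated",
≥ 0.3 "reasonably separated", boundaries inclusive. Distances are
computed on the modeling scale because the cut-points are only
meaningful there. Two aggregations are emitted with labels: percent of
essays whose *every* pair clears the cut (strict reading, the default)
and percent of pairs clearing the cut, since "percentage of separated
cases" is ambiguous between the two.

## Cleaning

An essay is excluded iff it has fewer than 30 pause events AND zero
human scores — by default both strand scores zero ("both"); an
"either" switch exists for sensitivity analysis. "Fewer than 30" is
strict: 30 events is kept. The rationale: below ~30 observations an
8-parameter mixture has hopeless precision, and a zero score carries no
signal for the correlation stage. The characters-typed / pause-events
ratio (means across essays) diagnoses the removed set: engaged essays
sit near the characters-per-keystroke rate (~1.7), while low-effort
essays (a few characters, near-zero pause events) push the ratio an
order of magnitude higher. Zero-event essays are representable
throughout; the ratio raises an explicit degenerate-ratio error when
the mean pause count is zero.

## Association with scores

Each essay with a converged fit at the analysis K (default 3)
contributes μ_1..μ_K, σ_1..σ_K, π_1..π_K; essays without one are
dropped and counted. Each parameter is correlated with both strand
scores by Pearson r (scores treated as numeric; a rank-based option
exists), with a Fisher-z interval: z = atanh r, SE = 1/√(n−3), normal
quantile, back-transformed. A flag marks intervals excluding zero; no
multiplicity correction is applied, and the output metadata says so.
`score_band_dispersion` quantifies the funnel pattern — the spread
(IQR, SD) of a parameter within each score level — as a testable
statistic rather than a visual impression.

## Keystroke parsing

The eight context labels are assigned by a precedence state machine
over consecutive events plus minimal text state (a committed-text
suffix and the backspace-run flag):

1. `Edit` if the upcoming event is cut/paste/replace/cursor-move;
2. `SingleBackspace` for a BACKSPACE starting a deletion run;
3. `MultipleBackspace` for a BACKSPACE continuing one;
4. `BackSpace` for the first keypress after a run ends;
5. `BetweenParagraph` if the interval spans an ENTER;
6. `BetweenSentence` if the committed text ends `. ! ?` (+ spaces);
7. `BetweenWord` if the interval spans a SPACE;
8. `WithinWord` otherwise.

Zero-latency (same-timestamp) intervals are dropped as logging
artifacts; every positive interval receives exactly one label, so
per-context counts partition the intervals. Classification never
consults timestamps, which makes the generator/parser round trip exact:
the synthetic log generator runs this same state machine to decide each
planted latency's label, and emits delimiter presses (SPACE/ENTER) at
zero latency so that boundary pauses are carried by the interval
leading out of the delimiter. The BackSpace/Single/Multiple distinction
(run-position semantics) is a documented reading of overlapping label
glosses, isolated in one classifier so it can be swapped. After an edit
operation the text suffix is cleared (document position unknown), so
the next pause falls back to `WithinWord` unless a later rule fires.

## The synthetic corpus generator

No public corpus of scored, keystroke-logged essays exists at this
granularity, so the generator reproduces the statistical structure the
pipeline assumes; it defines the package's validation conditions.

- **Essay lengths.** Pause counts per engaged essay: negative binomial,
  mean 568, dispersion 2.5, floored at 31 — quartiles ≈ (303, 494, 753)
  and 99.9th percentile ≈ 2,334, matching the spread reported for real
  eighth-grade 45-minute essays. The floor at 31 keeps engaged essays
  clear of the cleaning rule by construction.
- **Latencies.** Default truth: K=3, μ = (4.6, 5.8, 7.0) log-ms
  (medians ≈ 0.1 s, 0.33 s, 1.1 s), σ = 0.45 each,
  π base = (0.55, 0.30, 0.15); adjacent means 1.2 apart (≥ the "well
  separated" cut-point).
- **Ability link.** Ability a ~ N(0,1);
  logit π_1 = logit(0.55) − 0.8·a, remaining weights scaled pro rata
  (π stays on the simplex for any slope). The slope 0.8 gives π_1 a
  realistic spread (roughly 0.25–0.85), comparable to the wide range of
  mixing proportions reported for real essays — and wide enough that
  the planted signal survives per-essay estimation noise. Strand
  scores: a noisy copy of ability, rescaled and rounded into 0..5 (the
  real rubric range is not public; the scale is configurable). The
  score-noise SD is calibrated by Monte-Carlo bisection so that
  corr(true π_1, score) hits `target_corr` (default −0.23); |corr| is
  monotone in the noise SD, so the root is bracketed.
- **Low effort.** Exactly ⌊0.09·n⌋ essays get < 30 events (clipped
  exponential), both scores 0, and a token character count — they
  satisfy the cleaning rule by construction, and their char/pause ratio
  is far above the engaged essays' ~1.69.
- **Funnel option.** `pi_noise_scale > 0` adds ability-dependent noise
  to logit π_1 (SD ∝ expit(−a)), making low-ability essays more
  dispersed — the generative analogue of the score-band funnel.
- **Reproducibility.** All randomness derives from one seed through
  per-essay `SeedSequence` spawns: corpora are element-wise
  reproducible and independent of generation order.

**What the generator does not emulate** — and hence what passing tests
do not establish about real data: real text content (only boundary
structure), within-session fatigue or drift, revision bursts,
context-dependent latency differences (all generated pauses carry the
analysis context), rater effects beyond independent per-strand noise,
and any dependence of essay length on ability. Conclusions about real
keystroke corpora require the real corpora.

## Numerical and design notes

- Natural logarithms everywhere (transform and BIC's ln N).
- `fit_em` demands at least K distinct log-latencies, else it raises a
  `NotEstimable` signal that the corpus census counts as non-converged;
  degenerate underflow raises rather than returning NaN.
- K=1 is fitted in closed form (sample mean / population-style SD).
- Ties in component means are ordered stably by original index.
- Separation percentages, census counts and selection tallies are
  computed over converged fits; inestimable and non-converged fits are
  counted, never silently dropped.
- Pipeline artifacts are plain JSON/JSONL/CSV; the manifest records the
  config hash and artifact SHA-256 checksums, and identical
  config + seed reproduce identical checksums.

**Known limitations.** Under the default truth, the three-component
structure is only ~5–12 log-likelihood units above the best
two-component approximation at realistic essay lengths, so BIC
frequently prefers K=2 below ~1,500 events and recovers K=3 in only
~85–90% of essays even at 2,000 events; per-essay π̂ carries mode-level
noise (see "Estimator behavior"). Gamma and exponential mixture
families are out of scope (hooks only); no standard errors are reported
for mixture parameters; Pearson intervals treat small ordinal scores as
numeric.

## Validation problem sizes

The test suite validates EM ascent on 1,000 random datasets (n=200),
global optimality against a brute-force grid on 20 tiny datasets
(n=30), parameter and model-order recovery on 100 essays of 2,000
events, planted-association recovery on 20 corpora of 900 essays, 200
parser round trips, and Fisher-z coverage on 1,000 replicates.
`scripts/acceptance.py` runs the full pipeline on a 600-essay corpus
plus a 100-essay recovery block; both finish in minutes on one CPU.
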