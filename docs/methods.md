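# Methods

## Scope and pipeline

`ued` turns a turn-structured dialogue transcript plus two word–emotion
lexicons into per-speaker emotion-dynamics profiles and cross-speaker
analyses.  The pipeline is: parse and merge turns → tokenize/lemmatize →
select main characters (≥ 50 turns by default) → filter each speaker's
words to those covered by the dimensional lexicon → 10-word trailing
rolling average of valence and arousal (the *location* series) → home
bases, variability, displacements, rates → pairwise discordance and
density-arc trends on normalized narrative time.

## Statistical conventions

* **Variance and SD** use the population denominator (divide by N)
  throughout, including inside the 1-D home-base band.  This keeps the
  variability metric, the band and the ellipse mutually consistent.
* **Critical values** for coverage c are two-sided: the Student-t quantile
  at 1 − (1 − c)/2 with N − 1 degrees of freedom for the band, and the
  χ²(2 df) quantile at c for the ellipse (ψ ≈ 2.2789 at c = 0.68).
  Monte-Carlo coverage checks in the test suite confirm this reading: the
  68% band covers the true mean of Gaussian samples in ≈ 68% of
  replicates, and the 68% ellipse contains ≈ 68% of iid bivariate-Gaussian
  points.
* **Home-base basis.**  Band, ellipse and variability are computed over
  the rolling-trajectory points by default (`stat_basis="trajectory"`):
  the home base is defined as the region where the windowed location
  usually lies, and displacements are detected on the same series.  A
  `raw` option computes them over unsmoothed word scores instead.
* **Mean valence/arousal** in profiles are plain means over
  lexicon-covered words (they equal the score-weighted emotion-word
  density), independent of `stat_basis`.

## Trajectory construction

Only full trailing windows are used: point *k* averages scored words
*k* … *k* + w − 1 and is anchored at the last word's movie-global
position.  Partial leading windows would have inflated variance and
produce spurious early displacements; the trailing anchor keeps the series
causal.  Consecutive trajectory points differ by exactly one
lexicon-covered word, so index differences are word counts.

Normalized narrative time maps global word position p to (p + 0.5)/T with
T the movie's total token count (all speakers, all tokens).  The
movie-global axis is the default so different characters' trajectories are
directly comparable, as the discordance analysis requires; a per-character
axis can be obtained by passing the narrative's own length as T.

## Geometry

A point is inside the ellipse when its quadratic form in principal-axis
coordinates is ≤ 1 (boundary counts as inside, with a 1e−9 tolerance on
the form).  Perimeter distance uses the **radial** convention by default —
the distance from the point to the boundary along the ray from the center,
|p − c|·(1 − q^(−1/2)) for form value q > 1.  It is a closed form, strictly
increasing in q along any ray (so peak selection within an excursion is
well ordered), and coincides with |p − c| − r for circles.  The exact
orthogonal nearest-point distance (Newton/bracketing solve on the standard
ellipse foot-point equation, tolerance 1e−9) is available via
`method="nearest"`; it never exceeds the radial distance.  Eigenvalues
below 1e−12 are treated as degenerate geometry and raise an error naming
the deficient axis.

## Displacement accounting

Each maximal run of consecutive outside points bounded by inside points on
both sides is one displacement.  Length counts the outside points
(lexicon-covered words strictly outside), matching the "words uttered
between leaving and returning" reading.  Rise words run from the last
inside point to the peak and recovery words from the peak to the first
inside point after the run, so both are ≥ 1 and rates are finite.  Peak
ties break to the earliest index for determinism.  Runs touching either
trajectory end are flagged `truncated`, reported, and excluded from all
averages; profile-level averages are withheld entirely (reported as
missing) when fewer than `min_displacements` (default 5) usable
excursions exist, since a handful of excursions gives unreliable rate
averages.  The threshold is configurable.

## Discordance and trends

Trajectories are aligned on G = 100 time bins with centers (k + 0.5)/G —
percentage-point resolution.  Within a bin each speaker's points are
averaged; interior empty bins are linearly interpolated between occupied
neighbours, but nothing is extrapolated before a speaker's first or after
their last occupied bin (no emotional state is invented where a character
is absent) — those bins stay missing.  Pair eligibility requires at least
one token in the first and last 10% of the movie, so paired characters
span comparable narrative lengths.

Density arcs use a 30-word trailing window with **all** tokens in the
denominator (consistent with emotion word density).  Trend extraction
fits a penalized cubic smoothing spline with the smoothing parameter
chosen by generalized cross-validation (`lam` overridable); duplicate
abscissae are collapsed to weighted means first.  Curves are evaluated
with constant extension outside the fitted range, and extrema are located
on a 1001-point grid over [0, 1]; extrema at a grid or data-range boundary
carry a boundary flag, and curves whose range is below 1e−9 are flagged as
having no distinct extremum.  Model-based significance testing is out of
scope; a seeded permutation check on the linear time slope
(`permutation_slope_test`) is provided as a descriptive alternative.

## Tokenization and lemmatization

Tokenization lowercases, splits on non-word boundaries (apostrophes split:
"I'm" → `i`, `m`) and keeps 1-character fragments; lexicon lookup simply
misses non-words.  The lemmatizer is a pluggable `str -> str` callable
with an identity default, so analyses are reproducible without an external
language model; any lemmatizer (e.g. a WordNet-based one) can be passed
in.

## Synthetic generator

The generator is the package's ground-truth instrument.  A speaker's
noise-free path sits at a home center with Gaussian per-word noise
(SD σ_b) and piecewise-linear displacement events: deviation ramps
linearly to the amplitude vector over `rise` words, holds `hold` words,
and returns over `recovery` words.  Ramps (rather than smooth bumps) make
the injected rise/recovery word counts exact integers.  Words are emitted
by nearest-neighbour lookup into a deterministic lattice lexicon
(50×50 over [0.05, 0.95]², spacing ≈ 0.018), so emitted-score
quantization error is bounded by spacing/√2 and the path is recoverable.
Tokens are chunked into alternating-speaker turns with geometric lengths;
the interleaver always hands the next turn to the speaker proportionally
furthest behind, so every speaker spans the whole movie.  All randomness
flows from the spec-level seed through one named generator.

Default study conditions: center (0.5, 0.5), σ_b = 0.03, 600 focal words,
three events of amplitude 0.3 (= 10 σ_b) at word ordinals 150/300/510 with
rise = hold = recovery = 10 and inter-event gaps ≥ 3 rolling windows.  The
directions sketch a story arc — a positive-valence lift early, an arousal
surge mid-story, a negative-valence excursion near 85% — so corpus-level
trend outputs (negative density peaking late, discordance rising toward
the end) are interpretable.  The hold of one window guarantees the
smoothed trajectory actually attains the full amplitude, which is what
makes "peak distance ≈ amplitude − home-base radius along the event
direction" a sharp prediction.

What the generator does **not** emulate: real word-frequency
distributions, topical or syntactic structure, lexicon coverage gaps
(coverage is 100% by construction), speaker asymmetries in verbosity, and
autocorrelated baseline drift.  Passing the recovery tests therefore shows
the *estimators* are correct and calibrated under known conditions — not
that any particular empirical corpus result will replicate.

A note on recovery tolerances: the detector's rise/recovery counts are not
the raw ramp parameters — the trailing window and the finite home-base
radius shift exit and peak indices by a deterministic, geometry-dependent
lag.  The recovery tests therefore compare the noisy-run counts against
the counts obtained by the identical pipeline on the zero-noise
realization of the same spec (exact integers, by the ramp construction),
requiring agreement within ±2 words on replicate means.

## Problem sizes

The validation suite uses 600-word focal narratives, 50-replicate recovery
runs, 2000-point ellipse-coverage clouds and 1000-replicate band-coverage
simulations; the acceptance script's corpus is ten speakers (five
two-speaker movies, ≈ 12,000 tokens).  These sizes give stable
Monte-Carlo estimates (coverage SE ≈ 1 percentage point) while keeping a
full run in seconds.

## Known limitations

* Word-level lexicon scoring ignores negation, sarcasm and context; it is
  a strong baseline, not a sentence-level emotion model.
* The discordance binning scheme is one concrete realization of
  "distance between emotional states at the same narrative time"; other
  alignment schemes (e.g. nearest-point matching) would give slightly
  different series.
* Whether home-base statistics should be computed on raw word scores or
  the rolling trajectory is a genuine modeling choice; both are offered,
  and results differ (smoothing contracts variance, so trajectory-based
  home bases are smaller and displacement counts higher).
* Speaker-name aliasing, screenplay scraping and scene/action-line
  stripping are upstream concerns; the reader expects clean dialogue
  records.
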