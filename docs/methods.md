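# Methods

This note documents the models behind `suturemetrics`, the defaults and
why they were chosen, and what the synthetic generator does and does not
emulate.

## Zone analysis

The microscope field is partitioned by two concentric circles into zone 1
(cornea, radius `r_cornea`, default 5.75 mm), zone 2 (mounting base minus
cornea, outer radius `r_base`, default 15 mm) and zone 3 (outside).
Coordinates follow the image convention (x right, y down); the defaults
correspond to a ~11.5 mm corneal diameter held in a ~30 mm artificial
anterior chamber base.

Attribution rules:

* a sample with no visible instrument is zone 3 by definition;
* distances exactly equal to a radius belong to the inner zone (`<=`),
  so zone 1 is topologically closed — the "surface of the cornea"
  includes its rim;
* when a frame yields several candidate instrument positions, the
  innermost zone dominates; trace files carry one position per sample
  (the innermost tool).

Traces are resampled at `sampling_hz` (default 1 Hz) by nearest-in-time
selection on a tick grid inclusive of both endpoints, ties resolved
toward the earlier sample. Summaries report occupancy fractions (their
sum is 1 — the package reports a single partition per sample; published
per-instrument percentages that jointly exceed 100% are not
representable and this difference is intentional), a 3x3 transition
table, and a back-and-forth measure between zones 1 and 2. Two variants
are exposed because the underlying field practice is described only
qualitatively: `transitions_12` is the raw count of 1→2 plus 2→1 moves;
`back_and_forth_12` counts direction reversals of the timeline
restricted to zones {1, 2} (an operator who goes out and comes back once
scores one reversal); a per-minute rate is derived from the timeline
span.

Frame-based input uses an intensity blob detector: Otsu's threshold
floored at 40% of full scale (so the faint zone-circle annotations drawn
into synthetic frames can never be detected as an instrument), largest
connected component, intensity-weighted centroid. Real-video instrument
segmentation is out of scope; the detector is intended for rendered
frames and similarly high-contrast imagery.

## Geometry analysis

Stitches are segments between entry and exit points measured on the
end-of-session photograph (pixel input is calibrated by `mm_per_px`).
Only completed stitches have geometry; uncompleted ones are excluded
from every criterion. Four criteria are computed:

* length `L_k` (Euclidean);
* length ratio `L_k / L_1` for k ≥ 2 (undefined and flagged when stitch
  1 is missing or uncompleted);
* inter-stitch distance for successive index pairs (1,2), (2,3):
  Euclidean distance between midpoints. Midpoints were chosen over
  entry-point distance because they are well defined for non-parallel
  stitches and measure spacing along the wound; the convention is
  documented here because either reading is defensible;
* inter-stitch angle for the same pairs: the acute angle between the
  undirected segment directions via |cos θ|, in [0°, 90°], i.e.
  deviation from parallel.

`quality_deviation` measures departures from the conventional ideal of
2 mm long stitches spaced 1 mm apart. All criteria are invariant to
rigid motions; lengths and distances scale linearly with coordinates
while ratios and angles are scale-free (property-tested).

## Time analysis

All times are kept in seconds internally and reported in minutes. The
raw total spans the first needle entry to the last thread cut. Each
required stitch left uncompleted adds a 300 s penalty to the total, so
giving up early never ranks better than finishing slowly. For a session
with no completed stitch the raw total falls back to the span up to the
last recorded event and the summary is flagged — the source practice
does not define this case precisely, so the convention is explicit.
Per-stitch time is entry-to-cut; the intermediate time is the mean gap
`entry_{k+1} − cut_k` over consecutive completed pairs, and pairs
involving an uncompleted stitch are excluded because the gap's endpoint
does not exist.

## Scoring

The suturing-quality rubric is a data file (12 labeled items, 5-point
scale each, total 12-60); the item labels shipped are representative
paraphrases, and the arithmetic depends only on the item count and scale
bounds, so the original 15-item instrument is equally representable by
editing the YAML. Per-session scores are the unrounded mean of per-rater
totals — the aggregation rule is not standardised, and the mean is the
least surprising choice; medians in reports are computed over the
aggregated values. Inter-rater correlation is not modeled.

RULA maps a posture observation through three published lookup tables:
Table A (upper arm, lower arm, wrist, wrist twist), Table B (neck,
trunk, legs), additive muscle-use and force adjustments giving scores C
and D, and Table C (saturated at its bounds) giving the grand score
1-7. The tables are stored as an editable JSON fixture whose sha256 is
recorded in `scoring.py`; loading an edited fixture warns. An exhaustive
sweep of the full input grid (663 552 combinations) verifies the grand
score stays in [1, 7] and is monotone non-decreasing in every input.
Some published reports tabulate RULA "out of 10"; the instrument's grand
score tops out at 7 and no rescaling is applied here.

## Synthetic sessions

The generator emulates the observables the analyses consume, not the
surgery itself:

* **Completion**: per-stitch Bernoulli(`completion_prob`).
* **Durations and gaps**: log-normal, parameterised by median and log-sd
  (positive, right-skewed, matching minute-scale medians with wide
  IQRs). An uncompleted attempt consumes its drawn duration but records
  no thread cut.
* **Trace**: a continuous-time Markov process over the three zones —
  the downstream observable is exactly a zone label per 1 Hz sample, so
  a 3-state process reproduces it directly. Default rate tables are
  built as `q_ij = λ π_j` (i ≠ j), which makes `π` the stationary law;
  positions are drawn uniformly inside the active region (disc or
  annulus) and zone-3 samples are flagged invisible. The process starts
  in zone 1 (the task begins on the cornea); an all-zero rate table
  therefore stays in zone 1.
* **Stitches**: an ideal template — midpoints evenly spaced by
  `spacing_mm` along the wound line, stitches perpendicular to the
  wound, length `stitch_length_mm × length_drift^(k−1)` — perturbed by
  along-wound spacing noise, length noise, and per-stitch angle jitter.
  With all noise parameters at zero the template is recovered exactly.
* **Scores**: rubric items are integer-rounded clipped-normal draws in
  [1, 5] for each of two raters; the RULA posture is drawn uniformly
  from the grid cells whose no-force grand score equals the profile's
  target mode.

Default group profiles are calibrated once to published group medians
from a 24-surgeon study (5 senior / 8 junior / 11 novice, three sessions
each): rubric totals near 58/50.5/36, penalized totals near
6.9/8.0/13.1 min (per-stitch medians derived as (raw total − 2 ×
intermediate)/3 → 93/121/192 s), intermediate gaps 67/57/78 s, length
drift 1.16/1.05/0.83, spacing 0.94/0.78/0.88 mm, angle jitter chosen so
successive-stitch angle medians land near 2.8/5.75/6.9°, zone-1
stationary occupancy 0.69/0.547/0.61 with switch rates 0.08/0.14/0.20
per second (less experienced surgeons switch zones more). Novice
completion probability 0.9 ≈ 0.727^(1/3) matches the fraction of novice
sessions achieving all three stitches.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: the bimodal novice failure pattern (real
novices who fail tend to fail every stitch; i.i.d. Bernoulli cannot
produce 21% zero-stitch sessions alongside 73% full completion),
within-session per-stitch time trends, learning across sessions,
within-participant correlation (sessions are independent given the
profile), spatial continuity of the instrument path (positions are drawn
i.i.d. within the active zone), multi-tool identity, and anything
photometric beyond a Gaussian blob on faint circle annotations.

Seeds: a cohort uses one master seed; each session's generator is
`SeedSequence([seed, group_index, participant_index, session_index])`,
so cohorts are reproducible and any single session can be regenerated in
isolation.

## Group statistics

The session-selection policy `"paper"` pools all sessions for novices
and keeps only session 1 for juniors and seniors (the groups that
practiced between sessions); `"first"` and `"all"` are also available.
Quartiles use linear interpolation (no convention is standard in the
source practice; this one matches `numpy.percentile`). The three-group
test is Kruskal-Wallis; pairwise comparisons use Mann-Whitney
(two-sided; exact null for tie-free samples up to n = 20 per group,
normal approximation with tie and continuity corrections otherwise). The
Kruskal-Wallis p-value uses the tie-corrected chi-square approximation
at cohort scale, but for tie-free totals of n ≤ 10 the implementation
enumerates the exact permutation null, where the chi-square
approximation is visibly off (at 3/3/3 the exact tail at the 5%
critical value is 0.050 versus 0.061 for chi-square). No
multiple-testing correction is applied across report rows; significance
is flagged at p < 0.05. Each report row states its unit of analysis
explicitly: per-session scalars for scores, times and zone percentages;
pooled individual measurements for the four geometry rows (each stitch
contributes a length, each successive pair a distance and an angle).

Type-I calibration: with the three group profiles made identical, the
fraction of 1 000 simulated cohorts (8 participants per group, one
session each) whose penalized-total Kruskal-Wallis test rejects at 5% is
verified to lie in 0.05 ± 0.02.

## Problem sizes and numerical conventions

The test suite exercises: 1 000-sample traces for the zone oracle
(render → detect → attribute, ≥ 99% agreement with direct attribution —
exact-boundary samples may flip under blob quantization); 1 000 random
stitch sets for geometry invariances at 1e-9 (angles at 1e-6, limited
by `arccos` conditioning near parallel); 1 000 simulated cohorts for
test calibration; 10 000+ samples for the stationary-occupancy check
(±0.05). Zone radius comparisons are exact (`<=`), direction vectors
are normalised before the dot product and its value clipped to [−1, 1],
stitch lengths generated with noise are floored at 0.05 mm, and all
CSV/YAML/JSON writers are deterministic (sorted keys, round-trip float
parsing) so rewriting a read session is byte-identical.

## Known limitations

* The blob detector is not a video instrument tracker; real microscope
  footage needs an external segmentation step whose output becomes
  `trace.csv`.
* Rubric and RULA inputs are rater-supplied; the package aggregates
  scores, it does not rate video.
* Geometry uses a single end-of-session photograph; knot position,
  tightness and suture depth are invisible to it.
* The achievement row reports counts per session, not a hypothesis
  test, because group definitions mix participants and sessions under
  the `"paper"` policy.
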