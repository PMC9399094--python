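# Methods

This note documents the models behind `oriscope`, the defaults and the
reasoning behind them, the numerical methods, where the generators are
deliberately unrealistic, and known limitations.

## 1. Tether and binding-event model (`kymo_sim`)

### Tether geometry

The simulated DNA is a 47,822-bp construct with an ARS1 element at
positions 33,499–33,999 (1-based, inclusive). These numbers follow from
the in-silico cloning model (section 5): a 48,502-bp λ-like vector cut at
its unique XhoI (site start 33,498) and NheI (site start 34,679) sites,
religated with a 501-bp insert. Imaging maps base pairs to pixels at
250 bp/px with a 0.1-s line time; the default recording is 200 lines.

### Nucleosomes

`simulate_tether` deposits 1–7 nucleosomes (uniform) at uniformly random
dyad positions with a minimum spacing of 2,000 bp (rejection sampling),
each carrying a fluorophore with probability 0.7.

* **1–7 nucleosomes** — sparse chromatinization so individual nucleosomes
  are optically resolvable on a ~192-px scan line.
* **Minimum spacing 2 kb** — the experiment this models uses sparse
  deposition in which each nucleosome is flanked by long free stretches;
  with 250 bp/px and a 1-px PSF, dyads closer than ~3 px are a single
  diffraction-limited spot and would not be censused as two nucleosomes.
  A bare 147-bp exclusion would produce such unresolvable clusters that
  the modeled experiment never scores.
* **Labeling 0.7** — typical maleimide/SNAP labeling efficiencies;
  exercises the "detected nucleosome" conditioning in downstream
  analyses.

### Binding events

`simulate_events` generates, per tether:

* A **stable ORC** at each nucleosome dyad with probability
  `p_orc_nuc_bind` (default 0.95), arriving in the first 10% of the
  recording and persisting to the end (the modeled dwell times are tens
  of minutes, much longer than a recording).
* A **stable ORC at the ARS midpoint** when Cdc6 is present and no
  nucleosome covers it.
* **Diffusive bare-DNA ORC excursions** (Poisson count, mean 2) with
  D = 0.2 kb²/s and a 5-s mean dwell. Their 1-D random walk (reflected
  Gaussian steps of SD √(2·D·Δt)) is confined between the flanking
  ORC-occupied nucleosome dyads ±73 bp, reflecting nucleosomes acting as
  roadblocks to sliding.
* **MCM events** only at stable ORC positions (probability 0.8 per ORC):
  licensing is strictly ORC/Cdc6-dependent. Each MCM is a double hexamer
  with probability `f_dh` (default 0.79), and each hexamer carries a dye
  with probability `p_label` (default 0.6) — one label slot per hexamer
  (a single tagged subunit per ring).

### Photophysics

Each labeled fluorophore emits `photons_per_fluor_per_line` (default 150)
photons centered on its position; rendering convolves emitters with a
Gaussian PSF (σ = 1 px), adds uniform background (20 photons/px), and
Poisson-samples every pixel. Dyes bleach as an exponential process.

* **Bleach rate 3 × 10⁻⁴ per line (default)** — recordings of this kind
  run 4–10 minutes (2,400–6,000 lines at 0.1 s/line) under an oxygen
  scavenger, so fluorophores must survive thousands of lines; 3 × 10⁻⁴
  per line gives a mean lifetime of ~3,300 lines (~5.5 min).
* **Bleach rate 0.01 per line in photobleaching assays** — step-counting
  experiments deliberately omit the scavenger so that dyes bleach within
  the trace; `simulate_bleach_traces` and the stoichiometry workflows
  pass this higher rate explicitly.

### High-salt wash

`apply_salt_wash` assigns each MCM event present at the wash line one of
`slide` / `stay` / `dissociate` (default probabilities 0.3/0.3/0.4) and
rewrites the post-wash trajectory: truncation for dissociation, an
unconfined (or optionally nucleosome-confined) random walk for sliding.
This models the 0.5 M NaCl challenge that distinguishes topologically
loaded MCM from surface-associated complexes.

## 2. Measurement pipeline (`trace_pipeline`)

* **Detection**: per line, a Gaussian matched filter (σ = 1 px); the
  noise scale is the median absolute deviation (MAD) of the filtered
  line, and candidates must exceed `snr_min` (default 4) × noise.
  Sub-pixel positions come from a 3-point parabolic fit around each
  maximum.
* **Linking**: greedy nearest-neighbour frame-to-frame linking with a
  3-px jump limit, gap closing up to 2 missed lines, and a 5-line
  minimum trajectory length.
* **Mobility**: a trajectory is "stable" when its robust positional
  variance — (1.4826 × MAD of positions)² — is below a threshold.
  The default (0.1 px²) can be replaced by
  `calibrate_variance_threshold`, the 99th percentile of the same
  statistic over simulated immobile emitters at the configured
  localization noise; the underlying papers state no criterion, so the
  threshold is calibrated, not copied. The robust statistic (instead of
  a plain variance) prevents a brief passage of a second, diffusing
  molecule through the same pixel column from flipping a stable
  trajectory to "diffusive".
* **Position**: "ARS" iff the median position lies within the ARS
  interval ± 1 kb (strictly inside the widened interval).
* **Colocalization**: for every temporally overlapping pair, the mean
  separation over common lines; pairs qualify when separation ≤ 500 bp
  and overlap ≥ 10 lines. Assignment is greedy by smallest separation
  with qualifying pairs assigned before non-qualifying ones (so a
  distant partner cannot consume a trajectory whose true partner
  qualifies). `one_to_one=False` switches to existence semantics — every
  trajectory is scored against its nearest partner even if shared —
  which is the right reduction for per-site occupancy questions: when a
  trajectory fragments (dye gap or bleach), exclusive pairing lets one
  fragment consume the partner and miscounts the other as unbound. With
  ≥ 2-kb nucleosome spacing and a 500-bp cutoff, a stable ORC can
  physically neighbour only one nucleosome site, so the two modes
  differ only through such artifacts.
* **Salt response**: trajectories present at the wash line are
  "dissociate" if they end within 5 lines of it, "slide" if the
  post-wash positional range exceeds 2 kb, else "stable". A slowly
  diffusing slider can legitimately stay within 2 kb over a short
  post-wash window, so slide recall is intrinsically < 1.
* **Arrival mode**: "sliding_1D" iff the first 10 lines show ≥ 1 kb of
  net displacement toward the final position, else "direct_3D".
* **Summaries**: per-replicate fractions with mean, SD (ddof = 1) and a
  two-sample equal-variance t-test across replicates when requested.

## 3. Photobleaching stoichiometry (`stoich`)

### Step fitting

Intensity traces are Poisson-distributed, so their noise is
signal-dependent. `fit_steps` therefore applies the **Anscombe
transform** z = 2√(y + 3/8), which makes the noise approximately unit
variance everywhere, and runs exact **PELT** (penalized least-squares
change-point detection with pruning) on z. The penalty default is
3·σ̂²·log n, with σ̂ estimated as MAD(Δz)/√2; segments shorter than 2
lines are disallowed. Steps are counted on the segment means, requiring a
drop of at least 3σ̂ (noise floor); any upward step marks the trace
"excluded" (aggregation or a second molecule arriving). Without variance
stabilization, a global noise estimate is dominated by the
low-background tail of the trace and over-segments the bright initial
plateau.

The PELT implementation is vectorized over candidate change points
(cumulative-sum segment costs) and is exact: the test suite checks it
against brute-force enumeration on short traces.

### Inference

With double-hexamer fraction *f* and per-hexamer labeling probability
*p*:

* P(invisible) = f·(1−p)² + (1−f)·(1−p)
* P(1 step) = f·2p(1−p) + (1−f)·p
* P(2 steps) = f·p²

`infer_dh_fraction` maximizes the binomial likelihood of the observed
1-step/2-step split in *f* (bounded MLE; the estimate clips to 1 when
the observed 2-step fraction exceeds the theoretical maximum p/(2−p))
and attaches a percentile bootstrap CI (2,000 resamples). The
statsmodels-style wrapper `DoubleHexamerModel(...).fit()` returns a
`DoubleHexamerResults` with `params`, `conf_int()`, `predict()` and
`summary()`.

## 4. Synthetic genomes and tracks (`genome_synth`)

* `sample_genome`: i.i.d. bases at yeast-like composition
  (A/T 0.31, C/G 0.19).
* `plant_motifs`: motif instances drawn from the PWM by rejection until
  they score above a floor, placed without overlap on random strands;
  the truth table records position, strand and exact score.
* `simulate_occupancy`: phased Gaussian nucleosome bumps (spacing
  165 bp, σ 40 bp) with smooth multiplicative depletion wells (depth 0.9)
  at NFR centers, Poisson-sampled at depth 100. NFR width default 150 bp
  sits in the canonical 80–300-bp range.
* `simulate_chip_coverage`: one Gaussian mound per site (σ 100 bp ≈
  sonication fragment spread), area proportional to site strength, an
  optional satellite mound 100–400 bp away (to exercise peak-cluster
  collapse), and uniform Poisson noise.

### Realism limits

These generators are deliberately simple: i.i.d. background sequence (no
codon structure, repeats, or GC landscape), stationary phasing, symmetric
Gaussian peaks, white Poisson noise, and no mappability or copy-number
artifacts. They are designed so that every downstream claim has an exact
planted truth, not to imitate real data statistically.

## 5. In-silico cloning

`build_lambda_ars1` performs a XhoI (C^TCGAG) + NheI (G^CTAGC) double
digest of a vector with exactly one site of each, and ligates an insert
given as the exact sequence appearing between the two top-strand cut
points (it must begin `TCGAG` and end `G`, regenerating both sites).
`make_synthetic_lambda_vector` produces a 48,502-bp random sequence with
the two sites at 1-based starts 33,498 and 34,679 and no spurious
occurrences elsewhere, so the standard accounting reproduces the real
construct: 33,498-bp left arm + 501-bp insert + 13,823-bp right arm =
47,822 bp with the insert at 33,499–33,999, and a 47,321-bp product for
an empty religation (1,181 bp excised). Only this geometry — not the λ
sequence itself — is reproduced.

## 6. Motif and peak analysis (`motif_peak`)

* **PWM scoring**: summed log₂(p/background) over a 17-bp window; the
  probability matrix is pseudocount-smoothed (0.01) and renormalized.
  Windows with non-ACGT characters score −∞. Scanning covers both
  strands via the reverse-complement matrix and uses a **strict** `>`
  cutoff.
* **Peak collapse**: peaks whose edges are within 500 bp cluster
  transitively; the largest-area peak represents each cluster (ties:
  leftmost summit).
* **Census**: per peak, the number of windows above the cutoff within
  ±500 bp of the summit, classed 0 / 1 / ≥2.
* **Threshold sweep**: fraction of peaks with ≥1 qualifying window over
  cutoffs 9–15 (best window scores computed once, then compared to each
  cutoff, guaranteeing monotonicity).
* **Ranking**: peak strength = coverage area within ±1 kb of the summit;
  Spearman correlation between strength rank (1 = strongest) and best
  motif score is reported (≤ −1 · perfect agreement ⇒ ρ = −1).
* `make_acs_like_pwm` is a synthetic 17-bp AT-rich matrix (strong
  positions at probability 0.85) for fixtures and demonstrations; it is
  **not** the published ACS matrix.

## 7. Occupancy heatmaps and NFR calling (`occupancy_nfr`)

* `build_heatmap` extracts ±flank windows around anchors, flips
  minus-strand rows, NaN-pads at track edges; `column_means` drops rows
  with > 50% missing values (with a warning) and averages the rest,
  ignoring remaining NaNs.
* `call_nfrs` divides the track by a running-median baseline (window
  2,001 bp — robust to both peaks and NFRs at the modeled nucleosome
  spacing) and calls maximal runs below `depletion_ratio` (0.5) of the
  baseline that are at least `min_width` (80 bp) wide, matching the
  lower edge of the canonical NFR width range.
* `motif_occupancy_fraction` reports the fraction of above-cutoff motif
  hits whose 17-bp footprint overlaps any peak (half-open interval
  overlap via binary search).

## 8. Numerical choices

* All randomness uses `numpy.random.default_rng`; every simulation
  function takes a seed or Generator, and the test suite is fully
  deterministic.
* PELT is exact (verified against exhaustive enumeration) and
  vectorized; fitting 5,000 500-line traces takes ≈ 1 minute.
* Bootstrap CIs use percentile intervals (2,000 binomial resamples).
* Intervals follow BED conventions (0-based half-open) in `motif_peak`,
  `occupancy_nfr` and `io`; the tether/cloning coordinates are 1-based
  inclusive, matching how such constructs are described.

## 9. Limitations

* The simulator has no stage drift, tether breathing, chromatic offset
  between channels, or camera read noise; localization error comes only
  from photon statistics.
* Nucleosomes are static (no sliding, eviction, or partial unwrapping),
  and stable ORC/MCM events never dissociate within a recording except
  through the salt wash.
* MCM stoichiometry treats each hexamer as a single label slot; dye
  blinking and FRET-like interactions are not modeled.
* The salt-wash "slide" class overlaps "stay" for slowly diffusing
  molecules over short post-wash windows; classification recall reflects
  physics, not a bug.
* Synthetic genomes/PWMs mean published genome-wide numbers (peak
  counts, census splits, occupancy fractions at given cutoffs) are not
  reproduced — the pipelines that would compute them from real data are
  tested on planted-truth fixtures instead.
* The colocalization acceptance target has a hard ceiling at the
  generator's 95% occupancy; with 50 tethers (~140 detected
  nucleosomes), run-to-run variation of a few percentage points is
  expected.
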