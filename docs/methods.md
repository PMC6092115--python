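# Methods

This note documents the models, parameters and numerical conventions behind
`pfk`, the design choices that were genuinely open, and what the synthetic
validation does and does not establish.

## Signal conditioning

All channels are uniformly sampled (200 Hz throughout this package's
defaults and generators) and low-pass filtered with a **dual-pass Butterworth
filter**: one forward pass and one time-reversed pass, which cancels the
phase response exactly and squares the magnitude response. "Fourth-order
dual-pass" is realised as a 2nd-order design per pass (effective 4th order),
the common biomechanics convention; `FilterSpec.order_per_pass` exposes the
alternative reading (4th per pass, effective 8th). The default cutoff is
10 Hz. Two consequences are deliberate and documented rather than hidden:

* The combined −3 dB point of the two-pass filter sits slightly below the
  nominal cutoff (at 10 Hz the combined gain is exactly 1/2, not 1/√2).
  `FilterSpec(correct_cutoff=True)` raises the design cutoff by
  `(√2 − 1)^(−1/(2n))` so the combined −3 dB lands on the nominal value; the
  correction is **off** by default because only the nominal cutoff is part of
  the protocol.
* Edge transients are suppressed by odd-reflection padding of exactly
  `3·(2·order_per_pass + 1)` samples, stripped after filtering, so outputs
  are reproducible bit for bit. Series must be longer than the padding.

Intervals are half-open `[start, end)` everywhere, timestamps are seconds
from trial start, and sample *i* sits at `t0 + i/fs` exactly.

## Onset detection (2-SD rule)

An onset is the first sample at/after the search start whose deviation from
the baseline mean exceeds `k·max(SD, sd_floor)` and stays beyond threshold
for at least `min_hold` seconds. `k = 2` (the protocol's rule),
`sd_floor = 1e-9` signal units so that noise-free baselines (SD exactly 0)
remain detectable, and polarity is configurable (`above`, `below`,
`absolute`).

`min_hold` deserves care. For raw, white-noise baselines 0.05 s (the core
default) suffices to reject isolated spikes. After 10 Hz low-pass filtering,
however, baseline noise is correlated over roughly the filter's impulse
response (~0.1 s), and 2-SD excursions routinely persist longer than 0.05 s:
with the hold at 0.05 s the APA detector fired early on noise in roughly a
quarter of trials at 5%-of-peak noise (mean |onset error| ≈ 0.23 s). The APA
pipeline therefore uses **`min_hold = 0.15 s`** — longer than any plausible
noise excursion, far shorter than the force plateau it must confirm — which
brings the mean onset error to ~6 ms at the same noise level. The hold only
confirms the crossing; the reported onset is still the first crossing sample.

## Freezing-of-gait analysis

Walk trials are analysed in sliding windows of **7.5 s** (hop 0.25 s) over
the 10 Hz-filtered lumbar vertical acceleration. Each window is demeaned,
Hann-tapered and turned into a one-sided periodogram (frequency resolution
1/7.5 Hz). The FoG index is the peak power in the freeze band (3–8 Hz)
divided by the peak power in the locomotor band, and windows with index
above the clinical threshold 2 are classified as freezing. Choices:

* **Locomotor band [0.5, 3] Hz.** Descriptions of the band vary between
  0–3 Hz and 0.5–3 Hz; the 0.5 Hz lower edge is used because it excludes DC
  and near-DC leakage from a ratio that is only meaningful during rhythmic
  movement. Both edges are configurable (`BandSpec`), and band edges are
  inclusive (the shared 3 Hz bin counts in both bands).
* **Hann taper.** Peak-power ratios need leakage control; the taper is part
  of the documented convention so results are reproducible.
* **Validity.** The index is only defined while the subject moves. A window
  is invalid (NaN, excluded from event calling) when its larger band peak
  falls below 1e-3 of the trial's largest band peak — this excludes quiet
  standing without excluding fully-frozen windows, whose locomotor content is
  legitimately near zero. The index denominator is additionally floored at
  1e-12 of the series variance so no window produces an infinite ratio.
* **Event calling and edge de-biasing.** A window covers its centre
  ± hop/2; maximal runs of freezing windows merge into events, and runs
  separated by < 0.5 s merge. Because a 7.5 s window classifies as freezing
  as soon as ≈ `√2/(ρ+√2)` of its Hann-weighted mass is freeze content
  (ρ = freeze/locomotor amplitude ratio), raw run extents over-reach a
  square-pulse episode's edges by an amplitude-dependent margin — about
  0.7 s per edge at ρ = 3. `detect_fog` therefore estimates ρ from the data
  (peak freeze power inside the event vs median locomotor power outside),
  inverts the Hann cumulative mass for the flip offset, and shrinks each
  edge by that margin. On the synthetic generator this reduces the duration
  bias from ≈ +1.6 s to ≈ ±0.3 s for 8 s episodes. The correction assumes
  an approximately square episode profile; it is conservative (capped) for
  episodes shorter than the window and can be disabled
  (`edge_debias=False`).
* **Gait time** uses trial start/stop marks when present; otherwise the
  extent of a 0.5 s moving-RMS envelope above the quiet-baseline mean +
  2·SD, with the SD floored at 5% of the envelope's dynamic range so that
  noise-free or demeaning-offset baselines behave.

## APA extraction

The mediolateral force onset uses the **absolute** deviation from the
baseline mean by default: the sign of the weight-shift shear depends on the
plate's axis convention and the stepping side, and the absolute deviation is
side-agnostic (a signed mode driven by `stepping_side` exists). The baseline
is the first 1 s of the trial (the protocol guarantees initial quiet
standing); it is configurable per trial. The step-onset search starts at the
APA onset — the step follows the weight shift — which keeps baseline jitter
from triggering it early. APA amplitude is the peak *deviation from the
baseline mean* of the mediolateral force between the onsets ("peak
amplitude" is ambiguous between absolute force and deviation; deviation is
used and recorded), divided by the subject's foot length (N/cm).

## Reactive posture

Axis convention: x anteroposterior (positive forward), y mediolateral,
z vertical; a backward platform translation is negative. COP requires
`|Fz| > 50 N` at every sample (plate statics are ill-conditioned at low
load; the error names the first offending timestamp). The segmental COM
model is shipped as a versioned JSON table (`pfk/data/winter_segments.json`):
foot 0.0145/0.50, shank 0.0465/0.433, thigh 0.100/0.433 (bilateral, count 2)
and HAT 0.678/0.626 from trochanter toward shoulder — fractions of body mass
and of segment length from the proximal marker. Only AP coordinates are
used, with one hemibody's markers standing for both sides (symmetric
displacement assumption); `Σ mass_fraction·count = 1` is validated.

Both series are filtered, referenced to their mean over the **1 s
immediately preceding perturbation onset** (displacement needs a zero; quiet
stance is the natural one), and summarised as RMS over **2.5 s after
onset** — the platform motion lasts < 1 s and recovery completes within
2–3 s. Window length and reference convention are parameters
(`ReactiveParams`, `PerturbationTrial.analysis_window`).

## Outcome statistics

Trial metrics are averaged per subject × condition; percent change is
`(ON − OFF)/OFF`; the improvement score negates variables where a decrease
is better (gait time, FoG time, APA duration, COP/COM RMS — lower RMS is
taken as better, consistent with describing higher excursions as worse
performance) and keeps the sign for APA amplitude. Group percent changes are
tested against zero with a **two-sided** one-sample Student t-test (the
conservative default; one-sided available), significance at p ≤ 0.05, no
multiple-testing correction by default (a Holm option exists). Subjects with
an OFF mean of exactly zero for a variable — typically no freeze episodes in
the OFF condition — are excluded for that variable with a logged note, so
FoG statistics run on the freezing subjects only. Degenerate t-test inputs
(n < 2 or zero variance) are reported as notes, never silently imputed.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of spec + seed (bit-reproducible; seeds
recorded in every truth file).

* **Walk**: locomotor sinusoid (2 Hz, 1 m/s² by default) active on a marked
  walking span, freeze episodes that *replace* the locomotor component with
  3–8 Hz trembling (default 5 Hz at 3× the locomotor amplitude — the
  episodic trembling dominates the trace, and halted progression is modelled
  by removing the locomotor component; an additive mode exists), plus white
  noise (0.05 m/s²).
* **Step**: half-cosine mediolateral force rise (0.10 s — the fast initial
  weight transfer of gait initiation) to a plateau, release after the step;
  half-cosine foot displacement (20 cm over 0.25 s); force noise 5% of the
  APA peak, marker noise 0.05 cm.
* **Perturbation**: trapezoidal-velocity platform displacement with the
  protocol parameters (12 cm, 15 cm/s, 100 cm/s²; onset drawn uniformly from
  the 1–3 s preparatory range); markers ride the platform plus a
  height-scaled second-order damped-oscillator sway (0.5 Hz, ζ = 0.3, gain
  0.25 — minimal plausible dynamics, not claimed physiological); plate
  channels built by inverse statics so the record's COP equals a known
  target trajectory. The target COP's inertial term is band-limited to
  10 Hz so the target carries no energy the analysis chain is designed to
  reject.
* **Study**: 4 subjects (two freezers), 3 conditions; the 300 Hz condition
  shortens APA duration and freeze time, raises APA amplitude and shortens
  gait time; the 60 Hz condition equals OFF (its observed effects are noise);
  reactive sway is condition-independent. Per-trial jitter (onsets ±30 ms,
  amplitudes ±5%, sway gain ±15%, walking span ±0.3 s) provides within-cell
  variability.

Passing the closed-loop tests therefore shows that the pipeline recovers
known two-band spectral structure, smooth ramp onsets and rigid-body statics
under realistic noise — it does **not** validate performance on real
pathological signals, which contain non-stationary cadence, turning
artifacts, multiple/aborted APAs ("knee trembling"), and marker occlusion,
none of which are modelled.

## Numerical and degenerate-input conventions

* Baseline SD uses the n−1 denominator; baselines need ≥ 2 samples.
* Absence of a threshold crossing returns `None` (not an error); trials
  without onsets are flagged invalid, logged, and excluded from averages.
* A step onset preceding the APA onset flags the trial invalid — never
  clamped.
* NaN/Inf cells in trial files are rejected at read time; the time column
  must be consistent with the declared sampling rate.
* Problem sizes used in validation: 60 s walks (20 seeds) for freeze-duration
  recovery, 50 seeded step trials for onset recovery, 2-subject reduced
  studies for byte-identity checks; the full 4-subject study (216 trials)
  runs in seconds and is driven by the `analysis/` scripts.

## Known limitations

* Event timing from 7.5 s windows localizes edges only to a few tenths of a
  second even after de-biasing; freeze episodes much shorter than the window
  are detected but their durations are biased.
* The FoG index's denominator floor and movement-validity rule are heuristics
  for "is the subject walking"; trials consisting mostly of standing should
  provide walk marks.
* COP statics assume a single rigid plate; the generator's default plate
  origin coincides with the surface (offset terms are exercised in unit
  tests, not in the synthetic study).
* The anthropometric table is an adult-average sagittal model; per-subject
  scaling is possible only by supplying a custom JSON table.
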