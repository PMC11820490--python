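# Methods

## Detection model

A change of direction (COD) in a V-cut trial shows up in the trunk's
horizontal speed as a pronounced braking trough: the athlete decelerates
from a ~4 m/s cruise to near 1 m/s, plants the cutting foot, and
re-accelerates along the new heading.  The detector exploits two facts:
(i) the trough is far deeper than stride-to-stride speed oscillation, so a
prominence threshold on the filtered speed isolates the cuts; and (ii) the
two foot-contact events that bound the analyzed window — the heel strike of
the penultimate foot contact (IF) and the toe off of the final foot contact
(FF) — bracket the trough closely, so a bounded search region around the
minimum suffices to find them in the binary contact channels.

Assumptions: the trunk velocity components are expressed in a global frame
whose x/y plane is horizontal (no re-orientation is attempted); the contact
channels are per-point (heel, toe) per foot — a source with a single
per-foot flag is duplicated into both points; the PFC and FFC are on
opposite feet, which holds for sidestep cuts of this angle.

## Signal processing

* Horizontal speed: `V_hor[t] = hypot(vx[t], vy[t])`; non-negative by
  construction.
* Filter: Butterworth low-pass of order 4 (per pass) at 1.5 Hz, applied
  forward and backward (`scipy.signal.filtfilt`).  The two-way pass doubles
  the magnitude attenuation (effective 8th-order magnitude) and has zero
  phase lag, so trough positions are not shifted — essential because the
  search region is anchored on them.  No cutoff-frequency correction is
  applied; the 1.5 Hz figure is taken as the per-pass design value.  Edge
  handling uses `filtfilt`'s default odd-reflection padding (configurable:
  odd/even/constant/none); series shorter than the padding requirement
  (16 samples at order 4) are rejected with the minimum length named.
* Minima: standard peak prominence on the negated series
  (`scipy.signal.find_peaks`).  Endpoints are never minima; a plateau
  minimum is reported at its first frame.  Default threshold 1.5 m/s.

## Event rules

With the minimum at frame `m` and region `[m − b, m + a]` (defaults
b = 40, a = 25 frames at the 60 Hz reference rate, scaled proportionally
for other rates and clipped to the trial):

* IF: latest `t ≤ m` with heel(PFC side)`[t] = 1` and a backward difference
  of +1 — the braking heel strike nearest the trough, skipping earlier
  steps.
* FF: earliest `t ≥ m` with toe(FFC side)`[t] = 0` and a unit-magnitude
  backward difference — the first airborne frame after the plant.  (A
  signed-difference reading of a "derivative = 1" rule cannot describe a
  1→0 step; the falling-edge reading is the one consistent with FF being a
  toe off.)
* Sides: the FFC side is the foot whose toe-off falls earliest at/after the
  minimum (tie → LEFT, deterministic); the PFC is contralateral.  A known
  cut schedule can be passed to override the inference.
* Missing transitions produce `IF_MISSING` / `FF_MISSING` / `BOTH_MISSING`
  statuses rather than errors; events are reported independently even when
  regions overlap.

## Evaluation

Differences are signed automatic − manual frames.  Summaries: median, mode
(ties toward the smallest absolute value), IQR (Q3−Q1, linear
interpolation); |E| = mean |diff|, s(E) = sample SD (n−1); AP_k = 100 ·
(matched pairs with |diff| ≤ k) / (all manual events) — undetected events
count only in the denominator; Bland–Altman bias ± 1.96·s(E); Pearson r of
total cutting times with R² = r² (an identity-line R² = 1 − SS_res/SS_tot
variant is exposed under a flag, since the two conventions differ whenever
the methods disagree systematically).  Matching pairs k-th with k-th when
counts agree; otherwise a minimum-total-distance assignment between
automatic minima and manual event midpoints, capped at one region width.
The tuning objective RMSE pools squared IF and FF differences; each
unmatched manual event, and each missing side of a matched pair,
contributes one penalty term (default: squared region width) so parameter
sets that drop events are never preferred.

## Tuning protocol

Whole-trial split with a per-stratum ceiling rule: the training count is
the smallest integer reaching the requested fraction (80% of 248 pooled
trials → 199 training / 49 test trials, 796/196 CODs at 4 per trial).
Assignment within strata is seeded and logged; counts are seed-invariant.
Grid search is exhaustive over user-specified prominence × region values
(shipped default grid: {0.5, 1, 1.5, 2, 2.5} × {20, 30, 40, 50} ×
{15, 25, 35}, bracketing the defaults); ties break toward the smaller
prominence, then the smaller total region width, then the smaller backward
bound.  The filter is fixed during tuning, so each trial is filtered once
and the trace reused across cells.

## Synthetic generator

`generate_trial` emulates a V-cut trial: a cruise-speed profile with one
raised-cosine dip per COD (depth cruise − trough ≈ 3.2 m/s, half-width 40%
of the 1.2 s inter-COD segment, monotone start/stop ramps), heading
alternating ±67.5° across troughs (a 135° cut), and alternating-foot stance
trains (3.5 steps/s, duty factor 0.35, heel and toe flagged together per
stance).  The PFC heel strike is anchored `if_offset` (default 18) frames
before each trough and the FFC toe off `ff_offset` (default 10) frames
after; the PFC→FFC interval contains no other steps, and filler steps
between CODs keep foot alternation and cadence.  Optional Gaussian velocity
noise (default SD 0.1 m/s, clipped at zero) and integer edge jitter; ground
truth records the *realized* edges, so exact recovery is a meaningful
end-to-end oracle.  `generate_dataset` varies cruise speed and offsets per
trial and assigns gender × team-category × test-type strata round-robin.

What the generator does **not** emulate: realistic joint kinematics, double
support irregularities, sensor soft-tissue artifacts, contact-detection
errors in the capture software, or annotator disagreement.  Passing tests
therefore demonstrate the correctness of the algorithmic chain and its
noise robustness at the signal level, not field accuracy on real cohorts.

Failure fixtures reuse the generator with overrides: `MIN_TOO_LATE` shifts
one trough's dip center past the true toe off (the detector latches a later
toe-off, and may also mis-assign the cutting side); `IF_OUTSIDE_REGION`
moves one true heel strike 55 frames before its trough, outside the default
region (IF wrong or missing).  The remaining CODs stay at zero error.

## Numerical and design choices

* Region rescaling uses `round()` of `bound · rate / 60`; frame indices are
  0-based over motion frames only (calibration poses excluded at parse).
* Prominence is in m/s on the filtered trace.
* Tabular CSV floats are read with round-trip precision so write→read is
  lossless; MVNX round-trips exactly via `repr` floats.
* Edge cases: a rising edge at frame 0 cannot qualify (no predecessor);
  degenerate zero-variance cutting times raise rather than return NaN.
* Problem sizes in tests and the acceptance script (50–60 noisy trials,
  248-trial cohort dataset, 12-cell grids on 12–24 trials) were chosen as
  the smallest sets at which the measured quantities are stable across
  seeds.

## Known limitations

* No velocity-based IF/FF fallback when contact channels are absent.
* The cutting-side inference assumes the first post-minimum toe-off belongs
  to the cutting foot; pathological double-support patterns can flip it
  (the schedule override exists for exactly this case).
* V-cut-with-ball trials are represented only as metadata plus a slightly
  lower cruise speed; ball handling has no kinematic signature here.
* The evaluation battery is descriptive; no inferential statistics (ICC,
  hypothesis tests) are provided.
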