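# Methods

## Signal model

A pulse radar alternates between transmitting a short pulse and sampling
the received echo. Within one echo, fast time τ maps to range (bin size
4 mm here); across pulses, slow time t advances by the scan interval
(0.01 s). The received analog signal is a superposition of delayed,
scaled copies of the transmitted pulse, one per scatterer; sampling both
axes gives the frame matrix `R[m, n]` (M scans × N = 256 bins). All
processing operates on this matrix. Indexing is 0-based internally (scan
m occurs at `m·T_s`; bin n spans `[4n, 4n+4)` mm); reports use seconds and
metres.

Amplitudes are arbitrary units throughout: the radar is uncalibrated and
every downstream statistic is either scale-invariant (motion variance) or
compares like with like (DTW over libraries recorded with the same gain).

## Pulse template

The transmitted pulse of the modeled radar chipset is not published, only
its band (6–10.2 GHz); the simulator therefore uses an idealized shape.
The default is a 24-bin asymmetric monocycle: a positive half-sine lobe
over the leading quarter and a shallower negative recovery lobe over the
remaining three quarters, scaled to sum exactly to zero and normalized to
unit peak. Two properties motivate this choice over a generic enveloped
multi-cycle sinusoid:

- its autocorrelation peaks sharply at zero lag (matched-filter behavior
  all CLEAN variants need);
- the leading quarter is everywhere ≥ 0 and the tail everywhere ≤ 0, so
  the short template's correlation with a later echo is never *increased*
  by the first echo's tail. This makes nearest-echo detection structural:
  for any gap of at least a quarter pulse and any second echo no stronger
  than the first, the argmax of the short-template correlation sits
  exactly on the first echo (exact ties at full separation resolve to the
  smaller bin). With a multi-cycle envelope the front window correlates
  positively with the tail at some lags and the property provably fails;
  we verified this numerically over a wide parameter grid before fixing
  the default. Multi-cycle Hann-windowed sinusoids remain available via
  `cycles ≥ 2` for experiments, without the guarantee.

The pulse length (24 bins ≈ 9.6 cm) is deliberately comparable to
lip–jaw echo separations so that conventional CLEAN's overlap weakness —
the reason the short-template variant exists — is present in simulation.

## Correlation normalization

"Normalized cross-correlation" is normalized by template energy only:
`s[n] = Σ_k y[n+k] v[k] / ‖v‖²`, signal zero-extended past its end. A
noiseless echo `a·v` then yields `s = a` at its bin, so detection
amplitudes scale with the received signal — necessary both for the
amplitude feature and for a stop threshold of 2.0 in amplitude units (a
cosine-normalized variant bounded by 1 could never cross it). The stop
threshold and the 25% short-template fraction (`⌊0.25 L⌋` samples) are
configuration knobs with those defaults.

## Clutter reduction

The background is the per-bin mean of the first 100 scans of a dedicated
empty-scene capture, subtracted from every live scan. A fallback
(`background_from_session`) averages the live session's own first 100
scans for use when no empty capture exists; the default path matches the
reference procedure. No adaptive clutter update is attempted.

## Activity detection

The normalized amplitude-difference profile has mean exactly 1/N by
construction; its variance about 1/N is the motion statistic, smoothed by
an EMA with α = 0.1 initialized at the first raw value (avoids a startup
transient toward zero). Identical consecutive frames define the profile
as uniform (variance 0, i.e. no motion). Segment timing: a segment opens
at the first frame at/above threshold; it closes when the smoothed trace
has stayed below threshold for 0.4 s, with the raw end placed at the
first below-threshold frame after the last above-threshold one; storage
margins of 0.2 s (start) and 0.1 s (end) compensate the filter lag, the
start clipped at zero. Crossings are timed on the smoothed trace
throughout.

The articulator gate takes the rest distance as the median primary-
detection bin over the 0.5 s preceding the raw segment start (an
estimator for "distance when there is no motion"; the reference procedure
does not specify one) and requires *every* in-segment detection within
[−4 cm, +3 cm] of it — a single spike beyond the gate indicates
non-articulator motion and discards the segment. Decreasing bin = toward
the radar, so −4 cm is the forward-lip bound. Non-speech articulator
movements inside the gate are accepted (a known limitation shared with
the modeled system).

## Motion threshold and simulator noise calibration

The motion threshold 1e−5 is a fixed operating constant selected above
no-movement data. For iid Gaussian receiver noise the no-motion value of
the variance statistic is amplitude-invariant and equals
`(Var|Z|/E|Z|²)/N² = (π/2 − 1)/N² ≈ 8.7e−6` at N = 256 — uncomfortably
close under the threshold, and its smoothed fluctuations occasionally
graze 1e−5. Real receivers additionally exhibit slow common-mode baseline
drift, which spreads frame differences evenly over all bins and pulls the
statistic *down*. The simulator models this as a bounded triangular
baseline wander (amplitude 0.08, period 0.6 s, random phase), whose
constant-magnitude per-frame step is ≈1.26× the per-bin difference sd at
the default noise_sd = 0.003. Calibration (done once, before the test
suite was written): across 200 three-second static sessions the worst
smoothed no-motion value was 8.6e−6 with zero threshold exceedances,
while amplitude-only articulation ("five"-like, +30% reflectivity over a
0.15 s ramp) exceeded threshold in 40/40 sessions with ≥2.6× margin.

## Scenes and the synthetic vocabulary

A speaker scene is one moving lip target (rest range 13.2 cm,
reflectivity 5) over an immobile face echo at 19 cm (reflectivity 2.5,
deliberately overlapping the lip echo within one pulse length), a room
reflector at 45 cm, and coupling leakage at bin 0. "two"-like words dip
the range by 2 cm with a 30% amplitude drop; "five"-like words keep range
constant and raise amplitude 30%. The five-word evaluation vocabulary
(push / drop / pull / tap / slide) uses distinct piecewise-linear
(range, amplitude) signatures; each repetition jitters onset (±0.08 s),
duration (×0.85–1.15) and excursion scale (×0.9–1.1) so repetitions vary
in length and detail. Sessions are 2 s with the word near 0.55–1.25 s,
leaving the ≥0.5 s rest window the gate estimator needs; background
captures are 1.2 s (≥100 scans).

What the simulator does *not* model: pulse distortion on reflection,
multiple moving articulators per scene, head-motion compensation,
antenna patterns, skin penetration, or amplitude calibration. Passing
tests therefore demonstrate algorithmic correctness and the pipeline's
behavior under the modeled phenomenology, not performance on human radar
recordings.

## Recognition

Features enter the DTW cost raw (bins and amplitude units unscaled); an
optional z-scaling is deliberately omitted from the default path for
fidelity to the reference formulation, and at the default scene scales
the two columns contribute comparably. DTW uses steps {(1,0),(0,1),(1,1)},
both ends anchored, no window, cost unnormalized by path length.
Classification ties resolve by (distance, label, library index).
Jackknife evaluation is leave-one-out, optionally within speaker groups;
per-class precision is diag/column-sum and recall diag/row-sum (0 and
flagged when the denominator is 0); the F-measure is the harmonic mean of
the *macro-averaged* precision and recall — this convention, rather than
averaging per-class F values, reproduces three-decimal published
summaries of the form P 0.946 / R 0.940 / F 0.943. Reported tables round
half-up to 3 decimals.

## Numerical and scale choices

- Delays are rounded to the nearest bin (half-to-even, the platform
  default); trajectory quantization noise is therefore at most half a bin.
- Conventional CLEAN carries a max_iter safety bound (50) absent from the
  reference description, preventing non-termination on inputs that are
  not template superpositions.
- The DTW inner loop is numba-compiled when numba is importable; a
  vectorized numpy fallback computes the identical recursion.
- Test problem sizes: 2 s sessions (200 scans × 256 bins), 20-repetition
  vocabularies, 20 seeds for the end-to-end study — sizes at which the
  full suite runs in well under a minute while every stage operates at
  the reference sampling geometry (N, T_s, bin size all unchanged).
- Session files store floats at 17 significant digits for lossless
  text round-trips.
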