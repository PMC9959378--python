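# Methods

This note records the models, parameter choices and numerical conventions
behind `baropod`, the points where the design was genuinely open, and what the
simulator does and does not capture about real gait data.

## Calibration

The load→reading map is the rational curve `y = (a·x + b)/(x + c)` with `x` in
grams and `y` in 12-bit ADC counts. The shipped parameter set is
`(3500, −5500, 300)`; any curve must satisfy `c > 0`, `a > 0` and `a·c > b`,
which makes `y` strictly increasing on `x ≥ 0` and bounded by the asymptote
`a`. The inverse `x = (−c·y + b)/(y − a)` is exact algebra, so the
forward/inverse round trip is identity to floating-point precision (tested at
1e−9 relative over (0, 10⁵] g).

Choices that the source material leaves open, resolved here:

* **Raw scaling** — bench rigs report on a 0–65,535 scale; scaling to 12 bits
  uses integer floor division by 16, which is what maps 65,535 onto 4095.
* **Percent mapping** — nothing fixes how an inverted load becomes a percent.
  We map linearly against the sensor's 10 kg manufacturer full scale, clamp to
  [0, 1], and round half-away-from-zero to an integer (the wire carries
  integers). The alternative — linear in the reading — would bake the sensor's
  nonlinearity into the user-facing scale.
* **Saturation** — the inverse is singular at `y = a`; readings at or above
  the asymptote are clamped to `a − 1` counts, which maps to 100%: physical
  saturation, not an error.
* **Fitting** — `scipy.optimize.least_squares` (Levenberg–Marquardt) on the
  plain residuals, initialized at `(max(y), −max(y), median(x))`. The fixed
  initialization makes the fit deterministic; on the packaged six-point bench
  table it converges to a curve whose SSE is below the shipped curve's. At
  least three distinct loads are required (three parameters); a converged
  solution violating `a·c > b` is rejected as a degenerate fit.
* **Dead zone** — loads under the 500 g trigger force are still mapped through
  the curve by the calibration layer; modeling the dead zone is the
  simulator's job, keeping the calibration a pure function.

## Firmware link

* **Gate** — suppress iff `max(values) < 10`: the strict inequality means a
  maximum of exactly 10 transmits. The gate models the firmware's energy
  saving; it is exhaustively tested over all frame maxima.
* **Schedule** — one slot per 150 ms, `floor(duration/period)` slots per
  window; 60 s gives 400. The adequacy check asserts
  `slots(60 s) ≥ 2 × cadence`, satisfied up to exactly 200 steps/min.
* **Wire format** — the source system does not document framing or how the
  two insoles share the air. We use fixed 18-byte frames: header (`0xD0`
  left, `0xD1` right; high nibble doubles as a version mark), 16 payload
  bytes, newline delimiter. Payload codepoint 10 collides with the newline,
  so the delimiter is positional only; resynchronization after corruption
  scans for a header byte, whose codepoints sit above any legal payload.
  Frames deliberately carry no timestamp — the receiver stamps frames on
  arrival, as the phone app does. The emulation keeps arrival times alongside
  the bytes (session bundles store them in `meta.json`).
* **Decoding strictness** — payload bytes 101–255 fit the byte but exceed the
  percent scale; the default decoder clamps them to 100 and records an
  `out_of_range` error, strict mode raises. Truncated trailing frames always
  produce an error record.

## Heatmap

The grid is 10×22 with a foot-shaped mask; 0-based coordinates, x right,
y down, toes at the top. The published system states the grid size, that each
sensor marks two squares, and the eight-neighbor averaging rule — but not the
sensor coordinates, the mask, or the update schedule. Decisions:

* **Canonical layout** — a reconstruction: row-convex foot outline
  (176 footprint cells), 16 sensors in heel (4), midfoot (4), metatarsal (5)
  and toe (3) zones, each as a vertical two-cell pair; fully overridable via
  layout JSON (dimensions, per-row mask runs, seed list).
* **Update scheme** — synchronous (Jacobi) passes: every empty footprint cell
  with at least one valued 8-neighbor simultaneously receives the mean of its
  valued 8-neighbors; repeat until complete. Synchronous updating makes the
  result independent of enumeration order (verified against a brute-force
  per-cell reference implementation).
* **Masked neighbors** are excluded from the denominator, not treated as
  zeros — zeros would artificially darken the footprint boundary.
* **Termination** — each productive pass fills at least one cell, so
  `width·height` passes always suffice and are used as the hard cap. For
  row-convex footprints with overlapping spans (the family this package
  generates) the wavefront reaches every cell within `width + height` passes,
  which the tests assert; a deliberately serpentine mask could legitimately
  need more.
* **Rendering** — footprint percents map linearly onto gray 26–255 so a
  zero-pressure footprint remains distinct from the background (0); PGM is
  plain-text P2, PNG optionally applies a matplotlib colormap. Output bytes
  are deterministic.

## Gait simulator

The simulator emulates the study conditions a desk test needs: a steady
runner on flat ground producing frames the firmware path can chew on.

* **Step clock** — at cadence `f` (both feet, default 180 steps/min — the
  upper end of elite shod running), each foot strikes every `120000/f` ms,
  right offset by half that; feet alternate strictly. Step counts at window
  edges are computed fraction-free to avoid float drift at exact multiples.
* **Stance envelope** — each sensor follows a raised-cosine bump
  `cos²(π(u − p))` over stance fraction `u ∈ [0, 1]`, zero outside half-width
  0.5, with zone-dependent peak phase `p` (heel strike: heel 0.25 → toe 0.85),
  giving heel-to-toe progression; forefoot strike reverses the emphasis.
  Zone amplitudes split the peak total load (`peak_load_factor` × body
  weight, default 2.0 — a typical vertical ground-reaction peak for running)
  so the instantaneous total never exceeds it. Per-step amplitude jitter is
  uniform on [0.92, 1.0], seeded, so repeats differ without breaching the
  peak bound.
* **Dead zone** — per-sensor loads under the 500 g trigger force read as 0.
* **ADC** — `reading = clamp(floor(curve(load) + N(0, σ)), 0, 4095)` with
  σ = `noise_sd_counts` (default 20 counts; a quiet but non-trivial ADC).
  Quantization truncates (floor), the natural ADC behavior; at zero load the
  curve is negative (−18.3 counts) and clamps to 0.
* **Sampling** — frames on the 150 ms transmission clock; a frame is treated
  as instantaneous at its timestamp (the ~14 µs intra-frame ADC skew of the
  real hardware is negligible at this period and not modeled).
* **GPS** — a constant 3 m/s due-north track, one fix per second, from a
  fixed origin; deliberately trivial so GPS analytics have an exact oracle.
* **RNG** — one `numpy` `default_rng` seeded from `SimConfig.random_seed`;
  per-foot noise streams derive from `seed + 1` / `seed + 2`. The seed is
  recorded in session metadata.

What the simulator does **not** capture: biomechanically validated
ground-reaction-force curves, pronation/supination, inter-stride timing
variability, surface and footwear effects, sensor hysteresis and drift, and
Bluetooth loss or latency jitter. Passing recovery tests therefore show that
the *pipeline* is lossless and the *detectors* are correctly wired — not that
the statistics are clinically validated on real gait.

## Analytics

* **Average pressure** — mean over transmitted frames of the per-frame mean of
  the 16 sensor percents. Gated frames are absent by construction; imputing
  zeros for them would make the statistic depend on the gate, which the
  receiving app never sees.
* **Step detection** — an event at each upward crossing of the per-frame
  maximum through `on_threshold` (default 20%), with two refinements: an
  inter-frame gap longer than `refractory_ms` (default 150 ms) resets the
  detector, because the gate removes swing-phase frames entirely and without
  the reset consecutive stances would merge into one crossing; and events
  within the refractory window of the previous accepted event are suppressed.
  Cadence is `events / duration × 60000`. Threshold monotonicity (higher
  threshold ⇒ no more events) holds for pulse-shaped per-step signals —
  which is what stance produces — not for arbitrary waveforms, where any
  crossing detector can split a run in two; the property test uses
  amplitude-varied pulse trains. Defaults recover the default simulator
  profile exactly; both are exposed.
* **GPS** — haversine on a 6,371,000 m sphere; no smoothing by default (an
  optional max-speed outlier filter was considered and left out — the source
  system applies none). GPX 1.1 input is parsed with `lxml` (track points
  with `lat`/`lon`/`time`); CSV input is `t_ms,lat,lon`.
* **Survey** — per-aspect arithmetic means and the grand mean of a
  raters × aspects table on the 1–5 scale, reported to two decimals, half-up
  (`decimal.Decimal` quantization, so 4.58333… prints as 4.58). For
  rectangular tables the grand mean equals the mean of aspect means exactly.

## Problem sizes

Tests and the acceptance script run at desk scale by design: 60-second
sessions (400 slots per foot), 10⁴-point inverse-identity grids, 1000-vector
codec round trips, and 100 randomized layout/vector fills. Each completes in
seconds; the full suite runs in a few seconds on one CPU.

## Known limitations

* The canonical sensor layout is a plausible reconstruction, not the physical
  insole's coordinates; heatmaps are comparable across runs of this package
  but not pixel-comparable to the original system's screens.
* Percent resolution is 1 point; sub-percent pressure differences are
  invisible on the wire by design.
* Step detection assumes one stance per above-threshold burst; shuffling
  gaits that never unload below the threshold would undercount.
* The byte codec has no checksum; corruption inside a frame's payload is
  undetectable unless it hits a header position.
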