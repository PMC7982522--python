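# Methods

## Scope and philosophy

phonosim is a reduced-order forward model of phonation with *prescribed*
vocal-fold motion: there is no tissue elasticity and no fluid–structure
interaction. The glottal flow is a quasi-steady orifice surrogate, and the
3D acoustic field is replaced by source-filter synthesis. These are open
simplifications: the package reproduces the model-defining kinematic and
geometric constants exactly and the aerodynamic/acoustic *orderings*
across configurations, not the absolute flow-field or sound-field values a
resolved turbulent simulation would give.

## Glottis geometry

Each closure type is two numbers: the minimum-opening gap area
A_i0 (mm²) and the closed-length fraction of the fold length
L_VF = 15 mm. The anterior–posterior axis is z ∈ [0, L_VF] with z = 0
anterior; triangular gaps are linear ramps opening toward the posterior
end, rectangular gaps are uniform. Width profiles are sampled at uniform
*cell centres*, so the midpoint-rule integral recovers A_i0 and the
closure boundaries of GC2/GC3 (60 %/30 %) fall exactly between stations at
the default 200 stations.

GC1's 0.5 mm² residual area is represented as a uniform hairline slit
(≈ 0.033 mm wide) over the full length. It exists for numerical
robustness of the downstream flow and is *functionally* closed; the
zero-width closure criterion (default tolerance 1e-9 m) therefore reports
GC1 as fully open unless the tolerance is raised above the slit width,
which the geometry tests do explicitly.

The GC2–GC4 gap areas (2, 5, 10 mm²) are shipped defaults chosen to be
strictly increasing between GC1's floor and GC5's half-maximum gap; no
published areas exist for them, and they are plain config values
(`gap_areas_mm2`) that users can override per closure type.

The baseline maximum GAW area is derived from the motion model rather
than set independently: a half-sine envelope peaking at the maximum
glottal width d_G = 4.66 mm integrates to
A_0max = (2/π)·d_G·L_VF ≈ 44.50 mm². This choice makes "peak width =
4.66 mm" and "peak area = A_0max" simultaneously exact for the baseline
(no-gap) validation configuration.

## Kinematics

The baseline GAW is a smooth parametric pulse: zero on cycle phase
[0.9, 1) ∪ [0, 0.1), a raised-cosine rise to A_0max at phase 0.36 and a
raised-cosine fall back to zero at 0.9. The peak position is the one free
shape parameter (default 0.36, giving speed quotient ≈ 0.48 < 1, i.e.
opening faster than closing); a sampled GAW can be loaded from CSV
instead to reproduce a measured waveform. With 2000 phase samples the
peak lies exactly on the grid.

The per-closure-type modification is the affine map
A_i(t) = A_i0 + (A_0max − A_i0)/A_0max · A_0(t), which pins the minimum
at A_i0 and preserves the maximum.

Wall motion splits the oscillatory area A_i(t) − A_i0 over the two folds
with the half-sine envelope sin(πz/L_VF); each fold's share is scaled by
its amplitude factor ∈ (0, 1]. The integrated width therefore equals
A_i0 + f̄·(A_i(t) − A_i0) with f̄ the mean factor — symmetric (1, 1)
motion reproduces the GAW exactly, and the asymmetric default (1, 0.5)
scales the oscillatory maxima to exactly 75 %. The minimum-gap offset is
deliberately *not* scaled: the gap is a geometric insufficiency, not a
motion amplitude. The reduced factor is assigned to the upper fold by
convention (configurable).

The mucosal wave is a duct-angle schedule, piecewise linear through
(0.1 T, 0°) → (0.21 T, +5°) → (0.32 T, 0°) → (0.61 T, −10°) → (0.9 T, 0°)
and zero during closure. The vertex placement at the interval midpoints
is a design choice; only the interval bounds and the ±extremes are
externally constrained, and the schedule attains both.

Velocities are periodic centred differences of the displacement field
(consistent to O(Δt²); the refinement tests bound the residual).

## Glottal flow surrogate

Q(t) = C_d·A(t)·√(2ΔP/ρ) with ΔP = 775 Pa, ρ = 1.18415 kg/m³ and
default discharge coefficient C_d = 1. Inertance and viscous losses are
omitted; ν is retained for Reynolds-number reporting only. Mean flow is
the phase average (exact trapezoid on the uniform periodic grid).
Resistance is ΔP/Q̄, reported in Pa·s per l/s.

The wall-pressure record is a two-state blend: the Bernoulli static
pressure of the minimal section (equal to the outlet pressure at
C_d = 1), raised toward the inlet pressure in proportion to the positive
(convergent) duct angle. Opening walls thus feel near-subglottal pressure
and closing walls near-ambient pressure, which makes the cycle-integrated
work ∮ Σ p (v·n̂) dS dt positive — the flow drives the tissue — and
monotonically decreasing with insufficiency (the oscillatory amplitude,
hence wall velocity, shrinks by the factor 1 − A_i0/A_0max). The wall
patch area uses a nominal medial-surface contact depth of 3 mm; it is a
pure scale on W_net. Energy magnitudes are surrogate-specific; only
signs and orderings are asserted.

## Acoustic synthesis

The source is the time derivative of the interpolated, tiled flow,
scaled by the free-field monopole factor ρ/(4πr) at the 5 cm reference
microphone. Because this monopole source already *is* the radiation
derivative, the optional +6 dB/octave lip-radiation stage is off by
default (enabling it would double-count the derivative and tilt the
spectrum so that a higher harmonic overtakes the fundamental); it remains
available (`lip_radiation: true`, unity gain at 1 kHz) for source signals
that are volume velocities rather than dQ/dt.

The /a/ vocal tract is a cascade of two Klatt-style two-pole resonators
with unity DC gain, default bandwidths 130 and 160 Hz. Neighbouring
resonators pull each other's magnitude peaks, so the pole frequencies are
iterated at construction until the *cascade's* peaks sit on the formant
targets (1020, 1350 Hz) to better than 1 mHz of drift per iteration
bound; a third formant is not modeled by default. Radiation between
microphones (5 → 8 → 20 cm) is spherical spreading (amplitude ∝ 1/r).

Synthesis runs 10 initialization cycles (discarded, covering the filter
transient) plus 10 analysis cycles at 44.1 kHz.

## Metrics

* **ASD** — Welch, Hann windows of 4 fundamental periods, 50 % overlap
  (resolution f₀/4 ≈ 37 Hz); amplitude = √PSD, Parseval-consistent.
* **SPL** — 20 log10(rms/20 µPa), computed at the 20 cm extrapolated
  signal.
* **VE** — 4πR²·10^((SPL−120)/10) / (P_sub·Q̄) with P_sub the 775 Pa
  driving pressure; reported in percent. Because SPL carries the source
  calibration constant, VE is meaningful only in ratio/trend form.
* **CPP** — per Hann frame, the dB log-magnitude spectrum is inverse
  transformed to a real cepstrum, truncated to the non-redundant first
  half of the quefrency axis (the full cepstrum is circularly symmetric
  and the mirror peak would otherwise tie with the true one); the peak in
  the 60–300 Hz quefrency band is measured against a linear regression
  over 1–15 ms. Defaults: 40 ms windows, 50 % overlap. The pipeline's
  10-cycle analysis segment is only 68 ms long, so `run_case` uses 20 ms
  windows (≈3 periods each, 5 frames) — documented here because it is the
  one place a default differs from the standalone metric. The cepstrum
  normalization (inverse-DFT 1/N convention) gives smaller absolute dB
  values than some published CPP scales; orderings are unaffected.
* **OQ/SQ** — threshold criterion on the area above its minimum (default
  threshold 0). Closure is a *sustained* phase: isolated single samples
  touching the minimum count as open, so a gapless sine has OQ = 1 while
  the baseline GAW with its flat closed segment has OQ ≈ 0.80. SQ is
  opening-time over closing-time between the open-phase endpoints and the
  peak.

## Synthetic data and what passing tests show

All inputs are generated: the geometry, waveforms and flows come from the
parametric models above, and metric tests use seeded fixtures
(sine, pulse train, white noise, harmonic-plus-noise). The generator
emulates periodic, noiseless, perfectly stationary phonation; it does not
emulate turbulence, cycle-to-cycle jitter, supraglottal vortex sound or
tissue compliance. Consequently CPP is *identical* across the ten default
cases (all their radiated signals are exact affine relatives), and the
asymmetric-CPP trend holds as equality; on real or turbulent signals CPP
separates cases, which the SNR-sweep fixtures demonstrate. Passing tests
establish the correctness of the implemented formulas and the directional
physics of the reduced-order chain, not fidelity to any resolved
flow-field quantity.

## Numerical choices and degenerate inputs

2000 phase samples/cycle, 200 stations, 44.1 kHz audio; these put every
discretization error bound well inside the asserted tolerances (GAW
integral < 1 %, W_net phase-halving drift < 0.5 %, width peak within
5 µm of 4.66 mm) while the full ten-case study runs in under a second.
Closed glottis ⇒ zero flow and undefined resistance (raised); all-zero
signals ⇒ undefined SPL (raised); constant GAW ⇒ undefined quotients
(raised); a missing cepstral peak returns the band maximum flagged
low-confidence instead of failing.

## Known limitations

* No fluid–structure coupling; the motion cannot respond to pressure.
* Quasi-steady flow: no inertance, no skewing of Q(t) relative to A(t),
  no turbulence → no breathiness noise floor, hence the degenerate CPP
  equality noted above.
* The printed resistances/energies of resolved 3D simulations are not
  recovered in magnitude — the surrogate's driving pressure and wall
  model differ by construction; trends are the deliverable.
* OQ measured from the area criterion is 0.80 by construction of the
  closure interval; measurement conventions that use a higher threshold
  on noisy imaging data report higher OQ values, so absolute OQ is not
  comparable across conventions.
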