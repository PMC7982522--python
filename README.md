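# phonosim

A desk-scale, prescribed-motion phonation simulator for studying how
**glottal insufficiency** (incomplete vocal-fold closure) and **left–right
asymmetric vocal-fold vibration** degrade the aerodynamics and acoustics of
voice production.

It is aimed at voice scientists and students who want a fast, fully
transparent forward model of disordered phonation: every stage — glottis
geometry, fold kinematics, glottal flow, sound synthesis, voice-quality
metrics — is an explicit, inspectable reduced-order model that runs in
well under a second per configuration on a laptop.

## The model

**Closure geometry.** Five glottal-closure types parameterize increasing
insufficiency by two numbers, the *initial (minimum-opening) gap area*
A<sub>i0</sub> and the *closed-length fraction* of the vocal-fold length
L<sub>VF</sub> = 15 mm:

| type | closed length | gap shape | A<sub>i0</sub> (mm²) |
|------|--------------|-----------|----------------------|
| GC1  | 100 %        | hairline slit (stability floor) | 0.5 |
| GC2  | 60 %         | triangular, posterior | 2 |
| GC3  | 30 %         | triangular, posterior | 5 |
| GC4  | 0 %          | triangular, posterior | 10 |
| GC5  | 0 %          | rectangular | ½ A<sub>0max</sub> ≈ 22.2 |

**Kinematics.** A baseline glottal area waveform A₀(t) (closed on
[0.9 T, 0.1 T], skewed raised-cosine peak, f₀ = 148 Hz) is remapped per
closure type without changing its maximum,

&nbsp;&nbsp;&nbsp;&nbsp;A<sub>i</sub>(t) = A<sub>i0</sub> + (A<sub>0max</sub> − A<sub>i0</sub>)/A<sub>0max</sub> · A₀(t),

and realized as wall motion with a half-sine anterior–posterior envelope
(peak total width 4.66 mm) plus a convergent/divergent duct-angle schedule
(0°→+5° while opening, −10°→0° while closing) emulating the mucosal wave.
Reducing one fold's amplitude to 50 % (the asymmetric cases) scales the
GAW oscillatory maxima to exactly 75 % of the symmetric ones.

**Flow and acoustics.** A quasi-steady Bernoulli orifice gives
Q(t) = C<sub>d</sub> A(t) √(2ΔP/ρ) under ΔP = 775 Pa; the radiated sound
is source-filter synthesis — a dQ/dt monopole source shaped by an /a/
vocal-tract resonator cascade (F1 = 1020 Hz, F2 = 1350 Hz) with spherical
spreading to virtual microphones at 5, 8 and 20 cm.

**Metrics.** Mean flow Q̄, glottal resistance ΔP/Q̄, net flow-to-tissue
work W<sub>net</sub> = ∮ Σ p·(v·n̂) dS dt, SPL re 20 µPa, vocal efficiency
VE = 4πR²·10<sup>(SPL−120)/10</sup> / (P<sub>sub</sub> Q̄), Hillenbrand-style
cepstral peak prominence, formants, and the open/speed quotients.

Absolute sound levels depend on a single source-calibration constant —
**only SPL/VE differences and trends between configurations are
meaningful**, as are the energy-transfer magnitudes of the surrogate flow.

## Worked example

```python
import phonosim as ps

for symmetric in (True, False):
    r = ps.run_case(ps.CaseSpec("GC2", symmetric=symmetric))
    print(r.case_label, f"Q={r.q_mean_l_s:.3f} l/s  R={r.r_glottis:.0f} Pa·s/l  "
          f"W={r.w_net_j*1e6:.1f} µJ  SPL={r.spl_db:.1f} dB  f0={r.f0_detected_hz:.1f} Hz")
```

prints

```
GC2-sym Q=0.687 l/s  R=1127 Pa·s/l  W=54.9 µJ  SPL=85.2 dB  f0=148.0 Hz
GC2-asym Q=0.534 l/s  R=1452 Pa·s/l  W=41.2 µJ  SPL=82.7 dB  f0=148.0 Hz
```

The asymmetric GC2 case moves less air (its GAW maxima are at 75 % of the
symmetric ones), so the glottal resistance rises while the energy the flow
feeds into the folds and the radiated level both drop — the characteristic
signature of asymmetric vibration. Running all ten cases
(`ps.run_study()`) additionally evaluates the directional trends: mean
flow rises and net energy transfer, SPL and vocal efficiency fall
monotonically from GC1 to GC5, with asymmetry compounding each deficit.

The same chain is scriptable from a shell:

```bash
phonosim run --all --out-dir out/        # 10 cases: WAV + CSV + JSON report
phonosim geometry --gc GC2 --out profile.csv
phonosim gaw --gc GC3 --asym 0.5 --out gaw.csv
phonosim synth --case GC1-sym --mic 8cm --wav gc1.wav
phonosim metrics gc1.wav --mic-distance 0.08
```

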