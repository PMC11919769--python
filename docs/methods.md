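# Methods

This note records the model assumptions, parameter choices and numerical
decisions behind `photopore`, and what the synthetic-data generator does and
does not emulate.

## Two-state photoswitch kinetics

Each arylazopyrazole switch is modelled as a two-state (E/Z) system.
Isomerization rates are strictly linear in irradiance — the simplest model
consistent with the observed proportionality between switching rate and
light intensity — with no saturation term. Under a light field with sources
(λ, Q):

    k_EZ = Σ σ_EZ(λ)·Q_λ,     k_ZE = Σ σ_ZE(λ)·Q_λ + k_thermal

The photostationary state `p_Z = k_EZ/(k_EZ+k_ZE)` is therefore
intensity-invariant for a single wavelength, and dual-wavelength mixing
moves `p_Z` monotonically between the two pure-wavelength values — the basis
of graded current levels and the 3-symbol messaging alphabet.

Wavelengths are matched by exact integer nm key; no spectral-bandwidth model
is included (narrowband filtering of the LEDs was reported to have little
effect on gating).

**Parameters (pzMe defaults).** PSS Z fractions: 0.96 at 365 nm, 0.07 at
530 nm (measured); 0.70 at 405 nm and 0.45 at 455 nm (not measured —
configuration values chosen so the four wavelengths produce ordered
intermediate currents; flagged as non-measured defaults). Thermal Z→E
relaxation is zero (stable for over an hour in the dark). The `pzH` and
`fAzo` presets store their measured PSS values verbatim, including pzH's
inverted wavelength→isomer pattern (65% E at 365 nm, 85% Z at 530 nm).

**Rate calibration.** The absolute scale of σ comes from the pore's
switching times: the time for all 7 independent switches to flip once is the
expected maximum of 7 i.i.d. exponential waiting times, `H₇/k` with
`H₇ ≈ 2.593`. Matching 1.8 s at 36.2 mW cm⁻² (365 nm) gives
σ_EZ(365) ≈ 0.0398 s⁻¹/(mW cm⁻²); matching 31.4 s at 30.3 mW cm⁻² (530 nm)
gives σ_ZE(530) ≈ 2.7·10⁻³. The strong UV/green asymmetry is absorbed
entirely into these unequal cross-sections. At 405/455 nm, where no
absolute rate is printed, the total cross-section per unit irradiance is
log-linearly interpolated in wavelength between the two calibrated anchors —
a smooth, order-preserving choice made once; only the PSS values (ratios)
matter for equilibrium levels, the interpolation affects kinetics alone.
An alternative response-time mapping (time to 90% of the mean-current span)
is available through `analysis.response_time`.

## Pore conductance

A pore configuration is the ordered 7-tuple of switch states; compositions
are `(n_E, n_Z)` with rotational arrangements counted as binary necklaces
under C₇ (no reflections; two Z switches among seven subunits → 3
arrangements, 20 classes in total).

The default configuration→conductance map is linear in `n_Z`
(`fraction = n_Z/7`): with only the end-state conductances printed, the
one-switch step size is taken uniform. Arrangement-dependent conductances
(distinct level per necklace class) would be needed to reproduce the finer
sublevel structure (more than ten distinguishable levels) seen in real
recordings, but no per-class values exist to anchor them, so the model does
not include them.

Branch I–V curves (per pore, defaults):

* ON branch: slope 0.64 nS at positive potentials (the +64 pA/pore at
  +100 mV ensemble-counting convention), ×0.58/0.46 at negative potentials
  (the measured weak rectification of the resistor state).
* OFF branch: 0.32 nS ohmic at negative potentials. At positive potentials
  a saturating leak `i_sat·tanh(V/30 mV)` anchored so the fully-OFF current
  at +100 mV is exactly `g_off_fraction` (default 0.05, calibrated from the
  95% single-channel gating) of the fully-ON current. The saturating shape
  is the simplest smooth curve through the printed anchors that also makes
  the rectification ratio grow roughly linearly with voltage up to
  ±150 mV, as observed; with purely linear branches the ratio would be
  voltage-independent.
* Mixed configurations interpolate linearly between branch currents with
  weight `n_Z/7`. Whether intermediate configurations rectify has not been
  characterized; linear mixing is an explicit assumption. Voltage
  dependence acts at the whole-pore level, not per switch.

Per-pore heterogeneity is a truncated normal over ON conductance
(mean 0.62, s.d. 0.30, bounds 0.12–1.27 nS — the measured spread); both
branches scale together per pore.

**NAND classification.** The four (wavelength, polarity) current magnitudes
at the two photostationary states are 78.7, 61.6, 35.4 and 7.5 pA/pore with
the defaults. The high/low threshold is placed in the largest gap of the
sorted magnitudes (between 7.5 and 35.4), which isolates the single low
output at (530 nm, +100 mV). A midpoint-of-extremes threshold (43.1 pA)
would misclassify the conducting (530 nm, −100 mV) input and was rejected.

## Trace synthesis

Switch dynamics are simulated exactly: within each constant-light interval
every switch draws exponential waiting times with its state-dependent
leaving rate; waiting times are redrawn at interval boundaries
(memorylessness makes this exact for piecewise-constant rates). The sampled
current is

    I(t) = Σ_p s_p·[i_off(V) + (n_Z,p/7)(i_on(V) − i_off(V))]
           + C·dV/dt + noise + drift

* **Capacitive current**: included analytically for the sinusoidal
  waveform; step/ramp edges are treated as amplifier-compensated (zero),
  as a capacitance-compensated patch-clamp amplifier would display.
  The default 100 pF is a typical planar-bilayer value; at 0.03 Hz it
  contributes ~1.9 pA — negligible against the resistive currents, so the
  slow AC rectification is clean, while at a few Hz it visibly erodes it.
* **Noise**: additive white Gaussian, specified as the s.d. *after* the
  20 Hz digital Bessel stage (default 0.3% of the fully-ON full-scale
  current — the dark-trace fluctuation of the recording chain). The raw
  s.d. is back-computed from the filter's numerically integrated
  equivalent-noise-bandwidth fraction, so the filtered trace lands on the
  specified level at any sampling rate.
* **Asymmetric salt**: a constant emf offset added to the applied
  potential; 59 mV for the 0.2/2 M KCl decade (Nernstian, activity
  coefficients ignored — a stated simplification).
* **Sampling**: 25 kHz by default (the digitization rate); simulations
  that carry no kilohertz content (message transmission, AC at millihertz)
  are generated at 0.2–1 kHz, and long analyses decimate to 1 kHz after
  anti-alias filtering.

The generator emulates: stochastic stepwise switching, PSS equilibria and
their intensity invariance, diode/resistor I–V behaviour, recording noise,
drift, capacitive current, and the filter chain. It does **not** emulate:
electrode electrochemistry, bilayer rupture or pore insertion (pore count
fixed per run), open-pore flicker/1-f noise, arrangement-dependent
sublevels, or any voltage dependence of the switching rates themselves.
Passing tests therefore validate the model's internal consistency and the
analysis pipeline's correctness, not these unmodelled features of real
recordings.

## Filters

Digital Bessel filters are bilinear transforms of the 4-pole analog
prototype with magnitude (−3 dB) normalization, applied causally — the
instrument filter is causal — with DC gain renormalized to exactly 1. The
order of the 20 Hz digital Bessel stage is not documented for the recording
chain being emulated; 4 poles (like the in-line filter) is the default and
is exposed in
`FilterSpec`. Savitzky–Golay smoothing uses polynomial order 1 over a
400 ms window by default. Decimation low-passes before down-sampling.

## Level estimation and gating

Two estimators are deliberately distinct:

* **Ensemble gating** averages the equilibrium window (final 20% of a light
  segment). At PSS the ensemble mean reflects the full binomial mixture of
  configurations, so ensemble I_gate% (≈88% with the defaults) sits below
  the single-channel value — partially-ON pores raise I_OFF.
* **Single-channel gating** reads the extreme sustained plateau (1 s
  rolling-mean extremum over the settled half of each segment, extreme
  across segments): a single pore at PSS dwells mostly in the extreme
  configuration with excursions to neighbours, and the printed
  single-channel gating is the fully-OFF/fully-ON plateau ratio, not the
  time average. The settled window is half the segment (wider than the
  ensemble window) because the pore must *visit* the extreme configuration:
  fully-OFF dwells under green light last tens of seconds. Green phases in
  the gating protocols run 120 s (~4 switching time constants) for the same
  reason.

`detect_steps` uses binary segmentation on the Savitzky–Golay-smoothed
trace with a BIC stopping rule, a minimum dwell (50 ms default) and a
minimum amplitude of 6× a robust noise scale estimated from lagged
differences (lag > smoothing window, so correlated smoothed noise does not
deflate the estimate). These are method choices of this package; no particular changepoint
procedure is prescribed by the measurements being emulated.

`response_time` is threshold-based by default (90% of the level span,
measured on a lightly smoothed trace from light onset); an exponential-fit
variant is provided since the operational definition behind the reported
times is unstated.

`level_capacity` reports range/fluctuation raw and rounded to one
significant figure (283 → ~300 for an 85% range and ±0.3% fluctuation).

## Messaging

Bit synchronization and the symbol→level key are assumed shared between
transmitter and receiver (no clock recovery). Each bit's level is the mean
over the final 50% of its window, skipping the switching transient — the
20 s bit was chosen so equilibrium is reached (the slowest default symbol,
455 nm at 56.3 mW cm⁻², equilibrates with τ ≈ 1.8 s). Morse gaps are
scheduled as dedicated 0-symbols (one between letters, three between
words); this convention is this package's own, as no gap convention is implied
by the reported transmissions. Decoding is invariant to uniform current rescaling when the
calibration levels are scaled consistently; ambiguous bits (two nearest
levels within 2% of the level span) are flagged as erasures. Faster bits at
higher irradiance are supported by scaling the schedule (`scaled_irradiance`),
reproducing the rate–intensity link qualitatively.

## Problem sizes

Defaults used by the test suite and the acceptance script: ensembles of
600 pores with 10 replicates for PSS-reduction statistics; 10 seeded
single-pore recordings of two 135 s UV/green cycles at 25 kHz for gating
recovery; 10⁴–2·10⁴ pores for census goodness-of-fit; 25–40 seeded runs for
response-time and plateau statistics. These sizes put Monte-Carlo error
well inside the tolerances asserted, with desk-scale runtimes.

## Known limitations

* The linear `n_Z/7` map ignores arrangement (necklace-class) effects on
  conductance, which the fine sublevel structure of real recordings
  suggests exist.
* Diode-mode mixing of intermediate configurations is an assumption.
* Asymmetric-salt driving is reduced to a constant emf offset.
* The mechanistic origin of the voltage-dependent (diode) behaviour is not
  modelled; branch I–V curves are empirical anchors.
* The reported switching times are assigned operationally: 1.8 s to the
  365 nm transition and 31.4 s to the 530 nm transition, consistent with
  the irradiance-series kinetics.
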