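# Methods

This note documents the models implemented in `cryonano`, their
assumptions, the defaults and why, and what the synthetic generators do
and do not emulate.

## Ice thickness from zero-loss imaging

Energy-filtered TEM measures thickness through inelastic scattering: a
slab of thickness `t` and inelastic mean free path (IMFP) `λ` attenuates
the zero-loss (elastically scattered) signal by `I0/I = exp(−t/λ)`.  Two
quantities are derived per pixel:

- `WET = λ_ice · ln(I/I0)` — the thickness of vitreous ice that would
  produce the observed attenuation (includes the membranes);
- `IT = WET − λ_ice · ln(1/r)` — the ice thickness after removing the
  membranes' contribution, with `r` the zero-loss ratio measured on bare
  membrane adjacent to the channel.

The membrane term is expressed in water-equivalent form so that `IT ≈ 0`
on bare membrane by construction; with the defaults it is
`320 · ln(1/0.89) ≈ 37.3 nm`.  The SiNx IMFP is calibrated from the bare
membrane ratio and the geometric film thickness known from ellipsometry,
`λ_SiNx = t_known / ln(1/r) = 19 / ln(1/0.89) ≈ 163 nm` at 300 kV.  The
ice IMFP default of 320 nm is a 300 kV literature value; both are plain
config fields for other voltages.

Assumptions and limits: single-scattering log-ratio model only — no
plural-scattering or collection-angle corrections; alignment of the image
pair is integer-pixel cross-correlation (the thickness maps are acquired
at coarse 4.7–73 Å/pixel samplings where sub-pixel refinement buys
nothing).  Pixels with `I0 > I` are clamped to zero rather than masked so
cross-section profiles stay defined; every clamp is counted and logged.

Cross-section profiles average five stripes per observation window along
the channel axis (configurable), and offsets are centered on a detected
midline.  Because a sagged channel is ~0 nm thick both at its center and
on the bare membrane outside, the midline is found as the midpoint
between the outermost above-half-max bands of the mean profile (the two
walls), which also handles rectangular channels where the single lumen
band is its own midline.

## Channel geometry and volumes

The top membrane sags onto the flat bottom membrane, touching at the
channel centerline: `t(x) = H·(2x/w)²`, zero at the center and `H` at the
walls.  This is the convention consistent with both the measured
cross-sections and the quoted aggregate volume: integrating the parabola
gives a per-channel volume of `L·w·H/3`, i.e. 1.25 fL for a 50 µm × 750 nm
× 100 nm channel and 6.25 fL for five.  Microchannels are plain boxes
(default 1 mm × 4 µm × 0.4 µm = 1.6 pL).  A `nearest_pL` rounding mode
reproduces the convention of quoting microchannel volumes to the nearest
picoliter before summing (2 + 2 + 0.006 ≈ 4 pL); the unrounded total is
3.206 pL.  Units are fixed: nm for transverse dimensions, µm for channel
lengths, fL/pL for volumes, and public names carry their units.

Device-to-device width variation (650–1000 nm) is parameterized but not
modelled; defaults use 750 nm.  No membrane elasticity or fabrication
tolerance modelling.

## Washburn filling kinetics

Capillary imbibition follows `x(t) = a·√(t−b) + c`.  The model is linear
in `(a, c)` once `b` is fixed, so the fit profiles `b` out: a 256-point
coarse grid over plausible time origins followed by a bounded scalar
minimization of the profiled residual, then a joint `curve_fit` polish.
This avoids the poor local minima a naive 3-parameter Levenberg–Marquardt
run falls into from secant initial guesses (the square-root branch has a
singular Jacobian in `b` at `t = b`).  Points with `t < b` contribute
through the clipped radical (they predict `x = c`) and are counted.

Uncertainties come from case-resampling bootstrap: 100 refits (default) of
n-out-of-n resampled (time, position) pairs, reported as means and
standard deviations, seeded and reproducible.  More than 20% failed refits
raises an error rather than returning optimistic statistics.  The
linearised diagnostic regresses `(x−c)²` on `t`; its slope equals `a²`
(displayed in 10⁶ µm²/s) and its intercept `−a²·b`.

Meniscus tracking defaults to a half-max edge: the threshold is the
midpoint of the 5th/95th intensity percentiles and the front is the extent
of the filled region growing from the channel entrance.  Frames without a
crossing (front not yet in view, or channel already full) are dropped with
a warning.  Manual picking is supported by passing a CSV trace directly.
No fluid-dynamic derivation of `a` from contact angle/viscosity is
attempted; the law is fitted empirically.

## Plunge cooling

The chip plunging into liquid ethane is modelled as external forced
convection over a flat plate: `Re = ρvL/µ`, `Pr = c_p·µ/k`,
`Nu = 0.664·Re^½·Pr^⅓`, `h = Nu·k/L`.  With ethane properties near
90–100 K (ρ = 650 kg/m³, µ = 1.2×10⁻³ Pa·s, k = 0.25 W/(m·K),
c_p = 2300 J/(kg·K)), a 1.5 m/s plunge over a 2 mm plate gives
`h ≈ 7.45×10³ W/(m²·K)`.  Tabulated cryogenic ethane properties vary
between sources; the conclusion (cooling below Tg in ≪ 10⁻⁵ s) is robust
to ±50% property variation.  The correlation warns above `Re = 5×10⁵`
where the laminar assumption fails.

Two thermal models share this `h`:

- **Lumped capacitance** for a thin layer cooled on `sides ∈ {1,2}`
  faces: `τ = ρ·c_p·d/(sides·h)`, `t(Tg) = τ·ln((T0−T∞)/(Tg−T∞))`.  For
  the 20 nm SiN membrane the Biot number is ~6×10⁻⁵, so the lumped
  assumption is excellent; a warning fires above Bi = 0.1.  With defaults
  (T0 = 293.15 K, Tg = 136 K, T∞ = 90 K) the membrane crosses Tg at
  ~4.3 µs.
- **1D finite differences** along the observation membrane:
  thickness-integrated in-plane conduction with a two-sided convective
  sink, `ρ·c_p·d·∂T/∂t = ∂x(k·d·∂x T) − 2h(T−T∞)`, default layup a 50 µm
  SiN membrane 20 nm thick flanked by 975 µm of 100 µm silicon base per
  side, insulated (symmetry) ends.  Backward-Euler stepping with
  harmonic-mean face conductances is unconditionally stable under the
  5000:1 thickness contrast; the default step resolves the fastest lumped
  time constant 100-fold, keeping the first-order time-discretisation
  error in the Tg crossing below ~1%.  The crossing time is interpolated
  linearly between steps.  In the uniform low-conductivity limit the FD
  solution collapses onto the lumped law at every node.

Tg defaults to 136 K (amorphous-water glass transition).  Out of scope by
construction: plunging hydrodynamics, boiling/Leidenfrost films, latent
heat, and 2D/3D conjugate transfer.

## Cryo-EM quality statistics

- **Vitreous fraction**: `100·n_kept/n_total`, displayed as integer
  percent, with a Wilson 95% interval (statsmodels).  The vitreous/icy
  classification itself is manual and enters as counts.
- **On-chip concentration**: `molar = n/(N_A·V)` with `V` in liters
  (1 nm³ = 10⁻²⁴ L, the single conversion constant in the package), mass
  concentration multiplies by the molecular weight, and the fold increase
  divides by the applied concentration.  Full-precision values are kept
  alongside 3-significant-figure display values so both can be pinned.
- **B-factor**: ordinary least squares of `1/d²` on `ln n`; `B = 2/slope`.
  A non-positive slope flags the result (`B = NaN`) instead of raising,
  since noisy small tables can legitimately produce one.  Multiple tables
  from independent reconstruction runs are averaged row-wise before
  fitting.
- **Motion RMSD**: whole-frame (global) alignment trajectories only;
  displacement is measured from each movie's position at the start of the
  exposure range and the RMS is taken across movies per frame.  Grouping
  by chip or beam-image-shift position summarises each group by the
  circular mean of net-displacement angles and the circular dispersion
  `1 − R` (0 by convention for single-movie groups).

## Synthetic data

Generators are pure functions of their parameters and a seed; each draws
from a stream keyed by (seed, generator name) so adding a generator never
perturbs another's output.

- **EFTEM pairs**: attenuation
  `I0/I = exp(−(t_ice(x)/λ_ice + t_SiN/λ_SiN))` over a vertical sagged
  channel, Poisson count noise (the physically appropriate model for
  direct-detector counts), optional injected integer shift.  The default
  grid (129 columns at 75 Å/pixel) places one pixel exactly on the
  centerline and one on each wall so noiseless round trips are exact at
  pixel centers.  Default dose 4000 counts/pixel, typical of the
  low-magnification thickness maps this emulates.
- **Kymographs**: a step edge at the Washburn front, filled side dark,
  10 fps and 1.6 µm/pixel as in the optical filling movies, Gaussian read
  noise.
- **ResLog tables**: rows drawn from `1/d² = (2/B)·ln n + c0`; default
  B = 178 Å² is a realistic single-particle value.
- **Trajectories**: per-cluster drift directions 120° apart (one per
  beam-shift position), exponentially decaying step sizes (fast early
  motion), net path normalised to a target (default 5.1 Å over
  40 e⁻/Å²), round-robin chip labels.

What they do *not* emulate: contrast transfer, multislice scattering,
detector MTF, radiation damage, stage drift or any spatial correlation of
noise.  Passing round-trip tests therefore demonstrates correctness of
the estimators under the stated statistical models, not robustness to
every instrument artifact in real data.

## Problem sizes

The test suite and reproduction script run at desk scale by choice:
64×129-pixel image pairs, 20-frame kymographs, 100-bootstrap fits,
500-seed bias checks, and ≤201-node finite-difference grids.  Each
quantity is either closed-form or converges at these sizes (the FD grid
test doubles resolution to confirm < 2% movement in the Tg crossing).

## Known limitations

- Integer-pixel alignment only; maps with sub-pixel drift blur the
  profile by up to half a pixel.
- The log-ratio thickness model saturates for very thick ice (multiple
  scattering) and is biased at very low dose even after clamping.
- The flat-plate correlation ignores the plunge transient and assumes the
  chip is instantly wetted; measured vitrification rates can be lower
  than the model's prediction for reasons outside its scope (trapped air,
  cryogen displacement).
- Circular dispersion is a descriptive statistic; no significance test
  for directional clustering is provided.
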