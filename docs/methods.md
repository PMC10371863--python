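# Methods

## Scope and model

`txas` covers the computational chain between *per-frame electronic-structure
output* (orbital energies and transition dipoles of core-to-valence
excitations along ionized molecular-dynamics trajectories) and *published
observables* (transient absorption maps, band amplitudes, timescales,
hydrogen-bond statistics). It does not compute electronic structure or run
dynamics; transition tables are its upstream interface.

### Cross-section synthesis

For one transition from core orbital φ_i (energy ε_i) to a valence vacancy
φ_f (energy ε_f), the photoabsorption cross-section in atomic units is

    σ(ω) = (4/3) π² ω α δ(ε_f − ε_i − ω) |⟨φ_f|d̂|φ_i⟩|²

with α the fine-structure constant. The squared transition dipole is the full
squared vector norm; the 1/3 isotropic orientation average is folded into the
4/3 prefactor (the standard isotropic formula, as opposed to 4π² with an
explicit 1/3). The line-shape function δ is replaced by a unit-area Lorentzian
of 0.5 eV FWHM (natural core-hole width plus spectrometer resolution); we read
the conventionally quoted "width" as FWHM — it is a parameter
(`LineShapeParams.lorentz_width`) if HWHM is preferred. Lorentzians are
evaluated analytically over the entire grid; no truncation radius.

Per time step, spectra are averaged over all trajectories of the ensemble
(all trajectories must share one time grid; ragged grids are rejected rather
than silently resampled). The delay axis is then convolved with a unit-area
Gaussian of 10 fs FWHM for the finite experimental time resolution;
edge handling is nearest-value padding, which preserves a constant map exactly
and interior signal area to better than 0.1 %.

Energies: transition tables are hartree, spectra/maps are eV; the single
conversion constant (27.211386 eV/hartree) lives in `txas.constants`.

### Energy calibration

Orbital-energy differences miss core-hole relaxation, so calculated spectra
are shifted **down** by `calc_core_binding − exp_core_ip`
(310.21 − 294.51 = 15.7 eV with the defaults). The experimental core IP itself
carries a reference correction: an IP measured against a reference level that
was later re-measured shifts by the same amount
(294.0 + (11.67 − 11.16) = 294.51 eV). A further **up**shift of 3.2 eV absorbs
the aqueous environment's effect on the valence binding energy, consistent
with the bookkeeping valence IP = core IP − resonance energy
(294.51 − 287.6 = 6.91 ≈ 6.9 eV), about 3.4 eV below the 10.28 eV gas-phase
value. `apply_calibration` translates the energy axis by
`−downshift + upshift` and never touches the values.

### ΔOD

ΔOD(t, ω) = −log₁₀(I_pump/I_unpump) on strictly positive intensities. When
intensities are modelled from cross-sections assuming full conversion, a free
`excited_fraction` rescales ΔOD; the actual ionization fraction of the
experiment is not known quantitatively, so this stays a free scaling
parameter.

## Band decomposition and kinetics

The transient map in the proton-transfer window (≈ 285.5–288.5 eV) is fitted
globally by three Gaussians (two pre-transfer bands near 286.7 and 287.3 eV,
one post-transfer band near 287.6 eV) with **shared centers and widths across
all delays** and free nonnegative per-delay amplitudes. Implementation:
variable projection — an outer trust-region least squares over the six shape
parameters (widths in log scale, both bounded by the window), an inner NNLS
per delay; five seed-jittered starts guard against local minima. Widths are
always fitted, never assumed: only the centers are known from the data.
Degenerate inputs: an identically zero map returns zero amplitudes with the
caller's shape parameters untouched.

The NNLS floor at zero makes the error of near-zero amplitudes one-sided
(half-normal), which biases downstream exponential fits and makes their
covariance optimistic. The fitted model therefore carries both the constrained
amplitudes (the model proper) and unconstrained least-squares traces
(`amplitudes_free`) whose errors are Gaussian; kinetic fits should use the
free traces, with the per-band standard errors propagated from the linear
stage (`amplitude_ses`, from σ²_pixel (GᵀG)⁻¹).

Amplitude traces are reduced with:

- **Exponential kinetics**: `baseline + A·exp(−t/τ)` or
  `baseline + A·(1 − exp(−t/τ))`, starting at t = 0, convolved with a Gaussian
  IRF. The convolution uses the closed-form exponentially-modified Gaussian,
  evaluated piecewise with `erfcx` for numerical stability; generator and
  fitter share this kernel, which is what makes zero-noise closure exact.
  Whether experimental decay fits included IRF convolution is not knowable
  here, so `irf_fwhm` is an explicit argument (0 disables it).
- **Sigmoidal half-rise**: a logistic with free asymptotes; the reported t½ is
  the time at the midpoint of the asymptotes, which the logistic gives in
  closed form (an erf-shaped alternative could be swapped in; the choice of
  form is a convention, both are "sigmoidal fits"). Traces must bracket the
  transition: fits whose midpoint lands within two logistic widths of a window
  edge are rejected with a window-extension hint instead of returning an
  extrapolated t½.
- **Erf 10–90 rise** (temporal resolution): `b + (A/2)(1 + erf((t−t₀)/σ√2))`;
  the reported rise is 2·z₀.₉·σ = 2.5631·σ, with z₀.₉ = 1.28155 the
  standard-normal 90 % quantile. Equivalently 1.0885 × the Gaussian FWHM.
- **Sequence check**: each band's time of crossing half its extremal
  amplitude (falling for decaying bands, rising for the growing band, linear
  interpolation between samples), plus a boolean for the first-band-decays →
  second-band-decays → third-band-rises ordering. Bands with an amplitude
  range below 5 % of the largest band are excluded with a notice; crossings
  closer than half a delay step are ties and make the ordering indeterminate.
  Whether a band is "rising" is decided from its late plateau relative to its
  full range, not from endpoint-vs-endpoint comparison, which noise flips for
  decay bands that start and end near zero.

All uncertainties are 1 s.e. from the fit covariance; ± values are reported
with the same convention.

## Hydrogen bonds

A donor–H···acceptor triple is a hydrogen bond when the donor–acceptor
distance is ≤ 3 Å and the hydrogen donor–acceptor angle is ≤ 20°. The phrase
"hydrogen donor–acceptor angle" is ambiguous; we take the angle **at the
donor** between donor→H and donor→acceptor (the common MD-tool convention for
a 20–30° cut). The alternative — deviation of the D–H···A angle at the
hydrogen from linearity — is selectable (`angle_at="hydrogen"`). Donors are
N/O with a covalently bound H, acceptors N/O of a *different* molecule;
connectivity and molecule partitioning come from a 1.2× covalent-radius
cutoff, so no topology file is needed.

Urea amine hydrogens: per NH₂ group, the hydrogen through-space nearer the
molecule's own carbonyl oxygen is *proximal* (cis to C=O), the other *distal*
— equivalent to cis/trans about the C–N bond for planar urea and robust to
mild pyramidalization. A deprotonated nitrogen (single H, post-transfer) is
classified by the O–C–N–H dihedral instead, since there is no partner to
compare against.

Formation kinetics: the waiting time of a candidate pair is the delay from the
series start to the first frame with a proximal-H bond present;
already-bonded-at-start and never-bonded (censored) series are counted
separately. The waiting-time distribution is fitted as
`w·Exp(τ_fast) + (1−w)·Exp(τ_slow)` by direct maximum likelihood on the times
(no histogram binning — bin choices would be an undocumented degree of
freedom). Standard errors come from the observed information
(finite-difference Hessian in (log τ_fast, log τ_slow, logit w), delta method
back). The two constants are read as one mixture (fast local fluctuations,
slow diffusion-limited channel); a collapsed fit (τ ratio < 2, or weight
within 0.05 of a boundary) is flagged rather than silently returned.

## Synthetic generators: what they emulate, and what a green test shows

`EnsembleConfig` states the world the tests run in: trajectories on a uniform
0.5 fs grid over 1 ps (the typical propagation length of the ionized-dynamics
simulations); a configurable proton-transfer fraction (default 0.07,
the HOMO-ionized dimer value); logistic growth of |d|² with a 134 fs half-rise
and of the transition energy (base 286.4 eV) by 1.2 eV with a 107 fs
half-rise (the ensemble-level values); a superposed vibrational oscillation;
Gaussian relative noise. Defaults chosen where no value is stated:

- `sigmoid_rise_width` (logistic 10–90 width) = 150 fs, read off the visual
  rise of the published cross-section curves; the half-rise time fixes only
  the midpoint, so a slope parameter is unavoidable.
- `vib_period` = 20 fs: the oscillation period underlying the "rapid
  oscillations" is not reported; 20 fs is the order of a C=O stretch and is
  flagged as arbitrary.
- `vib_amp` = 0.05 eV, a weak ripple relative to the 1.2 eV shift.
- pre-transfer |d|² = 10 % of the asymptote: non-transferring systems show a
  weak, nearly time-independent feature, not zero.
- PT-onset jitter: uniform over a 50 fs window, **centred** on the nominal
  midpoints. Centring matters: an uncentred 0–50 fs jitter would bias every
  ensemble half-rise by +25 fs, so the generator's stated half-rise would no
  longer be the ensemble's half-rise. With centred jitter the spread is kept
  and the ensemble midpoint is unbiased.
- `excited_state_tau` = 30 fs: with deeper-orbital (HOMO−3-like) ionization
  the generator adds a band 0.6 eV below the main one decaying with this
  constant, emulating absorption from the electronically excited cation before
  internal conversion.

`generate_experimental_map` builds ΔOD-like maps as unit-peak Gaussians with
exponential kinetics convolved with the IRF (closed form, same kernel as the
fitter), plus i.i.d. additive Gaussian pixel noise — "experiment-like" noise
in the tests is 5 % of the peak. An optional negative step band emulates the
ground-state bleach at 290 eV. The noise model is the simplest defensible one;
real data have correlated noise (shot-to-shot spectral fluctuations,
normalization drifts) that i.i.d. noise does not represent.

What green tests establish: generator–fitter **closure** — at zero noise every
fit recovers its generating parameters to ≤ 1 % (most to 10⁻⁶), and at
experiment-like noise medians are within 5 % with calibrated (≥ 60 % at 1 s.e.)
coverage over 100 seeded replicates. They do not establish that the
experimental values themselves are recoverable: the raw measured maps and the
ab initio trajectory ensembles live in an institutional archive and are not
re-derivable from the publication, so published timescales enter only as
realistic generator settings, not as assertions.

## Numerical choices

- Optimizers: `scipy.optimize.least_squares` (trust-region reflective, bounds)
  for the band model; `curve_fit` for 1-D kinetic traces; Nelder–Mead → BFGS
  for the mixture MLE. Seeds control every stochastic element (multi-start
  jitter, generators); identical config + seed reproduces outputs
  byte-identically.
- Default energy grid 280–300 eV at 0.02 eV.
- Readers reject unsorted axes and ragged grids instead of reordering.
- Dark transitions (zero dipole) are valid sticks of zero strength; an empty
  stick list broadens to a zero spectrum; ε_f ≤ ε_i is an error.

## Known limitations

- The logistic-vs-erf sigmoid choice and the FWHM reading of the Lorentzian
  width are conventions, exposed as parameters but defaulted.
- The mixture MLE treats censored series as excluded rather than contributing
  censored likelihood terms; with heavy censoring the slow constant would be
  biased low.
- No periodic-boundary minimum-image handling in H-bond geometry (frames are
  assumed whole-molecule, unwrapped clusters).
- `excited_fraction` in ΔOD modelling is a free scale, not derived from pump
  parameters.
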