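"""Physical constants and unit conversions used throughout the package.

Energies carried in transition tables are atomic units (hartree); photon-energy
axes of spectra and maps are eV. All conversions go through this table so the
convention lives in exactly one place.
"""

#: eV per hartree
HARTREE_EV: float = 27.211386

#: fine-structure constant alpha
FINE_STRUCTURE: float = 1.0 / 137.035999

#: FWHM of a Gaussian divided by its standard deviation, 2*sqrt(2*ln 2)
GAUSS_FWHM_PER_SIGMA: float = 2.3548200450309493

#: standard-normal 90% quantile; the 10->90 rise of an erf step is
#: 2 * Z90 * sigma_t
Z90: float = 1.2815515655446004

#: default Lorentzian line width (FWHM, eV) for core-excited line shapes
DEFAULT_LORENTZ_FWHM_EV: float = 0.5

#: default temporal Gaussian convolution width (FWHM, fs)
DEFAULT_TIME_FWHM_FS: float = 10.0

#: default energy-axis calibration of calculated spectra (eV):
#: core-relaxation downshift and aqueous-environment upshift
DEFAULT_DOWNSHIFT_EV: float = 15.7
DEFAULT_UPSHIFT_EV: float = 3.2
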