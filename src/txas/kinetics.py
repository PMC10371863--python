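"""Three-Gaussian band decomposition and timescale extraction.

A transient map in the proton-transfer window is modelled as three Gaussian
spectral components with shared (global) centers and widths and a free
nonnegative amplitude per band per delay. The fitted amplitude traces are then
reduced to timescales:

* exponential decay/rise constants (optionally convolved with a Gaussian
  instrument response, the standard pump-probe convention),
* logistic half-rise times for sigmoidal growth curves,
* the 10->90 rise of an error-function step (the operational measure of
  temporal resolution),
* and an ordering report for the sequential decay/rise of the three bands.

Uncertainties are 1 standard error from the fit covariance throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares, nnls
from scipy.special import erf

from .constants import GAUSS_FWHM_PER_SIGMA, Z90
from .io import TransientMap
from .synthetic import LOGISTIC_RISE_PER_K, irf_exp_decay, irf_exp_rise, logistic


class FitError(RuntimeError):
    """A fit failed to converge; carries the last iterate and residual history."""

    def __init__(self, message: str, last_params=None, residual_history=None):
        super().__init__(message)
        self.last_params = last_params
        self.residual_history = residual_history


@dataclass
class BandModel:
    """Three Gaussian bands with shared centers/widths and per-delay amplitudes.

    Gaussians have unit peak, so ``amplitudes[k, i]`` is band k's peak height
    at delay i. Centers must be strictly increasing and amplitudes nonnegative
    (the separate depletion band of dOD maps is not part of this model).
    """

    centers: np.ndarray  # (3,) eV
    widths: np.ndarray  # (3,) Gaussian s.d., eV
    amplitudes: np.ndarray | None = None  # (3, n_delays), nonnegative
    #: unconstrained amplitude traces: statistically well-behaved (Gaussian
    #: errors, no floor at zero), the preferred input for kinetic fits
    amplitudes_free: np.ndarray | None = None  # (3, n_delays)
    amplitude_ses: np.ndarray | None = None  # (3,) 1 s.e. per band (linear stage)
    residual_norms: np.ndarray | None = None  # (n_delays,)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.centers.size != self.widths.size:
            raise ValueError("need one width per center")
        if not np.all(np.diff(self.centers) > 0):
            raise ValueError("band centers must be strictly increasing")
        if np.any(self.widths <= 0):
            raise ValueError("band widths must be positive")
        if self.amplitudes is not None:
            self.amplitudes = np.asarray(self.amplitudes, dtype=float)
            if np.any(self.amplitudes < -1e-12):
                raise ValueError("band amplitudes must be nonnegative")

    @property
    def n_bands(self) -> int:
        return self.centers.size

    def design_matrix(self, energies: np.ndarray) -> np.ndarray:
        """(n_energies, n_bands) matrix of unit-peak Gaussians."""
        e = np.asarray(energies, dtype=float)[:, None]
        return np.exp(-((e - self.centers[None, :]) ** 2) / (2.0 * self.widths[None, :] ** 2))

    def evaluate(self, energies: np.ndarray) -> np.ndarray:
        """(n_delays, n_energies) model map from the fitted amplitudes."""
        if self.amplitudes is None:
            raise ValueError("model has no amplitudes")
        return self.amplitudes.T @ self.design_matrix(energies).T


@dataclass
class KineticsResult:
    """A fitted timescale: exponential tau, sigmoid half-rise or erf 10-90 rise."""

    kind: Literal["exp_decay", "exp_rise", "sigmoid", "erf_rise"]
    tau_or_thalf: float  # fs
    uncertainty: float  # fs, 1 s.e. from the fit covariance
    baseline: float = 0.0
    amplitude: float = 0.0
    amplitude_se: float = np.nan
    flags: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.uncertainty) and self.uncertainty < 0:
            raise ValueError("uncertainty must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "tau_or_thalf": self.tau_or_thalf,
            "uncertainty": self.uncertainty,
            "baseline": self.baseline,
            "amplitude": self.amplitude,
            "flags": list(self.flags),
            "params": dict(self.params),
        }


# ---------------------------------------------------------------------------
# global three-Gaussian band fit
# ---------------------------------------------------------------------------


def fit_band_model(
    tmap: TransientMap,
    init: BandModel,
    energy_window: tuple[float, float] | None = None,
    n_starts: int = 5,
    seed: int = 0,
    max_nfev: int = 400,
) -> BandModel:
    """Global least-squares band decomposition of a transient map.

    Centers and widths are shared across delays; amplitudes are free and
    nonnegative per delay (solved by NNLS inside the shape optimisation, a
    variable-projection scheme). ``n_starts`` jittered initialisations guard
    against local minima; the seeded jitter makes the fit reproducible.

    The returned model carries both the bound-constrained amplitudes and the
    unconstrained traces (``amplitudes_free``): the NNLS floor at zero makes
    errors of near-zero amplitudes one-sided, so the free traces are the
    better-behaved input for downstream kinetic fits.
    """
    e = tmap.energies
    mask = np.ones(e.size, dtype=bool)
    if energy_window is not None:
        mask = (e >= energy_window[0]) & (e <= energy_window[1])
        if not mask.any():
            raise ValueError("energy window excludes the whole grid")
    energies = e[mask]
    data = tmap.values[:, mask]
    if energy_window is not None and (
        init.centers.min() < energy_window[0] or init.centers.max() > energy_window[1]
    ):
        raise ValueError("energy window must cover all initial band centers")

    n_bands = init.n_bands
    e_lo, e_hi = energies[0], energies[-1]
    w_hi = (e_hi - e_lo) if e_hi > e_lo else 1.0

    def solve_amplitudes(centers, widths):
        g = np.exp(-((energies[:, None] - centers[None, :]) ** 2) / (2.0 * widths[None, :] ** 2))
        amps = np.empty((n_bands, data.shape[0]))
        resid = np.empty(data.shape[0])
        for i in range(data.shape[0]):
            amps[:, i], resid[i] = nnls(g, data[i])
        return g, amps, resid

    def residuals(p):
        centers, widths = p[:n_bands], np.exp(p[n_bands:])
        g, amps, _ = solve_amplitudes(centers, widths)
        return (g @ amps - data.T).ravel()

    rng = np.random.default_rng(seed)
    p0 = np.concatenate([init.centers, np.log(init.widths)])
    lb = np.concatenate([np.full(n_bands, e_lo), np.full(n_bands, np.log(1e-3 * w_hi))])
    ub = np.concatenate([np.full(n_bands, e_hi), np.full(n_bands, np.log(w_hi))])

    best = None
    history: list[float] = []
    zero_map = not np.any(np.abs(data) > 0)
    for start in range(n_starts if not zero_map else 1):
        p_init = p0.copy()
        if start > 0:
            p_init[:n_bands] += rng.uniform(-0.1, 0.1, n_bands)
            p_init[n_bands:] += rng.uniform(-0.2, 0.2, n_bands)
            p_init = np.clip(p_init, lb + 1e-9, ub - 1e-9)
        sol = least_squares(
            residuals, p_init, bounds=(lb, ub), method="trf", max_nfev=max_nfev
        )
        history.append(float(sol.cost))
        if sol.status <= 0:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError(
            "band-model fit did not converge",
            last_params=p_init,
            residual_history=history,
        )
    centers, widths = best.x[:n_bands], np.exp(best.x[n_bands:])
    order = np.argsort(centers)
    centers, widths = centers[order], widths[order]
    # degenerate (e.g. all-zero) maps: keep the caller's shape parameters
    if zero_map:
        centers, widths = init.centers.copy(), init.widths.copy()
    g, amps, resid = solve_amplitudes(centers, widths)
    # propagate pixel noise into per-band amplitude standard errors via the
    # linear stage: cov(a) = sigma_px^2 (G^T G)^-1, noise estimated from the
    # global fit residuals
    dof = max(data.size - (2 * n_bands + amps.size), 1)
    sigma_px_sq = float(np.sum(resid**2)) / dof
    try:
        amp_var = np.clip(np.diag(np.linalg.inv(g.T @ g)), 0, None) * sigma_px_sq
        amp_ses = np.sqrt(amp_var)
    except np.linalg.LinAlgError:
        amp_ses = np.full(n_bands, np.nan)
    amps_free, *_ = np.linalg.lstsq(g, data.T, rcond=None)
    return BandModel(
        centers=centers,
        widths=widths,
        amplitudes=amps if not zero_map else np.zeros_like(amps),
        amplitudes_free=amps_free if not zero_map else np.zeros_like(amps_free),
        amplitude_ses=amp_ses,
        residual_norms=resid,
    )


# ---------------------------------------------------------------------------
# exponential kinetics with IRF convolution
# ---------------------------------------------------------------------------


def fit_exponential(
    t: np.ndarray,
    y: np.ndarray,
    kind: Literal["decay", "rise"],
    irf_fwhm: float = 0.0,
    y_err: float | np.ndarray | None = None,
) -> KineticsResult:
    """Fit ``baseline + A*exp(-t/tau)`` (decay) or ``baseline + A*(1-exp(-t/tau))``
    (rise), each starting at t=0 and convolved with a Gaussian IRF.

    Returns tau with its 1-s.e. covariance uncertainty; when ``y_err`` (known
    1-s.e. of the trace values, e.g. propagated from a band fit) is given it is
    used as absolute weighting, otherwise uncertainties are scaled by the
    residual variance. A tau estimate pinned at the parameter bounds or an
    essentially flat trace is flagged, never silently returned as converged.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 8:
        raise ValueError("need at least 8 points to fit an exponential")
    sigma_irf = irf_fwhm / GAUSS_FWHM_PER_SIGMA if irf_fwhm > 0 else 0.0
    resp = irf_exp_decay if kind == "decay" else irf_exp_rise

    def model(tt, tau, amp, base):
        return base + amp * resp(tt, tau, sigma_irf)

    span = t[-1] - t[0]
    rng_y = float(y.max() - y.min())
    amp0 = rng_y if rng_y > 0 else 1.0
    base0 = float(y.min())
    tau0 = max(span / 4.0, 1e-3)
    tau_hi = 50.0 * span
    flags: list[str] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sigma = None
            if y_err is not None:
                sigma = np.broadcast_to(np.asarray(y_err, dtype=float), y.shape)
            popt, pcov = curve_fit(
                model,
                t,
                y,
                p0=[tau0, amp0, base0],
                sigma=sigma,
                absolute_sigma=sigma is not None,
                bounds=([1e-6, -np.inf, -np.inf], [tau_hi, np.inf, np.inf]),
                maxfev=10_000,
            )
    except RuntimeError as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    tau, amp, base = popt
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    if tau > 0.99 * tau_hi or tau < 2e-6:
        flags.append("tau_at_bound")
    amp_scale = rng_y if rng_y > 0 else max(float(np.abs(y).max()), 1.0)
    if abs(amp) < 0.05 * amp_scale:
        flags.append("amplitude_near_zero")
    if not np.all(np.isfinite(perr)):
        flags.append("covariance_singular")
    return KineticsResult(
        kind=f"exp_{kind}",  # type: ignore[arg-type]
        tau_or_thalf=float(tau),
        uncertainty=float(perr[0]),
        baseline=float(base),
        amplitude=float(amp),
        amplitude_se=float(perr[1]),
        flags=flags,
        params={"irf_fwhm": irf_fwhm},
    )


# ---------------------------------------------------------------------------
# sigmoidal half-rise
# ---------------------------------------------------------------------------


def fit_sigmoid(t: np.ndarray, y: np.ndarray) -> KineticsResult:
    """Fit a logistic with free asymptotes; report the time at the midpoint.

    The model is ``y0 + A / (1 + exp(-(t - t_half)/k))``; ``t_half`` is the
    time at the midpoint of the two asymptotes and is reported with its 1-s.e.
    uncertainty. Falling sigmoids are handled by a negative A. The trace must
    bracket the transition (both plateaus inside the window); otherwise the
    fit raises with a window-extension hint.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    span = t[-1] - t[0]

    def model(tt, t_half, k, amp, y0):
        return y0 + amp * logistic(tt, t_half, k)

    rng_y = float(y.max() - y.min())
    rising = y[-1] >= y[0]
    amp0 = rng_y if rising else -rng_y
    y0_0 = float(y[0])
    mid = y0_0 + amp0 / 2.0
    cross = np.nonzero(np.diff(np.sign(y - mid)))[0]
    t_half0 = float(t[cross[0]]) if cross.size else float(t[t.size // 2])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                model,
                t,
                y,
                p0=[t_half0, span / 10.0, amp0, y0_0],
                bounds=(
                    [t[0] - span, 1e-6, -np.inf, -np.inf],
                    [t[-1] + span, 10.0 * span, np.inf, np.inf],
                ),
                maxfev=10_000,
            )
    except RuntimeError as exc:
        raise FitError(f"sigmoid fit did not converge: {exc}") from exc
    t_half, k, amp, y0 = popt
    if not (t[0] + 2.0 * k <= t_half <= t[-1] - 2.0 * k):
        raise ValueError(
            "trace does not bracket the sigmoid transition; extend the time window"
        )
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return KineticsResult(
        kind="sigmoid",
        tau_or_thalf=float(t_half),
        uncertainty=float(perr[0]),
        baseline=float(y0),
        amplitude=float(amp),
        amplitude_se=float(perr[2]),
        params={"k": float(k), "k_se": float(perr[1]),
                "rise_10_90": float(LOGISTIC_RISE_PER_K * k)},
    )


# ---------------------------------------------------------------------------
# error-function rise (temporal resolution)
# ---------------------------------------------------------------------------


def fit_erf_rise(t: np.ndarray, y: np.ndarray) -> KineticsResult:
    """Fit a scaled error-function step; report the 10->90 rise time.

    The model is ``b + (A/2)(1 + erf((t - t0)/(sigma sqrt2)))``; the reported
    rise is the 10%->90% interval ``2 * z_0.9 * sigma = 2.5631 * sigma``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    span = t[-1] - t[0]

    def model(tt, t0, sig, amp, base):
        return base + 0.5 * amp * (1.0 + erf((tt - t0) / (np.sqrt(2.0) * sig)))

    rng_y = float(y.max() - y.min())
    mid = 0.5 * (y[0] + y[-1])
    cross = np.nonzero(np.diff(np.sign(y - mid)))[0]
    t0_0 = float(t[cross[0]]) if cross.size else float(t[t.size // 2])
    flags: list[str] = []
    # non-monotone trend beyond noise level: warn, still fit
    dy = np.diff(y)
    if rng_y > 0 and (-dy[dy < 0].sum() if np.any(dy < 0) else 0.0) > 0.5 * rng_y:
        warnings.warn("erf-rise trace is non-monotone beyond noise", stacklevel=2)
        flags.append("non_monotone")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                model,
                t,
                y,
                p0=[t0_0, span / 10.0, rng_y if rng_y > 0 else 1.0, float(y[0])],
                bounds=([t[0] - span, 1e-9, -np.inf, -np.inf],
                        [t[-1] + span, 10.0 * span, np.inf, np.inf]),
                maxfev=10_000,
            )
    except RuntimeError as exc:
        raise FitError(f"erf fit did not converge: {exc}") from exc
    t0, sig, amp, base = popt
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    rise = 2.0 * Z90 * sig
    return KineticsResult(
        kind="erf_rise",
        tau_or_thalf=float(rise),
        uncertainty=float(2.0 * Z90 * perr[1]),
        baseline=float(base),
        amplitude=float(amp),
        amplitude_se=float(perr[2]),
        flags=flags,
        params={"sigma_t": float(sig), "t0": float(t0)},
    )


# ---------------------------------------------------------------------------
# sequential-band ordering
# ---------------------------------------------------------------------------


@dataclass
class SequenceReport:
    """Half-crossing times of each band and whether they follow i -> ii -> iii."""

    crossing_times: dict[int, float]
    ordering_ok: bool
    indeterminate: bool
    excluded: list[int]
    notes: list[str]


def sequence_check(
    model: BandModel,
    delays: np.ndarray,
    flat_fraction: float = 0.05,
    tie_tol: float | None = None,
) -> SequenceReport:
    """Check the sequential decay/rise ordering of the fitted bands.

    For each band the time at which its amplitude crosses half of its extremal
    value (falling through it for decaying bands, rising through it for rising
    bands) is found by linear interpolation. Bands whose amplitude range is
    below ``flat_fraction`` of the largest band are excluded with a notice.
    Crossings closer than ``tie_tol`` (default: half the delay step) are
    reported as ties and make the ordering indeterminate.
    """
    if model.amplitudes is None:
        raise ValueError("band model has no fitted amplitudes")
    delays = np.asarray(delays, dtype=float)
    if tie_tol is None:
        tie_tol = 0.5 * float(np.median(np.diff(delays))) if delays.size > 1 else 0.0
    overall = float(model.amplitudes.max()) if model.amplitudes.size else 0.0
    crossing: dict[int, float] = {}
    excluded: list[int] = []
    notes: list[str] = []
    for k in range(model.n_bands):
        a = model.amplitudes[k]
        if a.max() - a.min() < flat_fraction * overall or overall == 0.0:
            excluded.append(k)
            notes.append(f"band {k}: flat amplitude trace, excluded from ordering")
            continue
        peak = float(a.max())
        half = 0.5 * peak
        i_peak = int(np.argmax(a))
        # a band is "rising" when its late plateau sits near its maximum;
        # endpoint-vs-endpoint comparison would be flipped by noise for decay
        # bands that start and end near zero
        n_edge = max(1, a.size // 10)
        rising_band = (a[-n_edge:].mean() - a[:n_edge].mean()) > 0.5 * (a.max() - a.min())
        if rising_band:
            seg, tseg = a[: i_peak + 1], delays[: i_peak + 1]
            idx = np.nonzero((seg[:-1] < half) & (seg[1:] >= half))[0]
        else:
            seg, tseg = a[i_peak:], delays[i_peak:]
            idx = np.nonzero((seg[:-1] >= half) & (seg[1:] < half))[0]
        if idx.size == 0:
            excluded.append(k)
            notes.append(f"band {k}: no half-amplitude crossing inside the window")
            continue
        i = idx[0]
        frac = (half - seg[i]) / (seg[i + 1] - seg[i])
        crossing[k] = float(tseg[i] + frac * (tseg[i + 1] - tseg[i]))
    order_ok = False
    indeterminate = False
    if len(crossing) == model.n_bands == 3:
        t0, t1, t2 = crossing[0], crossing[1], crossing[2]
        if min(abs(t1 - t0), abs(t2 - t1)) <= tie_tol:
            indeterminate = True
            notes.append("tie between band crossing times; ordering indeterminate")
        order_ok = (not indeterminate) and (t0 < t1 < t2)
    else:
        indeterminate = True
    return SequenceReport(
        crossing_times=crossing,
        ordering_ok=order_ok,
        indeterminate=indeterminate,
        excluded=excluded,
        notes=notes,
    )
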