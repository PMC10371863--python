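"""Synthetic trajectory ensembles, transient maps and H-bond event series.

The generators emulate the statistical structure of ionized-urea proton-transfer
data so that every downstream stage (spectral synthesis, band decomposition,
kinetic fitting, H-bond statistics) can be exercised without quantum chemistry:

* a configurable fraction of trajectories undergoes proton transfer (PT);
* in a PT trajectory the squared transition dipole grows sigmoidally (the
  valence-hole amplitude developing on the carbon site) and the transition
  energy shifts upward sigmoidally (the proton transfer itself), with a
  vibrational oscillation superposed;
* experiment-like dOD maps are built from three Gaussian bands with
  exponential decay/rise kinetics convolved with a Gaussian instrument
  response, plus i.i.d. pixel noise;
* hydrogen-bond formation waiting times are drawn from a two-component
  exponential mixture (fast local fluctuations, slow diffusion-limited).

All generators are deterministic for a fixed config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.special import erfc, erfcx

from .constants import GAUSS_FWHM_PER_SIGMA, HARTREE_EV
from .io import TransientMap, TransitionRecord

#: logistic 10->90 rise divided by the scale parameter k, ln(81)
LOGISTIC_RISE_PER_K = float(np.log(81.0))

#: fixed core-orbital energy used for synthetic records (hartree, ~ -299 eV)
SYNTH_EPS_CORE = -11.0


class EnsembleConfig(BaseModel):
    """Stated world for a synthetic ionized-trajectory ensemble.

    Defaults follow the phenomenology of HOMO-ionized urea dimers in 10 M
    aqueous solution: ~7% of trajectories transfer a proton, the carbon-site
    cross-section grows with a 134 fs half-rise, the transition energy shifts
    up by 1.2 eV with a 107 fs half-rise, and a weak vibrational oscillation
    rides on top. Records are produced on a uniform 0.5 fs grid over 1 ps.
    """

    n_traj: int = Field(50, gt=0)
    pt_fraction: float = Field(0.07, ge=0.0, le=1.0)
    t_half_amp: float = Field(134.0, gt=0)  # fs, cross-section half-rise
    t_half_shift: float = Field(107.0, gt=0)  # fs, energy-shift half-rise
    shift_magnitude: float = Field(1.2)  # eV, asymptotic upward shift
    base_energy: float = Field(286.4, gt=0)  # eV, pre-transfer transition energy
    vib_period: float = Field(20.0, gt=0)  # fs (order of a C=O stretch period)
    vib_amp: float = Field(0.05, ge=0)  # eV
    excited_state_tau: float = Field(30.0, gt=0)  # fs, excited-cation band decay
    noise_sd: float = Field(0.0, ge=0)  # relative
    seed: int = Field(0, ge=0)
    # grid and shape parameters
    t_start: float = 0.0  # fs
    t_end: float = Field(1000.0, gt=0)  # fs
    dt: float = Field(0.5, gt=0)  # fs
    sigmoid_rise_width: float = Field(150.0, gt=0)  # fs, logistic 10->90 width
    jitter_window: float = Field(50.0, ge=0)  # fs, PT-onset spread (centred)
    dipole_sq_max: float = Field(0.01, gt=0)  # a.u., post-transfer |d|^2 asymptote
    dipole_base_fraction: float = Field(0.1, ge=0, le=1.0)  # pre-transfer |d|^2 level

    @model_validator(mode="after")
    def _check_window(self) -> "EnsembleConfig":
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        return self


class HBondKineticsConfig(BaseModel):
    """Two-component exponential mixture of H-bond formation waiting times.

    Defaults are the formation constants of proximal-H urea-urea hydrogen
    bonds in 10 M solution: 227 fs for local fluctuations and 4.1 ps for
    diffusion-controlled formation.
    """

    tau_fast: float = Field(227.0, gt=0)  # fs
    tau_slow: float = Field(4100.0, gt=0)  # fs
    weight_fast: float = Field(0.5, ge=0.0, le=1.0)
    n_events: int = Field(10_000)
    seed: int = Field(0, ge=0)

    @model_validator(mode="after")
    def _check_order(self) -> "HBondKineticsConfig":
        if not self.tau_fast < self.tau_slow:
            raise ValueError("tau_fast must be smaller than tau_slow")
        return self


def logistic(t: np.ndarray, t_half: float, k: float) -> np.ndarray:
    """Logistic sigmoid with midpoint ``t_half`` and scale ``k`` (10-90 rise ln81*k)."""
    return 1.0 / (1.0 + np.exp(-np.clip((t - t_half) / k, -500, 500)))


# ---------------------------------------------------------------------------
# trajectories and ensembles
# ---------------------------------------------------------------------------


def generate_pt_trajectory(
    cfg: EnsembleConfig,
    undergoes_pt: bool,
    rng: np.random.Generator | None = None,
    traj_id: str = "traj0",
    ion_label: str = "HOMO",
) -> list[TransitionRecord]:
    """Transition records for one trajectory on a uniform time grid.

    If ``undergoes_pt``, |d|^2 follows a logistic with half-rise
    ``t_half_amp`` between ``dipole_base_fraction*dipole_sq_max`` and
    ``dipole_sq_max``, and the transition energy follows ``base_energy`` plus a
    logistic step of ``shift_magnitude`` with half-rise ``t_half_shift``; a
    vibrational oscillation ``vib_amp*sin(2 pi t/vib_period + phase)`` rides on
    the energy in both cases. Without PT both stay at their initial levels.

    For ``ion_label="HOMO-3"`` an additional band 0.6 eV below ``base_energy``
    decays exponentially with ``excited_state_tau``, emulating absorption in
    the electronically excited cation before internal conversion.

    The RNG supplies PT-onset jitter (uniform over ``jitter_window``, centred
    so the ensemble-mean half-rise is unbiased), the vibrational phase and the
    relative noise; pass ``None`` for the deterministic nominal trajectory.
    """
    if cfg.dt <= 0 or cfg.t_end <= cfg.t_start:
        raise ValueError("time window and step must be positive")
    t = np.arange(cfg.t_start, cfg.t_end + 0.5 * cfg.dt, cfg.dt)
    if rng is not None:
        jitter = rng.uniform(0.0, cfg.jitter_window) - 0.5 * cfg.jitter_window
        phase = rng.uniform(0.0, 2.0 * np.pi)
    else:
        jitter, phase = 0.0, 0.0

    k = cfg.sigmoid_rise_width / LOGISTIC_RISE_PER_K
    d2_lo = cfg.dipole_base_fraction * cfg.dipole_sq_max
    if undergoes_pt:
        s_amp = logistic(t, cfg.t_half_amp + jitter, k)
        s_shift = logistic(t, cfg.t_half_shift + jitter, k)
        d2 = d2_lo + (cfg.dipole_sq_max - d2_lo) * s_amp
        energy = cfg.base_energy + cfg.shift_magnitude * s_shift
    else:
        d2 = np.full_like(t, d2_lo)
        energy = np.full_like(t, cfg.base_energy)
    energy = energy + cfg.vib_amp * np.sin(2.0 * np.pi * t / cfg.vib_period + phase)

    if cfg.noise_sd > 0 and rng is not None:
        d2 = d2 * (1.0 + cfg.noise_sd * rng.standard_normal(t.size))
        d2 = np.clip(d2, 0.0, None)
        energy = energy + cfg.noise_sd * cfg.shift_magnitude * rng.standard_normal(t.size)

    records: list[TransitionRecord] = []
    for ti, d2i, ei in zip(t, d2, energy):
        records.append(_record(ti, ei, d2i, traj_id, ion_label))
        if ion_label == "HOMO-3":
            d2_exc = cfg.dipole_sq_max * np.exp(-max(ti, 0.0) / cfg.excited_state_tau)
            records.append(_record(ti, ei - 0.6, d2_exc, traj_id, ion_label))
    return records


def _record(t: float, energy_ev: float, d2: float, traj_id: str, ion_label: str) -> TransitionRecord:
    return TransitionRecord(
        time=float(t),
        eps_core=SYNTH_EPS_CORE,
        eps_vac=SYNTH_EPS_CORE + energy_ev / HARTREE_EV,
        dipole=np.array([0.0, 0.0, np.sqrt(max(d2, 0.0))]),
        traj_id=traj_id,
        ion_label=ion_label,
        system_label="dimer",
    )


@dataclass
class EnsembleResult:
    """Transition records for a whole ensemble plus per-trajectory PT flags."""

    records: list[TransitionRecord]
    pt_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def n_pt(self) -> int:
        return sum(self.pt_flags.values())

    def per_trajectory(self) -> dict[str, list[TransitionRecord]]:
        out: dict[str, list[TransitionRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.traj_id, []).append(rec)
        return out


def generate_ensemble(cfg: EnsembleConfig, ion_label: str = "HOMO") -> EnsembleResult:
    """Seeded ensemble of ``n_traj`` trajectories with Bernoulli PT flags.

    Each trajectory independently transfers a proton with probability
    ``pt_fraction`` (so the PT count is Binomial), and draws its own onset
    jitter, vibrational phase and noise from the seeded stream.
    """
    rng = np.random.default_rng(cfg.seed)
    flags = rng.random(cfg.n_traj) < cfg.pt_fraction
    records: list[TransitionRecord] = []
    pt_flags: dict[str, bool] = {}
    for i, flag in enumerate(flags):
        tid = f"traj{i:04d}"
        pt_flags[tid] = bool(flag)
        records.extend(
            generate_pt_trajectory(cfg, bool(flag), rng, traj_id=tid, ion_label=ion_label)
        )
    return EnsembleResult(records=records, pt_flags=pt_flags)


# ---------------------------------------------------------------------------
# IRF-convolved kinetic responses (shared with band_kinetics fitting)
# ---------------------------------------------------------------------------


def irf_exp_decay(t: np.ndarray, tau: float, irf_sigma: float) -> np.ndarray:
    """Unit-amplitude exponential decay starting at t=0, convolved with a
    Gaussian IRF of standard deviation ``irf_sigma`` (fs).

    Closed form ``0.5*exp(-t^2/(2 s^2))*erfcx((s/tau - t/s)/sqrt2)``; reduces to
    ``exp(-t/tau)*step(t)`` as s->0.
    """
    t = np.asarray(t, dtype=float)
    if irf_sigma <= 0:
        return np.where(t >= 0, np.exp(-np.clip(t, 0, None) / tau), 0.0)
    b = (irf_sigma / tau - t / irf_sigma) / np.sqrt(2.0)
    # piecewise-stable: erfcx form before/near time zero (b >= 0), plain
    # exp * erfc after (where the exponent is negative and erfc(b) -> 2)
    a = irf_sigma**2 / (2.0 * tau**2) - t / tau
    with np.errstate(over="ignore", invalid="ignore"):
        early = 0.5 * np.exp(-(t**2) / (2.0 * irf_sigma**2)) * erfcx(np.clip(b, 0, None))
        late = 0.5 * np.exp(np.where(b < 0, a, 0.0)) * erfc(np.clip(b, None, 0))
    return np.where(b >= 0, early, late)


def irf_step(t: np.ndarray, irf_sigma: float) -> np.ndarray:
    """Unit step at t=0 convolved with a Gaussian IRF."""
    t = np.asarray(t, dtype=float)
    if irf_sigma <= 0:
        return (t >= 0).astype(float)
    return 0.5 * erfc(-t / (np.sqrt(2.0) * irf_sigma))


def irf_exp_rise(t: np.ndarray, tau: float, irf_sigma: float) -> np.ndarray:
    """Unit-amplitude ``1 - exp(-t/tau)`` rise convolved with a Gaussian IRF."""
    return irf_step(t, irf_sigma) - irf_exp_decay(t, tau, irf_sigma)


# ---------------------------------------------------------------------------
# experiment-like dOD maps
# ---------------------------------------------------------------------------

BandKind = Literal["decay", "rise", "step"]


def generate_experimental_map(
    band_params: Sequence[tuple[float, float, float]],
    kinetics_params: Sequence[tuple[BandKind, float]],
    irf_fwhm: float,
    delay_grid: np.ndarray,
    energy_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
    depletion: tuple[float, float, float] | None = None,
) -> TransientMap:
    """Noisy dOD-like map from Gaussian bands with exponential kinetics.

    Parameters
    ----------
    band_params
        One ``(center_eV, sigma_eV, amplitude)`` per band; the Gaussian has
        unit peak, so the amplitude is the band's peak dOD.
    kinetics_params
        One ``(kind, tau_fs)`` per band: ``"decay"`` for A*exp(-t/tau),
        ``"rise"`` for A*(1-exp(-t/tau)), ``"step"`` ignores tau. All kinetics
        start at t=0 and are convolved with the Gaussian IRF (closed form).
    depletion
        Optional ``(center_eV, sigma_eV, amplitude)`` ground-state bleach band
        with step kinetics; its amplitude is typically negative.
    noise_sd
        Standard deviation of i.i.d. additive Gaussian noise per pixel, in map
        units.
    """
    delay_grid = np.asarray(delay_grid, dtype=float)
    energy_grid = np.asarray(energy_grid, dtype=float)
    if np.any(np.diff(delay_grid) <= 0) or np.any(np.diff(energy_grid) <= 0):
        raise ValueError("delay and energy grids must be strictly ascending")
    if len(band_params) != len(kinetics_params):
        raise ValueError("need one kinetics entry per band")
    sigma_irf = irf_fwhm / GAUSS_FWHM_PER_SIGMA
    values = np.zeros((delay_grid.size, energy_grid.size))
    bands = list(zip(band_params, kinetics_params))
    if depletion is not None:
        bands.append((depletion, ("step", 1.0)))
    for (center, width, amp), (kind, tau) in bands:
        if kind == "decay":
            a_t = irf_exp_decay(delay_grid, tau, sigma_irf)
        elif kind == "rise":
            a_t = irf_exp_rise(delay_grid, tau, sigma_irf)
        elif kind == "step":
            a_t = irf_step(delay_grid, sigma_irf)
        else:
            raise ValueError(f"unknown band kinetics kind: {kind!r}")
        profile = np.exp(-((energy_grid - center) ** 2) / (2.0 * width**2))
        values += amp * np.outer(a_t, profile)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + noise_sd * rng.standard_normal(values.shape)
    return TransientMap(delays=delay_grid, energies=energy_grid, values=values, kind="dod")


# ---------------------------------------------------------------------------
# H-bond formation waiting times
# ---------------------------------------------------------------------------


def generate_hbond_event_series(cfg: HBondKineticsConfig) -> np.ndarray:
    """I.i.d. waiting times (fs) from the fast/slow exponential mixture."""
    if cfg.n_events <= 0:
        raise ValueError("n_events must be positive")
    rng = np.random.default_rng(cfg.seed)
    fast = rng.random(cfg.n_events) < cfg.weight_fast
    times = np.where(
        fast,
        rng.exponential(cfg.tau_fast, cfg.n_events),
        rng.exponential(cfg.tau_slow, cfg.n_events),
    )
    return times


# ---------------------------------------------------------------------------
# idealized geometries (for exercising the H-bond stages)
# ---------------------------------------------------------------------------


def urea_geometry() -> tuple[list[str], np.ndarray]:
    """Idealized planar urea (CON2H4): elements and coordinates (Å).

    Standard bond lengths (C=O 1.21, C-N 1.345, N-H 1.01 Å) with 120° sp2
    angles; each NH2 has one hydrogen cis to the carbonyl oxygen (proximal)
    and one trans (distal).
    """
    elements = ["C", "O", "N", "N", "H", "H", "H", "H"]
    coords = [np.array([0.0, 0.0, 0.0]), np.array([0.0, 1.21, 0.0])]
    nh = 1.01
    for sign in (1.0, -1.0):
        ndir = np.array([sign * np.cos(np.radians(-31.0)), np.sin(np.radians(-31.0)), 0.0])
        n = 1.345 * ndir
        coords.append(n)
        to_c = -ndir
        for rot in (120.0, -120.0):
            th = np.radians(rot) * sign
            r = np.array(
                [[np.cos(th), -np.sin(th), 0.0], [np.sin(th), np.cos(th), 0.0], [0.0, 0.0, 1.0]]
            )
            coords.append(n + nh * (r @ to_c))
    # reorder so each N is followed by its hydrogens: C O N1 N2 H11 H12 H21 H22
    coords = [coords[0], coords[1], coords[2], coords[5], coords[3], coords[4],
              coords[6], coords[7]]
    return elements, np.vstack(coords)


def water_geometry() -> tuple[list[str], np.ndarray]:
    """A water molecule: elements and coordinates (Å)."""
    return ["O", "H", "H"], np.array(
        [[0.0, 0.0, 0.0], [0.96, 0.0, 0.0], [-0.24, 0.93, 0.0]]
    )


def waiting_times_to_presence(times: np.ndarray, t_grid: np.ndarray) -> np.ndarray:
    """Boolean presence series (n_series, n_frames): bond formed and kept.

    Convenience for exercising the waiting-time extraction on event series: the
    bond for series i is present at every frame with ``t_grid >= times[i]``.
    """
    times = np.asarray(times, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    return t_grid[None, :] >= times[:, None]
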