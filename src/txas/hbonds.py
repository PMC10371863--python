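"""Geometric hydrogen-bond detection, urea NH classification and formation kinetics.

A hydrogen bond is accepted when the donor-acceptor distance is at most
``d_max`` (3 Å by default) and the hydrogen donor-acceptor angle -- the angle
at the donor between the donor->H and donor->acceptor vectors -- is at most
``theta_max`` (20°). Donors are N/O atoms with a covalently bound H; acceptors
are N/O atoms of a *different* molecule. Covalent connectivity is inferred from
element-wise covalent radii (1.2x sum cutoff); no topology file is needed.

Urea amine hydrogens are classified as proximal (cis to the carbonyl oxygen,
through-space nearest) or distal; only proximal-linked urea dimers readily
transfer a proton, which makes the formation kinetics of proximal H-bonds the
relevant statistic. Formation waiting times are fitted with a two-component
exponential mixture by direct maximum likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .io import Frame

#: covalent radii (Å), Cordero et al. values for the elements handled here
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
}
BOND_SCALE = 1.2

DONOR_ELEMENTS = ("N", "O")
ACCEPTOR_ELEMENTS = ("N", "O")

UREA_FORMULA = {"C": 1, "O": 1, "N": 2, "H": 4}
WATER_FORMULA = {"O": 1, "H": 2}


@dataclass
class HBondCriterion:
    """Geometric acceptance cuts: distance ceiling (Å) and angle ceiling (deg)."""

    d_max: float = 3.0
    theta_max: float = 20.0
    #: where the angle is measured: "donor" (between donor->H and
    #: donor->acceptor) or "hydrogen" (deviation of D-H...A from linearity)
    angle_at: Literal["donor", "hydrogen"] = "donor"

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not 0 < self.theta_max < 90:
            raise ValueError("theta_max must be in (0, 90) degrees")


@dataclass
class HBondRecord:
    donor_atom: int
    hydrogen: int
    acceptor_atom: int
    distance: float  # Å, donor-acceptor
    angle: float  # degrees, per the criterion's convention
    donor_class: Literal["proximal", "distal", "water", "other"] = "other"


# ---------------------------------------------------------------------------
# connectivity
# ---------------------------------------------------------------------------


def bond_matrix(frame: Frame) -> np.ndarray:
    """Boolean covalent-bond matrix from the 1.2x covalent-radius cutoff."""
    radii = np.array([COVALENT_RADII.get(el, 0.75) for el in frame.elements])
    diff = frame.coords[:, None, :] - frame.coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    cut = BOND_SCALE * (radii[:, None] + radii[None, :])
    bonded = (dist <= cut) & (dist > 1e-8)
    return bonded


def infer_molecule_ids(frame: Frame) -> np.ndarray:
    """Assign molecule ids as connected components of the covalent-bond graph."""
    bonded = bond_matrix(frame)
    n_comp, labels = connected_components(csr_matrix(bonded), directed=False)
    return labels


def _molecule_ids(frame: Frame) -> np.ndarray:
    return frame.molecule_ids if frame.molecule_ids is not None else infer_molecule_ids(frame)


def molecule_formula(frame: Frame, molecule_id: int, mol_ids: np.ndarray | None = None) -> dict:
    mol_ids = _molecule_ids(frame) if mol_ids is None else mol_ids
    formula: dict[str, int] = {}
    for i in np.nonzero(mol_ids == molecule_id)[0]:
        formula[frame.elements[i]] = formula.get(frame.elements[i], 0) + 1
    return formula


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def detect_hbonds(frame: Frame, crit: HBondCriterion | None = None) -> list[HBondRecord]:
    """All intermolecular donor-H...acceptor triples passing both geometric cuts.

    The donor-acceptor distance must be <= ``d_max`` and the angle (at the
    donor by default) <= ``theta_max``. Intramolecular pairs are excluded via
    molecule ids (inferred from covalent connectivity when the frame carries
    none). Donor classes are assigned for urea N-H (proximal/distal) and water
    O-H donors.
    """
    crit = crit or HBondCriterion()
    elements = np.array(frame.elements)
    if not np.any(elements == "H"):
        warnings.warn("frame contains no hydrogen atoms; no bonds detected", stacklevel=2)
        return []
    mol_ids = _molecule_ids(frame)
    bonded = bond_matrix(frame)
    coords = frame.coords

    donor_class_cache: dict[int, dict[int, str]] = {}

    def h_class(donor: int, h: int) -> str:
        mid = int(mol_ids[donor])
        formula = molecule_formula(frame, mid, mol_ids)
        if elements[donor] == "O" and formula == WATER_FORMULA:
            return "water"
        if elements[donor] == "N" and formula.get("C") == 1 and formula.get("N") == 2 \
                and formula.get("O") == 1:
            if mid not in donor_class_cache:
                try:
                    donor_class_cache[mid] = classify_urea_hydrogens(frame, mid, mol_ids)
                except ValueError:
                    donor_class_cache[mid] = {}
            return donor_class_cache[mid].get(h, "other")
        return "other"

    records: list[HBondRecord] = []
    donors = np.nonzero(np.isin(elements, DONOR_ELEMENTS))[0]
    acceptors = np.nonzero(np.isin(elements, ACCEPTOR_ELEMENTS))[0]
    for d in donors:
        hydrogens = np.nonzero(bonded[d] & (elements == "H"))[0]
        if hydrogens.size == 0:
            continue
        for a in acceptors:
            if a == d or mol_ids[a] == mol_ids[d]:
                continue
            dist = float(np.linalg.norm(coords[a] - coords[d]))
            if dist > crit.d_max:
                continue
            for h in hydrogens:
                if crit.angle_at == "donor":
                    ang = _angle_deg(coords[h] - coords[d], coords[a] - coords[d])
                else:  # deviation of the D-H...A angle from linearity
                    ang = 180.0 - _angle_deg(coords[d] - coords[h], coords[a] - coords[h])
                if ang <= crit.theta_max:
                    records.append(
                        HBondRecord(
                            donor_atom=int(d),
                            hydrogen=int(h),
                            acceptor_atom=int(a),
                            distance=dist,
                            angle=ang,
                            donor_class=h_class(int(d), int(h)),
                        )
                    )
    return records


# ---------------------------------------------------------------------------
# urea NH classification
# ---------------------------------------------------------------------------


def classify_urea_hydrogens(
    frame: Frame, molecule_id: int, mol_ids: np.ndarray | None = None
) -> dict[int, str]:
    """Classify a urea molecule's amine hydrogens as proximal or distal.

    For each NH2 group the hydrogen nearer (through space) to the molecule's
    own carbonyl oxygen is proximal (cis to C=O), the other distal; an intact
    urea yields exactly 2 proximal + 2 distal. A nitrogen carrying a single
    hydrogen (post-transfer, deprotonated) is classified by the O-C-N-H
    dihedral (|phi| < 90° means cis, hence proximal) and the count asymmetry is
    visible in the returned map.
    """
    mol_ids = _molecule_ids(frame) if mol_ids is None else mol_ids
    atoms = np.nonzero(mol_ids == molecule_id)[0]
    elements = np.array(frame.elements)
    formula = molecule_formula(frame, molecule_id, mol_ids)
    n_h = formula.get("H", 0)
    if not (formula.get("C") == 1 and formula.get("O") == 1 and formula.get("N") == 2
            and n_h in (3, 4)):
        raise ValueError(
            f"molecule {molecule_id} is not urea-like (formula {formula})"
        )
    bonded = bond_matrix(frame)
    coords = frame.coords
    carbon = atoms[elements[atoms] == "C"][0]
    oxygen = atoms[elements[atoms] == "O"][0]
    nitrogens = atoms[elements[atoms] == "N"]
    out: dict[int, str] = {}
    for n in nitrogens:
        hs = [i for i in np.nonzero(bonded[n])[0] if elements[i] == "H"]
        if len(hs) == 2:
            d = [float(np.linalg.norm(coords[h] - coords[oxygen])) for h in hs]
            prox = hs[int(np.argmin(d))]
            for h in hs:
                out[int(h)] = "proximal" if h == prox else "distal"
        elif len(hs) == 1:
            phi = _dihedral_deg(coords[oxygen], coords[carbon], coords[n], coords[hs[0]])
            out[int(hs[0])] = "proximal" if abs(phi) < 90.0 else "distal"
    return out


def _dihedral_deg(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x, y = np.dot(n1, n2), np.dot(m1, n2)
    return float(np.degrees(np.arctan2(y, x)))


# ---------------------------------------------------------------------------
# QM-region candidate selection
# ---------------------------------------------------------------------------


@dataclass
class QMCandidate:
    frame_index: int
    molecules: tuple[int, int]
    linking_class: str  # proximal | distal | water | other


def select_qm_candidates(
    frames: Sequence[Frame],
    crit: HBondCriterion | None = None,
    mode: Literal["dimer", "monomer_water"] = "dimer",
    n_select: int | None = None,
    seed: int = 0,
) -> list[QMCandidate]:
    """Seeded uniform selection of H-bonded urea dimers or urea-water pairs.

    All molecule pairs satisfying the geometric criterion and the mode's
    composition (urea+urea or urea+water) are pooled over frames; ``n_select``
    of them are drawn uniformly without replacement (all of them if None).
    Each dimer candidate records which hydrogen class links it.
    """
    crit = crit or HBondCriterion()
    pool: list[QMCandidate] = []
    for fi, frame in enumerate(frames):
        mol_ids = _molecule_ids(frame)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bonds = detect_hbonds(frame, crit)
        seen: set[tuple[int, int]] = set()
        for b in bonds:
            md, ma = int(mol_ids[b.donor_atom]), int(mol_ids[b.acceptor_atom])
            pair = (min(md, ma), max(md, ma))
            if pair in seen:
                continue
            fd = molecule_formula(frame, md, mol_ids)
            fa = molecule_formula(frame, ma, mol_ids)
            is_urea_d = fd == UREA_FORMULA
            is_urea_a = fa == UREA_FORMULA
            if mode == "dimer":
                ok = is_urea_d and is_urea_a
            else:
                ok = (is_urea_d and fa == WATER_FORMULA) or (
                    is_urea_a and fd == WATER_FORMULA
                )
            if ok:
                seen.add(pair)
                pool.append(
                    QMCandidate(frame_index=fi, molecules=pair, linking_class=b.donor_class)
                )
    if not pool:
        warnings.warn(f"no qualifying {mode} pair found", stacklevel=2)
        return []
    if n_select is None or n_select >= len(pool):
        return pool
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n_select, replace=False)
    return [pool[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# formation kinetics
# ---------------------------------------------------------------------------


@dataclass
class FormationTimes:
    """First-formation waiting times plus the separately reported edge cases."""

    times: np.ndarray  # fs, first-formation delays of initially unbonded series
    n_bonded_at_t0: int  # series already bonded at the start (waiting time 0)
    n_never_bonded: int  # right-censored series (no formation in the window)


def formation_times(
    presence: np.ndarray, t_grid: np.ndarray
) -> FormationTimes:
    """Waiting time from series start to the first frame with a bond present.

    ``presence`` is (n_series, n_frames) boolean; series bonded at the first
    frame contribute waiting time 0 and are counted separately, series that
    never bond are counted as censored and excluded from ``times``.
    """
    presence = np.asarray(presence, dtype=bool)
    t_grid = np.asarray(t_grid, dtype=float)
    if presence.ndim != 2 or presence.shape[1] != t_grid.size:
        raise ValueError("presence must be (n_series, n_frames) matching t_grid")
    times = []
    n_t0 = 0
    n_never = 0
    for row in presence:
        if row[0]:
            n_t0 += 1
            continue
        idx = np.nonzero(row)[0]
        if idx.size == 0:
            n_never += 1
            continue
        times.append(t_grid[idx[0]] - t_grid[0])
    return FormationTimes(
        times=np.asarray(times, dtype=float), n_bonded_at_t0=n_t0, n_never_bonded=n_never
    )


@dataclass
class BiexpFit:
    tau_fast: float
    tau_fast_se: float
    tau_slow: float
    tau_slow_se: float
    weight_fast: float
    weight_fast_se: float
    loglik: float
    flags: list[str] = field(default_factory=list)


def biexp_loglik(times: np.ndarray, tau_fast: float, tau_slow: float, w: float) -> float:
    """Log-likelihood of the two-exponential mixture at the given parameters."""
    times = np.asarray(times, dtype=float)
    dens = w / tau_fast * np.exp(-times / tau_fast) + (1 - w) / tau_slow * np.exp(
        -times / tau_slow
    )
    return float(np.sum(np.log(np.clip(dens, 1e-300, None))))


def fit_biexponential(times: Iterable[float], min_n: int = 50) -> BiexpFit:
    """Maximum-likelihood fit of ``w Exp(tau_fast) + (1-w) Exp(tau_slow)``.

    Fitted directly on the waiting times (no histogram binning). Standard
    errors come from the observed information (finite-difference Hessian of the
    negative log-likelihood in (log tau_fast, log tau_slow, logit w), delta
    method back to natural scale). A collapsed mixture (components within a
    factor ~2 or a vanishing weight) is flagged.
    """
    t = np.asarray(list(times), dtype=float)
    t = t[t > 0]
    if t.size < min_n:
        raise ValueError(f"need at least {min_n} positive waiting times, got {t.size}")

    def unpack(p):
        return np.exp(p[0]), np.exp(p[1]), 1.0 / (1.0 + np.exp(-p[2]))

    def nll(p):
        tf, ts, w = unpack(p)
        return -biexp_loglik(t, tf, ts, w)

    med = float(np.median(t))
    p0 = np.array([np.log(max(med / 2, 1e-6)), np.log(med * 4), 0.0])
    sol = minimize(nll, p0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    sol = minimize(nll, sol.x, method="BFGS")
    p = sol.x
    tf, ts, w = unpack(p)
    flags: list[str] = []
    if tf > ts:  # enforce fast < slow labelling
        tf, ts, w = ts, tf, 1.0 - w
        p = np.array([np.log(tf), np.log(ts), np.log(w / (1 - w)) if 0 < w < 1 else 0.0])
    if ts / tf < 2.0:
        flags.append("components_collapsed")
    if min(w, 1.0 - w) < 0.05:
        flags.append("degenerate_weight")

    hess = _fd_hessian(nll, p)
    se_nat = np.full(3, np.nan)
    try:
        cov = np.linalg.inv(hess)
        d = np.clip(np.diag(cov), 0, None)
        # delta method: d tau/d log tau = tau ; d w/d logit w = w(1-w)
        se_nat = np.sqrt(d) * np.array([tf, ts, w * (1 - w)])
    except np.linalg.LinAlgError:
        flags.append("covariance_singular")
    return BiexpFit(
        tau_fast=float(tf), tau_fast_se=float(se_nat[0]),
        tau_slow=float(ts), tau_slow_se=float(se_nat[1]),
        weight_fast=float(w), weight_fast_se=float(se_nat[2]),
        loglik=float(-sol.fun), flags=flags,
    )


def _fd_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = x.size
    h = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            fij = f(x + ei + ej) - f(x + ei) - f(x + ej) + f0
            h[i, j] = h[j, i] = fij / eps**2
    return h
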