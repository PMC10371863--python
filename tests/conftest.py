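"""Shared fixtures: idealized molecular geometries and independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from txas.io import Frame
from txas.synthetic import urea_geometry, water_geometry


def rotation_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def combine(*molecules: tuple[list[str], np.ndarray]) -> Frame:
    """Stack molecules into one frame with sequential molecule ids."""
    elements: list[str] = []
    coords: list[np.ndarray] = []
    mol_ids: list[int] = []
    for mid, (els, xyz) in enumerate(molecules):
        elements.extend(els)
        coords.append(xyz)
        mol_ids.extend([mid] * len(els))
    return Frame(
        time=0.0,
        elements=elements,
        coords=np.vstack(coords),
        molecule_ids=np.array(mol_ids),
    )


@pytest.fixture
def urea_frame() -> Frame:
    els, xyz = urea_geometry()
    return Frame(time=0.0, elements=els, coords=xyz, molecule_ids=np.zeros(len(els), int))


def hbonded_pair(partner: str = "urea", d_no: float = 2.9) -> Frame:
    """Urea donating an N-H...O bond to a second urea (or water) at distance d_no.

    The acceptor oxygen sits exactly on the extended N-H axis of a proximal
    urea hydrogen, so the donor-angle is 0 and the geometry passes any sane
    criterion for d_no <= 3 Å.
    """
    els_a, xyz_a = urea_geometry()
    n = xyz_a[2]
    # proximal hydrogen of the first NH2 group (nearer the carbonyl O)
    h_candidates = [4, 5]
    h = xyz_a[min(h_candidates, key=lambda i: np.linalg.norm(xyz_a[i] - xyz_a[1]))]
    u = (h - n) / np.linalg.norm(h - n)
    target_o = n + d_no * u

    if partner == "urea":
        els_b, xyz_b = urea_geometry()
        o_idx, ref_dir = 1, np.array([0.0, -1.0, 0.0])  # O -> C direction
    else:
        els_b, xyz_b = water_geometry()
        o_idx = 0
        bisector = (xyz_b[1] + xyz_b[2]) / 2 - xyz_b[0]
        ref_dir = -bisector / np.linalg.norm(bisector)  # O away from its hydrogens

    ang = math.atan2(u[1], u[0]) - math.atan2(ref_dir[1], ref_dir[0])
    xyz_b = (rotation_z(ang) @ (xyz_b - xyz_b[o_idx]).T).T + target_o
    return combine((els_a, xyz_a), (els_b, xyz_b))


# ---------------------------------------------------------------------------
# independent exhaustive H-bond oracle (plain-Python triple scan)
# ---------------------------------------------------------------------------

_ORACLE_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07}


def oracle_hbonds(frame: Frame, d_max: float, theta_max: float) -> set[tuple[int, int, int]]:
    """Exhaustive O(N^3) scan over donor-H-acceptor triples, written separately
    from the package implementation (plain math, explicit loops)."""
    els = frame.elements
    xyz = frame.coords
    mol = frame.molecule_ids
    assert mol is not None
    n = len(els)

    def dist(i, j):
        return math.dist(xyz[i], xyz[j])

    def covalent(i, j):
        r = 1.2 * (_ORACLE_RADII.get(els[i], 0.75) + _ORACLE_RADII.get(els[j], 0.75))
        return 1e-8 < dist(i, j) <= r

    out: set[tuple[int, int, int]] = set()
    for don in range(n):
        if els[don] not in ("N", "O"):
            continue
        for h in range(n):
            if els[h] != "H" or not covalent(don, h):
                continue
            for acc in range(n):
                if acc == don or els[acc] not in ("N", "O"):
                    continue
                if mol[acc] == mol[don]:
                    continue
                if dist(don, acc) > d_max:
                    continue
                v1 = xyz[h] - xyz[don]
                v2 = xyz[acc] - xyz[don]
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if ang <= theta_max:
                    out.add((don, h, acc))
    return out


def random_fixture_frame(rng: np.random.Generator, max_atoms: int = 30) -> Frame:
    """Random N/O/C/H soup in a 6 Å box with contiguous molecule groups."""
    n = int(rng.integers(4, max_atoms + 1))
    elements = list(rng.choice(["N", "O", "C", "H"], size=n, p=[0.25, 0.25, 0.1, 0.4]))
    coords = rng.uniform(0.0, 6.0, size=(n, 3))
    mol_ids = []
    mid = 0
    while len(mol_ids) < n:
        size = int(rng.integers(1, 6))
        mol_ids.extend([mid] * min(size, n - len(mol_ids)))
        mid += 1
    return Frame(time=0.0, elements=elements, coords=coords, molecule_ids=np.array(mol_ids))
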