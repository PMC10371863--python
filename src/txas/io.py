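"""On-disk representations: XYZ trajectories, transition tables, transient maps.

Conventions
-----------
* Multi-frame XYZ: the standard atom-count / comment / N-atom-lines layout.
  If the comment line contains a ``t= <float>`` token the value is taken as the
  frame time in femtoseconds; otherwise times are synthesised as
  ``frame index * frame_time_step``.  An optional fifth integer column on atom
  lines is read as a molecule id.
* Delimited files are comma-separated with ``#``-prefixed metadata lines.
* Transition-table energies are hartree, dipoles atomic units, times fs.
* Transient-map layout: the first row holds the photon-energy axis (eV), the
  first column holds delays (fs); the top-left cell is empty.

Readers never silently reorder: files with unsorted axes are rejected.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TRANSITION_COLUMNS = ("time", "eps_core", "eps_vac", "dip_x", "dip_y", "dip_z")


class ParseError(ValueError):
    """A file violated the documented on-disk contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Frame:
    """One trajectory snapshot: element labels plus Cartesian coordinates (Å)."""

    time: float  # fs
    elements: list[str]
    coords: np.ndarray  # (N, 3) Å
    molecule_ids: np.ndarray | None = None  # int per atom, or None if unknown

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if len(self.elements) != self.coords.shape[0]:
            raise ValueError(
                f"{len(self.elements)} element labels but "
                f"{self.coords.shape[0]} coordinate rows"
            )
        if self.molecule_ids is not None:
            self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
            if self.molecule_ids.shape != (self.coords.shape[0],):
                raise ValueError("molecule_ids must have one entry per atom")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class TransitionRecord:
    """One core->valence transition stick.

    ``eps_core`` and ``eps_vac`` are orbital energies in hartree for the core
    orbital and the valence vacancy; ``dipole`` is the transition dipole vector
    in atomic units. The core orbital must lie far below the vacancy.
    """

    time: float  # fs
    eps_core: float  # hartree
    eps_vac: float  # hartree
    dipole: np.ndarray  # (3,) a.u.
    traj_id: str = ""
    ion_label: str = "HOMO"  # HOMO | HOMO-3 | other
    system_label: str = "dimer"  # dimer | monomer_water

    def __post_init__(self) -> None:
        self.dipole = np.asarray(self.dipole, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.dipole)):
            raise ValueError("dipole components must be finite")
        if not self.eps_core < self.eps_vac:
            raise ValueError(
                f"eps_core ({self.eps_core}) must be below eps_vac ({self.eps_vac})"
            )

    @property
    def dipole_sq(self) -> float:
        """|<phi_f|d|phi_i>|^2, the squared norm of the dipole vector (a.u.)."""
        return float(np.dot(self.dipole, self.dipole))


@dataclass
class TransientMap:
    """Delay-stacked spectra: ``values[i, j]`` at ``delays[i]``, ``energies[j]``.

    ``kind`` flags the physical content: ``"sigma"`` for absorption
    cross-sections (atomic units, nonnegative) or ``"dod"`` for pump-induced
    optical-density changes (either sign).
    """

    delays: np.ndarray  # fs, ascending
    energies: np.ndarray  # eV, ascending
    values: np.ndarray  # (n_delays, n_energies)
    kind: str = "sigma"

    def __post_init__(self) -> None:
        self.delays = np.atleast_1d(np.asarray(self.delays, dtype=float))
        self.energies = np.atleast_1d(np.asarray(self.energies, dtype=float))
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (self.delays.size, self.energies.size):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{self.delays.size} delays x {self.energies.size} energies"
            )
        if self.delays.size > 1 and not np.all(np.diff(self.delays) > 0):
            raise ValueError("delays must be strictly ascending")
        if self.energies.size > 1 and not np.all(np.diff(self.energies) > 0):
            raise ValueError("energies must be strictly ascending")
        if self.kind not in ("sigma", "dod"):
            raise ValueError(f"unknown map kind: {self.kind!r}")

    def copy(self) -> "TransientMap":
        return TransientMap(
            self.delays.copy(), self.energies.copy(), self.values.copy(), self.kind
        )


# ---------------------------------------------------------------------------
# XYZ trajectories
# ---------------------------------------------------------------------------


def _parse_time_token(comment: str) -> float | None:
    """Extract a ``t= <float>`` (fs) token from an XYZ comment line, if any."""
    tokens = comment.split()
    for i, tok in enumerate(tokens):
        if tok == "t=" and i + 1 < len(tokens):
            try:
                return float(tokens[i + 1])
            except ValueError:
                return None
        if tok.startswith("t=") and len(tok) > 2:
            try:
                return float(tok[2:])
            except ValueError:
                return None
    return None


def read_xyz_trajectory(path: str | Path, frame_time_step: float = 0.5) -> list[Frame]:
    """Read a multi-frame XYZ file into a list of :class:`Frame`.

    Parameters
    ----------
    path
        Multi-frame XYZ file (atom-count line, comment line, N atom lines).
    frame_time_step
        Frame spacing in fs, used when the comment line carries no ``t=`` token.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    pos = 0
    n_expected: int | None = None
    while pos < len(lines):
        if not lines[pos].strip():  # tolerate trailing blank lines
            pos += 1
            continue
        frame_idx = len(frames)
        try:
            n_atoms = int(lines[pos].strip())
        except ValueError as exc:
            raise ParseError(
                f"frame {frame_idx}: malformed atom-count line {lines[pos]!r}"
            ) from exc
        if n_expected is not None and n_atoms != n_expected:
            raise ParseError(
                f"frame {frame_idx}: atom count {n_atoms} differs from "
                f"first frame ({n_expected})"
            )
        n_expected = n_atoms
        if pos + 1 + n_atoms >= len(lines) + 1:
            raise ParseError(f"frame {frame_idx}: truncated (expected {n_atoms} atoms)")
        comment = lines[pos + 1]
        elements: list[str] = []
        coords = np.empty((n_atoms, 3))
        mol_ids: list[int] = []
        for j in range(n_atoms):
            parts = lines[pos + 2 + j].split()
            if len(parts) < 4:
                raise ParseError(f"frame {frame_idx}, atom {j}: malformed atom line")
            elements.append(parts[0])
            try:
                coords[j] = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise ParseError(
                    f"frame {frame_idx}, atom {j}: non-numeric coordinate"
                ) from exc
            if len(parts) >= 5:
                mol_ids.append(int(parts[4]))
        t = _parse_time_token(comment)
        if t is None:
            t = frame_idx * frame_time_step
        frames.append(
            Frame(
                time=t,
                elements=elements,
                coords=coords,
                molecule_ids=np.array(mol_ids) if len(mol_ids) == n_atoms else None,
            )
        )
        pos += 2 + n_atoms
    if not frames:
        warnings.warn(f"{path}: empty XYZ file, returning no frames", stacklevel=2)
    return frames


def write_xyz_trajectory(frames: Sequence[Frame], path: str | Path) -> None:
    """Write frames as multi-frame XYZ with ``t=`` time tokens (and molecule ids
    as a fifth column when present)."""
    out = []
    for fr in frames:
        out.append(str(fr.n_atoms))
        out.append(f"t= {fr.time:.6f}")
        for i in range(fr.n_atoms):
            x, y, z = fr.coords[i]
            line = f"{fr.elements[i]} {x:.10f} {y:.10f} {z:.10f}"
            if fr.molecule_ids is not None:
                line += f" {fr.molecule_ids[i]}"
            out.append(line)
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# transition tables
# ---------------------------------------------------------------------------


def read_transition_table(path: str | Path) -> list[TransitionRecord]:
    """Read a CSV transition table into :class:`TransitionRecord` objects.

    Required columns: ``time, eps_core, eps_vac, dip_x, dip_y, dip_z``.
    Optional: ``traj_id, ion_label, system_label``. Lines starting with ``#``
    are metadata. Units follow the package convention (fs / hartree / a.u.).
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRANSITION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError("missing column: " + ", ".join(missing))
    records: list[TransitionRecord] = []
    for idx, row in df.iterrows():
        vals = {}
        for c in TRANSITION_COLUMNS:
            try:
                vals[c] = float(row[c])
            except (TypeError, ValueError) as exc:
                raise ParseError(f"row {idx}: non-numeric value in column {c!r}") from exc
        records.append(
            TransitionRecord(
                time=vals["time"],
                eps_core=vals["eps_core"],
                eps_vac=vals["eps_vac"],
                dipole=np.array([vals["dip_x"], vals["dip_y"], vals["dip_z"]]),
                traj_id=str(row["traj_id"]) if "traj_id" in df.columns else "",
                ion_label=str(row["ion_label"]) if "ion_label" in df.columns else "HOMO",
                system_label=(
                    str(row["system_label"]) if "system_label" in df.columns else "dimer"
                ),
            )
        )
    return records


def write_transition_table(records: Iterable[TransitionRecord], path: str | Path) -> None:
    """Write records as CSV (fs / hartree / a.u., ``#`` metadata header)."""
    rows = [
        {
            "time": r.time,
            "eps_core": r.eps_core,
            "eps_vac": r.eps_vac,
            "dip_x": r.dipole[0],
            "dip_y": r.dipole[1],
            "dip_z": r.dipole[2],
            "traj_id": r.traj_id,
            "ion_label": r.ion_label,
            "system_label": r.system_label,
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write("# txas transition table; units: time=fs energies=hartree dipole=au\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# transient maps
# ---------------------------------------------------------------------------


def write_transient_map(tmap: TransientMap, path: str | Path) -> None:
    """Write a map as CSV: first row energies (eV), first column delays (fs)."""
    # TransientMap validates invariants on construction; re-validate in case the
    # arrays were mutated after construction.
    TransientMap(tmap.delays, tmap.energies, tmap.values, tmap.kind)
    with open(path, "w") as fh:
        fh.write(f"# txas transient map; kind={tmap.kind}\n")
        fh.write("," + ",".join(f"{e:.10g}" for e in tmap.energies) + "\n")
        for i, d in enumerate(tmap.delays):
            fh.write(
                f"{d:.10g}," + ",".join(f"{v:.10g}" for v in tmap.values[i]) + "\n"
            )


def read_transient_map(path: str | Path) -> TransientMap:
    """Read a map written by :func:`write_transient_map` (unsorted axes rejected)."""
    kind = "sigma"
    rows: list[list[str]] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if "kind=" in line:
                kind = line.split("kind=")[1].strip()
            continue
        if line.strip():
            rows.append(line.split(","))
    if not rows:
        raise ParseError(f"{path}: no data rows")
    energies = np.array([float(x) for x in rows[0][1:]])
    delays = np.array([float(r[0]) for r in rows[1:]])
    values = np.array([[float(x) for x in r[1:]] for r in rows[1:]])
    return TransientMap(delays=delays, energies=energies, values=values, kind=kind)


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
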