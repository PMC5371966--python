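"""Shared data model, trajectory/topology I/O and statistical utilities.

Units are fixed package-wide: lengths in nm, times in ps, energies in
kJ·mol⁻¹, charges in units of the elementary charge, temperatures in K.
Conversions to SI (J, V) happen only where a result is conventionally
reported in SI (bending stiffness, electrostatic potential).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Recognized atom-group tags.
KNOWN_TAGS = frozenset(
    {
        "water_oxygen",
        "phosphorus",
        "tail_carbon",
        "carbonyl_oxygen",
        "phosphate_oxygen",
        "na_ion",
        "cl_ion",
        "lipid",
        "water",
        "junction_carbon",
    }
)


class TrajectoryParseError(ValueError):
    """Malformed trajectory file (names the offending line where possible)."""


class ConfigurationError(ValueError):
    """Input configuration violates a precondition (e.g. no lipid atoms)."""


@dataclass(frozen=True)
class Frame:
    """One trajectory frame: coordinates plus the orthorhombic box.

    Attributes
    ----------
    time : float
        Time stamp in ps.
    coords : (N, 3) ndarray
        Cartesian coordinates in nm.
    box : (3,) ndarray
        Box edge lengths (L_x, L_y, L_z) in nm; all positive.
    """

    time: float
    coords: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        box = np.asarray(self.box, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {coords.shape}")
        if box.shape != (3,):
            raise ValueError(f"box must be length-3, got {box.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords contain non-finite values")
        if not np.all(box > 0):
            raise ValueError(f"box edges must be positive, got {box}")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "box", box)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Topology:
    """Per-atom metadata: names, types, charges, molecules, group tags, leaflets.

    ``tags`` holds one set of group labels per atom (non-exclusive);
    ``leaflet`` is 'upper', 'lower' or 'none' per atom.
    """

    atom_name: np.ndarray
    atom_type: np.ndarray
    charge: np.ndarray
    mol_id: np.ndarray
    tags: list[set]
    leaflet: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.atom_name)
        self.atom_name = np.asarray(self.atom_name, dtype=object)
        self.atom_type = np.asarray(self.atom_type, dtype=object)
        self.charge = np.asarray(self.charge, dtype=float)
        self.mol_id = np.asarray(self.mol_id, dtype=int)
        if not np.all(np.isfinite(self.charge)):
            raise ValueError("charges must be finite")
        for arr in (self.atom_type, self.charge, self.mol_id):
            if len(arr) != n:
                raise ValueError("topology columns have inconsistent lengths")
        if len(self.tags) != n:
            raise ValueError("tags length mismatch")
        self.tags = [set(t) for t in self.tags]
        if self.leaflet is None:
            self.leaflet = np.array(["none"] * n, dtype=object)
        else:
            self.leaflet = np.asarray(self.leaflet, dtype=object)
            if len(self.leaflet) != n:
                raise ValueError("leaflet length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def select(self, tag: str) -> np.ndarray:
        """Boolean mask of atoms carrying ``tag``."""
        return np.fromiter((tag in t for t in self.tags), dtype=bool, count=self.n_atoms)

    def copy(self) -> "Topology":
        return Topology(
            atom_name=self.atom_name.copy(),
            atom_type=self.atom_type.copy(),
            charge=self.charge.copy(),
            mol_id=self.mol_id.copy(),
            tags=[set(t) for t in self.tags],
            leaflet=self.leaflet.copy(),
        )


@dataclass(frozen=True)
class Constants:
    """Physical constants and the thermal energy scale at temperature ``T``."""

    T: float = 300.0
    k_B: float = 0.00831446  # kJ·mol⁻¹·K⁻¹
    N_A: float = 6.02214076e23  # mol⁻¹
    # e/(ε0·1 nm): volts per unit of (e·nm⁻¹), for charge-density double
    # integration.  e = 1.602176634e-19 C, ε0 = 8.8541878128e-12 F·m⁻¹.
    e_over_eps0_nm: float = 1.602176634e-19 / 8.8541878128e-12 * 1e9
    # kJ·mol⁻¹ per e·V (Faraday constant / 1000)
    kjmol_per_eV: float = 96.485

    @property
    def kT(self) -> float:
        """Thermal energy k_B·T in kJ·mol⁻¹ (≈2.494 at 300 K)."""
        return self.k_B * self.T

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(k_B T) in mol·kJ⁻¹."""
        return 1.0 / self.kT

    @property
    def kT_joule(self) -> float:
        """Thermal energy per molecule in J."""
        return self.kT * 1e3 / self.N_A


@dataclass(frozen=True)
class ScalarWithError:
    """A value with its statistical uncertainty and the method that produced it."""

    value: float
    error: float = 0.0
    method: str = "none"  # block | halves | propagation | none

    def __post_init__(self) -> None:
        if not np.isfinite(self.error) or self.error < 0:
            raise ValueError(f"error must be finite and ≥ 0, got {self.error}")
        if self.method not in {"block", "halves", "propagation", "none"}:
            raise ValueError(f"unknown error method {self.method!r}")


# --------------------------------------------------------------------------
# Trajectory I/O: GRO-style fixed width, and plain XYZ-with-box text.
# --------------------------------------------------------------------------

def read_trajectory(path, format_hint: str | None = None,
                    topology: Topology | None = None) -> list[Frame]:
    """Read a (possibly multi-frame) coordinate file into a list of Frames.

    Two text dialects are supported: GRO-style fixed-width frames terminated
    by a box line, and XYZ-with-box (atom count line, then a comment carrying
    ``time= <ps> box= <Lx> <Ly> <Lz>``, then ``name x y z`` rows).  The
    dialect is inferred from the extension unless ``format_hint`` ('gro' or
    'xyz') is given.  Frames must share one atom count; when a topology is
    supplied the count is validated against it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint or ("xyz" if path.suffix.lower() == ".xyz" else "gro")
    lines = path.read_text().splitlines()
    frames = _parse_gro(lines) if fmt == "gro" else _parse_xyz(lines)
    if not frames:
        raise TrajectoryParseError(f"{path}: no frames found")
    n0 = frames[0].n_atoms
    for i, fr in enumerate(frames):
        if fr.n_atoms != n0:
            raise TrajectoryParseError(
                f"{path}: frame {i} has {fr.n_atoms} atoms, expected {n0}")
    if topology is not None and topology.n_atoms != n0:
        raise TrajectoryParseError(
            f"{path}: {n0} atoms per frame but topology lists {topology.n_atoms}")
    return frames


def _parse_gro(lines: Sequence[str]) -> list[Frame]:
    frames: list[Frame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        time = 0.0
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (IndexError, ValueError):
                pass
        if i + 1 >= len(lines):
            raise TrajectoryParseError(f"line {i + 1}: truncated frame header")
        try:
            n = int(lines[i + 1].strip())
        except ValueError as exc:
            raise TrajectoryParseError(
                f"line {i + 2}: expected atom count, got {lines[i + 1]!r}") from exc
        last = i + 1 + n
        if last + 1 >= len(lines):
            raise TrajectoryParseError(f"line {i + 2}: frame with missing box line")
        coords = np.empty((n, 3))
        for k in range(n):
            ln = lines[i + 2 + k]
            try:
                # fixed columns: resid/name(20) then three 8.3f position fields
                coords[k, 0] = float(ln[20:28])
                coords[k, 1] = float(ln[28:36])
                coords[k, 2] = float(ln[36:44])
            except (ValueError, IndexError) as exc:
                raise TrajectoryParseError(
                    f"line {i + 3 + k}: malformed coordinate row {ln!r}") from exc
        box_fields = lines[last + 1].split()
        if len(box_fields) < 3:
            raise TrajectoryParseError(f"line {last + 2}: malformed box line")
        box = np.array([float(x) for x in box_fields[:3]])
        frames.append(Frame(time=time, coords=coords, box=box))
        i = last + 2
    return frames


def _parse_xyz(lines: Sequence[str]) -> list[Frame]:
    frames: list[Frame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryParseError(
                f"line {i + 1}: expected atom count, got {lines[i]!r}") from exc
        if i + 1 >= len(lines):
            raise TrajectoryParseError(f"line {i + 1}: truncated frame")
        comment = lines[i + 1]
        if "box=" not in comment:
            raise TrajectoryParseError(f"line {i + 2}: frame with missing box entry")
        time = 0.0
        if "time=" in comment:
            time = float(comment.split("time=")[1].split()[0])
        box = np.array([float(x) for x in comment.split("box=")[1].split()[:3]])
        if i + 1 + n >= len(lines) + 1 or i + 1 + n > len(lines):
            raise TrajectoryParseError(f"line {i + 1}: truncated frame body")
        coords = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise TrajectoryParseError(
                    f"line {i + 3 + k}: malformed atom row {lines[i + 2 + k]!r}")
            coords[k] = [float(p) for p in parts[1:4]]
        frames.append(Frame(time=time, coords=coords, box=box))
        i = i + 2 + n
    return frames


def write_trajectory(path, frames: Iterable[Frame],
                     topology: Topology | None = None,
                     fmt: str | None = None) -> None:
    """Write frames as multi-frame GRO (default) or XYZ-with-box text."""
    path = Path(path)
    fmt = fmt or ("xyz" if path.suffix.lower() == ".xyz" else "gro")
    out: list[str] = []
    for fr in frames:
        if fmt == "gro":
            out.append(f"memsalt frame t= {fr.time:.3f}")
            out.append(f"{fr.n_atoms:5d}")
            for k in range(fr.n_atoms):
                name = topology.atom_name[k] if topology is not None else "X"
                resid = int(topology.mol_id[k]) % 100000 if topology is not None else 1
                x, y, z = fr.coords[k]
                out.append(f"{resid:5d}{'MOL':<5s}{name:>5s}{(k % 100000) + 1:5d}"
                           f"{x:8.3f}{y:8.3f}{z:8.3f}")
            out.append(f"  {fr.box[0]:.5f}  {fr.box[1]:.5f}  {fr.box[2]:.5f}")
        else:
            out.append(str(fr.n_atoms))
            out.append(f"time= {fr.time:.3f} box= "
                       f"{fr.box[0]:.6f} {fr.box[1]:.6f} {fr.box[2]:.6f}")
            for k in range(fr.n_atoms):
                name = topology.atom_name[k] if topology is not None else "X"
                x, y, z = fr.coords[k]
                out.append(f"{name} {x:.6f} {y:.6f} {z:.6f}")
    path.write_text("\n".join(out) + "\n")


# --------------------------------------------------------------------------
# Topology I/O (TSV)
# --------------------------------------------------------------------------

def read_topology(path) -> Topology:
    """Read a topology TSV: atom_index, atom_name, atom_type, charge, mol_id,
    tags (semicolon-separated), leaflet."""
    df = pd.read_csv(path, sep="\t", dtype={"tags": str, "leaflet": str})
    df = df.sort_values("atom_index")
    tags = [set(t.split(";")) - {""} if isinstance(t, str) else set()
            for t in df["tags"].fillna("")]
    return Topology(
        atom_name=df["atom_name"].to_numpy(),
        atom_type=df["atom_type"].to_numpy(),
        charge=df["charge"].to_numpy(),
        mol_id=df["mol_id"].to_numpy(),
        tags=tags,
        leaflet=df["leaflet"].fillna("none").to_numpy(),
    )


def write_topology(path, top: Topology) -> None:
    df = pd.DataFrame(
        {
            "atom_index": np.arange(top.n_atoms),
            "atom_name": top.atom_name,
            "atom_type": top.atom_type,
            "charge": top.charge,
            "mol_id": top.mol_id,
            "tags": [";".join(sorted(t)) for t in top.tags],
            "leaflet": top.leaflet,
        }
    )
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Membrane centering and leaflet assignment
# --------------------------------------------------------------------------

def center_membrane(frames: Sequence[Frame], topology: Topology) -> list[Frame]:
    """Shift each frame along z so the lipid slab is contiguous and centered.

    The bilayer may be split across the periodic z boundary; a candidate
    shift minimizing the wrapped lipid z-extent is found by a bin scan, the
    lipid mean z after unwrapping is subtracted, and all z coordinates are
    remapped into [−L_z/2, L_z/2).  x and y are untouched.
    """
    lipid = topology.select("lipid")
    if not lipid.any():
        raise ConfigurationError("no atoms tagged 'lipid'; cannot center membrane")
    out = []
    for fr in frames:
        lz = fr.box[2]
        z = fr.coords[:, 2].copy()
        zl = np.mod(z[lipid], lz)
        # scan candidate origins: choose the wrap origin minimizing lipid extent
        candidates = np.linspace(0.0, lz, 64, endpoint=False)
        spans = [np.ptp(np.mod(zl - c, lz)) for c in candidates]
        c = candidates[int(np.argmin(spans))]
        unwrapped = np.mod(zl - c, lz)
        shift = c + unwrapped.mean()  # lipid mean z in original coordinates
        znew = np.mod(z - shift + lz / 2.0, lz) - lz / 2.0
        coords = fr.coords.copy()
        coords[:, 2] = znew
        out.append(replace(fr, coords=coords))
    return out


def assign_leaflets(frame: Frame, topology: Topology) -> Topology:
    """Assign each lipid molecule to the upper (P z > 0) or lower leaflet.

    Requires a centered frame.  The phosphorus atom of each lipid decides;
    z exactly 0 goes to the lower leaflet (documented tie-break).  Returns a
    new Topology with the ``leaflet`` column filled for all lipid atoms.
    """
    top = topology.copy()
    lipid = top.select("lipid")
    phos = top.select("phosphorus")
    lipid_mols = np.unique(top.mol_id[lipid])
    z = frame.coords[:, 2]
    n_upper = 0
    for mol in lipid_mols:
        in_mol = top.mol_id == mol
        p_idx = np.flatnonzero(in_mol & phos)
        if p_idx.size == 0:
            raise ConfigurationError(f"lipid molecule {mol} has no phosphorus atom")
        side = "upper" if z[p_idx[0]] > 0 else "lower"
        if side == "upper":
            n_upper += 1
        top.leaflet[in_mol] = side
    if n_upper == 0 or n_upper == len(lipid_mols):
        logger.warning("all lipids assigned to one leaflet (monolayer?)")
    return top


# --------------------------------------------------------------------------
# Statistical error utilities
# --------------------------------------------------------------------------

def block_average_error(series, n_blocks: range | None = None) -> ScalarWithError:
    """Mean and block-averaging standard error of a correlated time series.

    The series is split into n equal blocks for each n in the scan (default
    5..20); the reported error is the maximum over the scan of the standard
    error of the block means, which approximates the plateau of the
    block-error curve for correlated data.
    """
    x = np.asarray(series, dtype=float)
    scan = n_blocks if n_blocks is not None else range(5, 21)
    min_blocks = min(scan)
    if x.size < 2 * min_blocks:
        raise ValueError(
            f"series of length {x.size} too short for {min_blocks} blocks")
    errors = []
    for nb in scan:
        if x.size < 2 * nb:
            continue
        usable = (x.size // nb) * nb
        blocks = x[:usable].reshape(nb, -1).mean(axis=1)
        errors.append(blocks.std(ddof=1) / np.sqrt(nb))
    return ScalarWithError(value=float(x.mean()), error=float(max(errors)),
                           method="block")


def halves_error(a, b=None) -> ScalarWithError:
    """Two-sample (simulation-halves) estimate: mean of the halves, error
    = stdev of the two halves / √2 = |a − b| / 2.

    Accepts either two half-estimates or a single series that is split in two
    and averaged half-wise.
    """
    if b is None:
        x = np.asarray(a, dtype=float)
        if x.size < 2:
            raise ValueError("need at least 2 samples to form halves")
        h = x.size // 2
        a, b = x[:h].mean(), x[h: 2 * h].mean()
    a, b = float(a), float(b)
    return ScalarWithError(value=(a + b) / 2.0, error=abs(a - b) / 2.0,
                           method="halves")
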