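"""Trajectory stability metrics.

Implements the four standard MD stability observables over multi-model
coordinate ensembles sharing a topology:

* RMSD per frame after optimal least-squares (Kabsch) superposition onto a
  reference, in Angstrom;
* per-residue RMSF about the iteratively refined mean structure, Angstrom;
* radius of gyration (mass-weighted by default), reported in nm;
* Shrake-Rupley solvent-accessible surface area, reported in nm^2.

Internal coordinates are Angstrom throughout; Rg and SASA are converted to
nm / nm^2 at the reporting boundary to match the conventions of MD analysis
plots. Trajectories are read and written as multi-model PDB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from . import _chem
from .structure import (
    Atom,
    PDBParseError,
    Residue,
    ResidueKey,
    Structure,
    _format_atom_record,
    structure_from_gemmi_model,
)

AtomPredicate = Callable[[Atom, Residue], bool]
Selection = str | AtomPredicate

A_PER_NM = 10.0


class DegenerateGeometryError(ValueError):
    """Raised when a point set is too degenerate for superposition."""


@dataclass
class Trajectory:
    topology: Structure
    coords: np.ndarray          # (n_frames, n_atoms, 3), Angstrom
    times: np.ndarray           # ps, strictly increasing

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"coords must have shape (n_frames, {self.topology.n_atoms}, 3)")
        if len(self.times) != len(self.coords):
            raise ValueError("one time per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    def frame_structure(self, index: int) -> Structure:
        return self.topology.with_coords(self.coords[index])


@dataclass
class SeriesResult:
    metric: Literal["rmsd", "rg", "sasa"]
    values: np.ndarray
    units: str
    times: np.ndarray
    reference_note: str = ""


@dataclass
class RMSFProfile:
    values: dict[ResidueKey, float]   # residue key -> RMSF, Angstrom
    selection_note: str = ""

    def by_number(self) -> dict[int, float]:
        return {key[1]: v for key, v in self.values.items()}


# ---------------------------------------------------------------------------
# Selections


def _predicate(selection: Selection) -> AtomPredicate:
    if callable(selection):
        return selection
    named: dict[str, AtomPredicate] = {
        "ca": lambda a, r: a.name == "CA" and a.is_heavy,
        "backbone": lambda a, r: a.is_backbone and a.is_heavy,
        "heavy": lambda a, r: a.is_heavy,
        "all": lambda a, r: True,
    }
    try:
        return named[selection]
    except KeyError:
        raise ValueError(f"unknown selection {selection!r}; "
                         f"expected one of {sorted(named)}") from None


def selection_indices(s: Structure, selection: Selection) -> np.ndarray:
    pred = _predicate(selection)
    idx, i = [], 0
    for res in s.residues:
        for atom in res.atoms:
            if pred(atom, res):
                idx.append(i)
            i += 1
    if not idx:
        raise ValueError("selection matches no atoms")
    return np.asarray(idx, dtype=int)


# ---------------------------------------------------------------------------
# Superposition


def kabsch_superpose(
    mobile: np.ndarray,
    ref: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal least-squares rigid superposition of ``mobile`` onto ``ref``.

    Returns ``(R, t, rmsd)`` with the proper rotation R (det +1) and
    translation t minimizing sum w_i ||R m_i + t - r_i||^2;
    rmsd = sqrt(sum w_i ||.||^2 / sum w_i) in the input length unit.
    """
    mobile = np.asarray(mobile, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if mobile.shape != ref.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and ref must both have shape (n, 3)")
    n = len(mobile)
    if n < 3:
        raise ValueError("at least 3 points are required for superposition")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()

    cm = w @ mobile
    cr = w @ ref
    m0 = mobile - cm
    r0 = ref - cr
    h = (m0 * w[:, None]).T @ r0
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-10 * max(s[0], 1e-30):
        raise DegenerateGeometryError(
            "point set is (near-)collinear; rotation is not determined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cr - rot @ cm
    resid = (m0 @ rot.T) - r0
    msd = float(np.sum(w * np.sum(resid ** 2, axis=1)))
    return rot, t, float(np.sqrt(max(msd, 0.0)))


def coordinate_rmsd(
    a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """RMSD between two already-aligned coordinate sets (no superposition):
    sqrt(sum w_i ||a_i - b_i||^2 / sum w_i)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate sets must have equal shape")
    if weights is None:
        w = np.full(len(a), 1.0 / len(a))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    return float(np.sqrt(np.sum(w * ((a - b) ** 2).sum(axis=1))))


def rmsd_series(
    traj: Trajectory,
    ref: Structure | np.ndarray | str = "first_frame",
    selection: Selection = "ca",
) -> SeriesResult:
    """Per-frame RMSD (A) of the selection after Kabsch superposition onto
    the reference selection (default: the first frame)."""
    idx = selection_indices(traj.topology, selection)
    if isinstance(ref, str):
        if ref != "first_frame":
            raise ValueError("ref must be 'first_frame', a Structure, or coordinates")
        ref_coords = traj.coords[0][idx]
        note = "reference: first frame"
    elif isinstance(ref, Structure):
        ref_coords = ref.coord_matrix()[selection_indices(ref, selection)]
        note = f"reference: structure {ref.id!r}"
    else:
        ref_coords = np.asarray(ref, dtype=float)[idx]
        note = "reference: supplied coordinates"
    values = np.array([
        kabsch_superpose(frame[idx], ref_coords)[2] for frame in traj.coords
    ])
    return SeriesResult(metric="rmsd", values=values, units="A",
                        times=traj.times.copy(), reference_note=note)


def rmsf_per_residue(
    traj: Trajectory,
    selection: Selection = "ca",
    equilibration_skip: int = 0,
    max_iterations: int = 10,
    drift_tol: float = 1e-6,
) -> RMSFProfile:
    """Per-residue RMSF (A) about the iteratively refined mean structure.

    Frames are superposed onto the running mean of the selection, the mean
    is recomputed, and the cycle repeats until the mean drifts less than
    ``drift_tol`` A (or ``max_iterations``). RMSF_i = sqrt(<|r_i - <r_i>|^2>)
    per selected atom, averaged per residue.
    """
    idx = selection_indices(traj.topology, selection)
    frames = traj.coords[equilibration_skip:]
    if len(frames) < 2:
        raise ValueError("at least 2 frames are required after equilibration skip")

    sel = frames[:, idx, :]
    mean = sel[0].copy()
    aligned = sel.copy()
    for _ in range(max_iterations):
        for f in range(len(sel)):
            rot, t, _ = kabsch_superpose(sel[f], mean)
            aligned[f] = sel[f] @ rot.T + t
        new_mean = aligned.mean(axis=0)
        drift = float(np.abs(new_mean - mean).max())
        mean = new_mean
        if drift < drift_tol:
            break

    per_atom = np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))

    atoms = list(traj.topology.atoms())
    per_res: dict[ResidueKey, list[float]] = {}
    for sel_pos, atom_index in enumerate(idx):
        key = atoms[atom_index].residue_ref
        per_res.setdefault(key, []).append(per_atom[sel_pos])
    values = {key: float(np.mean(v)) for key, v in per_res.items()}
    note = selection if isinstance(selection, str) else "custom predicate"
    return RMSFProfile(values=values, selection_note=f"selection: {note}")


# ---------------------------------------------------------------------------
# Radius of gyration


def radius_of_gyration(
    coords: np.ndarray, masses: np.ndarray | None = None
) -> float:
    """Rg in the input length unit: sqrt(sum m_i |r_i - r_com|^2 / sum m_i)."""
    coords = np.asarray(coords, dtype=float)
    if masses is None:
        m = np.ones(len(coords))
    else:
        m = np.asarray(masses, dtype=float)
    total = m.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (m[:, None] * coords).sum(axis=0) / total
    return float(np.sqrt((m * ((coords - com) ** 2).sum(axis=1)).sum() / total))


def gyration_series(traj: Trajectory, mass_weighted: bool = True) -> SeriesResult:
    """Per-frame radius of gyration, reported in nm."""
    if mass_weighted:
        masses = np.array([
            _chem.element_mass(a.element) for a in traj.topology.atoms()
        ])
    else:
        masses = None
    values = np.array([
        radius_of_gyration(frame, masses) for frame in traj.coords
    ]) / A_PER_NM
    return SeriesResult(metric="rg", values=values, units="nm",
                        times=traj.times.copy(),
                        reference_note="mass-weighted" if mass_weighted else "unweighted")


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5 ** 0.5) * k
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


@dataclass
class SASAResult:
    total: float                       # nm^2
    per_residue: dict[ResidueKey, float] = field(default_factory=dict)  # nm^2
    per_atom: np.ndarray | None = None  # A^2, heavy atoms in roster order


def shrake_rupley_sasa(
    frame: Structure,
    probe: float = 1.4,
    n_points: int = 960,
    fallback_radius: float | None = None,
) -> SASAResult:
    """Shrake-Rupley solvent-accessible surface area of one structure.

    For each heavy atom, ``n_points`` quasi-uniform points are placed on the
    sphere of radius r_vdw + probe; the exposed fraction (points not buried
    inside any neighbouring atom's expanded sphere) times 4 pi r^2 is the
    atom's SASA. Totals are reported in nm^2 (computed internally in A^2).
    Unknown elements fall back to a configurable radius with a warning.
    """
    atoms = [a for a in frame.atoms() if a.is_heavy]
    if not atoms:
        raise ValueError("structure has no heavy atoms")
    coords = np.array([a.coords for a in atoms])
    radii = np.empty(len(atoms))
    for i, a in enumerate(atoms):
        el = a.element.upper()
        if el not in _chem.VDW_RADII:
            warnings.warn(
                f"no vdW radius for element {a.element!r}; using fallback",
                stacklevel=2)
        radii[i] = _chem.element_radius(el, fallback=fallback_radius)
    expanded = radii + probe

    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.zeros(len(atoms))
    for i in range(len(atoms)):
        neighbors = [
            j for j in tree.query_ball_point(coords[i], expanded[i] + max_reach / 2.0)
            if j != i
            and np.linalg.norm(coords[j] - coords[i]) < expanded[i] + expanded[j]
        ]
        pts = coords[i] + expanded[i] * unit
        if neighbors:
            ncoords = coords[neighbors]
            nradii = expanded[neighbors]
            d2 = ((pts[:, None, :] - ncoords[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nradii ** 2)[None, :]).any(axis=1)
            exposed_frac = 1.0 - buried.mean()
        else:
            exposed_frac = 1.0
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * exposed_frac

    per_residue: dict[ResidueKey, float] = {}
    for a, area in zip(atoms, areas):
        per_residue[a.residue_ref] = per_residue.get(a.residue_ref, 0.0) + area
    nm2 = 1.0 / (A_PER_NM ** 2)
    return SASAResult(
        total=float(areas.sum()) * nm2,
        per_residue={k: v * nm2 for k, v in per_residue.items()},
        per_atom=areas,
    )


def sasa_series(
    traj: Trajectory, probe: float = 1.4, n_points: int = 960
) -> SeriesResult:
    """Per-frame total SASA (nm^2)."""
    values = np.array([
        shrake_rupley_sasa(traj.frame_structure(f), probe=probe, n_points=n_points).total
        for f in range(traj.n_frames)
    ])
    return SeriesResult(metric="sasa", values=values, units="nm^2",
                        times=traj.times.copy(),
                        reference_note=f"probe {probe} A, {n_points} points")


# ---------------------------------------------------------------------------
# Region statistics


@dataclass
class RegionStats:
    name: str
    mean: float
    max: float
    delta_mean: float | None = None  # other - this, when a second profile is given


def region_stats(
    profile: RMSFProfile,
    regions: dict[str, tuple[int, int]],
    other: RMSFProfile | None = None,
) -> dict[str, RegionStats]:
    """Mean/max RMSF over named residue-number ranges (inclusive), with the
    per-region mean difference when a second profile (e.g. a variant) is
    supplied: delta_mean = mean(other) - mean(profile)."""
    by_num = profile.by_number()
    other_by_num = other.by_number() if other is not None else None
    out: dict[str, RegionStats] = {}
    for name, (start, end) in regions.items():
        numbers = [n for n in by_num if start <= n <= end]
        if not numbers:
            raise ValueError(f"region {name!r} ({start}-{end}) has no residues "
                             "in the profile")
        vals = [by_num[n] for n in numbers]
        delta = None
        if other_by_num is not None:
            common = [n for n in numbers if n in other_by_num]
            if not common:
                raise ValueError(f"region {name!r} absent from comparison profile")
            delta = float(np.mean([other_by_num[n] for n in common])
                          - np.mean([by_num[n] for n in common]))
        out[name] = RegionStats(name=name, mean=float(np.mean(vals)),
                                max=float(np.max(vals)), delta_mean=delta)
    return out


# ---------------------------------------------------------------------------
# Multi-model PDB I/O


def read_trajectory(
    pdb_text: str,
    dt_ps: float = 100.0,
    altloc_policy: str = "highest_occupancy",
    include_hetero: bool = False,
) -> Trajectory:
    """Read a multi-model PDB file as a trajectory (one MODEL per frame).

    The first model defines the topology; every model must carry the same
    atom count. Frame times are 0, dt_ps, 2*dt_ps, ...
    """
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover
        raise PDBParseError(str(exc)) from exc
    if len(st) == 0:
        raise PDBParseError("no models in input")
    topology = structure_from_gemmi_model(
        st[0], st.name or "trajectory", altloc_policy=altloc_policy,
        include_hetero=include_hetero, source="pdb")
    frames = []
    for model in st:
        frame = structure_from_gemmi_model(
            model, "frame", altloc_policy=altloc_policy,
            include_hetero=include_hetero)
        if frame.n_atoms != topology.n_atoms:
            raise PDBParseError(
                f"model atom count {frame.n_atoms} differs from topology "
                f"({topology.n_atoms})")
        frames.append(frame.coord_matrix())
    coords = np.stack(frames)
    times = np.arange(len(frames), dtype=float) * dt_ps
    return Trajectory(topology=topology, coords=coords, times=times)


def write_trajectory(traj: Trajectory) -> str:
    """Serialize a trajectory as multi-model PDB text."""
    lines = []
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:>4}")
        serial = 0
        frame = traj.topology.with_coords(traj.coords[f])
        for res in frame.residues:
            for atom in res.atoms:
                serial += 1
                lines.append(_format_atom_record(atom, res, serial))
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"
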