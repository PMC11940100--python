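"""Seeded synthetic-data generators with planted ground truth.

Every input class the pipeline consumes can be generated here at desk
scale: toy structures with planted hydrogen bonds, salt bridges,
hydrophobic clusters and catalytic-proximity candidates; predictor
candidate tables with controlled consensus structure; harmonic-fluctuation
trajectories around a reference; and assay curves (first-order decay,
Boltzmann sigmoid, Michaelis-Menten, cycle yields) with known parameters.

Generated structures use idealized geometry: residues live in spatially
isolated pockets so that the only interactions present are the planted
ones, and planted distances are exact. Chemical realism is not a goal;
detectability with known truth is. Each generator returns its dataset plus
a JSON-serializable "planted truth" dictionary, and identical
(seed, parameters) always produce identical output.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .assays import ActivityTimeCourse, CycleYields, KineticsDataset, MeltCurve
from .structure import Structure, read_structure
from .trajectory import Trajectory


class GenerationError(ValueError):
    """Raised when a requested synthetic scenario is geometrically infeasible."""


PREDICTOR_NAMES = ("PROSS", "FireProt2", "ABAUCS")

_AA1 = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Structures


def _fmt_atom(serial: int, name: str, aa3: str, resnum: int, xyz, element: str) -> str:
    x, y, z = xyz
    nm = name if len(name) >= 4 else f" {name:<3}"
    return (f"ATOM  {serial:>5} {nm} {aa3:>3} A{resnum:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2}")


def _backbone_left(center):
    """Backbone atoms confined to x <= -0.3 of the residue center."""
    c = np.asarray(center, dtype=float)
    return [
        ("N", c + (-1.2, 0.3, 0.0), "N"),
        ("CA", c + (-0.3, -0.9, 0.2), "C"),
        ("C", c + (-1.5, -0.8, -0.3), "C"),
        ("O", c + (-2.2, 0.2, 0.3), "O"),
    ]


def _backbone_right(center):
    c = np.asarray(center, dtype=float)
    return [
        ("N", c + (1.2, 0.3, 0.0), "N"),
        ("CA", c + (0.3, -0.9, 0.2), "C"),
        ("C", c + (1.5, -0.8, -0.3), "C"),
        ("O", c + (2.2, 0.2, 0.3), "O"),
    ]


def _backbone_radial(vertex, outward):
    """Backbone pushed radially away from a cluster center."""
    v = np.asarray(vertex, dtype=float)
    u = np.asarray(outward, dtype=float)
    p = np.array([-u[1], u[0], 0.0])
    if np.linalg.norm(p) < 1e-9:
        p = np.array([1.0, 0.0, 0.0])
    p = p / np.linalg.norm(p)
    return [
        ("N", v + 1.2 * u + 0.3 * p + (0, 0, 0.3), "N"),
        ("CA", v + 0.6 * u + (0, 0, -0.3), "C"),
        ("C", v + 1.2 * u - 0.4 * p + (0, 0, -0.1), "C"),
        ("O", v + 2.0 * u + 0.2 * p + (0, 0, 0.2), "O"),
    ]


_CANDIDATE_DIRECTIONS = [
    np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]),
    np.array([0.0, 0.0, 1.0]), np.array([-1.0, 0.0, 0.0]),
    np.array([0.0, -1.0, 0.0]), np.array([0.0, 0.0, -1.0]),
]


def make_structure(
    seed: int = 0,
    n_residues: int = 30,
    n_hbonds: int = 2,
    n_salt_bridges: int = 1,
    cluster_sizes: Iterable[int] = (3,),
    candidate_distances: Iterable[float] = (),
    jitter: float = 0.05,
) -> tuple[str, dict]:
    """Toy single-chain structure (PDB text) with planted interactions.

    Planted features occupy spatially isolated pockets ~40 A apart:

    * each hydrogen bond is a Ser OG donor 2.9 A from an Asn OD1 acceptor
      at sequence separation 2;
    * each salt bridge is a Lys NZ 3.8 A from a Glu OE1 (outside the
      hydrogen-bond cutoff, inside the salt-bridge cutoff);
    * each hydrophobic cluster is a ring of Leu residues with CB-CB contact
      distance 4.6 A;
    * each entry of ``candidate_distances`` places a Gly residue whose
      nearest heavy atom sits exactly that many A from a single-atom
      "catalytic" residue.

    Background residues are Gly on a distant grid with positional jitter of
    scale ``jitter`` (planted geometry is never jittered). Returns
    ``(pdb_text, truth)`` where the truth dict lists every planted feature
    by residue key.
    """
    cluster_sizes = list(cluster_sizes)
    candidate_distances = list(candidate_distances)
    if any(k < 3 for k in cluster_sizes):
        raise GenerationError("hydrophobic clusters need at least 3 members")
    if len(candidate_distances) > len(_CANDIDATE_DIRECTIONS):
        raise GenerationError(
            f"at most {len(_CANDIDATE_DIRECTIONS)} catalytic-proximity "
            "candidates are supported")
    needed = 3 * n_hbonds + 3 * n_salt_bridges + sum(cluster_sizes)
    if candidate_distances:
        needed += 1 + len(candidate_distances)
    if needed > n_residues:
        raise GenerationError(
            f"{needed} residues needed for the requested features, "
            f"only {n_residues} available")

    rng = np.random.default_rng(seed)
    # residue number -> (aa3, [(atom name, xyz, element), ...])
    placed: dict[int, tuple[str, list]] = {}
    truth: dict = {"hbonds": [], "salt_bridges": [], "clusters": [],
                   "catalytic": None, "candidates": [], "n_residues": n_residues}
    pocket = 0
    ptr = 1

    def pocket_origin() -> np.ndarray:
        nonlocal pocket
        origin = np.array([40.0 * pocket, -40.0, 0.0])
        pocket += 1
        return origin

    for _ in range(n_hbonds):
        P = pocket_origin()
        i, j = ptr, ptr + 2
        ptr += 3
        placed[i] = ("SER", _backbone_left(P) + [("OG", P + (2.3, 0, 0), "O")])
        placed[j] = ("ASN", _backbone_right(P + (7.5, 0, 0))
                     + [("OD1", P + (5.2, 0, 0), "O")])
        truth["hbonds"].append([[f"A:{i}", "OG"], [f"A:{j}", "OD1"]])

    for _ in range(n_salt_bridges):
        P = pocket_origin()
        i, j = ptr, ptr + 2
        ptr += 3
        placed[i] = ("LYS", _backbone_left(P) + [("NZ", P + (2.3, 0, 0), "N")])
        placed[j] = ("GLU", _backbone_right(P + (8.1, 0, 0))
                     + [("OE1", P + (6.1, 0, 0), "O")])
        truth["salt_bridges"].append([[f"A:{i}", "NZ"], [f"A:{j}", "OE1"]])

    for size in cluster_sizes:
        P = pocket_origin()
        side = 4.6
        circumradius = side / (2.0 * np.sin(np.pi / size))
        members = []
        for m in range(size):
            angle = 2.0 * np.pi * m / size
            u = np.array([np.cos(angle), np.sin(angle), 0.0])
            vertex = P + circumradius * u
            num = ptr
            ptr += 1
            placed[num] = ("LEU", _backbone_radial(vertex, u)
                           + [("CB", vertex, "C")])
            members.append(f"A:{num}")
        truth["clusters"].append(members)

    if candidate_distances:
        P = pocket_origin()
        cat = ptr
        ptr += 1
        placed[cat] = ("GLY", [("CA", P, "C")])
        truth["catalytic"] = f"A:{cat}"
        for d, u in zip(candidate_distances, _CANDIDATE_DIRECTIONS):
            if d <= 0:
                raise GenerationError("candidate distances must be positive")
            num = ptr
            ptr += 1
            perp = np.array([-u[1], u[0], 0.0])
            if np.linalg.norm(perp) < 1e-9:
                perp = np.array([1.0, 0.0, 0.0])
            placed[num] = ("GLY", [
                ("CA", P + d * u, "C"),
                ("N", P + (d + 1.2) * u + 0.3 * perp, "N"),
                ("C", P + (d + 2.0) * u - 0.4 * perp, "C"),
                ("O", P + (d + 2.9) * u + 0.3 * perp, "O"),
            ])
            truth["candidates"].append({"position": num, "distance": float(d)})

    # background grid, far from every pocket (y >= 40)
    slot = 0
    for num in range(1, n_residues + 1):
        if num in placed:
            continue
        col, row = slot % 8, slot // 8
        slot += 1
        c = np.array([12.0 * col, 40.0 + 12.0 * row, 0.0])
        c = c + rng.normal(0.0, jitter, size=3)
        placed[num] = ("GLY", [
            ("N", c + (-1.2, 0.3, 0.0), "N"),
            ("CA", c, "C"),
            ("C", c + (1.2, -0.5, 0.0), "C"),
            ("O", c + (2.0, 0.5, 0.0), "O"),
        ])

    lines, serial = [], 0
    for num in range(1, n_residues + 1):
        aa3, atoms = placed[num]
        for name, xyz, element in atoms:
            serial += 1
            lines.append(_fmt_atom(serial, name, aa3, num, np.round(xyz, 3), element))
    lines.append("END")
    return "\n".join(lines) + "\n", truth


# ---------------------------------------------------------------------------
# Predictor tables


def make_predictor_tables(
    seed: int = 0,
    sizes: tuple[int, int, int] = (31, 13, 32),
    n_triple: int = 4,
    n_pairs: tuple[int, int, int] = (3, 2, 2),
    position_range: tuple[int, int] = (2, 400),
) -> tuple[list[pd.DataFrame], dict]:
    """Three predictor candidate tables with planted consensus structure.

    ``sizes`` fixes the number of proposals per predictor; ``n_triple``
    positions are proposed by all three, and ``n_pairs`` = (AB, AC, BC)
    positions by exactly the corresponding pair; the remainder are
    single-predictor sites. The truth dict records the consensus count per
    position. Tables have columns ``predictor, mutation, score``.
    """
    rng = np.random.default_rng(seed)
    ab, ac, bc = n_pairs
    loads = (
        n_triple + ab + ac, n_triple + ab + bc, n_triple + ac + bc,
    )
    singles = [s - l for s, l in zip(sizes, loads)]
    if any(x < 0 for x in singles):
        raise GenerationError(
            f"overlap plan needs per-predictor loads {loads}, exceeding sizes {sizes}")

    n_positions = n_triple + ab + ac + bc + sum(singles)
    lo, hi = position_range
    if hi - lo < n_positions:
        raise GenerationError("position range too small for the requested sites")
    positions = rng.choice(np.arange(lo, hi), size=n_positions, replace=False)

    combos: list[tuple[int, ...]] = (
        [(0, 1, 2)] * n_triple + [(0, 1)] * ab + [(0, 2)] * ac + [(1, 2)] * bc
        + [(0,)] * singles[0] + [(1,)] * singles[1] + [(2,)] * singles[2]
    )
    rows: list[list] = [[], [], []]
    consensus: dict[int, int] = {}
    for pos, combo in zip(positions, combos):
        pos = int(pos)
        wt = _AA1[rng.integers(len(_AA1))]
        consensus[pos] = len(combo)
        for p in combo:
            new = wt
            while new == wt:
                new = _AA1[rng.integers(len(_AA1))]
            rows[p].append([PREDICTOR_NAMES[p], f"{wt}{pos}{new}",
                            float(np.round(rng.normal(-1.0, 0.5), 3))])
    tables = [
        pd.DataFrame(r, columns=["predictor", "mutation", "score"])
        .sort_values("mutation", ignore_index=True)
        for r in rows
    ]
    truth = {
        "consensus": consensus,
        "sizes": list(sizes),
        "n_triple": n_triple,
        "n_pairs": list(n_pairs),
    }
    return tables, truth


# ---------------------------------------------------------------------------
# Trajectories


def make_trajectory(
    ref: Structure | str,
    seed: int = 0,
    n_frames: int = 100,
    dt_ps: float = 100.0,
    sigma_bg: float = 0.1,
    region_sigmas: dict[tuple[int, int], float] | None = None,
    rigid_motion: bool = False,
) -> tuple[Trajectory, dict]:
    """Harmonic-fluctuation trajectory around a reference structure.

    Each frame displaces every atom independently by isotropic Gaussian
    noise: scale ``sigma_bg`` (A per coordinate) in the background and the
    region's own sigma inside any ``region_sigmas`` residue-number range
    (inclusive). With ``rigid_motion`` every frame is additionally rotated
    and translated rigidly, which a correct superposition must remove.

    The per-atom RMS displacement implied by a sigma is sigma*sqrt(3),
    recorded in the truth dict as the expected RMSF per residue.
    """
    if isinstance(ref, str):
        ref = read_structure(ref)
    region_sigmas = dict(region_sigmas or {})
    rng = np.random.default_rng(seed)
    base = ref.coord_matrix()
    atoms = list(ref.atoms())

    sigma_atom = np.full(len(atoms), float(sigma_bg))
    sigma_residue: dict[int, float] = {}
    for i, a in enumerate(atoms):
        number = a.residue_ref[1]
        s = float(sigma_bg)
        for (start, end), rs in region_sigmas.items():
            if start <= number <= end:
                s = float(rs)
        sigma_atom[i] = s
        sigma_residue[number] = s

    coords = np.empty((n_frames, len(atoms), 3))
    for f in range(n_frames):
        frame = base + rng.normal(0.0, 1.0, size=base.shape) * sigma_atom[:, None]
        if rigid_motion:
            frame = frame @ _random_rotation(rng).T + rng.normal(0.0, 5.0, size=3)
        coords[f] = frame

    traj = Trajectory(topology=ref, coords=coords,
                      times=np.arange(n_frames, dtype=float) * dt_ps)
    truth = {
        "sigma_bg": float(sigma_bg),
        "region_sigmas": {f"{a}-{b}": float(s) for (a, b), s in region_sigmas.items()},
        "expected_rmsf": {int(n): float(s * np.sqrt(3.0))
                          for n, s in sigma_residue.items()},
        "rigid_motion": bool(rigid_motion),
    }
    return traj, truth


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix, det +1)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


# ---------------------------------------------------------------------------
# Assay curves


def make_decay_curve(
    seed: int = 0,
    t_half: float = 295.0,
    temperature: float = 60.0,
    times: Iterable[float] = tuple(range(0, 301, 30)),
    noise_sigma: float = 0.0,
) -> tuple[ActivityTimeCourse, dict]:
    """First-order inactivation time course A(t) = 100 exp(-ln2 t / t_half)
    with optional multiplicative Gaussian noise of relative scale
    ``noise_sigma``."""
    rng = np.random.default_rng(seed)
    t = np.asarray(list(times), dtype=float)
    k = np.log(2.0) / t_half
    a = 100.0 * np.exp(-k * t)
    if noise_sigma > 0:
        a = a * (1.0 + rng.normal(0.0, noise_sigma, size=a.shape))
        a = np.clip(a, 1e-6, None)
    tc = ActivityTimeCourse(temperature=temperature, times=t, residual=a)
    return tc, {"t_half": float(t_half), "k": float(k),
                "noise_sigma": float(noise_sigma)}


def make_melt_curve(
    seed: int = 0,
    tm: float = 50.0,
    slope: float = 2.0,
    t_min: float = 20.0,
    t_max: float = 95.0,
    step: float = 1.0,
    f_min: float = 100.0,
    f_max: float = 1000.0,
    aggregation_onset: float | None = None,
    noise_sigma: float = 0.0,
) -> tuple[MeltCurve, dict]:
    """Boltzmann-sigmoid DSF curve with optional post-peak aggregation decay
    starting at ``aggregation_onset`` (degrees C) and optional additive
    Gaussian noise of scale ``noise_sigma`` x (f_max - f_min)."""
    rng = np.random.default_rng(seed)
    T = np.arange(t_min, t_max + 0.5 * step, step)
    F = f_min + (f_max - f_min) / (1.0 + np.exp((tm - T) / slope))
    if aggregation_onset is not None:
        onset_val = f_min + (f_max - f_min) / (1.0 + np.exp((tm - aggregation_onset) / slope))
        mask = T > aggregation_onset
        F[mask] = onset_val - 8.0 * (T[mask] - aggregation_onset)
    if noise_sigma > 0:
        F = F + rng.normal(0.0, noise_sigma * (f_max - f_min), size=F.shape)
    return MeltCurve(temperatures=T, fluorescence=F), {
        "tm": float(tm), "slope": float(slope), "noise_sigma": float(noise_sigma)}


def make_kinetics(
    seed: int = 0,
    vmax: float = 28.63,
    km: float = 5.31,
    concentrations: Iterable[float] = (2.0, 4.0, 6.0, 8.0, 10.0),
    substrate_units: str = "mg/mL",
    noise_sigma: float = 0.0,
) -> tuple[KineticsDataset, dict]:
    """Michaelis-Menten rate data v = Vmax S / (Km + S) with optional
    multiplicative Gaussian noise."""
    rng = np.random.default_rng(seed)
    S = np.asarray(list(concentrations), dtype=float)
    v = vmax * S / (km + S)
    if noise_sigma > 0:
        v = v * (1.0 + rng.normal(0.0, noise_sigma, size=v.shape))
        v = np.clip(v, 0.0, None)
    kd = KineticsDataset(substrate=S, rates=v, substrate_units=substrate_units)
    return kd, {"vmax": float(vmax), "km": float(km),
                "noise_sigma": float(noise_sigma)}


def make_cycle_yields(
    seed: int = 0,
    first_cycle: float = 21.11,
    fold: float = 4.08,
    n_cycles: int = 5,
    noise_sigma: float = 0.0,
    mode: str = "accumulation",
) -> tuple[CycleYields, dict]:
    """Running product totals over reuse cycles, interpolated geometrically
    from the first-cycle value to first_cycle x fold at the final cycle."""
    rng = np.random.default_rng(seed)
    if n_cycles < 1:
        raise GenerationError("at least one cycle is required")
    if n_cycles == 1:
        vals = np.array([first_cycle], dtype=float)
    else:
        growth = fold ** (1.0 / (n_cycles - 1))
        vals = first_cycle * growth ** np.arange(n_cycles)
    if noise_sigma > 0:
        vals = vals * (1.0 + rng.normal(0.0, noise_sigma, size=vals.shape))
    cy = CycleYields(values=vals, mode=mode)
    return cy, {"first_cycle": float(first_cycle), "fold": float(fold),
                "n_cycles": int(n_cycles)}


def make_assay_data(kind: str, seed: int = 0, **params):
    """Dispatcher over the assay generators: kind in
    {'decay', 'melt', 'kinetics', 'cycles'}."""
    makers = {
        "decay": make_decay_curve,
        "melt": make_melt_curve,
        "kinetics": make_kinetics,
        "cycles": make_cycle_yields,
    }
    try:
        maker = makers[kind]
    except KeyError:
        raise ValueError(f"unknown assay kind {kind!r}; expected one of "
                         f"{sorted(makers)}") from None
    return maker(seed=seed, **params)
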