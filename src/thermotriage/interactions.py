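"""Geometric detection of stabilizing interactions.

Hydrogen bonds (heavy-atom donor-acceptor distance criterion, with an
optional D-H...A angle test when explicit hydrogens are present), salt
bridges (basic side-chain nitrogen vs carboxylate oxygen), and hydrophobic
clusters (connected components of the side-chain contact graph over apolar
residues). A differ reports which interactions a variant model gained or
lost relative to the wild type.

Crystal structures usually lack hydrogens, so the default hydrogen-bond
criterion is distance-only; the angle test engages automatically when the
donor carries explicit hydrogens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import _chem
from .structure import Residue, ResidueKey, Structure, format_residue_key


@dataclass(frozen=True)
class GeometryConfig:
    """Distance/angle cutoffs for the interaction detectors.

    hbond_max : donor-acceptor heavy-atom cutoff, A
    hbond_angle_min : D-H...A angle cutoff in degrees (explicit H only)
    salt_bridge_max : N(+)...O(-) cutoff, A
    hydrophobic_max : side-chain heavy-atom contact cutoff, A
    min_sequence_separation : |i-j| below which same-chain pairs are
        ignored for hydrogen bonds (suppresses trivially bonded neighbours)
    """

    hbond_max: float = 3.5
    hbond_angle_min: float = 120.0
    salt_bridge_max: float = 4.0
    hydrophobic_max: float = 5.0
    min_sequence_separation: int = 2

    def __post_init__(self) -> None:
        for name in ("hbond_max", "salt_bridge_max", "hydrophobic_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True, order=True)
class Interaction:
    kind: Literal["hbond", "salt_bridge"]
    donor: tuple[str, str]     # (residue key string, atom name); donor/basic partner
    acceptor: tuple[str, str]  # acceptor/acidic partner
    distance: float = field(compare=False)

    @property
    def partners(self) -> tuple[tuple[str, str], tuple[str, str]]:
        return (self.donor, self.acceptor)

    def identity(self) -> tuple:
        """Canonical identity used for set comparison (distance excluded)."""
        return (self.kind, self.donor, self.acceptor)

    def __str__(self) -> str:
        d, a = self.donor, self.acceptor
        return f"{self.kind} {d[0]}/{d[1]} -- {a[0]}/{a[1]} ({self.distance:.2f} A)"


@dataclass
class HydrophobicCluster:
    members: frozenset[str]  # residue key strings
    contact_edges: list[tuple[str, str, float]]  # (key_a, key_b, min side-chain distance)

    def __post_init__(self) -> None:
        if len(self.members) < 3:
            raise ValueError("a hydrophobic cluster has at least 3 members")


@dataclass
class InteractionDelta:
    gained: list[Interaction]
    lost: list[Interaction]
    clusters_gained: list[HydrophobicCluster]
    clusters_lost: list[HydrophobicCluster]

    @property
    def is_empty(self) -> bool:
        return not (self.gained or self.lost or self.clusters_gained or self.clusters_lost)


def _donor_atoms(res: Residue) -> list:
    out = []
    sc = _chem.SIDECHAIN_DONORS.get(res.aa3, frozenset())
    for a in res.atoms:
        if a.name == "N" and res.aa3 != "PRO":
            out.append(a)
        elif a.name in sc:
            out.append(a)
    return out


def _acceptor_atoms(res: Residue) -> list:
    out = []
    sc = _chem.SIDECHAIN_ACCEPTORS.get(res.aa3, frozenset())
    for a in res.atoms:
        if a.name in ("O", "OXT") or a.name in sc:
            out.append(a)
    return out


def _sequence_adjacent(ra: Residue, rb: Residue, min_sep: int) -> bool:
    return ra.chain == rb.chain and abs(ra.number - rb.number) < min_sep


def _hydrogens_on(res: Residue, donor_name: str) -> list:
    """Hydrogens covalently associated with a donor heavy atom, located by
    proximity (< 1.3 A)."""
    donor = res.atom(donor_name)
    return [
        a for a in res.atoms
        if a.element.upper() == "H"
        and np.linalg.norm(a.coords - donor.coords) < 1.3
    ]


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b, degrees."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(s: Structure, params: GeometryConfig | None = None) -> list[Interaction]:
    """All donor-acceptor N/O pairs of non-adjacent residues within the
    heavy-atom cutoff; when the donor has explicit hydrogens the best
    D-H...A angle must also clear ``hbond_angle_min``."""
    cfg = params or GeometryConfig()
    found: dict[tuple, Interaction] = {}
    residues = s.residues
    for i, ra in enumerate(residues):
        donors = _donor_atoms(ra)
        if not donors:
            continue
        for rb in residues:
            if ra.key == rb.key or _sequence_adjacent(ra, rb, cfg.min_sequence_separation):
                continue
            for d in donors:
                for a in _acceptor_atoms(rb):
                    if d.residue_ref == a.residue_ref and d.name == a.name:
                        continue
                    dist = float(np.linalg.norm(d.coords - a.coords))
                    if dist > cfg.hbond_max:
                        continue
                    hydrogens = _hydrogens_on(ra, d.name)
                    if hydrogens:
                        best = max(
                            _angle_deg(d.coords, h.coords, a.coords) for h in hydrogens
                        )
                        if best < cfg.hbond_angle_min:
                            continue
                    inter = Interaction(
                        kind="hbond",
                        donor=(format_residue_key(ra.key), d.name),
                        acceptor=(format_residue_key(rb.key), a.name),
                        distance=dist,
                    )
                    found.setdefault(inter.identity(), inter)
    return sorted(found.values())


def detect_salt_bridges(s: Structure, params: GeometryConfig | None = None) -> list[Interaction]:
    """Side-chain N(+) of Lys/Arg/His within ``salt_bridge_max`` of a
    side-chain carboxylate O of Asp/Glu."""
    cfg = params or GeometryConfig()
    found: dict[tuple, Interaction] = {}
    basic = [
        (r, a) for r in s.residues
        for a in r.atoms if a.name in _chem.BASIC_ATOMS.get(r.aa3, frozenset())
    ]
    acidic = [
        (r, a) for r in s.residues
        for a in r.atoms if a.name in _chem.ACIDIC_ATOMS.get(r.aa3, frozenset())
    ]
    for rb, ab in basic:
        for ra, aa in acidic:
            dist = float(np.linalg.norm(ab.coords - aa.coords))
            if dist <= cfg.salt_bridge_max:
                inter = Interaction(
                    kind="salt_bridge",
                    donor=(format_residue_key(rb.key), ab.name),
                    acceptor=(format_residue_key(ra.key), aa.name),
                    distance=dist,
                )
                found.setdefault(inter.identity(), inter)
    return sorted(found.values())


def _sidechain_min_distance(ra: Residue, rb: Residue) -> float:
    ca = ra.coord_array(heavy_only=True, sidechain_only=True)
    cb = rb.coord_array(heavy_only=True, sidechain_only=True)
    if ca.size == 0 or cb.size == 0:
        return np.inf
    diff = ca[:, None, :] - cb[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).min())


def detect_hydrophobic_clusters(
    s: Structure, params: GeometryConfig | None = None
) -> list[HydrophobicCluster]:
    """Connected components (>= 3 residues) of the side-chain contact graph
    over the apolar residue set {A,V,L,I,M,F,W,P,Y}."""
    cfg = params or GeometryConfig()
    hydrophobes = [r for r in s.residues if r.aa1 in _chem.HYDROPHOBIC_AA1]
    n = len(hydrophobes)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    edges: list[tuple[int, int, float]] = []
    for i in range(n):
        for j in range(i + 1, n):
            d = _sidechain_min_distance(hydrophobes[i], hydrophobes[j])
            if d <= cfg.hydrophobic_max:
                edges.append((i, j, d))
                parent[find(i)] = find(j)

    components: dict[int, list[int]] = {}
    for i in range(n):
        components.setdefault(find(i), []).append(i)

    clusters = []
    for members in components.values():
        if len(members) < 3:
            continue
        keys = frozenset(format_residue_key(hydrophobes[i].key) for i in members)
        member_set = set(members)
        comp_edges = sorted(
            (
                *sorted((format_residue_key(hydrophobes[i].key),
                         format_residue_key(hydrophobes[j].key))),
                d,
            )
            for i, j, d in edges
            if i in member_set and j in member_set
        )
        clusters.append(HydrophobicCluster(members=keys, contact_edges=comp_edges))
    clusters.sort(key=lambda c: sorted(c.members))
    return clusters


def _mutated_positions(wt: Structure, mut: Structure) -> set[ResidueKey]:
    common = {r.key for r in wt.residues} & {r.key for r in mut.residues}
    return {k for k in common if wt.residue(k).aa3 != mut.residue(k).aa3}


def diff_interactions(
    wt: Structure,
    mut: Structure,
    params: GeometryConfig | None = None,
) -> InteractionDelta:
    """Interactions gained/lost by a variant relative to the wild type.

    Both structures must share residue numbering. At mutated positions the
    residue type (and hence its atom names) changes, so interactions there
    are compared by residue pair rather than exact atom identity.
    """
    wt_keys = {r.key for r in wt.residues}
    mut_keys = {r.key for r in mut.residues}
    if not (wt_keys & mut_keys):
        raise ValueError("structures share no residue keys; cannot align for diffing")

    cfg = params or GeometryConfig()
    mutated = {format_residue_key(k) for k in _mutated_positions(wt, mut)}

    def ident(inter: Interaction) -> tuple:
        # at a mutated position atom names are not comparable across models
        d = (inter.donor[0], None) if inter.donor[0] in mutated else inter.donor
        a = (inter.acceptor[0], None) if inter.acceptor[0] in mutated else inter.acceptor
        return (inter.kind, d, a)

    wt_inter = {ident(i): i for i in detect_hbonds(wt, cfg) + detect_salt_bridges(wt, cfg)}
    mut_inter = {ident(i): i for i in detect_hbonds(mut, cfg) + detect_salt_bridges(mut, cfg)}

    gained = sorted(v for k, v in mut_inter.items() if k not in wt_inter)
    lost = sorted(v for k, v in wt_inter.items() if k not in mut_inter)

    wt_clusters = {c.members: c for c in detect_hydrophobic_clusters(wt, cfg)}
    mut_clusters = {c.members: c for c in detect_hydrophobic_clusters(mut, cfg)}
    clusters_gained = [v for k, v in mut_clusters.items() if k not in wt_clusters]
    clusters_lost = [v for k, v in wt_clusters.items() if k not in mut_clusters]

    return InteractionDelta(
        gained=gained, lost=lost,
        clusters_gained=clusters_gained, clusters_lost=clusters_lost,
    )
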