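"""Atomic structure model and geometric selection primitives.

Reads PDB-format text into a validated ``Structure`` (chains -> residues ->
atoms, coordinates in Angstrom, author residue numbering) and provides the
distance primitives every downstream analysis uses: minimum inter-residue
distance and neighbourhood queries around a residue set (e.g. "all residues
within 5 A of the catalytic centre").

Parsing is delegated to :mod:`gemmi`; this module owns altloc resolution,
HETATM/water filtering, and the in-memory model.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import gemmi
import numpy as np

from . import _chem

ResidueKey = tuple[str, int, str]  # (chain id, author residue number, icode)

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


class PDBParseError(ValueError):
    """Raised when PDB text cannot be parsed into a structure."""


class MissingResidueError(KeyError):
    """Raised when a residue key is absent from a structure."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    residue_ref: ResidueKey
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    @property
    def is_backbone(self) -> bool:
        return self.name in _chem.BACKBONE_ATOMS


@dataclass
class Residue:
    chain: str
    number: int
    icode: str
    aa3: str
    atoms: list[Atom] = field(default_factory=list)
    het: bool = False

    @property
    def key(self) -> ResidueKey:
        return (self.chain, self.number, self.icode)

    @property
    def aa1(self) -> str | None:
        """One-letter code, or None for non-standard residues."""
        return _chem.AA3_TO_AA1.get(self.aa3)

    @property
    def is_standard(self) -> bool:
        return self.aa3 in _chem.AA3_TO_AA1

    def coord_array(self, heavy_only: bool = True, sidechain_only: bool = False) -> np.ndarray:
        sel = [
            a.coords
            for a in self.atoms
            if (a.is_heavy or not heavy_only)
            and (not sidechain_only or not a.is_backbone)
        ]
        if not sel:
            return np.empty((0, 3))
        return np.vstack(sel)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not in residue {self.key}")


@dataclass
class Structure:
    id: str
    residues: list[Residue]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("a Structure must contain at least one residue")
        self._index: dict[ResidueKey, Residue] = {}
        for r in self.residues:
            if r.key in self._index:
                raise ValueError(f"duplicate residue key {r.key}")
            self._index[r.key] = r

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, key: ResidueKey | str) -> Residue:
        k = parse_residue_key(key) if isinstance(key, str) else normalize_key(key)
        try:
            return self._index[k]
        except KeyError:
            raise MissingResidueError(f"residue {k} not in structure {self.id!r}") from None

    def __contains__(self, key: ResidueKey | str) -> bool:
        k = parse_residue_key(key) if isinstance(key, str) else normalize_key(key)
        return k in self._index

    def atoms(self) -> Iterator[Atom]:
        for r in self.residues:
            yield from r.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coord_matrix(self) -> np.ndarray:
        """All atom coordinates in file order, shape (n_atoms, 3)."""
        return np.array([a.coords for a in self.atoms()], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of the structure with every atom's coordinates replaced
        (same atom roster and order)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected coordinates of shape ({self.n_atoms}, 3)")
        residues: list[Residue] = []
        i = 0
        for r in self.residues:
            atoms = []
            for a in r.atoms:
                atoms.append(dataclasses.replace(a, coords=coords[i].copy()))
                i += 1
            residues.append(dataclasses.replace(r, atoms=atoms))
        return Structure(id=self.id, residues=residues, source=self.source)

    def find_position(self, number: int, chain: str | None = None) -> Residue:
        """Residue by author number alone; ``chain`` disambiguates when the
        number occurs in several chains."""
        hits = [
            r for r in self.residues
            if r.number == number and (chain is None or r.chain == chain)
        ]
        if not hits:
            raise MissingResidueError(f"no residue numbered {number} in structure {self.id!r}")
        if len(hits) > 1:
            raise MissingResidueError(
                f"residue number {number} is ambiguous across chains "
                f"{sorted({r.chain for r in hits})}; specify a chain"
            )
        return hits[0]


def normalize_key(key: ResidueKey | tuple) -> ResidueKey:
    chain, number, *rest = key
    icode = rest[0] if rest else ""
    return (str(chain), int(number), str(icode))


def parse_residue_key(text: str) -> ResidueKey:
    """Parse ``"A:67"`` or ``"A:67B"`` into a residue key."""
    chain, _, res = text.partition(":")
    if not _ or not chain or not res:
        raise ValueError(f"residue key {text!r} is not of the form CHAIN:NUMBER[icode]")
    num = res.rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    icode = res[len(num):]
    return (chain, int(num), icode)


def format_residue_key(key: ResidueKey) -> str:
    chain, number, icode = normalize_key(key)
    return f"{chain}:{number}{icode}"


@dataclass(frozen=True)
class Mutation:
    """A point substitution in ``S67G`` notation (wild-type residue,
    author position, new residue)."""

    wt_aa: str
    position: int
    new_aa: str
    chain: str | None = None

    def __post_init__(self) -> None:
        for aa in (self.wt_aa, self.new_aa):
            if aa not in _chem.AA1_TO_AA3:
                raise ValueError(f"unknown amino-acid code {aa!r}")
        if self.wt_aa == self.new_aa:
            raise ValueError(f"mutation {self} is a no-op (wt == new)")

    @classmethod
    def parse(cls, text: str, chain: str | None = None) -> "Mutation":
        text = text.strip()
        if len(text) < 3:
            raise ValueError(f"cannot parse mutation {text!r}")
        return cls(wt_aa=text[0].upper(), position=int(text[1:-1]),
                   new_aa=text[-1].upper(), chain=chain)

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.new_aa}"


@dataclass(frozen=True)
class MutationValidation:
    ok: bool
    reason: str | None = None
    observed_aa3: str | None = None


# ---------------------------------------------------------------------------
# PDB input / output


def _prescan_pdb(pdb_text: str) -> int:
    """Validate coordinate fields line-by-line; returns the ATOM record count."""
    n_atom = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        if rec == "ATOM":
            n_atom += 1
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except (ValueError, IndexError):
            raise PDBParseError(
                f"line {lineno}: malformed coordinate field in {rec} record"
            ) from None
    return n_atom


def _altloc_char(atom: gemmi.Atom) -> str:
    alt = atom.altloc
    return "" if alt in ("", "\x00", " ") else alt


def _resolve_altlocs(atoms: list[gemmi.Atom], policy: str) -> list[gemmi.Atom]:
    by_name: dict[str, list[gemmi.Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    chosen = []
    for name in order:
        group = by_name[name]
        if len(group) == 1 or policy == "first":
            chosen.append(group[0])
        elif policy == "highest_occupancy":
            # stable max: ties go to the first-listed conformer
            chosen.append(max(group, key=lambda a: a.occ))
        else:
            raise ValueError(f"unknown altloc policy {policy!r}")
    return chosen


def structure_from_gemmi_model(
    model: gemmi.Model,
    structure_id: str,
    altloc_policy: str = "highest_occupancy",
    include_hetero: bool = False,
    source: str = "",
) -> Structure:
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            if het and (not include_hetero or res.name in WATER_NAMES):
                continue
            atoms = _resolve_altlocs(list(res), altloc_policy)
            icode = res.seqid.icode.strip()
            out = Residue(chain=chain.name, number=res.seqid.num, icode=icode,
                          aa3=res.name, het=het)
            for a in atoms:
                out.atoms.append(Atom(
                    serial=a.serial,
                    name=a.name,
                    element=a.element.name.upper(),
                    residue_ref=(chain.name, res.seqid.num, icode),
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=a.occ,
                ))
            if out.atoms:
                residues.append(out)
    if not residues:
        raise PDBParseError("no residues survived parsing/filtering")
    return Structure(id=structure_id, residues=residues, source=source)


def read_structure(
    pdb_text: str,
    altloc_policy: str = "highest_occupancy",
    include_hetero: bool = False,
    structure_id: str | None = None,
) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Only the first MODEL is read (multi-model files are trajectories; see
    :func:`thermotriage.trajectory.read_trajectory`). Waters are always
    dropped; other HETATM groups are kept only with ``include_hetero``.
    Alternate locations are resolved per ``altloc_policy``
    (``"highest_occupancy"`` with ties to the first conformer, or
    ``"first"``).
    """
    if _prescan_pdb(pdb_text) == 0:
        raise PDBParseError("no ATOM records in input")
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise PDBParseError(str(exc)) from exc
    if len(st) == 0:
        raise PDBParseError("no models in input")
    sid = structure_id if structure_id is not None else (st.name or "structure")
    return structure_from_gemmi_model(
        st[0], sid, altloc_policy=altloc_policy,
        include_hetero=include_hetero, source="pdb",
    )


def _format_atom_record(atom: Atom, res: Residue, serial: int) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3}"
    rec = "HETATM" if res.het else "ATOM  "
    x, y, z = atom.coords
    return (
        f"{rec}{serial:>5} {name}{'':1}{res.aa3:>3} {res.chain[:1]:1}"
        f"{res.number:>4}{res.icode[:1]:1}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}          "
        f"{atom.element[:2]:>2}"
    )


def write_structure(s: Structure) -> str:
    """Serialize a structure to single-model PDB text."""
    lines = []
    serial = 0
    for res in s.residues:
        for atom in res.atoms:
            serial += 1
            lines.append(_format_atom_record(atom, res, serial))
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Geometric primitives


def min_distance(
    s: Structure,
    res_a: ResidueKey | str,
    res_b: ResidueKey | str,
    heavy_only: bool = True,
) -> float:
    """Minimum pairwise Euclidean distance (Angstrom) between the atoms of
    two residues. A residue against itself is 0."""
    ra, rb = s.residue(res_a), s.residue(res_b)
    if ra.key == rb.key:
        return 0.0
    ca = ra.coord_array(heavy_only=heavy_only)
    cb = rb.coord_array(heavy_only=heavy_only)
    if ca.size == 0 or cb.size == 0:
        raise ValueError("residue has no atoms under the requested selection")
    diff = ca[:, None, :] - cb[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).min())


def residues_within(
    s: Structure,
    center: Iterable[ResidueKey | str],
    cutoff: float,
    heavy_only: bool = True,
) -> set[ResidueKey]:
    """All residues whose minimum heavy-atom distance to any residue of
    ``center`` is <= ``cutoff`` (A). Center residues are always included."""
    center_keys = {s.residue(k).key for k in center}
    if not center_keys:
        raise ValueError("center residue set must be non-empty")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    center_coords = np.vstack([
        s.residue(k).coord_array(heavy_only=heavy_only) for k in center_keys
    ])
    hits: set[ResidueKey] = set(center_keys)
    for res in s.residues:
        if res.key in hits:
            continue
        rc = res.coord_array(heavy_only=heavy_only)
        if rc.size == 0:
            continue
        diff = rc[:, None, :] - center_coords[None, :, :]
        if np.sqrt((diff ** 2).sum(axis=2)).min() <= cutoff:
            hits.add(res.key)
    return hits


def validate_mutation(s: Structure, m: Mutation) -> MutationValidation:
    """Check that a mutation's wild-type residue matches the structure."""
    try:
        res = s.find_position(m.position, chain=m.chain)
    except MissingResidueError:
        return MutationValidation(ok=False, reason="position not in structure")
    if res.aa1 != m.wt_aa:
        return MutationValidation(
            ok=False,
            reason=f"expected {m.wt_aa} at {m.position}, found {res.aa3}",
            observed_aa3=res.aa3,
        )
    return MutationValidation(ok=True, observed_aa3=res.aa3)
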