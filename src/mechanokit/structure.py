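"""Hierarchical macromolecular structure model and geometric primitives.

Structures are read and written through gemmi (PDB and mmCIF per the wwPDB
standards) and held in a small chain/residue/atom hierarchy that carries the
per-residue confidence (pLDDT, stored in the B-factor column of predicted
models) needed by the interface-scoring stage.  Distances and least-squares
rigid superposition (Kabsch) are the geometric primitives shared by every
downstream analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "StructureModel",
    "AtomAddress",
    "StructureError",
    "LookupError_",
    "DegenerateGeometryError",
    "read_structure",
    "write_structure",
    "atom_distance",
    "kabsch",
    "kabsch_superpose",
]

HYDROGENS = {"H", "D"}


class StructureError(ValueError):
    """Raised for unreadable or empty structure files."""


class LookupError_(KeyError):
    """Raised when an atom address does not resolve uniquely."""


class DegenerateGeometryError(ValueError):
    """Raised when a superposition problem is rank-deficient."""


class AtomAddress(NamedTuple):
    """(chain, residue number, atom name[, insertion code]) atom address."""

    chain_id: str
    residue_number: int
    atom_name: str
    icode: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        ic = self.icode.strip()
        return f"{self.chain_id}/{self.residue_number}{ic}/{self.atom_name}"


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name}: position must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.name}: empty element symbol")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in HYDROGENS


@dataclass
class Residue:
    chain_id: str
    number: int
    name: str
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class StructureModel:
    """A single-model structure: ordered chains of ordered residues.

    ``predicted`` flags that B-factors hold pLDDT values in [0, 100].
    """

    id: str
    chains: list[Chain] = field(default_factory=list)
    predicted: bool = False
    source_format: str = "PDB"

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise LookupError_(f"no chain {chain_id!r}; chains present: {[c.id for c in self.chains]}")

    def residue(self, chain_id: str, number: int, icode: str = "") -> Residue:
        ch = self.chain(chain_id)
        for r in ch.residues:
            if r.number == number and r.icode == icode:
                return r
        near = [r.number for r in ch.residues if abs(r.number - number) <= 2]
        raise LookupError_(
            f"no residue {number}{icode} in chain {chain_id}; nearby numbers: {near}"
        )

    def atom(self, address: AtomAddress | tuple) -> Atom:
        addr = AtomAddress(*address)
        res = self.residue(addr.chain_id, addr.residue_number, addr.icode)
        a = res.atom(addr.atom_name)
        if a is None:
            raise LookupError_(
                f"no atom {addr.atom_name!r} in {addr.chain_id}/{addr.residue_number}; "
                f"atoms present: {[x.name for x in res.atoms]}"
            )
        return a

    def iter_residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues

    def iter_atoms(self, heavy_only: bool = False) -> Iterator[tuple[Residue, Atom]]:
        for r in self.iter_residues():
            for a in r.atoms:
                if heavy_only and a.is_hydrogen:
                    continue
                yield r, a

    def n_atoms(self, heavy_only: bool = False) -> int:
        return sum(1 for _ in self.iter_atoms(heavy_only=heavy_only))


# ---------------------------------------------------------------------------
# I/O


def _dedup_altlocs(atoms: Sequence[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep the highest-occupancy altloc per atom name; ties prefer altloc 'A'."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name in order:
        group = by_name[name]
        alt = lambda a: a.altloc if a.altloc != "\x00" else ""
        group.sort(key=lambda a: (-a.occ, alt(a) or "~"))
        kept.append(group[0])
    return kept


def _convert_model(gmodel: gemmi.Model, struct_id: str, predicted: bool, fmt: str) -> StructureModel:
    chains: list[Chain] = []
    for gch in gmodel:
        residues: list[Residue] = []
        for gres in gch:
            icode = gres.seqid.icode.strip()
            atoms: list[Atom] = []
            for ga in _dedup_altlocs(list(gres)):
                altloc = ga.altloc if ga.altloc != "\x00" else ""
                b = float(ga.b_iso)
                if predicted and not (0.0 <= b <= 100.0):
                    raise StructureError(
                        f"predicted model but B-factor {b} outside pLDDT range "
                        f"at {gch.name}/{gres.seqid.num}/{ga.name}"
                    )
                atoms.append(
                    Atom(
                        name=ga.name,
                        element=ga.element.name,
                        position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=float(ga.occ),
                        bfactor=b,
                        altloc=altloc,
                    )
                )
            if atoms:
                residues.append(Residue(gch.name, gres.seqid.num, gres.name, icode, atoms))
        if residues:
            chains.append(Chain(gch.name, residues))
    if not chains:
        raise StructureError(f"structure {struct_id!r} contains no atoms")
    return StructureModel(id=struct_id, chains=chains, predicted=predicted, source_format=fmt)


def read_structure(
    path: str | Path,
    format: str = "auto",
    predicted: bool = False,
    all_models: bool = False,
) -> StructureModel | list[StructureModel]:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Only the first model is returned unless ``all_models=True`` (multi-model
    files are then exposed as a list, one entry per MODEL record).  Altlocs
    are reduced to the highest-occupancy conformer (ties resolved toward
    altloc 'A').  ``predicted=True`` asserts that B-factors carry pLDDT.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"structure file {path} holds no models")
    src = "mmCIF" if str(path).lower().endswith((".cif", ".cif.gz", ".mmcif")) else "PDB"
    if fmt in ("pdb", "mmcif", "cif"):
        src = "mmCIF" if fmt != "pdb" else "PDB"
    models = [_convert_model(m, st.name or path.stem, predicted, src) for m in st]
    return models if all_models else models[0]


def _to_gemmi(s: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.id
    model = gemmi.Model("1")
    for ch in s.chains:
        gch = gemmi.Chain(ch.id)
        for res in ch.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.icode or " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.position)
                ga.occ = a.occupancy
                ga.b_iso = a.bfactor
                if a.altloc:
                    ga.altloc = a.altloc
                gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: StructureModel, path: str | Path, format: str = "auto") -> None:
    """Write minimal conformant coordinates as PDB or mmCIF (by extension)."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = _to_gemmi(s)
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt in ("mmcif", "cif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Geometry


def atom_distance(s: StructureModel, a: AtomAddress | tuple, b: AtomAddress | tuple) -> float:
    """Euclidean distance (Å) between two uniquely addressed atoms."""
    pa = s.atom(a).position
    pb = s.atom(b).position
    return float(np.linalg.norm(pa - pb))


def kabsch(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired coordinate sets.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``; the
    rotation is proper (det = +1).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate arrays required")
    if len(P) < 3:
        raise DegenerateGeometryError("at least 3 paired atoms required")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    # collinear sets leave the rotation about the line undetermined
    if np.linalg.matrix_rank(P0, tol=1e-8) < 2 or np.linalg.matrix_rank(Q0, tol=1e-8) < 2:
        raise DegenerateGeometryError("collinear point set: superposition is degenerate")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    fitted = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - Q) ** 2, axis=1))))
    return R, t, rmsd


def kabsch_superpose(
    mobile: StructureModel,
    reference: StructureModel,
    pairing: Iterable[tuple[AtomAddress | tuple, AtomAddress | tuple]],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Superpose ``mobile`` onto ``reference`` over explicitly paired atoms."""
    pm, pr = [], []
    for addr_m, addr_r in pairing:
        pm.append(mobile.atom(addr_m).position)
        pr.append(reference.atom(addr_r).position)
    return kabsch(np.array(pm), np.array(pr))


def transform(s: StructureModel, rotation: np.ndarray, translation: np.ndarray) -> StructureModel:
    """Return a copy of ``s`` with ``x -> R x + t`` applied to every atom."""
    import copy

    out = copy.deepcopy(s)
    for _, a in out.iter_atoms():
        a.position = rotation @ a.position + translation
    return out
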