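"""Interface-confidence (pDockQ) and steric-plausibility (clashscore) scoring.

Implements the two axes of the in silico pulldown screen: candidate partner
complexes predicted by co-folding are scored by pDockQ — a sigmoid-calibrated
confidence combining mean interface pLDDT with the log-count of interface
contacts — and by a heavy-atom clashscore (serious van der Waals overlaps per
1000 atoms).  A Pareto ranking over (maximize pDockQ, minimize clashscore)
orders the candidate library.

The pDockQ parameterization is the published one:

    pDockQ = 0.724 / (1 + exp(-0.052 (x - 152.611))) + 0.018,
    x = <interface pLDDT> * log10(n_contacts)

with interface contacts defined as cross-chain Cβ pairs (Cα for glycine)
within 8 Å.  The clashscore is a hydrogen-free approximation of the
MolProbity statistic: a clash is a non-bonded heavy-atom pair whose van der
Waals overlap exceeds 0.4 Å; relative ranking across candidates, not the
absolute MolProbity value, is the contract.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import Atom, Residue, StructureModel

__all__ = [
    "InterfaceContact",
    "PdockqScore",
    "ClashReport",
    "ScreenEntry",
    "find_interface_contacts",
    "compute_pdockq",
    "compute_clashscore",
    "rank_screen",
    "PDOCKQ_L",
    "PDOCKQ_K",
    "PDOCKQ_X0",
    "PDOCKQ_B",
    "VDW_RADII",
    "CLASH_OVERLAP",
]

# published sigmoid parameterization of the pDockQ scorer
PDOCKQ_L = 0.724
PDOCKQ_K = 0.052
PDOCKQ_X0 = 152.611
PDOCKQ_B = 0.018

CONTACT_CUTOFF = 8.0  # Å, Cβ–Cβ

# heavy-atom van der Waals radii (Å)
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
DEFAULT_RADIUS = 1.70
CLASH_OVERLAP = 0.4  # Å; overlap beyond this counts as a clash
COVALENT_GUARD = 1.2  # Å; closer pairs treated as covalent-record artifacts

# backbone pairs excluded between sequence-adjacent residues (i, i+1)
ADJACENT_EXCLUSIONS = {("C", "N"), ("C", "CA"), ("O", "N"), ("CA", "N")}


@dataclass(frozen=True)
class InterfaceContact:
    residue_a: tuple[str, int, str]  # (chain, number, icode)
    residue_b: tuple[str, int, str]
    distance: float


@dataclass(frozen=True)
class PdockqScore:
    n_contacts: int
    mean_if_plddt: float
    x: float
    score: float


@dataclass
class ClashReport:
    n_heavy_atoms: int
    clashes: list[tuple[tuple, tuple, float]]  # (atom key a, atom key b, overlap Å)
    clashscore: float


@dataclass(frozen=True)
class ScreenEntry:
    candidate_id: str
    pdockq: float
    clashscore: float
    pareto_rank: int


def _representative_atom(res: Residue) -> Atom | None:
    """Cβ, falling back to Cα for glycine (and Cβ-less residues)."""
    cb = res.atom("CB")
    if cb is not None:
        return cb
    return res.atom("CA")


def find_interface_contacts(
    s: StructureModel, chain_a: str, chain_b: str, cutoff: float = CONTACT_CUTOFF
) -> list[InterfaceContact]:
    """Cross-chain residue pairs whose representative atoms are within cutoff.

    Residues lacking both Cβ and Cα are skipped with a warning.  Output is
    ordered by (residue number in chain_a, then chain_b).
    """
    if cutoff <= 0:
        return []

    def reps(chain_id: str) -> list[tuple[Residue, np.ndarray]]:
        out = []
        for res in s.chain(chain_id).residues:
            atom = _representative_atom(res)
            if atom is None:
                warnings.warn(
                    f"residue {chain_id}/{res.number} {res.name} has no Cβ/Cα; skipped"
                )
                continue
            out.append((res, atom.position))
        return out

    ra = reps(chain_a)
    rb = reps(chain_b)
    if not ra or not rb:
        return []
    tree = cKDTree(np.array([p for _, p in rb]))
    contacts: list[InterfaceContact] = []
    for res_a, pa in ra:
        for j in sorted(tree.query_ball_point(pa, cutoff)):
            res_b, pb = rb[j]
            d = float(np.linalg.norm(pa - pb))
            if d <= cutoff:
                contacts.append(InterfaceContact(res_a.key, res_b.key, d))
    contacts.sort(key=lambda c: (c.residue_a[1], c.residue_a[2], c.residue_b[1], c.residue_b[2]))
    return contacts


def pdockq_sigmoid(x: float) -> float:
    arg = -PDOCKQ_K * (x - PDOCKQ_X0)
    if arg > 700.0:  # exp would overflow; sigmoid is at its floor
        return PDOCKQ_B
    return PDOCKQ_L / (1.0 + math.exp(arg)) + PDOCKQ_B


def compute_pdockq(
    s: StructureModel, chain_a: str, chain_b: str, cutoff: float = CONTACT_CUTOFF
) -> PdockqScore:
    """pDockQ for a two-chain predicted complex (B-factors must hold pLDDT)."""
    if not s.predicted:
        raise ValueError(
            "pDockQ requires a predicted model (B-factor column interpreted as pLDDT); "
            "pass predicted=True when reading the structure"
        )
    contacts = find_interface_contacts(s, chain_a, chain_b, cutoff)
    n = len(contacts)
    if n == 0:
        return PdockqScore(n_contacts=0, mean_if_plddt=0.0, x=0.0, score=PDOCKQ_B)
    interface_keys = {c.residue_a for c in contacts} | {c.residue_b for c in contacts}
    plddts = []
    for chain_id, number, icode in interface_keys:
        res = s.residue(chain_id, number, icode)
        rep = _representative_atom(res)
        plddts.append(rep.bfactor)
    mean_plddt = float(np.mean(plddts))
    x = mean_plddt * math.log10(n)
    return PdockqScore(n_contacts=n, mean_if_plddt=mean_plddt, x=x, score=pdockq_sigmoid(x))


def _atom_key(res: Residue, atom: Atom) -> tuple:
    return (res.chain_id, res.number, res.icode, atom.name)


def _radius(element: str) -> float:
    el = element.capitalize()
    if el not in VDW_RADII:
        warnings.warn(f"unknown element {element!r}: using default vdW radius {DEFAULT_RADIUS} Å")
    return VDW_RADII.get(el, DEFAULT_RADIUS)


def _excluded(res_i: Residue, name_i: str, res_j: Residue, name_j: str) -> bool:
    """Connectivity-free bond exclusion rule."""
    if res_i.key == res_j.key:
        return True
    if res_i.chain_id == res_j.chain_id and res_i.icode == res_j.icode == "":
        if res_j.number - res_i.number == 1 and (name_i, name_j) in ADJACENT_EXCLUSIONS:
            return True
        if res_i.number - res_j.number == 1 and (name_j, name_i) in ADJACENT_EXCLUSIONS:
            return True
    return False


def compute_clashscore(s: StructureModel) -> ClashReport:
    """Heavy-atom clashscore: serious vdW overlaps per 1000 heavy atoms.

    A clash is an unordered non-bonded heavy-atom pair with
    d < r_i + r_j − 0.4 Å.  Pairs within one residue, the usual peptide-bond
    backbone pairs of sequence-adjacent residues, and pairs closer than
    1.2 Å (assumed covalent record errors) are excluded.
    """
    entries: list[tuple[Residue, Atom, float]] = []
    for res, atom in s.iter_atoms(heavy_only=True):
        entries.append((res, atom, _radius(atom.element)))
    n_heavy = len(entries)
    if n_heavy < 2:
        raise ValueError("clashscore needs at least 2 heavy atoms")
    coords = np.array([a.position for _, a, _ in entries])
    max_reach = 2 * max(DEFAULT_RADIUS, *VDW_RADII.values()) - CLASH_OVERLAP
    tree = cKDTree(coords)
    clashes: list[tuple[tuple, tuple, float]] = []
    for i, j in sorted(tree.query_pairs(max_reach)):
        res_i, atom_i, ri = entries[i]
        res_j, atom_j, rj = entries[j]
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < COVALENT_GUARD:
            continue
        overlap = ri + rj - d
        if overlap <= CLASH_OVERLAP:
            continue
        if _excluded(res_i, atom_i.name, res_j, atom_j.name):
            continue
        clashes.append((_atom_key(res_i, atom_i), _atom_key(res_j, atom_j), overlap))
    return ClashReport(
        n_heavy_atoms=n_heavy,
        clashes=clashes,
        clashscore=1000.0 * len(clashes) / n_heavy,
    )


def rank_screen(
    entries: list[tuple[str, float, float]], hit_pdockq: float = 0.5
) -> list[ScreenEntry]:
    """Pareto-rank screen candidates on (pDockQ max, clashscore min).

    Rank-1 entries are non-dominated; within each front entries sort by
    pDockQ descending, ties by candidate id.  NaN-scored entries are dropped
    with a warning.  ``hit_pdockq`` is report-only: front-1 entries above it
    are the screen's outlier "hits".
    """
    if not entries:
        raise ValueError("rank_screen needs at least one entry")
    clean = []
    for cid, p, c in entries:
        if not (np.isfinite(p) and np.isfinite(c)):
            warnings.warn(f"candidate {cid!r} has non-finite scores; rejected")
            continue
        clean.append((cid, float(p), float(c)))
    if not clean:
        raise ValueError("no entries with finite scores")

    def dominates(x: tuple, y: tuple) -> bool:
        return (x[1] >= y[1] and x[2] <= y[2]) and (x[1] > y[1] or x[2] < y[2])

    remaining = list(clean)
    ranked: list[ScreenEntry] = []
    rank = 1
    while remaining:
        front = [e for e in remaining if not any(dominates(o, e) for o in remaining)]
        front.sort(key=lambda e: (-e[1], e[0]))
        ranked.extend(ScreenEntry(cid, p, c, rank) for cid, p, c in front)
        front_set = {e[0] for e in front}
        remaining = [e for e in remaining if e[0] not in front_set]
        rank += 1
    return ranked


def screen_hits(ranked: list[ScreenEntry], hit_pdockq: float = 0.5) -> list[ScreenEntry]:
    """Front-1 candidates above the pDockQ hit threshold."""
    return [e for e in ranked if e.pareto_rank == 1 and e.pdockq >= hit_pdockq]
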