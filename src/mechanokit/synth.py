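"""Synthetic inputs with planted, machine-readable ground truth.

Every pipeline stage has a generator here that emits data in the same
standard formats the analysis modules read, together with a manifest of the
planted truths, so the full test suite is self-contained and every analysis
can be verified by round trip against known structure.  The generators
plant statistics, not physics: poly-alanine beads stand in for protein
geometry, lipids are resampled uniformly per frame rather than diffusing,
and noise is Gaussian.

All generators are deterministic under (parameters, seed); each draws from
a single explicitly seeded ``numpy.random.Generator`` and never touches
global random state.
"""

from __future__ import annotations

import copy
from typing import Sequence

import numpy as np
import pandas as pd

from .coevolution import CouplingMatrix
from .kinetics import ProgressCurve
from .lipids import Trajectory
from .structure import Atom, Chain, Residue, StructureModel

__all__ = [
    "gen_complex",
    "gen_coupling",
    "gen_membrane_trajectory",
    "gen_progress_curves",
    "gen_state_pair",
]

# Idealized alanine-like template, tip atom (CB) along +x, every other atom
# at x <= 0 so two facing residues meet tip-first with no other close pairs.
_TEMPLATE = {
    "N": (np.array([-1.20, 0.80, 0.0]), "N"),
    "CA": (np.array([0.0, 0.0, 0.0]), "C"),
    "C": (np.array([-1.20, -0.80, 0.0]), "C"),
    "O": (np.array([-2.40, -1.10, 0.0]), "O"),
    "CB": (np.array([1.53, 0.0, 0.0]), "C"),
}
_CB_OFFSET = 1.53


def _basis_for(u: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal basis with first axis along u."""
    u = u / np.linalg.norm(u)
    helper = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    v = np.cross(helper, u)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    return np.column_stack([u, v, w])


def _make_residue(
    chain_id: str,
    number: int,
    tip_point: np.ndarray,
    direction: np.ndarray,
    plddt: float,
    glycine: bool = False,
) -> Residue:
    """Residue placed so its representative atom sits at ``tip_point``.

    For alanine the representative (contact) atom is CB; for glycine it is
    CA, exercising the Cα-fallback rule downstream.
    """
    R = _basis_for(np.asarray(direction, dtype=float))
    name = "GLY" if glycine else "ALA"
    ca_at = tip_point if glycine else tip_point - R @ np.array([_CB_OFFSET, 0.0, 0.0])
    atoms = []
    for atom_name, (local, element) in _TEMPLATE.items():
        if glycine and atom_name == "CB":
            continue
        atoms.append(
            Atom(
                name=atom_name,
                element=element,
                position=ca_at + R @ local,
                occupancy=1.0,
                bfactor=plddt,
            )
        )
    return Residue(chain_id=chain_id, number=number, name=name, atoms=atoms)


def gen_complex(
    n_res_a: int,
    n_res_b: int,
    n_contacts: int,
    interface_plddt: float = 90.0,
    background_plddt: float = 60.0,
    n_clashes: int = 0,
    seed: int = 0,
    contact_distance: float = 6.0,
    glycine_contacts: Sequence[int] = (),
) -> tuple[StructureModel, dict]:
    """Two-chain poly-alanine complex with planted contacts and clashes.

    Plants exactly ``n_contacts`` cross-chain representative-atom pairs at
    ``contact_distance`` Å (one-to-one pairing of the first residues of each
    chain), exactly ``n_clashes`` non-bonded heavy-atom overlaps of 0.9 Å
    among far-apart chain-B residues, and writes the stated pLDDT values to
    B-factors (interface residues get ``interface_plddt``).  Indices in
    ``glycine_contacts`` make that contact's chain-A residue a glycine, so
    its representative atom is Cα.
    """
    if not (0 <= interface_plddt <= 100 and 0 <= background_plddt <= 100):
        raise ValueError("pLDDT values must lie in [0, 100]")
    if n_contacts > min(n_res_a, n_res_b):
        raise ValueError(
            "infeasible geometry: planted contacts are paired one-to-one, "
            f"so n_contacts <= min(n_res_a, n_res_b) = {min(n_res_a, n_res_b)}"
        )
    if n_res_b < n_contacts + 2 * n_clashes:
        raise ValueError(
            "infeasible geometry: each clash consumes two chain-B residues; "
            f"need n_res_b >= n_contacts + 2*n_clashes = {n_contacts + 2 * n_clashes}"
        )
    if contact_distance > 8.0 or contact_distance <= 0:
        raise ValueError("contact_distance must be in (0, 8] Å to register as a contact")
    rng = np.random.default_rng(seed)
    spacing = 25.0
    up, down = np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0])

    chain_a = Chain("A")
    chain_b = Chain("B")
    contacts = []
    # zig-zag in y keeps the chain-A Cα set non-collinear (superposable)
    for k in range(n_contacts):
        gly = k in glycine_contacts
        tip_a = np.array([spacing * k, 10.0 * (k % 2), 1.53])
        chain_a.residues.append(
            _make_residue("A", k + 1, tip_a, up, interface_plddt, glycine=gly)
        )
        tip_b = tip_a + np.array([0.0, 0.0, contact_distance])
        chain_b.residues.append(_make_residue("B", k + 1, tip_b, down, interface_plddt))
        contacts.append((k + 1, k + 1))
    for k in range(n_contacts, n_res_a):
        tip = np.array([spacing * k, 10.0 * (k % 2), 1.53])
        chain_a.residues.append(_make_residue("A", k + 1, tip, up, background_plddt))

    clash_pairs = []
    n_far = n_res_b - n_contacts - 2 * n_clashes
    for j in range(n_far):
        y = 200.0 + rng.uniform(0.0, 5.0)
        tip = np.array([spacing * j, y, 0.0])
        chain_b.residues.append(
            _make_residue("B", n_contacts + j + 1, tip, up, background_plddt)
        )
    num = n_contacts + n_far
    for c in range(n_clashes):
        x0 = 60.0 * c
        tip1 = np.array([x0, 400.0, 0.0])
        tip2 = np.array([x0 + 2.5, 400.0, 0.0])  # C–C at 2.5 Å: overlap 0.9 Å
        r1 = _make_residue("B", num + 2 * c + 1, tip1, np.array([1.0, 0.0, 0.0]), background_plddt)
        r2 = _make_residue("B", num + 2 * c + 2, tip2, np.array([-1.0, 0.0, 0.0]), background_plddt)
        chain_b.residues.extend([r1, r2])
        clash_pairs.append((num + 2 * c + 1, num + 2 * c + 2))

    s = StructureModel(
        id=f"synthetic-complex-{seed}",
        chains=[chain_a, chain_b],
        predicted=True,
        source_format="PDB",
    )
    manifest = {
        "n_res_a": n_res_a,
        "n_res_b": n_res_b,
        "contacts": contacts,
        "contact_distance": contact_distance,
        "interface_plddt": interface_plddt,
        "background_plddt": background_plddt,
        "clash_pairs": clash_pairs,
        "n_heavy_atoms": s.n_atoms(heavy_only=True),
        "glycine_contacts": list(glycine_contacts),
        "seed": seed,
    }
    return s, manifest


def gen_coupling(
    len_a: int = 40,
    len_b: int = 40,
    planted: Sequence[tuple[int, int, float]] = (),
    noise_scale: float = 1.0,
    seed: int = 0,
) -> tuple[CouplingMatrix, dict]:
    """Coupling matrix with half-normal background and planted high-Z cells.

    The inter-chain block is |N(0, scale)| noise; each planted (pos_a,
    pos_b, target_z) cell is set to mu + target_z * sigma of the realized
    non-planted background, so the planted pairs sit at approximately the
    target Z after standardization.
    """
    if noise_scale <= 0:
        raise ValueError("degenerate background: noise_scale must be positive")
    positions = [(a, b) for a, b, _ in planted]
    if len(set(positions)) != len(positions):
        raise ValueError("duplicate planted positions")
    for a, b, _ in planted:
        if not (1 <= a <= len_a and 1 <= b <= len_b):
            raise ValueError(f"planted position ({a}, {b}) outside partition")
    rng = np.random.default_rng(seed)
    L = len_a + len_b
    m = np.zeros((L, L))
    iu = np.triu_indices(L, k=1)
    m[iu] = np.abs(rng.normal(0.0, noise_scale, size=len(iu[0])))
    m = m + m.T

    block = m[:len_a, len_a:]
    planted_mask = np.zeros_like(block, dtype=bool)
    for a, b, _ in planted:
        planted_mask[a - 1, b - 1] = True
    bg = block[~planted_mask]
    mu, sigma = float(bg.mean()), float(bg.std(ddof=0))
    for a, b, tz in planted:
        val = mu + tz * sigma
        m[a - 1, len_a + b - 1] = val
        m[len_a + b - 1, a - 1] = val
    np.fill_diagonal(m, 0.0)
    manifest = {
        "len_a": len_a,
        "len_b": len_b,
        "planted": [(a, b, tz) for a, b, tz in planted],
        "background_mean": mu,
        "background_sd": sigma,
        "noise_scale": noise_scale,
        "seed": seed,
    }
    return CouplingMatrix(scores=m, L=L), manifest


def gen_membrane_trajectory(
    n_frames: int = 100,
    dt_ns: float = 1.0,
    n_lipids: dict[str, int] | None = None,
    box: tuple[float, float, float] = (100.0, 100.0, 70.0),
    pocket_center_xy: tuple[float, float] = (62.0, 50.0),
    pocket_occupancy_fraction: float = 0.4,
    extraction: tuple[int, float] | None = None,
    jitter_sigma: float = 0.5,
    seed: int = 0,
) -> tuple[Trajectory, dict]:
    """Two-leaflet lipid slab around a static dummy protein.

    The bilayer headgroup planes sit at box-center z ± 17 Å.  A dummy
    protein (a jittered backbone column plus a noise-free ring of six
    pocket-lining residues at the upper headgroup plane, radius 3 Å around
    ``pocket_center_xy``) is centred in xy.  One tagged LysoPG spends
    ``pocket_occupancy_fraction`` of the frames with its headgroup exactly
    at the pocket centre and is otherwise placed at least 12 Å from both
    pocket and protein; with ``extraction=(start_frame, rise)`` the tagged
    headgroup instead stays in the pocket and rises linearly by ``rise`` Å
    from ``start_frame`` to the final frame.

    The tagged lipid and the pocket ring are exempt from thermal jitter so
    the manifest's occupancy and contact schedules are exact.
    """
    if not (0.0 <= pocket_occupancy_fraction <= 1.0):
        raise ValueError("pocket_occupancy_fraction must be in [0, 1]")
    if jitter_sigma < 0:
        raise ValueError("jitter_sigma must be non-negative")
    box = np.asarray(box, dtype=float)
    pocket = np.asarray(pocket_center_xy, dtype=float)
    if not (0 <= pocket[0] <= box[0] and 0 <= pocket[1] <= box[1]):
        raise ValueError("pocket centre lies outside the box")
    if n_lipids is None:
        n_lipids = {"LYPG": 16, "LYPE": 16, "POPG": 24, "POPE": 24}
    rng = np.random.default_rng(seed)
    center = box[:2] / 2.0
    z_mid = box[2] / 2.0
    leaf_z = 17.0
    ring_radius = 3.0
    pocket_radius = 5.0

    names, elements, resnames, resids = [], [], [], []
    base_positions = []  # per-atom static base coordinate
    jitter_atoms = []  # per-atom bool

    def add_atom(name, element, resname, resid, pos, jitter):
        names.append(name)
        elements.append(element)
        resnames.append(resname)
        resids.append(resid)
        base_positions.append(np.asarray(pos, dtype=float))
        jitter_atoms.append(jitter)

    resid = 0
    column_resids = []
    for z in np.arange(-15.0, 15.1, 3.0):
        resid += 1
        column_resids.append(resid)
        for nm, el, off in (
            ("N", "N", (-1.2, 0.8, 0.0)),
            ("CA", "C", (0.0, 0.0, 0.0)),
            ("C", "C", (1.2, -0.8, 0.0)),
            ("O", "O", (2.4, -1.1, 0.0)),
        ):
            add_atom(nm, el, "ALA", resid, (center[0] + off[0], center[1] + off[1], z_mid + z + off[2]), True)
    pocket_resids = []
    for k in range(6):
        resid += 1
        pocket_resids.append(resid)
        ang = 2 * np.pi * k / 6
        pos = (
            pocket[0] + ring_radius * np.cos(ang),
            pocket[1] + ring_radius * np.sin(ang),
            z_mid + leaf_z,
        )
        add_atom("CA", "C", "ALA", resid, pos, False)

    lipid_leaflet: dict[int, str] = {}
    lipid_info = []  # (resid, resname, upper: bool, tagged: bool)
    tagged_resid = None
    for resname, count in n_lipids.items():
        for i in range(count):
            resid += 1
            upper = i < (count + 1) // 2
            tagged = resname == "LYPG" and upper and tagged_resid is None
            if tagged:
                tagged_resid = resid
            lipid_leaflet[resid] = "upper" if upper else "lower"
            lipid_info.append((resid, resname, upper, tagged))
            sign = 1.0 if upper else -1.0
            for nm, el, dz in (("P", "P", 0.0), ("C1", "C", -4.0 * sign), ("C2", "C", -8.0 * sign)):
                add_atom(nm, el, resname, resid, (0.0, 0.0, z_mid + sign * leaf_z + dz), True)
    if tagged_resid is None:
        raise ValueError("generator requires at least one upper-leaflet LYPG lipid")

    base = np.array(base_positions)
    jitter_mask = np.array(jitter_atoms)
    n_atoms = len(base)
    atom_resid = np.array(resids)

    # tagged-lipid schedule
    if extraction is not None:
        start_frame, rise = extraction
        if not (0 <= start_frame < n_frames):
            raise ValueError("extraction start_frame outside trajectory")
        in_pocket = np.ones(n_frames, dtype=bool)
    else:
        start_frame, rise = None, 0.0
        k = int(round(pocket_occupancy_fraction * n_frames))
        chosen = rng.choice(n_frames, size=k, replace=False)
        in_pocket = np.zeros(n_frames, dtype=bool)
        in_pocket[np.sort(chosen)] = True

    def far_xy() -> np.ndarray:
        while True:
            p = rng.uniform([0.0, 0.0], box[:2])
            if np.linalg.norm(p - pocket) >= 12.0 and np.linalg.norm(p - center) >= 12.0:
                return p

    coords = np.empty((n_frames, n_atoms, 3))
    head_dz = np.zeros(n_frames)
    if extraction is not None and n_frames - 1 > start_frame:
        ramp = np.arange(n_frames) - start_frame
        head_dz = np.where(ramp > 0, rise * ramp / (n_frames - 1 - start_frame), 0.0)

    tagged_atoms = np.flatnonzero(atom_resid == tagged_resid)
    for f in range(n_frames):
        frame = base.copy()
        for resid_l, resname, upper, tagged in lipid_info:
            idx = np.flatnonzero(atom_resid == resid_l)
            if tagged:
                xy = pocket if in_pocket[f] else far_xy()
            else:
                xy = rng.uniform([0.0, 0.0], box[:2])
            frame[idx, 0] += xy[0]
            frame[idx, 1] += xy[1]
        if jitter_sigma > 0:
            noise = rng.normal(0.0, jitter_sigma, size=(n_atoms, 3))
            noise[~jitter_mask] = 0.0
            noise[tagged_atoms] = 0.0
            frame = frame + noise
        frame[tagged_atoms, 2] += head_dz[f]
        coords[f] = frame

    topology = pd.DataFrame(
        {
            "name": names,
            "element": elements,
            "resname": resnames,
            "resid": resids,
            "segment": ["protein" if rn == "ALA" else "lipid" for rn in resnames],
        }
    )
    traj = Trajectory(
        topology=topology,
        coords=coords,
        dt_ns=dt_ns,
        box=np.tile(box, (n_frames, 1)),
    )
    # contact truth: head at pocket centre is ring_radius from every ring atom;
    # during extraction the head stays within the 4 Å cutoff while its rise
    # satisfies sqrt(ring_radius² + dz²) < cutoff.
    cutoff = 4.0
    max_dz = np.sqrt(cutoff**2 - ring_radius**2)
    contact_frames = [int(f) for f in range(n_frames) if in_pocket[f] and head_dz[f] < max_dz]
    manifest = {
        "n_frames": n_frames,
        "dt_ns": dt_ns,
        "box": box.tolist(),
        "pocket_center_xy": pocket.tolist(),
        "pocket_radius": pocket_radius,
        "pocket_resids": pocket_resids,
        "column_resids": column_resids,
        "tagged_resid": int(tagged_resid),
        "in_pocket_frames": [int(f) for f in np.flatnonzero(in_pocket)],
        "contact_frames": contact_frames,
        "contact_cutoff": cutoff,
        "leaflet": {int(k): v for k, v in lipid_leaflet.items()},
        "extraction": None if extraction is None else {"start_frame": int(start_frame), "rise": float(rise)},
        "jitter_sigma": jitter_sigma,
        "seed": seed,
    }
    return traj, manifest


def gen_progress_curves(
    Km: float,
    Vmax: float,
    concentrations: Sequence[float],
    noise_sigma: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
    curve_duration_s: float = 60.0,
    curve_points: int = 30,
    make_curves: bool = False,
) -> tuple[pd.DataFrame, list[ProgressCurve], dict]:
    """Michaelis–Menten rate table (and optional linear progress curves).

    Rates are v = Vmax·S/(Km+S) + N(0, noise_sigma), floored at zero (a
    spectrophotometric rate cannot be negative).  With ``make_curves`` each
    (S, v) also yields a linear absorbance curve of slope v.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    conc = np.asarray(list(concentrations), dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    curves: list[ProgressCurve] = []
    for rep in range(n_replicates):
        for S in conc:
            v_true = Vmax * S / (Km + S)
            v = max(0.0, v_true + rng.normal(0.0, noise_sigma)) if noise_sigma > 0 else v_true
            rows.append({"S": S, "v": v, "replicate": rep})
            if make_curves:
                t = np.linspace(0.0, curve_duration_s, curve_points)
                a = v * t + (rng.normal(0.0, noise_sigma, size=curve_points) if noise_sigma > 0 else 0.0)
                curves.append(ProgressCurve(t, a, label=f"S={S:g} rep{rep}"))
    manifest = {
        "Km": Km,
        "Vmax": Vmax,
        "concentrations": conc.tolist(),
        "noise_sigma": noise_sigma,
        "n_replicates": n_replicates,
        "seed": seed,
    }
    return pd.DataFrame(rows), curves, manifest


def gen_state_pair(
    base: StructureModel,
    moving_selection: str | Sequence[tuple[str, int]],
    translation: Sequence[float],
    seed: int = 0,
) -> tuple[StructureModel, StructureModel, dict]:
    """Apo-like / holo-like pair: the holo copy has a rigidly moved selection.

    ``moving_selection`` is a chain id or explicit (chain, residue number)
    pairs.  The first returned structure is the unmodified base; the second
    has the selection translated by ``translation`` (Å).
    """
    vec = np.asarray(translation, dtype=float)
    holo = copy.deepcopy(base)
    holo.id = base.id + "-moved"
    if isinstance(moving_selection, str):
        keys = {(moving_selection, r.number) for r in base.chain(moving_selection).residues}
    else:
        keys = set(moving_selection)
    if not keys:
        raise ValueError("empty moving selection")
    moved = []
    for res in holo.iter_residues():
        if (res.chain_id, res.number) in keys:
            for a in res.atoms:
                a.position = a.position + vec
            moved.append((res.chain_id, res.number))
    if not moved:
        raise ValueError("moving selection matched no residues")
    manifest = {
        "moved_residues": moved,
        "translation": vec.tolist(),
        "seed": seed,
    }
    return copy.deepcopy(base), holo, manifest
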