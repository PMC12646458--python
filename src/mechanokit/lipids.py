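"""Lipid analytics for membrane-protein trajectories.

Quantifies how lipids — in particular single-tailed lysophospholipids, the
candidate substrates of the transporter — behave around a membrane protein
over a molecular-dynamics trajectory:

* leaflet assignment from headgroup z against the per-frame bilayer midplane,
* a 30 x 30 residency grid (2.5 Å bins, 75 Å window centred on the protein's
  time-averaged xy centroid) of headgroup positions in one leaflet,
* the vertical (z) trace of a single lipid relative to the midplane, which
  exposes extraction events where a headgroup leaves the bilayer,
* per-residue contact propensity (fraction of frames with any heavy-atom
  pair within 4 Å), and
* RMSF / RMSD of a protein selection after superposition on a reference.

Trajectory I/O goes through MDAnalysis (GRO/PDB topologies; XTC, DCD or
multi-model PDB frames); coordinates are Å and times ns throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import kabsch

__all__ = [
    "Trajectory",
    "ResidencyGrid",
    "ZTrace",
    "read_trajectory",
    "write_trajectory",
    "select",
    "assign_leaflets",
    "residency_histogram",
    "z_trace",
    "contact_propensity",
    "rmsf",
    "rmsd_series",
]

WATER_RESNAMES = {"HOH", "SOL", "WAT", "TIP3", "W", "TIP", "SPC"}
ION_RESNAMES = {"NA", "CL", "K", "MG", "CA2", "SOD", "CLA", "NA+", "CL-", "ION"}
PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "MSE",
}
DEFAULT_HEADGROUP = "P"  # phosphate; coarse-grained beads (e.g. PO4) via config


@dataclass
class Trajectory:
    """Topology table + per-frame coordinates (Å) and box (Å), dt in ns.

    ``topology`` columns: name, element, resname, resid, segment
    (protein|lipid|solvent).  ``coords`` has shape (n_frames, n_atoms, 3).
    """

    topology: pd.DataFrame
    coords: np.ndarray
    dt_ns: float = 1.0
    box: np.ndarray | None = None  # (n_frames, 3) orthorhombic lengths

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != len(self.topology):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.topology)} topology atoms"
            )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if np.any(self.box <= 0):
                raise ValueError("box lengths must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times_ns(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ns

    def strided(self, stride: int) -> "Trajectory":
        if stride < 1:
            raise ValueError("stride must be >= 1")
        return Trajectory(
            topology=self.topology,
            coords=self.coords[::stride],
            dt_ns=self.dt_ns * stride,
            box=None if self.box is None else self.box[::stride],
        )


def classify_segment(resname: str) -> str:
    rn = resname.upper()
    if rn in PROTEIN_RESNAMES:
        return "protein"
    if rn in WATER_RESNAMES or rn in ION_RESNAMES:
        return "solvent"
    return "lipid"


def _element_from_name(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


def read_trajectory(
    topology_path: str,
    frames_path: str | list[str] | None = None,
    stride: int = 1,
    dt_ns: float | None = None,
) -> Trajectory:
    """Load a trajectory via MDAnalysis; GRO/PDB topology, XTC/DCD/PDB frames."""
    import MDAnalysis as mda

    if stride < 1:
        raise ValueError("stride must be >= 1")
    args = [topology_path]
    if frames_path is not None:
        args += frames_path if isinstance(frames_path, list) else [frames_path]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(*args)
    names = u.atoms.names
    resnames = u.atoms.resnames
    resids = u.atoms.resids
    try:
        elements = [e if e else _element_from_name(n) for e, n in zip(u.atoms.elements, names)]
    except Exception:
        elements = [_element_from_name(n) for n in names]
    top = pd.DataFrame(
        {
            "name": names,
            "element": elements,
            "resname": resnames,
            "resid": resids,
            "segment": [classify_segment(rn) for rn in resnames],
        }
    )
    coords, boxes = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory[::stride]:
            if len(ts.positions) != len(top):
                raise ValueError(
                    f"frame {ts.frame}: {len(ts.positions)} atoms, topology has {len(top)}"
                )
            coords.append(ts.positions.astype(float).copy())
            boxes.append(None if ts.dimensions is None else ts.dimensions[:3].astype(float).copy())
    if dt_ns is None:
        try:
            dt_ns = float(u.trajectory.dt) / 1000.0 * stride  # MDAnalysis dt is ps
        except Exception:
            dt_ns = float(stride)
    box = None if any(b is None for b in boxes) else np.array(boxes)
    return Trajectory(topology=top, coords=np.array(coords), dt_ns=dt_ns, box=box)


def write_trajectory(t: Trajectory, path: str, format: str = "auto") -> None:
    """Write a trajectory (multi-model PDB, GRO first frame, XTC or DCD)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    fmt = format.lower()
    if fmt == "auto":
        fmt = path.rsplit(".", 1)[-1].lower()
    top = t.topology
    resids_seq = top["resid"].to_numpy()
    # residue index by first appearance
    order = pd.unique(resids_seq)
    remap = {rid: i for i, rid in enumerate(order)}
    atom_resindex = np.array([remap[r] for r in resids_seq])
    res_first = top.drop_duplicates("resid")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            len(top),
            n_residues=len(order),
            atom_resindex=atom_resindex,
            residue_segindex=np.zeros(len(order), dtype=int),
            trajectory=True,
        )
        u.add_TopologyAttr("names", top["name"].tolist())
        u.add_TopologyAttr("elements", top["element"].tolist())
        u.add_TopologyAttr("resnames", res_first["resname"].tolist())
        u.add_TopologyAttr("resids", res_first["resid"].tolist())
        if t.box is not None:
            dims = np.hstack([t.box, np.full((t.n_frames, 3), 90.0)]).astype(np.float32)
        else:
            dims = None
        u.load_new(t.coords.astype(np.float32), format=MemoryReader, dimensions=dims)
        if fmt == "gro":
            with mda.Writer(path) as w:
                w.write(u.atoms)
        elif fmt in ("pdb", "xtc", "dcd"):
            multi = fmt == "pdb"
            with mda.Writer(path, n_atoms=len(top), multiframe=multi or None) as w:
                for _ in u.trajectory:
                    w.write(u.atoms)
        else:
            raise ValueError(f"unsupported trajectory format {format!r}")


def select(
    t: Trajectory,
    segment: str | None = None,
    resname: str | None = None,
    resids: tuple[int, int] | list[int] | int | None = None,
    names: str | list[str] | None = None,
    heavy_only: bool = False,
) -> np.ndarray:
    """Boolean atom mask from simple (segment, resname, resid, name) clauses."""
    top = t.topology
    mask = np.ones(len(top), dtype=bool)
    if segment is not None:
        mask &= (top["segment"] == segment).to_numpy()
    if resname is not None:
        mask &= (top["resname"] == resname).to_numpy()
    if resids is not None:
        if isinstance(resids, int):
            mask &= (top["resid"] == resids).to_numpy()
        elif isinstance(resids, tuple):
            lo, hi = resids
            mask &= ((top["resid"] >= lo) & (top["resid"] <= hi)).to_numpy()
        else:
            mask &= top["resid"].isin(resids).to_numpy()
    if names is not None:
        names = [names] if isinstance(names, str) else names
        mask &= top["name"].isin(names).to_numpy()
    if heavy_only:
        mask &= ~top["element"].str.upper().isin(["H", "D"]).to_numpy()
    return mask


# ---------------------------------------------------------------------------
# Analytics


def _headgroup_mask(t: Trajectory, headgroup: str) -> np.ndarray:
    mask = select(t, segment="lipid", names=headgroup)
    if not mask.any():
        raise ValueError(
            f"no lipid headgroup atoms named {headgroup!r}; "
            f"lipid atom names present: {sorted(set(t.topology.loc[t.topology.segment == 'lipid', 'name']))}"
        )
    return mask


def bilayer_midplane(t: Trajectory, headgroup: str = DEFAULT_HEADGROUP) -> np.ndarray:
    """Per-frame midplane z: mean z of all lipid headgroup reference atoms."""
    mask = _headgroup_mask(t, headgroup)
    return t.coords[:, mask, 2].mean(axis=1)


def assign_leaflets(
    t: Trajectory, headgroup: str = DEFAULT_HEADGROUP
) -> pd.DataFrame:
    """Per-frame upper/lower leaflet label for every lipid residue.

    A lipid is upper iff its headgroup z is strictly above the per-frame
    midplane (mean headgroup z); on an exact tie it is assigned lower, with
    a warning.  Returns a frames x lipids boolean DataFrame (True = upper),
    columns indexed by lipid resid.
    """
    mask = _headgroup_mask(t, headgroup)
    resids = t.topology.loc[mask, "resid"].to_numpy()
    if len(resids) < 2:
        raise ValueError("leaflet assignment needs at least 2 lipids")
    z = t.coords[:, mask, 2]  # frames x lipids
    mid = z.mean(axis=1, keepdims=True)
    upper = z > mid
    if np.any(z == mid):
        warnings.warn("headgroup exactly at midplane: assigned to lower leaflet")
    return pd.DataFrame(upper, columns=resids)


@dataclass
class ResidencyGrid:
    """2D frequency-density histogram of headgroup xy positions."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # (nx, ny) ints
    dropped: int  # observations outside the window
    lipid_type: str
    leaflet: str

    @property
    def density(self) -> np.ndarray:
        m = self.counts.max()
        return self.counts / m if m > 0 else self.counts.astype(float)

    def argmax_xy(self) -> tuple[float, float]:
        i, j = np.unravel_index(np.argmax(self.counts), self.counts.shape)
        return (
            float((self.x_edges[i] + self.x_edges[i + 1]) / 2),
            float((self.y_edges[j] + self.y_edges[j + 1]) / 2),
        )


def protein_centroid_xy(t: Trajectory) -> np.ndarray:
    mask = select(t, segment="protein")
    if not mask.any():
        raise ValueError("no protein atoms in trajectory")
    return t.coords[:, mask, :2].mean(axis=(0, 1))


def residency_histogram(
    t: Trajectory,
    lipid_type: str,
    leaflet: str = "upper",
    stride: int = 10,
    n_bins: int = 30,
    bin_size: float = 2.5,
    center: np.ndarray | None = None,
    headgroup: str = DEFAULT_HEADGROUP,
) -> ResidencyGrid:
    """Headgroup residency grid for one lipid type in one leaflet.

    Counts headgroup observations of the named lipid type over strided
    frames into an ``n_bins x n_bins`` grid of ``bin_size`` Å cells centred
    on ``center`` (default: the protein's time-averaged xy centroid).
    Observations outside the window are dropped and counted.
    """
    lipid_resnames = set(t.topology.loc[t.topology.segment == "lipid", "resname"])
    if lipid_type not in lipid_resnames:
        raise ValueError(f"unknown lipid type {lipid_type!r}; present: {sorted(lipid_resnames)}")
    if leaflet not in ("upper", "lower"):
        raise ValueError("leaflet must be 'upper' or 'lower'")
    leaflets = assign_leaflets(t, headgroup)  # full-resolution frames
    ts = t.strided(stride)
    upper = leaflets.to_numpy()[::stride]
    hg_mask = _headgroup_mask(t, headgroup)
    type_cols = (t.topology.loc[hg_mask, "resname"] == lipid_type).to_numpy()
    want_upper = leaflet == "upper"

    if center is None:
        center = protein_centroid_xy(t)
    half = n_bins * bin_size / 2.0
    x_edges = center[0] - half + bin_size * np.arange(n_bins + 1)
    y_edges = center[1] - half + bin_size * np.arange(n_bins + 1)

    xy = ts.coords[:, hg_mask, :2][:, type_cols, :]
    in_leaflet = (upper == want_upper)[:, type_cols]
    pts = xy[in_leaflet]  # (n_obs, 2)
    if len(pts) == 0:
        warnings.warn("no headgroup observations for the requested type/leaflet")
        return ResidencyGrid(x_edges, y_edges, np.zeros((n_bins, n_bins), int), 0, lipid_type, leaflet)
    counts, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[x_edges, y_edges])
    counts = counts.astype(int)
    dropped = len(pts) - int(counts.sum())
    return ResidencyGrid(x_edges, y_edges, counts, dropped, lipid_type, leaflet)


@dataclass
class ZTrace:
    times_ns: np.ndarray
    z: np.ndarray  # Å relative to reference plane; positive = periplasmic
    resid: int
    atom_name: str
    reference: str = "midplane"


def z_trace(
    t: Trajectory,
    resid: int,
    atom_name: str = DEFAULT_HEADGROUP,
    stride: int = 1,
    reference: str = "midplane",
    headgroup: str = DEFAULT_HEADGROUP,
) -> ZTrace:
    """Vertical position of one lipid atom relative to the bilayer.

    ``reference='midplane'`` (default) measures against the per-frame mean
    headgroup z; ``'upper-leaflet'`` against the mean headgroup z of the
    upper leaflet's lipids.
    """
    mask = select(t, resids=resid, names=atom_name)
    if mask.sum() == 0:
        raise KeyError(f"no atom {atom_name!r} in lipid resid {resid}")
    if mask.sum() > 1:
        raise KeyError(f"atom address resid={resid} name={atom_name} is ambiguous")
    ts = t.strided(stride)
    za = ts.coords[:, mask, 2][:, 0]
    if reference == "midplane":
        ref = bilayer_midplane(ts, headgroup)
    elif reference == "upper-leaflet":
        leaflets = assign_leaflets(ts, headgroup)
        hg = _headgroup_mask(ts, headgroup)
        z_all = ts.coords[:, hg, 2]
        up = leaflets.to_numpy()
        ref = np.array(
            [z_all[f, up[f]].mean() if up[f].any() else z_all[f].mean() for f in range(ts.n_frames)]
        )
    else:
        raise ValueError("reference must be 'midplane' or 'upper-leaflet'")
    return ZTrace(ts.times_ns, za - ref, resid, atom_name, reference)


def contact_propensity(
    t: Trajectory,
    lipid_resid: int,
    protein_resids: list[int] | None = None,
    cutoff: float = 4.0,
    stride: int = 1,
) -> pd.DataFrame:
    """Fraction of frames in which the lipid touches each protein residue.

    Contact in a frame means any heavy-atom pair (lipid atom, residue atom)
    closer than ``cutoff``.  Exact integer frame-count arithmetic.
    """
    lipid_mask = select(t, resids=lipid_resid, heavy_only=True)
    if not lipid_mask.any():
        raise ValueError(f"no heavy atoms for lipid resid {lipid_resid}")
    prot_mask = select(t, segment="protein", heavy_only=True)
    top = t.topology
    if protein_resids is not None:
        prot_mask &= top["resid"].isin(protein_resids).to_numpy()
    if not prot_mask.any():
        raise ValueError("empty protein selection")
    ts = t.strided(stride)
    prot_idx = np.flatnonzero(prot_mask)
    prot_resid = top["resid"].to_numpy()[prot_idx]
    residues = pd.unique(prot_resid)
    counts = {r: 0 for r in residues}
    for f in range(ts.n_frames):
        tree = cKDTree(ts.coords[f, lipid_mask])
        d, _ = tree.query(ts.coords[f, prot_idx], k=1)
        touched = np.unique(prot_resid[d < cutoff])
        for r in touched:
            counts[r] += 1
    resname_of = dict(zip(top["resid"], top["resname"]))
    return pd.DataFrame(
        {
            "resid": residues,
            "resname": [resname_of[r] for r in residues],
            "n_contact_frames": [counts[r] for r in residues],
            "n_frames": ts.n_frames,
            "propensity": [counts[r] / ts.n_frames for r in residues],
        }
    )


def _superposed_coords(
    t: Trajectory, measure_mask: np.ndarray, fit_mask: np.ndarray, ref_frame: int = 0
) -> np.ndarray:
    """Coordinates of the measured selection after per-frame rigid fit."""
    ref = t.coords[ref_frame, fit_mask]
    out = np.empty((t.n_frames, int(measure_mask.sum()), 3))
    for f in range(t.n_frames):
        R, tr, _ = kabsch(t.coords[f, fit_mask], ref)
        out[f] = t.coords[f, measure_mask] @ R.T + tr
    return out


def _default_fit_mask(t: Trajectory) -> np.ndarray:
    mask = select(t, segment="protein", names=["N", "CA", "C"])
    if not mask.any():
        mask = select(t, segment="protein")
    if not mask.any():
        raise ValueError("no protein atoms to superpose on")
    return mask


def rmsf(
    t: Trajectory,
    selection: np.ndarray | None = None,
    fit_selection: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-residue RMSF (Å) about the mean position after superposition.

    Every frame is first superposed onto the first frame over the fit
    selection (default: protein backbone).  Per-atom fluctuations
    sqrt(<|r - <r>|²>) are averaged within each residue.
    """
    if t.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    fit_mask = _default_fit_mask(t) if fit_selection is None else fit_selection
    mask = select(t, segment="protein") if selection is None else selection
    coords = _superposed_coords(t, mask, fit_mask)
    mean = coords.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    resid = t.topology["resid"].to_numpy()[mask]
    resname = t.topology["resname"].to_numpy()[mask]
    df = pd.DataFrame({"resid": resid, "resname": resname, "rmsf": per_atom})
    return (
        df.groupby(["resid", "resname"], sort=True)["rmsf"].mean().reset_index()
    )


def rmsd_series(
    t: Trajectory,
    selection: np.ndarray | None = None,
    reference_frame: int = 0,
) -> pd.DataFrame:
    """Per-frame RMSD (Å) to the reference frame after superposition."""
    if t.n_frames < 2:
        raise ValueError("RMSD series needs at least 2 frames")
    mask = _default_fit_mask(t) if selection is None else selection
    ref = t.coords[reference_frame, mask]
    vals = []
    for f in range(t.n_frames):
        _, _, r = kabsch(t.coords[f, mask], ref)
        vals.append(r)
    return pd.DataFrame({"time_ns": t.times_ns, "rmsd": vals})
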