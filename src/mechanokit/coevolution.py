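"""Inter-protein coevolution Z-analysis of paired-alignment coupling matrices.

A coupling matrix for a concatenated two-protein alignment (CCMPred plain
.mat dialect: L whitespace-separated rows of L floats) is partitioned into
its two chains; the inter-protein block is standardized to Z-scores against
the inter-protein pair population, the high-Z tail is extracted (the
screen's annotation threshold is Z > 10), and pairs are mapped onto a
complex structure to measure whether coevolving positions sit at the
physical interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .structure import StructureModel, atom_distance

__all__ = [
    "CouplingMatrix",
    "ChainPartition",
    "CoevolvingPair",
    "read_coupling_matrix",
    "write_coupling_matrix",
    "extract_interchain",
    "zscore_pairs",
    "top_pairs",
    "map_pairs_to_structure",
    "z_histogram",
    "apc_correct",
]


@dataclass
class CouplingMatrix:
    scores: np.ndarray  # (L, L) symmetric, zero diagonal
    L: int

    @classmethod
    def from_array(cls, arr: np.ndarray, symmetry_tol: float = 1e-6) -> "CouplingMatrix":
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError(f"coupling matrix must be square, got shape {arr.shape}")
        asym = float(np.abs(arr - arr.T).max()) if arr.size else 0.0
        if asym > symmetry_tol:
            warnings.warn(f"matrix asymmetric (max |M - M^T| = {asym:.3g}); symmetrizing")
        sym = (arr + arr.T) / 2.0
        np.fill_diagonal(sym, 0.0)
        return cls(scores=sym, L=arr.shape[0])


@dataclass(frozen=True)
class ChainPartition:
    len_a: int
    len_b: int
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        if self.len_a < 1 or self.len_b < 1:
            raise ValueError("both chain lengths must be >= 1")

    @property
    def L(self) -> int:
        return self.len_a + self.len_b


@dataclass(frozen=True)
class CoevolvingPair:
    pos_a: int  # 1-based within protein A
    pos_b: int  # 1-based within protein B
    raw: float
    z: float = float("nan")


def read_coupling_matrix(path: str | Path) -> CouplingMatrix:
    """Read a CCMPred-style plain matrix (L rows of L whitespace floats)."""
    rows: list[list[float]] = []
    with open(path) as fh:
        for idx, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric token in row {idx}: {exc}") from exc
    if not rows:
        raise ValueError(f"{path}: empty matrix")
    width = len(rows[0])
    for idx, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(f"{path}: ragged row {idx} (length {len(row)}, expected {width})")
    return CouplingMatrix.from_array(np.array(rows))


def write_coupling_matrix(m: CouplingMatrix | np.ndarray, path: str | Path) -> None:
    arr = m.scores if isinstance(m, CouplingMatrix) else np.asarray(m)
    np.savetxt(path, arr, fmt="%.17g", delimiter="\t")


def extract_interchain(
    m: CouplingMatrix, p: ChainPartition
) -> list[tuple[int, int, float]]:
    """All len_a x len_b inter-chain cells as (pos_a, pos_b, raw), 1-based."""
    if p.L != m.L:
        raise ValueError(f"partition length {p.L} != matrix size {m.L}")
    block = m.scores[: p.len_a, p.len_a :]
    out = []
    for i in range(p.len_a):
        for j in range(p.len_b):
            out.append((i + 1, j + 1, float(block[i, j])))
    return out


def zscore_pairs(pairs: list[tuple[int, int, float]]) -> list[CoevolvingPair]:
    """Standardize raw couplings over the inter-protein pair population.

    Uses the population (not sample) standard deviation: the pair set is the
    complete population of inter-chain cells, not a sample from one.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to standardize")
    raw = np.array([r for _, _, r in pairs], dtype=float)
    mu = raw.mean()
    sigma = raw.std(ddof=0)
    if sigma == 0:
        raise ValueError("degenerate background: all raw couplings identical")
    z = (raw - mu) / sigma
    return [CoevolvingPair(a, b, r, zz) for (a, b, r), zz in zip(pairs, z)]


def top_pairs(pairs: list[CoevolvingPair], z_min: float = 10.0) -> list[CoevolvingPair]:
    """Pairs with z strictly above the threshold, sorted by z descending."""
    hits = [p for p in pairs if p.z > z_min]
    hits.sort(key=lambda p: (-p.z, p.pos_a, p.pos_b))
    return hits


def apc_correct(m: CouplingMatrix) -> CouplingMatrix:
    """Average-product correction: M_ij - mean_i * mean_j / mean (off-diagonal)."""
    s = m.scores.copy()
    L = m.L
    if L < 2:
        return CouplingMatrix(s, L)
    off = ~np.eye(L, dtype=bool)
    row_mean = np.array([s[i, off[i]].mean() for i in range(L)])
    total_mean = s[off].mean()
    if total_mean == 0:
        return CouplingMatrix(s, L)
    corr = s - np.outer(row_mean, row_mean) / total_mean
    np.fill_diagonal(corr, 0.0)
    return CouplingMatrix((corr + corr.T) / 2.0, L)


def map_pairs_to_structure(
    pairs: list[CoevolvingPair],
    s: StructureModel,
    chain_map: dict[str, tuple[str, int]],
    partition: ChainPartition | None = None,
) -> pd.DataFrame:
    """Map coevolving pairs onto a complex and measure their separations.

    ``chain_map`` sends each protein label to ``(chain_id, residue-number
    offset)``: position p in the protein maps to residue ``p + offset`` of
    the chain.  Returns one row per pair with the Cα–Cα distance and the
    minimum heavy-atom distance; unmapped residues are reported in the
    ``note`` column rather than silently dropped.
    """
    part = partition or ChainPartition(1, 1)
    label_a, label_b = part.label_a, part.label_b
    for label in (label_a, label_b):
        if label not in chain_map:
            raise KeyError(f"chain label {label!r} missing from chain_map")
    rows = []
    for p in pairs:
        chain_a, off_a = chain_map[label_a]
        chain_b, off_b = chain_map[label_b]
        num_a, num_b = p.pos_a + off_a, p.pos_b + off_b
        note = ""
        ca_d = np.nan
        min_d = np.nan
        try:
            res_a = s.residue(chain_a, num_a)
            res_b = s.residue(chain_b, num_b)
            ca_d = atom_distance(s, (chain_a, num_a, "CA"), (chain_b, num_b, "CA"))
            pa = np.array([a.position for a in res_a.atoms if not a.is_hydrogen])
            pb = np.array([a.position for a in res_b.atoms if not a.is_hydrogen])
            diffs = pa[:, None, :] - pb[None, :, :]
            min_d = float(np.sqrt((diffs**2).sum(axis=2)).min())
        except KeyError as exc:
            note = f"unmapped: {exc}"
        rows.append(
            {
                "pos_a": p.pos_a,
                "pos_b": p.pos_b,
                "residue_a": f"{chain_a}/{num_a}",
                "residue_b": f"{chain_b}/{num_b}",
                "raw": p.raw,
                "z": p.z,
                "ca_distance": ca_d,
                "min_heavy_distance": min_d,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def z_histogram(
    pairs: list[CoevolvingPair], bin_width: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency histogram of pair Z-scores; edges cover [min z, max z]."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not pairs:
        raise ValueError("no pairs to histogram")
    z = np.array([p.z for p in pairs])
    lo, hi = float(z.min()), float(z.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    if edges[-1] < hi:  # guard fp shortfall
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(z, bins=edges)
    return edges, counts
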