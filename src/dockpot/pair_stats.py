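"""Cross-interface residue-pair distance statistics.

Counts N(i,j,d) of typed residue pairs across the receptor/ligand interface,
per distance bin, over a set of docking matches.  Accumulation is symmetrized
(each cross pair increments both (i,j) and (j,i)), so every derived potential
satisfies e(i,j,d) = e(j,i,d) by construction and the ordered-pair marginal
N(d) equals the full double sum over types.

Two radii play different roles: the distance *cutoff* (default 10 A, 21 bins)
bounds which pairs enter the distance histograms, while the 30 A *interface*
radius defines which residues count toward the per-type totals N(i) used for
mole fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import N_TYPES, PartnerStructure

#: Marker returned by bin_index for distances at or beyond the cutoff.
OUT_OF_RANGE = -1

DEFAULT_CUTOFF = 10.0
DEFAULT_N_BINS = 21
INTERFACE_RADIUS = 30.0


@dataclass(frozen=True)
class DistanceBinning:
    """Uniform half-open binning of [0, cutoff) into n_bins bins."""

    cutoff: float = DEFAULT_CUTOFF
    n_bins: int = DEFAULT_N_BINS

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    @property
    def width(self) -> float:
        return self.cutoff / self.n_bins

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, self.cutoff, self.n_bins + 1)

    def index(self, distance: float) -> int:
        return bin_index(distance, self)

    def indices(self, distances: np.ndarray) -> np.ndarray:
        """Vectorized bin_index; OUT_OF_RANGE for d >= cutoff."""
        distances = np.asarray(distances, dtype=float)
        if np.any(distances < 0):
            raise ValueError("negative distance")
        idx = np.floor(distances * self.n_bins / self.cutoff).astype(np.intp)
        idx[distances >= self.cutoff] = OUT_OF_RANGE
        # guard against float round-up at the last edge
        idx[idx >= self.n_bins] = self.n_bins - 1
        return idx


def bin_index(distance: float, binning: DistanceBinning) -> int:
    """Bin of a distance under left-inclusive, right-exclusive edges."""
    if distance < 0:
        raise ValueError("negative distance")
    if distance >= binning.cutoff:
        return OUT_OF_RANGE
    return min(int(distance * binning.n_bins / binning.cutoff), binning.n_bins - 1)


@dataclass
class PairCountTable:
    """Pair counts N(i,j,d) on the 60x60 type grid, with marginals.

    ``n_pairs_per_bin`` is the ordered-pair marginal N(d) = sum_ij counts,
    ``n_residue`` the per-type interface residue totals N(i) under the 30 A
    interface criterion.
    """

    binning: DistanceBinning
    counts: np.ndarray = None  # type: ignore[assignment]
    n_pairs_per_bin: np.ndarray = None  # type: ignore[assignment]
    n_residue: np.ndarray = None  # type: ignore[assignment]
    n_matches: int = 0
    n_complexes: int = 0

    def __post_init__(self) -> None:
        nb = self.binning.n_bins
        if self.counts is None:
            self.counts = np.zeros((N_TYPES, N_TYPES, nb), dtype=np.int64)
        if self.n_pairs_per_bin is None:
            self.n_pairs_per_bin = np.zeros(nb, dtype=np.int64)
        if self.n_residue is None:
            self.n_residue = np.zeros(N_TYPES, dtype=np.int64)
        if self.counts.shape != (N_TYPES, N_TYPES, nb):
            raise ValueError("counts shape mismatch with binning")

    @property
    def total_pairs(self) -> int:
        """Ordered (double-counted) pair total."""
        return int(self.counts.sum())

    def validate(self) -> None:
        if np.any(self.counts < 0) or np.any(self.n_pairs_per_bin < 0) or np.any(self.n_residue < 0):
            raise ValueError("negative counts")
        if not np.array_equal(self.counts, self.counts.transpose(1, 0, 2)):
            raise ValueError("counts not symmetric in type indices")
        if not np.array_equal(self.counts.sum(axis=(0, 1)), self.n_pairs_per_bin):
            raise ValueError("N(d) marginal inconsistent with counts")

    def add(self, other: "PairCountTable") -> "PairCountTable":
        if other.binning != self.binning:
            raise ValueError("binning mismatch")
        return PairCountTable(
            binning=self.binning,
            counts=self.counts + other.counts,
            n_pairs_per_bin=self.n_pairs_per_bin + other.n_pairs_per_bin,
            n_residue=self.n_residue + other.n_residue,
            n_matches=self.n_matches + other.n_matches,
            n_complexes=self.n_complexes + other.n_complexes,
        )


@dataclass
class MoleFractions:
    """Interface composition chi_i over the 60 types (sums to 1)."""

    chi: np.ndarray

    def __post_init__(self) -> None:
        self.chi = np.asarray(self.chi, dtype=float)
        if self.chi.shape != (N_TYPES,):
            raise ValueError("chi must have length 60")
        if np.any(self.chi < 0) or abs(self.chi.sum() - 1.0) > 1e-12:
            raise ValueError("chi must be a probability vector")


def interface_residues(
    receptor: PartnerStructure,
    ligand: PartnerStructure,
    radius: float = INTERFACE_RADIUS,
) -> tuple[set[int], set[int]]:
    """Indices (into each partner's residue list) of interface residues.

    A residue is at the interface if its centroid lies within ``radius``
    (inclusive) of any residue centroid of the other partner.
    """
    d = cdist(receptor.centroids(), ligand.centroids())
    within = d <= radius
    rec = set(np.nonzero(within.any(axis=1))[0].tolist())
    lig = set(np.nonzero(within.any(axis=0))[0].tolist())
    return rec, lig


def count_match(
    receptor: PartnerStructure,
    ligand: PartnerStructure,
    binning: DistanceBinning,
    table: PairCountTable,
    interface_radius: float = INTERFACE_RADIUS,
) -> None:
    """Accumulate one posed match into ``table`` in place."""
    tr = receptor.type_indices()
    tl = ligand.type_indices()
    d = cdist(receptor.centroids(), ligand.centroids())
    ri, li = np.nonzero(d < binning.cutoff)
    if ri.size:
        bins = binning.indices(d[ri, li])
        ti, tj = tr[ri], tl[li]
        np.add.at(table.counts, (ti, tj, bins), 1)
        np.add.at(table.counts, (tj, ti, bins), 1)
        np.add.at(table.n_pairs_per_bin, bins, 2)
    within = d <= interface_radius
    rec_iface = within.any(axis=1)
    lig_iface = within.any(axis=0)
    np.add.at(table.n_residue, tr[rec_iface], 1)
    np.add.at(table.n_residue, tl[lig_iface], 1)
    table.n_matches += 1


def collect_pair_counts(
    matches: Iterable[tuple[PartnerStructure, PartnerStructure]],
    binning: DistanceBinning | None = None,
    *,
    n_complexes: int | None = None,
) -> PairCountTable:
    """Build a :class:`PairCountTable` from posed (receptor, ligand) matches."""
    binning = binning or DistanceBinning()
    table = PairCountTable(binning=binning)
    n = 0
    for receptor, ligand in matches:
        count_match(receptor, ligand, binning, table)
        n += 1
    if n == 0:
        raise ValueError("empty match list")
    table.n_complexes = n_complexes if n_complexes is not None else 0
    return table


def mole_fractions(table: PairCountTable) -> MoleFractions:
    """chi_i = N(i) / sum_k N(k) over interface residues."""
    total = table.n_residue.sum()
    if total <= 0:
        raise ValueError("zero total interface residues")
    return MoleFractions(chi=table.n_residue / total)


# ---------------------------------------------------------------------------
# serialization: versioned TSV with sparse count rows and marginal blocks

_FMT_VERSION = "dockpot pair-counts v1"


def write_pair_counts(table: PairCountTable, path: str | Path) -> None:
    table.validate()
    b = table.binning
    lines = [
        f"# {_FMT_VERSION}",
        f"# cutoff={b.cutoff!r}\tn_bins={b.n_bins}",
        f"# n_matches={table.n_matches}\tn_complexes={table.n_complexes}",
        "# convention: symmetric ordered-pair (double) counting; bins half-open [lo, hi)",
        "@counts\ti\tj\tbin\tcount",
    ]
    i, j, d = np.nonzero(table.counts)
    keep = i <= j
    for ii, jj, dd in zip(i[keep], j[keep], d[keep]):
        lines.append(f"C\t{ii}\t{jj}\t{dd}\t{table.counts[ii, jj, dd]}")
    lines.append("@n_pairs_per_bin")
    for dd, v in enumerate(table.n_pairs_per_bin):
        lines.append(f"D\t{dd}\t{v}")
    lines.append("@n_residue")
    for tt, v in enumerate(table.n_residue):
        if v:
            lines.append(f"R\t{tt}\t{v}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pair_counts(path: str | Path) -> PairCountTable:
    lines = Path(path).read_text().splitlines()
    if not lines or _FMT_VERSION not in lines[0]:
        raise ValueError("not a pair-count table file")
    meta: dict[str, str] = {}
    for line in lines[1:4]:
        for tok in line.lstrip("# ").split("\t"):
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = v
    binning = DistanceBinning(cutoff=float(meta["cutoff"]), n_bins=int(meta["n_bins"]))
    table = PairCountTable(
        binning=binning,
        n_matches=int(meta.get("n_matches", 0)),
        n_complexes=int(meta.get("n_complexes", 0)),
    )
    for line in lines:
        if line.startswith("C\t"):
            _, i, j, d, c = line.split("\t")
            i, j, d, c = int(i), int(j), int(d), int(c)
            table.counts[i, j, d] = c
            table.counts[j, i, d] = c
        elif line.startswith("D\t"):
            _, d, v = line.split("\t")
            table.n_pairs_per_bin[int(d)] = int(v)
        elif line.startswith("R\t"):
            _, t, v = line.split("\t")
            table.n_residue[int(t)] = int(v)
    table.validate()
    return table
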