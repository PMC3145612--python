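"""Scoring of posed docking matches with a trained potential table.

A match's score is the sum of e(type_r, type_l, bin(d)) over every
receptor-ligand pseudo-residue pair closer than the potential's cutoff;
lower scores are better (energy convention).  Rankings are deterministic:
ties are broken by match_id, lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .pair_stats import OUT_OF_RANGE
from .reference_states import PotentialTable
from .structure_io import PartnerStructure


@dataclass
class PosedMatch:
    """One docking pose: a fixed receptor plus a ligand given either as full
    coordinates or as a rigid transform (x -> R x + t) of a reference ligand."""

    receptor: PartnerStructure
    match_id: str
    ligand: PartnerStructure | None = None
    rotation: np.ndarray | None = None
    translation: np.ndarray | None = None
    reference_ligand: PartnerStructure | None = None
    rmsd_label: float | None = None

    def __post_init__(self) -> None:
        has_coords = self.ligand is not None
        has_transform = self.rotation is not None and self.translation is not None
        if has_coords == has_transform:
            raise ValueError("provide either full ligand coordinates or a rigid transform, not both")
        if has_transform:
            if self.reference_ligand is None:
                raise ValueError("transform representation requires a reference ligand")
            self.rotation = np.asarray(self.rotation, dtype=float)
            self.translation = np.asarray(self.translation, dtype=float)
            _validate_rotation(self.rotation)

    def ligand_pose(self) -> PartnerStructure:
        """The ligand in the posed (receptor-fixed) frame."""
        if self.ligand is not None:
            return self.ligand
        return self.reference_ligand.transformed(self.rotation, self.translation)


def _validate_rotation(rotation: np.ndarray, tol: float = 1e-6) -> None:
    if rotation.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=tol):
        raise ValueError("rotation is not orthonormal")
    if abs(np.linalg.det(rotation) - 1.0) > tol:
        raise ValueError("rotation determinant is not +1 (improper rotation)")


@dataclass
class ScoreRecord:
    match_id: str
    score: float
    n_pairs: int
    rmsd_label: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("non-finite score")


def score_pose(
    receptor: PartnerStructure,
    ligand: PartnerStructure,
    potential: PotentialTable,
) -> tuple[float, int]:
    """Energy sum and pair count for one posed receptor/ligand pair."""
    d = cdist(receptor.centroids(), ligand.centroids())
    ri, li = np.nonzero(d < potential.binning.cutoff)
    if ri.size == 0:
        return 0.0, 0
    bins = potential.binning.indices(d[ri, li])
    assert np.all(bins != OUT_OF_RANGE)
    ti = receptor.type_indices()[ri]
    tj = ligand.type_indices()[li]
    return float(potential.energies[ti, tj, bins].sum()), int(ri.size)


def score_match(match: PosedMatch, potential: PotentialTable) -> ScoreRecord:
    score, n_pairs = score_pose(match.receptor, match.ligand_pose(), potential)
    return ScoreRecord(
        match_id=match.match_id,
        score=score,
        n_pairs=n_pairs,
        rmsd_label=match.rmsd_label,
    )


def score_decoy_set(decoys, potential: PotentialTable) -> list[ScoreRecord]:
    """Score every pose of a decoy set, ranked ascending by (score, match_id).

    Accepts a :class:`~dockpot.synthetic_data.DecoySet` or any iterable of
    :class:`PosedMatch`.
    """
    matches = getattr(decoys, "poses", decoys)
    records = [score_match(m, potential) for m in matches]
    if not records:
        raise ValueError("empty decoy set")
    records.sort(key=lambda r: (r.score, r.match_id))
    return records


# ---------------------------------------------------------------------------
# transform-list and score TSV formats

_TRANSFORM_VERSION = "dockpot transforms v1"


def write_transforms(matches: list[PosedMatch], path: str | Path) -> None:
    """TSV of (match_id, 9 row-major rotation entries, 3 translation entries,
    optional rmsd); only transform-representation poses are writable."""
    lines = [
        f"# {_TRANSFORM_VERSION}",
        "# match_id\tr11..r33 (row-major)\ttx ty tz\trmsd",
    ]
    for m in matches:
        if m.rotation is None:
            raise ValueError(f"match {m.match_id} has no transform representation")
        r = "\t".join(f"{v:.9f}" for v in m.rotation.ravel())
        t = "\t".join(f"{v:.6f}" for v in m.translation)
        rmsd = "" if m.rmsd_label is None else f"{m.rmsd_label:.6f}"
        lines.append(f"{m.match_id}\t{r}\t{t}\t{rmsd}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_transforms(
    path: str | Path,
    receptor: PartnerStructure,
    reference_ligand: PartnerStructure,
) -> list[PosedMatch]:
    lines = Path(path).read_text().splitlines()
    if not lines or _TRANSFORM_VERSION not in lines[0]:
        raise ValueError("not a transform list file")
    matches = []
    for line in lines:
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        match_id = parts[0]
        nums = [float(x) for x in parts[1:13]]
        rmsd = float(parts[13]) if len(parts) > 13 and parts[13] else None
        matches.append(
            PosedMatch(
                receptor=receptor,
                match_id=match_id,
                rotation=np.array(nums[:9]).reshape(3, 3),
                translation=np.array(nums[9:12]),
                reference_ligand=reference_ligand,
                rmsd_label=rmsd,
            )
        )
    return matches


def write_scores(records: list[ScoreRecord], path: str | Path) -> None:
    lines = ["rank\tmatch_id\tscore\tn_pairs\trmsd"]
    for rank, r in enumerate(records, start=1):
        rmsd = "" if r.rmsd_label is None else f"{r.rmsd_label:.6f}"
        lines.append(f"{rank}\t{r.match_id}\t{r.score:.6f}\t{r.n_pairs}\t{rmsd}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_scores(path: str | Path) -> list[ScoreRecord]:
    lines = Path(path).read_text().splitlines()
    records = []
    for line in lines[1:]:
        if not line:
            continue
        _rank, match_id, score, n_pairs, rmsd = line.split("\t")
        records.append(
            ScoreRecord(
                match_id=match_id,
                score=float(score),
                n_pairs=int(n_pairs),
                rmsd_label=float(rmsd) if rmsd else None,
            )
        )
    return records
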