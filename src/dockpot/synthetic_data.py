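"""Self-contained synthetic fixtures: toy complexes, rigid-body decoy sets,
and planted-signal training data.

The generator emulates the shape of a rigid-body docking scan: a fixed
receptor, a mobile ligand, a large pool of random-contact poses among which a
small controlled fraction is near-native (ligand backbone RMSD < 5 A).  It is
NOT a docking program — poses are random contacts, not shape-complementarity
optima — but it reproduces the statistical situation a scoring potential is
trained and evaluated in: rare near-native poses hidden in a sea of decoys.

Everything is deterministic under a fixed seed (numpy PCG64 generators,
spawned per complex from a single seed sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .evaluation import ligand_rmsd
from .scoring import PosedMatch, read_transforms, write_transforms
from .structure_io import (
    N_TYPES,
    PartnerStructure,
    PseudoResidue,
    read_pdb,
    read_pseudo_table,
    type_to_labels,
    write_pdb,
    write_pseudo_table,
)

NEAR_NATIVE_RMSD = 5.0  # ligand backbone RMSD threshold defining near-native
CONTACT_MAX = 8.0       # at least one cross pair closer than this
CLASH_MIN = 2.5         # no cross centroid pair closer than this
DEFAULT_SPACING = 3.8   # minimal intra-partner centroid spacing, A

#: zero-mean backbone offsets (N, CA, C, O) around each centroid, so that the
#: glycine main-chain centroid recomputes to the stored pseudo-atom position
_BACKBONE_OFFSETS = {
    "N": np.array([-1.5, 0.5, 0.0]),
    "CA": np.array([0.5, -0.5, 0.0]),
    "C": np.array([1.5, 0.5, 0.0]),
    "O": np.array([-0.5, -0.5, 0.0]),
}


@dataclass(frozen=True)
class TrainingManifest:
    """Bookkeeping of the two training-set definitions.

    Defaults are the component counts of the training corpus the method was
    developed on: set 1 combines the representative bound complexes with the
    unbound benchmark complexes; set 2 combines them with the bound benchmark
    complexes instead.
    """

    n_bound_representative: int = 358
    n_bound_benchmark: int = 71
    n_unbound_benchmark: int = 50
    matches_per_complex: int = 160_000
    near_native_threshold: float = NEAR_NATIVE_RMSD

    @property
    def set1_size(self) -> int:
        return self.n_bound_representative + self.n_unbound_benchmark

    @property
    def set2_size(self) -> int:
        return self.n_bound_representative + self.n_bound_benchmark


@dataclass
class SyntheticComplexSpec:
    """Parameters of one synthetic receptor/ligand complex."""

    n_receptor_residues: int = 12
    n_ligand_residues: int = 10
    composition: np.ndarray | None = None  # sampling weights over the 60 types
    spacing: float = DEFAULT_SPACING
    fold_radius: float | None = None  # None: auto from residue count
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_receptor_residues < 3 or self.n_ligand_residues < 3:
            raise ValueError("partner sizes must be >= 3 residues")
        if self.composition is None:
            self.composition = np.full(N_TYPES, 1.0 / N_TYPES)
        else:
            w = np.asarray(self.composition, dtype=float)
            if w.shape != (N_TYPES,) or np.any(w < 0) or w.sum() <= 0:
                raise ValueError("composition must be 60 non-negative weights")
            self.composition = w / w.sum()


@dataclass
class DecoySet:
    """A receptor/ligand pair plus a pool of labelled rigid-body poses."""

    complex_id: str
    receptor: PartnerStructure
    native_ligand: PartnerStructure
    poses: list[PosedMatch]
    metadata: dict = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.rmsd_label for p in self.poses], dtype=float)


# ---------------------------------------------------------------------------
# geometry primitives

def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (normalized 4-normal quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return Rotation.from_quat(q).as_matrix()


def _random_blob(rng: np.random.Generator, n: int, spacing: float, radius: float) -> np.ndarray:
    """n centroids uniform in a sphere with pairwise min distance >= spacing."""
    pts: list[np.ndarray] = []
    for _ in range(20000):
        p = rng.uniform(-radius, radius, size=3)
        if p @ p > radius * radius:
            continue
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < spacing:
            continue
        pts.append(p)
        if len(pts) == n:
            arr = np.array(pts)
            return arr - arr.mean(axis=0)
    raise RuntimeError("infeasible packing: could not place centroids")


def _auto_radius(n: int, spacing: float) -> float:
    # loose cube-root scaling leaves room for rejection sampling
    return max(2.0 * spacing, 0.75 * spacing * n ** (1 / 3) * 2.0)


def _make_partner(
    rng: np.random.Generator,
    label: str,
    chain_id: str,
    n: int,
    composition: np.ndarray,
    spacing: float,
    radius: float,
) -> PartnerStructure:
    centroids = _random_blob(rng, n, spacing, radius)
    types = rng.choice(N_TYPES, size=n, p=composition)
    residues = []
    for k in range(n):
        aa, ss = type_to_labels(int(types[k]))
        c = centroids[k]
        residues.append(
            PseudoResidue(
                chain_id=chain_id,
                residue_number=k + 1,
                amino_acid=aa,
                ss3=ss,
                centroid=c,
                backbone={name: c + off for name, off in _BACKBONE_OFFSETS.items()},
            )
        )
    return PartnerStructure(label=label, residues=residues)


def _set_gap(receptor_xyz: np.ndarray, ligand_xyz: np.ndarray, target_gap: float) -> np.ndarray:
    """Extra translation moving the ligand along its closest-approach axis
    until the minimal cross centroid distance equals ``target_gap``.

    Iterated because the closest pair can change as the ligand moves; both
    near-native and random poses go through this, so the realized contact-gap
    distribution is identical for the two classes.
    """
    shift = np.zeros(3)
    for _ in range(4):
        d = cdist(receptor_xyz, ligand_xyz + shift)
        ri, li = np.unravel_index(d.argmin(), d.shape)
        u = (ligand_xyz[li] + shift) - receptor_xyz[ri]
        norm = np.linalg.norm(u)
        if norm < 1e-9:
            break
        shift = shift + (target_gap - d.min()) * (u / norm)
        if abs(cdist(receptor_xyz, ligand_xyz + shift).min() - target_gap) < 1e-6:
            break
    return shift


def _approach_along(
    receptor_xyz: np.ndarray,
    ligand_xyz: np.ndarray,
    u: np.ndarray,
    target_gap: float,
) -> np.ndarray | None:
    """Translation bringing the ligand to contact gap ``target_gap`` along
    direction ``u``, then fine-tuned along the closest-approach axis.

    Returns None if the placement clashes or loses contact (caller retries).
    """
    t0 = receptor_xyz.max() - ligand_xyz.min() + 50.0  # safely separated start
    d0 = cdist(receptor_xyz, ligand_xyz + t0 * u).min()
    t = t0 - (d0 - target_gap)  # coarse approach along u
    shift = t * u + _set_gap(receptor_xyz, ligand_xyz + t * u, target_gap)
    dmin = cdist(receptor_xyz, ligand_xyz + shift).min()
    if dmin < CLASH_MIN or dmin >= CONTACT_MAX:
        return None
    return shift


def _place_in_contact(
    rng: np.random.Generator,
    receptor_xyz: np.ndarray,
    ligand_xyz: np.ndarray,
    target_gap: float,
) -> np.ndarray | None:
    """Random-direction contact placement (native-complex construction)."""
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    return _approach_along(receptor_xyz, ligand_xyz, u, target_gap)


def make_toy_complex(spec: SyntheticComplexSpec) -> tuple[PartnerStructure, PartnerStructure]:
    """Build a native receptor/ligand pair in contact (no centroid clash)."""
    rng = np.random.default_rng(spec.seed)
    r_rad = spec.fold_radius or _auto_radius(spec.n_receptor_residues, spec.spacing)
    l_rad = spec.fold_radius or _auto_radius(spec.n_ligand_residues, spec.spacing)
    receptor = _make_partner(rng, "receptor", "R", spec.n_receptor_residues, spec.composition, spec.spacing, r_rad)
    for _ in range(200):
        ligand = _make_partner(rng, "ligand", "L", spec.n_ligand_residues, spec.composition, spec.spacing, l_rad)
        gap = rng.uniform(3.5, 5.5)
        t = _place_in_contact(rng, receptor.centroids(), ligand.centroids(), gap)
        if t is not None:
            return receptor, ligand.transformed(np.eye(3), t)
    raise RuntimeError("infeasible packing: no contact placement found")


# ---------------------------------------------------------------------------
# decoy generation

def _pose_transform_about_center(rot: np.ndarray, center: np.ndarray, shift: np.ndarray):
    """(R, t) for: rotate about ``center`` then translate by ``shift``."""
    return rot, center - rot @ center + shift


def generate_decoys(
    receptor: PartnerStructure,
    native_ligand: PartnerStructure,
    n_poses: int = 2000,
    near_native_fraction: float = 0.01,
    seed: int = 0,
    complex_id: str = "synthetic",
) -> DecoySet:
    """Rigid-body decoy pool with a controlled near-native fraction.

    Near-native poses are small perturbations of the native placement
    (ligand RMSD < 5 A, verified); the rest are uniformly rotated ligands
    re-placed at random contact with the receptor, rejected if they happen to
    fall within 5 A ligand RMSD of the native.  Every pose carries its exact
    ligand-RMSD label, recomputed with the evaluation metric.
    """
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    if not 0.0 <= near_native_fraction <= 1.0:
        raise ValueError("near_native_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_near = int(round(n_poses * near_native_fraction))
    rec_xyz = receptor.centroids()
    lig_xyz = native_ligand.centroids()
    lig_center = lig_xyz.mean(axis=0)
    poses: list[PosedMatch] = []
    width = len(str(n_poses))
    # Every pose — near-native or not — is built by the SAME operator: rotate
    # the ligand about its center, approach the receptor along a direction,
    # stop at a contact gap drawn from one shared distribution.  Near-native
    # poses merely constrain the rotation to a small wobble and the approach
    # direction to a cone around the native one, so the two classes differ
    # only in their concentration around the native pose, never in trivial
    # contact-count or closest-approach statistics a potential could exploit.
    gap_lo, gap_hi = 3.2, 6.0
    u_native = lig_center - rec_xyz.mean(axis=0)
    u_native = u_native / np.linalg.norm(u_native)
    for k in range(n_poses):
        near = k < n_near
        for _attempt in range(500):
            gap = rng.uniform(gap_lo, gap_hi)
            if near:
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                angle = rng.uniform(0.0, 0.3)  # radians; small wobble
                rot = Rotation.from_rotvec(angle * axis).as_matrix()
                u = u_native + 0.12 * rng.normal(size=3)
            else:
                rot = random_rotation(rng)
                u = rng.normal(size=3)
            u = u / np.linalg.norm(u)
            r0, t0 = _pose_transform_about_center(rot, lig_center, np.zeros(3))
            rotated = lig_xyz @ r0.T + t0
            shift = _approach_along(rec_xyz, rotated, u, gap)
            if shift is None:
                continue
            r, t = r0, t0 + shift
            posed_xyz = lig_xyz @ r.T + t
            dmin = cdist(rec_xyz, posed_xyz).min()
            if dmin < CLASH_MIN or dmin >= CONTACT_MAX:
                continue
            match = PosedMatch(
                receptor=receptor,
                match_id=f"{complex_id}-{k:0{width}d}",
                rotation=r,
                translation=t,
                reference_ligand=native_ligand,
            )
            rmsd = ligand_rmsd(native_ligand, match.ligand_pose())
            if near != (rmsd < NEAR_NATIVE_RMSD):
                continue
            match.rmsd_label = rmsd
            poses.append(match)
            break
        else:
            raise RuntimeError(f"could not realize pose {k} after bounded retries")
    # shuffle and re-id so pose identifiers carry no information about the
    # near-native/decoy split (rank tie-breaking is by match_id)
    poses = [poses[i] for i in rng.permutation(n_poses)]
    for k, pose in enumerate(poses):
        pose.match_id = f"{complex_id}-{k:0{width}d}"
    return DecoySet(
        complex_id=complex_id,
        receptor=receptor,
        native_ligand=native_ligand,
        poses=poses,
        metadata={
            "seed": seed,
            "n_poses": n_poses,
            "near_native_fraction": near_native_fraction,
        },
    )


# ---------------------------------------------------------------------------
# planted signal

def plant_pair_signal(
    decoy_set: DecoySet,
    favored_pair: tuple[int, int],
    distance_window: tuple[float, float],
    strength: float,
    seed: int = 0,
    cutoff: float = 10.0,
) -> DecoySet:
    """Enrich one residue-pair type at a distance window among near-native poses.

    Every cross receptor-ligand residue pair of a near-native pose whose
    centroid distance falls in ``distance_window`` is, with probability
    ``strength``, retyped to ``favored_pair`` (receptor residue to the first
    type, ligand residue to the second).  Retyping is pose-local — geometry,
    and therefore every stored RMSD label, is untouched — and decoy poses are
    left in their shared transform representation, so only the near-native
    statistics carry the signal.
    """
    lo, hi = distance_window
    if not 0 <= lo < hi:
        raise ValueError("invalid distance window")
    if hi > cutoff:
        raise ValueError("distance window outside the scoring cutoff")
    ti, tj = favored_pair
    if not (0 <= ti < N_TYPES and 0 <= tj < N_TYPES):
        raise ValueError("invalid favored pair")
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    if strength == 0.0:
        return decoy_set
    rng = np.random.default_rng(seed)
    aa_i, ss_i = type_to_labels(ti)
    aa_j, ss_j = type_to_labels(tj)
    new_poses: list[PosedMatch] = []
    n_window = 0
    n_favored = 0
    for pose in decoy_set.poses:
        if pose.rmsd_label is None or pose.rmsd_label >= NEAR_NATIVE_RMSD:
            new_poses.append(pose)
            continue
        receptor = _copy_partner(pose.receptor)
        ligand = _copy_partner(pose.ligand_pose())
        d = cdist(receptor.centroids(), ligand.centroids())
        ri, li = np.nonzero((d >= lo) & (d < hi))
        for a, b in zip(ri, li):
            n_window += 1
            if rng.random() < strength:
                _retype(receptor.residues[a], aa_i, ss_i)
                _retype(ligand.residues[b], aa_j, ss_j)
        # recount achieved enrichment after retyping
        tr, tl = receptor.type_indices(), ligand.type_indices()
        n_favored += int(np.sum((tr[ri] == ti) & (tl[li] == tj)))
        new_poses.append(
            PosedMatch(
                receptor=receptor,
                match_id=pose.match_id,
                ligand=ligand,
                rmsd_label=pose.rmsd_label,
            )
        )
    meta = dict(decoy_set.metadata)
    meta["planted"] = {
        "favored_pair": (int(ti), int(tj)),
        "window": (float(lo), float(hi)),
        "strength": float(strength),
        "enrichment": (n_favored / n_window) if n_window else 0.0,
    }
    return DecoySet(
        complex_id=decoy_set.complex_id,
        receptor=decoy_set.receptor,
        native_ligand=decoy_set.native_ligand,
        poses=new_poses,
        metadata=meta,
    )


def _merge_backbone(partner: PartnerStructure, pdb_path: Path) -> PartnerStructure:
    """Attach backbone coordinates from the native PDB (the pseudo-residue
    table stores types and centroids only)."""
    chains = {r.chain_id for r in partner.residues}
    from_pdb = read_pdb(pdb_path, chains, label=partner.label)
    backbone_by_key = {r.key: r.backbone for r in from_pdb.residues}
    for r in partner.residues:
        r.backbone = {k: v.copy() for k, v in backbone_by_key.get(r.key, {}).items()}
    return partner


def _copy_partner(partner: PartnerStructure) -> PartnerStructure:
    return PartnerStructure(
        label=partner.label,
        residues=[
            PseudoResidue(
                r.chain_id, r.residue_number, r.amino_acid, r.ss3,
                r.centroid.copy(), r.icode, {k: v.copy() for k, v in r.backbone.items()},
            )
            for r in partner.residues
        ],
    )


def _retype(residue: PseudoResidue, amino_acid: str, ss3: str) -> None:
    residue.amino_acid = amino_acid
    residue.ss3 = ss3


# ---------------------------------------------------------------------------
# suites and serialization

def generate_suite(
    n_complexes: int = 20,
    n_poses: int = 2000,
    near_native_fraction: float = 0.01,
    seed: int = 0,
    spec: SyntheticComplexSpec | None = None,
    favored_pair: tuple[int, int] | None = None,
    distance_window: tuple[float, float] = (4.0, 6.0),
    strength: float = 0.0,
) -> list[DecoySet]:
    """A list of labelled decoy sets, optionally with a planted pair signal."""
    seq = np.random.SeedSequence(seed)
    children = seq.spawn(n_complexes)
    sets = []
    for k, child in enumerate(children):
        sub = np.random.default_rng(child)
        s1, s2, s3 = (int(x) for x in sub.integers(0, 2**31 - 1, size=3))
        cspec = SyntheticComplexSpec(
            n_receptor_residues=spec.n_receptor_residues if spec else 12,
            n_ligand_residues=spec.n_ligand_residues if spec else 10,
            composition=spec.composition if spec else None,
            spacing=spec.spacing if spec else DEFAULT_SPACING,
            fold_radius=spec.fold_radius if spec else None,
            seed=s1,
        )
        receptor, ligand = make_toy_complex(cspec)
        ds = generate_decoys(
            receptor, ligand, n_poses=n_poses,
            near_native_fraction=near_native_fraction,
            seed=s2, complex_id=f"cplx{k:03d}",
        )
        if strength > 0 and favored_pair is not None:
            ds = plant_pair_signal(ds, favored_pair, distance_window, strength, seed=s3)
        sets.append(ds)
    return sets


def write_decoy_set(ds: DecoySet, directory: str | Path) -> None:
    """Write native PDB, typed pseudo-residue tables (which, unlike PDB,
    preserve the secondary-structure labels), the transform list, and a
    regeneration manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_pdb([ds.receptor, ds.native_ligand], directory / "native.pdb")
    write_pseudo_table(ds.receptor, directory / "receptor.tsv")
    write_pseudo_table(ds.native_ligand, directory / "ligand.tsv")
    transform_poses = [p for p in ds.poses if p.rotation is not None]
    if transform_poses:
        write_transforms(transform_poses, directory / "transforms.tsv")
    manifest = {"complex_id": ds.complex_id, **ds.metadata}
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))


def read_decoy_set(directory: str | Path) -> DecoySet:
    """Load a decoy set written by :func:`write_decoy_set`.

    Only transform-representation poses round-trip; pose-local retyped copies
    (planted signal) are in-memory objects and are not serialized.
    """
    directory = Path(directory)
    receptor = _merge_backbone(read_pseudo_table(directory / "receptor.tsv"),
                               directory / "native.pdb")
    ligand = _merge_backbone(read_pseudo_table(directory / "ligand.tsv"),
                             directory / "native.pdb")
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    poses = read_transforms(directory / "transforms.tsv", receptor, ligand)
    return DecoySet(
        complex_id=manifest.pop("complex_id"),
        receptor=receptor,
        native_ligand=ligand,
        poses=poses,
        metadata=manifest,
    )
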