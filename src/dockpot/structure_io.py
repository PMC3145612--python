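"""Structure input: PDB parsing, DSSP secondary structure, and the coarse-grained
residue representation.

Each residue is reduced to a single pseudo-atom at the geometric center of its
side-chain heavy atoms (CB outward, hydrogens excluded); for glycine the center
of the main-chain heavy atoms (N, CA, C, O) is used.  A residue type combines
the amino acid with a three-state secondary-structure environment, giving a
60-letter alphabet (20 amino acids x {H, E, O}).

The three-state mapping intentionally differs from the common DSSP grouping:
only 'H' maps to helix and only 'E' to strand; every other DSSP state
(G, I, B, T, S, blank) is "other" (O).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.DSSP import make_dssp_dict

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by 3-letter code.  This ordering
#: (together with SS3_ORDER) fixes the 60-type index once and for all.
AMINO_ACIDS: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

SS3_ORDER: tuple[str, ...] = ("H", "E", "O")

N_TYPES = len(AMINO_ACIDS) * len(SS3_ORDER)  # 60

_AA_RANK = {aa: k for k, aa in enumerate(AMINO_ACIDS)}
_SS_RANK = {ss: k for k, ss in enumerate(SS3_ORDER)}

#: Nonstandard residues mapped onto standard parents; anything else is skipped.
NONSTANDARD_MAP = {"MSE": "MET"}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class PseudoResidue:
    """One residue reduced to a typed pseudo-atom.

    ``centroid`` is the side-chain geometric center (main-chain for GLY) in
    Angstroms; ``backbone`` maps backbone atom names (N, CA, C, O) to
    coordinates where present, so backbone RMSDs and PDB output remain
    possible after coarse-graining.
    """

    chain_id: str
    residue_number: int
    amino_acid: str
    ss3: str
    centroid: np.ndarray
    icode: str = ""
    backbone: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.amino_acid not in _AA_RANK:
            raise ValueError(f"nonstandard amino acid {self.amino_acid!r}")
        if self.ss3 not in _SS_RANK:
            raise ValueError(f"invalid 3-state secondary structure {self.ss3!r}")
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.centroid.shape != (3,) or not np.all(np.isfinite(self.centroid)):
            raise ValueError("centroid must be a finite 3-vector")

    @property
    def type_index(self) -> int:
        return assign_residue_type(self.amino_acid, self.ss3)

    @property
    def key(self) -> tuple[str, int, str]:
        """Identifier (chain, author residue number, insertion code)."""
        return (self.chain_id, self.residue_number, self.icode)


@dataclass
class PartnerStructure:
    """One docking partner (receptor or ligand) as an ordered list of
    pseudo-residues."""

    label: str
    residues: list[PseudoResidue]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("partner structure must contain at least one residue")
        keys = [r.key for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate residue identifiers within partner")

    def __len__(self) -> int:
        return len(self.residues)

    def centroids(self) -> np.ndarray:
        """(n, 3) array of pseudo-atom coordinates."""
        return np.array([r.centroid for r in self.residues], dtype=float)

    def type_indices(self) -> np.ndarray:
        """(n,) array of 60-type indices."""
        return np.array([r.type_index for r in self.residues], dtype=np.intp)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PartnerStructure":
        """Return a rigidly moved copy: x -> R x + t for every coordinate."""
        rotation = np.asarray(rotation, dtype=float)
        translation = np.asarray(translation, dtype=float)
        moved = []
        for r in self.residues:
            moved.append(
                PseudoResidue(
                    chain_id=r.chain_id,
                    residue_number=r.residue_number,
                    amino_acid=r.amino_acid,
                    ss3=r.ss3,
                    centroid=rotation @ r.centroid + translation,
                    icode=r.icode,
                    backbone={k: rotation @ v + translation for k, v in r.backbone.items()},
                )
            )
        return PartnerStructure(label=self.label, residues=moved)


def assign_residue_type(amino_acid: str, ss3: str) -> int:
    """Map (amino acid, secondary-structure state) to a type index in [0, 59].

    index = 3 * alphabetical-rank(aa) + rank(ss3) with H=0, E=1, O=2.
    """
    try:
        aa_rank = _AA_RANK[amino_acid]
    except KeyError:
        raise ValueError(f"nonstandard amino acid {amino_acid!r}") from None
    try:
        ss_rank = _SS_RANK[ss3]
    except KeyError:
        raise ValueError(f"invalid secondary structure state {ss3!r}") from None
    return 3 * aa_rank + ss_rank


def type_to_labels(index: int) -> tuple[str, str]:
    """Inverse of :func:`assign_residue_type`."""
    if not 0 <= index < N_TYPES:
        raise ValueError(f"type index {index} outside [0, {N_TYPES - 1}]")
    return AMINO_ACIDS[index // 3], SS3_ORDER[index % 3]


def map_ss_3state(dssp_code: str) -> str:
    """Collapse an 8-state DSSP code to {H, E, O}.

    Only 'H' and 'E' survive; G, I, B, T, S and blank all become O.  Unknown
    codes also map to O, with a warning.
    """
    code = (dssp_code or " ").strip().upper() or "-"
    if code == "H":
        return "H"
    if code == "E":
        return "E"
    if code not in {"G", "I", "B", "T", "S", "-", "P"}:
        warnings.warn(f"unknown DSSP code {dssp_code!r}; treated as O", stacklevel=2)
    return "O"


def side_chain_centroid(residue_atoms: list[tuple[str, np.ndarray]]) -> np.ndarray:
    """Geometric (unweighted) center of the side-chain heavy atoms.

    Side chain means every heavy atom other than the backbone (N, CA, C, O and
    the terminal OXT); hydrogens must already be excluded by the caller or are
    ignored here by element inference from the atom name.  For glycine-like
    inputs with no side-chain atoms, the main-chain heavy atoms are averaged;
    failing that, CA is used as a fallback (with a warning).
    """
    if not residue_atoms:
        raise ValueError("empty atom list")
    backbone_names = set(BACKBONE_ATOMS) | {"OXT"}
    side, main, ca = [], [], None
    for name, xyz in residue_atoms:
        name = name.strip().upper()
        if _is_hydrogen(name):
            continue
        xyz = np.asarray(xyz, dtype=float)
        if name in backbone_names:
            if name != "OXT":
                main.append(xyz)
            if name == "CA":
                ca = xyz
        else:
            side.append(xyz)
    if side:
        return np.mean(side, axis=0)
    if main:
        return np.mean(main, axis=0)
    if ca is not None:  # pragma: no cover - main includes CA
        return ca
    raise ValueError("no heavy atoms usable for centroid")


def _is_hydrogen(name: str) -> bool:
    # PDB v3 hydrogen names: H, HA, 1HB, HD11 ... deuterium D*.  Standard
    # amino acids contain no heavy element whose symbol starts with H or D.
    stripped = name.lstrip("0123456789")
    return stripped[:1] in ("H", "D")


def parse_dssp(path: str | Path) -> dict[tuple[str, int, str], str]:
    """Read a DSSP output file into {(chain, resnum, icode): 8-state code}.

    Chain-break ('!') lines are absent from the mapping.  Residues present in
    the PDB but missing here should be assigned 'O' by the caller.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dssp_dict, _keys = make_dssp_dict(str(path))
    out: dict[tuple[str, int, str], str] = {}
    for (chain_id, res_id), values in dssp_dict.items():
        _het, resnum, icode = res_id
        out[(chain_id, int(resnum), icode.strip())] = values[1]
    return out


def read_pdb(
    path: str | Path,
    chain_selection: set[str] | None = None,
    *,
    label: str = "receptor",
    ss_map: dict[tuple[str, int, str], str] | None = None,
) -> PartnerStructure:
    """Parse ATOM records of the selected chains into a :class:`PartnerStructure`.

    Policy: altlocs resolved to the highest-occupancy conformer (first in file
    on ties); waters and hetero residues ignored except MSE, which is treated
    as MET; residues whose centroid cannot be resolved are skipped with a
    warning.  ``ss_map`` supplies 8-state DSSP codes keyed like the output of
    :func:`parse_dssp`; residues absent from it get ss3='O'.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    residues: list[PseudoResidue] = []
    for chain in model:
        if chain_selection is not None and chain.id not in chain_selection:
            continue
        for res in chain:
            hetflag, resnum, icode = res.id
            resname = res.get_resname().strip()
            if hetflag.strip():  # hetero/water
                if resname in NONSTANDARD_MAP:
                    resname = NONSTANDARD_MAP[resname]
                else:
                    continue
            elif resname in NONSTANDARD_MAP:
                resname = NONSTANDARD_MAP[resname]
            if resname not in _AA_RANK:
                logger.warning("skipping nonstandard residue %s %s%s", resname, chain.id, resnum)
                continue
            atoms = []
            backbone: dict[str, np.ndarray] = {}
            for atom in _resolved_atoms(res):
                if atom.element == "H" or atom.element == "D":
                    continue
                coord = np.asarray(atom.coord, dtype=float)
                atoms.append((atom.get_name(), coord))
                if atom.get_name() in BACKBONE_ATOMS:
                    backbone[atom.get_name()] = coord
            if not atoms:
                logger.warning("residue %s %s%s has no usable atoms; skipped", resname, chain.id, resnum)
                continue
            try:
                centroid = side_chain_centroid(atoms)
            except ValueError:
                logger.warning("no centroid for %s %s%s; skipped", resname, chain.id, resnum)
                continue
            key = (chain.id, int(resnum), icode.strip())
            ss8 = ss_map.get(key, "-") if ss_map else "-"
            residues.append(
                PseudoResidue(
                    chain_id=chain.id,
                    residue_number=int(resnum),
                    amino_acid=resname,
                    ss3=map_ss_3state(ss8),
                    centroid=centroid,
                    icode=icode.strip(),
                    backbone=backbone,
                )
            )
    if not residues:
        raise ValueError(f"no residues parsed from {path} for chains {chain_selection}")
    return PartnerStructure(label=label, residues=residues)


def _resolved_atoms(res):
    """Yield atoms with altlocs resolved to highest occupancy, first-wins ties."""
    for atom in res:
        if atom.is_disordered():
            children = atom.disordered_get_list()
            best = max(children, key=lambda a: (a.get_occupancy() or 0.0))
            # max() keeps the first maximal element -> first-in-file wins ties
            yield best
        else:
            yield atom


def assign_ss_heuristic(partner: PartnerStructure) -> PartnerStructure:
    """Crude phi/psi-free 3-state assigner for synthetic fixtures ONLY.

    This is NOT DSSP: it labels every residue 'O'.  Real pipelines must supply
    DSSP output; synthetic fixtures carry their SS labels from the generator.
    """
    warnings.warn("heuristic SS assigner is for synthetic fixtures only, not a DSSP substitute")
    residues = [
        PseudoResidue(r.chain_id, r.residue_number, r.amino_acid, "O", r.centroid, r.icode, dict(r.backbone))
        for r in partner.residues
    ]
    return PartnerStructure(label=partner.label, residues=residues)


# ---------------------------------------------------------------------------
# pseudo-residue table I/O (debugging / fixtures)

_TABLE_HEADER = "chain\tresnum\ticode\taa\tss3\tx\ty\tz"


def write_pseudo_table(partner: PartnerStructure, path: str | Path) -> None:
    """Write a tab-separated pseudo-residue table (coordinates at 3 decimals)."""
    lines = [f"# dockpot pseudo-residues v1\tlabel={partner.label}", _TABLE_HEADER]
    for r in partner.residues:
        x, y, z = r.centroid
        lines.append(
            f"{r.chain_id}\t{r.residue_number}\t{r.icode}\t{r.amino_acid}\t{r.ss3}\t{x:.3f}\t{y:.3f}\t{z:.3f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_pseudo_table(path: str | Path) -> PartnerStructure:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("# dockpot pseudo-residues"):
        raise ValueError("not a pseudo-residue table")
    label = "receptor"
    for tok in lines[0].split("\t"):
        if tok.startswith("label="):
            label = tok[len("label="):]
    residues = []
    for line in lines[1:]:
        if not line or line.startswith(("#", "chain\t")):
            continue
        chain, resnum, icode, aa, ss3, x, y, z = line.split("\t")
        residues.append(
            PseudoResidue(chain, int(resnum), aa, ss3, np.array([float(x), float(y), float(z)]), icode)
        )
    return PartnerStructure(label=label, residues=residues)


def write_pdb(partners: list[PartnerStructure], path: str | Path) -> None:
    """Write backbone atoms (plus a CB-named pseudo-atom at the centroid) as a
    minimal PDB file, sufficient for round-tripping synthetic fixtures."""
    serial = 1
    lines = []
    for partner in partners:
        for r in partner.residues:
            named = list(r.backbone.items())
            if r.amino_acid != "GLY":
                named.append(("CB", r.centroid))
            for name, xyz in named:
                pad_name = f" {name:<3s}" if len(name) < 4 else name
                lines.append(
                    f"ATOM  {serial:5d} {pad_name}{'':1s}{r.amino_acid:>3s} {r.chain_id:1s}"
                    f"{r.residue_number:4d}{r.icode or ' ':1s}   "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {name[0]:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
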