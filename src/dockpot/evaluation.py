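"""Hit labelling, RMSD metrics, and success-rate-vs-top-N evaluation.

A hit is a pose within a strict RMSD threshold of the co-crystallized
complex.  Three presets exist: ligand backbone RMSD < 5 A (the training /
CAPRI-comparable criterion), ligand RMSD < 10 A, and interface C-alpha
RMSD < 2.5 A.  Ligand RMSD is computed in the receptor-fixed frame with no
re-superposition of the ligand; interface RMSD superposes the model onto the
native over the native-interface C-alpha set first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .pair_stats import DistanceBinning, collect_pair_counts
from .reference_states import derive_ref5
from .scoring import ScoreRecord, score_decoy_set
from .structure_io import BACKBONE_ATOMS, PartnerStructure


@dataclass(frozen=True)
class HitCriterion:
    metric: str  # ligand_backbone_rmsd | interface_calpha_rmsd
    threshold: float

    def __post_init__(self) -> None:
        if self.metric not in {"ligand_backbone_rmsd", "interface_calpha_rmsd"}:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


#: the three standard presets
LIGAND_5A = HitCriterion("ligand_backbone_rmsd", 5.0)
LIGAND_10A = HitCriterion("ligand_backbone_rmsd", 10.0)
INTERFACE_2_5A = HitCriterion("interface_calpha_rmsd", 2.5)

PRESETS = {"ligand-5": LIGAND_5A, "ligand-10": LIGAND_10A, "interface-2.5": INTERFACE_2_5A}


@dataclass
class EvaluationResult:
    per_complex: dict[str, list[bool]]
    success_rate: dict[int, float]  # topN -> percentage
    n_complexes_with_hits: int

    def __post_init__(self) -> None:
        rates = [self.success_rate[n] for n in sorted(self.success_rate)]
        if any(b < a - 1e-12 for a, b in zip(rates, rates[1:])):
            raise ValueError("success rate must be non-decreasing in N")
        if any(not 0 <= r <= 100 for r in rates):
            raise ValueError("success rates must be percentages")


def _paired_backbone(native: PartnerStructure, posed: PartnerStructure) -> tuple[np.ndarray, np.ndarray]:
    """Backbone atoms paired by (residue key, atom name); order follows the
    native residue list."""
    posed_by_key = {r.key: r for r in posed.residues}
    a, b = [], []
    for rn in native.residues:
        rp = posed_by_key.get(rn.key)
        if rp is None:
            raise ValueError(f"residue {rn.key} missing from posed ligand")
        for name in BACKBONE_ATOMS:
            if name in rn.backbone and name in rp.backbone:
                a.append(rn.backbone[name])
                b.append(rp.backbone[name])
    if not a:
        raise ValueError("no paired backbone atoms")
    return np.array(a), np.array(b)


def ligand_rmsd(native_ligand: PartnerStructure, posed_ligand: PartnerStructure) -> float:
    """Backbone RMSD of the posed ligand against the native one, receptor
    frames assumed already superposed — no further fitting is applied."""
    a, b = _paired_backbone(native_ligand, posed_ligand)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _kabsch_rmsd(ref: np.ndarray, mov: np.ndarray) -> float:
    """Least-squares RMSD after optimal superposition of mov onto ref."""
    rc, mc = ref.mean(axis=0), mov.mean(axis=0)
    p, q = ref - rc, mov - mc
    h = q.T @ p
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    r = vt.T @ d @ u.T
    diff = p - q @ r.T
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def interface_calpha_rmsd(
    native: tuple[PartnerStructure, PartnerStructure],
    model: tuple[PartnerStructure, PartnerStructure],
    interface_def_radius: float = 10.0,
) -> float:
    """C-alpha RMSD over the native-defined interface after superposition.

    Interface residues are those of either partner whose centroid lies within
    ``interface_def_radius`` of any centroid of the other partner, determined
    on the NATIVE complex; the model is least-squares superposed onto the
    native over exactly that C-alpha set.
    """
    nat_r, nat_l = native
    mod_r, mod_l = model
    d = cdist(nat_r.centroids(), nat_l.centroids())
    rec_iface = np.nonzero((d <= interface_def_radius).any(axis=1))[0]
    lig_iface = np.nonzero((d <= interface_def_radius).any(axis=0))[0]
    if rec_iface.size == 0 and lig_iface.size == 0:
        raise ValueError("empty native interface")
    ref, mov = [], []
    for partner_nat, partner_mod, idx in ((nat_r, mod_r, rec_iface), (nat_l, mod_l, lig_iface)):
        mod_by_key = {r.key: r for r in partner_mod.residues}
        for k in idx:
            rn = partner_nat.residues[k]
            rm = mod_by_key.get(rn.key)
            if rm is None or "CA" not in rn.backbone or "CA" not in rm.backbone:
                continue
            ref.append(rn.backbone["CA"])
            mov.append(rm.backbone["CA"])
    if len(ref) < 3:
        raise ValueError("fewer than 3 paired interface C-alpha atoms")
    return _kabsch_rmsd(np.array(ref), np.array(mov))


def label_hits(records: list[ScoreRecord], criterion: HitCriterion) -> list[bool]:
    """Hit flags in ranking order; strict '<' against the threshold."""
    flags = []
    for r in records:
        if r.rmsd_label is None:
            raise ValueError(f"record {r.match_id} has no RMSD label")
        flags.append(r.rmsd_label < criterion.threshold)
    return flags


def success_rate(
    per_complex_flags: dict[str, list[bool]],
    top_n_values: list[int],
) -> EvaluationResult:
    """Percentage of complexes with >=1 hit among the first N ranked poses."""
    if not per_complex_flags:
        raise ValueError("no complexes to evaluate")
    n_complexes = len(per_complex_flags)
    rates = {}
    for n in top_n_values:
        hit = sum(1 for flags in per_complex_flags.values() if any(flags[:n]))
        rates[n] = 100.0 * hit / n_complexes
    n_any = sum(1 for flags in per_complex_flags.values() if any(flags))
    return EvaluationResult(
        per_complex=dict(per_complex_flags),
        success_rate=rates,
        n_complexes_with_hits=n_any,
    )


def evaluate_ranking(
    decoy_sets,
    potential,
    criterion: HitCriterion,
    top_n_values: list[int],
) -> EvaluationResult:
    """Score each decoy set, label hits from stored RMSDs, aggregate."""
    flags = {}
    for ds in decoy_sets:
        records = score_decoy_set(ds, potential)
        flags[ds.complex_id] = label_hits(records, criterion)
    return success_rate(flags, top_n_values)


def train_ref5(decoy_sets, binning: DistanceBinning, near_threshold: float = 5.0, **derive_kwargs):
    """Train a state-5 potential from labelled decoy sets: poses with ligand
    RMSD below ``near_threshold`` feed the observed statistics, the rest the
    expected (decoy) statistics."""
    near, dec = [], []
    for ds in decoy_sets:
        for pose in ds.poses:
            pair = (pose.receptor, pose.ligand_pose())
            (near if pose.rmsd_label is not None and pose.rmsd_label < near_threshold else dec).append(pair)
    near_t = collect_pair_counts(near, binning, n_complexes=len(decoy_sets))
    dec_t = collect_pair_counts(dec, binning, n_complexes=len(decoy_sets))
    return derive_ref5(near_t, dec_t, **derive_kwargs)


def cutoff_sweep(
    decoy_sets,
    cutoffs: list[float],
    top_n_values: list[int],
    eval_sets=None,
    n_bins: int = 21,
    criterion: HitCriterion = LIGAND_5A,
) -> dict[float, dict[int, float]]:
    """Retrain a state-5 potential per cutoff (n_bins bins each) on the given
    labelled decoy sets and evaluate top-N success.

    ``eval_sets`` defaults to the training sets; pass held-out complexes to
    measure transferable (rather than memorized) discrimination.  Returns
    {cutoff: {topN: percent}}.  Deterministic for fixed inputs.
    """
    if not cutoffs:
        raise ValueError("empty cutoff list")
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be ascending")
    if eval_sets is None:
        eval_sets = decoy_sets
    out: dict[float, dict[int, float]] = {}
    for cutoff in cutoffs:
        binning = DistanceBinning(cutoff=cutoff, n_bins=n_bins)
        pot = train_ref5(decoy_sets, binning)
        result = evaluate_ranking(eval_sets, pot, criterion, top_n_values)
        out[cutoff] = result.success_rate
    return out


def write_success_curve(result: EvaluationResult, path) -> None:
    from pathlib import Path

    lines = ["topN\tpercent"]
    for n in sorted(result.success_rate):
        lines.append(f"{n}\t{result.success_rate[n]:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")
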