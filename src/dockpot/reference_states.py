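"""Inverse-Boltzmann energy tables under five reference states.

Every potential has the form

    e(i, j, d) = -RT * ln( pi_obs(i, j, d) / pi_exp(i, j, d) ),   RT = 1,

where the observed statistics come from near-native docking matches and the
expected statistics model the non-interacting state.  The five states differ
in how the two probabilities are built from pair counts:

1. joint pair probability scaled by the mole-fraction product chi_i*chi_j,
   with the expected side computed identically from non-native decoys
   (decoy interface composition included);
2. random mixing (KBP-style): observed N(i,j,d)/N(d) against chi_i*chi_j,
   both from the near-native matches;
3. Sippl sparse-data correction: the observed distribution is a convex blend
   of the distance marginal f(d) and the pair-conditional g_ij(d) with weight
   m_ij*sigma/(1 + m_ij*sigma), sigma = 0.02, against f(d);
4. RAPDF-style conditional: g_ij(d) against f(d), both near-native;
5. decoys-as-reference: near-native g_ij(d) against the decoy g_ij(d) — the
   best-performing state, and the basis of the single-bin (0-8 A) contact
   variant.

Sparse cells are handled by an additive pseudocount applied at the counts
level inside every smoothed distribution, an energy cap, and the rule that a
pair type never observed on the near-native side scores 0 (neutral) rather
than the cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pair_stats import DistanceBinning, PairCountTable, mole_fractions
from .structure_io import N_TYPES, assign_residue_type, type_to_labels

DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_ENERGY_CAP = 10.0
RT = 1.0

REFERENCE_STATES = ("1", "2", "3", "4", "5", "contact")


@dataclass
class ProbabilityTable:
    """pi(i,j,d) under one normalization mode.

    joint: sums to 1 over (i,j,d); conditional_pair: sums to 1 over d for
    every non-empty pair (empty pairs are flagged in ``empty_pairs``);
    conditional_distance: sums to 1 over (i,j) within each bin.
    """

    pi: np.ndarray
    normalization_mode: str
    binning: DistanceBinning
    empty_pairs: np.ndarray | None = None  # boolean (60, 60), conditional modes

    def __post_init__(self) -> None:
        if self.normalization_mode not in {"joint", "conditional_pair", "conditional_distance"}:
            raise ValueError(f"unknown normalization mode {self.normalization_mode!r}")
        if np.any(self.pi < -1e-15) or np.any(self.pi > 1 + 1e-12):
            raise ValueError("probabilities outside [0, 1]")


@dataclass
class PotentialTable:
    """Energies e(i,j,d) for one reference state, with its binning and the
    smoothing policy that produced it."""

    energies: np.ndarray
    binning: DistanceBinning
    reference_state: str
    rt: float = RT
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    energy_cap: float = DEFAULT_ENERGY_CAP
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.shape != (N_TYPES, N_TYPES, self.binning.n_bins):
            raise ValueError("energy grid shape mismatch with binning")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("non-finite energies")
        if str(self.reference_state) not in REFERENCE_STATES:
            raise ValueError(f"unknown reference state {self.reference_state!r}")
        self.reference_state = str(self.reference_state)

    def validate_symmetry(self) -> None:
        if not np.allclose(self.energies, self.energies.transpose(1, 0, 2), atol=0):
            raise ValueError("energy table not symmetric")


# ---------------------------------------------------------------------------
# smoothed building-block distributions

def _smoothed_joint(table: PairCountTable, eps: float) -> np.ndarray:
    c = table.counts + eps
    return c / c.sum()


def _smoothed_conditional_pair(table: PairCountTable, eps: float) -> np.ndarray:
    c = table.counts + eps
    with np.errstate(divide="ignore", invalid="ignore"):
        return c / c.sum(axis=2, keepdims=True)


def _smoothed_distance_marginal(table: PairCountTable, eps: float) -> np.ndarray:
    c = table.n_pairs_per_bin + eps
    return c / c.sum()


def _smoothed_chi(table: PairCountTable, eps: float) -> np.ndarray:
    c = table.n_residue + eps
    return c / c.sum()


def _pair_totals(table: PairCountTable) -> np.ndarray:
    """Raw per-pair totals m_ij = sum_d N(i,j,d)."""
    return table.counts.sum(axis=2)


# ---------------------------------------------------------------------------
# probability-table constructors (exact, no smoothing — analysis utilities)

def prob_joint(table: PairCountTable) -> ProbabilityTable:
    """pi(i,j,d) = N(i,j,d) / sum N; the full joint distribution."""
    total = table.counts.sum()
    if total <= 0:
        raise ValueError("empty pair-count table")
    return ProbabilityTable(table.counts / total, "joint", table.binning)

def prob_conditional_pair(table: PairCountTable) -> ProbabilityTable:
    """pi(d | i,j) = N(i,j,d) / m_ij; empty pairs flagged, not zero-normalized."""
    m = _pair_totals(table)
    empty = m == 0
    pi = np.zeros_like(table.counts, dtype=float)
    nz = ~empty
    pi[nz] = table.counts[nz] / m[nz][:, None]
    return ProbabilityTable(pi, "conditional_pair", table.binning, empty_pairs=empty)

def prob_distance_marginal(table: PairCountTable) -> np.ndarray:
    """f(d) = N(d) / sum N(d'), independent of residue types."""
    total = table.n_pairs_per_bin.sum()
    if total <= 0:
        raise ValueError("empty pair-count table")
    return table.n_pairs_per_bin / total


# ---------------------------------------------------------------------------
# energy assembly

def energy_from_probs(
    obs: ProbabilityTable,
    exp: ProbabilityTable,
    rt: float = RT,
    energy_cap: float = DEFAULT_ENERGY_CAP,
) -> PotentialTable:
    """e = -rt * ln(pi_obs / pi_exp), cells where both vanish scoring 0 and
    everything clamped to +/- energy_cap (an observed-only zero maps to +cap,
    an expected-only zero to -cap)."""
    if obs.pi.shape != exp.pi.shape or obs.binning != exp.binning:
        raise ValueError("shape/binning mismatch between observed and expected")
    po, pe = obs.pi, exp.pi
    e = np.zeros_like(po)
    both = (po > 0) & (pe > 0)
    e[both] = -rt * np.log(po[both] / pe[both])
    e[(po == 0) & (pe > 0)] = energy_cap
    e[(po > 0) & (pe == 0)] = -energy_cap
    np.clip(e, -energy_cap, energy_cap, out=e)
    return PotentialTable(
        energies=e,
        binning=obs.binning,
        reference_state="4",  # caller overwrites; placeholder valid state
        rt=rt,
        pseudocount=0.0,
        energy_cap=energy_cap,
    )


def _finalize(
    e: np.ndarray,
    binning: DistanceBinning,
    state: str,
    pseudocount: float,
    energy_cap: float,
    provenance: dict,
    neutral_pairs: np.ndarray | None = None,
) -> PotentialTable:
    e = np.nan_to_num(e, nan=0.0, posinf=energy_cap, neginf=-energy_cap)
    if neutral_pairs is not None:
        e[neutral_pairs] = 0.0
    np.clip(e, -energy_cap, energy_cap, out=e)
    # numerical noise cleanup: identical obs/exp must give exactly zero
    e[np.abs(e) < 1e-15] = 0.0
    pot = PotentialTable(
        energies=e,
        binning=binning,
        reference_state=state,
        pseudocount=pseudocount,
        energy_cap=energy_cap,
        provenance=provenance,
    )
    pot.validate_symmetry()
    return pot


def _check_shared_binning(a: PairCountTable, b: PairCountTable) -> None:
    if a.binning != b.binning:
        raise ValueError("near-native and decoy tables use different binnings")


def derive_ref1(
    near: PairCountTable,
    decoys: PairCountTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    energy_cap: float = DEFAULT_ENERGY_CAP,
) -> PotentialTable:
    """State 1: joint pair probability x mole-fraction product, observed from
    near-native matches, expected built identically from decoys."""
    _check_shared_binning(near, decoys)
    if pseudocount > 0:
        po = _smoothed_joint(near, pseudocount) * np.outer(_smoothed_chi(near, pseudocount), _smoothed_chi(near, pseudocount))[:, :, None]
        pe = _smoothed_joint(decoys, pseudocount) * np.outer(_smoothed_chi(decoys, pseudocount), _smoothed_chi(decoys, pseudocount))[:, :, None]
        e = _log_ratio(po, pe)
    else:
        chi_n = mole_fractions(near).chi
        chi_d = mole_fractions(decoys).chi
        po = prob_joint(near).pi * np.outer(chi_n, chi_n)[:, :, None]
        pe = prob_joint(decoys).pi * np.outer(chi_d, chi_d)[:, :, None]
        e = _raw_log_ratio(po, pe, energy_cap)
    return _finalize(
        e, near.binning, "1", pseudocount, energy_cap,
        {"form": "joint*chi_i*chi_j (obs: near-native, exp: decoys)"},
        neutral_pairs=_never_observed(near),
    )


def derive_ref2(
    near: PairCountTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    energy_cap: float = DEFAULT_ENERGY_CAP,
) -> PotentialTable:
    """State 2 (KBP-style random mixing): N(i,j,d)/N(d) against chi_i*chi_j."""
    if pseudocount > 0:
        po = (near.counts + pseudocount) / (near.n_pairs_per_bin + pseudocount * N_TYPES * N_TYPES)[None, None, :]
        chi = _smoothed_chi(near, pseudocount)
        pe = np.outer(chi, chi)[:, :, None] * np.ones(near.binning.n_bins)[None, None, :]
        e = _log_ratio(po, pe)
    else:
        nd = near.n_pairs_per_bin.astype(float)
        po = np.zeros_like(near.counts, dtype=float)
        nz = nd > 0
        po[:, :, nz] = near.counts[:, :, nz] / nd[nz]
        chi = mole_fractions(near).chi
        pe = np.outer(chi, chi)[:, :, None] * np.ones(near.binning.n_bins)[None, None, :]
        e = _raw_log_ratio(po, pe, energy_cap)
    return _finalize(
        e, near.binning, "2", pseudocount, energy_cap,
        {"form": "N(i,j,d)/N(d) vs chi_i*chi_j (near-native)"},
        neutral_pairs=_never_observed(near),
    )


def derive_ref3(
    near: PairCountTable,
    sigma: float = 0.02,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    energy_cap: float = DEFAULT_ENERGY_CAP,
) -> PotentialTable:
    """State 3 (Sippl sparse-data correction).

    pi_obs = f(d)/(1 + m_ij*sigma) + g_ij(d)*m_ij*sigma/(1 + m_ij*sigma),
    pi_exp = f(d).  With no data (m_ij = 0) the pair collapses exactly to the
    reference and scores 0; with abundant data it converges to state 4.
    """
    m = _pair_totals(near).astype(float)
    w = (m * sigma) / (1.0 + m * sigma)  # weight on the pair-specific term
    f = _smoothed_distance_marginal(near, pseudocount)
    g = _smoothed_conditional_pair(near, pseudocount)
    po = (1.0 - w)[:, :, None] * f[None, None, :] + w[:, :, None] * g
    e = _log_ratio(po, f[None, None, :])
    return _finalize(
        e, near.binning, "3", pseudocount, energy_cap,
        {"form": "Sippl blend of f(d) and g_ij(d) vs f(d)", "sigma": sigma},
    )


def derive_ref4(
    near: PairCountTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    energy_cap: float = DEFAULT_ENERGY_CAP,
) -> PotentialTable:
    """State 4 (RAPDF-style): g_ij(d) against the distance marginal f(d)."""
    f = _smoothed_distance_marginal(near, pseudocount)
    g = _smoothed_conditional_pair(near, pseudocount)
    e = _log_ratio(g, f[None, None, :])
    return _finalize(
        e, near.binning, "4", pseudocount, energy_cap,
        {"form": "g_ij(d) vs f(d) (near-native)"},
        neutral_pairs=_never_observed(near),
    )


def derive_ref5(
    near: PairCountTable,
    decoys: PairCountTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    energy_cap: float = DEFAULT_ENERGY_CAP,
    _state_label: str = "5",
) -> PotentialTable:
    """State 5 (decoys as reference): near-native g_ij(d) against decoy g_ij(d).

    With a single distance bin the conditional distribution is degenerate
    (identically 1), so the derivation switches to the joint contact-share
    distribution m_ij / sum m — a contact-count log-odds.  This is the same
    policy :func:`derive_contact` uses, making the two routes identical on
    one-bin binnings.
    """
    _check_shared_binning(near, decoys)
    if near.binning.n_bins == 1:
        mn = _pair_totals(near).astype(float) + pseudocount
        md = _pair_totals(decoys).astype(float) + pseudocount
        if pseudocount == 0:
            e = _raw_log_ratio((mn / mn.sum())[:, :, None], (md / md.sum())[:, :, None], energy_cap)
        else:
            e = _log_ratio(mn / mn.sum(), md / md.sum())[:, :, None]
        form = "contact log-odds m_ij/sum(m) near vs decoys (single bin)"
    else:
        if pseudocount == 0:
            e = _raw_log_ratio(prob_conditional_pair(near).pi, prob_conditional_pair(decoys).pi, energy_cap)
        else:
            gn = _smoothed_conditional_pair(near, pseudocount)
            gd = _smoothed_conditional_pair(decoys, pseudocount)
            e = _log_ratio(gn, gd)
        form = "g_ij(d) near-native vs g_ij(d) decoys"
    return _finalize(
        e, near.binning, _state_label, pseudocount, energy_cap,
        {"form": form},
        neutral_pairs=_never_observed(near),
    )


def derive_contact(
    near: PairCountTable,
    decoys: PairCountTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    energy_cap: float = DEFAULT_ENERGY_CAP,
) -> PotentialTable:
    """Contact potential: state 5 on a single 0-8 A bin.

    Inputs may carry any binning with cutoff 8 A; their counts are first
    collapsed onto the one-bin binning, then the state-5 single-bin rule
    applies.
    """
    _check_shared_binning(near, decoys)
    if abs(near.binning.cutoff - 8.0) > 1e-9:
        raise ValueError("contact potential requires an 8 A cutoff on the input counts")
    one_bin = DistanceBinning(cutoff=8.0, n_bins=1)
    pot = derive_ref5(
        _rebin_to_single(near, one_bin),
        _rebin_to_single(decoys, one_bin),
        pseudocount=pseudocount,
        energy_cap=energy_cap,
        _state_label="contact",
    )
    return pot


def _rebin_to_single(table: PairCountTable, one_bin: DistanceBinning) -> PairCountTable:
    return PairCountTable(
        binning=one_bin,
        counts=table.counts.sum(axis=2, keepdims=True),
        n_pairs_per_bin=np.array([table.n_pairs_per_bin.sum()]),
        n_residue=table.n_residue.copy(),
        n_matches=table.n_matches,
        n_complexes=table.n_complexes,
    )


def _never_observed(near: PairCountTable) -> np.ndarray:
    """(60, 60, 1)-broadcastable mask of pair types absent from the observed
    statistics; such pairs stay neutral (0) instead of inheriting the cap."""
    return (_pair_totals(near) == 0)[:, :, None] & np.ones(near.binning.n_bins, dtype=bool)[None, None, :]


def _log_ratio(po: np.ndarray, pe: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return -RT * np.log(po / pe)


def _raw_log_ratio(po: np.ndarray, pe: np.ndarray, energy_cap: float) -> np.ndarray:
    e = np.zeros_like(po, dtype=float)
    both = (po > 0) & (pe > 0)
    e[both] = -RT * np.log(po[both] / pe[both])
    e[(po == 0) & (pe > 0)] = energy_cap
    e[(po > 0) & (pe == 0)] = -energy_cap
    return e


DERIVATIONS = {
    "1": derive_ref1,
    "2": derive_ref2,
    "3": derive_ref3,
    "4": derive_ref4,
    "5": derive_ref5,
    "contact": derive_contact,
}

#: which states consume decoy statistics in addition to near-native ones
NEEDS_DECOYS = {"1": True, "2": False, "3": False, "4": False, "5": True, "contact": True}


def derive(
    state: str,
    near: PairCountTable,
    decoys: PairCountTable | None = None,
    **kwargs,
) -> PotentialTable:
    """Dispatch to the requested reference-state derivation."""
    state = str(state)
    if state not in DERIVATIONS:
        raise ValueError(f"unknown reference state {state!r}")
    if NEEDS_DECOYS[state]:
        if decoys is None:
            raise ValueError(f"reference state {state} requires decoy statistics")
        return DERIVATIONS[state](near, decoys, **kwargs)
    return DERIVATIONS[state](near, **kwargs)


# ---------------------------------------------------------------------------
# potential-table serialization: versioned, self-describing TSV

_POT_VERSION = "dockpot potential v1"


def write_potential(pot: PotentialTable, path: str | Path) -> None:
    """Write a potential table; energies at 6 decimals, upper triangle only
    (the table is symmetric).  Round-trips exactly at that precision."""
    b = pot.binning
    edges = b.edges
    lines = [
        f"# {_POT_VERSION}",
        f"# reference_state={pot.reference_state}",
        f"# cutoff={b.cutoff!r}\tn_bins={b.n_bins}",
        f"# rt={pot.rt!r}\tpseudocount={pot.pseudocount!r}\tenergy_cap={pot.energy_cap!r}",
        f"# provenance={pot.provenance!r}",
        "# columns: aa_i ss_i aa_j ss_j bin_low bin_high energy",
    ]
    for i in range(N_TYPES):
        aa_i, ss_i = type_to_labels(i)
        for j in range(i, N_TYPES):
            aa_j, ss_j = type_to_labels(j)
            for d in range(b.n_bins):
                e = pot.energies[i, j, d]
                if e == 0.0:
                    continue
                lines.append(
                    f"{aa_i}\t{ss_i}\t{aa_j}\t{ss_j}\t{edges[d]:.4f}\t{edges[d + 1]:.4f}\t{e:.6f}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_potential(path: str | Path) -> PotentialTable:
    lines = Path(path).read_text().splitlines()
    if not lines or _POT_VERSION not in lines[0]:
        raise ValueError("not a potential table file")
    meta: dict[str, str] = {}
    body_start = 0
    for k, line in enumerate(lines):
        if line.startswith("#"):
            stripped = line.lstrip("# ")
            for tok in stripped.split("\t"):
                if "=" in tok and not tok.startswith(("provenance", "columns")):
                    key, v = tok.split("=", 1)
                    meta[key] = v
            body_start = k + 1
        else:
            break
    binning = DistanceBinning(cutoff=float(meta["cutoff"]), n_bins=int(meta["n_bins"]))
    energies = np.zeros((N_TYPES, N_TYPES, binning.n_bins))
    width = binning.width
    for line in lines[body_start:]:
        if not line or line.startswith("#"):
            continue
        aa_i, ss_i, aa_j, ss_j, lo, _hi, e = line.split("\t")
        i = assign_residue_type(aa_i, ss_i)
        j = assign_residue_type(aa_j, ss_j)
        d = min(int(round(float(lo) / width)), binning.n_bins - 1)
        energies[i, j, d] = float(e)
        energies[j, i, d] = float(e)
    return PotentialTable(
        energies=energies,
        binning=binning,
        reference_state=meta["reference_state"],
        rt=float(meta.get("rt", RT)),
        pseudocount=float(meta.get("pseudocount", DEFAULT_PSEUDOCOUNT)),
        energy_cap=float(meta.get("energy_cap", DEFAULT_ENERGY_CAP)),
    )
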