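"""Estimator interface: train a potential from labelled poses, score new ones.

:class:`DockingPotential` follows the scikit-learn estimator contract
(``get_params``/``set_params``, ``fit``, fitted attributes with a trailing
underscore) so it composes with sklearn model selection.  ``X`` is a sequence
of poses — ``PosedMatch`` objects or ``(receptor, ligand)`` partner tuples —
and ``y`` the binary near-native labels (1 = near-native); with ``y=None``
labels are taken from each pose's stored ligand RMSD against the 5 A
threshold.  ``score_samples`` returns the interaction energy of each pose:
LOWER is better (energy convention), deliberately opposite to the
density-estimator convention.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .pair_stats import DistanceBinning, collect_pair_counts
from .reference_states import NEEDS_DECOYS, derive
from .scoring import PosedMatch, score_pose
from .structure_io import PartnerStructure


class DockingPotential(BaseEstimator):
    """Distance- and environment-dependent coarse-grained docking potential.

    Parameters
    ----------
    reference_state : {'1', '2', '3', '4', '5', 'contact'}, default='5'
        How the expected (non-interacting) pair distribution is modelled.
        State 5 — near-native statistics against decoy statistics — is the
        best-performing default; 'contact' is its single 0-8 A bin variant.
    cutoff : float, default=10.0
        Maximum pseudo-atom pair distance (A) entering statistics and scores.
        Forced to 8.0 for the contact state.
    n_bins : int, default=21
        Number of uniform distance bins over [0, cutoff).
    pseudocount : float, default=1.0
        Additive count-level smoothing inside every probability estimate.
    energy_cap : float, default=10.0
        Energies clamped to +/- this value (units of RT = 1).
    sigma : float, default=0.02
        Sparse-data weight of the Sippl blend (reference state 3 only).
    near_threshold : float, default=5.0
        Ligand RMSD (A) below which an unlabelled pose counts as near-native.

    Attributes
    ----------
    potential_ : PotentialTable
        The derived energy table e(i, j, d).
    near_counts_, decoy_counts_ : PairCountTable
        Training pair statistics (decoy_counts_ only for states that use one).
    """

    def __init__(
        self,
        reference_state: str = "5",
        cutoff: float = 10.0,
        n_bins: int = 21,
        pseudocount: float = 1.0,
        energy_cap: float = 10.0,
        sigma: float = 0.02,
        near_threshold: float = 5.0,
    ):
        self.reference_state = reference_state
        self.cutoff = cutoff
        self.n_bins = n_bins
        self.pseudocount = pseudocount
        self.energy_cap = energy_cap
        self.sigma = sigma
        self.near_threshold = near_threshold

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _as_pair(item) -> tuple[PartnerStructure, PartnerStructure]:
        if isinstance(item, PosedMatch):
            return item.receptor, item.ligand_pose()
        receptor, ligand = item
        return receptor, ligand

    def _labels(self, X, y) -> np.ndarray:
        if y is not None:
            y = np.asarray(y)
            if len(y) != len(X):
                raise ValueError("X and y length mismatch")
            return y.astype(bool)
        labels = []
        for item in X:
            rmsd = getattr(item, "rmsd_label", None)
            if rmsd is None:
                raise ValueError("y=None requires poses with stored RMSD labels")
            labels.append(rmsd < self.near_threshold)
        return np.array(labels, dtype=bool)

    def _binning(self) -> DistanceBinning:
        state = str(self.reference_state)
        if state == "contact":
            return DistanceBinning(cutoff=8.0, n_bins=self.n_bins)
        return DistanceBinning(cutoff=self.cutoff, n_bins=self.n_bins)

    # -- sklearn API ------------------------------------------------------
    def fit(self, X, y=None) -> "DockingPotential":
        """Derive the energy table from labelled poses."""
        X = list(X)
        if not X:
            raise ValueError("empty training set")
        state = str(self.reference_state)
        labels = self._labels(X, y)
        if not labels.any():
            raise ValueError("no near-native poses in the training set")
        binning = self._binning()
        pairs = [self._as_pair(item) for item in X]
        near = [p for p, is_near in zip(pairs, labels) if is_near]
        dec = [p for p, is_near in zip(pairs, labels) if not is_near]
        self.near_counts_ = collect_pair_counts(near, binning)
        kwargs = dict(pseudocount=self.pseudocount, energy_cap=self.energy_cap)
        if state == "3":
            kwargs["sigma"] = self.sigma
        if NEEDS_DECOYS[state]:
            if not dec:
                raise ValueError(f"reference state {state} needs decoy poses in the training set")
            self.decoy_counts_ = collect_pair_counts(dec, binning)
            self.potential_ = derive(state, self.near_counts_, self.decoy_counts_, **kwargs)
        else:
            self.decoy_counts_ = None
            self.potential_ = derive(state, self.near_counts_, **kwargs)
        return self

    def score_samples(self, X) -> np.ndarray:
        """Interaction energy of each pose; lower = better."""
        self._check_fitted()
        return np.array(
            [score_pose(*self._as_pair(item), self.potential_)[0] for item in X]
        )

    def predict(self, X) -> np.ndarray:
        """Alias for :meth:`score_samples` (energies, lower = better)."""
        return self.score_samples(X)

    def rank(self, X) -> np.ndarray:
        """Indices of poses from best (lowest energy) to worst."""
        scores = self.score_samples(X)
        return np.argsort(scores, kind="stable")

    def _check_fitted(self) -> None:
        if not hasattr(self, "potential_"):
            raise AttributeError("DockingPotential is not fitted; call fit() first")
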