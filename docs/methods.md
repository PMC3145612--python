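# Methods

## Coarse-grained representation

Every residue is a single pseudo-atom at the unweighted geometric center of
its side-chain heavy atoms, CB included, hydrogens excluded; glycine uses the
mean of its main-chain heavy atoms (N, CA, C, O).  Non-glycine residues with
no resolved side-chain atoms fall back to CA rather than being dropped, so
sparse unbound structures remain usable.  MSE is read as MET; other
non-standard residues are skipped with a warning.  Altloc conformers resolve
to the highest occupancy, first-in-file on ties.

Residue types carry a secondary-structure environment.  The three states are
deliberately minimal: DSSP 'H' → H, DSSP 'E' → E, and *everything* else —
including G and I helices and isolated β-bridges, which conventional
three-state groupings assign to helix/strand — → O.  This gives
20 × 3 = 60 types, indexed as 3·rank(aa) + rank(ss) with amino acids ordered
alphabetically by 3-letter code and H < E < O.  Secondary structure is taken
from DSSP output files computed once per unbound monomer; rigid-body poses
cannot change internal secondary structure, so per-pose reassignment would be
wasted work.  Residues absent from the DSSP file get O.

## Pair statistics

Two radii serve different purposes.  Distance histograms N(i,j,d) collect
cross-interface pairs closer than the scoring cutoff (default 10 Å, 21
uniform half-open bins, pairs at exactly the cutoff excluded).  Interface
*composition* N(i) — the input to mole fractions χᵢ — counts residues whose
centroid is within 30 Å (inclusive) of any partner centroid.  Pairs at 30 Å
cannot populate 10 Å histograms, so the two radii cannot feed the same
statistic; this split is the only self-consistent assignment.

Accumulation is symmetrized: each cross pair increments both (i,j,d) and
(j,i,d), and the marginal N(d) counts ordered pairs.  Probability ratios are
invariant to this double-counting as long as it is uniform, and every derived
table satisfies e(i,j,d) = e(j,i,d) by construction.

## Reference states

All five potentials share e = −RT·ln(π_obs/π_exp) with RT ≡ 1.

1. **Decoy-referenced joint/mole-fraction form.**  π_obs is the joint pair
   probability from near-native matches scaled by χᵢχⱼ; π_exp is the same
   construction computed from decoys, including decoy interface composition.
2. **Random mixing.**  π_obs = N(i,j,d)/N(d); π_exp = χᵢχⱼ, distance-free,
   both from near-native matches.
3. **Sparse-data-corrected conditional.**  π_obs blends the distance marginal
   f(d) and the pair-conditional g_ij(d) with weights 1/(1+m_ij σ) and
   m_ij σ/(1+m_ij σ); σ = 0.02, m_ij the raw pair-count total Σ_d N(i,j,d).
   π_exp = f(d).  With no data the pair collapses exactly to the reference
   (energy 0); with abundant data it converges to state 4.
4. **Conditional vs marginal.**  π_obs = g_ij(d), π_exp = f(d), both
   near-native.
5. **Decoys as reference (default).**  π_obs = g_ij(d) from near-native
   matches, π_exp = g_ij(d) from decoys.  Conditioning on the pair type makes
   the state blind to raw type frequencies; only *where* a pair sits relative
   to where it sits in random decoy contacts matters.

**Contact variant.**  On a single 0–8 Å bin the conditional g_ij is
identically 1 and the state-5 form degenerates, so one-bin derivations switch
to the joint contact-share distribution m_ij/Σm — a contact-count log-odds.
`derive_ref5` applies this rule itself whenever n_bins = 1, and
`derive_contact` merely collapses its input histograms (which must carry an
8 Å cutoff) and delegates, so the two routes are identical by shared code
path and by an independent rebinning test.

## Numerical policies

- **Pseudocount.**  ε = 1 added at the counts level inside every smoothed
  distribution (joint, conditional, marginal, mole fractions) before
  normalization.  Identical observed/expected inputs therefore still give
  exactly zero energies.  Hand-arithmetic checks in the tests pass ε = 0,
  where zero-probability cells follow an explicit rule: both zero → 0,
  observed-only zero → +cap, expected-only zero → −cap.
- **Energy cap.**  Energies clamp to ±10 RT, keeping scores finite and
  rank-stable under sparse statistics.
- **Neutral unseen pairs.**  A pair type never observed on the near-native
  side scores 0 rather than the cap, so unseen chemistry is not penalized.
- **Tie-breaking.**  Rankings sort by (score, match_id); equal-scoring poses
  order lexicographically, making every ranking reproducible.
- **Serialization.**  Potentials round-trip through a self-describing TSV at
  6 decimals (upper triangle only); zero cells are omitted and restored.

## Evaluation protocol

A hit is a pose within a strict (`<`) RMSD threshold: ligand backbone RMSD
5 Å (the training and CAPRI-comparable criterion), ligand 10 Å, or interface
Cα RMSD 2.5 Å.  Ligand RMSD is computed in the receptor-fixed frame with no
re-superposition — the standard rigid-docking convention.  Interface-Cα RMSD
defines the interface on the native complex (residue centroid within 10 Å of
the partner) and least-squares-superposes the model onto the native over
exactly that Cα set.  The success rate at top N is the percentage of
complexes with at least one hit among the first N ranked poses; it is
non-decreasing in N and saturates at the fraction of complexes having any
hit.  The cutoff sweep retrains a state-5 potential per cutoff (21 bins
each) and evaluates on the training sets or, optionally, on held-out
complexes; held-out evaluation separates transferable signal from
per-complex memorization.

## Synthetic data

The generator emulates the statistical situation of a rigid-body docking
scan — rare near-native poses in a large random-contact pool — not docking
itself.  Partners are compact random centroid blobs (minimum spacing 3.8 Å)
with zero-mean synthetic backbone frames so backbone RMSDs and PDB output
work.  Defaults are desk-scale: 2,000 poses per complex, ~20 complexes, 1%
near-native; full scan scale (160,000 poses) is a parameter, not a test
requirement.  The 1% fraction keeps a random top-10 baseline near 10%,
mirroring the rarity of hits in real scan output.

Every pose — near-native or decoy — is produced by the *same* operator:
rotate the ligand about its center, approach the receptor along a direction,
stop at a contact gap drawn from one shared distribution (3.2–6 Å), accept
under one clash/contact window (2.5–8 Å).  Near-native poses only constrain
the rotation (≤ 0.3 rad) and the approach direction (cone around the native
one); labels are verified by recomputation and pose identifiers are shuffled
so rank tie-breaking cannot leak the label.  This symmetry matters: early
versions that placed the two classes differently let a potential separate
them through trivial closest-approach statistics alone.  What passing the
planted-signal tests shows is therefore that the potential recovers a
*typed, distance-localized* enrichment — not that it would rank real docking
decoys, which carry shape complementarity, side-chain packing and
electrostatics the generator does not model.

The planted signal retypes residues of in-window (4–6 Å) cross pairs in
near-native poses to one favored pair type, on pose-local copies, leaving
geometry — and hence every RMSD label — untouched.  Composition planting was
chosen over geometry resampling precisely to preserve the labels.

## Training-set bookkeeping

`TrainingManifest` records the corpus the method was developed on: 358
representative bound complexes plus 50 unbound benchmark complexes (set 1,
408 total) or plus 71 bound benchmark complexes (set 2, 429 total), with
160,000 scan poses per complex and the 5 Å near-native threshold.  Totals are
computed from the components, never stored.

## Known limitations

- The potential is residue-level by design; no atom-level reference states,
  volume corrections, or iterative refinement.
- The synthetic generator produces random-contact poses without shape
  complementarity; conclusions about real decoy archives require real data.
- mmCIF input is not supported; DSSP output is consumed, not recomputed.
- State 1's joint×χχ coupling is one consistent reading of a form whose
  original algebra is ambiguous; its provenance metadata flags this, and the
  default state (5) does not depend on it.
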