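# Methods

This note records the models, conventions, parameter choices and known
limitations behind `cdrflex`, at the level of detail a user needs to judge
what a result does and does not mean.

## Data model and units

Coordinates are stored in nanometres throughout (every distance threshold
in the pipeline — 0.15 nm clustering cut-off, 0.45 nm contact cut-off — is
naturally expressed in nm); PDB Ångström values are converted at the I/O
boundary. Residue numbering is 1-based and taken verbatim from the
coordinate file, so loop definitions written against the published residue
ranges apply without renumbering. Region configs are accepted as given and
never reconciled against sequence content. The Boltzmann constant is fixed
at k_B = 0.0083144621 kJ/(mol·K) so that reweighting results are
bit-reproducible.

The native trajectory format is multi-model PDB. That choice keeps the
tested I/O path text-based and exactly reproducible; binary formats can be
converted upstream by any trajectory tool.

## Reweighting

Weights are w_i ∝ exp(V_PB,i / k_B T) with the per-frame parallel-bias
potential consumed as-is: the bias is assumed to be the *time-independent*
bias computed in post-processing, so no time-averaging or final-bias
variant is applied here. The implementation subtracts the maximum reduced
bias before exponentiating, which makes the weights exactly invariant
under adding any constant to the bias (the formula is only defined up to
such a constant, and real bias magnitudes overflow `exp` otherwise). The
Kish effective sample size 1/Σw² is reported as a diagnostic; observables
computed from an ensemble whose ESS is a small fraction of the frame count
carry correspondingly larger errors.

## Pairwise RMSD and superposition

Superposition is the closed-form Kabsch solution (SVD of the 3×3
cross-covariance, with the usual determinant correction so the rotation is
proper; a reflected conformer is *not* considered equivalent). The pairwise
matrix uses the identity

    rmsd²(i,j) = (G_i + G_j − 2(σ₁+σ₂±σ₃)) / n_atoms

with σ the singular values of the cross-covariance of the centred frames
and the sign of σ₃ flipped when the optimum would be improper; this is
evaluated in batched form (one SVD batch per matrix row), so the full
5000×5000 matrix of an 18-residue loop takes ~30 s on one CPU. Loop RMSD
is fit-on-self: the same loop-Cα set is used for the fit and the deviation,
matching the default of standard trajectory clustering tools. Pairwise
fitted RMSD violates the triangle inequality in general; nothing here
assumes it is a metric.

## Clustering

GROMOS/Daura clustering repeatedly takes the frame with the most
neighbours strictly within the cut-off as a centre and removes it with its
neighbours. Neighbour counting is *unweighted* (the original algorithm and
the GROMACS implementation count frames); statistical weights enter only
in the population of each cluster, Σ of member weights. Two determinism
rules are fixed because the algorithm is otherwise ambiguous: candidate
centres with equal neighbour counts resolve to the lowest frame index, and
final cluster ids are ordered by decreasing weighted population with ties
broken by centre index. Hierarchical clustering delegates to
scikit-learn's average-linkage agglomeration on the precomputed matrix,
cut at the distance threshold; centres are medoids.

## Entropies

Cluster entropy is S = −Σ p_i ln p_i in nats (natural log; the base only
rescales and all ranking statements are base-invariant), with 0·ln 0 := 0.

Dihedral entropy uses a weighted 2D histogram of (φ, ψ) on [−π, π]² with
100 bins **per dimension** (a 100×100 grid). A coarser or finer grid is a
parameter; entropy values are only comparable at a fixed bin count, since
the histogram entropy of a continuous distribution grows with resolution.
φ_i is the torsion C(i−1)–N(i)–CA(i)–C(i) and ψ_i is N(i)–CA(i)–C(i)–N(i+1),
IUPAC sign convention; terminal residues lack one angle and are reported
missing and excluded from sums, never imputed.

The bootstrap draws `n_samples` (default 20) samples of
`frames_per_sample` (default 10,000) frames with replacement with
probability equal to the weights, re-clusters each sample from scratch on
the sliced RMSD submatrix with uniform within-sample weights, and reports
the per-sample entropies, their mean and the [2.5, 97.5] percentile band.
Slicing the precomputed matrix makes re-clustering exact and cheap. A
`mode="map"` shortcut reuses the whole-ensemble clustering and only
recounts populations; it is an approximation appropriate for very large
inputs.

## Contacts, collective variables and free energy

Two residues are in contact when any pair of heavy atoms is strictly
closer than 0.45 nm. Pairs with sequence separation < 2 (a residue with
itself and its immediate neighbours) are excluded: nearest-neighbour
heavy-atom contacts are present in every conformation and carry no
conformational signal. Cross-region pairs are unaffected since regions are
disjoint. The exclusion threshold is a parameter for users who want the
literal all-pairs definition.

The two collective variables are the per-frame counts of intra-CDR3 and
CDR3–scaffold residue contacts, each divided by the maximum count of its
class over the ensemble, giving values in [0, 1]. This normalisation is a
package choice (the axes are then directly comparable across ensembles of
different loop lengths); normalising by the theoretical pair count is
available via the returned normalisation constants. The free-energy
surface is F = −k_B T ln(p/p_max) on a weighted 2D histogram (default
50×50 bins over the unit square); empty bins are masked rather than set to
zero, and the occupied minimum anchors F = 0. Only free-energy
*differences* are meaningful; the anchor is a convention.

RMSF superposes every frame onto the weighted mean structure on scaffold
Cα atoms, recomputing the mean after each fit (two iterations), then takes
the weighted root-mean-square deviation of each residue's Cα. Fitting on
the scaffold rather than on all atoms prevents a mobile loop from leaking
apparent fluctuation into the scaffold.

## Convergence

After discarding the first 10% of frames (default), the remaining
ensemble is clustered once as a whole; populations are then recomputed
over the first and second halves with weights renormalised within each
half. Clusters below a population floor of 0.001 (10 frames in 10,000)
are too rare for a meaningful verdict and are excluded. The flag threshold
is calibrated as follows: the weighted bootstrap draws samples of size
ESS/2 (so its standard deviation estimates the error of one
half-trajectory population under the actual weight distribution), and a
cluster is flagged when |Δp| exceeds 3·√2 times that standard deviation —
the √2 because a difference of two independent halves carries twice the
variance of one, and 3 standard errors so that genuinely stationary
ensembles pass at the ~99% level. The 95th-percentile band is reported
alongside as an error bar. The 20-sample percentile band itself is *not*
used as the threshold: extreme percentiles estimated from 20 draws are
noisy and biased narrow, and a ~2-SE threshold flags stationary ensembles
far too often.

The halves are defined by frame index on the concatenated trajectory;
per-walker splits are not recoverable from concatenated input, which is a
documented limitation when walkers are interleaved.

## Synthetic ensembles

The generator emulates the features of a metadynamics ensemble that the
pipeline is sensitive to, with full ground-truth control:

* **Multi-basin structure.** Each basin is a backbone template (N, CA, C,
  O per residue) built from a φ/ψ profile with idealised bond geometry via
  sequential internal-coordinate placement. The flexible loop (default:
  the 18 C-terminal residues of a 40-residue chain, mimicking a long CDR3
  near the C-terminus) takes a basin-specific helix/sheet block pattern;
  the scaffold profile is shared. The stock patterns are ordered so that
  any prefix of them is mutually well separated (≥ ~0.5 nm loop-Cα RMSD),
  and templates are redrawn until the requested `min_separation` holds.
  Basins must satisfy min_separation > 4σ√3 to be resolvable over the
  coordinate noise.
* **Intra-basin fluctuation.** Isotropic Gaussian coordinate noise
  (default σ = 0.02 nm), giving intra-basin pair RMSD ≈ σ√6 ≈ 0.05 nm,
  comfortably inside the 0.15 nm clustering cut-off.
* **Bias.** In `reweight-to-target` mode basins are sampled uniformly and
  each frame carries V = k_B T ln(target population) + constant, so
  reweighting must recover the targets; the constant exercises the shift
  invariance.
* **Dihedral mixtures.** von Mises (φ, ψ) mixtures with known parameters,
  plus an intentionally naive double-loop histogram-entropy oracle kept
  independent of the pipeline implementation.

What the generator does **not** emulate: force-field energetics, side
chains, solvent, correlated (non-isotropic) fluctuations, kinetic ordering
of frames, and bias-potential noise. Passing tests therefore demonstrate
the correctness of the *analysis* — reweighting algebra, clustering
assignment, entropy estimation, contact counting, convergence logic — not
the realism of any simulated ensemble.

## Problem sizes and numerical choices

The reference recovery conditions used in the tests and the acceptance
script are 3 basins with populations 0.6/0.3/0.1, σ = 0.02 nm and 5000
frames (analytic entropy 0.8979 nats, recovered within ±0.05); the
entropy-ranking ladder uses population sets {1.0}, {0.7, 0.3},
{0.4, 0.3, 0.3} (entropies 0 < 0.611 < 1.089 nats) at 400 frames per rung
across 20 seeds; the rare-state construction uses 10⁵ frames with a
minor-state weight of 0.001 on a 16-residue chain. These sizes were chosen
so each stage's sampling error is several times smaller than the effect it
must resolve while a full run stays in the minutes range on one CPU.

Tolerances in tests are tied to the statistics of the construction
(binomial standard errors for recovered populations, half-normal
calibration for split-half differences) or to machine precision for
algebraic identities (shift invariance to 1e-12, histogram-entropy oracle
agreement to 1e-9). Stochastic properties are tested as calibration
statements over multiple seeds rather than hard bounds on a single draw.

All generators and bootstraps take explicit integer seeds, which are
recorded in every JSON output; reruns with the same configuration are
bit-identical.

## Known limitations

* Pairwise-RMSD storage is O(n²); beyond ~2·10⁴ frames the matrix should
  be computed blockwise or the ensemble strided.
* The bias table reader supports the COLVAR dialect (`#! FIELDS` header)
  only; one bias column is consumed per run.
* Hierarchical clustering inherits scikit-learn's memory behaviour on the
  full dense matrix.
* Contact CVs normalised by the ensemble maximum are comparable across
  ensembles only qualitatively; for strict cross-ensemble comparison use
  the returned raw normalisation constants.
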