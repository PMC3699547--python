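# Methods

`connida` implements a multiclass discriminative analysis of whole-brain
resting-state functional connectivity: Pearson-correlation edge features
over a regional parcellation, intrinsic discriminant analysis (IDA) for
supervised dimensionality reduction, one-against-rest linear SVMs under
leave-one-out cross-validation (LOOCV), and back-projection of classifier
weights to rank individual connections. Because clinical scans are rarely
shareable, the package ships a synthetic-data generator that reproduces the
statistical shape of such a study, so the entire pipeline is testable with
known ground truth.

## Connectivity features

Each subject is a region × time matrix of mean BOLD signals (optionally
extracted from a 4-D NIfTI volume plus an integer label atlas by voxel
averaging). The temporal pipeline is:

1. discard the first 5 volumes (magnetic-saturation transient; applied when
   the run has ≥ 20 volumes, configurable);
2. band-pass 0.01–0.08 Hz with a Chebyshev type-I filter, order 4, 0.5 dB
   passband ripple, applied forward–backward (`filtfilt`) for zero phase —
   the family and order are a standard resting-state choice and are
   verified in tests against the filter's analytic frequency response;
3. ordinary-least-squares regression of each region on an intercept, the
   across-region mean time course (global signal; toggleable, as its use is
   contested in the field) and the 6 realignment motion parameters.

Filtering precedes regression by default; the order is a config flag.
Pearson correlations of all region pairs form the feature vector — with
p = 116 regions, p(p−1)/2 = 6670 edges, enumerated as the row-major upper
triangle with 0-based region indices. Correlations are used raw (no Fisher
z-transform). The regression includes an intercept so residuals are
orthogonal to DC, which keeps the subsequent correlation well defined.

## Intrinsic discriminant analysis

Every training sample x_ij (sample j of class i) is decomposed as

    x_ij = m + (m_i − m) + (x_ij − m_i),

a common component (global mean), a class-common component and an
individual difference. With H_cc the matrix of class-mean deviations
weighted by √n_i (so S_cc = H_cc H_ccᵀ is the standard between-class
scatter) and H_ind the matrix of within-class deviations
(S_ind = H_ind H_indᵀ), the transformation matrix W solves the perturbed
generalized eigenproblem

    S_cc w = λ (S_ind + εI) w,

keeping the d eigenvectors of largest λ. The ridge ε > 0 makes the
right-hand side invertible in the small-sample regime (N ≪ P, where S_ind
is singular). ε defaults to 1e−4 × the mean diagonal of S_ind (falling
back to 1e−8 when S_ind vanishes): a scale-free conditioning choice, since
the problem's natural scale is the within-class variance per feature.

**Numerics.** All linear algebra happens in the span of the centered
training samples: a thin QR gives an orthonormal basis Q (rank ≤ N), both
scatters are congruent to small r × r matrices there, and a dense
generalized symmetric eigensolve finishes the job. This is exact — both
scatter operators map the span into itself, and any eigenvector with
λ ≠ 0 lies inside it — and no P × P matrix is ever formed. Columns of W
are normalized to unit length and signs are fixed by making the
largest-magnitude entry positive, so back-projection is reproducible.
Eigenvalue ties at the embedding cut trigger a warning and keep the first
computed basis; ties among the ≈0 eigenvalues beyond rank(S_cc) ≤ c − 1
are structural and silent.

A consequence worth knowing: with c classes, S_cc has rank ≤ c − 1, so
only the first c − 1 embedding dimensions carry class-mean information;
further dimensions are low-within-scatter noise directions. For a 3-class
problem the accuracy-vs-dimension curve is therefore essentially flat
beyond d = 2 on clean synthetic data.

The maximal admissible embedding dimension for a fit on N samples is
N − 1 (the rank bound of the centered span); an 89-subject study admits
d up to 88. Under LOOCV the training folds hold N − 1 samples, so the
dimension grid is capped at N − 2 (with a warning) before any fold runs.

## Classification protocol

One linear SVM per class (hinge loss, C = 1 by default, unweighted — the
embeddings are low-dimensional so regularization is uncritical), class i
positive against all others negative; prediction by highest decision
value, exact ties to the lowest class index. Under LOOCV both the reducer
(IDA, or the PCA baseline: leading principal axes of the mean-centered
training data) and the SVMs are refit on each fold's N − 1 training
samples; the held-out subject influences neither means, eigenvectors nor
margins, which a refit-comparison test asserts directly. The embedding
dimension is selected by a grid search over LOOCV accuracy (smallest d on
ties). This mirrors the common small-n protocol and is optimistically
biased, since d is chosen on the accuracy being reported; an honest
nested-CV variant (`nested_grid_search`) is provided but off by default.
Within the grid, each fold's reducer is fit once at the largest d and
truncated, which is exact because both reducers order their components.

## Discriminative-edge mapping

Per classifier, the LOOCV fold weight vectors are averaged in embedding
space (arithmetic mean, no normalization) and mapped back to edge space
through W refit on all N samples: w_edge = W w_emb, so decision values are
identical whether computed in edge or embedding space. An alternative
route — back-project each fold with its own W, then average in edge
space — is available (`backproject_per_fold=True`); on planted data the
two routes agree on the majority of top edges. The consensus set is the
top 5% of edges by |weight| (floor count; ties at the cutoff break by
ascending edge id — magnitude ranks because sign encodes direction, not
importance). Region weight is the number of consensus edges incident to a
region. Edge-weight line strengths follow mean |weight| across folds; the
alternative (per-fold selection frequency) is not implemented.

Combining the two patient-vs-rest classifiers:

* **convergent** edges are those in both consensus sets *with same-signed
  weights*. The sign condition matters: an edge altered in only one
  patient group also enters the other classifier's consensus, but with the
  opposite sign (for that classifier the unaffected group lies on the far
  side of its boundary, in "rest"). A genuinely convergent alteration
  shifts both groups away from controls in the same direction and hence
  carries concordant weights. Without the sign condition the intersection
  absorbs class-specific edges and the divergent set below loses them; the
  condition is switchable (`require_sign_concordance`).
* **divergent** edges are the top fraction of the difference profile
  |w_A − w_B| over back-projected weights, excluding convergent edges and
  zeros. Shared alterations cancel in the difference; private ones remain.
  A rank-sum variant of the profile is available.

## Synthetic data generator

A subject of class k is y = L_k z + s·g·1_p, where L_k is the Cholesky
factor of the class correlation matrix, z is region-wise AR(1) Gaussian
noise with unit marginal variance, and g is a per-subject global time
course with amplitude s shared by all regions (giving global-signal
regression a real target). Class matrices start from a base correlation
(default 0.1 everywhere off-diagonal), receive per-class edge deltas, and
are repaired to positive definiteness by eigenvalue clipping at 1e−6 and
re-normalization to unit diagonal — deterministic, but nominal targets can
shift slightly when perturbations break definiteness. Motion tables are
independent smooth AR(1) drift (they influence nothing, so motion
regression is exercised without confounding). A master seed expands to
per-subject streams keyed by subject index, so subject sets are
reproducible under subsetting.

Defaults mirror a typical clinical resting-state study: three groups of
19/32/38 subjects, 116 regions, 180 volumes at TR = 2 s (a ~6-minute
session), AR(1) coefficient 0.3, global-signal amplitude 0.5, motion
amplitude 0.05. The planted-study helper perturbs 10 edges shared by the
two "patient" groups plus 10 private edges each (30 distinct edges) at
delta = 0.4 — a strong, clean effect chosen so recovery is decidable at
this sample size. The generator produces no hemodynamic forward model, no
voxel level, no scanner artifacts, and its group differences are exactly
covariance shifts; passing tests therefore demonstrate that the pipeline
recovers linear covariance structure under realistic dimensions and noise
correlations, not that it would attain any particular accuracy on
clinical data.

Two behaviors of the protocol show up clearly on synthetic data and are
worth flagging. First, LOOCV with permuted labels runs slightly *below*
chance (the held-out subject's class is underrepresented in its training
fold — a documented pessimistic bias of LOOCV), though within the 99%
binomial band around 1/3 at the tested conditions. Second, when planted
effects dominate total variance, unsupervised PCA axes already align with
class structure, so the IDA-vs-PCA ordering at the grid optimum is not
systematically in IDA's favor on this generator; IDA's accuracy is the
more stable of the two across seeds (92–96% vs 81–97% at the default
conditions).

## Problem sizes used in validation

Study-scale checks run at the full 116-region, 6670-edge geometry with 89
subjects and a dimension grid of [2, 20] (the curve is flat beyond
d = c − 1, so the wider grid adds nothing on 3-class data); the dense
eigensolver cross-check runs at P = 200, where forming both scatters
explicitly is cheap; the permutation null uses 3 × 13 balanced subjects.

## Known limitations

* No spatial preprocessing (realignment, normalization, smoothing): the
  pipeline starts from regional time series or registered volumes.
* Consensus fractions and the convergent/divergent rules are heuristics
  over linear classifier weights; no per-edge significance testing is
  performed.
* The grid-search protocol's optimism is reproduced deliberately; use the
  nested variant for unbiased accuracy estimates.
* Only linear reductions and linear SVMs; no kernel or online variants.
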