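# Methods

This note documents the statistical model the package implements, the
defaults and why they were chosen, the numerical decisions, what the
synthetic generator does and does not emulate, and known limitations.

## Data model

Profiles live on an evenly spaced periodic grid of L angles covering
[0, 360) (default L = 180, step 2°, TSNIT order). The canonical internal
grid is t_l = step·(l−1); scanner exports label the columns 2°..360°, and
the 360° column is stored at internal angle 0 — periodicity makes the two
labellings the same circle, and one canonical grid avoids off-by-one drift.
Right and left eyes are both exported in TSNIT order, which already aligns
anatomical sectors, so no mirroring is applied. Age strata are half-open:
[40, 50), [50, 60), [60, ∞).

## Outlier rule and normalization

The outlier threshold is X_out = max_l mean + factor · max_l sd with the
n−1 sd and factor 3.5 by default; the two maxima are taken separately over
angles. Detection is a single pass on the raw (pre-normalization) grid
values — a spike artifact is sharpest there, whereas a band-limited
reconstruction would smooth it away — and the threshold is not recomputed
after removals. Note a consequence at very small n: the threshold is a
function of the spiked set itself, so one spike among a handful of curves
inflates the pointwise sd enough to evade its own flag; the rule is meant
for cohort-scale inputs. Normalization divides each curve by its
rectangle-rule circular integral; it is idempotent and scale-invariant, and
is optional (config flag) for analyses where magnitude matters.

## Fourier modeling and the choice of p

The basis is the orthonormal Fourier system on the circle of period 360:
ψ₁ = 1/√360, ψ₂ₘ = √(2/360)·sin(2πmt/360), ψ₂ₘ₊₁ the matching cosine. On
the uniform grid the design matrix has Gram matrix (L/360)·I for harmonics
below the Nyquist order, so ordinary least squares is the exact discrete
Fourier projection; no roughness penalty is used. Integrals use the
rectangle rule with Δt = step, which is exact for trigonometric polynomials
below the Nyquist order on a uniform periodic grid. TV equals Δt times the
trace of the pointwise sample covariance, and FVE is nondecreasing in p
(nested projections). The basis order is the smallest odd p with
FVE > 0.99, scanned over 1..41 by default; the scan range safely brackets
the orders relevant at cohort scale, and p can be pinned in the config.

## The discriminative functional mixture

Coefficient vectors follow a K-component Gaussian mixture whose component
means and covariances are confined to a d-dimensional discriminative
subspace U (orthonormal, d < p), with isotropic residual variance β outside
it: cov_k = U Σ_k Uᵀ + β_k (I − U Uᵀ). Twelve variants constrain Σ_k
(full / diagonal / isotropic × cluster-specific / shared) and β
(cluster-specific / shared). Free parameters: (K−1) mixing + K·d means +
(pd − d(d+1)/2) for the Stiefel subspace + the variant's covariance and
noise counts.

Fitting details:

- **Centering.** The model puts component means inside the subspace, so the
  grand coefficient mean — the cohort's shared mean curve, which carries no
  cluster information — is removed before fitting and stored with the model.
- **E-step** uses the subspace decomposition of the Gaussian (Mahalanobis
  term inside the subspace, residual energy over β, log-determinants); on
  small cases it agrees with direct dense evaluation to 1e−6 and is O(npd).
- **F-step** updates U as the top-d generalized eigenvectors of the
  responsibility-weighted between-cluster scatter against the total scatter
  (a soft Fisher criterion), QR-orthonormalized with a deterministic sign
  convention; the total scatter gets a 1e−8 relative ridge.
- **M-step** computes weighted moments of the projected data under the
  variant's constraints, pooling over clusters for shared parameters;
  β_k = (tr C_k − tr UᵀC_kU)/(p−d) with a 1e−10 floor.
- **Monotonicity.** The F-step is a heuristic, not an exact maximizer, so
  the likelihood is not provably monotone; an iteration that would lower
  the log-likelihood by more than the tolerance is rejected (previous
  parameters kept) and the run stops, so the recorded trace is
  nondecreasing.
- **Initialization** is k-means on *whitened* coefficients (eigenvalue
  sphering of the total covariance, numerically dead directions dropped):
  shared high-variance within-cluster directions otherwise mask the mean
  separations. Five restarts by default, best log-likelihood kept; empty
  components trigger a restart.
- d defaults to min(K−1, p−1), the dimension of a K-class Fisher problem.

Model choice: AIC = ℓ − m, BIC = ℓ − (m/2)·log n, ICL = BIC − the
responsibilities' entropy (all maximize-oriented, so ICL ≤ BIC). The
variant for each K is the best by BIC; K is chosen at the elbow of the BIC
trace, made algorithmic as the largest second difference over interior K
(smaller K on ties), with a guard returning the smallest K when no larger K
improves on it. The full criterion trace is always exported so the
automatic elbow can be overridden by inspection.

## Sparse metaclustering

Each functional cluster is summarized by its mean vector over the nine
clinical covariates. The sparse clustering criterion (alternating a unit
pair-dissimilarity vector u and a soft-thresholded weight vector w with
w ≥ 0, ‖w‖₂ ≤ 1, ‖w‖₁ ≤ wbound; per-feature squared differences; the
threshold found by bisection) yields both feature weights and a weighted
dissimilarity, agglomerated with complete linkage.

**Standardization.** The nine covariates carry incommensurate units, so raw
squared distances would be dominated by CCT (µm-scale). Z-scoring across
the handful of cluster rows was considered and rejected: it forces every
column to unit variance across rows, so a covariate that barely separates
the clusters relative to its natural variability looks exactly as
informative as one that separates them strongly, and feature selection
degenerates. Instead, each covariate's cluster means are divided by its
pooled within-cluster sd (computed from the sample-level table), i.e.
dissimilarities compare standardized effect sizes. Row-z-scoring remains
the fallback for matrices supplied without sample-level scale information.

wbound is scanned over 2..5 and chosen by a permutation gap statistic
(columns permuted independently, 25 permutations, seeded). Note that with
nine covariates ‖w‖₂ ≤ 1 already implies ‖w‖₁ ≤ 3, so bounds above 3 are
inactive. Dendrogram heights are rescaled so the root merge sits at 1
before the flat cut at 0.1, making a common threshold meaningful across
strata whose raw dissimilarity scales differ. Metaclusters are matched
across strata greedily by ascending distance between their size-weighted
mean vectors on the top-weighted covariates; metaclusters beyond the
smaller stratum's count are labelled distinct.

## Baselines and validation indices

k-means (k-means++ with 10 restarts), PAM (BUILD + SWAP to a local optimum
of the distance-to-medoid cost) and Gaussian mixtures (diagonal/spherical
covariance per K by BIC) run on the normalized grid values by default
(configurable to raw µm). K is chosen by the average silhouette width
(singletons score 0); the Dunn index is min between-cluster point
separation over max within-cluster diameter, Euclidean throughout.

## The synthetic generator

Defaults define the reference study conditions: K = 3 clusters of 200 eyes
each on the 180-point grid; band-limited templates (harmonics ≤ 5) sharing
a mean level of 90 µm — echoing typical average rim thickness — and a ~33%
depression centred at 0° (the temporal dip of the ISNT rule), differing
across clusters only in harmonics 3–5 at 6 µm amplitude; within-cluster
variation of the 11 Fourier coefficients concentrated in a random
d = 2 subspace with anisotropic sds (150, 40) in coefficient units (one
dominant mode of rim-shape variability, ≈ 11 and 3 µm of curve amplitude)
plus isotropic coefficient noise of sd 8; uniform ages over 40–75; spike
outliers placed at (max pointwise mean) + magnitude × (max pointwise sd) so
they cross the detection threshold exactly when magnitude > 3.5; covariate
means per cluster at clinically plausible levels with the metagroup signal
carried by average CDR (0.44/0.54/0.62) and cup volume (0.10/0.20/0.30).
This regime makes clusters overlap in raw Euclidean distance (silhouette
prefers two groups) while remaining separable in the discriminative
subspace — the qualitative situation the comparative analysis probes.

What the generator does **not** emulate: instrument noise and segmentation
artifacts beyond single-angle spikes, eye-level correlation between two
eyes of one participant, age-dependent thinning of the rim, missing
covariates, and non-Gaussian covariate distributions. Passing tests
therefore demonstrate correctness of the algorithms under the assumed
generative family, not robustness to those real-data features.

Templates are checked to be strictly positive; sampled curves are clipped
at 0 with a logged warning in the rare tail event.

## Problem sizes and determinism

Tests and the acceptance script run desk-scale problems: cohorts of 600
eyes, K scans over 2..6 for the functional mixture (bracketing the planted
K = 3) and 2..10 for baselines, 10 seeds for the stochastic recovery
checks. All randomness flows through explicit integer seeds; the same seed
reproduces byte-identical cohorts and manifests.

## Known limitations

- The elbow rule is a heuristic formalization of "no significant gain";
  on near-flat BIC traces it can be sensitive to single-fit noise, which is
  why the traces are exported.
- The Fisher-EM style F-step can stall at a subspace where the safeguard
  stops iteration early; restarts mitigate but do not eliminate this.
- PAM is a local optimizer (BUILD + SWAP); it does not guarantee the global
  medoid configuration.
- With very small n the outlier threshold is computed on a set the spike
  itself perturbs (see above).
- Conformance checks against a study's deposited per-eye tables require
  those tables locally; only their loader and the checking logic ship here.
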