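# Methods

## The model

`hyperembed` embeds an undirected simple graph into (D+1)-dimensional
hyperbolic space under the geometric soft configuration model on the
D-sphere (the S^D model).  Each node *i* carries a hidden degree
κ_i > 0 (its expected degree in the ensemble) and a position **v**_i on a
D-sphere of radius R chosen so that the node density is one,

    R = [N Γ((D+1)/2) / (2 π^((D+1)/2))]^(1/D).

Nodes connect independently with the gravity-law probability

    p_ij = 1 / (1 + χ_ij^β),   χ_ij = R Δθ_ij / (μ κ_i κ_j)^(1/D),

where Δθ_ij is the angular separation, β > D (the inverse temperature)
couples topology to geometry and controls clustering, and

    μ = β Γ(D/2) sin(Dπ/β) / (2 π^(1+D/2) ⟨k⟩)

fixes the mean degree in the large-N limit.  Mapping hidden degrees to
radial coordinates r_i = R̂ − (2/D) ln(κ_i/κ_0), with
R̂ = 2 ln(2R/(μκ_0²)^(1/D)), turns the same probability into the logistic
form 1/(1+exp[(β/2)(x_ij − R̂)]) with the effective hyperbolic distance
x_ij = r_i + r_j + 2 ln(Δθ_ij/2).  The identity is exact algebra and is
asserted to 1e-12 in the tests; x_ij approximates the true geodesic only for
Δθ_ij ≫ 2√(e^(−2r_i) + e^(−2r_j)) and the library treats it as an
*effective* distance (greedy routing ranks neighbors by it), never as an
exact geodesic.  κ_0 defaults to the smallest hidden degree (configurable).

## The embedding pipeline

Four stages, all driven by one seeded `numpy.random.Generator`:

1. **Hidden degrees and β.**  One κ per observed-degree class, initialized
   at the degree itself and nudged by |κ + (k − k̄(κ))u|, u ~ U(0,1), until
   max_i |k̄(κ_i) − k_i| ≤ ε (default 0.01).  Expected degrees integrate the
   connection probability against the sphere's separation density
   (Gauss–Legendre panels split at the knee θ* = (μκκ′)^(1/D)/R and at 4θ*,
   48 nodes per panel; validated against adaptive quadrature to 1e-8).
   β is found by matching the model's expected mean local clustering —
   a Monte-Carlo estimate (m = 600 samples per degree class; neighbor
   classes drawn from the degree-biased law, separations by inverse-CDF
   tables of the connected-pair distance density, 2048-point grids) — to the
   empirical value: start uniform in (D, D+1), multiply by 1.5 while the
   model clustering is low, then bisect to |c̄(β) − c̄_emp| < 0.01, refitting
   the hidden degrees and recomputing μ at every candidate β.  Local
   clustering is averaged over nodes of degree ≥ 2 on both the empirical and
   the model side, keeping the two comparable (nodes of degree < 2 have no
   defined local clustering).

2. **Spectral initialization.**  Degree-one nodes carry no geometric
   information and are peeled recursively (a removal can create new leaves;
   reattachment later runs in reverse order so every anchor is placed).  On
   the remaining core, each edge gets the model-expected chord length
   2 sin(⟨Δθ⟩/2), with ⟨Δθ⟩ the mean separation of connected pairs given
   the two hidden degrees, and Gaussian weights ω_ij = exp(−chord²/t).
   Coordinates are the D+1 lowest non-trivial eigenvectors of the
   weight-normalized (generalized) Laplacian eigenproblem
   L y = λ I y — the constrained minimizer of the classic Laplacian
   Eigenmaps loss — row-normalized onto the sphere.  Peeled leaves are
   reattached at separations drawn from the connected-pair distance density
   with uniform azimuth.

   Two numerical choices matter here and were fixed by validation on
   synthetic ground truth:

   * the bandwidth t is the *mean squared* chord over connected pairs (the
     classic heat-kernel bandwidth).  Reading the one-clause prescription as
     the variance of the plain chords makes the weight contrast explode at
     weak coupling and destroys the initialization (min per-axis correlation
     0.4–0.7 instead of ≈0.95 at β = 1.5D); `scale=` exposes the
     alternatives;
   * heavy-tailed graphs can grow spurious *localized* eigenmodes below the
     geometric ones.  Three extra eigenpairs are computed and modes whose
     inverse participation ratio exceeds 5× the delocalized reference 3/n
     are discarded before the lowest D+1 are taken.  On affected instances
     the spurious modes sit 10–140× above the reference while geometric
     modes stay below 2×, so the filter is sharp; `n_extra=0` disables it.

3. **Likelihood refinement.**  Nodes are visited in onion-decomposition
   order (innermost layer first, random within layers, reshuffled every
   sweep).  For node i, 100·max(ln N, 1) candidate positions are drawn from
   an isotropic normal around the κ^(−2)-weighted mean of its neighbors'
   vectors and radially normalized; the candidate (or incumbent) with the
   highest local log-likelihood Σ_j [a_ij ln p_ij + (1−a_ij) ln(1−p_ij)]
   wins, probabilities clamped to [1e-15, 1−1e-15].  Because the incumbent
   always competes, the global log-likelihood is non-decreasing.  The
   proposal spread σ = max(π/2, Δθ_max/2) is implemented literally — which
   is constantly π/2, since Δθ_max ≤ π; a `sigma_mode='min'` switch provides
   the localized variant in case the bound was intended the other way.
   Sweeps stop at a relative log-likelihood change below 1e-4 or after
   `max_sweeps` (default 8).  Candidate scoring runs vectorized in single
   precision (score differences of parts in 1e6, far below the candidate
   sampling noise); reported log-likelihoods are double precision.

   After the candidate sweeps a *gradient polish* runs: per node, one
   backtracking projected-gradient step of the local log-likelihood per
   sweep (default 20 sweeps, steps 0.3 → 0.01 chord units, each move
   accepted only if the local log-likelihood improves, preserving
   monotonicity).  The candidate search finds the right basin but is an
   inefficient within-basin optimizer; the polish costs O(N) per node
   instead of O(candidates·N) and, on hard instances, pushes the global
   log-likelihood beyond what refinement started from the planted truth
   reaches.  `gradient_sweeps=0` disables it.  `refine_rounds > 1` in the
   pipeline alternates further refinement with hidden-degree readjustment.

4. **Final hidden-degree adjustment.**  With positions fixed, expected
   degrees become position-conditional sums Σ_{j≠i} p_ij and κ is re-tuned
   per node (not per class) by the same noisy update until the ε contract
   holds.  The update direction contracts the residual, matching stage 1.

## The synthetic generator

The generator *is* the study-condition definition used by the tests: hidden
degrees follow a truncated power law ρ(κ) ∝ κ^(−γ) on
[κ_0, κ_0 N^(1/(γ−1))] with κ_0 = (γ−2)⟨k⟩/(γ−1) (inverse transform);
positions are uniform on the sphere (normalized Gaussians) or, for planted
communities, uniform within spherical caps of polar angle Δθ_T (default
0.7 rad) around apices spread evenly — exact layouts on the circle and for
symmetric counts on the 2-sphere, maximin repulsion otherwise; nodes are
assigned to caps round-robin, so sizes differ by at most one.  Every pair is
then linked by an independent Bernoulli draw of the gravity law with μ from
the closed form at the *target* mean degree.

Because μ is a large-N calibration and the natural cutoff lowers E[κ] below
⟨k⟩ for γ < 3, realized mean degrees undershoot the nominal target at heavy
tails (≈6 for the nominal 8 at N = 2000, γ = 2.5, β = 3) and the realized
degree-vs-κ slope falls below one — the very finite-size distortions the
inference stage corrects.  With constant κ and β ≫ D the realized mean
matches the target to three decimals, which pins the per-pair sampling as
exact.  What passing recovery tests show is therefore robustness of the
*inference* to these distortions, not that the generator hits nominal
targets at heavy tails.

## Evaluation suite

* **Greedy routing** forwards each message to the neighbor with the
  smallest effective distance x to the target (ties to the smallest index);
  failure on any revisit or after N hops; stretch is greedy hops over BFS
  hops, averaged over successes.  Pairs are sampled (default 10⁴ ordered
  pairs, exhaustive when fewer exist).
* **Community concentration** ρ_{i,l} = (n_{i,l}/n_g)(N/N_l) over the
  n_g = ⌈N/10⌉ angularly nearest other nodes; c_C is its mean.  Note the
  enrichment's uninformative baseline is 1 (the raw co-membership fraction
  then sits at 1/N_C); caps concentrate up to N_C.
* **Alignment** is orthogonal Procrustes (rotations and reflections) with
  per-axis Pearson correlations and the mean residual angle.
* **Geometric communities** by average-linkage agglomerative clustering on
  angular distances (scikit-learn); partition scores are Newman–Girvan
  modularity and arithmetic-mean NMI.
* **Dimension selection**: embed at candidate dimensions, let each metric
  vote for the dimension where it peaks (stretch votes for its minimum);
  the consensus is the modal vote, ties reported unresolved.

## Problem sizes and defaults

Tests and the acceptance script use desk-scale versions of the study
conditions: coordinate recovery at N = 2000 (the headline setting),
β recovery at N = 1000 with 10 seeds per dimension, navigability and
cap-concentration protocols at N = 400 with 5 seeds, ensemble oracles at
N = 500 with 50 replicas.  Tolerances are never scaled.  Mean degree for
the navigability and cap fixtures is 10, a density at which greedy routing
is informative without saturating.

## Known limitations

* The weak-geometric regime β ≤ D is out of scope; `compute_mu` refuses it.
* x_ij is an effective distance; exact hyperboloid geodesics are not
  provided.
* The β search assumes expected clustering increases with β (verified
  empirically over the supported grid); graphs with near-zero clustering
  cannot constrain β and are rejected.
* Likelihood maximization is a local heuristic on a multimodal landscape;
  on hard weak-coupling instances the maximum-likelihood configuration
  itself may sit a little away from the planted truth (per-axis r ≈ 0.96
  rather than ≈ 0.99 at β/D = 1.5, γ = 2.5).
* The clustering-matching β estimator conditions on one hidden degree per
  observed-degree class; ignoring within-class dispersion biases the
  expected clustering slightly upward, and where c̄(β) flattens (high β,
  higher D) this translates into a systematic few-percent underestimate of
  β (measured ≈ −5 to −7% at D = 3, β = 7.5).
* Greedy-routing stretch is averaged over successful paths only; because
  embeddings at and above the native dimension succeed on different pair
  sets, their conditional mean stretches are statistically
  indistinguishable at desk scale even when the success rate clearly peaks
  at the native dimension.
* Memory: evaluation and the final adjustment build dense N×N matrices
  (O(N²) memory); practical up to a few 10⁴ nodes.
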