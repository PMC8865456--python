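# Methods

## The model

`klsenet` builds a *single-subject* metabolic connectivity network from one
static, spatially normalized PET intensity volume.  Group-level metabolic
connectivity is usually defined through across-subject correlations of
regional uptake; the KLSE (Kullback–Leibler similarity estimation) approach
instead compares the *within-region distribution* of uptake values between
every pair of regions of one brain.  The assumption: regions with similar
glucose metabolism are strongly interconnected, so the similarity of their
intensity distributions is a connectivity weight.

Pipeline, per subject:

1. **Nodes.** A 100-parcel functional cortical parcellation grouped into 8
   intrinsic networks — visual (13 parcels), somatomotor (14), dorsal
   attention (13), ventral attention/salience (14), limbic (5), control
   (16), default mode (21), frontoparietal (4).  Parcels with fewer than
   `min_voxels = 800` voxels are excluded, cohort-wide (a parcel dropped
   for any subject is dropped for all, so all matrices share one node set).
2. **Densities.** Voxel values are normalized to the pooled mean over all
   retained parcels (the atlas stands in for grey matter; an external
   grey-matter mean can be supplied).  Each parcel's PDF is estimated by a
   Gaussian-kernel KDE with the diffusion (Botev) plug-in bandwidth,
   evaluated on one *standardized grid* shared by all parcels and subjects,
   and renormalized to unit trapezoidal integral on that grid.
3. **Edges.** For parcels i, j the symmetrized Kullback–Leibler divergence

       DKL(P, Q) = ∫ P log(P/Q) + Q log(Q/P) dx

   is computed by the trapezoidal rule on the grid (densities floored at
   `epsilon` and renormalized first), and the edge weight is
   KLS(P, Q) = e^−DKL ∈ (0, 1].  The matrix is fully weighted and never
   thresholded or binarized.
4. **Graph metrics.** Mean connectivity strength (within scopes and between
   network pairs), characteristic path length, Onnela weighted clustering,
   weighted local efficiency, betweenness centrality, and a 4-criterion hub
   score (details below).
5. **Aging models.** For every metric × scope, Y = β₀ + β₁·age and
   Y = β₀ + β₁·age + β₂·age² are fitted by OLS; the extra-sum-of-squares
   F test picks the quadratic only when its added term is significant
   (α = 0.05); the chosen model's overall p, the multiple correlation r,
   the predictions Ŷ(20), Ŷ(80) and the lifespan change
   100·(Ŷ(80) − Ŷ(20))/Ŷ(20) are reported.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| grid range | [0, 3] | GM-normalized uptake | covers plausible normalized uptake; the upstream description fixes only *that* a shared range exists, not its value |
| grid points | 256 | — | KDE resolution vs trapezoid integration noise |
| `min_voxels` | 800 | voxels | PDF-robustness rule for retained parcels |
| `epsilon` | 1e-12 | density | floor before logs; keeps KLS > 0 and the graph fully weighted |
| bandwidth | diffusion (Botev) | uptake units | automatic, deterministic per sample; Silverman fallback if the fixed point cannot be bracketed |
| Botev mesh | 256 (dyadic) | bins | resolves unimodal samples of ≤10⁴ values; bandwidths move <1 % under refinement |
| `top_fraction` | 0.20 | — | hub slots per criterion, k = round(0.2·n), ties broken by ascending node id |
| α | 0.05 | — | per-test significance; no multiple-testing correction by default (a correction switch exists but mirrors the reference analysis by staying off) |
| viz threshold | 0.80 | weight | edge export for connectome rendering only; never used in metrics |

Numerical conventions for the graph metrics:

* Path-based metrics use edge lengths ℓ = 1/w.  (−log w is rejected:
  weights of exactly 1 would give zero-length edges.)
* "Degree" on a complete weighted graph is nodal strength (sum of
  weights); the binary degree would be the constant n − 1.
* Clustering is the Onnela geometric-mean form on max-normalized weights
  ŵ = w/max(w): C_i = Σ_{j≠h}(ŵ_ij ŵ_ih ŵ_jh)^{1/3}/(k_i(k_i−1)).
* Local efficiency of node i is computed on the subgraph induced by its
  neighbours, with shortest distances taken *inside* that subgraph:
  E_i = Σ_{j,h∈N_i,j≠h}(w_ij w_ih/d_jh(N_i))^{1/3}/(k_i(k_i−1)).
  The exact weighted generalizations in the reference literature are not
  uniquely pinned down; the Onnela/neighbour-subgraph forms are the
  standard brain-connectivity-toolbox choices and are what the test
  oracles verify.
* Betweenness is Brandes' algorithm on lengths 1/w, endpoints excluded,
  unnormalized, each unordered source–target pair counted once.
* Hubs: one point per criterion for membership in the top 20 % by
  (a) highest degree, (b) lowest nodal path length, (c) lowest clustering,
  (d) highest betweenness; hub ⇔ score ≥ 2.
* Model-selection tie (both SSE = 0): the simpler linear model is kept.
* Age-tertile split: age-sorted, sizes as equal as possible, remainder to
  the oldest groups — n = 67 gives 22/22/23.
* Report rounding (2 decimals for values, 1 for percentages, half away
  from zero) happens only in the report layer; everything internal is full
  precision.

## KDE implementation

The diffusion bandwidth follows the fixed-point algorithm: histogram the
sample on a dyadic mesh over its 10 %-expanded range, take the type-II DCT,
and solve t = ξγ^[7](t) for the squared (scaled) bandwidth by bracketing;
the bandwidth is √t·range.  The kernel sum itself is evaluated by linear
binning on a 4× oversampled copy of the standard grid followed by
convolution with a truncated discrete Gaussian (`method="binned"`, the
default), which matches direct evaluation (`method="exact"`) to better
than 0.5 % of the peak density while being an order of magnitude faster —
the difference is far below the sampling noise of an 800-voxel parcel.
Mass smoothed beyond the grid edges is folded back by renormalization, so
every density satisfies the probability axioms the KL integral needs.

## What the synthetic cohort emulates — and what it does not

No public PET cohort accompanies the method, so the package ships a
phantom generator that reproduces the *statistical* structure the analysis
consumes, with no anatomical geometry (parcels are contiguous blocks; the
connectivity math never looks at voxel positions).

Generative model for a subject of age a: voxels of parcel p are drawn from
a Normal(μ_p, σ_p) truncated at zero (truncation by re-draw, so no point
mass at 0 distorts the KDE), with

    μ_p = 1 + δ_p · s_g(a) · exp(ε_g),   σ_p = 0.10,

where δ_p ~ N(0, 0.05) are fixed per-parcel offsets, s_g(a) is the
network's dispersion scale, and ε_g ~ N(0, 0.12) is an independent
subject × network scatter (regional rather than global inter-subject
variability — a global factor would largely cancel in grey-matter
normalization).  The volume is recentred to unit mean over labelled
voxels.  Growing s spreads the parcel means apart, raises every pairwise
divergence ∝ s², and therefore lowers KLS strength — the mechanism by
which the phantom ages.

Scenario presets (`aging_effect_model`):

* **linear** — s grows 1.0 → 1.5 between ages 20 and 80 in the five
  affected networks (default mode, control, dorsal attention, ventral
  attention, frontoparietal); somatomotor, limbic and visual stay flat.
  This yields whole-brain strength declines of roughly 10–20 % over the
  lifespan with fit r ≈ 0.5–0.75 at n = 67.
* **quadratic** — s = 1 + c·(age − 45)², minimum at mid-life and
  s(80) = 2.0: strength follows an inverted U peaking in middle age with
  an accelerating late-life decline, the trajectory a quadratic age model
  describes (recovered coefficients have β₁ > 0, β₂ < 0).  A one-sided
  parabola anchored at age 20 was deliberately rejected: after the bounded
  KLS transform its trajectory is nearly straight and the F test cannot
  tell it from a line.
* **null** — every network flat; only the subject scatter remains.

Effect sizes and scatter are calibrated to produce *reliably detectable*
trends at the default cohort size (n = 67, ages uniform on [20, 82]): the
linear slope is recovered with |t| ≳ 6 and the quadratic term with ~100 %
selection frequency.  Real cohorts are noisier (published fits of this
kind report r ≈ 0.3–0.5, vs ≈ 0.6–0.75 here); passing recovery tests
therefore demonstrates the pipeline's correctness and power under clean
conditions, not the effect sizes, inter-subject variance, spatial
autocorrelation, scanner effects or partial-volume behaviour of real FDG
data.  Cohort randomness is split into independently spawned streams for
ages and per-subject noise, so the two share no seed entropy.

A note on specificity: the fit-both-then-report-the-chosen-model
procedure is intrinsically slightly anticonservative — with a true null,
the chosen model's overall p is below 0.05 about 6–8 % of the time
(the quadratic branch is selected exactly when chance curvature is large).
This is a property of the procedure, which the package reproduces
faithfully, not of the implementation; the recovery suite's specificity
bound (≥ 90 % of null-network regressions non-significant) accounts for
it.

## Problem sizes

The recovery experiments run 50 linear-effect cohorts, 20
quadratic-effect cohorts and 50 null cohorts of 67 subjects each at full
study scale (100 parcels × 800 voxels), a few seconds per cohort with the
binned KDE path.  The brute-force oracle comparisons use 100 random
complete weighted graphs of 6–10 nodes (the path-enumeration betweenness
oracle uses a 25–40 graph subset — exhaustive enumeration grows
factorially).

## Known limitations

* The standardized grid's range/bin count and the exact ε-handling of the
  log ratios are this package's choices (the source description leaves
  them open); both are recorded in every matrix's metadata and
  configurable.
* Between-network analysis covers the C(8,2) = 28 pairs of the 8 named
  networks; a published between-network tally of 36 implies 9 entities
  whose composition is not reconstructible from the 8-network definition.
* Whether uptake normalization happened before or after parcel exclusion
  is unstated upstream; normalization here happens after exclusion.
* r for quadratic fits is the full-model multiple correlation.
* The generator emulates intensity *distributions*, not images: no
  partial-volume effects, motion, smoothing kernels or atrophy, and
  nothing spatial.
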