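# Methods

## Problem

Multilevel thresholding partitions an 8-bit grayscale image into `k + 1`
intensity classes by choosing `k` cut points `th_1 < … < th_k` on its
histogram. The package targets thermogram-like images — smooth multimodal
histograms where each tissue region contributes a roughly Gaussian
intensity mode — but nothing in it is specific to thermography beyond the
synthetic generator.

A pixel with gray level `g` belongs to class `j` when `th_{j-1} < g <=
th_j` (sentinels `th_0 = -1`, `th_{k+1} = L-1`, `L = 256`). The inclusive-
upper convention is used *everywhere* — objectives, oracle, segmenter —
so all components agree on which partition a threshold vector denotes.
Thresholds live in `[0, L-2]`; a threshold at `L-1` would only ever create
an empty top class.

## Objectives

Both criteria are functions of the normalized histogram `p_i = n_i / N`
alone and are maximized.

**Otsu between-class variance.**
`sigma_B^2(th) = sum_j omega_j (mu_j - mu_T)^2` with class mass
`omega_j = sum_{i in C_j} p_i`, class mean
`mu_j = sum_{i in C_j} i p_i / omega_j`, and global mean `mu_T`.
Maximizing `sigma_B^2` is equivalent to minimizing the pooled
within-class variance; the identity
`sigma_B^2 + sum_j omega_j sigma_j^2 = sigma_total^2`
holds for every histogram and threshold vector and is asserted to 1e-9 in
the tests.

**Kapur entropy.**
`f(th) = sum_j H_j`, `H_j = -sum_{i in C_j} (p_i/omega_j) ln(p_i/omega_j)`.
Natural logarithm throughout; the maximizing thresholds are invariant to
the log base, so the choice is a documented constant rather than a
behavioral one. Terms with `p_i = 0` contribute 0 (the `x ln x -> 0`
limit).

**Degenerate classes.** A class with `omega_j = 0` contributes 0 to either
objective instead of raising. This lets the stochastic search traverse
candidates whose rounded components collide; such candidates decode to a
valid coarser partition with identical fitness.

All class statistics come from three prefix-sum vectors (of `p_i`,
`i p_i`, `p_i ln p_i`), making each class O(1) and a whole candidate
O(k).

## Exact oracle

`exhaustive_optimal` enumerates every threshold combination for
`k <= 3` using a precomputed 256x256 per-segment score matrix; for `k=3`
the enumeration over C(255, 3) ≈ 2.7M triples is vectorized per leading
threshold and runs in well under a second per histogram. Ties are broken
by the lexicographically smallest vector. The returned fitness is
re-evaluated through the same code path the metaheuristics use, so
"optimizer hit the oracle" can be tested at `|Δ| <= 1e-9` without
floating-point ambiguity. For Otsu the oracle is cross-checked in the
test suite against scikit-image's `threshold_multiotsu` (an independent
implementation of the same criterion), and against plain brute-force
enumeration on small alphabets for both objectives.

## Black widow optimization (BWOA)

Candidates ("widows") are real vectors in the box `[0, 254]^k`; they are
decoded (clamp, round half-up, sort) only at fitness evaluation, so the
evolutionary operators work on an unconstrained continuous space.
Defaults follow the standard protocol: population `N = 50`, 350
iterations, procreation (crossover) rate `PP = 0.8`, cannibalism rate
`CR = 0.5`, mutation rate `PM = 0.4`.

Each generation:

1. **Breeding pool** — the best `round(PP N)` widows, paired by a random
   permutation (`round(PP N) / 2` disjoint pairs).
2. **Procreation** — per offspring pair, a fresh uniform mixing vector
   `a` gives `V1 = a x1 + (1-a) x2`, `V2 = a x2 + (1-a) x1`. The number
   of offspring per pair defaults to `max(2, 2 ceil(k/2))`.
3. **Cannibalism** — sexual: the lower-fitness parent is discarded (the
   fitter parent is the "female"; ties keep the first listed). Sibling:
   the best `ceil(CR n)` offspring survive. The "mother eaten by
   spiderlings" case needs no separate operator: if every kept offspring
   out-ranks the surviving parent, the parent simply drops out at
   selection.
4. **Mutation** — `round(PM N)` members of the merged survivor pool,
   chosen without replacement; the default strategy redraws one component
   uniformly in bounds ("reset"). A component-swap strategy is provided
   for completeness, but because threshold vectors are sorted at decode
   time a swap is fitness-neutral here, so reset is the default.
5. **Selection** — the next generation is the `N` best of the merged
   pool and the current population. With the default rates the merged
   pool holds only ~40 members, fewer than `N`; topping up from the
   ranked current population both restores the population-size invariant
   and subsumes keep-the-incumbent elitism, so the best-so-far fitness is
   non-decreasing by construction. Two alternatives (fresh-random top-up;
   duplicate-collapsing selection) were evaluated during design and
   performed no better once the Lévy kick below was in place.

Stopping: fixed iteration budget by default; a fitness-stall criterion
(no improvement beyond `tol` for `patience` generations) and a target-
fitness criterion are available.

**Reproducibility.** One `numpy` Generator drives everything in a fixed
draw order (pairing permutation → alpha → Lévy steps if enabled →
mutation selection → mutation values → QOBL gate and draws if enabled).
Runs are bit-reproducible from the seed; repeated-seed studies use
`seed + run_index` so paired algorithm comparisons share seeds run by
run.

## Improvements (IBWOA)

**Lévy-flight procreation.** Mantegna steps
`step = 0.01 R6 / |R7|^(1/beta)`, `R6 ~ N(0, sigma^2)`, `R7 ~ N(0, 1)`,
`beta = 1.5`, with
`sigma = [Γ(1+b) sin(pi b/2) / (Γ((1+b)/2) b 2^((b-1)/2))]^(1/b)`
(≈ 0.6966 at `b = 1.5`; `sigma_R7 = 1` is the standard Mantegna choice).
Each offspring pair receives an antisymmetric kick scaled by the box
width: `V1 + step (u - l)`, `V2 - step (u - l)`, clipped to the box. Two
interpretations of where the Lévy term enters were considered: perturbing
the mixing vector `a`, or perturbing the offspring directly. The first
shifts offspring by `delta (x1 - x2)` and therefore dies exactly when the
population has contracted onto one point — the regime where stagnation
relief is needed; measured oracle-hit rates under it fell to 0.52–0.79
on the Kapur objective at k = 2–3. The box-scaled kick keeps a constant
exploration scale (typically one to two gray levels, heavy-tailed above
that), conserves the pair sum before clipping, and raised those rates to
0.90–1.00, so it is the implemented design. With `scale = 0` the kick —
and its random draws — vanish entirely.

**Quasi-opposition-based learning (QOBL).** For `x` in `[l, u]` the
opposite is `x_o = u + l - x`; the quasi-opposite is uniform between the
box midpoint and `x_o`. At initialization the quasi-opposites of the
whole population are evaluated and the best `N` of the `2N` candidates
kept; thereafter, with probability 0.3 per generation, the same
keep-best merge is applied to the current generation. The merge can only
raise the population's best fitness. Placement and frequency follow the
common quasi-oppositional-DE pattern and are configurable. Setting the
jump rate to 0 disables QOBL everywhere (including initialization) and,
together with Lévy scale 0, makes IBWOA replay the plain BWOA trace
bit-for-bit — a tested identity.

## Quality metrics

Metrics compare the original image against its **class-mean
reconstruction** (each pixel replaced by its class's rounded mean gray
level); a class-midpoint mode exists as well. Comparing against raw class
labels would be meaningless for intensity metrics.

* `RMSE = sqrt(mean((a-b)^2))`; `PSNR = 20 log10(255 / RMSE)` dB,
  infinite for identical images.
* **SSIM** uses whole-image statistics exactly as the single-statistic
  formula is written, with 8-bit stabilizers `C1 = (0.01·255)^2 = 6.5025`
  and `C2 = (0.03·255)^2 = 58.5225`. A windowed mean-SSIM mode
  (scikit-image) is provided for cross-checking; published SSIM tables
  may use either convention.
* **FSIM** pools `S_PC · S_G` weighted by `PCm = max(PC1, PC2)`, with
  `T1 = 0.85`, `T2 = 160` (the published 8-bit defaults) and Scharr
  gradients. FSIM is undefined (raises) when neither image has any
  phase-congruent structure.
* **Phase congruency** uses the standard log-Gabor construction: 4
  scales, 4 orientations, minimum wavelength 6 px, scale multiplier 2,
  bandwidth ratio `sigma_onf = 0.55`, Rayleigh noise threshold at
  `noise_k = 2` standard deviations, estimated from the smallest-scale
  amplitude response. Every constant is an argument. The image is
  reflect-padded by 16 px before the FFT so periodic wrap-around does not
  fabricate border edges. No down-sampling is applied (the test images
  are 128x128).

## Synthetic generator

`MixtureSpec` describes a 2–6 component Gaussian intensity mixture on
[0, 255] (mean, sd, weight per mode) plus image geometry and a seed — the
histogram shape of a cropped thermogram. Two renderings:

* the **analytic histogram**: each mode is a rounded Gaussian truncated
  to [0, 255], discretized to 256 levels, mixed by weight — noise-free
  input for oracle and optimizer tests;
* the **sampled image**: per-mode pixel counts match the weights exactly
  (largest-remainder rounding); each non-background mode claims a
  connected elliptical region (random center, aspect, orientation), the
  heaviest mode forms the background; gray values within a region are
  drawn by stratified inverse-CDF sampling from the mode's discrete
  distribution and shuffled spatially. Stratified sampling keeps the
  empirical histogram within total-variation distance ~0.01 of the
  analytic one at 128x128, and the blob layout provides the gradients
  and phase structure FSIM needs.

What the generator does **not** emulate: sensor noise, smooth intra-region
temperature gradients, ROI-cropping artifacts, or any thermogram physics
(no temperature calibration). Passing tests therefore demonstrate
correctness of the objectives/optimizers/metrics on histograms with
realistic mode structure — not clinical performance on real thermograms.

The canonical test corpus is 20 images at 128x128, cycling 2-, 3- and
4-mode specs with means spread over [35, 220], sds of 6–14 (tighter for
more modes) and mostly equal weights (one in four cases gets Dirichlet
weights). A case is flagged *well separated* when weights are equal and
consecutive means differ by at least 2.5 (sd_i + sd_j); those cases carry
the valley-property guarantee (each Otsu threshold at k = modes-1 falls
strictly between consecutive mode means). Exhaustive-oracle optima for
k = 1..3 under both objectives are cached per case, computed on the
sampled image's histogram — the same histogram the optimizers see.

## Study conditions and problem sizes

Repeated-seed experiments run the full standard protocol: population 50,
350 iterations, 5 seeds per image over the 20-image corpus (100 runs per
algorithm/objective/k cell). The default study run count for the CLI is
35 (the protocol is quoted with both 35 and 51 runs in the literature;
35 is the default here, overridable). Oracle-hit means
`|fitness - exact optimum| <= 1e-9`.

## Known limitations

* The exhaustive oracle stops at k = 3 (enumeration only; no
  dynamic-programming exact solver).
* Whole-image SSIM and the specific phase-congruency constants are one of
  several published conventions; absolute FSIM/SSIM values are only
  comparable within a convention.
* Kapur's criterion rewards cutting near-empty histogram bands, so its
  exact optimum can sit on a plateau of near-ties; the k = 3 oracle-hit
  rate of the improved optimizer is ~0.9, not 1.0, under the default
  budget.
* Offspring count per pair, generation replacement and QOBL
  placement are design choices documented above; the underlying
  published algorithm text leaves them open.
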