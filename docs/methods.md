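# Methods

`relaxo` is a desk-scale, fully synthetic replica of a multicenter
quantitative-MRI workflow: T1 and T2 mapping of the rat brain at 7 T,
region-wise summarization over a 29-region parcellation obtained by
multi-atlas label fusion, and agreement statistics between acquisition
centers, fitting pipelines, atlas sets and repeated scans. This note
records the models, the defaults and the design choices that were
genuinely open.

## Signal models and fitting

**Inversion recovery (T1).** Magnitude IR data carry no phase, so the
package fits the three-parameter absolute-value model

    s(TI) = | A (1 − B e^(−TI/T1)) |

with A the equilibrium amplitude, B the inversion efficiency (B = 2 for a
perfect 180° inversion) and T1 the longitudinal relaxation time. Leaving B
free absorbs imperfect inversion and incomplete recovery at finite TR
identically in simulation and fitting, so no explicit TR-saturation term is
modeled. The default timing vector is the seven-point protocol
TI = 247, 408, 674, 1112, 1838, 3030, 5000 ms with TR = 6500 ms.

Rather than restoring signal polarity explicitly, each voxel is fitted with
a multistart strategy: T1 is initialized from the TI of the observed signal
minimum via the null-point relation T1₀ = TI_min / ln 2, plus starts at
neighboring TIs (3 by default). This avoids the local minimum that the
absolute value creates around the null crossing. The start with the lowest
residual wins.

**Multi-echo decay (T2).** A two-parameter mono-exponential,
`s(TE) = A e^(−TE/T2)`, over the default 28-echo train TE = 8…224 ms
(8 ms spacing, TR = 600 ms — a TR shorter than the last echo is normal for
an echo train and is deliberately not rejected by validation).
Initialization is a log-linear regression on the first half of the echoes.
A constant noise-floor offset term exists as an option
(`FitOptions.t2_noise_floor_offset`) but is off by default, keeping the
model family identical across all pipelines.

**Optimizers.** Two interchangeable backends fit the same models:
Levenberg-Marquardt (`scipy.optimize.least_squares`, analytic Jacobian;
the sign of the IR model enters the Jacobian through sign(f)) and
Nelder-Mead simplex on the sum of squared residuals. The simplex backend
screens the multistart candidates with a coarse pass (≤40 iterations),
polishes the winner with a full run, and restarts once from the found
optimum with a fresh simplex to guard against premature collapse.
Convergence: relative parameter/cost change below 10⁻⁶ or 500 iterations.
Both backends are verified against a brute-force oracle
(`grid_search_fit`) that scans the time constant on a 1 ms grid and solves
the amplitude terms in closed form per grid value; on noisy voxels the
optimizers reach residuals at or below the oracle's.

**Plausibility filter.** After fitting, voxels with non-positive estimates
or estimates above 3000 ms (T1) / 300 ms (T2) are marked invalid. The
bound itself is inclusive — only values strictly greater are discarded —
an explicit convention, since "greater than" alone does not decide the
boundary case. Invalid voxels carry NaN and a False validity flag; all
downstream statistics consume the flag only. Voxels whose peak signal is
below `min_signal` (default: 3× the median border-voxel peak, a cheap
background estimate) are skipped as background. Because this default is
estimated from the whole volume, tests of per-voxel independence pass an
explicit `min_signal`.

## The digital phantom

The phantom exists so that every stage is testable without any scanner
data. It is schematic by design: 29 regions (13 bilateral pairs + 3
non-lateralized structures, the standard rat parcellation naming) are grown
inside an ellipsoidal "brain" envelope by capacity-constrained nearest-seed
assignment — each region claims its target number of nearest unassigned
voxels, smallest regions first, with mirrored seeds for left/right pairs.
Target sizes preserve the empirical ordering that ventricles are an order
of magnitude smaller than parenchymal structures (relative weights
3500 : 11000 : 33000 for lateral ventricles, third-and-fourth ventricles,
and other regions), with an 8-voxel floor so the smallest regions remain
representable on coarse test grids. Realized sizes match targets exactly up
to rounding.

Ground-truth T1/T2/proton-density values are piecewise constant per region,
set to plausible 7 T rat values (cortex ≈ 1.8–1.9 s / 43–46 ms, white
matter ≈ 1.6 s / 37–38 ms, CSF-filled ventricles 2.5–2.6 s / 105–110 ms).
Noise is Rician — magnitude of complex Gaussian noise,
`out = sqrt((s+n₁)² + n₂²)` — not Gaussian, since magnitude MRI has a
Rayleigh floor of mean σ√(π/2) at zero signal; the simulator's floor is
verified against that analytic value. Noise levels are quoted as peak-SNR:
σ = (peak signal of the noiseless series)/SNR. The standard test condition
is peak-SNR 50.

Per-center differences are modeled as a multiplicative gain, a smooth
multiplicative bias field (random low-frequency separable cosine modes,
normalized so the peak deviation from 1 equals the requested amplitude)
and additional Rician noise. This is a generic surrogate for coil and
sequence differences, not a physical model of any particular mechanism
(e.g. stimulated echoes). A scan–rescan replicate is the same phantom and
center effect with a fresh noise seed only.

Atlas variability (delineation + registration error) is emulated by
warping the ground-truth parcellation through a smooth random displacement
field (Gaussian-smoothed white noise, σ = 3 voxels, rescaled to a requested
RMS vector amplitude) with nearest-neighbor pull-back. Overlap with the
original decreases monotonically with the displacement amplitude.

What the phantom does *not* emulate: realistic anatomy and region adjacency,
partial-volume mixtures at boundaries, B1/slice-profile effects,
registration failures with topology change, physiological drift. Passing
tests therefore demonstrate correctness of the estimation and comparison
machinery under controlled conditions, not performance on real scans.

## Label fusion

"Maximum probability" fusion is per-voxel plurality voting over hard
labels (vote fraction = label probability), with background (label 0) as a
regular candidate and ties broken deterministically to the smallest label
id. Registration is assumed done upstream: fusion consumes co-registered
label volumes. Dice of two empty masks is defined as 1 (a region absent
from both parcellations is perfect agreement, avoiding 0/0).

## Agreement statistics

* Sample SDs (n−1) everywhere; a single-voxel region gets SD 0.
* Bland-Altman limits are mean ± exactly 2 SD (not 1.96 SD).
* Mean percent error is symmetric: mean(|x−y| / ((x+y)/2)) × 100. The
  symmetric form makes the report direction-free; note the alternative
  |x−y|/x changes values at the 0.1% level.
* Mann–Whitney U and Wilcoxon signed-rank use exact enumeration (with
  midrank tie handling) for combined sample sizes ≤ 12, and the
  tie-corrected normal approximation (scipy) above that. Two-sided exact
  p = P(|T − center| ≥ |t − center|) under the permutation null. Wilcoxon
  drops zero differences; an all-zero difference vector is reported as "no
  difference" rather than tested.
* Shapiro–Wilk (scipy) gates test choice at α = 0.05 per sample; a constant
  sample raises. Inter-center significance calls use α = 0.01, stated in
  the report.
* The scan–rescan criterion is |mean₁ − mean₂| < 2·max(sd₁, sd₂) per
  region, with the larger scan SD as the yardstick (the criterion does not
  name which scan's SD; the conservative choice is the larger). A zero
  difference always passes, including for uniform regions with SD 0.

## Study orchestration

One YAML config defines the whole design; `master_seed` is mandatory and
every random draw derives its seed as CRC-32 of a stable key path
(subject/center/scan/stage) XOR the master seed, so reruns are
bit-identical and adding a subject never changes another subject's data.
Atlas-set seeds derive from the set's own seed, not its name, so two sets
configured identically contain identical atlases — the null-control case,
which must yield Dice 1 between their fusions. Inter-subject variability is
a multiplicative per-region jitter of the truth values (SD 3% for T1, 5%
for T2, clipped at the plausibility bounds) — the same order of regional
spread as typical cohort data, not a calibrated reproduction of any
specific cohort.

## Problem sizes and numerical choices

Default grids: 64×64×32 for segmentation-only analyses (≈50k brain voxels;
fusion and Dice are cheap), 32×32×16 (≈6k brain voxels) as the standard
fitting phantom, and 16×16×8 for orchestration smoke tests. These sizes
keep the full simulate–fit–compare loop interactive on a single CPU while
leaving every region at least 8 voxels. Zero-noise round trips recover
regional T1 and T2 to better than 0.1%; at peak-SNR 50 the per-class
regional bias stays below 2% (T1) and 3% (T2) — the residual T2 bias is
the expected Rician-floor inflation of late echoes, largest for short T2.

## Known limitations

* The IR model family is one fixed parameterization; systematic offsets
  between genuinely different model equations (as can occur between
  independently developed fitting tools) are outside what the two-backend
  comparison can show.
* Fusion is unweighted plurality; STAPLE-style or locally weighted fusion
  is out of scope.
* No multiple-testing correction across the 29 regions, matching the
  study design being replicated.
* Region statistics assume co-registered inputs; nothing resamples or
  reorients volumes.
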