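# Methods

This note documents the models, conventions, and design choices behind
`restgraph`, in the order the pipeline applies them.

## Synthetic cohort

The generator emulates a two-group resting-state fMRI study at the level of
ROI-averaged signals. Defaults: 27 control-like ("a") and 18 patient-like
("b") subjects; 210 frames at TR = 2 s (a 7-minute run); 90 regions split
into six anatomical blocks (medial temporal, subcortical, occipital,
frontal, temporal, parietal-(pre)motor; 45 structures × 2 hemispheres).

**Correlation structure.** Each group has a target correlation matrix with
r = 0.35 inside a block and r = 0.10 between blocks. Group b differs on ten
planted edges (|Δr| = 0.3): five increases inside the medial temporal block,
concentrated on the two hippocampi (three incident edges each), and five
decreases within/between the frontal and parietal-(pre)motor blocks,
concentrated on the left precuneus and right middle frontal gyrus. The
concentration is deliberate: the n-to-1 connectivity weight w = 1/(1 − r²)
is convex in |r|, so (a) single incident edges cannot move a node's Γ beyond
between-subject noise, and (b) decreases of the same |Δr| move w roughly
four times less than increases. Only increase-loaded nodes are therefore
node-level recoverable, and a useful ground truth must concentrate them.
The effect size 0.3 is a test-design choice, not an empirical estimate —
no effect-size information exists for the real contrast.

**Noise model.** Signals follow a multivariate AR(1): x_t = φx_{t−1} +
√(1−φ²)·η_t with η ~ N(0, Σ) and φ = 0.3, so the stationary correlation
equals the target Σ while mimicking BOLD autocorrelation. Added on top:
a linear trend plus a 0.005 Hz sinusoid (amplitude 0.5, giving the
band-pass filter something real to remove) and two AR(1) nuisance reference
signals ("ventricle", "white matter") leaked into every region with
coefficient 0.2, giving the nuisance regressions something real to remove.

**PSD repair.** Planted shifts can make a target matrix indefinite; it is
repaired by eigenvalue clipping at 1e-8 followed by correlation
renormalization. If the repair moves any entry by more than 0.05 the
construction raises rather than silently changing the ground truth.

**Motion.** Six smoothed random-walk axes per subject, rescaled so
non-violators peak at 0.05–0.5 (mm or degrees) relative to the first frame,
while each designated violator exceeds the exclusion limit on exactly one
axis (peak 1.1–1.6). This makes the exclusion rule's ground truth
unambiguous.

**What the generator does not emulate:** hemodynamic response shapes,
physiological (cardiac/respiratory) aliasing, spatial autocorrelation
between neighboring regions, registration errors, or motion-correlated
signal artifacts. Passing recovery tests therefore shows the statistical
chain is correct and calibrated under the stated noise model — not that the
pipeline is robust to every artifact of real scanner data.

## Preprocessing

Order: discard 10 frames → band-pass → regress 6 motion parameters →
regress ventricular signal → regress white-matter signal → linear detrend.
The three regressions run *sequentially* as separate OLS models (not one
joint model) to mirror the conventional enumeration of these steps;
the result differs slightly from a joint fit. Filtering before regression
is the default (`filter_first=False` swaps the order).

The band-pass is a zero-phase frequency-domain mask (rFFT) with
raised-cosine transitions of width 0.002 Hz and the DC bin zeroed. This
realization has testable, near-ideal band edges: pass-band ratio ≥ 0.95,
stop-band ≤ 0.05, exact linearity.

The motion summary is the mean frame-to-frame Euclidean displacement,
(1/(M−1))·Σ √(Δx² + Δy² + Δz²), computed separately for translations (mm)
and rotations (degrees). Exclusion uses single-axis displacement relative
to the first frame (the realignment reference) with limits 1 mm / 1°.

## Connectivity and thresholding

Pearson r per region pair over the conditioned series (L = 200 frames under
defaults); Fisher z = atanh(r) for variance stabilization. Edge p-values
use the normal approximation with variance 1/(L−3) — the convention
consistent with quoting d.f. = 197 at L = 200 — with an exact-t alternative
(d.f. = L−2) behind a flag. Thresholding uses |z| by default (negative
correlations can form edges); a positive-only mode exists for sensitivity
analysis. The `target_mean_degree` mode picks the cut from the sorted |z|
values so the realized mean degree is closest to the target *from below*,
ties resolved toward the sparser graph (reproducible and conservative).

## Topology metrics

All metrics operate on symmetric boolean adjacency matrices. Geodesics are
computed by level-synchronous BFS through float32 matrix products, which on
dense ≤100-node graphs is substantially faster than sparse Dijkstra and is
verified exactly against Floyd–Warshall and networkx in the tests.
Conventions: C_i = 0 for nodes of degree < 2; disconnected graphs have
L computed on the largest component with a logged warning (strict mode
raises); efficiency treats unreachable pairs as 0 contribution.

Γ uses d_ij = √(1 − r_ij²) and w_ij = d_ij^(−α) with α = 2 (so
w = 1/(1−r²)); an exponential kernel e^(−α·d) is available by
configuration. Γ̃ normalizes by the sum over nodes (Σ Γ̃_i = 1), making
group comparisons scale-free.

## Null models and the small-world regime

Degree-preserving randomization by double-edge swaps: pick edges (a,b),
(c,d) with four distinct endpoints and (a,d),(c,b) absent; swap. The budget
is 10× the edge count (the common convergence heuristic), with a stall cap
of 20× that many attempts — near-complete graphs have few legal swaps and
come back close to the input, which is correct: their degree-matched null
set is tiny. The swap loop runs in a compiled (numba) kernel with an
identical pure-Python fallback; results are deterministic per seed within a
backend.

Small-world indices compare against rewired ensembles (default 100
realizations) rather than the theoretical Erdős–Rényi values C = K/N,
L = ln N/ln K, which are computed and reported but are a poorer control
when the degree distribution is non-Gaussian. The regime sweep (step 0.005)
uses 20 rewirings per threshold as a speed/accuracy trade (recorded in the
output); a threshold is in-regime iff the graph is fully connected, has
K ≥ 2 ln N, and beats its ensemble on both efficiency comparisons with
strict inequalities (ties fail). Grids include their endpoint when it falls
within half a step.

## Group statistics

Edge-wise tests operate on subject-level Fisher-z values (normality), with
pooled-variance (Student) t by default — Welch behind a flag — and BH-FDR
across the 4005-pair family (BY behind a flag). An optional p ≤ p₀ pre-mask
restricts the FDR family; both the mask and the q level are recorded in the
output. Node-wise and curve-wise comparisons reuse the same machinery with
FDR across 90 regions or across grid points. Clinical correlations are
plain Pearson r with uncorrected two-sided p, flagged exploratory. The
subject-mean of Γ̃ is constant by construction (Σ Γ̃ = 1), so clinical
correlations use the raw Γ strength.

## Degree-distribution model selection

The empirical cumulative probability P(K ≥ k) at distinct positive degrees
is fit by nonlinear least squares (5 deterministic start points per family)
to a·k^(τ−1), a·e^(−k/k_c), and a·k^(τ−1)·e^(−k/k_c); families are ranked
by AIC = n·ln(SSE/n) + 2p. Fits are in linear space to keep SSE/R²/RMSE on
the reported scale; log-log is for display only.

**Known limitation.** The truncated power law nests the exponential
(τ = 1). AIC's 2-point penalty leaves a non-vanishing probability —
≈ P(χ²₁ > 2) ≈ 16% even for ideal maximum-likelihood fits, and considerably
more for least squares on cumulative curves, whose residuals are strongly
autocorrelated partial sums — of selecting the richer family when the
simpler one generated the data. In practice exponential-law degree samples
of size 90 are attributed to the truncated family in roughly half of the
replicates, while truncated-law samples are recovered reliably (≥ 90%).
Conclusions that a degree distribution is *broad-scale/truncated* are
therefore much stronger than conclusions that it is *purely exponential*;
treat a truncated-vs-exponential AIC margin smaller than a few points as
inconclusive.

## Determinism and problem sizes

Every stochastic component accepts a seed; the pipeline derives stage seeds
from one master seed by documented SeedSequence splitting, and identical
configurations reproduce byte-identical numeric outputs. Test and
acceptance runs use scaled problem sizes chosen to exercise every code path
at full region count (90) while keeping ensembles and replicate counts
modest: 100-graph ensembles for reported indices, 20 for sweeps, 5–50
replicates for calibration and recovery checks.
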