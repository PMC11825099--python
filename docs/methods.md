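# Methods

## The model

`bimodalkit` studies how bimodal single-cell expression distributions arise
and disappear in bacteria.  Its core is a reduced stochastic model of one
gene whose promoter switches between two transcription states:

* **Promoter switching.** The free promoter flips L→H at rate `k_H` and
  H→L at rate `k_L` (subscripts name the destination state).  Switching is
  only allowed while no RNAP is engaged; an RNAP caught between binding and
  escape plausibly blocks the change (`switch_when_occupied=True` exposes
  the alternative).
* **Two rate-limiting steps of initiation.** In state X an RNAP holoenzyme
  binds the free promoter at the effective rate `k_bind_X · n_holo`
  (`n_holo` is the σ70 or σ38 holoenzyme copy number, a fixed concentration
  parameter, not a consumed species), then escapes at `k_esc_X`, releasing
  one RNA and freeing the promoter.  While occupied, the promoter accepts
  no new binding.  The effective transcription rate of the cycle is the
  harmonic composition `r_X = 1/(1/(k_bind_X·n_holo) + 1/k_esc_X)`.
* **Expression.** Translation RNA → RNA + Protein at `k_tr`; first-order
  decays `kd_rna`, `kd_prot` lump degradation and dilution by division.
  Cell lineage and partitioning noise are deliberately absent.

With the promoter locked in state X the stationary means are
`⟨RNA⟩ = r_X/kd_rna` and `⟨P⟩ = r_X·k_tr/(kd_rna·kd_prot)`; with switching,
state H carries weight `π_H = k_H/(k_H+k_L)`.  When switching is slower
than every other process, each cell effectively lives in one state for many
protein lifetimes and the snapshot distribution of protein numbers is a
mixture of the two locked-state laws — bimodal.

Single-state *collapse variants* replace the two transcription states by
one whose effective rate is `r_L`, `(r_L+r_H)/2` or `r_H`; the averaged
variant scales both H-state steps by a common factor (which scales `r`
exactly), keeping the two-step occupancy noise.  A *positive-feedback
variant* lets the protein itself bind the promoter region (one molecule is
sequestered while bound) and switch it to the high-transcription
configuration; with the shipped `DEFAULT_FEEDBACK_PARAMS` both the basal
and the self-sustained configuration persist for roughly ten protein
lifetimes and the snapshot distribution is bimodal.

## Default parameters (units: minutes, molecules)

| parameter | default | why |
|---|---|---|
| `k_bind_H·n70`, `k_esc_H` | 0.5, 1.0 /min | H-state initiation of an active bacterial promoter |
| `k_bind_L·n70`, `k_esc_L` | 0.05, 0.1 /min | one order of magnitude below H |
| `k_tr` | 0.4 /min | sets the expression scale (see below) |
| `kd_rna` | 0.2 /min | 5-min mRNA lifetime (exponential growth) |
| `kd_prot` | 0.02 /min | 50-min protein lifetime, dominated by dilution |
| `k_H = k_L` | 0.001 /min | switching slower than everything else; state memory ~1000 min |
| `n_rnap70`, `n_rnap38` | 500, 50 | exponential-phase holoenzyme pools |

These give locked-state protein means of ≈3.3 (L) and ≈33 (H).  The scale
was chosen, together with the classifier held fixed, so that the documented
qualitative behavior genuinely holds in the exact (master-equation)
distributions, not merely in the classifier's verdicts: ten-fold reductions
of `k_bind_H`, `k_esc_H` or `k_tr`, and ten-fold increases of `kd_rna` or
`kd_prot`, each merge the two modes into one low-centered mode, while the
gradual stationary-phase transition (below) leaves them resolved.  At
substantially larger means the translation/decay perturbations leave two
genuinely separated modes (the collapse pattern disappears); at much
smaller means the reference distribution itself degenerates.

**Switching initialization.** Ensembles start each cell with the promoter
drawn from the switching chain's stationary law (`π_H`), RNA = Protein = 0,
and are sampled after 20 protein lifetimes.  This removes the
initial-state bias that a fixed L-start would impose whenever the snapshot
time is not large compared with `1/(k_H+k_L)`, and makes SSA snapshots
directly comparable to the stationary master-equation oracle at any
switching speed.

**Stationary-growth target.** Entry into stationary phase is modeled from
known physiology: mRNA mean lifetime 7.8 min (`kd_rna = 1/7.8`); dilution
(0.019/min of the reference `kd_prot`) cut by 91.5% while the residual
degradation (0.001/min) rises 8%; translation cut 40-fold; and the
conserved 550-molecule holoenzyme pool shifted so σ38 holds 30%
(`sigma38_fraction`, configurable — larger shifts push the low mode
against zero).  Intermediate conditions interpolate each rate
geometrically (rates act multiplicatively and must stay positive) and the
pools linearly with rounding.

## Simulation and oracles

The simulator is the exact direct-method SSA (copy numbers are small;
tau-leaping would trade away the exactness the tests anchor on), with a
numba-compiled inner loop for ensembles.  Per-cell seeds derive from one
master seed through `numpy.random.SeedSequence`, so ensembles are
reproducible and independent of evaluation order; a length-n ensemble's
first k cells coincide with the length-k ensemble's.

Two independent oracles check it: closed-form stationary means (above) and
the stationary solution of the truncated chemical master equation.  The
CME solver enumerates the reachable state space by breadth-first search
inside per-species copy-number bounds (reactions that would leave the box
are suppressed), orders states lexicographically, and solves πQ = 0 by
sparse LU with one probability pinned and the result renormalized — a
dense normalization row would destroy the factorization's sparsity.
Bounds default to mean + 10·SD with a super-Poissonian variance allowance
(RNA ×3, protein ×10) and expand ×1.5 until the probability mass on the
box boundary is below 1e-6 (reported in the result).

SSA-vs-CME distances are total variation on a 40-bin equal-width
histogram: with 1e4 samples spread over hundreds of distinct protein
counts, unbinned empirical TV has a sampling floor of order 0.1 even for a
perfect simulator, so only the binned distance is informative at the 0.05
level.

## Bimodality classification

Two criteria, OR-combined; either suffices for a bimodal verdict:

* **Peaks** — Gaussian KDE on a 512-point grid spanning the data, Silverman
  bandwidth; local maxima need prominence ≥ 5% of the peak density and
  separation ≥ 5% of the data range.
* **BIC mixture** — 1- vs 2-component Gaussian mixtures by EM (10 restarts,
  deterministic seeds) on the analysis scale; bimodal requires
  ΔBIC ≥ 10, minor weight ≥ 0.05, mean separation ≥ 2·min(σ) *and*
  Ashman's D = |μ₂−μ₁|/√((σ₁²+σ₂²)/2) ≥ 2 *and* a two-moded fitted
  density.  The last two guards matter for bursty count data: a
  two-Gaussian fit beats one Gaussian by ΔBIC ≫ 10 on *any* right-skewed
  sample, so without them the criterion reports mixture structure (two
  latent populations) rather than bimodality (two density modes).  D ≥ 2
  is the classical condition for a two-Gaussian mixture to show two modes.

Analysis scales: fluorescence intensities on log10 (positive,
right-skewed), simulated protein counts raw.  Integer-valued low-count
data get lattice-aware floors — KDE bandwidth ≥ 0.6 and EM component SD
≥ 0.5 of the smallest observed value spacing — so the integer lattice is
not resolved as structure.  All rules (Silverman, data-range grid, lattice
floors) are covariant under positive affine rescaling, which makes the
shape statistics exactly invariant to instrument gain and offset.

For a bimodal sample with dominant peaks pk₁ < pk₂ of heights PDF₁, PDF₂
(mixture means stand in for peaks when only the BIC criterion fires):

    d = (pk2 − pk1) / (max − min)      relative mode distance
    h = (PDF1 − PDF2) / max density    relative height difference
    o = #{pk1 < v < pk2} / n           fraction of cells between the peaks

`d` uses the empirical sample range, not the grid span; `o` counts strictly
between the peak positions; `h` is reported with the lower-position peak
first (the `h_convention` field records this, as the opposite sign
convention also circulates).  d, o ∈ [0,1]; h ∈ [−1,1]; all three are
defined only for bimodal calls.

## In-silico experiments

* **Single-parameter sweeps** over 7 log-spaced factors in [0.1, 10]
  (coupled pairs such as `k_L,k_H` at fixed ratio supported); per point:
  snapshot (default 5000 cells at 20 protein lifetimes), verdict, shape
  parameters, moments.  Seeds per grid point derive from the master seed
  by spawn keys, so results are order-independent and bit-reproducible.
* **Extended L-rate sweeps** move `k_bind_L` *and* `k_esc_L` geometrically
  up to the H-state values (the companion rate-limiting step is matched);
  at full progress the states coincide and the distribution collapses onto
  the original high state.
* **Stationary transition** over an f-grid of interpolated conditions.
* **Transient collapse** (`run_unimodal_shift`): the two-state stationary
  ensemble is handed to a collapse variant at t=0 and classified at a
  series of times; the relaxation time is the first time the verdict turns
  unimodal and stays so.
* **Hysteresis ramps** (`run_ramp_cycle`): a condition sequence is visited
  forward then backward.  Equilibrated mode re-equilibrates at every
  condition (20 protein lifetimes); lagged mode carries one ensemble and
  dwells only 30 min (≈ half a protein lifetime) per condition, holding
  the deepest condition 8 dwells as a sustained stress episode.  The
  shipped cycle ramps `k_bind_H` through (1, 0.7, 0.5, 0.36, 0.22, 0.1)×:
  the turnaround sits in the unimodal-collapse region, so the forward pass
  still resembles the starting distribution while the backward pass
  carries a memory of the collapse — a large, reproducible loop.

`loop_gap` quantifies loop non-closure as the mean Euclidean distance in
(d, o) between direction-matched bimodal conditions (h is excluded: it is
sensitive to how cells are subsampled between passes; non-bimodal points
are gaps, not imputed).  The metric is this package's operationalization —
path inspection is inherently visual — and whether a gap means anything is
judged against a resampling null: the loop gaps of independently
re-equilibrated cycles, whose forward and backward passes differ only by
sampling noise.  Single-cycle gaps have a broad, right-skewed null
distribution dominated by the extreme-value jitter of the sample range
inside d (the peak positions themselves are comparatively stable), so the
control experiment compares medians over repeated cycles (five
equilibrated, three lagged) against the null's 97.5th percentile over
twelve cycles.

## Synthetic cytometry

`synthetic_cytometry` generates analysis-ready stand-ins for reporter-strain
flow cytometry: per cell, intensity = autofluorescence (log-normal floor)
+ a draw from a log-normal expressing mixture × a multiplicative log-normal
extrinsic-noise factor; three biological replicates per condition with
small log-scale mean shifts, merged before fitting; and SSC-H / FSC-H /
pulse-width size proxies that are unimodal log-normals tied to
log-intensity through a Gaussian copula (sample Pearson correlation equals
the requested coefficient).  `model_to_intensity` bridges simulator output
to this space (intensity = autofluorescence + gain × count × extrinsic
factor): intrinsic reaction noise alone is far narrower than measured
distributions, and the extrinsic factor stands in for shared-component
variability and measurement error.  The seven shipped fixtures are labelled
synthetic and imitate qualitative styles only (distant vs close modes,
asymmetric vs even weights); none claims to match a measured gene.  What
passing tests on these data show is that the analysis stack recovers known
structure under realistic skew, background and replicate structure — not
that real cytometry artifacts (gating, compensation, cell-cycle structure)
are handled.

## Calibration

Two reporter libraries measure the same promoters on different fluorescence
scales.  Four anchors per distribution — minimum cell signal, weak-mode
mean, high-mode mean, maximum signal (mode means from the 2-component
mixture on log scale, back-transformed) — are matched between scales and
values map by piecewise-linear interpolation through the anchor pairs,
extrapolating with the terminal segments' slopes (the only monotone choice
without data beyond the anchors).  The map is strictly increasing, so rank
statistics and mode structure survive; inverse-composition is exact on the
anchors.  OLS summaries (slope, R², slope t-test, 95% CI) describe paired
anchor levels of matched strains.

## Numerical choices and degenerate inputs

Fewer than 50 values, constant samples, non-positive intensities on the
log scale, unimodal calls passed to `shape_params` or `compute_anchors`,
non-increasing anchor sets, constant x in regression — all raise
`ValueError` rather than guessing.  EM non-convergence makes the BIC
criterion false.  An SSA whose propensities all vanish ends early with the
absorbing state recorded.  Zero holoenzymes with positive binding constants
is a legal silent promoter.  Geometric interpolation falls back to linear
for a rate that is zero at either endpoint.

## Problem sizes

Defaults were sized for a desk-scale reproduction: 1e4 cells for oracle
comparisons and mixture-weight limits, 5e3 per sweep point, 6e3–1e4 per
hysteresis condition, 100 seeded datasets per classifier-calibration arm.
At these sizes the full test suite and the acceptance script each complete
in minutes on one CPU.

## Known limitations

* No cell lineage, division, partitioning noise or cell-cycle gating;
  decay rates subsume dilution.
* Perturbations act through rate-constant changes only; the mechanistic
  chain from antibiotic to rate is not modeled.
* The classifier's thresholds (ΔBIC 10, weight 0.05, D ≥ 2, 5% prominence)
  are conventions, config-exposed; distributions engineered near those
  boundaries will flip verdicts with the seed.
* Rate constants are not fitted to data — no likelihood links the model to
  cytometry measurements; comparisons are qualitative by design.
* `o` is a between-peak count, so it conflates state-switching frequency
  with mode breadth and is not monotone under mode convergence (the
  between-peak window shrinks as peaks approach).
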