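# Methods

## Scope and model

`kinasemsm` implements the standard Markov-state-model (MSM) route to the
thermodynamics and kinetics of a kinase catalytic domain's conformational
ensemble: feature extraction from coordinate trajectories, time-lagged
independent component analysis (tICA) to find slow collective coordinates,
K-means discretization of the reduced space, reversible maximum-likelihood
estimation of the transition matrix at a Markov lag τ, spectral analysis
(populations, implied timescales), kinetic Monte Carlo (KMC) synthesis of
long mock trajectories, mean first passage times (MFPTs) by linear solve,
and whole-trajectory bootstrap for confidence intervals.

The underlying model is a discrete-time, discrete-state Markov chain at lag
τ: p(t+τ) = p(t)·T(τ). Estimation assumes (i) the process is Markovian at
the chosen lag in the discretized space, (ii) microscopic reversibility
(detailed balance π_i T_ij = π_j T_ji), and (iii) the input trajectories are
equilibrium samples, so pooled transition counts are unbiased. Relaxation
timescales follow from the eigenvalues μ of T as t_i = −τ/ln μ_{i+1}.

Because the millisecond-scale MD data such an analysis is normally applied
to cannot be shipped, the package carries a first-class synthetic generator
(`synthetic`) whose chains have *known* free energies, barriers and MFPTs,
so every stage is tested as a parameter-recovery problem.

## The four-state kinase landscape fixture

The generator realizes the canonical apo-kinase landscape: four macrostates
— active, intermediate, Src-like inactive, and DFG-out — with hub
connectivity (the intermediate alone exchanges with the other three; direct
active↔Src-like and DFG-in↔DFG-out shortcuts are disallowed by infinite
barriers). Each macrostate is split into 3 microstates with low internal
barriers, giving a 12-state chain whose lumping into 4 states is a
nontrivial task for the pipeline; the 12-microstate granularity is a free
design choice, standing in for the much finer discretization a real dataset
supports.

Transition probabilities use Metropolis-like barrier rates

    T_ij = c · exp(−(B_ij − G_i)/kT),  B_ij = B_ji,

which guarantee detailed balance with Boltzmann stationary weights
exp(−G_i/kT). All analyses use T = 300 K (kT = 0.596 kcal/mol). The rate
prefactor c is fixed at 0.25 for the packaged fixtures (validated: every row
keeps a positive diagonal, i.e. the chain is metastable at the 80 ns frame
interval); when chains are built directly, c defaults to the largest value
leaving a 0.1 diagonal margin.

Two fixtures emulate the effect of protonating the DFG aspartate:

| target                                   | ASP (deprotonated) | ASH (protonated) |
|------------------------------------------|--------------------|------------------|
| populations (src-like / active / dfg-out)| 52% / 7% / 1%      | 47% / 6% / 9%    |
| MFPT DFG-in → DFG-out                    | 1.2 ms             | 300 µs           |

Calibration is exact by construction: microstate free energies follow from
Boltzmann inversion of the population targets (macrostate weight split
equally over its 3 microstates), and the intermediate↔DFG-out flip barrier
is then root-found (Brent, bracket 0.3–9 kcal/mol) so the π-weighted MFPT
from the DFG-in macrostates to DFG-out hits the target at the 80 ns lag.
Secondary barriers are fixed (0.8 kcal/mol intra-macrostate, 1.5 kcal/mol
for the intermediate↔active and intermediate↔Src-like exchanges above the
higher minimum) so that DFG-in equilibration is fast relative to the flip.

Two consequences of this calibration are worth stating. First, the DFG-out
stabilization implied by the populations is ΔΔG = −kT·ln(0.09/0.01) ≈ −1.31
kcal/mol, consistent in sign and magnitude with the ~1 kcal/mol shift the
landscape emulates. Second, detailed balance *pins* the reverse (DFG-out →
DFG-in) MFPTs once the forward MFPTs and populations are set: they come out
at ≈12 µs (ASP) and ≈30 µs (ASH). The reverse passage therefore stays on the
tens-of-microseconds scale and changes by ~2.4× while the forward passage
changes fourfold — qualitatively "relatively similar", though the exact
factor is not a free parameter of the generator.

## Feature emissions: what is emulated and what is not

Observed features are Gaussian emissions around per-microstate means: 20
signal dimensions plus 30 i.i.d. standard-normal distractor dimensions
(50 total). Macrostate means sit on a regular tetrahedron with pairwise
distance 16σ; microstates are offset 1.2σ from their macrostate mean in
seeded random directions (layout seed 1234, part of the fixture definition).

The 16σ separation is deliberate. A linear readout of a two-state exchange
with minor-state population π contributes variance π(1−π)·d² against the
emission noise σ², so the tICA eigenvalue of that mode is deflated by the
factor x/(1+x) with x = π(1−π)·(d/σ)². For the 1%-populated DFG-out basin,
separations below ~8σ push the flip mode beneath intra-macrostate modes and
the mode — and with it the basin — disappears from a 3-component tICA
model. In real MD feature vectors a conformational switch moves many
correlated features (dihedral sines/cosines flip by O(1) against within-
basin noise of ~0.1–0.2), so collective separations of tens of σ along the
discriminating direction are the realistic regime; 16σ reproduces the
situation where the DFG flip is a leading tICA mode. It also makes
frame-level state assignment error negligible (≈8σ to the decision
boundary), which is what permits population recovery *within* bootstrap
confidence intervals rather than merely near the targets.

What the generator does **not** emulate: continuous within-basin diffusion
(emissions are i.i.d. given the state, so within-state autocorrelation is
zero); non-Markovian memory at the frame interval (trajectories are exactly
Markovian at 80 ns, which is why implied timescales are flat in lag);
anisotropic or state-dependent emission noise (supported but not default);
and non-equilibrium initial conditions (fixture trajectories start from the
stationary distribution). Passing recovery tests therefore demonstrates
correctness of the estimators under the model's own assumptions — not
robustness to the projection and memory errors real MD carries. A separate
AR(1) generator provides the continuous-process oracle for tICA: its lag-τ
autocorrelation is exp(−τ/τ_r) in closed form.

## Estimation choices

- **tICA.** Covariances are mean-free and pooled across trajectories; the
  lagged correlation uses only within-trajectory (t, t+τ) pairs and is
  symmetrized as (C + Cᵀ)/2 before solving C(τ)ν = λΣν (the reversible
  estimator). Σ is shrunk toward its diagonal with weight γ = 1e-8 plus a
  1e-12 trace-scaled ridge: full-rank on the fixtures, but rank-deficient
  feature sets (duplicated columns) must not crash. Eigenvector signs are
  fixed (largest-magnitude loading positive) for cross-platform
  reproducibility. *Kinetic mapping* scales component i by λ_i so Euclidean
  distances approximate kinetic distances; it is on by default, matching
  the selected-model convention this pipeline follows (tICA lag 208 ns and
  3 components by default; the fixture configuration uses an 80 ns tICA lag
  because its frame interval is 80 ns and lags must be integer multiples).
- **Counting.** Sliding-window counts (every (t, t+lag) pair) for maximal
  data use; the effective-sample optimism this causes is absorbed by the
  trajectory-level bootstrap.
- **Ergodic trim.** Largest strongly connected component of the C_ij > 0
  graph; ties broken by total counts, then lowest index.
- **Reversible MLE.** Classical self-consistent edge-weight iteration
  x_ij ← (C_ij+C_ji)/(c_i/x_i + c_j/x_j), converged when the log-likelihood
  change per sweep falls below 1e-10 (cap 10⁶ sweeps). Symmetric counts
  reproduce plain row normalization exactly. Spectra are computed from the
  π-symmetrized form, so eigenvalues are real by construction.
- **Macrostates.** Explicit, total predicate rules over cluster centers (no
  automated lumping): the packaged rule assigns each center to the nearest
  macrostate anchor, where anchors are the macrostate emission centroids
  projected through the fitted normalizer and tICA model. Non-partitions
  raise with the offending centers listed.
- **Free energies.** G_i = −kT·ln(p_i/p_ref); the reference is the most
  populated macrostate of the designated reference ensemble, held fixed
  across ensembles so ΔΔG is meaningful. Zero populations map to +inf, not
  an exception.
- **Ensemble comparison.** tICA and K-means are fit on the pooled ensembles
  (one set of state definitions); counts and MSMs are estimated per
  ensemble. The pooled frames are canonically sorted before the K-means fit
  so the shared discretization — and hence every downstream number — is
  invariant to the order in which the ensembles are given.
- **MFPT.** Linear solve m = (I−Q)⁻¹·τ1 over non-sink states; a source
  *set* is averaged with stationary weights renormalized within the set
  (uniform fallback for zero-measure sets). Sources pool all DFG-in
  macrostates (active, intermediate, Src-like) unless told otherwise.
- **KMC oracle.** First-hit validation propagates walker *counts* with
  per-state multinomial draws — distributionally identical to independent
  walkers at O(n_states²) cost per step — so 10⁵ walkers through a
  15,000-step mean passage take seconds.
- **Bootstrap.** Resamples whole trajectories with replacement (respecting
  autocorrelation), re-estimates counts → trim → MLE → observables on the
  fixed discretization, and reports median with 2.5/97.5 percentiles.
  Rounds failing estimation (disconnected resamples) are skipped and the
  skip count surfaced, never imputed. Default 200 rounds.
- **Cross-validation.** Hyperparameters are scored by the generalized
  matrix Rayleigh quotient: the training model's top-m eigenfunctions are
  evaluated on held-out trajectories via tr[(VᵀC₀₀V)⁻¹(VᵀC₀τV)], folds split
  by whole trajectories, m = n_timescales + 1. This variational score is
  the documented stand-in for model selection; under-discretization lowers
  it and time-shuffled data collapse it toward 1.

## Problem sizes and determinism

The packaged study conditions are 100 trajectories × 5,000 steps (5×10⁵
frames at 80 ns, i.e. 40 ms aggregate) per ensemble, 12 clusters, 3 tICs,
200 bootstrap rounds; tICA closed-form checks run at 10⁶ AR(1) frames and
the MFPT oracle at 10⁵ walkers. One ensemble fit takes ~10 s and the full
comparison ~40 s on one CPU. Every stochastic step takes an explicit seed
(trajectory sampling, emissions, K-means, KMC, bootstrap), and reruns with
identical config and inputs are byte-identical, including persisted tables.

## Geometry module

Torsions use the atan2 formulation with the convention that the trans
arrangement maps to +π; they are emitted as (sin, cos) pairs. RMSDs use
Kabsch superposition (SVD with determinant correction) fit on the measured
selection by default — whether to fit on the motif or the whole protein is
configurable because conventions differ — against a user-supplied reference
structure (for the kinase panel: a double-helical inactive conformation).
The switch panel reports activation-loop (539–559), P-loop (410–415),
R-spine ({540, 449, 519, 460}) and DFG (539–541) heavy-atom RMSDs plus the
Glu439(CD)–Arg468(CZ) and Glu445(CD)–Lys430(NZ) salt-bridge distances,
author residue numbering throughout. Moving averages are trailing (a
centered window would be an equally defensible reading of "average across
10 frames"). Exact reproduction of any particular published feature vector
is not attempted: such selections depend on unpublished atom choices, so
the dihedral/contact sets are configuration, not constants. mdtraj handles
on-disk trajectory formats and serves as an independent cross-check for the
geometry kernels in the test suite.

## Known limitations

- Macrostate definitions rely on user-supplied anchors or predicates; there
  is no spectral lumping (PCCA-style), by design.
- The bootstrap keeps the discretization fixed across rounds; uncertainty
  from tICA/clustering variability is not propagated.
- Populations of very rare states (~1%) carry the sampling noise of a
  handful of flip events even at the packaged data sizes; their bootstrap
  intervals are honest but wide.
- No continuous-time (rate-matrix) estimation, transition-path theory, or
  hidden-Markov refinement.
- The sparse/L1 tICA variant is out of scope; the dense reversible
  estimator with kinetic mapping is the implemented method.
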