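# kinasemsm

Markov state model (MSM) analysis of kinase conformational ensembles:
time-lagged independent component analysis (tICA), reversible MSM
estimation, spectral thermodynamics, kinetic Monte Carlo, mean first passage
times, and bootstrap uncertainty — packaged with a calibrated synthetic
generator of the four-state kinase landscape so the entire pipeline is
testable as a parameter-recovery problem without any external dataset.

## The problem

Protein kinases such as BTK interconvert between an active conformation and
several inactive ones (a Src-like state with a folded activation loop, a
DFG-out state that opens the classic type-II drug pocket, and a
structurally loose intermediate that acts as the hub between them). The
populations of these states and the timescales of exchange — e.g. how fast
the DFG motif flips, and how protonating the DFG aspartate shifts the
balance — are exactly what an MSM built from many short MD trajectories
estimates:

- propagation law: `p(t + τ) = p(t) · T(τ)`
- relaxation timescales: `t_i = −τ / ln μ_{i+1}` for eigenvalues μ of T(τ)
- tICA: solve `C(τ) ν = λ Σ ν` for the slowest linear collective variables
- MFPT: solve `m = (I − Q)⁻¹ τ·1` over non-sink states
- free energies: `G_i = −kT ln(p_i / p_ref)`

The library modules (`src/kinasemsm/`) implement each stage; the numbered
scripts under `analysis/` run the study end to end and write tables under
`results/`; `docs/methods.md` documents the model, parameter choices and
limitations.

## Worked example

Calibrate the two ground-truth chains (deprotonated "ASP" and protonated
"ASH" DFG aspartate), sample 100 trajectories × 5,000 steps at the 80 ns
lag, and run the full pipeline with bootstrap:

```bash
python analysis/01_calibrate_chains.py
python analysis/03_fit_asp_msm.py
```

which prints (abridged):

```
[asp] populations: {'active': 0.07, 'intermediate': 0.4, 'src_like': 0.52, 'dfg_out': 0.01}
[asp] DFG-in→out MFPT 1200.0 µs, reverse 12.1 µs, flip barrier 2.821 kcal/mol
[ash] DFG-in→out MFPT 300.0 µs, reverse 29.6 µs, flip barrier 3.353 kcal/mol
protonation stabilizes DFG-out by -1.31 kcal/mol (from the stationaries)

  macrostate  generator  median   lo95   hi95  covered
      active       0.07  0.0705 0.0666 0.0747     True
intermediate       0.40  0.4026 0.3981 0.4080     True
    src_like       0.52  0.5180 0.5111 0.5245     True
     dfg_out       0.01  0.0084 0.0054 0.0128     True
```

Reading this: the calibrated ASP chain has Src-like as the dominant state
(52%), a rare DFG-out state (1%) reached on the millisecond scale, and the
full pipeline (featurize → normalize → tICA → K-means → reversible MSM →
macrostate lumping) recovers every macrostate population within its
200-round bootstrap 95% interval. `analysis/04_compare_protonation.py` then
compares the two ensembles on one shared set of state definitions and
reports the protonation signature — DFG-out population rising from ~1% to
~10% (ΔΔG ≈ −1.5 kcal/mol against the generator's −1.31) and the DFG-in →
DFG-out MFPT dropping from ~1.2 ms to ~300 µs. `analysis/05_kmc_and_fes.py`
synthesizes an 800 µs kinetic Monte Carlo trajectory (10,000 frames × 80 ns)
and writes MSM-reweighted free-energy surfaces over the two leading tICs on
a common zero.

## Layout

```
src/kinasemsm/
  synthetic.py   ground-truth chains, calibration, emissions, AR(1), toy structures
  features.py    topologies, dihedrals, distances, RMSD, order-parameter panel
  tica.py        covariances, generalized eigenproblem, projection, timescales
  msm.py         K-means, counting, ergodic trim, reversible MLE, spectra, GMRQ CV
  kinetics.py    kinetic Monte Carlo, MFPT, first-hit oracle, bootstrap
  pipeline.py    config-driven runs, ensemble comparison, free-energy surfaces
analysis/        numbered end-to-end drivers (write tables to results/)
tests/           pytest suite (unit, property and end-to-end recovery tests)
```
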