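# mirffl

Stochastic modelling of microRNA incoherent feed-forward loops (FFLs) and
the single-cell noise statistics used to study them — built around the
activation-induced microRNA target CD69 in developing T cells
(thymocytes), where the T-cell receptor input induces both *Cd69* mRNA
and the microRNAs miR-17/miR-20a that repress it.

The package is for quantitative biologists who want to (i) simulate small
gene-regulatory circuits exactly and ask how a co-regulated microRNA arm
changes the mean and cell-to-cell variability of a target protein, and
(ii) compute the flow-cytometry population statistics that quantify such
variability — on synthetic event data with known ground truth.

## What it computes

**Circuit simulation.** Exact Gillespie (direct-method) simulation of
mass-action networks with Hill-modulated propensities,
`h_act(x) = x^n/(K^n + x^n)` and `h_rep(x) = 1/(1 + (x/K)^n)`. Two FFL
variants are built in: a transcription factor TF activates both a target
mRNA and a microRNA, and the microRNA either represses target translation
or drives target-mRNA degradation through a miRNA:mRNA complex. A
CD69-calibrated instance maps measured copy numbers (≈6 target mRNAs per
activated cell; microRNA at ≈9 resting / ≈42 activated copies) onto rate
constants by rate balance. The headline comparison contrasts activation
*with* the microRNA arm responding against activation with the microRNA
held at its resting production rate, over ensembles of 10,000 runs.

**Noise analytics.** The coefficient of variation (CV = 100·SD/mean,
sample SD), the technical-noise bound (CV of the per-cell ratio of two
channels reporting an obligate heterodimer — biology cancels, measurement
noise remains), peak-channel skew on log-spaced bins, the law-of-total-
variance CV of mixtures, computational unmixing (CV of the remainder
after subtracting a scaled reference density), and Welch t-tests on
replicate CVs.

**Reporter quantification.** Dual-fluorescence (eGFP/mCherry) reporter
analysis: double-positive gating, orthogonal (total-least-squares)
regression slope as the relative eGFP level, normalization to the empty
vector, and the de-repression ratio between microRNA-deficient and
control cells.

**Synthetic data.** Log-normal event generators for every input above —
single populations, heterodimer channel pairs, labelled mixtures, and
dual-reporter events — parameterized by true mean and CV and fully
seed-deterministic.

See `docs/methods.md` for models, parameters and numerical choices.

## Worked example

```python
from mirffl import calibrate_cd69_model, run_scenario, compare_ffl_effect

params = calibrate_cd69_model()
print(f"k_tx_target={params.k_tx_target:.3f}  k_tx_mir_leak={params.k_tx_mir_leak:.3f}  "
      f"k_tx_mir_base={params.k_tx_mir_base:.3f}")

with_ffl = run_scenario(params, "activated_with_FFL", n_runs=2000, seed=1)
without = run_scenario(params, "activated_without_FFL", n_runs=2000, seed=2)
print(f"with FFL:    mean={with_ffl.protein_mean:.0f}  CV={with_ffl.protein_cv:.1f}%")
print(f"without FFL: mean={without.protein_mean:.0f}  CV={without.protein_cv:.1f}%")

comp = compare_ffl_effect(with_ffl, without, n_boot=5000, seed=0)
print(f"dCV={comp.delta_cv:.2f} points, bootstrap p={comp.p_cv:.1g}, Welch p(mean)={comp.p_mean:.1g}")
```

prints

```
k_tx_target=0.072  k_tx_mir_leak=0.054  k_tx_mir_base=0.396
with FFL:    mean=880  CV=22.2%
without FFL: mean=1278  CV=24.7%
dCV=-2.52 points, bootstrap p=0.0004, Welch p(mean)=0
```

Reading this: calibration turns the copy-number targets into transcription
rates (0.072 for the target mRNA; a constitutive microRNA leak of 0.054
plus a TF-activated component of 0.396). Letting the microRNA arm respond
to activation lowers the mean protein level (880 vs 1278 copies — the
repression ratio set by Hill repression at 42 vs 9 microRNA copies) *and*
narrows the distribution across cells (CV 22.2% vs 24.7%), the signature
of noise buffering by an incoherent FFL; both differences are highly
significant. The absolute CVs sit on a ~20% floor of intrinsic noise from
the ~6-copy target mRNA, which the FFL cannot cancel — see
`docs/methods.md` for the decomposition.

The same analyses are scriptable from the shell:

```sh
mirffl ffl --out runs/ffl --seed 1 --n-runs 2000
mirffl noise --out runs/noise --seed 1
mirffl reporter --out runs/reporter --seed 1
mirffl copies freqs.csv --anchor miR-181a --anchor-copies 400 800
```

Each run writes delimited tables and JSON summaries carrying the config
hash, seed and package version; reruns are byte-identical.

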