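# phosdyn

Analysis pipeline for time-resolved phosphoproteomics of kinase
activation — built around the WEE1-inhibition setting, where releasing
CDK1/CDK2 from inhibitory phosphorylation activates their substrates
over minutes. The package takes complete phosphopeptide and protein
abundance matrices (TSV), a proteome (FASTA) with per-residue disorder
scores, and a kinase–substrate annotation table, and produces
normalized abundances, per-time-point differential calls, kinase
activity profiles, kinetic substrate classes, and sequence-based
kinase–substrate predictions. A synthetic-data generator with planted
ground truth stands in for the mass-spectrometry data, so every stage
is testable end to end.

The core computations:

- **Normalization** — sample-loading scaling `SF_i = ĀS / AS_i`
  equalizes column sums; artificial internal reference standards
  (ARS) equalize each feature's within-replicate totals,
  `ARSSF_{i,j} = ĀRS_j / ARS_{i,j}`, removing replicate batch
  effects; phospho profiles are corrected for total protein change.
- **Differential testing** — empirical-Bayes moderated t per time
  point vs t = 0 (`s̃² = (d0·s0² + d·s²)/(d0+d)`; validated against R
  limma to 1e-9), BH-FDR per contrast.
- **Kinase activity** — Stouffer combination of peptide-wise z-scores
  over a kinase's annotated substrates, `RKA_k = Σ S_i / √n`, with
  per-condition means from a linear model and a 1% normal-quantile
  significance threshold (2.3263).
- **Dynamics** — fuzzy c-means (8 clusters, fuzzifier 2) on regulated
  sites' scaled profiles; Michaelis–Menten fits `y = Vm·x/(K+x)`
  label the increasing clusters "fast" (smallest half-time K) and
  "slow" (largest).
- **PSSM prediction** — 21×20 binomial log-odds matrices
  `RS = −log10[P(k ≥ K_a)/P(k ≤ K_a)]` over ±10 flanks with a
  disorder-filtered background (disorder > 0.4), logistic calibration
  on balanced 80/20 splits, ROC/Youden probability cutoffs.
- **Empirical CDK calling** — PSSM probability ∧ fast/slow cluster ∧
  significant up-regulation, with bootstrap motif-composition
  comparison and Cy-motif ([R/K]-x-[L/V/I]) spacing analysis between
  the fast and slow classes.

See `docs/methods.md` for models, assumptions and parameter choices.

## Worked example

Simulate the default scenario and run the full pipeline:

```sh
phosdyn simulate --seed 1 --outdir results/simdata
phosdyn run --indir results/simdata --outdir results/run --seed 1
```

or run the numbered stage drivers under `analysis/`
(`python analysis/01_simulate.py` … `08_motif_comparison.py`), which
print what each stage found. With seed 1:

```
t = 20 min:  177 up,  361 down (FDR < 5%)
t = 90 min:  204 up,  682 down (FDR < 5%)
 CDK1: shift at 90 min = +25.79 +/- 0.25 (significant)
 PKAC: shift at 90 min = -6.78 +/- 0.89 (ns)
 fast: cluster_2 (K = 10.2 min, Vm = 2.81, 107 sites)
 slow: cluster_8 (K = 82.2 min, Vm = 4.93, 99 sites)
 CDK1: 100 training sites, test AUC 0.989, strongest preference P at +1
theoretical CDK sites: 348
empirical CDK sites:   193
recovery vs planted truth: sensitivity 0.960, precision 0.995
```

Reading: of 2,260 simulated sites, the ~200 planted CDK substrates
are called significantly up-regulated; the planted kinases' activity
shifts clear the 1% threshold while the flat-substrate control does
not; the two activation-kinetics classes are recovered as distinct
clusters with half-times bracketing the planted 10/60 min; the PSSM
rediscovers the planted S/T-P-x-K consensus; and the combined
empirical filter recovers 96% of planted substrates at ~0.5% decoy
contamination. `results/run/report.md` summarizes a run, including
recovery against the truth table when present.

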