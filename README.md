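# dynstates

Dynamic functional-connectivity (dFC) state analysis for network component
time courses, with a synthetic multi-subject generator that plants known
connectivity states so every stage of the pipeline can be validated against
ground truth.

## What it does

Resting-state fMRI studies of the triple-network model (default mode,
central executive, and salience networks) increasingly ask not just *how
strongly* networks are coupled on average, but *how coupling reconfigures
over time*. The standard analysis takes five network time courses per
subject (aDMN, pDMN, LCEN, RCEN, SN, from group ICA), slides a tapered
window along the scan, estimates a connectivity matrix per window, clusters
all windows from all subjects into a small number of recurring **FC
states**, and compares groups on how subjects move through those states.

`dynstates` implements that pipeline end to end:

1. **Post-processing** (`dynstates.prep`) — discard equilibration volumes,
   remove polynomial trends (orders 1–3), regress six realignment
   parameters and their temporal derivatives, repair outliers flagged by a
   median-absolute-deviation rule with a cubic-spline fit through the clean
   samples, and low-pass filter at 0.15 Hz (zero-phase Butterworth).
   Spectral QC metrics (low-frequency power ratio, dynamic range) are
   provided for component selection.
2. **Windowed connectivity** (`dynstates.dfc`) — a tapered window
   (rectangle of width *W* = 30 TRs convolved with a Gaussian, σ = 3 TRs)
   slides in steps of 1 TR, giving ⌊(T−W)/step⌋ windows (140 windows for
   170 retained volumes). Per window, the covariance is estimated from an
   L1-penalized precision matrix (graphical LASSO), standardized to
   correlation, and Fisher r-to-z transformed:
   *z* = arctanh(*r*). Window-level z values are residualized across
   subjects against age and sex.
3. **State clustering** (`dynstates.clustering`) — k-means under the
   correlation distance d(a,b) = 1 − Pearson(a,b), 500 random restarts on
   the pooled windows, final centroids as element-wise medians of the
   assigned windows; the number of states is selected by an elbow
   criterion on a within/between cluster validity index.
4. **Temporal properties** (`dynstates.metrics`) — per subject:
   fractional windows per state (%), mean dwell time (windows), and the
   number of state transitions.
5. **Group statistics** (`dynstates.stats`) — Mann–Whitney U tests (nine-
   test Benjamini–Hochberg FDR family: 4 fractions + 4 dwells +
   transitions), two-sample t-tests of FC strength on subject state
   centroids, chi-square for the sex ratio, and partial correlations
   between state metrics and clinical scores (SDMT, TMT-A) controlling for
   age, sex, and education.
6. **Synthetic cohorts** (`dynstates.synthetic`) — two groups of subjects
   whose five-channel time courses follow hidden-Markov covariance states
   with group-specific transition kernels, plus demographic covariates,
   metric-linked clinical scores, and injected nuisance (trends, motion
   leakage, spikes). The hidden sequences and their exact temporal metrics
   are emitted as ground truth.

## Worked example

```python
from dynstates import CohortConfig, generate_cohort, analyze_cohort

cfg = CohortConfig(n_patients=10, n_controls=10, seed=0)
subjects, truth = generate_cohort(cfg)
result = analyze_cohort(subjects, k=4, n_replicates=30, seed=0)

print("windows per subject:", result.n_windows)
print("occupancy (% of all windows):", result.occupancy_pct.round(1))
print(result.temporal_stats[["metric", "state", "z", "p_raw", "p_fdr"]]
      .to_string(index=False))
```

Output from this exact run:

```
windows per subject: 140
occupancy (% of all windows): [37.5 21.9 20.9 19.7]
            metric   state         z    p_raw    p_fdr
fractional_windows       1  2.122996 0.037062 0.055592
fractional_windows       2 -2.139823 0.035712 0.055592
fractional_windows       3 -3.329990 0.001001 0.003986
fractional_windows       4 -0.554769 0.606453 0.606453
   mean_dwell_time       1  2.427199 0.016882 0.037984
   mean_dwell_time       2 -2.021780 0.047464 0.061025
   mean_dwell_time       3 -3.249361 0.001329 0.003986
   mean_dwell_time       4 -0.554769 0.606453 0.606453
     n_transitions overall -3.369434 0.000865 0.003986
```

The 170 retained volumes yield 140 sliding windows; state 1 (the state the
patient kernel is biased toward) holds the largest share of windows.
Positive z means patients rank higher: patients spend more windows in
state 1 and dwell there longer, and switch states less often than controls
(negative z for transitions). At this small n = 10/group, the state-1
dwell and transitions effects already survive FDR while the state-1
fraction misses narrowly (p_fdr = 0.056); all three are strongly
significant at the study's design sample sizes (see
`scripts/acceptance.py`). A YAML-driven
command line covers the same flow (`dynstates simulate`, `dynstates run
--config study.yaml --out out/`), writing TSV tables, a JSON/Markdown
report, and a reproducibility manifest.

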