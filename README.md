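# hoplandscape

Analysis toolkit for **transposon-hopping reporter experiments**: mapping
where a Sleeping Beauty (SB) reporter cassette re-integrated across a locus,
and inferring from sorted cell pools how strongly each genomic position
activates the reporter.

The experimental design it serves: an SB cassette carrying a promoter-driven
fluorescent reporter is mobilized from a launch pad, cells are FACS-sorted
into expression gates (P1 high … P6 low), and the ITR–genome junctions of
each sorted pool are sequenced by tagmentation. Every mapped integration is
then a (position → expression gate) observation, and pooling thousands of
them yields a positional **activation landscape** of the locus — here
modelled on the *Sox2* region and its distal enhancer cluster (SCR).

## What the package computes

- **Integration calling** (`hoplandscape.calling`): junction reads →
  integrations per pool (mapq ≥ 10; ≥ 2 unique reads for sorted pools,
  dual-ITR support for the top gate, ≥ 1 read for large unsorted pools;
  contaminant-coordinate blacklist with an exemption for the origin launch
  pad), and clone genotyping (≥ 10 unique reads, strict <20%-of-top rule;
  one dual-ITR site → insertion, two single-ITR sites → hopping-induced
  deletion with its interval).
- **Expression landscape** (`hoplandscape.landscape`): the sort-fraction
  weighted windowed score with bootstrap confidence intervals,

  ```
  Fsort_P,E = ((R_P + 1) / T) / S_P × (m / r_P)
  score_W   = Σ_E Σ_P Fsort_P,E · N_W,P,E · Fluo_P,E
            / Σ_E Σ_P Fsort_P,E · N_W,P,E
  ```

  where `R_P`/`T` are recorded-cell counts, `S_P` sorted cells, `m/r_P` a
  replicate-imbalance factor, `Fluo_P,E` the median gate fluorescence and
  `N_W,P,E` integrations of gate P, experiment E in window W. Windows are
  `window_bins` step-bins (default 5 kb windows, 500 bp steps), masked below
  3 integrations; CIs are 2.5–97.5 percentiles over 5000 bootstrap
  resamples of the integration list. Deletion cell lines are handled by
  shifting coordinates across the deletion before scoring and back after.
- **Flow normalization** (`hoplandscape.flow`): spillover correction (1.6%
  mTurq→GFP), autofluorescence subtraction, eGFP normalization, same-day
  reference scaling, per-cell relative expression, 99th-percentile
  negative/positive thresholds, and bimodal expression-mode detection.
- **RNA kinetics** (`hoplandscape.kinetics`): one-phase decay fits
  (`Y0·exp(−kt)`, half-life ln 2/k) from actinomycin-D Ct time courses, and
  reporter RNA level relative to the endogenous alleles by ΔCt with a
  1.96 × sd interval.
- **Contact maps** (`hoplandscape.contacts`): virtual 4C profiles,
  insulation scores (log2 ratio to the region mean, 20-bin window), and
  Spearman correlation of the expression score with contact frequency and
  genomic distance (≥ 3 integrations per bin).
- **Synthetic data** (`hoplandscape.synthetic`): a generative model of the
  whole experiment — Laplace reintegration kernel around the launch pad,
  non-mobilized and in-trans fractions, log-normal fluorescence noise,
  capped gate sorting, truncated negative-binomial junction-read counts
  with contaminants, decay Ct tables and TAD-structured contact matrices —
  used for validation with known ground truth.

## Worked example

`python examples/01_simulate_and_score.py` simulates the default scenario
(two activation peaks inside a sharply bounded 400 kb permissive domain,
two replicates, six gates, ~5000 retained integrations) and recovers the
landscape:

```
junction reads simulated:   47612
integrations called:        5506
windows scored (unmasked):  791 of 791
Spearman rho vs truth:      0.988
top-scoring window:         chr3:34752500-34757500 (score 6474, 95% CI 6253-6592)
true enhancer peak center:  chr3:34757000
```

The score track ranks windows almost exactly like the hidden landscape
(ρ = 0.988) and the top-scoring 5 kb window lands on the planted enhancer
peak. The other examples cover clone genotyping, the flow-normalization
chain (recovering a planted 3-fold reporter difference as `mTurq_rel ≈
3.03`), decay fitting (a true 3.5 h half-life recovered as 3.44 h), and the
contact correlation (ρ_contact = +0.99 versus ρ_distance = −0.75 for a
contact-driven landscape).

A thin CLI wraps the same functions:

```bash
hoplandscape run --seed 1 --outdir out          # simulate → call → score
hoplandscape call-integrations --reads reads.tsv --mode clone
hoplandscape score --integrations ints.tsv --populations pops.tsv \
    --region chr3:34550001-34950000 --bootstrap 5000 --seed 1
```

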