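# Methods

## The estimation problem

A cut-and-paste transposon carrying a fluorescent reporter is mobilized from
a launch pad and re-integrates, mostly locally. Cells are sorted into
fluorescence gates and the ITR–genome junctions of each sorted pool are
sequenced. Each mapped integration is one observation linking a genomic
position to an expression gate. The quantity of interest is the positional
activation landscape: the expected reporter expression as a function of
integration position.

Two sampling distortions stand between the raw data and that landscape:

1. **Unequal gate representation.** Gates hold very different fractions of
   the population, and only up to a fixed cap of cells per gate is sorted.
   A mapped integration from a rare bright gate therefore represents far
   fewer cells of the original population than one from a crowded dim gate.
2. **Replicate imbalance.** When one gate was sorted in more replicate
   experiments than another, its integrations are over-represented.

The sort-fraction correction addresses both:

    Fsort_P,E = ((R_P + 1) / T) / S_P * (m / r_P)

with R_P recorded cells in gate P, T total recorded cells, S_P sorted
cells, r_P the number of replicates for that population and m the minimum
across populations. The +1 pseudo-count keeps gates that were too rare to
appear in the FACS recording usable. Fsort is the fraction of the original
population represented by each sorted integration; the formula is applied
with the pseudo-count always active (not only at R_P = 0), which is what
the expression implies.

The windowed expression score is the Fsort-weighted mean of gate
fluorescence estimates over the integrations in a window, summed over gates
and experiments. Because weights enter both numerator and denominator, a
common rescaling of all Fsort values cancels; per-window the score is a
ratio estimator bounded by the smallest and largest contributing gate
fluorescence. Fluo and Fsort stay per-experiment throughout — replicates
are pooled only inside the sums, never by averaging their inputs.

**Windowing.** Integrations are counted in step-bins (half-open, 0-based
internally); a window is `window_bins` consecutive bins sliding one bin at
a time. Defaults are 500 bp bins and 10-bin (5 kb) windows, suited to a
~5000-integration experiment over a few hundred kb; window and step should
be chosen by integration density. Windows with fewer than 3 sorted
integrations are masked.

**Bootstrap.** The integration list is resampled with replacement as one
genome-wide list (labels travel with each integration), the track is
recomputed per resample, and the 2.5th/50th/97.5th percentiles (linear
interpolation) are reported per window. Masking always uses observed, not
resampled, counts. The full 5000-resample default runs in seconds because
resampling reduces to a bincount plus two sliding sums.

**Deletion cell lines.** For a line carrying a known deletion, integration
coordinates beyond the deletion are shifted left by its width before
binning and the windows are shifted back afterwards, so windows never
straddle a gap of missing sequence. Integrations inside the deletion are a
data inconsistency and abort the run.

## Integration calling

Junction reads need mapping quality ≥ 10. Reads are grouped by (chrom,
position, orientation, pool, replicate); the unique-read count of a group is
its number of distinct fragment ends, since tagmentation duplicates share
fragment ends — the deduplication key is a package convention, chosen
because no finer-grained definition is available in the data model.
Retention rules: sorted pools ≥ 2 unique reads; the top expression gate
additionally needs ≥ 1 read from each ITR side (a cassette that lost its
partner ITR usually marks a deletion, not a bright integration); large
unsorted pools keep single-read integrations. Known contaminant coordinates
(carry-over from earlier experiments, plus launch-pad positions) are removed
by exact interval containment, except the launch pad the reporter was
actually mobilized from. Identical integrations appearing in several pools
are kept as separate data points: they were independently sorted.

Clonal libraries are genotyped more stringently: candidate locations need
≥ 10 unique reads, and candidates below 20% (strictly) of the top
candidate's count are discarded as index-swap or off-target artifacts.
Exactly one dual-ITR candidate is a confident insertion; exactly two
single-ITR candidates, one per side on one chromosome, are a
hopping-induced deletion whose interval spans the two junction positions
(width in 1-based inclusive arithmetic; the junctions themselves are the
endpoints). Everything else — extra locations, same-side pairs,
cross-chromosome pairs, coincident endpoints — is returned for manual
review with a machine-readable reason; there is no automatic rescue.
Candidate grouping ignores orientation because the two ITR junctions of one
insertion map in opposite orientations.

## Flow normalization

The chain is: (1) subtract 1.6% of the mTurq signal from the eGFP channel
(spectral spillover); (2) subtract the median fluorescence (MFI) of a
non-fluorescent control line per channel; (3) divide mCherry and mTurq by
the same sample's corrected eGFP — the untouched allele acts as a same-cell
control for global expression effects; (4) divide by the same quantities of
a standard reporter line measured the same day. Step 3 is skipped for the
"not normalized" variant. Negative corrected intensities are legitimate
background-subtraction artifacts; only non-positive corrected eGFP aborts
(per-sample as an error, per-cell by dropping the cell with a logged
count). Borrowing a wild-type control from another day is supported only
through an explicit context flag. Per-cell relative expression uses only
the middle gates (default P2–P4): the extreme gates are dominated by
non-mobilized reporters.

Negative/positive classification thresholds are the 99th percentile of the
wild-type control (linear-interpolation percentile) and 1.5 times it.
Bimodal clones are summarized by their dominant expression mode: intensities
are display-transformed with arcsinh(x/150) — a biexponential-family
transform standing in for instrument logicle display, the cofactor
configurable — a Gaussian KDE with Silverman bandwidth is evaluated on a
512-point grid, local maxima are found by discrete sign change, the two
highest-density peaks are kept and the one at the higher transformed value
is returned, back-transformed. Mode values are therefore
transform-dependent at the margin; tests tolerate 10%.

## RNA kinetics

Technical triplicates are averaged on the Ct scale; ΔCt against the t = 0
sample gives relative abundance 2^(−ΔCt) (exactly 1 at t = 0; triplicate
variance is not propagated). A one-phase decay Y0·exp(−kt) is fit by
unweighted nonlinear least squares on the abundance scale, per replicate,
seeded with Y0 = first abundance and k from the log-linear slope. Half-life
is ln 2/k; a fitted decay of less than 10⁻⁶ over the observed span is
reported as k = 0 with the half-life undefined. Reporter level relative to
the endogenous alleles: per replicate ΔCt = ((Ct_T − Ct_G) + (Ct_T −
Ct_C))/2, level = 2^(−mean), interval = 2^(−(mean ± 1.96 sd)); the qPCR
targets are assumed near-100% efficient.

## Contact maps

Virtual 4C: mean contact of each bin with the viewpoint bins; the diagonal
and viewpoint self-contacts are excluded, and missing (NaN) entries are
absent from means, not zero. Insulation: mean contact between the w bins
upstream and w bins downstream of each bin (default w = 20 at 1 kb),
log2-normalized to the mean over defined bins of the analyzed region —
region-mean normalization matches the region-capture setting where no
chromosome-wide background exists. Bins within w of an edge are undefined.
The two bins flanking a block boundary tie exactly in symmetric matrices;
boundary assertions accept either. Correlation with the expression score
uses bin-level scores (window of one bin on the matrix grid), keeps bins
with ≥ 3 integrations and a defined profile value, and reports Spearman rho
(average ranks; large-sample p-values, labelled approximate) against
contact and against center-to-center distance from the viewpoint.

## The synthetic generative model

The simulator produces every input the analysis consumes, with known ground
truth, and defines the conditions under which the pipeline is validated:

- **Landscape**: baseline_outside outside a sharply bounded permissive
  domain; inside, baseline_inside plus peaks decaying as
  `A·exp(−|x−c|/w)`. The Laplace peak shape (sharp apex, heavy tails) makes
  activation fall off continuously with distance from an enhancer, which is
  both what real landscapes look like and what a rank-correlation
  validation requires — an exactly flat stretch has no rank signal to
  recover.
- **Hopping**: symmetric Laplace reintegration kernel (scale 200 kb,
  truncated to the simulated region by inverse-CDF sampling), 33%
  non-mobilized cassettes staying at the launch pad, 28% of mobilized
  cassettes leaving the region entirely (dropped, counted), orientation
  Bernoulli(0.5). The kernel scale is a free modelling parameter, not an
  estimate: only the 1–2 Mb order of magnitude of local hopping is
  constrained.
- **Fluorescence**: multiplicative log-normal per-cell noise (default
  log-sd 0.25); flow intensities are log-distributed and gates are drawn on
  log axes.
- **Sorting**: six log-spaced gates, half-open intervals jointly covering
  the range, at most 2000 cells sorted per gate; a configurable fraction of
  the stream is "recorded" for the accounting numbers R_P and T.
- **Reads**: unique-read counts per sorted integration are negative
  binomial (mean 3, dispersion 0.6) truncated at ≥ 1; each read gets an ITR
  side, a mapping quality from a categorical mixture (25% below 30,
  including 10% below the filter threshold), and a fragment end 30–500 bp
  from the junction. Contaminant positions are injected at 1–2 reads across
  pools. Sparser read regimes (most integrations single-read, as in
  non-exhaustive mapping) are reachable by lowering `mean_reads`.
- **Decay and contacts**: Ct tables follow Ct(t) = Ct₀ + kt/ln 2 plus
  Gaussian noise per technical measurement; contact matrices follow
  |i−j|^(−α) with block (TAD) and focal-pair multipliers, optional
  symmetric log-normal jitter, and the diagonal set to the per-row
  off-diagonal maximum (it is excluded downstream anyway).

**Default scenario.** A 1.6 Mb region with a 400 kb permissive domain
(chr3:34.55–34.95 Mb in the coordinate frame of the modelled locus), a
strong enhancer-cluster peak (amplitude 8000, tail scale 30 kb) and a
weaker promoter-proximal peak (2500, 15 kb), launch pad inside the domain,
8000 cells per replicate and two replicates — sized to yield roughly 5000
retained integrations after the read-support filter. The scored region is
the permissive domain itself, mirroring the practice of scoring the densely
covered region of interest. Under these conditions the recovered track
reaches Spearman ρ ≈ 0.97–0.99 against the truth with the top window on
the planted peak.

All simulator randomness flows from the explicit seed of each call, so a
config plus a seed reproduces every artifact byte for byte; the pipeline
fans one run seed out into deterministic per-stage child seeds.

## What passing tests do and do not show

The generator reproduces the statistical structure the analysis assumes —
local reintegration, gate quantization, capped sorting, overdispersed read
support, contamination — but real data add layers it does not model:
base-level sequencing error, PCR duplication mechanics, mapping artifacts
beyond a quality score, cell-cycle and silencing dynamics (bimodal
expression arises here only as an explicit mixture), and allele-specific
effects. Recovery results on synthetic data therefore validate the
estimator and its implementation, not the biology of any particular locus.

## Numerical conventions and edge cases

Median: midpoint of the central order statistics; percentiles: linear
interpolation — both fixed everywhere. Score windows report [first bin
start, last bin end), 0-based half-open internally, 1-based only at I/O
boundaries. Weights cancel exactly in algebra but not in floating point:
"exact" identities hold to ~10⁻¹² relative. Populations with zero sorted
cells are dropped with a warning (no integration can reference them);
empty gates raise when a fluorescence estimate is requested. The bootstrap
leaves all-NaN windows masked rather than erroring. Insulation requires
more than twice the window in bins.

## Known limitations

Uniqueness of mapping reads is operationalized by fragment end; if a real
pipeline defines duplicates differently, unique-read counts shift at the
margin of the ≥ 2 filter. The ≥ 2-unique-read pool filter counts uniqueness
jointly across ITR sides. Index-swap rescue is deliberately manual (review
verdict), so recall on clones with minor cross-contamination is lower than
an automated rescue would give. The expression score estimates a
gate-quantized, sort-weighted mean, so between-gate resolution is limited
by the gate layout; confidence intervals quantify sampling, not gate
quantization. FCS parsing, matrix balancing, read alignment and
allele-phasing are out of scope: the package consumes tables and binned
matrices.
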