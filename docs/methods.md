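# Methods

## Scoring model

The analysis treats every well's reporter ratio `x = R1/R2` as the basic
observation; R2 (constitutive renilla) absorbs cell-number and viability
variation, so multiplicative perturbations of cell number cancel in the
ratio.  Scoring is per plate replicate:

1. **Median normalization.** All ratios on a plate are divided by the
   median of that plate's *sample* wells, so plate-to-plate sensitivity
   differences (reagent lots, reader drift, week effects) drop out.  The
   output sample median is exactly 1 by construction.  Controls are
   divided by the same sample median, never by their own.
2. **Log transform (secondary tier only).** Screen ratios are closer to
   lognormal; the secondary tier scores `log2` of the normalized ratio,
   where replicate distributions are more nearly Gaussian.  The primary
   tier scores unlogged normalized ratios.
3. **Robust z.** `z = (x − median) / (1.4826·MAD)`, center and scale
   estimated on the sample wells of the plate replicate and applied to
   controls as well.  The 1.4826 factor makes the MAD a consistent
   estimator of the normal σ.  The estimation window is per plate: for
   the primary tier the four replicate wells of a SMARTpool share one
   plate, so they share one center/scale; for the secondary tier each
   weekly plate copy is standardized separately.
4. **Aggregation.** Primary: gene score = mean of the four well z-scores.
   Secondary: per-siRNA z = mean over the three week replicates, gene
   score = median of the six per-siRNA z (even count: mean of the 3rd and
   4th order statistics).  The median over six independent sequences is
   the off-target defence — at most two aberrant sequences leave it
   essentially unmoved.

Degenerate inputs: a well with R2 = 0 is flagged and excluded (its pool
can still be scored from the remaining wells, minimum two); a plate needs
at least 8 finite sample ratios and a positive sample median; if the MAD
is zero but values vary, the sample standard deviation is used with a
warning; a perfectly constant plate scores all-zero with a warning rather
than erroring, since "no variation" genuinely means "no evidence of
effect" and it keeps noise-free simulations scorable.  These choices are
the package's own; the scoring literature does not pin them down.

## Hit calling

Primary thresholds are inclusive (score ≤ −1.5 / ≥ +2.8), matching the
way the selection rule is stated; `strict_boundaries=True` switches to
the strict inequalities used by the public deposit's activity bins (the
two differ only for scores exactly at a cutpoint — the package reports
both behaviours rather than silently picking one).  Activity scores are
the deposit's 0/25/50/75/100 binning by strictly exceeding per-tier
cutpoints (primary: ±1, 2.8/−1.5, 4/−2, 5/−2.5; secondary: 1/−0.75,
1.5/−1, 2/−1.5, 2.5/−2); outcome is 2 ("active") iff the score is ≥ 50,
the bin whose boundaries equal the hit thresholds — "active" is not
otherwise defined, so this is a configurable package choice.  Controls
are fixed at score 0, outcome 4.

The expression filter uses the strict rule p < 0.1 in at least one of
the two conditions; probe-level tables are collapsed to genes by minimum
detection p per condition (the most permissive evidence of expression)
and maximum log2 signal.  Genes absent from the expression table keep
their call but are flagged `unmeasured_expression` — dropping them would
silently discard hits for a data-coverage reason.

Secondary candidate selection is rank-based (n lowest / n highest gene
medians after exclusions, defaults 26/13) because the underlying z
cutoffs behind those counts are not published; ties at the cut break by
the number of individual siRNAs beyond the tier threshold, then by gene
symbol, so selection is deterministic.  The shipped canonical-pathway
exclusion default (TLR4, LY96, CD14, MYD88, TIRAP, IRAK1, IKBKG, MAP3K7)
is a convenience; real analyses should supply their own lists — the
complete lists are not public and hard-coding a guess would fake
fidelity.

Tertiary confirmation uses strict fractional-effect cuts: F < 0.70
(>30% reduction) or F > 1.25 (>25% increase) for at least one non-LPS
stimulus, with replicate wells averaged before division by the matched
NTC readout.

## Plate QC

The four gates (≥5-fold induction, ≥85% renilla knockdown, ≥85% siTLR4
reduction, no renilla saturation) use arithmetic means over control wells
(median available by flag; with at-least-three control wells per class
the difference is minor).  The saturation limit defaults to 2^21 − 1
counts and is configurable — it is an instrument property, not part of
the method.

The uniformity test partitions each LPS dose's wells into four positional
groups and computes `max pairwise |group-mean difference| / mean of the
four group means × 100`, failing a dose at ≥20%.  The default grouping
is contiguous column blocks — with the repeating 2-column H/M/L pattern
these are exactly the four repeats of the pattern across the plate, which
is the partition with power against left-to-right gradients.  Quadrant
grouping is available (`grouping="quadrant"`) but is provably blind to
linear column gradients of realistic size: a gradient spanning g
multiplicatively moves column-half means by only ~g/2, so a 30–35%
gradient stays under the 20% fail line.  This is why column blocks are
the default.

Replicate CV (primary) is the sample standard deviation over mean of the
four raw replicate ratios per SMARTpool; replicate correlation
(secondary) is Pearson on per-plate median-normalized log2 values by
default, raw-ratio correlation by flag.

## Synthetic screens

The generator emits the real layouts: primary plates with samples in
columns 2–9/12–23, controls in 10/11/24, column 1 empty, four consecutive
replicate wells per SMARTpool (80 pools/plate); secondary plates with the
outer two rows/columns empty, controls in columns 11–13/22, six siRNAs
per gene in separate plate regions (32 genes/plate), three weekly
replicate copies; three uniformity plates with the staggered 2-column
H/M/L dose pattern (plate 1 starts H, plate 2 M, plate 3 L).

Signal model (all multiplicative):

* `R2 = baseline · viability · plate_factor · edge · (knockdown residual
  for siRenilla wells)`, viability lognormal with CV
  `viability_cv`;
* `R1 = R2 · basal_ratio · induction^stimulated · effect · noise · edge`,
  noise lognormal with CV `noise_cv`.

Because R1 is built on R2, viability and plate factors cancel exactly in
the ratio.  The edge factor is deliberately applied once more to R1 than
to R2, modelling positional artifacts that act on stimulation efficiency
(evaporation, temperature) and not only on cell number: an artifact
confined to cell number would cancel in the ratio and be undetectable by
any ratio-based QC, which would make the uniformity assay pointless.  The
edge model is a linear column gradient spanning `edge_gradient`
multiplicatively (off by default).

Defaults and their anchors: `induction_fold=10` (10 ng/ml LPS gives
roughly an order of magnitude induction, comfortably above the 5-fold
gate); `noise_cv=0.15` (the primary screen's replicate CV scale, ≈0.145);
`renilla_kd_effect=0.05` (≈95% knockdown, matching the reported screen
averages of 96–97%); `tlr4_effect=0.12` (88% reduction — a residual of
0.15 would sit exactly on the 85% gate and make half of all simulated
plates fail by noise alone, so the default leaves the same margin the
real control evidently had); positive/negative regulator effects
U(0.1, 0.6) and U(1.8, 4) on the induced ratio; `frac_pos=0.02`,
`frac_neg=0.013` (the ≈2%/1.3% primary hit rates of a genome-wide
screen); secondary per-siRNA efficacy U(0.6, 1.0) and off-target rate
0.05 per siRNA, with off-target effect sizes drawn from the same
distributions as true effects but attached to a single sequence.
Readouts are emitted as floating-point counts (not integer-rounded) so
that the viability component cancels exactly in the ratio and noise-free
configurations score exactly zero.

Truth tables record each gene's class and effect, each siRNA's efficacy
and off-target multiplier, and each plate's factor, keyed so that every
emitted sample siRNA has exactly one truth row.  Generation is a pure
function of (config, seed); identical inputs give byte-identical CSVs.

What the generator does **not** emulate: nucleotide-level siRNA/seed
sequences (off-target effects are planted at effect level), spatially
correlated cell-seeding artifacts other than the column gradient,
saturating detector response, batch drift within a week, or probe-level
microarray structure (the expression generator draws gene-level detection
p-values directly).  Passing tests on synthetic screens therefore
demonstrate the correctness and calibration of the *analysis* under the
stated noise model, not robustness to every failure mode of real plates.

## Problem sizes used in tests

The shipped test and acceptance runs use screens of 80–480 genes (one to
six plates), 100 seeds for null calibration, 25 seeds for recovery and
off-target rejection, and 200 seeds for the uniformity operating
characteristics — sizes chosen so the full suite completes in well under
a minute of simulation while the binomial margins on every asserted rate
remain decisive (e.g. 16 000 null gene scores against a <1% tail bound).

## Known limitations

* The reader accepts the long (one row per well) and wide (Rep1–3
  columns) deposit dialects but writes only the long dialect.
* Plate counts and layouts are data-driven, never asserted: partially
  filled daughter plates are representable (empty wells are explicit
  records, so layout checks can fire on them).
* Deposit validation compares recomputed and deposited z-scores by
  correlation and reports which centering variant (sample wells vs all
  wells) matches better; it does not attempt to reverse-engineer
  undocumented preprocessing beyond that.
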