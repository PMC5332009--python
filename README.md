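# sirnascreen

Tiered analysis of genome-wide dual-luciferase siRNA screens of
inflammatory signalling — plate QC, reporter-ratio normalization, robust
z-scoring, multi-siRNA hit validation, expression filtering, multi-ligand
confirmation and deposit-schema export — together with a synthetic-screen
generator that plants known regulator effects so every stage can be
verified without any external data.

## The problem

Genome-wide RNAi screens knock down each gene in turn and read out a
pathway reporter; here the readout is a dual-luciferase assay in
macrophage-like cells, with firefly luciferase (R1) driven by the *TNF*
promoter reporting LPS-induced TLR4-pathway activation and renilla
luciferase (R2) driven by the constitutive *UBC* promoter reporting cell
number and viability.  The ratio R1/R2 is a viability-corrected measure of
the TNF transcriptional response.  The analysis problem is to turn
hundreds of 384-well plates of (R1, R2) counts into a ranked, validated
list of pathway regulators while defending against the two dominant error
sources of such screens: positional/plate artifacts and siRNA off-target
effects.

## The method

For each plate, sample-well ratios are normalized to the intra-plate
median and standardized with the robust z-score

```
z_i = (x_i − median(x)) / (1.4826 · MAD(x)),   MAD(x) = median(|x − median(x)|)
```

with center and scale estimated on sample wells and applied to controls
too.  The **primary tier** runs each siRNA SMARTpool in four replicate
wells of one plate; the gene score is the mean of the four well z-scores,
and hits are called at score ≤ −1.5 (positive regulators: knockdown
lowers the TNF response) or ≥ +2.8 (negative regulators).  The
**secondary tier** retests candidates with six independent siRNAs per
gene across three weekly plate replicates, scoring on log2-transformed
normalized ratios; each siRNA's z is averaged over replicates and the
gene score is the **median of the six per-siRNA z-scores**, so a
phenotype carried by a single (off-target) sequence cannot move the gene
score far.  Candidates must also be detectably expressed in the assay
cells (microarray detection p < 0.1 in at least one of the ±LPS
conditions).  The **tertiary tier** measures the fractional effect
F = readout/NTC per TLR ligand (LPS, P3C, PGN, R848, P2C, FLG, plus a
mycobacterial extract) and confirms a candidate when F < 0.70 (>30%
reduction) or F > 1.25 (>25% increase) for at least one non-LPS stimulus.

Each plate must pass four acceptance gates (≥5-fold LPS induction of NTC
wells, ≥85% renilla knockdown by siRenilla, ≥85% reporter reduction by
siTLR4, no renilla saturation), and dedicated uniformity plates with a
staggered high/medium/low LPS dose pattern detect edge effects (a dose
fails when the maximal difference between four positional group means
exceeds 20% of their mean).

## Worked example

```python
from sirnascreen import SimConfig, generate_primary_screen, run_primary, activity_score

cfg = SimConfig(n_genes=160, seed=7)          # two 384-well plates
dataset, truth = generate_primary_screen(cfg) # planted ground truth
out = run_primary(dataset)

print(out["manifest"].record_counts)
# {'input_wells': 768, 'genes_input': 160, 'genes_scored': 160,
#  'genes_unscorable': 0, 'flagged_wells': 0,
#  'called_positive': 3, 'called_negative': 2, 'called_none': 155}

print(out["hits"].sort_values("score").head(3).round(2))
#              score                call  activity_score  outcome
# gene_symbol
# GENE00109    -5.30  positive_regulator             100        2
# GENE00148    -2.89  positive_regulator             100        2
# GENE00099    -2.83  positive_regulator             100        2

print(truth.genes_of_class("positive"))
# ['GENE00099', 'GENE00109', 'GENE00148']   # all three recovered

print(activity_score(-2.3, tier="primary"))
# (75, 2)   # deposit activity bin and "active" outcome for z = -2.3
```

The three genes called positive regulators are exactly the three planted
ones; their scores sit far below the −1.5 threshold while the 155 null
genes stay inside it.  The first plate's QC gates read
`fold=8.00  kd=0.957  red=0.869  passed=True` — induction, transfection
efficiency and pathway-control reduction all clear their thresholds.

The same pipeline is available from the shell:

```sh
sirnascreen simulate --tier primary --seed 7 --n-genes 160 --out-dir sim/
sirnascreen qc   sim/primary_screen.csv --out-dir qc/
sirnascreen call sim/primary_screen.csv --out-dir hits/
sirnascreen validate-deposit sim/primary_screen.csv --out report.json
```

`validate-deposit` recomputes ratios, z-scores, replicate CV and gene
counts from the raw R1/R2 columns of a locally saved deposit-schema CSV
export and compares them with the deposited score columns; the tool never
accesses the network.

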