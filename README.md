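# splicequant

Quantification of intron retention from split RNA-seq reads, significance
filtering of alternative-splicing events, additive decomposition of
combined-perturbation splicing effects, and fitting of the quadratic
total-anisotropy binding isotherm — together with a synthetic-data
generator that produces every input with known truth, so the whole
pipeline is testable without any external data.

## Who this is for

Groups studying splicing factors by combined genetic perturbations
(e.g. a knockout crossed with a knockdown, profiled by stranded paired-end
RNA-seq) who need to (i) measure intron retention directly from aligned
reads, (ii) apply consistent coverage and significance rules across
rMATS-quantified event types and retention events, (iii) ask whether the
double-perturbation effect is explained by a weighted mean of the single
perturbations, and (iv) quantify RNA–protein binding from fluorescence
anisotropy titrations of the implicated factor.

## The statistics at the core

**Intron retention.** Each aligned read is intersected with every
annotated intron its genomic span overlaps by ≥ 3 bases (strand-aware,
dUTP-style mate conventions supported). Reads with one block (no
alignment gap) are *unspliced* if they cross an intron boundary and
*intronic* if fully contained; split reads are *spliced* when a gap
matches the intron exactly at both coordinates, else *alternatively
spliced*. Per intron and sample,

    IR = n_unspliced / (n_unspliced + 2 · n_spliced)

the factor 2 reflecting that a spliced junction is observable from both
exon sides while a boundary-crossing read reports on one boundary.
Retention differences between conditions are tested with a two-tailed
pooled-variance Student's t-test on replicate IR fractions; calls require
p < 0.01 and |ΔPSI| ≥ 0.05. rMATS-quantified events require FDR < 0.01
and |ΔPSI| ≥ 0.1; every event type first passes a median-50-reads
coverage rule, and retained-intron events additionally require all
flanking exons ≤ 500 nt. All thresholds are configurable.

**Additive decomposition.** With per-event inclusion-level differences
ID_A and ID_B for the two single perturbations, the combined effect is
modelled as ID_A·(1−w) + ID_B·w; the weight w is recovered by maximising
the Pearson correlation with the observed combined differences over a
0.01-step grid, pooled and per event type.

**Binding isotherm.** The measured total anisotropy at total protein P,
total RNA R and dissociation constant K_d is

    A_T = A_R + (A_PR − A_R)/R · ( (P+R+K_d)/2 − √( ((P+R+K_d)/2)² − P·R ) )

fitted by unweighted nonlinear least squares on (K_d, A_R, A_PR) with R
fixed to the assay's labelled-RNA concentration.

## Worked example

The `pipeline` subcommand simulates a 4-condition × 3-replicate study
(control, knockout A, knockdown B, combined; 50 nt stranded paired-end
reads), quantifies retention from the emitted SAM files, applies the
coverage and significance rules, and recovers the mixture weight:

```bash
$ cat sim.yaml
seed: 7
n_genes: 40
introns_per_gene: 3
depth: 80
n_events: 2000

$ splicequant pipeline --config sim.yaml -o run/
pipeline outputs written to run

$ cat run/decomp.summary.json
{
  "best_weight": 0.57,
  "n_events": 1123,
  "n_significant_ir": {
    "KD": 1,
    "KO": 11,
    "KOKD": 6
  },
  "per_type_best": {
    "A3SS": 0.72,
    "A5SS": 0.36,
    "MXE": 0.57,
    "RI": 0.47,
    "SE": 0.58
  },
  "r_at_best": 0.6992885943274358
}
```

The generator's default mixture weight is 0.6: from 1123 events passing
the all-conditions coverage filter the sweep recovers `best_weight` 0.57,
with the per-type profiles alongside. `n_significant_ir` counts introns
passing the retention significance rule in each comparison against the
control — the knockout (which the generator enriches for retention
shifts) yields 11 significant introns here, the knockdown 1.

Binding curves work the same way:

```bash
$ splicequant simulate binding --seed 7 -o bind/
$ splicequant fit-binding --data bind/binding_curve.tsv --rna-total 20e-9
Kd = 9.849e-07 M (se 5.6e-08), A_R = 0.06014, A_PR = 0.1986, sse = 3.37e-05, n = 12
```

The generating constants were K_d = 1 µM, A_R = 0.06, A_PR = 0.20 with 1%
measurement noise on a 12-point, 0–10 µM titration at 20 nM RNA; the fit
recovers K_d within 2%.

Other subcommands: `simulate {annotation,reads,tables,binding,all}`,
`quantify-ir`, `filter-events`, `decompose`. Every run writes a
`manifest.json` (config echo, seed, input checksums, versions); rerunning
any command with the same seed reproduces its outputs byte for byte.

## Layout

- `src/splicequant/annotation.py` — gene models, BED/GTF I/O, intron derivation
- `src/splicequant/alignments.py` — CIGAR → blocks, mate/strand protocol
- `src/splicequant/ir.py` — read classification, counting, IR statistic
- `src/splicequant/significance.py` — coverage filter, t-test/FDR rules, rMATS I/O
- `src/splicequant/decomposition.py` — weighted-mean model, weight sweep, OLS summary
- `src/splicequant/binding.py` — quadratic isotherm and its fit
- `src/splicequant/simulate.py` — synthetic annotation/reads/tables/titrations
- `src/splicequant/cli.py` — `splicequant` console entry point
- `docs/methods.md` — models, assumptions, parameter choices, limitations
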