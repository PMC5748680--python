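# genefam

A desk-scale, fully tested re-implementation of a genome-wide gene-family
survey pipeline:

- **domain_scan** — repeat-domain detection with a log-odds PWM scanner
  (greedy non-overlap resolution), repeat-count subfamily classification
  (`1R` / `R2R3` / `R1R2R3` / `ATYPICAL`), and Bjellqvist-style pI plus
  average molecular weight.
- **genome_map** — ordering/naming of family genes along linkage groups,
  tandem-duplication arrays under the "≤ 3 intervening genes" rule
  (transitively chained), per-LG cross-tabulation with headline anchored /
  tandem percentages, and exon/intron profiles.
- **phylogeny** — all-pairs global-alignment p-distances (affine gaps,
  BLOSUM62), classical Neighbor-Joining with deterministic tie-breaking,
  column-resampling bootstrap over a star alignment, and reference-anchored
  subgroup assignment by tree path length.
- **orthology** — exact Smith–Waterman local alignment, Karlin–Altschul
  E-values (E = K·m·n·e^(−λS)), the E ≤ 1e−40 / similarity ≥ 70% filter,
  best-hit label transfer, and copy-number summaries.
- **expression** — RPKM tissue-presence grouping with Venn counts,
  fold-change DEG calling (> 2 up, < 0.5 down), temporal pattern
  clustering, cross-stress Venn comparison, and 2^−ΔΔCt qPCR
  quantification.
- **synthetic_data** — a generator that plants all of the above (subfamily
  labels, tandem arrays, ortholog maps, tissue patterns, stress pattern
  groups, qPCR folds) into a 16-linkage-group synthetic dataset so every
  stage is verifiable against ground truth without any downloads.
- **io_formats** — FASTA / GFF3 / TSV / YAML / plain-text PWM readers and
  writers, the domain types, and deterministic TSV reports.

## CLI

Every stage is exposed through one entry point:

```bash
genefam --seed 1 --out-dir out simulate            # synthetic dataset + truth.json
genefam --out-dir out scan  --fasta out/proteins.fasta
genefam --out-dir out map   --gff out/genes.gff3 --scan out/scan_results.tsv
genefam --out-dir out tree  --fasta family.fasta --bootstrap 100
genefam --out-dir out orthologs --queries out/proteins.fasta \
        --refs out/refs.fasta --labels out/ref_labels.tsv
genefam --out-dir out express --tissues out/tissues.tsv \
        --stress out/waterlogging.tsv --stress out/drought.tsv
genefam --out-dir out qpcr  --ct out/qpcr.tsv --reference ACTIN
genefam --seed 1 --out-dir out all                 # simulate + run everything
```

Global flags: `--config <yaml>` (see `PipelineConfig` for keys), `--seed`,
`--out-dir`, `--log-level`.

## Notes

- Coordinates are 1-based inclusive everywhere (GFF3 dialect).
- A gap of length L costs `gap_open + (L − 1)·gap_extend` (defaults 10 /
  0.2).
- The molecular-weight report is in daltons (some published tables label
  the same magnitudes "kDa"; dimensionally they are Da).
- The detection profile is a versioned PWM fixture
  (`src/genefam/data/repeat_pwm.txt`): a 52-residue consensus with
  Dirichlet-perturbed columns; the scan threshold defaults to 60% of the
  consensus self-score.
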