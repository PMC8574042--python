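# enhancerxai

Interpretable enhancer prediction from binned histone-modification
signals. The classifier is an interval type-2 fuzzy rule base — at most
50 human-readable IF/THEN rules with up to three (mark, low/medium/high)
antecedents each — learned by a seeded, elitist genetic algorithm under
hard explainability constraints. Downstream tooling converts per-bin
enhancer probabilities into called regions, classifies them by size
(fragment / enhancer / super-enhancer) and by overlap with a reference
set (common / putative), links them to gene promoters via proximity and
enriched 3D-contact records, and characterizes them with signal
profiles, bidirectional-transcription scores, and observed/expected
enrichment statistics. A bundled synthetic-data generator plants
ground-truth rules and enhancers so every stage is testable offline.

## Layout

| module | contents |
| --- | --- |
| `enhancerxai.fuzzy` | trapezoidal interval type-2 sets, linguistic partitions, rules, rule-base serialization, Mamdani-style inference and natural-language explanations |
| `enhancerxai.induction` | quantile-anchored partition initialization, the genetic rule-base search, expert-rule injection, metrics (accuracy/precision/recall/average recall/AUC/gini) |
| `enhancerxai.tracks` | genome tiling, bedGraph/wiggle signal aggregation into bins, min-max normalization, peak expansion and labeling, stratified sampling, the `BinDataset` container |
| `enhancerxai.calling` | probability thresholding (≥ 0.8), gap-limited merging (≤ 100 bp, strict mean > 0.8), size and origin classification |
| `enhancerxai.linkage` | promoter intervals (250 bp upstream of TSS), enriched-contact flagging, proximal/distal promoter linkage categories, linked expression |
| `enhancerxai.profiles` | ±5 kb profile matrices, winsorize/rescale, transcription directionality (log10 plus/minus ratio), obs/exp signal enrichment, genomic-feature overlap enrichment, TAD-border proximity, body percentile scores |
| `enhancerxai.synth` | synthetic genomes: planted rules and enhancers, gene annotation (GFF3), contact records, expression tables, stranded nascent transcription |
| `enhancerxai.pipeline` / `enhancerxai.cli` | end-to-end orchestration with a provenance manifest, and the `enhancer-xai` command-line interface |

## CLI

```sh
# generate a synthetic genome with planted enhancer rules
enhancer-xai simulate --outdir sim --seed 1

# build the labeled bin dataset from tracks + peaks
enhancer-xai make-dataset --chrom-sizes sim/chrom.sizes \
    --track mark01=sim/tracks/mark01.bedGraph \
    --track mark02=sim/tracks/mark02.bedGraph \
    --peaks sim/true_enhancers.bed --out ds

# train, evaluate, call, link
enhancer-xai train --dataset ds --seed 1 --out model.json
enhancer-xai evaluate --model model.json --dataset ds --report report.tsv
enhancer-xai call --model model.json --dataset ds \
    --reference sim/true_enhancers.bed --out calls.bed
enhancer-xai link --calls calls.bed --genes sim/annotation.gff3 \
    --contacts sim/contacts.tsv --fpkm sim/fpkm.tsv --out linkage.tsv

# add an expert rule to a trained model
enhancer-xai add-rule --model model.json \
    --rule "mark01=high & mark02=high => enhancer" --dataset ds

# or run everything from one YAML config
enhancer-xai run --config pipeline.yaml
```

A pipeline YAML holds per-stage sections (`synthetic`, `dataset`,
`induction`, `calling`, `linkage`, `profiles`) plus a global `seed` and
`outdir`; every output is a pure function of (config, seed) and a
`manifest.json` makes re-runs no-ops unless inputs change.

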