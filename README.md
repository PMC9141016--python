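# splicescan

Convolutional splice-site prediction in eukaryotic genomic sequences:
dataset construction from annotated genes, a trainable 1-D CNN window
classifier, per-nucleotide genome scanning, and ranked-retrieval evaluation
metrics. A synthetic-genome generator with planted GT/AG boundary signals
lets the entire pipeline train and evaluate without any external downloads.

The classifier stacks convolutional blocks (batch normalization, ReLU,
stride-1 'same' 1-D convolution with L1 weight penalty, max-pooling),
followed by position-wise dense layers, flattening, and a 3-class softmax
over (donor, acceptor, other). The default architecture uses four blocks
with 16/32/64/64 filters of widths 11/11/21/41, dense units 32/16, L1 of
7e-5, and trains with Adam at learning rate 0.001 halved once after epoch 6.
The network is implemented directly on NumPy (explicit forward/backward
passes), so it has no deep-learning-framework dependency and is exactly
reproducible for a fixed seed.

## CLI

```bash
# 1. generate synthetic annotated genes (FASTA + site table + truth GFF3)
splicescan simulate --n-genes 50 --seed 1 --out sim/

# 2. build the 3-class window dataset with an 80/10/10 split
splicescan build-dataset --fasta sim/synthetic.fasta \
    --annotations sim/synthetic.sites.tsv --flanking 200 \
    --neg-ratio 1.571 --split 0.8,0.1,0.1 --stratify window \
    --seed 1 --out ds/

# 3. train (YAML config can override any model/training field)
splicescan train --dataset ds/ --seed 1 --out model.npz --history-out hist.json

# 4. scan every nucleotide of new sequences
splicescan scan --model model.npz --fasta sim/synthetic.fasta --out scans/ --bed

# 5. evaluate a probability track against truth sites
splicescan evaluate --track scans/synth_gene_0000.track.tsv \
    --sites sim/synthetic.sites.tsv --percents 50
```

Annotations are accepted as GFF3/GTF (sites derived from `intron` features
or exon adjacency; 1-based coordinates converted internally to 0-based) or
as a tab-separated site table with columns
`gene_id, site_type{donor|acceptor}, position, coordinate_base`.
Donor sites are anchored on the first intron base (the G of GT), acceptors
on the last intron base (the G of AG).

## Layout

- `src/splicescan/encoding_io.py` — FASTA/GFF3/GTF/site-table readers,
  one-hot encoding, centered window extraction
- `src/splicescan/dataset_builder.py` — 3-class window dataset and splits
- `src/splicescan/model_core/` — layer implementations, model assembly,
  training loop, hyperparameter search space
- `src/splicescan/genome_scanner.py` — per-nucleotide scanning, site
  calling, TSV/BED/GFF3 output
- `src/splicescan/metrics.py` — classification report, top-k / top-percent
  accuracy, false-positive percentage, per-gene evaluation rows
- `src/splicescan/synthetic_genome.py` — synthetic gene generator
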