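# aakmer

Alignment-free assignment of nucleotide reads to taxa-agnostic clusters of
homologous proteins, using a precomputed amino-acid k-mer frequency model.

The model is a nested map `kmer -> {cluster -> frequency}`, where the
frequency of a k-mer in a cluster is its total occurrence count across the
cluster's proteins divided by the cluster size (it can exceed 1 for repeated
motifs). A query read is six-frame translated, frames containing a stop
codon are discarded, and every amino-acid k-mer occurrence in the remaining
frames adds its per-cluster frequency to that cluster's score. The read is
assigned to the cluster with the global maximum score if the score exceeds
the threshold (default 3, strict); only the model — never the input — is
held in memory.

The package also ships:

- **simulators** — synthetic clustered protein databases, a binomial-rate
  point-mutation read simulator, a simulator guaranteeing exactly *m*
  amino-acid changes per read, and reverse-translated substring generation
  for unseen proteins, all seeded and fully deterministic;
- **evaluation statistics** — accuracy/coverage against truth labels,
  multimap resolution, agreement with external aligner hit tables
  (outfmt-6-like TSV), per-cluster concordance, keyword homogeneity of
  cluster annotations, and ROC/FPR-capped score thresholding;
- a greedy k-mer-containment clusterer for building fixture databases
  (deliberately simple; not a CD-HIT replacement).

## CLI

```sh
# synthetic clustered database (writes proteins.faa, clusters.tsv, cds.fna)
aakmer simulate db --n-clusters 50 --proteins-per-cluster 20 \
    --protein-length 300 --identity 0.8 --seed 0 --out-prefix db

# build the k-mer frequency model
aakmer build --proteins db.proteins.faa --clusters db.clusters.tsv \
    --k 5 --out model.bin

# k hyperparameter search by the protein-truncation protocol
aakmer build --proteins db.proteins.faa --clusters db.clusters.tsv \
    --out unused.bin --select-k-candidates 3,4,5,6

# simulate truth-labeled reads (binomial rate, or exactly m AA changes)
aakmer simulate reads-rate --cds db.cds.fna --rate 0.001 --length 150 \
    --n-reads 2000 --seed 1 --out-prefix sim
aakmer simulate reads-fixed --cds db.cds.fna --m 2 --length 150 \
    --n-reads 1000 --seed 1 --out-prefix fixed

# classify (FASTA/FASTQ, optionally .gz; streaming, constant memory)
aakmer classify --model model.bin --reads sim.reads.fna \
    --out assign.tsv --threshold 3 --summary summary.json

# evaluate
aakmer evaluate accuracy --assignments assign.tsv --truth sim.truth.tsv
aakmer evaluate multimap --hits hits.tsv --clusters db.clusters.tsv
aakmer evaluate agreement --assignments assign.tsv --hits hits.tsv \
    --clusters db.clusters.tsv --identity-floor 66.6
aakmer evaluate roc --scores scores.tsv --fpr-cap 0.05
```

A `key=value` config file can supply option defaults for any subcommand via
`aakmer --config FILE ...`.

## File formats

- **Cluster membership TSV**: header
  `cluster_id  protein_id  is_representative  annotation`.
- **Assignments TSV**: header
  `read_id  cluster_id  score  classified  annotation`.
- **Truth sidecar TSV**: header
  `read_id  true_cluster  true_protein  n_mutations  start  length`.
- **Hit table**: TSV with `qseqid/sseqid/pident/evalue` columns (column
  remapping and headerless outfmt-6 supported).
- **Model file**: small versioned binary container (magic `AAKM`, version,
  k, cluster table, sorted k-mer records with integer counts); a
  `kmer/cluster_id/count` TSV debug export is available via
  `aakmer build --export-tsv`.

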