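# cdr3vec

Embedding-based clustering and dispersion analysis of TCRβ CDR3
repertoires.

## The problem

The CDR3 loop of the T-cell receptor β chain dominates antigen contact,
and its diversity — generated by V(D)J recombination — encodes the state
of the adaptive immune system. Alignment-based comparison struggles on
these short, hypervariable peptides, so `cdr3vec` treats a repertoire as
a text corpus: each CDR3 amino-acid sequence is segmented into
overlapping trigrams, trigrams are embedded with a skip-gram
(word2vec-style) model trained on pooled healthy-control repertoires,
and each sequence becomes the mean of its trigram vectors,

    x_s = (1/|T_s|) Σ_{t ∈ T_s} v_t ,

where v_t are the d-dimensional input vectors of the skip-gram model
(negative-sampling loss, 2·V·d trainable parameters for a vocabulary of
V trigrams). Per cohort, the embeddings are reduced by PCA to the L
components reaching 90% explained variance, clustered with KMeans with k
chosen by the silhouette coefficient over k = 2..15 (with an elbow
fallback when the silhouette peaks trivially at the smallest k), and
summarized by each sequence's Euclidean distance to its cluster
centroid. Cohorts — e.g. ARDS patients vs non-ARDS ICU patients vs
healthy controls — are then compared with Levene's test for equality of
variances on those centroid distances: disrupted repertoires show
diffuse, fragmented cluster topologies and hence larger, more variable
distances.

The package is aimed at computational immunologists who have
IgBlast-style clonotype tables (CSV) or CDR3 FASTA and want a tested,
reproducible implementation of this pipeline, plus a synthetic
repertoire generator for method development when patient data is not
available.

## Worked example

`examples/03_cluster_and_dispersion.py` runs the whole pipeline on the
three built-in synthetic cohorts (254 control, 139 ARDS-like, 115
non-ARDS-like sequences; tight / diffuse / intermediate topologies):

```
$ python examples/03_cluster_and_dispersion.py
vocabulary 491 trigrams, 98200 model parameters
control   n=254 L= 4 k= 5 (silhouette) silhouette=0.842 mean centroid distance=0.225
ards      n=139 L= 6 k= 6 (elbow_fallback) silhouette=0.234 mean centroid distance=0.481
non_ards  n=115 L= 4 k= 6 (elbow_fallback) silhouette=0.446 mean centroid distance=0.233
Levene ards     vs control : W=  28.24  p=1.80e-07
Levene ards     vs non_ards: W=  15.13  p=1.28e-04
Levene control  vs non_ards: W=   0.00  p=9.62e-01
```

Reading the output: the control cohort forms five clean clusters (high
silhouette, small centroid distances — a conserved repertoire), the
ARDS-like cohort is diffuse (low silhouette, roughly double the mean
centroid distance), and Levene's test confirms its dispersion differs
from both other groups while control and non-ARDS do not differ from
each other. `examples/01_simulate_and_curate.py` and
`examples/02_embed_cdr3.py` walk through the earlier stages (data
generation + curation; tokenization + embedding, including the
co-occurrence similarity property).

The same run is available from the shell:

```sh
cdr3vec run --simulate --seed 7 --outdir out/
cdr3vec simulate --seed 7 --out synthetic.csv
cdr3vec curate --in table.csv --out curated.csv --report report.json
```

Every run writes `summary.json` (corpus stats, vocabulary size,
parameter count, per-cohort k/silhouette/dispersion, pairwise Levene
results) plus per-cohort PCA coordinates, cluster labels and scan curves
as TSV; reruns with the same config and seed are byte-identical.

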