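# Methods

## Overview

`cdr3vec` analyzes the structure of TCRβ CDR3 amino-acid repertoires with
a language-model analogy: CDR3 sequences are tokenized into overlapping
trigrams, trigrams are embedded by a skip-gram model trained on pooled
healthy-control repertoires, sequences become the mean of their token
vectors, and per-cohort PCA + KMeans expose each cohort's cluster
topology. Group differences are quantified as intra-cluster dispersion —
each sequence's Euclidean distance to its assigned cluster centroid —
compared across cohorts with Levene's test. The working hypothesis is
that immune perturbation shows up as repertoire fragmentation: dispersed,
overlapping clusters in disease (ARDS-like), tight conserved clusters in
health, intermediate organization in other ICU (non-ARDS) patients.

## Curation model

A usable CDR3 is a productive rearrangement written over the 20 standard
amino acids, starting at the conserved cysteine and ending at the
conserved phenylalanine/glycine, and at least k residues long (k = the
k-mer size; shorter sequences emit no token). Drop reasons are disjoint
and ordered (non-productive → bad alphabet → bad boundary → too short);
the first failing rule wins, so report counts always sum to the number
of dropped records and curation is idempotent. The boundary rule is
applied as a filter even though annotation tools use it as a detection
criterion — this guarantees downstream invariants on arbitrary input
tables — and can be disabled for pre-trimmed data. Duplicate CDR3s are
retained: abundance structure is information, not noise. V-gene calls
are carried as metadata only.

## Embedding model

Skip-gram with negative sampling, written against the canonical
formulation. For a center token c with context token o and noise tokens
n₁..n_m drawn from the unigram^0.75 distribution, the loss is

    L = −log σ(u_o·v_c) − Σⱼ log σ(−u_{nⱼ}·v_c)

with v (input matrix `W_in`) and u (output matrix `W_out`) both V×d, so
the model carries 2·V·d trainable parameters. Defaults are the study
profile: d = 100, window 5, min_count 1, 10 epochs, 5 negatives, SGD
with learning rate decaying linearly 0.025 → 1e-4. No frequent-token
subsampling and no random window shrinking: both would add randomness
without benefit at this corpus scale, and seeded bit-reproducibility is
a contract (single-threaded training only, one `numpy` generator).

Numerical/implementation choices:

- `W_in` initialized uniform(−0.5/d, 0.5/d), `W_out` at zero (the
  classical initialization).
- All (context, negative) updates belonging to one center position are
  applied as a single vectorized SGD step (`np.add.at` accumulates
  duplicate rows). This deviates from strictly sequential per-pair
  updates but is deterministic and an order of magnitude faster; the
  analytic gradient of the per-pair loss is verified against central
  differences to 1e-5 relative error.
- A negative draw that collides with its own positive context token is
  skipped, following the reference implementations.
- A sequence is embedded as the unweighted mean of its tokens' `W_in`
  rows — order-invariant and scale-stable. A `sum` reduction is exposed
  in config; it encodes vocabulary-coverage in the vector magnitude,
  which also couples dispersion to token-frequency (norm) heterogeneity
  and in practice degrades the cohort contrast, so `mean` is the
  default. Out-of-vocabulary tokens are skipped; a sequence with no
  known token cannot be embedded and raises (the pipeline instead drops
  such sequences and logs the count, because cohorts embedded with a
  control-trained model can legitimately contain fully novel sequences).

## Dimensionality reduction and clustering

PCA (full SVD) retains the smallest number of components L whose
cumulative explained variance reaches 90% (configurable; L can also be
forced manually). Components are orthonormal to 1e-8, reconstruction
with all components reproduces the centered data to 1e-8, and the score
variance equals the centered-data variance — all under test.

KMeans is Lloyd's algorithm from k-means++ starts (best of n_init = 10
restarts by inertia, max_iter = 300). The per-iteration assignment-step
inertia trace is recorded on the result; it is non-increasing by
construction and asserted in tests. Termination is label stability, so
the returned solution is an exact fixed point: every centroid is the
mean of its assigned points and every point is assigned to its nearest
centroid (`tol` > 0 enables an earlier center-shift stop that trades the
exact mean property for speed; the default is 0). An emptied cluster is
reseeded to the point farthest from its current centroid, which cannot
increase the assignment inertia.

The number of clusters is scanned over k = 2..15. The default selection
rule is the silhouette argmax; when that argmax sits at the smallest k
scanned it is treated as a trivial coarse split (the silhouette rewards
merging everything into two blobs) and the knee of the inertia curve is
used instead, found as the point of maximum perpendicular distance from
the chord joining the curve's endpoints (ties to smaller k; a collinear
curve returns the smallest k with a warning). A manual override always
wins, and the applied rule is recorded. Silhouette uses the standard
(b−a)/max(a,b) per point with two fixed conventions: singletons score
0, and coincident data with a = b = 0 scores 0. The implementation is
verified against a literal O(N²) per-point oracle to 1e-10.

Partition stability is assessed by K-fold cross-validation: fit on the
training folds, assign held-out points to the nearest fitted centroid,
score the held-out silhouette (degenerate validation folds score 0 by
the singleton convention).

## Dispersion statistics

The observation unit is the per-sequence Euclidean distance to its
assigned centroid, computed in the cohort's PCA space; squared distances
sum to the clustering inertia by definition. Cohorts are compared with
Levene's test on these distances: with Z_ij = |Y_ij − center(Y_i)|,

    W = (N−g)/(g−1) · Σ n_i (Z̄_i − Z̄)² / Σ_i Σ_j (Z_ij − Z̄_i)²

referred to the upper tail of F(g−1, N−g). Centering defaults to the
group mean (classical Levene); median centering (Brown–Forsythe) is
available. The implementation matches `scipy.stats.levene` to 1e-10 and
its type-I error is calibration-tested (5% ± 2% at α = 0.05 over 1000
null simulations). Degenerate input where all within-group deviations
are constant returns W = 0, p = 1 when the group deviations are also
equal (exactly equal dispersion), and raises otherwise (the F reference
does not apply). Multi-group reports emit every pairwise comparison with
raw and Bonferroni-adjusted p-values; groups with fewer than two members
are excluded with a warning.

## Synthetic repertoires

Because no patient data ships with the package, a generator produces
cohorts with controllable topology. A cohort is defined by a number of
motif families (template CDR3s), a per-position substitution rate, and a
background fraction of fully random sequences; lengths follow a
truncated normal (mean 15, sd 2, bounds [8, 22], matching typical CDR3
length structure). All sequences are curate-clean by construction.
Presets encode the three study conditions at the printed cohort sizes:

| cohort   | n   | families | mutation | background | topology |
|----------|-----|----------|----------|------------|----------|
| control  | 254 | 5        | 0.02     | 0.00       | tight    |
| ards     | 139 | 9        | 0.15     | 0.20       | diffuse  |
| non_ards | 115 | 2        | 0.05     | 0.05       | middle   |

Family counts mirror the cluster counts characteristic of each group
(5/9/2). Two generator properties matter and are deliberate:

- **Restricted motif space.** Interior residues are drawn from a
  strongly skewed Gly/Ser-rich frequency profile rather than uniformly.
  Real CDR3 junctions occupy a heavily constrained trigram space — a
  repertoire corpus contains orders of magnitude fewer distinct trigrams
  than the 8000 possible — and that restriction is load-bearing: it is
  what lets a vocabulary trained on one cohort cover the others. A
  uniform 20-letter alphabet makes cohort trigram sets nearly disjoint,
  a structure no real repertoire shows, and the transfer setting
  collapses.
- **Clonotype uniqueness.** Every family member carries at least one
  substitution relative to its template (unless the rate is exactly 0,
  a degenerate mode kept for testing). Curated clonotype tables list
  unique rearrangements; without this rule half of a low-mutation cohort
  would be exact duplicates of its template, producing a zero-distance
  core no real table shows.

Substitutions are i.i.d. per interior position, uniform over the other
19 letters; boundary residues are never touched; no indels (a non-goal —
length structure stays simple and curation-safe). Generation is fully
determined by the profile seed.

What the generator does **not** emulate: V(D)J generation probabilities,
abundance/clonal-expansion structure across samples, multiple patients
per cohort (each preset cohort is one pooled pseudo-sample), sequencing
error, or realistic trigram co-occurrence statistics beyond the skewed
residue usage. Passing end-to-end tests therefore demonstrates that the
pipeline's machinery recovers planted topology differences of this
specific kind; it does not validate the biological claims on real data.

## Pipeline conventions

The embedding model is trained on the pooled control cohort only
(maximizing generality of the learned motif space); every cohort is then
embedded with that fixed model and analyzed separately — own PCA, own k
scan, own clustering — before distances are pooled for the group
comparison. One global seed expands through `numpy.random.SeedSequence`
into named per-stage seeds (simulation, embedding init, kmeans, k-fold),
so a run is reproducible from its config alone; summaries are written
with sorted keys and no timestamps, making reruns byte-identical.

## Known limitations

- Levene's test on centroid distances is a blunt instrument for cohort
  contrasts of this kind: distances to centroids concentrate (chi-like)
  in a handful of PCA dimensions, so moderate differences in noise rate
  translate into small differences in distance spread. Under the preset
  conditions the ARDS-like cohort's mean distance exceeds both others
  essentially always, but the ARDS vs non-ARDS Levene comparison at
  p < 0.01 holds in only roughly two thirds of seeds, with silhouette
  argmax jitter on flat curves (ARDS k drifting toward the scan ceiling,
  which fragments clusters and shrinks distances) accounting for much of
  the remainder.
- Silhouette-based k selection is unstable when the true structure is
  diffuse; the recorded selection rule and full scan curves are part of
  every result so this can be audited.
- The vocabulary is data-dependent; with `min_count` = 1 on synthetic
  control cohorts it lands in the hundreds of trigrams, far above the
  handful a heavily redundant clinical corpus can show.
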