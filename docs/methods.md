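# Methods

`repdab` detects condition-associated CDR3β sequences by comparing T-cell
receptor repertoires between two groups of samples. This note describes the
model, the numerical choices behind it, and what the synthetic validation
does and does not demonstrate.

## The detection model

The unit of comparison is not the individual clonotype — repertoires are so
private that almost no clonotype recurs across subjects — but the
*sub-repertoire*: a group of CDR3s with similar subsequence composition that
recurs across individuals. The pipeline proceeds in four steps.

**1. Within-sample clustering.** Each CDR3 is encoded as a dense vector of
contiguous k-mer counts (nucleotide 4-mers, 256 features, by default;
amino-acid 3-mers, 8000 features, as an option). Within each sample the
vectors are clustered by complete-linkage agglomerative clustering on
Euclidean distances, and the dendrogram is cut adaptively per branch (see
*Adaptive branch cut* below). Counting is over overlapping windows, so a
CDR3 of length L contributes L−k+1 window counts; raw counts are the
default feature values, with per-sequence normalization available.

**2. Cross-sample matching.** Each cluster is summarized by its centroid:
the *unweighted* arithmetic mean of member k-mer rows. Clone sizes are
deliberately ignored so the centroid reflects subsequence composition
alone. Centroids from all samples are pooled and clustered again, by
k-means with k chosen to maximize the oK score

    oK = (nS + avS) / 2,

where, over the k centroid clusters, `nS` is the fraction of clusters whose
mean silhouette exceeds the average cluster silhouette and `avS` is that
average silhouette mapped from [−1, 1] to [0, 1]. k is swept from the
smallest to the largest per-sample cluster count; ties break toward smaller
k (coarser matching keeps sub-repertoires populated across more samples,
which the presence filter rewards). Hierarchical matching with the same
adaptive cut is available instead of k-means. Centroid clusters are the
sub-repertoires; if one sample contributes several clusters to a
sub-repertoire they are merged back in that sample (single pass) and the
centroid updated as the unweighted mean over the union.

**3. Differential abundance.** Samples are first depth-normalized to the
minimum total count (scaled counts stay fractional). A sub-repertoire's
abundance in a sample is the sum of its member counts (default), the
relative frequency of that sum, or the mean member clone size over the mean
sample clone size. Sub-repertoires present in at least 3 samples per group
are tested with a two-sample t-test (paired or unpaired) or a two-class
rank-product test (geometric mean of fold-change ranks over all cross-group
sample pairs, with sample-label permutation p-values, enumerated
exhaustively when the label space is small). The per-round significance
cut-off is deliberately lenient (p < 0.1): rounds only nominate candidates,
and the final filter does the real discrimination.

**4. Candidate ranking.** Members of differentially abundant
sub-repertoires, pooled over all resample rounds, are ranked by six
factors: random-forest importance of the candidate's per-sample abundance
(R1), mean Fisher's exact p over cross-group sample comparisons (R2), mean
Haldane-corrected odds ratio from the same tables (R3), mean
condition/control ratio of nucleotide-variant counts per amino-acid CDR3
(convergent recombination, R4), the condition-minus-control difference in
sample presence (R5), and the number of resample rounds in which the
candidate was detected (R6). Per direction (enrichment / de-enrichment,
with the R3/R4/R5 orientations reversed for the latter), each factor is
converted to average-tied ranks, min-max scaled to [0, 1] (0 = best), and
summed into the rank score C. C's p-value is the fraction of rank sums, in
1000 permutations that shuffle each factor independently across candidates,
at or below C (no add-one smoothing). Final calls require p < 0.05 and
decoy-estimated q < 0.05.

### Numerical details worth knowing

- **Fisher comparisons** use raw (pre-normalization) integer counts against
  the remaining sample depth. A comparison in which the candidate is absent
  from both samples has a symmetric table whose exact p is 1 and odds ratio
  is 1; it is included in the mean at those values. Dropping such
  comparisons instead would systematically reward sparsely observed
  candidates, whose few informative comparisons are extreme — on synthetic
  data this inverted the ranking between public true positives and private
  null clonotypes.
- **R1** is the classical per-tree out-of-bag mean decrease in accuracy,
  computed by a thin bagging loop over decision trees. Forest-level
  permutation importance is useless here: candidate features are massively
  redundant (cluster co-members), so permuting any single feature never
  changes the ensemble vote.
- **R4** counts distinct nucleotide sequences per (amino-acid CDR3, V, J)
  per sample; a zero denominator takes a +1 pseudocount on both sides.
- **Zero-variance rows** under the t-test get p = 1 and a flag.
- **Degenerate candidate sets** (fewer than two candidates in a direction)
  are skipped with a warning; permutation p needs at least two.

### Adaptive branch cut

A single cut height cannot handle repertoire k-mer spaces, where tight
motif-driven clusters close low in the dendrogram while diffuse background
merges almost to the root. The cut replays the linkage bottom-up:
undersized branches (< `min_cluster_size`, default 5) are always absorbed
into their sibling; two grown branches are kept apart when the join height
exceeds the lower branch's *mean internal merge height* by more than a
`deep_split`-controlled fraction of the total tree height (default level 3,
0.15), and merged otherwise. Two properties motivated this exact rule.
First, under complete linkage the *diameter* of even a tight cluster creeps
up to its join height, so diameter-based gaps under-split; the mean
internal height keeps a usable margin. Second, pure height-*ratio*
criteria cannot simultaneously keep a smooth, diffuse family whole and peel
a tight motif cluster off background — the two cases present nearly equal
ratios — whereas an absolute gap on the scale of the whole tree separates
them cleanly. The defaults were validated on synthetic motif-planted data:
planted clusters of ~10–50 observed members separate from background in
essentially every sample, and a sample of identical vectors yields one
cluster. The known trade-off: a dataset whose largest pairwise distance is
inflated by a single outlier raises the splitting threshold everywhere.

### Decoy-based FDR

Decoy CDR3s drawn from a healthy reference repertoire are spiked into every
sample before step 1 at a decoy:real ratio of 0.1 (configurable), traverse
the whole pipeline, and their detection rate estimates the false discovery
rate: at threshold t, `FDR(t) = (decoys with p <= t / ratio) / (reals with
p <= t)` clipped to [0, 1], and q(t) is the minimal FDR at any threshold
>= t. Injection happens once, before the resample loop, so decoy detection
counts are comparable with real ones.

For this estimate to be meaningful the decoys must be exchangeable with
condition-irrelevant clonotypes on *all six* factors. The injection
therefore copies the dataset's own empirical profile: each decoy inherits
the presence count of a randomly chosen real clonotype (reproducing the
public/private sharing spectrum), receives per-sample counts resampled from
the receiving sample's clone-size distribution, and carries a fixed
synonymous nucleotide variant at the data's empirical convergent-variant
rate (otherwise factor R4 systematically favours real clonotypes). The
bundled healthy reference (`null_reference`) is fully cluster-structured —
like any repertoire it consists of motif-sharing public clusters — but its
motifs are its own: decoys form their own clusters and sub-repertoires and
are tested like everything else, without free-riding inside truly
condition-associated clusters.

## The synthetic data generator

`repdab.simulate` builds immunoseq-format two-group cohorts with known
ground truth. It emulates exactly the structure the method exploits and no
more:

- toy germline segments (8 V of 4 codons with a conserved leading cysteine,
  4 J of 4 codons, 2 D labels) with realistic names; CDR3s are assembled
  codon-wise (V + N1 + 5-codon motif + N2 + J) from non-stop codons, so
  every sequence is in-frame and productive;
- 12 shared clusters, each a pool of 60 clonotypes around a common
  junctional motif and V/J pair, drawn into every sample with probability
  0.9 — the cross-sample public cluster structure. Cluster members carry
  fixed-length single-codon inserts (antigen-selected responses are
  junction-length restricted), background CDR3s 1–3-codon inserts;
- clone sizes from a rounded log-normal(0.5, 1.0) by default (a discrete
  power law is available). The log-normal keeps the post-singleton-filter
  repertoire larger than the resampling subsample, which is the operating
  regime of the method on real data — with a Zipf(2.5) law three quarters
  of clonotypes are singletons and the subsample step degenerates into the
  identity, silencing the detection-count machinery;
- convergent recombination: clonotypes are emitted as two synonymous
  nucleotide variants at rate 0.1; spiked clonotypes in affected condition
  samples at rate 0.5 (antigen-driven convergent selection — the
  phenomenon ranking factor R4 measures). The alternative variant is fixed
  per clonotype, as recurrent variants are across individuals;
- spikes: the counts of 2 chosen clusters are multiplied by fold_change
  (default 4) in all condition samples.

What the generator does *not* emulate: V(D)J recombination statistics and
generation probabilities, sequencing error, frame-shifted/unproductive
reads, depth imbalance between groups, batch effects, HLA-driven V-gene
usage structure, and clone-size correlation across samples of one subject.
Passing tests on this generator therefore demonstrate that the machinery
recovers planted compositional enrichment under realistic sparsity and
sharing — not that the method is robust to the technical noise of real
RepSeq data.

## Validation scales and expectations

The bundled acceptance runs use desk-scale cohorts: a no-effect cohort
(8 × 1000 clonotypes, subsamples of 500, 10 rounds) and a spiked cohort
(4 vs 4 × 2000 clonotypes, subsamples of 1000, 10 rounds), against the
published protocol's 100 rounds of 5000-CDR3 subsamples per sample. On the
spiked cohort the pipeline recovers the planted clonotypes with high recall
at near-zero decoy FDR.

On the no-effect cohort a handful of final calls remain. This is a known
small-scale property of the decoy arithmetic, not a tuning failure: calls
require q < 0.05, which at a 10:1 real:decoy budget effectively demands
*zero* decoys below the call threshold, so the expected number of null
calls per direction approaches (candidate pool size)/(decoy candidates + 1)
when decoys and null candidates are exchangeable. With pools of a few
hundred and a few dozen decoy candidates that ratio is intrinsically
O(10), shrinking only as pools and decoy counts grow toward
production scale. The same-condition behaviour should therefore be read as
"an order of magnitude fewer calls than a spiked run", not as an absolute
count.

## Parameters that matter

| Parameter | Default | Meaning |
|---|---|---|
| k-mer space | nt, k=4 | 256 features; `aa3` gives 8000 |
| `n_resamples` | 100 | resample rounds of steps 1–3 |
| `subsample_size` | 5000 | unique CDR3s drawn per sample per round |
| `min_cluster_size` | 5 | smallest separable within-sample cluster |
| `deep_split` | 3 | branch-cut zoom level (0–4) |
| `da_p_cutoff` | 0.1 | per-round sub-repertoire test cut-off |
| `min_per_group` | 3 | presence filter (samples per group) |
| `n_perm` | 1000 | rank-sum permutations |
| `final_p/q_cutoff` | 0.05 | final call thresholds |
| `decoy_ratio` | 0.1 | injected decoy:real ratio |

All randomness flows from one master seed; per-round and per-sample seeds
are derived deterministically, so runs are reproducible end to end.
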