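# repdab

**Clustering-based detection of condition-associated CDR3 sequences in
T-cell receptor repertoires.**

High-throughput TCR repertoire sequencing yields hundreds of thousands of
unique CDR3β clonotypes per person, almost all private to that person.
Asking "which clonotypes are expanded in patients versus controls?" at the
level of individual sequences is therefore nearly hopeless — the same
sequence is rarely seen twice. `repdab` implements a population-level
alternative for immunologists and computational biologists working with
immunoseq- or MiXCR-format repertoire data:

1. **cluster** each sample's CDR3s by their k-mer composition (nucleotide
   4-mers by default, 256 features per CDR3) with complete-linkage
   hierarchical clustering and an adaptive per-branch dendrogram cut;
2. **match** clusters across samples into *sub-repertoires* — recurring
   compositional neighbourhoods shared by unrelated individuals — via
   k-means over pooled cluster centroids, with k chosen by the
   **oK score**, oK = (nS + avS)/2, combining the fraction of
   above-average-silhouette clusters (nS) with the rescaled mean silhouette
   (avS);
3. **test** sub-repertoire abundances between the two groups (t-test or a
   rank-product permutation test) in repeated random subsamples of each
   repertoire;
4. **rank** the member CDR3s of differentially abundant sub-repertoires by
   six factors (classifier importance, mean Fisher's exact p and odds
   ratio, convergent-recombination ratio, cross-group publicness, and
   detection count across resample rounds) into a rank score
   C = Σₖ Rₖ with a permutation p-value, and estimate the FDR with decoy
   CDR3s spiked in from a healthy reference repertoire.

CDR3s with p < 0.05 and decoy q < 0.05 are reported as enriched (clonally
expanded) or de-enriched in the condition group. A synthetic-repertoire
generator with planted ground truth (`repdab.simulate`) makes every stage
testable without any data download.

See [docs/methods.md](docs/methods.md) for the model, assumptions and
numerical choices.

## A worked example

`examples/03_full_pipeline.py` plants a four-fold clonal expansion in two
CDR3 clusters of a synthetic 4-vs-4 cohort and asks the pipeline to find
it:

```
$ python examples/03_full_pipeline.py
completed 5 resample rounds
final calls at p<0.05 & q<0.05: 159 (159 enriched, 0 de-enriched)
recall of planted enrichment: 156/228 spiked keys called
false enriched calls: 3
```

156 of the 159 enriched calls are genuinely spiked clonotypes (the ground
truth is known because the data are simulated); the remaining spiked keys
ranked below the final cut-offs at this small number of resample rounds.
Each called row carries the six scaled rank
factors, the rank score C, its permutation p, the decoy q, and the
detection count. The other example scripts cover data simulation
(`01`), the clustering/matching machinery with the oK score (`02`), and
post-hoc characterization — V-gene usage bias, positional amino-acid
information content in bits, and overlap with known condition-associated
CDR3 sets (`04`).

A thin command-line interface wraps the same library calls:

```bash
repdab simulate --out sim --subjects 8 --fold 4 --seed 1
repdab run --input-dir sim --metadata sim/metadata.csv --resamples 10 \
           --subsample 1000 --seed 1 --out results
```

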