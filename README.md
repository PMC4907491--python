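# readbias

Recognition and quantification of sequence-composition bias in the
positioning of next-generation-sequencing read starts.

Read starts are not placed uniformly along a genome: library preparation and
sequencing chemistry make the probability that a read begins at a position
depend on the local sequence around it. `readbias` measures how strong that
dependence is in a dataset, using nothing but the reference sequence and a
per-position read-start count track.

## Who it is for

Anyone who has a coordinate-sorted BAM (or a simple per-position count table)
and wants a single calibrated number answering: *how predictable are my
read-start positions from local sequence composition alone?* — for example to
judge whether a GC-correction step actually removed composition bias.

## The method

1. **Pooling.** Genomic positions are sampled stratified by read-start
   frequency (0, 1, …, 10, 11+ reads starting there); each sampled position
   carries its ±20 bp window (41 bases).
2. **Features.** Each window is summarized by its overlapping k-mer
   frequencies, normalized within each order: 4 mono-, 16 di-, 64 tri- and
   256 tetra-nucleotide features (`mono` = 4, `multi` = 336, `all` = 340).
3. **Balanced classification.** Positions with no reads (class 0) and
   positions with ≥ m reads (class 1, m ∈ {1, 6, 11}) are balanced, split
   into disjoint train/test halves, and classified with a 3-nearest-neighbor
   classifier under Euclidean distance
   d(F₁, F₂) = √(∑ₓ (F₁(x) − F₂(x))²).
4. **Pattern effect index.** The test accuracy (in %) is rescaled as

       PEI = (accuracy − 50) / 50

   so PEI ≤ 0 means read positioning is random with respect to window
   composition and PEI = 1 means it is fully predictable. Under label
   shuffling the null accuracy is 50% with a small spread; three null
   standard deviations correspond to PEI ≈ 0.0482, so **PEI > 0.05** is read
   as composition-affected positioning. The measurement is replicated
   (default 5×) and the PEI of the mean accuracy reported.

Supporting tools: Euclidean distances between per-frequency-group local and
global mono+di distributions, GC summaries per group, genetic-algorithm
wrapper feature selection (population 50, 20 generations, p_c = 0.8,
p_m = 0.05, elitism), and a transition/entropy sequence-complexity score
√((q/q_max)·(h/h_max)).

A built-in simulator generates references and biased tracks with known
ground-truth bias strength β (placement weight exp(β·d(p)), where d(p) is
the local-vs-background composition distance; β = 0 is exactly uniform), so
the whole pipeline is testable without any external data.

## Worked example

```python
import readbias as rb

ref = rb.simulate_reference(50_000, rb.KmerDistribution.from_gc(0.5), seed=1, name="chr1")
track = rb.place_reads(ref, rb.BiasModel(order=2, beta=20.0), 100_000, seed=2)

model = rb.PatternEffectModel(
    refs=[ref], tracks=[track], min_reads=1, feature_set="all",
    pool_config=rb.PoolConfig(strata=rb.default_strata(0.1)),
)
print(model.fit(replicates=5, seed=0).summary())
```

prints

```
Pattern effect on read-start positioning
========================================
problem:            0 vs 1+ reads
feature set:        all
replicates:         5 (seeds [0, 1, 2, 3, 4])
accuracies (%):     83.00, 85.40, 84.60, 84.60, 83.40
mean accuracy (%):  84.20 (sd 0.98)
PEI:                0.6840
affected (PEI > 0.05): yes
```

The five replicate accuracies come from five independent pool/split/classify
rounds; their mean of 84.20% rescales to PEI = 0.684, far above the 0.05
threshold — as it should be, since the track was simulated with a strong
(β = 20) dinucleotide bias. Rerunning the same model on a β = 0 track gives
accuracies scattered around 50% and a PEI near 0 ("affected: no").

The same pipeline is available from the shell:

```bash
readbias simulate --length 50000 --order 2 --beta 20 --reads 100000 \
    --seed 1 --out-ref ref.fa --out-starts starts.tsv
readbias pei --ref ref.fa --starts starts.tsv --problem 1 --features all \
    --replicates 5 --seed 0 --out-prefix run1
```

Every subcommand writes a `*.manifest.txt` recording all resolved
parameters, seeds and input checksums; re-running with the manifest's
parameters reproduces the outputs byte-for-byte. Real data enter through
`--starts` (TSV `chrom  pos(1-based)  count`, or BED3), or via
`readbias.starts_from_bam(path, chrom)` for an indexed BAM.

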