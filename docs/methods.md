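# Methods

## The measurement

The package quantifies sequence-composition bias in read-start positioning
as the predictability of "reads start here" from the ±20 bp window around a
position. The full procedure for one measurement is:

1. sample positions stratified by read-start frequency and attach windows
   (the *sequence data pool*);
2. extract per-order-normalized k-mer frequency features from each window;
3. build a balanced, disjoint train/test pair for the binary problem
   "0 reads vs ≥ m reads";
4. classify the test half with 3-NN under Euclidean distance;
5. rescale the accuracy to the pattern effect index
   PEI = (accuracy% − 50)/50.

Steps 1–5 are repeated (default 5 replicates, seeds `seed + r`) and the PEI
of the mean accuracy is reported, together with the replicate spread.

The classifier is used descriptively, not predictively: it validates a
distance-based observation (positions with reads live far, in Euclidean
feature space, from positions without), so only a classifier that applies
Euclidean distance directly is appropriate. For the same reason the genetic
algorithm's fitness deliberately uses the *test* accuracy — it searches for
the features that carry the pattern in this dataset, not for a generalizing
model. This intentional leakage is confined to `ga_select` and is prominently
documented there.

## Decision threshold

Balanced classes put chance at 50%. Label-shuffling (10 permutations of each
train and test set) gives an empirical null for the accuracy; its spread is
of the order of 0.8 accuracy points, so a mean accuracy three null standard
deviations above chance, 49.98 + 3×0.81 = 52.41%, corresponds to
PEI = 0.0482. The package rounds this to a decision threshold of
**PEI > 0.05 ⇒ "affected"**. The test suite recomputes the null calibration
on synthetic data (mean shuffled accuracy within 3 standard errors of 50%)
rather than assuming it.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| halfwidth | 20 bp | window half-width; windows have 2·20+1 = 41 bases |
| strata | 5000/500×10/5000 × scale | positions requested per frequency class 0, 1..10, 11+ |
| min_reads | 1 (also 6, 11) | class-1 definition of the classification problem |
| feature_set | all (340) | mono (4), multi (16+64+256 = 336) or all (340) features |
| K | 3 | neighbors in the classifier; binary labels make 3-NN votes tie-free |
| replicates | 5 | independent pool/split/classify rounds per measurement |
| GA | pop 50, 20 gens, p_c 0.8, p_m 0.05, elitism | wrapper feature-selection settings |

Stratum sizes follow the 5000/500…500/5000 pattern of a five-chromosome
plant-genome analysis, scaled by a user factor (CLI default 0.1) so a
desk-scale run on a 50 kb simulation finishes in seconds; the test suite and
the acceptance script use 50 kb references with 10⁵ reads and scale 0.1 as
their standard problem size, chosen because the resulting class sizes
(roughly 200–250 instances per class and half) already separate the biased
and null regimes cleanly.

## The synthetic-data generator

`simulate_reference` draws an i.i.d. sequence from a given mononucleotide
composition. `place_reads` draws read starts multinomially over eligible
positions (window fits, N-free) with weight

    w(p) = exp(β · d(p)),

where d(p) is the Euclidean distance between the window's order-k k-mer
distribution and the model's background distribution. β = 0 recovers the
uniform null exactly; the exponential tilt is the simplest positive weight
with that property. Reads are forward-strand only and may stack on a
position, which is what populates the higher frequency strata.

**Order-specific ground truth.** For order k ≥ 2 the default background is
not the reference's own global distribution but that distribution displaced
along a *lower-order-neutral* direction: the k-fold outer product of
(1, −1, 1, −1)/2 over A, C, G, T (for k = 2, the purine/pyrimidine
correlation contrast; all row and column sums are zero, so every lower-order
marginal of the background is untouched). Because the displacement is large
compared to per-window fluctuations, d(p) ≈ ‖v‖ − ⟨δ_p, v̂⟩ is approximately
linear in the projection of the window's deviation δ_p onto the displacement
direction, and the induced bias is therefore specific to order k — largely
invisible to mononucleotide features. Without this construction, tilting on
the raw distance to the global distribution favours windows deviant in *any*
direction, most of which are mono-visible, and the "order-2" label would not
describe what the simulator actually produces. With it, an order-2, β = 20
simulation yields multi-nucleotide-feature accuracies well above
mono-nucleotide ones, matching the qualitative behaviour expected of a
genuinely multi-nucleotide pattern.

**What the generator does not emulate.** Real read-start bias includes
positional motifs (specific bases at specific offsets), mappability effects,
strand asymmetries, PCR duplication structure and chromosome-scale coverage
waves. The generator produces a purely compositional, position-exchangeable,
forward-strand bias on an i.i.d. reference. Passing tests therefore
demonstrate that the pipeline detects and calibrates compositional bias with
known strength; they do not certify behaviour on motif-driven or
mappability-driven bias.

## Numerical and procedural choices

- **Coordinates** are 0-based internally; all text formats are 1-based and
  say so in their headers. A BAM read start is the leftmost aligned
  reference coordinate regardless of strand (a `five-prime` mode is
  available); duplicate-flagged records are skipped by default, and both
  mates of a pair count as independent starts.
- **N policy**: windows containing N are ineligible everywhere (sampling,
  feature extraction, simulation); global k-mer counts skip N-containing
  k-mers. The feature space stays strictly 4-letter.
- **KNN ties** at the K-th neighbor are broken by lower train-instance
  index, making predictions deterministic; the implementation is verified
  against an exhaustive distance-sort oracle and against scikit-learn on
  tie-free data.
- **Splitting**: frequency-0 instances are halved (odd instance to train);
  the same per-half counts are drawn from class 1 without replacement; if
  class 1 is scarce both classes shrink to the feasible equal size with a
  warning. Train and test never share a (chrom, pos).
- **Distance tables** concatenate the mono and di blocks (each normalized
  within its order) before taking the Euclidean distance; a di-only variant
  is available via the `orders` argument, since either reading of
  "distribution of all local nucleotides" is defensible.
- **GA**: fitness-proportionate (roulette) selection by default with
  tournament selection behind a config switch; single-point crossover;
  per-bit mutation; elitism replaces the worst individual of the next
  generation with the best of the current, which makes the per-generation
  best-fitness trace non-decreasing. All-zero chromosomes are re-randomized
  before evaluation. Mask fitnesses are cached by bit pattern.
- **Complexity**: entropy uses natural log with h_max = ln 4 over the full
  alphabet regardless of which bases occur; q_max = length − 1. The ratio
  h/h_max is base-invariant.
- **Determinism**: every stochastic step takes an explicit seed;
  `measure_pei` derives replicate seeds as `seed + r` and reports them; CLI
  manifests record all seeds, so outputs are reproducible byte-for-byte.

## Known limitations

- The 3-NN accuracy — and hence the PEI — depends on pool size: very small
  pools are noisy, and PEI values from different stratum scales are not
  directly comparable. Replicate standard deviations are reported so users
  can judge the noise.
- Feature spaces of 336–340 dimensions with a few hundred training
  instances sit in the regime where Euclidean distances begin to
  concentrate; this mildly penalizes the larger feature sets and is
  inherent to the method.
- The balanced design discards the class-size imbalance of real genomes;
  PEI measures predictability, not effect size on coverage.
- GC-corrected tracks can be compared to uncorrected ones simply by running
  the measurement twice; the package does not implement the correction
  itself.
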