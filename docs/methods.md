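# Methods

## Gene models and counting units

A gene model is a set of transcripts on one strand; each transcript is
an ordered list of non-overlapping exon intervals in 1-based inclusive
genomic coordinates (the GFF3 convention, kept internally and in both
writers). Flattening cuts the union of a gene's exons at **every** exon
boundary observed in any transcript, yielding disjoint exonic bins that
partition the exon union exactly; each bin records the transcripts
whose exons cover it. One junction unit is added per distinct intron,
identified by (donor_end, acceptor_start). Effective lengths, which
drive read allocation in the simulator and the ψ normalization, are the
bin length in nt for exonic bins and `read_length − 1` for junctions —
the number of distinct read start positions that span a junction. The
default read length is 100 nt, a standard paired-end sequencing
configuration that yields a usable number of junction-spanning reads.

## Splice events

Two transcripts of a gene are compared through their exon interval
sets. Differing intervals are grouped into *local regions*: maximal
runs of differences not separated by a shared exonic segment. Each
region is classified:

- **SE** — the region is exactly one internal exon of one transcript
  and intronic in the other;
- **IR** — the region is exactly one intron of one transcript and
  fully exonic in the other;
- **A5SS / A3SS** — the region extends an exon past a boundary shared
  on exactly one side; the varying boundary is assigned to the donor or
  acceptor side of the adjacent intron strand-aware (on `+`, an exon's
  right end is a donor; on `−` the roles mirror);
- **MXE** — two non-overlapping internal exons, each private to one
  transcript;
- **complex** — anything else (e.g. an exon skip combined with an
  alternative donor in the same region).

Differences confined to the outer transcript ends are alternative
transcription start/termination, not splicing, and are ignored. This
choice affects gene classification counts on real annotations: a gene
pair differing only by TSS/TES is treated as splicing-identical.

Gene-level classes: a two-transcript gene with exactly one simple event
takes that event's type, with A3SS and A5SS merged into a single
`A3A5SS` class (the two are computationally indistinguishable targets).
Any complex event makes the gene `complex`; several distinct events
make it `multi_event`; genes with more than two transcripts are simple
only when every differing pair agrees on the same single event. For
three-way partitions (A3A5SS / IR / SE), MXE genes belong with
`complex`.

A note on a duality used in the tests: mirroring all coordinates on the
same strand swaps A3SS↔A5SS (donor and acceptor trade sides), while
mirroring *and* flipping the strand is a reverse complement and leaves
every event type fixed.

## Synthetic annotation generator

`synth_annotation` builds non-overlapping genes on one synthetic
chromosome, each constructed to realize a requested AS class and
verified by the classifier at generation time. Class counts follow a
deterministic largest-remainder allocation, so a requested mix is met
exactly; only exon/intron lengths, strands and donor/acceptor choices
are random (seeded). The default class mix (IR 0.40, A3A5SS 0.30,
SE 0.05, complex 0.15, multi_event 0.10) mirrors the splicing landscape
reported for compact plant genomes, where intron retention is the
dominant type (~40%) and exon skipping is rare (~5%). Default length
ranges (exons 60–300 nt, introns 70–400 nt) are likewise plant-like;
both are overridable.

What the generator does **not** emulate: overlapping genes, UTR
structure, sequence content (there are no sequences at all),
non-uniform read coverage along exons, and annotations with more than
two transcripts per gene. Conclusions from passing tests therefore
speak to the statistical behaviour of detectors on idealized counts,
not to alignment- or coverage-induced artifacts in real data.

## Count simulation

Simulation is a two-step scheme per gene and sample:

1. the gene total M ~ NB(μ·depth_factor, α_c) with Var = μ + αμ²;
   α_c is the condition's dispersion under the `Diff` pattern, or the
   control dispersion for both conditions under `Same`;
2. transcript counts ~ Multinomial(M, θ_c); each transcript's count is
   then scattered over its counting units by a second multinomial with
   weights proportional to effective length, and unit counts add up
   across transcripts. Totals are conserved exactly by construction.

Differential splicing is injected via **PALT**: for a true-AS gene the
designated alternative isoform has proportion `palt_control` in
condition 1 and `palt_treatment` in condition 2, the remaining mass
being split equally among the standard isoforms. Canonical contrasts
are 0.2 vs 0.4/0.6/0.8 (low/medium/high). Null multi-isoform genes
draw one symmetric Dirichlet(1) proportion vector and reuse it in both
conditions, making their condition labels exchangeable by construction
— the property that underwrites the null-calibration test. Depth
factors 1.0/0.6/0.25 correspond to 100×/60×/25× coverage scenarios.

NB parameters can be calibrated from a real gene×sample count matrix by
method of moments (μ = sample mean, α = max(0, (s² − m)/m²), pooled or
per-condition), chosen for robustness at the 2–3 replicates typical of
calibration data; negative moment estimates clamp to the Poisson limit.
Without calibration data, synthetic defaults are used: log-normal μ
(median 200 reads, σ_log = 1.5, the right-skewed shape of bulk RNA-seq
totals) and α ~ Uniform(0.05, 0.5) per condition. These defaults are
synthetic, not estimates from any particular data set.

## Detectors

**Unit-fraction permutation test.** Per gene, sample fractions are
unit counts over the gene total (samples with zero total are dropped);
p̂ᵢⱼ and v̂ᵢⱼ are across-replicate means and variances per condition,
and T = (1/U) Σᵢ (p̂ᵢ₁−p̂ᵢ₂)²/(v̂ᵢ₁+v̂ᵢ₂+ε) with ε = 1e−8 flooring
degenerate variances. p-values come from permuting condition labels
jointly across genes. Two regimes:

- *Monte-Carlo* (default): n_perm label permutations sampled with
  replacement; p = (1 + G + U·E)/(n_perm + 1) where G counts permuted
  statistics strictly above the observed one, E counts ties, and U is a
  per-gene Uniform(0,1) draw. Randomizing over ties is deliberate: T is
  label-swap symmetric, so a 3 vs 3 design admits only ~10 distinct
  permutation values, and any deterministic tie rule would lattice the
  null p-values at multiples of ~0.1. The randomized form is exactly
  uniform under the null at any design size and reduces to the familiar
  add-one estimator when there are no ties. Tie detection is
  float-tolerant (complementary label splits reproduce T only up to
  rounding). The deterministic conservative convention is available via
  `ties="count"`.
- *Exact*: all distinct label splits enumerated
  (`exact="always"`, or `"auto"` when there are at most n_perm of
  them); p is the exact tail fraction, deterministic, with minimum
  2/C(n, n₁) on balanced designs.

Genes with fewer than two usable replicates per condition or fewer than
two counting units are flagged NaN, excluded from BH adjustment, and
rank last in evaluation.

**√JSD permutation test.** The statistic is the square root of the
Jensen–Shannon divergence (base 2; √JSD is a metric bounded by 1)
between the two conditions' mean unit-fraction vectors, with the same
permutation machinery.

**ψ bootstrap.** For a simple event, per-sample
ψ = inclusion/(inclusion+exclusion) after dividing each side's summed
counts by its summed effective length (inclusion forms are physically
longer; normalization is on by default and switchable off). The score
is the bootstrap probability that |mean ψ₁ − mean ψ₂| > c, resampling
replicates within condition (default c = 0.1, 1000 draws). Events with
an uncovered condition are flagged rather than scored. This is a
reference construction, not a reimplementation of any published
Bayesian event model.

**Bonferroni gene aggregation.** min(1, k·min p) over k unit-level
p-values, the stringent convention used by region-testing methods.

## Evaluation

ROC curves are exact threshold sweeps over distinct ranking scores;
tied scores contribute one diagonal segment (the unbiased convention).
Targets missing from a method's output are scored −∞ and rank last.
The **restricted AUC** integrates the curve over FPR ∈ [0, 0.2] by
trapezoids, interpolating at the right edge. Because published DAS
AUC tables read on a 0.5-random/1.0-perfect scale while a raw partial
area over [0, 0.2] caps at 0.2, the standardized (McClish) form
½·(1 + (pAUC − pAUC_min)/(pAUC_max − pAUC_min)) is the default and the
raw area is always reported alongside — either convention of a
published table can thus be matched. Recall/precision use a
P_adj ≤ 0.05 cutoff with precision undefined (flagged, not 0) when
nothing is called. Rank concordance is Spearman's ρ with average ranks
over the intersection of targets; BH and Bonferroni adjustments are
delegated to statsmodels.

## Problem sizes and numerical choices

The test suite and the acceptance script run at 1000 genes, 3 vs 3
replicates and 1000 permutations — large enough for stable calibration
estimates (binomial s.e. of a 0.05 rate over 1000 genes ≈ 0.007) and
the scale at which the permutation machinery is fully vectorized.
Dispersion recovery uses 100 replicates per condition and μ = 200,
where the method-of-moments estimator's bias is negligible. All
randomness flows from explicit integer seeds; reruns are byte-identical.

## Known limitations

- The simulator emits unit/junction counts directly; there is no
  read-level model (fragment lengths, GC or positional bias, alignment
  errors), so detector differences caused by alignment are out of reach.
- Permutation p-values at 3 replicates per condition cannot survive BH
  correction at 0.05 over many genes; ranking metrics (pAUC) are the
  informative readout at small sample sizes.
- The event classifier restricts simple classes to locally
  single-difference regions; annotations rich in stacked differences
  will classify largely as complex/multi_event.
- `estimate_nb` is method-of-moments, not maximum likelihood: cheap and
  robust at few replicates, but less efficient than a GLM fit when many
  replicates are available.
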