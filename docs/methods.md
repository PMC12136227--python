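# Methods

`dualmpra` implements the computational side of a dual-readout episomal
reporter assay: every candidate transcriptional regulatory element (TRE) is
cloned between two reporter cassettes so that a single construct yields a
*promoter* readout (a transcript whose 5' UTR carries a promoter-activity
barcode, paBC) and an *enhancer* readout (a minimal-promoter-driven
transcript whose 3' UTR carries an enhancer-activity barcode, eaBC). The
pipeline turns raw index-mapping and RNA/DNA sequencing reads into
per-element activities, active calls, and duality analytics.

## Pipeline model

**Index construction.** Observed barcodes are error-corrected by greedy
abundance-ordered clustering: barcodes are processed by descending read
count (lexicographic tie-break) and join the earliest-founded cluster whose
*representative* lies within Hamming distance 1, else found a new cluster.
Clustering to the representative (rather than connected components) keeps
the distance-1 guarantee exact and the procedure deterministic; chains
A–B–C with end-to-end distance 2 split. Partial element sequences are
matched to the catalog by orientation-aware prefix comparison
(reverse-complement checked, mismatch budget 3, unique-best-hit rule,
no indel tolerance). A barcode pair (eaBC, paBC) is assigned to element A
only when its support is at least `min_support` (default 3) and at least
`dominance_ratio` (default 5) times the support of every other element seen
with that pair; everything else is discarded as a template-switching chimera
or ambiguity. "Significantly higher" is not quantified in the source
protocol; the ratio test is transparent and both knobs are exposed. Support
is counted in distinct UMIs so PCR jackpots cannot manufacture dominance.
The 3-bp minP tag is demultiplexed by exact match only — 3-mers cannot
absorb errors safely.

**Quantification.** Activity reads are matched to the index with Hamming
distance ≤ 1 to the cluster representative — the same tolerance used during
clustering. (Member-exact matching would silently lose ~18 % of reads at a
1 % per-base error rate on 20-mers; the distance-1 rule recovers every read
with at most one substitution, and ambiguous variants reachable from two
constructs are dropped.) Identical (barcode, UMI) copies collapse to one
molecule; counts are summed over each construct's barcodes per library, with
barcode-level matrices retained for QC and variance estimation. Reads whose
observed minP tag contradicts the index entry are dropped as index
violations.

**Activity and calls.** For element *i*, readout *r* ∈ {P, E}:

* CPM pre-filter: retain elements with CPM above `10 / (smallest DNA library
  size in millions)` in all DNA libraries.
* Control-anchored TMM: standard trimmed-mean-of-M-values machinery
  (reference column by control upper-quartile closest to the mean, double
  trim 30 % on M / 5 % on A, precision-weighted mean of M), with every
  statistic computed **only on negative-control ORF rows**. Factors are
  normalized to geometric mean 1. Because the precision weights use raw
  counts, exact absorption of a library-wide scale factor holds when control
  M-values are constant (e.g. an exactly doubled library); otherwise it is
  near-exact (weight perturbations of order 1e-4 in log2 activity, and a
  few-percent non-transitivity when the reference column changes).
* Activity `A = log2((RNA + c) / (DNA + c))` on factor-normalized counts,
  pseudocount c = 0.5 (half-count continuity correction, configurable).
  Replicates are combined by a precision-weighted mean with weights
  `n_barcodes / var(barcode-level log-ratios)` — a deliberate simplification
  of full mean-variance count modelling; with no barcode-level matrix the
  mean is unweighted.
* Boost index `BI_r = A_r / mu_r,ORF` with `mu_r,ORF` the mean control
  activity for that readout (and minP set). Because control-anchored
  normalization tends to pull `mu_ORF` toward 0, the division is refused
  when `|mu_ORF| < 0.05` (it is numerically unstable and inverts sign
  semantics for negative means); z-scores serve as the stable alternative.
  Note that Z-standardization is scale-invariant, so balance categories
  computed from standardized activities equal those from standardized boost
  indices whenever `mu_ORF > 0`.
* Active calls: `z = (A − mu_ORF) / sigma_ORF` per orientation, one-sided
  normal p, Benjamini–Hochberg per (readout, minP, orientation) over
  candidate elements (controls define the null and are excluded from the
  tested set), active iff adjusted p < alpha in **both** cloned
  orientations. The multiple-testing procedure is a declared default, not
  inherited from the protocol.

**Duality analytics.** Balance index `Bal = Z_P − Z_E` on vectors
standardized over the scored element set (controls excluded; sample SD,
ddof = 1); ±1 cutoffs give promoter-dominant / enhancer-dominant / balanced.
Activity ratio `R = BI_P − BI_E` with descending average ranks and tertiles
at the 33.3/66.7 percentiles (boundary values fall to the lower tertile).
Variant effects `dBI = BI_mut − BI_wt` per readout, only for variants with
both alleles scored; one-sample t vs 0 and Spearman coupling between
readouts. Concordance reports `rate(E|P) = |P∩E|/|P|` and `rate(P|E)` as
percentages (half-up, one decimal). Bland–Altman: bias ± 1.96·SD limits of
agreement and the fraction of points within. GC content counts G+C over the
full length; N counts toward the denominator only and flags the sequence.

**Genomic context.** Proximity: an element is proximal when its edge
distance to the nearest annotation interval (after merging, so duplicated
annotations are harmless) is < 500 bp; 0 inside intervals; BED-convention
coordinates throughout. Windowed signal supports the full criterion grid —
within-boundaries total, plus {flank-only, within-plus-flank} × {total,
mean} × {100, 250, 500} bp — with flanks downstream of forward and upstream
of reverse elements, and mean ≡ total / window length exactly.
Out-of-bounds windows clip with a warning. Reciprocal overlap requires the
intersection to cover at least `min_frac` of *both* intervals; one-to-many
matches resolve by largest intersection, ties to the leftmost partner
start.

## Simulator

The generator emulates the assay's statistical structure so every stage is
testable without external data:

* catalog of proximal / distal / ORF-control elements on a toy chromosome,
  sequences drawn from class-specific base compositions (GC defaults 0.60 /
  0.45 / 0.52) — GC is controlled by composition, not by sampling real
  sequence;
* latent (promoter, enhancer) activities per element from a bivariate
  normal with class mean/SD (defaults: proximal 2.0, distal 1.0, controls
  fixed at basal 0, SD 1 for candidates) and correlation
  `true_activity_corr` (default 0.8); each element is cloned in both
  orientations, reverse latents equal to forward plus optional asymmetry
  noise;
* barcode index with ≥ 10 pairs per construct (the assay's design minimum),
  eaBC collisions at `collision_rate`, and read-level chimeras at
  `chimera_rate`;
* index reads drawn as `3 + Poisson(mean − 3)` per pair — the floor models
  colony-level amplification (every cloned pair is deeply covered) and is
  what makes the noiseless round trip exact;
* molecule counts: per-pair abundance λ ~ `mean · LogNormal(0, sdlog)`
  shared across readouts and replicates, DNA ~ Poisson(λ), RNA ~
  Poisson(λ · 2^activity · ε) with log-normal ε (SD 0.3). This
  log-normal–Poisson RNA noise model is a stand-in chosen to match the
  overdispersion typical of reporter counts — **it is not derived from
  data**, and no published noise model exists for this assay;
* reads with iid per-base substitutions (default 0.1 %), UMI tagging, and
  PCR duplication at `1 + Poisson(mean)` copies per molecule; FASTQ written
  with flat Q37 qualities.

What the simulator does *not* model: chromatin context, splicing,
poly(A) read-through, quality-score structure, indels, adapter content
(raw-read filtering is an upstream external step recorded in the manifest),
and any sequence-driven activity. Passing recovery tests therefore shows the
pipeline inverts its own generative assumptions, not that those assumptions
capture all real-data pathologies.

## Reference experiments and their sizes

`dualmpra.benchmarks` fixes the package's standard studies:

* **Recovery**: 450 candidates + 50 controls, 10 barcode pairs each, both
  orientations, 2 replicates, benchmark depth 4 molecules/barcode (~1.4 M
  reads, ~10 s); reports Spearman(latent, estimated A) per readout. The
  depth keeps mean DNA coverage per construct far above the 10-raw-count
  pre-filter floor, as in a full-scale assay; at much lower depth the floor
  clips the log-normal abundance tail and silently drops one orientation of
  a few percent of constructs, capping both-orientation sensitivity.
* **Spike**: 100 true actives at +2 log2 among 400 exact nulls (+50
  controls); sensitivity and observed FDR of the both-orientation calls at
  alpha 0.05.
* **Null calibration**: 1000 basal elements, ideal counts, 500 ORF controls.
  The large control set is deliberate: the plug-in z-test inherits the
  sampling error of the estimated control SD, so with only ~100 control
  measurements the realized positive rate fluctuates well beyond binomial
  noise (±~0.02 across seeds); at ~1000 control measurements that component
  is below the binomial one and the rate sits near alpha. This is a known
  property of plug-in z-calling worth remembering when control panels are
  small.
* **Balance null**: 20 000 independent standardized pairs; balanced
  fraction vs the closed form `P(|N(0, 2)| ≤ 1) ≈ 0.5205`.

## Numerical choices and degenerate inputs

Ties in clustering break lexicographically; equal-best element matches are
no-hits; ambiguous barcode variants are dropped rather than guessed;
zero-SD control sets, < 2 usable controls, empty catalogs, and zero-size
libraries raise typed errors (`ConfigurationError` names the offending
field). All randomness flows from the single config seed through
per-stage `numpy` Generator streams, so reruns are byte-identical.

## Known limitations

* Mismatch-only element matching; indel-containing prefixes become no-hits.
* UMI collapse is exact-sequence; directional network collapse at distance
  1 is intentionally not applied (identical copies only).
* The replicate precision weighting is a simplification of mean-variance
  modelling; with one replicate it reduces to a plain log-ratio.
* Boost indices are undefined (refused) when the control mean activity is
  near zero — the common regime under control-anchored normalization.
* Reciprocal-overlap resolution is per-A greedy, not a global matching.
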