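# Methods

This note documents the models behind each stage, the defaults and why they
hold, what the synthetic generator does and does not emulate, and the
numerical choices a maintainer would otherwise have to reverse-engineer.

## Coordinates and sequences

All intervals are 0-based half-open (BED convention); printed 1-based
inclusive spans convert by `start − 1`, and loaders accept
`one_based_inclusive=True` for tables written that way (journal text is
often inconsistent about which convention a printed span uses, so the flag
is per-file). Genomes are uppercase over `{A,C,G,T,N}`; soft-masked
(lowercase) input is uppercased rather than excluded — masking-aware
scanning is out of scope. Any scan window containing `N` scores `−∞` and is
excluded, which avoids inventing an `N` emission probability.

## Core-promoter refinement

Histone-mark promoter calls are coarse (hundreds of bp to kb). The refiner
slides a fixed window (default **200 bp**, step 1) across the coarse
promoter and returns the window maximizing a promoter-propensity score.
Published core-promoter predictors use GC content plus DNA structural
profiles; their internals are not reproducible from the source study, so
the default scorer here is a declared stand-in: the window's GC fraction
z-scored against the genome-wide distribution of 200-bp window GC
(mean/SD estimated by tiling the loaded genome). The scorer is an object
with a `score_windows(seq)` method, so a structural-profile scorer can be
substituted without touching the refiner. Ties break to the leftmost
maximal window (determinism); refinement always runs on the genomic plus
strand (site scanning is two-stranded anyway, so the choice is neutral).
Promoters shorter than the window are returned whole and flagged
`truncated`. Whether the original analysis kept a single best window or
all windows above a threshold is not recorded; single-best is the default
(`refine_core_promoter`), which is the conservative choice for the
downstream ±15-kb search region.

## PWM scanning and top-K selection

Count matrices (TRANSFAC block or JASPAR letter-row dialects, parsed with
Bio.motifs) become probability matrices via
`p = (count + pc) / (Σ count + 4·pc)` with pseudocount 0.25. Hits score in
bits as summed log₂ odds against the background; the default background is
uniform 0.25 (keeps worked examples closed-form), with a genome-derived
mononucleotide background available. Every offset of each promoter search
region (core ± **15 kb**, clipped to the chromosome) is scored on both
strands — the minus strand by scoring the plus-strand sequence with the
reverse-complemented matrix; minus-strand hit coordinates refer to the
plus strand. Candidate sites are the pooled **top K = 500** hits across
all matrices and all regions, with the deterministic tie-break
(score desc, chrom, start, strand, matrix id). Per-matrix selection is
available by flag. Overlapping hits, including from different matrices,
are all kept: per-miRNA site counts in this study design are sums over
matrices and loci, not unions (counts reported per mature miRNA sum over
all pri-miRNA loci listing it). The pipeline's scan threshold defaults to
0 bits — windows likelier under the background than under the motif can
never reach a desk-scale top-K, and the cutoff keeps hit lists small.

`relative_position` of a hit is the signed distance from the promoter
anchor on the transcript's strand (negative = upstream); the pipeline
anchors at the core window start for plus-strand and core end for
minus-strand transcripts.

## Rank-product differential expression

Normalization default is **within-condition quantile normalization**:
replicates of one condition are forced onto their common mean quantile
vector. Global quantile normalization (all columns) is available
(`normalize="global"`) but is not the default, for a measured reason: with
a sizable regulated fraction (the emulated design has ~10% up and ~10%
down at fold change 4), forcing GM and DM onto one distribution compresses
true fold changes at the tails (observed 2.5–4.6× ratios shrink to ~2×)
and costs real sensitivity. Within-condition normalization removes
technical between-array variation while preserving between-condition
biology. Ties map to the average of the tied mean quantiles, which makes
the transform idempotent.

The rank product for a probe is the geometric mean of its fold-change
ranks over replicate pairs (rank 1 = most changed in the chosen
direction). Replicate pairing is **index-matched** by default (r-th DM
with r-th GM, k = min of the replicate counts): matched pairs share no
samples, so under the null the per-pair fold changes are independent and
the within-pair permutation null is exact — measured null p-values are
uniform (KS ≈ 0.03 at N = 500). All-cross pairing (k = r_DM·r_GM) is
available but its pairs share replicates, which correlates the per-pair
ranks and demonstrably distorts the permutation p-values (KS ≈ 0.13 under
the same null); it should be used only for point ranking, not inference.
P-values use +1 smoothing, `p = (1 + #{RP_null ≤ RP_obs}) / (n_perm + 1)`,
so finite sampling never reports zero. `exact=True` enumerates all
`(N!)^k` within-pair permutations for tiny problems, which is how the
sampled estimator is validated. Regulated sets are fold change > **2**
(down: < 1/2) at p ≤ **0.05**; raw permutation p-values are reported
(the emulated study reported uncorrected p-values), with an optional
Benjamini–Hochberg column.

## Sliding-window target enrichment

Probes are ordered most-up → most-down by ascending up-direction rank
product (fold change selectable), ties broken by probe id. A probe is
flagged 1 when *any* pri-miRNA locus of its mature miRNA carries ≥ 1
selected site. The curve is the mean flag in each **300-probe** window at
step **1**; the reference is the expected average Σflags/N, and a
pointwise band comes from element-wise quantiles over random flag
shuffles. Data tables index windows by start; plots map a window to the
probe rank at its center. Note an intrinsic property of this statistic:
because the background includes the flagged head itself, window means
averaged over the whole head *third* sit below the background whenever
the flagged block is much shorter than the window — the meaningful
comparison is between windows containing the planted/regulated block and
the background, which is what the tests assert.

## Seed matching

The seed is mature-miRNA positions 2–8 (1-based). On the UTR the scanner
anchors on the reverse complement of positions 2–7 and classifies
canonically: 8mer (seed match + match at position 8 + A opposite position
1), 7mer-m8, 7mer-A1, 6mer (reported only on request; default minimum
class "7mer" = either 7mer or better). U/T are interchangeable on input;
positions are 0-based on the UTR as given. No context scores,
conservation or free-energy terms — those belong to the external target
predictors this module stands in for. One documented corner: a site
spelled `ACATTC` (complement of miRNA positions 3–8) is an offset 6mer,
not a canonical 2–7 anchor, and is intentionally not reported by the
canonical classes.

## Network

Typed nodes (TF, miRNA, gene) and typed directed repressions
(transcriptional TF→miRNA, post-transcriptional miRNA→gene) in a networkx
DiGraph; a target gene named like the TF collapses onto the TF node, which
is what makes feedback representable. "Feedback loop" means exactly the
2-cycle TF⊣miRNA⊣TF; longer cycles are out of scope. Duplicate edges merge
their provenance labels. Literature edges enter via a tab-separated edge
table, never hard-coded. Export: SIF (short relations `represses-tx`,
`represses-pt`) and GraphML with node/edge attributes, both in
deterministic order.

## Synthetic study: what it emulates, and why these defaults

Every artifact flows from one seed through spawned child generators, and
file-writing stages record the seed in `provenance.json`.

- **Genome**: one 500-bp "cassette" chromosome per pri-miRNA holding a
  400-bp coarse promoter with a designated GC-rich (0.60) 200-bp core;
  i.i.d. background at GC 0.42 (mouse-like). The ±15-kb search region
  clips to the cassette. Rationale: an 8-nt consensus with two free
  positions matches background with probability ≈ 3.1×10⁻⁴ per position
  at GC 0.42, so a 500-bp cassette gives λ ≈ 0.3 expected chance sites per
  promoter — a background flag fraction (~25%) of the same order as the
  emulated study's observed target fraction ((30+27)/373 ≈ 15%). Genome
  scale cannot be increased without the consensus drowning in its own
  background matches; information-rich matrices, not longer sequence, are
  what make genome-scale scans sparse.
- **Planted sites**: 12 exact consensus instances (random N resolutions,
  random strand) inside each target's core window. Candidate promoters in
  this study design carry clustered sites (published per-miRNA counts run
  1–33, mean ≈ 8); clustering also puts the planted total (480) near the
  top-K budget (500), so pooled selection is a competition among genuine
  full-scoring sites rather than threshold fill-in.
- **Scan matrix**: a single count matrix sampled multinomially
  (24 observations, 88% of the mass on the consensus bases) rather than a
  flat consensus matrix. Empirical database matrices give consensus
  occurrences a continuous score spectrum; with a perfectly flat matrix
  every occurrence ties at the maximum and the deterministic tie-break
  truncates whole late-sorting chromosomes, an artifact no real matrix
  produces.
- **Expression**: baseline log₂ intensities ~ Normal(8, 1); up/down
  probes shift by ±log₂(4); every cell adds Normal(0, 0.25) log₂ noise;
  two replicates per condition. 10% of probes up and 10% down; the 40
  target miRNAs are planted among the up-regulated set (padded with random
  non-targets if the up budget exceeds the target count).
- **UTRs**: 1000-nt random UTRs; each target miRNA gets one downstream
  gene with 2 planted 7mer-m8 sites, and the TF's UTR carries one site per
  designated feedback miRNA (default: the first target), closing the loop
  end to end. Planted sites guard their context bases so the planted class
  is exactly 7mer-m8.

Not emulated: probe cross-hybridization, array spatial/batch effects,
chromatin tracks, real promoter sequence composition, conserved motif
flanks, multi-locus mature miRNAs (the generator is 1:1; multi-locus
counting is exercised by hand-built fixtures in the tests). A green
end-to-end test therefore establishes that the pipeline recovers planted
signal with calibrated statistics under idealized noise — not that it
would rediscover biology from real arrays.

## Numerical choices

- Tie-breaks are deterministic everywhere (documented per stage above);
  reruns with one seed are byte-identical.
- Intensity floor 10⁻⁶ before ratios; fold changes of floored
  denominators are logged, not errors.
- Permutation p-values never return 0 (+1 smoothing); default
  n_perm = 1000 in the config, 500 in the bundled end-to-end runs (the
  p-grid at 500 is finer than the 0.05 decision threshold needs).
- The enrichment stage clamps the 300-probe window to N/4 with a warning
  when a study has fewer than 300 probes; the primitive itself refuses
  w > N.
- Seeds derived from the user seed stay below 2³¹.

## Known limitations

- The GC z-score core scorer is a stand-in: it finds GC-defined cores by
  construction and will be weak on AT-rich core promoters.
- Rank-product p-values are marginal, not joint; probes sharing a
  permutation are correlated, so family-wise error control needs the
  optional BH column.
- Site counts sum overlapping hits from different matrices; with four
  near-identical matrices a single physical site can count four times
  (matching the emulated study's counting, but worth knowing).
- The seed module scores presence/absence only; it will over-call targets
  relative to context-aware predictors.
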