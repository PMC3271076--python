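# mircircuit

Genome-wide discovery of transcription-factor→miRNA regulatory circuits,
built for the promoter-centric study design used in skeletal myogenesis:
a repressive TF (YY1) silences muscle miRNAs (miR-1/miR-133/miR-206) in
myoblasts, the miRNAs are induced on differentiation, and some of them
target the TF's own 3′UTR, closing negative feedback loops. The package is
aimed at computational biologists who want to run, dissect or re-validate
this class of pipeline on their own annotation, motif and expression data —
or on a fully synthetic study it can generate itself.

## The pipeline

1. **Core-promoter refinement.** Histone-mark-derived pri-miRNA promoter
   annotations are coarse. Each promoter is refined to a 200-bp core window
   by maximizing a promoter-propensity score over all windows (step 1); the
   default scorer is the window GC fraction z-scored against the
   genome-wide 200-bp GC distribution (pluggable).
2. **Binding-site scanning.** The core window ± 15 kb is scanned on both
   strands with position weight matrices. A window *w* scores
   `S(w) = Σᵢ log₂(pᵢ(wᵢ)/b(wᵢ))` bits; candidate sites are the pooled
   **top K = 500** hits across all matrices and regions. An IUPAC consensus
   scanner (e.g. `CCATNTTN` for YY1) covers the degenerate-pattern search.
3. **Differential expression.** Probe intensities (growth medium GM vs
   differentiation medium DM, replicated) are quantile normalized and
   ranked by the **rank product**: per replicate pair the probe's fold
   change is ranked across probes, and `RP = (Πₖ rankₖ)^{1/k}`;
   significance comes from within-pair label permutations. Regulated sets
   are fold change > 2 at permutation p ≤ 0.05.
4. **Target enrichment.** Probes ordered most-up → most-down are flagged
   when their miRNA gene carries ≥ 1 selected site; the 300-probe sliding
   window (step 1) moving average is compared with the expected average
   (flagged/total) and a permutation envelope.
5. **Seed targets and feedback.** miRNA→gene edges come from canonical
   seed matching on 3′UTRs (8mer, 7mer-m8, 7mer-A1, optional 6mer; the
   seed is miRNA positions 2–8). A miRNA that is repressed by the TF and
   carries a seed site on the TF's own UTR is reported as a feedback
   2-cycle. The network exports to SIF/GraphML for Cytoscape.

A synthetic-study generator (`SyntheticStudyConfig`, `generate_study`)
emits genome, annotation, matrices, expression and UTR files in exactly
the formats the loaders consume, with truth tables, so the whole pipeline
is testable without any external download.

## Worked example

`examples/04_seed_targets_and_feedback.py` reproduces the canonical miR-1
worked example:

```
miR-1 seed (2-8): GGAAUGU  -> UTR site ACATTCC
Pax7 sites: [(1557, '7mer-m8'), (2100, '7mer-m8')]
YY1 site: [(440, '7mer-m8')]
YY1 mutant site: []
feedback loops through YY1: ['miR-1']
```

miR-1's seed reverse-complement `ACATTCC` is found at both planted Pax7
3′UTR offsets and on the YY1 UTR; mutating the site to `GGGCCTT` abolishes
detection, and miR-1 is reported as the miRNA closing the YY1 feedback
loop.

`examples/05_full_pipeline.py` runs every stage on the default synthetic
world (400 probes, 40 planted TF-target miRNAs):

```
candidates=38  precision=1.000  recall=0.950
enrichment background=0.278  head windows mean=0.289
```

Candidates are up-regulated miRNAs carrying ≥ 1 selected site; precision
and recall compare them with the planted target set, and the enrichment
curve exceeding its background over the head windows is the ranked-list
signature of TF-target enrichment. The other examples demonstrate promoter
refinement + scanning, rank-product differential expression and the
sliding-window statistic in isolation.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default synthetic study from the seed, executes the full
pipeline (promoter refinement → scanning → top-K selection → rank-product
differential expression → enrichment curve → seed targets → network), and
prints the recovery summary before writing the JSON result file.

## Layout

- `src/mircircuit/` — `intervals`, `formats`, `promoters`, `motifs`,
  `expression`, `enrichment`, `seeds`, `network`, `simulate`, `pipeline`
- `examples/` — one short narrative script per capability
- `docs/methods.md` — models, assumptions, parameter choices, limitations
- `tests/` — pytest suite (unit, property and acceptance tests)
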