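"""Synthetic study generator: genome, annotation, expression, UTRs, truth tables.

Emits exactly the formats the loaders consume, plus truth tables for tests.
The default world is a desk-scale miniature of a TF->miRNA promoter study:

* one 500-bp locus "cassette" chromosome per pri-miRNA holding a 400-bp
  coarse promoter (the search region, core +/- 15 kb, clips to the
  cassette). The cassette length keeps the expected background consensus
  count per promoter near 0.3, so the background target-flag fraction is
  of the same order as a genome-scale scan with information-rich matrices
  produces; see docs/methods.md for the arithmetic;
* i.i.d. background at mouse-like GC 0.42, with a designated GC-rich 200-bp
  core window per promoter so GC-based refinement is informative;
* exact consensus instances (random N resolutions) planted only in the core
  windows of target miRNAs, 12 per target — candidate promoters in this
  kind of study carry clustered sites (counts up to ~30, mean ~8), and the
  planted total (480) sits near the top-K budget (500) so pooled selection
  is a competition among full-scoring sites rather than threshold fill-in;
* a probe intensity matrix, two replicates per condition, with planted up-
  and down-regulation at fold change 4 and multiplicative log-normal noise
  (sigma 0.25 on the log2 scale); target miRNAs are planted among the
  up-regulated probes;
* random 3'UTRs with planted seed-complement sites, including sites on the
  TF's own UTR to create feedback loops.

All randomness flows from ``rng_seed`` through spawned child generators, so
every artifact is reproducible from the one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .formats import BASES, MotifMatrixRecord, ExpressionMatrix, parse_sample_labels
from .intervals import GenomeSequence, GenomicInterval, reverse_complement
from .motifs import IUPAC_CODES
from .promoters import Annotation, PrimiRNATranscript
from .seeds import MatureMiRNA, seed_of

_PLACEMENT_RETRIES = 500


@dataclass
class SyntheticStudyConfig:
    """Parameters of the generated study. Defaults are the stated world."""

    n_chrom: int | None = None  # None: one cassette chromosome per miRNA
    chrom_length: int = 500
    gc_background: float = 0.42
    n_mirnas: int = 400
    n_target_mirnas: int = 40
    motif_consensus: str = "CCATNTTN"
    sites_per_target: int = 12
    n_probes: int = 400
    replicates: int = 2
    de_up_fraction: float = 0.10
    de_down_fraction: float = 0.10
    true_fold_change: float = 4.0
    noise_sigma: float = 0.25
    utr_length: int = 1000
    planted_seed_sites: int = 2
    promoter_width: int = 400
    core_window: int = 200
    core_gc: float = 0.60
    rng_seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        for name in ("de_up_fraction", "de_down_fraction", "gc_background", "core_gc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name}={v} outside [0,1]")
        for name in (
            "chrom_length", "n_mirnas", "n_probes", "replicates",
            "utr_length", "promoter_width", "core_window", "chrom_length",
        ):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be positive")
        if self.n_target_mirnas > self.n_mirnas:
            problems.append("n_target_mirnas > n_mirnas")
        if self.n_probes < self.n_mirnas:
            problems.append("n_probes < n_mirnas (every mature miRNA needs a probe)")
        if self.core_window > self.promoter_width:
            problems.append("core_window > promoter_width")
        if self.promoter_width > self.chrom_length:
            problems.append("promoter_width > chrom_length")
        if any(c not in IUPAC_CODES for c in self.motif_consensus.upper()):
            problems.append(f"motif_consensus {self.motif_consensus!r} not IUPAC")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))

    def spawn_rngs(self, n: int) -> list:
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.rng_seed).spawn(n)]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticStudy:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SyntheticStudyConfig
    genome: dict
    annotation: Annotation
    pwm_record: MotifMatrixRecord
    site_truth: pd.DataFrame
    expression: ExpressionMatrix
    expression_truth: pd.DataFrame
    mirna_seqs: dict
    utrs: dict
    utr_truth: pd.DataFrame
    tf_id: str
    target_mirnas: list = field(default_factory=list)


def _random_dna(rng, n: int, gc: float) -> str:
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]
    return "".join(rng.choice(list(BASES), size=n, p=probs))


def _resolve_iupac(rng, pattern: str) -> str:
    return "".join(rng.choice(list(IUPAC_CODES[c])) for c in pattern.upper())


def consensus_count_matrix(
    consensus: str, observations: int = 24, rng=None
) -> MotifMatrixRecord:
    """A count matrix whose consensus is the given IUPAC pattern.

    Without ``rng`` each position distributes ``observations`` counts evenly
    over the bases the code admits (an N position is flat) — handy for
    closed-form tests. With ``rng`` the counts are a multinomial sample of
    ``observations`` binding-site observations (88% of the mass on the
    admitted bases), i.e. an empirical-style matrix: scores of consensus
    occurrences then spread over a continuum instead of tying at one
    maximum, like database matrices built from real site collections.
    """
    counts = np.zeros((len(consensus), 4))
    for i, code in enumerate(consensus.upper()):
        allowed = IUPAC_CODES[code]
        if rng is None:
            for b in allowed:
                counts[i, BASES.index(b)] = observations / len(allowed)
        else:
            p = np.empty(4)
            for j, b in enumerate(BASES):
                if len(allowed) == 4:
                    p[j] = 0.25
                elif b in allowed:
                    p[j] = 0.88 / len(allowed)
                else:
                    p[j] = 0.12 / (4 - len(allowed))
            counts[i] = rng.multinomial(observations, p)
            if counts[i].sum() == 0:  # pragma: no cover - multinomial total fixed
                counts[i] = 1.0
    return MotifMatrixRecord(f"SYN_{consensus.upper()}", counts)


def _mature_name(i: int) -> str:
    return f"syn-miR-{i + 1:03d}"


def _pri_name(i: int) -> str:
    return f"syn-pri-miR-{i + 1:03d}"


def make_genome_with_promoters(config: SyntheticStudyConfig, rng=None):
    """Generate (genome, annotation, target list, planted-site truth table).

    Target miRNAs receive ``sites_per_target`` exact consensus instances
    (random N resolutions, random strand) inside their designated GC-rich
    200-bp core window. The truth table records every planted coordinate.
    """
    if rng is None:
        rng = config.spawn_rngs(4)[0]
    n = config.n_mirnas
    n_chrom = n if config.n_chrom is None else config.n_chrom
    per_chrom = -(-n // n_chrom)  # ceil
    slot = config.chrom_length // per_chrom
    if slot < config.promoter_width:
        raise ValueError(
            f"{per_chrom} promoters of width {config.promoter_width} do not fit a "
            f"{config.chrom_length}-bp chromosome"
        )

    target_idx = set(rng.choice(n, size=config.n_target_mirnas, replace=False).tolist())
    chrom_seqs: dict[str, list] = {}
    transcripts: list[PrimiRNATranscript] = []
    truth_rows = []
    width = len(config.motif_consensus)

    for i in range(n):
        ci, pos_in_chrom = divmod(i, per_chrom)
        chrom = f"chr{ci + 1:04d}"
        if chrom not in chrom_seqs:
            chrom_seqs[chrom] = list(_random_dna(rng, config.chrom_length, config.gc_background))
        slack = slot - config.promoter_width
        pstart = pos_in_chrom * slot + int(rng.integers(0, slack + 1))
        pend = pstart + config.promoter_width
        strand = "+" if rng.random() < 0.5 else "-"

        # designated GC-rich core window inside the coarse promoter
        core_off = int(rng.integers(0, config.promoter_width - config.core_window + 1))
        core_start = pstart + core_off
        core = list(_random_dna(rng, config.core_window, config.core_gc))

        pri, mature = _pri_name(i), _mature_name(i)
        if i in target_idx:
            placed: list[tuple[int, int]] = []
            for _ in range(config.sites_per_target):
                for _try in range(_PLACEMENT_RETRIES):
                    off = int(rng.integers(0, config.core_window - width + 1))
                    if all(off + width <= s or off >= e for s, e in placed):
                        break
                else:
                    raise RuntimeError("could not place non-overlapping sites in core window")
                placed.append((off, off + width))
                site_seq = _resolve_iupac(rng, config.motif_consensus)
                site_strand = "+" if rng.random() < 0.5 else "-"
                planted = site_seq if site_strand == "+" else reverse_complement(site_seq)
                core[off : off + width] = list(planted)
                truth_rows.append(
                    {
                        "pri_id": pri, "mature_id": mature, "chrom": chrom,
                        "start": core_start + off, "end": core_start + off + width,
                        "strand": site_strand, "site_seq": site_seq,
                    }
                )
        chrom_seqs[chrom][core_start : core_start + config.core_window] = core
        promoter = GenomicInterval(chrom, pstart, pend, strand)
        transcripts.append(PrimiRNATranscript(pri, [mature], promoter, promoter, None))

    genome = {c: GenomeSequence(c, "".join(s)) for c, s in chrom_seqs.items()}
    mature_to_pri: dict[str, list] = {}
    for t in transcripts:
        for m in t.mature_ids:
            mature_to_pri.setdefault(m, []).append(t.pri_id)
    annotation = Annotation(transcripts, mature_to_pri)
    targets = sorted(_mature_name(i) for i in target_idx)
    truth = pd.DataFrame(
        truth_rows,
        columns=["pri_id", "mature_id", "chrom", "start", "end", "strand", "site_seq"],
    )
    return genome, annotation, targets, truth


def simulate_expression(config: SyntheticStudyConfig, targets: list, rng=None):
    """Generate (ExpressionMatrix, truth labels) with planted regulation.

    Baseline log2 intensities ~ Normal(8, 1). The up-regulated set is the
    target miRNAs padded with random non-targets up to
    ``round(de_up_fraction * n_probes)``; the down set is drawn from the
    remainder. DM3 replicates shift by +/- log2(true_fold_change); every
    cell gets Normal(0, noise_sigma) log2 noise, then intensities are
    exponentiated (multiplicative log-normal noise).
    """
    if rng is None:
        rng = config.spawn_rngs(4)[1]
    probes = [_mature_name(i) for i in range(config.n_mirnas)]
    probes += [f"syn-ctrl-{i + 1:03d}" for i in range(config.n_probes - config.n_mirnas)]
    n = len(probes)

    n_up = int(round(config.de_up_fraction * n))
    n_down = int(round(config.de_down_fraction * n))
    if len(targets) > n_up:
        raise ValueError(f"{len(targets)} targets exceed the up-regulated budget {n_up}")
    up = list(targets)
    pool = [p for p in probes if p not in set(up)]
    extra = rng.choice(len(pool), size=n_up - len(up), replace=False) if n_up > len(up) else []
    up += [pool[int(j)] for j in np.sort(np.asarray(extra, dtype=int))]
    remaining = [p for p in probes if p not in set(up)]
    down_pick = rng.choice(len(remaining), size=n_down, replace=False)
    down = [remaining[int(j)] for j in np.sort(down_pick)]

    shift = np.zeros(n)
    up_set, down_set = set(up), set(down)
    for i, p in enumerate(probes):
        if p in up_set:
            shift[i] = np.log2(config.true_fold_change)
        elif p in down_set:
            shift[i] = -np.log2(config.true_fold_change)

    baseline = rng.normal(8.0, 1.0, size=n)
    columns, labels = [], []
    for cond, delta in (("GM", 0.0), ("DM3", 1.0)):
        for r in range(1, config.replicates + 1):
            log2_int = baseline + delta * shift + rng.normal(0.0, config.noise_sigma, size=n)
            columns.append(np.exp2(log2_int))
            labels.append(f"{cond}_{r}")
    values = pd.DataFrame(np.column_stack(columns), index=pd.Index(probes, name="probe_id"),
                          columns=labels)
    conditions, replicates = parse_sample_labels(labels)
    truth = pd.DataFrame(
        {
            "probe_id": probes,
            "regulation": ["up" if p in up_set else "down" if p in down_set else "none"
                           for p in probes],
            "is_target": [p in set(targets) for p in probes],
        }
    ).set_index("probe_id")
    return ExpressionMatrix(values, conditions, replicates), truth


def generate_mirna_sequences(config: SyntheticStudyConfig, rng=None) -> dict:
    """Random 22-nt mature miRNA sequences, one per mature id."""
    if rng is None:
        rng = config.spawn_rngs(4)[2]
    out = {}
    for i in range(config.n_mirnas):
        name = _mature_name(i)
        seq = _random_dna(rng, 22, 0.5).replace("T", "U")
        out[name] = MatureMiRNA(name, seq)
    return out


def _plant_site(rng, utr: list, seed7_dna: str, occupied: list) -> int:
    """Plant one 7mer-m8 site (revcomp of the 7-nt seed) at a free offset."""
    width = 7
    site = reverse_complement(seed7_dna)
    for _try in range(_PLACEMENT_RETRIES):
        off = int(rng.integers(1, len(utr) - width - 1))
        if all(off + width + 1 <= s or off - 1 >= e for s, e in occupied):
            break
    else:
        raise RuntimeError("could not place non-overlapping seed sites in UTR")
    utr[off : off + width] = list(site)
    # avoid an accidental A1 so the planted class is exactly 7mer-m8
    if utr[off + width] == "A":
        utr[off + width] = "C"
    occupied.append((off, off + width))
    return off


def make_utrs(
    config: SyntheticStudyConfig,
    tf_id: str,
    mirna_seqs: dict,
    target_mirnas: list,
    feedback_mirnas: list | None = None,
    rng=None,
):
    """Generate (UTR map gene -> sequence, truth table of planted seed sites).

    Each target miRNA gets one downstream gene UTR carrying
    ``planted_seed_sites`` sites; the TF's own UTR carries one site per
    feedback miRNA (default: the first target miRNA), which is what closes
    the TF <-> miRNA feedback loops end to end.
    """
    if rng is None:
        rng = config.spawn_rngs(4)[3]
    if feedback_mirnas is None:
        feedback_mirnas = target_mirnas[:1]
    utrs: dict[str, str] = {}
    truth_rows = []

    tf_utr = list(_random_dna(rng, config.utr_length, config.gc_background))
    occupied: list[tuple[int, int]] = []
    for m in feedback_mirnas:
        seed_dna = seed_of(mirna_seqs[m]).replace("U", "T")
        off = _plant_site(rng, tf_utr, seed_dna, occupied)
        truth_rows.append({"gene": tf_id, "mirna": m, "position": off, "type": "7mer-m8"})
    utrs[tf_id] = "".join(tf_utr)

    for m in target_mirnas:
        gene = f"tgt-{m}"
        utr = list(_random_dna(rng, config.utr_length, config.gc_background))
        occupied = []
        seed_dna = seed_of(mirna_seqs[m]).replace("U", "T")
        for _ in range(config.planted_seed_sites):
            off = _plant_site(rng, utr, seed_dna, occupied)
            truth_rows.append({"gene": gene, "mirna": m, "position": off, "type": "7mer-m8"})
        utrs[gene] = "".join(utr)

    truth = pd.DataFrame(truth_rows, columns=["gene", "mirna", "position", "type"])
    truth = truth.sort_values(["gene", "position"], ignore_index=True)
    return utrs, truth


def generate_study(config: SyntheticStudyConfig, tf_id: str = "YY1") -> SyntheticStudy:
    """Generate the complete synthetic study from one seed."""
    rngs = config.spawn_rngs(5)
    genome, annotation, targets, site_truth = make_genome_with_promoters(config, rngs[0])
    expression, expr_truth = simulate_expression(config, targets, rngs[1])
    mirna_seqs = generate_mirna_sequences(config, rngs[2])
    utrs, utr_truth = make_utrs(config, tf_id, mirna_seqs, targets, None, rngs[3])
    return SyntheticStudy(
        config=config,
        genome=genome,
        annotation=annotation,
        pwm_record=consensus_count_matrix(config.motif_consensus, rng=rngs[4]),
        site_truth=site_truth,
        expression=expression,
        expression_truth=expr_truth,
        mirna_seqs=mirna_seqs,
        utrs=utrs,
        utr_truth=utr_truth,
        tf_id=tf_id,
        target_mirnas=targets,
    )
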