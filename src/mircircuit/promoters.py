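"""Pri-miRNA promoter annotation, core-promoter refinement, search regions.

Histone-mark-derived promoter annotations locate miRNA promoters only
coarsely. Each coarse promoter is refined to a 200-bp core window by
sliding a window at step 1 and maximizing a promoter-propensity score;
the default scorer is the window GC fraction z-scored against the
genome-wide distribution of 200-bp window GC (a declared stand-in for
GC-content/structural-feature core-promoter prediction, pluggable via
the ``scorer`` argument). The refined core is then extended by a
+/- 15 kb flank to form the binding-site search region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomeSequence, GenomicInterval, extract_sequence

logger = logging.getLogger(__name__)

CORE_WINDOW = 200
DEFAULT_FLANK = 15_000
PROMOTER_SANITY_BOUND = 50_000

_MANDATORY_COLUMNS = ("pri_id", "chrom", "strand", "promoter_start", "promoter_end", "mature_ids")


@dataclass
class PrimiRNATranscript:
    """A primary miRNA transcript with its coarse (histone-mark) promoter."""

    pri_id: str
    mature_ids: list
    locus: GenomicInterval
    promoter: GenomicInterval
    promoter_score: float | None = None

    def __post_init__(self) -> None:
        if not self.mature_ids:
            raise ValueError(f"{self.pri_id}: empty mature_ids")
        if self.promoter.chrom != self.locus.chrom:
            raise ValueError(f"{self.pri_id}: promoter and locus on different chromosomes")


@dataclass
class CorePromoter:
    """A refined fixed-width core-promoter window with its propensity score."""

    transcript: str
    window: GenomicInterval
    core_score: float
    truncated: bool = False  # promoter was shorter than the requested window


@dataclass
class Annotation:
    """Loaded pri-miRNA annotation plus the mature -> pri multimap."""

    transcripts: list = field(default_factory=list)
    mature_to_pri: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.transcripts)

    @property
    def mature_ids(self) -> list:
        return list(self.mature_to_pri)

    def by_pri(self) -> dict:
        return {t.pri_id: t for t in self.transcripts}


def load_annotation(
    path,
    one_based_inclusive: bool = False,
    sanity_bound: int = PROMOTER_SANITY_BOUND,
) -> Annotation:
    """Load a tab-separated pri-miRNA transcript/promoter table.

    Mandatory columns: pri_id, chrom, strand, promoter_start, promoter_end,
    mature_ids (comma-joined). Optional: locus_start, locus_end, score.
    A mature miRNA may be listed by several pri-miRNA loci; the returned
    multimap collects them all.
    """
    df = pd.read_csv(path, sep="\t", dtype={"pri_id": str, "chrom": str})
    missing = [c for c in _MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation missing mandatory column(s): {missing}")

    offset = 1 if one_based_inclusive else 0
    transcripts: list[PrimiRNATranscript] = []
    mature_to_pri: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        raw = "" if pd.isna(row.mature_ids) else str(row.mature_ids)
        mature = [m.strip() for m in raw.split(",") if m.strip()]
        if not mature:
            raise ValueError(f"{row.pri_id}: empty mature_ids")
        pstart = int(row.promoter_start) - offset
        pend = int(row.promoter_end)
        if pend - pstart > sanity_bound:
            raise ValueError(
                f"{row.pri_id}: promoter width {pend - pstart} exceeds sanity bound {sanity_bound}"
            )
        promoter = GenomicInterval(row.chrom, pstart, pend, row.strand)
        lstart = int(getattr(row, "locus_start", pstart)) - (
            offset if hasattr(row, "locus_start") else 0
        )
        lend = int(getattr(row, "locus_end", pend))
        locus = GenomicInterval(row.chrom, lstart, lend, row.strand)
        score = getattr(row, "score", None)
        score = None if score is None or pd.isna(score) else float(score)
        transcripts.append(PrimiRNATranscript(str(row.pri_id), mature, locus, promoter, score))
        for m in mature:
            mature_to_pri.setdefault(m, []).append(str(row.pri_id))
    return Annotation(transcripts, mature_to_pri)


def write_annotation(annotation: Annotation, path) -> None:
    rows = []
    for t in annotation.transcripts:
        rows.append(
            {
                "pri_id": t.pri_id,
                "chrom": t.promoter.chrom,
                "strand": t.promoter.strand,
                "promoter_start": t.promoter.start,
                "promoter_end": t.promoter.end,
                "mature_ids": ",".join(t.mature_ids),
                "locus_start": t.locus.start,
                "locus_end": t.locus.end,
                "score": "" if t.promoter_score is None else t.promoter_score,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Core-promoter scoring
# ---------------------------------------------------------------------------

def _gc_fraction_windows(seq: str, window: int) -> np.ndarray:
    """GC fraction of every ``window``-length substring (vectorized)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(float)
    if len(arr) < window:
        return np.empty(0)
    csum = np.concatenate([[0.0], np.cumsum(is_gc)])
    return (csum[window:] - csum[:-window]) / window


class GCZScoreScorer:
    """Core-promoter scorer: window GC fraction z-scored vs genome background.

    mu and sigma are estimated from the genome by tiling 200-bp windows at a
    fixed stride; a pluggable alternative scorer only needs ``score_windows``.
    """

    def __init__(self, mu: float, sigma: float, window: int = CORE_WINDOW):
        self.mu = mu
        self.sigma = max(sigma, 1e-9)
        self.window = window

    @classmethod
    def from_genome(cls, genome: dict, window: int = CORE_WINDOW, stride: int | None = None):
        stride = stride or window
        fracs = []
        for rec in genome.values():
            seq = rec.sequence if isinstance(rec, GenomeSequence) else rec
            w = _gc_fraction_windows(seq, window)
            fracs.append(w[::stride])
        allw = np.concatenate(fracs) if fracs else np.empty(0)
        if allw.size == 0:
            raise ValueError("genome too short to estimate GC background")
        return cls(float(allw.mean()), float(allw.std()), window)

    def score_windows(self, seq: str) -> np.ndarray:
        return (_gc_fraction_windows(seq, self.window) - self.mu) / self.sigma


def refine_core_promoter(
    transcript: PrimiRNATranscript,
    genome: dict,
    window: int = CORE_WINDOW,
    scorer=None,
) -> CorePromoter:
    """Slide a fixed window across the coarse promoter and keep the best one.

    Ties break to the leftmost maximal window (strand-independent; scanning
    is two-stranded downstream anyway). A promoter shorter than the window
    is returned whole, flagged ``truncated``.
    """
    if scorer is None:
        scorer = GCZScoreScorer.from_genome(genome, window)
    promoter = transcript.promoter
    seq = extract_sequence(
        genome, GenomicInterval(promoter.chrom, promoter.start, promoter.end, "+")
    )
    if promoter.width < window:
        whole = GCZScoreScorer(scorer.mu, scorer.sigma, promoter.width) if isinstance(
            scorer, GCZScoreScorer
        ) else scorer
        scores = whole.score_windows(seq)
        score = float(scores[0]) if scores.size else float("nan")
        logger.warning("promoter %s shorter than %d bp; returning whole", transcript.pri_id, window)
        return CorePromoter(transcript.pri_id, promoter, score, truncated=True)
    scores = scorer.score_windows(seq)
    best = int(np.argmax(scores))  # argmax returns the first (leftmost) maximum
    win = GenomicInterval(
        promoter.chrom, promoter.start + best, promoter.start + best + window, promoter.strand
    )
    return CorePromoter(transcript.pri_id, win, float(scores[best]))


def promoter_search_region(
    core: CorePromoter, flank: int = DEFAULT_FLANK, chrom_len: int | None = None
) -> GenomicInterval:
    """Extend the core window by ``flank`` bases on both sides, clipped to the chromosome."""
    start = max(0, core.window.start - flank)
    end = core.window.end + flank
    if chrom_len is not None:
        end = min(chrom_len, end)
    if start != core.window.start - flank or (chrom_len is not None and end != core.window.end + flank):
        logger.debug("search region for %s clipped to [%d, %d)", core.transcript, start, end)
    return GenomicInterval(core.window.chrom, start, end, core.window.strand)
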