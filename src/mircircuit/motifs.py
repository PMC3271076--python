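"""PWM construction, log-odds scoring, two-strand scanning, top-K selection.

A PWM hit is scored in bits as the summed log2 ratio of the position
probability to the background probability. Scanning a promoter search
region scores every offset on both strands; genome-wide candidate sites
are then the pooled top-K hits across all matrices and regions (default
K = 500). Windows containing N score -inf and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .formats import BASES, MotifMatrixRecord
from .intervals import GenomicInterval, extract_sequence

UNIFORM_BACKGROUND = np.full(4, 0.25)

_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_INDEX[ord(_b)] = _i

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to indices A=0,C=1,G=2,T=3; anything else (N) -> -1."""
    return _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PWM:
    """Position probability matrix with background, scored as log2 odds (bits)."""

    id: str
    probs: np.ndarray  # (L, 4) over A,C,G,T
    background: np.ndarray = None
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        bg = UNIFORM_BACKGROUND if self.background is None else np.asarray(self.background, float)
        object.__setattr__(self, "background", bg)
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.id!r}: position probabilities must sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.id!r}: background must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 4) log2(p/bg) with zero-probability cells at -inf."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs) - np.log2(self.background)

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())


@dataclass(frozen=True)
class MotifHit:
    """A scored PWM occurrence inside a promoter search region."""

    pwm_id: str
    transcript: str
    site: GenomicInterval
    strand: str
    score: float
    relative_position: int  # signed distance from promoter start, transcript strand

    @property
    def sort_key(self):
        return (-self.score, self.site.chrom, self.site.start, self.strand, self.pwm_id)


def pwm_from_counts(
    record: MotifMatrixRecord,
    pseudocount: float = 0.25,
    background: Sequence[float] | None = None,
) -> PWM:
    """probs[i][b] = (counts[i][b] + pseudocount) / (sum_b counts[i][b] + 4*pseudocount)."""
    counts = record.counts
    denom = counts.sum(axis=1, keepdims=True) + 4 * pseudocount
    probs = (counts + pseudocount) / denom
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    return PWM(record.id, probs, bg, pseudocount)


def log_odds_score(pwm: PWM, window: str) -> float:
    """Score one window of exactly PWM length, in bits; any N gives -inf."""
    if len(window) != len(pwm):
        raise ValueError(f"window length {len(window)} != PWM length {len(pwm)}")
    idx = encode(window.upper())
    if (idx < 0).any():
        return float("-inf")
    return float(pwm.log_odds[np.arange(len(pwm)), idx].sum())


def _score_all_offsets(pwm: PWM, idx: np.ndarray) -> np.ndarray:
    """Scores at every plus-strand offset of an encoded sequence (vectorized)."""
    L = len(pwm)
    n = idx.size - L + 1
    if n <= 0:
        return np.empty(0)
    lo = pwm.log_odds
    # windows with any N are forced to -inf via a masked gather
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(L):
        col = idx[j : j + n]
        ok = col >= 0
        valid &= ok
        scores += np.where(ok, lo[j][np.clip(col, 0, 3)], 0.0)
    scores[~valid] = -np.inf
    return scores


def reverse_complement_pwm(pwm: PWM) -> PWM:
    return PWM(pwm.id, pwm.probs[::-1, ::-1].copy(), pwm.background[::-1].copy(), pwm.pseudocount)


def scan_region(
    pwm: PWM,
    region: GenomicInterval,
    genome: dict,
    threshold: float | None = None,
    transcript: str = "",
    promoter_start: int | None = None,
) -> list[MotifHit]:
    """Score every offset of the region on both strands; return hits sorted by score.

    Minus-strand hit coordinates refer to the plus strand of the genome.
    ``relative_position`` is the signed distance of the site start from
    ``promoter_start`` (defaults to the region start) on the transcript's
    strand: negative means upstream of the promoter start.
    """
    seq = extract_sequence(genome, GenomicInterval(region.chrom, region.start, region.end, "+"))
    idx = encode(seq)
    L = len(pwm)
    if region.width < L:
        return []
    anchor = region.start if promoter_start is None else promoter_start
    hits: list[MotifHit] = []
    rc = reverse_complement_pwm(pwm)
    for strand, mat in (("+", pwm), ("-", rc)):
        # scoring the plus-strand sequence with the reverse-complemented PWM is
        # equivalent to scoring the reverse complement of each window
        scores = _score_all_offsets(mat, idx)
        for off in np.nonzero(np.isfinite(scores))[0] if threshold is None else np.nonzero(
            scores >= threshold
        )[0]:
            score = float(scores[off])
            if not np.isfinite(score):
                continue
            start = region.start + int(off)
            site = GenomicInterval(region.chrom, start, start + L, strand)
            if region.strand == "-":
                rel = anchor - (start + L)
            else:
                rel = start - anchor
            hits.append(MotifHit(pwm.id, transcript, site, strand, score, int(rel)))
    hits.sort(key=lambda h: h.sort_key)
    return hits


def select_top_k(hits: Iterable[MotifHit], k: int = 500) -> list[MotifHit]:
    """The k highest-scoring hits pooled across all matrices and regions.

    Ties break by (score desc, chrom, start, strand, pwm_id); idempotent and
    invariant to input order.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    ordered = sorted(hits, key=lambda h: h.sort_key)
    return ordered[:k]


# ---------------------------------------------------------------------------
# IUPAC consensus scanning
# ---------------------------------------------------------------------------

def _iupac_table(pattern: str) -> np.ndarray:
    """(L, 4) boolean table: position i admits base b."""
    table = np.zeros((len(pattern), 4), dtype=bool)
    for i, code in enumerate(pattern.upper()):
        if code not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC code {code!r} in pattern {pattern!r}")
        for b in IUPAC_CODES[code]:
            table[i, BASES.index(b)] = True
    return table


def reverse_complement_pattern(pattern: str) -> str:
    return pattern.upper().translate(_IUPAC_COMPLEMENT)[::-1]


def _match_offsets(table: np.ndarray, idx: np.ndarray) -> np.ndarray:
    L = table.shape[0]
    n = idx.size - L + 1
    if n <= 0:
        return np.empty(0, dtype=int)
    ok = np.ones(n, dtype=bool)
    for j in range(L):
        col = idx[j : j + n]
        ok &= (col >= 0) & table[j][np.clip(col, 0, 3)]
    return np.nonzero(ok)[0]


def consensus_scan(pattern: str, region: GenomicInterval, genome: dict) -> list[tuple]:
    """Every exact IUPAC match of ``pattern`` on both strands of the region.

    Returns (position, strand) pairs with positions on the genome plus strand,
    sorted by (position, strand). N matches any base in the pattern, but an N
    in the *sequence* matches nothing.
    """
    table = _iupac_table(pattern)
    seq = extract_sequence(genome, GenomicInterval(region.chrom, region.start, region.end, "+"))
    idx = encode(seq)
    out = [(region.start + int(p), "+") for p in _match_offsets(table, idx)]
    rc_table = _iupac_table(reverse_complement_pattern(pattern))
    out += [(region.start + int(p), "-") for p in _match_offsets(rc_table, idx)]
    return sorted(out)


# ---------------------------------------------------------------------------
# Per-miRNA site counting
# ---------------------------------------------------------------------------

def site_counts_per_mirna(selected_hits: Iterable[MotifHit], annotation) -> dict:
    """Count selected hits per mature miRNA, summed over all its pri-miRNA loci.

    Every mature miRNA in the annotation appears, zero-hit ones with count 0.
    Counts sum across matrices (overlapping hits are not collapsed).
    """
    per_pri: dict[str, int] = {t.pri_id: 0 for t in annotation.transcripts}
    for hit in selected_hits:
        if hit.transcript not in per_pri:
            raise KeyError(f"hit references unknown transcript {hit.transcript!r}")
        per_pri[hit.transcript] += 1
    return {
        mature: sum(per_pri[pri] for pri in pris)
        for mature, pris in annotation.mature_to_pri.items()
    }
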