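"""Readers and writers for the external formats the pipeline touches.

FASTA goes through Bio.SeqIO, motif matrices through Bio.motifs (TRANSFAC
and JASPAR dialects), tabular data through pandas. Network export lives in
:mod:`mircircuit.network`; the SIF writer here is shared plumbing.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomeSequence, GenomicInterval

DNA_ALPHABET = frozenset("ACGTN")
BASES = ("A", "C", "G", "T")

_SAMPLE_LABEL = re.compile(r"^([A-Za-z]+[0-9]*)_([0-9]+)$")


@dataclass(frozen=True)
class MotifMatrixRecord:
    """A named count matrix: positions x 4 counts ordered A,C,G,T."""

    id: str
    counts: np.ndarray  # shape (L, 4), float, non-negative

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] < 1:
            raise ValueError(f"matrix {self.id!r}: need >=1 positions x 4 counts")
        if (counts < 0).any():
            raise ValueError(f"matrix {self.id!r}: negative count")
        if (counts.sum(axis=1) <= 0).any():
            raise ValueError(f"matrix {self.id!r}: position with no positive count")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MotifMatrixRecord):
            return NotImplemented
        return self.id == other.id and np.allclose(self.counts, other.counts)

    def __len__(self) -> int:
        return self.counts.shape[0]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    """Read a FASTA file into an ordered map id -> :class:`GenomeSequence`.

    Sequences are uppercased; duplicate ids and characters outside
    {A,C,G,T,N} are errors.
    """
    genome: dict[str, GenomeSequence] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise ValueError(f"duplicate sequence id {record.id!r} in {path}")
        seq = str(record.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise ValueError(
                f"record {record.id!r}: character {seq[pos]!r} at position {pos} "
                f"outside alphabet ACGTN"
            )
        genome[record.id] = GenomeSequence(record.id, seq)
    return genome


def write_fasta(records: Mapping[str, GenomeSequence | str], path, width: int = 70) -> None:
    seqrecords = []
    for name, rec in records.items():
        seq = rec.sequence if isinstance(rec, GenomeSequence) else rec
        seqrecords.append(SeqRecord(Seq(seq), id=name, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecords)


# ---------------------------------------------------------------------------
# Motif matrices (TRANSFAC / JASPAR dialects)
# ---------------------------------------------------------------------------

def _looks_like_jaspar(text: str) -> bool:
    # JASPAR letter rows: "A [ 4 19 0 ]" or "A 4 19 0" under a ">name" header
    return bool(re.search(r"^[ACGT]\s*\[", text, flags=re.M)) or (
        text.lstrip().startswith(">")
        and not re.search(r"^P0\b", text, flags=re.M)
    )


def read_pwm(path) -> list[MotifMatrixRecord]:
    """Parse a motif count-matrix file in TRANSFAC block or JASPAR letter-row dialect.

    Both dialects of the same matrix yield identical records.
    """
    with open(path) as fh:
        text = fh.read()
    fmt = "jaspar" if _looks_like_jaspar(text) else "transfac"
    try:
        parsed = motifs.parse(io.StringIO(text), fmt, strict=False)
        records = []
        for m in parsed:
            name = None
            if isinstance(m, dict):  # transfac records are dict-like (ID/AC keys)
                name = m.get("ID") or m.get("AC")
            name = name or m.name or f"motif_{len(records) + 1}"
            counts = np.column_stack([np.asarray(m.counts[b], dtype=float) for b in BASES])
            records.append(MotifMatrixRecord(str(name), counts))
    except (ValueError, KeyError) as exc:
        raise ValueError(f"cannot parse motif file {path} as {fmt}: {exc}") from exc
    if not records:
        raise ValueError(f"no motif matrices found in {path}")
    return records


def write_pwm(records: Iterable[MotifMatrixRecord], path, dialect: str = "transfac") -> None:
    """Serialize count matrices in either supported dialect."""
    lines: list[str] = []
    for rec in records:
        if dialect == "transfac":
            lines.append(f"ID  {rec.id}")
            lines.append("P0      A      C      G      T")
            for i, row in enumerate(rec.counts, start=1):
                lines.append(
                    f"{i:02d} " + " ".join(f"{v:6.2f}" for v in row)
                )
            lines.append("//")
        elif dialect == "jaspar":
            lines.append(f">{rec.id} {rec.id}")
            for j, base in enumerate(BASES):
                vals = " ".join(f"{v:6.2f}" for v in rec.counts[:, j])
                lines.append(f"{base} [ {vals} ]")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Probe x sample intensity matrix with parsed condition/replicate labels.

    Sample columns are labeled ``<condition>_<replicate>``, e.g. ``GM_1``,
    ``DM3_2``. Intensities are positive fluorescence-scale reals.
    """

    values: pd.DataFrame  # probes x samples
    conditions: dict  # sample label -> condition
    replicates: dict  # sample label -> replicate index

    @property
    def probe_ids(self) -> list:
        return list(self.values.index)

    @property
    def condition_names(self) -> list:
        seen: dict[str, None] = {}
        for c in self.conditions.values():
            seen.setdefault(c, None)
        return list(seen)

    def samples_for(self, condition: str) -> list:
        out = [s for s, c in self.conditions.items() if c == condition]
        if not out:
            raise KeyError(f"no samples for condition {condition!r}")
        return out


def parse_sample_labels(labels: Iterable[str]) -> tuple[dict, dict]:
    conditions, replicates = {}, {}
    for label in labels:
        m = _SAMPLE_LABEL.match(str(label))
        if not m:
            raise ValueError(
                f"sample label {label!r} not of the form CONDITION_REPLICATE (e.g. GM_1)"
            )
        conditions[label] = m.group(1)
        replicates[label] = int(m.group(2))
    return conditions, replicates


def read_expression_table(path) -> ExpressionMatrix:
    """Read a tab-separated probe x sample intensity table."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate probe id(s): {dupes}")
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric intensity in {path}: {exc}") from exc
    conditions, replicates = parse_sample_labels(values.columns)
    return ExpressionMatrix(values, conditions, replicates)


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6f")


# ---------------------------------------------------------------------------
# BED / SIF
# ---------------------------------------------------------------------------

def write_bed(hits, path) -> None:
    """Write scored intervals as BED6: chrom, start, end, name, score, strand.

    ``hits`` is an iterable of objects with ``site`` (GenomicInterval), ``score``
    and a name (``pwm_id`` or ``name`` attribute), or plain
    (interval, name, score) tuples. Output ordering is deterministic
    (chrom, start, end, strand, name).
    """
    rows = []
    for h in hits:
        if isinstance(h, tuple):
            interval, name, score = h
        else:
            interval = h.site
            name = getattr(h, "pwm_id", None) or getattr(h, "name", "hit")
            score = h.score
        rows.append(
            (interval.chrom, interval.start, interval.end, str(name),
             float(score), interval.strand)
        )
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[5], r[3]))
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")


def write_sif(edges, path) -> None:
    """Write edges as SIF lines ``source<TAB>relation<TAB>target``, sorted."""
    lines = sorted(f"{s}\t{rel}\t{t}" for s, rel, t in edges)
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")


def read_sif(path) -> list:
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"malformed SIF line: {line!r}")
            edges.append(tuple(parts))
    return edges
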