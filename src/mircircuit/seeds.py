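"""miRNA seed-match site finding on 3'UTR sequences.

The seed is nucleotides 2-8 of the mature miRNA (5'->3'). A site on a UTR
is the reverse complement of the seed region, classified canonically:

* 8mer      — seed match (positions 2-8) plus an A opposite position 1
* 7mer-m8   — seed match at positions 2-8 (match at position 8, no A1)
* 7mer-A1   — match at positions 2-7 plus an A opposite position 1
* 6mer      — match at positions 2-7 only (reported only when requested)

Reported positions are 0-based offsets of the site's first base on the UTR
as given; U and T are interchangeable on input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .intervals import reverse_complement

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
_SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}  # 0 strongest

_RNA_ALPHABET = frozenset("ACGU")


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA: 5'->3' RNA string, 19-25 nt."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if not 19 <= len(seq) <= 25:
            raise ValueError(f"{self.id}: mature miRNA length {len(seq)} outside 19-25 nt")
        bad = set(seq) - _RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: characters {sorted(bad)} outside ACGU")


@dataclass(frozen=True)
class SeedSite:
    """One seed-match occurrence on a gene's 3'UTR."""

    gene: str
    mirna: str
    position: int  # 0-based offset of the site start on the UTR
    site_type: str


def seed_of(mirna: MatureMiRNA | str) -> str:
    """Nucleotides 2-8 (1-based inclusive) of the mature sequence: the 7-nt seed."""
    seq = mirna.sequence if isinstance(mirna, MatureMiRNA) else str(mirna).upper().replace("T", "U")
    if len(seq) < 8:
        raise ValueError(f"sequence of length {len(seq)} too short for a 2-8 seed")
    return seq[1:8]


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def find_seed_sites(
    mirna: MatureMiRNA, utr: str, gene: str = "", include_6mer: bool = False
) -> list[SeedSite]:
    """All seed-match sites of ``mirna`` on one UTR, strongest class per locus.

    The scan anchors on the 6mer core (reverse complement of miRNA positions
    2-7) and upgrades by the m8 match (complement of position 8 immediately
    5' of the core on the UTR) and the A1 (an A immediately 3' of the core).
    """
    seed7 = _dna(seed_of(mirna))  # miRNA positions 2..8
    core6 = seed7[:6]  # positions 2..7
    rc_core = reverse_complement(core6)  # 6 nt on the UTR
    m8_base = reverse_complement(seed7[6])  # UTR base pairing miRNA position 8
    utr_dna = _dna(utr)
    sites: list[SeedSite] = []
    start = 0
    while True:
        p = utr_dna.find(rc_core, start)
        if p == -1:
            break
        start = p + 1
        has_m8 = p >= 1 and utr_dna[p - 1] == m8_base
        has_a1 = p + 6 < len(utr_dna) and utr_dna[p + 6] == "A"
        if has_m8 and has_a1:
            site_type, pos = "8mer", p - 1
        elif has_m8:
            site_type, pos = "7mer-m8", p - 1
        elif has_a1:
            site_type, pos = "7mer-A1", p
        else:
            if not include_6mer:
                continue
            site_type, pos = "6mer", p
        sites.append(SeedSite(gene, mirna.id, pos, site_type))
    return sites


def targets_of(
    mirna: MatureMiRNA,
    utrs: Mapping[str, str],
    min_site_type: str = "7mer",
) -> dict:
    """Genes with >= 1 site of at least the requested class, with site counts.

    ``min_site_type`` is one of 8mer, 7mer-m8, 7mer-A1, 6mer, or the
    shorthand "7mer" (either 7mer class or better). Lowering the minimum
    class never removes genes.
    """
    if min_site_type == "7mer":
        max_rank = _SITE_RANK["7mer-A1"]
    elif min_site_type in _SITE_RANK:
        max_rank = _SITE_RANK[min_site_type]
    else:
        raise ValueError(f"unknown site class {min_site_type!r}")
    include_6mer = max_rank >= _SITE_RANK["6mer"]
    out: dict[str, int] = {}
    for gene, utr in utrs.items():
        sites = find_seed_sites(mirna, utr, gene, include_6mer=include_6mer)
        n = sum(1 for s in sites if _SITE_RANK[s.site_type] <= max_rank)
        if n:
            out[gene] = n
    return out


def sites_table(sites: Iterable[SeedSite]):
    """Tab-separated-ready table (gene, mirna, position, type)."""
    import pandas as pd

    rows = [(s.gene, s.mirna, s.position, s.site_type) for s in sites]
    return pd.DataFrame(rows, columns=["gene", "mirna", "position", "type"]).sort_values(
        ["gene", "position"], ignore_index=True
    )
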