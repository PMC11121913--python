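"""Candidate miRNA -> mRNA pairs from seed matches or a prediction table.

A mature miRNA recognises targets mainly through its seed (nucleotides
2-8).  The three canonical 3'UTR site classes are scanned here:

* ``8mer``     — perfect Watson-Crick match to positions 2-8 plus an A
  opposite position 1 (on the UTR: revcomp(seed) followed by ``A``);
* ``7mer-m8``  — perfect match to positions 2-8 (revcomp(seed)) without
  the A;
* ``7mer-A1``  — match to positions 2-7 plus the position-1 A.

At a shared locus only the highest-priority class is reported
(8mer > 7mer-m8 > 7mer-A1); distinct loci are independent.  Candidate
pairs are the cross-restriction of differentially expressed miRNAs and
genes with the prediction source (scanned sites or a supplied table).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedSite:
    gene: str
    mirna: str
    utr_start: int  # 0-based
    site_type: str

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")


@dataclass(frozen=True)
class CandidateTargetPair:
    mirna: str
    gene: str
    n_sites: int
    source: str  # "scanned" | "table"

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


def seed_of(mirna_sequence: str) -> str:
    """Seed heptamer: positions 2-8 (1-based) of the mature sequence."""
    seq = mirna_sequence.upper().replace("U", "T")
    if len(seq) < 8:
        raise ValueError(
            f"mature sequence of length {len(seq)} too short for a seed (need >= 8)"
        )
    return seq[1:8]


def _all_occurrences(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def scan_sites(utr_sequence: str, mirna_sequence: str, *, gene: str = "", mirna: str = "") -> list[SeedSite]:
    """All canonical seed sites of one miRNA on one (sense-strand) 3'UTR."""
    utr = utr_sequence.upper().replace("U", "T")
    seed = seed_of(mirna_sequence)
    m2_8 = revcomp(seed)            # 7 nt, pairs positions 2-8
    m2_7 = revcomp(seed[:6])        # 6 nt, pairs positions 2-7

    eightmer = m2_8 + "A"
    starts_8 = set(_all_occurrences(utr, eightmer))
    sites = [SeedSite(gene, mirna, i, "8mer") for i in starts_8]
    # 7mer-m8 coinciding with an 8mer start is the same locus, lower priority
    sites += [
        SeedSite(gene, mirna, i, "7mer-m8")
        for i in _all_occurrences(utr, m2_8)
        if i not in starts_8
    ]
    # 7mer-A1 one base into an 8mer is that 8mer's tail, not a new locus
    sites += [
        SeedSite(gene, mirna, i, "7mer-A1")
        for i in _all_occurrences(utr, m2_7 + "A")
        if (i - 1) not in starts_8
    ]
    return sorted(sites, key=lambda s: (s.utr_start, SITE_TYPES.index(s.site_type)))


def scan_all(
    utrs: Mapping[str, str], matures: Mapping[str, str]
) -> list[SeedSite]:
    """Scan every (gene, miRNA) combination; deterministic order."""
    sites: list[SeedSite] = []
    for gene in sorted(utrs):
        for mirna in sorted(matures):
            sites.extend(
                scan_sites(utrs[gene], matures[mirna], gene=gene, mirna=mirna)
            )
    return sites


def build_candidate_pairs(
    de_mirnas: Iterable[str],
    de_genes: Iterable[str],
    predictions: pd.DataFrame | Sequence[SeedSite],
) -> list[CandidateTargetPair]:
    """Cross-restrict a prediction source to DE miRNAs x DE genes.

    ``predictions`` is either a table with columns ``mirna``, ``gene``
    and optional ``site_count`` (duplicates collapsed, counts summed) or
    a list of scanned :class:`SeedSite`.  Output is lexicographically
    ordered by (mirna, gene).
    """
    mirnas, genes = set(de_mirnas), set(de_genes)
    counts: dict[tuple[str, str], int] = {}
    if isinstance(predictions, pd.DataFrame):
        source = "table"
        site_counts = (
            predictions["site_count"]
            if "site_count" in predictions.columns
            else pd.Series(1, index=predictions.index)
        )
        for (m, g), c in zip(
            zip(predictions["mirna"], predictions["gene"]), site_counts
        ):
            counts[(m, g)] = counts.get((m, g), 0) + int(c)
    else:
        source = "scanned"
        for site in predictions:
            key = (site.mirna, site.gene)
            counts[key] = counts.get(key, 0) + 1
    return [
        CandidateTargetPair(m, g, counts[(m, g)], source)
        for m, g in sorted(counts)
        if m in mirnas and g in genes
    ]
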