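"""Set enrichment, regimen comparison, ID conversion, cluster annotation.

Disease-set enrichment is a one-sided (greater) Fisher / hypergeometric
tail over an explicit universe; the universe is never chosen silently.
Regimen comparison splits the common DE features into direction-concordant
and -discordant subsets.  Cluster annotation strips the arm suffix from
mature miRNA names and tests precursor coordinates for overlap with
cluster intervals (e.g. the two DLK1-DIO3 clusters at 14q32.2/14q32.31).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .io import AliasTable, GenomicInterval
from .de import bh_adjust


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation: P(X >= k) over the universe."""

    overlap: int       # k
    list_size: int     # n, the query list
    set_size: int      # K, the annotated set
    universe_size: int # N
    p_value: float

    def __post_init__(self) -> None:
        if not (
            0 <= self.overlap <= min(self.list_size, self.set_size)
            and self.list_size <= self.universe_size
            and self.set_size <= self.universe_size
        ):
            raise ValueError(
                f"inconsistent counts k={self.overlap}, n={self.list_size}, "
                f"K={self.set_size}, N={self.universe_size}"
            )


def hypergeometric_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeom(N, K, n), log-space stable."""
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_enrichment(
    query: Iterable[str], annotated: Iterable[str], universe: Iterable[str]
) -> EnrichmentResult:
    """One-sided (greater) enrichment of ``query`` in ``annotated``.

    Both sets are intersected with the universe first; ``query`` must be
    a subset of the universe.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    outside = q - uni
    if outside:
        raise ValueError(f"query names outside universe: {sorted(outside)[:5]}")
    ann = set(annotated) & uni
    k = len(q & ann)
    p = hypergeometric_tail(k, len(q), len(ann), len(uni))
    return EnrichmentResult(k, len(q), len(ann), len(uni), p)


@dataclass
class RegimenComparison:
    """DE features shared by two regimens, split by direction agreement."""

    common: set[str]
    concordant: set[str]
    discordant: set[str]

    def __post_init__(self) -> None:
        assert self.common == self.concordant | self.discordant
        assert not (self.concordant & self.discordant)


def compare_regimens(de_a: pd.DataFrame, de_b: pd.DataFrame) -> RegimenComparison:
    """Compare two DE tables (feature_id, direction) on their shared ids."""
    dir_a = dict(zip(de_a["feature_id"], de_a["direction"]))
    dir_b = dict(zip(de_b["feature_id"], de_b["direction"]))
    common = set(dir_a) & set(dir_b)
    concordant = {f for f in common if dir_a[f] == dir_b[f]}
    return RegimenComparison(common, concordant, common - concordant)


def convert_ids(
    names: Iterable[str], aliases: AliasTable
) -> tuple[dict[str, str], list[str]]:
    """Map names to canonical registry names; unmapped are reported, not fatal."""
    mapped: dict[str, str] = {}
    unmapped: list[str] = []
    for name in names:
        canonical = aliases.canonical(name)
        if canonical is None:
            unmapped.append(name)
        else:
            mapped[name] = canonical
    return mapped, unmapped


# ---------------------------------------------------------------------------
# Genomic cluster annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterAnnotation:
    mature_name: str
    precursor_name: str
    cluster: str | None


def strip_arm(mature_name: str) -> str:
    """Precursor name: the mature name minus a trailing -3p/-5p arm suffix."""
    for suffix in ("-3p", "-5p"):
        if mature_name.endswith(suffix):
            return mature_name[: -len(suffix)]
    return mature_name


def annotate_cluster(
    mature_names: Iterable[str],
    mirna_genes: Sequence[GenomicInterval],
    clusters: Sequence[GenomicInterval],
) -> tuple[list[ClusterAnnotation], dict[str, int], list[str]]:
    """Assign mature miRNAs to genomic clusters via their precursor genes.

    Membership is half-open interval overlap of the precursor's
    coordinates with a cluster interval, strand-ignored.  Returns the
    per-name annotations, the per-cluster count of unique member
    precursors, and the names whose precursor has no coordinates (or is
    malformed — no miR/let token).
    """
    gene_by_name = {iv.name: iv for iv in mirna_genes}
    annotations: list[ClusterAnnotation] = []
    missing: list[str] = []
    members: dict[str, set[str]] = {}
    for name in mature_names:
        low = name.lower()
        if "mir" not in low and "let" not in low:
            missing.append(name)
            continue
        precursor = strip_arm(name)
        iv = gene_by_name.get(precursor)
        if iv is None:
            missing.append(name)
            continue
        cluster = next((c.name for c in clusters if iv.overlaps(c)), None)
        annotations.append(ClusterAnnotation(name, precursor, cluster))
        if cluster is not None:
            members.setdefault(cluster, set()).add(precursor)
    counts = {c: len(ms) for c, ms in sorted(members.items())}
    return annotations, counts, missing


def over_representation(
    gene_list: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each named set.

    Sets are intersected with the universe; BH-FDR across sets.  With an
    empty gene list every p is 1.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    query = set(gene_list) & uni
    rows = []
    for set_name in sorted(gene_sets):
        members = set(gene_sets[set_name]) & uni
        k = len(query & members)
        p = hypergeometric_tail(k, len(query), len(members), len(uni))
        rows.append((set_name, k, len(members), p))
    df = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size", "p_value"])
    df["fdr"] = bh_adjust(df["p_value"]) if len(df) else []
    return df
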