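"""Readers and writers for the external formats the pipeline touches.

Count matrices are plain delimited text (features x samples, one header
line); sequences come in as FASTA (RNA accepted and normalised to DNA);
genomic intervals follow the BED convention (0-based half-open); networks
go out as Cytoscape SIF or GraphML.  All parsers validate strictly and
raise :class:`FormatError` instead of silently coercing malformed fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """A file violated the format contract (bad cell, duplicate id, ...)."""


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Integer feature x sample count matrix with per-sample library sizes.

    Parameters
    ----------
    feature_ids, sample_ids
        Unique row / column identifiers.
    counts
        Non-negative integer array of shape ``(n_features, n_samples)``.
    library_sizes
        Positive per-sample totals; defaults to column sums.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    library_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D array")
        n_feat, n_samp = self.counts.shape
        if len(self.feature_ids) != n_feat or len(self.sample_ids) != n_samp:
            raise FormatError("id lists inconsistent with counts dimensions")
        for label, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise FormatError(f"duplicate {label} id: {dup!r}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0).astype(np.int64)
        else:
            self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
            if self.library_sizes.shape != (n_samp,):
                raise FormatError("library_sizes length must equal number of samples")
            col_max = self.counts.max(axis=0, initial=0)
            if np.any(self.library_sizes < col_max):
                raise FormatError("library size smaller than a column count")
        if n_samp and np.any(self.library_sizes <= 0):
            j = int(np.argmax(self.library_sizes <= 0))
            raise FormatError(f"non-positive library size for sample {self.sample_ids[j]!r}")

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    def subset_features(self, keep: Sequence[str]) -> "CountMatrix":
        keep_set = set(keep)
        idx = [i for i, f in enumerate(self.feature_ids) if f in keep_set]
        return CountMatrix(
            [self.feature_ids[i] for i in idx],
            list(self.sample_ids),
            self.counts[idx, :],
            library_sizes=self.library_sizes.copy(),
        )

    def subset_samples(self, keep: Sequence[str]) -> "CountMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in keep if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        idx = [pos[s] for s in keep]
        return CountMatrix(
            list(self.feature_ids),
            list(keep),
            self.counts[:, idx],
            library_sizes=self.library_sizes[idx],
        )


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_count_matrix(path: str | Path, sep: str = "\t") -> CountMatrix:
    """Read a delimited count table: first column feature ids, header samples."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no features")
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no samples")
    values = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col].to_numpy()):
            try:
                v = int(str(raw))
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: non-integer cell {raw!r} at row {df.index[i]!r}, column {col!r}"
                ) from None
            if v < 0:
                raise FormatError(
                    f"{path}: negative count {v} at row {df.index[i]!r}, column {col!r}"
                )
            values[i, j] = v
    return CountMatrix(
        [str(f) for f in df.index], [str(c) for c in df.columns], values
    )


def write_count_matrix(matrix: CountMatrix, path: str | Path, sep: str = "\t") -> None:
    matrix.to_frame().to_csv(path, sep=sep, index_label="feature_id")


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

CONDITIONS = ("control", "treated")
REGIMENS = ("co", "pre")


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    condition: str
    regimen: str
    replicate: int
    mirna_library_id: str
    mrna_library_id: str


@dataclass
class SampleSheet:
    """Condition/regimen design linking miRNA and mRNA libraries per sample."""

    records: list[SampleRecord]

    def __post_init__(self) -> None:
        dup = _first_duplicate([r.sample_id for r in self.records])
        if dup is not None:
            raise FormatError(f"duplicate sample_id: {dup!r}")
        for r in self.records:
            if r.condition not in CONDITIONS:
                raise FormatError(f"unknown condition {r.condition!r} for {r.sample_id}")
            if r.regimen not in REGIMENS:
                raise FormatError(f"unknown regimen {r.regimen!r} for {r.sample_id}")
            if r.replicate < 1:
                raise FormatError(f"replicate must be >= 1 for {r.sample_id}")

    def subset(self, regimen: str | None = None, condition: str | None = None) -> "SampleSheet":
        recs = [
            r
            for r in self.records
            if (regimen is None or r.regimen == regimen)
            and (condition is None or r.condition == condition)
        ]
        return SampleSheet(recs)

    def mirna_libraries(self) -> list[str]:
        return [r.mirna_library_id for r in self.records]

    def mrna_libraries(self) -> list[str]:
        return [r.mrna_library_id for r in self.records]

    def conditions(self) -> list[str]:
        return [r.condition for r in self.records]

    def validate_against(self, mirna: CountMatrix, mrna: CountMatrix) -> None:
        """Every referenced library id must exist in exactly one matrix."""
        mi = set(mirna.sample_ids)
        mr = set(mrna.sample_ids)
        for r in self.records:
            if r.mirna_library_id not in mi:
                raise FormatError(f"miRNA library {r.mirna_library_id!r} not in miRNA matrix")
            if r.mrna_library_id not in mr:
                raise FormatError(f"mRNA library {r.mrna_library_id!r} not in mRNA matrix")
            if r.mirna_library_id in mr or r.mrna_library_id in mi:
                raise FormatError(
                    f"library id of sample {r.sample_id!r} appears in both matrices"
                )

    def require_replicates(self, minimum: int = 2) -> None:
        from collections import Counter

        strata = Counter((r.condition, r.regimen) for r in self.records)
        for stratum, n in strata.items():
            if n < minimum:
                raise FormatError(
                    f"stratum {stratum} has {n} sample(s); at least {minimum} required"
                )


def read_sample_sheet(path: str | Path, sep: str = "\t") -> SampleSheet:
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {
        "sample_id", "condition", "regimen", "replicate",
        "mirna_library_id", "mrna_library_id",
    }
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {sorted(missing)}")
    records = [
        SampleRecord(
            sample_id=row.sample_id,
            condition=row.condition,
            regimen=row.regimen,
            replicate=int(row.replicate),
            mirna_library_id=row.mirna_library_id,
            mrna_library_id=row.mrna_library_id,
        )
        for row in df.itertuples()
    ]
    return SampleSheet(records)


def write_sample_sheet(sheet: SampleSheet, path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in sheet.records]).to_csv(
        path, sep=sep, index=False
    )


# ---------------------------------------------------------------------------
# Alias tables
# ---------------------------------------------------------------------------

@dataclass
class AliasTable:
    """Functional mapping alias -> canonical miRNA name (canonicals fixed)."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for canonical in set(self.mapping.values()):
            existing = self.mapping.get(canonical)
            if existing is not None and existing != canonical:
                raise FormatError(
                    f"canonical name {canonical!r} re-mapped to {existing!r}"
                )
            self.mapping[canonical] = canonical

    def canonical(self, name: str) -> str | None:
        return self.mapping.get(name)


def read_alias_table(path: str | Path, sep: str = "\t") -> AliasTable:
    """Two-column alias TSV: alias, canonical. A header line is optional."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep)
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            alias, canonical = parts[0].strip(), parts[1].strip()
            if lineno == 1 and {alias.lower(), canonical.lower()} & {"alias", "old", "canonical", "new"}:
                continue
            if alias in mapping and mapping[alias] != canonical:
                raise FormatError(f"{path}:{lineno}: alias {alias!r} mapped twice")
            mapping[alias] = canonical
    return AliasTable(mapping)


# ---------------------------------------------------------------------------
# Genomic intervals (BED, 0-based half-open)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} ({self.name})"
            )
        if self.strand not in {"+", "-", "."}:
            raise FormatError(f"invalid strand {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap; strand-ignored."""
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


def read_bed(path: str | Path) -> list[GenomicInterval]:
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 else "."
            try:
                intervals.append(GenomicInterval(parts[0], start, end, name, strand))
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_VALID_BASES = frozenset("ACGTN")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into name -> uppercase DNA sequence (U normalised to T)."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"{path}: duplicate FASTA header {record.id!r}")
        seq = str(record.seq).upper().replace("U", "T")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: illegal character {sorted(bad)[0]!r} in record {record.id!r}"
            )
        sequences[record.id] = seq
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Target prediction tables
# ---------------------------------------------------------------------------

def read_target_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a miRNA -> gene prediction table.

    Columns: mirna, gene, optional site_type, optional site_count.
    Duplicate (mirna, gene) rows are collapsed with site counts summed.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    if not {"mirna", "gene"} <= set(df.columns):
        raise FormatError(f"{path}: need columns 'mirna' and 'gene'")
    if "site_count" in df.columns:
        counts = pd.to_numeric(df["site_count"], errors="raise").astype(int)
        if (counts < 1).any():
            raise FormatError(f"{path}: site_count must be >= 1")
        df = df.assign(site_count=counts)
    else:
        df = df.assign(site_count=1)
    out = (
        df.groupby(["mirna", "gene"], as_index=False)["site_count"]
        .sum()
        .sort_values(["mirna", "gene"], ignore_index=True)
    )
    return out


def read_name_set(path: str | Path) -> set[str]:
    """Plain-text set: one name per line; blank lines and # comments skipped."""
    names: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                names.add(line)
    return names


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets: name <tab> description <tab> member1 <tab> ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT needs >= 3 columns")
            if parts[0] in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {parts[0]!r}")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

def write_network(graph: nx.Graph, fmt: str, path: str | Path) -> None:
    """Export a bipartite repression network as SIF or GraphML.

    SIF carries one ``mirna<TAB>represses<TAB>gene`` line per edge; GraphML
    carries node attributes (role, log2fc, degree) and edge attributes
    (r, fdr).
    """
    fmt = fmt.lower()
    if fmt == "sif":
        with open(path, "w") as fh:
            for u, v in sorted(graph.edges()):
                if graph.nodes[u].get("role") == "miRNA":
                    mirna, gene = u, v
                else:
                    mirna, gene = v, u
                fh.write(f"{mirna}\trepresses\t{gene}\n")
    elif fmt == "graphml":
        export = graph.copy()
        for _, data in export.nodes(data=True):
            data.setdefault("degree", 0)
        nx.write_graphml(export, str(path))
    else:
        raise ValueError(f"unknown network format {fmt!r}; use 'sif' or 'graphml'")


def read_network_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
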