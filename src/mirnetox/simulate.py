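"""Coupled miRNA/mRNA count simulation with planted repression structure.

The generator emulates a two-regimen oxidative-stress differentiation
design: for each regimen, 3 control and 3 treated biological replicates
of paired miRNA and mRNA libraries.  Counts are negative binomial
(variance mu + phi mu^2) around latent log2 means:

* miRNA i, sample s:   ``x = log2(base_i) + delta_i * 1[treated] + e``
* mRNA  j, sample s:   ``y = log2(base_j) - sum_planted beta * (x - log2 base_i) + f``

with e, f ~ N(0, latent_sd).  Repression therefore acts log-linearly on
latent means, inducing the anti-correlation the network analysis
assumes while keeping NB marginals.  A treated shift ``delta_i`` is
planted on a chosen subset of miRNAs; ``n_planted_pairs`` (miRNA, gene)
pairs couple a shifted miRNA to a repressed gene.  All randomness flows
from one seeded generator with a fixed draw order, so identical seeds
give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import reference
from .io import (
    CountMatrix,
    GenomicInterval,
    SampleRecord,
    SampleSheet,
    write_bed,
    write_count_matrix,
    write_fasta,
    write_sample_sheet,
)
from .targets import revcomp, seed_of

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate",
    "simulate_utrs",
    "write_fixture_bundle",
]


@dataclass
class SimulationConfig:
    """Study-design and generative parameters of the simulator.

    Defaults mirror the emulated design: two regimens of biological
    triplicates per condition, NB counts with moderate overdispersion,
    a quarter of miRNAs shifted by treatment, and 40 repressed pairs.
    """

    n_mirna: int = 200
    n_mrna: int = 300
    replicates: int = 3
    regimens: tuple[str, ...] = ("co", "pre")
    baseline_mean: float = 100.0
    dispersion: float = 0.1
    de_fraction_mirna: float = 0.25
    treatment_effect: float = 2.0  # |delta|, log2 units
    n_planted_pairs: int = 40
    repression_strength: float = 1.0  # beta
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    latent_sd: float = 0.25
    n_up_mirna: int | None = None    # override the 50/50 up/down split
    n_down_mirna: int | None = None
    # real small-RNA libraries are dominated by a few constitutive
    # high-abundance miRNAs; these never receive a treatment effect
    n_constitutive: int = 10
    constitutive_mass_fraction: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_mirna < 1 or self.n_mrna < 1:
            problems.append("n_mirna and n_mrna must be >= 1")
        if self.replicates < 2:
            problems.append("replicates must be >= 2")
        if not set(self.regimens) <= {"co", "pre"} or not self.regimens:
            problems.append("regimens must be a non-empty subset of {co, pre}")
        if self.baseline_mean <= 0:
            problems.append("baseline_mean must be > 0")
        if self.dispersion < 0:
            problems.append("dispersion must be >= 0")
        if not 0 <= self.de_fraction_mirna <= 1:
            problems.append("de_fraction_mirna must be in [0, 1]")
        if self.n_planted_pairs > self.n_mirna * self.n_mrna:
            problems.append("n_planted_pairs exceeds n_mirna * n_mrna")
        if self.repression_strength < 0:
            problems.append("repression_strength must be >= 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            problems.append("library_size_range must be a positive (lo, hi) pair")
        if self.n_constitutive < 0 or not 0 <= self.constitutive_mass_fraction < 1:
            problems.append("constitutive ballast parameters out of range")
        if problems:
            raise ValueError("invalid simulation config: " + "; ".join(problems))

    @property
    def n_de_mirna(self) -> int:
        if self.n_up_mirna is not None or self.n_down_mirna is not None:
            return (self.n_up_mirna or 0) + (self.n_down_mirna or 0)
        return int(round(self.de_fraction_mirna * self.n_mirna))


@dataclass
class GroundTruth:
    """Planted effects emitted alongside the simulated matrices.

    ``de_mirnas[regimen]`` maps miRNA name -> signed treatment shift
    (log2 units); ``planted_pairs[regimen]`` lists (mirna, gene, beta).
    """

    de_mirnas: dict[str, dict[str, float]]
    planted_pairs: dict[str, list[tuple[str, str, float]]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "de_mirnas": self.de_mirnas,
            "planted_pairs": {
                reg: [list(t) for t in pairs]
                for reg, pairs in self.planted_pairs.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            de_mirnas=payload["de_mirnas"],
            planted_pairs={
                reg: [(m, g, float(b)) for m, g, b in pairs]
                for reg, pairs in payload["planted_pairs"].items()
            },
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    # gamma-Poisson mixture == NB(mean, var = mean + phi mean^2)
    lam = rng.gamma(shape=r, scale=mean / r)
    return rng.poisson(lam)


def simulate(config: SimulationConfig) -> tuple[CountMatrix, CountMatrix, SampleSheet, GroundTruth]:
    """Generate paired miRNA/mRNA count matrices with known ground truth.

    Draw order (fixed for reproducibility): per-feature baselines, then
    per regimen: DE miRNA selection and signs, planted pair selection,
    library sizes, latent noise, counts (miRNA matrix then mRNA matrix).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mirna_ids = [f"sim-miR-{i + 1}-5p" for i in range(config.n_mirna)]
    gene_ids = [f"GENE{i + 1:04d}" for i in range(config.n_mrna)]

    # per-feature baselines, shared across regimens (lognormal around baseline_mean)
    base_mi = config.baseline_mean * np.exp(rng.normal(0.0, 0.7, config.n_mirna))
    base_mr = config.baseline_mean * np.exp(rng.normal(0.0, 0.7, config.n_mrna))

    # constitutive ballast: the first few miRNAs absorb a fixed share of
    # library mass and never receive a treatment effect (library realism)
    n_const = min(config.n_constitutive, config.n_mirna // 5)
    frac = config.constitutive_mass_fraction
    if n_const and frac > 0:
        rest_mass = float(base_mi[n_const:].sum())
        base_mi[:n_const] = rest_mass * frac / (1.0 - frac) / n_const

    records: list[SampleRecord] = []
    mi_cols: list[np.ndarray] = []
    mr_cols: list[np.ndarray] = []
    mi_libs: list[int] = []
    mr_libs: list[int] = []
    truth_de: dict[str, dict[str, float]] = {}
    truth_pairs: dict[str, list[tuple[str, str, float]]] = {}

    lo, hi = config.library_size_range
    for regimen in config.regimens:
        # --- planted structure ------------------------------------------------
        eligible = np.arange(n_const, config.n_mirna)
        n_de = min(config.n_de_mirna, eligible.size)
        de_idx = rng.choice(eligible, size=n_de, replace=False)
        delta = np.zeros(config.n_mirna)
        if config.n_up_mirna is not None or config.n_down_mirna is not None:
            n_up = min(config.n_up_mirna or 0, n_de)
        else:
            n_up = n_de // 2
        signs = np.array([1.0] * n_up + [-1.0] * (n_de - n_up))
        delta[de_idx] = signs * config.treatment_effect
        truth_de[regimen] = {
            mirna_ids[i]: float(delta[i]) for i in sorted(de_idx)
        }

        n_pairs = min(config.n_planted_pairs, n_de * config.n_mrna, config.n_mrna)
        pair_genes = rng.choice(config.n_mrna, size=n_pairs, replace=False)
        pair_mirnas = rng.choice(de_idx, size=n_pairs, replace=True) if n_de else np.array([], dtype=int)
        beta_j = np.zeros(config.n_mrna)
        partner = np.full(config.n_mrna, -1, dtype=int)
        beta_j[pair_genes] = config.repression_strength
        partner[pair_genes] = pair_mirnas
        truth_pairs[regimen] = sorted(
            (mirna_ids[int(m)], gene_ids[int(g)], float(config.repression_strength))
            for m, g in zip(pair_mirnas, pair_genes)
        )

        # --- samples ----------------------------------------------------------
        for condition in ("control", "treated"):
            for rep in range(1, config.replicates + 1):
                sample = f"{regimen}_{condition}_{rep}"
                records.append(
                    SampleRecord(sample, condition, regimen, rep, f"mi_{sample}", f"mr_{sample}")
                )
                lib_mi = int(rng.integers(lo, hi + 1))
                lib_mr = int(rng.integers(lo, hi + 1))
                treated = condition == "treated"

                e = rng.normal(0.0, config.latent_sd, config.n_mirna)
                x = np.log2(base_mi) + (delta if treated else 0.0) + e
                f = rng.normal(0.0, config.latent_sd, config.n_mrna)
                dev = x - np.log2(base_mi)  # miRNA deviation from baseline
                y = np.log2(base_mr) + f
                coupled = partner >= 0
                y[coupled] -= beta_j[coupled] * dev[partner[coupled]]

                mi_cols.append(_nb_draw(rng, 2.0 ** x * (lib_mi / 1e6), config.dispersion))
                mr_cols.append(_nb_draw(rng, 2.0 ** y * (lib_mr / 1e6), config.dispersion))
                mi_libs.append(lib_mi)
                mr_libs.append(lib_mr)

    sheet = SampleSheet(records)
    # library_sizes carry the generative depths, not column sums: CPM on the
    # emitted matrices is then an unbiased estimate of the latent expression
    mirna = CountMatrix(
        mirna_ids,
        [r.mirna_library_id for r in records],
        np.column_stack(mi_cols),
        library_sizes=np.array(mi_libs),
    )
    mrna = CountMatrix(
        gene_ids,
        [r.mrna_library_id for r in records],
        np.column_stack(mr_cols),
        library_sizes=np.array(mr_libs),
    )
    return mirna, mrna, sheet, GroundTruth(truth_de, truth_pairs)


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _forbidden_7mers(matures: dict[str, str]) -> set[str]:
    """Every UTR 7-mer that would create a canonical site for any miRNA."""
    bad: set[str] = set()
    for seq in matures.values():
        seed = seed_of(seq)
        bad.add(revcomp(seed))               # 7mer-m8 (and the 8mer prefix)
        bad.add(revcomp(seed[:6]) + "A")     # 7mer-A1
    return bad


def _is_clean(utr: str, forbidden: set[str]) -> bool:
    return not any(utr[i : i + 7] in forbidden for i in range(len(utr) - 6))


def simulate_utrs(
    truth: GroundTruth,
    gene_ids: list[str],
    mirna_ids: list[str],
    rng: np.random.Generator,
    utr_length: int = 80,
    mature_length: int = 22,
    max_attempts: int = 10_000,
) -> tuple[dict[str, str], dict[str, str]]:
    """Mature and 3'UTR FASTA sequences consistent with the planted pairs.

    Every planted (miRNA, gene) pair gets at least one exact 8mer site on
    the gene's UTR; every other UTR is rejection-sampled to contain no
    canonical 7-mer seed match for any simulated miRNA.
    """
    # distinct seeds so site assignments are unambiguous
    matures: dict[str, str] = {}
    seeds_seen: set[str] = set()
    for name in mirna_ids:
        for _ in range(max_attempts):
            seq = _random_seq(rng, mature_length)
            if seed_of(seq) not in seeds_seen:
                seeds_seen.add(seed_of(seq))
                matures[name] = seq
                break
        else:
            raise RuntimeError("could not draw a distinct seed; increase mature_length")

    forbidden = _forbidden_7mers(matures)
    planted_by_gene: dict[str, list[str]] = {}
    for pairs in truth.planted_pairs.values():
        for mirna, gene, _ in pairs:
            planted_by_gene.setdefault(gene, [])
            if mirna not in planted_by_gene[gene]:
                planted_by_gene[gene].append(mirna)

    utrs: dict[str, str] = {}
    for gene in gene_ids:
        partners = planted_by_gene.get(gene, [])
        for attempt in range(max_attempts):
            utr = _random_seq(rng, utr_length)
            if not _is_clean(utr, forbidden):
                continue
            if partners:
                # overwrite spaced windows with 8mer sites, then re-check
                # that no accidental site for a non-partner appeared
                utr_list = list(utr)
                step = max(10, utr_length // (len(partners) + 1))
                ok = True
                for k, mirna in enumerate(partners):
                    site = revcomp(seed_of(matures[mirna])) + "A"
                    start = (k + 1) * step - 8
                    if start < 0 or start + 8 > utr_length:
                        ok = False
                        break
                    utr_list[start : start + 8] = site
                if not ok:
                    raise RuntimeError(
                        f"UTR of {gene} too short for {len(partners)} planted sites; "
                        "increase utr_length"
                    )
                utr = "".join(utr_list)
                allowed = _forbidden_7mers({m: matures[m] for m in partners})
                stray = {
                    utr[i : i + 7]
                    for i in range(len(utr) - 6)
                    if utr[i : i + 7] in forbidden
                } - allowed
                if stray:
                    continue
            utrs[gene] = utr
            break
        else:
            raise RuntimeError(
                f"rejection sampling for {gene} exceeded {max_attempts} attempts; "
                "increase utr_length or reduce n_mirna"
            )
    return matures, utrs


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture_bundle(
    outdir: str | Path, config: SimulationConfig, force: bool = False
) -> dict[str, str]:
    """Emit every pipeline input with ground truth and a checksum manifest.

    Files: count matrices, sample sheet, mature/UTR FASTA, alias TSV and
    disease-set text (the bundled psychiatric miRNA catalogue), miRNA
    gene and cluster BEDs (synthetic coordinates placing the first 12
    simulated precursors in two neighbouring clusters), truth JSON.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty; pass force=True to overwrite")
    outdir.mkdir(parents=True, exist_ok=True)

    mirna, mrna, sheet, truth = simulate(config)
    write_count_matrix(mirna, outdir / "mirna_counts.tsv")
    write_count_matrix(mrna, outdir / "mrna_counts.tsv")
    write_sample_sheet(sheet, outdir / "samples.tsv")
    truth.to_json(outdir / "truth.json")

    rng = np.random.default_rng(config.seed + 1)
    matures, utrs = simulate_utrs(truth, mrna.feature_ids, mirna.feature_ids, rng)
    write_fasta(matures, outdir / "matures.fasta")
    write_fasta(utrs, outdir / "utrs.fasta")

    with open(outdir / "aliases.tsv", "w") as fh:
        fh.write("alias\tcanonical\n")
        for canonical, alias in reference.PSYCHIATRIC_MIRNA_ALIASES:
            fh.write(f"{alias}\t{canonical}\n")
    with open(outdir / "disease_mirnas.txt", "w") as fh:
        for canonical, _ in reference.PSYCHIATRIC_MIRNA_ALIASES:
            fh.write(canonical + "\n")

    # synthetic cluster layout: first 12 precursors split over two clusters
    gene_ivs = []
    cluster_a = GenomicInterval("chr14", 1_000, 11_000, "clusterA")
    cluster_b = GenomicInterval("chr14", 20_000, 64_000, "clusterB")
    for i, name in enumerate(mirna.feature_ids):
        precursor = name[:-3] if name.endswith(("-5p", "-3p")) else name
        if i < 2:
            start = 1_500 + i * 1_000
        elif i < 12:
            start = 21_000 + (i - 2) * 1_000
        else:
            start = 100_000 + i * 1_000
        gene_ivs.append(GenomicInterval("chr14", start, start + 80, precursor, "+"))
    write_bed(gene_ivs, outdir / "mirna_genes.bed")
    write_bed([cluster_a, cluster_b], outdir / "clusters.bed")

    manifest = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir()) if p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
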