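"""End-to-end orchestration: DE per regimen -> candidates -> network ->
hubs -> comparison/enrichment/cluster annotation, from one YAML config.

Every stage writes plain-text outputs into the configured directory and
records parameters, input checksums and output checksums in a JSON run
manifest.  A completed stage whose inputs and parameters are unchanged
is skipped on re-run (idempotence); ``force`` recomputes everything.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .de import DifferentialExpressionModel
from .enrichment import annotate_cluster, compare_regimens, convert_ids, fisher_enrichment
from .io import (
    AliasTable,
    read_alias_table,
    read_bed,
    read_count_matrix,
    read_fasta,
    read_name_set,
    read_sample_sheet,
    read_target_table,
    write_network,
)
from .network import CorrelationNetworkModel
from .targets import build_candidate_pairs, scan_all


class ConfigError(ValueError):
    """The pipeline configuration is invalid (exit code 2 at the CLI)."""


class DataError(ValueError):
    """A stage failed on its input data (exit code 3 at the CLI)."""


@dataclass
class PipelineConfig:
    mirna_counts: str
    mrna_counts: str
    samples: str
    outdir: str
    target_table: str | None = None
    utrs: str | None = None
    matures: str | None = None
    alias_table: str | None = None
    disease_set: str | None = None
    mirna_genes_bed: str | None = None
    clusters_bed: str | None = None
    regimens: list[str] = field(default_factory=lambda: ["co", "pre"])
    alpha_de: float = 0.05
    min_abs_log2fc: float = 0.6
    alpha_corr: float = 0.05
    min_hub_degree: int = 10
    min_raw: int = 5
    min_fraction: float = 0.5
    scale: str = "log2cpm"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from None

    def validate(self) -> None:
        for attr in ("mirna_counts", "mrna_counts", "samples"):
            p = getattr(self, attr)
            if not p or not Path(p).exists():
                raise ConfigError(f"required input {attr!r} missing: {p}")
        if self.target_table is None and (self.utrs is None or self.matures is None):
            raise ConfigError("need either target_table or both utrs and matures")
        for attr in (
            "target_table", "utrs", "matures", "alias_table",
            "disease_set", "mirna_genes_bed", "clusters_bed",
        ):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"configured input {attr!r} does not exist: {p}")
        for attr in ("alpha_de", "min_abs_log2fc", "alpha_corr", "min_raw"):
            if getattr(self, attr) <= 0:
                raise ConfigError(f"threshold {attr!r} must be positive")
        if self.min_hub_degree < 1:
            raise ConfigError("min_hub_degree must be >= 1")
        bad = set(self.regimens) - {"co", "pre"}
        if bad or not self.regimens:
            raise ConfigError(f"invalid regimen selection: {self.regimens}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, inputs: dict[str, str], outputs: list[Path],
               params: dict, rows: dict[str, int], cached: bool = False) -> None:
        self.stages[stage] = {
            "inputs": inputs,
            "parameters": params,
            "outputs": {p.name: _sha256(p) for p in outputs},
            "rows": rows,
            "cached": cached,
            "wall_stamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "valid": True,
        }

    def save(self, path: Path) -> None:
        path.write_text(json.dumps({"config": self.config, "stages": self.stages}, indent=1, sort_keys=True))


def run(config: PipelineConfig, force: bool = False, log=print) -> RunManifest:
    """Execute all stages in dependency order; returns the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"

    # whole-run cache: identical config + intact inputs/outputs => skip
    if not force and manifest_path.exists():
        try:
            prev = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            prev = None
        if prev and prev.get("config") == dataclasses.asdict(config):
            current_inputs = {
                "mirna_counts": _sha256(Path(config.mirna_counts)),
                "mrna_counts": _sha256(Path(config.mrna_counts)),
                "samples": _sha256(Path(config.samples)),
            }
            inputs_ok = all(
                stage.get("inputs") == current_inputs
                for stage in prev.get("stages", {}).values()
            )
            intact = inputs_ok and all(
                (outdir / name).exists() and _sha256(outdir / name) == digest
                for stage in prev.get("stages", {}).values()
                for name, digest in stage.get("outputs", {}).items()
            )
            if intact:
                log("[cache] inputs and outputs unchanged; skipping recompute")
                cached = RunManifest(config=prev["config"], stages=prev["stages"])
                for stage in cached.stages.values():
                    stage["cached"] = True
                return cached

    manifest = RunManifest(config=dataclasses.asdict(config))

    try:
        mirna = read_count_matrix(config.mirna_counts)
        mrna = read_count_matrix(config.mrna_counts)
        sheet = read_sample_sheet(config.samples)
        sheet.validate_against(mirna, mrna)
    except Exception as exc:
        raise DataError(f"input loading failed: {exc}") from exc

    aliases = read_alias_table(config.alias_table) if config.alias_table else None

    base_inputs = {
        "mirna_counts": _sha256(Path(config.mirna_counts)),
        "mrna_counts": _sha256(Path(config.mrna_counts)),
        "samples": _sha256(Path(config.samples)),
    }

    de_results: dict[str, tuple] = {}
    net_results: dict[str, object] = {}
    for regimen in config.regimens:
        # ------------------------------------------------------------- DE
        stage = f"de_{regimen}"
        params = {
            "alpha": config.alpha_de, "min_abs_log2fc": config.min_abs_log2fc,
            "min_raw": config.min_raw, "min_fraction": config.min_fraction,
            "regimen": regimen,
        }
        log(f"[{stage}] exact test, FDR < {config.alpha_de}, |log2FC| > {config.min_abs_log2fc}")
        try:
            res_mi = DifferentialExpressionModel.from_sample_sheet(
                mirna, sheet, regimen, which="mirna",
                min_raw=config.min_raw, min_fraction=config.min_fraction,
            ).fit(alpha=config.alpha_de, min_abs_log2fc=config.min_abs_log2fc)
            res_mr = DifferentialExpressionModel.from_sample_sheet(
                mrna, sheet, regimen, which="mrna",
                min_raw=config.min_raw, min_fraction=config.min_fraction,
            ).fit(alpha=config.alpha_de, min_abs_log2fc=config.min_abs_log2fc)
        except Exception as exc:
            raise DataError(f"stage {stage} failed: {exc}") from exc
        de_results[regimen] = (res_mi, res_mr)
        out_mi, out_mr = outdir / f"de_mirna_{regimen}.tsv", outdir / f"de_mrna_{regimen}.tsv"
        res_mi.to_tsv(out_mi)
        res_mr.to_tsv(out_mr)
        manifest.record(stage, base_inputs, [out_mi, out_mr], params,
                        {"mirna_tested": len(res_mi.table), "mrna_tested": len(res_mr.table)})

        # ----------------------------------------------------- candidates
        stage = f"candidates_{regimen}"
        de_mi = res_mi.significant_ids()
        de_mr = res_mr.significant_ids()
        if aliases is not None:
            mapped, _ = convert_ids(de_mi, aliases)
            de_mi = {mapped.get(n, n) for n in de_mi}
        log(f"[{stage}] {len(de_mi)} DE miRNAs x {len(de_mr)} DE genes")
        try:
            if config.target_table:
                predictions = read_target_table(config.target_table)
            else:
                predictions = scan_all(read_fasta(config.utrs), read_fasta(config.matures))
            pairs = build_candidate_pairs(de_mi, de_mr, predictions)
        except Exception as exc:
            raise DataError(f"stage {stage} failed: {exc}") from exc
        out = outdir / f"candidates_{regimen}.tsv"
        pd.DataFrame(
            [(p.mirna, p.gene, p.n_sites, p.source) for p in pairs],
            columns=["mirna", "gene", "n_sites", "source"],
        ).to_csv(out, sep="\t", index=False)
        manifest.record(stage, base_inputs, [out], {"regimen": regimen}, {"pairs": len(pairs)})

        # --------------------------------------------------------- network
        stage = f"network_{regimen}"
        log(f"[{stage}] Pearson on {config.scale}, FDR < {config.alpha_corr}, "
            f"hub degree >= {config.min_hub_degree}")
        params = {
            "alpha": config.alpha_corr, "min_hub_degree": config.min_hub_degree,
            "scale": config.scale, "regimen": regimen,
        }
        try:
            net = CorrelationNetworkModel(
                mirna, mrna, sheet, pairs, regimen=regimen, scale=config.scale
            ).fit(
                alpha=config.alpha_corr,
                min_hub_degree=config.min_hub_degree,
                mirna_log2fc=dict(zip(res_mi.table["feature_id"], res_mi.table["log2fc"])),
                gene_log2fc=dict(zip(res_mr.table["feature_id"], res_mr.table["log2fc"])),
            )
        except Exception as exc:
            raise DataError(f"stage {stage} failed: {exc}") from exc
        net_results[regimen] = net
        out_edges = outdir / f"edges_{regimen}.tsv"
        net.edges.to_csv(out_edges, sep="\t", index=False, float_format="%.6g")
        out_sif = outdir / f"network_{regimen}.sif"
        out_gml = outdir / f"network_{regimen}.graphml"
        write_network(net.graph, "sif", out_sif)
        write_network(net.graph, "graphml", out_gml)
        out_hubs = outdir / f"hubs_{regimen}.tsv"
        pd.DataFrame(net.hub_report.hubs, columns=["mirna", "degree"]).to_csv(
            out_hubs, sep="\t", index=False
        )
        manifest.record(stage, base_inputs, [out_edges, out_sif, out_gml, out_hubs], params,
                        {"edges_tested": len(net.edges), "edges_retained": len(net.retained),
                         "hubs": len(net.hub_report.hubs)})

    # ------------------------------------------------------- comparison
    if len(config.regimens) == 2:
        a, b = config.regimens
        comp = compare_regimens(de_results[a][0].significant, de_results[b][0].significant)
        out = outdir / "regimen_comparison.tsv"
        rows = (
            [(f, "concordant") for f in sorted(comp.concordant)]
            + [(f, "discordant") for f in sorted(comp.discordant)]
        )
        pd.DataFrame(rows, columns=["feature_id", "agreement"]).to_csv(out, sep="\t", index=False)
        manifest.record("comparison", base_inputs, [out], {"regimens": config.regimens},
                        {"common": len(comp.common), "concordant": len(comp.concordant),
                         "discordant": len(comp.discordant)})
        log(f"[comparison] {len(comp.common)} common "
            f"({len(comp.concordant)} concordant, {len(comp.discordant)} discordant)")

    # ------------------------------------------------------- enrichment
    if config.disease_set:
        disease = read_name_set(config.disease_set)
        rows = []
        for regimen in config.regimens:
            res_mi = de_results[regimen][0]
            universe = set(res_mi.table["feature_id"])
            de_mi = res_mi.significant_ids()
            if aliases is not None:
                mapped, _ = convert_ids(universe, aliases)
                universe = {mapped.get(n, n) for n in universe}
                de_mi = {mapped.get(n, n) for n in de_mi}
            enr = fisher_enrichment(de_mi, disease, universe)
            rows.append((regimen, enr.overlap, enr.list_size, enr.set_size,
                         enr.universe_size, enr.p_value))
        out = outdir / "disease_enrichment.tsv"
        pd.DataFrame(rows, columns=["regimen", "overlap", "n_de", "n_disease",
                                    "n_universe", "p_value"]).to_csv(
            out, sep="\t", index=False, float_format="%.6g")
        manifest.record("enrichment", base_inputs, [out],
                        {"disease_set": config.disease_set,
                         "universe": "expression-filtered miRNAs"},
                        {"regimens": len(rows)})
        log(f"[enrichment] one-sided Fisher over expression-filtered universe")

    # ------------------------------------------------- cluster annotation
    if config.mirna_genes_bed and config.clusters_bed:
        genes_bed = read_bed(config.mirna_genes_bed)
        clusters_bed = read_bed(config.clusters_bed)
        all_sig = sorted(
            set().union(*(de_results[r][0].significant_ids() for r in config.regimens))
        )
        annotations, counts, missing = annotate_cluster(all_sig, genes_bed, clusters_bed)
        out = outdir / "cluster_annotation.tsv"
        pd.DataFrame(
            [(a.mature_name, a.precursor_name, a.cluster or "") for a in annotations],
            columns=["mature_name", "precursor_name", "cluster"],
        ).to_csv(out, sep="\t", index=False)
        manifest.record("clusters", base_inputs, [out],
                        {"clusters_bed": config.clusters_bed},
                        {"annotated": len(annotations), "unmapped": len(missing),
                         **{f"members_{c}": n for c, n in counts.items()}})
        log(f"[clusters] per-cluster unique precursors: {counts}")

    # ---------------------------------------------------------- summary
    summary = summarize_results(de_results, net_results, config.regimens)
    out = outdir / "summary.tsv"
    summary.to_csv(out, sep="\t", index=False, float_format="%.4g")
    manifest.record("summary", base_inputs, [out], {}, {"regimens": len(summary)})

    manifest.save(manifest_path)
    return manifest


def summarize_results(de_results, net_results, regimens) -> pd.DataFrame:
    """Headline per-regimen counts in the order the reports use them."""
    rows = []
    for regimen in regimens:
        res_mi, _ = de_results[regimen]
        net = net_results[regimen]
        sig = res_mi.significant
        hr = net.hub_report
        rows.append({
            "regimen": regimen,
            "n_de_mirna": len(sig),
            "n_de_up": int((sig["direction"] == "up").sum()),
            "n_de_down": int((sig["direction"] == "down").sum()),
            "n_edges": len(net.retained),
            "n_network_mirnas": net.n_mirnas,
            "n_network_mrnas": net.n_genes,
            "n_hubs": len(hr.hubs),
            "hub_edges": hr.hub_edge_count,
            "hub_fraction": hr.hub_edge_fraction,
        })
    return pd.DataFrame(rows)


def summarize(outdir: str | Path) -> pd.DataFrame:
    """Re-derive the summary table from a completed run directory."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise DataError(f"no manifest in {outdir}")
    payload = json.loads(manifest_path.read_text())
    regimens = payload["config"]["regimens"]
    rows = []
    for regimen in regimens:
        de = pd.read_csv(outdir / f"de_mirna_{regimen}.tsv", sep="\t")
        sig = de[de["significant"]]
        edges = pd.read_csv(outdir / f"edges_{regimen}.tsv", sep="\t")
        retained = edges[(edges["r"] < 0) & (edges["fdr"] < payload["config"]["alpha_corr"])]
        hubs = pd.read_csv(outdir / f"hubs_{regimen}.tsv", sep="\t")
        hub_edges = int(hubs["degree"].sum()) if len(hubs) else 0
        rows.append({
            "regimen": regimen,
            "n_de_mirna": len(sig),
            "n_de_up": int((sig["direction"] == "up").sum()),
            "n_de_down": int((sig["direction"] == "down").sum()),
            "n_edges": len(retained),
            "n_network_mirnas": retained["mirna"].nunique(),
            "n_network_mrnas": retained["gene"].nunique(),
            "n_hubs": len(hubs),
            "hub_edges": hub_edges,
            "hub_fraction": hub_edges / len(retained) if len(retained) else 0.0,
        })
    return pd.DataFrame(rows)
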