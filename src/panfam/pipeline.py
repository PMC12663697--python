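"""Pipeline orchestration: simulate → build → classify → families → codon → kaks.

One run directory holds one reproducible analysis: the serialized config, a
subfolder of outputs per stage, a log file, and a machine-readable
``summary.json`` with per-stage counts and parameters. A completed run can
be re-executed from its own serialized config. Data outputs are
deterministic given the config; only the log and the wall-clock fields of
the summary vary between repeats.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import codon_metrics as cm
from . import family_assign as fa
from . import pan_classify as pc
from . import selection_metrics as sm
from .io_formats import (
    DEG_SCHEMA,
    DOMAINS_SCHEMA,
    DatasetManifest,
    PanfamError,
    load_manifest,
    read_table,
    write_table,
)
from .ogg_builder import (
    OGGS_SCHEMA,
    BuilderParams,
    build_pan_family,
    occupancy_matrix,
    oggs_to_table,
)
from .synthetic_data import SimConfig, simulate_pan_family

logger = logging.getLogger(__name__)

STAGES = ("simulate", "build", "classify", "families", "codon", "kaks")


@dataclass
class RunConfig:
    out_dir: str
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    input_dir: str | None = None  # dataset location when simulate is disabled
    sim: dict[str, Any] = field(default_factory=dict)  # SimConfig overrides
    min_identity: float = 90.0
    min_coverage: float = 90.0
    seed_accession: str | None = None
    kaks_max_pairs: int = 200
    kaks_p_filter: float | None = 0.01
    cai_reference: str | None = None  # path to a gene-id list; default: all genes
    seed: int = 0

    def sim_config(self) -> SimConfig:
        sim = dict(self.sim)
        sim.setdefault("seed", self.seed)
        if "ogg_length_range" in sim:
            sim["ogg_length_range"] = tuple(sim["ogg_length_range"])
        return SimConfig(**sim)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PanfamError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        stages = {s: True for s in STAGES}
        stages.update(cfg.stages or {})
        bad = set(stages) - set(STAGES)
        if bad:
            raise PanfamError(f"unknown stages: {sorted(bad)}")
        cfg.stages = stages
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "wt", encoding="utf-8") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)


def _dataset_dir(config: RunConfig, out: Path) -> Path:
    if config.stages.get("simulate"):
        return out / "sim"
    if config.input_dir is None:
        raise PanfamError("simulate stage disabled and no input_dir given")
    return Path(config.input_dir)


def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise PanfamError(
            f"stage {needed_by!r} requires {path.name} from stage {stage!r}; "
            f"run {stage!r} first (missing: {path})"
        )
    return path


# ---------------------------------------------------------------------------
# Individual stages (each usable on its own; the CLI maps onto these)


def stage_build(manifest: DatasetManifest, params: BuilderParams, out: Path) -> dict[str, Any]:
    out.mkdir(parents=True, exist_ok=True)
    oggs = build_pan_family(manifest, params)
    matrix = occupancy_matrix(oggs, manifest)
    write_table(oggs_to_table(oggs), OGGS_SCHEMA, out / "oggs.tsv")
    matrix.to_csv(out / "occupancy.tsv", sep="\t", index_label="ogg_id")
    return {
        "n_genes": len(manifest),
        "n_accessions": len(manifest.accessions),
        "n_oggs": len(oggs),
        "min_identity": params.min_identity,
        "min_coverage": params.min_coverage,
        "seed_accession": params.seed_accession or manifest.accessions[0],
    }


def read_occupancy(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="ogg_id")


def read_memberships(path: Path) -> dict[str, str]:
    rows = read_table(path, OGGS_SCHEMA)
    return {gene: r["ogg_id"] for r in rows for gene in str(r["members"]).split(";")}


def stage_classify(
    matrix: pd.DataFrame,
    population_map: Mapping[str, str],
    membership: Mapping[str, str],
    deg_flags: Mapping[str, tuple[str, str]] | None,
    out: Path,
) -> dict[str, Any]:
    out.mkdir(parents=True, exist_ok=True)
    categories, summary = pc.categorize(matrix)
    occupancy = (matrix > 0).sum(axis=1)
    write_table(
        [
            {"ogg_id": o, "occupancy": int(occupancy[o]), "category": c}
            for o, c in categories.items()
        ],
        {"ogg_id": "str", "occupancy": "int", "category": "str"},
        out / "categories.tsv",
    )
    breakdown = pc.population_breakdown(matrix, population_map, categories)
    breakdown.to_csv(out / "population_breakdown.tsv", sep="\t", index=False, na_rep=".")
    crosstab = pc.deg_crosstab(deg_flags or {}, membership, categories)
    crosstab.to_csv(out / "deg_crosstab.tsv", sep="\t", index=False, na_rep=".")
    return {"n_oggs": len(categories), "category_counts": dict(sorted(summary.items()))}


def stage_families(
    domains: Mapping[str, tuple[int, int]],
    manifest: DatasetManifest | None,
    out: Path,
    panel=None,
    params: BuilderParams | None = None,
) -> dict[str, Any]:
    out.mkdir(parents=True, exist_ok=True)
    genes = manifest.gene_index if manifest is not None else None
    rows = fa.assign_families(domains, genes, panel, params)
    write_table(rows, fa.FAMILIES_SCHEMA, out / "families.tsv")
    counts: dict[str, int] = {}
    for row in rows:
        counts[str(row["family"])] = counts.get(str(row["family"]), 0) + 1
    return {"n_annotated": len(rows), "family_counts": dict(sorted(counts.items()))}


def stage_codon(
    manifest: DatasetManifest,
    grouping: Mapping[str, tuple[str, str]],
    out: Path,
    reference_gene_ids: list[str] | None = None,
) -> dict[str, Any]:
    """Per-gene codon metrics, RSCU table and group×population comparisons.

    The CAI reference set defaults to all input genes — a stand-in for a
    highly-expressed genome-wide reference when no expression data is
    supplied — and can be restricted via ``reference_gene_ids``.
    """
    out.mkdir(parents=True, exist_ok=True)
    ref_ids = reference_gene_ids or sorted(manifest.gene_index)
    ref_counts = []
    for gid in ref_ids:
        if gid not in manifest.gene_index:
            raise PanfamError(f"CAI reference gene {gid!r} not in dataset")
        ref_counts.append(cm.count_codons(manifest.gene_index[gid].cds))
    weights = cm.build_reference_weights(ref_counts)

    metric_rows = []
    rscu_rows = []
    per_metric: dict[str, dict[str, float]] = {m: {} for m in ("cai", "enc", "gc", "gc1", "gc2", "gc3")}
    for gid in sorted(manifest.gene_index):
        record = manifest.gene_index[gid]
        group, population = grouping.get(gid, ("all", record.population))
        metrics = cm.codon_usage_metrics(record.cds, weights)
        metric_rows.append(
            {
                "gene_id": gid,
                "group": group,
                "population": population,
                **{k: metrics[k] for k in ("cai", "enc", "gc", "gc1", "gc2", "gc3")},
            }
        )
        for metric, value in metrics.items():
            if value is not None:
                per_metric[metric][gid] = value
        gene_rscu = cm.rscu(cm.count_codons(record.cds))
        rscu_rows.append({"gene_id": gid, **gene_rscu})

    schema = {
        "gene_id": "str",
        "group": "str",
        "population": "str",
        **{m: "float" for m in ("cai", "enc", "gc", "gc1", "gc2", "gc3")},
    }
    write_table(metric_rows, schema, out / "codon_metrics.tsv")
    pd.DataFrame(rscu_rows).to_csv(out / "rscu.tsv", sep="\t", index=False, na_rep=".")

    comparisons = []
    for metric, values in per_metric.items():
        frame = cm.compare_groups(values, grouping)
        frame.insert(0, "metric", metric)
        comparisons.append(frame)
    all_comp = pd.concat(comparisons, ignore_index=True)
    all_comp.to_csv(out / "codon_comparisons.tsv", sep="\t", index=False, na_rep=".")
    return {"n_genes": len(metric_rows), "n_comparisons": len(all_comp)}


def stage_kaks(
    manifest: DatasetManifest,
    membership: Mapping[str, str],
    categories: Mapping[str, str],
    out: Path,
    max_pairs: int = 200,
    seed: int = 0,
    p_filter: float | None = 0.01,
) -> dict[str, Any]:
    out.mkdir(parents=True, exist_ok=True)
    by_ogg: dict[str, list[str]] = {}
    for gid, ogg in membership.items():
        by_ogg.setdefault(ogg, []).append(gid)

    pair_frames = []
    summary_rows = []
    omega_by_category: dict[str, list[float]] = {}
    omega_by_population: dict[str, list[float]] = {}
    for ogg in sorted(by_ogg):
        gids = sorted(by_ogg[ogg])
        if len(gids) < 2:
            logger.info("skipping %s: fewer than two members", ogg)
            continue
        members = [(gid, manifest.gene_index[gid].cds) for gid in gids]
        pairs, summary = sm.ogg_pairwise_kaks(
            members, max_pairs=max_pairs, seed=seed, p_filter=p_filter
        )
        pairs.insert(0, "ogg_id", ogg)
        pair_frames.append(pairs)
        summary_rows.append(
            {
                "ogg_id": ogg,
                "category": categories.get(ogg),
                "n_members": len(gids),
                **summary,
            }
        )
        if summary["mean_omega"] is not None and categories.get(ogg):
            omega_by_category.setdefault(categories[ogg], []).append(summary["mean_omega"])
        for _, row in pairs.iterrows():
            if row["omega"] is None or pd.isna(row["omega"]):
                continue
            if p_filter is not None and row["p"] >= p_filter:
                continue
            pop_a = manifest.gene_index[row["gene_a"]].population
            pop_b = manifest.gene_index[row["gene_b"]].population
            if pop_a == pop_b:
                omega_by_population.setdefault(pop_a, []).append(float(row["omega"]))

    all_pairs = pd.concat(pair_frames, ignore_index=True) if pair_frames else pd.DataFrame()
    all_pairs.to_csv(out / "kaks_pairs.tsv", sep="\t", index=False, na_rep=".")
    pd.DataFrame(summary_rows).to_csv(out / "kaks_summary.tsv", sep="\t", index=False, na_rep=".")

    comp_frames = []
    for name, groups in (("category", omega_by_category), ("population", omega_by_population)):
        frame = sm.selection_compare(groups)
        frame.insert(0, "comparison", name)
        comp_frames.append(frame)
    comparisons = pd.concat(comp_frames, ignore_index=True)
    comparisons.to_csv(out / "kaks_comparisons.tsv", sep="\t", index=False, na_rep=".")

    pop_means = {
        pop: float(pd.Series(v).mean()) for pop, v in sorted(omega_by_population.items())
    }
    return {
        "n_oggs_estimated": len(summary_rows),
        "n_pairs": int(len(all_pairs)),
        "mean_omega_by_population": pop_means,
    }


# ---------------------------------------------------------------------------
# Orchestration


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("panfam")
    root.addHandler(handler)
    try:
        summary = _run_stages(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()
    with open(out / "summary.json", "wt", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _run_stages(config: RunConfig, out: Path) -> dict[str, Any]:
    summary: dict[str, Any] = {"stages": {}, "seed": config.seed}

    def record(stage: str, t0: float, info: dict[str, Any]) -> None:
        info["wall_clock_s"] = round(time.perf_counter() - t0, 3)
        summary["stages"][stage] = info
        logger.info("stage %s done: %s", stage, info)

    if config.stages.get("simulate"):
        t0 = time.perf_counter()
        sim_cfg = config.sim_config()
        simulate_pan_family(sim_cfg, out / "sim")
        record("simulate", t0, {"n_oggs": sim_cfg.n_oggs, "n_accessions": sim_cfg.n_accessions})

    data_dir = _dataset_dir(config, out)
    manifest = None
    if any(config.stages.get(s) for s in ("build", "codon", "kaks", "families")):
        manifest = load_manifest(data_dir)

    if config.stages.get("build"):
        t0 = time.perf_counter()
        params = BuilderParams(
            min_identity=config.min_identity,
            min_coverage=config.min_coverage,
            seed_accession=config.seed_accession,
        )
        record("build", t0, stage_build(manifest, params, out / "build"))

    categories: dict[str, str] = {}
    membership: dict[str, str] = {}
    if config.stages.get("classify"):
        t0 = time.perf_counter()
        matrix = read_occupancy(_require(out / "build" / "occupancy.tsv", "build", "classify"))
        membership = read_memberships(_require(out / "build" / "oggs.tsv", "build", "classify"))
        pop_rows = read_table(data_dir / "populations.tsv", {"accession_id": "str", "population": "str"})
        population_map = {r["accession_id"]: r["population"] for r in pop_rows}
        deg_flags = None
        if (data_dir / "deg.tsv").exists():
            deg_rows = read_table(data_dir / "deg.tsv", DEG_SCHEMA)
            deg_flags = {r["gene_id"]: (r["leaf_status"], r["root_status"]) for r in deg_rows}
        record(
            "classify",
            t0,
            stage_classify(matrix, population_map, membership, deg_flags, out / "classify"),
        )

    family_of: dict[str, str] = {}
    if config.stages.get("families"):
        t0 = time.perf_counter()
        domains_path = _require(data_dir / "domains.tsv", "simulate", "families")
        domain_rows = read_table(domains_path, DOMAINS_SCHEMA)
        domains = {r["gene_id"]: (int(r["ap2_count"]), int(r["b3_count"])) for r in domain_rows}
        record("families", t0, stage_families(domains, manifest, out / "families"))
        for row in read_table(out / "families" / "families.tsv", fa.FAMILIES_SCHEMA):
            family_of[str(row["gene_id"])] = str(row["family"])

    if config.stages.get("codon"):
        t0 = time.perf_counter()
        grouping = {
            gid: (family_of.get(gid, "all"), rec.population)
            for gid, rec in manifest.gene_index.items()
            if family_of.get(gid) != "unclassified"
        }
        ref_ids = None
        if config.cai_reference:
            with open(config.cai_reference, "rt", encoding="utf-8") as fh:
                ref_ids = [line.strip() for line in fh if line.strip()]
        record("codon", t0, stage_codon(manifest, grouping, out / "codon", ref_ids))

    if config.stages.get("kaks"):
        t0 = time.perf_counter()
        if not membership:
            membership = read_memberships(_require(out / "build" / "oggs.tsv", "build", "kaks"))
        if not categories:
            cats_path = _require(out / "classify" / "categories.tsv", "classify", "kaks")
            categories = {
                str(r["ogg_id"]): str(r["category"])
                for r in read_table(cats_path, {"ogg_id": "str", "occupancy": "int", "category": "str"})
            }
        if family_of:
            membership = {
                gid: ogg for gid, ogg in membership.items()
                if family_of.get(gid, "ERF-like") != "unclassified"
            }
        record(
            "kaks",
            t0,
            stage_kaks(
                manifest,
                membership,
                categories,
                out / "kaks",
                max_pairs=config.kaks_max_pairs,
                seed=config.seed,
                p_filter=config.kaks_p_filter,
            ),
        )

    total_genes = len(manifest) if manifest is not None else None
    summary["n_genes"] = total_genes
    return summary


def make_report(run_dir: str | Path) -> str:
    """Human-readable report over whatever stages a run directory contains."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise PanfamError(f"no summary.json under {run_dir}; not a completed run")
    with open(summary_path, "rt", encoding="utf-8") as fh:
        summary = json.load(fh)
    lines = [f"panfam run report — {run_dir}", "=" * 60, ""]
    lines.append("Stages run: " + ", ".join(sorted(summary.get("stages", {}))))
    lines.append("")

    def section(title: str) -> None:
        lines.extend([title, "-" * len(title)])

    build_info = summary["stages"].get("build")
    if build_info:
        section("Pan-family build")
        lines.append(
            f"{build_info['n_genes']} genes from {build_info['n_accessions']} accessions "
            f"-> {build_info['n_oggs']} OGGs "
            f"(identity >= {build_info['min_identity']}, coverage >= {build_info['min_coverage']}, "
            f"seed accession {build_info['seed_accession']})"
        )
        occ = run_dir / "build" / "occupancy.tsv"
        if occ.exists():
            matrix = read_occupancy(occ)
            per_accession = matrix.sum(axis=0)
            lines.append("Per-accession gene counts:")
            lines.append(per_accession.to_string())
        lines.append("")
    else:
        lines.append("[build: not run]\n")

    cls_info = summary["stages"].get("classify")
    if cls_info:
        section("Pan-category totals")
        for cat, n in cls_info["category_counts"].items():
            lines.append(f"  {cat:9s} {n}")
        crosstab = run_dir / "classify" / "deg_crosstab.tsv"
        if crosstab.exists():
            lines.append("DEG enrichment by category:")
            lines.append(pd.read_csv(crosstab, sep="\t").fillna("").to_string(index=False))
        lines.append("")
    else:
        lines.append("[classify: not run]\n")

    if summary["stages"].get("codon"):
        section("Codon-usage comparisons")
        comp = run_dir / "codon" / "codon_comparisons.tsv"
        if comp.exists():
            frame = pd.read_csv(comp, sep="\t").fillna("")
            lines.append(frame.to_string(index=False))
        lines.append("")
    else:
        lines.append("[codon: not run]\n")

    kaks_info = summary["stages"].get("kaks")
    if kaks_info:
        section("Ka/Ks summary")
        lines.append(f"OGGs with estimates: {kaks_info['n_oggs_estimated']}, pairs: {kaks_info['n_pairs']}")
        for pop, mean in kaks_info.get("mean_omega_by_population", {}).items():
            lines.append(f"  mean omega ({pop}): {mean:.3f}")
        comp = run_dir / "kaks" / "kaks_comparisons.tsv"
        if comp.exists():
            lines.append(pd.read_csv(comp, sep="\t").fillna("").to_string(index=False))
        lines.append("")
    else:
        lines.append("[kaks: not run]\n")
    return "\n".join(lines)
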