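"""Pipeline orchestration: config validation, stage wiring, manifests.

Each survey artifact (primer-mismatch table, OTU table, diversity table,
community dendrograms, Mantel table, qPCR abundances) is an independent
stage; this module validates one config document up front, runs the
requested stages in dependency order, and records a manifest of input and
output checksums so deterministic stages can be shown to reproduce
byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import community, diversity, ecostats, io as tio, otu as totu, primers as tprimers, qpcr as tqpcr
from .errors import ValidationError

__all__ = ["PipelineConfig", "RunManifest", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("primer_eval", "otu", "diversity", "compare", "stats", "qpcr")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``stages`` selects what to run; per-stage path/parameter mappings are
    free-form but cross-checked by :func:`validate_config` (e.g. the
    ``compare`` stage with a UniFrac metric requires a tree; ``qpcr``
    requires all three volume constants). ``seed`` is mandatory — no
    hidden entropy in permutation stages.
    """

    seed: int
    out_dir: Path
    stages: tuple[str, ...]
    cutoff: float = 0.05
    permutations: int = 999
    options: Mapping[str, Mapping[str, Any]] = field(default_factory=dict)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)

    def record(self, stage: str, elapsed: float, outputs: Mapping[str, Path]) -> None:
        self.stages[stage] = {
            "elapsed_s": round(elapsed, 3),
            "outputs": {k: _sha256(p) for k, p in outputs.items()},
        }

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, default=str, indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def validate_config(doc: Mapping[str, Any]) -> PipelineConfig:
    """Validate a parsed config document; aggregate all errors."""
    errors: list[str] = []
    if "seed" not in doc:
        errors.append("seed is required")
    cutoff = float(doc.get("cutoff", 0.05))
    if not (0 <= cutoff < 1):
        errors.append(f"cutoff must be in [0, 1), got {cutoff}")
    permutations = int(doc.get("permutations", 999))
    if permutations < 1:
        errors.append("permutations must be >= 1")
    stages = tuple(doc.get("stages", KNOWN_STAGES))
    for s in stages:
        if s not in KNOWN_STAGES:
            errors.append(f"unknown stage {s!r}")
    options = {k: dict(v) for k, v in doc.items() if k in KNOWN_STAGES}

    def need(stage: str, *keys: str):
        for key in keys:
            if key not in options.get(stage, {}):
                errors.append(f"{stage}: missing required option {key!r}")

    if "primer_eval" in stages:
        need("primer_eval", "primers", "templates")
    if "otu" in stages:
        need("otu", "distances", "membership")
    if "diversity" in stages and "otu" not in stages:
        need("diversity", "otu_table")
    if "compare" in stages:
        metric = options.get("compare", {}).get("metric", "braycurtis")
        if metric == "unifrac" and "tree" not in options.get("compare", {}):
            errors.append("compare: unifrac metric requires a tree")
    if "stats" in stages:
        need("stats", "env")
    if "qpcr" in stages:
        need("qpcr", "plate", "template_volume_ul", "elution_volume_ul", "filtered_volume_l")
        for key in ("template_volume_ul", "elution_volume_ul", "filtered_volume_l"):
            val = options.get("qpcr", {}).get(key)
            if val is not None and float(val) <= 0:
                errors.append(f"qpcr: {key} must be positive, got {val}")

    for stage in stages:
        for key, val in options.get(stage, {}).items():
            if isinstance(val, str) and ("/" in val or val.endswith((".tsv", ".csv", ".fasta", ".nwk", ".dist", ".yml"))):
                if not Path(val).exists():
                    errors.append(f"{stage}: path for {key!r} does not exist: {val}")

    if errors:
        raise ValidationError("invalid config:\n  - " + "\n  - ".join(errors))
    return PipelineConfig(
        seed=int(doc["seed"]),
        out_dir=Path(doc.get("out_dir", "thaumflow_out")),
        stages=stages,
        cutoff=cutoff,
        permutations=permutations,
        options=options,
    )


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages in dependency order.

    A stage failure aborts its downstream dependents but the partial
    manifest of completed stages is still returned/raised with context.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(
            {"seed": config.seed, "cutoff": config.cutoff, "stages": config.stages,
             "permutations": config.permutations, "options": config.options},
            sort_keys=True, default=str,
        ).encode()
    ).hexdigest()
    from . import __version__

    manifest = RunManifest(cfg_hash, __version__)
    state: dict[str, Any] = {}

    for stage in KNOWN_STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        outputs = _STAGE_FUNCS[stage](config, out, state)
        elapsed = time.perf_counter() - t0
        sizes = {k: Path(p).stat().st_size for k, p in outputs.items()}
        logger.info("stage %s done in %.2fs: %s", stage, elapsed, sizes)
        manifest.record(stage, elapsed, outputs)

    manifest.write(out / "manifest.json")
    return manifest


def _stage_primer_eval(config, out, state):
    opts = config.options["primer_eval"]
    primers = tio.read_primers(opts["primers"])
    templates = tio.read_templates(opts["templates"], opts.get("clades"))
    rows, triples = [], []
    for rec in templates:
        row = {"id": rec.id, "clade": rec.clade}
        for primer in primers:
            site = tprimers.align_primer(primer, rec)
            row[f"{primer.name}_pattern"] = tprimers.render_pattern(site.pattern)
            row[f"{primer.name}_mismatches"] = site.pattern.count
            row[f"{primer.name}_3prime"] = site.pattern.three_prime_mismatches()
            triples.append((rec.clade, primer.name, site.pattern.count))
        rows.append(row)
    table_path = out / "primer_mismatches.tsv"
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)
    summary = pd.DataFrame([s.__dict__ for s in tprimers.summarize_groups(triples)])
    summary_path = out / "primer_group_summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False)
    return {"table": table_path, "summary": summary_path}


def _stage_otu(config, out, state):
    opts = config.options["otu"]
    dm = tio.read_distance_matrix(opts["distances"])
    membership = (
        pd.read_csv(opts["membership"], sep="\t", header=None, names=["id", "sample"])
        .set_index("id")["sample"]
        .astype(str)
        .to_dict()
    )
    assignment = totu.cluster_furthest_neighbor(dm, config.cutoff)
    table = totu.build_otu_table(assignment, membership)
    state["otu_table"] = table
    list_path = out / "otus.list"
    tio.write_list_file(assignment, list_path)
    table_path = out / "otu_table.tsv"
    tio.write_otu_table(table, table_path)
    return {"list": list_path, "table": table_path}


def _stage_diversity(config, out, state):
    if "otu_table" in state:
        table = state["otu_table"]
    else:
        table = tio.read_otu_table(config.options["diversity"]["otu_table"])
        state["otu_table"] = table
    summary = diversity.library_summary(table)
    path = out / "diversity.tsv"
    summary.round({"shannon": 2, "chao1": 2}).to_csv(path, sep="\t")
    return {"table": path}


def _stage_compare(config, out, state):
    opts = config.options.get("compare", {})
    if "otu_table" in state:
        table = state["otu_table"]
    else:
        table = tio.read_otu_table(opts["otu_table"])
        state["otu_table"] = table
    metric = opts.get("metric", "braycurtis")
    tree = tio.read_tree(opts["tree"]) if "tree" in opts else None
    dm = community.sample_distance_matrix(table, metric=metric, tree=tree)
    state["community_dm"] = dm
    dm_path = out / f"{metric}_distances.tsv"
    tio.write_distance_matrix(dm, dm_path, fmt="tsv")
    dendro = community.upgma(dm)
    nwk_path = out / f"{metric}_upgma.nwk"
    tio.write_tree(dendro, nwk_path)
    labd = community.shared_otu_matrix(table)
    labd_path = out / "shared_otus_labd.tsv"
    labd.round(4).to_csv(labd_path, sep="\t")
    return {"distances": dm_path, "dendrogram": nwk_path, "labd": labd_path}


def _stage_stats(config, out, state):
    opts = config.options["stats"]
    env = pd.read_csv(opts["env"], index_col=0)
    if "community_dm" in state:
        dm = state["community_dm"]
    else:
        dm = tio.read_distance_matrix(opts["community"])
    env = env.loc[[s for s in dm.ids if s in env.index]]
    if list(env.index) != list(dm.ids):
        raise ValidationError("env table does not cover all community samples")
    rows = []
    matrices = {
        "distance_km": ecostats.geo_distance(env),
        "temp": ecostats.env_distance(env, ("temperature",)),
        "sal": ecostats.env_distance(env, ("salinity",)),
        "temp_sal": ecostats.env_distance(env, ("temperature", "salinity")),
    }
    for name, other in matrices.items():
        res = ecostats.mantel(dm, other, permutations=config.permutations, seed=config.seed)
        rows.append(
            {"variable": name, "mantel_r": round(res.statistic, 2),
             "p": res.pvalue, "stars": ecostats.significance_stars(res.pvalue)}
        )
    mantel_path = out / "mantel.tsv"
    pd.DataFrame(rows).to_csv(mantel_path, sep="\t", index=False)
    season = env["season"].to_dict()
    res = ecostats.anosim(dm, season, permutations=config.permutations, seed=config.seed)
    anosim_path = out / "anosim.tsv"
    pd.DataFrame(
        [{"grouping": "season", "R": round(res.statistic, 2), "p": res.pvalue}]
    ).to_csv(anosim_path, sep="\t", index=False)
    return {"mantel": mantel_path, "anosim": anosim_path}


def _stage_qpcr(config, out, state):
    opts = config.options["qpcr"]
    plate = pd.read_csv(opts["plate"])
    curves, results = tqpcr.summarize_plate(
        plate,
        template_volume_ul=float(opts["template_volume_ul"]),
        elution_volume_ul=float(opts["elution_volume_ul"]),
        filtered_volume_l=float(opts["filtered_volume_l"]),
        detection_ct=opts.get("detection_ct"),
    )
    diag_path = out / "qpcr_curves.tsv"
    pd.DataFrame(
        [
            {"gene": g, "slope": c.slope, "intercept": c.intercept,
             "r_squared": c.r_squared, "efficiency_pct": c.efficiency_pct}
            for g, c in curves.items()
        ]
    ).to_csv(diag_path, sep="\t", index=False)
    abund_path = out / "qpcr_abundances.tsv"
    pd.DataFrame([r.__dict__ for r in results]).to_csv(abund_path, sep="\t", index=False)
    return {"curves": diag_path, "abundances": abund_path}


_STAGE_FUNCS = {
    "primer_eval": _stage_primer_eval,
    "otu": _stage_otu,
    "diversity": _stage_diversity,
    "compare": _stage_compare,
    "stats": _stage_stats,
    "qpcr": _stage_qpcr,
}
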