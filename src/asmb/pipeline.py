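"""End-to-end orchestration: rarefy -> partition -> beta-diversity ->
group tests -> distance-decay -> variation partitioning -> null models ->
driver importance -> niche breadth, stratified by soil layer, writing one
results directory with a manifest.

Per-layer analyses subset the samples *before* any pairwise computation, so
no cross-layer pair ever enters a distance-decay, varpart or null-model
stage. Abundant/rare sub-tables keep the original rarefied counts of the
subset OTUs; they are not re-rarefied.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import betadiv, ddr, drivers, groupstats, niche, nullmodels
from .io import (
    ENV_GROUPS,
    OtuTable,
    read_metadata,
    read_newick,
    read_otu_table,
    check_tree_table_ids,
)

logger = logging.getLogger(__name__)

STAGES = (
    "rarefy",
    "partition",
    "betadiv",
    "grouptests",
    "ddr",
    "varpart",
    "nullmodels",
    "rf",
    "niche",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    table_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    group_map_path: str | None = None
    simulate: dict | None = None
    rarefy_depth: int | None = None
    abundant_min: float = 0.001
    rare_max: float = 0.0001
    bnti_cut: float = 2.0
    rc_cut: float = 0.95
    n_rand: int = 999
    n_perm: int = 999
    n_trees: int = 500
    seed: int = 0
    prune_to_tree: bool = False
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    def __post_init__(self):
        if not (0 < self.rare_max < self.abundant_min < 1):
            raise ValueError("thresholds must satisfy 0 < rare_max < abundant_min < 1")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        has_paths = self.table_path and self.tree_path and self.metadata_path
        if not has_paths and self.simulate is None:
            raise ValueError("config needs input paths or a simulate section")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence((seed, 7919, k)).generate_state(1)[0] % (2**31 - 1))


class _Run:
    def __init__(self, config: RunConfig, out_dir):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest = {
            "seed": config.seed,
            "settings": {
                k: v for k, v in asdict(config).items() if k not in ("stages",)
            },
            "stages": [],
        }

    def write_tsv(self, df: pd.DataFrame, name: str, stage: str, **meta) -> Path:
        path = self.out / name
        with open(path, "w") as fh:
            fh.write(f"# asmb stage={stage} seed={self.config.seed}")
            for k, v in meta.items():
                fh.write(f" {k}={v}")
            fh.write("\n")
            df.to_csv(fh, sep="\t")
        return path

    def record(self, stage: str, outputs: list[Path], settings: dict, notes=None):
        self.manifest["stages"].append(
            {
                "stage": stage,
                "outputs": {p.name: _sha256(p) for p in outputs},
                "settings": settings,
                "notes": notes or [],
            }
        )

    def skip(self, stage: str):
        self.manifest["stages"].append({"stage": stage, "skipped": True})


def _load_inputs(config: RunConfig):
    if config.table_path:
        table = read_otu_table(config.table_path)
        tree = read_newick(config.tree_path)
        metadata = read_metadata(config.metadata_path, config.group_map_path)
    else:
        from .simulate import SimulationConfig, simulate_dataset

        sim = SimulationConfig(**{**config.simulate, "seed": config.simulate.get("seed", config.seed)})
        table, tree, metadata = simulate_dataset(sim)
    missing = set(table.sample_ids) - set(metadata.sample_ids)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
    table, n_dropped = check_tree_table_ids(table, tree, config.prune_to_tree)
    if n_dropped:
        logger.warning("pruned %d OTUs absent from the tree", n_dropped)
    metadata = metadata.subset_samples(table.sample_ids)
    return table, tree, metadata


def run_all(config: RunConfig, out_dir) -> dict:
    """Run every enabled stage; returns the manifest (also written to disk)."""
    run = _Run(config, out_dir)
    try:
        table, tree, metadata = _load_inputs(config)
    except Exception as exc:
        raise PipelineError(f"stage=load: {exc}") from exc

    state: dict = {"metadata": metadata, "tree": tree}

    for k, stage in enumerate(STAGES):
        if not config.stages.get(stage, True):
            run.skip(stage)
            continue
        seed = _stage_seed(config.seed, k)
        try:
            _STAGE_FUNCS[stage](run, table, state, seed)
        except Exception as exc:
            raise PipelineError(f"stage={stage}: {exc}") from exc
        if stage == "rarefy":
            table = state["table"]

    manifest_path = run.out / "manifest.json"
    manifest_path.write_text(json.dumps(run.manifest, indent=2, sort_keys=True))
    return run.manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------
def _stage_rarefy(run, table, state, seed):
    depth = run.config.rarefy_depth or int(table.sample_sums().min())
    rare = betadiv.rarefy(table, depth, seed=seed)
    state["table"] = rare
    from .io import write_otu_table

    path = run.out / "table_rarefied.tsv"
    with open(path, "w") as fh:
        fh.write(f"# asmb stage=rarefy seed={run.config.seed} depth={depth}\n")
        write_otu_table(rare, fh)
    run.record("rarefy", [path], {"depth": depth, "stage_seed": seed})


def _stage_partition(run, table, state, seed):
    cfg = run.config
    part = betadiv.partition_by_abundance(table, cfg.abundant_min, cfg.rare_max)
    state["partition"] = part
    df = pd.DataFrame(
        [(o, "abundant") for o in part.abundant_ids]
        + [(o, "rare") for o in part.rare_ids]
        + [(o, "intermediate") for o in part.intermediate_ids],
        columns=["otu_id", "class"],
    ).set_index("otu_id")
    path = run.write_tsv(df, "abundance_partition.tsv", "partition",
                         abundant_min=cfg.abundant_min, rare_max=cfg.rare_max)
    run.record(
        "partition", [path],
        {"abundant_min": cfg.abundant_min, "rare_max": cfg.rare_max,
         "n_abundant": len(part.abundant_ids), "n_rare": len(part.rare_ids)},
    )


def _class_tables(table, state) -> dict[str, OtuTable]:
    out = {"overall": table}
    part = state.get("partition")
    if part is not None:
        for cls, ids in (("abundant", part.abundant_ids), ("rare", part.rare_ids)):
            ids = [o for o in ids if o in table.otu_ids]
            if len(ids) >= 2:
                out[cls] = table.subset_otus(ids)
    return out


def _stage_betadiv(run, table, state, seed):
    metadata, tree = state["metadata"], state["tree"]
    outputs, notes = [], []
    state["beta"] = {}
    for layer in ("topsoil", "subsoil"):
        md = metadata.subset_layer(layer)
        sub = table.subset_samples(md.sample_ids)
        for cls, t in _class_tables(sub, state).items():
            if (t.otu_sums() > 0).sum() < 2 or np.any(t.sample_sums() == 0):
                notes.append(f"{layer}/{cls}: too sparse, skipped")
                continue
            t = t.drop_empty_otus()
            bc = betadiv.bray_curtis(t)
            wu = betadiv.weighted_unifrac(t, tree)
            state["beta"][(layer, cls, "braycurtis")] = bc
            state["beta"][(layer, cls, "wunifrac")] = wu
            for metric, m in (("braycurtis", bc), ("wunifrac", wu)):
                p = run.write_tsv(
                    m.to_dataframe(), f"beta_{metric}_{layer}_{cls}.tsv", "betadiv",
                    metric=metric, layer=layer, otu_class=cls,
                )
                outputs.append(p)
    run.record("betadiv", outputs, {"metrics": ["braycurtis", "wunifrac"]}, notes)


def _stage_grouptests(run, table, state, seed):
    metadata = state["metadata"]
    bc = betadiv.bray_curtis(table)
    grouping = metadata.data["layer"]
    rows = []
    for i, fn in enumerate((groupstats.permanova, groupstats.anosim,
                            groupstats.mrpp, groupstats.permdisp)):
        res = fn(bc, grouping, n_perm=run.config.n_perm, seed=seed + i)
        rows.append(res.to_frame())
    df = pd.concat(rows, ignore_index=True).set_index("test")
    path = run.write_tsv(df, "group_tests.tsv", "grouptests", n_perm=run.config.n_perm)
    run.record("grouptests", [path], {"n_perm": run.config.n_perm, "stage_seed": seed})


def _stage_ddr(run, table, state, seed):
    metadata = state["metadata"]
    rows = []
    for layer in ("topsoil", "subsoil"):
        md = metadata.subset_layer(layer)
        spa = ddr.spatial_distance(md)
        env = ddr.environmental_distance(md)
        for (l, cls, metric), beta in state.get("beta", {}).items():
            if l != layer:
                continue
            sim = beta.to_similarity().subset(md.sample_ids)
            for dist_name, dist in (("spatial", spa), ("environment", env)):
                fit = ddr.fit_distance_decay(
                    sim, dist, n_perm=run.config.n_perm, seed=seed
                )
                row = fit.to_frame()
                row.insert(0, "distance", dist_name)
                row.insert(0, "metric", metric)
                row.insert(0, "otu_class", cls)
                row.insert(0, "layer", layer)
                rows.append(row)
    df = pd.concat(rows, ignore_index=True)
    path = run.write_tsv(df.set_index("layer"), "ddr_fits.tsv", "ddr",
                         n_perm=run.config.n_perm)
    run.record("ddr", [path], {"n_perm": run.config.n_perm, "stage_seed": seed})


def _stage_varpart(run, table, state, seed):
    metadata = state["metadata"]
    rows = []
    for layer in ("topsoil", "subsoil"):
        md = metadata.subset_layer(layer)
        spa = ddr.spatial_distance(md)
        env = ddr.environmental_distance(md)
        for (l, cls, metric), beta in state.get("beta", {}).items():
            if l != layer:
                continue
            vp = drivers.variation_partition(beta.subset(md.sample_ids), env, spa)
            row = vp.to_frame()
            row.insert(0, "metric", metric)
            row.insert(0, "otu_class", cls)
            row.insert(0, "layer", layer)
            rows.append(row)
    df = pd.concat(rows, ignore_index=True)
    path = run.write_tsv(df.set_index("layer"), "varpart.tsv", "varpart")
    run.record("varpart", [path], {})


def _stage_nullmodels(run, table, state, seed):
    metadata, tree = state["metadata"], state["tree"]
    cfg = run.config
    pair_frames, frac_rows, outputs = [], [], []
    for layer in ("topsoil", "subsoil"):
        md = metadata.subset_layer(layer)
        sub = table.subset_samples(md.sample_ids).drop_empty_otus()
        b = nullmodels.bnti(sub, tree, n_rand=cfg.n_rand, seed=seed)
        r = nullmodels.raup_crick_bray(sub, n_rand=cfg.n_rand, seed=seed + 1)
        summary = nullmodels.classify_processes(b, r, cfg.bnti_cut, cfg.rc_cut)
        pp = summary.per_pair.copy()
        pp.insert(0, "layer", layer)
        pair_frames.append(pp)
        for lab, frac in summary.fractions.items():
            frac_rows.append((layer, lab, frac))
        state.setdefault("process", {})[layer] = summary
    pairs = pd.concat(pair_frames, ignore_index=True).set_index("layer")
    outputs.append(run.write_tsv(pairs, "nullmodel_pairs.tsv", "nullmodels",
                                 n_rand=cfg.n_rand))
    fr = pd.DataFrame(frac_rows, columns=["layer", "process", "fraction"]).set_index("layer")
    outputs.append(run.write_tsv(fr, "process_fractions.tsv", "nullmodels",
                                 n_rand=cfg.n_rand))
    run.record("nullmodels", outputs,
               {"n_rand": cfg.n_rand, "bnti_cut": cfg.bnti_cut,
                "rc_cut": cfg.rc_cut, "stage_seed": seed})


def _stage_rf(run, table, state, seed):
    metadata = state["metadata"]
    rows = []
    for layer in ("topsoil", "subsoil"):
        md = metadata.subset_layer(layer)
        sub = table.subset_samples(md.sample_ids)
        beta = state.get("beta", {}).get((layer, "overall", "braycurtis"))
        if beta is None:
            beta = betadiv.bray_curtis(sub)
        beta = beta.subset(md.sample_ids)
        predictors = {"spatial": ddr.spatial_distance(md)}
        for g in ENV_GROUPS:
            if g in md.groups_present():
                predictors[g] = ddr.environmental_distance(md, [g])
        imp = drivers.rf_importance(beta, predictors,
                                    n_trees=run.config.n_trees, seed=seed)
        imp.insert(0, "layer", layer)
        rows.append(imp)
    df = pd.concat(rows, ignore_index=True).set_index("layer")
    path = run.write_tsv(df, "rf_importance.tsv", "rf", n_trees=run.config.n_trees)
    run.record("rf", [path], {"n_trees": run.config.n_trees, "stage_seed": seed})


def _stage_niche(run, table, state, seed):
    metadata = state["metadata"]
    part = state.get("partition")
    class_otus = {"overall": list(table.otu_ids)}
    if part is not None:
        for cls, ids in (("abundant", part.abundant_ids), ("rare", part.rare_ids)):
            ids = [o for o in ids if o in table.otu_ids]
            viable = True
            for layer in ("topsoil", "subsoil"):
                sub = table.subset_samples(metadata.subset_layer(layer).sample_ids)
                with_reads = set(
                    o for o, t in zip(sub.otu_ids, sub.otu_sums()) if t > 0
                )
                if len(with_reads & set(ids)) < 2:
                    viable = False
            if viable:
                class_otus[cls] = ids
    b = niche.breadths_by_class_and_layer(table, metadata, class_otus)
    comp = niche.compare_breadths(b)
    outputs = [
        run.write_tsv(comp.layer_tests.set_index("class"),
                      "niche_layer_tests.tsv", "niche"),
        run.write_tsv(comp.class_tests.set_index("layer"),
                      "niche_class_letters.tsv", "niche"),
    ]
    run.record("niche", outputs, {"classes": list(class_otus)})


_STAGE_FUNCS = {
    "rarefy": _stage_rarefy,
    "partition": _stage_partition,
    "betadiv": _stage_betadiv,
    "grouptests": _stage_grouptests,
    "ddr": _stage_ddr,
    "varpart": _stage_varpart,
    "nullmodels": _stage_nullmodels,
    "rf": _stage_rf,
    "niche": _stage_niche,
}
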