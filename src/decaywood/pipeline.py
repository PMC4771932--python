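"""End-to-end orchestration of the decay-study analysis.

Stage order mirrors the study workflow: per-replicate rarefaction ->
alpha diversity and diversity-vs-density regressions -> Bray-Curtis MRT
staging on replicate-averaged communities -> per-stage-pair
differential abundance -> per-stage and global co-occurrence networks
-> per-sample rank-abundance model comparison -> summary. Every stage
writes TSV/JSON artifacts into the run directory, and a manifest
records the config, seed and every excluded sample, so a run is a pure
function of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from decaywood import community_metrics as cmx
from decaywood import cooccurrence as cnet
from decaywood import decay_stage_mrt as mrt
from decaywood import diff_abundance as da
from decaywood import sad_assembly as sad
from decaywood import tables_io as tio

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run (serialized verbatim to the manifest)."""

    bacterial_table: str
    fungal_table: str
    taxonomy: str
    metadata: str
    output_dir: str
    seed: int = 0
    bacterial_depth: int = 1080
    fungal_depth: int = 2000
    orientation: str = "samples_as_rows"
    # MRT
    mrt_max_leaves: int = 3
    mrt_min_node_size: int = 1
    # differential abundance
    diffabund_rank: str = "genus"
    diffabund_n_perm: int = 1000
    diffabund_fdr: bool = True
    # networks
    network_rank: str = "genus"
    network_min_representatives: int = 5
    network_filter_mode: str = "reads"
    network_abs_r: float = 0.80
    network_p_max: float = 0.05
    network_use_fdr: bool = False
    network_q_max: float = 0.05
    # SAD model comparison
    sad_margin: float = 2.0
    sad_scoring: str = "configuration"
    sad_kingdoms: tuple = ("bacteria", "fungi")
    # stage skipping (outputs of other stages are unaffected)
    skip_diffabund: bool = False
    skip_network: bool = False
    skip_sad: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if "sad_kingdoms" in raw:
            raw["sad_kingdoms"] = tuple(raw["sad_kingdoms"])
        return cls(**raw)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs remain in the run dir."""


def _json_dump(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


_FLOAT_FMT = "%.10g"


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}
    # tuples are not JSON-stable across round trips; normalize
    manifest["config"]["sad_kingdoms"] = list(config.sad_kingdoms)

    try:
        bacteria = tio.read_count_table(config.bacterial_table,
                                        config.orientation)
        fungi = tio.read_count_table(config.fungal_table, config.orientation)
        taxonomy = tio.read_taxonomy(config.taxonomy)
        meta = tio.read_metadata(config.metadata)
    except Exception as exc:
        raise StageError(f"input stage failed: {exc}") from exc

    return _run(bacteria, fungi, taxonomy, meta, config, out, manifest)


def run_objects(bacteria: tio.CountMatrix, fungi: tio.CountMatrix,
                taxonomy: tio.TaxonomyMap, meta: tio.SampleMetadata,
                config: RunConfig) -> Path:
    """Run the pipeline on in-memory objects (inputs are not re-read)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}}
    manifest["config"]["sad_kingdoms"] = list(config.sad_kingdoms)
    return _run(bacteria, fungi, taxonomy, meta, config, out, manifest)


def _run(bacteria, fungi, taxonomy, meta, config: RunConfig, out: Path,
         manifest: dict) -> Path:
    seed = config.seed
    kingdom_tables = {}
    summary: dict = {}

    # ---- rarefaction (per replicate, excluded per kingdom only)
    try:
        for name, cm, depth in (("bacteria", bacteria,
                                 config.bacterial_depth),
                                ("fungi", fungi, config.fungal_depth)):
            meta.require_samples(cm.sample_ids)
            rarefied, excluded = cmx.rarefy_matrix(cm, depth, seed)
            rarefied = rarefied.drop_empty_taxa()
            kingdom_tables[name] = rarefied
            tio.write_count_table(rarefied, out / f"rarefied_{name}.tsv")
            manifest["stages"][f"rarefy_{name}"] = {
                "depth": depth, "seed": seed, "n_in": len(cm.sample_ids),
                "n_kept": len(rarefied.sample_ids), "excluded": excluded}
            if excluded:
                logger.warning("rarefy %s: excluded %s (below depth %d)",
                               name, excluded, depth)
    except Exception as exc:
        raise StageError(f"rarefaction stage failed: {exc}") from exc

    # ---- diversity + regressions vs wood density
    try:
        summary["regressions"] = {}
        for name, cm in kingdom_tables.items():
            div = cmx.diversity_table(cm)
            dens = meta.data.loc[div.index, "wood_density"]
            div.to_csv(out / f"diversity_{name}.tsv", sep="\t",
                       float_format=_FLOAT_FMT)
            regs = {}
            for metric in ("chao1", "shannon", "observed_richness"):
                fit = cmx.linear_fit(dens.to_numpy(), div[metric].to_numpy())
                regs[metric] = asdict(fit)
            pd.DataFrame(regs).T.rename_axis(index="metric").to_csv(
                out / f"regressions_{name}.tsv", sep="\t",
                float_format=_FLOAT_FMT)
            summary["regressions"][name] = regs
    except Exception as exc:
        raise StageError(f"diversity stage failed: {exc}") from exc

    # ---- MRT staging (bacterial community, replicate-averaged)
    try:
        bac = kingdom_tables["bacteria"]
        parent_rel = tio.average_replicates(bac, meta)
        parent_env = meta.parent_covariates().loc[parent_rel.index]
        tree = mrt.fit_mrt(parent_rel, parent_env,
                           max_leaves=config.mrt_max_leaves,
                           min_node_size=config.mrt_min_node_size)
        assignment = mrt.assign_stages(tree, parent_env)
        parent_stage = assignment.stages
        # replicates inherit the parent's stage
        rep_stage = {sid: parent_stage[meta.data.at[sid, "replicate_of"]]
                     for sid in bac.sample_ids
                     if meta.data.at[sid, "replicate_of"] in parent_stage}
        (out / "mrt_tree.txt").write_text(tree.render(), encoding="utf-8")
        _json_dump(tree.to_dict(), out / "mrt_tree.json")
        assignment.to_frame().to_csv(out / "stages_parents.tsv", sep="\t")
        pd.DataFrame({"stage": pd.Series(rep_stage)}).rename_axis(
            index="sample_id").to_csv(out / "stages_replicates.tsv", sep="\t")
        thresholds = sorted(
            (n.split_threshold for n in _internal_nodes(tree)
             if n.split_variable == "wood_density"), reverse=True)
        summary["mrt"] = {
            "split_variables": [n.split_variable
                                for n in _internal_nodes(tree)],
            "density_thresholds": thresholds,
            "stage_sizes": {s: sum(1 for v in parent_stage.values()
                                   if v == s)
                            for s in sorted(set(parent_stage.values()))},
        }
        manifest["stages"]["mrt"] = summary["mrt"]
    except Exception as exc:
        raise StageError(f"MRT stage failed: {exc}") from exc

    stage_parents: dict[str, list[str]] = {}
    for parent, stg in parent_stage.items():
        stage_parents.setdefault(stg, []).append(parent)
    stage_reps: dict[str, list[str]] = {}
    for sid, stg in rep_stage.items():
        stage_reps.setdefault(stg, []).append(sid)

    # ---- differential abundance per stage pair (bacteria)
    if not config.skip_diffabund:
        try:
            genus_bac = tio.aggregate_taxa(bac, taxonomy,
                                           config.diffabund_rank)
            pairs = [("early", "middle"), ("middle", "late"),
                     ("early", "late")]
            summary["diff_abundance"] = {}
            for ga, gb in pairs:
                if ga not in stage_reps or gb not in stage_reps:
                    continue
                res = da.metastats_test(
                    genus_bac, stage_reps[ga], stage_reps[gb],
                    n_perm=config.diffabund_n_perm, seed=seed)
                if not config.diffabund_fdr:
                    res = res.drop(columns=["q_value"])
                res.to_csv(out / f"diffabund_{ga}_vs_{gb}.tsv", sep="\t",
                           float_format=_FLOAT_FMT)
                sig = res["q_value"] <= 0.05 if config.diffabund_fdr \
                    else res["p_value"] <= 0.05
                summary["diff_abundance"][f"{ga}_vs_{gb}"] = {
                    "n_taxa": int(len(res)),
                    "n_significant": int(sig.sum())}
        except Exception as exc:
            raise StageError(f"differential abundance stage failed: "
                             f"{exc}") from exc

    # ---- co-occurrence networks (genus level, both kingdoms)
    if not config.skip_network:
        try:
            genus_tables = {}
            kingdoms: dict[str, str] = {}
            for name, cm in kingdom_tables.items():
                agg = tio.aggregate_taxa(cm, taxonomy, config.network_rank)
                genus_tables[name] = agg
                for genus in agg.taxon_ids:
                    kingdoms[genus] = name
            combined = pd.concat(
                [genus_tables["bacteria"].data, genus_tables["fungi"].data],
                axis=1).fillna(0).astype(np.int64)
            combined = tio.CountMatrix(combined)
            summary["networks"] = {}
            nets = {"all": sorted(parent_stage)}
            nets.update({s: sorted(ps) for s, ps in stage_parents.items()})
            for label, parents_in in nets.items():
                reps = [sid for sid in combined.sample_ids
                        if meta.data.at[sid, "replicate_of"] in parents_in]
                sub = combined.select_samples(reps).drop_empty_taxa()
                meta_sub = tio.SampleMetadata(meta.data.loc[reps].copy())
                try:
                    filtered = cnet.filter_genera(
                        sub, config.network_min_representatives,
                        config.network_filter_mode)
                    rel = tio.average_replicates(filtered, meta_sub)
                    r, p = cnet.correlation_matrix(rel)
                    net = cnet.build_network(
                        r, p, abs_r=config.network_abs_r,
                        p_max=config.network_p_max,
                        use_fdr=config.network_use_fdr,
                        q_max=config.network_q_max, kingdoms=kingdoms)
                except ValueError as ve:
                    logger.warning("network %s skipped: %s", label, ve)
                    summary["networks"][label] = {"skipped": str(ve)}
                    continue
                cnet.export_network(
                    net,
                    edge_path=out / f"network_{label}_edges.tsv",
                    node_path=out / f"network_{label}_nodes.tsv",
                    graphml_path=out / f"network_{label}.graphml")
                ns = cnet.network_stats(net)
                summary["networks"][label] = {
                    "n_nodes": ns["n_nodes"], "n_edges": ns["n_edges"],
                    "average_degree": ns["average_degree"],
                    "key_nodes": ns["key_nodes"][:10]}
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"network stage failed: {exc}") from exc

    # ---- per-sample SAD model comparison
    if not config.skip_sad:
        try:
            summary["sad"] = {}
            for name in config.sad_kingdoms:
                cm = kingdom_tables[name]
                rows = []
                weight_rows = {}
                for sid in cm.sample_ids:
                    ra = sad.RankAbundance.from_counts(
                        cm.data.loc[sid].to_numpy())
                    comp = sad.compare_models(ra, sample_id=sid,
                                              margin=config.sad_margin,
                                              scoring=config.sad_scoring)
                    weight_rows[sid] = comp.akaike_weight
                    for model in sad.ALL_MODELS:
                        fit = comp.fits[model]
                        rows.append({
                            "sample_id": sid, "model": model,
                            "params": json.dumps(fit.params,
                                                 sort_keys=True),
                            "log_likelihood": fit.log_likelihood,
                            "npar": fit.npar, "aic": fit.aic,
                            "akaike_weight": comp.akaike_weight[model],
                            "converged": fit.converged,
                            "best_model": comp.best_model,
                            "verdict": comp.verdict,
                            "stage": rep_stage.get(sid, "unstaged"),
                        })
                fits_df = pd.DataFrame(rows)
                fits_df.to_csv(out / f"sadfit_{name}.tsv", sep="\t",
                               index=False, float_format=_FLOAT_FMT)
                pd.DataFrame(weight_rows).T.rename_axis(
                    index="sample_id").to_csv(
                    out / f"sad_weights_{name}.tsv", sep="\t",
                    float_format=_FLOAT_FMT)
                verdicts = fits_df.drop_duplicates("sample_id")
                stage_verdicts = {}
                for stg in sorted(set(rep_stage.values())):
                    vs = verdicts.loc[verdicts["stage"] == stg, "verdict"]
                    stage_verdicts[stg] = dict(vs.value_counts())
                summary["sad"][name] = {
                    "stage_verdicts": {
                        s: {k: int(v) for k, v in d.items()}
                        for s, d in stage_verdicts.items()}}
        except Exception as exc:
            raise StageError(f"SAD stage failed: {exc}") from exc

    _json_dump(summary, out / "summary.json")
    _json_dump(manifest, out / "manifest.json")
    return out


def _internal_nodes(tree: mrt.MRTNode) -> list[mrt.MRTNode]:
    if tree.is_leaf:
        return []
    return [tree] + _internal_nodes(tree.left) + _internal_nodes(tree.right)
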