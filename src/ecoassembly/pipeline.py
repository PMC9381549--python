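"""End-to-end orchestration: simulate or load a dataset, then run the full
analysis graph (taxonomy filter → optional rarefaction → α-diversity →
total-sum scaling → Bray–Curtis and βMNTD → PCoA / PERMANOVA / dispersion →
assembly processes → cohesion → dbRDA + variance partitioning → FL–PA
pairwise dissimilarity → RDA), writing every stage's outputs plus a run
manifest sufficient to reproduce the run bit-for-bit.
"""
from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from . import __version__
from .core import (
    CountTable,
    align_table_and_tree,
    filter_by_taxonomy,
    rarefy,
    read_count_table,
    read_metadata,
    read_taxonomy,
    read_tree,
    to_relative_abundance,
    write_distance_matrix,
)
from .assembly import quantify_assembly, summarize_processes
from .cohesion import compute_cohesion
from .diversity import alpha_diversity, beta_mntd, bray_curtis
from .ordination import betadisper, db_rda, pcoa, permanova, rda, variance_partition, vif_prune
from .simulate import EstuaryConfig, simulate_estuary_dataset

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDE = (
    ("domain", "Eukaryota"),
    ("domain", "Archaea"),
    ("order", "Chloroplast"),
    ("family", "Mitochondria"),
)

OM_NUTRIENT_VARS = ("SPM", "POM_pct", "chla", "DOP", "phosphate")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending context."""


@dataclass
class AnalysisConfig:
    """Inputs and constants for one pipeline run.

    Either ``simulate`` is set (synthetic estuary scenario) or all four input
    paths are.  Null-model replicate counts and thresholds default to the
    standard values (999 null draws for βNTI/RC, 200 cohesion iterations,
    999/1000 permutations, |βNTI| threshold 2, |RC| threshold 0.95, VIF 10,
    prevalence 150 reads, persistence 0.1).
    """

    simulate: EstuaryConfig | None = None
    table_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    rarefaction_depth: int | None = None
    exclude_patterns: Sequence[tuple[str, str]] = DEFAULT_EXCLUDE
    n_null: int = 999
    cohesion_iterations: int = 200
    permanova_permutations: int = 999
    rda_permutations: int = 1000
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    vif_threshold: float = 10.0
    min_total_reads: int = 150
    persistence_cutoff: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("bnti_threshold", "rc_threshold", "vif_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.simulate is None and not all(
            (self.table_path, self.tree_path, self.metadata_path, self.taxonomy_path)
        ):
            raise ValueError("provide either a simulate block or all four input paths")


@dataclass
class RunManifest:
    config: dict
    version: str
    outputs: dict[str, str] = field(default_factory=dict)  # file -> sha256
    warnings: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str, sort_keys=True))


def _stage_seed(seed: int, stage: str) -> int:
    """Stage-name-hashed substream: adding a stage never perturbs the others."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(stage.encode()),))
    return int(ss.generate_state(1)[0]) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def flpa_pairwise_dissimilarity(
    bc: DistanceMatrix, bmntd: DistanceMatrix, metadata: pd.DataFrame
) -> pd.DataFrame:
    """FL-vs-PA dissimilarity per (station, date).

    Metadata must pair each free-living sample with its particle-attached
    counterpart by (station, date); unpaired keys are skipped with a warning,
    duplicated (station, date, fraction) keys are an error.
    """
    md = metadata
    for col in ("station", "date", "fraction"):
        if col not in md.columns:
            raise ValueError(f"metadata lacks column {col!r}")
    keys = md.groupby(["station", "date", "fraction"]).size()
    dup = keys[keys > 1]
    if len(dup):
        raise ValueError(f"duplicate pairing key(s): {list(dup.index)}")
    rows = []
    for (station, date), sub in md.groupby(["station", "date"], sort=True):
        fl = sub.index[sub["fraction"] == "FL"]
        pa = sub.index[sub["fraction"] == "PA"]
        if len(fl) != 1 or len(pa) != 1:
            logger.warning("unpaired station-date (%s, %s); skipped", station, date)
            continue
        a, b = fl[0], pa[0]
        if a not in bc.ids or b not in bc.ids:
            logger.warning("samples (%s, %s) absent from distance matrices; skipped", a, b)
            continue
        rows.append(
            {
                "station": station,
                "date": date,
                "bray_curtis": float(bc[a, b]),
                "beta_mntd": float(bmntd[a, b]),
            }
        )
    return pd.DataFrame(rows)


def _prune_and_fit(dist, predictors, groups, vif_threshold, n_perm, seed):
    pruned = vif_prune(predictors, threshold=vif_threshold)
    x = predictors[pruned.retained]
    fit = db_rda(dist, x, n_perm=n_perm, seed=seed)
    live_groups = {
        g: [c for c in cols if c in pruned.retained] for g, cols in groups.items()
    }
    live_groups = {g: cols for g, cols in live_groups.items() if cols}
    vp = variance_partition(dist, x, live_groups) if len(live_groups) >= 2 else None
    return pruned, fit, vp


def run_pipeline(config: AnalysisConfig, outdir: str | Path) -> RunManifest:
    """Execute every stage in order, writing stage outputs and a manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config), version=__version__)
    collector = _WarningCollector()
    logging.getLogger("ecoassembly").addHandler(collector)
    written: list[Path] = []

    def save_df(df: pd.DataFrame, name: str, **kwargs) -> None:
        path = out / name
        df.to_csv(path, sep="\t", **kwargs)
        written.append(path)

    def save_json(obj, name: str) -> None:
        path = out / name
        path.write_text(json.dumps(obj, indent=2, default=str, sort_keys=True))
        written.append(path)

    def stage(name):
        class _Stage:
            def __enter__(self):
                logger.info("stage: %s", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return _Stage()

    try:
        with stage("load"):
            if config.simulate is not None:
                ds = simulate_estuary_dataset(config.simulate)
                table, tree, metadata, taxonomy = ds.table, ds.tree, ds.metadata, ds.taxonomy
                save_json(ds.provenance, "provenance.json")
            else:
                table = read_count_table(config.table_path)
                tree = read_tree(config.tree_path)
                metadata = read_metadata(config.metadata_path)
                taxonomy = read_taxonomy(config.taxonomy_path)
            table.write(out / "table.tsv")
            written.append(out / "table.tsv")
            tree.write(str(out / "tree.nwk"))
            written.append(out / "tree.nwk")
            save_df(metadata, "metadata.tsv")
            save_df(taxonomy, "taxonomy.tsv")

        with stage("taxonomy_filter"):
            table = filter_by_taxonomy(table, taxonomy, config.exclude_patterns, strict=False)

        with stage("rarefy"):
            if config.rarefaction_depth is not None:
                result = rarefy(table, config.rarefaction_depth, seed=_stage_seed(config.seed, "rarefy"))
                table = result.table
                metadata = metadata.loc[table.sample_ids]
            table, tree = align_table_and_tree(table, tree)
            table.write(out / "filtered_table.tsv")
            written.append(out / "filtered_table.tsv")

        with stage("alpha_diversity"):
            save_df(alpha_diversity(table, tree), "alpha_diversity.tsv")

        with stage("relative_abundance"):
            rel = to_relative_abundance(table)

        with stage("beta_diversity"):
            bc = bray_curtis(rel)
            bm = beta_mntd(rel, tree)
            write_distance_matrix(bc, out / "bray_curtis.tsv")
            write_distance_matrix(bm, out / "beta_mntd.tsv")
            written += [out / "bray_curtis.tsv", out / "beta_mntd.tsv"]

        with stage("ordination"):
            ord_bc = pcoa(bc, correction="cailliez")
            save_df(ord_bc.coordinates.iloc[:, :4], "pcoa_bray_curtis.tsv")
            terms = ["station", "date", "fraction"]
            perm = permanova(
                bc, metadata, terms,
                n_perm=config.permanova_permutations,
                seed=_stage_seed(config.seed, "permanova"),
            )
            save_df(perm.table, "permanova.tsv")
            disp_rows = []
            for term in terms:
                res = betadisper(
                    bc, metadata[term],
                    n_perm=config.permanova_permutations,
                    seed=_stage_seed(config.seed, f"betadisper:{term}"),
                )
                disp_rows.append({"term": term, "f_statistic": res.f_statistic, "p_value": res.p_value})
            save_df(pd.DataFrame(disp_rows).set_index("term"), "betadisper.tsv")

        with stage("assembly_processes"):
            frames = []
            for fraction, sub in metadata.groupby("fraction"):
                ft = CountTable(table.data.loc[sub.index])
                _, ftree = align_table_and_tree(
                    CountTable(ft.data.loc[:, ft.data.sum(axis=0) > 0]), tree
                )
                ft = CountTable(ft.data.loc[:, ft.data.sum(axis=0) > 0])
                pairs = quantify_assembly(
                    ft, ftree,
                    n_null=config.n_null,
                    seed=_stage_seed(config.seed, f"assembly:{fraction}"),
                    bnti_threshold=config.bnti_threshold,
                    rc_threshold=config.rc_threshold,
                )
                pairs["fraction"] = fraction
                frames.append(pairs)
            assembly_pairs = pd.concat(frames)
            save_df(assembly_pairs, "assembly_pairs.tsv")
            summaries = []
            for fraction, sub in assembly_pairs.groupby("fraction"):
                s = summarize_processes(sub.drop(columns="fraction"))
                s.insert(0, "fraction", fraction)
                summaries.append(s)
            save_df(pd.concat(summaries), "assembly_summary.tsv")

        with stage("cohesion"):
            cohesion_frames = []
            conn_frames = []
            cohesion_prov = {}
            for fraction, sub in metadata.groupby("fraction"):
                ft = CountTable(table.data.loc[sub.index])
                res = compute_cohesion(
                    ft,
                    min_total_reads=config.min_total_reads,
                    persistence_cutoff=config.persistence_cutoff,
                    iterations=config.cohesion_iterations,
                    seed=_stage_seed(config.seed, f"cohesion:{fraction}"),
                )
                cohesion_frames.append(res.cohesion.assign(fraction=fraction))
                conn_frames.append(res.connectedness.assign(fraction=fraction))
                cohesion_prov[fraction] = res.provenance
            cohesion_table = pd.concat(cohesion_frames)
            save_df(cohesion_table, "cohesion.tsv")
            save_df(pd.concat(conn_frames), "connectedness.tsv")
            save_json(cohesion_prov, "cohesion_provenance.json")

        with stage("dbrda_varpart"):
            dbrda_out = {}
            for fraction, sub in metadata.groupby("fraction"):
                ids = list(sub.index)
                preds = metadata.loc[ids, ["salinity", "temperature", *OM_NUTRIENT_VARS]].copy()
                coh = cohesion_table.loc[ids]
                preds["positive_cohesion"] = coh["positive"]
                preds["abs_negative_cohesion"] = coh["abs_negative"]
                groups = {
                    "salinity": ["salinity"],
                    "temperature": ["temperature"],
                    "om_nutrients": list(OM_NUTRIENT_VARS),
                    "cohesion": ["positive_cohesion", "abs_negative_cohesion"],
                }
                pruned, fit, vp = _prune_and_fit(
                    bc.filter(ids), preds, groups, config.vif_threshold,
                    config.rda_permutations, _stage_seed(config.seed, f"dbrda:{fraction}"),
                )
                dbrda_out[fraction] = {
                    "retained_predictors": pruned.retained,
                    "removed_predictors": pruned.removed,
                    "r2": fit.r2,
                    "adjusted_r2": fit.adjusted_r2,
                    "p_overall": fit.p_overall,
                    "axis_p_values": None if fit.axis_p_values is None else fit.axis_p_values.tolist(),
                    "varpart": None if vp is None else {
                        "cells": {"+".join(sorted(k)): v for k, v in vp.cells.items()},
                        "total_adjusted_r2": vp.total_adjusted_r2,
                        "residual": vp.residual,
                    },
                }
            save_json(dbrda_out, "dbrda_varpart.json")

        with stage("flpa_dissimilarity"):
            flpa = flpa_pairwise_dissimilarity(bc, bm, metadata)
            save_df(flpa, "flpa_dissimilarity.tsv", index=False)

        with stage("flpa_rda"):
            rda_out = None
            if len(flpa) >= 8:
                key = flpa.set_index(["station", "date"])
                env = metadata[metadata["fraction"] == "FL"].set_index(["station", "date"])
                env = env.loc[key.index]
                coh_by_sample = cohesion_table
                fl_ids = metadata[metadata["fraction"] == "FL"].set_index(["station", "date"]).loc[key.index].index
                preds = env[["salinity", "temperature", "phosphate", "DOP", "SPM", "POM_pct", "chla"]].copy()
                for fraction in ("FL", "PA"):
                    md_f = metadata[metadata["fraction"] == fraction].reset_index().set_index(["station", "date"])
                    sid = md_f.loc[key.index, md_f.columns[0]]
                    preds[f"{fraction}_positive_cohesion"] = coh_by_sample.loc[sid.to_numpy(), "positive"].to_numpy()
                    preds[f"{fraction}_abs_negative_cohesion"] = coh_by_sample.loc[sid.to_numpy(), "abs_negative"].to_numpy()
                preds.index = [f"{s}|{d}" for s, d in key.index]
                resp = key[["bray_curtis", "beta_mntd"]].copy()
                resp.index = preds.index
                pruned = vif_prune(preds, threshold=config.vif_threshold)
                fit = rda(
                    resp, preds[pruned.retained],
                    n_perm=config.rda_permutations,
                    seed=_stage_seed(config.seed, "flpa_rda"),
                )
                rda_out = {
                    "retained_predictors": pruned.retained,
                    "r2": fit.r2,
                    "adjusted_r2": fit.adjusted_r2,
                    "p_overall": fit.p_overall,
                    "biplot_scores": fit.biplot_scores.to_dict(),
                }
            else:
                logger.warning("too few FL-PA pairs for an RDA; stage skipped")
            save_json(rda_out, "flpa_rda.json")
    finally:
        logging.getLogger("ecoassembly").removeHandler(collector)

    manifest.warnings = collector.messages
    for path in written:
        manifest.outputs[path.name] = _sha256(path)
    manifest.write(out / "manifest.json")
    return manifest
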