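"""End-to-end orchestration: simulate -> stability -> indicators -> network
-> diversity -> functions -> report, as one seeded, reproducible run.

One master seed is split deterministically per stage (fixed offsets) so a
stage rerun with the same config reproduces the full-pipeline result byte
for byte. Every output lands in the run directory; a manifest records the
merged configuration, the stage seeds and the files written.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from . import diversity as dv
from . import functions as fn
from . import indicators as ind
from . import io as rio
from . import network as nw
from . import simulate as sim
from . import stability as st

logger = logging.getLogger("rhizostab")

__all__ = ["RunConfig", "run_all", "load_config", "assemble_report"]

# Stage seed offsets from the master seed (kept below 2**31 by modulus).
STAGE_SEED_OFFSETS = {"simulate": 0, "indval": 11, "anosim": 13, "annotation": 17}


@dataclass
class RunConfig:
    """Merged configuration of a pipeline run: paths, thresholds, master seed."""

    out_dir: str = "run"
    simulate: bool = True
    counts: str | None = None
    metadata: str | None = None
    taxonomy: str | None = None
    tree: str | None = None
    annotations: str | None = None
    min_relab: float = 1e-5
    alpha: float = 0.05
    r_threshold: float = 0.7
    p_threshold: float = 0.001
    keystone_frac: float = 0.01
    nperm: int = 999
    top_k: int = 10
    top_modules: int = 4
    n_functions: int = 20
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.min_relab < 1):
            raise ValueError("min_relab must be in [0, 1)")
        for name in ("alpha", "p_threshold", "keystone_frac"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if not (-1 <= self.r_threshold <= 1):
            raise ValueError("r_threshold must be in [-1, 1]")
        if self.nperm < 1 or self.top_k < 1 or self.top_modules < 1:
            raise ValueError("nperm, top_k and top_modules must be >= 1")
        if self.seed is None:
            raise ValueError("a master seed is required for stochastic stages")
        if not self.simulate:
            for name in ("counts", "metadata", "taxonomy", "tree"):
                path = getattr(self, name)
                if path is None:
                    raise ValueError(f"--{name.replace('_', '-')} is required without --simulate")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{name} file not found: {path}")

    def stage_seed(self, stage: str) -> int:
        return (int(self.seed) + STAGE_SEED_OFFSETS[stage]) % (2 ** 31)


def load_config(path) -> dict:
    """Read a flat JSON or key=value config file into a dict."""
    text = Path(path).read_text()
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        out = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            out[key.strip()] = value.strip()
        return out


def _tsv(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, sep="\t", float_format=rio.FLOAT_FORMAT, **kw)
    return path


def run_all(cfg: RunConfig) -> dict:
    """Run every stage, returning a dict of output paths (also in the manifest)."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        # ---------------- inputs ----------------
        _stage("inputs")
        if cfg.simulate:
            study = sim.generate_study(sim.SimConfig(seed=cfg.stage_seed("simulate")))
            input_dir = out / "inputs"
            paths = sim.write_study(study, input_dir)
            counts, metadata, taxonomy, tree = (study.counts, study.metadata,
                                                study.taxonomy, study.tree)
            annotations = sim.generate_annotation_table(
                taxonomy, n_functions=cfg.n_functions, seed=cfg.stage_seed("annotation"))
            outputs.update({k: str(v) for k, v in paths.items()})
            outputs["annotations"] = str(_tsv(annotations, input_dir / "functions.tsv", index=False))
        else:
            counts = rio.read_count_table(cfg.counts)
            metadata = rio.read_metadata(cfg.metadata)
            taxonomy = rio.read_taxonomy(cfg.taxonomy)
            tree = rio.read_tree(cfg.tree)
            annotations = (fn.read_function_table(cfg.annotations)
                           if cfg.annotations else None)
        groups = metadata["group_years"].astype(str)

        # ---------------- stability ----------------
        _stage("stability")
        logger.info("mean relative-abundance filter: > %g", cfg.min_relab)
        relab = st.to_relative_abundance(counts)
        filtered = st.filter_by_mean_relab(relab, cfg.min_relab)
        counts_f = counts.loc[filtered.index]
        stab_group = st.avd(filtered, metadata, by="group")
        stab_cell = st.avd(filtered, metadata, by="group_season")
        per_sample = stab_group.per_sample.rename(columns={"avd": "avd_group",
                                                           "stability_index": "stability_group"})
        per_sample[["season"]] = metadata.loc[per_sample.index, ["season"]]
        per_sample["avd_group_season"] = stab_cell.per_sample["avd"]
        per_sample["stability_group_season"] = stab_cell.per_sample["stability_index"]
        outputs["stability_samples"] = str(_tsv(per_sample, out / "stability_samples.tsv"))
        groups_tbl = pd.concat([
            stab_group.per_group.assign(grouping="group"),
            stab_cell.per_group.assign(grouping="group_season"),
        ])
        outputs["stability_groups"] = str(_tsv(groups_tbl, out / "stability_groups.tsv", index=False))

        # ---------------- indicators ----------------
        _stage("indicators")
        logger.info("indicator alpha: %g, permutations: %d", cfg.alpha, cfg.nperm)
        factors = ind.tmm_factors(counts_f)
        cpm_table = ind.cpm(counts_f, factors)
        iv = ind.indval(filtered, groups, nperm=cfg.nperm,
                        seed=cfg.stage_seed("indval"), alpha=cfg.alpha)
        selected = ind.select_indicators(iv, taxonomy, alpha=cfg.alpha)
        lrt = ind.nb_lrt(counts_f, groups, factors)
        core = ind.select_core_taxa(iv, lrt, alpha=cfg.alpha)
        edges, accumulated = ind.bipartite_network(selected, filtered)
        outputs["indval"] = str(_tsv(selected, out / "indval.tsv"))
        outputs["lrt"] = str(_tsv(lrt, out / "lrt.tsv"))
        outputs["core_taxa"] = str(_tsv(pd.DataFrame(index=core), out / "core_taxa.tsv"))
        outputs["bipartite_edges"] = str(_tsv(edges, out / "bipartite_edges.tsv", index=False))
        if accumulated is not None:
            outputs["accumulated_indicators"] = str(
                _tsv(accumulated, out / "accumulated_indicators.tsv"))

        # ---------------- co-occurrence network ----------------
        _stage("network")
        logger.info("network thresholds: rho > %g, p < %g; keystone fraction %g",
                    cfg.r_threshold, cfg.p_threshold, cfg.keystone_frac)
        net = nw.spearman_network(cpm_table, taxonomy,
                                  r_threshold=cfg.r_threshold, p_threshold=cfg.p_threshold)
        modules, q = nw.greedy_modularity(net)
        keystones = nw.keystone_species(net, fraction=cfg.keystone_frac,
                                        abundance=filtered.sum(axis=1))
        summary = nw.module_abundance(net, core, filtered, metadata,
                                      top_k=cfg.top_modules)
        stats = nw.network_stats(net)
        stats["modularity"] = q
        net_paths = rio.write_network(net, out / "network")
        outputs["network_graphml"], outputs["network_edges"], outputs["network_nodes"] = map(
            str, net_paths)
        outputs["modules"] = str(_tsv(modules.to_frame(), out / "modules.tsv",
                                      index_label="otu_id"))
        outputs["keystones"] = str(_tsv(pd.DataFrame({"otu_id": keystones}),
                                        out / "keystones.tsv", index=False))
        outputs["module_abundance"] = str(_tsv(summary.per_sample,
                                               out / "module_abundance.tsv"))
        (out / "network_stats.json").write_text(
            json.dumps({k: v for k, v in stats.items() if k != "degree_histogram"},
                       indent=1, sort_keys=True))
        outputs["network_stats"] = str(out / "network_stats.json")

        # ---------------- diversity ----------------
        _stage("diversity")
        pd_series = dv.faith_pd_samples(tree, counts_f)
        div = pd_series.to_frame()
        div["stability_index"] = stab_group.per_sample["stability_index"]
        div["group_years"] = metadata.loc[div.index, "group_years"]
        div["season"] = metadata.loc[div.index, "season"]
        outputs["diversity"] = str(_tsv(div, out / "diversity.tsv", index_label="sample_id"))
        anova = dv.anova_oneway(pd_series, metadata["group_years"])
        bc = dv.bray_curtis(filtered)
        ano = dv.anosim(bc, groups, nperm=cfg.nperm, seed=cfg.stage_seed("anosim"))
        (out / "diversity_tests.json").write_text(json.dumps(
            {"pd_anova": anova,
             "anosim": {"R": ano.R, "p": ano.p, "nperm": ano.nperm}},
            indent=1, sort_keys=True))
        outputs["diversity_tests"] = str(out / "diversity_tests.json")

        # ---------------- report ----------------
        _stage("report")
        sig = selected[selected["significant"]]
        predictors = {
            "faith_pd": pd_series,
            "bacterial_indicators": filtered.reindex(
                sig.index[sig["kingdom"] == "Bacteria"]).fillna(0).sum(axis=0),
            "fungal_indicators": filtered.reindex(
                sig.index[sig["kingdom"] == "Fungi"]).fillna(0).sum(axis=0),
            "core_taxa": filtered.reindex(core).fillna(0).sum(axis=0),
            "keystone_taxa": filtered.reindex(keystones).fillna(0).sum(axis=0),
        }
        for mid in summary.top_modules:
            predictors[f"module_{mid}_core"] = summary.per_sample.loc[mid]
        report = dv.stability_association_report(
            stab_group.per_sample["stability_index"], predictors, metadata)
        outputs["associations"] = str(_tsv(report, out / "associations.tsv", index=False))

        # ---------------- functions ----------------
        if annotations is not None:
            _stage("functions")
            matrix, top = fn.aggregate_module_functions(
                net.modules, filtered, annotations, top_k=cfg.top_k)
            outputs["function_matrix"] = str(_tsv(matrix, out / "function_matrix.tsv"))
            outputs["function_top"] = str(_tsv(top, out / "function_top.tsv", index=False))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    manifest = {
        "package": "rhizostab",
        "version": __version__,
        "config": asdict(cfg),
        "stage_seeds": {s: cfg.stage_seed(s) for s in STAGE_SEED_OFFSETS},
        "outputs": {k: str(Path(v).relative_to(out)) for k, v in outputs.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    outputs["manifest"] = str(out / "manifest.json")
    return outputs


def assemble_report(run_dir) -> pd.DataFrame:
    """Re-read a finished run directory and return its association table."""
    path = Path(run_dir) / "associations.tsv"
    if not path.exists():
        raise FileNotFoundError(f"no associations.tsv under {run_dir}; run the pipeline first")
    return pd.read_csv(path, sep="\t")
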