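"""Synthetic wetland-recovery study generator with planted ground truth.

The generator emulates the statistical structure the analysis assumes: a
4-recovery-group (10/20/30/40 years) x 3-season x 14-transect design with
4 samples per transect (168 samples), two kingdoms of OTUs, planted
group-associated indicator OTUs, planted co-varying OTU modules, and a
per-group overdispersion gradient that makes younger wetlands noisier.

Counts are drawn per sample by a Dirichlet-multinomial-style scheme:
log-normal baseline abundances, an additive per-sample latent log factor
shared within each module (inducing positive rank correlation), an
indicator fold-change in the target group, independent gamma multipliers
with variance phi (the group's overdispersion), and finally a multinomial
draw at the sample's library size. Overdispersion - not mean shifts -
encodes the stability gradient, because AVD measures dispersion around
group means.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import skbio

from . import io as rio

__all__ = ["SimConfig", "GroundTruth", "SimulatedStudy", "generate_study",
           "generate_annotation_table", "write_study"]

# Fixed child-seed offsets so each stage is independently reproducible.
SEED_OFFSETS = {"abundance": 0, "tree": 101, "annotation": 202}

_BACTERIAL_PHYLA = {
    "Proteobacteria": 0.30, "Cyanobacteria": 0.12, "Bacteroidetes": 0.12,
    "Acidobacteria": 0.10, "Chloroflexi": 0.08, "Actinobacteria": 0.08,
    "Firmicutes": 0.06, "Nitrospirae": 0.06, "Euryarchaeota": 0.04,
    "Spirochaetes": 0.04,
}
_FUNGAL_PHYLA = {
    "Ascomycota": 0.45, "Basidiomycota": 0.25, "Rozellomycota": 0.12,
    "GS01": 0.06, "Monoblepharomycota": 0.06, "Glomeromycota": 0.06,
}

_GUILD_NAMES = (
    "soil_saprotroph", "wood_saprotroph", "plant_pathogen", "fungal_parasite",
    "ectomycorrhizal", "arbuscular_mycorrhizal", "animal_pathogen", "endophyte",
    "leaf_saprotroph", "undefined_saprotroph",
)


@dataclass
class SimConfig:
    """Study-design and noise parameters of the synthetic generator."""

    ages: tuple = (10, 20, 30, 40)
    transects_per_group: dict = field(default_factory=lambda: {10: 3, 20: 5, 30: 3, 40: 3})
    samples_per_transect: int = 4
    seasons: tuple = ("level", "wet", "dry")
    n_otus_bacteria: int = 600
    n_otus_fungi: int = 250
    n_indicator_otus: int = 30          # per recovery group, disjoint sets
    indicator_fold_change: float = 8.0
    n_modules: int = 4
    module_size: int = 25
    module_latent_sd: float = 1.0
    module_kingdoms: tuple | None = None  # default: 3 bacterial + 1 fungal style split
    module_baseline_boost: float = 2.0  # natural-log boost; core taxa are abundant
    baseline_log_sd: float = 1.5
    group_dispersion: dict = field(default_factory=lambda: {10: 0.8, 20: 0.4, 30: 0.25, 40: 0.2})
    library_size_mean: float = 5e4
    library_size_sd: float = 1e4
    seed: int = 0

    def validate(self) -> None:
        positive = [self.samples_per_transect, self.n_otus_bacteria, self.n_otus_fungi,
                    self.n_indicator_otus, self.indicator_fold_change, self.n_modules,
                    self.module_size, self.library_size_mean]
        if any(v <= 0 for v in positive):
            raise ValueError("all design sizes must be positive")
        if set(self.ages) != set(self.transects_per_group) or set(self.ages) != set(self.group_dispersion):
            raise ValueError("ages, transects_per_group and group_dispersion must agree")
        disp = [self.group_dispersion[a] for a in sorted(self.ages)]
        if any(d <= 0 for d in disp):
            raise ValueError("dispersions must be positive")
        if any(b < a for a, b in zip(disp[1:], disp[:-1])):
            # equal dispersions are allowed (null studies); increases are not
            raise ValueError("group dispersion must be non-increasing in age")
        n_otus = self.n_otus_bacteria + self.n_otus_fungi
        if self.n_modules * self.module_size > n_otus:
            raise ValueError("module_size x n_modules exceeds the number of OTUs")
        kingdoms = self.resolved_module_kingdoms()
        for kingdom, pool in (("Bacteria", self.n_otus_bacteria), ("Fungi", self.n_otus_fungi)):
            demand = kingdoms.count(kingdom) * self.module_size
            if demand > pool:
                raise ValueError(f"module demand exceeds {kingdom} OTU pool")

    def resolved_module_kingdoms(self) -> list:
        if self.module_kingdoms is not None:
            return list(self.module_kingdoms)
        n_bact = max(1, round(self.n_modules * self.n_otus_bacteria
                              / (self.n_otus_bacteria + self.n_otus_fungi)))
        n_bact = min(n_bact, self.n_modules)
        return ["Bacteria"] * n_bact + ["Fungi"] * (self.n_modules - n_bact)


@dataclass
class GroundTruth:
    """Planted structure of a simulated study."""

    indicators: dict        # otu_id -> target recovery age
    modules: dict           # otu_id -> module id (1-based)
    group_dispersion: dict  # age -> phi
    module_kingdoms: list

    def to_json(self, path) -> None:
        payload = {
            "indicators": self.indicators,
            "modules": self.modules,
            "group_dispersion": {str(k): v for k, v in self.group_dispersion.items()},
            "module_kingdoms": self.module_kingdoms,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            indicators={k: int(v) for k, v in payload["indicators"].items()},
            modules={k: int(v) for k, v in payload["modules"].items()},
            group_dispersion={int(k): float(v) for k, v in payload["group_dispersion"].items()},
            module_kingdoms=list(payload["module_kingdoms"]),
        )


@dataclass
class SimulatedStudy:
    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame
    tree: skbio.TreeNode
    truth: GroundTruth
    config: SimConfig


def _child_seed(seed: int, stage: str) -> int:
    return (int(seed) + SEED_OFFSETS[stage]) % (2 ** 31)


def _make_metadata(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    idx = 1
    for age in sorted(cfg.ages):
        for t in range(1, cfg.transects_per_group[age] + 1):
            transect = f"{age}y_T{t}"
            for season in cfg.seasons:
                for _ in range(cfg.samples_per_transect):
                    rows.append((f"S{idx:03d}", age, season, transect))
                    idx += 1
    return pd.DataFrame(rows, columns=["sample_id", "group_years", "season", "transect"]
                        ).set_index("sample_id")


def _make_taxonomy(otu_ids: list, kingdoms: list, rng: np.random.Generator) -> pd.DataFrame:
    records = []
    for otu, kingdom in zip(otu_ids, kingdoms):
        weights = _BACTERIAL_PHYLA if kingdom == "Bacteria" else _FUNGAL_PHYLA
        phyla = list(weights)
        p = np.array(list(weights.values()), dtype=float)
        phylum = phyla[rng.choice(len(phyla), p=p / p.sum())]
        records.append({"kingdom": kingdom, "phylum": phylum})
    tax = pd.DataFrame(records, index=pd.Index(otu_ids, name="otu_id"))
    for rank in rio.RANKS:
        if rank not in tax.columns:
            tax[rank] = pd.NA
    return tax[list(rio.RANKS)]


def _make_tree(otu_ids: list, seed: int) -> skbio.TreeNode:
    """Pure-birth (Yule) random tree over all OTUs."""
    rng = random.Random(seed)
    taxa = dendropy.TaxonNamespace(otu_ids)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=len(otu_ids),
        taxon_namespace=taxa, rng=rng,
    )
    newick = tree.as_string(schema="newick", suppress_rooting=True)
    return skbio.TreeNode.read([newick])


def generate_study(cfg: SimConfig | None = None) -> SimulatedStudy:
    """Draw a full synthetic study (counts, metadata, taxonomy, tree, truth)."""
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(_child_seed(cfg.seed, "abundance"))

    otu_ids = ([f"B{i:04d}" for i in range(1, cfg.n_otus_bacteria + 1)]
               + [f"F{i:04d}" for i in range(1, cfg.n_otus_fungi + 1)])
    kingdoms = ["Bacteria"] * cfg.n_otus_bacteria + ["Fungi"] * cfg.n_otus_fungi
    n_otus = len(otu_ids)
    metadata = _make_metadata(cfg)

    # --- planted modules (kingdom-pure) and indicator sets (disjoint) ---
    module_kingdoms = cfg.resolved_module_kingdoms()
    module_of = np.full(n_otus, 0, dtype=int)  # 0 = none
    bact_pool = list(range(cfg.n_otus_bacteria))
    fung_pool = list(range(cfg.n_otus_bacteria, n_otus))
    for mid, kingdom in enumerate(module_kingdoms, start=1):
        pool = bact_pool if kingdom == "Bacteria" else fung_pool
        chosen = rng.choice(len(pool), size=cfg.module_size, replace=False)
        members = [pool[i] for i in sorted(chosen)]
        for i in members:
            module_of[i] = mid
        pool[:] = [p for p in pool if module_of[p] == 0]

    free = [i for i in range(n_otus) if module_of[i] == 0]
    indicator_of = {}
    for age in sorted(cfg.ages):
        chosen = rng.choice(len(free), size=cfg.n_indicator_otus, replace=False)
        members = [free[i] for i in sorted(chosen)]
        for i in members:
            indicator_of[i] = age
        free = [f for f in free if f not in set(members)]

    # --- baseline abundances ---
    baseline = rng.normal(0.0, cfg.baseline_log_sd, size=n_otus)
    baseline[module_of > 0] += cfg.module_baseline_boost
    log_fold = np.log(cfg.indicator_fold_change)

    # --- per-sample draws ---
    counts = np.zeros((n_otus, len(metadata)), dtype=np.int64)
    for j, (sample, row) in enumerate(metadata.iterrows()):
        age = int(row["group_years"])
        phi = cfg.group_dispersion[age]
        x = baseline.copy()
        latents = rng.normal(0.0, cfg.module_latent_sd, size=cfg.n_modules)
        mask = module_of > 0
        x[mask] += latents[module_of[mask] - 1]
        for i, target in indicator_of.items():
            if target == age:
                x[i] += log_fold
        p = np.exp(x - x.max())
        u = rng.gamma(shape=1.0 / phi, scale=phi, size=n_otus)
        p = p * u
        p = p / p.sum()
        lib = max(1000, int(round(rng.normal(cfg.library_size_mean, cfg.library_size_sd))))
        counts[:, j] = rng.multinomial(lib, p)

    counts_df = pd.DataFrame(counts, index=pd.Index(otu_ids, name="otu_id"),
                             columns=metadata.index)
    taxonomy = _make_taxonomy(otu_ids, kingdoms, rng)
    tree = _make_tree(otu_ids, _child_seed(cfg.seed, "tree"))
    truth = GroundTruth(
        indicators={otu_ids[i]: age for i, age in sorted(indicator_of.items())},
        modules={otu_ids[i]: int(module_of[i]) for i in range(n_otus) if module_of[i] > 0},
        group_dispersion=dict(cfg.group_dispersion),
        module_kingdoms=module_kingdoms,
    )
    return SimulatedStudy(counts=counts_df, metadata=metadata, taxonomy=taxonomy,
                          tree=tree, truth=truth, config=cfg)


def generate_annotation_table(taxonomy: pd.DataFrame, n_functions: int = 20,
                              seed: int = 0) -> pd.DataFrame:
    """Random OTU -> function annotation table with per-OTU weights summing to 1.

    Bacterial functions get COG-style ids, fungal ones guild-style names.
    """
    if n_functions < 1:
        raise ValueError("n_functions must be >= 1")
    rng = np.random.default_rng(_child_seed(seed, "annotation"))
    cogs = [f"COG{400 + i:04d}" for i in range(n_functions)]
    guilds = [(_GUILD_NAMES[i] if i < len(_GUILD_NAMES) else f"guild_{i}")
              for i in range(n_functions)]
    rows = []
    for otu, row in taxonomy.iterrows():
        pool = guilds if row["kingdom"] == "Fungi" else cogs
        k = 1 if n_functions == 1 else int(rng.integers(1, min(3, n_functions) + 1))
        chosen = rng.choice(n_functions, size=k, replace=False)
        weights = rng.dirichlet(np.ones(k)) if k > 1 else np.array([1.0])
        for c, w in zip(sorted(chosen), weights):
            rows.append((otu, pool[c], float(w)))
    return pd.DataFrame(rows, columns=["otu_id", "function_id", "weight"])


def write_study(study: SimulatedStudy, outdir) -> dict:
    """Write all study files in the pipeline's external formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "metadata": outdir / "metadata.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "tree": outdir / "tree.nwk",
        "ground_truth": outdir / "ground_truth.json",
    }
    rio.write_count_table(study.counts, paths["counts"])
    rio.write_metadata(study.metadata, paths["metadata"])
    rio.write_taxonomy(study.taxonomy, paths["taxonomy"])
    rio.write_tree(study.tree, paths["tree"])
    study.truth.to_json(paths["ground_truth"])
    return paths
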