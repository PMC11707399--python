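"""End-to-end orchestration: standardize -> indices -> networks ->
composites -> structure -> association, from one config with one master
seed.

Stage seeds are derived as (master_seed + crc32(stage name)) mod 2^31, so
adding a stage never perturbs another stage's draws. Every stage echoes its
parameters into the run report, making a run self-describing; a stage
failure marks the stage and skips its dependents instead of aborting the
whole report.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core_io import (
    SampleTable,
    SyntheticDataset,
    read_environment_table,
    read_metadata,
    read_sample_table,
    read_tree,
    write_edge_list,
    write_network,
    write_report,
    write_sample_table,
    KIND_BIOMASS,
)
from . import alpha as alpha_mod
from . import composite as composite_mod
from . import env_assoc as assoc_mod
from . import network as network_mod
from . import phylo as phylo_mod
from . import structure as structure_mod
from .synthetic import ScenarioConfig, generate_dataset


@dataclass
class RunConfig:
    """Inputs, stage parameters and the master seed of one pipeline run."""

    # either a synthetic scenario ...
    scenario: dict | None = None
    # ... or file inputs
    abundance_path: str | None = None
    biomass_path: str | None = None
    environment_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None

    log_base: float = 10.0
    shannon_base: float = 2.0
    n_null: int = 999
    network: dict = field(default_factory=lambda: dict(
        min_occurrence=0.2, corr_method="spearman", rho_min=0.6,
        alpha=0.05, mt_correction="fdr_bh",
    ))
    robustness_reps: int = 1000
    dominance_threshold: float = 0.02
    similarity_cut: float = 0.30
    permutations: int = 999
    min_group_sites: int = 4
    rda_parameters: list = field(default_factory=lambda: ["Sa", "Tu", "SiO3", "DIN", "Depth", "pH"])
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def stage_seed(master: int, stage: str) -> int:
    return (int(master) + zlib.crc32(stage.encode())) % (2**31 - 1)


def _load_inputs(config: RunConfig):
    if config.scenario is not None:
        sc = dict(config.scenario)
        sc.setdefault("seed", config.seed)
        dataset = generate_dataset(ScenarioConfig(**sc))
        return dataset
    if config.abundance_path is None:
        raise ValueError("config needs either a scenario or input paths")
    abundance = read_sample_table(config.abundance_path)
    biomass = (
        read_sample_table(config.biomass_path, KIND_BIOMASS)
        if config.biomass_path else None
    )
    environment = (
        read_environment_table(config.environment_path)
        if config.environment_path else None
    )
    metadata = read_metadata(config.metadata_path) if config.metadata_path else None
    tree = read_tree(config.tree_path) if config.tree_path else None
    groups = metadata.data["group"] if metadata is not None else None
    return SyntheticDataset(
        abundance, biomass, environment, metadata, tree,
        groups, pd.DataFrame(),
    )


def run(config: RunConfig, out_dir=None) -> dict:
    """Execute the full assessment; returns (and optionally writes) the report."""
    report: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
        "failed_stages": [],
    }
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def fail(stage, exc):
        report["failed_stages"].append(stage)
        report["stages"][stage] = {"status": "failed", "error": str(exc)}

    # ---- inputs -----------------------------------------------------------
    dataset = _load_inputs(config)
    abundance, biomass = dataset.abundance, dataset.biomass
    groups = dataset.true_groups
    report["stages"]["inputs"] = {
        "status": "ok",
        "n_sites": len(abundance.sites),
        "n_species": len(abundance.species),
        "groups": sorted(groups.unique()) if groups is not None else None,
    }
    if out:
        write_sample_table(abundance, out / "abundance.tsv")
        if biomass is not None:
            write_sample_table(biomass, out / "biomass.tsv")

    # ---- alpha diversity --------------------------------------------------
    alpha_df = None
    try:
        alpha_df = alpha_mod.alpha_table(abundance, biomass, config.shannon_base)
        report["stages"]["alpha"] = {
            "status": "ok", "shannon_base": config.shannon_base,
            "n_units": len(alpha_df),
        }
        if out:
            alpha_df.to_csv(out / "alpha_indices.tsv", sep="\t")
    except Exception as exc:
        fail("alpha", exc)

    # ---- phylogenetic diversity ------------------------------------------
    phylo_df = None
    if dataset.tree is None:
        report["stages"]["phylo"] = {"status": "skipped", "reason": "no tree supplied"}
    else:
        try:
            phylo_df = phylo_mod.phylo_table(
                abundance, dataset.tree, config.n_null,
                stage_seed(config.seed, "phylo"),
            )
            report["stages"]["phylo"] = {
                "status": "ok", "n_null": config.n_null,
                "tree_coverage": phylo_df.attrs["tree_coverage"],
            }
            if out:
                phylo_df.to_csv(out / "phylo_indices.tsv", sep="\t")
        except Exception as exc:
            fail("phylo", exc)

    # ---- per-group networks and stability --------------------------------
    stability_df = None
    topology_report = {}
    if groups is None:
        report["stages"]["network"] = {"status": "skipped", "reason": "no group labels"}
    else:
        try:
            records = {}
            for label in sorted(groups.unique()):
                sites = list(groups.index[groups == label])
                if len(sites) < config.min_group_sites:
                    topology_report[label] = {"status": "skipped",
                                              "reason": f"{len(sites)} sites"}
                    continue
                sub = abundance.subset_sites(sites)
                g = network_mod.build_network(
                    sub, log_base=config.log_base,
                    seed=stage_seed(config.seed, f"network:{label}"),
                    **config.network,
                )
                topo = network_mod.topology(g, seed=stage_seed(config.seed, f"topology:{label}"))
                topology_report[label] = {"status": "ok", **topo.as_dict()}
                dom = structure_mod.dominance(sub, config.dominance_threshold)
                dominant = list(dom.index[dom["dominant"]])
                records[label] = network_mod.stability_record(
                    sub, g, dominant,
                    reps=config.robustness_reps,
                    log_base=config.log_base,
                    seed=stage_seed(config.seed, f"robustness:{label}"),
                )
                if out:
                    write_network(g, out / f"network_{label}.graphml")
                    write_edge_list(g, out / f"network_{label}_edges.tsv")
                    dom.to_csv(out / f"dominance_{label}.tsv", sep="\t")
            stability_df = pd.DataFrame.from_dict(records, orient="index")
            report["stages"]["network"] = {
                "status": "ok", **config.network,
                "topology": topology_report,
            }
            if out and not stability_df.empty:
                stability_df.to_csv(out / "stability_indices.tsv", sep="\t")
        except Exception as exc:
            fail("network", exc)

    # ---- composites -------------------------------------------------------
    composites = {}
    for kind, table in (
        ("diversity", alpha_df),
        ("phyl", phylo_df),
        ("stability", stability_df),
    ):
        if table is None or table.empty:
            report["stages"][f"composite_{kind}"] = {
                "status": "skipped", "reason": "index table unavailable",
            }
            continue
        if len(table) < 2:
            report["stages"][f"composite_{kind}"] = {
                "status": "skipped", "reason": "fewer than 2 alternatives",
            }
            continue
        try:
            matrix, orientation = composite_mod.assemble(kind, table)
            result = composite_mod.evaluate(matrix, orientation)
            composites[kind] = result
            entry = {
                "status": "ok",
                "weights": result.weights.round(6).to_dict(),
                "constant_columns": result.constant_columns,
            }
            if kind in ("diversity", "phyl") and groups is not None:
                entry["group_summary"] = composite_mod.group_summary(
                    result.scores, groups
                ).round(6).to_dict()
            else:
                entry["scores"] = result.scores.round(6).to_dict()
            report["stages"][f"composite_{kind}"] = entry
            if out:
                result.scores.to_csv(out / f"composite_{kind}_scores.tsv", sep="\t")
                result.weights.to_csv(out / f"composite_{kind}_weights.tsv", sep="\t")
        except Exception as exc:
            fail(f"composite_{kind}", exc)

    # ---- community structure ---------------------------------------------
    dm = None
    try:
        dm = structure_mod.bray_curtis(abundance, config.log_base)
        z, cluster_labels = structure_mod.upgma_cluster(dm, config.similarity_cut)
        ordination = structure_mod.pcoa_ordination(dm)
        entry = {
            "status": "ok",
            "similarity_cut": config.similarity_cut,
            "n_clusters": int(cluster_labels.nunique()),
            "proportion_explained_axis1": float(ordination["proportion_explained"][0]),
        }
        if groups is not None and groups.value_counts().min() >= 2:
            entry["permanova"] = structure_mod.permanova_test(
                dm, groups, config.permutations,
                stage_seed(config.seed, "permanova"),
            )
            entry["axis_tests"] = structure_mod.axis_group_tests(
                ordination["coordinates"], groups
            ).to_dict()
        report["stages"]["structure"] = entry
        if out:
            ordination["coordinates"].to_csv(out / "pcoa_coordinates.tsv", sep="\t")
            cluster_labels.to_csv(out / "clusters.tsv", sep="\t")
            (out / "dendrogram.nwk").write_text(
                structure_mod.linkage_to_newick(z, list(dm.ids))
            )
    except Exception as exc:
        fail("structure", exc)

    # ---- environment association -----------------------------------------
    if dataset.environment is None:
        report["stages"]["association"] = {"status": "skipped", "reason": "no environment table"}
    elif dm is None:
        report["stages"]["association"] = {"status": "skipped", "reason": "structure stage failed"}
    else:
        try:
            env_dm = assoc_mod.environment_distance(dataset.environment)
            mantel = assoc_mod.mantel_test(
                dm, env_dm, permutations=config.permutations,
                seed=stage_seed(config.seed, "mantel"),
            )
            entry = {"status": "ok", "mantel": mantel}
            dom_all = structure_mod.dominance(abundance, config.dominance_threshold)
            dominant = list(dom_all.index[dom_all["dominant"]])
            params = [p for p in config.rda_parameters
                      if p in dataset.environment.parameters]
            if len(dominant) >= 2 and len(params) >= 1:
                rda_res = assoc_mod.rda(
                    SampleTable(abundance.data[dominant], abundance.kind),
                    dataset.environment, params, config.log_base,
                )
                entry["rda"] = {
                    "proportion_explained": list(map(float, rda_res["proportion_explained"][:2])),
                    "total_constrained_proportion": rda_res["total_constrained_proportion"],
                    "parameters": params,
                }
                if out:
                    rda_res["site_scores"].to_csv(out / "rda_site_scores.tsv", sep="\t")
            report["stages"]["association"] = entry
        except Exception as exc:
            fail("association", exc)

    if out:
        write_report(report, out / "report.json")
    return report
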