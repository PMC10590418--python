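"""End-to-end orchestration: simulate/ingest → settlement categories →
compartment pooling → community statistics → core filtering → network
inference → annealed modularity → settlement annotation → manifest.

Every stochastic stage receives a recorded sub-seed derived from the run
seed, so a rerun with the same config is bit-identical. Conditioning
datasets (aquarium vs reef) are independent pipeline instances.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import community_stats as cs
from . import core_microbiome as core
from . import io as snio
from . import modularity as mod
from . import network_inference as net
from . import settlement as settle
from .synthetic_data import SimConfig, generate_experiment


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    out_dir: str = "settlenet_run"
    seed: int = 0
    # inputs: either a simulation config or paths to existing tables
    sim: SimConfig | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    settlement_path: str | None = None
    # settlement
    scheme: str = "aquarium"
    exclude_controls: bool = False
    merge_indistinct: bool = False
    merge_alpha: float = 0.05
    # community statistics
    n_permutations: int = 999
    nmds_restarts: int = 4
    # core microbiome
    prevalence_min: float = 2 / 3
    abundance_min: float = 1e-4
    abundance_mode: str = "mean"
    # network inference; conditioning depth 1 keeps factor-driven module
    # cohesion detectable at ~50 pooled samples while still pruning
    # indirect and compositional edges
    alpha: float = 0.01
    max_k: int = 1
    fdr: str = "bh"
    # annealing (geometric schedule; None → size-based defaults)
    T0: float | None = None
    cooling_factor: float = 0.95
    iters_per_T: int | None = None
    # annotation
    purity_threshold: float = 0.75
    betweenness_min: float = 3.0
    degree_range: tuple[int, int] = (2, 4)
    rare_cutoff: float = 0.001


def _sub_seed(seed: int, idx: int) -> int:
    return int((seed * 10_007 + idx) % (2 ** 31 - 1))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write all artifacts under ``config.out_dir`` and
    return the manifest (also written as manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    summary: dict = {"seed": config.seed}
    seeds = {name: _sub_seed(config.seed, i) for i, name in
             enumerate(["simulate", "permanova", "nmds", "network", "anneal"])}

    def save(name: str, writer) -> Path:
        path = out / name
        writer(path)
        artifacts[name] = _sha256(path)
        return path

    # --- ingest / simulate -------------------------------------------------
    stage = "io"
    try:
        if config.sim is not None:
            stage = "synthetic_data"
            sim = config.sim
            sim.seed = seeds["simulate"] if sim.seed is None else sim.seed
            table, metadata, taxonomy, settlement_counts, truth = generate_experiment(sim)
            save("counts.tsv", lambda p: snio.write_count_table(table, p))
            save("metadata.tsv", lambda p: snio.write_metadata(metadata, p))
            save("taxonomy.tsv", lambda p: snio.write_taxonomy(taxonomy, p))
            save("settlement.tsv",
                 lambda p: snio.write_settlement_counts(settlement_counts, p))
            save("truth.json", lambda p: p.write_text(
                json.dumps(truth.to_dict(), sort_keys=True, indent=1)))
        else:
            if not (config.counts_path and config.metadata_path
                    and config.settlement_path):
                raise PipelineError(
                    "io stage: need counts_path, metadata_path and settlement_path "
                    "when no simulation config is given")
            table = snio.read_count_table(config.counts_path)
            metadata = snio.read_metadata(config.metadata_path)
            taxonomy = (snio.read_taxonomy(config.taxonomy_path)
                        if config.taxonomy_path else None)
            settlement_counts = snio.read_settlement_counts(config.settlement_path)
            truth = None
        metadata.validate_against(table)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"{stage} stage: {exc}") from exc

    # --- settlement --------------------------------------------------------
    try:
        scheme = settle.SCHEMES[config.scheme]
        controls = set(metadata.table.loc[metadata.table["time_months"] == 0,
                                          "tetrapod_id"])
        records = settle.settlement_fractions(
            settlement_counts, exclude_controls=config.exclude_controls,
            control_ids=controls)
        records = settle.categorize(records, scheme)
        rec_frame = settle.records_to_frame(records)
        category_of = dict(zip(rec_frame["tetrapod_id"], rec_frame["category"]))
        tet_meta = metadata.table.drop_duplicates("tetrapod_id").set_index("tetrapod_id")
        cond = rec_frame[rec_frame["tetrapod_id"].map(
            lambda t: int(tet_meta.loc[t, "time_months"]) > 0 if t in tet_meta.index else False)]
        ct = pd.crosstab(cond["category"],
                         cond["tetrapod_id"].map(lambda t: int(tet_meta.loc[t, "time_months"])))
        ct = ct.loc[(ct.sum(axis=1) > 0), (ct.sum(axis=0) > 0)]
        if ct.shape[0] >= 2 and ct.shape[1] >= 2:
            x2, dof, pval = settle.chi_square(ct)
            summary["chi_square"] = {"X2": x2, "df": dof, "p": pval}
        else:
            summary["chi_square"] = None
        save("settlement_records.tsv", lambda p: rec_frame.to_csv(p, sep="\t", index=False))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"settlement stage: {exc}") from exc

    # --- pooling and community statistics ----------------------------------
    try:
        pooled, pooled_meta = cs.pool_compartments(table, metadata)
        save("pooled_counts.tsv", lambda p: snio.write_count_table(pooled, p))
        groups = np.array([category_of.get(t, "control") for t in pooled.sample_ids])
        dist = cs.bray_curtis(cs.log_transform(pooled))
        res = cs.permanova(dist, groups, n_perm=config.n_permutations,
                           seed=seeds["permanova"])
        summary["permanova"] = {"pseudo_F": res.pseudo_F, "df_among": res.df_among,
                                "df_within": res.df_within, "R2": res.R2,
                                "p": res.p_perm}
        pw = cs.pairwise_permanova(dist, groups, n_perm=config.n_permutations,
                                   seed=seeds["permanova"])
        save("pairwise_permanova.tsv", lambda p: pw.to_csv(p, sep="\t", index=False))
        coords, stress, _ = cs.nmds(dist, n_restarts=config.nmds_restarts,
                                    seed=seeds["nmds"])
        summary["nmds_stress"] = stress
        save("nmds_coordinates.tsv", lambda p: coords.to_csv(p, sep="\t"))
        if config.merge_indistinct:
            pw_p = {frozenset((r.group_a, r.group_b)): r.p_adjusted
                    for r in pw.itertuples()
                    if r.group_a != "control" and r.group_b != "control"}
            records, report = settle.merge_categories(records, pw_p,
                                                      alpha=config.merge_alpha)
            rec_frame = settle.records_to_frame(records)
            category_of = dict(zip(rec_frame["tetrapod_id"], rec_frame["category"]))
            summary["merged_categories"] = [list(g) for g in report.merged_groups]
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"community_stats stage: {exc}") from exc

    # --- core microbiome ----------------------------------------------------
    try:
        cats_present = sorted({c for c in category_of.values()})
        cores = []
        for c in cats_present:
            samples = [s for s in pooled.sample_ids if category_of.get(s) == c]
            if len(samples) < 3:
                continue
            sub = pooled.restrict(sample_ids=samples)
            cores.append(core.core_filter(sub, c, config.prevalence_min,
                                          config.abundance_min, config.abundance_mode))
        if not cores:
            raise PipelineError("core stage: no category with >=3 pooled samples")
        core_table, membership = core.recombine(cores, pooled)
        overlaps = core.set_overlaps({c.category: set(c.retained) for c in cores}) \
            if len(cores) >= 2 else {}
        summary["core_sizes"] = {c.category: len(c.retained) for c in cores}
        summary["core_overlaps"] = {"+".join(k): v for k, v in overlaps.items()}
        save("core_counts.tsv", lambda p: snio.write_count_table(core_table, p))
        save("core_membership.tsv", lambda p: membership.to_csv(p, sep="\t"))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"core_microbiome stage: {exc}") from exc

    # --- network inference --------------------------------------------------
    try:
        clr = net.clr_transform(core_table)
        graph = net.infer_network(clr, alpha=config.alpha, max_k=config.max_k,
                                  fdr=config.fdr, seed=seeds["network"])
        summary["network"] = net.network_summary(graph)
        save("network.graphml", lambda p: snio.write_network(graph, p, "graphml"))
        save("network_edges.tsv", lambda p: snio.write_network(graph, p, "edge_tsv"))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"network_inference stage: {exc}") from exc

    # --- modularity ---------------------------------------------------------
    try:
        part = mod.anneal_partition(graph, T0=config.T0,
                                    cooling_factor=config.cooling_factor,
                                    iters_per_T=config.iters_per_T,
                                    seed=seeds["anneal"])
        summary["modularity"] = {"Q": part.Q, "n_modules": part.n_modules}
        mods_frame = pd.DataFrame(
            {"module": [part.assignment[v] for v in sorted(graph.nodes, key=str)]},
            index=pd.Index(sorted(graph.nodes, key=str), name="node"))
        save("modules.tsv", lambda p: mods_frame.to_csv(p, sep="\t"))
        save("node_roles.tsv", lambda p: part.roles.to_csv(p, sep="\t"))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"modularity stage: {exc}") from exc

    # --- annotation ---------------------------------------------------------
    try:
        node_ann = ann.annotate_nodes(graph, part, core_table, category_of,
                                      betweenness_min=config.betweenness_min,
                                      degree_range=config.degree_range)
        save("node_annotation.tsv", lambda p: node_ann.to_csv(p, sep="\t"))
        comps = {}
        purity = {}
        for m in sorted(set(part.assignment.values())):
            comp = ann.module_settlement_composition(core_table, category_of, part, m)
            comps[m] = comp
            purity[m] = ann.label_module_purity(comp, config.purity_threshold)
        comp_frame = pd.DataFrame(comps).T
        comp_frame["purity"] = pd.Series(purity)
        comp_frame.index.name = "module"
        save("module_composition.tsv", lambda p: comp_frame.to_csv(p, sep="\t"))
        mg = ann.collapse_modules(graph, part)
        for m in mg.nodes:
            mg.nodes[m]["purity"] = purity.get(m, "mixed")
        save("module_graph.graphml", lambda p: snio.write_network(mg, p, "graphml"))
        excl = ann.exclusive_taxa(core_table, category_of, rank="asv")
        excl_frame = pd.DataFrame(
            [(c, t) for c, ts in excl.items() for t in sorted(ts)],
            columns=["category", "asv_id"])
        save("exclusive_asvs.tsv", lambda p: excl_frame.to_csv(p, sep="\t", index=False))
        summary["exclusive_counts"] = {c: len(ts) for c, ts in excl.items()}
        if taxonomy is not None:
            excl_fam = ann.exclusive_taxa(core_table, category_of, rank="family",
                                          taxonomy=taxonomy)
            fam_frame = pd.DataFrame(
                [(c, f) for c, fs in excl_fam.items() for f in sorted(fs)],
                columns=["category", "family"])
            save("exclusive_families.tsv",
                 lambda p: fam_frame.to_csv(p, sep="\t", index=False))
            rare, rare_mat = ann.rare_taxa(core_table, taxonomy,
                                           cutoff=config.rare_cutoff)
            summary["n_rare_families"] = len(rare)
            save("rare_family_log_abundance.tsv",
                 lambda p: rare_mat.to_csv(p, sep="\t"))
        summary["module_purity"] = {int(m): purity[m] for m in purity}
        summary["n_bridging_nodes"] = int(node_ann["bridging"].sum())
        summary["n_nodes_of_interest"] = int(node_ann["node_of_interest"].sum())
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"annotation stage: {exc}") from exc

    # --- manifest -----------------------------------------------------------
    manifest = {"config": _config_dict(config), "sub_seeds": seeds,
                "artifacts": artifacts, "summary": summary}
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1,
                                                  default=str))
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, sort_keys=True, indent=1, default=str))
    return manifest


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    if config.sim is not None:
        d["sim"] = asdict(config.sim)
    return d
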