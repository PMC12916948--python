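"""One-call orchestration of the full analysis chain on synthetic data.

Stage order mirrors the study: simulate (or load) panels -> motion QC ->
behavior summary + 2x2 ANOVA -> FC -> MST backbone + densification -> masked
weights -> nodal local efficiency -> paired comparison with FDR -> subnetwork
extraction from the significant regions -> NBS permutation inference ->
per-edge follow-up -> trial-averaged ACF -> intrinsic timescales + pairwise
comparison -> brain-behavior (edge weight vs mean RT) Spearman correlations.
Every table is written under the output directory together with a manifest
that echoes all settings and seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import rm_anova_2x2, summarize_behavior
from .connectivity import apply_mask, densify_to_sparsity, fc_matrix, mst_backbone
from .io import write_matrix, write_table
from .metrics import compare_nodal_metric, local_efficiency_all, node_degree
from .nbs import edge_followup_tests, extract_subnetwork_weights, nbs_permutation_test
from .qc import exclude_high_motion, framewise_displacement
from .simulate import (
    CONDITIONS,
    SimulationConfig,
    make_trial_events,
    simulate_behavior_trials,
    simulate_motion,
    simulate_panel,
)
from .stats import brain_behavior_correlation
from .timescale import compare_timescales, timescale_table

logger = logging.getLogger("bindnet")

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Settings for one end-to-end run on the synthetic generator."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    sparsity: float = 0.10
    alpha_primary: float = 0.05
    q_fdr: float = 0.05
    n_perm: int = 10_000
    epoch_window_trs: int = 10
    fd_threshold_mm: float = 0.5
    nbs_tail: str = "greater"
    subnetwork_override: tuple[int, ...] | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("sparsity", "alpha_primary", "q_fdr"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")

    def manifest(self) -> dict:
        sim = dataclasses.asdict(self.simulation)
        sim["phi"] = [float(v) for v in sim["phi"]]
        sim["planted_edges"] = [list(e) for e in sim["planted_edges"]]
        sim["dprime_true"] = {f"{c}:{s}": v for (c, s), v in sim["dprime_true"].items()}
        settings = {
            "simulation": sim,
            "sparsity": self.sparsity,
            "alpha_primary": self.alpha_primary,
            "q_fdr": self.q_fdr,
            "n_perm": self.n_perm,
            "epoch_window_trs": self.epoch_window_trs,
            "fd_threshold_mm": self.fd_threshold_mm,
            "nbs_tail": self.nbs_tail,
            "subnetwork_override": list(self.subnetwork_override)
            if self.subnetwork_override
            else None,
            "version": __version__,
        }
        blob = json.dumps(settings, sort_keys=True)
        settings["run_id"] = hashlib.sha256(blob.encode()).hexdigest()[:12]
        return settings


@dataclass
class ReportBundle:
    """All group-level tables produced by one pipeline run."""

    manifest: dict
    exclusion_log: list[str]
    behavior_summary: pd.DataFrame
    anova: pd.DataFrame
    nodal_comparison: pd.DataFrame
    significant_regions: list[str]
    nbs_summary: pd.DataFrame
    nbs_edges: pd.DataFrame
    null_max_sizes: np.ndarray
    timescales: pd.DataFrame
    timescale_pairs: pd.DataFrame
    brain_behavior: pd.DataFrame


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    sim = config.simulation
    labels = sim.region_labels

    _stage("simulate + motion QC")
    fd_means = {}
    for s in range(sim.n_subjects):
        _, fd_means[s] = framewise_displacement(simulate_motion(sim, s))
    subjects, exclusion_log = exclude_high_motion(fd_means, config.fd_threshold_mm)

    _stage("behavior")
    trials = pd.concat(
        [simulate_behavior_trials(sim, s) for s in subjects], ignore_index=True
    )
    behavior = summarize_behavior(trials)
    wide = behavior.pivot_table(
        index="subject", columns=["condition", "set_size"], values="dprime"
    )
    cells = np.stack(
        [
            [[wide[(c, s)].loc[subj] for s in sim.set_sizes] for c in ("either", "binding")]
            for subj in subjects
        ]
    )
    anova = rm_anova_2x2(cells)

    _stage("functional networks")
    panels = {
        (s, c): simulate_panel(sim, s, c) for s in subjects for c in CONDITIONS
    }
    masked = {}
    eloc = {c: np.zeros((len(subjects), sim.n_regions)) for c in CONDITIONS}
    degree = {c: np.zeros((len(subjects), sim.n_regions), dtype=int) for c in CONDITIONS}
    for si, s in enumerate(subjects):
        for c in CONDITIONS:
            fc = fc_matrix(panels[(s, c)])
            dense = densify_to_sparsity(fc, mst_backbone(fc), config.sparsity)
            masked[(s, c)] = apply_mask(fc, dense)
            eloc[c][si] = local_efficiency_all(dense)
            degree[c][si] = node_degree(dense)

    _stage("nodal comparison")
    nodal = compare_nodal_metric(
        eloc["binding"], eloc["either"], q=config.q_fdr, region_labels=labels
    )
    significant = list(nodal.loc[nodal["significant"], "region"])

    _stage("NBS")
    if config.subnetwork_override is not None:
        sub_idx = list(config.subnetwork_override)
    else:
        sub_idx = [labels.index(r) for r in significant]
    if len(sub_idx) >= 2:
        bind_w = extract_subnetwork_weights(
            [masked[(s, "binding")].w for s in subjects], sub_idx
        )
        eith_w = extract_subnetwork_weights(
            [masked[(s, "either")].w for s in subjects], sub_idx
        )
        union_mask = np.zeros((len(sub_idx), len(sub_idx)), dtype=bool)
        for s in subjects:
            for c in CONDITIONS:
                m = masked[(s, c)].mask.mask
                union_mask |= m[np.ix_(sub_idx, sub_idx)]
        sub_labels = [labels[i] for i in sub_idx]
        result = nbs_permutation_test(
            bind_w,
            eith_w,
            alpha_primary=config.alpha_primary,
            n_perm=config.n_perm,
            seed=sim.seed,
            tail=config.nbs_tail,
            node_labels=sub_labels,
            edge_mask=union_mask,
        )
        nbs_summary = pd.DataFrame(
            [
                {
                    "component": ci,
                    "n_edges": comp.size,
                    "n_nodes": len(comp.nodes),
                    "p_value": comp.p_value,
                    "nodes": ",".join(sub_labels[v] for v in comp.nodes),
                }
                for ci, comp in enumerate(result.components)
            ],
            columns=["component", "n_edges", "n_nodes", "p_value", "nodes"],
        )
        nbs_edges = edge_followup_tests(result, bind_w, eith_w, q=config.q_fdr)
        null_max = result.null_max_sizes
    else:
        logger.info("fewer than 2 subnetwork nodes; NBS skipped")
        nbs_summary = pd.DataFrame(
            columns=["component", "n_edges", "n_nodes", "p_value", "nodes"]
        )
        nbs_edges = pd.DataFrame(
            columns=[
                "component",
                "component_p",
                "node_i",
                "node_j",
                "t",
                "p",
                "p_adjusted",
                "significant",
                "direction",
            ]
        )
        null_max = np.zeros(0, dtype=int)
        bind_w = None
        sub_labels = []

    _stage("timescales")
    ts_regions = sub_idx if len(sub_idx) >= 2 else list(range(min(8, sim.n_regions)))
    ts_panels = {}
    ts_onsets = {}
    for s in subjects:
        for c in CONDITIONS:
            p = panels[(s, c)]
            sub_panel = dataclasses.replace(
                p,
                data=p.data[:, ts_regions],
                region_labels=[labels[i] for i in ts_regions],
            )
            events = make_trial_events(sim, s, c)
            fit = events["onset_seconds"] + config.epoch_window_trs * sim.tr_seconds <= (
                p.n_frames * sim.tr_seconds
            )
            ts_panels[(s, c)] = sub_panel
            ts_onsets[(s, c)] = events.loc[fit, "onset_seconds"].to_numpy()
    timescales = timescale_table(
        ts_panels, onsets=ts_onsets, window_trs=config.epoch_window_trs
    )
    ts_binding = timescales[timescales["condition"] == "binding"]
    timescale_pairs = compare_timescales(ts_binding, q=config.q_fdr)

    _stage("brain-behavior correlations")
    rt_binding = (
        behavior[behavior["condition"] == "binding"]
        .groupby("subject")["mean_rt_correct_seconds"]
        .mean()
        .loc[subjects]
        .to_numpy()
    )
    if bind_w is not None and len(nbs_edges):
        comp_edges = [
            (sub_labels.index(r.node_i), sub_labels.index(r.node_j))
            for r in nbs_edges.itertuples()
        ]
        weights = np.column_stack([bind_w[:, i, j] for i, j in comp_edges])
        edge_names = [f"{a}-{b}" for a, b in zip(nbs_edges["node_i"], nbs_edges["node_j"])]
        brain_behavior = brain_behavior_correlation(
            weights, rt_binding, edge_labels=edge_names, q=config.q_fdr
        )
    else:
        brain_behavior = pd.DataFrame(
            columns=["edge", "rho", "p", "p_adjusted", "significant"]
        )

    bundle = ReportBundle(
        manifest=config.manifest(),
        exclusion_log=exclusion_log,
        behavior_summary=behavior,
        anova=anova,
        nodal_comparison=nodal,
        significant_regions=significant,
        nbs_summary=nbs_summary,
        nbs_edges=nbs_edges,
        null_max_sizes=null_max,
        timescales=timescales,
        timescale_pairs=timescale_pairs,
        brain_behavior=brain_behavior,
    )
    if config.out_dir is not None:
        write_bundle(bundle, config.out_dir)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir) -> None:
    """Write every report table plus the run manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_id = bundle.manifest["run_id"]
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
    (out / "exclusion_log.txt").write_text(
        "\n".join([f"# run {run_id}", *bundle.exclusion_log]) + "\n"
    )
    tables = {
        "behavior_summary.tsv": bundle.behavior_summary,
        "anova.tsv": bundle.anova,
        "nodal_comparison.tsv": bundle.nodal_comparison,
        "nbs_components.tsv": bundle.nbs_summary,
        "nbs_edges.tsv": bundle.nbs_edges,
        "timescales.tsv": bundle.timescales,
        "timescale_pairs.tsv": bundle.timescale_pairs,
        "brain_behavior.tsv": bundle.brain_behavior,
    }
    for name, table in tables.items():
        t = table.copy()
        t.insert(0, "run_id", run_id)
        write_table(out / name, t)
    np.savetxt(out / "nbs_null_max_sizes.txt", bundle.null_max_sizes, fmt="%d")
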