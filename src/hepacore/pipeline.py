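"""End-to-end orchestration: DE -> profiles -> network -> core genes.

A run is driven by a :class:`PipelineConfig`, loadable from a flat YAML
key-value file (an archivable parameter record; the run summary embeds the
resolved config).  Defaults are the conventional thresholds of this
analysis family: p < 0.05 and FDR < 0.05 for differential expression, 1000
label permutations for the FDR, profile enrichment alpha 0.05 with c = 1
unit steps, |r| >= 0.9 co-expression edges, and core genes within 2 levels
of the maximum k-core.

Input is either a matrix + sample-sheet file pair or a synthetic study
(planted monotone profiles plus an optional correlated module) — exactly
one of the two.  Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from hepacore import io_formats, network, profiles, rvm_anova, synthetic
from hepacore.io_formats import ExpressionMatrix

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_pipeline"]

logger = logging.getLogger("hepacore")


class ConfigError(ValueError):
    """One or more invalid pipeline-config entries (all listed at once)."""


@dataclass
class PipelineConfig:
    """Resolved pipeline parameters.

    Exactly one input source must be set when running: the
    (``input_matrix``, ``input_sheet``) file pair XOR ``synthetic = True``.
    """

    # input
    input_matrix: str | None = None
    input_sheet: str | None = None
    synthetic: bool = False
    # synthetic study layout
    synthetic_n_genes: int = 500
    synthetic_n_increasing: int = 100
    synthetic_n_decreasing: int = 100
    synthetic_effect: float = 1.5
    synthetic_prior_a: float = 2.0
    synthetic_prior_b: float = 1.0
    synthetic_module_size: int = 0
    synthetic_module_loading: float = 0.98
    synthetic_time_points: tuple = ("control", "1h", "3h", "6h")
    synthetic_replicates: int = 3
    # thresholds
    p_threshold: float = rvm_anova.P_THRESHOLD
    fdr_threshold: float = rvm_anova.FDR_THRESHOLD
    profile_alpha: float = profiles.PROFILE_ALPHA
    profile_selection: str = "monotone"  # or "all-significant"
    r_threshold: float = network.R_THRESHOLD
    edge_rule: str = "absolute"
    core_depth: int = network.CORE_DEPTH
    n_perm: int = 1000
    c: int = 1
    seed: int = 0

    def validate(self, require_input: bool = False) -> "PipelineConfig":
        problems = []
        for name in ("p_threshold", "fdr_threshold", "profile_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                problems.append(f"{name} must be in (0, 1), got {v}")
        if not 0.0 < self.r_threshold <= 1.0:
            problems.append(f"r_threshold must be in (0, 1], got {self.r_threshold}")
        if self.edge_rule not in ("absolute", "positive"):
            problems.append(f"edge_rule must be absolute|positive, got {self.edge_rule}")
        if self.profile_selection not in ("monotone", "all-significant"):
            problems.append(
                "profile_selection must be monotone|all-significant, "
                f"got {self.profile_selection}"
            )
        if self.n_perm < 1:
            problems.append(f"n_perm must be >= 1, got {self.n_perm}")
        if self.c < 1:
            problems.append(f"c must be >= 1, got {self.c}")
        if self.core_depth < 0:
            problems.append(f"core_depth must be >= 0, got {self.core_depth}")
        has_files = self.input_matrix is not None or self.input_sheet is not None
        if has_files and (self.input_matrix is None or self.input_sheet is None):
            problems.append("input_matrix and input_sheet must be given together")
        if has_files and self.synthetic:
            problems.append(
                "exactly one input source allowed: file input XOR synthetic"
            )
        if require_input and not has_files and not self.synthetic:
            problems.append("no input source: set input_matrix/input_sheet or synthetic")
        if problems:
            raise ConfigError("; ".join(problems))
        return self


def validate_config(path) -> PipelineConfig:
    """Parse, default and validate a flat YAML config file.

    An empty file yields all defaults.  Unknown keys and out-of-range
    values are reported together in a single error.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config must be a flat key-value mapping, got {type(raw)}")
    known = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    problems = [f"unknown key: {k}" for k in raw if k not in known]
    if problems:
        # still run range checks on the known keys so everything is listed
        raw = {k: v for k, v in raw.items() if k in known}
    if "synthetic_time_points" in raw:
        raw["synthetic_time_points"] = tuple(raw["synthetic_time_points"])
    config = PipelineConfig(**raw)
    try:
        config.validate()
    except ConfigError as exc:
        problems.append(str(exc))
    if problems:
        raise ConfigError("; ".join(problems))
    return config


def _synthetic_input(config: PipelineConfig):
    T = len(config.synthetic_time_points)
    inc = tuple([1] * (T - 1))
    dec = tuple([-1] * (T - 1))
    spec = synthetic.SyntheticSpec(
        n_genes=config.synthetic_n_genes,
        time_points=config.synthetic_time_points,
        replicates_per_group=config.synthetic_replicates,
        variance_prior=(config.synthetic_prior_a, config.synthetic_prior_b),
        planted_profiles=[
            (inc, config.synthetic_n_increasing, config.synthetic_effect),
            (dec, config.synthetic_n_decreasing, config.synthetic_effect),
        ],
        seed=config.seed,
    )
    matrix, truth = synthetic.generate_profiled_matrix(spec)
    if config.synthetic_module_size > 0:
        # module rides on the leading increasing genes, keeping their trend
        module_ids = list(matrix.gene_ids[: config.synthetic_module_size])
        matrix, module_truth = synthetic.plant_correlated_module(
            matrix,
            n_genes=config.synthetic_module_size,
            loading=config.synthetic_module_loading,
            seed=config.seed + 1,
            gene_ids=module_ids,
            noise_sd=1.0 / (config.synthetic_prior_b ** 0.5),
            preserve_trend=True,
        )
        truth = truth.copy()
        truth.loc[module_ids] = module_truth
    return matrix, truth


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run DE -> profiles -> network -> core genes and write all reports.

    Writes into ``out_dir``: ``de_results.tsv``, ``profile_summary.tsv``,
    ``profile_assignments.tsv``, ``network_topology.tsv``,
    ``network.graphml``, ``network_edges.tsv``, ``core_genes.tsv``,
    ``run_summary.json`` and ``run.log``; synthetic runs also persist the
    generated matrix, sheet and truth labels.  Returns the run summary
    (also written as JSON; byte-identical across reruns of the same
    config + seed).
    """
    config.validate(require_input=True)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> dict:
    # ---- input
    try:
        if config.synthetic:
            matrix, truth = _synthetic_input(config)
            io_formats.write_expression_matrix(
                matrix, out / "matrix.tsv", out / "samples.tsv"
            )
            io_formats.write_truth_labels(truth, out / "truth.tsv")
        else:
            matrix = io_formats.read_expression_matrix(
                config.input_matrix, config.input_sheet
            )
    except Exception:
        logger.error("stage input failed")
        raise
    logger.info(
        "input: %d genes x %d samples, groups %s",
        matrix.n_genes, matrix.n_samples, ",".join(matrix.group_order),
    )

    # ---- stage 1: RVM-moderated differential expression
    try:
        s2, d = rvm_anova.pooled_variances(matrix)
        prior = rvm_anova.fit_variance_prior(s2, d)
        de = rvm_anova.rvm_f_test(matrix, prior)
        de["fdr"] = rvm_anova.permutation_fdr(
            matrix, prior, n_perm=config.n_perm, seed=config.seed
        )
        de["significant"] = (de["p"] < config.p_threshold) & (
            de["fdr"] < config.fdr_threshold
        )
        significant = rvm_anova.select_significant(
            de, config.p_threshold, config.fdr_threshold
        )
    except Exception:
        logger.error("stage de failed")
        raise
    io_formats.write_results_table(de.reset_index(), out / "de_results.tsv")
    logger.info("de: prior a=%.4g b=%.4g, %d significant genes",
                prior.a, prior.b, len(significant))

    # ---- stage 2: temporal model profiles
    try:
        model = profiles.enumerate_model_profiles(len(matrix.group_order), config.c)
        summary = rvm_anova.group_summarize(matrix.subset_genes(significant))
        normalized = summary.sub(summary.iloc[:, 0], axis=0)
        assignments = profiles.assign_genes(normalized, model)
        sig = profiles.profile_significance(
            assignments, normalized, model, alpha=config.profile_alpha
        )
        if config.profile_selection == "all-significant":
            selected = profiles.collect_profile_genes(
                assignments, sig, "all-significant"
            )
        else:
            selected = {}
            for w in ("most-significant-increasing", "most-significant-decreasing"):
                selected.update(profiles.collect_profile_genes(assignments, sig, w))
    except Exception:
        logger.error("stage profiles failed")
        raise
    io_formats.write_results_table(sig.reset_index(), out / "profile_summary.tsv")
    io_formats.write_results_table(
        assignments.reset_index(), out / "profile_assignments.tsv"
    )
    network_genes = [g for genes in selected.values() for g in genes]
    logger.info(
        "profiles: %d significant profiles, %d genes selected for the network",
        int(sig["significant"].sum()), len(network_genes),
    )

    # ---- stage 3: co-expression network
    try:
        if len(network_genes) >= 2:
            r_table = network.correlation_matrix(matrix, network_genes)
            graph = network.build_graph(
                r_table, config.r_threshold, config.edge_rule
            )
            topology = network.node_topology(graph)
            network.annotate_topology(graph, topology)
            core_genes = network.select_core_genes(topology, config.core_depth)
        else:
            graph = nx.Graph()
            topology = pd.DataFrame(columns=["gene", "clustering", "degree", "core"])
            core_genes = []
    except Exception:
        logger.error("stage network failed")
        raise
    io_formats.write_results_table(topology, out / "network_topology.tsv")
    io_formats.write_graph(graph, out / "network.graphml", "graphml")
    io_formats.write_graph(graph, out / "network_edges.tsv", "edge-list")
    io_formats.write_results_table(
        topology[topology["gene"].isin(core_genes)], out / "core_genes.tsv"
    )
    logger.info(
        "network: %d nodes, %d edges, max core %s, %d core genes",
        graph.number_of_nodes(), graph.number_of_edges(),
        int(topology["core"].max()) if len(topology) else 0, len(core_genes),
    )

    summary = {
        "config": _config_dict(config),
        "n_genes": int(matrix.n_genes),
        "n_samples": int(matrix.n_samples),
        "prior": {"a": float(prior.a), "b": float(prior.b),
                  "bound_hit": bool(prior.bound_hit)},
        "n_significant_genes": len(significant),
        "n_significant_profiles": int(sig["significant"].sum()),
        "significant_profiles": {
            str(pid): {
                "steps": [int(s) for s in sig.loc[pid, "steps"]],
                "observed": int(sig.loc[pid, "observed"]),
                "p": float(sig.loc[pid, "p"]),
            }
            for pid in sig.index[sig["significant"]]
        },
        "selected_profile_genes": {str(k): len(v) for k, v in selected.items()},
        "n_network_nodes": int(graph.number_of_nodes()),
        "n_network_edges": int(graph.number_of_edges()),
        "max_core": int(topology["core"].max()) if len(topology) else 0,
        "n_core_genes": len(core_genes),
        "core_genes": list(core_genes),
    }
    with open(out / "run_summary.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["synthetic_time_points"] = list(d["synthetic_time_points"])
    return d
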