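"""End-to-end pipeline: preprocess → filter → select → sample → infer → report.

A :class:`RunConfig` (loadable from a flat ``key = value`` text file) drives
the full workflow and every artifact embeds the config hash, so a run is
reproducible from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import expression, features, network, spikein
from .citests import CITester
from .expression import ExpressionMatrix, FilterSpec
from .pc import pc_infer

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("sccausal")


class ValidationError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Parameters of one causal-discovery run.

    Defaults mirror the packaged recommendations: alpha 0.1, 300 cells,
    k = 50 feature genes, DCC.gamma as the CI test.
    """

    case_path: str = ""
    control_path: str | None = None
    tf_list_path: str | None = None
    spike_matrix_path: str | None = None
    spike_edges_path: str | None = None
    input_format: str | None = None
    transform: str | None = "log2"
    # gene filtering
    min_mean_expr: float | None = 0.1
    min_pct_cells: float | None = 0.5
    min_variance: float | None = None
    min_abs_log_fc: float | None = None
    tf_only: bool = False
    # feature selection
    fs_method: str = "bahsic"  # bahsic | tree | union | none
    k: int = 50
    response_genes: tuple[str, ...] = ()
    add_genes: tuple[str, ...] = ()
    remove_genes: tuple[str, ...] = ()
    # cell sampling
    n_cells: int = 300
    sampling_mode: str = "random"
    # causal discovery
    ci_test: str = "dcc.gamma"
    alpha: float = 0.1
    max_cond_size: int = 3
    permutations: int = 100
    n_runs: int = 1
    seed: int = 0
    out_dir: str = "sccausal_out"

    def validate(self) -> None:
        if not self.case_path or not Path(self.case_path).exists():
            raise ValidationError(f"case matrix not found: {self.case_path!r}")
        for p in (self.control_path, self.tf_list_path, self.spike_matrix_path, self.spike_edges_path):
            if p and not Path(p).exists():
                raise ValidationError(f"input file not found: {p!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.n_runs < 1:
            raise ValidationError("n_runs must be positive")
        if self.fs_method not in ("bahsic", "tree", "union", "none"):
            raise ValidationError(f"unknown feature-selection method {self.fs_method!r}")
        if self.fs_method != "none" and not self.response_genes:
            raise ValidationError("feature selection requires response genes")

    # -- flat key=value serialization -----------------------------------
    _TUPLES = ("response_genes", "add_genes", "remove_genes")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        values: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            values[key] = val
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(values)

    @classmethod
    def from_dict(cls, values: dict) -> "RunConfig":
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict[str, object] = {}
        for key, val in values.items():
            if key not in fields:
                raise ValidationError(f"unknown config key {key!r}")
            kwargs[key] = _coerce(key, val, fields[key].type)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in self._TUPLES:
            d[key] = list(d[key])
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir")  # the output location does not affect the analysis
        text = json.dumps(d, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _coerce(key: str, val: object, annotation: object) -> object:
    if not isinstance(val, str):
        if key in RunConfig._TUPLES and isinstance(val, (list, tuple)):
            return tuple(str(v) for v in val)
        return val
    val = val.strip()
    if key in RunConfig._TUPLES:
        return tuple(g.strip() for g in val.split(",") if g.strip())
    if key == "fs_method":
        return val  # "none" is a meaningful method tag here
    if val.lower() in ("none", ""):
        return None
    if val.lower() in ("true", "false"):
        return val.lower() == "true"
    for cast in (int, float):
        try:
            if cast is int and "." in val:
                continue
            return cast(val)
        except ValueError:
            pass
    return val


def _load_gene_list(path: str | None) -> list[str] | None:
    if not path:
        return None
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def _load_spike(config: RunConfig) -> spikein.SpikeInSet | None:
    if not config.spike_matrix_path:
        return None
    mat = expression.load_expression(config.spike_matrix_path, config.input_format)
    if config.transform:
        mat = expression.transform(mat, config.transform)
    edges: list[tuple[str, str, bool]] = []
    if config.spike_edges_path:
        for ln in Path(config.spike_edges_path).read_text().splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#") or ln.startswith("gene_a"):
                continue
            parts = ln.split("\t")
            edges.append((parts[0], parts[1], bool(int(parts[2])) if len(parts) > 2 else False))
    return spikein.SpikeInSet(mat, tuple(edges))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured workflow and write artifacts into ``out_dir``.

    Returns the report dictionary (also written as ``report.json``).  Any
    stage failure is logged and re-raised; artifacts written before the
    failure are preserved.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    try:
        logger.info("config hash %s", chash)
        logger.info("config %s", json.dumps(config.to_dict(), sort_keys=True))

        case = expression.load_expression(config.case_path, config.input_format)
        control = (
            expression.load_expression(config.control_path, config.input_format)
            if config.control_path
            else None
        )
        if config.transform:
            case = expression.transform(case, config.transform)
            if control is not None:
                control = expression.transform(control, config.transform)
        tf_list = _load_gene_list(config.tf_list_path)

        attrs = expression.compute_gene_attributes(case, control, tf_list)
        expression.write_gene_attributes(attrs, out / "attributes.tsv", f"config_hash={chash}")

        spec = FilterSpec(
            min_mean_expr=config.min_mean_expr,
            min_pct_cells=config.min_pct_cells,
            min_variance=config.min_variance,
            min_abs_log_fc=config.min_abs_log_fc,
            tf_only=config.tf_only,
        )
        candidates = expression.filter_genes(attrs, spec)
        responses = [g for g in config.response_genes if g in case.gene_ids]
        pool = list(dict.fromkeys(candidates + responses))
        logger.info("%d genes pass filtering (of %d)", len(candidates), case.n_genes)
        if len(pool) < 2:
            raise ValidationError("fewer than two genes available after filtering")
        filtered = case.subset_genes(pool)

        if config.fs_method == "none":
            selected = [g for g in pool if g not in responses][: config.k]
        else:
            rankings = []
            if config.fs_method in ("bahsic", "union"):
                rankings.append(
                    features.bahsic_select(filtered, responses, min(config.k, len(pool) - len(responses) - 1), seed=config.seed)
                )
            if config.fs_method in ("tree", "union"):
                rankings.append(
                    features.tree_importance_select(filtered, responses, min(config.k, len(pool) - len(responses) - 1), seed=config.seed)
                )
            selected = features.union_select(rankings, config.k)
            frame = rankings[0].to_frame()
            for extra in rankings[1:]:
                frame = __import__("pandas").concat([frame, extra.to_frame()])
            with (out / "ranking.tsv").open("w") as fh:
                fh.write(f"# config_hash={chash}\n")
                frame.to_csv(fh, sep="\t", index=False)
        selected = features.merge_genes(selected, config.add_genes, config.remove_genes)
        node_genes = list(dict.fromkeys(responses + selected))
        logger.info("%d genes enter causal discovery", len(node_genes))

        working = case.subset_genes(node_genes)
        spike = _load_spike(config)
        if spike is not None:
            working = spikein.integrate_spike_in(working, spike, seed=config.seed)
            node_genes = list(working.gene_ids)
        n = min(config.n_cells, working.n_cells)
        sampled = expression.sample_cells(working, n, config.sampling_mode, seed=config.seed)
        data = sampled.values.T  # cells × genes for the CI tests

        nets = []
        for run in range(config.n_runs):
            tester = CITester(
                method=config.ci_test,
                permutations=config.permutations,
                seed=config.seed + run,
            )
            net = pc_infer(data, node_genes, tester, config.alpha, config.max_cond_size)
            net = network.annotate_edge_signs(net, data, node_genes)
            nets.append(net)
        net = nets[0]
        net.write_edge_list(out / "edges.tsv", f"config_hash={chash}")
        net.write_gml(out / "edges.gml")

        report: dict = {
            "config_hash": chash,
            "config": config.to_dict(),
            "n_genes_filtered": len(candidates),
            "n_genes_network": len(node_genes),
            "n_cells_used": n,
            "n_edges": net.n_edges(),
            "runtime_s": None,
        }
        if config.n_runs > 1:
            prof = network.edge_stability(nets)
            with (out / "stability.tsv").open("w") as fh:
                fh.write(f"# config_hash={chash}\n")
                prof.to_frame().to_csv(fh, sep="\t", index=False)
            report["stability_ge_fraction"] = prof.cumulative_fraction
        if spike is not None:
            sep = spikein.spike_separation_report(
                net, spike.prefixed_genes(), spike.expected_edges
            )
            report["spike_in"] = dataclasses.asdict(sep)
        report["runtime_s"] = round(time.time() - t0, 3)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        logger.info("finished in %.1f s with %d edges", report["runtime_s"], net.n_edges())
        return report
    except Exception:
        logger.exception("pipeline failed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
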