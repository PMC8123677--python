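"""End-to-end pipeline driver.

Stage order: simulate (or load) -> expression filter / zero-one rescale ->
MI inference -> DPI pruning -> edge signing -> shadow filter -> graph
metrics -> per-sample DEG -> regulon activity (GGEA) -> survival report.

Every stage draws randomness from its own substream, derived from the
single config seed and the stage name, so changing one stage's parameters
never shifts another stage's random draws.  A run manifest (config
snapshot, stage seeds, output checksums and row counts) is written with
every run; re-running with the same config reproduces outputs bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import pandas as pd

from . import deg as deg_mod
from . import ggea as ggea_mod
from . import graph as graph_mod
from . import inference, io, synthetic
from . import survival as surv_mod
from .config import PipelineConfig
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage substream seed below 2**31."""
    return int((seed * 0x9E3779B1 + zlib.crc32(stage.encode())) % (2**31))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    config: PipelineConfig,
    outdir,
    train: ExpressionMatrix | None = None,
    cohort: ExpressionMatrix | None = None,
    clinical: pd.DataFrame | None = None,
    regulators: set | None = None,
) -> dict:
    """Run all stages on synthetic data (default) or supplied matrices.

    Returns the manifest dict; all stage outputs are written under
    ``outdir`` as TSV/JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config
    manifest: dict = {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "stages": [],
        "outputs": {},
        "counts": {},
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"].append(stage)
        manifest["counts"].update(counts)

    def save(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False)
        manifest["outputs"][name] = _checksum(path)

    truth = None
    try:
        stage = "simulate"
        sim = cfg.simulate
        if train is None:
            network = synthetic.generate_planted_network(
                sim.n_regulators,
                sim.targets_per_regulator,
                frac_negative=sim.frac_negative,
                overlap_frac=sim.overlap_frac,
                seed=stage_seed(cfg.seed, "network"),
                beta=sim.beta,
            )
            train = synthetic.simulate_expression(
                network,
                sim.n_train_samples,
                sigma=sim.train_sigma,
                seed=stage_seed(cfg.seed, "train"),
                n_decoys=sim.n_decoys,
                n_low_expression=sim.n_low_expression,
            )
            active = set(network.regulator_ids[: sim.n_active_regulators])
            cohort, truth = synthetic.simulate_cohort(
                network,
                active,
                sim.n_tumour,
                sim.n_benign,
                delta=sim.delta,
                sigma=sim.cohort_sigma,
                active_fraction=sim.active_fraction,
                seed=stage_seed(cfg.seed, "cohort"),
                n_decoys=sim.n_decoys,
            )
            clinical = synthetic.simulate_survival(
                truth,
                synthetic.SurvivalTruth(sim.true_hr, sim.baseline_rate, sim.censor_time),
                seed=stage_seed(cfg.seed, "survival"),
            )
            io.write_expression_matrix(
                train, outdir / "train_expression.tsv", outdir / "train_annotation.tsv"
            )
            io.write_expression_matrix(
                cohort, outdir / "cohort_expression.tsv", outdir / "cohort_annotation.tsv"
            )
            save("clinical.tsv", clinical)
            (outdir / "truth.json").write_text(
                json.dumps(
                    {
                        "active_map": {s: sorted(v) for s, v in truth.active_map.items()},
                        "delta": truth.delta,
                        "planted_edges": sorted(
                            [r, t, s] for r, t, s, _ in network.edges
                        ),
                    },
                    indent=1,
                )
            )
        if cohort is None or clinical is None:
            raise ValueError("cohort matrix and clinical table are required when loading data")
        record(stage, n_train_samples=train.n_samples, n_cohort_samples=cohort.n_samples)

        stage = "filter_rescale"
        filtered = inference.filter_by_min_expression(train, cfg.inference.expression_threshold)
        rescaled = inference.rescale_zero_one(filtered)
        record(stage, n_genes_after_filter=rescaled.n_genes)

        stage = "infer"
        if regulators is None:
            if truth is None:
                raise ValueError("a regulator list is required when loading data")
            regulators = set(network.regulator_ids)
        edges = inference.infer_candidate_edges(
            rescaled,
            regulators,
            n_perm=cfg.inference.n_perm,
            fdr=cfg.inference.fdr,
            seed=stage_seed(cfg.seed, "infer"),
        )
        record(stage, n_candidate_edges=len(edges))

        stage = "dpi"
        edges = inference.apply_dpi(edges, tolerance=cfg.inference.dpi_tolerance)
        record(stage, n_edges_after_dpi=len(edges))

        stage = "sign"
        signed = inference.sign_edges(rescaled, edges)
        regulons = inference.assemble_regulons(signed)
        record(stage, n_regulons=len(regulons))

        stage = "shadow"
        if cfg.graph.shadow:
            regulons = graph_mod.shadow_filter(
                regulons,
                rescaled,
                overlap_alpha=cfg.graph.overlap_alpha,
                n_perm=cfg.graph.shadow_n_perm,
                seed=stage_seed(cfg.seed, "shadow"),
            )
        surviving = signed[signed["regulator"].isin(set(regulons.regulons))]
        io.write_edges(surviving, outdir / "edges.tsv")
        manifest["outputs"]["edges.tsv"] = _checksum(outdir / "edges.tsv")
        record(stage, n_regulons_after_shadow=len(regulons))

        stage = "metrics"
        g = graph_mod.build_graph(regulons)
        metrics = graph_mod.node_metrics(g)
        pairs, sharing = graph_mod.shared_target_pairs(regulons, cfg.graph.min_jaccard)
        save("node_metrics.tsv", metrics)
        save("overlap_pairs.tsv", pairs)
        record(stage, **{f"sharing_{k}": v for k, v in sharing.items()})

        stage = "deg"
        profiles = deg_mod.cohort_deg_profiles(
            cohort,
            pseudocount=cfg.deg.pseudocount,
            lfc_threshold=cfg.deg.lfc_threshold,
            fdr=cfg.deg.fdr,
        )
        summary = pd.DataFrame(
            [{"sample": p.sample, "n_up": p.n_up, "n_down": p.n_down} for p in profiles]
        )
        save("deg_summary.tsv", summary)
        record(stage, n_deg_profiles=len(profiles))

        stage = "ggea"
        activity = ggea_mod.activity_matrix(
            profiles,
            regulons,
            fdr=cfg.ggea.fdr,
            n_perm=cfg.ggea.n_perm,
            seed=stage_seed(cfg.seed, "ggea"),
            cap=cfg.ggea.cap,
            deg_fdr=cfg.deg.fdr,
        )
        freq = ggea_mod.activation_frequency(activity)
        save("activity.tsv", activity)
        save("activation_frequency.tsv", freq)
        record(stage, n_active_calls=int(activity["active"].sum()) if len(activity) else 0)

        stage = "survival"
        report = surv_mod.survival_report(
            clinical,
            activity,
            clinical_covariates=tuple(cfg.survival.covariates),
            alpha=cfg.survival.alpha,
        )
        save("regulon_ranking.tsv", report["regulon_ranking"])
        save("univariate.tsv", report["univariate"])
        save("multivariate.tsv", report["multivariate"])
        record(stage, n_ranked_regulons=len(report["regulon_ranking"]))
    except Exception as exc:  # abort with stage name + manifest so far
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise PipelineError(stage, exc) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
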