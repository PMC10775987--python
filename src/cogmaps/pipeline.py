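"""End-to-end orchestration: maze -> graph -> embedding -> predictions
-> local-frame errors -> circular statistics -> BIC model comparison.

The analysis scores each cognitive-map model by how well its shortcut
predictions explain directional estimates. Because an embedded map has
no privileged global orientation, every comparison happens in the local
reference frame of the starting arm: the estimate's angle relative to
the ground-truth orientation of the arm a navigator departs along, and
the model's predicted angle relative to that same arm as the model
represents it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import circstats as cs
from . import embed as emb
from . import maze as mz
from . import predict as pr
from . import synthdata as sd
from .geometry import wrap_signed_deg, wrap_unsigned_deg
from .graphbuild import LabeledGraph, Variant, build_graph, write_graph_json
from .maze import MazeSpec
from .synthdata import EstimateTable, StudyDesign

__all__ = [
    "AnalysisConfig",
    "ComparisonReport",
    "PipelineError",
    "run_analysis",
    "prediction_table",
    "load_deposited_estimates",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _round_floats(obj, digits: int = 10):
    """Recursively round floats to ``digits`` significant digits."""
    if isinstance(obj, float):
        return float(f"{obj:.{digits}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    if isinstance(obj, np.floating):
        return float(f"{float(obj):.{digits}g}")
    return obj


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything one full model-comparison run depends on."""

    maze_source: str = "replica"  # "replica" | "euclidean" | a JSON file path
    maze_seed: int = 0
    variant: Variant = Variant.WORMHOLE
    models: tuple[str, ...] = ("nonmetric", "embedded")
    design_tag: str = "rips_folds"  # "route_finding" | "rips_folds"
    design: StudyDesign | None = None  # overrides design_tag when given
    generative_model: str = "embedded"
    kappa: float = 4.0
    kappa_between: float | None = None
    data_seed: int = 1
    embed_config: emb.EmbedConfig = field(default_factory=emb.EmbedConfig)
    embedding_index: int | None = None  # None: lowest-stress local minimum
    object_placement: str = "snap"  # "snap" | "vertex"
    frame: str = "local"  # "local" | "global"
    param_convention: str = "ordered_triplets"
    alpha: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.frame not in ("local", "global"):
            raise ValueError("frame must be 'local' or 'global'")
        if self.object_placement not in ("snap", "vertex"):
            raise ValueError("object_placement must be 'snap' or 'vertex'")


@dataclass
class ModelStats:
    """Error statistics of one model against one estimate table."""

    mean_error_deg: float
    between_subject_ad_deg: float
    within_subject_ad_deg: float
    rayleigh_z: float
    rayleigh_p: float
    noise_mu_deg: float
    noise_kappa: float
    score: cs.ModelScore


@dataclass
class ComparisonReport:
    design_tag: str
    n_estimates: int
    n_subjects: int
    frame: str
    models: dict[str, ModelStats]
    pairwise: dict[str, dict]
    embedding_inventory: list[dict]
    selected_embedding: int
    provenance: dict

    def preferred_model(self) -> str:
        return min(self.models, key=lambda m: self.models[m].score.bic)

    def to_dict(self) -> dict:
        """Report as plain nested dicts.

        Floats are rounded to 10 significant digits: far below any
        scientifically meaningful precision here, but comfortably above
        the last-bit jitter numerical libraries may exhibit between
        runs, so serialized reports are byte-reproducible given the
        same seeds.
        """
        doc = asdict(self)
        doc["preferred_model"] = self.preferred_model()
        return _round_floats(doc)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for name, s in self.models.items():
            rows.append(
                {
                    "model": name,
                    "mean_error_deg": s.mean_error_deg,
                    "between_subject_ad_deg": s.between_subject_ad_deg,
                    "within_subject_ad_deg": s.within_subject_ad_deg,
                    "rayleigh_z": s.rayleigh_z,
                    "rayleigh_p": s.rayleigh_p,
                    "k": s.score.k,
                    "loglik": s.score.loglik,
                    "bic": s.score.bic,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _resolve_maze(config: AnalysisConfig) -> MazeSpec:
    src = config.maze_source
    if src == "replica":
        spec = sd.make_wormhole_replica(config.maze_seed)
    elif src == "euclidean":
        spec = sd.make_euclidean_maze(config.maze_seed)
    else:
        spec = mz.read_maze_json(src)
    if config.object_placement == "vertex":
        spec = mz.insert_object_corners(spec)
    return spec


def _design(config: AnalysisConfig) -> StudyDesign:
    if config.design is not None:
        return config.design
    if config.design_tag == "route_finding":
        return StudyDesign.route_finding()
    if config.design_tag == "rips_folds":
        return StudyDesign.rips_folds()
    raise PipelineError(f"design: unknown design tag {config.design_tag!r}")


def prediction_table(
    spec: MazeSpec,
    graph: LabeledGraph,
    embedding: emb.Embedding,
    pairs,
    variant: Variant = Variant.WORMHOLE,
) -> pd.DataFrame:
    """Per-pair predictions of all three models, in global and local frames.

    ``dir_global_equiv`` maps every model's local-frame prediction back
    through the ground-truth starting-arm orientation, giving the global
    direction a navigator following that model would walk; for the
    embedded model this is how its gauge-free prediction is compared
    with (or used to generate) global estimate angles.
    """
    rows = []
    for start, goal in pairs:
        a = mz.resolve_object(spec, start)
        b = mz.resolve_object(spec, goal)
        if a == b:
            raise PipelineError(
                f"predict: objects {start!r} and {goal!r} resolve to one vertex"
            )
        nm = pr.predict_nonmetric(graph, spec, a, b, variant)
        arm_gt = pr.start_arm_orientation(spec, list(nm.path), variant)
        successor = nm.path[1]
        gt = pr.predict_ground_truth(spec, a, b)
        ed = pr.predict_embedded(embedding, a, b)
        arm_emb = embedding.direction(a, successor)
        local = {
            "nonmetric": pr.to_local_reference(nm.direction_deg, arm_gt),
            "embedded": pr.to_local_reference(ed.direction_deg, arm_emb),
            "ground_truth": pr.to_local_reference(gt.direction_deg, arm_gt),
        }
        glob = {
            "nonmetric": nm.direction_deg,
            "embedded": wrap_unsigned_deg(arm_gt + local["embedded"]),
            "ground_truth": gt.direction_deg,
        }
        for model in ("nonmetric", "embedded", "ground_truth"):
            rows.append(
                {
                    "model": model,
                    "start": start,
                    "goal": goal,
                    "start_vertex": a,
                    "goal_vertex": b,
                    "direction_deg_global": glob[model],
                    "direction_deg_local": local[model],
                    "start_arm_deg": arm_gt if model != "embedded" else arm_emb,
                    "length": {"nonmetric": nm, "embedded": ed, "ground_truth": gt}[
                        model
                    ].length,
                    "path": "-".join(map(str, nm.path)) if model == "nonmetric" else "",
                    "dir_global_equiv": glob[model],
                }
            )
    return pd.DataFrame(rows)


def _model_errors(
    estimates: pd.DataFrame,
    preds: pd.DataFrame,
    model: str,
    frame: str,
) -> pd.DataFrame:
    """Signed prediction error per estimate row, in degrees."""
    p = preds[preds["model"] == model].set_index(["start", "goal"])
    rows = estimates.copy()
    key = list(zip(rows["start"], rows["goal"]))
    try:
        pred_global = np.array([p.loc[k, "dir_global_equiv"] for k in key])
        arm = np.array([p.loc[k, "start_arm_deg"] for k in key])
    except KeyError as err:
        raise PipelineError(f"errors: no prediction for pair {err.args[0]}") from None
    est = rows["estimate_deg"].to_numpy(dtype=float)
    if frame == "local":
        # both sides expressed relative to the physical starting arm
        nm = preds[preds["model"] == "nonmetric"].set_index(["start", "goal"])
        arm_gt = np.array([nm.loc[k, "start_arm_deg"] for k in key])
        err_deg = wrap_signed_deg(
            pr.to_local_reference(est, arm_gt)
            - pr.to_local_reference(pred_global, arm_gt)
        )
    else:
        err_deg = wrap_signed_deg(est - pred_global)
    rows["error_deg"] = err_deg
    rows["model"] = model
    return rows


def _stats_for_model(
    errors: pd.DataFrame, model: str, graph: LabeledGraph, config: AnalysisConfig
) -> tuple[ModelStats, pd.Series]:
    per_subject = errors.groupby("subject")["error_deg"].apply(
        lambda e: cs.circ_summary(e).mean_deg
    )
    between = cs.circ_summary(per_subject.to_numpy())
    within = errors.groupby("subject")["error_deg"].apply(
        lambda e: cs.circ_summary(e).angular_deviation_deg
    )
    ray = cs.rayleigh_test(per_subject.to_numpy())
    ll, noise = cs.von_mises_loglik(errors["error_deg"].to_numpy())
    k = cs.count_parameters(model, graph, config.param_convention)
    score = cs.bic(k, len(errors), ll)
    return (
        ModelStats(
            mean_error_deg=between.mean_deg,
            between_subject_ad_deg=between.angular_deviation_deg,
            within_subject_ad_deg=float(within.mean()),
            rayleigh_z=ray.statistic,
            rayleigh_p=ray.p_value,
            noise_mu_deg=noise.mu_deg,
            noise_kappa=noise.kappa,
            score=score,
        ),
        per_subject,
    )


def run_analysis(
    config: AnalysisConfig,
    estimates: EstimateTable | None = None,
    out_dir: str | Path | None = None,
) -> ComparisonReport:
    """Execute the full model comparison; deterministic given the seeds.

    When no estimate table is passed, a synthetic one is generated from
    the configured generative model's predictions with von Mises noise.
    Writes all artifacts (maze, graph, embedding, predictions,
    estimates, report) to ``out_dir`` when given.
    """
    try:
        spec = _resolve_maze(config)
    except Exception as err:
        raise PipelineError(f"maze: {err}") from err
    try:
        graph = build_graph(spec, config.variant)
    except Exception as err:
        raise PipelineError(f"graph: {err}") from err
    try:
        minima = emb.embed_graph(graph, config.embed_config)
    except Exception as err:
        raise PipelineError(f"embed: {err}") from err
    sel = config.embedding_index if config.embedding_index is not None else 0
    if not 0 <= sel < len(minima):
        raise PipelineError(
            f"embed: embedding index {sel} out of range ({len(minima)} minima)"
        )
    embedding = minima[sel]

    design = _design(config)
    try:
        preds = prediction_table(
            spec, graph, embedding, sorted(set(design.pairs)), config.variant
        )
    except pr.PredictionError as err:
        raise PipelineError(f"predict: {err}") from err

    if estimates is None:
        gen = preds[preds["model"] == config.generative_model]
        pred_map = {
            (r.start, r.goal): r.dir_global_equiv for r in gen.itertuples()
        }
        estimates = sd.generate_estimates(
            pred_map, design, config.kappa, config.data_seed, config.kappa_between
        )
    if len(estimates.data) != design.n_rows:
        raise PipelineError(
            f"estimates: expected {design.n_rows} rows for design "
            f"{design.tag!r}, got {len(estimates.data)}"
        )

    model_stats: dict[str, ModelStats] = {}
    per_subject_means: dict[str, pd.Series] = {}
    all_errors = []
    for model in config.models:
        errs = _model_errors(estimates.data, preds, model, config.frame)
        all_errors.append(errs)
        try:
            model_stats[model], per_subject_means[model] = _stats_for_model(
                errs, model, graph, config
            )
        except Exception as err:
            raise PipelineError(f"stats[{model}]: {err}") from err

    pairwise: dict[str, dict] = {}
    names = list(config.models)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            g1 = per_subject_means[a].to_numpy()
            g2 = per_subject_means[b].to_numpy()
            ww = cs.watson_williams([g1, g2])
            d = cs.cohens_d_circular(g1, g2)
            pairwise[f"{a}_vs_{b}"] = {
                "F": ww.statistic,
                "df": list(ww.df),
                "p": ww.p_value,
                "significant": ww.p_value < config.alpha,
                "cohens_d": d,
            }

    report = ComparisonReport(
        design_tag=design.tag,
        n_estimates=len(estimates.data),
        n_subjects=design.n_subjects,
        frame=config.frame,
        models=model_stats,
        pairwise=pairwise,
        embedding_inventory=[
            {
                "stress": m.stress,
                "n_hits": m.n_hits,
                "restart_index": m.restart_index,
                "converged": m.converged,
            }
            for m in minima
        ],
        selected_embedding=sel,
        provenance={
            "maze_source": config.maze_source,
            "maze_seed": config.maze_seed,
            "variant": Variant(config.variant).value,
            "embed_seed": config.embed_config.seed,
            "embed_restarts": config.embed_config.n_restarts,
            "data_seed": config.data_seed,
            "generative_model": config.generative_model,
            "kappa": None if np.isinf(config.kappa) else config.kappa,
            "estimate_meta": dict(estimates.meta),
        },
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mz.write_maze_json(spec, out / "maze.json")
        write_graph_json(graph, out / "graph.json")
        for n, m in enumerate(minima):
            emb.write_embedding_csv(
                m, out / f"embedding_{n}.csv", out / f"embedding_{n}.json"
            )
        preds.to_csv(out / "predictions.csv", index=False)
        sd.write_estimates_csv(estimates, out / "estimates.csv", out / "estimates.json")
        pd.concat(all_errors).to_csv(out / "errors.csv", index=False)
        report.to_json(out / "report.json")
        report.summary_frame().to_csv(out / "report.csv", index=False, float_format="%.10g")
    return report


# ---------------------------------------------------------------------------
# deposited-data adapter
# ---------------------------------------------------------------------------


def load_deposited_estimates(
    path,
    column_map: dict[str, str],
    spec: MazeSpec | None = None,
    angles: str = "global",
) -> EstimateTable:
    """Load an external estimate table via an explicit column map.

    ``column_map`` names the file's columns for the required fields
    ``subject``, ``start``, ``goal`` and ``angle``. ``angles`` declares
    the convention: "global" directions, or "relative_to_ground_truth"
    (signed deviation from the straight-line direction in ground-truth
    coordinates, in which case ``spec`` must be given to convert back
    to global angles).
    """
    df = pd.read_csv(path)
    required = ("subject", "start", "goal", "angle")
    missing = [f for f in required if f not in column_map]
    if missing:
        raise PipelineError(f"load: column_map lacks entries for {missing}")
    absent = [column_map[f] for f in required if column_map[f] not in df.columns]
    if absent:
        raise PipelineError(
            f"load: columns {absent} not in file; available: {list(df.columns)}"
        )
    out = pd.DataFrame(
        {
            "subject": df[column_map["subject"]].astype(str),
            "start": df[column_map["start"]].astype(str),
            "goal": df[column_map["goal"]].astype(str),
        }
    )
    ang = df[column_map["angle"]].to_numpy(dtype=float)
    if angles == "global":
        out["estimate_deg"] = wrap_unsigned_deg(ang)
    elif angles == "relative_to_ground_truth":
        if spec is None:
            raise PipelineError(
                "load: ground-truth-relative angles need the maze to convert"
            )
        gt_dirs = np.array(
            [
                pr.predict_ground_truth(
                    spec, mz.resolve_object(spec, s), mz.resolve_object(spec, g)
                ).direction_deg
                for s, g in zip(out["start"], out["goal"])
            ]
        )
        out["estimate_deg"] = wrap_unsigned_deg(gt_dirs + ang)
    else:
        raise PipelineError(f"load: unknown angle convention {angles!r}")
    return EstimateTable(data=out, design_tag="custom", meta={"source": str(path)})
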