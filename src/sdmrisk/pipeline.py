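"""End-to-end orchestration: simulate -> filter -> fit -> ensemble -> assess.

``run_pipeline`` composes the whole analysis for one (synthetic) species:
grid thinning and background generation, replicated 70/30 splits,
collinearity filtering, the four-learner fit, MTSS thresholds and
TSS-weighted ensembling, per-scenario change accounting and the Red List
assessment. Everything is seeded through the config; two runs with the
same config are byte-identical on disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, io, models, predictors, redlist, synthetic
from .ensemble import binarize, change_map, change_summary, classify_suitability, ensemble_map
from .grid import EnvStack
from .occurrences import OccurrenceSet, generate_background, thin_to_grid, train_test_split

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run; every threshold has its field-standard default."""

    species: str = "virtual_species"
    n_rows: int = 72
    n_cols: int = 72
    n_layers: int = 12
    mask_fraction: float = 0.0
    n_presence: int = 200
    n_background: int = 1000
    test_fraction: float = 0.3
    n_replicates: int = 5
    algorithms: tuple[str, ...] = models.ALGORITHMS
    vif_max: float = 5.0
    cor_max: float = 0.75
    class_low: float = 0.3
    class_high: float = 0.5
    n_locations: int = 2
    decline: tuple[str, ...] = ("i", "iv", "v")
    seed: int = 0
    truth_noise_sd: float = 0.0
    perturbation_sd: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.vif_max < 1 or not 0 < self.cor_max <= 1:
            raise ValueError("collinearity thresholds out of range")
        if not 0 <= self.class_low <= self.class_high <= 1:
            raise ValueError("class bounds must satisfy 0 <= low <= high <= 1")

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        for seq_field in ("algorithms", "decline"):
            setattr(cfg, seq_field, tuple(getattr(cfg, seq_field)))
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["algorithms"] = list(d["algorithms"])
        d["decline"] = list(d["decline"])
        return d


@dataclass
class PipelineResult:
    """In-memory handles to every stage's output."""

    stack: EnvStack
    occurrences: OccurrenceSet
    vif_report: predictors.VifReport
    model_set: models.ModelSet
    eval_results: dict[str, list[evaluation.EvalResult]]
    eval_table: pd.DataFrame
    ensemble_current: object
    mtss: float
    importance: dict[str, float]
    change_summaries: dict[str, object] = field(default_factory=dict)
    assessments: pd.DataFrame | None = None
    range_metrics: redlist.RangeMetrics | None = None


def run_pipeline(config: RunConfig, outdir: Path | None = None,
                 scenarios=None) -> PipelineResult:
    """Run every stage on a synthetic landscape; optionally persist artifacts.

    Stage failures raise after logging the stage name; previously written
    artifacts stay on disk.
    """
    stage = "simulate"
    try:
        spec = synthetic.LandscapeSpec(
            n_rows=config.n_rows, n_cols=config.n_cols, n_layers=config.n_layers,
            mask_fraction=config.mask_fraction, seed=config.seed)
        stack = synthetic.generate_env_stack(spec)
        truth = synthetic.default_truth_model(stack, noise_sd=config.truth_noise_sd)
        suit = synthetic.truth_suitability(stack, truth, seed=config.seed + 1)
        occ = synthetic.sample_occurrences(suit, config.n_presence,
                                           seed=config.seed + 2,
                                           species=config.species)

        stage = "thin"
        occ = thin_to_grid(occ, stack.cell_km, stack.origin)

        stage = "background"
        background = generate_background(stack, config.n_background,
                                         seed=config.seed + 3, exclude=occ)

        stage = "split"
        splits = train_test_split(occ, background, config.test_fraction,
                                  config.n_replicates, seed=config.seed + 4)

        stage = "vif"
        site_points = np.vstack([occ.points, background.points])
        site_X = stack.extract(site_points).dropna()
        vif_report = predictors.vif_filter(site_X, config.cor_max, config.vif_max)
        retained = vif_report.retained

        stage = "fit"
        model_set = models.fit_all(splits, stack, config.algorithms,
                                   predictor_names=retained, seed=config.seed)

        stage = "evaluate"
        eval_results: dict[str, list[evaluation.EvalResult]] = {
            a: [] for a in config.algorithms}
        tss_by_model = []
        split_by_id = {s.replicate_id: s for s in splits}
        for m in model_set.models:
            s = split_by_id[m.replicate_id]
            Xtr, ytr = s.training_xy(stack)
            Xte, yte = s.testing_xy(stack)
            res = evaluation.evaluate(m.predict(Xtr[retained]), ytr,
                                      m.predict(Xte[retained]), yte)
            eval_results[m.algorithm].append(res)
            tss_by_model.append(res.tss)
        eval_table = evaluation.summarize_replicates(
            {a: r for a, r in eval_results.items() if r})

        stage = "ensemble"
        maps = [models.predict_map(m, stack) for m in model_set.models]
        ens = ensemble_map(maps, tss_by_model)
        # ensemble MTSS on all training data pooled over replicates
        Xall = stack.extract(site_points)
        ok = np.all(np.isfinite(Xall[retained].to_numpy()), axis=1)
        yall = np.r_[np.ones(len(occ)), np.zeros(len(background))][ok]
        w = np.maximum(np.asarray(tss_by_model), 0)
        w = w / w.sum()
        ens_scores = np.zeros(ok.sum())
        for m, wi in zip(model_set.models, w):
            ens_scores += wi * m.predict(Xall[retained][ok])
        mtss, _ = evaluation.mtss_threshold(ens_scores, yall)

        stage = "importance"

        def ens_predict(X: pd.DataFrame) -> np.ndarray:
            out = np.zeros(len(X))
            for m, wi in zip(model_set.models, w):
                out += wi * m.predict(X[retained])
            return out

        importance = predictors.variable_importance(
            ens_predict, Xall[retained][ok], n_perm=5, seed=config.seed + 5)

        stage = "project"
        current_bin = binarize(ens, mtss)
        classes = classify_suitability(ens, config.class_low, config.class_high)
        if scenarios is None:
            scenarios = synthetic.default_scenarios(stack)
        summaries: dict[str, object] = {}
        losses_full: dict[str, float] = {}
        losses_limited: dict[str, float] = {}
        future_bins: dict[str, object] = {}
        for sc in scenarios:
            label = f"{sc.scenario_id}_{sc.period}"
            fstack = synthetic.make_future_stack(
                stack, sc, seed=config.seed + 6,
                perturbation_sd=config.perturbation_sd)
            fmaps = [models.predict_map(m, fstack) for m in model_set.models]
            fens = ensemble_map(fmaps, tss_by_model)
            fbin = binarize(fens, mtss)
            future_bins[label] = fbin
            cm = change_map(current_bin, fbin)
            summaries[label] = change_summary(cm)
            _, losses_full[label] = redlist.projected_aoo(current_bin, fbin, "full")
            _, losses_limited[label] = redlist.projected_aoo(current_bin, fbin, "limited")

        stage = "assess"
        rm = redlist.RangeMetrics(
            eoo_km2=redlist.eoo(occ.points),
            aoo_km2=redlist.aoo(occ.points),
            n_locations=config.n_locations,
            occupied_cells=redlist.occupied_cells(occ.points),
        )
        flags = redlist.ConditionFlags(severely_fragmented=True,
                                       continuing_decline=config.decline)
        current = redlist.assess(rm, flags)
        rows = [{"species": config.species, "scenario": label,
                 "loss_full": losses_full[label],
                 "loss_limited": losses_limited[label],
                 "current_status": current.category}
                for label in summaries]
        assessments = redlist.assessment_table(rows)

        result = PipelineResult(stack, occ, vif_report, model_set, eval_results,
                                eval_table, ens, mtss, importance, summaries,
                                assessments, rm)
        if outdir is not None:
            _write_artifacts(result, config, Path(outdir), current_bin,
                             classes, future_bins)
        return result
    except Exception:
        log.error("pipeline failed in stage %r", stage)
        raise


def recovery_experiment(seed: int, n_rows: int = 100, n_cols: int = 100,
                        n_layers: int = 12, n_presence: int = 300,
                        n_background: int = 1000, n_replicates: int = 1,
                        algorithms: tuple[str, ...] = models.ALGORITHMS
                        ) -> dict:
    """Fit the ensemble on a noise-free virtual species and score recovery.

    Returns the held-out TSS-weighted ensemble AUC (mean over replicates),
    the permutation-importance percentages over the collinearity-filtered
    predictor set, and the virtual species' true driver layers. This is the
    package's self-check that the pipeline recovers a known truth; no maps
    are projected, so it runs much faster than :func:`run_pipeline`.
    """
    spec = synthetic.LandscapeSpec(n_rows=n_rows, n_cols=n_cols,
                                   n_layers=n_layers, seed=seed)
    stack = synthetic.generate_env_stack(spec)
    truth = synthetic.default_truth_model(stack)
    suit = synthetic.truth_suitability(stack, truth)
    occ = thin_to_grid(synthetic.sample_occurrences(suit, n_presence,
                                                    seed=seed + 1),
                       stack.cell_km, stack.origin)
    background = generate_background(stack, n_background, seed=seed + 2,
                                     exclude=occ)
    splits = train_test_split(occ, background, 0.3, n_replicates,
                              seed=seed + 3)
    site_points = np.vstack([occ.points, background.points])
    site_X = stack.extract(site_points)
    retained = predictors.vif_filter(site_X).retained

    model_set = models.fit_all(splits, stack, algorithms,
                               predictor_names=retained, seed=seed)
    split_by_id = {s.replicate_id: s for s in splits}
    tss_by_model, aucs = [], []
    test_preds: dict[int, list[np.ndarray]] = {r: [] for r in split_by_id}
    for m in model_set.models:
        sp = split_by_id[m.replicate_id]
        Xtr, ytr = sp.training_xy(stack)
        Xte, _ = sp.testing_xy(stack)
        _, tss = evaluation.mtss_threshold(m.predict(Xtr[retained]), ytr)
        tss_by_model.append(max(tss, 0.0))
        test_preds[m.replicate_id].append(m.predict(Xte[retained]))
    w = np.asarray(tss_by_model)
    for rid, sp in split_by_id.items():
        idx = [i for i, m in enumerate(model_set.models)
               if m.replicate_id == rid]
        wr = w[idx] / w[idx].sum()
        ens = np.sum([wi * p for wi, p in zip(wr, test_preds[rid])], axis=0)
        _, yte = sp.testing_xy(stack)
        aucs.append(evaluation.auc(ens, yte))

    wall = w / w.sum()

    def ens_predict(X: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(X))
        for m, wi in zip(model_set.models, wall):
            out += wi * m.predict(X[retained])
        return out

    importance = predictors.variable_importance(ens_predict, site_X[retained],
                                                n_perm=5, seed=seed + 4)
    return {
        "ensemble_auc": float(np.mean(aucs)),
        "importance": importance,
        "truth_layers": truth.layer_names,
        "retained": retained,
    }


def _fmt(x: float) -> str:
    return f"{x:.17g}"


def _write_artifacts(result: PipelineResult, config: RunConfig, outdir: Path,
                     current_bin, classes, future_bins) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_stack(result.stack, outdir / "stack")
    io.write_occurrences(result.occurrences, outdir / "occurrences.csv")
    result.vif_report.to_frame().to_csv(outdir / "vif_report.csv", index=False)

    # performance table: metrics as rows, algorithms as columns, mean +/- SD
    tbl = result.eval_table
    disp = pd.DataFrame({
        col: [f"{tbl[('mean', col)][m]:.2f} ± {tbl[('sd', col)][m]:.2f}"
              for m in evaluation.METRIC_ROWS]
        for col in tbl["mean"].columns
    }, index=list(evaluation.METRIC_ROWS))
    disp.to_csv(outdir / "performance.csv")

    pd.DataFrame(sorted(result.importance.items(),
                        key=lambda kv: -kv[1]),
                 columns=["variable", "importance_pct"]).to_csv(
        outdir / "importance.csv", index=False)

    io.write_grid(result.ensemble_current, outdir / "ensemble_current.tif")
    io.write_grid(current_bin, outdir / "binary_current.tif")
    io.write_grid(classes, outdir / "classes_current.tif")
    rows = []
    for label, s in result.change_summaries.items():
        row = {"scenario": label}
        row.update({k: _fmt(v) for k, v in s.__dict__.items()})
        row.update({f"{k}_display": f"{v:.1f}"
                    for k, v in s.rounded().items() if k.endswith("pct") or
                    k.endswith("pct_of_area")})
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "change_summary.csv", index=False)
    for label, fbin in future_bins.items():
        io.write_grid(fbin, outdir / f"binary_{label}.tif")

    result.assessments.to_csv(outdir / "assessment.csv", index=False)
    (outdir / "range_metrics.json").write_text(json.dumps({
        "eoo_km2": result.range_metrics.eoo_km2,
        "aoo_km2": result.range_metrics.aoo_km2,
        "occupied_cells": result.range_metrics.occupied_cells,
        "mtss_threshold": result.mtss,
    }, indent=2, sort_keys=True))
    io.write_manifest(outdir, config.to_dict())
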