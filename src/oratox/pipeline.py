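"""End-to-end orchestration of the dossier analysis.

One master seed fans out to every stage; given the same config the report
bundle is byte-identical. Stages write plain-text artifacts (TSV/CSV/JSON)
into an output directory, and a ``manifest.json`` records the substance
count at every filter step so the funnel is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import dossier, evaluation, importance, knn, models, similarity, synthetic

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {message}")


@dataclass
class PipelineConfig:
    seed: int = 0
    generator: dict = field(default_factory=dict)
    ld50_threshold: float = 2000.0
    noael_threshold: float = 200.0
    taylor_threshold: float = 1000.0
    similarity_threshold: float = 0.7
    knn_k: int = 5
    perceptron_epochs: int = 500
    perceptron_hidden: int | None = None
    run_cv: bool = True
    cv_folds: int = 10
    loo_subsample: int = 0  # 0 disables the leave-one-out stage
    run_importance: bool = True
    importance_subsets: int = 100
    # ingest mode: paths to interchange files instead of the generator
    study_table: str | None = None
    fingerprint_file: str | None = None
    descriptor_table: str | None = None

    @property
    def ingest_mode(self) -> bool:
        return self.study_table is not None

    def generator_config(self) -> synthetic.GeneratorConfig:
        kwargs = dict(self.generator)
        kwargs.setdefault("seed", self.seed)
        return synthetic.GeneratorConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError("config", f"unknown keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _knn_config(cfg: PipelineConfig) -> knn.KnnConfig:
    return knn.KnnConfig(k=cfg.knn_k, neighbor_threshold=cfg.similarity_threshold)


STAGES = ("generate", "graph", "knn", "train", "importance", "concordance",
          "evaluate")


def run_pipeline(
    cfg: PipelineConfig, outdir: str | Path, stages: set[str] | None = None
) -> dict:
    """Run the requested stages (default: all) and write the report bundle.

    Upstream prerequisites of a requested stage are recomputed in memory
    (generation is deterministic under the seed) but only the requested
    stages write artifacts. Returns the manifest.
    """
    if stages is not None and not set(stages) <= set(STAGES):
        raise PipelineError("config", f"unknown stages: {sorted(set(stages) - set(STAGES))}")
    want = lambda s: stages is None or s in stages
    heavy = {"train", "importance", "evaluate"}
    need_models = stages is None or bool(heavy & stages)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(cfg), "counts": {}, "inputs": {}}
    counts = manifest["counts"]

    # ---- stage: data -----------------------------------------------------
    if cfg.ingest_mode:
        for name in ("study_table", "fingerprint_file", "descriptor_table"):
            value = getattr(cfg, name)
            if value is None or not Path(value).exists():
                raise PipelineError("ingest", f"missing input file for {name}: {value}")
            manifest["inputs"][name] = _sha256(Path(value))
        try:
            acute_studies = dossier.read_study_table(cfg.study_table)
            fp_map = dossier.read_fingerprints(cfg.fingerprint_file)
            descriptors = dossier.read_descriptor_table(cfg.descriptor_table)
        except (dossier.SchemaError, dossier.StudyTableError) as exc:
            raise PipelineError("ingest", str(exc)) from exc
        substances = [
            dossier.SubstanceRecord(
                substance_id=sid,
                fingerprint=fp_map[sid],
                descriptors=descriptors.loc[sid].to_dict(),
            )
            for sid in descriptors.index
            if sid in fp_map
        ]
        repeated_studies = [
            s for s in acute_studies if s.endpoint != "acute_oral"
        ]
        acute_studies = [s for s in acute_studies if s.endpoint == "acute_oral"]
        data = synthetic.Dossier(substances, acute_studies, repeated_studies,
                                 cfg.generator_config())
    else:
        data = synthetic.generate_dossier(cfg.generator_config())
        if want("generate"):
            dossier.write_study_table(
                data.acute_studies + data.repeated_studies,
                outdir / "studies.csv",
            )
            dossier.write_fingerprints(data.substances,
                                       outdir / "fingerprints.txt")
            dossier.write_descriptor_table(data.substances,
                                           outdir / "descriptors.csv")
    counts["substances"] = len(data.substances)
    counts["acute_studies"] = len(data.acute_studies)
    counts["repeated_studies"] = len(data.repeated_studies)

    # ---- stage: aggregate + label ---------------------------------------
    modeling_rule = dossier.SelectionRule(max_klimisch=1)
    agg = dossier.aggregate_dataset(data.acute_studies, modeling_rule,
                                    "acute_oral")
    labels = (agg["mean_value"] < cfg.ld50_threshold)
    counts["modeling_substances"] = len(agg)
    counts["toxicants"] = int(labels.sum())
    counts["non_toxicants"] = int((~labels).sum())
    if want("generate"):
        agg.assign(toxicant=labels).to_csv(outdir / "aggregated_acute.csv")

    sub_by_id = {s.substance_id: s for s in data.substances}
    modeled = [sub_by_id[sid] for sid in agg.index if sid in sub_by_id]
    if len(modeled) != len(agg):
        raise PipelineError("aggregate", "studies reference unknown substances")
    F = np.asarray([s.fingerprint for s in modeled], dtype=np.uint8)
    ids = [s.substance_id for s in modeled]
    y = labels.loc[ids].to_numpy()

    # ---- stage: similarity graph + modules -------------------------------
    graph = similarity.build_graph((ids, F), cfg.similarity_threshold)
    similarity.detect_modules(graph, seed=cfg.seed)
    if want("graph"):
        similarity.write_edge_list(graph, outdir / "graph_edges.tsv")
        similarity.write_module_table(graph, outdir / "graph_modules.tsv")
    counts["graph_nodes"] = graph.graph.number_of_nodes()
    counts["graph_edges"] = graph.graph.number_of_edges()
    counts["modules"] = graph.n_modules
    manifest["modularity_q"] = round(graph.q, 6)

    # ---- stage: knn ------------------------------------------------------
    knn_cfg = _knn_config(cfg)
    knn_frame = knn.knn_feature_column(F, ids, y, knn_cfg)
    if want("knn"):
        knn.write_predictions(knn_frame, outdir / "knn_predictions.tsv")
    counts["knn_in_domain"] = int(knn_frame["in_domain"].sum())

    # ---- stage: modeling dataset -----------------------------------------
    X = pd.DataFrame(
        [s.descriptors for s in modeled], index=pd.Index(ids, name="substance_id")
    )[list(dossier.DESCRIPTOR_NAMES)]
    X = X.assign(KNN=knn_frame["knn"].to_numpy()).reset_index(drop=True)
    weights = models.compute_class_weights(y, "paper").weights
    dataset = models.ModelingDataset(
        ids=ids, X=X, y=y, weights=weights, fingerprints=F
    )
    counts["modeling_rows"] = dataset.n

    # ---- stage: supervised models ----------------------------------------
    if not need_models:
        tree = mlp = None
    else:
        tree, mlp, p_cfg = _train_models(cfg, dataset, y)
        manifest["tree_features"] = list(tree.feature_names)

    # ---- stage: evaluation -----------------------------------------------
    if need_models:
        module_of = graph.module_of
        rows = []
        knn_pred = knn_frame["knn"].to_numpy().astype(bool)
        rows.append(evaluation.confusion(y, knn_pred, "knn:train").as_row())
        rows.append(
            evaluation.confusion(y, tree.predict(dataset.X),
                                 "tree:train").as_row()
        )
        mlp_train_pred = mlp.predict(dataset.X)
        rows.append(evaluation.confusion(y, mlp_train_pred,
                                         "mlp:train").as_row())
        if cfg.run_cv and want("evaluate"):
            trainer = lambda d, s: models.train_perceptron(
                d, dataclasses.replace(p_cfg, seed=s)
            )
            cv = evaluation.stratified_kfold(
                dataset, trainer, k=cfg.cv_folds, seed=cfg.seed,
                knn_cfg=knn_cfg, knn_mode="fold",
            )
            rows.append(dataclasses.replace(cv.pooled, scope="mlp:cv").as_row())
        if want("train") or want("evaluate"):
            pd.DataFrame(rows).set_index("scope").to_csv(
                outdir / "model_summary.tsv", sep="\t"
            )
        if want("evaluate"):
            evaluation.per_module_confusion(
                y, knn_pred, module_of, ids
            ).to_csv(outdir / "knn_modules.tsv", sep="\t")
            evaluation.per_module_confusion(
                y, mlp_train_pred, module_of, ids
            ).to_csv(outdir / "mlp_modules.tsv", sep="\t")
            if cfg.loo_subsample:
                rng = np.random.default_rng(cfg.seed)
                take = min(cfg.loo_subsample, dataset.n)
                idx = np.sort(rng.choice(dataset.n, size=take, replace=False))
                sub = dataset.subset(idx)
                loo_pred = evaluation.leave_one_out(
                    sub, lambda d, s: models.train_perceptron(
                        d, dataclasses.replace(p_cfg, seed=s)
                    ),
                    seed=cfg.seed, knn_cfg=knn_cfg, size_warning=10**9,
                )
                evaluation.per_module_confusion(
                    sub.y, loo_pred, module_of, sub.ids
                ).to_csv(outdir / "mlp_loo_modules.tsv", sep="\t")
                counts["loo_substances"] = sub.n

    # ---- stage: feature importance ---------------------------------------
    if cfg.run_importance and want("importance"):
        n_subsets = min(cfg.importance_subsets,
                        int(min(y.sum(), (~y).sum())))
        subsets = importance.make_balanced_subsets(y, n_subsets, seed=cfg.seed)
        ranker = importance.ranker_evaluate(dataset, subsets, seed=cfg.seed)
        wrapper = importance.wrapper_evaluate(dataset, subsets, seed=cfg.seed)
        report = ranker.table.join(wrapper.table)
        report.to_csv(outdir / "feature_importance.tsv", sep="\t")
        counts["importance_subsets"] = n_subsets
        manifest["top_features"] = list(report.index[:3])

    # ---- stage: concordance ----------------------------------------------
    if want("concordance"):
        _write_concordance(cfg, data, outdir, counts)

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _train_models(cfg: PipelineConfig, dataset: models.ModelingDataset,
                  y: np.ndarray):
    """Decision tree on (KNN, next-most-informative descriptor) + MLP."""
    ranker_all = importance.ranker_evaluate(
        dataset, importance.make_balanced_subsets(y, min(cfg.importance_subsets,
                                                         int(min(y.sum(), (~y).sum()))),
                                                  seed=cfg.seed),
        seed=cfg.seed,
    )
    descriptor_rank = [f for f in ranker_all.table.index if f != "KNN"]
    tree_features = ("KNN", descriptor_rank[0])
    tree = models.train_decision_tree(dataset, tree_features, seed=cfg.seed)
    p_cfg = models.PerceptronConfig(
        hidden_units=cfg.perceptron_hidden, epochs=cfg.perceptron_epochs,
        seed=cfg.seed,
    )
    mlp = models.train_perceptron(dataset, p_cfg)
    return tree, mlp, p_cfg


def _write_concordance(cfg: PipelineConfig, data: synthetic.Dossier,
                       outdir: Path, counts: dict) -> None:
    summary: dict = {}
    # the NOAEL/LD50 analyses need acute studies alongside the repeated
    # block; the generator's repeated cohort carries its own coupled acute
    # studies, ingested tables may not
    repeated = list(data.repeated_studies)
    if repeated and not any(s.endpoint == "acute_oral" for s in repeated):
        repeated = repeated + list(data.acute_studies)
    data = dataclasses.replace(data, repeated_studies=repeated)
    if any(s.hazard_flags for s in data.substances):
        prev = conc.hazard_prevalence(data.substances)
        prev.to_csv(outdir / "hazard_prevalence.tsv", sep="\t")
        summary["oral_nontoxic_pct"] = conc.oral_nontoxic_percent(prev)
    agreement = conc.guideline_agreement(data.acute_studies,
                                         cfg.ld50_threshold)
    agreement.to_csv(outdir / "guideline_agreement.tsv", sep="\t")
    if data.repeated_studies:
        for scope in ("all", "key_only"):
            res = conc.bulgheroni_table(
                data.repeated_studies,
                noael_threshold=cfg.noael_threshold,
                ld50_threshold=cfg.ld50_threshold,
                scope=scope,
            )
            summary[f"bulgheroni_{scope}"] = {
                "npv_pct": res.npv_pct,
                "ppv_pct": res.ppv_pct,
                "avoidable_count": res.avoidable_count,
                "n": res.n_substances,
                "cells": dataclasses.asdict(res.table),
            }
        pairs = conc.noael_pairs(data.repeated_studies)
        counts["noael_pairs"] = len(pairs)
        summary["taylor_all"] = conc.taylor_predictivity(
            pairs, cfg.taylor_threshold
        )
        flags = conc.taylor_filter(data.substances, data.repeated_studies,
                                   limit_dose=cfg.taylor_threshold)
        kept = pairs.index.intersection(flags.index[flags["passes"]])
        counts["taylor_filtered"] = len(kept)
        if len(kept):
            summary["taylor_filtered"] = conc.taylor_predictivity(
                pairs.loc[kept], cfg.taylor_threshold
            )
        key_pairs = conc.noael_pairs(
            data.repeated_studies, dossier.SelectionRule(key_only=True)
        )
        if len(key_pairs):
            summary["factor3"] = conc.factor3_check(key_pairs)
    with open(outdir / "concordance_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
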