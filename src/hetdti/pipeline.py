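"""End-to-end orchestration: similarities -> H_DP -> encoder -> forest -> scores.

`run_pipeline` executes the full procedure on user files or a generated
synthetic dataset, evaluates it by 5-fold cross-validation plus an
independent test split, and scores every unknown drug-protein pair.
`run_ablation` and `run_forest_sweep` reproduce the configuration sweeps
(string encoding x layer plan, and forest size) on a shared split plan.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np

from .alignment import AlignmentScoring
from .classifier import ForestConfig, fit_forest, predict_scores
from .embeddings import EmbeddingParams
from .encoder import EncoderConfig, encode, fuse, train_encoder
from .evaluation import (
    SplitPlan,
    all_negative_pairs,
    best_report,
    make_splits,
    mean_report,
    run_cross_validation,
    run_fold,
    score_report,
)
from .hetnet import build_hetnet, node_features
from .io_formats import (
    DrugRecord,
    InteractionTable,
    ProteinRecord,
    read_drug_table,
    read_interactions,
    read_proteins,
    write_predictions,
)
from .similarity import SimilarityMatrix, drug_similarity_matrix, drug_vectors, prepare_drugs, protein_similarity_matrix
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    drug_table: str | None = None
    protein_file: str | None = None
    interaction_file: str | None = None
    synthetic: SyntheticConfig | None = None
    drug_encoding: str = "selfies"  # or "smiles"
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    embedding: EmbeddingParams = field(default_factory=EmbeddingParams)
    split_seed: int = 0
    outdir: str = "hetdti_out"

    def __post_init__(self) -> None:
        have_files = all(x is not None for x in
                         (self.drug_table, self.protein_file, self.interaction_file))
        if not have_files and self.synthetic is None:
            raise ValueError("either all three input files or a synthetic config is required")


def config_from_mapping(data: dict) -> PipelineConfig:
    """Build a PipelineConfig from a plain key-value mapping (e.g. YAML).

    Nested sections (``encoder``, ``forest``, ``embedding``, ``synthetic``)
    map onto the corresponding config dataclasses; unknown keys are errors.
    """
    data = dict(data)
    kwargs: dict = {}
    nested = {"encoder": EncoderConfig, "forest": ForestConfig,
              "embedding": EmbeddingParams, "synthetic": SyntheticConfig}
    for key, cls in nested.items():
        if key in data:
            section = data.pop(key)
            if "layer_plan" in section:
                section["layer_plan"] = tuple(section["layer_plan"])
            if "hidden_dims" in section:
                section["hidden_dims"] = tuple(section["hidden_dims"])
            kwargs[key] = cls(**section)
    allowed = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs.update(data)
    return PipelineConfig(**kwargs)


@dataclass
class Dataset:
    drugs: list[DrugRecord]
    proteins: list[ProteinRecord]
    interactions: InteractionTable


def load_dataset(config: PipelineConfig) -> Dataset:
    if config.synthetic is not None:
        syn = generate_dataset(config.synthetic)
        return Dataset(drugs=syn.drugs, proteins=syn.proteins,
                       interactions=syn.interactions)
    drugs = read_drug_table(config.drug_table)
    proteins = read_proteins(config.protein_file)
    interactions = read_interactions(
        config.interaction_file,
        drug_ids=[d.drug_id for d in drugs],
        protein_ids=[p.protein_id for p in proteins],
    )
    return Dataset(drugs=drugs, proteins=proteins, interactions=interactions)


def compute_similarities(
    dataset: Dataset,
    drug_encoding: str = "selfies",
    embedding: EmbeddingParams | None = None,
    scoring: AlignmentScoring | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """S_D and S_P for a dataset under the chosen drug string encoding."""
    t0 = time.perf_counter()
    prepare_drugs(dataset.drugs, encoding=drug_encoding)
    vecs, _ = drug_vectors(dataset.drugs, embedding)
    s_d = drug_similarity_matrix([d.drug_id for d in dataset.drugs], vecs)
    t1 = time.perf_counter()
    s_p = protein_similarity_matrix(dataset.proteins, scoring)
    logger.info("similarities: S_D %.2fs, S_P %.2fs", t1 - t0, time.perf_counter() - t1)
    return s_d, s_p


def _manifest(config: PipelineConfig) -> dict:
    cfg = asdict(config)
    try:
        ver = _pkg_version("hetdti")
    except Exception:  # pragma: no cover - not installed
        ver = "unknown"
    return {"config": cfg, "version": ver}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the complete procedure and write all artifacts to ``outdir``.

    Returns a summary dict with the CV mean report, best-fold report,
    independent-test report and the path of the predictions file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        dataset = load_dataset(config)
        stage = "similarity"
        s_d, s_p = compute_similarities(dataset, config.drug_encoding, config.embedding)
        stage = "split"
        positives = sorted(dataset.interactions.edges)
        negatives = all_negative_pairs([d.drug_id for d in dataset.drugs],
                                       [p.protein_id for p in dataset.proteins],
                                       set(positives))
        plan = make_splits(positives, negatives, seed=config.split_seed)
        stage = "cross-validation"
        t0 = time.perf_counter()
        fold_reports, cv_mean = run_cross_validation(
            s_d, s_p, plan, config.encoder, config.forest,
            extra_edges=dataset.interactions)
        logger.info("cross-validation: %.2fs", time.perf_counter() - t0)
        stage = "independent-test"
        train_all = _cv_training_pairs(plan)
        test_scores, test_labels = run_fold(
            s_d, s_p, train_all, plan.test_pairs, config.encoder, config.forest,
            extra_edges=dataset.interactions)
        test_report = score_report(test_scores, test_labels, seed=plan.seed)
        stage = "predict-unknown"
        pred_path = outdir / "predictions.tsv"
        _predict_unknown(s_d, s_p, dataset, train_all, config, pred_path)
        stage = "write-reports"
        cv_mean.to_json(outdir / "cv_mean_report.json")
        test_report.to_json(outdir / "test_report.json")
        with open(outdir / "cv_fold_scores.tsv", "w", encoding="utf-8") as fh:
            fh.write("fold\troc_auc\tpr_auc\tf1\taccuracy\trecall\n")
            for i, r in enumerate(fold_reports):
                fh.write(f"{i}\t{r.roc_auc:.4f}\t{r.pr_auc:.4f}\t{r.f1:.4f}"
                         f"\t{r.accuracy:.4f}\t{r.recall:.4f}\n")
        (outdir / "manifest.json").write_text(
            json.dumps(_manifest(config), indent=2, default=str) + "\n", encoding="utf-8")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return {
        "cv_mean": cv_mean,
        "cv_best": best_report(fold_reports),
        "cv_folds": fold_reports,
        "test": test_report,
        "predictions": str(pred_path),
    }


def _cv_training_pairs(plan: SplitPlan) -> list[tuple[tuple[str, str], int]]:
    """All CV positives plus each fold's validation negatives as the final
    training set (test pairs stay held out)."""
    pairs: dict[tuple[str, str], int] = {}
    for train, val in plan.folds:
        for p, y in val:
            pairs[p] = y
    return sorted(pairs.items())


def _predict_unknown(s_d, s_p, dataset, train_all, config, path) -> None:
    """Train on all known data and score every unknown pair."""
    table = InteractionTable(edges={p for p, y in train_all if y == 1},
                             drug_drug_edges=dataset.interactions.drug_drug_edges,
                             target_target_edges=dataset.interactions.target_target_edges)
    net = build_hetnet(s_d, s_p, table)
    F = node_features(net)
    model, _ = train_encoder(net, F, train_all, config.encoder)
    emb = encode(net, F, model)
    Z_train = fuse(emb, [p for p, _ in train_all])
    y_train = np.array([y for _, y in train_all])
    forest = fit_forest(Z_train, y_train, config.forest)
    unknown = all_negative_pairs([d.drug_id for d in dataset.drugs],
                                 [p.protein_id for p in dataset.proteins],
                                 dataset.interactions.edges)
    scores = predict_scores(forest, fuse(emb, unknown))
    write_predictions([(d, p, float(s)) for (d, p), s in zip(unknown, scores)], path)


def run_ablation(
    config: PipelineConfig,
    encodings: tuple[str, ...] = ("selfies", "smiles"),
    plans: tuple[tuple[str, ...], ...] = (("gcn", "gat"), ("gcn", "gat", "gcn")),
    mode: str = "test",
) -> list[dict]:
    """Evaluate every (encoding, layer plan) cell on one shared split plan.

    ``mode="test"`` trains on the CV pool and scores the independent test
    split (one training per cell); ``mode="cv"`` runs the full 5-fold
    protocol per cell.
    """
    dataset = load_dataset(config)
    positives = sorted(dataset.interactions.edges)
    negatives = all_negative_pairs([d.drug_id for d in dataset.drugs],
                                   [p.protein_id for p in dataset.proteins],
                                   set(positives))
    plan = make_splits(positives, negatives, seed=config.split_seed)
    sims: dict[str, tuple[SimilarityMatrix, SimilarityMatrix]] = {}
    rows = []
    for encoding in encodings:
        if encoding not in sims:
            sims[encoding] = compute_similarities(dataset, encoding, config.embedding)
        s_d, s_p = sims[encoding]
        for layer_plan in plans:
            enc_cfg = dataclasses.replace(
                config.encoder, layer_plan=tuple(layer_plan),
                hidden_dims=config.encoder.hidden_dims[: len(layer_plan)])
            if mode == "cv":
                _, rep = run_cross_validation(s_d, s_p, plan, enc_cfg, config.forest,
                                              extra_edges=dataset.interactions)
            else:
                scores, labels = run_fold(s_d, s_p, _cv_training_pairs(plan),
                                          plan.test_pairs, enc_cfg, config.forest,
                                          extra_edges=dataset.interactions)
                rep = score_report(scores, labels, seed=plan.seed)
            rows.append({
                "encoding": encoding,
                "layer_plan": "+".join(p.upper() for p in layer_plan),
                "roc_auc": rep.roc_auc,
                "pr_auc": rep.pr_auc,
                "f1": rep.f1,
                "accuracy": rep.accuracy,
                "recall": rep.recall,
            })
    return rows


def run_forest_sweep(
    config: PipelineConfig,
    tree_counts: tuple[int, ...] = (10, 50, 100, 200),
) -> list[dict]:
    """ROC/PR-AUC on the independent test split as a function of forest size.

    The split plan, similarities and encoder are fixed; only the forest is
    refit per tree count (mirroring a subtree-number sweep).
    """
    dataset = load_dataset(config)
    s_d, s_p = compute_similarities(dataset, config.drug_encoding, config.embedding)
    positives = sorted(dataset.interactions.edges)
    negatives = all_negative_pairs([d.drug_id for d in dataset.drugs],
                                   [p.protein_id for p in dataset.proteins],
                                   set(positives))
    plan = make_splits(positives, negatives, seed=config.split_seed)
    train_all = _cv_training_pairs(plan)
    table = InteractionTable(edges={p for p, y in train_all if y == 1})
    net = build_hetnet(s_d, s_p, table)
    F = node_features(net)
    model, _ = train_encoder(net, F, train_all, config.encoder)
    emb = encode(net, F, model)
    Z_train = fuse(emb, [p for p, _ in train_all])
    y_train = np.array([y for _, y in train_all])
    Z_test = fuse(emb, [p for p, _ in plan.test_pairs])
    labels = np.array([y for _, y in plan.test_pairs])
    rows = []
    for t in tree_counts:
        forest = fit_forest(Z_train, y_train,
                            dataclasses.replace(config.forest, n_trees=int(t)))
        rep = score_report(predict_scores(forest, Z_test), labels, seed=plan.seed)
        rows.append({"n_trees": int(t), "roc_auc": rep.roc_auc, "pr_auc": rep.pr_auc})
    return rows
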