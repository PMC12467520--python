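"""Training orchestration, cross-validated evaluation and biomarker ranking.

The pipeline is staged the way the model is deployed: per-subject
features are extracted first (volumetric extractor on structural and
temporally collapsed functional volumes, edge-sensitive pooling on each
atlas's brain graph), then the gated multimodal fusion and the
attention-pruned population-graph classifier are trained jointly and
transductively — all subjects sit in one graph, folds are loss masks.

Metrics are reported as percentages: accuracy, sensitivity, specificity
from the 0.5-thresholded confusion table and AUC from the ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .acfe import AcfeNetwork, AcfeParams, extract_embeddings
from .autodiff import Adam, Tensor, concat
from .brain_graph import EspmNetwork, EspmParams, build_atlas_graph
from .core_io import AtlasSpec, RunConfig, ValidationError, get_logger, log_stage
from .marl import FeatureBundle, MarlParams, marl_fuse
from .popgraph import (GatParams, PopulationGraph, build_population_graph,
                       compute_loss, encode_phenotypes, gat_forward_with_dagp)
from .synthetic import Cohort

__all__ = [
    "MetricReport", "CVReport", "ImportanceReport", "FoldDivergenceError",
    "confusion_metrics", "auc", "kfold_split", "extract_features",
    "train_model", "mc_dropout_predict", "rank_biomarkers",
]


class FoldDivergenceError(RuntimeError):
    """Training loss became non-finite within a fold."""


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Percentage metrics plus the confusion counts they derive from."""

    acc: float | None
    sen: float | None
    spe: float | None
    auc: float | None
    tp: int
    tn: int
    fp: int
    fn: int
    undefined: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_metrics(y: np.ndarray, y_hat: np.ndarray,
                      threshold: float = 0.5) -> MetricReport:
    """ACC/SEN/SPE from the confusion table; score ties go positive."""
    y = np.asarray(y).astype(int)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    pred = (y_hat >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    undefined: list[str] = []
    acc = 100.0 * (tp + tn) / len(y) if len(y) else None
    sen = spe = None
    if tp + fn > 0:
        sen = 100.0 * tp / (tp + fn)
    else:
        undefined.append("sen")
    if tn + fp > 0:
        spe = 100.0 * tn / (tn + fp)
    else:
        undefined.append("spe")
    auc_val = auc(y, y_hat) if len(np.unique(y)) == 2 else None
    if auc_val is None:
        undefined.append("auc")
    return MetricReport(acc=acc, sen=sen, spe=spe, auc=auc_val,
                        tp=tp, tn=tn, fp=fp, fn=fn, undefined=undefined)


def auc(y: np.ndarray, scores: np.ndarray) -> float | None:
    """Area under the ROC curve as a percentage; None if one class absent."""
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        get_logger().warning("AUC undefined: only one class present")
        return None
    return float(roc_auc_score(y, np.asarray(scores, dtype=np.float64)) * 100.0)


@dataclass
class CVReport:
    """Per-fold metrics with mean +/- SD aggregation."""

    folds: list[MetricReport]

    def _values(self, key: str) -> np.ndarray:
        vals = [getattr(f, key) for f in self.folds if getattr(f, key) is not None]
        return np.asarray(vals, dtype=np.float64)

    def mean(self, key: str) -> float:
        return float(self._values(key).mean())

    def sd(self, key: str) -> float:
        return float(self._values(key).std(ddof=1)) if len(self._values(key)) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [{"fold": i, "acc": f.acc, "sen": f.sen, "spe": f.spe,
                 "auc": f.auc, "tp": f.tp, "tn": f.tn, "fp": f.fp, "fn": f.fn}
                for i, f in enumerate(self.folds)]
        summary = {"fold": "mean±sd"}
        for key in ("acc", "sen", "spe", "auc"):
            summary[key] = f"{self.mean(key):.2f}±{self.sd(key):.2f}"
        rows.append(summary)
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Cross-validation folds
# --------------------------------------------------------------------------

def kfold_split(labels: np.ndarray, k: int = 10, seed: int = 0
                ) -> list[np.ndarray]:
    """Stratified k-fold test masks; unstratified fallback for tiny classes."""
    labels = np.asarray(labels).astype(int)
    n = len(labels)
    if n < k:
        raise ValidationError(f"cannot split {n} subjects into {k} folds")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        warnings.warn("a class is smaller than the fold count; "
                      "degrading to unstratified folds", stacklevel=2)
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n))
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(np.zeros(n), labels)
    masks = []
    for _, test_idx in split_iter:
        mask = np.zeros(n, dtype=bool)
        mask[test_idx] = True
        masks.append(mask)
    return masks


# --------------------------------------------------------------------------
# Feature extraction (per-subject, ahead of graph training)
# --------------------------------------------------------------------------

@dataclass
class ExtractedFeatures:
    bundle: FeatureBundle
    alphas: dict[str, np.ndarray]        # atlas -> n_subjects x n_nodes
    atlases: list[AtlasSpec]


def extract_features(cohort: Cohort, config: RunConfig) -> ExtractedFeatures:
    """Run the volumetric and brain-graph feature stages over a cohort."""
    modalities: list[str] = []
    features: dict[str, np.ndarray] = {}
    n = len(cohort.records)
    if config.use_acfe:
        acfe_params = AcfeParams(
            n_blocks=len(config.acfe_channels), channels=config.acfe_channels,
            kernel=config.acfe_kernel, reduction_ratio=config.reduction_ratio,
            spatial_kernel=config.spatial_kernel, pooled_grid=config.pooled_grid,
            out_dim=config.embed_dim, use_channel_attn=config.use_channel_attn,
            use_spatial_attn=config.use_spatial_attn,
            use_residual=config.use_residual)
        net_s = AcfeNetwork.init(acfe_params, seed=config.seed)
        net_f = net_s if config.share_acfe_weights else \
            AcfeNetwork.init(acfe_params, seed=config.seed + 1)
        with log_stage("acfe_smri", seed=config.seed, config_hash=config.hash()):
            features["smri"] = extract_embeddings(net_s, cohort.smri,
                                                  batch_size=config.batch_size)
        collapsed = (cohort.fmri.std(axis=-1) if config.fmri_collapse == "std"
                     else cohort.fmri.mean(axis=-1))
        with log_stage("acfe_fmri", seed=config.seed, config_hash=config.hash()):
            features["fmri"] = extract_embeddings(net_f, collapsed,
                                                  batch_size=config.batch_size)
        modalities += ["smri", "fmri"]

    alphas: dict[str, np.ndarray] = {}
    for a_idx, atlas in enumerate(cohort.atlases):
        espm = EspmNetwork.init(
            EspmParams(in_dim=atlas.n_nodes, hidden=config.espm_hidden,
                       post_hidden=config.espm_hidden, out_dim=config.embed_dim),
            seed=config.seed + 100 + a_idx)
        emb = np.empty((n, config.embed_dim))
        alpha = np.empty((n, atlas.n_nodes))
        with log_stage(f"espm_{atlas.name}", seed=config.seed,
                       config_hash=config.hash()):
            for i in range(n):
                g = build_atlas_graph(cohort.timeseries[atlas.name][i], atlas,
                                      knn_k=config.knn_k,
                                      subject_id=cohort.records[i].subject_id)
                emb[i], alpha[i] = espm.embed(g, prune=config.use_espm)
        features[atlas.name] = emb
        alphas[atlas.name] = alpha
        modalities.append(atlas.name)
    bundle = FeatureBundle(features=features, modalities=tuple(modalities))
    return ExtractedFeatures(bundle=bundle, alphas=alphas,
                             atlases=list(cohort.atlases))


# --------------------------------------------------------------------------
# Model wrapper and training
# --------------------------------------------------------------------------

@dataclass
class FoldModel:
    """One fold's trained parameters plus everything needed to re-forward."""

    marl: MarlParams
    gat: GatParams
    bundle: FeatureBundle
    graph: PopulationGraph
    phenotypes: np.ndarray
    config: RunConfig

    def _node_features(self) -> Tensor:
        fused = marl_fuse(self.bundle, self.marl, enabled=self.config.use_marl)
        if self.config.popgraph_mode == "features":
            return fused
        pheno = Tensor(self.phenotypes)
        if self.config.popgraph_mode == "phenotypes":
            return pheno
        return concat([fused, pheno], axis=1)

    def forward(self, rng: np.random.Generator | None = None):
        """Predicted probabilities; pass an rng to activate dropout."""
        x = self._node_features()
        return gat_forward_with_dagp(self.graph, self.gat,
                                     prune_percent=self.config.prune_percent,
                                     rng=rng, x=x)

    def predict(self, rng: np.random.Generator | None = None,
                passes: int | None = None) -> np.ndarray:
        """Predictive mean over Monte Carlo dropout passes.

        The classifier is trained with dropout active, so the model's
        calibrated output is the dropout predictive mean rather than the
        single deterministic forward (which systematically shrinks the
        logits the stochastic layers were trained to produce).
        """
        passes = passes if passes is not None else self.config.mc_passes
        rng = rng or np.random.default_rng(0)
        draws = np.empty((passes, self.graph.n_nodes))
        for t in range(passes):
            draws[t] = self.forward(rng=rng)[0].data
        return draws.mean(axis=0)

    def parameters(self) -> list[Tensor]:
        params = list(self.gat.parameters())
        if self.config.use_marl:
            params += self.marl.parameters()
        else:
            params += [self.marl.tensors["fuse_w"], self.marl.tensors["fuse_b"]]
        return params

    def weight_matrices(self) -> list[Tensor]:
        return self.marl.weight_matrices() + self.gat.weight_matrices()


@dataclass
class TrainResult:
    report: CVReport
    history: list[list[float]]            # per-fold training loss per epoch
    predictions: pd.DataFrame             # subject_id, y_hat, label, fold
    alphas: dict[str, np.ndarray]
    atlases: list[AtlasSpec]
    last_model: FoldModel
    fused_embeddings: np.ndarray          # last fold's trained fusion output


def _bce(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-7, 1 - 1e-7)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).sum())


def _identity_graph(n: int, x: np.ndarray, labels: np.ndarray,
                    ids: list[str]) -> PopulationGraph:
    return PopulationGraph(x=x, adjacency=np.zeros((n, n)), labels=labels,
                           subject_ids=ids)


def _val_split(train_mask: np.ndarray, labels: np.ndarray,
               rng: np.random.Generator, frac: float = 0.1) -> np.ndarray:
    """Carve a stratified validation mask out of the training mask."""
    val = np.zeros_like(train_mask)
    for cls in np.unique(labels[train_mask]):
        idx = np.nonzero(train_mask & (labels == cls))[0]
        n_val = max(1, int(round(frac * len(idx))))
        val[rng.choice(idx, size=n_val, replace=False)] = True
    return val


def train_model(cohort: Cohort, config: RunConfig,
                features: ExtractedFeatures | None = None) -> TrainResult:
    """Cross-validated transductive training of the fusion + graph classifier.

    Features are extracted once (they are label-free forward passes);
    each fold re-initialises and trains the fusion module and classifier
    with Adam on the masked loss, early-stopping on a held-out slice of
    the training mask.
    """
    logger = get_logger()
    if features is None:
        features = extract_features(cohort, config)
    bundle = features.bundle
    labels = cohort.labels
    ids = [r.subject_id for r in cohort.records]
    phenotypes = encode_phenotypes(cohort.records)
    masks = kfold_split(labels, k=config.folds, seed=config.seed)

    fold_reports: list[MetricReport] = []
    history: list[list[float]] = []
    pred_rows = []
    last_model: FoldModel | None = None
    for fold, test_mask in enumerate(masks):
        fold_seed = (config.seed * 1009 + fold) % (2 ** 31)
        rng = np.random.default_rng(fold_seed)
        marl = MarlParams.init(dim=bundle.dim, fusion_dim=config.fusion_dim,
                               modalities=bundle.modalities,
                               scalar_gate=config.scalar_gate, seed=fold_seed)
        fused0 = marl_fuse(bundle, marl, enabled=config.use_marl).data
        if config.use_papg:
            graph = build_population_graph(cohort.records, fused0,
                                           th=config.similarity_threshold,
                                           mode=config.popgraph_mode)
        else:
            graph = _identity_graph(len(labels), fused0, labels, ids)
        pheno_width = phenotypes.shape[1]
        in_dim = {"both": config.fusion_dim + pheno_width,
                  "features": config.fusion_dim,
                  "phenotypes": pheno_width}[config.popgraph_mode]
        gat = GatParams.init(in_dim=in_dim, hidden=config.gat_hidden,
                             heads=config.gat_heads, out_dim=config.gat_out_dim,
                             leaky_slope=config.leaky_slope,
                             dropout=config.dropout, seed=fold_seed + 1)
        model = FoldModel(marl=marl, gat=gat, bundle=bundle, graph=graph,
                          phenotypes=phenotypes, config=config)

        train_mask = ~test_mask
        val_mask = _val_split(train_mask, labels, rng)
        fit_mask = train_mask & ~val_mask
        opt = Adam(model.parameters(), lr=config.lr)
        best_val = np.inf
        best_state = [p.data.copy() for p in model.parameters()]
        patience_left = config.patience
        losses: list[float] = []
        with log_stage(f"fold{fold}_train", seed=fold_seed,
                       config_hash=config.hash()):
            for epoch in range(config.epochs):
                y_hat, _ = model.forward(rng=rng)
                loss = compute_loss(labels, y_hat, model.weight_matrices(),
                                    lam=config.weight_decay, mask=fit_mask)
                if not np.isfinite(loss.data):
                    raise FoldDivergenceError(
                        f"fold {fold}: non-finite loss at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
                # validation every 2nd epoch on the Monte Carlo predictive
                # mean (the model's calibrated output; see FoldModel.predict)
                if epoch % 2 == 1 or epoch == config.epochs - 1:
                    y_val = model.predict(
                        rng=np.random.default_rng([fold_seed % 10_000, epoch]),
                        passes=4)
                    val_loss = _bce(labels[val_mask], y_val[val_mask])
                    if val_loss < best_val - 1e-6:
                        best_val = val_loss
                        best_state = [p.data.copy() for p in model.parameters()]
                        patience_left = config.patience
                    elif epoch + 1 >= config.min_epochs:
                        patience_left -= 2
                        if patience_left <= 0:
                            break
        for p, s in zip(model.parameters(), best_state):
            p.data = s
        y_pred = model.predict(rng=np.random.default_rng(fold_seed + 7),
                               passes=config.mc_passes)
        rep = confusion_metrics(labels[test_mask], y_pred[test_mask])
        fold_reports.append(rep)
        history.append(losses)
        logger.info("fold=%d epochs=%d acc=%s auc=%s", fold, len(losses),
                    f"{rep.acc:.2f}" if rep.acc is not None else "NA",
                    f"{rep.auc:.2f}" if rep.auc is not None else "NA")
        for i in np.nonzero(test_mask)[0]:
            pred_rows.append({"subject_id": ids[i], "y_hat": float(y_pred[i]),
                              "label": int(labels[i]), "fold": fold})
        last_model = model

    fused_final = marl_fuse(bundle, last_model.marl,
                            enabled=config.use_marl).data
    return TrainResult(report=CVReport(fold_reports), history=history,
                       predictions=pd.DataFrame(pred_rows),
                       alphas=features.alphas, atlases=features.atlases,
                       last_model=last_model, fused_embeddings=fused_final)


# --------------------------------------------------------------------------
# Monte Carlo dropout uncertainty
# --------------------------------------------------------------------------

def mc_dropout_predict(model: FoldModel, passes: int = 20,
                       rng: np.random.Generator | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean and SD over stochastic forward passes with dropout on."""
    if passes < 2:
        raise ValidationError("Monte Carlo dropout needs at least 2 passes")
    rng = rng or np.random.default_rng(0)
    draws = np.empty((passes, model.graph.n_nodes))
    for t in range(passes):
        y_hat, _ = model.forward(rng=rng)
        draws[t] = y_hat.data
    return draws.mean(axis=0), draws.std(axis=0)


# --------------------------------------------------------------------------
# Biomarker ranking
# --------------------------------------------------------------------------

@dataclass
class ImportanceReport:
    """ROI importance aggregated over subjects, globally ranked."""

    table: pd.DataFrame                 # atlas, roi_index, roi_label, mean_alpha, rank

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.table.nsmallest(k, "rank").reset_index(drop=True)


def rank_biomarkers(alphas: dict[str, np.ndarray], atlases: list[AtlasSpec],
                    k: int = 10) -> ImportanceReport:
    """Average node importance per ROI, ranked descending across atlases.

    The appended average-signal node is excluded; ties break toward the
    lower ROI index (within the atlas iteration order) for determinism.
    """
    rows = []
    for atlas in atlases:
        alpha = np.asarray(alphas[atlas.name], dtype=np.float64)
        if alpha.shape[1] != atlas.n_nodes:
            raise ValidationError(
                f"alpha width {alpha.shape[1]} != node count {atlas.n_nodes} "
                f"for atlas {atlas.name}")
        mean_alpha = alpha.mean(axis=0)[:atlas.n_regions]   # drop average node
        for i, label in enumerate(atlas.region_labels):
            rows.append({"atlas": atlas.name, "roi_index": i, "roi_label": label,
                         "mean_alpha": float(mean_alpha[i])})
    table = pd.DataFrame(rows)
    if k > len(table):
        warnings.warn(f"k={k} exceeds ROI count {len(table)}; clamping",
                      stacklevel=2)
        k = len(table)
    order = np.argsort(-table["mean_alpha"].to_numpy(), kind="stable")
    rank = np.empty(len(table), dtype=int)
    rank[order] = np.arange(1, len(table) + 1)
    table["rank"] = rank
    return ImportanceReport(table=table.sort_values("rank").reset_index(drop=True))
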