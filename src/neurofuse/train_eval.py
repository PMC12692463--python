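"""Training loop, cross-validation protocols, metrics, and embedding export.

Protocols implemented:

* ``train`` — seeded mini-batch AdamW optimization of the adversarial
  objective, with per-epoch loss/accuracy history.
* ``kfold_cv`` — stratified k-fold cross-validation (default k=5) with
  normalization statistics fitted on each training split.
* ``loso_cv`` — leave-one-site-out: each site in turn is the held-out test
  set; inside the test site the majority diagnosis class is randomly
  down-sampled (seeded, without replacement) to the minority count before
  evaluation, so per-site accuracy is chance-corrected by construction.
* ``compute_metrics`` — confusion-matrix metrics (accuracy, recall,
  precision, F1, balanced accuracy, FPR/TPR) plus AUC via the Mann–Whitney
  rank statistic with midrank tie handling.
* ``export_embeddings`` / ``tsne_embed`` — per-subject fused-embedding table
  and its seeded 2-D t-SNE projection for site-mixing visualization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.manifold import TSNE
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .autodiff import Tensor
from .heads import cross_entropy, total_loss
from .io_data import normalize_gmv, normalize_timeseries, pad_and_mask
from .model import ModelConfig, MultimodalNet
from .nn import AdamW
from .synthetic import CohortArrays

__all__ = ["TrainConfig", "MetricsReport", "train", "evaluate", "kfold_cv",
           "loso_cv", "compute_metrics", "export_embeddings", "tsne_embed",
           "site_probe_accuracy"]


@dataclass
class TrainConfig:
    """Optimization protocol.

    Defaults follow the full-scale protocol (AdamW, μ=5e-5, batch 16,
    50 epochs, 5-fold CV, β=0.1).  ``desk_scale`` returns the compact
    protocol used for the bundled synthetic cohorts, where 5e-5 over a few
    hundred samples would barely move the weights.
    """

    lr: float = 5e-5
    weight_decay: float = 0.01
    batch_size: int = 16
    epochs: int = 50
    beta: float = 0.1
    k_folds: int = 5
    clip_norm: float | None = 5.0
    seed: int = 0
    # Adversarial inner maximization: before each epoch the affine site head
    # is refit to (near-)optimality on the current fused embeddings, so the
    # reversed gradient pushes features against a strong adversary rather
    # than a lagging one.  The per-batch updates themselves keep the exact
    # coupled min-max semantics.  Set False for plain alternating updates.
    site_head_refit: bool = True
    grl_strength: float = 1.0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")

    @classmethod
    def desk_scale(cls, epochs: int = 16, seed: int = 0,
                   beta: float = 0.1) -> "TrainConfig":
        return cls(lr=1e-3, batch_size=32, epochs=epochs, beta=beta,
                   seed=seed)


@dataclass
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    recall: float
    precision: float
    f1: float
    balanced_accuracy: float
    fpr: float
    tpr: float
    auc: float | None

    def validate(self, tol: float = 1e-12) -> None:
        """Each derived metric must match its formula recomputed from the
        stored counts."""
        tp, tn, fp, fn = self.tp, self.tn, self.fp, self.fn
        n = tp + tn + fp + fn
        checks = {
            "accuracy": (tp + tn) / n,
            "recall": tp / (tp + fn) if tp + fn else 0.0,
            "precision": tp / (tp + fp) if tp + fp else 0.0,
            "fpr": fp / (fp + tn) if fp + tn else 0.0,
            "tpr": tp / (tp + fn) if tp + fn else 0.0,
        }
        checks["balanced_accuracy"] = 0.5 * (checks["recall"]
                                             + (tn / (tn + fp)
                                                if tn + fp else 0.0))
        pr, rc = checks["precision"], checks["recall"]
        checks["f1"] = 2 * pr * rc / (pr + rc) if pr + rc else 0.0
        for name, value in checks.items():
            if abs(getattr(self, name) - value) > tol:
                raise AssertionError(f"{name} inconsistent with counts")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("tp", "tn", "fp", "fn", "accuracy", "recall", "precision",
                 "f1", "balanced_accuracy", "fpr", "tpr", "auc")}


def _rank_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the Mann–Whitney U statistic with midranks for ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    ranks = rankdata(scores, method="average")
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(labels: np.ndarray, scores: np.ndarray | None = None,
                    predicted: np.ndarray | None = None,
                    threshold: float = 0.5) -> MetricsReport:
    """Confusion-matrix metrics from labels and positive-class scores.

    Predictions default to thresholding the scores at 0.5.  With a single
    class present the AUC is undefined and reported as None.
    """
    labels = np.asarray(labels)
    if predicted is None:
        if scores is None:
            raise ValueError("need scores or predicted labels")
        predicted = (np.asarray(scores) >= threshold).astype(int)
    predicted = np.asarray(predicted)
    if len(predicted) != len(labels):
        raise ValueError("labels and predictions must have equal length")
    tp = int(((labels == 1) & (predicted == 1)).sum())
    tn = int(((labels == 0) & (predicted == 0)).sum())
    fp = int(((labels == 0) & (predicted == 1)).sum())
    fn = int(((labels == 1) & (predicted == 0)).sum())
    n = len(labels)
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    auc = None
    if scores is not None and len(np.unique(labels)) == 2:
        auc = _rank_auc(labels, scores)
    elif scores is not None:
        warnings.warn("single-class labels: AUC undefined", stacklevel=2)
    report = MetricsReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=(tp + tn) / n,
        recall=recall,
        precision=precision,
        f1=(2 * precision * recall / (precision + recall)
            if precision + recall else 0.0),
        balanced_accuracy=0.5 * (recall + specificity),
        fpr=fp / (fp + tn) if fp + tn else 0.0,
        tpr=recall,
        auc=auc)
    report.validate()
    return report


# --------------------------------------------------------------------- dataset
@dataclass
class _Prepared:
    """Normalized, index-addressable view of a cohort."""

    ts: list[np.ndarray]
    gmv: np.ndarray
    labels: np.ndarray
    sites: np.ndarray

    def batch(self, idx: np.ndarray):
        ts_batch = pad_and_mask([self.ts[i] for i in idx])
        return ts_batch, self.gmv[idx], self.labels[idx], self.sites[idx]


def _prepare(cohort: CohortArrays, train_idx: np.ndarray) -> _Prepared:
    ts, _ = normalize_timeseries(cohort.ts, train_idx=list(train_idx))
    gmv, _ = normalize_gmv(cohort.gmv, train_idx=list(train_idx))
    return _Prepared(ts=ts, gmv=gmv, labels=cohort.labels,
                     sites=cohort.sites)


def _bucketed_batches(train_idx: np.ndarray, lengths: np.ndarray,
                      batch_size: int, rng: np.random.Generator
                      ) -> list[np.ndarray]:
    """Random batches bucketed by sequence length.

    Indices are shuffled, then stably sorted by length so each mini-batch
    pads to roughly its own scan length rather than the cohort maximum;
    batch order is shuffled again.  This changes only the grouping of the
    stochastic updates, not the data seen per epoch.
    """
    perm = rng.permutation(len(train_idx))
    order = perm[np.argsort(lengths[perm], kind="stable")]
    shuffled = train_idx[order]
    batches = [shuffled[s:s + batch_size]
               for s in range(0, len(shuffled), batch_size)]
    return [batches[i] for i in rng.permutation(len(batches))]


# -------------------------------------------------------------------- training
def train(cohort: CohortArrays, model_config: ModelConfig,
          train_config: TrainConfig,
          train_idx: np.ndarray | None = None,
          prepared: _Prepared | None = None
          ) -> tuple[MultimodalNet, pd.DataFrame]:
    """Fit the model on (a subset of) a cohort; returns model + history.

    Deterministic given the seed: model initialization, batch order and
    dropout all derive from ``train_config.seed``.
    """
    if train_idx is None:
        train_idx = np.arange(len(cohort))
    train_idx = np.asarray(train_idx)
    labels = cohort.labels[train_idx]
    sites = cohort.sites[train_idx]
    beta = train_config.beta if model_config.use_grl else 0.0
    if beta > 0 and np.unique(sites).size < 2:
        raise ValueError("beta > 0 requires at least two training sites")
    if np.unique(labels).size < 2:
        raise ValueError("training data must contain both classes")

    if prepared is None:
        prepared = _prepare(cohort, train_idx)
    model = MultimodalNet(model_config, seed=train_config.seed)
    opt = AdamW(model.parameters(), lr=train_config.lr,
                weight_decay=train_config.weight_decay,
                clip_norm=train_config.clip_norm)
    rng = np.random.default_rng(train_config.seed + 1)
    lengths = np.array([prepared.ts[i].shape[0] for i in train_idx])
    history = []
    adversarial = model.site_head is not None and beta > 0
    if adversarial:
        model.site_head.grl_strength = train_config.grl_strength
    for epoch in range(train_config.epochs):
        if adversarial and train_config.site_head_refit and epoch >= 1:
            _refit_site_head(model, prepared, train_idx)
        batches = _bucketed_batches(train_idx, lengths,
                                    train_config.batch_size, rng)
        ep_ld, ep_ls, ep_obj, n_correct, n_seen = 0.0, 0.0, 0.0, 0, 0
        for idx in batches:
            if len(idx) < 2:
                continue  # batch norm needs > 1 sample
            ts_batch, gmv, y, site = prepared.batch(idx)
            out = model(ts_batch, gmv)
            l_d = cross_entropy(out.disease_logits, y)
            if model.site_head is not None and beta > 0:
                l_s = cross_entropy(out.site_logits, site)
            else:
                l_s = Tensor(0.0)
            bundle = total_loss(l_d, l_s, beta)
            opt.zero_grad()
            bundle.total.backward()
            opt.step()
            ep_ld += float(l_d.data) * len(idx)
            ep_ls += float(l_s.data) * len(idx)
            ep_obj += bundle.reported_objective * len(idx)
            n_correct += int((out.disease_logits.data.argmax(axis=1) == y).sum())
            n_seen += len(idx)
        history.append({"epoch": epoch,
                        "loss_disease": ep_ld / n_seen,
                        "loss_site": ep_ls / n_seen,
                        "reported_objective": ep_obj / n_seen,
                        "train_accuracy": n_correct / n_seen})
    return model, pd.DataFrame(history)


def embed_fusion(model: MultimodalNet, prepared: _Prepared,
                 idx: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Eval-mode fused embeddings z_fusion for the given subjects."""
    model.eval()
    blocks = []
    for start in range(0, len(idx), batch_size):
        ts_batch, gmv, _, _ = prepared.batch(idx[start:start + batch_size])
        blocks.append(model(ts_batch, gmv).z_fusion.data)
    model.train()
    return np.concatenate(blocks)


def _refit_site_head(model: MultimodalNet, prepared: _Prepared,
                     train_idx: np.ndarray) -> None:
    """Solve the adversary's inner maximization: fit the affine site head
    to the current embeddings with a multinomial logistic regression."""
    z = embed_fusion(model, prepared, train_idx)
    sites = prepared.sites[train_idx]
    with warnings.catch_warnings():
        # near-optimal is sufficient for the adversary; don't surface
        # lbfgs iteration-cap warnings to callers every epoch
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf = LogisticRegression(max_iter=500).fit(z, sites)
    coef, intercept = clf.coef_, clf.intercept_
    if coef.shape[0] == 1:  # sklearn collapses the two-class case
        coef = np.vstack([-coef / 2, coef / 2])
        intercept = np.r_[-intercept / 2, intercept / 2]
    weight = np.zeros_like(model.site_head.linear.weight.data)
    bias = np.zeros_like(model.site_head.linear.bias.data)
    weight[:, clf.classes_] = coef.T
    bias[clf.classes_] = intercept
    model.site_head.linear.weight.data = weight
    model.site_head.linear.bias.data = bias


def predict_scores(model: MultimodalNet, prepared: _Prepared,
                   idx: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Positive-class (MDD) probabilities for the given subjects."""
    model.eval()
    scores = []
    for start in range(0, len(idx), batch_size):
        sub = idx[start:start + batch_size]
        ts_batch, gmv, _, _ = prepared.batch(sub)
        logits = model(ts_batch, gmv).disease_logits.data
        z = logits - logits.max(axis=1, keepdims=True)
        p = np.exp(z)
        p /= p.sum(axis=1, keepdims=True)
        scores.append(p[:, 1])
    model.train()
    return np.concatenate(scores)


def evaluate(model: MultimodalNet, prepared: _Prepared,
             idx: np.ndarray) -> MetricsReport:
    scores = predict_scores(model, prepared, idx)
    return compute_metrics(prepared.labels[idx], scores=scores)


def kfold_cv(cohort: CohortArrays, model_config: ModelConfig,
             train_config: TrainConfig
             ) -> tuple[list[MetricsReport], pd.DataFrame]:
    """Stratified k-fold cross-validation over diagnosis labels."""
    skf = StratifiedKFold(n_splits=train_config.k_folds, shuffle=True,
                          random_state=train_config.seed)
    reports = []
    for fold, (tr, te) in enumerate(
            skf.split(np.zeros(len(cohort)), cohort.labels)):
        if np.unique(cohort.labels[te]).size < 2:
            raise ValueError(f"fold {fold} lost a class during stratification")
        prepared = _prepare(cohort, tr)
        model, _ = train(cohort, model_config, train_config, train_idx=tr,
                         prepared=prepared)
        reports.append(evaluate(model, prepared, te))
    rows = [r.as_dict() for r in reports]
    df = pd.DataFrame(rows)
    summary = pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})
    return reports, summary


def balanced_test_indices(labels: np.ndarray, idx: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Down-sample the majority class within ``idx`` to the minority count,
    without replacement."""
    idx = np.asarray(idx)
    pos = idx[labels[idx] == 1]
    neg = idx[labels[idx] == 0]
    k = min(len(pos), len(neg))
    pos = rng.choice(pos, size=k, replace=False)
    neg = rng.choice(neg, size=k, replace=False)
    return np.sort(np.concatenate([pos, neg]))


def loso_cv(cohort: CohortArrays, model_config: ModelConfig,
            train_config: TrainConfig) -> pd.DataFrame:
    """Leave-one-site-out evaluation with majority-class down-sampling.

    For each site: train on all remaining sites, balance the held-out site's
    class counts by seeded down-sampling, evaluate.  Sites whose held-out
    set contains a single class are skipped with a warning.
    """
    sites = np.unique(cohort.sites)
    if sites.size < 3:
        raise ValueError("leave-one-site-out needs at least three sites")
    rng = np.random.default_rng(train_config.seed + 7919)
    rows = []
    for s in sites:
        te = np.where(cohort.sites == s)[0]
        tr = np.where(cohort.sites != s)[0]
        assert not np.intersect1d(tr, te).size
        if np.unique(cohort.labels[te]).size < 2:
            warnings.warn(f"site {s} has a single class; skipped",
                          stacklevel=2)
            continue
        te_bal = balanced_test_indices(cohort.labels, te, rng)
        prepared = _prepare(cohort, tr)
        model, _ = train(cohort, model_config, train_config, train_idx=tr,
                         prepared=prepared)
        report = evaluate(model, prepared, te_bal)
        row = {"site": int(s), "n_test": len(te_bal),
               "n_mdd": int(cohort.labels[te_bal].sum()),
               "n_hc": int((1 - cohort.labels[te_bal]).sum())}
        row.update(report.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ embeddings
def export_embeddings(model: MultimodalNet, cohort: CohortArrays,
                      prepared: _Prepared | None = None,
                      batch_size: int = 64) -> pd.DataFrame:
    """Per-subject fused-embedding table (id, site, label, z_fusion...)."""
    if prepared is None:
        prepared = _prepare(cohort, np.arange(len(cohort)))
    model.eval()
    blocks = []
    all_idx = np.arange(len(cohort))
    for start in range(0, len(cohort), batch_size):
        idx = all_idx[start:start + batch_size]
        ts_batch, gmv, _, _ = prepared.batch(idx)
        blocks.append(model(ts_batch, gmv).z_fusion.data)
    model.train()
    z = np.concatenate(blocks)
    df = pd.DataFrame(z, columns=[f"z{j}" for j in range(z.shape[1])])
    df.insert(0, "subject_id", [r.subject_id for r in cohort.records])
    df.insert(1, "site_id", cohort.sites)
    df.insert(2, "label", cohort.labels)
    return df


def tsne_embed(embedding_table: pd.DataFrame, perplexity: float = 30.0,
               seed: int = 0) -> pd.DataFrame:
    """Seeded 2-D t-SNE of an exported embedding table."""
    z_cols = [c for c in embedding_table.columns if c.startswith("z")]
    z = embedding_table[z_cols].to_numpy()
    perplexity = min(perplexity, (len(z) - 1) / 3.0)
    coords = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                  init="pca").fit_transform(z)
    out = embedding_table[["subject_id", "site_id", "label"]].copy()
    out["tsne1"], out["tsne2"] = coords[:, 0], coords[:, 1]
    return out


def site_probe_accuracy(features: np.ndarray, site_ids: np.ndarray,
                        seed: int = 0, k_folds: int = 5) -> float:
    """Cross-validated accuracy of a post-hoc linear site classifier.

    A multinomial logistic regression trained on frozen features; used to
    measure how much linearly decodable site information survives in an
    embedding (chance = 1/S for balanced sites).
    """
    clf = LogisticRegression(max_iter=2000)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    scores = cross_val_score(clf, np.asarray(features), np.asarray(site_ids),
                             cv=skf, scoring="accuracy")
    return float(scores.mean())
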