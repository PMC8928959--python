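"""Orchestration: repeated trials, ablation grids, independent-set
evaluation, and frozen-autoencoder baselines.

Every entry point is deterministic given its base seed: trial ``t`` of a
repeated run uses ``base_seed + t``, and all aggregates are recomputable
from the stored per-trial records.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import _nn
from .cksaap import CksaapConfig, encode_dataset
from .latent import pca1d_gcnr
from .metrics import (MetricReport, aggregate_reports, compute_confusion,
                      compute_metrics, mse_db, pr_auc, roc_auc)
from .model import DeepLSE, DeepLSEResults, ModelConfig
from .seqio import LabeledDataset, ProteinRecord, validate_records

__all__ = [
    "TrialOutcome",
    "AblationResult",
    "run_trials",
    "run_ablation",
    "evaluate_independent",
    "tally_outcomes",
    "baseline_ae_comparison",
]

_EXTRA_METRICS = ("roc_auc", "pr_auc", "mse_db")


@dataclass(frozen=True)
class TrialOutcome:
    """One training trial: seed, full metric dict, fitted results."""

    seed: int
    metrics: dict[str, float]
    results: Optional[DeepLSEResults] = None


def _evaluate_trial(results: DeepLSEResults, X_test: np.ndarray, y_test: np.ndarray) -> dict[str, float]:
    proba, pred = results.predict(X_test)
    report = compute_metrics(compute_confusion(y_test, pred))
    out = report.as_dict()
    out["roc_auc"] = roc_auc(y_test, proba[:, 1])
    out["pr_auc"] = pr_auc(y_test, proba[:, 1])
    out["mse_db"] = results.reconstruction_db(X_test)
    return out


def run_trials(X_train: np.ndarray, y_train: np.ndarray, X_test: np.ndarray,
               y_test: np.ndarray, config: ModelConfig, n_trials: int,
               base_seed: int, keep_models: bool = False) -> tuple[list[TrialOutcome], dict]:
    """Repeat training ``n_trials`` times with seeds ``base_seed + t``.

    Returns the per-trial outcomes and the mean/std aggregate per metric
    (undefined metrics are skipped with a count).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    trials = []
    for t in range(n_trials):
        seed = base_seed + t
        results = DeepLSE(X_train, y_train, replace(config, seed=seed)).fit()
        trials.append(TrialOutcome(
            seed=seed,
            metrics=_evaluate_trial(results, X_test, np.asarray(y_test)),
            results=results if keep_models else None,
        ))
    aggregate = aggregate_reports([t.metrics for t in trials])
    return trials, aggregate


@dataclass
class AblationResult:
    """Grid of per-cell aggregates over repeated trials.

    ``cells[(k, LV)]`` holds the per-trial metric dicts and their
    aggregate; ``best_cell`` maximises mean balanced accuracy with ties
    broken toward smaller k, then smaller LV.
    """

    cells: dict[tuple[int, int], dict]
    n_trials: int
    N: int
    base_seed: int

    @property
    def best_cell(self) -> tuple[int, int]:
        def key(cell):
            k, lv = cell
            mean = self.cells[cell]["aggregate"]["balanced_accuracy"]["mean"]
            return (-mean, k, lv)

        return min(self.cells, key=key)

    def table(self, metric: str = "balanced_accuracy") -> pd.DataFrame:
        """Mean +/- std matrix, rows k, columns LV."""
        ks = sorted({k for k, _ in self.cells})
        lvs = sorted({lv for _, lv in self.cells})
        data = {}
        for lv in lvs:
            col = []
            for k in ks:
                agg = self.cells[(k, lv)]["aggregate"][metric]
                col.append(f"{agg['mean']:.3f}±{agg['std']:.3f}")
            data[lv] = col
        df = pd.DataFrame(data, index=ks)
        df.index.name = "k"
        df.columns.name = "LV"
        return df

    def mean_surface(self, metric: str = "balanced_accuracy") -> pd.DataFrame:
        ks = sorted({k for k, _ in self.cells})
        lvs = sorted({lv for _, lv in self.cells})
        arr = [[self.cells[(k, lv)]["aggregate"][metric]["mean"] for lv in lvs] for k in ks]
        return pd.DataFrame(arr, index=pd.Index(ks, name="k"), columns=pd.Index(lvs, name="LV"))

    def trial_frame(self) -> pd.DataFrame:
        """Flat per-trial records from which every aggregate is recomputable."""
        rows = []
        for (k, lv), cell in self.cells.items():
            for trial in cell["trials"]:
                rows.append({"k": k, "LV": lv, "seed": trial["seed"], **trial["metrics"]})
        return pd.DataFrame(rows)


def run_ablation(train_set: LabeledDataset, test_set: LabeledDataset,
                 k_values: Sequence[int], lv_values: Sequence[int], N: int,
                 n_trials: int, base_seed: int,
                 config: Optional[ModelConfig] = None) -> AblationResult:
    """Sweep the (k, LV) grid, encoding once per k and training
    ``n_trials`` models per cell with seeds ``base_seed + t``."""
    if not k_values or not lv_values:
        raise ValueError("k_values and lv_values must be non-empty")
    base = config if config is not None else ModelConfig(N=N)
    cells: dict[tuple[int, int], dict] = {}
    for k in k_values:
        cc = CksaapConfig(k=k)
        X_tr, y_tr, _ = encode_dataset(train_set, cc)
        X_te, y_te, _ = encode_dataset(test_set, cc)
        for lv in lv_values:
            cfg = replace(base, N=N, k=k, LV=lv)
            trials, aggregate = run_trials(X_tr, y_tr, X_te, y_te, cfg, n_trials, base_seed)
            cells[(k, lv)] = {
                "trials": [{"seed": t.seed, "metrics": t.metrics} for t in trials],
                "aggregate": aggregate,
            }
    return AblationResult(cells=cells, n_trials=n_trials, N=N, base_seed=base_seed)


def evaluate_independent(results: DeepLSEResults, records: Sequence[ProteinRecord],
                         k: Optional[int] = None) -> dict:
    """Predict a set of known-positive proteins and tally correctness.

    Returns a per-record table (id, predicted label, correct) plus the
    correct/total count and accuracy.
    """
    records = validate_records(list(records))
    if not records:
        raise ValueError("no records to evaluate")
    use_k = results.config.k if k is None else k
    if use_k != results.config.k:
        raise ValueError(f"requested k={use_k} but the model was trained with k={results.config.k}")
    X, _, ids = encode_dataset(records, CksaapConfig(k=use_k))
    _, pred = results.predict(X)
    table = pd.DataFrame({"id": ids, "predicted": pred, "correct": pred == 1})
    correct = int(table["correct"].sum())
    return {
        "table": table,
        "correct": correct,
        "total": len(records),
        "accuracy": correct / len(records),
    }


def tally_outcomes(outcomes: Mapping[str, bool]) -> dict:
    """Bookkeeping for published per-protein outcome tables.

    ``outcomes`` maps a protein id to whether the predictor identified it
    correctly; returns correct/total and accuracy, as used to score
    predictors on independent sets of reviewed antioxidant proteins.
    """
    if not outcomes:
        raise ValueError("no outcomes to tally")
    correct = sum(bool(v) for v in outcomes.values())
    total = len(outcomes)
    return {"correct": correct, "total": total, "accuracy": correct / total}


# ------------------- frozen-autoencoder baselines -------------------


def _train_mlp_head(Z_train: np.ndarray, y_train: np.ndarray, config: ModelConfig,
                    seed: int) -> "_MLPHead":
    """Train the classifier head alone on frozen latent codes."""
    rng = np.random.default_rng(seed)
    widths = [Z_train.shape[1], *config.classifier_hidden, 2]
    net = _nn.mlp_block(widths, config.dropout_rate, rng, None)
    opt = _nn.RMSprop(lr=config.learning_rate)
    onehot = np.eye(2)[y_train]

    # small stratified holdout for early stopping, as in joint training
    val_idx = []
    for cls_label in (0, 1):
        idx = rng.permutation(np.flatnonzero(y_train == cls_label))
        val_idx.append(idx[: max(1, int(round(config.validation_fraction * idx.size)))])
    val = np.sort(np.concatenate(val_idx))
    tr = np.setdiff1d(np.arange(y_train.size), val)

    best_state, best_loss, wait = None, np.inf, 0
    for _ in range(config.max_epochs):
        perm = rng.permutation(tr)
        for start in range(0, perm.size, config.batch_size):
            batch = perm[start : start + config.batch_size]
            if batch.size < 2:
                continue
            probs = _nn.softmax(net.forward(Z_train[batch], train=True, rng=rng))
            net.backward((probs - onehot[batch]) / batch.size)
            opt.step({"head": net})
        val_probs = _nn.softmax(net.forward(Z_train[val], train=False))
        val_loss = _nn.cross_entropy(val_probs, onehot[val])
        if val_loss < best_loss:
            best_state, best_loss, wait = net.state(), val_loss, 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    net.load_state(best_state)
    return _MLPHead(net)


class _MLPHead:
    def __init__(self, net: _nn.Sequential):
        self._net = net

    def predict(self, Z: np.ndarray) -> np.ndarray:
        probs = _nn.softmax(self._net.forward(Z, train=False))
        return (probs[:, 1] > probs[:, 0]).astype(np.int64)


def baseline_ae_comparison(X_train: np.ndarray, y_train: np.ndarray,
                           X_test: np.ndarray, y_test: np.ndarray,
                           config: ModelConfig, bins: int = 100) -> dict:
    """Compare joint training against a conventional autoencoder pipeline.

    A reconstruction-only autoencoder (identical widths, ``lam = 1``) is
    trained, its latent codes frozen, and three classifiers fitted on the
    codes: the same MLP head, an RBF-kernel SVM (C=1000, balanced class
    weights), and Gaussian naive Bayes with equal priors.  All four
    models — the three frozen-latent baselines and the jointly trained
    model — are evaluated on the identical test split; latent
    1D-PCA-GCNR scores for both latent spaces are included.
    """
    from sklearn.naive_bayes import GaussianNB
    from sklearn.svm import SVC

    y_train = np.asarray(y_train)
    y_test = np.asarray(y_test)

    joint = DeepLSE(X_train, y_train, config).fit()
    ae = DeepLSE(X_train, y_train, replace(config, lam=1.0)).fit()

    Z_train = ae.encode_latent(X_train)
    Z_test = ae.encode_latent(X_test)

    def report(pred: np.ndarray) -> MetricReport:
        return compute_metrics(compute_confusion(y_test, pred))

    head = _train_mlp_head(Z_train, y_train, config, seed=config.seed)
    svm = SVC(kernel="rbf", C=1000.0, class_weight="balanced", random_state=config.seed)
    svm.fit(Z_train, y_train)
    nb = GaussianNB(priors=[0.5, 0.5])
    nb.fit(Z_train, y_train)

    _, joint_pred = joint.predict(X_test)
    joint_latent = joint.encode_latent(X_test)

    return {
        "deeplse": report(joint_pred),
        "ae_mlp": report(head.predict(Z_test)),
        "ae_svm": report(svm.predict(Z_test).astype(np.int64)),
        "ae_nb": report(nb.predict(Z_test).astype(np.int64)),
        "deeplse_latent_gcnr": pca1d_gcnr(joint_latent, y_test, bins=bins, source_space="latent").gcnr,
        "ae_latent_gcnr": pca1d_gcnr(Z_test, y_test, bins=bins, source_space="latent").gcnr,
        "deeplse_results": joint,
        "ae_results": ae,
    }
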