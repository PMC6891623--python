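"""End-to-end experiment harness: train on source, evaluate on target.

Reproduces the evaluation design of a carrier-transfer study: the labeled
source domain is split ~2:1 (Kennard–Stone, per class) into training and
testing sets; an ELM trained on the source training set is evaluated on the
source test set and on the target domain under three arms:

``none``
    no correction — target features standardized with the *source-fitted*
    statistics (the deployment situation: the training pipeline's scaler is
    applied to incoming data) and fed to the source model;
``pca_source``
    both domains projected onto the *source* principal subspace S_S, the
    target again through the source-fitted scaler;
``sais``
    the full subspace alignment pipeline — which standardizes each domain
    with its own statistics as part of the method — with a sweep over the
    number n of target samples (per class) used to fit the target subspace,
    plus "all".

The baselines use the source scaler deliberately: fitting the target
domain's own statistics is already a (partial) domain correction, and the
no-correction baseline by definition does not model the target domain.
Target labels are used for evaluation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .alignment import effective_rank, pca_subspace, sais_transform
from .elm import elm_predict, elm_train
from .errors import InvalidParameterError, ShapeMismatchError
from .preprocessing import DomainDataset, zscore_standardize
from .selection import SplitResult, kennard_stone_split_per_class

KNOWN_METHODS = ("none", "pca_source", "sais")


@dataclass
class EvaluationReport:
    """One evaluation arm's accuracies (all percentages in [0, 100])."""

    method: str
    overall_accuracy: float
    per_class_accuracy: dict = field(default_factory=dict)   # class id -> percent
    source_test_accuracy: float = float("nan")
    n_target_for_subspace: object = None    # int, "all" or None
    subspace_size: int | None = None
    seed: int = 0


def accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Recognition rate: 100 × (exact matches) / M."""
    p = np.asarray(predicted).ravel()
    t = np.asarray(truth).ravel()
    if p.shape != t.shape or p.size == 0:
        raise ShapeMismatchError("predicted and truth must be equal, non-empty vectors")
    return 100.0 * float(np.mean(p == t))


def per_class_accuracy(predicted: np.ndarray, truth: np.ndarray) -> dict:
    """Recognition rate per true class (diagonal of the confusion matrix)."""
    p = np.asarray(predicted).ravel()
    t = np.asarray(truth).ravel()
    if p.shape != t.shape or p.size == 0:
        raise ShapeMismatchError("predicted and truth must be equal, non-empty vectors")
    classes = np.unique(t)
    cm = confusion_matrix(t, p, labels=classes)
    rates = 100.0 * np.diag(cm) / cm.sum(axis=1)
    return {int(c): float(r) for c, r in zip(classes, rates)}


def _evaluate(model, feats_test, y_test, feats_target, y_target) -> tuple:
    src_acc = accuracy(elm_predict(model, feats_test), y_test)
    pred_t = elm_predict(model, feats_target)
    return src_acc, accuracy(pred_t, y_target), per_class_accuracy(pred_t, y_target)


def run_experiment(
    source: DomainDataset,
    target: DomainDataset,
    methods=KNOWN_METHODS,
    D: int = 25,
    n_sweep=(5, 10, 15, 20, 25, 30),
    seed: int = 0,
    train_fraction: float = 0.7,
    n_hidden: int = 200,
    include_all: bool = True,
) -> list[EvaluationReport]:
    """Run the requested arms and return one report each (sais: one per n).

    All randomness (ELM initialization, target-subset draws) derives from
    ``seed``; two calls with identical inputs produce identical reports.
    """
    unknown = set(methods) - set(KNOWN_METHODS)
    if unknown:
        raise InvalidParameterError(f"unknown method(s): {sorted(unknown)}")
    if source.labels is None or target.labels is None:
        raise InvalidParameterError("source and (for evaluation) target labels required")

    zs, s_mu, s_sd = zscore_standardize(source)
    # deployment standardization of the target for the baseline arms
    zt_dep = (target.features - s_mu) / s_sd
    split = kennard_stone_split_per_class(zs.features, zs.labels, train_fraction)
    tr, te = np.array(split.train_indices), np.array(split.test_indices)
    ys, yt = zs.labels, target.labels
    elm_seed = int(np.random.default_rng(seed).integers(2**31))

    reports: list[EvaluationReport] = []

    if "none" in methods:
        model = elm_train(zs.features[tr], ys[tr], L=n_hidden, seed=elm_seed)
        s_acc, t_acc, per_cls = _evaluate(model, zs.features[te], ys[te], zt_dep, yt)
        reports.append(
            EvaluationReport("none", t_acc, per_cls, s_acc, None, None, seed)
        )

    if "pca_source" in methods:
        D_s = min(D, effective_rank(zs.features))
        sub = pca_subspace(zs, D_s)
        Ps, Pt = zs.features @ sub.basis, zt_dep @ sub.basis
        model = elm_train(Ps[tr], ys[tr], L=n_hidden, seed=elm_seed)
        s_acc, t_acc, per_cls = _evaluate(model, Ps[te], ys[te], Pt, yt)
        reports.append(
            EvaluationReport("pca_source", t_acc, per_cls, s_acc, None, D_s, seed)
        )

    if "sais" in methods:
        sweep = list(n_sweep) + (["all"] if include_all else [])
        for k, n in enumerate(sweep):
            rng = np.random.default_rng([seed, k])
            Ps, Pt, _ = sais_transform(source, target, D=D, n_target_for_subspace=n, rng=rng)
            model = elm_train(Ps[tr], ys[tr], L=n_hidden, seed=elm_seed)
            s_acc, t_acc, per_cls = _evaluate(model, Ps[te], ys[te], Pt, yt)
            reports.append(
                EvaluationReport("sais", t_acc, per_cls, s_acc, n, Ps.shape[1], seed)
            )

    return reports


def reports_to_frame(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Flatten reports into a table mirroring the usual results layout."""
    rows = []
    for r in reports:
        row = {
            "method": r.method,
            "n_target_for_subspace": r.n_target_for_subspace,
            "subspace_size": r.subspace_size,
            "seed": r.seed,
            "source_test_accuracy": r.source_test_accuracy,
            "overall_accuracy": r.overall_accuracy,
        }
        row.update({f"class_{c}_accuracy": v for c, v in r.per_class_accuracy.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def plot_domain_pca(source: DomainDataset, target: DomainDataset, output_path) -> None:
    """Per-class 2-D PCA scatter (PC1 vs PC2) comparing the two domains.

    Both domains are standardized with their own statistics, pooled, and
    projected on the pooled first two principal directions — a quick visual
    of how far the carrier moved each class.
    """
    zs, _, _ = zscore_standardize(source)
    zt, _, _ = zscore_standardize(target)
    pooled = DomainDataset(np.vstack([zs.features, zt.features]), domain_tag="source")
    sub = pca_subspace(pooled, 2)
    Ps, Pt = zs.features @ sub.basis, zt.features @ sub.basis

    fig, ax = plt.subplots(figsize=(6, 5))
    classes = np.unique(zs.labels) if zs.labels is not None else [None]
    cmap = plt.get_cmap("tab10")
    for k, c in enumerate(classes):
        ms = slice(None) if c is None else zs.labels == c
        mt = slice(None) if c is None else (zt.labels == c if zt.labels is not None else slice(None))
        ax.scatter(*Ps[ms].T, s=12, color=cmap(k), marker="o",
                   label=f"source class {c}" if c is not None else "source")
        ax.scatter(*Pt[mt].T, s=12, color=cmap(k), marker="x",
                   label=f"target class {c}" if c is not None else "target")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title("Domain distributions in the pooled 2-D principal plane")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(output_path, dpi=120)
    plt.close(fig)


def domain_shift_statistic(source: DomainDataset, target: DomainDataset) -> tuple[float, float]:
    """(mean per-class inter-domain centroid distance, mean intra-domain scatter).

    Computed in the pooled 2-D principal plane used by :func:`plot_domain_pca`;
    a shift is 'visible' when the first number exceeds the second.
    """
    if source.labels is None or target.labels is None:
        raise InvalidParameterError("both domains need labels for the shift statistic")
    zs, _, _ = zscore_standardize(source)
    zt, _, _ = zscore_standardize(target)
    pooled = DomainDataset(np.vstack([zs.features, zt.features]), domain_tag="source")
    sub = pca_subspace(pooled, 2)
    Ps, Pt = zs.features @ sub.basis, zt.features @ sub.basis

    centroid_dists, scatters = [], []
    for c in np.unique(zs.labels):
        ps, pt = Ps[zs.labels == c], Pt[zt.labels == c]
        cs, ct = ps.mean(axis=0), pt.mean(axis=0)
        centroid_dists.append(np.linalg.norm(cs - ct))
        scatters.append(np.linalg.norm(ps - cs, axis=1).mean())
        scatters.append(np.linalg.norm(pt - ct, axis=1).mean())
    return float(np.mean(centroid_dists)), float(np.mean(scatters))
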