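"""Confusion-matrix metrics, oversampled cross-validation, sweeps, ROC.

Metrics follow the usual confusion-count definitions: Sn = TP/P,
Sp = TN/N, Acc = (TP+TN)/(P+N), PPV = TP/(TP+FP),
MCC = (TP*TN - FP*FN) / sqrt(P * N * (TP+FP) * (TN+FN)),
Gmean = sqrt(Sn * Sp).

Cross-validation is stratified and seeded. When oversampling is enabled,
positives are duplicated only inside each training fold until they match
that fold's negative count; held-out folds are always evaluated on the
original, unduplicated instances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .contexts import extract_many
from .distances import (
    DistanceParams,
    KernelParams,
    combine_components,
    distance_components,
    kernel_from_distance,
    kernel_matrix,
)
from .exceptions import ParameterError

METRIC_COLUMNS = ("sn", "sp", "acc", "ppv", "mcc", "gmean")


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (the convention used for printed values)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass(frozen=True)
class MetricsReport:
    sn: float
    sp: float
    acc: float
    ppv: float  # NaN when undefined (no positive calls)
    mcc: float
    gmean: float
    ppv_defined: bool = True
    auc: float | None = None
    roc_points: np.ndarray | None = field(default=None, compare=False)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in METRIC_COLUMNS}
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def gmean(sn: float, sp: float) -> float:
    """Geometric mean of sensitivity and specificity."""
    if not (0.0 <= sn <= 1.0 and 0.0 <= sp <= 1.0):
        raise ParameterError("gmean inputs must be in [0, 1]")
    return math.sqrt(sn * sp)


def _metrics(tp: float, fp: float, tn: float, fn: float,
             auc: float | None = None,
             roc_points: np.ndarray | None = None) -> MetricsReport:
    """Metric formulas on (possibly fractional) confusion counts."""
    p, n = tp + fn, tn + fp
    if p <= 0 or n <= 0:
        raise ParameterError("both classes must be represented (P >= 1, N >= 1)")
    sn = tp / p
    sp = tn / n
    acc = (tp + tn) / (p + n)
    ppv_defined = (tp + fp) > 0
    ppv = tp / (tp + fp) if ppv_defined else float("nan")
    denom = math.sqrt(p * n * (tp + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return MetricsReport(sn=sn, sp=sp, acc=acc, ppv=ppv, mcc=mcc,
                         gmean=gmean(sn, sp), ppv_defined=ppv_defined,
                         auc=auc, roc_points=roc_points)


def compute_metrics(c: ConfusionCounts, auc: float | None = None,
                    roc_points: np.ndarray | None = None) -> MetricsReport:
    """The six criteria from integer confusion counts."""
    return _metrics(c.tp, c.fp, c.tn, c.fn, auc=auc, roc_points=roc_points)


def metrics_from_rates(sn: float, sp: float, p: int, n: int) -> MetricsReport:
    """Reconstruct the full report from printed Sn/Sp and class sizes.

    Uses exact expected counts (TP = sn*p etc., not rounded to integers)
    so the reconstruction is free of double-rounding artifacts.
    """
    return _metrics(tp=sn * p, fp=(1.0 - sp) * n, tn=sp * n, fn=(1.0 - sn) * p)


def oversample_to_balance(minority: list, target_size: int, seed: int = 0):
    """Duplicate a minority class to exactly ``target_size`` members.

    Whole cyclic copies first, then a seeded random remainder drawn
    without replacement. Returns ``(oversampled_list, fold_factor)``.
    """
    n = len(minority)
    if n == 0:
        raise ParameterError("minority set is empty")
    if target_size < n:
        raise ParameterError(
            f"target_size {target_size} smaller than minority size {n}"
        )
    copies, rem = divmod(target_size, n)
    out = list(minority) * copies
    if rem:
        rng = np.random.default_rng(seed)
        out.extend(minority[i] for i in rng.choice(n, rem, replace=False))
    return out, target_size / n


def roc_auc(decision_values, truth_labels):
    """Trapezoidal AUC from a threshold sweep (ties share a step).

    ``truth_labels`` > 0 are positives. Returns ``(auc, points)`` with
    points an (m, 2) array of (FPR, TPR) from (0, 0) to (1, 1).
    """
    dv = np.asarray(decision_values, dtype=float)
    y = np.asarray(truth_labels) > 0
    p, n = int(y.sum()), int((~y).sum())
    if p == 0 or n == 0:
        raise ParameterError("ROC requires both classes in the truth labels")
    order = np.argsort(-dv, kind="mergesort")
    dv_s, y_s = dv[order], y[order]
    tps = np.cumsum(y_s)
    fps = np.cumsum(~y_s)
    # keep only the last index of each tied block of decision values
    last = np.r_[np.flatnonzero(np.diff(dv_s) != 0), dv_s.size - 1]
    tpr = np.r_[0.0, tps[last] / p]
    fpr = np.r_[0.0, fps[last] / n]
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


@dataclass
class CVResult:
    fold_reports: list[MetricsReport]
    pooled: MetricsReport
    decision_values: np.ndarray  # aligned with pos + neg input order
    y_true: np.ndarray
    fold_of: np.ndarray


def _cv_precomputed(K: np.ndarray, y: np.ndarray, nfolds: int, C: float,
                    seed: int, oversample: bool) -> CVResult:
    npos = int((y == 1).sum())
    nneg = int((y == -1).sum())
    if min(npos, nneg) < nfolds:
        raise ParameterError(
            f"each class needs >= nfolds members (pos={npos}, neg={nneg}, "
            f"nfolds={nfolds})"
        )
    skf = StratifiedKFold(n_splits=nfolds, shuffle=True, random_state=seed)
    dv_all = np.empty(y.shape[0])
    fold_of = np.empty(y.shape[0], dtype=int)
    fold_reports: list[MetricsReport] = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for fold, (tr, te) in enumerate(skf.split(np.zeros_like(y), y)):
        tr_pos = tr[y[tr] == 1]
        tr_neg = tr[y[tr] == -1]
        if oversample and tr_pos.size < tr_neg.size:
            tr_pos_aug, _ = oversample_to_balance(
                list(tr_pos), tr_neg.size, seed=seed * 1000 + fold
            )
            tr_aug = np.concatenate([np.asarray(tr_pos_aug, dtype=int), tr_neg])
        else:
            tr_aug = tr
        clf = SVC(C=C, kernel="precomputed")
        clf.fit(K[np.ix_(tr_aug, tr_aug)], y[tr_aug])
        dv = clf.decision_function(K[np.ix_(te, tr_aug)])
        dv_all[te] = dv
        fold_of[te] = fold
        pred = np.where(dv > 0, 1, -1)
        c = ConfusionCounts(
            tp=int(((pred == 1) & (y[te] == 1)).sum()),
            fp=int(((pred == 1) & (y[te] == -1)).sum()),
            tn=int(((pred == -1) & (y[te] == -1)).sum()),
            fn=int(((pred == -1) & (y[te] == 1)).sum()),
        )
        fold_reports.append(compute_metrics(c))
        pooled = pooled + c
    auc, points = roc_auc(dv_all, y)
    return CVResult(
        fold_reports=fold_reports,
        pooled=compute_metrics(pooled, auc=auc, roc_points=points),
        decision_values=dv_all,
        y_true=y,
        fold_of=fold_of,
    )


def cross_validate(pos, neg, nfolds: int, dp: DistanceParams,
                   kp: KernelParams, C: float = 1.0, seed: int = 0,
                   oversample: bool = True) -> CVResult:
    """Stratified N-fold CV of the binary classifier on contexts."""
    if nfolds < 2:
        raise ParameterError(f"nfolds must be >= 2, got {nfolds}")
    seqs = list(pos) + list(neg)
    y = np.concatenate([np.ones(len(pos)), -np.ones(len(neg))]).astype(int)
    K = kernel_matrix(seqs, dp=dp, kp=kp)
    return _cv_precomputed(K, y, nfolds, C, seed, oversample)


def sweep_w(pos, neg, w_grid, dp_base: DistanceParams, kp: KernelParams,
            nfolds: int = 5, C: float = 1.0, seed: int = 0,
            oversample: bool = True) -> pd.DataFrame:
    """Cross-validate over a grid of distance weights w.

    The edit and Hamming component matrices are computed once and
    recombined per w.
    """
    seqs = list(pos) + list(neg)
    y = np.concatenate([np.ones(len(pos)), -np.ones(len(neg))]).astype(int)
    E, H = distance_components(seqs, dp=dp_base)
    rows = []
    for w in w_grid:
        dp = DistanceParams(w=float(w), l1=dp_base.l1, l2=dp_base.l2)
        K = kernel_from_distance(combine_components(E, H, dp), kp)
        res = _cv_precomputed(K, y, nfolds, C, seed, oversample)
        rows.append({"w": float(w), **res.pooled.as_dict()})
    return pd.DataFrame(rows)


def sweep_length(pos_sites, neg_sites, genome, lengths=(11, 21, 31, 41, 51),
                 kp: KernelParams = KernelParams(), nfolds: int = 5,
                 C: float = 1.0, seed: int = 0,
                 oversample: bool = True) -> pd.DataFrame:
    """Re-extract contexts per length; CV each pure distance (edit, Hamming)."""
    rows = []
    for length in lengths:
        if length % 2 == 0:
            raise ParameterError(f"context lengths must be odd, got {length}")
        flank = (length - 1) // 2
        pos_ctx, _ = extract_many(genome, pos_sites, flank, label="positive")
        neg_ctx, _ = extract_many(genome, neg_sites, flank, label="negative")
        for distance, w in (("edit", 1.0), ("hamming", 0.0)):
            dp = DistanceParams(w=w, l1=length, l2=length)
            res = cross_validate(pos_ctx, neg_ctx, nfolds, dp, kp, C=C,
                                 seed=seed, oversample=oversample)
            rows.append({
                "length": length,
                "distance": distance,
                "n_pos": len(pos_ctx),
                "n_neg": len(neg_ctx),
                **res.pooled.as_dict(),
            })
    return pd.DataFrame(rows)


def write_metrics_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_roc_tsv(points: np.ndarray, path) -> None:
    pd.DataFrame(points, columns=["fpr", "tpr"]).to_csv(path, sep="\t", index=False)
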