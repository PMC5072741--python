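"""Maximal-margin classifiers over the precomputed string kernel.

The quadratic programs are solved by scikit-learn's libsvm bindings with
``kernel='precomputed'``; the bespoke content is the kernel itself and
the support-expansion persistence, so a trained model is portable as a
plain JSON file carrying its support sequences and dual coefficients.

Label convention: +1 is an editing event, -1 a non-editing event; a
decision value of exactly 0 is called -1 (conservative).
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC, OneClassSVM

from .distances import (
    DistanceParams,
    KernelParams,
    kernel_matrix,
    warn_if_indefinite,
)
from .exceptions import LengthMismatchError, ModelFormatError, ParameterError

MODEL_FORMAT = "editscan-model"
MODEL_VERSION = 1


@dataclass
class TrainedModel:
    mode: str  # "binary" | "one-class"
    support_seqs: list[str]
    dual_coefs: np.ndarray
    bias: float
    dp: DistanceParams
    kp: KernelParams
    hyper: dict
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("binary", "one-class"):
            raise ParameterError(f"unknown model mode {self.mode!r}")
        self.dual_coefs = np.asarray(self.dual_coefs, dtype=float)
        if len(self.support_seqs) != self.dual_coefs.shape[0]:
            raise ModelFormatError(
                "support sequence / dual coefficient count mismatch"
            )


def _seqs_of(xs) -> list[str]:
    return [(x.seq if hasattr(x, "seq") else str(x)).upper() for x in xs]


def _check_lengths(seqs: Sequence[str], l1: int) -> None:
    for i, s in enumerate(seqs):
        if len(s) != l1:
            raise LengthMismatchError(
                f"sequence {i} has length {len(s)}, model expects l1={l1}"
            )


def train_binary(pos, neg, dp: DistanceParams, kp: KernelParams,
                 C: float = 1.0) -> TrainedModel:
    """Soft-margin binary SVM on the precomputed string kernel."""
    if not pos or not neg:
        raise ParameterError("both classes must be non-empty")
    if not C > 0:
        raise ParameterError(f"C must be > 0, got {C}")
    seqs = _seqs_of(pos) + _seqs_of(neg)
    _check_lengths(seqs, dp.l1)
    y = np.concatenate([np.ones(len(pos)), -np.ones(len(neg))])
    K = kernel_matrix(seqs, dp=dp, kp=kp)
    warn_if_indefinite(K)
    clf = SVC(C=C, kernel="precomputed")
    clf.fit(K, y)
    sv = clf.support_
    return TrainedModel(
        mode="binary",
        support_seqs=[seqs[i] for i in sv],
        dual_coefs=clf.dual_coef_[0].copy(),
        bias=float(clf.intercept_[0]),
        dp=dp,
        kp=kp,
        hyper={"C": float(C)},
        meta={
            "n_pos": len(pos),
            "n_neg": len(neg),
            "n_support": int(sv.shape[0]),
            "trained_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        },
    )


def train_one_class(pos, dp: DistanceParams, kp: KernelParams,
                    nu: float = 0.1) -> TrainedModel:
    """One-class SVM trained on positives only.

    ``nu`` upper-bounds the fraction of training points falling outside
    the learned boundary and lower-bounds the support-vector fraction.
    """
    if not pos:
        raise ParameterError("positive set must be non-empty")
    if not 0.0 < nu < 1.0:
        raise ParameterError(f"nu must be in (0, 1), got {nu}")
    seqs = _seqs_of(pos)
    _check_lengths(seqs, dp.l1)
    K = kernel_matrix(seqs, dp=dp, kp=kp)
    warn_if_indefinite(K)
    clf = OneClassSVM(kernel="precomputed", nu=nu)
    clf.fit(K)
    sv = clf.support_
    return TrainedModel(
        mode="one-class",
        support_seqs=[seqs[i] for i in sv],
        dual_coefs=clf.dual_coef_[0].copy(),
        bias=float(clf.intercept_[0]),
        dp=dp,
        kp=kp,
        hyper={"nu": float(nu)},
        meta={
            "n_pos": len(pos),
            "n_support": int(sv.shape[0]),
            "trained_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        },
    )


def decision_values(model: TrainedModel, xs) -> np.ndarray:
    """Kernel expansion sum_i coef_i * K(x, sv_i) + bias for each input."""
    seqs = _seqs_of(xs)
    _check_lengths(seqs, model.dp.l1)
    if not seqs:
        return np.empty(0)
    Kx = kernel_matrix(seqs, model.support_seqs, dp=model.dp, kp=model.kp)
    return Kx @ model.dual_coefs + model.bias


def predict(model: TrainedModel, xs):
    """Return ``(labels, decision_values)``; label +1 iff decision value > 0."""
    dv = decision_values(model, xs)
    labels = np.where(dv > 0, 1, -1).astype(int)
    return labels, dv


def save_model(model: TrainedModel, path) -> None:
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "mode": model.mode,
        "dp": {"w": model.dp.w, "l1": model.dp.l1, "l2": model.dp.l2},
        "kp": {"gamma": model.kp.gamma},
        "hyper": model.hyper,
        "bias": model.bias,
        "support_seqs": model.support_seqs,
        "dual_coefs": [float(c) for c in model.dual_coefs],
        "meta": model.meta,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_model(path) -> TrainedModel:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelFormatError(f"cannot parse model file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != MODEL_FORMAT:
        raise ModelFormatError(f"{path} is not an editscan model file")
    if doc.get("version") != MODEL_VERSION:
        raise ModelFormatError(
            f"unsupported model version {doc.get('version')!r} "
            f"(expected {MODEL_VERSION})"
        )
    try:
        return TrainedModel(
            mode=doc["mode"],
            support_seqs=list(doc["support_seqs"]),
            dual_coefs=np.asarray(doc["dual_coefs"], dtype=float),
            bias=float(doc["bias"]),
            dp=DistanceParams(**doc["dp"]),
            kp=KernelParams(**doc["kp"]),
            hyper=dict(doc["hyper"]),
            meta=dict(doc.get("meta", {})),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelFormatError(f"corrupt model file {path}: {exc}") from exc
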