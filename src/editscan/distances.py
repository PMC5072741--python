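"""Combined edit/Hamming string distance and the Gaussian string kernel.

The distance between two L1-mers is

    D = w * DEdit / L1 + (1 - w) * DHamming / L2

where DEdit is the Levenshtein distance over the full L1-mer and DHamming
is computed on the centered inner L2-mer. The kernel is
K(a, b) = exp(-gamma * D(a, b)**2).

Ambiguous bases: an uppercase 'N' never matches anything, including
another 'N', in Hamming (and clustering-identity) comparisons; the edit
distance treats characters literally. All comparisons are
case-insensitive (inputs are uppercased on entry).

The pairwise kernels are numba-compiled; for a few thousand 41-mers a
full matrix takes well under a second after warm-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .exceptions import LengthMismatchError, ParameterError

logger = logging.getLogger(__name__)

_N = 78  # ord('N'): wildcard-mismatch sentinel


@dataclass(frozen=True)
class DistanceParams:
    """Weight and window lengths of the combined distance.

    ``w`` blends the two components (w=1 pure edit, w=0 pure Hamming);
    ``l1`` is the full context length, ``l2`` the centered inner window
    the Hamming term is computed on. Only the nested case l2 <= l1 is
    supported.
    """

    w: float = 0.2
    l1: int = 41
    l2: int = 31

    def __post_init__(self):
        if not 0.0 <= self.w <= 1.0:
            raise ParameterError(f"w must be in [0, 1], got {self.w}")
        if self.l1 % 2 == 0 or self.l2 % 2 == 0:
            raise ParameterError(
                f"window lengths must be odd, got l1={self.l1}, l2={self.l2}"
            )
        if self.l1 < 1 or self.l2 < 1:
            raise ParameterError("window lengths must be >= 1")
        if self.l2 > self.l1:
            raise ParameterError(
                f"l2 ({self.l2}) > l1 ({self.l1}) is not supported"
            )

    @property
    def inner_offset(self) -> int:
        return (self.l1 - self.l2) // 2


@dataclass(frozen=True)
class KernelParams:
    gamma: float = 0.1

    def __post_init__(self):
        if not self.gamma > 0:
            raise ParameterError(f"gamma must be > 0, got {self.gamma}")


def _seq_of(x) -> str:
    return (x.seq if hasattr(x, "seq") else str(x)).upper()


def encode(seq: str) -> np.ndarray:
    """Encode a string as a uint8 array of ASCII codes."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def encode_all(seqs: Iterable) -> np.ndarray:
    """Stack equal-length sequences into an (n, L) uint8 matrix."""
    rows = [encode(_seq_of(s)) for s in seqs]
    if not rows:
        return np.empty((0, 0), dtype=np.uint8)
    lengths = {r.shape[0] for r in rows}
    if len(lengths) > 1:
        raise LengthMismatchError(f"mixed sequence lengths: {sorted(lengths)}")
    return np.stack(rows)


@njit(cache=True)
def _lev(a, b):  # pragma: no cover - exercised via the wrappers
    la, lb = a.shape[0], b.shape[0]
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev = np.empty(lb + 1, np.int64)
    curr = np.empty(lb + 1, np.int64)
    for j in range(lb + 1):
        prev[j] = j
    for i in range(la):
        curr[0] = i + 1
        ai = a[i]
        for j in range(lb):
            cost = 0 if ai == b[j] else 1
            best = prev[j] + cost
            if prev[j + 1] + 1 < best:
                best = prev[j + 1] + 1
            if curr[j] + 1 < best:
                best = curr[j] + 1
            curr[j + 1] = best
        tmp = prev
        prev = curr
        curr = tmp
    return prev[lb]


@njit(cache=True)
def _ham(a, b):  # pragma: no cover
    d = 0
    for i in range(a.shape[0]):
        if a[i] != b[i] or a[i] == _N:
            d += 1
    return d


@njit(cache=True)
def _component_matrices(X, Y, off, l2, symmetric):  # pragma: no cover
    n, m = X.shape[0], Y.shape[0]
    E = np.empty((n, m), np.float64)
    H = np.empty((n, m), np.float64)
    for i in range(n):
        jstart = i if symmetric else 0
        for j in range(jstart, m):
            e = _lev(X[i], Y[j])
            h = _ham(X[i, off : off + l2], Y[j, off : off + l2])
            E[i, j] = e
            H[i, j] = h
            if symmetric:
                E[j, i] = e
                H[j, i] = h
    return E, H


def edit_distance(a, b) -> int:
    """Levenshtein distance with unit costs (any lengths)."""
    return int(_lev(encode(_seq_of(a)), encode(_seq_of(b))))


def hamming_distance(a, b) -> int:
    """Number of mismatching positions between equal-length strings."""
    ea, eb = encode(_seq_of(a)), encode(_seq_of(b))
    if ea.shape[0] != eb.shape[0]:
        raise LengthMismatchError(
            f"hamming_distance requires equal lengths ({ea.shape[0]} vs {eb.shape[0]})"
        )
    return int(_ham(ea, eb))


def combined_distance(a, b, dp: DistanceParams) -> float:
    """Weighted, length-normalized edit + inner-window Hamming distance."""
    sa, sb = _seq_of(a), _seq_of(b)
    if len(sa) != dp.l1 or len(sb) != dp.l1:
        raise LengthMismatchError(
            f"combined_distance requires length l1={dp.l1} "
            f"(got {len(sa)} and {len(sb)})"
        )
    de = edit_distance(sa, sb)
    off = dp.inner_offset
    dh = hamming_distance(sa[off : off + dp.l2], sb[off : off + dp.l2])
    return dp.w * de / dp.l1 + (1.0 - dp.w) * dh / dp.l2


def kernel_value(a, b, dp: DistanceParams, kp: KernelParams) -> float:
    d = combined_distance(a, b, dp)
    return float(np.exp(-kp.gamma * d * d))


def distance_components(
    X: Sequence, Y: Sequence | None = None, *, dp: DistanceParams
):
    """Raw edit and inner-Hamming count matrices (for w-sweep caching).

    Returns ``(E, H)`` where E[i, j] is the edit distance over the full
    l1-mers and H[i, j] the Hamming distance over the centered l2-mers.
    When ``Y`` is None the matrices are computed against X itself,
    exploiting symmetry.
    """
    eX = encode_all(X)
    if eX.size and eX.shape[1] != dp.l1:
        raise LengthMismatchError(
            f"sequences have length {eX.shape[1]}, expected l1={dp.l1}"
        )
    if Y is None:
        return _component_matrices(eX, eX, dp.inner_offset, dp.l2, True)
    eY = encode_all(Y)
    if eY.size and eY.shape[1] != dp.l1:
        raise LengthMismatchError(
            f"sequences have length {eY.shape[1]}, expected l1={dp.l1}"
        )
    return _component_matrices(eX, eY, dp.inner_offset, dp.l2, False)


def combine_components(E, H, dp: DistanceParams) -> np.ndarray:
    return dp.w * E / dp.l1 + (1.0 - dp.w) * H / dp.l2


def distance_matrix(X, Y=None, *, dp: DistanceParams) -> np.ndarray:
    E, H = distance_components(X, Y, dp=dp)
    return combine_components(E, H, dp)


def kernel_from_distance(D: np.ndarray, kp: KernelParams) -> np.ndarray:
    return np.exp(-kp.gamma * D * D)


def kernel_matrix(X, Y=None, *, dp: DistanceParams, kp: KernelParams) -> np.ndarray:
    """|X| x |Y| matrix of kernel values (symmetric, unit diagonal when Y is X)."""
    return kernel_from_distance(distance_matrix(X, Y, dp=dp), kp)


def warn_if_indefinite(K: np.ndarray, max_n: int = 256, tol: float = -1e-6,
                       seed: int = 0) -> float:
    """Log a warning when a sampled kernel submatrix is strongly indefinite.

    The distance underlying the kernel is not Euclidean, so K is not
    guaranteed PSD; the solver consumes it as-is. Returns the smallest
    eigenvalue of the sampled submatrix.
    """
    n = K.shape[0]
    if n > max_n:
        idx = np.sort(np.random.default_rng(seed).choice(n, max_n, replace=False))
        sub = K[np.ix_(idx, idx)]
    else:
        sub = K
    lam_min = float(np.linalg.eigvalsh(sub)[0])
    if lam_min < tol:
        logger.warning(
            "kernel matrix appears indefinite (min sampled eigenvalue %.3g); "
            "training proceeds on the matrix as-is", lam_min,
        )
    return lam_min


def dump_matrix_tsv(M: np.ndarray, path) -> None:
    """Debug dump of a distance/kernel matrix as TSV."""
    np.savetxt(path, M, delimiter="\t", fmt="%.10g")
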