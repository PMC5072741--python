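"""Editing-sequence contexts: extraction, negative sampling, redundancy.

A context is the odd-length DNA window centered on a (putative) edited
adenine. Minus-strand sites are sampled at forward-strand 'T' positions
and reverse-complemented on extraction, so the stored sequence always
carries the adenine at its center on its own strand.

Coordinates are 1-based on input (Darned style) and converted to 0-based
half-open internally; BED output is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .distances import encode_all
from .exceptions import (
    AmbiguousSequenceError,
    BoundaryError,
    LengthMismatchError,
    NotAdenineCenteredError,
    ParameterError,
)
from .io import revcomp

_VALID_BASES = frozenset("ACGTN")
_N = 78  # ord('N')

MAX_N_FRACTION = 0.2  # contexts with more ambiguous bases are rejected

LABELS = ("positive", "negative", "unlabeled")


@dataclass(frozen=True)
class GenomicSite:
    """Strand-aware 1-based genomic coordinate of a (putative) editing adenine."""

    chrom: str
    pos: int
    strand: str

    def __post_init__(self):
        # tolerate the typographic minus sign
        if self.strand == "−":
            object.__setattr__(self, "strand", "-")
        if self.strand not in ("+", "-"):
            raise ParameterError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.pos < 1:
            raise ParameterError(f"pos must be >= 1, got {self.pos}")


@dataclass(frozen=True)
class ContextSequence:
    """Odd-length, adenine-centered DNA window with an optional label."""

    seq: str
    label: str = "unlabeled"
    origin: GenomicSite | None = field(default=None, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())
        if len(self.seq) % 2 == 0 or not self.seq:
            raise ParameterError(
                f"context length must be odd and >= 1, got {len(self.seq)}"
            )
        if not set(self.seq) <= _VALID_BASES:
            bad = sorted(set(self.seq) - _VALID_BASES)
            raise ParameterError(f"invalid characters in context: {bad}")
        if self.label not in LABELS:
            raise ParameterError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.label != "unlabeled" and self.center != "A":
            raise ParameterError(
                f"labeled context must be adenine-centered, center is {self.center!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def center(self) -> str:
        return self.seq[len(self.seq) // 2]


def extract_context(genome: Mapping[str, str], site: GenomicSite,
                    flank: int, label: str = "unlabeled") -> ContextSequence:
    """Extract the (2*flank+1)-mer centered on ``site``.

    For minus-strand sites the reverse complement is returned, so the
    center of the result is the edited adenine on its own strand.
    Raises ``BoundaryError`` when the window leaves the contig,
    ``NotAdenineCenteredError`` when the strand-resolved center is not
    'A', and ``AmbiguousSequenceError`` for N-rich windows.
    """
    if flank < 1:
        raise ParameterError(f"flank must be >= 1, got {flank}")
    try:
        contig = genome[site.chrom]
    except KeyError:
        raise ParameterError(f"unknown chromosome {site.chrom!r}") from None
    if site.pos > len(contig):
        raise BoundaryError(
            f"position {site.pos} beyond end of {site.chrom} ({len(contig)} nt)"
        )
    lo = site.pos - 1 - flank
    hi = site.pos + flank
    if lo < 0 or hi > len(contig):
        raise BoundaryError(
            f"window [{lo + 1}, {hi}] around {site.chrom}:{site.pos} "
            f"leaves the contig (length {len(contig)})"
        )
    window = contig[lo:hi].upper()
    if window.count("N") > MAX_N_FRACTION * len(window):
        raise AmbiguousSequenceError(
            f"window at {site.chrom}:{site.pos} has >{MAX_N_FRACTION:.0%} N bases"
        )
    if site.strand == "-":
        window = revcomp(window)
    center = window[flank]
    if center != "A":
        raise NotAdenineCenteredError(site, center)
    return ContextSequence(window, label=label, origin=site)


def extract_many(genome: Mapping[str, str], sites: Iterable[GenomicSite],
                 flank: int, label: str = "unlabeled",
                 skip_errors: bool = True):
    """Extract contexts for many sites; returns ``(contexts, n_skipped)``."""
    out, skipped = [], 0
    for site in sites:
        try:
            out.append(extract_context(genome, site, flank, label=label))
        except (BoundaryError, NotAdenineCenteredError, AmbiguousSequenceError):
            if not skip_errors:
                raise
            skipped += 1
    return out, skipped


def sample_negative_sites(genome: Mapping[str, str], rate: float, seed: int,
                          exclude: Iterable = (), flank: int = 20
                          ) -> list[ContextSequence]:
    """Sample background adenine-centered contexts at a per-nucleotide rate.

    One independent Bernoulli draw per genomic position per strand; a '+'
    draw is kept when the forward base is 'A', a '-' draw when it is 'T'
    (the context is then reverse-complemented). Windows that leave the
    contig or are N-rich are dropped, as is any context whose sequence
    exactly matches a member of ``exclude``. Deterministic given ``seed``.
    """
    if not 0.0 < rate < 1.0:
        raise ParameterError(f"rate must be in (0, 1), got {rate}")
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ParameterError("genome is empty")
    exclude_set = {(x.seq if hasattr(x, "seq") else str(x)).upper() for x in exclude}
    rng = np.random.default_rng(seed)
    out: list[ContextSequence] = []
    for chrom, contig in genome.items():
        n = len(contig)
        for strand, base in (("+", "A"), ("-", "T")):
            hits = np.flatnonzero(rng.random(n) < rate)
            for i in hits:
                if contig[i].upper() != base:
                    continue
                site = GenomicSite(chrom, int(i) + 1, strand)
                try:
                    ctx = extract_context(genome, site, flank, label="negative")
                except (BoundaryError, AmbiguousSequenceError):
                    continue
                if ctx.seq in exclude_set:
                    continue
                out.append(ctx)
    return out


def _identity_to_rows(rows: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Fraction of exactly matching positions of q against each row (N never matches)."""
    return (((rows == q[None, :]) & (q[None, :] != _N)).sum(axis=1)
            / q.shape[0])


def _orientations(seq: str, both_strands: bool) -> list[np.ndarray]:
    s = seq.upper()
    enc = [np.frombuffer(s.encode(), dtype=np.uint8)]
    if both_strands:
        enc.append(np.frombuffer(revcomp(s).encode(), dtype=np.uint8))
    return enc


def redundancy_filter(seqs: Sequence, identity_threshold: float = 0.8,
                      both_strands: bool = True):
    """Greedy CD-HIT-style clustering at an identity threshold.

    In input order, a sequence joins the first existing representative
    whose identity (matching positions / length, max over forward and
    reverse-complement orientation when ``both_strands``) is strictly
    greater than the threshold; otherwise it founds a new cluster.
    Returns ``(representatives, cluster_index_per_input)``.
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ParameterError(
            f"identity_threshold must be in (0, 1], got {identity_threshold}"
        )
    strs = [(s.seq if hasattr(s, "seq") else str(s)).upper() for s in seqs]
    if strs and len({len(s) for s in strs}) > 1:
        raise LengthMismatchError("redundancy_filter requires equal-length sequences")
    reps: list = []
    rep_rows: list[np.ndarray] = []
    assign: list[int] = []
    for orig, s in zip(seqs, strs):
        cluster = -1
        if rep_rows:
            rows = np.stack(rep_rows)
            best = np.zeros(len(rep_rows))
            for q in _orientations(s, both_strands):
                best = np.maximum(best, _identity_to_rows(rows, q))
            hit = np.flatnonzero(best > identity_threshold)
            if hit.size:
                cluster = int(hit[0])
        if cluster < 0:
            cluster = len(reps)
            reps.append(orig)
            rep_rows.append(np.frombuffer(s.encode(), dtype=np.uint8))
        assign.append(cluster)
    return reps, assign


def cross_set_similarity(setA: Sequence, setB: Sequence,
                         identity_threshold: float = 0.8,
                         both_strands: bool = True) -> int:
    """Count members of A similar (identity > threshold) to any member of B."""
    if not 0.0 < identity_threshold <= 1.0:
        raise ParameterError(
            f"identity_threshold must be in (0, 1], got {identity_threshold}"
        )
    if not setA or not setB:
        return 0
    rowsB = encode_all(setB)
    strsA = [(s.seq if hasattr(s, "seq") else str(s)).upper() for s in setA]
    if any(len(s) != rowsB.shape[1] for s in strsA):
        raise LengthMismatchError("cross_set_similarity requires equal-length sequences")
    count = 0
    for s in strsA:
        for q in _orientations(s, both_strands):
            if (_identity_to_rows(rowsB, q) > identity_threshold).any():
                count += 1
                break
    return count
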