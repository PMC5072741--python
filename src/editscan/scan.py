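"""Whole-sequence scanning and the two-stage putative-site caller.

Stage order mirrors the intended pipeline: candidate enumeration (or
mismatch-tolerant seed matching against known editing contexts), a
one-class pre-filter that discards clearly unlikely sites, then the
binary classifier for the final call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from numba import njit

from .contexts import ContextSequence, GenomicSite
from .distances import encode_all
from .exceptions import LengthMismatchError, ParameterError
from .io import revcomp
from .model import TrainedModel, predict

logger = logging.getLogger(__name__)

_N = 78


@dataclass(frozen=True)
class ScanHit:
    chrom: str
    pos: int  # 1-based center position
    strand: str
    context: ContextSequence
    oneclass_pass: bool | None = None
    binary_label: int | None = None
    decision_value: float | None = None
    seed_id: int | None = None
    mismatches: int | None = None

    @property
    def site(self) -> GenomicSite:
        return GenomicSite(self.chrom, self.pos, self.strand)


def enumerate_candidates(genome: Mapping[str, str], l1: int
                         ) -> Iterator[tuple[GenomicSite, ContextSequence]]:
    """Yield every adenine-centered candidate on both strands.

    Forward 'A' -> '+' candidate; forward 'T' -> '-' candidate with a
    reverse-complemented context. Positions whose window would leave the
    contig, and N-rich windows, are skipped (counted at debug level).
    """
    if l1 % 2 == 0:
        raise ParameterError(f"l1 must be odd, got {l1}")
    flank = l1 // 2
    n_edge = 0
    for chrom, contig in genome.items():
        contig = contig.upper()
        n = len(contig)
        n_edge += min(n, 2 * flank)
        for i in range(flank, n - flank):
            base = contig[i]
            if base == "A":
                strand = "+"
            elif base == "T":
                strand = "-"
            else:
                continue
            window = contig[i - flank : i + flank + 1]
            if window.count("N") > 0.2 * l1:
                continue
            if strand == "-":
                window = revcomp(window)
            site = GenomicSite(chrom, i + 1, strand)
            yield site, ContextSequence(window, origin=site)
    logger.debug("enumerate_candidates: %d edge positions skipped", n_edge)


@njit(cache=True)
def _mismatch_scan(contig, seeds, max_mm):  # pragma: no cover
    L = seeds.shape[1]
    k = seeds.shape[0]
    n = contig.shape[0] - L + 1
    cap = 1024
    starts = np.empty(cap, np.int64)
    seed_ids = np.empty(cap, np.int64)
    mms = np.empty(cap, np.int64)
    cnt = 0
    for i in range(n):
        best_mm = max_mm + 1
        best_s = -1
        for s in range(k):
            mm = 0
            for j in range(L):
                c = contig[i + j]
                if c != seeds[s, j] or c == _N:
                    mm += 1
                    if mm > max_mm:
                        break
            if mm <= max_mm and mm < best_mm:
                best_mm = mm
                best_s = s
                if mm == 0:
                    break
        if best_s >= 0:
            if cnt == cap:
                cap *= 2
                ns = np.empty(cap, np.int64); ns[:cnt] = starts[:cnt]; starts = ns
                ni = np.empty(cap, np.int64); ni[:cnt] = seed_ids[:cnt]; seed_ids = ni
                nm = np.empty(cap, np.int64); nm[:cnt] = mms[:cnt]; mms = nm
            starts[cnt] = i
            seed_ids[cnt] = best_s
            mms[cnt] = best_mm
            cnt += 1
    return starts[:cnt], seed_ids[:cnt], mms[:cnt]


def seed_match(seeds: Sequence, genome: Mapping[str, str],
               max_mismatch: int = 0) -> list[ScanHit]:
    """Find genome windows within ``max_mismatch`` substitutions of a seed.

    Both orientations are searched (a '-' hit means the reverse
    complement of the forward window matches the seed). Exact matching
    uses a hash index; mismatch matching is an early-exit scan. Hits at
    the same (chrom, pos, strand) are merged keeping the lowest-mismatch
    seed (ties broken by seed input order).
    """
    if not 0 <= max_mismatch <= 3:
        raise ParameterError(
            f"max_mismatch must be in 0..3, got {max_mismatch}"
        )
    seed_strs = [(s.seq if hasattr(s, "seq") else str(s)).upper() for s in seeds]
    if not seed_strs:
        return []
    if len({len(s) for s in seed_strs}) > 1:
        raise LengthMismatchError("seeds must share one length")
    L = len(seed_strs[0])
    flank = L // 2
    best: dict[tuple[str, int, str], tuple[int, int, str]] = {}

    def _offer(chrom, start, strand, seed_idx, mm, window):
        key = (chrom, start + flank + 1, strand)
        ctx = window if strand == "+" else revcomp(window)
        cur = best.get(key)
        if cur is None or mm < cur[0] or (mm == cur[0] and seed_idx < cur[1]):
            best[key] = (mm, seed_idx, ctx)

    if max_mismatch == 0:
        fwd = {}
        rc = {}
        for idx, s in enumerate(seed_strs):
            fwd.setdefault(s, idx)
            rc.setdefault(revcomp(s), idx)
        for chrom, contig in genome.items():
            contig = contig.upper()
            for i in range(len(contig) - L + 1):
                w = contig[i : i + L]
                if w in fwd:
                    _offer(chrom, i, "+", fwd[w], 0, w)
                if w in rc:
                    _offer(chrom, i, "-", rc[w], 0, w)
    else:
        S = encode_all(seed_strs)
        RC = encode_all([revcomp(s) for s in seed_strs])
        for chrom, contig in genome.items():
            arr = np.frombuffer(contig.upper().encode("ascii"), dtype=np.uint8)
            if arr.shape[0] < L:
                continue
            for strand, mat in (("+", S), ("-", RC)):
                starts, ids, mms = _mismatch_scan(arr, mat, max_mismatch)
                for i, sid, mm in zip(starts, ids, mms):
                    w = contig[i : i + L].upper()
                    _offer(chrom, int(i), strand, int(sid), int(mm), w)

    hits = [
        ScanHit(chrom=c, pos=p, strand=st,
                context=ContextSequence(ctx, origin=GenomicSite(c, p, st)),
                seed_id=sid, mismatches=mm)
        for (c, p, st), (mm, sid, ctx) in best.items()
    ]
    hits.sort(key=lambda h: (h.chrom, h.pos, h.strand))
    logger.info("seed_match: %d hits at max_mismatch=%d", len(hits), max_mismatch)
    return hits


def _as_hit(cand) -> ScanHit:
    if isinstance(cand, ScanHit):
        return cand
    site, ctx = cand
    return ScanHit(chrom=site.chrom, pos=site.pos, strand=site.strand, context=ctx)


def two_stage_scan(candidates: Iterable, oneclass_model: TrainedModel,
                   binary_model: TrainedModel) -> list[ScanHit]:
    """One-class pre-filter followed by the binary call.

    Candidates the one-class model labels -1 are dropped; survivors are
    returned with ``binary_label`` and ``decision_value`` populated
    (putative editing sites are those with binary_label == +1).
    """
    if oneclass_model.mode != "one-class" or binary_model.mode != "binary":
        raise ParameterError("expected (one-class, binary) models in that order")
    if oneclass_model.dp != binary_model.dp or oneclass_model.kp != binary_model.kp:
        raise ParameterError(
            "one-class and binary models must share distance/kernel parameters"
        )
    hits = [_as_hit(c) for c in candidates]
    if not hits:
        return []
    seqs = [h.context.seq for h in hits]
    oc_labels, _ = predict(oneclass_model, seqs)
    survivors = [h for h, lab in zip(hits, oc_labels) if lab == 1]
    logger.info("two_stage_scan: %d candidates, %d pass one-class",
                len(hits), len(survivors))
    if not survivors:
        return []
    bin_labels, bin_dv = predict(binary_model, [h.context.seq for h in survivors])
    out = [
        replace(h, oneclass_pass=True, binary_label=int(lab),
                decision_value=float(dv))
        for h, lab, dv in zip(survivors, bin_labels, bin_dv)
    ]
    logger.info("two_stage_scan: %d binary positives",
                sum(1 for h in out if h.binary_label == 1))
    return out


_TSV_HEADER = ("chrom", "pos", "strand", "context", "oneclass_pass",
               "binary_label", "decision_value", "mismatches", "seed_id")


def write_hits(hits: Sequence[ScanHit], path, format: str = "tsv") -> None:
    """Write hits as TSV (all fields) or BED6, ordered by (chrom, pos, strand).

    BED scores rescale the decision values to [0, 1000] (min-max over the
    written hits; 500 when degenerate).
    """
    if format not in ("tsv", "bed"):
        raise ParameterError(f"format must be 'tsv' or 'bed', got {format!r}")
    hits = sorted(hits, key=lambda h: (h.chrom, h.pos, h.strand))
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("#" + "\t".join(_TSV_HEADER) + "\n")
            for h in hits:
                fh.write("\t".join(str(x) if x is not None else "." for x in (
                    h.chrom, h.pos, h.strand, h.context.seq, h.oneclass_pass,
                    h.binary_label, h.decision_value, h.mismatches, h.seed_id,
                )) + "\n")
        return
    dvs = np.array([h.decision_value if h.decision_value is not None else np.nan
                    for h in hits], dtype=float)
    finite = np.isfinite(dvs)
    scores = np.zeros(len(hits), dtype=int)
    if finite.any():
        lo, hi = dvs[finite].min(), dvs[finite].max()
        if hi > lo:
            scores[finite] = np.round((dvs[finite] - lo) / (hi - lo) * 1000).astype(int)
        else:
            scores[finite] = 500
    with open(path, "w") as fh:
        for i, h in enumerate(hits):
            fh.write(f"{h.chrom}\t{h.pos - 1}\t{h.pos}\thit{i + 1}\t"
                     f"{scores[i]}\t{h.strand}\n")


def read_hits_tsv(path) -> list[ScanHit]:
    """Read back a TSV written by :func:`write_hits`."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            (chrom, pos, strand, ctx, oc, lab, dv, mm, sid) = \
                line.rstrip("\n").split("\t")
            site = GenomicSite(chrom, int(pos), strand)
            out.append(ScanHit(
                chrom=chrom, pos=int(pos), strand=strand,
                context=ContextSequence(ctx, origin=site),
                oneclass_pass=None if oc == "." else oc == "True",
                binary_label=None if lab == "." else int(lab),
                decision_value=None if dv == "." else float(dv),
                mismatches=None if mm == "." else int(mm),
                seed_id=None if sid == "." else int(sid),
            ))
    return out
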