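"""Readers and writers for the plain-text formats editscan exchanges.

Genomes are held in memory as ``{contig_name: uppercase_sequence}``
mappings — adequate for desk-scale genomes (tens of Mb). FASTA parsing is
delegated to Biopython; everything else is simple TSV/BED.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .exceptions import ParameterError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

FASTA_WIDTH = 60


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    Record names are truncated at the first whitespace; sequences are
    uppercased.
    """
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise ParameterError(f"no FASTA records found in {path}")
    return genome


def write_fasta(genome: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WIDTH):
                fh.write(seq[i : i + FASTA_WIDTH] + "\n")


def read_sequences(path: str | os.PathLike) -> list[str]:
    """Read sequences from FASTA or one-sequence-per-line text."""
    with open(path) as fh:
        head = fh.read(1)
    if head == ">":
        return [seq for seq in read_fasta(path).values()]
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line.upper())
    return out


def write_sequences(seqs: Iterable[str], path: str | os.PathLike,
                    names: Sequence[str] | None = None) -> None:
    """Write sequences as FASTA (auto-named when ``names`` is omitted)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(seqs):
            name = names[i] if names is not None else f"seq{i + 1}"
            fh.write(f">{name}\n{seq}\n")


def read_sites(path: str | os.PathLike):
    """Read a site-list TSV: ``chrom  pos(1-based)  strand  [label]``.

    Lines starting with ``#`` are comments. Returns a list of
    ``(GenomicSite, label_or_None)`` tuples.
    """
    from .contexts import GenomicSite

    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParameterError(
                    f"{path}:{ln}: expected at least 3 tab-separated columns"
                )
            chrom, pos, strand = parts[0], parts[1], parts[2]
            label = parts[3] if len(parts) > 3 else None
            out.append((GenomicSite(chrom, int(pos), strand), label))
    return out


def write_sites(sites, path: str | os.PathLike, labels=None) -> None:
    """Write a site-list TSV with a ``#`` header (1-based positions)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tstrand\tlabel\n")
        for i, site in enumerate(sites):
            label = labels[i] if labels is not None else ""
            fh.write(f"{site.chrom}\t{site.pos}\t{site.strand}\t{label}\n")


def write_bed6(sites, path: str | os.PathLike, names=None, scores=None) -> None:
    """Write sites as BED6 (0-based half-open single-base intervals)."""
    with open(path, "w") as fh:
        for i, site in enumerate(sites):
            name = names[i] if names is not None else f"site{i + 1}"
            score = scores[i] if scores is not None else 0
            fh.write(
                f"{site.chrom}\t{site.pos - 1}\t{site.pos}\t{name}\t"
                f"{score}\t{site.strand}\n"
            )
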