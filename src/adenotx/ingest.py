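"""Spliced long-read alignment ingest.

Converts SAM/BAM records aligned to the viral genome into per-read exon
chains (ordered genomic blocks split at N CIGAR operations) with polyA-tail
evidence taken from the 3' soft clip. Direct RNA-seq reads are sequenced from
the polyA tail, so retained reads are 3'-anchored and the tail shows up as a
soft-clipped A-run next to the transcript's 3' end.

Retention filters follow the one-best-placement-per-read model implied by the
percentage tables downstream: primary alignments to the viral reference only,
above a mapping-quality floor. Antisense placements are retained with their
strand recorded; they simply fail ORF naming later.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path

import pysam

from .genome import revcomp

log = logging.getLogger(__name__)

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")


class CigarError(ValueError):
    """Raised for malformed CIGAR strings; carries the character offset."""


@dataclass(frozen=True)
class ExonChain:
    """One read's footprint on the genome.

    ``blocks`` are 0-based half-open genomic intervals, strictly increasing
    and separated by at least 1 nt (the introns). ``polya_len`` is the
    measured soft-clipped polyA tail.
    """

    read_id: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    polya_len: int = 0
    mapq: int = 0
    sample: str = ""

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"{self.read_id}: chain needs at least one block")
        prev_end = None
        for s, e in self.blocks:
            if e - s < 1:
                raise ValueError(f"{self.read_id}: empty block ({s},{e})")
            if prev_end is not None and s - prev_end < 1:
                raise ValueError(f"{self.read_id}: blocks overlap or touch at {s}")
            prev_end = e

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Half-open (donor, acceptor) intervals between consecutive blocks."""
        return tuple(
            (self.blocks[i][1], self.blocks[i + 1][0]) for i in range(len(self.blocks) - 1)
        )

    @property
    def five_prime(self) -> int:
        """0-based genomic position of the transcript's first base."""
        return self.blocks[0][0] if self.strand == "+" else self.blocks[-1][1] - 1

    @property
    def three_prime(self) -> int:
        """0-based genomic position of the transcript's last base."""
        return self.blocks[-1][1] - 1 if self.strand == "+" else self.blocks[0][0]

    @property
    def span_len(self) -> int:
        return sum(e - s for s, e in self.blocks)


def cigar_to_blocks(pos: int, cigar: str) -> tuple[tuple[int, int], ...]:
    """Reference blocks of an alignment starting at 1-based ``pos``.

    M/=/X/D consume reference within a block, N splits blocks, I/S/H/P
    consume none. Output is 0-based half-open.
    """
    if pos < 1:
        raise ValueError(f"alignment position must be >= 1, got {pos}")
    blocks: list[tuple[int, int]] = []
    ref = pos - 1
    block_start = ref
    offset = 0
    for m in _CIGAR_TOKEN.finditer(cigar):
        if m.start() != offset:
            raise CigarError(f"malformed CIGAR {cigar!r} at offset {offset}")
        offset = m.end()
        n, op = int(m.group(1)), m.group(2)
        if n == 0:
            raise CigarError(f"zero-length op {op} in {cigar!r} at offset {m.start()}")
        if op in "M=XD":
            ref += n
        elif op == "N":
            if ref > block_start:
                blocks.append((block_start, ref))
            ref += n
            block_start = ref
        # I, S, H, P consume no reference
    if offset != len(cigar) or not cigar:
        raise CigarError(f"malformed CIGAR {cigar!r} at offset {offset}")
    if ref > block_start:
        blocks.append((block_start, ref))
    if not blocks:
        raise CigarError(f"CIGAR {cigar!r} consumes no reference")
    return tuple(blocks)


def blocks_to_cigar(blocks: tuple[tuple[int, int], ...], clip5: int = 0, clip3: int = 0) -> str:
    """Pure match/skip CIGAR for a block chain, with optional soft clips."""
    parts: list[str] = []
    if clip5:
        parts.append(f"{clip5}S")
    for i, (s, e) in enumerate(blocks):
        if i:
            parts.append(f"{s - blocks[i - 1][1]}N")
        parts.append(f"{e - s}M")
    if clip3:
        parts.append(f"{clip3}S")
    return "".join(parts)


def detect_polya(soft_clip_seq: str, search_window: int = 5) -> int:
    """Length of the longest A-run starting within the first few clipped bases.

    ``soft_clip_seq`` must be oriented in read direction, beginning at the
    base adjacent to the transcript's 3' end. Returns 0 when no run starts
    inside the window.
    """
    best = 0
    for m in re.finditer(r"A+", soft_clip_seq):
        if m.start() >= search_window:
            break
        best = max(best, m.end() - m.start())
    return best


def _clip_3prime(read: pysam.AlignedSegment) -> str:
    """3'-side soft-clipped bases, oriented in read direction."""
    ct = read.cigartuples or []
    seq = read.query_sequence or ""
    if read.is_reverse:
        if ct and ct[0][0] == 4:  # leading S holds the (reverse-complemented) tail
            return revcomp(seq[: ct[0][1]])
    else:
        if ct and ct[-1][0] == 4:
            return seq[len(seq) - ct[-1][1]:]
    return ""


def load_alignments(
    path: str | Path,
    reference: str,
    min_mapq: int = 1,
    sample: str = "",
) -> list[ExonChain]:
    """Read a SAM/BAM file and return one ExonChain per retained read.

    Keeps primary alignments to ``reference`` with mapq >= ``min_mapq``;
    secondary, supplementary and unmapped records are dropped, as are reads
    placed on any other reference (host / control filtering is assumed done
    upstream by the aligner run, but other references present in the file are
    ignored here as well).
    """
    chains: list[ExonChain] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        if reference not in fh.references:
            raise ValueError(
                f"reference {reference!r} absent from {path}; available: {list(fh.references)}"
            )
        n_dropped = 0
        for read in fh.fetch(until_eof=True) if fh.has_index() else fh:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                n_dropped += 1
                continue
            if read.reference_name != reference or read.mapping_quality < min_mapq:
                n_dropped += 1
                continue
            blocks = cigar_to_blocks(read.reference_start + 1, read.cigarstring)
            chains.append(
                ExonChain(
                    read_id=read.query_name,
                    strand="-" if read.is_reverse else "+",
                    blocks=blocks,
                    polya_len=detect_polya(_clip_3prime(read)),
                    mapq=read.mapping_quality,
                    sample=sample,
                )
            )
    log.info("%s: retained %d chains (%d records dropped)", path, len(chains), n_dropped)
    return chains
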