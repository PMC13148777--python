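"""Collapse exon chains into transcript classes.

A transcript class is defined by its junction signature (the ordered list of
intron donor/acceptor coordinates on one strand) plus clustered transcript
ends. Nanopore junction wobble is absorbed in two steps:

1. junction snapping: each observed intron within a small tolerance of a
   unique self-trained "known" intron is moved onto it;
2. end clustering: within a signature group, 5' ends are gathered around the
   modal 5' position (direct RNA-seq piles full-length reads onto the true
   start, while 5'-truncated reads smear downstream and seed their own
   classes), and 3' ends are joined by single linkage, splitting only at gaps
   wider than the end window (tails are 3'-anchored, so genuine polyA sites
   are far apart).

Intron validation checks the first and last two intron bases on the
transcript strand against the canonical spliceosomal GT..AG motif (GU:AG on
the RNA).
"""

from __future__ import annotations

import csv
import logging
import statistics
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .genome import Genome, revcomp
from .ingest import ExonChain

log = logging.getLogger(__name__)

DEFAULT_SNAP_TOL = 3
DEFAULT_TSS_WINDOW = 50
DEFAULT_END_WINDOW = 30
DEFAULT_MIN_KNOWN_COUNT = 5


@dataclass
class TranscriptClass:
    """A collapsed isoform: junction signature, representative ends, counts."""

    class_id: str
    strand: str
    introns: tuple[tuple[int, int], ...]
    rep_start: int  # 0-based position of the 5'-most transcript base
    rep_end: int    # 0-based position of the 3'-most transcript base
    counts: dict[str, int] = field(default_factory=dict)
    member_ids: tuple[str, ...] = ()
    polya_median: float = 0.0
    intron_motifs: tuple[str, ...] = ()
    canonical: tuple[bool, ...] = ()

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def blocks(self) -> tuple[tuple[int, int], ...]:
        """Representative exon blocks rebuilt from the signature and ends."""
        gmin = min(self.rep_start, self.rep_end)
        gmax = max(self.rep_start, self.rep_end) + 1
        edges = [gmin]
        for d, a in self.introns:
            edges.extend([d, a])
        edges.append(gmax)
        return tuple((edges[i], edges[i + 1]) for i in range(0, len(edges), 2))

    @property
    def exonic_len(self) -> int:
        return sum(e - s for s, e in self.blocks)


def learn_known_introns(
    chains: Iterable[ExonChain],
    min_count: int = DEFAULT_MIN_KNOWN_COUNT,
    tol: int = DEFAULT_SNAP_TOL,
    extra: Iterable[tuple[int, int]] = (),
) -> set[tuple[int, int]]:
    """Self-train the known-intron set used for junction snapping.

    Introns seen at least ``min_count`` times are candidates; candidates
    within the snap tolerance of a more frequent candidate are suppressed so
    the survivors are unambiguous snap targets (non-maximum suppression).
    User-supplied introns in ``extra`` are always kept.
    """
    counts: Counter[tuple[int, int]] = Counter()
    for chain in chains:
        counts.update(chain.introns)
    ranked = sorted(
        (iv for iv, n in counts.items() if n >= min_count),
        key=lambda iv: (-counts[iv], iv),
    )
    known: set[tuple[int, int]] = set(extra)
    for d, a in ranked:
        if any(abs(d - kd) <= tol and abs(a - ka) <= tol for kd, ka in known):
            continue
        known.add((d, a))
    return known


def correct_junctions(
    chain: ExonChain,
    known: Iterable[tuple[int, int]],
    tol: int = DEFAULT_SNAP_TOL,
) -> ExonChain:
    """Snap each intron within ``tol`` nt (both ends) of a unique known intron.

    Ambiguous introns (two known introns equally near) are left unchanged with
    a warning. ``tol=0`` returns the chain unchanged.
    """
    if tol <= 0 or not chain.introns:
        return chain
    known = list(known)
    new_introns: list[tuple[int, int]] = []
    changed = False
    for d, a in chain.introns:
        cands = [
            (max(abs(d - kd), abs(a - ka)), abs(d - kd) + abs(a - ka), kd, ka)
            for kd, ka in known
            if abs(d - kd) <= tol and abs(a - ka) <= tol
        ]
        if not cands:
            new_introns.append((d, a))
            continue
        cands.sort()
        if len(cands) > 1 and cands[0][:2] == cands[1][:2]:
            log.warning(
                "%s: intron (%d,%d) equidistant from two known introns; not snapped",
                chain.read_id, d, a,
            )
            new_introns.append((d, a))
            continue
        kd, ka = cands[0][2], cands[0][3]
        if (kd, ka) != (d, a):
            changed = True
        new_introns.append((kd, ka))
    if not changed:
        return chain
    # rebuild blocks around the snapped introns, conserving the outer ends
    edges = [chain.blocks[0][0]]
    for d, a in new_introns:
        edges.extend([d, a])
    edges.append(chain.blocks[-1][1])
    blocks = tuple((edges[i], edges[i + 1]) for i in range(0, len(edges), 2))
    return replace(chain, blocks=blocks)


def _median_end(values: Sequence[int], strand: str) -> int:
    """Median with even-count ties broken toward the 5'-most coordinate."""
    vals = sorted(values)
    n = len(vals)
    if n % 2:
        return vals[n // 2]
    lo, hi = vals[n // 2 - 1], vals[n // 2]
    return lo if strand == "+" else hi


def cluster_reads(
    chains: Iterable[ExonChain],
    tss_window: int = DEFAULT_TSS_WINDOW,
    end_window: int = DEFAULT_END_WINDOW,
) -> list[TranscriptClass]:
    """Collapse junction-corrected chains into transcript classes.

    Deterministic and order-independent: permuting the input yields identical
    classes and counts. Every chain lands in exactly one class.
    """
    groups: dict[tuple[str, tuple[tuple[int, int], ...]], list[ExonChain]] = defaultdict(list)
    for chain in chains:
        groups[(chain.strand, chain.introns)].append(chain)

    classes: list[TranscriptClass] = []
    for (strand, introns) in sorted(groups, key=lambda k: (k[0], k[1])):
        members = sorted(
            groups[(strand, introns)],
            key=lambda c: (c.five_prime, c.three_prime, c.read_id),
        )
        remaining = members
        while remaining:
            tally = Counter(c.five_prime for c in remaining)
            # modal 5' end; ties broken toward the 5'-most coordinate
            if strand == "+":
                anchor = min(tally, key=lambda v: (-tally[v], v))
            else:
                anchor = max(tally, key=lambda v: (tally[v], v))
            hit = [c for c in remaining if abs(c.five_prime - anchor) <= tss_window]
            remaining = [c for c in remaining if abs(c.five_prime - anchor) > tss_window]
            # 3' single linkage: split only at gaps wider than end_window
            hit.sort(key=lambda c: (c.three_prime, c.five_prime, c.read_id))
            sub: list[ExonChain] = []
            for c in hit:
                if sub and abs(c.three_prime - sub[-1].three_prime) > end_window:
                    classes.append(_make_class(strand, introns, sub))
                    sub = []
                sub.append(c)
            if sub:
                classes.append(_make_class(strand, introns, sub))

    classes.sort(key=lambda c: (c.strand, min(c.rep_start, c.rep_end), c.introns, c.rep_end))
    for i, cls in enumerate(classes):
        cls.class_id = f"c{i + 1:05d}"
    return classes


def _make_class(
    strand: str, introns: tuple[tuple[int, int], ...], members: list[ExonChain]
) -> TranscriptClass:
    return TranscriptClass(
        class_id="",
        strand=strand,
        introns=introns,
        rep_start=_median_end([c.five_prime for c in members], strand),
        rep_end=_median_end([c.three_prime for c in members], strand),
        counts=dict(sorted(Counter(c.sample for c in members).items())),
        member_ids=tuple(sorted(c.read_id for c in members)),
        polya_median=float(statistics.median(c.polya_len for c in members)),
    )


def validate_introns(genome: Genome, cls: TranscriptClass) -> list[tuple[str, bool]]:
    """Per-intron splice motif (transcript strand) and canonical GT..AG flag.

    Introns shorter than 4 nt are flagged non-canonical with a sentinel motif.
    """
    out: list[tuple[str, bool]] = []
    for d, a in cls.introns:
        if a - d < 4:
            out.append((f"len{a - d}", False))
            continue
        if cls.strand == "+":
            motif = f"{genome.slice(d, d + 2)}..{genome.slice(a - 2, a)}"
        else:
            motif = f"{revcomp(genome.slice(a - 2, a))}..{revcomp(genome.slice(d, d + 2))}"
        out.append((motif, motif == "GT..AG"))
    return out


def annotate_introns(genome: Genome, classes: Iterable[TranscriptClass]) -> None:
    """Fill ``intron_motifs`` and ``canonical`` on each class in place."""
    for cls in classes:
        res = validate_introns(genome, cls)
        cls.intron_motifs = tuple(m for m, _ in res)
        cls.canonical = tuple(ok for _, ok in res)


def _introns_str(introns: tuple[tuple[int, int], ...]) -> str:
    return ",".join(f"{d}-{a}" for d, a in introns)


def _parse_introns(text: str) -> tuple[tuple[int, int], ...]:
    if not text:
        return ()
    out = []
    for part in text.split(","):
        d, a = part.split("-")
        out.append((int(d), int(a)))
    return tuple(out)


def write_classes(
    classes: Sequence[TranscriptClass], samples: Sequence[str], path: str | Path
) -> None:
    """Class table TSV: id, strand, ends, introns, motifs, per-sample counts."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["class_id", "strand", "rep_start", "rep_end", "introns",
             "intron_motifs", "canonical_flags", "polya_median"]
            + [f"count_{s}" for s in samples]
        )
        for cls in classes:
            writer.writerow(
                [cls.class_id, cls.strand, cls.rep_start, cls.rep_end,
                 _introns_str(cls.introns), ",".join(cls.intron_motifs),
                 ",".join("1" if c else "0" for c in cls.canonical),
                 f"{cls.polya_median:g}"]
                + [cls.counts.get(s, 0) for s in samples]
            )


def read_classes(path: str | Path) -> tuple[list[TranscriptClass], list[str]]:
    """Read a class table written by :func:`write_classes`.

    Member read ids are not serialized; everything else round-trips exactly.
    """
    classes: list[TranscriptClass] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        samples = [c[len("count_"):] for c in reader.fieldnames or [] if c.startswith("count_")]
        for row in reader:
            motifs = tuple(m for m in row["intron_motifs"].split(",") if m)
            flags = tuple(c == "1" for c in row["canonical_flags"].split(",") if c)
            classes.append(
                TranscriptClass(
                    class_id=row["class_id"],
                    strand=row["strand"],
                    introns=_parse_introns(row["introns"]),
                    rep_start=int(row["rep_start"]),
                    rep_end=int(row["rep_end"]),
                    counts={s: int(row[f"count_{s}"]) for s in samples},
                    polya_median=float(row["polya_median"]),
                    intron_motifs=motifs,
                    canonical=flags,
                )
            )
    return classes, samples
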