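"""ORF-centric naming of transcript classes.

A transcript is defined as coding for an ORF when its 5'-most start codon is
the initiating methionine of that ORF — the first ATG of the spliced
transcript sequence, mapped back to the genome, must sit exactly on the
catalogued coding start. This first-ATG rule is absolute: Kozak context is
not modelled.

Beyond the direct match, three more outcomes are recognised:

* ``variant_bysplicing`` — the first ATG is an internal, in-frame ATG of a
  catalogued ORF whose annotated start was removed or bypassed by a splice
  inside the coding region. The adenoviral exemplar is the transcript
  equivalent to mature protein VII: a splice donor in the tripartite leader
  joins an acceptor inside pVII's precursor-coding region, so translation
  starts at the methionine at the protease-cleavage boundary.
* ``truncated`` — the class is a 3'-compatible sub-chain of a named class
  (its introns are a suffix of the parent's, its exons fall inside the
  parent's exons, its 3' end matches) whose 5' end lies well downstream of
  the parent's start. These are the 5'-decayed direct-RNA reads that pile up
  in the unnamed bin.
* ``none_from_list`` — everything else: the first start codon initiates no
  catalogued ORF.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio.Seq import Seq

from .classify import DEFAULT_END_WINDOW, DEFAULT_TSS_WINDOW, TranscriptClass
from .genome import FeatureTable, Genome, OrfFeature, revcomp

log = logging.getLogger(__name__)

CODES_ORF = "codes_orf"
VARIANT_BYSPLICING = "variant_bysplicing"
TRUNCATED = "truncated"
NONE_FROM_LIST = "none_from_list"
CATEGORIES = (CODES_ORF, VARIANT_BYSPLICING, TRUNCATED, NONE_FROM_LIST)

DEFAULT_MIN_COUNT = 2


@dataclass
class NamedClass:
    cls: TranscriptClass
    category: str
    orf_name: str = ""
    display_name: str = ""
    protein_seq: str = ""
    run_through: bool = False
    low_confidence: bool = False


def splice_sequence(genome: Genome, blocks: Sequence[tuple[int, int]], strand: str) -> str:
    """Spliced transcript sequence, 5'->3' on the sense strand."""
    seq = "".join(genome.slice(s, e) for s, e in blocks)
    return seq if strand == "+" else revcomp(seq)


def first_start_codon(seq: str) -> Optional[int]:
    """Offset of the 5'-most ATG, or None."""
    off = seq.find("ATG")
    return None if off < 0 else off


def translate(seq: str, offset: int) -> tuple[str, bool]:
    """Standard-code translation from ``offset`` to the first stop.

    Returns (protein, run_through); ``run_through`` is True when no stop codon
    occurs before the end of the sequence.
    """
    if seq[offset : offset + 3] != "ATG":
        raise ValueError(f"no ATG at offset {offset}")
    coding = seq[offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    prot = str(Seq(coding).translate())
    if "*" in prot:
        return prot.split("*", 1)[0], False
    return prot, True


def transcript_to_genomic(
    blocks: Sequence[tuple[int, int]], strand: str, offset: int
) -> int:
    """Genomic position of transcript base ``offset`` (0-based, sense)."""
    walk = list(blocks) if strand == "+" else [(s, e) for s, e in reversed(blocks)]
    remaining = offset
    for s, e in walk:
        ln = e - s
        if remaining < ln:
            return s + remaining if strand == "+" else e - 1 - remaining
        remaining -= ln
    raise ValueError(f"offset {offset} beyond transcript of length {sum(e - s for s, e in blocks)}")


def variant_label(orf_name: str) -> str:
    """ORF label used in a by-splicing variant's display name.

    The precursor prefix is stripped so the variant reads as the mature form
    (feature "preVII" -> variant label "VII", matching the L2_VII_bysplicing
    convention).
    """
    return orf_name[3:] if orf_name.startswith("pre") else orf_name


def display_for(feat: OrfFeature, category: str) -> str:
    base = feat.name if feat.name == feat.region else f"{feat.region}_{feat.name}"
    if category == CODES_ORF:
        return base
    if category == VARIANT_BYSPLICING:
        return f"{feat.region}_{variant_label(feat.name)}_bysplicing"
    raise ValueError(category)


def _upstream(strand: str, a: int, b: int) -> bool:
    """True when genomic position ``a`` is 5' of ``b`` on ``strand``."""
    return a < b if strand == "+" else a > b


def _in_annotated_frame(feat: OrfFeature, pos: int) -> bool:
    dist = pos - feat.cds_start if feat.strand == "+" else feat.cds_start - pos
    return dist % 3 == 0


def _splice_bypasses_start(cls: TranscriptClass, feat: OrfFeature, atg_pos: int) -> bool:
    """A splice inside the feature's coding region whose donor is 5' of the
    internal ATG (and whose acceptor lands at or before it)."""
    lo, hi = feat.cds_span
    for d, a in cls.introns:
        if cls.strand == "+":
            donor, exon_resume = d, a  # first exonic base after the intron
            if lo < exon_resume <= atg_pos and _upstream("+", donor, atg_pos):
                return True
        else:
            donor, exon_resume = a - 1, d - 1
            if atg_pos <= exon_resume < hi - 1 and _upstream("-", donor, atg_pos):
                return True
    return False


def _blocks_within(child: Sequence[tuple[int, int]], parent: Sequence[tuple[int, int]]) -> bool:
    return all(
        any(ps <= cs and ce <= pe for ps, pe in parent) for cs, ce in child
    )


def assign_orf(
    cls: TranscriptClass,
    features: FeatureTable,
    genome: Genome,
    parents: Sequence[NamedClass] = (),
    tss_window: int = DEFAULT_TSS_WINDOW,
    end_window: int = DEFAULT_END_WINDOW,
) -> NamedClass:
    """Categorise one transcript class against the ORF catalogue.

    ``parents`` are previously named coding classes, used only for the
    truncation check; omit them to classify in isolation.
    """
    seq = splice_sequence(genome, cls.blocks, cls.strand)
    off = first_start_codon(seq)
    if off is not None:
        g = transcript_to_genomic(cls.blocks, cls.strand, off)
        cands = [f for f in features if f.strand == cls.strand and f.cds_start == g]
        if cands:
            if len(cands) > 1:
                cands.sort(key=lambda f: (abs(f.expected_tss - cls.rep_start), f.name))
                log.warning(
                    "%s: first ATG matches several ORF starts (%s); choosing %s by expected TSS",
                    cls.class_id, ",".join(f.name for f in cands), cands[0].name,
                )
            feat = cands[0]
            prot, run_through = translate(seq, off)
            return NamedClass(
                cls=cls, category=CODES_ORF, orf_name=feat.name,
                display_name=display_for(feat, CODES_ORF),
                protein_seq=prot, run_through=run_through,
            )
        variants = []
        for f in features:
            if f.strand != cls.strand or f.cds_start == g:
                continue
            lo, hi = f.cds_span
            if not (lo < g < hi - 1):
                continue
            if not _in_annotated_frame(f, g):
                continue
            if _splice_bypasses_start(cls, f, g):
                variants.append(f)
        if variants:
            variants.sort(key=lambda f: (abs(g - f.cds_start), f.name))
            feat = variants[0]
            prot, run_through = translate(seq, off)
            return NamedClass(
                cls=cls, category=VARIANT_BYSPLICING, orf_name=feat.name,
                display_name=display_for(feat, VARIANT_BYSPLICING),
                protein_seq=prot, run_through=run_through,
            )
    parent = _find_truncation_parent(cls, parents, tss_window, end_window)
    if parent is not None:
        return NamedClass(
            cls=cls, category=TRUNCATED, orf_name=parent.orf_name, display_name=TRUNCATED
        )
    return NamedClass(cls=cls, category=NONE_FROM_LIST, display_name=NONE_FROM_LIST)


def _find_truncation_parent(
    cls: TranscriptClass,
    parents: Sequence[NamedClass],
    tss_window: int,
    end_window: int,
) -> Optional[NamedClass]:
    hits = []
    for parent in parents:
        p = parent.cls
        if p.strand != cls.strand:
            continue
        k = len(cls.introns)
        if k > len(p.introns) or (k and p.introns[len(p.introns) - k:] != cls.introns):
            continue
        # 5' end well downstream of the parent's start
        if cls.strand == "+":
            if cls.rep_start <= p.rep_start + tss_window:
                continue
        else:
            if cls.rep_start >= p.rep_start - tss_window:
                continue
        if abs(cls.rep_end - p.rep_end) > end_window:
            continue
        if not _blocks_within(cls.blocks, p.blocks):
            continue
        hits.append(parent)
    if not hits:
        return None
    hits.sort(key=lambda nc: (abs(cls.rep_end - nc.cls.rep_end), -nc.cls.total, nc.cls.class_id))
    return hits[0]


def name_classes(
    classes: Sequence[TranscriptClass],
    features: FeatureTable,
    genome: Genome,
    tss_window: int = DEFAULT_TSS_WINDOW,
    end_window: int = DEFAULT_END_WINDOW,
    min_count: int = DEFAULT_MIN_COUNT,
) -> list[NamedClass]:
    """Name every class: coding/variant first, then truncations against the
    named parents, everything else none_from_list.

    Classes below ``min_count`` total reads are kept but flagged
    low-confidence (the real data reports sub-0.5% transcripts, so there is
    no hard floor).
    """
    first_pass = [assign_orf(cls, features, genome) for cls in classes]
    parents = [nc for nc in first_pass if nc.category == CODES_ORF]
    named: list[NamedClass] = []
    for cls, nc in zip(classes, first_pass):
        if nc.category == NONE_FROM_LIST:
            nc = assign_orf(cls, features, genome, parents, tss_window, end_window)
        nc.low_confidence = cls.total < min_count
        named.append(nc)
    return named


NAMED_COLUMNS = ("category", "orf_name", "display_name", "protein_seq",
                 "run_through", "low_confidence")


def write_named(
    named: Sequence[NamedClass], samples: Sequence[str], path: str | Path
) -> None:
    """Named-class TSV: the class table columns plus naming columns."""
    from .classify import _introns_str  # shared formatting

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["class_id", "strand", "rep_start", "rep_end", "introns",
             "intron_motifs", "canonical_flags", "polya_median"]
            + [f"count_{s}" for s in samples]
            + list(NAMED_COLUMNS)
        )
        for nc in named:
            cls = nc.cls
            writer.writerow(
                [cls.class_id, cls.strand, cls.rep_start, cls.rep_end,
                 _introns_str(cls.introns), ",".join(cls.intron_motifs),
                 ",".join("1" if c else "0" for c in cls.canonical),
                 f"{cls.polya_median:g}"]
                + [cls.counts.get(s, 0) for s in samples]
                + [nc.category, nc.orf_name, nc.display_name, nc.protein_seq,
                   int(nc.run_through), int(nc.low_confidence)]
            )


def read_named(path: str | Path) -> tuple[list[NamedClass], list[str]]:
    from .classify import _parse_introns

    named: list[NamedClass] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        samples = [c[len("count_"):] for c in reader.fieldnames or [] if c.startswith("count_")]
        for row in reader:
            cls = TranscriptClass(
                class_id=row["class_id"],
                strand=row["strand"],
                introns=_parse_introns(row["introns"]),
                rep_start=int(row["rep_start"]),
                rep_end=int(row["rep_end"]),
                counts={s: int(row[f"count_{s}"]) for s in samples},
                polya_median=float(row["polya_median"]),
                intron_motifs=tuple(m for m in row["intron_motifs"].split(",") if m),
                canonical=tuple(c == "1" for c in row["canonical_flags"].split(",") if c),
            )
            named.append(
                NamedClass(
                    cls=cls,
                    category=row["category"],
                    orf_name=row["orf_name"],
                    display_name=row["display_name"],
                    protein_seq=row["protein_seq"],
                    run_through=row["run_through"] == "1",
                    low_confidence=row["low_confidence"] == "1",
                )
            )
    return named, samples


def export_unnamed_fasta(
    genome: Genome, named: Sequence[NamedClass], path: str | Path
) -> int:
    """FASTA of none_from_list transcript sequences (for external BLAST)."""
    n = 0
    with open(path, "w") as fh:
        for nc in named:
            if nc.category != NONE_FROM_LIST:
                continue
            seq = splice_sequence(genome, nc.cls.blocks, nc.cls.strand)
            fh.write(f">{nc.cls.class_id} total={nc.cls.total} strand={nc.cls.strand}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
            n += 1
    return n
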