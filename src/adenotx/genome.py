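"""Viral reference genome and ORF feature-table handling.

The feature table is the knowledge base that drives transcript naming: one row
per open reading frame (ORF) with its region label (E1A..E4, IX, IVa2, L1..L5),
strand, coding start/end, the transcription start site the transcript group is
expected to use, and the temporal expression class (early / intermediate /
late).

Coordinate conventions (used throughout the package):

* All internal coordinates are 0-based. SAM input (1-based) and BED output are
  converted at the boundary.
* For ``+`` strand features ``cds_start`` is the genomic position of the A of
  the initiating ATG and ``cds_end`` the exclusive end of the stop codon, so
  the CDS occupies ``[cds_start, cds_end)``.
* For ``-`` strand features coordinates follow the reading direction:
  ``cds_start`` is the genomic position of the A of the ATG *as read on the
  minus strand* (the larger coordinate) and ``cds_end`` is the exclusive end in
  reading direction, so the CDS occupies ``[cds_end + 1, cds_start + 1)`` on
  the genome.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}
TEMPORAL_CLASSES = ("early", "intermediate", "late")
TSV_COLUMNS = (
    "name",
    "region",
    "strand",
    "cds_start",
    "cds_end",
    "expected_tss",
    "temporal_class",
)


class GenomeFormatError(ValueError):
    """Raised for malformed genome FASTA input."""


class FeatureTableError(ValueError):
    """Raised for invalid ORF feature tables."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Genome:
    """A single viral reference sequence over the alphabet A/C/G/T/N."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise GenomeFormatError("genome sequence is empty")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise GenomeFormatError(
                f"invalid character {self.sequence[pos]!r} at position {pos}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Sequence of the half-open interval ``[start, end)``."""
        if start < 0 or end > self.length or start >= end:
            raise ValueError(f"interval [{start}, {end}) outside genome of length {self.length}")
        return self.sequence[start:end]


def load_genome(path: str | Path) -> Genome:
    """Load a genome FASTA; uppercases and converts U to T.

    If the file holds several records the first is used and a warning logged.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GenomeFormatError(f"no FASTA records in {path}")
    if len(records) > 1:
        log.warning(
            "%s contains %d records; using the first (%s)", path, len(records), records[0].id
        )
    rec = records[0]
    seq = str(rec.seq).upper().replace("U", "T")
    if not seq:
        raise GenomeFormatError(f"record {rec.id} in {path} is empty")
    return Genome(name=rec.id, sequence=seq)


def write_genome(genome: Genome, path: str | Path, description: str = "") -> None:
    with open(path, "w") as fh:
        header = f">{genome.name} {description}".rstrip()
        fh.write(header + "\n")
        for i in range(0, genome.length, 70):
            fh.write(genome.sequence[i : i + 70] + "\n")


def expected_temporal_class(region: str) -> Optional[str]:
    """Default region -> temporal class mapping (E* early; IX/IVa2 intermediate; L* late)."""
    if region in ("IX", "IVa2"):
        return "intermediate"
    if region.startswith("E"):
        return "early"
    if region.startswith("L"):
        return "late"
    return None


@dataclass(frozen=True)
class OrfFeature:
    """One catalogued viral ORF."""

    name: str
    region: str
    strand: str
    cds_start: int
    cds_end: int
    expected_tss: int
    temporal_class: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FeatureTableError(f"{self.name}: strand must be + or -, got {self.strand!r}")
        if self.temporal_class not in TEMPORAL_CLASSES:
            raise FeatureTableError(
                f"{self.name}: temporal_class {self.temporal_class!r} not in {TEMPORAL_CLASSES}"
            )
        if self.strand == "+":
            if not self.expected_tss <= self.cds_start < self.cds_end:
                raise FeatureTableError(
                    f"{self.name}: require expected_tss <= cds_start < cds_end on + strand"
                )
        else:
            if not self.expected_tss >= self.cds_start > self.cds_end:
                raise FeatureTableError(
                    f"{self.name}: require expected_tss >= cds_start > cds_end on - strand"
                )

    @property
    def cds_span(self) -> tuple[int, int]:
        """Genomic half-open interval covered by the CDS."""
        if self.strand == "+":
            return (self.cds_start, self.cds_end)
        return (self.cds_end + 1, self.cds_start + 1)

    @property
    def cds_len(self) -> int:
        lo, hi = self.cds_span
        return hi - lo

    def cds_sequence(self, genome: Genome) -> str:
        """Unspliced CDS on the coding strand (ATG .. stop)."""
        lo, hi = self.cds_span
        seq = genome.slice(lo, hi)
        return seq if self.strand == "+" else revcomp(seq)


@dataclass
class FeatureTable:
    """Ordered catalogue of ORF features with unique names."""

    entries: list[OrfFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [f.name for f in self.entries]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise FeatureTableError(f"duplicate feature names: {sorted(dupes)}")

    def __iter__(self) -> Iterator[OrfFeature]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, FeatureTable) and self.entries == other.entries

    def get(self, name: str) -> OrfFeature:
        for f in self.entries:
            if f.name == name:
                return f
        raise KeyError(name)

    def validate(self, genome: Optional[Genome] = None) -> None:
        """Check coordinates, start codons and temporal-class consistency.

        An ATG mismatch at ``cds_start`` is an error; a region/temporal-class
        mismatch only warns (the class is an input column, not inferred).
        """
        for f in self.entries:
            exp = expected_temporal_class(f.region)
            if exp is not None and exp != f.temporal_class:
                log.warning(
                    "%s: temporal_class %s unusual for region %s (expected %s)",
                    f.name, f.temporal_class, f.region, exp,
                )
            if genome is None:
                continue
            lo, hi = f.cds_span
            if lo < 0 or hi > genome.length or f.expected_tss >= genome.length:
                raise FeatureTableError(
                    f"{f.name}: coordinates outside genome of length {genome.length}"
                )
            cds = f.cds_sequence(genome)
            if cds[:3] != "ATG":
                raise FeatureTableError(
                    f"{f.name}: codon at cds_start is {cds[:3]!r}, expected ATG"
                )
            if f.cds_len % 3 != 0:
                raise FeatureTableError(f"{f.name}: CDS length {f.cds_len} not a multiple of 3")
            if cds[-3:] not in STOP_CODONS:
                log.warning("%s: CDS does not end in a stop codon (%s)", f.name, cds[-3:])


def feature_protein(genome: Genome, feat: OrfFeature) -> str:
    """Protein product of the feature's (unspliced) CDS, without the stop."""
    cds = feat.cds_sequence(genome)
    prot = str(Seq(cds).translate())
    return prot.split("*", 1)[0]


def _looks_like_gff3(path: Path) -> bool:
    if path.suffix.lower() in (".gff", ".gff3"):
        return True
    with open(path) as fh:
        first = fh.readline()
    return first.startswith("##gff-version")


def load_features(path: str | Path, genome: Optional[Genome] = None) -> FeatureTable:
    """Load a feature table from TSV or GFF3 and validate it.

    The TSV dialect has a header row with the seven columns
    ``name region strand cds_start cds_end expected_tss temporal_class``.
    The GFF3 alternative uses ``CDS`` lines carrying ``Name``, ``region``,
    ``temporal_class`` and ``expected_tss`` (0-based) attributes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = _load_features_gff3(path) if _looks_like_gff3(path) else _load_features_tsv(path)
    table.validate(genome)
    return table


def _load_features_tsv(path: Path) -> FeatureTable:
    entries = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(TSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise FeatureTableError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            entries.append(
                OrfFeature(
                    name=row["name"],
                    region=row["region"],
                    strand=row["strand"],
                    cds_start=int(row["cds_start"]),
                    cds_end=int(row["cds_end"]),
                    expected_tss=int(row["expected_tss"]),
                    temporal_class=row["temporal_class"],
                )
            )
    return FeatureTable(entries)


def _load_features_gff3(path: Path) -> FeatureTable:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    entries = []
    for feat in db.features_of_type("CDS", order_by="start"):
        name = feat.attributes["Name"][0]
        # GFF3 is 1-based inclusive; convert per the strand convention above.
        if feat.strand == "+":
            cds_start, cds_end = feat.start - 1, feat.end
        else:
            cds_start, cds_end = feat.end - 1, feat.start - 2
        entries.append(
            OrfFeature(
                name=name,
                region=feat.attributes["region"][0],
                strand=feat.strand,
                cds_start=cds_start,
                cds_end=cds_end,
                expected_tss=int(feat.attributes["expected_tss"][0]),
                temporal_class=feat.attributes["temporal_class"][0],
            )
        )
    # preserve file order, not coordinate order
    order = _gff3_name_order(path)
    entries.sort(key=lambda f: order.get(f.name, len(order)))
    return FeatureTable(entries)


def _gff3_name_order(path: Path) -> dict[str, int]:
    order: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            attrs = line.rstrip("\n").split("\t")[8]
            for part in attrs.split(";"):
                if part.startswith("Name="):
                    order.setdefault(part[5:], len(order))
    return order


def write_features(
    table: FeatureTable, path: str | Path, fmt: Optional[str] = None, seqid: str = "genome"
) -> None:
    """Write a feature table as TSV (default) or GFF3 (``fmt='gff3'``)."""
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "tsv"
    if fmt == "tsv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(TSV_COLUMNS)
            for f in table:
                writer.writerow(
                    [f.name, f.region, f.strand, f.cds_start, f.cds_end,
                     f.expected_tss, f.temporal_class]
                )
    elif fmt == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for f in table:
                if f.strand == "+":
                    start, end = f.cds_start + 1, f.cds_end
                else:
                    start, end = f.cds_end + 2, f.cds_start + 1
                attrs = (
                    f"ID={f.name};Name={f.name};region={f.region};"
                    f"temporal_class={f.temporal_class};expected_tss={f.expected_tss}"
                )
                fh.write(
                    "\t".join(
                        [seqid, "adenotx", "CDS", str(start), str(end), ".",
                         f.strand, "0", attrs]
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown feature format {fmt!r}")
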