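"""Abundance tables, group ratios, temporal profiles and browser exports.

Percentages are computed per sample over retained viral reads (every read
that survived the alignment filters sits in exactly one class), with the
unnamed pools ("truncated", "none_from_list") included as explicit rows so
each sample's percentages sum to 100. An alternative "named" denominator
restricted to coding/variant reads is available for comparison with tables
that exclude the unnamed bins.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .classify import TranscriptClass
from .genome import FeatureTable, Genome
from .naming import CODES_ORF, NONE_FROM_LIST, TRUNCATED, VARIANT_BYSPLICING, NamedClass

log = logging.getLogger(__name__)

# row ordering of the temporal profile: early genes first, late genes next,
# intermediate genes at the end of the graph, pools last
TEMPORAL_ORDER = {"early": 0, "late": 1, "intermediate": 2, "": 3}


class AbundanceTable:
    """Per-display-name counts and percentages across samples."""

    def __init__(self, df: pd.DataFrame, samples: list[str]):
        self.df = df
        self.samples = samples

    def count(self, display_name: str, sample: str) -> int:
        return int(self._row(display_name)[f"count_{sample}"])

    def percentage(self, display_name: str, sample: str) -> float:
        return float(self._row(display_name)[f"pct_{sample}"])

    def _row(self, display_name: str) -> pd.Series:
        hit = self.df[self.df["display_name"] == display_name]
        if hit.empty:
            raise KeyError(display_name)
        return hit.iloc[0]

    def to_tsv(self, path: str | Path) -> None:
        df = self.df.copy()
        for s in self.samples:
            df[f"pct_{s}"] = df[f"pct_{s}"].map(lambda v: f"{v:.3f}")
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AbundanceTable":
        df = pd.read_csv(path, sep="\t", dtype={"display_name": str, "temporal_class": str})
        df["temporal_class"] = df["temporal_class"].fillna("")
        samples = [c[len("count_"):] for c in df.columns if c.startswith("count_")]
        return cls(df, samples)


def build_table(
    named: Sequence[NamedClass],
    samples: Sequence[str],
    features: Optional[FeatureTable] = None,
    denominator: str = "retained",
) -> AbundanceTable:
    """Aggregate named classes into the per-timepoint abundance table.

    ``denominator='retained'`` (default) divides by all retained viral reads
    in the sample; ``'named'`` divides by coding + by-splicing reads only.
    """
    if denominator not in ("retained", "named"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    rows: dict[str, dict] = {}
    for nc in named:
        key = nc.display_name
        row = rows.setdefault(
            key,
            {
                "display_name": key,
                "temporal_class": _temporal_for(nc, features),
                "orf_name": nc.orf_name if nc.category in (CODES_ORF, VARIANT_BYSPLICING) else "",
                **{f"count_{s}": 0 for s in samples},
            },
        )
        for s in samples:
            row[f"count_{s}"] += nc.cls.counts.get(s, 0)

    df = pd.DataFrame(rows.values())
    for s in samples:
        if denominator == "retained":
            total = df[f"count_{s}"].sum()
        else:
            named_mask = ~df["display_name"].isin([TRUNCATED, NONE_FROM_LIST])
            total = df.loc[named_mask, f"count_{s}"].sum()
        if total == 0:
            raise ValueError(f"sample {s!r} has no retained reads; percentages undefined")
        df[f"pct_{s}"] = 100.0 * df[f"count_{s}"] / total

    anchor = _row_anchor(df, named)
    df["_ord"] = df["temporal_class"].map(TEMPORAL_ORDER).fillna(3)
    df["_pos"] = df["display_name"].map(anchor)
    df = df.sort_values(["_ord", "_pos", "display_name"]).drop(columns=["_ord", "_pos"])
    df = df.reset_index(drop=True)
    return AbundanceTable(df, list(samples))


def _temporal_for(nc: NamedClass, features: Optional[FeatureTable]) -> str:
    if features is None or nc.category not in (CODES_ORF, VARIANT_BYSPLICING):
        return ""
    try:
        return features.get(nc.orf_name).temporal_class
    except KeyError:
        return ""


def _row_anchor(df: pd.DataFrame, named: Sequence[NamedClass]) -> dict[str, int]:
    """Genomic position used to order rows within a temporal group."""
    anchor: dict[str, int] = {}
    for nc in named:
        pos = min(nc.cls.rep_start, nc.cls.rep_end)
        key = nc.display_name
        anchor[key] = min(anchor.get(key, pos), pos)
    return anchor


def group_ratio(
    table: AbundanceTable, numerator: str, denominator: str, sample: str
) -> Optional[float]:
    """Ratio of two groups' counts in one sample, rounded to 1 decimal.

    Returns None (undefined) when the denominator group has zero reads.
    """
    num = table.count(numerator, sample)
    den = table.count(denominator, sample)
    if den == 0:
        log.warning("ratio %s/%s undefined in %s: zero denominator", numerator, denominator, sample)
        return None
    return round(num / den, 1)


def most_abundant_per_orf(
    named: Sequence[NamedClass], sample: str
) -> dict[str, TranscriptClass]:
    """Per ORF, the class with the highest count in ``sample``.

    Ties go to the longer (exonic) transcript, then to the 5'-most start.
    """
    best: dict[str, NamedClass] = {}
    for nc in named:
        if nc.category != CODES_ORF:
            continue
        cur = best.get(nc.orf_name)
        if cur is None or _abundance_key(nc, sample) > _abundance_key(cur, sample):
            best[nc.orf_name] = nc
    return {orf: nc.cls for orf, nc in best.items()}


def _abundance_key(nc: NamedClass, sample: str) -> tuple:
    cls = nc.cls
    five = -cls.rep_start if cls.strand == "+" else cls.rep_start
    return (cls.counts.get(sample, 0), cls.exonic_len, five)


def temporal_profile(table: AbundanceTable, features: FeatureTable) -> pd.DataFrame:
    """Long-format (display_name, temporal_class, sample, percentage) table,
    ordered early -> late -> intermediate with pools last."""
    records = []
    for _, row in table.df.iterrows():
        for s in table.samples:
            records.append(
                {
                    "display_name": row["display_name"],
                    "temporal_class": row["temporal_class"],
                    "sample": s,
                    "percentage": row[f"pct_{s}"],
                }
            )
    return pd.DataFrame(records)


FORWARD_RGB = "0,0,0"
REVERSE_RGB = "0,0,255"


def export_bed12(
    named: Sequence[NamedClass],
    genome_name: str,
    path: str | Path,
    sample: Optional[str] = None,
    genome_length: Optional[int] = None,
) -> int:
    """BED12 transcript models: forward-strand classes black, reverse blue.

    ``sample`` selects which count becomes the score (capped at 1000); by
    default the total across samples is used. Classes with zero score for the
    selected sample are skipped.
    """
    n = 0
    with open(path, "w") as fh:
        for nc in named:
            cls = nc.cls
            blocks = cls.blocks
            if genome_length is not None and (blocks[0][0] < 0 or blocks[-1][1] > genome_length):
                raise ValueError(f"{cls.class_id}: blocks outside genome")
            count = cls.counts.get(sample, 0) if sample else cls.total
            if count == 0:
                continue
            chrom_start, chrom_end = blocks[0][0], blocks[-1][1]
            sizes = ",".join(str(e - s) for s, e in blocks)
            starts = ",".join(str(s - chrom_start) for s, e in blocks)
            name = nc.display_name or cls.class_id
            fh.write(
                "\t".join(
                    [
                        genome_name, str(chrom_start), str(chrom_end),
                        f"{name}|{cls.class_id}", str(min(count, 1000)), cls.strand,
                        str(chrom_start), str(chrom_end),
                        FORWARD_RGB if cls.strand == "+" else REVERSE_RGB,
                        str(len(blocks)), sizes, starts,
                    ]
                )
                + "\n"
            )
            n += 1
    return n


def import_bed12(path: str | Path) -> list[dict]:
    """Re-import a BED12 export; used for round-trip validation."""
    out = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            chrom_start = int(f[1])
            sizes = [int(x) for x in f[10].split(",") if x]
            starts = [int(x) for x in f[11].split(",") if x]
            blocks = tuple(
                (chrom_start + st, chrom_start + st + sz) for st, sz in zip(starts, sizes)
            )
            out.append(
                {
                    "chrom": f[0],
                    "name": f[3].split("|")[0],
                    "class_id": f[3].split("|")[1] if "|" in f[3] else "",
                    "score": int(f[4]),
                    "strand": f[5],
                    "rgb": f[8],
                    "blocks": blocks,
                }
            )
    return out


def ratio_report(
    named: Sequence[NamedClass],
    table: AbundanceTable,
    features: FeatureTable,
) -> pd.DataFrame:
    """Precursor vs by-splicing-variant ratios for every ORF with a variant."""
    pairs = sorted(
        {
            (nc.orf_name, nc.display_name)
            for nc in named
            if nc.category == VARIANT_BYSPLICING
        }
    )
    records = []
    for orf, variant_display in pairs:
        feat = features.get(orf)
        parent_display = feat.name if feat.name == feat.region else f"{feat.region}_{feat.name}"
        for s in table.samples:
            ratio = group_ratio(table, parent_display, variant_display, s)
            records.append(
                {
                    "sample": s,
                    "numerator": parent_display,
                    "denominator": variant_display,
                    "numerator_count": table.count(parent_display, s),
                    "denominator_count": table.count(variant_display, s),
                    "ratio": "undefined" if ratio is None else f"{ratio:.1f}",
                }
            )
    return pd.DataFrame(records)
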