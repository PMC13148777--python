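"""Synthetic adenovirus-like genome and direct RNA-seq read simulator.

The generator emulates the features of an adenovirus transcriptome that the
pipeline must handle, on a desk-scale ~34 kb toy genome:

* forward and reverse transcription units with early / intermediate / late
  cassettes;
* a major late promoter (MLP) with a three-exon tripartite leader spliced
  onto every late ORF (shared donor, per-ORF acceptors);
* a precursor/mature pair: the pVII-analog ORF carries an internal in-frame
  ATG at the protease-cleavage boundary, and one late isoform uses a deeper
  splice acceptor inside the precursor-coding region so that internal ATG
  becomes the transcript's first start codon;
* polyadenylated, 3'-anchored reads with frequent 5' truncation, polyA tails
  emitted as 3' soft clips, and per-timepoint abundance shifts
  (early-high at 24 h, late-high at 48/72 h);
* two decoys: a body-truncated copy of a late transcript and an unspliced
  transcript initiated and terminated inside the late coding span.

All intron contexts are written as canonical GT..AG (strand-aware) and every
ORF start is a planted ATG, so the generator's truth tables can act as exact
oracles for the classifier. Truth alignments are emitted directly as SAM; no
aligner is involved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam
import yaml

from .classify import TranscriptClass, validate_introns
from .genome import FeatureTable, Genome, OrfFeature, revcomp, write_genome, write_features
from .ingest import blocks_to_cigar
from .naming import splice_sequence, transcript_to_genomic

log = logging.getLogger(__name__)

CODONS_NO_STOP = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)

MIN_READ_LEN = 50  # truncated reads keep at least this much transcript


class LayoutError(ValueError):
    """Raised when the requested genome layout cannot be realised."""


@dataclass(frozen=True)
class IsoformSpec:
    """One simulated transcript architecture with per-sample weights."""

    name: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    polya_site: int  # 0-based genomic position of the transcript's last base
    weights: dict[str, float]
    truth_orf: str = ""
    truth_category: str = "codes_orf"
    intended_atg: Optional[int] = None  # genomic position of the expected first ATG

    @property
    def tss(self) -> int:
        return self.blocks[0][0] if self.strand == "+" else self.blocks[-1][1] - 1

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.blocks[i][1], self.blocks[i + 1][0]) for i in range(len(self.blocks) - 1)
        )

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.blocks)


@dataclass
class SynthSpec:
    """Full description of a simulated genome, transcripts and read noise."""

    seed: int
    features: FeatureTable
    isoforms: list[IsoformSpec]
    reads_per_sample: dict[str, int]
    genome_len: int = 34_000
    trunc_prob: float = 0.2
    polya_mean: float = 60.0
    polya_sd: float = 20.0
    end_jitter_sd: float = 8.0
    cds_codon_overrides: dict[str, dict[int, str]] = field(default_factory=dict)
    genome_name: str = "synthetic_adv"

    @property
    def samples(self) -> list[str]:
        return list(self.reads_per_sample)

    def validate(self) -> None:
        for s in self.samples:
            total = sum(iso.weights.get(s, 0.0) for iso in self.isoforms)
            if abs(total - 1.0) > 1e-9:
                raise LayoutError(f"isoform weights for sample {s} sum to {total}, not 1")
        for iso in self.isoforms:
            if iso.blocks[0][0] < 0 or iso.blocks[-1][1] > self.genome_len:
                raise LayoutError(f"{iso.name}: blocks outside genome of length {self.genome_len}")
            if iso.length <= MIN_READ_LEN + 10:
                raise LayoutError(f"{iso.name}: transcript too short to simulate")


# ---------------------------------------------------------------------------
# default scenario

# per-sample isoform weights: early genes dominate at 24 h.p.i., late genes
# take over at 48/72 h.p.i.; the precursor:mature pVII-analog pair is weighted
# 4.3:1 at 72 h.p.i.
_WEIGHTS = {
    "E1A":     {"24hpi": 0.18,  "48hpi": 0.06,  "72hpi": 0.04},
    "DBP":     {"24hpi": 0.16,  "48hpi": 0.08,  "72hpi": 0.05},
    "IX":      {"24hpi": 0.12,  "48hpi": 0.11,  "72hpi": 0.105},
    "IVa2":    {"24hpi": 0.06,  "48hpi": 0.06,  "72hpi": 0.055},
    "pIIIa":   {"24hpi": 0.05,  "48hpi": 0.07,  "72hpi": 0.08},
    "preVII":  {"24hpi": 0.08,  "48hpi": 0.13,  "72hpi": 0.1462},
    "VII_mat": {"24hpi": 0.03,  "48hpi": 0.035, "72hpi": 0.034},
    "pMu":     {"24hpi": 0.07,  "48hpi": 0.13,  "72hpi": 0.145},
    "hexon":   {"24hpi": 0.06,  "48hpi": 0.10,  "72hpi": 0.12},
    "fiber":   {"24hpi": 0.05,  "48hpi": 0.08,  "72hpi": 0.085},
    "dTrunc":  {"24hpi": 0.08,  "48hpi": 0.08,  "72hpi": 0.08},
    "dInter":  {"24hpi": 0.06,  "48hpi": 0.065, "72hpi": 0.0598},
}

# tripartite leader exons (classic ~41/72/90 nt sizes) and the shared donor
_LEADERS = ((5858, 5899), (6920, 6992), (7761, 7851))
_MLP_TSS = 5858

# read depths scaled down ~175x from the study's per-timepoint throughput
_DEFAULT_READS = {"24hpi": 5_000, "48hpi": 13_000, "72hpi": 17_000}


def default_scenario(
    seed: int = 7, reads_per_sample: Optional[dict[str, int]] = None
) -> SynthSpec:
    """The standard simulation: 3 timepoints, 12 isoforms, 9 catalogued ORFs."""
    features = FeatureTable(
        [
            OrfFeature("E1A", "E1A", "+", 775, 1048, 560, "early"),
            OrfFeature("DBP", "E2A", "-", 23769, 23316, 24000, "early"),
            OrfFeature("IX", "IX", "+", 3580, 3913, 3500, "intermediate"),
            OrfFeature("IVa2", "IVa2", "-", 21259, 20866, 21500, "intermediate"),
            OrfFeature("pIIIa", "L1", "+", 9120, 9693, _MLP_TSS, "late"),
            OrfFeature("preVII", "L2", "+", 11020, 11383, _MLP_TSS, "late"),
            OrfFeature("pMu", "L2", "+", 12220, 12448, _MLP_TSS, "late"),
            OrfFeature("hexon", "L3", "+", 14020, 14923, _MLP_TSS, "late"),
            OrfFeature("fiber", "L5", "+", 16720, 17263, _MLP_TSS, "late"),
        ]
    )

    def late(acceptor: int, last_end: int) -> tuple[tuple[int, int], ...]:
        return _LEADERS + ((acceptor, last_end),)

    w = _WEIGHTS
    isoforms = [
        IsoformSpec("E1A", "+", ((560, 620), (755, 1201)), 1200, w["E1A"],
                    "E1A", "codes_orf", 775),
        IsoformSpec("DBP", "-", ((23150, 23790), (23940, 24001)), 23150, w["DBP"],
                    "DBP", "codes_orf", 23769),
        IsoformSpec("IX", "+", ((3500, 4051),), 4050, w["IX"], "IX", "codes_orf", 3580),
        IsoformSpec("IVa2", "-", ((20700, 21280), (21440, 21501)), 20700, w["IVa2"],
                    "IVa2", "codes_orf", 21259),
        IsoformSpec("pIIIa", "+", late(9100, 9801), 9800, w["pIIIa"],
                    "pIIIa", "codes_orf", 9120),
        IsoformSpec("preVII", "+", late(11000, 11501), 11500, w["preVII"],
                    "preVII", "codes_orf", 11020),
        # mature-equivalent: deeper acceptor inside the precursor-coding
        # region; first ATG becomes the internal one at the cleavage boundary
        IsoformSpec("VII_mat", "+", late(11080, 11501), 11500, w["VII_mat"],
                    "preVII", "variant_bysplicing", 11092),
        IsoformSpec("pMu", "+", late(12200, 12601), 12600, w["pMu"],
                    "pMu", "codes_orf", 12220),
        IsoformSpec("hexon", "+", late(14000, 15101), 15100, w["hexon"],
                    "hexon", "codes_orf", 14020),
        IsoformSpec("fiber", "+", late(16700, 17401), 17400, w["fiber"],
                    "fiber", "codes_orf", 16720),
        # decoys: a body-truncated late transcript and an unspliced transcript
        # initiated and terminated inside the late coding span
        IsoformSpec("dTrunc", "+", ((14500, 15101),), 15100, w["dTrunc"],
                    "", "decoy_truncated"),
        IsoformSpec("dInter", "+", ((11150, 11701),), 11700, w["dInter"],
                    "", "decoy_intergenic"),
    ]

    spec = SynthSpec(
        seed=seed,
        features=features,
        isoforms=isoforms,
        reads_per_sample=dict(reads_per_sample or _DEFAULT_READS),
        cds_codon_overrides={
            # codon 19 carries the variant acceptor's AG; codons 20-23 are an
            # ATG-free spacer; codon 24 is the internal (cleavage-boundary) Met
            "preVII": {19: "GAG", 20: "CAA", 21: "CAA", 22: "CAA", 23: "CAA", 24: "ATG"},
        },
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# genome construction


def build_genome(spec: SynthSpec) -> Genome:
    """Deterministically build the toy genome implied by ``spec``.

    Random background, then planted CDS cassettes (ATG .. stop-free body ..
    TAA), canonical splice contexts for every intron, and an ATG-scrub of
    every transcript region 5' of its intended first start codon. Raises
    LayoutError if the layout cannot be realised.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    seq = list("".join(rng.choice(list("ACGT"), size=spec.genome_len)))
    protected: set[int] = set()

    # 1. ORF cassettes
    for feat in spec.features:
        n_codons = feat.cds_len // 3
        body = [CODONS_NO_STOP[i] for i in rng.integers(0, len(CODONS_NO_STOP), n_codons - 2)]
        codons = ["ATG"] + body + ["TAA"]
        for idx, codon in spec.cds_codon_overrides.get(feat.name, {}).items():
            codons[idx] = codon
        cds = "".join(codons)
        lo, hi = feat.cds_span
        if feat.strand == "-":
            cds = revcomp(cds)
        seq[lo:hi] = list(cds)
        protected.update(range(lo, hi))

    # 2. splice-site contexts (strand-aware canonical GT..AG)
    introns = {(iso.strand, iv) for iso in spec.isoforms for iv in iso.introns}
    for strand, (d, a) in sorted(introns):
        if a - d < 4:
            raise LayoutError(f"intron ({d},{a}) too short")
        donor, acceptor = ("GT", "AG") if strand == "+" else ("CT", "AC")
        for pos, base in zip((d, d + 1, a - 2, a - 1), donor + acceptor):
            if pos in protected and seq[pos] != base:
                raise LayoutError(f"splice base at {pos} conflicts with a planted CDS")
            seq[pos] = base
            protected.add(pos)

    # 3. scrub ATGs upstream of each transcript's intended first start codon
    genome = Genome(spec.genome_name, "".join(seq))
    for iso in spec.isoforms:
        if iso.intended_atg is None:
            continue
        for _ in range(8):  # repeated passes in case of shared regions
            genome = Genome(spec.genome_name, "".join(seq))
            tx = splice_sequence(genome, iso.blocks, iso.strand)
            target = _genomic_to_transcript(iso, iso.intended_atg)
            if tx[target : target + 3] != "ATG":
                raise LayoutError(f"{iso.name}: no ATG at intended position {iso.intended_atg}")
            early = tx.find("ATG")
            if early == target:
                break
            _scrub_atg(seq, iso, early, protected)
        else:
            raise LayoutError(f"{iso.name}: could not clear upstream ATGs")

    genome = Genome(spec.genome_name, "".join(seq))
    _verify_layout(spec, genome)
    return genome


def _genomic_to_transcript(iso: IsoformSpec, pos: int) -> int:
    walk = iso.blocks if iso.strand == "+" else tuple(reversed(iso.blocks))
    off = 0
    for s, e in walk:
        if s <= pos < e:
            return off + (pos - s if iso.strand == "+" else e - 1 - pos)
        off += e - s
    raise LayoutError(f"{iso.name}: position {pos} not exonic")


def _scrub_atg(seq: list[str], iso: IsoformSpec, tx_off: int, protected: set[int]) -> None:
    """Mutate one base of the ATG at transcript offset ``tx_off`` to remove it."""
    for delta, repl in ((1, "C"), (2, "C"), (0, "C")):  # prefer T->C (ATG -> ACG)
        gpos = transcript_to_genomic(iso.blocks, iso.strand, tx_off + delta)
        if gpos not in protected:
            seq[gpos] = repl if iso.strand == "+" else revcomp(repl)
            return
    raise LayoutError(
        f"{iso.name}: upstream ATG at transcript offset {tx_off} overlaps planted elements"
    )


def _verify_layout(spec: SynthSpec, genome: Genome) -> None:
    spec.features.validate(genome)
    for iso in spec.isoforms:
        for i, (motif, ok) in enumerate(
            validate_introns(
                genome,
                TranscriptClass("t", iso.strand, iso.introns,
                                rep_start=iso.tss, rep_end=iso.polya_site),
            )
        ):
            if not ok:
                raise LayoutError(f"{iso.name}: intron {iso.introns[i]} motif {motif} not GT..AG")
        if iso.intended_atg is not None:
            tx = splice_sequence(genome, iso.blocks, iso.strand)
            if tx.find("ATG") != _genomic_to_transcript(iso, iso.intended_atg):
                raise LayoutError(f"{iso.name}: first ATG is not the intended one")


# ---------------------------------------------------------------------------
# read simulation


def _truncate_blocks(
    blocks: tuple[tuple[int, int], ...], strand: str, offset: int
) -> tuple[tuple[int, int], ...]:
    """Drop the 5'-most ``offset`` transcript bases (strand-aware)."""
    if strand == "+":
        rem = offset
        for i, (s, e) in enumerate(blocks):
            if rem < e - s:
                return ((s + rem, e),) + blocks[i + 1:]
            rem -= e - s
    else:
        rem = offset
        for i in range(len(blocks) - 1, -1, -1):
            s, e = blocks[i]
            if rem < e - s:
                return blocks[:i] + ((s, e - rem),)
            rem -= e - s
    raise ValueError(f"truncation offset {offset} beyond transcript")


def _jitter_3prime(
    blocks: tuple[tuple[int, int], ...], strand: str, jitter: int, genome_len: int
) -> tuple[tuple[int, int], ...]:
    if strand == "+":
        s, e = blocks[-1]
        e = int(np.clip(e + jitter, s + 10, genome_len))
        return blocks[:-1] + ((s, e),)
    s, e = blocks[0]
    s = int(np.clip(s - jitter, 0, e - 10))
    return ((s, e),) + blocks[1:]


def _jitter_junctions(
    blocks: tuple[tuple[int, int], ...], rng: np.random.Generator, magnitude: int
) -> tuple[tuple[int, int], ...]:
    """Perturb junction ends by up to ``magnitude`` nt (noise-mode only).

    Centre-heavy wobble: the exact coordinate stays the per-end mode, as for
    real basecalled nanopore junctions, so junction self-training remains
    meaningful under noise.
    """
    shifts = np.arange(-magnitude, magnitude + 1)
    weights = 0.5 ** np.abs(shifts)
    weights[magnitude] = 2.0  # zero shift twice as likely as +/-1
    weights = weights / weights.sum()
    bl = [list(b) for b in blocks]
    for i in range(len(bl) - 1):
        for blk, side in ((bl[i], 1), (bl[i + 1], 0)):
            blk[side] += int(rng.choice(shifts, p=weights))
    # keep blocks valid after perturbation
    out = []
    for i, (s, e) in enumerate(bl):
        if e - s < 5 or (out and s <= out[-1][1]):
            return blocks  # give up on degenerate jitter; keep the clean chain
        out.append((s, e))
    return tuple(out)


def simulate_reads(
    spec: SynthSpec,
    genome: Genome,
    out_dir: str | Path,
    junction_jitter: int = 0,
    write_fasta: bool = False,
) -> dict[str, dict[str, Path]]:
    """Simulate per-sample truth SAM files (plus truth tables).

    Reads are drawn multinomially by isoform weight; the 3' end is anchored
    at the polyA site +/- end jitter; with probability ``trunc_prob`` the 5'
    end is uniform within the transcript body; the polyA tail is emitted as a
    3' soft clip. ``junction_jitter`` > 0 perturbs junction coordinates to
    exercise junction correction; the default truth SAM has exact junctions.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "unsorted"},
         "SQ": [{"SN": genome.name, "LN": genome.length}]}
    )
    paths: dict[str, dict[str, Path]] = {}
    for sample in spec.samples:
        n = spec.reads_per_sample[sample]
        weights = np.array([iso.weights.get(sample, 0.0) for iso in spec.isoforms])
        counts = rng.multinomial(n, weights)
        order = rng.permutation(np.repeat(np.arange(len(spec.isoforms)), counts))
        sam_path = out_dir / f"{sample}.sam"
        truth_path = out_dir / f"{sample}.truth.tsv"
        fasta_path = out_dir / f"{sample}.reads.fasta"
        fasta_fh = open(fasta_path, "w") if write_fasta else None
        with pysam.AlignmentFile(str(sam_path), "w", header=header) as sam, \
                open(truth_path, "w") as truth:
            truth.write(
                "read_id\tisoform\ttruth_category\ttruncated\tstrand\t"
                "five_prime\tthree_prime\tintrons\tpolya_len\n"
            )
            for i, idx in enumerate(order):
                iso = spec.isoforms[int(idx)]
                read_id = f"{sample}_r{i:06d}"
                blocks = iso.blocks
                truncated = bool(rng.random() < spec.trunc_prob)
                if truncated:
                    off = int(rng.integers(1, iso.length - MIN_READ_LEN + 1))
                    blocks = _truncate_blocks(blocks, iso.strand, off)
                jit = int(round(rng.normal(0.0, spec.end_jitter_sd)))
                blocks = _jitter_3prime(blocks, iso.strand, jit, genome.length)
                if junction_jitter > 0 and len(blocks) > 1:
                    blocks = _jitter_junctions(blocks, rng, junction_jitter)
                tail = max(10, int(round(rng.normal(spec.polya_mean, spec.polya_sd))))
                sense = splice_sequence(genome, blocks, iso.strand) + "A" * tail

                a = pysam.AlignedSegment(header)
                a.query_name = read_id
                a.reference_id = 0
                a.reference_start = blocks[0][0]
                a.mapping_quality = 60
                if iso.strand == "+":
                    a.flag = 0
                    a.query_sequence = sense
                    a.cigarstring = blocks_to_cigar(blocks, clip3=tail)
                else:
                    a.flag = 16
                    a.query_sequence = revcomp(sense)
                    a.cigarstring = blocks_to_cigar(blocks, clip5=tail)
                sam.write(a)
                if fasta_fh:
                    fasta_fh.write(f">{read_id}\n{sense}\n")

                chain_introns = ",".join(
                    f"{blocks[k][1]}-{blocks[k + 1][0]}" for k in range(len(blocks) - 1)
                )
                five = blocks[0][0] if iso.strand == "+" else blocks[-1][1] - 1
                three = blocks[-1][1] - 1 if iso.strand == "+" else blocks[0][0]
                truth.write(
                    f"{read_id}\t{iso.name}\t{iso.truth_category}\t{int(truncated)}\t"
                    f"{iso.strand}\t{five}\t{three}\t{chain_introns}\t{tail}\n"
                )
        if fasta_fh:
            fasta_fh.close()
        paths[sample] = {"sam": sam_path, "truth": truth_path}
        if write_fasta:
            paths[sample]["fasta"] = fasta_path
    return paths


def write_scenario_yaml(spec: SynthSpec, path: str | Path) -> None:
    doc = {
        "seed": spec.seed,
        "genome_len": spec.genome_len,
        "genome_name": spec.genome_name,
        "trunc_prob": spec.trunc_prob,
        "polya_mean": spec.polya_mean,
        "polya_sd": spec.polya_sd,
        "end_jitter_sd": spec.end_jitter_sd,
        "reads_per_sample": dict(spec.reads_per_sample),
        "features": [asdict(f) for f in spec.features],
        "isoforms": [
            {
                "name": iso.name,
                "strand": iso.strand,
                "blocks": [list(b) for b in iso.blocks],
                "polya_site": iso.polya_site,
                "weights": dict(iso.weights),
                "truth_orf": iso.truth_orf,
                "truth_category": iso.truth_category,
            }
            for iso in spec.isoforms
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def emit_scenario(
    spec: SynthSpec, out_dir: str | Path, junction_jitter: int = 0, write_fasta: bool = False
) -> dict:
    """Build the genome and write every scenario artifact into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome = build_genome(spec)
    write_genome(genome, out_dir / "genome.fa", "synthetic adenovirus-like toy genome")
    write_features(spec.features, out_dir / "features.tsv")
    write_scenario_yaml(spec, out_dir / "scenario.yaml")
    samples = simulate_reads(spec, genome, out_dir, junction_jitter, write_fasta)
    return {
        "genome": out_dir / "genome.fa",
        "features": out_dir / "features.tsv",
        "scenario": out_dir / "scenario.yaml",
        "samples": samples,
    }
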