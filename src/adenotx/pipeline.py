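"""End-to-end pipeline: alignments in, named/quantified transcript tables out.

Stages: load genome + feature table, ingest per-sample alignments, self-train
the known-intron set, snap junctions, collapse into classes, validate splice
motifs, name against the ORF catalogue, quantify, export. A JSON manifest
captures parameters and input/output checksums so a run can be reproduced
exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .classify import (
    DEFAULT_END_WINDOW,
    DEFAULT_MIN_KNOWN_COUNT,
    DEFAULT_SNAP_TOL,
    DEFAULT_TSS_WINDOW,
    annotate_introns,
    cluster_reads,
    correct_junctions,
    learn_known_introns,
    write_classes,
)
from .genome import load_features, load_genome
from .ingest import load_alignments
from .naming import DEFAULT_MIN_COUNT, export_unnamed_fasta, name_classes, write_named
from .quantify import build_table, export_bed12, ratio_report, temporal_profile

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised with the failing stage's name when any stage errors."""


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    genome: Path
    features: Path
    samples: dict[str, Path]  # ordered sample label -> SAM/BAM path
    out_dir: Path
    min_mapq: int = 1
    tol: int = DEFAULT_SNAP_TOL
    tss_window: int = DEFAULT_TSS_WINDOW
    end_window: int = DEFAULT_END_WINDOW
    min_known_intron_count: int = DEFAULT_MIN_KNOWN_COUNT
    denominator: str = "retained"
    min_count: int = DEFAULT_MIN_COUNT
    known_introns: tuple[tuple[int, int], ...] = ()
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.genome = Path(self.genome)
        self.features = Path(self.features)
        self.samples = {s: Path(p) for s, p in self.samples.items()}
        self.out_dir = Path(self.out_dir)
        for path in [self.genome, self.features, *self.samples.values()]:
            if not path.exists():
                raise FileNotFoundError(path)
        if not (0 <= self.tol <= 20 and 0 <= self.tss_window <= 1000
                and 0 <= self.end_window <= 1000 and self.min_mapq >= 0):
            raise ValueError("pipeline parameter outside its documented range")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        doc["known_introns"] = tuple(tuple(iv) for iv in doc.get("known_introns", ()))
        return cls(**doc)

    def parameters(self) -> dict:
        return {
            "min_mapq": self.min_mapq,
            "tol": self.tol,
            "tss_window": self.tss_window,
            "end_window": self.end_window,
            "min_known_intron_count": self.min_known_intron_count,
            "denominator": self.denominator,
            "min_count": self.min_count,
            "known_introns": [list(iv) for iv in self.known_introns],
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write all artifacts into ``config.out_dir``."""
    logging.basicConfig(level=config.log_level)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    samples = list(config.samples)

    stage = "load_reference"
    try:
        genome = load_genome(config.genome)
        features = load_features(config.features, genome)

        stage = "ingest_alignments"
        chains = []
        retained = {}
        for sample, path in config.samples.items():
            sample_chains = load_alignments(path, genome.name, config.min_mapq, sample)
            retained[sample] = len(sample_chains)
            chains.extend(sample_chains)

        stage = "correct_junctions"
        known = learn_known_introns(
            chains, config.min_known_intron_count, config.tol, config.known_introns
        )
        chains = [correct_junctions(c, known, config.tol) for c in chains]

        stage = "cluster_reads"
        classes = cluster_reads(chains, config.tss_window, config.end_window)
        annotate_introns(genome, classes)
        for sample in samples:
            classified = sum(cls.counts.get(sample, 0) for cls in classes)
            if classified != retained[sample]:
                raise PipelineError(
                    f"count conservation violated for {sample}: "
                    f"{classified} classified vs {retained[sample]} retained"
                )

        stage = "name_classes"
        named = name_classes(
            classes, features, genome,
            config.tss_window, config.end_window, config.min_count,
        )

        stage = "quantify"
        table = build_table(named, samples, features, config.denominator)
        ratios = ratio_report(named, table, features)
        profile = temporal_profile(table, features)

        stage = "write_outputs"
        outputs: dict[str, Path] = {}
        outputs["classes"] = out / "classes.tsv"
        write_classes(classes, samples, outputs["classes"])
        outputs["named_classes"] = out / "named_classes.tsv"
        write_named(named, samples, outputs["named_classes"])
        outputs["abundance"] = out / "abundance.tsv"
        table.to_tsv(outputs["abundance"])
        outputs["ratios"] = out / "ratios.tsv"
        ratios.to_csv(outputs["ratios"], sep="\t", index=False)
        outputs["temporal"] = out / "temporal.tsv"
        profile.to_csv(
            outputs["temporal"], sep="\t", index=False,
            float_format="%.3f",
        )
        for sample in samples:
            key = f"bed12_{sample}"
            outputs[key] = out / f"{sample}.bed12"
            export_bed12(named, genome.name, outputs[key], sample, genome.length)
        outputs["unnamed_fasta"] = out / "unnamed.fasta"
        export_unnamed_fasta(genome, named, outputs["unnamed_fasta"])

        stage = "manifest"
        manifest = {
            "adenotx_version": __version__,
            "parameters": config.parameters(),
            "samples": samples,
            "retained_reads": retained,
            "inputs": {
                str(p): _sha256(p)
                for p in [config.genome, config.features, *config.samples.values()]
            },
            "outputs": {k: _sha256(p) for k, p in outputs.items()},
        }
        outputs["manifest"] = out / "manifest.json"
        with open(outputs["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    log.info("pipeline complete: %d classes, outputs in %s", len(classes), out)
    return outputs
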