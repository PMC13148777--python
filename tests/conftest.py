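"""Shared fixtures: simulated scenarios at two depths plus pipeline runs.

The "unit" scenario uses the generator's default per-timepoint depths; the
"deep" scenario uses 20,000 reads per timepoint for the statistical
parameter-recovery checks. Both are built once per session.
"""

from __future__ import annotations

import math
from pathlib import Path

import pytest

from adenotx.genome import load_genome
from adenotx.pipeline import RunConfig, run_pipeline
from adenotx.simulate import (
    MIN_READ_LEN,
    IsoformSpec,
    SynthSpec,
    default_scenario,
    emit_scenario,
    _truncate_blocks,
)

SAMPLES = ("24hpi", "48hpi", "72hpi")


def _run(spec: SynthSpec, root: Path) -> dict:
    arts = emit_scenario(spec, root / "sim")
    cfg = RunConfig(
        genome=arts["genome"],
        features=arts["features"],
        samples={s: arts["samples"][s]["sam"] for s in spec.samples},
        out_dir=root / "run",
    )
    outputs = run_pipeline(cfg)
    return {"spec": spec, "arts": arts, "config": cfg, "outputs": outputs}


@pytest.fixture(scope="session")
def sim(tmp_path_factory) -> dict:
    """Default-depth scenario plus a full pipeline run."""
    return _run(default_scenario(7), tmp_path_factory.mktemp("sim_default"))


@pytest.fixture(scope="session")
def deep(tmp_path_factory) -> dict:
    """The 3 x 20,000-read scenario plus a full pipeline run."""
    spec = default_scenario(7, {s: 20_000 for s in SAMPLES})
    return _run(spec, tmp_path_factory.mktemp("sim_deep"))


@pytest.fixture(scope="session")
def sim_genome(sim):
    return load_genome(sim["arts"]["genome"])


@pytest.fixture(scope="session")
def deep_genome(deep):
    return load_genome(deep["arts"]["genome"])


# ---------------------------------------------------------------------------
# enumeration oracle for expected class composition


def _read_after_truncation(iso: IsoformSpec, offset: int):
    blocks = _truncate_blocks(iso.blocks, iso.strand, offset)
    introns = tuple((blocks[i][1], blocks[i + 1][0]) for i in range(len(blocks) - 1))
    five = blocks[0][0] if iso.strand == "+" else blocks[-1][1] - 1
    return introns, five


def expected_class_probability(
    spec: SynthSpec,
    target: IsoformSpec,
    sample: str,
    tss_window: int = 50,
    end_window: int = 30,
) -> float:
    """Probability that a read drawn in ``sample`` joins ``target``'s class.

    Exact enumeration under the generative model: a read contributes when its
    (possibly truncated) junction signature equals the target's, its 5' end
    falls within the clustering window of the target's start, and its polyA
    anchor matches the target's 3' cluster. Covers both a target's own
    truncated reads that stay near the start and cross-captured truncations
    of other isoforms that are read-identical to the target.
    """
    p = 0.0
    for iso in spec.isoforms:
        w = iso.weights.get(sample, 0.0)
        if w == 0.0 or iso.strand != target.strand:
            continue
        if abs(iso.polya_site - target.polya_site) > end_window:
            continue
        if iso.name == target.name:
            p += w * (1.0 - spec.trunc_prob)
        n_offsets = iso.length - MIN_READ_LEN  # offsets 1 .. L - MIN_READ_LEN
        hits = 0
        for u in range(1, n_offsets + 1):
            introns, five = _read_after_truncation(iso, u)
            if introns == target.introns and abs(five - target.tss) <= tss_window:
                hits += 1
        p += w * spec.trunc_prob * hits / n_offsets
    return p


@pytest.fixture(scope="session")
def class_probability_oracle():
    return expected_class_probability


def binomial_3se(p: float, n: int) -> float:
    return 3.0 * math.sqrt(p * (1.0 - p) / n)


@pytest.fixture(scope="session")
def three_se():
    return binomial_3se
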