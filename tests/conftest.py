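"""Shared fixtures: a toy genome build and one default synthetic run.

The session-scoped pipeline run uses the generator's default study
conditions (36 samples, 9 breeds, 3 regions, four noisy callers) and is
shared by the pipeline, recovery and determinism tests so the suite runs
the expensive chain once.
"""

from __future__ import annotations

import pytest

from cnvrpipe.genome import Chromosome, GenomeBuild
from cnvrpipe.pipeline import RunConfig, run_pipeline
from cnvrpipe.simulate import SyntheticConfig, plant_truth


@pytest.fixture(scope="session")
def toy_build() -> GenomeBuild:
    return GenomeBuild(
        "toy",
        (
            Chromosome("1", 10_000_000, True),
            Chromosome("2", 10_000_000, True),
            Chromosome("3", 10_000_000, True),
            Chromosome("X", 5_000_000, False),
        ),
    )


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run under default synthetic noise, seed 1."""
    out = tmp_path_factory.mktemp("pipeline_run")
    cfg = RunConfig(out_dir=str(out), seed=1, synthetic=SyntheticConfig())
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def default_truth():
    """The truth table matching ``default_run`` (same seed, same config)."""
    return plant_truth(SyntheticConfig(seed=1))
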