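"""Shared fixtures: one synthetic bundle and one full pipeline run per session."""

from __future__ import annotations

import pytest

from srnapipe.pipeline import PipelineConfig, run_pipeline
from srnapipe.synthetic_data import (
    SimulationParams,
    simulate_read_libraries,
    synthesize_genome,
    write_bundle,
)

SESSION_SEED = 11


@pytest.fixture(scope="session")
def bundle():
    """Synthetic genome + references + truth ledger at the session seed."""
    return synthesize_genome(SimulationParams(), seed=SESSION_SEED)


@pytest.fixture(scope="session")
def sim_dir(bundle, tmp_path_factory):
    """Bundle and read libraries written to disk."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(bundle, outdir)
    fastqs = simulate_read_libraries(bundle, outdir / "reads", seed=SESSION_SEED)
    return {"dir": outdir, "paths": paths, "fastqs": fastqs}


@pytest.fixture(scope="session")
def pipeline_config(sim_dir, tmp_path_factory):
    paths, fastqs = sim_dir["paths"], sim_dir["fastqs"]
    return PipelineConfig(
        reads={lib: str(p) for lib, p in fastqs.items()},
        genome=str(paths["genome"]),
        known_mirnas=str(paths["known_mirnas"]),
        refsets={
            cls: str(paths[cls])
            for cls in ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "protein_coding")
        },
        est=str(paths["est"]),
        gss=str(paths["gss"]),
        transcripts=str(paths["transcripts"]),
        outdir=str(tmp_path_factory.mktemp("results")),
        seed=SESSION_SEED,
    )


@pytest.fixture(scope="session")
def pipeline_result(pipeline_config):
    """One full end-to-end run on the synthetic bundle."""
    return run_pipeline(pipeline_config)
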