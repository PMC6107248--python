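import numpy as np
import pytest

from mtsirna import synthetic_data as syn
from mtsirna.pipeline import RunConfig, run_pipeline

#: compact tissue panel for unit tests (two tassel stages + four other organs)
SMALL_PANEL = [
    syn.TissueSample("tassel", "V8"),
    syn.TissueSample("tassel", "V10"),
    syn.TissueSample("leaf", "V6"),
    syn.TissueSample("root", "VE"),
    syn.TissueSample("ear", "1DAP"),
    syn.TissueSample("silk", "VT"),
]

SMALL_DEPTH = 30_000


@pytest.fixture(scope="session")
def small_study():
    """One synthetic study: transcriptome, planted cluster, libraries."""
    transcripts, truth = syn.generate_transcriptome(
        3, (600, 1200), seed=11, donor_length=1826
    )
    donor = transcripts[truth.donor_transcript_id]
    truth.planted_region = (550, 751)
    truth.planted_sirnas = syn.plant_sirna_cluster(
        donor, truth.planted_region, 12, seed=12
    )
    libraries = syn.generate_libraries(
        SMALL_PANEL, truth, depth=SMALL_DEPTH, background_rate=0.0, seed=13
    )
    return transcripts, truth, libraries


@pytest.fixture(scope="session")
def e2e_result(tmp_path_factory):
    """A full synthetic pipeline run shared across end-to-end tests."""
    outdir = tmp_path_factory.mktemp("e2e") / "run"
    config = RunConfig(outdir=str(outdir), seed=5, depth=30_000)
    return config, run_pipeline(config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
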