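"""Shared fixtures: one session-scoped synthetic bundle plus its pipeline run."""
from __future__ import annotations

import glob

import numpy as np
import pytest

from photonet import msio, networking, pipeline, synthetic_data as sd

#: Fixed seed for the session bundle; tests freeze expectations against it.
BUNDLE_SEED = 11


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    cfg = sd.GeneratorConfig(seed=BUNDLE_SEED)
    truth = sd.generate_bundle(cfg, out, force=True)
    return out, truth


@pytest.fixture(scope="session")
def truth(bundle_dir):
    return bundle_dir[1]


@pytest.fixture(scope="session")
def spectra(bundle_dir):
    return msio.read_mgf(bundle_dir[0] / "spectra.mgf")


@pytest.fixture(scope="session")
def feature_table(bundle_dir):
    return msio.read_feature_table(bundle_dir[0] / "feature_table.csv")


@pytest.fixture(scope="session")
def dad_traces(bundle_dir):
    traces = {}
    for path in sorted(glob.glob(str(bundle_dir[0] / "dad_*.csv"))):
        t = msio.read_dad_trace(path)
        traces[t.extract_id] = t
    return traces


@pytest.fixture(scope="session")
def network(spectra):
    return networking.build_network(spectra)


@pytest.fixture(scope="session")
def pipeline_run(bundle_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    cfg = pipeline.PipelineConfig(input_dir=str(bundle_dir[0]), output_dir=str(out))
    summary = pipeline.run(cfg)
    return out, summary


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
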