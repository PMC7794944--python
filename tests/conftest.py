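import warnings

import numpy as np
import pytest

from pupglearn.classify import PipelineConfig
from pupglearn.features import FEATURE_REGISTRY, extract_all, matrix_from_vectors
from pupglearn.preprocess import emd_denoise
from pupglearn.synth import SynthConfig, generate_dataset, generate_signal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quiet_cfg():
    """Noise-free single-component configuration for closed-form checks."""
    from pupglearn.synth import ClassMorphology

    morph = {
        "normal": ClassMorphology(heart_rate_jitter_bpm=0.0),
        "hypertension": ClassMorphology(
            heart_rate_jitter_bpm=0.0, dicrotic_amp=0.175, dicrotic_delay_s=0.22
        ),
    }
    return SynthConfig(
        n_per_class=1, powerline_amp=0.0, noise_sd=0.0, wander_amp=0.0,
        seed=7, morphology=morph,
    )


@pytest.fixture(scope="session")
def small_feature_matrix():
    """EMD-denoised 102-feature matrix for a small synthetic cohort (4 s records)."""
    cfg = SynthConfig(n_per_class=12, duration_s=4.0, seed=11)
    vectors = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for label in ("normal", "hypertension"):
            for i in range(cfg.n_per_class):
                sig = emd_denoise(generate_signal(cfg, label, i))
                vectors.append(extract_all(sig))
    matrix = matrix_from_vectors(vectors)
    X = matrix[FEATURE_REGISTRY].to_numpy()
    y = matrix["label"].to_numpy()
    return matrix, X, y


@pytest.fixture(scope="session")
def tiny_manifest(tmp_path_factory):
    """On-disk 3+3-signal dataset for pipeline/CLI tests."""
    out = tmp_path_factory.mktemp("tinydata")
    cfg = SynthConfig(n_per_class=5, duration_s=4.0, seed=21)
    generate_dataset(cfg, out)
    return out / "manifest.csv"


@pytest.fixture
def fast_pipeline_config():
    """HFSR + KNN-W configuration sized for tiny test cohorts."""
    return PipelineConfig(k_top=10, n_components=3)
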