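import numpy as np
import pytest

from ecgbench.annotations import builtin_task, default_label_dictionary
from ecgbench.synth import (
    GeneratorConfig,
    generate_beat_level_dataset,
    generate_recording_level_dataset,
)


@pytest.fixture(scope="session")
def label_dict():
    return default_label_dictionary()


@pytest.fixture(scope="session")
def form_task():
    return builtin_task("form")


@pytest.fixture(scope="session")
def rhythm_task():
    return builtin_task("rhythm_reduced")


@pytest.fixture(scope="session")
def beat_handle_small(tmp_path_factory):
    """12-patient beat-level dataset, 30 s records at 250 Hz."""
    cfg = GeneratorConfig(
        n_patients=12, records_per_patient=1, record_duration_s=30.0,
        fs=250.0, class_mixture={"SINUS": 0.6, "AFIB": 0.4}, noise_sd=0.05, seed=7,
    )
    return generate_beat_level_dataset(cfg, tmp_path_factory.mktemp("beat_small"))


@pytest.fixture(scope="session")
def beat_handle_40(tmp_path_factory):
    """40-patient beat-level dataset, 60 s records (the inter-patient
    cross-validation study condition)."""
    cfg = GeneratorConfig(
        n_patients=40, records_per_patient=1, record_duration_s=60.0,
        fs=250.0, class_mixture={"SINUS": 0.7, "AFIB": 0.3}, noise_sd=0.05, seed=1,
    )
    return generate_beat_level_dataset(cfg, tmp_path_factory.mktemp("beat40"))


@pytest.fixture(scope="session")
def rec_handle(tmp_path_factory):
    """Recording-level dataset: 30 single-label 10 s records at 500 Hz."""
    cfg = GeneratorConfig(
        n_patients=30, records_per_patient=1, record_duration_s=10.0,
        fs=500.0, noise_sd=0.05, seed=9,
        class_mixture={"SINUS": 0.4, "AFIB": 0.3, "STACH": 0.15, "SBRAD": 0.15},
    )
    return generate_recording_level_dataset(cfg, tmp_path_factory.mktemp("rec"))


def finite_diff_grad(tensor, f, eps=1e-6):
    """Central finite differences of scalar-valued f w.r.t. tensor.data."""
    g = np.zeros_like(tensor.data)
    it = np.nditer(tensor.data, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = tensor.data[i]
        tensor.data[i] = orig + eps
        fp = f()
        tensor.data[i] = orig - eps
        fm = f()
        tensor.data[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
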