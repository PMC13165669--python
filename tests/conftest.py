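"""Shared fixtures: synthetic datasets and desk-scale trained models.

The trained-model fixtures are session-scoped because training, although
reduced to desk scale (8 subjects, 200 segments, 30 epochs, narrow widths),
is the dominant cost of the suite; the end-to-end recovery and ablation
comparisons reuse the same seeded run.
"""

from __future__ import annotations

import numpy as np
import pytest

import radarecg as rg
from radarecg import autodiff as ad
from radarecg.demod import demodulate_displacement
from radarecg.model import ModelConfig
from radarecg.preprocess import preprocess_ecg, preprocess_radar
from radarecg.training import TrainConfig, predict, split_subject_kfold, train_fold

DESK_SEED = 11


def make_preprocessed_dataset(n_subjects: int, n_segments: int,
                              seed: int) -> rg.RadarEcgDataset:
    """Simulate, demodulate and preprocess a dataset in memory."""
    ds = rg.generate_dataset(n_subjects, n_segments, seed=seed)
    lam = ds.radar_config.wavelength
    for seg in ds.segments:
        x_rec = demodulate_displacement(seg.i_chan, seg.q_chan, lam)
        seg.x_rec = x_rec
        seg.x_card = preprocess_radar(x_rec)
        seg.ecg_clean = preprocess_ecg(seg.ecg)
    return ds


@pytest.fixture(scope="session")
def small_dataset() -> rg.RadarEcgDataset:
    """A quick 4-subject, 28-segment raw dataset for plumbing tests."""
    return rg.generate_dataset(4, 28, seed=5)


@pytest.fixture(scope="session")
def desk_dataset() -> rg.RadarEcgDataset:
    """The desk-scale study conditions: 8 subjects, 200 segments, preprocessed."""
    return make_preprocessed_dataset(8, 200, DESK_SEED)


@pytest.fixture(scope="session")
def desk_split(desk_dataset):
    folds = split_subject_kfold(desk_dataset.subject_ids, 4, seed=DESK_SEED)
    return folds[0]


def train_desk_model(dataset, fold, ablation: str):
    tcfg = TrainConfig(epochs=30, batch_size=4, k_folds=4, seed=DESK_SEED)
    mcfg = ModelConfig.desk_scale().with_ablation(ablation)
    with ad.use_dtype(np.float32):
        model, hist = train_fold(dataset, fold, tcfg, mcfg)
        test_segments = dataset.subset(fold[1]).segments
        y_hat = predict(model, test_segments)
    return model, hist, y_hat, test_segments


@pytest.fixture(scope="session")
def trained_full(desk_dataset, desk_split):
    return train_desk_model(desk_dataset, desk_split, "full")


@pytest.fixture(scope="session")
def trained_model1(desk_dataset, desk_split):
    return train_desk_model(desk_dataset, desk_split, "model1")


@pytest.fixture(scope="session")
def trained_model2(desk_dataset, desk_split):
    return train_desk_model(desk_dataset, desk_split, "model2")
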