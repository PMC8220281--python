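"""Shared fixtures: desk-scale regime study tables computed once per session."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import settings

import statescape as ss
from statescape.pipeline import PipelineConfig, run_pipeline

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

#: desk-scale study conditions for the full-pipeline regime comparison
N_SEEDS = 20
N_CHANNELS = 8
FS = 250.0


@pytest.fixture(scope="session")
def regime_tables():
    """Full-pipeline measure tables over 20 seeds x 3 regimes (C=8, 250 Hz, 10 s).

    Synthetic surrogates carry no mains interference and are generated in
    band, so the conditioning reduces to the global z-score.
    """
    cfg = PipelineConfig(filter_enabled=False)
    segments = []
    for seed in range(N_SEEDS):
        for regime in ("rich", "intermediate", "poor"):
            segments.append(
                ss.gen_regime(ss.RegimeSpec(regime, n_channels=N_CHANNELS, fs=FS, seed=1000 + seed))
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = run_pipeline(segments, cfg)
    assert not table.failures, f"pipeline failures on synthetic regimes: {table.failures}"
    for df in (table.opn_rows, table.tda_rows):
        df["regime"] = df["condition"].str.replace("synthetic-", "", regex=False)
        df["seed"] = df["segment"] // 3
    return table


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
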