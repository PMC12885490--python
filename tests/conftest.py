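"""Shared fixtures.

The expensive decoder-recovery experiment (high-separability session,
leave-one-run-out training over three seeds) runs once per session and is
shared by the model, xai, and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from mispeed.conformer import ConformerConfig, predict, train
from mispeed.preprocess import bandpass, epoch, iter_folds, normalize
from mispeed.simulate import (
    NoiseSpec,
    SessionDesign,
    default_conditions,
    generate_session,
)


@pytest.fixture(scope="session")
def study_design() -> SessionDesign:
    return SessionDesign()


@pytest.fixture(scope="session")
def small_design() -> SessionDesign:
    return SessionDesign(
        n_runs=1, trials_per_class_per_run={"rest": 2, "slow": 2, "medium": 2, "fast": 2}
    )


@pytest.fixture(scope="session")
def small_session(small_design):
    conds = default_conditions(small_design.channel_names)
    return generate_session(small_design, conds, NoiseSpec(), seed=11)


@pytest.fixture(scope="session")
def rhythm_band_models():
    """Models trained on a session whose only class-discriminative content is
    alpha/beta ERD over motor channels (no steady-state tones), for checking
    what frequency bands the temporal kernels specialize to."""
    import numpy as np

    from mispeed.montage import SSMRP_CHANNELS, gaussian_topography
    from mispeed.simulate import ConditionSpec

    design = SessionDesign(n_runs=2)
    ch = design.channel_names
    motor = gaussian_topography(ch, SSMRP_CHANNELS)
    erd = {"rest": (0, 0), "slow": (0.7, 0.05), "medium": (0.4, 0.4), "fast": (0.05, 0.7)}
    f0 = {"rest": 0.0, "slow": 0.9, "medium": 2.1, "fast": 2.6}
    conds = {
        lab: ConditionSpec(
            f0=f0[lab], harmonic_amps=(), erd_alpha=ea, erd_beta=eb, ssvep_amp=0.0,
            ssmrp_topography=motor, ssvep_topography=np.zeros(len(ch)),
        )
        for lab, (ea, eb) in erd.items()
    }
    noise = NoiseSpec(noise_scale=0.3, alpha_rhythm_amp=3.0, beta_rhythm_amp=2.0)
    session = generate_session(design, conds, noise, seed=13)
    epochs = normalize(epoch(bandpass(session, 4.0, 40.0), -1.0, 5.0))
    cfg = ConformerConfig(
        n_temporal_filters=8, embed_dim=8, n_attention_layers=1, n_heads=4,
        dropout=0.2, max_epochs=120, patience=30,
    )
    tr, te = next(iter_folds(epochs, "leave-one-run-out"))
    return [train(cfg, tr, te, seed=s) for s in (0, 1, 2)]


@pytest.fixture(scope="session")
def recovery_runs():
    """Three seeded leave-one-run-out recovery experiments on one
    high-separability session; returns per-seed pooled accuracies, the
    trained models, and the preprocessed epochs."""
    design = SessionDesign()
    conds = default_conditions(design.channel_names, grid_aligned=True, separability="high")
    session = generate_session(design, conds, NoiseSpec(noise_scale=0.5), seed=202)
    epochs = normalize(epoch(bandpass(session, 4.0, 40.0), -1.0, 5.0))
    cfg = ConformerConfig(max_epochs=60, patience=15)
    accuracies, models = [], []
    for seed in (0, 1, 2):
        y_true, y_pred = [], []
        for k, (tr, te) in enumerate(iter_folds(epochs, "leave-one-run-out")):
            tm = train(cfg, tr, te, seed=seed * 10 + k)
            y_true.append(te.labels)
            y_pred.append(predict(tm, te))
            if k == 0:
                models.append(tm)
        accuracies.append(float((np.concatenate(y_pred) == np.concatenate(y_true)).mean()))
    return {"accuracies": accuracies, "models": models, "epochs": epochs, "session": session}
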