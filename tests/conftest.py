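"""Shared fixtures: small layouts and one session-scoped end-to-end training run.

The expensive pipeline run (simulate -> thin -> train -> denoise -> evaluate)
is computed once per session and reused by the training-recovery and
acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from atacdenoise import (
    DenseTrack,
    GenomeLayout,
    ModelConfig,
    SyntheticGenomeSpec,
    TilingSpec,
    TrainConfig,
)
from atacdenoise.inference import denoise_genome
from atacdenoise.metrics import classification_metrics, track_regression_metrics
from atacdenoise.pipeline import DenoisingFixture, build_denoising_fixture, train_denoiser


@pytest.fixture
def small_layout() -> GenomeLayout:
    return GenomeLayout((("chrA", 1000), ("chrB", 500)))


@dataclass
class PipelineRun:
    fixture: DenoisingFixture
    tiling: TilingSpec
    model: object
    run: object
    denoised: DenseTrack
    prob: DenseTrack
    holdout_chrom: str
    pearson_noisy: float
    pearson_denoised: float
    auprc_noisy_coverage: float
    auprc_model_prob: float


#: study conditions of the synthetic-recovery experiment: ~3 Mb over a training
#: chromosome plus validation (chr20) and holdout (chr10) chromosomes, default
#: generator statistics, 10x thinning; small network trainable on one CPU core.
RECOVERY_LAYOUT = GenomeLayout(
    (("chr1", 2_000_000), ("chr20", 512_000), ("chr10", 512_000))
)
RECOVERY_SPEC = SyntheticGenomeSpec(layout=RECOVERY_LAYOUT, n_peaks=60, seed=11)
RECOVERY_TILING = TilingSpec(interval_len=25_000, pad=600)
RECOVERY_MODEL = ModelConfig(
    filters=8, kernel=25, dilation=4,
    n_blocks_regression=2, n_blocks_classification=1, seed=5,
)
RECOVERY_TRAIN = TrainConfig(lr=2e-3, epochs=10, batch_size=8, seed=17)


@pytest.fixture(scope="session")
def recovery_run() -> PipelineRun:
    """Train a small model on the thinned fixture and evaluate the holdout chromosome."""
    fx = build_denoising_fixture(RECOVERY_SPEC, thin_p=0.1)
    model, run = train_denoiser(fx, RECOVERY_MODEL, RECOVERY_TILING, RECOVERY_TRAIN)
    denoised, prob = denoise_genome(model, fx.noisy, tiling=RECOVERY_TILING)

    holdout = "chr10"
    sub_layout = GenomeLayout(((holdout, RECOVERY_LAYOUT.length_of(holdout)),))
    sub = lambda tr: DenseTrack(sub_layout, {holdout: tr[holdout]})  # noqa: E731
    r_noisy = track_regression_metrics(sub(fx.noisy), sub(fx.clean)).pearson
    r_den = track_regression_metrics(sub(denoised), sub(fx.clean)).pearson
    labels = fx.labels.mask_arrays(RECOVERY_LAYOUT)[holdout].astype(np.float64)
    auprc_noisy = classification_metrics(sub(fx.noisy).flatten(), labels)[0]
    auprc_prob = classification_metrics(sub(prob).flatten(), labels)[0]
    return PipelineRun(
        fixture=fx,
        tiling=RECOVERY_TILING,
        model=model,
        run=run,
        denoised=denoised,
        prob=prob,
        holdout_chrom=holdout,
        pearson_noisy=r_noisy,
        pearson_denoised=r_den,
        auprc_noisy_coverage=auprc_noisy,
        auprc_model_prob=auprc_prob,
    )
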