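"""End-to-end conveniences: fixture construction and the standard train/apply run.

These helpers wire the module-level operations together in the canonical
order (simulate -> thin -> cut sites -> coverage -> labels -> windows ->
train -> denoise -> evaluate) without adding behavior of their own.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genomic_io import DenseTrack, IntervalSet
from .model import ModelConfig, TrainedModel, build_model
from .preprocess import (
    TilingSpec,
    coverage_from_cutsites,
    cut_sites_from_reads,
    extract_examples,
    label_peaks,
    poisson_label_scores,
)
from .synthetic import ReadRecord, SyntheticGenomeSpec, simulate_reads, thin_reads
from .training import SplitSpec, TrainConfig, TrainingRun, split_examples, train

__all__ = ["DenoisingFixture", "build_denoising_fixture", "train_denoiser"]


@dataclass
class DenoisingFixture:
    """A matched clean/noisy pair with labels, as used for training."""

    spec: SyntheticGenomeSpec
    reads: list[ReadRecord]
    noisy_reads: list[ReadRecord]
    truth_peaks: IntervalSet
    clean: DenseTrack
    noisy: DenseTrack
    labels: IntervalSet


def build_denoising_fixture(
    spec: SyntheticGenomeSpec,
    thin_p: float = 0.1,
    extension: int = 100,
    label_cutoff: float = 3.0,
) -> DenoisingFixture:
    """Simulate a clean experiment, thin it, and build both coverage tracks.

    The clean track is the extended-cut-site coverage of all simulated reads;
    the noisy track comes from binomial thinning at ``thin_p``. Labels are
    Poisson-tail peak calls on the clean track (the clean-data peak calls that
    the classification head learns to reproduce).
    """
    reads, truth_peaks = simulate_reads(spec)
    noisy_reads = thin_reads(reads, thin_p, seed=spec.seed + 1)
    layout = spec.layout
    clean = coverage_from_cutsites(
        cut_sites_from_reads(reads, layout), extension, layout
    )
    noisy = coverage_from_cutsites(
        cut_sites_from_reads(noisy_reads, layout), extension, layout
    )
    labels = label_peaks(poisson_label_scores(clean), cutoff=label_cutoff)
    return DenoisingFixture(
        spec=spec,
        reads=reads,
        noisy_reads=noisy_reads,
        truth_peaks=truth_peaks,
        clean=clean,
        noisy=noisy,
        labels=labels,
    )


def train_denoiser(
    fixture: DenoisingFixture,
    model_config: ModelConfig,
    tiling: TilingSpec,
    train_config: TrainConfig,
    splitspec: SplitSpec = SplitSpec(),
) -> tuple[TrainedModel, TrainingRun]:
    """Window the fixture, split by chromosome, and train a fresh model."""
    examples = extract_examples(fixture.noisy, fixture.clean, fixture.labels, tiling)
    train_ex, val_ex, _holdout = split_examples(examples, splitspec)
    model = build_model(model_config)
    return train(model, train_ex, val_ex, train_config)
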