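"""Self-benchmarks: run the whole pipeline on simulated data with known
truth and score the recovery.

These helpers wire the stages together fully in memory (no files), so a
single call measures what the analysis — unique-index quantification,
trimmed-mean summarization, quantile-offset normalization, Welch/BH
calling — recovers from a dataset whose true differential genes are
known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diffexpr import DEConfig, DEResults, DifferentialExpression, ExperimentDesign
from .index import build_unique_index
from .mask import parse_mask
from .normalize import QuantileOffsetNormalization, make_quantile_grid
from .pipeline import PipelineConfig
from .quantify import count_reads, summarize_expression
from .simulate import SyntheticExperiment, make_experiment


@dataclass(frozen=True)
class RecoveryScore:
    """Confusion summary of one simulated differential-expression run."""

    seed: int
    n_true_up: int
    n_called_up: int
    true_positives: int
    false_positives: int

    @property
    def sensitivity(self) -> float:
        return self.true_positives / self.n_true_up if self.n_true_up else float("nan")

    @property
    def false_discovery_proportion(self) -> float:
        return self.false_positives / self.n_called_up if self.n_called_up else 0.0


def analyze_experiment(
    experiment: SyntheticExperiment, config: PipelineConfig | None = None
) -> DEResults:
    """Run index -> count -> quantify -> normalize -> de in memory."""
    config = config or PipelineConfig()
    mask = parse_mask(config.mask)
    index = build_unique_index(
        experiment.genome, experiment.annotation, mask, canonical=config.canonical
    )
    tables = [
        count_reads(experiment.read_seqs(s), index, sample_id=s)
        for s in experiment.truth.samples.index
    ]
    raw = summarize_expression(tables, index, config.trim_fraction)
    grid = make_quantile_grid(config.q_lo, config.q_hi, config.q_step)
    normalized = (
        QuantileOffsetNormalization(raw, grid=grid, pseudocount=config.pseudocount)
        .fit(method=config.offset_fit)
        .apply(raw)
    )
    groups = experiment.truth.samples["group"]
    design = ExperimentDesign(dict(groups), config.contrast)
    return DifferentialExpression(normalized, design).fit(
        DEConfig(fc_threshold=config.fc_threshold, alpha=config.alpha,
                 two_sided=config.two_sided)
    )


def score_recovery(
    seed: int, config: PipelineConfig | None = None, **experiment_kwargs
) -> RecoveryScore:
    """Simulate one experiment and score up-calls against the truth."""
    experiment = make_experiment(seed=seed, **experiment_kwargs)
    results = analyze_experiment(experiment, config)
    true_up = set(experiment.truth.true_up_genes())
    called = set(results.up)
    tp = len(called & true_up)
    return RecoveryScore(
        seed=seed, n_true_up=len(true_up), n_called_up=len(called),
        true_positives=tp, false_positives=len(called) - tp,
    )


def recovery_study(
    seeds, config: PipelineConfig | None = None, **experiment_kwargs
) -> tuple[float, float, list[RecoveryScore]]:
    """Average sensitivity and false-discovery proportion over seeds."""
    scores = [score_recovery(s, config, **experiment_kwargs) for s in seeds]
    sens = float(np.mean([s.sensitivity for s in scores]))
    fdp = float(np.mean([s.false_discovery_proportion for s in scores]))
    return sens, fdp, scores
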