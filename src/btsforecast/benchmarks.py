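"""Standard synthetic benchmarks used by the test suite and examples.

Two study settings are provided:

* a smoke benchmark — six i.i.d. 6,000-base sequences at the default
  pipeline configuration, exercising every stage end to end;
* an ablation benchmark — one 6,000-base first-order-Markov sequence with
  strongly persistent base composition (self-transition probability 0.99),
  condensed with 20-base windows so the windowed base statistics retain
  strong window-to-window correlation (the composition chain's second
  eigenvalue is near 0.987, giving roughly 0.75 correlation across a
  20-base window) — a stand-in for the compositional patchiness
  (isochores, GC islands) of real genomes — run at a reduced configuration
  small enough to repeat across many seeds.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .cnn_lstm import CnnLstmSpec
from .ensemble import PipelineConfig, run_sequence
from .pso import PsoConfig
from .sequence_io import DnaSequence, SyntheticSpec, generate_dna

#: Base-persistent transition matrix: stay with 0.99, switch uniformly.
PERSISTENT_TRANSITIONS = tuple(
    tuple(0.99 if i == j else 0.01 / 3 for j in range(4)) for i in range(4)
)


def smoke_config(seed: int = 0, n_sequences: int = 6, length: int = 6000) -> PipelineConfig:
    """Six i.i.d. synthetic sequences at the default configuration."""
    return PipelineConfig(
        synthetic=tuple(
            SyntheticSpec(length=length, seed=seed * 1000 + k) for k in range(n_sequences)
        ),
        seed=seed,
    )


def ablation_config(seed: int = 0, length: int = 6000, **overrides) -> PipelineConfig:
    """Reduced single-sequence Markov benchmark for repeated-seed sweeps."""
    base = PipelineConfig(
        synthetic=(
            SyntheticSpec(length=length, model="markov1",
                          base_probs=PERSISTENT_TRANSITIONS, seed=seed),
        ),
        seed=seed,
        window_len=20,
        arfima_pso=PsoConfig(swarm_size=3, iterations=2, seed=seed),
        arfima_bounds=((0, 3), (-0.49, 0.49), (0, 3)),
        cnn_spec=CnnLstmSpec(n_epochs=200, n_hidden=8, learning_rate=0.02,
                             n_kernels=16, kernel_width=2),
        cnn_pso=PsoConfig(swarm_size=3, iterations=2, seed=seed),
        cnn_bounds=((50, 250), (4, 16), (-2.5, -1.0)),
        sapt_patience=3,
        sapt_max_epochs=40,
    )
    return replace(base, **overrides)


ABLATION_FLAGS = {
    "full": {},
    "sapt": {"disable_sapt": True},
    "cnn": {"disable_cnn": True},
    "ar": {"disable_ar": True},
    "ea": {"disable_tuning": True},
}


def run_ablation_suite(seeds, variants=tuple(ABLATION_FLAGS)) -> dict[str, list[float]]:
    """Validation MAPE of each framework variant across seeds.

    Returns {variant: [val MAPE per seed]} with the input sequence shared
    across variants within a seed, so differences reflect the removed part
    rather than the data draw.
    """
    out: dict[str, list[float]] = {v: [] for v in variants}
    for seed in seeds:
        cfg0 = ablation_config(seed=seed)
        seq = generate_dna(cfg0.synthetic[0])
        for variant in variants:
            cfg = replace(cfg0, **ABLATION_FLAGS[variant])
            rep = run_sequence(seq, cfg)
            out[variant].append(rep["validation"]["mape"])
    return out


def median_ablation_deltas(results: dict[str, list[float]]) -> dict[str, float]:
    """Median validation MAPE of each ablated variant minus the full model.

    Positive deltas mean the removal hurt (the expected direction)."""
    med = {v: float(np.median(vals)) for v, vals in results.items()}
    return {v: med[v] - med["full"] for v in results if v != "full"}
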