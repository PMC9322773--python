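"""Synthetic fixtures: tone mixtures for EMD validation and degradation panels.

Two generators:

* :func:`make_tone_mixture` — sums of pure (optionally AM-modulated)
  sinusoids with additive Gaussian noise, with each noiseless component
  returned.  These are the classical EMD validation inputs: a correct
  decomposition recovers each tone as one IMF.

* :func:`make_expression_panel` — a gene x time expression matrix
  emulating an RNA-degradation time course: per-gene baselines (FPKM
  scale, log-uniform), exponential decay for a configurable fraction of
  genes, a shared oscillation, and multiplicative lognormal noise.  The
  returned truth record carries every drawn parameter and the noiseless
  values, so ground-truth comparisons need no re-simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionMatrix

__all__ = [
    "ToneSpec",
    "ToneMixtureSpec",
    "ExpressionPanelSpec",
    "make_tone_mixture",
    "make_expression_panel",
    "DEFAULT_TIME_GRID",
    "DEFAULT_TIME_LABELS",
]

# The degradation study's sampling layout: triplicates at 0, 2, 4, 6 h,
# labelled 0.1h ... 6.3h and treated as 12 consecutive time points.
DEFAULT_TIME_GRID = np.array(
    [0.1, 0.2, 0.3, 2.1, 2.2, 2.3, 4.1, 4.2, 4.3, 6.1, 6.2, 6.3]
)
DEFAULT_TIME_LABELS = [f"{t}h" for t in DEFAULT_TIME_GRID]


@dataclass
class ToneSpec:
    frequency: float
    amplitude: float = 1.0
    am_depth: float = 0.0
    am_rate: float = 0.0


@dataclass
class ToneMixtureSpec:
    tones: list[ToneSpec]
    duration: float = 2.0
    n_samples: int = 1000
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = [t.frequency for t in self.tones]
        if any(f <= 0 for f in freqs):
            raise ValueError("tone frequencies must be positive")
        if len(set(freqs)) != len(freqs):
            raise ValueError("tone frequencies must be distinct")
        fmax = max(freqs)
        if self.n_samples < 16 * fmax * self.duration:
            raise ValueError(
                f"unresolvable spec: {self.n_samples} samples cannot resolve "
                f"{fmax} Hz over {self.duration}s (need >= {16 * fmax * self.duration:.0f})"
            )


def make_tone_mixture(spec: ToneMixtureSpec) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Generate a tone mixture.

    Returns ``(t, signal, components)`` where ``components`` are the
    noiseless tones (ordered as in the spec) whose sum plus noise is the
    signal.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.linspace(0.0, spec.duration, spec.n_samples, endpoint=False)
    components = []
    for tone in spec.tones:
        env = tone.amplitude * (
            1.0 + tone.am_depth * np.sin(2 * np.pi * tone.am_rate * t)
        )
        components.append(env * np.sin(2 * np.pi * tone.frequency * t))
    signal = np.sum(components, axis=0)
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=t.size)
    return t, signal, components


@dataclass
class ExpressionPanelSpec:
    """Degradation-panel parameters.

    Defaults mirror the study conditions: 60 degradation-related genes
    over 12 time points (triplicates at 0/2/4/6 h), 70% of genes
    decaying with per-gene rates lambda ~ U(0.05, 0.5) per hour,
    log-uniform baselines on an FPKM-like scale, a mild shared
    oscillation (period matching the 2 h block spacing), and
    multiplicative lognormal noise at a replicate-level sigma of 0.15.
    """

    n_genes: int = 60
    time_grid: np.ndarray = field(default_factory=lambda: DEFAULT_TIME_GRID.copy())
    time_labels: list[str] | None = None
    decay_fraction: float = 0.7
    decay_rate_range: tuple[float, float] = (0.05, 0.5)  # per hour
    baseline_range: tuple[float, float] = (1.0, 1000.0)  # FPKM-like, log-uniform
    oscillation_amplitude: float = 0.15
    oscillation_period: float = 2.0  # hours
    noise_sd: float = 0.15  # lognormal sigma
    seed: int = 0


def make_expression_panel(
    spec: ExpressionPanelSpec,
) -> tuple[ExpressionMatrix, dict]:
    """Generate a synthetic degradation panel and its truth record.

    Each gene g follows ``b_g * exp(-lambda_g t) * (1 + A sin(2 pi t / P
    + phi_g)) * eps`` with lognormal eps.  The truth record holds the
    drawn baselines, decay rates, phases, and the noiseless matrix.
    """
    rng = np.random.default_rng(spec.seed)
    G = spec.n_genes
    t = np.asarray(spec.time_grid, dtype=float)
    T = t.size
    lo, hi = spec.baseline_range
    baselines = np.exp(rng.uniform(np.log(lo), np.log(hi), size=G))
    decaying = rng.random(G) < spec.decay_fraction
    rates = np.where(
        decaying, rng.uniform(*spec.decay_rate_range, size=G), 0.0
    )
    phases = rng.uniform(0, 2 * np.pi, size=G)
    osc = 1.0 + spec.oscillation_amplitude * np.sin(
        2 * np.pi * t[None, :] / spec.oscillation_period + phases[:, None]
    )
    noiseless = baselines[:, None] * np.exp(-rates[:, None] * t[None, :]) * osc
    if spec.noise_sd > 0:
        noise = np.exp(rng.normal(0.0, spec.noise_sd, size=(G, T)))
    else:
        noise = np.ones((G, T))
    values = noiseless * noise
    gene_ids = [f"gene{g + 1:03d}" for g in range(G)]
    labels = spec.time_labels or [f"{x}h" for x in t]
    matrix = ExpressionMatrix(gene_ids, list(labels), values)
    truth = {
        "seed": spec.seed,
        "time_grid": t.tolist(),
        "baselines": baselines.tolist(),
        "decay_rates": rates.tolist(),
        "decaying": decaying.tolist(),
        "phases": phases.tolist(),
        "noiseless": noiseless.tolist(),
    }
    return matrix, truth
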