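"""End-to-end Multi-LSTM orchestration.

The decomposition-combination recipe: withhold the target time column,
normalize the remaining matrix per gene, concatenate gene trajectories
into one series, decompose it by EMD, train one LSTM forecaster per
component, then for every gene predict each component one step past the
gene's last training position, sum the component predictions and invert
the normalization.  ``direction="reverse"`` predicts the *initial*
(0 h, undegraded) time point from later observations by time-reversing
every trajectory first; ``"forward"`` predicts the final time point.

Normalization is fit on the training columns only.  By default the
decomposition runs on the complete concatenated series while every
forecaster trains exclusively on windows that exclude the withheld
positions (``decompose_scope="full"``); a strictly causal
``"train_only"`` scope is selectable — the methods note discusses the
trade-off.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .data_io import (
    ExpressionMatrix,
    NormalizationRecord,
    assemble_series,
    denormalize,
    normalize,
)
from .emd import Decomposition, EMDConfig, decompose
from .lstm import LSTMForecaster, TrainingConfig
from .metrics import MetricsReport, evaluate_predictions

logger = logging.getLogger("multilstm")

__all__ = [
    "PipelineConfig",
    "MultiLSTMModel",
    "PredictionResult",
    "fit",
    "predict",
    "evaluate",
    "per_component_report",
    "persistence_baseline",
    "single_lstm_baseline",
]


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end run, with defaults."""

    direction: str = "reverse"  # "reverse": predict first column; "forward": last
    normalization: str = "minmax"
    norm_scope: str = "per_gene"
    ordering: str = "gene_major"
    decompose: bool = True
    # "full": decompose the complete concatenated series (the withheld
    # column enters the decomposition but never any forecaster's
    # training windows); "train_only": decompose the training columns
    # alone.  See the methods note for why "full" is the default.
    decompose_scope: str = "full"
    model_residual: bool = True
    emd: EMDConfig = field(default_factory=EMDConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def snapshot(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class MultiLSTMModel:
    config: PipelineConfig
    decomposition: Decomposition
    forecasters: list  # one per modeled component
    record: NormalizationRecord
    gene_ids: list[str]
    time_labels: list[str]  # original order, including the withheld label
    target_label: str
    train_series: np.ndarray  # assembled normalized signal the EMD saw
    n_train_times: int
    seg_len: int = 0  # per-gene block length in the assembled series

    @property
    def n_components(self) -> int:
        return len(self.forecasters)


@dataclass
class PredictionResult:
    per_component: np.ndarray  # (n_components, G) normalized predictions
    recombined: np.ndarray  # (G,) normalized, sum over components
    predictions: np.ndarray  # (G,) de-normalized expression at target time
    gene_ids: list[str]
    target_label: str
    direction: str
    n_components: int


def _oriented_values(matrix: ExpressionMatrix, direction: str) -> tuple[np.ndarray, list[str]]:
    """Time-reverse the matrix for reverse prediction so the target
    column is always the last one."""
    if direction == "reverse":
        return matrix.values[:, ::-1].copy(), list(matrix.time_labels[::-1])
    return matrix.values.copy(), list(matrix.time_labels)


def _gene_segment(
    comp: np.ndarray, g: int, G: int, n_seg: int, Tt: int, ordering: str
) -> np.ndarray:
    """Component values along gene g's *training* positions.

    ``n_seg`` is the per-gene block length in the assembled series (T
    when the full series was decomposed, T-1 otherwise); only the first
    ``Tt`` positions of each block are training positions.
    """
    if ordering == "gene_major":
        return comp[g * n_seg:g * n_seg + Tt]
    return comp[np.arange(Tt) * G + g]


def _within_gene_windows(
    comp: np.ndarray, G: int, n_seg: int, Tt: int, L: int, ordering: str
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding windows that never cross a gene boundary or touch a
    withheld position.

    The concatenated series resets sharply between genes (each gene is
    normalized to its own range); windows straddling that reset would
    teach the forecasters the artificial sawtooth instead of
    within-gene dynamics.  Restricting windows to one gene's training
    positions also matches the prediction task exactly: continue one
    gene's trajectory one step past its last observed point.
    """
    from .lstm import make_windows

    Xs, ys = [], []
    for g in range(G):
        seg = _gene_segment(comp, g, G, n_seg, Tt, ordering)
        X, y = make_windows(seg, L)
        Xs.append(X)
        ys.append(y)
    return np.vstack(Xs), np.concatenate(ys)


def _modeled_components(d: Decomposition, model_residual: bool) -> list[np.ndarray]:
    comps = [imf.c for imf in d.imfs]
    if model_residual:
        comps.append(d.residual)
    return comps


def fit(
    matrix: ExpressionMatrix,
    config: PipelineConfig | None = None,
    forecaster_factory=None,
) -> MultiLSTMModel:
    """Fit the full decomposition-combination model.

    The target column (first time point for reverse, last for forward)
    is withheld; the rest is normalized, assembled and decomposed, and
    one forecaster is trained per component.  ``forecaster_factory`` may
    replace the LSTM (it receives the window matrix, the targets and the
    training config and must return an object with
    ``predict_next(context, index)``) — used for plumbing checks with
    stub forecasters.
    """
    cfg = config or PipelineConfig()
    if matrix.n_times < 4:
        raise ValueError(f"need at least 4 time points, got {matrix.n_times}")
    values, labels = _oriented_values(matrix, cfg.direction)
    target_label = labels[-1]
    train = ExpressionMatrix(list(matrix.gene_ids), labels[:-1], values[:, :-1])
    train_norm, record = normalize(train, cfg.normalization, cfg.norm_scope)

    from .data_io import apply_normalization

    if cfg.decompose and cfg.decompose_scope == "full":
        # the decomposition sees the whole series (normalized with the
        # training record); forecaster windows never touch the withheld
        # positions
        full_norm = ExpressionMatrix(
            list(matrix.gene_ids), labels, apply_normalization(values, record)
        )
        signal = assemble_series(full_norm, cfg.ordering)
        n_seg = matrix.n_times
    else:
        signal = assemble_series(train_norm, cfg.ordering)
        n_seg = matrix.n_times - 1

    if cfg.decompose:
        d = decompose(signal.x, cfg.emd)
        if d.n_imfs == 0:
            logger.warning(
                "decomposition produced 0 IMFs; falling back to a single "
                "forecaster on the raw normalized series"
            )
            d = Decomposition(imfs=[], residual=signal.x.copy(), config=cfg.emd.snapshot())
            comps = [d.residual]
        else:
            comps = _modeled_components(d, cfg.model_residual)
    else:
        d = Decomposition(imfs=[], residual=signal.x.copy(), config={})
        comps = [d.residual]

    factory = forecaster_factory or (
        lambda X, y, tc: LSTMForecaster.fit_windows(X, y, tc)
    )
    G = matrix.n_genes
    Tt = matrix.n_times - 1
    forecasters = []
    for j, comp in enumerate(comps):
        X, y = _within_gene_windows(
            comp, G, n_seg, Tt, cfg.training.window, cfg.ordering
        )
        tc = TrainingConfig(
            window=cfg.training.window,
            hidden_size=cfg.training.hidden_size,
            learning_rate=cfg.training.learning_rate,
            epochs=cfg.training.epochs,
            seed=cfg.training.seed + cfg.seed + j,
            grad_clip=cfg.training.grad_clip,
        )
        forecasters.append(factory(X, y, tc))
        logger.debug("trained forecaster %d/%d", j + 1, len(comps))

    return MultiLSTMModel(
        config=cfg,
        decomposition=d,
        forecasters=forecasters,
        record=record,
        gene_ids=list(matrix.gene_ids),
        time_labels=list(matrix.time_labels),
        target_label=target_label,
        train_series=signal.x,
        n_train_times=Tt,
        seg_len=n_seg,
    )


def predict(model: MultiLSTMModel) -> PredictionResult:
    """Predict the withheld time point for every gene.

    For gene g (gene_major ordering) each component forecaster reads the
    last L component values of that gene's training trajectory and emits
    the component value one step ahead; component predictions are
    summed and the per-gene sums de-normalized.
    """
    cfg = model.config
    G = len(model.gene_ids)
    Tt = model.n_train_times
    L = cfg.training.window
    comps = _modeled_components(model.decomposition, cfg.model_residual) if (
        cfg.decompose and model.decomposition.n_imfs > 0
    ) else [model.decomposition.residual]
    per_comp = np.zeros((len(model.forecasters), G))
    for j, (comp, fc) in enumerate(zip(comps, model.forecasters)):
        for g in range(G):
            seg = _gene_segment(comp, g, G, model.seg_len, Tt, cfg.ordering)
            per_comp[j, g] = fc.predict_next(seg[-L:], g)
    recombined = per_comp.sum(axis=0)
    # de-normalize: the recombined value is the normalized expression at
    # the target time for each gene
    grid = np.repeat(recombined[:, None], 1, axis=1)
    denorm = denormalize(grid, model.record, (G, 1)).ravel()
    return PredictionResult(
        per_component=per_comp,
        recombined=recombined,
        predictions=denorm,
        gene_ids=list(model.gene_ids),
        target_label=model.target_label,
        direction=cfg.direction,
        n_components=len(model.forecasters),
    )


def evaluate(
    result: PredictionResult,
    truth,
    rmse_variant: str = "sample",
    r2_variant: str = "explained",
) -> MetricsReport:
    """Score predictions against per-gene truth at the target time."""
    truth = np.asarray(truth, dtype=float).ravel()
    if truth.size != result.predictions.size:
        raise ValueError(
            f"length mismatch: {truth.size} truths vs "
            f"{result.predictions.size} predictions"
        )
    return evaluate_predictions(
        truth,
        result.predictions,
        rmse_variant=rmse_variant,
        r2_variant=r2_variant,
        direction=result.direction,
        n_components=result.n_components,
    )


def per_component_report(
    model: MultiLSTMModel,
    matrix: ExpressionMatrix,
    result: PredictionResult | None = None,
    rmse_variant: str = "sample",
    r2_variant: str = "explained",
) -> list[dict]:
    """Per-component accuracy table at the withheld positions.

    Per-component "truth" is obtained by decomposing the *full* series
    (all time points, same config) and reading each component at the
    withheld positions; component counts of the full and training
    decompositions can differ, so rows are aligned by component index up
    to the shorter of the two (residual last).
    """
    cfg = model.config
    res = result or predict(model)
    values, labels = _oriented_values(matrix, cfg.direction)
    from .data_io import apply_normalization

    G, T = values.shape
    if cfg.decompose and cfg.decompose_scope == "full" and model.seg_len == T:
        d_full = model.decomposition
    else:
        # decompose the complete normalized series afresh
        full_norm = apply_normalization(values, model.record)
        full_mat = ExpressionMatrix(list(matrix.gene_ids), labels, full_norm)
        full_sig = assemble_series(full_mat, cfg.ordering)
        d_full = decompose(full_sig.x, cfg.emd)
    truth_comps = _modeled_components(d_full, cfg.model_residual)
    if cfg.ordering == "gene_major":
        target_pos = np.arange(G) * T + (T - 1)
    else:
        target_pos = (T - 1) * G + np.arange(G)
    rows = []
    n = min(len(truth_comps), res.per_component.shape[0])
    for j in range(n):
        truth_j = truth_comps[j][target_pos]
        pred_j = res.per_component[j]
        name = (
            f"IMF{j + 1}"
            if j < len(truth_comps) - (1 if cfg.model_residual else 0)
            else "residual"
        )
        rep = evaluate_predictions(
            truth_j, pred_j, rmse_variant=rmse_variant, r2_variant=r2_variant
        )
        rows.append(
            {
                "component": name,
                "rmse": rep.rmse,
                "mae": rep.mae,
                "r_squared": rep.r_squared,
                "n": rep.n,
            }
        )
    return rows


def persistence_baseline(matrix: ExpressionMatrix, direction: str = "reverse") -> np.ndarray:
    """Last-observation carry: predict the target column by its nearest
    observed neighbour in time."""
    values, _ = _oriented_values(matrix, direction)
    return values[:, -2].copy()


def single_lstm_baseline(
    matrix: ExpressionMatrix, config: PipelineConfig | None = None
) -> np.ndarray:
    """Single LSTM on the raw (undecomposed) normalized series."""
    cfg = config or PipelineConfig()
    base = PipelineConfig(
        direction=cfg.direction,
        normalization=cfg.normalization,
        norm_scope=cfg.norm_scope,
        ordering=cfg.ordering,
        decompose=False,
        model_residual=cfg.model_residual,
        emd=cfg.emd,
        training=cfg.training,
        seed=cfg.seed,
    )
    model = fit(matrix, base)
    return predict(model).predictions
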