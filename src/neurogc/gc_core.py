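"""Granger-causality estimation on top of the sequence regressors.

The Granger paradigm: a source channel is declared to influence a target
when removing the source from the regression increases the target's
prediction error.  The index reported here is the classical log error
ratio

    GC(source → target) = ln( err_restricted / err_full )

with errors measured as mean-squared prediction error on a held-out tail
of the series (20% by default), floored at zero in public matrices.

Four estimators share this interface:

``bilstm_gc``
    stacked bidirectional LSTM; the regression window extends on *both*
    sides of the prediction position, so dependencies on future samples
    (forward dependencies) are visible.
``rnn_gc``
    unidirectional single-layer LSTM over the past window only.
``nn_gc``
    one-hidden-layer feed-forward network on the flattened lag window
    (temporal structure deliberately discarded).
``linear_gc_oracle``
    ordinary least-squares vector autoregression — the textbook linear GC,
    used as an independent reference.

Edge detection uses circular-shift surrogates: the source channel is
rotated in time (destroying cross-channel coupling, preserving its
autocorrelation) and the score recomputed; by default the detection
threshold is the (1 − alpha) quantile of the *maximum* surrogate score
across all candidate pairs, which controls the family-wise false-positive
rate of the detected edge set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .neural_models import (
    MLPRegressor,
    PredictorConfig,
    StackedLSTMRegressor,
)

__all__ = [
    "GCConfig",
    "DetectionConfig",
    "GCMatrix",
    "DetectionResult",
    "PerfectFitError",
    "fit_full_model",
    "gc_pair",
    "estimate_matrix",
    "estimate",
    "detect_edges",
    "detect_pairs",
    "GCEstimationResult",
]

ESTIMATORS = ("bilstm_gc", "rnn_gc", "nn_gc", "linear_gc_oracle")


class PerfectFitError(RuntimeError):
    """Raised when the full model's held-out error is numerically zero."""


@dataclass
class DetectionConfig:
    """How scored matrices are turned into edge sets.

    ``permutation_null`` builds per-pair circular-shift surrogate scores;
    ``correction="max_stat"`` (default) thresholds every pair at the
    (1 − alpha) quantile of the across-pair maximum surrogate score, the
    permutation analogue of family-wise error control; ``correction="none"``
    uses per-pair quantiles.  ``fixed_threshold`` simply compares scores to
    ``threshold``.
    """

    method: str = "permutation_null"  # "permutation_null" | "fixed_threshold"
    alpha: float = 0.05
    threshold: float = 0.0
    n_permutations: int = 40
    correction: str = "max_stat"  # "max_stat" | "none"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.method not in ("permutation_null", "fixed_threshold"):
            raise ValueError(f"unknown detection method {self.method!r}")
        if self.method == "permutation_null" and self.n_permutations < 20:
            raise ValueError("permutation_null needs n_permutations >= 20")


@dataclass
class GCConfig:
    """Estimator choice plus everything needed to train and score it."""

    estimator: str = "bilstm_gc"
    model_order: int = 5  # lag window of nn_gc / linear_gc_oracle
    predictor: PredictorConfig = field(default_factory=PredictorConfig)
    n_trials: int = 10
    #: "retrain_without_channel" | "ablate_input_at_inference" | None.
    #: None picks the estimator's natural default: retraining for the linear
    #: oracle (classical GC), input ablation for the neural engines (makes
    #: multi-trial averaging desk-scale).
    restriction: str | None = None
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    holdout_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")

    @property
    def effective_restriction(self) -> str:
        if self.restriction is not None:
            return self.restriction
        return ("retrain_without_channel" if self.estimator == "linear_gc_oracle"
                else "ablate_input_at_inference")


@dataclass
class GCMatrix:
    """n×n directed dependency strengths; values[i, j] is i → j (0-based
    storage, 1-based in all I/O).  Off-diagonal entries are nonnegative log
    error ratios; the diagonal carries no information and is NaN."""

    values: np.ndarray
    channel_labels: list[str]
    estimator: str

    def __post_init__(self) -> None:
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("GC matrix must be square")
        np.fill_diagonal(self.values, np.nan)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass
class DetectionResult:
    """Detected edge set with the scores and null thresholds behind it.

    ``edges`` holds 1-based (source, target) pairs.
    """

    edges: set[tuple[int, int]]
    scores: GCMatrix
    null_quantiles: np.ndarray
    signed_scores: np.ndarray | None = None


# --------------------------------------------------------------------------
# window construction
# --------------------------------------------------------------------------

@dataclass
class _WindowSpec:
    """Geometry of the regression windows for one estimator."""

    kind: str               # "bidir" | "causal" | "flat"
    half: int = 0           # bidir: context samples on each side
    length: int = 0         # causal: past samples; flat: model order
    t_list: np.ndarray = None  # window centre positions (prediction targets)

    def positions(self, t: np.ndarray) -> np.ndarray:
        """Sample indices feeding the window centred/ending at t (2D: len(t)×W)."""
        if self.kind == "bidir":
            offs = np.concatenate([np.arange(-self.half, 0), np.arange(1, self.half + 1)])
        else:
            offs = np.arange(-self.length, 0)
        return t[:, None] + offs[None, :]


def _window_spec(series_len: int, estimator: str, config: GCConfig) -> _WindowSpec:
    if estimator == "bilstm_gc":
        half = config.predictor.max_sequence_length // 2
        t = np.arange(half, series_len - half)
        return _WindowSpec("bidir", half=half, t_list=t)
    if estimator == "rnn_gc":
        L = config.predictor.max_sequence_length
        t = np.arange(L, series_len)
        return _WindowSpec("causal", length=L, t_list=t)
    # nn_gc / linear_gc_oracle: flattened lag window of the model order
    p = config.model_order
    t = np.arange(p, series_len)
    return _WindowSpec("flat", length=p, t_list=t)


def _gather_windows(series: np.ndarray, spec: _WindowSpec, t: np.ndarray) -> np.ndarray:
    """(n_ch, T) series → (N, W, n_ch) sequence windows or (N, W*n_ch) flat."""
    pos = spec.positions(t)                       # (N, W)
    win = series[:, pos]                          # (n_ch, N, W)
    win = np.moveaxis(win, 0, 2)                  # (N, W, n_ch)
    if spec.kind == "flat":
        return win.reshape(win.shape[0], -1)      # time-major flatten
    return win


# --------------------------------------------------------------------------
# fitted full model
# --------------------------------------------------------------------------

@dataclass
class FittedModel:
    """A trained full regression for one target channel.

    Holds the standardization, window geometry and train/test split so
    restricted and surrogate errors can be computed from modified series.
    """

    estimator: str
    target: int                    # 0-based channel
    config: GCConfig
    spec: _WindowSpec
    mean: np.ndarray
    std: np.ndarray
    t_train: np.ndarray
    t_test: np.ndarray
    predictor: object              # StackedLSTMRegressor | MLPRegressor | None
    beta: np.ndarray | None        # linear oracle coefficients (with intercept)
    err_full_train: float
    err_full_test: float
    raw_target_var: float

    def standardize(self, series: np.ndarray) -> np.ndarray:
        return (series - self.mean[:, None]) / self.std[:, None]

    def _predict_flat(self, X: np.ndarray) -> np.ndarray:
        if self.beta is not None:
            return np.column_stack([X, np.ones(len(X))]) @ self.beta
        return self.predictor.predict(X)

    def test_error(self, series_std: np.ndarray, zero_channel: int | None = None,
                   chunk: int = 4096, t_eval: np.ndarray | None = None) -> float:
        """Held-out MSE, optionally with one input channel zeroed (ablated).

        ``t_eval`` restricts evaluation to a subset of held-out positions
        (used by pair-level detection to keep surrogate scoring affordable;
        observed and null statistics then share the same subset).
        """
        t_test = self.t_test if t_eval is None else t_eval
        y = series_std[self.target, t_test]
        X = _gather_windows(series_std, self.spec, t_test)
        if zero_channel is not None:
            if self.spec.kind == "flat":
                n_ch = series_std.shape[0]
                X = X.copy()
                X[:, zero_channel::n_ch] = 0.0
            else:
                X = X.copy()
                X[:, :, zero_channel] = 0.0
        preds = np.concatenate([
            self._predict_flat(X[i : i + chunk]) for i in range(0, len(X), chunk)
        ])
        return float(np.mean((preds - y) ** 2))

    def surrogate_errors(self, series_std: np.ndarray, source: int,
                         offsets: np.ndarray, chunk: int = 4096,
                         t_eval: np.ndarray | None = None) -> np.ndarray:
        """Held-out MSE with the source channel circularly shifted, one value
        per offset; all surrogates are evaluated in one batched pass."""
        n_ch = series_std.shape[0]
        t_test = self.t_test if t_eval is None else t_eval
        y = series_std[self.target, t_test]
        X = _gather_windows(series_std, self.spec, t_test)
        pos = self.spec.positions(t_test)
        K, N = len(offsets), len(t_test)
        Xbig = np.repeat(X[None], K, axis=0)
        for k, off in enumerate(offsets):
            rolled = np.roll(series_std[source], int(off))
            if self.spec.kind == "flat":
                Xbig[k][:, source::n_ch] = rolled[pos]
            else:
                Xbig[k][:, :, source] = rolled[pos]
        Xbig = Xbig.reshape((K * N,) + X.shape[1:])
        preds = np.concatenate([
            self._predict_flat(Xbig[i : i + chunk]) for i in range(0, len(Xbig), chunk)
        ]).reshape(K, N)
        return np.mean((preds - y[None, :]) ** 2, axis=1)


def _ols_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    A = np.column_stack([X, np.ones(len(X))])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta


def fit_full_model(
    series: np.ndarray,
    target: int,
    config: GCConfig,
    seed: int = 0,
) -> FittedModel:
    """Train the full (all-channel) regression for one target channel.

    The series is split in time: the leading (1 − holdout_fraction) of
    windows trains the model, the tail evaluates it.  Channels are centred
    and scaled to unit variance using training-range statistics.
    """
    series = np.asarray(series, dtype=float)
    n_ch, T = series.shape
    if n_ch < 2:
        raise ValueError("need at least 2 channels")
    est = config.estimator
    spec = _window_spec(T, est, config)
    if len(spec.t_list) < 10:
        raise ValueError(f"series too short ({T} samples) for estimator {est}")
    if np.std(series[target]) == 0:
        raise ValueError(f"target channel {target + 1} is constant")

    n_win = len(spec.t_list)
    n_test = max(1, int(round(config.holdout_fraction * n_win)))
    t_train = spec.t_list[: n_win - n_test]
    t_test = spec.t_list[n_win - n_test :]

    train_end = int(t_train[-1]) + 1
    mean = series[:, :train_end].mean(axis=1)
    std = series[:, :train_end].std(axis=1)
    std[std == 0] = 1.0
    series_std = (series - mean[:, None]) / std[:, None]

    X_train = _gather_windows(series_std, spec, t_train)
    y_train = series_std[target, t_train]

    pcfg = replace(config.predictor, seed=seed)
    predictor = None
    beta = None
    if est == "linear_gc_oracle":
        beta = _ols_fit(X_train, y_train)
    elif est == "nn_gc":
        predictor = MLPRegressor(X_train.shape[1], pcfg).fit(X_train, y_train)
    elif est == "rnn_gc":
        predictor = StackedLSTMRegressor(
            n_ch, pcfg, bidirectional=False
        ).fit(X_train, y_train)
    else:  # bilstm_gc
        half = spec.half
        predictor = StackedLSTMRegressor(
            n_ch, pcfg, bidirectional=True,
            pos_forward=half - 1, pos_backward=half,
        ).fit(X_train, y_train)

    fm = FittedModel(
        estimator=est, target=target, config=config, spec=spec,
        mean=mean, std=std, t_train=t_train, t_test=t_test,
        predictor=predictor, beta=beta,
        err_full_train=float("nan"), err_full_test=float("nan"),
        raw_target_var=float(np.var(series[target])),
    )
    if beta is not None:
        resid = np.column_stack([X_train, np.ones(len(X_train))]) @ beta - y_train
        fm.err_full_train = float(np.mean(resid ** 2))
    else:
        preds = np.concatenate([
            predictor.predict(X_train[i : i + 4096]) for i in range(0, len(X_train), 4096)
        ])
        fm.err_full_train = float(np.mean((preds - y_train) ** 2))
    fm.err_full_test = fm.test_error(series_std)
    return fm


# --------------------------------------------------------------------------
# pair scores
# --------------------------------------------------------------------------

_EPS = 1e-300
#: held-out error (on standardized data) below this is a numerically perfect fit
_PERFECT_FIT_TOL = 1e-12


def _restricted_error(fm: FittedModel, series_std: np.ndarray, source: int) -> float:
    cfg = fm.config
    if cfg.effective_restriction == "ablate_input_at_inference":
        return fm.test_error(series_std, zero_channel=source)
    # retrain without the source channel
    return _refit_error(fm, series_std, drop_channel=source)


def _refit_error(fm: FittedModel, series_std: np.ndarray, drop_channel: int | None,
                 replace_channel: tuple[int, np.ndarray] | None = None) -> float:
    """Refit the full model on (possibly modified) inputs; return held-out MSE."""
    cfg = fm.config
    n_ch = series_std.shape[0]
    s = series_std
    if replace_channel is not None:
        ch, values = replace_channel
        s = series_std.copy()
        s[ch] = values
    keep = [c for c in range(n_ch) if c != drop_channel]
    s_in = s[keep]
    y_train = s[fm.target, fm.t_train]
    y_test = s[fm.target, fm.t_test]
    X_train = _gather_windows(s_in, fm.spec, fm.t_train)
    X_test = _gather_windows(s_in, fm.spec, fm.t_test)
    if fm.estimator == "linear_gc_oracle":
        beta = _ols_fit(X_train, y_train)
        preds = np.column_stack([X_test, np.ones(len(X_test))]) @ beta
        return float(np.mean((preds - y_test) ** 2))
    # neural retraining path: same architecture, same seed, fewer channels
    pcfg = fm.config.predictor
    if fm.estimator == "nn_gc":
        net = MLPRegressor(X_train.shape[1], pcfg).fit(X_train, y_train)
    elif fm.estimator == "rnn_gc":
        net = StackedLSTMRegressor(len(keep), pcfg, bidirectional=False).fit(X_train, y_train)
    else:
        half = fm.spec.half
        net = StackedLSTMRegressor(
            len(keep), pcfg, bidirectional=True,
            pos_forward=half - 1, pos_backward=half,
        ).fit(X_train, y_train)
    preds = np.concatenate([
        net.predict(X_test[i : i + 4096]) for i in range(0, len(X_test), 4096)
    ])
    return float(np.mean((preds - y_test) ** 2))


def gc_pair(
    series: np.ndarray,
    source: int,
    target: int,
    config: GCConfig,
    seed: int = 0,
    fitted: FittedModel | None = None,
    signed: bool = False,
) -> float:
    """GC score of source → target (channels 0-based here; I/O is 1-based).

    Returns ``max(0, ln(err_restricted / err_full))`` unless ``signed=True``
    (the raw log ratio, used by detection nulls and group t-tests, where
    flooring would bias the statistic).
    """
    if source == target:
        raise ValueError("source and target must differ")
    series = np.asarray(series, dtype=float)
    fm = fitted or fit_full_model(series, target, config, seed=seed)
    series_std = fm.standardize(series)
    err_full = fm.err_full_test
    if err_full < _PERFECT_FIT_TOL:
        raise PerfectFitError(
            f"full model for channel {target + 1} has zero held-out error"
        )
    err_r = _restricted_error(fm, series_std, source)
    val = float(np.log(max(err_r, _EPS) / err_full))
    return val if signed else max(0.0, val)


# --------------------------------------------------------------------------
# matrices, trials, detection
# --------------------------------------------------------------------------

@dataclass
class GCEstimationResult:
    """Matrix plus the per-trial fitted models needed for detection."""

    matrix: GCMatrix
    signed_values: np.ndarray          # trial-averaged raw log ratios
    fits: list[dict[int, FittedModel]]  # one dict target→model per trial
    trial_series: list[np.ndarray]
    config: GCConfig
    seed: int


def _trial_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def estimate(
    series: np.ndarray,
    config: GCConfig,
    seed: int = 0,
    channel_labels: Sequence[str] | None = None,
    series_factory: Callable[[int], np.ndarray] | None = None,
) -> GCEstimationResult:
    """Score all ordered channel pairs, averaged over ``config.n_trials``.

    Each trial uses an independent training seed; when ``series_factory`` is
    given (the input is a simulator specification rather than a fixed
    recording) each trial also draws a fresh realization from it.
    """
    series = np.asarray(series, dtype=float)
    n_ch = series.shape[0]
    labels = list(channel_labels) if channel_labels else [str(i + 1) for i in range(n_ch)]
    seeds = _trial_seeds(seed, config.n_trials)
    acc = np.zeros((n_ch, n_ch))
    fits: list[dict[int, FittedModel]] = []
    trial_series: list[np.ndarray] = []
    for trial, tseed in enumerate(seeds):
        s = series_factory(tseed) if series_factory is not None else series
        trial_series.append(s)
        models: dict[int, FittedModel] = {}
        for tgt in range(n_ch):
            fm = fit_full_model(s, tgt, config, seed=tseed)
            models[tgt] = fm
            series_std = fm.standardize(s)
            if fm.err_full_test < _PERFECT_FIT_TOL:
                raise PerfectFitError(
                    f"full model for channel {tgt + 1} has zero held-out error"
                )
            for src in range(n_ch):
                if src == tgt:
                    continue
                err_r = _restricted_error(fm, series_std, src)
                acc[src, tgt] += np.log(max(err_r, _EPS) / fm.err_full_test)
        fits.append(models)
    signed = acc / config.n_trials
    values = np.maximum(signed, 0.0)
    matrix = GCMatrix(values=values, channel_labels=labels, estimator=config.estimator)
    return GCEstimationResult(
        matrix=matrix, signed_values=signed, fits=fits,
        trial_series=trial_series, config=config, seed=seed,
    )


def estimate_matrix(
    series: np.ndarray,
    config: GCConfig,
    seed: int = 0,
    channel_labels: Sequence[str] | None = None,
    series_factory: Callable[[int], np.ndarray] | None = None,
) -> GCMatrix:
    """Trial-averaged GC matrix (see :func:`estimate` for the full result)."""
    return estimate(series, config, seed, channel_labels, series_factory).matrix


def detect_edges(
    matrix: GCMatrix | None,
    series: np.ndarray,
    config: GCConfig,
    seed: int = 0,
    result: GCEstimationResult | None = None,
) -> DetectionResult:
    """Turn GC scores into a directed edge set.

    ``permutation_null`` mode recomputes each pair's score with the source
    channel circularly shifted (``n_permutations`` shared offsets, each at
    least one window length, so marginal autocorrelation is preserved while
    cross-channel alignment is destroyed).  With ``correction="max_stat"``
    an edge must exceed the (1 − alpha) quantile of the across-pair maximum
    surrogate score.  Passing the ``result`` of :func:`estimate` reuses its
    trained models; otherwise the estimation is rerun.
    """
    series = np.asarray(series, dtype=float)
    if result is None:
        result = estimate(series, config, seed=seed)
    mat = result.matrix if matrix is None else matrix
    n_ch = mat.n_channels
    det = config.detection
    pairs = [(s, t) for s in range(n_ch) for t in range(n_ch) if s != t]
    signed = result.signed_values

    if det.method == "fixed_threshold":
        edges = {(s + 1, t + 1) for s, t in pairs if mat.values[s, t] > det.threshold}
        nq = np.full((n_ch, n_ch), det.threshold)
        np.fill_diagonal(nq, np.nan)
        return DetectionResult(edges=edges, scores=mat, null_quantiles=nq,
                               signed_scores=signed)

    K = det.n_permutations
    rng = np.random.default_rng(_trial_seeds(seed ^ 0x5EED, 1)[0])
    surr = np.zeros((n_ch, n_ch, K))
    for trial, models in enumerate(result.fits):
        s_raw = result.trial_series[trial]
        T = s_raw.shape[1]
        # shared shift offsets, bounded away from 0 by a full window length
        margin = max(config.predictor.max_sequence_length, config.model_order) + 1
        offsets = rng.integers(margin, T - margin, size=K)
        for tgt in range(n_ch):
            fm = models[tgt]
            series_std = fm.standardize(s_raw)
            err_full = fm.err_full_test
            for src in range(n_ch):
                if src == tgt:
                    continue
                if fm.config.effective_restriction == "ablate_input_at_inference":
                    err_r = fm.test_error(series_std, zero_channel=src)
                    err_shift = fm.surrogate_errors(series_std, src, offsets)
                    surr[src, tgt] += np.log(max(err_r, _EPS) / np.maximum(err_shift, _EPS))
                else:
                    err_r = _refit_error(fm, series_std, drop_channel=src)
                    for k, off in enumerate(offsets):
                        rolled = np.roll(series_std[src], int(off))
                        err_shift = _refit_error(
                            fm, series_std, drop_channel=None,
                            replace_channel=(src, rolled),
                        )
                        surr[src, tgt, k] += np.log(max(err_r, _EPS) / max(err_shift, _EPS))
    surr /= len(result.fits)

    nq = np.full((n_ch, n_ch), np.nan)
    edges: set[tuple[int, int]] = set()
    # an edge must beat its surrogate null AND actually improve prediction
    # (signed score > 0): a null quantile below zero cannot admit a pair
    # whose restricted model outperformed the full one
    if det.correction == "max_stat":
        null_max = np.array([
            max(surr[s, t, k] for s, t in pairs) for k in range(K)
        ])
        thr = float(np.quantile(null_max, 1 - det.alpha, method="higher"))
        for s, t in pairs:
            nq[s, t] = thr
            if signed[s, t] > max(thr, 0.0):
                edges.add((s + 1, t + 1))
    else:
        for s, t in pairs:
            q = float(np.quantile(surr[s, t], 1 - det.alpha, method="higher"))
            nq[s, t] = q
            if signed[s, t] > max(q, 0.0):
                edges.add((s + 1, t + 1))
    return DetectionResult(edges=edges, scores=mat, null_quantiles=nq,
                           signed_scores=signed)


def detect_pairs(
    series: np.ndarray,
    pairs: Sequence[tuple[int, int]],
    config: GCConfig,
    seed: int = 0,
    eval_cap: int = 400,
) -> list[dict]:
    """Hypothesis-driven test of specific directed pairs (0-based channels).

    Unlike :func:`detect_edges`, which screens every ordered pair and
    controls the family-wise error of the whole edge set, this tests only
    the named pairs, each against its own circular-shift null at
    ``detection.alpha``.  Full models are fitted only for the targets that
    appear in ``pairs``, which makes trial-averaged tests affordable at
    full series length.

    Returns one dict per pair: source, target (1-based), score (trial-
    averaged signed log ratio), null_q, detected.
    """
    series = np.asarray(series, dtype=float)
    det = config.detection
    if det.method != "permutation_null":
        raise ValueError("detect_pairs requires the permutation_null method")
    K = det.n_permutations
    targets = sorted({t for _, t in pairs})
    seeds = _trial_seeds(seed, config.n_trials)
    rng = np.random.default_rng(_trial_seeds(seed ^ 0x5EED, 1)[0])
    T = series.shape[1]
    margin = max(config.predictor.max_sequence_length, config.model_order) + 1
    offsets = rng.integers(margin, T - margin, size=K)

    obs = {p: 0.0 for p in pairs}
    surr = {p: np.zeros(K) for p in pairs}
    for tseed in seeds:
        for tgt in targets:
            fm = fit_full_model(series, tgt, config, seed=tseed)
            if fm.err_full_test < _PERFECT_FIT_TOL:
                raise PerfectFitError(
                    f"full model for channel {tgt + 1} has zero held-out error"
                )
            # evenly spaced evaluation subset shared by observed and null
            n_test = len(fm.t_test)
            if eval_cap and n_test > eval_cap:
                t_eval = fm.t_test[np.linspace(0, n_test - 1, eval_cap).astype(int)]
            else:
                t_eval = fm.t_test
            series_std = fm.standardize(series)
            err_full = fm.test_error(series_std, t_eval=t_eval)
            for src, t2 in pairs:
                if t2 != tgt:
                    continue
                if fm.config.effective_restriction == "ablate_input_at_inference":
                    err_r = fm.test_error(series_std, zero_channel=src, t_eval=t_eval)
                    obs[(src, tgt)] += np.log(max(err_r, _EPS) / max(err_full, _EPS))
                    err_shift = fm.surrogate_errors(series_std, src, offsets,
                                                    t_eval=t_eval)
                else:
                    err_r = _refit_error(fm, series_std, drop_channel=src)
                    obs[(src, tgt)] += np.log(max(err_r, _EPS) / fm.err_full_test)
                    err_shift = np.array([
                        _refit_error(fm, series_std, drop_channel=None,
                                     replace_channel=(src, np.roll(series_std[src], int(off))))
                        for off in offsets
                    ])
                surr[(src, tgt)] += np.log(max(err_r, _EPS) / np.maximum(err_shift, _EPS))
    out = []
    for (src, tgt) in pairs:
        score = obs[(src, tgt)] / config.n_trials
        null = surr[(src, tgt)] / config.n_trials
        q = float(np.quantile(null, 1 - det.alpha, method="higher"))
        out.append({
            "source": src + 1, "target": tgt + 1, "score": float(score),
            "null_q": q, "detected": bool(score > max(q, 0.0)),
        })
    return out
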