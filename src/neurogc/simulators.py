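"""Ground-truthed multivariate time-series benchmarks.

Three generator families, each a small vector-autoregression with known
directed dependencies:

* model ``A`` — five channels, purely linear couplings with short lags;
* model ``B`` — same topology, but the 1→2 coupling is quadratic with a
  10-sample delay (long, nonlinear lag);
* model ``C`` — model B plus two *forward-dependent* channels ``y1``/``y2``
  whose current value is driven by **future** samples of ``x1``/``x4``/``x5``
  (negative lag), detectable only by acausal (bidirectional) regressors.

Every dataset carries its generating dependency set so estimators can be
scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "NoiseSpec",
    "DependencySpec",
    "SimulatedDataset",
    "simulate",
    "ground_truth_edges",
    "channel_labels",
    "MODEL_COEFFS",
]

#: default series lengths used throughout: 5000 samples for A/B, 5020 for C.
DEFAULT_LENGTH = {"A": 5000, "B": 5000, "C": 5020}

#: samples generated and discarded before the returned window, so the
#: returned series is near its stationary regime regardless of the all-zero
#: initial condition.
BURN_IN = 100

#: generator coefficients, exposed as overridable module constants.
MODEL_COEFFS = {
    "ar1": 0.952,       # x1 self, lag 1
    "ar2": -0.9025,     # x1 self, lag 2
    "c12": 0.5,         # x1 -> x2
    "c13": -0.4,        # x1 -> x3
    "c14": -0.5,        # x1 -> x4
    "c445": 0.252,      # x4/x5 cross and self couplings
    "cy1": 0.6,         # x1 -> y1 (forward, model C)
    "cy2": -0.5,        # x1 -> y2 (forward, model C)
}


class StreamPolicy(str, Enum):
    """How model C's noise terms are drawn.

    The printed y1/y2 equations literally reuse the innovation streams of x2
    and x4.  ``shared_as_written`` reproduces that literal reading;
    ``independent_per_equation`` (default) gives every equation its own
    stream, avoiding spurious instantaneous correlation between x2/y1 and
    x4/y2 that the shared reading would induce.
    """

    independent_per_equation = "independent_per_equation"
    shared_as_written = "shared_as_written"


@dataclass(frozen=True)
class NoiseSpec:
    """Innovation process: i.i.d. Gaussian, default zero mean / unit variance."""

    mean: float = 0.0
    variance: float = 1.0
    stream_policy: StreamPolicy = StreamPolicy.independent_per_equation

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError(f"noise variance must be >= 0, got {self.variance}")


@dataclass(frozen=True, order=True)
class DependencySpec:
    """One directed generator coupling.

    ``lag`` is in samples; a *negative* lag means the target depends on the
    source's future (a forward dependency).  Channels are 1-based, matching
    the human-readable ``1→2`` convention used in all I/O.
    """

    source: int
    target: int
    lag: int
    form: str = "linear"  # "linear" | "quadratic"
    coefficient: float = 0.0

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("self-dependencies are excluded from ground truth")
        if self.lag == 0:
            raise ValueError("lag must be nonzero")
        if self.form not in ("linear", "quadratic"):
            raise ValueError(f"unknown form {self.form!r}")


@dataclass
class SimulatedDataset:
    """A channels×samples matrix plus the dependency set that generated it."""

    series: np.ndarray
    ground_truth: frozenset[DependencySpec]
    model_id: str
    seed: int
    channel_labels: list[str] = field(default_factory=list)
    #: number of terminal samples of each forward channel that had no future
    #: source available and were filled with standard-normal draws (model C).
    terminal_fill: dict[str, int] = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.series.shape[0]

    @property
    def n_samples(self) -> int:
        return self.series.shape[1]


def channel_labels(model_id: str) -> list[str]:
    """Channel labels in storage order: x1..x5 (+ y1, y2 for model C)."""
    _check_model(model_id)
    labels = [f"x{i}" for i in range(1, 6)]
    if model_id == "C":
        labels += ["y1", "y2"]
    return labels


def _check_model(model_id: str) -> None:
    if model_id not in ("A", "B", "C"):
        raise ValueError(f"unknown model_id {model_id!r}; expected 'A', 'B' or 'C'")


def ground_truth_edges(model_id: str) -> frozenset[DependencySpec]:
    """The directed dependency set of a generator model (1-based channels).

    Models A and B share the five-pair topology 1→2, 1→3, 1→4, 4→5, 5→4;
    model B turns 1→2 quadratic with a 10-sample delay.  Model C keeps
    model B's five pairs and adds the forward couplings into y1 (channel 6)
    and y2 (channel 7), all with negative lag.
    """
    _check_model(model_id)
    c = MODEL_COEFFS
    if model_id == "A":
        e12 = DependencySpec(1, 2, 2, "linear", c["c12"])
    else:
        e12 = DependencySpec(1, 2, 10, "quadratic", c["c12"])
    edges = {
        e12,
        DependencySpec(1, 3, 3, "linear", c["c13"]),
        DependencySpec(1, 4, 2, "linear", c["c14"]),
        DependencySpec(4, 5, 1, "linear", -c["c445"]),
        DependencySpec(5, 4, 1, "linear", c["c445"]),
    }
    if model_id == "C":
        edges |= {
            DependencySpec(1, 6, -2, "linear", c["cy1"]),
            DependencySpec(1, 7, -2, "linear", c["cy2"]),
            DependencySpec(4, 7, -1, "linear", c["c445"]),
            DependencySpec(5, 7, -1, "linear", c["c445"]),
        }
    return frozenset(edges)


def simulate(
    model_id: str,
    length: int | None = None,
    seed: int = 0,
    noise: NoiseSpec | None = None,
) -> SimulatedDataset:
    """Generate one realization of model A, B or C.

    Parameters
    ----------
    model_id : {"A", "B", "C"}
    length : int, optional
        Returned number of samples per channel (defaults: 5000 for A/B,
        5020 for C).  A burn-in of 100 extra samples is generated and
        discarded so the returned window is near-stationary.
    seed : int
        Seeds a dedicated PCG64 stream; identical arguments give
        bit-identical output.
    noise : NoiseSpec, optional
        Innovation distribution and (for model C) stream-sharing policy.

    Returns
    -------
    SimulatedDataset
        ``series`` is channels×samples; rows follow ``channel_labels``.
        For model C the last two samples of y1 and y2 have no future source
        inside the window and are filled with standard-normal draws; the
        counts are recorded in ``terminal_fill``.
    """
    _check_model(model_id)
    if length is None:
        length = DEFAULT_LENGTH[model_id]
    min_len = 52 if model_id == "C" else 50
    if length < min_len:
        raise ValueError(f"model {model_id} needs length >= {min_len}, got {length}")
    noise = noise or NoiseSpec()

    rng = np.random.default_rng(seed)
    T = length + BURN_IN
    sd = float(np.sqrt(noise.variance))
    # one innovation matrix for the five x equations; model C's y equations
    # either reuse rows 1 and 3 (shared_as_written) or draw fresh rows.
    eps = rng.normal(noise.mean, sd, size=(5, T))
    c = MODEL_COEFFS

    x = np.zeros((5, T))
    for t in range(T):
        x1m1 = x[0, t - 1] if t >= 1 else 0.0
        x1m2 = x[0, t - 2] if t >= 2 else 0.0
        x1m3 = x[0, t - 3] if t >= 3 else 0.0
        x4m1 = x[3, t - 1] if t >= 1 else 0.0
        x5m1 = x[4, t - 1] if t >= 1 else 0.0
        x[0, t] = c["ar1"] * x1m1 + c["ar2"] * x1m2 + eps[0, t]
        if model_id == "A":
            x[1, t] = c["c12"] * x1m2 + eps[1, t]
        else:
            x1m10 = x[0, t - 10] if t >= 10 else 0.0
            x[1, t] = c["c12"] * x1m10 ** 2 + eps[1, t]
        x[2, t] = c["c13"] * x1m3 + eps[2, t]
        x[3, t] = c["c14"] * x1m2 + c["c445"] * x4m1 + c["c445"] * x5m1 + eps[3, t]
        x[4, t] = -c["c445"] * x4m1 + c["c445"] * x5m1 + eps[4, t]

    if model_id != "C":
        series = x[:, BURN_IN:]
        return SimulatedDataset(
            series=series,
            ground_truth=ground_truth_edges(model_id),
            model_id=model_id,
            seed=seed,
            channel_labels=channel_labels(model_id),
        )

    # model C: forward channels read future x samples.  The last 2 samples of
    # y1/y2 have no future source inside the generated range and are filled
    # with standard-normal draws, mirroring the generators' stated fallback
    # for unfillable points.
    if noise.stream_policy is StreamPolicy.shared_as_written:
        eps_y1, eps_y2 = eps[1], eps[3]
    else:
        eps_y1 = rng.normal(noise.mean, sd, size=T)
        eps_y2 = rng.normal(noise.mean, sd, size=T)

    y = np.zeros((2, T))
    y[0, : T - 2] = c["cy1"] * x[0, 2:] + eps_y1[: T - 2]
    y[1, : T - 2] = (
        c["cy2"] * x[0, 2:]
        + c["c445"] * x[3, 1 : T - 1]
        + c["c445"] * x[4, 1 : T - 1]
        + eps_y2[: T - 2]
    )
    n_fill = 2
    y[0, T - n_fill :] = rng.standard_normal(n_fill)
    y[1, T - n_fill :] = rng.standard_normal(n_fill)

    series = np.vstack([x, y])[:, BURN_IN:]
    return SimulatedDataset(
        series=series,
        ground_truth=ground_truth_edges("C"),
        model_id="C",
        seed=seed,
        channel_labels=channel_labels("C"),
        terminal_fill={"y1": n_fill, "y2": n_fill},
    )
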