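"""Core domain types: trial layout, source time series, frequency bands.

A trial is a continuous multichannel source-signal recording consisting of a
pre-stimulus baseline segment followed by a task segment that is divided into
three sequential cognitive phases (premise coding, premise integration,
conclusion). All durations are in milliseconds; all signals are node-by-sample
float64 arrays.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrialDesign",
    "SourceTimeSeries",
    "FrequencyBand",
    "DEFAULT_BANDS",
    "PHASE_NAMES",
    "default_design",
]

PHASE_NAMES = ("premise_coding", "premise_integration", "conclusion")


@dataclass(frozen=True)
class FrequencyBand:
    """A named frequency band [low, high) in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high):
            raise ValueError(f"band {self.name}: need 0 <= low < high, got [{self.low}, {self.high})")

    def contains(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Boolean membership mask over a frequency grid (Hz)."""
        f = np.asarray(freqs_hz, dtype=float)
        return (f >= self.low) & (f < self.high)


#: Conventional EEG band edges; the gamma ceiling matches the 60 Hz analysis
#: bandwidth of the preprocessing filter.
DEFAULT_BANDS: dict[str, FrequencyBand] = {
    "theta": FrequencyBand("theta", 4.0, 8.0),
    "alpha": FrequencyBand("alpha", 8.0, 13.0),
    "beta": FrequencyBand("beta", 13.0, 30.0),
    "gamma": FrequencyBand("gamma", 30.0, 60.0),
}


@dataclass(frozen=True)
class TrialDesign:
    """Static layout of one trial.

    Parameters
    ----------
    sampling_rate :
        Sampling rate in Hz.
    baseline_duration, task_duration :
        Durations in ms. The trial is ``baseline_duration + task_duration``
        long; the baseline precedes task onset.
    phase_boundaries :
        Strictly increasing ms offsets inside ``(0, task_duration)`` splitting
        the task segment into the three reasoning phases.
    frontal_nodes, parietal_nodes :
        Disjoint node-label sets; their union is the analyzed node set, in
        order ``frontal + parietal``.
    """

    sampling_rate: float = 500.0
    baseline_duration: float = 1000.0
    task_duration: float = 9000.0
    phase_boundaries: tuple[float, ...] = (3000.0, 6000.0)
    frontal_nodes: tuple[str, ...] = ()
    parietal_nodes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.baseline_duration < 0 or self.task_duration <= 0:
            raise ValueError("durations must be positive")
        pb = tuple(float(b) for b in self.phase_boundaries)
        if list(pb) != sorted(set(pb)):
            raise ValueError("phase_boundaries must be strictly increasing")
        if pb and (pb[0] <= 0 or pb[-1] >= self.task_duration):
            raise ValueError("phase_boundaries must lie strictly inside (0, task_duration)")
        if set(self.frontal_nodes) & set(self.parietal_nodes):
            raise ValueError("frontal and parietal node sets must be disjoint")
        object.__setattr__(self, "phase_boundaries", pb)
        object.__setattr__(self, "frontal_nodes", tuple(self.frontal_nodes))
        object.__setattr__(self, "parietal_nodes", tuple(self.parietal_nodes))

    # -- derived geometry ---------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        return self.frontal_nodes + self.parietal_nodes

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def total_duration(self) -> float:
        return self.baseline_duration + self.task_duration

    def ms_to_samples(self, ms: float) -> int:
        n = ms * self.sampling_rate / 1000.0
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"{ms} ms is not an integer number of samples at fs={self.sampling_rate}")
        return int(round(n))

    @property
    def n_baseline_samples(self) -> int:
        return self.ms_to_samples(self.baseline_duration)

    @property
    def n_task_samples(self) -> int:
        return self.ms_to_samples(self.task_duration)

    @property
    def n_samples(self) -> int:
        return self.n_baseline_samples + self.n_task_samples

    def phase_of(self, task_ms: float) -> str:
        """Phase label of a task-time offset (ms since task onset)."""
        for bound, name in zip(self.phase_boundaries, PHASE_NAMES):
            if task_ms < bound:
                return name
        return PHASE_NAMES[len(self.phase_boundaries)]


@dataclass
class SourceTimeSeries:
    """One trial's node-by-sample source signal with its design metadata."""

    data: np.ndarray  # (n_nodes, n_samples) float64
    design: TrialDesign
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (nodes x samples)")
        if self.data.shape[0] != self.design.n_nodes:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but design names {self.design.n_nodes} nodes"
            )
        if self.data.shape[1] != self.design.n_samples:
            raise ValueError(
                f"data has {self.data.shape[1]} samples but design requires {self.design.n_samples}"
            )

    @property
    def node_labels(self) -> tuple[str, ...]:
        return self.design.nodes

    def node_index(self, label: str) -> int:
        try:
            return self.design.nodes.index(label)
        except ValueError:
            raise KeyError(f"unknown node label {label!r}") from None

    def with_data(self, data: np.ndarray) -> "SourceTimeSeries":
        return SourceTimeSeries(data=data, design=self.design, meta=dict(self.meta))

    @property
    def baseline(self) -> np.ndarray:
        return self.data[:, : self.design.n_baseline_samples]

    @property
    def task(self) -> np.ndarray:
        return self.data[:, self.design.n_baseline_samples :]


def default_design(
    n_frontal: int = 8,
    n_parietal: int = 5,
    sampling_rate: float = 500.0,
) -> TrialDesign:
    """Standard trial layout: 1 s baseline + 9 s task in three 3 s phases.

    Node labels F1..Fk / P1..Pm. The default 8x5 layout yields the 40
    frontal->parietal ordered pairs used for the region-of-interest network.
    """
    return TrialDesign(
        sampling_rate=sampling_rate,
        frontal_nodes=tuple(f"F{i + 1}" for i in range(n_frontal)),
        parietal_nodes=tuple(f"P{i + 1}" for i in range(n_parietal)),
    )
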