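"""Core record types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoltageSweep", "UnitRecord", "TbSeries", "IVCurve", "PeriodSpec"]


@dataclass
class VoltageSweep:
    """One stimulus-locked membrane-potential trace.

    ``vm`` is in mV on a uniform time grid ``time_s`` (seconds).  The
    pre-stimulus window is used for baseline statistics and must end at
    or before ``stim_onset``.  For current-step protocols ``stim_onset``
    marks the step onset and ``injected_pa``/``step_duration`` describe
    the step.
    """

    time_s: np.ndarray
    vm: np.ndarray
    sampling_rate: float
    stim_onset: float
    pre_stim_window: tuple[float, float]
    temperature: float
    cell_id: str
    sweep_index: int
    injected_pa: float | None = None
    step_duration: float | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.vm = np.asarray(self.vm, dtype=float)
        if self.time_s.shape != self.vm.shape:
            raise ValueError("time_s and vm must have identical shape")
        if self.pre_stim_window[1] > self.stim_onset + 1e-12:
            raise ValueError("pre_stim_window must end at or before stim_onset")

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def pre_stim_mask(self) -> np.ndarray:
        # half-open [w0, w1): a sample at exactly the window end (typically
        # the stimulus-onset sample) belongs to the response, not baseline
        w0, w1 = self.pre_stim_window
        return (self.time_s >= w0 - 1e-12) & (self.time_s < w1 - 1e-12)


@dataclass
class UnitRecord:
    """A curated extracellular single unit over a recording session.

    Spike times are in seconds from session start; the mean waveform is
    in microvolts at ``waveform_sampling_rate``.  ``true_*`` fields carry
    generator ground truth and are absent (None) for real data.
    """

    unit_id: str
    spike_times: np.ndarray
    mean_waveform: np.ndarray
    waveform_sampling_rate: float
    animal_id: str = "animal0"
    true_class: str | None = None
    true_duration_ms: float | None = None
    true_base_rate_hz: float | None = None
    true_fever_gain: float | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.mean_waveform = np.asarray(self.mean_waveform, dtype=float)


@dataclass
class TbSeries:
    """Body-temperature readings on a uniform 5-minute grid."""

    times: np.ndarray
    tb: np.ndarray
    condition: str = "room"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.tb = np.asarray(self.tb, dtype=float)
        if self.times.size != self.tb.size:
            raise ValueError("times and tb must have equal length")
        if self.times.size > 1:
            spacing = np.diff(self.times)
            if not np.allclose(spacing, 300.0):
                raise ValueError("TbSeries requires uniform 300 s spacing")


@dataclass
class IVCurve:
    """Current density-voltage relationship under one pharmacological condition."""

    voltages: np.ndarray
    current_density: np.ndarray
    condition: str

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.current_density = np.asarray(self.current_density, dtype=float)
        if self.voltages.size != self.current_density.size:
            raise ValueError("voltages and current_density must have equal length")
        if np.any(np.diff(self.voltages) <= 0):
            raise ValueError("voltages must be strictly increasing")


@dataclass(frozen=True)
class PeriodSpec:
    """One session period with the sub-window used for rate estimates.

    The default session has three 45-minute periods (baseline, fever,
    recovery) separated by 5-minute temperature ramps that are excluded;
    only the last 25 minutes of each period enter the rate estimate, to
    limit transients (tissue recovery, heating onset).
    """

    name: str
    start_s: float
    end_s: float
    analysis_window: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.analysis_window is None:
            object.__setattr__(self, "analysis_window", (self.end_s - 1500.0, self.end_s))
        a0, a1 = self.analysis_window
        if not (self.start_s - 1e-9 <= a0 <= a1 <= self.end_s + 1e-9):
            raise ValueError("analysis_window must lie within [start_s, end_s]")


def default_periods() -> list[PeriodSpec]:
    """Baseline / fever / recovery layout of the 145-minute session."""
    return [
        PeriodSpec("baseline", 0.0, 2700.0),
        PeriodSpec("fever", 3000.0, 5700.0),
        PeriodSpec("recovery", 6000.0, 8700.0),
    ]
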