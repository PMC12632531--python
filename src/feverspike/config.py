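"""Configuration objects for the synthetic cohort generators.

Default values emulate the study conditions the analyses assume: evoked
responses recorded at 30/36/39 degC from a -50 mV holding potential with
11 sweeps per temperature, spike threshold depolarizing and input
resistance falling as temperature rises, and a temperature-gated boost
of excitatory drive (the TRPV3-like term) restricted to the cells whose
fate keeps them spiking at fever temperature.

Threshold and input-resistance distributions are order-of-magnitude
choices consistent with juvenile cortical pyramidal neurons; they are
deliberately configurable because per-cell population spreads are not
tabulated anywhere authoritative.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["SyntheticCohortConfig", "CellParams"]

FATES = ("never", "stay", "stop", "start")


@dataclass
class SyntheticCohortConfig:
    """Parameters of the synthetic intracellular cohort generator.

    Amplitude-like parameters are (mean, SD) pairs in mV; ``theta30`` is
    the spike-threshold distribution at 30 degC and ``theta_slope`` its
    depolarizing drift per degC.  ``rin_q10`` scales input resistance per
    10 degC (values < 1 encode the channel-opening-driven fall of R_in
    with warming).  ``stay_gain`` is the per-degC multiplicative boost of
    excitatory amplitude applied only to cells fated to spike at fever
    temperature (stay/start); ``ipsp_temp_factor`` is the per-degC
    fractional loss of inhibitory amplitude seen by every cell.
    """

    n_cells: int = 40
    # probabilities (never, stay, stop, start); must sum to 1
    fate_mix: tuple[float, float, float, float] = (0.2, 0.35, 0.25, 0.2)
    temperatures: tuple[float, ...] = (30.0, 36.0, 39.0)
    sweeps_per_temperature: int = 11
    sampling_rate: float = 20_000.0
    holding_vm: float = -50.0
    sweep_duration: float = 0.25
    stim_onset: float = 0.05
    theta30: tuple[float, float] = (-42.5, 1.5)
    theta_slope: float = 0.3
    rin30: tuple[float, float] = (150.0, 25.0)
    rin_q10: float = 0.8
    epsp_amp: tuple[float, float] = (8.0, 2.0)
    ipsp_amp: tuple[float, float] = (3.0, 1.0)
    ipsp_delay: float = 5.0
    epsp_tau_rise: float = 2.0
    epsp_tau_decay: float = 25.0
    ipsp_tau_rise: float = 8.0
    ipsp_tau_decay: float = 60.0
    synaptic_delay: float = 2.0
    stay_gain: float = 0.08
    ipsp_temp_factor: float = 0.04
    noise_sd: float = 0.2
    allow_burst: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fate_mix) != 4:
            raise ValueError("fate_mix needs four probabilities (never, stay, stop, start)")
        if abs(sum(self.fate_mix) - 1.0) > 1e-9:
            raise ValueError(f"fate_mix must sum to 1, got {sum(self.fate_mix)}")
        if any(p < 0 for p in self.fate_mix):
            raise ValueError("fate_mix probabilities must be nonnegative")
        temps = tuple(float(t) for t in self.temperatures)
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("temperatures must be strictly increasing")
        self.temperatures = temps
        if self.sampling_rate < 10_000:
            raise ValueError("sampling_rate must be >= 10 kHz")
        if self.sweep_duration < self.stim_onset + 0.160:
            raise ValueError("sweep must extend >= 160 ms past the stimulus")
        for name in (
            "theta30",
            "rin30",
            "epsp_amp",
            "ipsp_amp",
        ):
            pair = getattr(self, name)
            if len(pair) != 2 or pair[1] < 0:
                raise ValueError(f"{name} must be a (mean, SD) pair with SD >= 0")
        for name in (
            "epsp_tau_rise",
            "epsp_tau_decay",
            "ipsp_tau_rise",
            "ipsp_tau_decay",
            "ipsp_delay",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.epsp_tau_rise >= self.epsp_tau_decay or self.ipsp_tau_rise >= self.ipsp_tau_decay:
            raise ValueError("tau_rise must be smaller than tau_decay")
        if not (0 < self.rin_q10 <= 1):
            raise ValueError("rin_q10 must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    @classmethod
    def from_file(cls, path: str | Path) -> "SyntheticCohortConfig":
        """Load from a JSON or YAML mapping; unknown keys are rejected."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticCohortConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced = {
            k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
        }
        return cls(**coerced)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CellParams:
    """Passive/threshold parameters of one cell for current-step protocols."""

    rin_mohm: float = 150.0
    theta_mv: float = -42.5
    tau_m_ms: float = 20.0
    v_hold: float = -80.0

    def __post_init__(self) -> None:
        if self.rin_mohm <= 0 or self.tau_m_ms <= 0:
            raise ValueError("rin_mohm and tau_m_ms must be positive")
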