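"""Seeded synthetic-data generators with recorded ground truth.

Three families of data are generated:

* intracellular cohorts of stimulus-locked voltage sweeps across a
  rising temperature series, with per-cell spiking fates (never / stay /
  stop / start) realized exactly at zero noise;
* extracellular unit populations (spike trains over a three-period
  session plus mean waveforms with a bimodal trough-to-peak duration
  mixture);
* body-temperature series with optional planted fever bouts.

Every generator draws from a single ``numpy`` Generator seeded from the
config, so identical configuration and seed give identical output.

The intracellular model is deliberately phenomenological rather than
conductance-based.  The subthreshold response is a difference of
dual-exponential kernels (early excitatory, delayed inhibitory); the
excitatory amplitude is scaled by the temperature-dependent input
resistance and, for cells fated to remain (or become) active at fever
temperature, by a per-degC gain that stands in for a warmth-activated
depolarizing conductance.  When the noiseless trace reaches the
temperature-shifted spike threshold, a stereotyped 4-ms action-potential
template is spliced in at the crossing sample, so the threshold crossing
the second-derivative detector must recover is known exactly.  Recording
noise is added after spike insertion, which makes the spiking pattern --
and hence the fate label -- a noise-independent property of the drive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FATES, CellParams, SyntheticCohortConfig
from .records import PeriodSpec, TbSeries, UnitRecord, VoltageSweep, default_periods

__all__ = [
    "generate_pn_cohort",
    "generate_fi_sweeps",
    "analytic_rheobase",
    "generate_unit_population",
    "generate_body_temperature",
    "spike_template",
]

# Action-potential template geometry (ms); total length 4 ms so the
# second-derivative onset is sharp and the ground truth recordable.
_AP_PEAK_MV = 30.0
_AP_UPSTROKE_MS = 0.3
_AP_DOWNSTROKE_MS = 0.7
_AP_TOTAL_MS = 4.0
_AP_AHP_DROP_MV = 6.0


def _dual_exp(t_ms: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials kernel normalized to unit peak; 0 for t < 0."""
    k = np.where(
        t_ms >= 0.0,
        np.exp(-np.maximum(t_ms, 0.0) / tau_decay) - np.exp(-np.maximum(t_ms, 0.0) / tau_rise),
        0.0,
    )
    t_pk = tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    peak = math.exp(-t_pk / tau_decay) - math.exp(-t_pk / tau_rise)
    return k / peak


def spike_template(threshold_mv: float, tail_mv: float, fs: float) -> np.ndarray:
    """Stereotyped action potential starting at ``threshold_mv``.

    Linear upstroke to +30 mV, repolarization to an afterhyperpolarization
    dip below threshold, then linear recovery to ``tail_mv`` so the
    template splices continuously back into the subthreshold trace.
    """
    n_up = round(_AP_UPSTROKE_MS * 1e-3 * fs)
    n_down = round(_AP_DOWNSTROKE_MS * 1e-3 * fs)
    n_tot = round(_AP_TOTAL_MS * 1e-3 * fs)
    ahp = threshold_mv - _AP_AHP_DROP_MV
    up = np.linspace(threshold_mv, _AP_PEAK_MV, n_up + 1)
    down = np.linspace(_AP_PEAK_MV, ahp, n_down + 1)[1:]
    recover = np.linspace(ahp, tail_mv, n_tot - n_up - n_down + 1)[1:]
    return np.concatenate([up, down, recover])


@dataclass(frozen=True)
class _CellDraw:
    fate: str
    theta30: float
    rin30: float
    ipsp_amp: float
    epsp_amp: float  # calibrated base excitatory amplitude (mV at unit scaling)


def _rin(cfg: SyntheticCohortConfig, rin30: float, temp: float) -> float:
    return rin30 * cfg.rin_q10 ** ((temp - 30.0) / 10.0)


def _theta(cfg: SyntheticCohortConfig, theta30: float, temp: float) -> float:
    return theta30 + cfg.theta_slope * (temp - 30.0)


def _excit_scale(cfg: SyntheticCohortConfig, fate: str, temp: float) -> float:
    s = cfg.rin_q10 ** ((temp - 30.0) / 10.0)
    if fate in ("stay", "start"):
        s *= (1.0 + cfg.stay_gain) ** (temp - 30.0)
    return s


def _ipsp_scale(cfg: SyntheticCohortConfig, temp: float) -> float:
    return (1.0 - cfg.ipsp_temp_factor) ** (temp - 30.0)


def _drive_kernels(cfg: SyntheticCohortConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time grid and unit-peak excitatory/inhibitory kernels for one sweep."""
    n = round(cfg.sweep_duration * cfg.sampling_rate)
    t = np.arange(n) / cfg.sampling_rate
    t_ms = (t - cfg.stim_onset) * 1e3
    ke = _dual_exp(t_ms - cfg.synaptic_delay, cfg.epsp_tau_rise, cfg.epsp_tau_decay)
    ki = _dual_exp(
        t_ms - cfg.synaptic_delay - cfg.ipsp_delay, cfg.ipsp_tau_rise, cfg.ipsp_tau_decay
    )
    return t, ke, ki


def _required_amplitude(
    target_peak: float, ke_scaled: np.ndarray, inh: np.ndarray
) -> float:
    """Smallest excitatory amplitude whose drive peak reaches ``target_peak``.

    The drive ``A*ke - inh`` has a peak monotone increasing in ``A``;
    solved by bisection to float precision.
    """
    lo, hi = 0.0, max(1.0, target_peak)
    while np.max(hi * ke_scaled - inh) < target_peak:
        hi *= 2.0
        if hi > 1e7:
            raise RuntimeError("amplitude calibration failed to bracket")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.max(mid * ke_scaled - inh) >= target_peak:
            hi = mid
        else:
            lo = mid
    return hi


def _calibrate_amplitude(
    rho: np.ndarray, pattern: np.ndarray, rng: np.random.Generator
) -> float | None:
    """Pick a base amplitude realizing the given spiking pattern.

    ``rho[i]`` is the minimal base amplitude that reaches threshold at
    temperature ``i``.  Returns None when the pattern is infeasible under
    the configured temperature scalings.
    """
    spiking = rho[pattern]
    silent = rho[~pattern]
    if pattern.all():
        return float(np.max(rho) * rng.uniform(1.08, 1.30))
    if not pattern.any():
        return float(np.min(rho) * rng.uniform(0.55, 0.85))
    lo = float(np.max(spiking))
    hi = float(np.min(silent))
    if hi <= lo * 1.02:
        return None
    margin = 0.15 * (hi - lo)
    return float(rng.uniform(lo + margin, hi - margin))


def _fate_patterns(fate: str, n_temps: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Candidate spiking patterns for a fate, in random preference order."""
    if fate == "stay":
        return [np.ones(n_temps, dtype=bool)]
    if fate == "never":
        return [np.zeros(n_temps, dtype=bool)]
    cut_choices = list(range(1, n_temps))
    rng.shuffle(cut_choices)
    pats = []
    for cut in cut_choices:
        p = np.zeros(n_temps, dtype=bool)
        if fate == "stop":
            p[:cut] = True
        else:  # start
            p[cut:] = True
        pats.append(p)
    return pats


def generate_pn_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[VoltageSweep], pd.DataFrame]:
    """Generate an evoked-response cohort with known per-cell fates.

    Returns the sweeps (``n_cells * len(temperatures) * sweeps_per_temperature``)
    and a ground-truth table with one row per cell and temperature:
    fate, threshold, input resistance, subthreshold-drive peak and late
    deflection, whether a spike was inserted, and its onset time.

    The realized spiking pattern equals the assigned fate exactly,
    independent of ``noise_sd`` (noise is added after spike insertion).
    """
    cfg = config
    three_temp_fates = ("stop", "start")
    if len(cfg.temperatures) < 2 and any(
        cfg.fate_mix[FATES.index(f)] > 0 for f in three_temp_fates
    ):
        raise ValueError("stop/start fates require at least two temperatures")
    rng = np.random.default_rng(cfg.seed)
    t, ke, ki = _drive_kernels(cfg)
    post = t >= cfg.stim_onset
    late_mask = ((t - cfg.stim_onset) * 1e3 >= 50.0) & ((t - cfg.stim_onset) * 1e3 <= 150.0)

    sweeps: list[VoltageSweep] = []
    truth_rows: list[dict] = []
    temps = np.asarray(cfg.temperatures)

    for ci in range(cfg.n_cells):
        cell_id = f"cell{ci:04d}"
        fate = rng.choice(FATES, p=cfg.fate_mix)

        # A small fraction of intrinsic-parameter draws cannot realize the
        # assigned fate (e.g. a start cell whose threshold sits so close to
        # holding that its proportional rise outpaces the fever gain); the
        # cell's intrinsic parameters are redrawn, keeping the fate mix exact.
        amp = None
        for _attempt in range(64):
            theta30 = rng.normal(*cfg.theta30)
            # keep threshold above holding so depolarization-to-threshold > 0
            theta30 = max(theta30, cfg.holding_vm + 2.0)
            rin30 = max(rng.normal(*cfg.rin30), 20.0)
            ipsp_amp = max(rng.normal(*cfg.ipsp_amp), 0.0)

            # minimal base amplitude reaching threshold, per temperature
            rho = np.empty(temps.size)
            for ti, temp in enumerate(temps):
                target = _theta(cfg, theta30, temp) - cfg.holding_vm
                ke_s = _excit_scale(cfg, fate, temp) * ke
                inh = ipsp_amp * _ipsp_scale(cfg, temp) * ki
                rho[ti] = _required_amplitude(target, ke_s, inh)

            for pattern in _fate_patterns(fate, temps.size, rng):
                amp = _calibrate_amplitude(rho, pattern, rng)
                if amp is not None:
                    break
            if amp is not None:
                break
        if amp is None:
            raise RuntimeError(
                f"fate {fate!r} infeasible under the configured temperature scalings"
            )

        for ti, temp in enumerate(temps):
            theta_t = _theta(cfg, theta30, temp)
            ke_s = _excit_scale(cfg, fate, temp) * ke
            inh = ipsp_amp * _ipsp_scale(cfg, temp) * ki
            drive = amp * ke_s - inh
            vm0 = cfg.holding_vm + drive
            spike_here = bool(pattern[ti])
            onset_idx = -1
            base = vm0.copy()
            if spike_here:
                crossing = np.flatnonzero(post & (vm0 >= theta_t))
                onset_idx = int(crossing[0])
                n_tot = round(_AP_TOTAL_MS * 1e-3 * cfg.sampling_rate)
                end = min(onset_idx + n_tot, vm0.size - 1)
                tmpl = spike_template(vm0[onset_idx], vm0[end], cfg.sampling_rate)
                base[onset_idx : onset_idx + tmpl.size] = tmpl[: vm0.size - onset_idx]
                if cfg.allow_burst:
                    nxt = np.flatnonzero(post & (vm0 >= theta_t))
                    nxt = nxt[nxt > end + round(2e-3 * cfg.sampling_rate)]
                    while nxt.size:
                        o2 = int(nxt[0])
                        e2 = min(o2 + n_tot, vm0.size - 1)
                        tm2 = spike_template(vm0[o2], vm0[e2], cfg.sampling_rate)
                        base[o2 : o2 + tm2.size] = tm2[: vm0.size - o2]
                        nxt = nxt[nxt > e2 + round(2e-3 * cfg.sampling_rate)]

            truth_rows.append(
                {
                    "cell_id": cell_id,
                    "fate": fate,
                    "temperature": float(temp),
                    "theta_mv": float(vm0[onset_idx]) if spike_here else float(theta_t),
                    "delta_theta_mv": (
                        float(vm0[onset_idx]) - cfg.holding_vm
                        if spike_here
                        else float(theta_t) - cfg.holding_vm
                    ),
                    "rin_mohm": _rin(cfg, rin30, temp),
                    "psp_peak_mv": float(np.max(drive[post])),
                    "late_psp_mv": float(
                        drive[late_mask][np.argmax(np.abs(drive[late_mask]))]
                    ),
                    "spikes": spike_here,
                    "spike_onset_s": float(t[onset_idx]) if spike_here else np.nan,
                    "epsp_base_amp_mv": float(amp),
                    "ipsp_amp_mv": float(ipsp_amp),
                }
            )
            for si in range(cfg.sweeps_per_temperature):
                vm = base.copy()
                if cfg.noise_sd > 0:
                    vm = vm + rng.normal(0.0, cfg.noise_sd, size=vm.size)
                sweeps.append(
                    VoltageSweep(
                        time_s=t,
                        vm=vm,
                        sampling_rate=cfg.sampling_rate,
                        stim_onset=cfg.stim_onset,
                        pre_stim_window=(0.0, cfg.stim_onset),
                        temperature=float(temp),
                        cell_id=cell_id,
                        sweep_index=si,
                    )
                )
    truth = pd.DataFrame(truth_rows)
    return sweeps, truth


# --------------------------------------------------------------------------
# Current-step (F-I) protocol
# --------------------------------------------------------------------------

def generate_fi_sweeps(
    cell_params: CellParams,
    current_steps_pa,
    step_duration: float = 0.5,
    sampling_rate: float = 20_000.0,
    noise_sd: float = 0.0,
    temperature: float = 30.0,
    cell_id: str = "cell",
    seed: int = 0,
) -> list[VoltageSweep]:
    """Current-step sweeps from a leaky integrate-and-fire cell.

    The membrane charges exponentially toward ``v_hold + I*Rin`` with the
    membrane time constant; each threshold crossing inserts the 4-ms
    spike template and restarts charging from the afterhyperpolarization.
    At zero noise the spike count is nondecreasing in the injected
    current.
    """
    steps = [float(s) for s in current_steps_pa]
    if not steps:
        raise ValueError("current step list must not be empty")
    if any(b < a for a, b in zip(steps, steps[1:])):
        raise ValueError("current steps must be sorted ascending")
    p = cell_params
    fs = sampling_rate
    dt = 1.0 / fs
    pre, post = 0.1, 0.1
    n_pre = round(pre * fs)
    n_step = round(step_duration * fs)
    n_tot = n_pre + n_step + round(post * fs)
    t = np.arange(n_tot) / fs
    tau = p.tau_m_ms * 1e-3
    decay = math.exp(-dt / tau)
    n_ap = round(_AP_TOTAL_MS * 1e-3 * fs)
    rng = np.random.default_rng(seed)

    sweeps = []
    for si, current in enumerate(steps):
        vinf = p.v_hold + current * p.rin_mohm / 1000.0
        vm = np.full(n_tot, float(p.v_hold))
        i = n_pre
        v = p.v_hold
        while i < n_pre + n_step:
            v = vinf + (v - vinf) * decay
            if v >= p.theta_mv:
                end = min(i + n_ap, n_tot - 1)
                tmpl = spike_template(p.theta_mv, p.theta_mv - _AP_AHP_DROP_MV, fs)
                vm[i : i + tmpl.size] = tmpl[: n_tot - i]
                v = p.theta_mv - _AP_AHP_DROP_MV
                i += tmpl.size
            else:
                vm[i] = v
                i += 1
        # passive relaxation after the step
        for j in range(n_pre + n_step, n_tot):
            v = p.v_hold + (v - p.v_hold) * decay
            vm[j] = v
        if noise_sd > 0:
            vm = vm + rng.normal(0.0, noise_sd, size=n_tot)
        sweeps.append(
            VoltageSweep(
                time_s=t,
                vm=vm,
                sampling_rate=fs,
                stim_onset=pre,
                pre_stim_window=(0.0, pre),
                temperature=temperature,
                cell_id=cell_id,
                sweep_index=si,
                injected_pa=current,
                step_duration=step_duration,
            )
        )
    return sweeps


def analytic_rheobase(
    cell_params: CellParams,
    current_steps_pa,
    step_duration: float = 0.5,
    sampling_rate: float = 20_000.0,
) -> float | None:
    """Closed-form minimal grid step that elicits a spike at zero noise.

    A step of amplitude I reaches, at the k-th in-step sample,
    ``v_hold + (I*Rin/1000)*(1 - exp(-k*dt/tau))``; the maximum over the
    step is at the last sample.  Returns the first grid step at least as
    large as the continuous minimum, or None when no step suffices.
    """
    p = cell_params
    dt = 1.0 / sampling_rate
    n_step = round(step_duration * sampling_rate)
    tau = p.tau_m_ms * 1e-3
    reach = 1.0 - math.exp(-n_step * dt / tau)
    i_min = (p.theta_mv - p.v_hold) * 1000.0 / (p.rin_mohm * reach)
    for s in current_steps_pa:
        if s >= i_min:
            return float(s)
    return None


# --------------------------------------------------------------------------
# Extracellular unit population
# --------------------------------------------------------------------------

def _unit_waveform(
    duration_ms: float, amp_uv: float, fs: float, window_ms: float = 4.0
) -> np.ndarray:
    """Biphasic mean waveform with the given trough-to-peak duration.

    A negative Gaussian trough followed by a smaller positive Gaussian
    peak ``duration_ms`` later; widths scale with the duration so narrow
    (interneuron-like) and wide (principal-like) shapes look natural.
    """
    n = round(window_ms * 1e-3 * fs) + 1
    t = np.arange(n) / fs * 1e3  # ms
    t_trough = 1.2
    t_peak = t_trough + duration_ms
    w_tr = max(0.05, 0.15 * duration_ms)
    w_pk = max(0.10, 0.30 * duration_ms)
    wf = -amp_uv * np.exp(-0.5 * ((t - t_trough) / w_tr) ** 2) + 0.45 * amp_uv * np.exp(
        -0.5 * ((t - t_peak) / w_pk) ** 2
    )
    return wf


def _rate_profile(periods: list[PeriodSpec], gain: float) -> list[tuple[float, float, float, float]]:
    """Piecewise-linear relative-rate segments (t0, t1, r0, r1) over a session.

    Rate multiplier is 1 outside the fever period, ``gain`` inside it,
    with linear ramps across the inter-period gaps.
    """
    segs = []
    prev_end, prev_level = None, 1.0
    for per in periods:
        level = gain if per.name == "fever" else 1.0
        if prev_end is not None and per.start_s > prev_end:
            segs.append((prev_end, per.start_s, prev_level, level))
        segs.append((per.start_s, per.end_s, level, level))
        prev_end, prev_level = per.end_s, level
    return segs


def generate_unit_population(
    n_units: int = 633,
    interneuron_frac: float = 0.221,
    duration_mixture: tuple[tuple[float, float], tuple[float, float]] = (
        (0.35, 0.05),
        (0.90, 0.10),
    ),
    base_rate_dist: tuple[float, float] = (2.0, 0.5),
    fever_gain_dist: tuple[float, float] = (1.5, 0.1),
    periods: list[PeriodSpec] | None = None,
    n_animals: int = 5,
    waveform_sampling_rate: float = 30_000.0,
    refractory_s: float = 0.002,
    seed: int = 0,
) -> list[UnitRecord]:
    """Simulate a curated extracellular unit population.

    Trough-to-peak durations come from the two-component normal mixture
    (narrow component first); spike trains are refractory-corrected
    Poisson with the unit's base rate outside the fever period and
    ``base * gain`` inside it (linear ramps between periods).
    ``base_rate_dist`` is (median Hz, log-SD) of a lognormal;
    ``fever_gain_dist`` is (mean, SD) of a truncated normal.
    """
    if not (0.0 <= interneuron_frac <= 1.0):
        raise ValueError("interneuron_frac must be in [0, 1]")
    (mu_n, sd_n), (mu_w, sd_w) = duration_mixture
    if mu_n >= mu_w:
        raise ValueError("narrow-component mean must be below the wide-component mean")
    periods = periods if periods is not None else default_periods()
    session_end = max(p.end_s for p in periods)
    rng = np.random.default_rng(seed)

    units = []
    for ui in range(n_units):
        is_in = rng.random() < interneuron_frac
        if is_in:
            dur = max(0.08, rng.normal(mu_n, sd_n))
        else:
            dur = max(0.08, rng.normal(mu_w, sd_w))
        amp = rng.uniform(60.0, 120.0)
        wf = _unit_waveform(dur, amp, waveform_sampling_rate)
        base = float(np.exp(np.log(base_rate_dist[0]) + base_rate_dist[1] * rng.normal()))
        gain = float(max(rng.normal(*fever_gain_dist), 0.2))

        r_max = base * max(gain, 1.0)
        n_cand = rng.poisson(r_max * session_end)
        cand = np.sort(rng.uniform(0.0, session_end, size=n_cand))
        rel = np.ones(cand.size)
        for t0, t1, r0, r1 in _rate_profile(periods, gain):
            m = (cand >= t0) & (cand < t1)
            frac = np.where(t1 > t0, (cand[m] - t0) / (t1 - t0), 0.0)
            rel[m] = r0 + (r1 - r0) * frac
        keep = rng.random(cand.size) < (base * rel) / r_max
        times = cand[keep]
        if times.size:
            accepted = [times[0]]
            for s in times[1:]:
                if s - accepted[-1] >= refractory_s:
                    accepted.append(s)
            times = np.asarray(accepted)
        units.append(
            UnitRecord(
                unit_id=f"unit{ui:04d}",
                spike_times=times,
                mean_waveform=wf,
                waveform_sampling_rate=waveform_sampling_rate,
                animal_id=f"animal{ui % n_animals}",
                true_class="interneuron" if is_in else "principal",
                true_duration_ms=float(dur),
                true_base_rate_hz=base,
                true_fever_gain=gain,
            )
        )
    return units


# --------------------------------------------------------------------------
# Body temperature
# --------------------------------------------------------------------------

def generate_body_temperature(
    duration_h: float = 6.0,
    baseline: float = 36.5,
    fluct: float = 0.5,
    n_fever_bouts: int = 0,
    condition: str = "room",
    seed: int = 0,
    fever_level: float = 38.4,
    bout_readings: int = 3,
) -> TbSeries:
    """Body-temperature series sampled every 5 minutes.

    Room condition: mean-reverting fluctuation around ``baseline``
    bounded by ``+/- fluct``, with ``n_fever_bouts`` planted excursions
    to ``fever_level``.  Infrared condition: a few-reading onset ramp to
    a sustained elevation above 38 degC.
    """
    if duration_h <= 0:
        raise ValueError("duration_h must be positive")
    n = round(duration_h * 12)
    times = np.arange(n) * 300.0
    rng = np.random.default_rng(seed)

    # AR(1) fluctuation, hard-bounded at +/- fluct
    dev = np.zeros(n)
    phi, innov = 0.85, 0.35 * fluct
    for i in range(1, n):
        dev[i] = phi * dev[i - 1] + rng.normal(0.0, innov)
    dev = np.clip(dev, -fluct, fluct)
    tb = baseline + dev

    if condition == "infrared":
        onset = min(3, n - 1)
        ramp_len = min(4, n - onset)
        level = max(fever_level, 38.5)
        for i in range(n):
            if i >= onset + ramp_len:
                tb[i] = level + np.clip(dev[i], -0.3, 0.3)
            elif i >= onset:
                f = (i - onset + 1) / ramp_len
                tb[i] = baseline + f * (level - baseline)
    elif condition == "room":
        if n_fever_bouts > 0:
            gap = bout_readings + 2
            usable = n - 2 - n_fever_bouts * gap
            if usable < 0:
                raise ValueError("too many fever bouts for the series length")
            starts = 1 + np.sort(rng.choice(usable + 1, size=n_fever_bouts, replace=False))
            starts = starts + gap * np.arange(n_fever_bouts)
            for s in starts:
                for j in range(bout_readings):
                    tb[s + j] = fever_level + rng.uniform(-0.15, 0.15)
    else:
        raise ValueError(f"unknown condition {condition!r}")

    return TbSeries(times=times, tb=np.clip(tb, 30.0, 43.0), condition=condition)
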