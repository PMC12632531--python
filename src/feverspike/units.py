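"""Extracellular unit typing and period firing-rate analysis.

Curated single units are classified as putative interneurons (narrow
spikes) or principal cells (wide spikes) from the trough-to-peak
duration of the bandpass-filtered mean waveform: the duration
distribution is tested for bimodality with the dip test and split by
exact 1-D 2-means.  Units pass an inclusion filter (spike count,
refractory-period cleanliness, presence throughout the session), and
firing rates are computed per session period over the last 25 minutes
of each 45-minute period, then normalized to each unit's baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from . import stats
from .records import PeriodSpec, UnitRecord, default_periods

__all__ = [
    "UnitClassification",
    "ClassificationResult",
    "mean_waveform_duration",
    "inclusion_filter",
    "kmeans_1d_two",
    "classify_units",
    "period_firing_rates",
    "normalize_rates",
    "build_unit_table",
]


def mean_waveform_duration(
    waveform: np.ndarray,
    sampling_rate: float,
    band_hz: tuple[float, float] | None = (300.0, 6000.0),
    unit_id: str = "?",
) -> float:
    """Trough-to-peak duration (ms) of a mean spike waveform.

    The waveform is bandpass filtered (zero-phase 3rd-order Butterworth,
    so trough/peak timing is not skewed by filter delay); the duration
    is the time from the global trough to the subsequent maximum.
    Pass ``band_hz=None`` for waveforms that are already filtered.
    """
    wf = np.asarray(waveform, dtype=float)
    if band_hz is None:
        filt = wf
    else:
        nyq = sampling_rate / 2.0
        hi = min(band_hz[1], 0.95 * nyq)
        sos = butter(3, [band_hz[0] / nyq, hi / nyq], btype="band", output="sos")
        filt = sosfiltfilt(sos, wf)
    trough = int(np.argmin(filt))
    tail = filt[trough + 1 :]
    if tail.size == 0:
        raise ValueError(f"unit {unit_id}: waveform trough has no post-trough samples")
    peak_off = int(np.argmax(tail))
    if peak_off == tail.size - 1:
        raise ValueError(
            f"unit {unit_id}: no post-trough peak (monotone tail after filtering)"
        )
    return (peak_off + 1) / sampling_rate * 1e3


def inclusion_filter(
    unit: UnitRecord,
    session_length_s: float = 8700.0,
    min_spikes: int = 900,
    refractory_ms: float = 2.0,
    max_violation_frac: float = 0.01,
    presence_bins: int = 10,
) -> tuple[bool, str]:
    """Curation filter for single units.

    A unit is included when it has at least ``min_spikes`` spikes
    (~0.1 Hz over the 145-minute session), a clean refractory period
    (at most ``max_violation_frac`` of inter-spike intervals shorter
    than ``refractory_ms``), and spikes present throughout the session
    (every equal-width bin nonempty).  Returns (included, reason);
    reason is "ok" for included units.
    """
    t = unit.spike_times
    if t.size < min_spikes:
        return False, f"min_spikes ({t.size} < {min_spikes})"
    isi = np.diff(t)
    if isi.size:
        frac = float(np.mean(isi < refractory_ms * 1e-3))
        if frac > max_violation_frac:
            return False, f"refractory ({frac:.3%} ISIs < {refractory_ms} ms)"
    edges = np.linspace(0.0, session_length_s, presence_bins + 1)
    counts, _ = np.histogram(t, bins=edges)
    if np.any(counts == 0):
        return False, f"presence (empty session bin {int(np.argmin(counts > 0))})"
    return True, "ok"


def kmeans_1d_two(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Exact 1-D 2-means by exhaustive search over contiguous splits.

    For one-dimensional data the optimal 2-means partition is contiguous
    in sorted order, so scanning the n-1 splits with prefix sums gives
    the global optimum.  Returns (boolean mask of the low cluster,
    low-cluster mean, high-cluster mean).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    if np.all(v == v[0]):
        raise ValueError("all values identical; clustering undefined")
    order = np.argsort(v, kind="mergesort")
    s = v[order]
    csum = np.cumsum(s)
    csq = np.cumsum(s**2)
    n = s.size
    k = np.arange(1, n)
    sum1, sum2 = csum[k - 1], csum[-1] - csum[k - 1]
    sq1, sq2 = csq[k - 1], csq[-1] - csq[k - 1]
    sse = (sq1 - sum1**2 / k) + (sq2 - sum2**2 / (n - k))
    kb = int(k[np.argmin(sse)])
    mask = np.zeros(n, dtype=bool)
    mask[order[:kb]] = True
    return mask, float(np.mean(s[:kb])), float(np.mean(s[kb:]))


@dataclass(frozen=True)
class ClassificationResult:
    """Unit-type classification of a duration sample."""

    labels: tuple[str, ...]
    boundary_ms: float
    narrow_mean_ms: float
    wide_mean_ms: float
    n_interneuron: int
    n_principal: int
    dip: stats.DipResult


def classify_units(
    durations_ms, dip_n_boot: int = 2000, dip_seed: int = 0
) -> ClassificationResult:
    """Classify units from trough-to-peak durations.

    Records the dip test of unimodality, then splits the durations with
    exact 1-D 2-means; the narrow-mean cluster is labelled interneuron,
    the wide-mean cluster principal, and the boundary is the midpoint of
    the cluster means.  Units exactly on the boundary keep their cluster
    assignment.
    """
    d = np.asarray(durations_ms, dtype=float)
    if d.size < 10:
        raise ValueError("classification needs at least 10 durations")
    dip = stats.dip_test(d, n_boot=dip_n_boot, seed=dip_seed)
    narrow_mask, mean_lo, mean_hi = kmeans_1d_two(d)
    labels = tuple("interneuron" if m else "principal" for m in narrow_mask)
    return ClassificationResult(
        labels=labels,
        boundary_ms=0.5 * (mean_lo + mean_hi),
        narrow_mean_ms=mean_lo,
        wide_mean_ms=mean_hi,
        n_interneuron=int(narrow_mask.sum()),
        n_principal=int((~narrow_mask).sum()),
        dip=dip,
    )


def period_firing_rates(
    unit: UnitRecord, periods: list[PeriodSpec] | None = None
) -> dict[str, float]:
    """Mean firing rate (Hz) per period over its analysis window."""
    periods = periods if periods is not None else default_periods()
    spans = sorted((p.start_s, p.end_s) for p in periods)
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ValueError("periods must not overlap")
    out = {}
    for p in periods:
        w0, w1 = p.analysis_window
        if w1 <= w0:
            raise ValueError(f"period {p.name}: zero-length analysis window")
        n = int(np.sum((unit.spike_times >= w0) & (unit.spike_times < w1)))
        out[p.name] = n / (w1 - w0)
    return out


def normalize_rates(
    rates: pd.DataFrame, baseline_period: str = "baseline"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Baseline-normalized rates per unit and per-animal class means.

    ``rates`` has one row per unit with columns unit_id, animal_id,
    label, and one rate column per period.  Each unit's rates are
    divided by its own baseline rate (zero-baseline units are dropped
    with a warning); the per-animal table averages normalized rates over
    each animal's units of a given class.
    """
    period_cols = [
        c for c in rates.columns if c not in ("unit_id", "animal_id", "label")
    ]
    if baseline_period not in period_cols:
        raise ValueError(f"missing baseline column {baseline_period!r}")
    keep = rates[baseline_period] > 0
    if not keep.all():
        dropped = rates.loc[~keep, "unit_id"].tolist()
        warnings.warn(f"dropping units with zero baseline rate: {dropped}", stacklevel=2)
    df = rates.loc[keep].copy()
    for c in period_cols:
        df[f"norm_{c}"] = df[c] / df[baseline_period]
    norm_cols = [f"norm_{c}" for c in period_cols]
    per_animal = (
        df.groupby(["animal_id", "label"], sort=True)[norm_cols].mean().reset_index()
    )
    return df, per_animal


def build_unit_table(
    units: list[UnitRecord],
    periods: list[PeriodSpec] | None = None,
    session_length_s: float = 8700.0,
    dip_seed: int = 0,
) -> tuple[pd.DataFrame, ClassificationResult]:
    """Full per-unit table: duration, class label, inclusion, period rates."""
    periods = periods if periods is not None else default_periods()
    durations = [
        mean_waveform_duration(u.mean_waveform, u.waveform_sampling_rate, unit_id=u.unit_id)
        for u in units
    ]
    cls = classify_units(durations, dip_seed=dip_seed)
    rows = []
    for u, dur, label in zip(units, durations, cls.labels):
        included, reason = inclusion_filter(u, session_length_s=session_length_s)
        row = {
            "unit_id": u.unit_id,
            "animal_id": u.animal_id,
            "duration_ms": dur,
            "label": label,
            "included": included,
            "reason": reason,
        }
        row.update(period_firing_rates(u, periods))
        rows.append(row)
    return pd.DataFrame(rows), cls
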