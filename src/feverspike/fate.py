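"""Neuron-fate classification across temperatures and cohort statistics.

A cell's fate summarizes whether evoked spiking persists as temperature
rises: NEVER (silent throughout), STAY (spiking at every temperature),
STOP (spiking at the first temperature, lost on some transition), START
(silent at the first temperature, spiking later).  Cohort proportions
are compared with exact two-tailed binomial tests; body-temperature
series are summarized with fever-bout detection.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats
from .records import TbSeries

__all__ = [
    "FateLabel",
    "FeverBout",
    "TbSummary",
    "spiking_flags",
    "classify_fate",
    "build_fate_table",
    "fate_proportions",
    "compare_proportions_binomial",
    "summarize_tb",
]


class FateLabel(str, Enum):
    NEVER = "never"
    STAY = "stay"
    STOP = "stop"
    START = "start"


def spiking_flags(
    cells: pd.DataFrame, min_spikes: int = 1
) -> pd.DataFrame:
    """Per-cell, per-temperature spiking flags from a cell-summary table.

    A cell is "spiking" at a temperature when at least one sweep there
    carries >= ``min_spikes`` detected evoked spikes.  Expects the
    ``summarize_cells`` output (columns cell_id, temperature,
    n_sweeps_with_spikes or spike_count).
    """
    df = cells.copy()
    if "n_sweeps_with_spikes" in df.columns and min_spikes == 1:
        df["spiking"] = df["n_sweeps_with_spikes"] >= 1
    elif "max_spike_count" in df.columns:
        df["spiking"] = df["max_spike_count"] >= min_spikes
    else:
        raise ValueError("cell summary lacks spiking-count columns")
    wide = df.pivot(index="cell_id", columns="temperature", values="spiking")
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"cells missing temperatures: {missing}")
    return wide.sort_index(axis=1)


def classify_fate(flags: Sequence[bool], mode: str = "three_temp") -> FateLabel:
    """Map ordered per-temperature spiking flags to a fate label.

    Three-temperature rule: all-false is NEVER; a cell spiking at the
    first temperature is STAY if it spikes at all of them, otherwise
    STOP; a cell silent at the first temperature that spikes later is
    START.  Two-temperature rule: (T,T) STAY, (T,F) STOP, (F,T) START,
    (F,F) NEVER.
    """
    flags = [bool(f) for f in flags]
    if mode == "three_temp":
        if len(flags) != 3:
            raise ValueError(f"three_temp mode needs 3 flags, got {len(flags)}")
    elif mode == "two_temp":
        if len(flags) != 2:
            raise ValueError(f"two_temp mode needs 2 flags, got {len(flags)}")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not any(flags):
        return FateLabel.NEVER
    if flags[0]:
        return FateLabel.STAY if all(flags) else FateLabel.STOP
    return FateLabel.START


def build_fate_table(
    cells: pd.DataFrame, min_spikes: int = 1, mode: str | None = None
) -> pd.DataFrame:
    """Fate label per cell from a cell-summary table.

    Returns one row per cell with its flags (columns ``spiking_<T>``)
    and ``fate``.  ``mode`` defaults to three_temp/two_temp according to
    the number of temperatures present.
    """
    wide = spiking_flags(cells, min_spikes=min_spikes)
    n_temp = wide.shape[1]
    if mode is None:
        mode = {3: "three_temp", 2: "two_temp"}.get(n_temp)
        if mode is None:
            raise ValueError(f"no fate rule for {n_temp} temperatures")
    rows = []
    for cell_id, row in wide.iterrows():
        flags = row.tolist()
        rec = {"cell_id": cell_id, "fate": classify_fate(flags, mode=mode).value}
        rec.update({f"spiking_{t:g}": bool(v) for t, v in zip(wide.columns, flags)})
        rows.append(rec)
    return pd.DataFrame(rows)


def fate_proportions(fates: pd.DataFrame | Mapping[str, int]) -> dict:
    """Cohort counts and percentages per fate label.

    Accepts a fate table (with a ``fate`` column) or a mapping
    label -> count.  Percentages are reported raw, rounded to one
    decimal, and to the nearest integer.
    """
    if isinstance(fates, pd.DataFrame):
        counts = fates["fate"].value_counts().to_dict()
    else:
        counts = dict(fates)
    n = sum(counts.values())
    if n == 0:
        raise ValueError("empty cohort")
    out = {"n_cells": int(n), "labels": {}}
    for label in FateLabel:
        k = int(counts.get(label.value, 0))
        pct = 100.0 * k / n
        out["labels"][label.value] = {
            "count": k,
            "pct": pct,
            "pct_1dp": round(pct, 1),
            "pct_int": int(round(pct)),
        }
    return out


def compare_proportions_binomial(
    k: int, n: int, p0: float, method: str = "small-p"
) -> float:
    """Exact two-tailed binomial test of k/n against a reference proportion."""
    return stats.binomial_two_tailed(k, n, p0, method=method)


@dataclass(frozen=True)
class FeverBout:
    """A maximal run of consecutive readings at or above the fever threshold."""

    start_s: float
    end_s: float
    peak_tb: float


@dataclass(frozen=True)
class TbSummary:
    median: float
    max: float
    min: float
    bouts: tuple[FeverBout, ...]
    fever_threshold: float


def summarize_tb(series: TbSeries, fever_threshold: float = 38.0) -> TbSummary:
    """Median/extremes of a body-temperature series plus fever bouts."""
    if series.tb.size == 0:
        raise ValueError("empty body-temperature series")
    hot = series.tb >= fever_threshold
    bouts = []
    i = 0
    n = hot.size
    while i < n:
        if hot[i]:
            j = i
            while j + 1 < n and hot[j + 1]:
                j += 1
            bouts.append(
                FeverBout(
                    start_s=float(series.times[i]),
                    end_s=float(series.times[j]),
                    peak_tb=float(np.max(series.tb[i : j + 1])),
                )
            )
            i = j + 1
        else:
            i += 1
    return TbSummary(
        median=float(np.median(series.tb)),
        max=float(np.max(series.tb)),
        min=float(np.min(series.tb)),
        bouts=tuple(bouts),
        fever_threshold=float(fever_threshold),
    )
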