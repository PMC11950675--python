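"""Event-level cytometry statistics.

A sample's recorded events (one row per cell, one column per scatter or
fluorescence channel) are reduced here to the per-sample summaries the rest
of the pipeline consumes: rectangular live-cell scatter gating, positivity
thresholds derived from fluorescence-minus-one (FMO) controls, percent of
marker-positive cells, two-channel quadrant fractions, and the median
fluorescence intensity (MFI).

Positivity is strictly greater-than the threshold throughout: an event
sitting exactly at an FMO-derived cutoff behaves like the control and is
counted negative.  Empirical quantiles use linear interpolation between
order statistics so thresholds are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, EmptyGateError, ValidationError


@dataclass
class EventTable:
    """Per-event channel intensities for one stained sample."""

    sample_id: str
    events: pd.DataFrame  # rows: events, columns: channels

    def __post_init__(self) -> None:
        if self.events.shape[0] < 1:
            raise ValidationError(f"{self.sample_id}: event table has zero events")
        if self.events.columns.has_duplicates:
            raise ValidationError(f"{self.sample_id}: duplicate channel names")
        if not np.isfinite(self.events.to_numpy(dtype=float)).all():
            raise ValidationError(f"{self.sample_id}: non-finite event values")

    @property
    def channels(self) -> list[str]:
        return [str(c) for c in self.events.columns]

    @property
    def n_events(self) -> int:
        return int(self.events.shape[0])

    def channel_values(self, channel: str) -> np.ndarray:
        if channel not in self.events.columns:
            raise ValidationError(
                f"{self.sample_id}: channel {channel!r} not in {self.channels}"
            )
        return self.events[channel].to_numpy(dtype=float)


@dataclass(frozen=True)
class GateSpec:
    """Rectangular scatter gate plus per-channel positivity thresholds."""

    scatter_bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    thresholds: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch, (lo, hi) in self.scatter_bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi)) or lo > hi:
                raise ValidationError(f"bad scatter bounds for {ch!r}: ({lo}, {hi})")
        for ch, t in self.thresholds.items():
            if not np.isfinite(t):
                raise ValidationError(f"non-finite threshold for {ch!r}")


def apply_scatter_gate(events: EventTable, gate: GateSpec) -> tuple[EventTable, float]:
    """Keep events inside every closed scatter interval of ``gate``.

    Returns the gated table and the retained fraction.  Retaining zero
    events raises :class:`EmptyGateError` — that signals a mis-set gate,
    not an empty sample.
    """
    mask = np.ones(events.n_events, dtype=bool)
    for ch, (lo, hi) in gate.scatter_bounds.items():
        v = events.channel_values(ch)
        mask &= (v >= lo) & (v <= hi)
    retained = float(mask.mean())
    if not mask.any():
        raise EmptyGateError(
            f"{events.sample_id}: scatter gate retained 0 of {events.n_events} events"
        )
    gated = EventTable(events.sample_id, events.events.loc[mask].reset_index(drop=True))
    return gated, retained


def fmo_threshold(fmo_events: EventTable, channel: str,
                  percentile: float = 99.0) -> float:
    """Positivity cutoff as an empirical percentile of an FMO control."""
    if not 0 < percentile <= 100:
        raise ValidationError(f"percentile must be in (0, 100], got {percentile}")
    values = fmo_events.channel_values(channel)
    return float(np.percentile(values, percentile, method="linear"))


def median_fluorescence(events: EventTable, channel: str) -> float:
    """MFI: the median of a channel's per-event values."""
    return float(np.median(events.channel_values(channel)))


def percent_positive(events: EventTable, channel: str, threshold: float) -> float:
    """Percentage of events strictly above ``threshold``, in [0, 100]."""
    v = events.channel_values(channel)
    return float(100.0 * np.mean(v > threshold))


def quadrant_fractions(events: EventTable, ch_x: str, ch_y: str,
                       t_x: float, t_y: float) -> tuple[float, float, float, float]:
    """Percentages in the four quadrants of a two-marker plot.

    Order: (x-y-, x+y-, x-y+, x+y+).  The four values sum to 100 exactly.
    """
    x = events.channel_values(ch_x) > t_x
    y = events.channel_values(ch_y) > t_y
    n = events.n_events
    pp = float(100.0 * np.sum(x & y) / n)
    pn = float(100.0 * np.sum(x & ~y) / n)
    np_ = float(100.0 * np.sum(~x & y) / n)
    nn = float(100.0 * np.sum(~x & ~y) / n)
    return (nn, pn, np_, pp)


def stemness_percentages(events: EventTable, channels: Mapping[str, float]) -> dict:
    """Percent-positive for each (channel, threshold) pair. Convenience."""
    return {ch: percent_positive(events, ch, t) for ch, t in channels.items()}


def require_min_events(events: EventTable, minimum: int = 20_000) -> None:
    """Enforce the recording convention of at least 20,000 events/sample."""
    if events.n_events < minimum:
        raise DegenerateDataError(
            f"{events.sample_id}: {events.n_events} events recorded, "
            f"minimum required is {minimum}"
        )
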