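"""Event-level flow-cytometry statistics.

Gates are set from negative controls (unstained cells or isotype-stained
cells) as a high quantile of the control's intensity distribution; percent
positive, MFI (mean fluorescence intensity), autofluorescence correction,
death fraction and growth-curve normalization follow the conventions of
marker-expression tables: MFI is computed in the live (viability-negative)
population and reported relative to a reference sample scaled to 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Gate",
    "set_gate_from_control",
    "percent_positive",
    "mfi",
    "normalize_mfi",
    "correct_autofluorescence",
    "death_fraction",
    "normalize_growth",
]


@dataclass(frozen=True)
class Gate:
    """An intensity threshold on one channel, derived from a control quantile."""

    channel: str
    threshold: float
    quantile: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold):
            raise ValueError("gate threshold must be finite")


def _channel(events: pd.DataFrame, channel: str) -> pd.Series:
    if channel not in events.columns:
        raise ValueError(f"channel {channel!r} not present (have {list(events.columns)})")
    return events[channel]


def _live_mask(events: pd.DataFrame, live_gate: Gate | None) -> np.ndarray:
    if live_gate is None:
        return np.ones(len(events), dtype=bool)
    # live = viability-stain negative, i.e. at or below the viability threshold
    return (_channel(events, live_gate.channel) <= live_gate.threshold).to_numpy()


def set_gate_from_control(
    control: pd.DataFrame,
    channel: str,
    quantile: float = 0.995,
) -> Gate:
    """Threshold at a high quantile of a negative control's intensities.

    Events above the threshold in a stained sample are called positive;
    by construction about ``1 - quantile`` of control events exceed it.
    """
    if len(control) < 100:
        raise ValueError(f"control has {len(control)} events; need at least 100")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    threshold = float(_channel(control, channel).quantile(quantile))
    return Gate(channel, threshold, quantile)


def percent_positive(
    sample: pd.DataFrame,
    gate: Gate,
    live_gate: Gate | None = None,
) -> float:
    """Percentage of (live) events above the gate threshold.

    With a ``live_gate``, events are first restricted to the
    viability-negative population before the marker gate is applied.
    """
    live = _live_mask(sample, live_gate)
    if not live.any():
        raise ValueError("no live events after viability gating")
    intens = _channel(sample, gate.channel).to_numpy()[live]
    return 100.0 * float(np.mean(intens > gate.threshold))


def mfi(
    sample: pd.DataFrame,
    channel: str,
    live_gate: Gate | None = None,
    positive_gate: Gate | None = None,
) -> float:
    """Mean fluorescence intensity over (live) events.

    By default the mean spans the whole live population; pass
    ``positive_gate`` to restrict to gate-positive events instead.
    """
    live = _live_mask(sample, live_gate)
    intens = _channel(sample, channel).to_numpy()[live]
    if positive_gate is not None:
        intens = intens[intens > positive_gate.threshold]
    if intens.size == 0:
        raise ValueError("no events left after gating")
    return float(np.mean(intens))


def normalize_mfi(
    values: Mapping[str, float] | pd.Series,
    reference_sample: str,
) -> pd.Series:
    """Express per-sample MFIs relative to a reference sample scaled to 100."""
    values = pd.Series(values, dtype=float)
    if reference_sample not in values.index:
        raise ValueError(f"reference sample {reference_sample!r} not among values")
    ref = values[reference_sample]
    if ref <= 0:
        raise ValueError("reference MFI must be positive")
    # divide first so the reference maps to exactly 100 in floating point
    return (values / ref) * 100.0


def correct_autofluorescence(
    sample: pd.DataFrame,
    unstained: pd.DataFrame,
    channel: str,
) -> pd.DataFrame:
    """Subtract the unstained control's mean intensity from one channel.

    Only the named channel is shifted; negative corrected intensities are
    retained so downstream means stay unbiased.
    """
    offset = float(_channel(unstained, channel).mean())
    _channel(sample, channel)  # raises if missing
    out = sample.copy()
    out[channel] = out[channel] - offset
    return out


def death_fraction(sample: pd.DataFrame, viability_gate: Gate) -> float:
    """Percentage of events positive for the viability (dead-cell) stain."""
    intens = _channel(sample, viability_gate.channel).to_numpy()
    return 100.0 * float(np.mean(intens > viability_gate.threshold))


def normalize_growth(counts) -> np.ndarray:
    """Normalize a time-ordered viable-cell count series to its initial value."""
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty count series")
    if counts[0] <= 0:
        raise ValueError("initial cell count must be positive")
    return counts / counts[0]
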