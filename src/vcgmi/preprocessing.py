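"""Canonicalize records: resample to 500 Hz, band-pass 0.5-150 Hz, zero phase."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .signal_io import MultiLeadRecord

__all__ = ["resample", "bandpass", "preprocess", "EDGE_GUARD_S"]

#: Seconds at each end of a filtered record excluded from beat segmentation
#: (filter transients).
EDGE_GUARD_S = 0.5


def resample(record: MultiLeadRecord, target_rate: float = 500.0) -> MultiLeadRecord:
    """Polyphase-resample every lead to ``target_rate``.

    A record already at the target rate is returned unchanged (same arrays).
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if record.sampling_rate == target_rate:
        return record
    ratio = Fraction(target_rate / record.sampling_rate).limit_denominator(1000)
    up, down = ratio.numerator, ratio.denominator
    leads = {name: sps.resample_poly(sig, up, down) for name, sig in record.leads.items()}
    return MultiLeadRecord(record.record_id, target_rate, leads, record.units)


def bandpass(
    record: MultiLeadRecord,
    low: float = 0.5,
    high: float = 150.0,
    order: int = 4,
) -> MultiLeadRecord:
    """Zero-phase Butterworth band-pass; preserves lead names and length."""
    nyquist = record.sampling_rate / 2.0
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= nyquist:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist ({nyquist} Hz)")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=record.sampling_rate, output="sos")
    leads = {name: sps.sosfiltfilt(sos, sig) for name, sig in record.leads.items()}
    return record.with_leads(leads)


def preprocess(
    record: MultiLeadRecord,
    target_rate: float = 500.0,
    low: float = 0.5,
    high: float = 150.0,
    order: int = 4,
) -> MultiLeadRecord:
    """Resample first, then band-pass (the pipeline's canonical order)."""
    return bandpass(resample(record, target_rate), low, high, order)
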