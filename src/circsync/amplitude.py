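"""Circadian amplitude of expression waveforms, on unscaled values.

Amplitude is the peak-to-trough range (max - min) of the replicate-averaged
mean waveform over the sampled 24-h cycle, computed on original expression
units — never on min-max normalized profiles, which would force every
amplitude to 1. A half-range convention ((max - min)/2) is available but off
by default. Condition contrasts are expressed as amplitude ratios or log2
ratios (e.g. TRF/ALF per tissue), tested against no change with a one-sample
t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datasets import StudyDataset
from .errors import ValidationError
from .stats import one_sample_ttest, unpaired_ttest  # noqa: F401  (re-exported)

__all__ = [
    "AmplitudeRecord",
    "circadian_amplitude",
    "amplitude_change",
    "tissue_amplitudes",
    "one_sample_ttest",
    "unpaired_ttest",
]


@dataclass(frozen=True)
class AmplitudeRecord:
    gene: str
    tissue: str  # a tissue id or "whole-body"
    condition: str
    amplitude: float
    peak_time_h: float
    trough_time_h: float


def circadian_amplitude(
    waveform,
    timepoints_h,
    gene: str = "",
    tissue: str = "whole-body",
    condition: str = "",
    half_range: bool = False,
) -> AmplitudeRecord:
    """Peak-to-trough amplitude of a mean waveform in original units.

    Ties on the extreme values resolve to the earliest timepoint. A constant
    waveform has amplitude 0 (not an error).
    """
    w = np.asarray(waveform, dtype=float)
    tp = np.asarray(timepoints_h, dtype=float)
    if w.ndim != 1 or w.shape != tp.shape:
        raise ValidationError("waveform and timepoints must be equal-length 1-D")
    peak_i = int(np.argmax(w))      # argmax/argmin return the earliest tie
    trough_i = int(np.argmin(w))
    amp = float(w[peak_i] - w[trough_i])
    if half_range:
        amp /= 2.0
    return AmplitudeRecord(
        gene=gene,
        tissue=tissue,
        condition=condition,
        amplitude=amp,
        peak_time_h=float(tp[peak_i]),
        trough_time_h=float(tp[trough_i]),
    )


def amplitude_change(
    rec_a: AmplitudeRecord,
    rec_b: AmplitudeRecord,
    mode: str = "ratio",
) -> float:
    """Amplitude change B relative to A: ``ratio`` B/A or ``log2_ratio``."""
    if mode not in ("ratio", "log2_ratio"):
        raise ValidationError(f"unknown mode {mode!r}")
    if rec_a.gene != rec_b.gene or rec_a.tissue != rec_b.tissue:
        raise ValidationError("amplitude_change requires the same gene and tissue")
    if rec_a.amplitude == 0:
        raise ValidationError("amplitude change undefined for zero baseline amplitude")
    ratio = rec_b.amplitude / rec_a.amplitude
    if mode == "log2_ratio":
        if ratio <= 0:
            raise ValidationError("log2 ratio undefined for non-positive ratio")
        return math.log2(ratio)
    return ratio


def tissue_amplitudes(
    gene: str,
    dataset: StudyDataset,
    condition: str,
) -> list[AmplitudeRecord]:
    """Per-tissue amplitude records of one gene, on unscaled values."""
    out = []
    for tissue, ts in sorted(dataset.condition_series(condition).items()):
        if gene not in ts.genes:
            continue
        out.append(
            circadian_amplitude(
                ts.profile(gene),
                ts.timepoints_h,
                gene=gene,
                tissue=tissue,
                condition=condition,
            )
        )
    if not out:
        raise ValidationError(f"gene {gene!r} absent from every tissue")
    return out
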