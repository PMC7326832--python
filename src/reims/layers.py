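"""Bowel-wall layer indication and streaming burn-by-burn recognition.

The rectal mucosa is rich in glycerophospholipids (GPLs) while the submucosa
is rich in triglycerides (TGs), so the ratio of summed normalised intensity
in the GPL window to that in the TG window falls as a dissection moves from
mucosa into submucosa.  ``gpl_tg_ratio`` turns one spectrum into a layer
call; ``recognize_stream`` replays an ordered stream of burns against a
saved classifier, emitting a tissue prediction and a layer call per burn —
the in-vivo recognition mode, where the signal-to-noise exclusion is applied
as a warning only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .chemometrics import ClassPrediction, OplsDaModel, classify_mahalanobis, load_model
from .preprocess import DEFAULT_SNR_THRESHOLD, compute_snr, preprocess
from .simulate import GPL_WINDOW, TG_WINDOW
from .spectra import BinAxis, Spectrum, bin_spectrum

RATIO_CAP = 1e6
UPPER_THRESHOLD = 2.0
LOWER_THRESHOLD = 0.5

__all__ = [
    "LayerCall",
    "BurnEvent",
    "StreamSummary",
    "gpl_tg_ratio",
    "recognize_stream",
]


@dataclass(frozen=True)
class LayerCall:
    spectrum_id: str
    gpl_sum: float
    tg_sum: float
    ratio: float  # capped at RATIO_CAP when tg_sum == 0
    call: str  # mucosa | mixed | submucosa | undefined


@dataclass(frozen=True)
class BurnEvent:
    burn_index: int
    timestamp: float
    prediction: ClassPrediction
    layer: LayerCall
    snr: float
    snr_warning: bool


@dataclass(frozen=True)
class StreamSummary:
    n_events: int
    class_counts: dict[str, int]
    longest_disease_run: int


def gpl_tg_ratio(
    s: Spectrum,
    gpl_window: tuple[float, float] = GPL_WINDOW,
    tg_window: tuple[float, float] = TG_WINDOW,
    upper: float = UPPER_THRESHOLD,
    lower: float = LOWER_THRESHOLD,
) -> LayerCall:
    """GPL:TG intensity ratio of one spectrum, thresholded into a layer call.

    Intensities are normalised by the spectrum's total ion count before
    windowed summation, so the call is invariant to uniform rescaling.
    ``ratio > upper`` calls mucosa, ``ratio < lower`` submucosa, anything
    between is the mixed layer.  A zero TG sum gives a capped ratio; both
    sums zero gives an ``undefined`` call.
    """
    g_lo, g_hi = gpl_window
    t_lo, t_hi = tg_window
    if max(g_lo, t_lo) < min(g_hi, t_hi):
        raise ValueError("GPL and TG windows must be disjoint")
    total = s.intensity.sum()
    if total == 0:
        return LayerCall(s.spectrum_id, 0.0, 0.0, float("nan"), "undefined")
    norm = s.intensity / total
    gpl = float(norm[(s.mz >= g_lo) & (s.mz < g_hi)].sum())
    tg = float(norm[(s.mz >= t_lo) & (s.mz < t_hi)].sum())
    if gpl == 0 and tg == 0:
        return LayerCall(s.spectrum_id, gpl, tg, float("nan"), "undefined")
    ratio = min(gpl / tg, RATIO_CAP) if tg > 0 else RATIO_CAP
    if ratio > upper:
        call = "mucosa"
    elif ratio < lower:
        call = "submucosa"
    else:
        call = "mixed"
    return LayerCall(s.spectrum_id, gpl, tg, ratio, call)


def recognize_stream(
    model: OplsDaModel | str | Path,
    stream: Iterable[Spectrum],
    snr_threshold: float = DEFAULT_SNR_THRESHOLD,
    burn_interval: float = 1.0,
    gpl_window: tuple[float, float] = GPL_WINDOW,
    tg_window: tuple[float, float] = TG_WINDOW,
) -> tuple[list[BurnEvent], StreamSummary]:
    """Classify an ordered stream of burns against a saved model.

    Each burn is preprocessed exactly like training data (binned on the
    model's axis, TIC-normalised, logged), classified by Mahalanobis
    distance in predictive score space, and given a GPL:TG layer call.  The
    quality gate runs in warn-only mode: low-signal burns are flagged on the
    event, never dropped — matching in-vivo operation where signal levels
    differ from ex-vivo acquisition.  Burns are stateless, so the outputs
    for a stream equal the concatenated outputs for any split of it.
    """
    if not isinstance(model, OplsDaModel):
        model = load_model(model)
    if model.axis is None:
        raise ValueError("model archive lacks a bin axis")
    spectra = list(stream)
    if not spectra:
        raise ValueError("empty stream")
    events: list[BurnEvent] = []
    counts: dict[str, int] = {c: 0 for c in model.class_labels}
    longest = current = 0
    disease_like = {"disease", "tumour", "adenoma"}
    for i, s in enumerate(spectra):
        try:
            snr, _ = compute_snr(s)
        except ValueError:
            snr = 0.0
        warn = snr < snr_threshold
        if warn:
            warnings.warn(
                f"burn {i} ({s.spectrum_id!r}): SNR {snr:.3g} below "
                f"{snr_threshold:g} (warn-only in streaming mode)"
            )
        m = preprocess([s], model.axis)
        pred = classify_mahalanobis(model, m.X[0], spectrum_id=s.spectrum_id)
        layer = gpl_tg_ratio(s, gpl_window=gpl_window, tg_window=tg_window)
        events.append(
            BurnEvent(
                burn_index=i,
                timestamp=i * burn_interval,
                prediction=pred,
                layer=layer,
                snr=snr,
                snr_warning=warn,
            )
        )
        counts[pred.predicted_label] += 1
        if pred.predicted_label in disease_like:
            current += 1
            longest = max(longest, current)
        else:
            current = 0
    return events, StreamSummary(
        n_events=len(events), class_counts=counts, longest_disease_run=longest
    )
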