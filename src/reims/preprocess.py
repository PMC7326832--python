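"""Quality gating and spectral preprocessing.

The quality statistic is the ratio of the median intensity of the 20 largest
peaks to the median of all in-range intensities; acquisitions with a ratio
below 1500 are excluded as too noisy.  Surviving spectra are binned, TIC
(total ion count) normalised so each row is a relative-abundance profile, and
log-transformed to stabilise variance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .spectra import BinAxis, FeatureMatrix, Spectrum

DEFAULT_SNR_THRESHOLD = 1500.0
LOG_SCALE = 1e4

EXCLUSION_REASONS = ("none", "low_snr", "contamination", "insufficient_target_tissue")

__all__ = [
    "DEFAULT_SNR_THRESHOLD",
    "LOG_SCALE",
    "QcResult",
    "compute_snr",
    "qc_filter",
    "tic_normalize",
    "log_transform",
    "preprocess",
    "write_qc_report",
]


@dataclass(frozen=True)
class QcResult:
    spectrum_id: str
    snr: float
    n_peaks_used: int
    passed: bool
    exclusion_reason: str = "none"

    def __post_init__(self) -> None:
        if self.exclusion_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.exclusion_reason!r}")
        if self.passed != (self.exclusion_reason == "none"):
            raise ValueError("passed must hold exactly when exclusion_reason is 'none'")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")


def _peak_intensities(intensity: np.ndarray) -> np.ndarray:
    """Intensities at strict local maxima of the raw sequence."""
    if intensity.size < 3:
        return np.empty(0)
    mid = intensity[1:-1]
    is_peak = (mid > intensity[:-2]) & (mid > intensity[2:])
    return mid[is_peak]


def compute_snr(s: Spectrum, low: float = 600.0, high: float = 1000.0) -> tuple[float, int]:
    """Signal-to-background statistic of a raw spectrum.

    Peaks are strict local maxima of the in-range intensity sequence; the
    statistic is ``median(top-20 peak intensities) / median(all in-range
    intensities)``.  When fewer than 20 local maxima exist (flat or sparse
    signal) the 20 largest raw intensities are used instead.  A zero overall
    median is replaced by the smallest nonzero intensity so the ratio stays
    finite.

    Returns
    -------
    (snr, n_peaks_used)

    Raises
    ------
    ValueError
        If the in-range spectrum is empty or all-zero (uninformative).
    """
    r = s.restrict(low, high)
    inten = r.intensity
    if inten.size == 0 or not np.any(inten > 0):
        raise ValueError(
            f"spectrum {s.spectrum_id!r}: no nonzero intensity in [{low}, {high})"
        )
    peaks = _peak_intensities(inten)
    if peaks.size < 20:
        peaks = np.sort(inten)[-20:]
    top = np.sort(peaks)[-20:]
    denom = float(np.median(inten))
    if denom == 0:
        denom = float(inten[inten > 0].min())
    return float(np.median(top)) / denom, int(top.size)


def qc_filter(
    batch: Sequence[Spectrum],
    threshold: float = DEFAULT_SNR_THRESHOLD,
    flags: dict[str, str] | None = None,
    low: float = 600.0,
    high: float = 1000.0,
) -> tuple[list[Spectrum], list[QcResult]]:
    """Partition a batch into kept spectra and excluded QC records.

    A spectrum is excluded when its quality statistic is strictly below
    ``threshold`` (a value exactly equal to the threshold is kept), or when
    the caller supplies a metadata-driven exclusion flag for it
    (``contamination`` or ``insufficient_target_tissue`` — these reflect
    visual/histological assessment and are never computed from the spectrum).
    """
    if not batch:
        raise ValueError("empty batch")
    flags = flags or {}
    kept: list[Spectrum] = []
    excluded: list[QcResult] = []
    for s in batch:
        snr, n_used = compute_snr(s, low=low, high=high)
        flag = flags.get(s.spectrum_id)
        if flag is not None:
            if flag not in ("contamination", "insufficient_target_tissue"):
                raise ValueError(f"unknown exclusion flag {flag!r}")
            excluded.append(QcResult(s.spectrum_id, snr, n_used, False, flag))
        elif snr < threshold:
            excluded.append(QcResult(s.spectrum_id, snr, n_used, False, "low_snr"))
        else:
            kept.append(s)
    return kept, excluded


def qc_results(
    batch: Sequence[Spectrum],
    threshold: float = DEFAULT_SNR_THRESHOLD,
    flags: dict[str, str] | None = None,
) -> list[QcResult]:
    """QC record for every spectrum in the batch (kept ones included)."""
    kept, excluded = qc_filter(batch, threshold=threshold, flags=flags)
    by_id = {r.spectrum_id: r for r in excluded}
    out = []
    for s in batch:
        if s.spectrum_id in by_id:
            out.append(by_id[s.spectrum_id])
        else:
            snr, n_used = compute_snr(s)
            out.append(QcResult(s.spectrum_id, snr, n_used, True, "none"))
    return out


def write_qc_report(results: Iterable[QcResult], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("spectrum_id\tsnr\tpassed\treason\n")
        for r in results:
            fh.write(f"{r.spectrum_id}\t{r.snr:.6g}\t{r.passed}\t{r.exclusion_reason}\n")


def tic_normalize(m: FeatureMatrix) -> FeatureMatrix:
    """Divide every row by its total ion count; stage becomes ``normalized``."""
    if m.stage != "binned":
        raise ValueError(f"expected stage 'binned', got {m.stage!r}")
    sums = m.X.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        bad = ", ".join(m.spectrum_ids[i] for i in zero[:5])
        raise ValueError(f"all-zero rows cannot be TIC-normalised: {bad}")
    out = replace_stage(m, m.X / sums[:, None], "normalized")
    return out


def log_transform(m: FeatureMatrix, scale: float = LOG_SCALE) -> FeatureMatrix:
    """Map every entry x to log10(1 + scale*x); stage becomes ``logged``.

    Monotone, zero-preserving, and approximately linear below 1/scale, so
    empty bins stay at zero while abundant relative intensities are
    compressed onto a decade scale.
    """
    if m.stage != "normalized":
        raise ValueError(f"expected stage 'normalized', got {m.stage!r}")
    if np.any(m.X < 0):
        raise ValueError("negative entries cannot be log-transformed")
    return replace_stage(m, np.log10(1.0 + scale * m.X), "logged")


def replace_stage(m: FeatureMatrix, X: np.ndarray, stage: str) -> FeatureMatrix:
    return FeatureMatrix(
        axis=m.axis,
        X=X,
        spectrum_ids=list(m.spectrum_ids),
        patient_ids=list(m.patient_ids),
        sample_ids=list(m.sample_ids),
        tissue_labels=list(m.tissue_labels),
        stage=stage,
    )


def preprocess(
    spectra: Sequence[Spectrum], axis: BinAxis | None = None
) -> FeatureMatrix:
    """Bin, TIC-normalise and log-transform a batch in one call."""
    from .spectra import build_feature_matrix

    return log_transform(tic_normalize(build_feature_matrix(spectra, axis)))
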