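"""Spectrum containers, the fixed statistical m/z axis, and spectrum I/O.

Negative-ion REIMS spectra are handled as centroided m/z-intensity lists with
patient/sample/tissue metadata.  The statistical analysis operates on a fixed
binned axis (default m/z 600-1000, half-open 0.1 Th bins), onto which raw
spectra are mapped by intensity summation.

The canonical interchange format is a plain-text multi-spectrum file: each
spectrum starts with a ``>spectrum`` line, followed by ``key = value`` metadata
lines and then whitespace-delimited ``m/z  intensity`` rows.  Centroided
mzML files are read directly (XML via :mod:`lxml`, base64/zlib binary
arrays), input-only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

TISSUE_LABELS = ("normal", "adenoma", "tumour", "unknown")

__all__ = [
    "TISSUE_LABELS",
    "Spectrum",
    "BinAxis",
    "FeatureMatrix",
    "SpectrumFormatError",
    "bin_spectrum",
    "build_feature_matrix",
    "read_spectra",
    "write_spectra",
]


class SpectrumFormatError(ValueError):
    """Raised for malformed spectrum records; carries file position context."""


@dataclass(frozen=True)
class Spectrum:
    """One acquisition event: centroided peaks plus provenance metadata.

    Parameters
    ----------
    spectrum_id, patient_id, sample_id
        Identifiers; ``patient_id`` drives leave-one-patient-out folds and
        ``sample_id`` drives the sample-level decision rule.
    tissue_label
        One of ``normal | adenoma | tumour | unknown``; ``unknown`` is only
        meaningful in prediction/streaming contexts.
    mz, intensity
        Equal-length arrays; ``mz`` strictly ascending, intensities >= 0.
    burn_index
        Optional ordering of the acquisition within a procedure.
    """

    spectrum_id: str
    patient_id: str
    sample_id: str
    tissue_label: str
    mz: np.ndarray
    intensity: np.ndarray
    burn_index: int | None = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if self.tissue_label not in TISSUE_LABELS:
            raise ValueError(
                f"spectrum {self.spectrum_id!r}: unknown tissue_label "
                f"{self.tissue_label!r} (expected one of {TISSUE_LABELS})"
            )
        if mz.ndim != 1 or inten.ndim != 1 or mz.shape != inten.shape:
            raise ValueError(
                f"spectrum {self.spectrum_id!r}: mz and intensity must be "
                "1-D arrays of equal length"
            )
        if mz.size and np.any(np.diff(mz) <= 0):
            raise ValueError(f"spectrum {self.spectrum_id!r}: mz not strictly ascending")
        if np.any(inten < 0):
            raise ValueError(f"spectrum {self.spectrum_id!r}: negative intensity")
        if np.any(~np.isfinite(mz)) or np.any(~np.isfinite(inten)):
            raise ValueError(f"spectrum {self.spectrum_id!r}: non-finite values")

    def restrict(self, low: float, high: float) -> "Spectrum":
        """Return a copy keeping only peaks with ``low <= m/z < high``."""
        keep = (self.mz >= low) & (self.mz < high)
        return replace(self, mz=self.mz[keep], intensity=self.intensity[keep])


@dataclass(frozen=True)
class BinAxis:
    """Half-open binning axis ``[low + k*width, low + (k+1)*width)``.

    Defaults cover the lipid-rich negative-mode window m/z 600-1000 at 0.1 Th,
    i.e. 4000 bins.  The upper edge is exclusive, so a peak at exactly
    ``high`` is discarded.
    """

    low: float = 600.0
    high: float = 1000.0
    width: float = 0.1

    def __post_init__(self) -> None:
        if not (self.high > self.low and self.width > 0):
            raise ValueError("require high > low and width > 0")
        n = (self.high - self.low) / self.width
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"(high - low) / width = {n} must be an integer bin count"
            )

    @property
    def n_bins(self) -> int:
        return int(round((self.high - self.low) / self.width))

    @property
    def centers(self) -> np.ndarray:
        return self.low + (np.arange(self.n_bins) + 0.5) * self.width

    def bin_of(self, mz: float) -> int | None:
        """Index of the bin containing ``mz``, or None if out of range."""
        if not (self.low <= mz < self.high):
            return None
        return min(int((mz - self.low) / self.width), self.n_bins - 1)


def bin_spectrum(s: Spectrum, axis: BinAxis) -> np.ndarray:
    """Sum each peak's intensity into the half-open bin containing its m/z.

    Peaks outside ``[axis.low, axis.high)`` are discarded.  Binning conserves
    the total in-range intensity exactly (up to float association error).
    """
    out = np.zeros(axis.n_bins)
    keep = (s.mz >= axis.low) & (s.mz < axis.high)
    if not keep.any():
        return out
    idx = np.floor((s.mz[keep] - axis.low) / axis.width).astype(int)
    np.clip(idx, 0, axis.n_bins - 1, out=idx)  # guard float edge at high-width
    np.add.at(out, idx, s.intensity[keep])
    return out


@dataclass
class FeatureMatrix:
    """Binned spectra stacked as rows on a shared axis.

    ``stage`` tracks the preprocessing state: ``binned`` (raw summed counts),
    ``normalized`` (rows sum to one after TIC normalisation) or ``logged``.
    """

    axis: BinAxis
    X: np.ndarray
    spectrum_ids: list[str]
    patient_ids: list[str]
    sample_ids: list[str]
    tissue_labels: list[str]
    stage: str = "binned"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        n = self.X.shape[0]
        if self.X.ndim != 2 or self.X.shape[1] != self.axis.n_bins:
            raise ValueError("X must be (n_spectra, n_bins)")
        for name in ("spectrum_ids", "patient_ids", "sample_ids", "tissue_labels"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != row count")
        if self.stage not in ("binned", "normalized", "logged"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage == "normalized":
            sums = self.X.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise ValueError("normalized rows must sum to 1 within 1e-9")

    @property
    def n_spectra(self) -> int:
        return self.X.shape[0]

    def subset(self, rows: Sequence[int] | np.ndarray) -> "FeatureMatrix":
        rows = np.asarray(rows, dtype=int)
        return FeatureMatrix(
            axis=self.axis,
            X=self.X[rows],
            spectrum_ids=[self.spectrum_ids[i] for i in rows],
            patient_ids=[self.patient_ids[i] for i in rows],
            sample_ids=[self.sample_ids[i] for i in rows],
            tissue_labels=[self.tissue_labels[i] for i in rows],
            stage=self.stage,
        )


def build_feature_matrix(spectra: Sequence[Spectrum], axis: BinAxis | None = None) -> FeatureMatrix:
    """Bin a batch of spectra onto a common axis (stage ``binned``)."""
    axis = axis or BinAxis()
    if not spectra:
        raise ValueError("empty spectrum list")
    X = np.vstack([bin_spectrum(s, axis) for s in spectra])
    return FeatureMatrix(
        axis=axis,
        X=X,
        spectrum_ids=[s.spectrum_id for s in spectra],
        patient_ids=[s.patient_id for s in spectra],
        sample_ids=[s.sample_id for s in spectra],
        tissue_labels=[s.tissue_label for s in spectra],
    )


# ---------------------------------------------------------------------------
# delimited interchange format


def write_spectra(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra to the plain-text multi-spectrum interchange format."""
    path = Path(path)
    with path.open("w") as fh:
        for s in spectra:
            fh.write(">spectrum\n")
            fh.write(f"spectrum_id = {s.spectrum_id}\n")
            fh.write(f"patient_id = {s.patient_id}\n")
            fh.write(f"sample_id = {s.sample_id}\n")
            fh.write(f"tissue_label = {s.tissue_label}\n")
            if s.burn_index is not None:
                fh.write(f"burn_index = {s.burn_index}\n")
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{float(mz)!r}\t{float(inten)!r}\n")


def _finish_record(
    meta: dict[str, str],
    mz: list[float],
    inten: list[float],
    start_line: int,
) -> Spectrum:
    required = ("spectrum_id", "patient_id", "sample_id", "tissue_label")
    for key in required:
        if key not in meta:
            raise SpectrumFormatError(
                f"record starting at line {start_line}: missing metadata key {key!r}"
            )
    burn = meta.get("burn_index")
    try:
        return Spectrum(
            spectrum_id=meta["spectrum_id"],
            patient_id=meta["patient_id"],
            sample_id=meta["sample_id"],
            tissue_label=meta["tissue_label"],
            mz=np.array(mz),
            intensity=np.array(inten),
            burn_index=int(burn) if burn is not None else None,
        )
    except ValueError as exc:
        raise SpectrumFormatError(
            f"record starting at line {start_line}: {exc}"
        ) from exc


def _read_delimited(path: Path) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    meta: dict[str, str] = {}
    mz: list[float] = []
    inten: list[float] = []
    start_line = 0
    in_record = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == ">spectrum":
                if in_record:
                    spectra.append(_finish_record(meta, mz, inten, start_line))
                meta, mz, inten = {}, [], []
                in_record = True
                start_line = lineno
                continue
            if not in_record:
                raise SpectrumFormatError(
                    f"line {lineno}: data before first '>spectrum' header"
                )
            if "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                meta[key.strip()] = value.strip()
                continue
            parts = line.split()
            if len(parts) != 2:
                raise SpectrumFormatError(
                    f"line {lineno}: expected 'm/z intensity', got {line!r}"
                )
            try:
                mz.append(float(parts[0]))
                inten.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumFormatError(f"line {lineno}: {exc}") from exc
    if in_record:
        spectra.append(_finish_record(meta, mz, inten, start_line))
    return spectra


def _decode_binary_array(bda, ns: str) -> tuple[str | None, np.ndarray]:
    """Decode one mzML <binaryDataArray>: returns (kind, values)."""
    import base64
    import zlib

    accessions = {
        cv.get("accession") for cv in bda.findall(f"{ns}cvParam")
    }
    kind = None
    if "MS:1000514" in accessions:
        kind = "mz"
    elif "MS:1000515" in accessions:
        kind = "intensity"
    dtype = np.float32 if "MS:1000521" in accessions else np.float64
    node = bda.find(f"{ns}binary")
    raw = base64.b64decode(node.text or "")
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> list[Spectrum]:
    from lxml import etree

    tree = etree.parse(str(path))
    root = tree.getroot()
    ns = "{%s}" % root.nsmap[None] if None in root.nsmap else ""
    spectra: list[Spectrum] = []
    for i, scan in enumerate(root.iter(f"{ns}spectrum")):
        sid = scan.get("id", f"scan={i}")
        arrays: dict[str, np.ndarray] = {}
        for bda in scan.iter(f"{ns}binaryDataArray"):
            kind, values = _decode_binary_array(bda, ns)
            if kind is not None:
                arrays[kind] = values
        if "mz" not in arrays or "intensity" not in arrays:
            raise SpectrumFormatError(f"scan {sid!r}: missing m/z or intensity array")
        mz, inten = arrays["mz"], arrays["intensity"]
        if mz.size != inten.size:
            raise SpectrumFormatError(f"scan {sid!r}: array length mismatch")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        # collapse duplicate m/z values so ascending order is strict
        if mz.size > 1 and np.any(np.diff(mz) == 0):
            uniq, inv = np.unique(mz, return_inverse=True)
            summed = np.zeros_like(uniq)
            np.add.at(summed, inv, inten)
            mz, inten = uniq, summed
        try:
            spectra.append(
                Spectrum(
                    spectrum_id=str(sid),
                    patient_id="unknown",
                    sample_id="unknown",
                    tissue_label="unknown",
                    mz=mz,
                    intensity=inten,
                )
            )
        except ValueError as exc:
            raise SpectrumFormatError(f"scan {sid!r}: {exc}") from exc
    return spectra


def read_spectra(path: str | Path, format: str = "delimited") -> list[Spectrum]:
    """Read spectra from ``path`` in the declared format.

    Parameters
    ----------
    format
        ``"delimited"`` (the canonical interchange format) or ``"mzml"``
        (read-only, centroided; metadata defaults to ``unknown``).

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    SpectrumFormatError
        On malformed records (message names the offending line/scan) or
        duplicate spectrum ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited":
        spectra = _read_delimited(path)
    elif format == "mzml":
        spectra = _read_mzml(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    seen: set[str] = set()
    for s in spectra:
        if s.spectrum_id in seen:
            raise SpectrumFormatError(f"duplicate spectrum_id {s.spectrum_id!r}")
        seen.add(s.spectrum_id)
    return spectra
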