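"""Discriminant-ion discovery: per-bin ANOVA with FDR control, and
annotation of significant bins against a lipid mass reference table.

Each m/z bin of the preprocessed (TIC-normalised, logged) matrix is tested
with a one-way fixed-effects ANOVA across tissue classes; p-values are
adjusted by the Benjamini–Hochberg step-up procedure and bins with adjusted
p <= 0.05 are reported as discriminant.  Significant bins can be matched to
deprotonated lipid masses within a tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import FeatureMatrix

DEFAULT_ALPHA = 0.05

__all__ = [
    "FeatureTestResult",
    "LipidReference",
    "anova_per_feature",
    "bh_adjust",
    "feature_table",
    "annotate",
    "synthetic_lipid_reference",
]


@dataclass(frozen=True)
class FeatureTestResult:
    bin_mz: float
    f_stat: float
    p_raw: float
    p_adj: float
    significant: bool
    class_means: dict[str, float]


@dataclass(frozen=True)
class LipidReference:
    """Deprotonated lipid masses for annotation: (mass, name, lipid_class)."""

    entries: tuple[tuple[float, str, str], ...]
    tolerance: float = 0.05

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")

    @classmethod
    def from_file(cls, path: str | Path, tolerance: float = 0.05) -> "LipidReference":
        """Read a 3-column delimited table: mass, name, lipid_class."""
        df = pd.read_csv(path, sep="\t", comment="#", names=["mass", "name", "lipid_class"])
        return cls(
            entries=tuple(
                (float(r.mass), str(r.name), str(r.lipid_class)) for r in df.itertuples()
            ),
            tolerance=tolerance,
        )


def anova_per_feature(
    m: FeatureMatrix, labels: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """One-way ANOVA F and p per bin, from between/within sums of squares.

    Returns ``(f_stats, p_raw, class_means)``.  Bins with zero total variance
    are uninformative and get F = 0, p = 1.  Degrees of freedom are
    (C - 1, N - C) for C classes and N spectra.
    """
    if m.stage != "logged":
        raise ValueError(f"expected stage 'logged', got {m.stage!r}")
    labels = list(labels) if labels is not None else list(m.tissue_labels)
    lab_arr = np.array(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    n, p = m.X.shape
    groups = [m.X[lab_arr == c] for c in classes]
    if any(g.shape[0] < 2 for g in groups):
        raise ValueError("every class needs >= 2 spectra")
    grand = m.X.mean(axis=0)
    ss_between = np.zeros(p)
    ss_within = np.zeros(p)
    class_means: dict[str, np.ndarray] = {}
    for c, g in zip(classes, groups):
        gm = g.mean(axis=0)
        class_means[c] = gm
        ss_between += g.shape[0] * (gm - grand) ** 2
        ss_within += ((g - gm) ** 2).sum(axis=0)
    df_b, df_w = len(classes) - 1, n - len(classes)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stats = (ss_between / df_b) / (ss_within / df_w)
    total_var = ss_between + ss_within
    degenerate = total_var <= 0
    zero_within = (ss_within == 0) & ~degenerate
    f_stats[degenerate] = 0.0
    f_stats[zero_within] = np.inf
    p_raw = stats.f.sf(f_stats, df_b, df_w)
    p_raw[degenerate] = 1.0
    return f_stats, p_raw, class_means


def bh_adjust(p_raw: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    Ascending p_i becomes q_i = p_i * m / i, then the running minimum from
    the largest rank down enforces monotonicity, capped at 1.
    """
    p = np.asarray(p_raw, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m_tests = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m_tests / np.arange(1, m_tests + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(adj)
    out[order] = adj
    return out


def feature_table(
    m: FeatureMatrix,
    labels: Sequence[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> list[FeatureTestResult]:
    """Full per-bin test results with BH-adjusted significance calls."""
    f_stats, p_raw, class_means = anova_per_feature(m, labels)
    p_adj = bh_adjust(p_raw)
    centers = m.axis.centers
    results = []
    for j in range(len(centers)):
        results.append(
            FeatureTestResult(
                bin_mz=float(centers[j]),
                f_stat=float(f_stats[j]),
                p_raw=float(p_raw[j]),
                p_adj=float(p_adj[j]),
                significant=bool(p_adj[j] <= alpha),
                class_means={c: float(v[j]) for c, v in class_means.items()},
            )
        )
    return results


def annotate(
    results: Sequence[FeatureTestResult], ref: LipidReference
) -> pd.DataFrame:
    """Match significant bins to reference masses within the tolerance.

    Every reference mass within tolerance of a bin centre is reported
    (sorted by |Δ m/z|); bins with no match are labelled ``unassigned``.
    """
    rows = []
    for r in results:
        if not r.significant:
            continue
        matches = sorted(
            (
                (abs(r.bin_mz - mass), mass, name, cls)
                for mass, name, cls in ref.entries
                if abs(r.bin_mz - mass) <= ref.tolerance
            ),
        )
        if not matches:
            rows.append(
                {
                    "bin_mz": r.bin_mz,
                    "p_adj": r.p_adj,
                    "assignment": "unassigned",
                    "lipid_class": "",
                    "delta_mz": np.nan,
                }
            )
        for delta, mass, name, cls in matches:
            rows.append(
                {
                    "bin_mz": r.bin_mz,
                    "p_adj": r.p_adj,
                    "assignment": name,
                    "lipid_class": cls,
                    "delta_mz": delta,
                }
            )
    return pd.DataFrame(
        rows, columns=["bin_mz", "p_adj", "assignment", "lipid_class", "delta_mz"]
    )


def synthetic_lipid_reference(tolerance: float = 0.05) -> LipidReference:
    """An illustrative reference table built from the synthetic template
    library (not measured lipid masses — synthetic stand-in for a curated
    database, named accordingly)."""
    from .simulate import default_templates

    entries = []
    counters = {"GPL": 0, "TG": 0, "other": 0}
    for t in default_templates():
        counters[t.lipid_class] += 1
        entries.append(
            (t.mz, f"{t.lipid_class}-{counters[t.lipid_class]:02d}", t.lipid_class)
        )
    return LipidReference(entries=tuple(entries), tolerance=tolerance)
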