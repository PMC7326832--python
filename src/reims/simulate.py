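"""Synthetic REIMS cohort generator.

The study's spectra are not publicly deposited, so every downstream stage is
exercised on simulated cohorts with the statistical structure the analysis
assumes: class-structured log-normal lipid peak abundances (normal mucosa /
adenoma / tumour), a patient-level random effect, per-spectrum multiplicative
noise, an exponential chemical baseline, and an optional fraction of
low-signal acquisitions that the QC gate must reject.

Model for the intensity of lipid template j in a spectrum from patient p with
tissue class c::

    log I_j = base_j + scale * delta_{j,c} + u_p + eps,
    u_p ~ N(0, patient_effect_sd),  eps ~ N(0, spectrum_noise_sd)

``scale`` is the class-effect multiplier (0 gives an exchangeable null
cohort).  The patient effect is a single scalar per patient, i.e. a
multiplicative shift of the whole lipid profile; TIC normalisation largely
removes it, which keeps per-bin tests calibrated on null cohorts.  Peaks are
rendered at jittered centroids and exponential baseline noise is scattered
uniformly over the m/z range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import compute_snr
from .spectra import Spectrum

__all__ = [
    "LipidPeakTemplate",
    "SamplePlan",
    "CohortDesign",
    "default_templates",
    "layer_templates",
    "generate_cohort",
    "generate_spectrum",
    "rectal_study_design",
    "balanced_design",
    "generate_layer_spectrum",
    "generate_burn_stream",
]

GPL_WINDOW = (650.0, 850.0)
TG_WINDOW = (850.0, 1000.0)


@dataclass(frozen=True)
class LipidPeakTemplate:
    """One lipid species: a centroid m/z plus per-class mean log-abundance."""

    mz: float
    lipid_class: str  # GPL | TG | other
    class_log_abundance: dict  # tissue class -> mean log-abundance
    peak_sd: float = 0.01  # m/z jitter (Th)


@dataclass(frozen=True)
class SamplePlan:
    patient_id: str
    sample_id: str
    tissue_label: str
    n_spectra: int


@dataclass(frozen=True)
class CohortDesign:
    """Full parameterisation of a synthetic cohort.

    ``class_effect_scale`` multiplies every between-class log-abundance
    difference; 0 yields a null cohort in which labels are exchangeable.
    ``low_snr_fraction`` of spectra are attenuated until the QC statistic
    falls below 1500, guaranteeing the gate has true positives to find.
    """

    sample_plan: tuple[SamplePlan, ...]
    templates: tuple[LipidPeakTemplate, ...]
    patient_effect_sd: float = 0.3
    spectrum_noise_sd: float = 0.45
    baseline_level: float = 1.0
    n_baseline_points: int = 1200
    class_effect_scale: float = 1.0
    low_snr_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patient_effect_sd < 0 or self.spectrum_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not (0 <= self.low_snr_fraction <= 1):
            raise ValueError("low_snr_fraction must be in [0, 1]")
        if self.class_effect_scale < 0:
            raise ValueError("class_effect_scale must be >= 0")
        if not self.sample_plan:
            raise ValueError("empty sample plan")

    @property
    def n_patients(self) -> int:
        return len({p.patient_id for p in self.sample_plan})

    @property
    def n_samples(self) -> int:
        return len({p.sample_id for p in self.sample_plan})

    @property
    def n_spectra(self) -> int:
        return sum(p.n_spectra for p in self.sample_plan)


def default_templates(
    n_gpl: int = 40,
    n_tg: int = 20,
    n_other: int = 20,
    discriminant_fraction: float = 0.35,
    contrast_sd: float = 0.9,
    template_seed: int = 20180612,
) -> tuple[LipidPeakTemplate, ...]:
    """The shipped template library: 40 GPL + 20 TG + 20 other peaks.

    Centroids are fixed pseudo-random draws (GPL from [650, 850), TG from
    [850, 1000), other anywhere in [600, 1000)).  A ``discriminant_fraction``
    of templates carry class contrasts: the tumour offset is drawn from
    ``N(0, contrast_sd)`` and the adenoma offset is a damped copy of it plus
    independent noise, so adenomas sit between normal mucosa and tumour and
    are preferentially confused with tumour — the error mode a rectal REIMS
    classifier actually exhibits.
    """
    rng = np.random.default_rng(template_seed)
    specs = (
        [("GPL", GPL_WINDOW, 9.0)] * n_gpl
        + [("TG", TG_WINDOW, 8.5)] * n_tg
        + [("other", (600.0, 1000.0), 8.0)] * n_other
    )
    templates = []
    for lipid_class, (lo, hi), base_mean in specs:
        mz = float(rng.uniform(lo, hi))
        base = float(rng.normal(base_mean, 0.4))
        if rng.uniform() < discriminant_fraction:
            d_tum = float(rng.normal(0.0, contrast_sd))
            d_ade = 0.7 * d_tum + float(rng.normal(0.0, 0.3 * contrast_sd))
        else:
            d_tum = d_ade = 0.0
        templates.append(
            LipidPeakTemplate(
                mz=mz,
                lipid_class=lipid_class,
                class_log_abundance={
                    "normal": base,
                    "adenoma": base + d_ade,
                    "tumour": base + d_tum,
                },
            )
        )
    templates.sort(key=lambda t: t.mz)
    return tuple(templates)


def _render_spectrum(
    log_means: np.ndarray,
    templates: Sequence[LipidPeakTemplate],
    design: CohortDesign,
    rng: np.random.Generator,
    peak_factor: float = 1.0,
    baseline_factor: float = 1.0,
    yield_log_scale: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    noise = rng.normal(0.0, design.spectrum_noise_sd, size=len(log_means))
    peak_int = np.exp(log_means + noise) * peak_factor
    peak_mz = np.array(
        [t.mz + rng.normal(0.0, t.peak_sd) for t in templates]
    )
    base_mz = rng.uniform(600.0, 1000.0, size=design.n_baseline_points)
    # chemical baseline scales with overall signal yield (the patient /
    # acquisition effect), so TIC normalisation removes that scalar entirely
    base_int = (
        rng.exponential(design.baseline_level, size=design.n_baseline_points)
        * baseline_factor
        * np.exp(yield_log_scale)
    )
    mz = np.concatenate([peak_mz, base_mz])
    inten = np.concatenate([peak_int, base_int])
    order = np.argsort(mz)
    mz, inten = mz[order], inten[order]
    # strict ascent: merge the (vanishingly rare) exact float ties
    if np.any(np.diff(mz) == 0):
        uniq, inv = np.unique(mz, return_inverse=True)
        summed = np.zeros_like(uniq)
        np.add.at(summed, inv, inten)
        mz, inten = uniq, summed
    keep = (mz >= 600.0) & (mz < 1000.0)
    return mz[keep], inten[keep]


def generate_spectrum(
    design: CohortDesign,
    tissue: str,
    patient_effect: float,
    rng: np.random.Generator,
    spectrum_id: str = "s0",
    patient_id: str = "p0",
    sample_id: str = "s0",
    burn_index: int | None = None,
    low_snr: bool = False,
) -> Spectrum:
    """Draw one spectrum for a tissue class given a patient effect."""
    normal_means = np.array(
        [t.class_log_abundance["normal"] for t in design.templates]
    )
    class_means = np.array(
        [t.class_log_abundance[tissue] for t in design.templates]
    )
    log_means = (
        normal_means
        + design.class_effect_scale * (class_means - normal_means)
        + patient_effect
    )
    peak_factor, baseline_factor = 1.0, 1.0
    if low_snr:
        peak_factor, baseline_factor = 1e-3, 10.0
    mz, inten = _render_spectrum(
        log_means,
        design.templates,
        design,
        rng,
        peak_factor,
        baseline_factor,
        yield_log_scale=patient_effect,
    )
    s = Spectrum(
        spectrum_id=spectrum_id,
        patient_id=patient_id,
        sample_id=sample_id,
        tissue_label=tissue,
        mz=mz,
        intensity=inten,
        burn_index=burn_index,
    )
    if low_snr:
        # guarantee rejection: keep attenuating until the statistic is < 1500
        while compute_snr(s)[0] >= 1450.0:
            inten = np.where(mz_in_peaks(mz, design), inten * 0.1, inten)
            s = Spectrum(
                spectrum_id=spectrum_id,
                patient_id=patient_id,
                sample_id=sample_id,
                tissue_label=tissue,
                mz=mz,
                intensity=inten,
                burn_index=burn_index,
            )
    return s


def mz_in_peaks(mz: np.ndarray, design: CohortDesign, tol: float = 0.2) -> np.ndarray:
    centers = np.array([t.mz for t in design.templates])
    return np.min(np.abs(mz[:, None] - centers[None, :]), axis=1) < tol


def generate_cohort(design: CohortDesign) -> list[Spectrum]:
    """Generate the full labelled cohort described by ``design``.

    Deterministic given ``design.seed``.  Spectra are emitted in sample-plan
    order; the ``low_snr_fraction`` worst acquisitions are chosen uniformly
    at random over the whole cohort.
    """
    rng = np.random.default_rng(design.seed)
    patient_ids = sorted({p.patient_id for p in design.sample_plan})
    effects = {
        pid: float(rng.normal(0.0, design.patient_effect_sd)) for pid in patient_ids
    }
    n_total = design.n_spectra
    n_low = int(round(design.low_snr_fraction * n_total))
    low_idx = set(rng.choice(n_total, size=n_low, replace=False).tolist())
    spectra: list[Spectrum] = []
    k = 0
    for plan in design.sample_plan:
        for j in range(plan.n_spectra):
            spectra.append(
                generate_spectrum(
                    design,
                    plan.tissue_label,
                    effects[plan.patient_id],
                    rng,
                    spectrum_id=f"{plan.sample_id}-{j:02d}",
                    patient_id=plan.patient_id,
                    sample_id=plan.sample_id,
                    low_snr=k in low_idx,
                )
            )
            k += 1
    return spectra


def _split_counts(total: int, n_groups: int) -> list[int]:
    """Distribute ``total`` spectra as evenly as possible over ``n_groups``."""
    base, extra = divmod(total, n_groups)
    return [base + 1 if i < extra else base for i in range(n_groups)]


def rectal_study_design(seed: int = 0, low_snr_fraction: float = 0.0, **kwargs) -> CohortDesign:
    """A design reproducing the printed shape of the ex vivo rectal cohort.

    47 patients and 77 tissue samples yielding 266 spectra: 109 tumour
    (30 samples, one per tumour patient), 36 adenoma (12 samples) and 121
    normal (35 samples: one from each tumour patient plus five normal-only
    patients).  Per-sample spectrum counts are not published, so spectra are
    distributed as evenly as the printed totals allow.  Default effect sizes
    are frozen at values giving >= 90% binary leave-one-patient-out accuracy.
    """
    plan: list[SamplePlan] = []
    tumour_counts = _split_counts(109, 30)
    for i, c in enumerate(tumour_counts):
        pid = f"p{i + 1:02d}"
        plan.append(SamplePlan(pid, f"{pid}-T", "tumour", c))
    adenoma_counts = _split_counts(36, 12)
    for i, c in enumerate(adenoma_counts):
        pid = f"p{i + 31:02d}"
        plan.append(SamplePlan(pid, f"{pid}-A", "adenoma", c))
    normal_patients = [f"p{i + 1:02d}" for i in range(30)] + [
        f"p{i + 43:02d}" for i in range(5)
    ]
    normal_counts = _split_counts(121, 35)
    for pid, c in zip(normal_patients, normal_counts):
        plan.append(SamplePlan(pid, f"{pid}-N", "normal", c))
    return CohortDesign(
        sample_plan=tuple(plan),
        templates=default_templates(),
        low_snr_fraction=low_snr_fraction,
        seed=seed,
        **kwargs,
    )


def balanced_design(
    n_patients_per_class: int = 4,
    samples_per_patient: int = 1,
    spectra_per_sample: int = 3,
    classes: Sequence[str] = ("normal", "adenoma", "tumour"),
    seed: int = 0,
    **kwargs,
) -> CohortDesign:
    """A small balanced design (each patient contributes one tissue class)."""
    plan: list[SamplePlan] = []
    i = 0
    for cls in classes:
        for _ in range(n_patients_per_class):
            i += 1
            pid = f"p{i:02d}"
            for s in range(samples_per_patient):
                plan.append(
                    SamplePlan(pid, f"{pid}-s{s}", cls, spectra_per_sample)
                )
    return CohortDesign(
        sample_plan=tuple(plan),
        templates=kwargs.pop("templates", default_templates()),
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# bowel-wall layers and burn streams


def layer_templates(template_seed: int = 20180612) -> dict[str, np.ndarray]:
    """Per-layer mean log-abundances over the default template library.

    Mucosa is glycerophospholipid-rich, submucosa triglyceride-rich and the
    mixed layer intermediate, mirroring how the GPL:TG balance shifts as a
    transanal dissection passes from mucosa into submucosa.
    """
    templates = default_templates(template_seed=template_seed)
    # TG boost for the mixed layer balances the GPL-heavy template library so
    # both lipid classes contribute comparably, as in a mixed-depth burn
    shift = {"mucosa": (0.8, -1.5), "mixed": (0.0, 1.1), "submucosa": (-1.5, 1.2)}
    out = {}
    for layer, (d_gpl, d_tg) in shift.items():
        means = []
        for t in templates:
            base = t.class_log_abundance["normal"]
            if t.lipid_class == "GPL":
                base += d_gpl
            elif t.lipid_class == "TG":
                base += d_tg
            means.append(base)
        out[layer] = np.array(means)
    return out


def generate_layer_spectrum(
    layer: str,
    rng: np.random.Generator,
    design: CohortDesign | None = None,
    spectrum_id: str = "burn",
    burn_index: int | None = None,
) -> Spectrum:
    """One synthetic burn spectrum from a bowel-wall layer."""
    design = design or balanced_design()
    means = layer_templates()[layer]
    mz, inten = _render_spectrum(means, design.templates, design, rng)
    return Spectrum(
        spectrum_id=spectrum_id,
        patient_id="in-vivo",
        sample_id="in-vivo",
        tissue_label="unknown",
        mz=mz,
        intensity=inten,
        burn_index=burn_index,
    )


def generate_burn_stream(
    design: CohortDesign,
    n_burns: int,
    tissue: str = "normal",
    layer_sequence: Sequence[str] | None = None,
    seed: int = 0,
) -> list[Spectrum]:
    """An ordered stream of burn spectra from one tissue class.

    ``layer_sequence``, when given, cycles layer-specific GPL/TG balance into
    the burns (mucosa -> mixed -> submucosa as a dissection deepens);
    otherwise spectra are plain draws from the tissue class with a fresh
    patient effect (an unseen in vivo patient).
    """
    rng = np.random.default_rng(seed)
    patient_effect = float(rng.normal(0.0, design.patient_effect_sd))
    stream = []
    for i in range(n_burns):
        if layer_sequence is not None:
            layer = layer_sequence[i % len(layer_sequence)]
            s = generate_layer_spectrum(
                layer, rng, design, spectrum_id=f"burn-{i:03d}", burn_index=i
            )
        else:
            s = generate_spectrum(
                design,
                tissue,
                patient_effect,
                rng,
                spectrum_id=f"burn-{i:03d}",
                patient_id="in-vivo",
                sample_id="in-vivo",
                burn_index=i,
            )
        stream.append(s)
    return stream
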