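"""Synthetic mesocosm LC-HRMS study generator.

Emulates a two-factor mesocosm monitoring campaign: river water with and
without treated-wastewater influence (factor 1), sampled at seven time
points over ten days (factor 2), measured by centroided LC-MS1. The
generator plants ground-truth chemical components — each an elution peak
(Gaussian or exponentially modified Gaussian) times an isotope/adduct
spectrum — with treatment effects, temporal trends (including a regime
change between time points S4 and S5), internal standards at fixed level,
background/blank chemicals, broad baseline-drift signals, erratic
artifact signals, an injection-peak region in the first minutes of the
run, and instrument noise. Every downstream stage of the pipeline is
testable against the returned ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import exponnorm

from .ms_io import FeatureTable, ScanSet

__all__ = [
    "SampleInfo",
    "StudyDesign",
    "GroundTruthComponent",
    "NoiseModel",
    "EffectConfig",
    "SyntheticTruth",
    "TIME_LEVELS",
    "TIME_HOURS",
    "generate_design",
    "generate_components",
    "generate_background_components",
    "render_sample",
    "simulate_study",
    "emit_fp_feature_table",
    "DetectionConfig",
    "injection_components",
    "default_study_components",
    "elution_profile",
]

#: Sampling grid: seven time points over the 10-day campaign.
TIME_LEVELS = ["S1", "S2", "S3", "S4", "S5", "S6", "S7"]
TIME_HOURS = {"S1": 1, "S2": 12, "S3": 24, "S4": 48, "S5": 96, "S6": 168, "S7": 240}

ISOTOPE_SPACING = 1.00336  # 13C-12C mass difference, Da
NA_ADDUCT_OFFSET = 21.98194  # [M+Na]+ minus [M+H]+, Da


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    sample_type: str  # control | treatment | blank | qc
    time_level: str | None  # S1..S7, None for blanks/QC
    replicate: int
    role: str  # study | blank | qc


@dataclass
class StudyDesign:
    """Sample layout of the mesocosm study (2 types x 7 times x replicates)."""

    samples: list

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in design")

    @property
    def sample_ids(self) -> list:
        return [s.sample_id for s in self.samples]

    def of_role(self, role: str) -> list:
        return [s for s in self.samples if s.role == role]

    @property
    def study_samples(self) -> list:
        return self.of_role("study")

    @property
    def blank_ids(self) -> list:
        return [s.sample_id for s in self.of_role("blank")]

    @property
    def qc_ids(self) -> list:
        return [s.sample_id for s in self.of_role("qc")]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def is_balanced(self) -> bool:
        counts = {}
        for s in self.study_samples:
            counts.setdefault((s.sample_type, s.time_level), 0)
            counts[(s.sample_type, s.time_level)] += 1
        return len(set(counts.values())) <= 1

    def drop(self, sample_ids) -> "StudyDesign":
        """Remove samples (e.g. outliers); the result may be unbalanced."""
        drop = set(sample_ids)
        return StudyDesign([s for s in self.samples if s.sample_id not in drop])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "type": [s.sample_type for s in self.samples],
                "time_level": [s.time_level if s.time_level else "" for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
                "role": [s.role for s in self.samples],
            }
        )

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StudyDesign":
        samples = [
            SampleInfo(
                str(r.sample_id),
                str(r.type),
                str(r.time_level) if str(r.time_level) else None,
                int(r.replicate),
                str(r.role),
            )
            for r in df.itertuples()
        ]
        return cls(samples)

    @classmethod
    def from_csv(cls, path) -> "StudyDesign":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))


def generate_design(
    n_reps_per_cell: int = 3,
    include_blanks: bool = True,
    include_qc: bool = False,
    n_blanks: int = 3,
    n_qc: int = 8,
    seed: int | None = None,
) -> StudyDesign:
    """Build the mesocosm sample layout.

    Defaults reproduce the study layout of 45 water samples: 21 control,
    21 treatment (3 replicated mesocosms x 7 time points) and 3 blanks;
    with ``include_qc`` and 8 QC runs the total run count is 53.
    """
    if n_reps_per_cell < 1:
        raise ValueError("n_reps_per_cell must be >= 1")
    samples = []
    for stype, prefix in (("control", "C"), ("treatment", "T")):
        for t in TIME_LEVELS:
            for r in range(1, n_reps_per_cell + 1):
                samples.append(SampleInfo(f"{prefix}{r}_{t}", stype, t, r, "study"))
    if include_blanks:
        for r in range(1, n_blanks + 1):
            samples.append(SampleInfo(f"B{r}", "blank", None, r, "blank"))
    if include_qc:
        for r in range(1, n_qc + 1):
            samples.append(SampleInfo(f"QC{r}", "qc", None, r, "qc"))
    return StudyDesign(samples)


@dataclass
class GroundTruthComponent:
    """One planted chemical/background species."""

    component_id: str
    mz: float  # monoisotopic (base peak) m/z, Da
    satellites: list = field(default_factory=list)  # [(offset Da, relative intensity)]
    rt_center: float = 600.0  # s
    sigma: float = 6.0  # Gaussian width, s
    tau: float = 0.0  # exponential tailing constant, s (0 = pure Gaussian)
    base_area: float = 1e6  # counts*s of the base-peak trace
    treatment_multiplier: float = 1.0
    temporal_profile: dict = field(default_factory=lambda: {t: 1.0 for t in TIME_LEVELS})
    blank_presence: float = 0.0  # fraction of base area present in blanks
    presence_prob: float = 1.0  # per-sample Bernoulli presence (artifacts < 1)
    replicate_cv: float | None = None  # overrides NoiseModel.area_cv when set
    is_internal_standard: bool = False
    origin: str = "analyte"  # analyte | background-blank | background-drift | artifact | injection

    def __post_init__(self):
        for off, rel in self.satellites:
            if not (0 < rel <= 1):
                raise ValueError("satellite relative intensities must be in (0, 1]")
        if self.is_internal_standard:
            if self.treatment_multiplier != 1.0 or any(
                v != 1.0 for v in self.temporal_profile.values()
            ):
                raise ValueError("internal standards are flat across design cells")

    @property
    def masses(self) -> list:
        """All masses of the component spectrum: [(m/z, rel intensity)] with base peak first."""
        return [(self.mz, 1.0)] + [(self.mz + off, rel) for off, rel in self.satellites]

    def expected_area(self, sample: SampleInfo) -> float:
        """Design-cell mean area (before replicate noise) in the given sample."""
        if sample.role == "blank":
            return self.base_area * self.blank_presence
        if sample.role == "qc":
            # QC runs behave like pooled reference injections: internal
            # standards and analytes at base level, background present,
            # no treatment/time structure.
            return 0.0 if self.origin == "artifact" else self.base_area
        area = self.base_area * self.temporal_profile.get(sample.time_level, 1.0)
        if sample.sample_type == "treatment":
            area *= self.treatment_multiplier
        return area


@dataclass
class NoiseModel:
    """Instrumental artifact model for rendering.

    All scales are in detector counts unless noted; everything must be >= 0.
    """

    baseline_drift_amplitude: float = 0.02  # multiplicative slow modulation
    baseline_drift_timescale: float = 600.0  # s
    additive_scale: float = 30.0  # counts, per-centroid Gaussian
    multiplicative_cv: float = 0.01  # heteroscedastic intensity noise
    rt_shift_sigma: float = 1.5  # per-sample shift, s
    spike_rate: float = 0.02  # electric spikes per scan (Poisson)
    mz_jitter_sigma: float = 5e-4  # centroid mass jitter, Da
    area_cv: float = 0.15  # lognormal replicate scatter of true areas
    intensity_floor: float = 1.0  # centroids below this are not recorded

    def __post_init__(self):
        for name in (
            "baseline_drift_amplitude",
            "baseline_drift_timescale",
            "additive_scale",
            "multiplicative_cv",
            "rt_shift_sigma",
            "spike_rate",
            "mz_jitter_sigma",
            "area_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def quiet(cls) -> "NoiseModel":
        """All noise sources off (for exactness oracles)."""
        return cls(0.0, 600.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class EffectConfig:
    """How planted analytes carry the design effects."""

    treatment_fraction: float = 0.4
    treatment_multiplier_range: tuple = (2.0, 5.0)  # log-uniform draw
    time_fraction: float = 0.5
    step_fraction: float = 0.5  # of time-structured: abrupt S4->S5 regime change
    step_multiplier_range: tuple = (2.5, 6.0)
    trend_decay_range: tuple = (0.3, 0.8)  # end/start ratio of monotone trends
    n_internal_standards: int = 4
    sigma_range: tuple = (4.0, 8.0)
    tailing_fraction: float = 0.2
    tau_range: tuple = (3.0, 9.0)
    base_area_range: tuple = (2e5, 5e6)  # log-uniform
    n_isotopes_max: int = 2
    isotope_rel_range: tuple = (0.05, 0.4)
    adduct_prob: float = 0.3
    adduct_rel_range: tuple = (0.08, 0.3)
    blank_leak: float = 0.02  # carry-over of analytes into blanks


def _draw_satellites(rng: np.random.Generator, cfg: EffectConfig) -> list:
    sats = []
    n_iso = int(rng.integers(1, cfg.n_isotopes_max + 1))
    rel = rng.uniform(*cfg.isotope_rel_range)
    for k in range(1, n_iso + 1):
        sats.append((k * ISOTOPE_SPACING, rel**k if rel**k > 0.02 else 0.02))
    if rng.random() < cfg.adduct_prob:
        sats.append((NA_ADDUCT_OFFSET, rng.uniform(*cfg.adduct_rel_range)))
    return sats


def _log_uniform(rng, lo, hi):
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_components(
    n_components: int,
    mz_range: tuple = (150.0, 900.0),
    rt_range: tuple = (400.0, 1700.0),
    effect_config: EffectConfig | None = None,
    seed: int | None = None,
) -> list:
    """Draw ground-truth analyte components (including internal standards).

    A configured fraction carry a treatment effect; a fraction carry
    temporal structure, half of those as an abrupt regime change between
    S4 and S5 (mirroring the early/late subclass split seen in the
    mesocosm), half as a monotone trend.
    """
    if n_components == 0:
        return []
    if mz_range[1] <= mz_range[0] or rt_range[1] <= rt_range[0]:
        raise ValueError("empty mz_range or rt_range")
    cfg = effect_config or EffectConfig()
    rng = np.random.default_rng(seed)
    comps = []
    n_is = min(cfg.n_internal_standards, n_components)
    for i in range(n_components):
        is_standard = i < n_is
        mz = float(rng.uniform(*mz_range))
        rt = float(rng.uniform(*rt_range))
        sigma = float(rng.uniform(*cfg.sigma_range))
        tau = 0.0
        if not is_standard and rng.random() < cfg.tailing_fraction:
            tau = float(rng.uniform(*cfg.tau_range))
        profile = {t: 1.0 for t in TIME_LEVELS}
        tmult = 1.0
        if not is_standard:
            if rng.random() < cfg.treatment_fraction:
                tmult = _log_uniform(rng, *cfg.treatment_multiplier_range)
            if rng.random() < cfg.time_fraction:
                if rng.random() < cfg.step_fraction:
                    step = _log_uniform(rng, *cfg.step_multiplier_range)
                    if rng.random() < 0.5:
                        step = 1.0 / step
                    profile = {t: (1.0 if t in ("S1", "S2", "S3", "S4") else step) for t in TIME_LEVELS}
                else:
                    ratio = float(rng.uniform(*cfg.trend_decay_range))
                    if rng.random() < 0.5:
                        ratio = 1.0 / ratio
                    profile = {
                        t: float(ratio ** (j / (len(TIME_LEVELS) - 1)))
                        for j, t in enumerate(TIME_LEVELS)
                    }
        comps.append(
            GroundTruthComponent(
                component_id=f"IS{i + 1}" if is_standard else f"cp{i + 1}",
                mz=mz,
                satellites=_draw_satellites(rng, cfg),
                rt_center=rt,
                sigma=sigma,
                tau=tau,
                base_area=1e6 if is_standard else _log_uniform(rng, *cfg.base_area_range),
                treatment_multiplier=tmult,
                temporal_profile=profile,
                blank_presence=cfg.blank_leak,
                is_internal_standard=is_standard,
                origin="analyte",
            )
        )
    return comps


def generate_background_components(
    n_components: int,
    mz_range: tuple = (150.0, 900.0),
    rt_range: tuple = (400.0, 1700.0),
    proportions: tuple = (0.5, 0.25, 0.25),  # blank-chemical, drift, artifact
    seed: int | None = None,
    run_length: float = 1800.0,
) -> list:
    """Draw non-mesocosm components: system/blank chemicals that appear
    equally in blanks and samples, broad baseline-drift signals, and
    erratic artifact signals present in a random subset of samples."""
    rng = np.random.default_rng(seed)
    n_blank = int(round(n_components * proportions[0]))
    n_drift = int(round(n_components * proportions[1]))
    n_art = n_components - n_blank - n_drift
    comps = []
    k = 0
    for _ in range(n_blank):
        k += 1
        comps.append(
            GroundTruthComponent(
                component_id=f"bg{k}",
                mz=float(rng.uniform(*mz_range)),
                satellites=[(ISOTOPE_SPACING, float(rng.uniform(0.05, 0.3)))],
                rt_center=float(rng.uniform(*rt_range)),
                sigma=float(rng.uniform(4.0, 10.0)),
                base_area=_log_uniform(rng, 3e5, 3e6),
                blank_presence=float(rng.uniform(0.8, 1.2)),
                origin="background-blank",
            )
        )
    for _ in range(n_drift):
        k += 1
        comps.append(
            GroundTruthComponent(
                component_id=f"bg{k}",
                mz=float(rng.uniform(*mz_range)),
                satellites=[],
                rt_center=float(rng.uniform(0.35, 0.65) * run_length),
                sigma=float(rng.uniform(250.0, 450.0)),
                base_area=_log_uniform(rng, 1e7, 5e7),
                blank_presence=float(rng.uniform(0.8, 1.2)),
                origin="background-drift",
            )
        )
    for _ in range(n_art):
        k += 1
        comps.append(
            GroundTruthComponent(
                component_id=f"bg{k}",
                mz=float(rng.uniform(*mz_range)),
                satellites=[],
                rt_center=float(rng.uniform(*rt_range)),
                sigma=float(rng.uniform(4.0, 8.0)),
                base_area=_log_uniform(rng, 5e5, 5e6),
                blank_presence=0.0,
                presence_prob=0.2,
                replicate_cv=1.2,
                origin="artifact",
            )
        )
    return comps


def injection_components(mz_range=(150.0, 900.0), n: int = 6, seed: int | None = None) -> list:
    """Unretained material eluting in the injection-peak region (< 330 s)."""
    rng = np.random.default_rng(seed)
    return [
        GroundTruthComponent(
            component_id=f"inj{i + 1}",
            mz=float(rng.uniform(*mz_range)),
            satellites=[],
            rt_center=float(rng.uniform(40.0, 250.0)),
            sigma=float(rng.uniform(8.0, 25.0)),
            base_area=_log_uniform(rng, 1e6, 2e7),
            blank_presence=float(rng.uniform(0.5, 1.2)),
            origin="injection",
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# rendering


def elution_profile(times: np.ndarray, rt_center: float, sigma: float, tau: float) -> np.ndarray:
    """Unit-area elution profile: Gaussian, or EMG when tau > 0."""
    if tau > 0:
        K = tau / sigma
        return exponnorm.pdf(times, K, loc=rt_center, scale=sigma)
    z = (times - rt_center) / sigma
    return np.exp(-0.5 * z * z) / (sigma * np.sqrt(2.0 * np.pi))


def true_area(
    component: GroundTruthComponent,
    sample: SampleInfo,
    noise: NoiseModel,
    rng: np.random.Generator,
) -> float:
    """Realized base-peak area of one component in one sample."""
    mean = component.expected_area(sample)
    if component.presence_prob < 1.0 and sample.role == "study":
        if rng.random() >= component.presence_prob:
            return 0.0
    if mean <= 0:
        return 0.0
    cv = component.replicate_cv if component.replicate_cv is not None else noise.area_cv
    if cv > 0:
        s = np.sqrt(np.log1p(cv**2))
        mean *= float(rng.lognormal(-0.5 * s * s, s))
    return mean


def render_sample(
    components: list,
    sample_info: SampleInfo,
    noise: NoiseModel | None = None,
    scan_interval: float = 0.4,
    run_length: float = 1800.0,
    seed: int | None = None,
) -> tuple:
    """Render one sample's centroided run.

    Returns ``(ScanSet, truth)`` where ``truth`` is a dict with the
    realized per-component areas and the applied RT shift.

    Each present component contributes its elution profile sampled at the
    scan times, multiplied by its isotope/adduct spectrum; centroids then
    receive multiplicative and additive noise, m/z jitter, slow baseline
    modulation and occasional single-scan electric spikes.
    """
    noise = noise or NoiseModel()
    if scan_interval <= 0:
        raise ValueError("scan_interval must be positive")
    for c in components:
        if not (0.0 <= c.rt_center <= run_length):
            raise ValueError(f"component {c.component_id} RT outside run")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, run_length, scan_interval)
    n_scans = times.size
    rt_shift = float(rng.normal(0.0, noise.rt_shift_sigma)) if noise.rt_shift_sigma > 0 else 0.0

    areas = {}
    scan_idx_parts, mz_parts, int_parts = [], [], []
    for comp in components:
        area = true_area(comp, sample_info, noise, rng)
        areas[comp.component_id] = area
        if area <= 0:
            continue
        center = comp.rt_center + rt_shift
        span = 6.0 * comp.sigma + 8.0 * comp.tau
        i0 = max(0, int(np.floor((center - span) / scan_interval)))
        i1 = min(n_scans, int(np.ceil((center + span) / scan_interval)) + 1)
        if i1 <= i0:
            continue
        prof = elution_profile(times[i0:i1], center, comp.sigma, comp.tau) * area
        for mass, rel in comp.masses:
            inten = prof * rel
            keep = inten >= noise.intensity_floor
            if not keep.any():
                continue
            idx = np.nonzero(keep)[0] + i0
            scan_idx_parts.append(idx)
            mz_parts.append(np.full(idx.size, mass))
            int_parts.append(inten[keep])

    if scan_idx_parts:
        scan_idx = np.concatenate(scan_idx_parts)
        mzv = np.concatenate(mz_parts)
        intv = np.concatenate(int_parts)
    else:
        scan_idx = np.zeros(0, dtype=int)
        mzv = np.zeros(0)
        intv = np.zeros(0)

    # instrumental perturbations
    if noise.baseline_drift_amplitude > 0 and intv.size:
        phase = rng.uniform(0, 2 * np.pi)
        drift = 1.0 + noise.baseline_drift_amplitude * np.sin(
            2 * np.pi * times[scan_idx] / noise.baseline_drift_timescale + phase
        )
        intv = intv * drift
    if noise.multiplicative_cv > 0 and intv.size:
        intv = intv * (1.0 + rng.normal(0.0, noise.multiplicative_cv, intv.size))
    if noise.additive_scale > 0 and intv.size:
        intv = intv + rng.normal(0.0, noise.additive_scale, intv.size)
    if noise.mz_jitter_sigma > 0 and mzv.size:
        mzv = mzv + rng.normal(0.0, noise.mz_jitter_sigma, mzv.size)
    if noise.spike_rate > 0:
        n_spikes = rng.poisson(noise.spike_rate * n_scans)
        if n_spikes:
            scan_idx = np.concatenate([scan_idx, rng.integers(0, n_scans, n_spikes)])
            mzv = np.concatenate([mzv, rng.uniform(100.0, 1000.0, n_spikes)])
            intv = np.concatenate([intv, rng.exponential(5e4, n_spikes)])

    keep = intv >= noise.intensity_floor
    scan_idx, mzv, intv = scan_idx[keep], mzv[keep], intv[keep]

    order = np.lexsort((mzv, scan_idx))
    scan_idx, mzv, intv = scan_idx[order], mzv[order], intv[order]
    bounds = np.searchsorted(scan_idx, np.arange(n_scans + 1))
    mzs = [mzv[bounds[i] : bounds[i + 1]] for i in range(n_scans)]
    intens = [intv[bounds[i] : bounds[i + 1]] for i in range(n_scans)]

    scanset = ScanSet(sample_info.sample_id, times, mzs, intens)
    return scanset, {"areas": areas, "rt_shift": rt_shift}


@dataclass
class SyntheticTruth:
    """Ground truth of a rendered study: what the pipeline should recover."""

    components: list
    true_areas: pd.DataFrame  # samples x components (realized areas)
    rt_shifts: pd.Series
    design: StudyDesign

    def component(self, component_id: str) -> GroundTruthComponent:
        return next(c for c in self.components if c.component_id == component_id)

    def analyte_ids(self, rt_min: float = 0.0) -> list:
        """Components a correct pipeline should retain (analytes and
        internal standards eluting after ``rt_min``)."""
        return [
            c.component_id
            for c in self.components
            if c.origin == "analyte" and c.rt_center >= rt_min
        ]

    def to_files(self, stem) -> None:
        stem = Path(stem)
        self.true_areas.to_csv(stem.with_suffix(".areas.csv"))
        self.design.to_csv(stem.with_suffix(".design.csv"))
        import json

        meta = [
            {
                "component_id": c.component_id,
                "mz": c.mz,
                "satellites": c.satellites,
                "rt_center": c.rt_center,
                "sigma": c.sigma,
                "tau": c.tau,
                "base_area": c.base_area,
                "treatment_multiplier": c.treatment_multiplier,
                "temporal_profile": c.temporal_profile,
                "blank_presence": c.blank_presence,
                "presence_prob": c.presence_prob,
                "is_internal_standard": c.is_internal_standard,
                "origin": c.origin,
            }
            for c in self.components
        ]
        with open(stem.with_suffix(".components.json"), "w") as fh:
            json.dump(meta, fh, indent=1)


def simulate_study(
    design: StudyDesign,
    components: list,
    noise: NoiseModel | None = None,
    scan_interval: float = 0.4,
    run_length: float = 1800.0,
    seed: int | None = None,
) -> tuple:
    """Render every sample of a design; returns ``(scansets, truth)``.

    All randomness flows from one seed; per-sample streams are spawned
    deterministically so the result is reproducible sample-by-sample.
    """
    noise = noise or NoiseModel()
    ss = _as_seedseq(seed)
    child_seeds = ss.spawn(len(design.samples))
    scansets = {}
    rows = {}
    shifts = {}
    for sample, child in zip(design.samples, child_seeds):
        scanset, truth = render_sample(
            components, sample, noise, scan_interval, run_length, seed=child
        )
        scansets[sample.sample_id] = scanset
        rows[sample.sample_id] = truth["areas"]
        shifts[sample.sample_id] = truth["rt_shift"]
    true_areas = pd.DataFrame.from_dict(rows, orient="index")
    true_areas = true_areas.loc[design.sample_ids, [c.component_id for c in components]]
    return scansets, SyntheticTruth(
        components, true_areas, pd.Series(shifts).loc[design.sample_ids], design
    )


def default_study_components(
    n_analytes: int = 40,
    n_background: int = 40,
    seed: int | None = None,
    run_length: float = 1800.0,
) -> list:
    """The default synthetic study: analytes (incl. internal standards),
    an equal number of background/artifact components, and injection-peak
    material."""
    ss = _as_seedseq(seed)
    s1, s2, s3 = ss.spawn(3)
    rt_range = (400.0, max(run_length - 100.0, 500.0))
    return (
        generate_components(n_analytes, rt_range=rt_range, seed=s1)
        + generate_background_components(n_background, rt_range=rt_range, seed=s2, run_length=run_length)
        + injection_components(seed=s3)
    )


# ---------------------------------------------------------------------------
# surrogate feature-profiling table


@dataclass
class DetectionConfig:
    """What the surrogate feature-profiling tool can see."""

    min_intensity: float = 0.0  # apex counts required in >= 1 sample
    min_scan_span: int = 0  # scans above min_intensity required
    scan_interval: float = 0.4
    reject_tailing_tau: float = np.inf  # peaks with tau >= this are missed
    false_positive_rate: float = 0.0  # FP rows per true row
    gap_fill: bool = True  # fill missing areas at detection-limit level
    mz_decimals: int = 4


def _scans_above(comp: GroundTruthComponent, apex: float, thr: float, dt: float) -> int:
    """Scan count of the Gaussian part above an intensity threshold."""
    if apex <= thr or thr <= 0:
        return np.inf if thr <= 0 else 0
    width = 2.0 * comp.sigma * np.sqrt(2.0 * np.log(apex / thr))
    return int(width / dt) + 1


def emit_fp_feature_table(
    truth: SyntheticTruth,
    detection: DetectionConfig | None = None,
    seed: int | None = None,
) -> FeatureTable:
    """Emit a surrogate feature-profiling (MZmine-style) table from truth.

    One row per (component x spectrum mass) that passes the detection
    rules; areas are the realized true areas scaled by the satellite's
    relative intensity. Optional false-positive rows emulate artifact
    features with random m/z and RT. With ``gap_fill`` (the default,
    mirroring gap-filled exports) areas absent from a sample are replaced
    by a small area at the detection limit rather than an exact zero.
    """
    det = detection or DetectionConfig()
    rng = np.random.default_rng(seed)
    sample_ids = truth.design.sample_ids
    fill_scale = det.min_intensity if det.min_intensity > 0 else 100.0
    rows = []
    for comp in truth.components:
        if comp.tau >= det.reject_tailing_tau:
            continue
        areas = truth.true_areas[comp.component_id].to_numpy().copy()
        max_area = areas.max() if areas.size else 0.0
        apex = max_area / (comp.sigma * np.sqrt(2 * np.pi))
        if det.min_intensity > 0 and apex < det.min_intensity:
            continue
        if det.min_scan_span > 0:
            span = _scans_above(comp, apex, max(det.min_intensity, 1.0), det.scan_interval)
            if span < det.min_scan_span:
                continue
        for j, (mass, rel) in enumerate(comp.masses):
            if det.min_intensity > 0 and apex * rel < det.min_intensity:
                continue
            vals = areas * rel
            if det.gap_fill:
                missing = vals <= 0
                if missing.any():
                    vals = vals.copy()
                    vals[missing] = (
                        fill_scale * comp.sigma * np.sqrt(2 * np.pi) * rng.uniform(0.3, 1.0, missing.sum())
                    )
            rows.append(
                {
                    "feature_id": f"{comp.component_id}_m{j}",
                    "mz": round(mass, det.mz_decimals),
                    "rt": comp.rt_center,
                    **{sid: vals[k] for k, sid in enumerate(sample_ids)},
                }
            )
    n_fp = rng.binomial(len(rows), det.false_positive_rate) if det.false_positive_rate > 0 else 0
    for j in range(n_fp):
        level = fill_scale * 6.0 * np.sqrt(2 * np.pi) * np.exp(rng.uniform(0.0, 2.5))
        fake = level * rng.lognormal(0.0, 1.0, len(sample_ids))
        rows.append(
            {
                "feature_id": f"fp{j}",
                "mz": round(float(rng.uniform(150.0, 900.0)), det.mz_decimals),
                "rt": float(rng.uniform(330.0, 1700.0)),
                **{sid: fake[k] for k, sid in enumerate(sample_ids)},
            }
        )
    df = pd.DataFrame(rows, columns=["feature_id", "mz", "rt", *sample_ids])
    df = df.set_index("feature_id")
    return FeatureTable(df)
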