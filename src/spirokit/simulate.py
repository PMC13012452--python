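"""Synthetic spirogram, demographics, and cohort generation.

The curve family is piecewise in the volume domain: a linear rise of flow
with exhaled volume up to the peak, followed by a power-law descending limb

    Q(v) = PEF * (v / v_peak)                          for v <  v_peak
    Q(v) = PEF * ((FVC - v) / (FVC - v_peak)) ** k     for v >= v_peak

where ``v_peak = v_peak_frac * FVC``.  The shape exponent ``k`` directly
parameterises descending-limb morphology: ``k > 1`` gives the concave
("scooped") limb characteristic of airflow obstruction, ``k = 1`` a linear
limb, and ``k < 1`` a convex limb.  Both limbs of the volume ODE
``dv/dt = Q(v)`` admit closed-form time solutions, so maneuvers are emitted
by exact evaluation on a uniform time grid rather than by a numerical
stepper (see docs/methods.md), and every spirometric index has an analytic
oracle against which the metric engine is tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CurveParams",
    "Demographics",
    "SpiroCurve",
    "Record",
    "EffectConfig",
    "DemographicsConfig",
    "GenerationError",
    "flow_at_volume",
    "curve_timeline",
    "synthesize_curve",
    "sample_demographics",
    "generate_cohort",
    "separable_benchmark",
]

#: fraction of FVC used to bootstrap the rising-limb exponential (the ODE has
#: a fixed point at v=0, so the maneuver starts from a tiny seeded volume).
_BOOTSTRAP_FRAC = 1e-3


class GenerationError(ValueError):
    """Raised when curve parameters cannot produce a valid maneuver."""


@dataclass(frozen=True)
class CurveParams:
    """Parameters of one synthetic forced-expiratory maneuver."""

    fvc_true: float  # total exhalable volume, L
    pef_true: float  # peak expiratory flow, L/s
    v_peak_frac: float = 0.10  # fraction of FVC exhaled at peak flow
    shape_k: float = 1.0  # descending-limb exponent (k>1 concave)
    noise_sd: float = 0.0  # additive Gaussian flow noise, L/s
    dt: float = 0.01  # sampling interval, s
    end_flow_threshold: float = 0.025  # end-of-test flow criterion, L/s

    def __post_init__(self) -> None:
        if not self.fvc_true > 0:
            raise ValueError(f"fvc_true must be positive, got {self.fvc_true}")
        if not self.pef_true > 0:
            raise ValueError(f"pef_true must be positive, got {self.pef_true}")
        if not 0 < self.v_peak_frac < 1:
            raise ValueError(f"v_peak_frac must lie in (0, 1), got {self.v_peak_frac}")
        if not self.shape_k > 0:
            raise ValueError(f"shape_k must be positive, got {self.shape_k}")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.end_flow_threshold < 0:
            raise ValueError("end_flow_threshold must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def v_peak(self) -> float:
        return self.v_peak_frac * self.fvc_true


@dataclass(frozen=True)
class Demographics:
    """Subject covariates that drive expected lung volumes."""

    age: float  # years
    sex: str  # "male" | "female"
    height: float  # cm
    smoking: str = "never"  # "never" | "former" | "current"

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError("age must be positive")
        if not self.height > 0:
            raise ValueError("height must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.smoking not in ("never", "former", "current"):
            raise ValueError(f"unknown smoking status {self.smoking!r}")


@dataclass
class SpiroCurve:
    """One expiratory maneuver: uniformly sampled flow (L/s)."""

    flow: np.ndarray  # shape (T,), L/s
    dt: float  # s
    blow_id: int = 1

    def __post_init__(self) -> None:
        self.flow = np.asarray(self.flow, dtype=float)
        if self.flow.ndim != 1 or self.flow.size < 2:
            raise ValueError("flow must be a 1-D sequence with at least 2 samples")
        if not np.all(np.isfinite(self.flow)):
            raise ValueError("flow contains non-finite values")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.blow_id < 1:
            raise ValueError("blow_id must be >= 1")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.flow.size) * self.dt

    @property
    def duration(self) -> float:
        return (self.flow.size - 1) * self.dt


@dataclass
class Record:
    """One subject-instance: curves, demographics, diagnosis codes, label."""

    subject_id: str
    curves: list
    demographics: Demographics
    diagnosis_codes: list = field(default_factory=list)
    label: int = 0
    pft: object = None  # PFTResult, attached by the metrics stage
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.curves) < 1:
            raise ValueError("a record needs at least one curve")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def flow_at_volume(params: CurveParams, v):
    """Instantaneous flow (L/s) at exhaled volume ``v`` (L).

    Rising limb for ``v < v_peak``, power-law descending limb above.  Accepts
    scalars or arrays; raises for volumes outside ``[0, FVC]``.
    """
    v_arr = np.asarray(v, dtype=float)
    if np.any(v_arr < 0) or np.any(v_arr > params.fvc_true):
        raise ValueError(
            f"volume must lie in [0, {params.fvc_true}] L, got {v!r}"
        )
    vp = params.v_peak
    w = params.fvc_true - vp
    rising = params.pef_true * (v_arr / vp)
    falling = params.pef_true * ((params.fvc_true - v_arr) / w) ** params.shape_k
    out = np.where(v_arr < vp, rising, falling)
    return float(out) if np.isscalar(v) or v_arr.ndim == 0 else out


def _rise_rate(params: CurveParams) -> float:
    # dv/dt = (PEF/v_peak) * v on the rising limb
    return params.pef_true / params.v_peak


def _t_peak(params: CurveParams) -> float:
    """Time at which flow reaches PEF (exponential rise from v0)."""
    v0 = _BOOTSTRAP_FRAC * params.fvc_true
    lam = _rise_rate(params)
    return math.log(params.v_peak / v0) / lam


def _u_end(params: CurveParams) -> float:
    """Remaining volume FVC - v when noiseless flow first drops below the
    end-of-test threshold."""
    w = params.fvc_true - params.v_peak
    if params.end_flow_threshold <= 0:
        return 0.0
    ratio = min(params.end_flow_threshold / params.pef_true, 1.0)
    return w * ratio ** (1.0 / params.shape_k)


def _t_end(params: CurveParams) -> float:
    """Maneuver duration: time for the noiseless flow to fall to the
    end-of-test threshold (closed-form descending-limb solution)."""
    w = params.fvc_true - params.v_peak
    k = params.shape_k
    u_end = _u_end(params)
    tp = _t_peak(params)
    if k == 1.0:
        if u_end <= 0:
            raise GenerationError(
                "k=1 limb approaches FVC asymptotically; "
                "end_flow_threshold must be positive"
            )
        return tp + (w / params.pef_true) * math.log(w / u_end)
    # u^(1-k) is linear in t: u(t)^(1-k) = w^(1-k) + (k-1) PEF w^(-k) (t-tp)
    if u_end <= 0:
        if k > 1:
            raise GenerationError(
                "k>1 limb approaches FVC asymptotically; "
                "end_flow_threshold must be positive"
            )
        u_term = 0.0
    else:
        u_term = u_end ** (1.0 - k)
    return tp + (u_term - w ** (1.0 - k)) * w**k / (params.pef_true * (k - 1.0))


def curve_timeline(params: CurveParams, t):
    """Noiseless flow at times ``t`` (s): exact solution of dv/dt = Q(v)."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    v0 = _BOOTSTRAP_FRAC * params.fvc_true
    lam = _rise_rate(params)
    tp = _t_peak(params)
    w = params.fvc_true - params.v_peak
    k = params.shape_k

    flow = np.empty_like(t_arr)
    rising = t_arr < tp
    flow[rising] = lam * v0 * np.exp(lam * t_arr[rising])

    td = t_arr[~rising] - tp
    if k == 1.0:
        u = w * np.exp(-params.pef_true * td / w)
    else:
        base = w ** (1.0 - k) + (k - 1.0) * params.pef_true * (w**-k) * td
        if k < 1.0:
            # limb empties in finite time; clamp past the zero crossing
            base = np.maximum(base, 0.0)
        u = base ** (1.0 / (1.0 - k))
    flow[~rising] = params.pef_true * (u / w) ** k
    return flow if np.asarray(t).ndim else float(flow[0])


def synthesize_curve(
    params: CurveParams, seed=None, blow_id: int = 1
) -> SpiroCurve:
    """Emit one sampled maneuver, deterministic given ``seed``.

    The noiseless flow is the exact time solution of the volume ODE; Gaussian
    flow noise (``noise_sd``) is added per sample; the maneuver is truncated
    where the *noiseless* flow first drops below ``end_flow_threshold``.
    """
    t_end = _t_end(params)
    n = int(math.floor(t_end / params.dt)) + 1
    if n < 2:
        raise GenerationError(
            "maneuver shorter than two samples; decrease dt or the "
            "end-of-test threshold"
        )
    t = np.arange(n) * params.dt
    flow = curve_timeline(params, t)
    if not np.all(np.isfinite(flow)):
        raise GenerationError("non-finite flow during generation")
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        flow = flow + rng.normal(0.0, params.noise_sd, size=flow.shape)
    return SpiroCurve(flow=flow, dt=params.dt, blow_id=blow_id)


# ---------------------------------------------------------------------------
# demographics and cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DemographicsConfig:
    """Sampling distributions for subject covariates.

    Defaults emulate a middle-aged volunteer cohort of the kind spirometry
    biobanks enrol: ages uniform on [40, 70) years, sex-specific normal
    heights, and a never/former/current smoking mix.
    """

    age_range: tuple = (40.0, 70.0)
    height_mean: dict = field(
        default_factory=lambda: {"male": 175.0, "female": 162.0}
    )
    height_sd: dict = field(default_factory=lambda: {"male": 7.0, "female": 6.5})
    female_fraction: float = 0.5
    smoking_probs: dict = field(
        default_factory=lambda: {"never": 0.45, "former": 0.35, "current": 0.20}
    )


def sample_demographics(
    n: int, seed=None, config: DemographicsConfig | None = None
) -> list:
    """Draw ``n`` subjects' demographics, reproducible by ``seed``."""
    if n < 0:
        raise ValueError("n must be non-negative")
    config = config or DemographicsConfig()
    rng = np.random.default_rng(seed)
    out = []
    smoking_levels = list(config.smoking_probs)
    smoking_p = np.array([config.smoking_probs[s] for s in smoking_levels])
    smoking_p = smoking_p / smoking_p.sum()
    for _ in range(n):
        sex = "female" if rng.random() < config.female_fraction else "male"
        age = rng.uniform(*config.age_range)
        height = rng.normal(config.height_mean[sex], config.height_sd[sex])
        height = float(np.clip(height, 120.0, 220.0))
        smoking = smoking_levels[rng.choice(len(smoking_levels), p=smoking_p)]
        out.append(Demographics(age=age, sex=sex, height=height, smoking=smoking))
    return out


@dataclass(frozen=True)
class EffectConfig:
    """Class-conditional curve morphology and disease-effect sizes.

    Controls draw a near-linear descending limb (k around 1) and flow/volume
    close to their demographic expectation; obstructive cases draw a concave
    limb (k well above 1), a depressed peak flow, and a mild FVC reduction —
    jointly depressing FEV1 and the FEV1/FVC ratio, the physiological
    signature of airflow obstruction.
    """

    control_k_range: tuple = (0.8, 1.4)
    case_k_range: tuple = (2.0, 4.0)
    control_z_mean: float = 0.0  # FVC z-score location for controls
    case_z_mean: float = -0.8  # cases run smaller even before shape effects
    z_sd: float = 0.9
    case_pef_scale: float = 0.60  # multiplicative PEF depression in cases
    case_fvc_scale: float = 0.90
    pef_per_fvc: float = 2.0  # baseline PEF (L/s) per litre of FVC
    pef_jitter_sd: float = 0.12  # lognormal-ish multiplicative PEF noise
    min_duration: float = 1.2  # s; PEF is eased down until the maneuver
    # lasts at least this long, so FEV1 is always measurable
    v_peak_frac_range: tuple = (0.07, 0.14)
    noise_sd: float = 0.05  # flow noise, L/s
    blow_fvc_jitter_sd: float = 0.03  # multiplicative between-blow FVC jitter
    n_blows: int = 2
    label_noise: float = 0.0  # fraction of records whose physiology
    # contradicts their diagnosis codes
    dt: float = 0.01

    # diagnosis codes paired with labels (prefix-matchable by the QC stage)
    case_codes: tuple = ("J440", "J449", "J439", "self:1112")
    control_codes: tuple = ((), ("J45",), ())  # mostly empty, some asthma


def _expected_fvc(demo: Demographics) -> float:
    """Crude demographic FVC expectation (L) used when no reference table is
    supplied; height-cubed scaling with a linear age decline."""
    base = 5.2 if demo.sex == "male" else 4.1
    ref_h = 176.0 if demo.sex == "male" else 163.0
    age_term = 1.0 - 0.006 * (demo.age - 50.0)
    return base * (demo.height / ref_h) ** 2.5 * max(age_term, 0.4)


def generate_cohort(
    n: int,
    prevalence: float,
    effect_config: EffectConfig | None = None,
    seed=None,
    demo_config: DemographicsConfig | None = None,
) -> list:
    """Generate ``n`` labelled records with class-dependent morphology.

    Each record carries ``n_blows`` repeated maneuvers whose underlying FVC
    is jittered multiplicatively between blows, synthetic diagnosis codes
    consistent with the label, and (when ``label_noise`` > 0) a controllable
    fraction of records whose curve physiology is drawn from the *other*
    class — emulating diagnosis-code label noise.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    cfg = effect_config or EffectConfig()
    rng = np.random.default_rng(seed)
    demos = sample_demographics(n, seed=rng.integers(2**31), config=demo_config)
    records = []
    for i, demo in enumerate(demos):
        label = int(rng.random() < prevalence)
        phys_label = label
        noisy = cfg.label_noise > 0 and rng.random() < cfg.label_noise
        if noisy:
            phys_label = 1 - label

        if phys_label == 1:
            k = rng.uniform(*cfg.case_k_range)
            z = rng.normal(cfg.case_z_mean, cfg.z_sd)
            fvc_scale, pef_scale = cfg.case_fvc_scale, cfg.case_pef_scale
        else:
            k = rng.uniform(*cfg.control_k_range)
            z = rng.normal(cfg.control_z_mean, cfg.z_sd)
            fvc_scale, pef_scale = 1.0, 1.0

        fvc = _expected_fvc(demo) * math.exp(0.13 * z) * fvc_scale
        pef = cfg.pef_per_fvc * fvc * pef_scale * math.exp(
            rng.normal(0.0, cfg.pef_jitter_sd)
        )
        vpf = rng.uniform(*cfg.v_peak_frac_range)

        # ease PEF down until the maneuver outlasts the FEV1 window
        base = CurveParams(fvc_true=fvc, pef_true=pef, v_peak_frac=vpf,
                           shape_k=k, dt=cfg.dt)
        while _t_end(base) < cfg.min_duration:
            pef *= 0.85
            base = replace(base, pef_true=pef)

        curves = []
        for b in range(cfg.n_blows):
            jitter = math.exp(rng.normal(0.0, cfg.blow_fvc_jitter_sd))
            params = CurveParams(
                fvc_true=fvc * jitter,
                pef_true=pef,
                v_peak_frac=vpf,
                shape_k=k,
                noise_sd=cfg.noise_sd,
                dt=cfg.dt,
            )
            curves.append(
                synthesize_curve(params, seed=rng.integers(2**31), blow_id=b + 1)
            )

        if label == 1:
            codes = [cfg.case_codes[rng.integers(len(cfg.case_codes))]]
        else:
            codes = list(cfg.control_codes[rng.integers(len(cfg.control_codes))])
        records.append(
            Record(
                subject_id=f"S{i:06d}",
                curves=curves,
                demographics=demo,
                diagnosis_codes=codes,
                label=label,
                meta={"shape_k": k, "physiology_label": phys_label},
            )
        )
    return records


def separable_benchmark(
    n: int = 400, seed=None, dt: float = 0.02
) -> list:
    """A cleanly separable two-morphology benchmark cohort.

    Noiseless curves with a convex descending limb (k = 0.8, label 0) or a
    strongly concave one (k = 3, label 1); volumes and peak flows vary with
    demographics as in :func:`generate_cohort`, so the classes differ in
    limb shape rather than in a trivial scalar.  Used to verify that the
    curve encoder can recover morphology-defined labels.
    """
    cfg = EffectConfig(
        control_k_range=(0.8, 0.8),
        case_k_range=(3.0, 3.0),
        case_pef_scale=1.0,
        case_fvc_scale=1.0,
        case_z_mean=0.0,
        noise_sd=0.0,
        blow_fvc_jitter_sd=0.0,
        n_blows=1,
        dt=dt,
    )
    return generate_cohort(n, 0.5, effect_config=cfg, seed=seed)
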