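"""Ground-truth-labeled synthetic SmO2 traces for 3-min all-out tests.

The generator emulates the canonical kinetics of a maximal cycling effort as
seen by a wearable NIRS oximeter: a steady pre-test baseline, rapid
mono-exponential desaturation at effort onset, an end-test level near the
plateau, optional late linear drift that breaks the plateau, additive
Gaussian sensor noise, optional movement-artifact pulses, and exponential
reoxygenation after the effort ends. Samples span the full 4-min record
[-30, 210] s at the device's 2-s interval.

Every trial carries a ground-truth plateau label computed on the noise-free
backbone by running the detector itself with a labeling criterion (default
A5, anchored): this separates the behaviour of the criterion from noise
sensitivity, and guarantees label/detector consistency in the noiseless
limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .detection import PlateauCriterion, detect_plateau
from .io import ManifestRow, write_manifest, write_trial
from .trace import Condition, Muscle, SmO2Trace

#: End-test plateau levels reported for trained athletes, in a.u. of %SmO2.
FEMALE_PLATEAU_RANGE = (20.1, 22.1)
MALE_PLATEAU_RANGE = (10.6, 11.6)
#: Typical resting baseline range, a.u.
BASELINE_RANGE = (60.0, 75.0)

#: Default labeling criterion: anchored +/-5 a.u. over a 30-s window.
DEFAULT_LABEL_CRITERION = PlateauCriterion(mode="absolute", threshold=5.0)

#: Late drift applied to plateau-breaking trials, a.u./s over [135, 180]
#: (a 30-s anchored change of -9 a.u.: outside +/-5, inside +/-10).
DEFAULT_BREAKING_DRIFT = -0.3


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticParams:
    """Generative parameters for one synthetic trial.

    baseline_smo2 and plateau_level are in a.u. of %SmO2; tau_drop and
    reoxy_tau are exponential time constants in seconds; late_drift_slope
    (a.u./s) acts only within the analysis region [135, 180] so that a single
    knob switches a trial between plateau and non-plateau without changing
    the early kinetics; noise_sd is the per-sample Gaussian SD in a.u.;
    artifact_events is a list of (time_s, magnitude_au, duration_s) pulses.
    """

    baseline_smo2: float = 65.0
    plateau_level: float = 15.0
    onset_s: float = 0.0
    tau_drop: float = 15.0
    late_drift_slope: float = 0.0
    noise_sd: float = 1.0
    reoxy_tau: float = 20.0
    artifact_events: tuple[tuple[float, float, float], ...] = ()
    sample_dt: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.plateau_level < self.baseline_smo2 <= 100.0:
            raise SimulationError(
                "need 0 <= plateau_level < baseline_smo2 <= 100"
            )
        if self.tau_drop <= 0 or self.reoxy_tau <= 0:
            raise SimulationError("time constants must be > 0")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        if self.sample_dt <= 0:
            raise SimulationError("sample_dt must be > 0")


@dataclass
class LabeledTrial:
    trace: SmO2Trace
    truth_plateau: bool
    params: SyntheticParams


def backbone(t: np.ndarray, p: SyntheticParams) -> np.ndarray:
    """Noise-free, artifact-free signal model evaluated at times ``t``."""
    t = np.asarray(t, dtype=float)
    v = np.full_like(t, p.baseline_smo2)
    effort = (t >= p.onset_s) & (t <= 180.0)
    te = t[effort]
    v[effort] = (
        p.plateau_level
        + (p.baseline_smo2 - p.plateau_level)
        * np.exp(-(te - p.onset_s) / p.tau_drop)
        + p.late_drift_slope * np.maximum(0.0, te - 135.0)
    )
    post = t > 180.0
    if post.any():
        v180 = (
            p.plateau_level
            + (p.baseline_smo2 - p.plateau_level)
            * np.exp(-(180.0 - p.onset_s) / p.tau_drop)
            + p.late_drift_slope * 45.0
        )
        v[post] = p.baseline_smo2 + (v180 - p.baseline_smo2) * np.exp(
            -(t[post] - 180.0) / p.reoxy_tau
        )
    return v


def truth_label(
    p: SyntheticParams,
    criterion: PlateauCriterion = DEFAULT_LABEL_CRITERION,
) -> bool:
    """Ground-truth plateau label from the noise-free backbone at 1 Hz."""
    grid = np.arange(-30.0, 211.0)
    clean = SmO2Trace(
        subject_id="truth",
        muscle=Muscle.VASTUS_LATERALIS,
        condition=Condition.NORMOXIA,
        times=grid,
        values=np.clip(backbone(grid, p), 0.0, 100.0),
        nominal_dt=1.0,
    )
    return detect_plateau(clean, criterion).detected


def generate_trace(
    params: SyntheticParams,
    subject_id: str = "synthetic",
    muscle: Muscle = Muscle.VASTUS_LATERALIS,
    condition: Condition = Condition.NORMOXIA,
    label_criterion: PlateauCriterion = DEFAULT_LABEL_CRITERION,
    ar1_rho: float = 0.0,
) -> LabeledTrial:
    """Sample one noisy trial over [-30, 210] s with its ground-truth label.

    Noise is independent Gaussian per sample before clipping to [0, 100];
    ``ar1_rho`` > 0 switches to an AR(1) process with the same marginal SD
    for robustness studies. Movement artifacts are added as square pulses.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(240.0 / params.sample_dt)) + 1
    t = -30.0 + params.sample_dt * np.arange(n)
    v = backbone(t, params)
    if params.noise_sd > 0:
        eps = rng.normal(0.0, params.noise_sd, size=len(t))
        if ar1_rho:
            innov = eps * np.sqrt(1.0 - ar1_rho**2)
            innov[0] = eps[0]
            for i in range(1, len(eps)):
                eps[i] = ar1_rho * eps[i - 1] + innov[i]
        v = v + eps
    for start, magnitude, duration in params.artifact_events:
        v = v + magnitude * ((t >= start) & (t < start + duration))
    trace = SmO2Trace(
        subject_id=subject_id,
        muscle=muscle,
        condition=condition,
        times=t,
        values=np.clip(v, 0.0, 100.0),
        nominal_dt=params.sample_dt,
        smoothed=True,
    )
    return LabeledTrial(
        trace=trace,
        truth_plateau=truth_label(params, label_criterion),
        params=params,
    )


@dataclass(frozen=True)
class GroupSpec:
    """Per-group presets for cohort generation."""

    muscle: Muscle
    condition: Condition
    noise_sd: float = 1.0
    breaking_drift: float = DEFAULT_BREAKING_DRIFT


def default_group_specs() -> list[GroupSpec]:
    """The study's 2x2 design: both muscles in normoxia and hypoxia."""
    return [
        GroupSpec(m, c) for c in Condition for m in Muscle
    ]


def _draw_plateau_level(rng: np.random.Generator) -> float:
    # cohort sex mix of trained endurance athletes: 1/3 female, 2/3 male
    lo, hi = (
        FEMALE_PLATEAU_RANGE if rng.random() < 1 / 3 else MALE_PLATEAU_RANGE
    )
    return float(rng.uniform(lo, hi))


def generate_cohort(
    n_per_group: int = 30,
    plateau_fraction: float = 0.9,
    group_specs: list[GroupSpec] | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[LabeledTrial], Path | None]:
    """Reproducible cohort with a requested mix of plateau and drift trials.

    Each group contains floor(n * fraction + 0.5) true-plateau trials (zero
    late drift) and the remainder plateau-breaking drift trials; assignment
    order is shuffled per group. When ``out_dir`` is given, trial CSVs and a
    ``manifest.csv`` consumable by the IO layer are written there.
    """
    if n_per_group <= 0:
        raise SimulationError("n_per_group must be > 0")
    if not 0.0 <= plateau_fraction <= 1.0:
        raise SimulationError("plateau_fraction must be in [0, 1]")
    group_specs = group_specs or default_group_specs()
    root = np.random.default_rng(seed)
    n_true = int(np.floor(n_per_group * plateau_fraction + 0.5))
    trials: list[LabeledTrial] = []
    for spec in group_specs:
        is_plateau = np.zeros(n_per_group, dtype=bool)
        is_plateau[:n_true] = True
        root.shuffle(is_plateau)
        for i in range(n_per_group):
            params = SyntheticParams(
                baseline_smo2=float(root.uniform(*BASELINE_RANGE)),
                plateau_level=_draw_plateau_level(root),
                late_drift_slope=0.0 if is_plateau[i] else spec.breaking_drift,
                noise_sd=spec.noise_sd,
                seed=int(root.integers(0, 2**31 - 1)),
            )
            trials.append(
                generate_trace(
                    params,
                    subject_id=f"S{i + 1:02d}",
                    muscle=spec.muscle,
                    condition=spec.condition,
                )
            )
    manifest_path: Path | None = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for trial in trials:
            tr = trial.trace
            fname = f"{tr.subject_id}_{tr.muscle.value}_{tr.condition.value}.csv"
            write_trial(tr, out_dir / fname)
            rows.append(
                ManifestRow(
                    path=out_dir / fname,
                    subject_id=tr.subject_id,
                    muscle=tr.muscle,
                    condition=tr.condition,
                )
            )
        manifest_path = write_manifest(rows, out_dir / "manifest.csv")
    return trials, manifest_path
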