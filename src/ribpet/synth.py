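"""Seeded synthetic cohort generator.

Produces every input the analysis pipeline consumes — per-animal washout
time-activity series, 3-D dose/activity volumes, longitudinal caliper tables
and grip-strength/spine-activity records — with the statistical structure
the analysis assumes: a Poisson-counted double-exponential washout whose
dose contrast mirrors the in vivo observation (a strong fast component at
low dose that essentially disappears at high dose), separable beam-shaped
volumes, dose-dependent tumour growth with burden-limit censoring, and grip
strength anticorrelated with the fraction of PET counts in the spine.

All randomness flows from ``CohortSpec.seed`` through per-stream
``numpy.random.Generator`` instances, so identical specs give byte-identical
outputs.  The washout truth parameters are modelling choices of this
generator (no published per-animal rate constants exist to copy); they are
recorded in the manifest of every generated cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .beam import BeamConfig, build_sobp, implanted_activity_profile, sobp_pristine_set
from .decay import DecayMixture, TimeActivitySeries, c11_beam_mixture
from .profiles import Volume3D
from .washout import BioWashoutParams, washout_activity

__all__ = [
    "WashoutTruth",
    "CohortSpec",
    "WashoutAnimal",
    "gen_washout_series",
    "gen_volumes",
    "gen_growth",
    "gen_grip",
    "generate_cohort",
]

# stream ids keep the per-stage rngs independent of call order
_STREAM_WASHOUT = 1
_STREAM_VOLUMES = 2
_STREAM_GROWTH = 3
_STREAM_GRIP = 4


@dataclass(frozen=True)
class WashoutTruth:
    """Ground-truth washout parameters for one dose group."""

    a0: float
    ws: float
    ks: float
    kf: float

    def as_params(self) -> BioWashoutParams:
        return BioWashoutParams(
            a0=self.a0, ws=self.ws, ks=self.ks, kf=self.kf, n_components=2
        )


def _default_truths() -> dict[int, WashoutTruth]:
    # Encodes the qualitative dose contrast: at low dose roughly half the
    # activity leaves through a fast perfusion component, at high dose the
    # fast component has essentially disappeared (vascular shutdown).
    return {
        5: WashoutTruth(a0=2.0e4, ws=0.5, ks=8.0e-4, kf=1.2e-2),
        20: WashoutTruth(a0=2.0e4, ws=0.95, ks=8.0e-4, kf=1.2e-2),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic study.

    Group labels are doses in Gy (0 = sham-irradiated control).  Defaults
    mirror the study design this generator emulates: 27 controls, 7 animals
    at 5 Gy and 8 at 20 Gy in the washout arm; 60-s PET frames over the 30
    minutes after the end of irradiation; caliper follow-up twice a week for
    28 days with euthanasia at a 15 mm tumour diameter; biweekly grip tests
    with toxicity read from week 6.
    """

    seed: int = 0
    n_per_group: Mapping[int, int] = field(
        default_factory=lambda: {0: 27, 5: 7, 20: 8}
    )
    washout_truth: Mapping[int, WashoutTruth] = field(default_factory=_default_truths)
    mixture: DecayMixture = field(default_factory=c11_beam_mixture)
    bin_width_s: float = 60.0
    duration_s: float = 1800.0
    rate_jitter_cv: float = 0.2  # per-animal lognormal CV on ks, kf
    noise_model: str = "poisson"  # "poisson" | "gaussian" | "none"
    gaussian_sigma: float = 50.0  # counts, if noise_model == "gaussian"

    # tumour growth
    growth_days: tuple[float, ...] = (0, 4, 7, 11, 14, 18, 21, 25, 28)
    v0_mm3: float = 50.0
    control_growth_rate: float = 0.2  # 1/day
    growth_rate_cv: float = 0.3
    kill_rate: float = 0.12  # 1/day regression after irradiation
    regrowth_day: float = 14.0  # recurrence onset in the low-dose group
    caliper_cv: float = 0.10
    burden_limit_mm: float = 15.0

    # grip / spine activity
    grip_weeks: tuple[int, ...] = tuple(range(1, 26, 2))
    grip_n_control: int = 8
    grip_baseline: float = 130.0  # as-recorded force units
    grip_noise_sd: float = 15.0
    grip_slope: float = 600.0  # force-unit loss per unit spine fraction
    spine_frac_median: float = 0.05
    spine_frac_sigma: float = 0.4  # log-scale sd
    total_counts: float = 1.0e6

    def rng(self, stream: int, *extra: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream, *extra])


@dataclass(frozen=True)
class WashoutAnimal:
    """One synthetic animal's washout measurement and its ground truth."""

    animal_id: str
    group: int
    truth: BioWashoutParams
    series: TimeActivitySeries


def _lognormal_jitter(rng: np.random.Generator, value: float, cv: float) -> float:
    """Mean-preserving multiplicative lognormal jitter with the given CV."""
    if cv <= 0:
        return value
    sigma = np.sqrt(np.log1p(cv**2))
    return float(value * rng.lognormal(-0.5 * sigma**2, sigma))


def _apply_noise(spec: CohortSpec, rng: np.random.Generator, mean: np.ndarray):
    if spec.noise_model == "poisson":
        return rng.poisson(mean).astype(float)
    if spec.noise_model == "gaussian":
        return np.maximum(mean + rng.normal(0.0, spec.gaussian_sigma, mean.shape), 0.0)
    if spec.noise_model == "none":
        return mean.copy()
    raise ValueError(f"unknown noise_model {spec.noise_model!r}")


def gen_washout_series(spec: CohortSpec, group: int) -> list[WashoutAnimal]:
    """Per-animal post-irradiation time-activity series for one dose group.

    Activity is the two-factor washout model evaluated at 60-s bin centres
    over 30 min, with per-animal lognormal jitter (CV
    ``spec.rate_jitter_cv``) on the rate constants and the configured
    counting noise.  Only irradiated groups carry washout data.
    """
    if group not in spec.washout_truth:
        raise ValueError(f"group {group} has no washout truth (not irradiated?)")
    base = spec.washout_truth[group]
    n = spec.n_per_group.get(group)
    if not n or n < 1:
        raise ValueError(f"group {group} has no animals")
    times = np.arange(spec.bin_width_s / 2.0, spec.duration_s, spec.bin_width_s)
    animals = []
    for i in range(n):
        rng = spec.rng(_STREAM_WASHOUT, group, i)
        ks = _lognormal_jitter(rng, base.ks, spec.rate_jitter_cv)
        kf = _lognormal_jitter(rng, base.kf, spec.rate_jitter_cv)
        if ks > kf:  # extreme jitter could cross; keep labels meaningful
            ks, kf = kf, ks
        truth = BioWashoutParams(
            a0=base.a0, ws=base.ws, ks=ks, kf=kf, n_components=2
        )
        mean = washout_activity(truth, spec.mixture, times)
        values = _apply_noise(spec, rng, np.asarray(mean))
        series = TimeActivitySeries(
            times, values, spec.bin_width_s, "end_of_irradiation"
        )
        animals.append(
            WashoutAnimal(f"{group:02d}Gy-{i:03d}", group, truth, series)
        )
    return animals


def gen_volumes(
    spec: CohortSpec,
    config: BeamConfig | None = None,
    modulation_mm: float = 12.0,
    transverse_step_mm: float = 1.0,
    depth_step_mm: float = 0.1,
    noise_counts: float | None = None,
    activity_shift_mm: float = 0.0,
) -> tuple[Volume3D, Volume3D]:
    """Separable 3-D dose and activity volumes for a modulated beam.

    The depth dependence comes from the analytic SOBP and the matching
    implanted-activity profile; the transverse dependence is the elliptical
    Gaussian beam spot.  ``noise_counts`` (peak expected counts) switches on
    Poisson noise in the activity volume; ``activity_shift_mm`` rigidly
    shifts the activity in depth, emulating a range deviation to be detected
    by the profile metrics.

    Returns ``(dose, activity)`` volumes on identical grids, beam along +z.
    """
    cfg = config or BeamConfig()
    r = cfg.range_mm
    grid = np.arange(0.0, 1.3 * r, depth_step_mm)
    pristines = sobp_pristine_set(cfg, modulation_mm, 1.0, grid)
    weights, sobp = build_sobp(pristines, modulation_mm)
    components = [
        (w, r - k * 1.0) for k, w in enumerate(weights) if w > 0
    ]
    act = implanted_activity_profile(cfg, grid, components=components)
    dose_z = sobp.values
    act_z = act.values
    if activity_shift_mm != 0.0:
        shift = int(round(activity_shift_mm / depth_step_mm))
        act_z = np.roll(act_z, shift)
        if shift > 0:
            act_z[:shift] = 0.0
        elif shift < 0:
            act_z[shift:] = 0.0
    sx = cfg.spot_fwhm_x / 2.3548200450309493
    sy = cfg.spot_fwhm_y / 2.3548200450309493
    x = np.arange(-20.0, 20.0 + transverse_step_mm / 2, transverse_step_mm)
    y = np.arange(-15.0, 15.0 + transverse_step_mm / 2, transverse_step_mm)
    gx = np.exp(-0.5 * (x / sx) ** 2)
    gy = np.exp(-0.5 * (y / sy) ** 2)
    dose_vox = gx[:, None, None] * gy[None, :, None] * dose_z[None, None, :]
    act_vox = gx[:, None, None] * gy[None, :, None] * act_z[None, None, :]
    if noise_counts is not None:
        rng = spec.rng(_STREAM_VOLUMES)
        scale = noise_counts / act_vox.max()
        act_vox = rng.poisson(act_vox * scale).astype(float) / scale
    spacing = (transverse_step_mm, transverse_step_mm, depth_step_mm)
    origin = (float(x[0]), float(y[0]), 0.0)
    return (
        Volume3D(dose_vox, spacing, origin),
        Volume3D(act_vox, spacing, origin),
    )


def _true_volume(spec: CohortSpec, group: int, rate: float, day: float) -> float:
    """Noise-free tumour volume trajectory for one animal."""
    if group == 0:
        return spec.v0_mm3 * np.exp(rate * day)
    if group >= 20:
        return spec.v0_mm3 * np.exp(-spec.kill_rate * day)
    # low dose: regression followed by recurrence
    if day <= spec.regrowth_day:
        return spec.v0_mm3 * np.exp(-spec.kill_rate * day)
    v_min = spec.v0_mm3 * np.exp(-spec.kill_rate * spec.regrowth_day)
    return v_min * np.exp(rate * (day - spec.regrowth_day))


def gen_growth(spec: CohortSpec) -> pd.DataFrame:
    """Longitudinal caliper table with burden-limit censoring.

    Controls grow exponentially (per-animal lognormal rate jitter); the
    high-dose group regresses monotonically; the low-dose group regresses
    and then recurs from ``spec.regrowth_day``.  Caliper axes are
    back-computed from the true volume assuming a = b and perturbed with
    multiplicative lognormal noise (CV ``spec.caliper_cv``).  An animal's
    rows stop after the first measurement at or beyond the burden-limit
    diameter (the triggering measurement is kept).
    """
    rows = []
    for group, n in sorted(spec.n_per_group.items()):
        for i in range(n):
            rng = spec.rng(_STREAM_GROWTH, group, i)
            rate = _lognormal_jitter(
                rng, spec.control_growth_rate, spec.growth_rate_cv
            )
            animal = f"{group:02d}Gy-{i:03d}"
            for day in spec.growth_days:
                v = _true_volume(spec, group, rate, day)
                a_true = (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)
                a = _lognormal_jitter(rng, a_true, spec.caliper_cv)
                b = _lognormal_jitter(rng, a_true, spec.caliper_cv)
                rows.append(
                    {
                        "animal_id": animal,
                        "group": group,
                        "day": float(day),
                        "a_mm": a,
                        "b_mm": b,
                    }
                )
                if max(a, b) >= spec.burden_limit_mm:
                    break  # euthanized at burden limit
    return pd.DataFrame(rows)


def gen_grip(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Grip-strength table and spine-activity records.

    Each irradiated animal draws a lognormal spine-count fraction; its grip
    strength at every biweekly timepoint is the shared baseline minus
    ``grip_slope`` times that fraction, plus Gaussian noise.  Controls share
    the baseline without a deficit and carry no spine record (they are not
    PET-imaged).  Returns ``(grip, spine)`` tables.
    """
    grip_rows = []
    spine_rows = []
    log_med = np.log(spec.spine_frac_median)
    irradiated = [g for g in sorted(spec.n_per_group) if g > 0]
    for group in irradiated:
        for i in range(spec.n_per_group[group]):
            rng = spec.rng(_STREAM_GRIP, group, i)
            animal = f"{group:02d}Gy-{i:03d}"
            frac = float(
                np.clip(rng.lognormal(log_med, spec.spine_frac_sigma), 0.0, 1.0)
            )
            total = float(rng.poisson(spec.total_counts))
            spine = min(float(rng.poisson(frac * total)), total)
            spine_rows.append(
                {
                    "animal_id": animal,
                    "spine_counts": spine,
                    "total_counts": total,
                }
            )
            mean = spec.grip_baseline - spec.grip_slope * frac
            for week in spec.grip_weeks:
                force = max(mean + rng.normal(0.0, spec.grip_noise_sd), 0.0)
                grip_rows.append(
                    {
                        "animal_id": animal,
                        "group": f"irradiated({group})",
                        "week": int(week),
                        "peak_force": force,
                    }
                )
    for i in range(spec.grip_n_control):
        rng = spec.rng(_STREAM_GRIP, 0, i)
        animal = f"ctrl-{i:03d}"
        for week in spec.grip_weeks:
            force = max(
                spec.grip_baseline + rng.normal(0.0, spec.grip_noise_sd), 0.0
            )
            grip_rows.append(
                {
                    "animal_id": animal,
                    "group": "control",
                    "week": int(week),
                    "peak_force": force,
                }
            )
    return pd.DataFrame(grip_rows), pd.DataFrame(spine_rows)


def generate_cohort(spec: CohortSpec) -> dict:
    """Generate every pipeline input plus a ground-truth manifest.

    Returns a dict with keys ``washout`` (group -> list of
    :class:`WashoutAnimal`), ``growth``, ``grip``, ``spine`` (DataFrames),
    ``volumes`` (dose/activity :class:`~ribpet.profiles.Volume3D` pair) and
    ``manifest`` (the spec and per-animal truths, JSON-serialisable).
    """
    washout = {g: gen_washout_series(spec, g) for g in spec.washout_truth}
    growth = gen_growth(spec)
    grip, spine = gen_grip(spec)
    dose_vol, act_vol = gen_volumes(spec)
    manifest = {
        "seed": spec.seed,
        "n_per_group": {str(k): v for k, v in spec.n_per_group.items()},
        "washout_truth": {
            str(g): asdict(t) for g, t in spec.washout_truth.items()
        },
        "washout_truth_per_animal": {
            a.animal_id: {
                "a0": a.truth.a0,
                "ws": a.truth.ws,
                "ks": a.truth.ks,
                "kf": a.truth.kf,
            }
            for animals in washout.values()
            for a in animals
        },
        "noise_model": spec.noise_model,
    }
    return {
        "washout": washout,
        "growth": growth,
        "grip": grip,
        "spine": spine,
        "volumes": (dose_vol, act_vol),
        "manifest": manifest,
    }
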