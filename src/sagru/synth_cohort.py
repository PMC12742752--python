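"""Seeded simulator of hospitalized-cohort CGM traces.

Emulates the statistical shape of an inpatient type-2-diabetes CGM study:
15-minute cadence (96 readings/day), stays of 4-14 days, a fixed hospital
meal schedule (07:00, 11:30, 17:30), and occasional nocturnal hypoglycemic
dips. Per patient the trace is::

    glucose(t) = baseline + circadian sinusoid
               + sum of post-meal excursions (30-min linear rise, then
                 exponential decay)
               + AR(1) noise

with nocturnal hypoglycemic episodes (random nights, 00:00-04:00) applied
as a smooth pull toward a sub-70 mg/dL nadir, so an episode always reaches
the hypoglycemic range at its peak regardless of the patient's baseline,

clipped to the sensor range [39.6, 500.4] mg/dL. The AR(1) noise (rather
than white noise) gives the series the short-range smoothness of real CGM
data, so that short-horizon forecasting is non-trivially learnable. With
every stochastic amplitude set to zero the trace is a deterministic
function of (last observed glucose, clock time), which gives the training
loop an exactly learnable sanity target.

Everything is a pure function of the parameter set, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from datetime import datetime, timedelta

import numpy as np

from sagru.cgm_data import Cohort, GlucoseReading, PatientSeries
from sagru.events import adverse_from_glucose

READINGS_PER_DAY = 96  # 24 h at a 15-min cadence


@dataclass(frozen=True)
class SyntheticCohortParams:
    """Generative settings for the simulator.

    Amplitudes are mg/dL. ``meal_amplitude_mean``/``sd`` control the peak
    height of post-meal excursions (drawn per patient and meal);
    ``meal_rise_minutes`` the linear rise time and ``meal_decay_minutes``
    the exponential decay constant after the peak. ``ar1_rho`` is the
    lag-1 autocorrelation of the stationary AR(1) noise whose marginal SD
    is ``noise_sd``. ``nocturnal_hypo_rate`` is the per-night probability
    of a hypoglycemic episode between 00:00 and 04:00; an episode pulls the
    glucose toward a nadir drawn around ``hypo_nadir`` (< 70 mg/dL) with a
    Gaussian time profile of width ``hypo_width_minutes``.
    """

    n_patients: int = 40
    stay_days: tuple[int, int] = (4, 14)
    cadence_minutes: int = 15
    baseline_mean: float = 145.0
    baseline_sd: float = 25.0
    circadian_amplitude: float = 10.0
    meal_times: tuple[str, ...] = ("07:00", "11:30", "17:30")
    meal_amplitude_mean: float = 60.0
    meal_amplitude_sd: float = 15.0
    meal_rise_minutes: float = 30.0
    meal_decay_minutes: float = 90.0
    ar1_rho: float = 0.9
    noise_sd: float = 5.0
    nocturnal_hypo_rate: float = 0.15
    hypo_nadir: float = 58.0
    hypo_nadir_sd: float = 4.0
    hypo_width_minutes: float = 45.0
    clip_bounds: tuple[float, float] = (39.6, 500.4)
    start_date: str = "2023-04-01"
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (1 <= self.stay_days[0] <= self.stay_days[1]):
            raise ValueError(f"invalid stay_days range {self.stay_days}")
        if not (0.0 <= self.ar1_rho < 1.0):
            raise ValueError("ar1_rho must be in [0, 1)")
        if not (0.0 <= self.nocturnal_hypo_rate <= 1.0):
            raise ValueError("nocturnal_hypo_rate must be a probability")
        if self.clip_bounds[0] >= self.clip_bounds[1]:
            raise ValueError("clip_bounds must be increasing")

    def noiseless(self) -> "SyntheticCohortParams":
        """The deterministic configuration: no noise, no random episode,
        and shared meal amplitudes, so the future is an exact function of
        the observed history and the clock."""
        return replace(
            self, noise_sd=0.0, nocturnal_hypo_rate=0.0, meal_amplitude_sd=0.0
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stay_days"] = list(self.stay_days)
        d["meal_times"] = list(self.meal_times)
        d["clip_bounds"] = list(self.clip_bounds)
        return d


def _meal_kernel(minutes_since: np.ndarray, rise: float, decay: float) -> np.ndarray:
    """Unit-peak excursion: linear rise over ``rise`` min, then exp decay."""
    k = np.zeros_like(minutes_since, dtype=float)
    up = (minutes_since >= 0) & (minutes_since < rise)
    k[up] = minutes_since[up] / rise
    down = minutes_since >= rise
    k[down] = np.exp(-(minutes_since[down] - rise) / decay)
    return k


def simulate_patient(params: SyntheticCohortParams, patient_seed,
                     patient_id: str = "P0", stay_days: int | None = None) -> PatientSeries:
    """Simulate one patient's trace; deterministic given (params, seed).

    ``patient_seed`` may be an int or a ``np.random.SeedSequence``.
    """
    ss = patient_seed if isinstance(patient_seed, np.random.SeedSequence) \
        else np.random.SeedSequence(patient_seed)
    # independent streams so that e.g. raising the hypo rate cannot
    # perturb the baseline/meal/noise draws
    s_traits, s_noise, s_hypo = ss.spawn(3)
    rng_traits = np.random.default_rng(s_traits)
    rng_noise = np.random.default_rng(s_noise)
    rng_hypo = np.random.default_rng(s_hypo)

    if stay_days is None:
        stay_days = int(rng_traits.integers(params.stay_days[0], params.stay_days[1] + 1))
    n = stay_days * READINGS_PER_DAY
    cad = params.cadence_minutes
    t_min = np.arange(n) * cad  # minutes since admission (midnight start)
    hour_of_day = (t_min / 60.0) % 24.0

    baseline = params.baseline_mean + params.baseline_sd * rng_traits.standard_normal()
    # late-morning circadian peak; phase fixed across patients
    circadian = params.circadian_amplitude * np.sin(2 * np.pi * (hour_of_day - 4.0) / 24.0)

    meal_hours = [
        int(h) + int(m) / 60.0 for h, m in (mt.split(":") for mt in params.meal_times)
    ]
    meals = np.zeros(n)
    for mh in meal_hours:
        amp = params.meal_amplitude_mean + params.meal_amplitude_sd * rng_traits.standard_normal()
        amp = max(amp, 0.0)
        for day in range(stay_days):
            since = t_min - (day * 24.0 + mh) * 60.0
            meals += amp * _meal_kernel(since, params.meal_rise_minutes, params.meal_decay_minutes)

    if params.noise_sd > 0:
        innov_sd = params.noise_sd * np.sqrt(1.0 - params.ar1_rho**2)
        eps = rng_noise.standard_normal(n)
        noise = np.empty(n)
        noise[0] = params.noise_sd * eps[0]
        for i in range(1, n):
            noise[i] = params.ar1_rho * noise[i - 1] + innov_sd * eps[i]
    else:
        noise = np.zeros(n)

    glucose = baseline + circadian + meals + noise

    # nocturnal episodes: uniforms drawn for every night regardless of the
    # rate, so raising nocturnal_hypo_rate at a fixed seed only adds
    # episodes and never reshuffles the other draws
    night_u = rng_hypo.uniform(size=stay_days)
    night_center = rng_hypo.uniform(0.0, 4.0, size=stay_days)  # 00:00-04:00
    night_nadir = params.hypo_nadir + params.hypo_nadir_sd * rng_hypo.standard_normal(stay_days)
    for day in range(stay_days):
        if night_u[day] < params.nocturnal_hypo_rate:
            center = (day * 24.0 + night_center[day]) * 60.0
            w = params.hypo_width_minutes
            pull = np.exp(-0.5 * ((t_min - center) / w) ** 2)
            glucose = glucose + (night_nadir[day] - glucose) * pull

    glucose = np.clip(glucose, *params.clip_bounds)

    start = datetime.fromisoformat(params.start_date)
    readings = [
        GlucoseReading(start + timedelta(minutes=int(m)), float(g))
        for m, g in zip(t_min, glucose)
    ]
    return PatientSeries(patient_id, readings, cadence_minutes=cad)


def simulate_cohort(params: SyntheticCohortParams, name: str = "synthetic") -> Cohort:
    """Simulate a cohort; per-patient seeds spawn from the master seed."""
    root = np.random.SeedSequence(params.seed)
    seeds = root.spawn(params.n_patients)
    patients = [
        simulate_patient(params, seeds[i], patient_id=f"P{i:04d}")
        for i in range(params.n_patients)
    ]
    return Cohort(patients, name=name)


def event_prevalence(cohort: Cohort) -> float:
    """Fraction of all readings that are adverse (hypo- or hyperglycemic)."""
    total = cohort.total_readings()
    if total == 0:
        raise ValueError("empty cohort")
    adverse = sum(int(np.sum(adverse_from_glucose(p.glucose_values))) for p in cohort)
    return adverse / total
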