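"""Synthetic-data generators for every pipeline input.

Each generator has known ground truth so downstream estimators can be
checked against what was injected:

* :func:`simulate_cohort` — expression linear in age per gene plus a
  subject-specific aging offset ``delta_i`` (applied as ``a_G * delta_i`` on
  every gene) and i.i.d. Gaussian noise.  The offsets are mean-centered and
  decorrelated from CA so the clock's residual-ratio estimate recovers them
  exactly in the noiseless limit.
* :func:`simulate_rr` — beat times from an integral pulse frequency
  modulation (IPFM) model: a beat fires each time the running integral of
  ``(1 + m(t)) / T`` crosses an integer, with a sinusoidal LF+HF modulating
  signal ``m(t)`` and optional premature (ectopic) beats.
* :func:`simulate_actigraphy` — epoch-level wrist acceleration (milli-g)
  drawn from a named intensity law, with a wear mask.
* :func:`simulate_intervention` — paired pre/post values with a known
  location shift.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clock import ExpressionMatrix

__all__ = [
    "CohortSimSpec",
    "RRSimSpec",
    "ActigraphySimSpec",
    "simulate_cohort",
    "simulate_rr",
    "simulate_actigraphy",
    "simulate_intervention",
]

SECONDS_PER_DAY = 86_400


@dataclass
class CohortSimSpec:
    """Study-cohort generator settings.

    ``genes`` maps gene name to ``(intercept b_G, slope a_G per year,
    noise_sd)`` in expression units; ``offset_sd`` (years) is the SD of the
    per-subject true aging offset ``delta_i``.
    """

    n_subjects: int = 60
    age_range: tuple[float, float] = (20.0, 100.0)
    genes: list[tuple[str, float, float, float]] = field(
        default_factory=lambda: [
            # name, intercept, slope (expr units / year), noise_sd — gently
            # declining expression with age, qPCR-positive over the age range
            ("ABLIM1", 1.20, -0.008, 0.05),
            ("CCR7", 1.50, -0.010, 0.06),
            ("LEF1", 1.35, -0.009, 0.05),
        ]
    )
    offset_sd: float = 8.0
    center_offsets: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy min < max")
        if self.offset_sd < 0:
            raise ValueError("offset_sd must be >= 0")
        for name, _b, _a, sd in self.genes:
            if sd < 0:
                raise ValueError(f"gene {name!r}: noise_sd must be >= 0")


def simulate_cohort(spec: CohortSimSpec) -> tuple[ExpressionMatrix, pd.Series]:
    """Draw a cohort; returns the expression matrix and the true offsets.

    CA is uniform on ``age_range``; ``delta_i ~ Normal(0, offset_sd)`` then
    (by default) mean-centered and orthogonalized against CA by regression,
    with the SD restored, so that the OLS projection inside the clock leaves
    them intact.  Expression of gene G for subject i is
    ``b_G + a_G * (CA_i + delta_i) + Normal(0, noise_sd)``.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = pd.Index([f"S{i:03d}" for i in range(spec.n_subjects)],
                        name="subject_id")
    ca = rng.uniform(*spec.age_range, size=spec.n_subjects)
    delta = rng.normal(0.0, spec.offset_sd, size=spec.n_subjects)
    if spec.center_offsets and spec.offset_sd > 0 and spec.n_subjects > 2:
        # residualize on CA, then rescale back to the requested SD
        slope, intercept = np.polyfit(ca, delta, 1)
        delta = delta - (intercept + slope * ca)
        sd = delta.std()
        if sd > 0:
            delta *= spec.offset_sd / sd

    cols = {}
    for name, b, a, noise_sd in spec.genes:
        eps = rng.normal(0.0, noise_sd, size=spec.n_subjects) if noise_sd > 0 \
            else np.zeros(spec.n_subjects)
        cols[name] = b + a * (ca + delta) + eps
    values = pd.DataFrame(cols, index=subjects)
    kind = "qpcr" if (values > 0).all().all() else "transcriptomic"
    expr = ExpressionMatrix(values=values, ca=pd.Series(ca, index=subjects,
                                                        name="ca"),
                            source_kind=kind)
    return expr, pd.Series(delta, index=subjects, name="true_offset")


@dataclass
class RRSimSpec:
    """IPFM heart-beat generator settings.

    ``lf`` and ``hf`` are ``(frequency Hz, fractional modulation amplitude)``
    pairs inside the standard low/high HRV bands; ``mean_rr`` is the mean
    beat interval (ms).  ``ectopic_rate`` is the per-beat probability of a
    premature beat, produced by advancing a beat by ``ectopic_advance`` of
    its local interval.
    """

    duration: float = 300.0
    mean_rr: float = 1000.0
    lf: tuple[float, float] = (0.1, 0.0)
    hf: tuple[float, float] = (0.25, 0.0)
    ectopic_rate: float = 0.0
    ectopic_advance: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if not 0.04 <= self.lf[0] <= 0.15:
            raise ValueError("LF frequency must lie in [0.04, 0.15] Hz")
        if not 0.15 <= self.hf[0] <= 0.4:
            raise ValueError("HF frequency must lie in [0.15, 0.4] Hz")
        for amp in (self.lf[1], self.hf[1]):
            if not 0 <= amp < 0.5:
                raise ValueError("modulation amplitudes must lie in [0, 0.5)")
        if self.lf[1] + self.hf[1] >= 1.0:
            raise ValueError("combined modulation would make 1 + m(t) <= 0")
        if not 0 <= self.ectopic_rate < 1:
            raise ValueError("ectopic_rate must lie in [0, 1)")


def _ipfm_beat_times(spec: RRSimSpec) -> np.ndarray:
    """Integrate (1+m(t))/T on a 1 ms grid; beats at integer crossings."""
    dt = 0.001
    T = spec.mean_rr / 1000.0
    # pad past the nominal duration so a crossing at exactly t=duration is
    # resolved despite floating-point roundoff; trimmed below
    t = np.arange(0.0, spec.duration + 2 * T + dt, dt)
    m = (spec.lf[1] * np.sin(2 * np.pi * spec.lf[0] * t)
         + spec.hf[1] * np.sin(2 * np.pi * spec.hf[0] * t))
    rate = (1.0 + m) / T
    # cumulative integral by trapezoid on the grid
    integral = np.concatenate(
        ([0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * dt))
    )
    n_beats = int(np.floor(integral[-1]))
    beats = np.empty(n_beats)
    idx = np.searchsorted(integral, np.arange(1, n_beats + 1))
    for k, j in enumerate(idx):
        # linear interpolation of the integer crossing between grid points
        f0, f1 = integral[j - 1], integral[j]
        beats[k] = t[j - 1] + dt * (k + 1 - f0) / (f1 - f0)
    return beats[beats <= spec.duration + 1e-9]


def simulate_rr(spec: RRSimSpec):
    """Generate an RR-interval series from the IPFM model.

    Returns an :class:`~gamclock.hrv.RRSeries` whose ``ectopic_flags`` mark
    the beats that were artificially advanced.
    """
    from .hrv import RRSeries  # local import to avoid a cycle

    # the oscillator starts with a beat at t=0, then one per integer crossing
    beats = np.concatenate(([0.0], _ipfm_beat_times(spec)))
    flags = np.zeros(len(beats), dtype=bool)
    if spec.ectopic_rate > 0 and len(beats) > 2:
        rng = np.random.default_rng(spec.seed)
        hit = rng.random(len(beats) - 2) < spec.ectopic_rate
        for i in np.flatnonzero(hit) + 1:  # never the first or last beat
            local = beats[i] - beats[i - 1]
            beats[i] -= spec.ectopic_advance * local
            flags[i] = True
        beats = np.sort(beats)
    rr = np.diff(beats) * 1000.0
    return RRSeries(rr=rr, beat_times=beats[1:], ectopic_flags=flags[1:])


#: Supported actigraphy intensity laws and their required parameters.
INTENSITY_LAWS = {
    "constant": ("value_mg",),
    "gamma": ("mean_mg", "shape"),
    "lognormal": ("median_mg", "sigma"),
    "active_blocks": ("baseline_mg", "blocks"),
}


@dataclass
class ActigraphySimSpec:
    """Epoch-level acceleration generator settings.

    ``intensity_law`` names a distribution from :data:`INTENSITY_LAWS` with
    parameters in ``law_params``.  ``wear_fraction`` of each day is flagged
    worn; the non-worn remainder is a contiguous block at the start of the
    day (emulating device-off overnight).
    """

    n_days: int = 7
    epoch_s: int = 5
    intensity_law: str = "gamma"
    law_params: dict = field(default_factory=lambda: {"mean_mg": 30.0,
                                                      "shape": 1.5})
    wear_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if 60 % self.epoch_s != 0:
            raise ValueError("epoch_s must divide 60")
        if not 0 < self.wear_fraction <= 1:
            raise ValueError("wear_fraction must lie in (0, 1]")
        if self.intensity_law not in INTENSITY_LAWS:
            raise ValueError(
                f"unknown intensity_law {self.intensity_law!r}; choose from "
                f"{sorted(INTENSITY_LAWS)}"
            )


def _draw_day(spec: ActigraphySimSpec, rng: np.random.Generator,
              n_epochs: int) -> np.ndarray:
    p = spec.law_params
    if spec.intensity_law == "constant":
        return np.full(n_epochs, float(p["value_mg"]))
    if spec.intensity_law == "gamma":
        shape = float(p["shape"])
        scale = float(p["mean_mg"]) / shape
        return rng.gamma(shape, scale, size=n_epochs)
    if spec.intensity_law == "lognormal":
        return rng.lognormal(np.log(float(p["median_mg"])), float(p["sigma"]),
                             size=n_epochs)
    # active_blocks: a flat baseline plus blocks of (minutes, mg) activity
    # placed back to back from noon; explicit MX ground truth.
    values = np.full(n_epochs, float(p["baseline_mg"]))
    per_min = 60 // spec.epoch_s
    pos = n_epochs // 2
    for minutes, mg in p["blocks"]:
        n = int(minutes) * per_min
        values[pos:pos + n] = float(mg)
        pos += n
    return values


def simulate_actigraphy(spec: ActigraphySimSpec):
    """Generate a multi-day epoch series with wear flags."""
    from .actigraphy import EpochSeries  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    per_day = SECONDS_PER_DAY // spec.epoch_s
    n_nonwear = int(round((1 - spec.wear_fraction) * per_day))
    values, wear = [], []
    for _day in range(spec.n_days):
        v = _draw_day(spec, rng, per_day)
        w = np.ones(per_day, dtype=bool)
        w[:n_nonwear] = False
        values.append(v)
        wear.append(w)
    t = np.arange(spec.n_days * per_day, dtype=float) * spec.epoch_s
    return EpochSeries(timestamp=t, value=np.concatenate(values),
                       wear=np.concatenate(wear), epoch_s=spec.epoch_s)


def simulate_intervention(
    n: int,
    shift: float,
    noise_sd: float,
    seed: int = 0,
    baseline_mean: float = 100.0,
    baseline_sd: float = 15.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Paired pre/post values with a known location shift.

    ``post_i = pre_i + shift + Normal(0, noise_sd)``.  Returns
    ``(pre, post, shift)`` so tests can compare the estimated effect to the
    injected ground truth.
    """
    if n < 5:
        raise ValueError("need at least 5 pairs")
    rng = np.random.default_rng(seed)
    pre = rng.normal(baseline_mean, baseline_sd, size=n)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
    post = pre + shift + noise
    return pre, post, float(shift)
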