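"""Synthetic crossover-study generator for PWT time courses.

Emulates the study design the analysis assumes: each animal receives all
five stimulation patterns (one tonic, four time-dynamic) in a randomized
session order; behavioral thresholds are read on a 15-min grid spanning a
60- or 90-min stimulation-on period plus 30 min post-stimulation.  The
forward model inverts the analysis' normalization,

    PWT(t) = baseline + max_reversal * f_unit(t) + noise,

where ``f_unit`` is the unit-scale (I = 1) double sigmoid for that
pattern's kinetics, noise is additive Gaussian on grams, and the result is
optionally snapped to a discrete von Frey filament series with a 15 g
ceiling.  Ground-truth parameters are retained per time course so
downstream recovery can be tested exactly.

Default kinetics encode the study's directional findings — tonic has the
fastest wash-in, the steepest wash-out, and the smallest normalized FWHM,
with its half-decay falling inside a 90-min stimulation window (so
prolonged tonic stimulation loses efficacy while the dynamic patterns
hold).  The exact numbers are configuration, not claims about real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .fitting import DT_MIN, PATTERNS, TimeCourse
from .io import timecourses_to_frame
from .model import SigmoidParams, double_sigmoid

__all__ = [
    "DEFAULT_FILAMENTS",
    "PatternKinetics",
    "DEFAULT_KINETICS",
    "SimulationConfig",
    "StudyDataset",
    "grid_for_cohort",
    "simulate_timecourse",
    "simulate_study",
]

#: Ascending von Frey filament forces in grams, 15 g ceiling.  The study's
#: own series is not published; this is a standard rat hind-paw set.
DEFAULT_FILAMENTS = (0.4, 0.6, 1.0, 1.4, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0)

#: Stimulation-on duration (min) per cohort; observations run 30 min longer.
T_STIM_BY_COHORT = {1: 60.0, 2: 90.0}


@dataclass(frozen=True)
class PatternKinetics:
    """Generative kinetics for one stimulation pattern.

    Midpoints are expressed as fractions of the stimulation duration so a
    single setting serves both cohort designs: ``t_mid1 = t_mid1_frac *
    T_stim`` and ``t_mid2 = t_mid1 + fwhm_frac * T_stim``.
    """

    a1: float
    a2: float
    t_mid1_frac: float
    fwhm_frac: float
    max_reversal_g: float

    def params(self, t_stim: float) -> SigmoidParams:
        t_mid1 = self.t_mid1_frac * t_stim
        return SigmoidParams(I=1.0, a1=self.a1, a2=self.a2,
                             t_mid1=t_mid1,
                             t_mid2=t_mid1 + self.fwhm_frac * t_stim)


#: Tonic: fast wash-in, steep early wash-out (half-decay inside a 90-min
#: stimulation window).  Dynamic patterns: slower wash-in, shallower
#: wash-out, half-decay beyond the stimulation window.  Steepness values
#: are kept gentle enough that both transitions span at least two 15-min
#: sampling intervals — on this grid a much steeper transition would fall
#: between observations and leave the fitted steepness (hence the slopes)
#: unidentified.
DEFAULT_KINETICS: dict[str, PatternKinetics] = {
    "tonic": PatternKinetics(a1=0.40, a2=-0.40, t_mid1_frac=0.22,
                             fwhm_frac=0.65, max_reversal_g=5.5),
    "amplitude": PatternKinetics(a1=0.13, a2=-0.24, t_mid1_frac=0.28,
                                 fwhm_frac=0.92, max_reversal_g=4.0),
    "pulse_width": PatternKinetics(a1=0.14, a2=-0.22, t_mid1_frac=0.30,
                                   fwhm_frac=0.93, max_reversal_g=4.4),
    "rate": PatternKinetics(a1=0.20, a2=-0.26, t_mid1_frac=0.25,
                            fwhm_frac=0.94, max_reversal_g=4.6),
    "stochastic": PatternKinetics(a1=0.14, a2=-0.28, t_mid1_frac=0.27,
                                  fwhm_frac=0.90, max_reversal_g=4.2),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of a synthetic crossover study.

    ``n_cohort1`` animals follow the 60-min design (7 observations),
    ``n_cohort2`` the 90-min design (9 observations); the study's own mix
    is 8 + 15.  Baselines are drawn per animal from a normal distribution
    truncated above 1 g; measurement noise is additive Gaussian on grams
    before optional quantization to the filament series.  Quantization is
    off by default: staircase threshold estimation yields continuous
    values, so the continuous readout is the closer emulation of reported
    thresholds; enable it to emulate a raw single-filament readout.
    """

    n_cohort1: int = 8
    n_cohort2: int = 15
    baseline_mean: float = 6.0
    baseline_sd: float = 0.8
    noise_sd: float = 1.0
    quantize: bool = False
    filament_set: tuple[float, ...] = DEFAULT_FILAMENTS
    kinetics: dict[str, PatternKinetics] = field(
        default_factory=lambda: dict(DEFAULT_KINETICS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cohort1 < 0 or self.n_cohort2 < 0:
            raise InvalidInputError("cohort sizes must be non-negative")
        if self.n_cohort1 + self.n_cohort2 < 1:
            raise InvalidInputError("need at least one animal")
        if self.baseline_mean <= 0:
            raise InvalidInputError("baseline_mean must be > 0 g")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        fil = np.asarray(self.filament_set, float)
        if fil.ndim != 1 or fil.size < 2 or np.any(np.diff(fil) <= 0):
            raise InvalidInputError("filament_set must be strictly increasing")
        missing = set(PATTERNS) - set(self.kinetics)
        if missing:
            raise InvalidInputError(f"kinetics missing patterns: {sorted(missing)}")

    @property
    def n_animals(self) -> int:
        return self.n_cohort1 + self.n_cohort2


@dataclass(frozen=True)
class StudyDataset:
    """Simulated study: time courses, session orders, and ground truth.

    ``truth`` maps (animal_id, pattern) to the generative parameters on
    the normalized scale — i.e. with ``I = max_reversal / baseline`` — so
    fitted parameters can be compared directly.
    """

    timecourses: tuple[TimeCourse, ...]
    session_orders: dict[str, tuple[str, ...]]
    truth: dict[tuple[str, str], SigmoidParams]

    def to_frame(self) -> pd.DataFrame:
        return timecourses_to_frame(self.timecourses)

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            (animal, pattern, p.I, p.a1, p.a2, p.t_mid1, p.t_mid2)
            for (animal, pattern), p in sorted(self.truth.items())
        ]
        return pd.DataFrame(rows, columns=[
            "animal_id", "pattern", "I", "a1", "a2", "t_mid1", "t_mid2"])


def grid_for_cohort(cohort: int) -> np.ndarray:
    """15-min observation grid for a cohort: 0 .. T_stim + 30 inclusive."""
    if cohort not in T_STIM_BY_COHORT:
        raise InvalidInputError(f"cohort must be 1 or 2, got {cohort}")
    t_stim = T_STIM_BY_COHORT[cohort]
    return np.arange(0.0, t_stim + 30.0 + 0.5 * DT_MIN, DT_MIN)


def _quantize(pwt: np.ndarray, filaments) -> np.ndarray:
    """Snap each value to the nearest filament force; top filament is a ceiling."""
    fil = np.asarray(filaments, float)
    idx = np.argmin(np.abs(pwt[:, None] - fil[None, :]), axis=1)
    return fil[idx]


def simulate_timecourse(
    p: SigmoidParams,
    baseline: float,
    max_reversal: float,
    grid: np.ndarray,
    noise_sd: float,
    quantize: bool,
    filament_set,
    rng: np.random.Generator,
    *,
    animal_id: str = "sim",
    pattern: str = "tonic",
    cohort: int = 1,
    t_stim_min: float | None = None,
) -> TimeCourse:
    """Forward-simulate one PWT series from unit-scale kinetics.

    ``p`` is evaluated with its own scaling replaced by 1, so the
    normalized expectation of the output is ``(max_reversal / baseline) *
    f_unit(t)``.
    """
    grid = np.asarray(grid, float)
    if grid.ndim != 1 or grid.size == 0 or grid[0] != 0.0:
        raise InvalidInputError("grid must be 1-D and start at t = 0")
    if baseline <= 0:
        raise InvalidInputError("baseline must be > 0 g")
    unit = replace(p, I=1.0)
    pwt = baseline + max_reversal * double_sigmoid(grid, unit)
    if noise_sd > 0:
        pwt = pwt + rng.normal(0.0, noise_sd, size=grid.size)
    if quantize:
        pwt = _quantize(pwt, filament_set)
    else:
        # behavioral thresholds cannot be <= 0; clip at the lightest filament
        pwt = np.maximum(pwt, float(np.asarray(filament_set, float)[0]))
    if t_stim_min is None:
        t_stim_min = T_STIM_BY_COHORT.get(cohort, grid[-1] - 30.0)
    return TimeCourse(animal_id=animal_id, pattern=pattern, cohort=cohort,
                      t_stim_min=float(t_stim_min), times=grid, pwt=pwt)


def simulate_study(cfg: SimulationConfig) -> StudyDataset:
    """Simulate a full randomized crossover study.

    Each animal owns an independent random stream spawned from the master
    seed, so adding animals never perturbs the data of existing ones.
    The per-animal stream draws its truncated-normal baseline, its session
    order (a uniform random permutation of the five patterns), and the
    measurement noise of its five sessions.
    """
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_animals)

    timecourses: list[TimeCourse] = []
    session_orders: dict[str, tuple[str, ...]] = {}
    truth: dict[tuple[str, str], SigmoidParams] = {}

    for idx, child in enumerate(children):
        rng = np.random.default_rng(child)
        cohort = 1 if idx < cfg.n_cohort1 else 2
        animal_id = f"rat{idx + 1:02d}"
        t_stim = T_STIM_BY_COHORT[cohort]
        grid = grid_for_cohort(cohort)

        baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd)
        while baseline <= 1.0:
            baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd)

        order = tuple(rng.permutation(PATTERNS))
        session_orders[animal_id] = order

        for pattern in order:
            kin = cfg.kinetics[pattern]
            p_unit = kin.params(t_stim)
            tc = simulate_timecourse(
                p_unit, baseline, kin.max_reversal_g, grid,
                cfg.noise_sd, cfg.quantize, cfg.filament_set, rng,
                animal_id=animal_id, pattern=pattern, cohort=cohort,
                t_stim_min=t_stim,
            )
            timecourses.append(tc)
            truth[(animal_id, pattern)] = replace(
                p_unit, I=kin.max_reversal_g / baseline)

    return StudyDataset(timecourses=tuple(timecourses),
                        session_orders=session_orders, truth=truth)
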