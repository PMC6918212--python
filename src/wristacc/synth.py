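"""Synthetic wrist-accelerometer streams and cohort tables with known truth.

Every stage of the processing and validation pipeline is exercised against
data whose ground truth is known by construction: tri-axial 50 Hz streams
containing a unit-gravity component, white sensor noise and sinusoidal
activity bouts of chosen amplitude and duration; and cohort tables whose
between-/within-subject variances (hence true ICC), treatment effects per
change stratum, GRCS anchors and missingness rates are all planted.

The signal chain (linear filters, full-wave rectification, Euclidean norm)
is positively homogeneous of degree 1, so the activity count of a bout
scales exactly linearly with its raw amplitude.  The generator exploits
this: it measures the AC of a unit-amplitude bout once per (duration,
carrier, rate) and scales the amplitude so the planted AC lands wherever
the caller wants — making each bout's intensity class analytic ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd

from .clinimetrics import CohortTable, TIMEPOINTS
from .signal import (
    AccelStream,
    HIA,
    LIA,
    MIA,
    InputError,
    MagnitudeSeries,
    PipelineConfig,
    count_activity,
    preprocess,
)

__all__ = [
    "BoutSpec",
    "VariableSpec",
    "CohortSpec",
    "default_cohort_spec",
    "amplitude_for_ac",
    "bout_for_class",
    "generate_day",
    "generate_daily_series",
    "generate_cohort",
    "CLASS_TARGET_AC",
]

#: mid-class AC targets used when planting a bout of a given intensity
CLASS_TARGET_AC = {LIA: 45.0, MIA: 135.0, HIA: 270.0}

DEFAULT_RATE = 50.0
DEFAULT_CARRIER_HZ = 1.0  # near the transmission peak of the filter chain
DEFAULT_NOISE_SD_G = 0.005


@dataclass(frozen=True)
class BoutSpec:
    """A planted activity bout: where, how long, how strong."""

    start_s: float
    duration_s: float
    amplitude_g: float
    carrier_freq_hz: float = DEFAULT_CARRIER_HZ
    intended_class: str | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise InputError("bout duration must be positive")
        if self.amplitude_g < 0:
            raise InputError("bout amplitude must be nonnegative")
        if self.start_s < 0:
            raise InputError("bout start must be nonnegative")


@lru_cache(maxsize=128)
def _unit_bout_ac(
    duration_s: float, carrier_freq_hz: float, rate: float,
    cfg_key: tuple,
) -> float:
    """AC of a unit-amplitude, zero-phase sinusoid bout in a quiet stream."""
    cfg = PipelineConfig(**dict(cfg_key))
    pad_s = 30.0
    n = int(round((duration_s + 2 * pad_s) * rate))
    t = np.arange(n) / rate
    x = np.zeros(n)
    i0 = int(round(pad_s * rate))
    i1 = int(round((pad_s + duration_s) * rate))
    tt = t[i0:i1] - t[i0]
    x[i0:i1] = np.sin(2 * np.pi * carrier_freq_hz * tt)
    stream = AccelStream(ax=x, ay=np.zeros(n), az=np.ones(n), rate=rate)
    mag = preprocess(stream, cfg)
    return count_activity(mag, (i0, i1), cfg)


def _cfg_key(cfg: PipelineConfig) -> tuple:
    return tuple(sorted(vars(cfg).items()))


def amplitude_for_ac(
    target_ac: float,
    duration_s: float,
    carrier_freq_hz: float = DEFAULT_CARRIER_HZ,
    rate: float = DEFAULT_RATE,
    cfg: PipelineConfig | None = None,
) -> float:
    """Raw sinusoid amplitude whose planted bout integrates to ``target_ac``.

    Exact by the degree-1 homogeneity of the processing chain (up to the
    randomized carrier phase, which perturbs the AC only marginally).
    """
    if target_ac <= 0:
        raise InputError("target_ac must be positive")
    cfg = cfg or PipelineConfig()
    unit = _unit_bout_ac(
        float(duration_s), float(carrier_freq_hz), float(rate), _cfg_key(cfg)
    )
    return target_ac / unit


def bout_for_class(
    intensity: str,
    start_s: float,
    duration_s: float,
    carrier_freq_hz: float = DEFAULT_CARRIER_HZ,
    rate: float = DEFAULT_RATE,
    cfg: PipelineConfig | None = None,
) -> BoutSpec:
    """A BoutSpec calibrated so its AC lands mid-class for ``intensity``."""
    if intensity not in CLASS_TARGET_AC:
        raise InputError(f"unknown intensity class {intensity!r}")
    amp = amplitude_for_ac(
        CLASS_TARGET_AC[intensity], duration_s, carrier_freq_hz, rate, cfg
    )
    return BoutSpec(
        start_s=start_s,
        duration_s=duration_s,
        amplitude_g=amp,
        carrier_freq_hz=carrier_freq_hz,
        intended_class=intensity,
    )


def generate_day(
    bouts: list[BoutSpec],
    wear_time_s: float,
    noise_sd_g: float = DEFAULT_NOISE_SD_G,
    gravity_axis: str = "z",
    rate: float = DEFAULT_RATE,
    rng: np.random.Generator | int | None = None,
) -> tuple[AccelStream, list[BoutSpec]]:
    """One day of tri-axial signal: gravity + sensor noise + planted bouts.

    Bouts are sinusoids with randomized phase on the axis orthogonal to
    gravity; the planted specs are returned alongside as ground truth.
    """
    rng = np.random.default_rng(rng)
    n = int(round(wear_time_s * rate))
    if n < 1:
        raise InputError("wear_time_s too short")
    ordered = sorted(bouts, key=lambda b: b.start_s)
    for prev, cur in zip(ordered, ordered[1:]):
        if prev.start_s + prev.duration_s > cur.start_s:
            raise InputError(
                f"bouts overlap near t={cur.start_s:.1f}s"
            )
    for b in ordered:
        if b.start_s + b.duration_s > wear_time_s:
            raise InputError("bout extends past the end of wear time")

    axes = {"x": np.zeros(n), "y": np.zeros(n), "z": np.zeros(n)}
    if gravity_axis not in axes:
        raise InputError(f"gravity_axis must be x, y or z")
    axes[gravity_axis] += 1.0
    if noise_sd_g > 0:
        for k in axes:
            axes[k] = axes[k] + rng.normal(0.0, noise_sd_g, size=n)

    bout_axis = "x" if gravity_axis != "x" else "y"
    for b in ordered:
        i0 = int(round(b.start_s * rate))
        i1 = min(int(round((b.start_s + b.duration_s) * rate)), n)
        tt = np.arange(i1 - i0) / rate
        phase = rng.uniform(0, 2 * np.pi)
        axes[bout_axis][i0:i1] += b.amplitude_g * np.sin(
            2 * np.pi * b.carrier_freq_hz * tt + phase
        )
    stream = AccelStream(
        ax=axes["x"], ay=axes["y"], az=axes["z"], rate=rate
    )
    return stream, ordered


def generate_daily_series(
    n_subjects: int,
    n_days: int,
    between_sd: float,
    within_sd: float,
    mean: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> dict[int, np.ndarray]:
    """Per-subject daily values: latent trait + i.i.d. day-to-day noise.

    The single-day ICC is sigma_b^2 / (sigma_b^2 + sigma_e^2); a mean of m
    consecutive days has ICC sigma_b^2 / (sigma_b^2 + sigma_e^2 / m).
    """
    rng = np.random.default_rng(rng)
    latent = rng.normal(mean, between_sd, size=n_subjects)
    return {
        i: latent[i] + rng.normal(0.0, within_sd, size=n_days)
        for i in range(n_subjects)
    }


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class VariableSpec:
    """Marginal and longitudinal behaviour of one instrument score."""

    mean: float
    sd: float                # total (between + within) SD at baseline
    icc: float               # between-variance fraction, in [0, 1)
    direction: float = 1.0   # sign of the score change under improvement
    effect_w2_improved: float = 0.0   # effects in change-score SD units
                                      # (each equals the expected SRM)
    effect_w4_improved: float = 0.0
    effect_w2_stable: float = 0.0
    effect_w4_stable: float = 0.0
    is_accelerometry: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.icc < 1):
            raise InputError("true_icc must lie in [0, 1)")
        if self.sd <= 0:
            raise InputError("sd must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Study-shaped cohort: sizes, variances, effects, anchors, missingness.

    Defaults emulate the observational arm of the study: 38 subjects, two
    preinjection assessments, week-2 and week-4 follow-ups, roughly two
    thirds of subjects perceiving moderate-or-better improvement, and a
    38.6 % overall loss of accelerometry recording days (7.4 % forgotten
    wear/charge + 31.2 % device data loss, the latter clustered as
    whole-week outages).
    """

    n_subjects: int = 38
    variables: dict[str, VariableSpec] = field(default_factory=dict)
    p_improved: float = 0.66
    p_worsened: float = 0.026
    missing_day_rate: float = 0.074
    data_loss_rate: float = 0.312
    days_per_week: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in (
            ("p_improved", self.p_improved),
            ("p_worsened", self.p_worsened),
            ("missing_day_rate", self.missing_day_rate),
            ("data_loss_rate", self.data_loss_rate),
        ):
            if not (0 <= rate <= 1):
                raise InputError(f"{name} must lie in [0, 1]")
        if self.p_improved + self.p_worsened > 1:
            raise InputError("p_improved + p_worsened exceeds 1")
        if self.missing_day_rate + self.data_loss_rate > 1:
            raise InputError(
                "missing_day_rate + data_loss_rate exceeds 1; the two are "
                "tallied additively as the total expected day loss"
            )
        if self.n_subjects < 2:
            raise InputError("need at least 2 subjects")


def default_variables() -> dict[str, VariableSpec]:
    """Instrument battery mirroring the study's outcome set.

    Baseline means/SDs are typical for a rotator-cuff tendinopathy cohort;
    true ICCs sit in the ranges the instruments' literatures report.
    Effects encode the delayed accelerometry response: questionnaires and
    pain improve strongly by week 2 in the improved stratum, while
    activity-count-based measures move only by week 4.
    """
    q = dict(effect_w2_improved=1.4, effect_w4_improved=1.2,
             effect_w2_stable=0.15, effect_w4_stable=0.15)
    acc_delayed = dict(effect_w2_improved=0.1, effect_w4_improved=0.9,
                       effect_w2_stable=0.1, effect_w4_stable=0.05,
                       is_accelerometry=True)
    return {
        "worc": VariableSpec(50, 20, 0.87, +1, **q),
        "quickdash": VariableSpec(40, 18, 0.84, -1, **q),
        "vas_pain": VariableSpec(45, 22, 0.70, -1, **q),
        "vas_activity": VariableSpec(
            50, 22, 0.60, +1,
            effect_w2_improved=0.55, effect_w4_improved=0.5,
            effect_w2_stable=0.2, effect_w4_stable=0.05,
        ),
        "sane": VariableSpec(55, 20, 0.75, +1, **q),
        "jobe_strength_kg": VariableSpec(
            8, 3, 0.90, +1,
            effect_w2_improved=0.1, effect_w4_improved=0.1,
            effect_w2_stable=0.2, effect_w4_stable=0.2,
        ),
        "abduction_rom_deg": VariableSpec(
            140, 25, 0.85, +1,
            effect_w2_improved=0.25, effect_w4_improved=0.35,
            effect_w2_stable=0.05, effect_w4_stable=0.1,
        ),
        "active_time_ratio": VariableSpec(
            0.28, 0.08, 0.72, +1,
            effect_w2_improved=0.08, effect_w4_improved=0.06,
            effect_w2_stable=0.1, effect_w4_stable=0.1,
            is_accelerometry=True,
        ),
        "mean_ac_per_min": VariableSpec(150, 40, 0.83, +1, **acc_delayed),
        "prop_lia": VariableSpec(0.33, 0.08, 0.57, -1, **acc_delayed),
        "prop_mia": VariableSpec(0.33, 0.06, 0.63, +1, **acc_delayed),
        "prop_hia": VariableSpec(0.33, 0.08, 0.52, +1, **acc_delayed),
    }


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The study-condition CohortSpec with the default instrument battery."""
    return CohortSpec(
        variables=default_variables(), seed=seed, **overrides
    )


def _draw_grcs(
    stratum: str, true_change_sd: float, rng: np.random.Generator
) -> int:
    """GRCS as a deterministic map of planted change plus ordinal noise.

    Clipped into the stratum-consistent range so the anchor always agrees
    with the planted stratum.
    """
    noise = int(rng.integers(-1, 2))
    if stratum == "improved":
        base = 5 + int(round(min(true_change_sd, 2.0)))
        return int(np.clip(base + noise, 4, 7))
    if stratum == "worsened":
        return int(np.clip(-5 + noise, -7, -4))
    return int(np.clip(int(round(true_change_sd)) + noise, -3, 3))


def generate_cohort(
    spec: CohortSpec | None = None,
) -> tuple[CohortTable, dict]:
    """Generate a cohort table with planted ICCs, effects and missingness.

    Per variable with total variance sigma^2 and true ICC rho, each subject
    carries a latent trait ~ N(mean, rho*sigma^2) and every assessment adds
    independent error ~ N(0, (1-rho)*sigma^2).  Week-2/4 scores are shifted
    by the stratum's effect, expressed in SDs of the change score
    (sigma * sqrt(2*(1-rho))), in the variable's improvement direction —
    so a planted effect of e yields an expected standardized response mean
    of e in that stratum.  Accelerometry values go missing when a follow-up week
    retains fewer than 3 recording days.  Returns the table and a hidden
    truth record (strata, planted parameters, per-week day counts).
    """
    spec = spec or default_cohort_spec()
    if not spec.variables:
        spec = replace(spec, variables=default_variables())
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    subjects = np.arange(n)

    u = rng.uniform(size=n)
    strata = np.where(
        u < spec.p_improved, "improved",
        np.where(u < spec.p_improved + spec.p_worsened, "worsened", "stable"),
    )

    # whole-week device outages, then i.i.d. forgotten days on what's left;
    # expected day loss = data_loss_rate + missing_day_rate (additive tally)
    forget = (
        spec.missing_day_rate / (1 - spec.data_loss_rate)
        if spec.data_loss_rate < 1 else 1.0
    )
    week_days: dict[str, np.ndarray] = {}
    for wk in ("preinjection", "week2", "week4"):
        wiped = rng.uniform(size=n) < spec.data_loss_rate
        kept = rng.binomial(
            spec.days_per_week, min(1.0, 1.0 - forget), size=n
        )
        week_days[wk] = np.where(wiped, 0, kept)

    rows = {}
    truth_effects = {}
    for name, v in spec.variables.items():
        sb = v.sd * np.sqrt(v.icc)
        se = v.sd * np.sqrt(1 - v.icc)
        latent = rng.normal(v.mean, sb, size=n)
        eff = {
            ("week2", "improved"): v.effect_w2_improved,
            ("week4", "improved"): v.effect_w4_improved,
            ("week2", "stable"): v.effect_w2_stable,
            ("week4", "stable"): v.effect_w4_stable,
            ("week2", "worsened"): -v.effect_w2_stable,
            ("week4", "worsened"): -v.effect_w4_stable,
        }
        truth_effects[name] = {
            "icc": v.icc, "mean": v.mean, "sd": v.sd,
            "effect_w2_improved": v.effect_w2_improved,
            "effect_w4_improved": v.effect_w4_improved,
        }
        for tp in TIMEPOINTS:
            scores = latent + rng.normal(0.0, se, size=n)
            if tp in ("week2", "week4"):
                sd_change = v.sd * np.sqrt(2.0 * (1.0 - v.icc))
                shift = np.array(
                    [eff[(tp, s)] for s in strata]
                ) * sd_change * v.direction
                scores = scores + shift
                if v.is_accelerometry:
                    wk = "week2" if tp == "week2" else "week4"
                    scores = np.where(
                        week_days[wk] >= 3, scores, np.nan
                    )
            elif v.is_accelerometry:
                scores = np.where(
                    week_days["preinjection"] >= 3, scores, np.nan
                )
            rows[(name, tp)] = scores

    frames = []
    for tp in TIMEPOINTS:
        df = pd.DataFrame(
            {name: rows[(name, tp)] for name in spec.variables},
            index=pd.Index(subjects, name="subject_id"),
        )
        df["timepoint"] = tp
        frames.append(df.set_index("timepoint", append=True))
    scores = pd.concat(frames).sort_index()

    grcs = pd.DataFrame(
        {
            "grcs_week2": [
                _draw_grcs(s, 1.4 if s == "improved" else 0.2, rng)
                for s in strata
            ],
            "grcs_week4": [
                _draw_grcs(s, 1.2 if s == "improved" else 0.2, rng)
                for s in strata
            ],
        },
        index=pd.Index(subjects, name="subject_id"),
    )

    total_days = 3 * spec.days_per_week * n
    days_present = int(sum(week_days[w].sum() for w in week_days))
    truth = {
        "seed": spec.seed,
        "strata": {int(s): str(g) for s, g in zip(subjects, strata)},
        "variables": truth_effects,
        "week_days": {w: week_days[w].tolist() for w in week_days},
        "expected_day_loss": spec.missing_day_rate + spec.data_loss_rate,
        "observed_day_loss": 1.0 - days_present / total_days,
        "total_participant_days": total_days,
        "days_with_data": days_present,
    }
    return CohortTable(scores=scores, grcs=grcs), truth
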