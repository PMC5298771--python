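"""Seeded synthetic accelerometer trials with fall/ADL class structure.

The generator emits waist-acceleration traces with the statistical
structure the downstream analysis relies on, from parametric closed forms
rather than biomechanical simulation:

* **postures** — a constant gravity-reference vector plus sensor noise
  (standing reads (0, +1, 0) g; lying moves the 1 g axis);
* **gait** (walk/jog) — gravity plus a fundamental-and-harmonic sinusoid
  at a drawn stride frequency, vertical-dominant with a drawn horizontal
  share;
* **transient ADLs** — sit: a smooth raised-cosine bump (<= 2 g); jump: a
  near-zero-magnitude flight of 150-300 ms followed by a landing spike;
* **falls** — a pre-fall activity, then a 300-500 ms critical phase with
  a free-fall dip (magnitude drops to a drawn level) and an impact spike
  oriented by fall direction (forward +z, backward -z, lateral +/-x),
  then a lying posture.

An elderly cohort is emulated by one multiplicative factor
(``cohort_scale`` < 1) on every dynamic (non-gravity) component,
reflecting the lower movement amplitudes observed in older participants.
ADC quantization snaps emitted samples to the 13-bit +/-16 g grid.
Determinism: one root seed; per-trial child seeds derived by trial index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import protocol
from .io import ACC1, ACC2, AccelTrace, TrialRecord, trial_filename, write_trial

__all__ = ["SynthConfig", "SyntheticTrial", "make_posture", "make_adl", "make_fall",
           "generate_dataset", "ADL_FAMILIES", "FALL_DIRECTIONS", "PRE_ACTIVITIES"]

ADL_FAMILIES = ("walk", "jog", "sit", "jump")
FALL_DIRECTIONS = ("forward", "backward", "lateral")
PRE_ACTIVITIES = ("walk", "jog", "stand", "sit")

#: representative protocol activity code per synthetic family
_ADL_CODE = {"walk": "D01", "jog": "D04", "sit": "D07", "jump": "D19"}
_FALL_CODE = {
    ("forward", "walk"): "F01", ("backward", "walk"): "F02", ("lateral", "walk"): "F03",
    ("forward", "jog"): "F05", ("backward", "jog"): "F02", ("lateral", "jog"): "F03",
    ("forward", "stand"): "F08", ("backward", "stand"): "F11", ("lateral", "stand"): "F09",
    ("forward", "sit"): "F13", ("backward", "sit"): "F14", ("lateral", "sit"): "F15",
}

_POSTURE_VECTORS = {
    "standing": (0.0, 1.0, 0.0),
    "lying-supine": (0.0, 0.0, 1.0),
    "lying-prone": (0.0, 0.0, -1.0),
    "lying-lateral": (1.0, 0.0, 0.0),  # sign applied separately
}

_LYING_BY_DIRECTION = {"forward": "lying-prone", "backward": "lying-supine",
                       "lateral": "lying-lateral"}


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters. Ranges are (low, high) for uniform draws.

    Amplitudes are in g, frequencies in Hz, durations in seconds.
    ``cohort_scale`` multiplies every dynamic (non-gravity) component;
    1.0 emulates young adults, ``elderly_scale`` (default 0.7) the
    reduced-amplitude elderly cohort.
    """

    fs: float = protocol.DEFAULT_FS
    seed: int = 0
    # gait
    walk_freq_hz: tuple[float, float] = (1.4, 2.2)
    jog_freq_hz: tuple[float, float] = (2.4, 3.4)
    walk_amp_g: tuple[float, float] = (0.10, 0.30)
    jog_amp_g: tuple[float, float] = (0.40, 0.80)
    #: share of the gait/spike amplitude placed on the horizontal (x, z) axes
    horizontal_frac: tuple[float, float] = (0.2, 0.5)
    # transient ADLs (sit bump, jump landing spike)
    transient_amp_g: tuple[float, float] = (1.5, 3.0)
    flight_s: tuple[float, float] = (0.15, 0.30)
    # falls
    impact_amp_g: tuple[float, float] = (2.5, 9.0)
    critical_s: tuple[float, float] = (0.3, 0.5)
    dip_g: tuple[float, float] = (0.0, 0.3)
    #: post-impact settling into the lying posture (slow rotation)
    settle_s: tuple[float, float] = (1.0, 2.0)
    fall_duration_s: float = 15.0
    #: per-family ADL durations following the recording protocol
    adl_duration_s: Mapping[str, float] = field(
        default_factory=lambda: {"walk": 100.0, "jog": 100.0, "sit": 12.0, "jump": 12.0}
    )
    # cohort / sensor
    cohort_scale: float = 1.0
    elderly_scale: float = 0.7
    noise_sd_g: float = 0.02
    quantize: bool = True

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not 0 < self.cohort_scale <= 1:
            raise ValueError("cohort_scale must lie in (0, 1]")
        if not 0 < self.elderly_scale <= 1:
            raise ValueError("elderly_scale must lie in (0, 1]")
        if self.noise_sd_g < 0:
            raise ValueError("noise_sd_g must be nonnegative")
        for name in ("walk_freq_hz", "jog_freq_hz", "walk_amp_g", "jog_amp_g",
                     "horizontal_frac", "transient_amp_g", "flight_s",
                     "impact_amp_g", "critical_s", "dip_g"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a nonnegative (low, high) range")


@dataclass
class SyntheticTrial:
    """A generated trial with its ground-truth annotations."""

    trace: AccelTrace
    activity_code: str
    subject_code: str
    trial_index: int
    cohort: str
    label: str  # "fall" | "adl"
    family: str
    impact_index: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.impact_index is not None) != (self.label == "fall"):
            raise ValueError("impact_index must be set iff the trial is a fall")

    @property
    def trial_id(self) -> str:
        return f"{self.activity_code}_{self.subject_code}_R{self.trial_index:02d}"

    def to_record(self) -> TrialRecord:
        """Quantize to ADC counts: accelerometer-1 and -2 carry the trace,
        the gyroscope channels are emitted as zeros."""
        n = len(self.trace)
        channels = np.zeros((n, 9), dtype=np.int32)
        stacked = self.trace.stacked()
        channels[:, 0:3] = _to_counts(stacked, ACC1)
        channels[:, 6:9] = _to_counts(stacked, ACC2)
        return TrialRecord(
            subject_code=self.subject_code,
            activity_code=self.activity_code,
            trial_index=self.trial_index,
            channels=channels,
            fs=self.trace.fs,
        )


def _to_counts(values_g: np.ndarray, spec) -> np.ndarray:
    counts = np.rint(values_g / spec.scale)
    return np.clip(counts, spec.count_min, spec.count_max).astype(np.int32)


def _quantize_trace(trace: AccelTrace) -> AccelTrace:
    """Snap a trace to the primary accelerometer's ADC grid."""
    s = ACC1.scale
    q = lambda a: _to_counts(a, ACC1).astype(float) * s
    return AccelTrace(fs=trace.fs, ax=q(trace.ax), ay=q(trace.ay), az=q(trace.az))


def _noise(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.zeros((n, 3))
    return rng.normal(0.0, sd, size=(n, 3))


def _finalize(a: np.ndarray, config: SynthConfig, rng: np.random.Generator) -> AccelTrace:
    a = a + _noise(len(a), config.noise_sd_g, rng)
    trace = AccelTrace(fs=config.fs, ax=a[:, 0], ay=a[:, 1], az=a[:, 2])
    return _quantize_trace(trace) if config.quantize else trace


def make_posture(
    posture: str,
    duration_s: float,
    config: SynthConfig,
    rng: np.random.Generator,
    sign: int = 1,
) -> AccelTrace:
    """A static posture: constant gravity-reference vector plus noise."""
    if posture not in _POSTURE_VECTORS:
        raise ValueError(f"unknown posture {posture!r}; one of {sorted(_POSTURE_VECTORS)}")
    if not duration_s > 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * config.fs))
    vec = np.array(_POSTURE_VECTORS[posture])
    if posture == "lying-lateral":
        vec = vec * sign
    a = np.tile(vec, (n, 1)) + _noise(n, config.noise_sd_g, rng)
    return AccelTrace(fs=config.fs, ax=a[:, 0], ay=a[:, 1], az=a[:, 2])


def _gait_dynamics(
    n: int, fs: float, f0: float, amp: float, hfrac: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vertical-dominant periodic gait: fundamental plus a weaker second
    harmonic on y, a drawn horizontal share on x and z."""
    t = np.arange(n) / fs
    ph = rng.uniform(0, 2 * np.pi, size=4)
    dyn = np.zeros((n, 3))
    dyn[:, 1] = amp * np.sin(2 * np.pi * f0 * t + ph[0]) + 0.3 * amp * np.sin(
        4 * np.pi * f0 * t + ph[1]
    )
    dyn[:, 0] = hfrac * amp * np.sin(2 * np.pi * f0 * t + ph[2])
    dyn[:, 2] = hfrac * amp * np.sin(2 * np.pi * f0 * t + ph[3])
    return dyn


def _raised_cosine(n: int) -> np.ndarray:
    """Smooth 0 -> 1 -> 0 bump over n samples."""
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1)))


def _ramp(n: int) -> np.ndarray:
    """Smooth 0 -> 1 half-cosine ramp over n samples."""
    return 0.5 * (1 - np.cos(np.pi * np.arange(n) / max(n - 1, 1)))


def make_adl(
    family: str, config: SynthConfig, rng: np.random.Generator
) -> SyntheticTrial:
    """One ADL trial of the given family (walk | jog | sit | jump)."""
    if family not in ADL_FAMILIES:
        raise ValueError(f"unknown ADL family {family!r}")
    fs = config.fs
    scale = config.cohort_scale
    n = int(round(config.adl_duration_s[family] * fs))
    base = np.tile(_POSTURE_VECTORS["standing"], (n, 1))
    params: dict = {"family": family, "cohort_scale": scale}

    if family in ("walk", "jog"):
        freq_rng = config.walk_freq_hz if family == "walk" else config.jog_freq_hz
        amp_rng = config.walk_amp_g if family == "walk" else config.jog_amp_g
        f0 = rng.uniform(*freq_rng)
        amp = rng.uniform(*amp_rng) * scale
        hfrac = rng.uniform(*config.horizontal_frac)
        base += _gait_dynamics(n, fs, f0, amp, hfrac, rng)
        params.update(gait_freq_hz=f0, gait_amp_g=amp, horizontal_frac=hfrac)

    elif family == "sit":
        # smooth raised-cosine transient (capped at 2 g), vertical-dominant
        amp = min(rng.uniform(*config.transient_amp_g) * scale, 2.0)
        dur = rng.uniform(1.0, 2.0)
        nt = int(round(dur * fs))
        start = n // 2 - nt // 2
        hfrac = rng.uniform(*config.horizontal_frac)
        bump = amp * _raised_cosine(nt)
        base[start : start + nt, 1] += bump
        base[start : start + nt, 2] += 0.3 * hfrac * bump
        params.update(transient_amp_g=amp, transient_s=dur, horizontal_frac=hfrac)

    else:  # jump
        amp = rng.uniform(*config.transient_amp_g) * scale
        flight = rng.uniform(*config.flight_s)
        hfrac = rng.uniform(*config.horizontal_frac)
        theta = rng.uniform(0, 2 * np.pi)
        nf = int(round(flight * fs))
        nr = max(int(round(0.05 * fs)), 2)  # take-off/landing transitions
        ns = int(round(0.08 * fs)) | 1  # landing spike, odd length
        mid = n // 2
        # flight: gravity envelope ramps 1 -> 0, holds 0, ramps back at landing
        env = np.ones(n)
        env[mid - nr : mid] = 1 - _ramp(nr)
        env[mid : mid + nf] = 0.0
        env[mid + nf : mid + nf + nr] = _ramp(nr)
        base *= env[:, None]
        # landing spike: unit direction mostly vertical with horizontal share
        u = np.array([hfrac * np.cos(theta), np.sqrt(max(1 - hfrac**2, 0.0)),
                      hfrac * np.sin(theta)])
        spike = amp * np.sin(np.pi * np.arange(ns) / (ns - 1))
        s0 = mid + nf
        seg = min(ns, n - s0)
        base[s0 : s0 + seg] += spike[:seg, None] * u[None, :]
        params.update(landing_amp_g=amp, flight_s=flight, horizontal_frac=hfrac)

    trace = _finalize(base, config, rng)
    return SyntheticTrial(
        trace=trace, activity_code=_ADL_CODE[family], subject_code="SA01",
        trial_index=1, cohort="young", label="adl", family=family, params=params,
    )


def make_fall(
    direction: str,
    pre_activity: str,
    config: SynthConfig,
    rng: np.random.Generator,
) -> SyntheticTrial:
    """One fall trial: pre-activity, a 300-500 ms critical phase
    (free-fall dip then impact spike), then a lying posture."""
    if direction not in FALL_DIRECTIONS:
        raise ValueError(f"unknown fall direction {direction!r}")
    if pre_activity not in PRE_ACTIVITIES:
        raise ValueError(f"unknown pre-fall activity {pre_activity!r}")
    if config.impact_amp_g[1] * config.cohort_scale < config.jog_amp_g[1]:
        warnings.warn(
            "impact amplitudes at or below gait amplitudes: fall and ADL "
            "scores may overlap by design", stacklevel=2,
        )

    fs = config.fs
    scale = config.cohort_scale
    n = int(round(config.fall_duration_s * fs))

    tau = rng.uniform(*config.critical_s)
    dip = rng.uniform(*config.dip_g)
    amp = rng.uniform(*config.impact_amp_g) * scale
    settle_s = rng.uniform(*config.settle_s)
    lat_sign = int(rng.choice([-1, 1]))

    u = {"forward": np.array([0.0, 0.0, 1.0]),
         "backward": np.array([0.0, 0.0, -1.0]),
         "lateral": np.array([float(lat_sign), 0.0, 0.0])}[direction]
    lying = np.array(_POSTURE_VECTORS[_LYING_BY_DIRECTION[direction]])
    if direction == "lateral":
        lying = lying * lat_sign

    pre_s = rng.uniform(5.0, 8.0)
    n_pre = int(round(pre_s * fs))
    n_crit = int(round(tau * fs))

    base = np.zeros((n, 3))
    standing = np.array(_POSTURE_VECTORS["standing"])
    base[:n_pre] = standing
    if pre_activity in ("walk", "jog"):
        freq_rng = config.walk_freq_hz if pre_activity == "walk" else config.jog_freq_hz
        amp_rng = config.walk_amp_g if pre_activity == "walk" else config.jog_amp_g
        f0 = rng.uniform(*freq_rng)
        gamp = rng.uniform(*amp_rng) * scale
        hfrac = rng.uniform(*config.horizontal_frac)
        base[:n_pre] += _gait_dynamics(n_pre, fs, f0, gamp, hfrac, rng)

    # critical phase: magnitude ramps 1 -> dip, holds, then the impact spike
    n_dip = max(int(round(0.5 * n_crit)), 2)
    i_impact_rel = max(int(round(0.7 * n_crit)), n_dip)
    env = np.ones(n_crit)
    env[:n_dip] = 1 - (1 - dip) * _ramp(n_dip)
    env[n_dip:] = dip
    crit = standing[None, :] * env[:, None]

    ns = int(round(0.06 * fs)) | 1  # impact spike length (odd: exact peak)
    spike = np.sin(np.pi * np.arange(ns) / (ns - 1))
    i_peak_rel = i_impact_rel + (ns - 1) // 2

    seg_end = min(i_impact_rel + ns, n_crit)
    m = seg_end - i_impact_rel
    # the spike rides on the dip floor so the peak sample is exactly
    # amp * u (zero-noise magnitude equals the drawn amplitude)
    under = standing * dip
    w = spike[:m, None]
    crit[i_impact_rel:seg_end] = w * (amp * u)[None, :] + (1 - w) * under[None, :]
    base[n_pre : n_pre + n_crit] = crit
    # slow post-impact settling: the body rotates into the lying posture
    # over ~1-2 s rather than within the critical phase
    n_settle = min(int(round(settle_s * fs)), n - n_pre - n_crit)
    s0 = n_pre + n_crit
    if n_settle > 0:
        blend = _ramp(n_settle)[:, None]
        base[s0 : s0 + n_settle] = (1 - blend) * under[None, :] + blend * lying[None, :]
    base[s0 + n_settle :] = lying

    trace = _finalize(base, config, rng)
    impact_index = n_pre + i_peak_rel
    params = {
        "direction": direction, "pre_activity": pre_activity,
        "critical_s": tau, "dip_g": dip, "impact_amp_g": amp,
        "cohort_scale": scale, "lateral_sign": lat_sign,
    }
    return SyntheticTrial(
        trace=trace,
        activity_code=_FALL_CODE[(direction, pre_activity)],
        subject_code="SA01", trial_index=1, cohort="young", label="fall",
        family=f"fall-{direction}", impact_index=impact_index, params=params,
    )


def _allocate(n: int, mix: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n trials across cohorts."""
    keys = list(mix)
    total = sum(mix.values())
    exact = {c: n * mix[c] / total for c in keys}
    counts = {c: int(np.floor(exact[c])) for c in keys}
    rem = n - sum(counts.values())
    for c in sorted(keys, key=lambda c: exact[c] - counts[c], reverse=True)[:rem]:
        counts[c] += 1
    return counts


def generate_dataset(
    n_adl: int,
    n_fall: int,
    config: SynthConfig | None = None,
    cohort_mix: Mapping[str, float] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[SyntheticTrial], pd.DataFrame]:
    """Generate a labeled synthetic dataset plus its manifest.

    Activity families and fall scenarios are drawn uniformly. Cohorts are
    mixed per ``cohort_mix`` (default all young); elderly trials have
    their dynamic amplitudes multiplied by ``config.elderly_scale``.
    Reproducible given (config, seed): each trial uses a child seed
    derived from the root seed by trial index. With ``out_dir`` set, trial
    files, a manifest CSV and a ground-truth CSV are written.
    """
    if n_adl < 0 or n_fall < 0:
        raise ValueError("trial counts must be nonnegative")
    config = config or SynthConfig()
    cohort_mix = dict(cohort_mix or {"young": 1.0})
    adl_alloc = _allocate(n_adl, cohort_mix)
    fall_alloc = _allocate(n_fall, cohort_mix)

    n_total = n_adl + n_fall
    children = np.random.SeedSequence(config.seed).spawn(n_total)

    plan: list[tuple[str, str]] = []  # (kind, cohort)
    for cohort in cohort_mix:
        plan += [("adl", cohort)] * adl_alloc[cohort]
    for cohort in cohort_mix:
        plan += [("fall", cohort)] * fall_alloc[cohort]

    subjects = {"young": [f"SA{i:02d}" for i in range(1, protocol.N_YOUNG + 1)],
                "elderly": [f"SE{i:02d}" for i in range(1, protocol.N_ELDERLY + 1)]}
    subj_cursor: dict[str, int] = {c: 0 for c in cohort_mix}
    trial_counter: dict[tuple[str, str], int] = {}

    trials: list[SyntheticTrial] = []
    for i, (kind, cohort) in enumerate(plan):
        rng = np.random.default_rng(children[i])
        scale = config.cohort_scale * (config.elderly_scale if cohort == "elderly" else 1.0)
        cfg = replace(config, cohort_scale=scale)
        if kind == "adl":
            family = ADL_FAMILIES[rng.integers(len(ADL_FAMILIES))]
            trial = make_adl(family, cfg, rng)
        else:
            direction = FALL_DIRECTIONS[rng.integers(len(FALL_DIRECTIONS))]
            pre = PRE_ACTIVITIES[rng.integers(len(PRE_ACTIVITIES))]
            trial = make_fall(direction, pre, cfg, rng)

        pool = subjects.get(cohort, subjects["young"])
        subject = pool[subj_cursor[cohort] % len(pool)]
        subj_cursor[cohort] += 1
        key = (subject, trial.activity_code)
        trial_counter[key] = trial_counter.get(key, 0) + 1
        trial.subject_code = subject
        trial.cohort = cohort
        trial.trial_index = trial_counter[key]
        trials.append(trial)

    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    for trial in trials:
        path = ""
        if out_dir is not None:
            record = trial.to_record()
            path = str(write_trial(record, out_dir / trial_filename(record)))
        rows.append(
            {
                "subject": trial.subject_code, "cohort": trial.cohort,
                "activity": trial.activity_code, "label": trial.label,
                "trial": trial.trial_index, "path": path,
                "duration_s": trial.trace.duration_s, "family": trial.family,
                "impact_index": trial.impact_index,
            }
        )
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        truth = manifest.copy()
        truth["params"] = [repr(t.params) for t in trials]
        truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return trials, manifest
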