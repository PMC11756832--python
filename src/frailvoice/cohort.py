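"""Synthetic frailty-screening cohorts: demographics, K-FRAIL labels, and speech audio.

The study population this module emulates is a community-dwelling cohort aged 50+
screened with the K-FRAIL questionnaire (five binary items: Fatigue, Resistance,
Ambulation, Illnesses, Loss of weight).  A score of 0 is *robust*, 1-2 *prefrail*,
>=3 *frail*; for binary classification the prefrail and frail groups are pooled
into the positive class.  Positive participants are on average older and the
cohort is majority male; class-conditional defaults follow the published
characteristics table of the cohort this package models (robust: mean age 64.9,
SD 9.26, 27.4% female; positive: mean age 73.4, SD 10.84, 40% female).

Because the original recordings are not public, speech is synthesized with a
source-filter model (glottal pulse train -> formant resonators) organized into
voiced bursts separated by pauses.  Frailty severity modulates prosody linearly
in the K-FRAIL score: more pausing, slower burst rate, more jitter/shimmer, and
a flatter F0 contour at higher scores.
"""

from __future__ import annotations

import dataclasses
import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.io import wavfile
from scipy.optimize import brentq
from scipy.stats import truncnorm

__all__ = [
    "KFRAIL_ITEMS",
    "Participant",
    "AudioClassParams",
    "CohortSpec",
    "Recording",
    "kfrail_categorize",
    "binary_label",
    "generate_cohort",
    "severity_params",
    "synthesize_speech",
    "synthesize_cohort_audio",
    "generate_unlabeled_corpus",
    "write_cohort",
    "read_cohort",
    "cohort_to_frame",
    "MANIFEST_COLUMNS",
]

KFRAIL_ITEMS = ("fatigue", "resistance", "ambulation", "illnesses", "weight_loss")

MANIFEST_COLUMNS = [
    "participant_id",
    "age",
    "sex",
    "item_fatigue",
    "item_resistance",
    "item_ambulation",
    "item_illnesses",
    "item_weight_loss",
    "kfrail_score",
    "category",
    "label",
    "wav_path",
]

AGE_LO, AGE_HI = 50, 95


def kfrail_categorize(score: int) -> str:
    """Map a K-FRAIL score to its frailty category.

    0 -> ``"robust"``, 1-2 -> ``"prefrail"``, 3-5 -> ``"frail"``.
    """
    if not float(score).is_integer() or not (0 <= int(score) <= 5):
        raise ValueError(f"K-FRAIL score must be an integer in [0, 5], got {score!r}")
    score = int(score)
    if score == 0:
        return "robust"
    if score <= 2:
        return "prefrail"
    return "frail"


def binary_label(category: str) -> int:
    """Binary screening label: robust -> 0, prefrail or frail -> 1."""
    if category == "robust":
        return 0
    if category in ("prefrail", "frail"):
        return 1
    raise ValueError(f"unknown frailty category {category!r}")


@dataclass(frozen=True)
class Participant:
    """One cohort member with demographics and K-FRAIL outcome."""

    id: str
    age: int
    sex: str  # "female" | "male"
    kfrail_items: tuple[int, int, int, int, int]
    kfrail_score: int
    category: str
    label: int
    recording_path: str | None = None

    def __post_init__(self) -> None:
        if sum(self.kfrail_items) != self.kfrail_score:
            raise ValueError("kfrail_score must equal the sum of kfrail_items")
        if kfrail_categorize(self.kfrail_score) != self.category:
            raise ValueError("category inconsistent with kfrail_score")
        if binary_label(self.category) != self.label:
            raise ValueError("label inconsistent with category")
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")


@dataclass(frozen=True)
class AudioClassParams:
    """Source-filter synthesis parameters for one severity level.

    ``f0_base`` is keyed by sex; formants are (center Hz, bandwidth Hz) pairs of
    a neutral vowel-like tract.  ``speech_rate`` counts voiced bursts per
    second; ``pause_fraction`` is the silent share of each burst cycle.
    """

    f0_base: dict[str, float] = field(
        default_factory=lambda: {"male": 120.0, "female": 210.0}
    )
    f0_sd: float = 25.0
    jitter: float = 0.008
    shimmer: float = 0.04
    speech_rate: float = 3.8
    pause_fraction: float = 0.12
    formants: tuple[tuple[float, float], ...] = (
        (500.0, 80.0),
        (1500.0, 120.0),
        (2500.0, 200.0),
    )
    duration: float = 10.0
    sample_rate: int = 48_000

    def __post_init__(self) -> None:
        if not (0 <= self.pause_fraction < 1):
            raise ValueError("pause_fraction must lie in [0, 1)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        nyq = self.sample_rate / 2
        freqs = [f for f, _ in self.formants] + list(self.f0_base.values())
        if any(f >= nyq for f in freqs):
            raise ValueError("all frequencies must be below Nyquist")


# Maximal-severity (K-FRAIL score 5) prosodic shifts; intermediate scores
# interpolate linearly.  Calibrated so the acoustic class signal is learnable
# at cohort sizes around 200.
SEVERITY_MAX_SHIFT = {
    "pause_fraction": 0.50,
    "speech_rate": 1.8,
    "jitter": 0.05,
    "shimmer": 0.20,
    "f0_sd": 6.0,
}


def severity_params(base: AudioClassParams, kfrail_score: int) -> AudioClassParams:
    """Interpolate synthesis parameters linearly between score 0 and score 5."""
    if not (0 <= kfrail_score <= 5):
        raise ValueError("kfrail_score must lie in [0, 5]")
    w = kfrail_score / 5.0
    return replace(
        base,
        pause_fraction=(1 - w) * base.pause_fraction
        + w * SEVERITY_MAX_SHIFT["pause_fraction"],
        speech_rate=(1 - w) * base.speech_rate + w * SEVERITY_MAX_SHIFT["speech_rate"],
        jitter=(1 - w) * base.jitter + w * SEVERITY_MAX_SHIFT["jitter"],
        shimmer=(1 - w) * base.shimmer + w * SEVERITY_MAX_SHIFT["shimmer"],
        f0_sd=(1 - w) * base.f0_sd + w * SEVERITY_MAX_SHIFT["f0_sd"],
    )


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a seeded synthetic cohort.

    Defaults reproduce the modelled study's class structure: 51.2% positive
    prevalence, robust ages ~ N(64.9, 9.26^2) and positive ages ~ N(73.4,
    10.84^2) truncated to [50, 95], female fractions 0.274 / 0.40.
    """

    n: int = 127
    positive_prevalence: float = 65 / 127
    prefrail_fraction_within_positive: float = 0.7
    age_mean_robust: float = 64.9
    age_sd_robust: float = 9.26
    age_mean_positive: float = 73.4
    age_sd_positive: float = 10.84
    female_fraction_robust: float = 0.274
    female_fraction_positive: float = 0.40
    audio_params: AudioClassParams = field(default_factory=AudioClassParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be at least 2")
        if not (0 < self.positive_prevalence < 1):
            raise ValueError("positive_prevalence must lie in (0, 1)")
        if self.age_sd_robust <= 0 or self.age_sd_positive <= 0:
            raise ValueError("age SDs must be positive")


@dataclass(frozen=True)
class Recording:
    """A mono waveform with amplitudes in [-1, 1]."""

    samples: np.ndarray
    sample_rate: int
    participant_id: str

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if np.max(np.abs(self.samples), initial=0.0) > 1.0 + 1e-9:
            raise ValueError("recording amplitudes must lie in [-1, 1]")


def _truncated_loc(target_mean: float, sd: float) -> float:
    """Location of a [50,95]-truncated normal whose truncated mean hits target.

    Truncation alone would bias class means (by ~+1 year for the robust
    class), so the underlying location is solved for instead.
    """

    def truncated_mean(loc: float) -> float:
        a, b = (AGE_LO - loc) / sd, (AGE_HI - loc) / sd
        return float(truncnorm.mean(a, b, loc=loc, scale=sd))

    return float(
        brentq(lambda m: truncated_mean(m) - target_mean, AGE_LO - 3 * sd, AGE_HI)
    )


def _truncated_normal_ages(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    loc = _truncated_loc(mean, sd)
    a, b = (AGE_LO - loc) / sd, (AGE_HI - loc) / sd
    ages = truncnorm.rvs(a, b, loc=loc, scale=sd, size=n, random_state=rng)
    return np.clip(np.rint(ages), AGE_LO, AGE_HI).astype(int)


def _sample_items(rng: np.random.Generator, score: int) -> tuple[int, ...]:
    items = np.zeros(5, dtype=int)
    items[rng.choice(5, size=score, replace=False)] = 1
    return tuple(int(v) for v in items)


def generate_cohort(spec: CohortSpec) -> list[Participant]:
    """Draw a seeded cohort (demographics and labels; no audio yet).

    The positive count is ``round(n * prevalence)``; within the positive class
    prefrail (score 1-2) vs frail (score 3-5) follows
    ``prefrail_fraction_within_positive``, with the item pattern drawn uniformly
    given the score.  Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n * spec.positive_prevalence))
    if n_pos in (0, spec.n):
        raise ValueError(
            f"degenerate cohort: {n_pos} positives out of {spec.n}; "
            "adjust n or positive_prevalence"
        )
    n_rob = spec.n - n_pos

    participants: list[Participant] = []

    def build(i: int, age: int, sex: str, score: int) -> Participant:
        category = kfrail_categorize(score)
        return Participant(
            id=f"P{i:04d}",
            age=int(age),
            sex=sex,
            kfrail_items=_sample_items(rng, score),
            kfrail_score=score,
            category=category,
            label=binary_label(category),
        )

    ages_rob = _truncated_normal_ages(rng, n_rob, spec.age_mean_robust, spec.age_sd_robust)
    sexes_rob = np.where(
        rng.random(n_rob) < spec.female_fraction_robust, "female", "male"
    )
    ages_pos = _truncated_normal_ages(
        rng, n_pos, spec.age_mean_positive, spec.age_sd_positive
    )
    sexes_pos = np.where(
        rng.random(n_pos) < spec.female_fraction_positive, "female", "male"
    )
    prefrail_mask = rng.random(n_pos) < spec.prefrail_fraction_within_positive
    scores_pos = np.where(
        prefrail_mask, rng.integers(1, 3, size=n_pos), rng.integers(3, 6, size=n_pos)
    )

    i = 0
    for age, sex in zip(ages_rob, sexes_rob):
        participants.append(build(i, age, str(sex), 0))
        i += 1
    for age, sex, score in zip(ages_pos, sexes_pos, scores_pos):
        participants.append(build(i, age, str(sex), int(score)))
        i += 1
    return participants


def _resonator_sos(freq: float, bandwidth: float, sr: int) -> np.ndarray:
    """Second-order resonator section at `freq` Hz with the given -3 dB bandwidth."""
    r = np.exp(-np.pi * bandwidth / sr)
    theta = 2 * np.pi * freq / sr
    # unit DC-ish gain normalization via peak gain at resonance
    b0 = (1 - r) * np.sqrt(1 - 2 * r * np.cos(2 * theta) + r * r)
    return np.array([b0, 0.0, 0.0, 1.0, -2 * r * np.cos(theta), r * r])


def synthesize_speech(
    participant: Participant, params: AudioClassParams, seed: int
) -> Recording:
    """Render one participant's clip with the source-filter model.

    The glottal source is an impulse train whose period wanders with a slow F0
    random walk (spread ``f0_sd``) and is perturbed multiplicatively per cycle
    by ``jitter`` (period) and ``shimmer`` (amplitude).  The train is filtered
    by cascaded formant resonators, multiplied by a burst/pause envelope
    (``speech_rate`` cycles/s, silent share ``pause_fraction``), lightly mixed
    with aspiration noise, and peak-normalized to 0.9.  Bit-deterministic for a
    fixed (participant, params, seed).
    """
    if params.duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    sr = params.sample_rate
    n = int(round(params.duration * sr))

    f0 = params.f0_base[participant.sex]
    # slow F0 contour: smoothed random walk with SD ~ f0_sd
    n_ctrl = max(4, int(params.duration * 2))
    contour = rng.normal(0.0, params.f0_sd, size=n_ctrl)
    t_ctrl = np.linspace(0, n - 1, n_ctrl)
    f0_track = np.clip(f0 + np.interp(np.arange(n), t_ctrl, contour), 50.0, 420.0)

    # impulse train with jitter/shimmer
    source = np.zeros(n)
    t = 0.0
    while t < n:
        idx = int(t)
        period = sr / f0_track[min(idx, n - 1)]
        period *= 1.0 + params.jitter * rng.standard_normal()
        amp = 1.0 + params.shimmer * rng.standard_normal()
        if idx < n:
            source[idx] += amp
        t += max(period, sr / 500.0)

    sos = np.vstack([
        _resonator_sos(f, bw, sr) for f, bw in params.formants if f < sr / 2
    ])
    voiced = sps.sosfilt(sos, source)
    vpeak = np.max(np.abs(voiced))
    if vpeak > 0:  # cascade gain is far below unity; renormalize the voiced path
        voiced = voiced / vpeak

    # burst/pause envelope with 5 ms raised-cosine edges
    cycle = sr / params.speech_rate
    env = np.zeros(n)
    edge = int(0.005 * sr)
    ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, max(edge, 2))))
    pos = 0.0
    while pos < n:
        this_cycle = cycle * (1.0 + 0.1 * rng.standard_normal())
        von = (1.0 - params.pause_fraction) * this_cycle
        a, b = int(pos), min(int(pos + von), n)
        if b > a:
            env[a:b] = 1.0
            m = min(len(ramp), b - a)
            env[a : a + m] = np.minimum(env[a : a + m], ramp[:m])
            env[b - m : b] = np.minimum(env[b - m : b], ramp[:m][::-1])
        pos += max(this_cycle, edge + 1.0)

    clip = voiced * env
    clip += 5e-3 * rng.standard_normal(n) * env  # aspiration only inside bursts
    peak = np.max(np.abs(clip))
    if peak > 0:
        clip = 0.9 * clip / peak
    return Recording(samples=clip, sample_rate=sr, participant_id=participant.id)


def synthesize_cohort_audio(
    cohort: list[Participant],
    base_params: AudioClassParams | None = None,
    seed: int = 0,
) -> dict[str, Recording]:
    """Synthesize one clip per participant, severity scaled by K-FRAIL score."""
    base = base_params or AudioClassParams()
    ss = np.random.SeedSequence([seed, 0xA5D10])
    child_seeds = ss.generate_state(len(cohort))
    out: dict[str, Recording] = {}
    for p, s in zip(cohort, child_seeds):
        out[p.id] = synthesize_speech(p, severity_params(base, p.kfrail_score), int(s) % (2**31))
    return out


def generate_unlabeled_corpus(
    n_clips: int, params: AudioClassParams | None = None, seed: int = 0
) -> list[Recording]:
    """Severity-neutral unlabeled clips for self-supervised pretraining.

    Stands in for a public unlabeled speech corpus: baseline (score 0)
    prosody, sex drawn uniformly, independent seeds per clip.
    """
    base = params or AudioClassParams()
    rng = np.random.default_rng(seed)
    ss = np.random.SeedSequence([seed, 0xC09B])
    child_seeds = ss.generate_state(n_clips)
    clips = []
    for i, s in enumerate(child_seeds):
        sex = "female" if rng.random() < 0.5 else "male"
        dummy = Participant(
            id=f"U{i:04d}",
            age=65,
            sex=sex,
            kfrail_items=(0, 0, 0, 0, 0),
            kfrail_score=0,
            category="robust",
            label=0,
        )
        clips.append(synthesize_speech(dummy, base, int(s) % (2**31)))
    return clips


def cohort_to_frame(cohort: list[Participant]) -> pd.DataFrame:
    """Manifest-shaped DataFrame (without wav paths unless set)."""
    rows = []
    for p in cohort:
        row = {
            "participant_id": p.id,
            "age": p.age,
            "sex": p.sex,
            **{f"item_{k}": v for k, v in zip(KFRAIL_ITEMS, p.kfrail_items)},
            "kfrail_score": p.kfrail_score,
            "category": p.category,
            "label": p.label,
            "wav_path": p.recording_path or "",
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def write_cohort(
    cohort: list[Participant],
    directory: str | Path,
    recordings: dict[str, Recording] | None = None,
    base_params: AudioClassParams | None = None,
    seed: int = 0,
) -> Path:
    """Write one 16-bit PCM WAV per participant plus a manifest CSV.

    If ``recordings`` is not supplied they are synthesized with
    :func:`synthesize_cohort_audio`.  Returns the manifest path; the written
    tree round-trips through :func:`read_cohort`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if recordings is None:
        recordings = synthesize_cohort_audio(cohort, base_params, seed)

    updated: list[Participant] = []
    for p in cohort:
        rec = recordings[p.id]
        wav_path = directory / f"{p.id}.wav"
        pcm = np.clip(np.rint(rec.samples * 32767.0), -32768, 32767).astype(np.int16)
        try:
            wavfile.write(wav_path, rec.sample_rate, pcm)
        except OSError as exc:  # pragma: no cover
            raise OSError(f"failed to write {wav_path}: {exc}") from exc
        updated.append(dataclasses.replace(p, recording_path=wav_path.name))

    manifest = directory / "manifest.csv"
    cohort_to_frame(updated).to_csv(manifest, index=False, encoding="utf-8")
    return manifest


def read_cohort(manifest_path: str | Path) -> list[Participant]:
    """Read a manifest CSV back into Participant records."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, encoding="utf-8")
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {manifest_path} missing columns: {sorted(missing)}")
    out = []
    for _, r in df.iterrows():
        out.append(
            Participant(
                id=str(r["participant_id"]),
                age=int(r["age"]),
                sex=str(r["sex"]),
                kfrail_items=tuple(int(r[f"item_{k}"]) for k in KFRAIL_ITEMS),
                kfrail_score=int(r["kfrail_score"]),
                category=str(r["category"]),
                label=int(r["label"]),
                recording_path=str(r["wav_path"]) if r["wav_path"] else None,
            )
        )
    return out


def load_recording(path: str | Path, participant_id: str = "") -> Recording:
    """Load a mono 16-bit PCM WAV as a float waveform in [-1, 1]."""
    sr, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path}: expected mono WAV")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32768.0
    else:
        samples = data.astype(np.float64)
    return Recording(samples=samples, sample_rate=int(sr), participant_id=participant_id)
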