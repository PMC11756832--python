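"""Frame-level MFCC(+delta+delta-delta) features and per-clip functionals.

Each clip is resampled to a working rate (default 16 kHz), windowed into
short frames, and turned into mel-frequency cepstral coefficients: power
spectrum -> triangular mel filterbank (HTK mel scale) -> log with floor ->
orthonormal DCT-II, keeping the first ``n_coeff`` coefficients (default 20,
coefficient 0 included).  First- and second-order local-regression derivatives
are appended, giving 3 x n_coeff = 60 columns.

For the classical baselines, :func:`extract_functionals` reduces a clip to a
fixed 126-vector: mean and SD of each of the 60 frame features plus six
prosodic summaries (F0 mean/SD from an autocorrelation tracker, voiced
fraction, RMS loudness mean/SD, pause fraction).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.fft import dct, rfft

from .cohort import Recording

__all__ = [
    "FeatureConfig",
    "AcousticFeatureMatrix",
    "extract_mfcc_features",
    "compute_deltas",
    "extract_functionals",
    "FUNCTIONAL_NAMES",
    "write_functionals_csv",
    "save_feature_matrix",
    "load_feature_matrix",
]


@dataclass(frozen=True)
class FeatureConfig:
    target_sample_rate: int = 16_000
    frame_ms: float = 25.0
    hop_ms: float = 10.0
    window: str = "hann"
    n_mels: int = 64
    fmin: float = 20.0
    fmax: float | None = None  # None -> Nyquist
    n_coeff: int = 20
    delta_width: int = 9
    log_floor: float = 1e-10

    def __post_init__(self) -> None:
        if self.n_coeff > self.n_mels:
            raise ValueError("n_coeff must not exceed n_mels")
        if self.delta_width < 3 or self.delta_width % 2 == 0:
            raise ValueError("delta_width must be odd and >= 3")
        if self.effective_fmax > self.target_sample_rate / 2:
            raise ValueError("fmax must not exceed Nyquist")

    @property
    def effective_fmax(self) -> float:
        return self.fmax if self.fmax is not None else self.target_sample_rate / 2

    @property
    def frame_length(self) -> int:
        return int(round(self.frame_ms * self.target_sample_rate / 1000))

    @property
    def hop_length(self) -> int:
        return int(round(self.hop_ms * self.target_sample_rate / 1000))

    @property
    def n_fft(self) -> int:
        return 1 << (self.frame_length - 1).bit_length()

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass(frozen=True)
class AcousticFeatureMatrix:
    """T x (3*n_coeff) frame features: [MFCC | delta | delta-delta]."""

    values: np.ndarray
    frame_times: np.ndarray

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("feature matrix must be 2-D with at least one frame")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, sr: int, fmin: float, fmax: float) -> np.ndarray:
    """Triangular filters (n_mels x (n_fft//2 + 1)) on the HTK mel scale."""
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    fft_freqs = np.linspace(0, sr / 2, n_fft // 2 + 1)
    fb = np.zeros((n_mels, len(fft_freqs)))
    for m in range(n_mels):
        lo, c, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (fft_freqs - lo) / max(c - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - c, 1e-12)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def _resample(samples: np.ndarray, sr: int, target_sr: int) -> np.ndarray:
    if sr == target_sr:
        return samples
    frac = Fraction(target_sr, sr)
    return sps.resample_poly(samples, frac.numerator, frac.denominator)


def _frame_signal(x: np.ndarray, frame_length: int, hop: int) -> np.ndarray:
    if len(x) < frame_length:
        raise ValueError(
            f"clip of {len(x)} samples is shorter than one frame ({frame_length})"
        )
    n_frames = 1 + (len(x) - frame_length) // hop
    idx = np.arange(frame_length)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def compute_deltas(matrix: np.ndarray, order: int = 1, width: int = 9) -> np.ndarray:
    """Local least-squares slope of each column over a centered window.

    Weights are k / sum(k^2) for k = -(w-1)/2 .. (w-1)/2 with edge frames
    replicated; ``order=2`` applies the operator twice.
    """
    if width % 2 == 0:
        raise ValueError("delta window width must be odd")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    matrix = np.asarray(matrix, dtype=float)
    half = (width - 1) // 2
    k = np.arange(-half, half + 1)
    denom = float(np.sum(k**2))

    def once(m: np.ndarray) -> np.ndarray:
        padded = np.pad(m, ((half, half), (0, 0)), mode="edge")
        out = np.zeros_like(m)
        for j, kk in enumerate(k):
            out += kk * padded[j : j + m.shape[0]]
        return out / denom

    d = once(matrix)
    if order == 2:
        d = once(d)
    return d


def extract_mfcc_features(
    recording: Recording, config: FeatureConfig | None = None
) -> AcousticFeatureMatrix:
    """MFCC + delta + delta-delta frame matrix for one recording."""
    config = config or FeatureConfig()
    x = _resample(
        np.asarray(recording.samples, dtype=float),
        recording.sample_rate,
        config.target_sample_rate,
    )
    frames = _frame_signal(x, config.frame_length, config.hop_length)
    win = sps.get_window(config.window, config.frame_length, fftbins=True)
    spec = np.abs(rfft(frames * win, n=config.n_fft, axis=1)) ** 2
    fb = mel_filterbank(
        config.n_mels,
        config.n_fft,
        config.target_sample_rate,
        config.fmin,
        config.effective_fmax,
    )
    logmel = np.log(np.maximum(spec @ fb.T, config.log_floor))
    mfcc = dct(logmel, type=2, norm="ortho", axis=1)[:, : config.n_coeff]
    d1 = compute_deltas(mfcc, order=1, width=config.delta_width)
    d2 = compute_deltas(mfcc, order=2, width=config.delta_width)
    values = np.hstack([mfcc, d1, d2])
    times = (
        np.arange(frames.shape[0]) * config.hop_length + config.frame_length / 2
    ) / config.target_sample_rate
    return AcousticFeatureMatrix(values=values, frame_times=times)


# ---------------------------------------------------------------------------
# per-clip functionals

FUNCTIONAL_NAMES: tuple[str, ...] = tuple(
    [f"{stat}_{block}{i}" for stat in ("mean", "sd")
     for block, n0 in (("mfcc", 0), ("delta", 0), ("ddelta", 0))
     for i in range(20)]
) + ("f0_mean", "f0_sd", "voiced_fraction", "rms_mean", "rms_sd", "pause_fraction")


def _frame_rms(x: np.ndarray, frame_length: int, hop: int) -> np.ndarray:
    frames = _frame_signal(x, frame_length, hop)
    return np.sqrt(np.mean(frames**2, axis=1))


def detect_pauses(x: np.ndarray, sr: int, frame_ms: float = 25.0, hop_ms: float = 10.0):
    """Boolean pause mask per frame from an adaptive RMS threshold."""
    fl = int(round(frame_ms * sr / 1000))
    hop = int(round(hop_ms * sr / 1000))
    rms = _frame_rms(x, fl, hop)
    thr = max(1e-5, 0.05 * float(np.percentile(rms, 95)))
    return rms < thr, rms


def _track_f0(
    x: np.ndarray, sr: int, pause_mask: np.ndarray, hop: int, frame_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame F0 (Hz) and voicing flags via windowed autocorrelation, 60-400 Hz."""
    lag_min = int(sr / 400)
    lag_max = int(sr / 60)
    win = max(frame_length, 2 * lag_max)
    n_frames = len(pause_mask)
    f0 = np.zeros(n_frames)
    voiced = np.zeros(n_frames, dtype=bool)
    for t in range(n_frames):
        if pause_mask[t]:
            continue
        a = t * hop
        seg = x[a : a + win]
        if len(seg) < 2 * lag_min:
            continue
        seg = seg - seg.mean()
        denom = float(np.dot(seg, seg))
        if denom < 1e-12:
            continue
        ac = sps.correlate(seg, seg, mode="full")[len(seg) - 1 :] / denom
        hi = min(lag_max, len(ac) - 2)
        if hi <= lag_min:
            continue
        lag = lag_min + int(np.argmax(ac[lag_min : hi + 1]))
        if ac[lag] < 0.3:
            continue
        # parabolic interpolation around the peak
        y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
        denom2 = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom2 if abs(denom2) > 1e-12 else 0.0
        f0[t] = sr / (lag + shift)
        voiced[t] = True
    return f0, voiced


def extract_functionals(
    recording: Recording, config: FeatureConfig | None = None
) -> np.ndarray:
    """Fixed-length (126) per-clip summary vector; duration-invariant.

    A fully silent clip yields voiced fraction 0 and F0 statistics of 0.
    """
    config = config or FeatureConfig()
    feats = extract_mfcc_features(recording, config)
    x = _resample(
        np.asarray(recording.samples, dtype=float),
        recording.sample_rate,
        config.target_sample_rate,
    )
    pause_mask, rms = detect_pauses(
        x, config.target_sample_rate, config.frame_ms, config.hop_ms
    )
    f0, voiced = _track_f0(
        x, config.target_sample_rate, pause_mask, config.hop_length, config.frame_length
    )
    v = feats.values
    means = v.mean(axis=0)
    sds = v.std(axis=0, ddof=0)
    if voiced.any():
        f0_vals = f0[voiced]
        f0_mean, f0_sd = float(f0_vals.mean()), float(f0_vals.std(ddof=0))
    else:
        f0_mean = f0_sd = 0.0
    out = np.concatenate(
        [
            means,
            sds,
            [
                f0_mean,
                f0_sd,
                float(voiced.mean()),
                float(rms.mean()),
                float(rms.std(ddof=0)),
                float(pause_mask.mean()),
            ],
        ]
    )
    assert out.shape == (126,)
    return out


def write_functionals_csv(
    path: str | Path, ids: list[str], vectors: np.ndarray
) -> Path:
    path = Path(path)
    df = pd.DataFrame(np.asarray(vectors), columns=list(FUNCTIONAL_NAMES))
    df.insert(0, "participant_id", ids)
    df.to_csv(path, index=False)
    return path


def save_feature_matrix(
    path: str | Path, matrix: AcousticFeatureMatrix, config: FeatureConfig
) -> None:
    """Persist a feature matrix with its config hash and column layout."""
    np.savez(
        path,
        values=matrix.values,
        frame_times=matrix.frame_times,
        config_hash=np.array(config.config_hash()),
        layout=np.array("mfcc[0:20]|delta[20:40]|ddelta[40:60]"),
    )


def load_feature_matrix(path: str | Path) -> AcousticFeatureMatrix:
    with np.load(path, allow_pickle=False) as z:
        return AcousticFeatureMatrix(values=z["values"], frame_times=z["frame_times"])
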