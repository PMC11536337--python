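"""Audio I/O and spectral primitives shared by the detector and feature code.

Two fixed analysis profiles are used throughout the package, mirroring common
bioacoustic practice for very short tonal calls:

* ``TEMPORAL_PROFILE`` — FFT 64, Blackman window, 50% overlap (hop 32).  A
  64-sample window at 44.1 kHz gives ~1.45 ms time resolution, fine enough to
  place the boundaries of a ~64 ms call.
* ``SPECTRAL_PROFILE`` — FFT 1024, Blackman window, 90% overlap (hop 96
  samples at 44.1 kHz), ~43 Hz frequency resolution for peak/low/high
  frequency measurement.

The spectrogram is a one-sided power (magnitude-squared) spectrogram scaled so
that the per-frame sum over frequency bins equals the energy of the windowed
signal segment (Parseval-consistent), which makes band energies directly
comparable to waveform energies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.io import wavfile
from scipy.signal import get_window

__all__ = [
    "AudioRecording",
    "SpectrogramGrid",
    "TEMPORAL_PROFILE",
    "SPECTRAL_PROFILE",
    "read_wav",
    "write_wav",
    "spectrogram",
    "band_energy",
    "power_to_db",
    "bandpass",
]

#: fft_size 64 is the paper-style waveform/temporal view; hop defaults to 50%
#: overlap because the temporal hop is not otherwise pinned down.
TEMPORAL_PROFILE = {"fft_size": 64, "hop": 32, "window": "blackman"}
#: 1024-point view with 90% overlap (hop 96 at 44.1 kHz) for spectral measures.
SPECTRAL_PROFILE = {"fft_size": 1024, "hop": 96, "window": "blackman"}


class WavFormatError(ValueError):
    """Raised when a file cannot be parsed as PCM WAV."""


@dataclass
class AudioRecording:
    """Mono waveform plus the per-recording field metadata.

    ``samples`` are dimensionless floats nominally in [-1, 1];
    ``condition`` is one of ``"no clutches"``, ``"guarding"``, ``"brooding"``
    when known.
    """

    samples: np.ndarray
    sample_rate: float
    recording_id: str = "rec"
    male_id: Optional[str] = None
    condition: Optional[str] = None
    temperature_c: Optional[float] = None
    rainfall: Optional[bool] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D mono array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass
class SpectrogramGrid:
    """Time-frequency power grid with explicit axes.

    ``power[i, j]`` is the power in frequency bin ``freqs[i]`` for the frame
    centred at ``times[j]``.
    """

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray
    window: str
    fft_size: int
    hop: int

    def __post_init__(self) -> None:
        if self.power.shape != (self.freqs.size, self.times.size):
            raise ValueError("power matrix does not match axes")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.diff(self.freqs) > 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def frame_rate(self) -> float:
        """Frames per second (inverse of the frame hop in seconds)."""
        if self.times.size > 1:
            return 1.0 / (self.times[1] - self.times[0])
        return 1.0


def read_wav(path, recording_id: Optional[str] = None, **metadata) -> AudioRecording:
    """Read a PCM WAV file into an :class:`AudioRecording`.

    Integer samples are normalized to [-1, 1] by the full-scale value of the
    stored bit depth; stereo files are downmixed to mono (channel mean) with a
    warning.  Raises :class:`WavFormatError` for non-WAV or corrupt input.
    """
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # scipy raises assorted ValueError/struct errors
        raise WavFormatError(f"cannot read {path!r} as PCM WAV: {exc}") from exc
    if data.size == 0:
        raise WavFormatError(f"{path!r} contains no samples")
    if data.ndim == 2:
        warnings.warn(f"{path!r}: downmixing {data.shape[1]} channels to mono")
        data = data.astype(float).mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        if info.min < 0:
            scale = float(-info.min)
            samples = data.astype(float) / scale
        else:  # unsigned 8-bit: offset binary
            scale = (info.max + 1) / 2.0
            samples = (data.astype(float) - scale) / scale
    else:
        samples = data.astype(float)
    if recording_id is None:
        recording_id = str(path)
    return AudioRecording(samples=samples, sample_rate=float(rate),
                          recording_id=recording_id, **metadata)


def write_wav(path, rec_or_samples, sample_rate: Optional[float] = None) -> None:
    """Write samples in [-1, 1] as 16-bit PCM WAV (values clipped to range)."""
    if isinstance(rec_or_samples, AudioRecording):
        samples = rec_or_samples.samples
        sample_rate = rec_or_samples.sample_rate
    else:
        samples = np.asarray(rec_or_samples, dtype=float)
        if sample_rate is None:
            raise ValueError("sample_rate required when passing a bare array")
    q = np.clip(np.round(samples * 32768.0), -32768, 32767).astype(np.int16)
    wavfile.write(path, int(sample_rate), q)


def spectrogram(rec: AudioRecording, fft_size: int = 1024, hop: int = 96,
                window: str = "blackman") -> SpectrogramGrid:
    """One-sided power spectrogram with ``floor((n - fft)/hop) + 1`` frames.

    No padding is applied: each frame covers exactly ``fft_size`` samples and
    ``times`` holds the frame-centre instants.  The per-frame bin sum equals
    the windowed segment energy (Parseval).
    """
    if fft_size < 8:
        raise ValueError("fft_size must be >= 8")
    if not 0 < hop <= fft_size:
        raise ValueError("hop must satisfy 0 < hop <= fft_size")
    x = rec.samples
    if x.size < fft_size:
        raise ValueError(
            f"audio ({x.size} samples) shorter than fft_size ({fft_size})")
    win = get_window(window, fft_size, fftbins=True)
    frames = sliding_window_view(x, fft_size)[::hop]
    spec = np.fft.rfft(frames * win, axis=1)
    power = (np.abs(spec) ** 2) / fft_size
    # one-sided: double interior bins so bin sums equal windowed-frame energy
    power[:, 1:] *= 2.0
    if fft_size % 2 == 0:
        power[:, -1] /= 2.0
    fs = rec.sample_rate
    n_frames = frames.shape[0]
    times = (np.arange(n_frames) * hop + (fft_size - 1) / 2.0) / fs
    freqs = np.fft.rfftfreq(fft_size, d=1.0 / fs)
    return SpectrogramGrid(times=times, freqs=freqs, power=power.T,
                           window=window, fft_size=fft_size, hop=hop)


def band_energy(sg: SpectrogramGrid, f_lo: float, f_hi: float) -> np.ndarray:
    """Per-frame summed power over frequency bins in [f_lo, f_hi)."""
    if not f_lo < f_hi:
        raise ValueError("f_lo must be < f_hi")
    if f_lo > sg.freqs[-1] or f_hi <= sg.freqs[0]:
        raise ValueError(
            f"band [{f_lo}, {f_hi}) outside grid range "
            f"[{sg.freqs[0]}, {sg.freqs[-1]}]")
    mask = (sg.freqs >= f_lo) & (sg.freqs < f_hi)
    if not mask.any():
        raise ValueError(f"band [{f_lo}, {f_hi}) contains no frequency bins")
    return sg.power[mask].sum(axis=0)


def power_to_db(power: np.ndarray, floor_db: float = -120.0) -> np.ndarray:
    """10 log10 conversion with a configurable floor against log(0)."""
    floor = 10.0 ** (floor_db / 10.0)
    return 10.0 * np.log10(np.maximum(np.asarray(power, dtype=float), floor))


def bandpass(samples: np.ndarray, sample_rate: float,
             f_lo: float, f_hi: float) -> np.ndarray:
    """Zero-phase brick-wall band-pass via FFT bin zeroing.

    Used for in-band energy envelopes on short extracted segments; not meant
    for streaming use.
    """
    x = np.asarray(samples, dtype=float)
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, d=1.0 / sample_rate)
    spec[(freqs < f_lo) | (freqs >= f_hi)] = 0.0
    return np.fft.irfft(spec, n=x.size)
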