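"""Per-call parameter measurement, sequence structure and inclusion filters.

Eight parameters are measured per call:

* **CD** (s) — selection duration, end - begin.
* **CD90** (s) — span between the 5% and 95% points of the cumulative
  in-band energy (robust "central 90%" duration).
* **T95** (%) — position of the 95% cumulative-energy point relative to the
  call duration (envelope asymmetry).
* **ICI** (s) — gap from the end of a call to the beginning of the next.
* **PF, LF, HF, FR** (Hz) — peak frequency (argmax of the call's mean power
  spectrum), low/high frequencies at the 2.5%/97.5% cumulative
  spectral-energy quantiles, and their difference.

LF/HF by spectral-energy quantiles parallels the temporal energy-percentile
measures; a dB-below-peak crossing is available as an alternative.
"""

from __future__ import annotations

import warnings
from typing import List, Optional

import numpy as np
import pandas as pd

from .detect import CallSelection
from .dsp import AudioRecording, SPECTRAL_PROFILE, bandpass, spectrogram
from .stats import welch_t

__all__ = ["measure_temporal", "measure_spectral", "measure_calls",
           "compute_ici", "apply_inclusion_filters", "first_call_contrast",
           "MeasurementError", "NoQualifyingDataError", "FEATURE_COLUMNS"]

FEATURE_COLUMNS = ("cd_s", "cd90_s", "ici_s", "t95_pct",
                   "pf_hz", "lf_hz", "hf_hz", "fr_hz")


class MeasurementError(ValueError):
    """A call selection on which a parameter is undefined (e.g. zero energy)."""


class NoQualifyingDataError(ValueError):
    """Inclusion filters removed every call."""


def _cum_energy_time(x: np.ndarray, fs: float, q: float) -> float:
    """Time (s, from segment start) at which cumulative energy reaches q."""
    e = np.cumsum(x ** 2)
    total = e[-1]
    if total <= 0:
        raise MeasurementError("zero in-band energy in selection")
    # linear interpolation on the cumulative curve; sample k spans
    # ((k)/fs, (k+1)/fs] with cumulative value e[k] at its right edge
    target = q * total
    k = int(np.searchsorted(e, target))
    e_prev = e[k - 1] if k > 0 else 0.0
    frac = (target - e_prev) / max(e[k] - e_prev, np.finfo(float).tiny)
    return (k + frac) / fs


def measure_temporal(rec: AudioRecording, sel: CallSelection):
    """Measure CD, CD90 and T95 from the in-band waveform energy.

    Returns ``(cd_s, cd90_s, t95_pct)``.  Energy is accumulated over the
    band-limited samples inside [begin, end).
    """
    fs = rec.sample_rate
    i0 = max(int(round(sel.begin * fs)), 0)
    i1 = min(int(round(sel.end * fs)), rec.n_samples)
    if i1 - i0 < 2:
        raise MeasurementError("selection too short to measure")
    seg = bandpass(rec.samples[i0:i1], fs, sel.low_freq, sel.high_freq)
    cd = sel.end - sel.begin
    t05 = _cum_energy_time(seg, fs, 0.05)
    t95 = _cum_energy_time(seg, fs, 0.95)
    return cd, t95 - t05, 100.0 * t95 / cd


def measure_spectral(rec: AudioRecording, sel: CallSelection,
                     q_lo: float = 0.025, q_hi: float = 0.975,
                     profile: Optional[dict] = None,
                     method: str = "quantile", db_down: float = 20.0):
    """Measure PF, LF, HF and FR from the call's average power spectrum.

    The spectrum is the frame-mean of the spectral-profile spectrogram over
    frames overlapping the selection, restricted to the selection band.
    ``method="quantile"`` places LF/HF at cumulative spectral-energy
    quantiles; ``method="db_down"`` uses the outermost crossings of
    ``db_down`` dB below the peak.  Returns ``(pf, lf, hf, fr)`` in Hz.
    """
    profile = profile or SPECTRAL_PROFILE
    fs = rec.sample_rate
    pad = profile["fft_size"] / fs
    i0 = max(int((sel.begin - pad) * fs), 0)
    i1 = min(int(np.ceil((sel.end + pad) * fs)), rec.n_samples)
    seg = AudioRecording(rec.samples[i0:i1], fs, recording_id=rec.recording_id)
    sg = spectrogram(seg, **profile)
    t_off = i0 / fs
    frames = ((sg.times + t_off + 0.5 * profile["fft_size"] / fs > sel.begin)
              & (sg.times + t_off - 0.5 * profile["fft_size"] / fs < sel.end))
    if not frames.any():
        raise MeasurementError("no spectrogram frames overlap the selection")
    band = (sg.freqs >= sel.low_freq) & (sg.freqs < sel.high_freq)
    spectrum = sg.power[:, frames].mean(axis=1)
    spectrum = np.where(band, spectrum, 0.0)
    total = spectrum.sum()
    if total <= 0:
        raise MeasurementError("zero spectral energy in selection band")
    pf = float(sg.freqs[int(np.argmax(spectrum))])
    if method == "quantile":
        cum = np.cumsum(spectrum) / total
        lf = float(np.interp(q_lo, cum, sg.freqs))
        hf = float(np.interp(q_hi, cum, sg.freqs))
    elif method == "db_down":
        above = spectrum >= spectrum.max() * 10.0 ** (-db_down / 10.0)
        idx = np.flatnonzero(above)
        lf, hf = float(sg.freqs[idx[0]]), float(sg.freqs[idx[-1]])
    else:
        raise ValueError(f"unknown LF/HF method {method!r}")
    lf = min(lf, pf)
    hf = max(hf, pf)
    return pf, lf, hf, hf - lf


def measure_calls(rec: AudioRecording, selections: List[CallSelection],
                  seq_gap_threshold: float = 20.0,
                  q_lo: float = 0.025, q_hi: float = 0.975) -> pd.DataFrame:
    """Measure all parameters for each selection of one recording.

    Returns a tidy CallTable fragment (one row per call) with the recording's
    metadata attached; ICI and sequence flags are computed afterwards.
    """
    rows = []
    for k, sel in enumerate(sorted(selections, key=lambda s: s.begin)):
        cd, cd90, t95 = measure_temporal(rec, sel)
        pf, lf, hf, fr = measure_spectral(rec, sel, q_lo=q_lo, q_hi=q_hi)
        rows.append({
            "male_id": rec.male_id, "recording_id": rec.recording_id,
            "call_idx": k, "begin_s": sel.begin, "end_s": sel.end,
            "cd_s": cd, "cd90_s": cd90, "t95_pct": t95,
            "pf_hz": pf, "lf_hz": lf, "hf_hz": hf, "fr_hz": fr,
            "condition": rec.condition, "temperature_c": rec.temperature_c,
            "rainfall": rec.rainfall,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df = compute_ici(df, seq_gap_threshold=seq_gap_threshold)
    return df


def compute_ici(calls: pd.DataFrame,
                seq_gap_threshold: float = 20.0) -> pd.DataFrame:
    """Add ICI, sequence labels and first-of-sequence flags per recording.

    ICI_k = begin_{k+1} - end_k (undefined for the last call).  A call starts
    a new sequence iff it is the recording's first call or the preceding gap
    exceeds ``seq_gap_threshold``.  ICIs that span a sequence break are set to
    NaN (they are silence, not call spacing).  Overlapping calls raise.
    """
    out = []
    for rid, grp in calls.groupby("recording_id", sort=False):
        g = grp.sort_values("begin_s").copy()
        gaps = g["begin_s"].to_numpy()[1:] - g["end_s"].to_numpy()[:-1]
        if np.any(gaps < 0):
            raise ValueError(f"overlapping calls in recording {rid!r}")
        first = np.empty(len(g), dtype=bool)
        first[0] = True
        first[1:] = gaps > seq_gap_threshold
        seq = np.cumsum(first)
        ici = np.append(gaps, np.nan)
        ici[np.append(gaps > seq_gap_threshold, False)] = np.nan
        g["ici_s"] = ici
        g["first_of_sequence"] = first
        g["sequence"] = seq
        out.append(g)
    return pd.concat(out, ignore_index=True)


def apply_inclusion_filters(table: pd.DataFrame, min_calls: int = 30,
                            drop_first: int = 5, recordings_per_male: int = 3,
                            min_calls_final: int = 25,
                            drop_brooding: bool = True,
                            seed: int = 0) -> pd.DataFrame:
    """Apply the individuality-analysis inclusion filters, in order:

    1. drop recordings made while the male was brooding (their calls differ);
    2. drop recordings with fewer than ``min_calls`` calls (original count,
       inferred from the call index so the filter is idempotent);
    3. drop each recording's first ``drop_first`` calls (onset disturbance);
    4. drop every first-of-sequence call (they are shorter and quieter);
    5. drop recordings left with fewer than ``min_calls_final`` calls, then
       males with fewer than ``recordings_per_male`` qualifying recordings,
       and sample exactly ``recordings_per_male`` recordings per male
       (seeded).

    Raises :class:`NoQualifyingDataError` when nothing survives.
    """
    df = table.copy()
    if "n_calls_orig" not in df.columns:
        # remember the original per-recording call count so that re-applying
        # the filters is a no-op (idempotence)
        df["n_calls_orig"] = (
            df.groupby("recording_id")["call_idx"].transform("max") + 1)
    if drop_brooding and "condition" in df.columns:
        df = df[df["condition"] != "brooding"]
    df = df[df["n_calls_orig"] >= min_calls]
    df = df[df["call_idx"] >= drop_first]
    if "first_of_sequence" in df.columns:
        df = df[~df["first_of_sequence"].astype(bool)]
    counts = df.groupby("recording_id")["call_idx"].transform("size")
    df = df[counts >= min_calls_final]
    if df.empty:
        raise NoQualifyingDataError("no calls qualify after inclusion filters")
    per_male = df.groupby("male_id")["recording_id"].nunique()
    keep_males = per_male[per_male >= recordings_per_male].index
    df = df[df["male_id"].isin(keep_males)]
    if df.empty:
        raise NoQualifyingDataError(
            f"no male has {recordings_per_male} qualifying recordings")
    rng = np.random.default_rng(seed)
    keep_recs = []
    for mid, grp in df.groupby("male_id", sort=True):
        recs = sorted(grp["recording_id"].unique())
        chosen = rng.choice(len(recs), size=recordings_per_male, replace=False)
        keep_recs.extend(recs[i] for i in sorted(chosen))
    return df[df["recording_id"].isin(keep_recs)].reset_index(drop=True)


def first_call_contrast(table: pd.DataFrame, duration_col: str = "cd_s",
                        amplitude_col: Optional[str] = "amp") -> dict:
    """Welch's t-tests comparing first-of-sequence calls with the rest.

    Returns ``{"duration": (t, df, p), "amplitude": (t, df, p) or None}``.
    A negative duration ``t`` means first calls are shorter.
    """
    if "first_of_sequence" not in table.columns:
        raise ValueError("first_of_sequence flags not set; run compute_ici")
    first = table["first_of_sequence"].astype(bool)
    res = {"duration": welch_t(table.loc[first, duration_col].to_numpy(),
                               table.loc[~first, duration_col].to_numpy())}
    if amplitude_col is not None and amplitude_col in table.columns:
        res["amplitude"] = welch_t(table.loc[first, amplitude_col].to_numpy(),
                                   table.loc[~first, amplitude_col].to_numpy())
    else:
        res["amplitude"] = None
    return res
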