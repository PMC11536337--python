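"""Synthetic single-note "peep" call generator with known ground truth.

The generator emulates the statistical structure of a glassfrog advertisement
call dataset: each male owns a latent mean for six base call parameters (call
duration CD, inter-call interval ICI, envelope-asymmetry T95, and the peak /
low / high frequencies PF, LF, HF), recordings add a recording-level shift,
and individual calls jitter around that.  CD90 and FR are derived quantities
(from the rendered envelope and as HF - LF).

Default calibration
-------------------
Population means and variability follow the field data for this call type
(CD ~ 64 ms, PF ~ 6.7 kHz, ICI ~ 4 s, T95 ~ 79%).  The published
within-individual CV (``CVw``) is a *within-recording* CV, while the
between-individual CV (``CVb``) is the CV of all calls pooled across males;
the defaults therefore split the excess pooled variance evenly between a
male-level and a recording-level latent component::

    within_cv    = CVw
    between_cv   = recording_cv = sqrt((CVb**2 - CVw**2) / 2)

so that a simulated dataset reproduces both published CV levels.

Calls are rendered as tonal notes whose instantaneous frequency sweeps
LF -> PF -> HF and whose raised-cosine rise/decay envelope is solved so that
the 95% cumulative-energy point falls at the target T95.  Sequence structure
(occasional long breaks; first call of a sequence shorter and quieter),
condition-dependent shifts when males call while brooding/guarding, a
temperature effect on call duration, and white Gaussian background noise are
all included and fully recorded in the ground-truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dsp import AudioRecording

__all__ = [
    "PARAMS",
    "CONDITIONS",
    "PopulationSpec",
    "draw_population",
    "synth_recording",
    "simulate_call_table",
    "simulate_male_summaries",
    "simulate_nights",
    "render_call",
    "attack_fraction_for_t95",
    "envelope",
]

#: Base (independently drawn) call parameters; CD90 and FR are derived.
PARAMS = ("cd", "ici", "t95", "pf", "lf", "hf")
CONDITIONS = ("no clutches", "guarding", "brooding")

_TABLE_MEANS = {"cd": 0.064, "ici": 4.04, "t95": 78.9,
                "pf": 6724.3, "lf": 6439.9, "hf": 7153.1}
_TABLE_CVW = {"cd": 8.08, "ici": 18.3, "t95": 5.14,
              "pf": 1.37, "lf": 1.34, "hf": 1.59}
_TABLE_CVB = {"cd": 13.67, "ici": 36.21, "t95": 9.97,
              "pf": 3.58, "lf": 2.75, "hf": 5.22}


def _split_cv(cvb: float, cvw: float) -> float:
    """Latent male/recording CV so that pooled CV reproduces ``cvb``."""
    return math.sqrt(max(cvb**2 - cvw**2, 0.0) / 2.0)


@dataclass
class PopulationSpec:
    """Population-level description of the simulated calling males.

    ``mean`` holds population means per parameter (cd, ici in s; t95 in %;
    pf, lf, hf in Hz).  ``between_cv``, ``recording_cv`` and ``within_cv``
    are latent coefficients of variation in % of the mean (SD = mean*cv/100)
    at the male, recording and call level respectively.
    """

    n_males: int = 26
    mean: Dict[str, float] = field(default_factory=lambda: dict(_TABLE_MEANS))
    between_cv: Dict[str, float] = field(default_factory=lambda: {
        p: _split_cv(_TABLE_CVB[p], _TABLE_CVW[p]) for p in PARAMS})
    recording_cv: Dict[str, float] = field(default_factory=lambda: {
        p: _split_cv(_TABLE_CVB[p], _TABLE_CVW[p]) for p in PARAMS})
    within_cv: Dict[str, float] = field(default_factory=lambda: dict(_TABLE_CVW))
    #: first call of a sequence is shorter (0.055/0.065 s) and quieter
    first_call_duration_ratio: float = 0.846
    first_call_amp_ratio: float = 0.734
    #: per-condition offsets relative to "no clutches", chosen so that the
    #: pairwise contrasts are brooding-guarding = -0.005 s (CD), +0.719 s (ICI)
    condition_cd_offset_s: Dict[str, float] = field(default_factory=lambda: {
        "no clutches": 0.0, "guarding": 0.002, "brooding": -0.003})
    condition_ici_offset_s: Dict[str, float] = field(default_factory=lambda: {
        "no clutches": 0.0, "guarding": -0.187, "brooding": 0.532})
    #: call duration shortens with ambient temperature
    temp_cd_slope_s_per_c: float = -0.0005
    temp_ref_c: float = 25.0
    temp_sd_c: float = 1.5
    rain_prob: float = 0.4
    #: probability that a call starts a new sequence (after a long break)
    seq_break_prob: float = 0.05
    seq_break_gap_s: float = 21.0
    seq_break_gap_scale_s: float = 5.0
    #: white-noise RMS in dB relative to the nominal call peak amplitude
    noise_db: float = -30.0
    amplitude: float = 0.3
    #: log-scale amplitude spread: recording level (distance 0.5-2 m varies)
    #: and call level (orientation, micro-movements)
    amp_rec_log_sd: float = 0.3
    amp_call_log_sd: float = 0.1
    sample_rate: float = 44100.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_males < 1:
            raise ValueError("n_males must be >= 1")
        for d in (self.between_cv, self.recording_cv, self.within_cv):
            for p, v in d.items():
                if v < 0:
                    raise ValueError(f"negative CV for {p}")
        m = self.mean
        if not (0 < m["lf"] < m["pf"] < m["hf"]):
            raise ValueError("frequency means must satisfy 0 < LF < PF < HF")
        for name, r in (("first_call_duration_ratio", self.first_call_duration_ratio),
                        ("first_call_amp_ratio", self.first_call_amp_ratio)):
            if not 0 < r <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Envelope: raised-cosine attack / decay with asymmetry solved from T95
# ---------------------------------------------------------------------------

def envelope(t: np.ndarray, cd: float, attack_frac: float) -> np.ndarray:
    """Raised-cosine amplitude envelope on [0, cd].

    Rises as sin^2 over ``attack_frac * cd`` and decays as cos^2 over the
    remainder; zero outside [0, cd].
    """
    a = attack_frac * cd
    d = cd - a
    t = np.asarray(t, dtype=float)
    env = np.zeros_like(t)
    rise = (t >= 0) & (t < a)
    fall = (t >= a) & (t <= cd)
    if a > 0:
        env[rise] = np.sin(0.5 * np.pi * t[rise] / a) ** 2
    if d > 0:
        env[fall] = np.cos(0.5 * np.pi * (t[fall] - a) / d) ** 2
    else:
        env[t == cd] = 1.0
    return env


def _envelope_energy_quantiles(attack_frac: float, qs=(0.05, 0.95),
                               n: int = 4096) -> np.ndarray:
    """Positions (fractions of CD) of cumulative-energy quantiles."""
    u = (np.arange(n) + 0.5) / n
    e = envelope(u, 1.0, attack_frac) ** 2
    cum = np.cumsum(e)
    cum /= cum[-1]
    return np.interp(qs, cum, u)


@lru_cache(maxsize=4096)
def _t95_of_attack(attack_frac: float) -> float:
    return float(_envelope_energy_quantiles(attack_frac, (0.95,))[0])


def t95_bounds() -> tuple:
    """Attainable T95 range (fractions) for the raised-cosine family."""
    return (_t95_of_attack(1e-4) + 1e-3, _t95_of_attack(1 - 1e-4) - 1e-3)


@lru_cache(maxsize=4096)
def attack_fraction_for_t95(t95_frac: float) -> float:
    """Solve the attack fraction whose envelope has its 95% energy point at
    ``t95_frac`` of the call duration.  Targets outside the attainable range
    are clipped to it."""
    lo, hi = t95_bounds()
    target = min(max(t95_frac, lo), hi)
    return float(brentq(lambda a: _t95_of_attack(a) - target, 1e-4, 1 - 1e-4,
                        xtol=1e-6))


def cd90_fraction(attack_frac: float) -> float:
    """CD90/CD for the given envelope asymmetry (5%..95% energy span)."""
    q05, q95 = _envelope_energy_quantiles(attack_frac)
    return float(q95 - q05)


def render_call(sample_rate: float, cd: float, pf: float, lf: float, hf: float,
                t95_frac: float, amp: float = 0.3) -> np.ndarray:
    """Render one tonal call: LF -> PF -> HF sweep under the T95 envelope.

    The instantaneous frequency passes through PF at the envelope peak, so
    the spectral maximum of the rendered call sits near PF.
    """
    n = max(int(round(cd * sample_rate)), 8)
    t = (np.arange(n) + 0.5) / sample_rate
    af = attack_fraction_for_t95(round(t95_frac, 4))
    env = envelope(t, cd, af)
    a = af * cd
    f_inst = np.where(t < a,
                      lf + (pf - lf) * np.clip(t / max(a, 1e-12), 0, 1),
                      pf + (hf - pf) * np.clip((t - a) / max(cd - a, 1e-12), 0, 1))
    phase = 2.0 * np.pi * np.cumsum(f_inst) / sample_rate
    return amp * env * np.sin(phase)


# ---------------------------------------------------------------------------
# Population and recording simulation
# ---------------------------------------------------------------------------

def _male_ids(n: int):
    return [f"M{i + 1:02d}" for i in range(n)]


def draw_population(spec: PopulationSpec,
                    rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Draw one latent mean vector per male from the population.

    Frequencies are redrawn (bounded retries) until 0 < LF < PF < HF and all
    time parameters are positive; deterministic given the spec seed.
    """
    spec.validate()
    rng = spec.rng() if rng is None else rng
    rows = []
    for mid in _male_ids(spec.n_males):
        for _ in range(1000):
            draw = {p: rng.normal(spec.mean[p],
                                  spec.mean[p] * spec.between_cv[p] / 100.0)
                    for p in PARAMS}
            if (draw["cd"] > 0 and draw["ici"] > 0 and draw["t95"] > 0
                    and 0 < draw["lf"] < draw["pf"] < draw["hf"]):
                break
        else:
            raise RuntimeError(
                "could not draw admissible latent parameters after 1000 tries")
        rows.append({"male_id": mid, **draw})
    return pd.DataFrame(rows).set_index("male_id")


def _jitter(rng, value: float, cv_pct: float, lo: float = 1e-9) -> float:
    return max(value * (1.0 + rng.normal(0.0, cv_pct / 100.0)), lo)


def _recording_effects(spec: PopulationSpec, male: pd.Series,
                       rng) -> Dict[str, float]:
    eff = {}
    for _ in range(1000):
        eff = {p: _jitter(rng, float(male[p]), spec.recording_cv[p])
               for p in PARAMS}
        if eff["lf"] < eff["pf"] < eff["hf"]:
            return eff
    raise RuntimeError("could not draw admissible recording effects")


def _draw_call_params(spec: PopulationSpec, rec_eff: Dict[str, float],
                      condition: str, temperature: float, rng,
                      first_of_sequence: bool) -> Dict[str, float]:
    for _ in range(1000):
        p = {k: _jitter(rng, rec_eff[k], spec.within_cv[k]) for k in PARAMS}
        if p["lf"] < p["pf"] < p["hf"]:
            break
    else:
        raise RuntimeError("could not draw admissible call parameters")
    p["cd"] += (spec.condition_cd_offset_s[condition]
                + spec.temp_cd_slope_s_per_c * (temperature - spec.temp_ref_c))
    p["ici"] += spec.condition_ici_offset_s[condition]
    p["cd"] = max(p["cd"], 0.005)
    p["ici"] = max(p["ici"], 0.05)
    if first_of_sequence:
        p["cd"] *= spec.first_call_duration_ratio
    lo, hi = t95_bounds()
    p["t95"] = float(np.clip(p["t95"], lo * 100 + 0.1, hi * 100 - 0.1))
    return p


def synth_recording(male: pd.Series, duration_s: float, condition: str,
                    spec: PopulationSpec, rng: np.random.Generator,
                    recording_id: str = "R001",
                    temperature_c: Optional[float] = None,
                    rainfall: Optional[bool] = None):
    """Render one recording for a male; returns (AudioRecording, truth table).

    Ground-truth rows carry the exact begin/end times and all eight true
    parameter values of every rendered call.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    fs = spec.sample_rate
    if temperature_c is None:
        temperature_c = float(rng.normal(spec.temp_ref_c, spec.temp_sd_c))
    if rainfall is None:
        rainfall = bool(rng.random() < spec.rain_prob)
    rec_eff = _recording_effects(spec, male, rng)
    rec_amp = spec.amplitude * math.exp(rng.normal(0.0, spec.amp_rec_log_sd))
    mean_ici = max(rec_eff["ici"] + spec.condition_ici_offset_s[condition], 0.1)
    if duration_s < rec_eff["cd"] + 0.6:
        raise ValueError("duration too short for even one call at this ICI")

    n = int(round(duration_s * fs))
    wave = np.zeros(n)
    rows = []
    t = 0.3 + rng.random() * min(0.4, mean_ici)
    first = True
    idx = 0
    while True:
        p = _draw_call_params(spec, rec_eff, condition, temperature_c, rng, first)
        begin, end = t, t + p["cd"]
        if end > duration_s - 0.05:
            break
        amp = (rec_amp * math.exp(rng.normal(0.0, spec.amp_call_log_sd))
               * (spec.first_call_amp_ratio if first else 1.0))
        call = render_call(fs, p["cd"], p["pf"], p["lf"], p["hf"],
                           p["t95"] / 100.0, amp)
        i0 = int(round(begin * fs))
        seg = call[:max(min(call.size, n - i0), 0)]
        wave[i0:i0 + seg.size] += seg
        af = attack_fraction_for_t95(round(p["t95"] / 100.0, 4))
        rows.append({
            "male_id": male.name, "recording_id": recording_id,
            "call_idx": idx, "begin_s": begin, "end_s": end,
            "cd_s": p["cd"], "cd90_s": p["cd"] * cd90_fraction(af),
            "t95_pct": p["t95"], "pf_hz": p["pf"], "lf_hz": p["lf"],
            "hf_hz": p["hf"], "fr_hz": p["hf"] - p["lf"], "amp": amp,
            "first_of_sequence": first, "condition": condition,
        })
        idx += 1
        if rng.random() < spec.seq_break_prob:
            gap = spec.seq_break_gap_s + rng.exponential(spec.seq_break_gap_scale_s)
            first = True
        else:
            gap = max(float(p["ici"]), 0.05)
            first = False
        t = end + gap
    truth = pd.DataFrame(rows)
    if len(truth):
        ici = truth["begin_s"].shift(-1).to_numpy() - truth["end_s"].to_numpy()
        # a gap that spans a sequence break is silence, not call spacing
        next_first = truth["first_of_sequence"].shift(-1, fill_value=True)
        ici[next_first.to_numpy(dtype=bool)] = np.nan
        truth["ici_s"] = ici  # last row NaN: no following call
    if np.isfinite(spec.noise_db):
        sigma = spec.amplitude * 10.0 ** (spec.noise_db / 20.0)
        wave += rng.normal(0.0, sigma, size=n)
    rec = AudioRecording(samples=wave, sample_rate=fs,
                         recording_id=recording_id, male_id=str(male.name),
                         condition=condition, temperature_c=temperature_c,
                         rainfall=rainfall)
    return rec, truth


def simulate_call_table(spec: PopulationSpec, n_recordings: int = 3,
                        calls_per_recording: int = 40,
                        condition_weights: Optional[Dict[str, float]] = None,
                        rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Simulate a tidy per-call truth table directly (no audio rendering).

    This is the fast path for exercising the individuality and regression
    stages at realistic sample sizes; the audio path (`synth_recording`) and
    this path share the same parameter model.
    """
    spec.validate()
    rng = spec.rng() if rng is None else rng
    if condition_weights is None:
        condition_weights = {"no clutches": 0.5, "guarding": 0.35, "brooding": 0.15}
    conds = list(condition_weights)
    w = np.array([condition_weights[c] for c in conds], dtype=float)
    w /= w.sum()
    males = draw_population(spec, rng)
    rows = []
    for mid, male in males.iterrows():
        for r in range(n_recordings):
            rid = f"{mid}_R{r + 1:02d}"
            condition = str(rng.choice(conds, p=w))
            temperature = float(rng.normal(spec.temp_ref_c, spec.temp_sd_c))
            rainfall = bool(rng.random() < spec.rain_prob)
            rec_eff = _recording_effects(spec, male, rng)
            rec_amp = spec.amplitude * math.exp(
                rng.normal(0.0, spec.amp_rec_log_sd))
            t = 0.5
            last_end = None
            for k in range(calls_per_recording):
                first = k == 0 or rng.random() < spec.seq_break_prob
                p = _draw_call_params(spec, rec_eff, condition, temperature,
                                      rng, first)
                if k > 0:
                    gap = float(p["ici"])
                    if first:
                        gap = spec.seq_break_gap_s + rng.exponential(
                            spec.seq_break_gap_scale_s)
                    t = last_end + max(gap, 0.05)
                begin, end = t, t + p["cd"]
                af = attack_fraction_for_t95(round(p["t95"] / 100.0, 4))
                rows.append({
                    "male_id": mid, "recording_id": rid, "call_idx": k,
                    "begin_s": begin, "end_s": end,
                    "cd_s": p["cd"], "cd90_s": p["cd"] * cd90_fraction(af),
                    "t95_pct": p["t95"], "pf_hz": p["pf"], "lf_hz": p["lf"],
                    "hf_hz": p["hf"], "fr_hz": p["hf"] - p["lf"],
                    "amp": (rec_amp
                            * math.exp(rng.normal(0.0, spec.amp_call_log_sd))
                            * (spec.first_call_amp_ratio if first else 1.0)),
                    "first_of_sequence": first, "condition": condition,
                    "temperature_c": temperature, "rainfall": rainfall,
                })
                last_end = end
    df = pd.DataFrame(rows)
    grp = df.groupby("recording_id", sort=False)
    df["ici_s"] = grp["begin_s"].shift(-1) - df["end_s"]
    # gaps spanning a sequence break (or the end of the recording) are not ICIs
    next_first = grp["first_of_sequence"].shift(-1, fill_value=True)
    df.loc[next_first.to_numpy(dtype=bool), "ici_s"] = np.nan
    return df


# ---------------------------------------------------------------------------
# Behavioral-stage simulators (male summaries, nightly observations)
# ---------------------------------------------------------------------------

def simulate_male_summaries(spec: Optional[PopulationSpec] = None,
                            beta_cd: float = 73.0,
                            base_clutches: float = 4.7,
                            body_size_mean_mm: float = 22.0,
                            body_size_sd_mm: float = 1.2,
                            rng: Optional[np.random.Generator] = None
                            ) -> pd.DataFrame:
    """Per-male summary table with Poisson-distributed total mating success.

    Total clutch counts follow log E[clutches] = log(base) + beta_cd*(CD - mean
    CD); other call parameters and body size have no effect by construction,
    matching the study-scale effect of call duration on total mating success.
    """
    spec = PopulationSpec() if spec is None else spec
    rng = spec.rng() if rng is None else rng
    males = draw_population(spec, rng)
    body = rng.normal(body_size_mean_mm, body_size_sd_mm, size=len(males))
    eta = math.log(base_clutches) + beta_cd * (males["cd"].to_numpy()
                                               - spec.mean["cd"])
    clutches = rng.poisson(np.exp(eta))
    return pd.DataFrame({
        "male_id": males.index,
        "body_size_mm": body,
        "cd_s": males["cd"].to_numpy(),
        "ici_s": males["ici"].to_numpy(),
        "t95_pct": males["t95"].to_numpy(),
        "pf_hz": males["pf"].to_numpy(),
        "fr_hz": (males["hf"] - males["lf"]).to_numpy(),
        "total_clutches": clutches,
    })


def simulate_nights(n_males: int = 48, n_nights: int = 30,
                    beta0: float = -5.2894, beta_calling: float = 3.5396,
                    beta_clutch: float = 0.5671, sigma_male: float = 1.0,
                    p_calling: float = 0.7, p_clutch: float = 0.5,
                    rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Nightly observation table for the binomial mixed-model stage.

    Mating success on a night follows a logit model with the configured
    calling and clutch-presence effects and a per-male random intercept.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    b = rng.normal(0.0, sigma_male, size=n_males)
    rows = []
    for i, mid in enumerate(_male_ids(n_males)):
        calling = (rng.random(n_nights) < p_calling).astype(int)
        clutch = (rng.random(n_nights) < p_clutch).astype(int)
        eta = beta0 + beta_calling * calling + beta_clutch * clutch + b[i]
        success = (rng.random(n_nights) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
        for night in range(n_nights):
            rows.append({"male_id": mid, "night": night,
                         "calling": int(calling[night]),
                         "clutch_present": int(clutch[night]),
                         "mating_success": int(success[night])})
    return pd.DataFrame(rows)
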