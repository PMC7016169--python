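"""Synthetic 12-lead ECG generation with exact ground truth.

Each beat is a sum of Gaussian bumps for the P, Q, R, S and T waves
(a McSharry-style morphology without the dynamical system), placed at
R-peak times drawn from a rhythm model.  Leads I and II are synthesized
from independent wave-amplitude sets; the four derived limb leads are
constructed to satisfy the Einthoven/Goldberger identities exactly

    III = II - I,   aVR = -(I + II)/2,   aVL = I - II/2,   aVF = II - I/2,

and the precordial leads V1-V6 are affine combinations of I and II with a
progressive R-wave transition.  Because the identities hold by construction
and R-peak sample indices are returned exactly, every downstream stage
(denoising efficacy, QC discrimination, peak assignment) can be tested
against known truth.

Noise emulates the contamination sources present in clinical recordings:
power-line interference, baseline wander (sub-0.5 Hz sinusoids plus an
optional random-walk term), broadband white noise and band-limited muscle
artifact.  Noise is drawn independently per lead from a seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .io import CANONICAL_LEADS, DiagnosticsRow, ECGRecord


@dataclass(frozen=True)
class Wave:
    """One Gaussian bump: amplitude (uV), center offset from R (s), width (s)."""

    amplitude_uv: float
    center_s: float
    width_s: float

    def __post_init__(self) -> None:
        if self.width_s <= 0:
            raise ValueError("wave width must be positive")


@dataclass(frozen=True)
class BeatTemplate:
    """P/Q/R/S/T wave components of one beat, summed as Gaussian bumps."""

    p: Wave
    q: Wave
    r: Wave
    s: Wave
    t: Wave

    def __post_init__(self) -> None:
        if not (self.r.amplitude_uv > abs(self.q.amplitude_uv)
                and self.r.amplitude_uv > abs(self.s.amplitude_uv)):
            raise ValueError("R amplitude must dominate |Q| and |S| amplitudes")

    def waves(self, include_p: bool = True) -> tuple[Wave, ...]:
        ws = (self.q, self.r, self.s, self.t)
        return ((self.p,) + ws) if include_p else ws


#: Default lead-II morphology (amplitudes in uV, offsets/widths in s).
#: Widths are Gaussian SDs; they are chosen so the waves span realistic
#: durations (P ~ 120 ms, QRS ~ 70 ms, T ~ 200 ms) and the signal returns
#: to a true isoelectric baseline between beats.
LEAD_II_TEMPLATE = BeatTemplate(
    p=Wave(120.0, -0.17, 0.020),
    q=Wave(-100.0, -0.040, 0.010),
    r=Wave(1000.0, 0.0, 0.012),
    s=Wave(-180.0, 0.040, 0.012),
    t=Wave(280.0, 0.28, 0.035),
)

#: Default lead-I morphology: independent amplitude set, same wave timing.
LEAD_I_TEMPLATE = BeatTemplate(
    p=Wave(70.0, -0.17, 0.020),
    q=Wave(-60.0, -0.040, 0.010),
    r=Wave(600.0, 0.0, 0.012),
    s=Wave(-90.0, 0.040, 0.012),
    t=Wave(180.0, 0.28, 0.035),
)

# Precordial leads as affine combinations a*I + b*II (R-wave transition V1->V6).
_PRECORDIAL_COEF = {
    "V1": (-0.40, 0.20),
    "V2": (-0.20, 0.45),
    "V3": (0.05, 0.65),
    "V4": (0.30, 0.85),
    "V5": (0.50, 0.95),
    "V6": (0.60, 1.00),
}


@dataclass(frozen=True)
class RhythmSpec:
    """Heart-rate / RR-interval model for one record.

    ``rr_model`` is one of ``constant`` (metronomic), ``jitter`` (Gaussian
    RR perturbation with SD ``rr_sd_s``) or ``irregular``
    (irregularly-irregular RR train, P waves typically absent, emulating
    atrial fibrillation at the signal level).
    """

    mean_hr_bpm: float = 75.0
    rr_model: str = "jitter"
    rr_sd_s: float = 0.03
    p_wave: bool = True

    def __post_init__(self) -> None:
        if not 20.0 < self.mean_hr_bpm < 300.0:
            raise ValueError("mean heart rate must be in (20, 300) BPM")
        if self.rr_sd_s < 0:
            raise ValueError("RR SD must be >= 0")
        if self.rr_model not in ("constant", "jitter", "irregular"):
            raise ValueError(f"unknown rr_model {self.rr_model!r}")


#: Rhythm presets used by the CLI: sinus rhythm, bradycardia, tachycardia,
#: and an AFIB-like irregularly-irregular train without P waves.
RHYTHM_PRESETS = {
    "sr": RhythmSpec(mean_hr_bpm=75.0, rr_model="jitter", rr_sd_s=0.03),
    "sb": RhythmSpec(mean_hr_bpm=50.0, rr_model="jitter", rr_sd_s=0.03),
    "st": RhythmSpec(mean_hr_bpm=120.0, rr_model="jitter", rr_sd_s=0.02),
    "afib": RhythmSpec(mean_hr_bpm=110.0, rr_model="irregular", p_wave=False),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Additive contamination model, all amplitudes in uV.

    ``wander`` is a list of (frequency Hz, amplitude uV) sinusoids, all below
    0.5 Hz; ``wander_walk_uv`` adds a smoothed random-walk drift with the
    given RMS amplitude.  Muscle artifact is white noise band-passed to
    20-120 Hz and rescaled to ``muscle_sd_uv``.
    """

    powerline_hz: float = 50.0
    powerline_uv: float = 0.0
    wander: tuple[tuple[float, float], ...] = ()
    wander_walk_uv: float = 0.0
    white_sd_uv: float = 0.0
    muscle_sd_uv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.powerline_uv < 0 or self.white_sd_uv < 0 or self.muscle_sd_uv < 0:
            raise ValueError("noise amplitudes must be >= 0")
        for f, a in self.wander:
            if a < 0:
                raise ValueError("wander amplitudes must be >= 0")
            if f >= 0.5:
                raise ValueError("baseline wander components must be below 0.5 Hz")

    def is_zero(self) -> bool:
        return (self.powerline_uv == 0 and self.white_sd_uv == 0
                and self.muscle_sd_uv == 0 and self.wander_walk_uv == 0
                and all(a == 0 for _, a in self.wander))


#: Noise presets; `full` is the study condition for denoising efficacy:
#: wander-dominated contamination as in ambulatory recordings.
NOISE_PRESETS = {
    "clean": NoiseSpec(),
    "powerline": NoiseSpec(powerline_uv=50.0),
    "wander": NoiseSpec(wander=((0.15, 300.0), (0.30, 150.0), (0.45, 75.0))),
    "full": NoiseSpec(
        powerline_uv=50.0,
        wander=((0.15, 300.0), (0.30, 150.0), (0.45, 75.0)),
        white_sd_uv=20.0,
        muscle_sd_uv=20.0,
    ),
}


def noise_preset(name: str, seed: int = 0) -> NoiseSpec:
    try:
        spec = NOISE_PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown noise preset {name!r}; "
                         f"choose from {sorted(NOISE_PRESETS)}") from None
    return replace(spec, seed=seed)


def _rr_intervals(rhythm: RhythmSpec, duration_s: float, rng: np.random.Generator) -> np.ndarray:
    """Draw RR intervals (seconds) covering at least ``duration_s``."""
    mean_rr = 60.0 / rhythm.mean_hr_bpm
    n = int(math.ceil(duration_s / mean_rr)) + 3
    if rhythm.rr_model == "constant":
        rr = np.full(n, mean_rr)
    elif rhythm.rr_model == "jitter":
        rr = rng.normal(mean_rr, rhythm.rr_sd_s, size=n)
    else:  # irregular: wide uniform spread, no serial correlation
        rr = mean_rr * rng.uniform(0.65, 1.35, size=n)
    return np.clip(rr, 0.25 * mean_rr, 2.0 * mean_rr)


def _render_beats(template: BeatTemplate, r_idx: np.ndarray, n: int, fs: float,
                  include_p: bool) -> np.ndarray:
    t = np.arange(n) / fs
    x = np.zeros(n)
    for r in r_idx:
        tr = r / fs
        for w in template.waves(include_p):
            x += w.amplitude_uv * np.exp(-0.5 * ((t - tr - w.center_s) / w.width_s) ** 2)
    return x


def generate_clean_record(
    rhythm: RhythmSpec = RHYTHM_PRESETS["sr"],
    template_i: BeatTemplate = LEAD_I_TEMPLATE,
    template_ii: BeatTemplate = LEAD_II_TEMPLATE,
    duration_s: float = 10.0,
    fs: float = 500.0,
    seed: int = 0,
    record_id: str = "SYN0",
) -> tuple[ECGRecord, np.ndarray]:
    """Generate a noise-free 12-lead record plus exact R-peak indices.

    R-peak times are rounded to the sample grid before rendering, so the
    returned indices coincide exactly with the rendered wave centers.  The
    derived limb leads satisfy the lead identities to machine precision.
    """
    n_float = duration_s * fs
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9:
        raise ValueError(f"duration_s * fs = {n_float} is not an integer sample count")
    rng = np.random.default_rng(seed)

    rr = _rr_intervals(rhythm, duration_s, rng)
    r_times = 0.30 + np.cumsum(np.concatenate([[0.0], rr]))
    r_idx = np.round(r_times * fs).astype(int)
    r_idx = r_idx[r_idx < n]

    lead_i = _render_beats(template_i, r_idx, n, fs, include_p=rhythm.p_wave)
    lead_ii = _render_beats(template_ii, r_idx, n, fs, include_p=rhythm.p_wave)

    columns = {
        "I": lead_i,
        "II": lead_ii,
        "III": lead_ii - lead_i,
        "aVR": -(lead_i + lead_ii) / 2.0,
        "aVL": lead_i - lead_ii / 2.0,
        "aVF": lead_ii - lead_i / 2.0,
    }
    for name, (a, b) in _PRECORDIAL_COEF.items():
        columns[name] = a * lead_i + b * lead_ii
    samples = np.column_stack([columns[name] for name in CANONICAL_LEADS])
    record = ECGRecord(record_id=record_id, fs=fs, leads=CANONICAL_LEADS, samples=samples)
    return record, r_idx


def _muscle_noise(n: int, fs: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    raw = rng.normal(0.0, 1.0, size=n)
    hi = min(120.0, 0.45 * fs)
    sos = sps.butter(4, [20.0 / (fs / 2), hi / (fs / 2)], btype="band", output="sos")
    band = sps.sosfiltfilt(sos, raw)
    scale = band.std()
    return sd * band / scale if scale > 0 else np.zeros(n)


def add_noise(record: ECGRecord, noise: NoiseSpec) -> ECGRecord:
    """Add the contamination model to every lead, independently per lead.

    A zero-amplitude spec is the identity.  Repeated calls with the same
    spec (including seed) are bitwise identical.
    """
    if noise.is_zero():
        return record.copy()
    rng = np.random.default_rng(noise.seed)
    n, fs = record.n_samples, record.fs
    t = np.arange(n) / fs
    out = record.samples.copy()
    for j in range(len(record.leads)):
        lead_noise = np.zeros(n)
        if noise.powerline_uv > 0:
            phase = rng.uniform(0, 2 * np.pi)
            lead_noise += noise.powerline_uv * np.sin(2 * np.pi * noise.powerline_hz * t + phase)
        for f, a in noise.wander:
            if a > 0:
                phase = rng.uniform(0, 2 * np.pi)
                lead_noise += a * np.sin(2 * np.pi * f * t + phase)
        if noise.wander_walk_uv > 0:
            walk = np.cumsum(rng.normal(0, 1, size=n))
            # heavy smoothing keeps the walk below the 0.5 Hz wander band
            win = max(int(fs), 2)
            kernel = np.ones(win) / win
            walk = np.convolve(walk, kernel, mode="same")
            sd = walk.std()
            if sd > 0:
                lead_noise += noise.wander_walk_uv * walk / sd
        if noise.white_sd_uv > 0:
            lead_noise += rng.normal(0, noise.white_sd_uv, size=n)
        if noise.muscle_sd_uv > 0:
            lead_noise += _muscle_noise(n, fs, noise.muscle_sd_uv, rng)
        out[:, j] += lead_noise
    return record.with_samples(out)


CORRUPTION_MODES = ("flatline_lead", "break_einthoven", "swap_arm_electrodes")


def corrupt(record: ECGRecord, mode: str, lead: str = "II", seed: int = 0) -> ECGRecord:
    """Apply one QC failure mode.

    ``flatline_lead`` replaces the chosen lead by a constant (electrode
    slipped off); ``break_einthoven`` adds independent noise to one limb
    lead only, breaking the lead-II identity; ``swap_arm_electrodes``
    applies the algebra of an LA/RA electrode swap: lead I negated, II and
    III exchanged, aVR and aVL exchanged (the augmented-lead sum identity
    survives the swap).
    """
    if mode not in CORRUPTION_MODES:
        raise ValueError(f"unknown corruption mode {mode!r}; choose from {CORRUPTION_MODES}")
    out = record.samples.copy()
    leads = record.leads

    def col(name: str) -> int:
        return leads.index(name)

    if mode == "flatline_lead":
        out[:, col(lead)] = float(np.median(out[:, col(lead)]))
    elif mode == "break_einthoven":
        rng = np.random.default_rng(seed)
        out[:, col(lead)] += rng.normal(0, 100.0, size=record.n_samples)
    else:  # swap_arm_electrodes
        i, ii, iii = col("I"), col("II"), col("III")
        avr, avl = col("aVR"), col("aVL")
        src = record.samples
        out[:, i] = -src[:, i]
        out[:, ii] = src[:, iii]
        out[:, iii] = src[:, ii]
        out[:, avr] = src[:, avl]
        out[:, avl] = src[:, avr]
    return record.with_samples(out)


def synthetic_diagnostics(
    record: ECGRecord,
    r_peaks: np.ndarray,
    rhythm_label: str = "SR",
    age: float = 60.0,
    gender: str = "MALE",
) -> DiagnosticsRow:
    """Metadata row for a synthetic record.

    Signal-derivable fields (rates, QRS count) come from the exact ground
    truth; vendor-only measurements that the generator does not model
    (axes, QT) are left absent.
    """
    r_peaks = np.asarray(r_peaks)
    rr_s = np.diff(r_peaks) / record.fs
    rate = 60.0 / rr_s.mean() if rr_s.size else None
    return DiagnosticsRow(
        FileName=record.record_id,
        Rhythm=rhythm_label,
        Beat="NONE",
        PatientAge=float(age),
        Gender=gender,
        VentricularRate=None if rate is None else round(rate, 1),
        AtrialRate=None if rate is None else round(rate, 1),
        QRSCount=float(len(r_peaks)),
        QOnset=float(r_peaks[0]) if len(r_peaks) else None,
        QOffset=float(r_peaks[0] + 0.05 * record.fs) if len(r_peaks) else None,
    )
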