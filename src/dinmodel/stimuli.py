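"""Synthetic spoken-digit stimuli and calibrated digit-in-noise mixtures.

This module stands in for a licensed spoken-digit corpus: each of the ten
digit classes is generated from a hand-designed template of 2-3 acoustic
segments (formant-trajectory "vowels" synthesised additively from a harmonic
source, and band-limited noise bursts for consonant-like onsets/codas).
A :class:`TalkerProfile` perturbs the fundamental frequency and the formant
scale so that many distinct "talkers" can be realised deterministically.

Levels follow a fixed digital-to-pascal convention: a digital amplitude of
1.0 corresponds to 1 Pa, i.e. full-scale RMS of 1.0 is 94 dB SPL re 20 uPa.
All dB SPL computations in the package use this mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

__all__ = [
    "P_REF_PA",
    "DigitToken",
    "NoisyStimulus",
    "TalkerProfile",
    "measure_level_db_spl",
    "set_level",
    "synthesize_digit",
    "mix_with_noise",
    "build_stimulus_grid",
    "make_talkers",
    "read_wav",
    "write_wav",
    "DIGIT_TEMPLATES",
]

#: Reference pressure, 20 micropascal. Digital amplitude 1.0 == 1 Pa RMS == 94 dB SPL.
P_REF_PA = 20e-6

#: Default synthesis rate. 16 kHz covers the 100 Hz - 8 kHz cochlear grid at Nyquist;
#: the periphery upsamples internally where it needs headroom above 8 kHz.
DEFAULT_SAMPLE_RATE = 16_000


@dataclass(frozen=True)
class TalkerProfile:
    """A synthetic talker: fundamental frequency, vocal-tract length proxy, seed.

    Identical profile and seed produce bit-identical tokens.
    """

    f0_hz: float
    formant_scale: float
    seed: int

    def __post_init__(self) -> None:
        if not (50.0 <= self.f0_hz <= 400.0):
            raise ValueError(f"f0_hz {self.f0_hz} outside plausible speech range")
        if not (0.7 <= self.formant_scale <= 1.4):
            raise ValueError("formant_scale outside [0.7, 1.4]")


@dataclass
class DigitToken:
    """A single calibrated spoken-digit waveform."""

    samples: np.ndarray
    sample_rate: int
    digit: int
    talker_id: int
    level_db_spl: float
    duration_s: float = field(init=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("token samples must be finite")
        self.duration_s = len(self.samples) / self.sample_rate


@dataclass
class NoisyStimulus:
    """A digit token mixed with flat-spectrum white noise at a stated level."""

    samples: np.ndarray
    sample_rate: int
    digit: int
    talker_id: int
    speech_level_db_spl: float
    noise_level_db_spl: float

    @property
    def snr_db(self) -> float:
        return self.speech_level_db_spl - self.noise_level_db_spl


def measure_level_db_spl(samples: np.ndarray) -> float:
    """Sound pressure level of a digital waveform under the 1.0 == 1 Pa convention."""
    rms = float(np.sqrt(np.mean(np.square(np.asarray(samples, dtype=np.float64)))))
    if rms <= 0.0:
        raise ValueError("cannot measure the level of an all-zero signal")
    return 20.0 * np.log10(rms / P_REF_PA)


def set_level(samples: np.ndarray, target_db_spl: float) -> np.ndarray:
    """Rescale a waveform so its RMS corresponds to ``target_db_spl``.

    The gain is purely multiplicative, so the waveform shape is preserved.
    All-zero input has no defined gain and is rejected.
    """
    samples = np.asarray(samples, dtype=np.float64)
    current = measure_level_db_spl(samples)
    gain = 10.0 ** ((target_db_spl - current) / 20.0)
    return samples * gain


# ---------------------------------------------------------------------------
# Digit templates
# ---------------------------------------------------------------------------
# Each template is a list of segments. A "vowel" segment carries linear
# formant trajectories (F1, F2 in Hz, start -> end); F3/F4 are fixed fill
# formants. A "noise" segment is a band-passed white-noise burst. Durations
# are seconds; amplitudes are relative within the token (the whole token is
# re-calibrated afterwards). The formant patterns are caricatures of the
# English digit names, chosen to be well separated in (F1, F2) space.

DIGIT_TEMPLATES: dict[int, list[dict]] = {
    0: [  # "zero": voiced fricative onset, front vowel, back rounded coda
        {"kind": "noise", "band": (3000, 6500), "dur": 0.08, "amp": 0.35},
        {"kind": "vowel", "f1": (400, 320), "f2": (1900, 2250), "dur": 0.20, "amp": 1.0},
        {"kind": "vowel", "f1": (520, 480), "f2": (950, 850), "dur": 0.18, "amp": 0.9},
    ],
    1: [  # "one": back glide into low-central vowel, nasal-like coda
        {"kind": "vowel", "f1": (380, 750), "f2": (800, 1050), "dur": 0.26, "amp": 1.0},
        {"kind": "vowel", "f1": (300, 280), "f2": (950, 900), "dur": 0.16, "amp": 0.7},
    ],
    2: [  # "two": alveolar burst, high back rounded vowel
        {"kind": "noise", "band": (2500, 5000), "dur": 0.06, "amp": 0.5},
        {"kind": "vowel", "f1": (330, 310), "f2": (950, 700), "dur": 0.30, "amp": 1.0},
    ],
    3: [  # "three": dental fricative (high, narrow band), high front vowel
        {"kind": "noise", "band": (5500, 7800), "dur": 0.09, "amp": 0.4},
        {"kind": "vowel", "f1": (290, 270), "f2": (2250, 2400), "dur": 0.28, "amp": 1.0},
    ],
    4: [  # "four": labiodental fricative, open-mid back vowel with r-coloring
        {"kind": "noise", "band": (1500, 4000), "dur": 0.08, "amp": 0.4},
        {"kind": "vowel", "f1": (580, 520), "f2": (980, 800), "dur": 0.30, "amp": 1.0},
    ],
    5: [  # "five": fricative onset, wide diphthong
        {"kind": "noise", "band": (2000, 5500), "dur": 0.08, "amp": 0.4},
        {"kind": "vowel", "f1": (760, 360), "f2": (1150, 2050), "dur": 0.32, "amp": 1.0},
    ],
    6: [  # "six": sibilant - short front vowel - sibilant
        {"kind": "noise", "band": (4000, 7200), "dur": 0.10, "amp": 0.5},
        {"kind": "vowel", "f1": (420, 400), "f2": (1950, 1900), "dur": 0.14, "amp": 1.0},
        {"kind": "noise", "band": (4000, 7200), "dur": 0.11, "amp": 0.5},
    ],
    7: [  # "seven": sibilant onset (lower band), two mid vowels (disyllabic)
        {"kind": "noise", "band": (2500, 5200), "dur": 0.09, "amp": 0.5},
        {"kind": "vowel", "f1": (600, 580), "f2": (1750, 1700), "dur": 0.16, "amp": 1.0},
        {"kind": "vowel", "f1": (480, 440), "f2": (1200, 1100), "dur": 0.15, "amp": 0.85},
    ],
    8: [  # "eight": closing front diphthong, stop gap, release burst
        {"kind": "vowel", "f1": (520, 350), "f2": (2000, 2400), "dur": 0.26, "amp": 1.0},
        {"kind": "silence", "dur": 0.05},
        {"kind": "noise", "band": (3000, 6000), "dur": 0.05, "amp": 0.45},
    ],
    9: [  # "nine": nasal onset glide, open-to-close diphthong, nasal coda
        {"kind": "vowel", "f1": (700, 420), "f2": (1300, 2100), "dur": 0.30, "amp": 1.0},
        {"kind": "vowel", "f1": (340, 320), "f2": (1600, 1550), "dur": 0.13, "amp": 0.7},
    ],
}

_FILL_FORMANTS = ((2850.0, 200.0, 0.25), (3600.0, 280.0, 0.12))  # (freq, bw, gain)
_FORMANT_BWS = (90.0, 120.0)  # F1, F2 bandwidths, Hz


def _formant_envelope(freqs: np.ndarray, f1: np.ndarray, f2: np.ndarray,
                      scale: float) -> np.ndarray:
    """Spectral amplitude at ``freqs`` for time-varying formants (resonance peaks)."""
    env = np.zeros(np.broadcast_shapes(freqs.shape, f1.shape))
    for fc, bw, g in ((f1, _FORMANT_BWS[0] * scale, 1.0),
                      (f2, _FORMANT_BWS[1] * scale, 0.7)):
        env = env + g / (1.0 + ((freqs - fc) / bw) ** 2)
    for fc, bw, g in _FILL_FORMANTS:
        env = env + g / (1.0 + ((freqs - fc * scale) / bw) ** 2)
    return env


def _raised_cosine_envelope(n: int, sample_rate: int, ramp_s: float = 0.015) -> np.ndarray:
    ramp = min(int(ramp_s * sample_rate), max(n // 4, 1))
    env = np.ones(n)
    win = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp) / ramp))
    env[:ramp] = win
    env[n - ramp:] = win[::-1]
    return env


def _synth_vowel(seg: dict, f0: float, scale: float, sample_rate: int,
                 dur_jitter: float) -> np.ndarray:
    dur = seg["dur"] * dur_jitter
    n = int(round(dur * sample_rate))
    t = np.arange(n) / sample_rate
    # F0 declination over the segment, a universal feature of natural speech
    f0_traj = f0 * (1.0 - 0.12 * t / max(dur, 1e-9))
    f1 = scale * np.linspace(seg["f1"][0], seg["f1"][1], n)
    f2 = scale * np.linspace(seg["f2"][0], seg["f2"][1], n)

    n_harm = max(int(5000.0 / f0), 3)
    phase_base = 2.0 * np.pi * np.cumsum(f0_traj) / sample_rate
    out = np.zeros(n)
    for h in range(1, n_harm + 1):
        freq = h * f0_traj
        amp = _formant_envelope(freq, f1, f2, scale) / h ** 0.3
        out += amp * np.sin(h * phase_base)
    return seg["amp"] * _raised_cosine_envelope(n, sample_rate) * out / max(
        np.max(np.abs(out)), 1e-12)


def _synth_noise_burst(seg: dict, scale: float, sample_rate: int,
                       dur_jitter: float, rng: np.random.Generator) -> np.ndarray:
    dur = seg["dur"] * dur_jitter
    n = int(round(dur * sample_rate))
    lo, hi = seg["band"]
    lo, hi = lo * scale, min(hi * scale, 0.49 * sample_rate)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=sample_rate, output="sos")
    burst = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return seg["amp"] * _raised_cosine_envelope(n, sample_rate, 0.01) * burst / max(
        np.max(np.abs(burst)), 1e-12)


def synthesize_digit(digit: int, talker: TalkerProfile,
                     sample_rate: int = DEFAULT_SAMPLE_RATE,
                     level_db_spl: float = 70.0,
                     utterance: int = 0) -> DigitToken:
    """Render one spoken-digit token for a talker, calibrated to ``level_db_spl``.

    Deterministic: the same (digit, talker, sample_rate, utterance) always
    yields the identical sample vector; distinct ``utterance`` indices give the
    same talker slightly different renditions (jitter draws). Duration stays
    within [0.3, 0.7] s by template construction.
    """
    if digit not in DIGIT_TEMPLATES:
        raise ValueError(f"digit must be 0-9, got {digit!r}")
    if sample_rate < 16_000:
        raise ValueError("sample_rate must be >= 16 kHz")

    rng = np.random.default_rng([int(talker.seed) & 0x7FFFFFFF, digit,
                                 int(utterance), 0x5D])
    f0 = talker.f0_hz * (1.0 + 0.03 * (rng.uniform() - 0.5) * 2.0)
    pieces = []
    for seg in DIGIT_TEMPLATES[digit]:
        dur_jitter = 1.0 + 0.05 * (rng.uniform() - 0.5) * 2.0
        if seg["kind"] == "vowel":
            pieces.append(_synth_vowel(seg, f0, talker.formant_scale,
                                       sample_rate, dur_jitter))
        elif seg["kind"] == "noise":
            pieces.append(_synth_noise_burst(seg, talker.formant_scale,
                                             sample_rate, dur_jitter, rng))
        else:  # silence (stop gap)
            pieces.append(np.zeros(int(round(seg["dur"] * dur_jitter * sample_rate))))
    samples = set_level(np.concatenate(pieces), level_db_spl)
    token = DigitToken(samples=samples, sample_rate=sample_rate, digit=digit,
                       talker_id=talker.seed, level_db_spl=level_db_spl)
    assert 0.3 <= token.duration_s <= 0.7, "template durations out of contract"
    return token


def mix_with_noise(token: DigitToken, noise_level_db_spl: float, seed: int,
                   total_duration_s: float = 0.7) -> NoisyStimulus:
    """Add flat-spectrum white Gaussian noise at a calibrated level.

    The token is placed at the start of a ``total_duration_s`` window (default
    700 ms, the neurogram length) and noise fills the whole window, so tokens
    shorter than the window end in noise alone.
    """
    if not (0.0 <= noise_level_db_spl <= 100.0):
        raise ValueError("noise level must lie in [0, 100] dB SPL")
    n_total = max(int(round(total_duration_s * token.sample_rate)), len(token.samples))
    speech = np.zeros(n_total)
    speech[: len(token.samples)] = token.samples
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0xA3])
    noise_rms_pa = P_REF_PA * 10.0 ** (noise_level_db_spl / 20.0)
    noise = rng.standard_normal(n_total) * noise_rms_pa
    return NoisyStimulus(
        samples=speech + noise,
        sample_rate=token.sample_rate,
        digit=token.digit,
        talker_id=token.talker_id,
        speech_level_db_spl=token.level_db_spl,
        noise_level_db_spl=noise_level_db_spl,
    )


def make_talkers(n_talkers: int, seed: int = 0) -> list[TalkerProfile]:
    """A deterministic roster of talker profiles.

    Roughly half the roster gets male-like fundamentals (100-145 Hz, formant
    scale below 1) and half female-like (175-240 Hz, scale above 1), echoing a
    mixed-gender corpus.
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x7A])
    talkers = []
    for i in range(n_talkers):
        if i % 2 == 0:
            f0 = rng.uniform(100.0, 145.0)
            scale = rng.uniform(0.94, 1.02)
        else:
            f0 = rng.uniform(175.0, 240.0)
            scale = rng.uniform(1.02, 1.14)
        talkers.append(TalkerProfile(f0_hz=float(f0), formant_scale=float(scale), seed=i))
    return talkers


def build_stimulus_grid(n_talkers: int, utterances_per_digit: int,
                        noise_levels_db_spl,
                        speech_level_db_spl: float = 70.0,
                        seed: int = 0) -> pd.DataFrame:
    """Manifest of every digit+noise stimulus in a full factorial grid.

    Rows = n_talkers x utterances_per_digit x 10 digits x len(noise_levels).
    Nothing is rendered; each row carries the parameters and the noise seed
    needed to synthesise its waveform reproducibly.
    """
    noise_levels = list(noise_levels_db_spl)
    if n_talkers <= 0 or utterances_per_digit <= 0 or not noise_levels:
        raise ValueError("all grid counts must be positive")
    rows = []
    k = 0
    for talker in range(n_talkers):
        for digit in range(10):
            for utt in range(utterances_per_digit):
                for noise_db in noise_levels:
                    rows.append({
                        "talker_id": talker,
                        "digit": digit,
                        "utterance": utt,
                        "speech_db": speech_level_db_spl,
                        "noise_db": float(noise_db),
                        "snr_db": speech_level_db_spl - float(noise_db),
                        "seed": (seed * 1_000_003 + k) % (2**31 - 1),
                    })
                    k += 1
    return pd.DataFrame(rows)


def write_wav(path, samples: np.ndarray, sample_rate: int) -> None:
    """Write a mono float32 WAV (digital pascal convention preserved)."""
    wavfile.write(path, sample_rate, np.asarray(samples, dtype=np.float32))


def read_wav(path) -> tuple[np.ndarray, int]:
    sample_rate, data = wavfile.read(path)
    return np.asarray(data, dtype=np.float64), int(sample_rate)
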