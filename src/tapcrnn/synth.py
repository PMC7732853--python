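"""Synthetic phonocardiogram (PCG) generation and WAV I/O.

The simulator produces 10-second clips that mimic the gross acoustic
structure of auscultation recordings: periodic S1/S2 transients (short,
exponentially decaying low-frequency tone bursts) over a broadband noise
floor, with — for the murmur class — band-limited Gaussian noise filling
each S1→S2 (systolic) interval, the signature of a holosystolic murmur
such as the one produced by a ventricular septal defect.

Every clip carries ground-truth systolic intervals so that frame-level
attention explanations can be scored against known murmur locations.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

SITES = ("aortic", "pulmonic", "erb", "tricuspid", "mitral")
LABELS = ("normal", "murmur")

#: Relative murmur loudness per auscultation site. A VSD murmur is loudest
#: at the lower left sternal border (tricuspid area / Erb's point) and
#: attenuated toward the base and apex.
SITE_MURMUR_GAIN = {
    "aortic": 0.60,
    "pulmonic": 0.70,
    "erb": 1.00,
    "tricuspid": 1.00,
    "mitral": 0.70,
}


class SynthConfigError(ValueError):
    """Raised for physically inconsistent simulator settings."""


@dataclass(frozen=True)
class SynthConfig:
    """Simulator settings.

    Parameters
    ----------
    rate : int
        Sampling rate in Hz. Heart sounds live below ~1 kHz, so 4000 Hz
        keeps a 512-sample analysis frame at 128 ms.
    duration : float
        Clip length in seconds.
    heart_rate_bpm : float
        Beats per minute; one S1 and one S2 per beat.
    s1_s2_gap_fraction : float
        Fraction of the cardiac cycle between S1 onset and S2 onset
        (the systolic interval).
    murmur_band : tuple of float
        (low, high) passband in Hz of the murmur noise.
    murmur_snr_db : float
        Murmur RMS over the RMS of the total background (white floor
        plus ambient) measured within ``murmur_band``, in dB, before
        the per-site gain is applied — the level an auscultator
        competes against where the murmur lives. 10 dB gives clearly
        audible murmurs; 0 dB puts the murmur at the in-band
        background level.
    background_noise_db : float
        White background-noise RMS in dB relative to the unit S1 peak.
    ambient_noise_db : float
        RMS of a continuous colored ambient component (band-limited to
        ``ambient_band``), in dB relative to the unit S1 peak. Emulates
        room rumble and airflow that overlap murmur frequencies, so that
        a murmur is identified by its timing within the cardiac cycle
        rather than by average band energy alone.
    ambient_band : tuple of float
        Passband of the ambient component in Hz.
    seed : int
        Seed for the default random generator.
    """

    rate: int = 4000
    duration: float = 10.0
    heart_rate_bpm: float = 80.0
    s1_s2_gap_fraction: float = 0.35
    murmur_band: tuple[float, float] = (100.0, 600.0)
    murmur_snr_db: float = 10.0
    background_noise_db: float = -20.0
    ambient_noise_db: float = -24.0
    ambient_band: tuple[float, float] = (80.0, 700.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.duration <= 0:
            raise SynthConfigError("rate and duration must be positive")
        if not 0.0 < self.s1_s2_gap_fraction < 1.0:
            raise SynthConfigError(
                f"s1_s2_gap_fraction must lie in (0, 1), got {self.s1_s2_gap_fraction}"
            )
        if self.heart_rate_bpm <= 0:
            raise SynthConfigError("heart_rate_bpm must be positive")
        for name in ("murmur_band", "ambient_band"):
            lo, hi = getattr(self, name)
            if not 0.0 < lo < hi < self.rate / 2:
                raise SynthConfigError(
                    f"{name} {(lo, hi)} must satisfy 0 < low < high < rate/2"
                    f" = {self.rate / 2}"
                )


@dataclass
class PCGClip:
    """One labeled heart-sound recording.

    ``systolic_intervals`` holds the (start_s, end_s) of every S1→S2
    interval; it is populated by the simulator and absent (``None``) for
    clips read from plain WAV files without an annotation sidecar.
    """

    samples: np.ndarray
    rate: int
    subject_id: str
    site: str
    label: str
    systolic_intervals: list[tuple[float, float]] | None = None

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("PCGClip samples must be a mono 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("PCGClip samples must be finite")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")
        if self.systolic_intervals is not None:
            prev_end = 0.0
            for start, end in self.systolic_intervals:
                if not 0.0 <= start < end <= self.duration + 1e-9:
                    raise ValueError(f"systolic interval ({start}, {end}) out of range")
                if start < prev_end - 1e-9:
                    raise ValueError("systolic intervals must be sorted and disjoint")
                prev_end = end


def _tone_burst(
    rng: np.random.Generator,
    rate: int,
    dur_s: float,
    freqs: Sequence[float],
    decay_s: float,
) -> np.ndarray:
    """Exponentially decaying multi-tone transient, peak-normalized to 1."""
    t = np.arange(int(round(dur_s * rate))) / rate
    envelope = np.exp(-t / decay_s)
    burst = np.zeros_like(t)
    for f in freqs:
        burst += np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    burst *= envelope
    peak = np.max(np.abs(burst))
    return burst / peak if peak > 0 else burst


def _band_noise(
    rng: np.random.Generator, n: int, rate: int, band: tuple[float, float]
) -> np.ndarray:
    """Gaussian noise band-passed to ``band``, unit RMS."""
    white = rng.standard_normal(n + 2 * rate // 10)
    sos = signal.butter(4, band, btype="bandpass", fs=rate, output="sos")
    shaped = signal.sosfilt(sos, white)[rate // 10 : rate // 10 + n]
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def synthesize_clip(
    config: SynthConfig,
    label: str,
    subject_id: str = "s0",
    site: str = "tricuspid",
    rng: np.random.Generator | None = None,
) -> PCGClip:
    """Generate one synthetic PCG clip.

    S1 and S2 transients are placed periodically at the configured heart
    rate; for ``label == "murmur"`` band-limited noise at the configured
    SNR (scaled by the per-site gain) is gated onto every systolic
    interval. The waveform is peak-normalized to 0.9. Deterministic for a
    given config seed (or supplied generator state).
    """
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}, got {label!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n = int(round(config.duration * config.rate))
    rate = config.rate
    x = np.zeros(n)

    period_s = 60.0 / config.heart_rate_bpm
    gap_s = config.s1_s2_gap_fraction * period_s
    s1_dur, s2_dur = 0.055, 0.045

    noise_rms = 10.0 ** (config.background_noise_db / 20.0)
    ambient_rms = 10.0 ** (config.ambient_noise_db / 20.0)
    # reference the murmur to the in-band background it competes with
    background = _band_noise(rng, n, rate, config.ambient_band) * ambient_rms
    background += rng.standard_normal(n) * noise_rms
    sos = signal.butter(4, config.murmur_band, btype="bandpass", fs=rate, output="sos")
    inband_rms = float(np.sqrt(np.mean(signal.sosfilt(sos, background) ** 2)))
    murmur_rms = (
        inband_rms * 10.0 ** (config.murmur_snr_db / 20.0) * SITE_MURMUR_GAIN[site]
    )

    intervals: list[tuple[float, float]] = []
    t0 = 0.05  # first S1 onset
    while t0 + period_s <= config.duration:
        s1_onset, s2_onset = t0, t0 + gap_s
        amp1 = rng.uniform(0.9, 1.1)
        amp2 = rng.uniform(0.9, 1.1) * 0.8  # S2 slightly softer
        b1 = amp1 * _tone_burst(rng, rate, s1_dur, (40.0, 75.0, 110.0), 0.016)
        b2 = amp2 * _tone_burst(rng, rate, s2_dur, (55.0, 95.0, 140.0), 0.013)
        i1, i2 = int(round(s1_onset * rate)), int(round(s2_onset * rate))
        x[i1 : i1 + len(b1)] += b1[: max(0, n - i1)]
        if i2 + len(b2) <= n:
            x[i2 : i2 + len(b2)] += b2
        intervals.append((s1_onset, s2_onset))
        t0 += period_s

    if label == "murmur":
        murmur = _band_noise(rng, n, rate, config.murmur_band) * murmur_rms
        gate = np.zeros(n)
        edge = int(0.010 * rate)  # 10 ms raised-cosine flanks
        ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, edge)))
        for start, end in intervals:
            i0, i1 = int(round(start * rate)), int(round(end * rate))
            gate[i0:i1] = 1.0
            gate[i0 : i0 + edge] = np.minimum(gate[i0 : i0 + edge], ramp)
            if i1 <= n - 1:
                gate[i1 - edge : i1] = np.minimum(gate[i1 - edge : i1], ramp[::-1])
        x += murmur * gate

    x += background
    x *= 0.9 / np.max(np.abs(x))

    return PCGClip(
        samples=x,
        rate=rate,
        subject_id=subject_id,
        site=site,
        label=label,
        systolic_intervals=intervals,
    )


def synthesize_cohort(
    n_murmur_subjects: int,
    n_normal_subjects: int,
    clips_per_subject_per_site: int,
    config: SynthConfig,
) -> tuple[list[PCGClip], pd.DataFrame]:
    """Generate a cohort: every subject recorded at all five sites.

    Per-subject physiology and recording conditions (heart rate ±10 bpm,
    murmur SNR ±3 dB, background-noise floor ±6 dB) are jittered once per
    subject so that subject-exclusive splitting is meaningful and so that
    no single recording-level statistic (such as average band energy)
    separates the classes — as in real auscultation, where ambient noise
    varies between sessions. Returns the clips and a manifest DataFrame
    with columns ``path, subject_id, site, label`` (one row per clip;
    paths are the relative WAV names used by :func:`write_cohort`).
    """
    if n_murmur_subjects < 1 or n_normal_subjects < 1 or clips_per_subject_per_site < 1:
        raise SynthConfigError("subject and clip counts must be >= 1")
    master = np.random.default_rng(config.seed)
    clips: list[PCGClip] = []
    rows = []
    subjects = [("murmur", f"vsd{i:03d}") for i in range(n_murmur_subjects)] + [
        ("normal", f"nor{i:03d}") for i in range(n_normal_subjects)
    ]
    for label, sid in subjects:
        subj_cfg = replace(
            config,
            heart_rate_bpm=config.heart_rate_bpm + master.uniform(-10, 10),
            murmur_snr_db=config.murmur_snr_db + master.uniform(-3, 3),
            background_noise_db=config.background_noise_db + master.uniform(-6, 6),
            ambient_noise_db=config.ambient_noise_db + master.uniform(-6, 6),
        )
        for site in SITES:
            for k in range(clips_per_subject_per_site):
                clip = synthesize_clip(subj_cfg, label, subject_id=sid, site=site, rng=master)
                clips.append(clip)
                rows.append(
                    {
                        "path": f"{sid}_{site}_{k}.wav",
                        "subject_id": sid,
                        "site": site,
                        "label": label,
                    }
                )
    return clips, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# WAV + manifest I/O


def write_clip(clip: PCGClip, path: str | os.PathLike) -> Path:
    """Write a clip as mono 16-bit PCM WAV plus a TSV annotation sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pcm = np.clip(clip.samples, -1.0, 1.0)
    wavfile.write(path, clip.rate, (pcm * 32767.0).round().astype(np.int16))
    if clip.systolic_intervals is not None:
        sidecar = path.with_suffix(".intervals.tsv")
        pd.DataFrame(clip.systolic_intervals, columns=["start_s", "end_s"]).to_csv(
            sidecar, sep="\t", index=False
        )
    return path


def read_clip(path: str | os.PathLike, manifest_row: pd.Series | dict) -> PCGClip:
    """Read a mono 16-bit WAV back into a :class:`PCGClip`.

    Metadata (subject, site, label) comes from the manifest row; the
    annotation sidecar, when present next to the WAV, restores the
    systolic intervals.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"clip not found: {path}")
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"multichannel WAV not supported: {path}")
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32767.0
    elif np.issubdtype(data.dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV encoding {data.dtype} in {path}")
    sidecar = path.with_suffix(".intervals.tsv")
    intervals = None
    if sidecar.exists():
        tbl = pd.read_csv(sidecar, sep="\t")
        intervals = list(zip(tbl["start_s"], tbl["end_s"]))
    return PCGClip(
        samples=samples,
        rate=int(rate),
        subject_id=str(manifest_row["subject_id"]),
        site=str(manifest_row["site"]),
        label=str(manifest_row["label"]),
        systolic_intervals=intervals,
    )


def write_cohort(
    clips: Sequence[PCGClip], manifest: pd.DataFrame, out_dir: str | os.PathLike
) -> Path:
    """Write every clip of a cohort plus ``manifest.tsv`` to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(clips) != len(manifest):
        raise ValueError("manifest rows and clips must correspond one-to-one")
    for clip, path in zip(clips, manifest["path"]):
        write_clip(clip, out_dir / path)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return out_dir


def read_cohort(data_dir: str | os.PathLike) -> tuple[list[PCGClip], pd.DataFrame]:
    """Read a cohort directory written by :func:`write_cohort`."""
    data_dir = Path(data_dir)
    manifest = read_manifest(data_dir / "manifest.tsv")
    clips = [read_clip(data_dir / row["path"], row) for _, row in manifest.iterrows()]
    return clips, manifest


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t", dtype=str)
    required = {"path", "subject_id", "site", "label"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    if manifest["path"].duplicated().any():
        raise ValueError("manifest paths must be unique")
    bad = set(manifest["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"manifest labels outside {LABELS}: {sorted(bad)}")
    return manifest
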