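"""Short-time log-power spectral features.

A clip is framed with a hop of ``frame_shift`` samples (tail samples that
do not fill a whole frame are dropped), each frame is windowed and
transformed with a real FFT, and the squared magnitude is floored and
log-compressed. With the default 512/256 framing each frame becomes a
257-dimensional log-power vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

from .synth import PCGClip


@dataclass
class Spectrogram:
    """N x (frame_length/2 + 1) matrix of log-power frames."""

    frames: np.ndarray
    frame_length: int
    frame_shift: int
    rate: int

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_bins(self) -> int:
        return self.frames.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame center times in seconds."""
        starts = np.arange(self.n_frames) * self.frame_shift
        return (starts + self.frame_length / 2) / self.rate

    @property
    def freqs(self) -> np.ndarray:
        """Bin center frequencies in Hz (bin k at k * rate / frame_length)."""
        return np.arange(self.n_bins) * self.rate / self.frame_length


def n_frames_for(num_samples: int, frame_length: int, frame_shift: int) -> int:
    if num_samples < frame_length:
        return 0
    return (num_samples - frame_length) // frame_shift + 1


def stft_logpower(
    clip: PCGClip | np.ndarray,
    frame_length: int = 512,
    frame_shift: int = 256,
    log_floor: float = 1e-10,
    window: str = "hann",
    rate: int | None = None,
) -> Spectrogram:
    """Compute the log-power spectrogram of a clip.

    Entry (n, k) is ``log(max(|DFT_k(w * frame_n)|^2, log_floor))`` with a
    natural log. ``window`` may be any name accepted by
    :func:`scipy.signal.get_window` (e.g. ``"boxcar"`` for a rectangular
    window).

    Raises
    ------
    ValueError
        If the clip is shorter than one analysis frame.
    """
    if isinstance(clip, PCGClip):
        samples, rate = clip.samples, clip.rate
    else:
        samples = np.asarray(clip, dtype=np.float64)
        if rate is None:
            raise ValueError("rate is required when passing a bare sample array")
    if len(samples) < frame_length:
        raise ValueError(
            f"clip has {len(samples)} samples, shorter than one frame ({frame_length})"
        )
    framed = sliding_window_view(samples, frame_length)[::frame_shift]
    win = get_window(window, frame_length, fftbins=True)
    spectrum = np.fft.rfft(framed * win, axis=1)
    power = np.abs(spectrum) ** 2
    frames = np.log(np.maximum(power, log_floor))
    return Spectrogram(
        frames=frames, frame_length=frame_length, frame_shift=frame_shift, rate=rate
    )


def standardize(spec: Spectrogram, eps: float = 1e-8) -> Spectrogram:
    """Per-recording mean/variance standardization (one scalar mean and
    one scalar deviation over the whole log-power matrix).

    Removes the overall recording gain (a waveform scale shows up as a
    constant offset in log power) and tames the raw log-power scale
    before the features reach a model. A single recording-level affine
    keeps each frame's content local to that frame: standardizing every
    bin separately would imprint the recording's average spectral
    signature onto all frames, letting a model read the clip-level class
    from any frame and making frame-level attention explanations
    degenerate.
    """
    mu = spec.frames.mean()
    sd = spec.frames.std()
    frames = (spec.frames - mu) / (sd + eps)
    return Spectrogram(frames, spec.frame_length, spec.frame_shift, spec.rate)


def frame_annotations(clip: PCGClip, spec: Spectrogram) -> np.ndarray:
    """Per-frame binary murmur mask aligned with ``spec``.

    Frame n is 1 iff the clip is murmur-labeled and the frame's center
    time falls inside a systolic interval. Normal clips yield all zeros.
    """
    if clip.systolic_intervals is None:
        raise ValueError("clip carries no systolic-interval annotations")
    mask = np.zeros(spec.n_frames, dtype=np.int8)
    if clip.label != "murmur":
        return mask
    centers = spec.times
    for start, end in clip.systolic_intervals:
        mask[(centers >= start) & (centers < end)] = 1
    return mask
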