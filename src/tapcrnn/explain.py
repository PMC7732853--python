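"""Event-presence-likelihood (EPL) extraction and scoring.

The TAP-CRNN's per-frame product of global and local attention weights,
alpha_global(n) * beta_local(n), indicates where in the clip the model
found the evidence for its decision. On annotated synthetic clips the
EPL can be scored against the known murmur frames with a pairwise
ranking statistic (the probability that a random murmur frame receives
a higher EPL than a random non-murmur frame; ties count one half).
The ranking score is an artifact-level surrogate: it quantifies the
qualitative claim that murmur regions should receive high EPL, not a
clinically validated localization metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import FeatureConfig, featurize
from .features import frame_annotations
from .models import TapCrnnClassifier
from .synth import PCGClip


@dataclass
class EPLTrace:
    """Per-frame EPL of one clip, aligned to frame center times."""

    clip_id: str
    times: np.ndarray
    epl: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.times) != len(self.epl):
            raise ValueError("times and epl must have one entry per frame")
        if np.any(self.epl < -1e-12):
            raise ValueError("EPL must be nonnegative")
        if self.mask is not None and len(self.mask) != len(self.epl):
            raise ValueError("mask length must match the frame count")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.times, "epl": self.epl})
        if self.mask is not None:
            df["mask"] = self.mask.astype(int)
        return df

    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
        return path

    @classmethod
    def load(cls, path, clip_id: str = "") -> "EPLTrace":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        mask = df["mask"].to_numpy() if "mask" in df.columns else None
        return cls(
            clip_id=clip_id or Path(path).stem,
            times=df["time_s"].to_numpy(),
            epl=df["epl"].to_numpy(),
            mask=mask,
        )


def extract_epl(
    model: TapCrnnClassifier, clip: PCGClip, feat: FeatureConfig = FeatureConfig()
) -> EPLTrace:
    """Run a forward pass and return the per-frame EPL of one clip."""
    if not isinstance(model, TapCrnnClassifier):
        raise TypeError(
            "EPL is defined only for the TAP-CRNN architecture; "
            f"got {type(model).__name__}"
        )
    spec = featurize(clip, feat)
    trace = model.attention_trace(spec.frames)
    # reuse the raw (un-standardized) framing geometry for center times
    mask = None
    if clip.systolic_intervals is not None:
        mask = frame_annotations(clip, spec)
    return EPLTrace(
        clip_id=f"{clip.subject_id}_{clip.site}",
        times=spec.times,
        epl=trace.epl,
        mask=mask,
    )


def ranking_score(epl: np.ndarray, mask: np.ndarray) -> float:
    """P(random murmur frame outranks random non-murmur frame); ties = 1/2."""
    pos = np.asarray(epl)[np.asarray(mask) == 1]
    neg = np.asarray(epl)[np.asarray(mask) == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("mask must contain both murmur and non-murmur frames")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def epl_localization_score(traces: list[EPLTrace]) -> float:
    """Mean pairwise ranking score over clips with a two-class mask.

    Clips whose mask is all murmur or all non-murmur are skipped with a
    warning (the statistic is undefined for them).
    """
    scores = []
    for trace in traces:
        if trace.mask is None:
            raise ValueError(f"trace {trace.clip_id} carries no mask")
        m = np.asarray(trace.mask)
        if m.min() == m.max():
            warnings.warn(
                f"clip {trace.clip_id}: single-class mask, skipped", stacklevel=2
            )
            continue
        scores.append(ranking_score(trace.epl, m))
    if not scores:
        raise ValueError("no trace had both murmur and non-murmur frames")
    return float(np.mean(scores))


def plot_epl(
    trace: EPLTrace, clip: PCGClip, path, feat: FeatureConfig = FeatureConfig()
) -> Path:
    """Two-panel figure: spectrogram on top, EPL curve below."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .features import stft_logpower

    spec = stft_logpower(
        clip, frame_length=feat.frame_length, frame_shift=feat.frame_shift
    )
    fig, (ax1, ax2) = plt.subplots(
        2, 1, figsize=(10, 6), sharex=True, height_ratios=[2, 1]
    )
    ax1.imshow(
        spec.frames.T,
        origin="lower",
        aspect="auto",
        extent=(spec.times[0], spec.times[-1], spec.freqs[0], spec.freqs[-1]),
        cmap="magma",
    )
    ax1.set_ylabel("frequency (Hz)")
    ax1.set_title(f"{trace.clip_id} — log-power spectrogram")
    ax2.plot(trace.times, trace.epl, lw=1.2, color="tab:blue", label="EPL")
    if trace.mask is not None:
        ax2.fill_between(
            trace.times,
            0,
            trace.epl.max() * trace.mask,
            alpha=0.2,
            color="tab:red",
            label="annotated murmur",
        )
    ax2.set_xlabel("time (s)")
    ax2.set_ylabel("EPL")
    ax2.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
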