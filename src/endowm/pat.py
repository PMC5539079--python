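"""Reactive hyperemia index (RHI) from fingertip pulse-amplitude series.

RHI is the ratio of the post-occlusion to pre-occlusion average pulse
amplitude ("signal size").  Signal size per beat is peak-to-trough, the
conventional plethysmographic pulse amplitude; an RMS-envelope alternative
is available.  The occlusion phase is only used for a quality flag: its
residual amplitude should be under 10% of baseline if the cuff actually
occluded flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .synthetic import PatSignal

__all__ = ["RhiResult", "beat_amplitudes", "compute_rhi", "BeatDetectionError"]


class BeatDetectionError(ValueError):
    """Too few beats detected in an interval for amplitude estimation."""


@dataclass(frozen=True)
class RhiResult:
    pre_avg: float
    post_avg: float
    rhi: float
    beats_pre: int
    beats_post: int
    occlusion_ok: bool

    def as_dict(self) -> dict:
        return {
            "pre_avg": self.pre_avg,
            "post_avg": self.post_avg,
            "rhi": self.rhi,
            "beats_pre": self.beats_pre,
            "beats_post": self.beats_post,
            "occlusion_ok": self.occlusion_ok,
        }


def _estimate_beat_period(x: np.ndarray, fs: float) -> float:
    """Median peak spacing, from a permissive first-pass peak search."""
    span = float(x.max() - x.min())
    if span <= 0:
        raise BeatDetectionError("flat signal: no beats detectable")
    peaks, _ = find_peaks(x, prominence=0.25 * span)
    if len(peaks) < 2:
        raise BeatDetectionError(f"only {len(peaks)} beat(s) detected in interval")
    return float(np.median(np.diff(peaks))) / fs


def beat_amplitudes(
    signal: PatSignal,
    interval: tuple[int, int],
    method: str = "peak_trough",
) -> np.ndarray:
    """Per-beat pulse amplitudes over a half-open sample interval.

    Beats are local maxima separated by at least half the estimated beat
    period; each beat's amplitude is its peak value minus the adjacent
    (following) trough.  ``method='rms'`` instead returns a single
    RMS-derived peak-to-trough equivalent per beat interval.
    """
    s, e = interval
    if not (0 <= s < e <= len(signal.samples)):
        raise ValueError(f"interval [{s},{e}) outside signal bounds")
    x = np.asarray(signal.samples[s:e], dtype=float)
    period = _estimate_beat_period(x, signal.sample_rate)
    min_dist = max(1, int(round(0.5 * period * signal.sample_rate)))
    span = float(x.max() - x.min())
    peaks, _ = find_peaks(x, distance=min_dist, prominence=0.25 * span)
    if len(peaks) < 2:
        raise BeatDetectionError(f"only {len(peaks)} beat(s) detected in interval")

    if method == "rms":
        # sqrt(8) * RMS of the mean-removed segment equals peak-to-trough
        # for a pure sinusoid
        amps = []
        for a, b in zip(peaks[:-1], peaks[1:]):
            seg = x[a:b]
            amps.append(np.sqrt(8.0) * float(np.std(seg)))
        return np.asarray(amps)
    if method != "peak_trough":
        raise ValueError(f"unknown amplitude method {method!r}")

    amps = []
    for a, b in zip(peaks[:-1], peaks[1:]):
        trough = float(x[a:b].min())
        amps.append(float(x[a]) - trough)
    return np.asarray(amps)


def compute_rhi(
    signal: PatSignal,
    post_window: tuple[float, float] | None = None,
    method: str = "peak_trough",
) -> RhiResult:
    """Post/pre average pulse-amplitude ratio.

    ``post_window`` optionally restricts the post-occlusion average to a
    (start_s, end_s) window measured from the start of the post phase;
    default is the entire post phase.  The occlusion check is advisory:
    ``occlusion_ok`` is False when the occlusion-phase residual amplitude
    reaches 10% of baseline, but the ratio is still computed.
    """
    pre_iv = signal.phases["baseline"]
    post_iv = signal.phases["post"]
    if post_window is not None:
        w0, w1 = post_window
        if not (0 <= w0 < w1):
            raise ValueError("post_window must satisfy 0 <= start < end")
        fs = signal.sample_rate
        s = post_iv[0] + int(round(w0 * fs))
        e = min(post_iv[1], post_iv[0] + int(round(w1 * fs)))
        if e - s < 2:
            raise ValueError("post_window selects too few samples")
        post_iv = (s, e)

    pre = beat_amplitudes(signal, pre_iv, method=method)
    post = beat_amplitudes(signal, post_iv, method=method)
    pre_avg = float(pre.mean())
    post_avg = float(post.mean())
    if pre_avg <= 0:
        raise ValueError("pre-occlusion average amplitude is zero; RHI undefined")

    occ = signal.samples[slice(*signal.phases["occlusion"])]
    occ_amp = float(occ.max() - occ.min()) if occ.size else 0.0
    return RhiResult(
        pre_avg=pre_avg,
        post_avg=post_avg,
        rhi=post_avg / pre_avg,
        beats_pre=len(pre),
        beats_post=len(post),
        occlusion_ok=occ_amp < 0.1 * pre_avg,
    )
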