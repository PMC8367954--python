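"""Filtering, resampling, re-referencing, GFP and GFP-peak detection.

The stage turns a raw multichannel recording into clustering input:
a 1-40 Hz band-passed, notch-filtered, down-sampled, average-referenced
recording, its global field power (GFP) series, and the indices of GFP
local maxima at which topographies are sampled for clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import EEGRecording, GFPSeries, StateError


@dataclass
class PreprocessConfig:
    """Band-pass / notch / resampling settings.

    Defaults follow common toddler resting-state practice: 1-40 Hz
    Butterworth band-pass, 50 Hz notch, down-sampling to 125 Hz. The
    band-pass is a 4th-order Butterworth applied forward-backward
    (zero-phase) so filtering does not displace microstate boundaries;
    the notch is a 2nd-order zero-phase band-stop.
    """

    band_low_hz: float = 1.0
    band_high_hz: float = 40.0
    notch_hz: float | None = 50.0
    target_srate_hz: float = 125.0
    filter_order: int = 4
    zero_phase: bool = True

    def validate(self, srate: float) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 < band_low < band_high")
        if self.band_high_hz >= srate / 2:
            raise ValueError("band_high must be below Nyquist")
        if self.target_srate_hz > srate:
            raise ValueError("target_srate cannot exceed source rate")


def bandpass_notch(rec: EEGRecording, cfg: PreprocessConfig | None = None) -> EEGRecording:
    """Apply Butterworth band-pass plus notch channel-wise.

    The artifact mask is unchanged; the DC component of each channel is
    removed by the high-pass edge.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate(rec.srate)
    sos = signal.butter(cfg.filter_order, [cfg.band_low_hz, cfg.band_high_hz],
                        btype="bandpass", fs=rec.srate, output="sos")
    filt = signal.sosfiltfilt if cfg.zero_phase else signal.sosfilt
    data = filt(sos, rec.data, axis=1)
    if cfg.notch_hz is not None and cfg.notch_hz < rec.srate / 2:
        sos_n = signal.butter(2, [cfg.notch_hz - 2.0, cfg.notch_hz + 2.0],
                              btype="bandstop", fs=rec.srate, output="sos")
        data = filt(sos_n, data, axis=1)
    return rec.copy_with(data=data)


def resample(rec: EEGRecording, target_srate: float) -> EEGRecording:
    """Polyphase anti-aliased resampling to ``target_srate``.

    The artifact mask is resampled by logical OR over each source window:
    a target sample is masked if any source sample mapping onto it was
    masked (artifacts never silently shrink).
    """
    if target_srate <= 0:
        raise ValueError("target_srate must be positive")
    if target_srate > rec.srate:
        raise ValueError("upsampling is not supported")
    if target_srate == rec.srate:
        return rec
    frac = Fraction(target_srate / rec.srate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    data = signal.resample_poly(rec.data, up, down, axis=1)
    n_out = int(np.floor(rec.n_samples * target_srate / rec.srate))
    data = data[:, :n_out]
    # OR-pool the mask: target sample j covers source samples [j*d/u, (j+1)*d/u)
    src_idx = np.floor(np.arange(rec.n_samples) * target_srate / rec.srate).astype(int)
    mask = np.zeros(n_out, dtype=bool)
    np.logical_or.at(mask, src_idx[src_idx < n_out], rec.artifact_mask[src_idx < n_out])
    return rec.copy_with(data=data, srate=float(target_srate), artifact_mask=mask)


def rereference_average(rec: EEGRecording) -> EEGRecording:
    """Re-reference to the common average: every column gets mean zero.

    Idempotent; marks the recording as average-referenced.
    """
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return rec.copy_with(data=data, reference="average")


def compute_gfp(rec: EEGRecording) -> GFPSeries:
    """Global field power: population standard deviation across channels
    at each time point,

        GFP(t) = sqrt( (1/C) * sum_i (v_i(t) - vbar(t))^2 ).

    Requires an average-referenced recording (re-reference first).
    """
    if rec.reference != "average":
        raise StateError("compute_gfp requires an average-referenced recording")
    values = rec.data.std(axis=0, ddof=0)
    return GFPSeries(values=values, srate=rec.srate)


def detect_gfp_peaks(gfp: GFPSeries, mask: np.ndarray | None = None) -> GFPSeries:
    """Find strict interior local maxima of the GFP series.

    A peak satisfies ``values[i-1] < values[i] > values[i+1]`` (equal-valued
    plateaus yield no peak). Peaks on artifact-masked samples, or adjacent
    to a masked sample, are removed so no clustering input straddles an
    artifact boundary. An all-masked series yields an empty peak set.
    """
    v = gfp.values
    if v.size < 3:
        raise ValueError("series too short for peak detection")
    interior = np.arange(1, v.size - 1)
    is_peak = (v[interior] > v[interior - 1]) & (v[interior] > v[interior + 1])
    peaks = interior[is_peak]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        bad = mask[peaks] | mask[peaks - 1] | mask[peaks + 1]
        peaks = peaks[~bad]
    return GFPSeries(values=v, peak_indices=peaks, srate=gfp.srate)


def peak_maps(rec: EEGRecording, peaks: GFPSeries) -> np.ndarray:
    """Extract the topographies at GFP peaks, shape (n_peaks, n_channels)."""
    return rec.data[:, peaks.peak_indices].T.copy()
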