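"""Core domain types for the microstate pipeline.

All containers are thin dataclasses around numpy arrays / pandas frames.
Conventions used throughout the package:

* voltage matrices are ``(n_channels, n_samples)`` in microvolts;
* time is 0-based sample indexing, intervals are half-open ``[start, end)``,
  and conversions to milliseconds go through the sampling rate;
* the artifact mask is boolean per sample with ``True`` meaning *excluded*;
  masking never deletes samples, so run-length logic downstream always sees
  one coherent timeline;
* microstate labels are integers ``0..K-1``; :data:`UNLABELED` (= -1) marks
  samples that are artifact-masked or fall below the back-fitting
  correlation floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Sentinel label for samples not assigned to any microstate class.
UNLABELED: int = -1

#: Column order of the tidy temporal-parameter table.
PARAM_COLUMNS = ("gev", "mean_duration_ms", "coverage_pct", "occurrence_per_s")


class StateError(RuntimeError):
    """An operation was called on an object in the wrong state
    (e.g. GFP requested on a raw-referenced recording)."""


class FormatError(ValueError):
    """A file did not conform to the expected dialect."""


@dataclass
class EEGRecording:
    """A multichannel EEG segment with sampling rate and artifact mask.

    Parameters
    ----------
    data
        Voltage matrix, shape ``(n_channels, n_samples)``, microvolts.
    srate
        Sampling rate in Hz.
    channel_ids
        Ordered channel names, one per row of ``data``.
    artifact_mask
        Boolean per sample; ``True`` marks samples excluded from analysis.
        Defaults to all-``False``.
    reference
        ``"raw"`` or ``"average"``. Average-referenced data has zero mean
        across channels at every time point.
    """

    data: np.ndarray
    srate: float
    channel_ids: Sequence[str] = ()
    artifact_mask: np.ndarray | None = None
    reference: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        n_ch, n_s = self.data.shape
        if n_ch < 2 or n_s < 2:
            raise ValueError("need at least 2 channels and 2 samples")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if not self.channel_ids:
            self.channel_ids = [f"ch{i:03d}" for i in range(n_ch)]
        self.channel_ids = list(self.channel_ids)
        if len(self.channel_ids) != n_ch:
            raise ValueError("channel_ids length must match channel count")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(n_s, dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.shape != (n_s,):
            raise ValueError("artifact_mask length must equal sample count")
        if self.reference not in ("raw", "average"):
            raise ValueError(f"unknown reference {self.reference!r}")
        if self.reference == "average":
            col_means = self.data.mean(axis=0)
            scale = max(1.0, float(np.abs(self.data).max()))
            if np.abs(col_means).max() > 1e-6 * scale:
                raise ValueError("reference='average' but columns do not sum to 0")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.srate

    def copy_with(self, **kwargs) -> "EEGRecording":
        return replace(self, **kwargs)


@dataclass
class GFPSeries:
    """Global field power per sample and the indices of its local maxima."""

    values: np.ndarray
    peak_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    srate: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        if (self.values < 0).any():
            raise ValueError("GFP values must be nonnegative")
        if self.peak_indices.size and (np.diff(self.peak_indices) <= 0).any():
            raise ValueError("peak_indices must be strictly increasing")


@dataclass
class TemplateSet:
    """K microstate template topographies (unit-norm, mean-zero maps).

    ``level`` records provenance: ``"subject"``, ``"group"`` or ``"cohort"``.
    """

    maps: np.ndarray  # (k, n_channels)
    labels: Sequence[str] = ()
    level: str = "subject"

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 2:
            raise ValueError("maps must be 2-D (k x channels)")
        if not self.labels:
            self.labels = [chr(ord("A") + i) for i in range(self.k)]
        self.labels = list(self.labels)
        if len(self.labels) != self.k:
            raise ValueError("labels length must equal number of maps")
        if len(set(self.labels)) != self.k:
            raise ValueError("labels must be unique")
        if self.level not in ("subject", "group", "cohort"):
            raise ValueError(f"unknown level {self.level!r}")
        # enforce mean-zero, unit-norm
        centered = self.maps - self.maps.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        if (norms == 0).any():
            raise ValueError("template map with zero variance")
        self.maps = centered / norms[:, None]

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class Segmentation:
    """Winner-takes-all microstate labeling of a recording.

    ``labels[t]`` is the template index in ``0..K-1`` or :data:`UNLABELED`;
    ``corr[t]`` is the absolute spatial correlation with the winning
    template; ``gfp[t]`` the global field power.
    """

    labels: np.ndarray
    corr: np.ndarray
    gfp: np.ndarray
    srate: float
    artifact_mask: np.ndarray | None = None
    template_labels: Sequence[str] = ()
    template_ref: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.corr = np.asarray(self.corr, dtype=float)
        self.gfp = np.asarray(self.gfp, dtype=float)
        n = self.labels.size
        if self.corr.size != n or self.gfp.size != n:
            raise ValueError("labels, corr and gfp must have equal length")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(n, dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.size != n:
            raise ValueError("artifact_mask length mismatch")
        if (self.labels[self.artifact_mask] != UNLABELED).any():
            raise ValueError("artifact-masked samples must be UNLABELED")
        self.template_labels = list(self.template_labels)

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def k(self) -> int:
        if self.template_labels:
            return len(self.template_labels)
        return int(self.labels.max()) + 1 if (self.labels >= 0).any() else 0


@dataclass
class RunList:
    """Maximal constant-label stretches of labeled samples.

    Runs are ordered, non-overlapping, half-open in samples. A run never
    spans an UNLABELED or artifact-masked sample.
    """

    labels: np.ndarray  # template index per run
    starts: np.ndarray  # start sample (inclusive)
    ends: np.ndarray  # end sample (exclusive)
    srate: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.starts = np.asarray(self.starts, dtype=int)
        self.ends = np.asarray(self.ends, dtype=int)
        if not (self.labels.size == self.starts.size == self.ends.size):
            raise ValueError("run arrays must have equal length")
        if (self.ends <= self.starts).any():
            raise ValueError("runs must be non-empty half-open intervals")
        if self.starts.size > 1 and (self.starts[1:] < self.ends[:-1]).any():
            raise ValueError("runs must be ordered and non-overlapping")

    @property
    def n_runs(self) -> int:
        return self.labels.size

    @property
    def durations_ms(self) -> np.ndarray:
        return (self.ends - self.starts) * 1000.0 / self.srate


@dataclass
class TemporalParams:
    """Per-subject temporal parameters, one row per microstate class.

    ``table`` is indexed by map label with columns
    ``gev``, ``mean_duration_ms``, ``coverage_pct``, ``occurrence_per_s``.
    """

    subject_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PARAM_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"parameter table missing columns {missing}")
        self.table = self.table[list(PARAM_COLUMNS)].astype(float)


@dataclass
class TransitionResult:
    """Observed, occurrence-expected and normalized transition matrices.

    Rows index the source state, columns the destination; diagonals are
    structurally zero. ``observed`` and ``expected`` are row-stochastic for
    every state that actually transitions; rows of states with no outgoing
    transition are NaN ("missing").
    """

    observed: np.ndarray
    expected: np.ndarray
    normalized: np.ndarray
    n_transitions: int
    state_labels: Sequence[str] = ()

    def __post_init__(self) -> None:
        for name in ("observed", "expected", "normalized"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError(f"{name} must be square")
            setattr(self, name, m)
        self.state_labels = list(self.state_labels)
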