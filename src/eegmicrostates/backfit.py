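"""Back-fitting templates to continuous EEG and temporal parameters.

Every sample is labeled with the template of highest absolute spatial
correlation (winner-takes-all), provided that correlation exceeds the
configured floor (default 0.5, read strictly: corr == 0.5 stays
unlabeled). Artifact-masked samples are never labeled. From the resulting
segmentation the four standard temporal parameters are computed per
microstate class: GEV, mean duration, time coverage and occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (UNLABELED, EEGRecording, RunList, Segmentation,
                   StateError, TemplateSet, TemporalParams, PARAM_COLUMNS)


@dataclass
class BackfitConfig:
    """Back-fitting settings.

    ``corr_threshold`` is the labeling floor on the absolute spatial
    correlation; samples at or below it stay unlabeled. ``min_duration_ms``
    optionally rejects runs shorter than the given length (off by default:
    no temporal smoothing is applied unless asked for).
    """

    corr_threshold: float = 0.5
    ignore_polarity: bool = True
    min_duration_ms: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.corr_threshold <= 1.0:
            raise ValueError("corr_threshold must lie in [0, 1]")


def backfit(rec: EEGRecording, templates: TemplateSet,
            cfg: BackfitConfig | None = None) -> Segmentation:
    """Label every sample with its best-matching template.

    Ties in the argmax are broken toward the lowest template index. Samples
    whose topography has zero variance (flat across channels) cannot be
    correlated and stay unlabeled.
    """
    cfg = cfg or BackfitConfig()
    if rec.reference != "average":
        raise StateError("backfit requires an average-referenced recording")
    if rec.n_channels != templates.n_channels:
        raise ValueError("channel count mismatch between recording and templates")

    X = rec.data.T  # (n_samples, n_channels), columns already mean-zero
    norms = np.linalg.norm(X, axis=1)
    gfp = norms / np.sqrt(rec.n_channels)
    ok = norms > 0
    corr_mat = np.zeros((rec.n_samples, templates.k))
    corr_mat[ok] = (X[ok] / norms[ok, None]) @ templates.maps.T
    if cfg.ignore_polarity:
        corr_mat = np.abs(corr_mat)

    labels = corr_mat.argmax(axis=1)
    corr = corr_mat[np.arange(rec.n_samples), labels]
    labels[~ok] = UNLABELED
    labels[corr <= cfg.corr_threshold] = UNLABELED
    labels[rec.artifact_mask] = UNLABELED

    seg = Segmentation(labels=labels, corr=corr, gfp=gfp, srate=rec.srate,
                       artifact_mask=rec.artifact_mask,
                       template_labels=templates.labels)
    if cfg.min_duration_ms > 0:
        seg = _reject_short_runs(seg, cfg.min_duration_ms)
    return seg


def _reject_short_runs(seg: Segmentation, min_ms: float) -> Segmentation:
    runs = extract_runs(seg)
    min_samples = int(np.ceil(min_ms * seg.srate / 1000.0))
    labels = seg.labels.copy()
    for lab, s, e in zip(runs.labels, runs.starts, runs.ends):
        if e - s < min_samples:
            labels[s:e] = UNLABELED
    return Segmentation(labels=labels, corr=seg.corr, gfp=seg.gfp,
                        srate=seg.srate, artifact_mask=seg.artifact_mask,
                        template_labels=seg.template_labels)


def extract_runs(seg: Segmentation) -> RunList:
    """Maximal constant-label stretches of labeled samples.

    UNLABELED samples and artifact boundaries terminate runs; runs
    truncated by a mask still count (excluding them would bias durations
    downward in artifact-rich recordings).
    """
    labels = seg.labels
    n = labels.size
    if n == 0:
        return RunList(labels=np.array([], dtype=int), starts=np.array([], dtype=int),
                       ends=np.array([], dtype=int), srate=seg.srate)
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    keep = labels[starts] != UNLABELED
    return RunList(labels=labels[starts[keep]], starts=starts[keep],
                   ends=ends[keep], srate=seg.srate)


def temporal_parameters(seg: Segmentation, runs: RunList | None = None,
                        subject_id: str = "") -> TemporalParams:
    """The four temporal parameters per microstate class.

    For class m over the unmasked samples of the recording:

    * ``gev``: sum over samples labeled m of GFP(t)^2 * corr(t)^2, divided
      by the sum of GFP(t)^2 over *all* unmasked samples (labeled or not),
      so GEV stays a fraction of total signal variance;
    * ``mean_duration_ms``: average length of the runs of m;
    * ``coverage_pct``: 100 x labeled-m samples / unmasked samples;
    * ``occurrence_per_s``: number of runs of m per second of unmasked time.
    """
    if runs is None:
        runs = extract_runs(seg)
    unmasked = ~seg.artifact_mask
    n_unmasked = int(unmasked.sum())
    if n_unmasked == 0:
        raise StateError("no unmasked samples: temporal parameters undefined")
    k = seg.k
    denom = float((seg.gfp[unmasked] ** 2).sum())
    unmasked_s = n_unmasked / seg.srate

    rows = []
    for m in range(k):
        sel = seg.labels == m
        gev = float((seg.gfp[sel] ** 2 * seg.corr[sel] ** 2).sum() / denom) if denom > 0 else 0.0
        run_sel = runs.labels == m
        n_runs = int(run_sel.sum())
        mean_dur = float(runs.durations_ms[run_sel].mean()) if n_runs else np.nan
        coverage = 100.0 * sel.sum() / n_unmasked
        occurrence = n_runs / unmasked_s
        rows.append((gev, mean_dur, coverage, occurrence))

    labels = list(seg.template_labels) if seg.template_labels else [str(m) for m in range(k)]
    table = pd.DataFrame(rows, columns=list(PARAM_COLUMNS), index=pd.Index(labels, name="map"))
    return TemporalParams(subject_id=subject_id, table=table)
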