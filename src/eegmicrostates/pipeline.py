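"""End-to-end microstate analysis over a cohort of recordings.

Two-stage clustering (subject-level k-means on GFP-peak maps, then a group
k-means over the pooled subject templates), canonical A-E labeling,
back-fitting, temporal parameters, transition syntax, and the group
statistics — the full chain from recordings to result tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

import numpy as np
import pandas as pd

from .backfit import BackfitConfig, backfit, extract_runs, temporal_parameters
from .cluster import (ClusterConfig, ClusterSolution, assign_canonical_labels,
                      group_templates, modified_kmeans)
from .core import EEGRecording, TemplateSet, TemporalParams, TransitionResult
from .dynamics import observed_vs_expected, transition_counts
from .preprocess import compute_gfp, detect_gfp_peaks, peak_maps, rereference_average


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    params: TemporalParams
    transitions: TransitionResult


@dataclass
class PipelineResult:
    templates: TemplateSet  # group templates, canonically labeled
    group_gev: float  # total GEV of the group clustering over peak maps
    subjects: list[SubjectResult] = field(default_factory=list)

    def params_by_group(self) -> dict[str, list[TemporalParams]]:
        out: dict[str, list[TemporalParams]] = {}
        for s in self.subjects:
            out.setdefault(s.group, []).append(s.params)
        return out

    def transitions_by_group(self) -> dict[str, list[TransitionResult]]:
        out: dict[str, list[TransitionResult]] = {}
        for s in self.subjects:
            out.setdefault(s.group, []).append(s.transitions)
        return out


def subject_peak_maps(rec: EEGRecording) -> np.ndarray:
    """Average-reference a recording and return its GFP-peak topographies."""
    rec = rereference_average(rec)
    gfp = compute_gfp(rec)
    peaks = detect_gfp_peaks(gfp, rec.artifact_mask)
    return peak_maps(rec, peaks)


def analyze_cohort(recordings: Callable[[], Iterator[tuple[str, str, EEGRecording]]],
                   k: int = 5,
                   cluster_cfg: ClusterConfig | None = None,
                   backfit_cfg: BackfitConfig | None = None,
                   canonical_labels: bool = True) -> PipelineResult:
    """Run the full pipeline.

    ``recordings`` is a zero-argument callable returning an iterator of
    ``(subject_id, group, recording)`` — it is consumed twice (once for
    clustering, once for back-fitting), so recordings can be streamed or
    re-rendered instead of held in memory.
    """
    cluster_cfg = cluster_cfg or ClusterConfig()
    backfit_cfg = backfit_cfg or BackfitConfig()

    subject_sets: list[TemplateSet] = []
    for sid, group, rec in recordings():
        maps = subject_peak_maps(rec)
        sol = modified_kmeans(maps, k, cluster_cfg)
        subject_sets.append(sol.templates)

    group_sol = group_templates(subject_sets, k, cluster_cfg)
    templates = group_sol.templates
    if canonical_labels:
        templates = assign_canonical_labels(templates)

    result = PipelineResult(templates=templates, group_gev=group_sol.gev_total)
    for sid, group, rec in recordings():
        rec = rereference_average(rec)
        seg = backfit(rec, templates, backfit_cfg)
        runs = extract_runs(seg)
        params = temporal_parameters(seg, runs, subject_id=sid)
        counts = transition_counts(runs, k)
        coverage = params.table["coverage_pct"].to_numpy()
        if coverage.sum() == 0:
            coverage = np.ones(k)
        trans = observed_vs_expected(counts, coverage / coverage.sum(),
                                     state_labels=templates.labels)
        result.subjects.append(SubjectResult(subject_id=sid, group=group,
                                             params=params, transitions=trans))
    return result


def cohort_iterator(cohort) -> Callable[[], Iterator[tuple[str, str, EEGRecording]]]:
    """Adapter from a simulated :class:`~eegmicrostates.simulate.Cohort`
    to the streaming interface of :func:`analyze_cohort`."""
    def it():
        for sid, rec, truth in cohort.iter_recordings():
            yield sid, truth.group, rec
    return it
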