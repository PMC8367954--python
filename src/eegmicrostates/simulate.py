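"""Synthetic EEG cohort generator with known ground truth.

The generator emulates the structure the microstate model assumes: a
semi-Markov sequence of quasi-stable scalp topographies. Each subject gets

* a jittered copy of k smooth ground-truth template maps (dipolar patterns
  evaluated on a spherical sensor layout),
* a label sequence with gamma-distributed state durations (explicit
  durations make mean duration and occurrence independently controllable,
  which a first-order Markov chain cannot do),
* multichannel EEG rendered as ``template[L(t)] x carrier(t)`` plus
  spatially structured noise (the sinusoidal carrier's sign alternation
  exercises polarity invariance),
* contiguous artifact-masked blocks, and
* clinical score columns with configurable couplings to the true temporal
  parameters.

Group differences are injected through per-group per-map mean-duration and
coverage targets, defaulting to the reference cohort's printed group means
(ASD vs TD), so the map-B effect pattern is reproduced by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .backfit import temporal_parameters
from .core import UNLABELED, EEGRecording, Segmentation, TemplateSet, TemporalParams
from . import cohort_reference as ref

MAP_LABELS = tuple("ABCDE")

#: Default missing-data rates per clinical instrument, matching the
#: reference cohort's per-row Ns.
DEFAULT_MISSING_RATES = {
    "MSEL": {"ASD": 1 - 55 / 66, "TD": 1 - 35 / 47},
    "CBCL": {"ASD": 1 - 49 / 66, "TD": 1 - 34 / 47},
}


def _default_targets(parameter: str, group: str) -> tuple[float, ...]:
    col = "mean_asd" if group == "ASD" else "mean_td"
    t = ref.temporal_moments().set_index(["map", "parameter"])[col]
    return tuple(float(t[(m, parameter)]) for m in MAP_LABELS)


@dataclass
class SimConfig:
    """Cohort generation settings.

    Defaults mirror the reference study's conditions: 110 average-reference
    channels, 125 Hz, 5-minute records, five template maps, group sizes
    66 (ASD) / 47 (TD), and per-group mean-duration / coverage targets
    equal to the study's printed group means. ``effect_scale`` interpolates
    the ASD targets between the TD values (0: null cohort, no group
    effect) and the study values (1, default).

    ``snr`` is the template-to-noise amplitude ratio (ratio of the RMS
    instantaneous signal vector norm to the RMS noise vector norm);
    GFP-peak topographies in cleaned resting EEG are high-SNR, so the
    default is 10. ``template_jitter`` is the per-subject topography
    noise SD relative to the unit-norm group map.
    """

    n_channels: int = 110
    srate: float = 125.0
    duration_s: float = 300.0
    k_true: int = 5
    group_sizes: dict = field(default_factory=lambda: dict(ref.GROUP_SIZES))
    effect_scale: float = 1.0
    duration_targets_ms: dict | None = None  # {group: tuple per map}
    coverage_targets: dict | None = None  # {group: tuple per map, proportions}
    gamma_shape: float = 2.0
    template_jitter: float = 0.15
    carrier_freq_hz: float = 10.0
    amplitude_uv: float = 10.0
    snr: float = 10.0
    noise_components: int = 30
    noise_white_fraction: float = 0.3
    artifact_fraction: float = 0.1
    artifact_block_s: float = 5.0
    transition_bias: dict | None = None  # {(src_label, dst_label): multiplier}
    clinical_couplings: tuple = (("CBCL_AffP", "B", "coverage_pct", 0.4),)
    missing_rates: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_MISSING_RATES.items()})
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true > self.n_channels:
            raise ValueError("k_true cannot exceed n_channels")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if not 0 <= self.artifact_fraction < 1:
            raise ValueError("artifact_fraction must lie in [0, 1)")
        if self.duration_targets_ms is None:
            td = _default_targets("mean_duration_ms", "TD")[: self.k_true]
            asd = _default_targets("mean_duration_ms", "ASD")[: self.k_true]
            asd = tuple(t + self.effect_scale * (a - t) for a, t in zip(asd, td))
            self.duration_targets_ms = {"ASD": asd, "TD": td}
        if self.coverage_targets is None:
            td = np.array(_default_targets("coverage_pct", "TD")[: self.k_true])
            asd = np.array(_default_targets("coverage_pct", "ASD")[: self.k_true])
            asd = td + self.effect_scale * (asd - td)
            self.coverage_targets = {"ASD": tuple(asd / asd.sum()),
                                     "TD": tuple(td / td.sum())}
        for g, cov in self.coverage_targets.items():
            if min(cov) <= 0 or sum(cov) > 1 + 1e-9:
                raise ValueError(f"coverage targets for {g} must be positive "
                                 "proportions summing to <= 1")
        for g, dur in self.duration_targets_ms.items():
            if min(dur) <= 0:
                raise ValueError(f"durations for {g} must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.srate))

    @property
    def map_labels(self) -> tuple[str, ...]:
        return MAP_LABELS[: self.k_true]


@dataclass
class GroundTruth:
    """Everything the generator knows about one subject."""

    subject_id: str
    group: str
    templates: TemplateSet  # the subject's jittered true maps
    labels: np.ndarray  # true state per sample (mask applied -> UNLABELED)
    artifact_mask: np.ndarray
    params: TemporalParams  # recomputable exactly from `labels`
    transition: np.ndarray  # embedded-chain transition matrix used


# ---------------------------------------------------------------------------
# sensor layout and template maps


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """n roughly equidistant unit vectors on the upper hemisphere (a
    stand-in scalp sensor layout; no electrode coordinate files needed)."""
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    z = 0.05 + 0.95 * (i + 0.5) / n  # z in (0.05, 1): scalp cap
    theta = 2 * np.pi * i / golden
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _dipole_map(pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Potential of a random dipole inside the head sphere, mean-zero and
    unit-norm across sensors."""
    loc = rng.normal(size=3)
    loc = 0.6 * loc / np.linalg.norm(loc) * rng.uniform(0.3, 1.0)
    moment = rng.normal(size=3)
    moment /= np.linalg.norm(moment)
    d = pos - loc
    r3 = np.sum(d**2, axis=1) ** 1.5
    v = d @ moment / r3
    v = v - v.mean()
    return v / np.linalg.norm(v)


def make_templates(n_channels: int, k: int, seed: int = 0,
                   orthogonalize: bool = False,
                   max_sep_corr: float = 0.7,
                   max_tries: int = 500) -> TemplateSet:
    """k smooth, mean-zero, unit-norm topographies with pairwise
    |correlation| below ``max_sep_corr``.

    Maps are random dipole potentials on a spherical sensor layout;
    candidates too correlated with the accepted set are rejected.
    ``orthogonalize`` Gram-Schmidt-orthogonalizes the accepted maps for
    exactly uncorrelated templates.
    """
    if k > n_channels:
        raise ValueError("k cannot exceed n_channels")
    rng = np.random.default_rng(seed)
    pos = fibonacci_hemisphere(n_channels)
    maps: list[np.ndarray] = []
    for _ in range(max_tries):
        cand = _dipole_map(pos, rng)
        if all(abs(cand @ m) < max_sep_corr for m in maps):
            maps.append(cand)
        if len(maps) == k:
            break
    else:
        raise RuntimeError("could not build sufficiently separated maps")
    M = np.array(maps)
    if orthogonalize:
        q, _ = np.linalg.qr(M.T)
        M = q.T[:k]
        M = M - M.mean(axis=1, keepdims=True)
        M /= np.linalg.norm(M, axis=1, keepdims=True)
    labels = list(MAP_LABELS[:k]) if k <= 5 else [f"M{i}" for i in range(k)]
    return TemplateSet(maps=M, labels=labels, level="cohort")


# ---------------------------------------------------------------------------
# sequence and EEG rendering


def _embedded_weights(p: np.ndarray) -> np.ndarray:
    """Weights u for the chain P_ij = u_j/(1-u_i) (j != i) whose stationary
    distribution is p.

    That chain's stationary distribution is proportional to u(1-u), so u
    solves u_j(1-u_j) = c * p_j with sum(u) = 1; c is found by bisection.
    Unreachable targets (one state claiming more than half the runs) fall
    back to u = p with a warning.
    """
    c_hi = 1.0 / (4.0 * p.max())

    def u_of(c: float) -> np.ndarray:
        return (1.0 - np.sqrt(np.clip(1.0 - 4.0 * c * p, 0.0, None))) / 2.0

    if u_of(c_hi).sum() < 1.0 - 1e-9:
        import warnings
        warnings.warn("run-frequency targets unreachable for this chain "
                      "family; using proportional weights")
        return p / p.sum()
    lo, hi = 0.0, c_hi
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if u_of(mid).sum() < 1.0:
            lo = mid
        else:
            hi = mid
    u = u_of((lo + hi) / 2.0)
    return u / u.sum()


def _embedded_chain(cfg: SimConfig, group: str) -> tuple[np.ndarray, np.ndarray]:
    """Embedded-chain run frequencies w and transition matrix P.

    Stationary occupancy of the semi-Markov process is proportional to
    (run frequency) x (mean duration), so the target run frequencies are
    p_j proportional to coverage_j / duration_j; the chain weights that
    realize them are solved by :func:`_embedded_weights`.
    """
    cov = np.asarray(cfg.coverage_targets[group], dtype=float)
    dur = np.asarray(cfg.duration_targets_ms[group], dtype=float)
    p = cov / dur
    p /= p.sum()
    w = _embedded_weights(p)
    k = w.size
    P = np.tile(w, (k, 1)) / (1 - w)[:, None]
    np.fill_diagonal(P, 0.0)
    if cfg.transition_bias:
        labels = list(cfg.map_labels)
        for (src, dst), mult in cfg.transition_bias.items():
            i, j = labels.index(src), labels.index(dst)
            P[i, j] *= mult
    P /= P.sum(axis=1, keepdims=True)
    return p, P


def simulate_sequence(cfg: SimConfig, group: str,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Semi-Markov label sequence and the embedded transition matrix.

    State durations are gamma (shape ``cfg.gamma_shape``) with the group's
    per-map mean; the next state follows the embedded chain.
    """
    w, P = _embedded_chain(cfg, group)
    k = w.size
    dur_samples = np.asarray(cfg.duration_targets_ms[group]) * cfg.srate / 1000.0
    n = cfg.n_samples
    labels = np.empty(n, dtype=int)
    state = int(rng.choice(k, p=w))
    t = 0
    while t < n:
        mean_d = dur_samples[state]
        d = rng.gamma(cfg.gamma_shape, mean_d / cfg.gamma_shape)
        d = max(1, int(round(d)))
        labels[t:t + d] = state
        t += d
        state = int(rng.choice(k, p=P[state]))
    return labels, P


def _artifact_mask(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Contiguous masked blocks totalling ``artifact_fraction`` of samples."""
    n = cfg.n_samples
    mask = np.zeros(n, dtype=bool)
    total = int(round(cfg.artifact_fraction * n))
    if total == 0:
        return mask
    block = max(1, int(round(cfg.artifact_block_s * cfg.srate)))
    n_blocks = max(1, round(total / block))
    per_block = total // n_blocks
    seg_len = n // n_blocks
    for b in range(n_blocks):
        length = per_block if b < n_blocks - 1 else total - per_block * (n_blocks - 1)
        lo = b * seg_len
        start = lo + int(rng.integers(0, max(1, seg_len - length)))
        mask[start:start + length] = True
    return mask


def _structured_noise(cfg: SimConfig, pos_maps: np.ndarray, n_samples: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Spatially correlated Gaussian noise plus a white sensor component,
    scaled so the RMS column norm is amplitude_rms / snr."""
    C = pos_maps.shape[1]
    W = rng.standard_normal((cfg.noise_components, n_samples))
    structured = pos_maps.T @ W
    structured /= np.sqrt(np.mean(np.sum(structured**2, axis=0)))
    white = rng.standard_normal((C, n_samples))
    white /= np.sqrt(np.mean(np.sum(white**2, axis=0)))
    a = cfg.noise_white_fraction
    noise = np.sqrt(1 - a) * structured + np.sqrt(a) * white
    target = cfg.amplitude_uv / np.sqrt(2) / cfg.snr
    return noise * target


def render_eeg(cfg: SimConfig, templates: TemplateSet, labels: np.ndarray,
               mask: np.ndarray, rng: np.random.Generator) -> EEGRecording:
    """Render multichannel EEG from a label sequence.

    Each run of a state contributes ``template x amplitude x sin(2 pi f t
    + phi)`` with a random phase per run; structured noise is added on top.
    """
    n = labels.size
    t_axis = np.arange(n) / cfg.srate
    amp = np.zeros(n)
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [n]])
    phases = rng.uniform(0, 2 * np.pi, size=starts.size)
    for s, e, phi in zip(starts, ends, phases):
        amp[s:e] = np.sin(2 * np.pi * cfg.carrier_freq_hz * t_axis[s:e] + phi)
    signal = templates.maps[labels].T * (cfg.amplitude_uv * amp)[None, :]

    pos = fibonacci_hemisphere(cfg.n_channels)
    noise_maps = np.array([_dipole_map(pos, rng) for _ in range(cfg.noise_components)])
    data = signal + _structured_noise(cfg, noise_maps, n, rng)
    return EEGRecording(data=data, srate=cfg.srate, artifact_mask=mask,
                        reference="raw")


def _jitter_templates(true: TemplateSet, jitter: float,
                      rng: np.random.Generator) -> TemplateSet:
    pos = fibonacci_hemisphere(true.n_channels)
    maps = []
    for m in true.maps:
        noise = _dipole_map(pos, rng)
        maps.append(m + jitter * noise)
    return TemplateSet(maps=np.array(maps), labels=list(true.labels),
                       level="subject")


def _truth_params(labels: np.ndarray, mask: np.ndarray, srate: float,
                  k: int, map_labels: Sequence[str],
                  subject_id: str) -> TemporalParams:
    masked = labels.copy()
    masked[mask] = UNLABELED
    seg = Segmentation(labels=masked, corr=np.ones(labels.size),
                       gfp=np.ones(labels.size), srate=srate,
                       artifact_mask=mask, template_labels=list(map_labels))
    return temporal_parameters(seg, subject_id=subject_id)


def simulate_subject(cfg: SimConfig, templates: TemplateSet, group: str,
                     seed: int | Sequence[int] = 0,
                     subject_id: str = "S000") -> tuple[EEGRecording, GroundTruth]:
    """Simulate one subject: sequence, EEG, mask and ground truth."""
    rng = np.random.default_rng(seed)
    sub_templates = _jitter_templates(templates, cfg.template_jitter, rng)
    labels, P = simulate_sequence(cfg, group, rng)
    mask = _artifact_mask(cfg, rng)
    rec = render_eeg(cfg, sub_templates, labels, mask, rng)
    masked_labels = labels.copy()
    masked_labels[mask] = UNLABELED
    truth = GroundTruth(
        subject_id=subject_id, group=group, templates=sub_templates,
        labels=masked_labels, artifact_mask=mask,
        params=_truth_params(labels, mask, cfg.srate, cfg.k_true,
                             cfg.map_labels, subject_id),
        transition=P)
    return rec, truth


# ---------------------------------------------------------------------------
# cohort


@dataclass
class Cohort:
    """A simulated cohort: ground truths and clinical table held in memory,
    recordings rendered lazily (a full-scale cohort does not fit in RAM at
    once)."""

    config: SimConfig
    templates: TemplateSet  # cohort-level true maps
    truths: list[GroundTruth]
    clinical: pd.DataFrame
    _subject_seeds: dict = field(default_factory=dict)

    @property
    def subject_ids(self) -> list[str]:
        return [t.subject_id for t in self.truths]

    def truth(self, subject_id: str) -> GroundTruth:
        return next(t for t in self.truths if t.subject_id == subject_id)

    def recording(self, subject_id: str) -> EEGRecording:
        """Deterministically re-render one subject's EEG."""
        t = self.truth(subject_id)
        rec, _ = simulate_subject(self.config, self.templates, t.group,
                                  seed=self._subject_seeds[subject_id],
                                  subject_id=subject_id)
        return rec

    def iter_recordings(self) -> Iterator[tuple[str, EEGRecording, GroundTruth]]:
        for t in self.truths:
            yield t.subject_id, self.recording(t.subject_id), t


def simulate_cohort(cfg: SimConfig | None = None) -> Cohort:
    """Simulate the full two-group cohort with clinical scores.

    The ASD group receives the configured effect settings (default: the
    reference study's map-B pattern via the per-group targets). Clinical
    scores are drawn per group from the reference moments; each configured
    coupling (score, map, parameter, rho) replaces the score's independent
    Gaussian part with a correlated mixture of the subject's *true*
    temporal parameter, so correlation analyses have a known truth.
    """
    cfg = cfg or SimConfig()
    templates = make_templates(cfg.n_channels, cfg.k_true, seed=cfg.rng_seed)
    rng = np.random.default_rng([cfg.rng_seed, 0xC0])
    truths: list[GroundTruth] = []
    seeds: dict[str, list[int]] = {}
    idx = 0
    for group, size in cfg.group_sizes.items():
        for _ in range(size):
            sid = f"{group}{idx:03d}"
            seed = [cfg.rng_seed, 1, idx]
            sub_rng = np.random.default_rng(seed)
            sub_templates = _jitter_templates(templates, cfg.template_jitter, sub_rng)
            labels, P = simulate_sequence(cfg, group, sub_rng)
            mask = _artifact_mask(cfg, sub_rng)
            masked_labels = labels.copy()
            masked_labels[mask] = UNLABELED
            truths.append(GroundTruth(
                subject_id=sid, group=group, templates=sub_templates,
                labels=masked_labels, artifact_mask=mask,
                params=_truth_params(labels, mask, cfg.srate, cfg.k_true,
                                     cfg.map_labels, sid),
                transition=P))
            seeds[sid] = seed
            idx += 1
    clinical = _simulate_clinical(cfg, truths, rng)
    return Cohort(config=cfg, templates=templates, truths=truths,
                  clinical=clinical, _subject_seeds=seeds)


def _simulate_clinical(cfg: SimConfig, truths: Sequence[GroundTruth],
                       rng: np.random.Generator) -> pd.DataFrame:
    couplings = {(s, g): (m, p, r) for s, m, p, r in cfg.clinical_couplings
                 for g in ("ASD", "TD")}
    moments = ref.clinical_moments().set_index("score")
    rows: dict[str, list] = {"subject_id": [], "group": [], "sex": []}
    for t in truths:
        rows["subject_id"].append(t.subject_id)
        rows["group"].append(t.group)
        sexes = ref.SEX_COUNTS[t.group]
        p_m = sexes["M"] / (sexes["M"] + sexes["F"])
        rows["sex"].append("M" if rng.uniform() < p_m else "F")
    df = pd.DataFrame(rows)

    group_arr = df["group"].to_numpy()
    for score in moments.index:
        vals = np.empty(len(df))
        for g in ("ASD", "TD"):
            sel = group_arr == g
            mean = moments.loc[score, "mean_asd" if g == "ASD" else "mean_td"]
            sd = moments.loc[score, "sd_asd" if g == "ASD" else "sd_td"]
            eps = rng.standard_normal(sel.sum())
            if (score, g) in couplings and sd > 0 and sel.sum() > 1:
                m, p, rho = couplings[(score, g)]
                x = np.array([truths[i].params.table.loc[m, p]
                              for i in np.flatnonzero(sel)])
                z = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
                eps = rho * z + np.sqrt(1 - rho**2) * eps
            vals[sel] = mean + sd * eps
        colname = "age_years" if score == "age_years" else score
        df[colname] = vals
    # missing data per instrument, matching the reference per-row Ns
    for prefix, rates in cfg.missing_rates.items():
        cols = [c for c in df.columns if c.startswith(prefix)]
        for g, rate in rates.items():
            sel = np.flatnonzero(group_arr == g)
            drop = sel[rng.uniform(size=sel.size) < rate]
            df.loc[drop, cols] = np.nan
    df["age_years"] = df["age_years"].clip(lower=1.0)
    return df
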