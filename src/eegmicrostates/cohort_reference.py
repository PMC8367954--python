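"""Published summary statistics of the reference toddler cohort.

The synthetic generator emulates a resting-state high-density EEG study of
66 toddlers and preschoolers with autism spectrum disorder (ASD) and 47
typically developing (TD) peers, in which five microstate classes (A-E)
explained ~80% of the topographic variance and class B showed higher GEV,
mean duration, coverage and occurrence in the ASD group. The printed
group-level (mean, SD, N) summaries below serve two purposes: they are the
generator's default per-group targets, and they let moment-based tests and
power surrogates be run without the raw recordings (which are not
publicly distributed).
"""

from __future__ import annotations

import pandas as pd

GROUP_SIZES = {"ASD": 66, "TD": 47}
SEX_COUNTS = {"ASD": {"M": 55, "F": 11}, "TD": {"M": 39, "F": 8}}

# map, parameter -> (mean_asd, sd_asd, n_asd, mean_td, sd_td, n_td)
_TEMPORAL = {
    ("A", "gev"): (0.0909, 0.0310, 66, 0.0967, 0.0261, 47),
    ("A", "mean_duration_ms"): (71.58, 4.804, 66, 71.91, 3.985, 47),
    ("A", "coverage_pct"): (19.40, 4.853, 66, 20.65, 3.508, 47),
    ("A", "occurrence_per_s"): (2.357, 0.4418, 66, 2.503, 0.2859, 47),
    ("B", "gev"): (0.0983, 0.0317, 66, 0.0796, 0.0269, 47),
    ("B", "mean_duration_ms"): (72.48, 4.748, 66, 68.86, 3.500, 47),
    ("B", "coverage_pct"): (19.96, 4.390, 66, 16.36, 3.584, 47),
    ("B", "occurrence_per_s"): (2.398, 0.3540, 66, 2.092, 0.3333, 47),
    ("C", "gev"): (0.2249, 0.0483, 66, 0.2317, 0.0540, 47),
    ("C", "mean_duration_ms"): (84.12, 5.810, 66, 83.87, 6.313, 47),
    ("C", "coverage_pct"): (30.64, 5.100, 66, 30.76, 5.221, 47),
    ("C", "occurrence_per_s"): (3.081, 0.3300, 66, 3.111, 0.2675, 47),
    ("D", "gev"): (0.0747, 0.0270, 66, 0.0751, 0.0336, 47),
    ("D", "mean_duration_ms"): (70.01, 4.171, 66, 69.30, 4.183, 47),
    ("D", "coverage_pct"): (15.57, 4.353, 66, 15.61, 4.593, 47),
    ("D", "occurrence_per_s"): (1.951, 0.4640, 66, 1.976, 0.4438, 47),
    ("E", "gev"): (0.0627, 0.0295, 66, 0.0756, 0.0294, 47),
    ("E", "mean_duration_ms"): (68.27, 4.808, 66, 69.57, 5.057, 47),
    ("E", "coverage_pct"): (14.42, 5.152, 66, 16.62, 5.057, 47),
    ("E", "occurrence_per_s"): (1.846, 0.5499, 66, 2.090, 0.5178, 47),
}

# clinical score -> (mean_asd, sd_asd, n_asd, mean_td, sd_td, n_td)
_CLINICAL = {
    "age_years": (3.3, 1.0, 66, 3.3, 1.2, 55),
    "ADOS_total": (7.7, 1.8, 66, 1.0, 0.0, 55),
    "ADOS_SA": (6.7, 2.1, 66, 1.0, 0.0, 55),
    "ADOS_RRB": (8.7, 1.8, 66, 2.2, 1.9, 55),
    "MSEL_total_DQ": (73.4, 24.5, 55, 110.4, 13.7, 35),
    "MSEL_FM_DQ": (79.7, 21.3, 55, 104.0, 12.6, 35),
    "MSEL_VR_DQ": (86.4, 26.1, 55, 122.7, 23.8, 35),
    "MSEL_EL_DQ": (60.4, 28.5, 55, 104.2, 21.2, 35),
    "MSEL_RL_DQ": (67.0, 31.7, 55, 113.8, 16.5, 35),
    "CBCL_AffP": (58.7, 8.1, 49, 53.0, 5.4, 34),
    "CBCL_AnxP": (56.9, 9.7, 49, 52.4, 4.9, 34),
    "CBCL_ADHP": (55.9, 5.9, 49, 51.9, 3.3, 34),
    "CBCL_ODP": (54.9, 6.9, 49, 53.7, 7.1, 34),
    "CBCL_PDP": (68.7, 12.0, 49, 51.4, 4.1, 34),
}


def _to_frame(d: dict, keycols: list[str]) -> pd.DataFrame:
    rows = []
    for key, (ma, sa, na, mt, st, nt) in d.items():
        key = key if isinstance(key, tuple) else (key,)
        rows.append((*key, ma, sa, na, mt, st, nt))
    cols = keycols + ["mean_asd", "sd_asd", "n_asd", "mean_td", "sd_td", "n_td"]
    return pd.DataFrame(rows, columns=cols)


def temporal_moments() -> pd.DataFrame:
    """Group summary (mean, SD, N) of the four temporal parameters per map."""
    return _to_frame(_TEMPORAL, ["map", "parameter"])


def clinical_moments() -> pd.DataFrame:
    """Group summary (mean, SD, N) of age and the clinical score columns."""
    return _to_frame(_CLINICAL, ["score"])


def temporal_moment(map_label: str, parameter: str
                    ) -> tuple[float, float, int, float, float, int]:
    """(mean, SD, N) for ASD then TD for one map x parameter."""
    return _TEMPORAL[(map_label, parameter)]


def clinical_moment(score: str) -> tuple[float, float, int, float, float, int]:
    return _CLINICAL[score]
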