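"""Group comparisons, clinical correlations and bootstrap power analysis.

Group tests are normality-gated: when both samples pass the
D'Agostino-Pearson omnibus test the comparison uses an unpaired (Welch)
t-test, otherwise the Mann-Whitney U test; multiple comparisons are
corrected with Benjamini-Hochberg FDR within the natural block (the
4 parameters x K maps for temporal parameters; per clinical instrument
for correlations). The bootstrap subsampling analysis estimates, for each
simulated sample size, the likelihood of detecting a group difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import TemporalParams, PARAM_COLUMNS
from .io import params_to_frame, clinical_score_columns

#: Normality alpha for the D'Agostino-Pearson gate.
NORMALITY_ALPHA = 0.05
#: Minimum per-sample n for the omnibus test to be valid.
NORMALITY_MIN_N = 8

#: Clinical instrument blocks for FDR grouping, by column-name prefix.
INSTRUMENT_PREFIXES = {"ADOS": "ADOS", "MSEL": "MSEL", "CBCL": "CBCL"}


def normality_gate(sample_a: np.ndarray, sample_b: np.ndarray) -> str:
    """Choose ``"t"`` or ``"mann_whitney"`` for a two-sample comparison.

    Returns ``"t"`` iff both samples pass the D'Agostino-Pearson omnibus
    test at alpha 0.05. Samples below n = 8 (the test's validity floor)
    fall back to the rank test with a warning.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if min(a.size, b.size) < NORMALITY_MIN_N:
        warnings.warn("sample too small for the normality test; "
                      "using Mann-Whitney")
        return "mann_whitney"
    _, p_a = sps.normaltest(a)
    _, p_b = sps.normaltest(b)
    return "t" if (p_a >= NORMALITY_ALPHA and p_b >= NORMALITY_ALPHA) else "mann_whitney"


def _two_sample_test(a: np.ndarray, b: np.ndarray, test: str) -> tuple[float, float]:
    if test == "t":
        t, p = sps.ttest_ind(a, b, equal_var=False)
    else:
        t, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return float(t), float(p)


def compare_groups_fdr(params_a: Sequence[TemporalParams],
                       params_b: Sequence[TemporalParams],
                       alpha: float = 0.05) -> pd.DataFrame:
    """Compare every (map, parameter) between two groups of subjects.

    Produces one row per map x parameter (K x 4 comparisons) with the test
    chosen by :func:`normality_gate`, the raw p, and Benjamini-Hochberg
    FDR over the whole block.
    """
    if len(params_a) < 2 or len(params_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    fa = params_to_frame(params_a)
    fb = params_to_frame(params_b)
    rows = []
    for m in fa["map"].unique():
        for col in PARAM_COLUMNS:
            a = fa.loc[fa["map"] == m, col].dropna().to_numpy()
            b = fb.loc[fb["map"] == m, col].dropna().to_numpy()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                test = normality_gate(a, b)
            stat, p = _two_sample_test(a, b, test)
            rows.append((m, col, test, a.mean(), b.mean(), stat, p))
    df = pd.DataFrame(rows, columns=["map", "parameter", "test",
                                     "mean_a", "mean_b", "statistic", "p"])
    reject, q, _, _ = multipletests(df["p"], alpha=alpha, method="fdr_bh")
    df["q"] = q
    df["significant"] = reject
    return df


def welch_t_from_moments(mean_a: float, sd_a: float, n_a: int,
                         mean_b: float, sd_b: float, n_b: int
                         ) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test from summary moments.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom
    and a two-tailed p-value. Lets printed (mean, SD, N) summaries be
    re-tested without the raw data.
    """
    if sd_a < 0 or sd_b < 0 or n_a < 2 or n_b < 2:
        raise ValueError("need sd >= 0 and n >= 2 per group")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    if va + vb == 0:
        if mean_a == mean_b:
            raise ValueError("both SDs zero with equal means: t undefined")
        return np.inf, float(n_a + n_b - 2), 0.0
    t = (mean_a - mean_b) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def correlate_clinical(params: Sequence[TemporalParams] | pd.DataFrame,
                       clinical: pd.DataFrame,
                       score_set: Sequence[str] | None = None,
                       alpha: float = 0.05,
                       min_pairs: int = 8,
                       subset: str | None = None) -> pd.DataFrame:
    """Correlate each temporal parameter with each clinical score.

    Pearson when both variables pass the normality gate, Spearman
    otherwise; pairwise deletion of missing values; correlations with
    fewer than ``min_pairs`` complete pairs (or a constant variable) are
    skipped with a warning. FDR is applied within each clinical
    instrument block (ADOS / MSEL / CBCL; unrecognized scores form their
    own block). ``subset`` is an optional pandas query on the clinical
    table (e.g. ``"sex == 'M'"`` for a male-only sensitivity analysis).
    """
    frame = params if isinstance(params, pd.DataFrame) else params_to_frame(params)
    if subset:
        clinical = clinical.query(subset)
    scores = list(score_set) if score_set is not None else clinical_score_columns(clinical)
    wide = frame.pivot(index="subject_id", columns="map")
    wide.columns = [f"{m}_{p}" for p, m in wide.columns]
    merged = clinical.set_index(clinical["subject_id"].astype(str)).join(wide, how="inner")

    rows = []
    for pcol in wide.columns:
        for score in scores:
            if score not in merged.columns:
                continue
            sub = merged[[pcol, score]].apply(pd.to_numeric, errors="coerce").dropna()
            if len(sub) < min_pairs:
                warnings.warn(f"{pcol} vs {score}: fewer than {min_pairs} "
                              "complete pairs; skipped")
                continue
            x = sub[pcol].to_numpy()
            y = sub[score].to_numpy()
            if x.std() == 0 or y.std() == 0:
                warnings.warn(f"{pcol} vs {score}: constant variable; skipped")
                continue
            _, px = sps.normaltest(x)
            _, py = sps.normaltest(y)
            if px >= NORMALITY_ALPHA and py >= NORMALITY_ALPHA:
                method = "pearson"
                r, p = sps.pearsonr(x, y)
            else:
                method = "spearman"
                r, p = sps.spearmanr(x, y)
            rows.append((pcol, score, _instrument(score), method,
                         float(r), float(p), len(sub)))
    df = pd.DataFrame(rows, columns=["parameter", "score", "instrument",
                                     "method", "r", "p", "n"])
    if len(df):
        df["q"] = np.nan
        df["significant"] = False
        for _, idx in df.groupby("instrument").groups.items():
            reject, q, _, _ = multipletests(df.loc[idx, "p"], alpha=alpha,
                                            method="fdr_bh")
            df.loc[idx, "q"] = q
            df.loc[idx, "significant"] = reject
    return df


def _instrument(score: str) -> str:
    for prefix, name in INSTRUMENT_PREFIXES.items():
        if score.upper().startswith(prefix):
            return name
    return "other"


# ---------------------------------------------------------------------------
# bootstrap subsampling power analysis


@dataclass
class BootstrapConfig:
    """Subsampling settings: sample sizes ``n_min..n_max`` (step ``step``),
    ``reps`` bootstrap resamples per size, two-tailed t-test at ``alpha``.
    Resampling is with replacement within each group."""

    n_min: int = 3
    n_max: int = 47
    step: int = 1
    reps: int = 500
    alpha: float = 0.05
    rng_seed: int = 0
    with_replacement: bool = True

    def __post_init__(self) -> None:
        if self.n_min < 2:
            raise ValueError("n_min must be >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


def bootstrap_power_curve(values_a: np.ndarray, values_b: np.ndarray,
                          cfg: BootstrapConfig | None = None) -> pd.DataFrame:
    """Detection likelihood versus simulated sample size.

    For each n, draws ``reps`` resamples of size n per group (with
    replacement), applies an unpaired two-tailed t-test at ``alpha``, and
    reports the fraction significant. Returns a frame with columns
    (n, likelihood).
    """
    cfg = cfg or BootstrapConfig()
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    rng = np.random.default_rng(cfg.rng_seed)
    ns = np.arange(cfg.n_min, cfg.n_max + 1, cfg.step)
    rows = []
    for n in ns:
        if not cfg.with_replacement and (n > a.size or n > b.size):
            raise ValueError("n exceeds group size without replacement")
        if cfg.with_replacement:
            ra = a[rng.integers(0, a.size, size=(cfg.reps, n))]
            rb = b[rng.integers(0, b.size, size=(cfg.reps, n))]
        else:
            ra = np.stack([rng.choice(a, size=n, replace=False) for _ in range(cfg.reps)])
            rb = np.stack([rng.choice(b, size=n, replace=False) for _ in range(cfg.reps)])
        _, p = sps.ttest_ind(ra, rb, axis=1)
        rows.append((int(n), float(np.mean(p < cfg.alpha))))
    return pd.DataFrame(rows, columns=["n", "likelihood"])


def power_from_moments(mean_a: float, sd_a: float, mean_b: float, sd_b: float,
                       n: int, reps: int = 2000, alpha: float = 0.05,
                       rng: np.random.Generator | int | None = None) -> float:
    """Monte-Carlo detection likelihood for Gaussian groups given moments.

    Draws ``reps`` replicate pairs of size-``n`` samples from
    Normal(mean, sd) per group and reports the fraction of two-tailed
    unpaired t-tests significant at ``alpha``. This is the surrogate used
    when only printed summary statistics are available.
    """
    r = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    a = r.normal(mean_a, sd_a, size=(reps, n))
    b = r.normal(mean_b, sd_b, size=(reps, n))
    _, p = sps.ttest_ind(a, b, axis=1)
    return float(np.mean(p < alpha))
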