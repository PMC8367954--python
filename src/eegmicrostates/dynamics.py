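"""Markov-chain transition syntax of microstate sequences.

Observed transition probabilities between microstate classes are compared
with the probabilities expected if transitions only reflected how often
each class occurs; the elementwise ratio ("normalized" matrix) equals 1
under a memoryless sequence, so departures from 1 reveal syntax beyond
class prevalence.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import RunList, TransitionResult


def transition_counts(runs: RunList, k: int, bridge: int = 0) -> np.ndarray:
    """Count transitions between consecutive, temporally adjacent runs.

    A pair of successive runs (i then j) is counted only when the gap of
    unlabeled/masked samples between them is at most ``bridge`` samples
    (default 0: a transition across an excluded stretch is unobserved, not
    evidence). The diagonal is structurally zero — consecutive runs always
    differ in label unless separated by a gap, and same-label pairs across
    an allowed gap are ignored.
    """
    if runs.n_runs and int(runs.labels.max()) >= k:
        raise ValueError("k smaller than the largest run label")
    C = np.zeros((k, k))
    if runs.n_runs < 2:
        return C
    gaps = runs.starts[1:] - runs.ends[:-1]
    src = runs.labels[:-1]
    dst = runs.labels[1:]
    ok = (gaps <= bridge) & (src != dst)
    np.add.at(C, (src[ok], dst[ok]), 1.0)
    return C


def observed_vs_expected(counts: np.ndarray,
                         coverage: np.ndarray,
                         state_labels: Sequence[str] = ()) -> TransitionResult:
    """Observed, occurrence-expected and normalized transition matrices.

    Observed: ``P_ij = C_ij / sum_j C_ij``. Expected under prevalence
    alone: ``E_ij = c_j / sum_{m != i} c_m`` with ``c`` the per-class
    coverage proportions — the destination drawn by prevalence with the
    source excluded, which makes the normalized ratio exactly 1 for a
    memoryless sequence. Rows of states with no outgoing transitions are
    NaN (missing) and should be excluded from group statistics.
    """
    C = np.asarray(counts, dtype=float)
    k = C.shape[0]
    c = np.asarray(coverage, dtype=float)
    if c.shape != (k,) or (c < 0).any() or c.sum() <= 0:
        raise ValueError("coverage must be k nonnegative proportions with positive sum")
    c = c / c.sum()

    out = C.sum(axis=1)
    observed = np.full((k, k), np.nan)
    rows = out > 0
    observed[rows] = C[rows] / out[rows, None]

    expected = np.full((k, k), np.nan)
    for i in range(k):
        rest = c.sum() - c[i]
        if rest > 0:
            expected[i] = c / rest
            expected[i, i] = np.nan
    np.fill_diagonal(observed, np.nan)

    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = observed / expected
    return TransitionResult(observed=observed, expected=expected,
                            normalized=normalized,
                            n_transitions=int(C.sum()),
                            state_labels=list(state_labels))


def compare_transitions(group_a: Sequence[TransitionResult],
                        group_b: Sequence[TransitionResult],
                        alpha: float = 0.05,
                        use: str = "normalized") -> pd.DataFrame:
    """Edge-wise two-sample comparison of transition matrices.

    For every directed edge, the per-subject values of the chosen matrix
    (default the occurrence-normalized one) are compared between groups
    with an unpaired Welch t-test; Benjamini-Hochberg FDR is applied over
    all K(K-1) edges. Returns a tidy table with columns (source, dest,
    mean_a, mean_b, t, p, q, significant).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    k = getattr(group_a[0], use).shape[0]
    labels = group_a[0].state_labels or [str(i) for i in range(k)]

    def edge_values(group, i, j):
        vals = np.array([getattr(r, use)[i, j] for r in group])
        return vals[np.isfinite(vals)]

    rows = []
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            a = edge_values(group_a, i, j)
            b = edge_values(group_b, i, j)
            if a.size < 2 or b.size < 2:
                warnings.warn(f"edge {labels[i]}->{labels[j]} has too few "
                              "finite values; excluded")
                continue
            t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append((labels[i], labels[j], a.mean(), b.mean(), float(t), float(p)))
    df = pd.DataFrame(rows, columns=["source", "dest", "mean_a", "mean_b", "t", "p"])
    if len(df):
        reject, q, _, _ = multipletests(df["p"], alpha=alpha, method="fdr_bh")
        df["q"] = q
        df["significant"] = reject
    return df
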