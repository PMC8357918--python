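"""Consistency statistics: KS-D between normalized spectra, Spearman
correlation between vectorized connectivity matrices, the within-/between-
subject framework, repeated-measures ANOVA with partial eta squared, t-tests,
and ROI-wise consistency maps.

Within-subject consistency compares one subject's sessions across the three
timepoint pairs (BL-FU1, FU1-FU2, BL-FU2); between-subject consistency is, per
timepoint, the mean similarity of one subject with every other subject.  For
n subjects this yields n*3 within and n*3 between values per metric, so the
within-vs-between unpaired t-test on an 8-subject cohort has 24+24-2 = 46
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .connectivity import ConnectivityMatrix
from .spectral import PowerSpectrum

WITHIN_PAIRS = (("BL", "FU1"), ("FU1", "FU2"), ("BL", "FU2"))


class StatsError(ValueError):
    pass


@dataclass
class StatResult:
    name: str
    statistic: float
    df: tuple[int, int] | int
    p: float
    effect_size: float | None = None  # partial eta squared (ANOVA only)


def ks_spectral_distance(p: PowerSpectrum, q: PowerSpectrum,
                         return_p: bool = False):
    """Two-sample KS statistic between two normalized spectra.

    Each spectrum is treated as a probability mass over its frequency bins;
    D is the maximum absolute difference of the cumulative masses.  The
    optional p-value uses the asymptotic KS distribution with effective n =
    number of bins and is approximate (the bins are not independent samples).
    """
    if len(p.freqs) != len(q.freqs) or np.max(np.abs(p.freqs - q.freqs)) > 1e-9:
        raise StatsError("spectra must share one frequency grid")
    if p.band != q.band:
        raise StatsError("spectra must share the analysis band")
    mass_p = p.power / p.power.sum()
    mass_q = q.power / q.power.sum()
    d = float(np.max(np.abs(np.cumsum(mass_p) - np.cumsum(mass_q))))
    if not return_p:
        return d
    n_eff = len(p.freqs) / 2.0
    p_approx = float(sstats.kstwobign.sf(np.sqrt(n_eff) * d))
    return d, p_approx


def spearman_matrix_consistency(a: ConnectivityMatrix,
                                b: ConnectivityMatrix) -> float:
    """Spearman rho between the upper-triangle vectorizations (diagonal
    excluded) of two same-band connectivity matrices."""
    if a.band != b.band:
        raise StatsError("matrices must share the frequency band")
    va, vb = a.offdiag_vector(), b.offdiag_vector()
    if np.all(va == va[0]) or np.all(vb == vb[0]):
        raise StatsError("constant connectivity vector: rho undefined")
    rho, _ = sstats.spearmanr(va, vb)
    return float(rho)


def build_consistency_table(sessions: dict, timepoints=("BL", "FU1", "FU2"),
                            bands=("alpha", "beta")) -> pd.DataFrame:
    """Long-format within/between consistency table.

    ``sessions`` maps (subject, timepoint) to a dict with keys ``spectrum``
    (PowerSpectrum) and ``conn`` (band name -> ConnectivityMatrix).  Metrics:
    ``ks_d`` on spectra and ``spearman_<band>`` on connectivity matrices.
    """
    subjects = sorted({s for s, _ in sessions})
    for s in subjects:
        for t in timepoints:
            if (s, t) not in sessions:
                raise StatsError(f"missing session: subject {s}, timepoint {t}")

    def metric_value(metric, s1, t1, s2, t2):
        a, b = sessions[(s1, t1)], sessions[(s2, t2)]
        if metric == "ks_d":
            return ks_spectral_distance(a["spectrum"], b["spectrum"])
        band = metric.split("_", 1)[1]
        return spearman_matrix_consistency(a["conn"][band], b["conn"][band])

    metrics = ["ks_d"] + [f"spearman_{b}" for b in bands]
    rows = []
    for metric in metrics:
        for s in subjects:
            for t1, t2 in WITHIN_PAIRS:
                rows.append(dict(subject=s, kind="within", key=f"{t1}-{t2}",
                                 metric=metric,
                                 value=metric_value(metric, s, t1, s, t2)))
            for t in timepoints:
                others = [metric_value(metric, s, t, o, t)
                          for o in subjects if o != s]
                rows.append(dict(subject=s, kind="between", key=t,
                                 metric=metric, value=float(np.mean(others))))
    return pd.DataFrame(rows)


def rm_anova(values: np.ndarray) -> StatResult:
    """One-way repeated-measures ANOVA on an n_subjects x k_conditions table.

    F = MS_condition / MS_(condition x subject), df = (k-1, (k-1)(n-1));
    partial eta squared = SS_condition / (SS_condition + SS_error).
    """
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    if n < 2 or k < 2:
        raise StatsError("need at least 2 subjects and 2 conditions")
    grand = values.mean()
    ss_cond = n * np.sum((values.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((values.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((values - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    # sums of squares at the level of accumulated rounding noise are zero
    tol = n * k * (1e-12 * (np.abs(values).max() + 1.0)) ** 2
    if ss_cond < tol:
        ss_cond = 0.0
    if ss_err < tol:
        ss_err = 0.0
    df1, df2 = k - 1, (k - 1) * (n - 1)
    if ss_err == 0.0:
        f = np.inf if ss_cond > 0 else 0.0
        p = 0.0 if ss_cond > 0 else 1.0
    else:
        f = (ss_cond / df1) / (ss_err / df2)
        p = float(sstats.f.sf(f, df1, df2))
    denom = ss_cond + ss_err
    eta = ss_cond / denom if denom > 0 else 0.0
    return StatResult(name="rm_anova", statistic=float(f), df=(df1, df2),
                      p=p, effect_size=float(eta))


def compare_within_between(table: pd.DataFrame, metric: str) -> StatResult:
    """Two-tailed unpaired pooled-variance t-test of all within values against
    all between values for one metric."""
    sub = table[table.metric == metric]
    within = sub[sub.kind == "within"].value.to_numpy()
    between = sub[sub.kind == "between"].value.to_numpy()
    if len(within) < 2 or len(between) < 2:
        raise StatsError("need at least 2 values per group")
    pooled = np.var(within, ddof=1) + np.var(between, ddof=1)
    scale = (np.abs(within).max() + np.abs(between).max() + 1.0) ** 2
    if pooled <= 1e-20 * scale:
        raise StatsError("zero pooled variance")
    t, p = sstats.ttest_ind(within, between, equal_var=True)
    return StatResult(name=f"within_vs_between[{metric}]", statistic=float(t),
                      df=len(within) + len(between) - 2, p=float(p))


def paired_t(values_a: np.ndarray, values_b: np.ndarray,
             name: str = "paired_t") -> StatResult:
    """Paired two-tailed t-test; df = n - 1."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise StatsError("need two equal-length samples of size >= 2")
    diff = a - b
    scale = (np.abs(diff).max() + 1.0) ** 2
    if np.var(diff, ddof=1) <= 1e-20 * scale:
        if np.allclose(diff, 0.0, atol=1e-15):
            return StatResult(name=name, statistic=0.0, df=len(a) - 1, p=1.0)
        raise StatsError("zero variance of paired differences (degenerate)")
    t, p = sstats.ttest_rel(a, b)
    return StatResult(name=name, statistic=float(t), df=len(a) - 1,
                      p=float(p))


def roiwise_consistency_map(a: ConnectivityMatrix,
                            b: ConnectivityMatrix) -> np.ndarray:
    """Per-ROI Spearman rho between matching matrix rows, element (r, r)
    excluded — the ROI-resolved version of the matrix consistency."""
    if a.band != b.band:
        raise StatsError("matrices must share the frequency band")
    n = len(a.values)
    out = np.empty(n)
    for r in range(n):
        keep = np.arange(n) != r
        ra, rb = a.values[r, keep], b.values[r, keep]
        if np.all(ra == ra[0]) or np.all(rb == rb[0]):
            raise StatsError(f"constant row {r}: rho undefined")
        out[r] = sstats.spearmanr(ra, rb)[0]
    return out
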