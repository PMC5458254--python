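"""Statistical layer: rank correlation, paired t, Kaplan-Meier, log-rank.

These are the standard tools the hypoxia-mapping study design calls for:
Spearman rank correlation between imaging and histology/probe read-outs,
paired t-tests for within-animal contrasts, and survival comparison of
animals grouped by their low-PSIC area fraction.  Estimation is delegated
to scipy and lifelines; this module adds the study-specific grouping
rules, the exact-permutation Spearman p-value for small samples, and
plain-data containers for the results.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "DEFAULT_GROUP_CUTS",
    "spearman",
    "spearman_exact_p",
    "paired_t_test",
    "group_by_fraction",
    "km_estimate",
    "logrank_test",
    "correlate_fraction_histology",
]

#: Low-PSIC area-fraction cuts separating the low / medium / high groups.
DEFAULT_GROUP_CUTS = (0.20, 0.30)


@dataclass(frozen=True)
class SurvivalRecord:
    """One animal's follow-up: low-PSIC fraction, survival time, event flag."""

    subject_id: str
    low_fraction: float
    time_days: float
    event: bool

    def __post_init__(self) -> None:
        if self.time_days <= 0:
            raise ValueError("survival time must be positive")
        if not 0.0 <= self.low_fraction <= 1.0:
            raise ValueError("low_fraction must be in [0, 1]")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate at the observed event times."""

    event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk: np.ndarray
    n: int

    def __post_init__(self) -> None:
        t = np.asarray(self.event_times, dtype=float)
        s = np.asarray(self.survival_probs, dtype=float)
        r = np.asarray(self.at_risk, dtype=int)
        object.__setattr__(self, "event_times", t)
        object.__setattr__(self, "survival_probs", s)
        object.__setattr__(self, "at_risk", r)
        if not (len(t) == len(s) == len(r)):
            raise ValueError("event_times, survival_probs, at_risk must align")
        if len(s) and (np.any(np.diff(s) > 1e-12) or s[0] > 1.0 + 1e-12 or np.any(s < -1e-12)):
            raise ValueError("survival probabilities must be non-increasing within [0, 1]")

    @property
    def median_days(self) -> float:
        """Earliest event time with survival <= 0.5; NaN if never reached."""
        hit = np.nonzero(self.survival_probs <= 0.5 + 1e-12)[0]
        return float(self.event_times[hit[0]]) if len(hit) else math.nan


# ---------------------------------------------------------------------------
# Correlation and paired comparison
# ---------------------------------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Ties receive average ranks; rho is the Pearson correlation of the two
    rank vectors and the p-value uses the t distribution with n-2 df.
    A rank vector with zero variance (all values tied) has no defined
    correlation and raises ``ValueError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if len(x) < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.ptp(sps.rankdata(x)) == 0 or np.ptp(sps.rankdata(y)) == 0:
        raise ValueError("rank variance is zero: correlation undefined")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman_exact_p(x, y, max_n: int = 9) -> tuple[float, float]:
    """Spearman rho with an exact two-sided permutation p-value.

    Enumerates all n! permutations of the ranks of ``y`` (feasible for
    n <= 9) and reports the fraction with |rho| at least the observed
    |rho|.  Tie handling matches :func:`spearman` (average ranks).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if x.shape != y.shape or x.ndim != 1 or n < 3:
        raise ValueError("x and y must be 1-D, equal length, n >= 3")
    if n > max_n:
        raise ValueError(f"exact permutation p is limited to n <= {max_n}")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("rank variance is zero: correlation undefined")
    rxc = rx - rx.mean()
    sx = math.sqrt(float(rxc @ rxc))
    ryc = ry - ry.mean()
    sy = math.sqrt(float(ryc @ ryc))
    rho_obs = float(rxc @ ryc) / (sx * sy)
    perms = np.array(list(itertools.permutations(ry)), dtype=float)
    rhos = (perms - ry.mean()) @ rxc / (sx * sy)
    p = float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))
    return rho_obs, p


def paired_t_test(a, b) -> tuple[float, float, int]:
    """Two-sided paired Student t-test on ``a - b``.

    Returns ``(t, p, df)`` with ``df = n - 1``.  Identical samples
    (all differences zero) return ``(0, 1, n-1)``; constant nonzero
    differences have zero variance and raise ``ValueError``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired t-test needs two equal-length samples, n >= 2")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0, len(a) - 1
        raise ValueError("differences have zero variance: t statistic undefined")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), len(a) - 1


# ---------------------------------------------------------------------------
# Survival analysis
# ---------------------------------------------------------------------------

def group_by_fraction(
    records: list[SurvivalRecord],
    cuts: tuple[float, float] = DEFAULT_GROUP_CUTS,
) -> dict[str, list[SurvivalRecord]]:
    """Partition animals into low / medium / high low-PSIC-fraction groups.

    ``low: fraction < cuts[0]``; ``medium: cuts[0] <= fraction <= cuts[1]``
    (both boundaries belong to the medium group); ``high: fraction > cuts[1]``.
    """
    lo, hi = cuts
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("cuts must be strictly increasing within (0, 1)")
    groups: dict[str, list[SurvivalRecord]] = {"low": [], "medium": [], "high": []}
    for rec in records:
        if rec.low_fraction < lo:
            groups["low"].append(rec)
        elif rec.low_fraction <= hi:
            groups["medium"].append(rec)
        else:
            groups["high"].append(rec)
    return groups


def km_estimate(group: list[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate for one group.

    Censored observations reduce the risk set without contributing an
    event factor.  ``KMCurve.median_days`` is the earliest event time at
    which the estimate drops to 0.5 or below (NaN if never reached).
    """
    if not group:
        raise ValueError("cannot estimate a survival curve from an empty group")
    times = np.array([r.time_days for r in group], dtype=float)
    events = np.array([r.event for r in group], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    event_times = ev.index.to_numpy(dtype=float)
    at_risk = ev["at_risk"].to_numpy(dtype=int)
    survival = kmf.survival_function_at_times(event_times).to_numpy(dtype=float)
    return KMCurve(event_times=event_times, survival_probs=survival,
                   at_risk=at_risk, n=len(group))


def logrank_test(groups: list[list[SurvivalRecord]]) -> tuple[float, int, float]:
    """k-group log-rank test; returns ``(chi2, df, p)`` with ``df = k - 1``.

    At each distinct event time, observed events per group are compared
    with their hypergeometric expectation given the pooled risk set;
    ties across groups at the same time are pooled.
    """
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    times = np.concatenate([[r.time_days for r in g] for g in groups])
    events = np.concatenate([[r.event for r in g] for g in groups]).astype(bool)
    labels = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])
    if not events.any():
        raise ValueError("no events observed in any group: log-rank undefined")
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


def correlate_fraction_histology(
    fractions: list[tuple[str, float]],
    histo: list[tuple[str, float]],
) -> tuple[float, float, int]:
    """Spearman correlation of low-PSIC area fraction vs histology fraction.

    ``histo`` carries the combined (GLUT-1-positive + necrotic) area
    fraction per subject.  Subjects are matched by id; unmatched subjects
    are reported with a warning, never silently dropped.  Returns
    ``(rho, p, n_matched)``.
    """
    fa = pd.DataFrame(fractions, columns=["subject_id", "low_fraction"])
    fb = pd.DataFrame(histo, columns=["subject_id", "histo_fraction"])
    merged = fa.merge(fb, on="subject_id", how="outer", indicator=True)
    unmatched = merged.loc[merged["_merge"] != "both", "subject_id"].tolist()
    if unmatched:
        warnings.warn(f"subjects without a matched pair: {unmatched}", stacklevel=2)
    paired = merged[merged["_merge"] == "both"]
    if len(paired) < 3:
        raise ValueError(f"need >= 3 matched subjects, found {len(paired)}")
    rho, p = spearman(paired["low_fraction"].to_numpy(), paired["histo_fraction"].to_numpy())
    return rho, p, len(paired)
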