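"""Tissue pO2 probe-trace analysis.

A fiber-optic fluorescence-quenching probe records tissue oxygen partial
pressure (mmHg) continuously through the same three-stage gas protocol
as the imaging.  The summary statistic is

    delta_pO2 = pO2_max - pO2_pre

where, by definition, pO2_pre is the MEAN reading over the pre-oxygen
stage and pO2_max the MEAN reading over the 100% oxygen stage (despite
the "max" symbol).  Stage membership is decided purely by timestamp, so
the probe's sampling grid is independent of the MRI frame grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .psic import StageTiming

__all__ = ["PO2Trace", "PO2Summary", "clean_trace", "summarize_po2", "pair_psic_po2"]


@dataclass(frozen=True)
class PO2Trace:
    """A timestamped pO2 series from one probe site.

    Negative readings (probe artifacts) are retained but counted in
    ``n_negative``; use :func:`clean_trace` to floor them at zero.
    """

    times: np.ndarray
    values: np.ndarray
    site: str = "tumor"  # "tumor" or "penumbra"
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D and the same length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("trace times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("pO2 values must be finite")

    @property
    def n_negative(self) -> int:
        return int((self.values < 0).sum())


@dataclass(frozen=True)
class PO2Summary:
    """Stage-wise means and their difference, all in mmHg."""

    po2_pre: float
    po2_max: float

    @property
    def delta_po2(self) -> float:
        return self.po2_max - self.po2_pre


def clean_trace(trace: PO2Trace, floor_at_zero: bool = False) -> PO2Trace:
    """Optionally clamp negative probe readings to zero (off by default)."""
    if not floor_at_zero:
        return trace
    return replace(trace, values=np.maximum(trace.values, 0.0))


def summarize_po2(trace: PO2Trace, timing: StageTiming) -> PO2Summary:
    """Stage-wise summary of one trace.

    Requires at least two samples in each of the three stages.  Negative
    readings trigger a warning (they are retained; see
    :func:`clean_trace`).
    """
    pre, oxy, post = timing.stage_masks(trace.times)
    for name, mask in (("pre-oxygen", pre), ("oxygen", oxy), ("post-oxygen", post)):
        if mask.sum() < 2:
            raise ValueError(
                f"{name} stage holds {int(mask.sum())} samples of trace "
                f"{trace.subject_id}/{trace.site}; need >= 2"
            )
    if trace.n_negative:
        warnings.warn(
            f"trace {trace.subject_id}/{trace.site} contains {trace.n_negative} "
            "negative pO2 readings (retained; see clean_trace)",
            stacklevel=2,
        )
    return PO2Summary(
        po2_pre=float(trace.values[pre].mean()),
        po2_max=float(trace.values[oxy].mean()),
    )


def pair_psic_po2(
    roi_psics: pd.DataFrame, summaries: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inner-join ROI PSIC values with pO2 summaries on (subject_id, site).

    Parameters
    ----------
    roi_psics : DataFrame with columns ``subject_id, site, psic_pct``
    summaries : DataFrame with columns ``subject_id, site, po2_pre,
        po2_max, delta_po2``

    Returns
    -------
    (paired, unmatched)
        ``paired`` holds the inner join; ``unmatched`` reports every row
        of either table that found no partner (column ``source`` says
        which side it came from).  Duplicate (subject_id, site) keys in
        either table are rejected.
    """
    key = ["subject_id", "site"]
    for name, df in (("roi_psics", roi_psics), ("summaries", summaries)):
        if df.duplicated(subset=key).any():
            raise ValueError(f"duplicate (subject_id, site) keys in {name}")
    merged = roi_psics.merge(summaries, on=key, how="outer", indicator=True)
    paired = (
        merged[merged["_merge"] == "both"]
        .drop(columns="_merge")
        .reset_index(drop=True)
    )
    unmatched = merged[merged["_merge"] != "both"].copy()
    unmatched["source"] = unmatched["_merge"].map(
        {"left_only": "roi_psics", "right_only": "summaries"}
    )
    unmatched = unmatched.drop(columns="_merge").reset_index(drop=True)
    return paired, unmatched
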