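"""Protein abundance handling.

Quantification follows the standard isobaric-label workflow: each
peptide-spectrum match (PSM) carries one reporter intensity per time point;
PSM channels are normalized to the time-zero channel of the same PSM, and a
protein's abundance ratio at each time point is the median of its PSM ratios.
Proteins quantified by too few PSMs are discarded before network construction
(default: strictly more than 10 PSMs required).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass
class PSMTable:
    """PSM-level quantification: one row per PSM, one intensity per time point.

    ``frame`` columns: psm_id, protein_id, then one column per time point
    (column labels are the time points in hours, as floats).
    """

    frame: pd.DataFrame

    @property
    def time_points(self) -> tuple[float, ...]:
        return tuple(float(c) for c in self.frame.columns[2:])

    def psm_counts(self) -> pd.Series:
        return self.frame.groupby("protein_id").size()


@dataclass
class AbundanceMatrix:
    """Proteins x time points of abundance ratios relative to t=0.

    Rows are proteins, columns are time points in hours (strictly increasing,
    starting at 0). Values are dimensionless ratios; the t=0 column equals 1
    when produced by :func:`aggregate_psms`.
    """

    condition: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        cols = [float(c) for c in self.data.columns]
        if cols != sorted(cols) or (cols and cols[0] != 0.0):
            raise ValueError("time points must be strictly increasing and start at 0")
        self.data.columns = cols

    @property
    def proteins(self) -> list[str]:
        return list(self.data.index)

    @property
    def time_points(self) -> tuple[float, ...]:
        return tuple(self.data.columns)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def aggregate_psms(psms: PSMTable, condition: str = "") -> AbundanceMatrix:
    """Collapse PSM-level intensities to protein abundance ratios.

    Each PSM's channel intensities are divided by its own t=0 intensity; the
    protein ratio per time point is the median over its PSM ratios (standard
    midpoint median for even counts). PSMs with a non-positive t=0 intensity
    are rejected with a warning; proteins left with no PSM are dropped.
    """
    frame = psms.frame
    tcols = list(frame.columns[2:])
    t0 = frame[tcols[0]].to_numpy(dtype=float)
    bad = ~(t0 > 0)
    if bad.any():
        log.warning("rejecting %d PSMs with non-positive t=0 intensity", int(bad.sum()))
        frame = frame.loc[~bad]
        t0 = t0[~bad]
    ratios = frame[tcols].to_numpy(dtype=float) / t0[:, None]
    ratio_df = pd.DataFrame(ratios, columns=tcols)
    ratio_df["protein_id"] = frame["protein_id"].to_numpy()
    profile = ratio_df.groupby("protein_id").median().sort_index()
    profile.index.name = None
    return AbundanceMatrix(condition=condition, data=profile)


def filter_by_psm_count(psms: PSMTable, min_psms: int = 10) -> PSMTable:
    """Keep only proteins backed by strictly more than ``min_psms`` PSMs."""
    if min_psms < 0:
        raise ValueError("min_psms must be >= 0")
    counts = psms.psm_counts()
    keep = set(counts.index[counts > min_psms])
    return PSMTable(frame=psms.frame[psms.frame["protein_id"].isin(keep)].reset_index(drop=True))


@dataclass
class RelativeAbundance:
    """Per-protein difference profile vs. baseline and its total score."""

    profile: pd.DataFrame  # condition minus baseline, per time point
    total: pd.Series  # summed difference over all time points
    mode: str = "signed"


def relative_abundance(
    condition: AbundanceMatrix, baseline: AbundanceMatrix, mode: str = "signed"
) -> RelativeAbundance:
    """Difference of abundance profiles relative to the baseline condition.

    The difference profile is condition minus baseline at each shared time
    point, restricted to the shared proteome. The total score sums the
    differences over all time points between and including 0 and the last
    time point; ``mode="signed"`` (default) keeps the sign so that induction
    scores high, ``mode="absolute"`` sums absolute differences.
    """
    if condition.time_points != baseline.time_points:
        raise ValueError("condition and baseline must share time points")
    shared = condition.data.index.intersection(baseline.data.index)
    if len(shared) == 0:
        raise ValueError("no shared proteins between condition and baseline")
    diff = condition.data.loc[shared] - baseline.data.loc[shared]
    if mode == "signed":
        total = diff.sum(axis=1)
    elif mode == "absolute":
        total = diff.abs().sum(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    total.name = "total"
    return RelativeAbundance(profile=diff, total=total, mode=mode)
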