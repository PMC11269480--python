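"""Pooling of enzyme activities into C/N/P acquisition sums and ratios.

The five activities collapse into three acquisition pools:

    C = BG + CBH        (cellulose degradation)
    N = NAG + LAP       (chitin / peptide degradation)
    P = AP              (phosphomonoester hydrolysis)

Relative investment proportions feed the vector analysis:

    x = C / (C + P)     carbon- vs phosphorus-acquiring investment
    y = C / (C + N)     carbon- vs nitrogen-acquiring investment

Both are unit-free and invariant under uniform rescaling of all five
activities.  The global reference point is C:N:P ≈ 1:1:1, i.e.
x = y = 0.5.  An optional natural-log scale takes ln of each pooled sum
before forming the proportions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import DomainError, EnzymeProfile, SampleRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AcquisitionTriplet",
    "StoichSummary",
    "acquisitions",
    "investment_xy",
    "cohort_summary",
    "acquisition_frame",
]


@dataclass(frozen=True)
class AcquisitionTriplet:
    """Summed C-, N-, P-acquisition enzyme activities of one sample."""

    c_acq: float
    n_acq: float
    p_acq: float

    def __post_init__(self) -> None:
        for name in ("c_acq", "n_acq", "p_acq"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} is negative")


@dataclass(frozen=True)
class StoichSummary:
    """Cohort-level acquisition means and C-normalised ratios.

    ``ratio_n_to_c`` / ``ratio_p_to_c`` use the ratio of means (robust to
    small per-sample denominators); ``mean_ratio_*`` give the mean of
    per-sample ratios as a secondary view.
    """

    mean_c: float
    mean_n: float
    mean_p: float
    ratio_n_to_c: float
    ratio_p_to_c: float
    mean_ratio_n_to_c: float
    mean_ratio_p_to_c: float
    n: int


def acquisitions(profile: EnzymeProfile) -> AcquisitionTriplet:
    """Pool a five-enzyme profile into the C/N/P acquisition triplet."""
    return AcquisitionTriplet(
        c_acq=profile.bg + profile.cbh,
        n_acq=profile.nag + profile.lap,
        p_acq=profile.ap,
    )


def investment_xy(t: AcquisitionTriplet, ln_transform: bool = False) -> tuple[float, float]:
    """Relative investment proportions (x, y) for the vector analysis.

    Returns ``(nan, nan)`` when a denominator is zero (the sample is then
    excluded from vector statistics, with a log entry), and on the ln scale
    additionally when any pooled sum is ≤ 1 so that its log is not positive.
    """
    c, n, p = t.c_acq, t.n_acq, t.p_acq
    if ln_transform:
        if min(c, n, p) <= 0:
            logger.info("ln-scale investment undefined for non-positive pool")
            return (math.nan, math.nan)
        c, n, p = math.log(c), math.log(n), math.log(p)
        if c + p <= 0 or c + n <= 0 or min(c, n, p) < 0:
            logger.info("ln-scale investment outside the unit square; marked undefined")
            return (math.nan, math.nan)
    if c + p == 0 or c + n == 0:
        logger.info("zero acquisition denominator; sample marked undefined")
        return (math.nan, math.nan)
    return (c / (c + p), c / (c + n))


def acquisition_frame(
    records: Iterable[SampleRecord], ln_transform: bool = False
) -> pd.DataFrame:
    """Per-sample acquisition/investment table.

    Columns: sample_id, region, c_acq, n_acq, p_acq, x, y.
    """
    rows = []
    for r in records:
        t = acquisitions(r.enzymes)
        x, y = investment_xy(t, ln_transform=ln_transform)
        rows.append(
            {
                "sample_id": r.sample_id,
                "region": r.region.value,
                "c_acq": t.c_acq,
                "n_acq": t.n_acq,
                "p_acq": t.p_acq,
                "x": x,
                "y": y,
            }
        )
    return pd.DataFrame(rows)


def cohort_summary(records: Sequence[SampleRecord]) -> StoichSummary:
    """Pooled acquisition stoichiometry of a cohort, C normalised to 1."""
    if len(records) == 0:
        raise DomainError("cohort_summary requires at least one record")
    trips = [acquisitions(r.enzymes) for r in records]
    c = np.array([t.c_acq for t in trips])
    n = np.array([t.n_acq for t in trips])
    p = np.array([t.p_acq for t in trips])
    mean_c, mean_n, mean_p = c.mean(), n.mean(), p.mean()
    if mean_c <= 0:
        raise DomainError("mean C acquisition is zero; ratios undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = np.where(c > 0, n / c, np.nan)
        pc = np.where(c > 0, p / c, np.nan)
    return StoichSummary(
        mean_c=float(mean_c),
        mean_n=float(mean_n),
        mean_p=float(mean_p),
        ratio_n_to_c=float(mean_n / mean_c),
        ratio_p_to_c=float(mean_p / mean_c),
        mean_ratio_n_to_c=float(np.nanmean(nc)),
        mean_ratio_p_to_c=float(np.nanmean(pc)),
        n=len(records),
    )
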