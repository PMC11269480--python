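"""Vector analysis of ecoenzymatic stoichiometry.

Each sample's relative investments (x, y) — carbon vs phosphorus and
carbon vs nitrogen acquisition — define a point in the unit square.  The
vector from the origin to that point summarises metabolic limitation:

* vector length  VL = √(x² + y²): longer ⇒ stronger relative carbon
  limitation;
* vector angle   VA = degrees(arctan(y / x)), the angle of the point
  (x, y) above the x-axis: VA > 45° ⇒ phosphorus investment exceeds
  nitrogen investment (P limitation), VA < 45° ⇒ N limitation.

The angle convention matters: it is the first-quadrant angle of the point
(x, y), so that x = y gives exactly 45° and swapping x and y reflects the
angle about 45°.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DomainError, LimitationClass, RunConfig, SampleRecord
from .stoichiometry import acquisition_frame

logger = logging.getLogger(__name__)

__all__ = [
    "VectorResult",
    "vector_length",
    "vector_angle",
    "classify_limitation",
    "limitation_table",
    "cohort_vector_summary",
]

#: Half-width of the band around the threshold treated as an exact tie.
_TIE_TOL = 1e-9


@dataclass(frozen=True)
class VectorResult:
    """Vector statistics and limitation call for one sample."""

    sample_id: str
    x: float
    y: float
    length: float
    angle_deg: float
    limitation_class: LimitationClass


def vector_length(x: float, y: float) -> float:
    """Euclidean norm of the investment point; ranges over [0, √2]."""
    if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
        raise DomainError(f"investment proportions out of [0, 1]: x={x}, y={y}")
    return math.hypot(x, y)


def vector_angle(x: float, y: float) -> float:
    """First-quadrant angle of the point (x, y) in degrees.

    Returns ``nan`` for the origin (undefined direction); 90° when x = 0
    with y > 0, and 0° when y = 0 with x > 0.
    """
    if x < 0 or y < 0:
        raise DomainError(f"investment proportions must be non-negative: x={x}, y={y}")
    if x == 0 and y == 0:
        logger.info("vector angle undefined at the origin; sample excluded")
        return math.nan
    return math.degrees(math.atan2(y, x))


def classify_limitation(
    angle_deg: float, threshold: float = 45.0
) -> LimitationClass | None:
    """Call P vs N limitation from the vector angle.

    Angles above the threshold mean phosphorus limitation, below mean
    nitrogen limitation; ties within 1e-9° are reported as BALANCED.
    Returns ``None`` for an undefined (nan) angle.
    """
    if math.isnan(angle_deg):
        return None
    if abs(angle_deg - threshold) <= _TIE_TOL:
        return LimitationClass.BALANCED
    return (
        LimitationClass.P_LIMITED
        if angle_deg > threshold
        else LimitationClass.N_LIMITED
    )


def limitation_table(
    records: list[SampleRecord], cfg: RunConfig | None = None
) -> pd.DataFrame:
    """Per-sample vector results for a cohort.

    Columns: sample_id, region, x, y, length, angle_deg, class.  Samples
    with undefined investment (zero denominators) are retained with nan
    vector statistics and an empty class; they are excluded from summaries.
    """
    cfg = cfg or RunConfig()
    acq = acquisition_frame(records, ln_transform=cfg.ln_transform)
    out = []
    for _, row in acq.iterrows():
        x, y = row["x"], row["y"]
        if math.isnan(x) or math.isnan(y):
            vl = va = math.nan
            cls = None
        else:
            vl = vector_length(x, y)
            va = vector_angle(x, y)
            cls = classify_limitation(va, cfg.angle_threshold_deg)
        out.append(
            {
                "sample_id": row["sample_id"],
                "region": row["region"],
                "x": x,
                "y": y,
                "length": vl,
                "angle_deg": va,
                "class": cls.value if cls is not None else "",
            }
        )
    df = pd.DataFrame(out)
    if df["length"].notna().sum() == 0:
        raise DomainError("no sample has a defined limitation vector")
    return df


def cohort_vector_summary(vectors: pd.DataFrame, threshold: float = 45.0) -> dict:
    """Cohort summary: means and the P-limited fraction.

    The P-limited fraction is the share of defined samples lying above the
    1:1 enzymatic C:N vs C:P line (angle > threshold).
    """
    ok = vectors.dropna(subset=["length", "angle_deg"])
    n = len(ok)
    if n == 0:
        raise DomainError("no defined vectors to summarise")
    p_frac = float((ok["angle_deg"] > threshold + _TIE_TOL).mean())
    n_frac = float((ok["angle_deg"] < threshold - _TIE_TOL).mean())
    return {
        "n": n,
        "mean_length": float(ok["length"].mean()),
        "mean_angle_deg": float(ok["angle_deg"].mean()),
        "p_limited_fraction": p_frac,
        "n_limited_fraction": n_frac,
        "balanced_fraction": max(float(1.0 - p_frac - n_frac), 0.0),
    }
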