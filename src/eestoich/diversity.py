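"""Community diversity: Shannon index, Bray–Curtis, Hellinger, rarefaction.

Alpha diversity is the Shannon index in natural-log units (nats),
H = −Σ pᵢ ln pᵢ.  Beta diversity is the Bray–Curtis dissimilarity
Σ|aᵢ−bᵢ| / Σ(aᵢ+bᵢ), computed on raw counts; the Hellinger transformation
(square root of relative abundances) is exposed as the standard pre-step
for linear ordination methods.  Rarefaction subsamples each community
without replacement to a common depth so richness comparisons are not
driven by sequencing effort.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import CommunityTable, DistanceMatrix, DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "shannon_index",
    "bray_curtis",
    "distance_matrix",
    "hellinger",
    "rarefy",
    "diversity_frame",
]


def shannon_index(counts, base: float | None = None) -> float:
    """Shannon diversity H = −Σ pᵢ log pᵢ of one count vector.

    Natural log (nats) by default; pass ``base`` for other units.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if np.any(c < 0):
        raise DomainError("negative count in Shannon input")
    total = c.sum()
    if total == 0:
        raise DomainError("Shannon index undefined for an all-zero vector")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def bray_curtis(a, b) -> float:
    """Bray–Curtis dissimilarity Σ|aᵢ−bᵢ| / Σ(aᵢ+bᵢ) between two vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise DomainError("negative abundance in Bray-Curtis input")
    denom = (a + b).sum()
    if denom == 0:
        raise DomainError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(a - b).sum() / denom)


def distance_matrix(table: CommunityTable) -> DistanceMatrix:
    """Pairwise Bray–Curtis matrix over all samples with positive totals.

    All-zero samples are excluded with a warning.
    """
    depths = table.sample_depths()
    keep = depths > 0
    if keep.sum() < 2:
        raise DomainError("need at least 2 non-empty samples for a distance matrix")
    if not keep.all():
        dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
        logger.warning("excluding all-zero samples from distance matrix: %s", dropped)
    ids = [s for s, k in zip(table.sample_ids, keep) if k]
    counts = table.counts[keep].astype(float)
    d = squareform(pdist(counts, metric="braycurtis"))
    return DistanceMatrix(ids=ids, d=d)


def hellinger(table: CommunityTable) -> pd.DataFrame:
    """Hellinger-transformed abundances: √(countᵢⱼ / row totalᵢ).

    Each transformed row is a unit vector in Euclidean norm.
    """
    totals = table.sample_depths().astype(float)
    if np.any(totals == 0):
        raise DomainError("Hellinger transform undefined for all-zero samples")
    h = np.sqrt(table.counts / totals[:, None])
    return pd.DataFrame(h, index=table.sample_ids, columns=table.taxon_ids)


def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample every community to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning;
    the draw is a multivariate hypergeometric per sample and is
    reproducible for a fixed seed.
    """
    if depth < 1:
        raise DomainError("rarefaction depth must be >= 1")
    depths = table.sample_depths()
    if np.all(depths < depth):
        raise DomainError(f"no sample reaches rarefaction depth {depth}")
    rng = np.random.default_rng(seed)
    keep_ids, rows = [], []
    for sid, row, total in zip(table.sample_ids, table.counts, depths):
        if total < depth:
            logger.warning("dropping sample %s: %d reads < depth %d", sid, total, depth)
            continue
        if total == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
        keep_ids.append(sid)
    return CommunityTable(
        sample_ids=keep_ids,
        taxon_ids=list(table.taxon_ids),
        counts=np.array(rows, dtype=np.int64),
        phylum_of=dict(table.phylum_of),
    )


def diversity_frame(table: CommunityTable) -> pd.DataFrame:
    """Per-sample alpha diversity: Shannon (nats) and observed richness."""
    rows = []
    for sid, row in zip(table.sample_ids, table.counts):
        total = row.sum()
        rows.append(
            {
                "sample_id": sid,
                "shannon": shannon_index(row) if total > 0 else math.nan,
                "richness": int((row > 0).sum()),
            }
        )
    return pd.DataFrame(rows)
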