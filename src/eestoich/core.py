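"""Domain types shared by every stage of the pipeline.

The raw currency of the analysis is the activity of five hydrolytic
extracellular enzymes measured per sediment sample:

* BG  (β-1,4-glucosidase)       — carbon acquisition
* CBH (cellobiohydrolase)       — carbon acquisition
* NAG (β-N-acetyl-glucosaminidase) — nitrogen acquisition
* LAP (leucine aminopeptidase)  — nitrogen acquisition
* AP  (acid/alkaline phosphatase)  — phosphorus acquisition

All downstream statistics are ratios of these activities, so the pipeline
is unit-agnostic; by convention reports label activities as
nmol g⁻¹ dry sediment h⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Region",
    "LimitationClass",
    "EnzymeProfile",
    "SampleRecord",
    "CommunityTable",
    "DistanceMatrix",
    "RunConfig",
    "EEStoichError",
    "SchemaError",
    "ParseError",
    "DomainError",
    "ConfigError",
    "WATER_FIELDS",
    "SEDIMENT_FIELDS",
    "ENZYME_FIELDS",
]


class EEStoichError(Exception):
    """Base class for all package errors."""


class SchemaError(EEStoichError):
    """A required column or field is missing from an input table."""


class ParseError(EEStoichError):
    """A cell could not be parsed as the expected type."""


class DomainError(EEStoichError):
    """A value violates a domain precondition (negative activity, etc.)."""


class ConfigError(EEStoichError):
    """A run or generator configuration is infeasible."""


class Region(str, Enum):
    """Lake region: the small (SXK) and large (LXK) basins separated by a dyke."""

    SXK = "SXK"
    LXK = "LXK"


class LimitationClass(str, Enum):
    """Nutrient-limitation call from the vector angle relative to 45°."""

    P_LIMITED = "P_LIMITED"
    N_LIMITED = "N_LIMITED"
    BALANCED = "BALANCED"


# Canonical flat-table field names for the water / sediment compartments.
WATER_FIELDS: tuple[str, ...] = (
    "depth_m", "temp_c", "ph", "salinity", "tds_mg_l", "conductivity",
    "tn", "tp", "nh4", "no3", "no2", "po4", "n_to_p",
)
SEDIMENT_FIELDS: tuple[str, ...] = (
    "ph", "conductivity", "doc", "tc_g_kg", "tn_g_kg", "tp_g_kg",
    "nh4", "no3", "no2", "po4", "n_to_p",
)
ENZYME_FIELDS: tuple[str, ...] = ("bg", "cbh", "nag", "lap", "ap")


@dataclass(frozen=True)
class EnzymeProfile:
    """The five measured activities of one sediment sample.

    All values must be finite and non-negative; units cancel in every
    downstream ratio.
    """

    bg: float
    cbh: float
    nag: float
    lap: float
    ap: float

    def __post_init__(self) -> None:
        for name in ENZYME_FIELDS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise DomainError(f"enzyme activity {name!r} is not finite: {v!r}")
            if v < 0:
                raise DomainError(f"enzyme activity {name!r} is negative: {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.bg, self.cbh, self.nag, self.lap, self.ap])


@dataclass
class SampleRecord:
    """One site: region label, water and sediment physicochemistry, enzymes.

    ``water`` and ``sediment`` map field names (see :data:`WATER_FIELDS`,
    :data:`SEDIMENT_FIELDS`) to floats; missing measurements are stored as
    ``nan`` and handled pairwise downstream, never as silent zeros.
    """

    sample_id: str
    region: Region
    water: dict[str, float]
    sediment: dict[str, float]
    enzymes: EnzymeProfile

    def __post_init__(self) -> None:
        self.region = Region(self.region)
        depth = self.water.get("depth_m", math.nan)
        if math.isfinite(depth) and depth <= 0:
            raise DomainError(
                f"sample {self.sample_id!r}: water depth must be > 0, got {depth}"
            )
        for comp_name, comp in (("water", self.water), ("sediment", self.sediment)):
            for key, v in comp.items():
                if key in ("ph", "temp_c", "n_to_p"):
                    continue
                if math.isfinite(v) and v < 0:
                    raise DomainError(
                        f"sample {self.sample_id!r}: {comp_name}.{key} is negative"
                    )


def derived_n_to_p(tn: float, tp: float) -> float:
    """TN:TP ratio of one compartment; nan when either input is unusable."""
    if not (math.isfinite(tn) and math.isfinite(tp)) or tp <= 0 or tn < 0:
        return math.nan
    return tn / tp


@dataclass
class CommunityTable:
    """Samples × taxa count matrix with a taxon → phylum map.

    Counts are non-negative integers; every taxon has a phylum entry
    (possibly ``"Unclassified"``).
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray
    phylum_of: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n, t = self.counts.shape
        if n != len(self.sample_ids) or t != len(self.taxon_ids):
            raise ValueError("counts shape does not match id lists")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.taxon_ids)) != t:
            raise ValueError("duplicate taxon ids")
        if np.any(self.counts < 0):
            raise DomainError("negative count in community table")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise DomainError("non-integer count in community table")
            self.counts = self.counts.astype(np.int64)
        missing = [t_ for t_ in self.taxon_ids if t_ not in self.phylum_of]
        if missing:
            raise ValueError(f"taxa without phylum entry: {missing[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def sample_depths(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def phylum_proportions(self) -> "pd.DataFrame":  # noqa: F821
        """Per-sample relative abundance aggregated to phylum level."""
        import pandas as pd

        phyla = np.array([self.phylum_of[t] for t in self.taxon_ids])
        rel = self.counts / np.maximum(self.counts.sum(axis=1, keepdims=True), 1)
        df = pd.DataFrame(rel, index=self.sample_ids, columns=self.taxon_ids)
        return df.T.groupby(phyla).sum().T


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with sample labels."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries (row-major upper triangle, scipy order)."""
        iu = np.triu_indices(self.n, k=1)
        return self.d[iu]


@dataclass
class RunConfig:
    """Plumbing configuration for a pipeline run."""

    samples_path: str | None = None
    otu_bacteria_path: str | None = None
    otu_fungi_path: str | None = None
    taxonomy_bacteria_path: str | None = None
    taxonomy_fungi_path: str | None = None
    outdir: str = "results"
    seed: int = 0
    n_permutations: int = 999
    angle_threshold_deg: float = 45.0
    ln_transform: bool = False

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigError("permutation count must be >= 1")
        if not (0.0 < self.angle_threshold_deg < 90.0):
            raise ConfigError("angle threshold must lie in (0, 90) degrees")

    def to_dict(self) -> dict:
        return {
            "samples_path": self.samples_path,
            "otu_bacteria_path": self.otu_bacteria_path,
            "otu_fungi_path": self.otu_fungi_path,
            "taxonomy_bacteria_path": self.taxonomy_bacteria_path,
            "taxonomy_fungi_path": self.taxonomy_fungi_path,
            "outdir": self.outdir,
            "seed": self.seed,
            "n_permutations": self.n_permutations,
            "angle_threshold_deg": self.angle_threshold_deg,
            "ln_transform": self.ln_transform,
        }
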