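"""Delimited-table readers and writers.

Flat sample tables are CSV (TSV accepted) with one row per site.  Column
naming convention: water physicochemistry is prefixed ``water_``, sediment
``sed_``, and the five enzyme activities are bare lowercase symbols
(``bg, cbh, nag, lap, ap``).  OTU tables follow the classic tab-delimited
layout (taxa in rows, samples in columns, first column = OTU id) with a
two-column taxonomy TSV mapping OTU id to a lineage string.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .core import (
    ENZYME_FIELDS,
    SEDIMENT_FIELDS,
    WATER_FIELDS,
    CommunityTable,
    DomainError,
    EnzymeProfile,
    ParseError,
    Region,
    RunConfig,
    SampleRecord,
    SchemaError,
    derived_n_to_p,
)

logger = logging.getLogger(__name__)

#: Columns that must be present in a sample table.  The remaining water /
#: sediment fields are optional and read as missing when absent.
REQUIRED_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "region",
    "water_depth_m",
    "water_tds_mg_l",
    "water_conductivity",
    "sed_tc_g_kg",
    "sed_tn_g_kg",
    "sed_tp_g_kg",
    *ENZYME_FIELDS,
)

_NA_STRINGS = {"", "na", "nan", "n/a", "null"}


def _sniff_delimiter(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def _parse_cell(raw, row: int, column: str) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return math.nan
    s = str(raw).strip()
    if s.lower() in _NA_STRINGS:
        return math.nan
    try:
        return float(s)
    except ValueError:
        raise ParseError(
            f"non-numeric value {s!r} in column {column!r}, row {row}"
        ) from None


def read_sample_table(path: str | Path, delimiter: str | None = None) -> list[SampleRecord]:
    """Read a per-site sample table into :class:`SampleRecord` objects.

    Missing optional cells become ``nan`` (never silent zeros); ``n_to_p``
    ratio columns are derived from TN/TP of the same compartment when absent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"sample table not found: {path}")
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sample table is missing required columns: {missing}")

    records: list[SampleRecord] = []
    for i, row in df.iterrows():
        sid = str(row["sample_id"]).strip()
        try:
            region = Region(str(row["region"]).strip().upper())
        except ValueError:
            raise ParseError(
                f"unknown region {row['region']!r} for sample {sid!r} (expected SXK/LXK)"
            ) from None

        water = {
            f: _parse_cell(row.get(f"water_{f}"), i, f"water_{f}")
            for f in WATER_FIELDS
        }
        sediment = {
            f: _parse_cell(row.get(f"sed_{f}"), i, f"sed_{f}")
            for f in SEDIMENT_FIELDS
        }
        if not math.isfinite(water["n_to_p"]):
            water["n_to_p"] = derived_n_to_p(water["tn"], water["tp"])
        if not math.isfinite(sediment["n_to_p"]):
            sediment["n_to_p"] = derived_n_to_p(
                sediment["tn_g_kg"], sediment["tp_g_kg"]
            )

        enz = {f: _parse_cell(row.get(f), i, f) for f in ENZYME_FIELDS}
        bad = [k for k, v in enz.items() if not math.isfinite(v)]
        if bad:
            raise ParseError(
                f"sample {sid!r}: enzyme activities {bad} are missing or non-numeric"
            )
        records.append(
            SampleRecord(
                sample_id=sid,
                region=region,
                water=water,
                sediment=sediment,
                enzymes=EnzymeProfile(**enz),
            )
        )
    if not records:
        logger.warning("sample table %s contained no data rows", path)
    return records


def records_to_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    """Flatten records back into the canonical wide table."""
    rows = []
    for r in records:
        row: dict[str, object] = {"sample_id": r.sample_id, "region": r.region.value}
        row.update({f"water_{k}": r.water.get(k, math.nan) for k in WATER_FIELDS})
        row.update({f"sed_{k}": r.sediment.get(k, math.nan) for k in SEDIMENT_FIELDS})
        row.update({k: getattr(r.enzymes, k) for k in ENZYME_FIELDS})
        rows.append(row)
    return pd.DataFrame(rows)


def write_sample_table(records: Iterable[SampleRecord], path: str | Path) -> None:
    df = records_to_frame(records)
    df.to_csv(path, index=False, float_format="%.12g")


def _phylum_from_lineage(lineage: str) -> str:
    """Extract the phylum from a lineage string.

    Accepts greengenes/UNITE-style ``k__X;p__Y;...`` strings, plain
    semicolon-separated ranks (second field), or a bare phylum name.
    """
    s = lineage.strip()
    if not s:
        return "Unclassified"
    parts = [p.strip() for p in s.split(";")]
    for p in parts:
        if p.lower().startswith("p__"):
            name = p[3:].strip()
            return name or "Unclassified"
    if len(parts) >= 2 and parts[1]:
        return parts[1]
    return parts[0]


def read_otu_table(
    path: str | Path,
    taxonomy_path: str | Path,
    samples_in: str = "columns",
) -> CommunityTable:
    """Read an OTU count table plus taxonomy into a :class:`CommunityTable`.

    ``samples_in`` is ``"columns"`` for the classic taxa × samples layout or
    ``"rows"`` for its transpose.  Taxa absent from the taxonomy are mapped
    to ``"Unclassified"`` with a logged warning.
    """
    path, taxonomy_path = Path(path), Path(taxonomy_path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if samples_in == "rows":
        df = df.T
    elif samples_in != "columns":
        raise ValueError("samples_in must be 'columns' or 'rows'")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise DomainError(f"duplicated taxon ids in OTU table: {dupes[:5]}")
    counts = df.to_numpy()
    if np.any(~np.isfinite(counts.astype(float))):
        raise ParseError("non-numeric cell in OTU table")
    if np.any(counts < 0):
        raise DomainError("negative count in OTU table")

    tax = pd.read_csv(taxonomy_path, sep="\t", header=None, dtype=str)
    tax_map = dict(zip(tax.iloc[:, 0].str.strip(), tax.iloc[:, 1].fillna("")))
    taxon_ids = [str(t) for t in df.index]
    phylum_of: dict[str, str] = {}
    n_missing = 0
    for t in taxon_ids:
        if t in tax_map:
            phylum_of[t] = _phylum_from_lineage(tax_map[t])
        else:
            phylum_of[t] = "Unclassified"
            n_missing += 1
    if n_missing:
        logger.warning(
            "%d OTUs missing from taxonomy %s; mapped to 'Unclassified'",
            n_missing, taxonomy_path,
        )

    table = CommunityTable(
        sample_ids=[str(s) for s in df.columns],
        taxon_ids=taxon_ids,
        counts=counts.T.astype(np.int64),
        phylum_of=phylum_of,
    )
    empty = [s for s, d in zip(table.sample_ids, table.sample_depths()) if d == 0]
    if empty:
        logger.warning("samples with zero total counts (flagged): %s", empty)
    return table


def write_otu_table(table: CommunityTable, path: str | Path) -> None:
    df = pd.DataFrame(
        table.counts.T, index=pd.Index(table.taxon_ids, name="#OTU_ID"),
        columns=table.sample_ids,
    )
    df.to_csv(path, sep="\t")


def write_taxonomy(table: CommunityTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for t in table.taxon_ids:
            fh.write(f"{t}\tp__{table.phylum_of[t]}\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(
    tables: Mapping[str, pd.DataFrame],
    outdir: str | Path,
    *,
    config: Mapping | None = None,
    seed: int | None = None,
    extra: Mapping | None = None,
) -> dict:
    """Write one delimited file per named table plus a JSON run manifest.

    Returns the manifest.  Numeric columns are serialised at 12 significant
    digits so a write/read round trip is lossless at that precision, and two
    runs with the same seed produce byte-identical numeric payloads.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, dict] = {}
    for name, df in tables.items():
        sep = "\t" if name.endswith(".tsv") else ","
        fname = name if "." in name else f"{name}.csv"
        fpath = outdir / fname
        df.to_csv(fpath, sep=sep, index=False, float_format="%.12g")
        files[fname] = {"rows": int(len(df)), "sha256": _sha256(fpath)}
        if len(df) == 0:
            logger.warning("result table %s written with zero rows", fname)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config": dict(config) if config else {},
        "files": files,
    }
    if extra:
        manifest.update(extra)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_run_config(path: str | Path) -> RunConfig:
    with Path(path).open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def save_run_config(cfg: RunConfig, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
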