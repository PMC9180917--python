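"""Reading, filtering and aggregating CITES Trade Database-style records.

The CITES Trade Database exports bilateral, species-level transactions as CSV
with one row per (year, taxon, importer, exporter, term, ...) combination and
two independently reported quantities (importer- and exporter-side).  This
module parses that dialect, applies the wild-caught live-bird filter used
throughout the package, and reduces records to per-country trade totals.

Quantity reconciliation takes the maximum of the two reported values when both
are present, a common convention that mitigates one-sided under-reporting.
Records whose ``Origin`` differs from the ``Exporter`` are treated as
re-exports: the shipment still counts toward the importer's demand, but the
re-exporting country receives no supply credit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

logger = logging.getLogger(__name__)

#: Canonical internal column names, in output order.
TRADE_COLUMNS = [
    "year",
    "appendix",
    "taxon",
    "taxon_class",
    "importer",
    "exporter",
    "origin",
    "importer_qty",
    "exporter_qty",
    "term",
    "unit",
    "purpose",
    "source",
]

# Header-cell aliases, compared after lower-casing, stripping whitespace and
# trailing periods ("App." -> "app").
_HEADER_ALIASES = {
    "year": "year",
    "app": "appendix",
    "appendix": "appendix",
    "taxon": "taxon",
    "class": "taxon_class",
    "importer": "importer",
    "exporter": "exporter",
    "origin": "origin",
    "importer reported quantity": "importer_qty",
    "exporter reported quantity": "exporter_qty",
    "term": "term",
    "unit": "unit",
    "purpose": "purpose",
    "source": "source",
}

_MANDATORY = [
    "year",
    "taxon",
    "taxon_class",
    "importer",
    "exporter",
    "importer_qty",
    "exporter_qty",
    "term",
    "unit",
    "source",
]

# CSV header written by write_trade_csv, matching the public dialect.
_DIALECT_HEADER = {
    "year": "Year",
    "appendix": "App.",
    "taxon": "Taxon",
    "taxon_class": "Class",
    "importer": "Importer",
    "exporter": "Exporter",
    "origin": "Origin",
    "importer_qty": "Importer reported quantity",
    "exporter_qty": "Exporter reported quantity",
    "term": "Term",
    "unit": "Unit",
    "purpose": "Purpose",
    "source": "Source",
}


@dataclass
class TradeRecordSet:
    """An ordered collection of trade records plus provenance metadata.

    ``records`` is a DataFrame with the canonical :data:`TRADE_COLUMNS`;
    quantities are floats with NaN for missing, text columns are strings with
    "" for blank.  ``log_summary`` counts rows dropped during parsing.
    """

    records: pd.DataFrame
    provenance: str = "unknown"
    period: str | None = None
    log_summary: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class CountryTradeTotals:
    """Per-country totals of reconciled exported / imported quantities."""

    totals: pd.DataFrame  # index: country; columns: total_exported, total_imported
    period: str | None = None


@dataclass
class CovariateTable:
    """Per (country, period) governance covariates.

    ``rule_of_law`` is oriented so that higher means stronger enforcement;
    ``import_tariff`` and ``export_cost`` so that higher means a stronger
    trade barrier (the demander- and supplier-side proxies respectively).
    """

    table: pd.DataFrame  # columns: country, period, rule_of_law, import_tariff, export_cost


def _normalise_header(cell: str) -> str:
    return " ".join(str(cell).strip().lower().rstrip(".").split())


def read_trade_csv(path: str | Path) -> TradeRecordSet:
    """Parse a trade CSV in the CITES dialect into a :class:`TradeRecordSet`.

    Blank quantity cells become missing values (never zero).  Rows with a
    non-numeric quantity cell, an unparseable or pre-1900 year, or with both
    quantities missing are dropped and counted in ``log_summary``.

    Raises
    ------
    FormatError
        If a mandatory column is absent from the header.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)

    renames = {}
    for col in raw.columns:
        key = _normalise_header(col)
        if key in _HEADER_ALIASES:
            renames[col] = _HEADER_ALIASES[key]
    raw = raw.rename(columns=renames)
    for col in _MANDATORY:
        if col not in raw.columns:
            raise FormatError(f"mandatory column missing from {path.name}: {col!r}")
    for col in TRADE_COLUMNS:
        if col not in raw.columns:
            raw[col] = ""
    raw = raw[TRADE_COLUMNS]

    n_in = len(raw)
    bad = pd.Series(False, index=raw.index)

    year = pd.to_numeric(raw["year"].str.strip(), errors="coerce")
    bad |= year.isna() | (year <= 1900)

    qty = {}
    for col in ("importer_qty", "exporter_qty"):
        cells = raw[col].str.strip()
        parsed = pd.to_numeric(cells, errors="coerce")
        # blank is legitimately missing; non-blank yet unparseable is malformed
        bad |= parsed.isna() & (cells != "")
        bad |= parsed < 0
        qty[col] = parsed
    bad |= qty["importer_qty"].isna() & qty["exporter_qty"].isna()

    df = raw.loc[~bad].copy()
    df["year"] = year.loc[~bad].astype(int)
    for col in ("importer_qty", "exporter_qty"):
        df[col] = qty[col].loc[~bad].astype(float)
    for col in ("importer", "exporter", "origin"):
        df[col] = df[col].str.strip().str.upper()
    for col in ("taxon", "taxon_class", "term", "unit", "purpose", "source", "appendix"):
        df[col] = df[col].str.strip()

    n_dropped = int(bad.sum())
    if n_dropped:
        logger.warning("read_trade_csv(%s): dropped %d malformed row(s)", path.name, n_dropped)
    return TradeRecordSet(
        records=df.reset_index(drop=True),
        provenance=str(path),
        log_summary={"rows_read": n_in, "rows_dropped": n_dropped},
    )


def write_trade_csv(records: TradeRecordSet, path: str | Path) -> None:
    """Write records back out in the public CITES CSV dialect."""
    out = records.records.rename(columns=_DIALECT_HEADER)
    out.to_csv(path, index=False)


def filter_wild_live_birds(
    records: TradeRecordSet, period: tuple[int, int]
) -> TradeRecordSet:
    """Keep wild-sourced ("W"), live, whole-organism bird records in a period.

    The filter retains records with class Aves, term "live", source "W" and a
    blank unit (blank means whole organisms, as opposed to kg, parts, etc.),
    whose year falls in the closed interval ``period``.  Record order is
    preserved and the operation is idempotent.
    """
    year_lo, year_hi = period
    if year_lo > year_hi:
        raise ValueError(f"period lower bound {year_lo} exceeds upper bound {year_hi}")
    df = records.records
    keep = (
        (df["taxon_class"].str.lower() == "aves")
        & (df["term"].str.lower() == "live")
        & (df["source"] == "W")
        & (df["unit"] == "")
        & df["year"].between(year_lo, year_hi)
    )
    return TradeRecordSet(
        records=df.loc[keep].reset_index(drop=True),
        provenance=records.provenance,
        period=records.period,
        log_summary={**records.log_summary, "rows_filtered_out": int((~keep).sum())},
    )


def aggregate_totals(records: TradeRecordSet) -> CountryTradeTotals:
    """Reduce records to per-country exported / imported totals.

    Each record contributes its reconciled quantity -- the maximum of the
    present reported values -- to the exporter's ``total_exported`` and the
    importer's ``total_imported``.  Re-exports (``origin`` present and
    different from ``exporter``) are excluded from the exporter's total but
    still credited to the importer.
    """
    df = records.records
    qty = np.fmax(df["importer_qty"], df["exporter_qty"])  # NaN-aware max
    reexport = (df["origin"] != "") & (df["origin"] != df["exporter"])

    exported = (
        qty[~reexport].groupby(df.loc[~reexport, "exporter"]).sum()
        if (~reexport).any()
        else pd.Series(dtype=float)
    )
    imported = qty.groupby(df["importer"]).sum()
    totals = pd.DataFrame({"total_exported": exported, "total_imported": imported})
    totals = totals.fillna(0.0).sort_index()
    totals.index.name = "country"
    return CountryTradeTotals(totals=totals, period=records.period)


def read_covariates(path: str | Path) -> CovariateTable:
    """Read the per-country covariate CSV (country, period, three indices).

    Raises
    ------
    FormatError
        If a required column is missing.
    DataError
        If a (country, period) key is duplicated or a covariate is not finite.
    """
    path = Path(path)
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = ["country", "period", "rule_of_law", "import_tariff", "export_cost"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"covariate file missing column {col!r}")
    df = df[required].copy()
    df["country"] = df["country"].astype(str).str.strip().str.upper()
    df["period"] = df["period"].astype(str).str.strip()

    dup = df.duplicated(subset=["country", "period"], keep=False)
    if dup.any():
        key = df.loc[dup, ["country", "period"]].iloc[0]
        raise DataError(
            f"duplicated covariate key: country={key['country']!r} period={key['period']!r}"
        )
    values = df[["rule_of_law", "import_tariff", "export_cost"]].to_numpy(float)
    if not np.isfinite(values).all():
        bad_country = df.loc[~np.isfinite(values).all(axis=1), "country"].iloc[0]
        raise DataError(f"non-finite covariate for country {bad_country!r}")
    return CovariateTable(table=df.reset_index(drop=True))


def write_covariates(table: CovariateTable, path: str | Path) -> None:
    table.table.to_csv(path, index=False)
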