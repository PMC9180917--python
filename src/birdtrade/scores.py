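"""Country roles and the two scores linking geopolitics to trade volume.

A country is a *supplier* in a period when it exported more live wild birds
than it imported, a *demander* when the reverse holds, and excluded when the
two totals tie exactly.

The *expected score* E (0-8) summarises geopolitical weakness on two axes:
rule of law and trade barriers.  Each axis is quintile-binned within a
role-group into a 0-4 "weakness" bin (0 = strongest fifth, 4 = weakest fifth)
and the two bins are summed, so E = 0 means strong rule of law and strong
barriers and E = 8 means both weak.  The barrier proxy is role-dependent:
cost of exportation for suppliers, import tariffs for demanders.

The *real trade score* T (1-5) bins each country's traded volume into five
equal-width intervals of log10 volume, so T = 1 marks countries of low
importance in the bird trade and T = 5 the heaviest traders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cites_io import CountryTradeTotals, CovariateTable
from .errors import DegenerateBinningError, DomainError

logger = logging.getLogger(__name__)

ROLE_SUPPLIER = "supplier"
ROLE_DEMANDER = "demander"
ROLE_TIE = "excluded-tie"


@dataclass
class RoleAssignment:
    """Per-country market role with the volumes it is based on."""

    roles: pd.DataFrame  # index: country; columns: role, total_exported, total_imported
    period: str | None = None
    n_ties: int = 0


@dataclass
class VolumeBinCalibration:
    """Five equal-width log10 bins spanning a reference set of volumes."""

    edges: np.ndarray  # 6 strictly increasing log10 values
    role: str | None = None
    period: str | None = None

    def midpoints(self) -> np.ndarray:
        """log10 midpoint of each of the 5 bins."""
        return (self.edges[:-1] + self.edges[1:]) / 2.0


@dataclass
class ScoreTable:
    """Expected score and real trade score per country, role and period."""

    table: pd.DataFrame
    # columns: country, period, role, law_weakness_bin, barrier_weakness_bin,
    #          expected_score, volume, real_trade_score
    calibrations: dict | None = None  # role -> VolumeBinCalibration
    n_excluded_missing_covariates: int = 0


def assign_roles(totals: CountryTradeTotals) -> RoleAssignment:
    """Classify each country as supplier, demander, or excluded on a tie."""
    df = totals.totals
    role = np.where(
        df["total_exported"] > df["total_imported"],
        ROLE_SUPPLIER,
        np.where(df["total_imported"] > df["total_exported"], ROLE_DEMANDER, ROLE_TIE),
    )
    out = df.copy()
    out.insert(0, "role", role)
    n_ties = int((role == ROLE_TIE).sum())
    if n_ties:
        logger.warning("assign_roles: %d countr(y/ies) excluded on exact export/import tie", n_ties)
    return RoleAssignment(roles=out, period=totals.period, n_ties=n_ties)


def _rank_weakness_bins(values: np.ndarray, higher_is_stronger: bool) -> np.ndarray:
    # weakness ranks ascend from strongest (rank 1) to weakest (rank n)
    ranks = rankdata(-values if higher_is_stronger else values, method="average")
    bins = np.floor((ranks - 0.5) * 5.0 / values.size).astype(int)
    return np.clip(bins, 0, 4)


def bin_axis_weakness(values, higher_is_stronger: bool = True) -> np.ndarray:
    """Quintile-bin one governance axis into 0-4 weakness levels.

    Bin 0 holds the strongest fifth of the group and bin 4 the weakest;
    ``higher_is_stronger`` states the orientation of the raw values (True for
    a rule-of-law index or a barrier-strength proxy).  Ties share their
    average rank, so equal values always land in the same bin.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5 or np.unique(values).size < 5:
        raise DegenerateBinningError(
            f"need at least 5 distinct values to form quintiles, got "
            f"{np.unique(values).size} distinct of {values.size}; use coarser bins"
        )
    return _rank_weakness_bins(values, higher_is_stronger)


def expected_score(law_weakness_bin, barrier_weakness_bin):
    """Sum the two 0-4 weakness bins into the 0-8 expected score."""
    law = np.asarray(law_weakness_bin, dtype=int)
    barrier = np.asarray(barrier_weakness_bin, dtype=int)
    if ((law < 0) | (law > 4) | (barrier < 0) | (barrier > 4)).any():
        raise ValueError("weakness bins must lie in 0..4")
    total = law + barrier
    return int(total) if total.ndim == 0 else total


def fit_volume_bins(
    volumes, role: str | None = None, period: str | None = None,
    log_range: tuple[float, float] | None = None,
) -> VolumeBinCalibration:
    """Fit five equal-width log10 bins over a reference set of volumes.

    ``log_range`` overrides the data-driven [min, max] span, e.g. to reuse a
    calibration range fixed elsewhere.
    """
    volumes = np.asarray(volumes, dtype=float)
    if (volumes <= 0).any() or not np.isfinite(volumes).all():
        raise DomainError("volumes must be positive and finite")
    if log_range is not None:
        lo, hi = float(log_range[0]), float(log_range[1])
    else:
        logs = np.log10(volumes)
        lo, hi = float(logs.min()), float(logs.max())
    if not hi > lo:
        raise DomainError("degenerate volume range: all volumes equal")
    return VolumeBinCalibration(edges=np.linspace(lo, hi, 6), role=role, period=period)


def real_trade_score(volume, calibration: VolumeBinCalibration):
    """Map a volume to its 1-5 trade-score category under a calibration.

    The bin index of log10(volume) is clamped to [1, 5]; interior edges close
    their lower bin and the top bin is right-closed, so the maximum reference
    volume maps to 5.  Non-decreasing in volume for a fixed calibration.
    """
    volume = np.asarray(volume, dtype=float)
    if (volume <= 0).any():
        raise DomainError("volume must be positive")
    idx = np.searchsorted(calibration.edges, np.log10(volume), side="left")
    idx = np.clip(idx, 1, 5)
    return int(idx) if idx.ndim == 0 else idx


def build_score_table(
    roles: RoleAssignment,
    covariates: CovariateTable,
    period: str,
    volume_log_range: tuple[float, float] | None = None,
) -> ScoreTable:
    """Join roles, volumes and covariates into the per-country score table.

    Suppliers are scored on their exported volume with cost of exportation as
    the barrier proxy; demanders on their imported volume with import tariffs.
    Quintile bins and the volume calibration are computed within each
    role-group.  Countries without a covariate row for the period are excluded
    (counted, never silently dropped).
    """
    cov = covariates.table
    cov = cov[cov["period"] == period].set_index("country")

    frames = []
    n_missing = 0
    calibrations: dict[str, VolumeBinCalibration] = {}
    for role, volume_col, barrier_col in (
        (ROLE_SUPPLIER, "total_exported", "export_cost"),
        (ROLE_DEMANDER, "total_imported", "import_tariff"),
    ):
        group = roles.roles[roles.roles["role"] == role]
        present = group.index.intersection(cov.index)
        n_missing += len(group) - len(present)
        group = group.loc[present]
        if group.empty:
            continue
        law = cov.loc[present, "rule_of_law"].to_numpy(float)
        barrier = cov.loc[present, barrier_col].to_numpy(float)
        law_bin = bin_axis_weakness(law, higher_is_stronger=True)
        barrier_bin = bin_axis_weakness(barrier, higher_is_stronger=True)
        volumes = group[volume_col].to_numpy(float)
        calib = fit_volume_bins(volumes, role=role, period=period, log_range=volume_log_range)
        calibrations[role] = calib
        frames.append(
            pd.DataFrame(
                {
                    "country": present,
                    "period": period,
                    "role": role,
                    "law_weakness_bin": law_bin,
                    "barrier_weakness_bin": barrier_bin,
                    "expected_score": expected_score(law_bin, barrier_bin),
                    "volume": volumes,
                    "real_trade_score": real_trade_score(volumes, calib),
                }
            )
        )
    if n_missing:
        logger.warning(
            "build_score_table(%s): excluded %d countr(y/ies) lacking covariates",
            period,
            n_missing,
        )
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "country", "period", "role", "law_weakness_bin", "barrier_weakness_bin",
                "expected_score", "volume", "real_trade_score",
            ]
        )
    )
    return ScoreTable(
        table=table,
        calibrations=calibrations,
        n_excluded_missing_covariates=n_missing,
    )
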