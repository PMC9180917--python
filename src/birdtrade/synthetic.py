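"""Synthetic CITES-like worlds with known ground truth.

The generator emulates the data structure of the live wild-bird trade study:
a set of supplier countries (net exporters) and demander countries (net
importers), each with latent rule-of-law and trade-barrier positions on
[0, 1] (1 = strongest), a true expected geopolitical score E in 0-8 (sum of
two quintile weakness bins), a true trade-score category T in 1-5 drawn from
the cumulative-link model P(T <= k | E) = logistic(theta_k - beta * E) with
role-specific slope, and a true traded volume (a whole-bird count) placed
inside the category's equal-width log10 bin.

Two emitters serialise a world into the observable inputs of the pipeline:
bilateral trade records in the CITES CSV dialect (suppliers export to, and
demanders import from, rest-of-world partner codes, so each study country's
own-side total reproduces its true volume exactly) and a per-country
covariate table with seeded Gaussian observation noise, with the demander
import-tariff covariate shifted upward after the trade ban.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .cites_io import TRADE_COLUMNS, CovariateTable, TradeRecordSet
from .errors import ConfigurationError
from .scores import ROLE_DEMANDER, ROLE_SUPPLIER, _rank_weakness_bins

#: Year windows of the two study periods around the 2005 EU wild-bird ban.
PERIODS: dict[str, tuple[int, int]] = {"preban": (1995, 2005), "postban": (2006, 2017)}

_PERIOD_INDEX = {"preban": 1, "postban": 2}

#: Placeholder taxon for every synthetic record (a heavily traded parrot).
_PLACEHOLDER_TAXON = "Amazona aestiva"

_N_PARTNERS_POOL = 40  # rest-of-world partner codes available per role


@dataclass
class SyntheticWorldConfig:
    """Ground-truth parameters of a synthetic trade world.

    ``thresholds`` are the true cut points theta_1..theta_4 of the ordinal
    model shared by both roles; ``beta_supplier`` and ``beta_demander`` the
    role-specific slopes (positive and negative, respectively, in a world
    that mirrors the study's findings).  ``volume_log_mean``/``volume_log_sd``
    parameterise the log10 volume range spanned by the five trade-score bins
    (range = mean +/- 2.5 sd unless overridden by ``volume_log_min``/``max``).
    ``ban_shift`` is added to demander import tariffs after the ban.
    """

    n_suppliers: int = 80
    n_demanders: int = 80
    beta_supplier: float = 0.5
    beta_demander: float = -0.578
    thresholds: tuple[float, float, float, float] = (
        -1.3863, -0.4055, 0.4055, 1.3863,
    )
    volume_log_mean: float = 3.0
    volume_log_sd: float = 1.0
    volume_log_min: float | None = None
    volume_log_max: float | None = None
    covariate_noise_sd: float = 0.05
    ban_shift: float = 0.15
    volume_jitter: str = "uniform"  # "uniform" within bin, or "midpoint"
    seed: int = 0

    def validate(self) -> None:
        if self.n_suppliers < 2 or self.n_demanders < 2:
            raise ConfigurationError("need at least 2 countries per role")
        theta = np.asarray(self.thresholds, dtype=float)
        if theta.shape != (4,) or (np.diff(theta) <= 0).any():
            raise ConfigurationError("thresholds must be 4 strictly increasing reals")
        if self.volume_log_sd <= 0:
            raise ConfigurationError("volume_log_sd must be positive")
        if self.covariate_noise_sd < 0:
            raise ConfigurationError("covariate_noise_sd must be non-negative")
        if self.volume_jitter not in ("uniform", "midpoint"):
            raise ConfigurationError("volume_jitter must be 'uniform' or 'midpoint'")
        lo, hi = self.volume_log_range
        if not hi > lo:
            raise ConfigurationError("volume log range must have positive width")

    @property
    def volume_log_range(self) -> tuple[float, float]:
        lo = (
            self.volume_log_min
            if self.volume_log_min is not None
            else self.volume_log_mean - 2.5 * self.volume_log_sd
        )
        hi = (
            self.volume_log_max
            if self.volume_log_max is not None
            else self.volume_log_mean + 2.5 * self.volume_log_sd
        )
        return float(lo), float(hi)


@dataclass
class SyntheticWorld:
    """A generated world: per-country ground truth plus its configuration."""

    countries: pd.DataFrame
    # columns: country, role, law_latent, barrier_latent, law_weakness_bin,
    #          barrier_weakness_bin, expected_score, trade_category, volume
    config: SyntheticWorldConfig
    log_edges: np.ndarray  # 6 log10 bin edges shared by both roles


def _codes(prefix: str, n: int) -> list[str]:
    """ISO3-like codes; width grows beyond 3 characters for very large worlds."""
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    width = 2
    while 26**width < n:
        width += 1
    codes = []
    for i in range(n):
        suffix, k = "", i
        for _ in range(width):
            suffix = letters[k % 26] + suffix
            k //= 26
        codes.append(prefix + suffix)
    return codes


def _integer_volume_in_bin(x_log: np.ndarray, lo_edge: np.ndarray, hi_edge: np.ndarray) -> np.ndarray:
    """Round 10**x to a whole-bird count kept strictly inside its log bin."""
    v_lo = np.floor(10.0**lo_edge).astype(np.int64) + 1
    v_hi = np.floor(10.0**hi_edge).astype(np.int64)
    if (v_lo > v_hi).any():
        raise ConfigurationError(
            "a log-volume bin is too narrow to contain a whole-bird count; widen the range"
        )
    return np.clip(np.round(10.0**x_log).astype(np.int64), v_lo, v_hi)


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Draw a complete synthetic world from its configuration.

    Latent governance positions are uniform on [0, 1]; true weakness bins are
    the within-role quintile bins of those positions (the same binning rule
    the scoring stage applies); categories come from the configured
    cumulative-link model; volumes are whole-bird counts inside the
    category's log10 bin (uniform draw, or the bin midpoint when
    ``volume_jitter = "midpoint"``).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 11])
    theta = np.asarray(config.thresholds, dtype=float)
    lo, hi = config.volume_log_range
    edges = np.linspace(lo, hi, 6)

    frames = []
    for role, prefix, n, beta in (
        (ROLE_SUPPLIER, "S", config.n_suppliers, config.beta_supplier),
        (ROLE_DEMANDER, "D", config.n_demanders, config.beta_demander),
    ):
        law = rng.random(n)
        barrier = rng.random(n)
        law_bin = _rank_weakness_bins(law, higher_is_stronger=True)
        barrier_bin = _rank_weakness_bins(barrier, higher_is_stronger=True)
        E = law_bin + barrier_bin

        cum = expit(theta[None, :] - beta * E[:, None])  # n x 4, P(T <= k)
        u = rng.random(n)
        T = 1 + (u[:, None] > cum).sum(axis=1)

        if config.volume_jitter == "midpoint":
            x = (edges[T - 1] + edges[T]) / 2.0
        else:
            x = rng.uniform(edges[T - 1], edges[T])
        volume = _integer_volume_in_bin(x, edges[T - 1], edges[T])

        frames.append(
            pd.DataFrame(
                {
                    "country": _codes(prefix, n),
                    "role": role,
                    "law_latent": law,
                    "barrier_latent": barrier,
                    "law_weakness_bin": law_bin,
                    "barrier_weakness_bin": barrier_bin,
                    "expected_score": E,
                    "trade_category": T,
                    "volume": volume.astype(float),
                }
            )
        )
    return SyntheticWorld(
        countries=pd.concat(frames, ignore_index=True),
        config=config,
        log_edges=edges,
    )


def _split_integer(volume: int, shares: np.ndarray) -> np.ndarray:
    """Largest-remainder split of a whole count along Dirichlet shares."""
    raw = shares * volume
    parts = np.floor(raw).astype(np.int64)
    remainder = int(volume - parts.sum())
    order = np.argsort(-(raw - parts))
    parts[order[:remainder]] += 1
    return parts[parts > 0]


def emit_trade_records(world: SyntheticWorld, period: str) -> TradeRecordSet:
    """Serialise a world into CITES-dialect live wild-bird records.

    Suppliers appear on the exporter side and demanders on the importer side,
    each trading with 1-4 seeded rest-of-world partners ("X.." codes outside
    the study set); the per-country sum of own-side quantities equals the true
    volume exactly.  Years are drawn uniformly within the period window.
    """
    if period not in PERIODS:
        raise ValueError(f"unknown period {period!r}; expected one of {sorted(PERIODS)}")
    year_lo, year_hi = PERIODS[period]
    rng = np.random.default_rng([world.config.seed, _PERIOD_INDEX[period], 17])
    partners = _codes("X", _N_PARTNERS_POOL)

    rows = []
    for _, ctry in world.countries.iterrows():
        volume = int(ctry["volume"])
        k = min(int(rng.integers(1, 5)), volume)
        chosen = rng.choice(partners, size=k, replace=False)
        parts = _split_integer(volume, rng.dirichlet(np.ones(k)))
        for partner, qty in zip(chosen, parts):
            year = int(rng.integers(year_lo, year_hi + 1))
            supplier_side = ctry["role"] == ROLE_SUPPLIER
            rows.append(
                {
                    "year": year,
                    "appendix": "II",
                    "taxon": _PLACEHOLDER_TAXON,
                    "taxon_class": "Aves",
                    "importer": partner if supplier_side else ctry["country"],
                    "exporter": ctry["country"] if supplier_side else partner,
                    "origin": "",
                    "importer_qty": np.nan if supplier_side else float(qty),
                    "exporter_qty": float(qty) if supplier_side else np.nan,
                    "term": "live",
                    "unit": "",
                    "purpose": "T",
                    "source": "W",
                }
            )
    df = pd.DataFrame(rows, columns=TRADE_COLUMNS)
    df["appendix"] = df["appendix"].astype(str)
    return TradeRecordSet(records=df, provenance="synthetic", period=period)


def emit_covariates(world: SyntheticWorld, period: str) -> CovariateTable:
    """Noisy per-country observations of the latent governance positions.

    Each covariate is the latent position plus seeded Gaussian noise, clipped
    back to [0, 1].  After the ban ("postban"), demander import tariffs are
    additionally shifted by ``ban_shift`` (barriers raised by the ban), a
    uniform translation that leaves within-role rankings intact.
    """
    if period not in PERIODS:
        raise ValueError(f"unknown period {period!r}; expected one of {sorted(PERIODS)}")
    cfg = world.config
    rng = np.random.default_rng([cfg.seed, _PERIOD_INDEX[period], 29])
    df = world.countries
    n = len(df)

    def observe(latent: np.ndarray) -> np.ndarray:
        noise = rng.normal(0.0, cfg.covariate_noise_sd, size=n) if cfg.covariate_noise_sd else 0.0
        return np.clip(latent + noise, 0.0, 1.0)

    rule_of_law = observe(df["law_latent"].to_numpy())
    export_cost = observe(df["barrier_latent"].to_numpy())
    import_tariff = observe(df["barrier_latent"].to_numpy())
    if period == "postban":
        import_tariff = np.where(
            df["role"] == ROLE_DEMANDER, import_tariff + cfg.ban_shift, import_tariff
        )
    return CovariateTable(
        table=pd.DataFrame(
            {
                "country": df["country"],
                "period": period,
                "rule_of_law": rule_of_law,
                "import_tariff": import_tariff,
                "export_cost": export_cost,
            }
        )
    )


def config_to_dict(config: SyntheticWorldConfig) -> dict:
    """Plain-dict form of a config (for manifests and YAML round-trips)."""
    out = asdict(config)
    out["thresholds"] = list(out["thresholds"])
    return out
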