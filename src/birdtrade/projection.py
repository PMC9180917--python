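"""Monte-Carlo projection of trade volumes under geopolitical scenarios A-D.

Each scenario fixes a range of expected scores for suppliers and demanders
(e.g. under scenario A both roles face strong trade barriers and rule of law,
an expected score of 0-2; under scenario D both are weak, 6-8).  For every
replicate, each country draws an integer expected score uniformly from its
role's range, a trade-score category from the calibrated cumulative-link
model's predicted distribution at that score, and the category is
back-transformed to a volume at the midpoint of its log10 bin.  Summaries
over replicates give per-country and global projected volumes with
percentile uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ordinal import CLMFit, N_CATEGORIES, predict_category_probs
from .scores import ROLE_DEMANDER, ROLE_SUPPLIER, RoleAssignment, VolumeBinCalibration


@dataclass(frozen=True)
class ScenarioSpec:
    """Expected-score ranges (closed integer intervals) for the two roles."""

    name: str
    supplier_range: tuple[int, int]
    demander_range: tuple[int, int]

    def __post_init__(self):
        for lo, hi in (self.supplier_range, self.demander_range):
            if not (0 <= lo <= hi <= 8):
                raise ValueError("score ranges must be sub-intervals of [0, 8]")


#: The four storyline scenarios: strong (0-2) vs weak (6-8) geopolitics
#: crossed over the two roles.  A = both strong, B = strong suppliers / weak
#: demanders, C = weak suppliers / strong demanders, D = both weak.
DEFAULT_SCENARIOS: dict[str, ScenarioSpec] = {
    "A": ScenarioSpec("A", (0, 2), (0, 2)),
    "B": ScenarioSpec("B", (0, 2), (6, 8)),
    "C": ScenarioSpec("C", (6, 8), (0, 2)),
    "D": ScenarioSpec("D", (6, 8), (6, 8)),
}


@dataclass
class ScenarioProjection:
    """Per-country and per-replicate projection results for one scenario."""

    scenario: str
    country_summary: pd.DataFrame
    # columns: country, role, scenario, mean_volume, volume_lo, volume_hi,
    #          modal_category, count_1 .. count_5
    rep_totals: pd.DataFrame  # columns: supplier, demander (one row per replicate)
    n_reps: int
    seed: int


def score_to_volume(T, calibration: VolumeBinCalibration):
    """Back-transform a 1-5 category to the volume at its log10 bin midpoint."""
    T = np.asarray(T, dtype=int)
    if ((T < 1) | (T > N_CATEGORIES)).any():
        raise ValueError(f"category must lie in 1..{N_CATEGORIES}")
    vol = 10.0 ** calibration.midpoints()[T - 1]
    return float(vol) if vol.ndim == 0 else vol


def project_scenario(
    fit_supplier: CLMFit | None,
    fit_demander: CLMFit | None,
    roles: RoleAssignment,
    spec: ScenarioSpec,
    calib_supplier: VolumeBinCalibration | None,
    calib_demander: VolumeBinCalibration | None,
    n_reps: int = 1000,
    seed: int = 0,
    mode: str = "sample",
) -> ScenarioProjection:
    """Monte-Carlo projection of one scenario over the classified countries.

    ``mode="sample"`` draws the category from the full predicted distribution
    (propagating model uncertainty); ``mode="modal"`` always takes the modal
    category.  Tie-role countries are skipped.  Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if mode not in ("sample", "modal"):
        raise ValueError("mode must be 'sample' or 'modal'")
    role_info = {
        ROLE_SUPPLIER: (fit_supplier, calib_supplier, spec.supplier_range),
        ROLE_DEMANDER: (fit_demander, calib_demander, spec.demander_range),
    }
    present = roles.roles["role"]
    for role in (ROLE_SUPPLIER, ROLE_DEMANDER):
        fit, calib, _ = role_info[role]
        if (present == role).any() and (fit is None or calib is None):
            raise ValueError(f"no fitted model/calibration for role {role!r}")

    rng = np.random.default_rng([seed, ord(spec.name[0])])
    rows = []
    totals = {ROLE_SUPPLIER: np.zeros(n_reps), ROLE_DEMANDER: np.zeros(n_reps)}
    for country, role in present.items():
        if role not in role_info:
            continue  # excluded-tie
        fit, calib, (lo, hi) = role_info[role]
        scores = np.arange(lo, hi + 1)
        probs = np.stack([predict_category_probs(fit, int(s)) for s in scores])
        E_idx = rng.integers(0, len(scores), size=n_reps)
        if mode == "modal":
            T = probs.argmax(axis=1)[E_idx] + 1
        else:
            u = rng.random(n_reps)
            cum = np.cumsum(probs, axis=1)[E_idx]
            T = 1 + (u[:, None] > cum).sum(axis=1)
            T = np.minimum(T, N_CATEGORIES)  # guard cumsum rounding
        volumes = score_to_volume(T, calib)
        totals[role] += volumes
        counts = np.bincount(T, minlength=N_CATEGORIES + 1)[1:]
        rows.append(
            {
                "country": country,
                "role": role,
                "scenario": spec.name,
                "mean_volume": float(volumes.mean()),
                "volume_lo": float(np.percentile(volumes, 2.5)),
                "volume_hi": float(np.percentile(volumes, 97.5)),
                "modal_category": int(counts.argmax()) + 1,
                **{f"count_{k}": int(counts[k - 1]) for k in range(1, N_CATEGORIES + 1)},
            }
        )
    return ScenarioProjection(
        scenario=spec.name,
        country_summary=pd.DataFrame(rows),
        rep_totals=pd.DataFrame(
            {"supplier": totals[ROLE_SUPPLIER], "demander": totals[ROLE_DEMANDER]}
        ),
        n_reps=n_reps,
        seed=seed,
    )


def global_totals(projection: ScenarioProjection) -> pd.DataFrame:
    """Global projected volume per role: mean and 95% percentile interval."""
    out = []
    for role in (ROLE_SUPPLIER, ROLE_DEMANDER):
        reps = projection.rep_totals[role].to_numpy()
        out.append(
            {
                "scenario": projection.scenario,
                "role": role,
                "mean_total": float(reps.mean()),
                "total_lo": float(np.percentile(reps, 2.5)),
                "total_hi": float(np.percentile(reps, 97.5)),
            }
        )
    return pd.DataFrame(out)
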