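"""The over/under-representation statistic.

For each state, ordinary least squares of log10(unstructured occurrence
count) on log10(semi-structured record count) across species.  The
residual is the representation score: positive means the species is
over-represented on the unstructured platform relative to what its
semi-structured record count predicts; negative means under-represented.
Fitting per state absorbs state-level differences (observer base, effort,
avifauna) that are not of interest.

Zero counts cannot enter a log-log model; the default policy drops the
(state, species) pair from that state's fit and counts it in the fit
metadata, while the "add-one" policy applies log10(n + 1) on both axes as
a sensitivity variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigError

logger = logging.getLogger(__name__)

#: Minimum usable species for a per-state fit; keeps residual df positive.
MIN_SPECIES_PER_STATE = 3

ZERO_POLICIES = ("drop", "add-one")


@dataclass
class StateFit:
    """One state's log-log regression and its residuals."""

    state: str
    intercept: float
    slope: float
    r_squared: float
    n_species: int
    n_zero_dropped: int
    residuals: pd.Series = field(repr=False)  # species -> residual


def _log_axes(sub: pd.DataFrame, zero_policy: str) -> tuple[pd.DataFrame, int]:
    if zero_policy == "drop":
        usable = sub[(sub["n_ebird"] > 0) & (sub["n_inat"] > 0)].copy()
        n_zero = len(sub) - len(usable)
        usable["x"] = np.log10(usable["n_ebird"].to_numpy(dtype=float))
        usable["y"] = np.log10(usable["n_inat"].to_numpy(dtype=float))
    elif zero_policy == "add-one":
        usable = sub.copy()
        n_zero = 0
        usable["x"] = np.log10(usable["n_ebird"].to_numpy(dtype=float) + 1.0)
        usable["y"] = np.log10(usable["n_inat"].to_numpy(dtype=float) + 1.0)
    else:
        raise ConfigError(f"zero_policy must be one of {ZERO_POLICIES}, got {zero_policy!r}")
    return usable, n_zero


def fit_state_loglog(
    state_counts: pd.DataFrame, zero_policy: str = "drop"
) -> StateFit | None:
    """OLS of log10 unstructured count on log10 semi-structured count.

    ``state_counts`` holds one state's (species, n_ebird, n_inat) rows.
    Returns None (with a warning) when fewer than three usable species
    remain or the predictor is degenerate.
    """
    states = state_counts["state"].unique()
    if len(states) != 1:
        raise ValueError(f"fit_state_loglog expects a single state, got {list(states)}")
    state = states[0]
    usable, n_zero = _log_axes(state_counts, zero_policy)
    if len(usable) < MIN_SPECIES_PER_STATE:
        logger.warning(
            "state %s skipped: %d usable species (< %d)", state, len(usable),
            MIN_SPECIES_PER_STATE,
        )
        return None
    x = usable["x"].to_numpy()
    if np.ptp(x) == 0:
        logger.warning("state %s skipped: degenerate (constant) predictor", state)
        return None
    res = sm.OLS(usable["y"].to_numpy(), sm.add_constant(x)).fit()
    with np.errstate(invalid="ignore", divide="ignore"):
        r_squared = float(res.rsquared)
    if not np.isfinite(r_squared):  # constant response: 0/0 — fit is exact
        r_squared = 1.0 if res.ssr < 1e-12 else 0.0
    return StateFit(
        state=state,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        r_squared=r_squared,
        n_species=len(usable),
        n_zero_dropped=n_zero,
        residuals=pd.Series(res.resid, index=usable["species"].to_numpy()),
    )


def build_residual_table(
    counts: pd.DataFrame, zero_policy: str = "drop"
) -> tuple[pd.DataFrame, list[StateFit], list[str]]:
    """Per-state fits over an aggregated counts table.

    Returns the stacked residual table (state, species, residual, n_ebird,
    n_inat), the per-state fits, and the list of skipped states.  A
    species replicated across states appears once per state; the
    downstream mixed model's state random intercept accounts for that
    replication.
    """
    fits: list[StateFit] = []
    skipped: list[str] = []
    rows = []
    for state, sub in counts.groupby("state", sort=True):
        fit = fit_state_loglog(sub, zero_policy)
        if fit is None:
            skipped.append(state)
            continue
        fits.append(fit)
        merged = sub.merge(
            fit.residuals.rename("residual"),
            left_on="species",
            right_index=True,
            how="inner",
        )
        rows.append(merged[["state", "species", "residual", "n_ebird", "n_inat"]])
    if not rows:
        return (
            pd.DataFrame(columns=["state", "species", "residual", "n_ebird", "n_inat"]),
            fits,
            skipped,
        )
    table = pd.concat(rows, ignore_index=True)
    return table.sort_values(["state", "species"]).reset_index(drop=True), fits, skipped


def _r_squared(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return float(res.rsquared), float(res.params[1])


def summarize_correlations(
    counts: pd.DataFrame, state_checklist_totals: dict | pd.Series
) -> dict:
    """Cross-platform sampling-agreement summaries (log10 scale).

    State level: R^2 between a state's retained checklist total and its
    unstructured observation total.  Species level: R^2 between pooled
    per-species totals on the two platforms (species with zero on either
    platform excluded from the log fit).  Omitted (None) below 3 states
    or 3 species.
    """
    out: dict = {"state_level": None, "species_level": None}
    totals = pd.Series(state_checklist_totals, dtype=float)
    inat_by_state = counts.groupby("state")["n_inat"].sum()
    joint = pd.concat({"checklists": totals, "inat": inat_by_state}, axis=1).dropna()
    joint = joint[(joint > 0).all(axis=1)]
    if len(joint) >= 3 and np.ptp(np.log10(joint["checklists"].to_numpy())) > 0:
        r2, slope = _r_squared(
            np.log10(joint["checklists"].to_numpy()), np.log10(joint["inat"].to_numpy())
        )
        out["state_level"] = {"r_squared": r2, "slope": slope, "n": int(len(joint))}

    sp = counts.groupby("species")[["n_ebird", "n_inat"]].sum()
    sp = sp[(sp > 0).all(axis=1)]
    if len(sp) >= 3 and np.ptp(np.log10(sp["n_ebird"].to_numpy())) > 0:
        r2, slope = _r_squared(
            np.log10(sp["n_ebird"].to_numpy()), np.log10(sp["n_inat"].to_numpy())
        )
        out["species_level"] = {"r_squared": r2, "slope": slope, "n": int(len(sp))}
    return out
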