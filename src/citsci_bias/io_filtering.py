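"""Reading of the tabular inputs and the semi-structured quality filters.

Checklists carry effort metadata (protocol, complete flag, duration,
distance travelled).  Only "best quality" checklists enter the analysis:
complete, a non-incidental/non-historical protocol, travelled at most 5 km
and lasted between 5 and 240 minutes.  The boundaries are inclusive: a
checklist at exactly 5 km, 5 min or 240 min is retained.  Species are then
trimmed per state to the core avifauna by a checklist-prevalence cutoff
(default: species on fewer than 1% of a state's retained checklists are
removed; the inequality is strict, so exactly 1% survives), and per-(state,
species) observation totals are aggregated for both platforms, where one
observation is a single unique sighting of a species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, EmptyInputError, SchemaError

logger = logging.getLogger(__name__)

CHECKLIST_COLUMNS = (
    "checklist_id",
    "state",
    "protocol",
    "complete",
    "duration_minutes",
    "distance_km",
)
EBIRD_OBS_COLUMNS = ("checklist_id", "species", "count")
INAT_OBS_COLUMNS = ("observation_id", "state", "species")

#: Removal reasons used in :class:`FilterReport`, in evaluation order.
FILTER_CRITERIA = (
    "incomplete",
    "excluded_protocol",
    "distance_gt_max",
    "distance_missing",
    "duration_lt_min",
    "duration_gt_max",
    "duration_missing",
)


@dataclass(frozen=True)
class FilterConfig:
    """Quality-filter settings for semi-structured checklists.

    Defaults encode the standard effort filter: complete checklists only,
    no incidental/historical protocols, distance <= 5 km, duration within
    [5, 240] minutes, and a 1% per-state prevalence cutoff for the species
    trim.
    """

    max_distance_km: float = 5.0
    min_duration_min: float = 5.0
    max_duration_min: float = 240.0
    require_complete: bool = True
    exclude_protocols: frozenset = frozenset({"incidental", "historical"})
    prevalence_cutoff: float = 0.01

    def __post_init__(self):
        if not self.min_duration_min < self.max_duration_min:
            raise ConfigError(
                "min_duration_min must be < max_duration_min "
                f"(got {self.min_duration_min} >= {self.max_duration_min})"
            )
        if not 0.0 <= self.prevalence_cutoff <= 1.0:
            raise ConfigError(
                f"prevalence_cutoff must be in [0, 1], got {self.prevalence_cutoff}"
            )
        if self.max_distance_km < 0:
            raise ConfigError(f"max_distance_km must be >= 0, got {self.max_distance_km}")
        object.__setattr__(self, "exclude_protocols", frozenset(self.exclude_protocols))


@dataclass
class FilterReport:
    """Accounting for one pass of :func:`filter_checklists`.

    ``removals`` counts checklists failing each criterion; a checklist
    failing several criteria is counted once per criterion but removed
    once, so ``n_input == n_retained + n_removed`` always reconciles.
    """

    n_input: int
    n_retained: int
    n_removed: int
    removals: dict = field(default_factory=dict)

    def reconciles(self) -> bool:
        return self.n_input == self.n_retained + self.n_removed


@dataclass
class PrevalenceResult:
    """Per-(state, species) checklist prevalence plus drop accounting."""

    table: pd.DataFrame
    n_unreferenced_dropped: int
    empty_states: list


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required column(s): {', '.join(missing)}")


def _read_table(path, required, what: str, dialect: str = "csv") -> pd.DataFrame:
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ConfigError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True,
                         na_values=[""], skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{what} file {path} is empty") from None
    if df.empty:
        raise EmptyInputError(f"{what} file {path} contains a header but no rows")
    _require_columns(df, required, what)
    return df


def _parse_bool(s: pd.Series, path) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "t": True, "f": False, "yes": True, "no": False}
    out = s.str.strip().str.lower().map(mapping)
    bad = out.isna() & s.notna()
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2)[:5].tolist()  # +2: header + 1-based
        raise SchemaError(
            f"unparseable boolean 'complete' values in {path} near line(s) {lines}"
        )
    return out


def _parse_float(s: pd.Series, name: str, path) -> pd.Series:
    out = pd.to_numeric(s, errors="coerce")
    bad = out.isna() & s.notna()
    if bad.any():
        lines = (np.flatnonzero(bad.to_numpy()) + 2)[:5].tolist()
        raise SchemaError(f"unparseable {name!r} values in {path} near line(s) {lines}")
    return out


def read_checklists(path, dialect: str = "csv") -> pd.DataFrame:
    """Read a checklist table; blank effort cells stay missing, never zero."""
    df = _read_table(path, CHECKLIST_COLUMNS, "checklist", dialect)
    df["complete"] = _parse_bool(df["complete"], path)
    df["duration_minutes"] = _parse_float(df["duration_minutes"], "duration_minutes", path)
    df["distance_km"] = _parse_float(df["distance_km"], "distance_km", path)
    df["protocol"] = df["protocol"].str.strip().str.lower()
    if df["checklist_id"].duplicated().any():
        raise SchemaError(f"duplicate checklist_id values in {path}")
    if (df["state"].isna() | (df["state"].str.len() == 0)).any():
        raise SchemaError(f"empty state labels in {path}")
    return df.reset_index(drop=True)


def read_ebird_obs(path, dialect: str = "csv") -> pd.DataFrame:
    """Read checklist-linked species records; counts stay as strings ('X' legal)."""
    return _read_table(path, EBIRD_OBS_COLUMNS, "eBird observation", dialect).reset_index(drop=True)


def read_inat_obs(path, dialect: str = "csv") -> pd.DataFrame:
    """Read occurrence-per-row records from the unstructured platform."""
    return _read_table(path, INAT_OBS_COLUMNS, "occurrence", dialect).reset_index(drop=True)


def filter_checklists(
    checklists: pd.DataFrame, cfg: FilterConfig | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the quality filters; returns retained checklists and a report.

    Missing distance is allowed only for the stationary protocol (stationary
    implies 0 km travelled); missing duration always fails the duration
    filter.  Boundary values (exactly ``max_distance_km``,
    ``min_duration_min`` or ``max_duration_min``) are retained.
    """
    cfg = cfg or FilterConfig()
    n = len(checklists)
    fails = {}

    complete = checklists["complete"].fillna(False).to_numpy(dtype=bool)
    fails["incomplete"] = ~complete if cfg.require_complete else np.zeros(n, bool)

    protocol = checklists["protocol"].to_numpy()
    fails["excluded_protocol"] = np.isin(protocol, list(cfg.exclude_protocols))

    dist = checklists["distance_km"].to_numpy(dtype=float)
    dist_missing = np.isnan(dist)
    stationary = protocol == "stationary"
    fails["distance_gt_max"] = ~dist_missing & (dist > cfg.max_distance_km)
    fails["distance_missing"] = dist_missing & ~stationary

    dur = checklists["duration_minutes"].to_numpy(dtype=float)
    dur_missing = np.isnan(dur)
    fails["duration_lt_min"] = ~dur_missing & (dur < cfg.min_duration_min)
    fails["duration_gt_max"] = ~dur_missing & (dur > cfg.max_duration_min)
    fails["duration_missing"] = dur_missing

    any_fail = np.zeros(n, bool)
    for mask in fails.values():
        any_fail |= mask
    retained = checklists.loc[~any_fail].reset_index(drop=True)
    report = FilterReport(
        n_input=n,
        n_retained=len(retained),
        n_removed=int(any_fail.sum()),
        removals={k: int(m.sum()) for k, m in fails.items()},
    )
    if report.n_retained == 0:
        logger.warning("quality filter removed every checklist (%d input rows)", n)
    return retained, report


def compute_prevalence(
    ebird_obs: pd.DataFrame, retained_checklists: pd.DataFrame
) -> PrevalenceResult:
    """Per-(state, species) fraction of retained checklists containing the species.

    Duplicate species rows within one checklist count once.  Observations
    referencing checklists absent from ``retained_checklists`` are dropped
    and counted in the result.
    """
    state_of = retained_checklists.set_index("checklist_id")["state"]
    obs = ebird_obs.merge(
        state_of.rename("state"), left_on="checklist_id", right_index=True, how="left"
    )
    unref = obs["state"].isna()
    n_unref = int(unref.sum())
    if n_unref:
        logger.warning("dropped %d observation(s) referencing non-retained checklists", n_unref)
    obs = obs.loc[~unref]

    per_state_total = retained_checklists.groupby("state").size()
    hits = (
        obs.drop_duplicates(["checklist_id", "species"])
        .groupby(["state", "species"])
        .size()
        .rename("n_checklists_with_species")
        .reset_index()
    )
    hits["prevalence"] = (
        hits["n_checklists_with_species"] / hits["state"].map(per_state_total).to_numpy()
    )
    # States with zero retained checklists have no rows here: their species
    # were all dropped as unreferenced above and are counted in n_unref.
    empty_states: list = []
    return PrevalenceResult(
        table=hits.sort_values(["state", "species"]).reset_index(drop=True),
        n_unreferenced_dropped=n_unref,
        empty_states=empty_states,
    )


def trim_species(counts_with_prevalence: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Remove (state, species) rows with prevalence strictly below ``cutoff``.

    A species may survive in one state and not in another.  Prevalence
    exactly at the cutoff is retained.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ConfigError(f"prevalence cutoff must be in [0, 1], got {cutoff}")
    keep = counts_with_prevalence["prevalence"].to_numpy() >= cutoff
    return counts_with_prevalence.loc[keep].reset_index(drop=True)


def aggregate_counts(
    ebird_obs: pd.DataFrame,
    retained_checklists: pd.DataFrame,
    inat_obs: pd.DataFrame,
    retained_species: pd.DataFrame,
) -> pd.DataFrame:
    """Aggregate per-(state, species) observation totals for both platforms.

    ``n_ebird`` counts unique (checklist, species) records on retained
    checklists; ``n_inat`` counts occurrence rows.  Species retained by the
    trim but absent from the unstructured platform are emitted with
    ``n_inat = 0`` (zero handling is deferred downstream).
    """
    state_of = retained_checklists.set_index("checklist_id")["state"]
    eb = ebird_obs.merge(
        state_of.rename("state"), left_on="checklist_id", right_index=True, how="inner"
    )
    n_ebird = (
        eb.drop_duplicates(["checklist_id", "species"])
        .groupby(["state", "species"])
        .size()
        .rename("n_ebird")
    )
    n_inat = inat_obs.groupby(["state", "species"]).size().rename("n_inat")

    out = retained_species[["state", "species"]].drop_duplicates().copy()
    out = out.merge(n_ebird.reset_index(), on=["state", "species"], how="left")
    out = out.merge(n_inat.reset_index(), on=["state", "species"], how="left")
    out["n_ebird"] = out["n_ebird"].fillna(0).astype(int)
    out["n_inat"] = out["n_inat"].fillna(0).astype(int)
    return out.sort_values(["state", "species"]).reset_index(drop=True)
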