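"""Synthetic observation data with planted state and trait effects.

Every downstream stage is testable without the multi-hundred-GB real
extracts: the generator emulates their statistical structure — state-level
effort heterogeneity, positively skewed per-species record counts, a
per-state log-log linear relation between the two platforms, and
trait-dependent deviations from it — while retaining the planted truth for
parameter-recovery checks.

Two entry points:

* :func:`generate_counts_direct` draws aggregated per-(state, species)
  counts straight from the generative model; this is the fast path used by
  recovery studies.
* :func:`generate_event_level` additionally materialises checklists with
  effort metadata and labelled quality-filter violations, plus
  checklist-linked species records (including occasional "X" counts) and
  occurrence-per-row records, so the filtering stage is exercised on
  realistic inputs.

Defaults emulate contiguous-US-scale structure: per-state effort spanning
about an order of magnitude, species record rates positively skewed over
roughly two orders of magnitude, and an unstructured:semi-structured
volume ratio near 1:200 (state intercepts centred on -2.3 on the log10
scale at unit slope).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import traits as traits_mod
from .errors import ConfigError

_WHITE = np.array([255.0, 255.0, 255.0])
_BROWN = np.asarray(traits_mod.BROWN_RGB)
# Per-patch displacement factors along the brown->white axis; the first
# patch always attains the species' target displacement so the max over
# patches is monotone in the target.
_MALE_PATCH_FACTORS = np.array([1.0, 0.85, 0.7, 0.55, 0.4, 0.25])
_FEMALE_DIMORPHISM = 0.75

IUCN_LEVELS = ("Least Concern", "Near Threatened", "Vulnerable")


@dataclass(frozen=True)
class TraitGenConfig:
    """Distributional settings for the species-trait generator.

    Body mass is log-normal on the gram scale (defaults centre near 50 g
    with ~0.65 dex spread, songbird-to-waterbird range); flock size is 1
    plus a log-normal mean group size; the color target is Beta(2, 2) on
    [0, 1]; IUCN categories are drawn with probabilities over
    (Least Concern, Near Threatened, Vulnerable) plus an optional
    Endangered mass.
    """

    n_species: int = 150
    body_mass_log10_mean: float = 1.7
    body_mass_log10_sd: float = 0.65
    color_index_distribution: tuple = ("beta", 2.0, 2.0)
    flock_size_log10_mean: float = 0.35
    flock_size_log10_sd: float = 0.45
    iucn_probs: tuple = (0.88, 0.07, 0.05)
    endangered_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_species < 2:
            raise ConfigError(f"n_species must be >= 2, got {self.n_species}")
        for name in ("body_mass_log10_sd", "flock_size_log10_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        probs = (*self.iucn_probs, self.endangered_prob)
        if len(self.iucn_probs) != 3 or any(p < 0 for p in probs):
            raise ConfigError(f"iucn_probs must be 3 nonnegative values, got {self.iucn_probs}")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ConfigError(
                f"iucn_probs (+ endangered_prob) must sum to 1, got {sum(probs)!r}"
            )
        kind = self.color_index_distribution[0]
        params = self.color_index_distribution[1:]
        if kind == "beta":
            if len(params) != 2 or min(params) <= 0:
                raise ConfigError(
                    f"color_index_distribution beta needs two positive shapes, got {params}"
                )
        elif kind == "uniform":
            if len(params) != 2 or not 0 <= params[0] < params[1] <= 1:
                raise ConfigError(
                    f"color_index_distribution uniform needs 0 <= lo < hi <= 1, got {params}"
                )
        else:
            raise ConfigError(
                f"color_index_distribution kind must be 'beta' or 'uniform', got {kind!r}"
            )


@dataclass(frozen=True)
class PlantedEffects:
    """Ground-truth parameters of the generative log-log model.

    log10(unstructured count) = state intercept + slope_b * log10(record
    count) + per-trait effects on centred trait values + N(0, noise_sd).
    """

    slope_b: float
    state_intercepts: dict
    gamma_body: float = 0.0
    gamma_flock: float = 0.0
    gamma_color: float = 0.0
    gamma_iucn: float = 0.0
    noise_sd: float = 0.05

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not self.state_intercepts:
            raise ConfigError("state_intercepts must map every state to an intercept")

    @property
    def gammas(self) -> dict:
        return {
            "log10_body_mass": self.gamma_body,
            "log10_flock_size": self.gamma_flock,
            "color_index": self.gamma_color,
            "iucn_score": self.gamma_iucn,
        }

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedEffects":
        return cls(**json.loads(text))


def _color_targets(rng: np.random.Generator, cfg: TraitGenConfig) -> np.ndarray:
    kind, *params = cfg.color_index_distribution
    if kind == "beta":
        return rng.beta(params[0], params[1], size=cfg.n_species)
    return rng.uniform(params[0], params[1], size=cfg.n_species)


def generate_traits(cfg: TraitGenConfig) -> pd.DataFrame:
    """One row per species: mass, flock size, IUCN category, 36 patch channels.

    Patches lie on the brown->white axis at per-patch fractions of the
    species' target displacement, so the species' max distance from brown
    and max luminance are both affine in the target — the derived color
    index then reproduces the target's min-max ranks exactly.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    n = cfg.n_species
    df = pd.DataFrame({"species": [f"species_{i:04d}" for i in range(n)]})
    df["body_mass_g"] = 10.0 ** rng.normal(cfg.body_mass_log10_mean, cfg.body_mass_log10_sd, n)
    df["flock_size"] = 1.0 + 10.0 ** rng.normal(
        cfg.flock_size_log10_mean, cfg.flock_size_log10_sd, n
    )
    levels = (*IUCN_LEVELS, "Endangered")
    probs = (*cfg.iucn_probs, cfg.endangered_prob)
    df["iucn_category"] = rng.choice(levels, size=n, p=probs)

    u = _color_targets(rng, cfg)
    for sex, dimorph in (("male", 1.0), ("female", _FEMALE_DIMORPHISM)):
        for j, patch in enumerate(traits_mod.PATCHES):
            frac = _MALE_PATCH_FACTORS[j] * dimorph
            rgb = _BROWN + np.outer(u * frac, _WHITE - _BROWN)
            rgb = np.clip(np.rint(rgb), 0, 255).astype(int)
            for k, c in enumerate("rgb"):
                df[f"{sex}_{patch}_{c}"] = rgb[:, k]
    return df


def _centered_trait_matrix(traits: pd.DataFrame) -> pd.DataFrame:
    """Derived predictors (via the traits module) centred on species means."""
    vec = traits_mod.build_trait_vectors(traits).set_index("species")
    cols = ["log10_body_mass", "log10_flock_size", "color_index", "iucn_score"]
    centered = vec[cols] - vec[cols].mean(skipna=True)
    return centered.fillna(0.0)  # excluded/missing traits contribute no planted effect


def generate_counts_direct(
    traits: pd.DataFrame,
    states: list,
    effort: dict,
    truth: PlantedEffects,
    seed: int,
    rate_log10_mean: float = -1.1,
    rate_log10_sd: float = 0.35,
    rate_state_sd: float = 0.2,
) -> pd.DataFrame:
    """Draw paired per-(state, species) counts from the planted model.

    Semi-structured record counts are effort-scaled log-normal truncated
    at 1 (positively skewed, as in real per-species count distributions):
    a species baseline rate 10^N(rate_log10_mean, rate_log10_sd) per
    checklist, jittered per state by 10^N(0, rate_state_sd), times the
    state's checklist count.  Unstructured counts follow the planted
    log-log relation on centred traits, rounded to a nonnegative integer;
    rows rounding to zero are flagged (``inat_zero``), never dropped.  The
    pre-rounding ``log10_inat_latent`` column is retained as generator
    truth for rounding-perturbation checks.
    """
    truth.validate()
    missing = [s for s in states if s not in truth.state_intercepts]
    if missing:
        raise ConfigError(f"states missing from truth.state_intercepts: {missing}")
    missing = [s for s in states if s not in effort]
    if missing:
        raise ConfigError(f"states missing from effort map: {missing}")
    if any(effort[s] <= 0 for s in states):
        raise ConfigError("effort (checklist counts) must be positive for every state")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    centered = _centered_trait_matrix(traits)
    if not np.isfinite(centered.to_numpy()).all():
        raise ConfigError("trait table produced non-finite derived predictors")
    species = centered.index.to_numpy()
    n_sp = len(species)

    trait_effect = (
        centered["log10_body_mass"].to_numpy() * truth.gamma_body
        + centered["log10_flock_size"].to_numpy() * truth.gamma_flock
        + centered["color_index"].to_numpy() * truth.gamma_color
        + centered["iucn_score"].to_numpy() * truth.gamma_iucn
    )
    base_rate = rng.normal(rate_log10_mean, rate_log10_sd, n_sp)

    frames = []
    for state in states:
        rate = 10.0 ** (base_rate + rng.normal(0.0, rate_state_sd, n_sp))
        n_ebird = np.maximum(1, np.rint(effort[state] * rate)).astype(np.int64)
        latent = (
            truth.state_intercepts[state]
            + truth.slope_b * np.log10(n_ebird)
            + trait_effect
            + rng.normal(0.0, truth.noise_sd, n_sp)
        )
        n_inat = np.rint(10.0 ** latent).astype(np.int64)
        frames.append(
            pd.DataFrame(
                {
                    "state": state,
                    "species": species,
                    "n_ebird": n_ebird,
                    "n_inat": n_inat,
                    "inat_zero": n_inat == 0,
                    "log10_inat_latent": latent,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class EventGenConfig:
    """Settings for event-level (checklist + record) generation.

    ``contamination`` gives, per quality-filter criterion, the probability
    that a checklist is planted as violating exactly that criterion;
    remaining checklists are clean.  ``boundary_fraction`` of clean
    checklists sit exactly on a filter boundary (5 km, 5 min or 240 min) —
    these must be retained.  ``x_count_rate`` is the chance a species
    record reports "X" (present, uncounted) instead of a numeric count.
    """

    states: tuple = ("S01", "S02", "S03", "S04", "S05")
    checklists_per_state: int = 200
    contamination: dict = field(default_factory=dict)
    boundary_fraction: float = 0.02
    x_count_rate: float = 0.02
    stationary_fraction: float = 0.4
    stationary_missing_distance_rate: float = 0.3
    prevalence_log10_mean: float = -1.0
    prevalence_log10_sd: float = 0.4
    trait_cfg: TraitGenConfig = field(default_factory=TraitGenConfig)
    truth: PlantedEffects | None = None
    seed: int = 0

    def validate(self) -> None:
        known = {
            "incomplete", "excluded_protocol", "distance_gt_max",
            "duration_lt_min", "duration_gt_max", "duration_missing",
        }
        for key, rate in self.contamination.items():
            if key not in known:
                raise ConfigError(f"unknown contamination key {key!r}; known: {sorted(known)}")
            if rate < 0:
                raise ConfigError(f"contamination rate for {key!r} must be >= 0, got {rate}")
        if sum(self.contamination.values()) > 1:
            raise ConfigError("contamination rates must sum to <= 1")
        if self.checklists_per_state < 1:
            raise ConfigError("checklists_per_state must be >= 1")
        for name in ("boundary_fraction", "x_count_rate", "stationary_fraction",
                     "stationary_missing_distance_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        self.trait_cfg.validate()
        if self.truth is not None:
            self.truth.validate()


@dataclass
class SyntheticBundle:
    """All generated tables plus the planted truth and filter labels."""

    checklists: pd.DataFrame
    ebird_obs: pd.DataFrame
    inat_obs: pd.DataFrame
    traits: pd.DataFrame
    truth: PlantedEffects
    checklist_labels: pd.DataFrame  # checklist_id, true_fail (criterion or "")

    def write(self, outdir) -> dict:
        """CSV writers for the four tables; truth as JSON alongside."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("checklists", self.checklists),
            ("ebird_obs", self.ebird_obs),
            ("inat_obs", self.inat_obs),
            ("traits", self.traits),
        ):
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False, float_format="%.10g")
            paths[name] = str(p)
        p = outdir / "truth.json"
        p.write_text(self.truth.to_json() + "\n")
        paths["truth"] = str(p)
        return paths


def default_truth(states, rng: np.random.Generator, **gammas) -> PlantedEffects:
    """Planted effects with unit slope and ~1:200 platform volume ratio."""
    intercepts = {s: float(rng.normal(-2.3, 0.25)) for s in states}
    return PlantedEffects(slope_b=1.0, state_intercepts=intercepts, **gammas)


def default_event_truth(states, rng: np.random.Generator, **gammas) -> PlantedEffects:
    """Planted effects for desk-scale event-level bundles.

    Event-level bundles hold hundreds, not hundreds of thousands, of
    checklists per state, so realised per-species record counts are small;
    intercepts near 0 keep unstructured counts nonzero at that scale.  The
    real platforms' 1:200 volume ratio is preserved only by the aggregated
    direct path (:func:`default_truth`).
    """
    intercepts = {s: float(rng.normal(0.3, 0.25)) for s in states}
    return PlantedEffects(slope_b=1.0, state_intercepts=intercepts, **gammas)


def default_effort(states, rng: np.random.Generator) -> dict:
    """Per-state checklist totals spanning 10^4.7 to 10^5.7 (effort heterogeneity).

    The scale reproduces contiguous-US per-(state, species) record totals
    of order 10^4 on the semi-structured platform and order 10^2 on the
    unstructured one under the default 1:200 volume ratio.
    """
    return {s: float(10.0 ** rng.uniform(4.7, 5.7)) for s in states}


def generate_event_level(cfg: EventGenConfig) -> SyntheticBundle:
    """Checklists with labelled filter violations plus both record tables.

    Each contaminated checklist violates exactly the criterion it is
    labelled with and is otherwise clean, so the quality filter must
    remove exactly the labelled set.  Unstructured counts follow the
    planted log-log relation against each (state, species)'s realised
    record count on clean checklists.
    """
    cfg.validate()
    master = np.random.SeedSequence([int(cfg.seed), 2])
    rng_cl, rng_eb, rng_in = (np.random.default_rng(s) for s in master.spawn(3))

    traits = generate_traits(cfg.trait_cfg)
    species = traits["species"].to_numpy()
    n_sp = len(species)
    states = list(cfg.states)
    truth = cfg.truth or default_event_truth(states, np.random.default_rng(master.spawn(1)[0]))
    missing = [s for s in states if s not in truth.state_intercepts]
    if missing:
        raise ConfigError(f"states missing from truth.state_intercepts: {missing}")

    crits = ["incomplete", "excluded_protocol", "distance_gt_max",
             "duration_lt_min", "duration_gt_max", "duration_missing"]
    probs = np.array([cfg.contamination.get(c, 0.0) for c in crits])
    p_clean = 1.0 - probs.sum()

    cl_rows = []
    next_id = 0
    for state in states:
        m = cfg.checklists_per_state
        ids = [f"CL{next_id + i:07d}" for i in range(m)]
        next_id += m
        labels = rng_cl.choice(crits + ["clean"], size=m, p=np.append(probs, p_clean))

        protocol = np.where(
            rng_cl.random(m) < cfg.stationary_fraction, "stationary", "traveling"
        ).astype(object)
        complete = np.ones(m, dtype=bool)
        duration = rng_cl.uniform(5.0, 240.0, m)
        distance = np.where(protocol == "stationary", 0.0, rng_cl.uniform(0.0, 5.0, m))
        distance[(protocol == "stationary")
                 & (rng_cl.random(m) < cfg.stationary_missing_distance_rate)] = np.nan

        boundary = rng_cl.random(m) < cfg.boundary_fraction
        which = rng_cl.integers(0, 3, m)
        duration[boundary & (which == 0)] = 5.0
        duration[boundary & (which == 1)] = 240.0
        on_edge = boundary & (which == 2) & (protocol == "traveling")
        distance[on_edge] = 5.0

        complete[labels == "incomplete"] = False
        protocol[labels == "excluded_protocol"] = rng_cl.choice(
            ["incidental", "historical"], size=int((labels == "excluded_protocol").sum())
        )
        sel = labels == "distance_gt_max"
        protocol[sel] = "traveling"
        distance[sel] = rng_cl.uniform(5.0 + 1e-6, 30.0, int(sel.sum()))
        sel = labels == "duration_lt_min"
        duration[sel] = rng_cl.uniform(0.0, 5.0 - 1e-6, int(sel.sum()))
        sel = labels == "duration_gt_max"
        duration[sel] = rng_cl.uniform(240.0 + 1e-6, 600.0, int(sel.sum()))
        duration[labels == "duration_missing"] = np.nan

        cl_rows.append(
            pd.DataFrame(
                {
                    "checklist_id": ids,
                    "state": state,
                    "protocol": protocol,
                    "complete": complete,
                    "duration_minutes": duration,
                    "distance_km": distance,
                    "_label": labels,
                }
            )
        )
    checklists = pd.concat(cl_rows, ignore_index=True)
    labels_df = checklists[["checklist_id", "_label"]].rename(columns={"_label": "true_fail"})
    labels_df.loc[labels_df["true_fail"] == "clean", "true_fail"] = ""
    checklists = checklists.drop(columns="_label")

    # Species records on every checklist (quality problems do not stop people
    # recording birds); presence probability is a skewed per-species rate.
    prevalence = np.clip(
        10.0 ** rng_eb.normal(cfg.prevalence_log10_mean, cfg.prevalence_log10_sd, n_sp),
        0.002, 0.6,
    )
    flock = traits["flock_size"].to_numpy()
    obs_frames = []
    for state, sub in checklists.groupby("state", sort=True):
        m = len(sub)
        present = rng_eb.random((m, n_sp)) < prevalence[None, :]
        cl_idx, sp_idx = np.nonzero(present)
        counts = 1 + rng_eb.poisson(np.maximum(flock[sp_idx] - 1.0, 0.0))
        counts = counts.astype(object)
        x_mask = rng_eb.random(len(counts)) < cfg.x_count_rate
        counts[x_mask] = "X"
        obs_frames.append(
            pd.DataFrame(
                {
                    "checklist_id": sub["checklist_id"].to_numpy()[cl_idx],
                    "species": species[sp_idx],
                    "count": counts,
                }
            )
        )
    ebird_obs = pd.concat(obs_frames, ignore_index=True)

    # Unstructured occurrences per (state, species) from the planted relation
    # against realised record counts on clean checklists.
    clean_ids = set(labels_df.loc[labels_df["true_fail"] == "", "checklist_id"])
    state_of = checklists.set_index("checklist_id")["state"]
    eb_clean = ebird_obs[ebird_obs["checklist_id"].isin(clean_ids)]
    eb_counts = (
        eb_clean.assign(state=eb_clean["checklist_id"].map(state_of))
        .drop_duplicates(["checklist_id", "species"])
        .groupby(["state", "species"])
        .size()
    )
    centered = _centered_trait_matrix(traits)
    trait_effect = pd.Series(
        centered["log10_body_mass"].to_numpy() * truth.gamma_body
        + centered["log10_flock_size"].to_numpy() * truth.gamma_flock
        + centered["color_index"].to_numpy() * truth.gamma_color
        + centered["iucn_score"].to_numpy() * truth.gamma_iucn,
        index=centered.index,
    )
    inat_rows = []
    next_obs = 0
    for (state, sp), n_eb in eb_counts.items():
        latent = (
            truth.state_intercepts[state]
            + truth.slope_b * np.log10(n_eb)
            + trait_effect[sp]
            + rng_in.normal(0.0, truth.noise_sd)
        )
        k = int(np.rint(10.0 ** latent))
        if k > 0:
            inat_rows.append((state, sp, k))
    if inat_rows:
        agg = pd.DataFrame(inat_rows, columns=["state", "species", "k"])
        rep = agg.loc[agg.index.repeat(agg["k"])]
        inat_obs = pd.DataFrame(
            {
                "observation_id": [f"OBS{next_obs + i:08d}" for i in range(len(rep))],
                "state": rep["state"].to_numpy(),
                "species": rep["species"].to_numpy(),
            }
        )
    else:
        inat_obs = pd.DataFrame(columns=["observation_id", "state", "species"])

    return SyntheticBundle(
        checklists=checklists,
        ebird_obs=ebird_obs,
        inat_obs=inat_obs,
        traits=traits,
        truth=truth,
        checklist_labels=labels_df,
    )
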