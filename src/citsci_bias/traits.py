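"""Construction of the four species-level predictors.

The predictors proxy how likely a species is to be noticed, photographed
and submitted to an opportunistic recording platform:

* ``log10_body_mass`` — log10 adult body mass in grams.
* ``color_index`` — a [0, 1] colorfulness/brightness score combining two
  plumage components computed over six patches (upper breast, lower
  breast, crown, forehead, nape, throat) for both sexes: the maximum
  Euclidean distance in RGB space from brown, and the maximum relative
  luminance 0.2126 R + 0.7152 G + 0.0722 B.  Each component is min–max
  scaled over the species set, averaged, and rescaled to [0, 1].
* ``log10_flock_size`` — log10 of the mean reported individual count over
  all checklists where the species was reported, pooled across states; a
  gregariousness proxy.  "X" (present, uncounted) reports are excluded.
* ``iucn_score`` — ordinal Red List coding used as a commonness proxy:
  Least Concern = 2 (highest), Vulnerable = 1, Near Threatened = 0
  (lowest).  Endangered and rarer categories are excluded from
  IUCN-bearing models.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError

logger = logging.getLogger(__name__)

PATCHES = ("upper_breast", "lower_breast", "crown", "forehead", "nape", "throat")
SEXES = ("male", "female")

#: Default brown reference in RGB.
BROWN_RGB = (102.0, 68.0, 0.0)

#: sRGB -> relative luminance weights (Rec. 709 primaries).
LUMA_WEIGHTS = (0.2126, 0.7152, 0.0722)

_IUCN_SCORES = {
    "least concern": 2.0, "lc": 2.0,
    "vulnerable": 1.0, "vu": 1.0,
    "near threatened": 0.0, "nt": 0.0,
}
_IUCN_EXCLUDED = {
    "endangered", "en",
    "critically endangered", "cr",
    "extinct in the wild", "ew",
    "extinct", "ex",
}


@dataclass(frozen=True)
class ColorConfig:
    """Options for the color index.

    ``reference`` is the brown anchor of the distance component; the
    commonly printed transposed triple (102, 0, 68) can be supplied here
    for sensitivity checks.  ``space`` selects the distance metric space:
    "rgb" (Euclidean on raw channels, the default) or "lab" (CIE Lab under
    D65 via scikit-image).  ``weights`` are the relative weights of the
    (distance-from-brown, luminance) components before rescaling.
    """

    reference: tuple = BROWN_RGB
    space: str = "rgb"
    weights: tuple = (0.5, 0.5)

    def __post_init__(self):
        if self.space not in ("rgb", "lab"):
            raise ConfigError(f"color space must be 'rgb' or 'lab', got {self.space!r}")
        if len(self.reference) != 3:
            raise ConfigError("color reference must be an (R, G, B) triple")
        w = tuple(float(x) for x in self.weights)
        if len(w) != 2 or min(w) < 0 or sum(w) == 0:
            raise ConfigError(f"component weights must be two nonnegatives, got {self.weights}")
        object.__setattr__(self, "weights", w)


def patch_long_table(traits: pd.DataFrame) -> pd.DataFrame:
    """Melt a wide trait table into (species, sex, patch, r, g, b) rows.

    Wide columns follow ``{sex}_{patch}_{channel}`` naming, e.g.
    ``male_crown_r``.  Rows with any missing channel are dropped (missing
    plumage data yields a missing color trait downstream, never zero).
    """
    rows = []
    for sex in SEXES:
        for patch in PATCHES:
            cols = [f"{sex}_{patch}_{c}" for c in "rgb"]
            if not all(c in traits.columns for c in cols):
                continue
            sub = traits[["species", *cols]].copy()
            sub.columns = ["species", "r", "g", "b"]
            sub["sex"] = sex
            sub["patch"] = patch
            rows.append(sub)
    if not rows:
        raise SchemaError(
            "trait table has no plumage patch columns ({sex}_{patch}_{r|g|b})"
        )
    long = pd.concat(rows, ignore_index=True)
    long = long.dropna(subset=["r", "g", "b"])
    for c in "rgb":
        vals = long[c].to_numpy(dtype=float)
        if ((vals < 0) | (vals > 255)).any():
            raise SchemaError(f"RGB channel {c!r} outside [0, 255] in patch data")
    return long[["species", "sex", "patch", "r", "g", "b"]]


def _to_lab(rgb255: np.ndarray) -> np.ndarray:
    from skimage.color import rgb2lab  # optional dependency, only for space="lab"

    return rgb2lab((rgb255 / 255.0).reshape(-1, 1, 3)).reshape(-1, 3)


def distance_from_brown(
    patches: pd.DataFrame, reference: tuple = BROWN_RGB, space: str = "rgb"
) -> pd.Series:
    """Max distance of any patch (either sex) from the brown reference.

    In "rgb" space this is sqrt((R-102)^2 + (G-68)^2 + B^2) maximised over
    patches; in "lab" space the Euclidean distance after sRGB->Lab (D65)
    conversion of both the patch and the reference.
    """
    rgb = patches[["r", "g", "b"]].to_numpy(dtype=float)
    ref = np.asarray(reference, dtype=float)
    if space == "rgb":
        d = np.sqrt(((rgb - ref) ** 2).sum(axis=1))
    elif space == "lab":
        lab = _to_lab(rgb)
        ref_lab = _to_lab(ref.reshape(1, 3))[0]
        d = np.sqrt(((lab - ref_lab) ** 2).sum(axis=1))
    else:
        raise ConfigError(f"unknown color space {space!r}")
    return pd.Series(d, index=patches["species"].to_numpy()).groupby(level=0).max()


def relative_luminance(patches: pd.DataFrame) -> pd.Series:
    """Max relative luminance 0.2126 R + 0.7152 G + 0.0722 B over all patches."""
    rgb = patches[["r", "g", "b"]].to_numpy(dtype=float)
    lum = rgb @ np.asarray(LUMA_WEIGHTS)
    return pd.Series(lum, index=patches["species"].to_numpy()).groupby(level=0).max()


def _minmax(s: pd.Series, what: str) -> pd.Series:
    lo, hi = float(s.min()), float(s.max())
    if hi == lo:
        raise ValueError(
            f"{what} is constant across species; min-max scaling is undefined — "
            "exclude the constant trait or supply varying plumage data"
        )
    return (s - lo) / (hi - lo)


def color_index(
    distance: pd.Series, luminance: pd.Series, weights: tuple = (0.5, 0.5)
) -> pd.Series:
    """Combine the two color components into a [0, 1] index.

    Each component is min-max scaled over the species set, combined as a
    weighted mean, then min-max rescaled so the extremes hit exactly 0 and
    1.  Species missing either component get a missing index.
    """
    joint = pd.concat(
        {"distance": distance, "luminance": luminance}, axis=1, join="outer"
    ).dropna()
    if joint.empty:
        raise ValueError("no species has both color components")
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    sd = _minmax(joint["distance"], "distance-from-brown component")
    sl = _minmax(joint["luminance"], "luminance component")
    combined = w[0] * sd + w[1] * sl
    return _minmax(combined, "combined color score")


def parse_counts(counts: pd.Series) -> pd.Series:
    """Numeric checklist counts; 'X' (present, uncounted) becomes missing."""
    s = counts.astype(str).str.strip()
    out = pd.to_numeric(s.mask(s.str.upper() == "X"), errors="coerce")
    return out


def flock_size(ebird_obs: pd.DataFrame) -> pd.Series:
    """Mean reported individuals per species over all checklists reporting it.

    Pooled across all states/checklists; 'X' records contribute to neither
    numerator nor denominator.  Species with only 'X' records get NaN (a
    missing-trait flag, not zero); the exclusion rate is logged.
    """
    counts = parse_counts(ebird_obs["count"])
    n_x = int(counts.isna().sum())
    if n_x:
        logger.info("flock size: excluded %d 'X'/unparseable count record(s) of %d",
                    n_x, len(counts))
    return counts.groupby(ebird_obs["species"].to_numpy()).mean()


def encode_iucn(category) -> float:
    """Ordinal Red List score: LC=2 (highest), VU=1, NT=0 (lowest).

    Endangered and rarer categories return NaN, flagging the species for
    exclusion from IUCN-bearing models.  Unrecognized labels raise.
    """
    key = str(category).strip().lower().replace("_", " ").replace("-", " ")
    if key in _IUCN_SCORES:
        return _IUCN_SCORES[key]
    if key in _IUCN_EXCLUDED:
        return float("nan")
    accepted = sorted(set(_IUCN_SCORES) | _IUCN_EXCLUDED)
    raise ValueError(
        f"unrecognized IUCN category {category!r}; accepted labels: {', '.join(accepted)}"
    )


def encode_iucn_series(categories: pd.Series) -> pd.Series:
    return categories.map(encode_iucn).astype(float)


def build_trait_vectors(
    traits: pd.DataFrame,
    ebird_obs: pd.DataFrame | None = None,
    color: ColorConfig | None = None,
) -> pd.DataFrame:
    """Assemble the per-species predictor table.

    Flock size comes from checklist counts when ``ebird_obs`` is given,
    else from a ``flock_size`` column of the trait table.  Missing traits
    stay NaN so each model can apply its own completeness rule.
    """
    color = color or ColorConfig()
    if "species" not in traits.columns:
        raise SchemaError("trait table is missing required column: species")
    out = traits[["species"]].drop_duplicates().set_index("species")

    if "body_mass_g" in traits.columns:
        mass = pd.to_numeric(traits.set_index("species")["body_mass_g"], errors="coerce")
        if (mass <= 0).any():
            raise SchemaError("body_mass_g must be positive where present")
        out["log10_body_mass"] = np.log10(mass)
    else:
        out["log10_body_mass"] = np.nan

    try:
        patches = patch_long_table(traits)
        dist = distance_from_brown(patches, color.reference, color.space)
        lum = relative_luminance(patches)
        out["color_index"] = color_index(dist, lum, color.weights)
    except SchemaError:
        out["color_index"] = np.nan

    if ebird_obs is not None:
        fs = flock_size(ebird_obs)
    elif "flock_size" in traits.columns:
        fs = pd.to_numeric(traits.set_index("species")["flock_size"], errors="coerce")
    else:
        fs = pd.Series(dtype=float)
    fs = fs[fs >= 1]  # counts are positive integers; a mean below 1 is unusable
    out["log10_flock_size"] = np.log10(fs.reindex(out.index))

    if "iucn_category" in traits.columns:
        out["iucn_score"] = encode_iucn_series(
            traits.set_index("species")["iucn_category"]
        ).reindex(out.index)
    else:
        out["iucn_score"] = np.nan

    return out.reset_index()
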