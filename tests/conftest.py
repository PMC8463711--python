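"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from citsci_bias.synthetic import EventGenConfig, TraitGenConfig, generate_event_level


def ols_normal_equations(x, y):
    """Closed-form simple-regression oracle (independent of statsmodels)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return intercept, slope


def random_counts_fixture(rng, n_states=4, n_species=25):
    """Random positive paired counts for OLS-identity checks."""
    rows = []
    for s in range(n_states):
        n_eb = rng.integers(1, 100_000, n_species)
        n_in = rng.integers(1, 5_000, n_species)
        rows.append(
            pd.DataFrame(
                {
                    "state": f"S{s:02d}",
                    "species": [f"sp{i:03d}" for i in range(n_species)],
                    "n_ebird": n_eb,
                    "n_inat": n_in,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


CONTAMINATION = {
    "incomplete": 0.06,
    "excluded_protocol": 0.04,
    "distance_gt_max": 0.03,
    "duration_lt_min": 0.03,
    "duration_gt_max": 0.02,
    "duration_missing": 0.02,
}


def make_bundle(seed=11, n_states=4, n_species=40, checklists_per_state=150,
                contamination=CONTAMINATION):
    return generate_event_level(
        EventGenConfig(
            states=tuple(f"S{i:02d}" for i in range(n_states)),
            checklists_per_state=checklists_per_state,
            contamination=dict(contamination),
            trait_cfg=TraitGenConfig(n_species=n_species, seed=seed),
            seed=seed,
        )
    )


@pytest.fixture(scope="session")
def bundle():
    """A moderately sized labelled event-level bundle (shared, read-only)."""
    return make_bundle()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
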