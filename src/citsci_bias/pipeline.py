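"""End-to-end orchestration: inputs -> filters -> residuals -> models.

One :func:`run` call executes the whole procedure from a single validated
config, in synthetic mode (generated bundle with planted truth, enabling
a recovery report) or files mode (user-supplied CSV tables).  Every stage
logs its row counts into a manifest that must reconcile, and all
artifacts are written deterministically (stable row order, fixed float
formatting) so identical config + seed reproduce bit-identical outputs
apart from manifest timestamps.
"""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from . import io_filtering, representation, traits as traits_mod, trait_models, synthetic
from .config import RunConfig
from .errors import CitsciBiasError

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def _load_inputs(config: RunConfig):
    if config.mode == "synthetic":
        bundle = synthetic.generate_event_level(config.synthetic)
        return bundle.checklists, bundle.ebird_obs, bundle.inat_obs, bundle.traits, bundle.truth
    files = config.files
    checklists = io_filtering.read_checklists(files["checklists"])
    ebird_obs = io_filtering.read_ebird_obs(files["ebird_obs"])
    inat_obs = io_filtering.read_inat_obs(files["inat_obs"])
    trait_table = pd.read_csv(files["traits"])
    return checklists, ebird_obs, inat_obs, trait_table, None


def _models_to_csv(fits: dict, path: Path) -> None:
    rows = []
    for model_name, result in [("global", fits["global"])] + list(fits["per_trait"].items()):
        for term, fe in result.fixed_effects.items():
            rows.append(
                {
                    "model": model_name,
                    "term": term,
                    "estimate": fe.estimate,
                    "std_error": fe.std_error,
                    "ci_low": fe.ci_low,
                    "ci_high": fe.ci_high,
                    "p_value": fe.p_value,
                    "n_rows": result.n_rows,
                    "converged": result.converged,
                }
            )
    _write_csv(pd.DataFrame(rows), path)


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns the manifest (also written to disk)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.raw,
        "version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "started_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "stages": {},
    }

    checklists, ebird_obs, inat_obs, trait_table, truth = _load_inputs(config)
    manifest["stages"]["inputs"] = {
        "n_checklists": int(len(checklists)),
        "n_ebird_obs": int(len(ebird_obs)),
        "n_inat_obs": int(len(inat_obs)),
        "n_trait_species": int(trait_table["species"].nunique()),
    }

    retained, filt_report = io_filtering.filter_checklists(checklists, config.filter)
    if not filt_report.reconciles():
        raise CitsciBiasError("filter report does not reconcile with input counts")
    manifest["stages"]["filter"] = {
        "n_input": filt_report.n_input,
        "n_retained": filt_report.n_retained,
        "n_removed": filt_report.n_removed,
        "removals": filt_report.removals,
    }

    prev = io_filtering.compute_prevalence(ebird_obs, retained)
    manifest["stages"]["prevalence"] = {
        "n_state_species": int(len(prev.table)),
        "n_unreferenced_obs_dropped": prev.n_unreferenced_dropped,
    }

    vectors = traits_mod.build_trait_vectors(
        trait_table,
        ebird_obs=ebird_obs.merge(retained[["checklist_id"]], on="checklist_id"),
        color=config.color,
    )

    # Sensitivity sweep over prevalence cutoffs; nested survivor sets.
    sweep: dict = {}
    previous_survivors = None
    cutoffs = sorted(set([*config.prevalence_cutoffs, config.filter.prevalence_cutoff]))
    for cutoff in cutoffs:
        survivors = io_filtering.trim_species(prev.table, cutoff)
        key = f"{cutoff:g}"
        sweep[key] = {"n_state_species": int(len(survivors))}
        if previous_survivors is not None:
            cur = set(map(tuple, survivors[["state", "species"]].to_numpy()))
            prv = set(map(tuple, previous_survivors[["state", "species"]].to_numpy()))
            sweep[key]["nested_in_previous"] = cur.issubset(prv)
        previous_survivors = survivors

        counts = io_filtering.aggregate_counts(ebird_obs, retained, inat_obs, survivors)
        residuals, fits, skipped = representation.build_residual_table(
            counts, config.zero_policy
        )
        sweep[key]["n_residual_rows"] = int(len(residuals))
        sweep[key]["skipped_states"] = skipped

        is_main = cutoff == config.filter.prevalence_cutoff
        model_fits = trait_models.fit_all(residuals, vectors, config.model)
        _write_json(
            {
                "cutoff": cutoff,
                "global": model_fits["global"].to_dict(),
                "per_trait": {k: v.to_dict() for k, v in model_fits["per_trait"].items()},
                "frames": model_fits["frames"],
                "sign_agreement": model_fits["sign_agreement"],
            },
            outdir / f"models_cutoff_{key.replace('.', 'p')}.json",
        )
        sweep[key]["model_method"] = model_fits["global"].method

        if is_main:
            _write_csv(counts, outdir / "counts.csv")
            _write_csv(residuals, outdir / "residuals.csv")
            _write_csv(vectors, outdir / "trait_vectors.csv")
            _models_to_csv(model_fits, outdir / "models.csv")
            state_totals = retained.groupby("state").size().to_dict()
            correlations = representation.summarize_correlations(counts, state_totals)
            _write_json(correlations, outdir / "correlations.json")
            manifest["stages"]["main"] = {
                "cutoff": cutoff,
                "n_counts_rows": int(len(counts)),
                "n_residual_rows": int(len(residuals)),
                "skipped_states": skipped,
                "model_method": model_fits["global"].method,
                "global_converged": model_fits["global"].converged,
            }
            if truth is not None:
                recovery = trait_models.recovery_report([model_fits["global"]], truth)
                _write_json(recovery, outdir / "recovery.json")

    manifest["stages"]["cutoff_sweep"] = sweep
    manifest["finished_at"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    _write_json(manifest, outdir / "manifest.json")
    return manifest
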