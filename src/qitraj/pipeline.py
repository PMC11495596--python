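"""End-to-end orchestration: simulate → shrink → select/fit → profile.

A single :class:`~qitraj.config.PipelineConfig` drives the whole run.  All
randomness flows from one root seed, expanded per stage with
``numpy.random.SeedSequence``, so a rerun with the same config reproduces every
artifact bit for bit.  Each stage writes its table under ``out_dir`` and the
run ends with a JSON manifest recording the config hash, derived seeds,
library versions, per-stage output paths, the model-selection table, the
chosen number of groups and the group counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from . import __version__
from .config import PipelineConfig
from .errors import PipelineError
from .profiles import profile_groups, trend_table
from .shrinkage import shrink_panel
from .synthetic import TREND_COVARIATES, simulate_panel, panel_to_matrix, validate_panel
from .trajectory import order_and_name_groups, select_model
from . import plots

logger = logging.getLogger(__name__)


def setup_logging(log_file=None, level=logging.INFO):
    """Timestamped, level-tagged logging to stderr and optionally a file."""
    handlers = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    fmt = logging.Formatter("%(asctime)s [%(levelname)s] %(name)s: %(message)s")
    root = logging.getLogger("qitraj")
    root.setLevel(level)
    root.handlers = []
    for h in handlers:
        h.setFormatter(fmt)
        root.addHandler(h)
    return root


def config_hash(config: PipelineConfig) -> str:
    """Hash of the analysis-relevant configuration (filesystem paths excluded,
    so the same analysis written to a different directory hashes identically)."""
    doc = json.loads(config.model_dump_json())
    for path_field in ("out_dir", "panel_path", "covariates_path"):
        doc.pop(path_field, None)
    payload = json.dumps(doc, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def _stage_seeds(root_seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(root_seed).spawn(2)
    return {
        "simulate": int(children[0].generate_state(1)[0] % 2**31),
        "model": int(children[1].generate_state(1)[0] % 2**31),
    }


def _versions() -> dict[str, str]:
    import scipy
    import sklearn

    return {
        "qitraj": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the run manifest (also written to
    ``out_dir/manifest.json``).

    Raises :class:`PipelineError` naming the failing stage; partial outputs are
    retained and the manifest is still written with a failure marker.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = {
        "config_hash": config_hash(config),
        "root_seed": config.seed,
        "stage_seeds": seeds,
        "versions": _versions(),
        "outputs": {},
        "status": "running",
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def _write_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    def _fail(stage, exc):
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_manifest()
        raise PipelineError(stage, exc) from exc

    # --- stage 1: obtain the panel -------------------------------------------------
    covariates = None
    try:
        if config.panel_path is not None:
            path = Path(config.panel_path)
            if not path.exists():
                raise FileNotFoundError(f"panel file not found: {path}")
            panel = pd.read_csv(path)
            validate_panel(panel)
            if config.covariates_path is not None:
                cpath = Path(config.covariates_path)
                if not cpath.exists():
                    raise FileNotFoundError(f"covariates file not found: {cpath}")
                covariates = pd.read_csv(cpath)
            logger.info("loaded panel from %s (%d rows)", path, len(panel))
        else:
            sim_config = config.simulation.model_copy(update={"seed": seeds["simulate"]})
            panel, truth, covariates = simulate_panel(sim_config)
            truth.assignments.to_csv(out / "truth.csv", index=False)
            manifest["outputs"]["truth"] = str(out / "truth.csv")
            logger.info("simulated panel: %d areas × %d periods",
                        panel["area_id"].nunique(), panel["period"].nunique())
        panel.to_csv(out / "panel.csv", index=False)
        manifest["outputs"]["panel"] = str(out / "panel.csv")
        if covariates is not None:
            covariates.to_csv(out / "covariates.csv", index=False)
            manifest["outputs"]["covariates"] = str(out / "covariates.csv")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        _fail("simulate", exc)

    # --- stage 2: shrinkage --------------------------------------------------------
    try:
        shrunk = shrink_panel(panel, zero_case=config.zero_case_policy)
        shrunk.to_csv(out / "shrunk.csv", index=False)
        manifest["outputs"]["shrunk"] = str(out / "shrunk.csv")
        logger.info("shrinkage done: %d rows, %d fallback rows",
                    len(shrunk), int((shrunk["policy"] != "").sum()))
    except Exception as exc:
        _fail("shrink", exc)

    # --- stage 3: trajectory model selection --------------------------------------
    try:
        response = (shrunk["shrunk_prop"] if config.response_scale == "proportion"
                    else shrunk["shrunk_logit"])
        Y, area_ids, periods = panel_to_matrix(shrunk, response)
        table, chosen_K, fits = select_model(
            Y, range(config.k_min, config.k_max + 1), config.basis,
            seed=seeds["model"], n_starts=config.n_starts,
            periods=periods, area_ids=area_ids,
        )
        mixture, assignment, metrics = fits[chosen_K]
        transform = expit if config.response_scale == "logit" else None
        mixture, assignment = order_and_name_groups(
            mixture, assignment, config.naming_thresholds, curve_transform=transform
        )
        table.to_csv(out / "selection.csv", index=False)
        post = pd.DataFrame(assignment.posterior,
                            columns=[f"p_group{k}" for k in range(chosen_K)])
        post.insert(0, "area_id", area_ids)
        post["modal_group"] = assignment.modal
        post["group_name"] = [assignment.names[g] for g in assignment.modal]
        post.to_csv(out / "posteriors.csv", index=False)
        model_doc = {
            "K": chosen_K,
            "pi": mixture.pi.tolist(),
            "beta": mixture.beta.tolist(),
            "sigma2": mixture.sigma2,
            "loglik": mixture.loglik,
            "n_params": mixture.n_params,
            "BIC": metrics.bic,
            "WMAE": metrics.wmae,
            "WRSS": metrics.wrss,
            "basis": json.loads(config.basis.model_dump_json()),
            "response_scale": config.response_scale,
            "group_names": assignment.names,
            "group_short_names": assignment.short_names,
            "group_counts": assignment.counts.tolist(),
            "posteriors_file": str(out / "posteriors.csv"),
        }
        (out / "model.json").write_text(json.dumps(model_doc, indent=2))
        manifest["outputs"].update({
            "selection": str(out / "selection.csv"),
            "model": str(out / "model.json"),
            "posteriors": str(out / "posteriors.csv"),
        })
        manifest["selection_table"] = table.to_dict(orient="records")
        manifest["chosen_K"] = chosen_K
        manifest["group_counts"] = assignment.counts.tolist()
        manifest["group_names"] = assignment.names
        logger.info("chose K=%d; groups %s with counts %s",
                    chosen_K, assignment.short_names, assignment.counts.tolist())
        if config.make_plots:
            plots.save_fig(plots.plot_spaghetti(Y, periods), out / "spaghetti.png")
            plots.save_fig(plots.plot_group_curves(Y, mixture, assignment, periods),
                           out / "group_curves.png")
            manifest["outputs"]["plots"] = [str(out / "spaghetti.png"),
                                            str(out / "group_curves.png")]
    except Exception as exc:
        _fail("fit", exc)

    # --- stage 4: post-hoc group profiling ----------------------------------------
    try:
        if covariates is not None:
            prof = profile_groups(assignment, covariates)
            prof.to_csv(out / "profile.csv", index=False)
            manifest["outputs"]["profile"] = str(out / "profile.csv")
            have_trends = all(f"{v}_2014" in covariates.columns for v in TREND_COVARIATES)
            if have_trends:
                trends = trend_table(assignment, covariates)
                trends.to_csv(out / "trends.csv", index=False)
                manifest["outputs"]["trends"] = str(out / "trends.csv")
        else:
            logger.info("no covariates supplied; skipping group profiling")
    except Exception as exc:
        _fail("profile", exc)

    manifest["status"] = "ok"
    _write_manifest()
    manifest["manifest_path"] = str(out / "manifest.json")
    return manifest
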