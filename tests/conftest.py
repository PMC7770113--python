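"""Shared fixtures: a tiny fixture bundle and a desk-scale trained pipeline.

The heavy session fixtures are built once and shared across tests so the
full suite stays within a desktop time budget while still exercising the
end-to-end pipeline (stimuli -> periphery -> classifier -> psychometrics)
at a scale where its qualitative behavior is meaningful.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from dinmodel import adaptation as ad
from dinmodel import network as nw
from dinmodel import periphery as pp
from dinmodel import psychometrics as ps
from dinmodel import workbench as wb

warnings.filterwarnings("ignore", message="input batch does not look z-scored")


@pytest.fixture(scope="session")
def bundle() -> wb.FixtureBundle:
    """40 tokens x 3 noise levels x 2 cochlear states at 16 CFs."""
    return wb.make_fixtures(seed=0)


@pytest.fixture(scope="session")
def desk_data():
    """Desk-scale manifest plus NH and ANF-degraded neurogram sets (32 CFs)."""
    config = wb.desk_config(0)
    manifest = wb.build_manifest(config)
    grid = pp.make_cf_grid(config.n_cf)
    states = {s.state_id: s
              for s in pp.table1_states(grid, fiber_scale=config.fiber_scale)}
    nh = states["NH_mocr20_anf[2,2,6]"]
    deg = states["NH_mocr0_anf[0,0,5]"]
    return {
        "config": config,
        "manifest": manifest,
        "grid": grid,
        "nh_state": nh,
        "deg_state": deg,
        "nh": wb.build_neurogram_set(config, manifest, nh, grid),
        "deg": wb.build_neurogram_set(config, manifest, deg, grid),
        "folds": ad.make_folds(manifest, n_folds=3, seed=0),
    }


def _threshold(table) -> float:
    t = table.copy()
    if "fold" not in t:
        t["fold"] = 0
    curve = ps.PsychometricCurve.from_fold_table(t)
    fit = ps.fit_sigmoid(curve, "model")
    return ps.snr_at_accuracy(fit, 0.5)


@pytest.fixture(scope="session")
def trained_runs(desk_data):
    """Three seeds of the two-phase pipeline on the desk-scale data.

    Per seed: an NH-trained baseline, its NH test curve, and phase-2 runs of
    all three paradigms evaluated on the ANF-degraded state.
    """
    net_cfg = nw.NetworkConfig(input_shape=(desk_data["config"].n_cf, 70),
                               base_channels=8, batch_size=32)
    runs = []
    for seed in range(3):
        fold = desk_data["folds"][seed]
        baseline = nw.build_network(net_cfg, seed=seed)
        ad.train_phase(baseline, desk_data["nh"], fold.train_idx,
                       budget=10_000, seed=100 + seed)
        nh_table = ad.evaluate_by_snr(baseline, desk_data["nh"], fold.test_idx)
        run = {"seed": seed, "fold": fold, "baseline": baseline,
               "nh_table": nh_table, "nh_threshold": _threshold(nh_table)}
        for name in ("nh_control", "unconstrained", "constrained"):
            state, table = ad.run_paradigm(
                baseline, ad.PARADIGMS[name], fold, desk_data["nh"],
                desk_data["deg"], phase2_budget=5_000, seed=seed)
            run[name] = {"state": state, "table": table,
                         "threshold": _threshold(table)}
        run["nh_control_on_nh"] = ad.evaluate_by_snr(
            run["nh_control"]["state"], desk_data["nh"], fold.test_idx)
        runs.append(run)
    return runs
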