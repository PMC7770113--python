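"""Experiment orchestration: configs, presets, pipeline stages, fixtures.

Two presets are provided. The ``full`` preset reproduces the full study
grid — 225 talkers x 2 utterances per digit x 10 digits x 21 noise levels
(94,500 stimuli), 128 CFs, 100 fibers per CF, 250,000-sample training
phases — and exists chiefly so the combinatorics can be stated and checked;
rendering it is a cluster-scale job. The ``desk`` preset is the same
pipeline at a size a single CPU core finishes in minutes: fewer talkers, a
coarser noise grid, 32 CFs, a 10x-smaller fiber census, and a smaller
network, chosen to preserve every qualitative behavior under study
(sigmoidal psychometric curves, degradation-induced threshold shifts,
paradigm orderings) rather than absolute accuracies.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import adaptation as ad
from . import network as nw
from . import periphery as pp
from . import psychometrics as ps
from . import stimuli as st

__all__ = [
    "ExperimentConfig",
    "desk_config",
    "full_config",
    "human_protocol_config",
    "config_hash",
    "build_manifest",
    "build_neurogram_set",
    "run_experiment",
    "make_fixtures",
    "FixtureBundle",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one end-to-end run."""

    preset: str
    n_talkers: int
    utterances_per_digit: int
    noise_levels_db: tuple
    speech_level_db: float
    n_cf: int
    fiber_scale: float
    state_ids: tuple          # cochlear states to simulate (besides NH baseline)
    paradigms: tuple
    n_folds: int
    phase1_budget: int
    phase2_budget: int
    base_channels: int
    batch_size: int
    master_seed: int

    def network_config(self) -> nw.NetworkConfig:
        return nw.NetworkConfig(input_shape=(self.n_cf, 70),
                                base_channels=self.base_channels,
                                batch_size=self.batch_size)


def full_config(master_seed: int = 0) -> ExperimentConfig:
    """The full printed study grid (94,500 stimuli; cluster-scale to render)."""
    return ExperimentConfig(
        preset="full",
        n_talkers=225,
        utterances_per_digit=2,
        noise_levels_db=tuple(float(v) for v in range(0, 101, 5)),
        speech_level_db=70.0,
        n_cf=128,
        fiber_scale=1.0,
        state_ids=("NH_mocr0_anf[0,0,52]",),
        paradigms=("nh_control", "unconstrained", "constrained"),
        n_folds=10,
        phase1_budget=250_000,
        phase2_budget=250_000,
        base_channels=16,
        batch_size=256,
        master_seed=master_seed,
    )


def human_protocol_config(master_seed: int = 0) -> ExperimentConfig:
    """The behavioral-testing variant: speech at 65 dB SPL, SNRs -30..0 dB.

    Mirrors the listening-test protocol (noise 65-95 dB SPL in 5-dB steps)
    rather than the full model grid; otherwise identical to the full preset.
    """
    base = full_config(master_seed)
    return ExperimentConfig(**{
        **base.__dict__,
        "preset": "human_protocol",
        "speech_level_db": 65.0,
        "noise_levels_db": tuple(float(v) for v in range(65, 96, 5)),
    })


def desk_config(master_seed: int = 0) -> ExperimentConfig:
    """Single-CPU preset: ~1,000 stimuli per state, 32 CFs, a small network."""
    return ExperimentConfig(
        preset="desk",
        n_talkers=10,
        utterances_per_digit=1,
        noise_levels_db=(20.0, 35.0, 50.0, 60.0, 65.0, 70.0,
                         75.0, 80.0, 85.0, 90.0),
        speech_level_db=70.0,
        n_cf=32,
        fiber_scale=0.1,
        state_ids=("NH_mocr0_anf[0,0,5]",),
        paradigms=("nh_control", "constrained"),
        n_folds=3,
        phase1_budget=16_000,
        phase2_budget=8_000,
        base_channels=8,
        batch_size=32,
        master_seed=master_seed,
    )


def config_hash(config: ExperimentConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:16]


def build_manifest(config: ExperimentConfig) -> pd.DataFrame:
    return st.build_stimulus_grid(config.n_talkers, config.utterances_per_digit,
                                  config.noise_levels_db,
                                  speech_level_db_spl=config.speech_level_db,
                                  seed=config.master_seed)


def build_neurogram_set(config: ExperimentConfig, manifest: pd.DataFrame,
                        state: pp.CochlearState, cf_grid: pp.CFGrid,
                        periphery_config: pp.PeripheryConfig = pp.PeripheryConfig(),
                        normalize: bool = True) -> ad.NeurogramSet:
    """Render every manifest row through the periphery under one state.

    Tokens are synthesised once per (talker, digit, utterance) and reused
    across noise levels; each row's recorded seed drives both its noise and
    its Poisson spiking, so the result is reproducible row by row.
    """
    talkers = st.make_talkers(config.n_talkers, seed=config.master_seed)
    tokens: dict = {}
    values = np.empty((len(manifest), config.n_cf, 70))
    for i, row in enumerate(manifest.itertuples(index=False)):
        key = (row.talker_id, row.digit, row.utterance)
        if key not in tokens:
            tokens[key] = st.synthesize_digit(
                int(row.digit), talkers[int(row.talker_id)],
                level_db_spl=config.speech_level_db,
                utterance=int(row.utterance))
        mix = st.mix_with_noise(tokens[key], float(row.noise_db),
                                seed=int(row.seed))
        raw = pp.generate_neurogram(mix, state, cf_grid, seed=int(row.seed) + 1,
                                    config=periphery_config)
        values[i] = pp.finalize_neurogram(raw, state=state,
                                          config=periphery_config,
                                          normalize=normalize).values
    return ad.NeurogramSet(values=values, manifest=manifest.copy(),
                           state_id=state.state_id)


def _states_by_id(cf_grid: pp.CFGrid, fiber_scale: float) -> dict:
    return {s.state_id: s for s in pp.table1_states(cf_grid,
                                                    fiber_scale=fiber_scale)}


def run_experiment(config: ExperimentConfig, out_dir=None,
                   force: bool = False) -> dict:
    """Full pipeline: stimuli -> neurograms -> training -> psychometrics.

    Returns a results dictionary (accuracy tables, sigmoid fits, thresholds,
    layer-change reports); when ``out_dir`` is given, also writes a
    deterministic directory layout (stimuli/, neurograms/, checkpoints/,
    results/, run.json with the config hash, seeds, and per-stage timings).
    An existing output directory with a different config hash is refused
    unless ``force`` is set.
    """
    chash = config_hash(config)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        run_file = out / "run.json"
        if run_file.exists():
            prior = json.loads(run_file.read_text())
            if prior.get("config_hash") != chash and not force:
                raise RuntimeError(
                    f"output dir {out} holds results for config "
                    f"{prior.get('config_hash')}, not {chash}; pass force=True "
                    "to overwrite")
        for sub in ("stimuli", "neurograms", "checkpoints", "results"):
            (out / sub).mkdir(parents=True, exist_ok=True)

    timings: dict = {}
    t0 = time.time()
    manifest = build_manifest(config)
    cf_grid = pp.make_cf_grid(config.n_cf)
    states = _states_by_id(cf_grid, config.fiber_scale)
    nh_state = next(s for s in states.values()
                    if s.audiogram.kind == "NH" and s.mocr_gain_db == 20.0
                    and s.fiber_counts[0] > 0)
    timings["manifest_s"] = time.time() - t0

    t0 = time.time()
    nh_data = build_neurogram_set(config, manifest, nh_state, cf_grid)
    degraded_sets = {sid: build_neurogram_set(config, manifest, states[sid],
                                              cf_grid)
                     for sid in config.state_ids}
    timings["neurograms_s"] = time.time() - t0

    folds = ad.make_folds(manifest, n_folds=config.n_folds,
                          seed=config.master_seed)
    net_cfg = config.network_config()

    t0 = time.time()
    results_tables = []
    layer_changes = []
    baselines = []
    train_log: list = []
    for fold in folds:
        baseline = nw.build_network(net_cfg, seed=config.master_seed * 7 + fold.fold_id)
        ad.train_phase(baseline, nh_data, fold.train_idx, config.phase1_budget,
                       seed=config.master_seed * 13 + fold.fold_id,
                       log=train_log if fold.fold_id == 0 else None)
        baselines.append(baseline)
        nh_table = ad.evaluate_by_snr(baseline, nh_data, fold.test_idx)
        nh_table.insert(0, "paradigm", "nh_baseline")
        nh_table.insert(1, "fold", fold.fold_id)
        nh_table.insert(2, "state_id", nh_state.state_id)
        results_tables.append(nh_table)
        for sid, deg_data in degraded_sets.items():
            for name in config.paradigms:
                trained, table = ad.run_paradigm(
                    baseline, ad.PARADIGMS[name], fold, nh_data, deg_data,
                    config.phase2_budget, seed=config.master_seed)
                table.insert(2, "state_id", sid)
                results_tables.append(table)
                report = ad.layer_change(trained, baseline)
                frame = report.as_frame()
                frame.insert(0, "paradigm", name)
                frame.insert(1, "fold", fold.fold_id)
                frame.insert(2, "state_id", sid)
                layer_changes.append(frame)
    timings["training_s"] = time.time() - t0

    accuracy = pd.concat(results_tables, ignore_index=True)
    changes = pd.concat(layer_changes, ignore_index=True)

    # psychometric fits and 50% thresholds per (state, paradigm)
    fits = {}
    for (sid, name), sub in accuracy.groupby(["state_id", "paradigm"]):
        curve = ps.PsychometricCurve.from_fold_table(sub)
        try:
            fit = ps.fit_sigmoid(curve, "model")
            fits[f"{sid}|{name}"] = {
                "a": fit.a, "b": fit.b, "residual": fit.residual,
                "threshold_db": ps.snr_at_accuracy(fit, 0.5)}
        except ValueError as exc:
            fits[f"{sid}|{name}"] = {"error": str(exc)}

    results = {"config_hash": chash, "timings": timings,
               "accuracy": accuracy, "layer_changes": changes, "fits": fits,
               "n_stimuli": len(manifest)}

    if out is not None:
        manifest.to_csv(out / "stimuli" / "manifest.csv", index=False)
        accuracy.to_csv(out / "results" / "accuracy.csv", index=False)
        pd.DataFrame(train_log).assign(split="train").to_csv(
            out / "results" / "training_log.csv", index=False)
        changes.to_csv(out / "results" / "layer_changes.csv", index=False)
        (out / "results" / "fits.json").write_text(json.dumps(fits, indent=2))
        from .h5io import save_checkpoint, save_neurogram_set
        save_neurogram_set(out / "neurograms" / "nh.h5", nh_data, cf_grid)
        for sid, deg in degraded_sets.items():
            safe = sid.replace("[", "").replace("]", "").replace(",", "-")
            save_neurogram_set(out / "neurograms" / f"{safe}.h5", deg, cf_grid)
        save_checkpoint(out / "checkpoints" / "baseline_fold0.h5", baselines[0])
        (out / "run.json").write_text(json.dumps(
            {"config_hash": chash, "config": asdict(config),
             "timings": timings}, indent=2))
    return results


@dataclass
class FixtureBundle:
    """Tiny in-memory dataset for tests: tokens, manifest, neurogram sets."""

    manifest: pd.DataFrame
    cf_grid: pp.CFGrid
    states: dict
    sets: dict                      # state_id -> NeurogramSet (finalized)
    raw_example: pp.Neurogram
    tokens: dict = field(default_factory=dict)


def make_fixtures(seed: int = 0) -> FixtureBundle:
    """40 tokens (4 talkers x 10 digits), 3 noise levels, 2 cochlear states,
    16-CF neurograms — small enough to regenerate in seconds, rich enough to
    exercise every neurogram invariant. Byte-stable for a given seed."""
    config = ExperimentConfig(
        preset="fixture", n_talkers=4, utterances_per_digit=1,
        noise_levels_db=(40.0, 70.0, 90.0), speech_level_db=70.0, n_cf=16,
        fiber_scale=0.1, state_ids=("NH_mocr0_anf[0,0,5]",),
        paradigms=("constrained",), n_folds=1, phase1_budget=0,
        phase2_budget=0, base_channels=4, batch_size=16, master_seed=seed)
    manifest = build_manifest(config)
    cf_grid = pp.make_cf_grid(config.n_cf)
    states = _states_by_id(cf_grid, config.fiber_scale)
    nh = next(s for s in states.values()
              if s.audiogram.kind == "NH" and s.mocr_gain_db == 20.0
              and s.fiber_counts[0] > 0)
    deg = states["NH_mocr0_anf[0,0,5]"]
    sets = {s.state_id: build_neurogram_set(config, manifest, s, cf_grid)
            for s in (nh, deg)}
    talkers = st.make_talkers(config.n_talkers, seed=seed)
    tok = st.synthesize_digit(7, talkers[0])
    raw = pp.generate_neurogram(st.mix_with_noise(tok, 70.0, seed=seed + 5),
                                nh, cf_grid, seed=seed + 6)
    tokens = {(t, d): st.synthesize_digit(d, talkers[t])
              for t in range(2) for d in range(10)}
    return FixtureBundle(manifest=manifest, cf_grid=cf_grid, states=states,
                         sets=sets, raw_example=raw, tokens=tokens)
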