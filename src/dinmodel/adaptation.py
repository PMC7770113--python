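"""Two-phase, three-paradigm train/test framework for studying adaptation.

Phase 1 trains a baseline classifier on normal-hearing (NH) neurograms.
Phase 2 continues training under one of three paradigms, then evaluates on
held-out neurograms of the paradigm's cochlear state:

* ``nh_control``      — phase 2 on NH neurograms, all layers trainable
                        (a listener who never acquires hearing loss; when
                        tested on degraded neurograms it is the no-adaptation
                        snapshot of sudden cochlear damage),
* ``unconstrained``   — phase 2 on degraded neurograms, all layers trainable
                        (an upper bound on central plasticity),
* ``constrained``     — phase 2 on degraded neurograms, only the final fully
                        connected layer (F5) trainable (a conservative model
                        of adult plasticity).

Data are split into 10 talker-disjoint folds (70/10/20 train/val/test at the
talker level); the same fold split is reused across both phases and all
paradigms so that test talkers are never seen in training. Where the network
changes is quantified per parameter tensor by the normalized mean difference
against the baseline — the mean magnitude of per-parameter change in units
of the baseline tensor's standard deviation (see :func:`layer_change`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import network as nw
from .network import NetworkState

__all__ = [
    "FoldSplit",
    "Paradigm",
    "PARADIGMS",
    "LayerChangeReport",
    "NeurogramSet",
    "make_folds",
    "train_phase",
    "run_paradigm",
    "evaluate_by_snr",
    "layer_change",
    "normalized_mean_difference",
]


@dataclass(frozen=True)
class FoldSplit:
    """One talker-disjoint 70/10/20 partition of a stimulus manifest."""

    fold_id: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    train_talkers: frozenset
    val_talkers: frozenset
    test_talkers: frozenset
    fractions: tuple = (0.70, 0.10, 0.20)
    seed: int = 0


@dataclass(frozen=True)
class Paradigm:
    """A phase-2 training condition."""

    name: str                 # {"nh_control", "unconstrained", "constrained"}
    phase2_source: str        # {"NH", "degraded"}
    trainable_mask: frozenset

    def __post_init__(self) -> None:
        valid = {
            "nh_control": ("NH", frozenset(nw.full_mask())),
            "unconstrained": ("degraded", frozenset(nw.full_mask())),
            "constrained": ("degraded", frozenset(nw.final_layer_mask())),
        }
        if self.name not in valid:
            raise ValueError(f"unknown paradigm {self.name!r}")
        source, mask = valid[self.name]
        if self.phase2_source != source or self.trainable_mask != mask:
            raise ValueError(f"paradigm {self.name!r} violates its contract")


def _paradigm(name: str) -> Paradigm:
    source = "NH" if name == "nh_control" else "degraded"
    mask = nw.final_layer_mask() if name == "constrained" else nw.full_mask()
    return Paradigm(name=name, phase2_source=source, trainable_mask=frozenset(mask))


PARADIGMS = {name: _paradigm(name)
             for name in ("nh_control", "unconstrained", "constrained")}


@dataclass
class NeurogramSet:
    """In-memory neurogram collection aligned with a stimulus manifest.

    ``values`` has shape (n_stimuli, n_cf, n_frames) of z-scored neurograms;
    row i corresponds to manifest row i.
    """

    values: np.ndarray
    manifest: pd.DataFrame
    state_id: str

    def __post_init__(self) -> None:
        if len(self.values) != len(self.manifest):
            raise ValueError("neurogram array and manifest length mismatch")

    @property
    def labels(self) -> np.ndarray:
        return self.manifest["digit"].to_numpy()

    @property
    def snrs(self) -> np.ndarray:
        return self.manifest["snr_db"].to_numpy()


def make_folds(manifest: pd.DataFrame, n_folds: int = 10,
               fractions: tuple = (0.70, 0.10, 0.20),
               seed: int = 0) -> list[FoldSplit]:
    """Talker-level random partitions honoring train/test talker disjointness.

    Talkers are permuted and split by the given fractions; every utterance
    follows its talker, so no talker appears in more than one subset and —
    because each talker's utterances span the full noise-level grid — every
    SNR is represented in every subset. Reproducible given ``seed``.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    talkers = np.sort(manifest["talker_id"].unique())
    n = len(talkers)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    if n_train < 1 or n_val < 1 or n - n_train - n_val < 1:
        raise ValueError(f"{n} talkers are too few for a "
                         f"{fractions[0]:.0%}/{fractions[1]:.0%}/"
                         f"{fractions[2]:.0%} talker-disjoint split")
    talker_col = manifest["talker_id"].to_numpy()
    folds = []
    for fold_id in range(n_folds):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, fold_id, 0xF0])
        perm = rng.permutation(talkers)
        tr = frozenset(perm[:n_train].tolist())
        va = frozenset(perm[n_train:n_train + n_val].tolist())
        te = frozenset(perm[n_train + n_val:].tolist())
        folds.append(FoldSplit(
            fold_id=fold_id,
            train_idx=np.flatnonzero(np.isin(talker_col, list(tr))),
            val_idx=np.flatnonzero(np.isin(talker_col, list(va))),
            test_idx=np.flatnonzero(np.isin(talker_col, list(te))),
            train_talkers=tr, val_talkers=va, test_talkers=te,
            fractions=tuple(fractions), seed=int(seed)))
    return folds


def train_phase(state: NetworkState, data: NeurogramSet, idx: np.ndarray,
                budget: int, seed: int,
                trainable_mask: set | frozenset | None = None,
                log: list | None = None) -> NetworkState:
    """Train for ``budget`` samples drawn with replacement from ``idx``.

    The final partial batch (budget not a multiple of the batch size) is
    still trained on. Returns the same state object, mutated.
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x77])
    batch_size = state.config.batch_size
    mask = set(trainable_mask) if trainable_mask is not None else None
    done = 0
    while done < budget:
        take = min(batch_size, budget - done)
        pick = rng.choice(idx, size=take, replace=True)
        loss = nw.train_step(state, data.values[pick], data.labels[pick], mask)
        done += take
        if log is not None:
            log.append({"step": state.step, "samples": done, "loss": loss})
    return state


def evaluate_by_snr(state: NetworkState, data: NeurogramSet,
                    idx: np.ndarray) -> pd.DataFrame:
    """Per-SNR accuracy table over the given manifest rows."""
    preds = nw.predict(state, data.values[idx])
    labels = data.labels[idx]
    snrs = data.snrs[idx]
    rows = []
    for snr in np.unique(snrs):
        m = snrs == snr
        rows.append({"snr_db": float(snr),
                     "accuracy": float((preds[m] == labels[m]).mean()),
                     "n_test": int(m.sum())})
    return pd.DataFrame(rows).sort_values("snr_db", ignore_index=True)


def run_paradigm(baseline: NetworkState, paradigm: Paradigm, fold: FoldSplit,
                 nh_data: NeurogramSet, degraded_data: NeurogramSet,
                 phase2_budget: int, seed: int = 0
                 ) -> tuple[NetworkState, pd.DataFrame]:
    """Phase-2 training plus held-out evaluation for one paradigm and fold.

    ``baseline`` must already be phase-1 trained on NH neurograms; it is not
    modified. The paradigm's phase-2 source selects between ``nh_data`` and
    ``degraded_data`` (row-aligned manifests); evaluation always uses the
    paradigm's test state: NH for ``nh_control`` tested on NH in baseline
    comparisons is handled by the caller — here testing uses the degraded set
    unless the paradigm trains on NH and no degradation is under study, in
    which case pass the NH set as ``degraded_data`` too.
    """
    source = nh_data if paradigm.phase2_source == "NH" else degraded_data
    state = baseline.copy()
    train_phase(state, source, fold.train_idx, phase2_budget,
                seed=seed * 101 + fold.fold_id, trainable_mask=paradigm.trainable_mask)
    table = evaluate_by_snr(state, degraded_data, fold.test_idx)
    table.insert(0, "paradigm", paradigm.name)
    table.insert(1, "fold", fold.fold_id)
    return state, table


@dataclass
class LayerChangeReport:
    """Per-tensor normalized mean parameter difference against a baseline."""

    changes: dict            # (layer, param) -> float (nan if undefined)
    undefined: set = field(default_factory=set)
    step: int = 0

    def as_frame(self) -> pd.DataFrame:
        rows = [{"layer": l, "param": p, "normalized_mean_difference": v,
                 "undefined": (l, p) in self.undefined}
                for (l, p), v in self.changes.items()]
        return pd.DataFrame(rows)


def normalized_mean_difference(values: np.ndarray, mu_b: float,
                               sigma_b: float) -> float:
    """(1/n) sum_i |(v_i - mu_B) / sigma_B| — the scaled absolute deviation of
    a parameter vector from a baseline reference, in baseline-SD units."""
    if sigma_b == 0.0:
        raise ZeroDivisionError("sigma_B = 0: normalized difference undefined")
    v = np.asarray(values, dtype=np.float64)
    return float(np.mean(np.abs((v - mu_b) / sigma_b)))


def layer_change(current: NetworkState, baseline: NetworkState) -> LayerChangeReport:
    """Normalized mean difference of every tensor against the baseline.

    For each of the 20 tensors the per-parameter change P_i - B_i is scaled
    by the baseline tensor's standard deviation sigma_B and averaged in
    magnitude: (1/n) sum_i |P_i - B_i| / sigma_B. An unchanged (e.g. frozen)
    tensor therefore reports exactly 0, and a one-sigma shift of a single
    parameter contributes 1/n. A baseline tensor with sigma_B = 0 yields NaN
    and is flagged, never a silent 0.
    """
    if current.fc_widths != baseline.fc_widths or \
            current.config.input_shape != baseline.config.input_shape or \
            current.config.base_channels != baseline.config.base_channels:
        raise ValueError("architectures differ; layer change undefined")
    changes: dict = {}
    undefined: set = set()
    for layer, key in nw.PARAM_KEYS:
        p = current.params[layer][key]
        b = baseline.params[layer][key]
        sigma = b.std()
        if sigma == 0.0:
            changes[(layer, key)] = float("nan")
            undefined.add((layer, key))
        else:
            changes[(layer, key)] = float(np.mean(np.abs(p - b) / sigma))
    return LayerChangeReport(changes=changes, undefined=undefined,
                             step=current.step)
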