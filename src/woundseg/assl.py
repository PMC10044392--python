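"""Active semi-supervised learning (ASSL) round manager.

The loop grows a labeled pool from zero manual annotations:

round 0   a *pretrained* source-domain model predicts a mask for every
          image; each mask is validated (simulated oracle against ground
          truth, or recorded human decisions); accepted masks seed the
          labeled pool as pseudo-labels.
round r   the model is reset to the pretrained weights, trained on the
          current pool's train split, evaluated (F1/IoU) on a validation
          split frozen at round 1, then predicts on the *whole* dataset;
          every prediction is validated; the number of accepted
          segmentations over the whole dataset is the round's
          ``n_correct``, and newly accepted samples join the pool with
          their predicted masks as labels.

The loop stops when the accepted fraction reaches the target (default
80%), when ``max_rounds`` is hit, or when ``n_correct`` has not improved
for ``plateau_patience`` rounds.

Accounting invariants maintained (and tested): the labeled pool only
ever grows; accepted pseudo-labels are permanent and never re-validated;
validation-split ids never enter a training split; per-round training
always starts from a bit-identical copy of the pretrained weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import compare_masks
from .model import ModelState, TrainingConfig, UNetSegmenter
from .synthetic import ImageSample
from .validation import ValidationResult, ValidationThresholds, oracle_validate

__all__ = [
    "PoolState",
    "RoundState",
    "ASSLConfig",
    "ASSLRunner",
    "bootstrap_round0",
    "split_pool",
    "run_assl",
    "round_report",
    "decisions_from_csv",
]


@dataclass(frozen=True)
class PoolState:
    """Which samples carry accepted pseudo-labels at a point in time."""

    labeled: tuple[str, ...]
    unlabeled: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.labeled) & set(self.unlabeled):
            raise ValueError("labeled and unlabeled pools overlap")

    @property
    def total(self) -> int:
        return len(self.labeled) + len(self.unlabeled)


@dataclass(frozen=True)
class RoundState:
    """One row of the per-round accounting table."""

    round_index: int
    n_train: int
    n_val: int
    n_correct: int
    f1: float  # nan at round 0 (no trained model yet)
    iou: float
    pool: PoolState

    def to_dict(self) -> dict:
        return {
            "round_index": self.round_index,
            "n_train": self.n_train,
            "n_val": self.n_val,
            "n_correct": self.n_correct,
            "f1": None if math.isnan(self.f1) else self.f1,
            "iou": None if math.isnan(self.iou) else self.iou,
            "labeled": list(self.pool.labeled),
            "unlabeled": list(self.pool.unlabeled),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RoundState":
        return cls(
            round_index=d["round_index"], n_train=d["n_train"], n_val=d["n_val"],
            n_correct=d["n_correct"],
            f1=float("nan") if d["f1"] is None else d["f1"],
            iou=float("nan") if d["iou"] is None else d["iou"],
            pool=PoolState(labeled=tuple(d["labeled"]), unlabeled=tuple(d["unlabeled"])),
        )


@dataclass(frozen=True)
class ASSLConfig:
    """Knobs of the round manager.

    target_correct_fraction : stop once n_correct/total reaches this.
    max_rounds : hard cap on training rounds (round 0 not counted).
    plateau_patience : stop after this many rounds without an n_correct
        improvement.
    val_fraction : share of the labeled pool held out for metric
        evaluation; the split is drawn once at round 1 and frozen.
    val_count : optional exact validation-set size overriding the
        fraction rule.
    threshold : probability binarization threshold for predictions.
    """

    target_correct_fraction: float = 0.80
    max_rounds: int = 10
    plateau_patience: int = 2
    val_fraction: float = 0.10
    val_count: int | None = None
    threshold: float = 0.5
    seed: int = 0
    thresholds: ValidationThresholds = field(default_factory=ValidationThresholds)
    training: TrainingConfig = field(default_factory=TrainingConfig)

    def __post_init__(self) -> None:
        if not (0.0 < self.val_fraction < 0.5):
            raise ValueError("val_fraction must be in (0, 0.5)")
        if not (0.0 < self.target_correct_fraction <= 1.0):
            raise ValueError("target_correct_fraction must be in (0, 1]")
        if self.max_rounds < 1 or self.plateau_patience < 1:
            raise ValueError("max_rounds and plateau_patience must be >= 1")


def split_pool(
    labeled_ids, val_fraction: float, seed: int, val_count: int | None = None
) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive train/validation split of the labeled pool.

    ``n_val = max(1, round(val_fraction * n))`` unless ``val_count``
    overrides it.  Deterministic given the seed.
    """
    ids = sorted(labeled_ids)
    n = len(ids)
    if n < 2:
        raise ValueError(f"need at least 2 labeled samples to split, have {n}")
    n_val = val_count if val_count is not None else max(1, round(val_fraction * n))
    if not (0 < n_val < n):
        raise ValueError(f"validation size {n_val} infeasible for pool of {n}")
    rng = np.random.default_rng([seed, 0xA55])
    order = rng.permutation(n)
    val = sorted(ids[i] for i in order[:n_val])
    train = sorted(ids[i] for i in order[n_val:])
    return train, val


class ASSLRunner:
    """Drives the TL+ASSL loop over an in-memory dataset.

    Parameters
    ----------
    pretrained : ModelState
        The source-domain model every round restarts from.
    config : ASSLConfig
    decide : callable or None
        ``decide(sample_id, pred_mask, truth_mask) -> ValidationResult``.
        Defaults to the simulated oracle against each sample's ground
        truth.  Supplying a callable allows recorded human decisions (or
        degenerate policies such as accept-everything) to gate the pool
        instead.

    Attributes (after :meth:`run`)
    ------------------------------
    history_ : list[RoundState]
    pseudo_labels_ : dict[str, np.ndarray]   accepted masks by sample id
    decisions_ : pandas.DataFrame            per-round criterion booleans
    val_ids_ : list[str]                     frozen validation split
    """

    def __init__(self, pretrained: ModelState, config: ASSLConfig | None = None,
                 decide=None) -> None:
        self.pretrained = pretrained
        self.config = config or ASSLConfig()
        self.decide = decide

    # -- internals ----------------------------------------------------------

    def _oracle(self, sample: ImageSample, pred: np.ndarray) -> ValidationResult:
        if self.decide is not None:
            return self.decide(sample.sample_id, pred, sample.truth_mask)
        if sample.truth_mask is None:
            raise ValueError(
                f"sample {sample.sample_id} has no ground truth; oracle mode "
                "needs truth masks (supply a decide callable otherwise)"
            )
        return oracle_validate(pred, sample.truth_mask, self.config.thresholds)

    def _validate_all(self, samples, preds) -> pd.DataFrame:
        rows = []
        for s, p in zip(samples, preds):
            r = self._oracle(s, p)
            rows.append({
                "sample_id": s.sample_id, "covers_wound": r.covers_wound,
                "only_wound": r.only_wound, "boundary_ok": r.boundary_ok,
                "accepted": r.accepted,
            })
        return pd.DataFrame(rows)

    def _new_model(self, round_seed: int) -> UNetSegmenter:
        cfg, tr = self.config, self.config.training
        spec = self.pretrained.backbone
        return UNetSegmenter(
            backbone=spec.name, input_size=spec.input_size, base_width=spec.base_width,
            epochs=tr.epochs, learning_rate=tr.learning_rate, batch_size=tr.batch_size,
            alpha=tr.loss.alpha, gamma=tr.loss.gamma, beta=tr.loss.beta,
            horizontal_flip=tr.horizontal_flip, vertical_flip=tr.vertical_flip,
            threshold=cfg.threshold, pretrained=self.pretrained, seed=round_seed,
        )

    # -- the loop -----------------------------------------------------------

    def run(self, samples: list[ImageSample]) -> list[RoundState]:
        if not samples:
            raise ValueError("dataset is empty")
        cfg = self.config
        by_id = {s.sample_id: s for s in samples}
        if len(by_id) != len(samples):
            raise ValueError("duplicate sample ids in dataset")
        X = np.stack([s.pixels for s in samples])
        ids = [s.sample_id for s in samples]

        # ---- round 0: pretrained model bootstraps the pool
        model0 = UNetSegmenter(threshold=cfg.threshold).load_state(self.pretrained)
        preds = model0.predict(X)
        decisions = self._validate_all(samples, preds)
        decisions.insert(0, "round", 0)
        self.pseudo_labels_ = {
            sid: preds[i].copy()
            for i, sid in enumerate(ids)
            if bool(decisions.loc[i, "accepted"])
        }
        labeled = tuple(sorted(self.pseudo_labels_))
        pool = PoolState(labeled=labeled,
                         unlabeled=tuple(sorted(set(ids) - set(labeled))))
        n_correct = int(decisions["accepted"].sum())
        history = [RoundState(0, 0, 0, n_correct, float("nan"), float("nan"), pool)]
        self.decisions_ = decisions
        self.val_ids_ = []

        if not labeled:
            warnings.warn("round 0 accepted no masks; ASSL cannot start", stacklevel=2)
            self.history_ = history
            return history

        best_correct = n_correct
        stall = 0
        for r in range(1, cfg.max_rounds + 1):
            if n_correct / len(samples) >= cfg.target_correct_fraction:
                break
            if len(pool.labeled) < 2:
                warnings.warn("labeled pool too small to split; stopping", stacklevel=2)
                break

            if not self.val_ids_:
                train_ids, self.val_ids_ = split_pool(
                    pool.labeled, cfg.val_fraction, cfg.seed, cfg.val_count
                )
            else:
                train_ids = sorted(set(pool.labeled) - set(self.val_ids_))

            # weight reset is implicit: every round's model is constructed
            # from the same pretrained state
            model = self._new_model(cfg.seed + r)
            Xt = np.stack([by_id[i].pixels for i in train_ids])
            yt = np.stack([self.pseudo_labels_[i] for i in train_ids])
            model.fit(Xt, yt)

            f1s, ious = [], []
            val_preds = model.predict(np.stack([by_id[i].pixels for i in self.val_ids_]))
            for sid, vp in zip(self.val_ids_, val_preds):
                rep = compare_masks(vp, self.pseudo_labels_[sid])
                f1s.append(rep.f1)
                ious.append(rep.iou)

            preds = model.predict(X)
            dec = self._validate_all(samples, preds)
            dec.insert(0, "round", r)
            self.decisions_ = pd.concat([self.decisions_, dec], ignore_index=True)
            n_correct = int(dec["accepted"].sum())

            for i, sid in enumerate(ids):
                if bool(dec.loc[i, "accepted"]) and sid not in self.pseudo_labels_:
                    self.pseudo_labels_[sid] = preds[i].copy()
            labeled = tuple(sorted(self.pseudo_labels_))
            pool = PoolState(labeled=labeled,
                             unlabeled=tuple(sorted(set(ids) - set(labeled))))
            history.append(RoundState(
                round_index=r, n_train=len(train_ids), n_val=len(self.val_ids_),
                n_correct=n_correct, f1=float(np.mean(f1s)), iou=float(np.mean(ious)),
                pool=pool,
            ))
            self.last_model_ = model

            if n_correct > best_correct:
                best_correct = n_correct
                stall = 0
            else:
                stall += 1
                if stall >= cfg.plateau_patience:
                    break

        self.history_ = history
        return history


# ---------------------------------------------------------------------------
# functional wrappers


def bootstrap_round0(
    pretrained: ModelState, dataset: list[ImageSample], cfg: ASSLConfig | None = None
) -> tuple[PoolState, RoundState]:
    """Round 0 only: predict with the pretrained model and form the pool."""
    from dataclasses import replace

    # a vanishing target makes run() stop right after round 0
    runner = ASSLRunner(pretrained, replace(cfg or ASSLConfig(),
                                            target_correct_fraction=1e-9))
    history = runner.run(dataset)
    state = history[0]
    return state.pool, state


def run_assl(
    dataset: list[ImageSample], pretrained: ModelState, cfg: ASSLConfig | None = None,
    decide=None,
) -> list[RoundState]:
    """Full loop; returns the round history (see :class:`ASSLRunner`)."""
    return ASSLRunner(pretrained, cfg, decide=decide).run(dataset)


def decisions_from_csv(path, expected_ids=None):
    """Turn a recorded decisions CSV into a ``decide`` callable.

    The CSV needs at least ``sample_id`` and ``accepted`` columns (the
    review CLI's output); per-criterion columns (covers_wound,
    only_wound, boundary_ok) are used when present.  With
    ``expected_ids`` given, missing decisions raise immediately, listing
    every pending sample id — the signal that a human review round is
    incomplete.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns or "accepted" not in df.columns:
        raise ValueError(f"decisions file {path} needs sample_id and accepted columns")
    has_criteria = {"covers_wound", "only_wound", "boundary_ok"} <= set(df.columns)
    table = {}
    for row in df.itertuples(index=False):
        if has_criteria:
            table[row.sample_id] = ValidationResult(
                bool(row.covers_wound), bool(row.only_wound), bool(row.boundary_ok))
        else:
            acc = bool(row.accepted)
            table[row.sample_id] = ValidationResult(acc, acc, acc)
    if expected_ids is not None:
        pending = sorted(set(expected_ids) - set(table))
        if pending:
            raise ValueError(f"decisions missing for {len(pending)} samples: {pending}")

    def decide(sample_id, pred, truth):
        if sample_id not in table:
            raise ValueError(f"no recorded decision for sample {sample_id}")
        return table[sample_id]

    return decide


def round_report(history: list[RoundState]) -> pd.DataFrame:
    """Per-round accounting table with counts and percentage columns."""
    if not history:
        raise ValueError("history is empty")
    rows = []
    for st in history:
        n_lab = len(st.pool.labeled)
        rows.append({
            "round": st.round_index,
            "n_train": st.n_train,
            "train_pct": 100.0 * st.n_train / n_lab if n_lab else 0.0,
            "n_val": st.n_val,
            "val_pct": 100.0 * st.n_val / n_lab if n_lab else 0.0,
            "n_correct": st.n_correct,
            "correct_pct": 100.0 * st.n_correct / st.pool.total,
            "f1": st.f1,
            "iou": st.iou,
        })
    return pd.DataFrame(rows)
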