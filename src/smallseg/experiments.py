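"""Training strategies and cross-validation orchestration.

Five strategies are supported, mirroring the study design:

* ``supervised``      — train from scratch on the labeled training fold;
* ``supervised_aug``  — the same with geometric augmentation of the
                        training fold (rate in {1, 4, 8, 16, 32});
* ``finetune``        — start from a supervised pretrained checkpoint and
                        fine-tune all parameters for a small epoch budget
                        (2/4/6/8/10, default 6) on augmented data;
* ``layer_freeze``    — start from the same checkpoint but train only the
                        two decoder blocks nearest the output plus head;
* ``ssl``             — load a contrastively pretrained encoder, freeze
                        it, and train the decoder on augmented data.

Cross-validation schemes: three near-equal folds, or leave-one-out for
the small-tumor subset.  Augmented variants are only ever created from
the training side of a fold, and normal (tumor-free) cases never enter
training: they are scored by case-level detection only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .augment import expand_training_set
from .metrics import DetectionRule, DetectionTable, detect, detection_metrics, dice
from .models import SwinUNETRSegmenter, UNetSegmenter
from .preprocess import CanonicalCase
from .ssl import ContrastivePretrainer, downstream_train

STRATEGIES = ("supervised", "supervised_aug", "finetune", "layer_freeze", "ssl")
FINETUNE_EPOCHS = (2, 4, 6, 8, 10)
AUG_RATES = (1, 4, 8, 16, 32)


@dataclass
class TrainConfig:
    strategy: str = "supervised"
    epochs: int = 10
    finetune_epochs: int = 6
    augmentation_rate: int = 1
    loss: str = "dice"
    lr: float = 1e-3
    batch_size: int = 2
    seed: int = 0
    model: str = "swin"                      # swin | unet
    model_kwargs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.finetune_epochs not in FINETUNE_EPOCHS:
            raise ValueError(f"finetune_epochs must be in {FINETUNE_EPOCHS}")
        if self.augmentation_rate not in AUG_RATES:
            raise ValueError(f"augmentation_rate must be in {AUG_RATES}")
        if self.model not in ("swin", "unet"):
            raise ValueError("model must be 'swin' or 'unet'")


@dataclass
class FoldPlan:
    scheme: str                              # threefold | leave_one_out
    partitions: list[list[str]]

    def all_ids(self) -> list[str]:
        return [cid for part in self.partitions for cid in part]


def make_folds(case_ids: list[str], scheme: str, seed: int = 0) -> FoldPlan:
    """Disjoint covering test partitions for a CV scheme."""
    ids = list(case_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("case ids must be unique")
    if scheme == "threefold":
        if len(ids) < 3:
            raise ValueError("threefold CV needs at least 3 cases")
        rng = np.random.default_rng(seed)
        order = [ids[i] for i in rng.permutation(len(ids))]
        parts = [list(p) for p in np.array_split(order, 3)]
    elif scheme == "leave_one_out":
        if len(ids) < 2:
            raise ValueError("leave-one-out CV needs at least 2 cases")
        parts = [[cid] for cid in ids]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return FoldPlan(scheme=scheme, partitions=parts)


@dataclass
class StrategyResult:
    dice_per_case: dict[str, float]
    predictions: dict[str, np.ndarray]
    estimator: object


def _stack(cases: list[CanonicalCase]):
    X = np.stack([c.image for c in cases]).astype(np.float32)
    y = np.stack([c.label for c in cases]).astype(np.uint8)
    return X, y


def _build_estimator(config: TrainConfig, epochs: int, trainable: str,
                     init_state=None):
    common = dict(epochs=epochs, lr=config.lr, batch_size=config.batch_size,
                  loss=config.loss, trainable=trainable, init_state=init_state,
                  random_state=config.seed, **config.model_kwargs)
    if config.model == "unet":
        return UNetSegmenter(**common)
    return SwinUNETRSegmenter(**common)


def run_strategy(train_cases: list[CanonicalCase],
                 test_cases: list[CanonicalCase],
                 config: TrainConfig, pretrained=None) -> StrategyResult:
    """Train under one strategy and score Dice on the held-out cases.

    ``pretrained`` is a full-model state dict for finetune/layer_freeze,
    or an encoder state dict / fitted ContrastivePretrainer for ssl.
    """
    if not train_cases:
        raise ValueError("empty training set")
    strat = config.strategy
    needs_ckpt = strat in ("finetune", "layer_freeze", "ssl")
    if needs_ckpt and pretrained is None:
        raise ValueError(f"strategy {strat!r} requires a pretrained checkpoint")

    if strat in ("supervised_aug", "finetune", "layer_freeze", "ssl"):
        train_cases = expand_training_set(train_cases, config.augmentation_rate,
                                          seed=config.seed)
    X, y = _stack(train_cases)

    if strat == "ssl":
        est = downstream_train(pretrained, X, y, epochs=config.epochs,
                               lr=config.lr, batch_size=config.batch_size,
                               loss=config.loss, random_state=config.seed,
                               **config.model_kwargs)
    else:
        if strat in ("supervised", "supervised_aug"):
            est = _build_estimator(config, config.epochs, "all")
        elif strat == "finetune":
            est = _build_estimator(config, config.finetune_epochs, "all",
                                   init_state=pretrained)
        else:  # layer_freeze
            est = _build_estimator(config, config.epochs, "bottom_two_only",
                                   init_state=pretrained)
        est.fit(X, y)

    dices: dict[str, float] = {}
    preds: dict[str, np.ndarray] = {}
    for case in test_cases:
        Xt = case.image[None]
        pred = est.predict(Xt)[0]
        preds[case.source_id] = pred
        dices[case.source_id] = dice(pred, case.label).dice
    return StrategyResult(dice_per_case=dices, predictions=preds, estimator=est)


@dataclass
class ExperimentReport:
    scheme: str
    strategy: str
    per_fold: list[dict]
    mean_dice: float | None
    detection: dict | None = None

    def to_json(self) -> str:
        return json.dumps({
            "scheme": self.scheme, "strategy": self.strategy,
            "per_fold": self.per_fold, "mean_dice": self.mean_dice,
            "detection": self.detection}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentReport":
        d = json.loads(text)
        return cls(scheme=d["scheme"], strategy=d["strategy"],
                   per_fold=d["per_fold"], mean_dice=d["mean_dice"],
                   detection=d.get("detection"))


def run_experiment(cases: dict[str, CanonicalCase], plan: FoldPlan,
                   config: TrainConfig, pretrained=None,
                   extra_train: list[CanonicalCase] | None = None,
                   normal_cases: dict[str, tuple[CanonicalCase, str]] | None = None,
                   detection_rule: DetectionRule | None = None) -> ExperimentReport:
    """Cross-validated run of one strategy; optionally detection scoring.

    ``extra_train`` joins every training fold (the train-on-A+B
    pattern).  ``normal_cases`` maps id -> (case, group) with group in
    {normal_plain, normal_hyperintense}; normals never join training and
    are scored by detection with a model trained on all tumor cases.
    """
    master = np.random.default_rng(config.seed)
    per_fold = []
    all_dice = []
    tumor_detect: dict[str, bool] = {}
    rule = detection_rule or DetectionRule()
    for part in plan.partitions:
        fold_seed = int(master.integers(0, 2 ** 31 - 1))
        fold_cfg = TrainConfig(**{**vars(config), "seed": fold_seed})
        test = [cases[cid] for cid in part]
        train = [cases[cid] for cid in plan.all_ids() if cid not in part]
        if extra_train:
            train = list(extra_train) + train
        res = run_strategy(train, test, fold_cfg, pretrained=pretrained)
        per_fold.append({"test_ids": list(part),
                         "dice": {k: float(v) for k, v in res.dice_per_case.items()}})
        all_dice.extend(res.dice_per_case.values())
        for cid, pred in res.predictions.items():
            tumor_detect[cid] = detect(pred, rule)

    detection = None
    if normal_cases is not None:
        # normals are evaluated with a model trained on every tumor case
        final_cfg = TrainConfig(**{**vars(config),
                                   "seed": int(master.integers(0, 2 ** 31 - 1))})
        train = [cases[cid] for cid in plan.all_ids()]
        if extra_train:
            train = list(extra_train) + train
        final = run_strategy(train, [], final_cfg, pretrained=pretrained)
        table = DetectionTable()
        for cid, detected in tumor_detect.items():
            table.add("small_tumor", detected)
        for cid, (case, group) in normal_cases.items():
            pred = final.estimator.predict(case.image[None])[0]
            table.add(group, detect(pred, rule))
        detection = {
            "table": {"small_tumor": list(table.small_tumor),
                      "normal_hyperintense": list(table.normal_hyperintense),
                      "normal_plain": list(table.normal_plain)},
            "metrics": detection_metrics(table),
        }

    mean = float(np.mean(all_dice)) if all_dice else None
    return ExperimentReport(scheme=plan.scheme, strategy=config.strategy,
                            per_fold=per_fold, mean_dice=mean,
                            detection=detection)
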