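"""Data splitting and the training loop.

The protocol mirrors common practice for this architecture family: RMSprop at
learning rate 1e-3, batch size 2, 20 epochs, and a 70:10:20 train/validation/
test split.  The split sizes follow a fixed rounding rule — train gets
``floor(0.70 n)``, validation ``round-half-up(0.10 n)``, test the remainder —
so that n = 1158 yields 810/116/232.  Per-epoch training loss and validation
Dice are recorded, and the returned model carries the weights of the best
validation epoch.
"""

from __future__ import annotations

import copy
import json
import hashlib
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import metrics as M
from .model import TransResUNet
from .nn import tensor as T
from .nn.optim import RMSprop
from .postprocess import PostprocessConfig, binarize, postprocess

__all__ = ["TrainConfig", "DataSplit", "split_dataset", "train_model",
           "evaluate_split", "write_manifest"]

LOSSES = ("cross_entropy", "dice", "combined")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 2
    epochs: int = 20
    split_ratios: tuple[int, int, int] = (70, 10, 20)
    seed: int = 0
    loss: str = "cross_entropy"
    model_selection: str = "best"   # "best" (validation Dice) or "last"
    # RMSprop internals (recorded in run manifests for reproducibility)
    rmsprop_alpha: float = 0.99
    rmsprop_eps: float = 1e-8

    def __post_init__(self):
        r = self.split_ratios
        if len(r) != 3 or any(x <= 0 for x in r) or sum(r) != 100:
            raise ValueError("split_ratios must be three positive ints summing to 100")
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}")
        if self.model_selection not in ("best", "last"):
            raise ValueError("model_selection must be 'best' or 'last'")


@dataclass(frozen=True)
class DataSplit:
    train_ids: tuple
    val_ids: tuple
    test_ids: tuple

    def __post_init__(self):
        all_ids = self.train_ids + self.val_ids + self.test_ids
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("split partitions overlap")


def split_dataset(ids, ratios=(70, 10, 20), seed: int = 0) -> DataSplit:
    """Seeded shuffle then deterministic cut.

    Sizes: n_train = floor(r_t*n/100), n_val = round-half-up(r_v*n/100),
    n_test = remainder.  At n=1158 with 70:10:20 this gives 810/116/232.
    """
    ids = list(ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 ids to split")
    rt, rv, _ = ratios
    n_train = int(np.floor(rt * n / 100))
    n_val = int(np.floor(rv * n / 100 + 0.5))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"split of {n} ids at {ratios} leaves an empty part")
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in order]
    return DataSplit(tuple(shuffled[:n_train]),
                     tuple(shuffled[n_train:n_train + n_val]),
                     tuple(shuffled[n_train + n_val:]))


def _soft_dice_loss(logits, target: np.ndarray):
    """1 - soft Dice of the lung-probability channel against the mask."""
    probs = T.softmax(T.transpose(logits, (0, 2, 3, 1)))       # B,H,W,C
    b, h, w, c = probs.shape
    p1 = T.reshape(probs, (b * h * w, c)) @ np.array([[0.0], [1.0]], dtype=np.float32)
    t = np.asarray(target, dtype=np.float32).reshape(b * h * w, 1)
    eps = 1.0
    inter = T.tsum(p1 * t)
    denom = T.tsum(p1) + float(t.sum())
    return 1.0 - T.div(2.0 * inter + eps, denom + eps)


def compute_loss(logits, target: np.ndarray, kind: str):
    if kind == "cross_entropy":
        return T.softmax_cross_entropy(logits, target)
    if kind == "dice":
        return _soft_dice_loss(logits, target)
    ce = T.softmax_cross_entropy(logits, target)
    return ce + _soft_dice_loss(logits, target)


def _validation_dice(model: TransResUNet, data: dict, ids) -> float:
    scores = []
    for i in ids:
        img, mask = data[i]
        pred = binarize(model.predict_proba(img), 0.5)
        scores.append(M.dice(pred, mask))
    return float(np.mean(scores))


def train_model(model: TransResUNet, data: dict, split: DataSplit,
                tcfg: TrainConfig = TrainConfig(),
                log=None) -> tuple[TransResUNet, list[dict]]:
    """Optimise ``model`` on ``data`` (id -> (image, mask)) over ``split``.

    Returns the model (weights of the best-validation epoch when
    ``model_selection='best'``) and the per-epoch history.
    """
    if not split.train_ids:
        raise ValueError("empty training set")
    rng = np.random.default_rng(tcfg.seed)
    opt = RMSprop(model.parameters(), lr=tcfg.learning_rate,
                  alpha=tcfg.rmsprop_alpha, eps=tcfg.rmsprop_eps)
    history: list[dict] = []
    best = (-np.inf, None)
    for epoch in range(tcfg.epochs):
        model.train()
        order = rng.permutation(len(split.train_ids))
        losses = []
        for start in range(0, len(order), tcfg.batch_size):
            batch = [split.train_ids[i] for i in order[start:start + tcfg.batch_size]]
            imgs = np.stack([data[i][0] for i in batch])[:, None].astype(np.float32)
            masks = np.stack([data[i][1] for i in batch]).astype(np.int64)
            logits = model(imgs)
            loss = compute_loss(logits, masks, tcfg.loss)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {batch}: {loss.data}")
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_dice = (_validation_dice(model, data, split.val_ids)
                    if split.val_ids else float("nan"))
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_dice": val_dice})
        if log is not None:
            log(f"epoch {epoch + 1}/{tcfg.epochs}: "
                f"loss={history[-1]['train_loss']:.4f} val_dice={val_dice:.4f}")
        if tcfg.model_selection == "best" and np.isfinite(val_dice) and val_dice > best[0]:
            best = (val_dice, copy.deepcopy(model.state_dict()))
    if tcfg.model_selection == "best" and best[1] is not None:
        model.load_state_dict(best[1])
    model.eval()
    return model, history


def evaluate_split(model: TransResUNet, data: dict, ids,
                   post_cfg: PostprocessConfig | None = PostprocessConfig()
                   ) -> tuple[list[M.MetricsReport], M.MetricsReport]:
    """Per-image metrics (forward + optional post-processing) and their mean."""
    reports = []
    for i in ids:
        img, mask = data[i]
        prob = model.predict_proba(img)
        pred = (postprocess(prob, post_cfg) if post_cfg is not None
                else binarize(prob, 0.5))
        reports.append(M.report(pred, mask))
    return reports, M.aggregate(reports)


def run_phantom_study(seed: int = 0, n_images: int = 60, side: int = 64,
                      epochs: int = 20, log=None) -> dict:
    """Desk-scale end-to-end study on synthetic phantoms.

    Generates ``n_images`` phantoms, preprocesses them to ``side``, trains a
    tiny network under the standard protocol (RMSprop lr 1e-3, batch 2,
    70:10:20 split) and scores the held-out test set both with the raw
    0.5-binarised prediction and after morphological post-processing.
    """
    from .model import ModelConfig, TransResUNet
    from .phantom import PhantomConfig, generate_pairs
    from .preprocess import preprocess, resize_mask

    pcfg = PhantomConfig(seed=seed)
    pairs = generate_pairs(n_images, pcfg)
    data = {f"phantom_{i:04d}": (preprocess(raw, side).pixels.astype(np.float32),
                                 resize_mask(mask, side))
            for i, (raw, mask) in enumerate(pairs)}
    split = split_dataset(sorted(data), seed=seed)
    tcfg = TrainConfig(seed=seed, epochs=epochs)
    model = TransResUNet(ModelConfig.tiny(side), seed=seed)
    model, history = train_model(model, data, split, tcfg, log=log)
    _, agg_raw = evaluate_split(model, data, split.test_ids, post_cfg=None)
    _, agg_post = evaluate_split(model, data, split.test_ids)
    return {"split_sizes": (len(split.train_ids), len(split.val_ids),
                            len(split.test_ids)),
            "n_test": len(split.test_ids),
            "raw": agg_raw, "post": agg_post, "history": history,
            "model": model, "data": data, "split": split}


def write_manifest(path: Path | str, tcfg: TrainConfig, split: DataSplit,
                   extra: dict | None = None) -> dict:
    """Run manifest: config, its hash, seed and split ids — enough to replay."""
    payload = {"train_config": asdict(tcfg),
               "split": {"train_ids": list(split.train_ids),
                         "val_ids": list(split.val_ids),
                         "test_ids": list(split.test_ids)}}
    if extra:
        payload.update(extra)
    payload["config_hash"] = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]
    Path(path).write_text(json.dumps(payload, indent=2))
    return payload
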