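"""Class-weighted training loop, evaluation and ratio resampling."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .data import TripletDataset
from .metrics import MetricReport, auc_roc, evaluate_predictions
from .model import DSADeepFMNetwork, ModelConfig
from .nn import Adam
from .splits import SplitPlan

logger = logging.getLogger(__name__)

PROB_EPS = 1e-7  # probabilities are clamped to [eps, 1-eps] inside the loss


def weighted_cross_entropy(probs, labels, w_pos: float = 1.0, w_neg: float = 1.0):
    """Mean over the batch of -w(y) * log p(y).

    `probs` may be a (B, 2) array/Tensor of class probabilities or a (B,)
    vector of synergy probabilities.  Returns a Tensor when given a Tensor
    (for backprop), otherwise a float.
    """
    y = np.asarray(labels).astype(int)
    w = np.where(y == 1, w_pos, w_neg)
    is_tensor = isinstance(probs, Tensor)
    p = probs if is_tensor else Tensor(np.asarray(probs, dtype=np.float64))
    if p.ndim == 1:
        onehot = np.stack([1 - y, y], axis=1)
        from .autodiff import stack2

        p = stack2(1.0 - p, p, axis=1)
    else:
        onehot = np.zeros(p.shape)
        onehot[np.arange(len(y)), y] = 1.0
    p_true = (p * onehot).sum(axis=1).clip(PROB_EPS, 1.0 - PROB_EPS)
    loss = (p_true.log() * (-w)).mean()
    return loss if is_tensor else loss.item()


@dataclass
class TrainingHistory:
    train_loss: list = field(default_factory=list)
    val_auc: list = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False


def fit_network(
    net: DSADeepFMNetwork,
    cat: np.ndarray,
    num: np.ndarray,
    y: np.ndarray,
    val: tuple | None = None,
    rng: np.random.Generator | None = None,
) -> TrainingHistory:
    """Adam training with step learning-rate decay and early stopping on
    validation AUC-ROC.  Deterministic under a fixed config seed."""
    cfg = net.config
    rng = rng or np.random.default_rng(cfg.seed + 1)
    opt = Adam(
        net.parameters(), lr=cfg.lr,
        decay_rate=cfg.lr_decay_rate, decay_every=cfg.lr_decay_every,
    )
    history = TrainingHistory()
    best_auc = -np.inf
    best_state = None
    bad_epochs = 0
    n = len(y)
    for epoch in range(cfg.max_epochs):
        net.set_training(True)
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            bi = perm[start: start + cfg.batch_size]
            probs = net.forward(cat[bi], num[bi])
            loss = weighted_cross_entropy(probs, y[bi], cfg.w_pos, cfg.w_neg)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at epoch {epoch}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step(epoch)
            losses.append(loss.item())
        history.train_loss.append(float(np.mean(losses)))
        if val is not None:
            vc, vn, vy = val
            p_syn = net.predict_proba(vc, vn)[:, 1]
            vauc = auc_roc(vy, p_syn) if len(np.unique(vy)) > 1 else float("nan")
            history.val_auc.append(vauc)
            if np.isfinite(vauc) and vauc > best_auc + 1e-6:
                best_auc = vauc
                best_state = {k: v.copy() for k, v in net.named_state().items()}
                history.best_epoch = epoch
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= cfg.patience:
                    history.stopped_early = True
                    break
    if best_state is not None:
        net.load_state(best_state)
    net.set_training(False)
    return history


def build_network(dataset: TripletDataset, config: ModelConfig) -> DSADeepFMNetwork:
    return DSADeepFMNetwork(config, dataset.n_entities, dataset.num.shape[1])


def train(dataset: TripletDataset, plan: SplitPlan, config: ModelConfig,
          net: DSADeepFMNetwork | None = None):
    """Train a network on one split plan; returns (network, history)."""
    if net is None:
        net = build_network(dataset, config)
    tr, va = plan.train_idx, plan.val_idx
    history = fit_network(
        net,
        dataset.cat[tr], dataset.num[tr], dataset.y[tr],
        val=(dataset.cat[va], dataset.num[va], dataset.y[va]) if len(va) else None,
    )
    return net, history


def evaluate(net: DSADeepFMNetwork, dataset: TripletDataset,
             idx: np.ndarray | None = None, threshold: float = 0.5) -> MetricReport:
    """Eight-metric report on (a subset of) a dataset."""
    ds = dataset if idx is None else dataset.subset(idx)
    if len(ds) == 0:
        raise ValueError("empty evaluation set")
    p_syn = net.predict_proba(ds.cat, ds.num)[:, 1]
    return evaluate_predictions(ds.y, p_syn, threshold=threshold)


def resample_ratio(dataset: TripletDataset, plan: SplitPlan,
                   neg_pos_ratio: float, seed: int = 0) -> SplitPlan:
    """Downsample the training partition to a requested neg:pos ratio.

    Validation and test partitions are untouched.  Raises if the ratio is
    not achievable by downsampling either class.
    """
    rng = np.random.default_rng(seed)
    tr = plan.train_idx
    y = dataset.y[tr]
    pos = tr[y == 1]
    neg = tr[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("training partition lacks one of the classes")
    current = len(neg) / len(pos)
    if abs(current - neg_pos_ratio) < 1e-12:
        return plan
    if neg_pos_ratio > current:
        raise ValueError(
            f"ratio 1:{neg_pos_ratio} infeasible: training partition has only "
            f"a 1:{current:.3g} negative surplus (downsampling cannot add negatives)"
        )
    keep_neg = int(round(len(pos) * neg_pos_ratio))
    if keep_neg < 1:
        raise ValueError(f"ratio {neg_pos_ratio} infeasible: would keep 0 negatives")
    neg = rng.choice(neg, size=keep_neg, replace=False)
    new_train = np.sort(np.concatenate([pos, neg]))
    return SplitPlan(plan.regime, plan.fold, plan.seed, new_train,
                     plan.val_idx, plan.test_idx)
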