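"""The ten named ablation variants of the full model.

Each name maps to one combination of architectural switches on ModelConfig;
"full" is the unmodified model.  `run_ablation` trains any subset under
identical splits and seeds for paired comparisons, optionally removing the
prediction-stage attention residual from every model for fairness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .data import TripletDataset
from .model import DSADeepFMNetwork, ModelConfig
from .splits import SplitPlan
from .training import evaluate, train

VARIANT_SWITCHES: dict = {
    "full":         {},
    "cat":          {"use_numerical": False},
    "aux":          {"use_categorical": False},
    "w/o-attn":     {"attention_mode": "none"},
    "w/o-res":      {"residual_mode": "dense3"},
    "attn-rev":     {"attention_mode": "reverse"},
    "attn-field":   {"attention_mode": "field_only"},
    "attn-emb":     {"attention_mode": "emb_only"},
    "attn-unified": {"attention_mode": "unified"},
    "gated-sum":    {"fusion_mode": "gated_sum"},
    "gated-concat": {"fusion_mode": "gated_concat"},
}

VARIANT_NAMES = tuple(VARIANT_SWITCHES)


@dataclass(frozen=True)
class VariantSpec:
    name: str
    use_categorical: bool
    use_numerical: bool
    attention_mode: str
    residual_mode: str
    fusion_mode: str


def variant_spec(name: str, config: ModelConfig) -> VariantSpec:
    cfg = variant_config(name, config)
    return VariantSpec(name, cfg.use_categorical, cfg.use_numerical,
                       cfg.attention_mode, cfg.residual_mode, cfg.fusion_mode)


def variant_config(name: str, config: ModelConfig) -> ModelConfig:
    if name not in VARIANT_SWITCHES:
        raise ValueError(
            f"unknown variant {name!r}; valid names: {', '.join(VARIANT_NAMES)}"
        )
    return replace(config, **VARIANT_SWITCHES[name])


def build_variant(name: str, config: ModelConfig, n_entities: int,
                  num_input_dim: int) -> DSADeepFMNetwork:
    """Instantiate one named variant over the given entity/feature sizes."""
    return DSADeepFMNetwork(variant_config(name, config), n_entities, num_input_dim)


def run_ablation(dataset: TripletDataset, plan: SplitPlan, config: ModelConfig,
                 names=None, exclude_residual: bool = True) -> dict:
    """Train each requested variant on the same split and report test metrics.

    With `exclude_residual=True` (the fair-comparison setting for attention
    ablations) every trained model — including "full" — uses the plain
    three-layer dense prediction head instead of the attention residual.
    Returns {name: MetricReport}.
    """
    names = list(names) if names is not None else list(VARIANT_NAMES)
    results = {}
    for name in names:
        cfg = variant_config(name, config)
        if exclude_residual and name != "w/o-res":
            cfg = replace(cfg, residual_mode="dense3")
        net, _ = train(dataset, plan, cfg)
        results[name] = evaluate(net, dataset, plan.test_idx)
    return results


def ablation_table(results: dict) -> "np.ndarray":
    """Rows (name, eight metrics) for printing; import-light helper."""
    import pandas as pd

    return pd.DataFrame(
        [{"variant": k, **v.to_dict()} for k, v in results.items()]
    )
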