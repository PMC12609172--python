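"""DSA-DeepFM network: dense embedding, numerical feature extraction,
dual-stage attention fusion, factorization machine, hidden DNN, and a
prediction head with an attention-based residual branch.

Every block is an independently callable module so unit tests can probe it
against straight-line oracles.  All math runs on the package's numpy
autodiff core in float64.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml

from .autodiff import Tensor, concat, stack2
from .nn import BatchNorm1d, Dense, Dropout, Embedding, Module, glorot_uniform

ATTENTION_MODES = ("dual", "none", "reverse", "field_only", "emb_only", "unified")
RESIDUAL_MODES = ("dsa", "dense3")
FUSION_MODES = ("concat", "gated_sum", "gated_concat")

# column selectors used to peel the two softmax scores apart
_SEL0 = np.array([[1.0], [0.0]])
_SEL1 = np.array([[0.0], [1.0]])


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters.

    E is the shared embedding width of the three fields (drug 1, drug 2,
    cell line); K is the FM latent dimension and also the width of the FM
    and DNN outputs so the two can be fused directly.
    """

    E: int = 512
    K: int = 1024
    dnn_widths: tuple = (512, 1024)
    hidden_pred: int = 512
    extract_hidden: int | None = None   # None -> 3*E
    dropout: float = 0.5
    lr: float = 1e-3
    lr_decay_rate: float = 0.95
    lr_decay_every: int = 10
    w_pos: float = 1.0                  # class-weighted mode: 2.3
    w_neg: float = 1.0
    seed: int = 0
    batch_size: int = 256
    max_epochs: int = 100
    patience: int = 10
    freeze_embeddings: bool = False
    # ablation switches (the full model uses the defaults)
    use_categorical: bool = True
    use_numerical: bool = True
    attention_mode: str = "dual"
    residual_mode: str = "dsa"
    fusion_mode: str = "concat"
    dense3_widths: tuple = (512, 128)

    def __post_init__(self):
        if tuple(self.dnn_widths)[-1] != self.K:
            raise ValueError(
                f"last DNN width {self.dnn_widths[-1]} must equal the FM "
                f"output dimension K={self.K} so the two outputs can be fused"
            )
        if self.attention_mode not in ATTENTION_MODES:
            raise ValueError(f"attention_mode must be one of {ATTENTION_MODES}")
        if self.residual_mode not in RESIDUAL_MODES:
            raise ValueError(f"residual_mode must be one of {RESIDUAL_MODES}")
        if self.fusion_mode not in FUSION_MODES:
            raise ValueError(f"fusion_mode must be one of {FUSION_MODES}")
        if not self.use_categorical and not self.use_numerical:
            raise ValueError("at least one input stream must be enabled")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")

    @property
    def n_streams(self) -> int:
        return int(self.use_categorical) + int(self.use_numerical)

    @property
    def fused_dim(self) -> int:
        """Dimension of the attention-fused vector x fed to FM and DNN."""
        return 3 * self.E * self.n_streams

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dnn_widths"] = list(self.dnn_widths)
        d["dense3_widths"] = list(self.dense3_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["dnn_widths"] = tuple(d.get("dnn_widths", (512, 1024)))
        d["dense3_widths"] = tuple(d.get("dense3_widths", (512, 128)))
        return cls(**d)


class FieldAttention(Module):
    """Field-aware attention over the two feature streams.

    Each stream is projected into a shared space; per field a softmax over
    the two streams yields scalar scores (s_cat, s_num), and each stream row
    is residually rescaled: x <- x * s + x.
    """

    def __init__(self, rng, E: int):
        super().__init__()
        self.add_param("W_cat", glorot_uniform(rng, E, E))
        self.add_param("b_cat", np.zeros(E))
        self.add_param("W_num", glorot_uniform(rng, E, E))
        self.add_param("b_num", np.zeros(E))
        self.add_param("W_field", glorot_uniform(rng, 2 * E, 2))
        self.add_param("b_field", np.zeros(2))

    def __call__(self, x_cat: Tensor, x_num: Tensor):
        h_cat = x_cat.matmul(self.W_cat) + self.b_cat
        h_num = x_num.matmul(self.W_num) + self.b_num
        scores = (
            concat([h_cat, h_num], axis=-1).matmul(self.W_field) + self.b_field
        ).softmax(axis=-1)                                   # (B, F, 2)
        s_cat = scores.matmul(_SEL0)                          # (B, F, 1)
        s_num = scores.matmul(_SEL1)
        return x_cat * s_cat + x_cat, x_num * s_num + x_num, scores


class EmbeddingAttention(Module):
    """Embedding-dimension-aware attention over the two streams.

    Operates on transposed representations (rows = embedding dimensions,
    columns = fields); scorer parameters are shared across dimensions.
    Inputs are (B, F, E); outputs stay transposed as (B, E, F).
    """

    def __init__(self, rng, n_fields: int):
        super().__init__()
        F = n_fields
        self.add_param("W_cat", glorot_uniform(rng, F, F))
        self.add_param("b_cat", np.zeros(F))
        self.add_param("W_num", glorot_uniform(rng, F, F))
        self.add_param("b_num", np.zeros(F))
        self.add_param("W_emb", glorot_uniform(rng, 2 * F, 2))
        self.add_param("b_emb", np.zeros(2))

    def __call__(self, x_cat: Tensor, x_num: Tensor, transposed: bool = False):
        t_cat = x_cat if transposed else x_cat.swapaxes(1, 2)  # (B, E, F)
        t_num = x_num if transposed else x_num.swapaxes(1, 2)
        h_cat = t_cat.matmul(self.W_cat) + self.b_cat
        h_num = t_num.matmul(self.W_num) + self.b_num
        scores = (
            concat([h_cat, h_num], axis=-1).matmul(self.W_emb) + self.b_emb
        ).softmax(axis=-1)                                    # (B, E, 2)
        s_cat = scores.matmul(_SEL0)
        s_num = scores.matmul(_SEL1)
        return t_cat * s_cat + t_cat, t_num * s_num + t_num, scores


class DSABlock(Module):
    """Dual-stage attention: field-aware then embedding-aware, then the two
    updated streams are transposed back, flattened field-major and
    concatenated into a single vector of length 2 * F * E."""

    def __init__(self, rng, E: int, n_fields: int = 3):
        super().__init__()
        self.E = E
        self.n_fields = n_fields
        self.field_attn = FieldAttention(rng, E)
        self.emb_attn = EmbeddingAttention(rng, n_fields)

    @staticmethod
    def _flatten_field_major(t_stream: Tensor, n_fields: int, E: int) -> Tensor:
        # (B, E, F) -> (B, F, E) -> (B, F*E): each E-block is one field
        b = t_stream.shape[0]
        return t_stream.swapaxes(1, 2).reshape(b, n_fields * E)

    def __call__(self, x_cat: Tensor, x_num: Tensor, return_scores: bool = False):
        f_cat, f_num, s_field = self.field_attn(x_cat, x_num)
        t_cat, t_num, s_emb = self.emb_attn(f_cat, f_num)
        out = concat(
            [
                self._flatten_field_major(t_cat, self.n_fields, self.E),
                self._flatten_field_major(t_num, self.n_fields, self.E),
            ],
            axis=-1,
        )
        if return_scores:
            return out, s_field, s_emb
        return out


class ReverseDSABlock(Module):
    """Ablation: embedding-aware attention first, field-aware second."""

    def __init__(self, rng, E: int, n_fields: int = 3):
        super().__init__()
        self.E = E
        self.n_fields = n_fields
        self.emb_attn = EmbeddingAttention(rng, n_fields)
        self.field_attn = FieldAttention(rng, E)

    def __call__(self, x_cat: Tensor, x_num: Tensor):
        t_cat, t_num, _ = self.emb_attn(x_cat, x_num)
        f_cat, f_num, _ = self.field_attn(t_cat.swapaxes(1, 2), t_num.swapaxes(1, 2))
        b = f_cat.shape[0]
        d = self.n_fields * self.E
        return concat([f_cat.reshape(b, d), f_num.reshape(b, d)], axis=-1)


class UnifiedAttention(Module):
    """Ablation: one sigmoid gate with residual over the concatenated vector."""

    def __init__(self, rng, dim: int):
        super().__init__()
        self.gate = Dense(rng, dim, dim)

    def __call__(self, v: Tensor) -> Tensor:
        return v * self.gate(v).sigmoid() + v


class FMLayer(Module):
    """Factorization machine producing a K-vector.

    y = x W + sum_{i<j} (v_i ⊙ v_j) x_i x_j, computed with the standard
    O(dK) identity 0.5 * [(x V)^2 − (x^2)(V^2)].
    """

    def __init__(self, rng, d_in: int, K: int):
        super().__init__()
        self.add_param("W", glorot_uniform(rng, d_in, K))
        self.add_param("V", glorot_uniform(rng, d_in, K))

    def __call__(self, x: Tensor) -> Tensor:
        first = x.matmul(self.W)
        lin = x.matmul(self.V)
        sq = x.square().matmul(self.V.square())
        return first + (lin.square() - sq) * 0.5


class HiddenDNN(Module):
    """Two dense layers with sigmoid activations (dropout after each)."""

    def __init__(self, rng, d_in: int, widths, dropout: float, drop_rng):
        super().__init__()
        w1, w2 = widths
        self.fc1 = Dense(rng, d_in, w1)
        self.fc2 = Dense(rng, w1, w2)
        self.drop1 = Dropout(dropout, drop_rng)
        self.drop2 = Dropout(dropout, drop_rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.drop1(self.fc1(x).sigmoid())
        return self.drop2(self.fc2(h).sigmoid())


class GatedFusion(Module):
    """Per-dimension softmax weights over the stacked FM/DNN outputs."""

    def __init__(self, rng, mode: str):
        super().__init__()
        self.mode = mode
        self.add_param("W_gate", glorot_uniform(rng, 2, 2))
        self.add_param("b_gate", np.zeros(2))

    def __call__(self, y_fm: Tensor, y_dnn: Tensor):
        stacked = stack2(y_fm, y_dnn, axis=2)                 # (B, K, 2)
        s = (stacked.matmul(self.W_gate) + self.b_gate).softmax(axis=-1)
        fm_w = y_fm * s.matmul(_SEL0).reshape(*y_fm.shape)
        dnn_w = y_dnn * s.matmul(_SEL1).reshape(*y_dnn.shape)
        if self.mode == "gated_sum":
            return fm_w + dnn_w, s
        return concat([fm_w, dnn_w], axis=-1), s


class PredictionHead(Module):
    """Fuses FM and DNN outputs and produces class probabilities.

    Both branch outputs are batch-normalized, fused (concatenation by
    default), projected back to the width of the attention output x, and —
    in the full model — combined with x through a second, independent
    dual-stage attention acting on the natural E-wide blocks of both
    vectors.  Two dense layers with sigmoid activations and a final softmax
    yield (p_antagonistic, p_synergistic).
    """

    def __init__(self, rng, config: ModelConfig, drop_rng):
        super().__init__()
        cfg = config
        E, K, D = cfg.E, cfg.K, cfg.fused_dim
        self.E, self.D = E, D
        self.n_blocks = D // E
        self.bn_fm = BatchNorm1d(K)
        self.bn_dnn = BatchNorm1d(K)
        self.fusion_mode = cfg.fusion_mode
        if cfg.fusion_mode == "concat":
            fused = 2 * K
        else:
            self.gate = GatedFusion(rng, cfg.fusion_mode)
            fused = K if cfg.fusion_mode == "gated_sum" else 2 * K
        self.proj = Dense(rng, fused, D)
        self.drop = Dropout(cfg.dropout, drop_rng)
        self.residual_mode = cfg.residual_mode
        if cfg.residual_mode == "dsa":
            self.res_attn = DSABlock(rng, E, n_fields=self.n_blocks)
            self.fc2 = Dense(rng, 2 * D, cfg.hidden_pred)
            self.fc3 = Dense(rng, cfg.hidden_pred, 2)
        else:
            wa, wb = cfg.dense3_widths
            self.fc1d = Dense(rng, 2 * D, wa)
            self.fc2d = Dense(rng, wa, wb)
            self.fc3d = Dense(rng, wb, 2)

    def __call__(self, y_fm: Tensor, y_dnn: Tensor, x_dsa: Tensor,
                 return_internals: bool = False):
        fm_n = self.bn_fm(y_fm)
        dnn_n = self.bn_dnn(y_dnn)
        if self.fusion_mode == "concat":
            fused = concat([fm_n, dnn_n], axis=-1)            # x~(0)
        else:
            fused, _ = self.gate(fm_n, dnn_n)
        xt1 = self.drop(self.proj(fused).sigmoid())           # x~(1), length D
        b = xt1.shape[0]
        if self.residual_mode == "dsa":
            blocks1 = x_dsa.reshape(b, self.n_blocks, self.E)
            blocks2 = xt1.reshape(b, self.n_blocks, self.E)
            x_attn = self.res_attn(blocks1, blocks2)          # (B, 2D)
            h = self.fc2(x_attn).sigmoid()
            logits = self.fc3(h).sigmoid()
        else:
            x_attn = concat([x_dsa, xt1], axis=-1)
            h = self.fc2d(self.fc1d(x_attn).sigmoid()).sigmoid()
            logits = self.fc3d(h)
        probs = logits.softmax(axis=-1)
        if return_internals:
            return probs, {"xt1": xt1, "pre_prediction": x_attn}
        return probs


class DSADeepFMNetwork(Module):
    """The assembled network over one shared entity index space.

    `n_entities` = m drugs + n cell lines; `num_input_dim` = 2 * m_ref + g
    (two Tanimoto profiles plus an expression vector).
    """

    def __init__(self, config: ModelConfig, n_entities: int, num_input_dim: int):
        super().__init__()
        cfg = config
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        self.drop_rng = np.random.default_rng(rng.integers(0, 2**31))
        E = cfg.E
        if cfg.use_categorical:
            self.embedding = Embedding(
                rng, n_entities, E, trainable=not cfg.freeze_embeddings
            )
            self._buffers = {"initial_embedding": self.embedding.table.data.copy()}
        if cfg.use_numerical:
            hidden = cfg.extract_hidden or 3 * E
            self.extract1 = Dense(rng, num_input_dim, hidden)
            self.extract2 = Dense(rng, hidden, 3 * E)
        if cfg.n_streams == 2:
            if cfg.attention_mode == "dual":
                self.dsa = DSABlock(rng, E, n_fields=3)
            elif cfg.attention_mode == "reverse":
                self.dsa = ReverseDSABlock(rng, E, n_fields=3)
            elif cfg.attention_mode == "field_only":
                self.field_attn = FieldAttention(rng, E)
            elif cfg.attention_mode == "emb_only":
                self.emb_attn = EmbeddingAttention(rng, 3)
            elif cfg.attention_mode == "unified":
                self.unified = UnifiedAttention(rng, 6 * E)
        D = cfg.fused_dim
        self.fm = FMLayer(rng, D, cfg.K)
        self.dnn = HiddenDNN(rng, D, cfg.dnn_widths, cfg.dropout, self.drop_rng)
        self.head = PredictionHead(rng, cfg, self.drop_rng)
        self.n_entities = n_entities
        self.num_input_dim = num_input_dim

    # -- stage computations ----------------------------------------------------
    def embed_categorical(self, cat_idx: np.ndarray) -> Tensor:
        """(B, 3) entity indices -> (B, 3, E) embedding rows."""
        return self.embedding(cat_idx)

    def extract_numerical(self, num: np.ndarray) -> Tensor:
        """(B, 2*m_ref + g) -> (B, 3, E) via a two-layer extractor."""
        num = np.asarray(num, dtype=np.float64)
        if num.shape[-1] != self.num_input_dim:
            raise ValueError(
                f"numerical input has {num.shape[-1]} features, "
                f"expected {self.num_input_dim}"
            )
        h = self.extract2(self.extract1(Tensor(num)).relu())
        return h.reshape(num.shape[0], 3, self.config.E)

    def encode(self, cat_idx, num) -> dict:
        """Run the input and attention stages; returns all intermediates."""
        cfg = self.config
        out: dict = {}
        b = len(cat_idx)
        E = cfg.E
        if cfg.use_categorical:
            x_cat = self.embed_categorical(cat_idx)
            out["embedding"] = x_cat
        if cfg.use_numerical:
            x_num = self.extract_numerical(num)
            out["aux_extracted"] = x_num
        if cfg.n_streams == 1:
            stream = x_cat if cfg.use_categorical else x_num
            out["x"] = stream.reshape(b, 3 * E)
            return out
        if cfg.attention_mode in ("dual", "reverse"):
            out["x"] = self.dsa(x_cat, x_num)
        elif cfg.attention_mode == "field_only":
            f_cat, f_num, _ = self.field_attn(x_cat, x_num)
            out["x"] = concat(
                [f_cat.reshape(b, 3 * E), f_num.reshape(b, 3 * E)], axis=-1
            )
        elif cfg.attention_mode == "emb_only":
            t_cat, t_num, _ = self.emb_attn(x_cat, x_num)
            out["x"] = concat(
                [
                    DSABlock._flatten_field_major(t_cat, 3, E),
                    DSABlock._flatten_field_major(t_num, 3, E),
                ],
                axis=-1,
            )
        else:  # none / unified: plain concatenation of the flattened streams
            v = concat([x_cat.reshape(b, 3 * E), x_num.reshape(b, 3 * E)], axis=-1)
            out["x"] = self.unified(v) if cfg.attention_mode == "unified" else v
        return out

    def forward(self, cat_idx, num, return_internals: bool = False):
        """Full forward pass; returns (B, 2) probabilities (and internals)."""
        enc = self.encode(cat_idx, num)
        x = enc["x"]
        y_fm = self.fm(x)
        y_dnn = self.dnn(x)
        probs, internals = self.head(y_fm, y_dnn, x, return_internals=True)
        if return_internals:
            internals.update(enc)
            internals["y_fm"] = y_fm
            internals["y_dnn"] = y_dnn
            return probs, internals
        return probs

    def predict_proba(self, cat_idx, num, batch_size: int = 4096) -> np.ndarray:
        """Eval-mode synergy probabilities, deterministic across calls."""
        was_training = self.training
        self.set_training(False)
        chunks = []
        for start in range(0, len(cat_idx), batch_size):
            sl = slice(start, start + batch_size)
            chunks.append(self.forward(cat_idx[sl], num[sl]).data)
        if was_training:
            self.set_training(True)
        return np.vstack(chunks)

    # -- persistence -------------------------------------------------------------
    def save(self, path):
        state = self.named_state()
        state["__config__"] = np.frombuffer(
            yaml.safe_dump(self.config.to_dict()).encode(), dtype=np.uint8
        )
        state["__dims__"] = np.array([self.n_entities, self.num_input_dim])
        np.savez(path, **state)

    @classmethod
    def load(cls, path) -> "DSADeepFMNetwork":
        z = np.load(path)
        cfg = ModelConfig.from_dict(yaml.safe_load(bytes(z["__config__"]).decode()))
        n_entities, num_dim = (int(v) for v in z["__dims__"])
        net = cls(cfg, n_entities, num_dim)
        net.load_state({k: z[k] for k in z.files if not k.startswith("__")})
        return net


def expected_parameter_count(cfg: ModelConfig, n_entities: int, num_dim: int) -> int:
    """Closed-form parameter count of the full network (shape-drift guard)."""
    E, K, D = cfg.E, cfg.K, cfg.fused_dim
    total = 0
    if cfg.use_categorical:
        total += n_entities * E
    if cfg.use_numerical:
        hidden = cfg.extract_hidden or 3 * E
        total += (num_dim * hidden + hidden) + (hidden * 3 * E + 3 * E)

    def field_attn():
        return 2 * (E * E + E) + (2 * E * 2 + 2)

    def emb_attn(F):
        return 2 * (F * F + F) + (2 * F * 2 + 2)

    if cfg.n_streams == 2:
        if cfg.attention_mode in ("dual", "reverse"):
            total += field_attn() + emb_attn(3)
        elif cfg.attention_mode == "field_only":
            total += field_attn()
        elif cfg.attention_mode == "emb_only":
            total += emb_attn(3)
        elif cfg.attention_mode == "unified":
            total += 6 * E * 6 * E + 6 * E
    total += 2 * D * K                            # FM: W and V
    w1, w2 = cfg.dnn_widths
    total += (D * w1 + w1) + (w1 * w2 + w2)       # hidden DNN
    total += 2 * 2 * K                            # two batch norms
    fused = 2 * K if cfg.fusion_mode != "gated_sum" else K
    if cfg.fusion_mode != "concat":
        total += 2 * 2 + 2                        # gate
    total += fused * D + D                        # projection W(1)
    if cfg.residual_mode == "dsa":
        F = D // E
        total += field_attn() + emb_attn(F)
        total += (2 * D * cfg.hidden_pred + cfg.hidden_pred) + (cfg.hidden_pred * 2 + 2)
    else:
        wa, wb = cfg.dense3_widths
        total += (2 * D * wa + wa) + (wa * wb + wb) + (wb * 2 + 2)
    return total
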