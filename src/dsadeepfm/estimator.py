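"""scikit-learn style estimator wrapping the DSA-DeepFM network.

The design matrix convention is: the first three columns are integer entity
indices (drug 1, drug 2, cell line, in one shared index space of size
m + n), the remaining columns are the numerical features (two Tanimoto
profiles followed by the expression vector).  `TripletDataset.X` produces
exactly this layout.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .data import TripletDataset
from .model import DSADeepFMNetwork, ModelConfig
from .training import fit_network

_CONFIG_FIELDS = [
    "E", "K", "dnn_widths", "hidden_pred", "extract_hidden", "dropout", "lr",
    "lr_decay_rate", "lr_decay_every", "w_pos", "w_neg", "seed", "batch_size",
    "max_epochs", "patience", "freeze_embeddings", "use_categorical",
    "use_numerical", "attention_mode", "residual_mode", "fusion_mode",
    "dense3_widths",
]


class DSADeepFMClassifier(BaseEstimator, ClassifierMixin):
    """Binary classifier for synergistic drug-pair / cell-line triplets.

    Parameters mirror ModelConfig; `n_entities` fixes the embedding-table
    size (inferred from the data when None, which is only safe if every
    entity occurs in the training design matrix).

    Attributes set by fit: `network_`, `history_`, `classes_`,
    `n_features_in_`, `config_`.
    """

    def __init__(self, E=32, K=64, dnn_widths=(48, 64), hidden_pred=64,
                 extract_hidden=None, dropout=0.1, lr=1e-3,
                 lr_decay_rate=0.95, lr_decay_every=10, w_pos=1.0, w_neg=1.0,
                 seed=0, batch_size=256, max_epochs=100, patience=10,
                 freeze_embeddings=False, use_categorical=True,
                 use_numerical=True, attention_mode="dual",
                 residual_mode="dsa", fusion_mode="concat",
                 dense3_widths=(512, 128), n_entities=None,
                 validation_fraction=0.1):
        self.E = E
        self.K = K
        self.dnn_widths = dnn_widths
        self.hidden_pred = hidden_pred
        self.extract_hidden = extract_hidden
        self.dropout = dropout
        self.lr = lr
        self.lr_decay_rate = lr_decay_rate
        self.lr_decay_every = lr_decay_every
        self.w_pos = w_pos
        self.w_neg = w_neg
        self.seed = seed
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.freeze_embeddings = freeze_embeddings
        self.use_categorical = use_categorical
        self.use_numerical = use_numerical
        self.attention_mode = attention_mode
        self.residual_mode = residual_mode
        self.fusion_mode = fusion_mode
        self.dense3_widths = dense3_widths
        self.n_entities = n_entities
        self.validation_fraction = validation_fraction

    # -- helpers ---------------------------------------------------------------
    def _config(self) -> ModelConfig:
        return ModelConfig(**{f: getattr(self, f) for f in _CONFIG_FIELDS})

    @staticmethod
    def _split_X(X):
        if isinstance(X, TripletDataset):
            return X.cat, X.num
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] < 4:
            raise ValueError(
                "X must be 2-D with 3 index columns plus numerical features"
            )
        return X[:, :3].astype(np.int64), X[:, 3:]

    # -- sklearn API -------------------------------------------------------------
    def fit(self, X, y=None, X_val=None, y_val=None):
        if isinstance(X, TripletDataset) and y is None:
            y = X.y
        cat, num = self._split_X(X)
        y = np.asarray(y).astype(int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary {0, 1}")
        cfg = self._config()
        n_entities = self.n_entities
        if n_entities is None:
            n_entities = int(cat.max()) + 1
        self.config_ = cfg
        self.network_ = DSADeepFMNetwork(cfg, n_entities, num.shape[1])

        if X_val is not None:
            vc, vn = self._split_X(X_val)
            val = (vc, vn, np.asarray(y_val).astype(int))
        elif self.validation_fraction and len(y) >= 20:
            rng = np.random.default_rng(cfg.seed + 17)
            perm = rng.permutation(len(y))
            n_val = max(1, int(round(self.validation_fraction * len(y))))
            vi, ti = perm[:n_val], perm[n_val:]
            val = (cat[vi], num[vi], y[vi])
            cat, num, y = cat[ti], num[ti], y[ti]
        else:
            val = None
        self.history_ = fit_network(self.network_, cat, num, y, val=val)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 3 + num.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        cat, num = self._split_X(X)
        return self.network_.predict_proba(cat, num)

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= threshold).astype(int)

    def save(self, path):
        check_is_fitted(self, "network_")
        self.network_.save(path)

    @classmethod
    def from_network(cls, net: DSADeepFMNetwork) -> "DSADeepFMClassifier":
        clf = cls(**{f: getattr(net.config, f) for f in _CONFIG_FIELDS})
        clf.network_ = net
        clf.config_ = net.config
        clf.classes_ = np.array([0, 1])
        clf.n_features_in_ = 3 + net.num_input_dim
        return clf

    @classmethod
    def load(cls, path) -> "DSADeepFMClassifier":
        return cls.from_network(DSADeepFMNetwork.load(path))
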