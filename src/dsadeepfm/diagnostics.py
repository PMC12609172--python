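"""Representation diagnostics and candidate-pair discovery.

Covers: extraction of per-triplet vectors at six named model stages,
class-separation statistics under cosine geometry, drug-order consistency
of predictions, an audit of performance by entity training frequency, and
ranking of unseen drug pairs per cell line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import TripletDataset
from .metrics import auc_roc
from .model import DSADeepFMNetwork
from .splits import SplitPlan

STAGES = (
    "embedding_init", "embedding_trained", "aux_raw",
    "aux_extracted", "dsa_fused", "pre_prediction",
)


@dataclass
class StageRepresentation:
    stage: str
    matrix: np.ndarray   # (n_triplets, dims)
    labels: np.ndarray


@dataclass
class SeparationStats:
    intra: float
    inter: float
    margin: float
    ratio: float
    space: str = "original"
    degenerate: bool = False


def _as_network(model) -> DSADeepFMNetwork:
    return model.network_ if hasattr(model, "network_") else model


def extract_stage(model, dataset: TripletDataset, stage: str,
                  idx=None) -> StageRepresentation:
    """Deterministic (eval-mode) per-triplet vectors at a named boundary.

    embedding_init uses the snapshot of the embedding table taken at
    construction time; aux_raw is the numerical input verbatim.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; valid stages: {STAGES}")
    net = _as_network(model)
    ds = dataset if idx is None else dataset.subset(np.asarray(idx))
    labels = ds.y.copy()
    b = len(ds)
    if stage == "aux_raw":
        return StageRepresentation(stage, ds.num.copy(), labels)
    if stage == "embedding_init":
        table = net._buffers["initial_embedding"]
        mat = table[ds.cat].reshape(b, -1)
        return StageRepresentation(stage, mat, labels)
    was_training = net.training
    net.set_training(False)
    if stage == "embedding_trained":
        mat = net.embed_categorical(ds.cat).data.reshape(b, -1)
    elif stage == "aux_extracted":
        mat = net.extract_numerical(ds.num).data.reshape(b, -1)
    else:
        _, internals = net.forward(ds.cat, ds.num, return_internals=True)
        key = "x" if stage == "dsa_fused" else "pre_prediction"
        mat = internals[key].data
    if was_training:
        net.set_training(True)
    return StageRepresentation(stage, np.asarray(mat), labels)


def _normalize_rows(mat: np.ndarray) -> np.ndarray:
    # z-score per dimension (population SD, constant dims -> 0), then L2
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0)
    z = np.zeros_like(mat, dtype=np.float64)
    nz = sd > 0
    z[:, nz] = (mat[:, nz] - mean[nz]) / sd[nz]
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return z / norms


def separation_stats(rep: StageRepresentation, space: str = "original") -> SeparationStats:
    """Cosine-geometry class separation of a labeled representation.

    Rows are z-scored per dimension and L2-normalized.  intra = mean pairwise
    cosine distance within each class, averaged over the two classes;
    inter = cosine distance between the re-normalized class centroids;
    margin = inter - intra; ratio = intra / inter (degenerate when inter=0).
    """
    y = np.asarray(rep.labels).astype(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("separation statistics need both classes present")
    x = _normalize_rows(np.asarray(rep.matrix, dtype=np.float64))
    intra_vals = []
    centroids = []
    for c in classes:
        rows = x[y == c]
        if len(rows) < 2:
            raise ValueError(f"class {c} has fewer than 2 rows")
        gram = rows @ rows.T
        n = len(rows)
        iu = np.triu_indices(n, k=1)
        intra_vals.append(float(np.mean(1.0 - gram[iu])))
        centroid = rows.mean(axis=0)
        nrm = np.linalg.norm(centroid)
        centroids.append(centroid / nrm if nrm > 0 else centroid)
    intra = float(np.mean(intra_vals))
    inter = float(1.0 - centroids[0] @ centroids[1])
    degenerate = inter <= 1e-12
    ratio = float("nan") if degenerate else intra / inter
    return SeparationStats(intra=intra, inter=inter, margin=inter - intra,
                           ratio=ratio, space=space, degenerate=degenerate)


def tsne_project(matrix: np.ndarray, seed: int = 0, perplexity: float = 30.0):
    """2-D t-SNE projection (visualization plumbing, not a tested contract)."""
    from sklearn.manifold import TSNE

    perplexity = min(perplexity, (len(matrix) - 1) / 3.0)
    return TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca"
    ).fit_transform(np.asarray(matrix, dtype=np.float64))


def order_consistency(model, dataset: TripletDataset, idx=None) -> dict:
    """Predictions for both drug orderings of every triplet.

    Returns {"p_ab", "p_ba", "pearson", "constant"}; the correlation is
    flagged undefined when either ordering produces constant output.
    """
    net = _as_network(model)
    ds = dataset if idx is None else dataset.subset(np.asarray(idx))
    p_ab = net.predict_proba(ds.cat, ds.num)[:, 1]
    swapped_cat = ds.cat[:, [1, 0, 2]]
    m_ref = ds.num_sizes[0]
    swapped_num = np.concatenate(
        [ds.num[:, m_ref: 2 * m_ref], ds.num[:, :m_ref], ds.num[:, 2 * m_ref:]],
        axis=1,
    )
    p_ba = net.predict_proba(swapped_cat, swapped_num)[:, 1]
    constant = np.std(p_ab) == 0 or np.std(p_ba) == 0
    pearson = float("nan") if constant else float(np.corrcoef(p_ab, p_ba)[0, 1])
    return {"p_ab": p_ab, "p_ba": p_ba, "pearson": pearson, "constant": constant}


def frequency_quartile_audit(model, dataset: TripletDataset,
                             plan: SplitPlan) -> list:
    """Split the test set by minimum training frequency of its entities.

    Returns one dict per quartile with AUC-ROC (NaN when one-class) and the
    positive-class proportion.  Quartile sizes differ by at most one; ties
    in frequency are broken by stable triplet order.
    """
    if len(plan.test_idx) < 4:
        raise ValueError("need at least 4 test triplets for quartiles")
    net = _as_network(model)
    counts = np.bincount(
        dataset.cat[plan.train_idx].ravel(), minlength=dataset.n_entities
    )
    test = dataset.subset(plan.test_idx)
    min_freq = counts[test.cat].min(axis=1)
    order = np.argsort(min_freq, kind="stable")
    quartiles = np.array_split(order, 4)
    p_syn = net.predict_proba(test.cat, test.num)[:, 1]
    out = []
    for q, qidx in enumerate(quartiles):
        yq = test.y[qidx]
        auc = auc_roc(yq, p_syn[qidx]) if len(np.unique(yq)) > 1 else float("nan")
        out.append({
            "quartile": q,
            "n": int(len(qidx)),
            "auc_roc": auc,
            "positive_proportion": float(np.mean(yq == 1)),
            "min_frequency_range": (int(min_freq[qidx].min()),
                                    int(min_freq[qidx].max())),
        })
    return out


def discover(model, dataset: TripletDataset, cell_line_id: str,
             drug_panel=None, exclude=None, cutoff: float = 0.6,
             top_k: int | None = None) -> list:
    """Rank unseen unordered drug pairs on one cell line.

    Scores every candidate pair with the mean prediction over both drug
    orderings; returns dicts (drug1, drug2, score_ab, score_ba, score_mean)
    with score_mean >= cutoff, sorted descending, truncated to top_k.
    """
    net = _as_network(model)
    panel = sorted(drug_panel) if drug_panel is not None else list(dataset.drug_ids)
    if len(panel) < 2:
        raise ValueError("drug panel must contain at least 2 drugs")
    exclude = {frozenset(p) for p in (exclude or [])}
    candidates = [
        (a, b)
        for i, a in enumerate(panel)
        for b in panel[i + 1:]
        if frozenset((a, b)) not in exclude
    ]
    if not candidates:
        import warnings

        warnings.warn("no candidate pairs remain after exclusions")
        return []
    cats, nums = [], []
    for a, b in candidates:
        cat, num = dataset.features_for(a, b, cell_line_id)
        cats.append(cat)
        nums.append(num)
    cat = np.stack(cats)
    num = np.stack(nums)
    p_ab = net.predict_proba(cat, num)[:, 1]
    m_ref = dataset.num_sizes[0]
    num_swapped = np.concatenate(
        [num[:, m_ref: 2 * m_ref], num[:, :m_ref], num[:, 2 * m_ref:]], axis=1
    )
    p_ba = net.predict_proba(cat[:, [1, 0, 2]], num_swapped)[:, 1]
    mean = 0.5 * (p_ab + p_ba)
    rows = [
        {"drug1": a, "drug2": b, "score_ab": float(pa), "score_ba": float(pb),
         "score_mean": float(pm)}
        for (a, b), pa, pb, pm in zip(candidates, p_ab, p_ba, mean)
        if pm >= cutoff
    ]
    rows.sort(key=lambda r: (-r["score_mean"], r["drug1"], r["drug2"]))
    return rows[:top_k] if top_k is not None else rows
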