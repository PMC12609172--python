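"""Input tables, labeling rules and featurization for drug-combination triplets.

A triplet is (drug 1, drug 2, cell line).  Drugs are featurized as 1024-bit
ECFP6 (Morgan, radius 3) fingerprints and, numerically, as the vector of
Tanimoto similarities against a fixed reference panel of drugs.  Cell lines
carry a z-scored gene-expression vector.  Replicated synergy measurements
are thresholded (score > 30 synergistic, score < 0 antagonistic, the band
in between discarded) and resolved per unordered triplet by majority vote.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
EXCLUDED = "excluded"

FINGERPRINT_BITS = 1024
MORGAN_RADIUS = 3  # ECFP6 = diameter 6

SYNERGY_UPPER = 30.0  # scores strictly above -> synergistic
SYNERGY_LOWER = 0.0   # scores strictly below -> antagonistic


class InvalidMoleculeError(ValueError):
    pass


_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(
    radius=MORGAN_RADIUS, fpSize=FINGERPRINT_BITS
)


def compute_fingerprint(smiles: str, drug_id: str | None = None) -> np.ndarray:
    """ECFP6 fingerprint (1024 bits) of a SMILES string.

    Raises InvalidMoleculeError for unparseable input, naming the drug.
    """
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None:
        who = f" (drug {drug_id!r})" if drug_id else ""
        raise InvalidMoleculeError(f"unparseable SMILES {smiles!r}{who}")
    return _FP_GEN.GetFingerprintAsNumPy(mol).astype(np.uint8)


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| of two equal-length bit vectors.

    Two all-zero fingerprints are defined to have similarity 0.
    """
    fp_a = np.asarray(fp_a)
    fp_b = np.asarray(fp_b)
    if fp_a.shape != fp_b.shape:
        raise ValueError(
            f"fingerprint length mismatch: {fp_a.shape} vs {fp_b.shape}"
        )
    inter = int(np.sum((fp_a != 0) & (fp_b != 0)))
    union = int(np.sum((fp_a != 0) | (fp_b != 0)))
    return inter / union if union else 0.0


def tanimoto_profile(fp: np.ndarray, panel_fps: np.ndarray) -> np.ndarray:
    """Vector of Tanimoto similarities of `fp` against each panel fingerprint.

    The panel ordering is fixed per dataset so all profiles are comparable;
    a drug that is itself in the panel has a 1.0 at its own position.
    """
    panel_fps = np.atleast_2d(np.asarray(panel_fps))
    if panel_fps.shape[0] == 0:
        raise ValueError("reference panel must be nonempty")
    a = np.asarray(fp) != 0
    b = panel_fps != 0
    inter = (b & a).sum(axis=1)
    union = (b | a).sum(axis=1)
    out = np.zeros(len(panel_fps))
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    return out


def zscore_normalize(matrix, row_names=None, col_names=None) -> np.ndarray:
    """Per-gene (column) z-score with population SD; constant columns map to 0."""
    x = np.asarray(matrix, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("expression matrix must be 2-D with at least 2 rows")
    if not np.all(np.isfinite(x)):
        r, c = np.argwhere(~np.isfinite(x))[0]
        rn = row_names[r] if row_names is not None else r
        cn = col_names[c] if col_names is not None else c
        raise ValueError(f"non-finite expression value at cell line {rn}, gene {cn}")
    mean = x.mean(axis=0)
    sd = x.std(axis=0)  # population SD
    out = np.zeros_like(x)
    nz = sd > 0
    out[:, nz] = (x[:, nz] - mean[nz]) / sd[nz]
    return out


def label_by_threshold(score: float) -> str:
    """Threshold a synergy score: >30 positive, <0 negative, [0, 30] excluded."""
    if not np.isfinite(score):
        raise ValueError(f"non-finite synergy score: {score!r}")
    if score > SYNERGY_UPPER:
        return POSITIVE
    if score < SYNERGY_LOWER:
        return NEGATIVE
    return EXCLUDED


def majority_vote(labels) -> str:
    """Strict-majority label of a multiset of positive/negative votes; tie -> excluded."""
    labels = list(labels)
    if not labels:
        raise ValueError("majority_vote requires at least one vote")
    pos = sum(1 for l in labels if l == POSITIVE)
    neg = sum(1 for l in labels if l == NEGATIVE)
    if pos > neg:
        return POSITIVE
    if neg > pos:
        return NEGATIVE
    return EXCLUDED


@dataclass
class TripletDataset:
    """Model-ready dataset: categorical indices, numerical features, labels.

    Index convention: drugs occupy [0, m), cell lines [m, m+n) in one shared
    entity index space (so a single embedding table serves both).
    """

    cat: np.ndarray                 # (N, 3) int64: drug1, drug2, cell entity indices
    num: np.ndarray                 # (N, 2*m_ref + g) float64
    y: np.ndarray                   # (N,) int8 labels, 1 = synergistic
    drug_ids: list
    cell_ids: list
    num_sizes: tuple                # (m_ref, m_ref, g)
    drug_profiles: np.ndarray       # (m, m_ref) Tanimoto profile per drug
    cell_expr: np.ndarray           # (n, g) z-scored expression per cell line
    tissues: dict = field(default_factory=dict)  # cell_line_id -> tissue
    pair_keys: np.ndarray | None = None          # (N,) canonical "d1|d2|c" strings

    def __post_init__(self):
        if self.pair_keys is None:
            self.pair_keys = self.make_pair_keys(self.cat)

    @staticmethod
    def make_pair_keys(cat: np.ndarray) -> np.ndarray:
        lo = np.minimum(cat[:, 0], cat[:, 1])
        hi = np.maximum(cat[:, 0], cat[:, 1])
        return np.array([f"{a}|{b}|{c}" for a, b, c in zip(lo, hi, cat[:, 2])])

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_cell_lines(self) -> int:
        return len(self.cell_ids)

    @property
    def n_entities(self) -> int:
        return self.n_drugs + self.n_cell_lines

    def __len__(self):
        return len(self.y)

    @property
    def X(self) -> np.ndarray:
        """Flat design matrix [cat indices | numerical features] for estimators."""
        return np.hstack([self.cat.astype(np.float64), self.num])

    def subset(self, idx) -> "TripletDataset":
        idx = np.asarray(idx)
        return TripletDataset(
            cat=self.cat[idx], num=self.num[idx], y=self.y[idx],
            drug_ids=self.drug_ids, cell_ids=self.cell_ids,
            num_sizes=self.num_sizes, drug_profiles=self.drug_profiles,
            cell_expr=self.cell_expr, tissues=self.tissues,
            pair_keys=self.pair_keys[idx],
        )

    def features_for(self, drug1_id, drug2_id, cell_id):
        """(cat, num) rows for an arbitrary triplet of known entities."""
        d1 = self.drug_ids.index(drug1_id)
        d2 = self.drug_ids.index(drug2_id)
        c = self.cell_ids.index(cell_id)
        cat = np.array([d1, d2, self.n_drugs + c], dtype=np.int64)
        num = np.concatenate(
            [self.drug_profiles[d1], self.drug_profiles[d2], self.cell_expr[c]]
        )
        return cat, num

    def class_counts(self) -> tuple:
        pos = int((self.y == 1).sum())
        return pos, int(len(self.y) - pos)

    def save(self, path):
        meta = {
            "drug_ids": list(map(str, self.drug_ids)),
            "cell_ids": list(map(str, self.cell_ids)),
            "num_sizes": list(self.num_sizes),
            "tissues": {str(k): str(v) for k, v in self.tissues.items()},
        }
        np.savez_compressed(
            path, cat=self.cat, num=self.num, y=self.y,
            drug_profiles=self.drug_profiles, cell_expr=self.cell_expr,
            pair_keys=self.pair_keys.astype("U"), meta=json.dumps(meta),
        )

    @classmethod
    def load(cls, path) -> "TripletDataset":
        z = np.load(path, allow_pickle=False)
        meta = json.loads(str(z["meta"]))
        return cls(
            cat=z["cat"], num=z["num"], y=z["y"],
            drug_ids=meta["drug_ids"], cell_ids=meta["cell_ids"],
            num_sizes=tuple(meta["num_sizes"]),
            drug_profiles=z["drug_profiles"], cell_expr=z["cell_expr"],
            tissues=meta["tissues"], pair_keys=z["pair_keys"],
        )


def label_triplets(records: pd.DataFrame) -> pd.DataFrame:
    """Threshold each measurement, then majority-vote per unordered triplet.

    `records` needs columns drug1_id, drug2_id, cell_line_id, synergy_score.
    Returns one row per surviving triplet with columns drug1_id (lexicographically
    smaller), drug2_id, cell_line_id, label (0/1).
    """
    rec = records.copy()
    if (rec["drug1_id"] == rec["drug2_id"]).any():
        raise ValueError("synergy record with identical drug1 and drug2")
    rec["vote"] = [label_by_threshold(s) for s in rec["synergy_score"]]
    rec = rec[rec["vote"] != EXCLUDED]  # mid-band scores removed before voting
    pair = rec[["drug1_id", "drug2_id"]].astype(str)
    rec = rec.assign(drug1_id=pair.min(axis=1), drug2_id=pair.max(axis=1))
    rows = []
    for (d1, d2, c), grp in rec.groupby(["drug1_id", "drug2_id", "cell_line_id"]):
        verdict = majority_vote(grp["vote"])
        if verdict == EXCLUDED:
            continue
        rows.append((d1, d2, c, 1 if verdict == POSITIVE else 0))
    return pd.DataFrame(rows, columns=["drug1_id", "drug2_id", "cell_line_id", "label"])


def build_dataset(
    drugs: pd.DataFrame,
    expression: pd.DataFrame,
    synergy: pd.DataFrame,
    tissues: dict | None = None,
    augment_order: bool = False,
    gene_subset: list | None = None,
    reference_panel: list | None = None,
    fingerprints: dict | None = None,
) -> TripletDataset:
    """Assemble a labeled, featurized triplet dataset from raw tables.

    drugs: columns (drug_id, smiles); expression: cell lines x genes (index =
    cell line ids); synergy: measurement records.  Drugs with unparseable
    SMILES and records referencing unknown entities are dropped with logged
    counts.  `reference_panel` restricts the Tanimoto profile panel (for
    leave-drug-out experiments); default is every retained drug.
    `fingerprints` may supply precomputed drug_id -> bit-vector mappings,
    bypassing SMILES parsing.
    """
    fps = {}
    n_bad = 0
    for _, row in drugs.iterrows():
        did = row["drug_id"]
        if fingerprints is not None and did in fingerprints:
            fps[did] = np.asarray(fingerprints[did], dtype=np.uint8)
            continue
        try:
            fps[did] = compute_fingerprint(row.get("smiles"), drug_id=did)
        except InvalidMoleculeError as exc:
            logger.warning("dropping drug: %s", exc)
            n_bad += 1
    if n_bad:
        logger.warning("dropped %d drugs with invalid SMILES", n_bad)

    if gene_subset is not None:
        expression = expression.loc[:, [g for g in gene_subset if g in expression.columns]]

    labeled = label_triplets(synergy)
    known_drugs = set(fps)
    known_cells = set(expression.index)
    keep = (
        labeled["drug1_id"].isin(known_drugs)
        & labeled["drug2_id"].isin(known_drugs)
        & labeled["cell_line_id"].isin(known_cells)
    )
    if (~keep).any():
        logger.warning("dropped %d triplets with unresolved drugs/cell lines",
                       int((~keep).sum()))
    labeled = labeled[keep]
    if labeled.empty:
        raise ValueError("no labeled triplets survive thresholding/voting")

    used_drugs = sorted(set(labeled["drug1_id"]) | set(labeled["drug2_id"]))
    used_cells = sorted(set(labeled["cell_line_id"]))
    m = len(used_drugs)
    drug_idx = {d: i for i, d in enumerate(used_drugs)}
    cell_idx = {c: m + i for i, c in enumerate(used_cells)}

    panel_ids = list(reference_panel) if reference_panel is not None else used_drugs
    panel_fps = np.stack([fps[d] for d in panel_ids])
    profiles = np.stack([tanimoto_profile(fps[d], panel_fps) for d in used_drugs])

    # normalize over every available cell line, then subset to the used ones
    expr_all = zscore_normalize(
        expression.to_numpy(dtype=np.float64),
        row_names=list(expression.index), col_names=list(expression.columns),
    )
    row_of = {c: i for i, c in enumerate(expression.index)}
    expr = expr_all[[row_of[c] for c in used_cells]]
    g = expr.shape[1]

    cat = np.array(
        [
            (drug_idx[r.drug1_id], drug_idx[r.drug2_id], cell_idx[r.cell_line_id])
            for r in labeled.itertuples()
        ],
        dtype=np.int64,
    )
    y = labeled["label"].to_numpy(dtype=np.int8)
    if augment_order:
        swapped = cat[:, [1, 0, 2]]
        cat = np.vstack([cat, swapped])
        y = np.concatenate([y, y])

    num = np.empty((len(cat), 2 * len(panel_ids) + g))
    d1 = cat[:, 0]
    d2 = cat[:, 1]
    ci = cat[:, 2] - m
    num[:, : len(panel_ids)] = profiles[d1]
    num[:, len(panel_ids): 2 * len(panel_ids)] = profiles[d2]
    num[:, 2 * len(panel_ids):] = expr[ci]

    ds = TripletDataset(
        cat=cat, num=num, y=y, drug_ids=used_drugs, cell_ids=used_cells,
        num_sizes=(len(panel_ids), len(panel_ids), g),
        drug_profiles=profiles, cell_expr=expr,
        tissues=dict(tissues) if tissues else {},
    )
    pos, neg = ds.class_counts()
    logger.info("dataset: %d triplets (%d positive, %d negative, ratio 1:%.2f)",
                len(ds), pos, neg, neg / pos if pos else float("inf"))
    return ds


# -- table readers -------------------------------------------------------------

def read_drug_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    return df[["drug_id", "smiles"]]


def read_combo_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    cols = ["drug1_id", "drug2_id", "cell_line_id", "synergy_score"]
    if "source" in df.columns:
        cols.append("source")
    return df[cols]


def read_expression_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def read_tissue_map(path) -> dict:
    df = pd.read_csv(path, sep=None, engine="python")
    return dict(zip(df["cell_line_id"], df["tissue"]))
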