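"""Synthetic drug-combination benchmark with known latent structure.

Drugs carry cluster-structured binary fingerprints and latent factors; cell
lines carry tissue-structured latent factors projected into a Gaussian
expression matrix.  Continuous synergy scores follow a drug-order-symmetric
latent-factor surface (bilinear drug-drug interaction plus a cell-line
modulation), affinely calibrated on a pilot sample so that thresholding at
0 / 30 yields a requested negative:positive class ratio with a small band
of excluded mid-range scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# a small alphabet of valid template molecules for end-to-end SMILES tests
TEMPLATE_SMILES = [
    "CCO", "c1ccccc1", "CC(=O)Oc1ccccc1C(=O)O", "CN1CCC[C@H]1c1cccnc1",
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O", "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "NC(=O)c1ccc[nH]1", "OCC1OC(O)C(O)C(O)C1O",
]

SYNERGY_UPPER = 30.0
SYNERGY_LOWER = 0.0


@dataclass
class SyntheticConfig:
    m_drugs: int = 40
    n_cell_lines: int = 8
    n_tissues: int = 4
    g_genes: int = 60
    latent_dim: int = 6
    interaction_strength: float = 3.0
    noise_sd: float = 0.3
    target_neg_pos_ratio: float = 2.3
    seed: int = 0
    n_triplets: int = 4000
    n_drug_clusters: int = 4
    fp_density: float = 0.1          # expected fraction of set template bits
    fp_flip_rate: float = 0.02       # per-bit flip probability per drug
    mid_band_fraction: float = 0.05  # fraction of scores calibrated into [0, 30]
    cell_modulation: float = 1.0
    pilot_size: int = 10000

    def __post_init__(self):
        if self.m_drugs < 2:
            raise ValueError("need at least 2 drugs")
        if self.n_cell_lines < 1:
            raise ValueError("need at least 1 cell line")
        if self.n_tissues > self.n_cell_lines:
            raise ValueError("n_tissues cannot exceed n_cell_lines")
        if self.target_neg_pos_ratio <= 0:
            raise ValueError("target_neg_pos_ratio must be positive")
        if self.interaction_strength < 0 or self.noise_sd < 0:
            raise ValueError("interaction_strength and noise_sd must be >= 0")


@dataclass
class GroundTruth:
    drug_factors: np.ndarray        # (m, d)
    cell_factors: np.ndarray        # (n, d)
    interaction: np.ndarray         # (d, d) symmetric bilinear kernel
    scale: float                    # affine calibration: score = scale*raw + offset
    offset: float
    drug_clusters: np.ndarray       # (m,) cluster assignment
    tissue_of_cell: np.ndarray      # (n,) tissue index

    def raw_surface(self, i: int, j: int, k: int, strength: float,
                    cell_modulation: float) -> float:
        u, v, w = self.drug_factors[i], self.drug_factors[j], self.cell_factors[k]
        return float(
            strength * (u @ self.interaction @ v + cell_modulation * (w @ (u + v)))
        )

    def score(self, i: int, j: int, k: int, strength: float,
              cell_modulation: float) -> float:
        """Noise-free calibrated synergy score; symmetric in (i, j) exactly."""
        return self.scale * self.raw_surface(i, j, k, strength, cell_modulation) \
            + self.offset


def _component_rngs(seed: int) -> dict:
    """Independent, deterministic RNG streams per generator component, so the
    standalone generators reproduce exactly what generate_all emits."""
    root = np.random.SeedSequence(seed)
    names = ("latents", "drugs", "cells", "records", "pilot")
    return dict(zip(names, map(np.random.default_rng, root.spawn(len(names)))))


def _latents(config: SyntheticConfig, rng: np.random.Generator):
    c = config
    centers = rng.normal(0.0, 1.0, size=(c.n_drug_clusters, c.latent_dim))
    clusters = np.arange(c.m_drugs) % c.n_drug_clusters
    drug_factors = centers[clusters] + 0.3 * rng.normal(size=(c.m_drugs, c.latent_dim))
    tissue_centers = rng.normal(0.0, 1.0, size=(c.n_tissues, c.latent_dim))
    tissue_of_cell = np.arange(c.n_cell_lines) % c.n_tissues
    cell_factors = (
        tissue_centers[tissue_of_cell]
        + c.noise_sd * rng.normal(size=(c.n_cell_lines, c.latent_dim))
    )
    r = rng.normal(size=(c.latent_dim, c.latent_dim))
    interaction = 0.5 * (r + r.T)
    return drug_factors, cell_factors, interaction, clusters, tissue_of_cell


def generate_all(config: SyntheticConfig, emit_smiles: bool = False):
    """Generate (drugs, cell_lines, records, truth) under one seed.

    drugs: DataFrame(drug_id, fingerprint[, smiles]); cell_lines:
    (expression DataFrame indexed by cell id, tissue map dict); records:
    DataFrame of synergy measurements with randomized drug order.
    """
    c = config
    rngs = _component_rngs(c.seed)
    drug_factors, cell_factors, interaction, clusters, tissue_of_cell = _latents(
        c, rngs["latents"]
    )
    truth = GroundTruth(drug_factors, cell_factors, interaction, 1.0, 0.0,
                        clusters, tissue_of_cell)

    drugs = _make_drugs(c, rngs["drugs"], clusters, emit_smiles)
    expression, tissues = _make_cell_lines(
        c, rngs["cells"], cell_factors, tissue_of_cell
    )
    records = _make_records(c, rngs["records"], truth, rngs["pilot"])
    return drugs, (expression, tissues), records, truth


def generate_drugs(config: SyntheticConfig, emit_smiles: bool = False) -> pd.DataFrame:
    rngs = _component_rngs(config.seed)
    *_, clusters, _ = _latents(config, rngs["latents"])
    return _make_drugs(config, rngs["drugs"], clusters, emit_smiles)


def _make_drugs(c, rng, clusters, emit_smiles):
    templates = (rng.random((c.n_drug_clusters, 1024)) < c.fp_density).astype(np.uint8)
    flips = rng.random((c.m_drugs, 1024)) < c.fp_flip_rate
    fps = templates[clusters] ^ flips.astype(np.uint8)
    rows = []
    for i in range(c.m_drugs):
        row = {"drug_id": f"D{i:03d}", "fingerprint": fps[i], "cluster": int(clusters[i])}
        if emit_smiles:
            row["smiles"] = TEMPLATE_SMILES[i % len(TEMPLATE_SMILES)]
        rows.append(row)
    return pd.DataFrame(rows)


def generate_cell_lines(config: SyntheticConfig):
    rngs = _component_rngs(config.seed)
    _, cell_factors, _, _, tissue_of_cell = _latents(config, rngs["latents"])
    return _make_cell_lines(config, rngs["cells"], cell_factors, tissue_of_cell)


def _make_cell_lines(c, rng, cell_factors, tissue_of_cell):
    # expression = linear read-out of the cell latent factors; cells of one
    # tissue share a latent center, so noise_sd = 0 makes them identical
    gene_loadings = rng.normal(0.0, 1.0, size=(c.latent_dim, c.g_genes))
    expr = cell_factors @ gene_loadings
    cell_ids = [f"C{k:03d}" for k in range(c.n_cell_lines)]
    expression = pd.DataFrame(
        expr, index=cell_ids, columns=[f"G{g:04d}" for g in range(c.g_genes)]
    )
    tissues = {cid: f"T{tissue_of_cell[k]}" for k, cid in enumerate(cell_ids)}
    return expression, tissues


def generate_synergy_records(config: SyntheticConfig,
                             truth: GroundTruth | None = None) -> pd.DataFrame:
    rngs = _component_rngs(config.seed)
    if truth is None:
        drug_factors, cell_factors, interaction, clusters, tissue_of = _latents(
            config, rngs["latents"]
        )
        truth = GroundTruth(drug_factors, cell_factors, interaction, 1.0, 0.0,
                            clusters, tissue_of)
    return _make_records(config, rngs["records"], truth, rngs["pilot"])


def _make_records(c, rng, truth: GroundTruth, pilot_rng=None) -> pd.DataFrame:
    m, n = c.m_drugs, c.n_cell_lines
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    total = len(pairs) * n
    n_triplets = min(c.n_triplets, total)
    chosen = rng.choice(total, size=n_triplets, replace=False)
    pair_idx, cell_idx = np.divmod(chosen, n)

    u = truth.drug_factors
    w = truth.cell_factors
    pi = np.array([pairs[p][0] for p in pair_idx])
    pj = np.array([pairs[p][1] for p in pair_idx])
    bilinear = np.einsum("td,de,te->t", u[pi], truth.interaction, u[pj])
    modulation = np.einsum("td,td->t", w[cell_idx], u[pi] + u[pj])
    raw = (
        c.interaction_strength * (bilinear + c.cell_modulation * modulation)
        + c.noise_sd * rng.normal(size=n_triplets)  # one draw per unordered triplet
    )

    scale, offset = _calibrate(c, pilot_rng or rng, truth, raw)
    truth.scale, truth.offset = scale, offset
    scores = scale * raw + offset

    # randomize the stored drug order to exercise canonicalization downstream
    swap = rng.random(n_triplets) < 0.5
    d1 = np.where(swap, pj, pi)
    d2 = np.where(swap, pi, pj)
    return pd.DataFrame({
        "drug1_id": [f"D{i:03d}" for i in d1],
        "drug2_id": [f"D{j:03d}" for j in d2],
        "cell_line_id": [f"C{k:03d}" for k in cell_idx],
        "synergy_score": scores,
        "source": "synthetic",
    })


def _calibrate(c, rng, truth, raw_sample: np.ndarray):
    """Affine map so that P(score < 0) : P(score > 30) ~ target ratio with a
    small mid band.  Uses a pilot sample of triplets (the generated raw
    scores themselves, topped up to the pilot size if needed)."""
    pilot = raw_sample
    if len(pilot) < c.pilot_size:
        m, n = c.m_drugs, c.n_cell_lines
        extra = c.pilot_size - len(pilot)
        i = rng.integers(0, m, size=extra)
        j = rng.integers(0, m, size=extra)
        redraw = i == j
        j[redraw] = (j[redraw] + 1) % m
        k = rng.integers(0, n, size=extra)
        u, w = truth.drug_factors, truth.cell_factors
        bil = np.einsum("td,de,te->t", u[i], truth.interaction, u[j])
        mod = np.einsum("td,td->t", w[k], u[i] + u[j])
        extra_raw = (
            c.interaction_strength * (bil + c.cell_modulation * mod)
            + c.noise_sd * rng.normal(size=extra)
        )
        pilot = np.concatenate([pilot, extra_raw])
    spread = np.quantile(pilot, 0.99) - np.quantile(pilot, 0.01)
    if spread <= 0:
        # degenerate surface: map everything to a constant inside the mid band
        return 1.0, 15.0 - float(pilot[0])
    r = c.target_neg_pos_ratio
    f_mid = c.mid_band_fraction
    p_pos = (1.0 - f_mid) / (1.0 + r)
    p_neg = r * p_pos
    q_low = np.quantile(pilot, p_neg)
    q_high = np.quantile(pilot, p_neg + f_mid)
    if q_high <= q_low:
        q_high = q_low + 1e-9
    scale = (SYNERGY_UPPER - SYNERGY_LOWER) / (q_high - q_low)
    offset = SYNERGY_LOWER - scale * q_low
    return float(scale), float(offset)


def generate_dataset(config: SyntheticConfig, augment_order: bool = False):
    """End-to-end convenience: synthetic tables -> labeled TripletDataset.

    Returns (dataset, truth).  Fingerprints are passed through directly
    (no SMILES round-trip) so the cluster structure is preserved.
    """
    from .data import build_dataset

    drugs, (expression, tissues), records, truth = generate_all(config)
    fingerprints = dict(zip(drugs["drug_id"], drugs["fingerprint"]))
    ds = build_dataset(
        drugs, expression, records, tissues=tissues,
        augment_order=augment_order, fingerprints=fingerprints,
    )
    return ds, truth


def write_csv_bundle(config: SyntheticConfig, outdir, emit_smiles: bool = True):
    """Emit the CSV dialects the preprocessing pipeline reads, plus truth."""
    import os

    drugs, (expression, tissues), records, truth = generate_all(
        config, emit_smiles=emit_smiles
    )
    os.makedirs(outdir, exist_ok=True)
    cols = ["drug_id"] + (["smiles"] if emit_smiles else [])
    drugs[cols].to_csv(os.path.join(outdir, "drugs.csv"), index=False)
    np.savetxt(
        os.path.join(outdir, "fingerprints.csv"),
        np.stack(drugs["fingerprint"].to_numpy()), fmt="%d", delimiter=",",
    )
    expression.to_csv(os.path.join(outdir, "expression.csv"))
    pd.DataFrame(
        {"cell_line_id": list(tissues), "tissue": list(tissues.values())}
    ).to_csv(os.path.join(outdir, "tissues.csv"), index=False)
    records.to_csv(os.path.join(outdir, "combinations.csv"), index=False)
    np.savez(
        os.path.join(outdir, "ground_truth.npz"),
        drug_factors=truth.drug_factors, cell_factors=truth.cell_factors,
        interaction=truth.interaction,
        scale=truth.scale, offset=truth.offset,
        drug_clusters=truth.drug_clusters, tissue_of_cell=truth.tissue_of_cell,
    )
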