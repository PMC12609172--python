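"""Preprocessing: fingerprints, Tanimoto, z-scoring, labeling, dataset assembly."""

import numpy as np
import pandas as pd
import pytest

from dsadeepfm.data import (
    EXCLUDED, NEGATIVE, POSITIVE,
    InvalidMoleculeError, TripletDataset, build_dataset, compute_fingerprint,
    label_by_threshold, label_triplets, majority_vote, tanimoto,
    tanimoto_profile, zscore_normalize,
)


class TestFingerprint:
    def test_valid_molecule_sets_bits(self):
        fp = compute_fingerprint("CCO")
        assert fp.shape == (1024,)
        assert set(np.unique(fp)) <= {0, 1}
        assert fp.sum() >= 1

    def test_equivalent_smiles_give_identical_fingerprints(self):
        # non-canonical vs canonical writing of ethanol
        assert np.array_equal(compute_fingerprint("OCC"), compute_fingerprint("CCO"))

    @pytest.mark.parametrize("bad", ["", "not_a_smiles(", "C(C"])
    def test_invalid_smiles_raises_naming_drug(self, bad):
        with pytest.raises(InvalidMoleculeError, match="drugX"):
            compute_fingerprint(bad, drug_id="drugX")


class TestTanimoto:
    def test_identity_disjoint_and_counted_overlap(self):
        a = np.zeros(16, dtype=np.uint8)
        a[:4] = 1
        b = np.zeros(16, dtype=np.uint8)
        b[2:6] = 1
        assert tanimoto(a, a) == 1.0
        c = np.zeros(16, dtype=np.uint8)
        c[8:12] = 1
        assert tanimoto(a, c) == 0.0
        # |A|=4, |B|=4, |A∩B|=2 -> 2/6
        assert tanimoto(a, b) == pytest.approx(2 / 6)

    def test_all_zero_convention_and_length_mismatch(self):
        z = np.zeros(8)
        assert tanimoto(z, z) == 0.0
        with pytest.raises(ValueError, match="mismatch"):
            tanimoto(np.zeros(8), np.zeros(9))

    def test_symmetric_and_bounded_on_random_vectors(self, rng):
        for _ in range(50):
            a = rng.integers(0, 2, 64)
            b = rng.integers(0, 2, 64)
            t = tanimoto(a, b)
            assert 0.0 <= t <= 1.0
            assert t == tanimoto(b, a)
            if a.any():
                assert tanimoto(a, a) == 1.0

    def test_profile_matches_elementwise_calls_and_self_similarity(self, rng):
        panel = rng.integers(0, 2, (3, 32)).astype(np.uint8)
        prof = tanimoto_profile(panel[0], panel)
        assert prof.shape == (3,)
        assert prof[0] == 1.0
        for t in range(3):
            assert prof[t] == pytest.approx(tanimoto(panel[0], panel[t]))

    def test_unseen_drug_against_training_panel_has_panel_length(self, rng):
        train_panel = rng.integers(0, 2, (5, 32)).astype(np.uint8)
        unseen = rng.integers(0, 2, 32).astype(np.uint8)
        assert tanimoto_profile(unseen, train_panel).shape == (5,)
        with pytest.raises(ValueError):
            tanimoto_profile(unseen, np.empty((0, 32)))


class TestZScore:
    def test_known_column_population_sd(self):
        out = zscore_normalize(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out[:, 0], [-1.2247448, 0.0, 1.2247448], atol=1e-6)

    def test_constant_column_maps_to_zero(self):
        out = zscore_normalize(np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]]))
        assert np.all(out[:, 0] == 0.0)

    def test_idempotent(self, rng):
        x = rng.normal(size=(10, 4))
        once = zscore_normalize(x)
        np.testing.assert_allclose(zscore_normalize(once), once, atol=1e-9)

    def test_matches_brute_force_mean_sd_oracle(self, rng):
        x = rng.normal(2.0, 3.0, size=(15, 5))
        out = zscore_normalize(x)
        for j in range(5):
            col = x[:, j]
            expected = (col - col.mean()) / np.sqrt(((col - col.mean()) ** 2).mean())
            np.testing.assert_allclose(out[:, j], expected, atol=1e-12)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(out.std(axis=0), 1.0, atol=1e-6)

    def test_nonfinite_raises_naming_location(self):
        x = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValueError, match="CL2.*GeneA"):
            zscore_normalize(x, row_names=["CL1", "CL2"], col_names=["GeneA", "GeneB"])


class TestLabeling:
    @pytest.mark.parametrize("score,expected", [
        (45.0, POSITIVE), (-3.0, NEGATIVE),
        (30.0, EXCLUDED), (0.0, EXCLUDED), (15.0, EXCLUDED),
        (30.0000001, POSITIVE), (-1e-9, NEGATIVE),
    ])
    def test_threshold_rule(self, score, expected):
        assert label_by_threshold(score) == expected

    def test_nonfinite_score_raises(self):
        with pytest.raises(ValueError):
            label_by_threshold(float("nan"))

    def test_every_finite_score_maps_to_exactly_one_class(self, rng):
        for s in rng.uniform(-100, 100, 200):
            assert label_by_threshold(s) in (POSITIVE, NEGATIVE, EXCLUDED)

    @pytest.mark.parametrize("votes,expected", [
        ([POSITIVE, POSITIVE, NEGATIVE], POSITIVE),
        ([NEGATIVE], NEGATIVE),
        ([POSITIVE, NEGATIVE], EXCLUDED),
    ])
    def test_majority_vote(self, votes, expected):
        assert majority_vote(votes) == expected

    def test_majority_vote_empty_raises(self):
        with pytest.raises(ValueError):
            majority_vote([])


def _toy_tables():
    drugs = pd.DataFrame({
        "drug_id": ["A1", "A2", "B1", "B2", "C1", "C2", "D1", "D2"],
        "smiles": ["CCO", "CCN", "CCC", "CCCl", "CCBr", "CCI", "CCF", "CO"],
    })
    # triplets: A (45, 50) -> pos; B (-3) -> neg; C (31) -> pos;
    # D (12 excluded, -1 neg) -> neg from the single surviving vote
    combos = pd.DataFrame({
        "drug1_id": ["A1", "A2", "B1", "C1", "D1", "D2"],
        "drug2_id": ["A2", "A1", "B2", "C2", "D2", "D1"],
        "cell_line_id": ["CL1"] * 6,
        "synergy_score": [45.0, 50.0, -3.0, 31.0, 12.0, -1.0],
    })
    genes = [f"G{i}" for i in range(5)]
    rng = np.random.default_rng(0)
    expr = pd.DataFrame(rng.normal(size=(2, 5)), index=["CL1", "CL2"], columns=genes)
    return drugs, combos, expr


class TestBuildDataset:
    def test_toy_trace_reproduces_hand_derived_labels(self):
        drugs, combos, expr = _toy_tables()
        labeled = label_triplets(combos)
        got = {
            (r.drug1_id, r.drug2_id): r.label for r in labeled.itertuples()
        }
        assert got == {("A1", "A2"): 1, ("B1", "B2"): 0,
                       ("C1", "C2"): 1, ("D1", "D2"): 0}

    def test_dataset_assembly_and_counts(self):
        drugs, combos, expr = _toy_tables()
        ds = build_dataset(drugs, expr, combos)
        assert len(ds) == 4
        assert ds.class_counts() == (2, 2)
        m_ref, _, g = ds.num_sizes
        assert ds.num.shape == (4, 2 * m_ref + g)
        assert np.all(ds.num[:, : 2 * m_ref] >= 0)
        assert np.all(ds.num[:, : 2 * m_ref] <= 1)

    def test_order_augmentation_doubles_and_is_closed_under_swap(self):
        drugs, combos, expr = _toy_tables()
        plain = build_dataset(drugs, expr, combos)
        aug = build_dataset(drugs, expr, combos, augment_order=True)
        assert len(aug) == 2 * len(plain)
        seen = {(a, b, c, y) for (a, b, c), y in zip(map(tuple, aug.cat), aug.y)}
        for (a, b, c, y) in list(seen):
            assert (b, a, c, y) in seen

    def test_all_mid_band_scores_raise_empty_dataset(self):
        drugs, combos, expr = _toy_tables()
        combos = combos.assign(synergy_score=[10.0, 20.0, 5.0, 0.0, 30.0, 12.0])
        with pytest.raises(ValueError, match="no labeled triplets"):
            build_dataset(drugs, expr, combos)

    def test_unresolvable_entities_are_dropped(self, caplog):
        drugs, combos, expr = _toy_tables()
        combos.loc[2, "drug1_id"] = "UNKNOWN"
        ds = build_dataset(drugs, expr, combos)
        assert len(ds) == 3  # triplet B lost its only record's drug

    def test_identical_drugs_in_record_rejected(self):
        drugs, combos, expr = _toy_tables()
        combos.loc[0, "drug2_id"] = "A1"
        with pytest.raises(ValueError, match="identical"):
            build_dataset(drugs, expr, combos)

    def test_save_load_roundtrip(self, tmp_path, small_dataset):
        ds, _ = small_dataset
        path = tmp_path / "ds.npz"
        ds.save(path)
        back = TripletDataset.load(path)
        np.testing.assert_array_equal(back.cat, ds.cat)
        np.testing.assert_allclose(back.num, ds.num)
        np.testing.assert_array_equal(back.y, ds.y)
        assert back.drug_ids == [str(d) for d in ds.drug_ids]
        assert back.num_sizes == ds.num_sizes
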