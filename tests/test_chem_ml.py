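import dataclasses

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from fluxlip.chem_ml import (
    MoleculeRecord,
    balance,
    compute_descriptors,
    descriptor_table,
    freeviz_project,
    information_gain,
    loo_evaluate,
    read_molecules_tsv,
    select_features,
)
from fluxlip.synthetic_data import SyntheticSpec, make_lipid_classes

TAUROCHOLATE = (
    "C[C@H](CCC(=O)NCCS(=O)(=O)O)[C@H]1CC[C@@H]2[C@@]1([C@H](C[C@H]3[C@H]2"
    "[C@@H](C[C@H]4[C@@]3(CC[C@H](C4)O)C)O)O)C"
)


@pytest.fixture(scope="module")
def lipid_records():
    spec = SyntheticSpec(seed=7, n_elevated=30, n_decreased=20)
    return [r.with_descriptors() for r in make_lipid_classes(spec)]


class TestDescriptors:
    def test_pentadecanoic_acid(self):
        d = compute_descriptors("CCCCCCCCCCCCCCC(=O)O")
        assert d["nof_Rings"] == 0
        assert d["nof_COOH"] == 1
        assert d["nof_OH"] == 0

    def test_benzene(self):
        d = compute_descriptors("c1ccccc1")
        assert d["nof_Rings"] == 1
        assert d["C_sp3"] == 0
        assert d["C_R0"] == 0

    def test_taurocholate_ring_oracle(self):
        # independent ring-perception oracle: RDKit ring info on the parsed mol
        mol = Chem.MolFromSmiles(TAUROCHOLATE)
        assert mol.GetRingInfo().NumRings() == 4
        assert compute_descriptors(TAUROCHOLATE)["nof_Rings"] == 4

    def test_hydroxyl_excludes_carboxyl(self):
        # lactic acid: one COOH, one free OH
        d = compute_descriptors("CC(O)C(=O)O")
        assert d["nof_COOH"] == 1
        assert d["nof_OH"] == 1

    def test_rotatable_bonds_exclude_amide(self):
        # N-methylacetamide has no strict rotatable bonds
        assert compute_descriptors("CNC(C)=O")["nof_RotB"] == 0

    def test_chirals_include_unassigned(self):
        assert compute_descriptors("CC(O)CC(N)C")["nof_Chirals"] == 2

    def test_unparseable_smiles(self):
        with pytest.raises(ValueError, match="badrec"):
            compute_descriptors("C1CC", name="badrec")

    def test_determinism_on_canonical_smiles(self):
        smi = Chem.CanonSmiles("OCC(O)CN")
        assert compute_descriptors(smi) == compute_descriptors(smi)

    def test_count_descriptor_invariants(self, lipid_records):
        count_keys = [
            "nof_Rings", "nof_COOH", "nof_OH", "nof_RotB", "nof_Chirals",
            "C_sp3", "C_R0", "n_carbon",
        ]
        for rec in lipid_records:
            d = rec.descriptors
            for k in count_keys:
                assert d[k] >= 0 and d[k] == int(d[k])
            assert d["C_sp3"] <= d["n_carbon"]
            assert d["C_R0"] <= d["n_carbon"]
            mol = Chem.MolFromSmiles(rec.smiles)
            non_sp3 = sum(
                1
                for a in mol.GetAtoms()
                if a.GetSymbol() == "C"
                and a.GetHybridization() != Chem.HybridizationType.SP3
            )
            assert d["C_sp3"] + non_sp3 == d["n_carbon"]

    def test_panel_size(self):
        assert len(compute_descriptors("CCO")) >= 30

    def test_charged_species_positive_charge(self):
        d = compute_descriptors("C[N+](C)(C)CCO")
        assert d["posCharge_per_volume"] > 0
        assert d["formal_charge"] == 1


class TestFeatureSelection:
    def _records(self, feats: dict[str, np.ndarray], labels):
        n = len(labels)
        return [
            MoleculeRecord(
                f"m{i}", "C", labels[i],
                descriptors={k: float(v[i]) for k, v in feats.items()},
            )
            for i in range(n)
        ]

    def test_duplicate_feature_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        labels = ["elevated"] * 20 + ["decreased"] * 20
        recs = self._records(
            {"a": x, "a_copy": x.copy(), "b": rng.normal(size=40)}, labels
        )
        feats = select_features(recs, target_count=2)
        assert not {"a", "a_copy"} <= set(feats)

    def test_perfect_predictor_ranked_first(self):
        rng = np.random.default_rng(1)
        labels = ["elevated"] * 25 + ["decreased"] * 25
        indicator = np.array([1.0] * 25 + [0.0] * 25)
        recs = self._records(
            {"noise1": rng.normal(size=50), "oracle": indicator,
             "noise2": rng.normal(size=50)},
            labels,
        )
        feats = select_features(recs, target_count=2)
        assert feats[0] == "oracle"
        # its gain equals the class entropy (perfectly balanced -> 1 bit)
        assert information_gain(indicator, np.array(labels)) == pytest.approx(1.0)

    def test_ring_count_in_top_six_when_planted(self):
        # planted set: ring count separates the classes, everything else is noise
        rng = np.random.default_rng(2)
        labels = ["elevated"] * 30 + ["decreased"] * 20
        rings = np.array([0.0] * 30 + list(rng.integers(2, 5, size=20).astype(float)))
        feats_in = {"nof_Rings": rings}
        for j in range(8):
            feats_in[f"noise{j}"] = rng.normal(size=50)
        recs = self._records(feats_in, labels)
        assert "nof_Rings" in select_features(recs, target_count=6)

    def test_separating_features_outrank_noise_on_lipid_set(self, lipid_records):
        feats = select_features(lipid_records, target_count=6)
        y = np.array([r.direction for r in lipid_records])
        df = descriptor_table(lipid_records)
        gains = {f: information_gain(df[f].to_numpy(), y) for f in feats}
        # every selected feature carries real class information
        assert min(gains.values()) > 0.2

    def test_fewer_survivors_warns(self):
        labels = ["elevated", "elevated", "decreased", "decreased"]
        x = np.array([1.0, 2.0, 3.0, 4.0])
        recs = self._records({"a": x, "b": 2 * x}, labels)
        with pytest.warns(UserWarning, match="survive"):
            feats = select_features(recs, target_count=4)
        assert len(feats) < 4

    def test_target_count_validation(self, lipid_records):
        with pytest.raises(ValueError):
            select_features(lipid_records, target_count=1)


class TestBalance:
    def _records(self, n_elev, n_decr):
        return [
            MoleculeRecord(f"e{i}", "C", "elevated") for i in range(n_elev)
        ] + [MoleculeRecord(f"d{i}", "C", "decreased") for i in range(n_decr)]

    def _sizes(self, recs):
        out = {}
        for r in recs:
            out[r.direction] = out.get(r.direction, 0) + 1
        return out

    def test_downsample_86_40(self):
        out = balance(self._records(86, 40), "downsample", seed=0)
        assert self._sizes(out) == {"elevated": 40, "decreased": 40}

    def test_upsample_86_40(self):
        out = balance(self._records(86, 40), "upsample", seed=0)
        assert self._sizes(out) == {"elevated": 86, "decreased": 86}

    def test_combined_geometric_mean(self):
        out = balance(self._records(86, 40), "combined", seed=0)
        target = round((86 * 40) ** 0.5)  # 59
        assert self._sizes(out) == {"elevated": target, "decreased": target}

    def test_balanced_input_unchanged_downsample(self):
        recs = self._records(10, 10)
        out = balance(recs, "downsample", seed=3)
        assert sorted(r.name for r in out) == sorted(r.name for r in recs)

    def test_deterministic(self):
        recs = self._records(20, 9)
        a = balance(recs, "downsample", seed=5)
        b = balance(recs, "downsample", seed=5)
        assert [r.name for r in a] == [r.name for r in b]

    def test_empty_class_error(self):
        with pytest.raises(ValueError):
            balance(self._records(5, 0), "downsample", seed=0)

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            balance(self._records(5, 5), "sideways", seed=0)


class TestLOO:
    def test_separable_logistic(self, lipid_records):
        feats = select_features(lipid_records, target_count=6)
        rep = loo_evaluate(lipid_records, feats, "logistic", seed=7)
        assert rep.accuracy >= 0.95
        assert rep.confusion.sum() == len(lipid_records)
        assert rep.accuracy == pytest.approx(
            np.trace(rep.confusion) / rep.confusion.sum()
        )

    def test_permuted_labels_chance_level(self, lipid_records):
        rng = np.random.default_rng(11)
        perm = rng.permutation([r.direction for r in lipid_records])
        precs = [
            dataclasses.replace(r, direction=d)
            for r, d in zip(lipid_records, perm)
        ]
        feats = select_features(precs, target_count=6)
        rep = loo_evaluate(precs, feats, "knn", seed=11)
        assert 0.25 <= rep.accuracy <= 0.75

    def test_constant_features_chance(self):
        recs = [
            MoleculeRecord(f"m{i}", "C",
                           "elevated" if i % 2 else "decreased",
                           descriptors={"a": 1.0, "b": 1.0})
            for i in range(30)
        ]
        rep = loo_evaluate(recs, ["a", "b"], "knn", seed=0)
        assert 0.2 <= rep.accuracy <= 0.8

    def test_unknown_model(self, lipid_records):
        with pytest.raises(ValueError, match="supported"):
            loo_evaluate(lipid_records, ["nof_Rings"], "svm", seed=0)

    def test_misclassified_report_has_subpathways(self, lipid_records):
        rng = np.random.default_rng(12)
        perm = rng.permutation([r.direction for r in lipid_records])
        precs = [
            dataclasses.replace(r, direction=d)
            for r, d in zip(lipid_records, perm)
        ]
        rep = loo_evaluate(precs, ["nof_Rings", "nof_RotB"], "decision_tree", seed=0)
        mis = rep.misclassified
        assert len(mis) > 0
        assert "subpathway" in mis.columns

    def test_report_serializable(self, lipid_records):
        rep = loo_evaluate(lipid_records, ["nof_Rings", "nof_COOH"], "knn", seed=1)
        d = rep.to_dict()
        assert d["loo_accuracy"] == rep.accuracy
        assert np.asarray(d["confusion_matrix"]).sum() == len(lipid_records)


class TestFreeViz:
    def _split_records(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(n):
            cls = "elevated" if i < n // 2 else "decreased"
            f1 = (1.0 if cls == "elevated" else -1.0) + rng.normal(0, 0.2)
            recs.append(
                MoleculeRecord(f"m{i}", "C", cls,
                               descriptors={"f1": f1, "f2": rng.normal()})
            )
        return recs

    def test_informative_anchor_dominates(self):
        anchors, _ = freeviz_project(self._split_records(), ["f1", "f2"], seed=1)
        n1 = np.linalg.norm(anchors.loc["f1"])
        n2 = np.linalg.norm(anchors.loc["f2"])
        assert n1 > 5 * n2

    def test_longest_anchor_unit_length(self):
        anchors, _ = freeviz_project(self._split_records(), ["f1", "f2"], seed=1)
        assert np.linalg.norm(anchors.to_numpy(), axis=1).max() == pytest.approx(1.0)

    def test_random_labels_centroids_coincide(self):
        recs = self._split_records(seed=3)
        rng = np.random.default_rng(4)
        perm = rng.permutation([r.direction for r in recs])
        precs = [dataclasses.replace(r, direction=d) for r, d in zip(recs, perm)]
        _, emb = freeviz_project(precs, ["f1", "f2"], seed=5)
        cents = emb.groupby("direction")[["x", "y"]].mean()
        dist = np.linalg.norm(cents.iloc[0] - cents.iloc[1])
        spread = (
            emb.groupby("direction")
            .apply(
                lambda b: np.linalg.norm(
                    b[["x", "y"]].to_numpy() - b[["x", "y"]].mean().to_numpy(),
                    axis=1,
                ).mean(),
                include_groups=False,
            )
            .mean()
        )
        assert dist < spread

    def test_determinism(self):
        recs = self._split_records()
        a1, e1 = freeviz_project(recs, ["f1", "f2"], seed=9)
        a2, e2 = freeviz_project(recs, ["f1", "f2"], seed=9)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(e1, e2)

    def test_embedding_is_linear_projection(self):
        recs = self._split_records()
        anchors, emb = freeviz_project(recs, ["f1", "f2"], seed=2)
        X = np.array([[r.descriptors["f1"], r.descriptors["f2"]] for r in recs])
        X = (X - X.mean(0)) / X.std(0)
        np.testing.assert_allclose(
            emb[["x", "y"]].to_numpy(), X @ anchors.to_numpy(), atol=1e-9
        )

    def test_too_few_features(self):
        with pytest.raises(ValueError):
            freeviz_project(self._split_records(), ["f1"], seed=0)


class TestIO:
    def test_read_molecules_tsv(self, tmp_path):
        p = tmp_path / "mols.tsv"
        pd.DataFrame(
            {
                "name": ["a", "b"],
                "smiles": ["CCO", "c1ccccc1"],
                "direction": ["elevated", "decreased"],
                "subpathway": ["x", "y"],
            }
        ).to_csv(p, sep="\t", index=False)
        recs = read_molecules_tsv(p)
        assert len(recs) == 2
        assert recs[1].direction == "decreased"

    def test_missing_column(self, tmp_path):
        p = tmp_path / "mols.tsv"
        pd.DataFrame({"name": ["a"], "smiles": ["CCO"]}).to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="direction"):
            read_molecules_tsv(p)

    def test_descriptor_table_shape(self, lipid_records):
        df = descriptor_table(lipid_records)
        assert df.shape[0] == len(lipid_records)
        assert not df.isna().any().any()
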