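"""Bioactivity curation, scaffold thinning, metrics, and consensus modelling."""

import itertools
import json

import numpy as np
import pandas as pd
import pytest

from targetscreen.qsar import (
    ActivityRecord,
    ConsensusQSAR,
    QSARDataset,
    RFConfig,
    auc_rank,
    curate,
    records_from_table,
    scaffold_thin,
)
from targetscreen.synthetic import SyntheticSpec, gen_bioactivity


def _rec(mol_id, smiles, endpoint, value, unit):
    return ActivityRecord(mol_id, smiles, endpoint, value, unit)


class TestCurate:
    def test_nm_conversion_and_active_label(self):
        ds = curate([_rec("m1", "c1ccccc1CCO", "IC50", 5000.0, "nM")])
        assert len(ds) == 1
        assert ds.mean_activity_um[0] == pytest.approx(5.0)
        assert ds.labels[0] == 1

    def test_duplicate_inchikey_records_pool_to_mean(self):
        # same structure under two ids: 8 µM and 20 µM average to 14 µM
        ds = curate([
            _rec("m1", "OCCc1ccccc1", "IC50", 8.0, "uM"),
            _rec("m2", "c1ccccc1CCO", "Ki", 20.0, "uM"),
        ])
        assert len(ds) == 1
        assert ds.mean_activity_um[0] == pytest.approx(14.0)
        assert ds.labels[0] == 0

    def test_endpoint_whitelist_drops_kd(self):
        ds = curate([
            _rec("m1", "CCO", "Kd", 1.0, "uM"),
            _rec("m2", "CCN", "EC50", 1.0, "uM"),
        ])
        assert [m.mol_id for m in ds.molecules] == ["m2"]

    def test_exactly_10_um_is_inactive(self):
        ds = curate([
            _rec("m1", "CCO", "IC50", 10.0, "uM"),
            _rec("m2", "CCN", "IC50", 9.999, "uM"),
        ])
        assert ds.labels.tolist() == [0, 1]

    def test_molar_unit_conversion(self):
        ds = curate([_rec("m1", "CCO", "Ki", 2e-6, "M")])
        assert ds.mean_activity_um[0] == pytest.approx(2.0)

    def test_unparsable_structure_skipped_not_fatal(self):
        ds = curate([
            _rec("bad", "not_a_smiles", "IC50", 1.0, "uM"),
            _rec("ok", "CCO", "IC50", 1.0, "uM"),
        ])
        assert [m.mol_id for m in ds.molecules] == ["ok"]

    def test_provenance_records_filters(self):
        ds = curate([
            _rec("m1", "CCO", "Kd", 1.0, "uM"),
            _rec("m1", "CCO", "IC50", 2.0, "uM"),
        ])
        prov = ds.provenance[ds.molecules[0].inchikey]
        assert any("dropped endpoint Kd" in p for p in prov)
        assert any("mean=2" in p for p in prov)

    def test_log_mean_switch(self):
        recs = [_rec("m1", "CCO", "IC50", 1.0, "uM"),
                _rec("m1", "CCO", "IC50", 100.0, "uM")]
        assert curate(recs).mean_activity_um[0] == pytest.approx(50.5)
        assert curate(recs, use_log_mean=True).mean_activity_um[0] == pytest.approx(10.0)

    def test_records_from_table_column_mapping(self):
        df = pd.DataFrame({"smiles": ["CCO"], "endpoint": ["IC50"],
                           "value": [100.0], "unit": ["nM"], "mol_id": ["x"]})
        (rec,) = records_from_table(df)
        assert rec.mol_id == "x" and rec.value_um() == pytest.approx(0.1)


class TestScaffoldThin:
    def _dataset(self, n_per_class=8):
        recs = []
        subs = ["C", "CC", "CCC", "CCCC", "OC", "NC", "O", "N"]
        for i, s in enumerate(subs[:n_per_class]):
            recs.append(_rec(f"b{i}", f"{s}c1ccccc1", "IC50", 1.0, "uM"))
        recs.append(_rec("acy1", "CCO", "IC50", 1.0, "uM"))
        recs.append(_rec("acy2", "CCCO", "IC50", 1.0, "uM"))
        return curate(recs)

    def test_class_under_cap_untouched(self):
        ds = self._dataset(3)
        out = scaffold_thin(ds, max_per_scaffold=5, seed=1)
        assert len(out) == len(ds)

    def test_cap_semantics_and_seed_determinism(self):
        ds = self._dataset(8)
        out1 = scaffold_thin(ds, max_per_scaffold=5, seed=7)
        out2 = scaffold_thin(ds, max_per_scaffold=5, seed=7)
        benzenes = [m for m in out1.molecules if m.scaffold_smiles]
        assert len(benzenes) == 5
        assert [m.mol_id for m in out1.molecules] == [m.mol_id for m in out2.molecules]
        out3 = scaffold_thin(ds, max_per_scaffold=5, seed=8)
        assert len(out3) == len(out1)  # same cap, possibly different members

    def test_acyclic_molecules_form_singleton_classes(self):
        ds = self._dataset(8)
        out = scaffold_thin(ds, max_per_scaffold=1, seed=0)
        acyclic = [m.mol_id for m in out.molecules if not m.scaffold_smiles]
        assert sorted(acyclic) == ["acy1", "acy2"]

    def test_never_empties_a_class(self):
        ds = self._dataset(8)
        out = scaffold_thin(ds, max_per_scaffold=1, seed=0)
        scaffolds_in = {m.scaffold_smiles for m in ds.molecules}
        scaffolds_out = {m.scaffold_smiles for m in out.molecules}
        assert scaffolds_in == scaffolds_out

    def test_cap_below_one_rejected(self):
        with pytest.raises(ValueError):
            scaffold_thin(self._dataset(3), max_per_scaffold=0, seed=0)


def auc_brute_force(scores, labels):
    """Pairwise counting over all positive-negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAucRank:
    def test_perfect_separation(self):
        assert auc_rank([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_tied_is_half(self):
        assert auc_rank([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_hand_counted_mixed_case(self):
        # pairs: (.9,.4)+, (.9,.8)+, (.35,.4)-, (.35,.8)- → 2/4
        assert auc_rank([0.9, 0.4, 0.35, 0.8], [1, 0, 1, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_rank([0.1, 0.2], [1, 1])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            n = int(rng.integers(2, 31))
            labels = np.zeros(n, int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            assert auc_rank(scores, labels) == pytest.approx(
                auc_brute_force(scores, labels), abs=1e-12
            )


@pytest.fixture(scope="module")
def planted_results():
    spec = SyntheticSpec(seed=5, n_molecules=120, n_scaffolds=12)
    records, _ = gen_bioactivity(spec)
    ds = scaffold_thin(curate(records), max_per_scaffold=5, seed=5)
    model = ConsensusQSAR(ds, RFConfig(n_trees=200, seed=5))
    return model.fit()


class TestTrainCrossvalidated:
    def test_folds_partition_dataset_into_five(self, planted_results):
        folds = planted_results.fold_assignments
        assert set(folds) == {0, 1, 2, 3, 4}
        assert len(folds) == len(planted_results.model.dataset)

    def test_planted_signal_recovered(self, planted_results):
        assert planted_results.consensus_metrics.auc >= 0.9

    def test_consensus_is_mean_of_scheme_oofs(self, planted_results):
        r = planted_results
        stacked = np.mean([r.oof_probabilities[s] for s in r.oof_probabilities], axis=0)
        np.testing.assert_allclose(stacked, r.consensus_oof)

    def test_acc_identity_holds_exactly(self, planted_results):
        # ACC = (SE*n_pos + SP*n_neg) / (n_pos + n_neg), pooled and per fold
        r = planted_results
        ds = r.model.dataset
        for m in [*r.scheme_metrics.values(), r.consensus_metrics]:
            n_pos, n_neg = ds.n_active, len(ds) - ds.n_active
            assert m.acc == pytest.approx((m.se * n_pos + m.sp * n_neg) / len(ds))
            for row in m.per_fold.itertuples():
                fold_mask = m.fold_assignments == row.fold
                fp, fnn = ds.labels[fold_mask].sum(), (1 - ds.labels[fold_mask]).sum()
                assert row.ACC == pytest.approx((row.SE * fp + row.SP * fnn) / (fp + fnn))

    def test_metrics_in_unit_interval(self, planted_results):
        for m in [*planted_results.scheme_metrics.values(), planted_results.consensus_metrics]:
            for v in (m.se, m.sp, m.acc, m.auc):
                assert 0.0 <= v <= 1.0

    def test_identical_seed_reproduces_report_byte_for_byte(self):
        spec = SyntheticSpec(seed=13, n_molecules=60, n_scaffolds=6)
        records, _ = gen_bioactivity(spec)
        ds = scaffold_thin(curate(records), max_per_scaffold=5, seed=13)
        reports = [
            json.dumps(ConsensusQSAR(ds, RFConfig(n_trees=100, seed=13)).fit().report_dict(),
                       sort_keys=True)
            for _ in range(2)
        ]
        assert reports[0] == reports[1]

    def test_too_small_or_single_class_rejected(self):
        recs = [_rec(f"m{i}", f"{'C' * (i + 1)}c1ccccc1", "IC50", 1.0, "uM")
                for i in range(6)]
        ds = curate(recs)
        with pytest.raises(ValueError):
            ConsensusQSAR(ds).fit()

    def test_label_permutation_destroys_signal(self):
        # permuting labels on the planted dataset leaves chance-level AUC
        spec = SyntheticSpec(seed=21, n_molecules=100, n_scaffolds=10)
        records, _ = gen_bioactivity(spec)
        ds = scaffold_thin(curate(records), max_per_scaffold=5, seed=21)
        rng = np.random.default_rng(21)
        aucs = []
        for s in range(10):
            perm = QSARDataset(
                molecules=ds.molecules,
                mean_activity_um=ds.mean_activity_um,
                labels=rng.permutation(ds.labels),
                provenance=ds.provenance,
            )
            res = ConsensusQSAR(perm, RFConfig(n_trees=100, seed=s)).fit()
            aucs.append(res.consensus_metrics.auc)
        assert 0.40 <= np.mean(aucs) <= 0.60


class TestPredict:
    def test_consensus_probability_is_mean_and_bounded(self, planted_results):
        mols = planted_results.model.dataset.molecules[:10]
        df = planted_results.predict(mols)
        scheme_cols = [c for c in df.columns if c.startswith("prob_") and c != "prob_consensus"]
        means = df[scheme_cols].mean(axis=1)
        np.testing.assert_allclose(df["prob_consensus"], means)
        assert (df["prob_consensus"] >= df[scheme_cols].min(axis=1) - 1e-12).all()
        assert (df["prob_consensus"] <= df[scheme_cols].max(axis=1) + 1e-12).all()

    def test_boundary_half_calls_active(self, planted_results):
        df = planted_results.predict(planted_results.model.dataset.molecules[:20])
        for _, row in df.iterrows():
            assert row.call_active == (row.prob_consensus >= 0.5)

    def test_summary_mentions_all_schemes(self, planted_results):
        text = planted_results.summary()
        for token in ("CATS", "MACCS", "PHYSCHEM2D", "CONSENSUS", "AUC"):
            assert token in text

    def test_save_and_reload_bundle(self, tmp_path, planted_results):
        path = tmp_path / "model.joblib"
        planted_results.save(path)
        import joblib

        bundle = joblib.load(path)
        assert set(bundle["scheme_models"]) == {"CATS", "MACCS", "PHYSCHEM2D"}
        meta = json.loads((tmp_path / "model.joblib.meta.json").read_text())
        assert meta["consensus"]["AUC"] == pytest.approx(
            planted_results.consensus_metrics.auc
        )
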