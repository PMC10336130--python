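"""Feature table: per-sample quantification, export, compound grouping."""

import numpy as np
import pandas as pd
import pytest

import mztrail as mt
from mztrail.features import export_empirical_compounds
from mztrail.mass_grid import DELTA_C13, DELTA_NAH


@pytest.fixture(scope="module")
def identical_pair_result():
    """Two byte-identical samples through the full pipeline."""
    truth = mt.make_ground_truth(n_compounds=20, n_samples=1, seed=9)
    exp = mt.generate_experiment(truth)
    run = exp.runs[0]
    run_b = mt.SampleRun("S2", run.scan_times.copy(),
                         [(m.copy(), x.copy()) for m, x in run.scans])
    run_a = mt.SampleRun("S1", run.scan_times.copy(),
                         [(m.copy(), x.copy()) for m, x in run.scans])
    return mt.run_pipeline([run_a, run_b])


def test_identity_single_sample_area_equals_composite_area():
    truth = mt.make_ground_truth(n_compounds=15, n_samples=1, seed=9)
    exp = mt.generate_experiment(truth)
    res = mt.run_pipeline(exp.runs)
    by_row = {t.row_id: p for t, p in res.composite_peaks}
    for f in res.table.features:
        assert f.areas[res.table.sample_ids[0]] == pytest.approx(
            by_row[f.row_id].area, rel=1e-12
        )


def test_two_identical_samples_split_composite_area_evenly(identical_pair_result):
    res = identical_pair_result
    by_row = {t.row_id: p for t, p in res.composite_peaks}
    for f in res.table.features:
        a1, a2 = f.areas["S1"], f.areas["S2"]
        assert a1 == pytest.approx(a2, rel=1e-12)
        assert a1 + a2 == pytest.approx(by_row[f.row_id].area, rel=1e-12)


def test_drifted_sample_area_matches_undrifted(drift_experiment, drift_result):
    """+-5 s drift: per-sample areas still track the truth within 5%."""
    exp, res = drift_experiment, drift_result
    hits = mt.match_features(res.table, exp.truth)
    assert len(hits) >= 95
    for ci, f in hits.items():
        for s, sid in enumerate(res.table.sample_ids):
            true = exp.true_areas[ci, s]
            if true > 0:
                assert f.areas[sid] == pytest.approx(true, rel=0.05)


def test_feature_mz_equals_grid_row_mz(drift_result):
    res = drift_result
    for f in res.table.features:
        assert f.mz == res.grid.grid_mz[f.row_id]
        # provenance: the row's member tracks agree with the feature m/z
        for sid, tid in res.grid.row_members(f.row_id).items():
            s = res.table.sample_ids.index(sid)
            track = res.per_sample_tracks[s][tid]
            assert abs(track.mz - f.mz) <= 5e-6 * f.mz


def test_single_sample_compound_has_exactly_one_nonzero_area():
    truth = mt.make_ground_truth(n_compounds=25, n_samples=5, seed=14)
    private = truth.compounds[7]
    private.present[:] = False
    private.present[3] = True
    private.heights[:] = 8e5
    exp = mt.generate_experiment(truth)
    res = mt.run_pipeline(exp.runs)
    hits = mt.match_features(res.table, truth)
    assert 7 in hits
    areas = hits[7].areas
    nonzero = [sid for sid, a in areas.items() if a > 0]
    assert nonzero == ["S4"]
    assert hits[7].detected["S4"]


class TestExport:
    def _tiny_table(self):
        f = mt.Feature("F1", 0, 300.0, 120.0, 110.0, 130.0,
                       0.99, 55.0, 1.0, 1.0,
                       areas={"a": 1e6, "b": 2e6}, detected={"a": True, "b": True})
        return mt.FeatureTable(sample_ids=["a", "b"], features=[f])

    def test_one_feature_two_samples_layout(self, tmp_path):
        path = tmp_path / "t.tsv"
        mt.export_table(self._tiny_table(), path)
        df = pd.read_csv(path, sep="\t")
        assert df.shape == (1, 11)
        assert list(df.columns[:9]) == [
            "feature_id", "mz", "rt_apex", "rt_left", "rt_right",
            "shape", "snr", "cselectivity", "mselectivity",
        ]
        assert list(df.columns[9:]) == ["a", "b"]

    def test_round_trip_numeric_equality(self, tmp_path):
        path = tmp_path / "t.tsv"
        table = self._tiny_table()
        mt.export_table(table, path)
        df = pd.read_csv(path, sep="\t")
        assert df.loc[0, "mz"] == pytest.approx(300.0, abs=1e-6)
        assert df.loc[0, "a"] == pytest.approx(1e6, abs=1e-6)

    def test_byte_identical_across_reruns(self, tmp_path):
        p1, p2 = tmp_path / "1.tsv", tmp_path / "2.tsv"
        mt.export_table(self._tiny_table(), p1)
        mt.export_table(self._tiny_table(), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_table_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            mt.export_table(mt.FeatureTable(["a"], []), tmp_path / "e.tsv")


class TestEmpiricalCompounds:
    def _table(self, specs):
        feats = [
            mt.Feature(f"F{i+1}", i, mz, rt, rt - 5, rt + 5, 0.9, 10.0, 1.0, 1.0)
            for i, (mz, rt) in enumerate(specs)
        ]
        return mt.FeatureTable(["s"], feats)

    def test_isotope_pair_groups(self):
        groups = mt.group_empirical_compounds(
            self._table([(180.0634, 120.0), (180.0634 + DELTA_C13, 120.0)])
        )
        assert sorted(map(len, groups.values())) == [2]

    def test_rt_gate_blocks_grouping(self):
        groups = mt.group_empirical_compounds(
            self._table([(180.0634, 120.0), (180.0634 + DELTA_C13, 200.0)])
        )
        assert sorted(map(len, groups.values())) == [1, 1]

    def test_m_m1_sodium_form_one_component(self):
        m = 180.0634
        groups = mt.group_empirical_compounds(
            self._table([(m, 120.0), (m + DELTA_C13, 120.0), (m + DELTA_NAH, 121.0),
                         (400.0, 120.0)])
        )
        sizes = sorted(map(len, groups.values()))
        assert sizes == [1, 3]
        # brute-force pairwise linkage oracle
        mzs = [m, m + DELTA_C13, m + DELTA_NAH, 400.0]
        rts = [120.0, 120.0, 121.0, 120.0]
        import itertools
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(range(4))
        for i, j in itertools.combinations(range(4), 2):
            d = abs(mzs[j] - mzs[i])
            if (abs(d - DELTA_C13) <= 5e-6 * max(mzs[i], mzs[j])
                    or abs(d - DELTA_NAH) <= 5e-6 * max(mzs[i], mzs[j])):
                if abs(rts[i] - rts[j]) <= 6.0:
                    g.add_edge(i, j)
        oracle_sizes = sorted(len(c) for c in nx.connected_components(g))
        assert sizes == oracle_sizes

    def test_json_export(self, tmp_path):
        groups = {"EC1": ["F1", "F2"], "EC2": ["F3"]}
        path = tmp_path / "ec.json"
        export_empirical_compounds(groups, path)
        import json
        assert json.loads(path.read_text()) == groups
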