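"""Gating: I/O, log transform, density clustering, bead calibration, size gate."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from cytotraits.gating import (
    EventTable, log_transform, back_transform, read_events, write_events,
    cluster_events, calibrate_size, size_gate, SizeCalibration,
)
from cytotraits.synthio import SynthConfig, generate_culture_events, generate_beads


def _two_clouds(n=2000, seed=0):
    """Two well-separated lognormal clouds, 10:1 intensity ratio."""
    rng = np.random.default_rng(seed)
    hi = np.exp(np.log([5000, 2000, 8000, 6000]) + rng.standard_normal((n, 4)) * 0.3)
    lo = np.exp(np.log([500, 200, 800, 600]) + rng.standard_normal((n, 4)) * 0.3)
    values = np.vstack([hi, lo])
    truth = np.r_[np.ones(n, int), np.zeros(n, int)]
    order = rng.permutation(2 * n)
    table = EventTable("clouds", ["FSC", "SSC", "FL670", "FL692"], values[order])
    return table, truth[order]


class TestIO:
    def test_csv_roundtrip(self, tmp_path):
        table = EventTable("s", ["FSC", "FL670"], [[1.0, 2.0], [3.5, 0.0], [2, 9]])
        path = write_events(table, tmp_path / "s.csv")
        back = read_events(path)
        assert back.channels == ["FSC", "FL670"]
        assert back.n_events == 3
        np.testing.assert_allclose(back.values, table.values)

    def test_negative_value_names_row_and_channel(self, tmp_path):
        pd.DataFrame({"FSC": [1.0, -2.0], "SSC": [1.0, 1.0]}).to_csv(
            tmp_path / "bad.csv", index=False
        )
        with pytest.raises(ValueError, match=r"row 1.*'FSC'"):
            read_events(tmp_path / "bad.csv")

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown format"):
            read_events(tmp_path / "x.lmd", format="lmd")


class TestLogTransform:
    def test_closed_forms(self):
        table = EventTable("s", ["a"], [[0.0], [999.0]])
        out = log_transform(table)
        assert out.values[0, 0] == 0.0
        assert out.values[1, 0] == pytest.approx(3.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_back_transform_is_inverse(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 1e5, size=(20, 3))
        table = EventTable("s", ["a", "b", "c"], vals)
        restored = back_transform(log_transform(table))
        np.testing.assert_allclose(restored.values, vals, rtol=1e-9, atol=1e-9)


class TestClustering:
    def test_two_clouds_recovered_and_bright_selected(self):
        table, truth = _two_clouds()
        gated = cluster_events(log_transform(table))
        labels = gated.cluster_labels
        core = labels >= 0
        assert adjusted_rand_score(truth[core], labels[core]) >= 0.95
        # the selected population is the high-FL670 cloud
        assert truth[gated.member_index].mean() > 0.99

    def test_synthio_debris_fraction_gated_out(self, small_config):
        table, truth = generate_culture_events(
            small_config, "control", 0, return_truth=True
        )
        gated = cluster_events(log_transform(table))
        frac = gated.n_members / table.n_events
        assert abs(frac - 0.90) <= 0.03
        assert truth[gated.member_index].mean() > 0.98

    def test_single_cloud_kept_whole(self, rng):
        vals = np.exp(np.log([1000, 500, 2000, 1500]) +
                      rng.standard_normal((3000, 4)) * 0.25)
        table = EventTable("one", ["FSC", "SSC", "FL670", "FL692"], vals)
        gated = cluster_events(log_transform(table))
        assert gated.n_members >= 0.95 * table.n_events

    def test_shuffle_invariance_of_member_identity(self, rng):
        table, _ = _two_clouds(seed=3)
        perm = rng.permutation(table.n_events)
        shuffled = EventTable("sh", table.channels, table.values[perm])
        g1 = cluster_events(log_transform(table))
        g2 = cluster_events(log_transform(shuffled))
        ids1 = set(g1.member_index.tolist())
        ids2 = {int(perm[i]) for i in g2.member_index}
        overlap = len(ids1 & ids2) / len(ids1 | ids2)
        assert overlap >= 0.99

    def test_duplicated_events_select_same_population(self):
        table, _ = _two_clouds(n=1000, seed=4)
        doubled = EventTable(
            "dup", table.channels, np.vstack([table.values, table.values])
        )
        g1 = cluster_events(log_transform(table))
        g2 = cluster_events(log_transform(doubled))
        ids1 = set(g1.member_index.tolist())
        ids2 = {int(i % table.n_events) for i in g2.member_index}
        overlap = len(ids1 & ids2) / len(ids1 | ids2)
        assert overlap >= 0.95

    def test_no_population_found(self):
        table = EventTable("tiny", ["FSC", "SSC", "FL670", "FL692"],
                           np.ones((30, 4)))
        with pytest.raises(ValueError, match="no target population"):
            cluster_events(table, min_cluster_size=500)


class TestSizeCalibration:
    def test_log_linear_interpolation_closed_form(self, small_config):
        """FSC 100 -> 1 um and 10,000 -> 10 um imply FSC 1,000 -> ~3.16 um."""
        rng = np.random.default_rng(0)
        vals = np.ones((1000, 4)) * 50.0
        fsc = np.r_[100 * np.exp(rng.standard_normal(500) * 0.02),
                    10_000 * np.exp(rng.standard_normal(500) * 0.02)]
        vals[:, 0] = fsc
        beads = EventTable("beads", ["FSC", "SSC", "FL670", "FL692"], vals)
        cal = calibrate_size(beads, [1.0, 10.0])
        assert cal.size_um(np.array([1000.0]))[0] == pytest.approx(3.162, rel=0.03)

    def test_two_points_zero_residual(self, small_config):
        beads = generate_beads([1.0, 10.0], small_config)
        cal = calibrate_size(beads, [1.0, 10.0])
        # the fitted line passes through both (logFSC, log size) pairs
        for s in (1.0, 10.0):
            fsc_mode = 100.0 * s ** 2
            assert cal.size_um(np.array([fsc_mode]))[0] == pytest.approx(s, rel=0.02)

    def test_swapped_sizes_rejected(self, small_config):
        beads = generate_beads([1.0, 10.0], small_config)
        with pytest.raises(ValueError, match="monotone|increasing"):
            calibrate_size(beads, [10.0, 1.0])


class TestSizeGate:
    cal = SizeCalibration(slope=0.5, intercept=-1.0)  # size = sqrt(FSC)/10

    def _table(self, fsc):
        vals = np.ones((len(fsc), 2))
        vals[:, 0] = fsc
        return EventTable("s", ["FSC", "FL670"], vals)

    def test_boundaries_inclusive(self):
        # sizes exactly 0.5 and 10 um <=> FSC 25 and 10,000
        table = self._table([25.0, 10_000.0, 40_000.0])
        gate = size_gate(table, self.cal, 0.5, 10.0)
        assert gate.member_index.tolist() == [0, 1]

    def test_empty_gate_warns(self):
        table = self._table([40_000.0, 90_000.0])  # 20 and 30 um
        with pytest.warns(UserWarning, match="retained no events"):
            gate = size_gate(table, self.cal, 0.5, 10.0)
        assert gate.n_members == 0

    def test_ground_truth_subset_recovered(self, rng):
        fsc = np.r_[rng.uniform(30, 9000, 300), rng.uniform(50_000, 90_000, 100)]
        table = self._table(fsc)
        gate = size_gate(table, self.cal, 0.5, 10.0)
        assert set(gate.member_index.tolist()) == set(range(300))
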