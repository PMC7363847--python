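"""Event-table ingestion, filtering, gating, subsampling and anchoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cellcognize as cc
from cellcognize.fcm import (
    LOG10,
    PARAMETERS,
    ConfigError,
    EmptyTableError,
    FormatError,
)
from conftest import log_events


def write_csv(tmp_path, df, name="events.csv"):
    path = tmp_path / name
    df.to_csv(path, index=False)
    return path


class TestReadEventTable:
    def test_reads_all_events(self, tmp_path, raw_table):
        path = write_csv(tmp_path, raw_table.data)
        table = cc.read_event_table(path)
        assert table.n_events == 4
        assert table.scale == "raw"
        np.testing.assert_allclose(table.values, raw_table.values)

    def test_negative_events_dropped_with_warning(self, tmp_path, raw_table):
        df = raw_table.data.copy()
        df.loc[1, "FSC-H"] = -5.0
        path = write_csv(tmp_path, df)
        with pytest.warns(UserWarning, match="negative"):
            table = cc.read_event_table(path)
        assert table.n_events == 3

    def test_missing_column_names_the_column(self, tmp_path, raw_table):
        df = raw_table.data.drop(columns=["Width"])
        path = write_csv(tmp_path, df)
        with pytest.raises(FormatError, match="Width"):
            cc.read_event_table(path)

    def test_extra_columns_ignored(self, tmp_path, raw_table):
        df = raw_table.data.copy()
        df["Time"] = np.arange(len(df))
        path = write_csv(tmp_path, df)
        assert cc.read_event_table(path).n_events == 4

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(EmptyTableError):
            cc.read_event_table(path)

    def test_fcs_unsupported(self, tmp_path):
        with pytest.raises(NotImplementedError):
            cc.read_event_table(tmp_path / "x.fcs", format="fcs")

    def test_roundtrip_preserves_values(self, tmp_path, raw_table):
        path = tmp_path / "rt.csv"
        cc.write_event_table(raw_table, path)
        back = cc.read_event_table(path)
        # 12 significant digits
        np.testing.assert_allclose(back.values, raw_table.values, rtol=1e-12)


class TestPreprocess:
    def test_window_filter_on_one_parameter(self):
        data = pd.DataFrame(
            {p: [500.0, 500.0, 500.0, 500.0] for p in PARAMETERS}
        )
        data["FITC-H"] = [50.0, 150.0, 2000.0, 1e8]
        raw = cc.EventTable(data=data, scale="raw")
        out = cc.preprocess(raw, cc.FilterSpec(lower=100, upper=1e7))
        assert out.n_events == 2
        np.testing.assert_allclose(
            out.data["FITC-H"], np.log10([150.0, 2000.0])
        )

    def test_log10_of_lower_bound(self):
        data = pd.DataFrame({p: [100.0] for p in PARAMETERS})
        out = cc.preprocess(cc.EventTable(data=data), cc.FilterSpec())
        assert out.scale == LOG10
        np.testing.assert_array_equal(out.values, np.full((1, 7), 2.0))

    def test_out_of_bounds_on_single_parameter_removes_event(self):
        data = pd.DataFrame({p: [500.0] for p in PARAMETERS})
        data["Width"] = [50.0]  # below lower bound on one parameter only
        out = cc.preprocess(cc.EventTable(data=data), cc.FilterSpec())
        assert out.n_events == 0

    def test_all_removed_warns_not_raises(self):
        data = pd.DataFrame({p: [1.0] for p in PARAMETERS})
        with pytest.warns(UserWarning, match="removed all"):
            out = cc.preprocess(cc.EventTable(data=data), cc.FilterSpec())
        assert out.n_events == 0

    def test_metadata_preserved(self, raw_table):
        raw_table.analyzed_volume_ul = 17.0
        raw_table.dilution_factor = 5.0
        out = cc.preprocess(raw_table, cc.FilterSpec())
        assert out.analyzed_volume_ul == 17.0
        assert out.dilution_factor == 5.0

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_filter_never_increases_count_and_bounds_hold(self, seed):
        rng = np.random.default_rng(seed)
        data = pd.DataFrame(
            rng.uniform(1.0, 1e8, size=(50, 7)), columns=list(PARAMETERS)
        )
        spec = cc.FilterSpec(lower=100, upper=1e6)
        raw = cc.EventTable(data=data)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            out = cc.preprocess(raw, spec)
        assert out.n_events <= raw.n_events
        if out.n_events:
            assert np.all(out.values >= spec.log_lower - 1e-12)
            assert np.all(out.values <= spec.log_upper + 1e-12)


class TestGating:
    def make_log_table(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        return log_events(rng.uniform(2.0, 6.0, size=(n, 7)))

    def test_full_range_gate_keeps_everything(self):
        table = self.make_log_table()
        gate = cc.GateBox(
            bounds={p: (2.0, 6.0) for p in cc.GATE_PARAMETERS}, label="all"
        )
        ds = cc.apply_gate(table, gate)
        assert ds.n_events == table.n_events

    def test_small_fraction_warns_but_returns_events(self):
        values = np.full((100, 7), 4.0)
        values[:4, 1] = 3.0  # 4 events moved into the box on FITC-H
        table = log_events(values)
        gate = cc.GateBox(
            bounds={"FITC-H": (2.5, 3.5)}, label="sub", min_fraction=0.05
        )
        with pytest.warns(UserWarning, match="below"):
            ds = cc.apply_gate(table, gate)
        assert ds.n_events == 4

    def test_boundary_events_included(self):
        values = np.full((1, 7), 3.0)
        table = log_events(values)
        gate = cc.GateBox(bounds={"FITC-H": (3.0, 4.0)}, label="edge",
                          min_fraction=0.05)
        assert cc.apply_gate(table, gate).n_events == 1

    def test_non_gating_axis_rejected(self):
        with pytest.raises(ConfigError, match="FITC-A"):
            cc.GateBox(bounds={"FITC-A": (2.0, 3.0)}, label="bad")

    def test_first_matching_gate_wins(self):
        values = np.full((10, 7), 3.0)
        table = log_events(values)
        g1 = cc.GateBox(bounds={"FITC-H": (2.0, 4.0)}, label="first")
        g2 = cc.GateBox(bounds={"FITC-H": (2.5, 3.5)}, label="second")
        with pytest.warns(UserWarning):  # second gate captures nothing
            parts = cc.partition_by_gates(table, [g1, g2])
        assert parts["first"].n_events == 10
        assert parts["second"].n_events == 0


class TestSubsample:
    def make_standard(self, n=300, seed=3):
        rng = np.random.default_rng(seed)
        return cc.StandardDataset(
            standard_name="S", events=log_events(rng.uniform(2, 6, size=(n, 7)))
        )

    def test_exact_count_without_replacement(self):
        ds = cc.subsample_events(self.make_standard(300), 100, seed=0)
        assert ds.n_events == 100
        assert len(np.unique(ds.events.values, axis=0)) == 100

    def test_same_seed_reproduces(self):
        std = self.make_standard()
        a = cc.subsample_events(std, 50, seed=9)
        b = cc.subsample_events(std, 50, seed=9)
        np.testing.assert_array_equal(a.events.values, b.events.values)

    def test_shortfall_returns_all_with_warning(self):
        std = self.make_standard(80)
        with pytest.warns(UserWarning, match="available"):
            ds = cc.subsample_events(std, 100, seed=0)
        assert ds.n_events == 80

    def test_subsample_of_gated_is_subset(self):
        std = self.make_standard(200)
        sub = cc.subsample_events(std, 60, seed=4)
        full_rows = {tuple(r) for r in std.events.values}
        assert all(tuple(r) in full_rows for r in sub.events.values)


class TestAnchors:
    def test_anchor_rows_at_log_bounds(self):
        std = cc.StandardDataset(
            standard_name="S", events=log_events(np.full((5, 7), 3.0))
        )
        spec = cc.FilterSpec(lower=100, upper=1e5)
        out = cc.add_anchors(std, spec)
        assert out.n_events == 7
        np.testing.assert_array_equal(out.events.values[-2], np.full(7, 2.0))
        np.testing.assert_array_equal(out.events.values[-1], np.full(7, 5.0))
        assert out.anchor_mask.sum() == 2
        assert not out.anchor_mask[:-2].any()

    def test_idempotent_with_warning(self):
        std = cc.StandardDataset(
            standard_name="S", events=log_events(np.full((5, 7), 3.0))
        )
        once = cc.add_anchors(std, cc.FilterSpec())
        with pytest.warns(UserWarning, match="already present"):
            twice = cc.add_anchors(once, cc.FilterSpec())
        assert twice.n_events == once.n_events == 7

    def test_scaling_constants_independent_of_data(self):
        spec = cc.FilterSpec()
        rng = np.random.default_rng(0)
        mk = lambda lo, hi, seed: [
            cc.StandardDataset(
                standard_name=f"S{i}",
                events=log_events(
                    np.random.default_rng(seed + i).uniform(lo, hi, (50, 7))
                ),
            )
            for i in range(2)
        ]
        asm1 = cc.assemble_training_set(mk(3.0, 4.0, 1), 50, spec, seed=0)
        asm2 = cc.assemble_training_set(mk(4.5, 6.5, 7), 50, spec, seed=0)
        np.testing.assert_array_equal(asm1.scaling[0], asm2.scaling[0])
        np.testing.assert_array_equal(asm1.scaling[1], asm2.scaling[1])
        np.testing.assert_array_equal(asm1.scaling[0], spec.log_lower)
        np.testing.assert_array_equal(asm1.scaling[1], spec.log_upper)
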