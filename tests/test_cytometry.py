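"""Event I/O, density gating, and size-conditioned medians."""

import math

import numpy as np
import pandas as pd
import pytest

from contextgates import (
    DataError,
    EventTable,
    FormatError,
    NoiseModel,
    choose_scatter_reference,
    read_events,
    scatter_gate,
    simulate_events,
    size_conditioned_median,
)
from contextgates.synthetic_data import GateTruth, SensorMap


def table(fsc, ssc=None, fl1=None, **meta) -> EventTable:
    fsc = np.asarray(fsc, dtype=float)
    return EventTable(
        fsc=fsc,
        ssc=np.asarray(ssc, dtype=float) if ssc is not None else fsc * 0.6,
        fluorescence=np.asarray(fl1, dtype=float) if fl1 is not None else np.ones_like(fsc),
        metadata=meta,
    )


class TestReadWrite:
    def test_csv_roundtrip_identity(self, tmp_path):
        t = table([10.0, 20.0, 30.0], fl1=[1.5, -0.5, 2.0], role="gate", iptg_uM=40.0)
        path = t.to_csv(tmp_path / "sample.csv")
        back = read_events(path)
        assert len(back) == 3
        assert np.array_equal(back.fsc, t.fsc)
        assert np.array_equal(back.fluorescence, t.fluorescence)
        assert back.metadata == {"role": "gate", "iptg_uM": 40.0}

    def test_missing_channel_column_named_in_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"FSC": [1.0], "SSC": [1.0]}).to_csv(p, index=False)
        with pytest.raises(FormatError, match="FL1"):
            read_events(p)

    def test_empty_file_is_data_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        pd.DataFrame(columns=["FSC", "SSC", "FL1"]).to_csv(p, index=False)
        with pytest.raises(DataError):
            read_events(p)

    def test_fcs_format_unsupported(self, tmp_path):
        with pytest.raises(FormatError, match="CSV"):
            read_events(tmp_path / "x.fcs", format="fcs")

    def test_custom_channel_mapping(self, tmp_path):
        p = tmp_path / "renamed.csv"
        pd.DataFrame({"FSC-A": [2.0], "SSC-A": [1.0], "B1-A": [7.0]}).to_csv(p, index=False)
        t = read_events(p, channels={"fsc": "FSC-A", "ssc": "SSC-A", "fluorescence": "B1-A"})
        assert t.fluorescence[0] == 7.0


class TestEventTableInvariants:
    def test_rejects_length_mismatch(self):
        with pytest.raises(DataError):
            EventTable(fsc=[1.0, 2.0], ssc=[1.0], fluorescence=[1.0, 2.0])

    def test_rejects_nonpositive_scatter(self):
        with pytest.raises(DataError):
            table([1.0, 0.0])

    def test_negative_fluorescence_allowed(self):
        assert table([1.0], fl1=[-5.0]).fluorescence[0] == -5.0


class TestScatterGate:
    def test_full_coverage_is_identity(self):
        t = table(np.linspace(1, 100, 50))
        assert scatter_gate(t, 1.0) is t

    def test_unimodal_coverage_half(self):
        rng = np.random.default_rng(0)
        fsc = np.exp(rng.normal(3, 0.4, 20000))
        ssc = fsc * np.exp(rng.normal(0, 0.2, 20000))
        t = EventTable(fsc=fsc, ssc=ssc, fluorescence=np.zeros(20000))
        gated = scatter_gate(t, 0.5)
        frac = len(gated) / len(t)
        assert 0.5 <= frac <= 1.0
        assert gated.fsc.std() <= t.fsc.std()

    def test_two_clusters_keeps_denser_one(self):
        # 70% tight cluster near (100, 60), 30% near (1000, 600): at 50%
        # coverage every retained event must come from the dense cluster.
        rng = np.random.default_rng(1)
        dense = 100 + rng.normal(0, 2, 7000)
        sparse = 1000 + rng.normal(0, 2, 3000)
        fsc = np.concatenate([dense, sparse])
        t = EventTable(fsc=fsc, ssc=fsc * 0.6, fluorescence=np.zeros(10000))
        gated = scatter_gate(t, 0.5)
        assert len(gated) >= 5000
        assert gated.fsc.max() < 500

    def test_rejects_bad_coverage(self):
        t = table([1.0, 2.0])
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                scatter_gate(t, bad)


class TestSizeConditionedMedian:
    def test_linear_coupling_recovers_reference_signal(self):
        # fluorescence = 2 x FSC exactly: conditioning at FSC=10 gives ~20
        rng = np.random.default_rng(2)
        fsc = rng.uniform(1, 30, 5000)
        t = EventTable(fsc=fsc, ssc=fsc, fluorescence=2 * fsc)
        s = size_conditioned_median(t, scatter_reference=10.0, window_halfwidth=0.5, min_events=10)
        assert s.median_fluorescence == pytest.approx(20.0, abs=1.0)
        assert s.n_events_used < len(t)

    def test_infinite_window_is_plain_median(self):
        t = table([1.0, 2.0, 3.0, 4.0], fl1=[5.0, 1.0, 9.0, 7.0])
        s = size_conditioned_median(t, 2.0, math.inf, min_events=1)
        assert s.median_fluorescence == np.median(t.fluorescence)
        assert s.gating_coverage == 1.0

    def test_too_few_events_suggests_wider_window(self):
        t = table(np.linspace(1, 100, 200))
        with pytest.raises(DataError, match="widen"):
            size_conditioned_median(t, 50.0, 0.1, min_events=100)

    def test_invariant_to_event_order(self):
        rng = np.random.default_rng(3)
        fsc = rng.uniform(1, 10, 1000)
        fl1 = rng.normal(50, 5, 1000)
        t = EventTable(fsc=fsc, ssc=fsc, fluorescence=fl1)
        perm = rng.permutation(1000)
        t2 = EventTable(fsc=fsc[perm], ssc=fsc[perm], fluorescence=fl1[perm])
        a = size_conditioned_median(t, 5.0, 2.0, min_events=10)
        b = size_conditioned_median(t2, 5.0, 2.0, min_events=10)
        assert a.median_fluorescence == b.median_fluorescence
        assert a.n_events_used == b.n_events_used


class TestScatterReference:
    def test_constant_scatter(self):
        assert choose_scatter_reference([table([5.0, 5.0, 5.0])]) == 5.0

    def test_matches_histogram_mode_oracle(self):
        rng = np.random.default_rng(4)
        fsc = np.exp(rng.normal(3, 0.3, 10000))
        ref = choose_scatter_reference([table(fsc)], bins=64)
        counts, edges = np.histogram(fsc, bins=64)
        i = int(np.argmax(counts))
        assert edges[i] <= ref <= edges[i + 1]

    def test_reference_lies_in_denser_sample(self):
        dense = table(np.random.default_rng(5).uniform(10, 20, 9000))
        sparse = table(np.random.default_rng(6).uniform(100, 200, 1000))
        ref = choose_scatter_reference([dense, sparse])
        assert 10 <= ref <= 20

    def test_empty_pool_rejected(self):
        with pytest.raises(DataError):
            choose_scatter_reference([])


def test_size_conditioning_stabilizes_medians_across_cell_sizes():
    """With size-coupled fluorescence, medians conditioned at a common
    scatter value vary less across samples than plain medians do."""
    truth = GateTruth(
        gate_name="PhlF-P1", repressor_family="PhlF",
        ymin_true=0.1, ymax_true=2.0, k_true=0.2, n_true=2.0,
    )
    sensor = SensorMap.default()
    plain, conditioned = [], []
    # same biology measured on days with different cell-size distributions
    for i, size in enumerate((3e4, 4e4, 5e4, 6e4)):
        noise = NoiseModel(sigma_lognormal=0.05, scatter_mean=size, scatter_sigma=0.3, size_coupling=1.0)
        ev = simulate_events(truth, sensor, 0.0, 20000, noise, seed=10 + i)
        plain.append(np.median(ev.fluorescence))
        s = size_conditioned_median(ev, scatter_reference=4.5e4, window_halfwidth=8e3, min_events=100)
        conditioned.append(s.median_fluorescence)
    rel_sd = lambda v: np.std(v) / np.mean(v)  # noqa: E731
    assert rel_sd(conditioned) < rel_sd(plain)
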