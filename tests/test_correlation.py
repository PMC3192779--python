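"""Spearman ranking, signature selection, cutoff sweeps and optimum choice."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import receptorsig as rs
from receptorsig.data import DataError

from conftest import make_matrix


def spearman_oracle(x, y):
    """Brute-force rank correlation: explicit mid-ranks + Pearson formula."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return stats.pearsonr(rx, ry).statistic


class TestSpearmanVsStatus:
    def test_hand_computed_example(self, tiny_matrix):
        table = rs.spearman_vs_status(tiny_matrix, [0, 0, 1, 1])
        assert table.entries["a"] == pytest.approx(0.8944, abs=1e-4)
        assert table.entries["b"] == pytest.approx(-0.8944, abs=1e-4)

    def test_constant_probe_excluded(self, tiny_matrix):
        table = rs.spearman_vs_status(tiny_matrix, [0, 0, 1, 1])
        assert table.excluded_probes == ("c",)
        assert "c" not in table.entries

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            n = int(rng.integers(4, 30))
            labels = np.zeros(n, dtype=int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.min() == labels.max():
                continue
            values = np.round(rng.normal(size=(5, n)), 1)  # ties likely
            expr = make_matrix(values)
            table = rs.spearman_vs_status(expr, labels)
            for i, probe in enumerate(expr.probe_ids):
                if probe in table.entries:
                    assert table.entries[probe] == pytest.approx(
                        spearman_oracle(values[i], labels), abs=1e-12
                    )

    def test_label_flip_negates_every_rho(self):
        rng = np.random.default_rng(12)
        expr = make_matrix(rng.normal(size=(6, 15)))
        labels = (rng.random(15) < 0.5).astype(int)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        t1 = rs.spearman_vs_status(expr, labels)
        t2 = rs.spearman_vs_status(expr, 1 - labels)
        for probe, rho in t1.entries.items():
            assert t2.entries[probe] == pytest.approx(-rho, abs=1e-12)

    def test_single_class_rejected(self, tiny_matrix):
        with pytest.raises(DataError, match="both status classes"):
            rs.spearman_vs_status(tiny_matrix, [1, 1, 1, 1])


class TestSelectSignature:
    TABLE = rs.CorrelationTable({"a": 0.50, "b": 0.44, "c": -0.46, "d": 0.20}, 10)

    def test_threshold_on_absolute_rho(self):
        sig = rs.select_signature(self.TABLE, 0.45, "ER")
        assert set(sig.probe_ids) == {"a", "c"}

    def test_inclusive_bound_retains_all(self):
        sig = rs.select_signature(self.TABLE, 0.19, "ER")
        assert set(sig.probe_ids) == {"a", "b", "c", "d"}

    def test_empty_selection_names_cutoff(self):
        with pytest.raises(DataError, match="0.9"):
            rs.select_signature(self.TABLE, 0.9, "ER")

    @settings(derandomize=True, max_examples=50)
    @given(
        rhos=st.lists(st.floats(-1, 1, allow_nan=False), min_size=1, max_size=20),
        c1=st.floats(0.01, 0.98),
        c2=st.floats(0.01, 0.98),
    )
    def test_nesting_higher_cutoff_is_subset(self, rhos, c1, c2):
        lo, hi = sorted([c1, c2])
        table = rs.CorrelationTable({f"p{i}": r for i, r in enumerate(rhos)}, 10)
        try:
            sig_hi = rs.select_signature(table, hi, "ER")
        except DataError:
            return  # empty at the higher cutoff: nesting holds vacuously
        sig_lo = rs.select_signature(table, lo, "ER")
        assert set(sig_hi.probe_ids) <= set(sig_lo.probe_ids)


def midpoint_predictor(expr, sig):
    """Independent scorer: threshold the sign-aligned marker mean at its midpoint."""
    values = expr.frame.loc[sig.probe_ids].to_numpy()
    score = (np.sign(sig.rhos)[:, None] * values).mean(axis=0)
    return (score > (score.min() + score.max()) / 2).astype(int)


class TestSweepAndOptimum:
    def test_one_point_grid(self, synthetic_pair):
        (expr, clin, truth), _ = synthetic_pair
        labels = clin.binary_labels().to_numpy()
        points = rs.sweep(expr, labels, [0.5], midpoint_predictor)
        assert len(points) == 1 and points[0].n_probes == len(truth.planted_signature)

    def test_monotone_probe_counts_and_empty_points_kept(self, synthetic_pair):
        (expr, clin, _), _ = synthetic_pair
        labels = clin.binary_labels().to_numpy()
        grid = [0.1, 0.3, 0.5, 0.7, 0.95]
        points = rs.sweep(expr, labels, grid, midpoint_predictor)
        counts = [p.n_probes for p in points]
        assert counts == sorted(counts, reverse=True)
        assert points[-1].n_probes == 0 and np.isnan(points[-1].sensitivity)

    def test_planted_markers_hit_the_sweep_maximum(self, synthetic_pair):
        (expr, clin, truth), _ = synthetic_pair
        labels = clin.binary_labels().to_numpy()
        grid = [0.2, 0.4, 0.6]
        points = rs.sweep(expr, labels, grid, midpoint_predictor)
        best = max(p.sum_sens_spec for p in points if p.valid)
        corr = rs.spearman_vs_status(expr, labels)
        planted = set(truth.planted_signature.probe_ids)
        for p in points:
            if not p.valid:
                continue
            selected = set(rs.select_signature(corr, p.cutoff, "ER").probe_ids)
            if selected == planted:
                assert p.sum_sens_spec == pytest.approx(best)

    def test_choose_optimal_argmax(self):
        pts = [
            rs.SweepPoint(0.42, 40, 85.0, 85.1),
            rs.SweepPoint(0.43, 35, 90.6, 90.7),
            rs.SweepPoint(0.44, 30, 87.0, 88.0),
        ]
        assert rs.choose_optimal(pts) == 0.43

    def test_choose_optimal_tie_breaks_to_larger_cutoff(self):
        pts = [
            rs.SweepPoint(0.38, 40, 90.0, 90.0),
            rs.SweepPoint(0.39, 35, 85.0, 85.0),
            rs.SweepPoint(0.40, 30, 90.0, 90.0),
        ]
        assert rs.choose_optimal(pts) == 0.40

    def test_flat_primary_requires_secondary(self):
        flat = [rs.SweepPoint(c, 10, 90.0, 90.0) for c in (0.34, 0.36, 0.38)]
        with pytest.raises(DataError, match="second training set"):
            rs.choose_optimal(flat)

    def test_flat_primary_resolved_by_secondary(self):
        flat = [rs.SweepPoint(c, 10, 90.0, 90.0) for c in (0.34, 0.35, 0.36)]
        secondary = [
            rs.SweepPoint(0.34, 12, 80.0, 80.0),
            rs.SweepPoint(0.35, 10, 88.0, 89.0),
            rs.SweepPoint(0.36, 8, 82.0, 83.0),
        ]
        assert rs.choose_optimal(flat, secondary) == 0.35


class TestBestProbe:
    def test_argmax_of_signed_rho(self):
        table = rs.CorrelationTable({"a": 0.50, "b": 0.45, "c": -0.9}, 10)
        assert rs.best_probe(table) == "a"

    def test_tie_breaks_lexicographically(self):
        table = rs.CorrelationTable({"b": 0.4, "a": 0.4}, 10)
        assert rs.best_probe(table) == "a"
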