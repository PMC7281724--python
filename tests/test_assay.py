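import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spiralsort.assay import (
    AssayError,
    ParticleClass,
    UndefinedMetricError,
    bead_classes,
    blood_cell_classes,
    fabrication_error,
    recovery_rate,
    run_separation_assay,
    sample_sizes,
    viability_rate,
    volume_fraction_check,
)
from spiralsort.geometry import OutletChannel, OutletManifold


class TestSampling:
    def test_draws_respect_printed_range(self):
        dc = ParticleClass("DC", 10.0, 15.0, 0)
        sizes = sample_sizes(dc, 10_000, 42)
        assert sizes.shape == (10_000,)
        assert sizes.min() >= 10.0 and sizes.max() <= 15.0
        # truncated normal centred on the midpoint
        assert sizes.mean() == pytest.approx(12.5, abs=0.05)

    def test_empty_and_deterministic(self):
        rbc = ParticleClass("RBC", 6.0, 7.0, 0)
        assert sample_sizes(rbc, 0, 1).size == 0
        a = sample_sizes(rbc, 100, 123)
        b = sample_sizes(rbc, 100, 123)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, sample_sizes(rbc, 100, 124))

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(low_um=0.5, high_um=7.0),   # support below 1 um
            dict(low_um=6.0, high_um=31.0),  # support above 30 um
            dict(low_um=7.0, high_um=6.0),
            dict(low_um=6.0, high_um=7.0, sd_um=-1.0),
            dict(low_um=6.0, high_um=7.0, viable_fraction=1.5),
        ],
    )
    def test_invalid_class_rejected(self, kwargs):
        with pytest.raises(AssayError):
            ParticleClass("bad", count=10, **kwargs)


class TestMetrics:
    def test_recovery_rate_worked_example(self):
        # 772 of 1000 dendritic cells at Outlet 1 -> 77.2%
        labels = ("DC",)
        counts = np.array([[772, 100, 80, 48]])
        from spiralsort.assay import RecoveryMatrix

        m = RecoveryMatrix(labels, counts, np.zeros_like(counts))
        assert recovery_rate(m, "DC", 1) == pytest.approx(0.772)
        assert sum(recovery_rate(m, "DC", j) for j in range(1, 5)) == pytest.approx(1.0)
        assert m.modal_outlet("DC") == 1

    def test_recovery_undefined_for_empty_class(self):
        from spiralsort.assay import RecoveryMatrix

        m = RecoveryMatrix(("X",), np.zeros((1, 4), int), np.zeros((1, 4), int))
        with pytest.raises(UndefinedMetricError):
            recovery_rate(m, "X", 1)

    def test_viability_rate(self):
        assert viability_rate(0, 100) == 0.0
        assert viability_rate(100, 100) == 1.0
        assert viability_rate(818, 1000) == pytest.approx(0.818)
        with pytest.raises(UndefinedMetricError):
            viability_rate(0, 0)
        with pytest.raises(AssayError):
            viability_rate(5, 4)

    @pytest.mark.parametrize(
        "desired, fabricated, expected",
        [(200, 208, 4.0), (200, 193, 3.5), (400, 390, 2.5),
         (400, 412, 3.0), (600, 589, 1.8), (600, 608, 1.3), (250, 250, 0.0)],
    )
    def test_fabrication_error(self, desired, fabricated, expected):
        assert fabrication_error(desired, fabricated) == expected

    def test_volume_fraction_check(self):
        assert volume_fraction_check([], 1.0) == (0.0, False)
        # 10-um spheres: v = pi/6 * 1e-9 mm^3 each; 1 mL = 1e3 mm^3
        n_for_2pct = int(0.02 * 1e3 / (np.pi / 6 * 1e-9))
        ok = ParticleClass("beads", 9.9, 10.1, n_for_2pct, mean_um=10.0)
        frac, degraded = volume_fraction_check([ok], 1.0)
        assert frac == pytest.approx(0.02, rel=1e-3) and not degraded
        crowded = ParticleClass("beads", 9.9, 10.1, int(n_for_2pct * 2.5), mean_um=10.0)
        frac, degraded = volume_fraction_check([crowded], 1.0)
        assert frac == pytest.approx(0.05, rel=1e-3) and degraded


class TestSeparationAssay:
    def test_bead_mixture_routes_by_size(self, geom, manifold, fluid, model):
        beads = bead_classes(count=300)
        m = run_separation_assay(beads, geom, manifold, fluid, 1.8, model, seed=5)
        # 15 um -> Outlet 1, 10 um -> Outlet 2, 7 um -> Outlet 3
        assert m.modal_outlet("bead15") == 1
        assert m.modal_outlet("bead10") == 2
        assert m.modal_outlet("bead7") == 3
        for label in m.labels:
            assert m.class_total(label) == 300  # conservation

    def test_single_dominant_window_collects_everything(self, geom, fluid, model):
        # outlet 1 carries ~all the conductance -> its window spans the width
        manifold = OutletManifold(
            (OutletChannel(1, 300, 100, 1e-6), OutletChannel(2, 300, 100, 1e6))
        )
        cls = ParticleClass("WBC", 8.0, 11.0, 400)
        m = run_separation_assay([cls], geom, manifold, fluid, 1.8, model, seed=3)
        assert recovery_rate(m, "WBC", 1) == 1.0

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, derandomize=True, deadline=None)
    def test_counts_conserved_on_random_runs(self, geom, manifold, fluid, model, seed):
        rng = np.random.default_rng(seed)
        classes = [
            ParticleClass(f"c{i}", lo, lo + rng.uniform(0.5, 3.0), int(rng.integers(1, 80)))
            for i, lo in enumerate(rng.uniform(5, 12, size=2))
        ]
        q = float(rng.uniform(1.0, 2.4))
        m = run_separation_assay(classes, geom, manifold, fluid, q, model, seed=seed, n_steps=1500)
        assert m.counts.sum() == sum(c.count for c in classes)
        for c in classes:
            assert m.class_total(c.label) == c.count

    def test_seeded_runs_bit_reproducible(self, geom, manifold, fluid, model):
        classes = blood_cell_classes(count=200)
        a = run_separation_assay(classes, geom, manifold, fluid, 1.9, model, seed=11, n_steps=1000)
        b = run_separation_assay(classes, geom, manifold, fluid, 1.9, model, seed=11, n_steps=1000)
        c = run_separation_assay(classes, geom, manifold, fluid, 1.9, model, seed=12, n_steps=1000)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.viable_counts, b.viable_counts)
        assert not np.array_equal(a.counts, c.counts) or not np.array_equal(
            a.viable_counts, c.viable_counts
        )

    def test_overlapping_size_ranges_reduce_dc_recovery(self, geom, manifold, fluid, model):
        tight = run_separation_assay(
            blood_cell_classes(2000), geom, manifold, fluid, 1.9, model, seed=21
        )
        overlap = run_separation_assay(
            blood_cell_classes(2000, overlap=True), geom, manifold, fluid, 1.9, model, seed=21
        )
        assert recovery_rate(overlap, "DC", 1) < recovery_rate(tight, "DC", 1)

    def test_viability_annotation_tracks_input_fraction(self, geom, manifold, fluid, model):
        classes = blood_cell_classes(count=3000, viable_fraction=0.85)
        m = run_separation_assay(classes, geom, manifold, fluid, 1.9, model, seed=2)
        viab = [m.viability(j) for j in (1, 2, 3) if m.counts[:, j - 1].sum() > 0]
        assert all(abs(v - 0.85) < 0.05 for v in viab)

    def test_to_frame_schema(self, geom, manifold, fluid, model):
        m = run_separation_assay(bead_classes(50), geom, manifold, fluid, 1.8, model, seed=1, n_steps=1000)
        df = m.to_frame()
        assert list(df.columns) == ["class", "outlet", "count", "recovery"]
        assert len(df) == 3 * 4
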