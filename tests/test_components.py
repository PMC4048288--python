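"""Component planes, correlation, silhouettes, partitioning and FRI."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from eemsom import (
    ComponentPartition,
    component_planes,
    component_table,
    coordinate_partition,
    cluster_codebook,
    fri_volumes,
    plane_correlation,
    region_boundaries,
    rmode_som,
    select_partition,
    silhouette_scan,
    suggest_grid,
    train_som,
    GridSpec,
    TrainingSchedule,
    assemble_dataset,
)
from eemsom.components import ComponentPlaneSet, silhouette_values

from conftest import make_eem, toy_model


def grid_coords(n_ex=4, n_em=5):
    ex = 240.0 + 10.0 * np.arange(n_ex)
    em = 300.0 + 10.0 * np.arange(n_em)
    return np.array([(e, m) for e in ex for m in em])


class TestComponentPlanes:
    def test_planes_are_codebook_transpose(self, rng):
        m = toy_model(rng.normal(size=(6, 20)), 2, 3)
        m.coordinate_index = grid_coords()
        ps = component_planes(m)
        assert ps.planes.shape == (20, 6)
        for p in rng.choice(20, 5, replace=False):
            for u in range(6):
                assert ps.planes[p, u] == m.codebook[u, p]


class TestPlaneCorrelation:
    def test_self_and_negation(self, rng):
        base = rng.normal(size=6)
        planes = ComponentPlaneSet(
            np.vstack([base, -base, rng.normal(size=6)]), grid_coords(1, 3)
        )
        c = plane_correlation(planes)
        assert c[0, 0] == pytest.approx(1.0)
        assert c[0, 1] == pytest.approx(-1.0)

    def test_matches_textbook_double_loop(self, rng):
        M = rng.normal(size=(7, 9))
        c = plane_correlation(ComponentPlaneSet(M, grid_coords(1, 7)))
        for a in range(7):
            for b in range(7):
                xa, xb = M[a] - M[a].mean(), M[b] - M[b].mean()
                r = np.sum(xa * xb) / np.sqrt(np.sum(xa**2) * np.sum(xb**2))
                assert c[a, b] == pytest.approx(r, abs=1e-12)

    def test_symmetric_positive_semidefinite(self, rng):
        M = rng.normal(size=(12, 8))
        c = plane_correlation(ComponentPlaneSet(M, grid_coords(3, 4)))
        np.testing.assert_allclose(c, c.T, atol=1e-12)
        assert np.linalg.eigvalsh(c).min() > -1e-8

    def test_zero_variance_plane_gets_defined_values(self, rng):
        M = rng.normal(size=(4, 6))
        M[2] = 3.14
        with pytest.warns(UserWarning, match="zero-variance"):
            c = plane_correlation(ComponentPlaneSet(M, grid_coords(2, 2)))
        assert c[2, 2] == 1.0
        assert np.all(c[2, [0, 1, 3]] == 0.0)

    def test_too_few_units_rejected(self, rng):
        with pytest.raises(ValueError, match="unit"):
            plane_correlation(ComponentPlaneSet(rng.normal(size=(4, 2)), grid_coords(2, 2)))


def block_correlation_matrix(rng, sizes=(10, 10), rho=0.9):
    """Correlation matrix with two strongly intra-correlated blocks."""
    n = sum(sizes)
    c = np.full((n, n), -0.3)
    start = 0
    for s in sizes:
        c[start:start + s, start:start + s] = rho
        start += s
    np.fill_diagonal(c, 1.0)
    c += rng.normal(0, 0.01, size=(n, n))
    c = (c + c.T) / 2
    np.fill_diagonal(c, 1.0)
    return c


class TestRModeSOM:
    def test_blocks_land_close_on_grid(self, rng):
        c = block_correlation_matrix(rng)
        m = rmode_som(c, GridSpec(2, 3), TrainingSchedule(n_epochs=40, seed=0),
                      coordinate_index=grid_coords(4, 5))
        D = m.grid.distance_matrix()
        b = m.bmu_assignments
        within, between = [], []
        for i in range(20):
            for j in range(i + 1, 20):
                (within if (i < 10) == (j < 10) else between).append(D[b[i], b[j]])
        assert np.mean(within) < np.mean(between)

    def test_identical_rows_share_bmu(self):
        c = np.ones((6, 6))
        m = rmode_som(c, GridSpec(1, 2), TrainingSchedule(n_epochs=5, seed=0),
                      coordinate_index=grid_coords(2, 3))
        assert len(np.unique(m.bmu_assignments)) == 1

    def test_asymmetric_input_rejected(self, rng):
        c = rng.normal(size=(5, 5))
        with pytest.raises(ValueError, match="symmetric"):
            rmode_som(c, GridSpec(1, 2), TrainingSchedule(n_epochs=1, seed=0))


class TestSilhouettes:
    def test_matches_brute_force_and_sklearn(self, rng):
        pts = rng.normal(size=(12, 3))
        labels = np.array([1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3])
        ours = silhouette_values(pts, labels)
        np.testing.assert_allclose(ours, silhouette_samples(pts, labels), atol=1e-12)

    def test_two_separated_clouds(self, rng):
        pts = np.vstack([rng.normal(0, 0.1, (6, 2)), rng.normal(9, 0.1, (6, 2))])
        s = silhouette_values(pts, np.repeat([1, 2], 6))
        assert s.mean() > 0.9 and (s < 0).sum() == 0

    def test_singletons_zero_and_bounds(self, rng):
        pts = rng.normal(size=(5, 2))
        labels = np.array([1, 2, 3, 4, 4])
        s = silhouette_values(pts, labels)
        assert np.all(s[:3] == 0.0)
        assert np.all((s >= -1) & (s <= 1))

    def test_scan_columns_and_range(self, rng):
        m = toy_model(rng.normal(size=(12, 4)), 3, 4)
        tab = silhouette_scan(m, range(2, 6))
        assert list(tab.columns) == ["k", "S_mean", "S_min", "S_max", "n_neg"]
        assert list(tab["k"]) == [2, 3, 4, 5]

    def test_scan_matches_direct_computation(self, rng):
        m = toy_model(rng.normal(size=(10, 3)), 2, 5)
        tab = silhouette_scan(m, [4])
        s = silhouette_values(m.codebook, cluster_codebook(m, 4))
        row = tab.iloc[0]
        assert row["S_mean"] == pytest.approx(s.mean())
        assert row["n_neg"] == (s < 0).sum()


class TestSelectPartition:
    def test_published_table_selects_four(self):
        # printed silhouette statistics of the field data set
        table = pd.DataFrame({
            "k": range(2, 10),
            "S_mean": [0.56, 0.57, 0.54, 0.48, 0.48, 0.41, 0.42, 0.35],
            "S_min": [-0.74, -0.50, -0.29, -0.43, -0.44, -0.23, -0.23, -0.33],
            "S_max": [0.86, 0.80, 0.74, 0.72, 0.70, 0.70, 0.70, 0.70],
            "n_neg": [17, 13, 9, 13, 8, 7, 7, 16],
        })
        assert select_partition(table) == 4

    def test_single_row(self):
        t = pd.DataFrame({"k": [3], "S_mean": [0.5], "S_min": [0], "S_max": [1],
                          "n_neg": [2]})
        assert select_partition(t) == 3

    def test_full_tie_prefers_smaller_k(self):
        t = pd.DataFrame({"k": [4, 2], "S_mean": [0.5, 0.5],
                          "S_min": [0, 0], "S_max": [1, 1], "n_neg": [3, 3]})
        assert select_partition(t) == 2


class TestCoordinatePartition:
    def make_rmodel(self, rng, labels_per_unit=6):
        m = toy_model(rng.normal(size=(6, 4)), 2, 3)
        m.coordinate_index = grid_coords(4, 5)
        m.bmu_assignments = np.arange(20) % 6
        return m

    def test_single_label_everywhere(self, rng):
        m = self.make_rmodel(rng)
        part = coordinate_partition(m, np.ones(6, dtype=int))
        assert part.n_components == 1
        assert np.all(part.coordinate_labels == 1)

    def test_components_ordered_by_mean_emission(self, rng):
        m = toy_model(rng.normal(size=(2, 4)), 1, 2)
        m.coordinate_index = grid_coords(2, 4)
        # unit 0 catches long-emission coords, unit 1 short-emission ones
        m.bmu_assignments = np.array([1, 1, 0, 0, 1, 1, 0, 0])
        part = coordinate_partition(m, np.array([1, 2]))
        em = m.coordinate_index[:, 1]
        mean_c1 = em[part.coordinate_labels == 1].mean()
        mean_c2 = em[part.coordinate_labels == 2].mean()
        assert mean_c1 < mean_c2

    def test_planted_blocks_recovered(self, rng):
        c = block_correlation_matrix(rng)
        m = rmode_som(c, GridSpec(1, 2), TrainingSchedule(n_epochs=40, seed=1),
                      coordinate_index=grid_coords(4, 5))
        part = coordinate_partition(m, cluster_codebook(m, 2))
        truth = np.repeat([1, 2], 10)
        assert adjusted_rand_score(truth, part.coordinate_labels) == pytest.approx(1.0)


class TestRegions:
    def test_boundaries_and_coverage(self, rng):
        coords = grid_coords(3, 4)
        part = ComponentPartition(
            n_components=2,
            coordinate_labels=np.array([1] * 5 + [2] * 7),
            unit_labels=np.array([1, 2]),
            coordinate_index=coords,
        )
        rb = region_boundaries(part)
        assert rb["n_coordinates"].sum() == 12
        for _, row in rb.iterrows():
            member = coords[part.coordinate_labels == row["component"]]
            assert row["ex_min"] <= member[:, 0].min()
            assert row["em_max"] >= member[:, 1].max()

    def test_single_coordinate_component_degenerate(self):
        coords = grid_coords(2, 2)
        part = ComponentPartition(2, np.array([1, 2, 2, 2]), np.array([1, 2]), coords)
        rb = region_boundaries(part).set_index("component")
        assert rb.loc[1, "ex_min"] == rb.loc[1, "ex_max"]


class TestFRI:
    def make_partition(self, coords, labels):
        return ComponentPartition(
            n_components=int(np.max(labels)),
            coordinate_labels=np.asarray(labels),
            unit_labels=np.unique(labels),
            coordinate_index=coords,
        )

    def test_single_region_is_total_volume(self, rng):
        e = make_eem(rng.uniform(0.5, 1.5, size=(4, 5)))
        coords = grid_coords(4, 5)
        part = self.make_partition(coords, np.ones(20, dtype=int))
        res = fri_volumes(e, part)
        assert res.mf[0] == pytest.approx(1.0)
        assert res.percent[0] == pytest.approx(100.0)
        assert res.phi_n[0] == pytest.approx(np.sum(e.intensity * 100.0))

    def test_uniform_two_halves_split_50_50(self):
        e = make_eem(np.ones((4, 4)))
        coords = grid_coords(4, 4)
        labels = np.where(coords[:, 0] < 260, 1, 2)
        res = fri_volumes(e, self.make_partition(coords, labels))
        np.testing.assert_allclose(res.percent, [50.0, 50.0])

    def test_riemann_matches_cell_loop_oracle(self, rng):
        e = make_eem(rng.uniform(0, 2, size=(5, 6)))
        coords = grid_coords(5, 6)
        labels = rng.integers(1, 4, size=30)
        labels[:3] = [1, 2, 3]  # every region inhabited
        part = self.make_partition(coords, labels)
        res = fri_volumes(e, part, method="riemann")
        # hand loop: every cell is 10 nm x 10 nm on this grid
        for comp in (1, 2, 3):
            phi = 0.0
            area = 0.0
            for p, (ex, em) in enumerate(coords):
                if labels[p] == comp:
                    i = list(e.ex_wavelengths).index(ex)
                    j = list(e.em_wavelengths).index(em)
                    phi += e.intensity[i, j] * 100.0
                    area += 100.0
            assert res.phi[comp - 1] == pytest.approx(phi)
            assert res.mf[comp - 1] == pytest.approx(30 * 100.0 / area)

    def test_percent_sums_to_100_and_volume_conserved(self, rng):
        e = make_eem(rng.uniform(0.1, 3, size=(6, 6)))
        coords = grid_coords(6, 6)
        labels = rng.integers(1, 5, size=36)
        for c in (1, 2, 3, 4):
            labels[c - 1] = c
        res = fri_volumes(e, self.make_partition(coords, labels))
        assert np.nansum(res.percent) == pytest.approx(100.0, abs=1e-9)
        total_raw = np.sum(res.phi_n / res.mf)
        assert total_raw == pytest.approx(np.sum(e.intensity) * 100.0)

    def test_riemann_vs_trapezoid_agree_on_smooth_peak(self):
        # smooth single peak on a 5-nm grid, one region per half
        ex = np.arange(240.0, 341.0, 5.0)
        em = np.arange(300.0, 401.0, 5.0)
        surf = np.exp(
            -(((ex[:, None] - 290) / 30.0) ** 2) - (((em[None, :] - 350) / 30.0) ** 2)
        )
        e = make_eem(surf, ex=ex, em=em)
        coords = np.array([(a, b) for a in ex for b in em])
        labels = np.where(coords[:, 1] < 350, 1, 2)
        r1 = fri_volumes(e, self.make_partition(coords, labels), "riemann")
        r2 = fri_volumes(e, self.make_partition(coords, labels), "trapezoid")
        np.testing.assert_allclose(r1.phi, r2.phi, rtol=0.05)

    def test_zero_eem_percent_undefined(self):
        e = make_eem(np.zeros((3, 3)))
        coords = grid_coords(3, 3)
        part = self.make_partition(coords, np.ones(9, dtype=int))
        with pytest.warns(UserWarning, match="zero total"):
            res = fri_volumes(e, part)
        assert np.all(np.isnan(res.percent))


class TestComponentTable:
    def test_table_matches_fri_and_round_trips(self, tmp_path, rng):
        eems = [make_eem(rng.uniform(0.5, 2, size=(3, 4)), sample_id=f"s{i}")
                for i in range(3)]
        ds = assemble_dataset(eems)
        coords = ds.coordinate_index
        labels = (np.arange(len(coords)) % 2) + 1
        part = ComponentPartition(2, labels, np.array([1, 2]), coords)
        table = component_table(ds, part)
        assert len(table) == 3
        res0 = fri_volumes(ds.eems[0], part)
        assert table.loc[0, "pct_C1"] == pytest.approx(res0.percent[0])
        p = tmp_path / "fri.csv"
        table.to_csv(p, index=False)
        back = pd.read_csv(p)
        np.testing.assert_allclose(back["phi_n_C2"], table["phi_n_C2"])
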