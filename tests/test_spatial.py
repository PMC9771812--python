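import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from tmeco.spatial import (
    BoundaryGeometry,
    GateSpec,
    boundary_distance,
    density_profile,
    gate_phenotypes,
    nn_distances,
    nn_summary,
    proximity_counts,
)
from tmeco.synthetic import FovSpec, simulate_spatial_fov

GATES = GateSpec(
    thresholds={"panCK": 5.0, "CD68": 5.0, "CD8": 5.0, "PD1": 5.0, "PDL1": 5.0, "TOX": 5.0},
    phenotypes={
        "CD8+PD-1-TOX-": {"CD8": True, "PD1": False, "TOX": False},
        "CD8+PD-1+TOX-": {"CD8": True, "PD1": True, "TOX": False},
        "CD8+PD-1+TOX+": {"CD8": True, "PD1": True, "TOX": True},
        "panCK+PD-L1+": {"panCK": True, "PDL1": True},
        "panCK+PD-L1-": {"panCK": True, "PDL1": False},
        "CD68+PD-L1+": {"CD68": True, "PDL1": True},
    },
)


def _cells(rows):
    frame = pd.DataFrame(rows)
    frame.insert(0, "cell_id", [f"c{i}" for i in range(len(frame))])
    if "fov_id" not in frame.columns:
        frame["fov_id"] = "f0"
    return frame


class TestGatePhenotypes:
    def test_functional_state_assignment(self):
        cells = _cells(
            [{"x": 0, "y": 0, "panCK": 0, "CD68": 0, "CD8": 9, "PD1": 8, "PDL1": 0, "TOX": 1}]
        )
        out = gate_phenotypes(cells, GATES)
        assert list(out["phenotype"]) == ["CD8+PD-1+TOX-"]

    def test_all_negative_is_other(self):
        cells = _cells(
            [{"x": 0, "y": 0, "panCK": 0, "CD68": 0, "CD8": 0, "PD1": 0, "PDL1": 0, "TOX": 0}]
        )
        out = gate_phenotypes(cells, GATES)
        assert list(out["phenotype"]) == ["other"]

    def test_multi_lineage_object_duplicated(self):
        cells = _cells(
            [{"x": 3.0, "y": 4.0, "panCK": 9, "CD68": 0, "CD8": 9, "PD1": 0, "PDL1": 9, "TOX": 0}]
        )
        out = gate_phenotypes(cells, GATES)
        assert len(out) == 2
        assert set(out["phenotype"]) == {"panCK+PD-L1+", "CD8+PD-1-TOX-"}
        assert (out["x"] == 3.0).all() and (out["y"] == 4.0).all()

    def test_threshold_is_inclusive(self):
        cells = _cells(
            [{"x": 0, "y": 0, "panCK": 5.0, "CD68": 0, "CD8": 0, "PD1": 0, "PDL1": 5.0, "TOX": 0}]
        )
        out = gate_phenotypes(cells, GATES)
        assert list(out["phenotype"]) == ["panCK+PD-L1+"]

    def test_ungated_marker_in_definition_errors(self):
        with pytest.raises(ValueError, match="FOXP3"):
            GateSpec(thresholds={"CD8": 1.0}, phenotypes={"bad": {"CD8": True, "FOXP3": True}})


class TestBoundaryDistance:
    GEOM = BoundaryGeometry(
        tumour={
            "f0": Polygon([(0, -1e4), (1e4, -1e4), (1e4, 1e4), (0, 1e4)])  # tumour at x > 0
        }
    )

    def test_line_boundary_geometry(self):
        cells = _cells(
            [
                {"x": 10.0, "y": 0.0, "fov_id": "f0"},
                {"x": -7.0, "y": 0.0, "fov_id": "f0"},
                {"x": 0.0, "y": 5.0, "fov_id": "f0"},
            ]
        )
        out = boundary_distance(cells, self.GEOM)
        assert out["signed_distance"].tolist() == pytest.approx([10.0, -7.0, 0.0])

    def test_missing_fov_geometry_flagged(self):
        cells = _cells([{"x": 1.0, "y": 1.0, "fov_id": "f_unknown"}])
        out = boundary_distance(cells, self.GEOM)
        assert np.isnan(out["signed_distance"]).all()

    def test_polygon_distance_matches_densified_boundary(self, rng):
        poly = Polygon([(0, 0), (100, 10), (120, 80), (40, 120), (-10, 60)])
        geom = BoundaryGeometry(tumour={"f0": poly})
        pts = rng.uniform(-20, 140, size=(50, 2))
        cells = _cells([{"x": x, "y": y, "fov_id": "f0"} for x, y in pts])
        out = boundary_distance(cells, geom)
        # brute-force oracle: dense sampling of the boundary polyline
        ring = poly.exterior
        dense = np.array(
            [ring.interpolate(t, normalized=True).coords[0] for t in np.linspace(0, 1, 200001)]
        )
        for (x, y), signed in zip(pts, out["signed_distance"]):
            d = np.sqrt(((dense - [x, y]) ** 2).sum(axis=1)).min()
            assert abs(abs(signed) - d) < 0.01

    def test_degenerate_boundary_rejected(self):
        with pytest.raises(Exception):
            BoundaryGeometry(tumour={"f0": Polygon()})


class TestDensityProfile:
    def _profiled(self, distances, phenotype="CD8", others=()):
        rows = [
            {"x": 0, "y": 0, "fov_id": "f0", "phenotype": phenotype, "signed_distance": d}
            for d in distances
        ]
        rows += [
            {"x": 0, "y": 0, "fov_id": "f0", "phenotype": "other", "signed_distance": d}
            for d in others
        ]
        return _cells(rows)

    def test_single_band_concentration(self):
        cells = self._profiled([12.0, 13.0, 17.5])
        prof = density_profile(cells, "CD8")
        assert prof.loc[prof["band_start"] == 10.0, "density"].iloc[0] == 1.0
        assert prof["density"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_se_formula(self):
        # 50 CD8 and 50 other cells in one band: p=0.5, N=100 -> SE 0.05
        cells = self._profiled([5.0] * 50, others=[5.0] * 50)
        prof = density_profile(cells, "CD8")
        assert prof.loc[prof["band_start"] == 0.0, "se"].iloc[0] == pytest.approx(0.05)

    def test_bands_are_half_open_and_signed(self):
        cells = self._profiled([-0.001, 0.0, 9.999, 10.0])
        prof = density_profile(cells, "CD8")
        lookup = prof.set_index("band_start")["n_phenotype"]
        assert lookup[-10.0] == 1  # -0.001 falls in [-10, 0)
        assert lookup[0.0] == 2  # 0.0 and 9.999 in [0, 10)
        assert lookup[10.0] == 1

    def test_generator_truth_profile_peaks_at_boundary(self):
        spec = FovSpec(
            width=400,
            height=400,
            n_cells={"CD8": 1500},
            intensity={"CD8": lambda d: np.where(np.abs(d) < 30, 1.0, 0.02)},
        )
        cells = simulate_spatial_fov(spec, seed=6)
        prof = density_profile(cells, "CD8")
        top = prof.sort_values("density", ascending=False).head(3)["band_start"]
        assert set(top) <= {-30.0, -20.0, -10.0, 0.0, 10.0, 20.0}

    def test_absent_phenotype_errors(self):
        cells = self._profiled([1.0])
        with pytest.raises(ValueError):
            density_profile(cells, "CD68")


class TestNnDistances:
    def test_three_four_five_triangle(self):
        cells = _cells(
            [
                {"x": 0.0, "y": 0.0, "fov_id": "f0", "phenotype": "src"},
                {"x": 3.0, "y": 4.0, "fov_id": "f0", "phenotype": "tgt"},
                {"x": 6.0, "y": 8.0, "fov_id": "f0", "phenotype": "tgt"},
            ]
        )
        out = nn_distances(cells, "src", "tgt")
        assert out["nn_distance"].tolist() == [5.0]

    def test_self_excluded_for_same_phenotype(self):
        cells = _cells(
            [
                {"x": 0.0, "y": 0.0, "fov_id": "f0", "phenotype": "src"},
                {"x": 1.0, "y": 0.0, "fov_id": "f0", "phenotype": "src"},
                {"x": 5.0, "y": 0.0, "fov_id": "f0", "phenotype": "src"},
            ]
        )
        out = nn_distances(cells, "src", "src")
        assert out["nn_distance"].tolist() == pytest.approx([1.0, 1.0, 4.0])

    def test_matches_brute_force_exactly(self, rng):
        cells = _cells(
            [
                {
                    "x": x,
                    "y": y,
                    "fov_id": f"f{f}",
                    "phenotype": ph,
                }
                for f in range(3)
                for (x, y), ph in zip(
                    rng.uniform(0, 500, size=(200, 2)),
                    rng.choice(["a", "b"], 200),
                )
            ]
        )
        out = nn_distances(cells, "a", "b").set_index("cell_id")
        for fov, grp in cells.groupby("fov_id"):
            src = grp[grp["phenotype"] == "a"]
            tgt = grp[grp["phenotype"] == "b"][["x", "y"]].to_numpy()
            for row in src.itertuples():
                expected = np.sqrt(((tgt - [row.x, row.y]) ** 2).sum(axis=1)).min()
                assert out.loc[row.cell_id, "nn_distance"] == expected  # exact

    def test_fov_without_targets_yields_missing(self):
        cells = _cells(
            [
                {"x": 0.0, "y": 0.0, "fov_id": "f0", "phenotype": "src"},
                {"x": 0.0, "y": 0.0, "fov_id": "f1", "phenotype": "src"},
                {"x": 1.0, "y": 0.0, "fov_id": "f1", "phenotype": "tgt"},
            ]
        )
        out = nn_distances(cells, "src", "tgt")
        assert out["nn_distance"].isna().sum() == 1
        summary = nn_summary(out)
        pooled = summary[summary["fov_id"] == "pooled"]
        assert pooled["n"].iloc[0] == 1

    def test_asymmetry_between_phenotype_sets(self):
        cells = _cells(
            [
                {"x": 0.0, "y": 0.0, "fov_id": "f0", "phenotype": "a"},
                {"x": 1.0, "y": 0.0, "fov_id": "f0", "phenotype": "b"},
                {"x": 2.0, "y": 0.0, "fov_id": "f0", "phenotype": "b"},
            ]
        )
        ab = nn_distances(cells, "a", "b")["nn_distance"].tolist()
        ba = nn_distances(cells, "b", "a")["nn_distance"].tolist()
        assert ab != ba  # regression: not symmetric in general


class TestProximityCounts:
    FIXTURE = [
        {"x": 0.0, "y": 0.0, "fov_id": "f0", "phenotype": "src"},
        {"x": 100.0, "y": 0.0, "fov_id": "f0", "phenotype": "src"},
        {"x": 0.0, "y": 10.0, "fov_id": "f0", "phenotype": "tgt"},
    ]

    def test_radius_zero_counts_coincident_only(self):
        cells = _cells(self.FIXTURE + [{"x": 100.0, "y": 0.0, "fov_id": "f0", "phenotype": "tgt"}])
        out = proximity_counts(cells, "src", "tgt", radius=0.0)
        assert out.loc[out["fov_id"] == "pooled", "n_proximal"].iloc[0] == 1

    def test_saturating_radius_counts_all_sources(self):
        cells = _cells(self.FIXTURE)
        out = proximity_counts(cells, "src", "tgt", radius=1e6)
        assert out.loc[out["fov_id"] == "pooled", "n_proximal"].iloc[0] == 2

    def test_monotone_in_radius_and_matches_enumeration(self, rng):
        cells = _cells(
            [
                {"x": x, "y": y, "fov_id": "f0", "phenotype": ph}
                for (x, y), ph in zip(
                    rng.uniform(0, 200, size=(150, 2)), rng.choice(["src", "tgt"], 150)
                )
            ]
        )
        previous = -1
        for radius in (5, 15, 30, 60, 120):
            out = proximity_counts(cells, "src", "tgt", radius=radius)
            n = out.loc[out["fov_id"] == "pooled", "n_proximal"].iloc[0]
            assert n >= previous
            previous = n
            src = cells[cells["phenotype"] == "src"][["x", "y"]].to_numpy()
            tgt = cells[cells["phenotype"] == "tgt"][["x", "y"]].to_numpy()
            expected = sum(
                np.sqrt(((tgt - s) ** 2).sum(axis=1)).min() <= radius for s in src
            )
            assert n == expected
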