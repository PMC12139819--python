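import numpy as np
import pandas as pd
import pytest

from test_prediction import manual_fit  # hand-built fits
from zigrow.errors import AlignmentError, ConfigurationError, FormatError
from zigrow.model_design import FULL_COLUMNS
from zigrow.prediction import PredictionRequest, predict_components
from zigrow.projection import (
    BestGenotypeMap,
    ClimateGrid,
    project_best_genotype,
    read_climate_grid,
    shift_summary,
    write_climate_grid,
)


def toy_grid(values, nodata=-9999.0):
    arr = np.asarray(values, float)
    return ClimateGrid(mcmt=arr, geotransform=(0.0, 1.0, 0.0, float(arr.shape[0]), 0.0, -1.0),
                       nodata=nodata)


def two_genotype_table():
    # two pure quadratic responses crossing once inside the garden range
    return pd.DataFrame(
        {
            "genotype_id": ["A", "B"],
            "home_mcmt": [-20.0, -6.0],
            "pc1": [1.0, -1.0],
            "pc2": [0.0, 0.0],
            "pc3": [0.0, 0.0],
            "ancestry_q": [0.05, 0.95],
        }
    ).set_index("genotype_id", drop=False)


def crossing_fit():
    """eta = 0.2*g - 0.02*g^2 + 0.08*pc1: genotype A (pc1=1) beats B below
    t* and B beats A above; the pc1:g term makes the curves cross."""
    beta = np.zeros(18)
    beta[FULL_COLUMNS.index("g")] = 0.2
    beta[FULL_COLUMNS.index("g2")] = -0.02
    beta[FULL_COLUMNS.index("pc1")] = 0.08
    beta[FULL_COLUMNS.index("pc1:g")] = 0.04
    return manual_fit(beta, beta_zi=np.r_[-50.0, np.zeros(17)])


def analytic_crossing():
    # eta_A - eta_B = 0.08*(pc1_A - pc1_B) + 0.04*g*(pc1_A - pc1_B)
    #              = 2*(0.08 + 0.04 t) -> t* = -2
    return -2.0


class TestRasterIO:
    def test_ascii_round_trip_with_nodata(self, tmp_path):
        vals = [[-5.0, 3.25, -9999.0], [0.5, -1.75, 2.0], [7.0, -12.5, 4.0]]
        grid = toy_grid(vals)
        path = tmp_path / "grid.asc"
        write_climate_grid(grid, path)
        back = read_climate_grid(path)
        assert np.array_equal(back.mcmt, grid.mcmt)
        assert back.geotransform == pytest.approx(grid.geotransform)
        assert back.nodata == grid.nodata
        assert back.valid.sum() == 8  # one nodata cell flagged

    def test_geotiff_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        grid = toy_grid(rng.uniform(-20, 10, (6, 5)))
        path = tmp_path / "grid.tif"
        write_climate_grid(grid, path)
        back = read_climate_grid(path)
        assert np.allclose(back.mcmt, grid.mcmt.astype(np.float32), atol=0)
        assert back.geotransform == pytest.approx(grid.geotransform)

    def test_unsupported_format(self, tmp_path):
        p = tmp_path / "grid.nc"
        p.write_text("x")
        with pytest.raises(FormatError):
            read_climate_grid(p)


class TestProjection:
    def test_single_genotype_everywhere(self):
        fit = crossing_fit()
        genos = two_genotype_table().iloc[:1]
        grid = toy_grid(np.linspace(-15, 8, 36).reshape(6, 6))
        bmap = project_best_genotype(fit, genos, grid, mask_bounds=(-16.5, 9.8))
        assert np.all(bmap.best_genotype_index[~bmap.masked] == 0)
        assert np.all(np.isnan(bmap.best_ancestry_q[bmap.masked]))

    def test_crossing_matches_brute_force_and_mask(self):
        fit = crossing_fit()
        genos = two_genotype_table()
        rng = np.random.default_rng(1)
        vals = rng.uniform(-25, 12, (50, 50))
        vals[0, :3] = -9999.0
        grid = toy_grid(vals)
        bounds = (-16.5, 9.8)
        bmap = project_best_genotype(fit, genos, grid, mask_bounds=bounds)

        # per-cell brute force with the same 0.01 degC quantization
        t = np.round(grid.mcmt * 100) / 100
        expected_mask = ~((t >= bounds[0]) & (t <= bounds[1]) & grid.valid)
        assert np.array_equal(bmap.masked, expected_mask)
        for i in range(50):
            for j in range(0, 50, 7):
                if expected_mask[i, j]:
                    assert bmap.best_genotype_index[i, j] == -1
                    continue
                fits = []
                for _, row in genos.iterrows():
                    comp = predict_components(
                        fit,
                        PredictionRequest(
                            garden_mcmt=t[i, j], home_mcmt=row["home_mcmt"],
                            pc1=row["pc1"], pc2=row["pc2"], pc3=row["pc3"],
                        ),
                    )
                    fits.append(comp.overall[0])
                assert bmap.best_genotype_index[i, j] == int(np.argmax(fits))
        # assignment switches exactly at the analytic crossing temperature:
        # below t* the pc1 slope favors genotype B, above it genotype A
        tstar = analytic_crossing()
        unmasked = ~expected_mask
        assert np.all(bmap.best_genotype_index[unmasked & (t < tstar - 0.01)] == 1)
        assert np.all(bmap.best_genotype_index[unmasked & (t > tstar + 0.01)] == 0)

    def test_mask_widening_never_masks_more(self):
        fit = crossing_fit()
        genos = two_genotype_table()
        grid = toy_grid(np.random.default_rng(2).uniform(-25, 12, (20, 20)))
        narrow = project_best_genotype(fit, genos, grid, mask_bounds=(-10.0, 5.0))
        wide = project_best_genotype(fit, genos, grid, mask_bounds=(-20.0, 11.0))
        assert not np.any(wide.masked & ~narrow.masked)

    def test_empty_genotypes_error(self):
        fit = crossing_fit()
        with pytest.raises(ConfigurationError):
            project_best_genotype(
                fit, two_genotype_table().iloc[:0], toy_grid([[0.0]]), (-16.5, 9.8)
            )


class TestShiftSummary:
    def test_identity_maps_have_zero_switching(self):
        fit = crossing_fit()
        genos = two_genotype_table()
        grid = toy_grid(np.linspace(-15, 8, 100).reshape(10, 10))
        a = project_best_genotype(fit, genos, grid, mask_bounds=(-16.5, 9.8))
        table, agg = shift_summary(a, a)
        assert agg["switched_fraction"] == 0.0
        assert np.all(table["delta_q"] == 0.0)

    def test_counting_fraction(self):
        geno_ids = ("A", "B")
        idx = np.zeros((10, 10), dtype=np.int64)
        q = np.zeros((10, 10))
        masked = np.zeros((10, 10), bool)
        gt = (0.0, 1.0, 0.0, 10.0, 0.0, -1.0)
        a = BestGenotypeMap(idx, q, masked, gt, "unspecified", geno_ids)
        idx2 = idx.copy()
        idx2.flat[:4] = 1
        q2 = q.copy()
        q2.flat[:4] = 0.95
        b = BestGenotypeMap(idx2, q2, masked, gt, "unspecified", geno_ids)
        _, agg = shift_summary(a, b)
        assert agg["switched_fraction"] == pytest.approx(0.04)

    def test_uniform_warming_translates_the_boundary(self):
        fit = crossing_fit()
        genos = two_genotype_table()
        vals = np.linspace(-14, 4, 90).reshape(9, 10)
        hist = project_best_genotype(fit, genos, toy_grid(vals), mask_bounds=(-16.5, 9.8))
        fut = project_best_genotype(fit, genos, toy_grid(vals + 5.0), mask_bounds=(-16.5, 9.8))
        table, _ = shift_summary(hist, fut)
        tstar = analytic_crossing()
        t = np.round(vals * 100) / 100
        switched_cells = set(zip(table.loc[table.switched, "row"], table.loc[table.switched, "col"]))
        for i in range(9):
            for j in range(10):
                in_band = tstar - 5.0 <= t[i, j] < tstar
                assert ((i, j) in switched_cells) == in_band

    def test_alignment_errors(self):
        gt = (0.0, 1.0, 0.0, 4.0, 0.0, -1.0)
        ids = ("A",)
        a = BestGenotypeMap(np.zeros((4, 4), np.int64), np.zeros((4, 4)),
                            np.zeros((4, 4), bool), gt, "unspecified", ids)
        b = BestGenotypeMap(np.zeros((5, 4), np.int64), np.zeros((5, 4)),
                            np.zeros((5, 4), bool), gt, "unspecified", ids)
        with pytest.raises(AlignmentError):
            shift_summary(a, b)
        c = BestGenotypeMap(np.zeros((4, 4), np.int64), np.zeros((4, 4)),
                            np.zeros((4, 4), bool), gt, "unspecified", ("A", "B"))
        with pytest.raises(AlignmentError):
            shift_summary(a, c)
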