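import numpy as np
import pytest

import gpasim as g
from gpasim.errors import ParameterError
from gpasim.sweep import spec_from_config, spec_to_config


@pytest.fixture
def daet_spec():
    return g.SweepSpec(formula_id="daetwyler", x_param="n_train",
                       x_min=100, x_max=10000, n_points=25,
                       fixed={"h2": 0.5, "me": 1000.0})


class TestMakeGrid:
    def test_linear_spacing(self):
        spec = g.SweepSpec(formula_id="deloscampos", x_param="b",
                           x_min=0.1, x_max=0.9, n_points=5,
                           fixed={"h2": 0.5})
        xs = [p["b"] for p in g.make_grid(spec)]
        assert xs == pytest.approx([0.1, 0.3, 0.5, 0.7, 0.9], abs=1e-15)

    def test_two_points_are_exact_endpoints(self):
        spec = g.SweepSpec(formula_id="deloscampos", x_param="h2",
                           x_min=0.2, x_max=0.7, n_points=2,
                           fixed={"b": 1.0})
        xs = [p["h2"] for p in g.make_grid(spec)]
        assert xs == [0.2, 0.7]

    def test_log_spacing_geometric(self):
        spec = g.SweepSpec(formula_id="daetwyler", x_param="me",
                           x_min=10, x_max=1000, n_points=3, scale="log",
                           fixed={"n_train": 1000, "h2": 0.5})
        xs = [p["me"] for p in g.make_grid(spec)]
        # oracle: geometric sequence 10 * 10^k
        assert xs == pytest.approx([10.0, 100.0, 1000.0], rel=1e-12)
        assert xs[0] == 10.0 and xs[-1] == 1000.0  # endpoints exact

    def test_log_scale_requires_positive_min(self):
        with pytest.raises(ParameterError, match="log"):
            g.SweepSpec(formula_id="deloscampos", x_param="b", x_min=0.0,
                        x_max=1.0, n_points=5, scale="log",
                        fixed={"h2": 0.5})

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ParameterError, match="x_min < x_max"):
            g.SweepSpec(formula_id="deloscampos", x_param="b", x_min=0.5,
                        x_max=0.5, n_points=2, fixed={"h2": 0.5})

    def test_out_of_domain_grid_value_named(self):
        spec = g.SweepSpec.__new__(g.SweepSpec)  # bypass ctor validation
        object.__setattr__(spec, "formula_id", "daetwyler")
        object.__setattr__(spec, "x_param", "h2")
        object.__setattr__(spec, "x_min", 0.5)
        object.__setattr__(spec, "x_max", 1.5)
        object.__setattr__(spec, "n_points", 3)
        object.__setattr__(spec, "scale", "linear")
        object.__setattr__(spec, "fixed", {"n_train": 100, "me": 50.0})
        with pytest.raises(ParameterError, match="h2=1.5"):
            g.make_grid(spec)

    def test_integer_factor_rounded_and_deduplicated(self):
        spec = g.SweepSpec(formula_id="daetwyler", x_param="n_train",
                           x_min=10, x_max=12, n_points=5,
                           fixed={"h2": 0.5, "me": 100.0})
        xs = [p["n_train"] for p in g.make_grid(spec)]
        assert xs == [10, 11, 12]
        assert all(isinstance(x, int) for x in xs)

    def test_fixed_must_cover_exactly(self):
        with pytest.raises(ParameterError, match="missing"):
            g.SweepSpec(formula_id="daetwyler", x_param="n_train",
                        x_min=10, x_max=100, fixed={"h2": 0.5})
        with pytest.raises(ParameterError, match="unexpected"):
            g.SweepSpec(formula_id="daetwyler", x_param="n_train",
                        x_min=10, x_max=100,
                        fixed={"h2": 0.5, "me": 10.0, "ne": 50.0})

    def test_varying_factor_must_belong_to_formula(self):
        with pytest.raises(ParameterError, match="ne"):
            g.SweepSpec(formula_id="daetwyler", x_param="ne", x_min=1,
                        x_max=10, fixed={"n_train": 100, "h2": 0.5,
                                         "me": 10.0})


class TestRunSweep:
    def test_monotone_in_n(self, daet_spec):
        table = g.run_sweep(daet_spec)
        accs = [r.accuracy for r in table]
        assert all(a < b for a, b in zip(accs, accs[1:]))
        assert all(0.0 <= r.accuracy <= 1.0 for r in table)

    def test_purity(self, daet_spec):
        assert g.run_sweep(daet_spec) == g.run_sweep(daet_spec)

    def test_record_count_and_order(self, daet_spec):
        table = g.run_sweep(daet_spec)
        assert len(table) == 25
        xs = [r.x_value for r in table]
        assert xs == sorted(xs) and len(set(xs)) == len(xs)

    def test_rows_revalidate_through_evaluator(self, daet_spec):
        for rec in g.run_sweep(daet_spec):
            params = dict(rec.fixed)
            params[rec.x_param] = (int(rec.x_value)
                                   if rec.x_param == "n_train"
                                   else rec.x_value)
            assert g.evaluate(rec.formula_id, params) == rec.accuracy

    def test_goddard2011_b1_matches_daetwyler_pointwise(self):
        fixed_g = {"h2": 0.5, "me": 1000.0, "b": 1.0}
        fixed_d = {"h2": 0.5, "me": 1000.0}
        tg = g.run_sweep(g.SweepSpec(formula_id="goddard2011",
                                     x_param="n_train", x_min=100,
                                     x_max=10000, n_points=50,
                                     fixed=fixed_g))
        td = g.run_sweep(g.SweepSpec(formula_id="daetwyler",
                                     x_param="n_train", x_min=100,
                                     x_max=10000, n_points=50,
                                     fixed=fixed_d))
        for a, b in zip(tg, td):
            assert a.accuracy == pytest.approx(b.accuracy, rel=1e-12)

    def test_error_carries_grid_index(self):
        spec = g.SweepSpec(formula_id="rabier", x_param="h2",
                           x_min=0.5, x_max=1.0, n_points=3,
                           fixed={"n_train": 100, "me": 50.0})
        with pytest.raises(ParameterError, match="grid index 2"):
            g.run_sweep(spec)


class TestRunSurface:
    @pytest.fixture
    def surf_spec(self):
        fixed = {"h2_a": 0.5, "h2_b": 0.5, "me_ac": 500.0, "me_bc": 500.0,
                 "r_g_ac": 0.8, "r_g_bc": 0.8, "r_g_ab": 0.6,
                 "b_ac": 0.9, "b_bc": 0.9}
        return g.SurfaceSpec(formula_id="wientjes", x_param="n_a",
                             x_min=100, x_max=5000, x_points=6,
                             y_param="n_b", y_min=100, y_max=5000,
                             y_points=6, fixed=fixed)

    def test_two_by_two_grid(self):
        spec = g.SurfaceSpec(formula_id="daetwyler", x_param="n_train",
                             x_min=100, x_max=1000, x_points=2,
                             y_param="me", y_min=100, y_max=1000,
                             y_points=2, fixed={"h2": 0.5})
        table = g.run_surface(spec)
        assert len(table) == 4
        assert table.is_surface

    def test_symmetric_params_give_symmetric_surface(self, surf_spec):
        table = g.run_surface(surf_spec)
        vals = {(r.x_value, r.y_value): r.accuracy for r in table}
        for (x, y), acc in vals.items():
            assert acc == pytest.approx(vals[(y, x)], rel=1e-12)

    def test_each_cell_matches_direct_call(self, surf_spec):
        for rec in g.run_surface(surf_spec):
            params = dict(rec.fixed)
            params["n_a"] = int(rec.x_value)
            params["n_b"] = int(rec.y_value)
            assert g.wientjes(**params) == rec.accuracy

    def test_transposed_spec_transposes_surface(self, surf_spec):
        t1 = g.run_surface(surf_spec)
        t2 = g.run_surface(surf_spec.transposed())
        vals1 = {(r.x_value, r.y_value): r.accuracy for r in t1}
        vals2 = {(r.y_value, r.x_value): r.accuracy for r in t2}
        assert vals1 == vals2

    def test_identical_factors_rejected(self):
        with pytest.raises(ParameterError, match="distinct"):
            g.SurfaceSpec(formula_id="daetwyler", x_param="n_train",
                          x_min=10, x_max=100, y_param="n_train",
                          y_min=10, y_max=100, fixed={"h2": 0.5,
                                                      "me": 10.0})


class TestConfigFiles:
    def test_sweep_roundtrip(self, tmp_path, daet_spec):
        path = tmp_path / "sweep.cfg"
        spec_to_config(daet_spec, path)
        assert spec_from_config(path) == daet_spec

    def test_surface_roundtrip(self, tmp_path):
        spec = g.SurfaceSpec(formula_id="wientjes", x_param="n_a",
                             x_min=100, x_max=5000, x_points=4,
                             y_param="n_b", y_min=100, y_max=5000,
                             y_points=5,
                             fixed={"h2_a": 0.5, "h2_b": 0.5,
                                    "me_ac": 500.0, "me_bc": 500.0,
                                    "r_g_ac": 0.8, "r_g_bc": 0.8,
                                    "r_g_ab": 0.6, "b_ac": 0.9,
                                    "b_bc": 0.9})
        path = tmp_path / "surface.cfg"
        spec_to_config(spec, path)
        assert spec_from_config(path) == spec

    def test_comments_and_blank_lines(self, tmp_path):
        path = tmp_path / "c.cfg"
        path.write_text(
            "# a curve\n"
            "formula = daetwyler\n"
            "x_param = n_train\n"
            "x_min = 100  # lower bound\n"
            "x_max = 10000\n"
            "n_points = 11\n"
            "\n"
            "fixed.h2 = 0.5\n"
            "fixed.me = 1000\n")
        spec = spec_from_config(path)
        assert spec.formula_id == "daetwyler"
        assert spec.n_points == 11
        assert spec.fixed == {"h2": 0.5, "me": 1000}

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "c.cfg"
        path.write_text("formula = daetwyler\nx_param = n_train\n"
                        "x_min = 1\nx_max = 2\nbogus = 3\n")
        with pytest.raises(ParameterError, match="bogus"):
            spec_from_config(path)

    def test_missing_key_rejected(self, tmp_path):
        path = tmp_path / "c.cfg"
        path.write_text("formula = daetwyler\n")
        with pytest.raises(ParameterError, match="x_param"):
            spec_from_config(path)

    def test_malformed_line_cites_lineno(self, tmp_path):
        path = tmp_path / "c.cfg"
        path.write_text("formula = daetwyler\nnonsense line\n")
        with pytest.raises(ParameterError, match=":2"):
            spec_from_config(path)
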