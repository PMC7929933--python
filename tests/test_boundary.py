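"""Image-quantification pipeline: normalisation, typing, GP boundary."""

import numpy as np
import pandas as pd
import pytest

from grnprecision import boundary as B
from grnprecision.synth import (
    LOGISTIC_BAND_FACTOR,
    SyntheticEmbryoConfig,
    generate_embryo_table,
)


@pytest.fixture(scope="module")
def embryo():
    cfg = SyntheticEmbryoConfig(boundary_width_um=20.0, n_cells=1000, seed=21)
    tab, refs, truth = generate_embryo_table(cfg)
    return cfg, tab, refs, truth


@pytest.fixture(scope="module")
def preprocessed(embryo):
    cfg, tab, refs, truth = embryo
    pre = B.preprocess(tab, refs)
    return cfg, pre, truth


class TestPreprocess:
    def test_quantile_anchors_exact(self, preprocessed):
        _, pre, _ = preprocessed
        assert pre["nkx22"].quantile(0.40) == pytest.approx(0.08, abs=1e-12)
        assert pre["olig2"].quantile(0.40) == pytest.approx(0.08, abs=1e-12)
        assert pre["pax6"].quantile(0.60) == pytest.approx(0.60, abs=1e-12)
        assert pre["nkx22"].min() == pytest.approx(0.0, abs=1e-12)

    def test_alignment_puts_ventral_pole_at_origin(self, preprocessed):
        _, pre, _ = preprocessed
        assert pre["y_um"].min() > -1.0
        assert abs(pre["y_um"].max() - 300.0) < 5.0

    def test_idempotent_on_anchors(self, embryo, preprocessed):
        _, pre, _ = preprocessed
        refs0 = pd.DataFrame([{
            "embryo_id": pre["embryo_id"].iloc[0],
            "ventral_x": 0.0, "ventral_y": 0.0, "dorsal_x": 0.0, "dorsal_y": 300.0,
        }])
        twice = B.preprocess(pre, refs0)
        # anchors and alignment are reproduced exactly; the relative DAPI
        # cut may trim at most a sliver of the remaining lower tail
        assert twice["nkx22"].quantile(0.40) == pytest.approx(0.08, abs=1e-9)
        assert twice["pax6"].quantile(0.60) == pytest.approx(0.60, abs=1e-9)
        assert len(twice) >= 0.97 * len(pre)
        common = twice.merge(pre, on=["x_um", "y_um"], suffixes=("_2", "_1"))
        assert len(common) == len(twice)

    def test_artefacts_removed_and_real_cells_kept(self, embryo):
        cfg, tab, refs, truth = embryo
        pre = B.preprocess(tab, refs)
        kept = len(pre)
        n_artefacts = int(truth["artefact"].sum())
        # artefact DAPI sits 3.5 sd below the mean: all should be dropped
        assert kept <= len(tab) - n_artefacts
        # and not many genuine nuclei with them
        assert kept >= len(tab) - n_artefacts - int(0.05 * len(tab))

    def test_too_few_cells_names_embryo(self):
        cfg = SyntheticEmbryoConfig(n_cells=20, seed=1)
        tab, refs, _ = generate_embryo_table(cfg, embryo_id="tiny")
        with pytest.raises(B.PreprocessError, match="tiny"):
            B.preprocess(tab, refs, B.NormConfig(min_cells=50))


class TestClassifyCells:
    def test_rule_definitions(self):
        df = pd.DataFrame({
            "embryo_id": "E", "x_um": [0.0, 0.0], "y_um": [60.0, 90.0],
            "dapi": 1.0, "nkx22": [0.8, 0.05], "olig2": [0.05, 0.8], "pax6": [0.1, 0.6],
        })
        # provide dorsal context so the position windows are meaningful
        ctx = pd.DataFrame({
            "embryo_id": "E", "x_um": 0.0, "y_um": [299.0, 280.0],
            "dapi": 1.0, "nkx22": 0.02, "olig2": 0.02, "pax6": 0.7,
        })
        calls = B.classify_cells(pd.concat([df, ctx], ignore_index=True))
        assert calls.iloc[0] == "p3"
        assert calls.iloc[1] == "pMN"

    def test_accuracy_away_from_boundary(self, preprocessed):
        cfg, pre, truth = preprocessed
        calls = B.classify_cells(pre)
        # ground truth via aligned dorsoventral position (domains are
        # position-defined away from the mixing zone)
        yb = cfg.boundary_position_um
        far = (pre["y_um"] < yb - 2 * cfg.boundary_width_um) | (
            pre["y_um"] > yb + 2 * cfg.boundary_width_um
        )
        zone = (pre["y_um"] > 25.0) & (pre["y_um"] < 110.0)
        sel = far & zone
        expected = np.where(pre.loc[sel, "y_um"] < yb, "p3", "pMN")
        agree = (calls[sel].to_numpy() == expected).mean()
        assert agree >= 0.95

    def test_threshold_validation(self, preprocessed):
        _, pre, _ = preprocessed
        with pytest.raises(ValueError):
            B.classify_cells(pre, B.CellTypeThresholds(nkx_high=3.0))


class _AnalyticField:
    """Closed-form logistic probability field p(y) = 1/(1+exp((y-y0)/w))."""

    def __init__(self, y0=60.0, w=5.0):
        self.y0, self.w = y0, w
        self.bbox = (0.0, 100.0, 0.0, 300.0)
        self.hyperparameters = {}

    def __call__(self, x, y):
        return 1.0 / (1.0 + np.exp((np.asarray(y, float) - self.y0) / self.w))


class TestBoundaryWidthPosition:
    def test_sharp_step_field(self):
        f = _AnalyticField(w=1e-6)
        est = B.boundary_width_position(f, row_spacing=0.5)
        assert est.defined
        assert est.position_um == pytest.approx(60.0, abs=0.5)
        assert est.width_um <= 1.0

    def test_logistic_closed_form(self):
        w = 5.0
        est = B.boundary_width_position(_AnalyticField(w=w), row_spacing=0.25)
        assert est.width_um == pytest.approx(LOGISTIC_BAND_FACTOR * w, rel=0.05)
        assert est.position_um == pytest.approx(60.0, abs=0.5)

    def test_band_absent_flagged(self):
        class Flat:
            bbox = (0, 10, 0, 10)
            hyperparameters = {}

            def __call__(self, x, y):
                return np.full(np.asarray(x).size, 0.97)

        est = B.boundary_width_position(Flat())
        assert not est.defined


class TestGPClassifier:
    def test_separated_classes_confident(self, rng):
        n = 120
        y = np.concatenate([rng.uniform(0, 40, n), rng.uniform(80, 120, n)])
        x = rng.uniform(0, 50, 2 * n)
        tab = pd.DataFrame({"x_um": x, "y_um": y})
        calls = pd.Series(["p3"] * n + ["pMN"] * n)
        field = B.fit_boundary_classifier(tab, calls)
        p_in = field(np.full(5, 25.0), np.full(5, 20.0))
        p_out = field(np.full(5, 25.0), np.full(5, 100.0))
        assert np.all(p_in > 0.95)
        assert np.all(p_out < 0.05)

    def test_permutation_invariance(self, preprocessed, rng):
        _, pre, _ = preprocessed
        calls = B.classify_cells(pre)
        perm = rng.permutation(len(pre))
        f1 = B.fit_boundary_classifier(pre, calls)
        f2 = B.fit_boundary_classifier(pre.iloc[perm], calls.iloc[perm])
        xs = np.full(40, 50.0)
        ys = np.linspace(30, 100, 40)
        np.testing.assert_allclose(f1(xs, ys), f2(xs, ys), atol=5e-3)

    def test_single_class_rejected(self):
        tab = pd.DataFrame({"x_um": np.arange(30.0), "y_um": np.arange(30.0)})
        calls = pd.Series(["p3"] * 30)
        with pytest.raises(ValueError):
            B.fit_boundary_classifier(tab, calls)

    def test_contour_near_true_position(self, preprocessed):
        cfg, pre, _ = preprocessed
        calls = B.classify_cells(pre)
        field = B.fit_boundary_classifier(pre, calls)
        est = B.boundary_width_position(field)
        assert est.defined
        assert abs(est.position_um - cfg.boundary_position_um) < 5.0

    def test_translation_invariance(self, preprocessed):
        _, pre, _ = preprocessed
        calls = B.classify_cells(pre)
        f1 = B.fit_boundary_classifier(pre, calls)
        e1 = B.boundary_width_position(f1)
        shifted = pre.copy()
        shifted["y_um"] = shifted["y_um"] + 37.0
        f2 = B.fit_boundary_classifier(shifted, calls)
        e2 = B.boundary_width_position(f2)
        assert e2.position_um - e1.position_um == pytest.approx(37.0, abs=2.0)
        assert e2.width_um == pytest.approx(e1.width_um, rel=0.15)


class TestLevelAndVarianceReadouts:
    def test_tf_levels_empty_selection_warns(self, preprocessed):
        _, pre, _ = preprocessed
        calls = B.classify_cells(pre)

        class NoBand:
            def __call__(self, x, y):
                return np.zeros(np.asarray(x).size)

        with pytest.warns(UserWarning):
            out = B.tf_levels_boundary(pre, calls, NoBand())
        assert out.empty

    def test_tf_levels_selects_band_cells(self, preprocessed):
        cfg, pre, _ = preprocessed
        calls = B.classify_cells(pre)
        field = B.fit_boundary_classifier(pre, calls)
        out = B.tf_levels_boundary(pre, calls, field)
        assert not out.empty
        assert (out["p3_probability"].between(0.11, 0.89)).all()
        assert (out["olig2"] >= 0.3).all()

    def test_variance_stats_definitional(self, rng):
        tab = pd.DataFrame({
            "embryo_id": "E", "x_um": rng.uniform(0, 10, 4000),
            "y_um": rng.uniform(0, 10, 4000),
            "olig2": rng.normal(10, 2.0, 4000),
            "pax6": rng.normal(10, 3.0, 4000),
        })
        calls = pd.Series(["pMN"] * 4000)

        class Outside:
            def __call__(self, x, y):
                return np.zeros(np.asarray(x).size)

        stats = B.variance_stats(tab, calls, Outside())
        assert stats.rms_total == pytest.approx(np.sqrt(13.0), rel=0.1)

    def test_variance_stats_underpowered_is_none(self, rng):
        tab = pd.DataFrame({"embryo_id": "E", "x_um": [0.0], "y_um": [0.0],
                            "olig2": [1.0], "pax6": [1.0]})
        calls = pd.Series(["pMN"])

        class Outside:
            def __call__(self, x, y):
                return np.zeros(np.asarray(x).size)

        assert B.variance_stats(tab, calls, Outside()) is None
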