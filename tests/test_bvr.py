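"""BVR measures: closed forms, Poincare geometry, partial correlation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bvrpop.bvr import (
    bvr_measures,
    partial_correlation,
    partial_correlation_analysis,
    poincare,
)
from bvrpop.cell import APDSequence


class TestClosedForms:
    def test_constant_sequence_all_zero(self):
        m = bvr_measures(np.full(30, 250.0))
        assert (m.ran_APD, m.var_APD, m.STV_APD, m.LTV_APD) == (0, 0, 0, 0)

    def test_alternating_sequence(self):
        x = 250.0 + 5.0 * (-1.0) ** np.arange(30)
        m = bvr_measures(x)
        assert m.STV_APD == pytest.approx(5.0, abs=1e-12)
        assert m.LTV_APD == pytest.approx(0.0, abs=1e-12)
        assert m.ran_APD == pytest.approx(10.0)

    @pytest.mark.parametrize("slope", [0.5, 2.0])
    def test_linear_ramp(self, slope):
        x = 200.0 + slope * np.arange(1, 31)
        m = bvr_measures(x)
        assert m.STV_APD == pytest.approx(slope / 2.0, rel=1e-12)
        assert m.LTV_APD == pytest.approx(420.0 / 58.0 * slope, rel=1e-12)
        assert m.ran_APD == pytest.approx(29.0 * slope, rel=1e-12)

    def test_length_contract(self):
        with pytest.raises(ValueError, match="expected 30"):
            bvr_measures(np.arange(10.0) + 200.0, expected_length=30)
        with pytest.raises(ValueError, match="at least 2"):
            bvr_measures(np.array([250.0]))

    def test_incomplete_sequence_rejected(self):
        seq = APDSequence(np.full(30, 250.0), complete=False)
        with pytest.raises(ValueError, match="failure-flagged"):
            bvr_measures(seq)


@settings(max_examples=50, deadline=None)
@given(shift=st.floats(-50, 50), scale=st.floats(0.1, 10),
       seed=st.integers(0, 10_000))
def test_scale_equivariance(shift, scale, seed):
    """Adding a constant changes nothing; scaling by c scales STV/LTV/ran by c
    and var by c^2."""
    x = 230.0 + np.random.default_rng(seed).normal(0, 4, size=30)
    base = bvr_measures(x)
    shifted = bvr_measures(x + shift)
    assert shifted.STV_APD == pytest.approx(base.STV_APD, rel=1e-9, abs=1e-9)
    assert shifted.LTV_APD == pytest.approx(base.LTV_APD, rel=1e-9, abs=1e-9)
    assert shifted.ran_APD == pytest.approx(base.ran_APD, rel=1e-9, abs=1e-9)
    assert shifted.var_APD == pytest.approx(base.var_APD, rel=1e-9, abs=1e-9)
    scaled = bvr_measures(x * scale)
    assert scaled.STV_APD == pytest.approx(base.STV_APD * scale, rel=1e-9)
    assert scaled.var_APD == pytest.approx(base.var_APD * scale**2, rel=1e-9)


def test_formula_equals_poincare_geometry(rng):
    """STV/LTV from the printed sums equal the perpendicular/parallel mean
    distances of the Poincare points to the identity line (x sqrt(2))."""
    for _ in range(100):
        x = 230.0 + rng.normal(0, 5, size=30)
        m = bvr_measures(x)
        pairs, _ = poincare(x)
        d_perp = np.abs(pairs[:, 1] - pairs[:, 0]) / np.sqrt(2.0)
        along = (pairs[:, 0] + pairs[:, 1]) / np.sqrt(2.0)
        d_par = np.abs(along - 2.0 * x.mean() / np.sqrt(2.0))
        assert m.STV_APD == pytest.approx(d_perp.mean() / np.sqrt(2.0), rel=1e-12)
        assert m.LTV_APD == pytest.approx(d_par.mean() / np.sqrt(2.0), rel=1e-12)


class TestPoincare:
    def test_pair_count(self, rng):
        pairs, _ = poincare(230 + rng.normal(0, 3, 30))
        assert pairs.shape == (29, 2)

    def test_alternating_ratio_flagged(self):
        x = 250.0 + 5.0 * (-1.0) ** np.arange(30)
        pairs, ratio = poincare(x)
        assert ratio is None  # LTV = 0: ratio reported missing, never inf
        assert len(np.unique(pairs, axis=0)) == 2

    def test_white_noise_ratio_near_one(self, rng):
        ratios = []
        for _ in range(100):
            _, r = poincare(230 + rng.normal(0, 4, 30))
            ratios.append(r)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_single_beat_rejected(self):
        with pytest.raises(ValueError):
            poincare(np.array([250.0]))


class TestPartialCorrelation:
    def test_exact_linear_dependence(self, rng):
        X = rng.normal(size=(17, 4))
        y = X[:, 2].copy()
        r, p = partial_correlation(X[:, 2], y, np.delete(X, 2, axis=1))
        assert r == pytest.approx(1.0)
        for j in (0, 1, 3):
            rj, pj = partial_correlation(X[:, j], y, np.delete(X, j, axis=1))
            assert abs(rj) < 0.6
            assert pj > 0.05

    def test_insufficient_dof_rejected(self, rng):
        X = rng.normal(size=(5, 4))
        with pytest.raises(ValueError, match="degrees of freedom"):
            partial_correlation(X[:, 0], rng.normal(size=5), X[:, 1:])

    def test_collinear_controls_rejected(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        z = rng.normal(size=20)
        Z = np.column_stack([z, 2.0 * z, rng.normal(size=20)])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            partial_correlation(x, y, Z)

    def test_matches_pingouin(self, rng):
        """Residual-regression route agrees with the pingouin implementation."""
        import pandas as pd
        import pingouin as pg

        df = pd.DataFrame(rng.normal(size=(25, 5)),
                          columns=["x", "y", "a", "b", "c"])
        ours_r, ours_p = partial_correlation(
            df["x"].to_numpy(), df["y"].to_numpy(), df[["a", "b", "c"]].to_numpy())
        ref = pg.partial_corr(df, x="x", y="y", covar=["a", "b", "c"])
        assert ours_r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert ours_p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_analysis_table_flags(self, rng):
        import pandas as pd

        X = pd.DataFrame(rng.normal(size=(17, 4)),
                         columns=["N_IKr", "N_IKs", "N_to1", "N_CaL"])
        res = partial_correlation_analysis(X, X["N_to1"] * 2.0, measure="STV_APD")
        by_var = {r.variable: r for r in res}
        assert by_var["N_to1"].coefficient == pytest.approx(1.0)
        assert by_var["N_to1"].significant
        for r in res:
            assert -1.0 <= r.coefficient <= 1.0
            assert r.significant == (r.p_value <= 0.05)

    def test_constant_column_rejected(self, rng):
        import pandas as pd

        X = pd.DataFrame(rng.normal(size=(17, 4)), columns=list("abcd"))
        X["a"] = 3.0
        with pytest.raises(ValueError, match="constant"):
            partial_correlation_analysis(X, rng.normal(size=17))
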