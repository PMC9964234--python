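import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from deltacc.correlation import (
    CorrelationMatrix,
    correlation_matrix,
    correlation_summary,
    correlation_summary_blocked,
    delta_matrix,
    pearson,
)
from deltacc.io import ExpressionMatrix


def _em(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"G{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(pd.DataFrame(values, index=ids))


class TestPearson:
    def test_self_correlation_one(self):
        assert pearson([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_sign_flip_minus_one(self):
        assert pearson([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # sums of centered products: 3 / sqrt(2 * 14/3)
        assert pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(
            3 / math.sqrt(2 * 14 / 3)
        )
        assert pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(0.9820, abs=1e-4)

    def test_constant_vector_undefined(self):
        assert math.isnan(pearson([1, 1, 1], [1, 2, 3]))

    def test_length_mismatch_and_short_inputs_error(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson([1], [2])

    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=10),
        st.floats(0.1, 10),
        st.floats(-50, 50),
    )
    @settings(max_examples=100, deadline=None)
    def test_affine_invariance(self, xs, slope, offset):
        if max(xs) - min(xs) < 1e-6:
            return  # (near-)constant input: correlation degenerate
        ys = [2 * v + 1 for v in xs]
        r = pearson(xs, ys)
        if math.isnan(r):
            return
        r_pos = pearson([slope * v + offset for v in xs], ys)
        r_neg = pearson([-slope * v + offset for v in xs], ys)
        assert r_pos == pytest.approx(r, abs=1e-6)
        assert r_neg == pytest.approx(-r, abs=1e-6)


class TestCorrelationMatrix:
    def test_two_rows_off_diagonal_matches_pearson(self):
        m = _em([[1, 2, 3, 4], [2, 1, 4, 3]])
        cm = correlation_matrix(m)
        assert cm.cc[0, 1] == pytest.approx(pearson([1, 2, 3, 4], [2, 1, 4, 3]))

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        cm = correlation_matrix(_em(rng.normal(size=(10, 15))))
        assert np.allclose(cm.cc, cm.cc.T, atol=1e-12)
        assert np.allclose(np.diag(cm.cc), 1.0)
        assert np.all(np.abs(cm.cc) <= 1 + 1e-12)

    def test_zero_variance_row_gives_nan(self):
        m = _em([[1, 1, 1], [1, 2, 3], [3, 1, 2]])
        cm = correlation_matrix(m)
        assert np.isnan(cm.cc[0, 1]) and np.isnan(cm.cc[2, 0])
        assert np.isfinite(cm.cc[1, 2])

    def test_single_column_errors(self):
        with pytest.raises(ValueError):
            correlation_matrix(_em([[1], [2]]))

    def test_empirical_cc_matches_sampling_target(self):
        # correlated pair planted via known bivariate construction
        rng = np.random.default_rng(1)
        n = 5000
        rho = 0.8
        z1 = rng.standard_normal(n)
        z2 = rho * z1 + math.sqrt(1 - rho**2) * rng.standard_normal(n)
        extra = rng.standard_normal((3, n))
        cm = correlation_matrix(_em(np.vstack([z1, z2, extra])))
        assert cm.cc[0, 1] == pytest.approx(rho, abs=0.05)
        assert abs(cm.cc[0, 2]) < 0.05


class TestDeltaMatrix:
    def _cm(self, cc, ids, label=""):
        return CorrelationMatrix(ids, np.asarray(cc, float), label)

    def test_printed_study_values(self):
        # two pairs from the study's rewired-pair table
        ids = ["ACSL4", "CCNC"]
        d = delta_matrix(
            self._cm([[1, 0.75], [0.75, 1]], ids, "Pre"),
            self._cm([[1, -0.74], [-0.74, 1]], ids, "In"),
        )
        assert d.dcc[0, 1] == pytest.approx(-1.49)
        ids = ["CCL2", "CREB1"]
        d = delta_matrix(
            self._cm([[1, 0.93], [0.93, 1]], ids),
            self._cm([[1, -0.09], [-0.09, 1]], ids),
        )
        assert d.dcc[0, 1] == pytest.approx(-1.02)

    def test_identical_matrices_zero(self):
        rng = np.random.default_rng(2)
        cm = correlation_matrix(_em(rng.normal(size=(5, 10))))
        assert np.allclose(delta_matrix(cm, cm).dcc, 0.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        a = correlation_matrix(_em(rng.normal(size=(6, 12))))
        b = correlation_matrix(_em(rng.normal(size=(6, 12))))
        assert np.allclose(delta_matrix(a, b).dcc, -delta_matrix(b, a).dcc)

    def test_id_mismatch_errors(self):
        a = CorrelationMatrix(["X", "Y"], np.eye(2))
        b = CorrelationMatrix(["X", "Z"], np.eye(2))
        with pytest.raises(ValueError):
            delta_matrix(a, b)


class TestCorrelationSummary:
    def test_identity_matrix_all_weak(self):
        cm = CorrelationMatrix(list("abc"), np.eye(3))
        s = correlation_summary(cm)
        assert s.mean_abs_cc == 0.0
        assert s.frac_weak == 1.0

    def test_all_strong(self):
        cc = np.full((3, 3), 0.9)
        np.fill_diagonal(cc, 1.0)
        s = correlation_summary(CorrelationMatrix(list("abc"), cc))
        assert s.mean_abs_cc == pytest.approx(0.9)
        assert s.frac_strong == 1.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        s = correlation_summary(correlation_matrix(_em(rng.normal(size=(20, 10)))))
        assert s.frac_weak + s.frac_moderate + s.frac_strong == pytest.approx(1.0)

    def test_scrambled_condition_less_coordinated(self):
        # coordinated: strong shared factor; scrambled: independent noise
        rng = np.random.default_rng(5)
        factor = rng.standard_normal(30)
        coord = factor + 0.3 * rng.standard_normal((15, 30))
        scram = rng.standard_normal((15, 30))
        s_coord = correlation_summary(correlation_matrix(_em(coord)))
        s_scram = correlation_summary(correlation_matrix(_em(scram)))
        assert s_scram.mean_abs_cc < s_coord.mean_abs_cc

    def test_blocked_summary_matches_full(self):
        rng = np.random.default_rng(6)
        m = _em(rng.normal(size=(40, 12)))
        full = correlation_summary(correlation_matrix(m))
        blocked = correlation_summary_blocked(m, block_size=7)
        assert blocked.mean_abs_cc == pytest.approx(full.mean_abs_cc, abs=1e-12)
        assert blocked.frac_weak == pytest.approx(full.frac_weak)
        assert blocked.frac_moderate == pytest.approx(full.frac_moderate)
        assert blocked.frac_strong == pytest.approx(full.frac_strong)
        assert blocked.n_pairs == full.n_pairs

    def test_blocked_summary_counts_undefined_rows(self):
        vals = np.vstack([np.ones(10), np.random.default_rng(7).normal(size=(4, 10))])
        blocked = correlation_summary_blocked(_em(vals), block_size=2)
        assert blocked.n_undefined == 4  # constant row against the other 4
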