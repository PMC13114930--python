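"""Exact information-theoretic primitives against closed forms and oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.integrate import quad
from scipy.stats import norm

from mmib.infocore import (
    DiagGaussian,
    DiscreteJoint,
    conditional_mi_discrete,
    entropy_categorical,
    expected_calibration_error,
    kl_diag_gaussian,
    plugin_mi_discrete,
    predictive_entropy,
)


class TestEntropyCategorical:
    @pytest.mark.parametrize(
        "p, expected",
        [
            (np.full(5, 0.2), np.log(5)),
            ([1.0, 0.0, 0.0], 0.0),
            ([0.5, 0.5], np.log(2)),
        ],
    )
    def test_closed_forms(self, p, expected):
        assert entropy_categorical(p) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [[0.5, 0.6], [-0.1, 1.1], [0.2, 0.2]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            entropy_categorical(bad)

    @given(
        arrays(float, 4, elements=st.floats(0.01, 1.0)),
        arrays(float, 4, elements=st.floats(0.01, 1.0)),
        st.floats(0.0, 1.0),
    )
    def test_concavity(self, a, b, w):
        p, q = a / a.sum(), b / b.sum()
        mix = w * p + (1 - w) * q
        assert entropy_categorical(mix) >= (
            w * entropy_categorical(p) + (1 - w) * entropy_categorical(q) - 1e-9
        )


class TestKLDiagGaussian:
    def test_zero_iff_equal(self):
        q = DiagGaussian([0.0, 1.0], [1.0, 2.0])
        assert kl_diag_gaussian(q, q) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "q, r, expected",
        [
            (DiagGaussian([1.0], [1.0]), DiagGaussian([0.0], [1.0]), 0.5),
            (
                DiagGaussian([0.0], [4.0]),
                DiagGaussian([0.0], [1.0]),
                0.5 * (4 - np.log(4) - 1),
            ),
        ],
    )
    def test_closed_forms(self, q, r, expected):
        assert kl_diag_gaussian(q, r) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_quadrature_oracle(self, rng):
        """Closed form vs numerical integration of q ln(q/r) in 1-D."""
        for _ in range(100):
            mq, mr = rng.normal(size=2)
            vq, vr = rng.uniform(0.2, 3.0, size=2)
            f = lambda x: norm.pdf(x, mq, np.sqrt(vq)) * (
                norm.logpdf(x, mq, np.sqrt(vq)) - norm.logpdf(x, mr, np.sqrt(vr))
            )
            oracle, _ = quad(f, -30, 30, limit=200)
            val = kl_diag_gaussian(DiagGaussian([mq], [vq]), DiagGaussian([mr], [vr]))
            assert val == pytest.approx(oracle, abs=1e-6)
            assert val >= -1e-12

    def test_dimension_and_variance_validation(self):
        with pytest.raises(ValueError):
            kl_diag_gaussian(DiagGaussian([0.0], [1.0]), DiagGaussian([0.0, 0.0], [1.0, 1.0]))
        with pytest.raises(ValueError):
            DiagGaussian([0.0], [0.0])


def _random_joint(rng, shape):
    p = rng.random(shape) + 1e-3
    return DiscreteJoint(p / p.sum())


class TestPluginMI:
    def test_independent_product_is_zero(self, rng):
        px = rng.dirichlet(np.ones(3))
        py = rng.dirichlet(np.ones(4))
        joint = DiscreteJoint(np.outer(px, py))
        assert plugin_mi_discrete(joint) == pytest.approx(0.0, abs=1e-12)

    def test_xor_marginals_and_joint(self):
        pmf = np.zeros((2, 2, 2))
        for x1 in (0, 1):
            for x2 in (0, 1):
                pmf[x1, x2, x1 ^ x2] = 0.25
        joint = DiscreteJoint(pmf)
        assert plugin_mi_discrete(joint, ((0,), (1, 2))) == pytest.approx(
            np.log(2), abs=1e-12
        )  # I(X1; (X2,Y)) = ln 2: X1 is recoverable from (X2, Y)
        # I(X1;Y) = 0 by symmetry, I((X1,X2);Y) = ln 2
        m = DiscreteJoint(joint.marginal((0, 2)))
        assert plugin_mi_discrete(m) == pytest.approx(0.0, abs=1e-12)
        assert plugin_mi_discrete(joint, ((0, 1), (2,))) == pytest.approx(
            np.log(2), abs=1e-12
        )

    def test_binary_symmetric_channel(self):
        p = 0.1
        pmf = np.array([[(1 - p) / 2, p / 2], [p / 2, (1 - p) / 2]])
        expected = np.log(2) - (-p * np.log(p) - (1 - p) * np.log(1 - p))
        assert plugin_mi_discrete(DiscreteJoint(pmf)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_symmetry_in_blocks(self, rng):
        joint = _random_joint(rng, (3, 4))
        assert plugin_mi_discrete(joint, ((0,), (1,))) == pytest.approx(
            plugin_mi_discrete(joint, ((1,), (0,))), abs=1e-12
        )

    def test_data_processing_inequality(self, rng):
        """I(Z;Y) <= I(X;Y) on random Markov chains Y -> X -> Z."""
        for _ in range(100):
            py = rng.dirichlet(np.ones(3))
            px_y = rng.dirichlet(np.ones(3), size=3)  # rows: p(x|y)
            pz_x = rng.dirichlet(np.ones(3), size=3)
            joint_yx = py[:, None] * px_y
            joint_yxz = joint_yx[:, :, None] * pz_x[None, :, :]
            jd = DiscreteJoint(joint_yxz)  # axes (Y, X, Z)
            i_xy = plugin_mi_discrete(DiscreteJoint(jd.marginal((0, 1))))
            i_zy = plugin_mi_discrete(DiscreteJoint(jd.marginal((0, 2))))
            assert i_zy <= i_xy + 1e-9

    def test_chain_rule_with_conditional_mi(self, rng):
        """I((X1,X2);Y) = I(X1;Y) + I(X2;Y|X1) exactly on random joints."""
        for _ in range(20):
            joint = _random_joint(rng, (2, 3, 2))  # (X1, X2, Y)
            lhs = plugin_mi_discrete(joint, ((0, 1), (2,)))
            i1 = plugin_mi_discrete(DiscreteJoint(joint.marginal((0, 2))))
            cmi = conditional_mi_discrete(joint, (1,), (2,), (0,))
            assert lhs == pytest.approx(i1 + cmi, abs=1e-12)

    def test_invalid_groups_rejected(self, rng):
        joint = _random_joint(rng, (2, 2))
        with pytest.raises(ValueError):
            plugin_mi_discrete(joint, ((), (0, 1)))
        with pytest.raises(ValueError):
            plugin_mi_discrete(joint, ((0,), (0, 1)))


class TestECE:
    def test_confident_and_correct_is_zero(self):
        p = np.tile([1.0, 0.0], (20, 1))
        assert expected_calibration_error(p, np.zeros(20, int)) == pytest.approx(0.0)

    def test_single_bin_gap(self):
        p = np.tile([0.9, 0.1], (10, 1))
        y = np.array([0] * 5 + [1] * 5)
        assert expected_calibration_error(p, y) == pytest.approx(0.4, abs=1e-12)

    def test_two_bin_hand_enumeration(self):
        # bin (0.6,0.7]: 4 samples conf 0.65, 2 correct -> gap 0.15, weight 0.4
        # bin (0.9,1.0]: 6 samples conf 0.95, 5 correct -> gap |5/6-0.95|, weight 0.6
        p = np.array([[0.65, 0.35]] * 4 + [[0.95, 0.05]] * 6)
        y = np.array([0, 0, 1, 1] + [0] * 5 + [1])
        expected = 0.4 * 0.15 + 0.6 * abs(5 / 6 - 0.95)
        assert expected_calibration_error(p, y) == pytest.approx(expected, abs=1e-12)

    def test_invalid_bins(self):
        with pytest.raises(ValueError):
            expected_calibration_error(np.array([[1.0, 0.0]]), np.array([0]), n_bins=0)


def test_predictive_entropy_matches_categorical_entropy(rng):
    p = rng.dirichlet(np.ones(4), size=10)
    h = predictive_entropy(p)
    for row, hv in zip(p, h):
        assert hv == pytest.approx(entropy_categorical(row), abs=1e-9)
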