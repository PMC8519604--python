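"""Gaussian-kernel MMD, class weights and the label-conditional loss."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eegmsda as m
from eegmsda.local_mmd import llmmd


# ---- independent oracles -------------------------------------------------


def kernel_oracle(x, y, sigmas):
    return np.mean([np.exp(-np.sum((x - y) ** 2) / (2 * s**2)) for s in sigmas])


def mmd_oracle(X, Y, sigmas):
    n, mm = len(X), len(Y)
    kxx = sum(kernel_oracle(X[i], X[j], sigmas) for i in range(n) for j in range(n))
    kyy = sum(kernel_oracle(Y[i], Y[j], sigmas) for i in range(mm) for j in range(mm))
    kxy = sum(kernel_oracle(X[i], Y[j], sigmas) for i in range(n) for j in range(mm))
    return kxx / n**2 + kyy / mm**2 - 2 * kxy / (n * mm)


def llmmd_oracle(Xs, ys, Xt, pt, sigmas, literal=False):
    """Triple-loop per-class weighted kernel sums, one source domain."""
    C = ys.shape[1]
    counts = ys.sum(axis=0)
    ws = ys / np.where(counts > 0, counts, 1)
    mass = pt.sum(axis=0)
    wt = pt / np.where(mass > 0, mass, 1)
    ns, nt = len(Xs), len(Xt)
    total = 0.0
    for c in range(C):
        if counts[c] == 0 and mass[c] == 0:
            continue
        ss = sum(
            ws[i, c] * ws[j, c] * kernel_oracle(Xs[i], Xs[j], sigmas)
            for i in range(ns) for j in range(ns)
        )
        stt = sum(
            ws[i, c] * wt[j, c] * kernel_oracle(Xs[i], Xt[j], sigmas)
            for i in range(ns) for j in range(nt)
        )
        tt = sum(
            wt[i, c] * wt[j, c] * kernel_oracle(Xt[i], Xt[j], sigmas)
            for i in range(nt) for j in range(nt)
        )
        if literal:
            total += ss / ns**2 - 2 * stt / (ns * nt) + tt / nt**2
        else:
            total += ss - 2 * stt + tt
    return total / C


# ---- kernel & MMD --------------------------------------------------------


class TestKernel:
    def test_zero_distance_gives_one(self):
        x = np.array([[1.0, 2.0]])
        assert m.kernel_matrix(x, x)[0, 0] == pytest.approx(1.0)

    def test_printed_closed_form(self):
        k = m.kernel_matrix(np.array([[0.0]]), np.array([[np.sqrt(2.0)]]))
        assert k[0, 0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_symmetry_and_range(self, rng):
        X = rng.normal(size=(6, 3))
        K = m.kernel_matrix(X, X, m.KernelSpec(sigmas=(0.5, 1.0, 2.0)))
        np.testing.assert_allclose(K, K.T)
        assert (K > 0).all() and (K <= 1 + 1e-12).all()

    def test_dimension_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            m.kernel_matrix(rng.normal(size=(2, 3)), rng.normal(size=(2, 4)))


class TestMMD:
    def test_identical_samples_give_zero(self, rng):
        X = rng.normal(size=(10, 4))
        assert m.mmd_squared(X, X.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_two_dirac_closed_form(self):
        got = m.mmd_squared(np.array([[0.0]]), np.array([[np.sqrt(2.0)]]))
        assert got == pytest.approx(2 - 2 * np.exp(-1.0), abs=1e-12)

    def test_matches_bruteforce_on_random_instances(self, rng):
        sigmas = (0.7, 1.3)
        for _ in range(25):
            X = rng.normal(size=(rng.integers(2, 7), 3))
            Y = rng.normal(size=(rng.integers(2, 7), 3))
            got = m.mmd_squared(X, Y, m.KernelSpec(sigmas=sigmas))
            assert got == pytest.approx(mmd_oracle(X, Y, sigmas), rel=1e-10, abs=1e-12)

    def test_empty_set_rejected(self, rng):
        with pytest.raises(ValueError):
            m.mmd_squared(np.empty((0, 2)), rng.normal(size=(3, 2)))


# ---- class weights -------------------------------------------------------


class TestClassWeights:
    def test_hard_label_example(self):
        labels = np.eye(2)[[0, 0, 1, 1, 1]]
        ws = m.source_class_weights(labels)
        np.testing.assert_allclose(ws.class_weights(0), [0.5, 0.5])
        np.testing.assert_allclose(ws.class_weights(1), [1 / 3] * 3)

    def test_single_sample_class_gets_unit_weight(self):
        ws = m.source_class_weights(np.array([[1.0, 0.0]]))
        np.testing.assert_allclose(ws.class_weights(0), [1.0])
        assert ws.empty[1]

    def test_soft_weight_example(self):
        probs = np.array([[0.8, 0.2], [0.2, 0.8]])
        wt = m.target_class_weights(probs)
        np.testing.assert_allclose(wt.weights[:, 0], [0.8, 0.2])
        np.testing.assert_allclose(wt.weights[:, 1], [0.2, 0.8])

    def test_onehot_probs_reduce_to_hard_weights(self, rng):
        y = rng.integers(0, 2, size=12)
        onehot = np.eye(2)[y]
        np.testing.assert_allclose(
            m.target_class_weights(onehot).weights,
            m.source_class_weights(onehot).weights,
        )

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_per_class_sums_are_one(self, seed):
        rng = np.random.default_rng(seed)
        n, C = int(rng.integers(1, 20)), int(rng.integers(2, 5))
        probs = rng.dirichlet(np.ones(C), size=n)
        wt = m.target_class_weights(probs)
        np.testing.assert_allclose(wt.weights.sum(axis=0)[~wt.empty], 1.0)
        y = np.eye(C)[rng.integers(0, C, size=n)]
        ws = m.source_class_weights(y)
        np.testing.assert_allclose(ws.weights.sum(axis=0)[~ws.empty], 1.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            m.source_class_weights(np.array([[0.5, 0.5]]))
        with pytest.raises(ValueError):
            m.target_class_weights(np.array([[-0.1, 1.1]]))


# ---- the local loss ------------------------------------------------------


class TestLLMMD:
    def test_perfectly_aligned_pair_is_zero(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.eye(2)[rng.integers(0, 2, size=10)]
        res = llmmd([X], [y], X, y.astype(float))
        assert res.total == pytest.approx(0.0, abs=1e-10)

    def test_uniform_single_class_reduces_to_mmd(self, rng):
        X, Y = rng.normal(size=(8, 3)), rng.normal(size=(6, 3))
        y = np.ones((8, 1))
        pt = np.ones((6, 1))
        res = llmmd([X], [y], Y, pt)
        assert res.total == pytest.approx(m.mmd_squared(X, Y), rel=1e-10)

    def test_matches_triple_loop_oracle(self, rng):
        sigmas = (0.9,)
        for mode, literal in (("weighted", False), ("literal", True)):
            for _ in range(10):
                ns, nt = rng.integers(3, 8), rng.integers(3, 8)
                Xs = rng.normal(size=(ns, 2))
                Xt = rng.normal(size=(nt, 2))
                ys = np.eye(2)[rng.integers(0, 2, size=ns)]
                pt = rng.dirichlet(np.ones(2), size=nt)
                res = llmmd([Xs], [ys], Xt, pt, m.KernelSpec(sigmas=sigmas), mode=mode)
                want = llmmd_oracle(Xs, ys, Xt, pt, sigmas, literal=literal)
                assert res.total == pytest.approx(want, rel=1e-10, abs=1e-12)

    def test_invariant_under_sample_reordering(self, rng):
        Xs = rng.normal(size=(9, 3))
        ys = np.eye(2)[rng.integers(0, 2, size=9)]
        Xt = rng.normal(size=(7, 3))
        pt = rng.dirichlet(np.ones(2), size=7)
        a = llmmd([Xs], [ys], Xt, pt).total
        ps, ptm = rng.permutation(9), rng.permutation(7)
        b = llmmd([Xs[ps]], [ys[ps]], Xt[ptm], pt[ptm]).total
        assert a == pytest.approx(b, rel=1e-12)

    def test_decreases_as_target_interpolates_toward_source(self, rng):
        Xs = rng.normal(size=(60, 2))
        ys = np.eye(2)[np.repeat([0, 1], 30)]
        Xs[ys[:, 1] == 1] += 3.0
        far = Xs + np.array([4.0, -4.0])
        vals = []
        for t in (0.0, 0.5, 1.0):
            Xt = (1 - t) * far + t * Xs
            vals.append(llmmd([Xs], [ys], Xt, ys.astype(float)).total)
        assert vals[0] > vals[1] > vals[2]

    def test_class_absent_on_both_sides_is_flagged_zero(self, rng):
        Xs = rng.normal(size=(5, 2))
        ys = np.eye(2)[np.zeros(5, int)]  # class 1 absent
        Xt = rng.normal(size=(4, 2))
        pt = np.column_stack([np.ones(4), np.zeros(4)])
        res = llmmd([Xs], [ys], Xt, pt)
        assert (0, 1) in res.skipped
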