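import numpy as np
import pytest

from mbwater.fitting import (
    BasisSpec,
    FittedTerm,
    build_basis,
    default_spec,
    design_matrix,
    error_stats,
    feature_count,
    fit_replacement_terms,
    fit_term,
    _variable_permutations,
)
from mbwater.potentials import make_surrogate_potential, swap_terms
from mbwater.potentials.params import DistortionSpec
from mbwater.synthetic import (
    LabeledSet,
    label_set,
    sample_dimer_set,
    sample_trimer_set,
)


def _burnside_orbit_count(order: int, degree: int) -> int:
    """Independent oracle: Burnside's lemma over the variable permutation
    group; monomials of total degree 1..degree fixed by g are multisets
    over g's cycles."""
    perms = _variable_permutations(order)
    total = 0
    for g in perms:
        # cycle lengths of g
        seen = [False] * len(g)
        cycles = []
        for i in range(len(g)):
            if not seen[i]:
                length = 0
                j = i
                while not seen[j]:
                    seen[j] = True
                    j = g[j]
                    length += 1
                cycles.append(length)
        # DP: number of invariant monomials of each total degree
        counts = np.zeros(degree + 1)
        counts[0] = 1
        for ell in cycles:
            new = counts.copy()
            for d in range(ell, degree + 1):
                new[d] += new[d - ell]
            counts = new
        total += counts[1:].sum()
    return round(total / len(perms))


@pytest.mark.parametrize("order,degree", [(2, 1), (2, 2), (2, 3), (3, 1),
                                          (3, 2)])
def test_feature_count_matches_burnside(order, degree):
    spec = BasisSpec(order=order, degree=degree)
    assert feature_count(spec) == _burnside_orbit_count(order, degree)


def test_features_invariant_under_molecule_and_h_swaps(dimers_small):
    spec = default_spec(2)
    cfg = dimers_small[0]
    f0 = build_basis(cfg, spec)
    # swap the two molecules
    swapped = cfg.subset([1, 0])
    np.testing.assert_allclose(build_basis(swapped, spec), f0, atol=1e-12)
    # swap H atoms of molecule 0
    hs = cfg.copy()
    hs.coords[[1, 2]] = hs.coords[[2, 1]]
    np.testing.assert_allclose(build_basis(hs, spec), f0, atol=1e-12)


def test_features_vanish_beyond_switch(truth):
    from mbwater.config import assemble, reference_monomer

    spec = default_spec(2)
    cfg = assemble([reference_monomer(),
                    reference_monomer() + [0, 0, spec.r_out + 0.5]])
    assert np.abs(build_basis(cfg, spec)).max() == 0.0


def test_size_mismatch_rejected(trimers_small):
    with pytest.raises(ValueError):
        build_basis(trimers_small[0], default_spec(2))


class TestFitTerm:
    def test_in_basis_recovery(self, dimers_small):
        spec = default_spec(2)
        rng = np.random.default_rng(5)
        coef = rng.normal(scale=0.5, size=feature_count(spec))
        target = FittedTerm(spec, coef)
        cfgs = sample_dimer_set(600, (2.2, 8.0), seed=42)
        y = target.evaluate_batch(np.stack([c.coords for c in cfgs]))
        train = LabeledSet(cfgs, y, order=2, level_tag="in-basis")
        fitted = fit_term(train, spec, ridge=1e-12)
        assert fitted.training_stats.rmsd < 1e-8

    def test_noise_floor(self):
        """With Gaussian label noise the training RMSD approaches sigma."""
        spec = BasisSpec(order=2, degree=2)
        cfgs = sample_dimer_set(1500, (2.2, 8.0), seed=43)
        sigma = 0.3
        rng = np.random.default_rng(3)
        y = rng.normal(scale=sigma, size=len(cfgs))
        train = LabeledSet(cfgs, y, order=2, level_tag="noise")
        fitted = fit_term(train, spec, ridge=1e-10)
        assert fitted.training_stats.rmsd <= sigma * 1.05
        assert fitted.training_stats.rmsd >= sigma * 0.8

    def test_duplicated_training_set_same_coefficients(self, dimers_small):
        spec = BasisSpec(order=2, degree=2)
        cfgs = sample_dimer_set(200, (2.2, 8.0), seed=44)
        rng = np.random.default_rng(4)
        y = rng.normal(size=len(cfgs))
        t1 = fit_term(LabeledSet(cfgs, y, order=2, level_tag="x"), spec)
        t2 = fit_term(LabeledSet(cfgs + cfgs, np.concatenate([y, y]),
                                 order=2, level_tag="x"), spec)
        np.testing.assert_allclose(t1.coefficients, t2.coefficients,
                                   atol=1e-8)

    def test_order_mismatch(self, trimers_small, truth):
        lab = label_set(trimers_small[:5], truth, order=3)
        with pytest.raises(ValueError):
            fit_term(lab, default_spec(2))

    def test_permutation_invariance_of_fitted_term(self, dimers_small):
        spec = default_spec(2)
        rng = np.random.default_rng(9)
        term = FittedTerm(spec, rng.normal(size=feature_count(spec)))
        cfg = dimers_small[1]
        v = term.evaluate(cfg)
        assert term.evaluate(cfg.subset([1, 0])) == pytest.approx(
            v, abs=1e-12)


class TestErrorStats:
    def test_perfect_predictions(self, truth, dimers_small):
        lab = label_set(dimers_small[:10], truth, order=2)
        st = error_stats(truth, lab)
        assert st.rmsd == pytest.approx(0.0, abs=1e-10)
        assert st.pearson_r == pytest.approx(1.0, abs=1e-10)

    def test_constant_offset(self, truth, dimers_small):
        lab = label_set(dimers_small[:10], truth, order=2)
        shifted = LabeledSet(lab.configs, lab.energies - 0.7, order=2,
                             level_tag="shift")
        st = error_stats(truth, shifted)
        assert st.rmsd == pytest.approx(0.7, abs=1e-10)
        assert st.mae == pytest.approx(0.7, abs=1e-10)
        assert st.pearson_r == pytest.approx(1.0, abs=1e-9)

    def test_hand_computed_rmsd(self):
        spec = BasisSpec(order=2, degree=1)
        term = FittedTerm(spec, np.zeros(feature_count(spec)))
        cfgs = sample_dimer_set(5, (2.5, 5.0), seed=50)
        y = np.array([0.1, -0.2, 0.3, 0.0, -0.1])
        st = error_stats(term, LabeledSet(cfgs, y, order=2, level_tag="h"))
        assert st.rmsd == pytest.approx(np.sqrt(np.mean(y**2)), abs=1e-12)
        assert st.max_abs == pytest.approx(0.3, abs=1e-12)

    def test_empty_set_rejected(self, truth):
        with pytest.raises(ValueError):
            error_stats(truth, LabeledSet([], np.array([]), order=2,
                                          level_tag="x"))


def test_monotone_degradation_with_distortion(truth):
    """Surrogate labels drift monotonically from truth labels as the
    distortion is scaled x1, x2, x4 (the functional-rung trend analog)."""
    base = DistortionSpec(0.04, 0.05, 0.10, label="d")
    cfgs = sample_dimer_set(300, (2.3, 7.5), seed=55)
    lab_t = label_set(cfgs, truth, order=2)
    rmsds = []
    for f in (1.0, 2.0, 4.0):
        sur = make_surrogate_potential(truth, base.scaled(f))
        st = error_stats(sur, lab_t)
        rmsds.append(st.rmsd)
    assert rmsds[0] < rmsds[1] < rmsds[2]


def test_out_of_sample_within_twice_training_for_in_basis_target():
    """For a noise-free in-basis target, held-out RMSD stays within twice
    the training RMSD (both at the numerical-noise floor)."""
    spec = default_spec(2)
    rng = np.random.default_rng(70)
    target = FittedTerm(spec, rng.normal(scale=0.5,
                                         size=feature_count(spec)))
    train_cfg = sample_dimer_set(800, (2.2, 8.0), seed=60)
    test_cfg = sample_dimer_set(200, (2.2, 8.0), seed=62)
    y_train = target.evaluate_batch(np.stack([c.coords
                                              for c in train_cfg]))
    fitted = fit_term(LabeledSet(train_cfg, y_train, order=2,
                                 level_tag="in-basis"), spec, ridge=1e-12)
    y_test = target.evaluate_batch(np.stack([c.coords for c in test_cfg]))
    st = error_stats(fitted, LabeledSet(test_cfg, y_test, order=2,
                                        level_tag="in-basis"))
    assert st.rmsd < max(2.0 * fitted.training_stats.rmsd, 1e-8)


def test_hybrid_reproduces_surrogate_out_of_sample(truth, surrogate):
    """(2B+3B) term swap: the hybrid tracks the surrogate's 2B/3B energies
    on held-out clusters; the 3B polynomial only approximates the
    triple-dipole shape, so the tolerance is absolute and small against
    the ~0.1 kcal/mol 3B energy scale."""
    d_train = sample_dimer_set(800, (2.2, 8.0), seed=60)
    t_train = sample_trimer_set(500, (2.4, 6.0), seed=61)
    f2, f3 = fit_replacement_terms(
        truth,
        label_set(d_train, surrogate, order=2),
        label_set(t_train, surrogate, order=3),
    )
    hyb = swap_terms(truth, two_body=f2, three_body=f3)
    d_test = sample_dimer_set(150, (2.2, 8.0), seed=62)
    t_test = sample_trimer_set(100, (2.4, 6.0), seed=63)
    st2 = error_stats(hyb, label_set(d_test, surrogate, order=2))
    st3 = error_stats(hyb, label_set(t_test, surrogate, order=3))
    assert st2.rmsd < 5e-3
    assert st3.rmsd < 5e-3
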