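from dataclasses import replace
from math import comb

import numpy as np
import pytest

from mbwater import mbe
from mbwater.potentials import make_truth_potential
from mbwater.potentials.params import WaterParams
from mbwater.synthetic import sample_trimer_set


@pytest.fixture(scope="module")
def pairwise_potential():
    """Strictly pairwise-additive: charges + dispersion + repulsion, but no
    induction and no 3B term."""
    return make_truth_potential(
        replace(WaterParams(), alpha_o=0.0, c9=0.0))


@pytest.fixture(scope="module")
def one_body_potential():
    return make_truth_potential(
        replace(WaterParams(), alpha_o=0.0, c9=0.0, q_h=0.0, c6_oo=0.0,
                bm_a=0.0, bm_a_oh=0.0, bm_a_hh=0.0))


def test_subset_energy_definitions(truth, trimers_small):
    cfg = trimers_small[0]
    full = mbe.subset_energy(cfg, truth, (0, 1, 2))
    assert full == pytest.approx(truth.energy(cfg), abs=1e-12)
    e_i = mbe.subset_energy(cfg, truth, (1,))
    assert e_i == pytest.approx(truth.energy(cfg.subset([1])), abs=1e-12)
    # order independence
    assert mbe.subset_energy(cfg, truth, (2, 0)) == pytest.approx(
        mbe.subset_energy(cfg, truth, (0, 2)), abs=1e-12)
    with pytest.raises(ValueError):
        mbe.subset_energy(cfg, truth, (0, 0))


def test_dimer_term_is_pair_minus_monomers(truth, dimers_small):
    cfg = dimers_small[0]
    e2 = mbe.nbody_term(cfg, truth, (0, 1))
    expect = (mbe.subset_energy(cfg, truth, (0, 1))
              - mbe.subset_energy(cfg, truth, (0,))
              - mbe.subset_energy(cfg, truth, (1,)))
    assert e2 == pytest.approx(expect, abs=1e-12)


def test_recursive_and_moebius_agree(truth):
    from mbwater.synthetic import build_liquid_box

    box = build_liquid_box(5, 0.8, seed=13)
    cluster = box.copy()
    cluster.box_edge = None
    for k in (2, 3, 5):
        subset = tuple(range(k))
        a = mbe.nbody_term(cluster, truth, subset, method="moebius")
        b = mbe.nbody_term(cluster, truth, subset, method="recursive")
        assert a == pytest.approx(b, abs=1e-10)


def test_pairwise_potential_kills_high_orders(pairwise_potential,
                                              trimers_small):
    for cfg in trimers_small[:5]:
        assert abs(mbe.nbody_term(cfg, pairwise_potential, (0, 1, 2))) \
            < 1e-10


def test_one_body_potential_kills_two_body(one_body_potential,
                                           trimers_small):
    cfg = trimers_small[0]
    for pair in ((0, 1), (0, 2), (1, 2)):
        assert abs(mbe.nbody_term(cfg, one_body_potential, pair)) < 1e-10


def test_decompose_telescoping_and_counts(truth, compact_hexamer):
    dec = mbe.decompose(compact_hexamer, truth, max_order=6)
    assert dec.reconstruction_error() < 1e-10
    total_subsets = sum(comb(6, k) for k in range(1, 7))
    assert len(dec.nbody_terms) == total_subsets
    # 2B dominates the interaction energy of a compact hexamer
    fracs = dec.order_fractions()
    assert abs(fracs[2]) == max(abs(v) for v in fracs.values())
    df = dec.to_frame()
    assert len(df) == total_subsets


def test_decompose_pairwise_null(pairwise_potential, compact_hexamer):
    dec = mbe.decompose(compact_hexamer, pairwise_potential, max_order=4)
    assert abs(dec.order_sums[3]) < 1e-10
    assert abs(dec.order_sums[4]) < 1e-10


def test_decompose_validates_and_guards(truth, trimers_small):
    with pytest.raises(ValueError):
        mbe.decompose(trimers_small[0], truth, max_order=5)


def test_order_sums_label_invariant(truth):
    cfgs = sample_trimer_set(1, (2.6, 4.5), seed=31)
    cfg = cfgs[0]
    dec = mbe.decompose(cfg, truth, 3)
    perm = cfg.subset([2, 0, 1])
    dec_p = mbe.decompose(perm, truth, 3)
    for n in (1, 2, 3):
        assert dec.order_sums[n] == pytest.approx(dec_p.order_sums[n],
                                                  abs=1e-10)


class TestSamba:
    def test_single_level_collapse(self, truth, trimers_small):
        cfg = trimers_small[1]
        level_map = {n: truth for n in (1, 2, 3)}
        total = mbe.samba_energy(cfg, level_map)
        assert total == pytest.approx(truth.energy(cfg), abs=1e-10)

    def test_3b_only_distortion_above_order3_is_free(self, truth,
                                                     surrogate):
        """Orders 1-3 at truth, >=4 at a surrogate whose distortion touches
        only the 3B term: on a 4-mer the >=4B orders differ only through
        induction (unchanged), so the stratified total is exact."""
        from mbwater.potentials import (DistortionSpec,
                                        make_surrogate_potential)
        from mbwater.synthetic import build_liquid_box

        sur3 = make_surrogate_potential(truth, DistortionSpec(eps_3b=0.3))
        box = build_liquid_box(4, 0.9, seed=17)
        cluster = box.copy()
        cluster.box_edge = None
        level_map = {1: truth, 2: truth, 3: truth, 4: sur3}
        total = mbe.samba_energy(cluster, level_map)
        assert total == pytest.approx(truth.energy(cluster), abs=1e-10)

    def test_assembly_oracle(self, truth, surrogate):
        from mbwater.synthetic import build_liquid_box

        box = build_liquid_box(5, 0.9, seed=19)
        cluster = box.copy()
        cluster.box_edge = None
        level_map = {1: surrogate, 2: surrogate, 3: surrogate,
                     4: truth, 5: truth}
        total = mbe.samba_energy(cluster, level_map)
        dec_s = mbe.decompose(cluster, surrogate, 5)
        dec_t = mbe.decompose(cluster, truth, 5)
        hand = (sum(dec_s.order_sums[n] for n in (1, 2, 3))
                + sum(dec_t.order_sums[n] for n in (4, 5)))
        assert total == pytest.approx(hand, abs=1e-10)

    def test_missing_level_rejected(self, truth, trimers_small):
        with pytest.raises(ValueError):
            mbe.samba_energy(trimers_small[0], {1: truth, 3: truth})
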