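import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sfcr import assemble, build_S, build_weights, convolve_mids, eval_source
from sfcr import synthetic as syn
from sfcr.model_io import (CompartmentScaled, Convolution, FixedVector,
                           LabelingDataset, MeasuredMID, MIDVector)

mid_fractions = st.lists(st.floats(0.01, 1.0), min_size=1, max_size=5).map(
    lambda xs: np.array(xs) / np.sum(xs))


@pytest.mark.parametrize("a, b, expected", [
    ([1, 0, 0], [0, 1, 0], [0, 1, 0, 0, 0]),
    ([0.5, 0.5], [0.5, 0.5], [0.25, 0.5, 0.25]),
])
def test_convolution_examples(a, b, expected):
    out = convolve_mids(MIDVector("a", a), MIDVector("b", b))
    np.testing.assert_allclose(out.fractions, expected)
    assert out.n_carbons == len(a) + len(b) - 2


@given(mid_fractions, mid_fractions)
def test_convolution_conserves_mass(a, b):
    out = np.convolve(a, b)
    assert out.size == a.size + b.size - 1
    assert out.sum() == pytest.approx(a.sum() * b.sum(), rel=1e-12)
    assert np.all(out >= 0)


def test_eval_source_kinds(minicbc_scenario, minicbc_euler):
    ds, c = minicbc_euler, {"c_G": 0.4}
    t = 2
    g = eval_source(MeasuredMID("G"), ds, t)
    np.testing.assert_allclose(g, ds.mean_mid("G", t))
    scaled = eval_source(CompartmentScaled("c_G", MeasuredMID("G")), ds, t, c)
    np.testing.assert_allclose(scaled, 0.4 * g)
    np.testing.assert_allclose(eval_source(FixedVector([0, 1]), ds, t), [0, 1])
    conv = eval_source(Convolution(MeasuredMID("T"), MeasuredMID("T")), ds, t)
    np.testing.assert_allclose(conv, np.convolve(ds.mean_mid("T", t),
                                                 ds.mean_mid("T", t)))
    with pytest.raises(KeyError, match="c_G"):
        eval_source(CompartmentScaled("c_G", MeasuredMID("G")), ds, t, {})


def test_build_S_chain_row(toy5_scenario, toy5_euler):
    """Row of metabolite B (produced by v1 from A, consumed by v2):
    entries (x_A[j], -x_B[j], 0, 0, 0) in reaction order v1,v2,v3,vin,vexc."""
    sc, ds = toy5_scenario, toy5_euler
    t = 1
    S = build_S(sc.spec, ds, t, sc.network)
    rows = sc.spec.rows()
    for j in (0, 1):
        r = rows.index(("B", j))
        expected = [ds.mean_mid("A", t)[j], -ds.mean_mid("B", t)[j], 0, 0, 0]
        np.testing.assert_allclose(S[r], expected)


def test_unlabeled_S_consistent_with_N(toy5_scenario):
    """On fully unlabeled data the M+0 rows of S reproduce the net
    stoichiometric production of each tracked pool."""
    sc = toy5_scenario
    ds = syn.euler_propagate(syn.toy5(true_fluxes={r: 0.0 for r in
                                                   sc.network.reaction_ids}))
    S = build_S(sc.spec, ds, 0, sc.network)
    rows = sc.spec.rows()
    for met in "ABCD":
        r = rows.index((met, 0))
        i = sc.network.metabolite_ids.index(met)
        expected = sc.network.N[i].astype(float)
        # the vin source is fully labeled, so its M+0 contribution is 0
        expected[sc.network.reaction_index("vin")] = 0.0
        np.testing.assert_allclose(S[r], expected)


def test_compartmented_row_is_plastid_plus_scaled_cytosol(minicbc_scenario,
                                                          minicbc_euler):
    sc, ds = minicbc_scenario, minicbc_euler
    S_c = build_S(sc.spec, ds, 1, sc.network, {"c_G": 0.6})
    S_0 = build_S(sc.spec, ds, 1, sc.network, {"c_G": 0.0})
    diff = S_c - S_0
    col = sc.network.reaction_index("vsuc")
    rows = sc.spec.rows()
    for j in range(3):
        r = rows.index(("G", j))
        assert diff[r, col] == pytest.approx(-0.6 * ds.mean_mid("G", 1)[j])
    # everything else untouched
    diff[:, col] = 0.0
    assert np.all(diff == 0)


def test_block_counts_and_dt(toy5_scenario, toy5_euler):
    sc = toy5_scenario
    w = build_weights(toy5_euler, sc.spec, sigma_override=0.01)
    sys5 = assemble(sc.spec, toy5_euler, w, sc.network)
    assert sys5.n_intervals == 4
    np.testing.assert_allclose(sys5.dt, [5, 5, 10, 20])
    masked = toy5_euler.mask_times([0, 5, 10, 20])
    w4 = build_weights(masked, sc.spec, sigma_override=0.01)
    sys4 = assemble(sc.spec, masked, w4, sc.network)
    assert sys4.n_intervals == 3
    np.testing.assert_allclose(sys4.dt, [5, 5, 10])


def test_S_depends_only_on_its_own_time_point(toy5_scenario, toy5_euler):
    sc, ds = toy5_scenario, toy5_euler
    S0 = build_S(sc.spec, ds, 0, sc.network)
    # corrupt all later-time data; S(t_0) must not move
    mids = ds.mids.copy()
    later = mids["time_s"] > 0
    mids.loc[later, "fraction"] = np.random.default_rng(0).uniform(
        size=int(later.sum()))
    corrupted = LabelingDataset(mids, ds.pools, ds.boundary_fluxes)
    np.testing.assert_array_equal(build_S(sc.spec, corrupted, 0, sc.network), S0)


@pytest.mark.parametrize("scale", [0.25, 0.5, 1.0])
def test_forward_euler_consistency(toy5_scenario, scale):
    """For data generated by the Euler recursion with fluxes s*v*, every
    assembled block satisfies Y = S v dt to float precision."""
    sc = syn.toy5(true_fluxes={r: scale * v for r, v in
                               toy5_scenario.true_fluxes.items()})
    ds = syn.euler_propagate(sc)
    w = build_weights(ds, sc.spec, sigma_override=0.01)
    system = assemble(sc.spec, ds, w, sc.network)
    v = sc.v_star()
    for S, Y, dt in zip(system.S_blocks, system.Y_blocks, system.dt):
        np.testing.assert_allclose(S @ v * dt, Y, atol=1e-10)


def test_assemble_requires_two_time_points(toy5_scenario, toy5_euler):
    sc = toy5_scenario
    single = toy5_euler.mask_times([0.0])
    w = build_weights(toy5_euler, sc.spec, sigma_override=0.01)
    with pytest.raises(ValueError, match="two unmasked time points"):
        assemble(sc.spec, single, w, sc.network)
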