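import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sfcr import build_weights, mid_sigma
from sfcr import synthetic as syn
from sfcr.error_model import SigmaError
from sfcr.model_io import LabelingDataset


def _dataset_with_sds(sd_by_time):
    """Two-replicate toy dataset for one 2-carbon metabolite where the
    across-replicate SD of M+1 at time t is sd_by_time[t] (M+2 scatter-free)."""
    recs = []
    for ti, (t, sd) in enumerate(sorted(sd_by_time.items())):
        d = sd / np.sqrt(2)  # two replicates at +/- d have sample SD sd*sqrt(2)*d... ddof=1 SD of (x-d, x+d) = d*sqrt(2)
        for rep, sgn in ((0, -1), (1, 1)):
            m1 = 0.2 + sgn * sd / np.sqrt(2)
            recs += [("X", 0, t, rep, 0.7 - m1 + 0.2), ("X", 1, t, rep, m1),
                     ("X", 2, t, rep, 0.1)]
    mids = pd.DataFrame(recs, columns=["metabolite", "isotopologue", "time_s",
                                       "replicate", "fraction"])
    pools = pd.DataFrame({"metabolite": ["X"], "mean": [10.0], "sd": [0.5]})
    flux = pd.DataFrame({"reaction": ["vexc"], "mean": [1.0], "sd": [0.1]})
    return LabelingDataset(mids, pools, flux)


def _spec_for_x():
    from sfcr.model_io import BalanceTerm, MeasuredMID, MetaboliteBalance, MIDBalanceSpec
    return MIDBalanceSpec([MetaboliteBalance("X", 2, [
        BalanceTerm("vexc", -1.0, MeasuredMID("X"))])])


def test_sigma_is_max_over_time():
    ds = _dataset_with_sds({0.0: 0.01, 5.0: 0.03, 10.0: 0.02, 20.0: 0.0})
    sigma = mid_sigma(ds, _spec_for_x())
    assert sigma[("X", 1)] == pytest.approx(0.03, rel=1e-9)


def test_zero_sd_falls_back_to_lighter_isotopologue():
    ds = _dataset_with_sds({0.0: 0.015, 5.0: 0.01})
    sigma = mid_sigma(ds, _spec_for_x())
    # M+2 is scatter-free by construction -> inherits sigma of M+1
    assert sigma[("X", 2)] == sigma[("X", 1)] == pytest.approx(0.015, rel=1e-9)


def test_all_zero_sd_is_an_error(toy5_scenario, toy5_euler):
    with pytest.raises(SigmaError, match="sigma_floor"):
        mid_sigma(toy5_euler, toy5_scenario.spec)  # single replicate, no scatter
    sigma = mid_sigma(toy5_euler, toy5_scenario.spec, sigma_floor=0.02)
    assert all(s == 0.02 for s in sigma.values())


def test_fixed_pool_variance_rule():
    # mu_P = 10, sigma = 0.02 -> Var(Y) = 2 (10 * 0.02)^2 = 0.08
    ds = _dataset_with_sds({0.0: 0.02, 5.0: 0.02})
    w = build_weights(ds, _spec_for_x())
    np.testing.assert_allclose(1.0 / w.w_mid, 0.08, rtol=1e-12)


def test_variable_pool_variance_reduces_at_zero_pool_sd():
    ds = _dataset_with_sds({0.0: 0.02, 5.0: 0.02})
    ds.pools.loc[:, "sd"] = 0.0
    w_fix = build_weights(ds, _spec_for_x(), mode="fixed_pools")
    with pytest.raises(SigmaError):
        build_weights(ds, _spec_for_x(), mode="variable_pools")
    # with sigma_P -> 0 the Y-variance formula reduces to 2 sigma_x^2 mu_P^2,
    # identical to the fixed-pool rule; check via a tiny but positive SD
    ds.pools.loc[:, "sd"] = 1e-9
    w_var = build_weights(ds, _spec_for_x(), mode="variable_pools")
    np.testing.assert_allclose(w_var.w_mid, w_fix.w_mid, rtol=1e-6)


def test_doubling_property():
    """Var(Y) is exactly twice the single-measurement concentration variance."""
    ds = _dataset_with_sds({0.0: 0.02, 5.0: 0.02})
    w = build_weights(ds, _spec_for_x())
    mu_p, _ = ds.pool("X")
    single = (mu_p * w.sigma_mid) ** 2
    np.testing.assert_allclose(1.0 / w.w_mid, 2.0 * single, rtol=1e-12)


def test_boundary_flux_weight_is_inverse_variance():
    ds = _dataset_with_sds({0.0: 0.02, 5.0: 0.02})
    w = build_weights(ds, _spec_for_x())
    np.testing.assert_allclose(w.w_flux, [1.0 / 0.1 ** 2])


def test_zero_boundary_sd_is_an_error():
    ds = _dataset_with_sds({0.0: 0.02, 5.0: 0.02})
    ds.boundary_fluxes.loc[:, "sd"] = 0.0
    with pytest.raises(SigmaError, match="boundary"):
        build_weights(ds, _spec_for_x())


@given(st.randoms(use_true_random=False))
def test_weights_invariant_to_replicate_relabeling(rnd):
    """Permuting replicate labels and time ordering of the SD inputs leaves
    the weight model unchanged."""
    base = syn.add_noise(syn.euler_propagate(syn.toy5()), 0.01, 3, seed=5)
    spec = syn.toy5().spec
    w0 = build_weights(base, spec)
    mids = base.mids.copy()
    reps = list(mids["replicate"].unique())
    perm = reps.copy()
    rnd.shuffle(perm)
    mids["replicate"] = mids["replicate"].map(dict(zip(reps, perm)))
    mids = mids.sample(frac=1.0, random_state=rnd.randrange(2**16))
    shuffled = LabelingDataset(mids, base.pools, base.boundary_fluxes)
    w1 = build_weights(shuffled, spec)
    np.testing.assert_allclose(w1.w_mid, w0.w_mid, rtol=1e-12)
    np.testing.assert_allclose(w1.sigma_mid, w0.sigma_mid, rtol=1e-12)
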