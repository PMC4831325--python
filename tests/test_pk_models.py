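"""Forward-model unit tests: scalar conversions, AIF, compartment curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from mrgfr import pk_models as pk


# ---------------------------------------------------------------------------
# scalar conversions
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "rbc, mcv, expected", [(5.0, 82.0, 41.0), (4.0, 75.0, 30.0), (6.1, 80.0, 48.8)]
)
def test_hct_from_cbc(rbc, mcv, expected):
    assert pk.hct_from_cbc(rbc, mcv) == pytest.approx(expected)


@pytest.mark.parametrize("rbc, mcv", [(0.0, 82.0), (-1.0, 82.0), (5.0, 0.0)])
def test_hct_from_cbc_rejects_nonpositive(rbc, mcv):
    with pytest.raises(pk.DomainError):
        pk.hct_from_cbc(rbc, mcv)


def _curve(values, dt=1.7, n_precontrast=1):
    values = np.asarray(values, dtype=float)
    return pk.TimeSeriesCurve(times=dt * np.arange(values.size), values=values,
                              n_precontrast=n_precontrast)


def test_plasma_correct_scales_by_one_minus_hct():
    c = _curve([1.0, 0.59])
    assert pk.plasma_correct(c, 0.0).values == pytest.approx([1.0, 0.59])
    assert pk.plasma_correct(c, 0.41).values[1] == pytest.approx(1.0)
    # two hematocrits differ by the ratio of their plasma fractions
    low = pk.plasma_correct(c, 0.30).values
    high = pk.plasma_correct(c, 0.41).values
    assert high * (0.59 / 0.70) == pytest.approx(low, rel=1e-12)


@pytest.mark.parametrize("hct", [1.0, 1.5, -0.1])
def test_plasma_correct_rejects_bad_hct(hct):
    with pytest.raises(pk.DomainError):
        pk.plasma_correct(_curve([1.0, 2.0]), hct)


@pytest.mark.parametrize(
    "gfr_v, volume, expected", [(0.0, 241.0, 0.0), (0.40, 241.0, 96.4), (0.30, 200.0, 60.0)]
)
def test_gfr_from_gfrv(gfr_v, volume, expected):
    assert pk.gfr_from_gfrv(gfr_v, volume) == pytest.approx(expected)


def test_gfr_from_gfrv_rejects_negative():
    with pytest.raises(pk.DomainError):
        pk.gfr_from_gfrv(-0.1, 200.0)


def test_rpf_v_is_perfusion_per_volume():
    params = pk.KidneyModelParams(v_p=0.2, gfr_v=0.4, delay=1.0, t_disp=4.0)
    assert pk.rpf_v(params) == pytest.approx(60.0 * 0.2 / 4.0)


# ---------------------------------------------------------------------------
# domain-type invariants
# ---------------------------------------------------------------------------

def test_curve_rejects_nonuniform_times():
    with pytest.raises(pk.DomainError):
        pk.TimeSeriesCurve(times=np.array([0.0, 1.0, 2.5]), values=np.zeros(3))


def test_curve_rejects_nonfinite_values():
    with pytest.raises(pk.DomainError):
        _curve([0.0, np.nan, 1.0])


@pytest.mark.parametrize("n_pre", [0, 3])
def test_curve_rejects_bad_precontrast_count(n_pre):
    with pytest.raises(pk.DomainError):
        _curve([0.0, 1.0, 2.0], n_precontrast=n_pre)


def test_aif_model_rejects_recirculation_before_first_pass():
    with pytest.raises(pk.DomainError):
        pk.AifModel(a1=1, b1=2, c1=3, t1=10.0, a2=1, b2=1, c2=5, t2=5.0)


def test_kidney_params_reject_out_of_range():
    with pytest.raises(pk.DomainError):
        pk.KidneyModelParams(v_p=1.2, gfr_v=0.4, delay=0.0, t_disp=4.0)
    with pytest.raises(pk.DomainError):
        pk.KidneyModelParams(v_p=0.2, gfr_v=0.4, delay=0.0, t_disp=0.0)


# ---------------------------------------------------------------------------
# arterial input function
# ---------------------------------------------------------------------------

def test_aif_zero_before_onset(times, typical_aif):
    curve = pk.eval_aif(typical_aif, times)
    assert np.all(curve.values[times < typical_aif.t1] == 0.0)


def test_single_lobe_peak_matches_calculus(times):
    # with b = 1 the lobe a*x*exp(-x/c) peaks at x = c with value a*c/e
    model = pk.AifModel(a1=2.0, b1=1.0, c1=20.0, t1=0.0, a2=0.0, b2=1.0, c2=1.0, t2=0.0)
    fine = np.linspace(0, 200, 100001)
    vals = pk.eval_aif(model, fine).values
    assert fine[np.argmax(vals)] == pytest.approx(20.0, abs=0.01)
    assert vals.max() == pytest.approx(2.0 * 20.0 * np.exp(-1.0), rel=1e-6)


def test_boxcar_lobe_uses_zero_power_convention():
    model = pk.AifModel(a1=3.0, b1=0.0, c1=10.0, t1=1.7, a2=0.0, b2=1.0, c2=1.0, t2=1.7)
    vals = pk.eval_aif(model, np.array([0.0, 1.7, 3.4])).values
    assert vals[0] == 0.0
    assert vals[1] == pytest.approx(3.0)  # 0^0 := 1 at onset
    assert vals[2] == pytest.approx(3.0 * np.exp(-1.7 / 10.0))


def test_two_lobe_aif_is_superposition(times, typical_aif):
    full = pk.eval_aif(typical_aif, times).values
    lobe1 = pk.eval_aif(
        pk.AifModel(typical_aif.a1, typical_aif.b1, typical_aif.c1, typical_aif.t1,
                    0.0, 1.0, 1.0, typical_aif.t1), times).values
    lobe2 = pk.eval_aif(
        pk.AifModel(0.0, 1.0, 1.0, typical_aif.t1, typical_aif.a2, typical_aif.b2,
                    typical_aif.c2, typical_aif.t2), times).values
    np.testing.assert_allclose(full, lobe1 + lobe2, atol=1e-12)


# ---------------------------------------------------------------------------
# plasma compartment response
# ---------------------------------------------------------------------------

def test_plasma_response_zero_input_is_zero(times):
    silent = pk.AifModel(a1=0.0, b1=1.0, c1=1.0, t1=0.0, a2=0.0, b2=1.0, c2=1.0, t2=0.0)
    p = pk.plasma_compartment_response(silent, delay=0.0, t_disp=4.0, times=times)
    assert np.all(p.values == 0.0)


def test_plasma_response_step_input_matches_closed_form(times):
    # a boxcar lobe with a very long decay is a unit step at t = 0
    step = pk.AifModel(a1=1.0, b1=0.0, c1=1e12, t1=0.0, a2=0.0, b2=1.0, c2=1.0, t2=0.0)
    tau = 6.0
    p = pk.plasma_compartment_response(step, delay=0.0, t_disp=tau, times=times)
    expected = 1.0 - np.exp(-times / tau)
    assert np.max(np.abs(p.values - expected)) < 1e-6


def _ode_reference(aif, delay, t_disp, times):
    shifted = pk.AifModel(aif.a1, aif.b1, aif.c1, aif.t1 + delay,
                          aif.a2, aif.b2, aif.c2, aif.t2 + delay)

    def rhs(t, y):
        ta = np.array([t])
        u = (pk._gamma_lobe(ta, shifted.a1, shifted.b1, shifted.c1, shifted.t1)
             + pk._gamma_lobe(ta, shifted.a2, shifted.b2, shifted.c2, shifted.t2))[0]
        return (u - y[0]) / t_disp

    sol = solve_ivp(rhs, (times[0], times[-1]), [0.0], t_eval=times,
                    rtol=1e-11, atol=1e-13, max_step=0.5)
    return sol.y[0]


def test_plasma_response_agrees_with_ode_oracle(times, typical_aif):
    p = pk.plasma_compartment_response(typical_aif, delay=2.0, t_disp=4.0,
                                       times=times, refine=300).values
    q = _ode_reference(typical_aif, 2.0, 4.0, times)
    assert np.max(np.abs(p - q)) / np.max(np.abs(q)) < 1e-6


def test_plasma_response_rejects_nonpositive_dispersion(times, typical_aif):
    with pytest.raises(pk.DomainError):
        pk.plasma_compartment_response(typical_aif, delay=0.0, t_disp=0.0, times=times)


# ---------------------------------------------------------------------------
# kidney forward models
# ---------------------------------------------------------------------------

def test_uptake_without_filtration_is_vascular_only(times, typical_aif):
    params = pk.KidneyModelParams(v_p=0.23, gfr_v=0.0, delay=1.5, t_disp=5.0)
    ck = pk.forward_uptake(params, typical_aif, times).values
    p = pk.plasma_compartment_response(typical_aif, 1.5, 5.0, times).values
    np.testing.assert_allclose(ck, 0.23 * p, rtol=0, atol=1e-14)


def test_uptake_step_input_matches_closed_form(times):
    # step plasma input: P = 1-exp(-t/tau), integral = t - tau*(1-exp(-t/tau))
    step = pk.AifModel(a1=1.0, b1=0.0, c1=1e12, t1=0.0, a2=0.0, b2=1.0, c2=1.0, t2=0.0)
    tau, v_p, gfr_v = 5.0, 0.1, 0.6
    params = pk.KidneyModelParams(v_p=v_p, gfr_v=gfr_v, delay=0.0, t_disp=tau)
    ck = pk.forward_uptake(params, step, times, refine=100).values
    p = 1.0 - np.exp(-times / tau)
    expected = v_p * p + (gfr_v / 60.0) * (times - tau * p)
    assert np.max(np.abs(ck - expected)) < 1e-6


@settings(max_examples=20, deadline=None, derandomize=True)
@given(scale=st.floats(0.1, 10.0), seed=st.integers(0, 2**16))
def test_forward_curves_linear_in_aif_amplitude(scale, seed):
    """Scaling both lobe amplitudes scales every forward curve linearly."""
    rng = np.random.default_rng(seed)
    times = 1.7 * np.arange(60)
    aif = pk.AifModel(a1=rng.uniform(0.005, 0.05), b1=rng.uniform(1, 4),
                      c1=rng.uniform(1, 5), t1=rng.uniform(0, 20),
                      a2=rng.uniform(1e-6, 1e-3), b2=rng.uniform(1, 6),
                      c2=rng.uniform(5, 20), t2=rng.uniform(25, 50))
    params = pk.KidneyModelParams(v_p=rng.uniform(0.05, 0.4), gfr_v=rng.uniform(0.1, 0.8),
                                  delay=rng.uniform(0, 5), t_disp=rng.uniform(1, 10),
                                  t_tub=rng.uniform(50, 5000))
    for forward in (pk.forward_uptake, pk.forward_inflow_outflow):
        base = forward(params, aif, times).values
        scaled = forward(params, aif.scaled(scale), times).values
        np.testing.assert_allclose(scaled, scale * base, rtol=1e-10, atol=1e-14)


def test_inflow_outflow_limits_to_uptake_model(times, typical_aif):
    base = dict(v_p=0.2, gfr_v=0.4, delay=2.0, t_disp=4.0)
    uptake = pk.forward_uptake(pk.KidneyModelParams(**base), typical_aif, times).values
    io = pk.forward_inflow_outflow(
        pk.KidneyModelParams(**base, t_tub=1e9), typical_aif, times).values
    assert np.max(np.abs(io - uptake)) / np.max(np.abs(uptake)) < 1e-5


def test_inflow_outflow_without_filtration_is_vascular_only(times, typical_aif):
    params = pk.KidneyModelParams(v_p=0.2, gfr_v=0.0, delay=2.0, t_disp=4.0, t_tub=100.0)
    io = pk.forward_inflow_outflow(params, typical_aif, times).values
    vasc = pk.forward_uptake(
        pk.KidneyModelParams(v_p=0.2, gfr_v=0.0, delay=2.0, t_disp=4.0), typical_aif, times
    ).values
    np.testing.assert_allclose(io, vasc, atol=1e-14)


def test_outflow_only_removes_tracer(times, typical_aif):
    base = dict(v_p=0.2, gfr_v=0.4, delay=2.0, t_disp=4.0)
    uptake = pk.forward_uptake(pk.KidneyModelParams(**base), typical_aif, times).values
    io = pk.forward_inflow_outflow(
        pk.KidneyModelParams(**base, t_tub=120.0), typical_aif, times).values
    assert np.all(io <= uptake + 1e-12)


def test_inflow_outflow_requires_t_tub(times, typical_aif):
    params = pk.KidneyModelParams(v_p=0.2, gfr_v=0.4, delay=2.0, t_disp=4.0)
    with pytest.raises(pk.DomainError):
        pk.forward_inflow_outflow(params, typical_aif, times)
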