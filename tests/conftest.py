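"""Shared fixtures: analytic index oracles and a trained benchmark model.

The index oracle integrates the flow-vs-volume ODE numerically with a
high-order adaptive stepper (independent of the package's closed-form
curve synthesis) and extracts every spirometric index from the continuous
solution, so the metric engine is checked end to end against an
independent route.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from spirokit.simulate import CurveParams, flow_at_volume


def analytic_indices(params: CurveParams) -> dict:
    """Reference values of all indices from an adaptive ODE solution.

    Integrates dv/dt = Q(v) from the same bootstrap volume the generator
    uses, truncates where flow falls to the end-of-test threshold, and
    reads off FVC, FEV1 (1 s after the 5%-of-PEF time zero), PEF,
    t25/t75, FEF25-75, and FEF75 from the continuous solution.
    """
    v0 = 1e-3 * params.fvc_true

    def rhs(t, v):
        return [flow_at_volume(params, min(v[0], params.fvc_true))]

    def end_event(t, v):
        vv = min(v[0], params.fvc_true)
        if vv < params.v_peak:
            return 1.0
        return flow_at_volume(params, vv) - params.end_flow_threshold

    end_event.terminal = True
    end_event.direction = -1

    sol = solve_ivp(
        rhs, (0.0, 1e4), [v0], events=end_event, dense_output=True,
        rtol=1e-10, atol=1e-12, max_step=1.0,
    )
    assert sol.t_events[0].size, "maneuver never reached the end-of-test flow"
    t_end = float(sol.t_events[0][0])
    v_of_t = lambda t: float(sol.sol(t)[0])  # noqa: E731
    q_of_t = lambda t: flow_at_volume(  # noqa: E731
        params, min(v_of_t(t), params.fvc_true)
    )

    fvc = v_of_t(t_end)
    pef = params.pef_true
    # time zero: flow first reaches 5% of PEF, bracketed on the rising limb
    # (volume is monotone, so the peak time comes from v(t) = v_peak)
    t_pk = brentq(lambda t: v_of_t(t) - params.v_peak, 0.0, t_end)
    t0 = brentq(lambda t: q_of_t(t) - 0.05 * pef, 0.0, t_pk)
    t25 = brentq(lambda t: v_of_t(t) - 0.25 * fvc, 0.0, t_end)
    t75 = brentq(lambda t: v_of_t(t) - 0.75 * fvc, 0.0, t_end)
    fev1 = v_of_t(t0 + 1.0) if t0 + 1.0 <= t_end else None
    return {
        "FVC": fvc,
        "FEV1": fev1,
        "FEV1_FVC": None if fev1 is None else fev1 / fvc,
        "PEF": pef,
        "FEF25_75": 0.5 * fvc / (t75 - t25),
        "FEF75": flow_at_volume(params, 0.75 * fvc),
        "t25": t25,
        "t75": t75,
    }


def random_curve_params(rng: np.random.Generator, dt: float = 0.001) -> CurveParams:
    """Physiological random draw used by the metric-engine oracle checks."""
    fvc = rng.uniform(2.5, 6.0)
    pef = fvc * rng.uniform(1.6, 2.4)
    return CurveParams(
        fvc_true=fvc,
        pef_true=pef,
        v_peak_frac=rng.uniform(0.07, 0.18),
        shape_k=rng.uniform(0.8, 3.0),
        noise_sd=0.0,
        dt=dt,
    )


@pytest.fixture(scope="session")
def benchmark_records():
    from spirokit.simulate import separable_benchmark

    return separable_benchmark(400, seed=202, dt=0.02)


@pytest.fixture(scope="session")
def trained_benchmark(benchmark_records):
    """Encoder trained on the separable morphology benchmark (300 train /
    100 held out); shared across classifier and saliency tests."""
    from spirokit.encoder import EncoderConfig, train_encoder

    records = benchmark_records
    train, heldout = records[:300], records[300:]
    cfg = EncoderConfig(
        conv_channels=(16, 32, 32), kernel_sizes=(7, 5, 3), lstm_hidden=32,
        seed=0, max_epochs=15, patience=4,
    )
    model, history = train_encoder(train[:260], train[260:], cfg)
    return model, history, heldout


@pytest.fixture(scope="session")
def cohort_for_masking():
    """Small labelled cohort with reference-adjusted PFT results attached."""
    from spirokit.reference import full_pft, synthetic_reference_table
    from spirokit.simulate import EffectConfig, generate_cohort

    records = generate_cohort(
        40, 0.5, effect_config=EffectConfig(noise_sd=0.02), seed=99
    )
    coeffs = synthetic_reference_table()
    for r in records:
        r.pft = full_pft(r.curves[0], r.demographics, coeffs)
    return records


@pytest.fixture()
def constant_table():
    """LMS table with M = 4, S = 0.1, L = 1 for every index and sex."""
    from spirokit.reference import LMSCoefficients

    c = LMSCoefficients()
    for sex in ("male", "female"):
        for index in ("FVC", "FEV1", "FEV1_FVC", "PEF", "FEF25_75", "FEF75"):
            c.add(sex, index, a0=math.log(4.0), a1=0.0, a2=0.0,
                  b0=math.log(0.1), b1=0.0, L=1.0)
    return c
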