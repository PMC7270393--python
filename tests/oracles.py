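"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's analytic-convolution code path: the
compartment system is integrated as a stiff ODE driven by the linearly
interpolated plasma input.
"""

import numpy as np


def ode_tissue(params, input_fn, t_eval_min):
    """Stiff ODE integration of the 1TC/2TC tissue concentration."""
    from scipy.integrate import solve_ivp

    # the model's input is the time-shifted plasma curve resampled on the
    # 1-s grid (piecewise linear between grid points); the oracle must
    # integrate the same driving function
    cp_shifted = input_fn.plasma_at(input_fn.t_s, params.delta_s)

    def cp(t_min):
        return np.interp(t_min * 60.0, input_fn.t_s, cp_shifted,
                         left=0.0, right=cp_shifted[-1])

    if params.is_two_tissue:
        def rhs(t, y):
            c1, c2 = y
            return [
                params.k1 * cp(t) - (params.k2 + params.k3) * c1 + params.k4 * c2,
                params.k3 * c1 - params.k4 * c2,
            ]
        y0 = [0.0, 0.0]
    else:
        def rhs(t, y):
            return [params.k1 * cp(t) - params.k2 * y[0]]
        y0 = [0.0]
    # max_step = one input-grid interval: the driving term is piecewise
    # linear with kinks every second, so larger steps lose accuracy there
    sol = solve_ivp(rhs, (0.0, t_eval_min[-1]), y0, t_eval=t_eval_min,
                    method="LSODA", rtol=1e-11, atol=1e-13, max_step=1.0 / 60.0)
    return sol.y.sum(axis=0)


def analytic_tissue(params, input_fn, t_eval_min):
    """The package's analytic tissue curve sampled at the same times."""
    from lungkin.kinetics import _two_tissue_impulse, exp_conv

    cp = input_fn.plasma_at(input_fn.t_s, params.delta_s)
    if params.is_two_tissue:
        A1, a1, A2, a2 = _two_tissue_impulse(params)
        fine = A1 * exp_conv(cp, 1 / 60, a1) + A2 * exp_conv(cp, 1 / 60, a2)
    else:
        fine = params.k1 * exp_conv(cp, 1 / 60, params.k2)
    return np.interp(np.asarray(t_eval_min) * 60.0, input_fn.t_s, fine)
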