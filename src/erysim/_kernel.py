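"""JIT-compiled inner loop of the upwind transport scheme.

One first-order upwind step per class per time step,

    u[j] <- u[j] - (v dt/dmu) (u[j] - u[j-1]) + dt (beta - alpha_j) u[j],

with the boundary node set from the upstream outflux (``v u(t,0) = f``) after
each step.  The in-place sweep runs from the right so that ``u[j-1]`` is the
pre-step value.  EPO-dependent coefficients (CFU-E apoptosis, reticulocyte
velocity, neocytolysis) are evaluated from the per-step EPO array.  The
trapezoidal erythrocyte count after every step is written to ``rbc_out``.
"""
import numpy as np
from numba import njit


@njit(cache=True)
def run_segment(
    u0, u1, u2, u3, u4,       # densities of the five classes (modified in place)
    epo,                      # total EPO at the start of each step, length n_steps
    dt,
    d0, d1, d2, d3, d4,       # node spacing per class
    b0, b1, b2, b3,           # proliferation rates (erythrocytes: 0)
    a0, a2, a3,               # constant apoptosis rates (BFU-E, erythroblast, retic)
    a_min, a_max, s_alpha,    # CFU-E apoptosis function
    v_min, v_max, s_v,        # marrow-reticulocyte velocity function
    e_neo, mu_neo, a_neo,     # neocytolysis
    s0,                       # stem-cell influx, cells/day
    rbc_out,                  # erythrocyte count after each step, length n_steps
):
    n_steps = epo.shape[0]
    for m in range(n_steps):
        e = epo[m]
        a1 = a_min + (a_max - a_min) * np.exp(-s_alpha * e)
        v3 = v_min + s_v * e
        if v3 > v_max:
            v3 = v_max
        neo = 0.0
        if e < e_neo:
            neo = a_neo * (e_neo - e) / e_neo

        # boundary fluxes from the pre-step state
        f1 = u0[u0.shape[0] - 1]
        f2 = u1[u1.shape[0] - 1]
        f3 = u2[u2.shape[0] - 1]
        f4 = v3 * u3[u3.shape[0] - 1]

        c = dt / d0
        r = b0 - a0
        for j in range(u0.shape[0] - 1, 0, -1):
            u0[j] += -c * (u0[j] - u0[j - 1]) + dt * r * u0[j]
        u0[0] = s0

        c = dt / d1
        r = b1 - a1
        for j in range(u1.shape[0] - 1, 0, -1):
            u1[j] += -c * (u1[j] - u1[j - 1]) + dt * r * u1[j]
        u1[0] = f1

        c = dt / d2
        r = b2 - a2
        for j in range(u2.shape[0] - 1, 0, -1):
            u2[j] += -c * (u2[j] - u2[j - 1]) + dt * r * u2[j]
        u2[0] = f2

        c = dt * v3 / d3
        r = b3 - a3
        for j in range(u3.shape[0] - 1, 0, -1):
            u3[j] += -c * (u3[j] - u3[j - 1]) + dt * r * u3[j]
        u3[0] = f3 / v3

        c = dt / d4
        for j in range(u4.shape[0] - 1, 0, -1):
            a = neo if j * d4 <= mu_neo else 0.0
            u4[j] += -c * (u4[j] - u4[j - 1]) - dt * a * u4[j]
        u4[0] = f4

        total = 0.0
        for j in range(u4.shape[0]):
            total += u4[j]
        total -= 0.5 * (u4[0] + u4[u4.shape[0] - 1])
        rbc_out[m] = total * d4
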