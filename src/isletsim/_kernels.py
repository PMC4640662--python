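"""Compiled inner loop for the secretory-unit population.

One call advances the whole population by one time step: the firing test
is evaluated on start-of-step state, fired units dump their packet and
jump to the refractory threshold, and the continuous dynamics are then
advanced with an exponential integrator (exact for the threshold decay,
whose input G_n is constant, and exact for packet/potentiation relaxation
under inputs frozen over the step).  The exponential update is
unconditionally stable, which matters because recovery rates are sampled
log-normally and the fastest units would violate the explicit-Euler
stability bound at the nominal step sizes.

The per-unit decay factors exp(-rate*dt) are precomputed by the caller so
a simulation with fixed dt pays for them once.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap(args[0]) if args and callable(args[0]) else wrap


@njit(cache=True, fastmath=True)
def step_units_kernel(
    threshold,          # B_n, mM (updated in place)
    packet,             # J_n, pmol/kgBW (updated in place)
    potentiation,       # D_n, pmol/kgBW (updated in place)
    resting_threshold,  # G_n, mM
    refractory_threshold,  # R_n, mM
    decay_threshold,    # exp(-alpha_n * dt)
    decay_packet,       # exp(-zeta_n * dt)
    decay_potentiation,  # exp(-k_n * dt)
    steepness,          # gamma_n
    ln_half_glycemia,   # ln(Gamma_n)
    loading_over_decay,  # rho_n / k_n, pmol/kgBW
    basal_packet,       # Dbar_n, pmol/kgBW
    g_now,              # sensed glycemia, mM
    g_delayed,          # glycemia tau minutes ago, mM
):
    """Advance every unit one step; return (released mass, firing count)."""
    released = 0.0
    fired = 0
    n_units = threshold.shape[0]
    hill_on = g_delayed > 0.0
    ln_gd = math.log(g_delayed) if hill_on else 0.0
    for n in range(n_units):
        if g_now >= threshold[n]:
            released += packet[n]
            fired += 1
            threshold[n] = refractory_threshold[n]
            packet[n] = 0.0
        # threshold relaxation toward the resting value (exact)
        threshold[n] = resting_threshold[n] + (
            threshold[n] - resting_threshold[n]
        ) * decay_threshold[n]
        # potentiation drive: Hill function of delayed glycemia
        if hill_on:
            x = steepness[n] * (ln_half_glycemia[n] - ln_gd)
            if x > 50.0:
                drive = 0.0
            elif x < -50.0:
                drive = 1.0
            else:
                drive = 1.0 / (1.0 + math.exp(x))
        else:
            drive = 0.0
        target = basal_packet[n] + loading_over_decay[n] * drive
        potentiation[n] = target + (potentiation[n] - target) * decay_potentiation[n]
        packet[n] = potentiation[n] + (packet[n] - potentiation[n]) * decay_packet[n]
    return released, fired
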