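"""Compiled forward-simulation kernel.

The wastage estimator evaluates the seasonal lichen model tens of
thousands of times inside the cross-validated optimization, so the
inner loop is JIT-compiled with numba.  The kernel simulates a batch of
districts at once and writes the full annual biomass trajectory.

Season order everywhere: 0 = winter, 1 = spring, 2 = summer, 3 = autumn.
Growth-form codes: 0 = logistic, 1 = Gompertz, 2 = saturating
(power-logistic, ``r0 * z**a * (1 - z/K)``).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def growth_increment(z, g_eff, K, r0, gexp, gform):
    """Annual lichen growth (kg/ha) at post-consumption biomass ``z``."""
    if z <= 0.0 or z >= K:
        return 0.0
    if gform == 0:
        raw = r0 * z * (1.0 - z / K)
    elif gform == 1:
        raw = r0 * z * np.log(K / z)
    else:
        raw = r0 * z ** gexp * (1.0 - z / K)
    inc = g_eff * raw
    if inc < 0.0:
        inc = 0.0
    if z + inc > K:
        inc = K - z
    return inc


@njit(cache=True)
def simulate_batch(
    z0,            # (n_d,) initial biomass kg/ha
    area,          # (n_d,) lichen pasture area ha
    arb_pool,      # (n_d,) arboreal lichen available per winter, kg
    feed_kg,       # (n_d,) supplementary feed kg per head per winter
    g_eff,         # (n_d,) growth_rel * heavy-metal multiplier
    infra_w,       # (n_d,) infrastructure-induced wastage
    rotation,      # (n_d,) 1 if seasonal pasture rotation in use
    rd,            # (n_d, n_y, 4) reindeer-days per season
    p1, p2,        # (4,) seasonal wastage at biomass 0 and 1000 kg/ha
    demand,        # (4,) per-capita daily ground-lichen demand kg DM
    z_half,        # half-saturation biomass of the intake response
    feed_sub,      # kg lichen spared per kg feed
    arb_cap,       # max fraction of winter demand met from arboreal lichen
    K, r0, gexp, gform,
    days,          # (4,) season lengths, d
    exp_rot,       # (4,) exposure fraction of the winter range under rotation
    infra_season,  # (4,) 1 if infra wastage applies in that season
    traj,          # out: (n_d, n_y + 1)
):
    n_d = z0.shape[0]
    n_y = rd.shape[1]
    for d in range(n_d):
        z = z0[d]
        traj[d, 0] = z
        rot = rotation[d]
        for y in range(n_y):
            for e in range(4):
                expo = exp_rot[e] if rot == 1 else 1.0
                r_days = rd[d, y, e]
                if expo <= 0.0 or r_days <= 0.0 or z <= 0.0:
                    continue
                dem = demand[e]
                if e == 0:
                    spared = feed_sub * feed_kg[d] / days[0]
                    dem = dem - spared
                    if dem < 0.0:
                        dem = 0.0
                    arb_daily = arb_pool[d] / r_days
                    cap = arb_cap * dem
                    if arb_daily > cap:
                        arb_daily = cap
                    dem = dem - arb_daily
                intake_daily = dem * z / (z + z_half)
                w = p1[e] + (p2[e] - p1[e]) * z / 1000.0
                if infra_season[e] == 1:
                    w = w + infra_w[d]
                removal = intake_daily * r_days * expo * (1.0 + w) / area[d]
                z = z - removal
                if z < 0.0:
                    z = 0.0
            z = z + growth_increment(z, g_eff[d], K, r0, gexp, gform)
            traj[d, y + 1] = z
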