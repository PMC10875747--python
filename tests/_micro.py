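"""Individual-level Monte-Carlo micro-simulator: independent oracle for the
cohort-matrix Markov engine.

Mirrors the engine's event order (tunnel advance, screening, clinical
detection, other-cause death, incidence + undetected progression/death,
aftercare death) with Bernoulli/categorical draws per simulated person.
Kept deliberately separate from the package implementation: it shares the
parameter objects but none of the matrix code paths.
"""

import numpy as np

from lungscreen.markov import ModelParams, STAGES

HEALTHY, LC_DEATH, OTHER_DEATH = 0, 13, 14
U0, DNEW0, DPOST0 = 1, 5, 9


def microsim_stratum(n: int, params: ModelParams, p_inc_path, p_other_path,
                     offered, horizon: int, rng: np.random.Generator):
    """Simulate ``n`` individuals of one stratum; returns per-person outcomes.

    ``p_inc_path``/``p_other_path`` are per-cycle probabilities (index 0
    unused); ``offered`` is a boolean per-cycle screening-offer vector.
    Radiation feedback is ignored (run with excess_rr_per_screen = 0).
    """
    state = np.full(n, HEALTHY, dtype=np.int64)
    alive_prev = np.ones(n)
    ly = np.zeros(n)
    screens = np.zeros(n)
    fps = np.zeros(n)
    prog = params._prog_matrix
    for t in range(1, horizon + 1):
        # advance first-year tunnel
        newdiag = (state >= DNEW0) & (state < DNEW0 + 4)
        state[newdiag] += DPOST0 - DNEW0

        if offered[t]:
            adheres = rng.random(n) < params.adherence
            in_u = (state >= U0) & (state < U0 + 4)
            participants = adheres & ((state == HEALTHY) | in_u)
            screens += participants
            det = in_u & adheres & (rng.random(n) < params.sensitivity)
            state[det] += DNEW0 - U0
            fp = (state == HEALTHY) & adheres & (rng.random(n) < 1 - params.specificity)
            fps += fp

        in_u = (state >= U0) & (state < U0 + 4)
        stage = np.where(in_u, state - U0, 0)
        clin = in_u & (rng.random(n) < params._p_clin[stage])
        state[clin] += DNEW0 - U0

        dead_other = (state < LC_DEATH) & (rng.random(n) < p_other_path[t])
        state[dead_other] = OTHER_DEATH

        new_case = (state == HEALTHY) & (rng.random(n) < p_inc_path[t])
        state[new_case] = U0  # stage I

        in_u = (state >= U0) & (state < U0 + 4) & ~new_case
        stage = np.where(in_u, state - U0, 0)
        lc_dead = in_u & (rng.random(n) < params._p_lcd[stage])
        state[lc_dead] = LC_DEATH
        in_u = in_u & ~lc_dead
        if in_u.any():
            u = rng.random(n)
            cum = np.cumsum(prog, axis=1)  # (4, 4) cumulative move probabilities
            stage = state - U0
            for s_idx in range(3):  # stage IV cannot progress
                here = in_u & (stage == s_idx)
                if not here.any():
                    continue
                c = cum[s_idx]
                draw = u[here]
                dest = np.searchsorted(c, draw, side="right")
                dest = np.where(draw < c[-1], dest, -1)  # -1: stays put
                moved = dest >= 0
                idx = np.flatnonzero(here)
                state[idx[moved]] = U0 + dest[moved]

        in_post = (state >= DPOST0) & (state < DPOST0 + 4)
        stage = np.where(in_post, state - DPOST0, 0)
        after = in_post & (rng.random(n) < params._p_after[stage])
        state[after] = LC_DEATH

        alive = (state < LC_DEATH).astype(float)
        ly += 0.5 * (alive_prev + alive)
        alive_prev = alive

    return {
        "lc_death": (state == LC_DEATH).astype(float),
        "life_years": ly,
        "screens": screens,
        "false_positives": fps,
    }
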