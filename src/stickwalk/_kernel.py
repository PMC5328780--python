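"""Compiled fixed-step RK4 kernel for the full three-leg network.

The continuous state is packed into one flat float64 vector::

    X[0:60]    membrane potentials (20 units per leg, legs FL, ML, HL)
    X[60:78]   slow inactivation h of the 18 CPG neurons (6 per leg)
    X[78:96]   muscle activations (6 per leg)
    X[96:105]  joint angles (alpha, beta, gamma per leg, degrees)
    X[105:111] sensory trigger pulses (touch-down, lift-off per leg)
    X[111:113] intersegmental synaptic resources r (FL input, ML input)
    X[113:116] load signals (low-pass filtered ground contact per leg)

Per-leg unit order (offset 20*leg): C_pro, C_ret, C_lev, C_dep, C_ext,
C_flex, then the six premotor INs, the six MNs (same muscle order:
pro, ret, lev, dep, ext, flex), then the two sensory INs (touch-down
trigger, lift-off trigger).

Discrete state — the intraleg PR/EF gate latches — lives in two int32[3]
arrays updated once per step from β threshold crossings.  The crossing
direction encodes the sign of dβ, which debounces the thresholds.

The same membrane equations are implemented object-per-unit in
:mod:`stickwalk.core`; this module is the performance path and adds the
state-dependent conductances (intersegmental β-mapping, gate drives,
trigger pulses) that make the network a closed sensorimotor loop.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---- state layout ----------------------------------------------------------
NLEG = 3
NUNIT = 20
NV = NLEG * NUNIT          # 60
NH = NLEG * 6              # 18
NMUS = NLEG * 6            # 18
NANG = NLEG * 3            # 9
OFF_H = NV                 # 60
OFF_A = OFF_H + NH         # 78
OFF_TH = OFF_A + NMUS      # 96
OFF_P = OFF_TH + NANG      # 105
OFF_R = OFF_P + 2 * NLEG   # 111
OFF_L = OFF_R + 2          # 113
NX = OFF_L + NLEG          # 116

# unit roles within a leg
U_C_PRO, U_C_RET, U_C_LEV, U_C_DEP, U_C_EXT, U_C_FLEX = 0, 1, 2, 3, 4, 5
U_IN0, U_MN0, U_SIN_TD, U_SIN_LO = 6, 12, 18, 19

# ---- scalar parameter vector indices ---------------------------------------
P_THM, P_SGM, P_THH, P_SGH, P_TAUH0 = 0, 1, 2, 3, 4
P_THS, P_SGS, P_EINH = 5, 6, 7
P_GGATE, P_THRPR, P_THREF = 8, 9, 10
P_MAPTHR, P_MAPSLOPE, P_TAUREC, P_TAUDEP = 11, 12, 13, 14
P_TAUPULSE, P_GPULSE = 15, 16
P_TAUACT, P_KALPHA, P_KBETA, P_KGAMMA = 17, 18, 19, 20
P_AMIN, P_AMAX, P_BMIN, P_BMAX, P_GMIN, P_GMAX = 21, 22, 23, 24, 25, 26
P_ATD, P_ALO = 27, 28
P_VSANITY = 29
P_TAULOAD, P_GLOAD, P_GDEPF = 30, 31, 32
P_GLOADLEV = 33
P_GPARK, P_BPARK = 34, 35
P_GGROUND, P_EDEP = 36, 37
NP_SCAL = 38


@njit(cache=True)
def _sig(x):
    # overflow-safe logistic
    if x > 40.0:
        return 1.0
    if x < -40.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True)
def _rhs(X, dX, nrn, h_slot, syn_idx, syn_par, drv_post, drv_par,
         P, gate_pr, gate_ef, is_mode, is_g, is_E):
    ths = P[P_THS]
    sgs = P[P_SGS]
    s = np.empty(NV)
    for i in range(NV):
        s[i] = _sig((X[i] - ths) / sgs)

    I = np.zeros(NV)
    for k in range(syn_idx.shape[0]):
        pre = syn_idx[k, 0]
        post = syn_idx[k, 1]
        I[post] += syn_par[k, 0] * s[pre] * (X[post] - syn_par[k, 1])
    for k in range(drv_post.shape[0]):
        j = drv_post[k]
        I[j] += drv_par[k, 0] * (X[j] - drv_par[k, 1])

    # intraleg sensory gates: routed excitatory command to one side of the
    # PR and EF half-centers (protract/retract, extend/flex)
    gg = P[P_GGATE]
    for L in range(NLEG):
        base = NUNIT * L
        if gate_pr[L] == 0:
            I[base + U_C_PRO] += gg * (X[base + U_C_PRO] - 0.0)
        else:
            I[base + U_C_RET] += gg * (X[base + U_C_RET] - 0.0)
        if gate_ef[L] == 0:
            I[base + U_C_EXT] += gg * (X[base + U_C_EXT] - 0.0)
        else:
            I[base + U_C_FLEX] += gg * (X[base + U_C_FLEX] - 0.0)

    # sensory trigger interneurons driven by decaying pulse conductances
    gp = P[P_GPULSE]
    for L in range(NLEG):
        base = NUNIT * L
        I[base + U_SIN_TD] += gp * X[OFF_P + 2 * L] * (X[base + U_SIN_TD] - 0.0)
        I[base + U_SIN_LO] += gp * X[OFF_P + 2 * L + 1] * (X[base + U_SIN_LO] - 0.0)

    # load reflex: ground contact (low-pass filtered) excites the depressor
    # CPG neuron and inhibits the levator CPG neuron — load opposes swing
    # initiation, so a grounded uncoupled leg stays grounded
    gload = P[P_GLOAD]
    gloadlev = P[P_GLOADLEV]
    einh = P[P_EINH]
    for L in range(NLEG):
        l = X[OFF_L + L]
        tgt = NUNIT * L + U_C_DEP
        I[tgt] += gload * l * (X[tgt] - 0.0)
        tgt = NUNIT * L + U_C_LEV
        I[tgt] += gloadlev * l * (X[tgt] - einh)
        grounded = 1.0 if X[OFF_TH + 3 * L + 1] <= P[P_THRPR] else 0.0
        dX[OFF_L + L] = (grounded - l) / P[P_TAULOAD]
        # swing-end reflex: an elevated, fully protracted leg tonically
        # excites its depressor CPG neuron so the swing always terminates
        if X[OFF_TH + 3 * L + 1] >= P[P_BPARK] and X[OFF_TH + 3 * L] <= P[P_ATD]:
            tgt = NUNIT * L + U_C_DEP
            I[tgt] += P[P_GPARK] * (X[tgt] - 0.0)
        # ground-proximity reflex: an unsupported leg below full elevation
        # whose levator CPG neuron is silent has its levator motoneuron
        # inhibited, so touch-down always completes (swing ascent, with the
        # levator CPG active, is unaffected)
        b = X[OFF_TH + 3 * L + 1]
        if P[P_THRPR] < b < P[P_BPARK] and s[NUNIT * L + U_C_LEV] < 0.3:
            tgt = NUNIT * L + U_MN0 + 2
            I[tgt] += P[P_GGROUND] * (X[tgt] - einh)

    # intersegmental inhibition of the anterior LD CPG pair, strength a
    # sigmoid of the next posterior leg's beta, scaled by the slow synaptic
    # resource r.  During the posterior swing both the anterior levator and
    # depressor neurons are suppressed; at posterior touch-down the release
    # lets the levator (slow variable primed by the hyperpolarization) win
    # the restart race against the returning load drive, producing the
    # chained lift-off.  Overrides (decoupling) act on the levator branch
    # and silence the depressor branch.
    for L in range(2):  # L=0: onto FL C3/C4 from beta_ML; L=1: onto ML C9/C10 from beta_HL
        beta_post = X[OFF_TH + 3 * (L + 1) + 1]
        act = _sig((beta_post - P[P_MAPTHR]) / P[P_MAPSLOPE])
        r = X[OFF_R + L]
        mstrength = is_g[L] * act * r
        if is_mode[L] == 0:      # baseline: modulated inhibition of the pair
            tgt = NUNIT * L + U_C_LEV
            I[tgt] += mstrength * (X[tgt] - is_E[L])
            # the depressor branch is shunting (reversal at rest): it
            # silences the depressor during the pulse without priming a
            # post-inhibitory rebound, so the levator wins at release
            tgt = NUNIT * L + U_C_DEP
            I[tgt] += P[P_GDEPF] * mstrength * (X[tgt] - P[P_EDEP])
        elif is_mode[L] == 1:    # constant override on the levator branch
            tgt = NUNIT * L + U_C_LEV
            I[tgt] += is_g[L] * (X[tgt] - is_E[L])
        else:                    # modulated override (e.g. reversal flipped)
            tgt = NUNIT * L + U_C_LEV
            I[tgt] += mstrength * (X[tgt] - is_E[L])
        dX[OFF_R + L] = (1.0 - r) / P[P_TAUREC] - act * r / P[P_TAUDEP]

    # membrane equations (activation/inactivation kinetics per neuron:
    # nrn columns 5..9 are theta_m, sigma_m, theta_h, sigma_h, tau_h0)
    for i in range(NV):
        Ci = nrn[i, 0]
        Ii = I[i] + nrn[i, 1] * (X[i] - nrn[i, 2])
        gP = nrn[i, 3]
        if gP > 0.0:
            hh = X[OFF_H + h_slot[i]]
            minf = _sig((X[i] - nrn[i, 5]) / nrn[i, 6])
            Ii += gP * minf * hh * (X[i] - nrn[i, 4])
            hinf = _sig(-(X[i] - nrn[i, 7]) / nrn[i, 8])
            tau = nrn[i, 9] / np.cosh((X[i] - nrn[i, 7]) / (2.0 * nrn[i, 8]))
            dX[OFF_H + h_slot[i]] = (hinf - hh) / tau
        dX[i] = -Ii / Ci

    # muscle activations follow motoneuron output, first order
    tact = P[P_TAUACT]
    for L in range(NLEG):
        base = NUNIT * L
        for m in range(6):
            j = OFF_A + 6 * L + m
            dX[j] = (s[base + U_MN0 + m] - X[j]) / tact

    # joint angles: antagonistic velocity drive, hard-stopped at the
    # anatomical range
    for L in range(NLEG):
        ja = OFF_A + 6 * L
        a_pro, a_ret = X[ja + 0], X[ja + 1]
        a_lev, a_dep = X[ja + 2], X[ja + 3]
        a_ext, a_flex = X[ja + 4], X[ja + 5]
        jt = OFF_TH + 3 * L
        v = P[P_KALPHA] * (a_ret - a_pro)      # retraction increases alpha
        if (X[jt] >= P[P_AMAX] and v > 0.0) or (X[jt] <= P[P_AMIN] and v < 0.0):
            v = 0.0
        dX[jt] = v
        v = P[P_KBETA] * (a_lev - a_dep)       # levation increases beta
        if (X[jt + 1] >= P[P_BMAX] and v > 0.0) or (X[jt + 1] <= P[P_BMIN] and v < 0.0):
            v = 0.0
        dX[jt + 1] = v
        v = P[P_KGAMMA] * (a_flex - a_ext)     # flexion increases gamma
        if (X[jt + 2] >= P[P_GMAX] and v > 0.0) or (X[jt + 2] <= P[P_GMIN] and v < 0.0):
            v = 0.0
        dX[jt + 2] = v

    # sensory trigger pulses decay exponentially
    for i in range(OFF_P, OFF_P + 2 * NLEG):
        dX[i] = -X[i] / P[P_TAUPULSE]


@njit(cache=True)
def run_segment(X, gate_pr, gate_ef, nrn, h_slot, syn_idx, syn_par,
                drv_post, drv_par, P, is_mode, is_g, is_E,
                t0, dt, n_steps, stride, step0, rec):
    """Integrate n_steps of RK4, recording every `stride` global steps.

    Returns (status, n_recorded): status -1 on success, otherwise the index
    of the first unit whose V left the sanity range (the step count at
    failure is encoded in n_recorded).  Gate latches, pulses and clamps are
    updated once per step.
    """
    k1 = np.empty(NX)
    k2 = np.empty(NX)
    k3 = np.empty(NX)
    k4 = np.empty(NX)
    Xt = np.empty(NX)
    nrec = 0
    vs = P[P_VSANITY]
    thrpr, thref = P[P_THRPR], P[P_THREF]
    atd, alo = P[P_ATD], P[P_ALO]

    for step in range(n_steps):
        b_prev0 = X[OFF_TH + 1]
        b_prev1 = X[OFF_TH + 4]
        b_prev2 = X[OFF_TH + 7]
        a_prev0 = X[OFF_TH + 0]
        a_prev1 = X[OFF_TH + 3]
        a_prev2 = X[OFF_TH + 6]

        _rhs(X, k1, nrn, h_slot, syn_idx, syn_par, drv_post, drv_par, P,
             gate_pr, gate_ef, is_mode, is_g, is_E)
        for i in range(NX):
            Xt[i] = X[i] + 0.5 * dt * k1[i]
        _rhs(Xt, k2, nrn, h_slot, syn_idx, syn_par, drv_post, drv_par, P,
             gate_pr, gate_ef, is_mode, is_g, is_E)
        for i in range(NX):
            Xt[i] = X[i] + 0.5 * dt * k2[i]
        _rhs(Xt, k3, nrn, h_slot, syn_idx, syn_par, drv_post, drv_par, P,
             gate_pr, gate_ef, is_mode, is_g, is_E)
        for i in range(NX):
            Xt[i] = X[i] + dt * k3[i]
        _rhs(Xt, k4, nrn, h_slot, syn_idx, syn_par, drv_post, drv_par, P,
             gate_pr, gate_ef, is_mode, is_g, is_E)
        for i in range(NX):
            X[i] = X[i] + (dt / 6.0) * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])

        # clamp bounded quantities exactly
        for i in range(OFF_H, OFF_H + NH):
            if X[i] < 0.0:
                X[i] = 0.0
            elif X[i] > 1.0:
                X[i] = 1.0
        for i in range(OFF_A, OFF_A + NMUS):
            if X[i] < 0.0:
                X[i] = 0.0
            elif X[i] > 1.0:
                X[i] = 1.0
        for L in range(NLEG):
            jt = OFF_TH + 3 * L
            if X[jt] < P[P_AMIN]:
                X[jt] = P[P_AMIN]
            elif X[jt] > P[P_AMAX]:
                X[jt] = P[P_AMAX]
            if X[jt + 1] < P[P_BMIN]:
                X[jt + 1] = P[P_BMIN]
            elif X[jt + 1] > P[P_BMAX]:
                X[jt + 1] = P[P_BMAX]
            if X[jt + 2] < P[P_GMIN]:
                X[jt + 2] = P[P_GMIN]
            elif X[jt + 2] > P[P_GMAX]:
                X[jt + 2] = P[P_GMAX]
        for i in range(OFF_P, OFF_P + 2 * NLEG):
            if X[i] < 0.0:
                X[i] = 0.0
        for i in range(OFF_R, OFF_L + NLEG):
            if X[i] < 0.0:
                X[i] = 0.0
            elif X[i] > 1.0:
                X[i] = 1.0

        # gate latches from beta crossings; crossing direction = sign(dbeta)
        for L in range(NLEG):
            if L == 0:
                b0 = b_prev0
            elif L == 1:
                b0 = b_prev1
            else:
                b0 = b_prev2
            b1 = X[OFF_TH + 3 * L + 1]
            # lift-off latch sits slightly above the ground threshold so a
            # leg parked at the threshold cannot chatter the gates
            if b0 < thrpr + 0.8 and b1 >= thrpr + 0.8:   # lift-off
                gate_pr[L] = 0                     # protract
                gate_ef[L] = 1 if L == 2 else 0    # hind leg: flex in swing
            if b0 > thref and b1 <= thref:        # descending early threshold
                gate_ef[L] = 0 if L == 2 else 1    # hind leg: extend for stance
            if b0 > thrpr and b1 <= thrpr:        # ground contact
                gate_pr[L] = 1                     # retract
            # static complement of the lift-off rule: a fully elevated,
            # protracting leg takes the swing tibia posture even if no
            # ground-threshold crossing occurred (e.g. after a mid-air hold)
            if b1 >= P[P_BPARK] and gate_pr[L] == 0:
                gate_ef[L] = 1 if L == 2 else 0
        # alpha-position trigger pulses
        for L in range(NLEG):
            if L == 0:
                a0 = a_prev0
            elif L == 1:
                a0 = a_prev1
            else:
                a0 = a_prev2
            a1 = X[OFF_TH + 3 * L]
            if a0 > atd and a1 <= atd:            # protraction complete
                # the posterior leg's swing gates the anterior touch-down
                # trigger pathway: a crossing during the intersegmental
                # pulse is not transmitted
                gated = (L < 2 and is_mode[L] == 0
                         and X[OFF_TH + 3 * (L + 1) + 1] > P[P_MAPTHR])
                if not gated:
                    X[OFF_P + 2 * L] = 1.0
            if a0 < alo and a1 >= alo:            # retraction complete
                X[OFF_P + 2 * L + 1] = 1.0

        if (step % 50) == 0:
            for i in range(NV):
                if not (np.isfinite(X[i]) and -vs < X[i] < vs):
                    return i, step
        gstep = step0 + step + 1
        if gstep % stride == 0:
            j = nrec
            for i in range(NX):
                rec[j, i] = X[i]
            nrec += 1

    return -1, nrec
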