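"""Compiled event loops shared by the model variants.

These kernels implement the per-step event dynamics on raw arrays:
``species`` (int64 labels), ``counts`` (label-indexed occupation counts,
pre-sized so every innovation fits), and ``carrier`` (bool flags). Diversity
``S`` and carrier count ``B`` are carried incrementally. Each kernel seeds
numba's per-thread Mersenne generator, so a run is reproducible from
(arrays, parameters, seed).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def crp_labels(M, theta, seed):
    """Chinese-restaurant partition of M patches, concentration theta."""
    np.random.seed(seed)
    labels = np.empty(M, np.int64)
    n_labels = 0
    for i in range(M):
        if i == 0 or np.random.random() * (theta + i) < theta:
            labels[i] = n_labels
            n_labels += 1
        else:
            labels[i] = labels[np.random.randint(i)]
    return labels, n_labels


@njit(cache=True)
def neutral_run(species, counts, S, next_label, nu, n_steps, record_every, seed):
    """Innovation + neutral migration-sweep dynamics (no gene).

    Per step: a focal patch i is drawn uniformly; with probability nu its
    species is replaced by a fresh label, otherwise its species sweeps a
    uniformly chosen other patch j.
    """
    np.random.seed(seed)
    M = species.shape[0]
    cap = n_steps // record_every + 2
    rec_step = np.empty(cap, np.int64)
    rec_S = np.empty(cap, np.int64)
    k = 0
    rec_step[k] = 0
    rec_S[k] = S
    k += 1
    for t in range(1, n_steps + 1):
        i = np.random.randint(M)
        if np.random.random() < nu:
            old = species[i]
            counts[old] -= 1
            if counts[old] == 0:
                S -= 1
            species[i] = next_label
            counts[next_label] = 1
            next_label += 1
            S += 1
        else:
            j = np.random.randint(M - 1)
            if j >= i:
                j += 1
            old = species[j]
            new = species[i]
            if old != new:
                counts[old] -= 1
                if counts[old] == 0:
                    S -= 1
                species[j] = new
                counts[new] += 1
        if t % record_every == 0:
            rec_step[k] = t
            rec_S[k] = S
            k += 1
    if rec_step[k - 1] != n_steps and n_steps > 0:
        rec_step[k] = n_steps
        rec_S[k] = S
        k += 1
    return rec_step[:k].copy(), rec_S[:k].copy(), S, next_label


@njit(cache=True)
def sweep_run(species, counts, carrier, S, B, p_m, p_h, max_steps, record_every, seed):
    """Single-gene spread with no diversity restoration.

    Per step an ordered pair (i, j), i != j, is drawn uniformly. Only
    carrier -> non-carrier pairs act: with probability p_m patch j is swept
    by i's species together with the gene (migration-sweep), else with
    probability p_h the gene alone transfers (HGT-sweep). Stops at fixation
    (B == M) or after max_steps.
    """
    np.random.seed(seed)
    M = species.shape[0]
    cap = max_steps // record_every + 3
    rec_step = np.empty(cap, np.int64)
    rec_S = np.empty(cap, np.int64)
    rec_B = np.empty(cap, np.int64)
    k = 0
    rec_step[k] = 0
    rec_S[k] = S
    rec_B[k] = B
    k += 1
    fix = -1
    s_sum = 0.0
    n_sum = 0
    steps_done = 0
    for t in range(1, max_steps + 1):
        i = np.random.randint(M)
        j = np.random.randint(M - 1)
        if j >= i:
            j += 1
        if carrier[i] and not carrier[j]:
            u = np.random.random()
            if u < p_m:
                old = species[j]
                new = species[i]
                if old != new:
                    counts[old] -= 1
                    if counts[old] == 0:
                        S -= 1
                    species[j] = new
                    counts[new] += 1
                carrier[j] = True
                B += 1
            elif u < p_m + p_h:
                carrier[j] = True
                B += 1
        steps_done = t
        s_sum += S
        n_sum += 1
        if t % record_every == 0:
            rec_step[k] = t
            rec_S[k] = S
            rec_B[k] = B
            k += 1
        if B == M:
            fix = t
            break
    if k == 0 or rec_step[k - 1] != steps_done:
        rec_step[k] = steps_done
        rec_S[k] = S
        rec_B[k] = B
        k += 1
    return (
        rec_step[:k].copy(), rec_S[:k].copy(), rec_B[:k].copy(),
        S, B, fix, s_sum, n_sum, steps_done,
    )


@njit(cache=True)
def full_run(species, counts, carrier, S, B, next_label, nu, p_m, p_h,
             arrivals, n_steps, record_every, seed, arrivals_seen):
    """Innovation + neutral sweeps + selective migration/HGT sweeps.

    Per step: with probability nu an innovation replaces the species of a
    uniform focal patch by a fresh label, which carries the gene with
    probability f0 = B/M (evaluated at the event). Otherwise an ordered pair
    (i, j) is drawn: same carrier status -> neutral migration-sweep of j by
    i's species; carrier -> non-carrier -> selective migration-sweep with
    probability p_m, else HGT-sweep with probability p_h; non-carrier ->
    carrier -> no-op.

    ``arrivals`` (sorted elementary steps) reset all carrier flags and seed
    the newest gene on one uniform patch; each inter-arrival window yields
    one row of episode statistics.
    """
    np.random.seed(seed)
    M = species.shape[0]
    na = arrivals.shape[0]
    cap = n_steps // record_every + 3
    rec_step = np.empty(cap, np.int64)
    rec_S = np.empty(cap, np.int64)
    rec_B = np.empty(cap, np.int64)
    rec_A = np.empty(cap, np.int64)
    k = 0

    epcap = na + 1
    ep_start = np.empty(epcap, np.int64)
    ep_end = np.empty(epcap, np.int64)
    ep_Sstart = np.empty(epcap, np.int64)
    ep_Smin = np.empty(epcap, np.int64)
    ep_Sminfix = np.empty(epcap, np.int64)
    ep_Smax = np.empty(epcap, np.int64)
    ep_Ssum = np.empty(epcap, np.float64)
    ep_n = np.empty(epcap, np.int64)
    ep_Send = np.empty(epcap, np.int64)
    ep_fix = np.empty(epcap, np.int64)
    n_ep = 0

    ai = 0
    # arrivals at time 0 apply before anything else
    while ai < na and arrivals[ai] <= 0:
        for q in range(M):
            carrier[q] = False
        p = np.random.randint(M)
        carrier[p] = True
        B = 1
        arrivals_seen += 1
        ai += 1

    cur_start = 0
    cur_Sstart = S
    cur_Smin = S
    cur_Sminfix = S
    cur_Smax = S
    cur_Ssum = 0.0
    cur_n = 0
    cur_fix = 0 if B == M else -1

    rec_step[k] = 0
    rec_S[k] = S
    rec_B[k] = B
    rec_A[k] = arrivals_seen
    k += 1

    for t in range(1, n_steps + 1):
        u0 = np.random.random()
        if u0 < nu:
            i = np.random.randint(M)
            f0 = B / M
            newc = np.random.random() < f0
            old = species[i]
            counts[old] -= 1
            if counts[old] == 0:
                S -= 1
            if carrier[i]:
                B -= 1
            species[i] = next_label
            counts[next_label] = 1
            next_label += 1
            S += 1
            carrier[i] = newc
            if newc:
                B += 1
        else:
            i = np.random.randint(M)
            j = np.random.randint(M - 1)
            if j >= i:
                j += 1
            ci = carrier[i]
            cj = carrier[j]
            if ci == cj:
                old = species[j]
                new = species[i]
                if old != new:
                    counts[old] -= 1
                    if counts[old] == 0:
                        S -= 1
                    species[j] = new
                    counts[new] += 1
            elif ci:
                u = np.random.random()
                if u < p_m:
                    old = species[j]
                    new = species[i]
                    if old != new:
                        counts[old] -= 1
                        if counts[old] == 0:
                            S -= 1
                        species[j] = new
                        counts[new] += 1
                    carrier[j] = True
                    B += 1
                elif u < p_m + p_h:
                    carrier[j] = True
                    B += 1
        cur_n += 1
        cur_Ssum += S
        if S < cur_Smin:
            cur_Smin = S
        if S > cur_Smax:
            cur_Smax = S
        if cur_fix < 0:
            if S < cur_Sminfix:
                cur_Sminfix = S
            if B == M:
                cur_fix = t
        if t % record_every == 0:
            rec_step[k] = t
            rec_S[k] = S
            rec_B[k] = B
            rec_A[k] = arrivals_seen
            k += 1
        if ai < na and arrivals[ai] <= t and t < n_steps:
            # close the window [cur_start, t]
            ep_start[n_ep] = cur_start
            ep_end[n_ep] = t
            ep_Sstart[n_ep] = cur_Sstart
            ep_Smin[n_ep] = cur_Smin
            ep_Sminfix[n_ep] = cur_Sminfix
            ep_Smax[n_ep] = cur_Smax
            ep_Ssum[n_ep] = cur_Ssum
            ep_n[n_ep] = cur_n
            ep_Send[n_ep] = S
            ep_fix[n_ep] = cur_fix
            n_ep += 1
            while ai < na and arrivals[ai] <= t:
                for q in range(M):
                    carrier[q] = False
                p = np.random.randint(M)
                carrier[p] = True
                B = 1
                arrivals_seen += 1
                ai += 1
            if rec_step[k - 1] == t:
                rec_B[k - 1] = B
                rec_A[k - 1] = arrivals_seen
            cur_start = t
            cur_Sstart = S
            cur_Smin = S
            cur_Sminfix = S
            cur_Smax = S
            cur_Ssum = 0.0
            cur_n = 0
            cur_fix = -1
    if rec_step[k - 1] != n_steps and n_steps > 0:
        rec_step[k] = n_steps
        rec_S[k] = S
        rec_B[k] = B
        rec_A[k] = arrivals_seen
        k += 1
    ep_start[n_ep] = cur_start
    ep_end[n_ep] = n_steps
    ep_Sstart[n_ep] = cur_Sstart
    ep_Smin[n_ep] = cur_Smin
    ep_Sminfix[n_ep] = cur_Sminfix
    ep_Smax[n_ep] = cur_Smax
    ep_Ssum[n_ep] = cur_Ssum
    ep_n[n_ep] = cur_n
    ep_Send[n_ep] = S
    ep_fix[n_ep] = cur_fix
    n_ep += 1
    return (
        rec_step[:k].copy(), rec_S[:k].copy(), rec_B[:k].copy(), rec_A[:k].copy(),
        ep_start[:n_ep].copy(), ep_end[:n_ep].copy(), ep_Sstart[:n_ep].copy(),
        ep_Smin[:n_ep].copy(), ep_Sminfix[:n_ep].copy(), ep_Smax[:n_ep].copy(),
        ep_Ssum[:n_ep].copy(), ep_n[:n_ep].copy(), ep_Send[:n_ep].copy(),
        ep_fix[:n_ep].copy(), S, B, next_label, arrivals_seen,
    )
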