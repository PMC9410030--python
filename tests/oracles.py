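"""Independent brute-force oracles and shared fixture matrices.

Everything here is deliberately naive (path enumeration, augmented-chain
stationary solves) and independent of the package's production code paths,
so it can certify them.
"""

import itertools

import numpy as np

# 3-state chain with moderate metastability: MFPTs of a few tens of frames,
# so 10^5-10^6-frame samples contain thousands of passage events.
T3 = np.array([
    [0.90, 0.07, 0.03],
    [0.05, 0.90, 0.05],
    [0.04, 0.06, 0.90],
])

# Hidden 4-state chain {A, I1, I2, B} whose lumping I = {I1, I2} produces a
# strongly non-Markov observable: I1 is reachable only from A and returns
# mostly to A; I2 is reachable only from B. Conditioned on last core A, the
# walker in I is really in I1, so P(next=B | I, hist=A) = 0.10, far from the
# unconditional mixture over I1/I2.
T_HIDDEN = np.array([
    [0.85, 0.15, 0.00, 0.00],   # A
    [0.80, 0.10, 0.00, 0.10],   # I1
    [0.10, 0.00, 0.10, 0.80],   # I2
    [0.00, 0.00, 0.15, 0.85],   # B
])
LUMP_MAP = np.array([0, 1, 1, 2])   # observed A=0, I=1, B=2


def fptd_by_path_enumeration(T, source, target, n):
    """P(first passage source→target at exactly step n) by summing all paths.

    Enumerates every intermediate-state sequence of length n−1 avoiding the
    target; exponential cost, usable only for tiny n.
    """
    T = np.asarray(T, dtype=float)
    others = [k for k in range(T.shape[0]) if k != target]
    if n == 1:
        return float(T[source, target])
    total = 0.0
    for path in itertools.product(others, repeat=n - 1):
        p = T[source, path[0]]
        for a, b in zip(path[:-1], path[1:]):
            p *= T[a, b]
        p *= T[path[-1], target]
        total += p
    return float(total)


def mfpt_by_absorbing_solve(T, source, target):
    """Exact MFPT in lag units by the standard absorbing-chain linear solve.

    Written directly from the fundamental-matrix identity, not through the
    package.
    """
    T = np.asarray(T, dtype=float)
    idx = [i for i in range(T.shape[0]) if i != target]
    Q = T[np.ix_(idx, idx)]
    F = np.linalg.solve(np.eye(len(idx)) - Q, np.ones(len(idx)))
    return float(F[idx.index(source)])


def stationary_distribution(T):
    """Stationary vector by solving the balance equations directly."""
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    A = np.vstack([T.T - np.eye(n), np.ones(n)])
    b = np.concatenate([np.zeros(n), [1.0]])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return pi


def augmented_conditional_next_B(T_hidden, lump_map, A_obs, B_obs):
    """Exact P(next observed = B | observed = I, history = A) and the
    unconditional P(next observed = B | observed = I).

    Built on the augmented chain over (hidden state, last-visited core),
    whose stationary distribution is solved exactly.
    """
    T = np.asarray(T_hidden, dtype=float)
    lump = np.asarray(lump_map)
    nh = T.shape[0]
    cores = (A_obs, B_obs)
    # augmented states: (h, mu) with mu in {A_obs, B_obs}
    states = [(h, mu) for h in range(nh) for mu in cores]
    index = {s: k for k, s in enumerate(states)}
    Ta = np.zeros((len(states), len(states)))
    for (h, mu), k in index.items():
        for h2 in range(nh):
            if T[h, h2] == 0:
                continue
            mu2 = lump[h2] if lump[h2] in cores else mu
            Ta[k, index[(h2, mu2)]] += T[h, h2]
    pi = stationary_distribution(Ta)
    # restrict to observed-I hidden states
    i_states = [h for h in range(nh) if lump[h] not in cores]
    # conditional on history A
    wA = np.array([pi[index[(h, A_obs)]] for h in i_states])
    toB = np.array([sum(T[h, h2] for h2 in range(nh) if lump[h2] == B_obs)
                    for h in i_states])
    cond = float(wA @ toB / wA.sum())
    # unconditional over both histories
    w = np.array([pi[index[(h, A_obs)]] + pi[index[(h, B_obs)]] for h in i_states])
    uncond = float(w @ toB / w.sum())
    return cond, uncond
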