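"""Naive double-loop reference implementation of the permutation p-value
machinery, used as an independent oracle on exhaustively enumerated
permutations. Deliberately written with explicit Python loops over
rearrangements and direct quadratic forms — no shared code with the package
beyond numpy."""

import numpy as np

TARGETS = ("M", "I", "B")


def quad(r, K):
    return float(np.asarray(r) @ np.asarray(K) @ np.asarray(r))


def snap(obs, null):
    """The shared tie convention: statistics are compared on a relative
    ~1e-12 grid (scale snapped to a power of two)."""
    null = np.asarray(null, dtype=float)
    s = max(float(np.max(np.abs(null), initial=0.0)), abs(obs))
    if s == 0.0:
        return obs, null
    grid = 2.0 ** np.ceil(np.log2(s)) * 1e-12
    return float(np.round(obs / grid) * grid), np.round(null / grid) * grid


def naive_full_analysis(endog_by_kernel, residuals, perms):
    """All p-values for a multi-kernel analysis, from scratch.

    endog_by_kernel: {label: {"M": K, "I": K, "B": K}} explicit matrices.
    perms: list of index arrays (the shared rearrangement plan).
    Returns a dict with per-kernel and omnibus p-values.
    """
    residuals = np.asarray(residuals, dtype=float)
    R = len(perms)
    obs = {h: {t: quad(residuals, ks[t]) for t in TARGETS} for h, ks in endog_by_kernel.items()}
    null = {
        h: {t: np.array([quad(residuals[p], ks[t]) for p in perms]) for t in TARGETS}
        for h, ks in endog_by_kernel.items()
    }
    for h in obs:
        for t in TARGETS:
            obs[h][t], null[h][t] = snap(obs[h][t], null[h][t])
    return naive_pvalues_from_stats(obs, null)


def naive_pvalues_from_stats(obs, null):
    """P-values from given observed/null statistics via explicit loops."""
    kernels = list(obs)
    R = len(next(iter(null[kernels[0]].values())))
    out = {"per_kernel": {}, "omnibus": {}}

    P = {}
    loo = {}
    for h in kernels:
        P[h] = {}
        loo[h] = {}
        for t in TARGETS:
            P[h][t] = sum(null[h][t][r] >= obs[h][t] for r in range(R)) / R
            loo[h][t] = np.array(
                [
                    sum(null[h][t][r] >= null[h][t][rp] for r in range(R) if r != rp)
                    / (R - 1)
                    for rp in range(R)
                ]
            )
        t_h = min(P[h][t] for t in TARGETS)
        t_h_null = np.array([min(loo[h][t][rp] for t in TARGETS) for rp in range(R)])
        p_h = sum(t_h_null[rp] <= t_h for rp in range(R)) / R
        out["per_kernel"][h] = {
            "P": dict(P[h]),
            "loo": {t: loo[h][t] for t in TARGETS},
            "t_minp": t_h,
            "minp_null": t_h_null,
            "p_minp": p_h,
        }

    t_om, O, p_om, Q = {}, {}, {}, {}
    for t in TARGETS:
        t_om[t] = min(P[h][t] for h in kernels)
        O[t] = np.array([min(loo[h][t][rp] for h in kernels) for rp in range(R)])
        p_om[t] = sum(O[t][rp] <= t_om[t] for rp in range(R)) / R
        Q[t] = np.array(
            [
                sum(O[t][r] <= O[t][rp] for r in range(R) if r != rp) / (R - 1)
                for rp in range(R)
            ]
        )
    t_omnik = min(p_om[t] for t in TARGETS)
    null_t = np.array([min(Q[t][rp] for t in TARGETS) for rp in range(R)])
    p_omnik = sum(null_t[rp] <= t_omnik for rp in range(R)) / R
    out["omnibus"] = {
        "t_endog": t_om,
        "null_endog": O,
        "p_endog": p_om,
        "t_omnik": t_omnik,
        "p_omnik": p_omnik,
    }
    return out
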