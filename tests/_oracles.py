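"""Brute-force reference implementations used only as test oracles.

These deliberately avoid the package's vectorized code paths: statistics are
computed with plain Python loops so they can disagree with the
implementation if either is wrong.
"""

import itertools
import math

from scipy import stats as sps


def brute_force_cluster_test(eta, weights, alpha):
    """Exhaustive within-unit relabelling cluster test by nested loops.

    ``eta``: nested list or array of shape (n_units, 3, n_frames), no
    missing values.  Returns (observed_clusters, p_values, null_max_masses)
    where each observed cluster is (start, end, mass) and
    p = #(null >= |mass|) / 6**n_units with the identity included.
    """
    U = len(eta)
    F = len(eta[0][0])
    perms = list(itertools.permutations(range(3)))
    crit = sps.t.ppf(1 - alpha / 2, U - 1)

    def t_series(assign):
        ts = []
        for f in range(F):
            scores = [
                sum(weights[k] * eta[u][perms[assign[u]][k]][f] for k in range(3))
                for u in range(U)
            ]
            m = sum(scores) / U
            var = sum((s - m) ** 2 for s in scores) / (U - 1)
            ts.append(m / math.sqrt(var / U) if var > 1e-18 else float("nan"))
        return ts

    def clusters(ts):
        out = []
        cur = None
        for f, t in enumerate(ts):
            sig = t == t and abs(t) >= crit
            sgn = 0 if not sig else (1 if t > 0 else -1)
            if cur is not None and (not sig or sgn != cur[2]):
                out.append(cur)
                cur = None
            if sig and cur is None:
                cur = [f, f, sgn, 0.0]
            if sig:
                cur[1] = f
                cur[3] += t
        if cur is not None:
            out.append(cur)
        return [(c[0], c[1], c[3]) for c in out]

    observed = clusters(t_series([0] * U))
    null = []
    for assign in itertools.product(range(6), repeat=U):
        cl = clusters(t_series(assign))
        null.append(max((abs(m) for _, _, m in cl), default=0.0))
    ps = [
        sum(1 for m in null if m >= abs(mass) - 1e-9) / len(null)
        for _, _, mass in observed
    ]
    return observed, ps, null


def brute_force_sign_flip_test(diffs):
    """Exhaustive two-sided sign-flip test on per-subject differences.

    Returns p = #(|mean(signs * d)| >= |mean(d)|) / 2**n.
    """
    n = len(diffs)
    obs = abs(sum(diffs) / n)
    count = 0
    total = 0
    for signs in itertools.product((1.0, -1.0), repeat=n):
        stat = abs(sum(s * d for s, d in zip(signs, diffs)) / n)
        if stat >= obs - 1e-12:
            count += 1
        total += 1
    return count / total
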