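"""Independent reference implementations used as oracles in tests.

These deliberately avoid the package's own code paths: the sibling joint
distribution is obtained by exhaustive Mendelian enumeration, and the Cox
coefficient by explicit-loop Efron partial-likelihood maximisation.
"""

import math

import numpy as np
from scipy import optimize, stats


def enumerate_sibling_joint(p: float) -> np.ndarray:
    """Exhaustive enumeration over ordered HWE parental pairs.

    Each offspring receives one allele from each parent by Mendelian
    segregation, independently; two offspring of the same parents give the
    sibling joint genotype distribution.
    """
    q = 1.0 - p
    parent_probs = [q * q, 2 * p * q, p * p]
    transmit = [0.0, 0.5, 1.0]  # P(pass minor allele | parent genotype)
    joint = np.zeros((3, 3))
    for f in range(3):
        for m in range(3):
            tf, tm = transmit[f], transmit[m]
            child = np.zeros(3)
            for af in (0, 1):
                for am in (0, 1):
                    pr = (tf if af else 1 - tf) * (tm if am else 1 - tm)
                    child[af + am] += pr
            joint += parent_probs[f] * parent_probs[m] * np.outer(child, child)
    return joint


def brute_force_efron(g, time, event=None):
    """Explicit-loop Efron partial likelihood maximised by Brent search."""
    g = np.asarray(g, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.ones(g.size, dtype=bool) if event is None else np.asarray(event, dtype=bool)

    def loglik(beta):
        ll = 0.0
        for ut in np.unique(time[event]):
            D = np.where((time == ut) & event)[0]
            R = np.where(time >= ut)[0]
            d = len(D)
            s0 = sum(math.exp(beta * g[i]) for i in D)
            S0 = sum(math.exp(beta * g[i]) for i in R)
            ll += beta * g[D].sum()
            for l in range(d):
                ll -= math.log(S0 - (l / d) * s0)
        return ll

    res = optimize.minimize_scalar(
        lambda b: -loglik(b), bracket=(-2.0, 0.0, 2.0),
        method="brent", options={"xtol": 1e-12},
    )
    beta = float(res.x)
    info = 0.0
    for ut in np.unique(time[event]):
        D = np.where((time == ut) & event)[0]
        R = np.where(time >= ut)[0]
        d = len(D)

        def sums(idx, k):
            return sum(math.exp(beta * g[i]) * g[i] ** k for i in idx)

        for l in range(d):
            D0 = sums(R, 0) - (l / d) * sums(D, 0)
            D1 = sums(R, 1) - (l / d) * sums(D, 1)
            D2 = sums(R, 2) - (l / d) * sums(D, 2)
            info += D2 / D0 - (D1 / D0) ** 2
    se = 1.0 / math.sqrt(info)
    p = 2 * stats.norm.sf(abs(beta / se))
    return beta, se, p
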