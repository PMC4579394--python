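"""Independent brute-force oracles used by the tests.

These deliberately share no code with the package: posterior copying
probabilities come from explicit enumeration of all K^T copying paths.
"""

import itertools

import numpy as np

from panelimpute.hmm import emission_epsilon


def enumerate_posteriors(obs, refs, dists_cm, ne, epsilon=None):
    """Exact state posteriors (T x K) by summing over all copying paths."""
    refs = np.asarray(refs)
    obs = np.asarray(obs)
    k, t = refs.shape
    eps = emission_epsilon(k) if epsilon is None else epsilon
    pnr = np.exp(-4.0 * ne * (np.asarray(dists_cm, dtype=float) / 100.0) / k)
    post = np.zeros((t, k))
    total = 0.0
    for path in itertools.product(range(k), repeat=t):
        p = 1.0 / k
        for i in range(t):
            if i > 0:
                p *= (1.0 - pnr[i - 1]) / k + (pnr[i - 1] if path[i] == path[i - 1] else 0.0)
            p *= (1.0 - eps) if refs[path[i], i] == obs[i] else eps
        total += p
        for i in range(t):
            post[i, path[i]] += p
    return post / total


def posterior_alt_mixture(gamma_row, ref_alleles_at_site, epsilon):
    """P(ALT) emission mixture for one site given a posterior state row."""
    a = np.asarray(ref_alleles_at_site, dtype=float)
    return float(np.sum(gamma_row * ((1.0 - epsilon) * a + epsilon * (1.0 - a))))
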