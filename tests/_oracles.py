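"""Independent brute-force oracles, deliberately written without reusing the
implementation's code paths: explicit path-walking for haplogroup scoring,
exact rational hypergeometric enumeration for Fisher's test, and a
covariance eigendecomposition for PCA."""

from fractions import Fraction
from math import comb


def brute_force_best_haplogroup(sample_calls, tree_root, panel_positions, reference):
    """Exhaustive argmax of the Kulczynski score over every tree node.

    Recomputes each node's expected states by explicitly walking the
    root-to-node variant path; ties broken by depth (desc) then label (asc).
    """
    results = []

    def walk(node, path_variants, depth):
        states = {}
        for v in path_variants:
            states[v.position] = v.derived
        n_exp = n_match = n_obs = 0
        for pos, call in sample_calls.items():
            if call is None or pos not in panel_positions:
                continue
            ref = reference[pos]
            exp = states.get(pos, ref)
            if exp != ref:
                n_exp += 1
                if call == exp:
                    n_match += 1
            if call != ref:
                n_obs += 1
        recall = n_match / n_exp if n_exp else 1.0
        precision = n_match / n_obs if n_obs else 1.0
        results.append((0.5 * (recall + precision), depth, node.label))
        for child in node.children:
            walk(child, path_variants + child.defining_variants, depth + 1)

    walk(tree_root, list(tree_root.defining_variants), 0)
    results.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return results[0][2], results[0][0]


def fisher_two_tailed_exact(a, b, c, d):
    """Two-tailed Fisher p for [[a,b],[c,d]] by exact rational enumeration.

    Sums hypergeometric probabilities of every table with the same margins
    whose probability is <= that of the observed table (exact comparison,
    no floating-point fudge).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for k in range(lo, hi + 1):
        p_k = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if p_k <= p_obs:
            total += p_k
    return float(total)


def pca_eigenvalues_by_covariance(matrix):
    """Eigenvalues of the sample covariance of the rows, descending."""
    import numpy as np

    X = np.asarray(matrix, dtype=float)
    centred = X - X.mean(axis=0)
    cov = centred.T @ centred / (X.shape[0] - 1)
    vals = np.linalg.eigvalsh(cov)[::-1]
    return vals
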