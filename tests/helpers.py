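"""Shared independent oracles for the synthetic-generator tests."""

import numpy as np

from embedlex.semantics import LABEL_ORDER


def closed_form_expected_kappa(base, kernel, agreement_prob):
    """Expected pairwise kappa under the annotation label model.

    Enumerates the joint distribution of one annotator pair's labels:
    P(A=x, B=y) = sum_r base[r] * f(r,x) * f(r,y) with
    f(r,x) = a*1[x=r] + (1-a)*kernel[r,x]; then p_o from the diagonal and
    p_e from the marginals.
    """
    n = len(LABEL_ORDER)
    base = np.asarray(base, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    a = agreement_prob
    f = a * np.eye(n) + (1 - a) * kernel  # f[r, x]
    joint = np.einsum("r,rx,ry->xy", base, f, f)
    p_o = float(np.trace(joint))
    marg_a = joint.sum(axis=1)
    marg_b = joint.sum(axis=0)
    p_e = float(np.dot(marg_a, marg_b))
    if p_e >= 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1 - p_e)


def kappa_monte_carlo_se(base, kernel, agreement_prob, n_items):
    """Approximate SE of the empirical kappa via the binomial SE of p_o
    scaled by 1/(1 - p_e)."""
    n = len(LABEL_ORDER)
    base = np.asarray(base, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    a = agreement_prob
    f = a * np.eye(n) + (1 - a) * kernel
    joint = np.einsum("r,rx,ry->xy", base, f, f)
    p_o = float(np.trace(joint))
    p_e = float(np.dot(joint.sum(axis=1), joint.sum(axis=0)))
    se_po = np.sqrt(p_o * (1 - p_o) / n_items)
    return se_po / (1 - p_e)


def brute_force_top(source, query_key, m):
    """Full-scan cosine ranking oracle; returns the m best keys."""
    q = source.vector(query_key)
    scored = []
    for key in source.vocabulary:
        if key == query_key:
            continue
        v = source.vector(key)
        c = float(np.dot(q, v) / (np.linalg.norm(q) * np.linalg.norm(v)))
        scored.append((key, c))
    scored.sort(key=lambda kv: (-kv[1], kv[0]))
    return [k for k, _ in scored[:m]]
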