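"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by enumeration or direct loops,
staying independent of the package's vectorized/memoized implementations.
"""

from __future__ import annotations

import numpy as np


def enumerate_paths(children: dict[str, set[str]], start: str, goal: str):
    """All directed paths start -> goal following parent->child edges."""
    if start == goal:
        yield [start]
        return
    for child in children[start]:
        for tail in enumerate_paths(children, child, goal):
            yield [start] + tail


def path_contribution(dag, term: str, disease: str, delta: float) -> float:
    """max over directed paths term ~> disease of delta ** path_length."""
    children = {node: dag.children(node) for node in dag.nodes}
    best = None
    for path in enumerate_paths(children, term, disease):
        weight = delta ** (len(path) - 1)
        if best is None or weight > best:
            best = weight
    if best is None:
        raise ValueError(f"no path from {term} to {disease}")
    return best


def profile_by_paths(dag, disease: str, delta: float) -> dict[str, float]:
    terms = dag.ancestors(disease) | {disease}
    return {t: path_contribution(dag, t, disease, delta) for t in terms}


def similarity_by_paths(dag, a: str, b: str, delta: float) -> float:
    pa = profile_by_paths(dag, a, delta)
    pb = profile_by_paths(dag, b, delta)
    shared = set(pa) & set(pb)
    if not shared:
        return 0.0
    num = sum(pa[t] + pb[t] for t in shared)
    return num / (sum(pa.values()) + sum(pb.values()))


def concordance_auc(labels, scores) -> float:
    """Pairwise Mann-Whitney concordance with ties counted 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def mlp_forward_loops(weights, biases, x):
    """Straight-line per-sample forward pass: ReLU hiddens, softmax output."""
    out = []
    for row in np.asarray(x, dtype=float):
        a = row
        for w, b in zip(weights[:-1], biases[:-1]):
            a = np.array([max(0.0, float(a @ w[:, k] + b[k])) for k in range(w.shape[1])])
        w, b = weights[-1], biases[-1]
        logits = np.array([float(a @ w[:, k] + b[k]) for k in range(w.shape[1])])
        ez = np.exp(logits - logits.max())
        out.append(ez / ez.sum())
    return np.array(out)


def finite_difference_grads(loss_fn, params, eps: float = 1e-6):
    """Central finite-difference gradients of loss_fn() w.r.t. each array."""
    grads = []
    for p in params:
        g = np.zeros_like(p)
        it = np.nditer(p, flags=["multi_index"])
        while not it.finished:
            idx = it.multi_index
            orig = p[idx]
            p[idx] = orig + eps
            hi = loss_fn()
            p[idx] = orig - eps
            lo = loss_fn()
            p[idx] = orig
            g[idx] = (hi - lo) / (2 * eps)
            it.iternext()
        grads.append(g)
    return grads
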