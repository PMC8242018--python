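"""Naive step-by-step FuzzyART reference, independent of the package.

Written with plain Python loops and scalar arithmetic straight from the
category equations, to serve as an oracle for the vectorized
implementation.  Deliberately simple and slow.
"""

from __future__ import annotations


def _complement(row):
    return [float(v) for v in row] + [1.0 - float(v) for v in row]


def _l1_min(a, b):
    return sum(min(x, y) for x, y in zip(a, b))


def reference_fit(rows, rho, alpha, beta, max_epochs=50):
    """Return (weights, assignments, epochs, converged) the slow way."""
    coded = [_complement(r) for r in rows]
    weights: list[list[float]] = []
    assign = [None] * len(rows)
    epochs = 0
    converged = False
    for _ in range(max_epochs):
        epochs += 1
        changed = False
        for i, I in enumerate(coded):
            norm_i = sum(I)
            scored = []
            for j, w in enumerate(weights):
                t = _l1_min(I, w) / (alpha + sum(w))
                scored.append((-t, j))
            scored.sort()                      # descending T, ties -> low index
            winner = None
            for _, j in scored:
                m = _l1_min(I, weights[j]) / norm_i
                if m >= rho:
                    winner = j
                    break
            if winner is None:
                winner = len(weights)
                weights.append(list(I))
                changed = True
            else:
                w = weights[winner]
                new_w = [beta * min(x, y) + (1 - beta) * y
                         for x, y in zip(I, w)]
                if new_w != w:
                    weights[winner] = new_w
                    changed = True
            if assign[i] != winner:
                assign[i] = winner
                changed = True
        if not changed:
            converged = True
            break
    return weights, assign, epochs, converged
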