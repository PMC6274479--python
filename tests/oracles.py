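"""Independent naive oracles used to cross-check the package.

Everything here is written as plain Python loops over dense sequences,
deliberately sharing no code with fpscreen. Keep it slow and obvious.
"""

import math


def asmtp_scalar(v1, v2, mu, lam):
    """Naive per-feature evaluation: F = sum(N*)/sum(Nu); S = (F+lam)/(1+lam)."""
    num = 0.0
    den = 0
    for a, b, m in zip(v1, v2, mu):
        if a > 0 and b > 0:
            num += 0.5 * (1.0 + math.exp(-(((a - b) / m) ** 2)))
            den += 1
        elif a == 0 and b == 0:
            pass
        else:
            num += -lam
            den += 1
    if den == 0:
        raise ZeroDivisionError("empty union")
    f = num / den
    return (f + lam) / (1.0 + lam)


def tanimoto_continuous_scalar(v1, v2):
    dot = sum(a * b for a, b in zip(v1, v2))
    denom = sum(a * a for a in v1) + sum(b * b for b in v2) - dot
    return dot / denom


def mean_nonzero(column):
    vals = [v for v in column if v > 0]
    if not vals:
        return 1.0, 0
    return sum(vals) / len(vals), len(vals)


def recall_scalar(order, actives, pct):
    n = len(order)
    k = max(1, round(pct * n / 100.0))
    hits = sum(1 for mol in order[:k] if mol in actives)
    return 100.0 * hits / len(actives)


def ef_scalar(order, actives, pct):
    n = len(order)
    k = max(1, round(pct * n / 100.0))
    hits = sum(1 for mol in order[:k] if mol in actives)
    return (hits / k) / (len(actives) / n)


def auc_scalar(order, scores, actives):
    """Mann-Whitney AUC with ties scored 0.5; equals tie-grouped trapezoid ROC."""
    act = [s for mol, s in zip(order, scores) if mol in actives]
    inact = [s for mol, s in zip(order, scores) if mol not in actives]
    total = 0.0
    for a in act:
        for b in inact:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(act) * len(inact))


def bedroc_scalar(active_ranks, n, n_actives, alpha):
    """Direct summation of the Truchon-Bayly formula (1-based ranks)."""
    ra = n_actives / n
    s = sum(math.exp(-alpha * r / n) for r in active_ranks)
    rie = s / (ra * (1.0 - math.exp(-alpha)) / (math.exp(alpha / n) - 1.0))
    factor = (
        rie
        * ra
        * math.sinh(alpha / 2.0)
        / (math.cosh(alpha / 2.0) - math.cosh(alpha / 2.0 - alpha * ra))
    )
    return factor + 1.0 / (1.0 - math.exp(alpha * (1.0 - ra)))


def sensitivity_specificity_scalar(order, actives, k):
    tp = sum(1 for mol in order[:k] if mol in actives)
    fn = sum(1 for mol in order[k:] if mol in actives)
    fp = k - tp
    tn = len(order) - k - fn
    return tp / (tp + fn), tn / (tn + fp)
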