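"""Independent reference implementations used to validate the package.

Each oracle recomputes a quantity by a different route than the library
(direct definitions, numeric optimization, Gower centring, exhaustive
enumeration) so agreement is meaningful.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar


def jsd_oracle(p: dict, q: dict) -> float:
    """Jensen-Shannon distance by direct KL-to-mixture computation."""
    support = set(p) | set(q)
    m = {t: 0.5 * (p.get(t, 0.0) + q.get(t, 0.0)) for t in support}

    def kl(a):
        return sum(a[t] * math.log2(a[t] / m[t])
                   for t in support if a.get(t, 0.0) > 0)

    return math.sqrt(0.5 * kl(p) + 0.5 * kl(q))


def frequency_score_oracle(frequencies, input_masses) -> float | None:
    """Re-fit both one-parameter models by numeric optimization."""
    f = np.asarray(frequencies, dtype=float)
    x_all = np.asarray(input_masses, dtype=float)
    mask = f > 0
    n = int(mask.sum())
    if n < 3:
        return None
    x, y = np.log(x_all[mask]), np.log(f[mask])
    ssr_c = minimize_scalar(lambda b: float(np.sum((y - (-x + b)) ** 2))).fun
    ssr_0 = minimize_scalar(lambda c: float(np.sum((y - c) ** 2))).fun
    if ssr_c < 1e-12:
        return 0.0
    if ssr_0 < 1e-12:
        return 1.0
    return float(stats.f.cdf(ssr_c / ssr_0, n - 1, n - 1))


def prevalence_score_oracle(present_pos, n_pos, present_nc, n_nc) -> float:
    """One-sided tail by explicit hypergeometric pmf summation."""
    total = n_pos + n_nc
    k = present_pos + present_nc
    num = 0.0
    for x in range(present_nc, min(k, n_nc) + 1):
        num += (math.comb(k, x) * math.comb(total - k, n_nc - x)
                / math.comb(total, n_nc))
    return num


def sweep_oracle(pairs, reads, truth, mode, grid):
    """Exhaustive threshold sweep with inline rule evaluation.

    Returns (chosen threshold, full_precision_attained).
    """
    rows = []
    for t in grid:
        tp = fp = fn = tn = 0
        for pair in pairs:
            r = reads.get(pair.taxon, 0)
            if not pair.present_in_positives:
                contam = True
            else:
                bf = pair.score_freq is not None and pair.score_freq < t
                bp = pair.score_prev is not None and pair.score_prev < t
                contam = {"frequency": bf, "prevalence": bp,
                          "either": bf or bp}[mode]
            if truth[pair.taxon]:
                tp, fn = (tp + r, fn) if contam else (tp, fn + r)
            else:
                fp, tn = (fp + r, tn) if contam else (fp, tn + r)
        recall = tp / (tp + fn) if (tp + fn) else 0.0
        precision = tp / (tp + fp) if (tp + fp) else None
        rows.append((float(t), tp, fp, precision, recall))
    perfect = [row for row in rows if row[2] == 0]
    if perfect:
        chosen = max(perfect, key=lambda row: (row[4], row[0]))
        attained = any(row[1] > 0 for row in perfect)
        return chosen[0], attained
    defined = [row for row in rows if row[3] is not None]
    chosen = max(defined, key=lambda row: (row[3], row[4], row[0]))
    return chosen[0], False


def permanova_oracle(d: np.ndarray, labels) -> tuple[float, float]:
    """Pseudo-F and R^2 via Gower centring and projection traces."""
    n = len(labels)
    a_mat = -0.5 * np.asarray(d, dtype=float) ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a_mat @ j
    uniq = sorted(set(labels), key=str)
    x = np.zeros((n, len(uniq)))
    for i, lab in enumerate(labels):
        x[i, uniq.index(lab)] = 1.0
    h = x @ np.linalg.pinv(x.T @ x) @ x.T
    ss_between = float(np.trace(h @ g @ h))
    ss_total = float(np.trace(g))
    ss_within = ss_total - ss_between
    a = len(uniq)
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between / ss_total


def permanova_exact_p_oracle(d: np.ndarray, labels) -> float:
    """Exact permutation p by enumerating every label order."""
    f_obs, _ = permanova_oracle(d, labels)
    labels = list(labels)
    count = total = 0
    for perm in itertools.permutations(range(len(labels))):
        f_perm, _ = permanova_oracle(d, [labels[i] for i in perm])
        count += f_perm >= f_obs - 1e-12
        total += 1
    return count / total


def random_abundance_profile(rng: np.random.Generator, n_taxa: int,
                             alphabet: int = 26) -> dict:
    """A random normalized profile on a random taxon subset."""
    taxa = rng.choice(alphabet, size=n_taxa, replace=False)
    w = rng.dirichlet(np.ones(n_taxa))
    return {f"t{int(t)}": float(x) for t, x in zip(taxa, w)}
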