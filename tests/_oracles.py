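"""Literal reference implementations used as independent test oracles.

Everything here is written as plain double loops over genes, samples and
pairs, with no shared code with the package, so agreement is meaningful.
"""

from __future__ import annotations

import math
import statistics

import numpy as np
from scipy import stats


def oracle_pairwise(
    values,
    exp_samples,
    base_samples,
    f_major=0.50,
    f_minor=0.30,
    thr=0.5,
    alpha=0.05,
    floor=1.0,
):
    """Brute-force pairwise selection over a pandas DataFrame.

    Returns {gene: {slr: {(i,j): v}, calls, n_increase, n_decrease,
    freq_increase, freq_decrease, mean_slr, t, p_raw, p_bonferroni,
    selected, direction, criterion, score}}.
    """
    genes = list(values.index)
    n_tested = len(genes)
    out = {}
    for g in genes:
        slr = {}
        calls = {}
        for i in exp_samples:
            for j in base_samples:
                vi = max(values.at[g, i], floor)
                vj = max(values.at[g, j], floor)
                s = math.log2(vi) - math.log2(vj)
                slr[(i, j)] = s
                if s > thr:
                    calls[(i, j)] = 1
                elif s < -thr:
                    calls[(i, j)] = -1
                else:
                    calls[(i, j)] = 0
        n_pairs = len(slr)
        n_inc = sum(1 for c in calls.values() if c == 1)
        n_dec = sum(1 for c in calls.values() if c == -1)
        vals = list(slr.values())
        mean = sum(vals) / n_pairs
        sd = statistics.stdev(vals) if n_pairs > 1 else 0.0
        if sd == 0:
            t = 0.0 if mean == 0 else math.copysign(math.inf, mean)
            p = 1.0 if mean == 0 else 0.0
        else:
            t = mean / (sd / math.sqrt(n_pairs))
            p = 2.0 * stats.t.sf(abs(t), df=n_pairs - 1)
        p_bonf = min(1.0, p * n_tested)

        def cv(samples):
            logs = [math.log2(max(values.at[g, s], floor)) for s in samples]
            m = sum(logs) / len(logs)
            s_ = statistics.stdev(logs)
            return s_ / abs(m) if m != 0 else math.inf

        more_hom = cv(exp_samples) < cv(base_samples)
        fi, fd = n_inc / n_pairs, n_dec / n_pairs
        sig = p_bonf <= alpha
        up = sig and (fi >= f_major or (fi >= f_minor and more_hom))
        down = sig and (fd >= f_major or (fd >= f_minor and more_hom))
        if up and down:
            if fi > fd:
                down = False
            elif fd > fi:
                up = False
            else:
                up = down = False
        direction = "up" if up else ("down" if down else "none")
        if up:
            criterion = "major" if fi >= f_major else "minor"
        elif down:
            criterion = "major" if fd >= f_major else "minor"
        else:
            criterion = "none"
        out[g] = {
            "slr": slr,
            "calls": calls,
            "n_increase": n_inc,
            "n_decrease": n_dec,
            "freq_increase": fi,
            "freq_decrease": fd,
            "mean_slr": mean,
            "t": t,
            "p_raw": p,
            "p_bonferroni": p_bonf,
            "selected": up or down,
            "direction": direction,
            "criterion": criterion,
            "score": mean * (n_inc + n_dec) / n_pairs,
        }
    return out


def oracle_collapse(scores: dict, mapping: dict) -> dict:
    """Group-by-max |score| with lexicographic tie-break; returns gene->probe."""
    by_gene: dict[str, list[str]] = {}
    for probe in scores:
        gene = mapping.get(probe, probe)
        by_gene.setdefault(gene, []).append(probe)
    rep = {}
    for gene, probes in by_gene.items():
        best = sorted(probes, key=lambda p: (-abs(scores[p]), p))[0]
        rep[gene] = best
    return rep


def oracle_quantile_normalize(values):
    """Rank-mean normalisation with tied ranks averaged, via explicit loops."""
    arr = np.asarray(values, dtype=float)
    n, m = arr.shape
    target = [
        sum(sorted(arr[:, j])[k] for j in range(m)) / m for k in range(n)
    ]
    out = np.empty_like(arr)
    for j in range(m):
        col = list(arr[:, j])
        order = sorted(range(n), key=lambda k: (col[k], k))
        assigned = [0.0] * n
        for pos, k in enumerate(order):
            assigned[k] = target[pos]
        for k in range(n):
            tied = [assigned[q] for q in range(n) if col[q] == col[k]]
            out[k, j] = sum(tied) / len(tied)
    return out


def oracle_pca_percent_variance(X):
    """Percent variance per component from covariance eigenvalues.

    X: samples x features, will be column-centred here.
    """
    X = np.asarray(X, dtype=float)
    X = X - X.mean(axis=0)
    cov = X.T @ X / (X.shape[0] - 1)
    eig = np.linalg.eigvalsh(cov)[::-1]
    eig = np.clip(eig, 0.0, None)
    return 100.0 * eig / eig.sum()
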