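"""Numba kernel for the missingness-aware numeric split search.

For every candidate threshold s both child assignments of missing values are
scored ("split A": x <= s or NA, versus "split B": x > s or NA), and the
weighted-Gini-minimizing candidate is returned. Two extra candidates separate
missing from observed values entirely: threshold -inf with NA routed left
(NA-only left child) and threshold max(x) with NA routed right (NA-only right
child).

Tie-breaking is by candidate order: thresholds ascending, split A before
split B, with a strict 1e-12 improvement requirement, so the kernel is
deterministic.
"""

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def best_numeric_split(v, y, min_child):
    """Best MIA split of ``v`` (float64, NaN = missing) for binary labels ``y``.

    Returns ``(found, impurity, threshold, na_left)`` where ``impurity`` is the
    weighted Gini impurity of the two children. Left child is
    ``x <= threshold`` (plus NA when ``na_left``).
    """
    n = v.shape[0]
    n_miss = 0
    miss1 = 0
    for i in range(n):
        if np.isnan(v[i]):
            n_miss += 1
            miss1 += y[i]
    n_obs = n - n_miss
    if n_obs == 0:
        return False, 0.0, 0.0, True

    vo = np.empty(n_obs)
    yo = np.empty(n_obs, dtype=np.int64)
    k = 0
    for i in range(n):
        if not np.isnan(v[i]):
            vo[k] = v[i]
            yo[k] = y[i]
            k += 1
    order = np.argsort(vo, kind="mergesort")
    vs = np.empty(n_obs)
    c1 = np.empty(n_obs + 1, dtype=np.int64)
    c1[0] = 0
    for i in range(n_obs):
        vs[i] = vo[order[i]]
        c1[i + 1] = c1[i] + yo[order[i]]
    total1 = c1[n_obs] + miss1

    best_imp = np.inf
    best_thr = 0.0
    best_na_left = True
    found = False

    # Candidates in ascending threshold order.
    n_mid = 0
    for i in range(n_obs - 1):
        if vs[i] != vs[i + 1]:
            n_mid += 1
    n_cand = n_mid + (2 if n_miss > 0 else 0)
    if n_cand == 0:
        return False, 0.0, 0.0, True

    cand_thr = np.empty(n_cand)
    cand_lc = np.empty(n_cand, dtype=np.int64)
    c = 0
    if n_miss > 0:
        cand_thr[c] = NEG_INF  # NA-only left child
        cand_lc[c] = 0
        c += 1
    for i in range(n_obs - 1):
        if vs[i] != vs[i + 1]:
            thr = 0.5 * (vs[i] + vs[i + 1])
            if thr >= vs[i + 1]:  # rounding guard: keep partition exact
                thr = vs[i]
            cand_thr[c] = thr
            cand_lc[c] = i + 1
            c += 1
    if n_miss > 0:
        cand_thr[c] = vs[n_obs - 1]  # NA-only right child (split B)
        cand_lc[c] = n_obs
        c += 1

    for ci in range(n_cand):
        lc = cand_lc[ci]
        thr = cand_thr[ci]
        for variant in range(2):  # 0 = split A (NA left), 1 = split B
            if variant == 1 and n_miss == 0:
                continue
            if variant == 0:
                nl = lc + n_miss
                l1 = c1[lc] + miss1
            else:
                nl = lc
                l1 = c1[lc]
            nr = n - nl
            r1 = total1 - l1
            if nl < min_child or nr < min_child:
                continue
            pl = l1 / nl
            pr = r1 / nr
            gl = 1.0 - pl * pl - (1.0 - pl) * (1.0 - pl)
            gr = 1.0 - pr * pr - (1.0 - pr) * (1.0 - pr)
            imp = (nl * gl + nr * gr) / n
            if imp < best_imp - 1e-12:
                best_imp = imp
                best_thr = thr
                best_na_left = variant == 0
                found = True

    return found, best_imp, best_thr, best_na_left
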