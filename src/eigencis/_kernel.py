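"""Numba kernel for the exhaustive two-step BDe parent-set search.

One call scores the observed labelling plus all permuted labellings of one
system/eigensystem.  Per labelling it (Step 1) scores every composite motif
as a singleton parent of the loading-sign node and keeps the top pool, then
(Step 2) exhaustively scores every subset of the pool of size <= 3 and
records the optimum.  Counting uses the sparse per-gene feature lists
(contingency tables of a subset follow from single/pair/triple carrier
counts by inclusion-exclusion), and the Dirichlet-multinomial terms come
from log-gamma lookup tables, so a full search over ~3e5 subsets of a
120-feature pool costs milliseconds.

The BDeu marginal likelihood of a parent set with q = 2^{#parents}
configurations and pseudocounts alpha_jc = ESS / (2 q) factorises over
configurations j as

    prod_j  Gamma(2a) / Gamma(2a + N_j) *
            Gamma(a + N_j,up) Gamma(a + N_j,down) / Gamma(a)^2,

which is `_g(size, up, down)` below with per-size lookup tables.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.special import gammaln


def make_luts(n: int, ess: float) -> tuple[np.ndarray, np.ndarray]:
    """Log-gamma tables for parent-set sizes 0..3 (q = 1, 2, 4, 8)."""
    m = np.arange(n + 1, dtype=float)
    lg_a = np.empty((4, n + 1))
    lg_t = np.empty((4, n + 1))
    for s in range(4):
        q = 2.0**s
        a = ess / (2.0 * q)
        lg_a[s] = gammaln(m + a) - gammaln(a)
        lg_t[s] = gammaln(m + 2.0 * a) - gammaln(2.0 * a)
    return lg_a, lg_t


@njit(cache=True, inline="always")
def _g(lg_a, lg_t, s, u, d):
    return lg_a[s, u] + lg_a[s, d] - lg_t[s, u + d]


@njit(cache=True)
def search_batch(
    indptr,  # int64[n+1]   CSR: gene -> universe feature ids
    findex,  # int32[nnz]   ascending within each gene
    sizes,  # int32[n_univ] composite sizes (1..3)
    c_univ,  # int64[n_univ] carrier counts (label-independent)
    labels,  # uint8[R, n]   row 0 = observed, rest = permutations
    pool_size,  # int
    max_parents,  # int (1..3)
    lg_a,
    lg_t,  # float64[4, n+1]
    ln_kappa,  # float
    pool_given,  # int32[*] ascending; used for every row when use_given
    use_given,  # bool
    topk,  # int: size of the ranked list kept for row 0
):
    R, n = labels.shape
    n_univ = c_univ.shape[0]

    if use_given:
        P = pool_given.shape[0]
    else:
        P = min(pool_size, n_univ)

    # offsets for flat pair / triple indexing over the pool
    off2 = np.zeros(P, dtype=np.int64)
    for i in range(1, P):
        off2[i] = off2[i - 1] + (P - i)
    n2 = P * (P - 1) // 2
    off3 = np.zeros(P, dtype=np.int64)
    for i in range(1, P):
        rem = P - i  # elements after i-1
        off3[i] = off3[i - 1] + rem * (rem - 1) // 2
    n3 = P * (P - 1) * (P - 2) // 6

    cu = np.zeros(n_univ, dtype=np.int64)
    s1 = np.zeros(n_univ, dtype=np.float64)
    pool = np.zeros(P, dtype=np.int32)
    pool_pos = np.full(n_univ, -1, dtype=np.int32)
    cnt2 = np.zeros(n2, dtype=np.int32)
    up2 = np.zeros(n2, dtype=np.int32)
    cnt3 = np.zeros(n3, dtype=np.int32)
    up3 = np.zeros(n3, dtype=np.int32)
    buf = np.zeros(max(P, 1), dtype=np.int64)

    best_scores = np.zeros(R, dtype=np.float64)
    top_scores = np.full(topk, -np.inf, dtype=np.float64)
    top_sets = np.full((topk, 3), -1, dtype=np.int32)
    pool0 = np.zeros(P, dtype=np.int32)
    s1_obs = np.zeros(n_univ, dtype=np.float64)

    for r in range(R):
        n_up = 0
        for g in range(n):
            n_up += labels[r, g]
        n_dn = n - n_up
        lme = _g(lg_a, lg_t, 0, n_up, n_dn)

        # ---- Step 1: singleton scores over the whole universe
        for f in range(n_univ):
            cu[f] = 0
        for g in range(n):
            if labels[r, g] == 1:
                for t in range(indptr[g], indptr[g + 1]):
                    cu[findex[t]] += 1
        for f in range(n_univ):
            cf = c_univ[f]
            cuf = cu[f]
            lml = _g(lg_a, lg_t, 1, cuf, cf - cuf) + _g(
                lg_a, lg_t, 1, n_up - cuf, n_dn - (cf - cuf)
            )
            s1[f] = lml + sizes[f] * ln_kappa - lme
        if r == 0:
            for f in range(n_univ):
                s1_obs[f] = s1[f]

        # ---- pool: top-P singletons (score desc, universe index asc)
        if use_given:
            for i in range(P):
                pool[i] = pool_given[i]
        else:
            tmp = np.sort(s1)  # ascending
            thresh = tmp[n_univ - P]
            m = 0
            for f in range(n_univ):
                if s1[f] > thresh:
                    pool[m] = f
                    m += 1
            for f in range(n_univ):
                if m >= P:
                    break
                if s1[f] == thresh:
                    pool[m] = f
                    m += 1
            pool[:P] = np.sort(pool[:P])
        for f in range(n_univ):
            pool_pos[f] = -1
        for i in range(P):
            pool_pos[pool[i]] = i
        if r == 0:
            for i in range(P):
                pool0[i] = pool[i]

        # ---- best over subsets; empty set scores 0 by definition
        best = 0.0
        b0 = -1
        b1 = -1
        b2 = -1
        for i in range(P):
            sc = s1[pool[i]]
            if sc > best:
                best = sc
                b0, b1, b2 = i, -1, -1
            if r == 0 and sc > top_scores[topk - 1]:
                _insert_top(top_scores, top_sets, sc, i, -1, -1)

        do_pairs = max_parents >= 2 and P >= 2
        do_triples = max_parents >= 3 and P >= 3

        if do_pairs:
            for x in range(n2):
                cnt2[x] = 0
                up2[x] = 0
            if do_triples:
                for x in range(n3):
                    cnt3[x] = 0
                    up3[x] = 0
            # sparse counting of pair / triple co-carriers
            for g in range(n):
                m = 0
                for t in range(indptr[g], indptr[g + 1]):
                    p = pool_pos[findex[t]]
                    if p >= 0:
                        buf[m] = p
                        m += 1
                if m < 2:
                    continue
                lab = labels[r, g]
                for a in range(m):
                    ia = buf[a]
                    mi = P - ia - 1
                    for b in range(a + 1, m):
                        ib = buf[b]
                        p2 = off2[ia] + ib - ia - 1
                        cnt2[p2] += 1
                        up2[p2] += lab
                        if do_triples and b + 1 < m:
                            aa = ib - ia - 1
                            t3base = (
                                off3[ia]
                                + aa * mi
                                - (aa * (aa + 1)) // 2
                                - ia
                                - aa
                                - 2
                            )
                            for c in range(b + 1, m):
                                p3 = t3base + buf[c]
                                cnt3[p3] += 1
                                up3[p3] += lab

            # ---- pair scores
            for i in range(P):
                fi = pool[i]
                ci = c_univ[fi]
                cui = cu[fi]
                szi = sizes[fi]
                for j in range(i + 1, P):
                    fj = pool[j]
                    p2 = off2[i] + j - i - 1
                    cij = cnt2[p2]
                    uij = up2[p2]
                    cj = c_univ[fj]
                    cuj = cu[fj]
                    u10 = cui - uij
                    u01 = cuj - uij
                    u00 = n_up - cui - cuj + uij
                    t10 = ci - cij
                    t01 = cj - cij
                    t00 = n - ci - cj + cij
                    lml = (
                        _g(lg_a, lg_t, 2, uij, cij - uij)
                        + _g(lg_a, lg_t, 2, u10, t10 - u10)
                        + _g(lg_a, lg_t, 2, u01, t01 - u01)
                        + _g(lg_a, lg_t, 2, u00, t00 - u00)
                    )
                    sc = lml + (szi + sizes[fj]) * ln_kappa - lme
                    if sc > best:
                        best = sc
                        b0, b1, b2 = i, j, -1
                    if r == 0 and sc > top_scores[topk - 1]:
                        _insert_top(top_scores, top_sets, sc, i, j, -1)

            # ---- triple scores
            if do_triples:
                t3 = 0
                for i in range(P):
                    fi = pool[i]
                    ci = c_univ[fi]
                    cui = cu[fi]
                    szi = sizes[fi]
                    for j in range(i + 1, P):
                        fj = pool[j]
                        cj = c_univ[fj]
                        cuj = cu[fj]
                        p_ij = off2[i] + j - i - 1
                        cij = cnt2[p_ij]
                        uij = up2[p_ij]
                        szij = szi + sizes[fj]
                        for k in range(j + 1, P):
                            fk = pool[k]
                            ck = c_univ[fk]
                            cuk = cu[fk]
                            p_ik = off2[i] + k - i - 1
                            p_jk = off2[j] + k - j - 1
                            cik = cnt2[p_ik]
                            uik = up2[p_ik]
                            cjk = cnt2[p_jk]
                            ujk = up2[p_jk]
                            c111 = cnt3[t3]
                            u111 = up3[t3]
                            t3 += 1
                            # inclusion-exclusion for the 8 configurations
                            c110 = cij - c111
                            c101 = cik - c111
                            c011 = cjk - c111
                            c100 = ci - cij - cik + c111
                            c010 = cj - cij - cjk + c111
                            c001 = ck - cik - cjk + c111
                            c000 = n - ci - cj - ck + cij + cik + cjk - c111
                            u110 = uij - u111
                            u101 = uik - u111
                            u011 = ujk - u111
                            u100 = cui - uij - uik + u111
                            u010 = cuj - uij - ujk + u111
                            u001 = cuk - uik - ujk + u111
                            u000 = n_up - cui - cuj - cuk + uij + uik + ujk - u111
                            lml = (
                                _g(lg_a, lg_t, 3, u111, c111 - u111)
                                + _g(lg_a, lg_t, 3, u110, c110 - u110)
                                + _g(lg_a, lg_t, 3, u101, c101 - u101)
                                + _g(lg_a, lg_t, 3, u011, c011 - u011)
                                + _g(lg_a, lg_t, 3, u100, c100 - u100)
                                + _g(lg_a, lg_t, 3, u010, c010 - u010)
                                + _g(lg_a, lg_t, 3, u001, c001 - u001)
                                + _g(lg_a, lg_t, 3, u000, c000 - u000)
                            )
                            sc = lml + (szij + sizes[fk]) * ln_kappa - lme
                            if sc > best:
                                best = sc
                                b0, b1, b2 = i, j, k
                            if r == 0 and sc > top_scores[topk - 1]:
                                _insert_top(top_scores, top_sets, sc, i, j, k)

        best_scores[r] = best

    return best_scores, top_scores, top_sets, pool0, s1_obs


@njit(cache=True, inline="always")
def _insert_top(top_scores, top_sets, sc, i, j, k):
    kk = top_scores.shape[0] - 1
    while kk > 0 and top_scores[kk - 1] < sc:
        top_scores[kk] = top_scores[kk - 1]
        top_sets[kk, 0] = top_sets[kk - 1, 0]
        top_sets[kk, 1] = top_sets[kk - 1, 1]
        top_sets[kk, 2] = top_sets[kk - 1, 2]
        kk -= 1
    top_scores[kk] = sc
    top_sets[kk, 0] = i
    top_sets[kk, 1] = j
    top_sets[kk, 2] = k
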