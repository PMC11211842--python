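"""Numba kernels for likelihood and parsimony computations.

Layouts (shared with :mod:`inference`):

* conditional likelihood vectors (CLVs): ``float64[n_nodes, P, C, 4]``
  with per-node per-pattern log-scale accumulators ``float64[n_nodes, P]``
  (P = compressed site patterns, C = rate categories);
* tip states: ``uint8[n_leaves, P]`` with 0..3 = ACGT and 4 = ambiguous;
* transition matrices from the frequency-symmetrized eigendecomposition
  ``P(t) = V exp(lam * r * t) Vinv``.

The "down" CLV of a node is the likelihood of the data below it given its
state; the "up" vector of a node x is the likelihood of everything outside
x's subtree given the state at x's parent, with the stationary prior
folded in at the root, so the product across any edge yields the full tree
likelihood.
"""

import numpy as np
from numba import njit

MIN_BLEN = 1e-8
MAX_BLEN = 8.0


# ---------------------------------------------------------------------------
# small helpers
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _pmat(V, Vinv, lam, rt, out):
    """out = V @ diag(exp(lam*rt)) @ Vinv."""
    e0 = np.exp(lam[0] * rt)
    e1 = np.exp(lam[1] * rt)
    e2 = np.exp(lam[2] * rt)
    e3 = np.exp(lam[3] * rt)
    for i in range(4):
        vi0 = V[i, 0] * e0
        vi1 = V[i, 1] * e1
        vi2 = V[i, 2] * e2
        vi3 = V[i, 3] * e3
        for j in range(4):
            out[i, j] = (
                vi0 * Vinv[0, j] + vi1 * Vinv[1, j] + vi2 * Vinv[2, j] + vi3 * Vinv[3, j]
            )


@njit(cache=True, fastmath=True)
def _build_pmats(V, Vinv, lam, crates, t, out):
    """out[c] = P(t * crates[c]) for each category."""
    for c in range(crates.shape[0]):
        _pmat(V, Vinv, lam, crates[c] * t, out[c])


# ---------------------------------------------------------------------------
# CLV passes
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def down_pass(
    order, child1, child2, blen, tip, nleaves, V, Vinv, lam, crates, clv, lsc
):
    """Fill down-CLVs for the internal nodes listed in ``order``
    (children-first; may include the root as the last entry)."""
    P = tip.shape[1]
    C = crates.shape[0]
    P1 = np.empty((C, 4, 4))
    P2 = np.empty((C, 4, 4))
    for oi in range(order.shape[0]):
        u = order[oi]
        c1 = child1[u]
        c2 = child2[u]
        _build_pmats(V, Vinv, lam, crates, blen[c1], P1)
        _build_pmats(V, Vinv, lam, crates, blen[c2], P2)
        leaf1 = c1 < nleaves
        leaf2 = c2 < nleaves
        for p in range(P):
            m = 0.0
            for c in range(C):
                for i in range(4):
                    if leaf1:
                        k = tip[c1, p]
                        s1 = P1[c, i, k] if k < 4 else 1.0
                    else:
                        s1 = (
                            P1[c, i, 0] * clv[c1, p, c, 0]
                            + P1[c, i, 1] * clv[c1, p, c, 1]
                            + P1[c, i, 2] * clv[c1, p, c, 2]
                            + P1[c, i, 3] * clv[c1, p, c, 3]
                        )
                    if leaf2:
                        k = tip[c2, p]
                        s2 = P2[c, i, k] if k < 4 else 1.0
                    else:
                        s2 = (
                            P2[c, i, 0] * clv[c2, p, c, 0]
                            + P2[c, i, 1] * clv[c2, p, c, 1]
                            + P2[c, i, 2] * clv[c2, p, c, 2]
                            + P2[c, i, 3] * clv[c2, p, c, 3]
                        )
                    v = s1 * s2
                    clv[u, p, c, i] = v
                    if v > m:
                        m = v
            ls = 0.0
            if not leaf1:
                ls += lsc[c1, p]
            if not leaf2:
                ls += lsc[c2, p]
            if m > 0.0:
                inv = 1.0 / m
                for c in range(C):
                    for i in range(4):
                        clv[u, p, c, i] *= inv
                ls += np.log(m)
            lsc[u, p] = ls


@njit(cache=True, fastmath=True)
def up_pass(
    pre,
    parent,
    child1,
    child2,
    blen,
    tip,
    nleaves,
    freqs,
    root,
    V,
    Vinv,
    lam,
    crates,
    clv,
    lsc,
    uvec,
    ulsc,
):
    """Fill up-vectors for the internal nodes in ``pre`` (parents before
    children, root and leaf 0 excluded); leaf up-vectors are never
    consumed and are skipped."""
    P = tip.shape[1]
    C = crates.shape[0]
    Ps = np.empty((C, 4, 4))
    Pp = np.empty((C, 4, 4))
    for oi in range(pre.shape[0]):
        x = pre[oi]
        if child1[x] < 0:
            continue
        p = parent[x]
        if p == root:
            # complement of x's subtree is leaf 0 at zero distance
            for ptn in range(P):
                k = tip[0, ptn]
                for c in range(C):
                    for j in range(4):
                        if k < 4:
                            uvec[x, ptn, c, j] = freqs[j] if j == k else 0.0
                        else:
                            uvec[x, ptn, c, j] = freqs[j]
                ulsc[x, ptn] = 0.0
            continue
        sib = child1[p] if child2[p] == x else child2[p]
        _build_pmats(V, Vinv, lam, crates, blen[sib], Ps)
        _build_pmats(V, Vinv, lam, crates, blen[p], Pp)
        sleaf = sib < nleaves
        for ptn in range(P):
            m = 0.0
            for c in range(C):
                for j in range(4):
                    if sleaf:
                        k = tip[sib, ptn]
                        s = Ps[c, j, k] if k < 4 else 1.0
                    else:
                        s = (
                            Ps[c, j, 0] * clv[sib, ptn, c, 0]
                            + Ps[c, j, 1] * clv[sib, ptn, c, 1]
                            + Ps[c, j, 2] * clv[sib, ptn, c, 2]
                            + Ps[c, j, 3] * clv[sib, ptn, c, 3]
                        )
                    # time-reversed transition along p's own edge
                    t = (
                        Pp[c, 0, j] * uvec[p, ptn, c, 0]
                        + Pp[c, 1, j] * uvec[p, ptn, c, 1]
                        + Pp[c, 2, j] * uvec[p, ptn, c, 2]
                        + Pp[c, 3, j] * uvec[p, ptn, c, 3]
                    )
                    v = s * t
                    uvec[x, ptn, c, j] = v
                    if v > m:
                        m = v
            ls = ulsc[p, ptn]
            if not sleaf:
                ls += lsc[sib, ptn]
            if m > 0.0:
                inv = 1.0 / m
                for c in range(C):
                    for j in range(4):
                        uvec[x, ptn, c, j] *= inv
                ls += np.log(m)
            ulsc[x, ptn] = ls


@njit(cache=True, fastmath=True)
def root_loglik(clv_root, lsc_root, freqs, w, pinv, linv):
    """Full log-likelihood from the root CLV (Gamma/I mixture)."""
    P = clv_root.shape[0]
    C = clv_root.shape[1]
    total = 0.0
    for p in range(P):
        s = 0.0
        for c in range(C):
            for i in range(4):
                s += freqs[i] * clv_root[p, c, i]
        s *= (1.0 - pinv) / C
        if s < 1e-300:
            s = 1e-300
        if pinv > 0.0:
            a = np.log(s) + lsc_root[p]
            b = np.log(pinv * linv[p] + 1e-300)
            hi = a if a > b else b
            total += w[p] * (hi + np.log(np.exp(a - hi) + np.exp(b - hi)))
        else:
            total += w[p] * (np.log(s) + lsc_root[p])
    return total


# ---------------------------------------------------------------------------
# edge-wise likelihood in the eigenbasis (for branch-length optimization)
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def edge_profile(Y, lsY, X, lsX, V, Vinv, Z, ls):
    """Z[p,c,k] = (Y V)[k] * (Vinv X)[k]; ls = lsY + lsX.

    Along the edge, sum_j Y_j P(t)_{j,i} X_i = sum_k Z_k exp(lam_k r t).
    """
    P = Y.shape[0]
    C = Y.shape[1]
    for p in range(P):
        for c in range(C):
            for k in range(4):
                yt = (
                    Y[p, c, 0] * V[0, k]
                    + Y[p, c, 1] * V[1, k]
                    + Y[p, c, 2] * V[2, k]
                    + Y[p, c, 3] * V[3, k]
                )
                xt = (
                    Vinv[k, 0] * X[p, c, 0]
                    + Vinv[k, 1] * X[p, c, 1]
                    + Vinv[k, 2] * X[p, c, 2]
                    + Vinv[k, 3] * X[p, c, 3]
                )
                Z[p, c, k] = yt * xt
        ls[p] = lsY[p] + lsX[p]


@njit(cache=True, fastmath=True)
def edge_loglik(Z, ls, w, lam, crates, pinv, linv, t):
    P = Z.shape[0]
    C = Z.shape[1]
    ex = np.empty((C, 4))
    for c in range(C):
        for k in range(4):
            ex[c, k] = np.exp(lam[k] * crates[c] * t)
    total = 0.0
    for p in range(P):
        s = 0.0
        for c in range(C):
            s += (
                Z[p, c, 0] * ex[c, 0]
                + Z[p, c, 1] * ex[c, 1]
                + Z[p, c, 2] * ex[c, 2]
                + Z[p, c, 3] * ex[c, 3]
            )
        s *= (1.0 - pinv) / C
        if s < 1e-300:
            s = 1e-300
        if pinv > 0.0:
            a = np.log(s) + ls[p]
            b = np.log(pinv * linv[p] + 1e-300)
            hi = a if a > b else b
            total += w[p] * (hi + np.log(np.exp(a - hi) + np.exp(b - hi)))
        else:
            total += w[p] * (np.log(s) + ls[p])
    return total


@njit(cache=True, fastmath=True)
def _edge_derivs(Z, ls, w, lam, crates, pinv, linv, t):
    """(loglik, d loglik/dt, d2 loglik/dt2) of the edge profile at t."""
    P = Z.shape[0]
    C = Z.shape[1]
    ex = np.empty((C, 4))
    lr = np.empty((C, 4))
    for c in range(C):
        for k in range(4):
            r = lam[k] * crates[c]
            lr[c, k] = r
            ex[c, k] = np.exp(r * t)
    alpha = (1.0 - pinv) / C
    ll = 0.0
    g1 = 0.0
    g2 = 0.0
    for p in range(P):
        s = 0.0
        s1 = 0.0
        s2 = 0.0
        for c in range(C):
            for k in range(4):
                v = Z[p, c, k] * ex[c, k]
                s += v
                rv = lr[c, k] * v
                s1 += rv
                s2 += lr[c, k] * rv
        if s < 1e-300:
            s = 1e-300
        la = np.log(alpha * s) + ls[p]
        if pinv > 0.0 and linv[p] > 0.0:
            lb = np.log(pinv * linv[p])
            hi_ = la if la > lb else lb
            lf = hi_ + np.log(np.exp(la - hi_) + np.exp(lb - hi_))
            q = 1.0 / (1.0 + np.exp(lb - la))
        else:
            lf = la
            q = 1.0
        r1 = s1 / s
        r2 = s2 / s
        ll += w[p] * lf
        g1 += w[p] * q * r1
        g2 += w[p] * (q * r2 - q * q * r1 * r1)
    return ll, g1, g2


@njit(cache=True, fastmath=True)
def brent_edge(Z, ls, w, lam, crates, pinv, linv, lo, hi, xtol, t0):
    """Bounded maximization of the edge log-likelihood over t.

    Safeguarded Newton on the analytic derivatives (bisection fallback on
    a sign-change bracket); never returns a point worse than the start.
    """
    t = t0
    if t < lo:
        t = lo
    if t > hi:
        t = hi
    ll0, g1, g2 = _edge_derivs(Z, ls, w, lam, crates, pinv, linv, t)
    a = lo
    b = hi
    best_t = t
    best_ll = ll0
    prev_ll = ll0
    for _ in range(25):
        if abs(g1) < 1e-8:
            break
        if g1 > 0.0:
            a = t
        else:
            b = t
        if b - a < xtol * b + 1e-8:
            break
        if g2 < 0.0:
            tn = t - g1 / g2
        else:
            tn = -1.0
        if not (a < tn < b):
            tn = 0.5 * (a + b)
        last = abs(tn - t) < xtol * t + 1e-9
        t = tn
        ll, g1, g2 = _edge_derivs(Z, ls, w, lam, crates, pinv, linv, t)
        if ll > best_ll:
            best_ll = ll
            best_t = t
        # flat likelihood (e.g. a saturated branch): stop early
        if last or abs(ll - prev_ll) < 1e-6:
            break
        prev_ll = ll
    return best_t, best_ll


# ---------------------------------------------------------------------------
# local message algebra (for quartet / local-5 optimization)
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _apply_P(msg, Pm, out):
    """out[p,c,i] = sum_j Pm[c,i,j] msg[p,c,j]."""
    P = msg.shape[0]
    C = msg.shape[1]
    for p in range(P):
        for c in range(C):
            for i in range(4):
                out[p, c, i] = (
                    Pm[c, i, 0] * msg[p, c, 0]
                    + Pm[c, i, 1] * msg[p, c, 1]
                    + Pm[c, i, 2] * msg[p, c, 2]
                    + Pm[c, i, 3] * msg[p, c, 3]
                )


@njit(cache=True, fastmath=True)
def _apply_PT(msg, Pm, out):
    """out[p,c,j] = sum_i Pm[c,i,j] msg[p,c,i] (time-reversed)."""
    P = msg.shape[0]
    C = msg.shape[1]
    for p in range(P):
        for c in range(C):
            for j in range(4):
                out[p, c, j] = (
                    Pm[c, 0, j] * msg[p, c, 0]
                    + Pm[c, 1, j] * msg[p, c, 1]
                    + Pm[c, 2, j] * msg[p, c, 2]
                    + Pm[c, 3, j] * msg[p, c, 3]
                )


@njit(cache=True, fastmath=True)
def _hadamard(x, y, out):
    P = x.shape[0]
    C = x.shape[1]
    for p in range(P):
        for c in range(C):
            for i in range(4):
                out[p, c, i] = x[p, c, i] * y[p, c, i]


@njit(cache=True, fastmath=True)
def quartet_optimize(
    A,
    lsA,
    B,
    lsB,
    Cm,
    lsC,
    U,
    lsU,
    t,
    V,
    Vinv,
    lam,
    crates,
    w,
    pinv,
    linv,
    nsweeps,
    xtol,
    ws,
    lsws,
):
    """Coordinate-ascent optimization of the 5 branch lengths around an
    internal edge with fixed peripheral messages.

    Local system: node x joins subtrees A (edge t[0]) and B (t[1]); its
    parent p joins sibling C (t[2]) and the rest of the tree through U
    (t[3], time-reversed); t[4] is the central edge x--p.  ``t`` is
    updated in place; returns the final log-likelihood.  ``ws`` is a
    reusable (6, P, C, 4) scratch buffer and ``lsws`` a (3, P) one.
    """
    P = A.shape[0]
    C = A.shape[1]
    Pa = np.empty((C, 4, 4))
    Pb = np.empty((C, 4, 4))
    Pc = np.empty((C, 4, 4))
    Pd = np.empty((C, 4, 4))
    Pe = np.empty((C, 4, 4))
    tmp1 = ws[0]
    tmp2 = ws[1]
    tmp3 = ws[2]
    X = ws[3]
    Y = ws[4]
    Z = ws[5]
    lsZ = lsws[0]
    lsX = lsws[1]
    lsY = lsws[2]
    if nsweeps == 0:
        # fast mode: optimize only the central branch
        _build_pmats(V, Vinv, lam, crates, t[0], Pa)
        _build_pmats(V, Vinv, lam, crates, t[1], Pb)
        _build_pmats(V, Vinv, lam, crates, t[2], Pc)
        _build_pmats(V, Vinv, lam, crates, t[3], Pd)
        _apply_P(A, Pa, tmp1)
        _apply_P(B, Pb, tmp2)
        _hadamard(tmp1, tmp2, X)
        _apply_P(Cm, Pc, tmp1)
        _apply_PT(U, Pd, tmp2)
        _hadamard(tmp1, tmp2, Y)
        for p in range(P):
            lsX[p] = lsA[p] + lsB[p]
            lsY[p] = lsC[p] + lsU[p]
        edge_profile(Y, lsY, X, lsX, V, Vinv, Z, lsZ)
        t4, ll = brent_edge(
            Z, lsZ, w, lam, crates, pinv, linv, MIN_BLEN, MAX_BLEN, xtol, t[4]
        )
        t[4] = t4
        return ll
    ll = -1e300
    for sweep in range(nsweeps):
        prev = ll
        # ---- center edge t[4]
        _build_pmats(V, Vinv, lam, crates, t[0], Pa)
        _build_pmats(V, Vinv, lam, crates, t[1], Pb)
        _build_pmats(V, Vinv, lam, crates, t[2], Pc)
        _build_pmats(V, Vinv, lam, crates, t[3], Pd)
        _apply_P(A, Pa, tmp1)
        _apply_P(B, Pb, tmp2)
        _hadamard(tmp1, tmp2, X)
        for p in range(P):
            lsX[p] = lsA[p] + lsB[p]
        _apply_P(Cm, Pc, tmp1)
        _apply_PT(U, Pd, tmp2)
        _hadamard(tmp1, tmp2, Y)
        for p in range(P):
            lsY[p] = lsC[p] + lsU[p]
        edge_profile(Y, lsY, X, lsX, V, Vinv, Z, lsZ)
        t4, ll = brent_edge(
            Z, lsZ, w, lam, crates, pinv, linv, MIN_BLEN, MAX_BLEN, xtol, t[4]
        )
        t[4] = t4
        _build_pmats(V, Vinv, lam, crates, t[4], Pe)
        # ---- edge a (t[0]): rest = (Pb B) o (Pe^T Y)
        _apply_PT(Y, Pe, tmp1)
        _apply_P(B, Pb, tmp2)
        _hadamard(tmp1, tmp2, tmp3)
        for p in range(P):
            lsX[p] = lsY[p] + lsB[p]
        edge_profile(tmp3, lsX, A, lsA, V, Vinv, Z, lsZ)
        t0, ll = brent_edge(
            Z, lsZ, w, lam, crates, pinv, linv, MIN_BLEN, MAX_BLEN, xtol, t[0]
        )
        t[0] = t0
        _build_pmats(V, Vinv, lam, crates, t[0], Pa)
        # ---- edge b (t[1])
        _apply_PT(Y, Pe, tmp1)
        _apply_P(A, Pa, tmp2)
        _hadamard(tmp1, tmp2, tmp3)
        for p in range(P):
            lsX[p] = lsY[p] + lsA[p]
        edge_profile(tmp3, lsX, B, lsB, V, Vinv, Z, lsZ)
        t1, ll = brent_edge(
            Z, lsZ, w, lam, crates, pinv, linv, MIN_BLEN, MAX_BLEN, xtol, t[1]
        )
        t[1] = t1
        _build_pmats(V, Vinv, lam, crates, t[1], Pb)
        # rebuild X with updated a, b
        _apply_P(A, Pa, tmp1)
        _apply_P(B, Pb, tmp2)
        _hadamard(tmp1, tmp2, X)
        for p in range(P):
            lsX[p] = lsA[p] + lsB[p]
        # ---- edge c (t[2]): rest at p = (Pd^T U) o (Pe X)
        _apply_PT(U, Pd, tmp1)
        _apply_P(X, Pe, tmp2)
        _hadamard(tmp1, tmp2, tmp3)
        for p in range(P):
            lsY[p] = lsU[p] + lsX[p]
        edge_profile(tmp3, lsY, Cm, lsC, V, Vinv, Z, lsZ)
        t2, ll = brent_edge(
            Z, lsZ, w, lam, crates, pinv, linv, MIN_BLEN, MAX_BLEN, xtol, t[2]
        )
        t[2] = t2
        _build_pmats(V, Vinv, lam, crates, t[2], Pc)
        # ---- edge d (t[3]): below-at-p = (Pc C) o (Pe X); Y side = U
        _apply_P(Cm, Pc, tmp1)
        _apply_P(X, Pe, tmp2)
        _hadamard(tmp1, tmp2, tmp3)
        for p in range(P):
            lsY[p] = lsC[p] + lsX[p]
        edge_profile(U, lsU, tmp3, lsY, V, Vinv, Z, lsZ)
        t3, ll = brent_edge(
            Z, lsZ, w, lam, crates, pinv, linv, MIN_BLEN, MAX_BLEN, xtol, t[3]
        )
        t[3] = t3
        _build_pmats(V, Vinv, lam, crates, t[3], Pd)
        if ll - prev < 1e-4 and sweep > 0:
            break
    return ll


@njit(cache=True, fastmath=True)
def _refresh_down(u, child1, child2, blen, V, Vinv, lam, crates, clv, lsc, P1, P2):
    """Recompute one node's down-CLV from its children's CLVs (leaf rows
    are prefilled tip indicators with zero log-scale)."""
    P = clv.shape[1]
    C = crates.shape[0]
    c1 = child1[u]
    c2 = child2[u]
    _build_pmats(V, Vinv, lam, crates, blen[c1], P1)
    _build_pmats(V, Vinv, lam, crates, blen[c2], P2)
    for p in range(P):
        m = 0.0
        for c in range(C):
            for i in range(4):
                s1 = (
                    P1[c, i, 0] * clv[c1, p, c, 0]
                    + P1[c, i, 1] * clv[c1, p, c, 1]
                    + P1[c, i, 2] * clv[c1, p, c, 2]
                    + P1[c, i, 3] * clv[c1, p, c, 3]
                )
                s2 = (
                    P2[c, i, 0] * clv[c2, p, c, 0]
                    + P2[c, i, 1] * clv[c2, p, c, 1]
                    + P2[c, i, 2] * clv[c2, p, c, 2]
                    + P2[c, i, 3] * clv[c2, p, c, 3]
                )
                v = s1 * s2
                clv[u, p, c, i] = v
                if v > m:
                    m = v
        ls = lsc[c1, p] + lsc[c2, p]
        if m > 0.0:
            inv = 1.0 / m
            for c in range(C):
                for i in range(4):
                    clv[u, p, c, i] *= inv
            ls += np.log(m)
        lsc[u, p] = ls


@njit(cache=True, fastmath=True)
def sweep_branch_lengths(
    vstart,
    parent,
    child1,
    child2,
    blen,
    clv,
    lsc,
    uvec,
    ulsc,
    V,
    Vinv,
    lam,
    crates,
    w,
    pinv,
    linv,
    xtol,
):
    """One depth-first branch-length optimization sweep.

    ``uvec[vstart]``/``ulsc[vstart]`` must hold the prior-laden up-message
    for the start edge.  Each edge is optimized against exact conditional
    likelihoods for the current parameter values; down-CLVs are refreshed
    on the way back up, so every 1-D step is an exact ascent.  Up-messages
    written below ``vstart`` are scratch and stale on return.
    """
    N = parent.shape[0]
    P = clv.shape[1]
    C = crates.shape[0]
    Z = np.empty((P, C, 4))
    lsZ = np.empty(P)
    tmp1 = np.empty((P, C, 4))
    urev = np.empty((P, C, 4))
    Pm1 = np.empty((C, 4, 4))
    Pm2 = np.empty((C, 4, 4))
    stack_node = np.empty(3 * N + 8, dtype=np.int32)
    stack_state = np.empty(3 * N + 8, dtype=np.int32)
    top = 0
    stack_node[top] = vstart
    stack_state[top] = 0
    top += 1
    while top > 0:
        top -= 1
        x = stack_node[top]
        state = stack_state[top]
        if state == 0:
            # optimize edge above x
            edge_profile(uvec[x], ulsc[x], clv[x], lsc[x], V, Vinv, Z, lsZ)
            t, _ = brent_edge(
                Z, lsZ, w, lam, crates, pinv, linv, MIN_BLEN, MAX_BLEN, xtol, blen[x]
            )
            blen[x] = t
            if child1[x] < 0:
                continue
            c1 = child1[x]
            c2 = child2[x]
            # U[c1] = (P_{c2} down[c2]) o (P_x^T U[x])
            _build_pmats(V, Vinv, lam, crates, blen[x], Pm1)
            _apply_PT(uvec[x], Pm1, urev)
            _build_pmats(V, Vinv, lam, crates, blen[c2], Pm2)
            _apply_P(clv[c2], Pm2, tmp1)
            _hadamard(tmp1, urev, uvec[c1])
            for p in range(P):
                ulsc[c1, p] = lsc[c2, p] + ulsc[x, p]
            stack_node[top] = x
            stack_state[top] = 1
            top += 1
            stack_node[top] = c1
            stack_state[top] = 0
            top += 1
        elif state == 1:
            # first child done (its subtree refreshed); build U[c2]
            c1 = child1[x]
            c2 = child2[x]
            _build_pmats(V, Vinv, lam, crates, blen[x], Pm1)
            _apply_PT(uvec[x], Pm1, urev)
            _build_pmats(V, Vinv, lam, crates, blen[c1], Pm2)
            _apply_P(clv[c1], Pm2, tmp1)
            _hadamard(tmp1, urev, uvec[c2])
            for p in range(P):
                ulsc[c2, p] = lsc[c1, p] + ulsc[x, p]
            stack_node[top] = x
            stack_state[top] = 2
            top += 1
            stack_node[top] = c2
            stack_state[top] = 0
            top += 1
        else:
            _refresh_down(
                x, child1, child2, blen, V, Vinv, lam, crates, clv, lsc, Pm1, Pm2
            )


@njit(cache=True, fastmath=True)
def scan_nnis(
    edges,
    parent,
    child1,
    child2,
    blen,
    clv,
    lsc,
    uvec,
    ulsc,
    V,
    Vinv,
    lam,
    crates,
    w,
    pinv,
    linv,
    ll,
    margin,
    nsweeps,
    ws,
    lsws,
    gains,
    whichs,
    t5out,
):
    """Score both NNI swaps around every internal edge.

    mode ``nsweeps`` >= 1: central-branch prefilter at ``margin`` below
    the current likelihood, then ``nsweeps`` local-5 sweeps for survivors;
    per edge the better swap's (gain, which, optimized lengths) are
    written to the output arrays (gain = -inf when nothing competitive).
    ``nsweeps`` = -2 computes both swaps with 2 full sweeps and stores
    their likelihoods in t5out[:, 0:2] (for NNI feature differences).
    """
    E = edges.shape[0]
    t5 = np.empty(5)
    for ei in range(E):
        x = edges[ei]
        p = parent[x]
        c1 = child1[x]
        c2 = child2[x]
        sib = child1[p] if child2[p] == x else child2[p]
        best_gain = -1e300
        best_which = -1
        for wi in range(2):
            if wi == 0:
                which = 1
                a_, b_, c_ = c1, sib, c2
                t5[0] = blen[c1]
                t5[1] = blen[sib]
                t5[2] = blen[c2]
            else:
                which = 0
                a_, b_, c_ = c2, sib, c1
                t5[0] = blen[c2]
                t5[1] = blen[sib]
                t5[2] = blen[c1]
            t5[3] = blen[p]
            t5[4] = blen[x]
            if nsweeps >= 1:
                quick = quartet_optimize(
                    clv[a_], lsc[a_], clv[b_], lsc[b_], clv[c_], lsc[c_],
                    uvec[p], ulsc[p], t5,
                    V, Vinv, lam, crates, w, pinv, linv, 0, 1e-4, ws, lsws,
                )
                if quick < ll - margin:
                    continue
                cand = quartet_optimize(
                    clv[a_], lsc[a_], clv[b_], lsc[b_], clv[c_], lsc[c_],
                    uvec[p], ulsc[p], t5,
                    V, Vinv, lam, crates, w, pinv, linv, nsweeps, 1e-4, ws, lsws,
                )
                gain = cand - ll
                if gain > best_gain:
                    best_gain = gain
                    best_which = which
                    for k in range(5):
                        t5out[ei, k] = t5[k]
            else:
                cand = quartet_optimize(
                    clv[a_], lsc[a_], clv[b_], lsc[b_], clv[c_], lsc[c_],
                    uvec[p], ulsc[p], t5,
                    V, Vinv, lam, crates, w, pinv, linv, 2, 1e-5, ws, lsws,
                )
                t5out[ei, wi] = cand
        gains[ei] = best_gain
        whichs[ei] = best_which


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------


@njit(cache=True)
def fitch_score(order, child1, child2, nleaves, tipsets, w):
    """Weighted Fitch score over patterns; ``order`` lists internal nodes
    children-first with the (rooted) top node last."""
    P = tipsets.shape[1]
    N = child1.shape[0]
    sets = np.zeros((N, P), dtype=np.uint8)
    total = 0.0
    for p in range(P):
        cnt = 0
        for oi in range(order.shape[0]):
            u = order[oi]
            c1 = child1[u]
            c2 = child2[u]
            s1 = tipsets[c1, p] if c1 < nleaves else sets[c1, p]
            s2 = tipsets[c2, p] if c2 < nleaves else sets[c2, p]
            inter = s1 & s2
            if inter != 0:
                sets[u, p] = inter
            else:
                sets[u, p] = s1 | s2
                cnt += 1
        total += w[p] * cnt
    return total


@njit(cache=True)
def fitch_dir_sets(
    order, pre, parent, child1, child2, root, rootleaf, nleaves, tipsets, dsets, usets
):
    """Directional Fitch state sets for every edge node.

    dsets[x] = downpass set of x's subtree; usets[x] = downpass set of the
    complement (rooted toward x's parent).  Leaf rows of dsets hold the
    tip sets.
    """
    P = tipsets.shape[1]
    for x in range(nleaves):
        for p in range(P):
            dsets[x, p] = tipsets[x, p]
    for oi in range(order.shape[0]):
        u = order[oi]
        c1 = child1[u]
        c2 = child2[u]
        for p in range(P):
            inter = dsets[c1, p] & dsets[c2, p]
            dsets[u, p] = inter if inter != 0 else (dsets[c1, p] | dsets[c2, p])
    for oi in range(pre.shape[0]):
        x = pre[oi]
        pr = parent[x]
        if pr == root:
            for p in range(P):
                usets[x, p] = tipsets[rootleaf, p]
            continue
        sib = child1[pr] if child2[pr] == x else child2[pr]
        for p in range(P):
            inter = usets[pr, p] & dsets[sib, p]
            usets[x, p] = inter if inter != 0 else (usets[pr, p] | dsets[sib, p])


@njit(cache=True)
def attach_costs(edges, dsets, usets, xset, w):
    """Exact incremental Fitch cost of attaching a new leaf (state sets
    ``xset``) on each candidate edge."""
    E = edges.shape[0]
    P = xset.shape[0]
    out = np.zeros(E)
    for e in range(E):
        x = edges[e]
        acc = 0.0
        for p in range(P):
            inter = dsets[x, p] & usets[x, p]
            m = inter if inter != 0 else (dsets[x, p] | usets[x, p])
            if m & xset[p] == 0:
                acc += w[p]
        out[e] = acc
    return out


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------


@njit(cache=True)
def stepwise_build(perm, tipsets, w, rand_u, parent, child1, child2, dsets, usets):
    """Randomized stepwise-addition parsimony tree construction.

    Taxa are inserted in ``perm`` order; each insertion picks a Fitch-
    optimal attachment edge with uniform tie-breaking driven by
    ``rand_u``.  Fills parent/child arrays of a tree rooted (virtually)
    on the first taxon's pendant edge; the caller converts to a Tree.
    """
    n = tipsets.shape[0]
    Nmax = 2 * n - 1
    root = Nmax - 1
    for i in range(Nmax):
        parent[i] = -1
        child1[i] = -1
        child2[i] = -1
    l0 = perm[0]
    v = n
    parent[l0] = root
    parent[v] = root
    child1[root] = l0
    child2[root] = v
    parent[perm[1]] = v
    parent[perm[2]] = v
    child1[v] = perm[1]
    child2[v] = perm[2]
    next_internal = n + 1

    order = np.empty(Nmax, dtype=np.int32)
    pre = np.empty(Nmax, dtype=np.int32)
    stack = np.empty(Nmax, dtype=np.int32)
    for ti in range(3, n):
        x = perm[ti]
        # internal nodes, children-first (reversed preorder), root last
        top = 0
        stack[top] = root
        top += 1
        cnt = 0
        while top > 0:
            top -= 1
            u = stack[top]
            order[cnt] = u
            cnt += 1
            c = child1[u]
            if c >= n:
                stack[top] = c
                top += 1
            c = child2[u]
            if c >= n:
                stack[top] = c
                top += 1
        for i in range(cnt // 2):
            tmp = order[i]
            order[i] = order[cnt - 1 - i]
            order[cnt - 1 - i] = tmp
        # edge nodes in preorder
        rc = child1[root] if child1[root] != l0 else child2[root]
        top = 0
        stack[top] = rc
        top += 1
        m = 0
        while top > 0:
            top -= 1
            u = stack[top]
            pre[m] = u
            m += 1
            if child1[u] >= 0:
                stack[top] = child1[u]
                top += 1
                stack[top] = child2[u]
                top += 1
        fitch_dir_sets(
            order[:cnt], pre[:m], parent, child1, child2, root, l0, n,
            tipsets, dsets, usets,
        )
        cc = attach_costs(pre[:m], dsets, usets, tipsets[x], w)
        best = cc[0]
        for i in range(1, m):
            if cc[i] < best:
                best = cc[i]
        ntie = 0
        for i in range(m):
            if cc[i] <= best + 1e-9:
                ntie += 1
        pick = int(rand_u[ti] * ntie)
        if pick >= ntie:
            pick = ntie - 1
        j = 0
        k = 0
        for i in range(m):
            if cc[i] <= best + 1e-9:
                if k == pick:
                    j = i
                    break
                k += 1
        y = pre[j]
        mnode = next_internal
        next_internal += 1
        py = parent[y]
        if child1[py] == y:
            child1[py] = mnode
        else:
            child2[py] = mnode
        parent[mnode] = py
        child1[mnode] = y
        child2[mnode] = x
        parent[y] = mnode
        parent[x] = mnode


@njit(cache=True)
def pdist_matrix(codes, w):
    """Weighted mismatch proportions between all sequence pairs,
    ignoring positions where either sequence is a gap."""
    n = codes.shape[0]
    P = codes.shape[1]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            tot = 0.0
            mis = 0.0
            for p in range(P):
                a = codes[i, p]
                b = codes[j, p]
                if a > 3 or b > 3:
                    continue
                tot += w[p]
                if a != b:
                    mis += w[p]
            d = mis / tot if tot > 0 else 0.0
            D[i, j] = d
            D[j, i] = d
    return D
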