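"""Numba kernels for damped min-sum (max-product in the log domain) message
passing on the grid CRF.

Variables are pixels with K illuminance levels.  Factors are 4-neighbour
pairwise factors ``w * (delta * |ki - kj|) ** p`` and 2×2-block straightness
factors that charge ``w_straight`` when the block's illuminance-edge pattern
forms a corner.  Messages are passed asynchronously: a freshly updated
message is visible to the next update through the incrementally maintained
per-variable message-sum array.

The 2×2-clique message is computed exactly in O(K) per output label by
enumerating the partition patterns of the four pixel levels.  Patterns whose
edge set is empty, a straight pass-through (two opposite edges) or a full
crossing (all four edges) are free; every other pattern costs ``w_straight``
and is dominated by ``w_straight`` plus the unconstrained minimum of the
three incoming messages.
"""

from __future__ import annotations

import numpy as np
from collections import namedtuple

from numba import njit

_Workspace = namedtuple(
    "_Workspace", ["dtv", "dtz", "s0", "s1", "s2", "m0", "m1", "m2", "idx", "val"]
)


def make_workspace(K):
    return _Workspace(
        dtv=np.empty(K, dtype=np.int64),
        dtz=np.empty(K + 1),
        s0=np.empty(K),
        s1=np.empty(K),
        s2=np.empty(K),
        m0=np.empty(K),
        m1=np.empty(K),
        m2=np.empty(K),
        idx=np.empty((6, 4), dtype=np.int64),
        val=np.empty((6, 4)),
    )

BIG = 1e30

# slot layout within a 2x2 block: 0=TL, 1=TR, 2=BL, 3=BR
# for each target slot: (row-mate, col-mate, diagonal)
_MATES = np.array([[1, 2, 3], [0, 3, 2], [3, 0, 1], [2, 1, 0]], dtype=np.int64)


@njit(cache=True)
def _top4(arr, idx, val):
    """Indices and values of the four smallest entries (K >= 4)."""
    K = arr.shape[0]
    for j in range(4):
        idx[j] = -1
        val[j] = BIG
    for i in range(K):
        v = arr[i]
        if v < val[3]:
            j = 3
            while j > 0 and v < val[j - 1]:
                val[j] = val[j - 1]
                idx[j] = idx[j - 1]
                j -= 1
            val[j] = v
            idx[j] = i
    return idx, val


@njit(cache=True)
def _dt_quadratic(f, c, out, v, z):
    """out[i] = min_j f[j] + c * (i - j)**2 via the lower-envelope transform."""
    K = f.shape[0]
    k = 0
    v[0] = 0
    z[0] = -BIG
    z[1] = BIG
    for q in range(1, K):
        while True:
            s = ((f[q] + c * q * q) - (f[v[k]] + c * v[k] * v[k])) / (
                2.0 * c * (q - v[k])
            )
            if s <= z[k]:
                k -= 1
            else:
                break
        k += 1
        v[k] = q
        z[k] = s
        z[k + 1] = BIG
    k = 0
    for q in range(K):
        while z[k + 1] < q:
            k += 1
        d = q - v[k]
        out[q] = c * d * d + f[v[k]]


@njit(cache=True)
def _pair_message(m_in, w, D, power, delta, out, dtv, dtz):
    """out[k] = min_k' ( w * D[k, k'] + m_in[k'] ), normalized to min 0.

    For the quadratic step cost the minimization is a 1-D distance
    transform, computed in O(K); other exponents fall back to the generic
    O(K²) scan.
    """
    K = m_in.shape[0]
    if power == 2.0 and w > 0.0:
        _dt_quadratic(m_in, w * delta * delta, out, dtv, dtz)
        best_all = BIG
        for k in range(K):
            if out[k] < best_all:
                best_all = out[k]
    elif w == 0.0:
        best_all = BIG
        for k in range(K):
            if m_in[k] < best_all:
                best_all = m_in[k]
        for k in range(K):
            out[k] = best_all
        best_all = best_all
    else:
        best_all = BIG
        for k in range(K):
            best = BIG
            for kp in range(K):
                v = w * D[k, kp] + m_in[kp]
                if v < best:
                    best = v
            out[k] = best
            if best < best_all:
                best_all = best
    for k in range(K):
        out[k] -= best_all


@njit(cache=True)
def _update_pair(unary, msum, pmsg, pa, pb, pw, D, power, delta, p, to_slot, damp, rho, scratch, ws):
    """Send the message of pairwise factor ``p`` to one of its two variables.

    The variable-to-factor message weights the sum of incoming messages by
    ``rho`` (fractional/tree-reweighted min-sum); ``rho = 1`` is standard
    min-sum, smaller values counteract overcounting around the grid loops.
    """
    if to_slot == 0:
        src, dst = pb[p], pa[p]
        m_in = rho * (unary[src] + msum[src]) - pmsg[p, 1]
    else:
        src, dst = pa[p], pb[p]
        m_in = rho * (unary[src] + msum[src]) - pmsg[p, 0]
    _pair_message(m_in, pw[p], D, power, delta, scratch, ws.dtv, ws.dtz)
    K = scratch.shape[0]
    lo = BIG
    for k in range(K):
        nv = damp * pmsg[p, to_slot, k] + (1.0 - damp) * scratch[k]
        scratch[k] = nv
        if nv < lo:
            lo = nv
    for k in range(K):
        nv = scratch[k] - lo
        msum[dst, k] += nv - pmsg[p, to_slot, k]
        pmsg[p, to_slot, k] = nv


@njit(cache=True)
def _minexc(val1, idx1, val2, k):
    """min over v != k given (min, argmin, second-min)."""
    if idx1 != k:
        return val1
    return val2


@njit(cache=True)
def _clique_message(mR, mC, mD, w_s, out, ws):
    """Exact min-sum message of a straightness clique to one variable.

    ``mR``/``mC``/``mD`` are the incoming messages of the target pixel's
    row-mate, column-mate and diagonal mate.  Free (zero-cost) level
    partitions are enumerated exactly; all corner-forming partitions are
    covered by ``w_s`` plus the unconstrained floor.
    """
    K = mR.shape[0]
    S_cd = ws.s0
    S_rd = ws.s1
    S_rc = ws.s2
    for k in range(K):
        S_cd[k] = mC[k] + mD[k]
        S_rd[k] = mR[k] + mD[k]
        S_rc[k] = mR[k] + mC[k]
    iR, vR = ws.idx[0], ws.val[0]
    iC, vC = ws.idx[1], ws.val[1]
    iD, vD = ws.idx[2], ws.val[2]
    iCD, vCD = ws.idx[3], ws.val[3]
    iRD, vRD = ws.idx[4], ws.val[4]
    iRC, vRC = ws.idx[5], ws.val[5]
    _top4(mR, iR, vR)
    _top4(mC, iC, vC)
    _top4(mD, iD, vD)
    _top4(S_cd, iCD, vCD)
    _top4(S_rd, iRD, vRD)
    _top4(S_rc, iRC, vRC)
    floor = vR[0] + vC[0] + vD[0]
    lo = BIG
    for k in range(K):
        best = w_s + floor
        # all four equal
        v = mR[k] + mC[k] + mD[k]
        if v < best:
            best = v
        # pass-through / two-value crossings: {A,row}{col,diag}, {A,col}{row,diag},
        # {A,diag}{row,col}
        v = mR[k] + _minexc(vCD[0], iCD[0], vCD[1], k)
        if v < best:
            best = v
        v = mC[k] + _minexc(vRD[0], iRD[0], vRD[1], k)
        if v < best:
            best = v
        v = mD[k] + _minexc(vRC[0], iRC[0], vRC[1], k)
        if v < best:
            best = v
        # {A,diag}{row}{col}: full cross, row/col distinct and != k
        base = mD[k]
        for a in range(4):
            u = iR[a]
            if u == k or u < 0:
                continue
            for b in range(4):
                t = iC[b]
                if t == k or t == u or t < 0:
                    continue
                v = base + vR[a] + vC[b]
                if v < best:
                    best = v
                break  # inner candidates sorted: first valid is minimal
        # {row,col}{A}{diag}: full cross, shared value v != k, diag != v
        for a in range(4):
            s = iRC[a]
            if s == k or s < 0:
                continue
            v = vRC[a] + _minexc(vD[0], iD[0], vD[1], s)
            if v < best:
                best = v
        # all distinct, none equal k: full cross
        for a in range(4):
            u = iR[a]
            if u == k or u < 0:
                continue
            for b in range(4):
                t = iC[b]
                if t == k or t == u or t < 0:
                    continue
                for c in range(4):
                    s = iD[c]
                    if s == k or s == u or s == t or s < 0:
                        continue
                    v = vR[a] + vC[b] + vD[c]
                    if v < best:
                        best = v
                    break
        out[k] = best
        if best < lo:
            lo = best
    for k in range(K):
        out[k] -= lo


@njit(cache=True)
def _update_clique(unary, msum, cmsg, cvars, cl, slot, w_s, damp, rho, scratch, ws):
    mates = _MATES[slot]
    vR = cvars[cl, mates[0]]
    vC = cvars[cl, mates[1]]
    vD = cvars[cl, mates[2]]
    K = unary.shape[1]
    mR = ws.m0
    mC = ws.m1
    mD = ws.m2
    for k in range(K):
        mR[k] = rho * (unary[vR, k] + msum[vR, k]) - cmsg[cl, mates[0], k]
        mC[k] = rho * (unary[vC, k] + msum[vC, k]) - cmsg[cl, mates[1], k]
        mD[k] = rho * (unary[vD, k] + msum[vD, k]) - cmsg[cl, mates[2], k]
    _clique_message(mR, mC, mD, w_s, scratch, ws)
    K = scratch.shape[0]
    dst = cvars[cl, slot]
    lo = BIG
    for k in range(K):
        nv = damp * cmsg[cl, slot, k] + (1.0 - damp) * scratch[k]
        scratch[k] = nv
        if nv < lo:
            lo = nv
    for k in range(K):
        nv = scratch[k] - lo
        msum[dst, k] += nv - cmsg[cl, slot, k]
        cmsg[cl, slot, k] = nv


@njit(cache=True)
def run_bp(
    unary,
    pa,
    pb,
    pw,
    D,
    cvars,
    w_s,
    m,
    n,
    pmsg,
    cmsg,
    orders,
    iterations,
    full_link,
    damp,
    rho,
    power,
    delta,
):
    """Run the fixed iteration budget; returns (belief, message_update_count).

    One iteration of the original schedule: forward+backward sweeps along
    every row (horizontal pairwise factors), then along every column
    (vertical pairwise factors), then one message from every straightness
    clique to each of its four pixels.  The full-link schedule appends a
    second phase in which every factor-to-variable link (all pairwise links
    again plus all clique links) fires once in randomized order, exactly
    doubling the per-iteration message count.
    """
    N, K = unary.shape
    P = pa.shape[0]
    C = cvars.shape[0]
    n_h = m * (n - 1)  # horizontal pairs come first, row-major
    msum = np.zeros((N, K))
    for p in range(P):
        for s in range(2):
            lo = BIG
            for k in range(K):
                if pmsg[p, s, k] < lo:
                    lo = pmsg[p, s, k]
            for k in range(K):
                pmsg[p, s, k] -= lo
        for k in range(K):
            msum[pa[p], k] += pmsg[p, 0, k]
            msum[pb[p], k] += pmsg[p, 1, k]
    for cl in range(C):
        for s in range(4):
            lo = BIG
            for k in range(K):
                if cmsg[cl, s, k] < lo:
                    lo = cmsg[cl, s, k]
            for k in range(K):
                cmsg[cl, s, k] -= lo
                msum[cvars[cl, s], k] += cmsg[cl, s, k]
    scratch = np.empty(K)
    ws = _Workspace(
        np.empty(K, dtype=np.int64), np.empty(K + 1), np.empty(K), np.empty(K),
        np.empty(K), np.empty(K), np.empty(K), np.empty(K),
        np.empty((6, 4), dtype=np.int64), np.empty((6, 4)),
    )
    count = np.int64(0)
    for it in range(iterations):
        # --- phase 1: structured sweeps -----------------------------------
        for r in range(m):
            base = r * (n - 1)
            for c in range(n - 1):  # forward: push right
                _update_pair(unary, msum, pmsg, pa, pb, pw, D, power, delta,
                             base + c, 1, damp, rho, scratch, ws)
            count += n - 1
            for c in range(n - 2, -1, -1):  # backward: push left
                _update_pair(unary, msum, pmsg, pa, pb, pw, D, power, delta,
                             base + c, 0, damp, rho, scratch, ws)
            count += n - 1
        for c in range(n):
            for r in range(m - 1):  # downward
                p = n_h + r * n + c
                _update_pair(unary, msum, pmsg, pa, pb, pw, D, power, delta,
                             p, 1, damp, rho, scratch, ws)
            count += m - 1
            for r in range(m - 2, -1, -1):  # upward
                p = n_h + r * n + c
                _update_pair(unary, msum, pmsg, pa, pb, pw, D, power, delta,
                             p, 0, damp, rho, scratch, ws)
            count += m - 1
        for cl in range(C):
            for s in range(4):
                _update_clique(unary, msum, cmsg, cvars, cl, s, w_s,
                               damp, rho, scratch, ws)
            count += 4
        # --- phase 2: every link once, randomized order -------------------
        if full_link:
            order = orders[it]
            for li in range(order.shape[0]):
                link = order[li]
                if link < 2 * P:
                    _update_pair(unary, msum, pmsg, pa, pb, pw, D, power, delta,
                                 link // 2, link % 2, damp, rho, scratch, ws)
                else:
                    link -= 2 * P
                    _update_clique(unary, msum, cmsg, cvars,
                                   link // 4, link % 4, w_s, damp, rho, scratch, ws)
                count += 1
    belief = unary + msum
    return belief, count


# ---------------------------------------------------------------------------
# monotone region-shift refinement
# ---------------------------------------------------------------------------


@njit(cache=True)
def assignment_energy(a, unary, pa, pb, pw, delta, power, cvars, w_s):
    """Exact energy of a flat assignment (level indices per pixel)."""
    N = a.shape[0]
    total = 0.0
    for i in range(N):
        total += unary[i, a[i]]
    P = pa.shape[0]
    for p in range(P):
        d = a[pa[p]] - a[pb[p]]
        if d != 0:
            if d < 0:
                d = -d
            total += pw[p] * (delta * d) ** power
    C = cvars.shape[0]
    for cl in range(C):
        ka, kb = a[cvars[cl, 0]], a[cvars[cl, 1]]
        kc, kd = a[cvars[cl, 2]], a[cvars[cl, 3]]
        top = ka != kb
        bottom = kc != kd
        left = ka != kc
        right = kb != kd
        cnt = 0
        if top:
            cnt += 1
        if bottom:
            cnt += 1
        if left:
            cnt += 1
        if right:
            cnt += 1
        if cnt == 0 or cnt == 4:
            continue
        if cnt == 2 and ((top and bottom) or (left and right)):
            continue
        total += w_s
    return total


@njit(cache=True)
def _components(a, m, n, comp_out):
    """4-connected components of equal label; returns component count."""
    N = m * n
    for i in range(N):
        comp_out[i] = -1
    stack = np.empty(N, dtype=np.int64)
    ncomp = 0
    for s in range(N):
        if comp_out[s] >= 0:
            continue
        comp_out[s] = ncomp
        stack[0] = s
        top = 1
        while top > 0:
            top -= 1
            i = stack[top]
            r, c = i // n, i % n
            for t in range(4):
                if t == 0 and c + 1 < n:
                    j = i + 1
                elif t == 1 and c - 1 >= 0:
                    j = i - 1
                elif t == 2 and r + 1 < m:
                    j = i + n
                elif t == 3 and r - 1 >= 0:
                    j = i - n
                else:
                    continue
                if comp_out[j] < 0 and a[j] == a[i]:
                    comp_out[j] = ncomp
                    stack[top] = j
                    top += 1
        ncomp += 1
    return ncomp


@njit(cache=True)
def _block_cost(ka, kb, kc, kd, w_s):
    top = ka != kb
    bottom = kc != kd
    left = ka != kc
    right = kb != kd
    cnt = 0
    if top:
        cnt += 1
    if bottom:
        cnt += 1
    if left:
        cnt += 1
    if right:
        cnt += 1
    if cnt == 0 or cnt == 4:
        return 0.0
    if cnt == 2 and ((top and bottom) or (left and right)):
        return 0.0
    return w_s


@njit(cache=True)
def refine_assignment(a, unary, pa, pb, pw, delta, power, cvars, w_s, m, n, K,
                      max_passes):
    """Greedy monotone descent over uniform shifts of constant-label regions.

    Loopy message passing is good at discovering which regions should carry
    their own illuminance but tends to misjudge the size of the step.  This
    pass keeps the discovered region structure and descends the exact energy
    over per-region level shifts (including snapping a region onto a
    neighbour's level, which merges regions).  Energy deltas are evaluated
    incrementally over the region boundary; the energy never increases.
    """
    N = m * n
    P = pa.shape[0]
    C = cvars.shape[0]
    comp = np.empty(N, dtype=np.int64)

    # pixel -> incident pairwise factors (CSR)
    deg_p = np.zeros(N + 1, dtype=np.int64)
    for p in range(P):
        deg_p[pa[p] + 1] += 1
        deg_p[pb[p] + 1] += 1
    for i in range(N):
        deg_p[i + 1] += deg_p[i]
    pix_pairs = np.empty(2 * P, dtype=np.int64)
    fill = deg_p[:-1].copy()
    for p in range(P):
        pix_pairs[fill[pa[p]]] = p
        fill[pa[p]] += 1
        pix_pairs[fill[pb[p]]] = p
        fill[pb[p]] += 1

    # pixel -> incident cliques (CSR)
    deg_c = np.zeros(N + 1, dtype=np.int64)
    for cl in range(C):
        for s in range(4):
            deg_c[cvars[cl, s] + 1] += 1
    for i in range(N):
        deg_c[i + 1] += deg_c[i]
    pix_blocks = np.empty(4 * C, dtype=np.int64)
    fillc = deg_c[:-1].copy()
    for cl in range(C):
        for s in range(4):
            v = cvars[cl, s]
            pix_blocks[fillc[v]] = cl
            fillc[v] += 1

    pair_stamp = np.full(P, -1, dtype=np.int64)
    block_stamp = np.full(C, -1, dtype=np.int64)
    stamp = 0
    kb4 = np.empty(4, dtype=np.int64)

    for _ in range(max_passes):
        improved = False
        ncomp = _components(a, m, n, comp)
        # component pixel lists (CSR)
        csize = np.zeros(ncomp + 1, dtype=np.int64)
        for i in range(N):
            csize[comp[i] + 1] += 1
        for ci in range(ncomp):
            csize[ci + 1] += csize[ci]
        cpix = np.empty(N, dtype=np.int64)
        cfill = csize[:-1].copy()
        for i in range(N):
            cpix[cfill[comp[i]]] = i
            cfill[comp[i]] += 1

        for ci in range(ncomp):
            lo_px, hi_px = csize[ci], csize[ci + 1]
            if hi_px <= lo_px:
                continue
            cur = a[cpix[lo_px]]
            # candidate levels: shifts up to 8 plus adjacent regions' levels
            cand = np.full(24, -1, dtype=np.int64)
            nc = 0
            for sft in range(1, 9):
                if cur + sft < K:
                    cand[nc] = cur + sft
                    nc += 1
                if cur - sft >= 0:
                    cand[nc] = cur - sft
                    nc += 1
            for t in range(lo_px, hi_px):
                if nc >= 24:
                    break
                i = cpix[t]
                for q in range(deg_p[i], deg_p[i + 1]):
                    p = pix_pairs[q]
                    j = pa[p] if pb[p] == i else pb[p]
                    if comp[j] != ci:
                        lv = a[j]
                        seen = False
                        for u in range(nc):
                            if cand[u] == lv:
                                seen = True
                                break
                        if not seen and nc < 24:
                            cand[nc] = lv
                            nc += 1
            best_lv = -1
            best_de = -1e-12
            for u in range(nc):
                lv = cand[u]
                if lv < 0 or lv == cur:
                    continue
                de = 0.0
                stamp += 1
                for t in range(lo_px, hi_px):
                    i = cpix[t]
                    de += unary[i, lv] - unary[i, a[i]]
                    for q in range(deg_p[i], deg_p[i + 1]):
                        p = pix_pairs[q]
                        if pair_stamp[p] == stamp:
                            continue
                        pair_stamp[p] = stamp
                        j = pa[p] if pb[p] == i else pb[p]
                        d_old = a[i] - a[j]
                        d_new = 0 if comp[j] == ci else lv - a[j]
                        if d_old < 0:
                            d_old = -d_old
                        if d_new < 0:
                            d_new = -d_new
                        if d_old == d_new:
                            continue
                        if power == 2.0:
                            de += pw[p] * delta * delta * (
                                d_new * d_new - d_old * d_old
                            )
                        else:
                            de += pw[p] * (
                                (delta * d_new) ** power - (delta * d_old) ** power
                            )
                    for q in range(deg_c[i], deg_c[i + 1]):
                        cl = pix_blocks[q]
                        if block_stamp[cl] == stamp:
                            continue
                        block_stamp[cl] = stamp
                        inside = 0
                        for sslot in range(4):
                            if comp[cvars[cl, sslot]] == ci:
                                inside += 1
                        if inside == 4:
                            continue
                        for sslot in range(4):
                            kb4[sslot] = a[cvars[cl, sslot]]
                        old_c = _block_cost(kb4[0], kb4[1], kb4[2], kb4[3], w_s)
                        for sslot in range(4):
                            if comp[cvars[cl, sslot]] == ci:
                                kb4[sslot] = lv
                        new_c = _block_cost(kb4[0], kb4[1], kb4[2], kb4[3], w_s)
                        de += new_c - old_c
                if de < best_de:
                    best_de = de
                    best_lv = lv
            if best_lv >= 0:
                for t in range(lo_px, hi_px):
                    a[cpix[t]] = best_lv
                improved = True
        # halfplane sub-region moves: split a region along a straight grid
        # line and shift one side (straight illuminance edges are free or
        # cheap, so these are the natural escape moves)
        for ci in range(ncomp):
            lo_px, hi_px = csize[ci], csize[ci + 1]
            if hi_px - lo_px < 2:
                continue
            r0b, r1b, c0b, c1b = m, -1, n, -1
            for t in range(lo_px, hi_px):
                i = cpix[t]
                r, c = i // n, i % n
                if r < r0b:
                    r0b = r
                if r > r1b:
                    r1b = r
                if c < c0b:
                    c0b = c
                if c > c1b:
                    c1b = c
            cur = a[cpix[lo_px]]
            for axis in range(2):
                lo_cut = r0b + 1 if axis == 0 else c0b + 1
                hi_cut = r1b + 1 if axis == 0 else c1b + 1
                for cut in range(lo_cut, hi_cut):
                    for side in range(2):
                        best_lv = -1
                        best_de = -1e-12
                        for sft in range(-6, 7):
                            lv = cur + sft
                            if sft == 0 or lv < 0 or lv >= K:
                                continue
                            de = 0.0
                            stamp += 1
                            nsel = 0
                            for t in range(lo_px, hi_px):
                                i = cpix[t]
                                pos = i // n if axis == 0 else i % n
                                inside = (pos < cut) if side == 0 else (pos >= cut)
                                if not inside:
                                    continue
                                nsel += 1
                                de += unary[i, lv] - unary[i, a[i]]
                                for q in range(deg_p[i], deg_p[i + 1]):
                                    p = pix_pairs[q]
                                    if pair_stamp[p] == stamp:
                                        continue
                                    pair_stamp[p] = stamp
                                    j = pa[p] if pb[p] == i else pb[p]
                                    jpos = j // n if axis == 0 else j % n
                                    j_in = (comp[j] == ci) and (
                                        (jpos < cut) if side == 0 else (jpos >= cut)
                                    )
                                    d_old = a[i] - a[j]
                                    d_new = 0 if j_in else lv - a[j]
                                    if d_old < 0:
                                        d_old = -d_old
                                    if d_new < 0:
                                        d_new = -d_new
                                    if d_old == d_new:
                                        continue
                                    if power == 2.0:
                                        de += pw[p] * delta * delta * (
                                            d_new * d_new - d_old * d_old
                                        )
                                    else:
                                        de += pw[p] * ((delta * d_new) ** power
                                                       - (delta * d_old) ** power)
                                for q in range(deg_c[i], deg_c[i + 1]):
                                    cl = pix_blocks[q]
                                    if block_stamp[cl] == stamp:
                                        continue
                                    block_stamp[cl] = stamp
                                    for sslot in range(4):
                                        kb4[sslot] = a[cvars[cl, sslot]]
                                    old_c = _block_cost(kb4[0], kb4[1], kb4[2],
                                                        kb4[3], w_s)
                                    for sslot in range(4):
                                        v = cvars[cl, sslot]
                                        vpos = v // n if axis == 0 else v % n
                                        v_in = (comp[v] == ci) and (
                                            (vpos < cut) if side == 0 else (vpos >= cut)
                                        )
                                        if v_in:
                                            kb4[sslot] = lv
                                    new_c = _block_cost(kb4[0], kb4[1], kb4[2],
                                                        kb4[3], w_s)
                                    de += new_c - old_c
                            if nsel == 0:
                                continue
                            if de < best_de:
                                best_de = de
                                best_lv = lv
                        if best_lv >= 0:
                            for t in range(lo_px, hi_px):
                                i = cpix[t]
                                pos = i // n if axis == 0 else i % n
                                inside = (pos < cut) if side == 0 else (pos >= cut)
                                if inside:
                                    a[i] = best_lv
                            improved = True
        # single-pixel moves: may split regions that the region shifts cannot
        for i in range(N):
            cur = a[i]
            best_lv = -1
            best_de = -1e-12
            for lv in range(K):
                if lv == cur:
                    continue
                de = unary[i, lv] - unary[i, cur]
                if de >= best_de + 0.0 and de > 50.0:
                    continue  # cheap reject: unary alone already far worse
                for q in range(deg_p[i], deg_p[i + 1]):
                    p = pix_pairs[q]
                    j = pa[p] if pb[p] == i else pb[p]
                    d_old = cur - a[j]
                    d_new = lv - a[j]
                    if d_old < 0:
                        d_old = -d_old
                    if d_new < 0:
                        d_new = -d_new
                    if power == 2.0:
                        de += pw[p] * delta * delta * (d_new * d_new - d_old * d_old)
                    else:
                        de += pw[p] * ((delta * d_new) ** power
                                       - (delta * d_old) ** power)
                for q in range(deg_c[i], deg_c[i + 1]):
                    cl = pix_blocks[q]
                    for sslot in range(4):
                        kb4[sslot] = a[cvars[cl, sslot]]
                    old_c = _block_cost(kb4[0], kb4[1], kb4[2], kb4[3], w_s)
                    for sslot in range(4):
                        if cvars[cl, sslot] == i:
                            kb4[sslot] = lv
                    new_c = _block_cost(kb4[0], kb4[1], kb4[2], kb4[3], w_s)
                    de += new_c - old_c
                if de < best_de:
                    best_de = de
                    best_lv = lv
            if best_lv >= 0:
                a[i] = best_lv
                improved = True
        if not improved:
            break
    return assignment_energy(a, unary, pa, pb, pw, delta, power, cvars, w_s)
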