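"""Compiled CART kernels used by the forest engine.

A tree is stored as five parallel arrays (``feature``, ``threshold``,
``left``, ``right``, ``value``).  Internal nodes have ``feature >= 0``;
rows with ``x[feature] <= threshold`` descend left.  Leaf ``value`` is the
mean of the training outcome in that leaf (for binary outcomes this is the
class-1 fraction; variance-reduction splitting on a 0/1 outcome selects the
same split as the Gini criterion, so one kernel serves both tasks).

Split search follows the standard axis-aligned CART rules: at each node a
random subset of ``mtry`` candidate features is drawn, every boundary
between distinct sorted values with both children of size >= ``min_leaf``
is scanned, and the split maximising the variance reduction is kept.
Thresholds are midpoints between adjacent distinct values.  Ties are broken
toward the first candidate encountered in the (seeded) feature order, which
makes tree growth bit-reproducible for a fixed seed.
"""

import numpy as np
from numba import njit

__all__ = [
    "build_tree",
    "build_tree_inbag",
    "inbag_sorted_rows",
    "predict_tree",
    "train_forest_kernel",
    "forest_vimp_kernel",
]


@njit(cache=True, inline="always")
def _splitmix64(state):
    # SplitMix64: tiny, seedable, platform-independent PRNG for feature draws.
    state = (state + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = state
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    return state, z ^ (z >> np.uint64(31))


@njit(cache=True)
def _sort_pairs(vals, ys, lo, hi):
    # iterative quicksort of vals[lo:hi] with ys permuted alongside;
    # insertion sort below a small cutoff
    stack = np.empty((64, 2), np.int64)
    stack[0, 0] = lo
    stack[0, 1] = hi
    top = 1
    while top > 0:
        top -= 1
        a = stack[top, 0]
        b = stack[top, 1]
        while b - a > 16:
            # median-of-three pivot
            mid = (a + b - 1) >> 1
            if vals[mid] < vals[a]:
                vals[a], vals[mid] = vals[mid], vals[a]
                ys[a], ys[mid] = ys[mid], ys[a]
            if vals[b - 1] < vals[a]:
                vals[a], vals[b - 1] = vals[b - 1], vals[a]
                ys[a], ys[b - 1] = ys[b - 1], ys[a]
            if vals[b - 1] < vals[mid]:
                vals[mid], vals[b - 1] = vals[b - 1], vals[mid]
                ys[mid], ys[b - 1] = ys[b - 1], ys[mid]
            pivot = vals[mid]
            i = a
            j = b - 1
            while True:
                while vals[i] < pivot:
                    i += 1
                while vals[j] > pivot:
                    j -= 1
                if i >= j:
                    break
                vals[i], vals[j] = vals[j], vals[i]
                ys[i], ys[j] = ys[j], ys[i]
                i += 1
                j -= 1
            # recurse into smaller half, loop on larger
            if j + 1 - a < b - (j + 1):
                stack[top, 0] = j + 1
                stack[top, 1] = b
                top += 1
                b = j + 1
            else:
                stack[top, 0] = a
                stack[top, 1] = j + 1
                top += 1
                a = j + 1
        for i in range(a + 1, b):
            v = vals[i]
            w = ys[i]
            j = i - 1
            while j >= a and vals[j] > v:
                vals[j + 1] = vals[j]
                ys[j + 1] = ys[j]
                j -= 1
            vals[j + 1] = v
            ys[j + 1] = w


@njit(cache=True)
def build_tree(X, y, mtry, min_leaf, seed):
    """Grow one CART tree on (X, y); returns the parallel-array encoding.

    X : float64 (n, p) C-contiguous; y : float64 (n,).
    A node is terminal when it is pure, has fewer than ``2 * min_leaf``
    rows, or no candidate feature admits a valid split.
    """
    n, p = X.shape
    max_nodes = 2 * n + 1
    feature = np.full(max_nodes, -1, np.int32)
    threshold = np.zeros(max_nodes, np.float64)
    left = np.full(max_nodes, -1, np.int32)
    right = np.full(max_nodes, -1, np.int32)
    value = np.zeros(max_nodes, np.float64)

    idx = np.arange(n)
    buf = np.empty(n, np.int64)
    vals = np.empty(n, np.float64)
    ysort = np.empty(n, np.float64)
    feats = np.empty(p, np.int64)
    rng_state = np.uint64(seed) ^ np.uint64(0x5851F42D4C957F2D)

    # explicit stack: (node_id, start, end)
    stack = np.empty((64 + 2 * n, 3), np.int64)
    stack[0, 0] = 0
    stack[0, 1] = 0
    stack[0, 2] = n
    top = 1
    n_nodes = 1

    while top > 0:
        top -= 1
        node = stack[top, 0]
        start = stack[top, 1]
        end = stack[top, 2]
        m = end - start

        s = 0.0
        lo = y[idx[start]]
        hi = lo
        for i in range(start, end):
            v = y[idx[i]]
            s += v
            if v < lo:
                lo = v
            if v > hi:
                hi = v
        value[node] = s / m

        if m < 2 * min_leaf or lo == hi:
            continue  # leaf

        # draw mtry distinct candidate features (partial Fisher-Yates)
        for j in range(p):
            feats[j] = j
        k = mtry if mtry < p else p
        for j in range(k):
            rng_state, r = _splitmix64(rng_state)
            pick = j + np.int64(r % np.uint64(p - j))
            feats[j], feats[pick] = feats[pick], feats[j]

        best_score = -np.inf
        best_feat = -1
        best_thr = 0.0
        for j in range(k):
            f = feats[j]
            for i in range(m):
                vals[i] = X[idx[start + i], f]
                ysort[i] = y[idx[start + i]]
            _sort_pairs(vals, ysort, 0, m)
            # cumulative sums of y in sorted order
            cum = 0.0
            # scan valid boundaries: left size t+1 in [min_leaf, m-min_leaf]
            for t in range(m - 1):
                cum += ysort[t]
                nl = t + 1
                if nl < min_leaf:
                    continue
                if m - nl < min_leaf:
                    break
                vlo = vals[t]
                vhi = vals[t + 1]
                if vhi <= vlo:
                    continue
                rsum = s - cum
                score = cum * cum / nl + rsum * rsum / (m - nl)
                if score > best_score:
                    best_score = score
                    best_feat = f
                    thr = 0.5 * (vlo + vhi)
                    if thr >= vhi:  # guard against rounding up
                        thr = vlo
                    best_thr = thr

        if best_feat < 0:
            continue  # no valid split among candidates -> leaf

        # stable partition of idx[start:end] by the chosen split
        nl = 0
        nr = 0
        for i in range(start, end):
            if X[idx[i], best_feat] <= best_thr:
                buf[start + nl] = idx[i]
                nl += 1
        for i in range(start, end):
            if X[idx[i], best_feat] > best_thr:
                buf[start + nl + nr] = idx[i]
                nr += 1
        for i in range(start, end):
            idx[i] = buf[i]

        feature[node] = best_feat
        threshold[node] = best_thr
        lchild = n_nodes
        rchild = n_nodes + 1
        n_nodes += 2
        left[node] = lchild
        right[node] = rchild
        stack[top, 0] = lchild
        stack[top, 1] = start
        stack[top, 2] = start + nl
        top += 1
        stack[top, 0] = rchild
        stack[top, 1] = start + nl
        stack[top, 2] = end
        top += 1

    return (
        feature[:n_nodes].copy(),
        threshold[:n_nodes].copy(),
        left[:n_nodes].copy(),
        right[:n_nodes].copy(),
        value[:n_nodes].copy(),
    )


@njit(cache=True)
def inbag_sorted_rows(global_order, counts):
    """Per-feature sorted row lists for one bootstrap sample.

    global_order : (p, n) int32, rows sorted by each feature on the full
    training block; counts : (n,) bootstrap multiplicities.  Rows drawn k
    times appear k times (adjacent, equal feature values), so node-size
    accounting matches fitting on the duplicated sample.
    """
    p, n = global_order.shape
    m0 = 0
    for i in range(n):
        m0 += counts[i]
    out = np.empty((p, m0), np.int32)
    for f in range(p):
        k = 0
        for i in range(n):
            r = global_order[f, i]
            for _ in range(counts[r]):
                out[f, k] = r
                k += 1
    return out


@njit(cache=True)
def _grow(XF, y, rows, mtry, min_leaf, seed, feature, threshold, left, right, value,
          scratch, feats, stack):
    """Grow one CART tree from presorted in-bag row lists into the
    provided output slices; returns the node count.

    ``rows`` is a (p, m0) matrix holding the same in-bag multiset per
    feature, each sorted by that feature; it is partitioned in place at
    every split, which avoids any per-node sorting.  ``XF`` should be
    Fortran-ordered for cache-friendly column access.
    """
    p = XF.shape[1]
    m0 = rows.shape[1]
    rng_state = np.uint64(seed) ^ np.uint64(0x5851F42D4C957F2D)
    feature[: 2 * m0 + 1] = -1
    stack[0, 0] = 0
    stack[0, 1] = 0
    stack[0, 2] = m0
    top = 1
    n_nodes = 1

    while top > 0:
        top -= 1
        node = stack[top, 0]
        start = stack[top, 1]
        end = stack[top, 2]
        m = end - start

        s = 0.0
        lo = y[rows[0, start]]
        hi = lo
        for i in range(start, end):
            v = y[rows[0, i]]
            s += v
            if v < lo:
                lo = v
            if v > hi:
                hi = v
        value[node] = s / m

        if m < 2 * min_leaf or lo == hi:
            continue

        for j in range(p):
            feats[j] = j
        k = mtry if mtry < p else p
        for j in range(k):
            rng_state, r = _splitmix64(rng_state)
            pick = j + np.int64(r % np.uint64(p - j))
            feats[j], feats[pick] = feats[pick], feats[j]

        best_score = -np.inf
        best_feat = -1
        best_thr = 0.0
        for j in range(k):
            f = feats[j]
            cum = 0.0
            for t in range(m - 1):
                r = rows[f, start + t]
                cum += y[r]
                nl = t + 1
                if nl < min_leaf:
                    continue
                if m - nl < min_leaf:
                    break
                vlo = XF[r, f]
                vhi = XF[rows[f, start + t + 1], f]
                if vhi <= vlo:
                    continue
                rsum = s - cum
                score = cum * cum / nl + rsum * rsum / (m - nl)
                if score > best_score:
                    best_score = score
                    best_feat = f
                    thr = 0.5 * (vlo + vhi)
                    if thr >= vhi:
                        thr = vlo
                    best_thr = thr

        if best_feat < 0:
            continue

        # stable partition of every feature's sorted row list
        nl = 0
        for f in range(p):
            a = 0
            b = 0
            for i in range(start, end):
                r = rows[f, i]
                if XF[r, best_feat] <= best_thr:
                    rows[f, start + a] = r
                    a += 1
                else:
                    scratch[b] = r
                    b += 1
            for i in range(b):
                rows[f, start + a + i] = scratch[i]
            nl = a

        feature[node] = best_feat
        threshold[node] = best_thr
        lchild = n_nodes
        rchild = n_nodes + 1
        n_nodes += 2
        left[node] = lchild
        right[node] = rchild
        stack[top, 0] = lchild
        stack[top, 1] = start
        stack[top, 2] = start + nl
        top += 1
        stack[top, 0] = rchild
        stack[top, 1] = start + nl
        stack[top, 2] = end
        top += 1

    return n_nodes


@njit(cache=True)
def build_tree_inbag(XF, y, sorted_rows, mtry, min_leaf, seed):
    """Grow one tree from presorted in-bag row lists (reference wrapper
    around :func:`_grow`); returns the parallel-array encoding."""
    p = XF.shape[1]
    m0 = sorted_rows.shape[1]
    max_nodes = 2 * m0 + 1
    feature = np.empty(max_nodes, np.int32)
    threshold = np.zeros(max_nodes, np.float64)
    left = np.full(max_nodes, -1, np.int32)
    right = np.full(max_nodes, -1, np.int32)
    value = np.zeros(max_nodes, np.float64)
    rows = sorted_rows.copy()
    scratch = np.empty(m0, np.int32)
    feats = np.empty(p, np.int64)
    stack = np.empty((64 + 2 * m0, 3), np.int64)
    n_nodes = _grow(
        XF, y, rows, mtry, min_leaf, seed,
        feature, threshold, left, right, value, scratch, feats, stack,
    )
    return (
        feature[:n_nodes].copy(),
        threshold[:n_nodes].copy(),
        left[:n_nodes].copy(),
        right[:n_nodes].copy(),
        value[:n_nodes].copy(),
    )


@njit(cache=True)
def train_forest_kernel(XF, y, order, draws, seeds, mtry, min_leaf):
    """Train all trees of a forest in one compiled call.

    Parameters: Fortran-ordered features, outcome, per-feature global
    sort order (p, n), bootstrap draw matrix (T, k), per-tree split
    seeds.  Returns packed parallel arrays of shape (T, 2k+1) plus the
    per-tree node counts and the OOB membership mask (T, n).
    """
    n, p = XF.shape
    T, k = draws.shape
    stride = 2 * k + 1
    feature = np.empty((T, stride), np.int32)
    threshold = np.zeros((T, stride), np.float64)
    left = np.full((T, stride), -1, np.int32)
    right = np.full((T, stride), -1, np.int32)
    value = np.zeros((T, stride), np.float64)
    n_nodes = np.empty(T, np.int64)
    oob = np.empty((T, n), np.uint8)

    counts = np.empty(n, np.int64)
    rows = np.empty((p, k), np.int32)
    scratch = np.empty(k, np.int32)
    feats = np.empty(p, np.int64)
    stack = np.empty((64 + 2 * k, 3), np.int64)

    for t in range(T):
        counts[:] = 0
        for j in range(k):
            counts[draws[t, j]] += 1
        for i in range(n):
            oob[t, i] = 1 if counts[i] == 0 else 0
        for f in range(p):
            pos = 0
            for i in range(n):
                r = order[f, i]
                for _ in range(counts[r]):
                    rows[f, pos] = r
                    pos += 1
        n_nodes[t] = _grow(
            XF, y, rows, mtry, min_leaf, seeds[t],
            feature[t], threshold[t], left[t], right[t], value[t],
            scratch, feats, stack,
        )
    return feature, threshold, left, right, value, n_nodes, oob


@njit(cache=True, inline="always")
def _leaf_value(feature, threshold, left, right, value, x):
    node = 0
    while feature[node] >= 0:
        if x[feature[node]] <= threshold[node]:
            node = left[node]
        else:
            node = right[node]
    return value[node]


@njit(cache=True)
def forest_vimp_kernel(
    feature, threshold, left, right, value, oob,
    XC, y, col, perms, perm_offsets, n_perm, classify,
):
    """Per-tree OOB loss differences for permuting one column.

    ``perms`` concatenates, tree by tree and permutation by permutation,
    the within-OOB permutation index vectors (``perm_offsets[t]`` marks
    tree t's first entry).  Trees without OOB rows yield NaN.  With
    ``classify`` the leaf value is read as a class-1 fraction and 0-1
    loss is used (ties to class 0); otherwise squared error.
    """
    T = feature.shape[0]
    n, p = XC.shape
    out = np.full(T, np.nan)
    xrow = np.empty(p, np.float64)
    for t in range(T):
        n_oob = 0
        for i in range(n):
            if oob[t, i]:
                n_oob += 1
        if n_oob == 0:
            continue
        rows_t = np.empty(n_oob, np.int64)
        j = 0
        for i in range(n):
            if oob[t, i]:
                rows_t[j] = i
                j += 1
        base_pred = np.empty(n_oob, np.float64)
        base_loss = 0.0
        for i in range(n_oob):
            r = rows_t[i]
            for f in range(p):
                xrow[f] = XC[r, f]
            v = _leaf_value(feature[t], threshold[t], left[t], right[t], value[t], xrow)
            base_pred[i] = v
            if classify:
                pred_cls = 1.0 if v > 0.5 else 0.0
                if pred_cls != y[r]:
                    base_loss += 1.0
            else:
                d = y[r] - v
                base_loss += d * d
        base_loss /= n_oob

        acc = 0.0
        off = perm_offsets[t]
        for rperm in range(n_perm):
            loss = 0.0
            for i in range(n_oob):
                r = rows_t[i]
                src = rows_t[perms[off + rperm * n_oob + i]]
                for f in range(p):
                    xrow[f] = XC[r, f]
                xrow[col] = XC[src, col]
                v = _leaf_value(feature[t], threshold[t], left[t], right[t], value[t], xrow)
                if classify:
                    pred_cls = 1.0 if v > 0.5 else 0.0
                    if pred_cls != y[r]:
                        loss += 1.0
                else:
                    d = y[r] - v
                    loss += d * d
            acc += loss / n_oob - base_loss
        out[t] = acc / n_perm
    return out


@njit(cache=True)
def predict_tree(feature, threshold, left, right, value, X):
    """Leaf value for every row of X (float64 (n, p))."""
    n = X.shape[0]
    out = np.empty(n, np.float64)
    for i in range(n):
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = value[node]
    return out
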