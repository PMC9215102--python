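"""Numba kernels for chi-square-split tree growth.

Kept separate from the public API so the compiled core stays small and
cacheable.  All randomness (feature subsets, bootstrap rows) is drawn by
the caller with a numpy Generator; the kernels themselves are pure.
"""

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _chi2_2x2(a, b, c, d):
    """Pearson chi-square of the 2x2 table [[a, b], [c, d]], no
    continuity correction; 0 when any margin is empty."""
    r1 = a + b
    r2 = c + d
    c1 = a + c
    c2 = b + d
    if r1 == 0.0 or r2 == 0.0 or c1 == 0.0 or c2 == 0.0:
        return 0.0
    n = r1 + r2
    diff = a * d - b * c
    return n * diff * diff / (r1 * r2 * c1 * c2)


@njit(cache=True)
def grow_tree_arrays(X, y, feat_subset, min_node_size, max_depth):
    """Grow one unpruned tree; return flat node arrays.

    X : (n, p) float64 feature matrix (all block OTUs).
    y : (n,) int8 binary labels.
    feat_subset : sorted int64 column indices this tree may split on.
    min_node_size : nodes smaller than this are not split.
    max_depth : nodes at this depth are not split (root depth = 1).

    Splits send ``value <= threshold`` left.  The split maximising the
    chi-square of (value > threshold) x label is chosen; ties go to the
    smaller column index, then the smaller threshold (guaranteed by the
    ascending scan with strictly-greater updates).

    Returns (feat, thr, chi, depth, n_node, left, right); feat == -1
    marks a leaf.
    """
    n = X.shape[0]
    max_nodes = 2 * n + 1
    node_feat = np.full(max_nodes, -1, np.int64)
    node_thr = np.zeros(max_nodes, np.float64)
    node_chi = np.zeros(max_nodes, np.float64)
    node_depth = np.zeros(max_nodes, np.int64)
    node_n = np.zeros(max_nodes, np.int64)
    node_left = np.full(max_nodes, -1, np.int64)
    node_right = np.full(max_nodes, -1, np.int64)

    idx = np.arange(n)
    buf = np.empty(n, np.int64)
    v = np.empty(n, np.float64)

    stack = np.empty((max_nodes, 4), np.int64)
    stack[0, 0] = 0
    stack[0, 1] = 0
    stack[0, 2] = n
    stack[0, 3] = 1
    top = 1
    n_nodes = 1

    while top > 0:
        top -= 1
        nid = stack[top, 0]
        start = stack[top, 1]
        end = stack[top, 2]
        depth = stack[top, 3]
        m = end - start
        node_depth[nid] = depth
        node_n[nid] = m

        ncase = 0
        for i in range(start, end):
            ncase += y[idx[i]]
        if m < min_node_size or ncase == 0 or ncase == m or depth >= max_depth:
            continue

        best_chi = 0.0
        best_f = -1
        best_thr = 0.0
        for fi in range(feat_subset.shape[0]):
            f = feat_subset[fi]
            for i in range(m):
                v[i] = X[idx[start + i], f]
            order = np.argsort(v[:m])
            cum = 0
            for k in range(1, m):
                cum += y[idx[start + order[k - 1]]]
                lo = v[order[k - 1]]
                hi = v[order[k]]
                if hi > lo:
                    a = float(cum)            # left cases
                    b = float(k - cum)        # left controls
                    c = float(ncase - cum)    # right cases
                    d = float(m - k - ncase + cum)
                    chi = _chi2_2x2(a, b, c, d)
                    if chi > best_chi * (1.0 + 1e-12) + 1e-12:
                        best_chi = chi
                        best_f = f
                        best_thr = 0.5 * (lo + hi)

        if best_f < 0 or best_chi <= 0.0:
            continue

        # stable partition: <= threshold left, > threshold right
        nl = 0
        nr = 0
        for i in range(start, end):
            if X[idx[i], best_f] <= best_thr:
                buf[nl] = idx[i]
                nl += 1
        for i in range(start, end):
            if X[idx[i], best_f] > best_thr:
                buf[nl + nr] = idx[i]
                nr += 1
        for i in range(m):
            idx[start + i] = buf[i]

        node_feat[nid] = best_f
        node_thr[nid] = best_thr
        node_chi[nid] = best_chi
        left_id = n_nodes
        right_id = n_nodes + 1
        n_nodes += 2
        node_left[nid] = left_id
        node_right[nid] = right_id
        stack[top, 0] = left_id
        stack[top, 1] = start
        stack[top, 2] = start + nl
        stack[top, 3] = depth + 1
        top += 1
        stack[top, 0] = right_id
        stack[top, 1] = start + nl
        stack[top, 2] = end
        stack[top, 3] = depth + 1
        top += 1

    return (node_feat[:n_nodes], node_thr[:n_nodes], node_chi[:n_nodes],
            node_depth[:n_nodes], node_n[:n_nodes],
            node_left[:n_nodes], node_right[:n_nodes])


@njit(cache=True)
def forest_importance_kernel(vals_sorted, ids_sorted, y, subsets,
                             min_node_size, max_depth):
    """Grow all trees of one forest and accumulate depth importance.

    Presorted variant of :func:`grow_tree_arrays`: per-feature sorted
    sample orders are computed once by the caller and maintained under
    splitting by stable partition, so no sorting happens inside nodes.
    Split choice, tie-breaks and stopping rules are identical to the
    single-tree kernel (pinned by tests).

    vals_sorted : (p, n) float64, feature values in ascending order.
    ids_sorted  : (p, n) int64, matching sample ids.
    y           : (n,) int8 labels.
    subsets     : (n_trees, m) int64 sorted feature indices per tree.

    Returns the summed (not averaged) importance per feature.
    """
    p, n = vals_sorted.shape
    n_trees, msub = subsets.shape
    scores = np.zeros(p, np.float64)

    fvals = np.empty((msub, n), np.float64)
    fids = np.empty((msub, n), np.int64)
    tmp_v = np.empty(n, np.float64)
    tmp_i = np.empty(n, np.int64)
    flag = np.empty(n, np.uint8)
    stack = np.empty((2 * n + 1, 3), np.int64)

    for t in range(n_trees):
        subset = subsets[t]
        for a in range(msub):
            f = subset[a]
            for i in range(n):
                fvals[a, i] = vals_sorted[f, i]
                fids[a, i] = ids_sorted[f, i]
        stack[0, 0] = 0
        stack[0, 1] = n
        stack[0, 2] = 1
        top = 1
        while top > 0:
            top -= 1
            start = stack[top, 0]
            end = stack[top, 1]
            depth = stack[top, 2]
            m = end - start
            ncase = 0
            for i in range(start, end):
                ncase += y[fids[0, i]]
            if m < min_node_size or ncase == 0 or ncase == m or depth >= max_depth:
                continue
            best_chi = 0.0
            best_a = -1
            best_thr = 0.0
            best_k = 0
            for a in range(msub):
                cum = 0
                for i in range(start + 1, end):
                    cum += y[fids[a, i - 1]]
                    lo = fvals[a, i - 1]
                    hi = fvals[a, i]
                    if hi > lo:
                        k = i - start
                        aa = float(cum)
                        bb = float(k - cum)
                        cc = float(ncase - cum)
                        dd = float(m - k - ncase + cum)
                        chi = _chi2_2x2(aa, bb, cc, dd)
                        if chi > best_chi * (1.0 + 1e-12) + 1e-12:
                            best_chi = chi
                            best_a = a
                            best_thr = 0.5 * (lo + hi)
                            best_k = k
            if best_a < 0 or best_chi <= 0.0:
                continue
            scores[subset[best_a]] += 2.0 ** (-float(depth)) * best_chi
            # left members are the first best_k of the chosen feature's
            # sorted segment (values <= threshold)
            for i in range(start, end):
                flag[fids[best_a, i]] = 1 if i - start < best_k else 0
            for a in range(msub):
                l = 0
                r = best_k
                for i in range(start, end):
                    sid = fids[a, i]
                    if flag[sid] == 1:
                        tmp_i[l] = sid
                        tmp_v[l] = fvals[a, i]
                        l += 1
                    else:
                        tmp_i[r] = sid
                        tmp_v[r] = fvals[a, i]
                        r += 1
                for i in range(m):
                    fids[a, start + i] = tmp_i[i]
                    fvals[a, start + i] = tmp_v[i]
            stack[top, 0] = start
            stack[top, 1] = start + best_k
            stack[top, 2] = depth + 1
            top += 1
            stack[top, 0] = start + best_k
            stack[top, 1] = end
            stack[top, 2] = depth + 1
            top += 1
    return scores


@njit(cache=True)
def accumulate_depth_importance(node_feat, node_chi, node_depth, out):
    """Add each internal node's 2^(-depth) * chi-square to out[feat]."""
    for t in range(node_feat.shape[0]):
        f = node_feat[t]
        if f >= 0:
            out[f] += 2.0 ** (-float(node_depth[t])) * node_chi[t]
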