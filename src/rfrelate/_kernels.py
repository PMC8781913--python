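"""Numba kernels for tree growth, surrogate search and prediction.

Everything in here is deterministic given the 64-bit seed state passed in:
the random stream is an xorshift64* generator advanced only inside these
kernels, so forests are bit-reproducible across runs and independent of
how trees are scheduled by the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_U = np.uint64

# ----------------------------------------------------------------------
# random stream (xorshift64*)
# ----------------------------------------------------------------------


@njit(cache=True)
def _rng_u64(state):
    s = state[0]
    s ^= s >> _U(12)
    s ^= s << _U(25)
    s ^= s >> _U(27)
    state[0] = s
    return s * _U(0x2545F4914F6CDD1D)


@njit(cache=True)
def _rng_uniform(state):
    # 53-bit mantissa uniform in [0, 1)
    return (_rng_u64(state) >> _U(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True)
def _rng_below(state, n):
    # modulo bias is negligible for n << 2^64
    return np.int64(_rng_u64(state) % _U(n))


@njit(cache=True)
def _shuffle(values, state):
    # Fisher-Yates, in place
    for i in range(values.shape[0] - 1, 0, -1):
        j = _rng_below(state, i + 1)
        tmp = values[i]
        values[i] = values[j]
        values[j] = tmp


# ----------------------------------------------------------------------
# split evaluation
# ----------------------------------------------------------------------


@njit(cache=True)
def _gini(counts, total):
    if total <= 0.0:
        return 0.0
    s = 0.0
    for c in range(counts.shape[0]):
        p = counts[c] / total
        s += p * p
    return 1.0 - s


@njit(cache=True)
def _eval_split(vals, order, cls, wts, tot_counts, total_w):
    """Best Gini-decrease split of one value vector.

    Thresholds are midpoints between consecutive distinct sorted values;
    ties in the decrease keep the lowest threshold.  Returns
    (decrease, threshold); decrease is -1.0 when no valid threshold exists.
    """
    k = tot_counts.shape[0]
    m = vals.shape[0]
    gp = _gini(tot_counts, total_w)
    left = np.zeros(k)
    right = tot_counts.copy()
    lw = 0.0
    best_dec = -1.0
    best_thr = 0.0
    for i in range(m - 1):
        j = order[i]
        c = cls[j]
        left[c] += wts[j]
        right[c] -= wts[j]
        lw += wts[j]
        v0 = vals[j]
        v1 = vals[order[i + 1]]
        if v1 > v0:
            rw = total_w - lw
            dec = gp - (lw * _gini(left, lw) + rw * _gini(right, rw)) / total_w
            if dec < 0.0:
                dec = 0.0  # guards float round-off; true decrease is >= 0
            if dec > best_dec:
                best_dec = dec
                best_thr = 0.5 * (v0 + v1)
    return best_dec, best_thr


@njit(cache=True)
def _eval_surrogate(vals, order, go_left, wts, total_w, left_w):
    """Best agreement split of one candidate surrogate feature.

    Scans thresholds (midpoints of distinct sorted values) in both
    directions; agreement A is the in-bag-weighted fraction of node samples
    routed to the same child as the primary split.  Returns
    (adjusted_agreement, threshold, flip) where flip=1 means "values <=
    threshold go right".  adjusted = (A - maj) / (1 - maj) with maj the
    weight share of the primary split's larger child.  Returns adjusted
    -2.0 when no threshold exists.
    """
    right_w = total_w - left_w
    maj = left_w if left_w >= right_w else right_w
    maj = maj / total_w
    m = vals.shape[0]
    cum_l = 0.0
    cum_w = 0.0
    best_a = -1.0
    best_thr = 0.0
    best_flip = 0
    for i in range(m - 1):
        j = order[i]
        if go_left[j]:
            cum_l += wts[j]
        cum_w += wts[j]
        v0 = vals[j]
        v1 = vals[order[i + 1]]
        if v1 > v0:
            # "<= thr goes left": agree = primary-left below + primary-right above
            a_norm = cum_l + (right_w - (cum_w - cum_l))
            a_flip = total_w - a_norm
            if a_norm >= a_flip:
                a = a_norm
                flip = 0
            else:
                a = a_flip
                flip = 1
            if a > best_a:
                best_a = a
                best_thr = 0.5 * (v0 + v1)
                best_flip = flip
    if best_a < 0.0:
        return -2.0, 0.0, 0
    adj = (best_a / total_w - maj) / (1.0 - maj)
    return adj, best_thr, best_flip


# ----------------------------------------------------------------------
# bootstrap
# ----------------------------------------------------------------------


@njit(cache=True)
def _bootstrap(cum_prob, n_draws, state, w_out):
    """Weighted sampling with replacement; w_out receives draw counts."""
    w_out[:] = 0.0
    n = cum_prob.shape[0]
    for _ in range(n_draws):
        u = _rng_uniform(state)
        lo = 0
        hi = n - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if u <= cum_prob[mid]:
                hi = mid
            else:
                lo = mid + 1
        w_out[lo] += 1.0


# ----------------------------------------------------------------------
# tree growth
# ----------------------------------------------------------------------


@njit(cache=True)
def _grow_tree(
    X,
    ycls,
    k,
    w_inbag,
    mtry,
    min_node_size,
    s_sur,
    air_mode,
    state,
    node_feature,
    node_threshold,
    node_left,
    node_right,
    node_depth,
    node_counts,
    sur_feat,
    sur_adj,
    sur_flip,
    sur_count,
    air_score,
    pool,
    sur_pool,
):
    """Grow one tree on the in-bag multiset encoded by ``w_inbag``.

    Nodes are laid out in preorder.  When ``air_mode`` is nonzero, each
    candidate feature competes both with its actual values and with a
    within-node permuted copy; the chosen variant's decrease is added to
    (actual) or subtracted from (permuted) ``air_score`` of that feature,
    and the node is routed by the winning variant.  Surrogates (when
    ``s_sur > 0``) mimic the realized primary assignment and are searched
    over all other features.

    Exact ties -- equal best gains among candidates, equal adjusted
    agreements among surrogate candidates -- are broken in seeded-random
    order (candidate draw order / a per-node feature permutation held in
    ``sur_pool``): ties are frequent at small nodes where agreement counts
    are discrete, and any fixed preference order would systematically
    favor some columns over others, distorting permutation-based null
    references.

    Returns the number of nodes written.
    """
    n, p = X.shape

    # distinct in-bag sample indices
    m_root = 0
    for i in range(n):
        if w_inbag[i] > 0.0:
            m_root += 1
    idx = np.empty(m_root, np.int64)
    j = 0
    for i in range(n):
        if w_inbag[i] > 0.0:
            idx[j] = i
            j += 1

    max_nodes = 2 * m_root + 1
    st_start = np.empty(max_nodes, np.int64)
    st_end = np.empty(max_nodes, np.int64)
    st_depth = np.empty(max_nodes, np.int64)
    st_parent = np.empty(max_nodes, np.int64)
    st_isleft = np.empty(max_nodes, np.int64)

    tmp = np.empty(m_root, np.int64)
    adj_all = np.empty(p)
    thr_all = np.empty(p)
    flip_all = np.empty(p, np.int8)

    w_root = 0.0
    for t in range(m_root):
        w_root += w_inbag[idx[t]]

    top = 0
    st_start[0] = 0
    st_end[0] = m_root
    st_depth[0] = 0
    st_parent[0] = -1
    st_isleft[0] = 0
    top = 1
    n_nodes = 0

    while top > 0:
        top -= 1
        start = st_start[top]
        end = st_end[top]
        depth = st_depth[top]
        parent = st_parent[top]
        isleft = st_isleft[top]

        nid = n_nodes
        n_nodes += 1
        if parent >= 0:
            if isleft == 1:
                node_left[parent] = nid
            else:
                node_right[parent] = nid
        node_depth[nid] = depth
        node_left[nid] = -1
        node_right[nid] = -1
        node_feature[nid] = -1
        node_threshold[nid] = 0.0
        sur_count[nid] = 0

        m = end - start
        total_w = 0.0
        for c in range(k):
            node_counts[nid, c] = 0.0
        for t in range(start, end):
            i = idx[t]
            node_counts[nid, ycls[i]] += w_inbag[i]
            total_w += w_inbag[i]
        max_c = 0.0
        for c in range(k):
            if node_counts[nid, c] > max_c:
                max_c = node_counts[nid, c]
        if m < 2 or m <= min_node_size or max_c == total_w:
            continue  # leaf

        # draw mtry candidate features (partial Fisher-Yates on the pool);
        # evaluation keeps the random draw order so gain ties break randomly
        for i in range(mtry):
            jj = i + _rng_below(state, p - i)
            tmp_f = pool[i]
            pool[i] = pool[jj]
            pool[jj] = tmp_f
        cand = pool[:mtry].copy()

        vals = np.empty(m)
        cls = np.empty(m, np.int64)
        wts = np.empty(m)
        for t in range(m):
            i = idx[start + t]
            cls[t] = ycls[i]
            wts[t] = w_inbag[i]

        perm_vals = np.empty(m)
        best_perm_vals = np.empty(m)
        best_dec = -1.0
        best_thr = 0.0
        best_feat = -1
        best_is_perm = 0
        counts_node = node_counts[nid].copy()

        for ci in range(mtry):
            f = cand[ci]
            for t in range(m):
                vals[t] = X[idx[start + t], f]
            order = np.argsort(vals)
            dec, thr = _eval_split(vals, order, cls, wts, counts_node, total_w)
            if dec > best_dec:
                best_dec = dec
                best_thr = thr
                best_feat = f
                best_is_perm = 0
            if air_mode != 0:
                for t in range(m):
                    perm_vals[t] = vals[t]
                _shuffle(perm_vals, state)
                order_p = np.argsort(perm_vals)
                dec_p, thr_p = _eval_split(
                    perm_vals, order_p, cls, wts, counts_node, total_w
                )
                if dec_p > best_dec:
                    best_dec = dec_p
                    best_thr = thr_p
                    best_feat = f
                    best_is_perm = 1
                    for t in range(m):
                        best_perm_vals[t] = perm_vals[t]

        if best_dec < 0.0:
            continue  # no candidate admits a split: leaf

        go_left = np.empty(m, np.bool_)
        if best_is_perm == 1:
            for t in range(m):
                go_left[t] = best_perm_vals[t] <= best_thr
        else:
            for t in range(m):
                go_left[t] = X[idx[start + t], best_feat] <= best_thr

        if air_mode != 0:
            contrib = best_dec * (total_w / w_root)
            if best_is_perm == 1:
                air_score[best_feat] -= contrib
            else:
                air_score[best_feat] += contrib

        node_feature[nid] = best_feat
        node_threshold[nid] = best_thr

        # surrogate search over all other features
        if s_sur > 0:
            left_w = 0.0
            for t in range(m):
                if go_left[t]:
                    left_w += wts[t]
            maj = left_w if left_w >= total_w - left_w else total_w - left_w
            if maj < total_w:  # degenerate primary -> no surrogates
                for f in range(p):
                    if f == best_feat:
                        adj_all[f] = -2.0
                        continue
                    for t in range(m):
                        vals[t] = X[idx[start + t], f]
                    order = np.argsort(vals)
                    adj, thr, flip = _eval_surrogate(
                        vals, order, go_left, wts, total_w, left_w
                    )
                    adj_all[f] = adj
                    thr_all[f] = thr
                    flip_all[f] = flip
                # per-node random feature order for tie-free top-s selection
                for i in range(p - 1, 0, -1):
                    jj = _rng_below(state, i + 1)
                    tmp_f = sur_pool[i]
                    sur_pool[i] = sur_pool[jj]
                    sur_pool[jj] = tmp_f
                ns = 0
                for r in range(s_sur):
                    best_a = 0.0
                    best_f = -1
                    for fi in range(p):
                        f = sur_pool[fi]
                        if adj_all[f] > best_a:
                            best_a = adj_all[f]
                            best_f = f
                    if best_f < 0:
                        break
                    sur_feat[nid, ns] = best_f
                    sur_adj[nid, ns] = best_a
                    sur_flip[nid, ns] = flip_all[best_f]
                    adj_all[best_f] = -2.0
                    ns += 1
                sur_count[nid] = ns

        # stable partition of idx[start:end] by go_left
        pos = 0
        for t in range(m):
            if go_left[t]:
                tmp[pos] = idx[start + t]
                pos += 1
        mid = pos
        for t in range(m):
            if not go_left[t]:
                tmp[pos] = idx[start + t]
                pos += 1
        for t in range(m):
            idx[start + t] = tmp[t]

        # push right first so the left child is processed (numbered) first
        st_start[top] = start + mid
        st_end[top] = end
        st_depth[top] = depth + 1
        st_parent[top] = nid
        st_isleft[top] = 0
        top += 1
        st_start[top] = start
        st_end[top] = start + mid
        st_depth[top] = depth + 1
        st_parent[top] = nid
        st_isleft[top] = 1
        top += 1

    return n_nodes


# ----------------------------------------------------------------------
# prediction
# ----------------------------------------------------------------------


@njit(cache=True)
def _accumulate_leaf(
    Xq, feat, thr, left, right, offsets, leaf_payload, inbag, oob_only, out, n_trees_used
):
    """Sum leaf payload vectors over trees per query sample.

    leaf_payload is (n_nodes_total, k); for probability forests it holds
    leaf class proportions, for vote prediction a one-hot majority vector.
    """
    nq = Xq.shape[0]
    ntree = offsets.shape[0] - 1
    k = leaf_payload.shape[1]
    for i in range(nq):
        used = 0
        for t in range(ntree):
            if oob_only != 0 and inbag[t, i] > 0:
                continue
            node = offsets[t]
            while feat[node] >= 0:
                if Xq[i, feat[node]] <= thr[node]:
                    node = left[node]
                else:
                    node = right[node]
            for c in range(k):
                out[i, c] += leaf_payload[node, c]
            used += 1
        n_trees_used[i] = used


@njit(cache=True)
def _smd_accumulate(feat, depth, sur_feat, sur_count, offsets, p, out_sum):
    """Add each tree's per-feature surrogate minimal depth to out_sum.

    A feature absent from a tree (never primary, never surrogate) is
    assigned that tree's maximal node depth.
    """
    ntree = offsets.shape[0] - 1
    md = np.empty(p)
    for t in range(ntree):
        lo = offsets[t]
        hi = offsets[t + 1]
        maxd = 0
        for nd in range(lo, hi):
            if depth[nd] > maxd:
                maxd = depth[nd]
        for f in range(p):
            md[f] = maxd
        for nd in range(lo, hi):
            f = feat[nd]
            if f >= 0:
                d = depth[nd]
                if d < md[f]:
                    md[f] = d
                for si in range(sur_count[nd]):
                    g = sur_feat[nd, si]
                    if d < md[g]:
                        md[g] = d
        for f in range(p):
            out_sum[f] += md[f]


@njit(cache=True)
def _maa_accumulate(feat, sur_feat, sur_adj, sur_count, adj_sum, primary_nodes):
    """Accumulate surrogate adjusted agreements by (surrogate, primary) pair."""
    n_nodes = feat.shape[0]
    for nd in range(n_nodes):
        j = feat[nd]
        if j >= 0:
            primary_nodes[j] += 1
            for si in range(sur_count[nd]):
                i = sur_feat[nd, si]
                adj_sum[i, j] += sur_adj[nd, si]
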