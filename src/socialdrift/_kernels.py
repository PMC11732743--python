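"""Jitted inner loops.

The social-group simulator advances whole populations tick by tick for tens
of thousands of ticks; the conditional equilibrium-heterozygosity simulator
places mutations one at a time on millions of genealogies.  Both are
implemented twice: a readable numpy reference path in their home modules and
the equivalent single-pass kernels here, compiled with numba.  The kernels
follow exactly the same event rules and draw all randomness from the same
``numpy.random.Generator``; tests assert rule-level postconditions against
both paths.

Only ``Generator.random()`` is consumed inside the kernels; discrete draws
go through inverse-CDF tables and random bits are extracted 48 at a time
from one double (a double carries 53 random bits).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def wrap(f):
            return f

        if a and callable(a[0]):
            return a[0]
        return wrap


_BITCHUNK = 48


@njit(cache=True, inline="always")
def _cdf_draw(cdf, u):
    """Index of the first cdf entry >= u (inverse-CDF sampling)."""
    lo, hi = 0, len(cdf) - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if cdf[mid] < u:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def _count_distinct(states, scratch):
    n = states.size
    for i in range(n):
        scratch[i] = states[i]
    scratch[:n].sort()
    k = 1
    for i in range(1, n):
        if scratch[i] != scratch[i - 1]:
            k += 1
    return k


@njit(cache=True)
def first_passage_states(cum, leaf_sets, k_target, cap, states, scratch, rng):
    """Add SMM mutations uniformly on the tree until k_target alleles.

    ``cum`` is the cumulative branch-length vector, ``leaf_sets`` the
    (n_nodes, n_leaves) boolean incidence matrix.  ``states`` is zeroed and
    filled in place.  Returns the mutation count, or -1 if ``cap`` was hit
    (caller redraws the genealogy).
    """
    n = states.size
    for i in range(n):
        states[i] = 0
    if k_target == 1:
        return 0
    total = cum[len(cum) - 1]
    n_mut = 0
    while n_mut < cap:
        u = rng.random() * total
        b = _cdf_draw(cum, u)
        step = 1 if rng.random() < 0.5 else -1
        for leaf in range(n):
            if leaf_sets[b, leaf]:
                states[leaf] += step
        n_mut += 1
        if _count_distinct(states, scratch) == k_target:
            return n_mut
    return -1


@njit(cache=True)
def last_exit_states(cum, leaf_sets, k_target, cap, states, kept, scratch, rng):
    """Add SMM mutations until the allele count first exceeds k_target and
    keep the configuration seen at the last visit to exactly k_target.

    Homoplasy keeps reshuffling a k-allele configuration before a further
    allele establishes, so the retained sample reflects the mutation-drift
    balance at that allele number rather than the instant the k-th allele
    first arose.  ``kept`` receives the retained configuration.  Returns
    the mutation count at the retained visit, or -1 if no k_target-allele
    configuration was visited within ``cap`` mutations (caller redraws).
    """
    n = states.size
    for i in range(n):
        states[i] = 0
        kept[i] = 0
    if k_target == 1:
        return 0
    total = cum[len(cum) - 1]
    n_mut = 0
    visited = -1
    while n_mut < cap:
        u = rng.random() * total
        b = _cdf_draw(cum, u)
        step = 1 if rng.random() < 0.5 else -1
        for leaf in range(n):
            if leaf_sets[b, leaf]:
                states[leaf] += step
        n_mut += 1
        k = _count_distinct(states, scratch)
        if k == k_target:
            for i in range(n):
                kept[i] = states[i]
            visited = n_mut
        elif k > k_target and visited > 0:
            return visited
    return visited


@njit(cache=True)
def conditional_heq_batch(n_genes, k_target, n_reps, cap, rule, rng):
    """Batch of conditional equilibrium-heterozygosity replicates.

    For each replicate: draw a Kingman genealogy (rate k(k-1) in 4N units,
    uniform pair choice), add SMM mutations uniformly on the tree until the
    sample carries ``k_target`` alleles (``rule`` 0: first passage; 1:
    last k-allele visit before the count first exceeds k), and return the
    unbiased gene diversity of that configuration.  A replicate that fails
    within ``cap`` mutations is discarded and redrawn with a fresh
    genealogy.
    """
    n = n_genes
    n_nodes = 2 * n - 1
    leaf_sets = np.zeros((n_nodes, n), np.bool_)
    node_time = np.zeros(n_nodes)
    branch_length = np.zeros(n_nodes)
    cum = np.zeros(n_nodes)
    active = np.zeros(n, np.int64)
    parent = np.zeros(n_nodes, np.int64)
    states = np.zeros(n, np.int64)
    kept = np.zeros(n, np.int64)
    scratch = np.zeros(n, np.int64)
    out = np.empty(n_reps)
    r = 0
    while r < n_reps:
        # --- genealogy -------------------------------------------------
        for v in range(n_nodes):
            node_time[v] = 0.0
            for leaf in range(n):
                leaf_sets[v, leaf] = False
        for leaf in range(n):
            leaf_sets[leaf, leaf] = True
            active[leaf] = leaf
        t = 0.0
        for step in range(n - 1):
            k = n - step
            t += -np.log(rng.random()) / (k * (k - 1.0))
            i = np.int64(rng.random() * k)
            a = active[i]
            active[i] = active[k - 1]
            j = np.int64(rng.random() * (k - 1))
            b = active[j]
            new = n + step
            active[j] = new
            parent[a] = new
            parent[b] = new
            node_time[new] = t
            for leaf in range(n):
                leaf_sets[new, leaf] = leaf_sets[a, leaf] or leaf_sets[b, leaf]
        total = 0.0
        for v in range(n_nodes - 1):
            branch_length[v] = node_time[parent[v]] - node_time[v]
            total += branch_length[v]
            cum[v] = total
        cum[n_nodes - 1] = total  # root carries no branch

        # --- conditional SMM mutations ----------------------------------
        if rule == 0:
            n_mut = first_passage_states(
                cum, leaf_sets, k_target, cap, states, scratch, rng
            )
            final = states
        else:
            n_mut = last_exit_states(
                cum, leaf_sets, k_target, cap, states, kept, scratch, rng
            )
            final = kept
        if n_mut < 0:
            continue
        # --- unbiased gene diversity of the final configuration ---------
        for idx in range(n):
            scratch[idx] = final[idx]
        scratch.sort()
        sum_sq = 0.0
        run = 1
        for idx in range(1, n):
            if scratch[idx] == scratch[idx - 1]:
                run += 1
            else:
                sum_sq += run * run
                run = 1
        sum_sq += run * run
        nn = float(n)
        out[r] = nn / (nn - 1.0) * (1.0 - sum_sq / (nn * nn))
        r += 1
    return out


@njit(cache=True)
def social_tick(
    meta,
    alive,
    female,
    age,
    lifespan,
    group,
    rs,
    last_birth,
    geno,
    free,
    lifespan_cdf,
    litter_cdf,
    n_groups,
    quota_m,
    quota_f,
    rep_age,
    birth_interval,
    infant_mortality,
    log1m_mu,
    rng,
):
    """One tick: aging, mortality, reproduction, vacancy filling, colonization.

    ``meta`` = [top, n_free, tick], updated in place.  ``free`` is the
    recycled-slot stack.  Gamete mutations use geometric skipping over the
    transmitted-allele stream (restarted each tick; geometric waiting times
    are memoryless, so the restart is distribution-neutral).  The caller
    guarantees slot headroom for the worst-case number of births.
    """
    top = meta[0]
    n_free = meta[1]
    tick = meta[2]
    G = n_groups
    L = geno.shape[1]

    # ---- aging and mortality -------------------------------------------
    for i in range(top):
        if alive[i]:
            age[i] += 1
            if age[i] > lifespan[i]:
                alive[i] = False
                rs[i] = False
                free[n_free] = i
                n_free += 1

    # ---- per-group RS male lists for father assignment ------------------
    rsm_cnt = np.zeros(G, np.int64)
    for i in range(top):
        if alive[i] and rs[i] and not female[i]:
            rsm_cnt[group[i]] += 1
    m_off = np.zeros(G + 1, np.int64)
    for g in range(G):
        m_off[g + 1] = m_off[g] + rsm_cnt[g]
    mlist = np.empty(m_off[G], np.int64)
    cursor = m_off[:G].copy()
    for i in range(top):
        if alive[i] and rs[i] and not female[i]:
            g = group[i]
            mlist[cursor[g]] = i
            cursor[g] += 1

    # ---- reproduction ----------------------------------------------------
    # geometric skip until the next mutated transmitted allele
    if log1m_mu < 0.0:
        skip = np.int64(np.log(rng.random()) / log1m_mu)
    else:
        skip = np.int64(1) << 60  # mu = 0: never mutate
    bitword = np.int64(0)
    nbits = 0
    top0 = top
    n_born = 0
    for i in range(top0):
        if not (alive[i] and rs[i] and female[i]):
            continue
        if age[i] < rep_age or tick - last_birth[i] < birth_interval:
            continue
        g = group[i]
        if rsm_cnt[g] == 0:
            continue
        father = mlist[m_off[g] + np.int64(rng.random() * rsm_cnt[g])]
        last_birth[i] = tick
        litter = _cdf_draw(litter_cdf, rng.random())
        for _ in range(litter):
            if rng.random() < infant_mortality:
                continue
            if n_free > 0:
                n_free -= 1
                slot = free[n_free]
            else:
                slot = top
                top += 1
            alive[slot] = True
            female[slot] = rng.random() < 0.5
            age[slot] = 0
            lifespan[slot] = _cdf_draw(lifespan_cdf, rng.random())
            group[slot] = g
            rs[slot] = False
            last_birth[slot] = -(np.int64(1) << 30)
            n_born += 1
            if L > 0:
                for c in range(2):
                    parent = father if c == 0 else i
                    for l in range(L):
                        if nbits == 0:
                            bitword = np.int64(rng.random() * 281474976710656.0)
                            nbits = _BITCHUNK
                        pick = bitword & 1
                        bitword >>= 1
                        nbits -= 1
                        allele = geno[parent, l, pick]
                        if skip == 0:
                            if nbits == 0:
                                bitword = np.int64(rng.random() * 281474976710656.0)
                                nbits = _BITCHUNK
                            allele += np.int16(1) if (bitword & 1) else np.int16(-1)
                            bitword >>= 1
                            nbits -= 1
                            skip = np.int64(np.log(rng.random()) / log1m_mu)
                        else:
                            skip -= 1
                        geno[slot, l, c] = allele

    # ---- vacancy filling --------------------------------------------------
    rsf_cnt = np.zeros(G, np.int64)
    rsm_cnt2 = np.zeros(G, np.int64)
    for i in range(top):
        if alive[i] and rs[i]:
            if female[i]:
                rsf_cnt[group[i]] += 1
            else:
                rsm_cnt2[group[i]] += 1

    # candidate lists: non-RS adults by sex (flat, with group ids implicit)
    n_cf = 0
    n_cm = 0
    for i in range(top):
        if alive[i] and not rs[i] and age[i] >= rep_age:
            if female[i]:
                n_cf += 1
            else:
                n_cm += 1
    cand_f = np.empty(n_cf, np.int64)
    cand_m = np.empty(n_cm, np.int64)
    a = 0
    b = 0
    for i in range(top):
        if alive[i] and not rs[i] and age[i] >= rep_age:
            if female[i]:
                cand_f[a] = i
                a += 1
            else:
                cand_m[b] = i
                b += 1

    for g in range(G):
        # female slots: strictly philopatric
        need = quota_f - rsf_cnt[g]
        while need > 0:
            chosen = np.int64(-1)
            for _ in range(64):  # in-group rejection sampling
                if n_cf == 0:
                    break
                j = cand_f[np.int64(rng.random() * n_cf)]
                if not rs[j] and group[j] == g:
                    chosen = j
                    break
            if chosen < 0:  # deterministic scan: any in-group candidate?
                for idx in range(n_cf):
                    j = cand_f[idx]
                    if not rs[j] and group[j] == g:
                        chosen = j
                        break
            if chosen < 0:
                break
            rs[chosen] = True
            rsf_cnt[g] += 1
            need -= 1
        # male slots: migrants only, and only into a group that still has
        # a breeding female (males migrate to reproduce)
        if rsf_cnt[g] == 0:
            continue
        need = quota_m - rsm_cnt2[g]
        while need > 0:
            chosen = np.int64(-1)
            for _ in range(64):
                if n_cm == 0:
                    break
                j = cand_m[np.int64(rng.random() * n_cm)]
                if not rs[j] and group[j] != g:
                    chosen = j
                    break
            if chosen < 0:
                for idx in range(n_cm):
                    j = cand_m[idx]
                    if not rs[j] and group[j] != g:
                        chosen = j
                        break
            if chosen < 0:
                break
            rs[chosen] = True
            group[chosen] = g
            need -= 1

    # ---- colonization of vanished groups ----------------------------------
    members = np.zeros(G, np.int64)
    for i in range(top):
        if alive[i]:
            members[group[i]] += 1
    for g in range(G):
        if members[g] != 0:
            continue
        avail_m = 0
        avail_f = 0
        for idx in range(n_cm):
            j = cand_m[idx]
            if not rs[j]:
                avail_m += 1
        for idx in range(n_cf):
            j = cand_f[idx]
            if not rs[j]:
                avail_f += 1
        if avail_m < quota_m or avail_f < quota_f:
            continue
        placed = 0
        while placed < quota_m:
            chosen = np.int64(-1)
            for _ in range(64):
                j = cand_m[np.int64(rng.random() * n_cm)]
                if not rs[j]:
                    chosen = j
                    break
            if chosen < 0:
                for idx in range(n_cm):
                    j = cand_m[idx]
                    if not rs[j]:
                        chosen = j
                        break
            rs[chosen] = True
            group[chosen] = g
            placed += 1
        placed = 0
        while placed < quota_f:
            chosen = np.int64(-1)
            for _ in range(64):
                j = cand_f[np.int64(rng.random() * n_cf)]
                if not rs[j]:
                    chosen = j
                    break
            if chosen < 0:
                for idx in range(n_cf):
                    j = cand_f[idx]
                    if not rs[j]:
                        chosen = j
                        break
            rs[chosen] = True
            group[chosen] = g
            placed += 1
        members[g] = quota_m + quota_f

    meta[0] = top
    meta[1] = n_free
    meta[2] = tick + 1
    return n_born
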