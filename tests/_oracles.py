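"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized/sufficient-statistics code
paths: correlations come from scipy.stats.pearsonr on explicitly assembled
vectors, neighbor search is a plain sort, and prediction/leave-one-out are
nested loops over gene pairs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from emaplink import EMapMatrix


def random_screens(
    seed: int,
    n_shared: int = 5,
    n_a: int = 5,
    n_b: int = 5,
    missing: float = 0.25,
    scale: float = 2.0,
) -> tuple[EMapMatrix, EMapMatrix]:
    """Two independent random screens over overlapping gene sets."""
    rng = np.random.default_rng(seed)
    shared = [f"s{i:02d}" for i in range(n_shared)]
    a_only = [f"a{i:02d}" for i in range(n_a)]
    b_only = [f"b{i:02d}" for i in range(n_b)]

    def mat(genes, label):
        n = len(genes)
        a = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        v = rng.normal(0, scale, len(iu[0]))
        v[rng.random(len(iu[0])) < missing] = np.nan
        a[iu] = v
        a = a + a.T
        np.fill_diagonal(a, np.nan)
        return EMapMatrix(pd.DataFrame(a, index=genes, columns=genes), name=label)

    return mat(shared + a_only, "A"), mat(shared + b_only, "B")


def bf_profile_corr(emap, x, y, min_support):
    """Pearson correlation over co-measured partners, mutual cells excluded."""
    xs, ys = [], []
    for g in emap.alleles:
        if g == x or g == y:
            continue
        vx = emap.get(x, g)
        vy = emap.get(y, g)
        if vx is not None and vy is not None:
            xs.append(vx)
            ys.append(vy)
    if len(xs) < max(min_support, 2):
        return None
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        return None
    r = stats.pearsonr(xs, ys).statistic
    if np.isnan(r):
        return None
    return float(r), len(xs)

def bf_nearest(emap, gene, anchors, threshold, min_support):
    """Best anchor by r desc, support desc, identifier asc; None below threshold."""
    cands = []
    for a in anchors:
        if a == gene:
            continue
        res = bf_profile_corr(emap, gene, a, min_support)
        if res is not None:
            cands.append((res[0], res[1], a))
    if not cands:
        return None
    cands.sort(key=lambda t: (-t[0], -t[1], t[2]))
    r, n, a = cands[0]
    return (a, r) if r >= threshold else None


def bf_predict(emap_a, emap_b, threshold, min_support):
    """Nested-loop cross-screen prediction: pair -> (score, sorted source values)."""
    set_a, set_b = set(emap_a.alleles), set(emap_b.alleles)
    overlap = [g for g in emap_a.alleles if g in set_b]
    a_only = [g for g in emap_a.alleles if g not in set_b]
    b_only = [g for g in emap_b.alleles if g not in set_a]
    nearest_b = {j: bf_nearest(emap_b, j, overlap, threshold, min_support) for j in b_only}
    out = {}
    for i in a_only:
        ni = bf_nearest(emap_a, i, overlap, threshold, min_support)
        for j in b_only:
            sources = []
            if ni is not None:
                v = emap_b.get(ni[0], j)
                if v is not None:
                    sources.append(v)
            nj = nearest_b[j]
            if nj is not None:
                v = emap_a.get(i, nj[0])
                if v is not None:
                    sources.append(v)
            if sources:
                out[(i, j)] = (float(np.mean(sources)), tuple(sorted(sources)))
    return out


def bf_leave_one_out(emap_a, emap_b, threshold, min_support):
    """Nested-loop leave-one-out with full matrix copies per withheld cell."""
    out = {}
    for screen, partner in ((emap_a, emap_b), (emap_b, emap_a)):
        partner_set = set(partner.alleles)
        overlap = sorted(g for g in screen.alleles if g in partner_set)
        queries = sorted(g for g in screen.alleles if g not in partner_set)
        for i in queries:
            for s in overlap:
                if screen.get(i, s) is None:
                    continue
                held = screen.data.copy()
                held.at[i, s] = np.nan
                held.at[s, i] = np.nan
                withheld = EMapMatrix(held, name=screen.name)
                sources = []
                ni = bf_nearest(withheld, i, overlap, threshold, min_support)
                if ni is not None:
                    v = withheld.get(ni[0], s)
                    if v is not None:
                        sources.append(v)
                ns = bf_nearest(partner, s, overlap, threshold, min_support)
                if ns is not None:
                    v = withheld.get(i, ns[0])
                    if v is not None:
                        sources.append(v)
                if sources:
                    out[(screen.name, i, s)] = float(np.mean(sources))
    return out


def mc_enrichment_pvalue(N, K, n, k_obs, n_draws, rng):
    """Monte-Carlo upper-tail P(overlap >= k_obs) drawing n of N with K successes."""
    count = 0
    for _ in range(n_draws):
        idx = rng.permutation(N)[:n]
        if int((idx < K).sum()) >= k_obs:
            count += 1
    return count / n_draws
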