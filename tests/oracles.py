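"""Brute-force reference implementations used only to check the package.

Every function here recomputes a quantity by direct enumeration (explicit
loops over branches, permutations or pairs), independently of the
vectorised incidence-matrix code paths in the package.
"""

import itertools

import numpy as np
from scipy import stats


def branch_list(tree):
    """(length, tip_name_set) for every non-root branch, via skbio subsets."""
    out = []
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            tips = {node.name}
        else:
            tips = {t.name for t in node.tips()}
        out.append((node.length or 0.0, tips))
    return out


def faith_pd_bruteforce(present, tree):
    present = set(present)
    total = 0.0
    for length, tips in branch_list(tree):
        if tips & present:
            total += length
    return total


def allen_entropy_bruteforce(proportions, tree):
    h = 0.0
    for length, tips in branch_list(tree):
        p = sum(proportions.get(t, 0.0) for t in tips)
        if p > 0:
            h += length * (-p * np.log(p))
    tbar = 0.0
    for tip in tree.tips():
        depth = 0.0
        node = tip
        while node.parent is not None:
            depth += node.length or 0.0
            node = node.parent
        tbar += proportions.get(tip.name, 0.0) * depth
    return h, float(np.exp(h / tbar)) if tbar > 0 else 1.0


def unifrac_bruteforce(counts_a, counts_b, tree, weighted):
    """counts_* map tip name -> count for one sample each."""
    ta = sum(counts_a.values())
    tb = sum(counts_b.values())
    num = den = 0.0
    for length, tips in branch_list(tree):
        pa = sum(counts_a.get(t, 0) for t in tips) / ta
        pb = sum(counts_b.get(t, 0) for t in tips) / tb
        if weighted:
            num += length * abs(pa - pb)
            den += length * (pa + pb)
        else:
            ia, ib = pa > 0, pb > 0
            num += length * (1.0 if ia != ib else 0.0)
            den += length * (1.0 if (ia or ib) else 0.0)
    return num / den if den > 0 else 0.0


def permanova_f(d2, labels):
    labels = np.asarray(labels)
    n = len(labels)
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in set(labels):
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(d2[i, j] for i in idx for j in idx if i < j) \
            / len(idx)
    a = len(set(labels))
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova_exhaustive_p(d, labels):
    """Exact p over every distinct relabeling (labeled groups)."""
    d2 = np.asarray(d) ** 2
    labels = list(labels)
    f_obs = permanova_f(d2, labels)
    count = total = 0
    for perm in set(itertools.permutations(labels)):
        f = permanova_f(d2, list(perm))
        total += 1
        if f >= f_obs - 1e-12:
            count += 1
    return count / total


def mantel_exhaustive_p(d1, d2, method="spearman"):
    n = d1.shape[0]
    iu = np.triu_indices(n, 1)
    def corr(a, b):
        if method == "spearman":
            return np.corrcoef(stats.rankdata(a), stats.rankdata(b))[0, 1]
        return np.corrcoef(a, b)[0, 1]
    r_obs = corr(d1[iu], d2[iu])
    count = total = 0
    for perm in itertools.permutations(range(n)):
        p = np.asarray(perm)
        r = corr(d1[iu], d2[np.ix_(p, p)][iu])
        total += 1
        if r >= r_obs - 1e-12:
            count += 1
    return count / total


def kw_exhaustive_p(values, labels):
    """Exact Kruskal-Wallis p over all labeled assignments of observations."""
    values = np.asarray(values, dtype=float)
    labels = list(labels)
    uniq = sorted(set(labels), key=str)
    sizes = [labels.count(g) for g in uniq]

    def h_stat(lab):
        groups = [values[[i for i in range(len(lab)) if lab[i] == g]]
                  for g in uniq]
        return stats.kruskal(*groups).statistic

    h_obs = h_stat(labels)
    count = total = 0
    for perm in set(itertools.permutations(labels)):
        total += 1
        if h_stat(list(perm)) >= h_obs - 1e-12:
            count += 1
    return count / total
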