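"""Independent brute-force oracles used to validate the estimators.

These are deliberately written from the defining sums of squares /
sums over alleles with explicit Python loops, sharing no code with the
package implementations they check.
"""

from __future__ import annotations

import numpy as np


def wc_components_oracle(genotypes: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Weir-Cockerham (a, b, c) per locus from the three-level ANOVA
    mean squares on gene-copy allele indicators.

    a = (MSP - MSI) / (2 n_c),  b = (MSI - MSG) / 2,  c = MSG,
    with MSP/MSI/MSG the among-population, among-individual-within-
    population and within-individual mean squares.
    """
    genotypes = np.asarray(genotypes)
    groups = np.asarray(groups)
    L = genotypes.shape[1]
    out = np.full((L, 3), np.nan)
    for l in range(L):
        pair = genotypes[:, l, :]
        typed = (pair != 0).all(axis=1)
        labels = [
            g for g in dict.fromkeys(groups) if (typed & (groups == g)).sum() > 0
        ]
        n_i = [int((typed & (groups == g)).sum()) for g in labels]
        r = len(labels)
        if r < 2:
            continue
        n = sum(n_i)
        n_bar = n / r
        if n_bar <= 1:
            continue
        n_c = (n - sum(x * x for x in n_i) / n) / (r - 1)
        if n_c <= 0:
            continue
        alleles = sorted(set(pair[typed].ravel().tolist()))
        a_tot = b_tot = c_tot = 0.0
        for al in alleles:
            all_copies = []
            ssp = ssi = ssg = 0.0
            per_group = []
            for g in labels:
                rows = pair[typed & (groups == g)]
                copies = [
                    [1.0 if rows[i, k] == al else 0.0 for k in (0, 1)]
                    for i in range(len(rows))
                ]
                per_group.append(copies)
                for c2 in copies:
                    all_copies.extend(c2)
            grand = sum(all_copies) / len(all_copies)
            for g_idx, copies in enumerate(per_group):
                flat = [v for c2 in copies for v in c2]
                gmean = sum(flat) / len(flat)
                ssp += len(flat) * (gmean - grand) ** 2
                for c2 in copies:
                    imean = (c2[0] + c2[1]) / 2
                    ssi += 2 * (imean - gmean) ** 2
                    ssg += (c2[0] - imean) ** 2 + (c2[1] - imean) ** 2
            msp = ssp / (r - 1)
            msi = ssi / (n - r)
            msg = ssg / n
            a_tot += (msp - msi) / (2 * n_c)
            b_tot += (msi - msg) / 2
            c_tot += msg
        out[l] = (a_tot, b_tot, c_tot)
    return out


def haploid_theta_oracle(haps: np.ndarray, groups: np.ndarray) -> float:
    """Weir-Cockerham theta for haploid data via the one-way ANOVA on
    allele indicators: theta = (MSP - MSG)/(MSP + (n_c - 1) MSG)."""
    haps = np.asarray(haps)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups))
    r = len(labels)
    sizes = np.array([(groups == g).sum() for g in labels], float)
    n = sizes.sum()
    n_c = (n - (sizes**2).sum() / n) / (r - 1)
    ssp = ssg = 0.0
    for al in sorted(set(haps.tolist())):
        y = (haps == al).astype(float)
        grand = y.mean()
        for g, sz in zip(labels, sizes):
            yg = y[groups == g]
            ssp += sz * (yg.mean() - grand) ** 2
            ssg += ((yg - yg.mean()) ** 2).sum()
    msp = ssp / (r - 1)
    msg = ssg / (n - r)
    return (msp - msg) / (msp + (n_c - 1) * msg)


def loiselle_oracle(genotypes: np.ndarray) -> np.ndarray:
    """Pairwise Loiselle kinship by explicit sums over loci and alleles."""
    genotypes = np.asarray(genotypes)
    n, L, _ = genotypes.shape
    num = np.zeros((n, n))
    typed_pair = np.zeros((n, n), bool)
    den = 0.0
    for l in range(L):
        pair = genotypes[:, l, :]
        typed = (pair != 0).all(axis=1)
        copies = pair[typed].ravel().tolist()
        if not copies:
            continue
        alleles = sorted(set(copies))
        if len(alleles) < 2:
            continue
        n_copies = len(copies)
        p = {a: copies.count(a) / n_copies for a in alleles}
        den += sum(pa * (1 - pa) for pa in p.values())
        corr = sum(pa * (1 - pa) for pa in p.values()) / (n_copies - 1)
        for i in range(n):
            if not typed[i]:
                continue
            for j in range(n):
                if not typed[j]:
                    continue
                s = 0.0
                for a in alleles:
                    xi = (
                        (1 if pair[i, 0] == a else 0) + (1 if pair[i, 1] == a else 0)
                    ) / 2
                    xj = (
                        (1 if pair[j, 0] == a else 0) + (1 if pair[j, 1] == a else 0)
                    ) / 2
                    s += (xi - p[a]) * (xj - p[a])
                num[i, j] += s + corr
                typed_pair[i, j] = True
    out = num / den
    out[~typed_pair] = np.nan
    return out
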