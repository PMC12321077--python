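"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: plain floats, explicit loops, no
log-space tricks and no shared code with the package.
"""

from __future__ import annotations

import math
import statistics


def wakefield_bf(beta: float, se: float, prior_sd: float) -> float:
    """Wakefield approximate Bayes factor on the natural scale."""
    v = se * se
    w = prior_sd * prior_sd
    z = beta / se
    return math.sqrt(v / (v + w)) * math.exp(0.5 * z * z * w / (v + w))


def coloc_enumerate(beta1, se1, beta2, se2, priors, prior_sd):
    """Posterior over H0..H4 by explicit enumeration of causal configurations.

    Configurations: the empty one (H0), m single-causal ones per trait
    (H1/H2), m*(m-1) ordered distinct pairs (H3) and m shared ones (H4),
    weighted by per-SNP priors and per-configuration Bayes factors.
    """
    p1, p2, p12 = priors
    m = len(beta1)
    bf1 = [wakefield_bf(beta1[i], se1[i], prior_sd[0]) for i in range(m)]
    bf2 = [wakefield_bf(beta2[i], se2[i], prior_sd[1]) for i in range(m)]
    w0 = 1.0
    w1 = sum(p1 * b for b in bf1)
    w2 = sum(p2 * b for b in bf2)
    w3 = 0.0
    for i in range(m):
        for j in range(m):
            if i != j:
                w3 += p1 * p2 * bf1[i] * bf2[j]
    w4 = sum(p12 * bf1[i] * bf2[i] for i in range(m))
    tot = w0 + w1 + w2 + w3 + w4
    return [w0 / tot, w1 / tot, w2 / tot, w3 / tot, w4 / tot]


def naive_trimmed_mean(values, trim):
    """Sort, drop floor(trim*n) per tail, average; SE = stdev/sqrt(k)."""
    vals = sorted(values)
    k = int(math.floor(trim * len(vals)))
    kept = vals[k : len(vals) - k]
    mean = sum(kept) / len(kept)
    se = 0.0 if len(kept) == 1 else statistics.stdev(kept) / math.sqrt(len(kept))
    return mean, se


def naive_bh(pvals):
    """O(n^2) Benjamini-Hochberg step-up adjusted p-values."""
    n = len(pvals)
    qs = []
    for p in pvals:
        candidates = []
        for pj in pvals:
            if pj >= p:
                rank = sum(1 for pk in pvals if pk <= pj)
                candidates.append(min(1.0, n * pj / rank))
        qs.append(min(candidates))
    return qs


def naive_dedupe(rows):
    """One row per (side_effect, gene): min qval, then max f_stat, then min snp."""
    best = {}
    for r in rows:
        key = (r["side_effect"], r["gene"])
        if key not in best:
            best[key] = r
            continue
        b = best[key]
        cand = (r["qval"], -r["f_stat"], r["snp"])
        cur = (b["qval"], -b["f_stat"], b["snp"])
        if cand < cur:
            best[key] = r
    return sorted(best.values(), key=lambda r: (r["side_effect"], r["gene"]))


def naive_aggregate(terms):
    """Group sums of signed and absolute term values per drug / receptor / side-effect."""
    drugs, receptors, entries = {}, {}, {}
    for t in terms:
        v = t["signed_value"]
        d = t["drug"]
        drugs.setdefault(d, [0.0, 0.0])
        drugs[d][0] += v
        drugs[d][1] += abs(v)
        rk = (d, t["receptor"])
        receptors.setdefault(rk, [0.0, 0.0])
        receptors[rk][0] += v
        receptors[rk][1] += abs(v)
        ek = (d, t["side_effect"])
        entries.setdefault(ek, [0.0, 0.0])
        entries[ek][0] += v
        entries[ek][1] += abs(v)
    return drugs, receptors, entries
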