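"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written from first principles (per-base scans, term-by-
term series, naive definitions) and deliberately shares no code with the
package internals it checks.
"""

from __future__ import annotations

import math

import numpy as np


def poisson_tail_series(k: int, lam: float) -> float:
    """P(X >= k) by direct 64-bit term-by-term summation of the upper tail.

    The leading term is taken through log space so deep tails (p ~ 1e-300)
    keep full relative precision instead of cancelling against the CDF.
    """
    if k <= 0:
        return 1.0
    log_term = k * math.log(lam) - lam - math.lgamma(k + 1)  # log P(X = k)
    if log_term < -745.0:
        return 0.0  # below double-precision range
    term = math.exp(log_term)
    total = term
    j = k
    while True:
        j += 1
        term *= lam / j
        total += term
        if term == 0.0 or (term < total * 1e-18 and j > lam):
            break
    return total


def neglog10_poisson_tail_series(k: int, lam: float, n_terms: int = 400) -> float:
    """-log10 P(X >= k) via log-space tail summation (valid even when the
    tail underflows in linear space)."""
    if k <= 0:
        return 0.0
    p = poisson_tail_series(k, lam)
    if p > 1e-280:
        return -math.log10(p)
    log_terms = []
    for j in range(k, k + n_terms):
        log_terms.append(j * math.log(lam) - lam - math.lgamma(j + 1))
    m = max(log_terms)
    return -(m + math.log(sum(math.exp(t - m) for t in log_terms))) / math.log(10.0)


def bh_naive(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values by the textbook step-up definition."""
    p = list(map(float, pvalues))
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [0.0] * n
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        q[i] = running_min
    return np.array(q)


def brute_force_pileup(tags, shift, extsize, chrom_sizes):
    """Per-base coverage by looping over every window position of every tag."""
    cov = {c: np.zeros(l, dtype=np.int64) for c, l in chrom_sizes.items()}
    for t in tags:
        if t.strand == "+":
            cut = t.start
            wstart = cut + shift
        else:
            cut = t.end - 1
            wstart = cut - shift - extsize + 1
        for pos in range(wstart, wstart + extsize):
            if 0 <= pos < chrom_sizes[t.chrom]:
                cov[t.chrom][pos] += 1
    return cov


def brute_force_call_peaks(tags, config, chrom_sizes):
    """Per-base Poisson scan equivalent of the production caller.

    Returns a list of dicts with keys chrom/start/end/summit/pvalue/qvalue
    (p, q on the -log10 scale, matching narrowPeak semantics).
    """
    tags = list(tags)
    if not tags:
        return []
    shift = config.pileup.shift
    extsize = config.pileup.extsize
    cov = brute_force_pileup(tags, shift, extsize, chrom_sizes)
    genome_len = (
        config.effective_genome_length
        if config.effective_genome_length is not None
        else sum(l for _, l in chrom_sizes.items())
    )
    lambda_bg = len(tags) * extsize / genome_len
    half = config.local_window // 2

    p_flat = []
    per_chrom = {}
    for chrom in chrom_sizes:
        c = cov[chrom]
        n = c.size
        p = np.empty(n)
        neglogp = np.empty(n)
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            lam = max(lambda_bg, int(c[lo:hi].sum()) / (hi - lo))
            k = int(c[i])
            p[i] = poisson_tail_series(k, lam)
            neglogp[i] = neglog10_poisson_tail_series(k, lam)
        per_chrom[chrom] = (c, p, neglogp)
        p_flat.append(p)
    q_all = bh_naive(np.concatenate(p_flat))

    peaks = []
    offset = 0
    min_len = config.min_length if config.min_length is not None else extsize
    for chrom in chrom_sizes:
        c, p, neglogp = per_chrom[chrom]
        n = c.size
        q = q_all[offset : offset + n]
        offset += n
        passing = [i for i in range(n) if q[i] <= config.qvalue_cutoff]
        # merge passing positions when gaps <= merge_gap
        regions = []
        for i in passing:
            if regions and i - regions[-1][1] <= config.merge_gap:
                regions[-1][1] = i
            else:
                regions.append([i, i])
        for s, e_incl in regions:
            e = e_incl + 1
            if e - s < min_len:
                continue
            summit = s + int(np.argmax(c[s:e]))  # leftmost maximum
            best = s + int(np.argmax(neglogp[s:e]))
            peaks.append(
                {
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "summit": summit - s,
                    "pvalue": float(neglogp[best]),
                    "qvalue": float(-np.log10(max(q[best], 1e-300))),
                }
            )
    return peaks
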