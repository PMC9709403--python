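"""Pseudo-replicate construction and IDR-based consistent-peak selection.

The reproducibility model is a two-component Gaussian copula mixture: an
irreproducible component (independent standard bivariate normal) and a
reproducible component (bivariate normal with common mean mu, sd sigma and
correlation rho).  Observed peak scores are rank-transformed to pseudo-
values through the inverse of the current mixture marginal CDF and the
mixture is fitted by EM.  The local idr of a peak pair is its posterior
probability of belonging to the irreproducible component; the global IDR at
rank i is the running mean of local idr over the i most reproducible pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import ChromSizes, Peak
from .peak_calling import PeakCallConfig, call_peaks

__all__ = [
    "IDRConfig",
    "IDRModel",
    "ReproducibilityReport",
    "split_pseudoreplicates",
    "match_peaks",
    "fit_idr",
    "consistent_peaks",
]


@dataclass(frozen=True)
class IDRConfig:
    cutoff_true_reps: float = 0.05
    cutoff_self_pseudo: float = 0.02
    cutoff_pooled_pseudo: float = 0.01
    em_tolerance: float = 1e-6
    max_iterations: int = 1000
    min_pairs: int = 50
    seed: int = 0
    # EM initialisation
    init_pi: float = 0.5
    init_mu: float = 2.0
    init_sigma: float = 1.0
    init_rho: float = 0.5

    def __post_init__(self):
        for name in ("cutoff_true_reps", "cutoff_self_pseudo", "cutoff_pooled_pseudo"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class IDRModel:
    pi: float                     # reproducible mixture weight
    mu: float
    sigma: float
    rho: float
    local_idr: np.ndarray         # per pair, input order
    global_idr: np.ndarray        # per pair, input order
    converged: bool
    n_iterations: int

    def n_passing(self, cutoff: float) -> int:
        return int(np.sum(self.global_idr <= cutoff))


def split_pseudoreplicates(tags, n_splits: int = 2, seed: int = 0):
    """Uniform random partition of the tag multiset into near-equal halves.

    Deterministic given ``seed``; sizes differ by at most 1.
    """
    tags = list(tags)
    if len(tags) < n_splits:
        raise ValueError(f"need >= {n_splits} tags to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(tags))
    splits = []
    for i in range(n_splits):
        splits.append([tags[j] for j in sorted(perm[i::n_splits])])
    return tuple(splits)


def match_peaks(peaks_1, peaks_2) -> tuple[list[tuple[Peak, Peak]], list[Peak], list[Peak]]:
    """Pair peaks across two sets by best mutual overlap (>= 1 bp).

    Greedy one-to-one matching by decreasing overlap; ties broken toward the
    higher-scoring partner pair.  Returns (pairs, unmatched_1, unmatched_2).
    """
    peaks_1, peaks_2 = list(peaks_1), list(peaks_2)
    if not peaks_1 or not peaks_2:
        warnings.warn("match_peaks: one peak set is empty; no pairs", stacklevel=2)
        return [], peaks_1, peaks_2
    candidates = []
    by_chrom: dict[str, list[tuple[int, Peak]]] = {}
    for j, q in enumerate(peaks_2):
        by_chrom.setdefault(q.chrom, []).append((j, q))
    for j_list in by_chrom.values():
        j_list.sort(key=lambda t: t[1].start)
    for i, p in enumerate(peaks_1):
        for j, q in by_chrom.get(p.chrom, ()):
            if q.start >= p.end:
                break
            overlap = min(p.end, q.end) - max(p.start, q.start)
            if overlap > 0:
                candidates.append((overlap, p.pvalue + q.pvalue, i, j))
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))
    used_1: set[int] = set()
    used_2: set[int] = set()
    pairs = []
    for _, _, i, j in candidates:
        if i in used_1 or j in used_2:
            continue
        used_1.add(i)
        used_2.add(j)
        pairs.append((peaks_1[i], peaks_2[j]))
    unmatched_1 = [p for i, p in enumerate(peaks_1) if i not in used_1]
    unmatched_2 = [p for j, p in enumerate(peaks_2) if j not in used_2]
    return pairs, unmatched_1, unmatched_2


def _mixture_marginal_cdf_grid(pi, mu, sigma, rho):
    """Grid (z, G(z)) of the mixture marginal CDF for interpolation-based inversion."""
    lo = min(-8.0, mu - 8.0 * sigma)
    hi = max(8.0, mu + 8.0 * sigma)
    z = np.linspace(lo, hi, 4096)
    g = pi * stats.norm.cdf(z, loc=mu, scale=sigma) + (1.0 - pi) * stats.norm.cdf(z)
    return z, g


def _bvn_logpdf(z1, z2, mu, sigma, rho):
    d1 = (z1 - mu) / sigma
    d2 = (z2 - mu) / sigma
    quad = (d1 * d1 - 2.0 * rho * d1 * d2 + d2 * d2) / (1.0 - rho * rho)
    return (
        -np.log(2.0 * np.pi)
        - 2.0 * np.log(sigma)
        - 0.5 * np.log(1.0 - rho * rho)
        - 0.5 * quad
    )


_SIGMA_FLOOR = 1e-2
_RHO_CAP = 0.999
_PI_EPS = 1e-6


def fit_idr(score_pairs, config: IDRConfig = IDRConfig()) -> IDRModel:
    """Fit the two-component copula mixture to paired peak scores by EM.

    ``score_pairs`` is an (n, 2) array-like of scores (higher = stronger).
    Requires at least ``config.min_pairs`` pairs.
    """
    scores = np.asarray(score_pairs, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("score_pairs must have shape (n, 2)")
    n = scores.shape[0]
    if n < config.min_pairs:
        raise ValueError(
            f"fit_idr needs >= {config.min_pairs} matched pairs, got {n}; "
            "provide more data"
        )
    # ECDF per margin; ties get average ranks; pulled slightly off {0,1}
    u = np.column_stack(
        [stats.rankdata(scores[:, j], method="average") / (n + 1) for j in (0, 1)]
    )
    pi, mu, sigma, rho = (
        config.init_pi,
        config.init_mu,
        config.init_sigma,
        config.init_rho,
    )
    loglik_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        # pseudo-values: invert the current mixture marginal CDF
        zgrid, ggrid = _mixture_marginal_cdf_grid(pi, mu, sigma, rho)
        z = np.interp(u, ggrid, zgrid)
        z1, z2 = z[:, 0], z[:, 1]
        # E-step
        log_rep = np.log(max(pi, _PI_EPS)) + _bvn_logpdf(z1, z2, mu, sigma, rho)
        log_null = np.log(max(1.0 - pi, _PI_EPS)) + stats.norm.logpdf(
            z1
        ) + stats.norm.logpdf(z2)
        m = np.maximum(log_rep, log_null)
        denom = m + np.log(np.exp(log_rep - m) + np.exp(log_null - m))
        gamma = np.exp(log_rep - denom)  # posterior reproducible prob
        loglik = float(np.sum(denom))
        # M-step
        w = gamma.sum()
        pi = float(np.clip(w / n, _PI_EPS, 1.0 - _PI_EPS))
        if w > 0:
            mu = float(np.sum(gamma * (z1 + z2)) / (2.0 * w))
            var = float(np.sum(gamma * ((z1 - mu) ** 2 + (z2 - mu) ** 2)) / (2.0 * w))
            sigma = float(max(np.sqrt(max(var, 0.0)), _SIGMA_FLOOR))
            rho_num = float(np.sum(gamma * (z1 - mu) * (z2 - mu)) / w)
            rho = float(np.clip(rho_num / (sigma * sigma), 0.0, _RHO_CAP))
        if abs(loglik - loglik_prev) < config.em_tolerance * max(1.0, abs(loglik)):
            converged = True
            break
        loglik_prev = loglik
    if not converged:
        warnings.warn("fit_idr: EM did not converge; returning best estimate", stacklevel=2)
    # identifiability guard: on null-like data the reproducible component
    # drifts onto the null itself (mu ~ 0, sigma ~ 1, rho ~ 0) and pi is then
    # arbitrary along a likelihood plateau; collapse to pi = 0 in that case.
    # A component that differs from the null in location, scale or
    # correlation is genuine signal and is kept.
    if rho < 0.1 and abs(mu) < 0.5 and 0.5 < sigma < 2.0:
        pi = 0.0
        gamma = np.zeros(n)
    local_idr = 1.0 - gamma
    order = np.argsort(local_idr, kind="stable")
    global_sorted = np.cumsum(local_idr[order]) / np.arange(1, n + 1)
    global_idr = np.empty(n)
    global_idr[order] = global_sorted
    return IDRModel(
        pi=pi,
        mu=mu,
        sigma=sigma,
        rho=rho,
        local_idr=local_idr,
        global_idr=global_idr,
        converged=converged,
        n_iterations=it,
    )


@dataclass
class ReproducibilityReport:
    n_true: int | None = None
    n_self: dict[str, int] = field(default_factory=dict)
    n_pooled_pseudo: int | None = None
    rescue_ratio: float | None = None
    self_consistency_ratio: float | None = None
    skipped_stages: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def n_final(self) -> int:
        vals = [v for v in (self.n_true, self.n_pooled_pseudo) if v is not None]
        return max(vals) if vals else 0


def _scores(pairs) -> np.ndarray:
    # rank statistic: -log10 p, ties broken by pileup (tiny jitter-free tiebreak)
    return np.array(
        [(a.pvalue + 1e-9 * a.pileup, b.pvalue + 1e-9 * b.pileup) for a, b in pairs]
    )


def _idr_count(peaks_a, peaks_b, cutoff, config, stage, report) -> int | None:
    pairs, _, _ = match_peaks(peaks_a, peaks_b)
    if len(pairs) < config.min_pairs:
        report.skipped_stages.append(stage)
        return None
    model = fit_idr(_scores(pairs), config)
    return model.n_passing(cutoff)


def consistent_peaks(
    rep_tags,
    config: IDRConfig,
    peak_config: PeakCallConfig,
    chrom_sizes: ChromSizes,
    rep_peaks=None,
    pooled_peaks=None,
    conservative: bool = False,
) -> tuple[list[Peak], ReproducibilityReport]:
    """ENCODE-style consistent-peak selection from >= 2 replicate tag lists.

    Runs three IDR analyses — true replicates (cutoff 0.05), per-replicate
    self pseudo-replicates (0.02) and pooled pseudo-replicates (0.01) — then
    returns the top ``max(N_t, N_p)`` pooled peaks by score (the "optimal"
    set; ``conservative`` gives ``N_t``), with a reproducibility report.
    """
    rep_tags = [list(t) for t in rep_tags]
    if len(rep_tags) < 2:
        raise ValueError("consistent_peaks requires >= 2 replicates")
    if len(rep_tags) > 2:
        raise NotImplementedError("only 2 true replicates are supported")
    report = ReproducibilityReport()
    if rep_peaks is None:
        rep_peaks = [call_peaks(t, peak_config, chrom_sizes) for t in rep_tags]
    pooled_tags = [t for rep in rep_tags for t in rep]
    if pooled_peaks is None:
        pooled_peaks = call_peaks(pooled_tags, peak_config, chrom_sizes)

    # 1) true replicates
    report.n_true = _idr_count(
        rep_peaks[0], rep_peaks[1], config.cutoff_true_reps, config, "true_reps", report
    )
    # 2) self pseudo-replicates of each replicate
    for i, tags in enumerate(rep_tags):
        half_a, half_b = split_pseudoreplicates(tags, seed=config.seed + i + 1)
        pa = call_peaks(half_a, peak_config, chrom_sizes)
        pb = call_peaks(half_b, peak_config, chrom_sizes)
        n = _idr_count(
            pa, pb, config.cutoff_self_pseudo, config, f"self_pseudo_rep{i + 1}", report
        )
        if n is not None:
            report.n_self[f"rep{i + 1}"] = n
    # 3) pooled pseudo-replicates
    pool_a, pool_b = split_pseudoreplicates(pooled_tags, seed=config.seed)
    ppa = call_peaks(pool_a, peak_config, chrom_sizes)
    ppb = call_peaks(pool_b, peak_config, chrom_sizes)
    report.n_pooled_pseudo = _idr_count(
        ppa, ppb, config.cutoff_pooled_pseudo, config, "pooled_pseudo", report
    )

    if report.n_true and report.n_pooled_pseudo:
        report.rescue_ratio = report.n_pooled_pseudo / report.n_true
        if not (0.5 <= report.rescue_ratio <= 2.0):
            report.flags.append("rescue ratio outside [0.5, 2]: replicates imbalanced")
    if len(report.n_self) == 2:
        ns = list(report.n_self.values())
        if min(ns) > 0:
            report.self_consistency_ratio = max(ns) / min(ns)
            if report.self_consistency_ratio > 2.0:
                report.flags.append("self-consistency ratio > 2: replicate quality differs")

    if conservative:
        n_final = report.n_true or 0
    else:
        n_final = report.n_final
    ranked = sorted(pooled_peaks, key=lambda p: (-p.pvalue, -p.pileup, p.chrom, p.start))
    final = sorted(ranked[:n_final], key=lambda p: (p.chrom, p.start))
    return final, report
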