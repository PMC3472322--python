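"""Per-site genotype calling: iML, the original ML caller, and a MAF threshold.

Given the ranked nucleotide counts n1 >= n2 >= n3 >= n4 at one cluster
position (n = n1+n2+n3+n4) and a per-base sequencing error rate epsilon, the
three callers are:

iML
    Scores three categories, combining the multinomial read-sampling term,
    the depth model and the error model::

        hom = multinom(n; n1..n4) * f_1(n) * (1 - 3eps/4)^n1 * (eps/4)^(n2+n3+n4)
        het = multinom(n; n1..n4) * f_1(n) * (0.5 - eps/4)^(n1+n2) * (eps/4)^(n3+n4)
        und = sum_{k=2..M} [a_k / (1 - a_1)] * f_k(n)

    where f_k is the fitted depth model's k-th component (Poisson(n | k*C) or
    Normal(n | k*C, sigma_k)). The "undetermined" category absorbs composite
    (repeat-derived) clusters: their total depth sits near k*C for k >= 2
    where f_1 is negligible. With ``category_priors`` (default) the categories
    are weighted a_1/2, a_1/2 and (1 - a_1) before normalization so they form
    a coherent partition; without it the raw scores above are used.

ML
    The classical reference-free caller: hom vs het using only the
    multinomial-error factors (no depth term, no undetermined category).

threshold
    Heterozygote iff the minor allele fraction n2/(n1+n2) exceeds a fixed
    cutoff (default 0.35, strict inequality); n3 and n4 are treated as error.

All scores are computed in log space; the caller picks the category with the
largest posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp, xlogy

from .clustering import ReadCluster
from .depth_model import DepthModelSpec, NORMAL_FAMILIES

CATEGORIES = ("homozygote", "heterozygote", "undetermined")
_BASES = "ACGT"


class CallerError(ValueError):
    pass


class NoDataError(CallerError):
    """No reads cover the site."""


@dataclass
class SiteCounts:
    """Rank-ordered nucleotide counts at one site.

    ``counts`` is sorted in decreasing order with ties broken by the fixed
    base order A<C<G<T; ``bases`` records which nucleotide holds each rank.
    """

    counts: np.ndarray
    bases: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4,):
            raise CallerError("SiteCounts needs exactly four counts")
        if (np.diff(self.counts) > 0).any() or (self.counts < 0).any():
            raise CallerError("counts must be non-negative and rank-ordered")
        if self.n < 1:
            raise NoDataError("no reads at site")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_acgt(cls, acgt) -> "SiteCounts":
        """Build from counts given in A, C, G, T order."""
        acgt = np.asarray(acgt, dtype=np.int64)
        order = np.argsort(-acgt, kind="stable")  # stable: ties keep A<C<G<T
        return cls(acgt[order], tuple(_BASES[i] for i in order))


@dataclass
class CallerConfig:
    """Shared caller settings; ``model`` is required for iML only."""

    epsilon: float = 0.01
    model: DepthModelSpec | None = None
    maf_threshold: float = 0.35
    min_posterior_margin: float = 0.0
    category_priors: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.epsilon < 1):
            raise CallerError("epsilon must be in [0, 1)")
        if not (0 < self.maf_threshold < 0.5):
            raise CallerError("maf_threshold must be in (0, 0.5)")
        if self.min_posterior_margin < 0:
            raise CallerError("min_posterior_margin must be >= 0")


@dataclass
class GenotypeCall:
    category: str
    allele1: str | None
    allele2: str | None
    posteriors: np.ndarray   # (hom, het, und), normalized

    def __post_init__(self) -> None:
        self.posteriors = np.asarray(self.posteriors, dtype=float)
        assert abs(self.posteriors.sum() - 1.0) < 1e-9


# ---------------------------------------------------------------------------
# Vectorized score kernels (rows = sites)
# ---------------------------------------------------------------------------

def _depth_log_components(n: np.ndarray, model: DepthModelSpec) -> np.ndarray:
    comps = np.arange(1, model.M + 1, dtype=float)
    if model.family in NORMAL_FAMILIES:
        return stats.norm.logpdf(n[:, None].astype(float), model.C * comps[None, :],
                                 model.sigmas[None, :])
    return stats.poisson.logpmf(n[:, None], model.C * comps[None, :])


def _error_log_factors(counts: np.ndarray, eps: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(log multinomial coeff, hom error term, het error term) per row."""
    n = counts.sum(axis=1)
    log_mult = gammaln(n + 1) - gammaln(counts + 1).sum(axis=1)
    n1 = counts[:, 0]
    n2 = counts[:, 1]
    tail2 = counts[:, 1:].sum(axis=1)     # n2 + n3 + n4
    tail34 = counts[:, 2:].sum(axis=1)    # n3 + n4
    hom = xlogy(n1, 1.0 - 0.75 * eps) + xlogy(tail2, eps / 4.0)
    het = xlogy(n1 + n2, 0.5 - eps / 4.0) + xlogy(tail34, eps / 4.0)
    return log_mult, hom, het


def iml_log_scores(counts: np.ndarray, config: CallerConfig) -> np.ndarray:
    """Log-scale iML category scores for rank-ordered count rows.

    ``counts`` is (N, 4) with each row sorted decreasingly. Returns (N, 3)
    unnormalized log scores in the order (hom, het, und).
    """
    model = config.model
    if model is None:
        raise CallerError("iML requires a fitted depth model")
    if model.M < 2 or model.weights[0] >= 1.0:
        raise CallerError("iML requires a mixture model with M >= 2 and a_1 < 1")
    counts = np.atleast_2d(np.asarray(counts, dtype=np.int64))
    n = counts.sum(axis=1)
    log_mult, hom_err, het_err = _error_log_factors(counts, config.epsilon)
    depth = _depth_log_components(n, model)
    a = model.weights
    with np.errstate(divide="ignore"):
        log_cond = np.log(a[1:] / (1.0 - a[0]))
        und = logsumexp(depth[:, 1:] + log_cond[None, :], axis=1)
    hom = log_mult + depth[:, 0] + hom_err
    het = log_mult + depth[:, 0] + het_err
    if config.category_priors:
        with np.errstate(divide="ignore"):
            hom = hom + np.log(a[0] / 2.0)
            het = het + np.log(a[0] / 2.0)
            und = und + np.log(1.0 - a[0])
    return np.stack([hom, het, und], axis=1)


def ml_log_scores(counts: np.ndarray, config: CallerConfig) -> np.ndarray:
    """Log-scale ML scores (hom, het) — error model only, no depth factor."""
    counts = np.atleast_2d(np.asarray(counts, dtype=np.int64))
    log_mult, hom_err, het_err = _error_log_factors(counts, config.epsilon)
    return np.stack([log_mult + hom_err, log_mult + het_err], axis=1)


def _normalize(log_scores: np.ndarray) -> np.ndarray:
    return np.exp(log_scores - logsumexp(log_scores, axis=1, keepdims=True))


def iml_scores(counts: SiteCounts, config: CallerConfig) -> np.ndarray:
    """Unnormalized log scores (hom, het, und) for a single site."""
    return iml_log_scores(counts.counts[None, :], config)[0]


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def _call_from_posteriors(post: np.ndarray, bases, margin: float) -> GenotypeCall:
    order = np.argsort(-post, kind="stable")
    top = int(order[0])
    tie = post[order[0]] - post[order[1]] <= 1e-12
    if tie or post[order[0]] - post[order[1]] < margin:
        top = 2  # undetermined on ties / insufficient margin
    category = CATEGORIES[top]
    if category == "homozygote":
        a1 = a2 = bases[0]
    elif category == "heterozygote":
        a1, a2 = bases[0], bases[1]
    else:
        a1 = a2 = None
    return GenotypeCall(category, a1, a2, post)


def call_site(counts: SiteCounts, config: CallerConfig, method: str = "iml") -> GenotypeCall:
    """Genotype one site with the chosen caller.

    iML picks the arg-max of the three normalized posteriors (ties go to
    undetermined); ML compares hom vs het only (ties go to homozygote, i.e.
    no SNP); the threshold rule calls a heterozygote iff
    n2/(n1+n2) > maf_threshold.
    """
    if counts.n == 0:
        raise NoDataError("no reads at site")
    row = counts.counts[None, :]
    if method == "iml":
        post = _normalize(iml_log_scores(row, config))[0]
        return _call_from_posteriors(post, counts.bases, config.min_posterior_margin)
    if method == "ml":
        two = _normalize(ml_log_scores(row, config))[0]
        post = np.array([two[0], two[1], 0.0])
        if two[1] > two[0]:
            return GenotypeCall("heterozygote", counts.bases[0], counts.bases[1], post)
        return GenotypeCall("homozygote", counts.bases[0], counts.bases[0], post)
    if method == "threshold":
        n12 = counts.counts[0] + counts.counts[1]
        is_het = counts.counts[1] / n12 > config.maf_threshold
        post = np.array([0.0, 1.0, 0.0]) if is_het else np.array([1.0, 0.0, 0.0])
        if is_het:
            return GenotypeCall("heterozygote", counts.bases[0], counts.bases[1], post)
        return GenotypeCall("homozygote", counts.bases[0], counts.bases[0], post)
    raise CallerError(f"unknown method {method!r}")


@dataclass
class ClusterCalls:
    """All per-position calls for one cluster plus its SNP summary."""

    cluster_id: int
    calls: list[GenotypeCall]
    snp_positions: list[int]
    repeat_flagged: bool


def call_cluster(cluster: ReadCluster, config: CallerConfig,
                 method: str = "iml") -> ClusterCalls:
    """Genotype every position of a cluster.

    A SNP is reported at each heterozygote position. Clusters in which the
    undetermined category wins at a majority of positions are flagged
    repeat-derived and contribute no SNPs.
    """
    acgt = cluster.counts
    L = acgt.shape[0]
    order = np.argsort(-acgt, axis=1, kind="stable")
    sorted_counts = np.take_along_axis(acgt, order, axis=1)
    n = sorted_counts.sum(axis=1)
    covered = n > 0

    posts = np.zeros((L, 3))
    if method == "iml":
        posts[covered] = _normalize(iml_log_scores(sorted_counts[covered], config))
    elif method == "ml":
        two = _normalize(ml_log_scores(sorted_counts[covered], config))
        posts[covered, 0] = two[:, 0]
        posts[covered, 1] = two[:, 1]
    elif method == "threshold":
        n12 = sorted_counts[:, 0] + sorted_counts[:, 1]
        het = np.zeros(L, dtype=bool)
        het[covered] = sorted_counts[covered, 1] / n12[covered] > config.maf_threshold
        posts[np.arange(L), np.where(het, 1, 0)] = 1.0
    else:
        raise CallerError(f"unknown method {method!r}")

    calls: list[GenotypeCall] = []
    snps: list[int] = []
    n_und = 0
    for p in range(L):
        if not covered[p]:
            calls.append(GenotypeCall("undetermined", None, None,
                                      np.array([0.0, 0.0, 1.0])))
            n_und += 1
            continue
        bases = tuple(_BASES[i] for i in order[p])
        if method == "ml":
            call = (GenotypeCall("heterozygote", bases[0], bases[1], posts[p])
                    if posts[p, 1] > posts[p, 0]
                    else GenotypeCall("homozygote", bases[0], bases[0], posts[p]))
        elif method == "threshold":
            call = (GenotypeCall("heterozygote", bases[0], bases[1], posts[p])
                    if posts[p, 1] == 1.0
                    else GenotypeCall("homozygote", bases[0], bases[0], posts[p]))
        else:
            call = _call_from_posteriors(posts[p], bases, config.min_posterior_margin)
        if call.category == "undetermined":
            n_und += 1
        elif call.category == "heterozygote":
            snps.append(p)
        calls.append(call)

    repeat_flagged = n_und > L / 2
    return ClusterCalls(cluster.cluster_id, calls,
                        [] if repeat_flagged else snps, repeat_flagged)
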