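"""Mixture models of read-cluster depth and their EM estimation.

In reduced-representation sequencing at mean per-locus coverage C, the depth
of a unique locus's cluster is approximately Poisson(C). Clusters that merge
reads from i copies of a repeat concentrate near i*C, so the observed depth
distribution is a mixture whose i-th component has mean i*C and weight a_i:

    Pr(k | C) = sum_{i=1..M} a_i f(k | i*C)

with f either a Poisson pmf or a normal density with per-component scale
sigma_i (real libraries are over-dispersed, hence the normal family). The
weight complement 1 - a_1 estimates the fraction of composite (repeat-derived)
clusters, and the per-depth posterior of components i >= 2 is the quantity
the iML genotyper uses to absorb repeat clusters into its "undetermined"
category.

Parameters are estimated by EM with all component means tied to a single C.
The E-step responsibilities and weight update are::

    P_j(d_t) = a_j f(d_t | j*C) / sum_j a_j f(d_t | j*C)
    a_j <- (1/n) sum_t P_j(d_t)

Two C updates are offered. The default, ``c_update="all"``, maximizes the
complete-data log-likelihood with the means tied to j*C::

    C <- sum_t d_t / sum_t sum_j j * P_j(d_t)

which makes every step a true EM step (the observed-data log-likelihood
never decreases). The variant ``c_update="component1"``::

    C <- sum_t d_t P_1(d_t) / sum_t P_1(d_t)

anchors the mean on component-1 responsibilities; it is a consistent
estimator that converges to essentially the same fit here, but it is not an
M-step of the tied-means mixture, and close to the fixed point the
log-likelihood can decrease by ~1e-6 relative. The iteration stops when
every weight and C move by at most ``tolerance`` (default 1e-6).

Goodness of fit is assessed with a one-sample Kolmogorov-Smirnov test against
the fitted mixture CDF, and EM uncertainty with a balanced bootstrap in which
every observation appears exactly B times across the B replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats
from scipy.special import logsumexp

POISSON_FAMILIES = ("poisson", "mixed_poisson")
NORMAL_FAMILIES = ("normal", "mixed_normal")
FAMILIES = POISSON_FAMILIES + NORMAL_FAMILIES

_SIGMA_FLOOR = 1e-3


class DepthModelError(ValueError):
    pass


@dataclass
class DepthObservations:
    """Observed cluster depths d_1..d_n."""

    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.depths.size < 1:
            raise DepthModelError("need at least one depth observation")
        if (self.depths < 1).any():
            raise DepthModelError("cluster depths must be positive integers")

    @property
    def n(self) -> int:
        return int(self.depths.size)


@dataclass
class DepthModelSpec:
    """A fitted depth distribution.

    Component i (1-based) has mean i*C and weight ``weights[i-1]``; normal
    families additionally carry per-component standard deviations.
    """

    family: str
    C: float
    weights: np.ndarray
    sigmas: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise DepthModelError(f"unknown family {self.family!r}")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.C <= 0:
            raise DepthModelError("C must be positive")
        if (self.weights < 0).any() or abs(self.weights.sum() - 1.0) > 1e-9:
            raise DepthModelError("weights must be a simplex point (sum to 1)")
        if self.family in NORMAL_FAMILIES:
            if self.sigmas is None:
                raise DepthModelError("normal families require sigmas")
            self.sigmas = np.asarray(self.sigmas, dtype=float)
            if (self.sigmas <= 0).any():
                raise DepthModelError("sigmas must be positive")
            if self.sigmas.size != self.weights.size:
                raise DepthModelError("one sigma per component required")

    @property
    def M(self) -> int:
        return int(self.weights.size)

    def to_yaml(self, path: str | Path, extra: dict | None = None) -> None:
        doc = {"family": self.family, "C": float(self.C),
               "weights": [float(w) for w in self.weights]}
        if self.sigmas is not None:
            doc["sigmas"] = [float(s) for s in self.sigmas]
        if extra:
            doc.update(extra)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DepthModelSpec":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(family=doc["family"], C=doc["C"],
                   weights=np.asarray(doc["weights"], dtype=float),
                   sigmas=None if doc.get("sigmas") is None
                   else np.asarray(doc["sigmas"], dtype=float))


@dataclass
class EMConfig:
    M: int = 3
    tolerance: float = 1e-6
    max_iterations: int = 10_000
    init_C: float | str = "auto"
    init_weights: np.ndarray | str = "auto"
    seed: int | None = None
    c_update: str = "all"   # "all" (true EM step) or "component1"

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise DepthModelError("tolerance must be positive")
        if self.M < 1:
            raise DepthModelError("M must be >= 1")
        if self.c_update not in ("component1", "all"):
            raise DepthModelError("c_update must be 'component1' or 'all'")


@dataclass
class FitResult:
    model: DepthModelSpec
    log_likelihood: float
    iterations: int
    converged: bool
    log_likelihoods: list[float] = field(default_factory=list)


@dataclass
class KSResult:
    statistic: float
    p_value: float
    model: DepthModelSpec


# ---------------------------------------------------------------------------
# Densities
# ---------------------------------------------------------------------------

def _component_log_density(k: np.ndarray, model: DepthModelSpec) -> np.ndarray:
    """(len(k), M) matrix of log f(k | i*C) for components i=1..M."""
    k = np.atleast_1d(np.asarray(k, dtype=float))
    comps = np.arange(1, model.M + 1, dtype=float)
    if model.family in POISSON_FAMILIES:
        return stats.poisson.logpmf(k[:, None], model.C * comps[None, :])
    return stats.norm.logpdf(k[:, None], model.C * comps[None, :],
                             model.sigmas[None, :])


def mixture_log_density(k, model: DepthModelSpec) -> np.ndarray:
    """log of sum_i a_i f(k | i*C), computed via log-sum-exp."""
    with np.errstate(divide="ignore"):
        lw = np.log(model.weights)
    return logsumexp(_component_log_density(k, model) + lw[None, :], axis=1)


def mixture_density(k, model: DepthModelSpec):
    """Mixture pmf (Poisson families, exact) or density (normal families) at depth k."""
    karr = np.atleast_1d(np.asarray(k, dtype=float))
    if (karr < 0).any():
        raise DepthModelError("depth k must be non-negative")
    out = np.exp(mixture_log_density(karr, model))
    return float(out[0]) if np.isscalar(k) else out


def mixture_cdf(k, model: DepthModelSpec) -> np.ndarray:
    """Mixture CDF: the weighted sum of component CDFs."""
    k = np.atleast_1d(np.asarray(k, dtype=float))
    comps = np.arange(1, model.M + 1, dtype=float)
    if model.family in POISSON_FAMILIES:
        cdfs = stats.poisson.cdf(k[:, None], model.C * comps[None, :])
    else:
        cdfs = stats.norm.cdf(k[:, None], model.C * comps[None, :],
                              model.sigmas[None, :])
    return cdfs @ model.weights


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_single(obs: DepthObservations, family: str) -> FitResult:
    """Closed-form MLE of the single-component models.

    Poisson: C is the sample mean. Normal: C is the sample mean, sigma the
    sample SD (a zero SD is rejected as degenerate).
    """
    if family not in ("poisson", "normal"):
        raise DepthModelError("fit_single handles 'poisson' and 'normal'")
    d = obs.depths.astype(float)
    C = float(d.mean())
    if family == "poisson":
        model = DepthModelSpec("poisson", C, np.array([1.0]))
    else:
        if obs.n < 2:
            raise DepthModelError("normal fit needs at least 2 observations")
        sd = float(d.std(ddof=0))
        if sd == 0.0:
            raise DepthModelError("degenerate normal fit: zero depth variance")
        model = DepthModelSpec("normal", C, np.array([1.0]), np.array([sd]))
    ll = float(mixture_log_density(obs.depths, model).sum())
    return FitResult(model, ll, iterations=0, converged=True, log_likelihoods=[ll])


def _auto_init(vals: np.ndarray, cnts: np.ndarray, M: int) -> tuple[float, np.ndarray]:
    # C0: mode of the depth histogram after box smoothing (window 5); robust
    # to the heavy right tail that corrupts the sample mean.
    full = np.zeros(int(vals.max()) + 1, dtype=float)
    full[vals] = cnts
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(full, kernel, mode="same")
    C0 = float(max(np.argmax(smooth), 1))
    if M == 3:
        a0 = np.array([0.90, 0.07, 0.03])
    elif M == 1:
        a0 = np.array([1.0])
    else:
        a0 = np.full(M, 0.10 / (M - 1))
        a0[0] = 0.90
    return C0, a0


def fit_em(obs: DepthObservations, family: str,
           config: EMConfig | None = None) -> FitResult:
    """Fit a mixed Poisson or mixed normal depth model by EM.

    Component means stay tied to a single C (component i at i*C); see the
    module docstring for the two available C updates. For the normal family
    each sigma_j is the responsibility-weighted SD of depths about j*C.
    Convergence requires every weight and C to move by at most
    ``config.tolerance``.

    Returns a :class:`FitResult` whose ``log_likelihoods`` trajectory holds
    the observed-data log-likelihood at the start of every iteration plus the
    final value; EM ascent can be checked against it.
    """
    if family not in ("mixed_poisson", "mixed_normal"):
        raise DepthModelError("fit_em handles 'mixed_poisson' and 'mixed_normal'")
    config = config or EMConfig()
    M = config.M
    if obs.n < 10 * M:
        warnings.warn(f"only {obs.n} depths for an M={M} mixture; estimates may be "
                      "unstable", stacklevel=2)

    vals, cnts = np.unique(obs.depths, return_counts=True)
    n = obs.n
    if config.init_C == "auto" or config.init_weights == "auto":
        C_auto, a_auto = _auto_init(vals, cnts, M)
    C = float(config.init_C) if config.init_C != "auto" else C_auto
    a = (np.asarray(config.init_weights, dtype=float)
         if not isinstance(config.init_weights, str) else a_auto.copy())
    if a.size != M or abs(a.sum() - 1.0) > 1e-9:
        raise DepthModelError("init_weights must be a length-M simplex point")

    comps = np.arange(1, M + 1, dtype=float)
    sigmas = np.sqrt(C * comps) if family == "mixed_normal" else None

    def model_at(C_, a_, s_):
        return DepthModelSpec(family, C_, a_, None if s_ is None else s_.copy())

    lls: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        spec = model_at(C, a, sigmas)
        with np.errstate(divide="ignore"):
            lp = _component_log_density(vals, spec) + np.log(a)[None, :]
        lse = logsumexp(lp, axis=1)
        if not np.isfinite(lse).all():
            raise DepthModelError(
                "all component densities underflow for some depths; rescale or "
                "check the initial C")
        lls.append(float((cnts * lse).sum()))
        resp = np.exp(lp - lse[:, None])          # responsibilities per unique depth
        w = cnts[:, None] * resp                   # weighted by multiplicity
        a_new = w.sum(axis=0) / n
        if config.c_update == "component1":
            C_new = float((vals * w[:, 0]).sum() / w[:, 0].sum())
        else:
            # maximizer of the complete-data likelihood with means tied to j*C
            C_new = float((vals * cnts).sum() / (w @ comps).sum())
        if family == "mixed_normal":
            var = ((vals[:, None] - C_new * comps[None, :]) ** 2 * w).sum(axis=0)
            sigmas = np.sqrt(np.maximum(var / np.maximum(w.sum(axis=0), 1e-300),
                                        _SIGMA_FLOOR ** 2))
        moved = max(float(np.abs(a_new - a).max()), abs(C_new - C))
        a, C = a_new / a_new.sum(), C_new
        if moved <= config.tolerance:
            converged = True
            break

    final = model_at(C, a, sigmas)
    ll = float((cnts * mixture_log_density(vals, final)).sum())
    lls.append(ll)
    return FitResult(final, ll, iterations=it, converged=converged,
                     log_likelihoods=lls)


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def composite_fraction(model: DepthModelSpec) -> float:
    """Estimated fraction of composite (repeat-derived) clusters: 1 - a_1."""
    return float(1.0 - model.weights[0])


def composite_posterior(k, model: DepthModelSpec):
    """Posterior probability that a cluster of depth k is composite.

    ``sum_{i>=2} a_i f(k|i*C) / sum_{i>=1} a_i f(k|i*C)``; 0 everywhere for
    single-component models.
    """
    karr = np.atleast_1d(np.asarray(k, dtype=float))
    if model.M == 1:
        out = np.zeros_like(karr)
        return float(out[0]) if np.isscalar(k) else out
    with np.errstate(divide="ignore"):
        lw = np.log(model.weights)
    lp = _component_log_density(karr, model) + lw[None, :]
    num = logsumexp(lp[:, 1:], axis=1)
    den = logsumexp(lp, axis=1)
    out = np.exp(num - den)
    return float(out[0]) if np.isscalar(k) else out


def repeat_depth_threshold(model: DepthModelSpec) -> int:
    """Smallest integer depth at which the composite posterior exceeds 1/2.

    This is the dashed-line diagnostic of depth-threshold genotyping; iML
    itself classifies probabilistically and does not hard-exclude at it.
    """
    if model.M < 2 or model.weights[0] >= 1.0:
        raise DepthModelError("threshold undefined for single-component models")
    upper = int(np.ceil(20 * model.M * model.C)) + 1
    ks = np.arange(upper)
    post = composite_posterior(ks, model)
    above = np.flatnonzero(post > 0.5)
    if above.size == 0:
        raise DepthModelError("composite posterior never exceeds 1/2 below the scan bound")
    return int(above[0])


def ks_fitness(obs: DepthObservations, model: DepthModelSpec) -> KSResult:
    """One-sample Kolmogorov-Smirnov fitness of depths against the model CDF.

    Uses the asymptotic p-value with the fitted parameters treated as fixed,
    so p-values on data the model was fitted to are optimistic in the usual
    way; they are used for ranking candidate families.
    """
    if obs.n < 20:
        raise DepthModelError("K-S fitness needs at least 20 observations")
    # Depths are integers: compare the ECDF and the model CDF at the same
    # right-continuous convention on the integer support. The continuous-data
    # convention (sup over F(x) - ECDF(x-)) degenerates to the modal pmf under
    # heavy ties and rejects any discrete model at large n.
    ks = np.arange(int(obs.depths.max()) + 1)
    ecdf = np.searchsorted(np.sort(obs.depths), ks, side="right") / obs.n
    statistic = float(np.abs(ecdf - mixture_cdf(ks, model)).max())
    p_value = float(stats.kstwobign.sf(np.sqrt(obs.n) * statistic))
    return KSResult(statistic, p_value, model)


# ---------------------------------------------------------------------------
# Balanced bootstrap
# ---------------------------------------------------------------------------

def balanced_bootstrap_indices(n: int, B: int,
                               rng: np.random.Generator) -> np.ndarray:
    """(B, n) index array in which every observation occurs exactly B times."""
    pool = np.tile(np.arange(n), B)
    rng.shuffle(pool)
    return pool.reshape(B, n)


@dataclass
class BootstrapResult:
    B: int
    mean_C: float
    sd_C: float
    mean_weights: np.ndarray
    sd_weights: np.ndarray
    n_failures: int


def bootstrap_em(obs: DepthObservations, family: str, config: EMConfig,
                 B: int = 100, seed: int | None = None) -> BootstrapResult:
    """Balanced-bootstrap uncertainty of the EM estimates.

    The pooled resampling scheme guarantees each observation appears exactly
    B times across the B replicates; each replicate (size n) is refit with
    :func:`fit_em`. Errors in more than 20% of replicates abort.
    """
    if B < 2:
        raise DepthModelError("bootstrap needs B >= 2")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    idx = balanced_bootstrap_indices(obs.n, B, rng)
    Cs, As = [], []
    failures = 0
    for b in range(B):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_em(DepthObservations(obs.depths[idx[b]]), family, config)
            Cs.append(fit.model.C)
            As.append(fit.model.weights)
        except DepthModelError:
            failures += 1
    if failures > 0.2 * B:
        raise DepthModelError(f"EM failed in {failures}/{B} bootstrap replicates")
    Cs = np.asarray(Cs)
    As = np.asarray(As)
    return BootstrapResult(B, float(Cs.mean()), float(Cs.std(ddof=1)),
                           As.mean(axis=0), As.std(axis=0, ddof=1), failures)
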