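"""Genome-resampling empirical null for the overlap count.

Cross-validates the analytic hypergeometric tail: draw many random gene
samples of the same size from the universe, record each one's overlap with
the functional set, and estimate the p-value as the (add-one smoothed)
fraction of resampled overlaps at least as large as the observed one.
Sampling is gene-label-uniform without replacement; no covariate matching.

Implementation note: a uniform n-subset of the universe equals the n
smallest entries of a vector of i.i.d. uniform random keys, so overlaps are
computed vectorized over chunks of iterations instead of per-draw Python
loops.  Results are bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gene_sets import FunctionalGeneSet, GeneUniverse
from .stats import hypergeom_tail

__all__ = ["ResamplingResult", "AgreementReport", "resample_null", "compare_to_analytic"]


@dataclass(frozen=True)
class ResamplingResult:
    """Summary of an empirical null for one (sample size, set) configuration."""

    iterations: int
    seed: int
    observed: int
    null_mean: float
    null_sd: float
    null_max: int
    p_empirical: float

    def __post_init__(self) -> None:
        if not 1.0 / (self.iterations + 1) <= self.p_empirical <= 1.0:
            raise ValueError("empirical p outside its attainable range")


@dataclass(frozen=True)
class AgreementReport:
    """Agreement between an empirical and an analytic p-value.

    ``agree`` is true when the empirical estimate lies within four binomial
    Monte-Carlo standard errors of the analytic value, or when both are below
    the resampling resolution ``1/M`` (the empirical test cannot resolve
    tails smaller than one count in ``M`` draws).
    """

    p_empirical: float
    p_analytic: float
    delta: float
    tolerance: float
    below_resolution: bool
    agree: bool


def resample_null(
    observed: int,
    n: int,
    fset: FunctionalGeneSet,
    universe: GeneUniverse,
    iterations: int = 100_000,
    seed: int = 0,
    chunk: int = 2_000,
) -> ResamplingResult:
    """Empirical null distribution of the overlap of an ``n``-gene sample.

    Draws ``iterations`` samples of ``n`` distinct genes uniformly without
    replacement from the explicit universe and records each overlap with
    ``fset``.  The add-one smoothed estimate
    ``p = (1 + #{overlap >= observed}) / (iterations + 1)`` never returns a
    literal zero.
    """
    if not universe.is_explicit:
        raise ValueError("resampling requires an explicit universe")
    N = universe.size
    if n > N:
        raise ValueError(f"sample size n={n} exceeds universe size N={N}")
    if iterations < 1:
        raise ValueError("need at least one iteration")
    restricted = fset.restricted_to(universe)
    # Positions of set members in a fixed (sorted) universe ordering.
    ordering = {g: i for i, g in enumerate(sorted(universe.members))}  # type: ignore[arg-type]
    fidx = np.fromiter((ordering[g] for g in restricted.members), dtype=np.intp)

    rng = np.random.default_rng(seed)
    n_ge = 0
    total = 0.0
    total_sq = 0.0
    null_max = 0
    done = 0
    while done < iterations:
        b = min(chunk, iterations - done)
        keys = rng.random((b, N))
        if n == N:
            ov = np.full(b, len(fidx))
        else:
            # n-th smallest key is the inclusion threshold for each draw
            kth = np.partition(keys, n - 1, axis=1)[:, n - 1]
            ov = (keys[:, fidx] <= kth[:, None]).sum(axis=1)
        n_ge += int((ov >= observed).sum())
        total += float(ov.sum())
        total_sq += float((ov.astype(np.float64) ** 2).sum())
        null_max = max(null_max, int(ov.max()))
        done += b
    mean = total / iterations
    var = max(total_sq / iterations - mean**2, 0.0)
    return ResamplingResult(
        iterations=iterations,
        seed=seed,
        observed=observed,
        null_mean=mean,
        null_sd=float(np.sqrt(var)),
        null_max=null_max,
        p_empirical=(1 + n_ge) / (iterations + 1),
    )


def compare_to_analytic(res: ResamplingResult, p_analytic: float) -> AgreementReport:
    """Check an empirical p against the analytic hypergeometric tail."""
    if res.iterations < 1000:
        raise ValueError("agreement check needs at least 1000 iterations")
    M = res.iterations
    resolution = 1.0 / M
    below = res.p_empirical < resolution + 1e-12 and p_analytic < resolution
    tol = 4.0 * float(np.sqrt(p_analytic * (1.0 - p_analytic) / M))
    delta = abs(res.p_empirical - p_analytic)
    # the +1 smoothing itself shifts the estimate by at most 1/(M+1)
    agree = below or delta <= tol + 1.0 / (M + 1)
    return AgreementReport(
        p_empirical=res.p_empirical,
        p_analytic=p_analytic,
        delta=delta,
        tolerance=tol,
        below_resolution=below,
        agree=agree,
    )
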