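"""Statistical core: one-sided exact overlap test and derived table columns.

The question answered throughout is: given a disease-associated sample of
``n`` genes drawn from a universe of ``N`` genes, is its overlap ``O`` with a
functional category of ``K`` genes larger than chance?  Under the null the
overlap is hypergeometric, and the one-sided Fisher exact p-value of the 2×2
membership table equals the upper tail ``P(X >= O)``.  Around that test this
module computes the conventional summary columns of an enrichment table:

* expected overlap ``E = K*n/N`` and expected/observed percentages,
* representation factor ``RF = O/E`` (fold-enrichment under independence),
* a one-sided 95% confidence bound on the number of matches
  (exact Clopper–Pearson lower bound on the proportion ``O/n``, scaled to
  counts; the upper bound is the trivial ``n``),
* Bonferroni correction ``min(1, m*p)`` over a family of ``m`` tests,
* display conventions: two-significant-figure scientific notation with the
  customary ``2.2E-16`` floor of exact-test software, and star labels.

Raw, unrounded values are always retained alongside display strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from scipy.stats import beta as _beta
from scipy.stats import hypergeom as _hypergeom

from .gene_sets import DiseaseGeneSample, FunctionalGeneSet, GeneUniverse, overlap_count

__all__ = [
    "P_FLOOR",
    "DEFAULT_STAR_THRESHOLDS",
    "DIRECTIONAL_STAR_THRESHOLDS",
    "hypergeom_tail",
    "expected_overlap",
    "expected_pct",
    "representation_factor",
    "overlap_ci",
    "bonferroni",
    "format_p",
    "significance_label",
    "EnrichmentResult",
    "EnrichmentTable",
    "enrich",
    "enrich_counts",
]

#: Display floor for p-values; values below are rendered as "2.2E-16", the
#: conventional smallest magnitude printed by exact-test software.
P_FLOOR = 2.22e-16
_P_FLOOR_TEXT = "2.2E-16"

#: Star labels for association tables, applied to the Bonferroni-corrected p.
DEFAULT_STAR_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (1e-6, "***"),
    (1e-3, "**"),
    (1e-2, "*"),
)

#: Star labels for directional (up/down expression) tables.
DIRECTIONAL_STAR_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (0.01, "**"),
    (0.05, "*"),
)


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    if N < 1:
        raise ValueError("universe size must be >= 1")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"set size K={K} and sample size n={n} must lie in [0, N={N}]")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail ``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.

    This is the one-sided exact test p-value for observing at least ``k``
    shared genes between an ``n``-gene sample and a ``K``-gene set in an
    ``N``-gene universe.  Evaluated through the survival function, which
    works in log space internally and stays accurate far below 1e-300.
    """
    _check_counts(k, K, n, N)
    if k == 0:
        return 1.0
    return float(_hypergeom.sf(k - 1, N, K, n))


def expected_overlap(K: int, n: int, N: int) -> float:
    """Chance expectation ``K*n/N`` of the overlap count (unrounded)."""
    if N < 1:
        raise ValueError("universe size must be >= 1")
    if K > N or n > N:
        raise ValueError("set and sample must fit in the universe")
    return K * n / N


def expected_pct(K: int, N: int) -> float:
    """Expected overlap as a percentage of the sample: ``100*K/N``."""
    if N < 1:
        raise ValueError("universe size must be >= 1")
    return 100.0 * K / N


def representation_factor(O: int, E: float) -> float:
    """Observed over expected overlap; > 1 indicates overrepresentation."""
    if E <= 0:
        raise ValueError("expected overlap must be positive (empty set or sample?)")
    return O / E


def overlap_ci(O: int, n: int, confidence: float = 0.95) -> tuple[int, int]:
    """One-sided confidence bounds on the number of matches, ``(lower, n)``.

    The lower bound inverts the exact binomial (Clopper–Pearson) test for the
    proportion ``O/n`` at one-sided level ``confidence`` and scales back to
    counts; the upper bound is the trivial maximum ``n``.
    """
    if not 0 <= O <= n:
        raise ValueError(f"observed overlap O={O} outside [0, n={n}]")
    if O == 0:
        return 0, n
    p_lo = float(_beta.ppf(1.0 - confidence, O, n - O + 1))
    return round(n * p_lo), n


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value ``min(1, m*p)`` for a family of ``m`` tests."""
    if not 0 < p <= 1:
        raise ValueError(f"p-value {p} outside (0, 1]")
    if m < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, m * p)


def format_p(p: float) -> tuple[str, bool]:
    """Render a p-value at two significant figures; floor tiny values.

    Returns ``(text, floored)``.  Values below :data:`P_FLOOR` are displayed
    as the floor itself with ``floored=True``; the raw value is kept in
    machine-readable output.
    """
    if not 0 < p <= 1:
        raise ValueError(f"p-value {p} outside (0, 1]")
    if p < P_FLOOR:
        return _P_FLOOR_TEXT, True
    return f"{p:.1E}", False


def significance_label(p_corrected: float, star_thresholds: Sequence[tuple[float, str]] = DEFAULT_STAR_THRESHOLDS) -> str:
    """Star label for a corrected p-value; ``"NS"`` above every cutoff."""
    for cutoff, label in sorted(star_thresholds):
        if p_corrected <= cutoff:
            return label
    return "NS"


@dataclass(frozen=True)
class EnrichmentResult:
    """One row of an enrichment table.

    ``p_nominal``/``p_corrected`` are the raw, unrounded values;
    ``nominal_text``/``corrected_text`` are their floored two-significant-
    figure renderings.  By the display convention of the source statistical
    environment, the printed corrected value is the family size times the
    *floored* nominal value, so ``corrected_text`` is derived from
    ``max(p_nominal, floor)``; ``floored`` flags rows where the floor bit.
    """

    set_label: str
    set_size: int          # K
    sample_size: int       # n
    universe_size: int     # N
    expected: float        # E = K*n/N
    observed: int          # O
    expected_pct: float    # 100*K/N
    observed_pct: float    # 100*O/n
    rf: float              # O/E
    ci_lower: int
    ci_upper: int
    p_nominal: float
    p_corrected: float
    family_size: int
    floored: bool
    nominal_text: str
    corrected_text: str
    significance: str


@dataclass(frozen=True)
class EnrichmentTable:
    """An ordered family of enrichment results sharing one correction."""

    rows: tuple[EnrichmentResult, ...]
    family_size: int
    alpha: float = 0.01
    star_thresholds: tuple[tuple[float, str], ...] = DEFAULT_STAR_THRESHOLDS
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family_size < 1:
            raise ValueError("family size must be >= 1")
        cutoffs = [c for c, _ in self.star_thresholds]
        if sorted(set(cutoffs)) != sorted(cutoffs):
            raise ValueError("star thresholds must be distinct")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def row(self, label: str) -> EnrichmentResult:
        for r in self.rows:
            if r.set_label == label:
                return r
        raise KeyError(label)


def enrich_counts(
    set_label: str,
    K: int,
    n: int,
    N: int,
    O: int,
    family_size: int = 1,
    star_thresholds: Sequence[tuple[float, str]] = DEFAULT_STAR_THRESHOLDS,
    confidence: float = 0.95,
    p_nominal: float | None = None,
) -> EnrichmentResult:
    """Build an :class:`EnrichmentResult` from raw counts.

    ``p_nominal`` may be supplied externally (e.g. when reproducing a
    published table whose nominal p-values are inputs); otherwise it is the
    exact hypergeometric tail at the given counts.
    """
    if K < 1:
        raise ValueError(f"functional set {set_label!r} is empty")
    if n < 1:
        raise ValueError("sample is empty")
    _check_counts(O, K, n, N)
    E = expected_overlap(K, n, N)
    if p_nominal is None:
        p_nominal = hypergeom_tail(O, K, n, N)
    lo, hi = overlap_ci(O, n, confidence)
    nominal_text, floored = format_p(p_nominal)
    # Printed corrected value follows the floored nominal (display convention);
    # the raw corrected value keeps full precision.
    p_display_base = max(p_nominal, P_FLOOR) if floored else p_nominal
    corrected_display = bonferroni(p_display_base, family_size)
    corrected_text, _ = format_p(corrected_display)
    return EnrichmentResult(
        set_label=set_label,
        set_size=K,
        sample_size=n,
        universe_size=N,
        expected=E,
        observed=O,
        expected_pct=expected_pct(K, N),
        observed_pct=100.0 * O / n,
        rf=representation_factor(O, E),
        ci_lower=lo,
        ci_upper=hi,
        p_nominal=p_nominal,
        p_corrected=bonferroni(p_nominal, family_size),
        family_size=family_size,
        floored=floored,
        nominal_text=nominal_text,
        corrected_text=corrected_text,
        significance=significance_label(corrected_display, star_thresholds),
    )


def enrich(
    sample: DiseaseGeneSample,
    fset: FunctionalGeneSet,
    universe: GeneUniverse,
    family_size: int = 1,
    star_thresholds: Sequence[tuple[float, str]] = DEFAULT_STAR_THRESHOLDS,
    confidence: float = 0.95,
) -> EnrichmentResult:
    """Test one functional set against one disease sample.

    With an explicit universe both inputs are restricted to it first, so all
    counts refer to a single population.  A size-only universe requires the
    sample and set to be pre-restricted by the caller.
    """
    s = sample.restricted_to(universe)
    f = fset.restricted_to(universe)
    O = overlap_count(s, f)
    return enrich_counts(
        f.label, len(f), len(s), universe.size, O,
        family_size=family_size, star_thresholds=star_thresholds,
        confidence=confidence,
    )
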