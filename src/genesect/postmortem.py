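"""Directional expression-enrichment stage.

Postmortem differential-expression studies yield separate lists of up- and
downregulated genes, measured on an array that covers only part of the
genome.  Enrichment of functional categories in those lists must therefore
be computed against the measured background, not the whole genome: every
functional set is first restricted to the background, and the universe size
is the number of measured genes.

Also provided: a cross-tabulation of a reference gene list (for example,
genes downregulated by cerebral ischemia) against probe categories,
reporting the member fraction and the one-sided exact overlap p per probe.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .gene_sets import DiseaseGeneSample, FunctionalGeneSet, GeneUniverse, overlap_count
from .stats import (
    DIRECTIONAL_STAR_THRESHOLDS,
    EnrichmentTable,
    enrich_counts,
    hypergeom_tail,
)

__all__ = [
    "DirectionalExpressionSample",
    "CrosstabRow",
    "run_directional_analysis",
    "crosstab_against_reference",
]


@dataclass(frozen=True)
class DirectionalExpressionSample:
    """Up/downregulated gene lists plus the measured background.

    Invariants enforced at construction: the two directions are disjoint and
    both lie inside the background.
    """

    label: str
    up: frozenset[str]
    down: frozenset[str]
    background: GeneUniverse

    def __post_init__(self) -> None:
        if not self.background.is_explicit:
            raise ValueError("directional analysis needs an explicit measured background")
        both = self.up & self.down
        if both:
            raise ValueError(f"genes in both directions: {sorted(both)[:5]}")
        outside = (self.up | self.down) - self.background.members  # type: ignore[operator]
        if outside:
            raise ValueError(f"genes outside measured background: {sorted(outside)[:5]}")
        if not self.up or not self.down:
            raise ValueError("both direction lists must be non-empty")


def run_directional_analysis(
    sample: DirectionalExpressionSample,
    sets: Mapping[str, FunctionalGeneSet],
    alpha: float = 0.05,
    star_thresholds: Sequence[tuple[float, str]] = DIRECTIONAL_STAR_THRESHOLDS,
) -> tuple[EnrichmentTable, EnrichmentTable]:
    """Enrichment of functional sets in the up and down lists, separately.

    Each direction forms its own Bonferroni family (one test per set).
    Returns ``(up_table, down_table)``; rows carry the direction in the
    table provenance.
    """
    N = sample.background.size
    m = len(sets)
    if m < 1:
        raise ValueError("no functional sets supplied")

    def direction_table(genes: frozenset[str], direction: str) -> EnrichmentTable:
        ds = DiseaseGeneSample(
            label=f"{sample.label}:{direction}", members=genes, source_kind="postmortem",
        )
        rows = []
        for fset in sets.values():
            restricted = fset.restricted_to(sample.background)
            O = overlap_count(ds, restricted)
            rows.append(
                enrich_counts(
                    restricted.label, len(restricted), len(genes), N, O,
                    family_size=m, star_thresholds=star_thresholds,
                )
            )
        return EnrichmentTable(
            rows=tuple(rows),
            family_size=m,
            alpha=alpha,
            star_thresholds=tuple(star_thresholds),
            provenance={
                "direction": direction,
                "background_size": N,
                "sample_label": sample.label,
                "n_genes": len(genes),
            },
        )

    return direction_table(sample.up, "up"), direction_table(sample.down, "down")


@dataclass(frozen=True)
class CrosstabRow:
    probe_label: str
    overlap: int
    reference_size: int
    fraction_pct: float
    p_value: float


def crosstab_against_reference(
    reference: FunctionalGeneSet,
    probes: Mapping[str, FunctionalGeneSet],
    universe: GeneUniverse,
) -> tuple[CrosstabRow, ...]:
    """Fraction of a reference gene list falling in each probe category.

    For each probe set reports ``|reference ∩ probe| / |reference|`` as a
    percentage and the one-sided exact p-value of that overlap against the
    universe (reference as sample, probe as set).
    """
    ref = reference.restricted_to(universe)
    if not ref.members:
        raise ValueError("reference set is empty")
    n = len(ref)
    rows = []
    for probe in probes.values():
        restricted = probe.restricted_to(universe)
        O = overlap_count(ref, restricted)
        rows.append(
            CrosstabRow(
                probe_label=restricted.label,
                overlap=O,
                reference_size=n,
                fraction_pct=100.0 * O / n,
                p_value=hypergeom_tail(O, len(restricted), n, universe.size),
            )
        )
    return tuple(rows)
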