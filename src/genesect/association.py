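"""Association-study analysis stage.

Builds a family of functional gene sets — base categories plus derived ones
written in a small set-algebra grammar (``"V | I"`` for union, ``"VI × ND"``
for interaction, ``"V − PV"`` for exclusion) — and tests every one of them
against a disease-associated gene sample on a genome background, producing an
enrichment table with a shared Bonferroni family.

The module also ships the printed inputs of the reference intersection
analysis of schizophrenia-associated genes against vascular (V), perivascular
(PV), shear-stress (SS), ischemia (I), postischemic-repair (R),
neurodevelopmental (ND) and synaptic (SY) gene sets: 23 rows, a combined
sample of 345 genes, a 21,000-gene background and family size 23.
``reproduce_table1`` recomputes every derived column (expected counts and
percentages, RF, confidence bounds, corrected p, significance) from those
printed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .gene_sets import (
    DiseaseGeneSample,
    FunctionalGeneSet,
    GeneUniverse,
    set_exclusion,
    set_interaction,
    set_union,
)
from .stats import (
    DEFAULT_STAR_THRESHOLDS,
    EnrichmentTable,
    enrich,
    enrich_counts,
)

__all__ = [
    "AnalysisPlan",
    "evaluate_recipe",
    "materialize_sets",
    "run_association_analysis",
    "TABLE1_UNIVERSE_SIZE",
    "TABLE1_SAMPLE_SIZE",
    "TABLE1_FAMILY_SIZE",
    "TABLE1_BASE_SIZES",
    "TABLE1_RECIPES",
    "TABLE1_ROW_ORDER",
    "TABLE1_PRINTED_INPUTS",
    "reproduce_table1",
]

_UNION_OPS = {"|", "+", "∪"}
_INTER_OPS = {"×", "x", "&", "∩"}
_EXCL_OPS = {"−", "-", "\\"}


def evaluate_recipe(
    expr: str,
    defined: Mapping[str, FunctionalGeneSet],
    label: str | None = None,
) -> FunctionalGeneSet:
    """Evaluate a set-algebra expression over already-defined sets.

    Operators (all left-associative, equal precedence): union ``|``/``+``,
    interaction ``×``/``x``/``&``, exclusion ``−``/``-``.  Operands are
    whitespace-separated labels of previously defined sets, so recipes are
    acyclic by construction.  Union labels concatenate (``"V | I"`` yields
    label ``"VI"``); pass ``label`` to override the derived label.
    """
    tokens = expr.split()
    if not tokens or len(tokens) % 2 == 0:
        raise ValueError(f"malformed recipe {expr!r}")

    def lookup(name: str) -> FunctionalGeneSet:
        try:
            return defined[name]
        except KeyError:
            raise KeyError(f"recipe {expr!r} references undefined set {name!r}") from None

    result = lookup(tokens[0])
    for op, name in zip(tokens[1::2], tokens[2::2]):
        operand = lookup(name)
        if op in _UNION_OPS:
            result = set_union(result, operand)
        elif op in _INTER_OPS:
            result = set_interaction(result, operand)
        elif op in _EXCL_OPS:
            result = set_exclusion(result, operand)
        else:
            raise ValueError(f"unknown operator {op!r} in recipe {expr!r}")
    if label is not None:
        result = FunctionalGeneSet(label=label, members=result.members)
    return result


@dataclass(frozen=True)
class AnalysisPlan:
    """Everything needed to run one association analysis.

    ``recipes`` is an ordered list of ``(label_or_None, expression)`` pairs
    evaluated in order; ``row_order`` selects and orders the sets actually
    tested (default: base sets then recipes, in definition order).  The
    Bonferroni family size defaults to the number of rows.
    """

    universe: GeneUniverse
    base_sets: Mapping[str, FunctionalGeneSet]
    recipes: Sequence[tuple[str | None, str]] = ()
    row_order: Sequence[str] | None = None
    alpha: float = 0.01
    star_thresholds: tuple[tuple[float, str], ...] = DEFAULT_STAR_THRESHOLDS
    family_size: int | None = None


def materialize_sets(plan: AnalysisPlan) -> dict[str, FunctionalGeneSet]:
    """Restrict base sets to the universe and evaluate recipes in order."""
    defined: dict[str, FunctionalGeneSet] = {}
    for name, fset in plan.base_sets.items():
        defined[name] = fset.restricted_to(plan.universe)
    for label, expr in plan.recipes:
        derived = evaluate_recipe(expr, defined, label=label)
        if derived.label in defined:
            raise ValueError(f"recipe redefines set {derived.label!r}")
        defined[derived.label] = derived
    return defined


def run_association_analysis(plan: AnalysisPlan, sample: DiseaseGeneSample) -> EnrichmentTable:
    """Test every planned set against one disease sample.

    Returns one row per planned set, in plan order, sharing a single
    Bonferroni family (by default ``m`` = number of rows).
    """
    sets = materialize_sets(plan)
    order = list(plan.row_order) if plan.row_order is not None else list(sets)
    missing = [lbl for lbl in order if lbl not in sets]
    if missing:
        raise KeyError(f"row_order references undefined sets: {missing}")
    m = plan.family_size if plan.family_size is not None else len(order)
    restricted = sample.restricted_to(plan.universe)
    rows = tuple(
        enrich(
            restricted, sets[lbl], plan.universe,
            family_size=m, star_thresholds=plan.star_thresholds,
        )
        for lbl in order
    )
    return EnrichmentTable(
        rows=rows,
        family_size=m,
        alpha=plan.alpha,
        star_thresholds=plan.star_thresholds,
        provenance={
            "universe_size": plan.universe.size,
            "universe_label": plan.universe.label,
            "family_size": m,
            "sample_label": sample.label,
            "sample_size": restricted.size,
        },
    )


# --- reference intersection table -----------------------------------------

TABLE1_UNIVERSE_SIZE = 21_000
TABLE1_SAMPLE_SIZE = 345
TABLE1_FAMILY_SIZE = 23

#: Published sizes of the base functional categories (after restriction to
#: the analysis universe, PV is a subset of V).
TABLE1_BASE_SIZES: dict[str, int] = {
    "V": 3249,
    "PV": 253,
    "SS": 2818,
    "I": 1673,
    "R": 159,
    "ND": 3211,
    "SY": 1977,
}

#: Derived-set recipes, in evaluation order.
TABLE1_RECIPES: tuple[tuple[str | None, str], ...] = (
    (None, "V | I"),               # label "VI"
    (None, "V | I | R | ND"),      # label "VIRND"
    ("Repair", "R | ND"),
    (None, "V − PV"),
    (None, "VI × ND"),
    (None, "VI × Repair"),
    (None, "V × ND"),
    (None, "V × Repair"),
    (None, "I × ND"),
    (None, "I × Repair"),
    (None, "VI − ND"),
    (None, "VI − SY"),
    (None, "I − ND"),
    (None, "I − SY"),
    (None, "ND − VI"),
    (None, "SY − VI"),
)

#: Row order of the reference table.
TABLE1_ROW_ORDER: tuple[str, ...] = (
    "VIRND", "VI", "V", "PV", "V − PV", "SS", "I", "R", "Repair", "ND",
    "VI × ND", "VI × Repair", "V × ND", "V × Repair", "I × ND", "I × Repair",
    "SY", "VI − ND", "VI − SY", "I − ND", "I − SY", "ND − VI", "SY − VI",
)

#: Printed inputs per row: set size K, observed overlap O, nominal one-sided
#: exact p as printed (two significant figures; 2.2e-16 entries are floored).
TABLE1_PRINTED_INPUTS: tuple[tuple[str, int, int, float], ...] = (
    ("VIRND", 6409, 195, 2.2e-16),
    ("VI", 4213, 139, 2.2e-16),
    ("V", 3249, 110, 2.2e-14),
    ("PV", 253, 35, 2.2e-16),
    ("V − PV", 2996, 75, 1.1e-04),
    ("SS", 2818, 69, 4.3e-04),
    ("I", 1673, 74, 4.8e-15),
    ("R", 159, 31, 2.2e-16),
    ("Repair", 3319, 129, 2.2e-16),
    ("ND", 3211, 111, 3.8e-15),
    ("VI × ND", 1050, 57, 8.8e-16),
    ("VI × Repair", 1123, 73, 2.2e-16),
    ("V × ND", 783, 44, 7.6e-13),
    ("V × Repair", 844, 59, 2.2e-16),
    ("I × ND", 522, 37, 6.1e-14),
    ("I × Repair", 568, 47, 2.2e-16),
    ("SY", 1977, 91, 2.2e-16),
    ("VI − ND", 3163, 82, 1.4e-05),
    ("VI − SY", 3273, 76, 9.8e-04),
    ("I − ND", 1151, 37, 8.9e-05),
    ("I − SY", 1180, 38, 6.9e-05),
    ("ND − VI", 2161, 54, 1.3e-03),
    ("SY − VI", 1037, 28, 7.5e-03),
)


def reproduce_table1(
    universe_size: int = TABLE1_UNIVERSE_SIZE,
    sample_size: int = TABLE1_SAMPLE_SIZE,
    family_size: int = TABLE1_FAMILY_SIZE,
    use_printed_p: bool = True,
) -> EnrichmentTable:
    """Recompute the derived columns of the reference table.

    Expected counts/percentages, observed percentages, RF, confidence bounds,
    corrected p and significance labels are all derived at run time from the
    printed per-row inputs (K, n, O and — when ``use_printed_p`` — the printed
    nominal p, which enters the corrected column; the corrected value is the
    family size times the nominal one).  With ``use_printed_p=False`` the
    nominal p is recomputed from the hypergeometric tail instead.
    """
    rows = tuple(
        enrich_counts(
            label, K, sample_size, universe_size, O,
            family_size=family_size,
            p_nominal=p if use_printed_p else None,
        )
        for label, K, O, p in TABLE1_PRINTED_INPUTS
    )
    return EnrichmentTable(
        rows=rows,
        family_size=family_size,
        provenance={
            "universe_size": universe_size,
            "family_size": family_size,
            "sample_size": sample_size,
            "nominal_p_source": "printed" if use_printed_p else "computed",
        },
    )
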