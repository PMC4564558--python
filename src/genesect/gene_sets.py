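"""Core data model: gene symbols, universes, functional sets, disease samples.

Every downstream statistic in this package is a statement about set
cardinalities, so the data model is deliberately thin: genes are normalized
symbol strings, and all containers hold ``frozenset`` members.  The set
algebra here (interaction ``×``, exclusion ``−``, union) is the grammar used
to build derived functional categories such as ``VI × ND`` or ``V − PV``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

log = logging.getLogger("genesect")

__all__ = [
    "normalize_symbol",
    "normalize_symbols",
    "GeneUniverse",
    "FunctionalGeneSet",
    "DiseaseGeneSample",
    "set_interaction",
    "set_exclusion",
    "set_union",
    "combine_samples",
    "overlap_count",
]


def normalize_symbol(raw: str) -> str:
    """Canonicalize a gene symbol: trim whitespace, uppercase.

    Symbol lists compiled from heterogeneous sources mix case freely; a single
    canonical form prevents silent undercounting of intersections.  Raises
    :class:`ValueError` for symbols that are empty after trimming.
    """
    sym = raw.strip().upper()
    if not sym:
        raise ValueError("empty gene symbol")
    return sym


def normalize_symbols(raws: Iterable[str]) -> frozenset[str]:
    """Normalize and deduplicate a collection of symbols.

    Duplicates after normalization are silently merged; the caller is
    responsible for logging counts where that matters (see :mod:`genesect.io`).
    """
    return frozenset(normalize_symbol(r) for r in raws)


@dataclass(frozen=True)
class GeneUniverse:
    """The background population against which expectations are computed.

    Either an explicit membership (``members``) or a bare size
    (``size_only``), for analyses where only the background count is known.
    A size-only universe supports expectation and test computations but not
    membership queries.
    """

    label: str = "universe"
    members: frozenset[str] | None = None
    size_only: int | None = None

    def __post_init__(self) -> None:
        if (self.members is None) == (self.size_only is None):
            raise ValueError("specify exactly one of members / size_only")
        if self.size < 1:
            raise ValueError("universe must contain at least one gene")

    @classmethod
    def from_symbols(cls, symbols: Iterable[str], label: str = "universe") -> "GeneUniverse":
        return cls(label=label, members=normalize_symbols(symbols))

    @classmethod
    def from_size(cls, size: int, label: str = "universe") -> "GeneUniverse":
        return cls(label=label, size_only=int(size))

    @property
    def size(self) -> int:
        return len(self.members) if self.members is not None else int(self.size_only)  # type: ignore[arg-type]

    @property
    def is_explicit(self) -> bool:
        return self.members is not None

    def __contains__(self, symbol: str) -> bool:
        if self.members is None:
            raise TypeError(f"universe '{self.label}' is size-only; membership is undefined")
        return symbol in self.members

    def __len__(self) -> int:
        return self.size


@dataclass(frozen=True)
class FunctionalGeneSet:
    """A labeled functional category of genes (e.g. vascular, ischemia-induced).

    ``label`` follows the display notation used in output tables; derived
    labels are built by the algebra functions (``"A × B"``, ``"A − B"``).
    """

    label: str
    members: frozenset[str]
    provenance: str = ""

    @classmethod
    def from_symbols(cls, label: str, symbols: Iterable[str], provenance: str = "") -> "FunctionalGeneSet":
        return cls(label=label, members=normalize_symbols(symbols), provenance=provenance)

    @property
    def size(self) -> int:
        return len(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def restricted_to(self, universe: GeneUniverse) -> "FunctionalGeneSet":
        """Restrict membership to an explicit universe, logging dropped genes.

        Expectations are only coherent when every set lives in one population,
        so restriction is the default preparation step before testing.
        """
        if not universe.is_explicit:
            return self
        kept = self.members & universe.members  # type: ignore[operator]
        dropped = len(self.members) - len(kept)
        if dropped:
            log.info(
                "set %r: dropped %d of %d genes outside universe %r",
                self.label, dropped, len(self.members), universe.label,
            )
        return replace(self, members=kept)


@dataclass(frozen=True)
class DiseaseGeneSample:
    """A disease-associated gene list (one study sample or a combination)."""

    label: str
    members: frozenset[str]
    source_kind: str = "synthetic"

    _KINDS = frozenset({
        "TDT", "case_control", "GWAS_catalog", "convergent", "SWGPGC",
        "postmortem", "combined", "synthetic",
    })

    def __post_init__(self) -> None:
        if self.source_kind not in self._KINDS:
            raise ValueError(f"unknown source_kind {self.source_kind!r}")
        if not self.members:
            raise ValueError(f"sample {self.label!r} is empty")

    @classmethod
    def from_symbols(cls, label: str, symbols: Iterable[str], source_kind: str = "synthetic") -> "DiseaseGeneSample":
        return cls(label=label, members=normalize_symbols(symbols), source_kind=source_kind)

    @property
    def size(self) -> int:
        return len(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def restricted_to(self, universe: GeneUniverse) -> "DiseaseGeneSample":
        if not universe.is_explicit:
            return self
        kept = self.members & universe.members  # type: ignore[operator]
        dropped = len(self.members) - len(kept)
        if dropped:
            log.info(
                "sample %r: dropped %d of %d genes outside universe %r",
                self.label, dropped, len(self.members), universe.label,
            )
        return replace(self, members=kept)


# --- set algebra -----------------------------------------------------------

def set_interaction(a: FunctionalGeneSet, b: FunctionalGeneSet) -> FunctionalGeneSet:
    """Interaction (intersection) of two functional sets, labeled ``"a × b"``."""
    return FunctionalGeneSet(label=f"{a.label} × {b.label}", members=a.members & b.members)


def set_exclusion(a: FunctionalGeneSet, b: FunctionalGeneSet) -> FunctionalGeneSet:
    """Exclusion (difference) — members of ``a`` with ``b``'s removed, ``"a − b"``."""
    return FunctionalGeneSet(label=f"{a.label} − {b.label}", members=a.members - b.members)


def set_union(a: FunctionalGeneSet, b: FunctionalGeneSet, label: str | None = None) -> FunctionalGeneSet:
    """Union of two functional sets.

    Combined categories conventionally get a concatenated label ("V" and "I"
    make "VI"); pass ``label`` to override.
    """
    return FunctionalGeneSet(label=label or f"{a.label}{b.label}", members=a.members | b.members)


def combine_samples(samples: Sequence[DiseaseGeneSample], label: str = "combined") -> DiseaseGeneSample:
    """Deduplicated union of several disease samples (``source_kind="combined"``)."""
    if not samples:
        raise ValueError("no samples to combine")
    members: frozenset[str] = frozenset()
    for s in samples:
        members = members | s.members
    return DiseaseGeneSample(label=label, members=members, source_kind="combined")


def overlap_count(sample: DiseaseGeneSample | FunctionalGeneSet, fset: FunctionalGeneSet) -> int:
    """Number of genes shared by a sample and a functional set (symmetric)."""
    return len(sample.members & fset.members)
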