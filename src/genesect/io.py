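"""File I/O: plain gene lists, GMT gene-set files, TSV tables, manifests.

Formats are deliberately boring.  Gene lists are UTF-8 text with one symbol
per line (``#`` comments and blank lines ignored); GMT is the standard
tab-separated gene-set format (name, description, members).  Enrichment
tables are written as TSV with the reference column layout plus raw
(unfloored) p columns.  Every table write can be accompanied by a JSON
manifest recording inputs, seeds and digests, sufficient to reproduce the
TSV byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from importlib import metadata
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .gene_sets import DiseaseGeneSample, FunctionalGeneSet, normalize_symbol
from .stats import EnrichmentTable

log = logging.getLogger("genesect")

__all__ = [
    "read_symbols",
    "read_gene_list",
    "read_functional_set",
    "read_gmt",
    "write_gene_list",
    "write_gmt",
    "table_to_frame",
    "write_table",
    "RunManifest",
    "write_manifest",
]

TABLE_COLUMNS = [
    "Functions", "N", "SZ N", "E (N)", "O (N)", "E (%)", "O (%)", "RF", "CI",
    "Nominal P", "Bonferroni corrected P", "significance",
    "raw nominal P", "raw corrected P",
]


def read_symbols(path: str | Path) -> list[str]:
    """Read and normalize a plain gene list; returns ordered unique symbols.

    Malformed (empty-after-trim) non-comment lines and duplicate counts are
    logged with line numbers.  Raises on files with no usable symbols.
    """
    path = Path(path)
    seen: dict[str, None] = {}
    duplicates = 0
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        try:
            sym = normalize_symbol(stripped)
        except ValueError:
            log.warning("%s:%d: malformed gene symbol %r", path, lineno, line)
            continue
        if sym in seen:
            duplicates += 1
        else:
            seen[sym] = None
    if not seen:
        raise ValueError(f"{path}: no gene symbols found")
    if duplicates:
        log.info("%s: %d duplicate symbols merged", path, duplicates)
    return list(seen)


def read_gene_list(path: str | Path, label: str | None = None, source_kind: str = "synthetic") -> DiseaseGeneSample:
    path = Path(path)
    return DiseaseGeneSample.from_symbols(
        label or path.stem, read_symbols(path), source_kind=source_kind,
    )


def read_functional_set(path: str | Path, label: str | None = None) -> FunctionalGeneSet:
    path = Path(path)
    return FunctionalGeneSet.from_symbols(label or path.stem, read_symbols(path), provenance=str(path))


def read_gmt(path: str | Path) -> dict[str, FunctionalGeneSet]:
    """Read a GMT file: one set per line as ``name<TAB>description<TAB>genes…``.

    Duplicate set names and lines with fewer than three fields are errors
    (reported with line numbers); duplicate members within a line are merged
    and logged.
    """
    path = Path(path)
    sets: dict[str, FunctionalGeneSet] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description and members")
        name, description, *genes = fields
        name = name.strip()
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        fset = FunctionalGeneSet.from_symbols(name, (g for g in genes if g.strip()), provenance=description)
        if len(fset) < len([g for g in genes if g.strip()]):
            log.info("%s:%d: duplicate members merged in set %r", path, lineno, name)
        sets[name] = fset
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_gene_list(symbols: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in sorted(symbols)), encoding="utf-8")


def write_gmt(sets: Mapping[str, FunctionalGeneSet], path: str | Path) -> None:
    lines = []
    for name, fset in sets.items():
        desc = fset.provenance or "-"
        lines.append("\t".join([name, desc, *sorted(fset.members)]))
    Path(path).write_text("".join(f"{l}\n" for l in lines), encoding="utf-8")


def table_to_frame(table: EnrichmentTable) -> pd.DataFrame:
    """Enrichment table as a DataFrame in the reference column layout.

    Counts are rounded to integers and percentages/RF to one decimal for the
    display columns; the raw p columns keep full precision.
    """
    records = []
    for r in table.rows:
        records.append({
            "Functions": r.set_label,
            "N": r.set_size,
            "SZ N": r.sample_size,
            "E (N)": round(r.expected),
            "O (N)": r.observed,
            "E (%)": round(r.expected_pct, 1),
            "O (%)": round(r.observed_pct, 1),
            "RF": round(r.rf, 1),
            "CI": f"{r.ci_lower}–{r.ci_upper}",
            "Nominal P": r.nominal_text,
            "Bonferroni corrected P": r.corrected_text,
            "significance": r.significance,
            "raw nominal P": repr(r.p_nominal),
            "raw corrected P": repr(r.p_corrected),
        })
    return pd.DataFrame.from_records(records, columns=TABLE_COLUMNS)


def write_table(table: EnrichmentTable, path: str | Path) -> None:
    """Write an enrichment table as TSV (deterministic byte layout)."""
    if not table.rows:
        raise ValueError("refusing to write an empty table")
    frame = table_to_frame(table)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility record accompanying an output table."""

    command: str
    parameters: dict = field(default_factory=dict)
    universe_size: int | None = None
    family_size: int | None = None
    seeds: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    package_version: str = ""
    timestamp: str = ""

    @staticmethod
    def digest(path: str | Path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    @classmethod
    def create(
        cls,
        command: str,
        parameters: Mapping | None = None,
        universe_size: int | None = None,
        family_size: int | None = None,
        seeds: Mapping | None = None,
        inputs: Iterable[str | Path] = (),
    ) -> "RunManifest":
        try:
            version = metadata.version("genesect")
        except metadata.PackageNotFoundError:
            version = "unknown"
        return cls(
            command=command,
            parameters=dict(parameters or {}),
            universe_size=universe_size,
            family_size=family_size,
            seeds=dict(seeds or {}),
            input_digests={str(p): cls.digest(p) for p in inputs},
            package_version=version,
            timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )


def write_manifest(manifest: RunManifest, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(manifest), indent=2, sort_keys=True) + "\n", encoding="utf-8")
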