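"""Readers and writers for expression tables, regulon lists and assays.

All tabular I/O in the pipeline goes through this module so that gene-ID
canonicalization and float formatting are applied uniformly. Tables are
plain TSV/CSV; regulons are one gene ID per line.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from gradientnet.errors import TableFormatError, TableParseError, ValidationError

__all__ = [
    "ExpressionProfile",
    "RegulonTable",
    "GerminationAssay",
    "TableDialect",
    "canonicalize_gene_id",
    "load_expression_table",
    "write_expression_table",
    "load_regulon",
    "resolve_regulon_conflicts",
    "load_germination_table",
    "format_float",
]

#: Locus pattern: "At" + chromosome (1-5, C or M) + "g" + 5 digits.
_LOCUS_RE = re.compile(r"^at([1-5cm])g(\d{5})$", re.IGNORECASE)


def canonicalize_gene_id(gene_id: str) -> str:
    """Normalize a locus identifier to the canonical ``AtNgNNNNN`` form.

    Comparison is case-insensitive: ``AT2G28470``, ``at2g28470`` and
    ``At2g28470`` all map to ``At2g28470``. Organellar chromosomes keep an
    uppercase letter (``AtCg00490``).

    Raises
    ------
    ValueError
        If the identifier does not match the locus pattern.
    """
    m = _LOCUS_RE.match(gene_id.strip())
    if m is None:
        raise ValueError(f"not a valid locus identifier: {gene_id!r}")
    chrom = m.group(1).upper() if m.group(1).isalpha() else m.group(1)
    return f"At{chrom}g{m.group(2)}"


def format_float(x: float) -> str:
    """Render a float with 6 significant digits (stable TSV output)."""
    return f"{x:.6g}"


@dataclass(frozen=True)
class ExpressionProfile:
    """One gene's raw (and optionally area-normalized) tissue signals."""

    gene_id: str
    fun: float
    csc: float
    dsc_raw: float
    dsc_norm: float | None = None

    def __post_init__(self) -> None:
        for name in ("fun", "csc", "dsc_raw"):
            value = getattr(self, name)
            if not (value >= 0):
                raise ValidationError(
                    f"{self.gene_id}: {name} must be non-negative, got {value}"
                )
        if self.dsc_norm is not None and not (self.dsc_norm >= 0):
            raise ValidationError(
                f"{self.gene_id}: dsc_norm must be non-negative, got {self.dsc_norm}"
            )

    def with_dsc_norm(self, dsc_norm: float) -> "ExpressionProfile":
        return replace(self, dsc_norm=dsc_norm)


@dataclass(frozen=True)
class RegulonTable:
    """Gene set regulated by one hormone in one direction."""

    hormone: str
    direction: str
    genes: frozenset[str]
    name: str = ""

    _HORMONES = ("auxin", "ABA", "brassinosteroid")
    _DIRECTIONS = ("up", "down")

    def __post_init__(self) -> None:
        if self.hormone not in self._HORMONES:
            raise ValidationError(
                f"unknown hormone {self.hormone!r}; expected one of {self._HORMONES}"
            )
        if self.direction not in self._DIRECTIONS:
            raise ValidationError(
                f"unknown direction {self.direction!r}; expected 'up' or 'down'"
            )
        if not self.name:
            object.__setattr__(self, "name", f"{self.hormone}-{self.direction}")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GerminationAssay:
    """Per-dish germination counts with an explicit mutant/control pairing.

    Control (wild-type) dishes leave ``paired_control_dish`` empty; every
    mutant dish names exactly one control dish.
    """

    genotype: str
    dish_id: str
    germinated: int
    total: int
    paired_control_dish: str = ""

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValidationError(f"dish {self.dish_id}: total must be positive")
        if self.germinated < 0:
            raise ValidationError(f"dish {self.dish_id}: germinated must be >= 0")
        if self.germinated > self.total:
            raise ValidationError(
                f"dish {self.dish_id}: germinated ({self.germinated}) exceeds "
                f"total ({self.total})"
            )


@dataclass(frozen=True)
class TableDialect:
    """Column naming and separator for expression tables."""

    sep: str = "\t"
    gene_col: str = "gene"
    fun_col: str = "FUN"
    csc_col: str = "CSC"
    dsc_col: str = "DSC"
    dsc_norm_col: str = "DSC_norm"


DEFAULT_DIALECT = TableDialect()


def _parse_signal(raw: object, column: str, row_number: int) -> float:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise TableParseError(
            f"row {row_number}: non-numeric value {raw!r} in column {column!r}"
        ) from None
    if value != value:  # NaN from empty cells
        raise TableParseError(
            f"row {row_number}: non-numeric value {raw!r} in column {column!r}"
        )
    return value


def load_expression_table(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> list[ExpressionProfile]:
    """Read a tissue-resolved expression table into validated profiles.

    One row per gene; IDs are canonicalized, duplicates (after
    canonicalization) are an error, and ``dsc_norm`` is left unset.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=dialect.sep, dtype=str)
    required = [dialect.gene_col, dialect.fun_col, dialect.csc_col, dialect.dsc_col]
    for column in required:
        if column not in frame.columns:
            raise TableFormatError(
                f"{path.name}: missing required column {column!r} "
                f"(found {list(frame.columns)})"
            )

    profiles: list[ExpressionProfile] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        record = dict(zip(frame.columns, row))
        raw_id = record[dialect.gene_col]
        try:
            gene_id = canonicalize_gene_id(str(raw_id))
        except ValueError as exc:
            raise TableParseError(f"row {idx}: {exc}") from None
        profiles.append(
            ExpressionProfile(
                gene_id=gene_id,
                fun=_parse_signal(record[dialect.fun_col], dialect.fun_col, idx),
                csc=_parse_signal(record[dialect.csc_col], dialect.csc_col, idx),
                dsc_raw=_parse_signal(record[dialect.dsc_col], dialect.dsc_col, idx),
            )
        )

    seen: dict[str, int] = {}
    duplicates: list[str] = []
    for profile in profiles:
        seen[profile.gene_id] = seen.get(profile.gene_id, 0) + 1
    duplicates = sorted(g for g, n in seen.items() if n > 1)
    if duplicates:
        raise ValidationError(
            "duplicate gene IDs after canonicalization: " + ", ".join(duplicates)
        )
    return profiles


def write_expression_table(
    profiles: Iterable[ExpressionProfile],
    path: str | Path,
    dialect: TableDialect = DEFAULT_DIALECT,
) -> None:
    """Write profiles as TSV/CSV; floats at 6 significant digits."""
    profiles = list(profiles)
    with_norm = any(p.dsc_norm is not None for p in profiles)
    columns = [dialect.gene_col, dialect.fun_col, dialect.csc_col, dialect.dsc_col]
    if with_norm:
        columns.append(dialect.dsc_norm_col)
    lines = [dialect.sep.join(columns)]
    for p in profiles:
        cells = [p.gene_id, format_float(p.fun), format_float(p.csc), format_float(p.dsc_raw)]
        if with_norm:
            cells.append("" if p.dsc_norm is None else format_float(p.dsc_norm))
        lines.append(dialect.sep.join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def load_regulon(
    path: str | Path, hormone: str, direction: str, name: str = ""
) -> RegulonTable:
    """Read a one-gene-per-line (or one-column) regulon list.

    Unparseable IDs are skipped with a warning; an empty file yields an
    empty regulon with a warning.
    """
    path = Path(path)
    genes: set[str] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        token = line.strip().split("\t")[0].split(",")[0].strip()
        if not token or token.startswith("#"):
            continue
        if token.lower() in ("gene", "gene_id", "locus"):  # tolerated header
            continue
        try:
            genes.add(canonicalize_gene_id(token))
        except ValueError:
            warnings.warn(
                f"{path.name} line {lineno}: skipping unparseable ID {token!r}",
                stacklevel=2,
            )
    if not genes:
        warnings.warn(f"{path.name}: empty regulon list", stacklevel=2)
    return RegulonTable(
        hormone=hormone,
        direction=direction,
        genes=frozenset(genes),
        name=name or f"{hormone}-{direction}",
    )


def resolve_regulon_conflicts(
    up: RegulonTable, down: RegulonTable
) -> tuple[RegulonTable, RegulonTable, list[str]]:
    """Enforce up/down disjointness for one hormone.

    Genes claimed by both directions are dropped from both and reported.
    """
    if up.hormone != down.hormone:
        raise ValidationError(
            f"cannot reconcile regulons of different hormones: "
            f"{up.hormone} vs {down.hormone}"
        )
    conflicts = sorted(up.genes & down.genes)
    if conflicts:
        warnings.warn(
            f"{up.hormone}: {len(conflicts)} gene(s) in both up and down "
            "regulons dropped from both: " + ", ".join(conflicts),
            stacklevel=2,
        )
    up_clean = replace(up, genes=frozenset(up.genes - set(conflicts)))
    down_clean = replace(down, genes=frozenset(down.genes - set(conflicts)))
    return up_clean, down_clean, conflicts


_GERM_COLUMNS = ("genotype", "dish_id", "germinated", "total", "paired_control_dish")


def load_germination_table(path: str | Path) -> list[GerminationAssay]:
    """Read and validate a paired germination-assay table (TSV)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in _GERM_COLUMNS:
        if column not in frame.columns:
            raise TableFormatError(f"{path.name}: missing required column {column!r}")

    assays: list[GerminationAssay] = []
    for idx, row in enumerate(frame.itertuples(index=False), start=2):
        record = dict(zip(frame.columns, row))
        try:
            germinated = int(record["germinated"])
            total = int(record["total"])
        except ValueError:
            raise TableParseError(f"row {idx}: non-integer count") from None
        assays.append(
            GerminationAssay(
                genotype=record["genotype"],
                dish_id=record["dish_id"],
                germinated=germinated,
                total=total,
                paired_control_dish=record["paired_control_dish"].strip(),
            )
        )

    dish_ids = [a.dish_id for a in assays]
    if len(set(dish_ids)) != len(dish_ids):
        raise ValidationError(f"{path.name}: duplicate dish_id values")
    known = set(dish_ids)
    for assay in assays:
        ref = assay.paired_control_dish
        if ref and ref not in known:
            raise ValidationError(
                f"dish {assay.dish_id}: paired control dish {ref!r} not found"
            )
        if ref == assay.dish_id:
            raise ValidationError(f"dish {assay.dish_id}: paired with itself")
    return assays


def profiles_to_frame(profiles: Sequence[ExpressionProfile]) -> pd.DataFrame:
    """Convenience view of profiles as a DataFrame (analysis/report use)."""
    return pd.DataFrame(
        {
            "gene_id": [p.gene_id for p in profiles],
            "fun": [p.fun for p in profiles],
            "csc": [p.csc for p in profiles],
            "dsc_raw": [p.dsc_raw for p in profiles],
            "dsc_norm": [p.dsc_norm for p in profiles],
        }
    )
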