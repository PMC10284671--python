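"""Readers and writers for DepMap-dialect tables.

DepMap ships its gene-level matrices with cell lines in rows and column
headers of the form ``"SYMBOL (ENTREZ)"`` (e.g. ``"ARID1A (8289)"``).  This
module normalizes everything to a single in-memory model:

* :class:`GeneMatrix` — a genes × lines float matrix (``NaN`` = missing) with
  a declared role (copy number, mRNA/protein expression, KO effect score, or
  lethality probability),
* sample annotations and MAF-like mutation calls as tidy ``pandas``
  DataFrames with normalized column names and closed vocabularies.

Column names of the source files are configurable; the defaults follow the
DepMap release dialect.  Gene symbols are the primary key throughout; Entrez
IDs parsed from matrix headers are retained as passive metadata.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, ParseError, SchemaError

__all__ = [
    "Consequence",
    "Zygosity",
    "MatrixRole",
    "MutationRecord",
    "GeneMatrix",
    "SampleColumns",
    "MutationColumns",
    "MISSING_TOKENS",
    "read_sample_annotations",
    "read_mutations",
    "read_gene_matrix",
    "write_results_table",
    "read_results_table",
    "records_from_frame",
]

#: Source tokens interpreted as a missing value in numeric matrices.
MISSING_TOKENS: tuple[str, ...] = ("", "NA")

_HEADER_RE = re.compile(r"^\s*(?P<symbol>.+?)\s*\((?P<entrez>\d+)\)\s*$")


class Consequence(str, Enum):
    """Closed consequence vocabulary; unknown source strings map to OTHER."""

    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    START_LOST = "start_lost"
    MISSENSE = "missense"
    SILENT = "silent"
    OTHER = "other"


class Zygosity(str, Enum):
    HOMOZYGOUS = "homozygous"
    HETEROZYGOUS = "heterozygous"
    UNKNOWN = "unknown"


class MatrixRole(str, Enum):
    COPY_NUMBER = "copy_number"
    EXPRESSION_MRNA = "expression_mrna"
    EXPRESSION_PROTEIN = "expression_protein"
    KO_EFFECT = "ko_effect"
    LETHALITY_PROB = "lethality_prob"


#: MAF-style variant classifications → closed vocabulary.
CONSEQUENCE_MAP: dict[str, Consequence] = {
    "nonsense_mutation": Consequence.NONSENSE,
    "nonsense": Consequence.NONSENSE,
    "frame_shift_del": Consequence.FRAMESHIFT,
    "frame_shift_ins": Consequence.FRAMESHIFT,
    "frameshift": Consequence.FRAMESHIFT,
    "splice_site": Consequence.SPLICE_SITE,
    "start_codon_snp": Consequence.START_LOST,
    "start_codon_del": Consequence.START_LOST,
    "start_codon_ins": Consequence.START_LOST,
    "translation_start_site": Consequence.START_LOST,
    "start_lost": Consequence.START_LOST,
    "missense_mutation": Consequence.MISSENSE,
    "missense": Consequence.MISSENSE,
    "silent": Consequence.SILENT,
    "synonymous": Consequence.SILENT,
}

_ZYGOSITY_MAP: dict[str, Zygosity] = {
    "hom": Zygosity.HOMOZYGOUS,
    "homozygous": Zygosity.HOMOZYGOUS,
    "het": Zygosity.HETEROZYGOUS,
    "heterozygous": Zygosity.HETEROZYGOUS,
}


def normalize_consequence(value: str) -> Consequence:
    return CONSEQUENCE_MAP.get(str(value).strip().lower(), Consequence.OTHER)


def normalize_zygosity(value: str) -> Zygosity:
    return _ZYGOSITY_MAP.get(str(value).strip().lower(), Zygosity.UNKNOWN)


@dataclass(frozen=True)
class MutationRecord:
    """One variant call for (cell line, gene)."""

    line_id: str
    gene: str
    consequence: Consequence
    zygosity: Zygosity = Zygosity.UNKNOWN
    protein_change: str = ""
    is_damaging: bool = False

    @property
    def key(self) -> tuple[str, str, str, str]:
        """Deduplication / distinctness key."""
        return (self.line_id, self.gene, self.consequence.value, self.protein_change)


@dataclass(frozen=True)
class SampleColumns:
    """Source column names for the sample-annotation table (DepMap defaults)."""

    line_id: str = "DepMap_ID"
    line_name: str = "stripped_cell_line_name"
    cancer_type: str = "primary_disease"
    lineage: str = "lineage"


@dataclass(frozen=True)
class MutationColumns:
    """Source column names for the MAF-like mutation table (DepMap defaults).

    ``zygosity``, ``protein_change`` and ``is_damaging`` are optional in the
    source; absent columns yield UNKNOWN / "" / False.
    """

    line_id: str = "DepMap_ID"
    gene: str = "Hugo_Symbol"
    consequence: str = "Variant_Classification"
    zygosity: str = "Variant_annotation_zygosity"
    protein_change: str = "Protein_Change"
    is_damaging: str = "isDeleterious"


@dataclass
class GeneMatrix:
    """A genes × lines numeric matrix with a declared role.

    ``values`` is a float DataFrame indexed by gene symbol with line IDs as
    columns; missing entries are ``NaN``.  ``entrez`` maps gene symbols to
    the numeric IDs parsed from ``"SYMBOL (ENTREZ)"`` headers (metadata only).
    """

    values: pd.DataFrame
    role: MatrixRole
    entrez: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.role = MatrixRole(self.role)
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate gene symbols in matrix: {dupes[:5]}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise IntegrityError(f"duplicate line IDs in matrix: {dupes[:5]}")
        self.values = self.values.astype(float)
        if self.role is MatrixRole.LETHALITY_PROB:
            vals = self.values.to_numpy()
            bad = np.nansum((vals < 0) | (vals > 1))
            if bad:
                raise IntegrityError(
                    f"{int(bad)} lethality probabilities outside [0, 1]"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def lines(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def profile(self, gene: str) -> pd.Series:
        """Row for one gene (raises :class:`GeneNotFoundError` if absent)."""
        from .errors import GeneNotFoundError

        if gene not in self.values.index:
            raise GeneNotFoundError(
                f"gene {gene!r} not present in {self.role.value} matrix"
            )
        return self.values.loc[gene]

    def all_missing_genes(self, lines: Sequence[str] | None = None) -> list[str]:
        """Genes with no observed value across ``lines`` (default: all lines).

        Flagged rather than dropped; downstream stages report them with
        missing statistics.
        """
        sub = self.values if lines is None else self.values.loc[:, list(lines)]
        mask = sub.isna().all(axis=1)
        return list(sub.index[mask])

    def subset_lines(self, lines: Sequence[str]) -> "GeneMatrix":
        keep = [c for c in lines if c in self.values.columns]
        return replace(self, values=self.values.loc[:, keep])


def _require_columns(df: pd.DataFrame, needed: Mapping[str, str], path: str) -> None:
    for role, col in needed.items():
        if col not in df.columns:
            raise SchemaError(
                f"{path}: missing required column {col!r} (expected to hold {role})"
            )


def read_sample_annotations(
    path: str | Path, columns: SampleColumns = SampleColumns()
) -> pd.DataFrame:
    """Read the cell-line annotation CSV into a tidy DataFrame.

    Returns columns ``line_id, line_name, cancer_type, lineage`` (the last
    two empty-string filled when absent from the source).  Duplicate line IDs
    are an integrity error.
    """
    path = str(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, {"line ID": columns.line_id}, path)
    out = pd.DataFrame({"line_id": raw[columns.line_id].str.strip()})
    for name, col in (
        ("line_name", columns.line_name),
        ("cancer_type", columns.cancer_type),
        ("lineage", columns.lineage),
    ):
        out[name] = raw[col].str.strip() if col in raw.columns else ""
    if out["line_id"].duplicated().any():
        dupes = out.loc[out["line_id"].duplicated(), "line_id"].unique().tolist()
        raise IntegrityError(f"{path}: duplicate line_id values: {dupes[:5]}")
    return out


def read_mutations(
    path: str | Path, columns: MutationColumns = MutationColumns()
) -> pd.DataFrame:
    """Read a MAF-like mutation CSV into normalized records.

    Output columns: ``line_id, gene, consequence, zygosity, protein_change,
    is_damaging``.  Consequence and zygosity strings are mapped onto the
    closed vocabularies (unknown → ``other`` / ``unknown``).  Rows identical
    in (line_id, gene, consequence, protein_change) are deduplicated.
    """
    path = str(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(
        raw,
        {"line ID": columns.line_id, "gene symbol": columns.gene,
         "variant consequence": columns.consequence},
        path,
    )
    out = pd.DataFrame(
        {
            "line_id": raw[columns.line_id].str.strip(),
            "gene": raw[columns.gene].str.strip(),
            "consequence": raw[columns.consequence].map(
                lambda s: normalize_consequence(s).value
            ),
        }
    )
    out["zygosity"] = (
        raw[columns.zygosity].map(lambda s: normalize_zygosity(s).value)
        if columns.zygosity in raw.columns
        else Zygosity.UNKNOWN.value
    )
    out["protein_change"] = (
        raw[columns.protein_change].str.strip()
        if columns.protein_change in raw.columns
        else ""
    )
    if columns.is_damaging in raw.columns:
        out["is_damaging"] = (
            raw[columns.is_damaging].str.strip().str.lower().isin(("true", "1", "yes"))
        )
    else:
        out["is_damaging"] = False
    out = out.drop_duplicates(
        subset=["line_id", "gene", "consequence", "protein_change"], ignore_index=True
    )
    return out


def records_from_frame(df: pd.DataFrame) -> list[MutationRecord]:
    """Convert a normalized mutation DataFrame into :class:`MutationRecord`s."""
    return [
        MutationRecord(
            line_id=r.line_id,
            gene=r.gene,
            consequence=Consequence(r.consequence),
            zygosity=Zygosity(r.zygosity),
            protein_change=r.protein_change,
            is_damaging=bool(r.is_damaging),
        )
        for r in df.itertuples(index=False)
    ]


def parse_gene_header(header: str) -> tuple[str, str | None]:
    """Split ``"ARID1A (8289)"`` into ``("ARID1A", "8289")``.

    Headers without the parenthesized Entrez ID pass through unchanged with
    ``None`` for the ID.
    """
    m = _HEADER_RE.match(header)
    if m:
        return m.group("symbol"), m.group("entrez")
    return header.strip(), None


def read_gene_matrix(
    path: str | Path,
    role: MatrixRole | str,
    orientation: str = "lines_in_rows",
    missing_tokens: Iterable[str] = MISSING_TOKENS,
) -> GeneMatrix:
    """Read a numeric gene × cell-line CSV into a :class:`GeneMatrix`.

    Parameters
    ----------
    orientation
        ``"lines_in_rows"`` (the DepMap shipping layout: one row per cell
        line, gene headers across the top) or ``"genes_in_rows"``.  The
        result is always normalized to genes × lines.
    missing_tokens
        Source strings treated as missing (default ``""`` and ``"NA"``).
        Any other non-numeric cell raises :class:`ParseError` with its
        row/column coordinates.
    """
    path = str(path)
    raw = pd.read_csv(
        path,
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    tokens = set(missing_tokens)

    def _to_float(cell: str) -> float:
        if cell.strip() in tokens:
            return np.nan
        return float(cell)

    numeric = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        try:
            numeric[col] = raw[col].map(_to_float)
        except ValueError:
            for row_label, cell in raw[col].items():
                try:
                    _to_float(cell)
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric cell {cell!r} at row "
                        f"{row_label!r}, column {col!r}"
                    ) from None
            raise

    if orientation == "lines_in_rows":
        numeric = numeric.T
    elif orientation != "genes_in_rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    entrez: dict[str, str] = {}
    symbols = []
    for header in numeric.index:
        sym, ent = parse_gene_header(str(header))
        symbols.append(sym)
        if ent is not None:
            entrez[sym] = ent
    numeric.index = pd.Index(symbols, name="gene")
    numeric.columns = [str(c).strip() for c in numeric.columns]
    return GeneMatrix(values=numeric, role=MatrixRole(role), entrez=entrez)


def write_results_table(
    rows: pd.DataFrame,
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    """Write a result table as TSV with full float precision.

    ``header_lines`` are emitted first, ``#``-prefixed (used for knee
    metadata).  Floats are serialized with 17 significant digits so the
    matching reader round-trips them bit-identically.  An empty collection is
    an error — a screen that produced nothing should fail loudly, not write
    an empty file.
    """
    if rows is None or len(rows) == 0:
        raise ValueError("refusing to write an empty results table")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        rows.to_csv(fh, sep="\t", index=False, float_format="%.17g", lineterminator="\n")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_results_table` (skipping ``#`` lines)."""
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


def read_result_header(path: str | Path) -> list[str]:
    """Return the ``#`` metadata lines of a results TSV, prefix stripped."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            out.append(line.lstrip("#").strip())
    return out
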