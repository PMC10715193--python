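"""Parse per-protein COG annotations and build organism x category count matrices.

The counting semantics follow the multi-category splitting rule: a protein
annotated "KT" is counted once as K and once as T, and contributes 2 to its
organism's total functional annotations.  Duplicate letters within one record
each count ("CC" adds 2 to C).  The per-organism total is, by construction,
exactly the row sum of the category counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cogscale.errors import FormatError, MappingError, ValidationError

logger = logging.getLogger(__name__)

_UPPER = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ")

#: category fields treated as "unannotated" and skipped by the parser
_EMPTY_CATEGORY = {"", "-"}


@dataclass(frozen=True)
class AnnotationRecord:
    """One protein's functional annotation.

    ``categories`` is a string of one or more COG one-letter classes; a
    multi-letter string means the protein belongs to several categories at
    once and is counted once in each.
    """

    organism_id: str
    protein_id: str
    categories: str

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValidationError("categories must be non-empty")
        bad = set(self.categories) - _UPPER
        if bad:
            raise ValidationError(
                f"categories must be uppercase letters, got {sorted(bad)!r} "
                f"in record ({self.organism_id}, {self.protein_id})"
            )


def split_categories(categories: str) -> list[str]:
    """Split a multi-category letter string into individual category letters.

    "KT" -> ["K", "T"]; order is preserved and duplicates are kept, so each
    letter contributes one count downstream.
    """
    if not categories:
        raise ValidationError("categories must be non-empty")
    bad = set(categories) - _UPPER
    if bad:
        raise ValidationError(f"non-letter category characters: {sorted(bad)!r}")
    return list(categories)


@dataclass
class ParseResult:
    records: list[AnnotationRecord]
    n_skipped: int


def parse_annotation_table(
    path,
    *,
    columns: tuple[int, int, int] = (0, 1, 2),
    sep: str = "\t",
) -> ParseResult:
    """Read an eggNOG-mapper-style TSV of per-protein annotations.

    Parameters
    ----------
    path
        Tab-separated file; each data row carries organism id, protein id and
        a category letter string.  Lines starting with ``#`` are comments.
    columns
        Zero-based positions of the (organism, protein, categories) columns,
        so both raw mapper output and pre-digested 3-column tables work.
    sep
        Field separator.

    Returns
    -------
    ParseResult
        Parsed records plus the number of rows skipped because their category
        field was empty or ``-`` (unannotated proteins).
    """
    records: list[AnnotationRecord] = []
    n_skipped = 0
    need = max(columns) + 1
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep)
            if len(parts) < need:
                raise FormatError(
                    f"{path}:{lineno}: expected at least {need} columns, got {len(parts)}"
                )
            org, prot, cats = (parts[i].strip() for i in columns)
            if cats in _EMPTY_CATEGORY:
                n_skipped += 1
                continue
            records.append(AnnotationRecord(org, prot, cats))
    if n_skipped:
        logger.info("parse_annotation_table: skipped %d unannotated rows", n_skipped)
    return ParseResult(records, n_skipped)


def parse_taxon_map(path, *, sep: str = "\t") -> pd.DataFrame:
    """Read an organism -> (domain, phylum) table.

    Expects columns organism_id, domain, phylum (header optional; a first row
    literally starting with 'organism' is treated as a header).  The phylum
    column may be missing or empty for some organisms.
    """
    df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: taxon map needs at least organism and domain columns")
    if str(df.iloc[0, 0]).lower().startswith("organism"):
        df = df.iloc[1:].reset_index(drop=True)
    df = df.iloc[:, :3]
    df.columns = ["organism_id", "domain", "phylum"][: df.shape[1]]
    if "phylum" not in df.columns:
        df["phylum"] = pd.NA
    dup = df["organism_id"].duplicated()
    if dup.any():
        raise FormatError(f"{path}: duplicate organism ids in taxon map")
    return df.set_index("organism_id")


@dataclass
class CategoryCountMatrix:
    """Organisms x COG-category count matrix with per-organism totals.

    Invariant: ``total`` equals the row sum of ``counts`` exactly; the total is
    the organism's "total protein annotations" used as the x axis of every
    scaling fit.
    """

    counts: pd.DataFrame  # index = organism ids, columns = category letters, int
    taxon: pd.DataFrame  # index = organism ids, columns domain, phylum
    total: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts.index.name = "organism_id"
        self.taxon.index.name = "organism_id"
        if self.total is None:
            self.total = self.counts.sum(axis=1)
        self.validate()

    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValidationError("duplicate organism ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative counts")
        if not np.array_equal(self.total.to_numpy(), self.counts.sum(axis=1).to_numpy()):
            raise ValidationError("total != row sum of counts")

    @property
    def organisms(self) -> list[str]:
        return list(self.counts.index)

    @property
    def categories(self) -> list[str]:
        return list(self.counts.columns)

    def domain_of(self, organism: str) -> str:
        return self.taxon.loc[organism, "domain"]

    def groups(self, level: str) -> pd.Series:
        """Per-organism group label at ``level`` ('domain' or 'phylum')."""
        if level not in ("domain", "phylum"):
            raise ValidationError(f"level must be domain or phylum, got {level!r}")
        return self.taxon.loc[self.counts.index, level]

    def subset(self, organisms) -> "CategoryCountMatrix":
        idx = pd.Index(organisms)
        return CategoryCountMatrix(
            counts=self.counts.loc[idx].copy(),
            taxon=self.taxon.loc[idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat table: category columns plus total, domain, phylum."""
        out = self.counts.copy()
        out["total"] = self.total
        out["domain"] = self.taxon.loc[out.index, "domain"]
        out["phylum"] = self.taxon.loc[out.index, "phylum"]
        out.index.name = "organism_id"
        return out

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CategoryCountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        taxon = df[["domain", "phylum"]].astype(object)
        counts = df.drop(columns=["total", "domain", "phylum"]).astype(int)
        m = cls(counts=counts, taxon=taxon)
        if not np.array_equal(m.total.to_numpy(), df["total"].to_numpy()):
            raise ValidationError(f"{path}: stored total column disagrees with row sums")
        return m


def matrix_to_records(matrix: CategoryCountMatrix) -> list[AnnotationRecord]:
    """Expand a count matrix back into single-letter annotation records.

    One record per counted letter, with synthetic protein ids.  Round-trips
    through ``build_count_matrix`` exactly, and gives shuffle-null code a
    record-level view of simulated matrices.
    """
    records: list[AnnotationRecord] = []
    for org, row in matrix.counts.iterrows():
        k = 0
        for cat, cnt in row.items():
            for _ in range(int(cnt)):
                records.append(AnnotationRecord(org, f"{org}_p{k:06d}", cat))
                k += 1
    return records


def build_count_matrix(
    records,
    taxon_map: pd.DataFrame,
    *,
    include: set[str] | None = None,
    permissive: bool = False,
) -> CategoryCountMatrix:
    """Count split category letters per organism.

    ``counts[i, c]`` is the number of split letters equal to ``c`` over
    organism ``i``'s records, optionally restricted to the ``include``
    whitelist; the total is the row sum after restriction.  Organisms with no
    records contribute no row (they would contribute no point to any fit).

    With ``permissive=False`` (default) every organism must appear in
    ``taxon_map``; otherwise unmapped organisms get domain/phylum 'unknown'.
    """
    if isinstance(records, ParseResult):
        records = records.records
    tallies: dict[str, dict[str, int]] = {}
    for rec in records:
        row = tallies.setdefault(rec.organism_id, {})
        for letter in split_categories(rec.categories):
            if include is not None and letter not in include:
                continue
            row[letter] = row.get(letter, 0) + 1
    # drop organisms whose every annotation was filtered out
    tallies = {org: row for org, row in tallies.items() if row}
    if not tallies:
        raise ValidationError("no countable annotations")

    missing = set(tallies) - set(taxon_map.index)
    if missing and not permissive:
        raise MappingError(missing)

    counts = (
        pd.DataFrame.from_dict(tallies, orient="index")
        .fillna(0)
        .astype(int)
        .sort_index()
    )
    counts = counts[sorted(counts.columns)]
    taxon = pd.DataFrame(index=counts.index, columns=["domain", "phylum"], dtype=object)
    known = counts.index.intersection(taxon_map.index)
    taxon.loc[known, "domain"] = taxon_map.loc[known, "domain"]
    taxon.loc[known, "phylum"] = taxon_map.loc[known, "phylum"]
    taxon = taxon.fillna("unknown")
    return CategoryCountMatrix(counts=counts, taxon=taxon)
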