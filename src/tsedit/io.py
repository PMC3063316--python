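"""Reading and writing of the pipeline's tabular inputs and reports.

The pipeline consumes three plain-text tables:

* a site catalog (``chrom<TAB>strand<TAB>position[<TAB>gene]``, 1-based,
  fully-closed coordinates; a 6-column BED variant is accepted via
  ``bed=True`` and converted internally),
* a library table (``library_id<TAB>tissue_annotation``),
* an observation table (``sequence_id<TAB>library_id<TAB>chrom<TAB>strand
  <TAB>position<TAB>observed_base_plus``) derived from expressed-sequence
  alignments; the base is always the letter read on the genome plus strand —
  strand reconciliation is the classifier's job, not the reader's.

Observations are held in a :class:`pandas.DataFrame` whose rows follow the
:class:`SiteObservation` schema; sites and libraries are small typed records.
The site catalog is authoritative for strand: an observation row whose strand
disagrees with the catalog is dropped and counted, as is any row referencing
an unknown site or library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

logger = logging.getLogger("tsedit")

VALID_STRANDS = frozenset({"+", "-"})
VALID_BASES = frozenset({"A", "C", "G", "T", "N"})

OBSERVATION_COLUMNS = [
    "sequence_id",
    "library_id",
    "chrom",
    "strand",
    "position",
    "observed_base_plus",
]

REPORT_COLUMNS = ["tissue", "chrom", "strand", "position", "fdr_corrected_p", "gene"]


class CatalogParseError(ValueError):
    """A malformed row in one of the input tables (reports the line number)."""


class ValidationError(ValueError):
    """Structurally valid input violating a semantic contract."""


@dataclass(frozen=True, order=True)
class EditingSite:
    """One known A-to-I editing site: genomic location plus transcript strand."""

    chrom: str
    strand: str
    position: int
    gene: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r} (must be + or -)")
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.chrom, self.strand, self.position)


@dataclass(frozen=True)
class LibraryRecord:
    """One cDNA library with its free-text tissue annotation (may be empty)."""

    library_id: str
    tissue_annotation: str


class SiteObservation(NamedTuple):
    """Row schema of the observation table: one expressed sequence at one site."""

    sequence_id: str
    library_id: str
    chrom: str
    strand: str
    position: int
    observed_base_plus: str


def _normalize_strand(raw: str) -> str:
    # tolerate the typographic minus sign used in printed tables
    s = raw.strip().replace("−", "-")
    if s not in VALID_STRANDS:
        raise ValidationError(f"invalid strand {raw!r}")
    return s


def read_sites(path: str | Path, *, bed: bool = False) -> list[EditingSite]:
    """Read an editing-site catalog, collapsing duplicate (chrom, strand, position).

    ``bed=True`` reads 6-column BED (0-based, half-open, strand in column 6,
    name column used as gene); the default is the native 1-based TSV with
    columns ``chrom, strand, position[, gene]``.  The number of collapsed
    duplicate rows is logged.  Malformed strand or non-positive position
    raises :class:`CatalogParseError` naming the offending line.
    """
    path = Path(path)
    sites: dict[tuple[str, str, int], EditingSite] = {}
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() in {"chrom", "track", "browser"}:
                continue  # header / track lines
            try:
                if bed:
                    if len(fields) < 6:
                        raise ValidationError("BED mode requires 6 columns")
                    chrom = fields[0]
                    start = int(fields[1])
                    end = int(fields[2])
                    if end - start != 1:
                        raise ValidationError(
                            f"BED interval {start}-{end} is not a single base"
                        )
                    gene = fields[3] if fields[3] not in {"", "."} else None
                    strand = _normalize_strand(fields[5])
                    site = EditingSite(chrom, strand, start + 1, gene)
                else:
                    if len(fields) < 3:
                        raise ValidationError("expected chrom, strand, position")
                    chrom = fields[0]
                    strand = _normalize_strand(fields[1])
                    position = int(fields[2])
                    gene = fields[3].strip() or None if len(fields) > 3 else None
                    site = EditingSite(chrom, strand, position, gene)
            except (ValidationError, ValueError) as exc:
                raise CatalogParseError(f"{path}:{lineno}: {exc}") from exc
            if site.key in sites:
                n_dup += 1
            else:
                sites[site.key] = site
    if n_dup:
        logger.info("read_sites: collapsed %d duplicate site rows", n_dup)
    return list(sites.values())


def write_sites(sites: Iterable[EditingSite], path: str | Path) -> None:
    """Write a site catalog in the native TSV layout (round-trips read_sites)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstrand\tposition\tgene\n")
        for s in sites:
            fh.write(f"{s.chrom}\t{s.strand}\t{s.position}\t{s.gene or ''}\n")


def read_libraries(path: str | Path) -> list[LibraryRecord]:
    """Read the library table unfiltered; annotations are preserved verbatim.

    Tissue curation (exclusion of mixed/unannotated libraries, merging) is
    deliberately *not* applied here.  Duplicate library ids raise
    :class:`ValidationError`.
    """
    records: list[LibraryRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line and lineno > 1:
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "library_id":
                continue
            lib_id = fields[0]
            annotation = fields[1] if len(fields) > 1 else ""
            if lib_id in seen:
                raise ValidationError(f"duplicate library_id {lib_id!r} at line {lineno}")
            seen.add(lib_id)
            records.append(LibraryRecord(lib_id, annotation))
    return records


def write_libraries(records: Iterable[LibraryRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("library_id\ttissue_annotation\n")
        for r in records:
            fh.write(f"{r.library_id}\t{r.tissue_annotation}\n")


def read_observations(
    path: str | Path,
    sites: Sequence[EditingSite],
    libraries: Sequence[LibraryRecord],
) -> pd.DataFrame:
    """Read the observation table, joined to the site catalog.

    Each row is matched to its catalog site by (chrom, position); rows whose
    site or library is unknown are dropped, as are rows whose stated strand
    disagrees with the catalog (the catalog is authoritative for strand).
    Drop counts are logged.  Base letters are normalized to upper case; a
    letter outside {A, C, G, T, N} raises :class:`CatalogParseError`.

    Returns a DataFrame with the :class:`SiteObservation` columns plus a
    ``gene`` column carried over from the catalog.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "sequence_id": str,
            "library_id": str,
            "chrom": str,
            "strand": str,
            "position": "int64",
            "observed_base_plus": str,
        },
    )
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogParseError(f"{path}: missing columns {missing}")
    df["observed_base_plus"] = df["observed_base_plus"].str.upper()
    bad = ~df["observed_base_plus"].isin(VALID_BASES)
    if bad.any():
        lineno = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
        raise CatalogParseError(
            f"{path}:{lineno}: invalid base {df.loc[df.index[bad][0], 'observed_base_plus']!r}"
        )
    df["strand"] = df["strand"].str.replace("−", "-", regex=False)

    site_strand = {(s.chrom, s.position): s.strand for s in sites}
    site_gene = {(s.chrom, s.position): s.gene for s in sites}
    known_libs = {r.library_id for r in libraries}

    keys = list(zip(df["chrom"], df["position"]))
    catalog_strand = pd.Series([site_strand.get(k) for k in keys], index=df.index)
    known_site = catalog_strand.notna()
    strand_ok = df["strand"] == catalog_strand
    known_lib = df["library_id"].isin(known_libs)

    n_unknown_site = int((~known_site).sum())
    n_strand_conflict = int((known_site & ~strand_ok).sum())
    n_unknown_lib = int((known_site & strand_ok & ~known_lib).sum())
    if n_unknown_site or n_strand_conflict or n_unknown_lib:
        logger.info(
            "read_observations: dropped %d rows at unknown sites, "
            "%d with strand conflicting the catalog, %d from unknown libraries",
            n_unknown_site,
            n_strand_conflict,
            n_unknown_lib,
        )
    keep = known_site & strand_ok & known_lib
    out = df.loc[keep, OBSERVATION_COLUMNS].copy()
    out["gene"] = [site_gene[k] for k in zip(out["chrom"], out["position"])]
    return out.reset_index(drop=True)


def write_observations(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, OBSERVATION_COLUMNS].to_csv(path, sep="\t", index=False)


def _format_p(p: float) -> str:
    """Render an adjusted p-value with at least 3 significant digits."""
    return format(p, ".4g")


def write_report(calls: Sequence, path: str | Path) -> None:
    """Write tissue-specific calls as a TSV report.

    Columns are ``tissue, chrom, strand, position, fdr_corrected_p, gene``,
    sorted by tissue then ascending position; adjusted p-values are rendered
    with at least three significant digits.  ``calls`` are
    :class:`tsedit.stats.SpecificityCall` records.
    """
    rows = sorted(calls, key=lambda c: (c.tissue, c.site.chrom, c.site.position))
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for c in rows:
            fh.write(
                f"{c.tissue}\t{c.site.chrom}\t{c.site.strand}\t{c.site.position}\t"
                f"{_format_p(c.adjusted_p)}\t{c.site.gene or ''}\n"
            )


def read_report(path: str | Path) -> pd.DataFrame:
    """Read a report TSV back into a DataFrame (used by report-check and tests)."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"tissue": str, "chrom": str, "strand": str, "gene": str},
        keep_default_na=False,
    )
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogParseError(f"{path}: report missing columns {missing}")
    df["position"] = df["position"].astype("int64")
    df["fdr_corrected_p"] = df["fdr_corrected_p"].astype(float)
    df["strand"] = df["strand"].str.replace("−", "-", regex=False)
    if not df["strand"].isin(VALID_STRANDS).all() and len(df):
        bad = df.loc[~df["strand"].isin(VALID_STRANDS), "strand"].iloc[0]
        raise ValidationError(f"report contains invalid strand {bad!r}")
    if ((df["fdr_corrected_p"] <= 0) | (df["fdr_corrected_p"] > 1)).any():
        raise ValidationError("report contains p-values outside (0, 1]")
    return df
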