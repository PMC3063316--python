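"""Library-to-tissue curation and edited/unedited classification.

cDNA libraries carry free-text tissue annotations.  Curation excludes
libraries that lack a tissue source (empty/whitespace annotation) or that
come from mixed samples (annotation matching a configurable pattern list),
then merges the remainder into tissue categories — by an explicit merge map
when given (this is how normal and cancerous samples of one tissue collapse
to a single category), otherwise by case-folded, trimmed identity.

Each expressed sequence overlapping a site is classified from the base read
on the genome plus strand: the letter is complemented onto the transcript
strand for minus-strand sites, then G means edited (inosine is read as
guanosine by reverse transcriptase) and A means unedited.  Any other
transcript-strand letter — a SNP or a sequencing error at the site — is
excluded from both counts rather than counted as unedited, which would bias
editing levels downward.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import EditingSite, LibraryRecord, ValidationError

logger = logging.getLogger("tsedit")

#: annotation substrings (case-insensitive) marking a mixed-tissue sample
DEFAULT_MIXED_PATTERNS: tuple[str, ...] = ("mix", "pool")

REASON_NO_SOURCE = "no tissue source"
REASON_MIXED = "mixed tissue sample"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class EditStatus(enum.Enum):
    EDITED = "edited"
    UNEDITED = "unedited"
    OTHER = "other"


@dataclass
class TissueCatalog:
    """Curated mapping of tissue category -> library ids, plus exclusions."""

    categories: dict[str, set[str]] = field(default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)  # library_id -> reason

    def tissue_of(self) -> dict[str, str]:
        """Invert to a library_id -> tissue lookup."""
        out: dict[str, str] = {}
        for tissue, libs in self.categories.items():
            for lib in libs:
                out[lib] = tissue
        return out

    @property
    def n_categorized(self) -> int:
        return sum(len(v) for v in self.categories.values())


def read_merge_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping raw annotation -> tissue category.

    An annotation mapped to two different categories is a configuration
    error.
    """
    merge: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "annotation":
                continue
            key = _normalize_annotation(fields[0])
            value = fields[1].strip()
            if key in merge and merge[key] != value:
                raise ValidationError(
                    f"merge map assigns annotation {fields[0]!r} to two categories: "
                    f"{merge[key]!r} and {value!r}"
                )
            merge[key] = value
    return merge


def _normalize_annotation(annotation: str) -> str:
    return annotation.strip().casefold()


def curate_libraries(
    libraries: Sequence[LibraryRecord],
    merge_map: Mapping[str, str] | None = None,
    mixed_patterns: Iterable[str] = DEFAULT_MIXED_PATTERNS,
) -> TissueCatalog:
    """Group libraries into tissue categories, excluding unusable ones.

    Exclusion rules: an empty or all-whitespace annotation means the library
    has no clear tissue source; an annotation containing any of
    ``mixed_patterns`` (case-insensitive substring) marks a mixed sample.
    Remaining annotations are trimmed and case-folded, then mapped through
    ``merge_map`` when given (keys are normalized the same way), otherwise
    used directly as the category name.
    """
    patterns = tuple(p.casefold() for p in mixed_patterns)
    merge = {_normalize_annotation(k): v for k, v in (merge_map or {}).items()}
    if merge_map:
        seen: dict[str, str] = {}
        for k, v in (merge_map or {}).items():
            nk = _normalize_annotation(k)
            if nk in seen and seen[nk] != v:
                raise ValidationError(
                    f"merge map assigns annotation {k!r} to two categories"
                )
            seen[nk] = v
    catalog = TissueCatalog()
    for rec in libraries:
        norm = _normalize_annotation(rec.tissue_annotation)
        if not norm:
            catalog.excluded[rec.library_id] = REASON_NO_SOURCE
            continue
        if any(p in norm for p in patterns):
            catalog.excluded[rec.library_id] = REASON_MIXED
            continue
        category = merge.get(norm, norm)
        catalog.categories.setdefault(category, set()).add(rec.library_id)
    logger.info(
        "curate_libraries: %d libraries in %d tissue categories, %d excluded",
        catalog.n_categorized,
        len(catalog.categories),
        len(catalog.excluded),
    )
    return catalog


def write_exclusion_summary(catalog: TissueCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("library_id\treason\n")
        for lib, reason in sorted(catalog.excluded.items()):
            fh.write(f"{lib}\t{reason}\n")


def classify_base(site: EditingSite, observed_base_plus: str) -> EditStatus:
    """Classify one plus-strand base call at a site as edited/unedited/other.

    The base is first converted onto the transcript strand (complemented for
    minus-strand sites); transcript-strand G is edited, A is unedited,
    anything else is "other" and excluded from counting downstream.
    """
    base = observed_base_plus.upper()
    if base not in _COMPLEMENT:
        raise ValidationError(f"invalid base letter {observed_base_plus!r}")
    transcript_base = base if site.strand == "+" else _COMPLEMENT[base]
    if transcript_base == "G":
        return EditStatus.EDITED
    if transcript_base == "A":
        return EditStatus.UNEDITED
    return EditStatus.OTHER


def tabulate(observations: pd.DataFrame, catalog: TissueCatalog) -> pd.DataFrame:
    """Count edited/unedited observations per (site, tissue).

    ``observations`` is the DataFrame produced by
    :func:`tsedit.io.read_observations` (or the synthetic generator).  One
    sequence contributes at most one observation per site (duplicates by
    sequence_id are collapsed, first kept).  Observations from excluded
    libraries, and observations whose transcript-strand base is neither G
    nor A, are omitted; omitted totals are logged.

    Returns a DataFrame with columns ``chrom, strand, position, gene,
    tissue, edited, unedited`` containing every (site, tissue) pair with at
    least one retained observation.
    """
    if observations.empty:
        return pd.DataFrame(
            columns=["chrom", "strand", "position", "gene", "tissue", "edited", "unedited"]
        )
    df = observations.drop_duplicates(
        subset=["chrom", "strand", "position", "sequence_id"], keep="first"
    )
    n_dup = len(observations) - len(df)

    tissue_of = catalog.tissue_of()
    tissue = df["library_id"].map(tissue_of)
    n_excluded = int(tissue.isna().sum())

    base = df["observed_base_plus"].str.upper()
    transcript_base = base.where(df["strand"] == "+", base.map(_COMPLEMENT))
    status = transcript_base.map({"G": "edited", "A": "unedited"})
    n_other = int(status.isna().sum())

    keep = tissue.notna() & status.notna()
    if n_dup or n_excluded or n_other:
        logger.info(
            "tabulate: collapsed %d duplicate sequence observations, omitted %d "
            "from excluded libraries and %d with non-A/G transcript base",
            n_dup,
            n_excluded,
            n_other,
        )
    kept = df.loc[keep].assign(
        tissue=tissue[keep],
        edited=(status[keep] == "edited").astype("int64"),
        unedited=(status[keep] == "unedited").astype("int64"),
    )
    if "gene" not in kept.columns:
        kept = kept.assign(gene=None)
    counts = (
        kept.groupby(["chrom", "strand", "position", "tissue"], sort=True)
        .agg(gene=("gene", "first"), edited=("edited", "sum"), unedited=("unedited", "sum"))
        .reset_index()
    )
    return counts[["chrom", "strand", "position", "gene", "tissue", "edited", "unedited"]]
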