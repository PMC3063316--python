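"""Sequence-level consequences of an A-to-G edit.

A-to-I editing is read as an A→G substitution on the transcript strand.
Three classes of consequence are annotated:

* gain or loss of exonic splicing enhancers (ESEs), scored by
  position-weight matrices in the style of the SR-protein motifs SF2/ASF,
  SC35, SRp40 and SRp55: every window of matrix width is scored as the sum
  of per-position, per-base weights, and windows scoring at or above the
  matrix threshold are functional elements (equality counts as functional);
* gain or loss of exonic splicing silencer (ESS) hexamers by exact match
  against a hexamer set (FAS-hex-3 style);
* amino-acid changes when the edit falls in a coding sequence, under the
  standard genetic code.

All scanning operates on transcript-strand sequence; extracting that
sequence from the genome (strand, splicing) is the caller's job, with
:func:`classify_region` locating a genomic site within transcript features.
Gained motifs are reported alongside lost ones: the symmetric difference is
strictly more informative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from Bio.Seq import Seq

from .io import EditingSite, ValidationError

logger = logging.getLogger("tsedit")

_BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASE_ORDER)}

#: EditFunc-style analyses this package deliberately does not provide
UNSUPPORTED_ANALYSES = frozenset(
    {
        "phosphorylation",  # NetPhos
        "signal-peptide",  # SignalP
        "glycosylation",  # NetNGlyc / NetOGlyc / NetCGlyc
        "propeptide-cleavage",  # ProP
        "splice-site-model",  # GeneID splice-site scoring
        "mirna-target",
        "pirna-target",
    }
)


def require_supported(analysis: str) -> None:
    """Raise a clear error for analyses that depend on external predictors."""
    if analysis in UNSUPPORTED_ANALYSES:
        raise NotImplementedError(
            f"analysis {analysis!r} requires an external trained predictor or "
            "annotation database and is not provided; supported analyses are "
            "ESE/ESS motif differencing and codon recoding"
        )


@dataclass(frozen=True)
class ScoringMatrix:
    """A position-weight matrix with a functional-score threshold.

    ``weights`` has shape (width, 4) with columns in A, C, G, T order.
    A window is a functional ESE when its summed score >= threshold.
    """

    name: str
    weights: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4 or w.shape[0] < 1:
            raise ValidationError(
                f"matrix {self.name!r}: weights must have shape (width, 4)"
            )
        if not np.isfinite(w).all() or not np.isfinite(self.threshold):
            raise ValidationError(f"matrix {self.name!r}: non-finite weight or threshold")
        object.__setattr__(self, "weights", w)

    @property
    def width(self) -> int:
        return int(self.weights.shape[0])


class MotifHit(NamedTuple):
    """A motif occurrence: 1-based start, motif name, matrix score (None for hexamers)."""

    start: int
    motif: str
    score: float | None = None


@dataclass(frozen=True)
class HexamerSet:
    """A named set of 6-base silencer motifs."""

    name: str
    hexamers: frozenset[str]

    def __post_init__(self) -> None:
        for h in self.hexamers:
            if len(h) != 6 or any(ch not in _BASE_INDEX for ch in h):
                raise ValidationError(f"invalid hexamer {h!r} in set {self.name!r}")


@dataclass(frozen=True)
class AminoAcidChange:
    """Consequence of the edit on the encoded protein (one-letter residues)."""

    ref_residue: str
    protein_position: int
    alt_residue: str

    @property
    def synonymous(self) -> bool:
        return self.ref_residue == self.alt_residue

    @property
    def stop_gain(self) -> bool:
        return self.alt_residue == "*" and self.ref_residue != "*"

    @property
    def stop_loss(self) -> bool:
        return self.ref_residue == "*" and self.alt_residue != "*"


@dataclass
class EditEffectReport:
    """All predicted consequences of one edit in one transcript sequence."""

    lost_ese: list[MotifHit]
    gained_ese: list[MotifHit]
    lost_ess: list[MotifHit]
    gained_ess: list[MotifHit]
    amino_acid_change: AminoAcidChange | None = None


def _check_sequence(sequence: str) -> str:
    seq = sequence.upper()
    bad = set(seq) - set(_BASE_ORDER)
    if bad:
        raise ValidationError(f"sequence contains non-ACGT letters: {sorted(bad)}")
    return seq


def apply_edit(sequence: str, position: int) -> str:
    """Substitute G for the A at 1-based ``position`` (the A-to-I edit)."""
    seq = _check_sequence(sequence)
    if not 1 <= position <= len(seq):
        raise ValidationError(
            f"position {position} outside sequence of length {len(seq)}"
        )
    if seq[position - 1] != "A":
        raise ValidationError(
            f"base at position {position} is {seq[position - 1]!r}, expected 'A'"
        )
    return seq[: position - 1] + "G" + seq[position:]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


_CODE = np.zeros(128, dtype=np.int64)
for _b, _i in _BASE_INDEX.items():
    _CODE[ord(_b)] = _i


def _window_scores(seq: str, matrix: ScoringMatrix) -> np.ndarray:
    """Score every window of matrix width; empty array if seq is too short."""
    w = matrix.width
    if len(seq) < w:
        return np.empty(0)
    idx = _CODE[_encode(seq)]
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    return matrix.weights[np.arange(w), windows].sum(axis=1)


def scan_ese(sequence: str, matrix: ScoringMatrix) -> list[MotifHit]:
    """All windows scoring at or above the matrix threshold (1-based starts)."""
    seq = _check_sequence(sequence)
    scores = _window_scores(seq, matrix)
    return [
        MotifHit(start=i + 1, motif=matrix.name, score=float(s))
        for i, s in enumerate(scores)
        if s >= matrix.threshold
    ]


def _overlaps(start: int, width: int, position: int) -> bool:
    return start <= position <= start + width - 1


def diff_ese(
    sequence: str, position: int, matrices: Sequence[ScoringMatrix]
) -> tuple[list[MotifHit], list[MotifHit]]:
    """ESE hits destroyed or created by the edit at ``position``.

    A hit is lost when the unedited window is functional but the same window
    scores below threshold after editing; gained is the converse.  Only
    windows overlapping the edited position can change.
    """
    seq = _check_sequence(sequence)
    edited = apply_edit(seq, position)
    lost: list[MotifHit] = []
    gained: list[MotifHit] = []
    for matrix in matrices:
        before = _window_scores(seq, matrix)
        after = _window_scores(edited, matrix)
        for i, (s0, s1) in enumerate(zip(before, after)):
            if not _overlaps(i + 1, matrix.width, position):
                continue
            if s0 >= matrix.threshold and s1 < matrix.threshold:
                lost.append(MotifHit(i + 1, matrix.name, float(s0)))
            elif s0 < matrix.threshold and s1 >= matrix.threshold:
                gained.append(MotifHit(i + 1, matrix.name, float(s1)))
    return lost, gained


def scan_ess(sequence: str, hexamer_set: HexamerSet) -> list[MotifHit]:
    """All exact hexamer matches (1-based starts)."""
    seq = _check_sequence(sequence)
    return [
        MotifHit(start=i + 1, motif=seq[i : i + 6])
        for i in range(max(0, len(seq) - 5))
        if seq[i : i + 6] in hexamer_set.hexamers
    ]


def diff_ess(
    sequence: str, position: int, hexamer_set: HexamerSet
) -> tuple[list[MotifHit], list[MotifHit]]:
    """ESS hexamers destroyed or created by the edit at ``position``."""
    seq = _check_sequence(sequence)
    edited = apply_edit(seq, position)
    before = {h for h in scan_ess(seq, hexamer_set) if _overlaps(h.start, 6, position)}
    after = {h for h in scan_ess(edited, hexamer_set) if _overlaps(h.start, 6, position)}
    key = lambda h: h.start
    return sorted(before - after, key=key), sorted(after - before, key=key)


def translate_codon_change(cds: str, cds_position: int) -> AminoAcidChange:
    """Amino-acid consequence of editing the A at ``cds_position`` (1-based).

    The CDS length must be a multiple of 3; translation uses the standard
    genetic code with '*' for stop.  Synonymous changes and stop gain/loss
    are exposed as properties of the returned record.
    """
    seq = _check_sequence(cds)
    if len(seq) % 3 != 0:
        raise ValidationError(f"CDS length {len(seq)} is not a multiple of 3")
    if not 1 <= cds_position <= len(seq):
        raise ValidationError(f"cds_position {cds_position} outside CDS")
    if seq[cds_position - 1] != "A":
        raise ValidationError(
            f"base at CDS position {cds_position} is {seq[cds_position - 1]!r}, expected 'A'"
        )
    codon_index = (cds_position - 1) // 3
    codon = seq[codon_index * 3 : codon_index * 3 + 3]
    offset = (cds_position - 1) % 3
    edited_codon = codon[:offset] + "G" + codon[offset + 1 :]
    ref = str(Seq(codon).translate())
    alt = str(Seq(edited_codon).translate())
    return AminoAcidChange(ref, codon_index + 1, alt)


# ---------------------------------------------------------------------------
# transcript features and region classification

REGION_LABELS = ("CDS", "5UTR", "3UTR", "intron")
_LABEL_PRIORITY = {label: i for i, label in enumerate(REGION_LABELS)}


class TranscriptFeature(NamedTuple):
    """A strand-aware transcript interval, 1-based fully closed."""

    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    label: str


class RegionLabel(NamedTuple):
    transcript_id: str | None
    label: str


def classify_region(
    site: EditingSite, features: Sequence[TranscriptFeature]
) -> list[RegionLabel]:
    """Per-transcript region label of a site; "intergenic" when uncovered.

    A site may fall in the 3'-UTR of one isoform and an intron of another;
    all labels are reported.  When a transcript covers the site with more
    than one feature, CDS takes priority over UTRs over intron.
    """
    per_transcript: dict[str, str] = {}
    for f in features:
        if f.chrom != site.chrom or f.strand != site.strand:
            continue
        if not f.start <= site.position <= f.end:
            continue
        prev = per_transcript.get(f.transcript_id)
        if prev is None or _LABEL_PRIORITY[f.label] < _LABEL_PRIORITY[prev]:
            per_transcript[f.transcript_id] = f.label
    if not per_transcript:
        return [RegionLabel(None, "intergenic")]
    return [RegionLabel(t, lab) for t, lab in sorted(per_transcript.items())]


_GFF_LABELS = {
    "CDS": "CDS",
    "five_prime_UTR": "5UTR",
    "three_prime_UTR": "3UTR",
}


def read_features(path: str | Path) -> list[TranscriptFeature]:
    """Read transcript features from BED-like TSV or GFF3.

    The TSV form has columns ``transcript_id, chrom, strand, start, end,
    label`` (1-based closed; label one of CDS/5UTR/3UTR/intron).  GFF3 files
    (detected by extension or the ``##gff-version`` pragma) contribute their
    CDS and UTR features directly, plus introns derived from the gaps
    between consecutive exons of each transcript.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if path.suffix.lower() in {".gff", ".gff3"} or first.startswith("##gff-version"):
        return _read_gff3(path)
    features: list[TranscriptFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "transcript_id":
                continue
            if len(fields) < 6:
                raise ValidationError(f"{path}:{lineno}: expected 6 columns")
            tid, chrom, strand, start, end, label = fields[:6]
            if label not in REGION_LABELS:
                raise ValidationError(f"{path}:{lineno}: unknown label {label!r}")
            features.append(
                TranscriptFeature(tid, chrom, strand, int(start), int(end), label)
            )
    return features


def _read_gff3(path: Path) -> list[TranscriptFeature]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    features: list[TranscriptFeature] = []
    exons: dict[str, list[tuple[str, str, int, int]]] = {}
    for feat in db.all_features():
        parents = feat.attributes.get("Parent", [feat.id])
        for parent in parents:
            if feat.featuretype in _GFF_LABELS:
                features.append(
                    TranscriptFeature(
                        parent, feat.seqid, feat.strand, feat.start, feat.end,
                        _GFF_LABELS[feat.featuretype],
                    )
                )
            elif feat.featuretype == "exon":
                exons.setdefault(parent, []).append(
                    (feat.seqid, feat.strand, feat.start, feat.end)
                )
    for tid, ex in exons.items():
        ex.sort(key=lambda e: e[2])
        for (c1, s1, _a1, e1), (_c2, _s2, a2, _e2) in zip(ex, ex[1:]):
            if a2 - e1 > 1:
                features.append(TranscriptFeature(tid, c1, s1, e1 + 1, a2 - 1, "intron"))
    return features


# ---------------------------------------------------------------------------
# bundled motif resources

def load_matrix(path: str | Path) -> ScoringMatrix:
    """Read one scoring matrix from TSV.

    Layout: comment headers ``# name: <name>`` and ``# threshold: <value>``,
    a column-header row ``A C G T``, then one row of four weights per motif
    position.
    """
    name = Path(path).stem
    threshold: float | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("name:"):
                    name = body.split(":", 1)[1].strip()
                elif body.lower().startswith("threshold:"):
                    threshold = float(body.split(":", 1)[1])
                continue
            fields = line.split("\t")
            if fields[0].upper() == "A" and [f.upper() for f in fields[:4]] == list("ACGT"):
                continue
            rows.append([float(x) for x in fields[:4]])
    if threshold is None:
        raise ValidationError(f"{path}: missing '# threshold:' header")
    return ScoringMatrix(name, np.asarray(rows), threshold)


def load_hexamers(path: str | Path, name: str | None = None) -> HexamerSet:
    """Read a hexamer set: one 6-mer per line, '#' comments allowed."""
    hexes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip().upper()
            if not line or line.startswith("#"):
                continue
            hexes.add(line)
    return HexamerSet(name or Path(path).stem, frozenset(hexes))


def _data_path(filename: str) -> Path:
    return Path(resources.files("tsedit").joinpath("data", filename))  # type: ignore[arg-type]


def load_bundled_matrices() -> list[ScoringMatrix]:
    """The four bundled SR-protein ESE matrices.

    The bundled weight values are synthetic placeholders (the published
    nucleotide-frequency matrices are distributed with ESEfinder and are not
    redistributable here); widths and thresholds follow the published
    motifs.  Replace the files under ``tsedit/data`` with the real matrices
    for production annotation.
    """
    names = ["ese_sf2asf", "ese_sc35", "ese_srp40", "ese_srp55"]
    return [load_matrix(_data_path(f"{n}.synthetic.tsv")) for n in names]


def load_bundled_hexamers() -> HexamerSet:
    """The bundled ESS hexamer set (synthetic subset of a FAS-hex-3 style list)."""
    return load_hexamers(_data_path("ess_hexamers.synthetic.txt"), name="FAS-hex-3-subset")
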