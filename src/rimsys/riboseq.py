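"""Post-alignment ribosome-profiling quantification and regulon calling.

Implements the footprint pipeline used downstream of genome alignment:

1. keep alignments whose reference span is 23-41 nt inclusive,
2. build strand-specific centre-weighted coverage (each kept read
   increments the positions of its alignment after trimming 11 nt from
   either end, i.e. ``span - 22`` positions, by one),
3. per-gene RPKM from the gene-strand coverage inside the gene interval,
   normalised by gene length (kb) and the genome-wide counted-position
   total (millions),
4. log2 contrast ratios (with a +0.5 RPKM pseudocount) and the
   class 1/2/3/glutamation-only regulon partition at threshold tau = 1.0,
5. the proteomic significance filter (>= 2 unique peptides, >= 2-fold
   difference of regulation, at least one p-value <= 0.05).

Coordinates: SAM is 1-based (pysam converts to 0-based), GFF3 is 1-based
inclusive; everything internal is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedRead",
    "CoverageTrack",
    "GeneModel",
    "MIN_FOOTPRINT",
    "MAX_FOOTPRINT",
    "TRIM",
    "read_alignments",
    "filter_reads",
    "center_weighted_coverage",
    "coverage_tracks",
    "rpkm_table",
    "log2_contrast",
    "classify_regulon",
    "differential_protein_filter",
    "read_gff3",
    "write_bedgraph",
]

MIN_FOOTPRINT = 23
MAX_FOOTPRINT = 41
TRIM = 11

REGULON_LABELS = ("class1", "class2", "class3", "glutamation_only", "unaffected")


@dataclass(frozen=True)
class AlignedRead:
    """A mapped footprint: reference, strand, 0-based start, reference span."""

    reference: str
    strand: str
    start: int
    span: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.span < 1:
            raise ValueError("span must be >= 1")
        if self.start < 0:
            raise ValueError("start must be >= 0")


@dataclass
class CoverageTrack:
    """Per-position centre-weighted counts for one reference and strand."""

    reference: str
    strand: str
    counts: np.ndarray

    @property
    def total(self) -> float:
        """Total counted positions on this track."""
        return float(self.counts.sum())


@dataclass(frozen=True)
class GeneModel:
    """A gene interval in GFF convention (1-based, inclusive)."""

    gene_id: str
    reference: str
    strand: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length_nt(self) -> int:
        return self.end - self.start + 1

    @property
    def interval0(self) -> tuple[int, int]:
        """0-based half-open interval."""
        return self.start - 1, self.end


def read_alignments(path: str) -> list[AlignedRead]:
    """Parse mapped reads from a SAM (or BAM) file.

    The reference span comes from the CIGAR (soft clips excluded).
    Unmapped or span-less records are skipped with a logged warning count.
    """
    out: list[AlignedRead] = []
    skipped = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.reference_name is None:
                skipped += 1
                continue
            span = rec.reference_length
            if not span:
                skipped += 1
                continue
            out.append(
                AlignedRead(
                    reference=rec.reference_name,
                    strand="-" if rec.is_reverse else "+",
                    start=rec.reference_start,
                    span=int(span),
                )
            )
    if skipped:
        logger.warning("skipped %d unmapped/malformed records", skipped)
    return out


def filter_reads(
    reads: Iterable[AlignedRead],
    min_span: int = MIN_FOOTPRINT,
    max_span: int = MAX_FOOTPRINT,
) -> Iterator[AlignedRead]:
    """Keep footprints whose span is within [min_span, max_span], inclusive."""
    for r in reads:
        if min_span <= r.span <= max_span:
            yield r


def center_weighted_coverage(
    reads: Iterable[AlignedRead],
    reference_length: int,
    strand: str,
    reference: str = "",
    trim: int = TRIM,
) -> CoverageTrack:
    """Centre-weighted coverage for one strand of one reference.

    A read covering 0-based positions ``[s, s + span)`` increments
    ``[s + trim, s + span - trim)``; reads must already be length-filtered
    so the window is non-empty.  Windows reaching past the reference end
    are clipped with a warning.
    """
    counts = np.zeros(reference_length, dtype=np.int64)
    clipped = 0
    for r in reads:
        if r.strand != strand or (reference and r.reference != reference):
            continue
        lo = r.start + trim
        hi = r.start + r.span - trim
        if hi > reference_length or lo < 0:
            clipped += 1
            lo, hi = max(lo, 0), min(hi, reference_length)
        if hi > lo:
            counts[lo:hi] += 1
    if clipped:
        logger.warning(
            "%d trimmed windows clipped at reference bounds (%s%s)",
            clipped,
            reference or "?",
            strand,
        )
    return CoverageTrack(reference=reference, strand=strand, counts=counts)


def coverage_tracks(
    reads: Iterable[AlignedRead], reference_lengths: Mapping[str, int]
) -> dict[tuple[str, str], CoverageTrack]:
    """Both-strand coverage for every reference; strands kept separate."""
    reads = list(reads)
    tracks = {}
    for ref, length in reference_lengths.items():
        for strand in "+-":
            tracks[(ref, strand)] = center_weighted_coverage(
                reads, length, strand, reference=ref
            )
    return tracks


def rpkm_table(
    tracks: Mapping[tuple[str, str], CoverageTrack],
    genes: Sequence[GeneModel],
) -> pd.DataFrame:
    """Per-gene counts and RPKM from strand-specific coverage.

    A gene's count is the sum of its own-strand track inside its interval;
    RPKM divides by gene length in kb and the genome-wide counted-position
    total (both strands) in millions.
    """
    unknown = [
        g.gene_id for g in genes if (g.reference, g.strand) not in tracks
    ]
    if unknown:
        raise KeyError(f"genes on unknown reference/strand: {unknown}")
    total = sum(t.total for t in tracks.values())
    rows = []
    for g in genes:
        lo, hi = g.interval0
        count = float(tracks[(g.reference, g.strand)].counts[lo:hi].sum())
        if total > 0:
            rpkm = count / ((g.length_nt / 1e3) * (total / 1e6))
        else:
            rpkm = 0.0
        rows.append(
            {
                "gene_id": g.gene_id,
                "count": count,
                "length_nt": g.length_nt,
                "rpkm": rpkm,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def log2_contrast(
    rpkm_num: pd.Series, rpkm_den: pd.Series, pseudocount: float = 0.5
) -> pd.Series:
    """log2 ratio of two RPKM vectors with a symmetric pseudocount."""
    num, den = rpkm_num.align(rpkm_den, join="inner")
    return np.log2((num + pseudocount) / (den + pseudocount))


def classify_regulon(table: pd.DataFrame, tau: float = 1.0) -> pd.Series:
    """Partition genes by the two-contrast scheme at threshold ``tau``.

    ``table`` must carry ``log2_a`` (deletion vs wild type) and ``log2_b``
    (glutamation allele vs deletion).  With ``sig(x) = |x| > tau``:

    * ``class1``            sig(A) and not sig(B)
    * ``class2``            sig(A) and sig(B), same sign
    * ``class3``            sig(A) and sig(B), opposite sign
    * ``glutamation_only``  not sig(A) and sig(B)
    * ``unaffected``        otherwise

    Genes with a missing contrast are labelled ``unclassifiable``.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    a = table["log2_a"].astype(float)
    b = table["log2_b"].astype(float)
    labels = pd.Series("unaffected", index=table.index, dtype=object)
    sig_a = a.abs() > tau
    sig_b = b.abs() > tau
    labels[sig_a & ~sig_b] = "class1"
    labels[sig_a & sig_b & (np.sign(a) == np.sign(b))] = "class2"
    labels[sig_a & sig_b & (np.sign(a) != np.sign(b))] = "class3"
    labels[~sig_a & sig_b] = "glutamation_only"
    labels[a.isna() | b.isna()] = "unclassifiable"
    return labels


def differential_protein_filter(
    records: pd.DataFrame,
    min_peptides: int = 2,
    min_log2_delta: float = 1.0,
    max_p: float = 0.05,
) -> pd.DataFrame:
    """Flag proteins differentially regulated between wild type and mutant.

    A record passes when it has at least ``min_peptides`` unique peptides,
    the wild-type and mutant log2 condition ratios differ by at least
    ``min_log2_delta`` (2-fold by default), and at least one of the two
    (pre-adjusted) p-values is <= ``max_p``.  Direction is the sign of
    (mutant - wild type).  Records missing a p-value are excluded with a
    warning.
    """
    required = {"peptides", "log2_wt", "log2_mut", "p_wt", "p_mut"}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise ValueError(f"missing columns: {sorted(missing_cols)}")
    has_p = records["p_wt"].notna() & records["p_mut"].notna()
    if (~has_p).any():
        logger.warning(
            "%d records excluded for missing p-values", int((~has_p).sum())
        )
    usable = records[has_p]
    delta = usable["log2_mut"] - usable["log2_wt"]
    flagged = (
        (usable["peptides"] >= min_peptides)
        & (delta.abs() >= min_log2_delta)
        & (usable[["p_wt", "p_mut"]].min(axis=1) <= max_p)
    )
    out = usable[flagged].copy()
    out["direction"] = np.where(delta[flagged] > 0, "up", "down")
    return out


def read_gff3(path: str, feature_type: str = "gene") -> list[GeneModel]:
    """Load gene models from a GFF3 file (via an in-memory gffutils db)."""
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type(feature_type, order_by="start"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                reference=feat.seqid,
                strand=feat.strand,
                start=feat.start,
                end=feat.end,
            )
        )
    return genes


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    """Write a coverage track as bedGraph (0-based half-open, runs merged)."""
    counts = track.counts
    with open(path, "w") as fh:
        fh.write(
            f'track type=bedGraph name="{track.reference}{track.strand}"\n'
        )
        if counts.size == 0:
            return
        breaks = np.flatnonzero(np.diff(counts)) + 1
        starts = np.concatenate([[0], breaks])
        ends = np.concatenate([breaks, [counts.size]])
        for s, e in zip(starts, ends):
            v = counts[s]
            if v != 0:
                fh.write(f"{track.reference}\t{s}\t{e}\t{v}\n")
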