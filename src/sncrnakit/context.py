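"""Genomic-context classification of small noncoding RNA loci.

Small noncoding RNAs (tRNAs, snRNAs, snoRNAs, miRNAs, ribozymes) fall into a
few characteristic genomic neighbourhoods: inside introns of protein-coding
genes, in the untranslated flanks immediately outside an open reading frame,
or in deep intergenic space.  When genuine UTR annotation is unavailable the
flanking category is operationalised as a *pseudo-UTR*: any locus lying
outside every ORF but within a fixed distance (default 2,000 bp) of the
nearer ORF boundary (start codon or stop codon).

All coordinates in this module are 0-based half-open; the io module converts
from and to the 1-based inclusive conventions of GFF3 and printed locus
tables.  Distances, however, follow the 1-based counting convention used in
printed tables: a locus immediately adjacent to an ORF has distance 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Literal, Sequence

__all__ = [
    "GeneModel",
    "SncRnaLocus",
    "LocationCall",
    "DistributionSummary",
    "Histogram",
    "RNA_CLASSES",
    "infer_rna_class",
    "nearest_boundary_distance",
    "classify_locus",
    "summarize_locations",
    "distance_histogram",
    "round_half_away",
    "DEFAULT_UTR_THRESHOLD",
]

DEFAULT_UTR_THRESHOLD = 2000

RNA_CLASSES = ("snRNA", "snoRNA", "tRNA", "miRNA", "ribozyme", "other")

Category = Literal["intron", "pseudo_utr", "intergenic", "orf_overlap"]


class NoNeighborError(LookupError):
    """No gene annotated on the locus's contig."""


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene reduced to its ORF span and coding exons.

    ``start``/``end`` delimit the ORF (start codon through stop codon),
    0-based half-open.  ``exons`` are the coding-exon intervals, sorted and
    disjoint, tiling a subset of the ORF span; introns are exactly the gaps
    between consecutive exons.
    """

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: empty ORF span")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"gene {self.gene_id}: empty exon ({s}, {e})")
            if s < self.start or e > self.end:
                raise ValueError(f"gene {self.gene_id}: exon outside ORF span")
            if prev_end is not None and s < prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = e
        if self.exons:
            if self.exons[0][0] != self.start or self.exons[-1][1] != self.end:
                raise ValueError(
                    f"gene {self.gene_id}: exons do not reach the ORF boundaries"
                )

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def start1(self) -> int:
        return self.start + 1

    @property
    def end1(self) -> int:
        return self.end


@dataclass(frozen=True)
class SncRnaLocus:
    """One small noncoding RNA locus (0-based half-open span)."""

    id: str
    rna_class: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"locus {self.id}: empty span")
        if self.strand not in ("+", "-"):
            raise ValueError(f"locus {self.id}: bad strand {self.strand!r}")
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"locus {self.id}: unknown class {self.rna_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def start1(self) -> int:
        return self.start + 1

    @property
    def end1(self) -> int:
        return self.end


@dataclass(frozen=True)
class LocationCall:
    """Classification of one locus relative to the gene annotation.

    ``distance`` is present exactly for the pseudo_utr and intergenic
    categories (1-based convention: adjacency = 1); intronic and
    ORF-overlapping calls carry the containing/overlapping gene instead.
    A locus on a contig without genes yields the no-neighbor sentinel:
    category ``intergenic`` with both distance and neighbor ``None``.
    """

    locus_id: str
    category: Category
    distance: int | None
    neighbor: str | None

    def __post_init__(self) -> None:
        if self.category in ("intron", "orf_overlap") and self.distance is not None:
            raise ValueError(f"{self.locus_id}: {self.category} call carries a distance")


_CLASS_PATTERNS: tuple[tuple[re.Pattern[str], str], ...] = (
    (re.compile(r"^mir", re.IGNORECASE), "miRNA"),
    (re.compile(r"^U\d"), "snRNA"),
    (re.compile(r"^trna", re.IGNORECASE), "tRNA"),
    (re.compile(r"^hammerhead", re.IGNORECASE), "ribozyme"),
    (re.compile(r"^(sno|snr|snord|afu)", re.IGNORECASE), "snoRNA"),
)


def infer_rna_class(locus_id: str) -> str:
    """Map a printed locus id to its RNA class.

    Ids follow the conventions of the Rfam-derived tables: ``U2.1`` (snRNA),
    ``miR-190a-3p`` (miRNA), ``Hammerhead_3.1`` (ribozyme), ``snoZ13_snr52.2``
    / ``SNORD24.1`` / ``Afu_455.1`` (snoRNA).  Anything unrecognised
    (e.g. ``RNase_MRP.1``) is classed ``other``.
    """
    for pattern, cls in _CLASS_PATTERNS:
        if pattern.match(locus_id):
            return cls
    return "other"


def round_half_away(value: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (printed-percentage style)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _genes_on_contig(locus: SncRnaLocus, genes: Iterable[GeneModel]) -> list[GeneModel]:
    return [g for g in genes if g.contig == locus.contig]


def nearest_boundary_distance(
    locus: SncRnaLocus, genes: Sequence[GeneModel]
) -> tuple[int, str]:
    """Distance from a locus to the nearer ORF boundary over all genes.

    The distance is the 1-based coordinate difference to the closer of the
    start-codon and stop-codon boundaries, minimised over every gene on the
    locus's contig; an immediately adjacent locus has distance 1.  Distances
    are strand-agnostic.  Ties between equidistant genes are broken by the
    lexicographically smallest gene id.

    Raises ``NoNeighborError`` when the contig carries no gene and
    ``ValueError`` when the locus overlaps an ORF (precondition violation).
    """
    candidates = _genes_on_contig(locus, genes)
    if not candidates:
        raise NoNeighborError(f"no gene on contig {locus.contig} for locus {locus.id}")
    best: tuple[int, str] | None = None
    for g in candidates:
        if locus.end <= g.start:
            d = g.start - locus.end + 1
        elif locus.start >= g.end:
            d = locus.start - g.end + 1
        else:
            raise ValueError(
                f"locus {locus.id} overlaps ORF of gene {g.gene_id}; "
                "nearest_boundary_distance requires an ORF-free locus"
            )
        if best is None or (d, g.gene_id) < best:
            best = (d, g.gene_id)
    assert best is not None
    return best


def classify_locus(
    locus: SncRnaLocus,
    genes: Sequence[GeneModel],
    utr_threshold: int = DEFAULT_UTR_THRESHOLD,
) -> LocationCall:
    """Assign a locus to intron / pseudo_utr / intergenic / orf_overlap.

    Priority: full containment in a single intron wins; any other overlap
    with an ORF span (exon overlap or straddling an ORF edge) is flagged
    ``orf_overlap`` and excluded from distance summaries; otherwise the
    nearest-boundary distance decides between pseudo_utr (distance <=
    ``utr_threshold``) and intergenic (strictly greater).
    """
    if utr_threshold <= 0:
        raise ValueError("utr_threshold must be positive")
    candidates = sorted(_genes_on_contig(locus, genes), key=lambda g: g.gene_id)
    overlapping: list[GeneModel] = []
    for g in candidates:
        if locus.start < g.end and locus.end > g.start:
            for ivl_s, ivl_e in g.introns:
                if ivl_s <= locus.start and locus.end <= ivl_e:
                    return LocationCall(locus.id, "intron", None, g.gene_id)
            overlapping.append(g)
    if overlapping:
        return LocationCall(locus.id, "orf_overlap", None, overlapping[0].gene_id)
    try:
        distance, neighbor = nearest_boundary_distance(locus, candidates)
    except NoNeighborError:
        return LocationCall(locus.id, "intergenic", None, None)
    category: Category = "pseudo_utr" if distance <= utr_threshold else "intergenic"
    return LocationCall(locus.id, category, distance, neighbor)


@dataclass(frozen=True)
class Histogram:
    """Fixed-width distance histogram; bin k covers [k*w+1, (k+1)*w]."""

    bin_width: int
    bins: dict[int, int]
    overflow: int

    @property
    def total(self) -> int:
        return sum(self.bins.values()) + self.overflow


def distance_histogram(
    calls: Iterable["LocationCall | int"],
    bin_width: int = 500,
    n_bins: int | None = None,
) -> Histogram:
    """Bin nearest-boundary distances; intron/orf_overlap calls are excluded.

    Accepts LocationCalls or bare distances.  With ``n_bins`` set, distances
    beyond the last bin are accumulated in ``overflow`` so that bin counts
    plus overflow always equal the number of distance-bearing calls.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    distances = []
    for c in calls:
        if isinstance(c, LocationCall):
            if c.distance is not None:
                distances.append(c.distance)
        else:
            distances.append(int(c))
    if n_bins is None:
        n_bins = max(((d - 1) // bin_width for d in distances), default=0) + 1
    bins = {k: 0 for k in range(n_bins)}
    overflow = 0
    for d in distances:
        k = (d - 1) // bin_width
        if k < n_bins:
            bins[k] += 1
        else:
            overflow += 1
    return Histogram(bin_width=bin_width, bins=bins, overflow=overflow)


@dataclass(frozen=True)
class DistributionSummary:
    """Aggregate location statistics for one RNA class (or all classes)."""

    rna_class: str | None
    n_total: int
    n_intron: int
    n_orf_overlap: int
    distances: tuple[int, ...]
    histogram: Histogram = field(repr=False)

    @property
    def max_distance(self) -> int | None:
        return max(self.distances) if self.distances else None

    def n_within(self, d: int) -> int:
        return sum(1 for x in self.distances if x <= d)

    def n_beyond(self, d: int) -> int:
        return sum(1 for x in self.distances if x > d)

    def percent_intron(self) -> float:
        return round_half_away(100.0 * self.n_intron / self.n_total)

    def percent_within(self, d: int) -> float:
        return round_half_away(100.0 * self.n_within(d) / self.n_total)


def summarize_locations(
    rows: Sequence[object],
    rna_class: str | None = None,
    bin_width: int = 500,
) -> DistributionSummary:
    """Summarise location calls or printed locus-table rows.

    ``rows`` may mix LocationCalls and locus-table rows (any object with
    ``id`` and ``location_field`` attributes, the latter a distance or the
    intron sentinel).  With ``rna_class`` set, rows are filtered by the class
    inferred from their id.  Duplicated printed rows count as distinct
    records; all counts are over rows, not unique ids.
    """
    if not rows:
        raise ValueError("summarize_locations: empty input")
    n_total = n_intron = n_overlap = 0
    distances: list[int] = []
    for row in rows:
        if isinstance(row, LocationCall):
            rid, category, distance = row.locus_id, row.category, row.distance
        else:
            rid = row.id  # type: ignore[attr-defined]
            loc = row.location_field  # type: ignore[attr-defined]
            if isinstance(loc, str):
                category, distance = "intron", None
            else:
                category, distance = "pseudo_utr", int(loc)
        if rna_class is not None and infer_rna_class(rid) != rna_class:
            continue
        n_total += 1
        if category == "intron":
            n_intron += 1
        elif category == "orf_overlap":
            n_overlap += 1
        elif distance is not None:
            distances.append(distance)
    if n_total == 0:
        raise ValueError(f"summarize_locations: no rows of class {rna_class!r}")
    return DistributionSummary(
        rna_class=rna_class,
        n_total=n_total,
        n_intron=n_intron,
        n_orf_overlap=n_overlap,
        distances=tuple(sorted(distances)),
        histogram=distance_histogram(distances, bin_width=bin_width),
    )
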