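"""Seeded synthetic data: genomes, gene models, planted sncRNA loci with
ground-truth location calls, and diverged ortholog genomes.

The generators stand in for real assemblies in tests and demos.  Defaults
mirror a mushroom-forming fungus survey: contigs at ~49.54% GC, intron-
bearing gene models, sncRNA loci planted at known categories/distances under
the 2,000-bp pseudo-UTR threshold, and a panel of six related genomes plus
one distant outgroup produced by site-independent substitution at per-species
rates.  Every generator is a pure function of (parameters, seed).

Divergence is Jukes-Cantor-like: each site substitutes independently with
the given probability, uniformly over the three alternative bases; no rate
heterogeneity.  Planted loci are indel-protected by default so each locus
has an exactly computable expected identity; a flag releases this for
stress tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .context import (
    DEFAULT_UTR_THRESHOLD,
    GeneModel,
    LocationCall,
    RNA_CLASSES,
    SncRnaLocus,
)
from .homology import reverse_complement

__all__ = [
    "PlantSpec",
    "DivergenceSpec",
    "PlantResult",
    "DivergenceResult",
    "PanelResult",
    "DEFAULT_GC",
    "CladeSpec",
    "random_genome",
    "plant_genes",
    "plant_sncrnas",
    "diverge_genome",
    "make_species_panel",
    "make_clade_panel",
    "default_panel_rates",
    "default_clade_panel",
    "default_plant_specs",
    "simulate_study",
]

#: Default genomic GC fraction (typical of the oyster-mushroom assembly class
#: this simulator emulates).
DEFAULT_GC = 0.4954

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _contig_cls():
    from .io import Contig

    return Contig


@dataclass(frozen=True)
class PlantSpec:
    """Request to plant one sncRNA at a known category/distance."""

    rna_class: str
    target_category: str
    target_distance: int | None
    length: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown rna_class {self.rna_class!r}")
        if self.target_category not in ("intron", "pseudo_utr", "intergenic"):
            raise ValueError(f"unknown category {self.target_category!r}")
        if self.length < 19:
            raise ValueError("planted sncRNAs must be at least 19 nt")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.target_category == "intron":
            if self.target_distance is not None:
                raise ValueError("intron plants carry no target distance")
        else:
            if self.target_distance is None or self.target_distance < 1:
                raise ValueError("non-intron plants need a positive distance")
            if (
                self.target_category == "pseudo_utr"
                and self.target_distance > DEFAULT_UTR_THRESHOLD
            ):
                raise ValueError("pseudo_utr distance exceeds the 2000-bp threshold")
            if (
                self.target_category == "intergenic"
                and self.target_distance <= DEFAULT_UTR_THRESHOLD
            ):
                raise ValueError("intergenic distance must exceed 2000 bp")


@dataclass(frozen=True)
class DivergenceSpec:
    """Per-species divergence parameters (seeded, bit-reproducible)."""

    substitution_rate: float
    indel_rate: float = 0.0
    indel_length: float = 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= r < 0.5:
                raise ValueError("rates must lie in [0, 0.5)")
        if self.indel_length < 1.0:
            raise ValueError("mean indel length must be >= 1")


def random_genome(
    n_contigs: int,
    lengths: "int | Sequence[int]",
    gc_fraction: float = DEFAULT_GC,
    seed: int = 0,
) -> list:
    """Random contigs with the requested GC fraction (min length 1 kb)."""
    Contig = _contig_cls()
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must lie strictly between 0 and 1")
    if isinstance(lengths, int):
        lengths = [lengths] * n_contigs
    if len(lengths) != n_contigs:
        raise ValueError("need one length per contig")
    if any(ln < 1000 for ln in lengths):
        raise ValueError("contig lengths must be at least 1 kb")
    rng = np.random.default_rng(seed)
    p = np.array(
        [
            (1 - gc_fraction) / 2,
            gc_fraction / 2,
            gc_fraction / 2,
            (1 - gc_fraction) / 2,
        ]
    )
    contigs = []
    for i, ln in enumerate(lengths, start=1):
        draw = rng.choice(_BASES, size=ln, p=p)
        contigs.append(Contig(id=f"contig{i}", sequence=draw.tobytes().decode()))
    return contigs


def plant_genes(
    genome: Sequence,
    n_genes: int,
    exons_per_gene: int = 3,
    intron_lengths: "int | Sequence[int]" = 300,
    min_intergenic_gap: int = 500,
    exon_length_range: tuple[int, int] = (150, 450),
    edge_margin: int = 6000,
    seed: int = 0,
) -> list[GeneModel]:
    """Place non-overlapping intron-bearing gene models along the genome.

    Genes are laid out left to right with inter-ORF gaps of at least
    ``min_intergenic_gap``; each gene gets ``exons_per_gene`` exons separated
    by introns of the requested lengths (an int applies to every intron).
    ``edge_margin`` keeps the first/last gene away from the contig ends so
    deep-intergenic loci (beyond the 2,000-bp pseudo-UTR band) have room.
    """
    if exons_per_gene < 1:
        raise ValueError("exons_per_gene must be >= 1")
    n_introns = exons_per_gene - 1
    if isinstance(intron_lengths, int):
        intron_lens = (intron_lengths,) * n_introns
    else:
        intron_lens = tuple(intron_lengths)
        if len(intron_lens) != n_introns:
            raise ValueError(
                f"need {n_introns} intron lengths for {exons_per_gene} exons"
            )
    if any(ln < 1 for ln in intron_lens):
        raise ValueError("intron lengths must be positive")
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    # round-robin over contigs so genes (and intergenic room) spread evenly
    cursors = {
        c.id: edge_margin
        + int(rng.integers(min_intergenic_gap, 3 * min_intergenic_gap))
        for c in genome
    }
    open_contigs = list(genome)
    gene_no = 1
    while gene_no <= n_genes and open_contigs:
        for contig in list(open_contigs):
            if gene_no > n_genes:
                break
            exon_lens = rng.integers(
                exon_length_range[0], exon_length_range[1] + 1, size=exons_per_gene
            )
            gene_len = int(exon_lens.sum()) + sum(intron_lens)
            cursor = cursors[contig.id]
            if cursor + gene_len + min_intergenic_gap + edge_margin > contig.length:
                open_contigs.remove(contig)
                continue
            exons = []
            pos = cursor
            for idx, el in enumerate(exon_lens):
                exons.append((pos, pos + int(el)))
                pos += int(el)
                if idx < n_introns:
                    pos += intron_lens[idx]
            genes.append(
                GeneModel(
                    gene_id=f"g{gene_no}",
                    contig=contig.id,
                    strand="+" if rng.random() < 0.5 else "-",
                    start=cursor,
                    end=cursor + gene_len,
                    exons=tuple(exons),
                )
            )
            gene_no += 1
            cursors[contig.id] = cursor + gene_len + int(
                rng.integers(min_intergenic_gap, 2 * min_intergenic_gap)
            )
    if gene_no <= n_genes:
        raise ValueError(
            f"could not place {n_genes} genes (placed {gene_no - 1}); "
            "use fewer genes or longer contigs"
        )
    return genes


@dataclass(frozen=True)
class PlantResult:
    """Planted loci, their ground-truth calls, sequences, updated genome."""

    loci: tuple[SncRnaLocus, ...]
    truth: tuple[LocationCall, ...]
    sequences: dict[str, str]
    genome: tuple


def _brute_nearest(start: int, end: int, genes: Sequence[GeneModel]) -> tuple[int, str]:
    """Generator-local nearest-boundary arithmetic (kept independent of the
    classifier so planted-truth recovery is a genuine cross-check)."""
    best: tuple[int, str] | None = None
    for g in genes:
        if end <= g.start:
            d = g.start - end + 1
        elif start >= g.end:
            d = start - g.end + 1
        else:
            return (-1, g.gene_id)  # overlap sentinel
        if best is None or (d, g.gene_id) < best:
            best = (d, g.gene_id)
    assert best is not None
    return best


def plant_sncrnas(
    genome: Sequence,
    annotation: Sequence[GeneModel],
    specs: Sequence[PlantSpec],
    seed: int = 0,
) -> PlantResult:
    """Plant sncRNA loci with exactly known categories and distances.

    Each spec is placed so that the generator's own brute-force arithmetic
    confirms the target category and distance; the random RNA sequence is
    written into the genome (reverse-complemented for minus-strand loci) and
    recorded so homology searches have exact ground truth.
    """
    Contig = _contig_cls()
    rng = np.random.default_rng(seed)
    seqs = {c.id: bytearray(c.sequence.encode()) for c in genome}
    by_contig: dict[str, list[GeneModel]] = {}
    for g in annotation:
        by_contig.setdefault(g.contig, []).append(g)
    occupied: dict[str, list[tuple[int, int]]] = {c.id: [] for c in genome}
    for genes in by_contig.values():
        for g in genes:
            occupied[g.contig].append((g.start, g.end))
    planted_ivls: dict[str, list[tuple[int, int]]] = {c.id: [] for c in genome}

    def free(contig_id: str, start: int, end: int) -> bool:
        blocked = occupied.get(contig_id, []) + planted_ivls.get(contig_id, [])
        return all(end <= s or start >= e for s, e in blocked)

    def clear_of_plants(contig_id: str, start: int, end: int) -> bool:
        return all(
            end <= s or start >= e for s, e in planted_ivls.get(contig_id, [])
        )

    loci: list[SncRnaLocus] = []
    truth: list[LocationCall] = []
    sequences: dict[str, str] = {}
    for idx, spec in enumerate(specs, start=1):
        locus_id = f"plant{idx}_{spec.rna_class}"
        placed = None
        if spec.target_category == "intron":
            candidates = [
                (g, iv)
                for genes in by_contig.values()
                for g in genes
                for iv in g.introns
                if iv[1] - iv[0] >= spec.length
            ]
            order = rng.permutation(len(candidates))
            for ci in order:
                g, (iv_s, iv_e) = candidates[int(ci)]
                slack = iv_e - iv_s - spec.length
                start = iv_s + int(rng.integers(0, slack + 1))
                end = start + spec.length
                if not clear_of_plants(g.contig, start, end):
                    continue
                placed = (g.contig, start, end, None, g.gene_id)
                break
            if placed is None:
                raise ValueError(f"unplaceable spec {locus_id}: no intron is long enough")
        else:
            d = spec.target_distance
            assert d is not None
            candidates = []
            for contig_id, genes in by_contig.items():
                contig_len = len(seqs[contig_id])
                for g in genes:
                    up_end = g.start - d + 1
                    up_start = up_end - spec.length
                    if up_start >= 0:
                        candidates.append((contig_id, up_start, up_end))
                    down_start = g.end + d - 1
                    down_end = down_start + spec.length
                    if down_end <= contig_len:
                        candidates.append((contig_id, down_start, down_end))
            order = rng.permutation(len(candidates))
            for ci in order:
                contig_id, start, end = candidates[int(ci)]
                if not free(contig_id, start, end):
                    continue
                nd, neighbor = _brute_nearest(start, end, by_contig[contig_id])
                if nd != d:
                    continue
                placed = (contig_id, start, end, d, neighbor)
                break
            if placed is None:
                raise ValueError(
                    f"unplaceable spec {locus_id}: no position realises "
                    f"distance {d} without conflicts"
                )
        contig_id, start, end, distance, neighbor = placed
        rna = rng.choice(_BASES, size=spec.length).tobytes().decode()
        genomic = rna if spec.strand == "+" else reverse_complement(rna)
        seqs[contig_id][start:end] = genomic.encode()
        planted_ivls.setdefault(contig_id, []).append((start, end))
        loci.append(
            SncRnaLocus(
                id=locus_id,
                rna_class=spec.rna_class,
                contig=contig_id,
                start=start,
                end=end,
                strand=spec.strand,
            )
        )
        truth.append(
            LocationCall(
                locus_id=locus_id,
                category=spec.target_category,
                distance=distance,
                neighbor=neighbor,
            )
        )
        sequences[locus_id] = rna
    new_genome = tuple(
        Contig(id=c.id, sequence=seqs[c.id].decode()) for c in genome
    )
    return PlantResult(
        loci=tuple(loci), truth=tuple(truth), sequences=sequences, genome=new_genome
    )


@dataclass(frozen=True)
class DivergenceResult:
    """Diverged genome plus realised substitution counts per planted locus."""

    genome: tuple
    substitutions: dict[str, int]


def diverge_genome(
    genome: Sequence,
    spec: DivergenceSpec,
    planted_loci: Sequence[SncRnaLocus] = (),
    protect_planted: bool = True,
) -> DivergenceResult:
    """Apply site-independent substitutions (and optional indels).

    Substitutions hit every site independently with ``substitution_rate``,
    uniformly over the three alternative bases; the realised count inside
    every planted locus is returned so its exact expected identity,
    ``100 * (1 - subs/len)``, is known.  With ``protect_planted`` (default)
    indels are never applied inside planted loci.
    """
    Contig = _contig_cls()
    rng = np.random.default_rng(spec.seed)
    loci_by_contig: dict[str, list[SncRnaLocus]] = {}
    for locus in planted_loci:
        loci_by_contig.setdefault(locus.contig, []).append(locus)
    out = []
    subs_per_locus: dict[str, int] = {}
    for contig in genome:
        arr = np.frombuffer(contig.sequence.encode(), dtype=np.uint8).copy()
        is_base = arr != ord("N")
        hit = (rng.random(len(arr)) < spec.substitution_rate) & is_base
        if hit.any():
            code = np.zeros(len(arr), dtype=np.uint8)
            for i, b in enumerate(b"ACGT"):
                code[arr == b] = i
            shift = rng.integers(1, 4, size=len(arr))
            new_code = (code + shift) % 4
            arr[hit] = _BASES[new_code[hit]]
        for locus in loci_by_contig.get(contig.id, []):
            subs_per_locus[locus.id] = int(hit[locus.start : locus.end].sum())
        seq = arr.tobytes().decode()
        if spec.indel_rate > 0:
            seq = _apply_indels(
                seq,
                spec,
                rng,
                [
                    (l.start, l.end)
                    for l in loci_by_contig.get(contig.id, [])
                    if protect_planted
                ],
            )
        out.append(Contig(id=contig.id, sequence=seq))
    return DivergenceResult(genome=tuple(out), substitutions=subs_per_locus)


def _apply_indels(
    seq: str,
    spec: DivergenceSpec,
    rng: np.random.Generator,
    protected: list[tuple[int, int]],
) -> str:
    positions = np.nonzero(rng.random(len(seq)) < spec.indel_rate)[0]
    if protected:
        keep = [
            p for p in positions if all(not (s <= p < e) for s, e in protected)
        ]
        positions = np.asarray(keep, dtype=int)
    if len(positions) == 0:
        return seq
    starts = sorted(s for s, _ in protected)
    pieces: list[str] = []
    prev = 0
    for p in positions:
        p = int(p)
        if p < prev:
            continue
        length = int(rng.geometric(1.0 / spec.indel_length))
        pieces.append(seq[prev:p])
        if rng.random() < 0.5:  # deletion; never allowed to run into a
            # protected span, so clamp at the next protected start
            end = min(len(seq), p + length)
            for s in starts:
                if p < s < end:
                    end = s
                    break
            prev = end
        else:  # insertion
            pieces.append(rng.choice(_BASES, size=length).tobytes().decode())
            prev = p
    pieces.append(seq[prev:])
    return "".join(pieces)


@dataclass(frozen=True)
class PanelResult:
    """Independently diverged genomes keyed by species name."""

    genomes: dict[str, tuple]
    substitutions: dict[str, dict[str, int]]
    rates: dict[str, float]


def make_species_panel(
    genome: Sequence,
    clade_spec: Mapping[str, DivergenceSpec],
    seed: int = 0,
    planted_loci: Sequence[SncRnaLocus] = (),
) -> PanelResult:
    """Diverge the reference independently into a named species panel.

    Species without an explicit seed get one derived deterministically from
    the panel seed and their position; the per-species substitution rates
    are recorded as the planted divergence-tier truth.
    """
    if not clade_spec:
        raise ValueError("empty species panel")
    names = list(clade_spec)
    if len(names) != len(set(names)):
        raise ValueError("duplicate species names")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    genomes: dict[str, tuple] = {}
    subs: dict[str, dict[str, int]] = {}
    rates: dict[str, float] = {}
    for child, name in zip(children, names):
        spec = clade_spec[name]
        if spec.seed is None:
            derived = int(child.generate_state(1)[0] % (2**31))
            spec = DivergenceSpec(
                substitution_rate=spec.substitution_rate,
                indel_rate=spec.indel_rate,
                indel_length=spec.indel_length,
                seed=derived,
            )
        result = diverge_genome(genome, spec, planted_loci=planted_loci)
        genomes[name] = result.genome
        subs[name] = result.substitutions
        rates[name] = spec.substitution_rate
    return PanelResult(genomes=genomes, substitutions=subs, rates=rates)


@dataclass(frozen=True)
class CladeSpec:
    """One clade: shared ancestor divergence plus per-member divergence.

    The ancestor stage models the lineage shared by the clade members, so
    their identity profiles carry correlated, locus-specific deficits — the
    signal rank-correlation clustering actually keys on.  Indel-free only:
    planted-locus coordinates must stay valid across both stages.
    """

    ancestor: DivergenceSpec
    members: Mapping[str, DivergenceSpec]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("clade has no members")
        if self.ancestor.indel_rate > 0 or any(
            m.indel_rate > 0 for m in self.members.values()
        ):
            raise ValueError("clade panels are substitution-only (no indels)")


def make_clade_panel(
    genome: Sequence,
    clades: Mapping[str, CladeSpec],
    seed: int = 0,
    planted_loci: Sequence[SncRnaLocus] = (),
) -> PanelResult:
    """Diverge the reference through shared clade ancestors into species.

    Every clade first accumulates its ancestor's substitutions once; each
    member then diverges independently from that ancestor.  Per-locus
    substitution counts are the realised Hamming distances between the
    reference and each final genome over the planted spans (exact, since no
    indels are allowed).  The clade grouping is the planted truth topology.
    """
    if not clades:
        raise ValueError("empty clade panel")
    all_names = [m for c in clades.values() for m in c.members]
    if len(all_names) != len(set(all_names)):
        raise ValueError("duplicate species names across clades")
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(sum(1 + len(c.members) for c in clades.values())))

    def with_seed(spec: DivergenceSpec) -> DivergenceSpec:
        if spec.seed is not None:
            return spec
        derived = int(next(children).generate_state(1)[0] % (2**31))
        return DivergenceSpec(
            substitution_rate=spec.substitution_rate,
            indel_rate=spec.indel_rate,
            indel_length=spec.indel_length,
            seed=derived,
        )

    ref_by_id = {c.id: c.sequence for c in genome}
    genomes: dict[str, tuple] = {}
    subs: dict[str, dict[str, int]] = {}
    rates: dict[str, float] = {}
    for clade in clades.values():
        anc = diverge_genome(
            genome, with_seed(clade.ancestor), planted_loci=planted_loci
        )
        for name, member_spec in clade.members.items():
            dv = diverge_genome(
                anc.genome, with_seed(member_spec), planted_loci=planted_loci
            )
            genomes[name] = dv.genome
            final_by_id = {c.id: c.sequence for c in dv.genome}
            counts: dict[str, int] = {}
            for locus in planted_loci:
                ref = ref_by_id[locus.contig][locus.start : locus.end]
                fin = final_by_id[locus.contig][locus.start : locus.end]
                counts[locus.id] = sum(1 for a, b in zip(ref, fin) if a != b)
            subs[name] = counts
            ra = clade.ancestor.substitution_rate
            rm = member_spec.substitution_rate
            rates[name] = 1.0 - (1.0 - ra) * (1.0 - rm)
    return PanelResult(genomes=genomes, substitutions=subs, rates=rates)


def default_clade_panel() -> dict[str, CladeSpec]:
    """The default 6+1 study panel as clades.

    One conspecific genome nearly identical to the reference, a close clade
    and a farther clade of related species (>=3x rate separation between the
    clades at both stages), and one distant outgroup so far diverged that
    essentially nothing is matched (its all-zero profile takes the maximal
    dissimilarity and joins the tree last).
    """
    return {
        "self": CladeSpec(
            ancestor=DivergenceSpec(substitution_rate=0.0),
            members={"conspecific": DivergenceSpec(substitution_rate=0.01)},
        ),
        "close": CladeSpec(
            ancestor=DivergenceSpec(substitution_rate=0.05),
            members={
                "close_1": DivergenceSpec(substitution_rate=0.015),
                "close_2": DivergenceSpec(substitution_rate=0.02),
            },
        ),
        "far": CladeSpec(
            ancestor=DivergenceSpec(substitution_rate=0.15),
            members={
                "far_1": DivergenceSpec(substitution_rate=0.05),
                "far_2": DivergenceSpec(substitution_rate=0.05),
                "far_3": DivergenceSpec(substitution_rate=0.06),
            },
        ),
        "basal": CladeSpec(
            ancestor=DivergenceSpec(substitution_rate=0.0),
            members={"outgroup": DivergenceSpec(substitution_rate=0.40)},
        ),
    }


def default_panel_rates() -> dict[str, float]:
    """Six related genomes plus one distant outgroup (substitution rates).

    The conspecific genome is nearly identical; five congeners span a graded
    band of divergence; the outgroup is far enough that most short queries
    drop below the seeding/e-value floor, emulating a basal species whose
    sncRNA complement is largely unmatched.
    """
    return {
        "conspecific": 0.01,
        "close_1": 0.06,
        "close_2": 0.08,
        "mid_1": 0.10,
        "mid_2": 0.12,
        "far_1": 0.15,
        "outgroup": 0.40,
    }


def simulate_study(
    seed: int,
    n_contigs: int = 2,
    contig_length: int = 30000,
    n_genes: int = 10,
    n_per_class: int = 8,
    max_tries: int = 8,
) -> tuple[list[GeneModel], PlantResult]:
    """One complete synthetic study: genome, gene models, planted loci.

    Placement of an exact-distance locus can be infeasible under an
    unlucky random gene layout; such layouts are re-drawn deterministically
    from follow-on seeds (same study parameters), so the function is still
    a pure function of its arguments.
    """
    last: Exception | None = None
    for attempt in range(max_tries):
        base = seed + 1_000_003 * attempt
        try:
            genome = random_genome(n_contigs, contig_length, seed=base)
            genes = plant_genes(genome, n_genes, seed=base + 1)
            specs = default_plant_specs(n_per_class=n_per_class, seed=base + 2)
            return genes, plant_sncrnas(genome, genes, specs, seed=base + 3)
        except ValueError as exc:
            last = exc
    raise ValueError(
        f"no feasible layout in {max_tries} attempts from seed {seed}: {last}"
    )


def default_plant_specs(
    n_per_class: int = 6, seed: int = 0
) -> list[PlantSpec]:
    """A mixed panel of plant requests covering all categories and the
    length spectrum of the sncRNA classes (miRNA 19-23 nt up to snRNA
    ~190 nt)."""
    rng = np.random.default_rng(seed)
    length_ranges = {
        "miRNA": (19, 23),
        "tRNA": (71, 90),
        "snoRNA": (83, 110),
        "snRNA": (100, 191),
        "ribozyme": (55, 55),
        # graded lengths across the seed-survival transition band
        "other": (24, 200),
    }
    categories = ("intron", "pseudo_utr", "intergenic")
    specs: list[PlantSpec] = []
    for cls, (lo, hi) in length_ranges.items():
        for i in range(n_per_class):
            cat = categories[i % len(categories)]
            if cat == "intron":
                dist = None
            elif cat == "pseudo_utr":
                # mostly tight to the ORF (as real loci are); occasional
                # deep-pseudo-UTR draws exercise the threshold band
                if rng.random() < 0.8:
                    dist = int(rng.integers(1, 301))
                else:
                    dist = int(rng.integers(301, DEFAULT_UTR_THRESHOLD + 1))
            else:
                dist = int(rng.integers(DEFAULT_UTR_THRESHOLD + 1, 4500))
            specs.append(
                PlantSpec(
                    rna_class=cls,
                    target_category=cat,
                    target_distance=dist,
                    length=int(rng.integers(lo, hi + 1)),
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
    return specs
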