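import pytest

from sncrnakit.context import GeneModel, SncRnaLocus
from sncrnakit.simulate import (
    default_plant_specs,
    plant_genes,
    plant_sncrnas,
    random_genome,
)


@pytest.fixture(scope="session")
def small_genome():
    return random_genome(2, 30000, seed=11)


@pytest.fixture(scope="session")
def small_genes(small_genome):
    return plant_genes(small_genome, 10, seed=12)


@pytest.fixture(scope="session")
def planted(small_genome, small_genes):
    specs = default_plant_specs(n_per_class=6, seed=13)
    return plant_sncrnas(small_genome, small_genes, specs, seed=14)


def random_gene_models(rng, contig="c1", n_genes=5, span=50000):
    """Random non-overlapping intron-bearing gene models for oracle tests."""
    genes = []
    cursor = int(rng.integers(200, 2000))
    for i in range(n_genes):
        n_exons = int(rng.integers(1, 4))
        exons = []
        pos = cursor
        for j in range(n_exons):
            e = pos + int(rng.integers(100, 400))
            exons.append((pos, e))
            pos = e + (int(rng.integers(50, 400)) if j < n_exons - 1 else 0)
        # drop trailing intron gap bookkeeping: last exon ends the ORF
        start, end = exons[0][0], exons[-1][1]
        genes.append(
            GeneModel(
                gene_id=f"g{i + 1}",
                contig=contig,
                strand="+" if rng.random() < 0.5 else "-",
                start=start,
                end=end,
                exons=tuple(exons),
            )
        )
        cursor = end + int(rng.integers(300, 3000))
        if cursor > span:
            break
    return genes


def random_locus(rng, genes, contig="c1", span=60000):
    length = int(rng.integers(19, 200))
    start = int(rng.integers(0, span - length))
    return SncRnaLocus(
        id=f"L{start}",
        rna_class="other",
        contig=contig,
        start=start,
        end=start + length,
        strand="+" if rng.random() < 0.5 else "-",
    )


def brute_force_classify(locus, genes, utr_threshold=2000):
    """Independent reference classifier: test every gene, intron and side."""
    same = sorted(
        (g for g in genes if g.contig == locus.contig), key=lambda g: g.gene_id
    )
    for g in same:
        for iv_s, iv_e in g.introns:
            if iv_s <= locus.start and locus.end <= iv_e:
                return ("intron", None, g.gene_id)
    overlapping = [
        g for g in same if locus.start < g.end and locus.end > g.start
    ]
    if overlapping:
        return ("orf_overlap", None, overlapping[0].gene_id)
    best = None
    for g in same:
        for d in (g.start - locus.end + 1, locus.start - g.end + 1):
            if d >= 1 and (best is None or (d, g.gene_id) < best):
                best = (d, g.gene_id)
    if best is None:
        return ("intergenic", None, None)
    d, gid = best
    cat = "pseudo_utr" if d <= utr_threshold else "intergenic"
    return (cat, d, gid)
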