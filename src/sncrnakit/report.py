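"""Summary report over the shipped Rfam/miRNA locus tables.

The package ships the two printed locus tables of the survey it
re-implements (Rfam-derived sncRNAs and mature miRNAs of an oyster-mushroom
genome assembly) as verbatim TSV fixtures.  ``paper_report`` recomputes
every distribution aggregate from those rows: per-class totals, intron
counts, maximum distances, within-distance counts, beyond-threshold counts
and class-member tallies.  A checksum guard refuses silently edited
fixtures.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

from .context import round_half_away, summarize_locations
from .io import LocusTableRow, read_locus_table

__all__ = ["paper_report", "render_report_tsv", "FixtureError"]

_FIXTURES = {
    "table2": (
        "table2_rfam_loci.tsv",
        "b076d16790485c8e5d00b50e407c107eef2db53ddd6d5a89b409e5f234df36da",
    ),
    "table3": (
        "table3_mirna_loci.tsv",
        "e2551df8077b676a30016369a5ce35ebef778eb92a462f5d643b3071a111935a",
    ),
}


class FixtureError(RuntimeError):
    """Shipped locus-table fixture failed its checksum."""


def fixture_path(name: str) -> Path:
    fname, want = _FIXTURES[name]
    path = resources.files("sncrnakit.data").joinpath(fname)
    got = hashlib.sha256(path.read_bytes()).hexdigest()
    if got != want:
        raise FixtureError(
            f"fixture {fname} checksum mismatch (got {got[:12]}..., "
            f"expected {want[:12]}...); refusing silently edited data"
        )
    return Path(str(path))


def _ids_starting(rows: list[LocusTableRow], prefix: str) -> list[LocusTableRow]:
    return [r for r in rows if r.id.startswith(prefix)]


def paper_report(
    table2: "str | Path | None" = None, table3: "str | Path | None" = None
) -> dict:
    """Recompute every distribution aggregate from the locus-table fixtures.

    Row semantics follow the printed tables: repeated rows are distinct
    records, and all counts are over rows.
    """
    rows2 = read_locus_table(table2 if table2 is not None else fixture_path("table2"))
    rows3 = read_locus_table(table3 if table3 is not None else fixture_path("table3"))

    snrna = summarize_locations(rows2, rna_class="snRNA")
    # everything in the Rfam table that is not a spliceosomal snRNA:
    # snoRNAs, Hammerhead ribozymes, the RNase MRP RNA
    other_rows = [r for r in rows2 if not _ids_starting([r], "U")]
    other = summarize_locations(other_rows)
    mirna = summarize_locations(rows3, rna_class="miRNA")

    snrna_non_u5 = [
        r.location_field
        for r in rows2
        if r.id[0] == "U" and not r.id.startswith("U5") and not r.is_intron
    ]
    mirna_lengths = [r.length for r in rows3]

    return {
        "snrna": {
            "n_total": snrna.n_total,
            "n_intron": snrna.n_intron,
            "max_distance": snrna.max_distance,
            "max_distance_excluding_u5": max(snrna_non_u5),
            "n_within_1000": snrna.n_within(1000),
            "u2_candidates": len(_ids_starting(rows2, "U2.")),
            "u4_candidates": len(_ids_starting(rows2, "U4.")),
            "u5_candidates": len(_ids_starting(rows2, "U5.")),
            "u6_candidates": len(_ids_starting(rows2, "U6.")),
        },
        "other_sncrna": {
            "n_total": other.n_total,
            "n_intron": other.n_intron,
            "max_distance": other.max_distance,
            "hammerhead_entries": len(_ids_starting(rows2, "Hammerhead")),
            "rnase_mrp_entries": len(_ids_starting(rows2, "RNase_MRP")),
            "snorna_entries": sum(
                1 for r in other_rows if r.id[:3].lower() in ("sno", "snr")
                or r.id.startswith(("SNORD", "Afu"))
            ),
        },
        "mirna": {
            "n_total": mirna.n_total,
            "n_intron": mirna.n_intron,
            "percent_intron": mirna.percent_intron(),
            "n_beyond_2000": mirna.n_beyond(2000),
            "max_distance": mirna.max_distance,
            "length_min": min(mirna_lengths),
            "length_max": max(mirna_lengths),
        },
    }


def render_report_tsv(report: dict) -> str:
    """Flatten the nested report into a two-column TSV (block.key, value)."""
    lines = ["metric\tvalue"]
    for block, metrics in report.items():
        for key, value in metrics.items():
            if isinstance(value, float):
                value = f"{round_half_away(value):.2f}"
            lines.append(f"{block}.{key}\t{value}")
    return "\n".join(lines) + "\n"
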