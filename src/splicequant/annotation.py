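"""Gene models and the intron universe used for read classification.

All coordinates are 0-based half-open genomic intervals on a named
chromosome. GTF input (1-based inclusive) is converted on read; BED input
is taken as-is. A single convention internally avoids the usual off-by-one
bug classes when intersecting reads with introns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GeneModel",
    "Intron",
    "parse_intron_bed",
    "write_intron_bed",
    "derive_introns",
    "read_gtf_genes",
    "write_gtf",
]

_STRANDS = ("+", "-")


def coordinate_id(chrom: str, start: int, end: int, strand: str) -> str:
    """Deterministic intron identifier from its genomic key."""
    return f"{chrom}:{start}-{end}:{strand}"


@dataclass(frozen=True)
class Intron:
    """A strand-aware intronic interval.

    ``gene_id`` may hold several comma-joined parent gene ids when the same
    genomic intron is shared by overlapping gene models; introns are keyed
    by (chrom, start, end, strand).
    """

    chrom: str
    start: int
    end: int
    strand: str
    intron_id: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"intron {self.intron_id!r}: invalid strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(
                f"intron {self.intron_id!r}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """One gene as an ordered set of exons on a single chromosome/strand.

    Exons are sorted on construction and must be non-overlapping (touching
    exons are allowed and yield no intron between them).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in _STRANDS:
            raise ValueError(f"gene {self.gene_id!r}: invalid strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id!r}: at least one exon required")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for s, e in exons:
            if e <= s:
                raise ValueError(f"gene {self.gene_id!r}: exon ({s},{e}) has end <= start")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"gene {self.gene_id!r}: overlapping exons ({s1},{e1}) and ({s2},{e2})"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


def parse_intron_bed(path: str | Path) -> list[Intron]:
    """Read a 6-column BED file of introns (0-based half-open).

    Names equal to ``.`` are replaced by ``chrom:start-end:strand``;
    duplicated explicit names are an error. Malformed rows raise
    ``ValueError`` naming the offending line.
    """
    introns: list[Intron] = []
    seen: set[str] = set()
    path = Path(path)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(
                    f"{path.name}: line {lineno}: expected 6 BED columns, found {len(fields)}"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path.name}: line {lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"{path.name}: line {lineno}: start >= end ({start} >= {end})")
            if strand not in _STRANDS:
                raise ValueError(f"{path.name}: line {lineno}: invalid strand {strand!r}")
            if name == ".":
                name = coordinate_id(chrom, start, end, strand)
            else:
                if name in seen:
                    raise ValueError(f"{path.name}: line {lineno}: duplicate intron id {name!r}")
                seen.add(name)
            introns.append(Intron(chrom, start, end, strand, intron_id=name))
    return introns


def write_intron_bed(introns: Iterable[Intron], path: str | Path) -> None:
    """Write introns as 6-column BED; the name column carries the intron id."""
    with open(path, "w") as fh:
        for intron in introns:
            fh.write(
                f"{intron.chrom}\t{intron.start}\t{intron.end}\t"
                f"{intron.intron_id}\t0\t{intron.strand}\n"
            )


def derive_introns(genes: Sequence[GeneModel]) -> list[Intron]:
    """Derive the intron universe as maximal gaps between consecutive exons.

    Single-exon genes contribute nothing. Introns shared by several genes
    are emitted once, keyed by (chrom, start, end, strand), with all parent
    gene ids recorded. Output is sorted by (chrom, start, end, strand).
    """
    by_key: dict[tuple[str, int, int, str], list[str]] = {}
    for gene in genes:
        for (s1, e1), (s2, e2) in zip(gene.exons, gene.exons[1:]):
            if s2 > e1:  # touching exons leave no intron
                by_key.setdefault((gene.chrom, e1, s2, gene.strand), []).append(gene.gene_id)
    out = [
        Intron(
            chrom,
            start,
            end,
            strand,
            intron_id=coordinate_id(chrom, start, end, strand),
            gene_id=",".join(sorted(set(gids))),
        )
        for (chrom, start, end, strand), gids in by_key.items()
    ]
    out.sort(key=lambda i: (i.chrom, i.start, i.end, i.strand))
    return out


def read_gtf_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF exon features.

    For genes with several transcripts the longest transcript (by summed
    exon length; lexicographically smallest transcript id on ties) defines
    the exon chain, keeping the derived intron universe unambiguous.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    tx: dict[tuple[str, str], dict] = {}
    for ex in db.features_of_type("exon"):
        gid = ex.attributes["gene_id"][0]
        tid = ex.attributes["transcript_id"][0]
        entry = tx.setdefault((gid, tid), {"chrom": ex.seqid, "strand": ex.strand, "exons": []})
        entry["exons"].append((ex.start - 1, ex.end))  # GTF is 1-based inclusive

    best: dict[str, tuple[int, str, dict]] = {}
    for (gid, tid), entry in tx.items():
        length = sum(e - s for s, e in entry["exons"])
        current = best.get(gid)
        # longest transcript wins; ties resolved by smallest transcript id
        if current is None or length > current[0] or (length == current[0] and tid < current[1]):
            best[gid] = (length, tid, entry)
    genes = [
        GeneModel(gene_id=gid, chrom=e["chrom"], strand=e["strand"], exons=tuple(sorted(e["exons"])))
        for gid, (_, _, e) in best.items()
    ]
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "splicequant") -> None:
    """Write gene/transcript/exon GTF lines (1-based inclusive on output)."""
    with open(path, "w") as fh:
        for gene in genes:
            attrs = f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.t1";'
            fh.write(
                f"{gene.chrom}\t{source}\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f'{gene.strand}\t.\tgene_id "{gene.gene_id}";\n'
            )
            fh.write(
                f"{gene.chrom}\t{source}\ttranscript\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\t{attrs}\n"
            )
            for s, e in gene.exons:
                fh.write(f"{gene.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t{attrs}\n")
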