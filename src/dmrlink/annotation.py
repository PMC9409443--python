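"""Gene models, promoter windows, and assignment of consensus regions.

Internally every interval is 0-based half-open.  GFF3 input (1-based,
inclusive) is converted on read; BED is taken as-is.  The promoter is a
window of ``flank`` bp either side of the strand-aware TSS — for a +
strand gene the TSS is the gene start, for a - strand gene the last base
of the gene interval — so the window is [tss - flank, tss + flank + 1)
(2*flank + 1 positions), clipped at zero.

A consensus region "hits" a promoter or a gene body when the intervals
share at least one base.  Per gene, the promoter status is hyper / hypo /
both / none and the body status unique_hyper / unique_hypo / mixed /
none; mixed-body genes (both directions present) are excluded from the
downstream unique-signal association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .segmentation import MethRegion

logger = logging.getLogger(__name__)

DEFAULT_FLANK = 1000

_STRANDS = {"+", "-"}


@dataclass(frozen=True)
class GeneModel:
    """One gene with its strand-aware promoter window (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    tss: int
    promoter_start: int
    promoter_end: int

    @property
    def body(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def promoter(self) -> tuple[int, int]:
        return (self.promoter_start, self.promoter_end)


@dataclass(frozen=True)
class GeneMethStatus:
    """Promoter and gene-body methylation category of one gene."""

    gene_id: str
    promoter_status: str  # hyper | hypo | both | none
    body_status: str  # unique_hyper | unique_hypo | mixed | none


def _make_gene(gene_id: str, chrom: str, start: int, end: int, strand: str, flank: int) -> GeneModel:
    if start >= end:
        raise ValueError(f"gene {gene_id}: degenerate interval [{start}, {end})")
    tss = start if strand == "+" else end - 1
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        tss=tss,
        promoter_start=max(0, tss - flank),
        promoter_end=tss + flank + 1,
    )


def _parse_gff3_attr(attrs: str) -> str | None:
    for field in attrs.strip().split(";"):
        field = field.strip()
        for key in ("ID=", "gene_id=", "Name="):
            if field.startswith(key):
                return field[len(key):]
    return None


def load_annotation(
    path, flank: int = DEFAULT_FLANK, dialect: str = "auto"
) -> list[GeneModel]:
    """Load gene models from GFF3 or BED6.

    ``dialect`` is "gff3", "bed", or "auto" (by file extension).  GFF3
    rows are used only when the feature type is "gene".  Records with an
    unknown strand symbol are skipped with a warning; structurally
    malformed lines raise with their line number.
    """
    path = str(path)
    if dialect == "auto":
        low = path.lower()
        dialect = "gff3" if low.endswith((".gff", ".gff3")) else "bed"
    if dialect not in ("gff3", "bed"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")

    genes: list[GeneModel] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            try:
                if dialect == "gff3":
                    if len(parts) < 9:
                        raise ValueError("expected 9 GFF3 columns")
                    chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts[:9]
                    if ftype != "gene":
                        continue
                    gene_id = _parse_gff3_attr(attrs) or f"gene_line{lineno}"
                    start0 = int(start) - 1  # 1-based inclusive -> 0-based half-open
                    end0 = int(end)
                else:
                    if len(parts) < 6:
                        raise ValueError("expected 6 BED columns")
                    chrom, start, end, gene_id, _score, strand = parts[:6]
                    start0 = int(start)
                    end0 = int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record ({exc})") from exc
            if strand not in _STRANDS:
                logger.warning("%s:%d: unknown strand %r, record skipped", path, lineno, strand)
                skipped += 1
                continue
            genes.append(_make_gene(gene_id, chrom, start0, end0, strand, flank))
    if skipped:
        logger.warning("%s: %d records skipped for unknown strand", path, skipped)
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


HIT_COLUMNS = [
    "gene_id", "element", "direction",
    "region_chrom", "region_start", "region_end",
    "element_start", "element_end", "region_pair",
]


def assign_regions(
    regions: list[MethRegion], genes: list[GeneModel]
) -> pd.DataFrame:
    """Overlap consensus regions with promoter windows and gene bodies.

    A hit is any >= 1 bp intersection; one region may hit several genes
    and both elements of a single gene.  Regions on chromosomes absent
    from the annotation are logged and left unassigned.  Returns the hit
    table (one row per region x element overlap).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    rows = []
    hit_regions = set()
    unassigned_chroms = set()
    for ridx, r in enumerate(regions):
        chrom_genes = by_chrom.get(r.chrom)
        if chrom_genes is None:
            unassigned_chroms.add(r.chrom)
            continue
        for g in chrom_genes:
            for element, (es, ee) in (("promoter", g.promoter), ("body", g.body)):
                if max(r.start, es) < min(r.end, ee):
                    hit_regions.add(ridx)
                    rows.append(
                        (g.gene_id, element, r.direction, r.chrom, r.start, r.end,
                         es, ee, r.pair)
                    )
    for chrom in sorted(unassigned_chroms):
        logger.warning("regions on %s have no annotation; left unassigned", chrom)
    logger.info(
        "assigned %d of %d regions to %d gene-element hits",
        len(hit_regions), len(regions), len(rows),
    )
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return df.sort_values(
        ["gene_id", "element", "region_chrom", "region_start"], kind="mergesort"
    ).reset_index(drop=True)


def classify_genes(hits: pd.DataFrame, genes: list[GeneModel]) -> list[GeneMethStatus]:
    """Per-gene promoter / body methylation category from the hit table.

    Promoter: hyper or hypo if only that direction hit the window, both
    if both did, none otherwise.  Body: unique_hyper / unique_hypo when
    exactly one direction is present, mixed when both are.
    """
    promoter_dirs: dict[str, set] = {}
    body_dirs: dict[str, set] = {}
    for row in hits.itertuples(index=False):
        target = promoter_dirs if row.element == "promoter" else body_dirs
        target.setdefault(row.gene_id, set()).add(row.direction)

    statuses = []
    for g in genes:
        pd_ = promoter_dirs.get(g.gene_id, set())
        bd = body_dirs.get(g.gene_id, set())
        if pd_ == {"hyper", "hypo"}:
            promoter_status = "both"
        elif pd_:
            promoter_status = next(iter(pd_))
        else:
            promoter_status = "none"
        if bd == {"hyper", "hypo"}:
            body_status = "mixed"
        elif bd:
            body_status = f"unique_{next(iter(bd))}"
        else:
            body_status = "none"
        statuses.append(GeneMethStatus(g.gene_id, promoter_status, body_status))
    statuses.sort(key=lambda s: s.gene_id)
    return statuses


def status_frame(statuses: list[GeneMethStatus]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.gene_id, s.promoter_status, s.body_status) for s in statuses],
        columns=["gene_id", "promoter_status", "body_status"],
    )
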