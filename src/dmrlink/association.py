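"""Crossing gene-level methylation categories with expression classes.

The report tallies four differential-methylation categories and the six
Venn-style intersections with the up-/down-regulated gene sets:

* promoter_hyper / promoter_hypo — counted in REGION units (number of
  consensus regions overlapping >= 1 promoter window of that direction);
* body_unique_hyper / body_unique_hypo — counted in GENE units (genes
  whose body carries signals of exactly one direction);
* body_mixed — genes whose body carries both directions, excluded from
  the body intersections.

The mixed unit convention (regions for promoters, genes for bodies, then
summed into one total) mirrors how such category totals are convention-
ally reported for this analysis; each count is labelled with its unit.
Derived identities: the four-category total, the hypo share of that
total, and the up share of the DE genes, percentages rounded to the
nearest integer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import pandas as pd

logger = logging.getLogger(__name__)

INTERSECTION_KEYS = [
    "promoter_hyper_down",
    "promoter_hypo_up",
    "body_hyper_down",
    "body_hyper_up",
    "body_hypo_up",
    "body_hypo_down",
]

CATEGORY_UNITS = {
    "promoter_hyper": "regions",
    "promoter_hypo": "regions",
    "body_unique_hyper": "genes",
    "body_unique_hypo": "genes",
    "body_mixed": "genes",
}


@dataclass
class AssociationReport:
    """Category tallies, intersection gene lists and derived identities."""

    counts: dict = field(default_factory=dict)
    intersections: dict = field(default_factory=dict)
    identities: dict = field(default_factory=dict)
    units: dict = field(default_factory=lambda: dict(CATEGORY_UNITS))
    diagnostics: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "AssociationReport":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            try:
                with open(source) as fh:
                    data = json.load(fh)
            except (OSError, ValueError):
                data = json.loads(source)
        return cls(**data)


def identity_check(
    promoter_hyper: int,
    promoter_hypo: int,
    body_unique_hyper: int,
    body_unique_hypo: int,
    n_up: int | None = None,
    n_down: int | None = None,
) -> dict:
    """Derived identities over the category counts.

    total is the sum of the four differential-methylation categories;
    hypo_share_pct the hypo fraction of that total; up_share_pct the up
    fraction of the DE genes (when given).  Percentages are rounded to
    the nearest integer.  Inconsistent inputs (negative counts) raise;
    a zero total yields null shares with a logged warning rather than a
    silent division.
    """
    cats = (promoter_hyper, promoter_hypo, body_unique_hyper, body_unique_hypo)
    if any(c < 0 for c in cats) or (n_up is not None and n_up < 0) or (
        n_down is not None and n_down < 0
    ):
        raise ValueError("category counts must be non-negative")
    total = sum(cats)
    n_hypo = promoter_hypo + body_unique_hypo
    out = {
        "total_dm": total,
        "n_hypo": n_hypo,
        "hypo_share_pct": round(100.0 * n_hypo / total) if total else None,
    }
    if total == 0:
        logger.warning("identity_check: zero differential-methylation total")
    if n_up is not None and n_down is not None:
        n_de = n_up + n_down
        out["n_de"] = n_de
        out["up_share_pct"] = round(100.0 * n_up / n_de) if n_de else None
        if n_de == 0:
            logger.warning("identity_check: zero DE total")
    return out


def cross(
    statuses: pd.DataFrame,
    de_table: pd.DataFrame,
    hits: pd.DataFrame | None = None,
) -> AssociationReport:
    """Build the association report from gene statuses and DE classes.

    ``statuses`` has gene_id / promoter_status / body_status,
    ``de_table`` gene_id / de_class (plus exclusivity when available).
    ``hits`` — the per-element hit table — supplies the region-unit
    promoter counts; without it the promoter categories fall back to
    gene units (recorded in ``report.units``).  Mixed-body genes are
    excluded from the body intersections.  DE genes missing from the
    annotation are counted in the diagnostics, never fatal.
    """
    anno_genes = set(statuses["gene_id"])
    de_genes = set(de_table["gene_id"])
    unmatched = sorted(de_genes - anno_genes)
    if unmatched:
        logger.warning(
            "%d of %d DE genes absent from the annotation (e.g. %s)",
            len(unmatched), len(de_genes), unmatched[:3],
        )

    up = set(de_table.loc[de_table["de_class"] == "up", "gene_id"])
    down = set(de_table.loc[de_table["de_class"] == "down", "gene_id"])

    prom_hyper_genes = set(
        statuses.loc[statuses["promoter_status"].isin(["hyper", "both"]), "gene_id"]
    )
    prom_hypo_genes = set(
        statuses.loc[statuses["promoter_status"].isin(["hypo", "both"]), "gene_id"]
    )
    body_uhyper = set(statuses.loc[statuses["body_status"] == "unique_hyper", "gene_id"])
    body_uhypo = set(statuses.loc[statuses["body_status"] == "unique_hypo", "gene_id"])
    body_mixed = set(statuses.loc[statuses["body_status"] == "mixed", "gene_id"])

    units = dict(CATEGORY_UNITS)
    if hits is not None and len(hits):
        prom = hits[hits["element"] == "promoter"]
        region_key = ["region_chrom", "region_start", "region_end"]
        n_prom_hyper = prom.loc[prom["direction"] == "hyper", region_key].drop_duplicates().shape[0]
        n_prom_hypo = prom.loc[prom["direction"] == "hypo", region_key].drop_duplicates().shape[0]
    else:
        n_prom_hyper = len(prom_hyper_genes)
        n_prom_hypo = len(prom_hypo_genes)
        units["promoter_hyper"] = units["promoter_hypo"] = "genes"
        if hits is None:
            logger.info("no hit table given; promoter categories counted in gene units")

    counts = {
        "promoter_hyper": n_prom_hyper,
        "promoter_hypo": n_prom_hypo,
        "body_unique_hyper": len(body_uhyper),
        "body_unique_hypo": len(body_uhypo),
        "body_mixed": len(body_mixed),
        "up": len(up),
        "down": len(down),
    }
    intersections = {
        "promoter_hyper_down": sorted(prom_hyper_genes & down),
        "promoter_hypo_up": sorted(prom_hypo_genes & up),
        "body_hyper_down": sorted(body_uhyper & down),
        "body_hyper_up": sorted(body_uhyper & up),
        "body_hypo_up": sorted(body_uhypo & up),
        "body_hypo_down": sorted(body_uhypo & down),
    }
    identities = identity_check(
        counts["promoter_hyper"],
        counts["promoter_hypo"],
        counts["body_unique_hyper"],
        counts["body_unique_hypo"],
        n_up=counts["up"],
        n_down=counts["down"],
    )
    diagnostics = {
        "n_de_genes_unmatched": len(unmatched),
        "n_annotation_genes": len(anno_genes),
    }
    return AssociationReport(
        counts=counts,
        intersections=intersections,
        identities=identities,
        units=units,
        diagnostics=diagnostics,
    )


def write_gene_lists(report: AssociationReport, outdir) -> None:
    """One plain-text gene list per intersection, one gene per line."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key in INTERSECTION_KEYS:
        genes = report.intersections.get(key, [])
        (outdir / f"{key}.txt").write_text("".join(g + "\n" for g in genes))
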