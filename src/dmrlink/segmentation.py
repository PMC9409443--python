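"""Aggregation of significant per-site contrasts into methylation regions.

Sites whose |z| clears the two-sided normal critical value are flagged
hyper (z > 0) or hypo (z < 0).  Within one pair and one direction,
flagged sites are merged into maximal runs in which consecutive flagged
sites lie at most ``max_gap`` bp apart; a run of fewer than ``min_sites``
sites is dropped.  A run becomes a region spanning its first to last site
(inclusive), scored by the Stouffer combination sum(z_i)/sqrt(n).

The published segmentation used an external algorithm whose internals are
not described; gap-bounded run merging is a transparent, brute-force
checkable stand-in that is monotone in signal strength (see the methods
note).  An opposite-direction flagged site splits a run, which keeps the
hyper and hypo region tracks of one pair mutually disjoint.

A region is *consensus* differential methylation when the male-pair and
female-pair tracks contain same-direction regions that overlap; the
consensus interval is the intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .methylation import DEFAULT_ALPHA, z_critical

logger = logging.getLogger(__name__)

DEFAULT_MAX_GAP = 500
DEFAULT_MIN_SITES = 3

REGION_COLUMNS = ["chrom", "start", "end", "direction", "n_sites", "region_z", "pair"]


@dataclass(frozen=True)
class MethRegion:
    """A contiguous interval called hyper- or hypo-methylated.

    Coordinates are 0-based half-open.  ``pair`` is "male", "female" or
    "consensus".
    """

    chrom: str
    start: int
    end: int
    direction: str  # hyper | hypo
    n_sites: int
    region_z: float
    pair: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty region [{self.start}, {self.end})")
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"direction must be hyper|hypo, got {self.direction!r}")


def regions_to_frame(regions: list[MethRegion]) -> pd.DataFrame:
    """Region list as a sorted DataFrame (stable across input order)."""
    df = pd.DataFrame([vars(r) for r in regions], columns=REGION_COLUMNS)
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
        drop=True
    )


def flag_sites(contrasts: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Attach per-site significance flags (+1 hyper / -1 hypo / 0) to contrasts.

    Thresholds are inclusive: |z| >= z_crit flags the site.  The input
    must already be sorted by (chrom, pos); sorting is the importer's
    contract and violating it here is an error, not a silent fix.
    """
    pos_sorted = contrasts.groupby("chrom", sort=False)["pos"].apply(
        lambda s: bool(s.is_monotonic_increasing)
    )
    if not bool(pos_sorted.all()):
        raise ValueError("contrast table must be sorted by (chrom, pos)")
    crit = z_critical(alpha)
    z = contrasts["z"].to_numpy()
    flag = np.where(z >= crit, 1, np.where(z <= -crit, -1, 0))
    out = contrasts.copy()
    out["flag"] = flag
    logger.info(
        "flagged %d hyper, %d hypo of %d sites at alpha=%g",
        int((flag == 1).sum()), int((flag == -1).sum()), len(flag), alpha,
    )
    return out


def _runs_one_chrom(
    pos: np.ndarray, z: np.ndarray, flag: np.ndarray, max_gap: int, min_sites: int
) -> list[tuple[int, int, int, int, float]]:
    """Runs of same-direction flagged sites on one chromosome.

    Returns (start_pos, end_pos, direction, n_sites, z_sum) tuples with
    positions as given (inclusive ends).  A run ends when the next
    same-direction site is more than max_gap away or when an
    opposite-direction flagged site intervenes; unflagged sites are
    transparent.
    """
    flagged = flag != 0
    fpos = pos[flagged]
    fz = z[flagged]
    fdir = flag[flagged]
    runs = []
    i = 0
    m = len(fpos)
    while i < m:
        j = i
        while (
            j + 1 < m
            and fdir[j + 1] == fdir[i]
            and fpos[j + 1] - fpos[j] <= max_gap
        ):
            j += 1
        n = j - i + 1
        if n >= min_sites:
            runs.append((int(fpos[i]), int(fpos[j]), int(fdir[i]), n, float(fz[i : j + 1].sum())))
        i = j + 1
    return runs


def segment(
    flagged: pd.DataFrame,
    pair: str,
    max_gap: int = DEFAULT_MAX_GAP,
    min_sites: int = DEFAULT_MIN_SITES,
) -> list[MethRegion]:
    """Merge flagged sites of one pair into MethRegions.

    Input positions are 1-based (pileup convention); emitted regions are
    0-based half-open spanning the first to last contributing site.
    """
    regions: list[MethRegion] = []
    for chrom, sub in flagged.groupby("chrom", sort=True):
        runs = _runs_one_chrom(
            sub["pos"].to_numpy(),
            sub["z"].to_numpy(),
            sub["flag"].to_numpy(),
            max_gap,
            min_sites,
        )
        for start_pos, end_pos, direction, n, z_sum in runs:
            regions.append(
                MethRegion(
                    chrom=str(chrom),
                    start=start_pos - 1,
                    end=end_pos,  # 1-based inclusive end == 0-based half-open end
                    direction="hyper" if direction > 0 else "hypo",
                    n_sites=n,
                    region_z=z_sum / np.sqrt(n),
                    pair=pair,
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    logger.info("pair %s: %d regions", pair, len(regions))
    return regions


def reconcile_pairs(
    regions_male: list[MethRegion], regions_female: list[MethRegion]
) -> list[MethRegion]:
    """Intersect the two pair tracks into consensus differential methylation.

    A male and a female region produce a consensus region iff they share
    a direction and overlap by >= 1 bp; the consensus interval is the
    intersection, n_sites the smaller of the two supports, and the score
    the Stouffer combination of the two region scores.  Opposite-direction
    overlaps are discarded.
    """
    by_chrom_f: dict[str, list[MethRegion]] = {}
    for r in regions_female:
        by_chrom_f.setdefault(r.chrom, []).append(r)
    out: list[MethRegion] = []
    for rm in regions_male:
        for rf in by_chrom_f.get(rm.chrom, []):
            start = max(rm.start, rf.start)
            end = min(rm.end, rf.end)
            if start < end and rm.direction == rf.direction:
                out.append(
                    MethRegion(
                        chrom=rm.chrom,
                        start=start,
                        end=end,
                        direction=rm.direction,
                        n_sites=min(rm.n_sites, rf.n_sites),
                        region_z=(rm.region_z + rf.region_z) / np.sqrt(2.0),
                        pair="consensus",
                    )
                )
    out.sort(key=lambda r: (r.chrom, r.start, r.end))
    logger.info("consensus: %d regions", len(out))
    return out


def write_bed(regions: list[MethRegion], path) -> None:
    """Regions as BED6: name = direction, score = clamped |region_z|*100."""
    with open(path, "w") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
            score = min(1000, int(round(abs(r.region_z) * 100))) if np.isfinite(r.region_z) else 1000
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.direction}\t{score}\t.\n")


def read_bed_regions(path, pair: str = "consensus") -> list[MethRegion]:
    """Read regions back from the BED6 written by :func:`write_bed`."""
    regions = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, score, _strand = line.rstrip("\n").split("\t")[:6]
            regions.append(
                MethRegion(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    direction=name,
                    n_sites=1,
                    region_z=float(score) / 100.0,
                    pair=pair,
                )
            )
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return regions
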