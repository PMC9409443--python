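"""End-to-end orchestration: pileups -> contrasts -> regions -> report.

``run`` executes the stages in order on a validated
:class:`PipelineConfig` and writes the full artifact bundle: per-site
contrast TSV, per-pair region BEDs, consensus BED, per-gene status TSV,
element hit TSV, DE table TSV, association JSON with per-intersection
gene lists, and a run manifest recording parameters and input checksums.
The run is deterministic: identical config and inputs give byte-identical
outputs (all stages use stable sorts and fixed seeds).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import annotation as anno
from . import association as assoc
from . import expression as expr
from . import methylation as meth
from . import segmentation as seg

logger = logging.getLogger(__name__)

PAIRS = ("male", "female")


class ValidationError(ValueError):
    """Configuration or input validation failure (CLI exit code 2)."""


@dataclass
class PipelineConfig:
    """Paths, parameters and convention flags for one pipeline run.

    ``pileups`` maps the four track labels (ctrl_male, as_male,
    ctrl_female, as_female) to cytosine-report paths.  Exactly one of
    ``counts`` (gene x sample matrix; needs ctrl/case sample names) or
    ``de_table`` (externally computed DE results) supplies expression.
    """

    pileups: dict = field(default_factory=dict)
    annotation: str = ""
    counts: str | None = None
    ctrl_samples: list = field(default_factory=lambda: ["ctrl_1", "ctrl_2"])
    case_samples: list = field(default_factory=lambda: ["as_1", "as_2"])
    de_table: str | None = None
    outdir: str = "dmrlink_out"

    min_coverage: int = meth.DEFAULT_MIN_COVERAGE
    alpha: float = meth.DEFAULT_ALPHA
    ci_level: float = meth.DEFAULT_CI_LEVEL
    max_gap: int = seg.DEFAULT_MAX_GAP
    min_sites: int = seg.DEFAULT_MIN_SITES
    flank: int = anno.DEFAULT_FLANK
    dispersion: float = expr.DEFAULT_DISPERSION
    logfc_base: float = 2.0
    call_convention: str = "printed"
    annotation_dialect: str = "auto"
    seed: int = 0

    def validate(self) -> None:
        expected = {"ctrl_male", "as_male", "ctrl_female", "as_female"}
        if set(self.pileups) != expected:
            missing = expected - set(self.pileups)
            raise ValidationError(
                f"pileups must name exactly {sorted(expected)}; missing {sorted(missing)}"
            )
        for label, path in self.pileups.items():
            if not Path(path).is_file():
                raise ValidationError(f"pileup {label}: no such file {path}")
        if not Path(self.annotation).is_file():
            raise ValidationError(f"annotation: no such file {self.annotation}")
        if (self.counts is None) == (self.de_table is None):
            raise ValidationError("exactly one of counts / de_table must be set")
        for p in (self.counts, self.de_table):
            if p is not None and not Path(p).is_file():
                raise ValidationError(f"expression input: no such file {p}")
        if self.min_coverage < 1:
            raise ValidationError("min_coverage must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0,1)")
        if not (0 < self.ci_level < 1):
            raise ValidationError("ci_level must be in (0,1)")
        if self.max_gap < 0 or self.min_sites < 1 or self.flank < 0:
            raise ValidationError("max_gap >= 0, min_sites >= 1, flank >= 0 required")
        if self.call_convention not in ("printed", "standard"):
            raise ValidationError(f"unknown call convention {self.call_convention!r}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: PipelineConfig) -> dict:
    """Execute all stages; returns {"report": AssociationReport, "paths": ...}.

    Any stage failure is re-raised annotated with the stage name.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "call-sites"
    try:
        contrasts = {}
        for pair in PAIRS:
            ctrl = meth.read_cytosine_report(
                config.pileups[f"ctrl_{pair}"], convention=config.call_convention
            )
            case = meth.read_cytosine_report(
                config.pileups[f"as_{pair}"], convention=config.call_convention
            )
            contrasts[pair] = meth.contrast_table(
                ctrl, case, pair=pair,
                min_coverage=config.min_coverage, level=config.ci_level,
            )
        all_sites = pd.concat(contrasts.values(), ignore_index=True)
        sites_path = outdir / "site_contrasts.tsv"
        all_sites.to_csv(sites_path, sep="\t", index=False, float_format="%.6g")

        stage = "segment"
        regions = {}
        for pair in PAIRS:
            flagged = seg.flag_sites(contrasts[pair], alpha=config.alpha)
            regions[pair] = seg.segment(
                flagged, pair=pair, max_gap=config.max_gap, min_sites=config.min_sites
            )
            seg.write_bed(regions[pair], outdir / f"regions_{pair}.bed")
        consensus = seg.reconcile_pairs(regions["male"], regions["female"])
        consensus_path = outdir / "regions_consensus.bed"
        seg.write_bed(consensus, consensus_path)

        stage = "annotate"
        genes = anno.load_annotation(
            config.annotation, flank=config.flank, dialect=config.annotation_dialect
        )
        hits = anno.assign_regions(consensus, genes)
        statuses = anno.status_frame(anno.classify_genes(hits, genes))
        hits.to_csv(outdir / "element_hits.tsv", sep="\t", index=False)
        statuses.to_csv(outdir / "gene_status.tsv", sep="\t", index=False)

        stage = "de"
        if config.counts is not None:
            counts = pd.read_csv(config.counts, sep="\t")
            de_table = expr.de_test(
                counts, list(config.ctrl_samples), list(config.case_samples),
                dispersion=config.dispersion,
            )
        else:
            de_table = expr.import_de_table(config.de_table, logfc_base=config.logfc_base)
        de_path = outdir / "de_table.tsv"
        de_table.to_csv(de_path, sep="\t", index=False, float_format="%.6g")

        stage = "associate"
        report = assoc.cross(statuses, de_table, hits=hits)
        report.to_json(outdir / "association.json")
        assoc.write_gene_lists(report, outdir / "gene_lists")
    except Exception as exc:
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "parameters": asdict(config),
        "input_sha256": {
            **{k: _sha256(v) for k, v in config.pileups.items()},
            "annotation": _sha256(config.annotation),
            "expression": _sha256(config.counts or config.de_table),
        },
        "stage_counts": {
            "sites": int(len(all_sites)),
            "regions_male": len(regions["male"]),
            "regions_female": len(regions["female"]),
            "consensus": len(consensus),
            "hits": int(len(hits)),
            "genes": len(genes),
        },
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "report": report,
        "consensus": consensus,
        "regions": regions,
        "statuses": statuses,
        "de_table": de_table,
        "manifest": manifest,
        "outdir": outdir,
    }
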