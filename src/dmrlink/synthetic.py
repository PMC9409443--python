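"""Synthetic whole-genome bisulfite counts and expression with planted truth.

The generator emulates the data model the pipeline consumes: four
per-cytosine count tracks (a control and a case sample in each of two
sex-matched pairs), a gene annotation, and a small gene x sample count
matrix.  Per-site baseline methylation frequencies are Beta-distributed
and shared by all four samples; inside planted differentially methylated
elements the case samples' frequencies are shifted by +/- effect_delta
on the logit scale (so shifted values stay inside (0,1) without
clamping), with the same direction in both pairs by construction.
Coverage is Poisson per site and sample, methylated counts binomial.
Expression counts are negative binomial with planted fold changes;
promoter-hypomethylated genes can be coupled to up-regulation with a
configurable probability.

Reproducibility: every track draws from its own RNG stream seeded by
(master seed, stream index), so the same seed gives bit-identical output
and adding samples would not reshuffle existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

TRACK_NAMES = ("ctrl_male", "as_male", "ctrl_female", "as_female")
SAMPLE_NAMES = ("ctrl_1", "ctrl_2", "as_1", "as_2")

# fixed stream indices: 0-3 methylation tracks, then auxiliary streams
_STREAM_BASELINE = 100
_STREAM_GENOME = 101
_STREAM_TRUTH = 102
_STREAM_EXPR = 200


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of the synthetic world.

    Defaults aim at a small but realistic slice of a mammalian
    methylome: ~10 CpG-like sites per kb, 30x coverage, mid-range
    baseline methylation (Beta(2,2)), a logit effect of 2 in planted
    elements, and negative-binomial expression with dispersion 0.1.
    frac_up / frac_down plant expression changes independent of
    methylation; coupling_prob additionally up-regulates
    promoter-hypomethylated genes.
    """

    n_chromosomes: int = 2
    chrom_length: int = 2_000_000
    site_density: float = 10.0  # expected sites per kb
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (2_000, 10_000)
    promoter_flank: int = 1000
    coverage_mean: float = 30.0
    baseline_meth_alpha: float = 2.0
    baseline_meth_beta: float = 2.0
    effect_delta: float = 2.0  # logit shift in planted elements
    frac_hyper: float = 0.05
    frac_hypo: float = 0.20
    frac_up: float = 0.05
    frac_down: float = 0.05
    expr_mean_log_range: tuple[float, float] = (1.0, 3.0)  # log10 of NB mean
    expr_dispersion: float = 0.1
    planted_fc: float = 4.0
    coupling_prob: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_hyper": self.frac_hyper,
            "frac_hypo": self.frac_hypo,
            "frac_up": self.frac_up,
            "frac_down": self.frac_down,
            "coupling_prob": self.coupling_prob,
        }
        for name, val in fracs.items():
            if not (0.0 <= val <= 1.0):
                raise ConfigError(f"{name} must be in [0,1], got {val}")
        if self.frac_hyper + self.frac_hypo > 1.0:
            raise ConfigError("frac_hyper + frac_hypo exceeds 1")
        if self.coverage_mean <= 0:
            raise ConfigError(f"coverage_mean must be > 0, got {self.coverage_mean}")
        if self.effect_delta < 0:
            raise ConfigError(f"effect_delta must be >= 0, got {self.effect_delta}")
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ConfigError("need >= 1 chromosome of positive length")
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ConfigError(f"bad gene_length_range {self.gene_length_range}")
        if self.site_density <= 0:
            raise ConfigError("site_density must be > 0")
        if self.expr_dispersion <= 0:
            raise ConfigError("expr_dispersion must be > 0")
        if self.planted_fc <= 0:
            raise ConfigError("planted_fc must be > 0")
        if self.baseline_meth_alpha <= 0 or self.baseline_meth_beta <= 0:
            raise ConfigError("Beta shape parameters must be > 0")

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["gene_length_range"] = list(data["gene_length_range"])
        data["expr_mean_log_range"] = list(data["expr_mean_log_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("gene_length_range", "expr_mean_log_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class TruthTable:
    """Planted ground truth.

    ``elements``: one row per planted DM element (gene_id, kind
    promoter|body, direction hyper|hypo, chrom, start, end; 0-based
    half-open).  ``genes``: per-gene true DE class and fold change.
    """

    elements: pd.DataFrame
    genes: pd.DataFrame

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.elements.to_csv(outdir / "truth_elements.tsv", sep="\t", index=False)
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)


ELEMENT_COLUMNS = ["gene_id", "kind", "direction", "chrom", "start", "end"]
GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tss"]


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> tuple[dict, pd.DataFrame]:
    """Site map and gene annotation.

    Returns (sites, genes): ``sites`` maps chromosome name to a strictly
    increasing array of 1-based positions (a Poisson process at
    site_density per kb); ``genes`` has 0-based half-open intervals,
    strand and strand-aware TSS, placed non-overlapping with a
    promoter-sized margin.
    """
    config.validate()
    rng = config._rng(_STREAM_GENOME)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]

    sites: dict[str, np.ndarray] = {}
    for chrom in chroms:
        n_sites = rng.poisson(config.site_density * config.chrom_length / 1000.0)
        pos = np.unique(rng.integers(1, config.chrom_length + 1, size=n_sites))
        sites[chrom] = pos

    rows = []
    if config.n_genes > 0:
        per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
        per_chrom[: config.n_genes % config.n_chromosomes] += 1
        lo, hi = config.gene_length_range
        margin = config.promoter_flank + 1
        gi = 0
        for chrom, n_c in zip(chroms, per_chrom):
            if n_c == 0:
                continue
            slot = config.chrom_length // n_c
            if slot < hi + 2 * margin:
                raise ConfigError(
                    f"{chrom} too short for {n_c} genes of up to {hi} bp "
                    f"plus {margin} bp margins (slot {slot} bp)"
                )
            for s in range(n_c):
                length = int(rng.integers(lo, hi + 1))
                lo_start = s * slot + margin
                hi_start = (s + 1) * slot - margin - length
                start = int(rng.integers(lo_start, hi_start + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                end = start + length
                tss = start if strand == "+" else end - 1
                rows.append((f"gene_{gi:05d}", chrom, start, end, strand, tss))
                gi += 1
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    return sites, genes


# ---------------------------------------------------------------------------
# truth plan
# ---------------------------------------------------------------------------

def plan_truth(genes: pd.DataFrame, config: SimConfig) -> TruthTable:
    """Choose planted DM elements and true DE classes.

    With effect_delta == 0 no DM elements exist (null world).  Planted
    genes receive one element each, promoter window or gene body with
    equal probability; hyper and hypo gene sets are disjoint.  DE truth:
    promoter-hypo genes are up-regulated with probability coupling_prob;
    additional up/down genes are drawn independently at frac_up /
    frac_down with fold changes planted_fc and 1/planted_fc.
    """
    config.validate()
    rng = config._rng(_STREAM_TRUTH)
    n = len(genes)
    flank = config.promoter_flank

    el_rows = []
    dm_direction: dict[str, tuple[str, str]] = {}  # gene_id -> (kind, direction)
    if n > 0 and config.effect_delta > 0:
        n_hyper = int(round(config.frac_hyper * n))
        n_hypo = int(round(config.frac_hypo * n))
        order = rng.permutation(n)
        chosen = {
            "hyper": order[:n_hyper],
            "hypo": order[n_hyper : n_hyper + n_hypo],
        }
        for direction, idx in chosen.items():
            for i in sorted(idx):
                g = genes.iloc[i]
                kind = "promoter" if rng.random() < 0.5 else "body"
                if kind == "promoter":
                    start = max(0, g.tss - flank)
                    end = g.tss + flank + 1
                else:
                    start, end = int(g.start), int(g.end)
                el_rows.append((g.gene_id, kind, direction, g.chrom, start, end))
                dm_direction[g.gene_id] = (kind, direction)
    elements = pd.DataFrame(el_rows, columns=ELEMENT_COLUMNS)

    de_class = {}
    fc = {}
    promoter_hypo = [
        gid for gid, (kind, d) in dm_direction.items() if kind == "promoter" and d == "hypo"
    ]
    # coupling draws first so they are stable under frac_up/frac_down changes
    for gid in promoter_hypo:
        if rng.random() < config.coupling_prob:
            de_class[gid] = "up"
            fc[gid] = config.planted_fc
    free = [gid for gid in genes["gene_id"] if gid not in de_class]
    n_up = int(round(config.frac_up * n))
    n_down = int(round(config.frac_down * n))
    picked = rng.permutation(len(free))
    if config.planted_fc != 1.0:
        for j in picked[:n_up]:
            de_class[free[j]] = "up"
            fc[free[j]] = config.planted_fc
        for j in picked[n_up : n_up + n_down]:
            de_class[free[j]] = "down"
            fc[free[j]] = 1.0 / config.planted_fc
    if config.planted_fc == 1.0:
        de_class = {}
        fc = {}

    truth_genes = genes[["gene_id"]].copy()
    truth_genes["de_class"] = [de_class.get(g, "ns") for g in truth_genes["gene_id"]]
    truth_genes["fold_change"] = [fc.get(g, 1.0) for g in truth_genes["gene_id"]]
    return TruthTable(elements=elements, genes=truth_genes)


# ---------------------------------------------------------------------------
# methylation tracks
# ---------------------------------------------------------------------------

def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_methylation(
    sites: dict, truth: TruthTable, config: SimConfig
) -> dict[str, pd.DataFrame]:
    """Four cytosine-count tracks keyed by TRACK_NAMES.

    Baseline per-site frequencies are Beta(alpha, beta), shared by all
    samples; case samples get a +/- effect_delta logit shift inside
    planted elements (hyper: +, hypo: -), identically in both pairs.
    Coverage is Poisson(coverage_mean) independently per site and
    sample; zero-coverage sites are emitted, not dropped.
    """
    config.validate()
    base_rng = config._rng(_STREAM_BASELINE)

    chroms = sorted(sites.keys())
    baseline = {}
    strands = {}
    for chrom in chroms:
        m = len(sites[chrom])
        baseline[chrom] = base_rng.beta(
            config.baseline_meth_alpha, config.baseline_meth_beta, size=m
        )
        strands[chrom] = np.where(base_rng.random(m) < 0.5, "+", "-")

    # per-chromosome logit shift applied to the case samples
    shift = {chrom: np.zeros(len(sites[chrom])) for chrom in chroms}
    for el in truth.elements.itertuples(index=False):
        pos = sites.get(el.chrom)
        if pos is None:
            continue
        # element coords are 0-based half-open; site positions 1-based
        inside = (pos >= el.start + 1) & (pos <= el.end)
        sgn = 1.0 if el.direction == "hyper" else -1.0
        shift[el.chrom][inside] = sgn * config.effect_delta

    tracks: dict[str, pd.DataFrame] = {}
    for track_idx, name in enumerate(TRACK_NAMES):
        rng = config._rng(track_idx)
        is_case = name.startswith("as_")
        frames = []
        for chrom in chroms:
            pos = sites[chrom]
            f = baseline[chrom]
            if is_case:
                f = _expit(_logit(np.clip(f, 1e-12, 1 - 1e-12)) + shift[chrom])
            cov = rng.poisson(config.coverage_mean, size=len(pos))
            k = rng.binomial(cov, f)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "strand": strands[chrom],
                        "count_methylated": k,
                        "count_total": cov,
                    }
                )
            )
        tracks[name] = pd.concat(frames, ignore_index=True)
    return tracks


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def simulate_expression(
    genes: pd.DataFrame, truth: TruthTable, config: SimConfig
) -> pd.DataFrame:
    """Gene x sample NB count matrix (2 control + 2 case columns).

    Per-gene base means are log-uniform over 10**expr_mean_log_range;
    case-sample means are base mean times the gene's true fold change.
    Counts ~ NB(mean, dispersion) with var = mu + dispersion * mu^2.
    """
    config.validate()
    if len(genes) == 0:
        raise ValueError("annotation is empty; nothing to simulate")
    rng = config._rng(_STREAM_EXPR)
    n = len(genes)
    lo, hi = config.expr_mean_log_range
    base_mean = 10.0 ** rng.uniform(lo, hi, size=n)
    fc = truth.genes.set_index("gene_id")["fold_change"].reindex(genes["gene_id"]).to_numpy()

    r = 1.0 / config.expr_dispersion
    out = {"gene_id": genes["gene_id"].to_numpy()}
    for sample in SAMPLE_NAMES:
        mu = base_mean * (fc if sample.startswith("as_") else 1.0)
        p = r / (r + mu)
        out[sample] = rng.negative_binomial(r, p)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# one-call bundle and writers
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """Everything one simulation run produces."""

    config: SimConfig
    sites: dict
    genes: pd.DataFrame
    truth: TruthTable
    tracks: dict
    counts: pd.DataFrame = field(default=None)


def simulate(config: SimConfig) -> SimResult:
    """Run genome, truth, methylation and expression generation."""
    sites, genes = simulate_genome(config)
    truth = plan_truth(genes, config)
    tracks = simulate_methylation(sites, truth, config)
    counts = simulate_expression(genes, truth, config) if len(genes) else None
    return SimResult(
        config=config, sites=sites, genes=genes, truth=truth, tracks=tracks, counts=counts
    )


def write_cytosine_report(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", header=False, index=False)


def write_gff3(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples(index=False):
            # internal 0-based half-open -> GFF3 1-based inclusive
            fh.write(
                f"{g.chrom}\tdmrlink_sim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_bed6(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for g in genes.itertuples(index=False):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def write_all(result: SimResult, outdir) -> dict:
    """Write every artifact; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, track in result.tracks.items():
        p = outdir / f"{name}.cytosine.tsv"
        write_cytosine_report(track, p)
        paths[name] = p
    write_gff3(result.genes, outdir / "genes.gff3")
    write_bed6(result.genes, outdir / "genes.bed")
    paths["gff3"] = outdir / "genes.gff3"
    paths["bed"] = outdir / "genes.bed"
    if result.counts is not None:
        write_counts(result.counts, outdir / "expression_counts.tsv")
        paths["counts"] = outdir / "expression_counts.tsv"
    result.truth.write(outdir)
    paths["truth_elements"] = outdir / "truth_elements.tsv"
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    result.config.to_yaml(outdir / "sim_config.yaml")
    paths["config"] = outdir / "sim_config.yaml"
    return paths
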