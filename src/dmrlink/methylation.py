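"""Per-site methylation statistics for a two-sample (case vs control) contrast.

The per-site procedure, applied independently within each sex-matched pair:

1. The methylation frequency at a cytosine is ``f = k/n`` where ``k`` is the
   number of methylated-call reads and ``n`` the total coverage.
2. A 95% confidence interval for ``f`` from the likelihood-ratio (Wilks)
   condition for the binomial: ``{p : 2[l(f) - l(p)] <= chi2_1(0.95)}``.
3. Frequencies and CI margins are mapped through ``v = ln((1+f)/(1-f))``,
   a quasi-normalising transform (monotone, v(0)=0).  Note this is the
   doubled form of the classical arctanh transform.
4. ``sd(v)`` is taken as one sixth of the transformed CI length.
5. A two-observation least-squares fit ``Y = b0 + b1*group`` with group
   coded -1 (control) / +1 (case) gives ``b1 = (v_case - v_ctrl)/2`` and,
   by independence of the two observations,
   ``sd(b1) = sqrt(sd_ctrl^2 + sd_case^2)/2``.  The per-site score is
   ``z = b1/sd(b1)``; positive z means hyper-methylated in the case group.

With exactly two observations the fit is exact (zero residual), so the
closed forms above coincide with the generic ``(X'X)^-1 X'Y`` solution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

logger = logging.getLogger(__name__)

#: default minimum per-sample coverage for a site to enter the contrast
DEFAULT_MIN_COVERAGE = 5
#: default two-sided significance level for per-site flags
DEFAULT_ALPHA = 0.05
#: default confidence level of the per-site binomial CI
DEFAULT_CI_LEVEL = 0.95

_BISECT_TOL = 1e-8


class NoCoverageError(ValueError):
    """Raised when a frequency is requested for a site with zero coverage."""


@dataclass(frozen=True)
class SitePileup:
    """Observed counts for one cytosine in one sample.

    ``k`` counts the reads supporting a methylated call (on the + strand
    these are C>T variant alignments, on the - strand A>G, following the
    upstream caller's convention); ``n`` is total coverage.
    """

    chrom: str
    pos: int  # 1-based
    strand: str
    k: int
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n):
            raise ValueError(f"require 0 <= k <= n, got k={self.k}, n={self.n}")
        if self.pos < 1:
            raise ValueError(f"positions are 1-based, got pos={self.pos}")


@dataclass(frozen=True)
class SiteMethylation:
    """Per-site estimate: frequency, CI, transformed value and its SD."""

    f: float
    ci_lo: float
    ci_hi: float
    v: float
    sd_v: float


@dataclass(frozen=True)
class PairContrast:
    """Least-squares contrast of one site between control and case.

    ``direction`` is "hyper" for b1 > 0 (case more methylated), "hypo" for
    b1 < 0, None when b1 == 0.  ``degenerate`` marks sd_b1 == 0 with
    b1 != 0; such sites carry an infinite z of the sign of b1 and are
    treated as significant downstream.
    """

    b0: float
    b1: float
    sd_b1: float
    z: float
    direction: str | None
    degenerate: bool = False


# ---------------------------------------------------------------------------
# frequency and confidence interval
# ---------------------------------------------------------------------------

def site_frequency(site: SitePileup) -> float:
    """Methylated read fraction k/n; raises for uncovered sites."""
    if site.n == 0:
        raise NoCoverageError(
            f"site {site.chrom}:{site.pos} has zero coverage; filter before estimating"
        )
    return site.k / site.n


def _binom_loglik(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    # 0*log(0) := 0 at the boundaries
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(k > 0, k * np.log(p), 0.0)
        t2 = np.where(n - k > 0, (n - k) * np.log1p(-p), 0.0)
    return t1 + t2


def wilks_ci_arrays(
    k: np.ndarray, n: np.ndarray, level: float = DEFAULT_CI_LEVEL
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised likelihood-ratio CI for binomial proportions.

    Solves ``2[l(k/n) - l(p)] = chi2_1(level)`` by bisection on each side
    of the MLE; the boundary MLEs k=0 and k=n pin lo=0 and hi=1 exactly.
    """
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("wilks_ci requires n >= 1")
    if np.any((k < 0) | (k > n)):
        raise ValueError("wilks_ci requires 0 <= k <= n")
    crit = chi2.ppf(level, df=1)
    fhat = k / n
    llmax = _binom_loglik(k, n, fhat)

    def boundary(lo: np.ndarray, hi: np.ndarray, lower_side: bool) -> np.ndarray:
        lo = lo.astype(float).copy()
        hi = hi.astype(float).copy()
        # ~50 halvings reach 1e-8 swiftly on [0,1]
        while np.max(hi - lo) > _BISECT_TOL:
            mid = 0.5 * (lo + hi)
            inside = 2.0 * (llmax - _binom_loglik(k, n, mid)) <= crit
            if lower_side:
                hi = np.where(inside, mid, hi)
                lo = np.where(inside, lo, mid)
            else:
                lo = np.where(inside, mid, lo)
                hi = np.where(inside, hi, mid)
        return 0.5 * (lo + hi)

    lo = np.where(k == 0, 0.0, boundary(np.zeros_like(fhat), fhat, lower_side=True))
    hi = np.where(k == n, 1.0, boundary(fhat, np.ones_like(fhat), lower_side=False))
    return lo, hi


def wilks_ci(k: int, n: int, level: float = DEFAULT_CI_LEVEL) -> tuple[float, float]:
    """Likelihood-ratio (Wilks) confidence interval for a single site."""
    lo, hi = wilks_ci_arrays(np.array([k]), np.array([n]), level=level)
    return float(lo[0]), float(hi[0])


# ---------------------------------------------------------------------------
# transform and SD rule
# ---------------------------------------------------------------------------

def clamp_frequency(f, n):
    """Clamp f into [0, 1 - 1/(2n)] so the transform stays finite.

    The cap scales with the site's own coverage: a fully methylated site
    at coverage n is treated as f = 1 - 1/(2n), half a read short of
    saturation, which keeps the transformed value finite and monotone
    in k at fixed n.
    """
    f = np.asarray(f, dtype=float)
    n = np.asarray(n, dtype=float)
    cap = 1.0 - 1.0 / (2.0 * np.maximum(n, 1.0))
    return np.clip(f, 0.0, cap)


def transform(f):
    """v = ln((1+f)/(1-f)); odd, strictly increasing, v(0) = 0.

    Callers must clamp f below 1 first (see :func:`clamp_frequency`);
    f == 1 maps to +inf.
    """
    f = np.asarray(f, dtype=float)
    with np.errstate(divide="ignore"):
        v = np.log1p(f) - np.log1p(-f)
    return v if v.ndim else float(v)


def transform_sd(ci_lo, ci_hi, n=None):
    """SD of the transformed value: one sixth of the transformed CI length.

    If ``n`` is given the margins are coverage-clamped before transforming.
    """
    lo = np.asarray(ci_lo, dtype=float)
    hi = np.asarray(ci_hi, dtype=float)
    if np.any(lo > hi):
        raise ValueError("require ci_lo <= ci_hi")
    if n is not None:
        lo = clamp_frequency(lo, n)
        hi = clamp_frequency(hi, n)
    sd = (transform(hi) - transform(lo)) / 6.0
    return sd if np.ndim(sd) else float(sd)


def site_methylation(
    site: SitePileup, level: float = DEFAULT_CI_LEVEL
) -> SiteMethylation:
    """Full per-site estimate (frequency, CI, transform, SD) for one sample."""
    f = site_frequency(site)
    lo, hi = wilks_ci(site.k, site.n, level=level)
    v = transform(clamp_frequency(f, site.n))
    sd_v = transform_sd(lo, hi, n=site.n)
    return SiteMethylation(f=f, ci_lo=lo, ci_hi=hi, v=float(v), sd_v=float(sd_v))


# ---------------------------------------------------------------------------
# two-observation least-squares contrast
# ---------------------------------------------------------------------------

def pair_contrast(ctrl: SiteMethylation, case: SiteMethylation) -> PairContrast:
    """Contrast one site between control and case within a pair.

    Closed form of the exact 2-observation least-squares fit with design
    X = [[1,-1],[1,+1]]: b0 is the mean of the two transformed values, b1
    half their difference.  Swapping the arguments negates b1 and z.
    """
    b0 = 0.5 * (ctrl.v + case.v)
    b1 = 0.5 * (case.v - ctrl.v)
    sd_b1 = 0.5 * float(np.hypot(ctrl.sd_v, case.sd_v))
    degenerate = False
    if sd_b1 > 0.0:
        z = b1 / sd_b1
    elif b1 == 0.0:
        z = 0.0
    else:
        z = float(np.sign(b1)) * float("inf")
        degenerate = True
    direction = "hyper" if b1 > 0 else ("hypo" if b1 < 0 else None)
    return PairContrast(
        b0=b0, b1=b1, sd_b1=sd_b1, z=z, direction=direction, degenerate=degenerate
    )


def contrast_table(
    ctrl: pd.DataFrame,
    case: pd.DataFrame,
    pair: str,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    level: float = DEFAULT_CI_LEVEL,
) -> pd.DataFrame:
    """Vectorised per-site contrast of two pileup tables from one pair.

    Inputs are cytosine-report frames (chrom, pos, strand,
    count_methylated, count_total).  Sites are matched on (chrom, pos,
    strand); only sites with coverage >= min_coverage in *both* samples
    enter.  Returns a frame sorted by (chrom, pos) with columns
    chrom, pos, strand, f_ctrl, f_as, v_ctrl, v_as, b1, sd_b1, z, pair.
    """
    key = ["chrom", "pos", "strand"]
    merged = ctrl.merge(case, on=key, suffixes=("_ctrl", "_as"))
    n_in = len(merged)
    keep = (merged["count_total_ctrl"] >= min_coverage) & (
        merged["count_total_as"] >= min_coverage
    )
    merged = merged.loc[keep].reset_index(drop=True)
    logger.info(
        "pair %s: %d matched sites, %d pass coverage >= %d",
        pair, n_in, len(merged), min_coverage,
    )

    out = merged[key].copy()
    for grp in ("ctrl", "as"):
        k = merged[f"count_methylated_{grp}"].to_numpy(dtype=float)
        n = merged[f"count_total_{grp}"].to_numpy(dtype=float)
        f = np.divide(k, n, out=np.zeros_like(k), where=n > 0)
        lo, hi = wilks_ci_arrays(k, n, level=level)
        v = transform(clamp_frequency(f, n))
        sd_v = (transform(clamp_frequency(hi, n)) - transform(clamp_frequency(lo, n))) / 6.0
        out[f"f_{grp}"] = f
        out[f"v_{grp}"] = v
        out[f"sd_{grp}"] = sd_v

    b1 = 0.5 * (out["v_as"] - out["v_ctrl"]).to_numpy()
    sd_b1 = 0.5 * np.hypot(out["sd_ctrl"].to_numpy(), out["sd_as"].to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(
            sd_b1 > 0,
            b1 / np.where(sd_b1 > 0, sd_b1, 1.0),
            np.where(b1 == 0, 0.0, np.sign(b1) * np.inf),
        )
    out["b1"] = b1
    out["sd_b1"] = sd_b1
    out["z"] = z
    out["pair"] = pair
    out = out.drop(columns=["sd_ctrl", "sd_as"])
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def z_critical(alpha: float = DEFAULT_ALPHA) -> float:
    """Two-sided normal critical value, e.g. 1.959964 at alpha = 0.05."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    return float(norm.ppf(1.0 - alpha / 2.0))


# ---------------------------------------------------------------------------
# cytosine-report import
# ---------------------------------------------------------------------------

_REPORT_COLS = ["chrom", "pos", "strand", "count_methylated", "count_total"]

Convention = Literal["printed", "standard"]


def read_cytosine_report(
    path,
    dialect: Literal["auto", "simple", "bismark"] = "auto",
    convention: Convention = "printed",
) -> pd.DataFrame:
    """Read a per-cytosine count table into the (k, n) pileup frame.

    Two dialects:

    * ``simple`` — 5 columns: chrom, 1-based pos, strand, methylated
      count, total coverage (the format this package writes).
    * ``bismark`` — a CpG-report style table with separate methylated /
      unmethylated counts (chrom, pos, strand, count_meth, count_unmeth,
      [context...]); total = meth + unmeth.

    ``convention`` records which reads count as "methylated".  Under
    "printed" the converted-read count (C>T on +, A>G on -) is used as k,
    matching the upstream formula as stated; under "standard" k is the
    unconverted (truly methylated) count.  For the ``simple`` dialect the
    file is already (k, n) and the flag is metadata only; for ``bismark``
    it selects which count column becomes k.  The chosen convention is
    stored in ``frame.attrs["convention"]``.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    ncol = df.shape[1]
    if dialect == "auto":
        dialect = "simple" if ncol == 5 else "bismark"
    if dialect == "simple":
        if ncol != 5:
            raise ValueError(f"simple cytosine report needs 5 columns, found {ncol}")
        df.columns = _REPORT_COLS
    elif dialect == "bismark":
        if ncol < 5:
            raise ValueError(f"bismark-style report needs >= 5 columns, found {ncol}")
        meth = df.iloc[:, 3].astype(int)
        unmeth = df.iloc[:, 4].astype(int)
        k = unmeth if convention == "printed" else meth
        df = pd.DataFrame(
            {
                "chrom": df.iloc[:, 0],
                "pos": df.iloc[:, 1].astype(int),
                "strand": df.iloc[:, 2],
                "count_methylated": k,
                "count_total": meth + unmeth,
            }
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df["pos"] = df["pos"].astype(int)
    df["count_methylated"] = df["count_methylated"].astype(int)
    df["count_total"] = df["count_total"].astype(int)
    bad = (df["count_methylated"] < 0) | (df["count_methylated"] > df["count_total"])
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"methylated count exceeds coverage at data row {i}")
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    df.attrs["convention"] = convention
    return df
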