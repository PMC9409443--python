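"""Differential expression classes at fixed fold-change and p thresholds.

A gene is called *up* when p < 0.005 and linear fold change > 1.5, *down*
when p < 0.005 and fold change < 0.6, otherwise *ns*; all comparisons are
strict.  Fold change is (mean normalized case + 0.5)/(mean normalized
control + 0.5); the 0.5 pseudocount keeps genes expressed in only one
group finite, and such genes are additionally flagged exclusive_as /
exclusive_ctrl.

Two routes produce the (fold change, p) table:

* an imported table from an external DE tool (header-mapped; logFC
  columns are exponentiated, base configurable), or
* a built-in stand-in test on the count matrix: a two-sided normal score
  test of the group-mean difference of per-million-normalized counts
  under a negative-binomial variance model var = mu + dispersion*mu^2
  evaluated at the pooled null mean.  This is intentionally simple and
  documented as a stand-in, not a reimplementation of any published DE
  method.

Benjamini-Hochberg q-values are reported as an extra column but play no
role in classification (the thresholds above use the raw p).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

P_THRESHOLD = 0.005
FC_UP = 1.5
FC_DOWN = 0.6
PSEUDOCOUNT = 0.5
DEFAULT_DISPERSION = 0.1

DE_COLUMNS = ["gene_id", "fold_change", "p_value", "q_value", "de_class", "exclusivity"]


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample column to sum to one million (CPM).

    ``counts`` is genes x samples with a gene_id index or column.  An
    all-zero sample column is an error naming the sample.
    """
    mat = counts.set_index("gene_id") if "gene_id" in counts.columns else counts.copy()
    if mat.shape[0] < 1:
        raise ValueError("count matrix has no genes")
    sums = mat.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total counts")
    return mat * (1e6 / sums)


def _classify_row(fc: float, p: float) -> str:
    if p < P_THRESHOLD and fc > FC_UP:
        return "up"
    if p < P_THRESHOLD and fc < FC_DOWN:
        return "down"
    return "ns"


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(p, method="bh")


def de_test(
    counts: pd.DataFrame,
    ctrl_samples: list[str],
    case_samples: list[str],
    dispersion: float = DEFAULT_DISPERSION,
) -> pd.DataFrame:
    """Built-in stand-in DE test on a gene x sample count matrix.

    Requires at least two samples per group (with one the score test has
    no footing; import an external DE table instead).  Returns the DE
    table with fold_change, p_value, q_value, de_class and exclusivity.
    """
    if len(ctrl_samples) < 2 or len(case_samples) < 2:
        raise ValueError(
            "built-in test needs >= 2 samples per group; "
            "use import_de_table() for externally computed results"
        )
    if dispersion <= 0:
        raise ValueError(f"dispersion must be > 0, got {dispersion}")
    norm = normalize(counts)
    missing = [s for s in (*ctrl_samples, *case_samples) if s not in norm.columns]
    if missing:
        raise ValueError(f"samples not in count matrix: {missing}")

    m_ctrl = norm[ctrl_samples].mean(axis=1).to_numpy()
    m_case = norm[case_samples].mean(axis=1).to_numpy()
    n1, n2 = len(ctrl_samples), len(case_samples)
    mu0 = (m_ctrl * n1 + m_case * n2) / (n1 + n2)
    var0 = mu0 + dispersion * mu0**2
    se = np.sqrt(var0 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        zscore = np.where(se > 0, (m_case - m_ctrl) / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(zscore))
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    fc = (m_case + PSEUDOCOUNT) / (m_ctrl + PSEUDOCOUNT)
    exclusivity = np.where(
        (m_ctrl == 0) & (m_case > 0),
        "exclusive_as",
        np.where((m_case == 0) & (m_ctrl > 0), "exclusive_ctrl", ""),
    )
    out = pd.DataFrame(
        {
            "gene_id": norm.index,
            "fold_change": fc,
            "p_value": p,
            "q_value": _bh_qvalues(p),
            "exclusivity": exclusivity,
        }
    )
    out["de_class"] = [_classify_row(f, pv) for f, pv in zip(out["fold_change"], out["p_value"])]
    out = out[DE_COLUMNS].sort_values("gene_id", kind="mergesort").reset_index(drop=True)
    logger.info(
        "DE stand-in test: %d genes, %d up, %d down",
        len(out), int((out["de_class"] == "up").sum()), int((out["de_class"] == "down").sum()),
    )
    return out


_GENE_ALIASES = ("gene_id", "gene", "genes", "id", "symbol")
_FC_ALIASES = ("fold_change", "fc", "foldchange")
_LOGFC_ALIASES = ("logfc", "log_fc", "log2fc", "log2foldchange")
_P_ALIASES = ("p_value", "pvalue", "p", "pval", "p.value")


def import_de_table(table, logfc_base: float = 2.0) -> pd.DataFrame:
    """Adapt an externally computed DE table to the internal DE frame.

    ``table`` is a path to a TSV or an existing DataFrame.  The gene, p
    and fold-change columns are found case-insensitively among common
    header names; a logFC column (if no linear FC column exists) is
    exponentiated with ``logfc_base`` (2 for most DE tools, e for
    natural-log output).  Classification applies the same strict
    thresholds as the built-in test.
    """
    df = pd.read_csv(table, sep="\t") if not isinstance(table, pd.DataFrame) else table.copy()
    cols = {c.lower().strip(): c for c in df.columns}

    def find(aliases):
        for a in aliases:
            if a in cols:
                return cols[a]
        return None

    gene_col = find(_GENE_ALIASES)
    p_col = find(_P_ALIASES)
    fc_col = find(_FC_ALIASES)
    logfc_col = find(_LOGFC_ALIASES)
    if gene_col is None or p_col is None or (fc_col is None and logfc_col is None):
        raise ValueError(
            f"cannot map DE table headers {list(df.columns)}: need gene, p-value "
            "and fold_change (or logFC) columns"
        )
    fc = (
        df[fc_col].astype(float)
        if fc_col is not None
        else np.power(float(logfc_base), df[logfc_col].astype(float))
    )
    p = df[p_col].astype(float)
    out = pd.DataFrame(
        {
            "gene_id": df[gene_col].astype(str),
            "fold_change": fc,
            "p_value": p,
            "q_value": _bh_qvalues(p.to_numpy()),
            "exclusivity": "",
        }
    )
    out["de_class"] = [_classify_row(f, pv) for f, pv in zip(out["fold_change"], out["p_value"])]
    return out[DE_COLUMNS].sort_values("gene_id", kind="mergesort").reset_index(drop=True)


def classify(de_table: pd.DataFrame) -> tuple[set, set]:
    """(up set, down set) of gene ids at the strict thresholds."""
    recls = [_classify_row(f, p) for f, p in zip(de_table["fold_change"], de_table["p_value"])]
    up = set(de_table.loc[[c == "up" for c in recls], "gene_id"])
    down = set(de_table.loc[[c == "down" for c in recls], "gene_id"])
    return up, down
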