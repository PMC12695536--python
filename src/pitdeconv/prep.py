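"""Reference quality control, normalization, marker discovery, signatures.

Implements the marker-based arm of the workflow: cells are filtered on
feature/count/mitochondrial thresholds, counts are scaled to CPM and
log-transformed, one-vs-rest differentially expressed genes are found
with a bimodal likelihood-ratio test, and gene-expression-signature
(GES) matrices of a chosen per-type size are assembled from the top
markers ranked by within-type mean expression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import AnnotatedCounts

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "SignatureMatrix",
    "qc_filter",
    "cpm_normalize",
    "log_transform",
    "find_markers",
    "build_ges",
]


@dataclass(frozen=True)
class QCThresholds:
    """Cell-level QC bounds; all comparisons are strict inequalities."""

    min_features: int = 1000
    max_features: int = 5000
    min_counts: int = 200
    max_mito: float = 0.05

    def __post_init__(self) -> None:
        if not self.min_features < self.max_features:
            raise ValueError("QCThresholds: min_features must be < max_features")
        if self.max_mito <= 0 or self.min_counts < 0:
            raise ValueError("QCThresholds: bounds must be positive")


def qc_filter(data: AnnotatedCounts, thr: QCThresholds = QCThresholds()) -> AnnotatedCounts:
    """Retain cells with min_features < n_features < max_features,
    n_counts > min_counts and pct_mito < max_mito (all strict).

    Logs how many cells each criterion removed. An empty result is returned
    (with a warning), never raised.
    """
    ann = data.annotation
    ok_feat_lo = ann["n_features"] > thr.min_features
    ok_feat_hi = ann["n_features"] < thr.max_features
    ok_counts = ann["n_counts"] > thr.min_counts
    ok_mito = ann["pct_mito"] < thr.max_mito
    keep = ok_feat_lo & ok_feat_hi & ok_counts & ok_mito
    for name, ok in [
        ("n_features <= min", ok_feat_lo),
        ("n_features >= max", ok_feat_hi),
        ("n_counts <= min", ok_counts),
        ("pct_mito >= max", ok_mito),
    ]:
        removed = int((~ok).sum())
        if removed:
            logger.info("qc_filter: %d cells fail %s", removed, name)
    if not keep.any():
        logger.warning("qc_filter removed every cell")
    kept = data.subset_cells(list(ann.index[keep]))
    if hasattr(data, "marker_blocks"):
        kept.marker_blocks = data.marker_blocks  # type: ignore[attr-defined]
    return kept


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale every column to sum to one million (counts per million)."""
    sums = counts.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"cpm_normalize: zero-sum column(s): {list(zero.index)}")
    return counts / sums * 1e6


def log_transform(cpm: pd.DataFrame, base: str = "e") -> pd.DataFrame:
    """Elementwise log(x + 1); ``base`` is 'e' (natural) or '10'."""
    vals = cpm.to_numpy()
    if np.any(vals < 0):
        raise ValueError("log_transform: negative values in input")
    if base in ("e", math.e):
        out = np.log1p(vals)
    elif base in ("10", 10):
        out = np.log10(vals + 1.0)
    else:
        raise ValueError(f"log_transform: unsupported base {base!r}")
    return pd.DataFrame(out, index=cpm.index, columns=cpm.columns)


# --------------------------------------------------------------------------
# bimodal likelihood-ratio marker test

_SD_FLOOR = 1e-3


def _bimod_loglik(x: np.ndarray) -> float:
    """Log-likelihood of log-expression under a zero point mass with
    probability 1-pi plus a normal on the nonzero values."""
    n = x.size
    nz = x[x > 0]
    k = nz.size
    ll = 0.0
    if 0 < k < n:
        pi = k / n
        ll += k * math.log(pi) + (n - k) * math.log1p(-pi)
    if k >= 1:
        mu = float(nz.mean())
        sd = max(float(nz.std()), _SD_FLOOR)
        ll += float(np.sum(stats.norm.logpdf(nz, mu, sd)))
    return ll


def find_markers(
    log_cpm: pd.DataFrame,
    cell_types: pd.Series,
    min_pct: float = 0.25,
    min_cells: int = 50,
    cpm: pd.DataFrame | None = None,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """One-vs-rest differential expression with a bimodal LRT.

    Per cell type, a gene is tested if it is detected (value > 0) in at
    least ``min_pct`` of cells in the type or in the rest. Expression is
    modelled per group as a point mass at zero plus a normal on nonzero
    log values; the statistic 2(l_alt - l_null) is referred to chi2 with
    3 degrees of freedom (group-specific vs shared detection rate, mean
    and spread). logFC is the natural-log ratio of (mean CPM + 1) in the
    type vs the rest; p-values are Bonferroni-corrected over all genes in
    the matrix (``adjust='none'`` disables).

    Types with fewer than ``min_cells`` cells are dropped before testing.
    ``cpm`` may supply the linear-scale matrix; otherwise it is recovered
    as expm1 of the natural-log input.

    Returns a table with columns cell_type, gene, p_value, adj_p, logFC,
    pct_in, pct_out, mean_cpm_in.
    """
    cell_types = cell_types.reindex(log_cpm.columns)
    counts = cell_types.value_counts()
    keep_types = [t for t in counts.index if counts[t] >= min_cells]
    dropped = [t for t in counts.index if counts[t] < min_cells]
    if dropped:
        logger.info("find_markers: dropping low-representation types %s", dropped)
    if len(keep_types) < 2:
        raise ValueError("find_markers: need >= 2 cell types after the min_cells exclusion")

    if cpm is None:
        cpm = np.expm1(log_cpm)
    X = log_cpm.to_numpy()
    C = cpm.to_numpy()
    genes = log_cpm.index.to_numpy()
    n_genes = len(genes)
    crit_df = 3

    rows = []
    for t in keep_types:
        in_mask = (cell_types == t).to_numpy()
        Xin, Xout = X[:, in_mask], X[:, ~in_mask]
        pct_in = (Xin > 0).mean(axis=1)
        pct_out = (Xout > 0).mean(axis=1)
        testable = np.where((pct_in >= min_pct) | (pct_out >= min_pct))[0]
        mean_in = C[:, in_mask].mean(axis=1)
        mean_out = C[:, ~in_mask].mean(axis=1)
        logfc = np.log((mean_in + 1.0) / (mean_out + 1.0))
        for g in testable:
            ll_alt = _bimod_loglik(Xin[g]) + _bimod_loglik(Xout[g])
            ll_null = _bimod_loglik(X[g])
            lrt = max(2.0 * (ll_alt - ll_null), 0.0)
            p = float(stats.chi2.sf(lrt, crit_df))
            rows.append(
                (t, genes[g], p, pct_in[g], pct_out[g], logfc[g], mean_in[g])
            )

    table = pd.DataFrame(
        rows,
        columns=["cell_type", "gene", "p_value", "pct_in", "pct_out", "logFC", "mean_cpm_in"],
    )
    if adjust == "bonferroni":
        table["adj_p"] = np.minimum(table["p_value"] * n_genes, 1.0)
    elif adjust == "none":
        table["adj_p"] = table["p_value"]
    else:
        raise ValueError(f"find_markers: unknown adjustment {adjust!r}")
    return table[
        ["cell_type", "gene", "p_value", "adj_p", "logFC", "pct_in", "pct_out", "mean_cpm_in"]
    ]


# --------------------------------------------------------------------------
# GES signature matrices


@dataclass
class SignatureMatrix:
    """Genes x cell-types reference of mean CPM on discriminative genes.

    ``values`` has one row per gene in the union of the per-type member
    sets; ``members`` records which genes were selected for each type.
    """

    values: pd.DataFrame
    members: dict[str, list[str]]
    name: str = "signature"

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def types(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("SignatureMatrix: duplicate genes")
        if len(self.types) < 2:
            raise ValueError("SignatureMatrix: need >= 2 cell types")
        if not (self.values.max(axis=1) > 1.0).all():
            raise ValueError("SignatureMatrix: every gene must exceed 1 CPM in some type")


def build_ges(
    markers: pd.DataFrame,
    mean_profiles: pd.DataFrame,
    n: int = 300,
    adj_p_max: float = 0.05,
    min_logfc: float = 1.0,
    min_cpm: float = 1.0,
    name: str | None = None,
) -> SignatureMatrix:
    """Assemble a GES-``n`` signature from a marker table.

    For each type, markers with adj_p <= ``adj_p_max`` and logFC >
    ``min_logfc`` are ranked by within-type mean CPM (descending; ties by
    smaller adj_p, then gene id) and the top ``n`` kept. The union of the
    per-type sets forms the gene axis, genes at or below ``min_cpm`` CPM in
    every type are dropped, and values are the per-type mean CPM profiles.
    """
    if n <= 0:
        raise ValueError("build_ges: n must be positive")
    sig = markers[(markers["adj_p"] <= adj_p_max) & (markers["logFC"] > min_logfc)]
    members: dict[str, list[str]] = {}
    for t in mean_profiles.columns:
        sub = sig[sig["cell_type"] == t]
        if sub.empty:
            logger.warning("build_ges: no significant markers for type %r", t)
            members[t] = []
            continue
        sub = sub.sort_values(
            ["mean_cpm_in", "adj_p", "gene"], ascending=[False, True, True], kind="mergesort"
        )
        members[t] = sub["gene"].head(n).tolist()

    union: list[str] = []
    seen: set[str] = set()
    for t in mean_profiles.columns:
        for g in members[t]:
            if g not in seen:
                seen.add(g)
                union.append(g)
    values = mean_profiles.loc[union]
    keep = values.max(axis=1) > min_cpm
    if (~keep).any():
        logger.info("build_ges: dropping %d genes at or below %g CPM in all types",
                    int((~keep).sum()), min_cpm)
        dropped_genes = set(values.index[~keep])
        members = {t: [g for g in gs if g not in dropped_genes] for t, gs in members.items()}
        values = values[keep]
    out = SignatureMatrix(values=values, members=members, name=name or f"GES{n}")
    return out
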