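"""Residual-normal-tissue quantification and flagging in bulk tumors.

A deconvolved tumor sample's composition is partitioned, given its
histotype and a cell-type -> lineage map, into

* ``tumor_fraction`` — the histotype's own tumor cell type(s),
* ``same_lineage_fraction`` — other endocrine types of the tumor lineage
  (stem/progenitor signal counts here for PIT1 tumors by default, as it
  commonly reflects tumor-intrinsic reprogramming rather than residue),
* ``residual_normal_fraction`` — endocrine (and posterior) types outside
  the tumor lineage: the contamination readout,
* ``tme_fraction`` — stromal and immune populations.

Independently of deconvolution, contaminated samples can be flagged from
expression alone: batch-adjusted log-CPM profiles are clustered (complete
linkage, Euclidean distance on the top highly-variable genes) and samples
whose cluster majority-lineage disagrees with their annotation flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .prep import cpm_normalize
from .simulate import DEFAULT_LINEAGES

logger = logging.getLogger(__name__)

__all__ = [
    "LineageMap",
    "bulk_cpm",
    "contamination_score",
    "contamination_report",
    "batch_adjust",
    "hvg_select",
    "hcluster",
    "flag_discordant",
]

_ENDOCRINE_CLASSES = {"PIT1", "TPIT", "SF1", "stem/progenitor", "posterior"}
_TME_CLASSES = {"stromal", "immune"}


@dataclass
class LineageMap:
    """Cell type -> lineage class and histotype -> tumor cell types.

    Lineage classes: PIT1, TPIT, SF1, stem/progenitor, posterior, stromal,
    immune. ``stem_as_same_lineage`` counts stem/progenitor fractions as
    same-lineage for PIT1 tumors (else they are residual).
    """

    type_lineage: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_LINEAGES))
    histotype_tumor_types: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "GH": ("somatotroph",),
            "PRL": ("lactotroph",),
            "TSH": ("thyrotroph",),
            "ACTH": ("corticotroph",),
            "FSH/LH": ("gonadotroph",),
            "somatotroph": ("somatotroph",),
            "lactotroph": ("lactotroph",),
            "thyrotroph": ("thyrotroph",),
            "corticotroph": ("corticotroph",),
            "gonadotroph": ("gonadotroph",),
        }
    )
    stem_as_same_lineage: bool = True

    def tumor_types(self, histotype: str) -> tuple[str, ...]:
        try:
            return self.histotype_tumor_types[histotype]
        except KeyError:
            raise ValueError(f"unknown histotype {histotype!r}") from None

    def tumor_lineage(self, histotype: str) -> str:
        lin = {self.type_lineage[t] for t in self.tumor_types(histotype)}
        if len(lin) != 1:
            raise ValueError(f"histotype {histotype!r} maps to multiple lineages {lin}")
        return lin.pop()

    def lineage_of(self, cell_type: str) -> str:
        try:
            return self.type_lineage[cell_type]
        except KeyError:
            raise ValueError(f"cell type {cell_type!r} missing from lineage map") from None


def bulk_cpm(raw_counts: pd.DataFrame) -> pd.DataFrame:
    """CPM-normalize a bulk count matrix (shared with the reference path)."""
    return cpm_normalize(raw_counts)


def contamination_score(
    proportions: pd.Series,
    histotype: str,
    lineage_map: LineageMap | None = None,
    flag_threshold: float = 0.20,
) -> pd.Series:
    """Partition one sample's estimated composition into the four fractions.

    Returns a Series with tumor_fraction, same_lineage_fraction,
    residual_normal_fraction, tme_fraction (summing to the proportions'
    total) plus the boolean ``contaminated`` flag
    (residual_normal_fraction >= flag_threshold).
    """
    lm = lineage_map or LineageMap()
    tumor_types = set(lm.tumor_types(histotype))
    tumor_lin = lm.tumor_lineage(histotype)
    tumor = same = residual = tme = 0.0
    for t, p in proportions.items():
        lin = lm.lineage_of(str(t))
        if t in tumor_types:
            tumor += p
        elif lin in _TME_CLASSES:
            tme += p
        elif lin == tumor_lin:
            same += p
        elif lin == "stem/progenitor" and lm.stem_as_same_lineage and tumor_lin == "PIT1":
            same += p
        else:
            residual += p
    return pd.Series(
        {
            "tumor_fraction": tumor,
            "same_lineage_fraction": same,
            "residual_normal_fraction": residual,
            "tme_fraction": tme,
            "contaminated": residual >= flag_threshold,
        }
    )


def contamination_report(
    proportions: pd.DataFrame,
    histotypes: pd.Series,
    lineage_map: LineageMap | None = None,
    flag_threshold: float = 0.20,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-sample contamination partition plus the cohort summary.

    ``proportions`` is samples x types; ``histotypes`` maps sample ->
    histotype. The summary reports the mean and SD of
    residual_normal_fraction over the flagged (contaminated) samples, and
    over all samples.
    """
    rows = {
        s: contamination_score(
            proportions.loc[s], str(histotypes[s]), lineage_map, flag_threshold
        )
        for s in proportions.index
    }
    report = pd.DataFrame(rows).T
    report.index.name = "sample"
    for c in report.columns.drop("contaminated"):
        report[c] = report[c].astype(float)
    report["contaminated"] = report["contaminated"].astype(bool)
    flagged = report[report["contaminated"].astype(bool)]
    summary = {
        "n_samples": int(len(report)),
        "n_contaminated": int(len(flagged)),
        "mean_residual_flagged": float(flagged["residual_normal_fraction"].mean())
        if len(flagged)
        else float("nan"),
        "sd_residual_flagged": float(flagged["residual_normal_fraction"].std(ddof=1))
        if len(flagged) > 1
        else float("nan"),
        "mean_residual_all": float(report["residual_normal_fraction"].mean()),
        "sd_residual_all": float(report["residual_normal_fraction"].std(ddof=1)),
    }
    return report, summary


# --------------------------------------------------------------------------
# expression-level clustering and flagging


def batch_adjust(matrices: Sequence[pd.DataFrame], batches: Sequence[str]) -> pd.DataFrame:
    """Merge log-CPM matrices and align batches by per-gene location/scale.

    Genes are inner-joined across matrices (dropped genes are logged). Each
    gene is standardized within batch and mapped to the pooled mean and
    variance. Size-1 batches are only re-centered (with a warning), since a
    scale cannot be estimated from one sample.
    """
    if len(matrices) != len(batches):
        raise ValueError("batch_adjust: one batch label per matrix required")
    shared = matrices[0].index
    for m in matrices[1:]:
        shared = shared.intersection(m.index)
    dropped = sum(len(m.index) - len(shared) for m in matrices)
    if dropped:
        logger.info("batch_adjust: dropped %d non-shared gene rows", dropped)
    merged = pd.concat([m.loc[shared] for m in matrices], axis=1)
    batch_of = np.concatenate(
        [[b] * matrices[i].shape[1] for i, b in enumerate(batches)]
    )

    X = merged.to_numpy(dtype=float)
    pooled_mean = X.mean(axis=1, keepdims=True)
    pooled_sd = X.std(axis=1, keepdims=True)
    out = X.copy()
    for b in pd.unique(batch_of):
        cols = batch_of == b
        nb = int(cols.sum())
        mb = X[:, cols].mean(axis=1, keepdims=True)
        if nb < 2:
            logger.warning("batch_adjust: batch %r has one sample; centering only", b)
            out[:, cols] = X[:, cols] - mb + pooled_mean
            continue
        sb = X[:, cols].std(axis=1, keepdims=True)
        scale = np.divide(pooled_sd, sb, out=np.ones_like(sb), where=sb > 0)
        out[:, cols] = (X[:, cols] - mb) * scale + pooled_mean
    return pd.DataFrame(out, index=shared, columns=merged.columns)


def hvg_select(matrix: pd.DataFrame, n: int = 500) -> pd.Index:
    """Top-``n`` genes by cross-sample variance; ties broken by gene id."""
    if n > len(matrix):
        raise ValueError("hvg_select: n exceeds gene count")
    var = matrix.var(axis=1, ddof=1)
    order = sorted(matrix.index, key=lambda g: (-var[g], g))
    return pd.Index(order[:n])


def hcluster(matrix: pd.DataFrame) -> np.ndarray:
    """Complete-linkage hierarchical clustering of samples (columns) on
    Euclidean distances; returns the scipy linkage matrix."""
    if matrix.shape[1] < 2:
        raise ValueError("hcluster: need >= 2 samples")
    d = pdist(matrix.to_numpy(dtype=float).T, metric="euclidean")
    return linkage(d, method="complete")


def flag_discordant(
    link: np.ndarray,
    lineages: pd.Series,
    k: int,
) -> pd.Series:
    """Flag samples whose clustering disagrees with their annotated lineage.

    The dendrogram is cut into ``k`` clusters. A sample is flagged when it
    clusters *away from its lineage* in either sense:

    * its cluster's majority (> 50%) lineage differs from its own, or the
      cluster has no majority lineage; or
    * its cluster is a *distinct group*: not the home cluster of its
      lineage, where the home cluster is the one holding the plurality of
      that lineage's samples (ties broken toward the larger cluster, then
      the lower cluster label, for determinism).

    ``lineages`` is indexed like (and ordered as) the clustered columns.
    """
    n_lineages = lineages.nunique()
    if k < n_lineages:
        raise ValueError(f"flag_discordant: k={k} below the {n_lineages} distinct lineages")
    assign = pd.Series(fcluster(link, t=k, criterion="maxclust"), index=lineages.index)

    cluster_sizes = assign.value_counts()
    home: dict[str, int] = {}
    for lin in lineages.unique():
        counts = assign[lineages == lin].value_counts()
        best = sorted(
            counts.index,
            key=lambda c: (-counts[c], -cluster_sizes[c], c),
        )[0]
        home[lin] = best

    majority: dict[int, str | None] = {}
    for c in cluster_sizes.index:
        shares = lineages[assign == c].value_counts(normalize=True)
        majority[c] = shares.index[0] if shares.iloc[0] > 0.5 else None

    flags = pd.Series(False, index=lineages.index)
    for s in lineages.index:
        c = assign[s]
        own = lineages[s]
        flags[s] = (majority[c] != own) or (home[own] != c)
    return flags
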