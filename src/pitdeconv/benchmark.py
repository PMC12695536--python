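"""Scoring deconvolution accuracy against known composition.

Per cell type, estimated fractions are correlated with the true fractions
across samples (Pearson); an estimate is called *validated* when r > 0.70
with two-sided p < 0.05. The benchmark matrix runs a set of engines over a
mixture set and collects one report row per (engine, signature, type).
"""

from __future__ import annotations

import logging
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .engines import DeconvResult
from .pseudobulk import MixtureSet

logger = logging.getLogger(__name__)

__all__ = ["evaluate", "benchmark_matrix", "R_THRESHOLD", "P_THRESHOLD"]

R_THRESHOLD = 0.70
P_THRESHOLD = 0.05


def evaluate(
    true: pd.DataFrame,
    estimated: pd.DataFrame,
    r_threshold: float = R_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Per-type Pearson validation of estimated vs true proportions.

    Both inputs are samples x types. Types present in only one input are
    reported with reason ``absent``; constant vectors give an undefined r
    and reason ``degenerate``. Returns a DataFrame indexed by cell type
    with columns r, p_value, n_samples, validated, reason.
    """
    if not true.index.equals(estimated.index):
        if set(true.index) != set(estimated.index):
            raise ValueError(
                "evaluate: sample axes differ: "
                f"{sorted(set(true.index) ^ set(estimated.index))[:5]}"
            )
        estimated = estimated.reindex(true.index)
    all_types = list(dict.fromkeys(list(true.columns) + list(estimated.columns)))
    rows = []
    for t in all_types:
        if t not in true.columns or t not in estimated.columns:
            rows.append((t, np.nan, np.nan, len(true), False, "absent"))
            continue
        x = true[t].to_numpy(dtype=float)
        y = estimated[t].to_numpy(dtype=float)
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((t, np.nan, np.nan, len(x), False, "degenerate"))
            continue
        r, p = pearsonr(x, y)
        ok = bool(p < p_threshold and r > r_threshold)
        rows.append((t, float(r), float(p), len(x), ok, "ok"))
    return pd.DataFrame(
        rows, columns=["cell_type", "r", "p_value", "n_samples", "validated", "reason"]
    ).set_index("cell_type")


def benchmark_matrix(
    engines: Mapping[str, Callable[[pd.DataFrame], DeconvResult]],
    mixtures: MixtureSet,
    r_threshold: float = R_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Run every engine on the mixture set and tabulate validation reports.

    ``engines`` maps a label to a callable taking the CPM mixture matrix and
    returning a :class:`DeconvResult`. Engine failures are recorded (reason
    ``error: ...``) and the run continues. The output is long-format with
    columns engine, signature, cell_type, r, p_value, n_samples, validated,
    reason; a summary attribute ``median_r`` per engine is attached via
    ``result.attrs``.
    """
    rows = []
    for label, fn in engines.items():
        try:
            res = fn(mixtures.mixtures)
        except Exception as exc:  # noqa: BLE001 - failures become report rows
            logger.warning("benchmark_matrix: engine %r failed: %s", label, exc)
            for t in mixtures.true_proportions.columns:
                rows.append((label, "", t, np.nan, np.nan, 0, False, f"error: {exc}"))
            continue
        rep = evaluate(mixtures.true_proportions, res.proportions, r_threshold, p_threshold)
        for t, row in rep.iterrows():
            rows.append(
                (label, res.signature, t, row["r"], row["p_value"],
                 int(row["n_samples"]), bool(row["validated"]), row["reason"])
            )
    out = pd.DataFrame(
        rows,
        columns=["engine", "signature", "cell_type", "r", "p_value",
                 "n_samples", "validated", "reason"],
    )
    out.attrs["median_r"] = out.groupby("engine")["r"].median().to_dict()
    return out
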