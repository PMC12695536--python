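"""Pseudobulk mixtures with known cell-type composition.

Ground-truth benchmarks for deconvolution: pseudobulk profiles are the
summed raw counts of randomly selected single cells (no per-cell scaling),
CPM-normalized, with the selecting proportions recorded. The random-mixing
scheme draws a composition uniformly on the simplex of available types and
allocates a fixed cell budget multinomially.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prep import cpm_normalize
from .simulate import AnnotatedCounts

__all__ = ["MixtureSet", "simulate_pseudobulk", "pseudobulk_from_labels"]


@dataclass
class MixtureSet:
    """CPM mixtures (genes x samples), true proportions (samples x types),
    and the sampled cell ids per sample."""

    mixtures: pd.DataFrame
    true_proportions: pd.DataFrame
    provenance: dict[str, list[str]] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.mixtures.columns.equals(self.true_proportions.index):
            raise ValueError("true_proportions rows must match mixture columns")
        if (self.true_proportions.to_numpy() < 0).any():
            raise ValueError("true proportions must be non-negative")
        row_sums = self.true_proportions.sum(axis=1)
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise ValueError("true proportion rows must sum to 1")


def simulate_pseudobulk(
    data: AnnotatedCounts,
    n_samples: int = 150,
    cells_per_sample: int = 500,
    seed: int = 0,
) -> MixtureSet:
    """Random-mixing pseudobulk: per sample, draw a composition from a flat
    Dirichlet over the types present, allocate ``cells_per_sample`` cells
    multinomially, sample cells with replacement within each type, sum their
    raw counts and convert to CPM. True proportions are the realized
    allocated-cell fractions.
    """
    if n_samples <= 0:
        raise ValueError("simulate_pseudobulk: n_samples must be positive")
    if cells_per_sample < 1:
        raise ValueError("simulate_pseudobulk: cells_per_sample must be >= 1")
    rng = np.random.default_rng(seed)
    ann = data.annotation
    types = list(pd.unique(ann["cell_type"]))
    by_type = {t: np.asarray(ann.index[ann["cell_type"] == t]) for t in types}

    counts = data.matrix.to_numpy()
    col_of = {c: i for i, c in enumerate(data.matrix.columns)}
    cols, props, prov = [], [], {}
    for s in range(n_samples):
        name = f"pseudobulk{s:03d}"
        p = rng.dirichlet(np.ones(len(types)))
        alloc = rng.multinomial(cells_per_sample, p)
        chosen: list[str] = []
        for t, k in zip(types, alloc):
            if k:
                chosen.extend(rng.choice(by_type[t], size=k, replace=True))
        total = counts[:, [col_of[c] for c in chosen]].sum(axis=1)
        cols.append(total)
        props.append(alloc / cells_per_sample)
        prov[name] = chosen

    names = list(prov.keys())
    raw = pd.DataFrame(np.column_stack(cols), index=data.matrix.index, columns=names)
    return MixtureSet(
        mixtures=cpm_normalize(raw),
        true_proportions=pd.DataFrame(props, index=names, columns=types),
        provenance=prov,
        seed=seed,
    )


def pseudobulk_from_labels(data: AnnotatedCounts, sample_of: pd.Series) -> MixtureSet:
    """Pseudobulk by explicit cell-to-sample assignment.

    ``sample_of`` maps cell id -> sample id; unassigned cells are ignored.
    True proportions are the labelled cell-type fractions per sample.
    """
    missing = sample_of.index.difference(data.matrix.columns)
    if len(missing):
        raise ValueError(f"pseudobulk_from_labels: unknown cells {list(missing[:5])}")
    samples = list(pd.unique(sample_of))
    types = list(pd.unique(data.annotation["cell_type"]))
    cols, props, prov = [], [], {}
    for s in samples:
        cells = list(sample_of.index[sample_of == s])
        if not cells:
            raise ValueError(f"pseudobulk_from_labels: sample {s!r} has no cells")
        cols.append(data.matrix[cells].sum(axis=1).to_numpy())
        frac = data.annotation.loc[cells, "cell_type"].value_counts(normalize=True)
        props.append([frac.get(t, 0.0) for t in types])
        prov[s] = cells
    raw = pd.DataFrame(np.column_stack(cols), index=data.matrix.index, columns=samples)
    return MixtureSet(
        mixtures=cpm_normalize(raw),
        true_proportions=pd.DataFrame(props, index=samples, columns=types),
        provenance=prov,
    )
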