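"""Synthetic single-nucleus reference and bulk tumor cohorts.

Generates count data with the statistical structure the deconvolution
pipeline assumes: cell types with disjoint marker-gene blocks on a
log-normal gene baseline, log-normal donor (subject) effects shared by
all cells of a subject, negative-binomial (gamma-Poisson) counts with a
per-cell library size, and a designated set of mitochondrial genes.

Bulk cohorts are multinomial count mixtures of a dominant tumor cell
type plus a planted fraction of residual normal pituitary tissue drawn
from other lineages, emulating incompletely microdissected tumor
specimens.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "AnnotatedCounts",
    "ENDOCRINE_TYPES",
    "STROMAL_TYPES",
    "IMMUNE_TYPES",
    "DEFAULT_LINEAGES",
    "generate_reference",
    "generate_bulk_cohort",
]

# Default 13-type anterior-pituitary atlas: 7 endocrine populations
# (five hormone-secreting, one stem, one progenitor), 3 stromal, 3 immune.
ENDOCRINE_TYPES = (
    "somatotroph",
    "lactotroph",
    "thyrotroph",
    "gonadotroph",
    "corticotroph",
    "stem_cell",
    "progenitor",
)
STROMAL_TYPES = ("endothelial", "pericyte", "smooth_muscle")
IMMUNE_TYPES = ("t_cell", "macrophage", "nk_cell")

#: cell type -> lineage class used downstream for contamination calls
DEFAULT_LINEAGES: dict[str, str] = {
    "somatotroph": "PIT1",
    "lactotroph": "PIT1",
    "thyrotroph": "PIT1",
    "gonadotroph": "SF1",
    "corticotroph": "TPIT",
    "stem_cell": "stem/progenitor",
    "progenitor": "stem/progenitor",
    "endothelial": "stromal",
    "pericyte": "stromal",
    "smooth_muscle": "stromal",
    "t_cell": "immune",
    "macrophage": "immune",
    "nk_cell": "immune",
}


class ConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


def _default_cells_per_type() -> dict[str, int]:
    out = {t: 160 for t in ENDOCRINE_TYPES}
    out.update({t: 100 for t in STROMAL_TYPES})
    out.update({t: 60 for t in IMMUNE_TYPES})
    return out


@dataclass
class SimConfig:
    """Parameters of the synthetic single-nucleus reference.

    Attributes
    ----------
    cell_types:
        Ordered type labels. The default is the 13-type pituitary atlas.
    n_genes:
        Total genes, including mitochondrial genes.
    markers_per_type:
        Size of each type's disjoint marker block.
    cells_per_type:
        Either one integer for all types or a mapping per type.
    n_subjects:
        Number of donors; cells are assigned round-robin per type so every
        (subject, type) stratum is populated.
    marker_fold:
        Multiplicative enrichment of a type's marker genes in that type
        (dimensionless, > 1; 1 disables the marker structure).
    nb_dispersion:
        Negative-binomial dispersion alpha (variance = mu + alpha*mu^2).
    libsize_mean:
        Expected total counts per cell; scalar or per-type mapping.
    libsize_log_sd:
        SD of the log-normal per-cell library-size jitter.
    baseline_log_sd:
        SD of the log-normal gene baseline expression.
    subject_sd:
        SD of the per-(subject, gene) log-normal donor effect.
    mito_fraction_range:
        Per-cell mitochondrial count fraction is drawn uniformly here.
    n_mito_genes:
        Number of genes labelled mitochondrial (prefixed ``MT-``).
    """

    cell_types: Sequence[str] = field(
        default_factory=lambda: ENDOCRINE_TYPES + STROMAL_TYPES + IMMUNE_TYPES
    )
    n_genes: int = 2000
    markers_per_type: int = 120
    cells_per_type: int | Mapping[str, int] = field(default_factory=_default_cells_per_type)
    n_subjects: int = 3
    marker_fold: float = 8.0
    nb_dispersion: float = 0.25
    libsize_mean: float | Mapping[str, float] = 6000.0
    libsize_log_sd: float = 0.25
    baseline_log_sd: float = 1.0
    subject_sd: float = 0.20
    mito_fraction_range: tuple[float, float] = (0.005, 0.04)
    n_mito_genes: int = 13
    seed: int = 0

    @property
    def n_types(self) -> int:
        return len(self.cell_types)

    def cells_for(self, cell_type: str) -> int:
        if isinstance(self.cells_per_type, Mapping):
            try:
                return int(self.cells_per_type[cell_type])
            except KeyError:
                raise ConfigError(f"cells_per_type missing entry for {cell_type!r}")
        return int(self.cells_per_type)

    def libsize_for(self, cell_type: str) -> float:
        if isinstance(self.libsize_mean, Mapping):
            try:
                return float(self.libsize_mean[cell_type])
            except KeyError:
                raise ConfigError(f"libsize_mean missing entry for {cell_type!r}")
        return float(self.libsize_mean)

    def validate(self) -> None:
        if self.n_types < 2:
            raise ConfigError("cell_types: at least 2 cell types required")
        if len(set(self.cell_types)) != self.n_types:
            raise ConfigError("cell_types: labels must be unique")
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.markers_per_type < 0:
            raise ConfigError("markers_per_type must be non-negative")
        if self.markers_per_type * self.n_types + self.n_mito_genes > self.n_genes:
            raise ConfigError(
                "n_genes too small: markers_per_type * n_types + n_mito_genes "
                f"= {self.markers_per_type * self.n_types + self.n_mito_genes} "
                f"exceeds n_genes = {self.n_genes}"
            )
        if self.marker_fold < 1:
            raise ConfigError("marker_fold must be >= 1")
        for t in self.cell_types:
            if self.cells_for(t) <= 0:
                raise ConfigError(f"cells_per_type must be positive (type {t!r})")
            if self.libsize_for(t) <= 0:
                raise ConfigError(f"libsize_mean must be positive (type {t!r})")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        lo, hi = self.mito_fraction_range
        if not (0 <= lo <= hi < 1):
            raise ConfigError("mito_fraction_range must satisfy 0 <= lo <= hi < 1")
        if self.n_mito_genes < 0:
            raise ConfigError("n_mito_genes must be >= 0")


@dataclass
class AnnotatedCounts:
    """Genes x cells integer count matrix plus per-cell annotation.

    ``matrix`` is a DataFrame indexed by gene id with one column per cell.
    ``annotation`` is indexed by cell id with columns ``cell_type``,
    ``subject``, ``n_features`` (genes with count > 0), ``n_counts``
    (column sum) and ``pct_mito`` (fraction of counts on mito genes).
    """

    matrix: pd.DataFrame
    annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.matrix.columns.equals(self.annotation.index):
            raise ValueError("annotation index must match matrix columns exactly")

    @property
    def cell_types(self) -> list[str]:
        return list(pd.unique(self.annotation["cell_type"]))

    def subset_cells(self, cell_ids: Sequence[str]) -> "AnnotatedCounts":
        return AnnotatedCounts(self.matrix[list(cell_ids)], self.annotation.loc[list(cell_ids)])


def annotate_counts(
    matrix: pd.DataFrame, cell_type: pd.Series, subject: pd.Series, mito_genes: Sequence[str]
) -> AnnotatedCounts:
    """Build an :class:`AnnotatedCounts` computing QC metrics from counts."""
    vals = matrix.to_numpy()
    n_counts = vals.sum(axis=0)
    mito_mask = matrix.index.isin(mito_genes)
    with np.errstate(invalid="ignore"):
        pct = np.where(n_counts > 0, vals[mito_mask].sum(axis=0) / np.maximum(n_counts, 1), 0.0)
    ann = pd.DataFrame(
        {
            "cell_type": cell_type.reindex(matrix.columns),
            "subject": subject.reindex(matrix.columns),
            "n_features": (vals > 0).sum(axis=0),
            "n_counts": n_counts.astype(int),
            "pct_mito": pct,
        },
        index=matrix.columns,
    )
    ann.index.name = "cell_id"
    return AnnotatedCounts(matrix, ann)


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Gamma-Poisson draw with mean mu and variance mu + alpha*mu^2."""
    if alpha <= 0:
        return rng.poisson(mu)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mu)
    return rng.poisson(lam)


def _expected_profiles(config: SimConfig, rng: np.random.Generator):
    """Gene labels, mito mask, per-type relative-expression matrix and the
    per-(subject, gene) donor factors. Profiles columns sum to 1."""
    n_body = config.n_genes - config.n_mito_genes
    genes = [f"GENE{i:04d}" for i in range(n_body)] + [
        f"MT-{i:02d}" for i in range(config.n_mito_genes)
    ]
    baseline = rng.lognormal(mean=0.0, sigma=config.baseline_log_sd, size=config.n_genes)
    fold = np.ones((config.n_genes, config.n_types))
    marker_blocks: dict[str, list[str]] = {}
    for j, t in enumerate(config.cell_types):
        lo = j * config.markers_per_type
        hi = lo + config.markers_per_type
        fold[lo:hi, j] = config.marker_fold
        marker_blocks[t] = genes[lo:hi]
    mito_mask = np.zeros(config.n_genes, dtype=bool)
    if config.n_mito_genes:
        mito_mask[n_body:] = True
    rel = baseline[:, None] * fold
    rel[mito_mask] = 0.0
    rel /= rel.sum(axis=0, keepdims=True)
    mito_w = baseline[mito_mask]
    if config.n_mito_genes:
        mito_w = mito_w / mito_w.sum()
    donor = rng.lognormal(
        mean=0.0, sigma=config.subject_sd, size=(config.n_subjects, config.n_genes)
    )
    return genes, mito_mask, rel, mito_w, donor, marker_blocks


def generate_reference(config: SimConfig | None = None) -> AnnotatedCounts:
    """Simulate an annotated single-nucleus count matrix.

    Each cell type carries a disjoint marker block whose mean expression is
    ``marker_fold`` times its baseline within the owning type. Counts are
    negative-binomial around a per-cell library size; donor effects multiply
    gene means log-normally per subject. Deterministic for a fixed seed.

    The marker-block gene ids are attached as ``result.marker_blocks``
    (type -> list of planted marker genes) for validation use.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, mito_mask, rel, mito_w, donor, marker_blocks = _expected_profiles(config, rng)

    cols: list[np.ndarray] = []
    cell_ids: list[str] = []
    types: list[str] = []
    subjects: list[str] = []
    lo_m, hi_m = config.mito_fraction_range
    for j, t in enumerate(config.cell_types):
        n_cells = config.cells_for(t)
        libmean = config.libsize_for(t)
        for c in range(n_cells):
            subj = c % config.n_subjects
            base = rel[:, j] * donor[subj]
            base[mito_mask] = 0.0
            base = base / base.sum()
            m_frac = rng.uniform(lo_m, hi_m) if config.n_mito_genes else 0.0
            pi = base * (1.0 - m_frac)
            if config.n_mito_genes:
                pi[mito_mask] = mito_w * m_frac
            lib = rng.lognormal(
                mean=np.log(libmean) - 0.5 * config.libsize_log_sd**2,
                sigma=config.libsize_log_sd,
            )
            cols.append(_nb_sample(rng, lib * pi, config.nb_dispersion))
            cell_ids.append(f"{t}_s{subj}_{c:04d}")
            types.append(t)
            subjects.append(f"subject{subj}")

    matrix = pd.DataFrame(
        np.column_stack(cols).astype(np.int64), index=pd.Index(genes, name="gene"), columns=cell_ids
    )
    out = annotate_counts(
        matrix,
        pd.Series(types, index=cell_ids),
        pd.Series(subjects, index=cell_ids),
        [g for g, m in zip(genes, mito_mask) if m],
    )
    out.marker_blocks = marker_blocks  # type: ignore[attr-defined]
    return out


def type_mean_cpm(reference: AnnotatedCounts) -> pd.DataFrame:
    """Per-type mean profile on the CPM scale (genes x types).

    The profile of a type is the CPM of its pooled (summed) counts, i.e. a
    library-size-weighted mean over the type's cells.
    """
    groups = reference.annotation.groupby("cell_type", sort=False).groups
    prof = {}
    for t, cells in groups.items():
        s = reference.matrix[list(cells)].sum(axis=1).astype(float)
        prof[t] = s / s.sum() * 1e6
    return pd.DataFrame(prof, index=reference.matrix.index)


def generate_bulk_cohort(
    reference: AnnotatedCounts,
    tumor_type: str,
    contamination_fractions: Sequence[float],
    reads_per_sample: int = 5_000_000,
    seed: int = 0,
    residue_split: Mapping[str, float] | None = None,
    lineages: Mapping[str, str] | None = None,
    sample_prefix: str | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Simulate bulk RNA-seq counts of tumors carrying residual normal tissue.

    Sample ``s`` with planted fraction ``f_s`` is a multinomial count draw
    from the mixture profile ``(1 - f_s) * tumor + f_s * residue``, where the
    residue is spread over normal endocrine populations. By default the
    residue is split uniformly over endocrine types *outside* the tumor's
    lineage (stem/progenitor excluded), so ``f_s`` equals the sample's true
    cross-lineage residual-normal fraction. Pass ``residue_split`` (type ->
    weight, renormalized) to plant a different composition.

    Returns ``(counts, true_fraction, histotype)``: genes x samples counts,
    the planted fraction per sample, and the tumor type label per sample.
    """
    lineages = dict(lineages or DEFAULT_LINEAGES)
    available = set(reference.annotation["cell_type"])
    if tumor_type not in available:
        raise ValueError(f"unknown tumor_type {tumor_type!r}: not present in reference")
    fr = np.asarray(list(contamination_fractions), dtype=float)
    if np.any((fr < 0) | (fr >= 1)):
        raise ValueError("contamination fractions must lie in [0, 1)")

    profiles = type_mean_cpm(reference) / 1e6  # columns sum to 1
    if residue_split is None:
        tumor_lin = lineages.get(tumor_type)
        residue_types = [
            t
            for t in profiles.columns
            if t != tumor_type
            and lineages.get(t) not in (tumor_lin, "stem/progenitor", "stromal", "immune")
        ]
        if not residue_types:
            raise ValueError("no cross-lineage endocrine types available for the residue")
        residue_split = {t: 1.0 / len(residue_types) for t in residue_types}
    else:
        unknown = set(residue_split) - available
        if unknown:
            raise ValueError(f"residue_split names unknown cell types: {sorted(unknown)}")
    w = pd.Series(residue_split, dtype=float)
    w = w / w.sum()
    residue_profile = profiles[w.index].to_numpy() @ w.to_numpy()

    rng = np.random.default_rng(seed)
    prefix = sample_prefix or tumor_type
    cols, names = [], []
    for i, f in enumerate(fr):
        pi = (1.0 - f) * profiles[tumor_type].to_numpy() + f * residue_profile
        cols.append(rng.multinomial(reads_per_sample, pi / pi.sum()))
        names.append(f"{prefix}_bulk{i:02d}")
    counts = pd.DataFrame(np.column_stack(cols), index=profiles.index, columns=names)
    return counts, pd.Series(fr, index=names, name="true_fraction"), pd.Series(
        tumor_type, index=names, name="histotype"
    )
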