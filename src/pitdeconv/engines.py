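"""Cell-fraction estimation engines.

Two complementary estimators of bulk composition against a single-cell
reference:

* :func:`svr_deconvolve` — linear nu-support-vector regression of the
  (standardized) bulk profile on the signature-matrix columns, with the
  nu hyperparameter selected by reconstruction RMSE, negative
  coefficients clipped, fractions renormalized to sum to one ("relative"
  mode), and an optional permutation test of the reconstruction
  correlation against random pseudo-mixtures.

* :func:`wnnls_deconvolve` — iterative weighted non-negative least
  squares against multi-subject cell-type profiles: per-gene weights are
  the inverse of the cross-subject variance of the reconstructed
  expression under the current fraction estimate, so genes whose
  reference expression is inconsistent across donors are down-weighted.

Marker-free signatures are built from the annotated cells directly
(:func:`build_signature_from_cells`), selecting the per-type gene-set
size that minimizes the condition number of the resulting matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.svm import NuSVR

from .prep import SignatureMatrix
from .simulate import AnnotatedCounts, type_mean_cpm

logger = logging.getLogger(__name__)

__all__ = [
    "SVRConfig",
    "DeconvResult",
    "SubjectProfiles",
    "svr_deconvolve",
    "build_signature_from_cells",
    "build_subject_profiles",
    "wnnls_deconvolve",
]


@dataclass(frozen=True)
class SVRConfig:
    """nu-SVR engine settings.

    nu bounds the support-vector fraction; the grid is searched per sample
    and the value minimizing reconstruction RMSE wins. ``standardize``
    z-scores the signature (as one block) and each mixture column before
    the fit. ``n_permutations`` random pseudo-mixtures drive the
    significance test; 0 disables it.
    """

    nu_grid: tuple[float, ...] = (0.25, 0.5, 0.75)
    n_permutations: int = 100
    standardize: bool = True
    C: float = 1.0
    tol: float = 1e-2  # libsvm stopping tolerance; coefficients are stable well above default

    def __post_init__(self) -> None:
        if not self.nu_grid or any(not (0 < v < 1) for v in self.nu_grid):
            raise ValueError("SVRConfig: nu values must lie in (0, 1)")
        if self.n_permutations < 0:
            raise ValueError("SVRConfig: n_permutations must be >= 0")
        if self.tol <= 0:
            raise ValueError("SVRConfig: tol must be positive")


@dataclass
class DeconvResult:
    """Estimated fractions plus per-sample fit statistics.

    ``proportions`` is samples x types, rows non-negative and summing to
    one. ``rmse`` and ``pearson_r`` describe the reconstruction of the
    standardized mixture; ``p_value`` is the permutation p (NaN when
    permutations were disabled).
    """

    proportions: pd.DataFrame
    rmse: pd.Series
    pearson_r: pd.Series
    p_value: pd.Series
    engine: str
    signature: str = "signature"
    converged: pd.Series | None = None

    def to_frame(self) -> pd.DataFrame:
        out = self.proportions.copy()
        out["rmse"] = self.rmse
        out["pearson_r"] = self.pearson_r
        out["p_value"] = self.p_value
        out["engine"] = self.engine
        out["signature"] = self.signature
        if self.converged is not None:
            out["converged"] = self.converged
        return out


def _shared_genes(mixture: pd.DataFrame, genes: pd.Index) -> pd.Index:
    shared = mixture.index.intersection(genes)
    if len(shared) < 2:
        raise ValueError(
            f"deconvolution requires >= 2 shared genes; found {len(shared)}"
        )
    return shared


def _fit_sample(X: np.ndarray, y: np.ndarray, cfg: SVRConfig) -> tuple[np.ndarray, float, float]:
    """Fit the nu grid on one standardized sample; return (fractions, rmse, r)."""
    best = None
    for nu in cfg.nu_grid:
        model = NuSVR(kernel="linear", nu=nu, C=cfg.C, tol=cfg.tol)
        model.fit(X, y)
        w = model.coef_.ravel().copy()
        w[w < 0] = 0.0
        total = w.sum()
        if total <= 0:
            continue
        w /= total
        recon = X @ w
        rmse = float(np.sqrt(np.mean((recon - y) ** 2)))
        r = float(np.corrcoef(recon, y)[0, 1]) if np.std(recon) > 0 else 0.0
        if best is None or rmse < best[1]:
            best = (w, rmse, r)
    if best is None:
        # all-negative coefficients at every nu: degenerate flat answer
        k = X.shape[1]
        return np.full(k, 1.0 / k), float("nan"), 0.0
    return best


def svr_deconvolve(
    mixture: pd.DataFrame,
    signature: SignatureMatrix,
    cfg: SVRConfig = SVRConfig(),
    seed: int = 0,
) -> DeconvResult:
    """Estimate cell-type fractions per mixture column by linear nu-SVR.

    Per sample: restrict to genes shared with the signature, z-score the
    signature block and the sample vector, fit a linear nu-SVR for each nu
    in the grid, keep the fit with the lowest reconstruction RMSE, clip
    negative coefficients to zero and renormalize to sum one. The
    permutation p-value is the fraction of random pseudo-mixtures (gene
    values resampled with replacement from the whole mixture matrix) whose
    reconstruction Pearson R reaches the observed R.
    """
    shared = _shared_genes(mixture, signature.genes)
    S = signature.values.loc[shared].to_numpy(dtype=float)
    M = mixture.loc[shared].to_numpy(dtype=float)
    if np.any(M.sum(axis=0) <= 0):
        bad = list(mixture.columns[M.sum(axis=0) <= 0])
        raise ValueError(f"svr_deconvolve: all-zero sample(s) on shared genes: {bad}")

    if cfg.standardize:
        Xs = (S - S.mean()) / S.std()
    else:
        Xs = S
    rng = np.random.default_rng(seed)

    def standardize_y(y: np.ndarray) -> np.ndarray:
        sd = y.std()
        return (y - y.mean()) / sd if (cfg.standardize and sd > 0) else y

    n_samples = mixture.shape[1]
    props = np.zeros((n_samples, S.shape[1]))
    rmses, rs = np.zeros(n_samples), np.zeros(n_samples)
    for i in range(n_samples):
        w, rmse, r = _fit_sample(Xs, standardize_y(M[:, i]), cfg)
        props[i], rmses[i], rs[i] = w, rmse, r

    pvals = np.full(n_samples, np.nan)
    if cfg.n_permutations > 0:
        pool = M.ravel()
        null_r = np.empty(cfg.n_permutations)
        for b in range(cfg.n_permutations):
            y = standardize_y(rng.choice(pool, size=len(shared), replace=True))
            _, _, null_r[b] = _fit_sample(Xs, y, cfg)
        pvals = np.array(
            [(np.sum(null_r >= r_obs) + 0.0) / cfg.n_permutations for r_obs in rs]
        )

    idx = mixture.columns
    return DeconvResult(
        proportions=pd.DataFrame(props, index=idx, columns=signature.types),
        rmse=pd.Series(rmses, index=idx, name="rmse"),
        pearson_r=pd.Series(rs, index=idx, name="pearson_r"),
        p_value=pd.Series(pvals, index=idx, name="p_value"),
        engine="svr",
        signature=signature.name,
    )


# --------------------------------------------------------------------------
# single-cell-mode signature construction


def build_signature_from_cells(
    data: AnnotatedCounts,
    genes_per_type: Sequence[int] = (50, 100, 150, 200, 250, 300),
    min_cells: int = 50,
    min_cpm: float = 1.0,
    cond_max: float = 1e12,
) -> SignatureMatrix:
    """Marker-free signature from annotated cells.

    Types with fewer than ``min_cells`` cells are excluded. Candidate genes
    are ranked per type by the fold change of the type's mean CPM over the
    maximum mean of the other types; for each candidate size G the union of
    per-type top-G sets forms a signature, and the G whose matrix has the
    smallest 2-norm condition number is selected (ill-conditioned matrices
    make the mixture inversion unstable). Genes at or below ``min_cpm`` in
    every type are excluded up front.
    """
    counts = data.annotation["cell_type"].value_counts()
    keep = [t for t in counts.index if counts[t] >= min_cells]
    if len(keep) < 2:
        raise ValueError("build_signature_from_cells: need >= 2 types with enough cells")
    dropped = sorted(set(counts.index) - set(keep))
    if dropped:
        logger.info("build_signature_from_cells: excluding low-count types %s", dropped)

    profiles = type_mean_cpm(data)[keep]
    profiles = profiles[profiles.max(axis=1) > min_cpm]
    P = profiles.to_numpy()
    order = {}
    for j, t in enumerate(keep):
        others = np.delete(P, j, axis=1).max(axis=1)
        fc = P[:, j] / (others + 1.0)
        # descending fold change; ties by gene id for reproducibility
        order[t] = profiles.index.to_numpy()[
            np.lexsort((profiles.index.to_numpy(), -fc))
        ]

    best: tuple[float, int, SignatureMatrix] | None = None
    for g in genes_per_type:
        members = {t: list(order[t][:g]) for t in keep}
        union: list[str] = []
        seen: set[str] = set()
        for t in keep:
            for gene in members[t]:
                if gene not in seen:
                    seen.add(gene)
                    union.append(gene)
        sub = profiles.loc[union]
        cond = float(np.linalg.cond(sub.to_numpy()))
        if not np.isfinite(cond) or cond > cond_max:
            continue
        if best is None or cond < best[0]:
            best = (cond, g, SignatureMatrix(values=sub, members=members, name=f"sc_top{g}"))
    if best is None:
        raise ValueError(
            "build_signature_from_cells: signature singular or ill-conditioned at every size"
        )
    logger.info(
        "build_signature_from_cells: selected top-%d per type (condition number %.1f)",
        best[1], best[0],
    )
    return best[2]


# --------------------------------------------------------------------------
# weighted NNLS against multi-subject profiles


@dataclass
class SubjectProfiles:
    """Per-(subject, type) mean CPM profiles with cell counts and per-type
    mean library sizes (cell size factors).

    ``profiles[subject]`` is a genes x types DataFrame of the subject's
    type profiles (CPM of pooled counts); ``mean_profile`` averages the
    subjects that contribute each type; ``size_factors`` carry the mean
    per-cell library size per type, converting RNA-mass coefficients into
    cell-count fractions.
    """

    profiles: dict[str, pd.DataFrame]
    mean_profile: pd.DataFrame
    cross_subject_var: pd.DataFrame
    size_factors: pd.Series
    cell_counts: pd.DataFrame

    @property
    def types(self) -> list[str]:
        return list(self.mean_profile.columns)


def build_subject_profiles(data: AnnotatedCounts, min_cells: int = 50) -> SubjectProfiles:
    """Summarize an annotated reference into per-subject type profiles."""
    ann = data.annotation
    counts = ann["cell_type"].value_counts()
    types = [t for t in counts.index if counts[t] >= min_cells]
    if len(types) < 2:
        raise ValueError("build_subject_profiles: need >= 2 types with enough cells")
    subjects = list(pd.unique(ann["subject"]))
    genes = data.matrix.index

    ncell = pd.DataFrame(0, index=subjects, columns=types)
    lib_tot = pd.Series(0.0, index=types)
    blocks: dict[str, pd.DataFrame] = {}
    for s in subjects:
        block = pd.DataFrame(np.nan, index=genes, columns=types)
        for t in types:
            cells = ann.index[(ann["subject"] == s) & (ann["cell_type"] == t)]
            if len(cells) == 0:
                continue
            summed = data.matrix[list(cells)].sum(axis=1).astype(float)
            block[t] = summed / summed.sum() * 1e6
            ncell.loc[s, t] = len(cells)
            lib_tot[t] += summed.sum()
        blocks[s] = block

    cube = np.stack([blocks[s].to_numpy() for s in subjects])  # subjects x genes x types
    with np.errstate(invalid="ignore"):
        mean_profile = pd.DataFrame(np.nanmean(cube, axis=0), index=genes, columns=types)
        var = pd.DataFrame(
            np.nan_to_num(np.nanvar(cube, axis=0, ddof=0)), index=genes, columns=types
        )
    size = pd.Series(
        {t: lib_tot[t] / max(int(ncell[t].sum()), 1) for t in types}, name="size_factor"
    )
    if len(subjects) < 2:
        logger.warning(
            "build_subject_profiles: single subject; weights degenerate to unweighted NNLS"
        )
    return SubjectProfiles(
        profiles=blocks,
        mean_profile=mean_profile.fillna(0.0),
        cross_subject_var=var,
        size_factors=size,
        cell_counts=ncell,
    )


def wnnls_deconvolve(
    mixture: pd.DataFrame,
    profiles: SubjectProfiles,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> DeconvResult:
    """Iteratively re-weighted NNLS cell-fraction estimation.

    The design matrix holds type mean profiles scaled by per-type cell
    size factors, so the non-negative coefficients are proportional to
    cell-count fractions. Each iteration solves NNLS with per-gene
    weights ``w_g = 1 / (eps + var_g)`` where ``var_g`` is the
    cross-subject variance of the reconstructed expression under the
    current fractions; iteration stops when the largest fraction change
    falls below ``tol``. With homoscedastic profiles (zero cross-subject
    variance) the result equals unweighted NNLS.
    """
    shared = _shared_genes(mixture, profiles.mean_profile.index)
    types = profiles.types
    mp = profiles.mean_profile.loc[shared]
    var = profiles.cross_subject_var.loc[shared]
    size = profiles.size_factors[types].to_numpy()
    D = mp.to_numpy() * size[None, :] / 1e6  # genes x types design
    V = var.to_numpy() * (size[None, :] / 1e6) ** 2
    M = mixture.loc[shared].to_numpy(dtype=float) / 1e6

    n_samples = mixture.shape[1]
    props = np.zeros((n_samples, len(types)))
    rmses, rs = np.zeros(n_samples), np.zeros(n_samples)
    conv = np.zeros(n_samples, dtype=bool)
    for i in range(n_samples):
        y = M[:, i]
        coef, _ = nnls(D, y)
        p = coef / coef.sum() if coef.sum() > 0 else np.full(len(types), 1.0 / len(types))
        converged = False
        for _ in range(max_iter):
            recon_var = V @ (coef**2) if coef.sum() > 0 else V.mean(axis=1)
            eps = 1e-8 * max(float(recon_var.mean()), 1e-300)
            w = 1.0 / (eps + recon_var)
            sw = np.sqrt(w / w.max())
            coef, _ = nnls(D * sw[:, None], y * sw)
            p_new = coef / coef.sum() if coef.sum() > 0 else p
            if np.max(np.abs(p_new - p)) < tol:
                p = p_new
                converged = True
                break
            p = p_new
        if not converged:
            logger.warning("wnnls_deconvolve: sample %s did not converge", mixture.columns[i])
        props[i] = p
        recon = D @ coef
        rmses[i] = float(np.sqrt(np.mean((recon - y) ** 2)))
        rs[i] = float(np.corrcoef(recon, y)[0, 1]) if np.std(recon) > 0 else 0.0
        conv[i] = converged

    idx = mixture.columns
    return DeconvResult(
        proportions=pd.DataFrame(props, index=idx, columns=types),
        rmse=pd.Series(rmses, index=idx, name="rmse"),
        pearson_r=pd.Series(rs, index=idx, name="pearson_r"),
        p_value=pd.Series(np.nan, index=idx, name="p_value"),
        engine="wnnls",
        signature="subject_profiles",
        converged=pd.Series(conv, index=idx, name="converged"),
    )
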