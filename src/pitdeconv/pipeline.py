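"""Top-level pipeline: reference -> signature -> benchmark -> contamination.

Runs the full workflow on either bundled synthetic inputs or files named
in the configuration, persisting every stage's output and the effective
configuration (seed included) to a run directory so two runs with the
same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .benchmark import benchmark_matrix
from .contamination import LineageMap, bulk_cpm, contamination_report
from .engines import (
    SVRConfig,
    build_signature_from_cells,
    build_subject_profiles,
    svr_deconvolve,
    wnnls_deconvolve,
)
from .prep import (
    QCThresholds,
    build_ges,
    cpm_normalize,
    find_markers,
    log_transform,
    qc_filter,
)
from .pseudobulk import simulate_pseudobulk
from .simulate import SimConfig, generate_bulk_cohort, generate_reference, type_mean_cpm

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; defaults give the synthetic demo."""

    seed: int = 0
    reference_path: str | None = None  # directory for read_annotated_counts; None -> simulate
    sim: SimConfig = field(default_factory=SimConfig)
    qc: QCThresholds = field(default_factory=QCThresholds)
    ges_sizes: tuple[int, ...] = (50, 100, 200, 300)
    engines: tuple[str, ...] = ("svr_sc", "svr_ges", "wnnls")
    svr: SVRConfig = field(default_factory=lambda: SVRConfig(n_permutations=0))
    n_samples: int = 150
    cells_per_sample: int = 500
    min_cells: int = 50
    r_threshold: float = 0.70
    p_threshold: float = 0.05
    bulk_counts_path: str | None = None  # TSV genes x samples; None -> simulate cohort
    bulk_samples_path: str | None = None  # TSV sample sheet (sample_id, histotype, batch)
    bulk_tumor_type: str = "somatotroph"
    bulk_fractions: tuple[float, ...] = (0.0, 0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
    bulk_reads: int = 2_000_000
    flag_threshold: float = 0.20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "sim" in kwargs:
            sim = dict(kwargs["sim"])
            if "mito_fraction_range" in sim:
                sim["mito_fraction_range"] = tuple(sim["mito_fraction_range"])
            kwargs["sim"] = SimConfig(**sim)
        if "qc" in kwargs:
            kwargs["qc"] = QCThresholds(**kwargs["qc"])
        if "svr" in kwargs:
            svr = dict(kwargs["svr"])
            if "nu_grid" in svr:
                svr["nu_grid"] = tuple(svr["nu_grid"])
            kwargs["svr"] = SVRConfig(**svr)
        for key in ("ges_sizes", "engines", "bulk_fractions"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Execute prep -> signature -> simulate -> deconvolve -> evaluate ->
    contamination, writing each stage's artifact under ``outdir``.

    Returns a dict of stage name -> written path. A stage failure raises
    with the stage name; artifacts written so far remain on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def _persist(name: str, path: Path) -> None:
        artifacts[name] = path
        logger.info("stage %s -> %s", name, path)

    cfg_path = outdir / "effective_config.yaml"
    cfg_path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    _persist("config", cfg_path)

    stage = "reference"
    try:
        if config.reference_path:
            reference = pio.read_annotated_counts(config.reference_path)
        else:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            reference = generate_reference(sim)
        reference = qc_filter(reference, config.qc)
        if reference.matrix.shape[1] == 0:
            raise ValueError("QC removed every cell; relax the thresholds")
        pio.write_annotated_counts(reference, outdir / "reference", fmt="mtx_dir")
        _persist(stage, outdir / "reference")

        stage = "signature"
        cpm = cpm_normalize(reference.matrix)
        logcpm = log_transform(cpm, base="e")
        markers = find_markers(
            logcpm, reference.annotation["cell_type"], min_cells=config.min_cells, cpm=cpm
        )
        markers.to_csv(outdir / "markers.tsv", sep="\t", index=False)
        profiles = type_mean_cpm(reference)
        ges = {}
        for n in config.ges_sizes:
            sig = build_ges(markers, profiles, n=n)
            ges[n] = sig
            pio.write_signature(sig, outdir / f"ges{n}.tsv")
        sc_sig = build_signature_from_cells(reference, min_cells=config.min_cells)
        pio.write_signature(sc_sig, outdir / "signature_sc.tsv")
        _persist(stage, outdir / "signature_sc.tsv")

        stage = "pseudobulk"
        mixtures = simulate_pseudobulk(
            reference, config.n_samples, config.cells_per_sample, seed=config.seed + 1
        )
        pio.write_expression(mixtures.mixtures, outdir / "pseudobulk.tsv")
        mixtures.true_proportions.to_csv(outdir / "true_proportions.tsv", sep="\t")
        _persist(stage, outdir / "pseudobulk.tsv")

        stage = "benchmark"
        profiles_subj = build_subject_profiles(reference, min_cells=config.min_cells)
        engine_fns = {}
        if "svr_sc" in config.engines:
            engine_fns["svr_sc"] = lambda m: svr_deconvolve(m, sc_sig, config.svr, seed=config.seed)
        if "svr_ges" in config.engines:
            best_n = max(ges)
            engine_fns[f"svr_ges{best_n}"] = lambda m: svr_deconvolve(
                m, ges[best_n], config.svr, seed=config.seed
            )
        if "wnnls" in config.engines:
            engine_fns["wnnls"] = lambda m: wnnls_deconvolve(m, profiles_subj)
        report = benchmark_matrix(
            engine_fns, mixtures, config.r_threshold, config.p_threshold
        )
        report.to_csv(outdir / "benchmark.tsv", sep="\t", index=False)
        _persist(stage, outdir / "benchmark.tsv")

        stage = "contamination"
        if config.bulk_counts_path:
            bulk_counts = pio.read_expression(config.bulk_counts_path)
            sheet = pd.read_csv(config.bulk_samples_path, sep="\t", index_col="sample_id")
            histotypes = sheet["histotype"]
        else:
            bulk_counts, _, histotypes = generate_bulk_cohort(
                reference,
                config.bulk_tumor_type,
                config.bulk_fractions,
                reads_per_sample=config.bulk_reads,
                seed=config.seed + 2,
            )
        bulk = bulk_cpm(bulk_counts)
        deconv = svr_deconvolve(bulk, sc_sig, config.svr, seed=config.seed)
        deconv.to_frame().to_csv(outdir / "bulk_deconvolution.tsv", sep="\t")
        creport, summary = contamination_report(
            deconv.proportions, histotypes, LineageMap(), config.flag_threshold
        )
        creport.to_csv(outdir / "contamination.tsv", sep="\t")
        (outdir / "contamination_summary.json").write_text(json.dumps(summary, indent=1))
        _persist(stage, outdir / "contamination.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return artifacts
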