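"""End-to-end orchestration: simulate or load, then run every stage per tissue.

Stage order mirrors the analysis workflow: low-count filtering and
normalization, differential expression between conditions, per-gene stage
correlations with set algebra, PCA on the DE and stage-correlated gene
subsets with factor overlays and the quadrant Fisher test, sex inference
from X / Y markers, and the cross-tissue congruence and coordination
comparisons. All stages run deterministically from one seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import crosstissue, diffexpr, io, multivariate, preprocess, stagecorr
from .datamodel import Dataset, ValidationError
from .simulate import SimConfig, simulate_dataset

logger = logging.getLogger("conceptome")


@dataclass
class PipelineConfig:
    """Inputs and thresholds for a full run.

    Exactly one of ``input_paths`` (mapping with keys ``counts_embryo``,
    ``counts_yolk_sac``, ``metadata``, ``annotation``) or ``sim`` (a
    :class:`SimConfig`) must be provided.
    """

    input_paths: dict | None = None
    sim: SimConfig | None = None
    filter_policy: str = "mean"
    filter_min: float = 3.0
    de_alpha: float = 0.1
    fc_threshold: float = 1.5
    corr_cutoff: float = 0.5
    shift_delta: float = 0.2
    pca_max_dim: int = 10
    n_permutations: int = 1000
    seed: int = 0
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if (self.input_paths is None) == (self.sim is None):
            raise ValidationError(
                "provide exactly one of input_paths or a simulation config")
        if not 0 < self.de_alpha < 1:
            raise ValidationError("de_alpha must be in (0, 1)")
        if not 0 < self.corr_cutoff < 1:
            raise ValidationError("corr_cutoff must be in (0, 1)")
        if self.shift_delta < 0 or self.shift_delta > 2:
            raise ValidationError("shift_delta must be in [0, 2]")


@dataclass
class PipelineResult:
    """All per-stage outputs plus the JSON-serializable summary."""

    dataset: Dataset
    de: dict[str, pd.DataFrame]
    stage_records: dict[str, pd.DataFrame]
    set_summary: dict[str, stagecorr.CorrSetSummary]
    pca_de: dict[str, multivariate.PCAResult]
    pca_stage: dict[str, multivariate.PCAResult]
    sex_calls: pd.DataFrame
    summary: dict = field(default_factory=dict)


def _load_dataset(paths: dict) -> Dataset:
    counts = {
        "embryo": io.read_counts(paths["counts_embryo"]),
        "yolk_sac": io.read_counts(paths["counts_yolk_sac"]),
    }
    meta = io.read_metadata(paths["metadata"])
    annotation = io.read_annotation(paths["annotation"])
    from .datamodel import validate_dataset
    return validate_dataset(counts, meta, annotation)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage for both tissues and assemble the summary."""
    if config.sim is not None:
        logger.info("simulating dataset (seed=%d)", config.seed)
        dataset, _truth = simulate_dataset(config.sim, config.seed)
    else:
        logger.info("loading dataset from %s", config.input_paths)
        dataset = _load_dataset(config.input_paths)

    summary: dict = {"seed": config.seed,
                     "thresholds": {"filter_min": config.filter_min,
                                    "filter_policy": config.filter_policy,
                                    "de_alpha": config.de_alpha,
                                    "fc_threshold": config.fc_threshold,
                                    "corr_cutoff": config.corr_cutoff,
                                    "shift_delta": config.shift_delta}}
    de, stage_records, set_summary = {}, {}, {}
    pca_de, pca_stage = {}, {}
    norms = {}
    for tissue in ("embryo", "yolk_sac"):
        stage_name = f"{tissue}:filter"
        try:
            cm = dataset.counts[tissue]
            filtered, report = preprocess.filter_low_counts(
                cm, min_per_sample=config.filter_min,
                policy=config.filter_policy)
            norm = preprocess.lognormalize(filtered)
            norms[tissue] = norm
            scaled = preprocess.scale_genes(norm)
            meta = dataset.meta

            stage_name = f"{tissue}:de"
            de_res, excluded = diffexpr.de_test(
                filtered, meta, alpha=config.de_alpha,
                fc_threshold=config.fc_threshold)
            de[tissue] = de_res
            fc = diffexpr.classify_fold_changes(de_res, config.fc_threshold)

            stage_name = f"{tissue}:stagecorr"
            records = stagecorr.stage_correlations(
                norm, meta, cutoff=config.corr_cutoff, delta=config.shift_delta)
            stage_records[tissue] = records
            algebra = stagecorr.correlation_set_algebra(
                records, cutoff=config.corr_cutoff)
            set_summary[tissue] = algebra

            stage_name = f"{tissue}:pca"
            sig_genes = de_res.loc[de_res["significant"], "gene_id"].tolist()
            corr_set, anti_set = stagecorr.select_strong(
                records, cutoff=config.corr_cutoff, stratum="all")
            stage_genes = sorted(corr_set | anti_set)
            tissue_summary = {
                "n_genes_input": report.n_input,
                "n_genes_retained": report.n_retained,
                "n_genes_excluded_all_zero": len(excluded),
                "de": fc,
                "strong_sets": algebra.to_dict(),
            }
            if len(sig_genes) >= 2:
                p_de = multivariate.pca(scaled, gene_subset=sig_genes,
                                        n_dim=config.pca_max_dim,
                                        subset_label=f"{tissue}:de_genes")
                pca_de[tissue] = p_de
                quad = multivariate.quadrant_classification(p_de, meta, dim=2)
                scan = multivariate.factor_association_scan(
                    p_de, meta, "condition", max_dim=1,
                    n_permutations=config.n_permutations, seed=config.seed)
                tissue_summary["pca_de"] = {
                    "variance_fraction_dim1": float(p_de.variance_fraction[0]),
                    "variance_fraction_dim2": float(p_de.variance_fraction[1]),
                    "condition_statistic_dim1": float(scan["statistic"][0]),
                    "quadrant": quad.to_dict(),
                }
            if len(stage_genes) >= 2:
                p_st = multivariate.pca(scaled, gene_subset=stage_genes,
                                        n_dim=config.pca_max_dim,
                                        subset_label=f"{tissue}:stage_genes")
                pca_stage[tissue] = p_st
                quad = multivariate.quadrant_classification(p_st, meta, dim=2)
                tissue_summary["pca_stage"] = {
                    "variance_fraction_dim1": float(p_st.variance_fraction[0]),
                    "variance_fraction_dim2": float(p_st.variance_fraction[1]),
                    "quadrant": quad.to_dict(),
                }
            summary[tissue] = tissue_summary
        except ValidationError as err:
            raise ValidationError(f"stage {stage_name} failed: {err}") from err

    sex_calls = preprocess.infer_sex(norms, dataset.meta,
                                     annotation=dataset.annotation)
    summary["sex_inference"] = {
        "n_conceptuses": int(len(sex_calls)),
        "n_unknown": int((sex_calls["call"] == "unknown").sum()),
        "n_female": int((sex_calls["call"] == "female").sum()),
        "n_male": int((sex_calls["call"] == "male").sum()),
    }

    cross: dict = {}
    if "embryo" in stage_records and "yolk_sac" in stage_records:
        for universe in crosstissue.GENE_UNIVERSES:
            rep = crosstissue.correlation_congruence(
                stage_records["embryo"], stage_records["yolk_sac"],
                gene_universe=universe, cutoff=config.corr_cutoff)
            cross[universe] = rep.to_dict()
    if "embryo" in de and "yolk_sac" in de:
        cross["de_direction"] = crosstissue.de_direction_congruence(
            de["embryo"], de["yolk_sac"]).to_dict()
    if "embryo" in pca_de and "yolk_sac" in pca_de:
        coord = crosstissue.composite_coordination(
            pca_de["embryo"], pca_de["yolk_sac"], dataset.meta)
        cross["coordination"] = coord.to_dict()
    summary["cross_tissue"] = cross

    result = PipelineResult(dataset=dataset, de=de, stage_records=stage_records,
                            set_summary=set_summary, pca_de=pca_de,
                            pca_stage=pca_stage, sex_calls=sex_calls,
                            summary=summary)
    if config.outdir is not None:
        _write_outputs(result, config)
    return result


def _round_floats(obj, digits: int = 10):
    if isinstance(obj, float):
        return round(obj, digits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    return obj


def summary_json(summary: dict) -> str:
    """Deterministic JSON rendering of a run summary."""
    return json.dumps(_round_floats(summary), indent=2, sort_keys=True)


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for tissue, table in result.de.items():
        io.write_table(table, outdir / f"de_{tissue}.tsv")
    for tissue, table in result.stage_records.items():
        io.write_table(table, outdir / f"stage_corr_{tissue}.tsv")
    for tissue, p in result.pca_de.items():
        coords = p.coordinates.copy()
        coords.insert(0, "sample_id", coords.index)
        io.write_table(coords, outdir / f"pca_de_coords_{tissue}.tsv")
    io.write_table(result.sex_calls, outdir / "sex_calls.tsv")
    (outdir / "summary.json").write_text(summary_json(result.summary))
    logger.info("outputs written to %s", outdir)


@dataclass
class DesignStats:
    """Litter-size comparison and glucose relationships of the design table."""

    litter_sizes: dict[str, list[int]]
    mean_litter: dict[str, float]
    ttest_p: float
    r2_litter_glucose: float

    def to_dict(self) -> dict:
        return {"litter_sizes": self.litter_sizes,
                "mean_litter": self.mean_litter, "ttest_p": self.ttest_p,
                "r2_litter_glucose": self.r2_litter_glucose}


def design_stats(pregnancies: pd.DataFrame,
                 censor_value: float = 600.0) -> DesignStats:
    """Summary statistics of a per-dam pregnancy table.

    Expects columns ``dam_id``, ``condition``, ``glucose_mating``,
    ``glucose_dissection`` and ``litter_size``. Censored glucometer readings
    (strings like ``">600"``, the reader's saturation point) are replaced by
    ``censor_value``. Reports a Welch two-sided t-test of litter size by
    condition and the squared Pearson correlation of litter size with
    glucose at dissection within the diabetic group. Identical zero-variance
    litter sizes in both groups are reported as p = 1 by convention.
    """
    req = ("dam_id", "condition", "glucose_dissection", "litter_size")
    missing = [c for c in req if c not in pregnancies.columns]
    if missing:
        raise ValidationError(f"pregnancy table missing column(s): {missing}")
    df = pregnancies.copy()
    for col in ("glucose_mating", "glucose_dissection"):
        if col in df.columns:
            df[col] = df[col].map(lambda v: _decensor(v, censor_value))
    sizes = {c: grp["litter_size"].astype(int).tolist()
             for c, grp in df.groupby("condition")}
    import warnings
    for c, vals in sizes.items():
        if len(vals) < 3:
            warnings.warn(f"condition {c!r} has < 3 dams; statistics are NaN",
                          stacklevel=2)
            return DesignStats(sizes, {c: float(np.mean(v))
                                       for c, v in sizes.items()},
                               float("nan"), float("nan"))
    a, b = sizes.get("normal", []), sizes.get("diabetic", [])
    if np.var(a) == 0 and np.var(b) == 0:
        p = 1.0 if np.mean(a) == np.mean(b) else 0.0
    else:
        p = float(sstats.ttest_ind(a, b, equal_var=False).pvalue)
    dia = df[df["condition"] == "diabetic"]
    glu = dia["glucose_dissection"].to_numpy(float)
    lit = dia["litter_size"].to_numpy(float)
    if np.var(glu) == 0 or np.var(lit) == 0:
        r2 = float("nan")
    else:
        r2 = float(sstats.pearsonr(lit, glu).statistic ** 2)
    return DesignStats(litter_sizes=sizes,
                       mean_litter={c: float(np.mean(v))
                                    for c, v in sizes.items()},
                       ttest_p=p, r2_litter_glucose=r2)


def _decensor(value, censor_value: float) -> float:
    if isinstance(value, str) and value.strip().startswith(">"):
        return float(censor_value)
    return float(value)
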