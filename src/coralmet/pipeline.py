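"""End-to-end orchestration: ingest -> preprocess -> network -> annotate ->
differential statistics -> report, driven by a single YAML config."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, network, preprocess, stats
from .io import (
    FeatureTable,
    match_spectra_to_table,
    read_mgf,
    read_quant_table,
)
from .simulate import INTERNAL_STANDARD_ID, SyntheticConfig, write_dataset

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "make_synthetic",
           "format_summary"]

log = logging.getLogger("coralmet")


@dataclass
class PipelineConfig:
    """All stage parameters, with the study's published defaults."""

    mgf: str = ""
    quant: str = ""
    metadata: str = ""
    library: str = ""  # optional MGF with NAME= entries
    pathway_map: str = ""  # optional TSV (pathway_id, metabolite_id)
    internal_standard: str = INTERNAL_STANDARD_ID
    normalize: bool = True
    cv_max: float = 0.30
    min_intensity: float = 20000.0
    frag_tol: float = 0.02
    cosine_threshold: float = 0.7
    min_matched: int = 2
    topk: int = 10
    max_component: int = 100
    library_threshold: float = 0.7
    library_min_matched: int = 2
    vip_thr: float = 1.0
    p_thr: float = 0.05
    alpha_normality: float = 0.05
    log_transform_tests: bool = True
    log_transform_multivariate: bool = True
    k_folds: int = 7
    n_perm: int = 200
    run_permutation: bool = True
    run_screening: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def format_summary(
    total: int,
    higher_a: int,
    higher_b: int,
    unique_a: int = 0,
    unique_b: int = 0,
    n_significant: int | None = None,
    group_a: str = "group A",
    group_b: str = "group B",
) -> dict:
    """Counts and one-decimal percentages for the run summary.

    Percentages are count/total rounded to one decimal on the percent
    scale (2044 of 3815 -> 53.6).
    """
    def pct(count: int) -> float:
        return round(100.0 * count / total, 1) if total else 0.0

    out = {
        "total_features": total,
        "higher_in_A": higher_a,
        "higher_in_A_pct": pct(higher_a),
        "higher_in_B": higher_b,
        "higher_in_B_pct": pct(higher_b),
        "unique_to_A": unique_a,
        "unique_to_B": unique_b,
        "group_a": group_a,
        "group_b": group_b,
    }
    if n_significant is not None:
        out["n_significant"] = n_significant
    return out


def _diversity_frame(table: FeatureTable) -> pd.DataFrame:
    rows = []
    for sample in table.samples_in_group("A") + table.samples_in_group("B"):
        d = stats.shannon_diversity(table.intensities[sample].to_numpy(), sample)
        rows.append({"sample_id": sample, "group": table.sample_group[sample],
                     "H_bits": d.H, "n_nonzero": d.n_nonzero})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write per-stage outputs under ``outdir``.

    Returns the summary dictionary (also written as summary.json). Any
    stage failure raises :class:`PipelineError` naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("parameters: %s", json.dumps(asdict(config), sort_keys=True))
    try:
        summary: dict = {}

        # ingest -----------------------------------------------------------
        stage = "ingest"
        try:
            spectra = read_mgf(config.mgf)
            table = read_quant_table(config.quant, config.metadata)
            match_spectra_to_table(spectra, table)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
        log.info("ingest: %d spectra, %d x %d table", len(spectra),
                 table.n_features, table.n_samples)

        # preprocess -------------------------------------------------------
        stage = "preprocess"
        try:
            if config.normalize:
                table = preprocess.normalize_internal_standard(
                    table, config.internal_standard
                )
            table, removed = preprocess.qc_cv_filter(table, config.cv_max)
            if config.internal_standard in table.intensities.index:
                table = table.subset_features(
                    [f for f in table.feature_ids if f != config.internal_standard]
                )
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
        log.info("preprocess: removed %d features by QC CV", len(removed))
        spectra = [s for s in spectra if s.feature_id in set(table.feature_ids)]

        # network ----------------------------------------------------------
        stage = "network"
        try:
            net = network.build_network(
                spectra,
                score_threshold=config.cosine_threshold,
                min_matched=config.min_matched,
                topk=config.topk,
                max_component=config.max_component,
                frag_tol=config.frag_tol,
                min_intensity=config.min_intensity,
            )
            network.write_graphml(net, outdir / "network.graphml")
            network.write_edge_list(net, outdir / "network_edges.tsv")
            families = network.connected_families(net)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc
        log.info("network: %d edges, %d families of size >= 2",
                 net.number_of_edges(),
                 sum(1 for f in families if len(f) > 1))

        # annotate ---------------------------------------------------------
        stage = "annotate"
        annotations = []
        try:
            if config.library:
                library = read_mgf(config.library)
                for spec in spectra:
                    hits = annotate.library_search(
                        network.filter_peaks(spec, config.min_intensity),
                        library,
                        config.library_threshold,
                        config.library_min_matched,
                        config.frag_tol,
                    )
                    if hits:
                        annotations.append(hits[0])
                pd.DataFrame(
                    [
                        {"feature_id": h.feature_id, "name": h.compound_name,
                         "level": h.annotation_level, "score": h.score}
                        for h in annotations
                    ]
                ).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        # diffstats --------------------------------------------------------
        stage = "diffstats"
        try:
            X, y = preprocess.analysis_matrix(table)
            venn = stats.venn_counts(table)
            _diversity_frame(table).to_csv(
                outdir / "diversity.tsv", sep="\t", index=False
            )
            counts = {"total_significant": 0, "higher_in_A": 0, "higher_in_B": 0}
            Xmv = X.to_numpy(float)
            if config.log_transform_multivariate:
                Xmv = preprocess.log_intensities(Xmv)
            pca = stats.fit_pca(preprocess.scale(Xmv, "unit_variance").values)
            pd.DataFrame(
                {
                    "sample_id": list(X.index),
                    "group": ["A" if g == 0 else "B" for g in y],
                    "PC1": pca.scores[:, 0],
                    "PC2": pca.scores[:, 1],
                    "T2": pca.t2,
                    "within_95_ellipse": pca.within_ellipse,
                }
            ).to_csv(outdir / "pca_scores.tsv", sep="\t", index=False)
            if config.run_screening:
                model = stats.OPLSDA(
                    scale="pareto", k_folds=config.k_folds,
                    random_state=config.seed,
                ).fit(Xmv, y)
                tests = stats.gated_tests_matrix(
                    X.to_numpy(float), y, config.alpha_normality,
                    log_transform=config.log_transform_tests,
                )
                p_adj = stats.adjust_pvalues([t.p_value for t in tests])
                mean_a = X.to_numpy(float)[y == 0].mean(axis=0)
                mean_b = X.to_numpy(float)[y == 1].mean(axis=0)
                results, counts = stats.screen_differential(
                    list(X.columns), model.vip_, p_adj, mean_a, mean_b,
                    p_raw=np.array([t.p_value for t in tests]),
                    test_used=[t.test_used for t in tests],
                    vip_thr=config.vip_thr, p_thr=config.p_thr,
                )
                pd.DataFrame([asdict(r) for r in results]).to_csv(
                    outdir / "differential.tsv", sep="\t", index=False
                )
                model_summary = {
                    "R2X": model.r2x_, "R2Y": model.r2y_, "Q2": model.q2_,
                    "n_orthogonal": model.n_orthogonal_,
                }
                if config.run_permutation:
                    perm = stats.permutation_test(
                        Xmv, y, n_perm=config.n_perm,
                        seed=config.seed, scale="pareto",
                        k_folds=config.k_folds,
                    )
                    model_summary["permutation_p"] = perm.p_empirical
                    model_summary["q2_intercept"] = perm.q2_intercept
                    model_summary["r2y_intercept"] = perm.r2y_intercept
                (outdir / "model.json").write_text(
                    json.dumps(model_summary, indent=2, sort_keys=True)
                )
            if config.pathway_map and counts["total_significant"]:
                pmap = stats.read_pathway_map(config.pathway_map)
                diff_ids = [r.feature_id for r in results if r.significant]
                stats.pathway_ora(
                    diff_ids, list(X.columns), pmap
                ).to_csv(outdir / "pathway_ora.tsv", sep="\t", index=False)

            higher_a = int((X.to_numpy(float)[y == 0].mean(axis=0)
                            > X.to_numpy(float)[y == 1].mean(axis=0)).sum())
            higher_b = int((X.to_numpy(float)[y == 1].mean(axis=0)
                            > X.to_numpy(float)[y == 0].mean(axis=0)).sum())
            summary = format_summary(
                total=table.n_features,
                higher_a=higher_a,
                higher_b=higher_b,
                unique_a=len(venn.unique_to_a),
                unique_b=len(venn.unique_to_b),
                n_significant=(
                    counts["total_significant"] if config.run_screening else None
                ),
            )
            if config.run_screening:
                summary["significant_higher_in_A"] = counts["higher_in_A"]
                summary["significant_higher_in_B"] = counts["higher_in_B"]
            summary["n_network_edges"] = net.number_of_edges()
            summary["n_molecular_families"] = sum(
                1 for f in families if len(f) > 1
            )
            summary["n_annotated"] = len(annotations)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(stage, exc) from exc

        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        log.info("summary: %s", json.dumps(summary, sort_keys=True))
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()


def make_synthetic(config: SyntheticConfig, outdir: str | Path) -> PipelineConfig:
    """Write a synthetic dataset and return a PipelineConfig pointing at it."""
    mgf, quant, meta, _truth = write_dataset(config, outdir)
    return PipelineConfig(
        mgf=str(mgf), quant=str(quant), metadata=str(meta), seed=config.seed
    )
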