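"""End-to-end orchestration: score -> rank/segregate -> correlate ->
exclusivity -> group comparison -> survival, from a single config, with a
machine-readable JSON report.

Stage order is fixed; a failure in any stage aborts the run with an error
naming that stage. The report carries a provenance block (config hash, seed,
package version) and validates against the JSON schema shipped as
``report_schema.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._schema import validate as validate_schema
from .datatypes import ScoreTable, SignatureDefinition, ZScoreResult
from .io import (
    gene_sets_to_signatures,
    read_annotations,
    read_expression_matrix,
    read_gene_sets_gmt,
    write_json,
    write_score_table,
)
from .scoring import compute_zscores, dichotomize_gene, rank_and_segregate, score_all
from .simulate import (
    SLUG_OE,
    STAT3,
    EMT,
    STEM_PROGENITOR,
    GeneratorConfig,
    generate_cohort,
)
from .stats import compare_groups_welch, mutual_exclusivity, pearson_correlation
from .survival import geometric_mean_split, km_estimate, logrank_test, quadrant_stratify

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "run_pipeline",
    "order_heatmap_matrix",
]


class PipelineStageError(RuntimeError):
    """Raised when a pipeline stage fails; message is prefixed by the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"{stage}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run.

    Exactly one of the file-input triple (``expression_path`` +
    ``gene_sets_path`` [+ ``annotations_path``]) or ``generator`` must be
    supplied. When the generator is used, ``seed`` overrides the generator's
    own seed so a run has a single source of randomness.
    """

    output_dir: str = "sigscore_out"
    seed: int = 0
    # inputs (file mode)
    expression_path: str | None = None
    gene_sets_path: str | None = None
    annotations_path: str | None = None
    # inputs (generator mode)
    generator: GeneratorConfig | None = None
    # scoring options
    log_transform: bool = True
    segregation_threshold: float = 0.0
    dichotomization_z: float = 1.0
    ranking_signature: str = STEM_PROGENITOR
    # analysis toggles / selections
    run_correlations: bool = True
    correlation_pairs: list[tuple[str, str]] | None = None  # None -> all pairs
    run_exclusivity: bool = True
    exclusivity_gene_pairs: list[tuple[str, str]] | None = None
    run_group_comparison: bool = True
    group_comparison_score: str = SLUG_OE
    group_comparison_column: str = "primary_or_recurrent"
    run_survival: bool = True
    survival_split_gene: str | None = None
    quadrant_scores: tuple[str, str] = (STAT3, EMT)
    geometric_mean_pseudocount: float = 0.0

    def __post_init__(self) -> None:
        file_mode = self.expression_path is not None
        gen_mode = self.generator is not None
        if file_mode == gen_mode:
            raise ValueError(
                "exactly one of expression_path/gene_sets_path or generator "
                "must be supplied"
            )
        if file_mode and self.gene_sets_path is None:
            raise ValueError("file mode requires gene_sets_path")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        if gen is not None:
            raw["generator"] = GeneratorConfig(**gen)
        if "correlation_pairs" in raw and raw["correlation_pairs"] is not None:
            raw["correlation_pairs"] = [tuple(p) for p in raw["correlation_pairs"]]
        if "exclusivity_gene_pairs" in raw and raw["exclusivity_gene_pairs"] is not None:
            raw["exclusivity_gene_pairs"] = [
                tuple(p) for p in raw["exclusivity_gene_pairs"]
            ]
        if "quadrant_scores" in raw:
            raw["quadrant_scores"] = tuple(raw["quadrant_scores"])
        return cls(**raw)

    def canonical_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if self.generator is not None:
            out["generator"] = dataclasses.asdict(self.generator)
        return out


def _config_hash(config: PipelineConfig) -> str:
    canon = config.canonical_dict()
    canon.pop("output_dir", None)  # output location is not analysis-relevant
    return hashlib.sha256(
        json.dumps(canon, sort_keys=True, default=str).encode()
    ).hexdigest()


def _load_inputs(config: PipelineConfig):
    if config.generator is not None:
        gen = dataclasses.replace(config.generator, seed=config.seed)
        cohort = generate_cohort(gen)
        return cohort.expression, cohort.signatures, cohort.annotations
    expr = read_expression_matrix(config.expression_path)
    sigs = gene_sets_to_signatures(read_gene_sets_gmt(config.gene_sets_path))
    ann = None
    if config.annotations_path is not None:
        ann = read_annotations(config.annotations_path)
        missing = ann.index.difference(expr.columns)
        if len(missing):
            raise ValueError(
                f"annotated samples absent from the expression matrix: "
                f"{missing.tolist()[:5]}"
            )
    return expr, sigs, ann


def _default_exclusivity_pairs(
    config: PipelineConfig, sigs: list[SignatureDefinition]
) -> list[tuple[str, str]]:
    if config.exclusivity_gene_pairs is not None:
        return config.exclusivity_gene_pairs
    by_name = {s.name: s for s in sigs}
    slug = by_name.get(SLUG_OE)
    if slug is not None and slug.down_set is not None:
        # planted anti-aligned pair: one SLUG-up and one SLUG-down gene
        return [(slug.up_set.genes[0], slug.down_set.genes[0])]
    return []


def _default_split_gene(
    config: PipelineConfig, sigs: list[SignatureDefinition]
) -> str | None:
    if config.survival_split_gene is not None:
        return config.survival_split_gene
    by_name = {s.name: s for s in sigs}
    slug = by_name.get(SLUG_OE)
    if slug is not None:
        return slug.up_set.genes[0]
    return None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report dict and writes
    ``scores.tsv``, ``report.json``, ``survival_curves.tsv`` and ``run.log``
    into ``config.output_dir``."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("sigscore")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> dict:
    report: dict = {
        "provenance": {
            "package": "sigscore",
            "version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
        },
        "multiple_testing_correction": "none",
    }

    # ---- stage: inputs -------------------------------------------------
    try:
        expr, sigs, ann = _load_inputs(config)
        logger.info(
            "inputs: %d genes x %d samples, %d signatures, annotations=%s",
            expr.shape[0],
            expr.shape[1],
            len(sigs),
            "yes" if ann is not None else "no",
        )
    except Exception as exc:
        raise PipelineStageError("inputs", str(exc)) from exc

    # ---- stage: scoring ------------------------------------------------
    try:
        zres = compute_zscores(expr, log_transform=config.log_transform)
        table = score_all(zres, sigs)
        write_score_table(table, outdir / "scores.tsv")
        logger.info(
            "scoring: %d signatures, coverage %s",
            len(sigs),
            {k: round(v, 3) for k, v in table.coverage.items()},
        )
        report["scores_file"] = "scores.tsv"
        report["coverage"] = {k: float(v) for k, v in table.coverage.items()}
    except Exception as exc:
        raise PipelineStageError("scoring", str(exc)) from exc

    # ---- stage: ranking ------------------------------------------------
    try:
        if config.ranking_signature not in table.scores.columns:
            raise ValueError(
                f"ranking signature {config.ranking_signature!r} not among scores"
            )
        order, labels = rank_and_segregate(
            table.scores[config.ranking_signature],
            threshold=config.segregation_threshold,
        )
        n_high = int((labels == "high").sum())
        logger.info("ranking: %d high / %d low", n_high, len(labels) - n_high)
        report["ranking"] = {
            "signature": config.ranking_signature,
            "threshold": config.segregation_threshold,
            "order": list(map(str, order)),
            "labels": {str(k): v for k, v in labels.items()},
        }
    except Exception as exc:
        raise PipelineStageError("ranking", str(exc)) from exc

    # ---- stage: correlations -------------------------------------------
    if config.run_correlations:
        try:
            pairs = config.correlation_pairs
            if pairs is None:
                pairs = list(itertools.combinations(table.scores.columns, 2))
            entries = []
            for a, b in pairs:
                res = pearson_correlation(table.scores[a], table.scores[b])
                entries.append({"signatures": [a, b], **res.to_dict()})
            logger.info("correlations: %d pair(s)", len(entries))
            report["correlations"] = entries
        except Exception as exc:
            raise PipelineStageError("correlations", str(exc)) from exc

    # ---- stage: exclusivity --------------------------------------------
    if config.run_exclusivity:
        try:
            entries = []
            for ga, gb in _default_exclusivity_pairs(config, sigs):
                la = dichotomize_gene(zres, ga, z_threshold=config.dichotomization_z)
                lb = dichotomize_gene(zres, gb, z_threshold=config.dichotomization_z)
                res = mutual_exclusivity(la, lb)
                entries.append(
                    {
                        "genes": [ga, gb],
                        "table": res.table.as_list(),
                        **res.fisher.to_dict(),
                        "co_occurrence": res.co_occurrence,
                        "exclusive": res.exclusive,
                    }
                )
            logger.info("exclusivity: %d pair(s)", len(entries))
            report["exclusivity"] = entries
        except Exception as exc:
            raise PipelineStageError("exclusivity", str(exc)) from exc

    # ---- stage: group_comparison ---------------------------------------
    if config.run_group_comparison:
        try:
            entries = []
            col = config.group_comparison_column
            if ann is not None and col in ann.columns:
                aligned = ann.loc[table.scores.index, col]
                groups = sorted(pd.unique(aligned.dropna()).tolist())
                if len(groups) == 2:
                    res = compare_groups_welch(
                        table.scores[config.group_comparison_score], aligned
                    )
                    entries.append(
                        {
                            "score": config.group_comparison_score,
                            "grouping": col,
                            "groups": groups,
                            **res.to_dict(),
                        }
                    )
                else:
                    logger.warning(
                        "group_comparison: column %r has %d level(s); skipped",
                        col,
                        len(groups),
                    )
            else:
                logger.warning("group_comparison: column %r unavailable; skipped", col)
            report["group_comparisons"] = entries
        except Exception as exc:
            raise PipelineStageError("group_comparison", str(exc)) from exc

    # ---- stage: survival_analysis --------------------------------------
    if config.run_survival:
        try:
            if ann is None or "survival_time" not in getattr(ann, "columns", []):
                raise ValueError("missing columns survival_time/event")
            ann_s = ann.loc[table.scores.index]
            times = ann_s["survival_time"].to_numpy(dtype=float)
            events = ann_s["event"].to_numpy(dtype=bool)
            survival: dict = {}
            curves: list[pd.DataFrame] = []

            split_gene = _default_split_gene(config, sigs)
            if split_gene is not None:
                labels, sizes = geometric_mean_split(
                    expr, split_gene, pseudocount=config.geometric_mean_pseudocount
                )
                labels = labels.loc[table.scores.index]
                masks = {lvl: (labels == lvl).to_numpy() for lvl in ("high", "low")}
                if all(m.any() for m in masks.values()):
                    lr = logrank_test(
                        times[masks["high"]],
                        events[masks["high"]],
                        times[masks["low"]],
                        events[masks["low"]],
                    )
                    medians = {}
                    for lvl, m in masks.items():
                        curve = km_estimate(times[m], events[m])
                        medians[lvl] = (
                            curve.median if curve.median_reached else "not reached"
                        )
                        cf = curve.to_frame()
                        cf.insert(0, "stratum", f"{split_gene}_{lvl}")
                        curves.append(cf)
                    survival["geometric_mean_split"] = {
                        "gene": split_gene,
                        "sizes": sizes,
                        "medians": medians,
                        "logrank": lr.to_dict(),
                    }
                else:
                    raise ValueError(
                        f"geometric-mean split of {split_gene!r} left a stratum empty"
                    )

            qa, qb = config.quadrant_scores
            if qa in table.scores.columns and qb in table.scores.columns:
                quad_labels, pos, neg = quadrant_stratify(
                    table.scores[qa], table.scores[qb]
                )
                if len(pos) == 0 or len(neg) == 0:
                    raise ValueError(
                        "quadrant stratification produced an empty contrast group"
                    )
                mp = table.scores.index.isin(pos)
                mn = table.scores.index.isin(neg)
                lr = logrank_test(times[mp], events[mp], times[mn], events[mn])
                for name, mask in (("double_positive", mp), ("double_negative", mn)):
                    cf = km_estimate(times[mask], events[mask]).to_frame()
                    cf.insert(0, "stratum", name)
                    curves.append(cf)
                survival["quadrant"] = {
                    "scores": [qa, qb],
                    "sizes": {
                        q: int((quad_labels == q).sum())
                        for q in ("++", "+-", "-+", "--")
                    },
                    "logrank": lr.to_dict(),
                }

            if curves:
                pd.concat(curves, ignore_index=True).to_csv(
                    outdir / "survival_curves.tsv", sep="\t", index=False
                )
            logger.info("survival_analysis: %d strata", len(curves))
            report["survival"] = survival
        except Exception as exc:
            raise PipelineStageError("survival_analysis", str(exc)) from exc

    # ---- stage: report -------------------------------------------------
    try:
        schema = json.loads(
            importlib.resources.files("sigscore")
            .joinpath("report_schema.json")
            .read_text()
        )
        validate_schema(report, schema)
        write_json(report, outdir / "report.json")
        logger.info("report: written to %s", outdir / "report.json")
    except Exception as exc:
        raise PipelineStageError("report", str(exc)) from exc
    return report


def order_heatmap_matrix(
    zres: ZScoreResult,
    score: pd.Series,
    sigs: list[SignatureDefinition],
) -> pd.DataFrame:
    """Signature-gene z sub-matrix with samples ordered by descending score
    and genes grouped by signature (up-sets first, then down-sets).

    A gene belonging to several signatures is assigned to the first one in
    ``sigs`` order (logged).
    """
    sample_order = score.sort_values(ascending=False, kind="stable").index
    seen: set[str] = set()
    rows: list[str] = []
    for attr in ("up_set", "down_set"):
        for sig in sigs:
            gene_set = getattr(sig, attr)
            if gene_set is None:
                continue
            for g in gene_set.genes:
                if g not in zres.z.index:
                    continue
                if g in seen:
                    logger.info(
                        "gene %r in several signatures; kept with its first", g
                    )
                    continue
                seen.add(g)
                rows.append(g)
    if not rows:
        raise ValueError("no signature gene overlaps the z-score matrix")
    return zres.z.loc[rows, sample_order]
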