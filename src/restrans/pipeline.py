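"""End-to-end analysis pipeline: filters -> distances -> group tests ->
contrasts -> divergence -> flexibility -> dip -> tails -> summaries.

Stage order is fixed: the sample-depth filter runs first; Sorensen-Dice
matrices are computed for the field and common-garden strata separately
and each stratum gets its own PERMANOVA and dispersion test (the strata
are never pooled for location tests); garden-vs-field contrasts and the
divergence regression run on the pooled distance matrix; the flexibility
stage applies the prevalence filter internally (prevalence is a
flexibility-stage filter by default, not a global one — an option applies
it before the beta-diversity stages too).

Every stage writes its artifact to the output directory and contributes
to one consolidated JSON report. All p-values are uncorrected (no
multiple-testing adjustment is applied anywhere, and the report says so).
Identical config + seed gives a byte-identical report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from . import io as rio
from .distance import pairwise_comparisons, sorensen_dice_matrix
from .dip import dip_test
from .errors import RestransError, ValidationError
from .filters import DepthFilter, PrevalenceFilter
from .flexibility import FlexibilityScorer, order_level_summary, select_tails
from .stats import dispersion_test, divergence_regression, permanova

logger = logging.getLogger("restrans")

TableLike = Union[str, Path, pd.DataFrame]


@dataclass
class PipelineConfig:
    table: TableLike = None
    metadata: TableLike = None
    taxonomy: Optional[TableLike] = None
    out_dir: Union[str, Path] = "restrans_out"
    seed: int = None
    min_reads: int = 1000
    min_prevalence: float = 0.01
    n_permutations: int = 999
    tail_fraction: float = 0.01
    dip_bootstrap: int = 2000
    prevalence_before_beta: bool = False
    do_multivariate: bool = True
    do_contrast: bool = True
    do_divergence: bool = True
    do_flexibility: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("a seed is mandatory for a pipeline run")


def validate_inputs(table: pd.DataFrame, meta: pd.DataFrame) -> Dict[str, List[str]]:
    """Cross-validate the count table against the metadata.

    Fatal: table samples absent from the metadata; fewer than two
    populations among the table's samples. Warnings: metadata rows without
    a table sample; a source category (field / common_garden) absent.
    """
    fatal, warnings = [], []
    missing = [s for s in table.index if s not in meta.index]
    if missing:
        fatal.append(f"samples missing from metadata: {missing}")
        return {"fatal": fatal, "warnings": warnings}
    sub = meta.loc[table.index]
    extra = [s for s in meta.index if s not in table.index]
    if extra:
        warnings.append(f"{len(extra)} metadata rows without a table sample")
    if sub["population"].nunique() < 2:
        fatal.append("a single population cannot support any group contrast")
    for source in ("field", "common_garden"):
        if not (sub["source"] == source).any():
            warnings.append(f"no {source} samples present")
    return {"fatal": fatal, "warnings": warnings}


def _load(obj: TableLike, reader):
    if isinstance(obj, pd.DataFrame):
        return obj
    return reader(obj)


def _stage_seeds(seed: int, n: int) -> List[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2 ** 31)) for s in state]


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    if isinstance(obj, Path):
        return str(obj)
    return obj


class _Stage:
    """Context tracking the running stage for precise abort messages."""

    def __init__(self, report, name):
        self.report = report
        self.name = name

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        return self

    def done(self, **counts):
        entry = {"stage": self.name, "status": "complete", **_jsonify(counts)}
        self.report["stages"].append(entry)
        logger.info("stage %s: %s", self.name, counts)

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            self.report["stages"].append(
                {"stage": self.name, "status": "FAILED", "error": str(exc)}
            )
        return False


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute the full analysis; returns the report dict (also written
    as ``report.json``). Any stage error aborts the run, leaving partial
    outputs plus a FAILED marker naming the stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, 8)
    report: Dict = {
        "config": _jsonify({k: v for k, v in asdict(config).items()
                            if not isinstance(v, pd.DataFrame)}),
        "stages": [],
        "results": {},
        "warnings": [],
        "p_values": "uncorrected",
    }

    try:
        with _Stage(report, "load_and_validate") as st:
            table = _load(config.table, rio.read_asv_table)
            meta = rio.validate_metadata(_load(config.metadata, rio.read_metadata))
            taxonomy = None
            if config.taxonomy is not None:
                taxonomy = _load(config.taxonomy, rio.read_taxonomy)
            checks = validate_inputs(table, meta)
            report["warnings"].extend(checks["warnings"])
            if checks["fatal"]:
                raise ValidationError("; ".join(checks["fatal"]))
            meta = meta.loc[table.index]
            st.done(n_samples=len(table), n_asvs=table.shape[1])

        with _Stage(report, "depth_filter") as st:
            depth = DepthFilter(min_reads=config.min_reads).fit(table)
            table_f = depth.transform(table)
            meta_f = meta.loc[table_f.index]
            report["results"]["depth_filter"] = {
                "min_reads": config.min_reads,
                "n_removed": len(depth.removed_samples_),
                "removed_samples": depth.removed_samples_,
            }
            st.done(n_in=len(table), n_out=len(table_f),
                    n_removed=len(depth.removed_samples_))

        beta_table = table_f
        if config.prevalence_before_beta:
            with _Stage(report, "prevalence_filter") as st:
                pf = PrevalenceFilter(min_fraction=config.min_prevalence).fit(beta_table)
                beta_table = pf.transform(beta_table)
                st.done(n_in=table_f.shape[1], n_out=beta_table.shape[1])

        strata = {}
        with _Stage(report, "distances") as st:
            for source in ("field", "common_garden"):
                ids = meta_f.index[meta_f["source"] == source]
                if len(ids) >= 2:
                    dm = sorensen_dice_matrix(beta_table.loc[ids])
                    strata[source] = dm
                    rio.write_distance_matrix(dm, out / f"distances_{source}.tsv")
            dm_all = sorensen_dice_matrix(beta_table)
            rio.write_distance_matrix(dm_all, out / "distances_all.tsv")
            st.done(strata=sorted(strata), n_samples=len(dm_all.ids))

        if config.do_multivariate:
            with _Stage(report, "multivariate_tests") as st:
                for i, (source, dm) in enumerate(sorted(strata.items())):
                    groups = meta_f.loc[list(dm.ids), "population"]
                    perm = permanova(dm, groups,
                                     n_permutations=config.n_permutations,
                                     seed=seeds[i])
                    disp = dispersion_test(dm, groups,
                                           n_permutations=config.n_permutations,
                                           seed=seeds[2 + i])
                    report["results"][f"permanova_{source}"] = perm.to_dict()
                    report["results"][f"dispersion_{source}"] = disp.to_dict()
                st.done(n_tests=2 * len(strata))

        pairs_gf = None
        if config.do_contrast or config.do_divergence:
            with _Stage(report, "garden_vs_field_pairs") as st:
                pairs_gf = pairwise_comparisons(
                    dm_all, meta_f,
                    set_a_filter=meta_f["source"] == "common_garden",
                    set_b_filter=meta_f["source"] == "field",
                )
                pairs_gf.to_csv(out / "comparisons_garden_vs_field.tsv",
                                sep="\t", index=False)
                st.done(n_pairs=len(pairs_gf))

        if config.do_contrast:
            with _Stage(report, "contrast_rank_sum") as st:
                from .stats import rank_sum_test
                within = pairs_gf.loc[
                    pairs_gf["comparison_class"] == "within_population", "dissimilarity"]
                between = pairs_gf.loc[
                    pairs_gf["comparison_class"] == "between_population", "dissimilarity"]
                res_all = rank_sum_test(within, between)
                report["results"]["contrast_all_timepoints"] = {
                    **res_all.to_dict(),
                    "mean_within": float(within.mean()),
                    "mean_between": float(between.mean()),
                }
                final_t = meta_f.loc[meta_f["source"] == "common_garden", "timepoint"].max()
                fin = pairs_gf[pairs_gf["timepoint"] == final_t]
                res_fin = rank_sum_test(
                    fin.loc[fin["comparison_class"] == "within_population", "dissimilarity"],
                    fin.loc[fin["comparison_class"] == "between_population", "dissimilarity"],
                )
                report["results"]["contrast_final_timepoint"] = {
                    **res_fin.to_dict(), "final_timepoint": float(final_t),
                }
                st.done(n_within=len(within), n_between=len(between))

        if config.do_divergence:
            with _Stage(report, "divergence_regression") as st:
                fits = divergence_regression(pairs_gf, per_population=True)
                report["results"]["divergence"] = [f.to_dict() for f in fits]
                pd.DataFrame([f.to_dict() for f in fits]).to_csv(
                    out / "divergence.tsv", sep="\t", index=False)
                st.done(n_fits=len(fits))

        if config.do_flexibility:
            with _Stage(report, "flexibility") as st:
                scorer = FlexibilityScorer(min_prevalence=config.min_prevalence)
                scorer.fit(table_f, meta_f["population"])
                fs_table = scorer.scores_
                fs_table.to_csv(out / "flexibility.tsv", sep="\t")
                res = fs_table["residency"].value_counts()
                report["results"]["flexibility_summary"] = {
                    "n_scored": int(len(fs_table)),
                    "n_resident": int(res.get("resident", 0)),
                    "n_transient": int(res.get("transient", 0)),
                    "n_neutral": int(res.get("neutral", 0)),
                    "n_undefined": scorer.n_undefined_,
                    "n_infinite": scorer.n_infinite_,
                }
                st.done(n_asvs_in=table_f.shape[1], n_scored=len(fs_table))

            with _Stage(report, "dip_test") as st:
                fs = fs_table["fs"].to_numpy()
                finite = fs[np.isfinite(fs)]
                dip = dip_test(finite, n_bootstrap=config.dip_bootstrap,
                               seed=seeds[4])
                report["results"]["dip"] = {
                    **dip.to_dict(),
                    "n_infinite_excluded": int(np.isinf(fs).sum()),
                }
                st.done(n_values=finite.size)

            with _Stage(report, "tails") as st:
                tails = select_tails(fs_table, fraction=config.tail_fraction)
                pd.DataFrame({
                    "asv_id": tails.top_asvs + tails.bottom_asvs,
                    "tail": ["top"] * len(tails.top_asvs)
                            + ["bottom"] * len(tails.bottom_asvs),
                }).to_csv(out / "tails.tsv", sep="\t", index=False)
                report["results"]["tails"] = {
                    "fraction": config.tail_fraction,
                    "top_asvs": tails.top_asvs,
                    "bottom_asvs": tails.bottom_asvs,
                }
                st.done(n_top=len(tails.top_asvs), n_bottom=len(tails.bottom_asvs))

            if taxonomy is not None:
                with _Stage(report, "order_summary") as st:
                    summary = order_level_summary(fs_table, taxonomy)
                    summary.to_csv(out / "order_summary.tsv", sep="\t")
                    report["results"]["order_summary_n_orders"] = int(len(summary))
                    st.done(n_orders=len(summary))

    except Exception as exc:
        (out / "FAILED").write_text(
            f"stage: {report['stages'][-1]['stage'] if report['stages'] else 'setup'}\n"
            f"error: {exc}\n"
        )
        _write_report(report, out)
        raise

    _write_report(report, out)
    return report


def _write_report(report: Dict, out: Path) -> None:
    text = json.dumps(_jsonify(report), indent=2, sort_keys=True)
    (out / "report.json").write_text(text + "\n")
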