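"""End-to-end driver: indices → ranking → trends + outliers → correlations.

``run_full_analysis`` reads a matrix and metadata from disk, computes the
GFE profile table, the restarted S-ranking, a polynomial size-trend with
boxplot outliers for each requested measure, and the partial-correlation
table, then writes plain-TSV outputs plus a JSON manifest.  All randomness
flows from the single configured seed, and reruns with the same inputs and
seed produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy

import gfex

from .correlations import CorrelationTable, measure_correlation_table
from .indices import gfe_profile_table
from .matrix import (
    GeneFamilyMatrix,
    check_metadata_covers,
    read_matrix,
    read_metadata,
)
from .ranking import RankingResult, s_rank
from .trend import OutlierReport, TrendFit, detect_outliers, fit_trend

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "AnalysisBundle", "PipelineError", "run_full_analysis", "analyze"]

VALID_MEASURES = ("p_i", "ave", "mp", "rank")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    matrix_path: str
    metadata_path: str
    matrix_format: str = "dense-tsv"
    measures: tuple[str, ...] = VALID_MEASURES
    criterion: str = "aic"
    degrees: tuple[int, ...] = tuple(range(1, 11))
    n_restarts: int = 10
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.measures:
            raise ValueError("measures must be non-empty")
        bad = set(self.measures) - set(VALID_MEASURES)
        if bad:
            raise ValueError(f"unknown measures {sorted(bad)}; valid: {VALID_MEASURES}")


@dataclasses.dataclass
class AnalysisBundle:
    profiles: pd.DataFrame
    ranking: RankingResult
    trends: dict[str, TrendFit]
    outlier_reports: dict[str, OutlierReport]
    correlations: Optional[CorrelationTable]
    manifest: dict


def _config_hash(config: AnalysisConfig) -> str:
    fields = dataclasses.asdict(config)
    fields.pop("out_dir", None)  # output location is not part of the analysis
    payload = json.dumps(fields, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def analyze(
    matrix: GeneFamilyMatrix,
    metadata: pd.DataFrame,
    measures: Sequence[str] = VALID_MEASURES,
    criterion: str = "aic",
    degrees: Sequence[int] = tuple(range(1, 11)),
    n_restarts: int = 10,
    seed: int = 0,
) -> AnalysisBundle:
    """Run every stage on in-memory inputs; see ``run_full_analysis``."""
    check_metadata_covers(matrix, metadata)
    meta = metadata.set_index("genome_id").loc[matrix.genome_ids].reset_index()

    profiles = gfe_profile_table(matrix)
    n_mp_missing = int(profiles["mp"].isna().sum())
    if n_mp_missing:
        logger.info("analyze: mp undefined for %d genome(s); excluded per measure", n_mp_missing)

    try:
        ranking = s_rank(matrix, n_restarts=n_restarts, seed=seed)
    except Exception as e:  # pragma: no cover - defensive
        raise PipelineError(f"rank stage failed: {e}") from e

    values = {
        "p_i": profiles.set_index("genome_id")["p_i"],
        "ave": profiles.set_index("genome_id")["ave"],
        "mp": profiles.set_index("genome_id")["mp"],
        "rank": pd.Series(ranking.mean_rank),
    }
    sizes = meta.set_index("genome_id")["size_mbp"]

    trends: dict[str, TrendFit] = {}
    reports: dict[str, OutlierReport] = {}
    for m in measures:
        y = values[m].loc[matrix.genome_ids]
        try:
            fit = fit_trend(
                sizes.loc[matrix.genome_ids].to_numpy(),
                y.to_numpy(dtype=float),
                degrees=degrees,
                criterion=criterion,
                ids=matrix.genome_ids,
            )
            reports[m] = detect_outliers(fit.residuals)
        except ValueError as e:
            raise PipelineError(f"trend stage failed for measure {m!r}: {e}") from e
        trends[m] = fit

    correlations: Optional[CorrelationTable] = None
    if matrix.n_genomes >= 4:
        try:
            correlations = measure_correlation_table(
                profiles, ranking.to_frame(), meta, control="genome_size"
            )
        except ValueError as e:
            raise PipelineError(f"correlation stage failed: {e}") from e

    manifest = {
        "package_version": gfex.__version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "n_restarts": n_restarts,
        "criterion": criterion,
        "measures": list(measures),
        "n_genomes": matrix.n_genomes,
        "n_cogs": matrix.n_cogs,
        "n_mp_undefined": n_mp_missing,
        "consensus_objective": ranking.objective,
        "selected_degrees": {m: trends[m].degree for m in trends},
    }
    return AnalysisBundle(
        profiles=profiles,
        ranking=ranking,
        trends=trends,
        outlier_reports=reports,
        correlations=correlations,
        manifest=manifest,
    )


def run_full_analysis(config: AnalysisConfig) -> AnalysisBundle:
    """Read inputs, run all stages, optionally write the output bundle."""
    try:
        matrix = read_matrix(config.matrix_path, format=config.matrix_format)
        metadata = read_metadata(config.metadata_path)
    except Exception as e:
        raise PipelineError(f"input stage failed: {e}") from e

    bundle = analyze(
        matrix,
        metadata,
        measures=config.measures,
        criterion=config.criterion,
        degrees=config.degrees,
        n_restarts=config.n_restarts,
        seed=config.seed,
    )
    bundle.manifest["config_hash"] = _config_hash(config)

    if config.out_dir is not None:
        write_bundle(bundle, config.out_dir)
    return bundle


def write_bundle(bundle: AnalysisBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.profiles.to_csv(out / "profiles.tsv", sep="\t", index=False)
    bundle.ranking.to_frame().to_csv(out / "ranks.tsv", sep="\t", index=False)

    outlier_rows = []
    for m, fit in bundle.trends.items():
        report = bundle.outlier_reports[m]
        (out / f"trend_{m}.json").write_text(
            json.dumps(
                {
                    "measure": m,
                    "degree": fit.degree,
                    "criterion": fit.criterion,
                    "aic": fit.aic,
                    "bic": fit.bic,
                    "rss": fit.rss,
                    "n": fit.n,
                    "n_dropped": fit.n_dropped,
                    "coefficients_raw": list(fit.coefficients),
                    "coefficients_scaled": list(fit.scaled_coefficients),
                    "domain_mbp": list(fit.domain),
                    "boxplot": {
                        "q1": report.q1,
                        "q2": report.q2,
                        "q3": report.q3,
                        "iqr": report.iqr,
                        "lower_whisker": report.lower_whisker,
                        "upper_whisker": report.upper_whisker,
                    },
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        for g in sorted(report.outliers):
            outlier_rows.append(
                {
                    "genome_id": g,
                    "measure": m,
                    "observed": fit.fitted[g] + fit.residuals[g],
                    "fitted": fit.fitted[g],
                    "residual": fit.residuals[g],
                    "side": report.sides[g],
                }
            )
    pd.DataFrame(
        outlier_rows,
        columns=["genome_id", "measure", "observed", "fitted", "residual", "side"],
    ).to_csv(out / "outliers.tsv", sep="\t", index=False)

    if bundle.correlations is not None:
        bundle.correlations.to_long().to_csv(out / "pcor.tsv", sep="\t", index=False)
    (out / "manifest.json").write_text(
        json.dumps(bundle.manifest, indent=2, sort_keys=True) + "\n"
    )
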