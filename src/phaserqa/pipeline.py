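"""Batch analysis: classify trials, run general and region-based MdRQA,
and export a tidy long-format table plus descriptive summaries.

The long table has one ``general`` row per analyzable trial and one row
per phase region (r1/r2/r3) for successful and unsuccessful trials only —
incomplete trials never desynchronize enough for a region pass, so
region-based analysis is restricted to the trial types it can compare.
Missing metrics stay missing (empty cells), never 0.

The exported table carries every column needed to fit the study-style
mixed-effects models downstream (trial_type, language_group, tempo_bin,
scope, participant_id as grouping key); the models themselves are out of
scope here.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .phase import (
    EmptyTrialError,
    assign_regions,
    classify_trial,
    relative_phase,
    tempo_bin,
)
from .rqa import REGION_LABELS, RQAMetrics, RQAParams, mdrqa, region_metrics
from .trials import Trial, read_manifest

logger = logging.getLogger("phaserqa")

METRICS_COLUMNS = (
    "participant_id",
    "trial_index",
    "tempo_bpm",
    "tempo_bin",
    "language_group",
    "trial_type",
    "scope",
    "rec",
    "det",
    "maxl",
    "n_taps",
)

_METRIC_NAMES = ("rec", "det", "maxl")


def log_run_header(params: RQAParams, seed: Optional[int] = None) -> None:
    """Provenance header: version, config hash, seed, parameters verbatim."""
    blob = json.dumps(params.to_dict(), sort_keys=True)
    digest = hashlib.sha256(blob.encode()).hexdigest()[:12]
    logger.info("phaserqa %s | config sha256:%s | seed=%s", __version__, digest, seed)
    logger.info(
        "MdRQA parameters: EMB=%d DEL=%d NORM=%s RAD=%g ZSCORE=%d "
        "(lmin=%d, theiler=%d)",
        params.emb,
        params.delay,
        params.norm,
        params.radius,
        int(params.zscore),
        params.lmin,
        params.theiler,
    )


def _metrics_fields(metrics: RQAMetrics) -> dict:
    return {
        "rec": np.nan if metrics.rec is None else metrics.rec,
        "det": np.nan if metrics.det is None else metrics.det,
        "maxl": np.nan if metrics.maxl is None else metrics.maxl,
        "n_taps": metrics.n,
    }


def analyze_trial(trial: Trial, params: RQAParams = RQAParams()) -> List[dict]:
    """All metric rows for one trial (general + region rows when due)."""
    classification = classify_trial(trial)
    series = relative_phase(trial)
    base = {
        "participant_id": trial.participant_id,
        "trial_index": trial.trial_index,
        "tempo_bpm": trial.tempo_bpm,
        "tempo_bin": tempo_bin(trial.tempo_bpm),
        "language_group": trial.language_group,
        "trial_type": classification.label,
    }
    _, general = mdrqa(series, params)
    rows = [dict(base, scope="general", **_metrics_fields(general))]
    if classification.label in ("successful", "unsuccessful"):
        regions = assign_regions(series.psi_wrapped)
        per_region = region_metrics(series, regions, params)
        for label in REGION_LABELS:
            rows.append(dict(base, scope=label, **_metrics_fields(per_region[label])))
    return rows


def run_batch(
    trials: Union[Path, str, Sequence[Trial]],
    params: RQAParams = RQAParams(),
) -> pd.DataFrame:
    """Analyze a manifest path or an in-memory trial sequence.

    Zero-tap trials are logged and excluded; any other per-trial failure
    is logged and skipped without aborting the batch.
    """
    if isinstance(trials, (str, Path)):
        trials = read_manifest(trials)
    rows: List[dict] = []
    for trial in trials:
        try:
            rows.extend(analyze_trial(trial, params))
        except EmptyTrialError:
            logger.warning(
                "excluding trial (%s, %d): no taps",
                trial.participant_id,
                trial.trial_index,
            )
        except Exception:
            logger.exception(
                "skipping trial (%s, %d) after error",
                trial.participant_id,
                trial.trial_index,
            )
    return pd.DataFrame(rows, columns=list(METRICS_COLUMNS))


def summarize(rows: pd.DataFrame) -> pd.DataFrame:
    """Descriptive summary per (trial_type x scope): unweighted mean,
    sample SD and effective N of each metric, missing values excluded."""
    if rows.empty:
        logger.warning("summarize called with no metric rows")
        return pd.DataFrame(
            columns=["trial_type", "scope", "metric", "mean", "sd", "n"]
        )
    out = []
    for (trial_type, scope), group in rows.groupby(
        ["trial_type", "scope"], sort=True
    ):
        for metric in _METRIC_NAMES:
            values = group[metric].dropna()
            out.append(
                {
                    "trial_type": trial_type,
                    "scope": scope,
                    "metric": metric,
                    "mean": values.mean() if len(values) else np.nan,
                    "sd": values.std(ddof=1) if len(values) > 1 else np.nan,
                    "n": int(len(values)),
                }
            )
    return pd.DataFrame(out)


def write_metrics(rows: pd.DataFrame, path: Path | str) -> Path:
    """Write the long table; missing metrics serialize as empty cells."""
    path = Path(path)
    rows.to_csv(path, index=False, na_rep="")
    return path
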