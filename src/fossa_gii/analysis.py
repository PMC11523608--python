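"""Operator-performance and phantom-accuracy statistics.

Covers the study's evaluation stack: Euclidean distance of puncture points
from the maximum-GII site and from the FO centroid (the thinnest point),
Pearson correlations between GII / centroid distance and procedural time,
Bland-Altman agreement between caliper and STL measurements, a Kruskal-Wallis
inter-rater test, and Likert questionnaire descriptives.

Conventions (all switchable where noted): Bland-Altman limits of agreement
use the sample SD (ddof=1), the standard convention; Likert tables report the
population SD (ddof=0); distances are 3D chordal Euclidean, not geodesic on
the FO surface.  No multiple-testing correction is applied — p-values are
reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "PunctureRecord",
    "AgreementResult",
    "CorrelationResult",
    "records_to_frame",
    "load_punctures_csv",
    "distance_metrics",
    "correlate",
    "bland_altman",
    "kruskal_wallis",
    "likert_summary",
    "format_likert_row",
]

PUNCTURE_COLUMNS = ["participant", "experience_years", "trial", "x", "y", "z", "time_s"]


@dataclass(frozen=True)
class PunctureRecord:
    """One tracked puncture attempt.

    ``experience_years`` codes the trainee as 0.  ``point`` is the puncture
    location in the FO/phantom frame (mm); ``time_s`` the procedural time
    from kit withdrawal from the SVC to needle crossing, seconds.
    """

    participant_id: str
    experience_years: float
    trial: int
    point: tuple[float, float, float]
    time_s: float

    def __post_init__(self) -> None:
        if self.time_s <= 0:
            raise ValidationError("procedural time must be positive")
        if self.trial < 1:
            raise ValidationError("trial index starts at 1")


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman agreement summary (units of the input, mm here)."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pct_within: float
    n: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def records_to_frame(records: list[PunctureRecord]) -> pd.DataFrame:
    if not records:
        raise ValidationError("no puncture records")
    return pd.DataFrame(
        {
            "participant": [r.participant_id for r in records],
            "experience_years": [r.experience_years for r in records],
            "trial": [r.trial for r in records],
            "x": [r.point[0] for r in records],
            "y": [r.point[1] for r in records],
            "z": [r.point[2] for r in records],
            "time_s": [r.time_s for r in records],
        }
    )


def load_punctures_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PUNCTURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"punctures CSV missing columns: {sorted(missing)}")
    if (df["time_s"] <= 0).any():
        raise ValidationError("procedural times must be positive")
    return df


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        if len(records) == 0:
            raise ValidationError("no puncture records")
        return records
    return records_to_frame(list(records))


def distance_metrics(
    records,
    argmax_point: np.ndarray,
    centroid: np.ndarray,
) -> pd.DataFrame:
    """Per-participant mean +/- SD distance to the max-GII point and centroid.

    Accepts a list of :class:`PunctureRecord` or an equivalent DataFrame.
    Distances are straight-line 3D Euclidean in mm; the SD is the sample SD
    (ddof=1, 0 for a single trial).  The result is sorted by experience
    (descending) then participant id.
    """
    df = _as_frame(records).copy()
    pts = df[["x", "y", "z"]].to_numpy(dtype=float)
    df["dist_gii"] = np.linalg.norm(pts - np.asarray(argmax_point, dtype=float), axis=1)
    df["dist_centroid"] = np.linalg.norm(pts - np.asarray(centroid, dtype=float), axis=1)

    def _sd(v):
        return float(np.std(v, ddof=1)) if len(v) > 1 else 0.0

    out = (
        df.groupby(["participant", "experience_years"], sort=False)
        .agg(
            n_trials=("trial", "size"),
            mean_dist_gii=("dist_gii", "mean"),
            sd_dist_gii=("dist_gii", _sd),
            mean_dist_centroid=("dist_centroid", "mean"),
            sd_dist_centroid=("dist_centroid", _sd),
        )
        .reset_index()
        .sort_values(["experience_years", "participant"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return out


def correlate(x, y) -> CorrelationResult:
    """Pearson correlation with a two-sided t-distribution p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValidationError("need at least 3 pairs for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance input to correlation")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=len(x))


def bland_altman(pairs) -> AgreementResult:
    """Bland-Altman agreement of paired measurements.

    Differences are a - b; bias is their mean and the limits of agreement are
    bias +/- 1.96 * sample SD.  ``pct_within`` counts the same pairs inside
    the limits (about 95% expected under normal differences).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValidationError("pairs must be an (n, 2) array-like")
    if len(arr) < 2:
        raise ValidationError("need at least 2 pairs")
    diff = arr[:, 0] - arr[:, 1]
    bias = float(diff.mean())
    sd = float(np.std(diff, ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    within = float(np.mean((diff >= lo) & (diff <= hi)) * 100.0)
    return AgreementResult(bias=bias, sd_diff=sd, loa_low=lo, loa_high=hi,
                           pct_within=within, n=len(arr))


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value (k-1 df).

    All observations identical across groups is a defined degenerate case:
    H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValidationError("every group needs at least one value")
    if sum(len(g) for g in groups) < 5:
        raise ValidationError("need at least 5 values in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def likert_summary(responses: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Per-question mean +/- SD of 1-5 Likert scores.

    ``responses`` has columns participant, question, score.  The default SD is
    the population SD (ddof=0), which reproduces published splits such as
    {4, 5} -> 4.50 +/- 0.50.
    """
    missing = {"question", "score"} - set(responses.columns)
    if missing:
        raise ValidationError(f"likert table missing columns: {sorted(missing)}")
    scores = responses["score"].to_numpy()
    if not np.all((scores == np.round(scores)) & (scores >= 1) & (scores <= 5)):
        raise ValidationError("Likert scores must be integers in [1, 5]")
    out = (
        responses.groupby("question", sort=True)["score"]
        .agg(n="size", mean="mean", sd=lambda v: float(np.std(v, ddof=ddof)))
        .reset_index()
    )
    return out


def format_likert_row(mean: float, sd: float) -> str:
    """Render one questionnaire row in the conventional '4.60 +/- 0.40' style."""
    return f"{mean:.2f} ± {sd:.2f}"
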