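"""Clinical statistics for the three-phase vedolizumab cohort.

Eleven IBD patients (ulcerative colitis or Crohn's disease) are observed
before treatment (t0), after 24 weeks (t1) and after 52 weeks (t2).
Per phase each patient carries an activity score (Partial Mayo Score for
UC, Harvey–Bradshaw Index for CD), the Robarts Histopathological Index
(RHI) from biopsy, and optionally TEER, FD4 permeability and *Roseburia*
relative abundance.

The pipeline produces cohort summaries (mean/median/std/min/max),
paired t-tests between phases, and disease-stratified Pearson
correlations between the activity score and RHI, pooling the per-patient
per-phase pairs across the three time points — the pooling convention
under which the clinical score/histology correlations are defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "PHASES",
    "ENDPOINTS",
    "PatientRecord",
    "CohortSummary",
    "TestResult",
    "CorrelationResult",
    "DegenerateTestError",
    "summarize",
    "paired_t",
    "pearson",
    "run_study_analysis",
]

PHASES = ("t0", "t1", "t2")
#: Endpoints a record may carry besides the activity score.
ENDPOINTS = ("activity", "rhi", "teer", "pm", "roseburia")


class DegenerateTestError(ValueError):
    """Raised when a test statistic is undefined (zero variance)."""


def _check_phase_map(name: str, values: Mapping[str, float] | None, lower=None, upper=None):
    if values is None:
        return
    for phase, v in values.items():
        if phase not in PHASES:
            raise ValueError(f"{name}: unknown phase {phase!r}")
        if lower is not None and v < lower:
            raise ValueError(f"{name}[{phase}] = {v!r} below {lower}")
        if upper is not None and v > upper:
            raise ValueError(f"{name}[{phase}] = {v!r} above {upper}")


@dataclass
class PatientRecord:
    """One subject's per-phase observations.

    ``activity_scores`` holds the PMS (UC) or HBI (CD) by phase; which
    index it is follows from ``disease``.  TEER (ohm*cm^2), permeability
    (cm^2/s) and *Roseburia* relative abundance are optional per-phase
    maps.
    """

    patient_id: int
    disease: str  # "UC" or "CD"
    therapy: str  # "naive" or "anti-TNF"
    activity_scores: dict[str, int] = field(default_factory=dict)
    rhi: dict[str, int] = field(default_factory=dict)
    teer: dict[str, float] | None = None
    pm: dict[str, float] | None = None
    roseburia: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.disease not in ("UC", "CD"):
            raise ValueError(f"disease must be 'UC' or 'CD', got {self.disease!r}")
        if self.therapy not in ("naive", "anti-TNF"):
            raise ValueError(f"therapy must be 'naive' or 'anti-TNF', got {self.therapy!r}")
        _check_phase_map("activity_scores", self.activity_scores, lower=0)
        _check_phase_map("rhi", self.rhi, lower=0)
        _check_phase_map("teer", self.teer, lower=0)
        _check_phase_map("pm", self.pm, lower=0)
        _check_phase_map("roseburia", self.roseburia, lower=0, upper=1)

    @property
    def score_name(self) -> str:
        return "PMS" if self.disease == "UC" else "HBI"

    def endpoint(self, name: str) -> Mapping[str, float] | None:
        mapping = {
            "activity": self.activity_scores,
            "rhi": self.rhi,
            "teer": self.teer,
            "pm": self.pm,
            "roseburia": self.roseburia,
        }
        if name not in mapping:
            raise KeyError(name)
        return mapping[name]


@dataclass(frozen=True)
class CohortSummary:
    """Sample statistics in the units of the input; std uses n-1."""

    mean: float
    median: float
    std: float
    minimum: float
    maximum: float
    n: int
    degenerate_std: bool = False  # set when n == 1 and std is reported as 0


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    tails: str  # "one" or "two"


@dataclass(frozen=True)
class CorrelationResult(TestResult):
    r: float = float("nan")


def summarize(values: Sequence[float]) -> CohortSummary:
    """Mean, median, sample std (n-1), min and max of a cohort column."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty list")
    degenerate = arr.size == 1
    return CohortSummary(
        mean=float(np.mean(arr)),
        median=float(np.median(arr)),
        std=0.0 if degenerate else float(np.std(arr, ddof=1)),
        minimum=float(np.min(arr)),
        maximum=float(np.max(arr)),
        n=int(arr.size),
        degenerate_std=degenerate,
    )


def _one_tailed(p_two: float, statistic: float) -> float:
    # one-tailed in the direction of the observed statistic
    return p_two / 2.0 if np.isfinite(statistic) else 0.0


def paired_t(x: Sequence[float], y: Sequence[float], tails: str = "two") -> TestResult:
    """Paired-samples t-test on the differences d = x - y.

    t = mean(d) / (std(d, ddof=1)/sqrt(n)) with n-1 degrees of freedom.
    ``tails='one'`` halves the two-sided p in the direction of the
    observed mean difference.  Identical lists (all differences zero)
    are a degenerate test; a constant nonzero shift gives an infinite
    statistic with p = 0.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired_t needs two equal-length lists of length >= 2")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    d = x - y
    n = d.size
    sd = float(np.std(d, ddof=1))
    dbar = float(np.mean(d))
    if sd == 0.0:
        if dbar == 0.0:
            raise DegenerateTestError("all paired differences are zero")
        t_stat = float(np.sign(dbar)) * float("inf")
        p_two = 0.0
    else:
        t_stat = dbar / (sd / np.sqrt(n))
        p_two = float(2.0 * sps.t.sf(abs(t_stat), df=n - 1))
    p = p_two if tails == "two" else _one_tailed(p_two, t_stat)
    return TestResult(statistic=t_stat, df=n - 1, p_value=p, tails=tails)


def pearson(x: Sequence[float], y: Sequence[float], tails: str = "two") -> CorrelationResult:
    """Sample Pearson correlation with a Student-t significance test.

    p comes from t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("pearson needs two equal-length lists of length >= 3")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise DegenerateTestError("zero variance in one of the variables")
    n = x.size
    r = float(sps.pearsonr(x, y).statistic)
    if abs(r) >= 1.0:
        t_stat = float(np.sign(r)) * float("inf")
        p_two = 0.0
    else:
        t_stat = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
        p_two = float(2.0 * sps.t.sf(abs(t_stat), df=n - 2))
    p = p_two if tails == "two" else _one_tailed(p_two, t_stat)
    return CorrelationResult(statistic=t_stat, df=n - 2, p_value=p, tails=tails, r=r)


def _pooled_pairs(records: Iterable[PatientRecord], disease: str):
    """(score, RHI) pairs pooled across phases within one disease group."""
    xs, ys = [], []
    for rec in records:
        if rec.disease != disease:
            continue
        for phase in PHASES:
            if phase in rec.activity_scores and phase in rec.rhi:
                xs.append(rec.activity_scores[phase])
                ys.append(rec.rhi[phase])
    return xs, ys


def run_study_analysis(
    records: Sequence[PatientRecord],
    controls: Mapping[str, Sequence[float]] | None = None,
) -> dict:
    """Full study report: summaries, paired tests and correlations.

    Per-phase cohort summaries are produced for every endpoint any
    record carries; paired t-tests compare t0 against t2 per endpoint;
    Pearson correlations between activity score and RHI are computed per
    disease group, pooled across phases, with both one- and two-tailed
    p-values reported.  ``controls`` optionally maps endpoint names to
    healthy-subject values compared against the patients' t0 values.
    Endpoints with insufficient data are skipped with a logged notice.
    """
    records = list(records)
    if not records:
        raise ValueError("empty cohort")

    report: dict = {
        "cohort": {
            "n_patients": len(records),
            "n_uc": sum(r.disease == "UC" for r in records),
            "n_cd": sum(r.disease == "CD" for r in records),
        },
        "summaries": {},
        "paired_tests": {},
        "correlations": {},
        "notes": [],
    }

    for endpoint in ENDPOINTS:
        per_phase = {}
        for phase in PHASES:
            vals = [
                rec.endpoint(endpoint)[phase]
                for rec in records
                if rec.endpoint(endpoint) and phase in rec.endpoint(endpoint)
            ]
            if vals:
                per_phase[phase] = asdict(summarize(vals))
        if per_phase:
            report["summaries"][endpoint] = per_phase
        else:
            logger.info("endpoint %r absent from all records; skipped", endpoint)
            continue

        x0, x2 = [], []
        for rec in records:
            data = rec.endpoint(endpoint)
            if data and "t0" in data and "t2" in data:
                x0.append(data["t0"])
                x2.append(data["t2"])
        if len(x0) >= 2:
            try:
                res = paired_t(x0, x2, tails="two")
            except DegenerateTestError:
                report["notes"].append(f"paired test on {endpoint} degenerate (no change)")
            else:
                entry = asdict(res)
                entry["p_one_tailed"] = _one_tailed(res.p_value, res.statistic)
                report["paired_tests"][endpoint] = {"t0_vs_t2": entry}
        else:
            logger.info("endpoint %r lacks t0/t2 pairs; paired test skipped", endpoint)

    for disease in ("UC", "CD"):
        xs, ys = _pooled_pairs(records, disease)
        if len(xs) < 3:
            logger.info("disease %s has too few score/RHI pairs; correlation skipped", disease)
            continue
        res = pearson(xs, ys, tails="two")
        report["correlations"][disease] = {
            "score": "PMS" if disease == "UC" else "HBI",
            "n_pairs": len(xs),
            "r": res.r,
            "statistic": res.statistic,
            "df": res.df,
            "p_two_tailed": res.p_value,
            "p_one_tailed": _one_tailed(res.p_value, res.statistic),
        }
    if report["correlations"]:
        report["notes"].append(
            "correlation p-values reported both two- and one-tailed; "
            "tail conventions differ between endpoints in historical reports"
        )

    if controls:
        report["controls"] = {}
        for endpoint, ctrl_vals in controls.items():
            t0_vals = [
                rec.endpoint(endpoint)["t0"]
                for rec in records
                if rec.endpoint(endpoint) and "t0" in rec.endpoint(endpoint)
            ]
            ctrl_vals = list(ctrl_vals)
            if len(t0_vals) < 2 or len(ctrl_vals) < 2:
                logger.info("controls comparison for %r skipped (too few values)", endpoint)
                continue
            if len(t0_vals) == len(ctrl_vals):
                res = paired_t(t0_vals, ctrl_vals, tails="two")
                kind = "paired"
            else:
                w = sps.ttest_ind(t0_vals, ctrl_vals, equal_var=False)
                res = TestResult(
                    statistic=float(w.statistic), df=int(np.floor(w.df)),
                    p_value=float(w.pvalue), tails="two",
                )
                kind = "welch"
            report["controls"][endpoint] = {"test": kind, **asdict(res)}

    return report
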