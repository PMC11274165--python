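"""Seeded synthetic cohorts with the study's statistical structure.

Emulates an 11-patient two-disease IBD cohort observed at three phases
(t0/t1/t2): activity scores and the histological index decline under
treatment, TEER rises, FD4 permeability falls and *Roseburia* abundance
rises.  Endpoints are drawn per phase from moment-matched truncated
normals (the parent mean/sd are solved so the truncated distribution
has exactly the configured mean/sd); the activity score and RHI are
drawn as correlated integers through a Gaussian copula whose latent
correlation is chosen so the POOLED (across-phase) score-RHI Pearson
correlation hits the configured target in expectation.

A single seed governs everything; each patient draws from its own
spawned substream, keyed by patient index, so enlarging the cohort
never reshuffles earlier patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize
from scipy import stats as sps

from . import link
from .clinical_stats import PHASES, PatientRecord

__all__ = [
    "CohortSpec",
    "InfeasibleCorrelationError",
    "default_cohort_spec",
    "generate_cohort",
    "fixture_cohort",
]


class InfeasibleCorrelationError(ValueError):
    """Target pooled correlation needs a latent correlation outside [-1, 1]."""


# In-study reference data: activity scores (PMS for UC / HBI for CD) and
# RHI per patient per phase, plus per-patient disease/therapy labels.
_FIXTURE_ROWS = [
    # (patient_id, disease, therapy, (score t0,t1,t2), (rhi t0,t1,t2))
    (1, "UC", "naive", (8, 4, 4), (17, 8, 8)),
    (2, "UC", "naive", (8, 2, 2), (12, 6, 6)),
    (3, "CD", "naive", (6, 6, 4), (6, 6, 6)),
    (4, "UC", "anti-TNF", (6, 3, 4), (14, 1, 1)),
    (5, "CD", "naive", (7, 5, 1), (12, 1, 1)),
    (6, "CD", "anti-TNF", (5, 4, 3), (6, 6, 6)),
    (7, "UC", "anti-TNF", (11, 1, 2), (23, 6, 6)),
    (8, "CD", "naive", (10, 1, 0), (17, 6, 7)),
    (9, "UC", "anti-TNF", (9, 3, 2), (23, 11, 6)),
    (10, "UC", "naive", (7, 3, 2), (23, 16, 9)),
    (11, "UC", "anti-TNF", (6, 6, 4), (19, 6, 6)),
]

# Cohort summary statistics of the barrier endpoints, per phase (t0, t1, t2):
# TEER in ohm*cm^2, permeability in cm^2/s.
TEER_MEANS = (12.27, 18.12, 18.36)
TEER_STDS = (3.15, 7.23, 4.86)
PM_MEANS = (0.883e-6, 0.814e-6, 0.735e-6)
PM_STDS = (0.451e-6, 0.446e-6, 0.552e-6)
#: Healthy-control summaries for the same endpoints.
TEER_CONTROL = {"mean": 21.15, "std": 9.14}
PM_CONTROL = {"mean": 0.686e-6, "std": 0.365e-6}

#: Coefficient of variation assumed for *Roseburia* abundance draws.
ROSEBURIA_CV = 0.20


def fixture_cohort() -> list[PatientRecord]:
    """The 11 in-study patients with their score and RHI triplets.

    TEER, permeability and *Roseburia* are left unset (only cohort
    summaries of those endpoints are available, not per-patient values).
    """
    return [
        PatientRecord(
            patient_id=pid,
            disease=disease,
            therapy=therapy,
            activity_scores=dict(zip(PHASES, scores)),
            rhi=dict(zip(PHASES, rhi)),
        )
        for pid, disease, therapy, scores, rhi in _FIXTURE_ROWS
    ]


def _fixture_moments():
    scores = np.array([row[3] for row in _FIXTURE_ROWS], dtype=float)
    rhi = np.array([row[4] for row in _FIXTURE_ROWS], dtype=float)
    return (
        tuple(scores.mean(axis=0)),
        tuple(scores.std(axis=0, ddof=1)),
        tuple(rhi.mean(axis=0)),
        tuple(rhi.std(axis=0, ddof=1)),
    )


def _roseburia_phase_means() -> tuple[float, float, float]:
    """Abundance means implied by chaining the two link equations.

    Inverting the permeability link at the per-phase cohort-mean
    permeabilities gives the concentrations that anchor each phase;
    feeding those into the abundance link yields an increasing sequence.
    """
    c1 = [link.invert_link(link.PERMEABILITY_COEFFS, pm) for pm in PM_MEANS]
    return tuple(float(link.eval_link(link.ROSEBURIA_COEFFS, c)) for c in c1)


@dataclass
class CohortSpec:
    """Configuration of the generator.

    ``endpoint_means``/``endpoint_stds`` map endpoint names (``teer``,
    ``pm``, ``rhi``, ``activity``, ``roseburia``) to per-phase (t0, t1,
    t2) values in the endpoint's units.  The score-RHI correlation is
    the target for pairs pooled across phases.
    """

    n_patients: int = 11
    uc_fraction: float = 7 / 11
    endpoint_means: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    endpoint_stds: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    target_score_rhi_correlation: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 <= self.uc_fraction <= 1.0:
            raise ValueError("uc_fraction must lie in [0, 1]")
        if not -1.0 <= self.target_score_rhi_correlation <= 1.0:
            raise ValueError("target correlation must lie in [-1, 1]")
        for name, stds in self.endpoint_stds.items():
            if any(s < 0 for s in stds):
                raise ValueError(f"negative std for endpoint {name!r}")


def default_cohort_spec(seed: int = 0, n_patients: int = 11) -> CohortSpec:
    """Spec reproducing the study conditions: 11 patients, 7 UC / 4 CD."""
    score_means, score_stds, rhi_means, rhi_stds = _fixture_moments()
    ros_means = _roseburia_phase_means()
    ros_stds = tuple(ROSEBURIA_CV * m for m in ros_means)
    return CohortSpec(
        n_patients=n_patients,
        uc_fraction=7 / 11,
        endpoint_means={
            "activity": score_means,
            "rhi": rhi_means,
            "teer": TEER_MEANS,
            "pm": PM_MEANS,
            "roseburia": ros_means,
        },
        endpoint_stds={
            "activity": score_stds,
            "rhi": rhi_stds,
            "teer": TEER_STDS,
            "pm": PM_STDS,
            "roseburia": ros_stds,
        },
        target_score_rhi_correlation=0.75,
        seed=seed,
    )


@lru_cache(maxsize=256)
def _truncnorm_parent(mean: float, std: float, upper: float = np.inf):
    """Parent (mu, sigma) whose [0, upper]-truncated normal has the given moments.

    Solved in std units (the problem is scale-invariant with the lower
    bound at zero), so endpoints spanning many orders of magnitude pose
    no conditioning problem.
    """
    if std == 0.0:
        return mean, 0.0
    m_ratio = mean / std
    u_ratio = upper / std if np.isfinite(upper) else np.inf

    def mismatch(params):
        mu, log_sigma = params
        sigma = np.exp(log_sigma)
        a = (0.0 - mu) / sigma
        b = (u_ratio - mu) / sigma if np.isfinite(u_ratio) else np.inf
        m, v = sps.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [m - m_ratio, np.sqrt(v) - 1.0]

    sol = optimize.fsolve(mismatch, x0=[m_ratio, 0.0], full_output=False)
    return float(sol[0] * std), float(np.exp(sol[1]) * std)


def _draw_truncated(rng: np.random.Generator, mean: float, std: float, upper: float = np.inf) -> float:
    if std == 0.0:
        return mean
    mu, sigma = _truncnorm_parent(mean, std, upper)
    a = (0.0 - mu) / sigma
    b = (upper - mu) / sigma if np.isfinite(upper) else np.inf
    return float(sps.truncnorm.rvs(a, b, loc=mu, scale=sigma, random_state=rng))


def latent_score_rhi_correlation(spec: CohortSpec) -> float:
    """Within-phase latent correlation that yields the pooled target.

    Pooled pairs mix within-phase noise with the systematic co-movement
    of the phase means; decomposing the pooled covariance gives

        rho = (target * total_sd_s * total_sd_r - Cov_phase(mu_s, mu_r))
              / mean_phase(sigma_s * sigma_r)

    which is the latent Gaussian-copula correlation applied per phase.
    Raises :class:`InfeasibleCorrelationError` when |rho| > 1.
    """
    mu_s = np.array(spec.endpoint_means["activity"], dtype=float)
    mu_r = np.array(spec.endpoint_means["rhi"], dtype=float)
    sd_s = np.array(spec.endpoint_stds["activity"], dtype=float)
    sd_r = np.array(spec.endpoint_stds["rhi"], dtype=float)
    between_cov = float(np.mean((mu_s - mu_s.mean()) * (mu_r - mu_r.mean())))
    tot_s = np.sqrt(np.mean(sd_s**2) + np.var(mu_s))
    tot_r = np.sqrt(np.mean(sd_r**2) + np.var(mu_r))
    within = float(np.mean(sd_s * sd_r))
    if within == 0.0:
        return 0.0
    rho = (spec.target_score_rhi_correlation * tot_s * tot_r - between_cov) / within
    if not -1.0 <= rho <= 1.0:
        raise InfeasibleCorrelationError(
            f"pooled target {spec.target_score_rhi_correlation} requires latent rho={rho:.3f}"
        )
    return rho


def _score_draw(rng: np.random.Generator, mean: float, std: float, z: float) -> int:
    # integer score: Gaussian draw via the copula's latent z, rounded, floored at 0
    return int(max(0, round(mean + std * z)))


def generate_cohort(spec: CohortSpec | None = None) -> list[PatientRecord]:
    """Draw a synthetic cohort; deterministic for a given ``spec.seed``."""
    if spec is None:
        spec = default_cohort_spec()
    if set(spec.endpoint_means) != set(spec.endpoint_stds):
        raise ValueError("endpoint_means and endpoint_stds must cover the same endpoints")
    if not spec.endpoint_means:
        base = default_cohort_spec()
        spec = CohortSpec(
            n_patients=spec.n_patients,
            uc_fraction=spec.uc_fraction,
            endpoint_means=base.endpoint_means,
            endpoint_stds=base.endpoint_stds,
            target_score_rhi_correlation=spec.target_score_rhi_correlation,
            seed=spec.seed,
        )
    rho = latent_score_rhi_correlation(spec)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov)

    n_uc = int(round(spec.n_patients * spec.uc_fraction))
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_patients)
    records = []
    for i in range(spec.n_patients):
        rng = np.random.default_rng(streams[i])
        disease = "UC" if i < n_uc else "CD"
        therapy = "naive" if rng.random() < 0.5 else "anti-TNF"
        activity, rhi = {}, {}
        teer, pm, ros = {}, {}, {}
        for j, phase in enumerate(PHASES):
            z = chol @ rng.standard_normal(2)
            activity[phase] = _score_draw(
                rng, spec.endpoint_means["activity"][j], spec.endpoint_stds["activity"][j], z[0]
            )
            rhi[phase] = _score_draw(
                rng, spec.endpoint_means["rhi"][j], spec.endpoint_stds["rhi"][j], z[1]
            )
            teer[phase] = _draw_truncated(
                rng, spec.endpoint_means["teer"][j], spec.endpoint_stds["teer"][j]
            )
            pm[phase] = _draw_truncated(
                rng, spec.endpoint_means["pm"][j], spec.endpoint_stds["pm"][j]
            )
            ros[phase] = _draw_truncated(
                rng, spec.endpoint_means["roseburia"][j], spec.endpoint_stds["roseburia"][j], upper=1.0
            )
        records.append(
            PatientRecord(
                patient_id=i + 1,
                disease=disease,
                therapy=therapy,
                activity_scores=activity,
                rhi=rhi,
                teer=teer,
                pm=pm,
                roseburia=ros,
            )
        )
    return records
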