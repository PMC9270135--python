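"""Synthetic patient cohorts with the structure the evaluation assumes.

No public melasma RCM dataset exists, so this module simulates cohorts with
the statistical shape the method expects: five ordinal RCM severity scores
per patient (each in {1..4}) driving a continuous treatment-effect target
in [0, 1], with higher pathology scores yielding lower expected response.

Ground truth is linear in the (rescaled) scores,

    g(s) = clip(1 - sum_k w_k * (s_k - 1) / 3, 0, 1),

with equal weights w_k = 0.2 by default, optionally plus an interaction
between the dendritic-cell and melanophage scores to stress the hidden
layer. Scores are drawn uniformly over {1..4} with a mild Gaussian-copula
correlation (rho ~ 0.4) between epidermal pigmentation and melanophage
burden — the two pigment-load markers — and the observed target adds
Gaussian noise, clipped back into [0, 1].

Cohort defaults mirror the evaluation design: 240 patients split at random
into 200 training and 40 test samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import norm

from .scoring import OutcomeGrade, RCMAssessment, grade_outcome

#: CSV feature columns, in genome/feature order.
FEATURE_COLUMNS = ["pigment", "dendritic", "melanophage", "elastosis", "vascularity"]
#: Copula correlation between pigmentation (col 0) and melanophages (col 2).
DEFAULT_COPULA_RHO = 0.4


@dataclass(frozen=True)
class CohortSpec:
    """Simulation design: cohort size, split, noise and ground-truth effects."""

    n_patients: int = 240
    n_train: int = 200
    n_test: int = 40
    noise_sd: float = 0.05
    feature_weights: tuple[float, ...] = (0.2, 0.2, 0.2, 0.2, 0.2)
    interaction: float = 0.0
    copula_rho: float = DEFAULT_COPULA_RHO
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("n_train and n_test must be >= 1")
        if self.n_train + self.n_test > self.n_patients:
            raise ValueError("n_train + n_test must not exceed n_patients")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.feature_weights) != 5:
            raise ValueError("feature_weights must have length 5")
        if not (-1.0 < self.copula_rho < 1.0):
            raise ValueError("copula_rho must be in (-1, 1)")


@dataclass(frozen=True)
class PatientRecord:
    """One cohort row: five RCM scores, the continuous target, and its grade."""

    id: int
    features: RCMAssessment
    target: float
    grade: OutcomeGrade

    def __post_init__(self) -> None:
        if not (0.0 <= self.target <= 1.0):
            raise ValueError(f"target must be in [0,1], got {self.target}")


def ground_truth(scores: np.ndarray, spec: CohortSpec) -> np.ndarray:
    """Noiseless treatment-effect g(s) for an (n, 5) array of scores in {1..4}."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    scaled = (scores - 1.0) / 3.0  # each in [0, 1]
    g = 1.0 - scaled @ np.asarray(spec.feature_weights, dtype=float)
    if spec.interaction:
        g = g - spec.interaction * scaled[:, 1] * scaled[:, 2]
    return np.clip(g, 0.0, 1.0)


def _sample_scores(n: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform ordinal scores in {1..4} via a Gaussian copula.

    Marginals are exactly uniform over the four levels; the copula induces
    the requested rank correlation between columns 0 and 2 only.
    """
    cov = np.eye(5)
    cov[0, 2] = cov[2, 0] = rho
    z = rng.multivariate_normal(np.zeros(5), cov, size=n, method="cholesky")
    u = norm.cdf(z)
    return np.minimum(np.floor(u * 4.0).astype(int) + 1, 4)


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Simulate ``spec.n_patients`` records; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    scores = _sample_scores(spec.n_patients, spec.copula_rho, rng)
    g = ground_truth(scores, spec)
    noise = rng.normal(0.0, spec.noise_sd, size=spec.n_patients) if spec.noise_sd > 0 else 0.0
    targets = np.clip(g + noise, 0.0, 1.0)
    records = []
    for i in range(spec.n_patients):
        target = float(targets[i])
        records.append(
            PatientRecord(
                id=i,
                features=RCMAssessment(*(int(s) for s in scores[i])),
                target=target,
                grade=grade_outcome(target),
            )
        )
    return records


def split_cohort(
    records: Sequence[PatientRecord], spec: CohortSpec
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Seeded random disjoint split into (n_train, n_test) records."""
    if len(records) < spec.n_train + spec.n_test:
        raise ValueError(
            f"need at least {spec.n_train + spec.n_test} records, got {len(records)}"
        )
    # distinct stream from generation so regenerating does not correlate
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    perm = rng.permutation(len(records))
    train = [records[i] for i in perm[: spec.n_train]]
    test = [records[i] for i in perm[spec.n_train : spec.n_train + spec.n_test]]
    return train, test


def to_arrays(records: Sequence[PatientRecord]) -> tuple[np.ndarray, np.ndarray]:
    """(features (n,5) float, targets (n,) float) arrays for model code."""
    X = np.array([r.features.as_tuple() for r in records], dtype=float)
    y = np.array([r.target for r in records], dtype=float)
    return X, y


def to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"id": r.id}
        row.update(zip(FEATURE_COLUMNS, r.features.as_tuple()))
        row["target"] = r.target
        row["grade"] = r.grade.name.lower()
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["id", *FEATURE_COLUMNS, "target", "grade"]
    )


def write_cohort(records: Sequence[PatientRecord], path: Union[str, Path]) -> None:
    """Write records as CSV; targets keep full precision (repr round-trip)."""
    df = to_frame(records)
    df.to_csv(path, index=False, float_format="%.17g")


class CohortParseError(ValueError):
    """Malformed cohort file; carries the offending line where known."""


def read_cohort(path: Union[str, Path]) -> list[PatientRecord]:
    """Read a cohort CSV written by :func:`write_cohort` (or hand-made).

    Requires the five feature columns and ``target``; ``id`` defaults to the
    row number and ``grade`` is rederived from the target if absent.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in (*FEATURE_COLUMNS, "target") if c not in df.columns]
    if missing:
        raise CohortParseError(f"missing column(s): {', '.join(missing)}")
    records = []
    for pos, (_, row) in enumerate(df.iterrows()):
        line_no = pos + 2  # header is line 1
        try:
            features = RCMAssessment(*(int(row[c]) for c in FEATURE_COLUMNS))
            target = float(row["target"])
            records.append(
                PatientRecord(
                    id=int(row["id"]) if "id" in df.columns else pos,
                    features=features,
                    target=target,
                    grade=grade_outcome(target),
                )
            )
        except (ValueError, TypeError) as exc:
            raise CohortParseError(f"line {line_no}: {exc}") from exc
    return records
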