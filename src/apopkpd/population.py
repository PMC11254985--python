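"""Virtual-population sampling (the synthetic-data generator).

Subjects are realized around the typical parameter vector with independent,
median-preserving lognormal inter-individual variability (IIV): a varied
parameter theta becomes ``theta * exp(eta)`` with
``eta ~ Normal(0, ln(1 + cv^2))``, so the coefficient of variation of the
sampled parameter equals ``cv`` exactly in distribution and its median stays
at the typical value.  The study design evaluates cv = 0.15, 0.30, 0.45;
``cv = 0`` reproduces the typical subject.

Variability is applied by default to the PK parameters and to the
drug-sensitivity parameters of the effect model (ke0, EC50).  Structural
constants stay fixed across subjects: bioavailability (a formulation
property), the Emax fraction and Hill exponent (fixed at 1 and 3 in the
source effect model), the MCIC response threshold (a clinical definition,
not a biological parameter), and the baseline motor score B0 — response
endpoints are defined relative to each subject's own baseline, and the
published summary statistics are consistent with a fixed baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .parameters import (
    InvalidParameterError,
    PdParameters,
    PkParameters,
    PkParametersSC,
    PkParametersSL,
)

#: Parameters receiving IIV unless the caller overrides the set.
DEFAULT_VARIED_PARAMETERS = frozenset(
    {
        "clearance_apparent",
        "volume_apparent",
        "ka",
        "k12",
        "k21",
        "ke0",
        "ec50",
    }
)

_PK_FIELDS = {
    "clearance_apparent",
    "volume_apparent",
    "ka",
    "k12",
    "k21",
    "bioavailability",
}
_PD_FIELDS = {"ke0", "ec50", "baseline_b0", "emax", "hill_g", "mcic"}


@dataclass(frozen=True)
class IivSpec:
    """Inter-individual-variability specification for one scenario cell."""

    cv: float
    varied_parameters: frozenset = DEFAULT_VARIED_PARAMETERS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise InvalidParameterError(f"cv must be >= 0, got {self.cv}")
        unknown = set(self.varied_parameters) - (_PK_FIELDS | _PD_FIELDS)
        if unknown:
            raise InvalidParameterError(f"unknown varied parameter(s): {sorted(unknown)}")
        object.__setattr__(self, "varied_parameters", frozenset(self.varied_parameters))

    @property
    def log_sd(self) -> float:
        """Standard deviation of eta: sqrt(ln(1 + cv^2))."""
        return float(np.sqrt(np.log1p(self.cv**2)))


@dataclass(frozen=True)
class SubjectParameters:
    """One simulated subject's realized PK and PD parameter vectors."""

    subject_id: int
    pk: PkParameters
    pd: PdParameters


def sample_population(
    pk_typical: PkParameters,
    pd_typical: PdParameters,
    iiv: IivSpec,
    n: int,
) -> list[SubjectParameters]:
    """Draw ``n`` subjects around the typical vectors, reproducibly from
    ``iiv.seed``.

    Varied parameters are sampled independently (no between-parameter
    correlation); non-varied parameters are copied.  The same seed always
    yields the identical population regardless of which parameters vary.
    """
    if n < 1:
        raise InvalidParameterError(f"population size must be >= 1, got {n}")
    pk_fields = [f.name for f in fields(pk_typical)]
    pd_fields_ = [f.name for f in fields(pd_typical)]
    rng = np.random.default_rng(iiv.seed)
    # One eta column per *possible* parameter, in fixed field order, so the
    # draw stream is independent of the varied-parameter selection.
    all_names = pk_fields + pd_fields_
    etas = rng.normal(0.0, iiv.log_sd if iiv.cv > 0 else 0.0, size=(n, len(all_names)))
    factors = {
        name: np.exp(etas[:, j]) if (iiv.cv > 0 and name in iiv.varied_parameters) else np.ones(n)
        for j, name in enumerate(all_names)
    }
    subjects = []
    for i in range(n):
        pk_i = replace(pk_typical, **{f: getattr(pk_typical, f) * factors[f][i] for f in pk_fields})
        pd_i = replace(pd_typical, **{f: getattr(pd_typical, f) * factors[f][i] for f in pd_fields_})
        subjects.append(SubjectParameters(subject_id=i, pk=pk_i, pd=pd_i))
    return subjects


def population_to_frame(subjects: Sequence[SubjectParameters]) -> pd.DataFrame:
    """One row per subject, one column per realized parameter (replayable)."""
    rows = []
    for s in subjects:
        row = {"subject_id": s.subject_id}
        row.update({f.name: getattr(s.pk, f.name) for f in fields(s.pk)})
        row.update({f.name: getattr(s.pd, f.name) for f in fields(s.pd)})
        rows.append(row)
    return pd.DataFrame(rows)


def population_from_frame(frame: pd.DataFrame, formulation: str) -> list[SubjectParameters]:
    """Rebuild a population from :func:`population_to_frame` output."""
    cls = {"sc": PkParametersSC, "sl": PkParametersSL}.get(formulation.lower())
    if cls is None:
        raise InvalidParameterError(f"unknown formulation {formulation!r}")
    pk_names = [f.name for f in fields(cls)]
    pd_names = [f.name for f in fields(PdParameters)]
    subjects = []
    for _, row in frame.iterrows():
        subjects.append(
            SubjectParameters(
                subject_id=int(row["subject_id"]),
                pk=cls(**{k: float(row[k]) for k in pk_names}),
                pd=PdParameters(**{k: float(row[k]) for k in pd_names}),
            )
        )
    return subjects
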