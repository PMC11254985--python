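"""Model parameter containers and the shipped default parameter sets.

Parameters follow the NONMEM-style population-PK convention: disposition
parameters are apparent (CL/F, V/F), all rate constants are first-order and
expressed in h^-1, concentrations in ng/mL, doses in mg.  The defaults are
loaded from ``data/default_parameters.yaml`` inside the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Union

import yaml

#: mg -> ng
MG_TO_NG = 1.0e6

#: relative |ka - kel| below which the SC model switches to the ka == kel
#: limit form of the absorption solution (removable singularity).
KA_KEL_DEGENERACY_RTOL = 1.0e-8


class InvalidParameterError(ValueError):
    """Raised when a parameter vector violates a model invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(msg)


@dataclass(frozen=True)
class PkParametersSC:
    """One-compartment, first-order absorption/elimination (subcutaneous).

    Attributes
    ----------
    clearance_apparent : float
        CL/F in L/h.
    volume_apparent : float
        V/F in L.
    ka : float
        First-order absorption rate constant, h^-1.
    bioavailability : float
        Fraction F in (0, 1].
    """

    clearance_apparent: float
    volume_apparent: float
    ka: float
    bioavailability: float = 1.0

    def __post_init__(self) -> None:
        _require(self.clearance_apparent > 0, "clearance_apparent must be > 0")
        _require(self.volume_apparent > 0, "volume_apparent must be > 0")
        _require(self.ka > 0, "ka must be > 0")
        _require(0 < self.bioavailability <= 1, "bioavailability must be in (0, 1]")

    @property
    def kel(self) -> float:
        """Elimination rate constant CL/V, h^-1 (always derived)."""
        return self.clearance_apparent / self.volume_apparent

    @property
    def is_degenerate(self) -> bool:
        """True when ka is numerically indistinguishable from kel."""
        return abs(self.ka - self.kel) < KA_KEL_DEGENERACY_RTOL * self.kel


@dataclass(frozen=True)
class PkParametersSL:
    """Two-compartment disposition with a three-transit absorption chain
    (sublingual).

    The absorbed dose passes through three transit compartments in series
    (each with rate ``ka``) before reaching the central compartment, which
    exchanges with a peripheral compartment at rates ``k12``/``k21`` and is
    eliminated at ``kel = CL/V``.
    """

    clearance_apparent: float
    volume_apparent: float
    ka: float
    k12: float
    k21: float
    bioavailability: float

    def __post_init__(self) -> None:
        _require(self.clearance_apparent > 0, "clearance_apparent must be > 0")
        _require(self.volume_apparent > 0, "volume_apparent must be > 0")
        _require(self.ka > 0, "ka must be > 0")
        _require(self.k12 > 0, "k12 must be > 0")
        _require(self.k21 > 0, "k21 must be > 0")
        _require(0 < self.bioavailability <= 1, "bioavailability must be in (0, 1]")

    @property
    def kel(self) -> float:
        """Elimination rate constant CL/V, h^-1 (always derived)."""
        return self.clearance_apparent / self.volume_apparent


@dataclass(frozen=True)
class PdParameters:
    """Effect-compartment + sigmoid-Emax model for the UPDRS motor score.

    The effect-site concentration Ce equilibrates with plasma at first-order
    rate ``ke0``; the score is ``Eff = B0 * (1 - Emax * Ce^g / (Ce^g + EC50^g))``,
    i.e. the drug can remove at most ``B0 * Emax`` points from baseline.
    ``mcic`` is the (positive) minimum clinically important change in the
    motor score used to declare a response.
    """

    ke0: float
    ec50: float
    baseline_b0: float
    emax: float = 1.0
    hill_g: float = 3.0
    mcic: float = 3.25

    def __post_init__(self) -> None:
        _require(self.ke0 > 0, "ke0 must be > 0")
        _require(self.ec50 > 0, "ec50 must be > 0")
        _require(self.baseline_b0 > 0, "baseline_b0 must be > 0")
        _require(0 < self.emax <= 1, "emax must be in (0, 1]")
        _require(self.hill_g > 0, "hill_g must be > 0")
        _require(self.mcic > 0, "mcic must be > 0")

    @property
    def response_attainable(self) -> bool:
        """Whether the MCIC lies below the maximum attainable change B0*Emax.

        A sampled subject may legitimately fall below this bound (it can then
        never respond); a *typical* vector violating it makes the whole study
        degenerate and is rejected by the trial layer.
        """
        return self.mcic < self.baseline_b0 * self.emax


PkParameters = Union[PkParametersSC, PkParametersSL]

_PK_CLASSES = {"sc": PkParametersSC, "sl": PkParametersSL}


def _load_defaults() -> dict:
    text = resources.files("apopkpd").joinpath("data/default_parameters.yaml").read_text()
    return yaml.safe_load(text)


def default_pk_parameters(formulation: str) -> PkParameters:
    """Return the shipped typical PK parameter set for ``'sc'`` or ``'sl'``."""
    key = formulation.lower()
    if key not in _PK_CLASSES:
        raise InvalidParameterError(f"unknown formulation {formulation!r}; expected 'sc' or 'sl'")
    raw = _load_defaults()["pk"][key]
    return _PK_CLASSES[key](**raw)


def default_pd_parameters() -> PdParameters:
    """Return the shipped typical PK/PD (effect-model) parameter set."""
    return PdParameters(**_load_defaults()["pd"])


def with_overrides(params, **overrides):
    """Return a copy of a parameter dataclass with named fields replaced."""
    valid = {f.name for f in fields(params)}
    unknown = set(overrides) - valid
    if unknown:
        raise InvalidParameterError(f"unknown parameter override(s): {sorted(unknown)}")
    return replace(params, **overrides)
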