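"""Literature equations predicting body surface area (BSA) from weight and height.

Ten equations are registered, spanning the classical DuBois power law through
recent equations fitted against 3D-optical-imaging criterion data (Tikuisis,
Kuehnapfel, Ashby-Thompson). All equations take weight in kilograms and height
in centimetres and return BSA in square metres; three of them carry distinct
male/female parameter sets and one (Livingston) uses weight alone.

Unit discipline is part of the contract: inputs far outside the human range
(e.g. weight passed in grams, height in metres) trigger a
:class:`UnitRangeWarning` so silent unit mistakes surface early.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "Subject",
    "EquationSpec",
    "PowerLawForm",
    "LinearForm",
    "UnitRangeWarning",
    "EQUATIONS",
    "METHOD_IDS",
    "predict_bsa",
    "predict_all",
    "registry_table",
]

SEXES = ("male", "female")

# Plausible human measurement ranges; outside these the equations remain
# algebraically defined but are unvalidated, so we warn instead of raising.
WEIGHT_RANGE_KG = (20.0, 150.0)
HEIGHT_RANGE_CM = (120.0, 220.0)


class UnitRangeWarning(UserWarning):
    """Input lies outside the validated human range — possible unit error."""


@dataclass(frozen=True)
class PowerLawForm:
    """BSA = coefficient * weight**weight_exp * height**height_exp.

    ``height_exp=None`` marks a weight-only equation.
    """

    coefficient: float
    weight_exp: float
    height_exp: Optional[float] = None

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("power-law coefficient must be positive")

    def evaluate(self, weight_kg: float, height_cm: Optional[float]) -> float:
        value = self.coefficient * weight_kg**self.weight_exp
        if self.height_exp is not None:
            value *= height_cm**self.height_exp
        return value


@dataclass(frozen=True)
class LinearForm:
    """BSA = slope * (weight + height) + intercept (Sendroy's chart fit)."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("linear slope must be positive")

    def evaluate(self, weight_kg: float, height_cm: Optional[float]) -> float:
        return self.slope * (weight_kg + height_cm) + self.intercept


@dataclass(frozen=True)
class EquationSpec:
    """One registered BSA equation, possibly with per-sex parameter sets."""

    method_id: str
    label: str
    forms: dict  # sex -> form, or {"any": form} for sex-neutral equations
    requires_height: bool = True

    @property
    def sex_specific(self) -> bool:
        return "any" not in self.forms

    def form_for(self, sex: Optional[str]):
        if not self.sex_specific:
            return self.forms["any"]
        if sex not in SEXES:
            raise ValueError(
                f"equation '{self.method_id}' is sex-specific; sex must be one of {SEXES}"
            )
        return self.forms[sex]


def _neutral(form) -> dict:
    return {"any": form}


EQUATIONS: dict[str, EquationSpec] = {
    spec.method_id: spec
    for spec in (
        EquationSpec(
            "dubois",
            "DuBois",
            _neutral(PowerLawForm(0.007184, 0.425, 0.725)),
        ),
        EquationSpec(
            "sendroy",
            "Sendroy",
            _neutral(LinearForm(0.0097, -0.545)),
        ),
        EquationSpec(
            "gehan",
            "Gehan",
            _neutral(PowerLawForm(0.0235, 0.51456, 0.42246)),
        ),
        EquationSpec(
            "mosteller",
            "Mosteller",
            _neutral(PowerLawForm(0.016667, 0.5, 0.5)),
        ),
        EquationSpec(
            "shuter",
            "Shuter",
            _neutral(PowerLawForm(0.00949, 0.441, 0.655)),
        ),
        EquationSpec(
            "tikuisis",
            "Tikuisis",
            {
                "male": PowerLawForm(0.01281, 0.44, 0.60),
                "female": PowerLawForm(0.01474, 0.47, 0.55),
            },
        ),
        EquationSpec(
            "livingston",
            "Livingston",
            _neutral(PowerLawForm(0.1173, 0.6466, None)),
            requires_height=False,
        ),
        EquationSpec(
            "schlich",
            "Schlich",
            {
                "male": PowerLawForm(0.000579479, 0.38, 1.24),
                "female": PowerLawForm(0.000975482, 0.46, 1.08),
            },
        ),
        EquationSpec(
            "kuehnapfel",
            "Kuehnapfel",
            _neutral(PowerLawForm(0.015, 0.4259, 0.5751)),
        ),
        EquationSpec(
            "ashby_thompson",
            "Ashby-Thompson",
            {
                "male": PowerLawForm(0.01624, 0.4725, 0.5231),
                "female": PowerLawForm(0.01522, 0.4921, 0.5231),
            },
        ),
    )
}

METHOD_IDS: tuple = tuple(EQUATIONS)


@dataclass
class Subject:
    """A measured athlete: anthropometry plus optional echo / criterion data."""

    id: str
    sex: str
    weight_kg: float
    height_cm: float
    criterion_bsa_m2: Optional[float] = None
    echo: Optional["EchoMeasurements"] = field(default=None)  # noqa: F821

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.weight_kg > 0:
            raise ValueError("weight must be strictly positive (kg)")
        if not self.height_cm > 0:
            raise ValueError("height must be strictly positive (cm)")


def _check_ranges(weight_kg: float, height_cm: Optional[float]) -> None:
    lo, hi = WEIGHT_RANGE_KG
    if not lo <= weight_kg <= hi:
        warnings.warn(
            f"weight {weight_kg} kg outside validated range {WEIGHT_RANGE_KG}; "
            "check units (kg expected)",
            UnitRangeWarning,
            stacklevel=3,
        )
    if height_cm is not None:
        lo, hi = HEIGHT_RANGE_CM
        if not lo <= height_cm <= hi:
            warnings.warn(
                f"height {height_cm} cm outside validated range {HEIGHT_RANGE_CM}; "
                "check units (cm expected)",
                UnitRangeWarning,
                stacklevel=3,
            )


def predict_bsa(
    method_id: str,
    weight_kg: float,
    height_cm: Optional[float] = None,
    sex: Optional[str] = None,
) -> float:
    """Evaluate one registered equation.

    Parameters
    ----------
    method_id
        One of :data:`METHOD_IDS`.
    weight_kg, height_cm
        Body weight in kilograms and stature in centimetres. Height may be
        omitted only for the weight-only Livingston equation.
    sex
        ``"male"`` or ``"female"``; required for the sex-specific equations
        (Tikuisis, Schlich, Ashby-Thompson).

    Returns
    -------
    float
        BSA in m² at full floating precision (round only for reporting).
    """
    try:
        spec = EQUATIONS[method_id]
    except KeyError:
        raise ValueError(
            f"unknown method_id {method_id!r}; expected one of {METHOD_IDS}"
        ) from None
    if not weight_kg > 0:
        raise ValueError("weight must be strictly positive (kg)")
    if spec.requires_height:
        if height_cm is None:
            raise ValueError(f"equation '{method_id}' requires height (cm)")
        if not height_cm > 0:
            raise ValueError("height must be strictly positive (cm)")
    _check_ranges(weight_kg, height_cm if spec.requires_height else None)
    form = spec.form_for(sex)
    return form.evaluate(weight_kg, height_cm)


def predict_all(subject: Subject) -> dict:
    """Evaluate every registered equation for one subject.

    Returns a dict mapping method_id -> BSA (m²), in registry (publication)
    order. Errors from individual equations propagate annotated with the
    method id.
    """
    estimates = {}
    for method_id in METHOD_IDS:
        try:
            estimates[method_id] = predict_bsa(
                method_id, subject.weight_kg, subject.height_cm, subject.sex
            )
        except ValueError as exc:
            raise ValueError(f"[{method_id}] {exc}") from exc
    return estimates


def registry_table() -> list[dict]:
    """Machine-readable dump of the equation registry (JSON-serialisable)."""
    rows = []
    for spec in EQUATIONS.values():
        for sex, form in spec.forms.items():
            row = {
                "method_id": spec.method_id,
                "label": spec.label,
                "sex": sex,
                "requires_height": spec.requires_height,
            }
            if isinstance(form, PowerLawForm):
                row.update(
                    form="power_law",
                    coefficient=form.coefficient,
                    weight_exponent=form.weight_exp,
                    height_exponent=form.height_exp,
                )
            else:
                row.update(form="linear", slope=form.slope, intercept=form.intercept)
            rows.append(row)
    return rows


def registry_json(indent: int = 2) -> str:
    return json.dumps(registry_table(), indent=indent)
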