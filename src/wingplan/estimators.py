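"""Closed-form folded-wing estimators of total wing area and aspect ratio.

The folded-wing method estimates the total planform area of both wings plus
the intervening body from three linear measurements that can be taken on an
ordinary study-skin specimen:

``WS``
    wingspan — wingtip-to-wingtip distance of the fully extended wings (cm);
``WL``
    wing length — distance from the wrist joint to the tip of the longest
    primary feather on the folded wing (cm);
``S1``
    wing width — distance from the wrist joint to the tip of the first
    secondary feather on the folded wing (cm), a proxy for wing chord.

The distal (hand-) wing is modelled as a simple geometric shape whose
dimensions are ``WL`` and ``S1``; the remaining area between the two
hand-wings (the "medial box") is the rectangle ``(WS - 2*WL) * S1``.  Three
named hand-wing geometries are supported, plus a continuous mixture family
that interpolates between them:

====================  =============================  =======================
model                 hand-wing area (both wings)    total area
====================  =============================  =======================
Triangle              ``WL*S1``                      ``(WS - WL)*S1``
Ellipse               ``(pi/2)*WL*S1``               ``(pi/2)*WL*S1 + box``
Ellipse-Triangle      ``((pi+1)/3)*WL*S1``           ``((pi+1)/3)*WL*S1 + box``
Mixture(f)            ``WL*S1*(f*pi/2 + 1 - f)``     hand + box
====================  =============================  =======================

The mixture fraction ``f`` is the share of ``S1`` occupied by a quarter
ellipse (the rest is a right triangle): ``f = 0`` is the Triangle model,
``f = 1`` the Ellipse model, and ``f = 2/3`` the Ellipse-Triangle model.
The wing aspect ratio is ``WS**2 / total_area``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PlanformModel",
    "FoldedWingMeasurements",
    "WingAreaEstimate",
    "AspectRatioValue",
    "InvalidMeasurementError",
    "GeometryViolationError",
    "hand_wing_area",
    "medial_box_area",
    "total_wing_area",
    "aspect_ratio",
]


class InvalidMeasurementError(ValueError):
    """A linear measurement or area is non-positive or missing."""


class GeometryViolationError(ValueError):
    """Measurements violate the planform geometry (e.g. WS < 2*WL)."""


class PlanformModel:
    """Hand-wing geometry, parameterised by the ellipse fraction ``f``.

    ``f`` is the fraction of the wing width ``S1`` occupied by a quarter
    ellipse; the remaining ``(1 - f) * S1`` is a right triangle.  Named
    models are exposed as class attributes (``TRIANGLE``, ``ELLIPSE``,
    ``ELLIPSE_TRIANGLE``); any other ``f`` in [0, 1] is an explicit
    ``MIXTURE`` — an extension beyond the three published geometries, and
    flagged as such in ``is_extension``.
    """

    __slots__ = ("name", "ellipse_fraction")

    TRIANGLE: "PlanformModel"
    ELLIPSE: "PlanformModel"
    ELLIPSE_TRIANGLE: "PlanformModel"

    def __init__(self, name: str, ellipse_fraction: float):
        f = float(ellipse_fraction)
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"ellipse fraction must be in [0, 1], got {f}")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "ellipse_fraction", f)

    def __setattr__(self, *a):  # immutable
        raise AttributeError("PlanformModel is immutable")

    @classmethod
    def mixture(cls, ellipse_fraction: float) -> "PlanformModel":
        """Mixture model with an explicit ellipse fraction."""
        f = float(ellipse_fraction)
        for named in (cls.TRIANGLE, cls.ELLIPSE_TRIANGLE, cls.ELLIPSE):
            if f == named.ellipse_fraction:
                return named
        return cls("MIXTURE", f)

    @classmethod
    def from_name(cls, name: str) -> "PlanformModel":
        """Resolve a model from a user-facing name like ``ellipse-triangle``."""
        key = name.strip().lower().replace("-", "_").replace(" ", "_")
        table = {
            "triangle": cls.TRIANGLE,
            "ellipse": cls.ELLIPSE,
            "ellipse_triangle": cls.ELLIPSE_TRIANGLE,
        }
        try:
            return table[key]
        except KeyError:
            raise ValueError(
                f"unknown planform model {name!r}; expected one of "
                "triangle, ellipse, ellipse-triangle"
            ) from None

    @property
    def is_extension(self) -> bool:
        """True for mixture fractions outside the three published geometries."""
        return self.name == "MIXTURE"

    @property
    def hand_coefficient(self) -> float:
        """Multiplier c in hand_area = c * WL * S1 (both wings combined)."""
        f = self.ellipse_fraction
        return f * math.pi / 2.0 + (1.0 - f)

    def __repr__(self) -> str:
        if self.name == "MIXTURE":
            return f"PlanformModel.mixture({self.ellipse_fraction:g})"
        return f"PlanformModel.{self.name}"

    def __eq__(self, other):
        return (
            isinstance(other, PlanformModel)
            and self.ellipse_fraction == other.ellipse_fraction
        )

    def __hash__(self):
        return hash(self.ellipse_fraction)


PlanformModel.TRIANGLE = PlanformModel("TRIANGLE", 0.0)
PlanformModel.ELLIPSE = PlanformModel("ELLIPSE", 1.0)
PlanformModel.ELLIPSE_TRIANGLE = PlanformModel("ELLIPSE_TRIANGLE", 2.0 / 3.0)


@dataclass(frozen=True)
class FoldedWingMeasurements:
    """The measurement triplet (WS, WL, S1) for one specimen, in cm."""

    wingspan: float
    wing_length: float
    wing_width: float
    specimen_id: str = ""
    species: str = ""

    def __post_init__(self):
        for name in ("wingspan", "wing_length", "wing_width"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v) or v <= 0:
                raise InvalidMeasurementError(
                    f"{name} must be a positive finite number, got {v!r}"
                    + (f" (specimen {self.specimen_id})" if self.specimen_id else "")
                )

    def scaled(self, k: float) -> "FoldedWingMeasurements":
        """All three lengths multiplied by ``k`` (unit conversion helper)."""
        return FoldedWingMeasurements(
            self.wingspan * k,
            self.wing_length * k,
            self.wing_width * k,
            self.specimen_id,
            self.species,
        )


@dataclass(frozen=True)
class WingAreaEstimate:
    """Total wing area (cm^2) split into hand-wing and medial-box components."""

    total_area: float
    hand_area: float
    box_area: float
    model: PlanformModel
    box_clamped: bool = False

    def __post_init__(self):
        if self.hand_area < 0 or self.box_area < 0:
            raise InvalidMeasurementError("area components must be non-negative")


@dataclass(frozen=True)
class AspectRatioValue:
    """Dimensionless aspect ratio WS^2 / A with its inputs recorded."""

    value: float
    wingspan_used: float
    area_used: float


def hand_wing_area(model: PlanformModel, wing_length: float, wing_width: float) -> float:
    """Combined hand-wing area of both wings, cm^2.

    Triangle: ``WL*S1`` (two right triangles of area ``WL*S1/2``);
    Ellipse: ``(pi/2)*WL*S1`` (two half- or quarter-ellipses — both give the
    same area); Ellipse-Triangle: ``((pi+1)/3)*WL*S1``; general mixture:
    ``WL*S1*(f*pi/2 + 1 - f)``.
    """
    if wing_length <= 0 or wing_width <= 0:
        raise InvalidMeasurementError(
            f"wing_length and wing_width must be positive, got "
            f"WL={wing_length!r}, S1={wing_width!r}"
        )
    return wing_length * wing_width * model.hand_coefficient


def medial_box_area(
    wingspan: float,
    wing_length: float,
    wing_width: float,
    *,
    clamp: bool = False,
    specimen_id: str = "",
) -> float:
    """Area of the medial box ``(WS - 2*WL) * S1``, cm^2.

    The box is the rectangle spanning the body and proximal wings between the
    two hand-wings.  ``WS < 2*WL`` is geometrically impossible for the model
    and raises :class:`GeometryViolationError` unless ``clamp`` is set, in
    which case the box area is clamped to zero (the caller is expected to
    flag the record).
    """
    if wingspan <= 0 or wing_length <= 0 or wing_width <= 0:
        raise InvalidMeasurementError(
            "wingspan, wing_length and wing_width must be positive"
        )
    span_excess = wingspan - 2.0 * wing_length
    if span_excess < 0:
        if not clamp:
            who = f" for specimen {specimen_id!r}" if specimen_id else ""
            raise GeometryViolationError(
                f"wingspan {wingspan} < 2 * wing length {wing_length}{who}: "
                "the medial box would have negative area (use clamp to force 0)"
            )
        return 0.0
    return span_excess * wing_width


def total_wing_area(
    model: PlanformModel,
    m: FoldedWingMeasurements,
    *,
    clamp: bool = False,
) -> WingAreaEstimate:
    """Total wing area estimate for one specimen under a hand-wing geometry.

    Returns the hand-wing and medial-box components along with their sum;
    the components always add exactly to the total.  For the Triangle model
    the total simplifies algebraically to ``(WS - WL) * S1``.
    """
    hand = hand_wing_area(model, m.wing_length, m.wing_width)
    raw_excess = m.wingspan - 2.0 * m.wing_length
    box = medial_box_area(
        m.wingspan, m.wing_length, m.wing_width, clamp=clamp,
        specimen_id=m.specimen_id,
    )
    return WingAreaEstimate(
        total_area=hand + box,
        hand_area=hand,
        box_area=box,
        model=model,
        box_clamped=raw_excess < 0,
    )


def aspect_ratio(wingspan: float, total_area: float) -> AspectRatioValue:
    """Wing aspect ratio ``WS^2 / A`` (dimensionless).

    Higher values indicate elongated, aerodynamically efficient wings
    (albatross ~14) and lower values short rounded wings (~4).
    """
    if wingspan <= 0:
        raise InvalidMeasurementError(f"wingspan must be positive, got {wingspan!r}")
    if total_area <= 0:
        raise InvalidMeasurementError(f"total area must be positive, got {total_area!r}")
    return AspectRatioValue(
        value=wingspan * wingspan / total_area,
        wingspan_used=wingspan,
        area_used=total_area,
    )
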