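"""10-component, 100-point diet quality score (DQS).

The DQS rates intake of ten food/beverage categories on a 0 (unhealthiest)
to 10 (healthiest) scale and sums them to a 0-100 total, higher = healthier.
Six components reward higher intake (vegetables, fruits, fish, dairy, whole
grains, vegetable oils); four reward lower intake (refined grains, processed
meats, unprocessed red meats, sugar-sweetened beverages).

Component scoring interpolates linearly between two intake anchors and
clamps to [0, 10]; reverse-scored components flip the scale.  Anchors and
units are configuration data loaded from a YAML scale file; a default set is
shipped with the package (``data/dqs_scales.yaml``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ComponentScale",
    "DQSResult",
    "FoodChange",
    "DQS_COMPONENTS",
    "load_scales",
    "default_scales",
    "score_component",
    "score_dqs",
    "score_dqs_table",
    "healthiest_intake",
    "unhealthiest_intake",
    "dqs_increment_equivalents",
    "apply_food_changes",
]

#: Canonical component order of the 10-item score.
DQS_COMPONENTS: tuple[str, ...] = (
    "vegetables",
    "fruits",
    "fish",
    "dairy",
    "whole_grains",
    "vegetable_oils",
    "refined_grains",
    "processed_meats",
    "unprocessed_red_meats",
    "sugar_sweetened_beverages",
)

HEALTHY_HIGH = "healthy_high"
HEALTHY_LOW = "healthy_low"


@dataclass(frozen=True)
class ComponentScale:
    """Scoring rule for one DQS component.

    ``healthy_high`` components map intake ``anchor_lo`` -> 0 points and
    ``anchor_hi`` -> 10 points; ``healthy_low`` components are
    reverse-scored (``anchor_lo`` -> 10, ``anchor_hi`` -> 0).  Intake
    between the anchors interpolates linearly; outside them the score is
    clamped to [0, 10].
    """

    name: str
    direction: str
    anchor_lo: float
    anchor_hi: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.direction not in (HEALTHY_HIGH, HEALTHY_LOW):
            raise ValueError(
                f"direction must be '{HEALTHY_HIGH}' or '{HEALTHY_LOW}', "
                f"got {self.direction!r}"
            )
        if not self.anchor_lo < self.anchor_hi:
            raise ValueError(
                f"{self.name}: anchor_lo ({self.anchor_lo}) must be < "
                f"anchor_hi ({self.anchor_hi})"
            )


@dataclass(frozen=True)
class DQSResult:
    """Total diet quality score (0-100) with the 10 component scores."""

    total: float
    per_component: dict[str, float]


@dataclass(frozen=True)
class FoodChange:
    """A single-component intake change and the score change it produces."""

    component: str
    intake_delta: float
    score_delta: float
    units: str

    @property
    def description(self) -> str:
        verb = "increase" if self.intake_delta >= 0 else "decrease"
        return (
            f"{verb} {self.component.replace('_', ' ')} by "
            f"{abs(self.intake_delta):.2f} {self.units} "
            f"(+{self.score_delta:.1f} DQS points)"
        )


def load_scales(path) -> dict[str, ComponentScale]:
    """Load a component scale set from a YAML scale file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    scales = {
        name: ComponentScale(name=name, **spec)
        for name, spec in raw["components"].items()
    }
    _check_components(scales.keys())
    return scales


def default_scales() -> dict[str, ComponentScale]:
    """The scale set shipped with the package."""
    ref = resources.files("span_mortality").joinpath("data/dqs_scales.yaml")
    with resources.as_file(ref) as path:
        return load_scales(path)


def _check_components(names: Iterable[str]) -> None:
    names = set(names)
    missing = set(DQS_COMPONENTS) - names
    extra = names - set(DQS_COMPONENTS)
    if missing:
        raise ValueError(f"missing DQS components: {sorted(missing)}")
    if extra:
        raise ValueError(f"unknown DQS components: {sorted(extra)}")


def score_component(intake: float, scale: ComponentScale) -> float:
    """Score one component's intake on the 0-10 scale."""
    intake = float(intake)
    if not np.isfinite(intake) or intake < 0:
        raise ValueError(
            f"{scale.name}: intake must be a finite non-negative frequency, "
            f"got {intake}"
        )
    frac = (intake - scale.anchor_lo) / (scale.anchor_hi - scale.anchor_lo)
    frac = min(max(frac, 0.0), 1.0)
    if scale.direction == HEALTHY_LOW:
        frac = 1.0 - frac
    return 10.0 * frac


def score_dqs(
    response: Mapping[str, float], scales: Mapping[str, ComponentScale]
) -> DQSResult:
    """Score a full 10-component FFQ response.

    Strict: the response must contain exactly the 10 scored components;
    missing or extra components raise a ``ValueError`` naming them.
    """
    _check_components(scales.keys())
    missing = [c for c in DQS_COMPONENTS if c not in response]
    if missing:
        raise ValueError(f"FFQ response missing components: {missing}")
    extra = sorted(set(response) - set(DQS_COMPONENTS))
    if extra:
        raise ValueError(f"FFQ response has unknown components: {extra}")
    per = {c: score_component(response[c], scales[c]) for c in DQS_COMPONENTS}
    return DQSResult(total=float(sum(per.values())), per_component=per)


def score_dqs_table(
    ffq: pd.DataFrame, scales: Mapping[str, ComponentScale]
) -> pd.DataFrame:
    """Vectorised scoring of an FFQ table (one column per component).

    Returns a frame with the 10 per-component scores plus a ``dqs`` total.
    """
    _check_components(scales.keys())
    missing = [c for c in DQS_COMPONENTS if c not in ffq.columns]
    if missing:
        raise ValueError(f"FFQ table missing components: {missing}")
    out = {}
    for c in DQS_COMPONENTS:
        s = scales[c]
        vals = ffq[c].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError(f"{c}: intakes must be finite and non-negative")
        frac = np.clip((vals - s.anchor_lo) / (s.anchor_hi - s.anchor_lo), 0, 1)
        if s.direction == HEALTHY_LOW:
            frac = 1.0 - frac
        out[c] = 10.0 * frac
    scored = pd.DataFrame(out, index=ffq.index)
    scored["dqs"] = scored[list(DQS_COMPONENTS)].sum(axis=1)
    return scored


def healthiest_intake(scale: ComponentScale) -> float:
    """The intake at which the component scores 10."""
    return scale.anchor_hi if scale.direction == HEALTHY_HIGH else scale.anchor_lo


def unhealthiest_intake(scale: ComponentScale) -> float:
    """The intake at which the component scores 0."""
    return scale.anchor_lo if scale.direction == HEALTHY_HIGH else scale.anchor_hi


def _intake_delta_for_points(points: float, scale: ComponentScale) -> float:
    """Signed intake change that raises the component score by ``points``."""
    step = points / 10.0 * (scale.anchor_hi - scale.anchor_lo)
    return step if scale.direction == HEALTHY_HIGH else -step


def dqs_increment_equivalents(
    delta: float,
    scales: Mapping[str, ComponentScale],
    components: Iterable[str] | None = None,
) -> list[FoodChange]:
    """Translate a DQS increment into concrete food-intake changes.

    For ``delta`` <= 10 a single-component change per candidate component is
    returned (each achieving the full ``delta`` on its own).  For larger
    increments a greedy multi-component bundle is returned whose score
    deltas sum to ``delta``: components are filled to their full 10-point
    range in the given order, with the remainder on the next component.
    """
    if not 0 < delta <= 100:
        raise ValueError(f"delta must be in (0, 100], got {delta}")
    order = list(components) if components is not None else list(DQS_COMPONENTS)
    _check_components(scales.keys())
    if delta <= 10:
        return [
            FoodChange(
                component=c,
                intake_delta=_intake_delta_for_points(delta, scales[c]),
                score_delta=float(delta),
                units=scales[c].units,
            )
            for c in order
        ]
    bundle: list[FoodChange] = []
    remaining = float(delta)
    for c in order:
        if remaining <= 0:
            break
        points = min(10.0, remaining)
        bundle.append(
            FoodChange(
                component=c,
                intake_delta=_intake_delta_for_points(points, scales[c]),
                score_delta=points,
                units=scales[c].units,
            )
        )
        remaining -= points
    return bundle


def apply_food_changes(
    response: Mapping[str, float], changes: Iterable[FoodChange]
) -> dict[str, float]:
    """Apply intake changes to an FFQ response (intakes floored at zero)."""
    out = dict(response)
    for ch in changes:
        out[ch.component] = max(0.0, out[ch.component] + ch.intake_delta)
    return out
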