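"""Screening reports: traffic-light classification of per-scale T-scores.

Children are flagged per scale as "red" (at risk), "orange" (monitoring
needed) or "green" (on track).  Default cut-offs put red below T=40 (about
the bottom 16% of the population metric) and orange below T=45; both are
configurable.  Intervals are half-open: a score exactly at a threshold
falls in the higher category.
"""

from __future__ import annotations

from dataclasses import dataclass

CATEGORIES = ("red", "orange", "green")
DEFAULT_RED_BELOW = 40.0
DEFAULT_ORANGE_BELOW = 45.0


@dataclass(frozen=True)
class TrafficLightReport:
    t_scores: dict[str, float]
    categories: dict[str, str]
    thresholds: tuple[float, float]
    child_id: str = ""
    age_group: str = ""

    def to_dict(self) -> dict:
        return {
            "child_id": self.child_id,
            "age_group": self.age_group,
            "thresholds": {
                "red_below": self.thresholds[0],
                "orange_below": self.thresholds[1],
            },
            "scales": {
                scale: {"t_score": self.t_scores[scale], "category": cat}
                for scale, cat in self.categories.items()
            },
        }


def classify_one(t: float, red_below: float, orange_below: float) -> str:
    if t < red_below:
        return "red"
    if t < orange_below:
        return "orange"
    return "green"


def classify_traffic_light(
    t_scores: dict[str, float],
    thresholds: tuple[float, float] = (DEFAULT_RED_BELOW, DEFAULT_ORANGE_BELOW),
    child_id: str = "",
    age_group: str = "",
) -> TrafficLightReport:
    """Classify per-scale T-scores into red/orange/green."""
    red_below, orange_below = thresholds
    if not red_below < orange_below:
        raise ValueError(
            f"thresholds must satisfy red_below < orange_below, "
            f"got {red_below} >= {orange_below}"
        )
    categories = {
        scale: classify_one(float(t), red_below, orange_below)
        for scale, t in t_scores.items()
    }
    return TrafficLightReport(
        t_scores={k: float(v) for k, v in t_scores.items()},
        categories=categories,
        thresholds=(red_below, orange_below),
        child_id=child_id,
        age_group=age_group,
    )
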