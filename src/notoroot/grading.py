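"""Commercial grading standard for *Panax notoginseng* taproots.

The market grades taproots by "head count" (roots per 500 g) and, per root, by
weight: larger roots command a higher grade. Grade I is the largest/best and
grade IV the smallest still sellable; anything lighter is below standard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .exceptions import BelowStandardError, SpecError

#: Grade labels, best (largest roots) first.
GRADES: tuple[str, ...] = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class GradingSpec:
    """Per-grade thresholds of the national grading standard.

    ``min_weight_g`` maps each grade to the minimum single-root weight in
    grams; ``max_heads`` maps each grade to the maximum number of roots per
    500 g. Defaults follow the Wenshan standard (GB/T 19086-2008):
    grade I >= 25.0 g (<= 20 heads), II >= 17.0 g (<= 30), III >= 12.5 g
    (<= 40), IV >= 8.5 g (<= 60).
    """

    min_weight_g: dict[str, float] = field(
        default_factory=lambda: {"I": 25.0, "II": 17.0, "III": 12.5, "IV": 8.5}
    )
    max_heads: dict[str, int] = field(
        default_factory=lambda: {"I": 20, "II": 30, "III": 40, "IV": 60}
    )

    def __post_init__(self) -> None:
        w = [self.min_weight_g[g] for g in GRADES]
        h = [self.max_heads[g] for g in GRADES]
        if not all(a > b for a, b in zip(w, w[1:])):
            raise SpecError("weight floors must strictly decrease from grade I to IV")
        if not all(a < b for a, b in zip(h, h[1:])):
            raise SpecError("head-count maxima must strictly increase from grade I to IV")

    def weight_interval(self, grade: str) -> tuple[float, float]:
        """[low, high) weight interval associated with ``grade``.

        The standard only gives floors; the interval for a grade runs from its
        floor up to the next better grade's floor, and grade I (unbounded
        above) up to 1.5x its floor.
        """
        idx = GRADES.index(grade)
        low = self.min_weight_g[grade]
        if idx == 0:
            return low, 1.5 * low
        return low, self.min_weight_g[GRADES[idx - 1]]


DEFAULT_GRADING = GradingSpec()


def assign_grade(weight_g: float, spec: GradingSpec = DEFAULT_GRADING) -> str:
    """Grade a single taproot by weight.

    Parameters
    ----------
    weight_g : positive weight of the root in grams.
    spec : grading thresholds; defaults to the national standard.

    Returns
    -------
    One of ``"I"``, ``"II"``, ``"III"``, ``"IV"``.

    Raises
    ------
    BelowStandardError if the weight falls under the grade-IV floor.
    """
    if not weight_g > 0:
        raise SpecError(f"weight must be positive, got {weight_g}")
    for grade in GRADES:
        if weight_g >= spec.min_weight_g[grade]:
            return grade
    raise BelowStandardError(
        f"{weight_g} g is below the grade-IV floor {spec.min_weight_g['IV']} g"
    )


def grade_to_code(grade: str) -> int:
    """Numeric coding of grades used by the RMSECV regression (I..IV -> 1..4)."""
    return GRADES.index(grade) + 1
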