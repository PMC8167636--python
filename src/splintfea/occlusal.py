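"""Occlusal-force calibration and per-tooth distribution.

The T-Scan pressure sensor records only *relative* occlusal force: a
dimensionless "raw sum" for the whole bite plus the percentage share carried
by each tooth.  A linear calibration converts the raw sum to an absolute
force in Newtons:

    F [N] = 0.021 * raw_sum + 8.022

The absolute force is then split over the mandibular teeth (FDI quadrants 3
and 4) according to the recorded percentage shares.  All arithmetic is kept
unrounded internally; one-decimal half-up rounding is applied only when a
report table is emitted, matching clinical reporting precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

__all__ = [
    "CALIBRATION_SLOPE",
    "CALIBRATION_INTERCEPT",
    "VALID_FDI",
    "LEFT_SIDE",
    "RIGHT_SIDE",
    "MOLARS",
    "OcclusalMeasurement",
    "ForceDistribution",
    "raw_to_newton",
    "distribute_force",
    "group_share",
    "measurement_ratio",
    "round_half_up",
]

#: Slope and intercept of the linear raw-sum -> Newton calibration.
CALIBRATION_SLOPE = 0.021
CALIBRATION_INTERCEPT = 8.022

#: Valid mandibular FDI codes: quadrant 3 (lower left) and 4 (lower right),
#: positions 1 (central incisor) .. 7 (second molar).
VALID_FDI = frozenset(range(31, 38)) | frozenset(range(41, 48))

LEFT_SIDE = frozenset(range(31, 38))
RIGHT_SIDE = frozenset(range(41, 48))
MOLARS = frozenset({36, 37, 46, 47})


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, as printed clinical tables do.

    Uses the shortest-repr decimal form of ``x`` so binary float artifacts
    (e.g. 257.35500000000002) do not perturb the tie direction.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OcclusalMeasurement:
    """One T-Scan acquisition: raw sum plus per-tooth percentage shares."""

    measurement_id: str
    raw_sum: int
    shares: Mapping[int, float]

    def __post_init__(self) -> None:
        if self.raw_sum < 0:
            raise ValueError(f"raw_sum must be non-negative, got {self.raw_sum}")
        if not self.shares:
            raise ValueError("shares must not be empty")
        bad = sorted(set(self.shares) - VALID_FDI)
        if bad:
            raise ValueError(f"invalid FDI tooth codes: {bad}")
        for tooth, s in self.shares.items():
            if not 0.0 <= s <= 100.0:
                raise ValueError(f"share for tooth {tooth} outside [0, 100]: {s}")
        total = sum(self.shares.values())
        if not 95.0 <= total <= 105.0:
            raise ValueError(
                f"shares sum to {total:.1f}%, outside the 95-105% rounding band"
            )

    @property
    def share_sum(self) -> float:
        return float(sum(self.shares.values()))


@dataclass(frozen=True)
class ForceDistribution:
    """Absolute per-tooth occlusal forces in Newtons."""

    total_force_N: float
    per_tooth_N: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_force_N <= 0.0:
            raise ValueError("total_force_N must be positive")

    def rounded(self, decimals: int = 1) -> "ForceDistribution":
        """Presentation-layer copy with forces rounded as printed in reports."""
        return ForceDistribution(
            total_force_N=round_half_up(self.total_force_N, decimals),
            per_tooth_N={
                t: round_half_up(f, decimals) for t, f in self.per_tooth_N.items()
            },
        )


def raw_to_newton(raw_sum: float) -> float:
    """Convert a dimensionless T-Scan raw sum to an absolute force in N.

    The returned value is unrounded; callers round to one decimal only for
    presentation.
    """
    if raw_sum < 0:
        raise ValueError(f"raw_sum must be non-negative, got {raw_sum}")
    return CALIBRATION_SLOPE * raw_sum + CALIBRATION_INTERCEPT


def distribute_force(
    total_force_N: float, measurement: OcclusalMeasurement
) -> ForceDistribution:
    """Split a total occlusal force over teeth by their percentage shares.

    Shares are used as recorded (no renormalisation even when the rounded
    percentages do not sum to exactly 100); per-tooth force = total * share/100.
    """
    if total_force_N <= 0.0:
        raise ValueError("total_force_N must be positive")
    per_tooth = {
        tooth: total_force_N * share / 100.0
        for tooth, share in measurement.shares.items()
    }
    return ForceDistribution(total_force_N=total_force_N, per_tooth_N=per_tooth)


def calibrate(measurement: OcclusalMeasurement) -> ForceDistribution:
    """Full calibration: raw sum -> Newtons -> per-tooth distribution."""
    return distribute_force(raw_to_newton(measurement.raw_sum), measurement)


def group_share(dist: ForceDistribution, teeth: Iterable[int]) -> float:
    """Percentage of the total force carried by a group of teeth."""
    teeth = set(teeth)
    missing = teeth - set(dist.per_tooth_N)
    if missing:
        raise KeyError(f"teeth not in distribution: {sorted(missing)}")
    return 100.0 * sum(dist.per_tooth_N[t] for t in teeth) / dist.total_force_N


def measurement_ratio(a: ForceDistribution, b: ForceDistribution) -> float:
    """Ratio of two measurements' total forces (a / b)."""
    if b.total_force_N == 0.0:
        raise ZeroDivisionError("denominator measurement has zero total force")
    return a.total_force_N / b.total_force_N
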