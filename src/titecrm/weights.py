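"""Follow-up weight functions for the TiTE-CRM.

A participant who has not (yet) had a DLT contributes to the weighted
likelihood with a weight that grows from 0 at treatment start to 1 at the
end of the DLT observation window ``T``.  A participant with a DLT always
contributes full weight, whatever their follow-up.

Two shapes are supported:

* ``linear`` — ``w = t / T``, appropriate when little is known about DLT
  timing or the hazard is roughly constant over the window;
* ``piecewise`` — piecewise-linear in ``t``, defined by ordered segments of
  ``(duration_days, mass)`` whose durations partition the window and whose
  masses sum to 1.  The scheme used in the olaparib chemoradiotherapy trial
  (a 1-year window whose first 3 months carry half the total weight, because
  haematological DLTs cluster early while pneumonitis occurs late) is the
  motivating example, available via :meth:`WeightSpec.olaparib`.

The module also implements the partial-treatment adjustment from that trial:
a DLT-free participant who received less than a threshold fraction (80% by
default) of the planned drug has follow-up counted only up to the last day
of full treatment, reducing their weight; a DLT still yields full weight so
the fitted curve never becomes overly optimistic.

All times are in days; calendar months must be declared in days by the
caller (e.g. the olaparib scheme as a 91-day acute segment in a 365-day
window).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "WeightSpec",
    "PartialTreatmentRule",
    "compute_weight",
    "effective_followup",
]

_KINDS = ("linear", "piecewise")


@dataclass(frozen=True)
class WeightSpec:
    """Shape of the follow-up weight function.

    ``segments`` is used only when ``kind == "piecewise"``: an ordered tuple
    of ``(duration_days, mass)`` pairs.  Durations must sum to the DLT
    window of the design the spec is used with (checked at evaluation time),
    masses to 1.
    """

    kind: str = "linear"
    segments: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind = {self.kind!r}; expected one of {_KINDS}")
        if self.kind == "piecewise":
            if not self.segments:
                raise ValueError("piecewise weight spec requires segments")
            segs = tuple((float(d), float(m)) for d, m in self.segments)
            for i, (d, m) in enumerate(segs):
                if d <= 0:
                    raise ValueError(f"segments[{i}] duration {d} must be positive")
                if m <= 0:
                    raise ValueError(f"segments[{i}] mass {m} must be positive")
            total = sum(m for _, m in segs)
            if abs(total - 1.0) > 1e-12:
                raise ValueError(
                    f"piecewise segment masses sum to {total}, expected 1"
                )
            object.__setattr__(self, "segments", segs)
        elif self.segments:
            raise ValueError("segments are only meaningful for kind='piecewise'")

    @classmethod
    def linear(cls) -> "WeightSpec":
        return cls(kind="linear")

    @classmethod
    def piecewise(cls, segments) -> "WeightSpec":
        return cls(kind="piecewise", segments=tuple(tuple(s) for s in segments))

    @classmethod
    def olaparib(
        cls,
        acute_days: float = 91.0,
        total_days: float = 365.0,
        acute_mass: float = 0.5,
    ) -> "WeightSpec":
        """Two-segment scheme: an acute period carrying ``acute_mass`` of the
        weight, the remainder spread over the rest of the window."""
        if not 0 < acute_days < total_days:
            raise ValueError("acute period must be shorter than the window")
        if not 0 < acute_mass < 1:
            raise ValueError("acute_mass must lie in (0, 1)")
        return cls.piecewise(
            [(acute_days, acute_mass), (total_days - acute_days, 1.0 - acute_mass)]
        )

    def window(self) -> float | None:
        """Total duration implied by the segments (piecewise only)."""
        if self.kind != "piecewise":
            return None
        return sum(d for d, _ in self.segments)


@dataclass(frozen=True)
class PartialTreatmentRule:
    """Evaluability weighting for participants who received less than
    ``threshold`` of the planned drug (disabled by default)."""

    enabled: bool = False
    threshold: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError(f"threshold = {self.threshold} must lie in (0, 1]")


def compute_weight(t: float, T: float, y: int, spec: WeightSpec | None = None) -> float:
    """Likelihood weight for follow-up ``t`` (days) in a window of length
    ``T``.

    A DLT (``y = 1``) always yields weight 1.  Otherwise the weight follows
    the spec's shape; follow-up beyond ``T`` is truncated (fully observed).
    """
    if spec is None:
        spec = WeightSpec.linear()
    if T <= 0:
        raise ValueError(f"DLT window T = {T} must be positive")
    if t < 0:
        raise ValueError(f"negative follow-up t = {t}")
    if y not in (0, 1):
        raise ValueError(f"y must be 0 or 1, got {y}")
    if y == 1:
        return 1.0
    if t >= T:
        return 1.0
    if spec.kind == "linear":
        return t / T
    seg_total = spec.window()
    if abs(seg_total - T) > 1e-9 * max(T, 1.0):
        raise ValueError(
            f"piecewise segment durations sum to {seg_total} days but the "
            f"DLT window is {T} days"
        )
    w = 0.0
    elapsed = 0.0
    for duration, mass in spec.segments:
        if t >= elapsed + duration:
            w += mass
            elapsed += duration
        else:
            w += mass * (t - elapsed) / duration
            break
    return min(w, 1.0)


def effective_followup(
    t: float,
    last_full_treatment_day: float,
    fraction_received: float,
    y: int,
    rule: PartialTreatmentRule,
) -> float:
    """Follow-up credited to a participant after the partial-treatment rule.

    If the rule is disabled, the planned-dose fraction meets the threshold,
    or the participant had a DLT (full weight downstream regardless), the
    observed follow-up is returned unchanged.  Otherwise follow-up counts
    only until the last day full treatment was received.
    """
    if not 0.0 <= fraction_received <= 1.0:
        raise ValueError(
            f"fraction_received = {fraction_received} outside [0, 1]"
        )
    if not 0.0 <= last_full_treatment_day <= t:
        raise ValueError(
            f"last_full_treatment_day = {last_full_treatment_day} outside "
            f"[0, t = {t}]"
        )
    if not rule.enabled or y == 1 or fraction_received >= rule.threshold:
        return t
    return last_full_treatment_day
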