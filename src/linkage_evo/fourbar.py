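"""Planar four-bar linkage geometry and kinematic transmission (KT).

A four-bar linkage is a closed chain of four rigid links: a fixed link
(frame) and three mobile links (input, output, coupler).  Rotating the
input link about its ground pivot forces the output link to rotate about
the other ground pivot.  Kinematic transmission is the ratio of output
angular motion to input angular motion, ``KT = |dtheta_out / dtheta_in|``:
high KT amplifies displacement, low KT amplifies force.

Geometry and conventions
------------------------
The frame runs from the input ground pivot ``A`` to the output ground
pivot ``D``.  The input angle ``theta_in`` is the interior angle between
the input link and the frame at ``A``; the output angle is measured from
the frame direction at ``D`` (180 deg minus the interior angle), so a
parallelogram satisfies ``theta_out == theta_in``.  Closure is solved with the law-of-cosines diagonal
decomposition: the diagonal ``d`` from the input-link tip to ``D``
satisfies

    d^2 = input^2 + fixed^2 - 2 * input * fixed * cos(theta_in)

and the chain closes iff ``|coupler - output| <= d <= coupler + output``.
Only the "open" (non-crossed) assembly branch is used, matching the
biological systems this package models (fish jaws, mantis-shrimp
raptorial appendages), which all operate as open chains.

KT is evaluated by central finite differences at a configurable step
(default 0.1 deg), with one-sided fallback at assembly-range boundaries.
Because KT is a ratio of angles, it is invariant to uniform scaling of
all four links.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import NonClosableLinkage, NonPositiveLength, RangeOutsideAssembly

__all__ = [
    "FourBarLinkage",
    "KTProfile",
    "assembly_range",
    "output_angle",
    "instantaneous_kt",
    "kt_profile",
    "min_kt_full_rotation",
    "static_kt",
    "size_correct",
]

@dataclass(frozen=True)
class FourBarLinkage:
    """Link lengths of one planar four-bar mechanism (consistent units)."""

    fixed_len: float
    input_len: float
    output_len: float
    coupler_len: float

    def __post_init__(self) -> None:
        for name in ("fixed_len", "input_len", "output_len", "coupler_len"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise NonPositiveLength(f"{name} must be positive and finite, got {v!r}")

    def scaled(self, factor: float) -> "FourBarLinkage":
        """Return the same linkage with every link multiplied by *factor*."""
        return FourBarLinkage(
            self.fixed_len * factor,
            self.input_len * factor,
            self.output_len * factor,
            self.coupler_len * factor,
        )

    def swapped_io(self) -> "FourBarLinkage":
        """Return the linkage with the roles of input and output exchanged."""
        return FourBarLinkage(self.fixed_len, self.output_len, self.input_len, self.coupler_len)


@dataclass(frozen=True)
class KTProfile:
    """Instantaneous KT sampled over a contiguous input-rotation range."""

    input_angles: np.ndarray
    kt_values: np.ndarray
    step: float
    min_kt: float = field(init=False)
    mean_kt: float = field(init=False)

    def __post_init__(self) -> None:
        angles = np.asarray(self.input_angles, dtype=float)
        kts = np.asarray(self.kt_values, dtype=float)
        if angles.size == 0 or angles.size != kts.size:
            raise ValueError("profile requires matching, non-empty angle and KT arrays")
        if angles.size > 1:
            diffs = np.diff(angles)
            if np.any(diffs <= 0) or not np.allclose(diffs, diffs[0], rtol=1e-6):
                raise ValueError("input_angles must increase with a constant step")
        if not np.all(np.isfinite(kts)) or np.any(kts < 0):
            raise ValueError("kt_values must be finite and non-negative")
        object.__setattr__(self, "input_angles", angles)
        object.__setattr__(self, "kt_values", kts)
        object.__setattr__(self, "min_kt", float(kts.min()))
        object.__setattr__(self, "mean_kt", float(kts.mean()))


def _diagonal(linkage: FourBarLinkage, theta_in_rad: float) -> float:
    """Distance from the input-link tip to the output ground pivot."""
    a, f = linkage.input_len, linkage.fixed_len
    d2 = a * a + f * f - 2.0 * a * f * math.cos(theta_in_rad)
    return math.sqrt(max(d2, 0.0))


def assembly_range(linkage: FourBarLinkage) -> tuple[float, float]:
    """Input-angle interval (degrees) over which the chain closes.

    The diagonal grows monotonically with the input angle, so the feasible
    set is a single closed interval ``[lo, hi]`` within [0, 180].  Raises
    :class:`NonClosableLinkage` when no input angle admits closure.
    """
    a, f = linkage.input_len, linkage.fixed_len
    c, o = linkage.coupler_len, linkage.output_len
    d_min, d_max = abs(f - a), f + a
    d_lo, d_hi = abs(c - o), c + o

    if d_min > d_hi or d_max < d_lo:
        raise NonClosableLinkage(
            f"diagonal range [{d_min:g}, {d_max:g}] never meets "
            f"closure range [{d_lo:g}, {d_hi:g}]"
        )

    def theta_at(d: float) -> float:
        cos_t = (a * a + f * f - d * d) / (2.0 * a * f)
        return math.degrees(math.acos(min(1.0, max(-1.0, cos_t))))

    lo = 0.0 if d_min >= d_lo else theta_at(d_lo)
    hi = 180.0 if d_max <= d_hi else theta_at(d_hi)
    if lo > hi:
        raise NonClosableLinkage("empty assembly range")
    return lo, hi


def output_angle(linkage: FourBarLinkage, theta_in: float) -> float:
    """Output-link angle (degrees) in the open configuration at *theta_in*.

    Solves closure via the diagonal: the angle at the output pivot is the
    sum of the frame-diagonal angle (triangle input/fixed/diagonal) and
    the diagonal-output angle (triangle diagonal/output/coupler).
    """
    lo, hi = assembly_range(linkage)
    if not (lo - 1e-12 <= theta_in <= hi + 1e-12):
        raise NonClosableLinkage(
            f"input angle {theta_in:g} outside assembly range [{lo:g}, {hi:g}]"
        )
    t = math.radians(theta_in)
    a, f = linkage.input_len, linkage.fixed_len
    c, o = linkage.coupler_len, linkage.output_len
    d = _diagonal(linkage, t)
    if d <= 1e-300:
        raise NonClosableLinkage("degenerate configuration: zero-length diagonal")

    def safe_acos(x: float) -> float:
        return math.acos(min(1.0, max(-1.0, x)))

    beta = safe_acos((d * d + f * f - a * a) / (2.0 * d * f))
    gamma = safe_acos((d * d + o * o - c * c) / (2.0 * d * o))
    # beta + gamma is the interior angle at the output pivot; report the
    # angle from the frame direction instead so that a parallelogram
    # satisfies theta_out == theta_in.
    return 180.0 - math.degrees(beta + gamma)


def instantaneous_kt(linkage: FourBarLinkage, theta_in: float, step: float = 0.1) -> float:
    """|dtheta_out/dtheta_in| at *theta_in* by finite differences.

    Uses a central difference of width *step* (degrees); falls back to a
    one-sided difference when ``theta_in +/- step`` leaves the assembly
    range.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    lo, hi = assembly_range(linkage)
    fwd_ok = theta_in + step <= hi
    bwd_ok = theta_in - step >= lo
    if fwd_ok and bwd_ok:
        num = output_angle(linkage, theta_in + step) - output_angle(linkage, theta_in - step)
        return abs(num) / (2.0 * step)
    if fwd_ok:
        return abs(output_angle(linkage, theta_in + step) - output_angle(linkage, theta_in)) / step
    if bwd_ok:
        return abs(output_angle(linkage, theta_in) - output_angle(linkage, theta_in - step)) / step
    raise NonClosableLinkage(
        f"cannot form a finite difference of width {step:g} around {theta_in:g} "
        f"inside assembly range [{lo:g}, {hi:g}]"
    )


def kt_profile(
    linkage: FourBarLinkage,
    theta_start: float,
    rotation: float,
    step: float = 0.1,
) -> KTProfile:
    """Instantaneous KT sampled every *step* degrees over an input rotation.

    The interval ``[theta_start, theta_start + rotation]`` must lie inside
    the assembly range.  ``min_kt`` and ``mean_kt`` on the returned profile
    are the dynamic (minimum) and averaged KT statistics.
    """
    if rotation <= 0:
        raise ValueError("rotation must be positive (empty profile disallowed)")
    if step <= 0:
        raise ValueError("step must be positive")
    lo, hi = assembly_range(linkage)
    theta_end = theta_start + rotation
    if theta_start < lo - 1e-12 or theta_end > hi + 1e-12:
        raise RangeOutsideAssembly(
            f"[{theta_start:g}, {theta_end:g}] not contained in "
            f"assembly range [{lo:g}, {hi:g}]"
        )
    n = int(math.floor(rotation / step + 1e-9)) + 1
    angles = theta_start + step * np.arange(n)
    kts = np.array([instantaneous_kt(linkage, t, step) for t in angles])
    return KTProfile(angles, kts, step)


def min_kt_full_rotation(linkage: FourBarLinkage, step: float = 0.1) -> float:
    """Minimum instantaneous KT over the whole assembly range.

    One step is trimmed off each endpoint because the output-angle
    derivative diverges at collinear (coupler/output in line) boundary
    configurations.
    """
    lo, hi = assembly_range(linkage)
    lo_t, hi_t = lo + step, hi - step
    if hi_t <= lo_t:
        raise NonClosableLinkage("assembly range narrower than two finite-difference steps")
    profile = kt_profile(linkage, lo_t, hi_t - lo_t, step)
    return profile.min_kt


def static_kt(linkage: FourBarLinkage, start_angle: float = 30.0, step: float = 0.1) -> float:
    """Instantaneous KT with the input link held at *start_angle* degrees.

    This is the static protocol used for oral four-bar jaw linkages, where
    30 deg of lower-jaw rotation is the biologically relevant posture.
    """
    return instantaneous_kt(linkage, start_angle, step)


def size_correct(
    input_len: float, output_len: float, coupler_len: float, fixed_len: float
) -> tuple[float, float, float]:
    """Dimensionless link lengths: each mobile link over the fixed link."""
    for name, v in (
        ("input_len", input_len),
        ("output_len", output_len),
        ("coupler_len", coupler_len),
        ("fixed_len", fixed_len),
    ):
        if not (math.isfinite(v) and v > 0):
            raise NonPositiveLength(f"{name} must be positive and finite, got {v!r}")
    return input_len / fixed_len, output_len / fixed_len, coupler_len / fixed_len


def kt_for_protocol(
    linkage: FourBarLinkage,
    mode: str = "static",
    start_angle: float = 30.0,
    rotation: float = 9.0,
    step: float = 0.1,
) -> float:
    """Compute one KT summary under a named measurement protocol.

    ``static``   instantaneous KT at *start_angle* (oral four-bars);
    ``min``      minimum KT over the full assembly range (raptorial and
                 opercular four-bars);
    ``min-range`` minimum KT over ``[start_angle, start_angle + rotation]``;
    ``mean``     averaged KT over the same window.
    """
    if mode == "static":
        return static_kt(linkage, start_angle, step)
    if mode == "min":
        return min_kt_full_rotation(linkage, step)
    if mode in ("min-range", "mean"):
        profile = kt_profile(linkage, start_angle, rotation, step)
        return profile.min_kt if mode == "min-range" else profile.mean_kt
    raise ValueError(f"unknown KT protocol {mode!r}")
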