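"""Bit-accurate emulation of the hardware fixed-point arithmetic.

The hardware holds every state variable in an 18-bit two's-complement
fixed-point word with 10 fractional bits: resolution 2^-10, representable
range [-128, 128 - 2^-10].  Constant multiplications are realised as sums
of right-shifted copies of the operand (e.g. the coefficient 0.021484375 is
2^-6 + 2^-8 + 2^-9, i.e. the sum of the sixth, eighth and ninth right
shifts).

The emulation computes each pipeline-stage result in float64 and quantizes
it once at the register boundary — round-half-even by default, with a
truncation option mimicking plain right-shifts — saturating at the format
limits.  Exact rounding of the authors' accumulators is not published, so
the emulator documents its own convention rather than claiming bit-identity
with the FPGA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FixedPointFormat", "ShiftAddPlan", "Quantizer", "quantize", "plan_shift_add"]


@dataclass(frozen=True)
class FixedPointFormat:
    """Signed fixed-point word layout."""

    total_bits: int = 18
    frac_bits: int = 10

    @property
    def resolution(self) -> float:
        return 2.0 ** (-self.frac_bits)

    @property
    def max_value(self) -> float:
        return 2.0 ** (self.total_bits - self.frac_bits - 1) - self.resolution

    @property
    def min_value(self) -> float:
        return -(2.0 ** (self.total_bits - self.frac_bits - 1))


def quantize(x, fmt: FixedPointFormat = FixedPointFormat(), mode: str = "round"):
    """Snap to the nearest representable value, saturating at the range limits.

    ``mode='round'`` uses round-half-even (the IEEE default); ``mode='trunc'``
    truncates toward negative infinity, which is what a plain arithmetic
    right-shift does.  Idempotent and monotone.
    """
    x = np.asarray(x, dtype=float)
    scaled = x * 2.0**fmt.frac_bits
    if mode == "round":
        q = np.round(scaled)
    elif mode == "trunc":
        q = np.floor(scaled)
    else:
        raise ValueError(f"unknown rounding mode {mode!r}")
    out = np.clip(q * fmt.resolution, fmt.min_value, fmt.max_value)
    return out if out.ndim else float(out)


@dataclass
class ShiftAddPlan:
    """Signed right-shift decomposition of a representable coefficient."""

    shifts: list[tuple[int, int]]  # (sign, shift amount); value = sum sign * 2^-shift
    coefficient: float

    def apply(self, x):
        """Shift-add multiplication: sum of signed right-shifted copies."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for sign, k in self.shifts:
            out = out + sign * (x * 2.0**-k)
        return out if out.ndim else float(out)


def plan_shift_add(coef: float, fmt: FixedPointFormat = FixedPointFormat()) -> ShiftAddPlan:
    """Decompose a representable coefficient into signed right shifts.

    Uses the canonical signed-digit form of the quantized magnitude; the
    reconstructed sum equals the quantized coefficient exactly.  Raises for
    coefficients that are not representable in the format, naming the
    nearest representable value.
    """
    q = quantize(coef, fmt)
    if q != coef:
        raise ValueError(
            f"coefficient {coef} not representable in "
            f"Q{fmt.total_bits - fmt.frac_bits}.{fmt.frac_bits}; nearest is {q}"
        )
    shifts: list[tuple[int, int]] = []
    remainder = coef
    sign_total = 1 if remainder >= 0 else -1
    mag = abs(remainder)
    # binary expansion of the magnitude over representable powers
    int_bits = fmt.total_bits - fmt.frac_bits - 1
    for k in range(-int_bits, fmt.frac_bits + 1):
        w = 2.0**-k
        if mag >= w:
            shifts.append((sign_total, k))
            mag -= w
    assert mag == 0.0
    return ShiftAddPlan(shifts=shifts, coefficient=coef)


class Quantizer:
    """Callable stage quantizer used by the simulation engine."""

    def __init__(self, fmt: FixedPointFormat = FixedPointFormat(), mode: str = "round"):
        self.fmt = fmt
        self.mode = mode
        self.saturation_events = 0

    def quantize(self, x):
        x_arr = np.asarray(x, dtype=float)
        out = quantize(x_arr, self.fmt, self.mode)
        self.saturation_events += int(
            np.count_nonzero((x_arr > self.fmt.max_value) | (x_arr < self.fmt.min_value))
        )
        return out

    __call__ = quantize
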