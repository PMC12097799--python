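"""Continuous-to-binary position mapping for wrapper feature selection.

Swarm updates operate in ``[0, 1]^D``; a feature subset is a bit vector
over the ``D`` features.  Three mapping families are supported:

* ``threshold`` — bit ``j`` is 1 iff ``x_j > 0.5`` (the default pipeline);
* ``s1``..``s4`` — S-shaped (sigmoid) transfer functions: the transfer
  value is the probability that the bit is *set*;
* ``v1``..``v4`` — V-shaped transfer functions: the transfer value is the
  probability that the current bit is *flipped*, so the V family keeps a
  persistent mask per agent across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf, expit

__all__ = [
    "TransferSpec",
    "threshold_binarize",
    "s_transfer",
    "v_transfer",
    "apply_transfer",
    "TRANSFER_NAMES",
]

TRANSFER_NAMES = ("threshold", "s1", "s2", "s3", "s4", "v1", "v2", "v3", "v4")


@dataclass(frozen=True)
class TransferSpec:
    """Which binarization rule to use.

    family is one of ``{"threshold", "S", "V"}``; ``variant`` selects one
    of the four functions within the S/V families and is ignored for the
    threshold rule.
    """

    family: str
    variant: int = 1

    def __post_init__(self) -> None:
        if self.family not in ("threshold", "S", "V"):
            raise ValueError(f"unknown transfer family {self.family!r}")
        if self.family != "threshold" and self.variant not in (1, 2, 3, 4):
            raise ValueError(f"transfer variant must be 1-4, got {self.variant}")

    @classmethod
    def from_name(cls, name: str) -> "TransferSpec":
        """Parse ``"threshold"``, ``"s1"``..``"s4"``, ``"v1"``..``"v4"``."""
        key = name.strip().lower()
        if key == "threshold":
            return cls("threshold")
        if len(key) == 2 and key[0] in "sv" and key[1] in "1234":
            return cls(key[0].upper(), int(key[1]))
        raise ValueError(f"unknown transfer name {name!r}; expected one of {TRANSFER_NAMES}")

    @property
    def name(self) -> str:
        if self.family == "threshold":
            return "threshold"
        return f"{self.family.lower()}{self.variant}"


def threshold_binarize(x: np.ndarray) -> np.ndarray:
    """Bit ``j = 1`` iff ``x_j > 0.5``; the boundary value 0.5 maps to 0."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("threshold_binarize requires finite entries")
    return (x > 0.5).astype(np.int8)


def s_transfer(x, variant: int):
    """S-shaped transfer value in (0, 1).

    ``S1(x) = 1/(1+e^-x)``, ``S2(x) = 1/(1+e^x)``,
    ``S3(x) = 1/(1+e^(-x/2))``, ``S4(x) = 1/(1+e^(-x/3))``.
    """
    x = np.asarray(x, dtype=float)
    if variant == 1:
        return expit(x)
    if variant == 2:
        return expit(-x)
    if variant == 3:
        return expit(x / 2.0)
    if variant == 4:
        return expit(x / 3.0)
    raise ValueError(f"unknown S variant {variant}")


def v_transfer(x, variant: int):
    """V-shaped transfer value in [0, 1): symmetric, zero at the origin.

    ``V1(x) = |tanh x|``, ``V2(x) = |erf(sqrt(pi)/2 x)|``,
    ``V3(x) = |x / sqrt(1+x^2)|``, ``V4(x) = |2/pi arctan(pi/2 x)|``.
    """
    x = np.asarray(x, dtype=float)
    if variant == 1:
        return np.abs(np.tanh(x))
    if variant == 2:
        return np.abs(erf(np.sqrt(np.pi) / 2.0 * x))
    if variant == 3:
        return np.abs(x / np.sqrt(1.0 + x * x))
    if variant == 4:
        return np.abs(2.0 / np.pi * np.arctan(np.pi / 2.0 * x))
    raise ValueError(f"unknown V variant {variant}")


def apply_transfer(
    x: np.ndarray,
    current_bits: np.ndarray | None,
    spec: TransferSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Map a continuous position to a bit mask under ``spec``.

    S family sets each bit with probability ``TF(x_j)``; V family flips
    the corresponding current bit with probability ``TF(x_j)`` and
    therefore requires ``current_bits``.  The threshold rule is
    deterministic and ignores both ``current_bits`` and ``rng``.
    """
    x = np.asarray(x, dtype=float)
    if spec.family == "threshold":
        return threshold_binarize(x)
    if spec.family == "S":
        tf = s_transfer(x, spec.variant)
        return (rng.random(x.shape) < tf).astype(np.int8)
    if current_bits is None:
        raise ValueError("V-family transfer needs the agent's current bit mask")
    current_bits = np.asarray(current_bits, dtype=np.int8)
    tf = v_transfer(x, spec.variant)
    flip = rng.random(x.shape) < tf
    return np.where(flip, 1 - current_bits, current_bits).astype(np.int8)
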