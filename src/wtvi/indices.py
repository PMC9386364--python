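"""The 12 vegetation indices, as per-pixel raster ops and scalar algebra.

Every index is expressed as a ratio ``numerator / denominator`` of band
algebra over the four working wavelengths {550, 670, 720, 800} nm.
Pixels whose denominator magnitude falls below ``DENOM_EPS`` are flagged
invalid instead of producing infinities, and masked input pixels stay
invalid; plot statistics use valid pixels only.

Two formula variants exist for OSAVI and RVI: the default ``"paper"``
variant follows the printed red-edge (720 nm) forms; ``"classical"``
substitutes the conventional red-band (670 nm) forms. The ambiguity is
deliberate and surfaced here rather than silently resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .errors import DegenerateDataError, InputError
from .raster_io import ReflectanceCube

__all__ = [
    "VIDefinition",
    "VIImage",
    "compute_vi",
    "compute_vi_scalar",
    "list_indices",
    "get_index",
    "INDEX_NAMES",
    "DENOM_EPS",
]

DENOM_EPS = 1e-12

#: Default weighting constant of the wide-dynamic-range index.
WDRVI_ALPHA = 0.2

Bands = Mapping[int, np.ndarray]
Formula = Callable[[Bands, Mapping[str, float]], tuple[np.ndarray, np.ndarray]]


@dataclass(frozen=True)
class VIDefinition:
    """A named index: required wavelengths plus its numerator/denominator."""

    name: str
    required_wavelengths: frozenset[int]
    formula: Formula
    parameters: Mapping[str, float] = field(default_factory=dict)
    normalized: bool = False  # normalized-difference family, range [-1, 1]


def _num_den(fn):
    """Coerce formula outputs to float arrays."""

    def wrapped(b: Bands, p: Mapping[str, float]):
        num, den = fn(b, p)
        return np.asarray(num, dtype=np.float64), np.asarray(den, dtype=np.float64)

    return wrapped


def _registry(variant: str) -> dict[str, VIDefinition]:
    if variant not in ("paper", "classical"):
        raise InputError(f"unknown formula variant {variant!r}")
    osavi_band = 720 if variant == "paper" else 670
    rvi_band = 720 if variant == "paper" else 670

    defs = [
        VIDefinition(
            "CI_red_edge",
            frozenset({800, 720}),
            _num_den(lambda b, p: (b[800] - b[720], b[720])),
        ),
        VIDefinition(
            "CI_green",
            frozenset({800, 550}),
            _num_den(lambda b, p: (b[800] - b[550], b[550])),
        ),
        VIDefinition(
            "NDVI",
            frozenset({800, 670}),
            _num_den(lambda b, p: (b[800] - b[670], b[800] + b[670])),
            normalized=True,
        ),
        VIDefinition(
            "GNDVI",
            frozenset({800, 550}),
            _num_den(lambda b, p: (b[800] - b[550], b[800] + b[550])),
            normalized=True,
        ),
        VIDefinition(
            "NDRE",
            frozenset({800, 720}),
            _num_den(lambda b, p: (b[800] - b[720], b[800] + b[720])),
            normalized=True,
        ),
        VIDefinition(
            "MTCI",
            frozenset({800, 720, 670}),
            _num_den(lambda b, p: (b[800] - b[720], b[720] - b[670])),
        ),
        VIDefinition(
            "WDRVI",
            frozenset({800, 670}),
            _num_den(
                lambda b, p: (
                    p["alpha"] * b[800] - b[670],
                    p["alpha"] * b[800] + b[670],
                )
            ),
            parameters={"alpha": WDRVI_ALPHA},
            normalized=True,
        ),
        VIDefinition(
            "EVI2",
            frozenset({800, 670}),
            _num_den(
                lambda b, p: (2.5 * (b[800] - b[670]), 1.0 + b[800] + 2.4 * b[670])
            ),
        ),
        VIDefinition(
            "VARI",
            frozenset({550, 670}),
            _num_den(lambda b, p: (b[550] - b[670], b[550] + b[670])),
            normalized=True,
        ),
        VIDefinition(
            "OSAVI",
            frozenset({800, osavi_band}),
            _num_den(
                lambda b, p, _w=osavi_band: (
                    1.16 * (b[800] - b[_w]),
                    b[800] + b[_w] + 0.16,
                )
            ),
        ),
        VIDefinition(
            "SR",
            frozenset({800, 550}),
            _num_den(lambda b, p: (b[800], b[550])),
        ),
        VIDefinition(
            "RVI",
            frozenset({800, rvi_band}),
            _num_den(lambda b, p, _w=rvi_band: (b[800], b[_w])),
        ),
    ]
    return {d.name: d for d in defs}


INDEX_NAMES = tuple(_registry("paper").keys())


def list_indices(variant: str = "paper") -> list[VIDefinition]:
    """All 12 registered index definitions."""
    return list(_registry(variant).values())


def get_index(name: str, variant: str = "paper") -> VIDefinition:
    reg = _registry(variant)
    if name not in reg:
        raise InputError(f"unknown index {name!r}; known: {sorted(reg)}")
    return reg[name]


@dataclass
class VIImage:
    """Per-pixel index values plus validity flags."""

    values: np.ndarray
    name: str
    valid_mask: np.ndarray

    def mean(self) -> float:
        """Mean over valid pixels; errors if none are valid."""
        if not self.valid_mask.any():
            raise DegenerateDataError(f"no valid pixels in {self.name} image")
        return float(self.values[self.valid_mask].mean())


def compute_vi(cube: ReflectanceCube, definition: VIDefinition) -> VIImage:
    """Evaluate one index over a reflectance cube.

    Invalid pixels (masked input or |denominator| < ``DENOM_EPS``) carry
    value 0.0 and ``valid_mask`` False.
    """
    bands = {wl: cube.band(wl) for wl in definition.required_wavelengths}
    num, den = definition.formula(bands, definition.parameters)
    valid = (np.abs(den) >= DENOM_EPS) & ~cube.nodata_mask
    values = np.zeros_like(num, dtype=np.float64)
    np.divide(num, den, out=values, where=valid)
    return VIImage(values=values, name=definition.name, valid_mask=valid)


def compute_vi_scalar(
    reflectances: Mapping[int, float], definition: VIDefinition
) -> float:
    """Scalar form of the same formula; NaN when the denominator vanishes."""
    bands = {wl: np.asarray(float(v)) for wl, v in reflectances.items()}
    num, den = definition.formula(bands, definition.parameters)
    if abs(float(den)) < DENOM_EPS:
        return float("nan")
    return float(num) / float(den)
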