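"""Tristimulus integration, chromaticity, and color-space transformations.

Because color matches are set at the level of the cone quantum catches, any
set of color matching functions (CMFs) is a linear transformation of the
cone fundamentals. This module provides the exact published matrices between
the LMS fundamentals, the Stiles-Burch 10-deg RGB CMFs (444/526/645 nm
primaries) and the XYZ CMFs (2-deg and 10-deg), plus tristimulus integration
against arbitrary power spectra and chromaticity projection.

In the XYZ transforms the y-bar row is a non-negative combination of l-bar
and m-bar (its S coefficient is zero) and the z-bar row is a pure scaling of
s-bar; in the RGB->LMS matrix the S-cone response to the red primary is
exactly zero and the blue-primary column is normalised to (1, 1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fundamentals import ConeFundamentalSet
from .templates import SpectralFunction, _matrix_record

__all__ = [
    "TransformMatrix",
    "Tristimulus",
    "builtin_matrix",
    "tristimulus",
    "chromaticity",
    "rgb_to_lms_10deg",
    "lms_to_rgb_10deg",
    "lms_to_xyz",
    "xyz_from_lms_matrix",
    "transform_cmfs",
    "matrix_from_primaries",
    "spectrum_locus",
]


@dataclass(frozen=True)
class TransformMatrix:
    """A labeled, invertible 3x3 linear map between color spaces."""

    from_space: str
    to_space: str
    m: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.m, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("matrix must be 3x3")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("matrix must be invertible")
        object.__setattr__(self, "m", m)

    def apply(self, t):
        return self.m @ np.asarray(t, dtype=float)

    def inverse(self) -> "TransformMatrix":
        return TransformMatrix(self.to_space, self.from_space, np.linalg.inv(self.m))


@dataclass(frozen=True)
class Tristimulus:
    """A tristimulus triple with its color-space label."""

    values: tuple
    space: str = "LMS"

    def __post_init__(self) -> None:
        v = tuple(float(x) for x in self.values)
        if len(v) != 3 or not all(np.isfinite(v)):
            raise ValueError("tristimulus needs three finite components")
        object.__setattr__(self, "values", v)


def builtin_matrix(name: str) -> TransformMatrix:
    """Published matrix by name: 'rgb10_to_lms10', 'lms2_to_xyz', 'lms10_to_xyz'."""
    rec = _matrix_record(name)
    return TransformMatrix(rec["from_space"], rec["to_space"], np.array(rec["m"]))


def tristimulus(power: SpectralFunction, cmfs) -> np.ndarray:
    """Tristimulus values of a light: rectangle-rule integrals of P(l)*cmf(l).

    ``cmfs`` is a :class:`ConeFundamentalSet` (or any object with ``L``, ``M``,
    ``S`` SpectralFunctions and a ``units`` tag). Energy-unit power spectra
    require energy-unit CMFs.
    """
    if power.units != "power":
        raise ValueError("power spectrum must carry the 'power' units tag")
    if getattr(cmfs, "units", "energy") != "energy":
        raise ValueError("tristimulus integration expects energy-unit CMFs")
    out = []
    for chan in (cmfs.L, cmfs.M, cmfs.S):
        if (chan.lambda_start != power.lambda_start
                or chan.lambda_step != power.lambda_step
                or chan.values.size != power.values.size):
            raise ValueError("power and CMF grids are not aligned")
        out.append(float(np.sum(power.values * chan.values) * power.lambda_step))
    return np.array(out)


def chromaticity(t) -> tuple:
    """Project a tristimulus triple to its first two chromaticity coordinates.

    (l, m) = (L, M) / (L + M + S); the third coordinate is 1 - l - m.
    Invariant under positive scaling of the triple.
    """
    v = np.asarray(t.values if isinstance(t, Tristimulus) else t, dtype=float)
    total = float(v.sum())
    if total == 0.0:
        raise ZeroDivisionError("chromaticity undefined for a zero-sum triple")
    return (float(v[0] / total), float(v[1] / total))


def rgb_to_lms_10deg(t) -> np.ndarray:
    """Stiles-Burch 10-deg RGB tristimuli -> LMS."""
    return builtin_matrix("rgb10_to_lms10").apply(_vals(t))


def lms_to_rgb_10deg(t) -> np.ndarray:
    """LMS tristimuli -> Stiles-Burch 10-deg RGB (numerical inverse)."""
    return builtin_matrix("rgb10_to_lms10").inverse().apply(_vals(t))


def xyz_from_lms_matrix(fov: str) -> TransformMatrix:
    if fov in ("deg2", "2", 2):
        return builtin_matrix("lms2_to_xyz")
    if fov in ("deg10", "10", 10):
        return builtin_matrix("lms10_to_xyz")
    raise ValueError("field must be 'deg2' or 'deg10'")


def lms_to_xyz(t, fov: str = "deg2") -> np.ndarray:
    """LMS tristimuli (energy units) -> XYZ with the field-appropriate matrix."""
    return xyz_from_lms_matrix(fov).apply(_vals(t))


def _vals(t) -> np.ndarray:
    return np.asarray(t.values if isinstance(t, Tristimulus) else t, dtype=float)


def transform_cmfs(cmfs: ConeFundamentalSet, matrix: TransformMatrix) -> dict:
    """Apply a space transform wavelength-by-wavelength to a CMF set.

    Returns a dict of three SpectralFunctions keyed by output channel index
    order; the transformed CMFs are NOT renormalised (the published matrices
    embed their own scaling conventions). Transformed values may be negative
    (real-primary CMFs necessarily are), so plain arrays are returned.
    """
    stack = np.vstack([cmfs.L.values, cmfs.M.values, cmfs.S.values])
    out = matrix.m @ stack
    return {"channels": out, "lambda_start": cmfs.L.lambda_start,
            "lambda_step": cmfs.L.lambda_step, "space": matrix.to_space}


def matrix_from_primaries(cmfs: ConeFundamentalSet, primaries,
                          to_space: str = "RGB") -> TransformMatrix:
    """Build an RGB->LMS matrix from cone sensitivities to three primaries.

    Each primary is either a monochromatic wavelength (nm, must lie on the
    CMF grid) or a broadband power :class:`SpectralFunction`, in which case
    the matrix entries are rectangle-rule integrals of the primary spectrum
    against each fundamental.
    """
    if len(primaries) != 3:
        raise ValueError("need exactly three primaries")
    cols = []
    for p in primaries:
        if isinstance(p, SpectralFunction):
            cols.append(tristimulus(p, cmfs))
        else:
            cols.append(np.array([cmfs.L.value_at(p), cmfs.M.value_at(p),
                                  cmfs.S.value_at(p)]))
    m = np.column_stack(cols)
    return TransformMatrix(to_space, "LMS", m)


def spectrum_locus(cmfs: ConeFundamentalSet, target_space: str = "lm") -> np.ndarray:
    """Chromaticity coordinates of the monochromatic spectrum locus.

    ``target_space``: 'lm' (cone space), 'rg' (Stiles-Burch 10-deg RGB) or
    'xy' (XYZ; uses the matrix matching the observer's field label, 2-deg by
    default). Returns an (n, 2) array ordered by wavelength.
    """
    stack = np.vstack([cmfs.L.values, cmfs.M.values, cmfs.S.values])
    if target_space == "lm":
        tri = stack
    elif target_space == "rg":
        tri = builtin_matrix("rgb10_to_lms10").inverse().m @ stack
    elif target_space == "xy":
        fov = "deg10" if "10" in cmfs.observer.field_label else "deg2"
        tri = xyz_from_lms_matrix(fov).m @ stack
    else:
        raise ValueError("target_space must be 'lm', 'rg' or 'xy'")
    total = tri.sum(axis=0)
    if np.any(total == 0):
        raise ZeroDivisionError("zero tristimulus sum on the locus")
    return np.column_stack([tri[0] / total, tri[1] / total])
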