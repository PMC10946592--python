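"""Fourier-polynomial spectral templates.

The photopigment absorbance spectra of the human L-, M- and S-cones, and the
optical-density spectra of the macular and lens pigments, are represented here
as truncated Fourier series ("Fourier polynomials") of the form

    F(theta) = a0 + sum_k [ a_k cos(k theta) + b_k sin(k theta) ]

evaluated over half a period (theta in [0, pi]) of a mapped wavelength axis.
Photopigment absorbance templates use a log10-wavelength axis spanning
360-850 nm, so that spectra of pigments with different peak wavelengths are
(approximately) shape-invariant translations of one another; the macular and
lens density templates use a linear wavelength axis over their fitted support.

Each template carries a post-scale: an additive renormalisation ``s`` for the
log-absorbance templates (chosen so the linear absorbance peaks at 1 at
lambda_max to the nearest 0.1 nm) or a multiplicative factor ``d`` for the
density templates (anchoring the macular density to 0.350 at 460 nm and the
lens density to 1.7649 at 400 nm).

The coefficients themselves are purely descriptive fits with no theoretical
significance; they are bundled verbatim in ``data/coefficients.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
import numpy as np

__all__ = [
    "FourierTemplate",
    "SpectralFunction",
    "builtin_template",
    "builtin_template_names",
    "find_lambda_max",
    "tabulate",
]

#: Units tags carried by SpectralFunction.
UNITS = (
    "log_absorbance",
    "linear_absorbance",
    "density",
    "quantal_sensitivity",
    "energy_sensitivity",
    "power",
)


@dataclass(frozen=True)
class SpectralFunction:
    """A function of wavelength sampled on a uniform grid.

    Parameters
    ----------
    lambda_start
        First wavelength of the grid, nm.
    lambda_step
        Grid spacing, nm (> 0).
    values
        Sampled values, one per grid point.
    units
        One of the tags in :data:`UNITS`.
    """

    lambda_start: float
    lambda_step: float
    values: np.ndarray
    units: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.lambda_step <= 0:
            raise ValueError("lambda_step must be positive")
        if v.size == 0:
            raise ValueError("values must be non-empty")
        if self.units not in UNITS:
            raise ValueError(f"unknown units tag {self.units!r}")
        if self.units != "log_absorbance" and np.nanmin(v) < 0:
            raise ValueError(f"{self.units} values must be non-negative")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.lambda_start + self.lambda_step * np.arange(self.values.size)

    @property
    def lambda_end(self) -> float:
        return float(self.wavelengths[-1])

    def value_at(self, lambda_nm: float) -> float:
        """Value at a grid wavelength (must lie on the grid)."""
        idx = (lambda_nm - self.lambda_start) / self.lambda_step
        i = int(round(idx))
        if not (0 <= i < self.values.size) or abs(idx - i) > 1e-6:
            raise ValueError(f"{lambda_nm} nm is not on the grid")
        return float(self.values[i])

    def with_values(self, values: np.ndarray, units: str | None = None) -> "SpectralFunction":
        return SpectralFunction(self.lambda_start, self.lambda_step, values,
                                units if units is not None else self.units)


@dataclass(frozen=True)
class FourierTemplate:
    """A truncated Fourier-series spectral template.

    ``evaluate`` returns log10 absorbance for absorbance templates (post-scale
    ``s`` added) and a clamped, non-negative optical density for density
    templates (post-scale ``d`` multiplied; exactly zero outside the fitted
    support).
    """

    name: str
    order: int
    a0: float
    a: tuple
    b: tuple
    post_scale_kind: str  # 'additive_s' | 'multiplicative_d'
    post_scale: float
    domain_axis: str  # 'log10_nm' | 'linear_nm'
    lambda_lo: float
    lambda_hi: float
    out_of_range: str  # 'error' | 'zero'
    output_units: str  # 'log_absorbance' | 'density'

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", tuple(float(x) for x in self.a))
        object.__setattr__(self, "b", tuple(float(x) for x in self.b))
        if len(self.a) != self.order or len(self.b) != self.order:
            raise ValueError("len(a) and len(b) must equal order")
        if not self.lambda_lo < self.lambda_hi:
            raise ValueError("lambda_lo must be < lambda_hi")
        if self.post_scale_kind not in ("additive_s", "multiplicative_d"):
            raise ValueError(f"bad post_scale_kind {self.post_scale_kind!r}")
        if self.domain_axis not in ("log10_nm", "linear_nm"):
            raise ValueError(f"bad domain_axis {self.domain_axis!r}")

    # -- support ---------------------------------------------------------
    @property
    def support(self) -> tuple:
        """(lo, hi) wavelengths over which the template is defined/nonzero."""
        return (self.lambda_lo, self.lambda_hi)

    @property
    def is_absorbance(self) -> bool:
        return self.output_units == "log_absorbance"

    # -- evaluation ------------------------------------------------------
    def map_theta(self, lambda_nm):
        """Map wavelength to the template's phase angle in [0, pi].

        Log-axis templates: theta = pi * log10(l/lo) / log10(hi/lo).
        Linear-axis templates: theta = pi * (l - lo) / (hi - lo).
        """
        lam = np.asarray(lambda_nm, dtype=float)
        tol = 1e-6  # absorb float rounding at shifted-support endpoints
        if np.any(lam < self.lambda_lo - tol) or np.any(lam > self.lambda_hi + tol):
            raise ValueError(
                f"wavelength outside template domain [{self.lambda_lo}, {self.lambda_hi}] nm")
        lam = np.clip(lam, self.lambda_lo, self.lambda_hi)
        # form the unit fraction first so theta(lambda_hi) is exactly pi
        if self.domain_axis == "log10_nm":
            frac = np.log10(lam / self.lambda_lo) / np.log10(self.lambda_hi / self.lambda_lo)
        else:
            frac = (lam - self.lambda_lo) / (self.lambda_hi - self.lambda_lo)
        th = np.pi * frac
        return th if th.ndim else float(th)

    def _fourier_sum(self, theta):
        th = np.atleast_1d(np.asarray(theta, dtype=float))[..., None]
        k = np.arange(1, self.order + 1)
        out = self.a0 + (np.array(self.a) * np.cos(k * th)
                         + np.array(self.b) * np.sin(k * th)).sum(axis=-1)
        return out

    def evaluate(self, lambda_nm):
        """Template value at wavelength(s).

        Absorbance templates return log10 absorbance and raise outside their
        domain; density templates return a density clamped at 0 from below and
        return exactly 0 outside their fitted support (for 360-850 nm input).
        """
        lam = np.asarray(lambda_nm, dtype=float)
        scalar = lam.ndim == 0
        lam = np.atleast_1d(lam)
        if self.out_of_range == "error":
            th = self.map_theta(lam)
            out = self._fourier_sum(th)
            if self.post_scale_kind == "additive_s":
                out = out + self.post_scale
            else:
                out = out * self.post_scale
        else:
            if np.any(lam < 360.0) or np.any(lam > 850.0):
                raise ValueError("wavelength outside 360-850 nm")
            out = np.zeros_like(lam)
            inside = (lam >= self.lambda_lo) & (lam <= self.lambda_hi)
            if np.any(inside):
                th = self.map_theta(lam[inside])
                v = self._fourier_sum(th)
                if self.post_scale_kind == "additive_s":
                    v = v + self.post_scale
                else:
                    v = v * self.post_scale
                out[inside] = v
        if self.output_units == "density":
            out = np.maximum(out, 0.0)
        return float(out[0]) if scalar else out

    def log_absorbance(self, lambda_nm):
        if not self.is_absorbance:
            raise TypeError(f"{self.name} is not an absorbance template")
        return self.evaluate(lambda_nm)

    def linear_absorbance(self, lambda_nm):
        return np.power(10.0, self.log_absorbance(lambda_nm))

    def lambda_max(self, resolution: float = 0.1) -> float:
        return find_lambda_max(self, resolution=resolution)


# ----------------------------------------------------------------------
# Built-in registry
# ----------------------------------------------------------------------

def _load_bundle() -> dict:
    text = resources.files("conefund").joinpath("data/coefficients.json").read_text()
    return json.loads(text)


_BUNDLE = _load_bundle()


def builtin_template_names() -> tuple:
    return tuple(_BUNDLE["templates"])


def builtin_template(name: str) -> FourierTemplate:
    """Return a bundled template by name.

    Names: ``L``, ``M``, ``S`` (mean cone absorbance spectra),
    ``L_ser180_poly`` (the L(ser180) polymorphic variant),
    ``L_common`` (the shape-invariant common template, aligned to L(ser180)),
    ``macular`` and ``lens`` (pre-receptoral pigment densities).
    """
    try:
        rec = _BUNDLE["templates"][name]
    except KeyError:
        raise KeyError(
            f"unknown template {name!r}; available: {builtin_template_names()}") from None
    return FourierTemplate(**rec)


def _matrix_record(name: str) -> dict:
    return _BUNDLE["matrices"][name]


# ----------------------------------------------------------------------
# Grid utilities
# ----------------------------------------------------------------------

def _grid(start: float, end: float, step: float) -> np.ndarray:
    if step <= 0:
        raise ValueError("step must be positive")
    if not start < end:
        raise ValueError("start must be < end")
    n = int(np.floor((end - start) / step + 1e-9)) + 1
    return start + step * np.arange(n)


def find_lambda_max(obj, resolution: float = 0.1) -> float:
    """Wavelength of peak linear value, to the given resolution.

    For a template (or any object exposing ``support`` and
    ``linear_absorbance``), the peak is located by evaluation on a uniform
    grid over the support. For a :class:`SpectralFunction`, the argmax of its
    sampled values is returned. Ties break toward the shorter wavelength.
    """
    if isinstance(obj, SpectralFunction):
        return float(obj.wavelengths[int(np.argmax(obj.values))])
    lo, hi = obj.support
    if not lo < hi:
        raise ValueError("degenerate support")
    lam = _grid(lo, hi, resolution)
    vals = obj.linear_absorbance(lam)
    # np.argmax returns the first (shortest-wavelength) maximiser on ties
    peak = lam[int(np.argmax(vals))]
    decimals = max(0, int(round(-np.log10(resolution))))
    return float(np.round(peak, decimals))


def tabulate(obj, lambda_start: float, lambda_end: float, step: float,
             linear: bool = False) -> SpectralFunction:
    """Sample a template (or template-like evaluator) on a uniform grid.

    Absorbance templates are tabulated as log10 absorbance (or linear
    absorbance with ``linear=True``); density templates as optical density.
    """
    lam = _grid(lambda_start, lambda_end, step)
    if getattr(obj, "is_absorbance", False):
        if linear:
            return SpectralFunction(lambda_start, step, obj.linear_absorbance(lam),
                                    "linear_absorbance")
        return SpectralFunction(lambda_start, step, obj.log_absorbance(lam), "log_absorbance")
    return SpectralFunction(lambda_start, step, obj.evaluate(lam), "density")
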