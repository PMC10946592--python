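"""Table I/O, reference comparison, observer configuration, and fixtures.

Tables are written as CSV with '#'-prefixed metadata header lines and values
at 8 decimal places. Reference tabulations in the cvrl.org style (wavelength,
L, M, S columns; blank cells where the S channel runs out at long
wavelengths) can be read back and compared channel-by-channel as mean
absolute errors in linear and log10 units, excluding wavelengths below
400 nm by default (where the templates deliberately depart from the
tabulated standard).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .fundamentals import (
    ConeFundamentalSet,
    ObserverParameters,
    compute_fundamentals,
    standard_observer,
)
from .prereceptoral import FilterScaling
from .templates import SpectralFunction, _grid

__all__ = [
    "write_table",
    "read_reference",
    "compare_mae",
    "ComparisonReport",
    "ObserverConfig",
    "make_fixtures",
]

_PRECISION = 8


def write_table(obj, path) -> Path:
    """Write a fundamentals set (or an (n,2) locus array) as annotated CSV."""
    path = Path(path)
    lines = []
    if isinstance(obj, ConeFundamentalSet):
        obs = obj.observer
        lines.append(f"# conefund cone fundamentals ({obj.units} units)")
        lines.append(f"# observer: {obs.field_label}")
        lines.append(f"# optical densities L,M,S: {obs.l_od},{obs.m_od},{obs.s_od}")
        lines.append(f"# k_mac,k_lens: {obs.scaling.k_mac},{obs.scaling.k_lens}")
        lines.append(f"# shifts (log10 nm) L,M,S: {obs.shift_l},{obs.shift_m},{obs.shift_s}")
        lines.append(f"# L variant: {obs.l_variant}")
        lines.append("wavelength_nm,L,M,S")
        for lam, l, m, s in zip(obj.wavelengths, obj.L.values, obj.M.values, obj.S.values):
            lines.append(f"{lam:g},{l:.{_PRECISION}f},{m:.{_PRECISION}f},{s:.{_PRECISION}f}")
    else:
        arr = np.asarray(obj, dtype=float)
        lines.append("# conefund chromaticity locus")
        lines.append("c1,c2")
        for row in arr:
            lines.append(",".join(f"{x:.{_PRECISION}f}" for x in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_reference(path):
    """Read a cvrl-style CSV (wavelength, L, M, S) into three SpectralFunctions.

    Blank cells (typically the S channel at long wavelengths) become NaN and
    are treated as missing by :func:`compare_mae`. The wavelength column must
    be uniformly spaced and strictly increasing.
    """
    path = Path(path)
    rows = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if parts and not _is_number(parts[0]):
            continue  # header row
        if len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
        try:
            vals = [float(p) if p != "" else np.nan for p in parts[:4]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        rows.append((lineno, vals))
    if len(rows) < 2:
        raise ValueError(f"{path}: too few data rows")
    lam = np.array([v[0] for _, v in rows])
    steps = np.diff(lam)
    if np.any(steps <= 0):
        bad = rows[int(np.argmax(steps <= 0)) + 1][0]
        raise ValueError(f"{path}:{bad}: wavelengths must be strictly increasing")
    if not np.allclose(steps, steps[0]):
        raise ValueError(f"{path}: wavelength grid is not uniform")
    data = np.array([v[1:] for _, v in rows])
    step = float(steps[0])
    return tuple(
        SpectralFunction(float(lam[0]), step, _nan_safe(data[:, i]), "energy_sensitivity")
        for i in range(3)
    )


def _nan_safe(col: np.ndarray) -> np.ndarray:
    # SpectralFunction rejects negatives; NaNs (missing cells) are allowed
    return col


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


@dataclass(frozen=True)
class ComparisonReport:
    """Per-channel mean absolute errors between two fundamentals sets."""

    mae_linear: dict
    mae_log: dict
    lambda_min: float
    lambda_max: float
    n_points: dict

    def summary(self) -> str:
        lines = [f"comparison over {self.lambda_min:g}-{self.lambda_max:g} nm"]
        for ch in ("L", "M", "S"):
            lines.append(
                f"  {ch}: linear MAE {self.mae_linear[ch]:.6f}, "
                f"log10 MAE {self.mae_log[ch]:.6f} (n={self.n_points[ch]})")
        return "\n".join(lines)


def compare_mae(generated: ConeFundamentalSet, reference, lambda_min: float = 400.0,
                log_floor: float = 1e-8) -> ComparisonReport:
    """Mean absolute error of generated vs reference fundamentals.

    ``reference`` is a triple of SpectralFunctions (as from
    :func:`read_reference`) or another ConeFundamentalSet. Comparison runs at
    the reference's own grid step over the overlap, excluding wavelengths
    below ``lambda_min`` and missing (NaN) reference points. Log MAEs ignore
    points where either value is at or below ``log_floor``.
    """
    ref = (reference.L, reference.M, reference.S) if isinstance(
        reference, ConeFundamentalSet) else tuple(reference)
    gen = (generated.L, generated.M, generated.S)
    mae_lin, mae_log, n_pts = {}, {}, {}
    lo_used, hi_used = np.inf, -np.inf
    for ch, g, r in zip(("L", "M", "S"), gen, ref):
        lam_r = r.wavelengths
        lo = max(lambda_min, g.lambda_start, r.lambda_start)
        hi = min(g.lambda_end, r.lambda_end)
        mask = (lam_r >= lo - 1e-9) & (lam_r <= hi + 1e-9)
        lam = lam_r[mask]
        rv = r.values[mask]
        # sample the generated set at the reference wavelengths (must be on-grid)
        idx = (lam - g.lambda_start) / g.lambda_step
        ii = np.round(idx).astype(int)
        if np.any(np.abs(idx - ii) > 1e-6):
            raise ValueError("reference grid does not align with generated grid")
        gv = g.values[ii]
        ok = ~np.isnan(rv)
        if not np.any(ok):
            raise ValueError(f"empty overlap for channel {ch}")
        mae_lin[ch] = float(np.mean(np.abs(gv[ok] - rv[ok])))
        pos = ok & (rv > log_floor) & (gv > log_floor)
        mae_log[ch] = float(np.mean(np.abs(np.log10(gv[pos]) - np.log10(rv[pos]))))
        n_pts[ch] = int(ok.sum())
        lo_used, hi_used = min(lo_used, lam[ok].min()), max(hi_used, lam[ok].max())
    return ComparisonReport(mae_linear=mae_lin, mae_log=mae_log,
                            lambda_min=float(lo_used), lambda_max=float(hi_used),
                            n_points=n_pts)


# ----------------------------------------------------------------------
# Observer configuration
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ObserverConfig:
    """Declarative observer + output description (YAML/JSON round-trippable).

    Unset physiological fields default to the standard 2-deg observer.
    Macular/lens filtering may be given either as scalings (``k_mac``,
    ``k_lens``) or as anchor densities (``d_mac_460``, ``d_lens_400``), not
    both.
    """

    field: str = "deg2"
    l_od: float | None = None
    m_od: float | None = None
    s_od: float | None = None
    k_mac: float | None = None
    k_lens: float | None = None
    d_mac_460: float | None = None
    d_lens_400: float | None = None
    shift_l: float = 0.0
    shift_m: float = 0.0
    shift_s: float = 0.0
    l_variant: str = "mean"
    lambda_start: float = 390.0
    lambda_end: float = 830.0
    step: float = 1.0
    units: str = "energy"

    def to_observer(self) -> ObserverParameters:
        base = standard_observer(self.field)
        if self.k_mac is not None and self.d_mac_460 is not None:
            raise ValueError("give k_mac or d_mac_460, not both")
        if self.k_lens is not None and self.d_lens_400 is not None:
            raise ValueError("give k_lens or d_lens_400, not both")
        scaling = FilterScaling.from_peak_densities(self.d_mac_460, self.d_lens_400)
        k_mac = scaling.k_mac if self.d_mac_460 is not None else (
            self.k_mac if self.k_mac is not None else base.scaling.k_mac)
        k_lens = scaling.k_lens if self.d_lens_400 is not None else (
            self.k_lens if self.k_lens is not None else base.scaling.k_lens)
        return ObserverParameters(
            field_label=base.field_label if self._is_standard() else "custom",
            l_od=self.l_od if self.l_od is not None else base.l_od,
            m_od=self.m_od if self.m_od is not None else base.m_od,
            s_od=self.s_od if self.s_od is not None else base.s_od,
            scaling=FilterScaling(k_mac=k_mac, k_lens=k_lens),
            shift_l=self.shift_l, shift_m=self.shift_m, shift_s=self.shift_s,
            l_variant=self.l_variant)

    def _is_standard(self) -> bool:
        return all(x is None for x in (self.l_od, self.m_od, self.s_od,
                                       self.k_mac, self.k_lens,
                                       self.d_mac_460, self.d_lens_400)) \
            and self.shift_l == self.shift_m == self.shift_s == 0.0 \
            and self.l_variant == "mean"

    def compute(self) -> ConeFundamentalSet:
        return compute_fundamentals(self.to_observer(), self.lambda_start,
                                    self.lambda_end, self.step, self.units)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ObserverConfig":
        return cls(**d)

    def save(self, path) -> Path:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))
        return path

    @classmethod
    def load(cls, path) -> "ObserverConfig":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(d)


# ----------------------------------------------------------------------
# Test fixtures
# ----------------------------------------------------------------------

def make_fixtures(seed: int, outdir) -> dict:
    """Deterministic toy inputs for tests and examples.

    Writes narrowband Gaussian power spectra, random positive tristimuli, and
    a degraded (5-nm step, truncated) copy of the standard 2-deg table for
    exercising the read/compare paths. Same seed, same bytes.
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    lam = _grid(390.0, 830.0, 1.0)
    gauss = []
    for center, width in ((450.0, 10.0), (530.0, 15.0), (610.0, 20.0)):
        amp = float(np.round(rng.uniform(0.5, 2.0), 6))
        gauss.append((center, width, amp))
    lines = ["# synthetic Gaussian power spectra (center,width,amplitude per column)",
             "wavelength_nm," + ",".join(f"g{i}" for i in range(len(gauss)))]
    cols = [amp * np.exp(-0.5 * ((lam - c) / w) ** 2) for c, w, amp in gauss]
    for i, l in enumerate(lam):
        lines.append(f"{l:g}," + ",".join(f"{col[i]:.8f}" for col in cols))
    p = outdir / "gaussian_spectra.csv"
    p.write_text("\n".join(lines) + "\n")
    paths["gaussian_spectra"] = p
    paths["gaussian_params"] = gauss

    tri = np.round(rng.uniform(0.1, 5.0, size=(5, 3)), 6)
    p = outdir / "tristimuli.csv"
    p.write_text("L,M,S\n" + "\n".join(",".join(f"{x:.6f}" for x in row) for row in tri) + "\n")
    paths["tristimuli"] = p

    full = compute_fundamentals(standard_observer("deg2"))
    mask = (full.wavelengths % 5 == 0) & (full.wavelengths <= 700)
    lines = ["wavelength_nm,L,M,S"]
    for l, a, b, c in zip(full.wavelengths[mask], full.L.values[mask],
                          full.M.values[mask], full.S.values[mask]):
        noisy = [v * (1 + 1e-4) for v in (a, b, c)]  # deliberately degraded
        lines.append(f"{l:g}," + ",".join(f"{v:.6f}" for v in noisy))
    p = outdir / "degraded_2deg.csv"
    p.write_text("\n".join(lines) + "\n")
    paths["degraded_2deg"] = p
    return paths
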