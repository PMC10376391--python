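"""Diffusion signal models and voxel-wise parameter-map fitting.

Two forward models of the trace-weighted DWI magnitude signal are supported:

* the diffusion kurtosis (DKI) model::

      S(b) = S0 * exp(-b*MD + b^2 * MD^2 * MK / 6)

  with kurtosis-corrected diffusivity MD (mm^2/s) and the dimensionless
  mean kurtosis MK quantifying the deviation of water displacement from a
  Gaussian profile, and

* the mono-exponential model::

      S(b) = S0 * exp(-b*ADC)

  yielding the apparent diffusion coefficient ADC (mm^2/s).

Fitting is nonlinear least squares on the signal (not the log-signal),
weighted per b-value by the number of excitations averaged (NEX), since the
variance of an NEX-fold average scales as 1/NEX.  Initial values come from
an ordinary least-squares fit of ln S against (b, b^2), which is exact on
noiseless data, so the optimizer only has to polish.  Diffusivities are held
in mm^2/s throughout this module; the reporting layer rescales to the
conventional 1e-3 mm^2/s.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

logger = logging.getLogger("dkitex")

__all__ = [
    "DEFAULT_SCHEME_ENTRIES",
    "BValueScheme",
    "DKIParams",
    "ADCParams",
    "FitConfig",
    "FitDiagnostics",
    "ParameterMaps",
    "GridMismatchError",
    "dki_forward",
    "adc_forward",
    "fit_dki_voxel",
    "fit_adc_voxel",
    "fit_maps",
]

#: 13 b-value clinical bladder protocol: (b in s/mm^2, NEX averages at that b).
DEFAULT_SCHEME_ENTRIES: tuple[tuple[float, int], ...] = (
    (0, 1), (50, 1), (80, 1), (100, 1), (150, 1), (200, 1),
    (300, 2), (500, 2), (800, 2), (1000, 4), (1300, 4), (1700, 6), (2000, 6),
)


class GridMismatchError(ValueError):
    """Raised when a volume and mask (or scheme) do not share a grid."""


@dataclass(frozen=True)
class BValueScheme:
    """Ordered diffusion-weighting scheme: (b, NEX) per acquisition."""

    entries: tuple[tuple[float, int], ...]

    def __post_init__(self) -> None:
        entries = tuple((float(b), int(nex)) for b, nex in self.entries)
        object.__setattr__(self, "entries", entries)
        b = np.array([e[0] for e in entries])
        nex = np.array([e[1] for e in entries])
        if len(entries) == 0:
            raise ValueError("scheme must contain at least one entry")
        if b[0] != 0:
            raise ValueError("first scheme entry must have b = 0")
        if np.any(b < 0):
            raise ValueError("b values must be nonnegative")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b values must be strictly increasing")
        if np.any(nex < 1):
            raise ValueError("NEX must be a positive integer for every entry")

    @classmethod
    def default(cls) -> "BValueScheme":
        """The 13 b-value protocol used as simulator default."""
        return cls(DEFAULT_SCHEME_ENTRIES)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BValueScheme":
        """Read a scheme from a TSV file with header ``b<TAB>nex``."""
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None or not {"b", "nex"} <= set(reader.fieldnames):
                raise ValueError(f"{path}: expected TSV header 'b\\tnex'")
            entries = [(float(row["b"]), int(row["nex"])) for row in reader]
        return cls(tuple(entries))

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["b", "nex"])
            for b, nex in self.entries:
                writer.writerow([f"{b:g}", nex])

    @property
    def b(self) -> np.ndarray:
        return np.array([e[0] for e in self.entries], dtype=float)

    @property
    def nex(self) -> np.ndarray:
        return np.array([e[1] for e in self.entries], dtype=float)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class DKIParams:
    """DKI model parameters for one voxel.

    s0 is the b=0 baseline signal (arbitrary units), md the kurtosis-corrected
    diffusivity in mm^2/s, mk the dimensionless mean kurtosis.
    """

    s0: float
    md: float
    mk: float
    mk_max: float = 3.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.s0) and self.s0 > 0):
            raise ValueError(f"s0 must be positive and finite, got {self.s0}")
        if not (np.isfinite(self.md) and self.md > 0):
            raise ValueError(f"md must be positive and finite, got {self.md}")
        if not (np.isfinite(self.mk) and 0 <= self.mk <= self.mk_max):
            raise ValueError(f"mk must lie in [0, {self.mk_max}], got {self.mk}")


@dataclass(frozen=True)
class ADCParams:
    """Mono-exponential model parameters for one voxel (adc in mm^2/s)."""

    s0: float
    adc: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.s0) and self.s0 > 0):
            raise ValueError(f"s0 must be positive and finite, got {self.s0}")
        if not (np.isfinite(self.adc) and self.adc > 0):
            raise ValueError(f"adc must be positive and finite, got {self.adc}")


def dki_forward(params: DKIParams, b) -> np.ndarray | float:
    """Evaluate the DKI signal model at diffusion weighting ``b`` (s/mm^2)."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be nonnegative")
    exponent = -b * params.md + b**2 * params.md**2 * params.mk / 6.0
    out = params.s0 * np.exp(exponent)
    return out if out.ndim else float(out)


def adc_forward(params: ADCParams, b) -> np.ndarray | float:
    """Evaluate the mono-exponential signal model at ``b`` (s/mm^2)."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be nonnegative")
    out = params.s0 * np.exp(-b * params.adc)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FitConfig:
    """Options controlling voxel-wise model fitting.

    Bounds cover the physiologic tissue range; the cost tolerance and
    iteration cap are deliberately tight so that noiseless forward-model
    input is recovered to ~1e-6 relative accuracy.
    """

    md_bounds: tuple[float, float] = (1e-5, 5e-3)   # mm^2/s
    mk_bounds: tuple[float, float] = (0.0, 3.0)
    adc_bounds: tuple[float, float] = (1e-6, 1e-2)  # mm^2/s
    adc_b_max: float = 1000.0      # mono-exponential fit restricted to b <= this
    cost_tol: float = 1e-10
    max_iter: int = 200

    @property
    def mk_max(self) -> float:
        return self.mk_bounds[1]


@dataclass(frozen=True)
class FitDiagnostics:
    """Per-voxel fit bookkeeping."""

    converged: bool
    residual_norm: float
    n_points_used: int
    at_bound: tuple[bool, ...] = ()
    message: str = ""


_BOUND_TOL = 1e-12


def _near_bound(value: float, lo: float, hi: float) -> bool:
    span = max(hi - lo, 1.0)
    return (value - lo) <= 1e-8 * span or (hi - value) <= 1e-8 * span


def _signal_ok(signal: np.ndarray) -> bool:
    return bool(np.all(np.isfinite(signal)) and np.any(signal > 0) and signal[0] > 0)


def fit_dki_voxel(
    signal: Sequence[float] | np.ndarray,
    scheme: BValueScheme,
    config: FitConfig | None = None,
) -> tuple[DKIParams | None, FitDiagnostics]:
    """Fit the DKI model to one voxel's multi-b signal.

    Returns ``(params, diagnostics)``; ``params`` is None (voxel unfittable)
    for all-zero or non-finite input rather than raising, so that volume-level
    fitting can continue.
    """
    config = config or FitConfig()
    signal = np.asarray(signal, dtype=float)
    if signal.shape != (len(scheme),):
        raise ValueError(
            f"signal length {signal.shape} does not match scheme length {len(scheme)}"
        )
    if len(scheme) < 4:
        raise ValueError("DKI fit needs at least 4 distinct b values")
    if not _signal_ok(signal):
        return None, FitDiagnostics(False, np.nan, 0, message="unfittable signal")

    b, nex = scheme.b, scheme.nex
    w = np.sqrt(nex)
    lo = np.array([1e-12, config.md_bounds[0], config.mk_bounds[0]])
    hi = np.array([np.inf, config.md_bounds[1], config.mk_bounds[1]])

    x0 = _init_dki(signal, b, config)

    def resid(x):
        s0, md, mk = x
        model = s0 * np.exp(-b * md + b**2 * md**2 * mk / 6.0)
        return w * (model - signal)

    def jac(x):
        s0, md, mk = x
        e = np.exp(-b * md + b**2 * md**2 * mk / 6.0)
        s = s0 * e
        J = np.empty((b.size, 3))
        J[:, 0] = e
        J[:, 1] = s * (-b + b**2 * md * mk / 3.0)
        J[:, 2] = s * b**2 * md**2 / 6.0
        return J * w[:, None]

    res = least_squares(
        resid, x0, jac=jac, bounds=(lo, hi), method="trf",
        ftol=config.cost_tol, xtol=1e-14, gtol=1e-14,
        x_scale=[max(x0[0], 1e-6), 1e-3, 1.0], max_nfev=config.max_iter,
    )
    s0, md, mk = res.x
    mk = float(np.clip(mk, config.mk_bounds[0], config.mk_bounds[1]))
    params = DKIParams(s0=float(s0), md=float(md), mk=mk, mk_max=config.mk_max)
    diag = FitDiagnostics(
        converged=bool(res.status > 0),
        residual_norm=float(np.sqrt(2.0 * res.cost)),
        n_points_used=int(b.size),
        at_bound=(
            False,
            _near_bound(md, *config.md_bounds),
            _near_bound(mk, *config.mk_bounds),
        ),
        message=res.message,
    )
    return params, diag


def _init_dki(signal: np.ndarray, b: np.ndarray, config: FitConfig) -> np.ndarray:
    """OLS of ln S on (1, b, b^2), mapped to (S0, MD, MK) and clipped to bounds."""
    pos = signal > 0
    bb, ss = b[pos], signal[pos]
    if bb.size >= 3:
        X = np.column_stack([np.ones_like(bb), bb, bb**2])
        c, *_ = np.linalg.lstsq(X, np.log(ss), rcond=None)
        s0 = float(np.exp(c[0]))
        md = float(-c[1])
        md = float(np.clip(md, *config.md_bounds))
        mk = float(6.0 * c[2] / md**2)
    else:  # degenerate: flat start
        s0, md, mk = float(ss.max()), 1e-3, 0.5
    mk = float(np.clip(mk, *config.mk_bounds))
    s0 = max(s0, 1e-9)
    return np.array([s0, md, mk])


def fit_adc_voxel(
    signal: Sequence[float] | np.ndarray,
    scheme: BValueScheme,
    config: FitConfig | None = None,
) -> tuple[ADCParams | None, FitDiagnostics]:
    """Fit the mono-exponential model, restricted to b <= ``config.adc_b_max``."""
    config = config or FitConfig()
    signal = np.asarray(signal, dtype=float)
    if signal.shape != (len(scheme),):
        raise ValueError(
            f"signal length {signal.shape} does not match scheme length {len(scheme)}"
        )
    keep = scheme.b <= config.adc_b_max
    b, nex, sig = scheme.b[keep], scheme.nex[keep], signal[keep]
    if np.unique(b).size < 2:
        raise ValueError(
            f"ADC fit needs >=2 distinct b values with b <= {config.adc_b_max}"
        )
    if not _signal_ok(sig):
        return None, FitDiagnostics(False, np.nan, 0, message="unfittable signal")

    w = np.sqrt(nex)
    pos = sig > 0
    X = np.column_stack([np.ones(pos.sum()), b[pos]])
    c, *_ = np.linalg.lstsq(X, np.log(sig[pos]), rcond=None)
    s0_init = max(float(np.exp(c[0])), 1e-9)
    adc_init = float(np.clip(-c[1], *config.adc_bounds))

    def resid(x):
        return w * (x[0] * np.exp(-b * x[1]) - sig)

    def jac(x):
        e = np.exp(-b * x[1])
        J = np.empty((b.size, 2))
        J[:, 0] = e
        J[:, 1] = -x[0] * b * e
        return J * w[:, None]

    res = least_squares(
        resid, np.array([s0_init, adc_init]), jac=jac,
        bounds=(np.array([1e-12, config.adc_bounds[0]]),
                np.array([np.inf, config.adc_bounds[1]])),
        method="trf", ftol=config.cost_tol, xtol=1e-14, gtol=1e-14,
        x_scale=[max(s0_init, 1e-6), 1e-3], max_nfev=config.max_iter,
    )
    params = ADCParams(s0=float(res.x[0]), adc=float(res.x[1]))
    diag = FitDiagnostics(
        converged=bool(res.status > 0),
        residual_norm=float(np.sqrt(2.0 * res.cost)),
        n_points_used=int(b.size),
        at_bound=(False, _near_bound(params.adc, *config.adc_bounds)),
        message=res.message,
    )
    return params, diag


@dataclass
class ParameterMaps:
    """Voxel grids of fitted model parameters plus fit diagnostics.

    ``params`` maps parameter name ("s0", "md", "mk" or "s0", "adc") to a 3D
    array with NaN outside the set of successfully fitted voxels.
    Diffusivities are stored in mm^2/s.
    """

    model: str
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    params: dict[str, np.ndarray]
    mask: np.ndarray                 # input VOI mask
    fitted: np.ndarray               # voxels with a usable fit
    converged: np.ndarray
    residual_norm: np.ndarray
    n_points_used: np.ndarray
    config: FitConfig = field(default_factory=FitConfig)

    @property
    def n_fitted(self) -> int:
        return int(self.fitted.sum())

    def save(self, outdir: str | Path, prefix: str, affine: np.ndarray | None = None) -> list[Path]:
        """Write one NIfTI per parameter plus a JSON sidecar of fit metadata."""
        import nibabel as nib

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if affine is None:
            affine = np.diag([*self.spacing, 1.0])
        written: list[Path] = []
        for name, arr in self.params.items():
            p = outdir / f"{prefix}_{self.model}_{name}.nii.gz"
            nib.save(nib.Nifti1Image(arr.astype(np.float64), affine), p)
            written.append(p)
        sidecar = {
            "model": self.model,
            "shape": list(self.shape),
            "spacing": list(self.spacing),
            "n_mask": int(self.mask.sum()),
            "n_fitted": self.n_fitted,
            "n_converged": int(self.converged.sum()),
            "median_residual_norm": float(np.nanmedian(
                np.where(self.fitted, self.residual_norm, np.nan))) if self.n_fitted else None,
            "fit_config": {
                "md_bounds": list(self.config.md_bounds),
                "mk_bounds": list(self.config.mk_bounds),
                "adc_bounds": list(self.config.adc_bounds),
                "adc_b_max": self.config.adc_b_max,
                "cost_tol": self.config.cost_tol,
                "max_iter": self.config.max_iter,
            },
        }
        sp = outdir / f"{prefix}_{self.model}_fit.json"
        sp.write_text(json.dumps(sidecar, indent=1))
        written.append(sp)
        return written


def fit_maps(
    series: np.ndarray,
    scheme: BValueScheme,
    mask: np.ndarray,
    model: str = "dki",
    config: FitConfig | None = None,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ParameterMaps:
    """Fit a signal model voxel-wise over a masked 4D DWI series.

    Only voxels inside ``mask`` are fitted; everything else is NaN in the
    output maps.  Voxel fits are mutually independent, so iteration order
    cannot change the result.
    """
    config = config or FitConfig()
    series = np.asarray(series, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if series.ndim != 4:
        raise GridMismatchError(f"series must be 4D, got shape {series.shape}")
    if series.shape[:3] != mask.shape:
        raise GridMismatchError(
            f"series grid {series.shape[:3]} does not match mask grid {mask.shape}"
        )
    if series.shape[3] != len(scheme):
        raise GridMismatchError(
            f"series has {series.shape[3]} volumes but scheme has {len(scheme)} entries"
        )
    if model not in ("dki", "adc"):
        raise ValueError(f"model must be 'dki' or 'adc', got {model!r}")

    shape = series.shape[:3]
    names = ("s0", "md", "mk") if model == "dki" else ("s0", "adc")
    params = {n: np.full(shape, np.nan) for n in names}
    fitted = np.zeros(shape, dtype=bool)
    converged = np.zeros(shape, dtype=bool)
    residual_norm = np.full(shape, np.nan)
    n_points = np.zeros(shape, dtype=np.int32)

    idx = np.argwhere(mask)  # C-order raster: deterministic
    if idx.size == 0:
        warnings.warn("fit_maps: mask is empty; no voxels fitted", stacklevel=2)
        logger.warning("fit_maps: empty mask, zero voxels fitted")
    fit_one = fit_dki_voxel if model == "dki" else fit_adc_voxel
    for i, j, k in idx:
        p, d = fit_one(series[i, j, k, :], scheme, config)
        converged[i, j, k] = d.converged
        residual_norm[i, j, k] = d.residual_norm
        n_points[i, j, k] = d.n_points_used
        if p is None:
            continue
        fitted[i, j, k] = True
        if model == "dki":
            params["s0"][i, j, k] = p.s0
            params["md"][i, j, k] = p.md
            params["mk"][i, j, k] = p.mk
        else:
            params["s0"][i, j, k] = p.s0
            params["adc"][i, j, k] = p.adc

    return ParameterMaps(
        model=model, shape=shape, spacing=tuple(spacing), params=params,
        mask=mask, fitted=fitted, converged=converged,
        residual_norm=residual_norm, n_points_used=n_points, config=config,
    )
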