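"""Synthetic DWI phantoms and patient cohorts.

The clinical dataset this pipeline was designed around is private, so this
module fabricates study-shaped inputs at two levels:

* **cohort level** — per-patient whole-tumor marker summaries (MD/MK histogram
  statistics and mean ADC) drawn from truncated normals whose defaults are the
  published per-group means/SDs at the published group sizes (67 NMIBC / 34
  MIBC for staging; 70 high-grade / 31 low-grade for grading), plus two
  readers' ordinal VI-RADS scores from a per-class score model;

* **image level** — 3D ellipsoidal lesions on a coarse pelvic grid with smooth
  Gaussian-random-field MD/MK ground truth, pushed through the DKI forward
  model and corrupted with Rician noise (complex Gaussian noise per excitation,
  magnitude taken, then averaged over NEX).

Everything is driven by ``numpy.random.Generator`` seeds and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .signal_models import BValueScheme

__all__ = [
    "GroupDistribution",
    "PhantomSpec",
    "ReaderScoreModel",
    "STAGE_NMIBC",
    "STAGE_MIBC",
    "GRADE_HIGH",
    "GRADE_LOW",
    "DEFAULT_READER_MODEL",
    "MARKER_LOWER_BOUNDS",
    "sample_cohort",
    "make_truth_fields",
    "simulate_dwi",
    "simulate_reader_scores",
]

# ---------------------------------------------------------------------------
# Group-level marker distributions (published per-group mean +/- SD).
# Diffusivity markers are on the 1e-3 mm^2/s scale used in the source tables.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupDistribution:
    """Marginal (mean, sd) of each patient-level marker for one class."""

    label: str
    n: int
    markers: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2, got {self.n}")
        for name, (_, sd) in self.markers.items():
            if sd <= 0:
                raise ValueError(f"group {self.label!r}: sd of {name} must be > 0")


def _markers(md, mk, adc_mean):
    keys = ["mean", "p5", "p25", "p50", "p75", "p90",
            "inhomogeneity", "skewness", "kurtosis", "entropy"]
    out = {f"md_{k}": v for k, v in zip(keys, md)}
    out.update({f"mk_{k}": v for k, v in zip(keys, mk)})
    out["adc_mean"] = adc_mean
    return out


STAGE_NMIBC = GroupDistribution(
    "NMIBC", 67,
    _markers(
        md=[(1.92, 0.38), (1.19, 0.39), (1.53, 0.38), (1.86, 0.42),
            (2.75, 0.33), (2.75, 0.33), (0.29, 0.08), (0.43, 0.63),
            (-0.37, 1.04), (3.88, 0.40)],
        mk=[(0.69, 0.16), (0.38, 0.50), (0.60, 0.15), (0.72, 0.15),
            (0.81, 0.18), (0.92, 0.33), (0.38, 0.76), (-1.05, 0.91),
            (2.25, 2.71), (3.78, 0.25)],
        adc_mean=(1.65, 0.42),
    ),
)

STAGE_MIBC = GroupDistribution(
    "MIBC", 34,
    _markers(
        md=[(1.42, 0.34), (0.91, 0.25), (1.11, 0.28), (1.31, 0.33),
            (1.63, 0.46), (2.06, 0.56), (0.32, 0.09), (1.31, 0.69),
            (2.45, 3.41), (3.89, 0.26)],
        mk=[(0.81, 0.20), (0.38, 0.27), (0.69, 0.22), (0.84, 0.20),
            (0.96, 0.22), (1.06, 0.25), (0.29, 0.16), (-0.78, 0.72),
            (1.76, 2.21), (3.84, 0.25)],
        adc_mean=(1.13, 0.31),
    ),
)

GRADE_HIGH = GroupDistribution(
    "high", 70,
    _markers(
        md=[(1.66, 0.41), (1.03, 0.32), (1.30, 0.34), (1.56, 0.41),
            (1.99, 0.54), (2.45, 0.56), (0.31, 0.09), (0.88, 0.74),
            (0.91, 2.82), (3.93, 0.26)],
        mk=[(0.78, 0.17), (0.43, 0.49), (0.67, 0.17), (0.81, 0.17),
            (0.92, 0.19), (1.04, 0.33), (0.37, 0.75), (-0.84, 0.77),
            (1.81, 2.02), (3.83, 0.25)],
        adc_mean=(1.37, 0.39),
    ),
)

GRADE_LOW = GroupDistribution(
    "low", 31,
    _markers(
        md=[(1.97, 0.44), (1.27, 0.42), (1.59, 0.47), (1.92, 0.51),
            (2.34, 0.54), (2.68, 0.42), (0.27, 0.08), (0.37, 0.74),
            (-1.47, 1.44), (3.77, 0.50)],
        mk=[(0.61, 0.15), (0.29, 0.24), (0.53, 0.16), (0.64, 0.13),
            (0.73, 0.15), (0.80, 0.18), (0.31, 0.15), (-1.22, 1.00),
            (2.73, 3.42), (3.72, 0.23)],
        adc_mean=(1.71, 0.42),
    ),
)


def _lower_bound(marker: str) -> float:
    """Physical lower bound used for truncated sampling (-inf if unbounded)."""
    stem = marker.split("_", 1)[1] if "_" in marker else marker
    if stem in ("mean", "p5", "p25", "p50", "p75", "p90", "inhomogeneity", "entropy"):
        return 0.0
    return -np.inf


MARKER_LOWER_BOUNDS = {
    m: _lower_bound(m) for m in STAGE_NMIBC.markers
}

# Conditional label coupling used to fill in the endpoint that was not
# sampled: essentially all MIBC are high grade; picked to reproduce the
# published marginals (70 high grade / 34 MIBC out of 101).
_P_HIGH_GIVEN_MIBC = 0.97
_P_HIGH_GIVEN_NMIBC = 0.55
_P_MIBC_GIVEN_HIGH = 0.46
_P_MIBC_GIVEN_LOW = 0.05


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float, size: int) -> np.ndarray:
    """Rejection-sampled normal truncated below at ``lower``."""
    out = rng.normal(mean, sd, size)
    bad = out < lower
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < lower
    return out


@dataclass(frozen=True)
class ReaderScoreModel:
    """Per-class VI-RADS score distributions and inter-reader disagreement.

    ``dist_pos``/``dist_neg`` are probabilities over scores 1..5 for the
    positive (muscle-invasive) and negative class.  The second reader copies
    the first and, with probability ``disagreement``, moves one point up or
    down (clipped to 1..5).  Defaults are calibrated so that the score>=3 rule
    has sensitivity 0.85 and specificity 0.88, matching the published reader
    performance.
    """

    dist_pos: tuple[float, ...] = (0.03, 0.12, 0.25, 0.35, 0.25)
    dist_neg: tuple[float, ...] = (0.40, 0.48, 0.08, 0.03, 0.01)
    disagreement: float = 0.22

    def __post_init__(self) -> None:
        for name, d in (("dist_pos", self.dist_pos), ("dist_neg", self.dist_neg)):
            d = np.asarray(d, dtype=float)
            if d.shape != (5,) or np.any(d < 0) or abs(d.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be 5 nonnegative probabilities summing to 1")
        if not 0 <= self.disagreement <= 1:
            raise ValueError("disagreement must be a probability")

    def analytic_sens_spec(self, threshold: int = 3) -> tuple[float, float]:
        """Closed-form (sensitivity, specificity) of the score>=threshold rule."""
        pos = np.asarray(self.dist_pos)
        neg = np.asarray(self.dist_neg)
        sens = float(pos[threshold - 1:].sum())
        spec = float(neg[: threshold - 1].sum())
        return sens, spec


DEFAULT_READER_MODEL = ReaderScoreModel()


def simulate_reader_scores(
    positive: np.ndarray,
    model: ReaderScoreModel = DEFAULT_READER_MODEL,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw two readers' ordinal 1-5 scores given a boolean positive-class vector."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positive = np.asarray(positive, dtype=bool)
    n = positive.size
    scores = np.empty(n, dtype=int)
    for cls, dist in ((True, model.dist_pos), (False, model.dist_neg)):
        m = positive == cls
        scores[m] = rng.choice(np.arange(1, 6), size=int(m.sum()), p=np.asarray(dist))
    flip = rng.random(n) < model.disagreement
    step = rng.choice([-1, 1], size=n)
    reader2 = np.where(flip, np.clip(scores + step, 1, 5), scores)
    return scores, reader2


def sample_cohort(
    dist_pos: GroupDistribution,
    dist_neg: GroupDistribution,
    seed: int | np.random.Generator = 0,
    endpoint: str = "stage",
    latent_rho: float = 0.0,
    reader_model: ReaderScoreModel = DEFAULT_READER_MODEL,
) -> pd.DataFrame:
    """Draw a two-class cohort of patient-level marker summaries.

    Each marker is sampled from a normal with the group's (mean, sd),
    truncated at its physical lower bound by rejection.  With
    ``latent_rho > 0`` a per-patient latent severity induces cross-marker
    correlation (sign per marker taken from the direction of the group-mean
    difference), which is what makes marker combinations informative.

    Returns a table with one row per patient: labels for both endpoints, two
    readers' VI-RADS scores, and ``truth_<marker>`` columns (diffusivities on
    the 1e-3 mm^2/s scale of the source tables).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if endpoint not in ("stage", "grade"):
        raise ValueError("endpoint must be 'stage' or 'grade'")
    if not 0 <= latent_rho < 1:
        raise ValueError("latent_rho must lie in [0, 1)")
    if set(dist_pos.markers) != set(dist_neg.markers):
        raise ValueError("both groups must define the same markers")

    rows = []
    marker_names = list(dist_pos.markers)
    signs = {
        m: 1.0 if dist_pos.markers[m][0] >= dist_neg.markers[m][0] else -1.0
        for m in marker_names
    }
    for dist, is_pos in ((dist_neg, False), (dist_pos, True)):
        z = rng.standard_normal(dist.n)
        block = {}
        for m in marker_names:
            mean, sd = dist.markers[m]
            lower = MARKER_LOWER_BOUNDS.get(m, -np.inf)
            if latent_rho == 0:
                vals = _truncated_normal(rng, mean, sd, lower, dist.n)
            else:
                eps = _truncated_normal(rng, 0.0, 1.0, -np.inf, dist.n)
                vals = mean + sd * (latent_rho * signs[m] * z
                                    + np.sqrt(1 - latent_rho**2) * eps)
                bad = vals < lower
                while bad.any():  # resample only the independent component
                    eps = rng.standard_normal(int(bad.sum()))
                    vals[bad] = (mean + sd * (latent_rho * signs[m] * z[bad]
                                              + np.sqrt(1 - latent_rho**2) * eps))
                    bad = vals < lower
            block[m] = vals
        for i in range(dist.n):
            rows.append({"positive": is_pos, "class_label": dist.label,
                         **{f"truth_{m}": block[m][i] for m in marker_names}})

    df = pd.DataFrame(rows)
    if endpoint == "stage":
        df["stage"] = df["class_label"]
        p_high = np.where(df["positive"], _P_HIGH_GIVEN_MIBC, _P_HIGH_GIVEN_NMIBC)
        df["grade"] = np.where(rng.random(len(df)) < p_high, "high", "low")
        invasive = df["stage"].to_numpy() == "MIBC"
    else:
        df["grade"] = df["class_label"]
        p_mibc = np.where(df["positive"], _P_MIBC_GIVEN_HIGH, _P_MIBC_GIVEN_LOW)
        df["stage"] = np.where(rng.random(len(df)) < p_mibc, "MIBC", "NMIBC")
        invasive = df["stage"].to_numpy() == "MIBC"

    r1, r2 = simulate_reader_scores(invasive, reader_model, rng)
    df["reader1_virads"] = r1
    df["reader2_virads"] = r2
    df.insert(0, "patient_id", [f"P{i + 1:03d}" for i in range(len(df))])
    cols = (["patient_id", "stage", "grade", "reader1_virads", "reader2_virads"]
            + [f"truth_{m}" for m in marker_names])
    return df[cols].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Image-level phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise model of one synthetic lesion volume.

    The grid mimics the clinical acquisition (coarse in-plane pelvic DWI,
    4 mm slices); lesions are ellipsoids of at least 10 mm diameter, per the
    study's inclusion rule.  ``field_cv`` is the intra-tumor spatial
    coefficient of variation of the MD/MK ground-truth fields;
    ``smoothness_mm`` their correlation length.  ``sigma`` is the Rician noise
    level per excitation, in the same arbitrary units as ``s0``.
    """

    shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (3.125, 3.125, 4.0)  # mm
    center_mm: tuple[float, float, float] | None = None
    semi_axes_mm: tuple[float, float, float] = (10.0, 10.0, 8.0)
    field_cv: float = 0.25
    smoothness_mm: float = 6.0
    two_compartment: tuple[float, float] | None = None  # (fraction, relative offset)
    s0: float = 100.0
    sigma: float = 2.0
    scheme: BValueScheme = field(default_factory=BValueScheme.default)

    def __post_init__(self) -> None:
        if min(self.semi_axes_mm) < 5.0:
            raise ValueError("lesion semi-axes must be >= 5 mm (>=10 mm diameter)")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.field_cv < 0:
            raise ValueError("field_cv must be nonnegative")
        center = self.center_mm
        if center is None:
            center = tuple((n - 1) / 2 * d for n, d in zip(self.shape, self.spacing))
            object.__setattr__(self, "center_mm", center)
        extents = tuple(n * d for n, d in zip(self.shape, self.spacing))
        for c, a, e in zip(center, self.semi_axes_mm, extents):
            if c - a < 0 or c + a > e:
                raise ValueError(
                    f"lesion (center {center} mm, semi-axes {self.semi_axes_mm} mm) "
                    f"does not fit inside the {extents} mm grid"
                )


def _ellipsoid_mask(spec: PhantomSpec) -> np.ndarray:
    coords = [np.arange(n) * d for n, d in zip(spec.shape, spec.spacing)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    cx, cy, cz = spec.center_mm
    ax, ay, az = spec.semi_axes_mm
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0


def _grf(spec: PhantomSpec, mean: float, sd: float, rng: np.random.Generator,
         mask: np.ndarray, floor: float) -> np.ndarray:
    """Smooth random field with the requested mean/SD inside the mask."""
    field3d = rng.standard_normal(spec.shape)
    sig_vox = [spec.smoothness_mm / d for d in spec.spacing]
    field3d = gaussian_filter(field3d, sig_vox)
    if sd > 0:
        inside = field3d[mask]
        std = inside.std()
        if std < 1e-12:
            field3d = np.zeros_like(field3d)
        else:
            field3d = (field3d - inside.mean()) / std
        out = mean + sd * field3d
    else:
        out = np.full(spec.shape, mean)
    return np.maximum(out, floor)


def make_truth_fields(
    spec: PhantomSpec,
    md_mean: float,
    mk_mean: float,
    seed: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Build ground-truth MD/MK/S0 volumes and the lesion mask.

    ``md_mean`` is in mm^2/s (not the 1e-3 table scale).  With
    ``spec.two_compartment = (f, delta)`` the lesion is split into two
    compartments along its first axis, a fraction ``f`` at ``mean*(1-delta)``
    and the rest at ``mean*(1+delta)``, instead of a smooth random field.
    Returns ``{"md", "mk", "s0", "mask"}``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = _ellipsoid_mask(spec)
    if spec.two_compartment is not None:
        frac, delta = spec.two_compartment
        if not 0 < frac < 1:
            raise ValueError("compartment fraction must lie in (0, 1)")
        md = np.full(spec.shape, md_mean)
        mk = np.full(spec.shape, mk_mean)
        idx = np.argwhere(mask)
        cut = idx[:, 0] < np.quantile(idx[:, 0], frac)
        lo_vox = tuple(idx[cut].T)
        hi_vox = tuple(idx[~cut].T)
        md[lo_vox] = md_mean * (1 - delta)
        md[hi_vox] = md_mean * (1 + delta)
        mk[lo_vox] = mk_mean * (1 - delta)
        mk[hi_vox] = mk_mean * (1 + delta)
        md = np.maximum(md, 1e-5)
        mk = np.clip(mk, 0.0, None)
    else:
        md = _grf(spec, md_mean, spec.field_cv * md_mean, rng, mask, floor=1e-5)
        mk = _grf(spec, mk_mean, spec.field_cv * mk_mean, rng, mask, floor=0.0)
    s0 = np.full(spec.shape, spec.s0)
    return {"md": md, "mk": mk, "s0": s0, "mask": mask}


def simulate_dwi(
    truth: Mapping[str, np.ndarray],
    scheme: BValueScheme,
    sigma: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Forward-simulate a 4D multi-b DWI volume with Rician noise.

    For each voxel, b value and excitation, the noiseless DKI signal receives
    independent complex Gaussian noise of SD ``sigma`` per channel and the
    magnitude is taken; the NEX magnitudes are then averaged, matching how
    scanners average repeated excitations.  ``sigma=0`` returns the exact
    noiseless forward model.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    md, mk, s0 = (np.asarray(truth[k], dtype=float) for k in ("md", "mk", "s0"))
    b = scheme.b
    clean = s0[..., None] * np.exp(
        -b * md[..., None] + b**2 * md[..., None] ** 2 * mk[..., None] / 6.0
    )
    if sigma == 0:
        return clean
    out = np.empty_like(clean)
    for i, (_, nex) in enumerate(scheme.entries):
        acc = np.zeros(clean.shape[:-1])
        for _ in range(int(nex)):
            re = clean[..., i] + rng.normal(0.0, sigma, clean.shape[:-1])
            im = rng.normal(0.0, sigma, clean.shape[:-1])
            acc += np.hypot(re, im)
        out[..., i] = acc / nex
    return out
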