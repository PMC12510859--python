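"""Synthetic phantoms and cohorts with the statistical structure the
analysis assumes.

No public imaging cohort exists for this problem, so every downstream stage
is exercised on generated data built to carry the effects the method is
meant to detect:

* paired CT volumes where — only in affected (RP+) subjects — the
  mid-treatment scan gains extra spatially correlated texture confined to
  named dose zones (strongest, by default, in the 50-55 Gy zone);
* a radially decreasing dose grid around a spherical target inside a
  two-ellipsoid lung, yielding the nine dose-gradient zones as nested
  shells;
* a clinical/hematology cohort where pneumonitis odds depend on tumor
  location and the week-4 neutrophil-to-lymphocyte ratio is shifted upward
  in affected subjects.

Generation is a pure function of (spec, seed): identical inputs give
identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from scipy.special import expit, logit

from .geometry import DEFAULT_LABELS, DoseZoneScheme, build_dose_zone_rois
from .volumes import ImageVolume, ROIMask

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "generate_phantom_pair",
    "generate_cohort_table",
    "split_cohort",
    "TIMEPOINTS",
    "COUNT_COLUMNS",
]

TIMEPOINTS = ("base", "1w", "2w", "3w", "4w", "5w")
COUNT_COLUMNS = tuple(
    f"{m}_{tp}" for m in ("N", "L", "M", "P") for tp in TIMEPOINTS
)

# weekly multiplicative trends of blood counts during radiotherapy
# (counts fall, lymphocytes fastest)
_TREND = {
    "N": (1.00, 0.90, 0.75, 0.80, 0.75, 0.80),
    "L": (1.00, 0.72, 0.56, 0.47, 0.42, 0.38),
    "M": (1.00, 0.95, 0.80, 0.70, 0.75, 0.70),
    "P": (1.00, 0.82, 0.77, 0.72, 0.70, 0.72),
}

_DEFAULT_MARKER_BASELINES = {
    # (mu, sigma) of log count; medians near observed mid-treatment cohorts
    "N": (1.335, 0.40),
    "L": (0.470, 0.35),
    "M": (-0.700, 0.40),
    "P": (5.470, 0.35),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise model for one synthetic subject's image set.

    ``texture_effect`` maps dose-zone labels to the multiplicative increase
    of local intensity variance injected into the resetting scan of affected
    subjects; an empty map disables the injection entirely.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 3.0)
    lung_geometry: tuple[tuple[tuple[float, float, float], tuple[float, float, float]], ...] = (
        ((-40.0, 0.0, 0.0), (26.0, 42.0, 54.0)),
        ((40.0, 0.0, 0.0), (26.0, 42.0, 54.0)),
    )
    target_center_mm: tuple[float, float, float] = (-40.0, 0.0, 0.0)
    target_radius_mm: float = 10.0
    dose_max_Gy: float = 60.0
    dose_falloff_mm: float = 7.0
    noise_sigma: float = 20.0
    texture_sigma: float = 60.0
    texture_corr_voxels: float = 3.0
    texture_effect: dict[str, float] = field(
        default_factory=lambda: {"50-55": 2.0}
    )
    rp_probability: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_radius_mm <= 0 or any(
            r <= 0 for _, radii in self.lung_geometry for r in radii
        ):
            raise ValueError("all radii must be positive")
        if not 0 < self.rp_probability < 1:
            raise ValueError("rp_probability must lie in (0, 1)")
        if self.dose_max_Gy <= 0:
            raise ValueError("dose_max_Gy must be positive")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        unknown = set(self.texture_effect) - set(DEFAULT_LABELS)
        if unknown:
            raise ValueError(f"texture_effect names unknown zones: {sorted(unknown)}")


@dataclass(frozen=True)
class CohortSpec:
    """Sampling model for the clinical/hematology table.

    ``location_effect`` is the odds multiplier of pneumonitis for
    middle/lower tumors; ``nlr4w_effect`` the additive shift of the week-4
    neutrophil-to-lymphocyte ratio in affected subjects.
    """

    n_subjects: int = 161
    train_fraction: float = 0.7
    rp_probability: float = 0.30
    location_effect: float = 8.0
    nlr4w_effect: float = 2.0
    p_middle_lower: float = 0.45
    marker_baselines: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_MARKER_BASELINES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_subjects < 20:
            raise ValueError("need at least 20 subjects")
        if not 0 < self.rp_probability < 1:
            raise ValueError("rp_probability must lie in (0, 1)")
        if self.location_effect <= 0 or self.nlr4w_effect < 0:
            raise ValueError("effects must be positive (nlr4w_effect >= 0)")


def _subject_rng(seed: int, subject_id) -> np.random.Generator:
    tag = zlib.crc32(str(subject_id).encode())
    return np.random.default_rng([seed & 0x7FFFFFFF, tag])


def _grid_coords(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple]:
    shape = spec.grid_shape
    spacing = spec.spacing_mm
    origin = tuple(-(n - 1) * s / 2.0 for n, s in zip(shape, spacing))
    axes = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    return (*np.meshgrid(*axes, indexing="ij"), origin)


def _ellipsoid(x, y, z, center, radii) -> np.ndarray:
    return (
        ((x - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((z - center[2]) / radii[2]) ** 2
    ) <= 1.0


def generate_phantom_pair(
    spec: PhantomSpec,
    subject_id,
    rp_label: int,
) -> tuple[ImageVolume, ImageVolume, ImageVolume, ROIMask, ROIMask]:
    """Generate (CT1, CT2, dose, lung mask, PTV mask) for one subject.

    The resetting scan CT2 equals CT1 plus fresh acquisition noise; iff
    ``rp_label`` is 1, zones named in ``texture_effect`` additionally gain a
    Gaussian-correlated field scaled so the local intensity variance of CT2
    in that zone is about ``factor`` times that of CT1.  The mean intensity
    is untouched, so the injected change is visible to variance/texture
    features only.
    """
    if rp_label not in (0, 1):
        raise ValueError("rp_label must be 0 or 1")
    x, y, z, origin = _grid_coords(spec)
    spacing = spec.spacing_mm

    lung = np.zeros(spec.grid_shape, dtype=bool)
    for center, radii in spec.lung_geometry:
        lung |= _ellipsoid(x, y, z, center, radii)
    tc = spec.target_center_mm
    r = np.sqrt((x - tc[0]) ** 2 + (y - tc[1]) ** 2 + (z - tc[2]) ** 2)
    ptv = r <= spec.target_radius_mm
    if not ptv.any():
        raise ValueError("target sphere lies outside the image grid")
    if not (ptv & lung).any():
        raise ValueError("target sphere does not intersect the lung")

    # radially symmetric sigmoid dose fall-off around the target
    r50 = spec.target_radius_mm + 18.0
    dose = spec.dose_max_Gy * expit(-(r - r50) / spec.dose_falloff_mm)

    rng = _subject_rng(spec.seed, subject_id)
    anatomy = np.full(spec.grid_shape, 40.0)
    # heterogeneous parenchyma: correlated HU texture around the lung base
    parenchyma = ndimage.gaussian_filter(
        rng.normal(0.0, 1.0, spec.grid_shape), sigma=spec.texture_corr_voxels
    )
    parenchyma /= parenchyma.std()
    anatomy[lung] = -700.0 + spec.texture_sigma * parenchyma[lung]
    anatomy[ptv] = 0.0
    ct1 = anatomy + rng.normal(0.0, spec.noise_sigma, spec.grid_shape)
    diff = rng.normal(0.0, spec.noise_sigma, spec.grid_shape)

    if rp_label == 1 and spec.texture_effect:
        lung_mask = ROIMask(lung, spacing, origin)
        dose_vol = ImageVolume(dose, spacing, origin)
        zones, _ = build_dose_zone_rois(dose_vol, lung_mask, DoseZoneScheme())
        by_label = {zn.zone_label: zn for zn in zones}
        for label, factor in spec.texture_effect.items():
            if factor < 1.0:
                raise ValueError("texture_effect factors must be >= 1")
            zone = by_label.get(label)
            if zone is None or factor == 1.0:
                continue
            raw = rng.normal(0.0, 1.0, spec.grid_shape)
            fieldv = ndimage.gaussian_filter(raw, sigma=2.0)
            fieldv /= fieldv.std()
            # the multiplier applies to the zone's local intensity variance:
            # scale the injected field so Var(CT2) ~ factor * Var(CT1) there
            local_var = float(ct1[zone.data].var())
            scale = np.sqrt((factor - 1.0) * local_var)
            diff = diff + zone.data * fieldv * scale

    ct2 = ct1 + diff
    return (
        ImageVolume(ct1, spacing, origin),
        ImageVolume(ct2, spacing, origin),
        ImageVolume(dose, spacing, origin),
        ROIMask(lung, spacing, origin),
        ROIMask(ptv, spacing, origin, zone_label="PTV"),
    )


def _solve_intercept(spec: CohortSpec) -> float:
    """Intercept making the marginal pneumonitis rate equal rp_probability
    under the location mixture and the latent-severity term."""
    beta_loc = np.log(spec.location_effect)
    # Gauss-Hermite quadrature over the latent severity (sd 0.5)
    nodes, weights = np.polynomial.hermite_e.hermegauss(21)
    weights = weights / weights.sum()
    sev = 0.5 * nodes

    def marginal(alpha: float) -> float:
        p_up = np.sum(weights * expit(alpha + sev))
        p_ml = np.sum(weights * expit(alpha + beta_loc + sev))
        return (1 - spec.p_middle_lower) * p_up + spec.p_middle_lower * p_ml

    return float(
        optimize.brentq(lambda a: marginal(a) - spec.rp_probability, -20.0, 20.0)
    )


def generate_cohort_table(spec: CohortSpec) -> pd.DataFrame:
    """Sample the per-subject outcome, covariates and longitudinal blood
    counts (N, L, M, P at baseline and weeks 1-5).

    Pneumonitis is drawn from a logistic model with a tumor-location effect
    and a latent severity term; counts are log-normal with falling weekly
    trends; in affected subjects the week-4 neutrophil count is raised so
    the week-4 NLR shifts additively by ``nlr4w_effect``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    alpha = _solve_intercept(spec)
    beta_loc = np.log(spec.location_effect)

    middle_lower = rng.random(n) < spec.p_middle_lower
    severity = rng.normal(0.0, 0.5, n)
    p_rp = expit(alpha + beta_loc * middle_lower + severity)
    rp = (rng.random(n) < p_rp).astype(int)
    comorbidity = (rng.random(n) < 0.30).astype(int)

    counts: dict[str, np.ndarray] = {}
    for m, (mu, sigma) in spec.marker_baselines.items():
        base_log = rng.normal(mu, sigma, n)
        for k, tp in enumerate(TIMEPOINTS):
            jitter = rng.normal(0.0, 0.15, n) if tp != "base" else 0.0
            counts[f"{m}_{tp}"] = np.exp(
                base_log + np.log(_TREND[m][k]) + jitter
            )
    # additive week-4 NLR shift in affected subjects: N4w += effect * L4w
    counts["N_4w"] = counts["N_4w"] + spec.nlr4w_effect * counts["L_4w"] * rp

    table = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "rp": rp,
            "location": np.where(middle_lower, "middle_lower", "upper"),
            "comorbidity": comorbidity,
            **{c: counts[c] for c in COUNT_COLUMNS},
        }
    )
    train_ids, _ = split_cohort(table, spec.train_fraction, spec.seed)
    table.insert(
        1, "set",
        np.where(table["subject_id"].isin(train_ids), "train", "valid"),
    )
    return table


def split_cohort(
    table: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Random, unstratified split into training and validation subject ids;
    training size is floor(n * fraction)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    if len(table) == 0:
        raise ValueError("empty cohort table")
    ids = list(table["subject_id"])
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(np.floor(len(ids) * train_fraction))
    train = sorted(ids[i] for i in order[:n_train])
    valid = sorted(ids[i] for i in order[n_train:])
    return train, valid
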