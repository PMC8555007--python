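"""Synthetic 4D DCE breast phantoms with known ground truth.

The phantom emulates a fat-suppressed dynamic breast acquisition: an
ellipsoidal breast in an air background, a thin skin rind, adipose interior,
a fibroglandular (FGT) blob, and an enhancing ellipsoidal tumour.  Each
tissue follows a piecewise-linear time-intensity curve fully parameterised
by its baseline signal S0, initial enhancement E1 (percent) and signal
enhancement ratio SER: the signal rises linearly from S0 to
S1 = S0 (1 + E1/100) over the first dynamic interval and then runs linearly
to Slast = S0 + (S1 - S0)/SER (washout SER > 1, plateau SER = 1, persistent
SER < 1; flat tissues stay at S0).  Voxels within a few morphological steps
of the tumour receive an outward-decaying share of the tumour's enhancement
(decay^d at shell distance d), reproducing the peri-tumoural enhancement
gradient.  Additive Gaussian noise (optionally Rician) is applied last and
clipped at zero.

Ground truth — tissue masks, noiseless generating curves, and the kinetic
parameters/concentrations implied by them — is returned alongside the
series, so segmentation accuracy and parameter recovery are measurable
exactly.  A cohort generator draws per-subject tumour curves from
grade-specific distributions, emulating a 12-low vs 44-high-grade design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .io_dce import DceSeries, VolumeMask
from .pharmacokinetics import (
    ConcentrationCurve,
    KineticParams,
    ReferenceCalibration,
    TimeIntensityCurve,
    concentration_curve,
    kinetic_params,
)

#: Minimum tumour diameter, voxels-as-mm (cohort inclusion used > 7 mm).
MIN_TUMOUR_DIAMETER = 7.0


# ---------------------------------------------------------------------------
# tissue curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueCurve:
    """Piecewise-linear generating curve of one tissue."""

    s0: float
    e1: float = 0.0            # percent initial enhancement
    ser: float = 1.0           # signal enhancement ratio
    curve_type: str = "flat"   # flat | persistent | plateau | washout

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ValidationError("tissue S0 must be positive")
        if self.curve_type not in ("flat", "persistent", "plateau", "washout"):
            raise ValidationError(f"unknown curve type {self.curve_type!r}")

    def values(self, n_timepoints: int) -> np.ndarray:
        """Signal at frames 0..n-1 (frame 0 pre-contrast)."""
        s = np.full(n_timepoints, self.s0, dtype=float)
        if self.curve_type == "flat" or n_timepoints < 2:
            return s
        s1 = self.s0 * (1.0 + self.e1 / 100.0)
        s[1] = s1
        if n_timepoints > 2:
            ser = 1.0 if self.curve_type == "plateau" else self.ser
            s_last = self.s0 + (s1 - self.s0) / ser
            s[1:] = np.linspace(s1, s_last, n_timepoints - 1)
        return s


def _default_tissues() -> dict[str, TissueCurve]:
    return {
        "air": TissueCurve(s0=2.0, curve_type="flat"),
        "skin": TissueCurve(s0=200.0, e1=20.0, ser=0.8, curve_type="persistent"),
        "adipose": TissueCurve(s0=100.0, curve_type="flat"),
        "fgt": TissueCurve(s0=220.0, e1=30.0, ser=0.7, curve_type="persistent"),
        "tumour": TissueCurve(s0=150.0, e1=150.0, ser=1.1, curve_type="washout"),
    }


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometry, curves and noise of one synthetic subject.

    Centres and semi-axes are in voxel units on the ``(z, y, x)`` grid;
    ellipsoids are rasterised by a centre-of-voxel inclusion test.  The
    defaults describe a 40 x 80 x 80 grid at 1 x 0.96 x 0.96 mm with a
    7-frame dynamic of 58.5 s per frame.
    """

    shape: tuple[int, int, int] = (40, 80, 80)
    voxel_spacing: tuple[float, float, float] = (1.0, 0.96, 0.96)
    frame_duration: float = 58.5
    n_timepoints: int = 7
    breast_centre: tuple[float, float, float] = (20.0, 40.0, 40.0)
    breast_semiaxes: tuple[float, float, float] = (17.0, 32.0, 34.0)
    skin_thickness: float = 2.0
    fgt_centre: tuple[float, float, float] = (20.0, 40.0, 22.0)
    fgt_semiaxes: tuple[float, float, float] = (10.0, 14.0, 14.0)
    tumour_centre: tuple[float, float, float] = (20.0, 40.0, 58.0)
    tumour_semiaxes: tuple[float, float, float] = (6.0, 7.0, 7.0)
    tissues: dict[str, TissueCurve] = field(default_factory=_default_tissues)
    peri_decay: float = 0.5
    n_decay_shells: int = 4
    noise_sd: float = 5.0
    rician: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 2:
            raise ValidationError("phantom needs >= 2 time points")
        if not 0 < self.peri_decay <= 1:
            raise ValidationError("peri_decay must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if 2.0 * min(self.tumour_semiaxes) <= MIN_TUMOUR_DIAMETER:
            raise ValidationError(
                f"tumour diameter must exceed {MIN_TUMOUR_DIAMETER} voxels"
            )


@dataclass
class PhantomTruth:
    """Ground truth of one phantom: masks, generating curves, true kinetics."""

    masks: dict[str, VolumeMask]
    curves: dict[str, TimeIntensityCurve]
    concentrations: dict[str, ConcentrationCurve]
    params: dict[str, KineticParams]
    calibration: ReferenceCalibration


def _ellipsoid(shape, centre, semiaxes) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = centre
    az, ay, ax = semiaxes
    return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _build_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    breast = _ellipsoid(spec.shape, spec.breast_centre, spec.breast_semiaxes)
    inner_axes = tuple(a - spec.skin_thickness for a in spec.breast_semiaxes)
    if min(inner_axes) <= 0:
        raise ValidationError("skin thicker than the breast")
    inner = _ellipsoid(spec.shape, spec.breast_centre, inner_axes)
    skin = breast & ~inner
    fgt = _ellipsoid(spec.shape, spec.fgt_centre, spec.fgt_semiaxes)
    tumour = _ellipsoid(spec.shape, spec.tumour_centre, spec.tumour_semiaxes)
    if not tumour.any():
        raise ValidationError("tumour rasterised to an empty mask")
    if np.any(tumour & ~inner):
        raise ValidationError("tumour must lie inside the breast")
    if np.any(tumour & fgt):
        raise ValidationError("tumour overlaps the FGT blob")
    fgt &= inner
    adipose = inner & ~fgt & ~tumour
    air = ~breast
    return {"air": air, "skin": skin, "adipose": adipose, "fgt": fgt, "tumour": tumour}


def _shell_distance(tumour: np.ndarray, n_shells: int) -> np.ndarray:
    """Morphological (6-connected) step distance from the tumour, capped."""
    dist = np.full(tumour.shape, np.iinfo(np.int32).max, dtype=np.int32)
    dist[tumour] = 0
    structure = ndimage.generate_binary_structure(3, 1)
    prev = tumour
    for d in range(1, n_shells + 1):
        cur = ndimage.binary_dilation(prev, structure=structure)
        dist[cur & ~prev] = d
        prev = cur
    return dist


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def phantom_truth(spec: PhantomSpec, masks: dict[str, np.ndarray] | None = None) -> PhantomTruth:
    """Ground truth (masks, noiseless curves, true kinetics) of a spec.

    Computable without rasterising the 4D series; used by both
    :func:`generate_phantom` and curve-level cohort simulations.
    """
    masks = masks if masks is not None else _build_masks(spec)
    times = np.arange(spec.n_timepoints) * spec.frame_duration / 60.0
    vmasks = {
        name: VolumeMask(grid, label=name, spacing=spec.voxel_spacing,
                         provenance={"op": "phantom_truth"})
        for name, grid in masks.items()
    }
    calib = ReferenceCalibration(s0_ref=spec.tissues["adipose"].s0)
    curves: dict[str, TimeIntensityCurve] = {}
    for name in ("tumour", "fgt", "adipose", "skin"):
        curves[name] = TimeIntensityCurve(
            region=name, s=spec.tissues[name].values(spec.n_timepoints),
            times=times, n_voxels=max(1, int(masks[name].sum())),
        )
    # true mean curve of shell d: adipose baseline + decay^d tumour enhancement
    tum = spec.tissues["tumour"].values(spec.n_timepoints)
    adi = spec.tissues["adipose"].values(spec.n_timepoints)
    for d in range(1, spec.n_decay_shells + 1):
        curves[f"shell{d}"] = TimeIntensityCurve(
            region=f"shell{d}", s=adi + spec.peri_decay ** d * (tum - tum[0]),
            times=times, n_voxels=1,
        )
    concentrations = {n: concentration_curve(t, calib) for n, t in curves.items()}
    params = {n: kinetic_params(curves[n], concentrations[n])
              for n in curves if curves[n].s.std() > 0}
    return PhantomTruth(masks=vmasks, curves=curves, concentrations=concentrations,
                        params=params, calibration=calib)


def generate_phantom(spec: PhantomSpec) -> tuple[DceSeries, PhantomTruth]:
    """Rasterise the 4D dynamic series and its ground truth.

    Deterministic given ``spec.seed``; two seeds differ only in noise, never
    in the truth masks or generating curves.
    """
    masks = _build_masks(spec)
    truth = phantom_truth(spec, masks)
    nt = spec.n_timepoints
    data = np.zeros((nt,) + tuple(spec.shape), dtype=float)
    for name, grid in masks.items():
        vals = spec.tissues[name].values(nt)
        for t in range(nt):
            data[t][grid] += vals[t]
    # peri-tumoural enhancement gradient on non-tumour voxels near the tumour
    tum = spec.tissues["tumour"].values(nt)
    dist = _shell_distance(masks["tumour"], spec.n_decay_shells)
    for d in range(1, spec.n_decay_shells + 1):
        ring = dist == d
        if not ring.any():
            continue
        for t in range(nt):
            data[t][ring] += spec.peri_decay ** d * (tum[t] - tum[0])
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        if spec.rician:
            n1 = rng.normal(0.0, spec.noise_sd, data.shape)
            n2 = rng.normal(0.0, spec.noise_sd, data.shape)
            data = np.sqrt((data + n1) ** 2 + n2 ** 2)
        else:
            data = data + rng.normal(0.0, spec.noise_sd, data.shape)
    np.clip(data, 0.0, None, out=data)
    series = DceSeries(data, voxel_spacing=spec.voxel_spacing,
                       frame_duration=spec.frame_duration, pre_contrast_index=0)
    return series, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortEffect:
    """Grade-specific distributions of the subject-level target quantity.

    The target is the true first-post-contrast tumour concentration
    (mmol/L); per-subject tumour E1 is back-computed so the generating curve
    realises the drawn concentration.  Defaults mirror the published cohort
    summaries (low grade 2.47 +- 1.61, high grade 4.15 +- 1.86 mmol/L).
    """

    mean_low: float = 2.47
    sd_low: float = 1.61
    mean_high: float = 4.15
    sd_high: float = 1.86

    @classmethod
    def from_cohens_d(cls, d: float, mean_low: float = 2.47, sd: float = 1.6) -> "CohortEffect":
        """Equal-SD effect with standardised mean difference ``d``."""
        return cls(mean_low=mean_low, sd_low=sd, mean_high=mean_low + d * sd, sd_high=sd)

    @classmethod
    def null(cls, mean: float = 2.47, sd: float = 1.6) -> "CohortEffect":
        return cls(mean_low=mean, sd_low=sd, mean_high=mean, sd_high=sd)


@dataclass
class CohortSubject:
    spec: PhantomSpec
    high_grade: bool
    true_tp2_concentration: float


@dataclass
class Cohort:
    subjects: list[CohortSubject]

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.high_grade for s in self.subjects])

    @property
    def true_concentrations(self) -> np.ndarray:
        return np.array([s.true_tp2_concentration for s in self.subjects])


#: Lower truncation of drawn concentrations, mmol/L (keeps E1 physical).
_MIN_CONCENTRATION = 0.2


def _e1_for_concentration(c: float, base: PhantomSpec) -> float:
    """Tumour E1 (%) whose generating curve yields concentration ``c`` at tp2."""
    calib = ReferenceCalibration(s0_ref=base.tissues["adipose"].s0)
    delta_s1 = c * calib.r1 * calib.t1_ref * calib.s0_ref
    return 100.0 * delta_s1 / base.tissues["tumour"].s0


def generate_cohort(
    n_low: int = 12,
    n_high: int = 44,
    effect: CohortEffect | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> Cohort:
    """Draw a two-grade cohort of phantom specs with known truth.

    Per-subject first-post-contrast tumour concentrations come from the
    grade-specific normal distributions in ``effect`` (truncated below 0.2
    mmol/L by redrawing); each subject's spec realises its drawn value
    exactly in the noiseless generating curve.  Labels and draws are
    reproducible per seed.
    """
    if n_low < 1 or n_high < 1:
        raise ValidationError("cohort needs n >= 1 per group")
    effect = effect or CohortEffect()
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    subjects: list[CohortSubject] = []
    groups = [(False, n_low, effect.mean_low, effect.sd_low),
              (True, n_high, effect.mean_high, effect.sd_high)]
    for high, n, mean, sd in groups:
        for _ in range(n):
            c = rng.normal(mean, sd)
            while c < _MIN_CONCENTRATION:
                c = rng.normal(mean, sd)
            tissues = dict(base.tissues)
            tissues["tumour"] = replace(base.tissues["tumour"],
                                        e1=_e1_for_concentration(c, base))
            spec = replace(base, tissues=tissues,
                           seed=int(rng.integers(0, 2**31 - 1)))
            subjects.append(CohortSubject(spec=spec, high_grade=high,
                                          true_tp2_concentration=float(c)))
    return Cohort(subjects=subjects)
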