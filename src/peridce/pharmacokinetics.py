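"""Region-mean kinetics: time-intensity curves, reference-tissue
concentrations, and the semi-quantitative parameters E1, Epeak, SER, AUC.

Signal is converted to contrast-agent concentration with a reference-tissue
model: the change in signal is normalised by the reference tissue's
pre-contrast signal and its literature baseline T1, scaled by the contrast
agent relaxivity,

    C(t) = (S(t) - S(0)) / (r1 * T1_ref * S0_ref)   [mmol/L],

with r1 in mM^-1 s^-1 and T1_ref in seconds.  Breast adipose tissue serves
as the reference (T1 = 366 ms at 3 T, r1 = 3.43 mM^-1 s^-1).

Kinetic parameters from the region-mean curve S with pre-contrast value S0,
first post-contrast S1, peak Speak and final Slast:

    E1    = 100% * (S1 - S0) / S0          initial percentage enhancement
    Epeak = 100% * (Speak - S0) / S0       peak percentage enhancement
    SER   = (S1 - S0) / (Slast - S0)       signal enhancement ratio

SER > 1 indicates washout, < 1 persistent enhancement.  AUC is the
trapezoidal integral of the concentration curve over time (mmol/L x min).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PeridceError, ValidationError
from .io_dce import DceSeries, RoiBox, VolumeMask, crop, deinterleave
from .segmentation import SegmentationConfig, segment_adipose, segment_fgt, segment_tumour
from .shells import ShellSet, make_shells, shell_report

#: Contrast agent relaxivity at 3 T, mM^-1 s^-1.
DEFAULT_R1 = 3.43
#: Adipose-tissue baseline T1 at 3 T, seconds (366 ms, literature value).
DEFAULT_T1_REF_S = 0.366


@dataclass
class TimeIntensityCurve:
    """Region-mean signal per dynamic frame."""

    region: str
    s: np.ndarray
    times: np.ndarray          # minutes from the pre-contrast frame start
    n_voxels: int
    pre_contrast_index: int = 0

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.s.size != self.times.size:
            raise ValidationError("curve and time axes differ in length")
        if self.s.size < 2:
            raise ValidationError("a curve needs at least 2 time points")
        if self.n_voxels <= 0:
            raise ValidationError("n_voxels must be positive")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")


@dataclass
class ReferenceCalibration:
    """Constants of the reference-tissue concentration model."""

    s0_ref: float
    r1: float = DEFAULT_R1
    t1_ref: float = DEFAULT_T1_REF_S   # seconds

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.t1_ref <= 0:
            raise ValidationError("r1 and t1_ref must be positive")
        if self.s0_ref <= 0:
            raise ValidationError("reference pre-contrast signal must be positive")

    @classmethod
    def from_ms(cls, s0_ref: float, r1: float = DEFAULT_R1, t1_ref_ms: float = 366.0):
        """Build a calibration with the reference T1 given in milliseconds."""
        return cls(s0_ref=s0_ref, r1=r1, t1_ref=t1_ref_ms / 1000.0)


@dataclass
class ConcentrationCurve:
    """Contrast-agent concentration (mmol/L) per dynamic frame."""

    region: str
    c: np.ndarray
    times: np.ndarray
    calibration: ReferenceCalibration
    pre_contrast_index: int = 0

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if not np.all(np.isfinite(self.c)):
            raise ValidationError("concentrations must be finite")


@dataclass
class KineticParams:
    """Semi-quantitative kinetic parameters of one region."""

    region: str
    e1: float                  # percent
    e_peak: float              # percent
    ser: float | None          # dimensionless; None when Slast == S0
    auc: float                 # mmol/L x min
    ser_defined: bool = True


# ---------------------------------------------------------------------------
# curve extraction
# ---------------------------------------------------------------------------

def mean_intensity_curve(series: DceSeries, mask: VolumeMask) -> TimeIntensityCurve:
    """Arithmetic mean of the *unmodified* intensities under the mask, per frame."""
    if mask.grid.shape != series.spatial_shape:
        raise ValidationError(
            f"mask shape {mask.grid.shape} does not match series {series.spatial_shape}"
        )
    if not mask.grid.any():
        raise PeridceError(f"mean_intensity_curve: mask '{mask.label}' is empty")
    voxels = series.data[:, mask.grid].astype(float)
    return TimeIntensityCurve(
        region=mask.label,
        s=voxels.mean(axis=1),
        times=series.times_minutes,
        n_voxels=mask.n_voxels,
        pre_contrast_index=series.pre_contrast_index,
    )


def concentration_curve(tic: TimeIntensityCurve, calib: ReferenceCalibration) -> ConcentrationCurve:
    """Reference-tissue concentration transform of a time-intensity curve."""
    s0 = tic.s[tic.pre_contrast_index]
    c = (tic.s - s0) / (calib.r1 * calib.t1_ref * calib.s0_ref)
    return ConcentrationCurve(region=tic.region, c=c, times=tic.times,
                              calibration=calib, pre_contrast_index=tic.pre_contrast_index)


def kinetic_params(tic: TimeIntensityCurve, conc: ConcentrationCurve) -> KineticParams:
    """E1, Epeak, SER from the intensity curve; AUC from the concentration curve.

    Speak is the maximum of the region-mean curve over post-contrast frames.
    SER is undefined (flagged, not zeroed) when Slast equals S0.
    """
    pre = tic.pre_contrast_index
    s0 = tic.s[pre]
    if s0 <= 0:
        raise PeridceError("kinetic_params: pre-contrast signal S0 must be positive")
    post = tic.s[pre + 1:]
    if post.size == 0:
        raise ValidationError("no post-contrast frames after the pre-contrast index")
    s1 = post[0]
    s_peak = post.max()
    s_last = post[-1]
    e1 = 100.0 * (s1 - s0) / s0
    e_peak = 100.0 * (s_peak - s0) / s0
    if np.isclose(s_last, s0):
        ser, defined = None, False
    else:
        ser, defined = float((s1 - s0) / (s_last - s0)), True
    auc = float(np.trapezoid(conc.c[pre:], conc.times[pre:]))
    return KineticParams(region=tic.region, e1=float(e1), e_peak=float(e_peak),
                         ser=ser, auc=auc, ser_defined=defined)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Everything one subject's run produces."""

    curves: dict[str, TimeIntensityCurve]
    concentrations: dict[str, ConcentrationCurve]
    params: dict[str, KineticParams]
    masks: dict[str, VolumeMask]
    shellset: ShellSet
    calibration: ReferenceCalibration
    provenance: dict

    def table(self) -> pd.DataFrame:
        """Tidy long table: one row per region x parameter."""
        rows = []
        for region, p in self.params.items():
            for name, value in (("E1_pct", p.e1), ("Epeak_pct", p.e_peak),
                                ("SER", p.ser), ("AUC_mmol_per_L_min", p.auc)):
                rows.append({"region": region, "parameter": name, "value": value,
                             "n_voxels": self.curves[region].n_voxels})
        return pd.DataFrame(rows)

    def curve_table(self) -> pd.DataFrame:
        rows = []
        for region, tic in self.curves.items():
            conc = self.concentrations[region]
            for t in range(tic.s.size):
                rows.append({"region": region, "frame": t,
                             "time_min": tic.times[t], "intensity": tic.s[t],
                             "concentration_mmol_per_L": conc.c[t]})
        return pd.DataFrame(rows)


def pipeline_run(
    series: DceSeries,
    tumour_box: RoiBox,
    healthy_box: RoiBox | None = None,
    config: SegmentationConfig | None = None,
    n_shells: int = 4,
    shell_connectivity: int = 6,
    r1: float = DEFAULT_R1,
    t1_ref: float = DEFAULT_T1_REF_S,
    s0_ref: float | None = None,
) -> PipelineResult:
    """Run crop -> segment -> shells -> curves -> concentrations -> kinetics.

    Regions produced: tumour, shells 1..n, and (when a healthy-breast box is
    given) adipose and FGT.  The adipose pre-contrast mean supplies the
    reference signal ``s0_ref`` unless an explicit value is passed.  All
    curves are measured on the unmodified intensities of the relevant crop.
    """
    config = config or SegmentationConfig()
    stage = "crop_tumour"
    try:
        tumour_series = crop(series, tumour_box)
        stage = "segment_tumour"
        volumes = deinterleave(tumour_series)
        tumour_mask, mip_mask = segment_tumour(
            volumes, config, spacing=series.voxel_spacing,
            pre_contrast_index=series.pre_contrast_index,
        )
        stage = "shells"
        shellset = make_shells(tumour_mask, n_shells=n_shells,
                               connectivity=shell_connectivity)

        masks: dict[str, VolumeMask] = {"tumour": tumour_mask}
        for shell in shellset.shells:
            masks[shell.label] = shell

        curves: dict[str, TimeIntensityCurve] = {}
        region_series: dict[str, DceSeries] = {}
        for name, mask in masks.items():
            region_series[name] = tumour_series

        if healthy_box is not None:
            stage = "segment_reference"
            healthy_series = crop(series, healthy_box)
            pre = deinterleave(healthy_series)[series.pre_contrast_index]
            adipose = segment_adipose(pre, config, spacing=series.voxel_spacing)
            fgt = segment_fgt(pre, config, spacing=series.voxel_spacing)
            masks["adipose"] = adipose
            masks["fgt"] = fgt
            region_series["adipose"] = healthy_series
            region_series["fgt"] = healthy_series

        stage = "curves"
        for name, mask in masks.items():
            curves[name] = mean_intensity_curve(region_series[name], mask)

        stage = "calibration"
        if s0_ref is None:
            if "adipose" not in curves:
                raise ValidationError(
                    "pipeline_run needs a healthy-breast box or an explicit s0_ref"
                )
            s0_ref = float(curves["adipose"].s[series.pre_contrast_index])
        calib = ReferenceCalibration(s0_ref=s0_ref, r1=r1, t1_ref=t1_ref)

        stage = "kinetics"
        concentrations = {n: concentration_curve(t, calib) for n, t in curves.items()}
        params = {n: kinetic_params(curves[n], concentrations[n]) for n in curves}
    except Exception as exc:
        raise PeridceError(f"pipeline stage '{stage}' failed: {exc}") from exc

    provenance = {
        "stages": ["crop", "segment", "shells", "curves", "concentration", "kinetics"],
        "config": {k: (list(v) if isinstance(v, (tuple, list)) else v)
                   for k, v in vars(config).items()},
        "calibration": {"r1": calib.r1, "t1_ref_s": calib.t1_ref, "s0_ref": calib.s0_ref},
        "n_shells": n_shells,
        "shell_connectivity": shell_connectivity,
        "shell_clipping": shellset.clipped_voxels,
        "frame_duration_s": series.frame_duration,
        "shell_report": shell_report(shellset).to_dict(orient="records"),
    }
    return PipelineResult(curves=curves, concentrations=concentrations, params=params,
                          masks=masks, shellset=shellset, calibration=calib,
                          provenance=provenance)
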