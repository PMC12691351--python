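"""Synthetic RF phantom cohorts with known scattering ground truth.

The simulator works on a 2-D imaging plane.  A phantom is a cloud of
point scatterers: positions uniform at a configurable areal density,
amplitudes zero-mean Gaussian with variance set by the per-region
acoustic concentration.  Echo formation is linear: each scatterer
contributes a delayed replica of a Gaussian-modulated pulse, shaped in
the frequency domain by the one-way Gaussian form-factor response
``exp(-b_ff * k^2 * a_eff^2)`` and by one-way depth attenuation
``alpha * f * z`` (dB).  A separable Gaussian lateral point-spread
function couples neighbouring lines so that speckle is fully developed.

Because every region's effective scatterer radius, acoustic
concentration and attenuation are known, the downstream spectral
estimators can be validated against ground truth, which is the entire
point of this module.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
import shapely.affinity
from shapely.geometry import Point, Polygon

__all__ = [
    "RegionAcoustics",
    "PhantomSpec",
    "RFFrame",
    "ROISet",
    "ClinicalRecord",
    "ScattererField",
    "PatientData",
    "AcquisitionGeometry",
    "generate_scatterer_field",
    "synthesize_rf_frame",
    "generate_reference_frames",
    "generate_cohort",
    "analytic_bsc",
    "save_cohort",
    "load_cohort",
]

logger = logging.getLogger(__name__)

MARGIN_WIDTH_MM = 5.0  # analysed rim around the tumor core


# ---------------------------------------------------------------------------
# domain types


@dataclass
class RegionAcoustics:
    """Ground-truth scattering parameters of one phantom region."""

    effective_radius_um: float  # a_eff; ASD = 2 * a_eff
    acoustic_concentration_db: float  # AAC on a dB scale

    def __post_init__(self) -> None:
        if self.effective_radius_um <= 0:
            raise ValueError("effective_radius_um must be positive")


@dataclass
class PhantomSpec:
    """Ground truth driving the simulator.

    ``scatterer_density_mm2`` should keep at least ~5 scatterers per
    resolution cell (~0.1 mm^2 for the default pulse and lateral PSF)
    for fully developed speckle; the default of 80 /mm^2 gives ~8.
    ``margin_heterogeneity`` is the log-amplitude of a smooth random
    modulation of the margin's concentration (0 = homogeneous margin).
    """

    regions: dict[str, RegionAcoustics]
    scatterer_density_mm2: float = 80.0
    attenuation_db_cm_mhz: float = 0.0
    margin_heterogeneity: float = 0.0
    heterogeneity_corr_mm: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scatterer_density_mm2 <= 0:
            raise ValueError("scatterer_density_mm2 must be positive")
        if self.attenuation_db_cm_mhz < 0:
            raise ValueError("attenuation_db_cm_mhz must be >= 0")
        if self.margin_heterogeneity < 0:
            raise ValueError("margin_heterogeneity must be >= 0")


@dataclass
class RFFrame:
    """A 2-D RF frame (axial sample index x lateral line) plus geometry.

    Axial sample ``n`` maps to depth ``z = n * c / (2 * fs)`` (pulse-echo
    convention); lateral line ``m`` to ``x = m * pitch``.
    """

    samples: np.ndarray
    fs_axial_mhz: float = 40.0
    lateral_pitch_mm: float = 0.12
    fc_mhz: float = 6.5
    band_mhz: tuple[float, float] = (3.0, 8.0)
    sound_speed_m_s: float = 1540.0
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (axial x lateral)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")
        if self.fs_axial_mhz <= 2 * self.band_mhz[1]:
            raise ValueError("fs_axial must exceed twice the band upper edge")
        if self.lateral_pitch_mm <= 0:
            raise ValueError("lateral_pitch_mm must be positive")

    @property
    def n_axial(self) -> int:
        return self.samples.shape[0]

    @property
    def n_lateral(self) -> int:
        return self.samples.shape[1]

    @property
    def axial_step_mm(self) -> float:
        """Depth increment per axial sample in mm."""
        return self.sound_speed_m_s / (2 * self.fs_axial_mhz * 1e6) * 1e3

    @property
    def depth_mm(self) -> float:
        return self.n_axial * self.axial_step_mm

    @property
    def width_mm(self) -> float:
        return self.n_lateral * self.lateral_pitch_mm

    def axial_coords_mm(self) -> np.ndarray:
        return np.arange(self.n_axial) * self.axial_step_mm

    def lateral_coords_mm(self) -> np.ndarray:
        return np.arange(self.n_lateral) * self.lateral_pitch_mm


@dataclass
class ROISet:
    """Tumor core contour and its 5 mm margin ring, in frame mm coordinates.

    x = lateral, y = axial depth (increasing downward), origin top-left.
    """

    core: Polygon
    margin: Polygon = None  # type: ignore[assignment]
    frame_id: str = ""

    def __post_init__(self) -> None:
        if self.core.is_empty or not self.core.is_valid:
            raise ValueError("core polygon is degenerate")
        if self.margin is None:
            self.margin = self.core.buffer(MARGIN_WIDTH_MM).difference(self.core)
        if self.margin.is_empty:
            raise ValueError("margin ring is empty")

    def union(self) -> Polygon:
        return self.core.union(self.margin)

    def masks_on_grid(
        self, x_mm: np.ndarray, y_mm: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Rasterize core and margin onto a grid of (y, x) centers.

        Returns boolean arrays of shape ``(len(y_mm), len(x_mm))``.
        """
        xx, yy = np.meshgrid(x_mm, y_mm)
        core = shapely.contains_xy(self.core, xx.ravel(), yy.ravel())
        marg = shapely.contains_xy(self.margin, xx.ravel(), yy.ravel())
        core = core.reshape(xx.shape)
        marg = marg.reshape(xx.shape) & ~core
        return core, marg


@dataclass
class ClinicalRecord:
    """Patient identifier, Oncotype DX recurrence score and its dichotomy."""

    patient_id: str
    odxrs: int
    label: int = None  # type: ignore[assignment]
    threshold: int = 15

    def __post_init__(self) -> None:
        expected = int(self.odxrs > self.threshold)
        if self.label is None:
            self.label = expected
        elif self.label != expected:
            raise ValueError(
                f"label {self.label} inconsistent with odxrs {self.odxrs} "
                f"at threshold {self.threshold}"
            )


@dataclass
class ScattererField:
    """Point-scatterer cloud: positions (mm), amplitudes, per-scatterer radius."""

    x_mm: np.ndarray
    z_mm: np.ndarray
    amplitude: np.ndarray
    a_eff_um: np.ndarray
    region: np.ndarray  # string labels

    def __len__(self) -> int:
        return len(self.x_mm)


@dataclass
class PatientData:
    frames: list[RFFrame]
    rois: list[ROISet]
    clinical: ClinicalRecord
    ground_truth: PhantomSpec | None = None


# ---------------------------------------------------------------------------
# scatterer field generation


def _smooth_field(
    rng: np.random.Generator, corr_mm: float, n_modes: int = 24
) -> "callable":
    """A smooth, approximately standard-normal random field on the plane.

    Sum of random-direction cosines (random-phase spectral synthesis)
    with wavelengths around ``corr_mm``; amplitude normalized so the
    marginal variance is 1.
    """
    theta = rng.uniform(0, 2 * np.pi, n_modes)
    k = 2 * np.pi / (corr_mm * rng.lognormal(0.0, 0.3, n_modes))
    phase = rng.uniform(0, 2 * np.pi, n_modes)
    kx = k * np.cos(theta)
    kz = k * np.sin(theta)
    amp = np.sqrt(2.0 / n_modes)

    def field(x: np.ndarray, z: np.ndarray) -> np.ndarray:
        return amp * np.sum(
            np.cos(np.outer(x, kx) + np.outer(z, kz) + phase), axis=1
        )

    return field


def generate_scatterer_field(
    spec: PhantomSpec,
    roi: ROISet | None,
    frame_extent_mm: tuple[float, float],
    seed: int | None = None,
) -> ScattererField:
    """Draw the scatterer cloud for one frame.

    Positions are uniform over the frame at ``spec.scatterer_density_mm2``;
    each scatterer takes the effective radius of the region containing it
    (``core`` / ``margin`` / ``background``) and an amplitude drawn
    N(0, sigma^2) with ``sigma^2 = 10^(AAC_dB/10) / density`` so that the
    ensemble backscattered power tracks the linear acoustic concentration.
    In the margin the amplitude s.d. is further modulated by
    ``exp(h/2 * g(x,z))`` with g a smooth unit-variance random field and
    h = ``spec.margin_heterogeneity``.
    """
    depth_mm, width_mm = frame_extent_mm
    if depth_mm <= 0 or width_mm <= 0:
        raise ValueError("frame extent must be positive")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    area = depth_mm * width_mm
    n = rng.poisson(spec.scatterer_density_mm2 * area)
    x = rng.uniform(0, width_mm, n)
    z = rng.uniform(0, depth_mm, n)

    region = np.full(n, "background", dtype=object)
    if roi is not None:
        in_core = shapely.contains_xy(roi.core, x, z)
        in_margin = shapely.contains_xy(roi.margin, x, z) & ~in_core
        region[in_core] = "core"
        region[in_margin] = "margin"
        for name in ("core", "margin"):
            if name in spec.regions and not np.any(region == name):
                raise ValueError(f"region {name!r} contains no scatterers")

    a_eff = np.empty(n)
    sigma = np.empty(n)
    for name in np.unique(region):
        acoustics = spec.regions.get(name)
        if acoustics is None:
            raise ValueError(f"no acoustics specified for region {name!r}")
        m = region == name
        a_eff[m] = acoustics.effective_radius_um
        sigma[m] = np.sqrt(
            10.0 ** (acoustics.acoustic_concentration_db / 10.0)
            / spec.scatterer_density_mm2
        )
    amplitude = rng.standard_normal(n) * sigma

    if roi is not None and spec.margin_heterogeneity > 0:
        g = _smooth_field(rng, spec.heterogeneity_corr_mm)
        m = region == "margin"
        amplitude[m] *= np.exp(0.5 * spec.margin_heterogeneity * g(x[m], z[m]))

    return ScattererField(x, z, amplitude, a_eff, region)


# ---------------------------------------------------------------------------
# RF synthesis


@dataclass
class AcquisitionGeometry:
    """Transducer / sampling metadata for synthesized frames."""

    depth_mm: float = 26.0
    width_mm: float = 30.0
    fs_axial_mhz: float = 40.0
    lateral_pitch_mm: float = 0.12
    fc_mhz: float = 6.5
    band_mhz: tuple[float, float] = (3.0, 8.0)
    sound_speed_m_s: float = 1540.0
    lateral_psf_sigma_mm: float = 0.12
    snr_db: float = 30.0

    @property
    def n_axial(self) -> int:
        step = self.sound_speed_m_s / (2 * self.fs_axial_mhz * 1e6) * 1e3
        return int(round(self.depth_mm / step))

    @property
    def n_lateral(self) -> int:
        return int(round(self.width_mm / self.lateral_pitch_mm))


def pulse_spectrum(f_mhz: np.ndarray, acq: AcquisitionGeometry) -> np.ndarray:
    """One-way Gaussian pulse amplitude spectrum covering the analysis band.

    The -6 dB points of the two-way (power) response sit at the band
    edges.
    """
    lo, hi = acq.band_mhz
    half = 0.5 * (hi - lo)
    # |P(fc +/- half)|^2 = 10^(-6/10) => sigma from the Gaussian profile
    sigma = half / np.sqrt(2 * 6 / 10 * np.log(10))
    return np.exp(-((f_mhz - acq.fc_mhz) ** 2) / (2 * sigma**2))


def synthesize_rf_frame(
    field: ScattererField,
    spec: PhantomSpec,
    acq: AcquisitionGeometry,
    seed: int = 0,
    b_ff: float = 0.827,
    frame_id: str = "",
) -> RFFrame:
    """Form the RF frame from a scatterer cloud.

    Frequency-domain synthesis per lateral line: each scatterer assigned
    to its nearest line contributes
    ``a_i * P(f) * exp(-b_ff k^2 a_i^2) * 10^(-alpha f z_i / 10) * e^(-2j pi f t_i)``
    with ``t_i = 2 z_i / c``; the inverse FFT gives the line's RF trace.
    A Gaussian lateral PSF then mixes neighbouring lines, and white
    Gaussian noise is added at ``acq.snr_db``.
    """
    if len(field) == 0:
        raise ValueError("scatterer field is empty")
    if acq.band_mhz[1] >= acq.fs_axial_mhz / 2:
        raise ValueError("pulse band exceeds Nyquist frequency")
    rng = np.random.default_rng(seed)
    n_ax, n_lat = acq.n_axial, acq.n_lateral
    f_mhz = np.fft.rfftfreq(n_ax, d=1.0 / acq.fs_axial_mhz)
    pulse = pulse_spectrum(f_mhz, acq)

    # per-scatterer spectral shaping
    c = acq.sound_speed_m_s
    k = 2 * np.pi * (f_mhz[None, :] * 1e6) / c  # 1/m
    line_idx = np.round(field.x_mm / acq.lateral_pitch_mm).astype(int)
    keep = (line_idx >= 0) & (line_idx < n_lat) & (field.z_mm < acq.depth_mm)
    spectra = np.zeros((n_lat, len(f_mhz)), dtype=complex)
    zs = field.z_mm[keep]
    amps = field.amplitude[keep]
    aeff_m = field.a_eff_um[keep] * 1e-6
    lines = line_idx[keep]
    t_us = 2 * zs * 1e-3 / c * 1e6  # round-trip delay in microseconds
    order = np.argsort(lines)
    lines, zs, amps, aeff_m, t_us = (
        arr[order] for arr in (lines, zs, amps, aeff_m, t_us)
    )
    starts = np.searchsorted(lines, np.arange(n_lat))
    stops = np.searchsorted(lines, np.arange(n_lat) + 1)
    alpha = spec.attenuation_db_cm_mhz
    for m in range(n_lat):
        sl = slice(starts[m], stops[m])
        if sl.start == sl.stop:
            continue
        response = np.exp(-b_ff * (k**2) * (aeff_m[sl, None] ** 2))
        if alpha > 0:
            # one-way alpha, round-trip path: 2*alpha*f*z dB of amplitude... in
            # amplitude terms 10^(-(2 alpha f z_cm)/20)
            response = response * 10.0 ** (
                -alpha * f_mhz[None, :] * (zs[sl, None] * 0.1) / 10.0
            )
        phase = np.exp(-2j * np.pi * f_mhz[None, :] * t_us[sl, None])
        spectra[m] = np.sum(amps[sl, None] * response * phase, axis=0)
    spectra *= pulse[None, :]
    rf = np.fft.irfft(spectra, n=n_ax, axis=1).T  # (axial, lateral)

    # separable Gaussian lateral PSF
    if acq.lateral_psf_sigma_mm > 0:
        from scipy.ndimage import gaussian_filter1d

        sigma_lines = acq.lateral_psf_sigma_mm / acq.lateral_pitch_mm
        rf = gaussian_filter1d(rf, sigma_lines, axis=1, mode="constant")

    rms = np.sqrt(np.mean(rf**2))
    if rms > 0 and np.isfinite(acq.snr_db):
        noise_std = rms * 10.0 ** (-acq.snr_db / 20.0)
        rf = rf + rng.standard_normal(rf.shape) * noise_std

    return RFFrame(
        rf,
        fs_axial_mhz=acq.fs_axial_mhz,
        lateral_pitch_mm=acq.lateral_pitch_mm,
        fc_mhz=acq.fc_mhz,
        band_mhz=acq.band_mhz,
        sound_speed_m_s=acq.sound_speed_m_s,
        frame_id=frame_id,
    )


def analytic_bsc(
    f_mhz: np.ndarray,
    asd_um: float,
    aac_db: float,
    b_ff: float = 0.827,
    sound_speed_m_s: float = 1540.0,
) -> np.ndarray:
    """Model backscatter coefficient ``AAC_lin * f^4 * exp(-2 b k^2 a^2)``.

    ``f`` in MHz (the f^4 factor uses MHz units), ``a = asd/2`` in meters
    inside ``k^2 a^2``.
    """
    f_mhz = np.asarray(f_mhz, dtype=float)
    a_m = asd_um / 2 * 1e-6
    k = 2 * np.pi * f_mhz * 1e6 / sound_speed_m_s
    return 10.0 ** (aac_db / 10.0) * f_mhz**4 * np.exp(-2 * b_ff * k**2 * a_m**2)


def generate_reference_frames(
    acq: AcquisitionGeometry,
    n_frames: int,
    seed: int = 0,
    asd_ref_um: float = 50.0,
    aac_ref_db: float = 0.0,
    b_ff: float = 0.827,
    scatterer_density_mm2: float = 80.0,
) -> tuple[list[RFFrame], dict]:
    """Homogeneous calibration phantom frames plus the analytic reference BSC.

    The reference phantom has zero attenuation by default so its spectrum
    is depth-independent, as a calibration target should be.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    spec = PhantomSpec(
        regions={"background": RegionAcoustics(asd_ref_um / 2, aac_ref_db)},
        scatterer_density_mm2=scatterer_density_mm2,
        attenuation_db_cm_mhz=0.0,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_frames):
        fseed = int(rng.integers(0, 2**31 - 1))
        fld = generate_scatterer_field(
            spec, None, (acq.depth_mm, acq.width_mm), seed=fseed
        )
        frames.append(
            synthesize_rf_frame(
                fld, spec, acq, seed=fseed + 1, b_ff=b_ff, frame_id=f"ref{i:03d}"
            )
        )
    reference = {
        "asd_um": asd_ref_um,
        "aac_db": aac_ref_db,
        "alpha_db_cm_mhz": 0.0,
        "b_ff": b_ff,
        "sound_speed_m_s": acq.sound_speed_m_s,
    }
    return frames, reference


# ---------------------------------------------------------------------------
# cohort generation


def _draw_long_axis_cm(
    rng: np.random.Generator, lo: float, hi: float
) -> float:
    """Tumor long axis (cm): lognormal matched to a ~2.2 cm mean / 1.7 cm
    median size distribution, truncated to [lo, hi]."""
    for _ in range(100):
        val = float(rng.lognormal(mean=np.log(1.7), sigma=0.55))
        if lo <= val <= hi:
            return val
    return float(np.clip(1.7, lo, hi))


def _make_tumor_roi(
    rng: np.random.Generator,
    acq: AcquisitionGeometry,
    long_axis_range_cm: tuple[float, float],
    frame_id: str,
) -> ROISet:
    """Elliptical core + 5 mm ring placed to fit inside the frame."""
    border = 1.0  # mm clearance between margin and frame edge
    max_long_mm = min(
        acq.width_mm - 2 * (MARGIN_WIDTH_MM + border),
        acq.depth_mm - 2 * (MARGIN_WIDTH_MM + border),
    )
    for attempt in range(50):
        long_mm = _draw_long_axis_cm(rng, *long_axis_range_cm) * 10.0
        if long_mm <= max_long_mm:
            break
        if attempt == 0:
            logger.warning(
                "tumor long axis %.1f mm exceeds frame FOV; resampling", long_mm
            )
    else:
        long_mm = max_long_mm
    short_mm = long_mm * rng.uniform(0.5, 0.9)
    a, b = long_mm / 2, short_mm / 2
    angle = rng.uniform(0, 180)
    # bounding half-extent after rotation is at most the long semi-axis
    pad = a + MARGIN_WIDTH_MM + border
    cx = rng.uniform(pad, acq.width_mm - pad)
    cz = rng.uniform(pad, acq.depth_mm - pad)
    ellipse = shapely.affinity.scale(Point(0, 0).buffer(1.0, quad_segs=64), a, b)
    ellipse = shapely.affinity.rotate(ellipse, angle)
    ellipse = shapely.affinity.translate(ellipse, cx, cz)
    return ROISet(core=ellipse, frame_id=frame_id)


def generate_cohort(
    n_low: int = 10,
    n_high: int = 21,
    frames_per_patient: int = 3,
    acq: AcquisitionGeometry | None = None,
    seed: int = 1,
    core_asd_um: float = 80.0,
    core_aac_db: float = 0.0,
    background_aac_db: float = -6.0,
    scatterer_density_mm2: float = 80.0,
    attenuation_db_cm_mhz: float = 0.5,
    margin_heterogeneity_low: float = 0.1,
    margin_heterogeneity_high: float = 0.8,
    margin_aac_delta_db_high: float = 2.0,
    long_axis_range_cm: tuple[float, float] = (0.7, 8.9),
    odxrs_threshold: int = 15,
) -> list[PatientData]:
    """Simulate the study cohort: ``n_low`` low-risk and ``n_high``
    intermediate-to-high-risk patients with ``frames_per_patient`` RF
    frames each.

    The class effect is injected where the discriminative features live
    in practice: high-risk margins get stronger spatial heterogeneity of
    acoustic concentration and a small mean concentration shift.
    """
    if n_low < 1 or n_high < 1:
        raise ValueError("both classes need at least one patient")
    acq = acq or AcquisitionGeometry()
    ss = np.random.SeedSequence(seed)
    patients: list[PatientData] = []
    labels = [0] * n_low + [1] * n_high
    child_seeds = ss.generate_state(len(labels) * (2 * frames_per_patient + 2)) % (
        2**31 - 1
    )
    si = 0
    for p_idx, label in enumerate(labels):
        rng = np.random.default_rng(child_seeds[si]); si += 1
        pid = f"P{p_idx:03d}"
        het = margin_heterogeneity_high if label else margin_heterogeneity_low
        margin_aac = core_aac_db + (margin_aac_delta_db_high if label else 0.0)
        spec = PhantomSpec(
            regions={
                "core": RegionAcoustics(core_asd_um / 2, core_aac_db),
                "margin": RegionAcoustics(core_asd_um / 2, margin_aac),
                "background": RegionAcoustics(core_asd_um / 2, background_aac_db),
            },
            scatterer_density_mm2=scatterer_density_mm2,
            attenuation_db_cm_mhz=attenuation_db_cm_mhz,
            margin_heterogeneity=het,
            seed=int(child_seeds[si]),
        ); si += 1
        if label:
            odxrs = int(rng.integers(odxrs_threshold + 1, 36))
        else:
            odxrs = int(rng.integers(1, odxrs_threshold + 1))
        frames, rois = [], []
        for f_idx in range(frames_per_patient):
            fid = f"{pid}_f{f_idx}"
            roi = _make_tumor_roi(rng, acq, long_axis_range_cm, fid)
            fld = generate_scatterer_field(
                spec, roi, (acq.depth_mm, acq.width_mm), seed=int(child_seeds[si])
            ); si += 1
            frames.append(
                synthesize_rf_frame(
                    fld, spec, acq, seed=int(child_seeds[si]), frame_id=fid
                )
            ); si += 1
            rois.append(roi)
        patients.append(
            PatientData(
                frames=frames,
                rois=rois,
                clinical=ClinicalRecord(pid, odxrs, threshold=odxrs_threshold),
                ground_truth=spec,
            )
        )
    return patients


# ---------------------------------------------------------------------------
# serialization


def save_cohort(patients: Sequence[PatientData], out_dir: str | Path) -> None:
    """One directory per patient: .npy RF frames + JSON sidecars, ROI
    polygons as JSON (mm; x = lateral, y = axial depth), clinical CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["patient_id,odxrs,label"]
    for pat in patients:
        pdir = out / pat.clinical.patient_id
        pdir.mkdir(exist_ok=True)
        rows.append(
            f"{pat.clinical.patient_id},{pat.clinical.odxrs},{pat.clinical.label}"
        )
        for frame, roi in zip(pat.frames, pat.rois):
            np.save(pdir / f"{frame.frame_id}.npy", frame.samples)
            meta = {
                "fs_axial_mhz": frame.fs_axial_mhz,
                "lateral_pitch_mm": frame.lateral_pitch_mm,
                "fc_mhz": frame.fc_mhz,
                "band_mhz": list(frame.band_mhz),
                "sound_speed_m_s": frame.sound_speed_m_s,
            }
            (pdir / f"{frame.frame_id}.json").write_text(json.dumps(meta))
            rois = {
                "core": list(map(list, roi.core.exterior.coords)),
                "frame_id": roi.frame_id,
            }
            (pdir / f"{frame.frame_id}.roi.json").write_text(json.dumps(rois))
    (out / "clinical.csv").write_text("\n".join(rows) + "\n")


def load_cohort(in_dir: str | Path) -> list[PatientData]:
    in_dir = Path(in_dir)
    clinical = {}
    for line in (in_dir / "clinical.csv").read_text().splitlines()[1:]:
        pid, odxrs, label = line.split(",")
        clinical[pid] = ClinicalRecord(pid, int(odxrs), int(label))
    patients = []
    for pid in sorted(clinical):
        pdir = in_dir / pid
        frames, rois = [], []
        for npy in sorted(pdir.glob("*.npy")):
            meta = json.loads((pdir / f"{npy.stem}.json").read_text())
            meta["band_mhz"] = tuple(meta["band_mhz"])
            frames.append(RFFrame(np.load(npy), frame_id=npy.stem, **meta))
            roi_data = json.loads((pdir / f"{npy.stem}.roi.json").read_text())
            rois.append(
                ROISet(core=Polygon(roi_data["core"]), frame_id=roi_data["frame_id"])
            )
        patients.append(PatientData(frames, rois, clinical[pid]))
    return patients
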