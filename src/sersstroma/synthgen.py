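"""Synthetic SERS tissue-phantom cohorts.

Generates seeded cohorts of annotated hyperspectral cubes with the
statistical structure the downstream analysis assumes: region-structured
tissue layouts (cancer nests embedded in stroma, adipose patches at the
margins, occasional normal gland), Lorentzian marker bands whose amplitudes
depend on (diagnosis, region) context, smooth per-pixel baselines,
multiplicative log-normal hotspot variation (emulating the electromagnetic
hotspot heterogeneity of nanoparticle SERS substrates), additive Gaussian
noise, and a narrow silicon calibration line near 520 cm^-1 with a
controllable miscalibration shift.

The default peak library injects differential amplitudes in stroma at the 27
reported marker wavenumbers -- e.g. the 480 cm^-1 polysulfide band elevated
in invasive stroma, the 974 cm^-1 hypotaurine band depressed there relative
to DCIS -- plus the 722 cm^-1 purine-nucleotide band as a non-differential
control. Intensities are arbitrary units throughout; only relative structure
is meaningful.

RNG discipline: one master seed per cohort; independent child streams are
spawned per patient and, within a patient, per operation (layout, baseline,
peak amplitudes, hotspots, noise) via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import (
    DIAGNOSES,
    AnnotationMask,
    ConfigError,
    DataError,
    SpectralCube,
    WavenumberAxis,
)

__all__ = [
    "REGIONS",
    "DEFAULT_FEATURE_WAVENUMBERS",
    "DEFAULT_DOMINANCE",
    "PeakSpec",
    "LayoutParams",
    "BaselineParams",
    "TissuePhantom",
    "make_phantom",
    "phantom_to_mask",
    "render_cube",
    "silicon_reference",
    "default_peak_library",
    "simulate_patient",
]

#: Tissue regions a phantom can contain.
REGIONS = ("nest", "stroma", "adipose", "normal")

#: The 27 stromal marker wavenumbers used as classifier features, in
#: descending order of reported importance.
DEFAULT_FEATURE_WAVENUMBERS = (
    382, 974, 480, 256, 888, 1250, 334, 1504, 1028, 840, 916, 1536, 1412,
    696, 760, 1140, 616, 1378, 642, 592, 1308, 532, 666, 798, 1570, 576, 1082,
)

#: Dominance direction injected per marker band: "D" means DCIS stroma
#: carries the higher amplitude, "I" means invasive stroma does. The split is
#: 19 D-dominant and 8 I-dominant bands; 480 (polysulfide) is I-dominant and
#: 382/974/1140/1250 are D-dominant, matching their known directions, while
#: the remaining assignments are a modelling choice.
_I_DOMINANT = frozenset({480, 888, 1028, 1308, 1412, 1504, 1536, 1570})
DEFAULT_DOMINANCE: Mapping[int, str] = {
    wn: ("I" if wn in _I_DOMINANT else "D") for wn in DEFAULT_FEATURE_WAVENUMBERS
}


@dataclass(frozen=True)
class PeakSpec:
    """One Lorentzian marker band.

    ``width`` is the half-width at half-maximum in cm^-1; ``amplitude`` maps
    (diagnosis, region) context to the mean apex height (a.u.);
    ``amplitude_cv`` is the coefficient of variation of a per-patient
    log-normal multiplier shared by all pixels of that patient.
    """

    center: float
    amplitude: Mapping[tuple[str, str], float]
    width: float = 4.0
    amplitude_cv: float = 0.12

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError(f"peak {self.center}: width must be > 0")
        if any(a < 0 for a in self.amplitude.values()):
            raise ConfigError(f"peak {self.center}: amplitudes must be >= 0")
        if self.amplitude_cv < 0:
            raise ConfigError(f"peak {self.center}: amplitude_cv must be >= 0")

    @classmethod
    def flat(
        cls,
        center: float,
        amplitude: float,
        width: float = 4.0,
        amplitude_cv: float = 0.12,
    ) -> "PeakSpec":
        """A band with the same mean amplitude in every context."""
        amp = {(d, r): float(amplitude) for d in DIAGNOSES for r in REGIONS}
        return cls(center=center, amplitude=amp, width=width, amplitude_cv=amplitude_cv)

    @classmethod
    def stromal_differential(
        cls,
        center: float,
        dominance: str,
        low: float = 100.0,
        high: float = 150.0,
        base: float = 100.0,
        width: float = 4.0,
        amplitude_cv: float = 0.12,
    ) -> "PeakSpec":
        """A band whose stroma amplitude differs by diagnosis.

        ``dominance`` "D" puts the high amplitude in DCIS stroma, "I" in
        invasive stroma; all other contexts get ``base``.
        """
        if dominance not in ("D", "I"):
            raise ConfigError("dominance must be 'D' or 'I'")
        amp = {(d, r): float(base) for d in DIAGNOSES for r in REGIONS}
        amp[("DCIS", "stroma")] = float(high if dominance == "D" else low)
        amp[("IBC", "stroma")] = float(low if dominance == "D" else high)
        return cls(center=center, amplitude=amp, width=width, amplitude_cv=amplitude_cv)


def default_peak_library(
    low: float = 100.0,
    high: float = 150.0,
    width: float = 4.0,
    amplitude_cv: float = 0.12,
) -> list[PeakSpec]:
    """The shipped marker-band library.

    All 27 reported stromal wavenumbers carry a diagnosis-dependent stroma
    amplitude (``high`` vs ``low``, direction from :data:`DEFAULT_DOMINANCE`),
    giving between-patient effects of roughly (high-low)/(cv*mean) pooled
    standard deviations; the 722 cm^-1 purine-nucleotide control band is
    equal in both diagnoses.
    """
    lib = [
        PeakSpec.stromal_differential(
            float(wn), DEFAULT_DOMINANCE[wn], low=low, high=high,
            width=width, amplitude_cv=amplitude_cv,
        )
        for wn in DEFAULT_FEATURE_WAVENUMBERS
    ]
    lib.append(PeakSpec.flat(722.0, 120.0, width=width, amplitude_cv=amplitude_cv))
    return lib


@dataclass(frozen=True)
class LayoutParams:
    """Target region fractions for a phantom layout (must sum to 1)."""

    nest_fraction: float = 0.20
    adipose_fraction: float = 0.15
    normal_fraction: float = 0.05
    stroma_fraction: float = 0.60

    def __post_init__(self) -> None:
        fracs = (
            self.nest_fraction,
            self.adipose_fraction,
            self.normal_fraction,
            self.stroma_fraction,
        )
        if any(f < 0 for f in fracs):
            raise ConfigError("layout fractions must be >= 0")
        if self.stroma_fraction <= 0:
            raise ConfigError("layout infeasible: stroma fraction must be > 0")
        if self.nest_fraction <= 0:
            raise ConfigError("layout infeasible: nest fraction must be > 0")
        if abs(sum(fracs) - 1.0) > 1e-6:
            raise ConfigError("layout fractions must sum to 1")

    def with_stroma(self, stroma_fraction: float) -> "LayoutParams":
        """Rescale the non-stroma fractions to hit a stroma target."""
        rest = 1.0 - stroma_fraction
        old_rest = 1.0 - self.stroma_fraction
        s = rest / old_rest if old_rest > 0 else 0.0
        return LayoutParams(
            nest_fraction=self.nest_fraction * s,
            adipose_fraction=self.adipose_fraction * s,
            normal_fraction=self.normal_fraction * s,
            stroma_fraction=stroma_fraction,
        )


@dataclass
class TissuePhantom:
    """Region-labelled tissue layout for one synthetic patient."""

    region_image: np.ndarray  # int codes into REGIONS
    diagnosis: str
    patient_id: str

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSES:
            raise DataError(f"unknown diagnosis {self.diagnosis!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.region_image.shape  # type: ignore[return-value]

    def region_names(self) -> np.ndarray:
        return np.asarray(REGIONS, dtype=object)[self.region_image]

    def region_fractions(self) -> dict[str, float]:
        n = self.region_image.size
        counts = np.bincount(self.region_image.ravel(), minlength=len(REGIONS))
        return {r: c / n for r, c in zip(REGIONS, counts)}


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    return (f - f.mean()) / (f.std() + 1e-12)


def make_phantom(
    shape: tuple[int, int],
    diagnosis: str,
    layout: LayoutParams | None = None,
    seed: int = 0,
) -> TissuePhantom:
    """Generate a connected-blob tissue layout.

    Nest blobs are biased toward the image centre, adipose patches toward the
    margins; pixel counts per region match the layout fractions exactly (up
    to rounding), so realized fractions track the targets. Deterministic per
    seed.
    """
    h, w = int(shape[0]), int(shape[1])
    if h < 8 or w < 8:
        raise DataError(f"degenerate phantom shape {shape}: need at least 8x8")
    if diagnosis not in DIAGNOSES:
        raise DataError(f"unknown diagnosis {diagnosis!r}")
    layout = layout or LayoutParams()

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sigma = max(1.5, min(h, w) / 8.0)
    yy, xx = np.meshgrid(
        np.linspace(-1, 1, h), np.linspace(-1, 1, w), indexing="ij"
    )
    r = np.sqrt(xx**2 + yy**2) / np.sqrt(2.0)

    score_nest = _smooth_field(rng, (h, w), sigma) - 2.0 * r
    score_adip = _smooth_field(rng, (h, w), sigma) + 2.0 * r
    score_norm = _smooth_field(rng, (h, w), sigma)

    n = h * w
    n_nest = int(round(layout.nest_fraction * n))
    n_adip = int(round(layout.adipose_fraction * n))
    n_norm = int(round(layout.normal_fraction * n))
    if n - n_nest - n_adip - n_norm <= 0:
        raise ConfigError("layout infeasible: no pixels left for stroma")

    codes = np.full(n, REGIONS.index("stroma"), dtype=np.uint8)
    order_nest = np.argsort(-score_nest.ravel(), kind="stable")
    nest_idx = order_nest[:n_nest]
    codes[nest_idx] = REGIONS.index("nest")

    remaining = np.ones(n, dtype=bool)
    remaining[nest_idx] = False
    rem_idx = np.nonzero(remaining)[0]
    order_adip = rem_idx[np.argsort(-score_adip.ravel()[rem_idx], kind="stable")]
    adip_idx = order_adip[:n_adip]
    codes[adip_idx] = REGIONS.index("adipose")

    remaining[adip_idx] = False
    rem_idx = np.nonzero(remaining)[0]
    order_norm = rem_idx[np.argsort(-score_norm.ravel()[rem_idx], kind="stable")]
    norm_idx = order_norm[:n_norm]
    codes[norm_idx] = REGIONS.index("normal")

    return TissuePhantom(
        region_image=codes.reshape(h, w),
        diagnosis=diagnosis,
        patient_id=f"{diagnosis}-{seed}",
    )


#: Mapping from phantom region to annotation vocabulary, per diagnosis.
_REGION_TO_LABEL = {
    "IBC": {"nest": "cancer_nest", "stroma": "cancer_stroma",
            "adipose": "fat", "normal": "normal_gland"},
    "DCIS": {"nest": "dcis", "stroma": "dcis_stroma",
             "adipose": "fat", "normal": "normal_gland"},
}


def phantom_to_mask(phantom: TissuePhantom) -> AnnotationMask:
    """Translate a phantom's region layout into the pathology vocabulary."""
    mapping = _REGION_TO_LABEL[phantom.diagnosis]
    names = np.empty(phantom.shape, dtype=object)
    region_names = phantom.region_names()
    for region, label in mapping.items():
        names[region_names == region] = label
    return AnnotationMask.from_names(names)


@dataclass(frozen=True)
class BaselineParams:
    """Smooth synthetic baseline: degree-3 polynomial plus one broad hump.

    Polynomial coefficients apply to the axis coordinate normalized to
    [0, 1]; the hump is a Gaussian in wavenumber. ``patient_cv`` scatters the
    coefficients between patients, ``pixel_cv`` between pixels of one
    patient.
    """

    poly_coeffs: tuple[float, float, float, float] = (120.0, -60.0, 90.0, -40.0)
    hump_amplitude: float = 150.0
    hump_center: float = 1100.0
    hump_width: float = 220.0
    patient_cv: float = 0.10
    pixel_cv: float = 0.05

    @classmethod
    def flat(cls) -> "BaselineParams":
        """A zero baseline (for noiseless identity tests)."""
        return cls(poly_coeffs=(0.0, 0.0, 0.0, 0.0), hump_amplitude=0.0,
                   patient_cv=0.0, pixel_cv=0.0)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean log-normal multipliers with the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size))


def render_cube(
    phantom: TissuePhantom,
    axis: WavenumberAxis | np.ndarray,
    peak_library: Sequence[PeakSpec],
    baseline: BaselineParams | None = None,
    noise_sd: float = 10.0,
    hotspot_cv: float = 0.25,
    seed: int = 0,
    miscalibration: float = 0.0,
    pixel_pitch: float = 11.65,
    return_truth: bool = False,
):
    """Render a phantom into a raw SERS cube.

    Each pixel's spectrum is ``baseline + sum_k Lorentzian_k * hotspot +
    noise``. The (diagnosis, region) context selects each band's mean apex
    amplitude; a per-patient log-normal multiplier (``amplitude_cv``) and a
    per-pixel log-normal hotspot factor (``hotspot_cv``, shared by all bands
    of a pixel) modulate it. ``miscalibration`` shifts every band center
    (and should be matched by the silicon reference) to emulate an
    uncalibrated instrument.

    With ``return_truth`` the generator also returns the noiseless
    components (baseline, clean spectrum, per-band mean amplitude images)
    for truth-recovery tests.
    """
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    wn = axis.values if isinstance(axis, WavenumberAxis) else np.asarray(axis, dtype=float)
    baseline = baseline or BaselineParams()
    h, w = phantom.shape
    n_chan = wn.size

    for pk in peak_library:
        c = pk.center + miscalibration
        if not (wn[0] <= c <= wn[-1]):
            raise DataError(
                f"peak at {pk.center:g} cm^-1 (rendered at {c:g}) falls outside "
                f"the axis [{wn[0]:g}, {wn[-1]:g}]"
            )
        for region in np.unique(phantom.region_names()):
            if (phantom.diagnosis, str(region)) not in pk.amplitude:
                raise DataError(
                    f"peak at {pk.center:g} cm^-1 has no amplitude for context "
                    f"({phantom.diagnosis}, {region})"
                )

    ss = np.random.SeedSequence(seed)
    rng_base, rng_amp, rng_hot, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    # --- baseline -----------------------------------------------------
    x = (wn - wn[0]) / (wn[-1] - wn[0])
    basis = np.stack([x**k for k in range(4)])  # (4, C)
    coeffs = np.asarray(baseline.poly_coeffs, dtype=float)
    coeffs = coeffs * (1.0 + baseline.patient_cv * rng_base.standard_normal(4))
    hump_amp = baseline.hump_amplitude * (
        1.0 + baseline.patient_cv * rng_base.standard_normal()
    )
    pixel_jitter = 1.0 + baseline.pixel_cv * rng_base.standard_normal((h, w, 5))
    hump = np.exp(-0.5 * ((wn - baseline.hump_center) / max(baseline.hump_width, 1e-9)) ** 2)
    base_img = np.einsum("hwk,k,kc->hwc", pixel_jitter[..., :4], coeffs, basis)
    base_img += (hump_amp * pixel_jitter[..., 4])[..., None] * hump[None, None, :]

    # --- peaks --------------------------------------------------------
    region_codes = phantom.region_image
    hotspot = _lognormal_factors(rng_hot, hotspot_cv, (h, w))
    clean = base_img.copy()
    amp_truth: dict[float, np.ndarray] = {}
    for pk in peak_library:
        m_patient = _lognormal_factors(rng_amp, pk.amplitude_cv, ())
        amp_by_region = np.array(
            [pk.amplitude.get((phantom.diagnosis, r), 0.0) for r in REGIONS]
        )
        amp_img = amp_by_region[region_codes] * m_patient
        profile = pk.width**2 / ((wn - (pk.center + miscalibration)) ** 2 + pk.width**2)
        clean += (amp_img * hotspot)[..., None] * profile[None, None, :]
        amp_truth[pk.center] = amp_img

    intensities = clean if noise_sd == 0 else clean + rng_noise.normal(0.0, noise_sd, clean.shape)

    cube = SpectralCube(
        intensities=intensities,
        wavenumbers=wn,
        pixel_pitch=pixel_pitch,
        metadata={
            "patient_id": phantom.patient_id,
            "diagnosis": phantom.diagnosis,
            "calibrated": False,
            "baseline_subtracted": False,
        },
    )
    if return_truth:
        truth = {
            "baseline": base_img,
            "clean": clean,
            "hotspot": hotspot,
            "amplitudes": amp_truth,
            "miscalibration": miscalibration,
        }
        return cube, truth
    return cube


SILICON_CENTER = 520.0


def silicon_reference(
    axis: WavenumberAxis | np.ndarray,
    shift: float = 0.0,
    amplitude: float = 5000.0,
    width: float = 2.0,
) -> np.ndarray:
    """A narrow silicon phonon calibration line with apex at 520 + shift cm^-1."""
    wn = axis.values if isinstance(axis, WavenumberAxis) else np.asarray(axis, dtype=float)
    apex = SILICON_CENTER + shift
    if not (wn[0] <= apex <= wn[-1]):
        raise DataError(
            f"silicon calibration apex {apex:g} cm^-1 outside axis "
            f"[{wn[0]:g}, {wn[-1]:g}]"
        )
    return amplitude * width**2 / ((wn - apex) ** 2 + width**2)


def simulate_patient(
    patient_id: str,
    diagnosis: str,
    shape: tuple[int, int],
    axis: WavenumberAxis,
    peak_library: Sequence[PeakSpec],
    baseline: BaselineParams | None = None,
    layout: LayoutParams | None = None,
    noise_sd: float = 10.0,
    hotspot_cv: float = 0.25,
    calibration_shift: float = 0.0,
    seed_sequence: np.random.SeedSequence | None = None,
):
    """Phantom + raw cube + full-resolution mask for one synthetic patient."""
    ss = seed_sequence or np.random.SeedSequence(0)
    seed_phantom, seed_render = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    phantom = make_phantom(shape, diagnosis, layout=layout, seed=seed_phantom)
    phantom.patient_id = patient_id
    cube = render_cube(
        phantom, axis, peak_library,
        baseline=baseline, noise_sd=noise_sd, hotspot_cv=hotspot_cv,
        seed=seed_render, miscalibration=calibration_shift,
    )
    cube.metadata["patient_id"] = patient_id
    mask = phantom_to_mask(phantom)
    silicon = silicon_reference(axis, shift=calibration_shift)
    return phantom, cube, mask, silicon
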