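"""Synthetic aging menstrual-bloodstain Raman spectra.

The generator emulates the statistical structure a time-since-deposition
(TSD) analysis of dried menstrual bloodstains relies on:

* a band library of blood (heme-dominated) and vaginal-fluid marker
  bands between 300 and 1800 cm^-1, Lorentzian line shapes;
* mono-exponential intensity kinetics ``y(h) = A exp(-h/t1) + y0`` for
  the hemoglobin-degradation marker bands (1369 cm^-1 metHb rise,
  1577 cm^-1 rise, 890 cm^-1 decay, an early 1448 cm^-1 rise) with
  donor-specific time constants, plus a 752 -> 745 cm^-1 band shift
  after 24 h (protein denaturation signature);
* a broad fluorescence background whose level grows with stain age,
  with spot-level non-monotone jitter;
* lognormal spot gains (stain heterogeneity), multiplicative-scale
  Gaussian channel noise, and rare saturated-background outlier spectra.

Two donors, a 12-point map per time point, and the 12-hour sampling
schedule 1-336 h are the default experiment layout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .spectra import RamanSpectrum, SpectraDataset, SpectrumMeta, default_grid

__all__ = [
    "CenterShift",
    "BandKineticsSpec",
    "BackgroundModel",
    "NoiseModel",
    "DonorProfile",
    "GeneratorConfig",
    "DEFAULT_SCHEDULE",
    "default_config",
    "band_profile",
    "generate_spectrum",
    "generate_dataset",
]

#: Default sampling schedule in hours post-deposition.
DEFAULT_SCHEDULE = (1.0, 5.0, 9.0, 24.0, 48.0, 72.0, 96.0, 120.0, 144.0, 168.0, 236.0, 336.0)

# Band library: (center / cm^-1, assignment, source fluid).  Heme bands
# dominate the near-IR Raman spectrum of blood; urea / lactic acid /
# lactate / acetic acid bands are the (minor) vaginal-fluid contribution.
BAND_LIBRARY = (
    (374.0, "heme (metHb)", "blood"),
    (417.0, "heme (oxyHb)", "blood"),
    (518.0, "heme", "blood"),
    (663.0, "heme", "blood"),
    (752.0, "tryptophan", "blood"),  # shifts to 745 after 24 h
    (794.0, "heme", "blood"),
    (890.0, "amino acids, lactate", "vaginal fluid"),
    (935.0, "acetic acid", "vaginal fluid"),
    (970.0, "proteins, lipids", "blood"),
    (1003.0, "phenylalanine", "blood"),
    (1050.0, "lactic acid, urea, proteins", "vaginal fluid"),
    (1075.0, "lactic acid", "vaginal fluid"),
    (1124.0, "heme, lactic acid, urea", "blood"),
    (1171.0, "heme", "blood"),
    (1248.0, "proteins (amide III), guanine, cytosine", "blood"),
    (1341.0, "tryptophan", "blood"),
    (1369.0, "heme (metHb)", "blood"),
    (1389.0, "urea", "vaginal fluid"),
    (1448.0, "tryptophan, lactic acid, urea", "blood"),
    (1540.0, "heme", "blood"),
    (1577.0, "proteins, DNA bases", "blood"),
    (1619.0, "heme", "blood"),
    (1660.0, "proteins (amide I), lactic acid, urea", "blood"),
)

#: Donor-specific mono-exponential time constants (h) for the kinetic
#: marker bands.  Increasing bands use A < 0 so the single functional
#: form y = A exp(-h/t1) + y0 covers growth and decay.
KINETIC_TIME_CONSTANTS = {
    "donor1": {1369.0: 70.0, 1577.0: 80.0, 890.0: 47.0},
    "donor2": {1369.0: 40.0, 1577.0: 110.0, 890.0: 25.0},
}

#: Kinetic amplitudes (A, y0) in units of the 1003 cm^-1 band == 1.0.
#: Each trajectory spans at least a two-fold intensity change over 0-336 h.
KINETIC_AMPLITUDES = {
    1369.0: (-0.7, 1.0),  # metHb marker, rises 0.3 -> 1.0
    1577.0: (-0.6, 0.9),  # rises 0.3 -> 0.9
    890.0: (0.45, 0.15),  # decays 0.6 -> 0.15
    1448.0: (-0.3, 0.55),  # early rise within the first hours
}

#: Time constant (h) of the early 1448 cm^-1 rise, shared by both donors.
T1448 = 5.0


@dataclass
class CenterShift:
    """Discrete band-center relocation after ``onset_hour``."""

    new_center: float
    onset_hour: float


@dataclass
class BandKineticsSpec:
    """Center, line width, and mono-exponential trajectory of one band.

    ``trajectory(h) = A exp(-h/t1) + y0``; a static band has ``A = 0``.
    """

    center: float
    width: float = 8.0  # HWHM, cm^-1
    assignment: str = ""
    A: float = 0.0
    t1: float = 1.0
    y0: float = 1.0
    center_shift: CenterShift | None = None

    def __post_init__(self):
        if self.t1 <= 0:
            raise ValueError("t1 must be > 0")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if not (300.0 <= self.center <= 1800.0):
            raise ValueError("center must lie within 300-1800 cm^-1")

    def trajectory(self, hour: float) -> float:
        """Band intensity at ``hour`` h post-deposition."""
        y = self.A * np.exp(-np.asarray(hour, float) / self.t1) + self.y0
        return float(y) if np.ndim(hour) == 0 else y

    def center_at(self, hour: float) -> float:
        if self.center_shift is not None and hour > self.center_shift.onset_hour:
            return self.center_shift.new_center
        return self.center


@dataclass
class BackgroundModel:
    """Broad fluorescence background that grows with stain age.

    Level follows ``b0 + b_gain (1 - exp(-hour/b_t))``; the spectral
    shape is a fixed smooth hump (Gaussian in wavenumber) with
    ``shape_center`` / ``shape_width`` curvature parameters.
    """

    b0: float = 2.0
    b_gain: float = 6.0
    b_t: float = 150.0
    shape_center: float = 1125.0
    shape_width: float = 675.0

    def shape(self, grid: np.ndarray) -> np.ndarray:
        return np.exp(-((grid - self.shape_center) ** 2) / (2.0 * self.shape_width**2))

    def level(self, hour: float, gain_factor: float = 1.0) -> float:
        return self.b0 + self.b_gain * gain_factor * (1.0 - np.exp(-hour / self.b_t))


@dataclass
class NoiseModel:
    sigma_rel: float = 0.03  # Gaussian channel noise, SD relative to local signal
    # Spot-to-spot variation is modest: maps are acquired from a stain
    # region chosen to be uniform and flat.
    spot_scale_sd: float = 0.05  # lognormal spot gain SD (stain heterogeneity)
    background_jitter_sd: float = 0.05  # lognormal spot-level jitter of b_gain

    def __post_init__(self):
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be >= 0")


@dataclass
class DonorProfile:
    donor_id: str
    band_specs: list
    background: BackgroundModel = field(default_factory=BackgroundModel)
    noise: NoiseModel = field(default_factory=NoiseModel)
    outlier_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be a probability")


@dataclass
class GeneratorConfig:
    donors: list
    schedule: tuple = DEFAULT_SCHEDULE
    spots_per_map: int = 12
    grid: np.ndarray = field(default_factory=default_grid)
    seed: int = 0

    def __post_init__(self):
        if self.spots_per_map < 1:
            raise ValueError("spots_per_map must be >= 1")
        sched = np.asarray(self.schedule, float)
        if sched.ndim != 1 or np.any(np.diff(sched) <= 0):
            raise ValueError("schedule must be strictly increasing")


def _build_band_specs(donor_key: str, static_amplitudes: dict) -> list:
    tcs = KINETIC_TIME_CONSTANTS[donor_key]
    specs = []
    for center, assignment, _fluid in BAND_LIBRARY:
        if center in KINETIC_AMPLITUDES and center != 1448.0:
            A, y0 = KINETIC_AMPLITUDES[center]
            specs.append(
                BandKineticsSpec(center, assignment=assignment, A=A, t1=tcs[center], y0=y0)
            )
        elif center == 1448.0:
            A, y0 = KINETIC_AMPLITUDES[center]
            specs.append(
                BandKineticsSpec(center, assignment=assignment, A=A, t1=T1448, y0=y0)
            )
        elif center == 752.0:
            specs.append(
                BandKineticsSpec(
                    center,
                    assignment=assignment,
                    A=0.0,
                    y0=0.5,
                    center_shift=CenterShift(new_center=745.0, onset_hour=24.0),
                )
            )
        else:
            specs.append(
                BandKineticsSpec(
                    center, assignment=assignment, A=0.0, y0=static_amplitudes[center]
                )
            )
    return specs


def default_config(seed: int = 0, outlier_rate: float = 2.0 / 288.0) -> GeneratorConfig:
    """Two donors x 12 time points x 12-spot maps on the 300-1800 grid.

    Static band amplitudes are drawn once (uniform 0.2-1.0 relative to
    the 1003 cm^-1 phenylalanine band = 1.0) and shared by both donors,
    so the donors differ only in the kinetic time constants; the default
    outlier rate makes about two saturated spectra expected among the
    288 of a full run.
    """
    amp_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(17,)))
    static_amplitudes = {}
    for center, _a, _f in BAND_LIBRARY:
        static_amplitudes[center] = (
            1.0 if center == 1003.0 else float(amp_rng.uniform(0.2, 1.0))
        )
    donors = [
        DonorProfile(
            donor_id=key,
            band_specs=_build_band_specs(key, static_amplitudes),
            outlier_rate=outlier_rate,
        )
        for key in ("donor1", "donor2")
    ]
    return GeneratorConfig(donors=donors, seed=seed)


def band_profile(center: float, width: float, grid) -> np.ndarray:
    """Unit-height Lorentzian ``1 / (1 + ((nu - center)/width)^2)`` on ``grid``,
    renormalized so the channel nearest ``center`` has value exactly 1."""
    if width <= 0:
        raise ValueError("width must be > 0")
    grid = np.asarray(grid, float)
    prof = 1.0 / (1.0 + ((grid - center) / width) ** 2)
    return prof / prof[np.argmin(np.abs(grid - center))]


def _noiseless_signal(profile: DonorProfile, hour: float, grid: np.ndarray,
                      background_gain_factor: float = 1.0) -> np.ndarray:
    signal = np.zeros_like(grid)
    for spec in profile.band_specs:
        signal += spec.trajectory(hour) * band_profile(spec.center_at(hour), spec.width, grid)
    signal += profile.background.level(hour, background_gain_factor) * profile.background.shape(grid)
    return signal


def generate_spectrum(
    profile: DonorProfile,
    hour: float,
    spot: int,
    grid,
    rng: np.random.Generator,
) -> RamanSpectrum:
    """Draw one map-spot spectrum at ``hour`` h post-deposition.

    With probability ``profile.outlier_rate`` the spectrum is replaced
    by a saturated-background outlier (background >= 20x the median band
    amplitude) and flagged ``"saturated"``.
    """
    if hour < 0:
        raise ValueError("hour must be >= 0")
    grid = np.asarray(grid, float)
    flags: set = set()

    is_outlier = rng.random() < profile.outlier_rate
    jitter = float(np.exp(rng.normal(0.0, profile.noise.background_jitter_sd)))
    spot_gain = float(np.exp(rng.normal(0.0, profile.noise.spot_scale_sd)))

    signal = np.zeros_like(grid)
    for spec in profile.band_specs:
        signal += spec.trajectory(hour) * band_profile(spec.center_at(hour), spec.width, grid)
    if is_outlier:
        med_amp = float(np.median([spec.trajectory(hour) for spec in profile.band_specs]))
        level = 50.0 * max(med_amp, 1.0)
        flags.add("saturated")
        flags.add("outlier")
    else:
        level = profile.background.level(hour, jitter)
    signal += level * profile.background.shape(grid)

    intensity = spot_gain * signal
    if profile.noise.sigma_rel > 0:
        intensity = intensity * (1.0 + rng.normal(0.0, profile.noise.sigma_rel, grid.size))
    intensity = np.clip(intensity, 0.0, None)  # counts cannot go negative

    return RamanSpectrum(
        grid, intensity, SpectrumMeta(profile.donor_id, float(hour), int(spot), flags)
    )


def generate_dataset(config: GeneratorConfig) -> SpectraDataset:
    """Generate |donors| x |schedule| x spots_per_map spectra.

    A single generator seeded from ``config.seed`` drives all randomness;
    donor, hour, and spot order is fixed, so identical configs give
    identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    spectra = []
    for profile in config.donors:
        for hour in config.schedule:
            for spot in range(config.spots_per_map):
                spectra.append(generate_spectrum(profile, hour, spot, config.grid, rng))
    return SpectraDataset(spectra)


def noiseless_spectrum(profile: DonorProfile, hour: float, grid) -> RamanSpectrum:
    """Expected (noise-free, unit-gain, mean-jitter-free) spectrum."""
    grid = np.asarray(grid, float)
    return RamanSpectrum(
        grid, _noiseless_signal(profile, hour, grid), SpectrumMeta(profile.donor_id, hour, -1)
    )


# ---------------------------------------------------------------------------
# Config serialization (YAML/JSON document mirroring GeneratorConfig)

def config_to_dict(config: GeneratorConfig) -> dict:
    def spec_dict(s: BandKineticsSpec) -> dict:
        d = {
            "center": s.center,
            "width": s.width,
            "assignment": s.assignment,
            "A": s.A,
            "t1": s.t1,
            "y0": s.y0,
        }
        if s.center_shift is not None:
            d["center_shift"] = dataclasses.asdict(s.center_shift)
        return d

    return {
        "schedule": list(config.schedule),
        "spots_per_map": config.spots_per_map,
        "grid": {
            "low": float(config.grid[0]),
            "high": float(config.grid[-1]),
            "step": float(config.grid[1] - config.grid[0]),
        },
        "seed": config.seed,
        "donors": [
            {
                "donor_id": p.donor_id,
                "outlier_rate": p.outlier_rate,
                "background": dataclasses.asdict(p.background),
                "noise": dataclasses.asdict(p.noise),
                "bands": [spec_dict(s) for s in p.band_specs],
            }
            for p in config.donors
        ],
    }


def config_from_dict(doc: dict) -> GeneratorConfig:
    donors = []
    for pd in doc["donors"]:
        specs = []
        for sd in pd["bands"]:
            shift = sd.get("center_shift")
            specs.append(
                BandKineticsSpec(
                    center=float(sd["center"]),
                    width=float(sd.get("width", 8.0)),
                    assignment=sd.get("assignment", ""),
                    A=float(sd.get("A", 0.0)),
                    t1=float(sd.get("t1", 1.0)),
                    y0=float(sd.get("y0", 1.0)),
                    center_shift=CenterShift(**shift) if shift else None,
                )
            )
        donors.append(
            DonorProfile(
                donor_id=pd["donor_id"],
                band_specs=specs,
                background=BackgroundModel(**pd.get("background", {})),
                noise=NoiseModel(**pd.get("noise", {})),
                outlier_rate=float(pd.get("outlier_rate", 0.0)),
            )
        )
    g = doc.get("grid", {})
    grid = default_grid(g.get("low", 300.0), g.get("high", 1800.0), g.get("step", 1.0))
    return GeneratorConfig(
        donors=donors,
        schedule=tuple(float(h) for h in doc.get("schedule", DEFAULT_SCHEDULE)),
        spots_per_map=int(doc.get("spots_per_map", 12)),
        grid=grid,
        seed=int(doc.get("seed", 0)),
    )
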