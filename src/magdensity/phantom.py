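"""Digital breast phantom and multi-echo gradient-echo simulator.

The phantom is a voxelized bilateral breast: two half-ellipsoid breasts in
prone, axial orientation attached to a chest-wall slab containing pectoral
muscle, with a skin shell and a subcutaneous fat layer.  Tissue labels drive
per-voxel true water/fat volume fractions; a smooth low-order polynomial
field map emulates B0 inhomogeneity.

The simulator produces the complex multi-echo signal of a spoiled
gradient-echo acquisition under a single-peak fat model (-3.4 ppm).  The
fat-water signal bias that the downstream correction removes is injected
through three mechanisms: proton-density differences, T1 saturation
(steady-state weighting at the scanner's flip angle and TR), and residual
water in adipose tissue.  Constant and linear (per-echo-index) phase errors
and complex Gaussian noise complete the model.

Axis convention: (x, y, z) = (left-right, anterior-posterior, head-foot),
0-based voxel indices; breasts extend toward low y (anterior).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError, SizingError

__all__ = [
    "GYROMAGNETIC_RATIO_MHZ_PER_T",
    "FAT_CHEMICAL_SHIFT_PPM",
    "LABELS",
    "ScannerProfile",
    "BreastPhantom",
    "EchoSeries",
    "fat_frequency_offset_hz",
    "scanner_presets",
    "steady_state_weight",
    "make_phantom",
    "signal_amplitudes",
    "implied_correction_factors",
    "simulate_echoes",
    "cohort_simulate",
]

GYROMAGNETIC_RATIO_MHZ_PER_T = 42.577
FAT_CHEMICAL_SHIFT_PPM = -3.4

#: Tissue label codes used in :attr:`BreastPhantom.labels`.
LABELS = {
    "air": 0,
    "adipose": 1,
    "fibroglandular": 2,
    "pectoral_muscle": 3,
    "skin": 4,
}

#: Residual water volume fraction assumed in adipose tissue.  Shared by the
#: phantom truth and every scanner preset so the implied correction factors
#: are mutually consistent.
DEFAULT_ADIPOSE_RESIDUAL_WATER = 0.10


@dataclass(frozen=True)
class ScannerProfile:
    """Acquisition and signal-bias parameters for one scanner.

    Echo times are in ms, T1s in ms, repetition_time in ms, field strength
    in tesla, flip angle in degrees, r2star in 1/s.  ``noise_sd`` is the
    standard deviation of the complex Gaussian noise on each of the real and
    imaginary channels, relative to the unit amplitude of pure water tissue.
    ``phase0``/``phase1`` are the constant and per-echo-index phase errors in
    radians.
    """

    name: str
    field_strength: float
    echo_times: tuple[float, ...]
    flip_angle: float
    repetition_time: float
    voxel_size: tuple[float, float, float]
    fat_t1: float
    water_t1: float
    fat_proton_density: float = 1.0
    water_proton_density: float = 1.0
    adipose_residual_water: float = DEFAULT_ADIPOSE_RESIDUAL_WATER
    phase0: float = 0.0
    phase1: float = 0.0
    noise_sd: float = 0.0
    r2star: float = 0.0

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times, dtype=float)
        if te.size < 3:
            raise DomainError(f"need at least 3 echoes, got {te.size}")
        if np.any(np.diff(te) <= 0):
            raise DomainError("echo_times must be strictly increasing")
        if self.field_strength <= 0:
            raise DomainError("field_strength must be positive")
        if not 0 < self.flip_angle <= 90:
            raise DomainError("flip_angle must be in (0, 90] degrees")
        if not 0 <= self.adipose_residual_water < 0.5:
            raise DomainError("adipose_residual_water must be in [0, 0.5)")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        object.__setattr__(self, "echo_times", tuple(float(t) for t in te))

    @property
    def echo_times_s(self) -> np.ndarray:
        return np.asarray(self.echo_times, dtype=float) * 1e-3

    @property
    def fat_offset_hz(self) -> float:
        return fat_frequency_offset_hz(self.field_strength)

    def with_(self, **kwargs) -> "ScannerProfile":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def fat_frequency_offset_hz(field_strength: float) -> float:
    """Chemical-shift frequency of the single fat peak relative to water.

    -3.4 ppm at 42.577 MHz/T; about -217 Hz at 1.5 T, -434 Hz at 3 T.
    """
    if field_strength <= 0:
        raise DomainError("field_strength must be positive")
    return FAT_CHEMICAL_SHIFT_PPM * 1e-6 * GYROMAGNETIC_RATIO_MHZ_PER_T * 1e6 * field_strength


def scanner_presets() -> dict[str, ScannerProfile]:
    """The three study scanner configurations.

    Acquisition timing follows the clinical protocols: the two 3T Siemens
    systems ("prisma", "mmr") share a six-echo GRE with TEs
    1.37..8.81 ms, flip 6 deg, TR 21.0 ms; the 1.5T GE system ("signa") uses
    TEs 2.88..18.66 ms, flip 12 deg, TR 22.4 ms.

    Bias parameters are simulation presets: T1s appropriate to each field
    strength, unit proton densities for the Siemens pair, and a reduced
    effective water proton density for "signa" so that its *uncorrected*
    density readings sit a few percentage points away from the Siemens pair
    - an emulation of the cross-vendor bias scale, not a hardware claim.
    Small, distinct echo-phase errors are included per scanner; noise is off
    by default and set explicitly by callers.
    """
    siemens_te = (1.37, 2.66, 4.92, 6.15, 7.38, 8.81)
    prisma = ScannerProfile(
        name="prisma",
        field_strength=3.0,
        echo_times=siemens_te,
        flip_angle=6.0,
        repetition_time=21.0,
        voxel_size=(1.97, 1.97, 4.0),
        fat_t1=385.0,
        water_t1=1450.0,
        phase0=0.10,
        phase1=0.02,
    )
    mmr = ScannerProfile(
        name="mmr",
        field_strength=3.0,
        echo_times=siemens_te,
        flip_angle=6.0,
        repetition_time=21.0,
        voxel_size=(1.97, 1.97, 4.0),
        fat_t1=385.0,
        water_t1=1450.0,
        phase0=-0.15,
        phase1=0.03,
    )
    signa = ScannerProfile(
        name="signa",
        field_strength=1.5,
        echo_times=(2.88, 6.04, 9.20, 12.35, 15.51, 18.66),
        flip_angle=12.0,
        repetition_time=22.4,
        voxel_size=(0.625, 0.625, 2.0),
        fat_t1=365.0,
        water_t1=1300.0,
        water_proton_density=0.35,
        phase0=0.30,
        phase1=-0.05,
    )
    return {"prisma": prisma, "mmr": mmr, "signa": signa}


def steady_state_weight(t1: float, profile: ScannerProfile) -> float:
    """Spoiled-GRE steady-state amplitude factor for a tissue of given T1.

    ``sin(a) * (1 - E1) / (1 - cos(a) * E1)`` with ``E1 = exp(-TR/T1)``:
    the mechanism by which T1 differences between fat and water bias the
    measured fat fraction.  Monotone decreasing in T1; tends to sin(a) as
    T1 -> 0.
    """
    if t1 <= 0:
        raise DomainError("t1 must be positive")
    alpha = np.deg2rad(profile.flip_angle)
    e1 = np.exp(-profile.repetition_time / t1)
    return float(np.sin(alpha) * (1.0 - e1) / (1.0 - np.cos(alpha) * e1))


@dataclass
class BreastPhantom:
    """Voxelized bilateral breast anatomy with ground truth.

    ``v_water_true`` holds the true volumetric water fraction per voxel
    (V_fat = 1 - V_water).  ``breast_mask_*`` cover the breast interior (the
    region a whole-breast segmentation would analyze), excluding the skin
    shell and the subcutaneous fat layer; the latter provides the "pure fat"
    reference ROI, and a block of pectoral muscle the "pure water" one.
    """

    labels: np.ndarray
    v_water_true: np.ndarray
    breast_mask_left: np.ndarray
    breast_mask_right: np.ndarray
    ref_fat_roi: np.ndarray
    ref_water_roi: np.ndarray
    field_map_true: np.ndarray
    seed: int
    adipose_residual_water: float = DEFAULT_ADIPOSE_RESIDUAL_WATER
    fibroglandular_fraction: float = float("nan")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def breast_mask(self) -> np.ndarray:
        return self.breast_mask_left | self.breast_mask_right

    def true_density_percent(self, side: str) -> float:
        """Realized fibroglandular voxel fraction inside one breast mask (%)."""
        mask = {"L": self.breast_mask_left, "R": self.breast_mask_right}[side]
        if not mask.any():
            raise DomainError(f"empty breast mask for side {side!r}")
        fg = self.labels[mask] == LABELS["fibroglandular"]
        return 100.0 * float(fg.mean())


@dataclass
class EchoSeries:
    """4-D complex multi-echo volume (x, y, z, echo) with echo times in ms."""

    data: np.ndarray
    echo_times: tuple[float, ...]
    scanner_name: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.echo_times = tuple(float(t) for t in self.echo_times)
        if self.data.ndim != 4:
            raise SizingError(f"echo data must be 4-D, got {self.data.ndim}-D")
        if self.data.shape[3] != len(self.echo_times):
            raise SizingError(
                f"echo axis length {self.data.shape[3]} != "
                f"{len(self.echo_times)} echo times"
            )
        if not (
            np.all(np.isfinite(self.data.real))
            and np.all(np.isfinite(self.data.imag))
        ):
            raise DomainError("echo data contains non-finite values")

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times)

    @property
    def echo_times_s(self) -> np.ndarray:
        return np.asarray(self.echo_times) * 1e-3


def _half_ellipsoid_mask(
    shape: tuple[int, int, int],
    center_x: float,
    chest_y: float,
    center_z: float,
    semi: tuple[float, float, float],
) -> np.ndarray:
    """Half ellipsoid extending anteriorly (toward y=0) from the chest wall."""
    x, y, z = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    r2 = (
        ((x - center_x) / semi[0]) ** 2
        + ((y - chest_y) / semi[1]) ** 2
        + ((z - center_z) / semi[2]) ** 2
    )
    return (r2 <= 1.0) & (y <= chest_y)


def make_phantom(
    shape: tuple[int, int, int],
    fibroglandular_fraction: float,
    seed: int,
    *,
    adipose_residual_water: float = DEFAULT_ADIPOSE_RESIDUAL_WATER,
    field_map_peak_hz: float = 30.0,
    fraction_right: float | None = None,
) -> BreastPhantom:
    """Build a bilateral breast phantom with a target fibroglandular fraction.

    Inside each breast interior, voxels are split between fibroglandular and
    adipose tissue by thresholding a smooth random texture at the quantile
    that realizes ``fibroglandular_fraction`` (so the realized fraction
    matches the target up to voxel rounding).  ``fraction_right`` optionally
    gives the right breast its own target.  Deterministic given ``seed``.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 8 for s in shape):
        raise SizingError(f"each grid extent must be >= 8, got {shape}")
    for frac in (fibroglandular_fraction, fraction_right):
        if frac is not None and not 0.0 <= frac <= 1.0:
            raise DomainError(f"fibroglandular fraction {frac} outside [0, 1]")
    if not 0.0 <= adipose_residual_water < 0.5:
        raise DomainError("adipose_residual_water must be in [0, 0.5)")

    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    labels = np.full(shape, LABELS["air"], dtype=np.uint8)

    # Chest wall: posterior ~20% of the AP extent; pectoral muscle inside it.
    chest_y = int(round(0.78 * (ny - 1)))
    labels[:, chest_y:, :] = LABELS["pectoral_muscle"]

    semi = (0.30 * nx, 0.72 * chest_y, 0.46 * nz)
    centers = {"R": 0.27 * (nx - 1), "L": 0.73 * (nx - 1)}
    cz = 0.5 * (nz - 1)
    breast = {
        side: _half_ellipsoid_mask(shape, cx, chest_y, cz, semi)
        for side, cx in centers.items()
    }

    # Shell thicknesses in voxels along the smallest breast semi-axis.
    from scipy import ndimage

    masks_interior: dict[str, np.ndarray] = {}
    targets = {
        "L": fibroglandular_fraction,
        "R": fibroglandular_fraction if fraction_right is None else fraction_right,
    }
    ref_fat = np.zeros(shape, dtype=bool)
    for side, bmask in breast.items():
        bmask = bmask & (labels == LABELS["air"])  # do not overwrite chest wall
        skin = bmask & ~ndimage.binary_erosion(bmask, iterations=1)
        subq = bmask & ~skin
        interior = ndimage.binary_erosion(subq, iterations=2)
        subq = subq & ~interior
        labels[skin] = LABELS["skin"]
        labels[subq] = LABELS["adipose"]
        ref_fat |= subq
        masks_interior[side] = interior

        n_in = int(interior.sum())
        if n_in == 0:
            raise SizingError("grid too small: empty breast interior")
        # Smooth texture biased toward the breast center so fibroglandular
        # tissue clusters centrally, as in real anatomy.
        noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.0)
        dist = ndimage.distance_transform_edt(interior)
        texture = noise + 0.8 * dist / max(dist.max(), 1.0)
        vals = texture[interior]
        frac = targets[side]
        if frac >= 1.0:
            fg_sel = np.ones(n_in, dtype=bool)
        elif frac <= 0.0:
            fg_sel = np.zeros(n_in, dtype=bool)
        else:
            k = int(round(frac * n_in))
            order = np.argsort(vals)  # ascending; take top-k as fibroglandular
            fg_sel = np.zeros(n_in, dtype=bool)
            if k > 0:
                fg_sel[order[n_in - k:]] = True
        inside = np.where(interior.reshape(-1))[0]
        flat = labels.reshape(-1)
        flat[inside[fg_sel]] = LABELS["fibroglandular"]
        flat[inside[~fg_sel]] = LABELS["adipose"]

    # Pure-water reference: a muscle block behind the breasts, away from edges.
    ref_water = np.zeros(shape, dtype=bool)
    y0 = chest_y + max(1, (ny - chest_y) // 4)
    y1 = min(ny, y0 + max(2, (ny - chest_y) // 2))
    x0, x1 = int(0.3 * nx), int(0.7 * nx)
    z0, z1 = max(0, nz // 4), min(nz, 3 * nz // 4)
    ref_water[x0:x1, y0:y1, z0:z1] = True
    ref_water &= labels == LABELS["pectoral_muscle"]
    if not ref_water.any() or not ref_fat.any():
        raise SizingError("grid too small to carve reference ROIs")

    v_water = np.zeros(shape, dtype=float)
    v_water[labels == LABELS["fibroglandular"]] = 1.0
    v_water[labels == LABELS["pectoral_muscle"]] = 1.0
    v_water[labels == LABELS["skin"]] = 1.0
    v_water[labels == LABELS["adipose"]] = adipose_residual_water

    # Smooth B0 field: low-order polynomial in normalized coordinates with
    # random coefficients, rescaled to the requested peak magnitude.
    xs = np.linspace(-1, 1, nx)[:, None, None]
    ys = np.linspace(-1, 1, ny)[None, :, None]
    zs = np.linspace(-1, 1, nz)[None, None, :]
    coef = rng.uniform(-1, 1, size=7)
    psi = (
        coef[0]
        + coef[1] * xs
        + coef[2] * ys
        + coef[3] * zs
        + coef[4] * xs * ys
        + coef[5] * xs**2
        + coef[6] * ys**2
    )
    peak = np.abs(psi).max()
    if peak > 0:
        psi = psi / peak * field_map_peak_hz
    psi = np.broadcast_to(psi, shape).astype(float).copy()

    return BreastPhantom(
        labels=labels,
        v_water_true=v_water,
        breast_mask_left=masks_interior["L"],
        breast_mask_right=masks_interior["R"],
        ref_fat_roi=ref_fat,
        ref_water_roi=ref_water,
        field_map_true=psi,
        seed=int(seed),
        adipose_residual_water=adipose_residual_water,
        fibroglandular_fraction=fibroglandular_fraction,
    )


def signal_amplitudes(
    phantom: BreastPhantom, profile: ScannerProfile
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel water and fat signal amplitudes (A_w, A_f).

    Amplitude = volume fraction x proton density x steady-state weight,
    normalized by the water steady-state weight so that pure water tissue
    has unit amplitude (making ``noise_sd`` a fraction of unit signal).
    """
    w_water = steady_state_weight(profile.water_t1, profile)
    w_fat = steady_state_weight(profile.fat_t1, profile)
    v_w = phantom.v_water_true
    tissue = phantom.labels != LABELS["air"]
    a_w = np.where(tissue, v_w * profile.water_proton_density, 0.0)
    a_f = np.where(
        tissue, (1.0 - v_w) * profile.fat_proton_density * (w_fat / w_water), 0.0
    )
    return a_w, a_f


def implied_correction_factors(profile: ScannerProfile) -> tuple[float, float]:
    """Theoretical reference fat-fraction values (a*, b*) under a profile.

    a* is the noiseless fat signal fraction of adipose tissue containing the
    profile's residual water; b* that of pure water tissue (exactly 0 under
    the single-peak model with no fat in muscle).  These are the values the
    per-image correction-factor estimation should recover.
    """
    w = profile.adipose_residual_water
    w_water = steady_state_weight(profile.water_t1, profile)
    w_fat = steady_state_weight(profile.fat_t1, profile)
    a_f = (1.0 - w) * profile.fat_proton_density * w_fat
    a_w = w * profile.water_proton_density * w_water
    return a_f / (a_f + a_w), 0.0


def simulate_echoes(
    phantom: BreastPhantom, profile: ScannerProfile, seed: int
) -> EchoSeries:
    """Simulate the complex multi-echo spoiled-GRE signal of a phantom.

    Per voxel and echo n:

        S_n = (A_w + A_f exp(i 2 pi df_fat TE_n)) exp(i 2 pi psi TE_n)
              exp(-TE_n r2*) exp(i (phase0 + phase1 n)) + noise

    with TE in seconds, df_fat the chemical-shift offset from the profile's
    field strength, psi the phantom's true field map (Hz), and complex
    Gaussian noise of standard deviation ``profile.noise_sd`` per channel.
    Deterministic given ``seed``.
    """
    if phantom.field_map_true.shape != phantom.labels.shape:
        raise SizingError("phantom grids are inconsistent")
    a_w, a_f = signal_amplitudes(phantom, profile)
    te = profile.echo_times_s  # (N,)
    df = profile.fat_offset_hz
    psi = phantom.field_map_true[..., None]

    fat_mod = np.exp(2j * np.pi * df * te)  # (N,)
    signal = (a_w[..., None] + a_f[..., None] * fat_mod) * np.exp(
        2j * np.pi * psi * te
    )
    if profile.r2star:
        signal = signal * np.exp(-te * profile.r2star)
    n_idx = np.arange(te.size)
    signal = signal * np.exp(1j * (profile.phase0 + profile.phase1 * n_idx))

    if profile.noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, profile.noise_sd, size=signal.shape + (2,))
        signal = signal + noise[..., 0] + 1j * noise[..., 1]

    return EchoSeries(
        data=np.ascontiguousarray(signal),
        echo_times=profile.echo_times,
        scanner_name=profile.name,
        provenance=f"simulated phantom seed={phantom.seed} noise seed={seed}",
    )


@dataclass
class CohortSubject:
    """One simulated subject: phantom plus an echo series per scanner."""

    subject_id: str
    phantom: BreastPhantom
    series: dict[str, EchoSeries] = field(default_factory=dict)


def cohort_simulate(
    n_subjects: int,
    profiles: Mapping[str, ScannerProfile] | Iterable[ScannerProfile],
    density_range: tuple[float, float] = (40.0, 80.0),
    seed: int = 0,
    *,
    shape: tuple[int, int, int] = (64, 64, 16),
    side_jitter_percent: float = 1.5,
) -> tuple[list[CohortSubject], pd.DataFrame]:
    """Simulate a cohort imaged on every scanner, with a ground-truth table.

    Each subject receives a target density drawn uniformly from
    ``density_range`` (percent); left and right breasts get independently
    jittered targets (sd ``side_jitter_percent``) to mimic natural left-right
    asymmetry.  The truth table has one row per (subject, side, scanner) with
    the realized fibroglandular percentage of that breast mask.
    """
    if n_subjects < 2:
        raise DomainError("n_subjects must be >= 2")
    if not isinstance(profiles, Mapping):
        profiles = {p.name: p for p in profiles}
    if not profiles:
        raise ConfigError("empty profile set")
    lo, hi = density_range
    if not 0 <= lo <= hi <= 100:
        raise DomainError(f"density_range {density_range} outside [0, 100]")

    rng = np.random.default_rng(seed)
    subjects: list[CohortSubject] = []
    rows = []
    for i in range(n_subjects):
        target = rng.uniform(lo, hi)
        f_left = float(np.clip(target + rng.normal(0, side_jitter_percent), lo, hi))
        f_right = float(np.clip(target + rng.normal(0, side_jitter_percent), lo, hi))
        phantom_seed = int(rng.integers(0, 2**31 - 1))
        phantom = make_phantom(
            shape, f_left / 100.0, phantom_seed, fraction_right=f_right / 100.0
        )
        subject = CohortSubject(subject_id=f"S{i + 1:02d}", phantom=phantom)
        for name, profile in profiles.items():
            noise_seed = int(rng.integers(0, 2**31 - 1))
            subject.series[name] = simulate_echoes(phantom, profile, noise_seed)
        subjects.append(subject)
        for name in profiles:
            for side in ("L", "R"):
                rows.append(
                    {
                        "subject_id": subject.subject_id,
                        "side": side,
                        "scanner": name,
                        "true_density_percent": phantom.true_density_percent(side),
                    }
                )
    truth = pd.DataFrame(rows)
    return subjects, truth
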