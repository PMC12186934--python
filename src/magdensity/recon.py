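"""Fat-water reconstruction: complex image formation, echo-phase correction,
and IDEAL decomposition.

The IDEAL solver alternates, per voxel, between (a) complex least squares
for the water/fat amplitudes given the off-resonance field psi, using the
design matrix with rows ``(1, exp(i 2 pi df_fat TE_n))`` after demodulating
``exp(i 2 pi psi TE_n)``, and (b) a Gauss-Newton (variable-projection)
update of psi.  To resolve the fat-water swap ambiguity, the solve is run
from two field-map starts (0 and df_fat/2) and the lower-residual solution
wins, with ties broken toward smaller |psi|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .errors import ConditioningError, DomainError, SizingError
from .phantom import EchoSeries, ScannerProfile

__all__ = [
    "FatWaterMaps",
    "combine_mag_phase",
    "estimate_echo_phase",
    "apply_phase_correction",
    "ideal_decompose",
    "fat_fraction_map",
]


@dataclass
class FatWaterMaps:
    """Water/fat magnitude, field-map and fat-fraction volumes.

    ``fat_fraction`` is S_fat/(S_fat+S_water) in [0, 1]; voxels with zero
    total signal are flagged NaN (invalid) and excluded downstream.
    """

    water: np.ndarray
    fat: np.ndarray
    field_map: np.ndarray
    fat_fraction: np.ndarray
    iterations_used: np.ndarray
    residual: np.ndarray | None = None

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.fat_fraction)


def combine_mag_phase(
    magnitude: np.ndarray,
    phase: np.ndarray,
    echo_times,
    scanner_name: str = "",
) -> EchoSeries:
    """Combine magnitude and phase stacks into a complex echo series."""
    magnitude = np.asarray(magnitude, dtype=float)
    phase = np.asarray(phase, dtype=float)
    if magnitude.shape != phase.shape:
        raise SizingError(
            f"magnitude {magnitude.shape} and phase {phase.shape} differ"
        )
    if np.any(magnitude < 0):
        raise DomainError("magnitude must be non-negative")
    data = magnitude * np.exp(1j * phase)
    return EchoSeries(
        data=data,
        echo_times=echo_times,
        scanner_name=scanner_name,
        provenance="combined from magnitude+phase",
    )


def _real_design(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Real-stacked design for non-negative real (A_w, A_f) amplitudes.

    Rows are [Re; Im] of the model ``A_w + A_f c_n``; returns (G, H) with
    H = (G^T G)^{-1} G^T so that amplitudes = y @ H^T for stacked data y.
    """
    n = c.size
    g = np.zeros((2 * n, 2))
    g[:n, 0] = 1.0
    g[:n, 1] = c.real
    g[n:, 1] = c.imag
    gtg = g.T @ g
    if np.linalg.cond(gtg) > 1e10:
        raise ConditioningError(
            "echo times leave fat and water indistinguishable (all in-phase)"
        )
    h = np.linalg.solve(gtg, g.T)
    return g, h


def _stack(d: np.ndarray) -> np.ndarray:
    return np.concatenate([d.real, d.imag], axis=-1)


def _real_amplitude_fit(
    s: np.ndarray,
    te_s: np.ndarray,
    c: np.ndarray,
    g: np.ndarray,
    h: np.ndarray,
    psi0: np.ndarray,
    n_iter: int = 30,
    psi_clip: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit real amplitudes + per-voxel field to complex data (V, N).

    Used by the echo-phase estimator: constraining the amplitudes to be real
    is what makes a global constant phase identifiable at all.  With
    ``psi_clip`` the field iterate is confined to the unambiguous window,
    keeping near-pure voxels off the fat-water swap branches.  Returns
    (amplitudes (V,2), psi (V,), stacked residual (V, 2N)).
    """
    psi = psi0.copy()
    for _ in range(n_iter):
        d = s * np.exp(-2j * np.pi * psi[:, None] * te_s)
        y = _stack(d)
        x = y @ h.T  # (V, 2)
        m = x @ g.T
        r = y - m
        u = _stack(-2j * np.pi * te_s * d)
        pu = u - (u @ h.T) @ g.T
        denom = np.einsum("vk,vk->v", pu, pu)
        num = np.einsum("vk,vk->v", pu, r)
        step = np.where(denom > 1e-30, -num / np.maximum(denom, 1e-30), 0.0)
        psi = psi + step
        if psi_clip is not None:
            psi = np.clip(psi, -psi_clip, psi_clip)
    d = s * np.exp(-2j * np.pi * psi[:, None] * te_s)
    y = _stack(d)
    x = y @ h.T
    r = y - x @ g.T
    return x, psi, r


def estimate_echo_phase(
    series: EchoSeries,
    mask: np.ndarray | None = None,
    profile: ScannerProfile | None = None,
    *,
    fat_offset_hz: float | None = None,
    max_voxels: int = 1500,
) -> tuple[float, float]:
    """Estimate the shared constant and linear echo-phase error.

    Fits, by nonlinear least squares over (phase0, phase1), a model in which
    every voxel is a real-amplitude water/fat pair with its own off-resonance
    frequency, while all voxels share one constant plus per-echo-index linear
    phase.  The fit runs on the highest-magnitude voxels (top decile by
    default, capped at ``max_voxels``).  Either ``profile`` or
    ``fat_offset_hz`` must supply the chemical-shift offset.
    """
    if series.n_echoes < 3:
        raise DomainError("need at least 3 echoes")
    if fat_offset_hz is None:
        if profile is None:
            raise DomainError("provide profile or fat_offset_hz")
        fat_offset_hz = profile.fat_offset_hz
    mag = np.abs(series.data).mean(axis=-1)
    if mask is None:
        nz = mag[mag > 0]
        if nz.size == 0:
            raise DomainError("series has no signal")
        mask = mag >= np.quantile(nz, 0.9)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != mag.shape:
            raise SizingError("mask shape does not match series grid")
        if not mask.any():
            raise DomainError("empty mask")

    s_all = series.data[mask]
    if s_all.shape[0] > max_voxels:
        order = np.argsort(mag[mask])[::-1][:max_voxels]
        s_all = s_all[order]
    te_s = series.echo_times_s
    c = np.exp(2j * np.pi * fat_offset_hz * te_s)
    g, h = _real_design(c)
    n_idx = np.arange(te_s.size)
    psi0 = np.zeros(s_all.shape[0])
    bound = swap_ambiguity_radius_hz(te_s, fat_offset_hz)

    def residuals(params: np.ndarray) -> np.ndarray:
        p0, p1 = params
        corrected = s_all * np.exp(-1j * (p0 + p1 * n_idx))
        _, _, r = _real_amplitude_fit(
            corrected, te_s, c, g, h, psi0, psi_clip=bound
        )
        return r.ravel()

    fit = optimize.least_squares(
        residuals, x0=np.zeros(2), method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15
    )
    p0, p1 = fit.x
    # Wrap the constant phase into (-pi, pi].
    p0 = float(np.angle(np.exp(1j * p0)))
    return p0, float(p1)


def apply_phase_correction(
    series: EchoSeries, phase0: float, phase1: float
) -> EchoSeries:
    """Remove a constant + linear-in-echo-index phase: echo n is multiplied
    by ``exp(-i (phase0 + phase1 n))``.  Magnitudes are unchanged."""
    if not (np.isfinite(phase0) and np.isfinite(phase1)):
        raise DomainError("phase parameters must be finite")
    n_idx = np.arange(series.n_echoes)
    corr = np.exp(-1j * (phase0 + phase1 * n_idx))
    return EchoSeries(
        data=series.data * corr,
        echo_times=series.echo_times,
        scanner_name=series.scanner_name,
        provenance=series.provenance
        + f"; phase corrected (phi0={phase0:.4g}, phi1={phase1:.4g})",
    )


def swap_ambiguity_radius_hz(te_s: np.ndarray, fat_offset_hz: float) -> float:
    """Half the field-map distance to the nearest fat-water swap branch.

    Swapped solutions live at offsets ``df_fat + k / mean(delta TE)``
    (k integer) from the true field; the closest of these sets the radius of
    the window in which the fat-water assignment is unique.
    """
    dte = float(np.mean(np.diff(te_s)))
    k = np.arange(-4, 5)
    gaps = np.abs(fat_offset_hz + k / dte)
    return float(gaps.min()) / 2.0


def _ideal_iterate(
    s: np.ndarray,
    te_s: np.ndarray,
    a: np.ndarray,
    pinv_a: np.ndarray,
    psi_init: float | np.ndarray,
    tol_hz: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run the alternating IDEAL iteration from one psi start.

    s: (V, N) complex.  Returns (amplitudes (V,2) complex, psi (V,),
    residual norm^2 (V,), iterations used (V,)).
    """
    v = s.shape[0]
    psi = (
        np.asarray(psi_init, dtype=float).copy()
        if np.ndim(psi_init)
        else np.full(v, float(psi_init))
    )
    iters = np.full(v, max_iter, dtype=np.int32)
    active = np.ones(v, dtype=bool)
    for it in range(max_iter):
        idx = np.where(active)[0]
        if idx.size == 0:
            break
        d = s[idx] * np.exp(-2j * np.pi * psi[idx, None] * te_s)
        x = d @ pinv_a.T  # (v, 2)
        m = x @ a.T
        r = d - m
        u = -2j * np.pi * te_s * d
        pu = u - (u @ pinv_a.T) @ a.T
        denom = np.einsum("vn,vn->v", pu.conj(), pu).real
        num = np.einsum("vn,vn->v", pu.conj(), r).real
        step = np.where(denom > 1e-30, -num / np.maximum(denom, 1e-30), 0.0)
        psi[idx] = psi[idx] + step
        done = np.abs(step) < tol_hz
        iters[idx[done]] = it + 1
        active[idx[done]] = False
    d = s * np.exp(-2j * np.pi * psi[:, None] * te_s)
    x = d @ pinv_a.T
    r = d - x @ a.T
    res2 = np.einsum("vn,vn->v", r.conj(), r).real
    return x, psi, res2, iters


def ideal_decompose(
    series: EchoSeries,
    profile: ScannerProfile,
    *,
    tol_hz: float = 0.01,
    max_iter: int = 50,
    smooth_sigma: float = 0.0,
    n_sweeps: int = 1,
    psi_starts: tuple[float, ...] | None = None,
    psi_bound_hz: float | None = None,
    out_window_ratio: float = 0.1,
) -> FatWaterMaps:
    """IDEAL fat-water decomposition of a multi-echo complex series.

    Per voxel, alternates complex least squares for (water, fat) given the
    field psi with a linearized psi update, until |delta psi| < ``tol_hz``
    or ``max_iter``.  Candidate solutions from the starts in ``psi_starts``
    (default 0 and df_fat/2) are compared by residual; the lower residual
    wins, ties go to smaller |psi|.  With ``smooth_sigma`` > 0 and
    ``n_sweeps`` > 1, the field map is Gaussian-smoothed between sweeps.

    Fat-water swap guard: a pure-fat voxel at field psi produces (nearly)
    the same signal as pure water at a field shifted by df_fat plus any
    multiple of the spectral alias 1/mean(delta TE), and with near-uniformly
    spaced echoes noise alone can decide the residual comparison between the
    true solution and the nearest such swap branch.  Candidates with |psi|
    inside ``psi_bound_hz`` - defaulting to half the distance to the nearest
    swap alias, the largest window in which the species assignment is
    unique - are therefore preferred over out-of-window ones unless the
    out-of-window residual is decisively lower (smaller than
    ``out_window_ratio`` times the in-window residual, as for noiseless
    data whose true field lies beyond the window); under noise the two
    branches differ in residual only at the noise scale, so residual alone
    cannot be trusted across the window boundary.
    """
    if series.n_echoes < 3:
        raise DomainError("need at least 3 echoes")
    te_s = series.echo_times_s
    df = profile.fat_offset_hz
    c = np.exp(2j * np.pi * df * te_s)
    a = np.stack([np.ones_like(c), c], axis=1)  # (N, 2)
    if np.linalg.cond(a) > 1e8:
        raise ConditioningError(
            "echo configuration is numerically singular for fat-water separation"
        )
    pinv_a = np.linalg.pinv(a)

    shape = series.data.shape[:3]
    s = series.data.reshape(-1, series.n_echoes)
    if psi_bound_hz is None:
        psi_bound_hz = swap_ambiguity_radius_hz(te_s, df)
    if psi_starts is None:
        # 0 and df/2 probe the two species assignments; the window-edge
        # starts reach true fields whose basin of attraction excludes 0.
        psi_starts = (0.0, df / 2.0, psi_bound_hz, -psi_bound_hz)

    best = None
    for start in psi_starts:
        x, psi, res2, iters = _ideal_iterate(
            s, te_s, a, pinv_a, start, tol_hz, max_iter
        )
        in_window = np.abs(psi) <= psi_bound_hz
        if best is None:
            best = [x, psi, res2, iters, in_window]
        else:
            bx, bpsi, bres2, biters, bwin = best
            lower = res2 < bres2 * (1.0 - 1e-9)
            tie = np.abs(res2 - bres2) <= 1e-9 * np.maximum(bres2, 1e-30)
            same_window = lower | (tie & (np.abs(psi) < np.abs(bpsi)))
            # across the window boundary: the outside candidate must be
            # better by a decisive factor to displace the inside one
            new_out_wins = ~in_window & bwin & (res2 < out_window_ratio * bres2)
            new_in_wins = in_window & ~bwin & ~(bres2 < out_window_ratio * res2)
            better = np.where(
                in_window == bwin, same_window, new_out_wins | new_in_wins
            )
            bx[better] = x[better]
            bpsi[better] = psi[better]
            bres2[better] = res2[better]
            biters[better] = iters[better]
            bwin[better] = in_window[better]
    x, psi, res2, iters, _ = best

    for _ in range(max(0, n_sweeps - 1)):
        if smooth_sigma > 0:
            psi = ndimage.gaussian_filter(
                psi.reshape(shape), sigma=smooth_sigma
            ).reshape(-1)
        x, psi, res2, it2 = _ideal_iterate(
            s, te_s, a, pinv_a, psi, tol_hz, max_iter
        )  # psi re-iterated from the smoothed start
        iters = iters + it2

    water = np.abs(x[:, 0]).reshape(shape)
    fat = np.abs(x[:, 1]).reshape(shape)
    total = water + fat
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = np.where(total > 0, fat / np.where(total > 0, total, 1.0), np.nan)
    return FatWaterMaps(
        water=water,
        fat=fat,
        field_map=psi.reshape(shape),
        fat_fraction=ff,
        iterations_used=iters.reshape(shape),
        residual=np.sqrt(res2).reshape(shape),
    )


def fat_fraction_map(maps: FatWaterMaps) -> np.ndarray:
    """Fat signal fraction S_fat/(S_fat+S_water); zero-signal voxels -> NaN."""
    if np.any(maps.water < 0) or np.any(maps.fat < 0):
        raise DomainError("water/fat magnitudes must be non-negative")
    total = maps.water + maps.fat
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total > 0, maps.fat / np.where(total > 0, total, 1.0), np.nan)
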