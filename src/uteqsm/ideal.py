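"""IDEAL-style complex multi-echo fitting of water, fat, B0 and T2*.

The single-voxel signal at echo time ``t`` is modeled as

    S(t) = ( S_W exp(-t/T2*) + S_F sum_k alpha_k exp(i 2 pi f_k t) )
           * exp( i (phi0 + 2 pi f_B0 t) ),

i.e. a water pool of amplitude ``S_W`` decaying with the effective
transverse relaxation time T2*, a fat pool of amplitude ``S_F`` with a
multi-peak spectrum (relative amplitudes ``alpha_k``, chemical shifts
``f_k``), a shared initial phase ``phi0`` and the B0 off-resonance
frequency ``f_B0``.  Only the water pool is damped; the fat terms are
undamped (an option to damp fat with the same T2* is provided).

Fitting uses variable projection: for a candidate (f_B0, R2*) the
amplitude/phase subproblem is solved in closed form, the resulting
reduced objective is scanned on a coarse grid to avoid fat--water swaps
(the dominant fat peak sits ~440 Hz from water at 3 T, which creates
distant local minima), and the best node is refined by a shrinking
pattern search.  Volume fitting seeds the full-resolution search from a
downsampled first pass so neighboring voxels land in the same basin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import scipy.optimize
from pydantic import BaseModel, Field, model_validator

from .core import GAMMA_BAR_HZ_PER_T, AcquisitionGeometry

__all__ = [
    "FatSpectrum",
    "default_fat_spectrum",
    "MultiEchoSeries",
    "SignalParams",
    "IdealFitVolume",
    "FitOptions",
    "eval_signal_model",
    "fit_ideal_voxel",
    "fit_ideal_volume",
    "derive_maps",
]


# ---------------------------------------------------------------------------
# fat spectrum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FatSpectrum:
    """Multi-peak fat spectral model.

    ``shifts_hz`` are chemical shifts relative to water at the reference
    field strength ``ref_field_T``; they scale linearly with B0.
    ``amplitudes`` are nonnegative and sum to 1.
    """

    amplitudes: tuple[float, ...]
    shifts_hz: tuple[float, ...]
    ref_field_T: float = 3.0

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        shifts = np.asarray(self.shifts_hz, dtype=float)
        if amps.size < 1 or amps.size != shifts.size:
            raise ValueError("amplitudes and shifts must be same nonzero length")
        if np.any(amps < 0) or abs(amps.sum() - 1.0) > 1e-9:
            raise ValueError("amplitudes must be nonnegative and sum to 1")
        if self.ref_field_T <= 0:
            raise ValueError("ref_field_T must be positive")
        object.__setattr__(self, "amplitudes", tuple(float(a) for a in amps))
        object.__setattr__(self, "shifts_hz", tuple(float(s) for s in shifts))

    @property
    def n_peaks(self) -> int:
        return len(self.amplitudes)

    def shifts_at(self, field_strength_T: float) -> np.ndarray:
        """Peak shifts in Hz at an arbitrary field strength (linear scaling)."""
        return np.asarray(self.shifts_hz) * (field_strength_T / self.ref_field_T)

    def phasor(self, t_s: np.ndarray, field_strength_T: float | None = None) -> np.ndarray:
        """Complex fat dephasing factor sum_k alpha_k exp(i 2 pi f_k t)."""
        f = self.shifts_at(field_strength_T if field_strength_T is not None else self.ref_field_T)
        t = np.atleast_1d(np.asarray(t_s, dtype=float))
        return (np.asarray(self.amplitudes) * np.exp(2j * np.pi * f * t[..., None])).sum(-1)


def default_fat_spectrum(field_strength_T: float = 3.0) -> FatSpectrum:
    """Packaged six-peak triglyceride calibration, scaled to ``field_strength_T``.

    The peak table (``data/fat_spectrum_6peak.json``) is a calibration
    artifact of this package: six peaks with shifts in ppm relative to
    water, chosen so the amplitude-weighted mean shift lands near the
    -440 Hz dominant methylene shift at 3 T.  Override by constructing a
    :class:`FatSpectrum` directly.
    """
    if field_strength_T <= 0:
        raise ValueError("field_strength_T must be positive")
    with resources.files("uteqsm.data").joinpath("fat_spectrum_6peak.json").open() as fh:
        table = json.load(fh)
    amps = [p["amplitude"] for p in table["peaks"]]
    shifts_hz = [
        p["shift_ppm"] * GAMMA_BAR_HZ_PER_T * field_strength_T * 1e-6
        for p in table["peaks"]
    ]
    return FatSpectrum(
        amplitudes=tuple(amps), shifts_hz=tuple(shifts_hz), ref_field_T=field_strength_T
    )


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MultiEchoSeries:
    """Complex multi-echo image stack: ``data[echo, x, y, z]`` plus echo times (s)."""

    data: np.ndarray
    echo_times_s: tuple[float, ...]
    geometry: AcquisitionGeometry
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        te = np.asarray(self.echo_times_s, dtype=float)
        if te.ndim != 1 or te.size < 1:
            raise ValueError("echo_times_s must be a nonempty 1D sequence")
        if te[0] < 0 or np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be nonnegative and strictly increasing")
        if self.data.shape != (te.size, *self.geometry.shape):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"({te.size}, *{self.geometry.shape})"
            )
        self.echo_times_s = tuple(float(x) for x in te)

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times_s)


@dataclass(frozen=True)
class SignalParams:
    """Single-voxel parameter set of the multi-echo signal model."""

    s_w: float
    s_f: float
    phi0: float
    f_b0_hz: float
    t2star_s: float


@dataclass
class IdealFitVolume:
    """Voxelwise fit results: amplitudes, phase, off-resonance, T2*."""

    s_w: np.ndarray
    s_f: np.ndarray
    phi0: np.ndarray
    f_b0_hz: np.ndarray
    t2star_s: np.ndarray
    converged: np.ndarray
    residual: np.ndarray
    geometry: AcquisitionGeometry
    spectrum: FatSpectrum | None = None
    options: "FitOptions | None" = None


class FitOptions(BaseModel):
    """Solver controls for the multi-echo fit.

    ``search_range_hz=None`` derives the f_B0 scan range from the echo
    spacing as +-1/(2*min(dTE)), the widest unambiguous window.  The
    R2* grid nodes seed the coarse search; refinement is bounded by
    ``r2star_bounds`` (1/s).
    """

    shared_phase: bool = True
    damp_fat: bool = False
    search_range_hz: float | None = None
    coarse_step_hz: float = 2.0
    r2star_nodes: tuple[float, ...] = (0.0, 10.0, 25.0, 60.0, 150.0, 400.0, 1000.0, 2500.0)
    r2star_bounds: tuple[float, float] = (0.0, 5000.0)
    downsample: int = 2
    local_window_hz: float = 45.0
    local_step_hz: float = 5.0
    pattern_levels: int = 12
    pattern_moves: int = 8

    @model_validator(mode="after")
    def _check(self):
        if self.coarse_step_hz <= 0 or self.local_step_hz <= 0:
            raise ValueError("grid steps must be positive")
        if self.r2star_bounds[0] < 0 or self.r2star_bounds[1] <= self.r2star_bounds[0]:
            raise ValueError("r2star_bounds must be 0 <= lo < hi")
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")
        return self


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def eval_signal_model(
    params: SignalParams,
    spectrum: FatSpectrum,
    t_s,
    field_strength_T: float | None = None,
    damp_fat: bool = False,
):
    """Evaluate the complex signal model at echo time(s) ``t_s`` (seconds)."""
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("echo times must be nonnegative")
    if params.t2star_s <= 0:
        raise ValueError("T2* must be positive")
    decay = np.exp(-t / params.t2star_s)
    fat = spectrum.phasor(t, field_strength_T)
    if damp_fat:
        fat = fat * decay
    core = params.s_w * decay + params.s_f * fat
    out = core * np.exp(1j * (params.phi0 + 2 * np.pi * params.f_b0_hz * t))
    return out if out.shape else complex(out)


# ---------------------------------------------------------------------------
# variable-projection machinery
# ---------------------------------------------------------------------------

def _amp_solve(z1, z2, maa, gab, mbb, s2, shared: bool, want_params: bool = False):
    """Closed-form amplitude/phase subproblem for fixed (f_B0, R2*).

    With the water/fat basis columns a, b (already demodulated by the
    off-resonance phasor), ``z1 = a^H s``, ``z2 = b^H s``, ``maa = |a|^2``,
    ``gab = a^H b`` and ``mbb = |b|^2``.  For the shared-phase model the
    real amplitude pair rho and common phase phi minimizing
    ``|s - exp(i phi) A rho|^2`` satisfy ``Re(A^H A) rho = Re(exp(-i phi) z)``;
    the optimal phi maximizes a quadratic form on the unit circle and is
    the principal eigenvector of a 2x2 symmetric matrix.  Nonnegativity
    of the amplitudes is enforced by falling back to the better of the
    water-only / fat-only boundary solutions when violated.
    """
    z1, z2, maa, gab, s2 = np.broadcast_arrays(z1, z2, maa, gab, s2)
    mbb = np.broadcast_to(mbb, z1.shape)
    tiny = 1e-300

    # single-component candidates (also the mixed-sign fallbacks)
    h_w = np.abs(z1) ** 2 / np.maximum(maa, tiny)
    h_f = np.abs(z2) ** 2 / np.maximum(mbb, tiny)

    if shared:
        mab = gab.real
        det = maa * mbb - mab**2
        det_safe = np.maximum(det, tiny)
        u1, v1 = z1.real, z1.imag
        u2, v2 = z2.real, z2.imag
        p1 = (mbb * u1 - mab * u2) / det_safe
        p2 = (-mab * u1 + maa * u2) / det_safe
        q1 = (mbb * v1 - mab * v2) / det_safe
        q2 = (-mab * v1 + maa * v2) / det_safe
        q11 = u1 * p1 + u2 * p2
        q22 = v1 * q1 + v2 * q2
        q12 = u1 * q1 + u2 * q2
        half = 0.5 * (q11 - q22)
        disc = np.hypot(half, q12)
        lam = 0.5 * (q11 + q22) + disc
        # principal eigenvector of [[q11,q12],[q12,q22]]; pick stable branch
        e1c, e1s = q12, lam - q11
        e2c, e2s = lam - q22, q12
        use2 = np.hypot(e2c, e2s) > np.hypot(e1c, e1s)
        ec = np.where(use2, e2c, e1c)
        es = np.where(use2, e2s, e1s)
        nrm = np.hypot(ec, es)
        degen = nrm < 1e-30  # isotropic form (e.g. zero signal): any phase
        ec = np.where(degen, 1.0, ec / np.where(degen, 1.0, nrm))
        es = np.where(degen, 0.0, es / np.where(degen, 1.0, nrm))
        y1 = u1 * ec + v1 * es
        y2 = u2 * ec + v2 * es
        rho1 = (mbb * y1 - mab * y2) / det_safe
        rho2 = (-mab * y1 + maa * y2) / det_safe
        # sign convention: total zero-TE amplitude nonnegative
        flip = rho1 + rho2 < 0
        rho1 = np.where(flip, -rho1, rho1)
        rho2 = np.where(flip, -rho2, rho2)
        ec = np.where(flip, -ec, ec)
        es = np.where(flip, -es, es)
        h_unc = y1 * rho1 + y2 * rho2
        feasible = (rho1 >= 0) & (rho2 >= 0) & (det > 1e-30)
        water_better = h_w >= h_f
        h = np.where(feasible, h_unc, np.where(water_better, h_w, h_f))
        resid2 = np.maximum(s2 - h, 0.0)
        if not want_params:
            return resid2
        sw_b = np.where(water_better, np.abs(z1) / np.maximum(maa, tiny), 0.0)
        sf_b = np.where(water_better, 0.0, np.abs(z2) / np.maximum(mbb, tiny))
        phi_b = np.where(water_better, np.angle(z1), np.angle(z2))
        sw = np.where(feasible, rho1, sw_b)
        sf = np.where(feasible, rho2, sf_b)
        phi = np.where(feasible, np.arctan2(es, ec), phi_b)
        return resid2, sw, sf, phi

    # independent complex amplitudes (relaxed phase model)
    det = maa * mbb - np.abs(gab) ** 2
    det_safe = np.maximum(det, tiny)
    c1 = (mbb * z1 - gab * z2) / det_safe
    c2 = (-np.conj(gab) * z1 + maa * z2) / det_safe
    h = (np.conj(z1) * c1 + np.conj(z2) * c2).real
    ok = det > 1e-30
    h = np.where(ok, h, h_w)
    resid2 = np.maximum(s2 - h, 0.0)
    if not want_params:
        return resid2
    sw = np.where(ok, np.abs(c1), np.abs(z1) / np.maximum(maa, tiny))
    sf = np.where(ok, np.abs(c2), 0.0)
    phi = np.where(ok, np.angle(c1), np.angle(z1))
    return resid2, sw, sf, phi


def _basis_moments(t, r2s, fat_ph, damp_fat: bool):
    """Per-voxel basis Gram pieces for R2* array ``r2s`` (shape X -> X, m ops)."""
    e = np.exp(-np.multiply.outer(r2s, t))  # (..., m)
    fat = fat_ph * e if damp_fat else np.broadcast_to(fat_ph, e.shape)
    maa = (e * e).sum(-1)
    gab = (e * fat).sum(-1)
    mbb = (fat * np.conj(fat)).real.sum(-1)
    return e, fat, maa, gab, mbb


def _objective(S, t, f, r2s, fat_ph, s2, shared, damp_fat, want_params=False):
    """Reduced objective for per-voxel parameter arrays ``f``, ``r2s``."""
    e, fat, maa, gab, mbb = _basis_moments(t, r2s, fat_ph, damp_fat)
    demod = np.exp(-2j * np.pi * np.multiply.outer(f, t)) * S
    z1 = (e * demod).sum(-1)
    z2 = (np.conj(fat) * demod).sum(-1)
    return _amp_solve(z1, z2, maa, gab, mbb, s2, shared, want_params)


def _grid_search(S, t, f_nodes, r_nodes, fat_ph, s2, shared, damp_fat):
    """Exhaustive scan over scalar (f_B0, R2*) nodes; returns per-voxel argmin.

    The Gram moments depend only on R2*, so for each f node a single
    matrix product against the R2* decay basis evaluates all R2* nodes.
    """
    n = S.shape[0]
    e = np.exp(-np.outer(r_nodes, t))  # (R, m)
    if damp_fat:
        fat = fat_ph[None, :] * e
    else:
        fat = np.broadcast_to(fat_ph, e.shape)
    maa = (e * e).sum(-1)
    gab = (e * fat).sum(-1)
    mbb = (fat * np.conj(fat)).real.sum(-1)

    best = np.full(n, np.inf)
    best_f = np.zeros(n)
    best_r = np.zeros(n)
    eT = e.T.astype(complex)  # (m, R)
    fatc = np.conj(fat)  # (R, m)
    for f in f_nodes:
        demod = np.exp(-2j * np.pi * f * t) * S  # (n, m)
        z1 = demod @ eT  # (n, R)
        z2 = demod @ fatc.T  # (n, R)
        resid2 = _amp_solve(z1, z2, maa[None, :], gab[None, :], mbb[None, :],
                            s2[:, None], shared)
        j = np.argmin(resid2, axis=1)
        val = np.take_along_axis(resid2, j[:, None], 1)[:, 0]
        upd = val < best
        best[upd] = val[upd]
        best_f[upd] = f
        best_r[upd] = r_nodes[j[upd]]
    return best_f, best_r, best


_R_EPS = 1.0  # softening (1/s) for the log parameterization of R2*


def _pattern_refine(S, t, f0, r0, fat_ph, s2, shared, damp_fat, options: FitOptions):
    """Shrinking axis-aligned pattern search in (f_B0, log(R2*+eps))."""
    lo, hi = options.r2star_bounds
    f = f0.copy()
    rho = np.log(np.clip(r0, lo, hi) + _R_EPS)
    rho_lo, rho_hi = np.log(lo + _R_EPS), np.log(hi + _R_EPS)

    def ev(fv, rhov):
        return _objective(S, t, fv, np.exp(rhov) - _R_EPS, fat_ph, s2, shared, damp_fat)

    best = ev(f, rho)
    df = max(options.coarse_step_hz, options.local_step_hz)
    drho = 0.3
    for _ in range(options.pattern_levels):
        for _ in range(options.pattern_moves):
            moved = False
            for cand_f, cand_rho in (
                (f + df, rho), (f - df, rho),
                (f, np.clip(rho + drho, rho_lo, rho_hi)),
                (f, np.clip(rho - drho, rho_lo, rho_hi)),
            ):
                val = ev(cand_f, cand_rho)
                upd = val < best
                if np.any(upd):
                    moved = True
                    best[upd] = val[upd]
                    f[upd] = cand_f[upd]
                    rho[upd] = cand_rho[upd]
            if not moved:
                break
        df = max(df * 0.5, 0.005)
        drho = max(drho * 0.5, 1e-4)
    return f, np.exp(rho) - _R_EPS, best


def _newton_polish(S, t, f0, r0, fat_ph, s2, shared, damp_fat,
                   options: FitOptions, iters: int = 4):
    """Guarded Newton refinement on the reduced objective in (f, log R2*).

    Finite-difference gradients/Hessians, vectorized across voxels; a
    step is only accepted where it decreases the objective and the local
    Hessian is positive definite, so the pattern-search result is never
    degraded.  This resolves nearly-flat valleys (e.g. high fat fraction
    with slow water decay) that stall a fixed-schedule pattern search.
    """
    lo, hi = options.r2star_bounds
    f = f0.copy()
    rho = np.log(np.clip(r0, lo, hi) + _R_EPS)
    rho_lo, rho_hi = np.log(lo + _R_EPS), np.log(hi + _R_EPS)
    hf, hr = 0.02, 1e-3

    def ev(fv, rhov):
        return _objective(S, t, fv, np.exp(np.clip(rhov, rho_lo, rho_hi)) - _R_EPS,
                          fat_ph, s2, shared, damp_fat)

    best = ev(f, rho)
    for _ in range(iters):
        j00 = best
        jpf, jmf = ev(f + hf, rho), ev(f - hf, rho)
        jpr, jmr = ev(f, rho + hr), ev(f, rho - hr)
        jpp = ev(f + hf, rho + hr)
        gf = (jpf - jmf) / (2 * hf)
        gr = (jpr - jmr) / (2 * hr)
        hff = (jpf - 2 * j00 + jmf) / hf**2
        hrr = (jpr - 2 * j00 + jmr) / hr**2
        hfr = (jpp - jpf - jpr + j00) / (hf * hr)
        det = hff * hrr - hfr**2
        pd = (hff > 0) & (det > 0)
        det_safe = np.where(pd, det, 1.0)
        df = np.where(pd, -(hrr * gf - hfr * gr) / det_safe, 0.0)
        dr = np.where(pd, -(-hfr * gf + hff * gr) / det_safe, 0.0)
        # trust region: cap the step to stay within the refined basin
        df = np.clip(df, -2.0, 2.0)
        dr = np.clip(dr, -0.2, 0.2)
        val = ev(f + df, rho + dr)
        upd = val < best
        best = np.where(upd, val, best)
        f = np.where(upd, f + df, f)
        rho = np.where(upd, np.clip(rho + dr, rho_lo, rho_hi), rho)
        if not upd.any():
            break
    return f, np.exp(rho) - _R_EPS, best


def _prepare(echo_times_s, spectrum, field_T):
    t = np.asarray(echo_times_s, dtype=float)
    if t.size < 4:
        raise ValueError("at least 4 echoes are required for the 5-parameter fit")
    fat_ph = spectrum.phasor(t, field_T)
    return t, fat_ph


def _default_range(t, options: FitOptions) -> float:
    if options.search_range_hz is not None:
        return float(options.search_range_hz)
    return 1.0 / (2.0 * float(np.min(np.diff(t))))


# ---------------------------------------------------------------------------
# public fitters
# ---------------------------------------------------------------------------

def fit_ideal_voxel(
    signal,
    echo_times_s,
    spectrum: FatSpectrum,
    options: FitOptions | None = None,
    field_strength_T: float = 3.0,
) -> SignalParams:
    """Fit the signal model to a single voxel's complex echo vector.

    Runs the full coarse grid over (f_B0, R2*), pattern-search
    refinement, and a final simplex polish of the reduced 2-parameter
    objective.  Raises ``ValueError`` on degenerate (all-zero or
    non-finite) input; in volume mode such voxels are flagged instead.
    """
    options = options or FitOptions()
    s = np.asarray(signal, dtype=complex)
    t, fat_ph = _prepare(echo_times_s, spectrum, field_strength_T)
    if s.shape != t.shape:
        raise ValueError("signal and echo_times_s must have the same length")
    if not np.all(np.isfinite(s.view(float))) or np.all(s == 0):
        raise ValueError("degenerate voxel signal (all-zero or non-finite)")

    S = s[None, :]
    s2 = np.array([(np.abs(s) ** 2).sum()])
    frange = _default_range(t, options)
    f_nodes = np.arange(-frange, frange + options.coarse_step_hz / 2, options.coarse_step_hz)
    r_nodes = np.clip(np.asarray(options.r2star_nodes, float), *options.r2star_bounds)
    f0, r0, _ = _grid_search(S, t, f_nodes, r_nodes, fat_ph, s2,
                             options.shared_phase, options.damp_fat)
    f1, r1, _ = _pattern_refine(S, t, f0, r0, fat_ph, s2,
                                options.shared_phase, options.damp_fat, options)

    lo, hi = options.r2star_bounds

    def reduced(x):
        fv = np.array([x[0]])
        rv = np.array([np.clip(np.exp(x[1]) - _R_EPS, lo, hi)])
        return float(_objective(S, t, fv, rv, fat_ph, s2,
                                options.shared_phase, options.damp_fat)[0])

    x0 = np.array([f1[0], np.log(np.clip(r1[0], lo, hi) + _R_EPS)])
    res = scipy.optimize.minimize(
        reduced, x0, method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-30, "maxiter": 400},
    )
    x = res.x if res.fun <= reduced(x0) else x0
    f_fit = np.array([x[0]])
    r_fit = np.array([np.clip(np.exp(x[1]) - _R_EPS, lo, hi)])
    resid2, sw, sf, phi = _objective(S, t, f_fit, r_fit, fat_ph, s2,
                                     options.shared_phase, options.damp_fat,
                                     want_params=True)
    r2s = float(r_fit[0])
    t2s = 1.0 / max(r2s, 1e-6)
    return SignalParams(
        s_w=float(sw[0]), s_f=float(sf[0]),
        phi0=float(np.angle(np.exp(1j * phi[0]))),
        f_b0_hz=float(f_fit[0]), t2star_s=t2s,
    )


def _block_reduce_mean(vol: np.ndarray, ds: int) -> np.ndarray:
    sl = tuple(slice(0, (n // ds) * ds) for n in vol.shape[-3:])
    v = vol[(..., *sl)]
    shp = v.shape[:-3] + (
        v.shape[-3] // ds, ds, v.shape[-2] // ds, ds, v.shape[-1] // ds, ds,
    )
    return v.reshape(shp).mean(axis=(-5, -3, -1))


def fit_ideal_volume(
    series: MultiEchoSeries,
    spectrum: FatSpectrum,
    mask: np.ndarray,
    options: FitOptions | None = None,
) -> IdealFitVolume:
    """Voxelwise model fit inside ``mask``.

    A downsampled first pass scans the full (f_B0, R2*) grid; its f_B0
    field seeds a local grid + pattern search at full resolution, which
    suppresses isolated fat--water swaps.  Deterministic for identical
    inputs and options.  Degenerate voxels (all-zero or non-finite
    signal) are flagged not-converged with zeroed outputs.
    """
    options = options or FitOptions()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.geometry.shape:
        raise ValueError("mask shape does not match series geometry")
    if not mask.any():
        raise ValueError("empty mask")
    field_T = series.geometry.field_strength_T
    t, fat_ph = _prepare(series.echo_times_s, spectrum, field_T)
    m = t.size

    data = series.data
    flat = data.reshape(m, -1)
    idx = np.flatnonzero(mask.ravel())
    S = np.ascontiguousarray(flat[:, idx].T)  # (n, m)
    finite = np.isfinite(S.view(float).reshape(S.shape[0], -1)).all(axis=1)
    nonzero = np.any(S != 0, axis=1)
    good = finite & nonzero
    Sg = np.where(good[:, None], S, 0.0)
    s2 = (np.abs(Sg) ** 2).sum(-1)

    frange = _default_range(t, options)
    f_nodes = np.arange(-frange, frange + options.coarse_step_hz / 2, options.coarse_step_hz)
    r_nodes = np.clip(np.asarray(options.r2star_nodes, float), *options.r2star_bounds)

    # --- downsampled global scan to seed f_B0 -----------------------------
    ds = options.downsample
    if ds > 1:
        data_ds = _block_reduce_mean(data, ds)
        mask_ds = _block_reduce_mean(mask.astype(float), ds) > 0
        S_ds = data_ds.reshape(m, -1)[:, np.flatnonzero(mask_ds.ravel())].T
        S_ds = np.where(np.isfinite(S_ds.view(float).reshape(S_ds.shape[0], -1)).all(1)[:, None],
                        S_ds, 0.0)
        s2_ds = (np.abs(S_ds) ** 2).sum(-1)
        f_c, r_c, _ = _grid_search(S_ds, t, f_nodes, r_nodes, fat_ph, s2_ds,
                                   options.shared_phase, options.damp_fat)
        f_map = np.zeros(mask_ds.shape)
        r_map = np.full(mask_ds.shape, float(np.median(r_nodes)))
        f_map.ravel()[np.flatnonzero(mask_ds.ravel())] = f_c
        r_map.ravel()[np.flatnonzero(mask_ds.ravel())] = r_c
        f_full = np.repeat(np.repeat(np.repeat(f_map, ds, 0), ds, 1), ds, 2)
        r_full = np.repeat(np.repeat(np.repeat(r_map, ds, 0), ds, 1), ds, 2)
        pad = [(0, n - s * ds) for n, s in zip(mask.shape, mask_ds.shape)]
        f_full = np.pad(f_full, pad, mode="edge")[: mask.shape[0], : mask.shape[1], : mask.shape[2]]
        r_full = np.pad(r_full, pad, mode="edge")[: mask.shape[0], : mask.shape[1], : mask.shape[2]]
        f_init = f_full.ravel()[idx]
        r_init = r_full.ravel()[idx]

        # local scan around the propagated seed
        offsets = np.arange(-options.local_window_hz, options.local_window_hz + 1e-9,
                            options.local_step_hz)
        r_scales = np.array([0.3, 0.55, 1.0, 1.8, 3.3])
        best = np.full(S.shape[0], np.inf)
        best_f = f_init.copy()
        best_r = r_init.copy()
        for off in offsets:
            for sc in r_scales:
                fv = f_init + off
                rv = np.clip(r_init * sc, *options.r2star_bounds)
                val = _objective(Sg, t, fv, rv, fat_ph, s2,
                                 options.shared_phase, options.damp_fat)
                upd = val < best
                best[upd] = val[upd]
                best_f[upd] = fv[upd]
                best_r[upd] = rv[upd]
    else:
        best_f, best_r, best = _grid_search(Sg, t, f_nodes, r_nodes, fat_ph, s2,
                                            options.shared_phase, options.damp_fat)

    f_fit, r_fit, _ = _pattern_refine(Sg, t, best_f, best_r, fat_ph, s2,
                                      options.shared_phase, options.damp_fat, options)
    f_fit, r_fit, _ = _newton_polish(Sg, t, f_fit, r_fit, fat_ph, s2,
                                     options.shared_phase, options.damp_fat, options)
    resid2, sw, sf, phi = _objective(Sg, t, f_fit, r_fit, fat_ph, s2,
                                     options.shared_phase, options.damp_fat,
                                     want_params=True)

    shape = series.geometry.shape
    lo, hi = options.r2star_bounds

    def to_map(vec, fill=0.0):
        out = np.full(np.prod(shape), fill)
        out[idx] = vec
        return out.reshape(shape)

    r2s = np.clip(r_fit, lo, hi)
    t2star = 1.0 / np.maximum(r2s, 1e-6)
    fit = IdealFitVolume(
        s_w=to_map(np.where(good, sw, 0.0)),
        s_f=to_map(np.where(good, sf, 0.0)),
        phi0=to_map(np.where(good, np.angle(np.exp(1j * phi)), 0.0)),
        f_b0_hz=to_map(np.where(good, f_fit, 0.0)),
        t2star_s=to_map(np.where(good, t2star, 0.0)),
        converged=to_map(good.astype(float)).astype(bool),
        residual=to_map(np.where(good, np.sqrt(resid2), 0.0)),
        geometry=series.geometry,
        spectrum=spectrum,
        options=options,
    )
    return fit


def derive_maps(fit: IdealFitVolume) -> dict[str, np.ndarray]:
    """Secondary maps: B0 (Hz), R2* (1/s), fat fraction (dimensionless)."""
    total = fit.s_w + fit.s_f
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = np.where(total > 0, fit.s_f / np.where(total > 0, total, 1.0), 0.0)
        r2s = np.where(fit.t2star_s > 0, 1.0 / np.where(fit.t2star_s > 0, fit.t2star_s, 1.0), 0.0)
    return {"b0_hz": fit.f_b0_hz.copy(), "r2star": r2s, "fat_fraction": ff}
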