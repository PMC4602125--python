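"""Monodomain reaction-diffusion solver on structured voxel grids.

The tissue is a node-centred finite-difference grid (1D cables, 2D sheets
or small 3D slabs).  Transmembrane voltage obeys

    beta * Cm * dV/dt = div( sigma grad V ) - beta * I_ion + beta * I_stim

with no-flux boundaries; sigma is the per-node conductivity tensor built
from the fiber angle (in-plane rotation of diag(sigma_l, sigma_t, sigma_t)).
Heterogeneous tensors are face-averaged with harmonic means so flux stays
continuous across tissue-type boundaries.  Time integration is operator
split per step: explicit diffusion, then membrane reaction (Rush-Larsen
gates, forward Euler voltage and concentrations).

Scar is passive tissue: it stays diffusively coupled (configurable) and
carries only a linear leak to resting potential, no active currents.

Units: mm for grid spacing (converted to cm internally), ms, mV, S/m for
conductivities, 1/cm for the surface-to-volume ratio, µF/cm² for Cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import lrd
from .lrd import (
    GZRemodeling, LUT_VMIN, LUT_DV, RTF, NA_O, K_O, CA_O, PR_NAK,
)

# cell-type codes shared across the package
CT_BACKGROUND = 0
CT_NORMAL = 1
CT_GZ = 2
CT_SCAR = 3

#: surface-to-volume ratio (1/cm).  This is the package's single calibration
#: constant: chosen once so that the default conductivities (0.28 S/m
#: longitudinal) yield 45 cm/s longitudinal conduction velocity on a cable
#: at 0.1 mm node spacing and dt = 0.02 ms, then frozen.  See docs/methods.md.
SURFACE_TO_VOLUME_DEFAULT = 4900.0

#: voltage the upstroke detector arms below / commits above (mV)
ACT_ARM_V = -60.0
ACT_COMMIT_V = -20.0
ACT_CROSS_V = -40.0
ACT_MIN_DVDT = 5.0  # mV/ms to start tracking an upstroke
MAX_ACTIVATIONS = 64


@dataclass(frozen=True)
class ConductivityParams:
    """Tissue conductivities and membrane constants.

    ``sigma_longitudinal``/``sigma_transverse`` are the normal-myocardium
    values (S/m).  Gray zone keeps the longitudinal value and scales the
    transverse one by ``gz_transverse_scale`` (connexin-43 lateralisation).
    Scar carries only a passive linear leak of conductance ``scar_leak``
    (mS/µF) toward ``scar_rest_mv``; set ``scar_coupled`` False for the
    zero-conductivity alternative.
    """

    sigma_longitudinal: float = 0.28  # S/m
    sigma_transverse: float = 0.026  # S/m
    gz_transverse_scale: float = 0.1
    membrane_capacitance: float = 1.0  # µF/cm²
    surface_to_volume: float = SURFACE_TO_VOLUME_DEFAULT  # 1/cm
    scar_coupled: bool = True
    scar_leak: float = 0.05  # mS/µF, passive membrane
    scar_rest_mv: float = float(lrd.RESTING_STATE[0])

    def __post_init__(self) -> None:
        for name in ("sigma_longitudinal", "sigma_transverse",
                     "membrane_capacitance", "surface_to_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 < self.gz_transverse_scale <= 1.0):
            raise ValueError("gz_transverse_scale must be in (0, 1]")


@dataclass(frozen=True)
class StimulusEvent:
    """Transmembrane current injection into a geometric ball of nodes."""

    onset_ms: float
    duration_ms: float
    amplitude: float  # µA/µF, positive depolarises
    center_mm: tuple[float, float, float]
    radius_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("stimulus duration must be > 0")


@dataclass
class TissueGrid:
    """Simulation-ready structured grid.

    ``celltype`` uses the module codes (0 background, 1 normal, 2 GZ,
    3 scar); ``fiber_angle_deg`` is the in-plane (xy) fiber angle.  The
    derived diffusion tensor components (cm²/ms) are filled in by
    :func:`build_tissue_grid`.
    """

    spacing_mm: tuple[float, float, float]
    celltype: np.ndarray
    fiber_angle_deg: np.ndarray
    cparams: ConductivityParams = field(default_factory=ConductivityParams)
    remodeling: GZRemodeling = field(default_factory=GZRemodeling)
    dxx: np.ndarray | None = None
    dyy: np.ndarray | None = None
    dzz: np.ndarray | None = None
    dxy: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.celltype.shape

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.celltype.shape))

    def node_index(self, pos_mm) -> tuple[int, int, int]:
        """Nearest node to a physical position (node centres at (i+0.5)h)."""
        idx = []
        for p, h, n in zip(pos_mm, self.spacing_mm, self.shape):
            i = int(np.clip(round(p / h - 0.5), 0, n - 1))
            idx.append(i)
        return tuple(idx)

    def node_position_mm(self, ijk) -> np.ndarray:
        return (np.asarray(ijk, dtype=float) + 0.5) * np.asarray(self.spacing_mm)

    def nodes_in_ball(self, center_mm, radius_mm, excitable_only=True) -> np.ndarray:
        """Flat indices of nodes whose centres lie within the ball."""
        nx, ny, nz = self.shape
        ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                                 indexing="ij")
        h = np.asarray(self.spacing_mm)
        dx = (ii + 0.5) * h[0] - center_mm[0]
        dy = (jj + 0.5) * h[1] - center_mm[1]
        dz = (kk + 0.5) * h[2] - center_mm[2]
        inside = dx * dx + dy * dy + dz * dz <= radius_mm ** 2
        if excitable_only:
            inside &= (self.celltype == CT_NORMAL) | (self.celltype == CT_GZ)
        return np.flatnonzero(inside.ravel())


def _tensor_components(sig_l, sig_t_eff, sig_t_plane, angle_deg):
    """In-plane rotation of diag(sig_l, sig_t) about z; zz stays transverse."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    sxx = sig_l * c * c + sig_t_eff * s * s
    syy = sig_l * s * s + sig_t_eff * c * c
    sxy = (sig_l - sig_t_eff) * c * s
    szz = np.full_like(sxx, 0.0) + sig_t_plane
    return sxx, syy, szz, sxy


def build_tissue_grid(celltype, fiber_angle_deg, spacing_mm,
                      cparams: ConductivityParams | None = None,
                      remodeling: GZRemodeling | None = None) -> TissueGrid:
    """Assemble a :class:`TissueGrid` with per-node diffusion tensors.

    ``celltype`` is a 1/2/3D array of cell-type codes (or a LabelVolume's
    ``labels``); ``fiber_angle_deg`` a matching array or a scalar angle.
    The diffusion tensor is sigma/(beta*Cm) in cm²/ms.
    """
    cparams = cparams or ConductivityParams()
    remodeling = remodeling or GZRemodeling()
    ct = np.asarray(celltype)
    while ct.ndim < 3:
        ct = ct[..., None]
    ct = np.ascontiguousarray(ct.astype(np.uint8))
    if np.isscalar(fiber_angle_deg):
        ang = np.full(ct.shape, float(fiber_angle_deg))
    else:
        ang = np.asarray(fiber_angle_deg, dtype=float)
        while ang.ndim < 3:
            ang = ang[..., None]
        if ang.shape != ct.shape:
            raise ValueError(
                f"fiber field shape {ang.shape} does not match labels {ct.shape}")
    spacing = tuple(float(s) for s in np.broadcast_to(np.asarray(spacing_mm, float).ravel(), (3,)))

    sig_l = cparams.sigma_longitudinal * 10.0  # S/m -> mS/cm
    sig_t = cparams.sigma_transverse * 10.0
    # per-node transverse conductivity: GZ reduced by the remodeling factor
    sig_t_node = np.where(ct == CT_GZ, sig_t * cparams.gz_transverse_scale, sig_t)
    sxx, syy, szz, sxy = _tensor_components(sig_l, sig_t_node, sig_t_node, ang)
    if cparams.scar_coupled:
        # dense scar couples isotropically at the transverse conductivity
        scar = ct == CT_SCAR
        sxx = np.where(scar, sig_t, sxx)
        syy = np.where(scar, sig_t, syy)
        szz = np.where(scar, sig_t, szz)
        sxy = np.where(scar, 0.0, sxy)
    else:
        scar = ct == CT_SCAR
        for arr in (sxx, syy, szz, sxy):
            arr[scar] = 0.0
    bg = ct == CT_BACKGROUND
    for arr in (sxx, syy, szz, sxy):
        arr[bg] = 0.0

    bcm = cparams.surface_to_volume * cparams.membrane_capacitance
    scale = 1.0 / bcm  # mS·cm²/µF per (mS/cm / (1/cm · µF/cm²)) -> cm²/ms
    grid = TissueGrid(spacing_mm=spacing, celltype=ct,
                      fiber_angle_deg=np.ascontiguousarray(ang),
                      cparams=cparams, remodeling=remodeling,
                      dxx=np.ascontiguousarray(sxx * scale),
                      dyy=np.ascontiguousarray(syy * scale),
                      dzz=np.ascontiguousarray(szz * scale),
                      dxy=np.ascontiguousarray(sxy * scale))
    return grid


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

def _build_faces(grid: TissueGrid):
    """Face coupling coefficients g = 2*Di*Dj/(Di+Dj)/h² (1/ms) per axis."""
    h = np.asarray(grid.spacing_mm, float) / 10.0  # cm
    faces = []
    for axis, d in enumerate((grid.dxx, grid.dyy, grid.dzz)):
        a = d
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi[axis] = slice(1, None)
        d0 = a[tuple(sl_lo)]
        d1 = a[tuple(sl_hi)]
        g = np.zeros_like(d0)
        m = (d0 > 0) & (d1 > 0)
        g[m] = 2.0 * d0[m] * d1[m] / (d0[m] + d1[m]) / (h[axis] ** 2)
        faces.append(np.ascontiguousarray(g))
    return faces


@njit(cache=True, fastmath=True)
def _diffusion_kernel(v, vout, gx, gy, gz, nx, ny, nz, dt):
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                acc = 0.0
                vij = v[i, j, k]
                if i > 0:
                    acc += gx[i - 1, j, k] * (v[i - 1, j, k] - vij)
                if i < nx - 1:
                    acc += gx[i, j, k] * (v[i + 1, j, k] - vij)
                if j > 0:
                    acc += gy[i, j - 1, k] * (v[i, j - 1, k] - vij)
                if j < ny - 1:
                    acc += gy[i, j, k] * (v[i, j + 1, k] - vij)
                if k > 0:
                    acc += gz[i, j, k - 1] * (v[i, j, k - 1] - vij)
                if k < nz - 1:
                    acc += gz[i, j, k] * (v[i, j, k + 1] - vij)
                vout[i, j, k] = vij + dt * acc


@njit(cache=True, fastmath=True)
def _diffusion_cross_kernel(v, vout, dxy, active3, hx, hy, dt):
    """Mixed-derivative anisotropy term d/dx(Dxy dV/dy) + d/dy(Dxy dV/dx).

    Centered differences; contributions are dropped where any participating
    node is inactive (approximate no-flux treatment of the cross term).
    """
    nx, ny, nz = v.shape
    for i in range(1, nx - 1):
        for j in range(1, ny - 1):
            for k in range(nz):
                if not active3[i, j, k]:
                    continue
                ok = (active3[i + 1, j, k] and active3[i - 1, j, k]
                      and active3[i, j + 1, k] and active3[i, j - 1, k]
                      and active3[i + 1, j + 1, k] and active3[i + 1, j - 1, k]
                      and active3[i - 1, j + 1, k] and active3[i - 1, j - 1, k])
                if not ok:
                    continue
                dyv_ip = (v[i + 1, j + 1, k] - v[i + 1, j - 1, k]) / (2.0 * hy)
                dyv_im = (v[i - 1, j + 1, k] - v[i - 1, j - 1, k]) / (2.0 * hy)
                t1 = (dxy[i + 1, j, k] * dyv_ip - dxy[i - 1, j, k] * dyv_im) / (2.0 * hx)
                dxv_jp = (v[i + 1, j + 1, k] - v[i - 1, j + 1, k]) / (2.0 * hx)
                dxv_jm = (v[i + 1, j - 1, k] - v[i - 1, j - 1, k]) / (2.0 * hx)
                t2 = (dxy[i, j + 1, k] * dxv_jp - dxy[i, j - 1, k] * dxv_jm) / (2.0 * hy)
                vout[i, j, k] += dt * (t1 + t2)


@njit(cache=True, fastmath=True)
def _update_nernst(states, active, ners):
    """Reversal potentials + slow Cai-dependent factors, refreshed lazily."""
    for ii in range(active.size):
        i = active[ii]
        nai = states[i, 8]
        ki = states[i, 9]
        cai = states[i, 10]
        ners[i, 0] = RTF * np.log(NA_O / nai)                     # ENa
        ners[i, 1] = RTF * np.log(K_O / ki)                       # EK
        ners[i, 2] = RTF * np.log((K_O + PR_NAK * NA_O) / (ki + PR_NAK * nai))  # EKs
        ners[i, 3] = 0.5 * RTF * np.log(CA_O / cai)               # ECa
        r = 3.8e-5 / cai
        ners[i, 4] = 1.0 + 0.6 / (1.0 + r ** 1.4)                 # GKs Cai factor


@njit(cache=True, fastmath=True)
def _reaction_kernel(states, active, ct, lut, dt, stim_amp, t_now,
                     na_sc, ca_sc, kr_sc, ks_sc, ners,
                     g_na, g_kr_bar, g_ks_bar, g_k1_bar, g_kp,
                     inak_bar, km_nai, km_ko, c_naca, ksat, km_fca,
                     i_pca_bar, km_pca, g_cab, g_nab, km_ns_ca,
                     cur_to_mm, vjsr_vmyo, vnsr_vmyo, vnsr_vjsr,
                     i_up_bar, km_up, kleak, tau_tr,
                     g_rel_bar, tau_on, tau_off, trig_v, rel_refrac,
                     trpn, km_trpn, cmdn, km_cmdn, csqn, km_csqn):
    npts = lut.shape[0]
    for ii in range(active.size):
        i = active[ii]
        c = ct[i]
        v = states[i, 0]
        nai = states[i, 8]
        ki = states[i, 9]
        cai = states[i, 10]
        cajsr = states[i, 11]
        cansr = states[i, 12]
        trel = states[i, 13]

        x = (v - LUT_VMIN) / LUT_DV
        k0 = int(x)
        if k0 < 0:
            k0 = 0
        elif k0 > npts - 2:
            k0 = npts - 2
        w = x - k0

        # gate updates (Rush-Larsen)
        m = states[i, 1]
        h = states[i, 2]
        j = states[i, 3]
        d = states[i, 4]
        f = states[i, 5]
        xr = states[i, 6]
        xs = states[i, 7]

        lo = lut[k0]
        hi = lut[k0 + 1]

        inf = lo[0] + w * (hi[0] - lo[0])
        edt = lo[1] + w * (hi[1] - lo[1])
        m = inf + (m - inf) * edt
        inf = lo[2] + w * (hi[2] - lo[2])
        edt = lo[3] + w * (hi[3] - lo[3])
        h = inf + (h - inf) * edt
        inf = lo[4] + w * (hi[4] - lo[4])
        edt = lo[5] + w * (hi[5] - lo[5])
        j = inf + (j - inf) * edt
        inf = lo[6] + w * (hi[6] - lo[6])
        edt = lo[7] + w * (hi[7] - lo[7])
        d = inf + (d - inf) * edt
        inf = lo[8] + w * (hi[8] - lo[8])
        edt = lo[9] + w * (hi[9] - lo[9])
        f = inf + (f - inf) * edt
        inf = lo[10] + w * (hi[10] - lo[10])
        edt = lo[11] + w * (hi[11] - lo[11])
        xr = inf + (xr - inf) * edt
        inf = lo[12] + w * (hi[12] - lo[12])
        edt = lo[13] + w * (hi[13] - lo[13])
        xs = inf + (xs - inf) * edt

        states[i, 1] = m
        states[i, 2] = h
        states[i, 3] = j
        states[i, 4] = d
        states[i, 5] = f
        states[i, 6] = xr
        states[i, 7] = xs

        a_ca = lo[14] + w * (hi[14] - lo[14])
        b_ca = lo[15] + w * (hi[15] - lo[15])
        a_cana = lo[16] + w * (hi[16] - lo[16])
        b_cana = lo[17] + w * (hi[17] - lo[17])
        a_cak = lo[18] + w * (hi[18] - lo[18])
        b_cak = lo[19] + w * (hi[19] - lo[19])
        a_ns = lo[20] + w * (hi[20] - lo[20])
        b_nsna = lo[21] + w * (hi[21] - lo[21])
        b_nsk = lo[22] + w * (hi[22] - lo[22])
        rkr = lo[23] + w * (hi[23] - lo[23])
        kp = lo[24] + w * (hi[24] - lo[24])
        fnak = lo[25] + w * (hi[25] - lo[25])
        ev = lo[26] + w * (hi[26] - lo[26])
        eev = lo[27] + w * (hi[27] - lo[27])

        ena = ners[i, 0]
        ek = ners[i, 1]
        eks = ners[i, 2]
        eca = ners[i, 3]
        gksf = ners[i, 4]

        ina = na_sc[c] * g_na * m * m * m * h * j * (v - ena)

        fca = 1.0 / (1.0 + cai / km_fca)
        dffca = ca_sc[c] * d * f * fca
        ica = dffca * (a_ca * cai - b_ca)
        icana = dffca * (a_cana * nai - b_cana)
        icak = dffca * (a_cak * ki - b_cak)

        ikr = kr_sc[c] * g_kr_bar * xr * rkr * (v - ek)
        iks = ks_sc[c] * g_ks_bar * gksf * xs * xs * (v - eks)

        # inward rectifier: k1_frac tabulated against (v - EK)
        xk = (v - ek - LUT_VMIN) / LUT_DV
        kk = int(xk)
        if kk < 0:
            kk = 0
        elif kk > npts - 2:
            kk = npts - 2
        wk = xk - kk
        k1f = lut[kk, 28] + wk * (lut[kk + 1, 28] - lut[kk, 28])
        ik1 = g_k1_bar * k1f * (v - ek)
        ikp = g_kp * kp * (v - ek)

        na3 = nai * nai * nai
        num = eev * (ev * na3 * CA_O - NA_O * NA_O * NA_O * cai)
        den = 1.0 + ksat * eev * (ev * na3 * CA_O + NA_O * NA_O * NA_O * cai)
        inaca = c_naca * num / den

        rkm = km_nai / nai
        inak = inak_bar * fnak / (1.0 + rkm * np.sqrt(rkm)) * K_O / (K_O + km_ko)

        rc = km_ns_ca / cai
        cans_gate = 1.0 / (1.0 + rc * rc * rc)
        insna = cans_gate * (a_ns * nai - b_nsna)
        insk = cans_gate * (a_ns * ki - b_nsk)

        ipca = i_pca_bar * cai / (cai + km_pca)
        icab = g_cab * (v - eca)
        inab = g_nab * (v - ena)

        itot = (ina + ica + icana + icak + ikr + iks + ik1 + ikp
                + inaca + inak + insna + insk + ipca + icab + inab)

        istim = stim_amp[i]
        v_new = v + dt * (-itot + istim)

        if v < trig_v and v_new >= trig_v and trel > rel_refrac:
            trel = 0.0
        else:
            trel = trel + dt

        if trel < 10.0 * tau_off:
            grel = g_rel_bar * (1.0 - np.exp(-trel / tau_on)) * np.exp(-trel / tau_off)
        else:
            grel = 0.0  # release episode fully decayed
        irel = grel * (cajsr - cai)
        iup = i_up_bar * cai / (cai + km_up)
        ileak = kleak * cansr
        itr = (cansr - cajsr) / tau_tr

        ina_tot = ina + icana + insna + inab + 3.0 * inaca + 3.0 * inak
        ik_tot = ikr + iks + ik1 + ikp + icak + insk - 2.0 * inak - istim
        ica_mem = ica + icab + ipca - 2.0 * inaca

        states[i, 8] = nai - dt * ina_tot * cur_to_mm
        states[i, 9] = ki - dt * ik_tot * cur_to_mm

        dc = km_trpn + cai
        dc2 = km_cmdn + cai
        bmyo = 1.0 / (1.0 + trpn * km_trpn / (dc * dc) + cmdn * km_cmdn / (dc2 * dc2))
        dcai = bmyo * (-ica_mem * cur_to_mm / 2.0 + irel * vjsr_vmyo
                       + (ileak - iup) * vnsr_vmyo)
        cai = cai + dt * dcai
        if cai < 1e-9:
            cai = 1e-9
        states[i, 10] = cai

        dj = km_csqn + cajsr
        bjsr = 1.0 / (1.0 + csqn * km_csqn / (dj * dj))
        cajsr = cajsr + dt * bjsr * (itr * vnsr_vjsr - irel)
        if cajsr < 1e-9:
            cajsr = 1e-9
        states[i, 11] = cajsr
        cansr = cansr + dt * (iup - ileak - itr)
        if cansr < 1e-9:
            cansr = 1e-9
        states[i, 12] = cansr

        states[i, 0] = v_new
        states[i, 13] = trel


@njit(cache=True, fastmath=True)
def _scar_kernel(states, scar_idx, dt, g_leak, v_rest, stim_amp):
    for ii in range(scar_idx.size):
        i = scar_idx[ii]
        v = states[i, 0]
        states[i, 0] = v + dt * (-g_leak * (v - v_rest) + stim_amp[i])


@njit(cache=True, fastmath=True)
def _track_activation(v_prev, v_new, active, dt, t_now, lat_mode,
                      up_state, up_best, up_tbest,
                      act_times, act_count):
    for ii in range(active.size):
        i = active[ii]
        v0 = v_prev[i]
        v1 = v_new[i]
        st = up_state[i]
        dvdt = (v1 - v0) / dt
        if st == 0:
            if v0 < ACT_ARM_V and v1 >= ACT_ARM_V:
                up_state[i] = 1
                up_best[i] = dvdt
                up_tbest[i] = t_now
        elif st == 1:
            if lat_mode == 0:
                if dvdt > up_best[i]:
                    up_best[i] = dvdt
                    up_tbest[i] = t_now
            else:
                if dvdt > up_best[i]:
                    up_best[i] = dvdt
                if v0 < ACT_CROSS_V and v1 >= ACT_CROSS_V:
                    frac = (ACT_CROSS_V - v0) / (v1 - v0)
                    up_tbest[i] = t_now - dt + frac * dt
            if v1 >= ACT_COMMIT_V:
                # a genuine upstroke must have accelerated past the floor
                if up_best[i] > ACT_MIN_DVDT:
                    n = act_count[i]
                    if n < act_times.shape[1]:
                        act_times[i, n] = up_tbest[i]
                        act_count[i] = n + 1
                up_state[i] = 2
            elif v1 < ACT_ARM_V:
                up_state[i] = 0  # aborted subthreshold bump
        else:  # st == 2, wait for repolarisation
            if v1 < ACT_ARM_V:
                up_state[i] = 0


# ---------------------------------------------------------------------------
# Simulation record and driver
# ---------------------------------------------------------------------------

@dataclass
class SimulationRecord:
    """Output of :func:`run_monodomain`.

    ``act_times``/``act_count`` store per-node activation times (ms, absolute)
    detected on the fly; ``frames`` holds voltage snapshots (float32) at
    ``frame_times`` if frame recording was requested.  ``final_states`` allows
    bit-exact restarts (used by the pacing protocols).
    """

    grid: TissueGrid
    dt: float
    t_start: float
    t_end: float
    probe_indices: np.ndarray
    probe_times: np.ndarray
    probe_traces: np.ndarray  # (n_probes, nt)
    act_times: np.ndarray  # (n_nodes, MAX_ACTIVATIONS)
    act_count: np.ndarray  # (n_nodes,)
    frames: np.ndarray | None
    frame_times: np.ndarray | None
    final_states: np.ndarray
    stimuli: tuple = ()
    lat_mode: str = "max_dvdt"
    checkpoints: dict | None = None  # t_ms -> state snapshot, if requested

    def node_activations(self, flat_index: int) -> np.ndarray:
        return self.act_times[flat_index, : self.act_count[flat_index]]

    def activations_at(self, pos_mm) -> np.ndarray:
        ijk = self.grid.node_index(pos_mm)
        flat = np.ravel_multi_index(ijk, self.grid.shape)
        return self.node_activations(flat)

    def save_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.attrs["dt"] = self.dt
            fh.attrs["t_start"] = self.t_start
            fh.attrs["t_end"] = self.t_end
            fh.attrs["lat_mode"] = self.lat_mode
            fh.attrs["spacing_mm"] = np.asarray(self.grid.spacing_mm)
            fh.create_dataset("celltype", data=self.grid.celltype, compression="gzip")
            fh.create_dataset("probe_indices", data=self.probe_indices)
            fh.create_dataset("probe_times", data=self.probe_times)
            fh.create_dataset("probe_traces", data=self.probe_traces)
            fh.create_dataset("act_times", data=self.act_times, compression="gzip")
            fh.create_dataset("act_count", data=self.act_count)
            fh.create_dataset("final_states", data=self.final_states, compression="gzip")
            if self.frames is not None:
                fh.create_dataset("frames", data=self.frames, compression="gzip")
                fh.create_dataset("frame_times", data=self.frame_times)


def initial_tissue_states(grid: TissueGrid) -> np.ndarray:
    """Every node starts at the packaged quiescent resting state."""
    states = np.tile(lrd.RESTING_STATE, (grid.n_nodes, 1))
    return np.ascontiguousarray(states)


def stability_bound(grid: TissueGrid) -> float:
    """Largest stable explicit dt (ms) for the diffusion substep."""
    h = np.asarray(grid.spacing_mm, float) / 10.0
    gx, gy, gz = _build_faces(grid)
    total = np.zeros(grid.shape)
    total[:-1, :, :] += gx
    total[1:, :, :] += gx
    total[:, :-1, :] += gy
    total[:, 1:, :] += gy
    total[:, :, :-1] += gz
    total[:, :, 1:] += gz
    m = float(total.max())
    if m <= 0:
        return np.inf
    return 1.0 / m


def run_monodomain(grid: TissueGrid, stimuli, duration_ms, dt=0.02,
                   probes_mm=(), probe_interval_ms=1.0,
                   frame_interval_ms=None, frame_window_ms=None,
                   initial_states=None, t_start=0.0,
                   lat_mode="max_dvdt", nernst_interval_steps=25,
                   stop_quiescent_after_ms=None, quiescent_v=-65.0,
                   quiescent_check_ms=25.0,
                   checkpoint_times_ms=()) -> SimulationRecord:
    """Operator-split monodomain simulation.

    Parameters mirror the module conventions: ``stimuli`` is a sequence of
    :class:`StimulusEvent`; ``probes_mm`` physical probe positions whose
    voltage is sampled every ``probe_interval_ms``; frames are recorded at
    ``frame_interval_ms`` (optionally only inside ``frame_window_ms``).
    If ``stop_quiescent_after_ms`` is set, the run ends early once every
    node is below ``quiescent_v`` after that (absolute) time — used by the
    pacing protocols to skip electrically dead tail time.

    Raises ``ValueError`` if ``dt`` violates the explicit diffusion
    stability bound.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be > 0")
    bound = stability_bound(grid)
    if dt > bound:
        raise ValueError(
            f"dt={dt} ms violates the diffusion stability bound {bound:.4g} ms")
    for ev in stimuli:
        if not (t_start <= ev.onset_ms <= t_start + duration_ms):
            raise ValueError(f"stimulus at {ev.onset_ms} ms outside the run window")

    nx, ny, nz = grid.shape
    n = grid.n_nodes
    ct_flat = grid.celltype.ravel()
    active = np.flatnonzero((ct_flat == CT_NORMAL) | (ct_flat == CT_GZ)).astype(np.int64)
    scar_idx = np.flatnonzero(ct_flat == CT_SCAR).astype(np.int64)
    if active.size == 0 and scar_idx.size == 0:
        raise ValueError("grid has no tissue")

    states = (initial_tissue_states(grid) if initial_states is None
              else np.array(initial_states, dtype=np.float64, copy=True))
    lut = lrd.build_lookup_tables(dt)
    gx, gy, gz = _build_faces(grid)
    has_cross = bool(np.any(np.abs(grid.dxy) > 1e-15))
    active3 = ((grid.celltype == CT_NORMAL) | (grid.celltype == CT_GZ)
               | (grid.celltype == CT_SCAR)) if has_cross else None

    rem = grid.remodeling
    na_sc = np.array([0.0, 1.0, rem.sodium_scale, 0.0])
    ca_sc = np.array([0.0, 1.0, rem.l_type_calcium_scale, 0.0])
    kr_sc = np.array([0.0, 1.0, rem.ikr_scale, 0.0])
    ks_sc = np.array([0.0, 1.0, rem.iks_scale, 0.0])

    ners = np.zeros((n, 5))
    _update_nernst(states, active, ners)

    # stimulus schedule: per-node amplitude array updated at event edges
    stim_amp = np.zeros(n)
    n_steps = int(round(duration_ms / dt))
    edges = []  # (step, node_indices, +/-amplitude)
    for ev in stimuli:
        nodes = grid.nodes_in_ball(ev.center_mm, ev.radius_mm)
        if nodes.size == 0:
            raise ValueError(
                f"stimulus site at {ev.center_mm} mm touches no excitable node")
        s0 = int(round((ev.onset_ms - t_start) / dt))
        s1 = int(round((ev.onset_ms + ev.duration_ms - t_start) / dt))
        edges.append((s0, nodes, ev.amplitude))
        edges.append((s1, nodes, -ev.amplitude))
    edges.sort(key=lambda e: e[0])
    edge_pos = 0

    # probes
    probe_idx = np.array(
        [np.ravel_multi_index(grid.node_index(p), grid.shape) for p in probes_mm],
        dtype=np.int64)
    probe_every = max(1, int(round(probe_interval_ms / dt)))
    nt_probe = n_steps // probe_every + 1
    probe_times = np.empty(nt_probe)
    probe_traces = np.empty((probe_idx.size, nt_probe))
    ip = 0

    # frames
    frames = None
    frame_times_list = []
    frames_list = []
    frame_every = None
    if frame_interval_ms is not None:
        frame_every = max(1, int(round(frame_interval_ms / dt)))

    # activation tracking
    lat_flag = 0 if lat_mode == "max_dvdt" else 1
    up_state = np.zeros(n, dtype=np.int8)
    up_best = np.zeros(n)
    up_tbest = np.zeros(n)
    act_times = np.full((n, MAX_ACTIVATIONS), np.nan)
    act_count = np.zeros(n, dtype=np.int32)

    v_flat = states[:, 0]
    v3 = v_flat.reshape(grid.shape)
    v_tmp = v3.copy()
    v_prev = v_flat.copy()

    quiesce_every = max(1, int(round(quiescent_check_ms / dt)))
    cpar = grid.cparams
    ckpt_steps = {int(round((t - t_start) / dt)): float(t)
                  for t in checkpoint_times_ms}
    checkpoints: dict | None = {} if ckpt_steps else None

    def sample_probes(step):
        nonlocal ip
        probe_times[ip] = t_start + step * dt
        for q in range(probe_idx.size):
            probe_traces[q, ip] = states[probe_idx[q], 0]
        ip += 1

    def want_frame(step):
        if frame_every is None or step % frame_every != 0:
            return False
        if frame_window_ms is None:
            return True
        t = t_start + step * dt
        return frame_window_ms[0] - 1e-9 <= t <= frame_window_ms[1] + 1e-9

    sample_probes(0)
    if want_frame(0):
        frames_list.append(states[:, 0].reshape(grid.shape).astype(np.float32).copy())
        frame_times_list.append(t_start)

    t_end_actual = t_start + n_steps * dt
    for step in range(n_steps):
        while edge_pos < len(edges) and edges[edge_pos][0] == step:
            _, nodes, amp = edges[edge_pos]
            stim_amp[nodes] += amp
            edge_pos += 1

        v_prev[:] = states[:, 0]
        # diffusion substep
        v3[:] = states[:, 0].reshape(grid.shape)
        _diffusion_kernel(v3, v_tmp, gx, gy, gz, nx, ny, nz, dt)
        if has_cross:
            h = np.asarray(grid.spacing_mm, float) / 10.0
            _diffusion_cross_kernel(v3, v_tmp, grid.dxy, active3, h[0], h[1], dt)
        states[:, 0] = v_tmp.ravel()

        # reaction substep
        t_now = t_start + (step + 1) * dt
        if step % nernst_interval_steps == 0:
            _update_nernst(states, active, ners)
        _reaction_kernel(
            states, active, ct_flat, lut, dt, stim_amp, t_now,
            na_sc, ca_sc, kr_sc, ks_sc, ners,
            lrd.G_NA, lrd.G_KR_BAR, lrd.G_KS_BAR, lrd.G_K1_BAR, lrd.G_KP,
            lrd.I_NAK_BAR, lrd.KM_NAI, lrd.KM_KO, lrd.C_NACA, lrd.KSAT_NACA,
            lrd.KM_FCA,
            lrd.I_PCA_BAR, lrd.KM_PCA, lrd.G_CAB, lrd.G_NAB, lrd.KM_NS_CA,
            lrd.CURRENT_TO_MM_MYO, lrd.V_JSR / lrd.V_MYO, lrd.V_NSR / lrd.V_MYO,
            lrd.V_NSR / lrd.V_JSR,
            lrd.I_UP_BAR, lrd.KM_UP, lrd.I_UP_BAR / lrd.CA_NSR_MAX, lrd.TAU_TR,
            lrd.G_REL_BAR, lrd.TAU_REL_ON, lrd.TAU_REL_OFF,
            lrd.REL_TRIGGER_V, lrd.REL_EPISODE_REFRACTORY,
            lrd.TRPN_BAR, lrd.KM_TRPN, lrd.CMDN_BAR, lrd.KM_CMDN,
            lrd.CSQN_BAR, lrd.KM_CSQN)
        if scar_idx.size:
            _scar_kernel(states, scar_idx, dt, cpar.scar_leak,
                         cpar.scar_rest_mv, stim_amp)

        _track_activation(v_prev, states[:, 0], active, dt, t_now, lat_flag,
                          up_state, up_best, up_tbest, act_times, act_count)

        if checkpoints is not None and (step + 1) in ckpt_steps:
            checkpoints[ckpt_steps[step + 1]] = states.copy()

        if (step + 1) % probe_every == 0 and ip < nt_probe:
            sample_probes(step + 1)
        if want_frame(step + 1):
            frames_list.append(states[:, 0].reshape(grid.shape).astype(np.float32).copy())
            frame_times_list.append(t_start + (step + 1) * dt)

        if not np.all(np.isfinite(states[active[:1], 0])):
            raise FloatingPointError(f"non-finite voltage at t={t_now} ms")

        if (stop_quiescent_after_ms is not None
                and t_now >= stop_quiescent_after_ms
                and (step + 1) % quiesce_every == 0):
            if float(states[active, 0].max()) < quiescent_v:
                t_end_actual = t_now
                break

    if not np.all(np.isfinite(states[:, 0])):
        bad = int(np.flatnonzero(~np.isfinite(states[:, 0]))[0])
        raise FloatingPointError(
            f"non-finite voltage at node {bad} by t={t_end_actual} ms")

    if frames_list:
        frames = np.stack(frames_list)
        frame_times = np.asarray(frame_times_list)
    else:
        frames, frame_times = None, None

    return SimulationRecord(
        grid=grid, dt=dt, t_start=t_start, t_end=t_end_actual,
        probe_indices=probe_idx,
        probe_times=probe_times[:ip], probe_traces=probe_traces[:, :ip],
        act_times=act_times, act_count=act_count,
        frames=frames, frame_times=frame_times,
        final_states=states, stimuli=tuple(stimuli), lat_mode=lat_mode,
        checkpoints=checkpoints)


def measure_cv(record: SimulationRecord, probe_a_mm, probe_b_mm,
               beat="last") -> float:
    """Conduction velocity (cm/s) between two activated probe positions.

    Activation time is the in-run convention (max dV/dt by default).  The
    probes must be separated by at least 5 mm and both activated; the last
    (or first) recorded activation at each probe is used.
    """
    pa = np.asarray(probe_a_mm, float)
    pb = np.asarray(probe_b_mm, float)
    dist_mm = float(np.linalg.norm(pb - pa))
    if dist_mm < 5.0:
        raise ValueError("probes must be separated by at least 5 mm")
    ta = record.activations_at(pa)
    tb = record.activations_at(pb)
    if ta.size == 0 or tb.size == 0:
        raise RuntimeError("probe not activated: propagation failure")
    sel = -1 if beat == "last" else 0
    dt_ms = abs(float(tb[sel]) - float(ta[sel]))
    if dt_ms <= 0:
        raise RuntimeError("zero activation-time difference between probes")
    return dist_mm / 10.0 / (dt_ms / 1000.0)
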