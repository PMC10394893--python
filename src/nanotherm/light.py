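"""Steady-state diffusion approximation of NIR light transport on the phantom grid.

The fluence rate ``u`` (W/cm^2) satisfies

    div(-C grad u) + mu_a u = f,      C = 1 / (3 (mu_s' + mu_a)),

discretised with a 7-point finite-difference stencil and harmonic-mean
diffusion coefficients at cell faces, over the body voxels only.  The
illuminated surface patch carries the laser irradiance either as a
strict Dirichlet value (``u = S`` on the patch, the default, matching a
prescribed-fluence-rate boundary) or as a partial-current (Robin) flux
condition ``u + 2 C du/dn = 4 S``; all other body-air faces are
zero-flux.  The linear system is symmetric positive definite and is
solved by Jacobi-preconditioned conjugate gradients to a relative
residual below ``rtol``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg, splu

from .phantom import Label, Phantom

__all__ = [
    "TissueOptics",
    "OpticalFieldProps",
    "LaserSource",
    "FluenceField",
    "assemble_optics",
    "illumination_patch",
    "solve_fluence",
    "external_heat",
    "SolverError",
]

MM_PER_CM = 10.0


class SolverError(RuntimeError):
    """Sparse solve failed to reach the requested residual."""


@dataclass(frozen=True)
class TissueOptics:
    """Bulk tissue optical parameters at the laser wavelength (cm^-1)."""

    mu_at_cm1: float = 2.0  # tissue absorption
    mu_st_cm1: float = 61.0  # tissue scattering
    g: float = 0.67  # scattering anisotropy

    def __post_init__(self):
        if not (0 <= self.g < 1):
            raise ValueError("anisotropy g must be in [0, 1)")
        if self.mu_at_cm1 <= 0 or self.mu_st_cm1 <= 0:
            raise ValueError("tissue coefficients must be positive")


@dataclass
class OpticalFieldProps:
    """Per-voxel absorption, reduced scattering and diffusion coefficient."""

    mu_a_cm1: np.ndarray
    mu_s_red_cm1: np.ndarray
    diff_c_cm: np.ndarray  # C = 1/(3(mu_s' + mu_a)), defined inside the body


@dataclass(frozen=True)
class LaserSource:
    """CW laser illumination of a surface patch.

    The beam footprint defaults to the projection of the tumor onto the
    body surface along ``axis`` (light travelling in ``direction``),
    dilated by ``margin_mm``; a circular spot can be forced with
    ``spot_center_mm``/``spot_radius_mm``.
    """

    wavelength_nm: float = 808.0
    irradiance_W_cm2: float = 1.4
    duration_s: float = 300.0
    axis: int = 1
    direction: int = -1  # light travels toward -axis, illuminating the +axis surface
    margin_mm: float = 1.0
    spot_center_mm: tuple | None = None
    spot_radius_mm: float | None = None

    def __post_init__(self):
        if self.irradiance_W_cm2 < 0:
            raise ValueError("irradiance must be non-negative")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be -1 or +1")


@dataclass
class FluenceField:
    """Fluence rate u (W/cm^2) on the grid; zero outside the body."""

    u_W_cm2: np.ndarray
    diagnostics: dict = field(default_factory=dict)


def assemble_optics(
    phantom: Phantom,
    tissue: TissueOptics = TissueOptics(),
    mu_an_ref_cm1: float = 54.0,
    mu_sn_ref_cm1: float = 7.0e-4,
    f_v_ref: float = 1.0e-7,
) -> OpticalFieldProps:
    """Combine tissue optics with the nanohybrid contribution.

    ``mu_an_ref``/``mu_sn_ref`` are the nanohybrid coefficients at the
    reference volume fraction ``f_v_ref`` (the tabulated simulation
    inputs by default, or a :class:`~nanotherm.nanoptics.GansResult`'s
    values); they scale linearly with the local ``f_V`` map.
    """
    body = phantom.body_mask
    scale = phantom.f_v / f_v_ref
    mu_a = np.where(body, tissue.mu_at_cm1 + mu_an_ref_cm1 * scale, 0.0)
    mu_s = np.where(body, tissue.mu_st_cm1 + mu_sn_ref_cm1 * scale, 0.0)
    mu_s_red = mu_s * (1.0 - tissue.g)
    with np.errstate(divide="ignore"):
        diff_c = np.where(body, 1.0 / (3.0 * (mu_s_red + mu_a)), 0.0)
    return OpticalFieldProps(mu_a_cm1=mu_a, mu_s_red_cm1=mu_s_red, diff_c_cm=diff_c)


def from_gans(phantom: Phantom, gans, tissue: TissueOptics = TissueOptics()) -> OpticalFieldProps:
    """assemble_optics with the reference coefficients taken from a GansResult."""
    return assemble_optics(
        phantom,
        tissue,
        mu_an_ref_cm1=gans.mu_an_cm1,
        mu_sn_ref_cm1=gans.mu_sn_cm1,
        f_v_ref=gans.f_v,
    )


def illumination_patch(phantom: Phantom, src: LaserSource) -> np.ndarray:
    """Boolean grid of surface voxels whose beam-facing face is illuminated.

    For every grid line parallel to the beam axis whose transverse
    position lies in the (dilated) tumor footprint — or in the explicit
    spot — the first body voxel seen from the incoming side is marked.
    """
    body = phantom.body_mask
    ax, d = src.axis, src.direction
    other = [a for a in range(3) if a != ax]

    if src.spot_center_mm is not None:
        if src.spot_radius_mm is None:
            raise ValueError("spot_radius_mm required with spot_center_mm")
        idx = np.indices(phantom.shape, dtype=float)
        r2 = sum(
            (phantom.origin_mm[a] + idx[a] * phantom.spacing_mm - src.spot_center_mm[a]) ** 2
            for a in other
        )
        footprint3d = r2 <= src.spot_radius_mm**2
        foot2d = footprint3d.any(axis=ax)
    else:
        tumor = phantom.tumor_mask
        if not tumor.any():
            tumor = body
        foot2d = tumor.any(axis=ax)
        n_dil = int(round(src.margin_mm / phantom.spacing_mm))
        if n_dil > 0:
            foot2d = ndimage.binary_dilation(foot2d, iterations=n_dil)

    # first body voxel along the beam for each transverse position
    arr = body if d > 0 else np.flip(body, axis=ax)
    first = np.argmax(arr, axis=ax)  # 0 where the line has no body voxel
    has_body = body.any(axis=ax)
    patch = np.zeros(phantom.shape, dtype=bool)
    it = np.argwhere(foot2d & has_body)
    n_ax = phantom.shape[ax]
    for ij in it:
        vox = np.empty(3, dtype=int)
        vox[other[0]], vox[other[1]] = ij
        f = first[tuple(ij)]
        vox[ax] = f if d > 0 else n_ax - 1 - f
        patch[tuple(vox)] = True
    if not patch.any():
        raise ValueError("laser footprint does not intersect the body surface")
    return patch


def _solve_spd(A, b, x0=None, rtol=1e-10, maxiter=20000, label="diffusion"):
    """Jacobi-preconditioned CG with an explicit residual check."""
    diag = A.diagonal()
    M = sparse.diags(1.0 / diag)
    x, info = cg(A, b, x0=x0, rtol=rtol, atol=0.0, maxiter=maxiter, M=M)
    bnorm = np.linalg.norm(b)
    res = np.linalg.norm(A @ x - b) / bnorm if bnorm > 0 else np.linalg.norm(A @ x - b)
    if info != 0 or not np.isfinite(res) or res > 10 * rtol:
        # one LU fallback before declaring failure, for stiff small systems
        try:
            x = splu(A.tocsc()).solve(b)
            res = np.linalg.norm(A @ x - b) / max(bnorm, 1e-300)
        except Exception as exc:  # pragma: no cover
            raise SolverError(f"{label}: CG info={info}, residual={res:.2e}") from exc
        if not np.isfinite(res) or res > 10 * rtol:
            raise SolverError(f"{label}: LU fallback residual={res:.2e}")
    return x, res


def _grid_system(mask: np.ndarray, coeff: np.ndarray, reaction: np.ndarray, h: float):
    """Symmetric 7-point system  sum_f C_f (u_i - u_j)/h^2 + reaction_i u_i  over mask voxels.

    Returns (A as LIL-ready COO parts, index map).  Harmonic-mean face
    coefficients; faces to non-mask voxels are handled by the caller via
    diagonal/boundary additions.
    """
    n = int(mask.sum())
    index = -np.ones(mask.shape, dtype=np.int64)
    index[mask] = np.arange(n)
    rows, cols, vals = [], [], []
    diag = reaction[mask].astype(float).copy()
    inv_h2 = 1.0 / h**2
    for ax in range(3):
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[ax] = slice(None, -1)
        sl_hi[ax] = slice(1, None)
        m_lo, m_hi = mask[tuple(sl_lo)], mask[tuple(sl_hi)]
        pair = m_lo & m_hi
        c_lo, c_hi = coeff[tuple(sl_lo)][pair], coeff[tuple(sl_hi)][pair]
        c_face = 2.0 * c_lo * c_hi / (c_lo + c_hi) * inv_h2
        i_lo = index[tuple(sl_lo)][pair]
        i_hi = index[tuple(sl_hi)][pair]
        rows += [i_lo, i_hi]
        cols += [i_hi, i_lo]
        vals += [-c_face, -c_face]
        np.add.at(diag, i_lo, c_face)
        np.add.at(diag, i_hi, c_face)
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()
    return A, index


def solve_fluence(
    phantom: Phantom,
    props: OpticalFieldProps,
    src: LaserSource,
    mode: str = "dirichlet",
    rtol: float = 1e-10,
    volume_source_W_cm3: np.ndarray | None = None,
    patch: np.ndarray | None = None,
) -> FluenceField:
    """Solve the diffusion equation for the fluence rate on the body voxels.

    ``mode='dirichlet'`` prescribes ``u = S`` on the illuminated patch
    (half-cell ghost-value discretisation); ``mode='partial_current'``
    injects the irradiance through the partial-current Robin condition
    ``u + 2C du/dn = 4S``.  Non-illuminated body-air faces are zero-flux.
    A ``volume_source_W_cm3`` (e.g. an isotropic point source for
    verification) can be supplied instead of, or on top of, the surface
    source.
    """
    if mode not in ("dirichlet", "partial_current"):
        raise ValueError(f"unknown boundary mode {mode!r}")
    body = phantom.body_mask
    h = phantom.spacing_mm / MM_PER_CM  # cm
    A, index = _grid_system(body, props.diff_c_cm, props.mu_a_cm1, h)
    n = A.shape[0]
    rhs = np.zeros(n)
    if volume_source_W_cm3 is not None:
        rhs += volume_source_W_cm3[body]

    s_val = src.irradiance_W_cm2
    if s_val > 0 or volume_source_W_cm3 is None:
        if patch is None:
            patch = illumination_patch(phantom, src)
        pidx = index[patch]
        if np.any(pidx < 0):
            raise ValueError("illumination patch must lie on body voxels")
        cdiag = props.diff_c_cm[patch]
        extra = np.zeros(n)
        if mode == "dirichlet":
            # ghost value S at the face, half-cell conductance 2C/h^2
            g = 2.0 * cdiag / h**2
            extra[pidx] = g
            rhs[pidx] += g * s_val
        else:
            # net inward flux (2S - u/2) per unit area -> per volume /h
            extra[pidx] = 0.5 / h
            rhs[pidx] += 2.0 * s_val / h
        A = A + sparse.diags(extra)

    x, res = _solve_spd(A, rhs, rtol=rtol, label="fluence")
    if np.any(~np.isfinite(x)):
        raise SolverError("non-finite fluence values")
    u = np.zeros(phantom.shape)
    u[body] = np.maximum(x, 0.0)
    return FluenceField(
        u_W_cm2=u,
        diagnostics={"residual": res, "n_unknowns": n, "mode": mode},
    )


def external_heat(props: OpticalFieldProps, fluence: FluenceField) -> np.ndarray:
    """Laser heat deposition Q_ext = mu_a * u, returned in W/m^3."""
    if props.mu_a_cm1.shape != fluence.u_W_cm2.shape:
        raise ValueError("field shapes do not match")
    q_w_cm3 = props.mu_a_cm1 * fluence.u_W_cm2
    return q_w_cm3 * 1.0e6  # W/cm^3 -> W/m^3
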