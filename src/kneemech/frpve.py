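"""Fibril-reinforced poroviscoelastic (FRPVE) cartilage/meniscus material.

The solid skeleton is split into a tension-only collagen-fibril network and
an isotropic compressible Neo-Hookean matrix representing proteoglycans and
minor constituents; the tissue is biphasic, so the total stress is

    sigma_tot = sigma_fibrillar + sigma_nonfibrillar - p I,

with p the pore fluid pressure.  Each fibril is a rheological network: a
strain-stiffening elastic branch (tangent modulus E0 + E_eps * eps) in
parallel with a Maxwell branch (linear spring E_eps in series with a damper
eta).  Fibrils carry tension only.  Permeability is strain dependent through
the void ratio, k = k0 ((1+e)/(1+e0))^M.

Stress units are MPa at this level (tissue scale); the FE module converts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

# ---------------------------------------------------------------------------
# material parameters (tissue presets)
# ---------------------------------------------------------------------------

#: printed tissue parameter sets: E_m, v_m [-], E_0, E_eps [MPa],
#: k0 [1e-15 m^4/(N s)], M [-], eta [MPa s], fluid fraction n_f(z), D [-].
TISSUE_PRESETS: dict[str, dict] = {
    "femoral cartilage": dict(E_m=0.215, v_m=0.15, E_0=0.92, E_eps=150.0,
                              k_0=6.0, M=5.09, eta=1062.0, D=12.16,
                              n_f=("depth", 0.8, -0.15)),
    "tibial cartilage": dict(E_m=0.106, v_m=0.15, E_0=0.18, E_eps=23.6,
                             k_0=18.0, M=15.64, eta=1062.0, D=12.16,
                             n_f=("depth", 0.8, -0.15)),
    "patellar cartilage": dict(E_m=0.505, v_m=0.15, E_0=1.88, E_eps=597.0,
                               k_0=1.9, M=15.93, eta=1062.0, D=12.16,
                               n_f=("depth", 0.8, -0.15)),
    "meniscus": dict(E_m=0.5, v_m=0.36, E_0=28.0, E_eps=0.0,
                     k_0=1.25, M=5.09, eta=0.0, D=12.16,
                     n_f=("const", 0.72, 0.0)),
}


@dataclass
class FRPVEMaterial:
    """Tissue parameter set.

    Moduli in MPa, permeability ``k_0`` in units of 1e-15 m^4/(N s), damper
    ``eta`` in MPa s.  ``n_f`` is (kind, a, b): fluid fraction a + b*z of
    normalised depth z (z = 0 articular surface, z = 1 bone interface) for
    cartilage, constant for meniscus.
    """

    E_m: float
    v_m: float
    E_0: float
    E_eps: float
    k_0: float
    M: float
    eta: float
    D: float
    n_f: tuple = ("depth", 0.8, -0.15)
    tissue: str = ""

    @classmethod
    def from_preset(cls, tissue: str) -> "FRPVEMaterial":
        key = tissue.lower()
        if key not in TISSUE_PRESETS:
            raise KeyError(f"unknown tissue preset {tissue!r}; have {sorted(TISSUE_PRESETS)}")
        return cls(tissue=key, **TISSUE_PRESETS[key])

    def fluid_fraction(self, z) -> np.ndarray:
        """Fluid fraction n_f at normalised depth z in [0, 1]."""
        _, a, b = self.n_f
        return a + b * np.asarray(z, dtype=float)

    def void_ratio(self, z) -> np.ndarray:
        """Initial void ratio e0 = n_f/(1 - n_f)."""
        nf = self.fluid_fraction(z)
        return nf / (1.0 - nf)

    @property
    def k0_si(self) -> float:
        """Initial permeability in m^4/(N s)."""
        return self.k_0 * 1e-15


def permeability(void_ratio, reference_void_ratio, mat: FRPVEMaterial):
    """Strain-dependent permeability k = k0 ((1+e)/(1+e0))^M  [m^4/(N s)]."""
    e = np.asarray(void_ratio, dtype=float)
    e0 = np.asarray(reference_void_ratio, dtype=float)
    return mat.k0_si * ((1.0 + e) / (1.0 + e0)) ** mat.M


# ---------------------------------------------------------------------------
# fibril rheology
# ---------------------------------------------------------------------------


@dataclass
class FibrilState:
    """Internal state of one fibril's Maxwell branch."""

    viscous_strain: float = 0.0
    stress: float = 0.0
    prev_strain: float = 0.0


def _parallel_branch_stress(eps, mat: FRPVEMaterial):
    """Strain-stiffening elastic branch: sigma = E0*eps + 0.5*E_eps*eps^2."""
    return mat.E_0 * eps + 0.5 * mat.E_eps * eps * eps


def fibril_stress_update(state: FibrilState, fibril_strain: float, dt: float,
                         mat: FRPVEMaterial) -> tuple[float, FibrilState]:
    """Advance one fibril by dt under the given total strain (tension only).

    Backward-Euler update of the Maxwell branch; whenever the fibril is slack
    (strain <= 0) the stress is zero and the branch relaxes completely.
    Returns (stress [MPa], new state).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    eps = float(fibril_strain)
    if eps <= 0.0:
        return 0.0, FibrilState(viscous_strain=eps, stress=0.0, prev_strain=eps)
    if mat.eta > 0.0 and mat.E_eps > 0.0:
        tau = mat.eta / mat.E_eps
        # eps = eps_e + eps_v;  d(eps_v)/dt = sigma_m / eta = E_eps*eps_e/eta
        eps_e = (eps - state.viscous_strain) / (1.0 + dt / tau)
        sigma_m = mat.E_eps * eps_e
        eps_v = eps - eps_e
    else:
        sigma_m, eps_v = 0.0, eps
    sigma = _parallel_branch_stress(eps, mat) + sigma_m
    if sigma < 0.0:  # Maxwell branch cannot push the fibril into compression
        sigma, eps_v = 0.0, eps
    return sigma, FibrilState(viscous_strain=eps_v, stress=sigma, prev_strain=eps)


def fibril_tangent(state: FibrilState, fibril_strain: float, dt: float,
                   mat: FRPVEMaterial) -> float:
    """Consistent d(sigma)/d(eps) of :func:`fibril_stress_update` at this step."""
    eps = float(fibril_strain)
    if eps <= 0.0:
        return 0.0
    tang = mat.E_0 + mat.E_eps * eps
    if mat.eta > 0.0 and mat.E_eps > 0.0:
        tau = mat.eta / mat.E_eps
        tang += mat.E_eps / (1.0 + dt / tau)
    return tang


# ---------------------------------------------------------------------------
# fibril architecture
# ---------------------------------------------------------------------------


@dataclass
class FibrilDirections:
    """Per material point: primary unit direction set (depth-dependent arcade
    or circumferential), a shared near-isotropic secondary set, and weights.
    """

    primary: np.ndarray  # (n_points, n_primary, 3)
    secondary: np.ndarray  # (n_secondary, 3), shared by all points
    depth: np.ndarray  # (n_points,)
    primary_weight: float
    secondary_weight: float

    def __post_init__(self) -> None:
        for name, arr in (("primary", self.primary), ("secondary", self.secondary)):
            norms = np.linalg.norm(arr, axis=-1)
            if not np.allclose(norms, 1.0, atol=1e-12):
                raise ValueError(f"{name} fibril directions must be unit length")


def secondary_direction_set(count: int = 13, seed: int = 7, isotropy_tol: float = 5e-3,
                            max_iter: int = 4000) -> np.ndarray:
    """A fixed, seeded set of near-isotropic unit directions.

    Starts from a seeded random draw and polishes by projected gradient
    descent on ||sum n n^T / N - I/3||_F^2 until the directional second
    moment is within ``isotropy_tol`` of I/3 (Frobenius), so a 13-direction
    set behaves isotropically to well under 2 %.
    """
    rng = np.random.default_rng(seed)
    n = rng.normal(size=(count, 3))
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    lr = 0.2
    for _ in range(max_iter):
        M = n.T @ n / count
        Dev = M - np.eye(3) / 3.0
        if np.linalg.norm(Dev) < isotropy_tol:
            break
        grad = 4.0 / count * n @ Dev  # d/dn of ||Dev||^2
        n = n - lr * grad
        n /= np.linalg.norm(n, axis=1, keepdims=True)
    return n


def build_fibril_architecture(depth: np.ndarray, surface_normal: np.ndarray,
                              tangent_field: np.ndarray | None, tissue: str,
                              n_primary: int = 2, n_secondary: int = 13,
                              D: float = 12.16, seed: int = 7) -> FibrilDirections:
    """Primary/secondary fibril directions for each material point.

    Cartilage: primary fibrils follow a Benninghoff-style arcade, rotating
    from the split-line tangent at the articular surface (z = 0) to the
    surface normal at the bone interface (z = 1); the two primary fibrils at
    a point are the two split-line senses (+t, -t) rotated by the same arcade
    angle.  Meniscus: primaries are circumferential (tangent field).
    Secondary fibrils are one fixed seeded near-isotropic set.

    The density ratio D weights each primary fibril D times a secondary one;
    weights are normalised so all fibrils at a point sum to 1.
    """
    z = np.atleast_1d(np.asarray(depth, dtype=float))
    npts = len(z)
    normals = np.broadcast_to(np.asarray(surface_normal, dtype=float), (npts, 3)).copy()
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    if tangent_field is None:
        raise ValueError(f"tissue {tissue!r} needs a tangent (split-line/circumferential) field")
    tangents = np.broadcast_to(np.asarray(tangent_field, dtype=float), (npts, 3)).copy()
    # orthogonalise tangents against the normal
    tangents -= np.einsum("ij,ij->i", tangents, normals)[:, None] * normals
    tnorm = np.linalg.norm(tangents, axis=1, keepdims=True)
    if np.any(tnorm < 1e-12):
        raise ValueError("tangent field is parallel to the surface normal somewhere")
    tangents /= tnorm

    primary = np.empty((npts, n_primary, 3))
    if tissue.lower() == "meniscus":
        for k in range(n_primary):
            primary[:, k] = tangents if k % 2 == 0 else -tangents
    else:
        theta = z * (np.pi / 2.0)  # arcade: tangent at surface -> normal at bone
        arc_p = np.cos(theta)[:, None] * tangents + np.sin(theta)[:, None] * normals
        arc_m = np.cos(theta)[:, None] * (-tangents) + np.sin(theta)[:, None] * normals
        for k in range(n_primary):
            primary[:, k] = arc_p if k % 2 == 0 else arc_m
    primary /= np.linalg.norm(primary, axis=2, keepdims=True)

    secondary = secondary_direction_set(n_secondary, seed=seed)
    w_sec = 1.0 / (D * n_primary + n_secondary)
    return FibrilDirections(primary=primary, secondary=secondary, depth=z,
                            primary_weight=D * w_sec, secondary_weight=w_sec)


def total_fibrillar_stress(directions: FibrilDirections, strain: np.ndarray,
                           states: list[FibrilState], dt: float,
                           mat: FRPVEMaterial, point: int = 0,
                           commit: bool = False) -> tuple[np.ndarray, list[FibrilState]]:
    """Sum of fibril stress dyads at one material point (MPa).

    Each fibril's uniaxial strain is n.E.n; its stress enters the tensor as
    w_i * sigma_i * (n x n).  ``states`` lists all fibril states at the
    point, primaries first.  Returns the stress tensor and updated states.
    """
    E = np.asarray(strain, dtype=float).reshape(3, 3)
    prim = directions.primary[point]
    dirs = np.vstack([prim, directions.secondary])
    weights = np.concatenate([
        np.full(len(prim), directions.primary_weight),
        np.full(len(directions.secondary), directions.secondary_weight),
    ])
    if len(states) != len(dirs):
        raise ValueError(f"expected {len(dirs)} fibril states, got {len(states)}")
    sigma = np.zeros((3, 3))
    new_states = []
    for n_vec, w, st in zip(dirs, weights, states):
        eps_n = float(n_vec @ E @ n_vec)
        s, st_new = fibril_stress_update(st, eps_n, dt, mat)
        sigma += w * s * np.outer(n_vec, n_vec)
        new_states.append(st_new)
    return sigma, (new_states if commit else states)


# ---------------------------------------------------------------------------
# non-fibrillar matrix and total stress
# ---------------------------------------------------------------------------


def nonfibrillar_stress(F: np.ndarray, mat: FRPVEMaterial) -> np.ndarray:
    """Compressible Neo-Hookean Cauchy stress of the matrix (MPa).

    sigma = [mu (B - I) + lam ln(J) I] / J with (mu, lam) from (E_m, v_m).
    Accepts complex input for complex-step differentiation.
    """
    F = np.asarray(F).reshape(3, 3)
    J = np.linalg.det(F)
    if np.real(J) <= 0:
        raise ValueError("inverted element: det(F) <= 0")
    mu = mat.E_m / (2.0 * (1.0 + mat.v_m))
    lam = mat.E_m * mat.v_m / ((1.0 + mat.v_m) * (1.0 - 2.0 * mat.v_m))
    B = F @ F.T
    I = np.eye(3, dtype=F.dtype)
    return (mu * (B - I) + lam * np.log(J) * I) / J


def nonfibrillar_strain_energy(F: np.ndarray, mat: FRPVEMaterial) -> float:
    """Strain-energy density W(F) of the Neo-Hookean matrix (per ref. volume)."""
    F = np.asarray(F, dtype=float).reshape(3, 3)
    J = np.linalg.det(F)
    mu = mat.E_m / (2.0 * (1.0 + mat.v_m))
    lam = mat.E_m * mat.v_m / ((1.0 + mat.v_m) * (1.0 - 2.0 * mat.v_m))
    I1 = np.trace(F.T @ F)
    return 0.5 * mu * (I1 - 3.0) - mu * np.log(J) + 0.5 * lam * np.log(J) ** 2


def total_stress(fibrillar: np.ndarray, nonfibrillar: np.ndarray,
                 pore_pressure: float) -> np.ndarray:
    """sigma_tot = sigma_f + sigma_nf - p I."""
    return (np.asarray(fibrillar) + np.asarray(nonfibrillar)
            - pore_pressure * np.eye(3))
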