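"""Charge-fluctuation lattice model of DNA-DNA attraction between lipid bilayers.

Two parallel 20-bp duplexes are reduced to two rows of N interface
phosphate sites at spacing b along the helical axis, a distance x apart.
Each site carries an occupation variable σ ∈ {0, 1}: a site occupied by
a divalent counterion has net charge σα − 1 = +1e, an empty site −1e.
Ions hopping between the rows create correlated charge fluctuations;
summing the screened Coulomb energy over *all* 2^(2N) occupancy
configurations gives a grand-canonical free energy

    F(x) = U_rod(x) − ln Σ_σ exp(−U_corr(σ, x) + μ n_σ)      [k_B T]

whose x-dependence decides whether the pair attracts or repels.  The
configuration-independent mean-field term U_rod is the screened
repulsion of two uniformly charged rods of effective charge ν_eff(x),

    U_rod(x) = 2 l_B (ν_eff/L)² L K₀(κ x),

the standard Debye-Hückel result for parallel line charges.  The
site-site coupling scale is the Bjerrum length of the *fluctuating
divalent ion*, l_B(αe) = α² l_B(e) — the same scale used by the Γ =
l_B/d coupling analysis of the confined Mg²⁺ ions; set
``coupling_valence=1`` for the monovalent (bare site charge) scale.

Besides exact enumeration the module provides an equivalent banded
transfer-matrix evaluation (exact once interactions are truncated at a
site-offset cutoff), ground-state search, and Boltzmann sampling of
occupancy configurations used by the synthetic-configuration generator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy.special import k0, logsumexp

from . import electrolyte
from .electrolyte import (
    DEFAULT_TEMPERATURE,
    LIPID_EPSILON_R,
    SOLUTION_EPSILON_R,
    ElectrolyteCondition,
    IonSpecies,
)

__all__ = [
    "LatticeParams",
    "BindingConfiguration",
    "RodParams",
    "FreeEnergyProfile",
    "site_charge",
    "correlation_energy",
    "rod_repulsion",
    "effective_charge",
    "partition_free_energy",
    "transfer_matrix_free_energy",
    "free_energy_profile",
    "ground_state",
    "configuration_energies",
    "sample_configurations",
    "lipid_preset",
    "solution_preset",
]

#: exact enumeration is refused above this many total sites (2N)
ENUMERATION_CAP = 24


def _bjerrum(epsilon_r: float, temperature: float, charge: float = 1.0) -> float:
    cond = ElectrolyteCondition(
        species=(IonSpecies("ref", 1.0, 1),),
        epsilon_r=epsilon_r,
        temperature=temperature,
    )
    return electrolyte.bjerrum_length(charge, cond)


@dataclass(frozen=True)
class LatticeParams:
    """Interface-site lattice of the two-strand fluctuation model.

    Parameters
    ----------
    n_sites:
        N, interface phosphate sites per strand (N ≈ L/b).
    site_spacing:
        b, distance between interface sites along one strand (nm).
    strand_length:
        L, duplex length (nm).
    counterion_valence:
        α; +2 for Mg²⁺.  An occupied site has charge α − 1.
    epsilon_r:
        relative permittivity of the medium.
    kappa_model:
        screening (nm⁻¹) applied *inside* the correlation term; the
        salt-depleted interstitial gap of the lamellar phase justifies a
        value well below the bulk Debye κ.
    chemical_potential:
        μ per bound ion, in k_B T (grand-canonical weighting).
    temperature:
        kelvin.
    coupling_valence:
        charge (in e) whose Bjerrum length sets the site-site coupling;
        ``None`` means the counterion valence α.
    include_intra_strand:
        include same-strand site pairs in U_corr (required for the
        alternating ground-state pattern).
    """

    n_sites: int = 4
    site_spacing: float = 1.75
    strand_length: float = 6.8
    counterion_valence: int = 2
    epsilon_r: float = LIPID_EPSILON_R
    kappa_model: float = 0.1
    chemical_potential: float = 0.0
    temperature: float = DEFAULT_TEMPERATURE
    coupling_valence: int | None = None
    include_intra_strand: bool = True

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("need at least one site per strand")
        if self.site_spacing <= 0:
            raise ValueError("site spacing must be positive")
        if self.counterion_valence < 1:
            raise ValueError("counterion valence must be >= 1")
        if self.kappa_model < 0:
            raise ValueError("kappa_model must be >= 0")

    @classmethod
    def from_length(cls, strand_length: float, site_spacing: float, **kwargs) -> "LatticeParams":
        """N = round(L/b) construction."""
        n = max(1, round(strand_length / site_spacing))
        return cls(
            n_sites=n, site_spacing=site_spacing, strand_length=strand_length, **kwargs
        )

    @property
    def coupling_bjerrum(self) -> float:
        """Bjerrum length (nm) of the coupling charge."""
        q = self.coupling_valence if self.coupling_valence is not None else self.counterion_valence
        return _bjerrum(self.epsilon_r, self.temperature, q)


@dataclass(frozen=True)
class BindingConfiguration:
    """Binary occupancies σ of the two strands' interface sites."""

    occupancy_strand1: tuple[int, ...]
    occupancy_strand2: tuple[int, ...]

    def __post_init__(self) -> None:
        for occ in (self.occupancy_strand1, self.occupancy_strand2):
            if any(s not in (0, 1) for s in occ):
                raise ValueError("occupancies must be 0 or 1")
        if len(self.occupancy_strand1) != len(self.occupancy_strand2):
            raise ValueError("both strands must have the same number of sites")

    @property
    def n_bound(self) -> int:
        return sum(self.occupancy_strand1) + sum(self.occupancy_strand2)


@dataclass(frozen=True)
class RodParams:
    """Effective-charge anchors and screening for the mean-field rod term."""

    nu_eff_free: float
    d_free: float
    strand_length: float
    kappa: float
    epsilon_r: float
    temperature: float = DEFAULT_TEMPERATURE
    nu_eff_condensed: float | None = None
    d_condensed: float | None = None

    def __post_init__(self) -> None:
        if self.strand_length <= 0:
            raise ValueError("strand length must be positive")
        if (self.nu_eff_condensed is None) != (self.d_condensed is None):
            raise ValueError("condensed anchor needs both nu_eff_condensed and d_condensed")
        if self.d_condensed is not None and self.d_free <= self.d_condensed:
            raise ValueError("free-state spacing must exceed condensed-state spacing")


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Gauged free-energy profile F(x) − F(x_max) and its classification."""

    spacings: np.ndarray
    free_energy: np.ndarray
    classification: Literal["attractive", "repulsive"]
    minimum_spacing: float
    minimum_depth: float  # F_min − F(x_max); <= 0


def site_charge(sigma: int, alpha: int) -> float:
    """Net charge (e) of one interface site: σα − 1."""
    if sigma not in (0, 1):
        raise ValueError("sigma must be 0 or 1")
    return sigma * alpha - 1.0


def _charge_vectors(occ: Sequence[int], alpha: int) -> np.ndarray:
    return np.asarray(occ, dtype=float) * alpha - 1.0


def _coupling_tables(
    spacing: float, params: LatticeParams, offset_cutoff: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Screened-Coulomb couplings (k_BT per unit charge product, charges in e).

    Returns ``(v_inter, v_intra)`` indexed by site offset |i − i'|;
    inter-strand pair distance r = sqrt(x² + b²Δ²), intra-strand r = bΔ
    (the Δ=0 intra entry is unused).  Offsets beyond ``offset_cutoff``
    are zeroed (shared truncation for the transfer-matrix route).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    lb = params.coupling_bjerrum
    offsets = np.arange(params.n_sites, dtype=float)
    r_inter = np.sqrt(spacing**2 + (params.site_spacing * offsets) ** 2)
    v_inter = lb * np.exp(-params.kappa_model * r_inter) / r_inter
    r_intra = params.site_spacing * offsets
    v_intra = np.zeros_like(r_intra)
    if params.include_intra_strand and params.n_sites > 1:
        v_intra[1:] = lb * np.exp(-params.kappa_model * r_intra[1:]) / r_intra[1:]
    if offset_cutoff is not None:
        if offset_cutoff < 0:
            raise ValueError("offset cutoff must be >= 0")
        v_inter[offset_cutoff + 1 :] = 0.0
        v_intra[offset_cutoff + 1 :] = 0.0
    return v_inter, v_intra


def correlation_energy(
    config: BindingConfiguration,
    spacing: float,
    params: LatticeParams,
    offset_cutoff: int | None = None,
) -> float:
    """U_corr(σ, x) in k_B T for one occupancy configuration.

    Sum of screened pair energies c_i c_j l_B exp(−κ_model r)/r over
    inter-strand site pairs, plus (by default) intra-strand pairs.
    """
    v_inter, v_intra = _coupling_tables(spacing, params, offset_cutoff)
    alpha = params.counterion_valence
    c1 = _charge_vectors(config.occupancy_strand1, alpha)
    c2 = _charge_vectors(config.occupancy_strand2, alpha)
    idx = np.arange(params.n_sites)
    off = np.abs(idx[:, None] - idx[None, :])
    energy = float(c1 @ v_inter[off] @ c2)
    if params.include_intra_strand and params.n_sites > 1:
        w = v_intra[off]
        energy += 0.5 * float(c1 @ w @ c1 + c2 @ w @ c2)  # diagonal is zero
    return energy


def effective_charge(spacing: float, params: RodParams) -> float:
    """ν_eff(x) in e: linear in x through the printed anchors.

    Constant ``nu_eff_free`` when no condensed-state anchor is supplied;
    otherwise linear interpolation/extrapolation between the two.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if params.nu_eff_condensed is None:
        return params.nu_eff_free
    slope = (params.nu_eff_free - params.nu_eff_condensed) / (
        params.d_free - params.d_condensed
    )
    return params.nu_eff_condensed + slope * (spacing - params.d_condensed)


def rod_repulsion(spacing: float, params: RodParams) -> float:
    """Mean-field screened rod-rod repulsion U_rod(x) in k_B T.

    2 l_B λ² L K₀(κx) with λ = ν_eff(x)/L; non-negative by construction
    (both rods carry the same effective charge).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    lb = _bjerrum(params.epsilon_r, params.temperature)
    lam = effective_charge(spacing, params) / params.strand_length
    return 2.0 * lb * lam * lam * params.strand_length * k0(params.kappa * spacing)


def _enumeration_tables(
    spacing: float, params: LatticeParams, offset_cutoff: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Energies of all 2^(2N) configurations, vectorized.

    Returns ``(E, n_bound, C)`` where ``E[a, b]`` is U_corr for strand-1
    configuration index a and strand-2 index b, both enumerated in
    lexicographic occupancy order, ``n_bound[a]`` is the per-strand
    bound-ion count and ``C`` the per-strand site-charge matrix.
    """
    n = params.n_sites
    if 2 * n > ENUMERATION_CAP:
        raise ValueError(
            f"{2 * n} sites exceed the enumeration cap ({ENUMERATION_CAP}); "
            "use transfer_matrix_free_energy"
        )
    v_inter, v_intra = _coupling_tables(spacing, params, offset_cutoff)
    occ = np.array(list(itertools.product((0, 1), repeat=n)), dtype=float)
    C = occ * params.counterion_valence - 1.0  # (2^n, n)
    idx = np.arange(n)
    off = np.abs(idx[:, None] - idx[None, :])
    E = C @ v_inter[off] @ C.T  # inter-strand part, (2^n, 2^n)
    if params.include_intra_strand and n > 1:
        w = v_intra[off]
        self_e = 0.5 * np.einsum("ai,ij,aj->a", C, w, C)
        E = E + self_e[:, None] + self_e[None, :]
    n_bound = occ.sum(axis=1)
    return E, n_bound, C


def configuration_energies(
    spacing: float, params: LatticeParams, offset_cutoff: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Flattened U_corr and bound counts over all 2^(2N) configurations.

    Configuration order is lexicographic in the concatenated occupancy
    vector (strand 1 then strand 2).
    """
    E, n_bound, _ = _enumeration_tables(spacing, params, offset_cutoff)
    return E.ravel(), (n_bound[:, None] + n_bound[None, :]).ravel()


def partition_free_energy(
    spacing: float,
    lattice: LatticeParams,
    rods: RodParams,
    offset_cutoff: int | None = None,
) -> float:
    """Grand-canonical free energy F(x) in k_B T by exact enumeration.

    F = U_rod(x) − ln Σ_σ exp(−U_corr(σ, x) + μ n_σ).  U_rod is
    configuration independent and factors out exactly.
    """
    energies, n_bound = configuration_energies(spacing, lattice, offset_cutoff)
    log_z = logsumexp(-energies + lattice.chemical_potential * n_bound)
    return rod_repulsion(spacing, rods) - float(log_z)


def transfer_matrix_free_energy(
    spacing: float,
    lattice: LatticeParams,
    rods: RodParams,
    offset_cutoff: int = 1,
) -> float:
    """F(x) via a banded transfer matrix over site columns.

    Interactions are truncated at site offset ``offset_cutoff`` (m);
    the result then equals :func:`partition_free_energy` with the same
    cutoff, at 4^m transfer states instead of 4^N terms.  A column state
    is the occupancy pair (σ₁ᵢ, σ₂ᵢ) of the two strands at site i.
    """
    n = lattice.n_sites
    if offset_cutoff < 0:
        raise ValueError("offset cutoff must be >= 0")
    if offset_cutoff > n:
        raise ValueError("offset cutoff exceeds the site count")
    m = min(offset_cutoff, n - 1)  # offsets beyond n-1 do not occur
    v_inter, v_intra = _coupling_tables(spacing, lattice, offset_cutoff=m)
    alpha = lattice.counterion_valence
    mu = lattice.chemical_potential

    cols = list(itertools.product((0, 1), repeat=2))  # (sigma1, sigma2)
    charges = [(s1 * alpha - 1.0, s2 * alpha - 1.0) for s1, s2 in cols]

    def onsite(c: int) -> float:
        q1, q2 = charges[c]
        s1, s2 = cols[c]
        return q1 * q2 * v_inter[0] - mu * (s1 + s2)

    def bond(ca: int, cb: int, delta: int) -> float:
        """Coupling between column i (ca) and column i+delta (cb)."""
        a1, a2 = charges[ca]
        b1, b2 = charges[cb]
        e = (a1 * b2 + a2 * b1) * v_inter[delta]
        e += (a1 * b1 + a2 * b2) * v_intra[delta]
        return e

    # State = the last min(m, filled) columns, encoded base-4, most recent last.
    # Seed with the first column, then append columns one at a time.
    states: dict[tuple[int, ...], float] = {}
    for c in range(4):
        states[(c,)] = -onsite(c)  # log-weights
    for _ in range(1, n):
        new: dict[tuple[int, ...], list[float]] = {}
        for hist, logw in states.items():
            for c in range(4):
                e = onsite(c)
                for delta, prev in enumerate(reversed(hist), start=1):
                    e += bond(prev, c, delta)
                key = (hist + (c,))[-m:] if m > 0 else ()
                new.setdefault(key, []).append(logw - e)
        states = {k: float(logsumexp(np.array(v))) for k, v in new.items()}
    log_z = float(logsumexp(np.array(list(states.values()))))
    return rod_repulsion(spacing, rods) - log_z


def free_energy_profile(
    x_grid: Sequence[float],
    lattice: LatticeParams,
    rods: RodParams,
    depth_threshold: float = 0.5,
) -> FreeEnergyProfile:
    """F(x) on a grid, gauged to zero at the largest spacing.

    The profile is *attractive* when its minimum over the grid
    (excluding the gauge point) lies below −``depth_threshold`` k_B T.
    The lattice model carries no hard-core term, so the minimum of an
    attractive profile may sit at the short-spacing (contact) edge of
    the domain rather than strictly inside it.
    """
    x = np.asarray(x_grid, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 grid points")
    if np.any(x <= 0) or np.any(np.diff(x) <= 0):
        raise ValueError("x grid must be strictly increasing and positive")
    f = np.array([partition_free_energy(xi, lattice, rods) for xi in x])
    f -= f[-1]
    i_min = int(np.argmin(f[:-1]))
    depth = float(f[i_min])
    classification = "attractive" if depth < -depth_threshold else "repulsive"
    return FreeEnergyProfile(
        spacings=x,
        free_energy=f,
        classification=classification,
        minimum_spacing=float(x[i_min]),
        minimum_depth=depth,
    )


def ground_state(
    spacing: float, lattice: LatticeParams
) -> tuple[BindingConfiguration, float]:
    """Configuration minimizing U_corr, ties broken lexicographically."""
    E, _, _ = _enumeration_tables(spacing, lattice)
    flat = E.ravel()
    i = int(np.argmin(flat))  # first minimum == lexicographically smallest
    n = lattice.n_sites
    a, b = divmod(i, 2**n)
    occ = lambda k: tuple((k >> (n - 1 - j)) & 1 for j in range(n))  # noqa: E731
    config = BindingConfiguration(occ(a), occ(b))
    return config, float(flat[i])


def sample_configurations(
    spacing: float,
    lattice: LatticeParams,
    n_samples: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw occupancy configurations from the exact Boltzmann distribution.

    Returns an (n_samples, 2N) 0/1 array; columns are strand-1 sites
    followed by strand-2 sites, matching the enumeration order of
    :func:`configuration_energies`.
    """
    energies, n_bound = configuration_energies(spacing, lattice)
    logw = -energies + lattice.chemical_potential * n_bound
    p = np.exp(logw - logsumexp(logw))
    p /= p.sum()
    draws = rng.choice(p.size, size=n_samples, p=p)
    n = lattice.n_sites
    bits = ((draws[:, None] >> np.arange(2 * n - 1, -1, -1)) & 1).astype(np.int8)
    return bits


def _bulk_kappa(epsilon_r: float, temperature: float, mg_molar: float = 0.05) -> float:
    cond = electrolyte.mgcl2(mg_molar, epsilon_r=epsilon_r, temperature=temperature)
    return 1.0 / electrolyte.debye_length(cond)


def lipid_preset(mg_molar: float = 0.05) -> tuple[LatticeParams, RodParams]:
    """Membrane-confined DNA pair: ε_r = 40.1, weakly screened interstitial gap.

    Effective-charge anchors: ν_eff(4.0 nm) = −1e (free state) and
    ν_eff(3.0 nm) = +0.17e, half the near-neutral condensed-state
    solvation-shell charge split over the two duplexes.
    """
    lattice = LatticeParams(epsilon_r=LIPID_EPSILON_R, kappa_model=0.1)
    rods = RodParams(
        nu_eff_free=-1.0,
        d_free=4.0,
        nu_eff_condensed=+0.17,
        d_condensed=3.0,
        strand_length=6.8,
        kappa=_bulk_kappa(LIPID_EPSILON_R, DEFAULT_TEMPERATURE, mg_molar),
        epsilon_r=LIPID_EPSILON_R,
    )
    return lattice, rods


def solution_preset(mg_molar: float = 0.05) -> tuple[LatticeParams, RodParams]:
    """DNA pair in bulk electrolyte: ε_r = 92.2, bulk screening everywhere.

    The interstitial gap holds bulk salt, so the correlation term is
    screened with the bulk Debye κ, unlike the salt-depleted lamellar
    gap of the lipid preset.
    """
    kappa = _bulk_kappa(SOLUTION_EPSILON_R, DEFAULT_TEMPERATURE, mg_molar)
    lattice = LatticeParams(epsilon_r=SOLUTION_EPSILON_R, kappa_model=kappa)
    rods = RodParams(
        nu_eff_free=-3.5,
        d_free=4.0,
        strand_length=6.8,
        kappa=kappa,
        epsilon_r=SOLUTION_EPSILON_R,
    )
    return lattice, rods


def preset(name: str, mg_molar: float = 0.05) -> tuple[LatticeParams, RodParams]:
    """Look up a named parameter preset (``lipid`` or ``solution``)."""
    presets = {"lipid": lipid_preset, "solution": solution_preset}
    try:
        return presets[name](mg_molar)
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}") from None


def default_spacing_grid(
    x_min: float = 2.0, x_max: float = 6.0, n_points: int = 41
) -> np.ndarray:
    """Interhelical-spacing grid (nm) from duplex contact to the far field."""
    return np.linspace(x_min, x_max, n_points)
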