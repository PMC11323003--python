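"""Synthetic membrane-DNA-ion configurations.

Idealized stand-ins for the simulated lipoplex system, with the
statistical structure the analyses assume: two 20-bp B-DNA duplexes
reduced to their backbone phosphate sites, two planar DOPC/DOTAP
head-group surfaces, hexahydrated Mg²⁺ and Cl⁻ point ions at ~50 mM
MgCl₂, and a 1-D lamellar density stack for scattering.  Coordinate
convention (stated in all output headers): DNA long axis z, interhelical
axis x, membrane normal y.

Charges: phosphate sites −1e (5′ termini unphosphorylated, so a 20-bp
duplex carries 38 phosphates and two duplexes −76e), TAP_N and PC_N
+1e, PC_OP −1e, Mg +2e, Cl −1e.  Every generated frame is made exactly
electroneutral by the Cl⁻ count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import PER_NM3_PER_MOLAR
from . import fluctuation_model as fm
from .traj_analysis import Frame

__all__ = [
    "SystemRecipe",
    "DEFAULT_SEQUENCE",
    "build_duplex_sites",
    "build_membrane_planes",
    "place_ions",
    "build_system",
    "build_lamellar_stack",
]

#: the 20-bp quasi-random duplex sequence (5'->3'; complement implied)
DEFAULT_SEQUENCE = "GCATCTGGGCTATAAAAGGG"

#: effective contact distance of hexahydrated Mg2+, nm
MG_CONTACT_RADIUS = 0.45


@dataclass(frozen=True)
class SystemRecipe:
    """Composition and geometry of one synthetic configuration.

    Defaults mirror the study conditions: 20-bp duplexes, ~50 mM Mg²⁺,
    DOPC mole fraction 0.6, duplex pair along x between two head-group
    planes along y.
    """

    n_bp: int = 20
    interhelical_spacing: float = 3.0  # nm, center to center
    box: tuple[float, float, float] = (12.0, 10.0, 6.8)
    mg_concentration: float = 0.05  # mol/L
    phi_dopc: float = 0.6
    membrane_gap: float = 6.0  # nm between the two head-group planes
    lipids_per_plane: int = 100
    bilayer_thickness: float = 42.0  # Å, lamellar stack component
    dna_layer_thickness: float = 25.0  # Å
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bp < 1:
            raise ValueError("n_bp must be >= 1")
        if self.mg_concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not 0.0 <= self.phi_dopc <= 1.0:
            raise ValueError("phi_dopc must be in [0, 1]")
        if any(b <= 0 for b in self.box):
            raise ValueError("box edges must be positive")

    @property
    def lamellar_repeat(self) -> float:
        """Bilayer + DNA-monolayer repeat distance, Å."""
        return self.bilayer_thickness + self.dna_layer_thickness


def build_duplex_sites(
    n_bp: int,
    axis_origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    rise: float = 0.34,
    twist: float = 36.0,
    radius: float = 0.94,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Backbone phosphate sites of one idealized B-DNA duplex.

    Two helical tracks around an axis along z; the 5′ terminus of each
    strand is unphosphorylated, so the duplex carries 2(n_bp − 1) sites
    of charge −1e.  Returns ``(positions, species, charges)``.
    """
    if n_bp < 1:
        raise ValueError("n_bp must be >= 1")
    origin = np.asarray(axis_origin, dtype=float)
    twist_rad = math.radians(twist)
    strand_phase = (0.0, math.radians(154.0))  # minor-groove offset
    positions = []
    for phase in strand_phase:
        for i in range(1, n_bp):  # skip the unphosphorylated 5' terminus
            theta = phase + i * twist_rad
            positions.append(
                origin + [radius * math.cos(theta), radius * math.sin(theta), i * rise]
            )
    pos = np.array(positions) if positions else np.empty((0, 3))
    n = len(pos)
    return pos, np.array(["DNA_P"] * n, dtype=object), np.full(n, -1.0)


def build_membrane_planes(
    recipe: SystemRecipe,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two planar head-group surfaces at y = ±membrane_gap/2.

    Each plane holds ``lipids_per_plane`` lipids on an x-z grid:
    round(φ_DOPC n) DOPC lipids contribute a PC_N (+1e) / PC_OP (−1e)
    pair, the rest are DOTAP with a single TAP_N (+1e).  Net plane
    charge is therefore +1e per DOTAP.  Lipid identities are shuffled
    deterministically from the recipe seed.
    """
    n = recipe.lipids_per_plane
    lx, ly, lz = recipe.box
    if recipe.membrane_gap >= ly:
        raise ValueError("membrane gap does not fit in the box along y")
    nx = max(1, int(math.ceil(math.sqrt(n * lx / lz))))
    nz = int(math.ceil(n / nx))
    if nx * nz < n:
        raise ValueError("plane grid construction failed")
    n_pc = round(recipe.phi_dopc * n)
    rng = np.random.default_rng(recipe.seed)
    positions, species, charges = [], [], []
    for side, y0 in enumerate((-recipe.membrane_gap / 2, recipe.membrane_gap / 2)):
        kinds = np.array(["PC"] * n_pc + ["TAP"] * (n - n_pc), dtype=object)
        rng.shuffle(kinds)
        k = 0
        for ix in range(nx):
            for iz in range(nz):
                if k >= n:
                    break
                x = (ix + 0.5) * lx / nx - lx / 2
                z = (iz + 0.5) * lz / nz
                # head groups face the gap: offset anionic site toward it
                inward = 1.0 if side == 0 else -1.0
                if kinds[k] == "PC":
                    positions.append([x, y0, z])
                    species.append("PC_N")
                    charges.append(+1.0)
                    positions.append([x, y0 + 0.25 * inward, z])
                    species.append("PC_OP")
                    charges.append(-1.0)
                else:
                    positions.append([x, y0, z])
                    species.append("TAP_N")
                    charges.append(+1.0)
                k += 1
    return (
        np.array(positions),
        np.array(species, dtype=object),
        np.array(charges),
    )


def _static_assembly(recipe: SystemRecipe) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """DNA pair plus membrane planes, centered in the box frame [0, box)."""
    half = recipe.interhelical_spacing / 2.0
    z0 = (recipe.box[2] - (recipe.n_bp - 1) * 0.34) / 2.0
    parts = [
        build_duplex_sites(recipe.n_bp, axis_origin=(-half, 0.0, z0)),
        build_duplex_sites(recipe.n_bp, axis_origin=(+half, 0.0, z0)),
        build_membrane_planes(recipe),
    ]
    pos = np.vstack([p[0] for p in parts])
    spec = np.concatenate([p[1] for p in parts])
    chg = np.concatenate([p[2] for p in parts])
    # shift from the centered frame into [0, box)
    pos = pos + np.array([recipe.box[0] / 2.0, recipe.box[1] / 2.0, 0.0])
    return pos, spec, chg


def _interface_site_positions(recipe: SystemRecipe, n_sites: int, spacing_b: float) -> np.ndarray:
    """3-D positions of the two rows of interface lattice sites."""
    half = recipe.interhelical_spacing / 2.0
    z0 = (recipe.box[2] - (n_sites - 1) * spacing_b) / 2.0
    rows = []
    for x in (-half, half):
        for i in range(n_sites):
            rows.append([x + recipe.box[0] / 2.0, recipe.box[1] / 2.0, z0 + i * spacing_b])
    return np.array(rows)


def place_ions(
    recipe: SystemRecipe,
    mode: str = "uniform",
    lattice: fm.LatticeParams | None = None,
    n_sweeps: int = 200,
    rng: np.random.Generator | None = None,
) -> Frame:
    """Assemble the full frame: DNA + membrane + Mg²⁺/Cl⁻ ions.

    The Mg count is round(c_Mg N_A V); the Cl⁻ count is then fixed by
    exact electroneutrality of the whole frame.  Modes:

    ``uniform``
        ions uniformly random in the box.
    ``metropolis``
        uniform start, then ``n_sweeps`` Metropolis sweeps with a
        screened-Coulomb pair energy, drawing ions toward oppositely
        charged sites.
    ``lattice_sampler``
        one occupancy configuration of the two-row interface lattice is
        drawn from its exact Boltzmann distribution and Mg ions are
        placed on the occupied sites; remaining ions are uniform.
    """
    rng = np.random.default_rng(recipe.seed) if rng is None else rng
    box = np.asarray(recipe.box, dtype=float)
    pos_s, spec_s, chg_s = _static_assembly(recipe)
    volume = float(np.prod(box))
    n_mg = int(round(recipe.mg_concentration * volume * PER_NM3_PER_MOLAR))
    static_charge = float(chg_s.sum())
    n_cl = int(round(static_charge + 2.0 * n_mg))
    if n_cl < 0:
        raise ValueError(
            "negative implied Cl- count: the fixed charges exceed the cation charge"
        )

    mg_pos = rng.uniform(0.0, 1.0, size=(n_mg, 3)) * box
    cl_pos = rng.uniform(0.0, 1.0, size=(n_cl, 3)) * box

    if mode == "lattice_sampler":
        lattice = lattice or fm.lipid_preset()[0]
        occ = fm.sample_configurations(
            recipe.interhelical_spacing, lattice, 1, rng
        )[0]
        sites = _interface_site_positions(recipe, lattice.n_sites, lattice.site_spacing)
        occupied = sites[occ.astype(bool)]
        k = min(len(occupied), n_mg)
        mg_pos[:k] = occupied[:k]
    elif mode == "metropolis":
        mg_pos, cl_pos = _metropolis_relax(
            pos_s, chg_s, mg_pos, cl_pos, box, n_sweeps, rng
        )
    elif mode != "uniform":
        raise ValueError("mode must be 'uniform', 'metropolis' or 'lattice_sampler'")

    positions = np.vstack([pos_s, mg_pos, cl_pos])
    species = np.concatenate(
        [spec_s, np.array(["MG"] * n_mg + ["CL"] * n_cl, dtype=object)]
    )
    charges = np.concatenate([chg_s, np.full(n_mg, 2.0), np.full(n_cl, -1.0)])
    frame = Frame(
        positions,
        species,
        charges,
        box,
        comment="axes: DNA z, interhelical x, membrane normal y",
    )
    return frame.wrapped()


def _metropolis_relax(
    static_pos: np.ndarray,
    static_chg: np.ndarray,
    mg: np.ndarray,
    cl: np.ndarray,
    box: np.ndarray,
    n_sweeps: int,
    rng: np.random.Generator,
    bjerrum: float = 1.39,
    kappa: float = 1.2,
    step: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-particle Metropolis moves in a screened-Coulomb field.

    Mobile-mobile interactions are neglected (the static DNA/membrane
    charges dominate); the energy of one ion of charge q at r is
    q Σ_s q_s l_B exp(−κ d)/d over static sites, with a hydrated-ion
    contact floor on d.
    """
    mobile = np.vstack([mg, cl])
    q_mobile = np.concatenate([np.full(len(mg), 2.0), np.full(len(cl), -1.0)])

    def energy(p: np.ndarray, q: float) -> float:
        d = static_pos - p
        d -= box * np.round(d / box)
        dist = np.maximum(np.linalg.norm(d, axis=1), MG_CONTACT_RADIUS)
        return float(q * np.sum(static_chg * bjerrum * np.exp(-kappa * dist) / dist))

    for _ in range(n_sweeps):
        order = rng.permutation(len(mobile))
        for i in order:
            trial = np.mod(mobile[i] + rng.normal(0.0, step, 3), box)
            de = energy(trial, q_mobile[i]) - energy(mobile[i], q_mobile[i])
            if de <= 0 or rng.random() < math.exp(-de):
                mobile[i] = trial
    return mobile[: len(mg)], mobile[len(mg) :]


def build_system(recipe: SystemRecipe, mode: str = "uniform") -> Frame:
    """Convenience wrapper: full electroneutral frame from a recipe."""
    return place_ions(recipe, mode=mode)


def build_lamellar_stack(recipe: SystemRecipe, n_repeats: int = 8) -> Frame:
    """1-D lamellar stack of bilayer and DNA layers along y.

    Each repeat (default 42 Å bilayer + 25 Å DNA monolayer = 67 Å)
    contributes two head-group planes at the bilayer faces and one DNA
    plane at the center of the DNA layer; particles are neutral density
    markers for scattering.  The box height is n_repeats × repeat.
    """
    if n_repeats < 2:
        raise ValueError("need at least two repeats")
    repeat_nm = recipe.lamellar_repeat / 10.0
    t_bilayer = recipe.bilayer_thickness / 10.0
    lx, lz = recipe.box[0], recipe.box[2]
    if repeat_nm > recipe.box[1]:
        raise ValueError("lamellar repeat larger than the box height (y)")
    n_grid = 6  # in-plane marker grid
    xs = (np.arange(n_grid) + 0.5) * lx / n_grid
    zs = (np.arange(n_grid) + 0.5) * lz / n_grid
    gx, gz = np.meshgrid(xs, zs, indexing="ij")
    plane = np.column_stack([gx.ravel(), np.zeros(gx.size), gz.ravel()])
    positions, species = [], []
    for k in range(n_repeats):
        y0 = k * repeat_nm
        for y_plane, sp in (
            (y0, "LIPID_HEAD"),
            (y0 + t_bilayer, "LIPID_HEAD"),
            (y0 + t_bilayer + (repeat_nm - t_bilayer) / 2.0, "DNA_P"),
        ):
            p = plane.copy()
            p[:, 1] = y_plane
            positions.append(p)
            species.extend([sp] * len(p))
    pos = np.vstack(positions)
    box = np.array([lx, n_repeats * repeat_nm, lz])
    return Frame(
        pos,
        np.array(species, dtype=object),
        np.zeros(len(pos)),
        box,
        comment=(
            "lamellar stack along y (membrane normal); "
            f"repeat {recipe.lamellar_repeat:.1f} A"
        ),
    ).wrapped()
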