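"""Frame-based observables for membrane-DNA-ion configurations.

Operates on labeled point-charge :class:`Frame` objects (the stand-in
for MD configurations): axis concentration profiles, solvation-shell
net-charge decomposition, coordination counts per base pair, head-group
contact and Mg-bridge censuses, radial distribution functions and mean
nearest-neighbor ion separations.  All distances use the minimum-image
convention on orthorhombic periodic boxes, in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import PER_NM3_PER_MOLAR

__all__ = [
    "Frame",
    "Profile1D",
    "concentration_profile",
    "shell_net_charge",
    "compensation_fraction",
    "coordination_count",
    "contact_census",
    "radial_distribution",
    "mean_ion_separation",
]

_AXES = {"x": 0, "y": 1, "z": 2}

#: cationic head-group site labels (choline/TAP nitrogens)
CATIONIC_HEAD_SPECIES = ("TAP_N", "PC_N")
#: anionic / polar membrane site labels that coordinate Mg
ANIONIC_HEAD_SPECIES = ("PC_OP", "PC_O", "TAP_O")


@dataclass
class Frame:
    """Labeled point particles in an orthorhombic periodic box.

    ``positions`` (N, 3) nm, ``species`` length-N labels, ``charges``
    length-N values in e, ``box`` three edge lengths in nm.
    """

    positions: np.ndarray
    species: np.ndarray
    charges: np.ndarray
    box: np.ndarray
    comment: str = ""

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.species = np.asarray(self.species, dtype=object)
        self.charges = np.asarray(self.charges, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        n = self.positions.shape[0]
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (N, 3)")
        if len(self.species) != n or len(self.charges) != n:
            raise ValueError("species/charges/positions lengths differ")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def wrapped(self) -> "Frame":
        """Copy with all positions wrapped into [0, box)."""
        pos = np.mod(self.positions, self.box)
        return Frame(pos, self.species.copy(), self.charges.copy(), self.box.copy(), self.comment)

    def select(self, species: str | Sequence[str]) -> np.ndarray:
        """Boolean mask for one label or a collection of labels."""
        wanted = {species} if isinstance(species, str) else set(species)
        return np.isin(self.species, list(wanted))

    def require_species(self, species: str | Sequence[str]) -> np.ndarray:
        mask = self.select(species)
        if not mask.any():
            available = sorted(set(self.species))
            raise ValueError(
                f"species {species!r} absent from frame; available: {available}"
            )
        return mask

    def translated(self, shift: Sequence[float]) -> "Frame":
        """Rigidly translated copy, wrapped back into the box."""
        pos = np.mod(self.positions + np.asarray(shift, dtype=float), self.box)
        return Frame(pos, self.species.copy(), self.charges.copy(), self.box.copy(), self.comment)


@dataclass
class Profile1D:
    """Binned 1-D profile: centers, values, a unit label and the bin width."""

    bin_centers: np.ndarray
    values: np.ndarray
    units: str
    bin_width: float

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_centers.shape != self.values.shape:
            raise ValueError("bin_centers and values must have equal length")
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers, "value": self.values})


def _min_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    return d - box * np.round(d / box)


def _pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """(len(a), len(b)) minimum-image distance matrix."""
    d = a[:, None, :] - b[None, :, :]
    return np.linalg.norm(_min_image(d, box), axis=-1)


def _tree(points: np.ndarray, box: np.ndarray) -> cKDTree:
    wrapped = np.mod(points, box)
    wrapped[wrapped >= box] = 0.0  # guard the p == box float edge case
    return cKDTree(wrapped, boxsize=box)


def _sphere_slab_overlap(center: float, radius: float, lo: float, hi: float) -> float:
    """Volume of a sphere clipped by the slab lo <= x <= hi (no periodicity)."""
    a = max(lo, center - radius)
    b = min(hi, center + radius)
    if b <= a:
        return 0.0
    # integrate pi * (r^2 - (x - c)^2) dx from a to b
    f = lambda x: radius**2 * x - (x - center) ** 3 / 3.0  # noqa: E731
    return float(np.pi * (f(b) - f(a)))


def concentration_profile(
    frames: Iterable[Frame],
    species: str,
    axis: str = "x",
    bin_width: float = 0.1,
    volume_mode: str = "slab",
    solute_radii: Mapping[str, float] | None = None,
) -> Profile1D:
    """Molar concentration c(u) of one species along a box axis.

    c(u) = <count in bin>/(N_A V_u) averaged over frames.  ``slab`` mode
    uses the geometric slab volume; ``accessible`` mode subtracts the
    sphere-approximated volume of solute particles (radii per species in
    nm via ``solute_radii``) from each slab.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if volume_mode not in ("slab", "accessible"):
        raise ValueError("volume_mode must be 'slab' or 'accessible'")
    ax = _AXES[axis]
    box = frames[0].box
    length = box[ax]
    n_bins = max(1, int(np.floor(length / bin_width + 1e-9)))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    # particles in the final partial region (if any) fold into the last bin
    cross_section = float(np.prod(np.delete(box, ax)))
    counts = np.zeros(n_bins)
    volumes = np.full(n_bins, bin_width * cross_section)
    if volume_mode == "accessible":
        solute_radii = dict(solute_radii or {})
        excluded = np.zeros(n_bins)
    for fr in frames:
        fr.require_species(species)
        coords = np.mod(fr.positions[fr.select(species), ax], length)
        idx = np.minimum((coords / bin_width).astype(int), n_bins - 1)
        counts += np.bincount(idx, minlength=n_bins)
        if volume_mode == "accessible":
            for sp, radius in solute_radii.items():
                for c in np.mod(fr.positions[fr.select(sp), ax], length):
                    for k in range(n_bins):
                        excluded[k] += _sphere_slab_overlap(c, radius, edges[k], edges[k + 1])
    counts /= len(frames)
    if volume_mode == "accessible":
        volumes = np.maximum(volumes - excluded / len(frames), 1e-12)
    values = counts / (volumes * PER_NM3_PER_MOLAR)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Profile1D(centers, values, units="mol/L", bin_width=bin_width)


def shell_net_charge(
    frame: Frame,
    core_species: str | Sequence[str],
    cutoff: float = 1.0,
) -> tuple[float, pd.Series]:
    """Net charge Q_T (e) within a solvation shell around the core.

    The shell is the union of spheres of radius ``cutoff`` around every
    core particle; a particle is inside by its center.  Core particles
    themselves are included (distance zero).  Returns ``(Q_T, per-species
    decomposition)``; the decomposition sums to Q_T exactly.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    core_mask = frame.require_species(core_species)
    core_tree = _tree(frame.positions[core_mask], frame.box)
    all_tree = _tree(frame.positions, frame.box)
    in_shell = np.zeros(len(frame), dtype=bool)
    for hits in core_tree.query_ball_tree(all_tree, r=cutoff):
        in_shell[hits] = True
    in_shell[core_mask] = True
    charges = pd.Series(frame.charges[in_shell], dtype=float)
    labels = pd.Series(frame.species[in_shell].astype(str))
    decomposition = charges.groupby(labels).sum().sort_index()
    return float(charges.sum()), decomposition


def compensation_fraction(q_species: float, q_core: float) -> float:
    """Percent of a core charge compensated by one species' shell charge.

    100 · |q_species| / |q_core|, e.g. the fraction of the bare DNA
    charge neutralized by in-shell Mg²⁺.
    """
    if q_core == 0:
        raise ValueError("core charge must be nonzero")
    return 100.0 * abs(q_species) / abs(q_core)


def coordination_count(
    frame: Frame,
    center_species: str,
    partner_species: str,
    cutoff: float,
    normalize_per: int = 1,
) -> float:
    """Partners within ``cutoff`` of any center, per ``normalize_per`` units.

    E.g. Mg²⁺ ions within the coordination cutoff of any DNA phosphate,
    divided by the number of base pairs.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if normalize_per <= 0:
        raise ValueError("normalize_per must be positive")
    centers = frame.positions[frame.require_species(center_species)]
    partners = frame.positions[frame.require_species(partner_species)]
    if cutoff < 1e-12:
        return 0.0
    hits = _tree(centers, frame.box).query_ball_tree(_tree(partners, frame.box), r=cutoff)
    coordinated = set()
    for h in hits:
        coordinated.update(h)
    return len(coordinated) / normalize_per


def contact_census(
    frame: Frame,
    cutoff_direct: float = 0.6,
    cutoff_bridge: float = 0.5,
) -> tuple[int, int]:
    """Direct head-group contacts and Mg bridges to the DNA backbone.

    ``n_direct``: cationic head-group sites (TAP_N, PC_N) within
    ``cutoff_direct`` of any DNA phosphate.  ``n_bridge``: Mg ions
    simultaneously within ``cutoff_bridge`` of at least one anionic
    membrane site (PC_OP, PC_O, TAP_O) *and* one DNA phosphate.  Zero
    counts are valid results, so missing species are not an error here.
    """
    if cutoff_direct <= 0 or cutoff_bridge <= 0:
        raise ValueError("cutoffs must be positive")
    dna = frame.positions[frame.select("DNA_P")]
    if dna.size == 0:
        return 0, 0
    dna_tree = _tree(dna, frame.box)

    cation = frame.positions[frame.select(CATIONIC_HEAD_SPECIES)]
    n_direct = 0
    if cation.size:
        hits = _tree(cation, frame.box).query_ball_tree(dna_tree, r=cutoff_direct)
        n_direct = sum(1 for h in hits if h)

    mg = frame.positions[frame.select("MG")]
    anion = frame.positions[frame.select(ANIONIC_HEAD_SPECIES)]
    n_bridge = 0
    if mg.size and anion.size:
        mg_tree = _tree(mg, frame.box)
        near_dna = mg_tree.query_ball_tree(dna_tree, r=cutoff_bridge)
        near_anion = mg_tree.query_ball_tree(_tree(anion, frame.box), r=cutoff_bridge)
        n_bridge = sum(1 for a, b in zip(near_dna, near_anion) if a and b)
    return n_direct, n_bridge


def radial_distribution(
    frames: Iterable[Frame],
    species_a: str,
    species_b: str,
    r_max: float,
    bin_width: float = 0.02,
) -> Profile1D:
    """Pair distribution g(r) between two species in the periodic box.

    Normalized by the ideal-gas pair density, so g → 1 at large r for
    uncorrelated species.  ``r_max`` must not exceed half the smallest
    box edge (minimum-image validity).
    """
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    box = frames[0].box
    if r_max > box.min() / 2 + 1e-12:
        raise ValueError("r_max exceeds half the smallest box edge")
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    hist = np.zeros(n_bins)
    norm = 0.0
    for fr in frames:
        a = fr.positions[fr.require_species(species_a)]
        b = fr.positions[fr.require_species(species_b)]
        d = _pair_distances(a, b, fr.box)
        same = species_a == species_b
        if same:
            iu = np.triu_indices(len(a), k=1)
            d = d[iu]
            n_pairs = len(a) * (len(a) - 1) / 2.0
        else:
            d = d.ravel()
            n_pairs = len(a) * len(b)
        hist += np.histogram(d, bins=edges)[0]
        norm += n_pairs / fr.volume
    shell = (4.0 / 3.0) * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    expected = shell * norm
    g = np.divide(hist, expected, out=np.zeros_like(hist), where=expected > 0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Profile1D(centers, g, units="dimensionless", bin_width=bin_width)


def mean_ion_separation(
    frame: Frame,
    species: str,
    region: tuple[str, float, float] | None = None,
) -> float:
    """Mean nearest-neighbor minimum-image distance among selected ions.

    ``region`` optionally restricts the selection to an axis-aligned
    slab ``(axis, lo, hi)`` in wrapped coordinates.
    """
    mask = frame.require_species(species)
    pos = np.mod(frame.positions[mask], frame.box)
    if region is not None:
        axis, lo, hi = region
        coord = pos[:, _AXES[axis]]
        pos = pos[(coord >= lo) & (coord <= hi)]
    if len(pos) < 2:
        raise ValueError("need at least two particles in the region")
    d = _pair_distances(pos, pos, frame.box)
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())
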