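"""Frame file I/O, result writers, run configuration and the pipeline.

Frames travel as extended-XYZ (species, position, charge columns;
multi-frame files are concatenated blocks) or as PDB via biotite, with
charges resolved from a species table since PDB does not carry them.
Profiles are written as CSV with ``#`` provenance headers; scalar
summaries as JSON.  Every pipeline run writes a manifest echoing the
resolved configuration and its hash, and reruns with the same
configuration and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import ANGSTROM_PER_NM
from .traj_analysis import Frame, Profile1D

__all__ = [
    "read_frames",
    "write_frames",
    "write_profile_csv",
    "write_json",
    "RunConfig",
    "run_pipeline",
    "DEFAULT_SPECIES_CHARGES",
]

#: default charge (e) per species, used where the format cannot store them
DEFAULT_SPECIES_CHARGES = {
    "DNA_P": -1.0,
    "MG": 2.0,
    "CL": -1.0,
    "PC_N": 1.0,
    "PC_OP": -1.0,
    "PC_O": 0.0,
    "TAP_N": 1.0,
    "TAP_O": 0.0,
    "LIPID_HEAD": 0.0,
}

# species <-> (residue, atom) mapping for the PDB boundary (PDB fields
# are too short for the composite labels)
_PDB_NAMES = {
    "DNA_P": ("DNA", "P"),
    "MG": ("MG", "MG"),
    "CL": ("CL", "CL"),
    "PC_N": ("PC", "N"),
    "PC_OP": ("PC", "OP"),
    "PC_O": ("PC", "O"),
    "TAP_N": ("TAP", "N"),
    "TAP_O": ("TAP", "O"),
    "LIPID_HEAD": ("LIP", "H"),
}
_PDB_SPECIES = {v: k for k, v in _PDB_NAMES.items()}


def _log(msg: str, verbose: bool = True) -> None:
    if verbose:
        print(msg, file=sys.stderr)


# ---------------------------------------------------------------- extxyz


def _write_extxyz(frames: Sequence[Frame], path: Path) -> None:
    with path.open("w") as fh:
        for fr in frames:
            lx, ly, lz = fr.box
            lattice = f"{lx:.8g} 0 0 0 {ly:.8g} 0 0 0 {lz:.8g}"
            comment = fr.comment.replace('"', "'")
            fh.write(f"{len(fr)}\n")
            fh.write(
                f'Lattice="{lattice}" '
                'Properties=species:S:1:pos:R:3:charge:R:1 '
                f'Comment="{comment}"\n'
            )
            for sp, (x, y, z), q in zip(fr.species, fr.positions, fr.charges):
                fh.write(f"{sp} {x:.8f} {y:.8f} {z:.8f} {q:.4f}\n")


def _read_extxyz(path: Path) -> list[Frame]:
    frames: list[Frame] = []
    lines = path.read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as err:
            raise ValueError(f"{path}:{i + 1}: expected an atom count") from err
        header = lines[i + 1] if i + 1 < len(lines) else ""
        box = _parse_lattice(header, path, i + 2)
        comment = ""
        if 'Comment="' in header:
            comment = header.split('Comment="', 1)[1].rsplit('"', 1)[0]
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise ValueError(f"{path}:{i + 1}: truncated frame (expected {n} atoms)")
        species, pos, chg = [], [], []
        for k, line in enumerate(body):
            parts = line.split()
            if len(parts) < 5:
                raise ValueError(f"{path}:{i + 3 + k}: expected 'species x y z charge'")
            species.append(parts[0])
            pos.append([float(v) for v in parts[1:4]])
            chg.append(float(parts[4]))
        frames.append(Frame(np.array(pos), np.array(species, dtype=object),
                            np.array(chg), box, comment))
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return frames


def _parse_lattice(header: str, path: Path, lineno: int) -> np.ndarray:
    if 'Lattice="' not in header:
        raise ValueError(f"{path}:{lineno}: missing Lattice record")
    nums = [float(v) for v in header.split('Lattice="', 1)[1].split('"', 1)[0].split()]
    if len(nums) != 9:
        raise ValueError(f"{path}:{lineno}: Lattice must hold 9 numbers")
    return np.array([nums[0], nums[4], nums[8]])


# ------------------------------------------------------------------- pdb


def _write_pdb(frames: Sequence[Frame], path: Path) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    arrays = []
    for fr in frames:
        atoms = struc.AtomArray(len(fr))
        atoms.coord = fr.positions * ANGSTROM_PER_NM
        res, names = zip(*(_PDB_NAMES.get(s, ("UNK", str(s)[:4])) for s in fr.species))
        atoms.res_name = np.array(res)
        atoms.atom_name = np.array(names)
        atoms.res_id = np.arange(1, len(fr) + 1)
        atoms.chain_id = np.full(len(fr), "A")
        atoms.element = np.array([str(n)[0] for n in names])
        atoms.box = np.diag(fr.box * ANGSTROM_PER_NM)
        arrays.append(atoms)
    pdb = PDBFile()
    pdb.set_structure(arrays[0] if len(arrays) == 1 else struc.stack(arrays))
    pdb.write(str(path))


def _read_pdb(path: Path, species_charges: Mapping[str, float]) -> list[Frame]:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()  # AtomArrayStack
    if stack.array_length() == 0:
        raise ValueError(f"{path}: no atoms found")
    frames = []
    for atoms in stack:
        species = np.array(
            [
                _PDB_SPECIES.get((r, a), f"{r}_{a}")
                for r, a in zip(atoms.res_name, atoms.atom_name)
            ],
            dtype=object,
        )
        unknown = sorted({s for s in species if s not in species_charges})
        if unknown:
            raise ValueError(
                f"{path}: no charge mapping for species {unknown}; "
                "provide a species->charge table"
            )
        charges = np.array([species_charges[s] for s in species])
        box = atoms.box
        if box is None:
            raise ValueError(f"{path}: PDB lacks a CRYST1 box record")
        frames.append(
            Frame(atoms.coord / ANGSTROM_PER_NM, species, charges,
                  np.diag(box) / ANGSTROM_PER_NM)
        )
    return frames


# ------------------------------------------------------------- public API


def write_frames(frames: Frame | Sequence[Frame], path: str | Path,
                 format: str | None = None) -> None:
    """Write one or more frames as extended-XYZ (default) or PDB."""
    if isinstance(frames, Frame):
        frames = [frames]
    path = Path(path)
    fmt = format or ("pdb" if path.suffix.lower() == ".pdb" else "extxyz")
    if fmt == "extxyz":
        _write_extxyz(frames, path)
    elif fmt == "pdb":
        _write_pdb(frames, path)
    else:
        raise ValueError(f"unknown frame format {fmt!r}")


def read_frames(
    path: str | Path,
    format: str | None = None,
    species_charges: Mapping[str, float] | None = None,
) -> list[Frame]:
    """Read frames from extended-XYZ or PDB (charges via species table)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("pdb" if path.suffix.lower() == ".pdb" else "extxyz")
    if fmt == "extxyz":
        return _read_extxyz(path)
    if fmt == "pdb":
        return _read_pdb(path, {**DEFAULT_SPECIES_CHARGES, **(species_charges or {})})
    raise ValueError(f"unknown frame format {fmt!r}")


def write_profile_csv(
    profile: Profile1D,
    path: str | Path,
    header: Mapping[str, Any] | None = None,
    columns: tuple[str, str] = ("bin_center", "value"),
) -> None:
    """CSV with ``#`` provenance comments followed by the two columns."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# units: {profile.units}; bin_width: {profile.bin_width}\n")
        for key, val in (header or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write(f"{columns[0]},{columns[1]}\n")
        for c, v in zip(profile.bin_centers, profile.values):
            fh.write(f"{c:.8g},{v:.10g}\n")


def read_profile_csv(path: str | Path) -> Profile1D:
    df = pd.read_csv(path, comment="#")
    units = "unknown"
    bin_width = 0.0
    for line in Path(path).read_text().splitlines():
        if line.startswith("# units:"):
            parts = line[1:].split(";")
            units = parts[0].split(":", 1)[1].strip()
            bin_width = float(parts[1].split(":", 1)[1])
            break
    centers = df.iloc[:, 0].to_numpy()
    if bin_width <= 0:
        bin_width = float(centers[1] - centers[0]) if len(centers) > 1 else 1.0
    return Profile1D(centers, df.iloc[:, 1].to_numpy(), units=units, bin_width=bin_width)


def write_json(record: Mapping[str, Any], path: str | Path) -> None:
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")


# -------------------------------------------------------------- pipeline


_ALLOWED_KEYS = {
    "seed",
    "out_dir",
    "verbose",
    "preset",
    "x_min",
    "x_max",
    "n_points",
    "recipe",
    "analyses",
    "scatter",
}


@dataclass
class RunConfig:
    """Resolved settings for one end-to-end synthetic run.

    ``recipe`` holds :class:`~lipodna.synthetic.SystemRecipe` field
    overrides, ``analyses`` the frame observables to compute
    (``shellcharge``, ``contacts``), ``scatter`` scattering options.
    Unknown keys are rejected up front.
    """

    seed: int = 0
    out_dir: str = "results"
    verbose: bool = True
    preset: str = "lipid"
    x_min: float = 2.0
    x_max: float = 6.0
    n_points: int = 41
    recipe: dict = field(default_factory=dict)
    analyses: tuple[str, ...] = ("shellcharge", "contacts")
    scatter: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any]) -> "RunConfig":
        unknown = set(raw) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items()})
        if isinstance(cfg.analyses, list):
            cfg.analyses = tuple(cfg.analyses)
        return cfg

    def digest(self) -> str:
        """Hash of the scientific settings (paths and verbosity excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        payload.pop("verbose")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=list).encode()
        ).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """synth → model → analyze → scatter, deterministic given the seed.

    Writes the free-energy profile CSV, a scattering CSV, a census JSON
    and a manifest under ``config.out_dir``; returns the summary record.
    Stage failures propagate with the stage name attached.
    """
    from . import fluctuation_model as fm
    from . import scattering as sc
    from . import synthetic as syn
    from . import traj_analysis as ta

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    header = {"config_sha256": digest, "seed": config.seed,
              "axes": "DNA z, interhelical x, membrane normal y"}
    summary: dict[str, Any] = {"config_sha256": digest}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as err:
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        return wrap

    def _synth():
        recipe = syn.SystemRecipe(seed=config.seed, **config.recipe)
        frame = syn.place_ions(recipe, mode="uniform")
        write_frames(frame, out / "system.extxyz")
        _log(f"[synth] wrote {len(frame)} particles", config.verbose)
        return recipe, frame

    recipe, frame = stage("synth")(_synth)

    def _model():
        lattice, rods = fm.preset(config.preset)
        grid = np.linspace(config.x_min, config.x_max, config.n_points)
        profile = fm.free_energy_profile(grid, lattice, rods)
        prof = Profile1D(profile.spacings, profile.free_energy,
                         units="kBT", bin_width=float(grid[1] - grid[0]))
        write_profile_csv(prof, out / "free_energy_profile.csv", header,
                          columns=("spacing_nm", "free_energy_kT"))
        summary["model"] = {
            "preset": config.preset,
            "classification": profile.classification,
            "minimum_spacing_nm": profile.minimum_spacing,
            "minimum_depth_kT": profile.minimum_depth,
        }
        _log(f"[model] {config.preset}: {profile.classification}", config.verbose)

    stage("model")(_model)

    def _analyze():
        census: dict[str, Any] = {}
        if "shellcharge" in config.analyses:
            q_t, decomposition = ta.shell_net_charge(frame, "DNA_P", cutoff=1.0)
            census["shell_net_charge_e"] = q_t
            census["shell_decomposition_e"] = decomposition.to_dict()
        if "contacts" in config.analyses:
            n_direct, n_bridge = ta.contact_census(frame)
            census["n_direct_contacts"] = n_direct
            census["n_mg_bridges"] = n_bridge
        write_json({**header, **census}, out / "census.json")
        summary["analyze"] = census

    stage("analyze")(_analyze)

    def _scatter():
        stack = syn.build_lamellar_stack(recipe)
        spec = sc.ScatteringSpec(**config.scatter) if config.scatter else sc.ScatteringSpec()
        prof = sc.intensity([stack], spec)
        write_profile_csv(prof, out / "scattering.csv", header,
                          columns=("q_invA", "intensity"))
        q_peak, period = sc.first_peak(prof)
        summary["scatter"] = {"q_peak_invA": q_peak, "period_A": period}
        _log(f"[scatter] first peak {q_peak:.4f} 1/A, period {period:.1f} A",
             config.verbose)

    stage("scatter")(_scatter)

    write_json({**header, "summary": summary,
                "config": dataclasses.asdict(config)}, out / "manifest.json")
    return summary
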