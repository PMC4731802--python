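"""Topology/trajectory input, per-residue site reduction, and mobility measures.

Structures are read from PDB files and coordinate ensembles from DCD, XTC,
multi-model PDB, or a plain-text fixture dialect (one ``FRAME k`` line
followed by one ``x y z`` line per atom, documented in the README).
Reduction to one three-dimensional site per residue (Cα for amino acids,
C1' for nucleotides, or the heavy-atom center of geometry) produces the
:class:`SiteTrajectory` that every downstream stage consumes.

All coordinates are in Ångström; XTC files (nm) are converted on read.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    AlignmentError,
    DegenerateFitError,
    DimensionError,
    EmptyInputError,
    FormatError,
    InsufficientFramesError,
)

logger = logging.getLogger(__name__)

#: Residue names treated as solvent/ions and stripped on read by default.
SOLVENT_RESNAMES = {
    "HOH", "WAT", "TIP3", "TIP4", "SPC", "SOL",
    "NA", "CL", "K", "MG", "CA2", "ZN", "NA+", "CL-", "SOD", "CLA", "POT",
}

#: Standard nucleotide residue names (DNA and RNA), for the C1' site rule.
NUCLEOTIDE_RESNAMES = {
    "DA", "DT", "DG", "DC", "DI", "A", "T", "G", "C", "U", "I",
    "ADE", "THY", "GUA", "CYT", "URA",
    "DA5", "DT5", "DG5", "DC5", "DA3", "DT3", "DG3", "DC3",
}


@dataclass
class StructureModel:
    """A static molecular model: atoms plus a residue table.

    Atom arrays are parallel (length ``n_atoms``); residue arrays are
    parallel (length ``n_residues``).  ``atom_resindex`` maps each atom to a
    0-based row of the residue table.  ``domains`` is optional per-residue
    annotation (e.g. ``"DBD"``, ``"LBD"``, ``"hinge"``, ``"DNA"``).
    """

    atom_names: np.ndarray
    atom_elements: np.ndarray
    atom_resindex: np.ndarray
    atom_coords: np.ndarray  # (n_atoms, 3), Å, first frame / crystal coords
    atom_is_hydrogen: np.ndarray
    res_ids: np.ndarray       # author residue numbers
    res_names: np.ndarray
    res_chains: np.ndarray
    domains: np.ndarray | None = None
    source: str | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_residues(self) -> int:
        return len(self.res_ids)

    def heavy_atom_indices(self, residue: int) -> np.ndarray:
        mask = (self.atom_resindex == residue) & ~self.atom_is_hydrogen
        return np.nonzero(mask)[0]


@dataclass
class Trajectory:
    """All-atom coordinates for every frame of one StructureModel."""

    coords: np.ndarray  # (n_frames, n_atoms, 3), Å
    frame_interval_ps: float | None = None

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]


@dataclass
class SiteTrajectory:
    """Per-residue fluctuation ensemble: frames × sites × 3 (Å).

    One site per residue, ordered as in the source residue table (chain
    order of the file, then residue order within the chain).  Each site is a
    3-dimensional variable; this dimensionality ``d = 3`` is what enters the
    generalized-correlation mapping downstream.
    """

    coords: np.ndarray  # (n_frames, n_sites, 3)
    res_ids: np.ndarray
    res_names: np.ndarray
    chains: np.ndarray
    domains: np.ndarray | None = None
    dim: int = 3

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_sites(self) -> int:
        return self.coords.shape[1]

    def site_labels(self) -> list[str]:
        """``CHAIN:RESID`` labels, the addressing used by the CLI."""
        return [f"{c}:{r}" for c, r in zip(self.chains, self.res_ids)]


@dataclass
class MobilityProfile:
    """Per-site RMSF or per-frame RMSD, in Å, with its reference."""

    values: np.ndarray
    kind: str  # "rmsf" | "rmsd"
    reference: str = "mean structure"
    res_ids: np.ndarray | None = None
    chains: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _validate_pdb_text(path: str) -> None:
    """Cheap pre-scan so coordinate format errors name the offending line."""
    n_atom_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                n_atom_records += 1
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        raise FormatError(
                            f"{path}: malformed coordinate field on line "
                            f"{lineno}: {line[lo:hi]!r}"
                        ) from None
    if n_atom_records == 0:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")


def read_topology(path: str, strip_solvent: bool = True) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Hydrogens are retained but flagged; solvent and monoatomic ions are
    stripped by default.  Chain ids and author residue numbering are
    preserved.  Only the first altLoc of each atom is kept.
    """
    import MDAnalysis as mda

    _validate_pdb_text(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(path)
    atoms = u.atoms
    # first altLoc only
    if hasattr(atoms, "altLocs"):
        keep = np.isin(atoms.altLocs, ("", "A"))
        if not keep.all():
            logger.warning("dropping %d alternate-location atoms", (~keep).sum())
            atoms = atoms[keep]
    resnames = np.char.strip(atoms.resnames.astype(str))
    if strip_solvent:
        keep = ~np.isin(resnames, list(SOLVENT_RESNAMES))
        atoms = atoms[keep]
        resnames = resnames[keep]
    if len(atoms) == 0:
        raise EmptyInputError(f"{path}: no atoms left after solvent stripping")

    names = np.char.strip(atoms.names.astype(str))
    try:
        elements = np.char.strip(atoms.elements.astype(str))
    except (AttributeError, mda.exceptions.NoDataError):
        # guess from the atom name, PDB convention
        elements = np.array([_guess_element(n) for n in names])
    is_h = np.char.upper(elements) == "H"

    if hasattr(atoms, "chainIDs"):
        chains = np.char.strip(atoms.chainIDs.astype(str))
    else:
        chains = np.char.strip(atoms.segids.astype(str))
    chains = np.where(chains == "", "A", chains)

    # build residue table in file order
    key = list(zip(chains, atoms.resids, resnames))
    res_index = np.empty(len(atoms), dtype=int)
    table: dict[tuple, int] = {}
    for a, k in enumerate(key):
        if k not in table:
            table[k] = len(table)
        res_index[a] = table[k]
    res_keys = list(table)
    model = StructureModel(
        atom_names=names,
        atom_elements=elements,
        atom_resindex=res_index,
        atom_coords=atoms.positions.astype(float).copy(),
        atom_is_hydrogen=is_h,
        res_ids=np.array([k[1] for k in res_keys]),
        res_names=np.array([k[2] for k in res_keys]),
        res_chains=np.array([k[0] for k in res_keys]),
        source=path,
    )
    # every residue needs at least one heavy atom
    for r in range(model.n_residues):
        if len(model.heavy_atom_indices(r)) == 0:
            logger.warning("residue %s%s has no heavy atoms",
                           model.res_chains[r], model.res_ids[r])
    _check_gaps(model)
    return model


def _guess_element(name: str) -> str:
    stripped = name.lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[0] == "H":
        return "H"
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _check_gaps(model: StructureModel) -> None:
    for chain in np.unique(model.res_chains):
        ids = model.res_ids[model.res_chains == chain]
        diffs = np.diff(np.sort(ids))
        if (diffs > 1).any():
            logger.warning("chain %s has %d residue-numbering gap(s)",
                           chain, int((diffs > 1).sum()))


def read_trajectory(path: str, model: StructureModel,
                    fmt: str | None = None) -> Trajectory:
    """Read multi-frame coordinates matching ``model``.

    ``fmt`` is inferred from the extension when not given: ``.dcd``/``.xtc``
    (via MDAnalysis, using ``model.source`` as topology), ``.pdb`` with
    MODEL/ENDMDL blocks, or the plain-text fixture dialect (anything else).
    """
    if fmt is None:
        low = path.lower()
        if low.endswith(".dcd"):
            fmt = "dcd"
        elif low.endswith(".xtc"):
            fmt = "xtc"
        elif low.endswith(".pdb"):
            fmt = "pdb"
        else:
            fmt = "text"

    if fmt == "text":
        coords = _read_fixture_frames(path)
    else:
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if fmt == "pdb":
                u = mda.Universe(path)
            else:
                if model.source is None:
                    raise FormatError(
                        "binary trajectory requires a model read from file "
                        "(model.source is unset)")
                u = mda.Universe(model.source, path)
            frames = [u.atoms.positions.astype(float).copy()
                      for _ in u.trajectory]
        coords = np.array(frames)

    if coords.shape[1] != model.n_atoms:
        raise DimensionError(
            f"trajectory has {coords.shape[1]} atoms per frame but the model "
            f"has {model.n_atoms}")
    interval = None
    return Trajectory(coords=coords, frame_interval_ps=interval)


def _read_fixture_frames(path: str) -> np.ndarray:
    """Parse the fixture dialect: ``FRAME k`` then one ``x y z`` per atom."""
    frames: list[list[list[float]]] = []
    with open(path) as fh:
        current: list[list[float]] | None = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.upper().startswith("FRAME"):
                if current is not None:
                    frames.append(current)
                current = []
                continue
            if current is None:
                raise FormatError(f"{path}:{lineno}: coordinates before FRAME")
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 'x y z', got {line!r}")
            try:
                current.append([float(p) for p in parts])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric coordinate in {line!r}"
                ) from None
        if current is not None:
            frames.append(current)
    if not frames:
        raise EmptyInputError(f"{path}: no frames")
    n0 = len(frames[0])
    for k, fr in enumerate(frames):
        if len(fr) != n0:
            raise FormatError(
                f"{path}: frame {k} truncated ({len(fr)} atoms, expected {n0})")
    return np.array(frames, dtype=float)


def read_fixture_coordinates(path: str) -> np.ndarray:
    """Read fixture-dialect frames as a bare (frames, atoms, 3) array."""
    return _read_fixture_frames(path)


def write_fixture_trajectory(coords: np.ndarray, path: str,
                             precision: int = 6) -> None:
    """Write frames in the fixture dialect at fixed printed precision."""
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        for k, frame in enumerate(coords):
            fh.write(f"FRAME {k}\n")
            for x, y, z in frame:
                fh.write(f"{x:.{precision}f} {y:.{precision}f} {z:.{precision}f}\n")


# ---------------------------------------------------------------------------
# Site selection
# ---------------------------------------------------------------------------

def select_sites(traj: Trajectory, model: StructureModel,
                 rule: str = "representative") -> SiteTrajectory:
    """Reduce an all-atom trajectory to one 3-D site per residue.

    ``rule="representative"`` picks Cα for amino acids and C1' for
    nucleotides, falling back to the heavy-atom center of geometry (with a
    logged warning) when the representative atom is absent.
    ``rule="cog"`` always uses the heavy-atom center of geometry.
    """
    if rule not in ("representative", "cog"):
        raise ValueError(f"unknown site rule {rule!r}")
    if model.n_residues == 0:
        raise EmptyInputError("model has no residues")
    if traj.n_atoms != model.n_atoms:
        raise DimensionError("trajectory/model atom counts differ")

    n_frames = traj.n_frames
    sites = np.empty((n_frames, model.n_residues, 3))
    for r in range(model.n_residues):
        idx = None
        if rule == "representative":
            resname = model.res_names[r]
            target = "C1'" if resname in NUCLEOTIDE_RESNAMES else "CA"
            mask = (model.atom_resindex == r) & np.isin(
                model.atom_names, (target, target.replace("'", "*")))
            cand = np.nonzero(mask)[0]
            if len(cand) > 0:
                idx = cand[:1]
            else:
                logger.warning(
                    "residue %s%s lacks %s; using heavy-atom centroid",
                    model.res_chains[r], model.res_ids[r], target)
        if idx is None:
            idx = model.heavy_atom_indices(r)
            if len(idx) == 0:  # hydrogens only; last resort
                idx = np.nonzero(model.atom_resindex == r)[0]
        sites[:, r, :] = traj.coords[:, idx, :].mean(axis=1)
    return SiteTrajectory(
        coords=sites,
        res_ids=model.res_ids.copy(),
        res_names=model.res_names.copy(),
        chains=model.res_chains.copy(),
        domains=None if model.domains is None else model.domains.copy(),
    )


# ---------------------------------------------------------------------------
# Superposition and mobility
# ---------------------------------------------------------------------------

def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation+translation mapping mobile onto ref (least squares)."""
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    H = (mobile - mc).T @ (ref - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    return R, rc - mc @ R


def superpose(traj: SiteTrajectory, reference: int | str = "mean",
              fit_selection: np.ndarray | None = None) -> SiteTrajectory:
    """Rigid-body least-squares superposition of every frame.

    ``reference`` is a frame index or ``"mean"``; fitting to the mean
    iterates (fit → recompute mean → refit) until the mean structure stops
    moving, the usual essential-dynamics convention, which also makes the
    operation idempotent.  ``fit_selection`` restricts the fit to a site
    subset (all sites are still transformed).
    """
    sel = np.arange(traj.n_sites) if fit_selection is None else np.asarray(fit_selection)
    if len(sel) < 3:
        raise DegenerateFitError("need at least 3 fit sites")

    def _fit_once(coords: np.ndarray, ref: np.ndarray) -> np.ndarray:
        refsel = ref[sel]
        centered = refsel - refsel.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise DegenerateFitError("fit selection is collinear")
        out = np.empty_like(coords)
        for f in range(coords.shape[0]):
            R, t = _kabsch(coords[f, sel], refsel)
            out[f] = coords[f] @ R + t
        return out

    coords = traj.coords
    if reference == "mean":
        fitted = coords
        ref = coords.mean(axis=0)
        for _ in range(50):
            fitted = _fit_once(fitted, ref)
            new_ref = fitted.mean(axis=0)
            if np.abs(new_ref - ref).max() < 1e-12:
                break
            ref = new_ref
    else:
        fitted = _fit_once(coords, coords[int(reference)])
    return replace(traj, coords=fitted)


def rmsd(traj: SiteTrajectory, reference: int | str = "mean") -> MobilityProfile:
    """Per-frame RMSD (Å) to a reference frame or the mean structure."""
    ref = traj.coords.mean(axis=0) if reference == "mean" else traj.coords[int(reference)]
    diff = traj.coords - ref[None]
    vals = np.sqrt((diff ** 2).sum(axis=2).mean(axis=1))
    return MobilityProfile(values=vals, kind="rmsd",
                           reference=str(reference))


def rmsf(traj: SiteTrajectory) -> MobilityProfile:
    """Per-site root-mean-square fluctuation (Å) about the time mean."""
    if traj.n_frames < 2:
        raise InsufficientFramesError("RMSF needs at least 2 frames")
    mean = traj.coords.mean(axis=0)
    diff = traj.coords - mean[None]
    vals = np.sqrt((diff ** 2).sum(axis=2).mean(axis=0))
    return MobilityProfile(values=vals, kind="rmsf",
                           res_ids=traj.res_ids.copy(), chains=traj.chains.copy())


def differential_rmsf(apo: MobilityProfile, bound: MobilityProfile) -> np.ndarray:
    """RMSF(apo) − RMSF(bound) per site; positive = stabilized on binding."""
    if apo.res_ids is not None and bound.res_ids is not None:
        if (len(apo.res_ids) != len(bound.res_ids)
                or (apo.res_ids != bound.res_ids).any()
                or (apo.chains != bound.chains).any()):
            raise AlignmentError("apo/bound site lists differ")
    elif len(apo.values) != len(bound.values):
        raise AlignmentError("apo/bound profile lengths differ")
    return apo.values - bound.values


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_scores_as_bfactor(model: StructureModel, scores: dict | np.ndarray,
                            path: str) -> None:
    """Write the model as PDB with per-residue scores in the B-factor column.

    ``scores`` maps residue index → value (or is a per-residue array).
    Missing residues get 0.00 with a warning; values outside the fixed-width
    column are clipped with a warning.
    """
    if isinstance(scores, np.ndarray):
        scores = {i: float(v) for i, v in enumerate(scores)}
    vals = np.zeros(model.n_residues)
    for r in range(model.n_residues):
        if r in scores:
            vals[r] = scores[r]
        else:
            logger.warning("residue index %d missing from scores; writing 0.00", r)
    clipped = np.clip(vals, -9.99, 999.99)
    if (clipped != vals).any():
        logger.warning("%d score(s) clipped to fit the B-factor column width",
                       int((clipped != vals).sum()))
    with open(path, "w") as fh:
        serial = 0
        for a in range(model.n_atoms):
            serial += 1
            r = model.atom_resindex[a]
            name = model.atom_names[a]
            pname = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
            x, y, z = model.atom_coords[a]
            fh.write(
                f"ATOM  {serial:5d} {pname} {model.res_names[r]:<3s} "
                f"{str(model.res_chains[r])[:1]}{int(model.res_ids[r]):4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{clipped[r]:6.2f}"
                f"          {model.atom_elements[a]:>2s}\n")
        fh.write("END\n")


def write_mobility_tsv(profile: MobilityProfile, path: str,
                       header_extra: str = "") -> None:
    """Write a mobility profile as TSV (site_index, chain, resid, value)."""
    with open(path, "w") as fh:
        if header_extra:
            fh.write(f"# {header_extra}\n")
        fh.write(f"# kind={profile.kind} reference={profile.reference}\n")
        fh.write("site_index\tchain\tresid\tvalue\n")
        for i, v in enumerate(profile.values):
            chain = profile.chains[i] if profile.chains is not None else "-"
            resid = profile.res_ids[i] if profile.res_ids is not None else i
            fh.write(f"{i}\t{chain}\t{resid}\t{v:.6f}\n")
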