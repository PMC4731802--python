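"""Essential dynamics: PCA of site fluctuations and free-energy landscapes.

The 3N×3N covariance of the (superposed) site coordinates is diagonalized;
eigenvectors sorted by eigenvalue are the principal modes, PC1 being the
highest-amplitude collective motion.  Projecting the trajectory on a mode
gives a 1-D reaction coordinate q whose sampled histogram yields a
free-energy profile

    F(q) = −k_B·T · ln( P(q) / P_MAX(q) ),

offset so the most probable bin has F = 0.  Empty bins are reported as
undefined (NaN), never as a fabricated finite value.  Covariance is
mass-unweighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, InsufficientFramesError
from .trajectory_io import SiteTrajectory

#: Boltzmann constant in kcal/(mol·K).
KB_KCAL = 0.0019872041

DEFAULT_BINS = 50


@dataclass
class PCAModel:
    """Principal modes of the positional fluctuations."""

    mean: np.ndarray          # (n_sites, 3)
    eigenvectors: np.ndarray  # (3N, n_modes), orthonormal columns
    eigenvalues: np.ndarray   # Å², descending, clamped >= 0

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def variance_fractions(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else self.eigenvalues


@dataclass
class FreeEnergySurface:
    """Binned −k_B·T·ln(P/P_max) profile along one or two principal modes.

    ``free_energy`` is in k_B·T units (``units="kT"``) or kcal/mol; empty
    bins carry NaN.  For 2-D surfaces the arrays are (bins, bins) with
    ``centers`` holding the axis-1 grid and ``centers_2`` the axis-2 grid.
    """

    centers: np.ndarray
    probability: np.ndarray
    free_energy: np.ndarray
    temperature: float
    units: str = "kT"
    centers_2: np.ndarray | None = None

    @property
    def is_2d(self) -> bool:
        return self.centers_2 is not None


def fit_pca(traj: SiteTrajectory) -> PCAModel:
    """Diagonalize the 3N×3N covariance of positional fluctuations.

    Modes are sorted by decreasing eigenvalue; tiny negative eigenvalues
    from round-off are clamped to zero.  Warns when the frame count does
    not exceed 3N (undersampled covariance).
    """
    if traj.n_frames < 2:
        raise InsufficientFramesError("PCA needs at least 2 frames")
    flat = traj.coords.reshape(traj.n_frames, -1)
    if traj.n_frames <= flat.shape[1]:
        warnings.warn(f"only {traj.n_frames} frames for {flat.shape[1]} "
                      "degrees of freedom: covariance is rank-deficient",
                      stacklevel=2)
    mean = flat.mean(axis=0)
    centered = flat - mean
    # time-average (1/N) convention, so the trace equals the summed
    # squared RMSF exactly
    cov = centered.T @ centered / traj.n_frames
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    vec = vec[:, order]
    return PCAModel(mean=mean.reshape(-1, 3), eigenvectors=vec, eigenvalues=lam)


def project(traj: SiteTrajectory, model: PCAModel, mode: int = 0) -> np.ndarray:
    """Per-frame projection q_t = (x_t − mean)·v_mode (Å)."""
    if mode >= model.n_modes:
        raise IndexError(f"mode {mode} out of range ({model.n_modes} modes)")
    flat = traj.coords.reshape(traj.n_frames, -1)
    if flat.shape[1] != model.eigenvectors.shape[0]:
        raise AlignmentError("trajectory and PCA model site counts differ")
    return (flat - model.mean.reshape(-1)) @ model.eigenvectors[:, mode]


def _finish(prob: np.ndarray, temperature: float, units: str) -> np.ndarray:
    pmax = prob.max()
    with np.errstate(divide="ignore"):
        f = -np.log(prob / pmax)
    f[prob == 0] = np.nan
    if units == "kcal/mol":
        f = f * KB_KCAL * temperature
    elif units != "kT":
        raise ValueError(f"unknown units {units!r}")
    return f


def free_energy_1d(series: np.ndarray, bins: int = DEFAULT_BINS,
                   temperature: float = 300.0,
                   units: str = "kT") -> FreeEnergySurface:
    """Free-energy profile along one projection series.

    The minimum over occupied bins is exactly 0 (most probable bin);
    F >= 0 everywhere; empty bins are NaN.  A constant series degenerates
    to a single occupied bin with a warning.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 100:
        warnings.warn(f"only {len(series)} samples for the histogram",
                      stacklevel=2)
    if bins < 10:
        warnings.warn("fewer than 10 bins gives a very coarse profile",
                      stacklevel=2)
    if np.ptp(series) == 0:
        warnings.warn("constant series: degenerate single-bin surface",
                      stacklevel=2)
        return FreeEnergySurface(centers=np.array([series[0]]),
                                 probability=np.array([1.0]),
                                 free_energy=np.array([0.0]),
                                 temperature=temperature, units=units)
    counts, edges = np.histogram(series, bins=bins)
    prob = counts / counts.sum()
    return FreeEnergySurface(centers=0.5 * (edges[:-1] + edges[1:]),
                             probability=prob,
                             free_energy=_finish(prob, temperature, units),
                             temperature=temperature, units=units)


def free_energy_2d(series_a: np.ndarray, series_b: np.ndarray,
                   bins: int = DEFAULT_BINS, temperature: float = 300.0,
                   units: str = "kT") -> FreeEnergySurface:
    """Joint free-energy landscape over two projection series."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if len(a) != len(b):
        raise AlignmentError("projection series lengths differ")
    counts, ex, ey = np.histogram2d(a, b, bins=bins)
    prob = counts / counts.sum()
    return FreeEnergySurface(centers=0.5 * (ex[:-1] + ex[1:]),
                             centers_2=0.5 * (ey[:-1] + ey[1:]),
                             probability=prob,
                             free_energy=_finish(prob, temperature, units),
                             temperature=temperature, units=units)


def write_surface_tsv(fes: FreeEnergySurface, path: str,
                      header_extra: str = "") -> None:
    """Gridded TSV: q, [q2,] P, F (NaN for undefined bins)."""
    with open(path, "w") as fh:
        if header_extra:
            fh.write(f"# {header_extra}\n")
        fh.write(f"# temperature={fes.temperature} units={fes.units}\n")
        if fes.is_2d:
            fh.write("q1\tq2\tP\tF\n")
            for i, q1 in enumerate(fes.centers):
                for j, q2 in enumerate(fes.centers_2):
                    fh.write(f"{q1:.10g}\t{q2:.10g}\t{fes.probability[i, j]:.10g}"
                             f"\t{fes.free_energy[i, j]:.10g}\n")
        else:
            fh.write("q\tP\tF\n")
            for q, p, f in zip(fes.centers, fes.probability, fes.free_energy):
                fh.write(f"{q:.10g}\t{p:.10g}\t{f:.10g}\n")
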