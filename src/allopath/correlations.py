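"""Mutual-information-based generalized correlations and residue scores.

The coupling between two fluctuating sites x_i, x_j (each d-dimensional) is
quantified by their mutual information, estimated with the Kraskov
k-nearest-neighbour estimator (algorithm 1, max-norm), and mapped to a
generalized correlation coefficient

    GC_ij = sqrt(1 − exp(−2·I_ij / d)),   GC_ij ∈ [0, 1],

which unlike a Pearson coefficient is independent of the relative
orientation of the fluctuations and captures nonlinear coupling.  For
jointly Gaussian 1-D variables GC equals |r|.

From the GC matrix two per-residue summaries are derived:

* the **correlation score** of residue i — the sum of its GC entries above
  an intensity cutoff (default 0.6), optionally restricted to intra- or
  inter-domain pairs — measuring both the number and the intensity of the
  correlations a residue engages in;
* the **contribution score** of a residue *type* — the accumulated score
  AS_i (sum of GC over pairs involving at least one residue of the type)
  minus the expected score ES_i = TS·N_i/N, where TS is the sum of all
  pairwise GC, N_i the number of residues of the type and N the total.
  Positive values mean the type carries more of the correlation network
  than its abundance alone would predict.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import digamma
from sklearn.neighbors import KDTree

from .errors import (
    AlignmentError,
    AnnotationError,
    DataError,
    SettingsError,
)
from .trajectory_io import SiteTrajectory

logger = logging.getLogger(__name__)

DEFAULT_K = 6
DEFAULT_INTENSITY_CUTOFF = 0.6


@dataclass
class MIEstimate:
    """One k-NN mutual-information estimate (nats, clamped to >= 0)."""

    mi: float
    raw_mi: float
    k: int
    n_frames: int
    clamped: bool = False
    jittered: bool = False


@dataclass
class CorrelationMatrix:
    """Symmetric generalized-correlation matrix with its MI companion."""

    gc: np.ndarray       # (n, n), diagonal 1 by convention
    mi: np.ndarray       # (n, n), nats, diagonal 0 (self-MI diverges)
    d: int
    k: int
    n_frames: int
    res_ids: np.ndarray
    res_names: np.ndarray
    chains: np.ndarray
    domains: np.ndarray | None = None
    n_replicas: int = 1
    n_clamped: int = 0

    @property
    def n_sites(self) -> int:
        return self.gc.shape[0]

    def site_labels(self) -> list[str]:
        return [f"{c}:{r}" for c, r in zip(self.chains, self.res_ids)]


@dataclass
class ScoreVector:
    """Per-residue correlation scores under a mode/intensity filter."""

    scores: np.ndarray
    mode: str            # "all" | "intra" | "inter"
    cutoff: float
    res_ids: np.ndarray
    chains: np.ndarray
    domains: np.ndarray | None = None


# ---------------------------------------------------------------------------
# k-NN mutual information (Kraskov algorithm 1)
# ---------------------------------------------------------------------------

def _as_2d(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return a[:, None] if a.ndim == 1 else a


def knn_mutual_information(x: np.ndarray, y: np.ndarray, k: int = DEFAULT_K,
                           jitter_seed: int = 0) -> MIEstimate:
    """Kraskov estimate of I(x; y) in nats.

    For each sample, the max-norm distance eps to its k-th neighbour in the
    joint space is found, then the numbers n_x, n_y of samples strictly
    within eps in each marginal space enter

        I = psi(k) + psi(N) − < psi(n_x + 1) + psi(n_y + 1) >.

    Duplicate-heavy input (zero k-th neighbour distances) gets a tiny seeded
    jitter and a warning.  Slightly negative estimates — ordinary estimator
    noise near independence — are clamped to 0 with the raw value kept.
    """
    x, y = _as_2d(x), _as_2d(y)
    n = x.shape[0]
    if y.shape[0] != n:
        raise AlignmentError("x and y sample counts differ")
    if n < k + 1:
        raise DataError(f"need at least k+1={k + 1} samples, got {n}")

    joint = np.hstack([x, y])
    eps = KDTree(joint, metric="chebyshev").query(joint, k=k + 1)[0][:, -1]
    jittered = False
    if (eps == 0).any():
        rng = np.random.default_rng(jitter_seed)
        scale = 1e-10 * max(1.0, np.abs(joint).max())
        x = x + rng.normal(0, scale, x.shape)
        y = y + rng.normal(0, scale, y.shape)
        joint = np.hstack([x, y])
        eps = KDTree(joint, metric="chebyshev").query(joint, k=k + 1)[0][:, -1]
        jittered = True
        warnings.warn("duplicate-heavy input: applied seeded jitter before "
                      "the k-NN MI estimate", stacklevel=2)
    r = np.nextafter(eps, 0.0)  # strict inequality in the marginal counts
    nx_ = KDTree(x, metric="chebyshev").query_radius(x, r, count_only=True) - 1
    ny_ = KDTree(y, metric="chebyshev").query_radius(y, r, count_only=True) - 1
    raw = float(digamma(k) + digamma(n)
                - np.mean(digamma(nx_ + 1) + digamma(ny_ + 1)))
    clamped = raw < 0
    if clamped:
        logger.debug("clamped negative MI estimate %.4g to 0", raw)
    return MIEstimate(mi=max(raw, 0.0), raw_mi=raw, k=k, n_frames=n,
                      clamped=clamped, jittered=jittered)


def mi_to_gc(mi, d: int = 3):
    """GC = sqrt(1 − exp(−2·I/d)), clipped into [0, 1]."""
    return np.sqrt(np.clip(1.0 - np.exp(-2.0 * np.asarray(mi) / d), 0.0, 1.0))


def gc_matrix(traj: SiteTrajectory, k: int = DEFAULT_K,
              jitter_seed: int = 0) -> CorrelationMatrix:
    """Generalized-correlation matrix over all site pairs of a trajectory.

    Marginal k-d trees are built once per site; each unordered pair is
    estimated once and mirrored.  The diagonal is fixed to 1 by convention
    (self-MI diverges).
    """
    coords = np.asarray(traj.coords, dtype=float)
    if not np.isfinite(coords).all():
        f, s = np.argwhere(~np.isfinite(coords).all(axis=2))[0]
        raise DataError(f"non-finite coordinate at frame {f}, site {s}")
    n_frames, n, d = coords.shape
    if n_frames < 100:
        warnings.warn(f"only {n_frames} frames: k-NN MI estimates will be "
                      "noisy (>=100 recommended)", stacklevel=2)

    marg = [coords[:, i, :] for i in range(n)]
    trees = [KDTree(m, metric="chebyshev") for m in marg]
    mi = np.zeros((n, n))
    n_clamped = 0
    psi_kn = digamma(k) + digamma(n_frames)
    for i in range(n):
        for j in range(i + 1, n):
            joint = np.hstack([marg[i], marg[j]])
            eps = KDTree(joint, metric="chebyshev").query(joint, k=k + 1)[0][:, -1]
            if (eps == 0).any():
                est = knn_mutual_information(marg[i], marg[j], k=k,
                                             jitter_seed=jitter_seed)
                mi[i, j] = mi[j, i] = est.mi
                n_clamped += est.clamped
                continue
            r = np.nextafter(eps, 0.0)
            ni = trees[i].query_radius(marg[i], r, count_only=True) - 1
            nj = trees[j].query_radius(marg[j], r, count_only=True) - 1
            raw = psi_kn - float(np.mean(digamma(ni + 1) + digamma(nj + 1)))
            if raw < 0:
                n_clamped += 1
                raw = 0.0
            mi[i, j] = mi[j, i] = raw
    if n_clamped:
        logger.info("clamped %d of %d pair MI estimates to 0",
                    n_clamped, n * (n - 1) // 2)
    gc = mi_to_gc(mi, d=d)
    np.fill_diagonal(gc, 1.0)
    np.fill_diagonal(mi, 0.0)
    return CorrelationMatrix(
        gc=gc, mi=mi, d=d, k=k, n_frames=n_frames,
        res_ids=traj.res_ids.copy(), res_names=traj.res_names.copy(),
        chains=traj.chains.copy(),
        domains=None if traj.domains is None else traj.domains.copy(),
        n_clamped=n_clamped)


def average_matrices(matrices: list[CorrelationMatrix]) -> CorrelationMatrix:
    """Entrywise mean of replica GC (and MI) matrices.

    Replicas must share site lists and estimator settings; the replica
    count is recorded in the result.
    """
    if not matrices:
        raise AlignmentError("no matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        if m.k != first.k or m.d != first.d:
            raise SettingsError("replicas were estimated with different "
                                f"settings (k={m.k} vs {first.k})")
        if (m.n_sites != first.n_sites
                or (m.res_ids != first.res_ids).any()
                or (m.chains != first.chains).any()):
            raise AlignmentError("replica site lists differ")
    gc = np.mean([m.gc for m in matrices], axis=0)
    mi = np.mean([m.mi for m in matrices], axis=0)
    np.fill_diagonal(gc, 1.0)
    return replace(first, gc=gc, mi=mi, n_replicas=sum(m.n_replicas for m in matrices))


# ---------------------------------------------------------------------------
# Correlation and contribution scores
# ---------------------------------------------------------------------------

def _pair_mode_mask(matrix: CorrelationMatrix, mode: str) -> np.ndarray:
    n = matrix.n_sites
    if mode == "all":
        return np.ones((n, n), dtype=bool)
    if matrix.domains is None or (np.asarray(matrix.domains) == None).any():  # noqa: E711
        raise AnnotationError(f"mode={mode!r} requires domain labels on all sites")
    dom = np.asarray(matrix.domains)
    same = dom[:, None] == dom[None, :]
    if mode == "intra":
        return same
    if mode == "inter":
        return ~same
    raise ValueError(f"unknown mode {mode!r}")


def correlation_scores(matrix: CorrelationMatrix, mode: str = "all",
                       cutoff: float = DEFAULT_INTENSITY_CUTOFF) -> ScoreVector:
    """Per-residue sum of GC entries passing the mode and intensity filter.

    score_i = sum over j != i of GC_ij, restricted to pairs allowed by
    ``mode`` (all / intra-domain / inter-domain) and with GC_ij strictly
    above ``cutoff``.
    """
    gc = matrix.gc.copy()
    np.fill_diagonal(gc, 0.0)
    mask = _pair_mode_mask(matrix, mode) & (gc > cutoff)
    scores = np.where(mask, gc, 0.0).sum(axis=1)
    return ScoreVector(scores=scores, mode=mode, cutoff=cutoff,
                       res_ids=matrix.res_ids.copy(), chains=matrix.chains.copy(),
                       domains=None if matrix.domains is None
                       else matrix.domains.copy())


def contribution_scores(matrix: CorrelationMatrix,
                        type_map: dict | np.ndarray | None = None
                        ) -> pd.DataFrame:
    """Per-residue-type contribution table.

    For each type i: N_i (count), AS_i (sum of GC over unordered pairs with
    at least one member of the type — a pair with both members counted
    once), ES_i = TS·N_i/N, and contribution = AS_i − ES_i, with TS the sum
    of GC over all unordered pairs.  Returns a DataFrame indexed by type
    with ``attrs['TS']`` and ``attrs['N']`` recorded.
    """
    n = matrix.n_sites
    if type_map is None:
        types = np.asarray(matrix.res_names, dtype=object)
    elif isinstance(type_map, dict):
        try:
            types = np.array([type_map[i] for i in range(n)], dtype=object)
        except KeyError as e:
            raise AnnotationError(f"residue index {e.args[0]} untyped") from None
    else:
        types = np.asarray(type_map, dtype=object)
        if len(types) != n:
            raise AnnotationError("type map length mismatch")
    if any(t is None for t in types):
        raise AnnotationError("every residue must be typed")

    gc = matrix.gc.copy()
    np.fill_diagonal(gc, 0.0)
    ts = float(np.triu(gc, k=1).sum())
    rows = []
    for t in sorted(set(types)):
        member = types == t
        n_i = int(member.sum())
        row_sum = float(gc[member].sum())           # both-member pairs twice
        within = float(np.triu(gc[np.ix_(member, member)], k=1).sum())
        as_i = row_sum - within                     # ... now counted once
        es_i = ts * n_i / n
        rows.append((t, n_i, as_i, es_i, as_i - es_i))
    df = pd.DataFrame(rows, columns=["type", "N_i", "AS_i", "ES_i",
                                     "contribution"]).set_index("type")
    df.attrs["TS"] = ts
    df.attrs["N"] = n
    return df


# ---------------------------------------------------------------------------
# Text I/O
# ---------------------------------------------------------------------------

def write_matrix(matrix: CorrelationMatrix, path: str, which: str = "gc",
                 header_extra: str = "") -> None:
    """Write GC or MI as dense whitespace-delimited text with a label header."""
    data = matrix.gc if which == "gc" else matrix.mi
    labels = " ".join(matrix.site_labels())
    head = (f"{header_extra}\n" if header_extra else "") + \
        (f"which={which} d={matrix.d} k={matrix.k} n_frames={matrix.n_frames} "
         f"n_replicas={matrix.n_replicas}\n{labels}")
    np.savetxt(path, data, fmt="%.10g", header=head)


def read_matrix(path: str) -> tuple[np.ndarray, list[str]]:
    """Read a matrix written by :func:`write_matrix`; returns (data, labels)."""
    labels: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                cand = line[1:].split()
                if cand and all(":" in c for c in cand):
                    labels = cand
            else:
                break
    return np.loadtxt(path), labels


def write_scores_tsv(sv: ScoreVector, path: str, header_extra: str = "") -> None:
    with open(path, "w") as fh:
        if header_extra:
            fh.write(f"# {header_extra}\n")
        fh.write(f"# mode={sv.mode} cutoff={sv.cutoff}\n")
        fh.write("site_index\tchain\tresid\tdomain\tscore\n")
        for i, s in enumerate(sv.scores):
            dom = sv.domains[i] if sv.domains is not None else "-"
            fh.write(f"{i}\t{sv.chains[i]}\t{sv.res_ids[i]}\t{dom}\t{s:.10g}\n")
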