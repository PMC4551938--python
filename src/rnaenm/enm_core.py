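"""Elastic network construction and harmonic analysis.

An elastic network connects beads of a reference structure by harmonic
springs whenever their reference distance falls below an interaction cutoff
R_c; all springs share one master constant k.  The second-order expansion of
the network energy around the reference yields the 3N x 3N Hessian M, whose
pseudoinverse (up to the k_B T / k prefactor, set to 1 here) is the
equilibrium covariance of bead fluctuations.  This module builds networks
and Hessians, removes the six rigid-body zero modes, reduces the Hessian to
bead subsets by Schur complement, and provides the fully connected random
network used as a significance null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist

from .exceptions import (
    ConnectivityError,
    ContractError,
    CutoffNotFoundError,
    DegenerateGeometryError,
    ReductionError,
)
from .structures_io import BeadStructure

logger = logging.getLogger(__name__)

#: relative eigenvalue threshold below which a mode counts as zero energy
ZERO_MODE_RTOL = 1e-10
#: condition-number limit for the discarded block in the Schur reduction
REDUCTION_CONDITION_LIMIT = 1e12


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class ElasticNetwork:
    """Bead positions plus the symmetric spring list.

    ``pairs`` holds (i, j) with i < j; ``spring_constants`` the k_ij and
    ``reference_distances`` the equilibrium lengths (Å).  ``cutoff`` is the
    interaction radius, or ``None`` for the fully connected random null.
    """

    structure: BeadStructure
    pairs: np.ndarray
    spring_constants: np.ndarray
    reference_distances: np.ndarray
    cutoff: float | None

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.spring_constants = np.asarray(self.spring_constants, dtype=float)
        self.reference_distances = np.asarray(self.reference_distances, dtype=float)
        m = len(self.pairs)
        if len(self.spring_constants) != m or len(self.reference_distances) != m:
            raise ContractError("spring arrays length mismatch")
        if m:
            if np.any(self.pairs[:, 0] >= self.pairs[:, 1]):
                raise ContractError("springs must have i < j")
            if len({tuple(p) for p in self.pairs}) != m:
                raise ContractError("duplicate spring pairs")
            if np.any(self.reference_distances <= 0):
                raise ContractError("non-positive reference distance")
            if np.any(self.spring_constants < 0):
                raise ContractError("negative spring constant")

    @property
    def n_beads(self) -> int:
        return self.structure.n_beads

    @property
    def n_springs(self) -> int:
        return len(self.pairs)


@dataclass
class HessianMatrix:
    """3N x 3N Hessian of the harmonic network energy (k = 1 units).

    Validated on construction: symmetric, translation-invariant (each
    3-row block sums to zero over all column blocks) and positive
    semi-definite.
    """

    entries: np.ndarray
    bead_labels: list | None = None
    validate: bool = True

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=float)
        n3 = self.entries.shape[0]
        if self.entries.shape != (n3, n3) or n3 % 3:
            raise ContractError("Hessian must be square with 3N rows")
        if self.validate:
            self._check_invariants()

    def _check_invariants(self):
        h = self.entries
        scale = max(np.abs(h).max(), 1.0)
        if np.abs(h - h.T).max() > 1e-12 * scale:
            raise ContractError("Hessian not symmetric")
        # block row sums: rigid translation must be annihilated
        n = self.n_beads
        block_sum = h.reshape(n, 3, n, 3).sum(axis=2)
        if np.abs(block_sum).max() > 1e-9 * scale:
            raise ContractError("Hessian violates translation invariance")
        evals = np.linalg.eigvalsh(h)
        if evals[0] < -1e-10 * max(evals[-1], 1e-30):
            raise ContractError("Hessian not positive semi-definite")

    @property
    def n_beads(self) -> int:
        return self.entries.shape[0] // 3


@dataclass
class GaussianModel:
    """Gaussian fluctuation model: 3N x 3N covariance with eigenmodes.

    ``eigenvalues`` are nonincreasing and nonnegative (Å² with scale = 1),
    ``eigenvectors`` the matching orthonormal columns.  For ENM covariances
    the six rigid-body modes are removed (``n_zero_modes_removed = 6``);
    ensemble covariances keep all modes.
    """

    covariance: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero_modes_removed: int = 0
    scale: float = 1.0

    def __post_init__(self):
        self.covariance = np.asarray(self.covariance, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-9 * max(self.eigenvalues.max(initial=0.0), 1e-30)):
            raise ContractError("eigenvalues must be nonincreasing")
        if np.any(self.eigenvalues < -1e-12):
            raise ContractError("negative covariance eigenvalue")

    @classmethod
    def from_covariance(cls, covariance: np.ndarray, scale: float = 1.0,
                        n_zero_modes_removed: int = 0) -> "GaussianModel":
        """Eigendecompose a symmetric PSD covariance (tiny negatives clipped)."""
        c = np.asarray(covariance, dtype=float)
        c = 0.5 * (c + c.T)
        evals, evecs = scipy.linalg.eigh(c)
        evals = np.clip(evals, 0.0, None)
        # round-off dust relative to the leading mode is exactly zero
        evals[evals < 1e-12 * evals.max(initial=0.0)] = 0.0
        order = np.argsort(evals)[::-1]
        return cls(c, evals[order], evecs[:, order], n_zero_modes_removed, scale)

    @property
    def n_beads(self) -> int:
        return self.covariance.shape[0] // 3

    def diagonal_block(self, i: int) -> np.ndarray:
        return self.covariance[3 * i:3 * i + 3, 3 * i:3 * i + 3]

    def cross_block(self, i: int, j: int) -> np.ndarray:
        return self.covariance[3 * i:3 * i + 3, 3 * j:3 * j + 3]


@dataclass
class FluctuationProfile:
    """Per-site scalar flexibility values (Å², or rad² for angles)."""

    labels: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.labels) != len(self.values):
            raise ContractError("labels/values length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ContractError("non-finite fluctuation value")
        if np.any(self.values < -1e-12):
            raise ContractError("negative fluctuation value")
        self.values = np.clip(self.values, 0.0, None)

    def __len__(self) -> int:
        return len(self.values)

    def to_text(self) -> str:
        lines = ["chain\tresidue\trole\tvalue"]
        for lab, v in zip(self.labels, self.values):
            chain = getattr(lab, "chain_id", "")
            res = getattr(lab, "residue_key", lab)
            role = getattr(lab, "role", "")
            lines.append(f"{chain}\t{res}\t{role}\t{v:.10g}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_network(structure: BeadStructure, cutoff: float, k: float = 1.0,
                  spring_function=None) -> ElasticNetwork:
    """Connect all bead pairs closer than ``cutoff`` (strict) with springs.

    Every spring gets the master constant ``k``; passing ``spring_function``
    (a callable ``k(d)`` of the reference distance) replaces the uniform
    constant with a distance-dependent one.
    """
    if cutoff <= 0:
        raise ContractError("cutoff must be positive")
    if k <= 0:
        raise ContractError("spring constant must be positive")
    if structure.n_beads < 2:
        raise ContractError("need at least 2 beads")
    dists = pdist(structure.coords)
    iu, ju = np.triu_indices(structure.n_beads, k=1)
    mask = dists < cutoff
    pairs = np.column_stack([iu[mask], ju[mask]])
    d = dists[mask]
    if spring_function is not None:
        ks = np.array([float(spring_function(x)) for x in d])
    else:
        ks = np.full(len(d), float(k))
    return ElasticNetwork(structure, pairs, ks, d, cutoff)


def build_random_network(structure: BeadStructure, seed: int) -> ElasticNetwork:
    """Fully connected null network with k_ij ~ Uniform[0, 1].

    Carries no structural information beyond the bead positions themselves;
    its agreement with a reference ensemble sets the significance floor for
    real elastic networks.
    """
    if structure.n_beads < 2:
        raise ContractError("need at least 2 beads")
    rng = np.random.default_rng(seed)
    dists = pdist(structure.coords)
    iu, ju = np.triu_indices(structure.n_beads, k=1)
    if np.any(dists <= 0):
        raise DegenerateGeometryError("coincident beads in structure")
    ks = rng.uniform(0.0, 1.0, size=len(dists))
    return ElasticNetwork(structure, np.column_stack([iu, ju]), ks, dists, None)


# ---------------------------------------------------------------------------
# Hessian and spectral analysis
# ---------------------------------------------------------------------------

def hessian(network: ElasticNetwork) -> HessianMatrix:
    """Hessian of the pairwise harmonic energy at the reference structure.

    For a springed pair (i, j) with unit reference separation d̂ the
    off-diagonal 3x3 block is −k_ij (d̂ ⊗ d̂); diagonal blocks accumulate
    the negated sum of the bead's off-diagonal blocks, which enforces
    translation invariance exactly.
    """
    n = network.n_beads
    h = np.zeros((3 * n, 3 * n))
    coords = network.structure.coords
    for (i, j), k_ij, d in zip(network.pairs, network.spring_constants,
                               network.reference_distances):
        sep = coords[j] - coords[i]
        norm = np.linalg.norm(sep)
        if norm < 1e-9:
            raise DegenerateGeometryError(
                f"coincident beads {i}, {j} share a spring"
            )
        u = sep / norm
        block = k_ij * np.outer(u, u)
        h[3 * i:3 * i + 3, 3 * j:3 * j + 3] -= block
        h[3 * j:3 * j + 3, 3 * i:3 * i + 3] -= block
        h[3 * i:3 * i + 3, 3 * i:3 * i + 3] += block
        h[3 * j:3 * j + 3, 3 * j:3 * j + 3] += block
    return HessianMatrix(h, network.structure.labels)


def network_energy(network: ElasticNetwork, coords: np.ndarray) -> float:
    """Harmonic network energy U = ½ Σ k_ij (|r_i − r_j| − d̃_ij)²."""
    coords = np.asarray(coords, dtype=float)
    diffs = coords[network.pairs[:, 1]] - coords[network.pairs[:, 0]]
    d = np.linalg.norm(diffs, axis=1)
    return float(0.5 * np.sum(network.spring_constants *
                              (d - network.reference_distances) ** 2))


def zero_modes(h: HessianMatrix, rel_tol: float = ZERO_MODE_RTOL):
    """Count and return the zero-energy modes of a Hessian.

    A mode counts as zero when its eigenvalue is below ``rel_tol`` times the
    largest eigenvalue.  A connected, non-collinear network has exactly the
    six rigid translations and rotations here; extra zero modes signal
    disconnected components or degenerate geometry.
    """
    evals, evecs = scipy.linalg.eigh(h.entries)
    lam_max = max(evals[-1], 0.0)
    if lam_max <= 0.0:
        count = len(evals)
    else:
        count = int(np.sum(evals < rel_tol * lam_max))
    return count, evecs[:, :count]


def min_viable_cutoff(structure: BeadStructure, scan_min: float = 3.0,
                      scan_max: float = 30.0, step: float = 1.0,
                      k: float = 1.0) -> float:
    """Smallest grid cutoff whose network has exactly six zero modes.

    Scans ``scan_min`` to ``scan_max`` inclusive in ``step`` increments
    (default 3–30 Å in 1 Å steps).
    """
    if not (scan_min < scan_max) or step <= 0:
        raise ContractError("invalid scan grid")
    grid = np.arange(scan_min, scan_max + 0.5 * step, step)
    counts = []
    for cutoff in grid:
        net = build_network(structure, float(cutoff), k=k)
        count, _ = zero_modes(hessian(net))
        if count == 6:
            return float(cutoff)
        counts.append(count)
    raise CutoffNotFoundError(
        "no grid cutoff yields exactly 6 zero modes "
        f"(zero-mode counts ranged {min(counts)}–{max(counts)})"
    )


def covariance_from_hessian(h: HessianMatrix, scale: float = 1.0,
                            expected_zero_modes: int | None = None) -> GaussianModel:
    """Equilibrium covariance as the scaled pseudoinverse of the Hessian.

    Requires the zero modes to be exactly the rigid-body ones — six for a
    connected non-collinear network (five for the degenerate two-bead case,
    which has no rotation about its own axis).  The rigid modes are removed
    and every internal mode m contributes scale × v_m v_mᵀ / λ_m.
    ``scale`` stands in for k_B T / k and defaults to 1 — every comparison
    downstream is invariant to it.
    """
    if expected_zero_modes is None:
        expected_zero_modes = 5 if h.n_beads == 2 else 6
    evals, evecs = scipy.linalg.eigh(h.entries)
    lam_max = max(evals[-1], 0.0)
    n_zero = len(evals) if lam_max <= 0 else int(np.sum(evals < ZERO_MODE_RTOL * lam_max))
    if n_zero != expected_zero_modes:
        raise ConnectivityError(
            f"Hessian has {n_zero} zero modes, expected {expected_zero_modes}; "
            "the network is disconnected or degenerate — increase the cutoff"
        )
    inv = np.zeros_like(evals)
    keep = evals >= ZERO_MODE_RTOL * lam_max
    inv[keep] = scale / evals[keep]
    cov = (evecs * inv) @ evecs.T
    order = np.argsort(inv)[::-1]
    return GaussianModel(
        covariance=0.5 * (cov + cov.T),
        eigenvalues=inv[order],
        eigenvectors=evecs[:, order],
        n_zero_modes_removed=n_zero,
        scale=scale,
    )


def msf(model: GaussianModel, labels=None) -> FluctuationProfile:
    """Mean square fluctuation per bead: trace of each diagonal 3x3 block."""
    n = model.n_beads
    diag = np.diagonal(model.covariance)
    values = diag.reshape(n, 3).sum(axis=1)
    if labels is None:
        labels = list(range(n))
    return FluctuationProfile(labels, values)


def effective_hessian(h: HessianMatrix, keep) -> HessianMatrix:
    """Reduce the Hessian to a bead subset by Schur complement.

    Partitioning M into kept (a) and discarded (b) blocks, the effective
    interaction matrix M_a − W M_b⁻¹ Wᵀ governs the marginal dynamics of
    the kept beads: its pseudoinverse equals the (a, a) sub-block of the
    full covariance.
    """
    keep = np.asarray(sorted(set(int(i) for i in np.atleast_1d(keep))), dtype=int)
    n = h.n_beads
    if keep.size == 0:
        raise ContractError("keep set must be non-empty")
    if keep[0] < 0 or keep[-1] >= n:
        raise ContractError("keep indices out of range")
    labels = ([h.bead_labels[i] for i in keep] if h.bead_labels is not None else None)
    if keep.size == n:
        return HessianMatrix(h.entries.copy(), labels)
    drop = np.setdiff1d(np.arange(n), keep)
    dof_a = (3 * keep[:, None] + np.arange(3)).ravel()
    dof_b = (3 * drop[:, None] + np.arange(3)).ravel()
    m_a = h.entries[np.ix_(dof_a, dof_a)]
    m_b = h.entries[np.ix_(dof_b, dof_b)]
    w = h.entries[np.ix_(dof_a, dof_b)]
    cond = np.linalg.cond(m_b)
    if not np.isfinite(cond) or cond > REDUCTION_CONDITION_LIMIT:
        raise ReductionError(
            f"discarded block numerically singular (cond={cond:.3g}); a "
            "discarded sub-component is decoupled from the kept beads"
        )
    x = scipy.linalg.solve(m_b, w.T, assume_a="sym")
    m_eff = m_a - w @ x
    return HessianMatrix(0.5 * (m_eff + m_eff.T), labels)


def rigid_mode_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis of rigid-body displacement fields of a bead set.

    Columns span the three uniform translations and the rotations about
    the centroid (six dimensions for a 3D cloud, five for a collinear one).
    Built geometrically from the coordinates — independent of any Hessian.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    centered = coords - coords.mean(axis=0)
    fields = []
    for mu in range(3):
        t = np.zeros((n, 3))
        t[:, mu] = 1.0
        fields.append(t.ravel())
    for axis in np.eye(3):
        fields.append(np.cross(axis, centered).ravel())
    basis = np.column_stack(fields)
    # orthonormalize, dropping dependent directions (collinear clouds)
    u, s, _ = np.linalg.svd(basis, full_matrices=False)
    return u[:, s > 1e-10 * s[0]]


def project_out_rigid(matrix: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Remove rigid-body components from a covariance (or vector) block.

    Projects both sides of a 3N x 3N matrix (or a 3N vector) onto the
    orthogonal complement of the rigid modes of the given bead
    coordinates.  The projected sub-block of a full-network covariance
    equals the pseudoinverse of the effective Hessian of those beads: the
    two descriptions differ only in which rigid-body gauge they fix.
    """
    basis = rigid_mode_basis(coords)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim == 1:
        return matrix - basis @ (basis.T @ matrix)
    p = np.eye(matrix.shape[0]) - basis @ basis.T
    return p @ matrix @ p


def neighbor_count(network: ElasticNetwork) -> float:
    """Mean number of springs per bead (average neighbor count)."""
    return 2.0 * network.n_springs / network.n_beads
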