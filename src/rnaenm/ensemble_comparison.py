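"""Comparing elastic-network predictions with conformer ensembles.

The ensemble-side covariance is the plain second moment of bead deviations
from the ensemble mean, taken after optimal rigid superposition onto a
reference.  Agreement between two Gaussian fluctuation models is scored by
the Pearson correlation of their mean-square-fluctuation profiles and by
the root weighted square inner product (RWSIP) of their essential dynamical
spaces,

    RWSIP = sqrt( Σ_ij λ_Ai λ_Bj (v_Ai · v_Bj)² / Σ_i λ_Ai λ_Bi ),

which is 1 when the ranked eigenspaces coincide and 0 when they are
orthogonal.  The cutoff scan profiles both scores against the interaction
cutoff R_c, per interaction-center role, reducing multi-bead networks with
the effective (Schur-complement) Hessian.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats

from .exceptions import (
    AlignmentError,
    ContractError,
    CutoffNotFoundError,
    UndefinedMeasureError,
)
from .enm_core import (
    FluctuationProfile,
    GaussianModel,
    build_network,
    covariance_from_hessian,
    effective_hessian,
    hessian,
    msf,
    neighbor_count,
    zero_modes,
)
from .structures_io import BeadScheme, BeadStructure, ConformerEnsemble

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# essential spaces
# ---------------------------------------------------------------------------

@dataclass
class EssentialSpace:
    """Eigenvalue-ranked orthonormal modes of a covariance matrix."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    def __post_init__(self):
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        if self.eigenvectors.shape[1] != len(self.eigenvalues):
            raise ContractError("eigenvalue/eigenvector count mismatch")
        if np.any(np.diff(self.eigenvalues) > 1e-9 * max(self.eigenvalues.max(initial=0.0), 1e-30)):
            raise ContractError("eigenvalues must be nonincreasing")
        gram = self.eigenvectors.T @ self.eigenvectors
        if np.abs(gram - np.eye(gram.shape[0])).max() > 1e-10:
            raise ContractError("eigenvectors not orthonormal")

    @classmethod
    def from_model(cls, model: GaussianModel) -> "EssentialSpace":
        return cls(model.eigenvalues, model.eigenvectors)

    @property
    def dim(self) -> int:
        return self.eigenvectors.shape[0]


def rwsip(a, b) -> float:
    """Root weighted square inner product of two essential spaces.

    Accepts :class:`EssentialSpace` or :class:`GaussianModel` arguments.
    Spectra of unequal mode count are zero-padded (zero eigenvalues
    contribute to neither sum).  Raises when either spectrum is all zero,
    which leaves the measure undefined.
    """
    a = EssentialSpace.from_model(a) if isinstance(a, GaussianModel) else a
    b = EssentialSpace.from_model(b) if isinstance(b, GaussianModel) else b
    if a.dim != b.dim:
        raise ContractError("essential spaces have different dimensions")
    la, lb = a.eigenvalues, b.eigenvalues
    n = min(len(la), len(lb))
    den = float(np.dot(la[:n], lb[:n]))
    if den <= 0.0:
        raise UndefinedMeasureError("RWSIP undefined: an all-zero spectrum")
    overlap = a.eigenvectors.T @ b.eigenvectors
    num = float(la @ (overlap * overlap) @ lb)
    value = np.sqrt(num / den)
    if value > 1.0 + 1e-9:
        raise ContractError(f"RWSIP exceeded 1 ({value})")
    return float(min(value, 1.0))


# ---------------------------------------------------------------------------
# superposition and ensemble covariance
# ---------------------------------------------------------------------------

def kabsch_align(ensemble: ConformerEnsemble, reference: np.ndarray,
                 subset=None) -> ConformerEnsemble:
    """Rigid-body superpose every frame onto a reference.

    The optimal rotation/translation minimizes the RMSD over ``subset``
    (default: all beads) and is then applied to the whole frame.  The
    subset must contain at least three non-collinear sites.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (ensemble.n_beads, 3):
        raise ContractError("reference shape does not match ensemble beads")
    subset = (np.arange(ensemble.n_beads) if subset is None
              else np.asarray(sorted(set(int(i) for i in np.atleast_1d(subset))), dtype=int))
    if subset.size < 3:
        raise AlignmentError("superposition needs at least 3 subset sites")
    ref_sub = reference[subset]
    ref_centroid = ref_sub.mean(axis=0)
    ref_c = ref_sub - ref_centroid
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise AlignmentError("superposition subset is collinear")

    frames = ensemble.frames
    centroids = frames[:, subset].mean(axis=1)
    moved = frames[:, subset] - centroids[:, None, :]
    # batched Kabsch: cross-covariance per frame, SVD, reflection-corrected
    cross = np.einsum("fni,nj->fij", moved, ref_c)
    u, _, vt = np.linalg.svd(cross)
    det = np.linalg.det(u @ vt)
    u[:, :, 2] *= np.sign(det)[:, None]
    rotations = u @ vt
    out = np.einsum("fni,fij->fnj", frames - centroids[:, None, :], rotations)
    out += ref_centroid
    return ConformerEnsemble(out, ensemble.bead_labels, aligned=True)


def ensemble_covariance(ensemble: ConformerEnsemble) -> GaussianModel:
    """Covariance of bead deviations from the ensemble mean (divisor n).

    The ensemble must be superposed first; the covariance of an unaligned
    ensemble mixes internal and rigid-body motion.
    """
    if not ensemble.aligned:
        raise ContractError("ensemble_covariance requires an aligned ensemble")
    if ensemble.n_frames < 2:
        raise ContractError("need at least 2 frames")
    flat = ensemble.frames.reshape(ensemble.n_frames, -1)
    dev = flat - flat.mean(axis=0)
    # displacements below 1e-10 Å are numerical noise, not fluctuations
    if np.abs(dev).max() < 1e-10:
        raise UndefinedMeasureError("ensemble has no fluctuations")
    cov = dev.T @ dev / ensemble.n_frames
    return GaussianModel.from_covariance(cov)


def split_half_models(ensemble: ConformerEnsemble):
    """Covariance models of the first and second half of the frames.

    Their mutual RWSIP is the self-agreement ceiling against which model
    scores are judged.
    """
    half = ensemble.n_frames // 2
    if half < 2:
        raise ContractError("need at least 4 frames for a split-half reference")
    first = ConformerEnsemble(ensemble.frames[:half], ensemble.bead_labels, True)
    second = ConformerEnsemble(ensemble.frames[half:], ensemble.bead_labels, True)
    return ensemble_covariance(first), ensemble_covariance(second)


# ---------------------------------------------------------------------------
# profile correlation
# ---------------------------------------------------------------------------

def msf_correlation(a: FluctuationProfile, b: FluctuationProfile,
                    method: str = "pearson") -> float:
    """Pearson or Spearman correlation of two fluctuation profiles."""
    if len(a) != len(b):
        raise ContractError("profiles have different lengths")
    if len(a) < 3:
        raise ContractError("need at least 3 sites to correlate")
    x, y = a.values, b.values
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedMeasureError("correlation undefined: zero-variance profile")
    if method == "pearson":
        return float(scipy.stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(scipy.stats.spearmanr(x, y).statistic)
    raise ContractError(f"unknown correlation method {method!r}")


# ---------------------------------------------------------------------------
# cutoff scan
# ---------------------------------------------------------------------------

#: columns of the scan table
SCAN_COLUMNS = ["cutoff", "role", "rwsip", "msf_pearson", "n_zero_modes",
                "n_springs", "mean_neighbors", "viable"]


def cutoff_scan(structure: BeadStructure, ensemble: ConformerEnsemble,
                scheme: BeadScheme | None = None, grid=None,
                k: float = 1.0) -> pd.DataFrame:
    """Score ENM-vs-ensemble agreement across interaction cutoffs.

    For every grid cutoff whose network has exactly six zero modes, the
    Hessian is reduced to each single-role bead subset (sugar, base,
    phosphate) by Schur complement and scored against the matching
    sub-block of the ensemble covariance with RWSIP and MSF Pearson
    correlation.  Grid points with the wrong zero-mode count appear with
    ``viable=False`` and NaN scores.  Default grid: 3–30 Å in 1 Å steps.
    """
    if scheme is None:
        scheme = structure.scheme
    if grid is None:
        grid = np.arange(3.0, 31.0, 1.0)
    grid = np.sort(np.asarray(grid, dtype=float))
    if ensemble.n_beads != structure.n_beads:
        raise ContractError("ensemble bead count does not match structure")

    roles = _comparison_roles(structure, scheme)
    md_by_role = ensemble_role_models(structure, ensemble, scheme)

    rows = []
    any_viable = False
    for cutoff in grid:
        net = build_network(structure, float(cutoff), k=k)
        h = hessian(net)
        n_zero, _ = zero_modes(h)
        if n_zero != 6:
            for role in roles:
                rows.append([cutoff, role, np.nan, np.nan, n_zero,
                             net.n_springs, neighbor_count(net), False])
            continue
        any_viable = True
        for role, idx in roles.items():
            if len(idx) == structure.n_beads:
                h_eff = h
            else:
                h_eff = effective_hessian(h, idx)
            enm_model = covariance_from_hessian(h_eff)
            md_sub, md_msf = md_by_role[role]
            score = rwsip(enm_model, md_sub)
            pearson = msf_correlation(msf(enm_model), md_msf, "pearson")
            rows.append([cutoff, role, score, pearson, n_zero,
                         net.n_springs, neighbor_count(net), True])

    if not any_viable:
        raise CutoffNotFoundError("no grid cutoff yields exactly 6 zero modes")
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)


def ensemble_role_models(structure: BeadStructure, ensemble: ConformerEnsemble,
                         scheme: BeadScheme | None = None) -> dict:
    """Role-restricted ensemble covariance models.

    Returns ``{role: (GaussianModel, FluctuationProfile)}``.  Following the
    comparison protocol, the superposition and the covariance for each role
    consider exclusively the beads of that role: frames are re-aligned on
    the role subset before the covariance of that subset is taken.
    """
    roles = _comparison_roles(structure, scheme or structure.scheme)
    out = {}
    for role, idx in roles.items():
        aligned = kabsch_align(ensemble, structure.coords, subset=idx)
        sub_model = ensemble_covariance(aligned.subset(idx))
        out[role] = (sub_model, msf(sub_model))
    return out


def null_reference(structure: BeadStructure, ensemble: ConformerEnsemble,
                   scheme: BeadScheme | None = None, n_seeds: int = 10,
                   seed: int = 0) -> pd.DataFrame:
    """Significance floor from the fully connected random network.

    Scores ``n_seeds`` independent random networks against the ensemble
    (per comparison role, via the effective Hessian) and reports the mean
    and standard deviation of RWSIP and MSF Pearson across seeds.
    """
    from .enm_core import build_random_network

    roles = _comparison_roles(structure, scheme or structure.scheme)
    md_by_role = ensemble_role_models(structure, ensemble, scheme)
    scores = {role: ([], []) for role in roles}
    for s in range(n_seeds):
        net = build_random_network(structure, seed + s)
        h = hessian(net)
        for role, idx in roles.items():
            h_eff = h if len(idx) == structure.n_beads else effective_hessian(h, idx)
            model = covariance_from_hessian(h_eff)
            md_sub, md_msf = md_by_role[role]
            scores[role][0].append(rwsip(model, md_sub))
            scores[role][1].append(msf_correlation(msf(model), md_msf))
    rows = []
    for role, (rw, pe) in scores.items():
        rows.append([role, float(np.mean(rw)), float(np.std(rw)),
                     float(np.mean(pe)), float(np.std(pe)), n_seeds])
    return pd.DataFrame(rows, columns=["role", "rwsip_mean", "rwsip_sd",
                                       "msf_pearson_mean", "msf_pearson_sd",
                                       "n_seeds"])


def split_half_reference(structure: BeadStructure, ensemble: ConformerEnsemble,
                         scheme: BeadScheme | None = None) -> pd.DataFrame:
    """Self-agreement ceiling: first versus second half of the frames."""
    half = ensemble.n_frames // 2
    if half < 2:
        raise ContractError("need at least 4 frames for a split-half reference")
    first = ConformerEnsemble(ensemble.frames[:half], ensemble.bead_labels,
                              ensemble.aligned)
    second = ConformerEnsemble(ensemble.frames[half:], ensemble.bead_labels,
                               ensemble.aligned)
    a_by_role = ensemble_role_models(structure, first, scheme)
    b_by_role = ensemble_role_models(structure, second, scheme)
    rows = []
    for role in a_by_role:
        a_model, a_msf = a_by_role[role]
        b_model, b_msf = b_by_role[role]
        rows.append([role, rwsip(a_model, b_model),
                     msf_correlation(a_msf, b_msf)])
    return pd.DataFrame(rows, columns=["role", "rwsip", "msf_pearson"])


def _comparison_roles(structure: BeadStructure, scheme: BeadScheme | None) -> dict:
    """Map comparison roles to bead indices for this structure/scheme."""
    roles = {}
    for role in ("P", "S", "B"):
        idx = structure.role_indices(role)
        if idx.size >= 3:
            roles[role] = idx
    if not roles:
        # single-role or unconventional labelling: compare over all beads
        roles = {"ALL": np.arange(structure.n_beads)}
    return roles


def mean_over_systems(tables) -> pd.DataFrame:
    """Unweighted mean of scan scores across systems, per (cutoff, role).

    Only rows viable in every system contribute to the mean at a grid point.
    """
    stacked = pd.concat(list(tables), keys=range(len(tables)), names=["system"])
    viable = stacked[stacked["viable"]]
    grouped = viable.groupby(["cutoff", "role"], as_index=False).agg(
        rwsip=("rwsip", "mean"),
        msf_pearson=("msf_pearson", "mean"),
        n_systems=("rwsip", "size"),
    )
    return grouped
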