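"""Deterministic fixture structures and Gaussian conformer ensembles.

The generators provide a regular double-helix bead structure (a statistical
stand-in for a short RNA duplex), seeded Gaussian ensembles sampled from
any :class:`GaussianModel`, and random point clouds.  They make every
operation in the package testable without downloading real structures;
they do not attempt to reproduce the geometry of any deposited PDB entry.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ContractError, PackingError
from .enm_core import GaussianModel
from .structures_io import BeadLabel, BeadStructure, BeadScheme, ConformerEnsemble

logger = logging.getLogger(__name__)

#: default per-role bead placement relative to the helix backbone:
#: (radial offset from helix_radius Å, angular offset deg, axial offset Å)
DEFAULT_BEAD_OFFSETS = {
    "P": (0.5, -14.0, -1.9),   # phosphate sits outward, behind the sugar
    "S": (0.0, 0.0, 0.0),      # C1' defines the backbone helix itself
    "B": (-6.4, 8.0, 0.5),     # C2 points inward toward the helix axis
}


@dataclass
class DuplexSpec:
    """Parameters of the ideal double-helix fixture.

    Defaults give an A-form-like geometry (rise 2.8 Å, twist 32.7° per base
    pair, C1' radius 9.4 Å); they are fixture constants, freely
    overridable, not measurements of any particular molecule.
    """

    n_bp: int = 16
    rise_per_base: float = 2.8
    twist_per_base: float = 32.7
    helix_radius: float = 9.4
    bead_offsets: dict = field(default_factory=lambda: dict(DEFAULT_BEAD_OFFSETS))
    seed: int = 0

    def __post_init__(self):
        if self.n_bp < 2:
            raise ContractError("n_bp must be at least 2")
        if self.rise_per_base <= 0 or self.helix_radius <= 0:
            raise ContractError("rise and radius must be positive")


def generate_duplex(spec: DuplexSpec | None = None) -> BeadStructure:
    """Ideal antiparallel duplex with sugar/base/phosphate beads.

    Strand A winds up a regular helix centered on the origin; strand B is
    its image under the exact two-fold (dyad) rotation about the x axis,
    with residues numbered so that A residue i pairs B residue n+1−i.  The
    construction is therefore exactly palindromic: the end-to-end
    relabeling (A, i) ↔ (B, n+1−i) maps the bead set onto itself.
    """
    spec = spec or DuplexSpec()
    n = spec.n_bp
    twist = math.radians(spec.twist_per_base)
    z0 = -0.5 * (n - 1) * spec.rise_per_base

    labels, coords = [], []
    strand_a = []
    for t in range(n):
        phi = t * twist
        z = z0 + t * spec.rise_per_base
        per_residue = {}
        for role in ("P", "S", "B"):
            dr, dphi_deg, dz = spec.bead_offsets[role]
            r = spec.helix_radius + dr
            a = phi + math.radians(dphi_deg)
            per_residue[role] = np.array([r * math.cos(a), r * math.sin(a), z + dz])
        strand_a.append(per_residue)

    dyad = np.diag([1.0, -1.0, -1.0])
    for t in range(n):
        for role in ("P", "S", "B"):
            labels.append(BeadLabel("A", t + 1, role))
            coords.append(strand_a[t][role])
    for t in range(n):
        # residue t+1 of strand B is the dyad image of A residue n-t
        source = strand_a[n - 1 - t]
        for role in ("P", "S", "B"):
            labels.append(BeadLabel("B", t + 1, role))
            coords.append(dyad @ source[role])

    structure = BeadStructure(labels, np.array(coords),
                              BeadScheme.from_code("SBP"))
    # the fixture must present a proper 3D cloud to be network-viable
    assert structure.coordinate_rank() == 3
    return _canonical_order(structure)


def _canonical_order(structure: BeadStructure) -> BeadStructure:
    """Re-sort beads into the canonical (chain, residue, P→S→B) order."""
    from .structures_io import ROLE_ORDER

    def key(item):
        lab = item[0]
        return (lab.chain_id, lab.residue_index, lab.insertion_code,
                ROLE_ORDER.get(lab.role, 99), lab.role)

    paired = sorted(zip(structure.labels, structure.coords), key=key)
    labels = [p[0] for p in paired]
    coords = np.array([p[1] for p in paired])
    return BeadStructure(labels, coords, structure.scheme)


def sample_ensemble(model: GaussianModel, reference: BeadStructure,
                    n_frames: int, amplitude: float = 1.0,
                    seed: int = 0) -> ConformerEnsemble:
    """Draw conformers from a zero-mean Gaussian around a reference.

    Displacements are generated through the eigendecomposition square root
    of the model covariance, so rank-deficient covariances (rigid-body
    modes removed) sample correctly inside the image of the covariance.
    Frames are ``reference + amplitude × z`` and the result is marked
    aligned (no rigid-body component is ever added).
    """
    if n_frames < 1:
        raise ContractError("n_frames must be at least 1")
    if amplitude <= 0:
        raise ContractError("amplitude must be positive")
    if model.covariance.shape[0] != 3 * reference.n_beads:
        raise ContractError("model dimension does not match reference beads")
    rng = np.random.default_rng(seed)
    positive = model.eigenvalues > 0.0
    basis = model.eigenvectors[:, positive] * np.sqrt(model.eigenvalues[positive])
    xi = rng.standard_normal((int(np.sum(positive)), n_frames))
    disp = (basis @ xi).T * amplitude
    frames = reference.coords[None, :, :] + disp.reshape(n_frames, reference.n_beads, 3)
    return ConformerEnsemble(frames, reference.labels, aligned=True)


def random_cloud(n: int, box: float = 20.0, min_separation: float = 2.0,
                 seed: int = 0, max_attempts_per_point: int = 1000) -> BeadStructure:
    """Uniform random points in a cube with a minimum pair separation.

    Points are drawn one at a time with rejection; generation fails with a
    packing error when the box cannot accommodate the requested separation
    within the attempt budget.  For n ≥ 4 a degenerate (non-3D) cloud is
    rejected as well, so the result is always network-viable.
    """
    if n < 2:
        raise ContractError("need at least 2 points")
    if min_separation < 0:
        raise ContractError("min_separation must be nonnegative")
    rng = np.random.default_rng(seed)
    points: list = []
    for _ in range(n):
        for attempt in range(max_attempts_per_point):
            candidate = rng.uniform(0.0, box, size=3)
            if all(np.linalg.norm(candidate - p) >= min_separation for p in points):
                points.append(candidate)
                break
        else:
            raise PackingError(
                f"could not place point {len(points) + 1}/{n} with "
                f"separation {min_separation} in a box of {box} Å"
            )
    coords = np.array(points)
    labels = [BeadLabel("X", i + 1, "S") for i in range(n)]
    structure = BeadStructure(labels, coords, BeadScheme.from_code("S"))
    if n >= 4 and structure.coordinate_rank() < 3:
        # vanishing-probability event for uniform draws; re-seed deterministically
        return random_cloud(n, box, min_separation, seed + 104729, max_attempts_per_point)
    return structure
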