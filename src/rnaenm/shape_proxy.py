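"""Base–base distance fluctuations as a proxy for SHAPE reactivity.

Within the harmonic model the variance of the distance between beads i and
j follows directly from the covariance matrix in the linear perturbation
regime:

    σ²_d = Σ_μν (d̃^μ d̃^ν / d̃²) (C_ii,μν + C_jj,μν − C_ij,μν − C_ji,μν)

with d̃ the reference separation.  Applied to consecutive base beads (C2
atoms) along each chain this yields a per-nucleotide flexibility profile
that correlates with experimental SHAPE reactivities; the module also
computes the matching empirical distance and angle variances from conformer
ensembles and the profile-vs-reactivity correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import scipy.stats

from .exceptions import (
    ContractError,
    DegenerateGeometryError,
    InsufficientOverlapError,
    ParseError,
    SchemeError,
)
from .enm_core import FluctuationProfile, GaussianModel
from .structures_io import BeadStructure, ConformerEnsemble

logger = logging.getLogger(__name__)

#: per-nucleotide assignment rules for pair (bond-wise) values
ASSIGNMENTS = ("mean_flank", "five_prime", "three_prime")


# ---------------------------------------------------------------------------
# analytic and empirical pair fluctuations
# ---------------------------------------------------------------------------

def distance_variance_enm(model: GaussianModel, structure: BeadStructure,
                          i: int, j: int) -> float:
    """Analytic variance of the i–j distance under the Gaussian model (Å²).

    Valid in the linear perturbation regime: fluctuations are projected on
    the reference separation direction.
    """
    if i == j:
        raise ContractError("bead indices must differ")
    sep = structure.coords[j] - structure.coords[i]
    d = np.linalg.norm(sep)
    if d < 1e-9:
        raise DegenerateGeometryError(f"beads {i} and {j} coincide in the reference")
    u = sep / d
    block = (model.diagonal_block(i) + model.diagonal_block(j)
             - model.cross_block(i, j) - model.cross_block(j, i))
    var = float(u @ block @ u)
    if var < -1e-12:
        raise ContractError(f"negative distance variance {var}")
    return max(var, 0.0)


def distance_variance_ensemble(ensemble: ConformerEnsemble, i: int, j: int) -> float:
    """Plain variance (divisor n) of the per-frame i–j Euclidean distance."""
    if ensemble.n_frames < 2:
        raise ContractError("need at least 2 frames")
    d = np.linalg.norm(ensemble.frames[:, j] - ensemble.frames[:, i], axis=1)
    return float(np.var(d))


def angle_variance_ensemble(ensemble: ConformerEnsemble, i: int, j: int,
                            k: int) -> float:
    """Variance (divisor n, rad²) of the i–j–k angle at vertex j."""
    if ensemble.n_frames < 2:
        raise ContractError("need at least 2 frames")
    a = ensemble.frames[:, i] - ensemble.frames[:, j]
    b = ensemble.frames[:, k] - ensemble.frames[:, j]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if np.any(na < 1e-9) or np.any(nb < 1e-9):
        raise DegenerateGeometryError("zero-length arm in an angle triplet")
    cosine = np.clip(np.einsum("fi,fi->f", a, b) / (na * nb), -1.0, 1.0)
    return float(np.var(np.arccos(cosine)))


# ---------------------------------------------------------------------------
# per-nucleotide profile from consecutive base-base distances
# ---------------------------------------------------------------------------

def c2c2_profile(model_or_ensemble, structure: BeadStructure,
                 assignment: str = "mean_flank") -> FluctuationProfile:
    """Per-nucleotide profile of consecutive C2–C2 distance fluctuations.

    Computes the distance variance for every pair of consecutive base beads
    within each chain — analytically from a :class:`GaussianModel` or
    empirically from a :class:`ConformerEnsemble` — and maps the pair
    values onto nucleotides:

    - ``mean_flank`` (default): each nucleotide takes the mean of its
      flanking pair values; chain ends keep their single flank.
    - ``five_prime``: each pair value is assigned to its 5' nucleotide
      (the 3'-terminal nucleotide of each chain is dropped).
    - ``three_prime``: assigned to the 3' nucleotide (5' end dropped).
    """
    if assignment not in ASSIGNMENTS:
        raise ContractError(f"unknown assignment rule {assignment!r}")
    chains = _base_beads_by_chain(structure)
    if isinstance(model_or_ensemble, GaussianModel):
        def pair_value(i, j):
            return distance_variance_enm(model_or_ensemble, structure, i, j)
    elif isinstance(model_or_ensemble, ConformerEnsemble):
        ens = model_or_ensemble
        if ens.n_beads != structure.n_beads:
            raise ContractError("ensemble bead count does not match structure")

        def pair_value(i, j):
            return distance_variance_ensemble(ens, i, j)
    else:
        raise ContractError("expected a GaussianModel or ConformerEnsemble")

    labels, values = [], []
    for chain_id, beads in chains.items():
        if len(beads) < 2:
            logger.warning("chain %s has fewer than 2 base beads; skipped", chain_id)
            continue
        pair_vals = [pair_value(beads[t][0], beads[t + 1][0])
                     for t in range(len(beads) - 1)]
        if assignment == "five_prime":
            site_iter = [(beads[t][1], pair_vals[t]) for t in range(len(pair_vals))]
        elif assignment == "three_prime":
            site_iter = [(beads[t + 1][1], pair_vals[t]) for t in range(len(pair_vals))]
        else:
            site_iter = []
            for t, (_, lab) in enumerate(beads):
                flanks = []
                if t - 1 >= 0:
                    flanks.append(pair_vals[t - 1])
                if t < len(pair_vals):
                    flanks.append(pair_vals[t])
                site_iter.append((lab, float(np.mean(flanks))))
        for lab, v in site_iter:
            labels.append(lab)
            values.append(v)
    if not labels:
        raise SchemeError("no chain provides 2 or more consecutive base beads")
    return FluctuationProfile(labels, np.array(values))


def _base_beads_by_chain(structure: BeadStructure) -> dict:
    """Base-bead (index, label) lists per chain, in residue order."""
    chains: dict = {}
    for idx in structure.role_indices("B"):
        lab = structure.labels[idx]
        chains.setdefault(lab.chain_id, []).append((int(idx), lab))
    if not chains:
        raise SchemeError("the bead scheme provides no base (C2) beads")
    for chain_id in chains:
        chains[chain_id].sort(key=lambda t: (t[1].residue_index, t[1].insertion_code))
    return chains


# ---------------------------------------------------------------------------
# SHAPE reactivity profiles
# ---------------------------------------------------------------------------

@dataclass
class ShapeProfile:
    """Per-nucleotide SHAPE reactivities keyed by (chain, residue).

    ``chain = None`` means the input file carried no chain column; such
    entries match any chain with the same residue number.  Negative or
    non-finite reactivities are kept but treated as missing when
    correlating.
    """

    entries: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.entries) == 0:
            raise ContractError("empty SHAPE profile")


def read_shape(text: str) -> ShapeProfile:
    """Parse delimited SHAPE text: ``residue [chain] reactivity`` per line.

    An optional header line is skipped; comment lines start with ``#``.
    """
    entries = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) not in (2, 3):
            raise ParseError(f"line {lineno}: expected 2 or 3 columns")
        try:
            residue = int(parts[0])
        except ValueError:
            if lineno == 1 or not entries:
                continue  # header line
            raise ParseError(f"line {lineno}: bad residue index {parts[0]!r}")
        chain = parts[1] if len(parts) == 3 else None
        try:
            value = float(parts[-1])
        except ValueError:
            value = math.nan  # explicit missing marker such as 'NA'
        key = (chain, residue)
        if key in entries:
            raise ParseError(f"line {lineno}: duplicate residue key {key}")
        entries[key] = value
    if not entries:
        raise ParseError("no SHAPE entries found")
    return ShapeProfile(entries)


class ShapeCorrelation(NamedTuple):
    r: float
    n_matched: int
    n_dropped: int


def shape_correlation(profile: FluctuationProfile, shape: ShapeProfile,
                      method: str = "pearson") -> ShapeCorrelation:
    """Correlate a flexibility profile with SHAPE reactivities by residue.

    Residues are matched on (chain, residue index); reactivities that are
    missing, non-finite or negative are dropped and counted.  Requires at
    least three matched residues.
    """
    xs, ys = [], []
    n_dropped = 0
    for lab, value in zip(profile.labels, profile.values):
        chain = getattr(lab, "chain_id", None)
        residue = getattr(lab, "residue_index", lab)
        react = shape.entries.get((chain, residue))
        if react is None:
            react = shape.entries.get((None, residue))
        if react is None:
            n_dropped += 1
            continue
        if not math.isfinite(react) or react < 0:
            n_dropped += 1
            continue
        xs.append(value)
        ys.append(react)
    if len(xs) < 3:
        raise InsufficientOverlapError(
            f"only {len(xs)} residues matched between profile and SHAPE data"
        )
    x, y = np.asarray(xs), np.asarray(ys)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ContractError("correlation undefined: zero-variance input")
    if method == "pearson":
        r = float(scipy.stats.pearsonr(x, y).statistic)
    elif method == "spearman":
        r = float(scipy.stats.spearmanr(x, y).statistic)
    else:
        raise ContractError(f"unknown correlation method {method!r}")
    return ShapeCorrelation(r, len(xs), n_dropped)
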