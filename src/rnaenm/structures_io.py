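"""Reading RNA structures and mapping atoms to elastic-network beads.

The coarse-grained representations place one bead per selected chemical
group of each nucleotide: the phosphate (P atom), the sugar (C1' atom) and
the base (C2 atom), or every heavy atom for the all-atom network.  This
module parses PDB text into flat atom records, selects beads under a
:class:`BeadScheme`, and handles conformer ensembles (multi-model PDB or
plain-text coordinate frames).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as _pdb

from .exceptions import (
    ContractError,
    EmptySelectionError,
    ModelIndexError,
    ParseError,
)

logger = logging.getLogger(__name__)

#: representative atom per chemical-group role
ROLE_ATOMS = {"P": "P", "S": "C1'", "B": "C2"}
#: canonical ordering of the single-letter roles within a residue
ROLE_ORDER = {"P": 0, "S": 1, "B": 2}

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}


# ---------------------------------------------------------------------------
# atom records and bead schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom read from a structure file (coordinates in Å)."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    is_hetero: bool = False
    insertion_code: str = ""

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ContractError(f"invalid position for atom {self.atom_name!r}")
        object.__setattr__(self, "position", pos)
        if not self.atom_name:
            raise ContractError("atom_name must be non-empty")

    @property
    def residue_key(self) -> str:
        """Residue identifier with any insertion code appended verbatim."""
        return f"{self.residue_index}{self.insertion_code}"


@dataclass(frozen=True)
class BeadScheme:
    """Which nucleotide groups define interaction centers.

    ``all_atom=True`` uses every heavy atom as a bead and the three group
    flags are ignored.  ``include_ligand`` adds the heavy atoms of hetero
    residues (e.g. a bound ligand) as extra beads.
    """

    use_phosphate: bool = False
    use_sugar: bool = False
    use_base: bool = False
    all_atom: bool = False
    include_ligand: bool = False

    def __post_init__(self):
        if not (self.all_atom or self.use_phosphate or self.use_sugar or self.use_base):
            raise ContractError("bead scheme selects no interaction centers")

    @classmethod
    def from_code(cls, code: str, include_ligand: bool = False) -> "BeadScheme":
        """Build a scheme from a short code: P, S, B, SP, BP, SB, SBP or AA."""
        code = code.upper()
        if code == "AA":
            return cls(all_atom=True, include_ligand=include_ligand)
        if not code or set(code) - set("PSB"):
            raise ContractError(f"unknown bead scheme code {code!r}")
        return cls(
            use_phosphate="P" in code,
            use_sugar="S" in code,
            use_base="B" in code,
            include_ligand=include_ligand,
        )

    @property
    def code(self) -> str:
        if self.all_atom:
            return "AA"
        # canonical spelling keeps S before B before P reversed: use SBP order
        return "".join(
            r for r, used in (
                ("S", self.use_sugar), ("B", self.use_base), ("P", self.use_phosphate)
            ) if used
        )

    @property
    def roles(self) -> tuple:
        """Single-letter roles selected by this scheme (empty for all-atom)."""
        if self.all_atom:
            return ()
        return tuple(
            r for r in ("P", "S", "B")
            if getattr(self, {"P": "use_phosphate", "S": "use_sugar", "B": "use_base"}[r])
        )


@dataclass(frozen=True)
class BeadLabel:
    """Identity of one interaction center."""

    chain_id: str
    residue_index: int
    role: str
    insertion_code: str = ""

    @property
    def residue_key(self) -> str:
        return f"{self.residue_index}{self.insertion_code}"


@dataclass
class BeadStructure:
    """Ordered interaction centers of one reference conformer.

    Beads are sorted by (chain, residue, role) with the fixed role order
    P → S → B; all-atom and ligand beads order alphabetically by atom name
    within the residue.  Coordinates are in Å.
    """

    labels: list
    coords: np.ndarray
    scheme: BeadScheme | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ContractError("coords must be an (N, 3) array")
        if len(self.labels) != len(self.coords):
            raise ContractError("labels and coords length mismatch")
        if len(self.labels) < 2:
            raise ContractError("a bead structure needs at least 2 beads")
        keys = [(b.chain_id, b.residue_key, b.role) for b in self.labels]
        if len(set(keys)) != len(keys):
            raise ContractError("duplicate (chain, residue, role) bead keys")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_beads(self) -> int:
        return len(self.labels)

    def coordinate_rank(self) -> int:
        """Rank of the centered coordinate array (3 = proper 3D cloud)."""
        centered = self.coords - self.coords.mean(axis=0)
        return int(np.linalg.matrix_rank(centered, tol=1e-8))

    def role_indices(self, role: str) -> np.ndarray:
        """Bead indices carrying a chemical-group role.

        ``role`` is one of ``P``/``S``/``B``; all-atom beads on the
        representative atom of that group (``ATOM:P`` etc.) also match, so
        the same comparison subsets can be taken from coarse-grained and
        all-atom networks.
        """
        atom = ROLE_ATOMS[role]
        wanted = {role, f"ATOM:{atom}"}
        return np.array(
            [i for i, b in enumerate(self.labels) if b.role in wanted], dtype=int
        )

    def to_text(self) -> str:
        """Serialize as delimited text (chain, residue, role, x, y, z)."""
        lines = ["chain\tresidue\trole\tx\ty\tz"]
        for b, xyz in zip(self.labels, self.coords):
            lines.append(
                f"{b.chain_id}\t{b.residue_key}\t{b.role}\t"
                f"{xyz[0]:.6f}\t{xyz[1]:.6f}\t{xyz[2]:.6f}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "BeadStructure":
        labels, coords = [], []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("chain"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ParseError(f"bad bead line: {line!r}")
            chain, reskey, role = parts[0], parts[1], parts[2]
            idx, icode = _split_residue_key(reskey)
            labels.append(BeadLabel(chain, idx, role, icode))
            coords.append([float(v) for v in parts[3:6]])
        if not labels:
            raise ParseError("no bead records found")
        return cls(labels, np.array(coords))


def _split_residue_key(key: str):
    digits = ""
    i = 0
    if key.startswith("-"):
        digits, i = "-", 1
    while i < len(key) and key[i].isdigit():
        digits += key[i]
        i += 1
    return int(digits), key[i:]


@dataclass
class ConformerEnsemble:
    """Stack of conformers sharing one bead labelling (frames × N × 3, Å)."""

    frames: np.ndarray
    bead_labels: list
    aligned: bool = False

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ContractError("frames must be an (F, N, 3) array")
        if self.frames.shape[0] < 1:
            raise ContractError("ensemble needs at least one frame")
        if self.frames.shape[1] < 2:
            raise ContractError("ensemble needs at least two beads")
        if self.bead_labels is not None and len(self.bead_labels) != self.frames.shape[1]:
            raise ContractError("bead_labels length mismatch")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]

    def subset(self, indices) -> "ConformerEnsemble":
        indices = np.asarray(indices, dtype=int)
        labels = [self.bead_labels[i] for i in indices] if self.bead_labels else None
        return ConformerEnsemble(self.frames[:, indices, :], labels, self.aligned)

    def to_text(self) -> str:
        """Plain-text frames: N lines of "x y z", blank line between frames."""
        blocks = []
        for frame in self.frames:
            blocks.append(
                "\n".join(f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in frame)
            )
        return "\n\n".join(blocks) + "\n"


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

def parse_structure(text: str, model_index: int = 0) -> list:
    """Parse PDB text into heavy-atom records of one model.

    Hydrogens are dropped; alternate locations resolve to the highest
    occupancy (ties keep the first in file order).  ``model_index`` is
    0-based over the MODEL blocks (a file without MODEL records has one
    model).
    """
    if not text or not text.strip():
        raise ParseError("empty structure text")
    try:
        pdb_file = _pdb.PDBFile.read(io.StringIO(text))
    except Exception as exc:  # malformed beyond biotite's tolerance
        raise ParseError(f"could not read PDB text: {exc}") from exc
    try:
        n_models = pdb_file.get_model_count()
    except Exception as exc:
        raise ParseError("no ATOM/HETATM records found") from exc
    if n_models == 0:
        raise ParseError("no ATOM/HETATM records found")
    if not 0 <= model_index < n_models:
        raise ModelIndexError(
            f"model_index {model_index} out of range (file has {n_models} models)"
        )
    atoms = _pdb.get_structure(
        pdb_file,
        model=model_index + 1,
        altloc="all",
        extra_fields=["occupancy"],
    )
    if atoms.array_length() == 0:
        raise ParseError("no ATOM/HETATM records found")
    return _resolve_altlocs(_atom_array_to_records(atoms))


def _resolve_altlocs(records: list) -> list:
    """Keep one location per atom: highest occupancy, ties by file order."""
    best: dict = {}
    order = []
    for rec in records:
        key = (rec.chain_id, rec.residue_index, rec.insertion_code, rec.atom_name)
        if key not in best:
            best[key] = rec
            order.append(key)
        elif rec.occupancy > best[key].occupancy:
            best[key] = rec
    return [best[key] for key in order]


def _atom_array_to_records(atoms) -> list:
    records = []
    ins_codes = (
        atoms.ins_code if "ins_code" in atoms.get_annotation_categories()
        else [""] * atoms.array_length()
    )
    occ = (
        atoms.occupancy if "occupancy" in atoms.get_annotation_categories()
        else np.ones(atoms.array_length())
    )
    for i in range(atoms.array_length()):
        element = str(atoms.element[i]).upper()
        if element in ("H", "D"):
            continue
        records.append(
            AtomRecord(
                chain_id=str(atoms.chain_id[i]),
                residue_index=int(atoms.res_id[i]),
                residue_name=str(atoms.res_name[i]),
                atom_name=str(atoms.atom_name[i]),
                element=element,
                position=atoms.coord[i],
                occupancy=float(occ[i]),
                is_hetero=bool(atoms.hetero[i]),
                insertion_code=str(ins_codes[i]).strip(),
            )
        )
    if not records:
        raise ParseError("structure contains no heavy atoms")
    return records


def model_count(text: str) -> int:
    """Number of models in PDB text."""
    if not text or not text.strip():
        raise ParseError("empty structure text")
    pdb_file = _pdb.PDBFile.read(io.StringIO(text))
    return pdb_file.get_model_count()


# ---------------------------------------------------------------------------
# bead extraction
# ---------------------------------------------------------------------------

def extract_beads(atoms: list, scheme: BeadScheme) -> BeadStructure:
    """Select interaction centers from atom records under a bead scheme.

    One bead per selected role per nucleotide; a residue missing the
    representative atom of a selected role contributes no bead for that role
    (a warning is logged).  Hetero residues are included only when
    ``scheme.include_ligand`` is set; waters are always skipped.  The result
    is independent of the input atom ordering.
    """
    if not atoms:
        raise ContractError("no atoms to extract beads from")

    by_residue: dict = {}
    for atom in atoms:
        if atom.residue_name.strip().upper() in _WATER_NAMES:
            continue
        key = (atom.chain_id, atom.residue_index, atom.insertion_code)
        by_residue.setdefault(key, []).append(atom)

    labels, coords = [], []
    seen: set = set()

    def push(chain, res_id, icode, role, position):
        label = BeadLabel(chain, res_id, role, icode)
        if label in seen:
            logger.warning("duplicate bead %s skipped", label)
            return
        seen.add(label)
        labels.append(label)
        coords.append(np.asarray(position, dtype=float))

    for key in sorted(by_residue, key=lambda k: (k[0], k[1], k[2])):
        chain, res_id, icode = key
        res_atoms = by_residue[key]
        hetero = all(a.is_hetero for a in res_atoms)
        if hetero and not scheme.include_ligand:
            continue
        if hetero:
            for atom in sorted(res_atoms, key=lambda a: a.atom_name):
                push(chain, res_id, icode, f"LIGAND:{atom.atom_name}", atom.position)
            continue
        if scheme.all_atom:
            for atom in sorted(res_atoms, key=lambda a: a.atom_name):
                push(chain, res_id, icode, f"ATOM:{atom.atom_name}", atom.position)
            continue
        by_name = {a.atom_name: a for a in res_atoms}
        for role in scheme.roles:
            atom = by_name.get(ROLE_ATOMS[role])
            if atom is None:
                logger.warning(
                    "residue %s/%s%s lacks atom %s: no %s bead",
                    chain, res_id, icode, ROLE_ATOMS[role], role,
                )
                continue
            push(chain, res_id, icode, role, atom.position)

    if not labels:
        raise EmptySelectionError(
            f"scheme {scheme.code!r} selected zero beads"
        )
    if len(labels) < 2:
        raise EmptySelectionError("fewer than 2 beads selected")
    return BeadStructure(labels, np.array(coords), scheme)


def structure_to_pdb(structure: BeadStructure) -> str:
    """Write beads as pseudo-atom PDB text (one ATOM record per bead)."""
    n = structure.n_beads
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(structure.coords, dtype=np.float32)
    for i, b in enumerate(structure.labels):
        atoms.chain_id[i] = b.chain_id
        atoms.res_id[i] = b.residue_index
        atoms.ins_code[i] = b.insertion_code
        atoms.res_name[i] = "U"
        name = b.role.split(":", 1)[1] if ":" in b.role else ROLE_ATOMS.get(b.role, "X")
        atoms.atom_name[i] = name
        atoms.element[i] = "P" if name == "P" else name[0]
        atoms.hetero[i] = b.role.startswith("LIGAND:")
    pdb_file = _pdb.PDBFile()
    _pdb.set_structure(pdb_file, atoms)
    out = io.StringIO()
    pdb_file.write(out)
    return out.getvalue()


def ensemble_to_pdb(ensemble: ConformerEnsemble, structure: BeadStructure) -> str:
    """Write an ensemble as a multi-model pseudo-atom PDB."""
    n = structure.n_beads
    stack = struc.AtomArrayStack(ensemble.n_frames, n)
    stack.coord = np.asarray(ensemble.frames, dtype=np.float32)
    for i, b in enumerate(structure.labels):
        stack.chain_id[i] = b.chain_id
        stack.res_id[i] = b.residue_index
        stack.ins_code[i] = b.insertion_code
        stack.res_name[i] = "U"
        name = b.role.split(":", 1)[1] if ":" in b.role else ROLE_ATOMS.get(b.role, "X")
        stack.atom_name[i] = name
        stack.element[i] = "P" if name == "P" else name[0]
        stack.hetero[i] = b.role.startswith("LIGAND:")
    pdb_file = _pdb.PDBFile()
    _pdb.set_structure(pdb_file, stack)
    out = io.StringIO()
    pdb_file.write(out)
    return out.getvalue()


# ---------------------------------------------------------------------------
# ensemble input
# ---------------------------------------------------------------------------

def ensemble_from_pdb(text: str, scheme: BeadScheme) -> ConformerEnsemble:
    """Read every model of a multi-model PDB as one conformer ensemble.

    Beads are extracted from each model under the same scheme; all models
    must yield the identical bead labelling.
    """
    n_models = model_count(text)
    frames, labels = [], None
    for m in range(n_models):
        beads = extract_beads(parse_structure(text, model_index=m), scheme)
        if labels is None:
            labels = beads.labels
        elif beads.labels != labels:
            raise ParseError(f"model {m} yields a different bead set")
        frames.append(beads.coords)
    return ConformerEnsemble(np.array(frames), labels, aligned=False)


def ensemble_from_text(text: str, bead_labels=None) -> ConformerEnsemble:
    """Read plain-text coordinate frames.

    Each frame is N lines of whitespace-separated ``x y z``; frames are
    separated by blank lines.  All frames must have the same N.
    """
    frames, current = [], []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            if current:
                frames.append(current)
                current = []
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ParseError(f"expected 3 coordinates, got: {line!r}")
        current.append([float(v) for v in parts])
    if current:
        frames.append(current)
    if not frames:
        raise ParseError("no coordinate frames found")
    n = len(frames[0])
    if any(len(f) != n for f in frames):
        raise ParseError("frames have inconsistent bead counts")
    return ConformerEnsemble(np.array(frames, dtype=float), bead_labels, aligned=False)


# ---------------------------------------------------------------------------
# reference selection
# ---------------------------------------------------------------------------

def centroid_of_ensemble(ensemble: ConformerEnsemble) -> int:
    """Index of the frame with the lowest mean square distance to all frames.

    The ensemble must already be superposed (``aligned=True``); apply
    :func:`rnaenm.ensemble_comparison.kabsch_align` first.  Ties resolve to
    the lowest index.
    """
    if not ensemble.aligned:
        raise ContractError("centroid_of_ensemble requires an aligned ensemble")
    flat = ensemble.frames.reshape(ensemble.n_frames, -1)
    sq = np.einsum("ij,ij->i", flat, flat)
    # pairwise MSD matrix via the Gram expansion, averaged over beads
    gram = flat @ flat.T
    msd = (sq[:, None] + sq[None, :] - 2.0 * gram) / ensemble.n_beads
    mean_msd = msd.mean(axis=1)
    return int(np.argmin(mean_msd))
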