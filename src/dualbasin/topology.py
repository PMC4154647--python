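"""Coarse-grained beads, contact pairs and the merged two-basin topology.

Proteins are reduced to one CA bead per residue; DNA to three beads per
nucleotide (phosphate, sugar, base group centroids).  The two-basin
topology stores the union of the native contacts of both reference
conformations, dual-valued bonded terms at hinge regions, and the
protein-DNA interface contact map, together with both sets of reference
coordinates.

A plain-text columnar file format (sections ``[beads]``, ``[bonds]``,
``[angles]``, ``[dihedrals]``, ``[contacts]``, ``[charges]``, ``[meta]``)
round-trips every field bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
import numpy as np

__all__ = [
    "BeadKind",
    "BasinClass",
    "Bead",
    "BondTerm",
    "AngleTerm",
    "DihedralTerm",
    "ContactPair",
    "TwoBasinTopology",
    "write_topology",
    "read_topology",
    "write_cg_pdb",
]


class BeadKind(str, Enum):
    CA = "CA"
    PHOSPHATE = "PHOSPHATE"
    SUGAR = "SUGAR"
    BASE = "BASE"


class BasinClass(str, Enum):
    INTRA_A = "INTRA_A"
    INTRA_B = "INTRA_B"
    SHARED = "SHARED"
    INTERFACE = "INTERFACE"


@dataclass
class Bead:
    """One coarse-grained particle.

    ``charge`` is an integer elementary charge: +1 for Arg/Lys CA beads,
    -1 for Asp/Glu CA beads and every phosphate bead, 0 otherwise.
    ``position`` is the A-basin (or only) reference coordinate in Angstrom.
    """

    global_index: int
    chain_id: str
    residue_index: int
    residue_name: str
    bead_kind: BeadKind
    charge: int
    position: np.ndarray

    def __post_init__(self) -> None:
        self.bead_kind = BeadKind(self.bead_kind)
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"bead {self.global_index}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"bead {self.global_index}: non-finite position")
        if self.charge not in (-1, 0, 1):
            raise ValueError(f"bead {self.global_index}: charge must be -1, 0 or +1")

    @property
    def is_protein(self) -> bool:
        return self.bead_kind == BeadKind.CA

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Bead):
            return NotImplemented
        return (
            self.global_index == other.global_index
            and self.chain_id == other.chain_id
            and self.residue_index == other.residue_index
            and self.residue_name == other.residue_name
            and self.bead_kind == other.bead_kind
            and self.charge == other.charge
            and np.array_equal(self.position, other.position)
        )


@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    r0: float


@dataclass(frozen=True)
class AngleTerm:
    """Harmonic angle with one reference per basin.

    Non-hinge terms satisfy ``theta0_A == theta0_B``; hinge terms carry the
    distinct values of the two reference conformations.  Angles in radians.
    """

    i: int
    j: int
    k: int
    theta0_A: float
    theta0_B: float
    hinge: bool = False


@dataclass(frozen=True)
class DihedralTerm:
    i: int
    j: int
    k: int
    l: int
    phi0_A: float
    phi0_B: float
    hinge: bool = False


@dataclass(frozen=True)
class ContactPair:
    """Native contact between beads ``i < j`` with minimum at ``r0`` (A)."""

    i: int
    j: int
    r0: float
    basin_class: BasinClass
    strength_scale: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "basin_class", BasinClass(self.basin_class))
        if self.i >= self.j:
            raise ValueError(f"contact ({self.i},{self.j}): requires i < j")
        if self.r0 <= 0:
            raise ValueError(f"contact ({self.i},{self.j}): r0 must be positive")
        if self.strength_scale < 0:
            raise ValueError(f"contact ({self.i},{self.j}): negative strength_scale")


@dataclass
class TwoBasinTopology:
    """Merged bonded terms, dual-basin contact map and interface contacts.

    ``ref_positions_A``/``ref_positions_B`` hold the coordinates of all
    beads in the two reference conformations (DNA coordinates are identical
    in both; the bound-complex DNA pose is used).  ``lf_t_contact_ids`` and
    ``lf_f_contact_ids`` index, into ``contacts``, the A-exclusive contacts
    between the mobile recognition domain and its A-state partner, and the
    B-exclusive contacts with its B-state partner; the latter set is the
    target of the ``eps_B`` scaling knob.  ``regions`` maps a region name
    (e.g. "LF", "linker", "core", DNA groove regions) to bead indices and
    drives the per-region native-contact coordinates of the analysis layer.
    """

    beads: list[Bead]
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    dihedrals: list[DihedralTerm] = field(default_factory=list)
    contacts: list[ContactPair] = field(default_factory=list)
    hinge_residues: set[int] = field(default_factory=set)
    linker_range: tuple[int, int] | None = None
    lf_f_contact_ids: list[int] = field(default_factory=list)
    lf_t_contact_ids: list[int] = field(default_factory=list)
    regions: dict[str, list[int]] = field(default_factory=dict)
    ref_positions_A: np.ndarray | None = None
    ref_positions_B: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.beads)
        if self.ref_positions_A is None:
            self.ref_positions_A = np.array([b.position for b in self.beads], float)
        self.ref_positions_A = np.asarray(self.ref_positions_A, float).reshape(n, 3)
        if self.ref_positions_B is None:
            self.ref_positions_B = self.ref_positions_A.copy()
        self.ref_positions_B = np.asarray(self.ref_positions_B, float).reshape(n, 3)
        self.validate()

    # -- basic views ---------------------------------------------------

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def charges(self) -> np.ndarray:
        return np.array([b.charge for b in self.beads], dtype=float)

    @property
    def protein_mask(self) -> np.ndarray:
        return np.array([b.is_protein for b in self.beads], dtype=bool)

    @property
    def dna_mask(self) -> np.ndarray:
        return ~self.protein_mask

    def ref_positions(self, basin: str) -> np.ndarray:
        if basin == "A":
            return self.ref_positions_A.copy()
        if basin == "B":
            return self.ref_positions_B.copy()
        raise ValueError(f"unknown basin {basin!r}")

    def contact_ids_by_class(self, basin_class: BasinClass) -> list[int]:
        basin_class = BasinClass(basin_class)
        return [c_id for c_id, c in enumerate(self.contacts) if c.basin_class == basin_class]

    def interface_contact_ids(self) -> list[int]:
        return self.contact_ids_by_class(BasinClass.INTERFACE)

    def validate(self) -> None:
        n = self.n_beads
        for b_id, bead in enumerate(self.beads):
            if bead.global_index != b_id:
                raise ValueError("bead global_index must equal its list position")
        for t in self.bonds:
            if not (0 <= t.i < n and 0 <= t.j < n):
                raise ValueError(f"bond {t} references an invalid bead")
        for t in self.angles:
            if not all(0 <= x < n for x in (t.i, t.j, t.k)):
                raise ValueError(f"angle {t} references an invalid bead")
            if not t.hinge and t.theta0_A != t.theta0_B:
                raise ValueError(f"non-hinge angle {t} has distinct basin references")
        for t in self.dihedrals:
            if not all(0 <= x < n for x in (t.i, t.j, t.k, t.l)):
                raise ValueError(f"dihedral {t} references an invalid bead")
            if not t.hinge and t.phi0_A != t.phi0_B:
                raise ValueError(f"non-hinge dihedral {t} has distinct basin references")
        for c in self.contacts:
            if not (0 <= c.i < n and 0 <= c.j < n):
                raise ValueError(f"contact {c} references an invalid bead")
        for ids in (self.lf_f_contact_ids, self.lf_t_contact_ids):
            for c_id in ids:
                if not 0 <= c_id < len(self.contacts):
                    raise ValueError(f"contact id {c_id} out of range")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TwoBasinTopology):
            return NotImplemented
        return (
            self.beads == other.beads
            and self.bonds == other.bonds
            and self.angles == other.angles
            and self.dihedrals == other.dihedrals
            and self.contacts == other.contacts
            and self.hinge_residues == other.hinge_residues
            and self.linker_range == other.linker_range
            and self.lf_f_contact_ids == other.lf_f_contact_ids
            and self.lf_t_contact_ids == other.lf_t_contact_ids
            and self.regions == other.regions
            and np.array_equal(self.ref_positions_A, other.ref_positions_A)
            and np.array_equal(self.ref_positions_B, other.ref_positions_B)
        )


# ---------------------------------------------------------------------------
# plain-text topology file format
# ---------------------------------------------------------------------------

_F = "%.17g"  # repr-exact float formatting for bit-exact round-trips


def write_topology(topology: TwoBasinTopology, path) -> None:
    """Write a topology to the columnar text format (bit-exact round-trip)."""
    lines: list[str] = ["# dualbasin topology v1"]
    lines.append("[beads]")
    lines.append("# index chain resid resname kind xA yA zA xB yB zB")
    for b_id, b in enumerate(topology.beads):
        xa = topology.ref_positions_A[b_id]
        xb = topology.ref_positions_B[b_id]
        coords = " ".join(_F % v for v in (*xa, *xb))
        lines.append(
            f"{b.global_index} {b.chain_id} {b.residue_index} {b.residue_name} "
            f"{b.bead_kind.value} {coords}"
        )
    lines.append("[charges]")
    lines.append("# index charge")
    for b in topology.beads:
        lines.append(f"{b.global_index} {b.charge}")
    lines.append("[bonds]")
    lines.append("# i j r0")
    for t in topology.bonds:
        lines.append(f"{t.i} {t.j} {_F % t.r0}")
    lines.append("[angles]")
    lines.append("# i j k theta0_A theta0_B hinge")
    for t in topology.angles:
        lines.append(
            f"{t.i} {t.j} {t.k} {_F % t.theta0_A} {_F % t.theta0_B} {int(t.hinge)}"
        )
    lines.append("[dihedrals]")
    lines.append("# i j k l phi0_A phi0_B hinge")
    for t in topology.dihedrals:
        lines.append(
            f"{t.i} {t.j} {t.k} {t.l} {_F % t.phi0_A} {_F % t.phi0_B} {int(t.hinge)}"
        )
    lines.append("[contacts]")
    lines.append("# i j r0 class strength_scale")
    for c in topology.contacts:
        lines.append(
            f"{c.i} {c.j} {_F % c.r0} {c.basin_class.value} {_F % c.strength_scale}"
        )
    meta = {
        "hinge_residues": sorted(topology.hinge_residues),
        "linker_range": list(topology.linker_range) if topology.linker_range else None,
        "lf_f_contact_ids": list(topology.lf_f_contact_ids),
        "lf_t_contact_ids": list(topology.lf_t_contact_ids),
        "regions": {k: list(v) for k, v in topology.regions.items()},
    }
    lines.append("[meta]")
    lines.append(json.dumps(meta, sort_keys=True))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_topology(path) -> TwoBasinTopology:
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                current = sections.setdefault(line[1:-1], [])
                continue
            if current is None:
                raise ValueError(f"{path}: content before first section header")
            current.append(line)

    charges = {}
    for line in sections.get("charges", []):
        idx, q = line.split()
        charges[int(idx)] = int(q)

    beads: list[Bead] = []
    ref_a, ref_b = [], []
    for line in sections.get("beads", []):
        parts = line.split()
        idx = int(parts[0])
        beads.append(
            Bead(
                global_index=idx,
                chain_id=parts[1],
                residue_index=int(parts[2]),
                residue_name=parts[3],
                bead_kind=BeadKind(parts[4]),
                charge=charges.get(idx, 0),
                position=[float(parts[5]), float(parts[6]), float(parts[7])],
            )
        )
        ref_a.append([float(parts[5]), float(parts[6]), float(parts[7])])
        ref_b.append([float(parts[8]), float(parts[9]), float(parts[10])])

    bonds = []
    for line in sections.get("bonds", []):
        i, j, r0 = line.split()
        bonds.append(BondTerm(int(i), int(j), float(r0)))
    angles = []
    for line in sections.get("angles", []):
        i, j, k, ta, tb, hinge = line.split()
        angles.append(AngleTerm(int(i), int(j), int(k), float(ta), float(tb), bool(int(hinge))))
    dihedrals = []
    for line in sections.get("dihedrals", []):
        i, j, k, l, pa, pb, hinge = line.split()
        dihedrals.append(
            DihedralTerm(int(i), int(j), int(k), int(l), float(pa), float(pb), bool(int(hinge)))
        )
    contacts = []
    for line in sections.get("contacts", []):
        i, j, r0, cls, scale = line.split()
        contacts.append(ContactPair(int(i), int(j), float(r0), BasinClass(cls), float(scale)))

    meta = json.loads(sections["meta"][0]) if sections.get("meta") else {}
    linker = meta.get("linker_range")
    return TwoBasinTopology(
        beads=beads,
        bonds=bonds,
        angles=angles,
        dihedrals=dihedrals,
        contacts=contacts,
        hinge_residues=set(meta.get("hinge_residues", [])),
        linker_range=tuple(linker) if linker else None,
        lf_f_contact_ids=list(meta.get("lf_f_contact_ids", [])),
        lf_t_contact_ids=list(meta.get("lf_t_contact_ids", [])),
        regions={k: list(v) for k, v in meta.get("regions", {}).items()},
        ref_positions_A=np.array(ref_a, float),
        ref_positions_B=np.array(ref_b, float),
    )


_KIND_ATOM = {
    BeadKind.CA: "CA",
    BeadKind.PHOSPHATE: "P",
    BeadKind.SUGAR: "S",
    BeadKind.BASE: "B",
}


def write_cg_pdb(topology: TwoBasinTopology, path, positions: np.ndarray | None = None) -> None:
    """Write the coarse-grained structure as a PDB with one atom per bead."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    if positions is None:
        positions = topology.ref_positions_A
    positions = np.asarray(positions, float).reshape(topology.n_beads, 3)
    arr = struc.AtomArray(topology.n_beads)
    arr.coord = positions
    arr.chain_id = np.array([b.chain_id[:4] for b in topology.beads])
    arr.res_id = np.array([b.residue_index for b in topology.beads])
    arr.res_name = np.array([b.residue_name[:5] for b in topology.beads])
    arr.atom_name = np.array([_KIND_ATOM[b.bead_kind] for b in topology.beads])
    arr.element = np.array(
        ["C" if b.bead_kind != BeadKind.PHOSPHATE else "P" for b in topology.beads]
    )
    arr.hetero = np.zeros(topology.n_beads, dtype=bool)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))
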