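"""Build a two-basin coarse-grained topology from two reference structures.

The protein is reduced to one CA bead per residue; each DNA nucleotide to
three beads at the centroids of its phosphate, sugar and base heavy-atom
groups.  Arg/Lys beads carry +1e, Asp/Glu and phosphate beads -1e.  Native
contacts are taken from an all-heavy-atom distance criterion on the atomic
structures (or from bead-bead distances for coarse-grained fixtures); the
contact maps of the two reference conformations are merged into a
dual-basin map, hinge regions are detected from bonded-geometry changes
between the two basins, and the protein-DNA interface map of the bound
complex supplies the specific binding interactions.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from dualbasin.geometry import bend_angles, torsion_angles, wrap_angle
from dualbasin.topology import (
    AngleTerm,
    BasinClass,
    Bead,
    BeadKind,
    BondTerm,
    ContactPair,
    DihedralTerm,
    TwoBasinTopology,
)

logger = logging.getLogger(__name__)

__all__ = [
    "coarse_grain_protein",
    "coarse_grain_dna",
    "assign_charges",
    "build_intra_contact_map",
    "build_interface_contact_map",
    "chain_bonded_terms",
    "identify_hinges",
    "merge_two_basin",
    "build_two_basin_model",
    "contact_counts_per_bead",
]

# charge rules: only Arg/Lys are positive, Asp/Glu negative; DNA phosphates -1
_POSITIVE_RESIDUES = {"ARG", "LYS"}
_NEGATIVE_RESIDUES = {"ASP", "GLU"}

_DNA_RESNAMES = {"DA": "A", "DT": "T", "DG": "G", "DC": "C",
                 "A": "A", "T": "T", "G": "G", "C": "C"}

_PHOSPHATE_ATOMS = {"P", "OP1", "O1P", "OP2", "O2P", "O5'"}
_SUGAR_ATOMS = {"C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O3'"}

# default contact criteria (all-heavy-atom, standard structure-based-model practice)
DEFAULT_ATOM_CUTOFF = 4.5  # A
DEFAULT_MIN_SEP = 4
DEFAULT_ANGLE_THRESHOLD_DEG = 15.0
DEFAULT_DIHEDRAL_THRESHOLD_DEG = 30.0


def _residue_groups(atoms) -> list[np.ndarray]:
    """Indices of ``atoms`` grouped by residue, in order of appearance."""
    import biotite.structure as struc

    starts = struc.get_residue_starts(atoms, add_exclusive_stop=True)
    return [np.arange(starts[g], starts[g + 1]) for g in range(len(starts) - 1)]


def _is_heavy(atoms) -> np.ndarray:
    return ~np.isin(atoms.element, ("H", "D"))


def coarse_grain_protein(atomic_structure, start_index: int = 0) -> list[Bead]:
    """One CA bead per residue at the CA coordinate.

    Raises if any residue lacks a CA atom or if the structure contains
    non-amino-acid residues.
    """
    import biotite.structure as struc

    atoms = atomic_structure
    if atoms.array_length() == 0:
        raise ValueError("empty structure")
    aa_mask = struc.filter_amino_acids(atoms)
    if not np.all(aa_mask):
        bad = np.unique(atoms.res_name[~aa_mask])
        raise ValueError(f"non-protein residues present: {', '.join(bad)}")

    beads: list[Bead] = []
    for group in _residue_groups(atoms):
        res_atoms = atoms[group]
        ca = np.where(res_atoms.atom_name == "CA")[0]
        if len(ca) == 0:
            raise ValueError(
                f"residue {res_atoms.res_name[0]} {int(res_atoms.res_id[0])} "
                f"(chain {res_atoms.chain_id[0]}) has no CA atom"
            )
        a = res_atoms[int(ca[0])]
        beads.append(
            Bead(
                global_index=start_index + len(beads),
                chain_id=str(a.chain_id),
                residue_index=int(a.res_id),
                residue_name=str(a.res_name),
                bead_kind=BeadKind.CA,
                charge=0,
                position=np.array(a.coord, float),
            )
        )
    return beads


def coarse_grain_dna(atomic_structure, start_index: int = 0) -> list[Bead]:
    """Three beads per nucleotide at phosphate/sugar/base group centroids.

    Bead order within each nucleotide is PHOSPHATE, SUGAR, BASE; 5'-terminal
    nucleotides without phosphate atoms get no phosphate bead (warned).
    """
    beads: list[Bead] = []
    atoms = atomic_structure
    heavy = _is_heavy(atoms)
    for group in _residue_groups(atoms):
        res_atoms = atoms[group[heavy[group]]]
        res_name = str(res_atoms.res_name[0])
        if res_name not in _DNA_RESNAMES:
            raise ValueError(f"unknown nucleotide residue name {res_name!r}")
        letter = _DNA_RESNAMES[res_name]
        names = res_atoms.atom_name
        phos = np.isin(names, tuple(_PHOSPHATE_ATOMS))
        sugar = np.isin(names, tuple(_SUGAR_ATOMS))
        base = ~(phos | sugar)
        groups = [
            (BeadKind.PHOSPHATE, phos),
            (BeadKind.SUGAR, sugar),
            (BeadKind.BASE, base),
        ]
        for kind, mask in groups:
            if not np.any(mask):
                if kind == BeadKind.PHOSPHATE:
                    logger.warning(
                        "nucleotide %s %d has no phosphate atoms; bead omitted",
                        res_name,
                        int(res_atoms.res_id[0]),
                    )
                    continue
                raise ValueError(
                    f"nucleotide {res_name} {int(res_atoms.res_id[0])}: "
                    f"empty {kind.value} atom group"
                )
            centroid = res_atoms.coord[mask].mean(axis=0)
            beads.append(
                Bead(
                    global_index=start_index + len(beads),
                    chain_id=str(res_atoms.chain_id[0]),
                    residue_index=int(res_atoms.res_id[0]),
                    residue_name=letter,
                    bead_kind=kind,
                    charge=0,
                    position=np.asarray(centroid, float),
                )
            )
    return beads


def assign_charges(beads: Sequence[Bead]) -> list[Bead]:
    """Apply the charge rules in place and return the beads.

    Arg/Lys CA beads +1, Asp/Glu CA beads -1, phosphate beads -1, all other
    beads 0.  Unknown residue names default to 0 with a warning.
    """
    known = _POSITIVE_RESIDUES | _NEGATIVE_RESIDUES | {
        "ALA", "CYS", "GLN", "ASN", "GLY", "HIS", "ILE", "LEU", "MET", "PHE",
        "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
    for bead in beads:
        if bead.bead_kind == BeadKind.PHOSPHATE:
            bead.charge = -1
        elif bead.bead_kind == BeadKind.CA:
            name = bead.residue_name.upper()
            if name in _POSITIVE_RESIDUES:
                bead.charge = 1
            elif name in _NEGATIVE_RESIDUES:
                bead.charge = -1
            else:
                if name not in known:
                    logger.warning(
                        "unknown residue name %r at bead %d; charge set to 0",
                        bead.residue_name,
                        bead.global_index,
                    )
                bead.charge = 0
        else:
            bead.charge = 0
    return list(beads)


def _atom_residue_pairs_within(atoms, residue_of_atom, cutoff):
    """Residue-index pairs with any heavy-atom pair within ``cutoff``."""
    heavy = _is_heavy(atoms)
    coords = atoms.coord[heavy]
    res_of = residue_of_atom[heavy]
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return set()
    ri = res_of[pairs[:, 0]]
    rj = res_of[pairs[:, 1]]
    lo = np.minimum(ri, rj)
    hi = np.maximum(ri, rj)
    keep = lo != hi
    return set(zip(lo[keep].tolist(), hi[keep].tolist()))


def build_intra_contact_map(
    beads: Sequence[Bead],
    cutoff: float,
    min_sep: int = DEFAULT_MIN_SEP,
    atomic_structure=None,
    basin_class: BasinClass = BasinClass.SHARED,
) -> list[ContactPair]:
    """Intra-protein native contacts.

    With an atomic structure, residue pairs with any heavy-atom pair within
    ``cutoff`` and sequence separation >= ``min_sep`` become contacts with
    r0 set to the CA-CA (bead) distance.  Without one (coarse-grained
    fixtures), the bead-bead distance itself is the criterion.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    beads = list(beads)
    positions = np.array([b.position for b in beads], float)

    if atomic_structure is not None:
        groups = _residue_groups(atomic_structure)
        if len(groups) != len(beads):
            raise ValueError(
                f"atomic structure has {len(groups)} residues but {len(beads)} beads"
            )
        residue_of_atom = np.empty(atomic_structure.array_length(), dtype=int)
        for r_id, group in enumerate(groups):
            residue_of_atom[group] = r_id
        close = _atom_residue_pairs_within(atomic_structure, residue_of_atom, cutoff)
        candidate_pairs = sorted(close)
    else:
        tree = cKDTree(positions)
        arr = tree.query_pairs(cutoff, output_type="ndarray")
        candidate_pairs = sorted(
            (min(i, j), max(i, j)) for i, j in arr.tolist()
        )

    contacts = []
    for i, j in candidate_pairs:
        if abs(beads[j].residue_index - beads[i].residue_index) < min_sep:
            continue
        r0 = float(np.linalg.norm(positions[j] - positions[i]))
        contacts.append(ContactPair(i, j, r0, basin_class))
    return contacts


def build_interface_contact_map(
    protein_beads: Sequence[Bead],
    dna_beads: Sequence[Bead],
    cutoff: float = 6.5,
    protein_structure=None,
    dna_structure=None,
    atom_cutoff: float = DEFAULT_ATOM_CUTOFF,
) -> list[ContactPair]:
    """Protein-DNA interface contacts in the bound complex.

    With atomic structures, a protein residue and a DNA bead group are in
    contact when any heavy-atom pair is within ``atom_cutoff``; otherwise
    the bead-bead distance against ``cutoff`` is used.  r0 is always the
    native bead-bead distance.  Bead indices in the returned pairs are
    global indices, so protein and DNA beads must already carry their final
    ``global_index``.
    """
    protein_beads = list(protein_beads)
    dna_beads = list(dna_beads)
    p_pos = np.array([b.position for b in protein_beads], float)
    d_pos = np.array([b.position for b in dna_beads], float)

    pairs: list[tuple[int, int, float]] = []
    if protein_structure is not None and dna_structure is not None:
        p_groups = _residue_groups(protein_structure)
        if len(p_groups) != len(protein_beads):
            raise ValueError("protein structure / beads mismatch")
        d_atom_groups = _dna_bead_atom_groups(dna_structure, dna_beads)
        p_heavy = _is_heavy(protein_structure)
        for pi, group in enumerate(p_groups):
            pa = protein_structure.coord[group[p_heavy[group]]]
            for di, atom_idx in enumerate(d_atom_groups):
                da = dna_structure.coord[atom_idx]
                dmin = np.min(
                    np.linalg.norm(pa[:, None, :] - da[None, :, :], axis=-1)
                )
                if dmin < atom_cutoff:
                    r0 = float(np.linalg.norm(p_pos[pi] - d_pos[di]))
                    pairs.append((pi, di, r0))
    else:
        d2 = np.linalg.norm(p_pos[:, None, :] - d_pos[None, :, :], axis=-1)
        for pi, di in zip(*np.where(d2 < cutoff)):
            pairs.append((int(pi), int(di), float(d2[pi, di])))

    contacts = []
    for pi, di, r0 in pairs:
        gi = protein_beads[pi].global_index
        gj = dna_beads[di].global_index
        i, j = (gi, gj) if gi < gj else (gj, gi)
        contacts.append(ContactPair(i, j, r0, BasinClass.INTERFACE))
    if not contacts:
        logger.warning("no protein-DNA interface contacts within cutoff")
    return contacts


def _dna_bead_atom_groups(dna_structure, dna_beads) -> list[np.ndarray]:
    """Heavy-atom index groups of ``dna_structure`` aligned with the DNA beads."""
    heavy = _is_heavy(dna_structure)
    groups = _residue_groups(dna_structure)
    by_nucleotide: dict[tuple[str, int], np.ndarray] = {}
    for group in groups:
        key = (str(dna_structure.chain_id[group[0]]), int(dna_structure.res_id[group[0]]))
        by_nucleotide[key] = group
    out = []
    kind_atoms = {
        BeadKind.PHOSPHATE: _PHOSPHATE_ATOMS,
        BeadKind.SUGAR: _SUGAR_ATOMS,
    }
    for bead in dna_beads:
        group = by_nucleotide[(bead.chain_id, bead.residue_index)]
        group = group[heavy[group]]
        names = dna_structure.atom_name[group]
        if bead.bead_kind in kind_atoms:
            mask = np.isin(names, tuple(kind_atoms[bead.bead_kind]))
        else:
            mask = ~np.isin(names, tuple(_PHOSPHATE_ATOMS | _SUGAR_ATOMS))
        out.append(group[mask])
    return out


def contact_counts_per_bead(contacts: Iterable[ContactPair], n_beads: int) -> np.ndarray:
    """Number of contacts touching each bead (e.g. per-nucleotide profiles)."""
    counts = np.zeros(n_beads, dtype=int)
    for c in contacts:
        counts[c.i] += 1
        counts[c.j] += 1
    return counts


def chain_bonded_terms(
    beads: Sequence[Bead], positions: np.ndarray
) -> tuple[list[BondTerm], list[AngleTerm], list[DihedralTerm]]:
    """Sequential bond/angle/dihedral terms along each protein chain.

    DNA beads get no bonded terms: the duplex is rigid and frozen in space.
    """
    positions = np.asarray(positions, float)
    runs: "OrderedDict[str, list[int]]" = OrderedDict()
    for b_id, bead in enumerate(beads):
        if bead.bead_kind == BeadKind.CA:
            runs.setdefault(bead.chain_id, []).append(b_id)

    bonds, angles, dihedrals = [], [], []
    for chain in runs.values():
        for a, b in zip(chain, chain[1:]):
            r0 = float(np.linalg.norm(positions[b] - positions[a]))
            bonds.append(BondTerm(a, b, r0))
        for a, b, c in zip(chain, chain[1:], chain[2:]):
            th = float(bend_angles(positions, [[a, b, c]])[0])
            angles.append(AngleTerm(a, b, c, th, th))
        for a, b, c, d in zip(chain, chain[1:], chain[2:], chain[3:]):
            ph = float(torsion_angles(positions, [[a, b, c, d]])[0])
            dihedrals.append(DihedralTerm(a, b, c, d, ph, ph))
    return bonds, angles, dihedrals


def identify_hinges(
    topoA: TwoBasinTopology,
    topoB: TwoBasinTopology,
    angle_threshold_deg: float = DEFAULT_ANGLE_THRESHOLD_DEG,
    dihedral_threshold_deg: float = DEFAULT_DIHEDRAL_THRESHOLD_DEG,
) -> set[int]:
    """Residues whose native bend/torsion differs between basins beyond thresholds.

    An angle term flags its central residue; a dihedral flags the two
    residues of its central bond.
    """
    if angle_threshold_deg <= 0 or dihedral_threshold_deg <= 0:
        raise ValueError("hinge thresholds must be positive")
    if topoA.n_beads != topoB.n_beads:
        raise ValueError("topologies have different bead counts")
    hinges: set[int] = set()
    thr_a = np.deg2rad(angle_threshold_deg)
    thr_d = np.deg2rad(dihedral_threshold_deg)
    posA, posB = topoA.ref_positions_A, topoB.ref_positions_A
    for t in topoA.angles:
        da = abs(
            float(bend_angles(posA, [[t.i, t.j, t.k]])[0])
            - float(bend_angles(posB, [[t.i, t.j, t.k]])[0])
        )
        if da > thr_a:
            hinges.add(topoA.beads[t.j].residue_index)
    for t in topoA.dihedrals:
        quad = [[t.i, t.j, t.k, t.l]]
        dp = abs(
            wrap_angle(
                float(torsion_angles(posA, quad)[0]) - float(torsion_angles(posB, quad)[0])
            )
        )
        if dp > thr_d:
            hinges.add(topoA.beads[t.j].residue_index)
            hinges.add(topoA.beads[t.k].residue_index)
    return hinges


def _region_of(bead_index: int, regions: dict[str, list[int]]) -> str | None:
    for name, members in regions.items():
        if bead_index in members:
            return name
    return None


def merge_two_basin(
    topoA: TwoBasinTopology,
    topoB: TwoBasinTopology,
    base_basin: str = "A",
    angle_threshold_deg: float = DEFAULT_ANGLE_THRESHOLD_DEG,
    dihedral_threshold_deg: float = DEFAULT_DIHEDRAL_THRESHOLD_DEG,
    linker_range: tuple[int, int] | None = None,
) -> TwoBasinTopology:
    """Merge two single-basin topologies into the dual-basin model.

    Contacts present in both inputs become SHARED (r0 from the bound B
    basin), A-only contacts INTRA_A, B-only INTRA_B; interface contacts
    keep their INTERFACE class.  Bonded terms take the ``base_basin``
    reference except where the basins disagree beyond the hinge thresholds,
    in which case both values are stored and the term is flagged.
    """
    if topoA.n_beads != topoB.n_beads:
        raise ValueError(
            f"bead count mismatch: {topoA.n_beads} (A) vs {topoB.n_beads} (B)"
        )
    posA = topoA.ref_positions_A
    posB = topoB.ref_positions_A

    mapA = {(c.i, c.j): c for c in topoA.contacts}
    mapB = {(c.i, c.j): c for c in topoB.contacts}
    merged: list[ContactPair] = []
    for key in sorted(set(mapA) | set(mapB)):
        in_a, in_b = key in mapA, key in mapB
        src = mapB.get(key, mapA.get(key))
        if src.basin_class == BasinClass.INTERFACE or (
            in_a and mapA[key].basin_class == BasinClass.INTERFACE
        ):
            cls = BasinClass.INTERFACE
        elif in_a and in_b:
            cls = BasinClass.SHARED
        elif in_a:
            cls = BasinClass.INTRA_A
        else:
            cls = BasinClass.INTRA_B
        r0 = mapA[key].r0 if (in_a and not in_b) else mapB[key].r0
        scale = src.strength_scale
        merged.append(ContactPair(key[0], key[1], r0, cls, scale))

    regions = dict(topoB.regions or topoA.regions)
    lf_t_ids, lf_f_ids = [], []
    for c_id, c in enumerate(merged):
        if regions:
            ra = _region_of(c.i, regions)
            rb = _region_of(c.j, regions)
            pair = {ra, rb}
            if c.basin_class == BasinClass.INTRA_A and pair == {"LF", "T"}:
                lf_t_ids.append(c_id)
            if c.basin_class == BasinClass.INTRA_B and pair == {"LF", "F"}:
                lf_f_ids.append(c_id)

    hinge_residues = identify_hinges(
        topoA, topoB, angle_threshold_deg, dihedral_threshold_deg
    )
    thr_a = np.deg2rad(angle_threshold_deg)
    thr_d = np.deg2rad(dihedral_threshold_deg)

    base_is_a = base_basin == "A"
    bonds = []
    for t in topoA.bonds:
        r0 = float(np.linalg.norm(
            (posA if base_is_a else posB)[t.j] - (posA if base_is_a else posB)[t.i]
        ))
        bonds.append(BondTerm(t.i, t.j, r0))
    angles = []
    for t in topoA.angles:
        triple = [[t.i, t.j, t.k]]
        ta = float(bend_angles(posA, triple)[0])
        tb = float(bend_angles(posB, triple)[0])
        if abs(ta - tb) > thr_a:
            angles.append(AngleTerm(t.i, t.j, t.k, ta, tb, hinge=True))
        else:
            base = ta if base_is_a else tb
            angles.append(AngleTerm(t.i, t.j, t.k, base, base))
    dihedrals = []
    for t in topoA.dihedrals:
        quad = [[t.i, t.j, t.k, t.l]]
        pa = float(torsion_angles(posA, quad)[0])
        pb = float(torsion_angles(posB, quad)[0])
        if abs(wrap_angle(pa - pb)) > thr_d:
            dihedrals.append(DihedralTerm(t.i, t.j, t.k, t.l, pa, pb, hinge=True))
        else:
            base = pa if base_is_a else pb
            dihedrals.append(DihedralTerm(t.i, t.j, t.k, t.l, base, base))

    return TwoBasinTopology(
        beads=[
            Bead(
                b.global_index, b.chain_id, b.residue_index, b.residue_name,
                b.bead_kind, b.charge, posA[b_id].copy(),
            )
            for b_id, b in enumerate(topoA.beads)
        ],
        bonds=bonds,
        angles=angles,
        dihedrals=dihedrals,
        contacts=merged,
        hinge_residues=hinge_residues,
        linker_range=linker_range,
        lf_f_contact_ids=lf_f_ids,
        lf_t_contact_ids=lf_t_ids,
        regions=regions,
        ref_positions_A=posA.copy(),
        ref_positions_B=posB.copy(),
    )


def build_two_basin_model(
    apo_structure,
    bound_protein_structure,
    dna_structure,
    atom_cutoff: float = DEFAULT_ATOM_CUTOFF,
    min_sep: int = DEFAULT_MIN_SEP,
    linker_range: tuple[int, int] | None = None,
    regions: dict[str, list[int]] | None = None,
) -> TwoBasinTopology:
    """End-to-end build from atomic structures (apo protein, bound complex).

    The apo structure defines the A basin, the bound complex the B basin
    and the protein-DNA interface; DNA coordinates (held rigid during
    simulation) come from the bound complex in both basins.
    """
    beads_a = assign_charges(coarse_grain_protein(apo_structure))
    beads_b = assign_charges(coarse_grain_protein(bound_protein_structure))
    if len(beads_a) != len(beads_b):
        raise ValueError(
            f"apo and bound proteins differ in residue count: "
            f"{len(beads_a)} vs {len(beads_b)}"
        )
    n_prot = len(beads_a)
    dna_beads = assign_charges(coarse_grain_dna(dna_structure, start_index=n_prot))

    pos_prot_a = np.array([b.position for b in beads_a], float)
    pos_prot_b = np.array([b.position for b in beads_b], float)
    pos_dna = np.array([b.position for b in dna_beads], float)

    bondsA, anglesA, dihedralsA = chain_bonded_terms(beads_a, pos_prot_a)
    contactsA = build_intra_contact_map(
        beads_a, atom_cutoff, min_sep, atomic_structure=apo_structure
    )
    contactsB = build_intra_contact_map(
        beads_b, atom_cutoff, min_sep, atomic_structure=bound_protein_structure
    )
    interface = build_interface_contact_map(
        beads_b,
        dna_beads,
        protein_structure=bound_protein_structure,
        dna_structure=dna_structure,
        atom_cutoff=atom_cutoff,
    )

    all_beads_a = beads_a + dna_beads
    all_beads_b = [
        Bead(b.global_index, b.chain_id, b.residue_index, b.residue_name,
             b.bead_kind, b.charge, pos_prot_b[k])
        for k, b in enumerate(beads_b)
    ] + dna_beads
    refA = np.vstack([pos_prot_a, pos_dna])
    refB = np.vstack([pos_prot_b, pos_dna])

    topoA = TwoBasinTopology(
        beads=[Bead(b.global_index, b.chain_id, b.residue_index, b.residue_name,
                    b.bead_kind, b.charge, refA[k]) for k, b in enumerate(all_beads_a)],
        bonds=bondsA, angles=anglesA, dihedrals=dihedralsA,
        contacts=contactsA, regions=regions or {}, ref_positions_A=refA,
    )
    topoB = TwoBasinTopology(
        beads=[Bead(b.global_index, b.chain_id, b.residue_index, b.residue_name,
                    b.bead_kind, b.charge, refB[k]) for k, b in enumerate(all_beads_b)],
        bonds=bondsA, angles=anglesA, dihedrals=dihedralsA,
        contacts=contactsB + interface, regions=regions or {}, ref_positions_A=refB,
    )
    return merge_two_basin(topoA, topoB, linker_range=linker_range)
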