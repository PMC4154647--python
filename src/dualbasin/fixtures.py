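"""Desk-scale synthetic systems with known ground truth, plus independent
quadrature oracles.

The fixtures emulate the archetype of the real problem -- a multi-domain
CA protein with two reference conformations related by a hinge rotation, a
rigid three-bead-per-nucleotide DNA duplex with charged phosphates, and a
known contact interface -- without mimicking any particular protein.  The
oracles (Boltzmann populations by quadrature, mean first-passage time by
the Smoluchowski double integral) are written independently of the energy
and sampling kernels they cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dualbasin import builder
from dualbasin.geometry import rotation_matrix
from dualbasin.topology import Bead, BeadKind, TwoBasinTopology

__all__ = [
    "ToyTwoBasinSystem",
    "make_toy_two_basin",
    "make_toy_complex",
    "make_ideal_dna",
    "ideal_dna_atoms",
    "PRIMER_14MER",
    "TEMPLATE_16MER",
    "DoubleWellReference",
    "DoubleWellSystem",
    "boltzmann_oracle",
    "double_well_populations",
    "mfpt_oracle",
]

# the primer/template substrate sequences used as the default duplex
PRIMER_14MER = "GGGACCCTTCGAAT"
TEMPLATE_16MER = "TTATTCGAAGGGTCCC"

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

# residue names cycled along toy chains; includes charged residues so the
# electrostel term is exercised
_TOY_RESNAMES = ["ALA", "LYS", "GLY", "GLU", "SER", "ARG", "THR", "ASP", "VAL", "LEU"]


# ---------------------------------------------------------------------------
# toy two-basin protein
# ---------------------------------------------------------------------------


@dataclass
class ToyTwoBasinSystem:
    """A generated two-domain hinge system together with its ground truth."""

    topology: TwoBasinTopology
    topo_a: TwoBasinTopology
    topo_b: TwoBasinTopology
    planted_hinge_residues: set[int]
    pivot_bead: int
    ground_truth: dict = field(default_factory=dict)
    notes: str = ""


def _helix_positions(n: int, radius: float = 2.3, rise: float = 1.5,
                     twist_deg: float = 100.0) -> np.ndarray:
    t = np.arange(n)
    ang = np.deg2rad(twist_deg) * t
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * t])


def _brute_force_contacts(positions: np.ndarray, cutoff: float, min_sep: int
                          ) -> set[tuple[int, int]]:
    """Independent O(n^2) contact enumeration (ground-truth sidecar)."""
    n = len(positions)
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            if j - i < min_sep:
                continue
            if np.linalg.norm(positions[j] - positions[i]) < cutoff:
                out.add((i, j))
    return out


def _zigzag_path(start: np.ndarray, end: np.ndarray, n_points: int) -> np.ndarray:
    """Interior points along start->end with a small perpendicular zigzag
    (keeps consecutive angles away from the colinear singularity)."""
    d = end - start
    perp = _unit_perp(d)
    pts = []
    for k in range(1, n_points + 1):
        frac = k / (n_points + 1)
        pts.append(start + frac * d + ((-1) ** k) * 0.8 * perp)
    return np.array(pts)


def _toy_chain(n_per_domain: int, hinge_rotation_deg: float):
    """Chain F - turn - T - linker - LF with a single torsion hinge at the
    middle linker bond; returns both basin coordinate sets plus bookkeeping.

    In basin A the mobile LF domain packs against the T domain; basin B
    applies a proper torsion of ``hinge_rotation_deg`` about the middle
    linker bond (beads beyond it rotate rigidly about the bond line), so
    every bond and bend angle is identical in the two basins and exactly
    one backbone dihedral differs.  The F domain is placed against the
    B-state LF pose, giving A-exclusive LF-T and B-exclusive LF-F contacts.
    """
    n = n_per_domain
    t_dom = _helix_positions(n)                     # axis at origin, ascending z
    t_last = t_dom[-1]
    l1 = t_last + np.array([2.6, 1.6, 1.6])
    l2 = l1 + np.array([3.1, -1.3, 1.2])
    l3 = l2 + np.array([2.7, 1.7, 1.1])

    # LF: descending helix anchored one bond length from L3, leaning toward
    # the T column so LF-T contacts form in basin A
    t_aim = np.array([5.0, 0.5, l3[2] - 2.0])
    anchor_dir = t_aim - l3
    anchor_dir /= np.linalg.norm(anchor_dir)
    k_arr = np.arange(n)
    ang = np.deg2rad(-100.0) * k_arr
    lf = np.column_stack(
        [2.3 * np.cos(ang), 2.3 * np.sin(ang), -1.5 * k_arr]
    )
    lf = lf - lf[0] + l3 + 3.7 * anchor_dir
    # nudge outward if the helix clips the T column
    for _ in range(6):
        dmin = np.min(
            np.linalg.norm(lf[:, None, :] - t_dom[None, :, :], axis=-1)
        )
        if dmin >= 3.4:
            break
        lf[:, 0] += 0.4

    pos_tail_a = np.vstack([t_dom, [l1, l2, l3], lf])

    # basin B: torsion about the L1-L2 bond line
    axis = (l2 - l1) / np.linalg.norm(l2 - l1)
    rot = rotation_matrix(axis, np.deg2rad(hinge_rotation_deg))
    idx_l2 = len(t_dom) + 1
    tail_b = pos_tail_a.copy()
    moved = slice(idx_l2 + 1, None)                 # L3 and every LF bead
    tail_b[moved] = (pos_tail_a[moved] - l1) @ rot.T + l1

    return pos_tail_a, tail_b, len(t_dom)


def make_toy_two_basin(
    n_per_domain: int = 8,
    hinge_rotation_deg: float = 165.0,
    seed: int = 0,
    contact_cutoff: float = 8.0,
    min_sep: int = 4,
) -> ToyTwoBasinSystem:
    """Three compact domains (F, T, LF) with a 3-bead linker and a planted
    torsion hinge at the middle linker bond.

    Basin B is basin A with everything beyond that bond rotated rigidly
    about the bond line by ``hinge_rotation_deg``: bonds and bend angles
    are identical in the two basins, exactly one backbone dihedral differs
    by the rotation, and the planted hinge residues are the two central
    linker residues of that dihedral.  The F domain sits against the
    B-state LF pose, so the merge yields A-exclusive LF-T contacts (the
    Q_A set) and B-exclusive LF-F contacts (the Q_iB set).
    """
    if n_per_domain < 3:
        raise ValueError("n_per_domain must be >= 3")
    if hinge_rotation_deg == 0.0:
        import warnings

        warnings.warn("hinge rotation of 0 deg gives a degenerate single basin")

    rng = np.random.default_rng(seed)
    tail_a, tail_b, n_t = _toy_chain(n_per_domain, hinge_rotation_deg)
    lf_slice = slice(n_t + 3, None)

    # place F against the B-state LF pose, clear of everything else
    lf_b = tail_b[lf_slice]
    lf_b_com = lf_b.mean(axis=0)
    lf_axis = lf_b[-1] - lf_b[0]
    lf_axis /= np.linalg.norm(lf_axis)
    perp1 = _unit_perp(lf_axis)
    perp2 = np.cross(lf_axis, perp1)
    f_dom_local = _helix_positions(n_per_domain)
    f_dom_local -= f_dom_local.mean(axis=0)
    # align the F helix axis with the LF(B) axis so the two pack side by side
    z_axis = np.array([0.0, 0.0, 1.0])
    cross = np.cross(z_axis, lf_axis)
    if np.linalg.norm(cross) > 1e-8:
        align = rotation_matrix(
            cross, float(np.arccos(np.clip(np.dot(z_axis, lf_axis), -1, 1)))
        )
        f_dom_local = f_dom_local @ align.T
    f_dom = None
    for dist in (5.6, 6.2, 6.8):
        for azimuth in np.deg2rad(np.arange(0.0, 360.0, 20.0)):
            direction = np.cos(azimuth) * perp1 + np.sin(azimuth) * perp2
            candidate = f_dom_local + lf_b_com + dist * direction
            d_a = np.linalg.norm(candidate[:, None, :] - tail_a[None, :, :], axis=-1)
            d_b_core = np.linalg.norm(
                candidate[:, None, :] - tail_b[None, : n_t + 3, :], axis=-1
            )
            d_b_lf = np.linalg.norm(candidate[:, None, :] - lf_b[None, :, :], axis=-1)
            if (d_a.min() > 3.6 and d_b_core.min() > 3.6
                    and 3.3 < d_b_lf.min() < 6.5):
                f_dom = candidate
                break
        if f_dom is not None:
            break
    if f_dom is None:
        raise RuntimeError("could not place the F domain without clashes")

    turn = _zigzag_path(f_dom[-1], tail_a[0], max(2, int(
        np.linalg.norm(tail_a[0] - f_dom[-1]) / 3.3)))
    pos_a = np.vstack([f_dom, turn, tail_a])
    pos_b = np.vstack([f_dom, turn, tail_b])
    jitter = 0.03 * rng.standard_normal(pos_a.shape)
    pos_a = pos_a + jitter
    pos_b = pos_b + jitter  # same jitter: fixed segments stay bit-identical
    n = len(pos_a)
    offset = n_per_domain + len(turn)               # chain index of first T bead
    idx_l1 = offset + n_t
    idx_l2 = idx_l1 + 1
    idx_l3 = idx_l1 + 2

    beads = [
        Bead(
            global_index=k,
            chain_id="P",
            residue_index=k + 1,
            residue_name=_TOY_RESNAMES[k % len(_TOY_RESNAMES)],
            bead_kind=BeadKind.CA,
            charge=0,
            position=pos_a[k].copy(),
        )
        for k in range(n)
    ]
    builder.assign_charges(beads)

    bonds, angles, dihedrals = builder.chain_bonded_terms(beads, pos_a)
    contacts_a = builder.build_intra_contact_map(beads, contact_cutoff, min_sep)
    beads_b = [
        Bead(b.global_index, b.chain_id, b.residue_index, b.residue_name,
             b.bead_kind, b.charge, pos_b[k])
        for k, b in enumerate(beads)
    ]
    contacts_b = builder.build_intra_contact_map(beads_b, contact_cutoff, min_sep)

    regions = {
        "F": list(range(n_per_domain)),
        "T": list(range(n_per_domain, idx_l1)),
        "linker": [idx_l1, idx_l2, idx_l3],
        "LF": list(range(idx_l3 + 1, n)),
    }
    topo_a = TwoBasinTopology(
        beads=[Bead(b.global_index, b.chain_id, b.residue_index, b.residue_name,
                    b.bead_kind, b.charge, pos_a[k]) for k, b in enumerate(beads)],
        bonds=bonds, angles=angles, dihedrals=dihedrals, contacts=contacts_a,
        regions=regions, ref_positions_A=pos_a.copy(),
    )
    topo_b = TwoBasinTopology(
        beads=beads_b, bonds=bonds, angles=angles, dihedrals=dihedrals,
        contacts=contacts_b, regions=regions, ref_positions_A=pos_b.copy(),
    )
    merged = builder.merge_two_basin(
        topo_a, topo_b,
        linker_range=(beads[idx_l1].residue_index, beads[idx_l3].residue_index),
    )

    # ground truth, independently of the builder code paths
    set_a = _brute_force_contacts(pos_a, contact_cutoff, min_sep)
    set_b = _brute_force_contacts(pos_b, contact_cutoff, min_sep)
    planted = {beads[idx_l1].residue_index, beads[idx_l2].residue_index}
    gt = {
        "n_beads": n,
        "n_shared": len(set_a & set_b),
        "n_a_only": len(set_a - set_b),
        "n_b_only": len(set_b - set_a),
        "total_charge": int(sum(b.charge for b in beads)),
        "planted_hinge_residues": sorted(planted),
    }
    return ToyTwoBasinSystem(
        topology=merged,
        topo_a=topo_a,
        topo_b=topo_b,
        planted_hinge_residues=planted,
        pivot_bead=idx_l2,
        ground_truth=gt,
        notes="single torsion hinge at the middle linker bond; bonds and "
        "angles identical between basins by construction; occupancies of "
        "this system have no closed form (cross-checked by MD); the 1D "
        "oracles live in DoubleWellReference",
    )


def make_toy_complex(
    n_per_domain: int = 8,
    hinge_rotation_deg: float = 165.0,
    seed: int = 0,
    n_bp: int = 6,
    interface_cutoff: float = 8.0,
) -> ToyTwoBasinSystem:
    """Toy protein plus a short rigid duplex docked against the B-state
    second domain, with planted interface contacts."""
    toy = make_toy_two_basin(n_per_domain, hinge_rotation_deg, seed)
    n_prot = toy.topology.n_beads
    seq = ("GCAT" * ((n_bp + 3) // 4))[:n_bp]
    dna_beads, helix_info = make_ideal_dna(seq, start_index=n_prot)
    dna_pos = np.array([b.position for b in dna_beads])

    # dock the duplex against the LF domain in the B conformation, clear of
    # clashes with either protein pose
    pos_a = toy.topo_a.ref_positions_A
    pos_b = toy.topo_b.ref_positions_A
    lf = toy.topology.regions["LF"]
    lf_com = pos_b[lf].mean(axis=0)
    axis_dir = pos_b[lf[-1]] - pos_b[lf[0]]
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    perp1 = _unit_perp(axis_dir)
    perp2 = np.cross(axis_dir, perp1)
    dna_centered = dna_pos - dna_pos.mean(axis=0)
    placed = None
    for dist in (11.0, 12.0, 13.0, 14.0):
        for azimuth in np.deg2rad(np.arange(0.0, 360.0, 20.0)):
            direction = np.cos(azimuth) * perp1 + np.sin(azimuth) * perp2
            cand = dna_centered + lf_com + dist * direction
            d_b = np.linalg.norm(pos_b[:, None, :] - cand[None, :, :], axis=-1)
            d_a = np.linalg.norm(pos_a[:, None, :] - cand[None, :, :], axis=-1)
            if d_b.min() > 3.3 and d_a.min() > 3.3 and (d_b < interface_cutoff).sum() >= 5:
                placed = cand
                break
        if placed is not None:
            break
    if placed is None:
        raise RuntimeError("could not dock the duplex without clashes")
    dna_pos = placed
    for k, b in enumerate(dna_beads):
        b.position = dna_pos[k]

    def with_dna(topo: TwoBasinTopology, contacts, ref):
        all_beads = [
            Bead(b.global_index, b.chain_id, b.residue_index, b.residue_name,
                 b.bead_kind, b.charge, ref[k])
            for k, b in enumerate(topo.beads)
        ] + dna_beads
        return TwoBasinTopology(
            beads=all_beads,
            bonds=topo.bonds, angles=topo.angles, dihedrals=topo.dihedrals,
            contacts=contacts, regions=topo.regions,
            ref_positions_A=np.vstack([ref, dna_pos]),
        )

    interface = builder.build_interface_contact_map(
        toy.topo_b.beads, dna_beads, cutoff=interface_cutoff
    )
    topo_a_full = with_dna(toy.topo_a, toy.topo_a.contacts, toy.topo_a.ref_positions_A)
    topo_b_full = with_dna(
        toy.topo_b, toy.topo_b.contacts + interface, toy.topo_b.ref_positions_A
    )
    linker_rng = toy.topology.linker_range
    merged = builder.merge_two_basin(topo_a_full, topo_b_full, linker_range=linker_rng)
    gt = dict(toy.ground_truth)
    gt["n_interface"] = len(interface)
    gt["n_dna_beads"] = len(dna_beads)
    return ToyTwoBasinSystem(
        topology=merged,
        topo_a=topo_a_full,
        topo_b=topo_b_full,
        planted_hinge_residues=toy.planted_hinge_residues,
        pivot_bead=toy.pivot_bead,
        ground_truth=gt,
        notes=toy.notes,
    )


def _unit_perp(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    w = np.cross(v, [0.0, 0.0, 1.0])
    if np.linalg.norm(w) < 1e-8:
        w = np.cross(v, [0.0, 1.0, 0.0])
    return w / np.linalg.norm(w)


# ---------------------------------------------------------------------------
# ideal rigid DNA
# ---------------------------------------------------------------------------


def make_ideal_dna(
    sequence: str,
    template: str | None = None,
    rise: float = 3.4,
    twist_deg: float = 36.0,
    start_index: int = 0,
    chain_ids: tuple[str, str] = ("D", "E"),
) -> tuple[list[Bead], dict]:
    """Three beads per nucleotide on an ideal B-form-like double helix.

    With only ``sequence`` given the second strand is its reverse
    complement; an explicit ``template`` (possibly of different length,
    e.g. a primer/template substrate with an overhang) is used verbatim.
    Returns the beads (phosphates charged -1) and a ground-truth dict with
    the analytic group centroids.
    """
    sequence = sequence.upper()
    for s in (sequence, template or ""):
        bad = set(s) - set("ATGC")
        if bad:
            raise ValueError(f"invalid base letters: {sorted(bad)}")
    if template is None:
        template = "".join(_COMPLEMENT[b] for b in reversed(sequence))
    template = template.upper()

    r_phos, r_sugar, r_base = 8.9, 6.9, 2.5
    phase_p, phase_s = np.deg2rad(95.0), np.deg2rad(70.0)
    omega = np.deg2rad(twist_deg)

    def strand_centroids(seq: str, strand2: bool) -> list[dict]:
        out = []
        n2 = len(template)
        for k, letter in enumerate(seq):
            if not strand2:
                ang = omega * k
                z = rise * k
                sgn = 1.0
            else:
                # antiparallel: nucleotide k pairs (geometrically) with
                # position n2-1-k of the first strand's frame
                ang = omega * (n2 - 1 - k) + np.pi
                z = rise * (n2 - 1 - k)
                sgn = -1.0
            out.append(
                {
                    "letter": letter,
                    "P": np.array(
                        [r_phos * np.cos(ang + sgn * phase_p),
                         r_phos * np.sin(ang + sgn * phase_p), z + sgn * 1.0]
                    ),
                    "S": np.array(
                        [r_sugar * np.cos(ang + sgn * phase_s),
                         r_sugar * np.sin(ang + sgn * phase_s), z + sgn * 0.5]
                    ),
                    "B": np.array([r_base * np.cos(ang), r_base * np.sin(ang), z]),
                }
            )
        return out

    strands = [
        (chain_ids[0], strand_centroids(sequence, strand2=False)),
        (chain_ids[1], strand_centroids(template, strand2=True)),
    ]

    beads: list[Bead] = []
    centroids = []
    for chain_id, nucleotides in strands:
        for k, nt in enumerate(nucleotides):
            for kind, key in (
                (BeadKind.PHOSPHATE, "P"),
                (BeadKind.SUGAR, "S"),
                (BeadKind.BASE, "B"),
            ):
                beads.append(
                    Bead(
                        global_index=start_index + len(beads),
                        chain_id=chain_id,
                        residue_index=k + 1,
                        residue_name=nt["letter"],
                        bead_kind=kind,
                        charge=0,
                        position=nt[key].copy(),
                    )
                )
                centroids.append(nt[key].copy())
    builder.assign_charges(beads)
    gt = {
        "n_nucleotides": len(sequence) + len(template),
        "n_beads": len(beads),
        "total_charge": int(sum(b.charge for b in beads)),
        "centroids": np.array(centroids),
        "rise": rise,
        "twist_deg": twist_deg,
    }
    return beads, gt


_PURINE_BASE_ATOMS = ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"]
_PYRIMIDINE_BASE_ATOMS = ["N1", "C2", "N3", "C4", "C5", "C6"]


def ideal_dna_atoms(beads):
    """Pseudo-atomic duplex whose group centroids equal the bead positions.

    Each bead's atom group is laid out symmetrically around the analytic
    centroid (pairs at +/- offsets, odd atom at the centroid), so the
    coarse-graining round-trip is exact by construction.  Synthetic: the
    atom positions are not a physical nucleotide geometry.
    """
    import biotite.structure as struc

    offsets = np.array(
        [[0.7, 0.0, 0.0], [0.0, 0.7, 0.0], [0.0, 0.0, 0.7], [0.4, 0.4, 0.0]]
    )
    records = []
    for bead in beads:
        c = bead.position
        if bead.bead_kind == BeadKind.PHOSPHATE:
            names = ["P", "OP1", "OP2", "O5'"]
            elements = ["P", "O", "O", "O"]
        elif bead.bead_kind == BeadKind.SUGAR:
            names = ["C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O3'"]
            elements = ["C"] * 5 + ["O", "O"]
        else:
            names = (
                _PURINE_BASE_ATOMS
                if bead.residue_name in ("A", "G")
                else _PYRIMIDINE_BASE_ATOMS
            )
            elements = [nm[0] for nm in names]
        m = len(names)
        coords = np.zeros((m, 3))
        for a in range(m // 2):
            coords[2 * a] = c + offsets[a % len(offsets)]
            coords[2 * a + 1] = c - offsets[a % len(offsets)]
        if m % 2:
            coords[-1] = c
        for nm, el, xyz in zip(names, elements, coords):
            records.append((bead, nm, el, xyz))

    arr = struc.AtomArray(len(records))
    arr.coord = np.array([r[3] for r in records])
    arr.chain_id = np.array([r[0].chain_id for r in records])
    arr.res_id = np.array([r[0].residue_index for r in records])
    arr.res_name = np.array(["D" + r[0].residue_name for r in records])
    arr.atom_name = np.array([r[1] for r in records])
    arr.element = np.array([r[2] for r in records])
    arr.hetero = np.zeros(len(records), dtype=bool)
    return arr


# ---------------------------------------------------------------------------
# 1D double well: sampler fixture and quadrature oracles
# ---------------------------------------------------------------------------


class DoubleWellSystem:
    """One mobile bead in a quartic double well along x.

    U = barrier * ((x^2 - a^2)/a^2)^2 + 0.5 * tilt * x / a
        + 0.5 * k_conf * (y^2 + z^2)

    The y/z confinement factorizes out of every x-marginal observable, so
    the system is effectively one-dimensional.  Supports batched force
    evaluation over leading array dimensions for kinetic ensembles.
    """

    def __init__(self, barrier: float, half_separation: float = 1.0,
                 tilt: float = 0.0, k_conf: float = 5.0):
        if barrier < 0:
            raise ValueError("barrier must be >= 0")
        self.h = float(barrier)
        self.a = float(half_separation)
        self.tilt = float(tilt)
        self.k_conf = float(k_conf)
        self.n_beads = 1
        self.masses = np.ones(1)
        self.frozen_mask = np.zeros(1, dtype=bool)
        self.supports_batch = True

    def potential_1d(self, x):
        x = np.asarray(x, float)
        a = self.a
        return self.h * ((x**2 - a**2) / a**2) ** 2 + 0.5 * self.tilt * x / a

    def energy(self, pos):
        pos = np.asarray(pos, float)
        x, y, z = pos[..., 0, 0], pos[..., 0, 1], pos[..., 0, 2]
        return self.potential_1d(x) + 0.5 * self.k_conf * (y**2 + z**2)

    def forces(self, pos):
        pos = np.asarray(pos, float)
        f = np.zeros_like(pos)
        x = pos[..., 0, 0]
        a = self.a
        dudx = 4.0 * self.h * x * (x**2 - a**2) / a**4 + 0.5 * self.tilt / a
        f[..., 0, 0] = -dudx
        f[..., 0, 1] = -self.k_conf * pos[..., 0, 1]
        f[..., 0, 2] = -self.k_conf * pos[..., 0, 2]
        return f

    def start_positions(self, x0: float) -> np.ndarray:
        return np.array([[x0, 0.0, 0.0]])


@dataclass
class DoubleWellReference:
    """Parameters of the 1D double-well oracle problem."""

    barrier: float            # eps
    half_separation: float = 1.0  # A; minima at +/- this value
    tilt: float = 0.0         # eps; energy difference scale between wells
    k_conf: float = 5.0
    temperature: float = 1.0  # eps
    friction: float = 10.0    # 1/tau

    def __post_init__(self) -> None:
        if self.barrier < 0:
            raise ValueError("barrier must be >= 0")

    def system(self) -> DoubleWellSystem:
        return DoubleWellSystem(self.barrier, self.half_separation,
                                self.tilt, self.k_conf)

    @property
    def diffusion(self) -> float:
        # overdamped diffusion constant, mass 1
        return self.temperature / self.friction


def boltzmann_oracle(
    energy_function,
    grid: np.ndarray,
    temperature: float,
    region_of=None,
    refine_tol: float = 1e-4,
) -> dict:
    """State populations by quadrature of exp(-U/T) over a 1D grid.

    ``region_of`` maps coordinates to region labels (default: sign of x,
    labels "left"/"right").  Raises if doubling the grid resolution moves
    any population by more than ``refine_tol``.
    """
    grid = np.asarray(grid, float)
    if grid.ndim != 1 or len(grid) < 8:
        raise ValueError("grid must be a 1D array with at least 8 points")
    if region_of is None:
        region_of = lambda x: np.where(x < 0, "left", "right")

    def populations(g):
        w = np.exp(-(energy_function(g) - np.min(energy_function(g))) / temperature)
        labels = np.asarray(region_of(g))
        total = np.trapezoid(w, g)
        out = {}
        for lab in np.unique(labels):
            wl = np.where(labels == lab, w, 0.0)
            out[str(lab)] = float(np.trapezoid(wl, g) / total)
        return out

    coarse = populations(grid)
    fine_grid = np.linspace(grid[0], grid[-1], 2 * len(grid) - 1)
    fine = populations(fine_grid)
    for lab in coarse:
        if abs(coarse[lab] - fine[lab]) > refine_tol:
            raise ValueError(
                f"grid too coarse: population of {lab!r} moved by "
                f"{abs(coarse[lab] - fine[lab]):.2e} on refinement"
            )
    return fine


def double_well_populations(ref: DoubleWellReference, n_grid: int = 4001) -> dict:
    """Left/right well populations of the reference double well."""
    span = ref.half_separation * 4.0
    grid = np.linspace(-span, span, n_grid)
    sys = ref.system()
    return boltzmann_oracle(sys.potential_1d, grid, ref.temperature)


def mfpt_oracle(
    ref: DoubleWellReference,
    x_start: float | None = None,
    x_target: float | None = None,
    n_grid: int = 20001,
    refine_tol: float = 0.01,
) -> float:
    """Mean first-passage time by the Smoluchowski double integral.

    tau = (1/D) * int_{x0}^{b} dy e^{U(y)/T} int_{-inf}^{y} dz e^{-U(z)/T}
    with an absorbing boundary at ``x_target`` and natural reflection far
    to the left.  Valid in the overdamped regime (friction >> well
    frequency).  Raises if the quadrature has not converged on refinement.
    """
    from scipy.integrate import cumulative_trapezoid

    if x_start is None:
        x_start = -ref.half_separation
    if x_target is None:
        x_target = ref.half_separation
    if x_target <= x_start:
        raise ValueError("x_target must exceed x_start")
    sys = ref.system()
    beta = 1.0 / ref.temperature

    def compute(n):
        left = x_start - 6.0 * ref.half_separation
        g = np.linspace(left, x_target, n)
        u = sys.potential_1d(g)
        u = u - u.min()
        inner = cumulative_trapezoid(np.exp(-beta * u), g, initial=0.0)
        mask = g >= x_start
        integrand = np.exp(beta * u[mask]) * inner[mask]
        tau = np.trapezoid(integrand, g[mask]) / ref.diffusion
        return tau

    tau = compute(n_grid)
    tau_fine = compute(2 * n_grid - 1)
    if not np.isfinite(tau_fine) or abs(tau - tau_fine) > refine_tol * abs(tau_fine):
        raise ValueError("MFPT quadrature did not converge on grid refinement")
    return float(tau_fine)
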