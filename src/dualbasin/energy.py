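"""Two-basin Hamiltonian: bonded terms, 12-10 native contacts, excluded
volume and Debye-Hueckel electrostatics, with analytic forces.

Reduced units throughout: lengths in Angstrom, energies in the native
contact unit ``eps``, temperature in ``eps`` (k_B = 1), bead mass 1, so the
internal time unit is ``tau = sqrt(m A^2 / eps)``.  The nominal dt = 2 fs
and friction 1 ps^-1 of an all-atom-calibrated run map to roughly
dt = 5e-4 tau and gamma = 0.25 tau^-1; both are plain configuration values
here.

Two scaling knobs modulate the conformational equilibrium: ``lambda_linker``
rescales the bonded strength of the hinge terms in the linker (their
reference geometry taken from ``bias_basin``), and ``eps_B_scale`` rescales
the B-basin contacts between the mobile recognition domain and its B-state
partner (the ``lf_f_contact_ids`` set of the topology).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import constants as const

from dualbasin.topology import TwoBasinTopology

__all__ = [
    "ForceFieldParams",
    "EnergyBreakdown",
    "TopologySystem",
    "debye_length_from_salt",
]


@dataclass
class ForceFieldParams:
    """Force-field parameters in reduced units (energies in ``eps``)."""

    eps: float = 1.0                      # native contact depth; the energy unit
    k_bond: float = 100.0                 # eps / A^2 (stiff harmonic bonds)
    k_angle: float = 20.0                 # eps / rad^2
    k_dihedral: float = 1.0               # eps
    sigma_excl: float = 4.0               # A, excluded-volume radius
    dielectric: float = 80.0              # relative permittivity
    salt_concentration: float = 0.15      # mol/L monovalent salt
    coulomb_prefactor: float = 332.0636   # eps*A/e^2 (eps ~ 1 kcal/mol scale)
    dh_prefactor: float = 1.0             # B(kappa) of the salt-calibrated DH form
    lambda_linker: float = 1.0            # linker rigidity scale, >= 0
    bias_basin: str = "A"                 # basin supplying hinge reference values
    eps_B_scale: float = 1.0              # B-state recognition-contact scale, >= 0
    reference_temperature_K: float = 298.0  # physical T for the Debye length only
    lj_cutoff_factor: float | None = 3.0  # contact cutoff = factor * r0; None = off
    excl_cutoff_factor: float | None = 3.0  # repulsion cutoff = factor * sigma
    dh_cutoff_factor: float | None = 3.0  # DH cutoff = factor * debye length
    include_like_charge_pairs: bool = False

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.dielectric <= 0:
            raise ValueError("dielectric must be positive")
        if self.salt_concentration < 0:
            raise ValueError("salt concentration must be non-negative")
        if self.lambda_linker < 0 or self.eps_B_scale < 0:
            raise ValueError("lambda_linker and eps_B_scale must be >= 0")
        if self.bias_basin not in ("A", "B"):
            raise ValueError("bias_basin must be 'A' or 'B'")

    @property
    def debye_length(self) -> float:
        return debye_length_from_salt(
            self.salt_concentration, self.dielectric, self.reference_temperature_K
        )

    @property
    def kappa(self) -> float:
        lam = self.debye_length
        return 0.0 if np.isinf(lam) else 1.0 / lam

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ForceFieldParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown force-field parameters: {sorted(unknown)}")
        return cls(**d)


def debye_length_from_salt(
    c_salt_molar: float, dielectric: float = 80.0, temperature_K: float = 298.0
) -> float:
    """Debye screening length in Angstrom for a monovalent salt.

    kappa^2 = 8 pi l_B N_A C with the Bjerrum length l_B at the given
    dielectric and physical temperature; zero salt gives an infinite
    screening length (plain Coulomb).
    """
    if c_salt_molar < 0:
        raise ValueError("salt concentration must be non-negative")
    if c_salt_molar == 0:
        return np.inf
    # Bjerrum length in Angstrom
    l_b = const.e**2 / (
        4.0 * np.pi * const.epsilon_0 * dielectric * const.k * temperature_K
    ) * 1e10
    # number density in A^-3
    rho = c_salt_molar * const.N_A * 1e-27
    kappa_sq = 8.0 * np.pi * l_b * rho
    return 1.0 / np.sqrt(kappa_sq)


@dataclass
class EnergyBreakdown:
    """Four-way native/non-native x electrostatic/LJ decomposition plus bonded."""

    bonded: float
    native_LJ: float
    nonnative_excl: float
    native_elect: float
    nonnative_elect: float

    @property
    def total(self) -> float:
        return (
            self.bonded
            + self.native_LJ
            + self.nonnative_excl
            + self.native_elect
            + self.nonnative_elect
        )

    def as_dict(self) -> dict:
        d = asdict(self)
        d["total"] = self.total
        return d


def _pair_energy_shifted(u_func, r, cutoff):
    """Evaluate a radial pair potential with optional truncate-and-shift."""
    u = u_func(r)
    if cutoff is not None:
        u = np.where(r < cutoff, u - u_func(cutoff), 0.0)
    return u


class TopologySystem:
    """A topology + parameters compiled into flat NumPy interaction arrays.

    Exposes ``energy``, ``energy_breakdown``, ``forces`` and the
    protein-DNA restricted ``interchain_breakdown`` used by the per-stage
    energy tables.  DNA beads are frozen: their force rows are identically
    zero and rigid DNA internal interactions are dropped (a constant).
    """

    def __init__(self, topology: TwoBasinTopology, params: ForceFieldParams):
        self.topology = topology
        self.params = params
        self.n_beads = topology.n_beads
        self.masses = np.ones(self.n_beads)
        self.frozen_mask = topology.dna_mask
        self.supports_batch = False
        self._compile()

    # ------------------------------------------------------------------
    def _compile(self) -> None:
        topo, p = self.topology, self.params
        n = self.n_beads
        frozen = self.frozen_mask

        linker = topo.linker_range

        def in_linker(bead_id: int) -> bool:
            res = topo.beads[bead_id].residue_index
            if not topo.beads[bead_id].is_protein:
                return False
            if linker is None:
                return True  # no linker declared: lambda acts on every hinge term
            return linker[0] <= res <= linker[1]

        self.bond_idx = np.array([[t.i, t.j] for t in topo.bonds], int).reshape(-1, 2)
        self.bond_r0 = np.array([t.r0 for t in topo.bonds], float)
        self.bond_k = np.full(len(topo.bonds), p.k_bond)

        bias_a = p.bias_basin == "A"
        self.angle_idx = np.array(
            [[t.i, t.j, t.k] for t in topo.angles], int
        ).reshape(-1, 3)
        self.angle_theta0 = np.array(
            [
                (t.theta0_A if bias_a else t.theta0_B) if t.hinge else t.theta0_A
                for t in topo.angles
            ],
            float,
        )
        self.angle_k = np.array(
            [
                p.k_angle * (p.lambda_linker if (t.hinge and in_linker(t.j)) else 1.0)
                for t in topo.angles
            ],
            float,
        )

        self.dihedral_idx = np.array(
            [[t.i, t.j, t.k, t.l] for t in topo.dihedrals], int
        ).reshape(-1, 4)
        self.dihedral_phi0 = np.array(
            [
                (t.phi0_A if bias_a else t.phi0_B) if t.hinge else t.phi0_A
                for t in topo.dihedrals
            ],
            float,
        )
        self.dihedral_k = np.array(
            [
                p.k_dihedral
                * (
                    p.lambda_linker
                    if (t.hinge and (in_linker(t.j) or in_linker(t.k)))
                    else 1.0
                )
                for t in topo.dihedrals
            ],
            float,
        )

        lf_f = set(topo.lf_f_contact_ids)
        self.contact_idx = np.array(
            [[c.i, c.j] for c in topo.contacts], int
        ).reshape(-1, 2)
        self.contact_r0 = np.array([c.r0 for c in topo.contacts], float)
        self.contact_eps = np.array(
            [
                p.eps
                * c.strength_scale
                * (p.eps_B_scale if c_id in lf_f else 1.0)
                for c_id, c in enumerate(topo.contacts)
            ],
            float,
        )
        self.contact_interchain = np.array(
            [frozen[c.i] != frozen[c.j] for c in topo.contacts], bool
        )

        # exclusions for the generic non-native lists: bonded 1-2/1-3/1-4 and contacts
        excluded: set[tuple[int, int]] = set()

        def _add(i: int, j: int) -> None:
            excluded.add((i, j) if i < j else (j, i))

        for t in topo.bonds:
            _add(t.i, t.j)
        for t in topo.angles:
            _add(t.i, t.k)
        for t in topo.dihedrals:
            _add(t.i, t.l)
        contact_set = {(c.i, c.j) for c in topo.contacts}
        excluded |= contact_set
        bonded_13 = set()
        for t in topo.bonds:
            bonded_13.add((min(t.i, t.j), max(t.i, t.j)))
        for t in topo.angles:
            bonded_13.add((min(t.i, t.k), max(t.i, t.k)))

        iu, ju = np.triu_indices(n, k=1)
        both_frozen = frozen[iu] & frozen[ju]
        keep = ~both_frozen
        pair_keys = list(zip(iu[keep].tolist(), ju[keep].tolist()))
        nonnative = [pr for pr in pair_keys if pr not in excluded]
        self.excl_idx = np.array(nonnative, int).reshape(-1, 2)
        self.excl_interchain = (
            frozen[self.excl_idx[:, 0]] != frozen[self.excl_idx[:, 1]]
            if len(self.excl_idx)
            else np.zeros(0, bool)
        )

        # Debye-Hueckel pair list: charged pairs (default: opposite sign only),
        # excluding 1-2/1-3 bonded neighbours and rigid DNA internal pairs
        q = topo.charges
        charged_pairs = []
        native_flags = []
        inter_flags = []
        for i, j in pair_keys:
            qq = q[i] * q[j]
            if qq == 0:
                continue
            if qq > 0 and not p.include_like_charge_pairs:
                continue
            if (i, j) in bonded_13:
                continue
            charged_pairs.append((i, j))
            native_flags.append((i, j) in contact_set)
            inter_flags.append(bool(frozen[i] != frozen[j]))
        self.charge_idx = np.array(charged_pairs, int).reshape(-1, 2)
        self.charge_qq = (
            q[self.charge_idx[:, 0]] * q[self.charge_idx[:, 1]]
            if len(self.charge_idx)
            else np.zeros(0)
        )
        self.charge_native = np.array(native_flags, bool)
        self.charge_interchain = np.array(inter_flags, bool)

        self.contact_cutoff = (
            None if p.lj_cutoff_factor is None else p.lj_cutoff_factor * self.contact_r0
        )
        self.excl_cutoff = (
            None
            if p.excl_cutoff_factor is None
            else p.excl_cutoff_factor * p.sigma_excl
        )
        lam = p.debye_length
        self.dh_cutoff = (
            None
            if (p.dh_cutoff_factor is None or np.isinf(lam))
            else p.dh_cutoff_factor * lam
        )

    # ------------------------------------------------------------------
    # distances

    @staticmethod
    def _pair_r(x: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = x[idx[:, 1]] - x[idx[:, 0]]
        r = np.linalg.norm(d, axis=-1)
        return d, r

    # ------------------------------------------------------------------
    # energy terms

    def bonded_energy(self, x: np.ndarray) -> tuple[float, dict]:
        e_bond = e_angle = e_dih = 0.0
        if len(self.bond_idx):
            _, r = self._pair_r(x, self.bond_idx)
            e_bond = float(np.sum(self.bond_k * (r - self.bond_r0) ** 2))
        if len(self.angle_idx):
            th = self._angles(x)
            e_angle = float(np.sum(self.angle_k * (th - self.angle_theta0) ** 2))
        if len(self.dihedral_idx):
            ph = self._dihedrals(x)
            dphi = ph - self.dihedral_phi0
            e_dih = float(
                np.sum(
                    self.dihedral_k
                    * ((1.0 - np.cos(dphi)) + 0.5 * (1.0 - np.cos(3.0 * dphi)))
                )
            )
        total = e_bond + e_angle + e_dih
        return total, {"bonds": e_bond, "angles": e_angle, "dihedrals": e_dih}

    def contact_energy(self, x: np.ndarray) -> float:
        e, _ = self._contact_energy_terms(x)
        return float(np.sum(e))

    def _contact_energy_terms(self, x: np.ndarray):
        if not len(self.contact_idx):
            return np.zeros(0), np.zeros(0)
        _, r = self._pair_r(x, self.contact_idx)
        if np.any(r == 0):
            raise ValueError("overlapping beads in a native contact (r = 0)")
        r0 = self.contact_r0
        epsc = self.contact_eps

        def u(rr):
            s = r0 / rr
            return epsc * (5.0 * s**12 - 6.0 * s**10)

        if self.contact_cutoff is not None:
            e = np.where(r < self.contact_cutoff, u(r) - u(self.contact_cutoff), 0.0)
        else:
            e = u(r)
        return e, r

    def excluded_volume_energy(self, x: np.ndarray) -> float:
        if not len(self.excl_idx):
            return 0.0
        _, r = self._pair_r(x, self.excl_idx)
        sigma = self.params.sigma_excl

        def u(rr):
            return self.params.eps * (sigma / rr) ** 12

        e = _pair_energy_shifted(u, r, self.excl_cutoff)
        return float(np.sum(e))

    def _dh_pair_energies(self, x: np.ndarray) -> np.ndarray:
        if not len(self.charge_idx):
            return np.zeros(0)
        _, r = self._pair_r(x, self.charge_idx)
        if np.any(r == 0):
            raise ValueError("overlapping charged beads (r = 0)")
        p = self.params
        kappa = p.kappa
        pref = p.coulomb_prefactor * p.dh_prefactor / p.dielectric

        def u(rr):
            return pref * self.charge_qq * np.exp(-kappa * rr) / rr

        if self.dh_cutoff is not None:
            return np.where(r < self.dh_cutoff, u(r) - u(self.dh_cutoff), 0.0)
        return u(r)

    def electrostatic_energy(self, x: np.ndarray) -> tuple[float, float]:
        e = self._dh_pair_energies(x)
        if not len(e):
            return 0.0, 0.0
        native = float(np.sum(e[self.charge_native]))
        nonnative = float(np.sum(e[~self.charge_native]))
        return native, nonnative

    def energy_breakdown(self, x: np.ndarray) -> EnergyBreakdown:
        bonded, _ = self.bonded_energy(x)
        native_lj = self.contact_energy(x)
        excl = self.excluded_volume_energy(x)
        nel, nnel = self.electrostatic_energy(x)
        return EnergyBreakdown(bonded, native_lj, excl, nel, nnel)

    def energy(self, x: np.ndarray) -> float:
        return self.energy_breakdown(x).total

    def interchain_breakdown(self, x: np.ndarray) -> EnergyBreakdown:
        """Protein-DNA interaction energy only (the per-stage table rows)."""
        e_c, _ = self._contact_energy_terms(x)
        native_lj = float(np.sum(e_c[self.contact_interchain])) if len(e_c) else 0.0
        if len(self.excl_idx):
            _, r = self._pair_r(x, self.excl_idx)
            sigma = self.params.sigma_excl

            def u(rr):
                return self.params.eps * (sigma / rr) ** 12

            e_x = _pair_energy_shifted(u, r, self.excl_cutoff)
            excl = float(np.sum(e_x[self.excl_interchain]))
        else:
            excl = 0.0
        e_q = self._dh_pair_energies(x)
        if len(e_q):
            nel = float(np.sum(e_q[self.charge_native & self.charge_interchain]))
            nnel = float(np.sum(e_q[~self.charge_native & self.charge_interchain]))
        else:
            nel = nnel = 0.0
        return EnergyBreakdown(0.0, native_lj, excl, nel, nnel)

    # ------------------------------------------------------------------
    # geometry internals

    def _angles(self, x: np.ndarray) -> np.ndarray:
        idx = self.angle_idx
        u = x[idx[:, 0]] - x[idx[:, 1]]
        v = x[idx[:, 2]] - x[idx[:, 1]]
        nu = np.linalg.norm(u, axis=-1)
        nv = np.linalg.norm(v, axis=-1)
        cos = np.einsum("ij,ij->i", u, v) / np.clip(nu * nv, 1e-300, None)
        return np.arccos(np.clip(cos, -1.0, 1.0))

    def _dihedrals(self, x: np.ndarray) -> np.ndarray:
        idx = self.dihedral_idx
        b1 = x[idx[:, 1]] - x[idx[:, 0]]
        b2 = x[idx[:, 2]] - x[idx[:, 1]]
        b3 = x[idx[:, 3]] - x[idx[:, 2]]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.clip(np.linalg.norm(b2, axis=-1, keepdims=True), 1e-300, None)
        m1 = np.cross(n1, b2 / nb2)
        xx = np.einsum("ij,ij->i", n1, n2)
        yy = np.einsum("ij,ij->i", m1, n2)
        return np.arctan2(yy, xx)

    # ------------------------------------------------------------------
    # forces

    def forces(self, x: np.ndarray) -> np.ndarray:
        f = np.zeros_like(x)
        self._add_pair_forces(f, x)
        self._add_angle_forces(f, x)
        self._add_dihedral_forces(f, x)
        if not np.all(np.isfinite(f)):
            bad = np.where(~np.all(np.isfinite(f), axis=-1))[0]
            raise FloatingPointError(
                f"non-finite force on beads {bad.tolist()[:5]}"
            )
        f[self.frozen_mask] = 0.0
        return f

    def _accumulate_radial(self, f, x, idx, dudr):
        """Add forces for a radial pair term given dU/dr per pair."""
        d, r = self._pair_r(x, idx)
        unit = d / r[:, None]
        contrib = dudr[:, None] * unit  # force on i is +dU/dr * unit(i->j)
        np.add.at(f, idx[:, 0], contrib)
        np.add.at(f, idx[:, 1], -contrib)

    def _add_pair_forces(self, f, x):
        p = self.params
        if len(self.bond_idx):
            _, r = self._pair_r(x, self.bond_idx)
            dudr = 2.0 * self.bond_k * (r - self.bond_r0)
            self._accumulate_radial(f, x, self.bond_idx, dudr)
        if len(self.contact_idx):
            _, r = self._pair_r(x, self.contact_idx)
            s = self.contact_r0 / r
            dudr = self.contact_eps * (-60.0 * s**12 + 60.0 * s**10) / r
            if self.contact_cutoff is not None:
                dudr = np.where(r < self.contact_cutoff, dudr, 0.0)
            self._accumulate_radial(f, x, self.contact_idx, dudr)
        if len(self.excl_idx):
            _, r = self._pair_r(x, self.excl_idx)
            dudr = -12.0 * p.eps * (p.sigma_excl / r) ** 12 / r
            if self.excl_cutoff is not None:
                dudr = np.where(r < self.excl_cutoff, dudr, 0.0)
            self._accumulate_radial(f, x, self.excl_idx, dudr)
        if len(self.charge_idx):
            _, r = self._pair_r(x, self.charge_idx)
            kappa = p.kappa
            pref = p.coulomb_prefactor * p.dh_prefactor / p.dielectric
            dudr = -pref * self.charge_qq * np.exp(-kappa * r) * (kappa * r + 1.0) / r**2
            if self.dh_cutoff is not None:
                dudr = np.where(r < self.dh_cutoff, dudr, 0.0)
            self._accumulate_radial(f, x, self.charge_idx, dudr)

    def _add_angle_forces(self, f, x):
        if not len(self.angle_idx):
            return
        idx = self.angle_idx
        u = x[idx[:, 0]] - x[idx[:, 1]]
        v = x[idx[:, 2]] - x[idx[:, 1]]
        nu = np.clip(np.linalg.norm(u, axis=-1), 1e-300, None)
        nv = np.clip(np.linalg.norm(v, axis=-1), 1e-300, None)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        cos = np.clip(np.einsum("ij,ij->i", uh, vh), -1.0, 1.0)
        sin = np.clip(np.sqrt(1.0 - cos**2), 1e-8, None)
        theta = np.arccos(cos)
        dudth = 2.0 * self.angle_k * (theta - self.angle_theta0)
        dth_di = -(vh - cos[:, None] * uh) / (nu * sin)[:, None]
        dth_dk = -(uh - cos[:, None] * vh) / (nv * sin)[:, None]
        dth_dj = -(dth_di + dth_dk)
        np.add.at(f, idx[:, 0], -dudth[:, None] * dth_di)
        np.add.at(f, idx[:, 1], -dudth[:, None] * dth_dj)
        np.add.at(f, idx[:, 2], -dudth[:, None] * dth_dk)

    def _add_dihedral_forces(self, f, x):
        if not len(self.dihedral_idx):
            return
        idx = self.dihedral_idx
        b1 = x[idx[:, 1]] - x[idx[:, 0]]
        b2 = x[idx[:, 2]] - x[idx[:, 1]]
        b3 = x[idx[:, 3]] - x[idx[:, 2]]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.clip(np.linalg.norm(b2, axis=-1), 1e-300, None)
        n1sq = np.clip(np.einsum("ij,ij->i", n1, n1), 1e-300, None)
        n2sq = np.clip(np.einsum("ij,ij->i", n2, n2), 1e-300, None)
        m1 = np.cross(n1, b2 / nb2[:, None])
        xx = np.einsum("ij,ij->i", n1, n2)
        yy = np.einsum("ij,ij->i", m1, n2)
        phi = np.arctan2(yy, xx)
        dphi = phi - self.dihedral_phi0
        dudphi = self.dihedral_k * (np.sin(dphi) + 1.5 * np.sin(3.0 * dphi))
        dphi_di = (nb2 / n1sq)[:, None] * n1
        dphi_dl = -(nb2 / n2sq)[:, None] * n2
        s = np.einsum("ij,ij->i", b1, b2) / nb2**2
        t = np.einsum("ij,ij->i", b3, b2) / nb2**2
        dphi_dj = -(1.0 + s)[:, None] * dphi_di + t[:, None] * dphi_dl
        dphi_dk = -(dphi_di + dphi_dj + dphi_dl)
        np.add.at(f, idx[:, 0], -dudphi[:, None] * dphi_di)
        np.add.at(f, idx[:, 1], -dudphi[:, None] * dphi_dj)
        np.add.at(f, idx[:, 2], -dudphi[:, None] * dphi_dk)
        np.add.at(f, idx[:, 3], -dudphi[:, None] * dphi_dl)
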