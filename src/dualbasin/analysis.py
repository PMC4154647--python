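"""Reaction coordinates, state/stage assignment, WHAM reweighting,
contact/energy profiling and mean passage times.

Coordinates follow the native-contact-fraction convention: a contact is
formed when r < formation_factor * r0 (default 1.2).  Q_iDNA runs over the
protein-DNA interface contacts, Q_A over the A-exclusive inter-domain set,
Q_iB over the B-exclusive set; D_COM is the protein-DNA centre-of-mass
distance.  Conformational states A/I/B and binding stages US/EC/IS/BS are
assigned by thresholds on these coordinates (the free-energy basins they
approximate are configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from dualbasin.energy import EnergyBreakdown
from dualbasin.simulate import FirstPassageRecord
from dualbasin.topology import TwoBasinTopology

logger = logging.getLogger(__name__)

__all__ = [
    "CoordinateFrame",
    "StateThresholds",
    "StageThresholds",
    "FESurface",
    "MPTEstimate",
    "fraction_native_contacts",
    "compute_frames",
    "assign_conformation",
    "assign_stage",
    "wham_offsets",
    "wham_weights",
    "free_energy_profile",
    "reweighted_populations",
    "population_table",
    "cutoff_contact_profile",
    "energy_stage_stats",
    "mean_passage_time",
]


# ---------------------------------------------------------------------------
# reaction coordinates
# ---------------------------------------------------------------------------


@dataclass
class CoordinateFrame:
    """Per-frame reaction coordinates."""

    q_idna: float
    q_a: float
    q_ib: float
    d_com: float
    cutoff_contact_count: int
    per_region_q: dict[str, float] = field(default_factory=dict)


def fraction_native_contacts(
    positions: np.ndarray,
    pair_idx: np.ndarray,
    r0: np.ndarray,
    formation_factor: float = 1.2,
) -> float:
    """Fraction of the contact subset with r < formation_factor * r0."""
    pair_idx = np.asarray(pair_idx, int).reshape(-1, 2)
    if len(pair_idx) == 0:
        raise ValueError("empty contact subset")
    d = positions[pair_idx[:, 1]] - positions[pair_idx[:, 0]]
    r = np.linalg.norm(d, axis=-1)
    return float(np.mean(r < formation_factor * np.asarray(r0)))


def _contact_arrays(topology: TwoBasinTopology, ids) -> tuple[np.ndarray, np.ndarray]:
    idx = np.array([[topology.contacts[c].i, topology.contacts[c].j] for c in ids],
                   int).reshape(-1, 2)
    r0 = np.array([topology.contacts[c].r0 for c in ids], float)
    return idx, r0


def _interface_region_ids(topology: TwoBasinTopology) -> dict[str, list[int]]:
    """Interface contact ids grouped by the protein-side region they touch."""
    protein = topology.protein_mask
    groups: dict[str, list[int]] = {}
    iface = topology.interface_contact_ids()
    for name, members in topology.regions.items():
        members = set(members)
        if not any(protein[m] for m in members):
            continue  # DNA-side region; profiled elsewhere
        ids = [
            c_id
            for c_id in iface
            if (topology.contacts[c_id].i in members and protein[topology.contacts[c_id].i])
            or (topology.contacts[c_id].j in members and protein[topology.contacts[c_id].j])
        ]
        if ids:
            groups[name] = ids
    recog = [c for nm in ("LF", "linker") for c in groups.get(nm, [])]
    if recog:
        groups["recognition"] = sorted(set(recog))
        core = sorted(set(iface) - set(groups["recognition"]))
        if core:
            groups["core"] = core
    return groups


def compute_frames(
    positions_frames: np.ndarray,
    topology: TwoBasinTopology,
    formation_factor: float = 1.2,
    contact_cutoff: float = 8.0,
) -> list[CoordinateFrame]:
    """Reaction coordinates for every frame of a trajectory.

    A coordinate whose defining contact subset is empty is reported as NaN.
    """
    positions_frames = np.asarray(positions_frames, float)
    if positions_frames.ndim == 2:
        positions_frames = positions_frames[None]
    protein = topology.protein_mask
    dna = topology.dna_mask
    has_dna = np.any(dna)

    subsets = {
        "q_idna": topology.interface_contact_ids(),
        "q_a": list(topology.lf_t_contact_ids),
        "q_ib": list(topology.lf_f_contact_ids),
    }
    arrays = {k: _contact_arrays(topology, v) for k, v in subsets.items() if v}
    region_ids = _interface_region_ids(topology)
    region_arrays = {k: _contact_arrays(topology, v) for k, v in region_ids.items()}

    out = []
    for x in positions_frames:
        vals = {}
        for key in ("q_idna", "q_a", "q_ib"):
            if key in arrays:
                idx, r0 = arrays[key]
                vals[key] = fraction_native_contacts(x, idx, r0, formation_factor)
            else:
                vals[key] = float("nan")
        if has_dna:
            d_com = float(np.linalg.norm(x[protein].mean(0) - x[dna].mean(0)))
            dd = np.linalg.norm(
                x[protein][:, None, :] - x[dna][None, :, :], axis=-1
            )
            n_cut = int(np.sum(dd < contact_cutoff))
        else:
            d_com = float("nan")
            n_cut = 0
        per_region = {
            name: fraction_native_contacts(x, idx, r0, formation_factor)
            for name, (idx, r0) in region_arrays.items()
        }
        out.append(CoordinateFrame(vals["q_idna"], vals["q_a"], vals["q_ib"],
                                   d_com, n_cut, per_region))
    return out


def frames_dataframe(frames: list[CoordinateFrame]) -> pd.DataFrame:
    rows = []
    for fr in frames:
        row = {
            "q_idna": fr.q_idna,
            "q_a": fr.q_a,
            "q_ib": fr.q_ib,
            "d_com": fr.d_com,
            "cutoff_contacts": fr.cutoff_contact_count,
        }
        for k, v in fr.per_region_q.items():
            row[f"q_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# state and stage assignment
# ---------------------------------------------------------------------------


@dataclass
class StateThresholds:
    """A-state: Q_A > hi with Q_iB at zero; B-state the mirror image;
    I-state: both below lo."""

    qa_hi: float = 0.8
    qib_hi: float = 0.8
    lo: float = 0.1
    zero_tol: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.qa_hi < 1 and 0 < self.lo < self.qib_hi < 1):
            raise ValueError("thresholds must satisfy 0 < lo < hi < 1")


@dataclass
class StageThresholds:
    """Cutoff surrogates for the four free-energy basins of binding."""

    d_free_offset: float = 15.0   # US: beyond native D_COM + this, no contacts
    contact_cutoff: float = 8.0   # EC entry: any inter-chain bead pair closer
    q_region: float = 0.6         # IS: recognition-region interface Q at least this
    core_lo: float = 0.1          # IS: core interface Q below this
    q_bound: float = 0.8          # BS: overall interface Q at least this


def assign_conformation(q_a: float, q_ib: float,
                        thresholds: StateThresholds | None = None) -> str:
    thr = thresholds or StateThresholds()
    if q_a > thr.qa_hi and q_ib <= thr.zero_tol:
        return "A"
    if q_ib > thr.qib_hi and q_a <= thr.zero_tol:
        return "B"
    if q_a < thr.lo and q_ib < thr.lo:
        return "I"
    return "UNASSIGNED"


def assign_stage(frame: CoordinateFrame, native_d_com: float,
                 thresholds: StageThresholds | None = None) -> str:
    """Mutually exclusive stage label with precedence BS > IS > EC > US."""
    thr = thresholds or StageThresholds()
    if frame.q_idna >= thr.q_bound:
        return "BS"
    rec = frame.per_region_q.get("recognition", float("nan"))
    core = frame.per_region_q.get("core", 0.0)
    if rec == rec and rec >= thr.q_region and core < thr.core_lo:
        return "IS"
    if frame.cutoff_contact_count > 0 or frame.d_com <= native_d_com + thr.d_free_offset:
        return "EC"
    return "US"


# ---------------------------------------------------------------------------
# WHAM (binless multi-temperature reweighting)
# ---------------------------------------------------------------------------


@dataclass
class FESurface:
    edges: list[np.ndarray]
    free_energy: np.ndarray   # k_B T at the target temperature, min-shifted
    sampled: np.ndarray       # mask of bins with any weight


def _check_overlap(energy_samples, temperatures):
    order = np.argsort(temperatures)
    for a, b in zip(order, order[1:]):
        lo_a, hi_a = np.min(energy_samples[a]), np.max(energy_samples[a])
        lo_b, hi_b = np.min(energy_samples[b]), np.max(energy_samples[b])
        if hi_a < lo_b or hi_b < lo_a:
            raise ValueError(
                f"no energy-histogram overlap between T={temperatures[a]:g} "
                f"and T={temperatures[b]:g}"
            )


def wham_offsets(
    energy_samples: list[np.ndarray],
    temperatures,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Self-consistent dimensionless free-energy offsets f_k per temperature.

    Solves f_k = -ln sum_i exp(-beta_k E_i) / sum_l N_l exp(f_l - beta_l E_i)
    over the pooled samples; f_0 is pinned to 0.
    """
    temperatures = np.asarray(temperatures, float)
    energy_samples = [np.asarray(e, float) for e in energy_samples]
    if len(energy_samples) != len(temperatures):
        raise ValueError("one energy sample array per temperature required")
    _check_overlap(energy_samples, temperatures)
    betas = 1.0 / temperatures
    n_k = np.array([len(e) for e in energy_samples], float)
    pooled = np.concatenate(energy_samples)

    f = np.zeros(len(temperatures))
    log_nk = np.log(n_k)
    be = betas[:, None] * pooled[None, :]  # (K, Ntot)
    for _ in range(max_iter):
        log_denom = logsumexp(log_nk[:, None] + f[:, None] - be, axis=0)
        f_new = -logsumexp(-be - log_denom[None, :], axis=1)
        f_new = f_new - f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            return f_new
        f = f_new
    raise RuntimeError("WHAM offsets failed to converge")


def wham_weights(
    energy_samples: list[np.ndarray],
    temperatures,
    f: np.ndarray,
    target_temperature: float,
) -> np.ndarray:
    """Normalized per-sample weights of the pooled data at the target T."""
    temperatures = np.asarray(temperatures, float)
    betas = 1.0 / temperatures
    n_k = np.array([len(e) for e in energy_samples], float)
    pooled = np.concatenate([np.asarray(e, float) for e in energy_samples])
    log_denom = logsumexp(
        np.log(n_k)[:, None] + f[:, None] - betas[:, None] * pooled[None, :], axis=0
    )
    log_w = -pooled / target_temperature - log_denom
    log_w -= logsumexp(log_w)
    return np.exp(log_w)


def free_energy_profile(
    coords: np.ndarray,
    weights: np.ndarray,
    bins: int | list = 50,
    ranges=None,
) -> FESurface:
    """Weighted 1D or 2D free-energy surface, -ln(p) in k_B T, min at 0."""
    coords = np.asarray(coords, float)
    if coords.ndim == 1:
        coords = coords[:, None]
    ndim = coords.shape[1]
    if ndim not in (1, 2):
        raise ValueError("profiles support 1 or 2 coordinates")
    hist, edges = np.histogramdd(coords, bins=bins, range=ranges, weights=weights)
    sampled = hist > 0
    fe = np.full(hist.shape, np.inf)
    fe[sampled] = -np.log(hist[sampled])
    fe -= fe[sampled].min()
    return FESurface(edges=[np.asarray(e) for e in edges], free_energy=fe,
                     sampled=sampled)


def reweighted_populations(labels, weights) -> dict[str, float]:
    """Weighted label fractions (e.g. state populations at a reweighted T)."""
    labels = np.asarray(labels)
    weights = np.asarray(weights, float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    return {
        str(lab): float(weights[labels == lab].sum() / total)
        for lab in np.unique(labels)
    }


# ---------------------------------------------------------------------------
# tables and profiles
# ---------------------------------------------------------------------------


def population_table(
    state_labels, stage_labels, weights=None,
    states=("A", "I", "B"), stages=("US", "EC", "IS", "BS"),
) -> pd.DataFrame:
    """Per-stage fractions of the conformational states (rows sum to 1 over
    assigned frames); stages with no frames are omitted with a warning."""
    state_labels = np.asarray(state_labels)
    stage_labels = np.asarray(stage_labels)
    weights = (
        np.ones(len(state_labels), float) if weights is None
        else np.asarray(weights, float)
    )
    rows = {}
    for stage in stages:
        sel = (stage_labels == stage) & np.isin(state_labels, states)
        total = weights[sel].sum()
        if total == 0:
            logger.warning("stage %s has no assigned frames; omitted", stage)
            continue
        rows[stage] = {
            s: float(weights[sel & (state_labels == s)].sum() / total) for s in states
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(states))


def cutoff_contact_profile(
    positions_frames: np.ndarray,
    topology: TwoBasinTopology,
    cutoff: float = 8.0,
) -> dict[str, pd.Series]:
    """Average inter-chain bead contacts per protein residue, per nucleotide
    and per DNA bead kind, over the given frames (native and non-native
    alike: any protein-DNA bead pair within the cutoff counts)."""
    positions_frames = np.asarray(positions_frames, float)
    if positions_frames.ndim == 2:
        positions_frames = positions_frames[None]
    protein = np.where(topology.protein_mask)[0]
    dna = np.where(topology.dna_mask)[0]
    counts = np.zeros((len(protein), len(dna)))
    for x in positions_frames:
        dd = np.linalg.norm(x[protein][:, None, :] - x[dna][None, :, :], axis=-1)
        counts += dd < cutoff
    counts /= len(positions_frames)

    res_index = [topology.beads[b].residue_index for b in protein]
    per_residue = pd.Series(counts.sum(axis=1), index=res_index, name="contacts")
    per_residue.index.name = "residue"

    nt_keys = [
        (topology.beads[b].chain_id, topology.beads[b].residue_index) for b in dna
    ]
    per_bead = pd.Series(counts.sum(axis=0),
                         index=pd.MultiIndex.from_tuples(nt_keys,
                                                         names=["chain", "nt"]))
    per_nucleotide = per_bead.groupby(level=["chain", "nt"]).sum()
    kinds = [topology.beads[b].bead_kind.value for b in dna]
    per_kind = pd.Series(counts.sum(axis=0), index=kinds).groupby(level=0).mean()
    per_kind.index.name = "bead_kind"
    return {
        "per_residue": per_residue,
        "per_nucleotide": per_nucleotide,
        "per_dna_bead_kind": per_kind,
    }


def energy_stage_stats(
    breakdowns: list[EnergyBreakdown],
    stage_labels,
    stages=("US", "EC", "IS", "BS"),
) -> pd.DataFrame:
    """Mean +/- SD of the native/non-native electrostatic/LJ decomposition
    per binding stage (energies in eps)."""
    stage_labels = np.asarray(stage_labels)
    comp = pd.DataFrame(
        {
            ("E_Elect", "Native"): [b.native_elect for b in breakdowns],
            ("E_Elect", "Non-native"): [b.nonnative_elect for b in breakdowns],
            ("E_LJ", "Native"): [b.native_LJ for b in breakdowns],
            ("E_LJ", "Non-native"): [b.nonnative_excl for b in breakdowns],
        }
    )
    blocks = {}
    for stage in stages:
        sel = stage_labels == stage
        if sel.sum() < 2:
            logger.warning("stage %s has fewer than 2 frames; column omitted", stage)
            continue
        sub = comp[sel]
        blocks[(stage, "mean")] = sub.mean()
        blocks[(stage, "sd")] = sub.std(ddof=1)
    table = pd.DataFrame(blocks)
    table.index = pd.MultiIndex.from_tuples(table.index, names=["part", "class"])
    table.columns = pd.MultiIndex.from_tuples(table.columns, names=["stage", "stat"])
    return table


# ---------------------------------------------------------------------------
# mean passage time
# ---------------------------------------------------------------------------


@dataclass
class MPTEstimate:
    mean: float
    stderr: float
    n_transitions: int
    n_censored: int
    censor_time: float


def mean_passage_time(
    records: list[FirstPassageRecord], censor_time: float | None = None
) -> MPTEstimate:
    """Mean passage time with censored runs scored at the observation
    horizon (the largest observation time), with its standard error."""
    if not records:
        raise ValueError("no first-passage records")
    if censor_time is None:
        censor_time = max(r.max_steps * r.dt for r in records)
    times = np.array(
        [r.time if not r.censored else censor_time for r in records], float
    )
    n = len(times)
    stderr = float(times.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return MPTEstimate(
        mean=float(times.mean()),
        stderr=stderr,
        n_transitions=int(sum(not r.censored for r in records)),
        n_censored=int(sum(r.censored for r in records)),
        censor_time=float(censor_time),
    )
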