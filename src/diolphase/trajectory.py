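"""Trajectory observables for protein/cosolvent simulation ensembles.

Implements the analysis layer applied to single-chain disordered-protein
simulations with small-molecule cosolvents (alkanediols): radius of gyration,
mean intrachain distances R_ij, residue-residue and residue-cosolvent contact
maps under a heavy-atom distance cutoff, atom-resolved contact maps, radial
distribution functions around side-chain centers of mass, solution mass
density, and replica-level standard errors.

Distances are in Angstrom throughout; boxes are orthorhombic (edge lengths per
frame).  A contact is formed when any heavy atom of one group lies within the
cutoff (default 4.5 Angstrom, inclusive) of any heavy atom of the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Trajectory",
    "ContactMap",
    "RijProfile",
    "RgDistribution",
    "CosolventContactProfile",
    "AtomContactMap",
    "RDFResult",
    "DensityResult",
    "DEFAULT_CUTOFF",
    "DEFAULT_SEPARATION_BINS",
    "minimum_image_distance",
    "radius_of_gyration",
    "intrachain_distances",
    "residue_contact_map",
    "contacts_by_separation",
    "cosolvent_contacts",
    "atomistic_contact_map",
    "rdf_sidechain_com",
    "solution_density",
    "replica_sem",
]

DEFAULT_CUTOFF = 4.5  # Angstrom; heavy-atom contact rule
#: separation bins |i-j| used for binned contact summaries; the last bin is
#: open-ended to capture the long-range (>100) regime.
DEFAULT_SEPARATION_BINS: tuple[tuple[int, int | None], ...] = (
    (1, 10),
    (11, 25),
    (26, 50),
    (51, 100),
    (101, None),
)

# 1 Da / Angstrom^3 in g/cm^3
_DA_PER_A3_TO_G_PER_CM3 = 1.66053906660


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

_TOPOLOGY_COLUMNS = (
    "residue_index",
    "residue_type",
    "atom_name",
    "element",
    "mass",
    "heavy",
    "sidechain",
    "molecule_id",
    "molecule_kind",
)


@dataclass
class Trajectory:
    """In-memory trajectory: per-atom topology table plus per-frame coordinates.

    Parameters
    ----------
    topology
        One row per atom with columns ``residue_index`` (1-based within the
        protein molecule), ``residue_type`` (one-letter code or small-molecule
        label), ``atom_name``, ``element``, ``mass`` (Da), ``heavy`` (bool),
        ``sidechain`` (bool), ``molecule_id`` (int), ``molecule_kind``
        (``protein`` | ``cosolvent`` | ``other``).
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in Angstrom.
    box
        Orthorhombic box edge lengths per frame, shape ``(n_frames, 3)``.
    replica_id
        Identifier used when aggregating independent replicas.
    """

    topology: pd.DataFrame
    coords: np.ndarray
    box: np.ndarray
    replica_id: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.box.shape != (self.coords.shape[0], 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box edge lengths must be positive")
        missing = [c for c in _TOPOLOGY_COLUMNS if c not in self.topology.columns]
        if missing:
            raise ValueError(f"topology missing columns: {missing}")
        if len(self.topology) != self.coords.shape[1]:
            raise ValueError("topology row count does not match coords atoms")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    # -- selections ---------------------------------------------------------
    def index_where(self, **conditions) -> np.ndarray:
        """Atom indices where every topology column equals the given value."""
        mask = np.ones(len(self.topology), dtype=bool)
        for col, val in conditions.items():
            mask &= (self.topology[col] == val).to_numpy()
        return np.flatnonzero(mask)

    def protein_heavy(self) -> np.ndarray:
        return np.flatnonzero(
            (self.topology["molecule_kind"] == "protein").to_numpy()
            & self.topology["heavy"].to_numpy()
        )

    def cosolvent_heavy(self) -> np.ndarray:
        return np.flatnonzero(
            (self.topology["molecule_kind"] == "cosolvent").to_numpy()
            & self.topology["heavy"].to_numpy()
        )

    def n_residues(self) -> int:
        prot = self.topology[self.topology["molecule_kind"] == "protein"]
        if prot.empty:
            return 0
        return int(prot["residue_index"].max())

    def translated(self, shift: Sequence[float]) -> "Trajectory":
        """Copy with every frame rigidly translated (used in invariance tests)."""
        return replace(self, coords=self.coords + np.asarray(shift, dtype=float))


@dataclass
class ContactMap:
    frequency: np.ndarray  # (N, N), diagonal NaN
    frame_count: int
    cutoff: float

    @property
    def n_residues(self) -> int:
        return self.frequency.shape[0]


@dataclass
class RijProfile:
    mean_distance: np.ndarray           # (N, N) mean over frames (and replicas)
    separations: np.ndarray             # 1..N-1
    profile: np.ndarray                 # mean R over pairs at each separation
    profile_sem: np.ndarray             # SEM over replicas (NaN if 1 replica)
    per_replica: np.ndarray             # (n_replicas, N-1)


@dataclass
class RgDistribution:
    per_frame: np.ndarray
    mean: float
    sem: float  # over replicas; NaN for a single replica
    per_replica_mean: np.ndarray


@dataclass
class CosolventContactProfile:
    per_residue: np.ndarray             # mean molecules in contact per frame
    residue_types: np.ndarray           # residue type per residue index
    by_type: pd.DataFrame               # columns: residue_type, mean, sd, n


@dataclass
class AtomContactMap:
    matrix: np.ndarray                  # (n_protein_atom_names, n_cosolvent_atom_names)
    row_labels: list[str]
    col_labels: list[str]
    row_marginal: np.ndarray
    col_marginal: np.ndarray
    residue_type: str
    n_instances: int


@dataclass
class RDFResult:
    bin_edges: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    bulk_density: float
    n_reference_sites: int
    n_targets: int
    reference: str
    target: str = "cosolvent heavy atoms"

    @property
    def r_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class DensityResult:
    per_frame: np.ndarray               # g/cm^3
    mean: float
    sem: float


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def minimum_image_distance(a, b, box) -> np.ndarray | float:
    """Minimum-image distance(s) between points under periodic boundaries.

    ``a`` and ``b`` broadcast against each other over the leading axes.
    ``box`` is either an edge-length triple (orthorhombic fast path: per-axis
    wrap) or a 3x3 matrix of box vectors (general triclinic: shortest distance
    over the 27 neighbor images).  Raises on zero/negative box edges.
    """
    box = np.asarray(box, dtype=float)
    delta = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if box.shape == (3, 3):
        if np.linalg.det(box) <= 0:
            raise ValueError("box vectors must span a positive volume")
        shifts = np.array(
            [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
        ) @ box
        # wrap into the primary cell first so 27 images suffice
        frac = delta @ np.linalg.inv(box)
        delta = (frac - np.round(frac)) @ box
        cand = delta[..., None, :] - shifts
        d = np.sqrt(np.sum(cand * cand, axis=-1)).min(axis=-1)
    else:
        if np.any(box <= 0):
            raise ValueError("box edge lengths must be positive")
        delta = delta - box * np.round(delta / box)
        d = np.sqrt(np.sum(delta * delta, axis=-1))
    return float(d) if d.ndim == 0 else d


def _min_image_cdist(x: np.ndarray, y: np.ndarray, box: np.ndarray) -> np.ndarray:
    """All-pairs minimum-image distances, shape (len(x), len(y))."""
    delta = x[:, None, :] - y[None, :, :]
    delta -= box * np.round(delta / box)
    return np.sqrt(np.einsum("ijk,ijk->ij", delta, delta))


def _validate_cutoff(cutoff: float, box: np.ndarray) -> None:
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    half_min_edge = 0.5 * float(np.min(box))
    if cutoff > half_min_edge:
        raise ValueError(
            f"cutoff {cutoff} exceeds half the minimum box edge "
            f"({half_min_edge:.3f}); minimum-image convention invalid"
        )


def _pairs_within(
    x: np.ndarray, y: np.ndarray, box: np.ndarray, cutoff: float
) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i into x, j into y) with min-image distance <= cutoff.

    Grid/tree neighbor search over the periodic box (coordinates wrapped into
    the primary cell first).  Inclusive at the cutoff boundary.
    """
    if len(x) == 0 or len(y) == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    xw = np.mod(x, box)
    yw = np.mod(y, box)
    # cKDTree requires coords strictly inside [0, L); fold exact-edge hits
    xw[xw >= box] = 0.0
    yw[yw >= box] = 0.0
    tree_y = cKDTree(yw, boxsize=box)
    tree_x = cKDTree(xw, boxsize=box)
    pairs = tree_x.query_ball_tree(tree_y, r=cutoff)
    ii = np.fromiter(
        (i for i, js in enumerate(pairs) for _ in js), dtype=int
    )
    jj = np.fromiter((j for js in pairs for j in js), dtype=int)
    return ii, jj


def _self_pairs_within(
    x: np.ndarray, box: np.ndarray, cutoff: float
) -> np.ndarray:
    """Unique unordered index pairs within x at min-image distance <= cutoff."""
    if len(x) < 2:
        return np.empty((0, 2), dtype=int)
    xw = np.mod(x, box)
    xw[xw >= box] = 0.0
    tree = cKDTree(xw, boxsize=box)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    return pairs


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def radius_of_gyration(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    mass_weighted: bool = True,
) -> RgDistribution:
    """Per-frame radius of gyration of the selected atoms.

    Rg = sqrt( sum_k m_k |x_k - x_com|^2 / sum_k m_k ); the unweighted option
    sets all masses to 1.  Defaults to all protein atoms.
    """
    if selection is None:
        selection = np.flatnonzero(
            (traj.topology["molecule_kind"] == "protein").to_numpy()
        )
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty atom selection")
    masses = traj.topology["mass"].to_numpy()[selection]
    if not mass_weighted:
        masses = np.ones_like(masses)
    x = traj.coords[:, selection, :]
    com = np.average(x, axis=1, weights=masses)
    dx = x - com[:, None, :]
    rg2 = np.average(np.sum(dx * dx, axis=2), axis=1, weights=masses)
    per_frame = np.sqrt(rg2)
    return RgDistribution(
        per_frame=per_frame,
        mean=float(per_frame.mean()),
        sem=float("nan"),
        per_replica_mean=np.array([per_frame.mean()]),
    )


def rg_over_replicas(replicas: Sequence[Trajectory], **kwargs) -> RgDistribution:
    """Rg distribution pooled over replicas with replica-level SEM."""
    dists = [radius_of_gyration(t, **kwargs) for t in replicas]
    per_frame = np.concatenate([d.per_frame for d in dists])
    means = np.array([d.mean for d in dists])
    mean, sem = replica_sem(list(means))
    return RgDistribution(
        per_frame=per_frame,
        mean=float(mean),
        sem=float(sem) if np.ndim(sem) == 0 else float("nan"),
        per_replica_mean=means,
    )


def _backbone_indices(traj: Trajectory) -> np.ndarray:
    prot = (traj.topology["molecule_kind"] == "protein").to_numpy()
    bb = prot & ~traj.topology["sidechain"].to_numpy()
    idx = np.flatnonzero(bb)
    order = np.argsort(traj.topology["residue_index"].to_numpy()[idx], kind="stable")
    return idx[order]


def _residue_com_coords(traj: Trajectory) -> np.ndarray:
    """Per-frame residue center-of-mass coordinates, shape (F, N, 3)."""
    prot = traj.topology[traj.topology["molecule_kind"] == "protein"]
    n_res = int(prot["residue_index"].max())
    out = np.zeros((traj.n_frames, n_res, 3))
    for r in range(1, n_res + 1):
        idx = np.flatnonzero(
            (traj.topology["molecule_kind"] == "protein").to_numpy()
            & (traj.topology["residue_index"] == r).to_numpy()
        )
        m = traj.topology["mass"].to_numpy()[idx]
        out[:, r - 1, :] = np.average(traj.coords[:, idx, :], axis=1, weights=m)
    return out


def intrachain_distances(
    replicas: Trajectory | Sequence[Trajectory],
    site: str = "backbone",
    chunk: int = 512,
) -> RijProfile:
    """Mean intrachain distances R_ij and the separation profile r(|i-j|).

    ``site`` selects the per-residue reference point: ``backbone`` (the
    backbone atom) or ``com`` (residue center of mass).  With multiple
    replicas, the separation profile carries the SEM over replicas; with a
    single replica the SEM is reported as NaN (not zero).
    """
    if isinstance(replicas, Trajectory):
        replicas = [replicas]
    if site not in ("backbone", "com"):
        raise ValueError("site must be 'backbone' or 'com'")

    per_rep_matrix = []
    for traj in replicas:
        if site == "backbone":
            idx = _backbone_indices(traj)
            if len(idx) < 2:
                raise ValueError("need at least 2 residues")
            pts = traj.coords[:, idx, :]
        else:
            pts = _residue_com_coords(traj)
            if pts.shape[1] < 2:
                raise ValueError("need at least 2 residues")
        n_res = pts.shape[1]
        acc = np.zeros((n_res, n_res))
        for start in range(0, pts.shape[0], chunk):
            block = pts[start : start + chunk]
            delta = block[:, :, None, :] - block[:, None, :, :]
            acc += np.sqrt(np.einsum("fijk,fijk->fij", delta, delta)).sum(axis=0)
        per_rep_matrix.append(acc / pts.shape[0])

    n_res = per_rep_matrix[0].shape[0]
    seps = np.arange(1, n_res)
    per_replica = np.empty((len(per_rep_matrix), n_res - 1))
    for k, mat in enumerate(per_rep_matrix):
        for s in seps:
            per_replica[k, s - 1] = np.mean(np.diagonal(mat, offset=s))
    mean_matrix = np.mean(per_rep_matrix, axis=0)
    np.fill_diagonal(mean_matrix, np.nan)
    profile, sem = replica_sem([per_replica[k] for k in range(per_replica.shape[0])])
    return RijProfile(
        mean_distance=mean_matrix,
        separations=seps,
        profile=np.asarray(profile),
        profile_sem=np.asarray(sem),
        per_replica=per_replica,
    )


def residue_contact_map(
    traj: Trajectory, cutoff: float = DEFAULT_CUTOFF
) -> ContactMap:
    """Residue-residue contact frequency map under the heavy-atom cutoff rule.

    f_ij is the fraction of frames in which any heavy atom of residue i lies
    within ``cutoff`` (inclusive) of any heavy atom of residue j, computed with
    a periodic grid neighbor search.  The diagonal is masked with NaN.
    """
    _validate_cutoff(cutoff, traj.box)
    heavy = traj.protein_heavy()
    if heavy.size == 0:
        raise ValueError("no protein heavy atoms present")
    res_of_atom = traj.topology["residue_index"].to_numpy()[heavy]
    n_res = traj.n_residues()
    counts = np.zeros((n_res, n_res))
    for f in range(traj.n_frames):
        pairs = _self_pairs_within(traj.coords[f, heavy, :], traj.box[f], cutoff)
        if len(pairs) == 0:
            continue
        ri = res_of_atom[pairs[:, 0]]
        rj = res_of_atom[pairs[:, 1]]
        keep = ri != rj
        if not np.any(keep):
            continue
        lo = np.minimum(ri[keep], rj[keep]) - 1
        hi = np.maximum(ri[keep], rj[keep]) - 1
        uniq = np.unique(lo * n_res + hi)
        counts[uniq // n_res, uniq % n_res] += 1.0
    freq = counts / traj.n_frames
    freq = freq + freq.T
    np.fill_diagonal(freq, np.nan)
    return ContactMap(frequency=freq, frame_count=traj.n_frames, cutoff=cutoff)


def contacts_by_separation(
    cmap: ContactMap,
    bins: Sequence[tuple[int, int | None]] = DEFAULT_SEPARATION_BINS,
) -> pd.DataFrame:
    """Mean contact frequency over residue pairs binned by separation |i-j|.

    Returns a table with columns ``bin``, ``lo``, ``hi``, ``mean``, ``n_pairs``;
    a bin containing no pairs is flagged ``empty=True`` with NaN mean.
    """
    n = cmap.n_residues
    i, j = np.triu_indices(n, k=1)
    sep = j - i
    f = cmap.frequency[i, j]
    rows = []
    for lo, hi in bins:
        if lo < 1:
            raise ValueError("separation bins start at 1")
        upper = hi if hi is not None else n - 1
        if hi is not None and hi < lo:
            raise ValueError("bin upper bound below lower bound")
        mask = (sep >= lo) & (sep <= upper)
        label = f"{lo}-{hi}" if hi is not None else f">{lo - 1}"
        rows.append(
            {
                "bin": label,
                "lo": lo,
                "hi": hi,
                "mean": float(np.mean(f[mask])) if mask.any() else float("nan"),
                "n_pairs": int(mask.sum()),
                "empty": not bool(mask.any()),
            }
        )
    return pd.DataFrame(rows)


def cosolvent_contacts(
    traj: Trajectory, cutoff: float = DEFAULT_CUTOFF
) -> CosolventContactProfile:
    """Mean number of cosolvent molecules in contact with each residue per frame.

    A molecule is in contact with a residue when any of its heavy atoms is
    within ``cutoff`` of any heavy atom of the residue; molecules (not atom
    pairs) are counted.  The per-residue profile is also binned by residue
    type (mean, sd, n over residues of that type).
    """
    _validate_cutoff(cutoff, traj.box)
    heavy_p = traj.protein_heavy()
    heavy_c = traj.cosolvent_heavy()
    n_res = traj.n_residues()
    res_of_atom = traj.topology["residue_index"].to_numpy()[heavy_p]
    mol_of_atom = traj.topology["molecule_id"].to_numpy()[heavy_c]
    totals = np.zeros(n_res)
    for f in range(traj.n_frames):
        if heavy_c.size == 0:
            break
        ii, jj = _pairs_within(
            traj.coords[f, heavy_p, :], traj.coords[f, heavy_c, :], traj.box[f], cutoff
        )
        if ii.size:
            pairs = np.unique(
                np.stack([res_of_atom[ii], mol_of_atom[jj]], axis=1), axis=0
            )
            np.add.at(totals, pairs[:, 0] - 1, 1.0)
    per_residue = totals / traj.n_frames

    prot = traj.topology[traj.topology["molecule_kind"] == "protein"]
    rtypes = (
        prot.drop_duplicates("residue_index")
        .sort_values("residue_index")["residue_type"]
        .to_numpy()
    )
    df = pd.DataFrame({"residue_type": rtypes, "contacts": per_residue})
    by_type = (
        df.groupby("residue_type")["contacts"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return CosolventContactProfile(
        per_residue=per_residue, residue_types=rtypes, by_type=by_type
    )


def atomistic_contact_map(
    traj: Trajectory, residue_type: str, cutoff: float = DEFAULT_CUTOFF
) -> AtomContactMap:
    """Atom-resolved contacts between one residue type's side chain and cosolvent.

    The matrix holds the mean number of contacts per frame per residue
    instance between each named side-chain heavy atom and each named cosolvent
    heavy atom; marginals are row/column sums.
    """
    _validate_cutoff(cutoff, traj.box)
    top = traj.topology
    sel_p = np.flatnonzero(
        (top["molecule_kind"] == "protein").to_numpy()
        & (top["residue_type"] == residue_type).to_numpy()
        & top["sidechain"].to_numpy()
        & top["heavy"].to_numpy()
    )
    if sel_p.size == 0:
        available = sorted(
            top.loc[top["molecule_kind"] == "protein", "residue_type"].unique()
        )
        raise ValueError(
            f"residue type {residue_type!r} absent; available: {available}"
        )
    sel_c = traj.cosolvent_heavy()
    row_labels = sorted(top["atom_name"].to_numpy()[sel_p].tolist())
    row_labels = list(dict.fromkeys(row_labels))
    col_labels = (
        list(dict.fromkeys(sorted(top["atom_name"].to_numpy()[sel_c].tolist())))
        if sel_c.size
        else []
    )
    n_inst = top.loc[
        (top["molecule_kind"] == "protein") & (top["residue_type"] == residue_type),
        "residue_index",
    ].nunique()
    mat = np.zeros((len(row_labels), max(len(col_labels), 1)))
    if sel_c.size:
        row_of = {name: k for k, name in enumerate(row_labels)}
        col_of = {name: k for k, name in enumerate(col_labels)}
        p_names = top["atom_name"].to_numpy()[sel_p]
        c_names = top["atom_name"].to_numpy()[sel_c]
        for f in range(traj.n_frames):
            ii, jj = _pairs_within(
                traj.coords[f, sel_p, :], traj.coords[f, sel_c, :], traj.box[f], cutoff
            )
            for i, j in zip(ii, jj):
                mat[row_of[p_names[i]], col_of[c_names[j]]] += 1.0
        mat /= traj.n_frames * n_inst
    if not col_labels:
        mat = np.zeros((len(row_labels), 0))
    return AtomContactMap(
        matrix=mat,
        row_labels=row_labels,
        col_labels=col_labels,
        row_marginal=mat.sum(axis=1),
        col_marginal=mat.sum(axis=0),
        residue_type=residue_type,
        n_instances=int(n_inst),
    )


def rdf_sidechain_com(
    traj: Trajectory,
    residue_type: str,
    r_max: float = 12.0,
    dr: float = 0.1,
) -> RDFResult:
    """g(r) between side-chain heavy-atom COMs of a residue type and cosolvent.

    Reference sites are the per-instance centers of mass of side-chain heavy
    atoms of ``residue_type``; targets are all cosolvent heavy atoms.  The
    shell normalisation uses the bulk target density N_target / V_box and the
    bin midpoint: g = <count in shell> / (4 pi r_mid^2 dr rho) per reference
    site per frame.
    """
    if dr <= 0:
        raise ValueError("dr must be positive")
    half_min_edge = 0.5 * float(np.min(traj.box))
    if r_max > half_min_edge:
        raise ValueError(
            f"r_max {r_max} exceeds half the minimum box edge ({half_min_edge:.3f}); "
            "minimum-image convention invalid"
        )
    top = traj.topology
    sel_c = traj.cosolvent_heavy()
    inst = top.loc[
        (top["molecule_kind"] == "protein")
        & (top["residue_type"] == residue_type)
        & top["sidechain"]
        & top["heavy"]
    ]
    if inst.empty:
        available = sorted(
            top.loc[top["molecule_kind"] == "protein", "residue_type"].unique()
        )
        raise ValueError(
            f"residue type {residue_type!r} has no side-chain heavy atoms; "
            f"available: {available}"
        )
    groups = [np.asarray(g.index) for _, g in inst.groupby("residue_index")]
    edges = np.arange(0.0, r_max + 0.5 * dr, dr)
    counts = np.zeros(len(edges) - 1)
    masses = top["mass"].to_numpy()
    n_frames = traj.n_frames
    vol_mean = 0.0
    for f in range(n_frames):
        box = traj.box[f]
        vol_mean += float(np.prod(box)) / n_frames
        refs = np.stack(
            [
                np.average(traj.coords[f, idx, :], axis=0, weights=masses[idx])
                for idx in groups
            ]
        )
        if sel_c.size == 0:
            continue
        d = _min_image_cdist(refs, traj.coords[f, sel_c, :], box).ravel()
        counts += np.histogram(d[d <= r_max], bins=edges)[0]
    rho = (sel_c.size / vol_mean) if sel_c.size else 0.0
    r_mid = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * np.pi * r_mid**2 * dr
    norm = len(groups) * n_frames * shell * rho
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(norm > 0, counts / np.where(norm > 0, norm, 1.0), 0.0)
    return RDFResult(
        bin_edges=edges,
        g=g,
        counts=counts,
        bulk_density=rho,
        n_reference_sites=len(groups),
        n_targets=int(sel_c.size),
        reference=f"sidechain COM of {residue_type}",
    )


def solution_density(traj: Trajectory) -> DensityResult:
    """Mass density of the box in g/cm^3, per frame with mean and SEM."""
    masses = traj.topology["mass"].to_numpy(dtype=float)
    if np.any(~np.isfinite(masses)):
        raise ValueError("topology masses missing or non-finite")
    total_mass = masses.sum()
    vol = np.prod(traj.box, axis=1)
    per_frame = total_mass / vol * _DA_PER_A3_TO_G_PER_CM3
    n = len(per_frame)
    sem = float(per_frame.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return DensityResult(per_frame=per_frame, mean=float(per_frame.mean()), sem=sem)


def replica_sem(
    per_replica_values: Sequence,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Elementwise mean and standard error over independent replicas.

    SEM = sd / sqrt(n) with ddof=1 for n >= 2; for a single replica the SEM is
    NaN (explicitly unavailable, never zero).  All replicas must share a shape.
    """
    if len(per_replica_values) == 0:
        raise ValueError("need at least one replica")
    arrays = [np.asarray(v, dtype=float) for v in per_replica_values]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("replica value shapes differ")
    stack = np.stack(arrays)
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    if n >= 2:
        sem = stack.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.full(shape, np.nan) if shape else float("nan")
    if mean.ndim == 0:
        return float(mean), float(sem) if np.ndim(sem) == 0 else sem
    return mean, sem
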