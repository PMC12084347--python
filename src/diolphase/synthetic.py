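"""Synthetic ground-truth generators for every pipeline input.

Each generator is a pure function of its spec and seed and emulates one class
of raw data consumed downstream:

* disordered-polymer chain ensembles with tunable compaction (freely jointed
  chain at zero confinement), standing in for single-chain simulations of a
  low-complexity domain;
* diffusing diol-like cosolvent boxes with tunable surface adsorption;
* per-residue chemical-shift-perturbation datasets where a shared per-residue
  pattern is scaled by a per-compound potency, mirroring the observation that
  different alkanediols induce the same CSP pattern to different extents;
* two-state van't Hoff thermal melts read out as molar residue ellipticity;
* octanol/water partition equilibria quantified through NMR-style integrals;
* fluorescence droplet images with known bright-area fraction and count.

No force-field energetics or dynamics are simulated: frames are i.i.d. draws,
which is exactly what the ensemble observables need for testable closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import disk as _disk
from skimage.measure import label as _label

from .trajectory import Trajectory

__all__ = [
    "ChainSpec",
    "CosolventSpec",
    "CSPPattern",
    "MeltSpec",
    "PartitionSpec",
    "ImageSpec",
    "FUS_LC_COMPOSITION",
    "gen_chain_ensemble",
    "gen_cosolvent_box",
    "gen_csp_dataset",
    "gen_melt_curve",
    "gen_partition_measurement",
    "gen_droplet_image",
    "random_lc_sequence",
]

GAS_CONSTANT_KJ = 8.31446261815324e-3  # kJ/(mol K)

#: Residue-type weights loosely matching a G/S/Q/Y-rich low-complexity domain,
#: so that residue-type binning downstream is exercised on a realistic alphabet.
FUS_LC_COMPOSITION: Mapping[str, float] = {
    "G": 0.24,
    "S": 0.26,
    "Q": 0.16,
    "Y": 0.15,
    "T": 0.08,
    "P": 0.06,
    "A": 0.05,
}


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{field_name}: {msg}")


# ---------------------------------------------------------------------------
# chain + cosolvent ensembles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainSpec:
    """Freely-jointed-chain ensemble spec for a disordered protein stand-in.

    ``confinement_strength`` = 0 gives an ideal freely jointed chain (i.i.d.
    frames); > 0 biases each step back toward the walk origin, producing
    compact, contact-rich ensembles while keeping bonds at exactly
    ``bond_length``.
    """

    n_residues: int = 163
    bond_length: float = 3.8  # Angstrom, Calpha-Calpha-like
    sidechain_atoms_per_residue: int = 2
    confinement_strength: float = 0.0
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_residues >= 2, "n_residues", "must be >= 2")
        _require(self.bond_length > 0, "bond_length", "must be > 0")
        _require(self.n_frames >= 1, "n_frames", "must be >= 1")
        _require(
            self.sidechain_atoms_per_residue >= 0,
            "sidechain_atoms_per_residue",
            "must be >= 0",
        )
        _require(
            self.confinement_strength >= 0, "confinement_strength", "must be >= 0"
        )


@dataclass(frozen=True)
class CosolventSpec:
    """Diol-like cosolvent box spec.

    ``adsorption_bias`` = 0 places molecule centers uniformly over the box;
    > 0 re-places a fraction bias/(1+bias) of them within ``adsorption_shell``
    of the nearest protein atom, emulating surface enrichment of the more
    amphiphilic diols.
    """

    n_molecules: int = 330
    heavy_atoms_per_molecule: int = 8  # hexanediol-like: 6 C + 2 O
    box_edge: float = 120.0  # Angstrom
    adsorption_bias: float = 0.0
    adsorption_shell: float = 6.0  # Angstrom
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_molecules >= 0, "n_molecules", "must be >= 0")
        _require(
            self.heavy_atoms_per_molecule >= 1,
            "heavy_atoms_per_molecule",
            "must be >= 1",
        )
        _require(
            self.box_edge > 2 * self.adsorption_shell,
            "box_edge",
            "must exceed twice the adsorption shell",
        )
        _require(self.adsorption_bias >= 0, "adsorption_bias", "must be >= 0")
        _require(self.adsorption_shell > 0, "adsorption_shell", "must be > 0")

    @property
    def adsorbed_fraction(self) -> float:
        """Fraction of molecules re-placed into the adsorption shell."""
        return self.adsorption_bias / (1.0 + self.adsorption_bias)


def random_lc_sequence(n_residues: int, rng: np.random.Generator) -> np.ndarray:
    types = np.array(list(FUS_LC_COMPOSITION))
    probs = np.array(list(FUS_LC_COMPOSITION.values()), dtype=float)
    probs /= probs.sum()
    return rng.choice(types, size=n_residues, p=probs)


def _random_unit(rng: np.random.Generator, shape) -> np.ndarray:
    v = rng.normal(size=shape + (3,))
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def gen_chain_ensemble(spec: ChainSpec) -> Trajectory:
    """Generate an i.i.d. ensemble of pseudo-atom chains.

    Each residue carries one backbone pseudo-heavy-atom on the chain walk
    (consecutive backbone atoms exactly ``bond_length`` apart) plus
    ``sidechain_atoms_per_residue`` pseudo-heavy-atoms offset by at most
    ``bond_length``.  Frames are independent; at zero confinement the walk is
    an ideal freely jointed chain.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n, b, nf = spec.n_residues, spec.bond_length, spec.n_frames
    c = spec.confinement_strength

    backbone = np.zeros((nf, n, 3))
    pos = np.zeros((nf, 3))
    for i in range(1, n):
        step = _random_unit(rng, (nf,))
        if c > 0:
            r = np.linalg.norm(pos, axis=1, keepdims=True)
            toward_origin = np.where(r > 0, -pos / np.where(r > 0, r, 1.0), 0.0)
            step = step + c * toward_origin
            step /= np.linalg.norm(step, axis=1, keepdims=True)
        pos = pos + b * step
        backbone[:, i, :] = pos

    nsc = spec.sidechain_atoms_per_residue
    coords = np.empty((nf, n * (1 + nsc), 3))
    coords[:, ::1 + nsc, :] = backbone
    if nsc:
        u = _random_unit(rng, (nf, n, nsc))
        radius = b * rng.random((nf, n, nsc, 1)) ** (1.0 / 3.0)
        sc = backbone[:, :, None, :] + radius * u
        for k in range(nsc):
            coords[:, 1 + k :: 1 + nsc, :] = sc[:, :, k, :]

    # generous box; re-centered so the whole chain sits inside it every frame
    edge = 2.0 * n * b
    box = np.full((nf, 3), edge)
    com = coords.mean(axis=1, keepdims=True)
    coords = coords - com + edge / 2.0

    rtypes = random_lc_sequence(n, np.random.default_rng(spec.seed + 1))
    rows = []
    for r in range(n):
        rows.append(
            dict(
                residue_index=r + 1,
                residue_type=rtypes[r],
                atom_name="BB",
                element="C",
                mass=56.0,  # backbone heavy-atom lump (N + CA + C + O scale)
                heavy=True,
                sidechain=False,
                molecule_id=0,
                molecule_kind="protein",
            )
        )
        for k in range(nsc):
            rows.append(
                dict(
                    residue_index=r + 1,
                    residue_type=rtypes[r],
                    atom_name=f"S{k + 1}",
                    element="C",
                    mass=13.0,
                    heavy=True,
                    sidechain=True,
                    molecule_id=0,
                    molecule_kind="protein",
                )
            )
    topology = pd.DataFrame(rows)
    return Trajectory(topology=topology, coords=coords, box=box)


def gen_cosolvent_box(spec: CosolventSpec, chain: Trajectory) -> Trajectory:
    """Append diol-like cosolvent molecules to every frame of a chain ensemble.

    The chain is re-centered into a cubic box of edge ``box_edge``; it is an
    error if any chain atom then falls outside.  Each cosolvent molecule is a
    rigid small cluster of heavy atoms (spread ~1.5 Angstrom) placed uniformly
    over the box, except for the adsorbed fraction, which is placed within
    ``adsorption_shell`` of a randomly chosen protein atom.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.box_edge
    nf = chain.n_frames

    com = chain.coords.mean(axis=1, keepdims=True)
    prot_coords = chain.coords - com + L / 2.0
    if np.any(prot_coords < 0) or np.any(prot_coords > L):
        raise ValueError("chain does not fit inside the cosolvent box")

    nmol = spec.n_molecules
    natm = spec.heavy_atoms_per_molecule
    cluster_radius = 1.5
    all_coords = [prot_coords]
    if nmol:
        n_ads = int(round(spec.adsorbed_fraction * nmol))
        centers = np.empty((nf, nmol, 3))
        centers[:, :, :] = rng.random((nf, nmol, 3)) * L
        if n_ads:
            atom_pick = rng.integers(0, prot_coords.shape[1], size=(nf, n_ads))
            direction = _random_unit(rng, (nf, n_ads))
            dist = rng.random((nf, n_ads, 1)) * spec.adsorption_shell
            anchors = np.take_along_axis(
                prot_coords, atom_pick[:, :, None], axis=1
            )
            centers[:, :n_ads, :] = np.mod(anchors + dist * direction, L)
        offsets = cluster_radius * rng.random((nf, nmol, natm, 1)) ** (1 / 3.0) * \
            _random_unit(rng, (nf, nmol, natm))
        atoms = np.mod(centers[:, :, None, :] + offsets, L)
        all_coords.append(atoms.reshape(nf, nmol * natm, 3))

    coords = np.concatenate(all_coords, axis=1)
    box = np.full((nf, 3), L)

    rows = []
    n_oxygen = min(2, natm)
    for m in range(nmol):
        for a in range(natm):
            is_o = a >= natm - n_oxygen
            rows.append(
                dict(
                    residue_index=0,
                    residue_type="HD6",
                    atom_name=f"O{a}" if is_o else f"C{a}",
                    element="O" if is_o else "C",
                    mass=15.999 if is_o else 12.011,
                    heavy=True,
                    sidechain=False,
                    molecule_id=m + 1,
                    molecule_kind="cosolvent",
                )
            )
    topology = pd.concat(
        [chain.topology, pd.DataFrame(rows)], ignore_index=True
    ) if rows else chain.topology.copy().reset_index(drop=True)
    return Trajectory(
        topology=topology, coords=coords, box=box, replica_id=chain.replica_id
    )


# ---------------------------------------------------------------------------
# NMR CSP dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CSPPattern:
    """Shared per-residue CSP sensitivity pattern scaled per compound.

    ``pattern`` holds dimensionless per-residue sensitivities p_i; each
    condition c perturbs residue i by potency * p_i (in ppm) plus Gaussian
    noise.  ``csat_map`` records each condition's true dilute-phase protein
    concentration, linked (affinely, by construction of the caller) to the
    potency so that slope-versus-Csat correlations have a known sign.
    """

    pattern: tuple[float, ...]
    potencies: Mapping[str, float]
    noise_sd: float = 0.0  # ppm
    csat_map: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(len(self.pattern) > 0, "pattern", "must be non-empty")
        if self.csat_map:
            _require(
                set(self.csat_map) == set(self.potencies),
                "csat_map",
                "conditions must match potencies",
            )


def gen_csp_dataset(
    spec: CSPPattern,
    sequence: str | Sequence[str],
    nucleus: str = "15N",
    spectrometer_mhz: float = 850.0,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame]:
    """Reference peak list, per-condition peak lists, and the truth table.

    Condition shifts are shift_ref + potency * p_i + noise for the chosen
    nucleus.  Returns ``(reference, {condition: peak_list}, truth)`` where the
    truth table has columns ``condition``, ``potency``, ``csat``.
    """
    seq = list(sequence)
    if len(seq) != len(spec.pattern):
        raise ValueError(
            f"pattern length {len(spec.pattern)} != sequence length {len(seq)}"
        )
    rng = np.random.default_rng(spec.seed)
    n = len(seq)
    base_shift = {"15N": 118.0, "1H": 8.2, "13C": 176.0}[nucleus]
    spread = {"15N": 6.0, "1H": 0.4, "13C": 2.0}[nucleus]
    ref_shifts = base_shift + spread * rng.standard_normal(n)
    ref_intensity = np.abs(1.0 + 0.2 * rng.standard_normal(n)) + 0.1

    def _peaklist(shifts, intensity, condition):
        return pd.DataFrame(
            {
                "residue_index": np.arange(1, n + 1),
                "residue_type": seq,
                "nucleus": nucleus,
                "shift_ppm": shifts,
                "intensity": intensity,
                "condition": condition,
                "spectrometer_mhz": spectrometer_mhz,
            }
        )

    reference = _peaklist(ref_shifts, ref_intensity, "reference")
    pattern = np.asarray(spec.pattern, dtype=float)
    conditions: dict[str, pd.DataFrame] = {}
    for name, lam in spec.potencies.items():
        noise = spec.noise_sd * rng.standard_normal(n) if spec.noise_sd else 0.0
        shifts = ref_shifts + lam * pattern + noise
        intensity = ref_intensity * np.abs(
            1.0 - 0.05 * lam + 0.02 * rng.standard_normal(n)
        )
        conditions[name] = _peaklist(shifts, intensity, name)
    truth = pd.DataFrame(
        {
            "condition": list(spec.potencies),
            "potency": [spec.potencies[c] for c in spec.potencies],
            "csat": [spec.csat_map.get(c, np.nan) for c in spec.potencies],
        }
    )
    return reference, conditions, truth


# ---------------------------------------------------------------------------
# thermal melts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeltSpec:
    """Two-state van't Hoff melt read out as MRE at 222 nm.

    theta(T) = [theta_N(T) + theta_U(T) K(T)] / [1 + K(T)],
    K(T) = exp[-(dH/R)(1/T - 1/Tm)], with linear folded/unfolded baselines
    (intercept in MRE units at 0 degC, slope per degC).
    """

    tm_true: float = 348.15  # K (75 degC)
    dh_vant_hoff: float = 400.0  # kJ/mol
    folded_baseline: tuple[float, float] = (-11000.0, 10.0)
    unfolded_baseline: tuple[float, float] = (-2500.0, 5.0)
    t_range: tuple[float, float] = (25.0, 90.0)  # degC
    noise_sd: float = 0.0  # MRE units
    n_points: int = 131
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.t_range
        if hi <= lo:
            raise ValueError("t_range: upper bound must exceed lower bound")
        _require(self.dh_vant_hoff > 0, "dh_vant_hoff", "must be > 0")
        _require(
            lo + 273.15 <= self.tm_true <= hi + 273.15,
            "tm_true",
            "must lie within t_range",
        )
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.n_points >= 10, "n_points", "must be >= 10")


def two_state_signal(
    t_celsius: np.ndarray,
    tm_k: float,
    dh_kj: float,
    folded: tuple[float, float],
    unfolded: tuple[float, float],
) -> np.ndarray:
    """Noise-free two-state melt signal at the given temperatures (degC)."""
    t_c = np.asarray(t_celsius, dtype=float)
    t_k = t_c + 273.15
    k_eq = np.exp(-(dh_kj / GAS_CONSTANT_KJ) * (1.0 / t_k - 1.0 / tm_k))
    theta_n = folded[0] + folded[1] * t_c
    theta_u = unfolded[0] + unfolded[1] * t_c
    return (theta_n + theta_u * k_eq) / (1.0 + k_eq)


def gen_melt_curve(spec: MeltSpec) -> pd.DataFrame:
    """Melting curve table with columns temperature_C and mre."""
    rng = np.random.default_rng(spec.seed)
    t = np.linspace(spec.t_range[0], spec.t_range[1], spec.n_points)
    theta = two_state_signal(
        t, spec.tm_true, spec.dh_vant_hoff, spec.folded_baseline, spec.unfolded_baseline
    )
    if spec.noise_sd:
        theta = theta + spec.noise_sd * rng.standard_normal(t.shape)
    return pd.DataFrame({"temperature_C": t, "mre": theta})


# ---------------------------------------------------------------------------
# octanol/water partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionSpec:
    """Octanol/water partition equilibrium with NMR-style quantification.

    Mass balance: c_w = n_tot / (V_w + P V_o), c_o = P c_w with
    P = 10**logp_true.  Integrals are proportional to concentration x protons
    with optional multiplicative Gaussian noise; a reference standard of known
    concentration provides the scale.
    """

    logp_true: float = 0.0
    total_amount: float = 1e-4  # mol
    v_octanol: float = 1e-3  # L
    v_water: float = 1e-3  # L
    protons_per_molecule: int = 12
    reference_concentration: float = 1e-3  # mol/L
    reference_protons: int = 9
    noise_sd: float = 0.0  # relative fraction
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.v_octanol > 0, "v_octanol", "must be > 0")
        _require(self.v_water > 0, "v_water", "must be > 0")
        _require(self.total_amount > 0, "total_amount", "must be > 0")
        _require(self.protons_per_molecule > 0, "protons_per_molecule", "must be > 0")
        _require(
            self.reference_concentration > 0, "reference_concentration", "must be > 0"
        )
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")


@dataclass(frozen=True)
class PartitionMeasurement:
    """NMR-style integrals from one partition experiment plus bookkeeping."""

    integral_octanol: float
    integral_water: float
    integral_reference: float
    protons_per_molecule: int
    reference_protons: int
    reference_concentration: float  # mol/L
    v_octanol: float
    v_water: float
    c_octanol_true: float  # mol/L
    c_water_true: float  # mol/L
    logp_true: float


def gen_partition_measurement(spec: PartitionSpec) -> PartitionMeasurement:
    """Equilibrium concentrations from mass balance plus noisy integrals."""
    rng = np.random.default_rng(spec.seed)
    p = 10.0**spec.logp_true
    c_w = spec.total_amount / (spec.v_water + p * spec.v_octanol)
    c_o = p * c_w
    scale = 1e6  # arbitrary instrument scale; cancels in quantification
    noise = lambda: 1.0 + spec.noise_sd * rng.standard_normal() if spec.noise_sd else 1.0
    i_o = scale * c_o * spec.protons_per_molecule * noise()
    i_w = scale * c_w * spec.protons_per_molecule * noise()
    i_ref = scale * spec.reference_concentration * spec.reference_protons * noise()
    return PartitionMeasurement(
        integral_octanol=i_o,
        integral_water=i_w,
        integral_reference=i_ref,
        protons_per_molecule=spec.protons_per_molecule,
        reference_protons=spec.reference_protons,
        reference_concentration=spec.reference_concentration,
        v_octanol=spec.v_octanol,
        v_water=spec.v_water,
        c_octanol_true=c_o,
        c_water_true=c_w,
        logp_true=spec.logp_true,
    )


# ---------------------------------------------------------------------------
# droplet images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageSpec:
    """Synthetic fluorescence droplet image: bright disks on background noise."""

    width: int = 256
    height: int = 256
    droplet_centers: tuple[tuple[float, float], ...] = ()
    droplet_radii: tuple[float, ...] = ()
    foreground_intensity: float = 10000.0
    background_intensity: float = 1000.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.width > 0 and self.height > 0, "width/height", "must be > 0")
        if len(self.droplet_centers) != len(self.droplet_radii):
            raise ValueError("droplet_centers: must match droplet_radii length")
        for (r, c), rad in zip(self.droplet_centers, self.droplet_radii):
            if not (rad <= r <= self.height - 1 - rad and rad <= c <= self.width - 1 - rad):
                raise ValueError(
                    "droplet_centers: droplets must lie fully inside the frame"
                )
        for v in (self.foreground_intensity, self.background_intensity):
            if not (0 <= v <= 65535):
                raise ValueError("foreground_intensity: intensities must fit 16-bit")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")


def gen_droplet_image(spec: ImageSpec) -> tuple[np.ndarray, dict]:
    """Grayscale image plus ground truth {area_fraction_pct, count, mask}.

    Overlapping disks are allowed; the true count is the number of merged
    connected components of the noise-free bright mask (8-connectivity).
    """
    rng = np.random.default_rng(spec.seed)
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    for (r, c), rad in zip(spec.droplet_centers, spec.droplet_radii):
        rr, cc = _disk((r, c), rad, shape=mask.shape)
        mask[rr, cc] = True
    image = np.where(mask, spec.foreground_intensity, spec.background_intensity).astype(
        float
    )
    if spec.noise_sd:
        image = image + spec.noise_sd * rng.standard_normal(image.shape)
    image = np.clip(image, 0, 65535)
    count = int(_label(mask, connectivity=2).max()) if mask.any() else 0
    truth = {
        "area_fraction_pct": 100.0 * float(mask.mean()),
        "count": count,
        "mask": mask,
    }
    return image, truth
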