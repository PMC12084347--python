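# Methods

`diolphase` is an analysis pipeline for studies of how alkanediols
(1,6-hexanediol and its isomers and shorter homologues) disrupt protein
liquid–liquid phase separation. It covers four experimental/computational
readouts — simulation-trajectory observables, NMR chemical-shift-perturbation
and relaxation analysis, bench phase-separation assays, and thermal-stability
plus octanol/water-partition measurements — and a synthetic-data layer that
generates every input with known ground truth so that the whole pipeline is
testable without any external data.

## Trajectory observables

The trajectory container holds a per-atom topology table (residue index and
type, atom name, element, mass, heavy/side-chain flags, molecule id and kind)
and per-frame coordinates with an orthorhombic periodic box; all lengths are
in Å, residue numbering is 1-based.

**Contacts.** A contact between two residues, or between a residue and a
cosolvent molecule, is formed when *any* heavy atom of one is within 4.5 Å of
any heavy atom of the other. The comparison is inclusive (≤ 4.5 Å); the
boundary behaviour is tested explicitly. The per-frame event is binary per
residue pair; the reported frequency f_ij ∈ [0, 1] is the fraction of frames
with a contact, averaged over replicas when several are supplied. Cosolvent
contacts count *molecules* in contact with a residue, not atom pairs; the
atom-resolved map (side-chain heavy atoms of one residue type × cosolvent
heavy atoms) reports mean contacts per frame per residue instance, with row
and column marginals. Pair finding uses a periodic grid/tree spatial index
(`scipy.spatial.cKDTree` with `boxsize`); the test suite compares it against
an independent O(N²) minimum-image brute force and requires exact agreement.
The cutoff must not exceed half the minimum box edge (minimum-image
validity); larger values raise.

**R_ij and Rg.** The intrachain-distance profile averages |x_i − x_j| over
frames per residue pair and then over pairs of equal separation |i−j|; the
per-residue site is the backbone atom by default (residue centre of mass
optional). Intrachain distances are computed without periodic wrapping, on
the assumption that the chain is whole (unwrapped) in the input; the
synthetic generator produces unwrapped chains. Rg is the usual mass-weighted
second moment about the centre of mass, with an unweighted option. Replica
aggregation reports SEM = sd/√n over replicas for n ≥ 2 and an explicit NaN
(never zero) for a single replica.

**RDF.** g(r) is measured from the centre of mass of the side-chain heavy
atoms of a chosen residue type to all cosolvent heavy atoms, with
minimum-image distances, bin width dr = 0.1 Å and r_max = 12 Å by default
(r_max again bounded by half the box edge). Normalisation is per reference
site per frame by the ideal-shell count 4π r_mid² dr ρ, with bulk density
ρ = N_target/V_box and r_mid the bin centre. Pair counts per bin are kept so
that Σ counts equals the number of distances ≤ r_max exactly.

**Density.** ρ = Σm_k/V_box converted from Da/Å³ to g/cm³ with the factor
1.66053907 (one dalton per cubic ångström is 1.66053907 g/cm³).

## Synthetic data: what it emulates and what it does not

The generators are pure functions of a spec dataclass plus a seed and are
bit-reproducible.

*Chain ensembles* are freely jointed chains: per frame an independent walk of
N−1 steps of exactly b = 3.8 Å (the Cα–Cα virtual bond scale), each residue
carrying side-chain pseudo-atoms offset by at most b. At confinement
strength c > 0 each step direction is the normalised sum of a uniform random
direction and c times the unit vector back toward the walk origin; bonds stay
exactly b while the ensemble compacts and gains long-range contacts. At
c = 0 the closed forms ⟨R_ij²⟩ = |i−j| b² and ⟨Rg²⟩ = b²(N²−1)/(6N) hold and
are asserted within Monte-Carlo error. Residue types are drawn from a
G/S/Q/Y/T/P/A-rich composition so residue-type binning is exercised. Frames
are i.i.d. — there is no dynamics, no excluded volume and no energetics, so
time-correlation and kinetic observables are out of reach by design; the
ensemble averages the pipeline measures do not need them.

*Cosolvent boxes* place rigid clusters of heavy atoms (8 per molecule for a
hexanediol-like species: 6 C + 2 O; cluster radius 1.5 Å) in a cubic box. At
adsorption bias β = 0 centres are uniform; at β > 0 a fraction β/(1+β) is
re-placed within the adsorption shell (default 6 Å) of a randomly chosen
protein atom. This reproduces, in controllable form, the surface enrichment
that distinguishes the more amphiphilic diols, and makes mean protein–diol
contacts and first-shell g(r) strictly increasing in β — the qualitative
ordering the contact and RDF analyses must resolve. It does not model
solvent, hydrogen bonding or any specific chemistry.

*CSP datasets* encode the central observation that different diols induce a
shared per-residue perturbation pattern scaled by a per-compound potency:
shift_cond,i = shift_ref,i + λ_c·p_i + noise. The truth table carries λ_c and
a per-condition dilute-phase concentration (Csat) linked affinely to λ_c, so
slope-versus-Csat correlations have a known sign and magnitude. Peak
intensities vary mildly with potency; no lineshapes or spectra are simulated.

*Melts* follow the two-state van't Hoff model
θ(T) = [θ_N(T) + θ_U(T)·K(T)]/[1 + K(T)], K = exp[−(ΔH/R)(1/T − 1/Tm)], with
linear folded/unfolded baselines in MRE units, sampled at 0.5 °C steps over
25–90 °C by default (Tm 75 °C, ΔH 400 kJ/mol — a lysozyme-like sharp
transition). SNR is defined on the baseline separation at Tm.

*Partition fixtures* solve the mass balance c_w = n_tot/(V_w + P·V_o),
c_o = P·c_w with P = 10^logP, and emit NMR-style integrals proportional to
concentration × proton count plus a reference-standard integral, with
optional multiplicative noise.

*Droplet images* are bright disks over background with Gaussian noise; the
truth records the exact bright-pixel fraction and the number of merged
connected components (overlaps allowed).

Passing tests on these fixtures demonstrate that the analysis code is
correct on data that satisfy its model assumptions; they do not validate the
models against real spectra, real micrograph artefacts (uneven illumination,
out-of-focus droplets) or real force fields.

## NMR analysis

Indirect referencing uses V_X = V_1H·Ξ/100 with Ξ(¹⁵N) = 10.132912 and
Ξ(¹³C) = 25.144953 (DSS-referenced gyromagnetic ratios). CSPs are computed
per nucleus as signed Δδ = δ_cond − δ_ref together with intensity ratios;
the per-nucleus tables are primary, with the common combined CSP
√(Δδ_H² + (0.2·Δδ_N)²) available as an option. Residues missing from either
peak list propagate as NaN, never as zero. Residue-type binning uses |Δδ| by
default (a signed option is retained). The cross-condition slope fits
Δδ_x against Δδ_ref by ordinary least squares with intercept by default — the
through-origin fit is available since the original fit form is not
determined — and reports the Pearson correlation alongside. Relaxation rates
come from I(t) = I₀e^(−Rt) nonlinear least squares initialised from the
log-linear regression; uncertainty is the fit covariance; non-decaying data
return a warning flag rather than a clamped rate. hetNOE is the plain
saturated/reference intensity ratio.

## Assays

Csat from supernatant A280 follows Beer–Lambert (c = A·dilution/(ε·l),
reported in μM; ε is a required input — extinction coefficients are never
guessed). Protein/RNA mixtures are deconvolved from (A260, A280) through the
2×2 extinction system; negative solutions are flagged diagnostics, not
errors and not clipped. Turbidity series subtract the per-condition control
mean and report replicate mean ± sd with n (replicates are never silently
dropped; negative corrected values are preserved). Droplet images are
thresholded by Otsu's criterion by default (a fixed threshold is available
for exactness; a constant image under Otsu raises with that suggestion); the
area fraction is the percentage of above-threshold pixels, and counts use
8-connected components with a minimum area of 5 px — ImageJ-like defaults.
Concentration-versus-diol trends are OLS on replicate means with an optional
1/sd² weighting.

## Stability, partition, correlations

Melting curves are fit with the same two-state van't Hoff model as the
generator (temperatures in K internally, reported in °C), initialised from
end-segment baselines and the steepest-descent temperature. A fit is flagged
unconverged when the optimizer fails, Tm leaves the data range, or the
baseline separation at Tm is not resolved above the residual scatter (flat
curve) — no Tm is fabricated. A model-free midpoint (min–max-normalised
signal crossing 0.5) is computed as a cross-check, and disagreement beyond
1 °C is flagged. ΔTm is a simple difference with quadrature uncertainty and
requires both fits converged.

logP = log₁₀(c_octanol/c_water) with concentrations from integrals via
c = c_ref·(I/protons)/(I_ref/protons_ref); protons-per-integral is an
explicit input.

The potency ledger outer-joins per-compound Csat, CSP slope, logP and ΔTm;
every pairwise Pearson correlation uses paired complete observations only
(no imputation), and outlier exclusion is always explicit by compound label
(e.g. excluding the branched isomers 2,5-HD and 1,2-HD), never automatic.
Fewer than 3 pairs yields an explicit "unavailable" result.

## Numerical choices and problem sizes

- Contact cutoffs validated against half the minimum box edge; RDF r_max
  likewise.
- The relaxation and melt fits are exact on their own model class at zero
  noise (asserted to 1e−8 and 0.01 K respectively).
- Statistical recovery tests use deliberately modest sizes chosen to give
  clear margins at Monte-Carlo precision: 10⁴ frames for the freely jointed
  chain closed forms (3-SE bands, with the standard error floored at float
  precision for the separation-1 bonds, which are exact by construction),
  500 uniform cosolvent atoms × 200 frames for the ideal-gas RDF, 10 seeds ×
  3 bias levels for the adsorption sign test, 100 repeats for relaxation
  recovery (mean relative error bounded by 2%, consistent with the
  Cramér–Rao limit of the delay ladder), and 50 seed pairs for ΔTm recovery
  (mean absolute error bounded by 0.3 °C; the per-curve fit σ at SNR 50 is
  ≈0.18 °C, so per-seed maxima are not a meaningful bound).
- Default separation bins for contact summaries: 1–10, 11–25, 26–50, 51–100,
  >100; the last matches the long-range regime of interest. Empty bins are
  flagged, not zeroed.

## Known limitations

- Observables assume orthorhombic boxes (the minimum-image primitive also
  handles triclinic boxes via a 27-image search, but the contact/RDF engines
  do not); truncated-octahedral production boxes should be converted first.
- Intrachain distances assume unwrapped (whole) chains; no automatic
  unwrapping across periodic images is performed.
- The synthetic chain has no excluded volume, so its contact statistics are
  those of an ideal or confined random walk, not of a real disordered
  protein.
- Droplet segmentation is global-threshold based; images with strong
  illumination gradients need preprocessing upstream.
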