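# diolphase

Quantitative analysis of how alkanediols (1,6-hexanediol, 2,5-hexanediol,
1,5-pentanediol, 1,4-butanediol, 1,2-hexanediol, 1,2-cyclohexanediol, …)
disrupt protein liquid–liquid phase separation, for researchers combining
molecular simulation, solution NMR, and bench phase-separation assays on
low-complexity disordered domains such as the FUS LC region.

Studies of this question produce four kinds of data, and `diolphase`
implements the analysis for all of them behind one tested API:

- **Trajectory observables** — from single-chain protein + cosolvent
  simulation trajectories: radius of gyration Rg, mean intrachain distances
  R_ij versus separation |i−j|, residue–residue contact maps under the
  heavy-atom rule (a contact is formed when any heavy atom of one residue
  lies within 4.5 Å of any heavy atom of the other), per-residue counts of
  diol molecules in contact (binned by residue type), atom-resolved
  side-chain/diol contact maps with 1D marginals, radial distribution
  functions g(r) from side-chain centres of mass to diol heavy atoms,
  solution mass density, and standard errors over independent replicas.
- **NMR analysis** — indirect chemical-shift referencing
  (V_X = V_1H·Ξ/100, Ξ(¹⁵N) = 10.132912, Ξ(¹³C) = 25.144953), per-residue
  chemical shift perturbations Δδ with intensity ratios, residue-type
  binning, cross-condition slope/correlation analysis (the readout that
  different diols induce one shared Δδ pattern scaled by a per-compound
  potency), monoexponential R1/R2 fits, and heteronuclear NOE ratios.
- **Phase-separation assays** — saturation concentration (Csat) from
  supernatant A280 by Beer–Lambert, two-wavelength (260/280 nm)
  protein/RNA deconvolution, background-corrected turbidity, droplet
  area-fraction and counting from fluorescence images, and linear
  Csat-versus-diol-concentration trends.
- **Stability & partition** — two-state van't Hoff melting fits
  (θ(T) = [θ_N + θ_U·K]/[1+K], K = exp[−(ΔH/R)(1/T − 1/Tm)]) for Tm and
  ΔTm, octanol/water logP from NMR concentration quantification, and the
  per-compound potency ledger joining Csat, Δδ slope, logP and ΔTm with
  Pearson correlations including explicit named-outlier exclusion.

A synthetic-data layer (`diolphase.synthetic`) generates every one of these
inputs with known ground truth — freely-jointed-chain ensembles, diol boxes
with tunable surface adsorption, potency-scaled CSP datasets, van't Hoff
melts, partition equilibria, droplet images — so the full pipeline is
testable end-to-end without any external data. See `docs/methods.md` for
the models and their assumptions.

## Worked example

A 50-residue disordered-chain ensemble with one side-chain pseudo-atom per
residue, solvated by 330 hexanediol-like molecules (8 heavy atoms each) in a
60 Å cubic box, comparing a non-adsorbing and a surface-adsorbing diol:

```python
import diolphase as dp

chain = dp.gen_chain_ensemble(dp.ChainSpec(
    n_residues=50, confinement_strength=0.3,
    sidechain_atoms_per_residue=1, n_frames=50, seed=0))
print("Rg:", round(dp.radius_of_gyration(chain).mean, 2))

for bias in (0.0, 0.2):
    traj = dp.gen_cosolvent_box(dp.CosolventSpec(
        n_molecules=330, heavy_atoms_per_molecule=8, box_edge=60.0,
        adsorption_bias=bias, adsorption_shell=6.0, seed=1), chain)
    prof = dp.cosolvent_contacts(traj)          # molecules within 4.5 Å
    rdf = dp.rdf_sidechain_com(traj, "Y", r_max=12.0, dr=0.5)
    print(f"bias={bias}: contacts/residue = {prof.per_residue.mean():.2f}, "
          f"g(r<=6 A) Tyr = {rdf.g[rdf.r_mid <= 6].mean():.2f}")
```

prints

```
Rg: 7.16
bias=0.0: contacts/residue = 1.35, g(r<=6 A) Tyr = 1.21
bias=0.2: contacts/residue = 14.08, g(r<=6 A) Tyr = 11.86
```

With uniformly placed diol the chain sees ~1.4 molecules per residue per
frame and the Tyr-side-chain RDF is flat near 1 (bulk level); giving the
diol a modest adsorption bias enriches the protein surface, raising both the
per-residue contact count and the first-shell g(r) by an order of magnitude —
the same contact/RDF signature that distinguishes a strongly adsorbing diol
from a weak one in real trajectories.

The same objects feed the contact-map summaries:

```python
cm = dp.residue_contact_map(chain, cutoff=4.5)
dp.contacts_by_separation(cm)
#    bin   mean  n_pairs
#   1-10  0.397      445
#  11-25  0.165      480
#  26-50  0.154      300
# 51-100    NaN        0   (flagged empty: no such pairs at N=50)
#   >100    NaN        0
```

A command-line layer mirrors the library for file-based workflows:
`diolphase traj rg|rij|contacts|cosolvent-contacts|atom-map|rdf|density`,
`diolphase nmr csp|slope|relax`, `diolphase assay csat|deconvolve|turbidity|image`,
`diolphase stability tm|dtm|logp|correlate --exclude "2,5-HD,1,2-HD"`.

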