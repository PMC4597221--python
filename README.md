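# cutofflens

Structure-based prediction of catalytic sites in enzymes from
coarse-grained elastic network models, using the *cutoff lensing*
strategy: instead of fixing the contact cutoff at the conventional
10–13 Å, the cutoff R_c is scanned up to physically unconventional
values, where per-residue indicator profiles sharpen onto
function-related sites before blurring out in the fully connected
limit.

The package is aimed at structural bioinformaticians who want a light,
download-free, fully reproducible implementation of the method: Cα-only
PDB input, seconds per structure, no sequence information required.

## The model

A protein of N residues is reduced to its Cα positions **R**_i, each
carrying the average residue mass M = 120 Da. Residues i, j interact
when |**R**_i − **R**_j| ≤ R_c, through identical Hookean springs of
stiffness k₂ = 5 kcal/mol/Å² anchored at the equilibrium distances.
Diagonalizing the mass-weighted Hessian of this network gives 3N normal
modes ξ^k with eigenvalues ω_k² (6 rigid-body zero modes for a
connected, non-collinear structure). Three per-residue indicators are
computed at each cutoff:

- **spectral stiffness** χ_i = Σ_{k ∈ top 5} Σ_α (ξ^k_{iα})² — the
  weight of the five highest-frequency modes at residue i (fast modes
  localize on stiff, highly connected sites); orthonormality gives
  Σ_i χ_i = 5;
- **local connectivity** c_i — the contact-graph degree;
- **closeness centrality** CC_i = (n−1)/Σ_j d_ij with d_ij the
  unweighted shortest-path length.

Each profile is reduced to a *peak pattern* by a high-pass filter
(keep values above the profile mean plus n_σ population standard
deviations; n_σ = 1 for χ and c, 0.5 for CC) followed, for CC only, by
a 4-point smoothing that merges quasi-degenerate peak clusters. The
surviving peaks are the candidate sites.

Scanning R_c shows each indicator has an optimal cutoff (stiffness
≃ 22 Å, connectivity ≈ 20 Å, closeness = 28 Å). At these optima the
three peak patterns are renormalized (each peak carries mass 1/N_p) and
combined with equal weights into the per-residue score

S_i = (1/3) [σ_i^(χ) + σ_i^(c) + σ_i^(CC)],  Σ_i S_i = 1,

and, for an annotated structure, the global score S_Δn sums S_i over
all residues within Δn sequence positions of a known catalytic
residue — a confidence in [0, 1].

## Worked example

Everything is testable without downloads through the synthetic
generators. A planted-hub decoy buries a 2-residue high-connectivity
cluster (annotated site A56) at the center of a 137-residue two-layer
chain:

```sh
cutofflens synth planted_hub --seed 0 --out-dir demo
cutofflens predict demo/hub-0.pdb --out-dir demo
```

prints

```
Sequential site inspection for hub-0 (N = 137 residues)
[1] connectivity peaks @ 20 A (broad regions): A13, A29, A33, A36, A39, A41, A45, A48, A52, A56
[2] closeness peaks    @ 28 A (narrowed):       A2, A9, A12, A15, A24, A31, A37, A45, A55
[3] stiffness peaks    @ 22 A (refined):       A56
[4] combined score ranking:
     1. A56     S = 0.3667
     2. A45     S = 0.0704
     ...
```

Read bottom-up, this is the recommended inspection sequence: broad
connectivity regions, narrowed by closeness, refined by stiffness; the
planted site A56 is the single surviving stiffness peak and tops the
combined ranking (it peaks in the connectivity pattern, one of 10
peaks, and alone in the stiffness pattern, so
S = (1/3)(1/10 + 1) ≈ 0.367). Against the annotation the global
scores are

```sh
cutofflens score demo/hub-0.pdb demo/hub-0_sites.tsv --out-dir demo
S_dn=1  0.4037
S_dn=2  0.4037
```

meaning ~40% of the total prediction mass falls within one residue of
the annotated site. `cutofflens scan` writes the full cutoff scan
(patterns and recovery metrics per cutoff and indicator) and
`cutofflens evaluate` pools recovery curves over a manifest of
structures, overall and by size class.

Real structures work the same way: `cutofflens predict 1A30.pdb` on an
HIV-1 protease PDB file (with its Catalytic Site Atlas annotation for
`score`) reproduces the method's published workflow for that enzyme.

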