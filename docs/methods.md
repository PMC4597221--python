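# Methods

## Model and assumptions

The elastic network model (ENM) used here is the standard residue-level
coarse-graining: one bead per amino acid at the crystallographic Cα
position, uniform bead mass M, and identical harmonic springs of
stiffness k₂ between every bead pair closer than the cutoff R_c
(inclusive boundary, |**R**_i − **R**_j| ≤ R_c). The potential is
harmonic about the deposited structure, so the model carries no
chemistry, no anharmonicity and no distance-dependent spring weights:
everything downstream is a function of network topology and geometry
alone. That is deliberate — the method's premise is that catalytic
sites sit in topologically stiff, buried neighbourhoods, and stripping
chemical detail exposes exactly that signal.

Mass weighting with a uniform M is a global 1/M scale, so eigenvalues
are reported in k₂/M units and never converted to physical
frequencies; only spectral ordering matters. A connected, non-collinear
network has exactly 6 zero modes (rigid translations and rotations).
Two degenerate regimes worth knowing about:

- a *collinear* chain has 2N+1 zero modes, not 5, because
  pairwise-distance springs exert no transverse restoring force; the
  textbook count of 5 holds only for the 2-particle dimer (whose single
  internal mode has the analytic eigenvalue 2k₂/M);
- a *disconnected* graph (common at small cutoffs) gets 3+3 zero modes
  per rigid component. Scans report component counts and proceed;
  nothing is silently dropped.

## Indicators

Three per-residue profiles are computed from one contact graph per
cutoff:

- **Spectral stiffness** χ_i: the summed squared components, at residue
  i, of the five highest-frequency normal modes. High-frequency modes
  localize where the local spring environment is stiffest (many
  contacts, geometrically concentrated), so χ flags vibrational
  hotspots. With uniform mode weighting, eigenvector orthonormality
  forces Σ_i χ_i = (number of modes included) — a useful built-in
  normalization check. The number of included modes (default 5) trades
  coverage against blurring: each fast mode localizes on roughly one or
  two sites, and typical enzymes carry a handful of catalytic residues.
  A `mode_weighting = inverse_omega2` option weights each mode by
  1/ω_k² (fluctuation amplitude) instead; across the narrow top-5 band
  the weights are near-uniform, so peak locations are essentially
  unchanged. Uniform is the default and the documented behaviour.
- **Local connectivity** c_i: the degree of residue i. Cheap, crude,
  and included because its peaks mark extended high-density regions
  that the other indicators refine.
- **Closeness centrality** CC_i: within a connected component of size
  n, CC_i = (n−1)/Σ_j d_ij with d_ij the shortest-path length counted
  in edges (not Å). Production code runs BFS from every node via
  `scipy.sparse.csgraph`; tests compare against an independent
  Floyd–Warshall implementation and networkx. For disconnected graphs
  closeness is computed per component with no cross-component rescaling
  (the Wasserman–Faust correction is deliberately not applied): lensing
  operates at large cutoffs where graphs are connected, and small-cutoff
  disconnection is flagged by a warning instead of being massaged.

## Pattern reduction

Raw profiles are rugged. A profile is reduced to its significant peaks
in three steps:

1. **High-pass filter**: keep values strictly above
   mean + n_σ · SD, where mean and SD are taken over the whole profile
   and SD is the population (1/N) form — the choice is immaterial at
   protein sizes and fixed for bit-reproducibility. Defaults:
   n_σ = 1.0 for χ and c, 0.5 for CC. CC profiles are much flatter
   than the other two, so a permissive threshold is needed to retain
   any signal ahead of the smoothing step; both values are config keys
   (`filter.*_nsigma`).
2. **4-point smoothing, CC only**: a moving average over the window
   (i−1 … i+2), truncated to the in-range subset at the boundaries so
   that a constant profile is a fixed point. Filtered CC profiles carry
   clusters of quasi-degenerate peaks; averaging merges each cluster
   into a single broader bump, i.e. one prediction. Any fixed 4-point
   window alignment would do; this near-centered one is the documented
   choice. Smoothing runs *after* filtering.
3. **Peak detection**: a peak is a maximal run of equal positive values
   strictly greater than both flanking values, with array boundaries
   counting as −∞ flanks (so a monotone ramp peaks at its end). A
   plateau contributes its lower-median index — deterministic and
   symmetric to within one residue.

Peak sets are invariant under positive affine rescaling of the raw
profile, and the peak count is non-increasing in n_σ; both properties
are tested. Max-normalization to [0, 1] exists for display only and
never feeds peak detection.

## Cutoff scan and evaluation

The scan grid default is 8–40 Å in 2 Å steps, spanning the conventional
10–13 Å ENM range through the large-cutoff regime where the graph
approaches completeness. Peak patterns are scored against annotations
by sequence distance Δn: |i−j| within a chain, infinite across chains
(a dimer's chains are separate sequences; this matters for multimeric
enzymes). Reported metrics per (cutoff, indicator): the fraction of
catalytic residues within Δn of a peak, the peak fraction N_p/N, their
ratio (reliability; undefined and reported as missing when N_p = 0),
and peaks per catalytic site. Dataset-level curves pool counts
(total recovered / total catalytic), equivalent to recomputing over the
union of all structures, with size classes defaulting to tertiles of
the input sizes (configurable boundaries).

## Combined scoring

At the per-indicator optimal cutoffs (χ 22 Å, c 20 Å, CC 28 Å —
config keys `score.cutoffs`), each reduced pattern is renormalized to
σ_i = 1/N_p at peaks, then combined with weights (1/3, 1/3, 1/3) into
S_i. When an indicator has no surviving peaks its weight is, by
default, redistributed equally over the indicators that do — this
keeps Σ_i S_i = 1 and preserves the fraction-like reading of the
global score S_Δn; `score.redistribute = false` keeps fixed weights
instead (total mass then drops below 1), and both behaviours are
tested. S_Δn sums S_i over residues within Δn of any annotated
catalytic residue, each residue counted once (set semantics), which
bounds S_Δn ≤ 1. Generalized weight triples are accepted by
`combined_score` for experimentation but ship untrained.

The prediction entry point for unannotated structures emits the
sequential-inspection report: connectivity peaks (broad regions),
closeness peaks (narrowed), stiffness peaks (refined), then the
combined ranking by S_i with index-order tie-breaking. Reports are
byte-deterministic for identical inputs.

## Synthetic study conditions

The generators produce the smallest structures on which each property
is meaningful, so the whole pipeline runs in seconds:

- **helix**: analytic α-helical trace (2.3 Å radius, 1.5 Å rise,
  100°/residue ⇒ 3.8 Å consecutive spacing) — geometry sanity checks.
- **globule**: a self-avoiding chain with exact 3.8 Å bonds grown by
  rejection sampling inside a spherical envelope; used for zero-mode
  counts, oracle comparisons and the blur limit.
- **planted hub**: a two-layer decoy of 137 residues — 55 in a dense
  inner annulus (6.5–11.5 Å), 80 in an outer shell (18.5–20.4 Å), and
  a 2-residue hub at the center (one member at the origin, annotated;
  one satellite at 1.6 Å). The layered geometry makes the buried hub
  the contact-count maximum at the 10 Å conventional cutoff *and*
  keeps that dominance alive at ~22 Å, where every off-center residue
  loses sight of part of the outer shell while the origin sees
  everything. Hub dominance is asserted per draw; failing draws are
  regenerated from an incremented sub-seed (bounded retries). A plain
  uniform globule cannot plant such a site: a residue adjacent to the
  hub always sees every hub member while a hub member sees one fewer,
  and with uniform spring constants local compression adds no
  stiffness — the layered construction is what makes the planted
  property hold by geometry rather than by luck.
- **dimer**: two globular chains (A, B) with a ~4 Å interface gap —
  exercises infinite cross-chain sequence distance and multi-chain
  parsing.

Generation is a pure function of (parameters, seed) through
`numpy.random.Generator(PCG64)`; the generator tag is written into PDB
headers, and coordinates are pre-rounded to PDB precision (3 decimals)
so every structure round-trips exactly through the writer/parser pair.

What the synthetics do *not* emulate: secondary structure, realistic
packing density gradients, side-chain effects, crystallographic noise,
missing residues. Passing the planted-hub regression therefore shows
that the pipeline's mathematics behaves as designed (peaks evaporate
and relocate onto the planted stiff site as the cutoff grows); it does
not by itself certify recovery rates on real enzymes, which depend on
curated annotation data.

## Numerical choices

- Dense `scipy.linalg.eigh` for the full spectrum (structures here are
  well under the ~2000-residue point where a partial extremal solver
  would pay off).
- Zero-mode threshold: |λ| < 10⁻⁸ × spectral radius.
- Degenerate top-of-spectrum eigenvalues: modes are taken by spectral
  rank after the ascending sort, ties resolved by solver order; tests
  on degenerate cases only assert basis-independent (subspace-level)
  quantities.
- Contact detection via `scipy.spatial.cKDTree.query_pairs` (≤ r, i.e.
  inclusive), verified against O(N²) thresholding.
- Coincident beads (zero-length springs) raise immediately rather than
  producing NaN unit vectors.

## Known limitations

- The optimal cutoffs (22/20/28 Å) are treated as fixed configuration,
  not re-derived per structure; for unusually small or large proteins
  the scan command is the honest tool.
- Reliability is undefined on peak-free patterns and reported as
  missing, which complicates naive curve averaging on very small
  structures.
- No mmCIF input, no NMR ensembles (first model only), no all-atom
  networks, no distance-weighted springs, no sequence-conservation
  integration — the method is a structural complement to such scores,
  not a replacement.
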