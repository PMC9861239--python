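# Methods

This note documents the models, conventions and numerical choices behind
`mntrdyn`, in the spirit of a methods section: what each stage computes,
what the synthetic data do and do not emulate, and where design decisions
were genuinely open.

## System and numbering

The target system is a C2-symmetric homodimer of 142-residue chains, each
chain split into an N-terminal DNA-binding domain (DBD, residues 1–63,
containing the DNA-binding helix), a linker helix (64–86) that hinges at
residue 75, and a C-terminal dimerization core (87–142). Residue numbers
are 1-based per chain, as in the source PDB files; for MntR specifically,
residue 1 of the model is the *second* residue of the gene product (the
N-terminal methionine is excised in vivo) — the package documents this
rather than renumbering.

Descriptors that span the dimer use **continuous numbering**: residue *r*
of the *k*-th chain (chains ordered alphabetically unless overridden) maps
to *r* plus the lengths of all preceding chains. With two 142-residue
chains, 189 → (B, 47) and 178 → (B, 36); this offset-by-142 reading makes
the four dihedral anchors the symmetric helix positions of the two chains,
which is the interpretation adopted here. Both the chain order and the
residue quadruple are user-overridable, since numbering conventions with
or without the excised Met differ by one.

## Descriptors

All four descriptors are pure functions of one frame, evaluated
vectorised over the trajectory; series carry units, the sampling interval
(ps/frame) and provenance metadata.

- **DBH dihedral** — signed torsion over the *backbone carbonyl carbons*
  (PDB atom name `C`) of continuous residues 47, 36, 189, 178, in that
  order. "Backbone C" is read as the carbonyl carbon, not Cα, because the
  Cα-based descriptors are named Cα explicitly elsewhere; the atom name is
  an argument for users who prefer Cα. Sign convention is IUPAC
  (positive = clockwise rotation of the far bond viewed along the central
  bond), range (−180°, 180°]. Summaries report the signed value; whether
  published positive means folded sign is unknowable from a printed mean,
  so no folding is applied. Note the identity that holds under this
  convention: the torsion is *invariant* under atom-order reversal and
  flips sign under mirror reflection (not under reversal).
- **Hinge angle** — planar angle at the carbonyl C of residue 75, arms to
  residues 64 and 86 of the same chain, range [0°, 180°]. Published
  per-system values do not state chain handling; the package reports per
  chain and defaults to the two-chain mean (which also halves the
  per-frame sampling variance).
- **Inter-chain Cα distance** — Euclidean distance between the Cα atoms of
  the same residue (default 41, Lys41) in the two chains.
- **Site-2 gap** — minimum distance over the side-chain carboxylate-oxygen
  pairs of Asp8 and Glu99 of one chain (OD1/OD2 × OE1/OE2; SG for the
  cysteine-bridge mutant), the chemically meaningful span of the second
  metal site. On backbone-only models it falls back to the Cα–Cα distance
  and flags `ca_fallback` in the series metadata.

## Superposition and RMSD

Rigid superposition is unweighted least squares via the Kabsch/SVD closed
form with the standard determinant correction, so reflections are never
returned; degenerate inputs (< 3 points, collinear sets) raise instead of
returning an arbitrary rotation. RMSF superposes all frames onto the
**iteratively refined mean** (fit–average–refit until the mean moves
< 10⁻⁶ Å RMS) before taking per-atom fluctuations; the same routine feeds
PCA, because fitting to a fixed first frame imprints reference bias on the
covariance. `crystal_ca_rmsd` compares two single-model structures by
pairing chains (alphabetically by default), intersecting the residue
numbers that carry a Cα in both, and minimizing the RMSD over the union of
matched atoms — the convention for comparing crystal forms of the same
dimer with differently modelled loops.

## Clustering

The gromos (Daura) algorithm on a pairwise minimized-RMSD matrix:
repeatedly, the unassigned frame with the most unassigned neighbours
within the cutoff becomes a centroid and absorbs those neighbours.
Conventions: neighbourhood is the closed ball (d ≤ cutoff); ties in
neighbour count break toward the lowest frame index (determinism);
cluster ids are discovery-ordered, which provably orders populations
non-increasingly. The default analysis uses the Cα atoms of chains
stripped of their first 3 / last 7 residues (the noisy termini), frames
from 20 ns onward, and a 1.8 Å cutoff; the cutoff is a comparison
constant, not a fitted quantity — only counts at the *same* cutoff are
comparable. The matrix is computed in tiles of batched SVDs
(rmsd²·N = |X|² + |Y|² − 2(σ₁+σ₂±σ₃)), default tile 256, so a
5000-frame ensemble needs ~200 MB transient memory and no full
coordinate cross-product ever materialises.

## PCA and factor loadings

Ensembles are merged (optionally windowed, default 200–500 ns when the
input is long enough), superposed onto the iterative mean, flattened to
3N-vectors, and decomposed via the sample covariance (ddof = 1) with
`eigh`; eigenvalues are clipped at zero and sorted descending. A static
input yields zero total variance and is flagged rather than raising.
Projections are centered dot products with the eigenvectors. Factor
loadings use the correlation-style definition
ℓⱼ = vⱼ√λ / σⱼ — exactly the Pearson correlation between coordinate *j*
and the component's projection series — with zero-variance coordinates
(σⱼ below 10⁻¹⁰ of the largest coordinate SD) assigned loading 0 and
flagged; per residue, the Euclidean norm over the residue's x, y, z
loadings. This standard definition was adopted because "factor loadings"
admits several conventions and the correlation form is both
scale-invariant and directly interpretable.

## Synthetic ensemble generator

The generator stands in for undeposited MD trajectories. What it
emulates: a two-chain backbone-only (N, CA, C) dimer whose DBH dihedral,
per-chain hinge angles and Lys41 separation follow prescribed Gaussian
laws, optionally AR(1)-correlated in time (default ar1 = 0, i.i.d.
frames — no published autocorrelation exists to calibrate against), at
100 ps/frame sampling.

Frames are posed by exact inverse geometry rather than rejection
sampling, so the achieved descriptor equals the drawn target to machine
precision before jitter:

1. **Hinge**: the sub-arm (residues 64–74) rotates about the normal of the
   (C₆₄, C₇₅, C₈₆) plane through the vertex, by the angle that maps the
   template hinge onto the target. Targets drawn outside [0°, 180°] are
   folded back (the measurable range), which biases the achieved mean by
   < 0.07° for the preset parameters — far below the 4-standard-error
   recovery tolerance used in tests.
2. **Dihedral**: the two rigid DBD blocks rotate by ∓δ/2 about the line
   through the two central torsion anchors (C of A:36 and B:47); both
   anchors lie on the axis, so the correction is exact and symmetric.
3. **Distance**: the blocks translate by ±s along the same axis direction;
   since that only rescales the central torsion bond without changing its
   direction, the dihedral is preserved exactly, and s solves a quadratic
   whose infeasibility (target below the domains' perpendicular offset)
   raises a generation error naming the frame.
4. **Jitter**: isotropic Gaussian noise (default σ = 0.05 Å) on every
   atom. The published per-state SDs already contain *all* conformational
   variance, so the jitter is kept small enough (adding ≲ 0.1° in
   quadrature to the angle spreads) not to double-count it; it exists to
   give coordinate-level realism, non-zero RMSF everywhere, and PDB
   round-trip robustness.

Metal-bound presets append two hetero metal ions per chain near the
dimerization core. Presets: apo (64.6 ± 12.5°, 170.3 ± 4.1°,
37.8 ± 2.8 Å), mn (36.5 ± 7.3°, 169.5 ± 3.7°, 37.2 ± 1.9 Å), zn (hinge
173.1 ± 3.5°; dihedral 80 ± 16° as a *stand-in* for "fluctuates even more
than apo"), mutant (Mn-like stand-in values). Stand-ins are flagged
per-descriptor in `SyntheticParams.paper_backed` and are excluded from
quantitative acceptance.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: side chains and packing, solvent, force-field
energetics, chain continuity at the rigid-block joints (the posing
rotations break the backbone between residues 63/64 and 74/75),
correlations *between* descriptors, and slow non-Gaussian conformational
transitions. Tests on synthetic data validate the *analysis pipeline*,
not any biophysical claim about MntR.

## Selections and I/O

PDB parsing/writing is delegated to biotite behind the package's own
validation layer: a cheap pre-scan names the first malformed ATOM/HETATM
line; insertion-coded residues are rejected; alternate locations other
than blank/'A' are dropped (deterministic, common practice); hetero metal
ions are retained. Multi-model files are trajectories (one MODEL per
frame); a one-frame trajectory is written in the single-model dialect
(no MODEL records). Coordinates must fit the fixed-width %8.3f field or
writing raises. Round-trips preserve atom identities exactly and
coordinates to 10⁻³ Å — which propagates to ~0.01–0.05° on the angle
descriptors, the attainable round-trip fidelity for angles.

Strip-based selections anchor the tail count to a *nominal* chain length
(`chain_length`, inferred as the highest residue number when unset):
"strip 3/7" keeps residues 4–135 of a 142-residue chain. A stripped chain
is indistinguishable from a shorter full chain by its residues alone, so
idempotent re-application requires the pinned anchor; the pipeline
defaults pin it for the 142-residue dimer.

## Problem sizes and tolerances

Test and acceptance runs use n = 3000 frames for distribution recovery
(4-standard-error tolerances; SE of the SD taken as σ/√(2(n−1))),
100–200 frames for clustering/PCA ensemble properties, and ≤ 12-frame
instances for exhaustive-oracle equality checks — sizes at which every
check is exact or statistically well-powered while the whole suite runs
in well under a minute. Quartiles use linear interpolation; overlap is the
Tukey-fence containment fraction (share of one ensemble's values inside
the other's [q1 − 1.5·IQR, q3 + 1.5·IQR]), a computable stand-in for the
qualitative "the distributions occasionally overlap".

## Known limitations

- Cluster *counts* of real trajectories (the published 144/172/76/113)
  and the exact 86/8/3% variance split are properties of the undeposited
  data; only the orderings and separations they support are testable, and
  those are covered by fixed-seed property tests.
- No autocorrelation-aware inference: reported mean ± SD treat frames as
  exchangeable, matching the upstream convention; with ar1 > 0 the SDs
  remain correct marginally but standard errors would not be.
- Single-conformer altloc handling and no mmCIF/binary trajectory
  formats; users supply the biological assembly they mean.
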