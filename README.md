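# mntrdyn

Conformational-ensemble analysis of the *Bacillus subtilis* MntR
metallosensor homodimer — and, more generally, of any two-chain protein
whose activation is read out by the relative orientation of two symmetric
helices.

MntR is a manganese-sensing transcription factor: Mn²⁺ binding does not
switch the dimer between two discrete conformations, it *narrows* the
conformational space so that DNA-binding-competent conformers dominate.
This package implements the trajectory-analysis pipeline behind that
picture, for people who have conformational ensembles (MD trajectories as
multi-model PDBs, or NMR-style multi-model files) and want quantitative,
reproducible readouts:

- **Geometric activation descriptors**, evaluated per frame:
  - the signed **DBH dihedral** θ(C₄₇, C₃₆, C₁₈₉, C₁₇₈) over backbone
    carbonyl carbons in continuous dimer numbering (residues 189/178 are
    47/36 of the second chain) — the orientation of the two DNA-binding
    helices relative to each other;
  - the **linker hinge angle** ∠(C₆₄, C₇₅, C₈₆), per chain or averaged;
  - the **inter-chain Lys41 Cα distance** and the **site-2 gap**
    (Asp8–Glu99 carboxylate separation).
- **gromos (Daura) conformational clustering** on tiled pairwise
  Kabsch-RMSD matrices, with the cluster count at a fixed cutoff (1.8 Å
  default) as the measure of ensemble breadth.
- **Essential-dynamics PCA** on Cartesian Cα coordinates of merged,
  mean-superposed ensembles, with per-frame projections and per-residue
  correlation-style factor loadings
  (ℓⱼ = vⱼ·√λ / σⱼ, aggregated per residue).
- **Ensemble comparison**: mean ± SD, quartiles, SD ratios and a
  Tukey-fence overlap fraction between labelled states.
- A **synthetic ensemble generator** that poses a coarse C2-symmetric
  dimer by exact inverse geometry so that the descriptor distributions
  match prescribed means/SDs — presets carry the published per-state
  statistics (apo 64.6 ± 12.5°, Mn²⁺ 36.5 ± 7.3° DBH dihedral, etc.), so
  every stage of the pipeline is testable without the original
  trajectories, which were never deposited.

## Worked example

Generate two synthetic states and compare them:

```sh
mntrdyn simulate apo -n 200 --seed 20260927 --out results/ensembles/apo.pdb
mntrdyn simulate mn  -n 200 --seed 20260928 --out results/ensembles/mn.pdb
mntrdyn report --input apo=results/ensembles/apo.pdb --input mn=results/ensembles/mn.pdb
```

which prints, among the three descriptor blocks:

```
descriptor: dbh_dihedral [degrees]
                  n       mean       sd       q1   median       q3
         apo    200     64.644   12.601   57.482   64.171   71.772
          mn    200     36.249    7.360   31.489   36.222   40.966
difference of means (apo − mn): 28.395 degrees
SD ratio: 1.712
overlap: 0.210 of apo inside mn's fences; 0.515 conversely
```

Read: on Mn binding the DBH dihedral mean drops by ~28° and its spread
narrows by ~40%, while (in the other two blocks) the hinge angle and the
Lys41 distance barely move — the inter-helix dihedral is the
discriminating descriptor of activation, and the two distributions still
overlap partially (the apo dimer *visits* Mn-like conformers, it just
rarely stays there).

The numbered scripts under `analysis/` run the same story end to end —
`01_simulate_ensembles.py` (four states), `02_descriptor_comparison.py`,
`03_cluster_counts.py` (6 apo vs 2 Mn clusters at 1.8 Å on the example
above), `04_pca_separation.py` (PC1 separates the states by 2.65 pooled
SDs; the strongest loadings sit in the mobile DNA-binding block) — writing
tables under `results/`.

## Layout

```
src/mntrdyn/     structio, geometry, descriptors, clustering, pca,
                 ensemble, synthdata, config, cli
analysis/        numbered narrative drivers over the library
tests/           unit + property + acceptance suite
docs/methods.md  models, conventions, numerical choices, limitations
```
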