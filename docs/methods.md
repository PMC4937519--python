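# Methods

## Surface distance model

The solvent accessible surface distance (SASD) between two crosslinkable
residues is the length of the shortest path joining their Cα atoms that
stays outside the protein's solvent-excluded volume. The computation has
three phases.

**Voxelization.** Atoms are mapped to the nearest point of a cubic grid
(ties toward the lower index). The grid spans the atom bounding box plus a
padding of max(4 voxels, largest rounded sphere radius + 1) per face — the
4-voxel floor is the conventional margin; the guard prevents expansion
spheres from clipping the boundary at coarse voxel sizes. Around every atom
a sphere of radius vdw(element) + 0.7 Å is expanded, the 0.7 Å being half
the van der Waals radius of a water molecule — the closest approach of a
water centre to the atom surface, so marked voxels approximate the
solvent-excluded volume rather than the bare atoms. The radius is rounded to
the nearest multiple of the voxel size (ties upward) so that borderline
exposed residues are not lost to discretization blur. Van der Waals radii
are the standard Bondi element set (`DEFAULT_VDW`). Atoms of lysine side
chains (CB, CG, CD, CE, NZ) and all side-chain atoms of each chain's first
residue are *excluded* from the expansion: the crosslinker attaches along
these side chains, which must not block their own attachment point. Whether
the exclusion should begin at CB or CG is not settled; we exclude from CB
outward. Waters are always discarded; other heteroatoms are ignored by
default and can be included as obstacles only.

**Boundary convention.** The occupancy expansion uses the *open* ball
(voxel-centre distance strictly below the rounded radius) while the
accessibility probe uses the closed ball. Without this asymmetry a residue
probed at its own Cα (the missing-side-chain fallback) would be sealed by
that backbone atom's excluded volume whenever the two radii round to the
same voxel count, misreporting free-standing residues as buried. With it,
an isolated Cα-only residue is accessible and an axis-aligned free-space
pair recovers its Euclidean separation exactly at 1 Å voxels.

**Accessibility.** For each lysine a probe sphere of radius
vdw(N) + 0.7 Å (rounded as above) is centred on the Nζ — on the Cα when the
side chain is unresolved, and on the Cα for non-lysine N-terminal residues.
Solvent voxels inside the sphere are recorded as path start voxels; a
residue with none is non-accessible. Residues lacking both Nζ and Cα are
reported unevaluable.

**Search.** Paths move between solvent voxels with 26-neighbour
connectivity and Euclidean step costs (1, √2, √3 voxel lengths), solved as a
shortest-path problem (Dijkstra on a sparse graph). A uniform-cost
6-connected traversal — equivalent to breadth-first layer counting — is
available via `connectivity=6`; it overestimates diagonal travel (L1 rather
than Euclidean geometry) and is provided for comparison only, the weighted
metric being the default because it returns geometric shortest paths. Each
residue is attached to the graph through a virtual node whose edges carry
the straight-line Cα-to-start-voxel lengths; a single-source solve from one
virtual node therefore yields, for every other residue, the exact minimum
over all start-voxel combinations of Cα-link + grid path + Cα-link. This
also makes per-source searches independent and embarrassingly parallel;
results are identical to serial execution. No maximum search distance is
applied unless requested. Equal-cost paths are broken deterministically by
node index; the reported distance is unaffected, the traced path geometry
may differ.

## Scoring model

Observed crosslinks evaluable on a model are partitioned into matched
(SASD computable) and non-accessible (buried endpoint or no solvent path).
MNXL sums, over matched crosslinks, the normal probability density of the
SASD under N(μ, σ²) when the SASD is within the maximum bound (33 Å
default), a flat −0.1 penalty when it exceeds the bound, and a flat −0.1
per non-accessible crosslink. The exact functional form of the positive
branch is implemented as the plain density (not log-density); it is a
pluggable callable on `ScoringConfig` so alternatives can be swapped in.
The two penalties are separately configurable but share the −0.1 default.
A distance exactly at the bound counts as matched-ok — the non-penalized
side of the boundary. Lysine pairs with a computable SASD that are *absent*
from the observed set contribute nothing: typical experiments recover well
under half of the theoretically possible crosslinks, so absence is weak
evidence. Monolinks are accepted by the readers but ignored by scoring.

μ and σ are the mean and sample (n−1) standard deviation of an empirical
SASD collection truncated at the fit cutoff (33 Å); no reference values are
bundled, so they are fitted from a user-supplied table
(`fit_sasd_distribution`) or set explicitly. The synthetic benchmarks fit
them from the reference structure's own sub-33 Å SASD set.

Comparison scores: NoV = count of crosslinks beyond the bound; SoVD =
summed excess distance; NoV+non-accessible adds the non-accessible count to
NoV. SoVD is not combined with non-accessible counts — the two are in
different units and there is no principled weighting. Ensemble scores are
min–max normalized to [0, 1] after orienting so 0 is the best model;
all-equal ensembles normalize to all zeros.

In Euclidean modes, distances are straight Cα–Cα lines; `euclidean_surface`
retains the non-accessible category by flagging pairs with a buried
endpoint, `euclidean_all` measures every pair (the category is empty by
definition). The same 33 Å bound is used by default for comparability.

## Evaluation

Model quality is Cα-RMSD over shared residues after optimal rigid
superposition (always applied — models need not share a frame). Correlation
is Pearson's r between normalized score and RMSD, so an effective score
gives positive r. Precision is TP/(TP+FP) over the top-20 models, TP
meaning RMSD ≤ 4 Å. When the 20th slot falls inside a cluster of tied
scores (equal within 1e-9 after normalization), remaining slots are drawn
uniformly without replacement from the cluster and the precision averaged
over 1000 draws; without boundary ties the computation is deterministic.

Bootstrap recovery: from the theoretical crosslink set (all pairs with
reference SASD < 33 Å), subsets of round-half-up(p·N/100) crosslinks
(minimum 1, so a 1% draw of a small set still tests something) are drawn
without replacement, each scored against all models; per-subset correlation
and precision are averaged over the bootstrap replicates. The maximum-bound
scan re-scores the ensemble at each cutoff in 20–80 Å, either holding the
fitted distribution fixed (default) or refitting it below each cutoff.

## Synthetic data

The fixtures module generates all test inputs. Residues are minimal
lysine-like constructions — backbone N/CA/C/O plus a linearly extended
CB–CG–CD–CE–NZ chain with Nζ 5.5 Å from the Cα (the side-chain reach used
in the maximal-span calculation) — not rotamer-correct amino acids. The
geometric fixtures (free pair, wall slab with a 2 Å carbon lattice, Nζ
enclosed in a dense carbon shell) have ground truth fixed by construction.
The benchmark ensemble perturbs a compact base assembly (eight lysines on a
12 Å cube around an alanine core) by displacing each residue rigidly with
seeded Gaussian noise; per-model noise magnitude ramps linearly from 0 to
15 Å over 50 models, spanning roughly 0–20 Å Cα-RMSD, so scored rank should
track perturbation magnitude. These fixtures lack real-protein features —
secondary structure, correlated backbone moves, realistic packing and
side-chain rotamers, crystallographic disorder — so passing tests establish
the geometric and statistical machinery, not performance on real ensembles,
which additionally depends on how crosslinks distribute over a genuine
protein surface. The ensemble size (50 models) and grid extents were chosen
to keep the benchmark comfortably desk-scale while leaving enough models
for a meaningful top-20 precision.

The independent shortest-path oracle used in tests (`grid_oracle`,
`sasd_oracle`) is a networkx Dijkstra over the same 26-neighbour metric,
sharing no code with the production sparse-graph search.

## Numerical choices and limitations

- Default voxel 1 Å; SASDs carry a discretization error of order the voxel
  size, hence the test tolerance SASD ≥ Euclidean − 2·voxel.
- Altloc resolution keeps the highest-occupancy conformer, ties → 'A'.
  Hydrogens are ignored by default (crystal structures typically lack
  them).
- Degenerate inputs: empty structures, all-equal distance fits, ensembles
  of one, and zero-variance correlation axes all raise or return explicit
  NaN rather than silently continuing.
- The grid search is exact on the discrete graph but the discrete path can
  exceed the true continuous geodesic by up to ~8% (the 26-neighbour metric
  error); at 1 Å voxels this is small against the 33 Å bound.
- Curation order (missing residue → self-link → non-lysine → duplicate →
  domain filter) fixes which rule a doubly-faulty record is attributed to;
  counts always sum to input minus output.
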