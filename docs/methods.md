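# Methods

`gt2spec` re-implements, as a tested pipeline, the bespoke computations used
to hunt for specificity-determining residues in GT2-family β-glucan
synthases: clade-aware conservation classification of alignment columns,
preliminary distance-based clade trees with sequence-refinement filters, an
idealized β-glucan chain builder, and the trajectory interaction metrics
(H-bond occupancy, aromatic–Glc stacking occupancy, glucan orientation and
position, RMSD/RMSF). This note records the models, conventions, parameter
choices and limitations.

## Conservation classification

Input is a master alignment whose sequences are partitioned into sub-family
clades (e.g. BcsA / CrdS / BgsA) with one reference sequence anchoring
residue numbering. Each column receives exactly one category, evaluated in
the precedence order FULL > DIFFERENTIAL > STRONG > NONE with strict (`>`)
threshold comparisons throughout:

- **FULL** — top-residue identity above `full` (default 0.99) on the pooled
  all-clade frequencies.
- **DIFFERENTIAL** — (a) every clade's consensus identity above
  `differential` (default 0.90) with at least two distinct consensus
  residues; or (b) exactly one clade below the bar, provided no residue that
  clade samples above `noise_floor` (default 0.01) equals any passing
  clade's consensus. The noise floor operationalises "not sampled" so that a
  single sequencing or annotation error cannot veto an otherwise clean
  pattern; it is configurable.
- **STRONG** — pooled top-residue identity above `strong` (default 0.75).
- **NONE** — everything else, including columns covered in fewer than two
  clades (their coverage is reported so truncated alignment regions can be
  judged by the user).

Identity denominators count non-gap characters only. `X` participates in
frequencies as a 21st symbol but is ineligible as a consensus residue, so
unknown characters cannot manufacture conservation. Consensus ties are
broken alphabetically and flagged in the output.

Whether family-wide conservation should be computed on pooled frequencies
or as "every clade individually above the bar with the same residue" is
genuinely open; both are provided (`mode="pooled"` is the default, matching
the family-wide reading of the category) and the choice only affects
FULL/STRONG, never DIFFERENTIAL.

Sequence-logo matrices report per-column information content
`log2(20) − H` (H the Shannon entropy of non-gap frequencies) with residue
heights `frequency × information`, i.e. the quantity a logo renderer draws.

## Preliminary clade trees

The preliminary sub-family assignment uses the classic distance pipeline:

1. **Refinement.** A column is an *insert column* when fewer than 10% of
   sequences have a residue there (`rare_column_fraction`, our
   operationalisation of "insertion region"; configurable and logged); a
   sequence is removed when more than 10 consecutive residues (strict `>`)
   fall in insert columns. One sequence per taxon is kept — the longest
   ungapped, ties to the lexicographically smaller id. Taxon labels are
   supplied as metadata because header formats vary. Both filters log the
   removed ids and are idempotent.
2. **Distances.** p-distances with pairwise deletion (gaps and `X`
   excluded), Jukes–Cantor corrected. The default is the classic 4-state
   formula `d = −(3/4)·ln(1 − (4/3)p)` — what general-purpose suites apply
   under the name "Jukes-Cantor" even for proteins — with the principled
   20-state protein variant `d = −(19/20)·ln(1 − (20/19)p)` selectable
   (`n_states=20`). The 4-state form saturates at p = 0.75 (error raised);
   deep protein comparisons should use the 20-state form, which saturates
   at 0.95.
3. **UPGMA.** Size-weighted agglomeration, node height d/2, deterministic
   tie-break by the lexicographically smallest cluster-label pair. The
   output is ultrametric by construction and reproduces additive
   ultrametric inputs exactly.
4. **Clade extraction.** `extract_clades(tree, k)` repeatedly splits the
   highest-rooted group until k groups exist (equal-height candidates are
   flagged and broken deterministically), exposing k rather than guessing
   how a published figure was cut.

## Idealized β-glucan chains

Chains are assembled from a single rigid β-D-glucopyranose ⁴C1 heavy-atom
template whose coordinates are fixed constants (standard pyranose bond
lengths and angles, all non-ring substituents equatorial, ring torsions
alternating at 53–62°). Each new residue is placed by internal coordinates:
the bridge oxygen extends the β-equatorial C1 direction of the previous
residue (C1–O 1.41 Å); φ = O5–C1–Ox–Cx and ψ = C1–Ox–Cx–C(x−1) torsions and
the 116° glycosidic valence angle then position the next ring, which is
mapped on by three-point superposition. Residues are numbered from the
non-reducing acceptor (Glc #0); the bridge oxygen belongs to the downstream
residue under its chemical name (O4 or O3), every residue carries C1–C6 and
O2–O6, and only the reducing end keeps an anomeric O1 — hence 12n − (n−1)
heavy atoms. Finished chains are rigidly placed with their axis along +y
and the acceptor at minimal y, the same frame the trajectory metrics use.

Default linkage conformers are named constants chosen from the literature
low-energy basins of the respective disaccharide maps so that the
chain-level observables emerge from geometry rather than being hard-coded:

| linkage | φ | ψ | emergent geometry |
|---|---|---|---|
| (1,4) | −110° | 110° | two-fold screw (neighbour rotation ≈ 178°), mean centre spacing ≈ 5.31 Å |
| (1,3) | −80° | 130° | single-helix, neighbour rotation ≈ −61°, spacing ≈ 4.82 Å |

The alternating (1,3;1,4) pattern gives ≈ 5.09 Å, intermediate as expected.
These idealized spacings approximate channel-bound ensemble averages only
to a few tenths of an Å — the (1,4) value sits ~0.2 Å below the in-channel
average — because a rigid single conformer cannot reproduce thermal
spreading of the glucosidic torsions. The curdlan 6₁ triple helix is
deliberately not buildable: it is a solution conformation that does not fit
a synthase TM channel, which is the regime this builder emulates. No
hydrogens, no ring-pucker variation (chains are restrained to the chair),
no energy model.

Rotations are measured as the signed angle about +y between xz-projections
of C2→C5 vectors (right-hand rule; wrapped to (−180°, 180]); near-axial
projections return null with a flag. Exocyclic sidedness projects C5→C6
onto the plane normal to the axis and compares signs against residue 0.

## Trajectory metrics

`Trajectory` is frames × named atoms with residue topology, read from
multi-model PDB. All channel-frame metrics assume
`align_to_channel_axis`, which per frame moves the bottom anchor (channel
entrance) to the origin and the bottom→top direction onto +y. Two anchors
leave the roll about the axis free; it is fixed deterministically (first
off-axis atom brought to the +x half-plane, or an explicit reference atom),
which makes aligned coordinates — not just the roll-invariant angle and
y-position metrics — reproducible under arbitrary per-frame rigid motion.

- **H-bonds**: donor–acceptor heavy-atom distance ≤ 3.4 Å and
  donor–H–acceptor deviation from linearity ≤ 60° for the best (most
  linear) bonded hydrogen. Donor hydrogens are inferred from covalent
  distance (< 1.2 Å) once per occupancy calculation — bonding is a topology
  property. Hydrogen-free inputs fall back to the distance-only criterion
  with an explicit flag (setting `angle_cut=180` reproduces this path
  exactly). Best-hydrogen rather than any-hydrogen semantics were chosen;
  with the linearity cut the two differ only when a donor carries several
  hydrogens pointing at the same acceptor.
- **Stacking**: count of heavy-atom pairs (backbone included) closer than
  5.5 Å (strict `<`) between an aromatic residue (Phe/Tyr/Trp, either
  argument position; anything else is an error) and a Glc; a frame stacks
  when the count strictly exceeds 25.
- **Occupancy** is the percentage of analysis-window frames satisfying the
  criterion; windows are given in frames, or in ns when frame times exist.
- **Glc orientation/position**: signed xz angle between the Glc C2→C5 and
  Trp CG→CZ3 projections (absolute values are also emitted, since reported
  sign conventions vary); y of the Glc heavy-atom centre minus y of the Trp
  Cα. Centres use unit masses by default — for an all-heavy-atom Glc the
  difference from true masses is < 0.1 Å — with atomic masses on a flag.
- **RMSD** over a named selection after optimal (Kabsch) superposition onto
  a reference frame (fit optional; < 3 atoms with fitting is an error).
  Presets carry the study proteins' domain residue ranges (catalytic, TM
  domain, TM channel, gating loop for RsBcsA and AtumCrdS).
- **RMSF** of each residue's representative atom (Cα for amino acids, C1
  for Glc) around the window-mean structure after a two-pass backbone (Cα)
  superposition; mobile glucans therefore cannot drag the frame of
  reference. Residues lacking their representative atom are reported null
  with a warning.

## Synthetic data

The generators exist so every stage is testable with known ground truth;
all randomness flows through NumPy's seeded PCG64 generator, so outputs are
bit-reproducible across platforms.

**Alignments** (`gen_clade_msa`, defaults: 3 clades × 20 sequences × 100
columns; 10 FULL + 10 STRONG + 10 DIFFERENTIAL planted, the rest
background): planted columns realise their identity level with exact
residue counts (`ceil(level·n)` consensus copies, default levels 1.00 /
0.80 / 0.92), so planted categories hold by construction, not merely in
expectation; `identity_jitter` lowers levels uniformly while clamping
inside the category-valid range. Background columns draw residues
uniformly from the 20 amino acids — the distribution most hostile to
spurious conservation — and carry the gaps (rate 0.02, never in planted
columns or the reference sequence). Real alignments differ in ways the
generator does not emulate: phylogenetic correlation between sequences,
BLOSUM-like residue preferences, indel structure; passing recovery tests
therefore demonstrates correctness of the classification rules, not
robustness to real-data column-identity estimation noise.

**Trajectories** (`gen_interaction_traj`, defaults: 1000 frames, p(H-bond)
0.6, p(stacking) 0.3, jitter σ = 0.05 Å): a toy channel-frame system (two
anchor Cαs, a Trp indole with its CG→CZ3 reference along +x, a Ser-OG/water
donor–acceptor pair, a Phe ring with a glucose stacked parallel above it,
and one glucose per planted orientation stacked along the axis). Per frame
each interaction switches to its "on" geometry with its planted
probability — H-bond 2.9 Å collinear vs 6.0 Å off; stacking 3.5 Å parallel
vs 9.0 Å off — and isotropic Gaussian jitter is added to every atom. The
on/off margins make the classification unambiguous at small σ; generation
refuses σ > 0.1 Å rather than blur them. No force field, no sterics: the
toy tests the measurement code, not molecular physics.

## Numerical choices and degenerate inputs

Strict inequalities at every published threshold (identity bars, 3.4 Å,
5.5 Å, 25 contacts) with boundary behaviour pinned by tests. Angles wrap to
(−180°, 180°]; degenerate xz-projections (below 1e−8) return null rather
than a garbage angle. The 4-state JC form raises on p ≥ 0.75 instead of
returning infinity. All-gap columns yield empty frequency maps with zero
coverage, not errors; columns covered in fewer than two clades classify as
NONE in profiles while direct classification of such input is an error.
UPGMA and consensus ties break lexicographically (flagged), never by hash
order.

## Analysis problem sizes

The numbered drivers under `analysis/` run the pipeline at desk scale: the
default 60 × 100 alignment, a 24-sequence tree after refinement spikes, the
three default chains, and a 1000-frame toy trajectory analysed over its
second half. These sizes make every script's output exactly reproducible in
seconds while exercising all code paths; the package functions accept
arbitrarily larger inputs.

## Known limitations

- The conservation categories assume the clade partition is given and
  correct; mis-assigned sequences dilute per-clade identities.
- The builder produces single rigid conformers; ensemble averages of
  channel-bound chains (spacings, rotations) are matched only to a few
  tenths of an Å / a few degrees.
- H-bond detection on hydrogen-free trajectories is distance-only and
  systematically over-counts relative to the angle-filtered criterion; the
  output flags it.
- UPGMA assumes a molecular clock; it is a *preliminary* clade tool, and no
  likelihood phylogeny, model selection or bootstrap support is provided.
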