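# Methods

## Quantitation model

A quantitation sample mixes the tryptic digests of two conditions, one
cross-linked with the light reagent and one with the heavy reagent. Every
cross-linked peptide pair observed as a doublet yields a signal ratio that
is oriented to conditions (not labels): log₂(condition1/condition2). The
pipeline applies, in order:

1. **Median normalization per sample.** The log-ratio median over all
   doublet peptide pairs in a sample estimates the condition-mixing bias
   and is subtracted. This assumes most links do not change between the
   conditions — valid here, where mutual links dominate.
2. **Median over supporting peptides** per residue pair (robust to a single
   aberrant peptide; even counts use the midpoint).
3. **Label-swap replica consistency.** Within an experiment the two swapped
   samples must both quantify the pair (values averaged) or both report a
   singlet for the same condition (a "unique" candidate). Anything else is
   rejected with a reason code. A pair seen as doublet in one experiment
   and singlet in the other resolves to the doublet value and carries a
   `mixed_detection` flag, since consistent doublets are direct evidence
   the link exists in both conditions.
4. **Experiment averaging.** Unweighted mean of the experiment values when
   a pair is quantified in both.

**Significance A.** Outlier p-values use the percentile-based robust z with
p = ½·erfc(z/√2), the spread on each side of the median estimated from the
15.87/84.13 percentiles. The test is applied to the pooled final fold
changes of a comparison, two-sided, at α = 0.05 with no multiple-testing
correction — matching the standard proteomics implementation of the test.
At least 8 values are required; degenerate spreads raise a typed error and
classification falls back to *mutual*. Note the test's known behavior: its
false-positive rate on genuinely null links is a few percent and grows when
per-link noise is heterogeneous (links supported by one peptide are noisier
than the pooled spread suggests).

**Three-way merge.** Two comparisons sharing their reference condition
partition the union of quantified links into six presence regions
(reference-only, each pairwise overlap, each exclusive set, and
all-three); links implying contradictory presence calls for the shared
reference keep a per-link conflict flag and are placed treating the
reference as present. The theoretically possible seventh region (present
in both non-reference conditions but not the reference) has its own label
rather than being silently merged.

## Structure assessment

Distances are Euclidean Cα–Cα. The theoretical cross-linkable limit is
spacer + side-chain lengths + 2 Å per residue (BS³: 11.4 Å spacer; K 6.0,
S/T 2.4, Y 6.5 Å; protein N terminus 0 Å as a conservative lower bound).
Residues missing from a model substitute the nearest resolved residue in
sequence (ties toward the lower number), with every substitution recorded.
Altlocs keep the highest occupancy; insertion-code residues are outside the
mature numbering and are skipped. Mature-protein numbering maps to author
numbering through per-chain offsets (identity by default, appropriate for
PDB entries 2A73/2I07).

## Coarse-grained Bayesian modeling

**Representation.** One bead per residue. Rigid bodies sit on Cα positions
of a source structure; flexible segments are strings of 3.0 Å beads (rigid
beads 2.4 Å). The shipped C3 partition (`data/c3_rigid_bodies.yaml`)
fuses the β-chain key-ring with the α′-NT segment into the core body and is
a *reconstruction* from the C3 crystal-structure literature; published
descriptions of the partition are graphical only.

**Score.** Negative log posterior =
−Σ log[ψ_c + (1 − 2ψ_c)·f(d)] + excluded volume + connectivity +
disulfide + ψ bounds. Two ψ classes are sampled, one for links identified
consistently across experiments, one for links identified once; ψ is
uniform on [0.01, 0.49] and proposed with a σ = 0.01 Gaussian reflected at
the bounds. The forward model f is logistic with inflection d₀ (default
35 Å, aligned with the satisfaction criterion) and steepness λ = 2 Å; a
`step` form (1 below d₀, 0 above) is available for data whose detection is
a hard distance cutoff — with the ψ terms the likelihood stays strictly
inside (0, 1). Excluded volume is a soft-sphere penalty k·overlap² between
beads of different bodies/strings, skipping pairs within 2 residues in
sequence (bonded neighbors are closer than the sum of their radii by
construction). Connectivity is an upper harmonic with rest length
4 Å × sequence gap; the disulfide is a harmonic at 6 Å with k = 10 Å⁻²
(no published constants exist for these terms; the values are declared choices).

**Sampling.** Replica-exchange Metropolis Monte Carlo: uniform choice among
rigid translation (≤4 Å), rigid rotation (≤0.03 rad), flexible-bead
translation (≤5 Å) and a ψ move; geometric temperature ladder (default
1.0–2.5, temperatures multiply the score in the acceptance ratio); neighbor
swaps by min(1, exp[(1/Tᵢ − 1/Tⱼ)(Sᵢ − Sⱼ)]) after every batch of moves;
models recorded from the lowest-temperature replica. Scores are updated
incrementally per move (only terms touching the moved group), which the
test suite checks against full recomputation. The core body is held fixed:
it is the superposition target of all analysis, so sampling it would only
add global drift. Mobile bodies initialize at random orientations inside a
bounding sphere (default 150 Å) around the core. The shipped default is the
desk-scale profile (8 replicas, 20,000 recorded models, one run); the
publication-scale protocol for this kind of system (32 replicas, 200,000
models, two independent runs) is available as the `paper` profile.

**Analysis.** The n best-scoring models (default 200) are superposed on the
core and clustered by k-means on flattened coordinates (Euclidean feature
distance ∝ RMSD); each cluster's center is the member with the lowest mean
RMSD to its co-members; the cluster best satisfying the cross-links
(fraction of links under the 35 Å criterion in at least one member; ties by
mean score) is flagged. Precision is the mean member-to-center RMSD after
core superposition; accuracy the mean RMSD to a reference structure;
per-domain values restrict the RMSD to each domain's beads. Localization
densities are per-voxel occupancy probabilities (fraction of members whose
domain spheres cover the voxel) written as CCP4 maps.

## Synthetic data and what the tests demonstrate

The generator emulates the experimental design, not mass spectra: a multi-domain
bead protein in named states that differ by rigid relocations of whole
domains; distance-limited cross-link detection; label-swap quantitation
tables.

The **two-state preset** is a four-domain chain. D1, D2 and the folded-back
D3 form a core whose arrangement is shared by both states; the terminal
domain D4 sits on D3 in state A and relocates into the three-sided pocket
formed by D1/D2/D3 in state B — a miniature of a thioester-containing
domain migrating along a molecule whose β-chain ring is conformationally
inert. Generator defaults (chosen once, as the conditions the preset emulates): 24 residues per domain, 12-residue linkers, 15 Å domain
spacing, reactive sites on every second residue (mirroring the abundance
and spread of lysines/serines/threonines/tyrosines), 12 Å detection cutoff
with 70% per-pair detection efficiency and a 5% spurious-link rate,
peptide-level log₂ noise sd 0.3, ±2.0 log₂ planted enrichment on 8% of
shared links per side (the order of enrichment rates seen in real QCLMS
comparisons), per-sample mixing bias ~N(0, 0.5), and 1–3 supporting
peptide pairs per link. Detectability is drawn per residue pair, not per
state, so state-exclusive links reflect geometry rather than detection
dropout; spurious links carry small random effects so the outlier test
faces a realistic null. Planted states are made physically self-consistent:
domains are pushed apart until no two interpenetrate and linkers are routed
around the domains with capped bond lengths, so the planted configuration
scores cleanly under the modeling priors.

The **category-recovery check** asks that ≥95% of genuine (non-spurious)
planted categories are recovered at the defaults, pooled over three seeds —
pooling because single-run proportions on ~100–250 links are dominated by
the binomial noise of the test's intrinsic few-percent false-positive rate.
Spurious links are excluded from the denominator: their planted "mutual"
label contradicts the random effect they are deliberately given.

The **configuration-recovery check** models state B from its simulated
links, starting from the state-A arrangement: the core is one fused rigid
body (its internal arrangement is "known" from state A, exactly as a
crystal structure of one conformation informs modeling of another), D4 is
mobile, and the forward model is the step form at d₀ = cutoff + 0.5 Å with
connectivity rest 5 Å/gap (matched to the generator's linker bond cap).
Recovery is measured as the RMSD of the mobile domain's beads, after core
superposition, between the chosen cluster's center and the planted
configuration — the ensemble-analysis metric of the modeling protocol. The
preset declares 5 Å; a desk-scale run (6 replicas, 4,000 recorded models,
about two minutes on one core) recovers the relocation at 2–4 Å across
seeds. Flexible linker beads are excluded from the metric: their positions
are only weakly determined by construction.

What passing these tests does **not** show about real data: the generator
has no peptide-level misassignment of cross-linked sites, no
retention-time or signal-transfer artifacts, no heteroscedastic peak-area
floor, and its detection model is a sharp distance cutoff rather than a
reactivity- and solvent-accessibility-weighted probability. Real systems
also carry ambiguity the toy lacks (homologous sites, symmetric
interfaces), and real rigid-body partitions are approximations that the
toy makes exact.

## Numerical choices and degeneracies

* Median conventions: midpoint for even counts, everywhere.
* `significance_A` needs ≥8 values and a positive one-sided spread; both
  violations raise typed errors rather than returning p-values.
* Cross-link identity is an unordered residue pair; duplicate swapped
  entries collapse in sets and dictionaries.
* k-means uses a fixed seed and n_init=10; cluster centers are members, so
  reported structures are always sampled models, never averages.
* Incremental MC scores drift only by floating-point accumulation
  (≤1e-8 over 10⁵ steps in the suite's checks).
* `select_best` breaks score ties by recording order, making selection
  reproducible.
* Degenerate inputs (empty ratio lists, empty clusters, oversized best-n,
  unknown reactive residue types, residues without beads) raise typed
  errors listed in `xlmstruct.errors`.

## Problem sizes used by the shipped checks

Synthetic end-to-end checks run the four-domain preset (~130 beads,
~200–260 links) with 6 replicas × 4,000 recorded models; the full suite
also exercises tiny 11-bead systems for oracle comparisons. These sizes are
the package's desk-scale defaults; the `paper` profile settings are
available unchanged for larger runs.

## Known limitations

* The C3 domain boundaries and rigid-body memberships are reconstructions;
  users with better annotations should edit the shipped YAML.
* The likelihood treats links independently; no correction for shared
  peptides or site ambiguity.
* Excluded volume is quadratic in bead count per evaluation (vectorized,
  with incremental updates during sampling); systems beyond a few thousand
  beads would need a neighbor grid.
* Localization densities use a hard sphere-overlap occupancy, not a
  Gaussian kernel; maps are written in P1 with the origin kept in the
  accompanying metadata rather than the CCP4 header.
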