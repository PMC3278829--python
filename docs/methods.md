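# Methods

`tethercoil` simulates the conformational ensemble of an intrinsically
disordered, proline/serine-rich protein region that is tethered to a
membrane by a transmembrane helix, and asks how that ensemble changes
when part of its space is excluded — by the membrane itself and by a
neighboring molecular assembly modelled as a second plane. The motivating
system is the intracellular domain of a single-pass receptor (LRP6-like),
whose phosphorylation motifs are thought to become accessible to kinases
only when the chain is forced into extended conformations.

## Chain model

Conformers are all-heavy-atom backbone models: N, CA, C, O per residue
plus a CB pseudo-atom for non-glycine residues. Hydrogens and side chains
beyond CB are not modelled. Chains are built residue-by-residue by NeRF
internal-coordinate construction with Engh–Huber bond lengths and angles
(N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å, CA–CB 1.530 Å;
N-CA-C 111.2°, CA-C-N 116.2°, C-N-CA 121.7°), a fixed trans peptide bond
(ω = 180°; cis-proline is not modelled), and an improper torsion
C-N-CA-CB of −120° fixing the L-configuration. Construction is exact:
measuring φ/ψ on built coordinates reproduces the input torsions to
better than 1e-6 degrees, which the test suite asserts.

The canonical build frame places residue 1's N at the origin with the
N→CA bond along +z and CA→C in the xz half-plane. With a helical anchor
this points the transmembrane helix roughly along +z and makes the
otherwise arbitrary azimuthal orientation of the vertical filter plane
reproducible.

## Torsion sampling

Backbone (φ, ψ) pairs are drawn from a mixture-of-basins library with
four residue classes: general, glycine, proline, and pre-proline
(residues immediately preceding proline, glycine excepted). Each basin
is a (φ, ψ) center with a circular-Gaussian width and a mixture weight.
The bundled default library ("coil-1", a YAML file inside the package)
uses basin centers for the extended-β, polyproline-II, right-handed α
and (general/Gly) left-handed α regions, with weights set to the
occupancy levels observed across *all* residues of high-resolution
structure databases — not coil regions only — because residue-specific
trajectory sampling of this kind draws from full-database statistics.
This choice sets the overall compaction of the ensemble: with it, the
mean radius of gyration of the unconstrained 243-residue test chain is
≈ 42.5 Å (2000 conformers), the scale reported for ensembles of this
segment generated with database-derived trajectory distributions. The
library is explicitly a configurable, versioned stand-in for those
(unpublished) distributions; any alternative can be supplied as YAML.

The transmembrane anchor span is forced helical by per-position
overrides (φ = −57°, ψ = −47°, probability 1), the plane-filter
equivalent of giving the helical basin full peak weight.

## Self-avoiding sampling

Sampled chains reject any placement that brings heavy atoms of residues
at sequence separation ≥ 2 closer than a clash cutoff (default 2.5 Å).
Placement is residue-wise: the step for residue *i* finalises every atom
whose position depends on (φᵢ, ψᵢ) — Cᵢ, Oᵢ, CBᵢ, N_{i+1}, CA_{i+1} — so
a clash can always be resolved by redrawing that residue. Each residue
is redrawn up to 50 times; when the limit is exhausted the sampler
backtracks 5 residues and continues, because growing a chain into a
compact self-avoiding state routinely dead-ends in a way that redrawing
the frontier residue alone cannot escape (restart-only sampling of a
243-mer with a realistic α-basin weight essentially never terminates).
A chain restarts from scratch when a per-chain attempt budget
(50 × chain length) is spent, up to 100 restarts, after which a
sampling-failure error reports an over-tight cutoff. Clash queries use a
uniform spatial grid with cell size equal to the cutoff. The ensemble is
a pure function of (sequence, library, sampler config): per-conformer
RNG streams are seeded as (global seed, conformer index).

## Spatial constraints

The membrane frame of a conformer is the least-squares axis through the
anchor-span CA positions (principal direction of the centered CA cloud,
signed N→C), the CA of the last anchor residue as anchor point, and a
lateral unit vector — the component of the build frame's +x orthogonal
to the axis — fixing the vertical plane's azimuth.

* Constraint 1 (membrane): every heavy atom of every post-anchor residue
  must satisfy (x − anchor)·axis ≥ −margin. Atom-level testing is the
  strict reading of "residues must lie on the cytoplasmic side"; margin
  defaults to 0.
* Constraint 2 (neighbor assembly at distance δ): every post-anchor
  heavy atom must satisfy (x − anchor)·lateral ≤ δ + margin, boundary
  inclusive, so survivor sets are nested across decreasing δ by
  construction. δ defaults to 20, 10 and 5 Å.

Anchor-span atoms are exempt from both tests (the helix sits in the
membrane). Both filters are asserted against a scalar signed-distance
oracle and are invariant under rigid motions applied jointly to the
conformer and its frame.

## Ensemble statistics

Radius of gyration is the RMS distance of all model atoms from their
unweighted centroid. Because the model omits hydrogens and side chains
beyond CB, absolute Rgyr values differ at the few-percent level from
all-atom ensembles; comparisons across filter stages are unaffected.
End-to-end distances are CA–CA distances; the canonical set for the
243-residue segment is the five equal-length pairs 24–126, 64–166,
106–208, 124–226, 141–243 (103 residues inclusive each), validated
against the expected residue letters when a true-sequence record is
supplied. Mean shifts (Δmean) are filtered-minus-initial means, always
against the initial unfiltered ensemble. Histograms report population
fractions with a default 2 Å bin width. Group comparisons use the
one-sided Welch unequal-variance t-test (Welch–Satterthwaite degrees of
freedom), computed by scipy and cross-checked in the tests against the
textbook formulas at 1e-10.

At desk scale (2000 initial conformers) the directional pattern of the
constrained ensembles reproduces clearly for Constraint 1 and δ = 20:
filtered mean Rgyr rises (≈ 42.7 → 45.8 → 46.4 Å at seed 0) and the
near-membrane distance D1 dominates the mean shifts (ΔD1 ≈ +12 Å under
Constraint 1 while D2–D5 stay near or below zero). The δ = 10 → δ = 5
increments are a different matter: the underlying effects are a few
tenths of an Å (Rgyr) against survivor samples of a few tens of
conformers (standard error ≈ 1.6 Å), so their sign at fixed seed and
desk scale is not statistically resolved in this model, and tests that
assert them can fail at that scale. This is a power limitation of the
thin-chain model at small n, not a missing mechanism: D1 remains
monotone in δ at larger n.

## Synthetic inputs

The package runs download-free. The control chain is the packaged
constant: the 23-residue transmembrane helix followed by an alternating
P/S repeat (242 residues as printed; a generalized constructor builds
P/S chains of any length, and 243-residue runs use it). The docking test
sequence embeds a peptide at the center of a P/S 100-mer (start =
floor((100 − len)/2) + 1, i.e. residues 40–61 for a 22-mer).

The synthetic reference complex stands in for a real kinase/peptide
structure and is labelled synthetic: the bound peptide is an ideal
α-helix, and the receptor is a half-cylindrical shell of pseudo-atoms
(radius 9 Å, azimuths 90–270° about the helix axis, 2.5 Å spacing, 6 Å
axial overhang, 0.2 Å positional jitter, deterministic per seed),
leaving an open corridor on one face. It reproduces the screen's
geometric logic — a buried bound pose with restricted exit paths for the
flanks — but none of the chemistry or shape of a real active site;
conclusions from it concern the screen, not any kinase.

Because a plain coil essentially never places 22 consecutive residues
in the exact bound pose, the docking run samples the binding region from
a mixture that draws the bound-pose torsions with weight 0.95 and coil
torsions otherwise, modelling transient preformation of the bound
conformation. With the default shell this yields a dockable fraction of
≈ 8% at n = 5000 — a small minority, as a geometric availability screen
should — and both groups are large enough for stable comparisons.

## Docking screen

For each conformer the binding-region backbone (N, CA, C) is superposed
onto the reference peptide pose by Kabsch/SVD superposition (proper
rotations only; reflection corrected via the smallest singular
direction). Conformers with RMSD > 0.5 Å are unavailable. Otherwise the
superposition is applied to the whole chain ("grafting": no bond
rebuilding) and heavy atoms outside the binding region are counted
against receptor atoms within 2.5 Å; availability requires zero clashes.
Raising the RMSD threshold can only grow the available set; raising the
clash cutoff can only shrink it. At seed 0 with n = 5000 the available
group has larger mean Rgyr and larger end-to-end distances for regions
1–40, 31–70 and 61–100, each at p < 0.01 (one-sided Welch).

## Numerical and degenerate-input policy

Angles are degrees at every interface (radians internally); dihedrals
follow the IUPAC sign convention and live in (−180°, 180°]. φ of residue
1, ψ of the last residue and ω of residue 1 are undefined and reported
as NaN. Helix-axis fitting raises on coincident CA positions and on
spans shorter than 4 residues; a lateral reference parallel to the axis
is degenerate and raises rather than guessing an azimuth. Welch tests
refuse samples of fewer than two values or zero pooled variance.
Summaries of empty subsets report count 0 with absent moments rather
than NaN arithmetic.

## Problem sizes

Default experiment sizes are 2000 initial conformers for the elongation
run and 5000 for the docking run; both complete in a few minutes on one
CPU. The published experiments used two orders of magnitude more
conformers (hundreds of thousands generated, 10000 survivors), which
narrows every standard error by ~10×; the package reproduces directions
and scales, not printed decimals, at desk sizes. The
`target_survivors` mode implements the generate-until-N-survivors
protocol with a generation cap of 100× the target.

## Known limitations

* No side chains beyond CB, no hydrogens, no rotamer sampling, no
  energetics: absolute compaction and clash statistics differ from
  all-atom ensembles; directional comparisons are the supported use.
* The membrane and the neighbor assembly are infinite half-spaces; no
  slab thickness, curvature or explicit neighbor geometry.
* The torsion library is a stand-in calibrated to ensemble scale, not a
  fit to any residue-specific database; per-residue idiosyncrasies
  (e.g. aromatic vs aliphatic coil preferences) are not represented.
* The synthetic reference complex supports testing of the screen's
  geometry only; real applications should supply a PDB complex via
  `read_reference_complex`.
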