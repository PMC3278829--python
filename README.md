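# tethercoil

Constrained conformational ensembles of membrane-anchored disordered
protein regions.

Intrinsically disordered, proline/serine-rich receptor tails — the
intracellular domain of LRP6 is the motivating case — have no stable
fold, but their conformational *ensemble* responds to geometry: the
plasma membrane bounds it on one side, and a neighboring molecular
assembly (a ligand-induced co-receptor complex, or a clustered neighbor)
bounds it on another. `tethercoil` asks what those exclusions do to the
ensemble, for anyone studying how unstructured signaling regions become
accessible to kinases.

The package provides:

* a statistical-coil conformer generator: all-heavy-atom backbone chains
  (N, CA, C, O, CB) built from φ/ψ torsions with ideal trans-peptide
  geometry, sampled from a configurable Ramachandran-basin library with
  the transmembrane span forced α-helical (φ = −57°, ψ = −47°) and
  self-avoidance enforced by a 2.5 Å heavy-atom clash cutoff;
* two half-space filters: a *membrane plane* through the last
  transmembrane residue perpendicular to the fitted helix axis, and a
  *neighbor plane* parallel to the axis at lateral distance δ
  (5/10/20 Å by default), with survivor sets nested in δ;
* ensemble statistics: radius of gyration
  R_g = sqrt(⟨|r_k − ⟨r⟩|²⟩) over all model atoms, five equal-length
  CA–CA end-to-end distances (D1–D5), population histograms, mean-shift
  (Δmean) tables, and one-sided Welch t-tests;
* a geometric docking-availability screen: Kabsch/SVD superposition of a
  binding region onto a reference bound-peptide pose (RMSD gate, 0.5 Å)
  followed by steric clash checking of the rest of the chain against the
  receptor;
* synthetic inputs for everything — the P/S-repeat control sequence, a
  peptide-in-the-middle 100-mer constructor, and a synthetic
  receptor/peptide reference complex — so the full pipeline runs with no
  downloads.

## Worked example

Generate 2000 conformers of a 243-residue P/S chain carrying the LRP6
transmembrane helix, filter, and tabulate:

```python
import warnings
from tethercoil import (LRP6_TM_ANCHOR, RunConfig, lrp6_distance_pairs,
                        make_ps_repeat_sequence, run_elongation_experiment)

record = make_ps_repeat_sequence(LRP6_TM_ANCHOR, 243, "control_243")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")      # control letters differ from LRP6
    pairs = lrp6_distance_pairs(record)

config = RunConfig(record=record, n_initial=2000, seed=0, pairs=pairs)
result = run_elongation_experiment(config, output_dir="run")
print(result.summary[result.summary.metric == "rgyr"].to_string(index=False))
```

prints (seed 0):

```
              stage metric  count      mean       min       max
            initial   rgyr   2000 42.651691 22.866692 82.328696
        constraint1   rgyr    316 45.796992 25.830150 79.020696
constraint2_delta20   rgyr     85 46.412447 27.858738 76.645634
constraint2_delta10   rgyr     42 47.273446 27.858738 76.645634
 constraint2_delta5   rgyr     27 46.524642 27.858738 64.876486
```

Reading it: of 2000 unconstrained conformers (mean R_g 42.65 Å), 316
keep every intracellular atom on the cytoplasmic side of the membrane
plane, and their mean R_g is ~3 Å larger — the membrane alone biases the
tail toward extended shapes. Confining survivors within δ of the helix
raises it further. The Δmean table (`result.delta_means`) shows the
shift is carried by the near-membrane segment: D1 (residues 24–126)
gains ~12–22 Å in mean while D2–D5 barely move or shrink. At these
survivor counts (tens of conformers at δ ≤ 10) the small δ-to-δ
increments sit within sampling noise; the C1 and δ=20 effects are the
robust ones.

The docking experiment runs the same way:

```python
from tethercoil import default_docking_run
result = default_docking_run(n_conformers=5000, seed=0, output_dir="dock")
print(result.comparison.round(4).to_string(index=False))
```

```
 metric  mean_nondockable  mean_dockable       t       df      p  n_nondockable  n_dockable
   rgyr           27.9682        30.8439 -9.5505 460.0141 0.0000           4604         396
  d1_40           38.3708        40.5767 -3.1688 473.7761 0.0008           4604         396
 d31_70           47.0442        52.6116 -9.1817 462.9437 0.0000           4604         396
d61_100           38.6405        41.0978 -3.6981 477.5809 0.0001           4604         396
```

396 of 5000 conformers can adopt the reference bound pose (backbone
RMSD ≤ 0.5 Å) without clashing into the receptor shell; they are more
extended than the unavailable majority on every measure, at p < 0.01.

A CLI mirrors these steps (`tethercoil generate | filter | measure |
dock | run-elongation | run-docking | report`); see `tethercoil --help`.

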