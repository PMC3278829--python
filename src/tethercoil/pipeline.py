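"""End-to-end experiment orchestration.

Two experiments are wired here:

* the elongation experiment — sample self-avoiding conformers of a
  membrane-anchored chain, filter them with the membrane plane and the
  neighbor plane at each delta, and tabulate radius-of-gyration and
  end-to-end statistics plus mean shifts; and
* the docking experiment — sample conformers of a peptide-in-the-middle
  test chain (no plane filters), screen each against a reference
  receptor/peptide complex, and compare dockable vs non-dockable groups.

Both runs are pure functions of (config, seed): per-conformer RNG streams
are derived from the global seed by a counter-based scheme, so generation
order and batching cannot change the ensemble.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .builder import Conformer, SamplerConfig, sample_conformer
from .complexes import ReferenceComplex, make_synthetic_reference_complex
from .docking import DockingConfig, compare_dockable, screen_ensemble
from .filters import filter_ensemble, fit_helix_axis
from .metrics import (DistancePairSet, EnsembleTable, delta_mean,
                      measure_ensemble, summarize)
from .sequences import SequenceRecord, make_docking_test_sequence
from .torsions import TorsionLibrary, default_library, with_bound_region


@dataclass
class RunConfig:
    """Configuration of one experiment run.

    Exactly one of ``n_initial`` (generate a fixed number of conformers)
    or ``target_survivors`` (generate until that many conformers pass the
    membrane filter and the largest delta) drives generation; with
    ``target_survivors`` a generation cap of ``cap_factor`` times the
    target bounds runtime against over-strict configurations.
    """

    record: SequenceRecord
    library: TorsionLibrary | None = None
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    deltas: tuple[float, ...] = (20.0, 10.0, 5.0)
    n_initial: int | None = None
    target_survivors: int | None = None
    cap_factor: int = 100
    pairs: DistancePairSet | None = None
    seed: int = 0
    # docking-only settings
    docking: DockingConfig | None = None
    reference: ReferenceComplex | None = None

    def __post_init__(self):
        if (self.n_initial is None) == (self.target_survivors is None):
            raise ValueError(
                "set exactly one of n_initial / target_survivors")
        if self.deltas != tuple(sorted(self.deltas, reverse=True)):
            raise ValueError("delta list must be strictly decreasing")
        if self.library is None:
            self.library = default_library().with_helical_anchor(self.record)


@dataclass
class RunManifest:
    """Stage counts, seeds and provenance of a completed run."""

    experiment: str
    sequence_id: str
    n_residues: int
    seed: int
    library_version: str
    sampler: dict
    counts: dict
    deltas: tuple[float, ...] = ()
    status: str = "complete"
    wall_clock_s: float = 0.0
    software_version: str = __version__

    def to_json(self, path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, default=str)


@dataclass
class ElongationResult:
    manifest: RunManifest
    table: EnsembleTable
    summary: pd.DataFrame
    delta_means: pd.DataFrame
    conformers: list[Conformer] = field(default_factory=list)


@dataclass
class DockingResult:
    manifest: RunManifest
    table: EnsembleTable
    verdicts: pd.DataFrame
    comparison: pd.DataFrame
    conformers: list[Conformer] = field(default_factory=list)


def conformer_seed(global_seed: int, index: int) -> tuple[int, int]:
    """Counter-based per-conformer RNG seed (order-independent)."""
    return (global_seed, index)


def _stage_masks(df: pd.DataFrame, deltas) -> dict[str, pd.Series]:
    masks = {"initial": pd.Series(True, index=df.index),
             "constraint1": df["pass_membrane"]}
    for d in deltas:
        masks[f"constraint2_delta{d:g}"] = (
            df["pass_membrane"] & df[f"pass_delta{d:g}"])
    return masks


def run_elongation_experiment(config: RunConfig,
                              output_dir=None,
                              keep_conformers: bool = False,
                              progress_every: int = 500
                              ) -> ElongationResult:
    """Generate, filter and measure a membrane-anchored coil ensemble.

    The initial (unfiltered) ensemble is always retained in the output
    table — mean shifts are computed against it — with per-conformer
    pass/fail flags for the membrane plane and each delta.
    """
    t0 = time.time()
    record = config.record
    deltas = config.deltas
    pairs = config.pairs
    rows_conf, rows_frame = [], []
    status = "complete"

    n_generated = 0
    n_largest = 0
    largest = deltas[0]
    cap = (config.n_initial if config.n_initial is not None
           else config.cap_factor * config.target_survivors)
    while True:
        if config.n_initial is not None and n_generated >= config.n_initial:
            break
        if (config.target_survivors is not None
                and n_largest >= config.target_survivors):
            break
        if n_generated >= cap:
            status = "generation-cap-reached"
            break
        sampler = SamplerConfig(
            clash_cutoff=config.sampler.clash_cutoff,
            max_residue_retries=config.sampler.max_residue_retries,
            max_chain_restarts=config.sampler.max_chain_restarts,
            backtrack_depth=config.sampler.backtrack_depth,
            rng_seed=conformer_seed(config.seed, n_generated),
        )
        conf = sample_conformer(record, config.library, sampler)
        frame = fit_helix_axis(conf, record.anchor_span)
        rows_conf.append(conf)
        rows_frame.append(frame)
        n_generated += 1
        flags = filter_ensemble([conf], [frame], deltas,
                                anchor_span=record.anchor_span,
                                ids=[n_generated - 1]).iloc[0]
        if flags["pass_membrane"] and flags[f"pass_delta{largest:g}"]:
            n_largest += 1

    flags = filter_ensemble(rows_conf, rows_frame, deltas,
                            anchor_span=record.anchor_span)
    table = measure_ensemble(rows_conf, pairs)
    df = pd.concat([table.df, flags.drop(columns="conformer_id")], axis=1)
    table = EnsembleTable(df, {
        "sequence_id": record.id,
        "library_version": config.library.version,
        "seed": config.seed,
        "deltas": list(deltas),
    })

    masks = _stage_masks(df, deltas)
    summaries = []
    for stage, mask in masks.items():
        s = summarize(table, mask)
        s.insert(0, "stage", stage)
        summaries.append(s)
    summary = pd.concat(summaries, ignore_index=True)

    initial = table
    dm_rows = []
    metrics = table.metric_columns()
    for stage, mask in masks.items():
        if stage == "initial":
            continue
        sub = table.subset(mask.to_numpy())
        if len(sub) == 0:
            continue
        row = {"stage": stage, "count": len(sub)}
        for m in metrics:
            row[m] = delta_mean(initial, sub, m)
        dm_rows.append(row)
    delta_means = pd.DataFrame(dm_rows)

    counts = {stage: int(mask.sum()) for stage, mask in masks.items()}
    counts["generated"] = n_generated
    manifest = RunManifest(
        experiment="elongation",
        sequence_id=record.id,
        n_residues=len(record),
        seed=config.seed,
        library_version=config.library.version,
        sampler=asdict(config.sampler),
        counts=counts,
        deltas=deltas,
        status=status,
        wall_clock_s=time.time() - t0,
    )
    result = ElongationResult(manifest, table, summary, delta_means,
                              rows_conf if keep_conformers else [])
    if output_dir is not None:
        _write_elongation(result, output_dir)
    return result


def _write_elongation(result: ElongationResult, output_dir) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.table.to_tsv(out / "ensemble_table.tsv")
    with open(out / "ensemble_table.meta.json", "w") as fh:
        json.dump(result.table.metadata, fh, indent=2, default=str)
    result.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    result.delta_means.to_csv(out / "delta_means.tsv", sep="\t", index=False)
    result.manifest.to_json(out / "manifest.json")


def run_docking_experiment(config: RunConfig,
                           output_dir=None,
                           keep_conformers: bool = False) -> DockingResult:
    """Generate docking-test conformers, screen each, compare groups."""
    if config.docking is None:
        raise ValueError("docking experiment needs a DockingConfig")
    if config.reference is None:
        raise ValueError("docking experiment needs a ReferenceComplex")
    if config.n_initial is None:
        raise ValueError("docking experiment uses a fixed n_initial")
    t0 = time.time()
    record = config.record
    confs = []
    for i in range(config.n_initial):
        sampler = SamplerConfig(
            clash_cutoff=config.sampler.clash_cutoff,
            max_residue_retries=config.sampler.max_residue_retries,
            max_chain_restarts=config.sampler.max_chain_restarts,
            backtrack_depth=config.sampler.backtrack_depth,
            rng_seed=conformer_seed(config.seed, i),
        )
        confs.append(sample_conformer(record, config.library, sampler))
    verdicts = screen_ensemble(confs, config.reference, config.docking)
    table = measure_ensemble(confs, config.pairs)
    df = table.df.copy()
    df["dockable"] = verdicts["dockable"]
    table = EnsembleTable(df, {
        "sequence_id": record.id,
        "library_version": config.library.version,
        "seed": config.seed,
        "reference_id": config.reference.id,
    })
    comparison = compare_dockable(table)
    manifest = RunManifest(
        experiment="docking",
        sequence_id=record.id,
        n_residues=len(record),
        seed=config.seed,
        library_version=config.library.version,
        sampler=asdict(config.sampler),
        counts={
            "generated": len(confs),
            "rmsd_pass": int((verdicts["rmsd"]
                              <= config.docking.rmsd_threshold).sum()),
            "dockable": int(verdicts["dockable"].sum()),
        },
        wall_clock_s=time.time() - t0,
    )
    result = DockingResult(manifest, table, verdicts, comparison,
                           confs if keep_conformers else [])
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.table.to_tsv(out / "ensemble_table.tsv")
        result.verdicts.to_csv(out / "verdicts.tsv", sep="\t", index=False)
        result.comparison.to_csv(out / "comparison.tsv", sep="\t", index=False)
        result.manifest.to_json(out / "manifest.json")
    return result


def default_docking_run(n_conformers: int = 5000, seed: int = 0,
                        peptide_length: int = 22, total_length: int = 100,
                        bound_weight: float = 0.95,
                        output_dir=None) -> DockingResult:
    """The packaged synthetic docking experiment with default settings."""
    record, region = make_docking_test_sequence("A" * peptide_length,
                                                total_length)
    library = default_library().with_helical_anchor(record)
    library = with_bound_region(library, region, bound_weight)
    reference = make_synthetic_reference_complex(peptide_length, rng_seed=0)
    pairs = DistancePairSet((
        ("d1_40", 1, 40), ("d31_70", 31, 70), ("d61_100", 61, 100),
    )) if total_length == 100 else None
    config = RunConfig(
        record=record, library=library, n_initial=n_conformers, seed=seed,
        docking=DockingConfig(binding_region=region),
        reference=reference, pairs=pairs,
    )
    return run_docking_experiment(config, output_dir=output_dir)


def report(run_directory) -> str:
    """Human-readable summary of a completed run directory."""
    out = Path(run_directory)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing artifact: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    lines = [f"{manifest['experiment']} run on {manifest['sequence_id']} "
             f"({manifest['n_residues']} residues, seed {manifest['seed']})",
             f"status: {manifest.get('status', 'complete')}",
             "counts:"]
    for stage, n in manifest["counts"].items():
        lines.append(f"  {stage}: {n}")
    if manifest["experiment"] == "elongation":
        for name in ("summary.tsv", "delta_means.tsv"):
            path = out / name
            if not path.exists():
                raise FileNotFoundError(f"missing artifact: {path}")
            lines.append("")
            lines.append(name)
            lines.append(pd.read_csv(path, sep="\t").to_string(index=False))
    else:
        path = out / "comparison.tsv"
        if not path.exists():
            raise FileNotFoundError(f"missing artifact: {path}")
        lines.append("")
        lines.append("dockable vs non-dockable comparison")
        lines.append(pd.read_csv(path, sep="\t").to_string(index=False))
    return "\n".join(lines)
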