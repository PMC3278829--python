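"""Per-conformer shape metrics and ensemble statistics.

Radius of gyration is the root-mean-square distance of all model atoms
from their unweighted centroid; end-to-end distances are CA-CA distances
between designated residue pairs.  Ensemble-level summaries (count, mean,
min, max), mean shifts between filtered and initial ensembles, population
histograms and the one-sided Welch t-test mirror the quantities reported
for constrained-coil elongation experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .builder import Conformer
from .sequences import SequenceRecord

#: The five equal-length (103-residue inclusive) CA-CA pairs of the LRP6
#: membrane-plus-intracellular segment, in local numbering, with the
#: residue letters expected at each position in the true LRP6 sequence.
LRP6_PAIRS = (
    ("d1", 24, 126, "C", "S"),
    ("d2", 64, 166, "G", "V"),
    ("d3", 106, 208, "T", "L"),
    ("d4", 124, 226, "E", "S"),
    ("d5", 141, 243, "T", "S"),
)


@dataclass(frozen=True)
class DistancePairSet:
    """Labelled (start, end) CA-CA pairs, 1-based inclusive."""

    pairs: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        for label, start, end in self.pairs:
            if start >= end:
                raise ValueError(f"pair {label}: start must precede end")

    def spans(self) -> dict[str, int]:
        """Inclusive span length per pair: end - start + 1."""
        return {label: end - start + 1 for label, start, end in self.pairs}


@dataclass
class EnsembleTable:
    """Per-conformer metric rows plus run metadata.

    ``df`` holds one row per conformer: ``conformer_id``, ``rgyr``, one
    column per distance pair, and any filter/dockable flag columns.
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.df["conformer_id"].duplicated().any():
            raise ValueError("conformer ids must be unique")

    def __len__(self) -> int:
        return len(self.df)

    def metric_columns(self) -> list[str]:
        flags = {"conformer_id"}
        return [c for c in self.df.columns
                if c not in flags and self.df[c].dtype.kind == "f"]

    def subset(self, mask) -> "EnsembleTable":
        return EnsembleTable(self.df[mask].reset_index(drop=True),
                             dict(self.metadata))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


def radius_of_gyration(conformer: Conformer) -> float:
    """RMS distance of all model atoms from their unweighted centroid (Å)."""
    coords = conformer.coords
    if coords.shape[0] == 0:
        raise ValueError("conformer has no atoms")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centered ** 2, axis=1))))


def end_to_end(conformer: Conformer, pair: tuple[int, int]) -> float:
    """Euclidean CA-CA distance between two 1-based residue indices (Å)."""
    start, end = pair
    n = len(conformer)
    if not (1 <= start <= n and 1 <= end <= n):
        raise ValueError(f"residue pair {pair} outside chain of length {n}")
    return float(np.linalg.norm(conformer.atom(end, "CA")
                                - conformer.atom(start, "CA")))


def lrp6_distance_pairs(record: SequenceRecord) -> DistancePairSet:
    """The five LRP6 end-to-end pairs (D1..D5), validated against the record.

    Requires a chain of at least 243 residues.  When the residue letters
    at the canonical positions do not match the true LRP6 sequence (as for
    a control chain), a warning is issued and the indices are used as-is.
    """
    if len(record) < 243:
        raise ValueError(
            f"LRP6 pair set needs >= 243 residues, got {len(record)}")
    mismatches = []
    for label, start, end, aa_start, aa_end in LRP6_PAIRS:
        if record.residues[start - 1] != aa_start:
            mismatches.append(f"{label}: residue {start} is "
                              f"{record.residues[start - 1]}, expected {aa_start}")
        if record.residues[end - 1] != aa_end:
            mismatches.append(f"{label}: residue {end} is "
                              f"{record.residues[end - 1]}, expected {aa_end}")
    if mismatches:
        warnings.warn(
            "sequence letters differ from the LRP6 reference at pair "
            "positions (expected for control chains): " + "; ".join(mismatches),
            stacklevel=2)
    return DistancePairSet(tuple((label, start, end)
                                 for label, start, end, _, _ in LRP6_PAIRS))


def measure_ensemble(conformers: list[Conformer],
                     pairs: DistancePairSet | None = None,
                     ids: list | None = None,
                     metadata: dict | None = None) -> EnsembleTable:
    """Rgyr (and end-to-end distances) for every conformer."""
    if ids is None:
        ids = list(range(len(conformers)))
    rows = []
    for cid, conf in zip(ids, conformers):
        row = {"conformer_id": cid, "rgyr": radius_of_gyration(conf)}
        if pairs is not None:
            for label, start, end in pairs.pairs:
                row[label] = end_to_end(conf, (start, end))
        rows.append(row)
    return EnsembleTable(pd.DataFrame(rows), metadata or {})


def summarize(table: EnsembleTable, mask=None) -> pd.DataFrame:
    """Count / mean / min / max per metric over an optional row subset."""
    df = table.df if mask is None else table.df[mask]
    metrics = table.metric_columns()
    if len(df) == 0:
        return pd.DataFrame(
            {"metric": metrics, "count": 0,
             "mean": np.nan, "min": np.nan, "max": np.nan})
    rows = [
        {"metric": m, "count": len(df), "mean": df[m].mean(),
         "min": df[m].min(), "max": df[m].max()}
        for m in metrics
    ]
    return pd.DataFrame(rows)


def delta_mean(initial: EnsembleTable, filtered: EnsembleTable,
               metric: str) -> float:
    """mean(filtered) - mean(initial) for one metric column (Å)."""
    if len(initial) == 0 or len(filtered) == 0:
        raise ValueError("delta_mean needs non-empty tables")
    return float(filtered.df[metric].mean() - initial.df[metric].mean())


def histogram(values, bin_width: float = 2.0
              ) -> tuple[np.ndarray, np.ndarray]:
    """Population-fraction histogram with fixed bin width.

    Returns (edges, fractions); fractions sum to 1.  Bin edges start at
    ``floor(min / bin_width) * bin_width`` so overlaid ensembles with a
    shared bin width share a grid.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("histogram needs at least one value")
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return edges, counts / values.size


def welch_one_sided(less_sample, greater_sample
                    ) -> tuple[float, float, float]:
    """One-sided Welch t-test of mean(less_sample) < mean(greater_sample).

    Returns (t, Welch-Satterthwaite df, one-sided p).  Both samples need
    at least two values and nonzero variance.
    """
    a = np.asarray(less_sample, dtype=float)
    b = np.asarray(greater_sample, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("degenerate samples: zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False, alternative="less")
    return float(res.statistic), float(res.df), float(res.pvalue)
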