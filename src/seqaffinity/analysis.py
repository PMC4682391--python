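"""Feature-importance and per-class compositional analyses.

Two complementary importance measures for a selected feature set of size m:

* Knock-out analysis — retrain with one selected property removed and report
  the drop in cross-validated accuracy (baseline minus leave-that-one-out
  accuracy), one number per property.  Measures each property's individual,
  non-redundant contribution.

* Main-effect difference (MED) — evaluate CV accuracy over the feature
  subsets defined by the rows of a two-level orthogonal array (level 1 =
  keep the property, level 2 = drop it) and report, per property, the mean
  accuracy of rows keeping it minus the mean accuracy of rows dropping it.
  Because every row toggles about half the properties at once, MED averages a
  property's effect over many backgrounds and its magnitude is typically much
  larger than the knock-out difference; the two are distinct statistics and
  reports label which was used.

Also provided: per-class mean amino-acid composition comparison and per-class
mean property statistics (optionally restricted to a residue subset, e.g.
hydrophobic residues only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .encoding import HIGH, LOW, ComplexRecord, FeatureMatrix, composition
from .models import cross_validate
from .properties import AMINO_ACIDS, AminoAcidPropertyTable


@dataclass
class KnockoutReport:
    baseline_accuracy: float                 # percent, all m features
    difference_accuracy: dict[str, float]    # property -> baseline - without-it

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "property_id": list(self.difference_accuracy),
                "difference_accuracy_pct": list(self.difference_accuracy.values()),
            }
        )
        df["baseline_accuracy_pct"] = self.baseline_accuracy
        return df.sort_values(
            "difference_accuracy_pct", ascending=False, ignore_index=True
        )


@dataclass
class MEDReport:
    med: dict[str, float]    # property -> main-effect difference (pct points)
    rank: dict[str, int]     # property -> 1..m, descending MED

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "property_id": list(self.med),
                "med_pct": list(self.med.values()),
            }
        )
        df["rank"] = df["property_id"].map(self.rank)
        return df.sort_values("rank", ignore_index=True)


def knockout_analysis(
    selected: Sequence[str],
    matrix: FeatureMatrix,
    labels,
    c: float,
    gamma: float,
    folds: int,
    seed: int,
) -> KnockoutReport:
    """Difference accuracy of each selected property under knock-out.

    Baseline is the stratified CV accuracy on all m selected properties; each
    property's difference is baseline minus the CV accuracy with that one
    column removed, holding the fold assignment (seed) fixed.
    """
    selected = list(selected)
    if len(selected) < 2:
        raise ValueError("knock-out needs at least 2 selected properties")
    full = matrix.subset(selected)
    baseline = cross_validate(full, labels, folds, c, gamma, seed).accuracy
    diffs: dict[str, float] = {}
    for prop in selected:
        rest = [p for p in selected if p != prop]
        acc = cross_validate(matrix.subset(rest), labels, folds, c, gamma, seed).accuracy
        diffs[prop] = baseline - acc
    return KnockoutReport(baseline_accuracy=baseline, difference_accuracy=diffs)


def _two_level_oa(n_factors: int) -> np.ndarray:
    """Two-level orthogonal array with >= n_factors columns (Hadamard
    construction, N = next power of two above n_factors).  Entry 0 = level 1
    (keep), 1 = level 2 (drop)."""
    if n_factors < 1:
        raise ValueError("need at least one factor")
    N = 4
    while N - 1 < n_factors:
        N *= 2
    rows = np.arange(N)
    cols = np.arange(1, n_factors + 1)
    # parity of popcount(i & j)
    levels = np.zeros((N, n_factors), dtype=int)
    for jidx, j in enumerate(cols):
        levels[:, jidx] = [bin(i & j).count("1") % 2 for i in rows]
    return levels


def main_effect_difference(
    selected: Sequence[str],
    matrix: FeatureMatrix,
    labels,
    c: float,
    gamma: float,
    folds: int,
    seed: int,
) -> MEDReport:
    """Main-effect difference of each selected property from an orthogonal
    design over keep/drop subsets (rows dropping every property are skipped).
    Ranks are 1..m in descending MED (ties broken by selection order).
    """
    selected = list(selected)
    m = len(selected)
    if m < 2:
        raise ValueError("MED needs at least 2 selected properties")
    if m > 31:
        raise ValueError("MED supports at most 31 properties (L32 array limit)")
    levels = _two_level_oa(m)
    accs: list[float] = []
    kept_rows: list[np.ndarray] = []
    for row in levels:
        keep = [selected[i] for i in range(m) if row[i] == 0]
        if not keep:
            continue
        acc = cross_validate(matrix.subset(keep), labels, folds, c, gamma, seed).accuracy
        accs.append(acc)
        kept_rows.append(row)
    acc_arr = np.array(accs)
    lev_arr = np.stack(kept_rows)
    med: dict[str, float] = {}
    for i, prop in enumerate(selected):
        keep_acc = acc_arr[lev_arr[:, i] == 0].mean()
        drop_acc = acc_arr[lev_arr[:, i] == 1].mean()
        med[prop] = float(keep_acc - drop_acc)
    order = sorted(range(m), key=lambda i: -med[selected[i]])
    rank = {selected[i]: pos + 1 for pos, i in enumerate(order)}
    return MEDReport(med=med, rank=rank)


@dataclass
class CompositionComparison:
    """Per-amino-acid mean composition (%) in each class and the difference."""

    high_pct: dict[str, float]
    low_pct: dict[str, float]

    @property
    def difference(self) -> dict[str, float]:
        return {aa: self.high_pct[aa] - self.low_pct[aa] for aa in AMINO_ACIDS}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "amino_acid": list(AMINO_ACIDS),
                "high_pct": [self.high_pct[a] for a in AMINO_ACIDS],
                "low_pct": [self.low_pct[a] for a in AMINO_ACIDS],
                "difference_pct": [self.difference[a] for a in AMINO_ACIDS],
            }
        )


def composition_comparison(records: Iterable[ComplexRecord]) -> CompositionComparison:
    """Mean amino-acid composition (percent) per affinity class and the
    high-minus-low difference; records must be labeled and both classes
    present."""
    comps = {HIGH: [], LOW: []}
    for rec in records:
        if rec.label is None:
            raise ValueError(f"{rec.complex_id}: unlabeled record")
        comps[rec.label].append(composition(rec))
    for cls, rows in comps.items():
        if not rows:
            raise ValueError(f"no records in class {cls!r}")
    mean_high = 100.0 * np.mean(comps[HIGH], axis=0)
    mean_low = 100.0 * np.mean(comps[LOW], axis=0)
    return CompositionComparison(
        high_pct=dict(zip(AMINO_ACIDS, mean_high.tolist())),
        low_pct=dict(zip(AMINO_ACIDS, mean_low.tolist())),
    )


def class_property_mean(
    records: Iterable[ComplexRecord],
    table: AminoAcidPropertyTable,
    restrict: Iterable[str] | None = None,
    weighting: str = "mean",
) -> dict[str, float]:
    """Per-class mean of a per-complex property statistic.

    For each complex the statistic is computed over the residues in
    ``restrict`` (default: all 20 amino acids; pass e.g. a hydrophobic subset
    for buried-hydrophobicity analyses) with one of two weightings:

    * ``"mean"`` — composition-weighted property value, sum over restricted
      residues of w(a) * PCP(a) with w the fraction over the whole complex;
    * ``"sum"`` — total property content, sum over restricted residues of
      count(a) * PCP(a).

    Returns {"high": mean, "low": mean} over labeled complexes.
    """
    restrict_set = set(restrict) if restrict is not None else set(AMINO_ACIDS)
    if not restrict_set & set(AMINO_ACIDS):
        raise ValueError("restriction excludes all standard amino acids")
    if weighting not in ("mean", "sum"):
        raise ValueError(f"weighting must be 'mean' or 'sum', got {weighting!r}")
    keep = np.array([aa in restrict_set for aa in AMINO_ACIDS])
    vals = table.as_array()
    per_class: dict[str, list[float]] = {HIGH: [], LOW: []}
    for rec in records:
        if rec.label is None:
            raise ValueError(f"{rec.complex_id}: unlabeled record")
        w = composition(rec)
        if weighting == "sum":
            w = w * len(rec.sequence)
        per_class[rec.label].append(float((w * vals)[keep].sum()))
    for cls, rows in per_class.items():
        if not rows:
            raise ValueError(f"no records in class {cls!r}")
    return {cls: float(np.mean(rows)) for cls, rows in per_class.items()}
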