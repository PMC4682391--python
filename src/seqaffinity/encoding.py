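"""Fixed-length physicochemical encoding of two-chain protein complexes.

A heterodimeric complex of arbitrary chain lengths is represented by its
amino-acid composition ``w`` (fractions over both chains pooled), and each
property table ``p`` contributes one feature

    TPCP(p) = sum_i w(a_i) * PCP_p(a_i)

the composition-weighted mean of the property over the complex.  The encoding
is order-independent by construction: permuting residues within a chain or
swapping the two chains leaves the features unchanged.

Feature columns are affinely rescaled to [-1, 1] using minima/maxima learned
from a training matrix only; out-of-range values in later data are clipped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .properties import AMINO_ACIDS, AminoAcidPropertyTable

logger = logging.getLogger(__name__)

#: Dissociation-constant threshold (molar) separating the affinity classes.
KD_THRESHOLD = 1e-8

HIGH, LOW = "high", "low"

_STANDARD = set(AMINO_ACIDS)


@dataclass
class ComplexRecord:
    """One heterodimer: two chain sequences plus optional affinity data."""

    complex_id: str
    chain_a: str
    chain_b: str
    kd: float | None = None
    pkd: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.complex_id:
            raise ValueError("complex record with an empty id")
        if self.label is not None and self.label not in (HIGH, LOW):
            raise ValueError(f"label must be {HIGH!r} or {LOW!r}, got {self.label!r}")
        if self.kd is not None and self.label is not None:
            expected = label_from_kd(self.kd)
            if expected != self.label:
                raise ValueError(
                    f"{self.complex_id}: label {self.label!r} contradicts "
                    f"kd={self.kd:g} M (threshold {KD_THRESHOLD:g})"
                )

    @property
    def sequence(self) -> str:
        """Both chains pooled (composition is computed over this)."""
        return self.chain_a + self.chain_b


def label_from_kd(kd: float) -> str:
    """Affinity class from the dissociation constant: high iff Kd < 1e-8 M."""
    if kd <= 0:
        raise ValueError(f"kd must be positive, got {kd!r}")
    return HIGH if kd < KD_THRESHOLD else LOW


def pkd_from_kd(kd: float) -> float:
    if kd <= 0:
        raise ValueError(f"kd must be positive, got {kd!r}")
    return -math.log10(kd)


def kd_from_pkd(pkd: float) -> float:
    return 10.0 ** (-pkd)


def sanitize_sequence(seq: str) -> str:
    """Uppercase and drop non-standard letters (X, B, Z, U, gaps, ``*``...)."""
    return "".join(c for c in seq.upper() if c in _STANDARD)


def sanitize_and_filter(
    records: Iterable[ComplexRecord], min_len: int = 50
) -> list[ComplexRecord]:
    """Sanitize sequences, then drop complexes with any chain shorter than
    ``min_len`` residues (strictly less; a 50-residue chain survives the
    default).  Drop reasons are logged."""
    kept: list[ComplexRecord] = []
    for rec in records:
        if not rec.complex_id:
            raise ValueError("complex record with an empty id")
        a = sanitize_sequence(rec.chain_a)
        b = sanitize_sequence(rec.chain_b)
        if min(len(a), len(b)) < min_len:
            logger.info(
                "dropping %s: chain length %d < %d after sanitization",
                rec.complex_id, min(len(a), len(b)), min_len,
            )
            continue
        kept.append(replace(rec, chain_a=a, chain_b=b))
    return kept


def composition(record: ComplexRecord) -> np.ndarray:
    """Amino-acid composition of the complex over both chains pooled.

    Returns fractions in :data:`properties.AMINO_ACIDS` order; they sum to 1.
    """
    seq = record.sequence
    if not seq:
        raise ValueError(f"{record.complex_id}: both chains empty")
    counts = np.zeros(20)
    for c in seq:
        try:
            counts[AMINO_ACIDS.index(c)] += 1
        except ValueError as exc:
            raise ValueError(
                f"{record.complex_id}: non-standard residue {c!r}; sanitize first"
            ) from exc
    return counts / counts.sum()


def tpcp(comp: np.ndarray, table: AminoAcidPropertyTable) -> float:
    """Total physicochemical property: composition-weighted property mean."""
    comp = np.asarray(comp, dtype=float)
    if comp.shape != (20,):
        raise ValueError("composition must be a length-20 vector")
    return float(comp @ table.as_array())


@dataclass
class FeatureMatrix:
    """Complexes x properties matrix of TPCP values.

    ``values`` is a DataFrame indexed by complex id with property-id columns.
    ``scaling`` (if set) maps each column to the (min, max) learned from a
    training matrix.
    """

    values: pd.DataFrame
    scaling: dict[str, tuple[float, float]] | None = None

    @property
    def complex_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def property_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, property_ids: Sequence[str]) -> "FeatureMatrix":
        missing = [p for p in property_ids if p not in self.values.columns]
        if missing:
            raise KeyError(f"unknown property ids: {missing}")
        scaling = (
            {p: self.scaling[p] for p in property_ids} if self.scaling else None
        )
        return FeatureMatrix(self.values.loc[:, list(property_ids)].copy(), scaling)

    def rows(self, complex_ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.values.loc[list(complex_ids)].copy(), self.scaling)


def encode_dataset(
    records: Sequence[ComplexRecord],
    tables: Sequence[AminoAcidPropertyTable],
) -> FeatureMatrix:
    """Encode complexes into a TPCP feature matrix.

    Rows follow record order, columns table order.  Duplicate complex or
    property ids are rejected.
    """
    if not records or not tables:
        raise ValueError("need at least one record and one property table")
    ids = [r.complex_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate complex ids in dataset")
    pids = [t.property_id for t in tables]
    if len(set(pids)) != len(pids):
        raise ValueError("duplicate property ids")
    comp = np.stack([composition(r) for r in records])  # (n, 20)
    prop = np.stack([t.as_array() for t in tables])     # (m, 20)
    values = pd.DataFrame(comp @ prop.T, index=ids, columns=pids)
    return FeatureMatrix(values)


def fit_scaling(matrix: FeatureMatrix) -> FeatureMatrix:
    """Learn per-column (min, max) from ``matrix`` and rescale it to [-1, 1].

    A constant training column maps to 0 everywhere.
    """
    mins = matrix.values.min(axis=0)
    maxs = matrix.values.max(axis=0)
    scaling = {p: (float(mins[p]), float(maxs[p])) for p in matrix.property_ids}
    scaled = apply_scaling(FeatureMatrix(matrix.values), scaling)
    return scaled


def apply_scaling(
    matrix: FeatureMatrix, scaling: dict[str, tuple[float, float]]
) -> FeatureMatrix:
    """Apply stored (min, max) scaling; values outside are clipped to [-1, 1]."""
    if list(matrix.values.columns) != list(scaling):
        if set(matrix.values.columns) != set(scaling):
            raise ValueError("scaling column ids do not match matrix columns")
    lo = np.array([scaling[p][0] for p in matrix.property_ids])
    hi = np.array([scaling[p][1] for p in matrix.property_ids])
    span = hi - lo
    constant = span <= 0
    safe_span = np.where(constant, 1.0, span)
    scaled = 2.0 * (matrix.values.to_numpy() - lo) / safe_span - 1.0
    scaled[:, constant] = 0.0
    scaled = np.clip(scaled, -1.0, 1.0)
    return FeatureMatrix(
        pd.DataFrame(scaled, index=matrix.values.index, columns=matrix.values.columns),
        scaling=dict(scaling),
    )


# ---------------------------------------------------------------------------
# File formats: paired-chain FASTA and TSV manifests


def read_complex_fasta(path) -> list[ComplexRecord]:
    """Read complexes from FASTA with two records per complex, ids
    ``<complex_id>_A`` and ``<complex_id>_B``."""
    from Bio import SeqIO

    chains: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "_" not in rec.id:
            raise ValueError(f"FASTA id {rec.id!r} lacks a _A/_B chain suffix")
        cid, suffix = rec.id.rsplit("_", 1)
        if suffix not in ("A", "B"):
            raise ValueError(f"FASTA id {rec.id!r}: chain suffix must be A or B")
        if cid not in chains:
            chains[cid] = {}
            order.append(cid)
        chains[cid][suffix] = str(rec.seq)
    records = []
    for cid in order:
        pair = chains[cid]
        if set(pair) != {"A", "B"}:
            raise ValueError(f"complex {cid!r}: need both _A and _B records")
        records.append(ComplexRecord(cid, pair["A"], pair["B"]))
    return records


def write_complex_fasta(records: Sequence[ComplexRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f">{r.complex_id}_A\n{r.chain_a}\n>{r.complex_id}_B\n{r.chain_b}\n")


def read_manifest(path) -> list[ComplexRecord]:
    """Read a TSV manifest with columns complex_id, chain_a, chain_b and
    optional kd_molar / pkd / label."""
    df = pd.read_csv(path, sep="\t", dtype={"complex_id": str})
    required = {"complex_id", "chain_a", "chain_b"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        kd = getattr(row, "kd_molar", None)
        pkd = getattr(row, "pkd", None)
        label = getattr(row, "label", None)
        kd = None if kd is None or pd.isna(kd) else float(kd)
        pkd = None if pkd is None or pd.isna(pkd) else float(pkd)
        label = None if label is None or pd.isna(label) else str(label)
        if kd is None and pkd is not None:
            kd = kd_from_pkd(pkd)
        if pkd is None and kd is not None:
            pkd = pkd_from_kd(kd)
        records.append(
            ComplexRecord(str(row.complex_id), str(row.chain_a), str(row.chain_b),
                          kd=kd, pkd=pkd, label=label)
        )
    return records


def write_manifest(records: Sequence[ComplexRecord], path) -> None:
    df = pd.DataFrame(
        {
            "complex_id": [r.complex_id for r in records],
            "chain_a": [r.chain_a for r in records],
            "chain_b": [r.chain_b for r in records],
            "kd_molar": [r.kd for r in records],
            "pkd": [r.pkd for r in records],
            "label": [r.label for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_feature_matrix(path) -> FeatureMatrix:
    return FeatureMatrix(pd.read_csv(path, sep="\t", index_col=0))


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="complex_id")
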