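"""Synthetic heterodimer datasets with planted informative structure.

The generator emulates the study design the rest of the package targets: a
balanced two-class set of two-chain complexes, a large panel of candidate
property tables, and a small planted subset of genuinely informative ones.

Construction.  Property tables get independent standard-normal values per
amino acid.  Both classes share a uniform base composition ``w0``; the class
profiles are ``w0 +- d/2`` where the shift ``d`` lies in the span of the
centered informative table vectors and is solved (via the Gram system) so
that each informative TPCP feature separates the class means by exactly
``effect_size`` pooled within-class standard deviations (the within-class SD
follows from multinomial sampling of residues at the mean total chain
length).  Non-informative tables are random directions, so their projections
of ``d`` are zero in expectation over tables.

Chains are drawn residue-by-residue from the class profile.  pKd is a
monotone (linear) function of the complex's empirical composition projected
on ``d``, centered at 8 (Kd = 1e-8 M, the class threshold) with class means
at 8 +- pkd_gain, plus Gaussian noise; the class label is the thresholding of
the resulting Kd, so labels and affinities are consistent by construction and
at effect_size 0 the labels are pure noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .encoding import ComplexRecord, label_from_kd
from .properties import AMINO_ACIDS, AminoAcidPropertyTable


@dataclass
class GeneratorSpec:
    """Study conditions for one synthetic dataset."""

    n_complexes: int = 200
    n_properties: int = 580
    n_informative: int = 5
    effect_size: float = 2.0          # class-mean separation, pooled-SD units
    chain_length_range: tuple[int, int] = (100, 300)
    pkd_noise_sd: float = 0.5         # pKd units
    pkd_gain: float = 2.0             # class-mean pKd offset from 8
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_properties:
            raise ValueError("n_informative cannot exceed n_properties")
        if self.chain_length_range[0] < 50:
            raise ValueError("chain lengths below 50 would be filtered out")
        if self.n_complexes < 2 or self.n_complexes % 2:
            raise ValueError("n_complexes must be an even number >= 2")


@dataclass
class GroundTruth:
    informative_ids: list[str]
    composition_high: np.ndarray = field(repr=False)
    composition_low: np.ndarray = field(repr=False)
    pkd_description: str = ""

    def to_json(self) -> str:
        return json.dumps(
            {
                "informative_ids": self.informative_ids,
                "composition_high": dict(zip(AMINO_ACIDS, self.composition_high.tolist())),
                "composition_low": dict(zip(AMINO_ACIDS, self.composition_low.tolist())),
                "pkd_description": self.pkd_description,
            },
            indent=2,
        )


def generate_property_tables(n: int, seed: int) -> list[AminoAcidPropertyTable]:
    """``n`` synthetic property tables with iid standard-normal values."""
    if n < 1:
        raise ValueError("need at least one property table")
    rng = np.random.default_rng(seed)
    tables = []
    width = len(str(n))
    for i in range(n):
        vals = rng.standard_normal(20)
        tables.append(
            AminoAcidPropertyTable(
                property_id=f"SYN{i:0{width}d}",
                description=f"synthetic standard-normal property {i}",
                values=dict(zip(AMINO_ACIDS, vals)),
            )
        )
    return tables


def _plant_shift(
    tables: list[AminoAcidPropertyTable],
    informative_idx: np.ndarray,
    effect_size: float,
    w0: np.ndarray,
    mean_total_length: float,
) -> np.ndarray:
    """Composition shift d with exact per-informative-feature effect sizes."""
    if effect_size == 0:
        return np.zeros(20)
    V = np.stack([tables[j].as_array() for j in informative_idx])  # (k, 20)
    Vc = V - V.mean(axis=1, keepdims=True)
    # within-class TPCP SD from multinomial composition noise at w0
    var = (w0 * V**2).sum(axis=1) - ((w0 * V).sum(axis=1)) ** 2
    sd = np.sqrt(var / mean_total_length)
    G = Vc @ Vc.T
    coef = np.linalg.solve(G, effect_size * sd)
    return Vc.T @ coef


def _decorrelate_from_shift(
    v0: np.ndarray, d: np.ndarray, basis: np.ndarray
) -> np.ndarray:
    """Nearest table to ``v0`` whose TPCP feature is uninformative about the
    planted structure.

    Three channels are closed.  (1) Orthogonality to the span of the centered
    informative tables (columns of ``basis``, which contains the shift d):
    kills the class-mean difference v . d and — because multinomial
    composition noise around a near-uniform profile is isotropic on the
    simplex tangent — makes the feature statistically independent of the
    informative features to first order, so noise columns cannot act as
    denoising helpers for them.  (2) The residual class-variance difference,
    proportional to (v*v) . d, is zeroed as well.  Solved by Gauss-Newton on
    the stacked constraints.
    """
    v = v0 - basis @ (basis.T @ v0)
    for _ in range(50):
        g = np.concatenate([basis.T @ v, [(v * v) @ d]])
        if np.abs(g).max() < 1e-12:
            break
        J = np.vstack([basis.T, 2 * (v * d)[None, :]])
        v = v - J.T @ np.linalg.solve(J @ J.T, g)
    return v


def generate_dataset(
    spec: GeneratorSpec,
) -> tuple[list[ComplexRecord], list[AminoAcidPropertyTable], GroundTruth]:
    """Generate records, candidate tables and ground truth for ``spec``."""
    ss = np.random.SeedSequence(spec.seed)
    table_seed, data_seed = ss.spawn(2)
    tables = generate_property_tables(
        spec.n_properties, int(table_seed.generate_state(1)[0] % 2**31)
    )
    rng = np.random.default_rng(data_seed)

    informative_idx = np.sort(
        rng.choice(spec.n_properties, size=spec.n_informative, replace=False)
    )
    w0 = np.full(20, 1 / 20)
    lo, hi = spec.chain_length_range
    mean_total_length = 2 * (lo + hi) / 2
    d = _plant_shift(tables, informative_idx, spec.effect_size, w0, mean_total_length)

    # Make the non-informative tables signal-free.  Composition features are
    # all projections of one 19-dimensional composition, so a random table
    # would otherwise pick up the planted class structure through its mean
    # (overlap with d), its class-dependent variance, or its multinomial
    # correlation with the informative features (which would let noise
    # columns denoise them), and the "ground truth" would be ill-defined.
    if d @ d > 0:
        informative_set = set(int(j) for j in informative_idx)
        Vc = np.stack(
            [tables[j].as_array() for j in informative_idx]
        )
        Vc = Vc - Vc.mean(axis=1, keepdims=True)
        basis, _ = np.linalg.qr(Vc.T)  # orthonormal span of informative dirs
        for p, tab in enumerate(tables):
            if p in informative_set:
                continue
            v = _decorrelate_from_shift(tab.as_array(), d, basis)
            tables[p] = AminoAcidPropertyTable(
                property_id=tab.property_id,
                description=tab.description,
                values=dict(zip(AMINO_ACIDS, v)),
            )

    w_high = w0 + d / 2
    w_low = w0 - d / 2
    if w_high.min() <= 1e-4 or w_low.min() <= 1e-4:
        raise ValueError(
            "planted effect size leaves the composition simplex; "
            "use a smaller effect_size"
        )

    d_norm2 = float(d @ d)
    aa = np.array(list(AMINO_ACIDS))
    records: list[ComplexRecord] = []
    half = spec.n_complexes // 2
    width = len(str(spec.n_complexes))
    for i in range(spec.n_complexes):
        profile = w_high if i < half else w_low
        la = int(rng.integers(lo, hi + 1))
        lb = int(rng.integers(lo, hi + 1))
        chain_a = "".join(rng.choice(aa, size=la, p=profile))
        chain_b = "".join(rng.choice(aa, size=lb, p=profile))
        counts = np.zeros(20)
        for c in chain_a + chain_b:
            counts[AMINO_ACIDS.index(c)] += 1
        w_hat = counts / counts.sum()
        t = 0.0 if d_norm2 == 0 else 2.0 * float((w_hat - w0) @ d) / d_norm2
        pkd = 8.0 + spec.pkd_gain * t + rng.normal(0.0, spec.pkd_noise_sd)
        kd = 10.0 ** (-pkd)
        records.append(
            ComplexRecord(
                complex_id=f"CPX{i:0{width}d}",
                chain_a=chain_a,
                chain_b=chain_b,
                kd=kd,
                pkd=pkd,
                label=label_from_kd(kd),
            )
        )

    truth = GroundTruth(
        informative_ids=[tables[j].property_id for j in informative_idx],
        composition_high=w_high,
        composition_low=w_low,
        pkd_description=(
            "pKd = 8 + pkd_gain * projection of (empirical composition - w0) on "
            "the planted shift d, normalized so class means sit at 8 +- pkd_gain, "
            f"plus N(0, {spec.pkd_noise_sd}) noise; label = thresholding of Kd"
        ),
    )
    return records, tables, truth


def write_dataset(records, tables, truth: GroundTruth, outdir) -> None:
    """Write the generator output in the formats the encoder reads:
    paired-chain FASTA, TSV manifest, AAindex1 property file, truth JSON."""
    from pathlib import Path

    from .encoding import write_complex_fasta, write_manifest
    from .properties import dump_aaindex

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_complex_fasta(records, out / "complexes.fasta")
    write_manifest(records, out / "manifest.tsv")
    (out / "properties.aaindex").write_text(dump_aaindex(tables), encoding="utf-8")
    (out / "ground_truth.json").write_text(truth.to_json(), encoding="utf-8")
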