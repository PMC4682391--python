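"""Amino-acid physicochemical property tables.

A property table assigns one real number to each of the 20 standard amino
acids (an "index" in AAindex parlance).  Tables are read from the AAindex1
flat-file dialect: entries delimited by ``//``, with an ``H`` line carrying
the accession, ``D`` lines the description, and an ``I`` block listing the 20
values in two rows of ten, ordered A/R/N/D/C/Q/E/G/H/I then
L/K/M/F/P/S/T/W/Y/V.

Three tables discussed throughout this package (apparent partition energy
GUYH850105, principal component IV SNEP660104, and beta-turn frequency
CHOP780101) ship with the package; see :func:`builtin_tables`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Mapping

#: Row order of the AAindex1 ``I`` block; the canonical amino-acid order used
#: for every 20-vector in this package.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

logger = logging.getLogger(__name__)


class AAindexParseError(ValueError):
    """Raised when an AAindex1 entry is structurally malformed."""


@dataclass(frozen=True)
class AminoAcidPropertyTable:
    """One physicochemical property: a value per standard amino acid."""

    property_id: str
    description: str
    values: Mapping[str, float] = field(repr=False)

    def __post_init__(self) -> None:
        got = set(self.values)
        if got != set(AMINO_ACIDS):
            missing = sorted(set(AMINO_ACIDS) - got)
            extra = sorted(got - set(AMINO_ACIDS))
            raise ValueError(
                f"property table {self.property_id!r} must cover exactly the 20 "
                f"standard amino acids (missing {missing}, extra {extra})"
            )
        for aa, v in self.values.items():
            if not math.isfinite(float(v)):
                raise ValueError(
                    f"property table {self.property_id!r} has non-finite value "
                    f"for {aa!r}"
                )

    def value(self, amino_acid: str) -> float:
        return float(self.values[amino_acid])

    def as_array(self):
        """Values as a length-20 numpy array in :data:`AMINO_ACIDS` order."""
        import numpy as np

        return np.array([self.values[aa] for aa in AMINO_ACIDS], dtype=float)


def _split_entries(text: str) -> list[list[str]]:
    entries: list[list[str]] = []
    current: list[str] = []
    for line in text.splitlines():
        if line.startswith("//"):
            if any(l.strip() for l in current):
                entries.append(current)
            current = []
        else:
            current.append(line)
    if any(l.strip() for l in current):
        entries.append(current)
    return entries


def _parse_entry(lines: list[str], position: int) -> AminoAcidPropertyTable | None:
    """Parse one entry; return None if it contains NA values (caller skips)."""
    accession: str | None = None
    description_parts: list[str] = []
    value_tokens: list[str] = []
    section = None
    for line in lines:
        if line[:1].isalpha() and (len(line) == 1 or line[1:2] in (" ", "\t")):
            section = line[0]
            rest = line[2:].strip()
        else:
            rest = line.strip()  # continuation of the current section
        if section == "H" and rest:
            if accession is None:
                accession = rest.split()[0]
        elif section == "D" and rest:
            description_parts.append(rest)
        elif section == "I":
            if rest and not rest[:1].isalpha():
                value_tokens.extend(rest.split())
            # the "A/L R/K ..." header row is skipped (starts with a letter)

    label = accession or f"<entry #{position}>"
    if accession is None:
        raise AAindexParseError(f"AAindex entry {label} lacks an H (accession) line")
    if not value_tokens:
        raise AAindexParseError(f"AAindex entry {label} lacks an I (values) block")
    if len(value_tokens) != 20:
        raise AAindexParseError(
            f"AAindex entry {label}: expected 20 values, found {len(value_tokens)}"
        )
    if any(tok.upper() == "NA" for tok in value_tokens):
        return None
    try:
        numbers = [float(tok) for tok in value_tokens]
    except ValueError as exc:
        raise AAindexParseError(f"AAindex entry {label}: non-numeric value") from exc
    return AminoAcidPropertyTable(
        property_id=accession,
        description=" ".join(description_parts),
        values=dict(zip(AMINO_ACIDS, numbers)),
    )


def load_aaindex(
    stream: IO[str] | str,
    *,
    skipped: list[str] | None = None,
) -> list[AminoAcidPropertyTable]:
    """Read property tables from an AAindex1 flat file.

    Entries whose ``I`` block contains ``NA`` (a missing amino-acid value)
    are skipped, not returned: every downstream computation requires a value
    per amino acid.  Skipped accessions are logged and, if ``skipped`` is
    given, appended to it.  Returned tables preserve stream order.
    """
    text = stream if isinstance(stream, str) else stream.read()
    tables: list[AminoAcidPropertyTable] = []
    for pos, lines in enumerate(_split_entries(text), start=1):
        table = _parse_entry(lines, pos)
        if table is None:
            accession = next(
                (l[2:].strip().split()[0] for l in lines if l.startswith("H ")),
                f"<entry #{pos}>",
            )
            logger.info("skipping AAindex entry %s: NA values", accession)
            if skipped is not None:
                skipped.append(accession)
        else:
            tables.append(table)
    return tables


def read_aaindex(path) -> list[AminoAcidPropertyTable]:
    with open(path, encoding="utf-8") as fh:
        return load_aaindex(fh)


def dump_aaindex(tables: Iterable[AminoAcidPropertyTable]) -> str:
    """Serialize tables back to the AAindex1 dialect (round-trip safe)."""
    chunks = []
    header = "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V"
    for t in tables:
        vals = t.as_array()
        row1 = " " + " ".join(f"{v:.10g}" for v in vals[:10])
        row2 = " " + " ".join(f"{v:.10g}" for v in vals[10:])
        chunks.append(f"H {t.property_id}\nD {t.description}\n{header}\n{row1}\n{row2}\n//\n")
    return "".join(chunks)


def builtin_tables() -> list[AminoAcidPropertyTable]:
    """The three bundled property tables (GUYH850105, SNEP660104, CHOP780101).

    Apparent partition energies from the Chothia buried-fraction index,
    Sneath's principal component IV (hydroxythiolation), and the Chou-Fasman
    normalized beta-turn frequency — the properties singled out by the
    importance analyses this package implements.
    """
    text = (
        resources.files("seqaffinity.data")
        .joinpath("builtin_properties.aaindex")
        .read_text(encoding="utf-8")
    )
    return load_aaindex(text)


def reference_class_composition():
    """Bundled per-class mean amino-acid compositions (percent).

    Published mean compositions of high- and low-binding-affinity heterodimer
    classes, provided for comparison examples; returns a pandas DataFrame
    indexed by one-letter amino acid with columns ``high_pct``/``low_pct``.
    """
    import pandas as pd

    with resources.as_file(
        resources.files("seqaffinity.data").joinpath("reference_class_composition.tsv")
    ) as path:
        df = pd.read_csv(path, sep="\t", index_col="amino_acid")
    return df
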