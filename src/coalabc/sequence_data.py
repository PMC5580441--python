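"""Multilocus alignment containers, I/O and descriptive site counts.

The data model mirrors a small multilocus Sanger dataset: per-locus FASTA
alignments (one sequence per individual, heterozygous sites encoded as
IUPAC degenerate bases), plus a two-column popmap assigning each sample to
a taxon. Three focal taxa (*albiceps*, *chilensis*, *pallatangae*) enter
the downstream demographic analyses; anything else is mapped to ``other``
and treated as an outgroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import AlignmentError, FormatError, InsufficientDataError, MetadataError

UNAMBIGUOUS = frozenset("ACGT")
#: IUPAC degenerate bases: real (heterozygous) but unphased data.
AMBIGUITY = frozenset("RYSWKMBDHV")
#: Symbols treated as missing for trimming and excluded from all statistics.
MISSING = frozenset("N-?")
ALPHABET = UNAMBIGUOUS | AMBIGUITY | MISSING

FOCAL_TAXA = ("albiceps", "chilensis", "pallatangae")
TAXON_VOCABULARY = FOCAL_TAXA + ("other",)

INHERITANCE_CLASSES = ("autosomal", "z_linked", "mitochondrial")


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced individual and its taxon assignment."""

    sample_id: str
    taxon: str
    locality: str | None = None

    def __post_init__(self) -> None:
        if self.taxon not in TAXON_VOCABULARY:
            raise MetadataError(
                f"taxon {self.taxon!r} not in vocabulary {TAXON_VOCABULARY}"
            )


@dataclass
class LocusAlignment:
    """One locus's aligned sequences.

    ``rows`` maps sample_id -> uppercase sequence string; all rows share one
    length. Symbols are restricted to A/C/G/T, the IUPAC ambiguity codes and
    the missing-data symbols N, ``-`` and ``?``.
    """

    locus_name: str
    inheritance: str
    rows: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.inheritance not in INHERITANCE_CLASSES:
            raise ValueError(f"unknown inheritance class {self.inheritance!r}")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise AlignmentError(
                f"locus {self.locus_name!r}: ragged alignment, "
                f"row lengths {sorted(lengths)}"
            )
        if self.rows and next(iter(lengths)) == 0:
            raise AlignmentError(f"locus {self.locus_name!r}: zero-length rows")

    @property
    def length(self) -> int:
        if not self.rows:
            return 0
        return len(next(iter(self.rows.values())))

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rows)

    def subset(self, sample_ids: Iterable[str]) -> "LocusAlignment":
        ids = [s for s in sample_ids if s in self.rows]
        return LocusAlignment(
            self.locus_name, self.inheritance, {s: self.rows[s] for s in ids}
        )

    def to_array(self) -> np.ndarray:
        """Rows as a (n_rows, length) uint8 byte matrix for vectorised scans."""
        if not self.rows:
            return np.empty((0, 0), dtype=np.uint8)
        return np.frombuffer(
            "".join(self.rows.values()).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_rows, self.length)


@dataclass
class MultiLocusDataset:
    """A sample table plus one alignment per locus."""

    samples: list[SampleRecord]
    loci: list[LocusAlignment]

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("dataset needs at least one locus")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise MetadataError("duplicate sample_id in sample table")
        known = set(ids)
        for aln in self.loci:
            orphans = set(aln.rows) - known
            if orphans:
                raise MetadataError(
                    f"locus {aln.locus_name!r} has rows for unknown samples "
                    f"{sorted(orphans)}"
                )

    @property
    def taxon_of(self) -> dict[str, str]:
        return {s.sample_id: s.taxon for s in self.samples}

    def presence_matrix(self) -> pd.DataFrame:
        """Boolean samples x loci matrix of sequenced sample-locus combinations."""
        ids = [s.sample_id for s in self.samples]
        data = {
            aln.locus_name: [sid in aln.rows for sid in ids] for aln in self.loci
        }
        return pd.DataFrame(data, index=ids)

    def coverage(self) -> float:
        """Fraction of sample-locus combinations actually sequenced."""
        m = self.presence_matrix()
        return float(m.values.mean())

    def loci_by_inheritance(self, inheritance: str) -> list[LocusAlignment]:
        return [a for a in self.loci if a.inheritance == inheritance]

    def taxon_rows(self, aln: LocusAlignment, taxon: str) -> list[str]:
        """Sequences of one taxon present at one locus, in sample-table order."""
        tx = self.taxon_of
        return [seq for sid, seq in aln.rows.items() if tx[sid] == taxon]


def read_fasta_alignment(
    path: str | Path, locus_name: str, inheritance: str
) -> LocusAlignment:
    """Read one locus's FASTA into a :class:`LocusAlignment`.

    Symbols are uppercased; anything outside the A/C/G/T + IUPAC + missing
    alphabet is rejected with the offending record and column named.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    rows: dict[str, str] = {}
    for rec in records:
        seq = str(rec.seq).upper()
        for col, sym in enumerate(seq):
            if sym not in ALPHABET:
                raise FormatError(
                    f"{path}: record {rec.id!r} column {col + 1}: "
                    f"illegal symbol {sym!r}"
                )
        if rec.id in rows:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        rows[rec.id] = seq
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise AlignmentError(
            f"{path}: ragged alignment, row lengths {sorted(lengths)}"
        )
    return LocusAlignment(locus_name, inheritance, rows)


def load_popmap(path: str | Path) -> list[SampleRecord]:
    """Read a two-column (sample_id <tab> taxon) popmap.

    Taxa outside the focal three are mapped to ``other`` (outgroups are kept
    in the table but excluded from demographic analyses). Records are
    returned in file order; duplicate ids are an error.
    """
    path = Path(path)
    records: list[SampleRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            sid, taxon = parts[0], parts[1]
            if sid in seen:
                raise MetadataError(f"{path}:{lineno}: duplicate sample_id {sid!r}")
            seen.add(sid)
            if taxon not in FOCAL_TAXA:
                taxon = "other"
            records.append(SampleRecord(sid, taxon))
    if not records:
        raise FormatError(f"{path}: empty popmap")
    return records


def _missing_mask(arr: np.ndarray) -> np.ndarray:
    mask = np.zeros(arr.shape, dtype=bool)
    for sym in MISSING:
        mask |= arr == ord(sym)
    return mask


def trim_terminal_missing(aln: LocusAlignment) -> LocusAlignment:
    """Truncate missing data at both terminal alignment ends.

    Keeps the maximal contiguous column block such that no retained leading
    or trailing column contains a missing symbol (N, -, ?) in any row.
    Interior missing data are untouched. IUPAC ambiguity codes are real
    (heterozygous) data and never trigger trimming.
    """
    if aln.n_rows == 0:
        raise AlignmentError("cannot trim an empty alignment")
    arr = aln.to_array()
    col_has_missing = _missing_mask(arr).any(axis=0)
    clean = np.flatnonzero(~col_has_missing)
    if clean.size == 0:
        raise AlignmentError(
            f"locus {aln.locus_name!r}: all columns contain terminal missing data"
        )
    start, stop = int(clean[0]), int(clean[-1]) + 1
    if start == 0 and stop == aln.length:
        return aln
    rows = {sid: seq[start:stop] for sid, seq in aln.rows.items()}
    return LocusAlignment(aln.locus_name, aln.inheritance, rows)


def concatenate_loci(
    alignments: Sequence[LocusAlignment],
    name: str = "concat",
    missing_fill: str = "N",
) -> LocusAlignment:
    """Concatenate loci over the union of sample ids, padding absent rows.

    Used for the trim-on-concatenation mode: the study trimmed terminal
    missing data from the concatenated nuclear alignment before clustering.
    """
    if not alignments:
        raise ValueError("nothing to concatenate")
    inheritance = alignments[0].inheritance
    ids: list[str] = []
    for aln in alignments:
        for sid in aln.rows:
            if sid not in ids:
                ids.append(sid)
    rows = {
        sid: "".join(
            aln.rows.get(sid, missing_fill * aln.length) for aln in alignments
        )
        for sid in ids
    }
    return LocusAlignment(name, inheritance, rows)


def count_sites(aln: LocusAlignment) -> tuple[int, int]:
    """(variable sites, parsimony-informative sites) for one alignment.

    A column is variable if it holds >=2 distinct unambiguous bases;
    parsimony-informative if >=2 distinct unambiguous bases each occur in
    >=2 rows. Ambiguity codes and missing symbols are ignored per column.
    """
    if aln.n_rows < 2:
        raise InsufficientDataError("site counting needs >=2 rows")
    arr = aln.to_array()
    counts = np.stack(
        [(arr == ord(b)).sum(axis=0) for b in "ACGT"], axis=0
    )  # (4, length)
    n_distinct = (counts > 0).sum(axis=0)
    n_common = (counts >= 2).sum(axis=0)
    variable = int((n_distinct >= 2).sum())
    informative = int((n_common >= 2).sum())
    return variable, informative


def write_fasta(aln: LocusAlignment, path: str | Path, width: int = 70) -> None:
    """Write an alignment as wrapped FASTA (round-trips through the reader)."""
    with open(path, "w") as fh:
        for sid, seq in aln.rows.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_popmap(samples: Sequence[SampleRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.taxon}\n")
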