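"""Alignment/metadata I/O and combined-barcode (concatenated) matrices.

The central type is :class:`LabeledAlignment`: an aligned nucleotide matrix
in which every row carries a sample id plus species and genus labels.
Alignments are read from plain aligned FASTA together with a tab-separated
metadata table, and can be concatenated into multi-marker supermatrices over
the intersection of their sample sets, retaining partition boundaries so
positions in a combined matrix can be mapped back to (marker, local column).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from .errors import (
    AlignmentError,
    ConcatenationError,
    InputError,
    MetadataError,
)

#: Permitted residue symbols: the four bases, IUPAC ambiguity codes, gap.
ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

#: Integer codes for unambiguous bases.  Everything else encodes as -1.
#: The code order (A=0, C=1, G=2, T=3) is load-bearing: transitions are
#: exactly the pairs with equal parity (A<->G even, C<->T odd) and the
#: transition partner of ``b`` is ``b ^ 2``.
BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
CODE_BASE = "ACGT"

_ENCODE_TABLE = np.full(256, -1, dtype=np.int8)
for _b, _c in BASE_CODE.items():
    _ENCODE_TABLE[ord(_b)] = _c


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a sequence string as int8 codes (A=0,C=1,G=2,T=3, other=-1)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_TABLE[raw]


def decode_sequence(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence`; code -1 decodes to ``-``."""
    return "".join("-" if c < 0 else CODE_BASE[c] for c in codes)


@dataclass(frozen=True)
class Sample:
    """One aligned row: sample id, taxonomy labels, and its sequence."""

    sample_id: str
    species: str
    genus: str
    sequence: str


@dataclass(frozen=True)
class SampleInfo:
    """Metadata-table row (no sequence)."""

    sample_id: str
    species: str
    genus: str
    origin: str = ""


class LabeledAlignment:
    """An aligned nucleotide matrix with per-row species/genus labels.

    Parameters
    ----------
    marker_name:
        Name of the marker (or ``+``-joined names for a combined matrix).
    samples:
        Ordered rows.  All sequences must have identical length, use only
        IUPAC nucleotide symbols or ``-``, and carry unique sample ids.
    partitions:
        Half-open column ranges ``(marker, start, end)`` (0-based) covering
        the matrix; defaults to a single partition spanning the alignment.
    """

    def __init__(
        self,
        marker_name: str,
        samples: Sequence[Sample],
        partitions: Sequence[tuple[str, int, int]] | None = None,
    ) -> None:
        samples = list(samples)
        if not samples:
            raise AlignmentError(f"{marker_name}: alignment has no sequences")
        length = len(samples[0].sequence)
        seen: set[str] = set()
        for s in samples:
            if len(s.sequence) != length:
                raise AlignmentError(
                    f"{marker_name}: sequence length mismatch for {s.sample_id!r} "
                    f"({len(s.sequence)} != {length})"
                )
            bad = set(s.sequence) - ALPHABET
            if bad:
                raise AlignmentError(
                    f"{marker_name}: illegal symbols {sorted(bad)} in {s.sample_id!r}"
                )
            if s.sample_id in seen:
                raise AlignmentError(
                    f"{marker_name}: duplicate sample id {s.sample_id!r}"
                )
            seen.add(s.sample_id)
        self.marker_name = marker_name
        self.samples = samples
        self._length = length
        if partitions is None:
            partitions = [(marker_name, 0, length)]
        self.partitions = list(partitions)
        self._encoded: np.ndarray | None = None

    # -- basic accessors -------------------------------------------------

    @property
    def length(self) -> int:
        return self._length

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def species_labels(self) -> list[str]:
        return [s.species for s in self.samples]

    @property
    def species_set(self) -> list[str]:
        """Distinct species labels in order of first appearance."""
        out: list[str] = []
        for s in self.samples:
            if s.species not in out:
                out.append(s.species)
        return out

    def species_map(self) -> dict[str, str]:
        return {s.sample_id: s.species for s in self.samples}

    def genus_map(self) -> dict[str, str]:
        return {s.sample_id: s.genus for s in self.samples}

    def encoded(self) -> np.ndarray:
        """Int8 matrix (n_samples x length); ambiguity/gap coded as -1."""
        if self._encoded is None:
            self._encoded = np.vstack(
                [encode_sequence(s.sequence) for s in self.samples]
            )
        return self._encoded

    # -- derived alignments ----------------------------------------------

    def subset(self, sample_ids: Iterable[str]) -> "LabeledAlignment":
        """Row subset in the given order; unknown ids raise MetadataError."""
        by_id = {s.sample_id: s for s in self.samples}
        rows = []
        for sid in sample_ids:
            if sid not in by_id:
                raise MetadataError(
                    f"{self.marker_name}: unknown sample id {sid!r}"
                )
            rows.append(by_id[sid])
        return LabeledAlignment(self.marker_name, rows, self.partitions)

    def drop(self, sample_id: str) -> "LabeledAlignment":
        rows = [s for s in self.samples if s.sample_id != sample_id]
        if len(rows) == len(self.samples):
            raise MetadataError(
                f"{self.marker_name}: unknown sample id {sample_id!r}"
            )
        return LabeledAlignment(self.marker_name, rows, self.partitions)

    def take_columns(
        self, columns: Sequence[int], marker_name: str | None = None
    ) -> "LabeledAlignment":
        """Column subset/resample (used by the bootstrap); drops partitions."""
        cols = list(columns)
        rows = [
            Sample(
                s.sample_id,
                s.species,
                s.genus,
                "".join(s.sequence[c] for c in cols),
            )
            for s in self.samples
        ]
        return LabeledAlignment(marker_name or self.marker_name, rows)

    def map_position(self, position: int) -> tuple[str, int]:
        """Map a 1-based combined-matrix column to (marker, local 1-based)."""
        if not 1 <= position <= self._length:
            raise ValueError(f"position {position} outside [1, {self._length}]")
        col = position - 1
        for marker, start, end in self.partitions:
            if start <= col < end:
                return marker, col - start + 1
        raise ValueError(f"position {position} not covered by partitions")

    # -- output -----------------------------------------------------------

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s in self.samples:
                fh.write(f">{s.sample_id}\n{s.sequence}\n")

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"LabeledAlignment({self.marker_name!r}, n={self.n_samples}, "
            f"length={self._length})"
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> dict[str, SampleInfo]:
    """Read the 4-column sample metadata TSV (header required).

    Columns: ``sample_id``, ``species``, ``genus``, ``origin`` (optional).
    """
    path = Path(path)
    out: dict[str, SampleInfo] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "species", "genus"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise MetadataError(
                f"{path}: metadata must be a TSV with header columns "
                f"sample_id, species, genus[, origin]"
            )
        for row in reader:
            sid = (row["sample_id"] or "").strip()
            species = (row["species"] or "").strip()
            genus = (row["genus"] or "").strip()
            if not sid:
                raise MetadataError(f"{path}: empty sample_id")
            if sid in out:
                raise MetadataError(f"{path}: duplicate sample_id {sid!r}")
            if not species or not genus:
                raise MetadataError(
                    f"{path}: species/genus must be non-empty for {sid!r}"
                )
            out[sid] = SampleInfo(sid, species, genus, (row.get("origin") or "").strip())
    if not out:
        raise MetadataError(f"{path}: metadata table has no rows")
    return out


def read_labeled_fasta(
    fasta_path: str | Path,
    metadata_path: str | Path | Mapping[str, SampleInfo],
    marker_name: str,
) -> LabeledAlignment:
    """Read an aligned FASTA and attach species/genus labels from metadata.

    FASTA record ids must match metadata ``sample_id`` exactly (the record
    description is ignored).  Sequences are uppercased on read.
    """
    if isinstance(metadata_path, (str, Path)):
        meta = read_metadata(metadata_path)
    else:
        meta = dict(metadata_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise InputError(f"{fasta_path}: no FASTA records found")
    rows = []
    for rec in records:
        if rec.id not in meta:
            raise MetadataError(
                f"{fasta_path}: record {rec.id!r} absent from metadata"
            )
        info = meta[rec.id]
        rows.append(
            Sample(rec.id, info.species, info.genus, str(rec.seq).upper())
        )
    return LabeledAlignment(marker_name, rows)


# ---------------------------------------------------------------------------
# concatenation (combined barcodes)
# ---------------------------------------------------------------------------

def concatenate_markers(
    alignments: Sequence[LabeledAlignment],
    order: Sequence[str] | None = None,
) -> LabeledAlignment:
    """Concatenate markers over the intersection of their sample sets.

    The combined sample set is the intersection of all input sample sets
    (samples missing from any marker are dropped), ordered as in the first
    alignment.  Partition boundaries of the inputs are carried through with
    shifted offsets, so rule positions on the combined matrix can be mapped
    back with :meth:`LabeledAlignment.map_position`.
    """
    if len(alignments) < 2:
        raise ConcatenationError("need at least two alignments to concatenate")
    by_name = {a.marker_name: a for a in alignments}
    if len(by_name) != len(alignments):
        raise ConcatenationError("duplicate marker names among inputs")
    if order is None:
        order = [a.marker_name for a in alignments]
    if sorted(order) != sorted(by_name):
        raise ConcatenationError(
            f"order {list(order)} does not cover exactly the given markers "
            f"{sorted(by_name)}"
        )
    ordered = [by_name[name] for name in order]

    shared = set(ordered[0].sample_ids)
    for aln in ordered[1:]:
        shared &= set(aln.sample_ids)
    if not shared:
        raise ConcatenationError(
            "no samples shared by all markers: " + "+".join(order)
        )
    kept = [s for s in ordered[0].samples if s.sample_id in shared]
    if len({s.species for s in kept}) < 2:
        raise ConcatenationError(
            "fewer than two species remain among shared samples"
        )

    parts: list[tuple[str, int, int]] = []
    offset = 0
    for aln in ordered:
        for marker, start, end in aln.partitions:
            parts.append((marker, offset + start, offset + end))
        offset += aln.length

    seq_of = [
        {s.sample_id: s.sequence for s in aln.samples} for aln in ordered
    ]
    rows = [
        Sample(
            s.sample_id,
            s.species,
            s.genus,
            "".join(m[s.sample_id] for m in seq_of),
        )
        for s in kept
    ]
    name = "+".join(order)
    return LabeledAlignment(name, rows, parts)


# ---------------------------------------------------------------------------
# writers (thin wrappers; table writers live in the pipeline module)
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path) -> None:
    """Write a tree in Newick, branch lengths + integer support labels."""
    from .trees import to_newick  # local import avoids a module cycle

    text = to_newick(tree)
    try:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise InputError(f"cannot write {path}: {exc}") from exc


def write_report_tables(bundle, outdir: str | Path) -> None:
    """Write the TSV report tables of a pipeline bundle (see pipeline.py)."""
    from .pipeline import write_report_tables as _write

    _write(bundle, outdir)


@dataclass
class _MetadataWriter:
    """Helper to emit a metadata TSV from SampleInfo rows."""

    rows: list[SampleInfo] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tspecies\tgenus\torigin\n")
            for r in self.rows:
                fh.write(f"{r.sample_id}\t{r.species}\t{r.genus}\t{r.origin}\n")


def write_metadata(rows: Iterable[SampleInfo], path: str | Path) -> None:
    _MetadataWriter(list(rows)).write(path)
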