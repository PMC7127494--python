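"""Aligned-FASTA and specimen-metadata I/O, concatenation of barcode markers.

A dataset couples one gapped multiple alignment (one marker, or a
concatenation of markers) with per-specimen metadata: the species label,
whether the sequence is a *query* (a specimen under study) or a *reference*
(a labelled barcode, e.g. from a public database), and optional locality and
accession bookkeeping.  All coordinates are 0-based half-open internally.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

UNKNOWN = "UNKNOWN"

#: Characters accepted in an aligned sequence after normalisation.
IUPAC_AMBIGUITY = set("RYSWKMBDHVN")
VALID_CHARS = set("ACGT-") | IUPAC_AMBIGUITY


class DataError(ValueError):
    """Malformed input data (ragged alignment, missing metadata, ...)."""


@dataclass(frozen=True)
class SpecimenRecord:
    """Metadata for one sequence in a dataset."""

    specimen_id: str
    species_label: str = UNKNOWN
    role: str = "query"  # "query" | "reference"
    locality: str | None = None
    accession_by_marker: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ("query", "reference"):
            raise DataError(f"{self.specimen_id}: role must be query or reference, got {self.role!r}")
        if self.role == "reference" and self.species_label == UNKNOWN:
            raise DataError(f"{self.specimen_id}: a reference must carry a species label")


@dataclass(frozen=True)
class ConcatenationMap:
    """Column spans of the source markers inside a concatenated alignment."""

    segments: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        pos = 0
        for marker, start, end in self.segments:
            if start != pos or end <= start:
                raise DataError(f"segment {marker}: [{start},{end}) not contiguous from {pos}")
            pos = end

    @property
    def columns(self) -> int:
        return self.segments[-1][2] if self.segments else 0


@dataclass(frozen=True)
class AlignedDataset:
    """Equal-length, labelled sequences for one marker (or a concatenation)."""

    marker: str
    columns: int
    sequences: dict[str, str]  # ordered: insertion order = dataset order
    records: tuple[SpecimenRecord, ...]

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise DataError(f"{self.marker}: need at least 2 sequences, got {len(self.sequences)}")
        by_id = {r.specimen_id for r in self.records}
        for sid, seq in self.sequences.items():
            if len(seq) != self.columns:
                raise DataError(
                    f"{self.marker}: sequence {sid!r} has {len(seq)} columns, expected {self.columns}"
                )
            if sid not in by_id:
                raise DataError(f"{self.marker}: sequence {sid!r} has no metadata record")
            bad = set(seq) - VALID_CHARS
            if bad:
                raise DataError(f"{self.marker}: sequence {sid!r} has invalid characters {sorted(bad)}")
        if len(by_id) != len(self.records):
            raise DataError(f"{self.marker}: duplicate specimen ids in metadata")

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    def record(self, specimen_id: str) -> SpecimenRecord:
        for r in self.records:
            if r.specimen_id == specimen_id:
                return r
        raise KeyError(specimen_id)

    def species_of(self) -> dict[str, str]:
        return {r.specimen_id: r.species_label for r in self.records}

    def subset(self, ids: list[str]) -> "AlignedDataset":
        keep = set(ids)
        return AlignedDataset(
            marker=self.marker,
            columns=self.columns,
            sequences={i: self.sequences[i] for i in ids},
            records=tuple(r for r in self.records if r.specimen_id in keep),
        )


def _normalise(seq: str) -> str:
    return seq.upper().replace("?", "-")


def read_metadata(path) -> dict[str, SpecimenRecord]:
    """Read the tab-delimited metadata table.

    Expected header: specimen_id, species, role, then optional locality and
    accession columns (``accession_<marker>``).  Empty species means UNKNOWN.
    """
    records: dict[str, SpecimenRecord] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for required in ("specimen_id", "species", "role"):
            if required not in idx:
                raise DataError(f"metadata {path}: missing column {required!r}")
        acc_cols = [(h[len("accession_"):], i) for h, i in idx.items() if h.startswith("accession_")]
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            sid = parts[idx["specimen_id"]]
            if sid in records:
                raise DataError(f"metadata {path}:{lineno}: duplicate specimen_id {sid!r}")
            species = parts[idx["species"]].strip() or UNKNOWN
            locality = parts[idx["locality"]] if "locality" in idx and len(parts) > idx["locality"] else None
            accessions = {
                marker: parts[i] for marker, i in acc_cols if len(parts) > i and parts[i].strip()
            }
            records[sid] = SpecimenRecord(
                specimen_id=sid,
                species_label=species,
                role=parts[idx["role"]].strip(),
                locality=locality or None,
                accession_by_marker=accessions,
            )
    return records


def write_metadata(records, path) -> None:
    markers = sorted({m for r in records for m in r.accession_by_marker})
    with open(path, "w") as fh:
        cols = ["specimen_id", "species", "role", "locality"] + [f"accession_{m}" for m in markers]
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [r.specimen_id, r.species_label, r.role, r.locality or ""]
            row += [r.accession_by_marker.get(m, "") for m in markers]
            fh.write("\t".join(row) + "\n")


def read_aligned_fasta(path, metadata, marker: str) -> AlignedDataset:
    """Read an aligned FASTA plus its metadata table into a validated dataset.

    ``metadata`` may be a path to the tab-delimited table or a pre-built
    ``{specimen_id: SpecimenRecord}`` mapping.  The FASTA id is the first
    whitespace-delimited header token.  Lowercase is upper-cased and ``?``
    becomes ``-``; any character outside A/C/G/T, the IUPAC ambiguity codes
    and ``-`` is rejected.
    """
    if not isinstance(metadata, dict):
        metadata = read_metadata(metadata)
    sequences: dict[str, str] = {}
    columns = None
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id
        seq = _normalise(str(rec.seq))
        if columns is None:
            columns = len(seq)
        elif len(seq) != columns:
            raise DataError(
                f"{path}: ragged alignment — {sid!r} has {len(seq)} columns, expected {columns}"
            )
        if sid not in metadata:
            raise DataError(f"{path}: FASTA id {sid!r} absent from metadata")
        sequences[sid] = seq
    if columns is None:
        raise DataError(f"{path}: no FASTA records")
    records = tuple(metadata[sid] for sid in sequences)
    return AlignedDataset(marker=marker, columns=columns, sequences=sequences, records=records)


def write_aligned_fasta(ds: AlignedDataset, path) -> None:
    recs = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in ds.sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta-2line")


def concatenate(
    datasets: list[AlignedDataset], missing: str = "strict"
) -> tuple[AlignedDataset, ConcatenationMap]:
    """Join per-marker alignments into one supermatrix, specimen by specimen.

    ``missing='strict'`` (default) errors if any specimen lacks a marker;
    ``missing='pad'`` fills the absent marker's span with gaps instead.
    """
    if len(datasets) < 2:
        raise DataError("concatenate needs at least 2 datasets")
    if missing not in ("strict", "pad"):
        raise DataError(f"unknown missing-marker policy {missing!r}")

    all_ids: list[str] = []
    seen: set[str] = set()
    for ds in datasets:
        for sid in ds.ids:
            if sid not in seen:
                seen.add(sid)
                all_ids.append(sid)

    if missing == "strict":
        absent = {
            ds.marker: sorted(set(all_ids) - set(ds.ids)) for ds in datasets if set(all_ids) - set(ds.ids)
        }
        if absent:
            detail = "; ".join(f"{m}: {', '.join(ids)}" for m, ids in absent.items())
            raise DataError(f"specimens missing from a marker under strict policy — {detail}")

    merged: dict[str, SpecimenRecord] = {}
    for ds in datasets:
        for r in ds.records:
            prev = merged.get(r.specimen_id)
            if prev is None:
                merged[r.specimen_id] = r
            else:
                if prev.species_label != r.species_label:
                    raise DataError(
                        f"conflicting species for {r.specimen_id!r}: "
                        f"{prev.species_label!r} vs {r.species_label!r}"
                    )
                merged[r.specimen_id] = replace(
                    prev, accession_by_marker={**prev.accession_by_marker, **r.accession_by_marker}
                )

    segments = []
    pos = 0
    for ds in datasets:
        segments.append((ds.marker, pos, pos + ds.columns))
        pos += ds.columns
    cmap = ConcatenationMap(segments=tuple(segments))

    sequences = {
        sid: "".join(ds.sequences.get(sid, "-" * ds.columns) for ds in datasets) for sid in all_ids
    }
    marker = "+".join(ds.marker for ds in datasets)
    out = AlignedDataset(
        marker=marker,
        columns=pos,
        sequences=sequences,
        records=tuple(merged[sid] for sid in all_ids),
    )
    return out, cmap


def slice_by_map(ds: AlignedDataset, cmap: ConcatenationMap, marker: str) -> AlignedDataset:
    """Recover one marker's alignment from a concatenated dataset."""
    for name, start, end in cmap.segments:
        if name == marker:
            return AlignedDataset(
                marker=marker,
                columns=end - start,
                sequences={sid: seq[start:end] for sid, seq in ds.sequences.items()},
                records=ds.records,
            )
    raise KeyError(marker)
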