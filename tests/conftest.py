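import numpy as np
import pytest

from barcodegap.dataio import AlignedDataset, SpecimenRecord


def make_dataset(seq_by_id, species_by_id=None, roles=None, marker="COI"):
    """Small in-memory dataset builder for unit tests."""
    species_by_id = species_by_id or {}
    roles = roles or {}
    records = tuple(
        SpecimenRecord(
            specimen_id=sid,
            species_label=species_by_id.get(sid, "sp1"),
            role=roles.get(sid, "query"),
        )
        for sid in seq_by_id
    )
    columns = len(next(iter(seq_by_id.values())))
    return AlignedDataset(marker=marker, columns=columns, sequences=dict(seq_by_id), records=records)


def write_fasta(path, seq_by_id):
    with open(path, "w") as fh:
        for sid, seq in seq_by_id.items():
            fh.write(f">{sid}\n{seq}\n")


def write_meta(path, rows):
    """rows: iterable of (specimen_id, species, role[, locality])."""
    with open(path, "w") as fh:
        fh.write("specimen_id\tspecies\trole\tlocality\n")
        for row in rows:
            row = tuple(row) + ("",) * (4 - len(row))
            fh.write("\t".join(row) + "\n")


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


@pytest.fixture
def toy_fasta(tmp_path):
    fasta = tmp_path / "toy.fasta"
    meta = tmp_path / "toy.tsv"
    write_fasta(fasta, {"s1": "ACGT", "s2": "ACGA"})
    write_meta(meta, [("s1", "sp1", "query"), ("s2", "sp1", "reference")])
    return fasta, meta
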