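"""Reading and writing the pipeline's on-disk formats.

FASTA (via Biopython), BED6/narrowPeak peak lists, the labeled-dataset
FASTA + TSV sidecar, the JSON dataset manifest, matrix TSVs, MEME minimal
motif files, and the filter-comparison TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dataset import Dataset, DatasetManifest, PeakRecord, SequenceExample
from .interpretation import ComparisonTable, PositionMatrix

__all__ = [
    "read_fasta", "write_fasta",
    "read_peaks", "write_peaks",
    "write_dataset", "read_dataset",
    "write_manifest", "read_manifest",
    "write_matrix_tsv", "read_matrix_tsv",
    "write_meme", "read_meme",
    "write_comparison_tsv",
]


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records),
        str(path), "fasta",
    )


def read_peaks(path) -> list[PeakRecord]:
    """BED6 or ENCODE narrowPeak (BED6+4), told apart by column count."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) not in (6, 10):
                raise ValueError(
                    f"expected 6 (BED6) or 10 (narrowPeak) columns, got {len(fields)}"
                )
            summit = None
            if len(fields) == 10:
                s = int(fields[9])
                summit = s if s >= 0 else None
            peaks.append(PeakRecord(
                chrom=fields[0], start=int(fields[1]), end=int(fields[2]),
                name=fields[3], score=float(fields[4]), summit_offset=summit,
            ))
    return peaks


def write_peaks(peaks: list[PeakRecord], path) -> None:
    """narrowPeak (BED6+4): strand '.', signalValue = score, p/q = -1,
    summit -1 unless recorded."""
    with open(path, "w") as fh:
        for p in peaks:
            summit = -1 if p.summit_offset is None else p.summit_offset
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:g}\t.\t"
                f"{p.score:g}\t-1\t-1\t{summit}\n"
            )


def write_dataset(dataset: Dataset, fasta_path, tsv_path) -> None:
    write_fasta([(e.name, e.sequence) for e in dataset.examples], fasta_path)
    with open(tsv_path, "w") as fh:
        fh.write("name\tlabel\tsplit\tprovenance\n")
        for e in dataset.examples:
            fh.write(f"{e.name}\t{e.label}\t{e.split}\t{e.provenance}\n")


def read_dataset(fasta_path, tsv_path) -> Dataset:
    seqs = dict(read_fasta(fasta_path))
    examples = []
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        assert header == ["name", "label", "split", "provenance"]
        for line in fh:
            name, label, split, provenance = line.rstrip("\n").split("\t")
            examples.append(SequenceExample(
                sequence=seqs[name], label=int(label),
                provenance=provenance, name=name, split=split,
            ))
    return Dataset(examples)


def write_manifest(manifest: DatasetManifest, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=2)


def read_manifest(path) -> DatasetManifest:
    with open(path) as fh:
        return DatasetManifest.from_dict(json.load(fh))


def write_matrix_tsv(matrix: PositionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# form: {matrix.form}\n")
        fh.write("base\t" + "\t".join(str(j) for j in range(matrix.width)) + "\n")
        for base, row in zip("ACGT", matrix.values):
            fh.write(base + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_matrix_tsv(path) -> PositionMatrix:
    with open(path) as fh:
        form = fh.readline().split(":")[1].strip()
        fh.readline()  # header
        rows = [list(map(float, fh.readline().split("\t")[1:])) for _ in range(4)]
    values = np.array(rows)
    if form == "probability":
        values = values / values.sum(axis=0, keepdims=True)  # undo rounding drift
    return PositionMatrix(values, form=form)


def write_meme(motifs: dict[str, PositionMatrix], path,
               background=(0.25, 0.25, 0.25, 0.25)) -> None:
    """MEME minimal motif format; probability-form matrices only."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*background))
        for name, m in motifs.items():
            if m.form != "probability":
                raise ValueError(f"motif {name}: MEME stores probability matrices")
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} "
                     f"nsites= 20 E= 0\n")
            for col in m.values.T:
                fh.write(" " + " ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def read_meme(path) -> dict[str, PositionMatrix]:
    motifs: dict[str, PositionMatrix] = {}
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if lines[i].startswith("MOTIF"):
            name = lines[i].split()[1]
            i += 1
            while not lines[i].startswith("letter-probability"):
                i += 1
            width = int(lines[i].split("w=")[1].split()[0])
            cols = []
            for j in range(width):
                cols.append([float(v) for v in lines[i + 1 + j].split()])
            i += width
            values = np.array(cols).T
            values = values / values.sum(axis=0, keepdims=True)
            motifs[name] = PositionMatrix(values, form="probability")
        i += 1
    return motifs


def write_comparison_tsv(tables: list[ComparisonTable], path,
                         name_a: str = "filter_a", name_b: str = "filter_b") -> None:
    with open(path, "w") as fh:
        fh.write(f"set\tn_sequences\tn_wins_{name_a}\tn_wins_{name_b}\tn_ties\n")
        for t in tables:
            fh.write(f"{t.set_label}\t{t.n_sequences}\t{t.n_wins_a}\t{t.n_wins_b}\t{t.n_ties}\n")
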