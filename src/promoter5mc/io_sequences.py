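"""Sequence I/O and strand-aware window extraction.

Candidate 5mC sites are cytosines on the forward strand or guanines on the
reverse strand; a candidate is represented by the fixed-length window of
2*delta + 1 nucleotides centred on it.  Reverse-strand windows are
reverse-complemented so that the central base of every emitted window is C,
while recorded coordinates always refer to the original input sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .exceptions import (
    BoundaryError,
    FastaFormatError,
    StratificationError,
    ValidationError,
)

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _validate_alphabet(seq: str, context: str = "sequence") -> None:
    for offset, base in enumerate(seq):
        if base not in DNA_ALPHABET:
            raise ValidationError(
                f"illegal character {base!r} at offset {offset} in {context}; "
                "allowed alphabet is A/C/G/T/N"
            )


@dataclass
class SequenceRecord:
    """A named DNA sequence with a declared strand.

    The sequence is upper-cased on construction; soft-masked (lower-case)
    input is treated as ordinary sequence, not as masked.
    """

    id: str
    seq: str
    strand: str = "+"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValidationError(f"record {self.id!r} has an empty sequence")
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"record {self.id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        _validate_alphabet(self.seq, context=f"record {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Sample:
    """One candidate site: a (2*delta+1)-nt window with a central cytosine.

    ``center_pos`` is the 0-based position of the candidate base in the
    original, un-complemented source sequence (a C on '+', a G on '-').
    ``label`` is 1 for a methylated (true 5mC) site, 0 for an unmethylated
    one, and None for an unlabeled prediction-time candidate.
    """

    window: str
    delta: int
    label: int | None = None
    source_id: str = ""
    center_pos: int = -1
    source_strand: str = "+"

    def __post_init__(self) -> None:
        self.window = self.window.upper()
        if self.delta < 1:
            raise ValidationError(f"delta must be >= 1, got {self.delta}")
        if len(self.window) != 2 * self.delta + 1:
            raise ValidationError(
                f"window length {len(self.window)} != 2*delta+1 = {2 * self.delta + 1}"
            )
        _validate_alphabet(self.window, context=f"window from {self.source_id!r}")
        if self.window[self.delta] != "C":
            raise ValidationError(
                f"central base must be 'C' after strand normalization, "
                f"got {self.window[self.delta]!r}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValidationError(f"label must be 0, 1 or None, got {self.label!r}")

    @property
    def contains_n(self) -> bool:
        """True when the window contains an ambiguous base."""
        return "N" in self.window


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A<->T, C<->G, N<->N)."""
    seq = seq.upper()
    _validate_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path, strand: str = "+") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, all tagged with ``strand``.

    Raises FileNotFoundError for a missing file, FastaFormatError for an
    empty or malformed file, ValidationError for characters outside
    A/C/G/T/N (naming the record and offset).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    text = path.read_text()
    if not text.strip():
        raise FastaFormatError(f"empty FASTA file: {path}")
    if not text.lstrip().startswith(">"):
        raise FastaFormatError(f"malformed FASTA (no '>' header): {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FastaFormatError(f"record {rec.id!r} in {path} has no sequence")
        records.append(SequenceRecord(id=rec.id, seq=str(rec.seq), strand=strand))
    if not records:
        raise FastaFormatError(f"no FASTA records parsed from {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(rec.seq[i : i + 70] + "\n")


def extract_window(
    record: SequenceRecord, center: int, delta: int, pad_n: bool = False
) -> Sample:
    """Extract the (2*delta+1)-window around a candidate base.

    On the '+' strand the base at ``center`` must be C; on the '-' strand it
    must be G and the window is reverse-complemented so its centre becomes C.
    With ``pad_n`` the window may overhang the sequence and is filled with N;
    otherwise an overhang raises BoundaryError.
    """
    seq = record.seq
    expected = "C" if record.strand == "+" else "G"
    if not 0 <= center < len(seq):
        raise BoundaryError(
            f"center {center} outside sequence {record.id!r} of length {len(seq)}"
        )
    if seq[center] != expected:
        raise ValidationError(
            f"record {record.id!r} position {center}: expected {expected!r} on "
            f"strand {record.strand}, found {seq[center]!r}"
        )
    lo, hi = center - delta, center + delta + 1
    if lo < 0 or hi > len(seq):
        if not pad_n:
            raise BoundaryError(
                f"window [{lo}, {hi}) overhangs sequence {record.id!r} "
                f"of length {len(seq)}"
            )
        window = "N" * max(0, -lo) + seq[max(lo, 0) : min(hi, len(seq))] + "N" * max(
            0, hi - len(seq)
        )
    else:
        window = seq[lo:hi]
    if record.strand == "-":
        window = reverse_complement(window)
    return Sample(
        window=window,
        delta=delta,
        source_id=record.id,
        center_pos=center,
        source_strand=record.strand,
    )


def scan_candidates(
    record: SequenceRecord, delta: int, pad_n: bool = False
) -> list[Sample]:
    """Emit one unlabeled Sample per eligible candidate site in the record.

    Eligible candidates are every C ('+' strand) or G ('-' strand) at least
    ``delta`` bases from both sequence ends (all positions when ``pad_n``),
    ordered by center_pos ascending.  Windows containing N are kept and can
    be recognised via ``Sample.contains_n``.
    """
    if delta < 1:
        raise ValidationError(f"delta must be >= 1, got {delta}")
    target = "C" if record.strand == "+" else "G"
    lo = 0 if pad_n else delta
    hi = len(record.seq) if pad_n else len(record.seq) - delta
    return [
        extract_window(record, i, delta, pad_n=pad_n)
        for i in range(lo, hi)
        if record.seq[i] == target
    ]


def split_dataset(
    samples: Sequence[Sample], train_fraction: float = 0.8, seed: int = 0
) -> tuple[list[Sample], list[Sample]]:
    """Stratified train/test split of labeled samples.

    Each class is split independently: the train count is the class size
    times ``train_fraction`` rounded to the nearest integer.  Deterministic
    given ``seed``; train and test are disjoint and their union is the input.
    """
    if not 0 < train_fraction < 1:
        raise ValidationError(f"train_fraction must be in (0,1), got {train_fraction}")
    labels = [s.label for s in samples]
    if any(lab is None for lab in labels):
        raise ValidationError("split_dataset requires labeled samples")
    rng = np.random.default_rng(seed)
    train: list[Sample] = []
    test: list[Sample] = []
    for cls in sorted(set(labels)):
        idx = np.flatnonzero(np.asarray(labels) == cls)
        if len(idx) < 2:
            raise StratificationError(
                f"class {cls} has {len(idx)} sample(s); need >= 2 to split"
            )
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))
        perm = rng.permutation(idx)
        train.extend(samples[i] for i in perm[:n_train])
        test.extend(samples[i] for i in perm[n_train:])
    return train, test


def read_sample_tsv(path: str | Path, delta: int | None = None) -> list[Sample]:
    """Read a labeled sample table (columns: window, label)."""
    df = pd.read_csv(path, sep="\t", dtype={"window": str})
    if "window" not in df.columns:
        raise ValidationError(f"{path}: expected a 'window' column")
    samples = []
    for i, row in enumerate(df.itertuples(index=False)):
        window = str(row.window)
        d = delta if delta is not None else (len(window) - 1) // 2
        label = int(row.label) if "label" in df.columns and not pd.isna(row.label) else None
        samples.append(Sample(window=window, delta=d, label=label, source_id=f"row{i}"))
    return samples


def write_sample_tsv(samples: Iterable[Sample], path: str | Path) -> None:
    df = pd.DataFrame(
        {"window": [s.window for s in samples], "label": [s.label for s in samples]}
    )
    df.to_csv(path, sep="\t", index=False)


def write_bed(
    calls: Iterable[tuple[Sample, float, int]], path: str | Path
) -> None:
    """Write per-site calls as BED6 (half-open, 0-based coordinates).

    ``calls`` yields (sample, fused_score, decision); the BED score column
    carries the fused score scaled to 0-1000.
    """
    with open(path, "w") as fh:
        for sample, score, decision in calls:
            fh.write(
                "\t".join(
                    [
                        sample.source_id,
                        str(sample.center_pos),
                        str(sample.center_pos + 1),
                        f"5mC_call={decision}",
                        str(int(round(1000 * score))),
                        sample.source_strand,
                    ]
                )
                + "\n"
            )
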