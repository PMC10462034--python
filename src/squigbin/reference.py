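"""Binned, shredded, class-labeled reference texts.

Each FASTA record is converted, on both strands, to its expected current
trace, quantized to bin symbols and run-compressed; the per-strand bin
sequences are concatenated with one terminator per strand-sequence into
the reference text.  Positions of the text are partitioned into
equal-length "shreds", each carrying a document id and a class label,
which is what match positions are later attributed to.

K-mers containing ambiguous bases (N) are rendered as a sentinel symbol
outside the bin alphabet so they can never match a query.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from squigbin.pore_model import BinningConfig, BinSequence, PoreModel, expected_signal
from squigbin.signal import compress_runs

#: internal text alphabet: terminator < bins < sentinel
TERMINATOR = 0

DEFAULT_SHRED_SIZE = 100_000  # symbols; sub-genome locality without index blowup


@dataclass
class StrandBinSeq:
    """One strand of one reference record, rendered over the bin alphabet.

    ``symbols`` are external bin symbols in [0, n_bins-1] plus possibly
    the sentinel value n_bins at ambiguous-base k-mers.
    """

    ref_name: str
    class_label: str
    strand: str  # '+' or '-'
    symbols: np.ndarray

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int16)


@dataclass
class ShredTable:
    """Equal-length reference partitions with document ids and class labels.

    Rows are ordered, disjoint, half-open intervals in concatenated
    bin-text coordinates, covering every non-terminator position.
    Reverse-strand rows share the doc_id of the mirrored forward shred
    so votes aggregate per locus; doc_ids are unique among '+' rows.
    """

    doc_id: np.ndarray
    ref_name: list[str]
    class_label: list[str]
    start: np.ndarray
    end: np.ndarray
    strand: list[str]
    shred_size: int = DEFAULT_SHRED_SIZE

    def __post_init__(self) -> None:
        self.doc_id = np.asarray(self.doc_id, dtype=np.int64)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)

    def __len__(self) -> int:
        return int(self.doc_id.size)

    def row_of_position(self, pos: int) -> int:
        """Row index of the shred containing text position ``pos`` (-1 if none)."""
        i = int(np.searchsorted(self.start, pos, side="right")) - 1
        if i < 0 or pos >= self.end[i]:
            return -1
        return i

    def doc_of_position(self, pos: int) -> int:
        i = self.row_of_position(pos)
        return int(self.doc_id[i]) if i >= 0 else -1

    def doc_meta(self) -> dict[int, tuple[str, str]]:
        """doc_id -> (ref_name, class_label), taken from forward rows."""
        meta: dict[int, tuple[str, str]] = {}
        for i in range(len(self)):
            d = int(self.doc_id[i])
            if d not in meta or self.strand[i] == "+":
                meta[d] = (self.ref_name[i], self.class_label[i])
        return meta

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "doc_id": self.doc_id,
                "ref_name": self.ref_name,
                "class": self.class_label,
                "start": self.start,
                "end": self.end,
                "strand": self.strand,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, shred_size: int = DEFAULT_SHRED_SIZE) -> "ShredTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            doc_id=df["doc_id"].to_numpy(),
            ref_name=df["ref_name"].astype(str).tolist(),
            class_label=df["class"].astype(str).tolist(),
            start=df["start"].to_numpy(),
            end=df["end"].to_numpy(),
            strand=df["strand"].astype(str).tolist(),
            shred_size=shred_size,
        )


@dataclass
class ReferenceText:
    """The concatenated binned reference plus its shred table and class map."""

    strands: list[StrandBinSeq]
    shred_table: ShredTable
    class_map: dict[str, str]  # class label -> {positive | null | plain}
    n_bins: int

    @property
    def sentinel(self) -> int:
        """External sentinel symbol for ambiguous-base k-mers."""
        return self.n_bins

    @property
    def internal_alphabet_size(self) -> int:
        # terminator + n_bins bin symbols + sentinel
        return self.n_bins + 2

    def text(self) -> np.ndarray:
        """Internal integer text: bins shifted +1, terminator 0 appended per strand.

        The terminator is lexicographically smallest and never occurs
        inside a bin sequence; the sentinel (n_bins + 1 internally)
        never matches a query symbol.
        """
        parts: list[np.ndarray] = []
        for s in self.strands:
            parts.append(s.symbols.astype(np.int64) + 1)
            parts.append(np.array([TERMINATOR], dtype=np.int64))
        if not parts:
            raise ValueError("empty reference text")
        return np.concatenate(parts)

    def strand_offsets(self) -> list[int]:
        """Start offset of each strand-sequence in text coordinates."""
        offs, pos = [], 0
        for s in self.strands:
            offs.append(pos)
            pos += s.symbols.size + 1  # + terminator
        return offs

    def doc_of_positions(self) -> np.ndarray:
        """Per-text-position doc_id (terminators get -1)."""
        n = sum(s.symbols.size + 1 for s in self.strands)
        docs = np.full(n, -1, dtype=np.int64)
        t = self.shred_table
        for i in range(len(t)):
            docs[t.start[i]:t.end[i]] = t.doc_id[i]
        return docs


def bin_sequence(seq: str, model: PoreModel, cfg: BinningConfig) -> np.ndarray:
    """expected_signal -> quantize (with sentinel at NaN) -> HPC, one strand."""
    levels = expected_signal(seq, model)
    nan = np.isnan(levels)
    b = np.floor((np.where(nan, cfg.min_p, levels) - cfg.min_p) / cfg.sp)
    b = np.clip(b, 0, cfg.n_bins - 1).astype(np.int16)
    b[nan] = cfg.n_bins  # sentinel, never matches a query symbol
    return compress_runs(BinSequence(b)).symbols


def _mirror_doc(local_mid: float, own_len: int, fwd_starts: np.ndarray,
                fwd_docs: np.ndarray, fwd_len: int) -> int:
    """Doc id of the forward shred mirroring a reverse-strand coordinate.

    HPC makes exact nucleotide correspondence between strands
    unavailable, so the mapping is proportional in post-HPC coordinates.
    """
    frac = 1.0 - local_mid / max(own_len, 1)
    pos = min(int(frac * fwd_len), fwd_len - 1)
    i = int(np.searchsorted(fwd_starts, pos, side="right")) - 1
    return int(fwd_docs[max(i, 0)])


def build_reference(fastas: Sequence[tuple[str | Path, str]], model: PoreModel,
                    cfg: BinningConfig, shred_size: int = DEFAULT_SHRED_SIZE,
                    include_reverse: bool = True,
                    class_roles: dict[str, str] | None = None) -> ReferenceText:
    """Build the binned, shredded reference from labeled FASTA files.

    ``fastas`` is a list of (path, class_label).  Every record
    contributes its forward strand and (by default) its reverse
    complement; both carry the record's class label, and reverse-strand
    shreds share the doc_id of the mirrored forward region.  Records
    shorter than k are skipped with a warning.
    """
    strands: list[StrandBinSeq] = []
    per_record: list[tuple[int, int | None]] = []  # (fwd strand idx, rev strand idx)
    classes_seen: set[str] = set()
    for path, class_label in fastas:
        if not str(class_label):
            raise ValueError(f"empty class label for {path}")
        n_records = 0
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper()
            if len(seq) < model.k:
                warnings.warn(
                    f"record {rec.id} shorter than k={model.k}; skipped",
                    stacklevel=2,
                )
                continue
            n_records += 1
            classes_seen.add(class_label)
            fwd = bin_sequence(seq, model, cfg)
            i_fwd = len(strands)
            strands.append(StrandBinSeq(rec.id, class_label, "+", fwd))
            if include_reverse:
                rev = bin_sequence(str(Seq(seq).reverse_complement()), model, cfg)
                strands.append(StrandBinSeq(rec.id, class_label, "-", rev))
                per_record.append((i_fwd, i_fwd + 1))
            else:
                per_record.append((i_fwd, None))
        if n_records == 0:
            raise ValueError(f"FASTA {path} contains no usable records")
    if not strands:
        raise ValueError("no reference sequences provided")

    # shred assignment in concatenated text coordinates
    offsets: list[int] = []
    pos = 0
    for s in strands:
        offsets.append(pos)
        pos += s.symbols.size + 1

    doc_ids: list[int] = []
    names: list[str] = []
    labels: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strand_col: list[str] = []
    next_doc = 0
    for i_fwd, i_rev in per_record:
        fwd = strands[i_fwd]
        n_fwd = fwd.symbols.size
        fwd_shred_starts = np.arange(0, n_fwd, shred_size, dtype=np.int64)
        fwd_docs = np.arange(next_doc, next_doc + fwd_shred_starts.size, dtype=np.int64)
        next_doc += fwd_shred_starts.size
        for j, s0 in enumerate(fwd_shred_starts):
            doc_ids.append(int(fwd_docs[j]))
            names.append(fwd.ref_name)
            labels.append(fwd.class_label)
            starts.append(offsets[i_fwd] + int(s0))
            ends.append(offsets[i_fwd] + int(min(s0 + shred_size, n_fwd)))
            strand_col.append("+")
        if i_rev is not None:
            rev = strands[i_rev]
            n_rev = rev.symbols.size
            for s0 in range(0, n_rev, shred_size):
                e0 = min(s0 + shred_size, n_rev)
                d = _mirror_doc((s0 + e0) / 2.0, n_rev, fwd_shred_starts,
                                fwd_docs, n_fwd)
                doc_ids.append(d)
                names.append(rev.ref_name)
                labels.append(rev.class_label)
                starts.append(offsets[i_rev] + s0)
                ends.append(offsets[i_rev] + e0)
                strand_col.append("-")

    table = ShredTable(
        doc_id=np.array(doc_ids), ref_name=names, class_label=labels,
        start=np.array(starts), end=np.array(ends), strand=strand_col,
        shred_size=shred_size,
    )
    roles = dict(class_roles or {})
    class_map = {c: roles.get(c, "plain") for c in sorted(classes_seen)}
    return ReferenceText(strands=strands, shred_table=table,
                         class_map=class_map, n_bins=cfg.n_bins)


# ---------------------------------------------------------------------------
# binned FASTA round trip

_ASCII_OFFSET = 33  # '!'; symbol s encodes to chr(33 + s)


def write_binned_fasta(ref: ReferenceText, path: str | Path) -> None:
    """Write the binned reference as printable-ASCII FASTA.

    One record per strand-sequence; terminators are not written (record
    boundaries encode them).  Header: ``name|strand|class``.
    """
    if ref.n_bins + 1 > 126 - _ASCII_OFFSET:
        raise ValueError("alphabet too large for printable ASCII encoding")
    with open(path, "w") as fh:
        for s in ref.strands:
            fh.write(f">{s.ref_name}|{s.strand}|{s.class_label}\n")
            chars = (s.symbols.astype(np.int32) + _ASCII_OFFSET).astype(np.uint8)
            line = chars.tobytes().decode("ascii")
            for i in range(0, len(line), 80):
                fh.write(line[i:i + 80] + "\n")


def read_binned_fasta(path: str | Path) -> list[StrandBinSeq]:
    """Read strand bin sequences written by :func:`write_binned_fasta`."""
    out: list[StrandBinSeq] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            name, strand, label = rec.id.split("|")
        except ValueError:
            name, strand, label = rec.id, "+", "unknown"
        raw = np.frombuffer(str(rec.seq).encode("ascii"), dtype=np.uint8)
        out.append(StrandBinSeq(name, label, strand,
                                raw.astype(np.int16) - _ASCII_OFFSET))
    return out
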