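"""Alignment reading, reference projection, labels and column frequencies.

The pipeline consumes an existing multiple sequence alignment of a
protein family (aligned FASTA or Stockholm) together with a table that
labels each sequence thermophilic, mesophilic or unknown.  All
statistics downstream are computed on the alignment *projected onto a
reference sequence*: only columns where the reference carries a residue
are kept, and positions are numbered 1..N along the ungapped reference,
so that mutation proposals can be written in the familiar
wild-type+position notation (S41, R206, ...).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO

from .alphabet import ALPHABET, GAP, GAP_INDEX, N_SYMBOLS, NONSTANDARD, SYMBOL_INDEX

logger = logging.getLogger("thermosector")

THERMOPHILIC = "thermophilic"
MESOPHILIC = "mesophilic"
UNKNOWN = "unknown"
VALID_LABELS = frozenset({THERMOPHILIC, MESOPHILIC, UNKNOWN})
_LABEL_SYNONYMS = {"unrecognized": UNKNOWN, "unknown": UNKNOWN,
                   "thermophilic": THERMOPHILIC, "mesophilic": MESOPHILIC}

#: minimum number of sequences for a labeled sub-alignment to be usable
MIN_SUBSET_SIZE = 5


@dataclass
class Alignment:
    """A residue matrix over the 20-amino-acid + gap alphabet.

    ``codes`` holds alphabet indices (uint8, M x C); ``source_columns``
    remembers which columns of the originally read alignment each
    current column came from, so projections stay traceable.
    """

    sequence_ids: list[str]
    codes: np.ndarray
    source_columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D matrix")
        m, c = self.codes.shape
        if m < 2:
            raise ValueError(f"alignment needs at least 2 sequences, got {m}")
        if c < 1:
            raise ValueError("alignment has no columns")
        if len(self.sequence_ids) != m:
            raise ValueError("sequence_ids length does not match matrix rows")
        dup = [s for s, n in Counter(self.sequence_ids).items() if n > 1]
        if dup:
            raise ValueError(f"duplicate sequence ids: {dup}")
        if self.codes.max(initial=0) >= N_SYMBOLS:
            raise ValueError("codes contain symbols outside the alphabet")
        if not self.source_columns:
            self.source_columns = list(range(c))
        if len(self.source_columns) != c:
            raise ValueError("source_columns length does not match columns")

    @property
    def n_sequences(self) -> int:
        return self.codes.shape[0]

    @property
    def n_columns(self) -> int:
        return self.codes.shape[1]

    def row(self, sequence_id: str) -> str:
        i = self.sequence_ids.index(sequence_id)
        return "".join(ALPHABET[c] for c in self.codes[i])

    def residues(self) -> np.ndarray:
        """The M x C matrix as one-character strings."""
        return np.array([list(ALPHABET)], dtype="U1")[0][self.codes]

    def take_rows(self, row_idx: np.ndarray | list[int],
                  ids: list[str]) -> "Alignment":
        return Alignment(ids, self.codes[np.asarray(row_idx)],
                         list(self.source_columns))


@dataclass(frozen=True)
class ReferenceMap:
    """1-based residue numbering of the ungapped reference sequence."""

    reference_id: str
    ref_positions: tuple[int, ...]
    column_of_position: dict[int, int]
    ref_residues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        pos = self.ref_positions
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("ref_positions must be strictly increasing")
        if set(pos) != set(self.column_of_position):
            raise ValueError("column mapping must cover exactly ref_positions")
        cols = list(self.column_of_position.values())
        if len(set(cols)) != len(cols):
            raise ValueError("column mapping must be injective")

    @property
    def n_positions(self) -> int:
        return len(self.ref_positions)


@dataclass
class LabelTable:
    """Thermal-class label for every sequence id."""

    label_of: dict[str, str]

    def __post_init__(self) -> None:
        bad = {s: l for s, l in self.label_of.items() if l not in VALID_LABELS}
        if bad:
            raise ValueError(f"labels outside {sorted(VALID_LABELS)}: {bad}")

    def ids_with(self, label: str) -> list[str]:
        return [s for s, l in self.label_of.items() if l == label]


@dataclass(frozen=True)
class FrequencyProfile:
    """Symbol fractions of one reference position (20 aa + gap)."""

    position: int
    freqs: np.ndarray
    support: int

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (N_SYMBOLS,):
            raise ValueError("freqs must have 21 components")
        if (f < 0).any() or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("freqs must be a probability vector")
        object.__setattr__(self, "freqs", f)


def _normalize_sequence(seq_id: str, seq: str, dropped: Counter) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.uint8)
    for j, ch in enumerate(seq.upper()):
        if ch in (".", "-"):
            out[j] = GAP_INDEX
        elif ch in NONSTANDARD:
            dropped[ch] += 1
            out[j] = GAP_INDEX
        else:
            idx = SYMBOL_INDEX.get(ch)
            if idx is None:
                raise ValueError(
                    f"sequence {seq_id!r}: unparseable symbol {ch!r}")
            out[j] = idx
    return out


def read_alignment(path: str | Path, format: str | None = None) -> Alignment:
    """Read an aligned FASTA or Stockholm file into an :class:`Alignment`.

    Symbols are uppercased; ``-`` and ``.`` become the gap symbol;
    ambiguity / non-standard codes (B, J, Z, X, U, O) are normalized to
    gap with a logged count.  Ragged rows are a hard error naming the
    offending sequence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "stockholm" if path.suffix.lower() in (".sto", ".stk", ".stockholm") else "fasta"
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {format!r}")
    try:
        msa = AlignIO.read(str(path), format)
    except ValueError as exc:
        # Biopython raises on ragged FASTA "alignments" and empty files;
        # re-raise with the filename and, where possible, the culprit id.
        raise ValueError(f"{path}: not a valid {format} alignment ({exc})") from exc
    if len(msa) == 0:
        raise ValueError(f"{path}: empty alignment")
    dropped: Counter = Counter()
    ids = [rec.id for rec in msa]
    width = msa.get_alignment_length()
    for rec in msa:
        if len(rec.seq) != width:
            raise ValueError(f"{path}: ragged row for sequence {rec.id!r}")
    codes = np.vstack([_normalize_sequence(rec.id, str(rec.seq), dropped)
                       for rec in msa])
    if dropped:
        logger.warning("normalized non-standard symbols to gap: %s",
                       dict(dropped))
    return Alignment(ids, codes)


def write_alignment_fasta(aln: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(aln.sequence_ids, aln.codes):
            fh.write(f">{sid}\n")
            fh.write("".join(ALPHABET[c] for c in row) + "\n")


def project_to_reference(aln: Alignment, reference_id: str
                         ) -> tuple[Alignment, ReferenceMap]:
    """Keep only columns where the reference sequence carries a residue.

    The surviving columns are numbered 1..N in reference residue order;
    projecting an already-projected alignment is the identity.
    """
    if reference_id not in aln.sequence_ids:
        raise ValueError(f"reference id {reference_id!r} not in alignment")
    ref_row = aln.codes[aln.sequence_ids.index(reference_id)]
    keep = np.flatnonzero(ref_row != GAP_INDEX)
    if keep.size == 0:
        raise ValueError(f"reference {reference_id!r} is all gaps")
    projected = Alignment(
        list(aln.sequence_ids),
        aln.codes[:, keep],
        [aln.source_columns[j] for j in keep],
    )
    positions = tuple(range(1, keep.size + 1))
    refmap = ReferenceMap(
        reference_id=reference_id,
        ref_positions=positions,
        column_of_position={p: j for p, j in zip(positions, range(keep.size))},
        ref_residues=tuple(ALPHABET[ref_row[j]] for j in keep),
    )
    return projected, refmap


def write_reference_map_tsv(refmap: ReferenceMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_position\talignment_column\tref_residue\n")
        for p in refmap.ref_positions:
            res = refmap.ref_residues[p - 1] if refmap.ref_residues else "?"
            fh.write(f"{p}\t{refmap.column_of_position[p]}\t{res}\n")


def attach_labels(aln: Alignment, table_path: str | Path) -> LabelTable:
    """Read a two-column TSV (sequence_id, label) and validate it.

    Labels are case-insensitive; "unrecognized" is stored as unknown.
    Alignment ids missing from the table default to unknown (logged);
    conflicting duplicate rows and labels outside the closed set are
    hard errors with line numbers.
    """
    table_path = Path(table_path)
    seen: dict[str, str] = {}
    with open(table_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["sequence_id", "label"]:
            raise ValueError(
                f"{table_path}: header must start with sequence_id<TAB>label")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{table_path}:{lineno}: expected 2 columns")
            sid, raw = parts[0], parts[1].strip().lower()
            label = _LABEL_SYNONYMS.get(raw)
            if label is None:
                raise ValueError(
                    f"{table_path}:{lineno}: label {parts[1]!r} outside "
                    f"{{thermophilic, mesophilic, unknown/unrecognized}}")
            if sid in seen and seen[sid] != label:
                raise ValueError(
                    f"{table_path}:{lineno}: conflicting duplicate label for {sid!r}")
            seen[sid] = label
    labels: dict[str, str] = {}
    missing = []
    for sid in aln.sequence_ids:
        if sid in seen:
            labels[sid] = seen[sid]
        else:
            labels[sid] = UNKNOWN
            missing.append(sid)
    if missing:
        logger.warning("%d sequences missing from label table default to "
                       "unknown (e.g. %s)", len(missing), missing[:5])
    return LabelTable(labels)


def subset_by_label(aln: Alignment, labels: LabelTable, which: str,
                    min_subset_size: int = MIN_SUBSET_SIZE,
                    exclude_ids: set[str] | None = None) -> Alignment:
    """Row-subset the alignment to sequences carrying one thermal label.

    ``exclude_ids`` removes e.g. the reference/target sequence, which
    plays no statistical role.  Fewer than ``min_subset_size`` matching
    sequences is a hard error: entropy profiles over a handful of
    sequences are meaningless.
    """
    if which not in VALID_LABELS:
        raise ValueError(f"unknown label {which!r}")
    exclude_ids = exclude_ids or set()
    idx = [i for i, sid in enumerate(aln.sequence_ids)
           if labels.label_of.get(sid) == which and sid not in exclude_ids]
    if len(idx) < min_subset_size:
        raise ValueError(
            f"only {len(idx)} sequences labeled {which!r}; "
            f"at least {min_subset_size} required")
    return aln.take_rows(idx, [aln.sequence_ids[i] for i in idx])


def symbol_count_matrix(aln: Alignment) -> np.ndarray:
    """C x 21 matrix of symbol counts per column."""
    counts = np.zeros((aln.n_columns, N_SYMBOLS), dtype=np.int64)
    for s in range(N_SYMBOLS):
        counts[:, s] = (aln.codes == s).sum(axis=0)
    return counts


def column_frequencies(aln: Alignment, position: int,
                       refmap: ReferenceMap) -> FrequencyProfile:
    """Symbol fractions (including gap) at one reference position."""
    if position not in refmap.column_of_position:
        raise ValueError(f"position {position} not in reference map")
    col = aln.codes[:, refmap.column_of_position[position]]
    counts = np.bincount(col, minlength=N_SYMBOLS).astype(float)
    return FrequencyProfile(position, counts / len(col), len(col))


__all__ = [
    "Alignment", "ReferenceMap", "LabelTable", "FrequencyProfile",
    "read_alignment", "write_alignment_fasta", "project_to_reference",
    "write_reference_map_tsv", "attach_labels", "subset_by_label",
    "column_frequencies", "symbol_count_matrix",
    "THERMOPHILIC", "MESOPHILIC", "UNKNOWN", "MIN_SUBSET_SIZE",
]
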