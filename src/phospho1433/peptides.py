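"""Phosphopeptide windows, FASTA/TSV adapters and the shared residue alphabet.

The unit of analysis throughout the package is a short Ser/Thr-centred
sequence window: ``left`` residues before the phosphoacceptor, the
phosphoacceptor itself and ``right`` residues after it.  Window positions
that fall outside the protein are padded with ``X``, and ``X`` also absorbs
every non-standard residue code (B, Z, U, O, J, gaps), so the working
alphabet has 21 symbols.

Coordinates are 1-based and inclusive, following the UniProt /
PhosphoSitePlus convention: a window ``[-a:+b]`` around position ``p``
covers residues ``p-a .. p+b``.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids in the fixed ordering used by every encoding
#: in this package (one-hot vectors, frequency-matrix rows).
AA20 = "ARNDCQEGHILKMFPSTWYV"

#: 21-symbol alphabet: the 20 standard residues plus 'X' for padding,
#: gaps and ambiguity codes.
ALPHABET = AA20 + "X"

AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

CENTER_RESIDUES = ("S", "T")
LABELS = ("POS", "NEG")


class ParseError(ValueError):
    """A file could not be interpreted in the expected format."""


class ValidationError(ValueError):
    """Input data violate a domain constraint (residue, width, label...)."""


def sanitize_residue(c: str) -> str:
    """Map any character outside the 20 standard residues to 'X'."""
    c = c.upper()
    return c if c in AA_INDEX and c != "X" else "X"


@dataclass(frozen=True)
class WindowSpec:
    """A ``[-left:+right]`` motif window around a phosphosite.

    ``width`` (the motif length k) counts flanking positions only; the
    central Ser/Thr is excluded, so the peptide string has ``width + 1``
    characters.  The canonical window is ``[-6:+4]`` (k = 10).
    """

    left: int = 6
    right: int = 4

    def __post_init__(self) -> None:
        if self.left < 0 or self.right < 0:
            raise ValidationError("window offsets must be non-negative")
        if self.left + self.right < 1:
            raise ValidationError("window must include at least one flank position")

    @property
    def width(self) -> int:
        """Number of flanking positions (the motif length k)."""
        return self.left + self.right

    @property
    def full_width(self) -> int:
        """Peptide string length including the central residue."""
        return self.width + 1

    def offsets(self) -> list[int]:
        """Flank offsets relative to the phosphosite, centre excluded."""
        return [o for o in range(-self.left, self.right + 1) if o != 0]

    def __str__(self) -> str:
        return f"[-{self.left}:+{self.right}]"

    @classmethod
    def parse(cls, text: str) -> "WindowSpec":
        """Parse '-6:4', '[-6:4]' or '[-6:+4]' into a WindowSpec."""
        body = text.strip().strip("[]")
        try:
            left_s, right_s = body.split(":")
            return cls(left=abs(int(left_s)), right=abs(int(right_s)))
        except (ValueError, TypeError) as exc:
            raise ParseError(f"cannot parse window spec {text!r}") from exc


@dataclass(frozen=True)
class PeptideWindow:
    """A fixed-width Ser/Thr-centred peptide with an optional POS/NEG label."""

    sequence: str
    label: str | None = None

    def center_residue(self, spec: WindowSpec) -> str:
        return self.sequence[spec.left]

    def flanks(self, spec: WindowSpec) -> str:
        """The k flanking residues with the central position removed."""
        return self.sequence[: spec.left] + self.sequence[spec.left + 1 :]

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Phosphosite:
    """An annotated phospho-Ser/Thr site: protein accession + 1-based position."""

    accession: str
    position: int
    residue: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValidationError(
                f"phosphosite position must be >= 1, got {self.position}"
            )
        if self.residue not in CENTER_RESIDUES:
            raise ValidationError(
                f"phosphosite residue must be S or T, got {self.residue!r}"
            )


@dataclass
class LabelledDataset:
    """A uniform-width collection of labelled peptide windows."""

    windows: list[PeptideWindow]
    window_spec: WindowSpec

    def __post_init__(self) -> None:
        want = self.window_spec.full_width
        for i, win in enumerate(self.windows):
            if len(win.sequence) != want:
                raise ValidationError(
                    f"window {i} ({win.sequence!r}) has width {len(win.sequence)}, "
                    f"expected {want} for spec {self.window_spec}"
                )
            if win.center_residue(self.window_spec) not in CENTER_RESIDUES:
                raise ValidationError(
                    f"window {i} ({win.sequence!r}) is not centred on S/T"
                )
            if win.label not in LABELS:
                raise ValidationError(
                    f"window {i} ({win.sequence!r}) has label {win.label!r}; "
                    f"expected one of {LABELS}"
                )

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[PeptideWindow]:
        return iter(self.windows)

    def sequences(self) -> list[str]:
        return [w.sequence for w in self.windows]

    def labels(self) -> list[str]:
        return [w.label for w in self.windows]  # type: ignore[misc]

    def subset(self, indices: Iterable[int]) -> "LabelledDataset":
        return LabelledDataset(
            [self.windows[i] for i in indices], self.window_spec
        )

    def by_label(self, label: str) -> "LabelledDataset":
        if label not in LABELS:
            raise ValidationError(f"unknown label {label!r}")
        return LabelledDataset(
            [w for w in self.windows if w.label == label], self.window_spec
        )


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly gzipped) multi-record FASTA into accession -> sequence.

    Sequences are upper-cased; non-standard characters are preserved here and
    collapse to 'X' only when windows are extracted.  Accessions are the
    first whitespace-separated token of the header.  Duplicate accessions and
    malformed files raise :class:`ParseError`.
    """
    path = Path(path)
    with _open_text(path) as fh:
        first = None
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first = (lineno, line)
                break
        if first is None:
            raise ParseError(f"{path}: empty FASTA file")
        if not first[1].startswith(">"):
            raise ParseError(
                f"{path}: line {first[0]}: expected FASTA header starting with '>'"
            )
    sequences: dict[str, str] = {}
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            if record.id in sequences:
                raise ParseError(f"{path}: duplicate accession {record.id!r}")
            sequences[record.id] = str(record.seq).upper()
    return sequences


def extract_window(
    sequence: str, position: int, spec: WindowSpec, label: str | None = None
) -> PeptideWindow:
    """Extract the ``[-left:+right]`` window around a 1-based Ser/Thr position.

    Positions outside ``1..len(sequence)`` are padded with 'X'; non-standard
    residues inside the window also become 'X'.
    """
    if not 1 <= position <= len(sequence):
        raise IndexError(
            f"position {position} outside sequence of length {len(sequence)}"
        )
    center = sequence[position - 1].upper()
    if center not in CENTER_RESIDUES:
        raise ValidationError(
            f"residue at position {position} is {center!r}, expected S or T"
        )
    chars = []
    for off in range(-spec.left, spec.right + 1):
        i = position + off
        if i < 1 or i > len(sequence):
            chars.append("X")
        else:
            chars.append(sanitize_residue(sequence[i - 1]))
    return PeptideWindow("".join(chars), label=label)


_SITE_HEADER_NAMES = {"accession", "position", "residue", "protein", "acc", "site"}


def read_phosphosites(path, sequences: Mapping[str, str] | None = None) -> list[Phosphosite]:
    """Read a phosphosite TSV (accession <TAB> position <TAB> residue).

    A header row is tolerated and detected by name.  Rows whose residue is
    not S/T are dropped with a logged count.  When ``sequences`` is given,
    each site is validated against the referenced sequence and a mismatch
    raises :class:`ValidationError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype=str
        ).dropna(how="all")
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 3:
        raise ParseError(f"{path}: expected 3 tab-separated columns, got {df.shape[1]}")
    rows = df.itertuples(index=False)
    out: list[Phosphosite] = []
    skipped = 0
    for rownum, row in enumerate(rows, start=1):
        acc, pos_raw, res = str(row[0]).strip(), str(row[1]).strip(), str(row[2]).strip()
        if rownum == 1 and acc.lower() in _SITE_HEADER_NAMES:
            continue
        try:
            position = int(pos_raw)
        except ValueError as exc:
            raise ParseError(
                f"{path}: row {rownum}: position {pos_raw!r} is not an integer"
            ) from exc
        residue = res.upper()
        if residue not in CENTER_RESIDUES:
            skipped += 1
            continue
        site = Phosphosite(acc, position, residue)
        if sequences is not None:
            if acc not in sequences:
                raise ValidationError(f"accession {acc!r} not present in sequences")
            seq = sequences[acc]
            if position > len(seq):
                raise ValidationError(
                    f"{acc}: position {position} beyond sequence length {len(seq)}"
                )
            actual = seq[position - 1].upper()
            if actual != residue:
                raise ValidationError(
                    f"{acc}: residue at {position} is {actual!r}, annotation says {residue!r}"
                )
        out.append(site)
    if skipped:
        logger.info("read_phosphosites: dropped %d non-Ser/Thr rows", skipped)
    return out


def load_peptide_table(path, spec: WindowSpec) -> LabelledDataset:
    """Load a labelled peptide TSV (columns ``peptide``, ``label``).

    Peptide strings include the central residue, i.e. they are exactly
    ``spec.full_width`` characters wide; anything else is an error naming
    the offending row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty peptide table") from None
    cols = {c.strip().lower(): c for c in df.columns}
    if "peptide" not in cols or "label" not in cols:
        raise ParseError(
            f"{path}: expected columns 'peptide' and 'label', found {list(df.columns)}"
        )
    windows: list[PeptideWindow] = []
    for rownum, (pep, label) in enumerate(
        zip(df[cols["peptide"]], df[cols["label"]]), start=1
    ):
        pep = str(pep).strip().upper()
        label = str(label).strip().upper()
        if len(pep) != spec.full_width:
            raise ValidationError(
                f"{path}: row {rownum}: peptide {pep!r} has width {len(pep)}, "
                f"expected {spec.full_width} for window {spec}"
            )
        if label not in LABELS:
            raise ValidationError(
                f"{path}: row {rownum}: label {label!r} not in {LABELS}"
            )
        pep = "".join(sanitize_residue(c) if i != spec.left else c
                      for i, c in enumerate(pep))
        if pep[spec.left] not in CENTER_RESIDUES:
            raise ValidationError(
                f"{path}: row {rownum}: peptide {pep!r} is not centred on S/T"
            )
        windows.append(PeptideWindow(pep, label=label))
    return LabelledDataset(windows, spec)


def load_peptide_list(path, spec: WindowSpec) -> list[str]:
    """Load an unlabelled peptide TSV (column ``peptide``), e.g. a background set."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    cols = {c.strip().lower(): c for c in df.columns}
    if "peptide" not in cols:
        raise ParseError(f"{path}: expected a 'peptide' column")
    out = []
    for rownum, pep in enumerate(df[cols["peptide"]], start=1):
        pep = str(pep).strip().upper()
        if len(pep) != spec.full_width:
            raise ValidationError(
                f"{path}: row {rownum}: peptide {pep!r} has width {len(pep)}, "
                f"expected {spec.full_width}"
            )
        out.append("".join(sanitize_residue(c) if i != spec.left else c
                           for i, c in enumerate(pep)))
    return out


def write_peptide_table(
    dataset: LabelledDataset, path, header_comment: str | None = None
) -> None:
    """Write a LabelledDataset as a peptide/label TSV (round-trips exactly)."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("peptide\tlabel\n")
        for win in dataset.windows:
            fh.write(f"{win.sequence}\t{win.label}\n")
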