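"""Readers and writers for the external file formats.

Four text formats are consumed: FASTA protein sequences, PSI-BLAST ASCII
PSSM profiles (the ``blastpgp -Q`` / ``psiblast -out_ascii_pssm`` dialect),
per-protein secondary-structure / solvent-accessibility annotation files
(SSpro-style: id line, sequence line, SS line, optional SA line), and a
tab-separated cysteine site-label table.

Positions are 1-based everywhere in the public API, matching the
convention of curated PTM-site tables; conversion to 0-based indexing
happens exactly once, inside the feature-extraction code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "AMINO_ACIDS",
    "PSSM_COLUMNS",
    "ProteinRecord",
    "PSSMProfile",
    "StructureAnnotation",
    "CysteineSite",
    "SiteTable",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_pssm",
    "write_pssm",
    "pseudo_pssm",
    "read_structure_annotation",
    "write_structure_annotation",
    "read_site_labels",
    "write_site_labels",
]

#: The 20 standard amino acids in PSI-BLAST's printed column order.
PSSM_COLUMNS = "ARNDCQEGHILKMFPSTWYV"
AMINO_ACIDS = PSSM_COLUMNS

_SS_ALPHABET = set("HEC")
_SA_ALPHABET = set("EB")


class FormatError(ValueError):
    """Raised when an input file violates its documented format."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence (letters of the 20-AA alphabet plus X)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("protein record with empty id")
        if not self.sequence:
            raise FormatError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS) - {"X"}
        if bad:
            raise FormatError(
                f"protein {self.id!r}: invalid residue letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PSSMProfile:
    """Per-residue 20-channel conservation scores.

    ``scores`` is an L x 20 array whose columns follow :data:`PSSM_COLUMNS`
    (PSI-BLAST's printed order).  Only the log-odds half of a PSI-BLAST
    file is kept; the weighted-percentage columns are discarded.
    """

    protein_id: str
    scores: np.ndarray
    residue_order: str = PSSM_COLUMNS

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise FormatError(
                f"PSSM for {self.protein_id!r}: expected L x 20 scores, "
                f"got shape {self.scores.shape}"
            )
        if self.residue_order != PSSM_COLUMNS:
            raise FormatError(
                f"PSSM for {self.protein_id!r}: unsupported column order "
                f"{self.residue_order!r}"
            )

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass
class StructureAnnotation:
    """Per-residue 3-state secondary structure and optional 2-state accessibility.

    ``ss`` uses H (helix), E (strand), C (coil); ``sa`` uses E (exposed),
    B (buried).
    """

    protein_id: str
    ss: str
    sa: str | None = None

    def __post_init__(self) -> None:
        if set(self.ss) - _SS_ALPHABET:
            raise FormatError(
                f"annotation for {self.protein_id!r}: SS letters outside H/E/C"
            )
        if self.sa is not None:
            if set(self.sa) - _SA_ALPHABET:
                raise FormatError(
                    f"annotation for {self.protein_id!r}: SA letters outside E/B"
                )
            if len(self.sa) != len(self.ss):
                raise FormatError(
                    f"annotation for {self.protein_id!r}: SA length "
                    f"{len(self.sa)} != SS length {len(self.ss)}"
                )

    def __len__(self) -> int:
        return len(self.ss)


POSITIVE = 1
NEGATIVE = -1
UNKNOWN = 0

_LABEL_MAP = {
    "1": POSITIVE,
    "+1": POSITIVE,
    "-1": NEGATIVE,
    "0": UNKNOWN,
    "?": UNKNOWN,
    "unknown": UNKNOWN,
}


@dataclass(frozen=True)
class CysteineSite:
    """A labelled cysteine instance: (protein, 1-based position, label).

    ``label`` is +1 (redox-sensitive), -1 (redox-insensitive) or 0 (unknown,
    prediction-only).  Whether the referenced residue really is a cysteine
    is checked lazily, at feature-extraction time, because the site table
    may be read before its sequences.
    """

    protein_id: str
    position: int
    label: int = UNKNOWN
    group: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(
                f"site {self.protein_id}:{self.position}: position must be >= 1"
            )
        if self.label not in (POSITIVE, NEGATIVE, UNKNOWN):
            raise FormatError(
                f"site {self.protein_id}:{self.position}: label {self.label!r} "
                "not in {+1, -1, 0}"
            )


@dataclass
class SiteTable:
    """Ordered, duplicate-free collection of :class:`CysteineSite`."""

    sites: list[CysteineSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for s in self.sites:
            key = (s.protein_id, s.position)
            if key in seen:
                raise FormatError(f"duplicate site {key[0]}:{key[1]}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def positives(self) -> list[CysteineSite]:
        return [s for s in self.sites if s.label == POSITIVE]

    def negatives(self) -> list[CysteineSite]:
        return [s for s in self.sites if s.label == NEGATIVE]

    def protein_ids(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for s in self.sites:
            if s.protein_id not in seen:
                seen.add(s.protein_id)
                out.append(s.protein_id)
        return out


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are upper-cased.  Selenocysteine (U) is mapped to C with a
    warning — Sec frequently occupies redox-active positions, and mapping
    it to cysteine keeps such sites addressable.  Any other non-standard
    letter is mapped to X.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        if "U" in seq:
            warnings.warn(
                f"record {rec.id!r}: selenocysteine (U) mapped to C",
                stacklevel=2,
            )
            seq = seq.replace("U", "C")
        seq = "".join(c if c in AMINO_ACIDS else "X" for c in seq)
        records.append(ProteinRecord(rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM


def read_pssm(
    path: str | Path,
    expected_sequence: str | None = None,
    protein_id: str | None = None,
) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM file.

    Only the first 20 numeric columns of each residue row (the log-odds
    scores) are kept; the weighted-percentage columns and trailing
    information-content fields, present in genuine PSI-BLAST output, are
    ignored.  If ``expected_sequence`` is given, the residue letter of
    every row must match it.
    """
    path = Path(path)
    rows: list[list[float]] = []
    letters: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            parts = raw.split()
            # A data row: 1-based index, residue letter, >= 20 numbers.
            if len(parts) >= 22 and parts[0].isdigit() and len(parts[1]) == 1:
                idx = int(parts[0])
                if idx != len(rows) + 1:
                    raise FormatError(
                        f"{path}:{lineno}: residue index {idx}, expected {len(rows) + 1}"
                    )
                try:
                    values = [float(x) for x in parts[2:22]]
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
                letters.append(parts[1])
                rows.append(values)
    if not rows:
        raise FormatError(f"{path}: no PSSM data rows found")
    if expected_sequence is not None:
        if len(rows) != len(expected_sequence):
            raise FormatError(
                f"{path}: {len(rows)} PSSM rows but sequence length "
                f"{len(expected_sequence)}"
            )
        for i, (got, want) in enumerate(zip(letters, expected_sequence)):
            if got != want:
                raise FormatError(
                    f"{path}: residue mismatch at position {i + 1}: "
                    f"PSSM has {got!r}, sequence has {want!r}"
                )
    pid = protein_id if protein_id is not None else path.stem
    return PSSMProfile(pid, np.array(rows, dtype=float))


def write_pssm(
    profile: PSSMProfile, path: str | Path, sequence: str | None = None
) -> None:
    """Write a profile in the PSI-BLAST ASCII layout (log-odds half only).

    Values are printed with three decimals, so any profile quantised to
    milli-units round-trips exactly.
    """
    seq = sequence if sequence is not None else "X" * len(profile)
    if len(seq) != len(profile):
        raise FormatError(
            f"PSSM for {profile.protein_id!r}: sequence length {len(seq)} "
            f"!= {len(profile)} rows"
        )
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("      " + "".join(f"{a:>9}" for a in PSSM_COLUMNS) + "\n")
        for i, (letter, row) in enumerate(zip(seq, profile.scores), start=1):
            cells = "".join(f"{v:>9.3f}" for v in row)
            fh.write(f"{i:>5} {letter}{cells}\n")


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def pseudo_pssm(
    sequence: str, substitution_matrix=None, protein_id: str = "pseudo"
) -> PSSMProfile:
    """Build a stand-in profile from a substitution matrix (default BLOSUM62).

    Row i is the matrix row of residue i over the 20 standard columns;
    X yields an all-zero row.  Deterministic; used when no PSI-BLAST
    profile exists (tests, quick predictions without a homology search).
    """
    matrix = _BLOSUM62 if substitution_matrix is None else substitution_matrix
    ProteinRecord("_tmp", sequence)  # validates the alphabet
    scores = np.zeros((len(sequence), 20), dtype=float)
    for i, aa in enumerate(sequence):
        if aa == "X":
            continue
        scores[i] = [matrix[aa, b] for b in PSSM_COLUMNS]
    return PSSMProfile(protein_id, scores)


# ---------------------------------------------------------------------------
# Structure annotations


def read_structure_annotation(path: str | Path) -> StructureAnnotation:
    """Read one per-protein annotation file.

    Layout: ``>id`` line, sequence line, SS line (H/E/C), optional SA line
    (E/B).  All per-residue lines must match the sequence length.
    """
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: expected id, sequence and SS lines")
    if not lines[0].startswith(">"):
        raise FormatError(f"{path}: first line must start with '>'")
    pid = lines[0][1:].split()[0]
    seq, ss = lines[1], lines[2]
    sa = lines[3] if len(lines) > 3 else None
    if len(ss) != len(seq):
        raise FormatError(
            f"{path}: SS length {len(ss)} != sequence length {len(seq)}"
        )
    if sa is not None and len(sa) != len(seq):
        raise FormatError(
            f"{path}: SA length {len(sa)} != sequence length {len(seq)}"
        )
    try:
        return StructureAnnotation(pid, ss, sa)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_structure_annotation(
    annotation: StructureAnnotation, sequence: str, path: str | Path
) -> None:
    if len(sequence) != len(annotation):
        raise FormatError(
            f"annotation for {annotation.protein_id!r}: sequence length "
            f"{len(sequence)} != annotation length {len(annotation)}"
        )
    with open(path, "w") as fh:
        fh.write(f">{annotation.protein_id}\n{sequence}\n{annotation.ss}\n")
        if annotation.sa is not None:
            fh.write(annotation.sa + "\n")


# ---------------------------------------------------------------------------
# Site-label tables


def read_site_labels(path: str | Path) -> SiteTable:
    """Read a tab-separated site table: protein_id, position, label[, group].

    Labels 1/+1 map to +1 (redox-sensitive), -1 to -1, and 0/?/unknown to
    the unknown class.  Duplicate (protein, position) rows are an error.
    Lines starting with '#' are comments.
    """
    path = Path(path)
    sites: list[CysteineSite] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields"
                )
            pid, pos_s, label_s = parts[0], parts[1], parts[2]
            group = parts[3] if len(parts) > 3 and parts[3] else None
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: position {pos_s!r} is not an integer"
                ) from None
            if label_s not in _LABEL_MAP:
                raise FormatError(f"{path}:{lineno}: unknown label {label_s!r}")
            sites.append(CysteineSite(pid, pos, _LABEL_MAP[label_s], group))
    try:
        return SiteTable(sites)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


def load_dataset_dir(directory: str | Path):
    """Load the standard on-disk layout into in-memory registries.

    Expects ``proteins.fasta``, ``sites.tsv``, and per-protein
    ``pssm/<id>.pssm`` and ``ss/<id>.ssa`` files (either subdirectory may
    be absent when the corresponding feature blocks are not used).
    Returns ``(records, pssms, annotations, site_table)`` where the first
    three are dicts keyed by protein id.
    """
    directory = Path(directory)
    records = {r.id: r for r in read_fasta(directory / "proteins.fasta")}
    table = read_site_labels(directory / "sites.tsv")
    pssms: dict[str, PSSMProfile] = {}
    annotations: dict[str, StructureAnnotation] = {}
    for pid, rec in records.items():
        p = directory / "pssm" / f"{pid}.pssm"
        if p.exists():
            pssms[pid] = read_pssm(p, expected_sequence=rec.sequence, protein_id=pid)
        a = directory / "ss" / f"{pid}.ssa"
        if a.exists():
            annotations[pid] = read_structure_annotation(a)
    return records, pssms, annotations, table


def write_site_labels(table: SiteTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# protein_id\tposition\tlabel\tgroup\n")
        for s in table:
            label = {POSITIVE: "1", NEGATIVE: "-1", UNKNOWN: "?"}[s.label]
            fh.write(f"{s.protein_id}\t{s.position}\t{label}\t{s.group or ''}\n")
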