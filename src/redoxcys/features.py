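"""Residue-centric feature encoding for cysteine sites.

Each labelled cysteine is turned into one fixed-length numeric vector by
concatenating up to five named blocks, always in this order:

``D``
    Sequential distances |i - j| to the n nearest other cysteines, sorted
    ascending.  Raw residue counts, no normalisation.  When the protein
    holds fewer than n other cysteines, missing entries are filled with
    the sequence length L (an unattainable-or-maximal distance), so the
    vector stays fixed-length.
``PSSM``
    The window x 20 slice of the protein's conservation profile around
    the site, flattened row-major.
``SS`` / ``SA``
    One-hot 3-state secondary structure (H, E, C) and 2-state solvent
    accessibility (E, B) over the same window.
``PCP``
    Four physico-chemical channels per window residue: hydrophobicity,
    side-chain net charge index, helix propensity and side-chain pKa.

Windows are centred on the cysteine; rows falling outside the sequence
are all-zero padding, so one-hot blocks encode "missing" as the all-zero
code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .seqio import (
    AMINO_ACIDS,
    UNKNOWN,
    CysteineSite,
    FormatError,
    ProteinRecord,
    PSSMProfile,
    SiteTable,
    StructureAnnotation,
)

__all__ = [
    "BLOCKS",
    "SS_STATES",
    "SA_STATES",
    "PCP_CHANNELS",
    "DEFAULT_PCP_TABLE",
    "FeatureSpec",
    "FeatureVector",
    "DesignMatrix",
    "cysteine_positions",
    "sequential_distances",
    "window_slice",
    "encode_site",
    "feature_dimension",
    "build_design_matrix",
]

BLOCKS = ("D", "PSSM", "SS", "SA", "PCP")
SS_STATES = "HEC"
SA_STATES = "EB"
PCP_CHANNELS = ("hydrophobicity", "nci", "propensity", "pka")

# Default physico-chemical table, one row per residue:
# Kyte-Doolittle hydrophobicity; net charge index of the side chain;
# Chou-Fasman alpha-helix propensity; side-chain pKa (0 when the side
# chain is not ionizable).  Config-replaceable via FeatureSpec.pcp_table.
DEFAULT_PCP_TABLE: dict[str, tuple[float, float, float, float]] = {
    "A": (1.8, 0.007187, 1.42, 0.0),
    "R": (-4.5, 0.043587, 0.98, 12.5),
    "N": (-3.5, 0.005392, 0.67, 0.0),
    "D": (-3.5, -0.02382, 1.01, 3.9),
    "C": (2.5, -0.03661, 0.70, 8.3),
    "Q": (-3.5, 0.049211, 1.11, 0.0),
    "E": (-3.5, 0.006802, 1.51, 4.1),
    "G": (-0.4, 0.179052, 0.57, 0.0),
    "H": (-3.2, -0.01069, 1.00, 6.0),
    "I": (4.5, 0.021631, 1.08, 0.0),
    "L": (3.8, 0.051672, 1.21, 0.0),
    "K": (-3.9, 0.017708, 1.16, 10.5),
    "M": (1.9, 0.002683, 1.45, 0.0),
    "F": (2.8, 0.037552, 1.13, 0.0),
    "P": (-1.6, 0.239531, 0.57, 0.0),
    "S": (-0.8, 0.004627, 0.77, 0.0),
    "T": (-0.7, 0.003352, 0.83, 0.0),
    "W": (-0.9, 0.037977, 1.08, 0.0),
    "Y": (-1.3, 0.023599, 0.69, 10.1),
    "V": (4.2, 0.057004, 1.06, 0.0),
}


@dataclass(frozen=True)
class FeatureSpec:
    """Configuration of the encoding.

    Parameters
    ----------
    n_neighbors
        How many nearby cysteines contribute a sequential distance
        (block D).  The cross-validated optimum on curated data is 6.
    window
        Odd width of the sliding window for the per-residue blocks.
        The cross-validated optimum is 9.
    blocks
        Which blocks to emit, any subset of ``("D","PSSM","SS","SA","PCP")``;
        concatenation order is always D, PSSM, SS, SA, PCP regardless of
        the order given here, so selected-feature indices are stable.
    """

    n_neighbors: int = 6
    window: int = 9
    blocks: tuple[str, ...] = ("D", "PSSM", "SS")
    distance_sentinel_policy: str = "sequence_length"
    pcp_table: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: DEFAULT_PCP_TABLE
    )

    def __post_init__(self) -> None:
        if self.n_neighbors < 0:
            raise ValueError("n_neighbors must be >= 0")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 1, got {self.window}")
        blocks = tuple(b for b in BLOCKS if b in self.blocks)
        unknown = set(self.blocks) - set(BLOCKS)
        if unknown:
            raise ValueError(f"unknown feature blocks: {sorted(unknown)}")
        if not blocks:
            raise ValueError("at least one feature block is required")
        object.__setattr__(self, "blocks", blocks)
        if self.distance_sentinel_policy != "sequence_length":
            raise ValueError(
                f"unknown distance sentinel policy {self.distance_sentinel_policy!r}"
            )
        missing = set(AMINO_ACIDS) - set(self.pcp_table)
        if missing:
            raise ValueError(f"pcp_table missing residues {sorted(missing)}")

    def with_blocks(self, blocks: Sequence[str]) -> "FeatureSpec":
        return replace(self, blocks=tuple(blocks))


@dataclass
class FeatureVector:
    """One encoded site: values plus per-dimension ``block:offset:channel`` names."""

    values: np.ndarray
    names: list[str]
    site: CysteineSite

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("feature values and names disagree in length")


def cysteine_positions(sequence: str) -> list[int]:
    """1-based positions of every C in the sequence, ascending."""
    return [i + 1 for i, aa in enumerate(sequence) if aa == "C"]


def sequential_distances(sequence: str, position: int, n: int) -> np.ndarray:
    """Distances |i - j| from the cysteine at ``position`` to its n nearest peers.

    Sorted ascending and padded with the sequence length when fewer than
    n other cysteines exist.  ``position`` is 1-based and must hold a C.
    """
    if not 1 <= position <= len(sequence):
        raise ValueError(f"position {position} outside sequence of length {len(sequence)}")
    if sequence[position - 1] != "C":
        raise ValueError(f"residue at position {position} is {sequence[position - 1]!r}, not C")
    others = [p for p in cysteine_positions(sequence) if p != position]
    dists = sorted(abs(position - p) for p in others)[:n]
    sentinel = len(sequence)
    dists += [sentinel] * (n - len(dists))
    return np.array(dists, dtype=float)


def window_slice(matrix: np.ndarray, position: int, window: int) -> np.ndarray:
    """window x K slice of a per-residue matrix centred on a 1-based position.

    Rows outside [1, L] are all-zero padding.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise ValueError("per-residue matrix must be 2-D")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    L = matrix.shape[0]
    if not 1 <= position <= L:
        raise ValueError(f"position {position} outside [1, {L}]")
    half = (window - 1) // 2
    out = np.zeros((window, matrix.shape[1]), dtype=float)
    lo = max(position - half, 1)
    hi = min(position + half, L)
    out[lo - (position - half) : hi - (position - half) + 1] = matrix[lo - 1 : hi]
    return out


def _one_hot(states: str, alphabet: str) -> np.ndarray:
    out = np.zeros((len(states), len(alphabet)), dtype=float)
    for i, s in enumerate(states):
        out[i, alphabet.index(s)] = 1.0
    return out


def _pcp_matrix(sequence: str, table: Mapping[str, tuple[float, ...]]) -> np.ndarray:
    out = np.zeros((len(sequence), 4), dtype=float)
    for i, aa in enumerate(sequence):
        if aa != "X":
            out[i] = table[aa]
    return out


def _offsets(window: int) -> range:
    half = (window - 1) // 2
    return range(-half, half + 1)


def feature_names(spec: FeatureSpec) -> list[str]:
    """Per-dimension names, ``block:offset:channel`` (D uses the neighbour rank)."""
    names: list[str] = []
    if "D" in spec.blocks:
        names += [f"D:{k}" for k in range(1, spec.n_neighbors + 1)]
    if "PSSM" in spec.blocks:
        names += [f"PSSM:{o}:{aa}" for o in _offsets(spec.window) for aa in AMINO_ACIDS]
    if "SS" in spec.blocks:
        names += [f"SS:{o}:{s}" for o in _offsets(spec.window) for s in SS_STATES]
    if "SA" in spec.blocks:
        names += [f"SA:{o}:{s}" for o in _offsets(spec.window) for s in SA_STATES]
    if "PCP" in spec.blocks:
        names += [f"PCP:{o}:{c}" for o in _offsets(spec.window) for c in PCP_CHANNELS]
    return names


def feature_dimension(spec: FeatureSpec) -> int:
    """Total vector length for a spec (e.g. 6 + 9*20 + 9*3 = 213 for the default)."""
    dim = 0
    if "D" in spec.blocks:
        dim += spec.n_neighbors
    per_residue = {"PSSM": 20, "SS": 3, "SA": 2, "PCP": 4}
    for block, k in per_residue.items():
        if block in spec.blocks:
            dim += spec.window * k
    return dim


def encode_site(
    site: CysteineSite,
    spec: FeatureSpec,
    record: ProteinRecord,
    pssm: PSSMProfile | None = None,
    annotation: StructureAnnotation | None = None,
) -> FeatureVector:
    """Encode one cysteine site into its fixed-length feature vector."""
    seq = record.sequence
    if site.protein_id != record.id:
        raise ValueError(f"site {site.protein_id}:{site.position} paired with record {record.id!r}")
    if not 1 <= site.position <= len(seq):
        raise FormatError(
            f"site {site.protein_id}:{site.position}: position outside sequence "
            f"of length {len(seq)}"
        )
    if seq[site.position - 1] != "C":
        raise FormatError(
            f"site {site.protein_id}:{site.position}: residue is "
            f"{seq[site.position - 1]!r}, not a cysteine"
        )
    parts: list[np.ndarray] = []
    if "D" in spec.blocks:
        parts.append(sequential_distances(seq, site.position, spec.n_neighbors))
    if "PSSM" in spec.blocks:
        if pssm is None:
            raise FormatError(
                f"site {site.protein_id}:{site.position}: PSSM block requested "
                f"but no profile for protein {site.protein_id!r}"
            )
        if len(pssm) != len(seq):
            raise FormatError(
                f"protein {site.protein_id!r}: PSSM has {len(pssm)} rows but "
                f"sequence length is {len(seq)}"
            )
        parts.append(window_slice(pssm.scores, site.position, spec.window).ravel())
    needs_ss = "SS" in spec.blocks
    needs_sa = "SA" in spec.blocks
    if needs_ss or needs_sa:
        if annotation is None:
            block = "SS" if needs_ss else "SA"
            raise FormatError(
                f"site {site.protein_id}:{site.position}: {block} block requested "
                f"but no structure annotation for protein {site.protein_id!r}"
            )
        if len(annotation) != len(seq):
            raise FormatError(
                f"protein {site.protein_id!r}: annotation length {len(annotation)} "
                f"!= sequence length {len(seq)}"
            )
    if needs_ss:
        ss_mat = _one_hot(annotation.ss, SS_STATES)
        parts.append(window_slice(ss_mat, site.position, spec.window).ravel())
    if needs_sa:
        if annotation.sa is None:
            raise FormatError(
                f"site {site.protein_id}:{site.position}: SA block requested but "
                f"annotation for {site.protein_id!r} has no accessibility string"
            )
        sa_mat = _one_hot(annotation.sa, SA_STATES)
        parts.append(window_slice(sa_mat, site.position, spec.window).ravel())
    if "PCP" in spec.blocks:
        pcp = _pcp_matrix(seq, spec.pcp_table)
        parts.append(window_slice(pcp, site.position, spec.window).ravel())
    values = np.concatenate(parts) if parts else np.empty(0)
    return FeatureVector(values, feature_names(spec), site)


@dataclass
class DesignMatrix:
    """Stacked encodings of a site table.

    ``X``/``y``/``sites`` hold the labelled rows (y in {+1,-1}); sites with
    unknown labels are routed to ``X_unknown``/``unknown_sites`` for
    prediction-only use.  Row order follows the input table order.
    """

    X: np.ndarray
    y: np.ndarray
    names: list[str]
    sites: list[CysteineSite]
    X_unknown: np.ndarray
    unknown_sites: list[CysteineSite]

    @property
    def groups(self) -> list[str | None]:
        return [s.group for s in self.sites]


def build_design_matrix(
    site_table: SiteTable,
    spec: FeatureSpec,
    records: Mapping[str, ProteinRecord],
    pssms: Mapping[str, PSSMProfile] | None = None,
    annotations: Mapping[str, StructureAnnotation] | None = None,
) -> DesignMatrix:
    """Encode every site of a table against a registry of per-protein data."""
    pssms = pssms or {}
    annotations = annotations or {}
    p = feature_dimension(spec)
    names = feature_names(spec)
    rows, labels, labelled = [], [], []
    u_rows, u_sites = [], []
    for site in site_table:
        record = records.get(site.protein_id)
        if record is None:
            raise FormatError(
                f"site {site.protein_id}:{site.position}: no sequence record "
                f"for protein {site.protein_id!r}"
            )
        fv = encode_site(
            site,
            spec,
            record,
            pssm=pssms.get(site.protein_id),
            annotation=annotations.get(site.protein_id),
        )
        if site.label == UNKNOWN:
            u_rows.append(fv.values)
            u_sites.append(site)
        else:
            rows.append(fv.values)
            labels.append(site.label)
            labelled.append(site)
    X = np.array(rows, dtype=float).reshape(len(rows), p)
    Xu = np.array(u_rows, dtype=float).reshape(len(u_rows), p)
    y = np.array(labels, dtype=int)
    return DesignMatrix(X, y, names, labelled, Xu, u_sites)
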