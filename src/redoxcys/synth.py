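"""Synthetic proteins, profiles and labelled cysteine sites.

The generator emulates the signal structure reported for curated
redox-sensitive cysteines, so that every pipeline stage can be exercised
without any external data or predictors:

* redox-sensitive (positive) cysteines sit in cysteine-sparse stretches —
  their sequential distances to neighbouring cysteines run longer than
  those of insensitive ones (``distance_shift``: an isolation radius, in
  residues, cleared of other cysteines around each positive site);
* conservation profiles around positive sites carry shifted log-odds in
  the H, I, L, M, F, P, Y channels (``pssm_shift`` added inside the
  flanking window);
* the flanking secondary structure of positive sites is coil-enriched and
  helix-depleted (``coil_bias``).

Profiles are substitution-matrix baselines (BLOSUM62 row of the residue)
plus Gaussian noise plus the planted shift, quantised to three decimals
so the text round-trip through the PSSM format is exact.  Secondary
structure is a 3-state Markov chain with window-local bias injection;
solvent accessibility is an unbiased coin.  With every effect size at
zero, positive and negative sites are exchangeable draws.

What this deliberately does not model: homology between proteins,
realistic amino-acid composition, structure-consistent SS segments, or
any coupling between the three effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .seqio import (
    AMINO_ACIDS,
    NEGATIVE,
    POSITIVE,
    CysteineSite,
    ProteinRecord,
    PSSMProfile,
    SiteTable,
    StructureAnnotation,
    write_fasta,
    write_pssm,
    write_site_labels,
    write_structure_annotation,
)

__all__ = ["SynthConfig", "SynthDataset", "generate", "write_fixture_tree"]

SHIFTED_CHANNELS = "HILMFPY"
_SHIFTED_COLS = [AMINO_ACIDS.index(a) for a in SHIFTED_CHANNELS]
_NON_CYS = [a for a in AMINO_ACIDS if a != "C"]
_GROUPS = ("oxidoreductase", "hydrolase", "transferase", "non_enzyme")


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults keep a full pipeline run (encode, RFE, tune, 10-fold CV)
    fast: 50 proteins of 100-400 residues at ~3 % cysteine density with
    100 positive sites.  Effect-size defaults are deliberately strong —
    an isolation radius of 40 residues (versus a ~11-residue median
    nearest-cysteine distance at this density), a 2.0 log-odds channel
    shift against noise of the same scale, and a 0.5 coil bias — so the
    planted signal is clearly recoverable; set them to 0 for null data.
    """

    n_proteins: int = 50
    length_range: tuple[int, int] = (100, 400)
    cysteine_density: float = 0.03
    n_positive_sites: int = 100
    distance_shift: float = 40.0
    pssm_shift: float = 2.0
    coil_bias: float = 0.5
    noise: float = 2.0
    window: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("length_range must satisfy 1 <= min <= max")
        if not 0 < self.cysteine_density < 1:
            raise ValueError("cysteine_density must be in (0, 1)")
        if min(self.distance_shift, self.pssm_shift, self.coil_bias) < 0:
            raise ValueError("effect sizes must be >= 0")
        if not 0 <= self.coil_bias <= 1:
            raise ValueError("coil_bias is a probability boost in [0, 1]")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if self.n_proteins < 1 or self.n_positive_sites < 0:
            raise ValueError("n_proteins >= 1 and n_positive_sites >= 0 required")

    def null(self) -> "SynthConfig":
        """The same conditions with every planted effect removed."""
        return replace(self, distance_shift=0.0, pssm_shift=0.0, coil_bias=0.0)


@dataclass
class SynthDataset:
    records: list[ProteinRecord]
    pssms: dict[str, PSSMProfile]
    annotations: dict[str, StructureAnnotation]
    site_table: SiteTable
    config: SynthConfig

    def registries(self):
        """(records, pssms, annotations) mappings for build_design_matrix."""
        return ({r.id: r for r in self.records}, self.pssms, self.annotations)


def _markov_ss(L: int, rng: np.random.Generator) -> np.ndarray:
    """3-state chain over H/E/C with sticky segments (stay prob 0.85)."""
    states = np.empty(L, dtype=int)
    states[0] = rng.integers(3)
    stay = 0.85
    for i in range(1, L):
        if rng.random() < stay:
            states[i] = states[i - 1]
        else:
            states[i] = (states[i - 1] + 1 + rng.integers(2)) % 3
    return states


def generate(config: SynthConfig) -> SynthDataset:
    """Draw a full dataset; deterministic under ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    half = (config.window - 1) // 2

    # 1. sequences with planted cysteines
    lengths = rng.integers(lo, hi + 1, size=config.n_proteins)
    cys_positions: list[list[int]] = []  # 0-based, per protein
    sequences: list[np.ndarray] = []
    for L in lengths:
        seq = rng.choice(list(_NON_CYS), size=L)
        m = max(2, int(round(config.cysteine_density * L)))
        pos = np.sort(rng.choice(L, size=min(m, L), replace=False))
        seq[pos] = "C"
        sequences.append(seq)
        cys_positions.append(pos.tolist())

    total_cys = sum(len(p) for p in cys_positions)
    if config.n_positive_sites > total_cys:
        raise ValueError(
            f"config asks for {config.n_positive_sites} positive sites but only "
            f"{total_cys} cysteines were generated"
        )

    # 2. choose positive sites; chosen positives within one protein stay
    #    pairwise farther apart than the isolation radius, so pruning
    #    (step 3) never deletes a positive
    pool = [(pi, c) for pi, plist in enumerate(cys_positions) for c in plist]
    rng.shuffle(pool)
    positives: dict[int, list[int]] = {}
    for pi, c in pool:
        if sum(len(v) for v in positives.values()) == config.n_positive_sites:
            break
        taken = positives.setdefault(pi, [])
        if all(abs(c - t) > config.distance_shift for t in taken):
            taken.append(c)
    n_chosen = sum(len(v) for v in positives.values())
    if n_chosen < config.n_positive_sites:
        raise ValueError(
            f"could only place {n_chosen} of {config.n_positive_sites} positive "
            "sites at the requested isolation radius; lower distance_shift or "
            "n_positive_sites, or raise protein count/length"
        )

    # 3. isolation pruning: clear other cysteines around each positive site
    for pi, taken in positives.items():
        seq = sequences[pi]
        kept = []
        for c in cys_positions[pi]:
            if c in taken:
                kept.append(c)
            elif any(abs(c - t) <= config.distance_shift for t in taken):
                seq[c] = rng.choice(_NON_CYS)
            else:
                kept.append(c)
        cys_positions[pi] = kept

    # 4. pruning thins the negative class; re-plant negatives outside every
    #    exclusion zone until the balanced draw has headroom
    n_neg = sum(len(p) for p in cys_positions) - n_chosen
    target_neg = max(n_neg, int(np.ceil(1.2 * n_chosen)))
    order = rng.permutation(config.n_proteins)
    for pi in order:
        if n_neg >= target_neg:
            break
        seq = sequences[pi]
        taken = positives.get(pi, [])
        allowed = [
            i
            for i in range(len(seq))
            if seq[i] != "C" and all(abs(i - t) > config.distance_shift for t in taken)
        ]
        if not allowed:
            continue
        per_protein_cap = max(1, int(round(config.cysteine_density * len(seq))))
        n_add = min(len(allowed), target_neg - n_neg, per_protein_cap)
        for i in rng.choice(allowed, size=n_add, replace=False):
            seq[i] = "C"
            cys_positions[pi].append(int(i))
        cys_positions[pi].sort()
        n_neg += n_add
    if n_neg < n_chosen:
        raise ValueError(
            f"only {n_neg} negative cysteines available for {n_chosen} positives; "
            "raise protein count or length"
        )

    records: list[ProteinRecord] = []
    pssms: dict[str, PSSMProfile] = {}
    annotations: dict[str, StructureAnnotation] = {}
    sites: list[CysteineSite] = []
    from .seqio import pseudo_pssm  # baseline rows; avoids cycle at import time

    protein_groups = rng.choice(list(_GROUPS), size=config.n_proteins)
    for pi, seq in enumerate(sequences):
        pid = f"synth{pi:04d}"
        seq_str = "".join(seq)
        record = ProteinRecord(pid, seq_str)
        records.append(record)
        L = len(seq_str)
        pos_set = set(positives.get(pi, []))

        # conservation profile: baseline + noise (+ window shift at positives)
        scores = pseudo_pssm(seq_str, protein_id=pid).scores
        scores = scores + rng.normal(0.0, config.noise, size=scores.shape)
        for c in pos_set:
            w0, w1 = max(0, c - half), min(L, c + half + 1)
            scores[w0:w1, _SHIFTED_COLS] += config.pssm_shift
        pssms[pid] = PSSMProfile(pid, np.round(scores, 3))

        # secondary structure (+ coil enrichment at positives) and SA
        ss_idx = _markov_ss(L, rng)
        if config.coil_bias > 0:
            p_coil = min(0.95, 1.0 / 3.0 + (2.0 / 3.0) * config.coil_bias)
            rest = 1.0 - p_coil
            probs = np.array([rest / 3.0, 2.0 * rest / 3.0, p_coil])  # H depleted
            for c in pos_set:
                w0, w1 = max(0, c - half), min(L, c + half + 1)
                ss_idx[w0:w1] = rng.choice(3, size=w1 - w0, p=probs)
        ss = "".join("HEC"[s] for s in ss_idx)
        sa = "".join(rng.choice(["E", "B"], size=L))
        annotations[pid] = StructureAnnotation(pid, ss, sa)

        group = str(protein_groups[pi])
        for c in cys_positions[pi]:
            label = POSITIVE if c in pos_set else NEGATIVE
            sites.append(CysteineSite(pid, c + 1, label, group))

    table = SiteTable(sites)
    if len(table.negatives()) < len(table.positives()):
        warnings.warn(
            "synthetic dataset has fewer negatives than positives; "
            "balanced sampling will fail",
            stacklevel=2,
        )
    return SynthDataset(records, pssms, annotations, table, config)


def write_fixture_tree(dataset: SynthDataset, directory: str | Path) -> list[Path]:
    """Write the dataset in the on-disk layout the readers consume.

    ``proteins.fasta`` and ``sites.tsv`` at the top level, one
    ``pssm/<id>.pssm`` and one ``ss/<id>.ssa`` per protein: 2n + 2 files.
    Returns the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if dataset.records:
        fasta = directory / "proteins.fasta"
        write_fasta(dataset.records, fasta)
        written.append(fasta)
        (directory / "pssm").mkdir(exist_ok=True)
        (directory / "ss").mkdir(exist_ok=True)
        for rec in dataset.records:
            p = directory / "pssm" / f"{rec.id}.pssm"
            write_pssm(dataset.pssms[rec.id], p, sequence=rec.sequence)
            written.append(p)
            a = directory / "ss" / f"{rec.id}.ssa"
            write_structure_annotation(dataset.annotations[rec.id], rec.sequence, a)
            written.append(a)
    sites = directory / "sites.tsv"
    write_site_labels(dataset.site_table, sites)
    written.append(sites)
    return written
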