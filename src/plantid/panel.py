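"""Species sequence panels: I/O, alignment, divergence scanning, coordinates.

A *panel* is the working unit of the assay design: one marker sequence
(e.g. the nrITS region) per species, each labelled as a design target or a
non-target background species. Panels may carry a multiple alignment, from
which divergent (species-discriminating) windows are located.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "Role",
    "SequenceRecord",
    "SequencePanel",
    "DivergenceProfile",
    "PanelError",
    "read_panel",
    "write_panel",
    "align_panel",
    "divergence_scan",
    "gapped_to_ungapped",
    "ungapped_to_gapped",
    "generate_synthetic_panel",
    "CONSERVED_5P_FLANK",
    "CONSERVED_MID",
    "CONSERVED_3P_FLANK",
]

_DNA = set("ACGTN")
GAP = "-"


class PanelError(ValueError):
    """Invalid panel content or structure."""


class Role(str, Enum):
    TARGET = "target"
    NON_TARGET = "non_target"


def _normalise_sequence(seq: str) -> str:
    s = str(seq).upper().replace("U", "T")
    if not s:
        raise PanelError("empty sequence")
    bad = set(s) - _DNA
    if bad:
        raise PanelError(f"non-IUPAC characters beyond N: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """One species' marker sequence with its design role."""

    id: str
    species: str
    role: Role
    sequence: str
    accession: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _normalise_sequence(self.sequence))
        object.__setattr__(self, "role", Role(self.role))


@dataclass
class DivergenceProfile:
    """Score of one alignment window: which species it can discriminate."""

    window_start: int
    window_length: int
    discriminating_species: frozenset[str]
    score: int


@dataclass
class SequencePanel:
    """Labelled marker sequences for a set of species, optionally aligned.

    ``aligned[i]`` is the gapped form of ``records[i].sequence``; ungapping
    any aligned row must reproduce the raw sequence exactly.
    """

    records: list[SequenceRecord]
    aligned: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise PanelError("panel has no records")
        species = [r.species for r in self.records]
        dupes = {s for s in species if species.count(s) > 1}
        if dupes:
            raise PanelError(f"duplicate species in panel: {sorted(dupes)}")
        if self.aligned is not None:
            self._check_alignment()

    def _check_alignment(self) -> None:
        assert self.aligned is not None
        if len(self.aligned) != len(self.records):
            raise PanelError("alignment row count != record count")
        widths = {len(row) for row in self.aligned}
        if len(widths) != 1:
            raise PanelError("alignment rows have unequal lengths")
        for row, rec in zip(self.aligned, self.records):
            if row.replace(GAP, "") != rec.sequence:
                raise PanelError(
                    f"ungapping aligned row for {rec.species} does not "
                    "reproduce the raw sequence"
                )

    # -- convenience accessors -------------------------------------------
    @property
    def is_aligned(self) -> bool:
        return self.aligned is not None

    @property
    def alignment_length(self) -> int:
        if self.aligned is None:
            raise PanelError("panel is not aligned")
        return len(self.aligned[0])

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.records]

    @property
    def targets(self) -> list[str]:
        return [r.species for r in self.records if r.role is Role.TARGET]

    @property
    def non_targets(self) -> list[str]:
        return [r.species for r in self.records if r.role is Role.NON_TARGET]

    def record(self, species: str) -> SequenceRecord:
        for r in self.records:
            if r.species == species:
                return r
        raise KeyError(species)

    def aligned_row(self, species: str) -> str:
        if self.aligned is None:
            raise PanelError("panel is not aligned")
        return self.aligned[self.species.index(species)]

    def subset(self, species: Iterable[str]) -> "SequencePanel":
        keep = set(species)
        recs = [r for r in self.records if r.species in keep]
        aligned = None
        if self.aligned is not None:
            aligned = [row for row, r in zip(self.aligned, self.records)
                       if r.species in keep]
        return SequencePanel(recs, aligned)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_panel(
    fasta_path: str | Path,
    metadata: Mapping[str, tuple[str, str]] | None = None,
) -> SequencePanel:
    """Read a multi-FASTA into a validated :class:`SequencePanel`.

    Species and role are taken either from ``metadata`` (record id ->
    ``(species, role)``) or, if absent, parsed from headers of the form
    ``id|species|role``. Gap characters, if present in every record, are
    interpreted as a pre-computed alignment.
    """
    fasta_path = Path(fasta_path)
    bio_records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not bio_records:
        raise PanelError(f"no FASTA records in {fasta_path}")

    records: list[SequenceRecord] = []
    gapped_rows: list[str] = []
    any_gaps = False
    for br in bio_records:
        raw = str(br.seq)
        header = br.description or br.id  # species names may contain spaces
        if metadata is not None:
            if header not in metadata:
                raise PanelError(f"record {header!r} missing from metadata")
            species, role = metadata[header]
            rec_id = header
        else:
            parts = header.split("|")
            if len(parts) < 3:
                raise PanelError(
                    f"header {header!r} not of form 'id|species|role' and no "
                    "metadata map was given"
                )
            rec_id, species, role = parts[0], parts[1], parts[2]
        gapped = raw.upper().replace("U", "T")
        if GAP in gapped:
            any_gaps = True
        records.append(
            SequenceRecord(rec_id, species, Role(role), gapped.replace(GAP, ""))
        )
        gapped_rows.append(gapped)

    aligned = None
    if any_gaps:
        widths = {len(row) for row in gapped_rows}
        if len(widths) != 1:
            raise PanelError("gapped input rows have unequal lengths")
        aligned = gapped_rows
    return SequencePanel(records, aligned)


def write_panel(panel: SequencePanel, fasta_path: str | Path,
                aligned: bool = False) -> None:
    """Write a panel as multi-FASTA with ``id|species|role`` headers."""
    rows: Sequence[str]
    if aligned:
        if panel.aligned is None:
            raise PanelError("panel is not aligned")
        rows = panel.aligned
    else:
        rows = [r.sequence for r in panel.records]
    out = []
    for rec, row in zip(panel.records, rows):
        header = f"{rec.id}|{rec.species}|{rec.role.value}"
        out.append(_BioSeqRecord(Seq(row), id=header, description=""))
    SeqIO.write(out, str(fasta_path), "fasta")


# ---------------------------------------------------------------------------
# Progressive alignment
# ---------------------------------------------------------------------------

def _nw_profile(profile: list[str], seq: str, match: float, mismatch: float,
                gap: float) -> tuple[list[str], str]:
    """Global (Needleman-Wunsch) alignment of ``seq`` against a profile.

    Column score for a base is the mean match/mismatch score over rows;
    gap characters inside a profile column score as mismatches.
    """
    ncol = len(profile[0])
    n = len(seq)
    nrows = len(profile)

    # per-column score for each possible incoming base
    cols = np.array([[row[j] for row in profile] for j in range(ncol)])
    col_score = np.empty((ncol, 4))
    bases = np.array(list("ACGT"))
    for b, base in enumerate(bases):
        eq = cols == base
        col_score[:, b] = (eq * match + (~eq) * mismatch).mean(axis=1)
    base_index = {b: i for i, b in enumerate("ACGT")}

    NEG = -1e18
    score = np.full((n + 1, ncol + 1), 0.0)
    ptr = np.zeros((n + 1, ncol + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(ncol + 1)
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, n + 1):
        ci = base_index.get(seq[i - 1])
        sub = col_score[:, ci] if ci is not None else np.full(ncol, mismatch)
        prev = score[i - 1]
        cur = score[i]
        pi = ptr[i]
        for j in range(1, ncol + 1):
            d = prev[j - 1] + sub[j - 1]
            u = prev[j] + gap
            l = cur[j - 1] + gap
            if d >= u and d >= l:
                cur[j] = d
                pi[j] = 0
            elif u >= l:
                cur[j] = u
                pi[j] = 1
            else:
                cur[j] = l
                pi[j] = 2

    # traceback
    i, j = n, ncol
    new_rows = [[] for _ in range(nrows)]
    new_seq: list[str] = []
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0:
            for k in range(nrows):
                new_rows[k].append(profile[k][j - 1])
            new_seq.append(seq[i - 1])
            i -= 1
            j -= 1
        elif p == 1:
            for k in range(nrows):
                new_rows[k].append(GAP)
            new_seq.append(seq[i - 1])
            i -= 1
        else:
            for k in range(nrows):
                new_rows[k].append(profile[k][j - 1])
            new_seq.append(GAP)
            j -= 1
    rows = ["".join(reversed(r)) for r in new_rows]
    return rows, "".join(reversed(new_seq))


def align_panel(panel: SequencePanel, match: float = 1.0,
                mismatch: float = -1.0, gap: float = -2.0) -> SequencePanel:
    """Progressively align a panel (guide order = input order).

    Each sequence is aligned to the growing profile by global
    Needleman-Wunsch with linear gap costs; sufficient for congeneric
    marker loci where indels are short and sparse.
    """
    for rec in panel.records:
        if not rec.sequence:
            raise PanelError(f"empty sequence for {rec.species}")
    if len(panel.records) == 1:
        return SequencePanel(panel.records, [panel.records[0].sequence])
    profile = [panel.records[0].sequence]
    for rec in panel.records[1:]:
        profile, new_row = _nw_profile(profile, rec.sequence, match, mismatch, gap)
        profile.append(new_row)
    return SequencePanel(list(panel.records), profile)


def pairwise_nw_score(a: str, b: str, match: float = 1.0,
                      mismatch: float = -1.0, gap: float = -2.0) -> float:
    """Optimal global alignment score of two sequences (linear gap cost)."""
    aligned, _ = _nw_profile([a], b, match, mismatch, gap)
    row_a, row_b = aligned[0], _
    score = 0.0
    for x, y in zip(row_a, row_b):
        if x == GAP or y == GAP:
            score += gap
        elif x == y:
            score += match
        else:
            score += mismatch
    return score


# ---------------------------------------------------------------------------
# Divergence scanning
# ---------------------------------------------------------------------------

def divergence_scan(panel: SequencePanel, window: int = 20,
                    stride: int = 5) -> list[DivergenceProfile]:
    """Score alignment windows by how many species they uniquely identify.

    A species is discriminating in a window iff its gapped window string
    differs from every other row's window string.
    """
    if panel.aligned is None:
        raise PanelError("panel must be aligned before scanning")
    ncol = panel.alignment_length
    if window > ncol:
        raise PanelError(f"window {window} exceeds alignment length {ncol}")
    if window < 1 or stride < 1:
        raise PanelError("window and stride must be positive")
    species = panel.species
    profiles: list[DivergenceProfile] = []
    for start in range(0, ncol - window + 1, stride):
        segs = [row[start:start + window] for row in panel.aligned]
        disc = frozenset(
            sp for i, sp in enumerate(species)
            if all(segs[i] != segs[j] for j in range(len(segs)) if j != i)
        )
        profiles.append(DivergenceProfile(start, window, disc, len(disc)))
    return profiles


# ---------------------------------------------------------------------------
# Coordinate maps (gapped <-> ungapped, 0-based half-open)
# ---------------------------------------------------------------------------

def gapped_to_ungapped(panel: SequencePanel, species: str,
                       gapped_index: int) -> tuple[int, bool]:
    """Map an alignment column to an ungapped position for one species.

    Returns ``(position, on_gap)``. If the column holds a gap in this
    species' row, the position of the next non-gap base is returned and
    ``on_gap`` is True (at end-of-row gaps this equals the sequence length).
    """
    row = panel.aligned_row(species)
    if not 0 <= gapped_index < len(row):
        raise IndexError(gapped_index)
    pos = sum(1 for c in row[:gapped_index] if c != GAP)
    return pos, row[gapped_index] == GAP


def ungapped_to_gapped(panel: SequencePanel, species: str,
                       ungapped_index: int) -> int:
    """Inverse map: ungapped position -> alignment column (exact, no flag)."""
    row = panel.aligned_row(species)
    count = 0
    for col, c in enumerate(row):
        if c != GAP:
            if count == ungapped_index:
                return col
            count += 1
    raise IndexError(ungapped_index)


# ---------------------------------------------------------------------------
# Synthetic ITS-like panel generation
# ---------------------------------------------------------------------------

# Conserved blocks are fixed (seed-independent) analogues of the rRNA genes
# flanking the two spacers, so that "universal" primers anchored in them
# amplify every species in a synthetic panel.
_FLANK_RNG = np.random.default_rng(20120728)
_B = np.array(list("ACGT"))
CONSERVED_5P_FLANK = "".join(_FLANK_RNG.choice(_B, size=62))
CONSERVED_MID = "".join(_FLANK_RNG.choice(_B, size=162))
CONSERVED_3P_FLANK = "".join(_FLANK_RNG.choice(_B, size=62))
_SPACER_LEN = 238  # each of the two variable spacers


def generate_synthetic_panel(
    n_species: int = 7,
    n_targets: int = 4,
    spacer_divergence: float = 0.05,
    seed: int = 0,
) -> SequencePanel:
    """Generate an unaligned panel emulating a ribosomal marker locus.

    Each sequence is conserved 5' flank + variable spacer 1 + conserved
    central gene + variable spacer 2 + conserved 3' flank (762 bp total).
    Species sequences derive from a common ancestor by random substitution
    at ``spacer_divergence`` per site, confined to the spacers. Two
    reserved positions per spacer per species carry a guaranteed private
    substitution, so every species has discriminating sites at any
    positive divergence.
    """
    if n_targets > n_species:
        raise PanelError("n_targets cannot exceed n_species")
    if not 0 <= spacer_divergence <= 0.3:
        raise PanelError("spacer_divergence must be in [0, 0.3]")
    if spacer_divergence == 0 and n_species > 1:
        warnings.warn(
            "divergence 0 with multiple species: sequences are identical and "
            "species-specific design will fail downstream",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    spacers = [
        "".join(rng.choice(_B, size=_SPACER_LEN)) for _ in range(2)
    ]

    # Reserved discriminating positions: 2 per spacer per species, spread
    # over the spacer interior and excluded from random mutation.
    n_reserved = 2 * n_species
    reserved: list[np.ndarray] = []
    for _ in spacers:
        pos = np.linspace(10, _SPACER_LEN - 11, n_reserved).round().astype(int)
        reserved.append(pos)

    records = []
    for i in range(n_species):
        parts = [CONSERVED_5P_FLANK]
        for s_idx, ancestor in enumerate(spacers):
            arr = np.array(list(ancestor))
            if spacer_divergence > 0:
                mask = rng.random(_SPACER_LEN) < spacer_divergence
                mask[reserved[s_idx]] = False
                for j in np.flatnonzero(mask):
                    alts = [b for b in "ACGT" if b != arr[j]]
                    arr[j] = alts[rng.integers(3)]
                # guaranteed private sites for this species, spread so that
                # different species' discriminating windows need not overlap
                for j in (reserved[s_idx][i], reserved[s_idx][i + n_species]):
                    alts = [b for b in "ACGT" if b != ancestor[j]]
                    arr[j] = alts[i % 3]
            parts.append("".join(arr))
            if s_idx == 0:
                parts.append(CONSERVED_MID)
        parts.append(CONSERVED_3P_FLANK)
        role = Role.TARGET if i < n_targets else Role.NON_TARGET
        species = f"Species_{i + 1:02d}"
        records.append(
            SequenceRecord(f"syn{i + 1:02d}", species, role, "".join(parts))
        )
    return SequencePanel(records)
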