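"""Species-specific primer candidate enumeration and pairing.

The specificity criterion is exact-match uniqueness: a candidate window (or
its reverse complement for reverse primers) must occur as a substring of
its own species' marker sequence and of no other sequence in the panel.
Candidates whose 3'-terminal bases differ from every other species get a
ranking bonus, since 3' mismatches dominate PCR discrimination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import insilico_pcr
from .panel import SequencePanel, ungapped_to_gapped
from .thermo import (
    Oligo,
    melting_temperature,
    reverse_complement,
    self_structure_score,
)

__all__ = [
    "Strand",
    "PrimerCandidate",
    "PrimerPair",
    "enumerate_candidates",
    "pair_candidates",
    "design_pairs",
    "verify_primer_table",
    "DEFAULT_LENGTH_RANGE",
    "DEFAULT_TM_RANGE",
    "DEFAULT_AMPLICON_RANGE",
]

from .insilico_pcr import Strand

DEFAULT_LENGTH_RANGE = (18, 27)
DEFAULT_TM_RANGE = (60.0, 73.0)
DEFAULT_AMPLICON_RANGE = (50, 300)


@dataclass(frozen=True)
class PrimerCandidate:
    """A strand-specific candidate primer on one species' template.

    ``site`` is the 0-based half-open top-strand interval the oligo covers;
    for reverse candidates the oligo is the reverse complement of the
    template substring at ``site``.
    """

    oligo: Oligo
    species: str
    strand: Strand
    site: tuple[int, int]
    tm: float
    three_prime_discriminates: bool = False

    def __len__(self) -> int:
        return len(self.oligo)


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse candidate pair for one species."""

    name: str
    forward: PrimerCandidate
    reverse: PrimerCandidate

    def __post_init__(self) -> None:
        if self.forward.species != self.reverse.species:
            raise ValueError("pair spans two species")
        if self.forward.strand is not Strand.PLUS:
            raise ValueError("forward candidate must be plus-strand")
        if self.reverse.strand is not Strand.MINUS:
            raise ValueError("reverse candidate must be minus-strand")
        if not self.forward.site[0] < self.reverse.site[1]:
            raise ValueError("reverse site must end after forward site starts")
        if self.amplicon_length < len(self.forward) + len(self.reverse):
            raise ValueError("amplicon shorter than the two primers")

    @property
    def species(self) -> str:
        return self.forward.species

    @property
    def amplicon_length(self) -> int:
        return self.reverse.site[1] - self.forward.site[0]


def _three_prime_discriminates(
    panel: SequencePanel, species: str, site: tuple[int, int],
    strand: Strand, n_terminal: int = 4,
) -> bool:
    """True iff the 3'-terminal columns differ from every other species."""
    if panel.aligned is None:
        return False
    if strand is Strand.PLUS:
        positions = range(site[1] - n_terminal, site[1])
    else:
        positions = range(site[0], site[0] + n_terminal)
    try:
        cols = [ungapped_to_gapped(panel, species, p) for p in positions]
    except IndexError:
        return False
    row = panel.aligned_row(species)
    mine = "".join(row[c] for c in cols)
    for other in panel.species:
        if other == species:
            continue
        other_row = panel.aligned_row(other)
        if "".join(other_row[c] for c in cols) == mine:
            return False
    return True


def enumerate_candidates(
    panel: SequencePanel,
    species: str,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    tm_range: tuple[float, float] = DEFAULT_TM_RANGE,
    structure_threshold: int | None = None,
) -> list[PrimerCandidate]:
    """Enumerate species-specific primer candidates for one target.

    Every returned window is an exact substring of the target's ungapped
    sequence and of no other panel sequence (same top-strand logic for
    both orientations); Tm is within ``tm_range`` and the oligo passes the
    self-structure screen. Output order is deterministic: forward
    candidates then reverse, by position then length.
    """
    if species not in panel.species:
        raise KeyError(species)
    target = panel.record(species).sequence
    others = [r.sequence for r in panel.records if r.species != species]

    candidates: list[PrimerCandidate] = []
    lo, hi = length_range
    kwargs = {} if structure_threshold is None else {"threshold": structure_threshold}
    for strand in (Strand.PLUS, Strand.MINUS):
        for start in range(0, len(target) - lo + 1):
            for n in range(lo, hi + 1):
                end = start + n
                if end > len(target):
                    break
                window = target[start:end]
                if "N" in window:
                    continue
                if any(window in o for o in others):
                    continue
                seq = window if strand is Strand.PLUS else reverse_complement(window)
                try:
                    tm = melting_temperature(seq)
                except ValueError:
                    continue
                if not tm_range[0] <= tm <= tm_range[1]:
                    continue
                oligo = Oligo(seq)
                if self_structure_score(oligo, **kwargs).flagged:
                    continue
                candidates.append(
                    PrimerCandidate(
                        oligo=oligo,
                        species=species,
                        strand=strand,
                        site=(start, end),
                        tm=tm,
                        three_prime_discriminates=_three_prime_discriminates(
                            panel, species, (start, end), strand
                        ),
                    )
                )
    if not candidates:
        warnings.warn(
            f"no discriminating primer windows found for {species}",
            stacklevel=2,
        )
    return candidates


def pair_candidates(
    forwards: list[PrimerCandidate],
    reverses: list[PrimerCandidate],
    amplicon_range: tuple[int, int] = DEFAULT_AMPLICON_RANGE,
) -> list[PrimerPair]:
    """All geometrically valid pairings, shortest amplicons first.

    The amplicon runs from the forward site's start to the reverse site's
    end (top strand, half-open); primer sites may not overlap. Pairs with a
    3'-discriminating member sort before equal-length pairs without one.
    """
    pairs: list[PrimerPair] = []
    species = {c.species for c in forwards} | {c.species for c in reverses}
    if len(species) > 1:
        raise ValueError(f"candidates span several species: {sorted(species)}")
    abbrev = _species_abbrev(next(iter(species))) if species else ""
    for f in forwards:
        for r in reverses:
            if f.site[1] > r.site[0]:
                continue
            length = r.site[1] - f.site[0]
            if not amplicon_range[0] <= length <= amplicon_range[1]:
                continue
            pairs.append(PrimerPair(name="", forward=f, reverse=r))
    pairs.sort(
        key=lambda p: (
            p.amplicon_length,
            not (p.forward.three_prime_discriminates
                 or p.reverse.three_prime_discriminates),
            p.forward.site,
            p.reverse.site,
        )
    )
    return [
        PrimerPair(
            name=f"{abbrev}.{i + 1}.{p.amplicon_length}bp",
            forward=p.forward,
            reverse=p.reverse,
        )
        for i, p in enumerate(pairs)
    ]


def _species_abbrev(species: str) -> str:
    parts = [p for p in species.replace(".", " ").replace("_", " ").split() if p]
    if len(parts) >= 2:
        return (parts[0][0] + parts[-1][:4]).title()
    return species[:5]


def _thin_candidates(cands: list[PrimerCandidate],
                     tm_range: tuple[float, float]) -> list[PrimerCandidate]:
    """Keep one candidate per (strand, 3'-end position).

    Exhaustive enumeration returns every window length at every start; for
    panel assembly one representative per priming position suffices.
    Preference: 3'-discriminating, then Tm nearest the middle of the
    window, then shortest oligo.
    """
    tm_mid = 0.5 * (tm_range[0] + tm_range[1])
    best: dict[tuple[Strand, int], PrimerCandidate] = {}
    for c in cands:
        three_prime = c.site[1] if c.strand is Strand.PLUS else c.site[0]
        key = (c.strand, three_prime)
        rank = (not c.three_prime_discriminates, abs(c.tm - tm_mid), len(c))
        prev = best.get(key)
        if prev is None:
            best[key] = c
            continue
        prev_rank = (not prev.three_prime_discriminates,
                     abs(prev.tm - tm_mid), len(prev))
        if rank < prev_rank:
            best[key] = c
    return sorted(best.values(), key=lambda c: (c.strand.value, c.site))


class _PairScreener:
    """Pair-level cross-amplification check with per-oligo site caching."""

    def __init__(self, panel: SequencePanel, species: str,
                 max_product_length: int, k_max: int, m: int) -> None:
        self.records = list(panel.records)
        self.species = species
        self.max_len = max_product_length
        self.k_max = k_max
        self.m = m
        self._cache: dict[tuple[str, str], list] = {}

    def _sites(self, oligo: Oligo, rec) -> list:
        key = (oligo.sequence, rec.species)
        hit = self._cache.get(key)
        if hit is None:
            hit = insilico_pcr.find_binding_sites(oligo, rec, self.k_max, self.m)
            self._cache[key] = hit
        return hit

    def passes(self, pair: "PrimerPair") -> bool:
        target_ok = False
        for rec in self.records:
            f_sites = [s for s in self._sites(pair.forward.oligo, rec)
                       if s.strand is Strand.PLUS]
            r_sites = [s for s in self._sites(pair.reverse.oligo, rec)
                       if s.strand is Strand.MINUS]
            products = [
                r.end - f.start
                for f in f_sites for r in r_sites
                if f.start < r.end and r.end - f.start <= self.max_len
            ]
            if rec.species == self.species:
                target_ok = pair.amplicon_length in products
            elif products:
                return False
        return target_ok


def design_pairs(
    panel: SequencePanel,
    species: str,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    tm_range: tuple[float, float] = DEFAULT_TM_RANGE,
    amplicon_range: tuple[int, int] = DEFAULT_AMPLICON_RANGE,
    screen: bool = True,
    max_pairs: int = 30,
) -> list[PrimerPair]:
    """End-to-end candidate design for one target species.

    Enumerates candidates, thins them to one per priming position, forms
    pairs (shortest amplicons first) and, if ``screen``, keeps pairs that
    pass the non-target cross-amplification screen. At most one pair per
    distinct amplicon length is kept (so the result spans a range of
    product sizes for multiplex spacing), stopping once ``max_pairs``
    pairs are collected; screening runs in ascending amplicon-length
    order, so the kept set is the shortest feasible one.
    """
    cands = enumerate_candidates(panel, species, length_range, tm_range)
    cands = _thin_candidates(cands, tm_range)
    forwards = [c for c in cands if c.strand is Strand.PLUS]
    reverses = [c for c in cands if c.strand is Strand.MINUS]
    pairs = pair_candidates(forwards, reverses, amplicon_range)
    screener = None
    if screen:
        screener = _PairScreener(
            panel, species, insilico_pcr.DEFAULT_MAX_PRODUCT_LENGTH,
            insilico_pcr.DEFAULT_K_MAX, insilico_pcr.DEFAULT_CLAMP,
        )
    kept: list[PrimerPair] = []
    seen_lengths: set[int] = set()
    for pair in pairs:
        if pair.amplicon_length in seen_lengths:
            continue
        if screener is not None and not screener.passes(pair):
            continue
        kept.append(pair)
        seen_lengths.add(pair.amplicon_length)
        if max_pairs and len(kept) >= max_pairs:
            break
    return kept


# ---------------------------------------------------------------------------
# Verification of a typed-in primer table
# ---------------------------------------------------------------------------

def verify_primer_table(
    pairs_tsv: str | Path | pd.DataFrame,
    panel: SequencePanel,
    max_product_length: int = insilico_pcr.DEFAULT_MAX_PRODUCT_LENGTH,
    k_max: int = 0,
    m: int = insilico_pcr.DEFAULT_CLAMP,
) -> pd.DataFrame:
    """Check a primer table against a template panel by in-silico PCR.

    The table needs columns ``name, forward_seq, reverse_seq, species,
    expected_length``. Each row is amplified in silico against its species'
    template (exact annealing by default: published primers are expected to
    match their reference templates perfectly). The returned frame adds
    ``status`` (ok / length_mismatch / no_product / unverifiable) and
    ``predicted_length``; ``verified`` is True only for ``ok`` rows.
    """
    if isinstance(pairs_tsv, pd.DataFrame):
        table = pairs_tsv.copy()
    else:
        table = pd.read_csv(pairs_tsv, sep="\t")
    required = {"name", "forward_seq", "reverse_seq", "species", "expected_length"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"primer table missing columns: {sorted(missing)}")

    statuses, predicted = [], []
    for row in table.itertuples(index=False):
        if row.species not in panel.species:
            statuses.append("unverifiable")
            predicted.append(None)
            continue
        template = panel.record(row.species)
        hits = insilico_pcr.predict_amplicons_from_oligos(
            str(row.name),
            Oligo(row.forward_seq),
            Oligo(row.reverse_seq),
            template,
            max_product_length=max_product_length,
            k_max=k_max,
            m=m,
        )
        if not hits:
            statuses.append("no_product")
            predicted.append(None)
        else:
            lengths = [h.length for h in hits]
            best = min(lengths, key=lambda L: abs(L - int(row.expected_length)))
            predicted.append(best)
            statuses.append(
                "ok" if best == int(row.expected_length) else "length_mismatch"
            )
    out = table.copy()
    out["predicted_length"] = predicted
    out["status"] = statuses
    out["verified"] = out["status"] == "ok"
    return out
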