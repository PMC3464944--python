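"""In-silico PCR: binding-site search, amplicon prediction, specificity screens.

The annealing model is deliberately binary and conservative: a primer can
prime iff it sits on the template with at most ``k_max`` total mismatches
and a perfect 3'-terminal clamp of ``m`` bases. Template ``N`` bases count
as mismatches. A degraded-template simulator (memoryless random breakage)
models why short amplicons survive in processed material while long ones
fail.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .panel import SequencePanel, SequenceRecord
from .thermo import Oligo, reverse_complement

__all__ = [
    "Strand",
    "BindingSite",
    "AmpliconPrediction",
    "SpecificityReport",
    "Fragment",
    "DEFAULT_K_MAX",
    "DEFAULT_CLAMP",
    "DEFAULT_MAX_PRODUCT_LENGTH",
    "find_binding_sites",
    "predict_amplicons",
    "predict_amplicons_from_oligos",
    "screen_nontarget_panel",
    "simulate_degraded_template",
    "amplicon_survives",
]

DEFAULT_K_MAX = 2
DEFAULT_CLAMP = 3
DEFAULT_MAX_PRODUCT_LENGTH = 1000


class Strand(str, Enum):
    PLUS = "plus"
    MINUS = "minus"


@dataclass(frozen=True)
class BindingSite:
    """A qualifying primer annealing site on a template (top-strand coords)."""

    template_id: str
    strand: Strand
    start: int
    end: int
    mismatches: int
    three_prime_mismatches: int


@dataclass(frozen=True)
class AmpliconPrediction:
    """A predicted PCR product on one template."""

    pair_name: str
    template_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SpecificityReport:
    """Cross-amplification screen outcome for one primer pair."""

    pair_name: str
    target_hits: list[AmpliconPrediction]
    nontarget_hits: list[AmpliconPrediction]
    expected_length: int | None = None

    @property
    def passed(self) -> bool:
        if self.nontarget_hits:
            return False
        if not self.target_hits:
            return False
        if self.expected_length is None:
            return True
        return any(h.length == self.expected_length for h in self.target_hits)


def _window_mismatches(template: np.ndarray, probe: str) -> np.ndarray:
    """Mismatch count of ``probe`` against every template window (vectorised)."""
    n = len(probe)
    tarr = template
    if len(tarr) < n:
        return np.zeros((0, n), dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(tarr, n)
    parr = np.frombuffer(probe.encode(), dtype="S1")
    return windows != parr  # boolean mismatch matrix (n_windows, n)


def find_binding_sites(
    primer: Oligo,
    template: SequenceRecord | str,
    k_max: int = DEFAULT_K_MAX,
    m: int = DEFAULT_CLAMP,
) -> list[BindingSite]:
    """Scan both strands of a template for qualifying annealing sites.

    A site qualifies iff it has <= ``k_max`` Hamming mismatches in total and
    zero mismatches in the primer's 3'-terminal ``m`` bases. On the plus
    strand the 3' end is the right edge of the interval; on the minus
    strand (primer binds the bottom strand) it is the left edge. Sites are
    ordered by strand (plus first) then position.
    """
    if isinstance(template, str):
        seq = template.upper()
        tid = ""
    else:
        seq = template.sequence
        tid = template.id
    n = len(primer)
    if n > len(seq):
        return []
    tarr = np.frombuffer(seq.encode(), dtype="S1")

    sites: list[BindingSite] = []
    # plus strand: primer equals top-strand substring, 3' end at interval end
    mm = _window_mismatches(tarr, primer.sequence)
    if mm.size:
        total = mm.sum(axis=1)
        clamp = mm[:, n - m:].sum(axis=1)
        for pos in np.flatnonzero((total <= k_max) & (clamp == 0)):
            sites.append(
                BindingSite(tid, Strand.PLUS, int(pos), int(pos) + n,
                            int(total[pos]), int(clamp[pos]))
            )
    # minus strand: reverse-complement of primer equals top-strand substring;
    # the primer's 3'-terminal bases map to the interval's left edge
    mm = _window_mismatches(tarr, reverse_complement(primer.sequence))
    if mm.size:
        total = mm.sum(axis=1)
        clamp = mm[:, :m].sum(axis=1)
        for pos in np.flatnonzero((total <= k_max) & (clamp == 0)):
            sites.append(
                BindingSite(tid, Strand.MINUS, int(pos), int(pos) + n,
                            int(total[pos]), int(clamp[pos]))
            )
    return sites


def predict_amplicons_from_oligos(
    name: str,
    forward: Oligo,
    reverse: Oligo,
    template: SequenceRecord | str,
    max_product_length: int = DEFAULT_MAX_PRODUCT_LENGTH,
    k_max: int = DEFAULT_K_MAX,
    m: int = DEFAULT_CLAMP,
) -> list[AmpliconPrediction]:
    """All products a forward/reverse oligo pair can make on one template.

    One prediction per (plus-strand forward site, minus-strand reverse
    site) combination with forward.start < reverse.end and product length
    at most ``max_product_length``. Multiple products are all reported.
    """
    tid = template.id if isinstance(template, SequenceRecord) else ""
    f_sites = [s for s in find_binding_sites(forward, template, k_max, m)
               if s.strand is Strand.PLUS]
    r_sites = [s for s in find_binding_sites(reverse, template, k_max, m)
               if s.strand is Strand.MINUS]
    out = []
    for f in f_sites:
        for r in r_sites:
            if f.start < r.end and r.end - f.start <= max_product_length:
                out.append(AmpliconPrediction(name, tid, f.start, r.end))
    out.sort(key=lambda p: (p.start, p.end))
    return out


def predict_amplicons(
    pair,
    template: SequenceRecord | str,
    max_product_length: int = DEFAULT_MAX_PRODUCT_LENGTH,
    k_max: int = DEFAULT_K_MAX,
    m: int = DEFAULT_CLAMP,
) -> list[AmpliconPrediction]:
    """Products of a designed :class:`~plantid.design.PrimerPair` on a template."""
    return predict_amplicons_from_oligos(
        pair.name, pair.forward.oligo, pair.reverse.oligo, template,
        max_product_length, k_max, m,
    )


def screen_nontarget_panel(
    pair,
    panel: SequencePanel,
    max_product_length: int = DEFAULT_MAX_PRODUCT_LENGTH,
    k_max: int = DEFAULT_K_MAX,
    m: int = DEFAULT_CLAMP,
) -> SpecificityReport:
    """Cross-amplification screen of one pair against a species panel.

    Target hits come from the pair's own species; non-target hits are
    pooled over every other species in the panel (the "all-but-one"
    non-target panel construction). The pair passes iff it yields at least
    one product of the expected length on its target and none elsewhere.
    """
    species = pair.forward.species
    target_rec = panel.record(species)
    target_hits = predict_amplicons(pair, target_rec, max_product_length, k_max, m)
    nontarget_hits: list[AmpliconPrediction] = []
    for rec in panel.records:
        if rec.species == species:
            continue
        nontarget_hits.extend(
            predict_amplicons(pair, rec, max_product_length, k_max, m)
        )
    return SpecificityReport(
        pair_name=pair.name,
        target_hits=target_hits,
        nontarget_hits=nontarget_hits,
        expected_length=getattr(pair, "amplicon_length", None),
    )


# ---------------------------------------------------------------------------
# Template degradation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fragment:
    """A contiguous surviving piece of a degraded template."""

    template_id: str
    start: int
    end: int
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start


def simulate_degraded_template(
    template: SequenceRecord | str,
    mean_fragment_length: float,
    seed: int = 0,
) -> list[Fragment]:
    """Fragment a template by memoryless random breakage.

    Breakpoints follow a Poisson process with rate ``1/mean_fragment_length``
    along the molecule, so a span of length L stays intact with probability
    ~= exp(-L/lambda). Deterministic for a fixed seed.
    """
    if mean_fragment_length <= 0:
        raise ValueError("mean_fragment_length must be positive")
    if isinstance(template, str):
        seq, tid = template.upper(), ""
    else:
        seq, tid = template.sequence, template.id
    L = len(seq)
    rng = np.random.default_rng(seed)
    n_breaks = rng.poisson(L / mean_fragment_length)
    cuts = sorted({int(x) for x in np.ceil(rng.uniform(0, L, size=n_breaks))
                   if 0 < x < L})
    bounds = [0, *cuts, L]
    return [
        Fragment(tid, a, b, seq[a:b])
        for a, b in zip(bounds[:-1], bounds[1:])
        if b > a
    ]


def amplicon_survives(fragments: Iterable[Fragment], start: int, end: int) -> bool:
    """True iff some fragment fully contains the interval [start, end)."""
    return any(f.start <= start and f.end >= end for f in fragments)
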