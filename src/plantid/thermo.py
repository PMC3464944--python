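"""Oligo thermodynamics and primer-interaction screening.

Melting temperatures come from the unified nearest-neighbour model with
monovalent + divalent salt correction. Primer-primer interactions are
screened with a total-complementarity score over all ungapped relative
offsets (the screening style of dimer-checking tools used for forensic
multiplexes), plus a simple stem-loop hairpin guard.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "Oligo",
    "DimerReport",
    "melting_temperature",
    "gc_content",
    "cross_dimer_score",
    "self_structure_score",
    "reverse_complement",
    "DEFAULT_DIMER_THRESHOLD",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Flag threshold for the +1/-1 total-complementarity score. Calibrated so
# that a published four-pair identification multiplex that passed its
# interaction screen sits just below the flag line (its worst self-score
# is 7): flag iff best_score >= 8.
DEFAULT_DIMER_THRESHOLD = 8


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Oligo:
    """A single-stranded DNA oligo, written 5'->3'."""

    sequence: str
    name: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError("empty oligo")
        if len(seq) > 40:
            raise ValueError(f"oligo longer than 40 nt: {self.name or seq}")
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(f"non-ACGT characters in oligo: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DimerReport:
    """Best interaction between two oligos over all ungapped offsets."""

    oligo_a: str
    oligo_b: str
    best_score: int
    best_offset: int
    max_contiguous: int
    flagged: bool
    hairpin: bool = False


def melting_temperature(
    oligo: Oligo | str,
    monovalent_mM: float = 50.0,
    divalent_mM: float = 2.5,
    oligo_conc_nM: float = 250.0,
) -> float:
    """Nearest-neighbour duplex Tm in deg C.

    Defaults mirror a standard PCR buffer (50 mM monovalent, 2.5 mM Mg2+,
    0.25 uM primer in excess over template). The divalent correction is
    Owczarzy (2008); with ``divalent_mM=0`` the Na+-only entropy correction
    is used, and at 1 M Na+ both corrections vanish, exposing the bare
    unified nearest-neighbour model.
    """
    seq = oligo.sequence if isinstance(oligo, Oligo) else Oligo(oligo).sequence
    if len(seq) < 10:
        raise ValueError(
            f"oligo of length {len(seq)} is below the nearest-neighbour "
            "model's range (>= 10 nt)"
        )
    saltcorr = 7 if divalent_mM > 0 else 5
    return float(
        _mt.Tm_NN(
            seq,
            Na=monovalent_mM,
            Mg=divalent_mM,
            dnac1=oligo_conc_nM,
            dnac2=0,
            saltcorr=saltcorr,
        )
    )


def gc_content(oligo: Oligo | str) -> float:
    seq = oligo.sequence if isinstance(oligo, Oligo) else Oligo(oligo).sequence
    return (seq.count("G") + seq.count("C")) / len(seq)


def cross_dimer_score(
    a: Oligo, b: Oligo, threshold: int = DEFAULT_DIMER_THRESHOLD
) -> DimerReport:
    """Score the strongest duplex between two primers.

    ``a`` is read 5'->3' against ``b`` read 3'->5'; at each relative offset
    every Watson-Crick complementary aligned base scores +1 and every other
    aligned base scores -1, summed over the overlap. ``best_score`` is the
    maximum over offsets; ``max_contiguous`` is the longest complementary
    run at the best offset. Flagged iff best_score >= threshold.
    """
    sa = a.sequence
    sb_rev = b.sequence[::-1]  # b read 3'->5'
    la, lb = len(sa), len(sb_rev)
    comp_a = sa.translate(_COMPLEMENT)  # comp_a[i] is the base pairing a[i]

    best_score = -(la + lb)  # below any achievable score
    best_offset = 0
    best_run = 0
    for offset in range(-(lb - 1), la):
        score = 0
        run = 0
        max_run = 0
        overlapped = False
        for i in range(max(0, offset), min(la, lb + offset)):
            overlapped = True
            if comp_a[i] == sb_rev[i - offset]:
                score += 1
                run += 1
                max_run = max(max_run, run)
            else:
                score -= 1
                run = 0
        if overlapped and score > best_score:
            best_score = score
            best_offset = offset
            best_run = max_run
    return DimerReport(
        oligo_a=a.name or sa,
        oligo_b=b.name or b.sequence,
        best_score=best_score,
        best_offset=best_offset,
        max_contiguous=best_run,
        flagged=best_score >= threshold,
    )


def _has_hairpin(seq: str, min_stem: int = 4, min_loop: int = 3) -> bool:
    n = len(seq)
    for stem in range(min_stem, n // 2 + 1):
        for i in range(0, n - 2 * stem - min_loop + 1):
            left = seq[i:i + stem]
            target = reverse_complement(left)
            for j in range(i + stem + min_loop, n - stem + 1):
                if seq[j:j + stem] == target:
                    return True
    return False


def self_structure_score(
    a: Oligo,
    threshold: int = DEFAULT_DIMER_THRESHOLD,
    min_stem: int = 4,
    min_loop: int = 3,
) -> DimerReport:
    """Self-dimer score plus a hairpin guard.

    The report is ``cross_dimer_score(a, a)``; additionally any self-
    complementary stem of >= ``min_stem`` bp enclosing a loop of >=
    ``min_loop`` nt flags the oligo as a hairpin former.
    """
    report = cross_dimer_score(a, a, threshold)
    report.hairpin = _has_hairpin(a.sequence, min_stem, min_loop)
    report.flagged = report.flagged or report.hairpin
    return report
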