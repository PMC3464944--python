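"""Multiplex panel assembly: one primer pair per target species.

A feasible multiplex must (i) keep amplicon sizes within any one dye
channel at least ``min_spacing`` bp apart so capillary electrophoresis can
resolve them, and (ii) be free of predicted primer-primer dimers across
every oligo in the mix, including self-interactions. Selection is an exact
backtracking search minimising total amplicon length (the short-amplicon
preference that keeps the assay usable on degraded templates).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .design import PrimerPair
from .thermo import DEFAULT_DIMER_THRESHOLD, Oligo, cross_dimer_score

__all__ = [
    "ChannelRole",
    "DyeChannel",
    "MultiplexPanel",
    "InfeasiblePanelError",
    "DEFAULT_MIN_SPACING",
    "DEFAULT_BIN_HALF_WIDTH",
    "DEFAULT_CHANNELS",
    "select_panel",
    "assign_dyes",
    "set_efficiency_weights",
    "validate_panel",
    "required_channel_count",
]

DEFAULT_MIN_SPACING = 5
DEFAULT_BIN_HALF_WIDTH = 0.5


class ChannelRole(str, Enum):
    PRIMER = "primer"
    SIZE_STANDARD = "size_standard"


@dataclass(frozen=True)
class DyeChannel:
    name: str
    role: ChannelRole = ChannelRole.PRIMER


# Standard five-dye chemistry: four primer dyes plus a reserved ladder dye.
DEFAULT_CHANNELS = [
    DyeChannel("FAM"),
    DyeChannel("VIC"),
    DyeChannel("NED"),
    DyeChannel("PET"),
    DyeChannel("ROX", ChannelRole.SIZE_STANDARD),
]


class InfeasiblePanelError(RuntimeError):
    """No mutually compatible one-pair-per-species assignment exists."""


@dataclass
class MultiplexPanel:
    """A selected multiplex: pairs, dyes, concentrations and size bins."""

    pairs: dict[str, PrimerPair]                  # species -> pair
    dye_of_pair: dict[str, str] = field(default_factory=dict)   # pair -> dye
    efficiency_weight: dict[str, float] = field(default_factory=dict)
    bins: dict[str, tuple[float, float]] = field(default_factory=dict)
    channels: list[DyeChannel] = field(default_factory=lambda: list(DEFAULT_CHANNELS))

    def __post_init__(self) -> None:
        for species, pair in self.pairs.items():
            if pair.species != species:
                raise ValueError(
                    f"pair {pair.name} keyed under {species} but designed "
                    f"for {pair.species}"
                )
            self.efficiency_weight.setdefault(pair.name, 1.0)
            self.bins.setdefault(
                pair.name, (float(pair.amplicon_length), DEFAULT_BIN_HALF_WIDTH)
            )
        primer_channels = self.primer_channels
        if len(primer_channels) > 4:
            raise ValueError("at most 4 primer dye channels are supported")
        if sum(c.role is ChannelRole.SIZE_STANDARD for c in self.channels) != 1:
            raise ValueError("exactly one channel must carry the size standard")

    @property
    def primer_channels(self) -> list[DyeChannel]:
        return [c for c in self.channels if c.role is ChannelRole.PRIMER]

    @property
    def ladder_channel(self) -> DyeChannel:
        return next(c for c in self.channels
                    if c.role is ChannelRole.SIZE_STANDARD)

    @property
    def species(self) -> list[str]:
        return sorted(self.pairs)

    def pair_for(self, species: str) -> PrimerPair:
        return self.pairs[species]

    def oligos(self) -> list[Oligo]:
        out = []
        for sp in self.species:
            p = self.pairs[sp]
            out.append(p.forward.oligo)
            out.append(p.reverse.oligo)
        return out

    def to_dict(self) -> dict:
        return {
            "pairs": {
                sp: {
                    "name": p.name,
                    "forward": p.forward.oligo.sequence,
                    "reverse": p.reverse.oligo.sequence,
                    "amplicon_length": p.amplicon_length,
                    "dye": self.dye_of_pair.get(p.name),
                    "weight_nM": self.efficiency_weight[p.name],
                    "bin": list(self.bins[p.name]),
                }
                for sp, p in self.pairs.items()
            },
            "ladder_channel": self.ladder_channel.name,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# Constraint checks
# ---------------------------------------------------------------------------

def _dimer_clean(oligos: list[Oligo], threshold: int) -> tuple[bool, str]:
    for a, b in itertools.combinations_with_replacement(oligos, 2):
        if cross_dimer_score(a, b, threshold).flagged:
            return False, f"cross-dimer between {a.name or a.sequence} and " \
                          f"{b.name or b.sequence} (threshold {threshold})"
    return True, ""


def required_channel_count(lengths: list[float], min_spacing: float) -> int:
    """Minimum number of dye channels needed to space out these sizes.

    Sizes conflict when they differ by less than ``min_spacing``; the
    conflict graph of points on a line is a unit-interval graph, so the
    chromatic number equals the maximum number of sizes inside any open
    window of width ``min_spacing``.
    """
    xs = sorted(lengths)
    worst = 1 if xs else 0
    for i in range(len(xs)):
        j = i
        while j + 1 < len(xs) and xs[j + 1] - xs[i] < min_spacing:
            j += 1
        worst = max(worst, j - i + 1)
    return worst


def _spacing_feasible(lengths: list[float], min_spacing: float,
                      n_channels: int) -> bool:
    return required_channel_count(lengths, min_spacing) <= n_channels


def validate_panel(
    panel: MultiplexPanel,
    min_spacing: float = DEFAULT_MIN_SPACING,
    dimer_threshold: int = DEFAULT_DIMER_THRESHOLD,
) -> list[str]:
    """Independent invariant checker; returns a list of violations (empty = ok)."""
    problems: list[str] = []
    by_dye: dict[str, list[float]] = {}
    for sp, pair in panel.pairs.items():
        dye = panel.dye_of_pair.get(pair.name)
        if dye is None:
            problems.append(f"pair {pair.name} has no dye assigned")
            continue
        by_dye.setdefault(dye, []).append(pair.amplicon_length)
    for dye, lengths in by_dye.items():
        for a, b in itertools.combinations(sorted(lengths), 2):
            if abs(a - b) < min_spacing:
                problems.append(
                    f"channel {dye}: amplicons {a} and {b} closer than "
                    f"{min_spacing} bp"
                )
    ok, msg = _dimer_clean(panel.oligos(), dimer_threshold)
    if not ok:
        problems.append(msg)
    for name, w in panel.efficiency_weight.items():
        if w <= 0:
            problems.append(f"non-positive weight for {name}")
    for name, (nominal, hw) in panel.bins.items():
        if hw <= 0:
            problems.append(f"non-positive bin half-width for {name}")
    return problems


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def select_panel(
    candidates: dict[str, list[PrimerPair]],
    min_spacing: float = DEFAULT_MIN_SPACING,
    dimer_threshold: int = DEFAULT_DIMER_THRESHOLD,
    n_dye_channels: int = 1,
    channels: list[DyeChannel] | None = None,
) -> MultiplexPanel:
    """Pick one pair per species forming an optimal compatible multiplex.

    Exact backtracking search: species are visited in order of ascending
    candidate count (ties lexicographic), candidates in ascending amplicon
    length; branches whose partial total cannot beat the incumbent are
    pruned. The returned panel minimises total amplicon length with
    lexicographic species/pair-name tie-breaking, and is re-validated by
    :func:`validate_panel` before being returned.
    """
    if not candidates:
        raise InfeasiblePanelError("no species to select for")
    for sp, cands in candidates.items():
        if not cands:
            raise InfeasiblePanelError(f"species {sp} has no candidate pairs")

    order = sorted(candidates, key=lambda sp: (len(candidates[sp]), sp))
    ordered = {
        sp: sorted(candidates[sp], key=lambda p: (p.amplicon_length, p.name))
        for sp in order
    }
    min_len = {sp: ordered[sp][0].amplicon_length for sp in order}

    # Pairwise dimer compatibility is checked incrementally and memoised.
    dimer_cache: dict[tuple[str, str], bool] = {}

    def clean(a: Oligo, b: Oligo) -> bool:
        key = (a.sequence, b.sequence) if a.sequence <= b.sequence \
            else (b.sequence, a.sequence)
        hit = dimer_cache.get(key)
        if hit is None:
            hit = not cross_dimer_score(a, b, dimer_threshold).flagged
            dimer_cache[key] = hit
        return hit

    best: dict | None = None
    blockers: set[str] = set()

    def search(idx: int, chosen: list[PrimerPair], total: int) -> None:
        nonlocal best
        if best is not None:
            bound = total + sum(min_len[sp] for sp in order[idx:])
            if bound > best["total"]:
                return
        if idx == len(order):
            key = tuple(p.name for p in sorted(chosen, key=lambda p: p.species))
            if best is None or total < best["total"] or (
                total == best["total"] and key < best["key"]
            ):
                best = {"total": total, "key": key, "pairs": list(chosen)}
            return
        sp = order[idx]
        for cand in ordered[sp]:
            ok = True
            for oligo in (cand.forward.oligo, cand.reverse.oligo):
                if not clean(oligo, oligo):
                    ok = False
                    blockers.add(f"self-dimer in {cand.name}")
                    break
            if ok and not clean(cand.forward.oligo, cand.reverse.oligo):
                ok = False
                blockers.add(f"forward/reverse dimer in {cand.name}")
            if ok:
                for prev in chosen:
                    for a in (cand.forward.oligo, cand.reverse.oligo):
                        for b in (prev.forward.oligo, prev.reverse.oligo):
                            if not clean(a, b):
                                ok = False
                                blockers.add(
                                    f"cross-dimer {cand.name} x {prev.name}"
                                )
                                break
                        if not ok:
                            break
                    if not ok:
                        break
            if not ok:
                continue
            lengths = [p.amplicon_length for p in chosen] + [cand.amplicon_length]
            if not _spacing_feasible(lengths, min_spacing, n_dye_channels):
                blockers.add(
                    f"size spacing < {min_spacing} bp in {n_dye_channels} "
                    f"channel(s) when adding {cand.name}"
                )
                continue
            chosen.append(cand)
            search(idx + 1, chosen, total + cand.amplicon_length)
            chosen.pop()

    search(0, [], 0)
    if best is None:
        shown = sorted(blockers)
        detail = "; ".join(shown[:6]) or "no compatible combination"
        if len(shown) > 6:
            detail += f"; ... ({len(shown) - 6} more binding constraints)"
        raise InfeasiblePanelError(
            f"no feasible one-pair-per-species multiplex: {detail}"
        )

    panel = MultiplexPanel(
        pairs={p.species: p for p in best["pairs"]},
        channels=list(channels) if channels is not None else list(DEFAULT_CHANNELS),
    )
    panel = assign_dyes(panel, panel.primer_channels[:n_dye_channels],
                        min_spacing=min_spacing)
    problems = validate_panel(panel, min_spacing, dimer_threshold)
    if problems:  # pragma: no cover - selection guarantees these hold
        raise InfeasiblePanelError("; ".join(problems))
    return panel


def assign_dyes(
    panel: MultiplexPanel,
    channels: list[DyeChannel] | None = None,
    min_spacing: float = DEFAULT_MIN_SPACING,
) -> MultiplexPanel:
    """Deterministically distribute pairs over primer dye channels.

    Pairs are taken in ascending amplicon-length order and placed in the
    first channel where the within-channel spacing constraint still holds
    (single-channel assays trivially put everything on the first dye).
    Raises with the number of channels actually needed if unsatisfiable.
    """
    if channels is None:
        channels = panel.primer_channels
    channels = [c for c in channels if c.role is ChannelRole.PRIMER]
    if not channels:
        raise ValueError("need at least one primer dye channel")

    pairs = sorted(panel.pairs.values(), key=lambda p: (p.amplicon_length, p.name))
    loads: dict[str, list[float]] = {c.name: [] for c in channels}
    assignment: dict[str, str] = {}
    for pair in pairs:
        placed = False
        for ch in channels:
            if all(abs(pair.amplicon_length - L) >= min_spacing
                   for L in loads[ch.name]):
                loads[ch.name].append(pair.amplicon_length)
                assignment[pair.name] = ch.name
                placed = True
                break
        if not placed:
            needed = required_channel_count(
                [p.amplicon_length for p in pairs], min_spacing
            )
            raise InfeasiblePanelError(
                f"amplicon sizes cannot be spaced >= {min_spacing} bp apart in "
                f"{len(channels)} channel(s); {needed} channel(s) needed"
            )
    panel.dye_of_pair = assignment
    return panel


def set_efficiency_weights(
    panel: MultiplexPanel, weights: dict[str, float]
) -> MultiplexPanel:
    """Record empirically optimised per-pair primer concentrations (nM).

    Keys may be species names or pair names. Weights are data, not
    inference: the simulator consumes them as relative amplification
    efficiencies.
    """
    resolved: dict[str, float] = {}
    for key, value in weights.items():
        if value is None or not value > 0:
            raise ValueError(f"weight for {key} must be positive")
        if key in panel.pairs:
            resolved[panel.pairs[key].name] = float(value)
        elif key in {p.name for p in panel.pairs.values()}:
            resolved[key] = float(value)
        else:
            raise KeyError(f"{key} names neither a species nor a pair")
    panel.efficiency_weight.update(resolved)
    return panel
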