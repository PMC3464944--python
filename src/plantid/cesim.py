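"""Capillary-electrophoresis read-out simulation and bin-based calling.

The simulator renders each multiplex product as a Gaussian peak on its
dye channel, with an affine size->scan mobility model whose constants are
private to the simulator: the caller must recover the calibration from the
co-electrophoresed size-standard ladder, exactly as a fragment-analysis
package does. Species are reported present iff a sized peak falls within
the pair's bin (nominal size +/- half-width) in the pair's channel.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .multiplex import MultiplexPanel

__all__ = [
    "TemplateMixture",
    "Electropherogram",
    "PeakCall",
    "SpeciesCallReport",
    "LadderError",
    "LadderCalibration",
    "Product",
    "load_ladder_sizes",
    "GENESCAN_500_ROX",
    "simulate_yields",
    "simulate_trace",
    "render_trace",
    "fit_ladder",
    "call_peaks",
    "call_species",
    "run_assay",
    "DEFAULT_MOBILITY_SD",
]

_DATA_DIR = Path(__file__).parent / "data"

# Sizing-model defaults. mobility_sd is the residual per-product sizing
# dispersion after ladder correction; 0.10 bp keeps the +/-0.5 bp bin a
# five-sigma interval (see docs/methods.md).
DEFAULT_MOBILITY_SD = 0.10
DEFAULT_SCAN_OFFSET = 500.0
DEFAULT_SCAN_SLOPE = 20.0      # scans per base
DEFAULT_PEAK_SD_BP = 0.35      # physical peak width, in bases
DEFAULT_LADDER_HEIGHT = 400.0
DEFAULT_HEIGHT_SCALE = 1000.0  # signal units per unit product quantity


def load_ladder_sizes(path: str | Path | None = None) -> list[float]:
    """Fragment sizes of the size standard (default: GeneScan-500 ROX set)."""
    p = Path(path) if path is not None else _DATA_DIR / "genescan500_rox.tsv"
    sizes = []
    with open(p) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            sizes.append(float(row["size_bp"]))
    return sorted(sizes)


GENESCAN_500_ROX = load_ladder_sizes()


class LadderError(RuntimeError):
    """Size-standard detection failed; traces cannot be sized."""


@dataclass
class TemplateMixture:
    """Template DNA amounts per species (arbitrary units), with optional
    degradation expressed as a mean intact fragment length in bases."""

    amounts: dict[str, float]
    degradation_lambda: float | None = None

    def __post_init__(self) -> None:
        for sp, amt in self.amounts.items():
            if not np.isfinite(amt) or amt < 0:
                raise ValueError(f"amount for {sp} must be finite and >= 0")
        if self.degradation_lambda is not None and self.degradation_lambda <= 0:
            raise ValueError("degradation_lambda must be positive")


@dataclass(frozen=True)
class Product:
    """A fragment population to render: dye channel, size (bp), quantity."""

    channel: str
    size: float
    quantity: float


@dataclass
class Electropherogram:
    """Per-dye signal arrays indexed by scan number, plus ladder metadata."""

    channels: dict[str, np.ndarray]
    ladder_channel: str
    ladder_sizes: list[float]
    noise_sd: float = 0.0
    mobility_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.ladder_channel not in self.channels:
            raise ValueError("ladder channel missing from trace")
        for name, sig in self.channels.items():
            if np.any(np.asarray(sig) < 0):
                raise ValueError(f"negative signal in channel {name}")

    @property
    def primer_channel_names(self) -> list[str]:
        return [c for c in self.channels if c != self.ladder_channel]

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        names = list(self.channels)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["scan", *names])
            for i in range(len(next(iter(self.channels.values())))):
                w.writerow([i, *(f"{self.channels[n][i]:.4f}" for n in names)])
        meta = {
            "ladder_channel": self.ladder_channel,
            "ladder_sizes": self.ladder_sizes,
            "noise_sd": self.noise_sd,
            "mobility_sd": self.mobility_sd,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2) + "\n"
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Electropherogram":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        with open(path) as fh:
            reader = csv.reader(fh)
            header = next(reader)
            names = header[1:]
            cols: list[list[float]] = [[] for _ in names]
            for row in reader:
                for c, v in zip(cols, row[1:]):
                    c.append(float(v))
        return cls(
            channels={n: np.asarray(c) for n, c in zip(names, cols)},
            ladder_channel=meta["ladder_channel"],
            ladder_sizes=meta["ladder_sizes"],
            noise_sd=meta.get("noise_sd", 0.0),
            mobility_sd=meta.get("mobility_sd", 0.0),
        )


@dataclass(frozen=True)
class PeakCall:
    channel: str
    measured_size: float
    height: float
    scan: float


@dataclass
class SpeciesCallReport:
    calls: dict[str, bool]
    supporting_peak: dict[str, PeakCall | None]
    unassigned_peaks: list[PeakCall]

    @property
    def present(self) -> set[str]:
        return {sp for sp, ok in self.calls.items() if ok}


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_yields(
    panel: MultiplexPanel,
    mix: TemplateMixture,
    seed: int | None = None,
) -> dict[str, float]:
    """Expected product quantity per pair.

    quantity = template amount x primer-pair efficiency weight x the
    probability exp(-L/lambda) that an amplicon of length L survived
    template degradation (1 if no degradation). Deterministic; the seed is
    reserved for downstream trace noise.
    """
    lam = mix.degradation_lambda
    out: dict[str, float] = {}
    for species, pair in panel.pairs.items():
        amount = mix.amounts.get(species, 0.0)
        survival = 1.0 if lam is None else float(
            np.exp(-pair.amplicon_length / lam)
        )
        out[pair.name] = amount * panel.efficiency_weight[pair.name] * survival
    return out


def render_trace(
    products: list[Product],
    ladder_channel: str = "ROX",
    ladder_sizes: list[float] | None = None,
    primer_channels: list[str] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    scan_offset: float = DEFAULT_SCAN_OFFSET,
    scan_slope: float = DEFAULT_SCAN_SLOPE,
    peak_sd_bp: float = DEFAULT_PEAK_SD_BP,
    height_scale: float = DEFAULT_HEIGHT_SCALE,
    ladder_height: float = DEFAULT_LADDER_HEIGHT,
) -> Electropherogram:
    """Render products at *exact* sizes into a multi-channel trace.

    Low-level renderer: no mobility jitter is applied here, so tests and
    calibration sweeps can place a peak at a precisely known size.
    """
    if ladder_sizes is None:
        ladder_sizes = GENESCAN_500_ROX
    channel_names = {p.channel for p in products}
    if primer_channels is not None:
        channel_names |= set(primer_channels)
    if ladder_channel in channel_names:
        raise ValueError("ladder channel must be distinct from primer channels")

    n_scans = int(scan_offset + scan_slope * (max(ladder_sizes) + 10))
    scans = np.arange(n_scans, dtype=float)
    rng = np.random.default_rng(seed)
    sd_scans = peak_sd_bp * scan_slope

    def gaussian(center: float, height: float) -> np.ndarray:
        return height * np.exp(-0.5 * ((scans - center) / sd_scans) ** 2)

    channels: dict[str, np.ndarray] = {
        name: np.zeros(n_scans) for name in sorted(channel_names)
    }
    channels[ladder_channel] = np.zeros(n_scans)
    for p in products:
        if p.quantity <= 0:
            continue
        center = scan_offset + scan_slope * p.size
        channels[p.channel] += gaussian(center, p.quantity * height_scale)
    for size in ladder_sizes:
        center = scan_offset + scan_slope * size
        channels[ladder_channel] += gaussian(center, ladder_height)
    if noise_sd > 0:
        for name in channels:
            channels[name] = np.clip(
                channels[name] + rng.normal(0.0, noise_sd, n_scans), 0.0, None
            )
    return Electropherogram(
        channels=channels,
        ladder_channel=ladder_channel,
        ladder_sizes=list(ladder_sizes),
        noise_sd=noise_sd,
    )


def simulate_trace(
    quantities: dict[str, float],
    panel: MultiplexPanel,
    noise_sd: float | None = None,
    mobility_sd: float = DEFAULT_MOBILITY_SD,
    seed: int | None = None,
    **render_kwargs,
) -> Electropherogram:
    """Simulate the electropherogram of a multiplex run.

    Each product renders a Gaussian peak at its nominal size plus
    N(0, mobility_sd) bp of residual sizing dispersion; the ladder channel
    carries the full size-standard fragment set. ``noise_sd`` defaults to
    1% of the maximum product signal. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    name_to_pair = {p.name: p for p in panel.pairs.values()}
    height_scale = render_kwargs.get("height_scale", DEFAULT_HEIGHT_SCALE)
    products = []
    for pair_name, qty in quantities.items():
        pair = name_to_pair[pair_name]
        nominal = panel.bins[pair_name][0]
        jitter = rng.normal(0.0, mobility_sd) if mobility_sd > 0 else 0.0
        dye = panel.dye_of_pair.get(pair_name, panel.primer_channels[0].name)
        products.append(Product(dye, nominal + jitter, qty))
    peak_max = max((q for q in quantities.values()), default=0.0)
    if noise_sd is None:
        noise_sd = 0.01 * peak_max * height_scale
    # keep the size standard commensurate with the products, as in a real
    # run where injection is balanced; otherwise product-scaled baseline
    # noise could drown the ladder
    render_kwargs.setdefault(
        "ladder_height",
        max(DEFAULT_LADDER_HEIGHT, 0.5 * peak_max * height_scale),
    )
    eph = render_trace(
        products,
        ladder_channel=panel.ladder_channel.name,
        primer_channels=[c.name for c in panel.primer_channels],
        noise_sd=noise_sd,
        seed=int(rng.integers(2**31)),
        **render_kwargs,
    )
    eph.mobility_sd = mobility_sd
    return eph


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def _local_maxima(signal: np.ndarray, min_height: float,
                  window: int = 5) -> list[int]:
    """Indices of peaks: points that dominate a +/-``window``-scan
    neighbourhood (ties broken leftward), at or above ``min_height``.
    The windowed test rejects noise wiggles riding on peak flanks."""
    s = np.asarray(signal)
    n = len(s)
    idx = []
    for i in np.flatnonzero(s >= min_height):
        if i == 0 or i == n - 1:
            continue
        lo, hi = max(0, i - window), min(n, i + window + 1)
        seg = s[lo:hi]
        if s[i] < seg.max():
            continue
        # leftmost point of any plateau/tie wins
        if np.argmax(seg) + lo == i:
            idx.append(int(i))
    return idx


def _apex(signal: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-scan apex via parabolic interpolation on log-signal.

    A Gaussian peak is exactly parabolic in log space, so the noiseless
    apex is recovered to machine precision; with a zero or negative
    neighbour the raw-signal parabola is used instead.
    """
    y0, y1, y2 = signal[i - 1], signal[i], signal[i + 1]
    if y0 > 0 and y1 > 0 and y2 > 0:
        l0, l1, l2 = np.log(y0), np.log(y1), np.log(y2)
        denom = l0 - 2 * l1 + l2
        delta = 0.0 if denom == 0 else 0.5 * (l0 - l2) / denom
    else:
        denom = y0 - 2 * y1 + y2
        delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return i + delta, float(y1)


@dataclass
class LadderCalibration:
    """Monotone scan->size map interpolated between detected ladder peaks."""

    scans: np.ndarray
    sizes: np.ndarray

    def size_at(self, scan: float) -> float | None:
        """Fragment size at a scan position; None outside the calibrated range
        (extrapolation is refused)."""
        if scan < self.scans[0] or scan > self.scans[-1]:
            return None
        return float(np.interp(scan, self.scans, self.sizes))


def fit_ladder(
    eph: Electropherogram,
    min_height: float | None = None,
) -> LadderCalibration:
    """Match detected ladder peaks to the known fragment sizes, in order.

    Piecewise-linear interpolation between adjacent ladder points; raises
    :class:`LadderError` if the detected peak count does not match the
    standard's fragment count or fewer than 4 peaks are found.
    """
    signal = eph.channels[eph.ladder_channel]
    n_expected = len(eph.ladder_sizes)
    if min_height is None:
        # low floor; the rank-based selection below does the real work
        min_height = 0.05 * float(signal.max()) if signal.max() > 0 else np.inf
    idx = _local_maxima(signal, min_height)
    if len(idx) < max(4, n_expected):
        raise LadderError(
            f"ladder failure: only {len(idx)} size-standard peaks detected "
            f"for a {n_expected}-fragment standard"
        )
    # Take the n tallest maxima as the ladder, requiring clear separation
    # from whatever noise maxima remain (else the ladder is ambiguous).
    by_height = sorted(idx, key=lambda i: -signal[i])
    chosen = by_height[:n_expected]
    if len(by_height) > n_expected:
        tallest_rest = signal[by_height[n_expected]]
        if tallest_rest > 0.5 * signal[chosen[-1]]:
            raise LadderError(
                f"ladder failure: {len(by_height)} comparable peaks for a "
                f"{n_expected}-fragment standard"
            )
    idx = sorted(chosen)
    apexes = [_apex(signal, i)[0] for i in idx]
    return LadderCalibration(
        scans=np.asarray(apexes), sizes=np.asarray(sorted(eph.ladder_sizes))
    )


def call_peaks(
    eph: Electropherogram,
    min_height: float | None = None,
    calibration: LadderCalibration | None = None,
) -> list[PeakCall]:
    """Detect, apex-interpolate and size peaks in every primer channel.

    ``min_height`` defaults to 5% of the largest primer-channel signal.
    Peaks whose apex lies outside the ladder's calibrated range are
    dropped (no extrapolated sizes).
    """
    if calibration is None:
        calibration = fit_ladder(eph)
    if min_height is None:
        peak_max = max(
            (float(eph.channels[c].max()) for c in eph.primer_channel_names),
            default=0.0,
        )
        if peak_max <= 0:
            return []
        min_height = 0.05 * peak_max
    calls: list[PeakCall] = []
    for name in eph.primer_channel_names:
        signal = eph.channels[name]
        for i in _local_maxima(signal, min_height):
            scan, height = _apex(signal, i)
            size = calibration.size_at(scan)
            if size is None:
                continue
            calls.append(PeakCall(name, size, height, scan))
    calls.sort(key=lambda c: (c.channel, c.measured_size))
    return calls


# Tolerance for bin-edge comparisons: measured sizes are floats recovered
# through interpolation, so an exactly-on-edge peak must not be lost to
# last-bit rounding.
_EDGE_EPS = 1e-9


def call_species(
    peaks: list[PeakCall],
    panel: MultiplexPanel,
    min_height: float = 0.0,
) -> SpeciesCallReport:
    """Assign sized peaks to species bins and report presence/absence.

    A species is present iff a peak in its pair's dye channel lies within
    nominal +/- half_width of its bin. Each peak supports at most one
    species: the nearest bin wins, and a peak exactly equidistant between
    two bins is left unassigned with a warning.
    """
    bin_items = []  # (species, pair_name, dye, nominal, half_width)
    for species, pair in panel.pairs.items():
        nominal, hw = panel.bins[pair.name]
        dye = panel.dye_of_pair.get(pair.name, panel.primer_channels[0].name)
        bin_items.append((species, pair.name, dye, nominal, hw))

    calls = {sp: False for sp in panel.pairs}
    supporting: dict[str, PeakCall | None] = {sp: None for sp in panel.pairs}
    unassigned: list[PeakCall] = []
    for peak in peaks:
        if peak.height < min_height:
            continue
        in_range = [
            (abs(peak.measured_size - nominal), species)
            for species, _name, dye, nominal, hw in bin_items
            if dye == peak.channel
            and abs(peak.measured_size - nominal) <= hw + _EDGE_EPS
        ]
        if not in_range:
            unassigned.append(peak)
            continue
        in_range.sort()
        if len(in_range) > 1 and np.isclose(in_range[0][0], in_range[1][0]):
            warnings.warn(
                f"peak at {peak.measured_size:.2f} bp equidistant between the "
                f"{in_range[0][1]} and {in_range[1][1]} bins; left unassigned",
                stacklevel=2,
            )
            unassigned.append(peak)
            continue
        species = in_range[0][1]
        calls[species] = True
        prev = supporting[species]
        if prev is None or peak.height > prev.height:
            supporting[species] = peak
    return SpeciesCallReport(calls, supporting, unassigned)


def run_assay(
    panel: MultiplexPanel,
    mix: TemplateMixture,
    seed: int | None = None,
    noise_sd: float | None = None,
    mobility_sd: float = DEFAULT_MOBILITY_SD,
    min_peak_height: float | None = None,
) -> SpeciesCallReport:
    """Full pipeline: yields -> trace -> ladder -> peaks -> species calls."""
    quantities = simulate_yields(panel, mix, seed)
    eph = simulate_trace(quantities, panel, noise_sd=noise_sd,
                         mobility_sd=mobility_sd, seed=seed)
    peaks = call_peaks(eph, min_height=min_peak_height)
    return call_species(peaks, panel)
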