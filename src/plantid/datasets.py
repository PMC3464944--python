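"""Bundled reference data.

``hypericum_primers.tsv`` is the published candidate primer panel for the
four-species *Hypericum* identification assay (nrITS species-specific
pairs with their reported melting temperatures and amplicon sizes); it is
input data for verification and multiplex-geometry work, not something
this package re-derives. The GenBank nrITS accessions the panel was
designed against are listed for optional validation runs; they are never
fetched automatically.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = [
    "load_hypericum_primers",
    "selected_amplicon_sizes",
    "HYPERICUM_ACCESSIONS",
    "HYPERICUM_PRIMER_MIX_NM",
    "BIN_SETS",
]

_DATA_DIR = Path(__file__).parent / "data"

#: GenBank nrITS accessions per species (optional validation templates).
HYPERICUM_ACCESSIONS = {
    "Hypericum calycinum": "AJ414728",
    "Hypericum perforatum": "AY555839",
    "Hypericum maculatum": "AY555842",
    "Hypericum athoum": "AY555846",
    "Hypericum ascyron": "AY555849",
    "Hypericum kouytchense": "AY555853",
    "Hypericum androsaemum": "AY573012",
}

#: Empirically optimised per-pair primer concentrations for the published
#: four-species multiplex (nM).
HYPERICUM_PRIMER_MIX_NM = {
    "Hypericum perforatum": 500.0,
    "Hypericum athoum": 110.0,
    "Hypericum androsaemum": 80.0,
    "Hypericum ascyron": 400.0,
}

#: Alternative published bin configurations for the selected four-pair
#: multiplex. The primer table reports the selected *H. athoum* amplicon at
#: 151 bp while the published electropherogram annotation reads 131 bp;
#: both size sets are carried and the table values are the default.
BIN_SETS = {
    "published_table": {
        "Hypericum androsaemum": 67.0,
        "Hypericum athoum": 151.0,
        "Hypericum perforatum": 222.0,
        "Hypericum ascyron": 231.0,
    },
    "electropherogram": {
        "Hypericum androsaemum": 67.0,
        "Hypericum athoum": 131.0,
        "Hypericum perforatum": 222.0,
        "Hypericum ascyron": 231.0,
    },
}


def load_hypericum_primers() -> pd.DataFrame:
    """The published candidate primer panel (19 pairs, 4 target species)."""
    return pd.read_csv(_DATA_DIR / "hypericum_primers.tsv", sep="\t")


def selected_amplicon_sizes(bin_set: str = "published_table") -> dict[str, float]:
    """Nominal amplicon sizes of the four selected pairs, by species."""
    return dict(BIN_SETS[bin_set])
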