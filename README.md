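# plantid

Species-specific multiplex PCR assay design and capillary-electrophoresis
read-out simulation, for DNA-based authentication of plant material in
complex mixtures (e.g. detecting a medicinal species and its adulterants in
one reaction).

## The problem

Herbal products are frequently adulterated or substituted, and neither
morphology nor chemistry can resolve a *mixture* of closely related species.
A fragment-analysis assay can: align the nuclear ribosomal internal
transcribed spacer (nrITS) marker across a set of congeneric species, design
a PCR primer pair that anneals *only* to one target species, make each
species' amplicon a distinct length, pool the pairs into one fluorescent
multiplex, and read the products on a capillary sequencer against a size
standard. Every expected species then appears as a peak in its own size bin
(nominal length ± 0.5 bp); an unexpected peak flags an adulterant. Keeping
amplicons as short as possible (the miniSTR principle) keeps the assay
working on degraded, highly processed material, where a ~750 bp marker no
longer amplifies but a ~160 bp fragment still does.

`plantid` implements that whole design-and-read-out loop as software:

| module | role |
|---|---|
| `plantid.panel` | panel I/O, progressive global alignment, divergence scanning, gapped↔ungapped coordinates, synthetic ITS-like panel generator |
| `plantid.thermo` | nearest-neighbour Tm, GC content, cross-dimer / hairpin screening (±1 complementarity score over all offsets) |
| `plantid.design` | species-specific candidate enumeration (exact-match uniqueness), pairing with shortest-amplicon preference, primer-table verification |
| `plantid.insilico_pcr` | mismatch-tolerant binding-site search (≤ k mismatches, perfect 3′ clamp), amplicon prediction, non-target cross-amplification screens, degraded-template simulation |
| `plantid.multiplex` | exact one-pair-per-species selection under size-spacing and dimer constraints, dye-channel assignment, per-pair concentration weights |
| `plantid.cesim` | multiplex yield model, electropherogram simulation, ladder fitting, peak calling, bin-based species calls |

The core decision rules, in the field's usual notation: a primer of length
*n* may prime a template site iff its Hamming mismatch count is ≤ *k*
(default 2) with zero mismatches in the 3′-terminal *m* bases (default 3);
two primers are dimer-flagged iff max over ungapped offsets of
Σ(+1 per Watson–Crick pair, −1 otherwise) ≥ 8; an amplicon of length *L*
survives degradation with mean fragment length λ with probability
exp(−L/λ); and a species is called present iff a sized peak lies within
±0.5 bp of its bin in its dye channel.

## Worked example

Design a four-species multiplex on a synthetic seven-species ITS-like
panel, then simulate and call a two-species mixture:

```python
from plantid import (align_panel, generate_synthetic_panel, design_pairs,
                     select_panel, TemplateMixture, run_assay)

panel = align_panel(generate_synthetic_panel(n_species=7, n_targets=4,
                                             spacer_divergence=0.05, seed=1))
candidates = {sp: design_pairs(panel, sp) for sp in panel.targets}
mpx = select_panel(candidates, min_spacing=5, n_dye_channels=1)
for sp in mpx.species:
    p = mpx.pairs[sp]
    print(f"{sp}: {p.forward.oligo.sequence} / {p.reverse.oligo.sequence}"
          f"  {p.amplicon_length} bp")

mix = TemplateMixture({"Species_01": 1.0, "Species_03": 0.5})
report = run_assay(mpx, mix, seed=42)
for sp, ok in sorted(report.calls.items()):
    peak = report.supporting_peak[sp]
    extra = f"{peak.measured_size:6.2f} bp  height {peak.height:7.0f}" if peak else ""
    print(f"{sp}: {'PRESENT' if ok else 'absent '}  {extra}")
```

prints

```
Species_01: CTTTAGAGATGAAGTCCTTAATTACAC / GTAGTGTAGTACAAATACCGGCG  50 bp
Species_02: GATGAAGTCGTTAATTACTCCTCCGGA / CTCTATGGGTATGCTAGGTAGCGT  60 bp
Species_03: AAGTCGTTAAGTACTCCTCCGGAATAT / GAGGCGACGCTACATGGATATG  65 bp
Species_04: TGAAGTCGTTAATTACTCATCCGGAAG / CATGGGTATGCTAGGTAGTGAAGGA  55 bp
Species_01: PRESENT   49.98 bp  height    1000
Species_02: absent
Species_03: PRESENT   65.06 bp  height     497
Species_04: absent
```

The selected pairs are mutually dimer-clean, their amplicon sizes are ≥5 bp
apart on the single FAM channel, and the read-out recovers exactly the
species present in the mixture; peak heights track the template amounts
(the 0.5-unit species gives roughly half the signal), which is the
semiquantitative side of the assay.

The same steps are available from the shell:

```bash
plantid panel synth --seed 1 --out panel.fasta
plantid multiplex select --panel panel.fasta --out panel.json
plantid simulate --panel panel.fasta --mix mix.yaml --seed 42
plantid thermo tm CACATCGTCGCCCCAAAC      # -> 65.4
```

A published four-species *Hypericum* (St John's Wort) identification panel
(19 nrITS candidate primer pairs with reported Tm values and amplicon
sizes, amplicon bins 67/151/222/231 bp) ships in
`plantid.datasets.load_hypericum_primers()` and is used as reference data
for the thermodynamics and multiplex-geometry tests. To verify a primer
table against real templates (e.g. the GenBank nrITS accessions listed in
`plantid.datasets.HYPERICUM_ACCESSIONS`, downloaded by you):

```bash
plantid verify --primers primers.tsv --templates its_accessions.fasta
```

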