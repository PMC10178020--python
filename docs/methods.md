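# Methods

## Decomposition model

An N-glycopeptide fragmentation spectrum is treated as the superposition
of three fragment classes: oxonium ions from the glycan, a Y-ion series
from stepwise glycosidic cleavage of the conserved
Asn–HexNAc–HexNAc–Hex–Hex–Hex core, and peptide backbone b/y ions that
may retain the proximal HexNAc. Decomposition proceeds in three fixed
steps — oxonium classification, core-pattern placement, composite
spectrum generation — each driven entirely by named constants in
`glycodec.config.Config`. All m/z values are positive-mode, singly
protonated; inputs are assumed centroided, deisotoped and decharged, so
per-peak charge annotations are advisory and unknown charges are treated
as 1+ during deconvolution.

### Oxonium classification

For each of the six table ions the most intense peak within ± 0.02 Da is
its match; a peak may serve only one entry (on conflict the entry closest
in m/z keeps the peak and the loser takes its next in-window candidate).
The decision statistic is the matched intensity divided by the total
intensity of the prefiltered spectrum, so it is invariant under uniform
intensity scaling. Both gates — ≥ 1 distinct ion and relative sum
≥ 0.0047 — are inclusive. The denominator is the whole prefiltered
spectrum, not the sub-region below the precursor.

### Core-pattern placement

Reference candidates must satisfy m/z ≥ 850 Da (above the lightest
tryptic sequon-bearing peptide-plus-HexNAc) and intensity ≥ 10 % of the
base peak (the Y₁ ion is characteristically intense). Each template
offset may match at most one peak (the most intense within ± 0.05 Da);
an offset whose target is non-positive or below the first peak is simply
unmatched. A placement needs ≥ 2 matched offsets (reference included)
and a positive derived glycan mass. Ranking is by match count, then
reference intensity, then ascending reference m/z as a deterministic
tie-break. Placements whose references differ by k × 1.00335 Da
(k ≤ 3, ± 0.05 Da) can be grouped as isotope duplicates for reporting;
grouping never affects ranking.

### Composite spectra

Peptide composite: deconvolute → delete peaks within ± 0.02 Da of any
table oxonium m/z → delete peaks above reference + 0.05 Da (the Y₁ peak
itself therefore survives) → set precursor to (reference m/z, 1+).
Glycan composite: the deconvoluted spectrum with the glycan-moiety mass
as metadata; peaks are untouched. By construction
`peptide_moiety_mass + glycan_moiety_mass` equals the precursor neutral
mass exactly.

### Composition generation

The enumerator walks the bounded count space depth-first with
residual-mass pruning (per-position minimum/maximum attainable remainder)
and is set-equivalent to the four-nested-loop brute force; completeness
is the contract, speed a convenience. Output is sorted by |Δmass|, ties
by the count vector in Hex, HexNAc, dHex, NeuAc order; Δ is composition
minus query.

## Constants and numerical choices

| constant | default | unit | note |
|---|---|---|---|
| min peak intensity | 15 | counts | inclusive; same unit as the input file |
| oxonium tolerance | 0.02 | Da | detection and removal |
| min oxonium ions | 1 | — | inclusive |
| oxonium sum threshold | 0.0047 | fraction | inclusive |
| min reference m/z | 850 | Da | inclusive |
| min reference rel. intensity | 0.1 | of base peak | inclusive |
| pattern tolerance | 0.05 | Da | also the Y-ion truncation margin |
| min pattern peaks | 2 | — | reference + one |
| composition tolerance | 0.1 | Da | |
| monosaccharides | Hex 162.05282, HexNAc 203.07937, dHex 146.05791, NeuAc 291.09542 | Da | residue masses |
| bounds | Hex 0–12, HexNAc 1–7, dHex 0–3, NeuAc 0–4 | counts | |
| proton | 1.00727646 | Da | CODATA; used for all charge arithmetic |
| isotope spacing | 1.00335 | Da | ¹³C − ¹²C |
| merge window | 0.001 | Da | post-deconvolution duplicate merge |

The oxonium and pattern constants are stored at their published precision
and used verbatim. `masses.oxonium_mz` recomputes m/z from monoisotopic
element masses (C 12, H 1.00782503, N 14.0030740, O 15.9949146); it
reproduces the stored table to ≤ 1e-6 Da for HexHexNAc, NeuAc, NeuAc−H₂O
and HexHexNAcNeuAc and to 4 decimals for HexNAc. Two stored constants are
kept although they disagree with first-principles arithmetic: the
HexHexNAcdHex entry (512.19793, ~0.55 mDa above the elemental value) and
the −220.0821 offset (17.0027 Da below Y₀, matching no standard
deamidation shift); both are retained verbatim for configuration
fidelity. Charge deconvolution merges peaks by gap-clustering (clusters
split where consecutive gaps exceed 0.001 Da, each cluster collapsing to
its intensity-weighted centroid), which makes the operation idempotent.

## The simulator

`glycodec.simulator` emulates the fragment inventory the decomposer
relies on, not CID physics. A glycopeptide spectrum contains: the
oxonium ions its composition implies (HexNAc always; HexHexNAc with
Hex ≥ 1; NeuAc and NeuAc−H₂O with NeuAc ≥ 1; HexHexNAcNeuAc with both;
HexHexNAcdHex with dHex and Hex), scaled to a target 5 % of total
intensity; the 8-peak core pattern at exact positions, each non-reference
peak present with probability 0.9; b/y and b/y+HexNAc ions (glycosite at
the first N-X≠P-S/T sequon) each with probability 0.7; and 50 noise
peaks uniform in m/z between 200 Da and precursor m/z × charge. Fragment
intensities are log-uniform over 1e2–1e4 counts with the Y₁ reference
biased ×1.0–1.3 above the maximum, reflecting that Y₁ is typically among
the most intense peaks; noise is log-uniform over roughly 16–2000
counts so it survives the intensity prefilter. Everything derives from a
single seeded generator; a fixed seed reproduces spectra and truth
tables byte-for-byte. Non-glycopeptide spectra contain b/y ions and
noise only, with every peak displaced out of the ± 0.02 Da oxonium
windows so labelled negatives are clean by construction (a b/y ion can
otherwise collide with an oxonium m/z by coincidence).

Default pools: seven tryptic plasma-style sequon-bearing peptides and
eight plasma-like compositions (complex di/tri-antennary, fucosylated,
high-mannose). Cohorts of 1000 spectra are the standard evaluation size;
they simulate and decompose in a few seconds.

What the simulator does **not** model — and what passing tests therefore
do not show about real data: isotope envelopes and deisotoping errors,
chimeric precursors, peak m/z jitter (fragments sit at exact theoretical
positions), intensity correlation along ion series, in-source decay, and
glycans with non-canonical cores. Recovery rates on this generator
(≈ 100 % rank-1 at default noise) are accordingly upper bounds; on real
plasma data the analogous rank-1 figure is substantially lower.

## Open design choices

- The 6-ion production oxonium list is used; the larger exploratory
  screen behind it was never published.
- Each pattern offset matches the most intense in-window peak rather
  than the nearest, consistent with the intensity-driven ranking.
- The intensity prefilter threshold, both oxonium gates, and both
  reference gates are inclusive; boundary semantics were unstated.
- Identification equivalence applies the isotope offset symmetrically
  (min over k of ||ΔG| − k·1.00335|), since either result may have
  anchored on a non-monoisotopic precursor.
- The CLI `simulate`/`classify`/`decompose`/`compose-glycans`/`compare`/
  `report` subcommands are thin wrappers; the library functions are the
  primary interface.

## Known limitations

- O-glycopeptides and non-canonical N-glycan cores are out of scope (the
  partial-match design would tolerate the latter but is untested there).
- Glycan fragment ions are not yet used to constrain compositions; the
  generator is mass-only.
- No FDR control or search-engine integration: peptide composites are
  written to ms2 for external search.
- mzML and vendor raw formats are not read; MGF is the canonical input
  and ms2 the canonical peptide-composite output.
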