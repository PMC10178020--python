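# glycodec

Decomposition of N-glycopeptide tandem mass spectra into separate
peptide-moiety and glycan-moiety composite spectra.

## The problem

Collision-induced dissociation of an N-glycopeptide produces a hybrid
fragmentation spectrum: glycan oxonium ions (B-type sugar cations such as
HexNAc⁺ at m/z 204.0867), a Y-ion ladder in which the glycan is peeled
off the peptide one residue at a time, and peptide backbone b/y ions with
and without the proximal HexNAc. Searching such spectra with an ordinary
peptide search engine fails, and treating the glycan as one enormous
variable modification is intractable. `glycodec` splits the problem:

1. **Oxonium filter** — a spectrum is called a glycopeptide spectrum when
   at least one of six diagnostic oxonium ions (HexHexNAc 366.139472,
   HexHexNAcNeuAc 657.234889, HexHexNAcdHex 512.19793, NeuAc 292.102693,
   NeuAc−H₂O 274.092128, HexNAc 204.0867) is detected within 0.02 Da and
   the matched peaks carry ≥ 0.47 % of the total spectrum intensity.
2. **Core pattern finder** — all N-glycans share the
   Asn–HexNAc–HexNAc–Hex–Hex–Hex core, whose stepwise cleavage yields an
   8-peak pattern with fixed offsets
   `[-220.0821, -203.0794, -120.0423, 0, 203.0794, 365.1322, 527.185, 689.2378]`
   Da around the Y₁ = [peptide + HexNAc]¹⁺ reference peak. Candidate
   references (m/z ≥ 850, intensity ≥ 10 % of the base peak) are scored by
   the number of in-window (± 0.05 Da) pattern peaks and ranked by match
   count, then reference intensity. The rank-1 placement fixes the
   peptide-moiety mass `p = reference − proton − HexNAc` and the glycan
   mass `G = M − p` from the precursor neutral mass `M`.
3. **Spectrum modifier** — the peptide composite is the charge-deconvoluted
   spectrum with oxonium peaks removed, truncated above Y₁, and given the
   pseudo-precursor (Y₁, 1+); the glycan composite carries `G` as metadata.
4. **Composition generator** — every count vector over
   Hex/HexNAc/dHex/NeuAc within bounds Hex 0–12, HexNAc 1–7, dHex 0–3,
   NeuAc 0–4 whose mass lies within 0.1 Da of `G` is enumerated,
   database-free.

A built-in simulator generates glycopeptide and non-glycopeptide spectra
with full ground truth, so the whole pipeline is testable offline; a
comparison module implements the standard identification-equivalence rule
(same peptide sequence, glycan masses equal within 0.05 Da up to three
¹³C isotope shifts).

## Worked example

```sh
glycodec simulate --n-glyco 5 --n-nonglyco 5 --seed 1 --out demo
glycodec decompose demo.mgf --out-prefix demo_out
```

prints the outcome counts

```
non-glyco=5	decomposed=5	glyco-no-pattern=0	error=0
```

— all five simulated glycopeptides were decomposed and all five plain
peptide spectra passed through untouched. The decomposition table starts

```
source_id	reference_mz	peptide_moiety_mass	glycan_moiety_mass	n_matched
glyco_00000	2485.133363	2281.046717	1216.42284	8
glyco_00001	2366.296586	2162.20994	2861.000031	7
```

`reference_mz` is the chosen Y₁ peak, `n_matched` how many of the 8
pattern peaks supported it, and the two masses always sum to the
precursor neutral mass. Feeding a glycan mass to the composition
generator:

```sh
glycodec compose-glycans --mass 2204.77
```

```
composition	mass	delta
Hex5HexNAc4NeuAc2	2204.77242	+0.00242
```

identifies the disialylated biantennary complex glycan as the unique
in-bounds composition within 0.1 Da. Peptide-moiety composite spectra are
written as `demo_out_peptide.ms2`, ready for an ordinary peptide search
engine.

Every constant above lives in one flat YAML config
(`glycodec --config my.yaml …`); defaults are embedded.

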