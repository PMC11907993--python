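# smadscan

Strand- and orientation-aware analysis of **SMAD composite DNA motifs** —
the short paired binding elements through which BMP-activated SMAD1/5/8
transcription-factor complexes switch on target genes.

## The science

SMAD MH1 domains recognise short DNA elements, each written 5'→3' with
its +1 guanine first:

| id | sequence | palindromic |
|---|---|---|
| `SBE` | `GTCTG` | no |
| `pGC_SBE` | `GGCGCC` | yes |
| `npGC_SBE` | `GGCTCC` | no |
| `pSBE` | `GTCTAGAC` | yes |
| `FIVE_GC` | `GGCGC` \| `GGCCG` | no |

A single element does not suffice for transcription.  Activation
requires a *composite motif*: two elements separated by a spacer of
exactly 5 bp, bound by two MH1 domains.  Because each MH1 engages the +1
guanine of its element, the strand carrying each element fixes the
relative orientation of the two domains:

- upstream element on the **minus** strand + downstream element on the
  **plus** strand → both +1 guanines flank the spacer on opposing
  strands → **back-to-back** (the productive, BMP-responsive mode);
- the mirror arrangement → **face-to-face**;
- both elements on the same strand → **face-to-back**.

`smadscan` encodes this grammar and everything around it:

- `smadscan.grammar` — elements, strand-aware occurrence matching,
  binding-mode classification, BMP/TGFβ responsiveness prediction;
- `smadscan.scanner` — composite scanning of sequences and screening of
  peak-region sets (BED + FASTA) for composite positivity;
- `smadscan.linkers` — spacer position-frequency matrices and
  information content, with guanine-enrichment flags;
- `smadscan.annotate` — promoter/UTR/exon/intron/intergenic
  classification and abundance-normalised class distributions;
- `smadscan.hill` — constrained Hill fits (`Y = Bmax·X^h/(Kd^h + X^h)`)
  of fraction-bound titrations;
- `smadscan.reporters` — a generator for the >65-construct luciferase
  reporter insert library (motif cassettes 10 bp upstream of a minimal
  adenoviral major late promoter) with predicted labels;
- `smadscan.simulate` — synthetic genomes/peak sets with planted
  composites and exact truth tables, G-boosted linker samples, noisy
  binding curves.

## Worked example

```python
from smadscan import CANONICAL_ELEMENTS, scan_composites

seq = "AAGGCGCCAACTTGTCTGAA"   # GC palindrome + 5-bp linker + SBE
(hit,) = scan_composites(
    seq, CANONICAL_ELEMENTS["pGC_SBE"], CANONICAL_ELEMENTS["SBE"], 5
)
print(hit.spacer_seq, sorted(m.value for m in hit.modes), hit.label.value)
```

prints

```
AACTT ['back_to_back', 'face_to_back'] BMP_responsive
```

The GC palindrome is readable on both strands, the downstream `GTCTG`
only on the plus strand, so back-to-back binding is achievable and the
5-bp spacer makes the site BMP-responsive.  Inverting the SBE
(`...AACTTCAGAC...`) removes the back-to-back mode and the label becomes
`nonresponsive`; placing the whole composite on the antisense strand
(`CAGAC-N5-GGCGCC`) keeps back-to-back binding but is downgraded to
`BMP_responsive_weak`.

From the shell, an end-to-end synthetic screen:

```sh
smadscan simulate peaks --n-regions 100 --plant-class pGC_SBE+SBE \
    --rate 0.03 --seed 7 --out-prefix demo
smadscan screen demo.peaks.bed demo.genome.fasta --out-prefix demo
```

which reports 3 of 100 regions positive for the `SBE+pGC_SBE/5` class —
exactly the planted truth in `demo.truth.tsv` — and zero positives for
every other class.  Other subcommands: `scan`, `pwm`, `annotate`,
`hillfit`, `library`, `simulate linkers|curve`, `pipeline`.

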