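# onesnpaway

Codon-level **single-nucleotide mutational accessibility** for protein-coding
genes — including genes embedded in a shifted reading frame of another gene.

## The problem

Saturation mutagenesis screens ask which residues of a protein matter, but a
random single-base mutagenesis can only reach the codons that are *one
substitution away* from the change of interest. Interpreting such a screen
therefore needs exact bookkeeping: which codons can become a stop (and which
stop — amber TAG, ochre TAA, or opal TGA), which can become proline (the
helix breaker: any codon matching `XCX` or `CXX`, except codons already
`CCN`), how close the screen is to saturating those positions, and — for the
remarkable gene pairs where one ORF is entirely embedded in the +1 or +2
frame of another, like the phage lambda spanin genes *Rz*/*Rz1* — what a
substitution does to **both** reading frames at once.

`onesnpaway` implements this exactly, for any coding sequence and any NCBI
genetic code:

* **seqcore** — codons, translation, the 9-codon Hamming-1 neighborhood,
  substitution classification (synonymous/missense/nonsense/start-loss,
  transition vs. transversion, stop naming).
* **snapaway** — the one-SNP-away scan: every codon with a single-base route
  to a target residue or stop, with per-window position counts.
* **overlap** — embedded-ORF architectures: locate ATG→stop ORFs in shifted
  frames, compute dual-frame effects, and *design* constrained mutations
  (e.g. "nonsense in the parent, synonymous in the embedded gene").
* **mutmap** — mutant-allele tables (TSV), domain-map summaries, saturation
  accounting under a uniform-draw coverage model
  `E[distinct] = m(1-(1-1/m)^n)`, coiled-coil heptad (abcdefg) registers,
  helical span arithmetic, and plain-text mutational maps.
* **covary** — complementary-charge covariation between aligned C-terminal
  segments of partner proteins across homolog families.
* **appio** — FASTA/GenBank I/O, the packaged lambda *Rz* CDS and mutant
  table, and seeded generators for synthetic CDSs, embedded-ORF pairs, and
  covarying families.

## Worked example

```python
from onesnpaway import (appio, scan_one_snp_away, count_accessible_in_ranges,
                        design_constrained)
from onesnpaway.overlap import effect_is, is_synonymous

rz = appio.lambda_rz_cds()                      # packaged 462-nt lambda Rz CDS
stops = scan_one_snp_away(rz, "STOP")
print(f"{rz.id}: {rz.sense_codon_count} sense codons, "
      f"{len(stops)} one-SNP-away nonsense positions")

pro = scan_one_snp_away(rz, "P")
for w, n in zip([(23, 63), (64, 93)],
                count_accessible_in_ranges(pro, [(23, 63), (64, 93)])):
    print(f"Pro-accessible codons in {w[0]}-{w[1]}: {n}")

arch = appio.lambda_architecture()              # Rz1 located in the +1 frame
for d in design_constrained(arch, effect_is("nonsense", "amber"), is_synonymous):
    s = d.substitution
    print(f"Rz codon {s.codon_index} {s.ref_base}>{s.alt_base} (offset {s.offset}): "
          f"{d.parent_effect.ref_aa}->amber, silent at Rz1 codon {d.embedded_codon_index}")
```

prints

```
Rz: 153 sense codons, 45 one-SNP-away nonsense positions
Pro-accessible codons in 23-63: 20
Pro-accessible codons in 64-93: 14
Rz codon 100 C>T (offset 1): Q->amber, silent at Rz1 codon 26
```

Reading the output: only 45 of Rz's 153 codons can become a stop codon in one
mutational step, so a screen recovering nonsense alleles should be judged
against 45, not 153. The proline scan shows 20 accessible codons in residues
23–63 and 14 in 64–93 — windows where recovered-vs-accessible ratios reveal
which helices cannot tolerate a helix breaker. The design query finds that a
C→T at the first base of Rz codon 100 creates an amber stop in Rz while
remaining synonymous in the embedded Rz1 — the unique single-base way to
knock out Rz without touching the Rz1 protein.

The same operations are available from the shell, e.g.:

```sh
onesnpaway scan rz.fasta STOP
onesnpaway overlap design rz.fasta --parent-effect nonsense \
    --embedded-effect synonymous --stop-name amber
onesnpaway fixtures make-pair --seed 7
```

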