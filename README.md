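# copiievo

Ancient-paralog detection and ancestral-complement reconstruction for the
COPII vesicle coat, with a gene duplication–loss simulator.

## The problem

The COPII coat (Sar1, Sec23, Sec24, Sec13, Sec31, with accessory Sec12,
Sec16 and the fungal Sed4) buds transport vesicles from the ER. Comparative
genomics across the eukaryotic supergroups asks two questions about it:
which components were already present in the Last Eukaryotic Common
Ancestor (LECA), and how many *ancient paralogs* — duplicates that predate
the LECA — each component had. Answering the second question is hard:
paralog splits are deep, alignable regions are short, and fast-evolving
lineages create long-branch artifacts.

`copiievo` implements the full workflow for users who want to run, stress
or extend it: reciprocal-best-hit (RBH) orthology over exact
Smith–Waterman search, supergroup-wise neighbor-joining trees with
bootstrap support, taxon-sampling reduction (keep the two shortest —
slowest-evolving — branches of every supported clade as surrogates, then
re-analyze the combined pan-eukaryotic set), and Dollo-parsimony
reconstruction of the ancestral complement. Because no public accessions
accompany the original survey, a first-class simulator generates families
along a five-supergroup species scaffold with pre-LECA duplications,
lineage-specific losses and long-branch lineages, so every inference is
checked against known ground truth.

## The core statistics

* **RBH orthology**: a candidate is an ortholog of a reference component
  iff its top reverse-search hit is the expected reference sequence and
  the next-best hit's E-value is ≥ 10² times larger, with
  E = K·m·n·e^(−λS) (Karlin–Altschul).
* **Supported clade**: ≥ 2 sequences from ≥ 2 organisms with support
  meeting every available method's threshold (posterior ≥ 0.8,
  bootstrap ≥ 50).
* **Ancient paralog clade**: a supported clade of the pan-eukaryotic
  surrogate tree spanning ≥ 2 supergroups, with at most one sequence per
  organism; the count of such clades estimates the component's LECA copy
  number.
* **Dollo parsimony**: one gain at the MRCA of the carriers, minimal
  secondary losses below it; a component is in the LECA complement iff the
  gain sits at the root.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```sh
python examples/04_scrollsaw_counts.py
```

simulates the shipped three-paralog Sec24 history (5 supergroups × 4 taxa,
500 residues; the third paralog lost in Opisthokonta and Excavata) and runs
the complete analysis:

```
Amoebozoa: 3 supported clade(s), surrogates ['Amo3_Sec24I', 'Amo4_Sec24I', ...]
...
Opisthokonta: 2 supported clade(s), surrogates ['Opi3_Sec24I', 'Opi4_Sec24I', ...]
pan-eukaryotic dataset: 26 surrogate sequences
inferred ancient paralog clades: 3 (truth: 3)
  clade of 10 spanning ['Amoebozoa', 'Archaeplastida', 'Excavata', 'Opisthokonta', 'SAR_CCTH']: ['Sec24I']
  clade of 10 spanning ['Amoebozoa', 'Archaeplastida', 'Excavata', 'Opisthokonta', 'SAR_CCTH']: ['Sec24II']
  clade of 6 spanning ['Amoebozoa', 'Archaeplastida', 'SAR_CCTH']: ['Sec24III']
```

Each supergroup resolves one clade per paralog it retains (Opisthokonta and
Excavata see only two — they lost the third paralog); two surrogates per
clade feed the pan-eukaryotic tree, whose three multi-supergroup clades
recover the three pre-LECA paralogs exactly. `examples/05_leca_reconstruction.py`
prints the Dollo reconstruction on the shipped 22-taxon presence matrix:
seven components gain at the LECA (Sec12 and Sec16 each with seven
independent secondary losses), while Sed4's gain lands inside the
Saccharomycetaceae and is excluded.

The other examples cover simulation (`01`), RBH orthology (`02`) and
tree inference with bootstrap (`03`). A thin CLI wraps the same calls:
`copii simulate|search|rbh|align|tree|scrollsaw|reconstruct|run`.

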