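# cosbr — in-silico co-selection BAC recombineering

`cosbr` is a desk-scale toolkit for designing and verifying mouse
conditional-knockout (CKO) gene-targeting vectors built by
**co-selection BAC recombineering** (CoSBR).  In that workflow a BAC
clone is modified at two positions *simultaneously* — a selectable
FRT-*Pgk1*-em7-neo-FRT-loxP cassette plus a non-selected single-stranded
loxP oligo — and the modified genomic fragment is then retrieved by gap
repair into a linearized vector, yielding the final CKO vector in just
two bacterial steps.  The wet-lab protocol lives or dies on getting
three synthesized components and one strand choice exactly right;
`cosbr` designs those components, simulates every DNA transaction of
the workflow so the final vector can be verified base-for-base before
anything is ordered, and models the polyclonal 96-well screening
statistics.

## What it does

**Design** (`cosbr.designer`) — emits the three synthesis components
with the standard architectures:

* *cassette insert* (463 nt with 6-bp release sites):
  `site + 100-nt 5' mini arm + FRT(34) + 71-nt Pgk1-promoter homology +
  60-nt BGH-polyA homology + FRT(34) + 18-nt spacer + loxP(34) +
  100-nt 3' mini arm + site`;
* *loxP oligo* (200 nt): `83-nt flank + loxP(34) + 83-nt flank`, with
  two phosphorothioate bonds annotated at each terminus (4 total);
* *retrieval insert*: `NotI + 200-nt arm + XhoI + 200-nt arm`, the arms
  matching the very ends of the genomic interval to retrieve;

plus a screening primer pair placed outside the oligo flanks, so a
loxP-positive template shifts the amplicon by exactly 34 bp.

**Strand logic** (`cosbr.strandlogic`) — BACs replicate unidirectionally
from OriS, against the T7→Sp6 insert arrow, so the lagging strand runs
*with* the arrow: a gene transcribed with the arrow gets a
coding-strand lagging oligo, a gene against it gets the template
strand.  Lagging-strand oligos prime Okazaki-fragment synthesis and are
generally the more efficient choice; the call is qualitative and the
simulated product is strand-independent.

**Simulation** (`cosbr.recombsim`, `cosbr.pipeline`) — exact-homology
recombineering (double-stranded cassettes and ssODNs), gap-repair
retrieval, Cre/Flp excision and inversion by midpoint crossover,
restriction digestion, PCR, and restriction-fingerprint comparison.
The full pipeline — marker insertion into the carrier plasmid, release
by digestion, BAC co-targeting, retrieval, then Flp and Cre — is
validated against an independently string-assembled expected vector.

**QC** (`cosbr.allele_qc`) — counts loxP/FRT sites, measures the
embryonic-stem-cell homology arms (working range 2.5–3.5 kb), confirms
the critical exon is floxed, and checks that removing it frameshifts
the spliced CDS (removed CDS length ≢ 0 mod 3), reporting the first
premature stop codon.

**Screening statistics** (`cosbr.platestats`) — the polyclonal 96-well
founder model.  With N kanamycin-resistant founders over W wells,
founders per well are Poisson with λ = N/W, each co-targeted with
probability f, so

```
P(loxP-positive well) = 1 − exp(−λ·f),      f̂ = −ln(1 − k/W) / λ
```

with Clopper–Pearson intervals on f̂.  The module also reproduces the
published per-colony and per-well screening tables from their raw
counts and the pooled-BAC arithmetic (10% bad clones → 1% risk that
both clones of a pool are bad).

**Fixtures** (`cosbr.fixtures`) — seeded generators for loci with
embedded multi-exon genes, mock BAC clones with a pBACe3.6-style
backbone stub, and complete end-to-end scenarios, so everything is
testable offline.

## Worked example

```
$ cosbr make-fixture --seed 17 --out-dir fx
$ cosbr design --config fx/config.yaml --out-dir out
{
  "cassette_insert_len": 463,
  "lox_oligo_len": 200,
  "retrieval_insert_len": 414,
  "phosphorothioate_bonds": [1, 2, 198, 199],
  "screen_primers": {
    "fwd": "GACTCAAAATCGGTTATCCT",
    "rev": "AATCCCCTTCGCACACTCGC",
    "wt_amplicon": 219,
    "targeted_amplicon": 253
  },
  ...
}
```

The 463-nt insert is the synthesized cassette (the "0.5 kb" piece); the
200-nt oligo carries its loxP at positions 84–117 with four
phosphorothioate bonds; the primers predict a 219 bp wild-type and a
253 bp loxP amplicon (a 34-bp shift).

```
$ cosbr simulate --config fx/config.yaml --out-dir sim
  "mixed_prep_bands": [457, 2226, 2692],
  "screen_amplicons": {"wild_type": [219], "cotargeted": [253],
                       "polyclonal_well": [219, 253]}
```

The mixed miniprep digest shows the classic three bands — vector
backbone, un-modified insert (~0.5 kb) and the size-shifted selection
cassette (~2.2 kb) — and a polyclonal well containing both neo-only and
co-targeted clones gives both amplicons.  `sim/` holds GenBank files
for every intermediate (co-targeted BAC, final CKO vector, post-Flp and
post-Cre alleles).

```
$ cosbr qc --vector sim/final_cko_vector.gb --config fx/config.yaml
{ "lox_count": 2, "frt_count": 2, "arm5_len": 3003, "arm3_len": 3001,
  "es_arm_in_range": true, "critical_exon_floxed": true,
  "frameshift": true, ... }
```

The final vector has the intended two-loxP/two-FRT architecture, ~3 kb
ES arms, and a frameshifting critical exon.

```
$ cosbr stats --colonies 365 --wells 95 --positives 34
{ "lambda_founders_per_well": 3.8421052631578947,
  "positive_well_fraction": 0.35789473684210527,
  "estimated_cotargeting_freq": 0.11530215782352551,
  "freq_ci95": [0.07911454331176926, 0.16172909424586523] }
```

A plate seeded at λ ≈ 3.8 founders/well with 36% positive wells implies
a per-colony co-targeting frequency of ~12%.

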