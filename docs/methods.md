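# Methods

## Sequence model

All molecules are strings over `{A,C,G,T,N}` with explicit topology.
Circular molecules are stored linearized with a topology flag and have
no privileged origin: every interval operation is rotation-invariant,
and a feature may wrap the stored origin (`start > end`).  Coordinates
are 0-based half-open internally; reports and GenBank output use the
1-based inclusive convention.  The canonical 34-nt loxP and minimal
34-nt FRT sequences are overridable module constants; the 34-bp length
is enforced on every site feature.

The 71-nt *Pgk1*-promoter homology, 60-nt BGH-polyA homology, 18-nt
spacer and all backbone stubs (pUC, pBACe3.6, pBlight-TK) are
**synthetic stand-in sequences**: only their lengths, order and marker
features matter to the algorithms, and they are generated
deterministically and kept free of the built-in enzyme sites.

## Recombineering model

Homology-directed exchange is modeled as **exact, unique substring
matching**: the donor's terminal `min_arm` windows (default 50 nt —
every arm the designer emits is ≥ 60 nt) are located on the target,
matches are extended maximally so junctions are exact, and the target
region spanned by the two matches is replaced by the donor between its
matches.  Ambiguous arms are an error, never a silent choice.  Donor
bases *outside* the arm matches (e.g. the restriction-site remnant left
by cassette release) are dropped, and the junction trace records how
much was dropped on each side.  The same engine serves double-stranded
cassettes and single-stranded oligos; an oligo matching the bottom
strand is reverse-complemented first, so the product is independent of
the lagging/leading choice — strand selection affects only in-vivo
efficiency, which is deliberately not modeled (the published data even
contain one counter-example to the lagging-strand preference, so no
numeric efficiency model would be honest).

Gap repair requires a linear vector whose two ends match the ends of a
unique interval on the circular clone, pointing inward; the product is
the full interval plus the vector backbone with each arm present once
(`len = len(vector) + len(interval) − 2·arm`).

Cre/Flp recombination crosses over between site midpoints, so each
product carries one full hybrid 34-nt site: direct repeats excise (a
circle plus the shortened parent; lengths and site counts are
conserved), inverted repeats invert the intervening segment.  With more
than two sites the pair must be named explicitly.

Digestion cuts at the 5' end of each recognition site — at gel-band
resolution overhang geometry is irrelevant — giving n+1 fragments on a
line and n on a circle, always summing to the input length.  Under this
convention the mixed cassette-prep digest shows bands of 457, 2,226 and
2,692 nt: the published ~0.5 kb/~2.2 kb insert bands minus one 6-bp
site, plus backbone.  The insert-region lengths themselves (463 and
2,232 = 463 − 71 − 60 + 1,900) are computed and checked exactly.

PCR is exact-match primer binding with no thermodynamics: the screening
assay distinguishes templates by a 34-bp size shift, which mismatch and
Tm models cannot change.  Either primer may act as the top-strand
primer (templates may be stored on either strand), divergent primers on
a circle amplify around the origin, and a pool of templates (a
polyclonal well) returns the union of amplicons — reproducing the
two-band wells of a real screen.  Fingerprint comparison greedily
matches fragment multisets within a 5% relative tolerance, the
in-silico analog of comparing a SpeI digest against a reference.

## Strand call

pBACe3.6-type clones replicate unidirectionally from OriS with the
fork moving in the Sp6-transcription direction, i.e. against the
T7→Sp6 arrow used to draw insert orientation; the lagging strand
therefore runs with the arrow.  The implementation applies that
operational rule verbatim — gene with the arrow ⇒ lagging = coding
strand; against ⇒ template strand — and records both inputs and the
branch taken in a rationale string, rather than re-deriving the
molecular convention from a replication-fork simulation.

## Allele QC

Splicing is plain exon concatenation in gene order (no alternative or
cryptic splicing — richer models would be unverifiable here).  A
conditional-null design requires the CDS content of the removed
exon(s) to be ≢ 0 mod 3; a frame-preserving removal is a *warning*,
not an error, because the tool reports and the designer decides.  When
the locus is available the post-excision CDS is translated with the
standard nuclear code and the first premature stop is reported as a
0-based codon index.  The removed exon may not be the first or last
coding exon (the splice model needs intact flanking coding exons).
ES-cell homology arms are measured from the retrieved-interval
boundaries to the outermost loxP sites, with 2.5–3.5 kb as the
recommended range.

## Founder model

Distributing an outgrowth of N kan-resistant founders across W wells
gives Poisson(λ = N/W) founders per well (the observed 131–463
colonies per experiment give λ ≈ 1.4–4.8, the expected "1–4 founders
per well").  Each founder is independently co-targeted with
probability f, so co-targeted founders are Poisson(λf) and
P(positive well) = 1 − exp(−λf); inverting gives f̂ = −ln(1 − k/W)/λ,
clamped to [0, 1], with a confidence interval obtained by transforming
an exact Clopper–Pearson interval on k/W.  A fully positive plate
leaves f unidentifiable and errors; k = 0 returns f̂ = 0.  PCR
sensitivity and within-well competition are ignored — the protocol
cultures wells long enough for resistant bacteria to dominate before
screening.  Per-colony frequencies are displayed at two significant
figures and per-well fractions at whole percents, matching the two
published table conventions; the raw fraction is always retained.

The estimator carries an O(1/W) Jensen bias (−ln(1−p) is convex),
non-negligible at high positive fractions: recovery tests therefore
accept `|mean f̂ − f| ≤ 3·SE + Var(p̂)/(2λ(1−p)²)`, a bound fixed from
the model rather than tuned.

## Synthetic data

The generators are pure functions of their seeds.  A default locus is
20 kb — not the real 100–200 kb clone scale, since nothing in the
algorithms is length-sensitive and tests stay sub-second — with a
7-exon gene whose CDS starts ATG, ends with a stop and is stop-free in
between; the critical exon (index 4, "exon 5") can be forced to any
CDS-length residue mod 3.  Loci are scrubbed of the six built-in
enzyme sites so designer preconditions hold anywhere; the BAC backbone
stub deliberately carries SpeI sites so fingerprints have bands.  The
end-to-end fixture randomizes gene strand and insert orientation,
places the oligo in the intron 5' of the critical exon and the
cassette 3' of it, sizes the retrieval interval for 3 kb ES arms, and
**independently string-assembles the expected final vector**, which
the simulated pipeline must reproduce base-for-base (compared up to
rotation and strand for circles).

What the fixtures do *not* emulate: repetitive or low-complexity
sequence, conservation constraints on arm placement, synthesis errors
in long oligos (the real protocol pools five positive wells for this
reason), recombineering efficiency, and plasmid multimer segregation.
Passing tests therefore demonstrate the correctness of the designs and
of the sequence arithmetic, not wet-lab success rates on repetitive
genomic targets.

## Problem sizes and numerics

The test suite and the acceptance script run the full pipeline on 100+
seeded scenarios (~4 s), the frameshift oracle on 200 generated genes,
and the founder-model recovery on 9 conditions × 1,000 plates of 95
wells.  Fragment-set comparison defaults to 5% relative tolerance;
primer selection scans outward from the oligo arms for the nearest
unique 20-mer at 40–60% GC, deterministic and free of thermodynamic
models.  Known limitations: exact-match homology (no SNP tolerance),
no more than two recombination sites without an explicit pair, no
modeling of the loxP:neo-only ratio inside pooled retrieval wells
beyond reporting amplicon unions.
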