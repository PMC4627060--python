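"""Structural and frameshift QC of designed/simulated alleles.

Two checks matter for a conditional-null design:

* removing the critical exon(s) must frameshift the downstream coding
  sequence (removed CDS length not divisible by 3), so that splicing of
  the remaining exons yields premature stops and a functional null;
* the final vector must carry the intended site architecture (two loxP,
  two FRT before Flp; the critical exon strictly between the loxP
  sites) and embryonic-stem-cell homology arms in the working range
  (by convention 2.5-3.5 kb on either side of the floxed region).

The splicing model is plain exon concatenation in gene order — no
alternative splicing, no cryptic splice sites.  A mod-3-clean removal
is reported as a design warning, not an error: the tool reports, the
designer decides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .designer import DesignParameters
from .seqcore import DnaMolecule, GeneModel, translate

__all__ = ["AlleleReport", "check_conditional_null", "verify_allele_structure", "DesignWarning"]


class DesignWarning(UserWarning):
    pass


@dataclass
class AlleleReport:
    lox_count: int = 0
    frt_count: int = 0
    arm5_len: int | None = None
    arm3_len: int | None = None
    es_arm_in_range: bool | None = None
    critical_exon_floxed: bool | None = None
    frameshift: bool | None = None
    removed_cds_len: int | None = None
    first_premature_stop: int | None = None


def check_conditional_null(
    gene: GeneModel, removed_exons: set[int], locus: DnaMolecule | None = None
) -> AlleleReport:
    """Frame arithmetic (and optional translation scan) for exon removal.

    ``removed_cds_len`` is the total CDS length inside the removed
    exons; the allele frameshifts iff it is not a multiple of 3.  With
    the locus sequence available, the post-excision CDS is spliced and
    translated, and the first stop codon occurring before the natural
    stop is reported as a 0-based codon index from the post-excision
    CDS start.
    """
    if not removed_exons:
        raise ValueError("removed_exons must be non-empty")
    for i in removed_exons:
        if not (0 <= i < len(gene.exons)):
            raise ValueError(f"exon index {i} out of range")
    coding = gene.coding_exon_indices()
    if not coding:
        raise ValueError("gene model has no CDS")
    for i in removed_exons:
        if gene.cds_len_in_exon(i) == 0:
            raise ValueError(f"removed exon {i} carries no CDS; its removal cannot frameshift")
        if i in (coding[0], coding[-1]):
            raise ValueError(
                f"exon {i} is the first or last coding exon; the splice model needs intact "
                "flanking coding exons to evaluate the post-excision reading frame"
            )
    removed = sum(gene.cds_len_in_exon(i) for i in removed_exons)
    frameshift = removed % 3 != 0
    if not frameshift:
        warnings.warn(
            f"removed CDS length {removed} is a multiple of 3: excision preserves frame "
            "and may yield an internally deleted, partially functional protein",
            DesignWarning,
            stacklevel=2,
        )
    stop_idx = None
    if locus is not None:
        spliced = gene.coding_sequence(locus, skip_exons=removed_exons)
        aa = translate(spliced)
        pos = aa.find("*")
        if pos != -1 and pos < len(aa) - 1:
            stop_idx = pos
    return AlleleReport(frameshift=frameshift, removed_cds_len=removed, first_premature_stop=stop_idx)


def verify_allele_structure(
    vector: DnaMolecule, gene: GeneModel, params: DesignParameters | None = None
) -> AlleleReport:
    """Count recombination sites and measure ES homology arms on a vector.

    The ES arms are the genomic sequence upstream of the first loxP site
    and downstream of the last loxP site, bounded by the retrieved
    genomic interval (located via the ``retrieval_arm_5/3`` features the
    gap-repair simulator annotates).  Also confirms that the critical
    exon(s) lie strictly between the two loxP sites.
    """
    p = params or DesignParameters()
    lox = sorted((f for f in vector.features_of("loxP") if not f.wraps()), key=lambda f: f.start)
    frt = vector.features_of("FRT")
    if not lox:
        raise ValueError("vector carries no loxP features")
    report = AlleleReport(lox_count=len(lox), frt_count=len(frt))

    arms = {f.label: f for f in vector.features_of("homology_arm")}
    a5, a3 = arms.get("retrieval_arm_5"), arms.get("retrieval_arm_3")
    if a5 is not None and a3 is not None and not a5.wraps() and not a3.wraps():
        genomic_lo, genomic_hi = a5.start, a3.end
        report.arm5_len = lox[0].start - genomic_lo
        report.arm3_len = genomic_hi - lox[-1].end
        lo, hi = p.es_arm_range
        report.es_arm_in_range = lo <= report.arm5_len <= hi and lo <= report.arm3_len <= hi
        if not report.es_arm_in_range:
            warnings.warn(
                f"ES homology arms of {report.arm5_len}/{report.arm3_len} nt fall outside "
                f"the recommended {lo}-{hi} nt range",
                DesignWarning,
                stacklevel=2,
            )
    if len(lox) >= 2:
        exon_feats = [f for f in vector.features_of("exon") if not f.wraps()]
        crit_labels = {f"exon{i + 1}" for i in gene.critical_exons}
        crit = [f for f in exon_feats if f.label in crit_labels]
        if crit:
            report.critical_exon_floxed = all(
                lox[0].end <= f.start and f.end <= lox[-1].start for f in crit
            )
    return report
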