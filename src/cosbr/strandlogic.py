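"""BAC replication direction and lagging/leading oligo strand selection.

BACs on a pBACe3.6-type backbone replicate unidirectionally from OriS,
with the fork moving in the direction of Sp6 transcription (from the
XhoI site in OriS toward the BglII site 130 bp downstream).  On genome
browsers the insert orientation is drawn as an arrow from the T7 end
toward the Sp6 end; replication runs *against* that arrow, so the
lagging strand (read 5'->3') runs *with* the arrow.

Operational rule implemented here: if the gene is transcribed in the
same direction as the T7->Sp6 arrow, the lagging strand equals the
coding strand of the gene; otherwise it equals the template strand.
Lagging-strand oligos can prime Okazaki-fragment synthesis and are
generally (not universally) the more efficient choice, so the call is
reported as a qualitative preference only — no efficiency is modeled,
and the simulated recombineering product is identical for either strand
version of an oligo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqcore import DnaMolecule, GeneModel, reverse_complement

__all__ = ["BacClone", "StrandCall", "infer_lagging_strand", "orient_oligo"]

ORIENTATIONS = ("T7_to_Sp6", "Sp6_to_T7")


@dataclass
class BacClone:
    """A mock BAC clone: genomic insert + stub backbone + orientation.

    ``insert`` is the genomic segment in genome-forward orientation;
    ``insert_orientation`` says whether the T7->Sp6 arrow of the clone
    runs with (+, ``T7_to_Sp6``) or against (``Sp6_to_T7``) the genome
    axis.  The backbone stub only needs to carry the Sp6/T7 ends, OriS,
    and the encoded replication direction — its sequence is synthetic.
    """

    clone_id: str
    insert: DnaMolecule
    insert_orientation: str
    backbone: DnaMolecule
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.insert_orientation not in ORIENTATIONS:
            raise ValueError(f"insert_orientation must be one of {ORIENTATIONS}")
        if len(self.insert) == 0:
            raise ValueError("empty BAC insert")

    def molecule(self) -> DnaMolecule:
        """Assembled circular clone: backbone followed by oriented insert.

        In clone coordinates the insert always runs from the T7 end
        toward the Sp6 end; ``Sp6_to_T7`` clones therefore carry the
        reverse complement of the genome-forward insert.
        """
        ins = self.insert if self.insert_orientation == "T7_to_Sp6" else reverse_complement(self.insert)
        seq = self.backbone.seq + ins.seq
        feats = [f for f in self.backbone.features]
        off = len(self.backbone.seq)
        for f in ins.features:
            feats.append(type(f)(f.kind, f.start + off, f.end + off, f.strand, f.label))
        return DnaMolecule(self.clone_id, seq, "circular", feats, dict(self.annotations))


@dataclass
class StrandCall:
    """Which physical strand the lagging strand corresponds to for a gene."""

    lagging_equals: str  # "coding_strand" | "template_strand"
    rationale: str

    def __post_init__(self) -> None:
        if self.lagging_equals not in ("coding_strand", "template_strand"):
            raise ValueError(f"bad lagging_equals {self.lagging_equals!r}")


def infer_lagging_strand(bac: BacClone, gene: GeneModel) -> StrandCall:
    """Deterministic lagging-strand call from insert orientation and gene strand.

    Raises if the gene model falls outside the BAC insert.
    """
    lo, hi = gene.genomic_span()
    if lo < 0 or hi > len(bac.insert):
        raise ValueError(f"gene {gene.gene_id} lies outside the insert of {bac.clone_id}")
    arrow = "+" if bac.insert_orientation == "T7_to_Sp6" else "-"
    same = gene.strand == arrow
    call = "coding_strand" if same else "template_strand"
    rationale = (
        f"insert orientation {bac.insert_orientation} => T7->Sp6 arrow is genome '{arrow}'; "
        f"gene {gene.gene_id} on '{gene.strand}' is {'the same as' if same else 'opposite to'} the arrow; "
        f"rule: lagging strand runs with the T7->Sp6 arrow, so lagging == {call.replace('_', ' ')}"
    )
    return StrandCall(call, rationale)


def orient_oligo(oligo: DnaMolecule, call: StrandCall, gene: GeneModel) -> DnaMolecule:
    """Return the lagging-strand version of a coding-strand oligo design.

    The input oligo is assumed to be written on the gene's coding
    strand; when the lagging strand is the template strand the oligo is
    reverse-complemented.  The choice is recorded in the annotations;
    it does not change the simulated recombineering product.
    """
    if call.lagging_equals == "coding_strand":
        out = oligo.copy()
        out.annotations["oligo_strand"] = "coding"
    else:
        out = reverse_complement(oligo)
        out.annotations["oligo_strand"] = "template"
    out.annotations["strand_version"] = "lagging"
    out.annotations["strand_rationale"] = call.rationale
    return out
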