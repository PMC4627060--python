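"""End-to-end in-silico CoSBR run: cassette prep, co-targeting, retrieval,
and the post-Flp / post-Cre alleles.

This is the orchestration layer behind ``cosbr simulate``: it chains
the individual simulators exactly as the bench protocol chains the
physical steps and returns every intermediate, so each junction can be
inspected or written out as GenBank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .designer import DesignParameters
from .recombsim import (
    DigestResult,
    digest,
    gap_repair,
    pcr,
    pooled_band_sizes,
    recombineer_ds,
    recombineer_ss,
    site_specific_recombine,
)
from .seqcore import DnaMolecule
from .strandlogic import BacClone

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    cassette_prep_plasmid: DnaMolecule
    released_cassette: DnaMolecule
    mixed_prep_bands: list[int]
    cotargeted_bac: DnaMolecule
    linearized_retrieval: DnaMolecule
    final_cko: DnaMolecule
    post_flp: DnaMolecule
    flp_excised: DnaMolecule
    post_cre: DnaMolecule
    cre_excised: DnaMolecule
    screen_amplicons: dict = field(default_factory=dict)
    trace: list = field(default_factory=list)


def _pick(mols, predicate, what):
    hits = [m for m in mols if predicate(m)]
    if len(hits) != 1:
        raise RuntimeError(f"expected exactly one {what}, found {len(hits)}")
    return hits[0]


def run_pipeline(
    bac: BacClone,
    puc_plasmid: DnaMolecule,
    selection_fragment: DnaMolecule,
    lox_oligo: DnaMolecule,
    retrieval_plasmid: DnaMolecule,
    params: DesignParameters | None = None,
    min_arm: int = 50,
    screen_primers=None,
) -> PipelineResult:
    """Simulate the full two-step CKO construction.

    1. marker insertion into the synthesized cassette carrier
       (recombineering), release by digestion, mixed-prep band sizes;
    2. BAC co-targeting with the released cassette and the loxP oligo;
    3. retrieval (gap repair) into the linearized retrieval vector
       -> final conditional-knockout vector;
    4. Flp (drop the selection marker), then Cre (drop the floxed
       exon) on the retrieved allele.
    """
    p = params or DesignParameters()
    prep = recombineer_ds(puc_plasmid, selection_fragment, min_arm)
    enzymes = {p.cassette_site_enzyme_5, p.cassette_site_enzyme_3}
    parent_digest = digest(puc_plasmid, enzymes)
    prep_digest = digest(prep, enzymes)
    bands = pooled_band_sizes([parent_digest, prep_digest])
    released = _pick(
        prep_digest.fragments,
        lambda m: any(f.kind == "marker" and "neo" in f.label for f in m.features),
        "released selection cassette",
    )

    bac_mol = bac.molecule()
    cotargeted = recombineer_ds(bac_mol, released, min_arm)
    cotargeted = recombineer_ss(cotargeted, lox_oligo, min_arm)

    lin_digest = digest(retrieval_plasmid, [p.retrieval_linearization_enzyme])
    if len(lin_digest.fragments) != 1 or lin_digest.fragments[0].is_circular:
        raise RuntimeError("retrieval plasmid must linearize at a unique site")
    linearized = lin_digest.fragments[0]
    final = gap_repair(cotargeted, linearized, min_arm)

    flp_products = site_specific_recombine(final, "FRT")
    post_flp = _pick(flp_products, lambda m: len(m.features_of("loxP")) == 2, "post-Flp allele")
    flp_excised = _pick(flp_products, lambda m: len(m.features_of("loxP")) != 2, "Flp-excised circle")
    cre_products = site_specific_recombine(post_flp, "loxP")
    # the floxed segment carries the residual FRT; the allele side does not
    post_cre = _pick(cre_products, lambda m: not m.features_of("FRT"), "post-Cre allele")
    cre_excised = _pick(cre_products, lambda m: m.features_of("FRT"), "Cre-excised circle")

    amplicons = {}
    if screen_primers is not None:
        sp = screen_primers
        amplicons = {
            "wild_type": pcr(bac_mol, sp.fwd, sp.rev),
            "cotargeted": pcr(cotargeted, sp.fwd, sp.rev),
            "polyclonal_well": pcr([bac_mol, cotargeted], sp.fwd, sp.rev),
        }

    prep.id = "cassette_prep_plasmid"
    cotargeted.id = f"{bac.clone_id[:24]}_cotargeted"
    final.id = "final_cko_vector"
    post_flp.id = "post_flp_allele"
    flp_excised.id = "flp_excised_marker"
    post_cre.id = "post_cre_allele"
    cre_excised.id = "cre_excised_exon"

    trace = []
    for m in (prep, cotargeted, final):
        trace.extend(m.annotations.get("recombination_trace", []))
    return PipelineResult(
        cassette_prep_plasmid=prep,
        released_cassette=released,
        mixed_prep_bands=bands,
        cotargeted_bac=cotargeted,
        linearized_retrieval=linearized,
        final_cko=final,
        post_flp=post_flp,
        flp_excised=flp_excised,
        post_cre=post_cre,
        cre_excised=cre_excised,
        screen_amplicons=amplicons,
        trace=trace,
    )
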