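"""Deterministic synthetic fixtures: loci, gene models, mock BAC clones,
and full end-to-end scenarios.

Everything here is a pure function of its seed, so the whole toolkit is
testable without downloads.  The generated loci emulate the relevant
properties of a real BAC-library situation — a multi-exon gene with a
valid, stop-free ORF embedded in random intergenic sequence, carried on
a circular clone with a unidirectional-origin backbone stub — at 20 kb
rather than the real 100-200 kb clone scale, because nothing in the
algorithms is length-sensitive.  All backbone stubs (pUC, pBACe3.6,
pBlight-TK) are synthetic sequences carrying only the marker features
the workflow consumes.

Generated loci are kept free of the built-in restriction-enzyme sites
so the designer's arm/release constraints are satisfiable anywhere on
the locus; the mock BAC backbone deliberately carries SpeI sites so
fingerprint comparisons have bands to work with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .designer import (
    BGH_PA_3P,
    CASSETTE_SPACER,
    DesignBundle,
    DesignParameters,
    PGK1_PROMOTER_5P,
    design_bundle,
)
from .seqcore import DnaMolecule, ENZYMES, Feature, GeneModel, reverse_complement, translate
from .strandlogic import BacClone

__all__ = [
    "FixtureSpec",
    "EndToEndFixture",
    "make_locus",
    "make_mock_bac",
    "make_selection_fragment",
    "make_puc_carrier",
    "make_retrieval_plasmid",
    "make_end_to_end_fixture",
]

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic locus/scenario; the seed fully determines
    the output."""

    seed: int
    locus_len: int = 20_000
    n_exons: int = 7
    exon_len_range: tuple[int, int] = (96, 210)
    critical_exon: int = 4  # 0-based => "exon 5", the classic floxing target
    gc: float = 0.5
    gene_strand: str = "+"
    bac_orientation: str = "T7_to_Sp6"
    inject_rearrangement: bool = False
    critical_cds_mod3: int | None = None  # 0/1/2 to force, None for unconstrained

    def __post_init__(self) -> None:
        if not (3 <= self.n_exons):
            raise ValueError("need at least 3 exons")
        if not (0 < self.critical_exon < self.n_exons - 1):
            raise ValueError("critical exon must be internal")
        if not (0.2 <= self.gc <= 0.8):
            raise ValueError("gc out of plausible range")


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(["A", "C", "G", "T"], size=n, p=p))


def _scrub_enzyme_sites(seq: list[str], rng: np.random.Generator, cds_intervals, max_iter: int = 500) -> None:
    """Mutate single bases until no built-in enzyme site remains.

    Positions inside a CDS are only changed when the resulting codon is
    not a stop and the position is outside the start/stop codons, so
    the embedded ORF stays valid.
    """
    protected: set[int] = set()
    if cds_intervals:
        flat = [i for s, e in sorted(cds_intervals) for i in range(s, e)]
        protected.update(flat[:3])
        protected.update(flat[-3:])
        pos_to_codon = {p: (flat[j - j % 3], flat[j - j % 3 + 1], flat[j - j % 3 + 2]) for j, p in enumerate(flat)}
    else:
        pos_to_codon = {}
    sites = list(ENZYMES.values())
    for _ in range(max_iter):
        text = "".join(seq)
        hit = None
        for site in sites:
            idx = text.find(site)
            if idx != -1:
                hit = (idx, idx + len(site))
                break
        if hit is None:
            return
        candidates = [p for p in range(*hit) if p not in protected]
        rng.shuffle(candidates)
        fixed = False
        for p in candidates:
            for nb in rng.permutation([b for b in "ACGT" if b != seq[p]]):
                old = seq[p]
                seq[p] = nb
                codon = pos_to_codon.get(p)
                if codon is not None and "".join(seq[q] for q in codon) in _STOPS:
                    seq[p] = old
                    continue
                fixed = True
                break
            if fixed:
                break
        if not fixed:
            raise RuntimeError("could not scrub an enzyme site without breaking the ORF")
    raise RuntimeError("enzyme-site scrubbing did not converge")


def make_locus(spec: FixtureSpec) -> tuple[DnaMolecule, GeneModel]:
    """A random locus at the requested GC with an embedded multi-exon gene.

    The native CDS starts with ATG, ends with a stop, and translates
    stop-free in between; exon/CDS features are attached to the
    molecule.  ``critical_cds_mod3`` forces the CDS content of the
    critical exon to a residue class mod 3 (1 or 2 => frameshifting
    removal by construction).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_exons
    lo, hi = spec.exon_len_range

    internal = [int(rng.integers(lo, hi + 1)) for _ in range(n - 2)]
    if spec.critical_cds_mod3 is not None:
        i = spec.critical_exon - 1  # index into internal exons
        internal[i] += (spec.critical_cds_mod3 - internal[i]) % 3
    cds_first = int(rng.integers(33, 90))
    cds_last = int(rng.integers(33, 90))
    total = cds_first + sum(internal) + cds_last
    cds_first += (-total) % 3
    utr5 = int(rng.integers(60, 160))
    utr3 = int(rng.integers(60, 160))

    cds_lens = [cds_first] + internal + [cds_last]
    total_cds = sum(cds_lens)
    n_codons = total_cds // 3
    body = "".join(rng.choice(_CODONS) for _ in range(n_codons - 2))
    cds_seq = "ATG" + body + "TAA"

    exon_lens = [utr5 + cds_first] + internal + [cds_last + utr3]
    intron_lens = [int(rng.integers(400, 1200)) for _ in range(n - 1)]
    gene_span = sum(exon_lens) + sum(intron_lens)
    flank5 = (spec.locus_len - gene_span) // 2
    flank3 = spec.locus_len - gene_span - flank5
    if flank5 < 600 or flank3 < 600:
        raise ValueError(
            f"infeasible spec: gene span {gene_span} leaves <600 nt flanks on a {spec.locus_len} nt locus"
        )

    seq = list(_random_dna(rng, spec.locus_len, spec.gc))
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    pos = flank5
    cds_cursor = 0
    for i in range(n):
        es = pos
        ee = pos + exon_lens[i]
        exons.append((es, ee))
        clen = cds_lens[i]
        cs = es + utr5 if i == 0 else es
        ce = cs + clen
        cds.append((cs, ce))
        seq[cs:ce] = list(cds_seq[cds_cursor : cds_cursor + clen])
        cds_cursor += clen
        pos = ee + (intron_lens[i] if i < n - 1 else 0)

    _scrub_enzyme_sites(seq, rng, cds)
    locus = DnaMolecule(f"synthlocus_{spec.seed}", "".join(seq), "linear")
    for i, (es, ee) in enumerate(exons):
        locus.features.append(Feature("exon", es, ee, "+", f"exon{i + 1}"))
    for cs, ce in cds:
        locus.features.append(Feature("CDS", cs, ce, "+", "CDS"))
    gene = GeneModel(f"syngene_{spec.seed}", "+", exons, cds, {spec.critical_exon})

    aa = translate(gene.coding_sequence(locus))
    assert aa.startswith("M") and aa.endswith("*") and "*" not in aa[:-1], "generator produced invalid ORF"

    if spec.gene_strand == "-":
        locus = reverse_complement(locus)
        gene = gene.reverse_complemented(len(locus))
    return locus, gene


def _delete_interval(mol: DnaMolecule, start: int, end: int) -> DnaMolecule:
    seq = mol.seq[:start] + mol.seq[end:]
    d = end - start
    feats = []
    for f in mol.features:
        if f.end <= start:
            feats.append(Feature(f.kind, f.start, f.end, f.strand, f.label))
        elif f.start >= end:
            feats.append(Feature(f.kind, f.start - d, f.end - d, f.strand, f.label))
    return DnaMolecule(mol.id + "_del", seq, mol.topology, feats)


def make_mock_bac(
    locus: DnaMolecule,
    orientation: str = "T7_to_Sp6",
    seed: int = 0,
    inject_rearrangement: bool = False,
) -> BacClone:
    """A circular mock clone: ~3 kb backbone stub + the locus as insert.

    The stub is synthetic sequence carrying Sp6/T7 promoter-end markers,
    an OriS origin feature, and two deliberate SpeI sites (so digest
    fingerprints have internal bands); only the orientation metadata is
    consumed by the strand logic.  ``inject_rearrangement`` deletes a
    random >= 2 kb internal chunk of the insert, emulating a rearranged
    library clone.
    """
    rng = np.random.default_rng(seed + 7_654_321)
    stub = list(_random_dna(rng, 3000, 0.5))
    _scrub_enzyme_sites(stub, rng, [])
    spe = ENZYMES["SpeI"]
    stub[700:706] = list(spe)
    stub[1900:1906] = list(spe)
    backbone = DnaMolecule(
        "pBACe3.6_stub",
        "".join(stub),
        "linear",
        [
            Feature("promoter_end", 20, 40, "+", "Sp6_end"),
            Feature("origin", 300, 420, "+", "OriS"),
            Feature("promoter_end", 2960, 2980, "+", "T7_end"),
        ],
    )
    backbone.annotations["replication"] = (
        "unidirectional from OriS, fork moving Sp6->T7 (against the T7->Sp6 insert arrow)"
    )
    insert = locus
    if inject_rearrangement:
        dlen = int(rng.integers(2000, 5000))
        dstart = int(rng.integers(500, len(locus) - dlen - 500))
        insert = _delete_interval(locus, dstart, dstart + dlen)
    return BacClone(f"mockBAC_{locus.id}_{orientation}", insert, orientation, backbone)


_PL452_CORE_LEN = 1769  # 71 + 1769 + 60 = 1900 nt, the "1.9 kb" marker fragment


def make_selection_fragment(seed: int = 0) -> DnaMolecule:
    """The linear dual-selection marker fragment (Pgk1-em7-neo-BGHpA).

    A synthetic stand-in for the 1.9 kb fragment released from the
    marker plasmid: its termini are exactly the 71-nt Pgk1-promoter and
    60-nt BGH-polyA homology blocks the cassette insert carries.
    """
    rng = np.random.default_rng(seed + 452)
    core = list(_random_dna(rng, _PL452_CORE_LEN, 0.5))
    _scrub_enzyme_sites(core, rng, [])
    seq = PGK1_PROMOTER_5P + "".join(core) + BGH_PA_3P
    feats = [
        Feature("homology_arm", 0, 71, "+", "Pgk1_5p_homology"),
        Feature("marker", 71, 71 + _PL452_CORE_LEN, "+", "Pgk1-em7-neo-BGHpA"),
        Feature("homology_arm", len(seq) - 60, len(seq), "+", "BGHpA_3p_homology"),
    ]
    return DnaMolecule("neo_selection_fragment", seq, "linear", feats)


def _stub_plasmid(name: str, length: int, seed: int, markers) -> DnaMolecule:
    rng = np.random.default_rng(seed)
    seq = list(_random_dna(rng, length, 0.5))
    _scrub_enzyme_sites(seq, rng, [])
    feats = [Feature("marker", s, e, "+", lab) for s, e, lab in markers]
    return DnaMolecule(name, "".join(seq), "linear", feats)


def make_puc_carrier(cassette_insert: DnaMolecule, seed: int = 0) -> DnaMolecule:
    """Circular pUC-stub carrier plasmid holding the synthesized insert."""
    stub = _stub_plasmid("pUC_stub", 2686, seed + 19, [(200, 1061, "Amp"), (1500, 2100, "ori")])
    feats = [Feature(f.kind, f.start, f.end, f.strand, f.label) for f in stub.features]
    off = len(stub)
    for f in cassette_insert.features:
        feats.append(Feature(f.kind, f.start + off, f.end + off, f.strand, f.label))
    return DnaMolecule("pUC_cassette_carrier", stub.seq + cassette_insert.seq, "circular", feats)


def make_retrieval_plasmid(retrieval_insert: DnaMolecule, seed: int = 0) -> DnaMolecule:
    """Circular pBlight-TK-stub retrieval plasmid holding the synthesized
    NotI-arm-XhoI-arm insert."""
    stub = _stub_plasmid("pBlightTK_stub", 4300, seed + 23, [(300, 1400, "TK"), (2000, 2861, "Amp")])
    feats = [Feature(f.kind, f.start, f.end, f.strand, f.label) for f in stub.features]
    off = len(stub)
    for f in retrieval_insert.features:
        feats.append(Feature(f.kind, f.start + off, f.end + off, f.strand, f.label))
    return DnaMolecule("pBlightTK_retrieval", stub.seq + retrieval_insert.seq, "circular", feats)


@dataclass
class EndToEndFixture:
    spec: FixtureSpec
    locus: DnaMolecule
    gene: GeneModel
    bac: BacClone
    design: DesignBundle
    params: DesignParameters
    puc_plasmid: DnaMolecule
    selection_fragment: DnaMolecule
    retrieval_plasmid: DnaMolecule
    expected_cko: DnaMolecule
    lox_point: int = 0
    cassette_point: int = 0
    retrieve_interval: tuple[int, int] = (0, 0)
    notes: dict = field(default_factory=dict)


def make_end_to_end_fixture(seed: int, params: DesignParameters | None = None) -> EndToEndFixture:
    """A full scenario bundle plus the string-assembled expected product.

    The critical exon's CDS length is forced to a non-multiple of 3, the
    loxP oligo goes in the intron 5' of the critical exon (gene
    orientation) and the cassette in the 3' intron, and the retrieval
    interval is sized so both embryonic-stem-cell arms come out at
    3,000 nt.  ``expected_cko`` is built by direct string concatenation,
    independent of the recombineering simulator, and serves as the
    oracle the simulated pipeline must reproduce base-for-base.
    """
    rng = np.random.default_rng(seed)
    p = params or DesignParameters()
    spec = FixtureSpec(
        seed=seed,
        gene_strand=str(rng.choice(["+", "-"])),
        bac_orientation=str(rng.choice(["T7_to_Sp6", "Sp6_to_T7"])),
        critical_cds_mod3=int(rng.choice([1, 2])),
    )
    locus, gene = make_locus(spec)
    crit_iv = gene.exons[spec.critical_exon]
    genomic = sorted(gene.exons)
    gi = genomic.index(crit_iv)
    left_gap = (genomic[gi - 1][1], crit_iv[0])
    right_gap = (crit_iv[1], genomic[gi + 1][0])
    ins_left = (left_gap[0] + left_gap[1]) // 2
    ins_right = (right_gap[0] + right_gap[1]) // 2
    if gene.strand == "+":
        lox_point, cassette_point = ins_left, ins_right
    else:
        lox_point, cassette_point = ins_right, ins_left

    payload_cassette = (
        p.frt_site
        + make_selection_fragment(seed).seq
        + p.frt_site
        + CASSETTE_SPACER[: p.spacer_len]
        + p.loxp_site
    )
    arm_target = 3000
    lox_payload_start, lox_payload_end = 0, len(p.loxp_site)
    cas_lox_start = 2 * len(p.frt_site) + 1900 + p.spacer_len
    cas_lox_end = cas_lox_start + len(p.loxp_site)
    if lox_point < cassette_point:
        i_s = lox_point - arm_target + lox_payload_start
        i_e = cassette_point + arm_target - (len(payload_cassette) - cas_lox_end)
    else:
        i_s = cassette_point - arm_target + cas_lox_start
        i_e = lox_point + arm_target - (len(p.loxp_site) - lox_payload_end)
    retrieve_interval = (i_s, i_e)

    bac = make_mock_bac(locus, spec.bac_orientation, seed)
    design = design_bundle(locus, gene, bac, lox_point, cassette_point, retrieve_interval, p)
    puc = make_puc_carrier(design.cassette_insert, seed)
    pl452 = make_selection_fragment(seed)
    retr = make_retrieval_plasmid(design.retrieval_insert, seed)

    e1, pay1 = min(lox_point, cassette_point), None
    e2, pay2 = max(lox_point, cassette_point), None
    pay1 = p.loxp_site if e1 == lox_point else payload_cassette
    pay2 = payload_cassette if pay1 is p.loxp_site else p.loxp_site
    modified = locus.seq[i_s:e1] + pay1 + locus.seq[e1:e2] + pay2 + locus.seq[e2:i_e]
    pblight_seq = retr.seq[:4300]
    expected = DnaMolecule(
        "expected_final_cko", modified + pblight_seq + ENZYMES[p.retrieval_release_enzyme], "circular"
    )
    return EndToEndFixture(
        spec=spec,
        locus=locus,
        gene=gene,
        bac=bac,
        design=design,
        params=p,
        puc_plasmid=puc,
        selection_fragment=pl452,
        retrieval_plasmid=retr,
        expected_cko=expected,
        lox_point=lox_point,
        cassette_point=cassette_point,
        retrieve_interval=retrieve_interval,
    )
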