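"""Design of the three synthesis components and the screening primers.

A conditional-knockout build needs exactly three synthesized pieces:

1. the **cassette insert** cloned into a pUC carrier —
   ``site5 + 5'mini-arm(100) + FRT(34) + Pgk1-5'(71) + BGHpA-3'(60) +
   FRT(34) + spacer(18) + loxP(34) + 3'mini-arm(100) + site3``
   (463 nt with 6-bp sites); the internal Pgk1/BGHpA homologies receive
   the full selection marker by recombineering;
2. the **loxP oligo** — a 200-nt single-stranded oligo,
   ``83-nt flank + loxP(34) + 83-nt flank``, with two phosphorothioate
   bonds at each terminus (4 total, annotation only);
3. the **retrieval insert** —
   ``NotI + 5'arm(200) + XhoI + 3'arm(200)``, whose arms match the very
   ends of the genomic interval to be retrieved by gap repair.

Every homology segment is copied verbatim from the locus, must be free
of N bases, and must be an exact substring of the locus — the simulator
relies on exact matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .seqcore import (
    DnaMolecule,
    ENZYMES,
    Feature,
    FRT_SITE,
    GeneModel,
    LOXP_SITE,
    SITE_LEN,
    revcomp,
)
from .strandlogic import BacClone, infer_lagging_strand, orient_oligo

__all__ = [
    "DesignParameters",
    "DesignBundle",
    "PrimerPair",
    "DesignError",
    "design_cassette_insert",
    "design_lox_oligo",
    "design_retrieval_insert",
    "design_screen_primers",
    "design_bundle",
    "PGK1_PROMOTER_5P",
    "BGH_PA_3P",
    "CASSETTE_SPACER",
]

# Synthetic stand-in sequences for the two selection-marker homology blocks
# and the spacer.  Only their lengths (71 / 60 / 18 nt) and role are
# architecture-determined; the literal bases are deterministic synthetic
# sequences kept free of the built-in enzyme sites.
PGK1_PROMOTER_5P = "CCTACCGAAGAGAAATTAATGCTTAGACCGTGGATCGATACAGAAACTGCCGCCTAAATGACTAACCGTGA"
BGH_PA_3P = "ACGGTAATGGGCTAAAGCGCTTACTCTTAGAGCTAGGCCTAGTCAGTTCTCTACGCTAAC"
CASSETTE_SPACER = "CACTTGGGGCGCACGGCA"

assert len(PGK1_PROMOTER_5P) == 71 and len(BGH_PA_3P) == 60 and len(CASSETTE_SPACER) == 18


class DesignError(ValueError):
    """A design constraint cannot be satisfied on this locus."""


@dataclass
class DesignParameters:
    """Tunable lengths/enzymes of the component architectures.

    Defaults are the published architecture; ``site_len`` is fixed at 34
    (loxP and minimal FRT are both 34 bp).
    """

    mini_arm_len: int = 100
    oligo_flank_len: int = 83
    site_len: int = SITE_LEN
    pgk1_homology_len: int = 71
    bghpa_homology_len: int = 60
    spacer_len: int = 18
    retrieval_arm_len: int = 200
    phosphorothioate_per_end: int = 2
    cassette_site_enzyme_5: str = "BamHI"
    cassette_site_enzyme_3: str = "BamHI"
    retrieval_linearization_enzyme: str = "XhoI"
    retrieval_release_enzyme: str = "NotI"
    es_arm_range: tuple[int, int] = (2500, 3500)
    primer_len: int = 20
    loxp_site: str = LOXP_SITE
    frt_site: str = FRT_SITE

    def __post_init__(self) -> None:
        for name in (
            "mini_arm_len",
            "oligo_flank_len",
            "pgk1_homology_len",
            "bghpa_homology_len",
            "spacer_len",
            "retrieval_arm_len",
            "primer_len",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.site_len != SITE_LEN:
            raise ValueError(f"site_len is fixed at {SITE_LEN} bp")
        if len(self.loxp_site) != SITE_LEN or len(self.frt_site) != SITE_LEN:
            raise ValueError(f"loxP/FRT sites must be {SITE_LEN} bp")
        for enz in (
            self.cassette_site_enzyme_5,
            self.cassette_site_enzyme_3,
            self.retrieval_linearization_enzyme,
            self.retrieval_release_enzyme,
        ):
            if enz not in ENZYMES:
                raise ValueError(f"unknown enzyme {enz!r}")


@dataclass
class PrimerPair:
    fwd: str
    rev: str
    fwd_start: int  # 0-based start of forward primer on the locus
    rev_end: int    # 0-based end (exclusive) of the reverse primer footprint
    wt_amplicon: int
    targeted_amplicon: int


@dataclass
class DesignBundle:
    """The three synthesis components plus screening primers."""

    cassette_insert: DnaMolecule
    lox_oligo: DnaMolecule
    retrieval_insert: DnaMolecule
    screen_primers: PrimerPair
    strand_rationale: str = ""
    coordinates: dict = field(default_factory=dict)

    def report(self) -> dict:
        """JSON-ready design report (1-based inclusive display coordinates)."""
        return {
            "cassette_insert_len": len(self.cassette_insert),
            "lox_oligo_len": len(self.lox_oligo),
            "retrieval_insert_len": len(self.retrieval_insert),
            "phosphorothioate_bonds": self.lox_oligo.annotations.get("phosphorothioate_bonds", []),
            "screen_primers": asdict(self.screen_primers),
            "strand_rationale": self.strand_rationale,
            "coordinates": {k: (v + 1 if isinstance(v, int) else [v[0] + 1, v[1]]) for k, v in self.coordinates.items()},
        }


def _clean_arm(locus: DnaMolecule, start: int, end: int, what: str) -> str:
    if start < 0 or end > len(locus):
        raise DesignError(f"{what} [{start},{end}) runs off the locus (length {len(locus)})")
    seg = locus.seq[start:end]
    if "N" in seg:
        raise DesignError(f"{what} contains N bases; homology arms must be exact-matchable")
    return seg


def design_cassette_insert(
    locus: DnaMolecule, insertion_point: int, params: DesignParameters | None = None
) -> DnaMolecule:
    """The synthesized cassette insert around ``insertion_point``.

    Mini homology arms are copied verbatim from the locus immediately 5'
    and 3' of the insertion point.  Raises :class:`DesignError` if an
    arm would run off the locus, contains N, or if a release-enzyme site
    occurs inside the insert interior (which would fragment the cassette
    on release).
    """
    p = params or DesignParameters()
    arm5 = _clean_arm(locus, insertion_point - p.mini_arm_len, insertion_point, "5' mini arm")
    arm3 = _clean_arm(locus, insertion_point, insertion_point + p.mini_arm_len, "3' mini arm")
    site5 = ENZYMES[p.cassette_site_enzyme_5]
    site3 = ENZYMES[p.cassette_site_enzyme_3]
    pgk = PGK1_PROMOTER_5P[: p.pgk1_homology_len]
    bgh = BGH_PA_3P[-p.bghpa_homology_len :]
    spacer = CASSETTE_SPACER[: p.spacer_len]
    if len(pgk) != p.pgk1_homology_len or len(bgh) != p.bghpa_homology_len or len(spacer) != p.spacer_len:
        raise DesignError("homology-block constants shorter than requested lengths")

    segs = [
        ("restriction_site", site5, p.cassette_site_enzyme_5),
        ("homology_arm", arm5, "mini_arm_5"),
        ("FRT", p.frt_site, "FRT"),
        ("homology_arm", pgk, "Pgk1_5p_homology"),
        ("homology_arm", bgh, "BGHpA_3p_homology"),
        ("FRT", p.frt_site, "FRT"),
        ("marker", spacer, "spacer"),
        ("loxP", p.loxp_site, "loxP"),
        ("homology_arm", arm3, "mini_arm_3"),
        ("restriction_site", site3, p.cassette_site_enzyme_3),
    ]
    seq, feats, pos = "", [], 0
    for kind, s, label in segs:
        feats.append(Feature(kind, pos, pos + len(s), "+", label))
        seq += s
        pos += len(s)
    interior = seq[len(site5) : len(seq) - len(site3)]
    for enz in {p.cassette_site_enzyme_5, p.cassette_site_enzyme_3}:
        idx = interior.find(ENZYMES[enz])
        if idx != -1:
            raise DesignError(
                f"{enz} site at insert position {idx + len(site5)} would fragment the cassette on release"
            )
    mol = DnaMolecule(f"{locus.id}_cassette_insert", seq, "linear", feats)
    mol.annotations["insertion_point"] = insertion_point
    return mol


def design_lox_oligo(
    locus: DnaMolecule, insertion_point: int, params: DesignParameters | None = None
) -> DnaMolecule:
    """The single-stranded loxP oligo, written on the locus forward strand.

    200 nt with default flanks: the loxP site sits at [83, 117).  The
    phosphorothioate bonds (2 per end, annotation only) are recorded as
    1-based internucleotide bond indices.
    """
    p = params or DesignParameters()
    fl = p.oligo_flank_len
    flank5 = _clean_arm(locus, insertion_point - fl, insertion_point, "5' oligo flank")
    flank3 = _clean_arm(locus, insertion_point, insertion_point + fl, "3' oligo flank")
    seq = flank5 + p.loxp_site + flank3
    feats = [
        Feature("homology_arm", 0, fl, "+", "oligo_flank_5"),
        Feature("loxP", fl, fl + SITE_LEN, "+", "loxP"),
        Feature("homology_arm", fl + SITE_LEN, len(seq), "+", "oligo_flank_3"),
    ]
    mol = DnaMolecule(f"{locus.id}_loxP_oligo", seq, "linear", feats)
    n_bonds = len(seq) - 1
    k = p.phosphorothioate_per_end
    mol.annotations["phosphorothioate_bonds"] = list(range(1, k + 1)) + list(range(n_bonds - k + 1, n_bonds + 1))
    mol.annotations["insertion_point"] = insertion_point
    return mol


def design_retrieval_insert(
    locus: DnaMolecule, retrieve_interval: tuple[int, int], params: DesignParameters | None = None
) -> DnaMolecule:
    """The synthesized retrieval-vector insert for a genomic interval.

    ``NotI + 5'arm + XhoI + 3'arm`` where the arms equal the first and
    last ``retrieval_arm_len`` bases of the interval.  The linearization
    enzyme must not cut inside either arm.
    """
    p = params or DesignParameters()
    start, end = retrieve_interval
    if end - start < 2 * p.retrieval_arm_len:
        raise DesignError(
            f"retrieve interval of {end - start} nt is shorter than two {p.retrieval_arm_len}-nt arms"
        )
    arm5 = _clean_arm(locus, start, start + p.retrieval_arm_len, "5' retrieval arm")
    arm3 = _clean_arm(locus, end - p.retrieval_arm_len, end, "3' retrieval arm")
    lin = ENZYMES[p.retrieval_linearization_enzyme]
    rel = ENZYMES[p.retrieval_release_enzyme]
    for name, arm in (("5'", arm5), ("3'", arm3)):
        if lin in arm:
            raise DesignError(
                f"{p.retrieval_linearization_enzyme} site inside the {name} retrieval arm"
            )
    seq = rel + arm5 + lin + arm3
    a = len(rel)
    feats = [
        Feature("restriction_site", 0, a, "+", p.retrieval_release_enzyme),
        Feature("homology_arm", a, a + len(arm5), "+", "retrieval_arm_5"),
        Feature("restriction_site", a + len(arm5), a + len(arm5) + len(lin), "+", p.retrieval_linearization_enzyme),
        Feature("homology_arm", a + len(arm5) + len(lin), len(seq), "+", "retrieval_arm_3"),
    ]
    mol = DnaMolecule(f"{locus.id}_retrieval_insert", seq, "linear", feats)
    mol.annotations["retrieve_interval"] = (start, end)
    return mol


def _gc_frac(s: str) -> float:
    return (s.count("G") + s.count("C")) / len(s)


def _unique_in_locus(primer: str, locus: DnaMolecule) -> bool:
    return (locus.seq.count(primer) + locus.seq.count(revcomp(primer))) == 1


def design_screen_primers(
    locus: DnaMolecule, lox_point: int, params: DesignParameters | None = None
) -> PrimerPair:
    """Pick a loxP-screening primer pair flanking the oligo homology arms.

    The published screen types wells by a 34-bp amplicon size shift, so
    both primers must bind *outside* the oligo flanks (otherwise the
    amplicon would not span the inserted site).  Selection scans outward
    from the arm edges for the nearest unique 20-mer with 40-60% GC; no
    thermodynamic model is used.
    """
    p = params or DesignParameters()
    fl = p.oligo_flank_len
    k = p.primer_len
    arm_lo, arm_hi = lox_point - fl, lox_point + fl

    fwd = fwd_start = None
    for s in range(arm_lo - k, -1, -1):
        cand = locus.seq[s : s + k]
        if "N" in cand:
            continue
        if 0.4 <= _gc_frac(cand) <= 0.6 and _unique_in_locus(cand, locus):
            fwd, fwd_start = cand, s
            break
    rev = rev_end = None
    for s in range(arm_hi, len(locus) - k + 1):
        site = locus.seq[s : s + k]
        if "N" in site:
            continue
        if 0.4 <= _gc_frac(site) <= 0.6 and _unique_in_locus(site, locus):
            rev, rev_end = revcomp(site), s + k
            break
    if fwd is None or rev is None:
        raise DesignError("no acceptable unique primer found outside the oligo arms")
    wt = rev_end - fwd_start
    return PrimerPair(fwd, rev, fwd_start, rev_end, wt, wt + SITE_LEN)


def design_bundle(
    locus: DnaMolecule,
    gene: GeneModel,
    bac: BacClone,
    lox_point: int,
    cassette_point: int,
    retrieve_interval: tuple[int, int],
    params: DesignParameters | None = None,
) -> DesignBundle:
    """Design all three components plus primers for one CKO project.

    The loxP oligo is converted to the gene's coding strand and then to
    the lagging-strand version implied by the BAC insert orientation.
    """
    p = params or DesignParameters()
    cassette = design_cassette_insert(locus, cassette_point, p)
    oligo_fwd = design_lox_oligo(locus, lox_point, p)
    from .seqcore import reverse_complement  # local import to avoid cycle noise

    coding = oligo_fwd if gene.strand == "+" else reverse_complement(oligo_fwd)
    call = infer_lagging_strand(bac, gene)
    oligo = orient_oligo(coding, call, gene)
    retrieval = design_retrieval_insert(locus, retrieve_interval, p)
    primers = design_screen_primers(locus, lox_point, p)
    return DesignBundle(
        cassette_insert=cassette,
        lox_oligo=oligo,
        retrieval_insert=retrieval,
        screen_primers=primers,
        strand_rationale=call.rationale,
        coordinates={
            "lox_point": lox_point,
            "cassette_point": cassette_point,
            "retrieve_interval": retrieve_interval,
        },
    )
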