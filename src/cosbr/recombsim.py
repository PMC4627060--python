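"""Simulation of every DNA transaction in the CoSBR workflow.

Homology-directed replacement/insertion (double-stranded cassettes and
single-stranded oligos), gap-repair retrieval into a linearized vector,
Cre/Flp site-specific recombination, restriction digestion, PCR, and
restriction-fingerprint comparison.

Homology matching is exact-substring only and must be unique — real
recombineering tolerates imperfect arms, but every arm the designer
emits is >= 60 nt of locus copy, and exactness makes products fully
deterministic.  An ambiguous arm is an error, never a choice.  Bases of
a donor molecule that lie *outside* its terminal arm matches (e.g.
restriction-site remnants left by cassette release) are dropped from
the product; the junction trace records what was dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .seqcore import (
    DnaMolecule,
    ENZYMES,
    Feature,
    find_occurrences,
    revcomp,
    reverse_complement,
    rotate,
)
from .strandlogic import BacClone

__all__ = [
    "RecombineeringError",
    "HomologyNotFoundError",
    "AmbiguousHomologyError",
    "HomologyMatch",
    "DigestResult",
    "FragmentMatchReport",
    "recombineer_ds",
    "recombineer_ss",
    "gap_repair",
    "site_specific_recombine",
    "digest",
    "pcr",
    "compare_fragment_sets",
    "pooled_band_sizes",
]


class RecombineeringError(ValueError):
    pass


class HomologyNotFoundError(RecombineeringError):
    pass


class AmbiguousHomologyError(RecombineeringError):
    def __init__(self, msg: str, positions: list[int]):
        super().__init__(f"{msg}; matches at {positions}")
        self.positions = positions


@dataclass
class HomologyMatch:
    """An exact arm match between a donor molecule and its target."""

    arm_id: str
    donor_start: int
    donor_end: int
    target_start: int
    target_end: int
    strand: str = "+"
    exact: bool = True


def _unique_hit(pattern: str, target: DnaMolecule, what: str) -> tuple[int, str] | None:
    hits = find_occurrences(pattern, target)
    if not hits:
        return None
    if len(hits) > 1:
        raise AmbiguousHomologyError(f"{what} matches the target more than once", [h[0] for h in hits])
    return hits[0]


def _scan_terminal_arm(donor_seq: str, target: DnaMolecule, min_arm: int, side: str, what: str):
    """Find the terminal-most ``min_arm`` window of ``donor_seq`` that hits
    the target uniquely; returns (donor_offset, target_pos, strand)."""
    n = len(donor_seq)
    if n < min_arm:
        raise RecombineeringError(f"{what}: donor shorter than min_arm={min_arm}")
    offsets = range(0, n - min_arm + 1) if side == "5p" else range(n - min_arm, -1, -1)
    for o in offsets:
        hit = _unique_hit(donor_seq[o : o + min_arm], target, what)
        if hit is not None:
            return o, hit[0], hit[1]
    raise HomologyNotFoundError(f"{what}: no {min_arm}-nt terminal homology found in target")


def _homologous_exchange(target: DnaMolecule, donor: DnaMolecule, min_arm: int, op: str) -> DnaMolecule:
    """Shared engine for ds-cassette and ss-oligo recombineering.

    The donor's terminal arms are located on the target (either strand;
    the donor is silently reverse-complemented when its arms match the
    bottom strand, so the product is independent of oligo strand).  The
    target region spanned by the two arm matches — inclusive — is
    replaced by the donor between (and including) its arm matches.
    """
    o5, t5, s5 = _scan_terminal_arm(donor.seq, target, min_arm, "5p", f"{op}: 5' arm")
    if s5 == "-":
        donor = reverse_complement(donor)
        o5, t5, s5 = _scan_terminal_arm(donor.seq, target, min_arm, "5p", f"{op}: 5' arm")
        if s5 == "-":
            raise RecombineeringError(f"{op}: arm orientation unresolved")
    o3, t3, s3 = _scan_terminal_arm(donor.seq, target, min_arm, "3p", f"{op}: 3' arm")
    if s3 != "+":
        raise RecombineeringError(f"{op}: arms found in inconsistent orientation")

    L = len(target)
    c5, c3 = o5, o3 + min_arm  # donor span [c5, c3) to integrate
    t3_end = t3 + min_arm
    # maximal extension keeps junctions exact when the scan skipped remnants
    while c5 > 0 and (target.is_circular or t5 > 0) and donor.seq[c5 - 1] == target.base(t5 - 1):
        c5 -= 1
        t5 -= 1
        if t5 <= -L:
            break
    while c3 < len(donor) and (target.is_circular or t3_end < L) and donor.seq[c3] == target.base(t3_end):
        c3 += 1
        t3_end += 1
        if t3_end >= t5 + L:
            break
    if target.is_circular:
        t5 %= L
        t3_end %= L

    if target.is_circular:
        work = rotate(target, t5)
        span = (t3_end - t5) % L
        if span == 0:
            raise RecombineeringError(f"{op}: degenerate replacement span")
        prefix_end = 0
    else:
        if t3_end < t5:
            raise RecombineeringError(f"{op}: arms match the target in inconsistent order")
        work = target
        span = t3_end - t5
        prefix_end = t5

    payload = donor.seq[c5:c3]
    if target.is_circular:
        new_seq = payload + work.seq[span:]
        delta0 = 0
    else:
        new_seq = work.seq[:prefix_end] + payload + work.seq[span + prefix_end :]
        delta0 = prefix_end
    feats: list[Feature] = []
    repl_lo, repl_hi = delta0, delta0 + span
    shift = len(payload) - span
    for f in work.features:
        if f.wraps() or (f.start < repl_hi and f.end > repl_lo):
            continue  # overlaps the replaced span (wrap features always cover origin-side)
        if f.end <= repl_lo:
            feats.append(Feature(f.kind, f.start, f.end, f.strand, f.label))
        else:
            feats.append(Feature(f.kind, f.start + shift, f.end + shift, f.strand, f.label))
    for f in donor.features:
        if f.start >= c5 and f.end <= c3:
            off = delta0 - c5
            feats.append(Feature(f.kind, f.start + off, f.end + off, f.strand, f.label))
    product = DnaMolecule(f"{target.id}+{donor.id}", new_seq, target.topology, feats, dict(target.annotations))
    trace = {
        "operation": op,
        "target": target.id,
        "donor": donor.id,
        "replaced_span_nt": span,
        "payload_nt": len(payload),
        "dropped_donor_prefix_nt": c5,
        "dropped_donor_suffix_nt": len(donor) - c3,
        "junctions_1based": [delta0 + 1, delta0 + len(payload)],
    }
    product.annotations.setdefault("recombination_trace", []).append(trace)
    return product


def recombineer_ds(target: DnaMolecule, cassette: DnaMolecule, min_arm: int = 50) -> DnaMolecule:
    """Homology-arm-guided replacement with a double-stranded cassette.

    The target region between (and including) the cassette's two
    terminal arm matches is replaced by the cassette, so
    ``len(product) == len(target) - replaced_span + integrated_payload``.
    """
    return _homologous_exchange(target, cassette, min_arm, "recombineer_ds")


def recombineer_ss(target: DnaMolecule, oligo: DnaMolecule, min_arm: int = 50) -> DnaMolecule:
    """ssODN-mediated insertion/replacement; strand-symmetric.

    The product is identical whichever strand version of the oligo is
    supplied — strand choice (lagging vs leading) only affects in-vivo
    efficiency, which is not simulated.
    """
    return _homologous_exchange(target, oligo, min_arm, "recombineer_ss")


def gap_repair(bac: BacClone | DnaMolecule, linearized_vector: DnaMolecule, min_arm: int = 50) -> DnaMolecule:
    """Retrieve the genomic interval between the vector's terminal arms.

    The linearized vector's two ends must match the two ends of a unique
    interval on the (circular) BAC, pointing inward; the circular
    product carries the full interval plus the vector backbone, with
    each arm present exactly once.
    """
    target = bac.molecule() if isinstance(bac, BacClone) else bac
    if linearized_vector.is_circular:
        raise RecombineeringError("gap_repair: vector must be linearized")
    vec = linearized_vector
    oL, tL, sL = _scan_terminal_arm(vec.seq, target, min_arm, "5p", "gap_repair: left-end arm")
    if sL == "-":
        vec = reverse_complement(vec)
        oL, tL, sL = _scan_terminal_arm(vec.seq, target, min_arm, "5p", "gap_repair: left-end arm")
        if sL == "-":
            raise RecombineeringError("gap_repair: arm orientation unresolved")
    oR, tR, sR = _scan_terminal_arm(vec.seq, target, min_arm, "3p", "gap_repair: right-end arm")
    if sR != "+":
        raise RecombineeringError("gap_repair: arms found in inconsistent orientation")

    L = len(target)
    # left end of the vector anneals to the interval's 3' end; right end to its 5' end
    bL_s, tL_s = oL, tL
    bL_e, tL_e = oL + min_arm, tL + min_arm
    bR_s, tR_s = oR, tR
    bR_e, tR_e = oR + min_arm, tR + min_arm
    while bL_e < len(vec) and vec.seq[bL_e] == target.base(tL_e):
        bL_e += 1
        tL_e += 1
    while bR_s > 0 and vec.seq[bR_s - 1] == target.base(tR_s - 1):
        bR_s -= 1
        tR_s -= 1
    tL_s %= L
    tL_e %= L
    tR_s %= L
    tR_e %= L
    interval_len = (tL_e - tR_s) % L
    if interval_len == 0 or tR_s == tL_s:
        raise RecombineeringError("gap_repair: degenerate interval (arms match the same position)")
    if interval_len < (tR_e - tR_s) % L + (tL_e - tL_s) % L:
        raise RecombineeringError("gap_repair: arms face outward or overlap on the BAC")

    work = rotate(target, tR_s)
    genomic = work.seq[:interval_len]
    backbone_part = vec.seq[bL_e:bR_s]
    seq = genomic + backbone_part
    feats: list[Feature] = []
    for f in work.features:
        if not f.wraps() and f.end <= interval_len:
            feats.append(Feature(f.kind, f.start, f.end, f.strand, f.label))
    for f in vec.features:
        if bL_e <= f.start and f.end <= bR_s:
            off = interval_len - bL_e
            feats.append(Feature(f.kind, f.start + off, f.end + off, f.strand, f.label))
    armA_len = (tR_e - tR_s) % L
    armB_len = (tL_e - tL_s) % L
    feats.append(Feature("homology_arm", 0, armA_len, "+", "retrieval_arm_5"))
    feats.append(Feature("homology_arm", interval_len - armB_len, interval_len, "+", "retrieval_arm_3"))
    product = DnaMolecule(f"{target.id}_retrieved", seq, "circular", feats)
    product.annotations["recombination_trace"] = [
        {
            "operation": "gap_repair",
            "bac": target.id,
            "vector": linearized_vector.id,
            "retrieved_interval_nt": interval_len,
            "vector_backbone_nt": len(backbone_part),
            "dropped_vector_end_nt": [bL_s, len(vec) - bR_e],
        }
    ]
    product.annotations["retrieved_interval_nt"] = interval_len
    return product


def site_specific_recombine(
    mol: DnaMolecule, site_kind: str, pair: tuple[str, str] | None = None
) -> list[DnaMolecule]:
    """Cre (loxP) or Flp (FRT) recombination between two annotated sites.

    Direct repeats excise (crossover between site midpoints, so every
    product carries one full 34-nt hybrid site); inverted repeats invert
    the intervening segment.  With more than two sites, the pair must be
    named by feature labels.
    """
    if site_kind not in ("loxP", "FRT"):
        raise ValueError("site_kind must be loxP or FRT")
    sites = sorted(mol.features_of(site_kind), key=lambda f: f.start)
    sites = [s for s in sites if not s.wraps()]
    if pair is not None:
        chosen = [s for s in sites if s.label in pair]
        if len(chosen) != 2:
            raise RecombineeringError(f"named site pair {pair} not found exactly once each")
        sites = sorted(chosen, key=lambda f: f.start)
    if len(sites) < 2:
        raise RecombineeringError(f"need >= 2 {site_kind} sites, found {len(sites)}")
    if len(sites) > 2:
        raise RecombineeringError(
            f"{len(sites)} {site_kind} sites present; name an explicit pair to recombine"
        )
    a, b = sites
    half = (a.end - a.start) // 2
    a_mid, b_mid = a.start + half, b.start + half
    if a.strand == b.strand:
        return _excise(mol, a, b, a_mid, b_mid, site_kind)
    return [_invert(mol, a, b, a_mid, b_mid)]


def _excise(mol, a, b, a_mid, b_mid, site_kind):
    site_len = a.end - a.start
    half = site_len // 2
    # excised circle: first half of B + (second half of A .. first half of B)
    circ_seq = mol.seq[b.start : b_mid] + mol.seq[a_mid : b.start]
    circ_feats = [Feature(site_kind, 0, site_len, a.strand, f"{a.label or site_kind}/hybrid")]
    for f in mol.features:
        if f in (a, b) or f.wraps():
            continue
        if a.end <= f.start and f.end <= b.start:
            circ_feats.append(Feature(f.kind, f.start - a_mid + half, f.end - a_mid + half, f.strand, f.label))
    excised = DnaMolecule(f"{mol.id}_excised", circ_seq, "circular", circ_feats)

    removed = b_mid - a_mid
    rem_seq = mol.seq[: a.start] + mol.seq[a.start : a_mid] + mol.seq[b_mid : b.end] + mol.seq[b.end :]
    rem_feats = [Feature(site_kind, a.start, a.start + site_len, a.strand, f"{a.label or site_kind}/hybrid")]
    for f in mol.features:
        if f in (a, b) or f.wraps():
            continue
        if f.end <= a.start:
            rem_feats.append(Feature(f.kind, f.start, f.end, f.strand, f.label))
        elif f.start >= b.end:
            rem_feats.append(Feature(f.kind, f.start - removed, f.end - removed, f.strand, f.label))
    remaining = DnaMolecule(f"{mol.id}_recombined", rem_seq, mol.topology, rem_feats)
    return [remaining, excised]


def _invert(mol, a, b, a_mid, b_mid):
    seg = revcomp(mol.seq[a_mid:b_mid])
    seq = mol.seq[:a_mid] + seg + mol.seq[b_mid:]
    feats = []
    for f in mol.features:
        if f.wraps():
            continue
        if f.end <= a_mid or f.start >= b_mid:
            feats.append(Feature(f.kind, f.start, f.end, f.strand, f.label))
        elif a_mid <= f.start and f.end <= b_mid:
            ns = a_mid + (b_mid - f.end)
            ne = a_mid + (b_mid - f.start)
            feats.append(Feature(f.kind, ns, ne, "-" if f.strand == "+" else "+", f.label))
    # both recognition sites are retained on an inversion
    for s in (a, b):
        if not any(g.kind == s.kind and g.start == s.start for g in feats):
            feats.append(Feature(s.kind, s.start, s.end, s.strand, s.label))
    return DnaMolecule(f"{mol.id}_inverted", seq, mol.topology, feats)


# ---------------------------------------------------------------------------
# Digestion / PCR / fingerprint comparison
# ---------------------------------------------------------------------------


@dataclass
class DigestResult:
    enzymes: tuple[str, ...]
    cut_positions: list[int]
    fragments: list[DnaMolecule]
    note: str = ""

    @property
    def fragment_lengths(self) -> list[int]:
        return sorted(len(f) for f in self.fragments)


def digest(mol: DnaMolecule, enzymes) -> DigestResult:
    """Cut at every recognition site of the given enzymes.

    Cut position is the 5' end of the recognition site (band-size
    resolution makes overhang geometry irrelevant).  A linear molecule
    with n cuts yields n+1 fragments; a circular one with n >= 1 cuts
    yields n fragments; fragment lengths always sum to the input length.
    """
    if isinstance(enzymes, str):
        enzymes = [enzymes]
    enzymes = tuple(enzymes)
    cuts: set[int] = set()
    for enz in enzymes:
        if enz not in ENZYMES:
            raise ValueError(f"unknown enzyme {enz!r}")
        for pos, strand in find_occurrences(ENZYMES[enz], mol):
            cuts.add(pos)
    positions = sorted(cuts)
    n = len(mol)
    if not positions:
        return DigestResult(enzymes, [], [mol.copy()], note="no cut sites; molecule intact")
    frags: list[DnaMolecule] = []
    if mol.is_circular:
        work = rotate(mol, positions[0])
        rel = sorted({(p - positions[0]) % n for p in positions})
        bounds = rel + [n]
        for i, (s, e) in enumerate(zip(bounds[:-1], bounds[1:])):
            frags.append(_fragment(work, s, e, f"{mol.id}_frag{i + 1}"))
        note = "circular: n cuts -> n fragments"
    else:
        bounds = [0] + positions + [n]
        for i, (s, e) in enumerate(zip(bounds[:-1], bounds[1:])):
            if e > s:
                frags.append(_fragment(mol, s, e, f"{mol.id}_frag{i + 1}"))
        note = "linear: n cuts -> n+1 fragments"
    return DigestResult(enzymes, positions, frags, note)


def _fragment(mol: DnaMolecule, s: int, e: int, fid: str) -> DnaMolecule:
    feats = [
        Feature(f.kind, f.start - s, f.end - s, f.strand, f.label)
        for f in mol.features
        if not f.wraps() and s <= f.start and f.end <= e
    ]
    return DnaMolecule(fid, mol.seq[s:e], "linear", feats)


def pcr(templates, fwd: str, rev: str, max_amplicon: int = 5000) -> list[int]:
    """Predicted amplicon lengths for a primer pair on one or more templates.

    Primer binding is exact-match (the screening PCR distinguishes
    products by a 34-nt size shift; thermodynamics adds nothing here):
    the forward primer anneals on the top strand, the reverse primer as
    its reverse complement.  A convergent pair within ``max_amplicon``
    yields one amplicon including both primer footprints; divergent
    primers on a circular template amplify around the origin.  Pools of
    templates (polyclonal wells) return the union of their amplicons.
    """
    if len(fwd) < 15 or len(rev) < 15:
        raise ValueError("primers must be >= 15 nt")
    if isinstance(templates, DnaMolecule):
        templates = [templates]
    out: set[int] = set()
    for mol in templates:
        lengths = []
        # a pair amplifies when either primer acts as the top-strand primer
        # and the other binds convergently downstream (the template may be
        # stored on either strand)
        for left, right in ((fwd, rev), (rev, fwd)):
            starts = [p for p, _ in find_occurrences(left, mol, both_strands=False)]
            ends = [p + len(right) for p, _ in find_occurrences(revcomp(right), mol, both_strands=False)]
            for f in starts:
                for r_end in ends:
                    if mol.is_circular:
                        ln = (r_end - f) % len(mol)
                        if ln == 0:
                            ln = len(mol)
                    else:
                        ln = r_end - f
                    if len(fwd) + len(rev) <= ln <= max_amplicon:
                        lengths.append(ln)
        lengths = sorted(set(lengths))
        if len(lengths) > 1:
            warnings.warn(f"{mol.id}: primer pair yields {len(lengths)} amplicons", stacklevel=2)
        out.update(lengths)
    return sorted(out)


@dataclass
class FragmentMatchReport:
    matched: list[tuple[int, int]] = field(default_factory=list)
    unmatched_observed: list[int] = field(default_factory=list)
    unmatched_expected: list[int] = field(default_factory=list)

    @property
    def is_match(self) -> bool:
        return not self.unmatched_observed and not self.unmatched_expected


def compare_fragment_sets(observed, expected, tolerance: float = 0.05) -> FragmentMatchReport:
    """Greedy size-matching of two fragment multisets within a relative
    tolerance — the in-silico analog of comparing a restriction
    fingerprint against a reference digest."""
    obs = sorted(observed, reverse=True)
    exp = sorted(expected, reverse=True)
    report = FragmentMatchReport()
    remaining = list(exp)
    for o in obs:
        best = None
        for e in remaining:
            if abs(o - e) <= tolerance * e and (best is None or abs(o - e) < abs(o - best)):
                best = e
        if best is None:
            report.unmatched_observed.append(o)
        else:
            remaining.remove(best)
            report.matched.append((o, best))
    report.unmatched_expected = remaining
    return report


def pooled_band_sizes(digests, tolerance: float = 0.05) -> list[int]:
    """Distinct gel bands from one or more digests (a mixed plasmid prep):
    fragment sizes within ``tolerance`` of each other co-migrate."""
    sizes = sorted(s for d in digests for s in d.fragment_lengths)
    bands: list[int] = []
    for s in sizes:
        if not bands or abs(s - bands[-1]) > tolerance * bands[-1]:
            bands.append(s)
    return bands
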