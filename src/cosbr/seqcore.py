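"""Core sequence/feature data model and file I/O.

Everything downstream (strand logic, component design, recombineering
simulation, allele QC) operates on two containers defined here:

``DnaMolecule``
    A DNA string over ``{A, C, G, T, N}`` with explicit topology
    (``linear`` or ``circular``) and a list of typed :class:`Feature`
    annotations.  Circular molecules are stored linearized with a
    topology flag; they have no privileged origin, and all interval
    operations are rotation-invariant.  A feature on a circular molecule
    may wrap the stored origin, represented as ``start > end``.

``GeneModel``
    Ordered exons with CDS sub-intervals and a strand; exon index 0 is
    always the 5'-most exon *in gene orientation*, so a minus-strand
    gene stores its exons in descending genomic order.

Coordinates are 0-based half-open internally; user-facing reports are
1-based inclusive (GenBank convention).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "DnaMolecule",
    "Feature",
    "GeneModel",
    "FEATURE_KINDS",
    "LOXP_SITE",
    "FRT_SITE",
    "SITE_LEN",
    "ENZYMES",
    "revcomp",
    "translate",
    "reverse_complement",
    "rotate",
    "canonical_circular",
    "molecules_equivalent",
    "find_occurrences",
    "load_locus",
    "write_construct",
    "read_construct",
]

_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Canonical 34-nt Cre recognition site.  The site length (34 bp) is fixed
#: by the biology; the sequence is the standard literature loxP and may be
#: overridden by callers that need a variant site.
LOXP_SITE = "ATAACTTCGTATAATGTATGCTATACGAAGTTAT"

#: Minimal 34-nt Flp recognition target (standard literature FRT).
FRT_SITE = "GAAGTTCCTATTCTCTAGAAAGTATAGGAACTTC"

SITE_LEN = 34

#: Built-in restriction enzyme table (all palindromic 6/8-cutters used by
#: the workflow).  Cut position is modeled at the 5' end of the site; at
#: gel band resolution overhang geometry is irrelevant.
ENZYMES = {
    "BamHI": "GGATCC",
    "EcoRI": "GAATTC",
    "NotI": "GCGGCCGC",
    "XhoI": "CTCGAG",
    "SpeI": "ACTAGT",
    "BglII": "AGATCT",
}

FEATURE_KINDS = frozenset(
    {
        "loxP",
        "FRT",
        "exon",
        "CDS",
        "homology_arm",
        "marker",
        "restriction_site",
        "primer_site",
        "origin",
        "promoter_end",
        "junction",
    }
)

_GENBANK_TYPE = {
    "loxP": "misc_recomb",
    "FRT": "misc_recomb",
    "exon": "exon",
    "CDS": "CDS",
    "homology_arm": "misc_feature",
    "marker": "misc_feature",
    "restriction_site": "misc_feature",
    "primer_site": "primer_bind",
    "origin": "rep_origin",
    "promoter_end": "misc_feature",
    "junction": "misc_feature",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a CDS with the standard nuclear code; '*' marks stops."""
    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate())


@dataclass
class Feature:
    """A typed annotation on a molecule.

    ``start``/``end`` are 0-based half-open.  On a circular molecule a
    wrap-around feature is represented with ``start > end``.
    """

    kind: str
    start: int
    end: int
    strand: str = "+"
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature strand must be '+' or '-', got {self.strand!r}")

    def length(self, mol_len: int | None = None) -> int:
        if self.start < self.end:
            return self.end - self.start
        if mol_len is None:
            raise ValueError("wrap-around feature length needs molecule length")
        return mol_len - self.start + self.end

    def wraps(self) -> bool:
        return self.start >= self.end


@dataclass
class DnaMolecule:
    id: str
    seq: str
    topology: str = "linear"
    features: list[Feature] = field(default_factory=list)
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError("empty sequence")
        bad = set(self.seq) - _ALPHABET
        if bad:
            raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"topology must be linear|circular, got {self.topology!r}")
        for f in self.features:
            self._check_feature(f)
        if self.is_circular:
            self.features = [_normalize_wrap(f, len(self.seq)) for f in self.features]

    def _check_feature(self, f: Feature) -> None:
        n = len(self.seq)
        if not (0 <= f.start <= n and 0 <= f.end <= n):
            raise ValueError(f"feature {f.label or f.kind} out of bounds [{f.start},{f.end}) on {n}-mer")
        if f.start >= f.end and self.topology == "linear":
            raise ValueError(f"feature {f.label or f.kind}: start >= end on a linear molecule")
        if f.kind in ("loxP", "FRT") and f.length(n) != SITE_LEN:
            raise ValueError(f"{f.kind} feature must be exactly {SITE_LEN} bp, got {f.length(n)}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def features_of(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    def base(self, i: int) -> str:
        """Base at position i; circular molecules index modulo length."""
        if self.is_circular:
            return self.seq[i % len(self.seq)]
        return self.seq[i]

    def segment(self, start: int, end: int) -> str:
        """Sequence of [start, end); wraps on circular molecules."""
        n = len(self.seq)
        if self.is_circular:
            start %= n
            end %= n
            if start < end:
                return self.seq[start:end]
            return self.seq[start:] + self.seq[:end]
        if not (0 <= start <= end <= n):
            raise ValueError(f"segment [{start},{end}) out of bounds on linear {n}-mer")
        return self.seq[start:end]

    def copy(self, **overrides) -> "DnaMolecule":
        data = {
            "id": self.id,
            "seq": self.seq,
            "topology": self.topology,
            "features": [dataclasses.replace(f) for f in self.features],
            "annotations": dict(self.annotations),
        }
        data.update(overrides)
        return DnaMolecule(**data)


def _normalize_wrap(f: Feature, n: int) -> Feature:
    # full-length wrap like [k, k) is not allowed; everything else kept as-is
    if f.start == f.end:
        raise ValueError(f"zero/full-length feature {f.label or f.kind} not representable")
    return f


def reverse_complement(mol: DnaMolecule) -> DnaMolecule:
    """Reverse-complement a molecule, remapping features and strands."""
    n = len(mol.seq)
    feats = []
    for f in mol.features:
        if f.wraps():
            # wrap [s, e) with s>e maps to wrap [n-e, n-s) with s'>e' again
            ns, ne = (n - f.end) % n, (n - f.start) % n
        else:
            ns, ne = n - f.end, n - f.start
        feats.append(Feature(f.kind, ns, ne, "-" if f.strand == "+" else "+", f.label))
    return DnaMolecule(mol.id, revcomp(mol.seq), mol.topology, feats, dict(mol.annotations))


def rotate(mol: DnaMolecule, offset: int) -> DnaMolecule:
    """Rotate a circular molecule so old position ``offset`` becomes 0."""
    if not mol.is_circular:
        raise ValueError("only circular molecules can be rotated")
    n = len(mol.seq)
    offset %= n
    seq = mol.seq[offset:] + mol.seq[:offset]
    feats = []
    for f in mol.features:
        ns = (f.start - offset) % n
        ne = (f.end - offset) % n
        if ne == 0 and not f.wraps():
            ne = n  # half-open end landing on the origin is position n, not 0
        feats.append(Feature(f.kind, ns, ne, f.strand, f.label))
    return DnaMolecule(mol.id, seq, "circular", feats, dict(mol.annotations))


def canonical_circular(seq: str) -> str:
    """Lexicographically minimal rotation over both strands.

    Used to compare circular molecules independent of stored origin and
    strand.  O(n^2) worst case but fine at plasmid/BAC-fixture scale.
    """
    best = None
    for s in (seq, revcomp(seq)):
        doubled = s + s
        for i in range(len(s)):
            cand = doubled[i : i + len(s)]
            if best is None or cand < best:
                best = cand
    return best  # type: ignore[return-value]


def molecules_equivalent(a: DnaMolecule, b: DnaMolecule) -> bool:
    """Sequence identity up to rotation/strand for circular, strand for linear."""
    if len(a) != len(b):
        return False
    if a.is_circular and b.is_circular:
        return canonical_circular(a.seq) == canonical_circular(b.seq)
    if not a.is_circular and not b.is_circular:
        return a.seq == b.seq or a.seq == revcomp(b.seq)
    return False


def find_occurrences(pattern: str, mol: DnaMolecule, both_strands: bool = True) -> list[tuple[int, str]]:
    """All (start, strand) occurrences of ``pattern``; circular search wraps.

    Start positions are on the stored top strand in [0, len); a '-' hit at
    ``s`` means revcomp(pattern) occurs at ``s``.
    """
    n = len(mol.seq)
    hay = mol.seq + (mol.seq[: len(pattern) - 1] if mol.is_circular and len(pattern) > 1 else "")
    out: list[tuple[int, str]] = []
    pats = [(pattern, "+")]
    if both_strands:
        rc = revcomp(pattern)
        if rc != pattern:
            pats.append((rc, "-"))
    for pat, strand in pats:
        i = hay.find(pat)
        while i != -1:
            if i < n:
                out.append((i, strand))
            i = hay.find(pat, i + 1)
    out.sort()
    return out


# ---------------------------------------------------------------------------
# Gene model
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """Exon/CDS structure of a gene on a locus.

    ``exons`` and ``cds`` are lists of (start, end) genomic intervals on
    the locus forward strand, ordered 5'->3' in *gene* orientation (so a
    '-' strand gene lists descending genomic coordinates).  Every CDS
    interval lies within exactly one exon.
    """

    gene_id: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    critical_exons: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r}")
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if e1 > s2:
                raise ValueError("exons overlap")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise ValueError("exons must be ordered 5'->3' on the gene strand")
        for cs, ce in self.cds:
            if self.exon_index_containing(cs, ce) is None:
                raise ValueError(f"CDS interval [{cs},{ce}) not contained in a single exon")
        csorted = sorted(self.cds)
        expected_cds = csorted if self.strand == "+" else csorted[::-1]
        if list(self.cds) != expected_cds:
            self.cds = expected_cds
        for i in self.critical_exons:
            if not (0 <= i < len(self.exons)):
                raise ValueError(f"critical exon index {i} out of range")

    def exon_index_containing(self, start: int, end: int) -> int | None:
        for i, (es, ee) in enumerate(self.exons):
            if es <= start and end <= ee:
                return i
        return None

    def cds_in_exon(self, i: int) -> list[tuple[int, int]]:
        es, ee = self.exons[i]
        return [(cs, ce) for cs, ce in self.cds if es <= cs and ce <= ee]

    def cds_len_in_exon(self, i: int) -> int:
        return sum(ce - cs for cs, ce in self.cds_in_exon(i))

    def coding_exon_indices(self) -> list[int]:
        return [i for i in range(len(self.exons)) if self.cds_len_in_exon(i) > 0]

    def coding_sequence(self, locus: DnaMolecule, skip_exons: Iterable[int] = ()) -> str:
        """Spliced CDS (gene orientation), optionally excising whole exons."""
        skip = set(skip_exons)
        parts = []
        for i in range(len(self.exons)):
            if i in skip:
                continue
            for cs, ce in self.cds_in_exon(i):
                s = locus.seq[cs:ce]
                parts.append(s if self.strand == "+" else revcomp(s))
        return "".join(parts)

    def genomic_span(self) -> tuple[int, int]:
        lo = min(s for s, _ in self.exons)
        hi = max(e for _, e in self.exons)
        return lo, hi

    def reverse_complemented(self, locus_len: int) -> "GeneModel":
        """Gene model on the reverse-complemented locus."""
        flip = lambda iv: (locus_len - iv[1], locus_len - iv[0])
        return GeneModel(
            self.gene_id,
            "-" if self.strand == "+" else "+",
            [flip(iv) for iv in self.exons],
            [flip(iv) for iv in self.cds],
            set(self.critical_exons),
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def load_locus(fasta_path: str | Path, annotation_path: str | Path) -> tuple[DnaMolecule, GeneModel]:
    """Read a single-record FASTA plus a BED6/BED12 or minimal GFF3 gene model.

    Exon/CDS features are attached to the returned molecule; coordinates
    are converted to the internal 0-based half-open convention.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    mol = DnaMolecule(rec.id, str(rec.seq), "linear")

    ann = Path(annotation_path)
    text = ann.read_text()
    if _looks_like_gff(text):
        gene = _parse_gff(text)
    else:
        gene = _parse_bed(text)
    span = gene.genomic_span()
    if span[1] > len(mol):
        raise ValueError("gene model extends past the locus sequence")
    for i, (es, ee) in enumerate(gene.exons):
        mol.features.append(Feature("exon", es, ee, gene.strand, f"exon{i + 1}"))
    for cs, ce in gene.cds:
        mol.features.append(Feature("CDS", cs, ce, gene.strand, "CDS"))
    return mol, gene


def _looks_like_gff(text: str) -> bool:
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        return len(cols) == 9
    raise ValueError("empty annotation file")


def _parse_strand(s: str) -> str:
    if s not in ("+", "-"):
        raise ValueError(f"unknown strand {s!r}")
    return s


def _parse_bed(text: str) -> GeneModel:
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith(("#", "track", "browser"))]
    rows = [l.rstrip("\n").split("\t") for l in lines]
    if not rows:
        raise ValueError("empty BED file")
    if len(rows[0]) >= 12:
        if len(rows) != 1:
            raise ValueError("BED12 gene model must be a single line")
        c = rows[0]
        chrom_start = int(c[1])
        name, strand = c[3], _parse_strand(c[5])
        thick = (int(c[6]), int(c[7]))
        sizes = [int(x) for x in c[10].rstrip(",").split(",")]
        starts = [int(x) for x in c[11].rstrip(",").split(",")]
        if len(sizes) != int(c[9]) or len(starts) != int(c[9]):
            raise ValueError("BED12 block count mismatch")
        exons = [(chrom_start + st, chrom_start + st + sz) for st, sz in zip(starts, sizes)]
        cds = []
        for es, ee in exons:
            cs, ce = max(es, thick[0]), min(ee, thick[1])
            if cs < ce:
                cds.append((cs, ce))
    else:
        if any(len(c) < 6 for c in rows):
            raise ValueError("BED6 lines need 6 columns")
        strands = {c[5] for c in rows}
        if len(strands) != 1:
            raise ValueError("all BED6 exon lines must share one strand")
        strand = _parse_strand(strands.pop())
        name = rows[0][3]
        exons = sorted((int(c[1]), int(c[2])) for c in rows)
        cds = []
    if strand == "-":
        exons = exons[::-1]
        cds = cds[::-1]
    return GeneModel(name, strand, exons, cds)


def _parse_gff(text: str) -> GeneModel:
    exons, cds = [], []
    strand, name = None, "gene"
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 9:
            raise ValueError("malformed GFF3 line")
        typ, start, end, st = cols[2], int(cols[3]) - 1, int(cols[4]), cols[6]
        if typ.lower() not in ("exon", "cds", "gene", "mrna"):
            continue
        if typ.lower() in ("gene", "mrna"):
            for kv in cols[8].split(";"):
                if kv.startswith(("ID=", "Name=")):
                    name = kv.split("=", 1)[1]
            continue
        st = _parse_strand(st)
        if strand is None:
            strand = st
        elif strand != st:
            raise ValueError("mixed strands in gene model")
        (exons if typ.lower() == "exon" else cds).append((start, end))
    if strand is None or not exons:
        raise ValueError("no exon lines found in GFF3")
    exons.sort()
    cds.sort()
    if strand == "-":
        exons, cds = exons[::-1], cds[::-1]
    return GeneModel(name, strand, exons, cds)


def _to_seqrecord(mol: DnaMolecule) -> SeqRecord:
    rec = SeqRecord(Seq(mol.seq), id=mol.id, name=mol.id[:16] or "construct", description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = mol.topology
    n = len(mol.seq)
    for f in mol.features:
        strand = 1 if f.strand == "+" else -1
        if f.wraps():
            loc = SimpleLocation(f.start, n, strand) + SimpleLocation(0, f.end, strand)
        else:
            loc = SimpleLocation(f.start, f.end, strand)
        sf = SeqFeature(loc, type=_GENBANK_TYPE[f.kind])
        sf.qualifiers["label"] = [f.label or f.kind]
        sf.qualifiers["note"] = [f"kind={f.kind}"]
        rec.features.append(sf)
    return rec


def write_construct(mol: DnaMolecule, path: str | Path, format: str = "genbank") -> None:
    """Write a molecule as FASTA (sequence only) or GenBank (with features).

    GenBank output marks circular topology on the LOCUS line and carries
    loxP/FRT as misc_recomb and primer sites as primer_bind features.
    """
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    if format == "fasta":
        rec = SeqRecord(Seq(mol.seq), id=mol.id, description=mol.annotations.get("description", ""))
        SeqIO.write([rec], str(path), "fasta")
    else:
        SeqIO.write([_to_seqrecord(mol)], str(path), "genbank")


def read_construct(path: str | Path) -> DnaMolecule:
    """Read back a GenBank construct written by :func:`write_construct`."""
    rec = SeqIO.read(str(path), "genbank")
    topology = rec.annotations.get("topology", "linear")
    feats = []
    n = len(rec.seq)
    for sf in rec.features:
        kind = None
        for note in sf.qualifiers.get("note", []):
            if note.startswith("kind="):
                kind = note[5:]
        if kind is None or kind not in FEATURE_KINDS:
            continue
        parts = getattr(sf.location, "parts", [sf.location])
        if len(parts) == 2 and int(parts[0].end) == n and int(parts[1].start) == 0:
            start, end = int(parts[0].start), int(parts[1].end)
        else:
            start, end = int(sf.location.start), int(sf.location.end)
        strand = "-" if sf.location.strand == -1 else "+"
        label = (sf.qualifiers.get("label") or [kind])[0]
        feats.append(Feature(kind, start, end, strand, label))
    return DnaMolecule(rec.id, str(rec.seq), topology, feats)
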