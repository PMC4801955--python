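"""Custom 18S V9 reference database: construction and interrogation.

The reference database holds barcode sequences (full-length rDNA fragments
or extracted V9 amplicons) with their taxonomic lineages.  On top of it sit
the resolution analyses a metabarcoding study needs before touching reads:

* amplicon extraction between a universal primer pair,
* pairwise identity (the quantity behind every identity threshold),
* synonymy groups — species whose amplicons are 100% identical over a
  minimum overlap and are therefore indistinguishable at this locus,
* diagnostic positions — the variable alignment columns that discriminate a
  set of near-identical species (the basis of character-based assignment).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

from ._align import encode, semiglobal_identity

__all__ = [
    "TaxonRecord",
    "PrimerPair",
    "ReferenceDatabase",
    "SynonymyGroup",
    "DiagnosticKey",
    "PrimerNotFoundError",
    "AmbiguousAmplificationError",
    "NotDiscriminableError",
    "extract_amplicon",
    "pairwise_identity",
    "find_synonymy_groups",
    "diagnostic_positions",
    "merge_local_into_base",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
]

_ALLOWED = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC degeneracy: primer symbol -> set of template bases it matches
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMP = str.maketrans("ACGTURYSWKMBDHVN", "TGCAAYRSWMKVHDBN")


class PrimerNotFoundError(ValueError):
    """Raised when no primer site is found on either strand."""


class AmbiguousAmplificationError(ValueError):
    """Raised when more than one candidate amplicon is delimited."""


class NotDiscriminableError(ValueError):
    """Raised when two inputs to the diagnostic scan are identical."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TaxonRecord:
    """One reference barcode with its taxonomy.

    ``lineage`` is ordered domain -> species; ``is_amplicon`` distinguishes
    an extracted V9 amplicon from a full-length source sequence.
    """

    id: str
    lineage: tuple[str, ...]
    sequence: str
    is_amplicon: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty sequence for %r" % self.id)
        bad = set(self.sequence.upper()) - _ALLOWED
        if bad:
            raise ValueError("non-IUPAC-core characters %r in %r" % (bad, self.id))
        if not self.lineage:
            raise ValueError("empty lineage for %r" % self.id)
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "lineage", tuple(self.lineage))

    @property
    def species(self) -> str:
        return self.lineage[-1]


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair as synthesized (5'->3').

    The reverse primer anneals to the opposite strand, so its reverse
    complement is what appears downstream on the template.
    """

    forward: str
    reverse: str
    max_mismatch: int = 0

    def __post_init__(self):
        if len(self.forward) < 10 or len(self.reverse) < 10:
            raise ValueError("primers must be at least 10 nt")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        object.__setattr__(self, "forward", self.forward.upper())
        object.__setattr__(self, "reverse", self.reverse.upper())

    @property
    def reverse_rc(self) -> str:
        return self.reverse.translate(_IUPAC_COMP)[::-1]


# EMP 18S V9 primers (Illumina_Euk_1391f / Illumina_EukBr); configuration
# defaults, replaceable by the user.
EMP_V9_PRIMERS = PrimerPair(
    forward="GTACACACCGCCCGTC", reverse="TGATCCTTCTGCAGGTTCACCTAC", max_mismatch=1
)


@dataclass(frozen=True)
class SynonymyGroup:
    """>=2 records whose amplicons are 100% identical over the compared span."""

    member_ids: frozenset[str]
    shared_sequence: str

    def __post_init__(self):
        if len(self.member_ids) < 2:
            raise ValueError("synonymy group needs >= 2 members")


@dataclass(frozen=True)
class DiagnosticKey:
    """Ordered diagnostic columns on an anchor amplicon plus the tuple->species map."""

    reference_anchor_id: str
    positions: tuple[int, ...]
    code_map: dict[tuple[str, ...], str]

    def __post_init__(self):
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("positions must be strictly increasing")
        for tup in self.code_map:
            if len(tup) != len(self.positions):
                raise ValueError("code_map tuple length mismatch")
        if len(set(self.code_map.values())) != len(self.code_map):
            raise ValueError("code_map species labels must be distinct")


class ReferenceDatabase:
    """Collection of :class:`TaxonRecord` keyed by unique id."""

    def __init__(self, records=(), metadata: dict | None = None):
        self.records: dict[str, TaxonRecord] = {}
        self.metadata = dict(metadata or {})
        for rec in records:
            self.add(rec)

    def add(self, rec: TaxonRecord) -> None:
        if rec.id in self.records:
            raise ValueError("duplicate record id %r" % rec.id)
        self.records[rec.id] = rec

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __contains__(self, rec_id):
        return rec_id in self.records

    def __getitem__(self, rec_id) -> TaxonRecord:
        return self.records[rec_id]

    def ids(self) -> list[str]:
        return sorted(self.records)

    def species_of(self, rec_id: str) -> str:
        return self.records[rec_id].species


def _site_matches(template: str, pos: int, primer: str, max_mismatch: int) -> bool:
    mism = 0
    for k, p in enumerate(primer):
        if template[pos + k] not in _IUPAC.get(p, p):
            mism += 1
            if mism > max_mismatch:
                return False
    return True


def _find_sites(template: str, primer: str, max_mismatch: int) -> list[int]:
    L = len(primer)
    return [
        i
        for i in range(len(template) - L + 1)
        if _site_matches(template, i, primer, max_mismatch)
    ]


def find_insert_span(
    sequence: str, primers: PrimerPair, search_revcomp: bool = True
) -> tuple[int, int, str]:
    """Locate the insert between the primer sites; 0-based half-open.

    Returns (start, end, strand) where strand is '+' or '-'.  Raises
    :class:`PrimerNotFoundError` / :class:`AmbiguousAmplificationError`.
    """
    for strand in "+-" if search_revcomp else "+":
        templ = sequence if strand == "+" else reverse_complement(sequence)
        f_sites = _find_sites(templ, primers.forward, primers.max_mismatch)
        spans = []
        for fpos in f_sites:
            ins_start = fpos + len(primers.forward)
            r_sites = [
                r
                for r in _find_sites(templ, primers.reverse_rc, primers.max_mismatch)
                if r >= ins_start
            ]
            spans.extend((ins_start, r) for r in r_sites)
        if len(spans) > 1:
            raise AmbiguousAmplificationError(
                "ambiguous-amplification: %d candidate inserts" % len(spans)
            )
        if spans:
            return spans[0][0], spans[0][1], strand
    raise PrimerNotFoundError("primer-not-found")


def extract_amplicon(record: TaxonRecord, primers: PrimerPair) -> TaxonRecord:
    """Extract the insert between (and excluding) the primer sites.

    If no primer site is found but the input already looks like an amplicon
    (length <= 200), the record is returned unchanged with ``is_amplicon``
    set.
    """
    try:
        start, end, strand = find_insert_span(record.sequence, primers)
    except PrimerNotFoundError:
        if len(record.sequence) <= 200:
            return replace(record, is_amplicon=True)
        raise
    templ = (
        record.sequence if strand == "+" else reverse_complement(record.sequence)
    )
    return replace(record, sequence=templ[start:end], is_amplicon=True)


def pairwise_identity(a: str, b: str) -> tuple[float, int]:
    """Fractional identity and aligned length under end-gap-free global alignment.

    Internal gaps count as mismatch columns; free end overhangs are excluded
    from the aligned length.  Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("empty-input")
    return semiglobal_identity(encode(a), encode(b))


def find_synonymy_groups(
    db: ReferenceDatabase, min_overlap: int = 64
) -> list[SynonymyGroup]:
    """Partition amplicons into maximal 100%-identity groups.

    Two amplicons are synonymous when their semi-global alignment is 100%
    identical over at least ``min_overlap`` aligned nucleotides (the study's
    BLASTN criterion).  Singleton groups are omitted; groups are ordered by
    their smallest member id.
    """
    ids = db.ids()
    enc = {i: encode(db[i].sequence) for i in ids}
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    # bucket exact duplicates first; align only cross-bucket representatives
    by_seq: dict[str, list[str]] = {}
    for i in ids:
        by_seq.setdefault(db[i].sequence, []).append(i)
    reps = sorted(by_seq, key=lambda s: by_seq[s][0])
    for sa, sb in itertools.combinations(reps, 2):
        ident, alen = semiglobal_identity(enc[by_seq[sa][0]], enc[by_seq[sb][0]])
        if ident == 1.0 and alen >= min_overlap:
            ra, rb = find(by_seq[sa][0]), find(by_seq[sb][0])
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    for members in by_seq.values():
        if len(db[members[0]].sequence) < min_overlap:
            continue
        for m in members[1:]:
            ra, rb = find(members[0]), find(m)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    out = []
    for root in sorted(groups):
        members = groups[root]
        if len(members) < 2:
            continue
        shared = min((db[m].sequence for m in members), key=len)
        out.append(SynonymyGroup(frozenset(members), shared))
    return out


def diagnostic_positions(
    amplicons: dict[str, str], anchor_id: str
) -> DiagnosticKey:
    """Find all variable columns among aligned amplicons and build the key.

    ``amplicons`` maps species label -> amplicon sequence; sequences must be
    equal length (pre-aligned, no-indel case).  Raises
    :class:`NotDiscriminableError` when two species share a character tuple
    (in particular when two inputs are identical).
    """
    if len(amplicons) < 2:
        raise ValueError("need >= 2 sequences")
    if anchor_id not in amplicons:
        raise KeyError("anchor %r not among inputs" % anchor_id)
    lengths = {len(s) for s in amplicons.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must be equal length (aligned)")
    L = lengths.pop()
    labels = sorted(amplicons)
    positions = tuple(
        j for j in range(L) if len({amplicons[s][j] for s in labels}) >= 2
    )
    code_map: dict[tuple[str, ...], str] = {}
    for s in labels:
        tup = tuple(amplicons[s][j] for j in positions)
        if tup in code_map:
            raise NotDiscriminableError(
                "not-discriminable: %r and %r share tuple %r" % (code_map[tup], s, tup)
            )
        code_map[tup] = s
    return DiagnosticKey(anchor_id, positions, code_map)


def merge_local_into_base(
    base: ReferenceDatabase, local: ReferenceDatabase, min_overlap: int = 64
) -> tuple[ReferenceDatabase, list[SynonymyGroup]]:
    """Union of base and local records (local wins id collisions) plus a
    synonymy report across the union."""
    merged = ReferenceDatabase(
        metadata={**base.metadata, **local.metadata, "merged_from": [len(base), len(local)]}
    )
    for rec in base:
        if rec.id not in local:
            merged.add(rec)
    for rec in local:
        merged.add(rec)
    report = find_synonymy_groups(merged, min_overlap=min_overlap)
    return merged, report


# ---------------------------------------------------------------------------
# FASTA I/O (SILVA-like dialect: ">id lineage;semicolon;delimited")

def read_fasta(path, is_amplicon: bool = False) -> ReferenceDatabase:
    from Bio import SeqIO

    db = ReferenceDatabase()
    for rec in SeqIO.parse(str(path), "fasta"):
        lineage = tuple(
            part.strip() for part in rec.description.split(None, 1)[-1].split(";")
        ) if " " in rec.description else (rec.id,)
        db.add(
            TaxonRecord(
                id=rec.id,
                lineage=lineage,
                sequence=str(rec.seq),
                is_amplicon=is_amplicon,
            )
        )
    return db


def write_fasta(db: ReferenceDatabase, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec_id in db.ids():
            rec = db[rec_id]
            fh.write(">%s %s\n" % (rec.id, ";".join(rec.lineage)))
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_synonymy_report(groups, path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tmember_id\tshared_length\n")
        for g_idx, group in enumerate(groups):
            for member in sorted(group.member_ids):
                fh.write("%d\t%s\t%d\n" % (g_idx, member, len(group.shared_sequence)))
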