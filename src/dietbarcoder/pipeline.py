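"""End-to-end glue: raw read pairs -> trimmed/merged inserts -> OTU table.

Mirrors the study pipeline: sliding-window quality trimming (Phred >= 20),
quality-arbitrated paired-end merging (or forward-only mode), primer
removal, closed-reference assignment at an identity threshold, singleton
removal.  Each step is the corresponding library function; this module only
sequences them and keeps the bookkeeping (per-sample counts of trimmed,
rejected and retained reads) that conservation tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .assign import Assignment, OtuTable, assign_reads, build_otu_table
from .reads import ReadPair, forward_only, merge_pair, quality_trim
from .refdb import (
    EMP_V9_PRIMERS,
    AmbiguousAmplificationError,
    PrimerNotFoundError,
    PrimerPair,
    ReferenceDatabase,
    find_insert_span,
    reverse_complement,
    _find_sites,
)

__all__ = ["ProcessStats", "process_pairs", "trim_primers", "run_sample", "run_mock_design"]


@dataclass
class ProcessStats:
    input: int = 0
    discarded_trim: int = 0
    rejected_merge: int = 0
    retained: int = 0
    extra: dict = field(default_factory=dict)


def trim_primers(sequence: str, primers: PrimerPair) -> str:
    """Cut a merged read down to the insert between the primer sites.

    Falls back to the untouched sequence when no site is found (end-gap-free
    identity makes untrimmed flanks harmless to assignment).
    """
    try:
        start, end, strand = find_insert_span(sequence, primers)
    except (PrimerNotFoundError, AmbiguousAmplificationError):
        return sequence
    if strand == "-":
        return reverse_complement(sequence)[start:end]
    return sequence[start:end]


def trim_forward_primer(sequence: str, primers: PrimerPair) -> str:
    """Single-direction primer trim: drop the leading forward primer and any
    (possibly partial, read-through) reverse-primer site at the 3' end."""
    sites = _find_sites(sequence, primers.forward, primers.max_mismatch)
    out = sequence[sites[0] + len(primers.forward):] if sites else sequence
    rsites = _find_sites(out, primers.reverse_rc, primers.max_mismatch)
    if rsites:
        return out[: rsites[0]]
    # read-through leaves only a prefix of the reverse primer before the read
    # ends; strip the longest terminal partial match of >= 6 nt
    rc = primers.reverse_rc
    for s in range(max(0, len(out) - len(rc)), len(out) - 5):
        frag = out[s:]
        mism = sum(a != b for a, b in zip(frag, rc))
        if mism <= max(primers.max_mismatch, len(frag) // 12):
            return out[:s]
    return out


def process_pairs(
    pairs: list[ReadPair],
    primers: PrimerPair = EMP_V9_PRIMERS,
    mode: str = "paired",
    q_threshold: int = 20,
    p_cutoff: float = 0.01,
    max_mismatch: int = 1,
    min_overlap: int = 10,
) -> tuple[list[tuple[str, str]], ProcessStats]:
    """Trim, merge (or take forward-only) and primer-trim read pairs.

    Returns ([(read_id, insert_sequence)], stats).  Read ids keep the pair
    stem (mate suffix stripped) so they join against simulator truth tables.
    """
    if mode not in ("paired", "forward-only"):
        raise ValueError("mode must be 'paired' or 'forward-only'")
    stats = ProcessStats(input=len(pairs))
    out: list[tuple[str, str]] = []
    for pair in pairs:
        stem = pair.forward.id.rsplit("/", 1)[0]
        fwd = quality_trim(pair.forward, q_threshold=q_threshold)
        if mode == "forward-only":
            if fwd is None:
                stats.discarded_trim += 1
                continue
            out.append((stem, trim_forward_primer(fwd.bases, primers)))
            stats.retained += 1
            continue
        rev = quality_trim(pair.reverse, q_threshold=q_threshold)
        if fwd is None or rev is None:
            stats.discarded_trim += 1
            continue
        merged = merge_pair(
            ReadPair(fwd, rev, tag=pair.tag),
            p_cutoff=p_cutoff,
            max_mismatch=max_mismatch,
            min_overlap=min_overlap,
        )
        if merged is None:
            stats.rejected_merge += 1
            continue
        out.append((stem, trim_primers(merged.bases, primers)))
        stats.retained += 1
    return out, stats


def run_sample(
    pairs: list[ReadPair],
    db: ReferenceDatabase,
    threshold: float = 0.99,
    primers: PrimerPair = EMP_V9_PRIMERS,
    mode: str = "paired",
    **process_kw,
) -> tuple[list[Assignment], ProcessStats]:
    inserts, stats = process_pairs(pairs, primers=primers, mode=mode, **process_kw)
    return assign_reads(inserts, db, threshold), stats


def run_mock_design(
    design,
    db: ReferenceDatabase,
    copy_numbers: dict[str, float],
    config,
    threshold: float = 0.99,
    primers: PrimerPair = EMP_V9_PRIMERS,
    mode: str = "paired",
) -> tuple[OtuTable, pd.DataFrame, dict[str, ProcessStats]]:
    """Simulate every sample of a mock design and assemble the OTU table."""
    from .simulate import communities_from_design, simulate_amplicon_reads

    assignments: dict[str, list[Assignment]] = {}
    stats: dict[str, ProcessStats] = {}
    truths = []
    for community in communities_from_design(design):
        pairs, truth = simulate_amplicon_reads(community, db, copy_numbers, config)
        truths.append(truth)
        assignments[community.sample_id], stats[community.sample_id] = run_sample(
            pairs, db, threshold=threshold, primers=primers, mode=mode
        )
    lineages = {rec.id: ";".join(rec.lineage) for rec in db}
    table = build_otu_table(
        assignments,
        lineages=lineages,
        provenance={"method": "closed", "threshold": threshold, "mode": mode},
    )
    return table, pd.concat(truths, ignore_index=True), stats


def design_otu_representatives(design, db: ReferenceDatabase) -> dict[str, str]:
    """Map each design OTU label to the record id its reads assign to.

    Members of a synonymy group share one sequence, so closed-reference
    assignment sends all their reads to the lexicographically smallest
    member id; that representative stands for the collapsed OTU.
    """
    reps = {}
    for otu in design.otus:
        member_ids = sorted(
            sp.replace(" ", "_") for sp in design.species if design.collapse[sp] == otu
        )
        reps[otu] = member_ids[0]
    return reps
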