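"""Character-based (diagnostic-SNP) species assignment and discrepancy report.

Closely related species whose barcodes differ at only 1-3 positions (the
clupeid fishes herring / sprat / sardine / anchovy in the motivating study)
can be discriminated by reading off just those diagnostic nucleotides.  Each
read is aligned to an anchor amplicon, the bases homologous to the key's
diagnostic columns are extracted, and the resulting tuple is looked up in
the key:

* tuple in the code map          -> that species,
* tuple absent (or containing N) -> "other-combination",
* a diagnostic column not covered by the read -> "too-short".

The discrepancy report contrasts these character-based counts with the
clustering-based (closed-reference) counts per species, as a percentage of
the clustering count.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._align import GAP_CODE, UNCOVERED, encode, map_to_anchor
from .refdb import DiagnosticKey

__all__ = [
    "CharacterAssignment",
    "classify_read",
    "classify_reads",
    "discrepancy",
    "OTHER_COMBINATION",
    "TOO_SHORT",
]

OTHER_COMBINATION = "other-combination"
TOO_SHORT = "too-short"


@dataclass(frozen=True)
class CharacterAssignment:
    read_id: str
    category: str  # species label | OTHER_COMBINATION | TOO_SHORT
    observed_tuple: tuple[str, ...]


def classify_read(
    read_id: str,
    sequence: str,
    key: DiagnosticKey,
    anchor_sequence: str,
    _cache: dict | None = None,
) -> CharacterAssignment:
    """Align a read to the anchor and classify it by its diagnostic tuple."""
    if _cache is not None and sequence in _cache:
        category, tup = _cache[sequence]
        return CharacterAssignment(read_id, category, tup)
    anchor = encode(anchor_sequence)
    mapping = map_to_anchor(anchor, encode(sequence))
    observed = []
    too_short = False
    for pos in key.positions:
        m = mapping[pos]
        if m == UNCOVERED:
            too_short = True
            observed.append("")
        elif m == GAP_CODE:
            observed.append("-")
        else:
            observed.append(sequence[m])
    tup = tuple(observed)
    if too_short:
        category = TOO_SHORT
    else:
        category = key.code_map.get(tup, OTHER_COMBINATION)
    if _cache is not None:
        _cache[sequence] = (category, tup)
    return CharacterAssignment(read_id, category, tup)


def classify_reads(reads, key: DiagnosticKey, anchor_sequence: str):
    """Classify (read_id, sequence) pairs, memoised over identical sequences."""
    cache: dict = {}
    return [
        classify_read(rid, seq, key, anchor_sequence, _cache=cache)
        for rid, seq in reads
    ]


def discrepancy(
    clustering_counts: dict[str, int],
    character_counts: dict[str, int],
    other_count: int = 0,
    too_short_count: int = 0,
) -> pd.DataFrame:
    """Per-species discrepancy between clustering- and character-based counts.

    discrepancy_pct = (clustering - character) / clustering * 100, one
    decimal.  The totals row uses summed species counts; the
    other-combination and too-short rows are expressed as a percent of total
    clustering-assigned reads.
    """
    extra = set(character_counts) - set(clustering_counts)
    if extra:
        raise KeyError("character labels missing from clustering counts: %s" % sorted(extra))
    rows = []
    for label in clustering_counts:
        clust = int(clustering_counts[label])
        char = int(character_counts.get(label, 0))
        if clust == 0:
            if char > 0:
                raise ZeroDivisionError("undefined-discrepancy for %r" % label)
            pct = 0.0
        else:
            pct = round((clust - char) / clust * 100, 1)
        rows.append((label, clust, char, pct))
    total_clust = sum(int(v) for v in clustering_counts.values())
    total_char = sum(int(character_counts.get(k, 0)) for k in clustering_counts)
    total_pct = (
        round((total_clust - total_char) / total_clust * 100, 1) if total_clust else 0.0
    )
    rows.append(("Total assigned", total_clust, total_char, total_pct))
    for label, n in ((OTHER_COMBINATION, other_count), (TOO_SHORT, too_short_count)):
        pct = round(n / total_clust * 100, 1) if total_clust else 0.0
        rows.append((label, 0, int(n), pct))
    return pd.DataFrame(
        rows, columns=["label", "clustering_count", "character_count", "discrepancy_pct"]
    )
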