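"""Closed- and open-reference taxonomic assignment and OTU tables.

Closed-reference assignment matches each read against every amplicon in the
reference database and keeps the best-identity hit when it reaches the
identity threshold (ties broken by lexicographic record id); everything else
is "Unassigned".  Open-reference assignment additionally clusters the
unassigned reads de novo with greedy abundance-ordered centroid clustering.

The candidate search is exhaustive over the database: equivalence is defined
against this exhaustive search, not against any particular clustering
heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._align import encode, semiglobal_identity
from .refdb import ReferenceDatabase

__all__ = [
    "Assignment",
    "OtuTable",
    "UNASSIGNED",
    "assign_closed",
    "assign_reads",
    "cluster_open",
    "build_otu_table",
    "remove_singletons",
    "remove_predator",
]

UNASSIGNED = "Unassigned"


@dataclass(frozen=True)
class Assignment:
    read_id: str
    otu_id: str
    identity: float
    method: str  # "closed" | "open"
    threshold: float


class OtuTable:
    """Samples x OTUs integer count matrix with lineage and provenance."""

    def __init__(self, samples, otus, counts, lineages=None, provenance=None):
        self.samples = list(samples)
        self.otus = list(otus)
        self.counts = np.asarray(counts, dtype=np.int64)
        if self.counts.shape != (len(self.samples), len(self.otus)):
            raise ValueError("counts shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.lineages = dict(lineages or {})
        self.provenance = dict(provenance or {})

    def copy(self, counts=None, otus=None):
        return OtuTable(
            self.samples,
            self.otus if otus is None else otus,
            self.counts.copy() if counts is None else counts,
            self.lineages,
            self.provenance,
        )

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def otu_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        totals = self.sample_totals().astype(float)
        totals[totals == 0] = 1.0
        return self.counts / totals[:, None]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.samples, columns=self.otus)

    def drop_otus(self, otu_ids) -> "OtuTable":
        drop = set(otu_ids)
        keep = [j for j, o in enumerate(self.otus) if o not in drop]
        return self.copy(
            counts=self.counts[:, keep], otus=[self.otus[j] for j in keep]
        )

    # classic tab-separated OTU-table dialect: rows = OTUs, columns = samples
    def write_tsv(self, path) -> None:
        df = self.to_dataframe().T
        df.insert(0, "lineage", [self.lineages.get(o, "Unknown") for o in self.otus])
        df.index.name = "otu_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "OtuTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        lineages = df.pop("lineage").to_dict()
        return cls(
            samples=list(df.columns),
            otus=list(df.index),
            counts=df.T.to_numpy(dtype=np.int64),
            lineages=lineages,
        )

    def write_sparse(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\totu_id\tcount\n")
            rows, cols = np.nonzero(self.counts)
            for i, j in zip(rows, cols):
                fh.write(
                    "%s\t%s\t%d\n" % (self.samples[i], self.otus[j], self.counts[i, j])
                )


def assign_closed(
    read_id: str,
    sequence: str,
    db: ReferenceDatabase,
    threshold: float,
    _cache: dict | None = None,
) -> Assignment:
    """Best-identity closed-reference assignment of one read."""
    if len(db) == 0:
        raise ValueError("empty reference database")
    if _cache is not None and sequence in _cache:
        otu, ident = _cache[sequence]
        return Assignment(read_id, otu, ident, "closed", threshold)
    enc = encode(sequence)
    best_id, best_ident = UNASSIGNED, 0.0
    for rec_id in db.ids():
        ident, _ = semiglobal_identity(enc, encode(db[rec_id].sequence))
        if ident > best_ident:
            best_ident, best_id = ident, rec_id
            if ident == 1.0:
                break
    if best_ident < threshold:
        best_id = UNASSIGNED
    if _cache is not None:
        _cache[sequence] = (best_id, best_ident)
    return Assignment(read_id, best_id, best_ident, "closed", threshold)


def assign_reads(reads, db: ReferenceDatabase, threshold: float) -> list[Assignment]:
    """Closed-reference assignment of (read_id, sequence) pairs with
    memoisation over identical sequences."""
    cache: dict = {}
    return [assign_closed(rid, seq, db, threshold, _cache=cache) for rid, seq in reads]


def cluster_open(
    unassigned, threshold: float
) -> tuple[dict[str, str], list[Assignment]]:
    """Greedy abundance-ordered de-novo clustering of unassigned reads.

    ``unassigned`` is a list of (read_id, sequence).  Reads are dereplicated,
    ordered by decreasing duplicate count (ties by smallest read id), and
    each joins the first centroid with identity >= threshold, else seeds a
    new centroid "denovo-<n>".  Returns (centroid sequences by cluster id,
    assignments).
    """
    groups: dict[str, list[str]] = {}
    for rid, seq in unassigned:
        groups.setdefault(seq, []).append(rid)
    order = sorted(groups, key=lambda s: (-len(groups[s]), min(groups[s])))
    centroids: list[tuple[str, str, np.ndarray]] = []  # (cluster_id, seq, enc)
    assignments = []
    for seq in order:
        enc = encode(seq)
        hit, hit_ident = None, 0.0
        for cid, cseq, cenc in centroids:
            ident, _ = semiglobal_identity(enc, cenc)
            if ident >= threshold:
                hit, hit_ident = cid, ident
                break
        if hit is None:
            hit = "denovo-%d" % len(centroids)
            hit_ident = 1.0
            centroids.append((hit, seq, enc))
        for rid in sorted(groups[seq]):
            assignments.append(Assignment(rid, hit, hit_ident, "open", threshold))
    return {cid: cseq for cid, cseq, _ in centroids}, assignments


def build_otu_table(
    assignments_per_sample: dict[str, list[Assignment]],
    lineages: dict[str, str] | None = None,
    provenance: dict | None = None,
) -> OtuTable:
    """Counts[s][o] = reads of sample s assigned to OTU o (incl. Unassigned)."""
    samples = sorted(assignments_per_sample)
    otu_set = set()
    for assigns in assignments_per_sample.values():
        otu_set.update(a.otu_id for a in assigns)
    otu_set.discard(UNASSIGNED)
    otus = sorted(otu_set) + [UNASSIGNED]
    index = {o: j for j, o in enumerate(otus)}
    counts = np.zeros((len(samples), len(otus)), dtype=np.int64)
    for i, sample in enumerate(samples):
        for a in assignments_per_sample[sample]:
            counts[i, index[a.otu_id]] += 1
    lineages = dict(lineages or {})
    lineages.setdefault(UNASSIGNED, "Unassigned")
    return OtuTable(samples, otus, counts, lineages, provenance)


def remove_singletons(table: OtuTable) -> OtuTable:
    """Drop OTUs whose total count across all samples is exactly 1."""
    totals = table.otu_totals()
    keep = totals != 1
    return table.copy(
        counts=table.counts[:, keep],
        otus=[o for o, k in zip(table.otus, keep) if k],
    )


def remove_predator(
    table: OtuTable, predator_otu_ids
) -> tuple[OtuTable, dict[str, float]]:
    """Drop predator OTUs; report per-sample removed fraction of assigned reads."""
    predator_otu_ids = list(predator_otu_ids)
    unknown = set(predator_otu_ids) - set(table.otus)
    if unknown:
        raise KeyError("unknown-otu: %s" % sorted(unknown))
    assigned_cols = [j for j, o in enumerate(table.otus) if o != UNASSIGNED]
    pred_cols = [j for j, o in enumerate(table.otus) if o in set(predator_otu_ids)]
    assigned_tot = table.counts[:, assigned_cols].sum(axis=1).astype(float)
    pred_tot = table.counts[:, pred_cols].sum(axis=1).astype(float)
    frac = {
        s: (pred_tot[i] / assigned_tot[i] if assigned_tot[i] > 0 else 0.0)
        for i, s in enumerate(table.samples)
    }
    return table.drop_otus(predator_otu_ids), frac
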