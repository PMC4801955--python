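"""Synthetic data with the statistical structure real 18S V9 data carries.

Generators for (i) reference sets containing deliberate synonymy groups
(several species sharing one amplicon) and near-identical species differing
at a handful of diagnostic positions, (ii) per-species rDNA copy numbers
spanning orders of magnitude, (iii) the printed mock-community design, and
(iv) paired 2x150 bp reads with a cycle-dependent quality profile and
quality-derived substitution errors.

Every generator is deterministic under a fixed seed; read counts are drawn
multinomially with template weights proportional to individual count times
rDNA copy number — the mechanism behind the semi-quantitative nature of
multicopy metabarcoding.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import MockDesign
from .reads import FastqRead, ReadPair
from .refdb import (
    EMP_V9_PRIMERS,
    DiagnosticKey,
    PrimerPair,
    ReferenceDatabase,
    TaxonRecord,
    reverse_complement,
)

__all__ = [
    "SimConfig",
    "SimCommunity",
    "generate_reference_set",
    "generate_reference_for_design",
    "clupeid_analogue_reference",
    "simulate_copy_numbers",
    "mock_from_table1",
    "simulate_amplicon_reads",
    "spike_predator",
    "simulate_diet_otu_table",
]

# fixed pseudo-adapter used to pad templates shorter than the read length
_ADAPTER_PAD = "CTGTCTCTTATACACATCTCCGAGCCCACGAGACATCTCGTATGCCGTCTTCTGCTTG"


@dataclass
class SimConfig:
    """Sequencing-simulation knobs.

    ``error_rate`` caps the quality-derived substitution probability
    p = 10^(-Q/10); zero disables errors entirely.  Qualities follow a
    linear per-cycle profile from ``q_start`` to ``q_end`` with per-base
    Gaussian jitter, which is what makes quality-arbitrated merging and the
    error-rate cap meaningful.
    """

    seed: int = 1
    read_length: int = 150
    error_rate: float = 0.0
    reads_per_sample: int = 20000
    q_start: float = 38.0
    q_end: float = 25.0
    q_jitter_sd: float = 4.0
    tags: dict[str, str] = field(default_factory=dict)  # sample -> 12-nt tag

    def __post_init__(self):
        if not 0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")


@dataclass
class SimCommunity:
    """Known species composition of one simulated sample."""

    sample_id: str
    counts: dict[str, int]
    lengths_mm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be >= 0")


def _rand_seq(rng, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def generate_reference_set(
    n_species: int,
    synonymy_spec: list[int] = (),
    near_identical_spec: list[tuple[int, int]] = (),
    length_range: tuple[int, int] = (120, 134),
    seed: int = 1,
    label_prefix: str = "SimSp",
):
    """Random reference database with planted synonymy and near-identity.

    ``synonymy_spec`` lists group sizes whose members share one amplicon;
    ``near_identical_spec`` lists (group size, n diagnostic positions)
    groups whose members differ at exactly the planted columns.  Remaining
    species get independent random amplicons.  Returns (db, ground_truth)
    where ground_truth records the planted groups and columns.
    """
    rng = np.random.default_rng(seed)
    planted = sum(synonymy_spec) + sum(g for g, _ in near_identical_spec)
    if planted > n_species:
        raise ValueError("spec-infeasible: planted group sizes exceed n_species")
    labels = ["%s%03d" % (label_prefix, i + 1) for i in range(n_species)]
    db = ReferenceDatabase(metadata={"seed": int(seed)})
    truth: dict = {"synonymy_groups": [], "near_identical_groups": []}
    cursor = 0

    def add(label, sequence):
        db.add(
            TaxonRecord(
                id=label.replace(" ", "_"),
                lineage=("Eukaryota", "SimulatedPhylum", label),
                sequence=sequence,
                is_amplicon=True,
            )
        )

    for size in synonymy_spec:
        seq = _rand_seq(rng, int(rng.integers(length_range[0], length_range[1] + 1)))
        members = labels[cursor : cursor + size]
        cursor += size
        for lab in members:
            add(lab, seq)
        truth["synonymy_groups"].append({"members": members, "sequence": seq})
    for size, n_pos in near_identical_spec:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        base = _rand_seq(rng, length)
        positions = np.sort(rng.choice(length, size=n_pos, replace=False))
        members = labels[cursor : cursor + size]
        cursor += size
        tuples = _distinct_tuples(rng, size, n_pos, base, positions)
        for lab, tup in zip(members, tuples):
            seq = list(base)
            for p, ch in zip(positions, tup):
                seq[p] = ch
            add(lab, "".join(seq))
        truth["near_identical_groups"].append(
            {
                "members": members,
                "positions": [int(p) for p in positions],
                "tuples": [tuple(t) for t in tuples],
            }
        )
    for lab in labels[cursor:]:
        add(lab, _rand_seq(rng, int(rng.integers(length_range[0], length_range[1] + 1))))
    return db, truth


def _distinct_tuples(rng, size, n_pos, base, positions):
    """Distinct nucleotide tuples, every planted column showing >= 2 states."""
    tuples = [tuple(base[p] for p in positions)]
    while len(tuples) < size:
        cand = tuple("ACGT"[i] for i in rng.integers(0, 4, size=n_pos))
        if cand not in tuples:
            tuples.append(cand)
    for k in range(n_pos):
        if len({t[k] for t in tuples}) < 2:
            last = list(tuples[-1])
            choices = [c for c in "ACGT" if c != last[k]]
            last[k] = choices[int(rng.integers(len(choices)))]
            if tuple(last) not in tuples[:-1]:
                tuples[-1] = tuple(last)
    return tuples


_CLUPEIDS = (
    "Clupea harengus",
    "Sprattus sprattus",
    "Sardina pilchardus",
    "Engraulis encrasicolus",
)
_CLUPEID_TUPLES = (("C", "G", "C"), ("C", "A", "T"), ("T", "G", "C"), ("C", "G", "T"))


def clupeid_analogue_reference(
    seed: int = 1, length: int = 134, positions=(31, 77, 102)
) -> tuple[ReferenceDatabase, DiagnosticKey]:
    """Four clupeid-analogue amplicons differing only at three diagnostic
    columns, with the herring/sprat/sardine/anchovy character tuples."""
    rng = np.random.default_rng(seed)
    base = _rand_seq(rng, length)
    db = ReferenceDatabase(metadata={"seed": int(seed)})
    code_map = {}
    for species, tup in zip(_CLUPEIDS, _CLUPEID_TUPLES):
        seq = list(base)
        for p, ch in zip(positions, tup):
            seq[p] = ch
        db.add(
            TaxonRecord(
                id=species.replace(" ", "_"),
                lineage=("Eukaryota", "Chordata", "Clupeiformes", species),
                sequence="".join(seq),
                is_amplicon=True,
            )
        )
        code_map[tup] = species
    anchor_id = _CLUPEIDS[0].replace(" ", "_")
    key = DiagnosticKey(anchor_id, tuple(int(p) for p in positions), code_map)
    return db, key


def generate_reference_for_design(
    design: MockDesign, seed: int = 1, length_range: tuple[int, int] = (120, 134)
) -> ReferenceDatabase:
    """Amplicon database for a mock design: species collapsed to the same
    OTU share one sequence (planted synonymy), all other amplicons are
    independent random sequences."""
    rng = np.random.default_rng(seed)
    db = ReferenceDatabase(metadata={"seed": int(seed)})
    otu_seq: dict[str, str] = {}
    for otu in design.otus:
        otu_seq[otu] = _rand_seq(
            rng, int(rng.integers(length_range[0], length_range[1] + 1))
        )
    for species in design.species:
        db.add(
            TaxonRecord(
                id=species.replace(" ", "_"),
                lineage=("Eukaryota", "Zooplankton", species),
                sequence=otu_seq[design.collapse[species]],
                is_amplicon=True,
            )
        )
    return db


def simulate_copy_numbers(
    species, orders_of_magnitude: float = 4, seed: int = 1, constant: bool = False
) -> dict[str, float]:
    """Per-species rDNA copy numbers, log-uniform on [1, 10^orders].

    ``constant`` (or zero orders) gives the all-ones null used to isolate
    multinomial sampling noise from copy-number bias.
    """
    species = list(species)
    if constant or orders_of_magnitude == 0:
        return {sp: 1.0 for sp in species}
    rng = np.random.default_rng(seed)
    draws = 10.0 ** rng.uniform(0.0, orders_of_magnitude, size=len(species))
    return {sp: float(c) for sp, c in zip(species, draws)}


def mock_from_table1() -> MockDesign:
    """The printed 13-species x 4-sample mock design (packaged fixture)."""
    path = importlib.resources.files("dietbarcoder.data") / "table1_mock_design.tsv"
    df = pd.read_csv(str(path), sep="\t")
    samples = ["MOCK-A", "MOCK-B", "MOCK-C", "MOCK-D"]
    return MockDesign(
        species=list(df["species"]),
        samples=samples,
        counts=df[samples].to_numpy(dtype=np.int64),
        mean_length_mm=dict(zip(df["species"], df["tl_mm"])),
        sd_length_mm=dict(zip(df["species"], df["sd_mm"])),
        collapse=dict(zip(df["species"], df["otu"])),
    )


def communities_from_design(design: MockDesign) -> list[SimCommunity]:
    return [
        SimCommunity(
            sample_id=sample,
            counts={
                sp: int(design.counts[i, j]) for i, sp in enumerate(design.species)
            },
            lengths_mm=dict(design.mean_length_mm),
        )
        for j, sample in enumerate(design.samples)
    ]


def _template(amplicon: str, primers: PrimerPair, read_length: int) -> str:
    t = primers.forward + amplicon + reverse_complement(primers.reverse)
    if len(t) < read_length:
        pad = (_ADAPTER_PAD * (read_length // len(_ADAPTER_PAD) + 1))[: read_length - len(t)]
        t = t + pad
    return t


def simulate_amplicon_reads(
    community: SimCommunity,
    refs: ReferenceDatabase,
    copy_numbers: dict[str, float],
    config: SimConfig,
    primers: PrimerPair = EMP_V9_PRIMERS,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Paired 2 x read_length reads for one sample plus the truth table.

    Template weights are count x copy number; reads are drawn multinomially.
    The forward read is the first ``read_length`` nt of
    primerF + amplicon + revcomp(primerR) (adapter-padded if shorter); the
    reverse read is the last ``read_length`` nt reverse-complemented.
    Substitution errors occur per base with probability
    min(10^(-Q/10), error_rate).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _stable_hash(community.sample_id)])
    )
    species = [sp for sp in sorted(community.counts) if community.counts[sp] > 0]
    missing = [sp for sp in species if sp.replace(" ", "_") not in refs]
    if missing:
        raise KeyError("community species missing from refs: %s" % missing)
    weights = np.array(
        [community.counts[sp] * copy_numbers.get(sp, 1.0) for sp in species],
        dtype=float,
    )
    weights /= weights.sum()
    n = config.reads_per_sample
    per_species = rng.multinomial(n, weights)
    rl = config.read_length

    templates = {
        sp: _template(refs[sp.replace(" ", "_")].sequence, primers, rl)
        for sp in species
    }
    profile = np.linspace(config.q_start, config.q_end, rl)

    pairs: list[ReadPair] = []
    truth_rows = []
    tag = config.tags.get(community.sample_id)
    read_idx = 0
    for sp, k in zip(species, per_species):
        if k == 0:
            continue
        t = templates[sp]
        fwd_t = np.frombuffer(t[:rl].encode(), dtype=np.uint8).copy()
        rev_t = np.frombuffer(
            reverse_complement(t[-rl:]).encode(), dtype=np.uint8
        ).copy()
        fwd_bases = np.tile(fwd_t, (k, 1))
        rev_bases = np.tile(rev_t, (k, 1))
        fwd_quals = _draw_quals(rng, profile, k, config)
        rev_quals = _draw_quals(rng, profile, k, config)
        _inject_errors(rng, fwd_bases, fwd_quals, config.error_rate)
        _inject_errors(rng, rev_bases, rev_quals, config.error_rate)
        for i in range(k):
            rid = "%s_r%06d" % (community.sample_id, read_idx)
            read_idx += 1
            pairs.append(
                ReadPair(
                    forward=FastqRead(
                        rid + "/1",
                        fwd_bases[i].tobytes().decode(),
                        tuple(int(q) for q in fwd_quals[i]),
                    ),
                    reverse=FastqRead(
                        rid + "/2",
                        rev_bases[i].tobytes().decode(),
                        tuple(int(q) for q in rev_quals[i]),
                    ),
                    tag=tag,
                )
            )
            truth_rows.append((rid, community.sample_id, sp))
    # deterministic shuffle so samples are not species-blocked
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]
    truth = pd.DataFrame(truth_rows, columns=["read_id", "sample", "species"]).iloc[
        order
    ].reset_index(drop=True)
    return pairs, truth


def _stable_hash(text: str) -> int:
    h = 2166136261
    for ch in text.encode():
        h = ((h ^ ch) * 16777619) % (2**31)
    return h


def _draw_quals(rng, profile, k, config) -> np.ndarray:
    q = profile[None, :] + rng.normal(0.0, config.q_jitter_sd, size=(k, profile.size))
    return np.clip(np.rint(q), 2, 40).astype(np.int16)


_SUB = {ord("A"): b"CGT", ord("C"): b"AGT", ord("G"): b"ACT", ord("T"): b"ACG"}


def _inject_errors(rng, bases, quals, error_rate) -> None:
    if error_rate <= 0:
        return
    p = np.minimum(10.0 ** (-quals / 10.0), error_rate)
    hit = rng.random(bases.shape) < p
    idx = np.nonzero(hit)
    for i, j in zip(*idx):
        subs = _SUB.get(int(bases[i, j]), b"ACG")
        bases[i, j] = subs[int(rng.integers(3))]


def spike_predator(
    pairs: list[ReadPair],
    truth: pd.DataFrame,
    predator_species: str,
    refs: ReferenceDatabase,
    fraction: float,
    config: SimConfig,
    primers: PrimerPair = EMP_V9_PRIMERS,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Replace a Binomial(n, fraction) subset of reads with predator reads."""
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    n = len(pairs)
    if fraction == 0 or n == 0:
        return list(pairs), truth.copy()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_777_777]))
    k = int(rng.binomial(n, fraction))
    if k == 0:
        return list(pairs), truth.copy()
    sample_id = truth["sample"].iloc[0]
    pred_cfg = SimConfig(
        seed=config.seed + 104729,
        read_length=config.read_length,
        error_rate=config.error_rate,
        reads_per_sample=k,
        q_start=config.q_start,
        q_end=config.q_end,
        q_jitter_sd=config.q_jitter_sd,
    )
    pred_pairs, _ = simulate_amplicon_reads(
        SimCommunity(sample_id, {predator_species: 1}),
        refs,
        {predator_species: 1.0},
        pred_cfg,
        primers=primers,
    )
    replace_at = rng.choice(n, size=k, replace=False)
    out = list(pairs)
    new_truth = truth.copy()
    for slot, pred in zip(replace_at, pred_pairs):
        old_id = truth["read_id"].iloc[slot]
        out[slot] = ReadPair(
            forward=FastqRead(old_id + "/1", pred.forward.bases, pred.forward.quals),
            reverse=FastqRead(old_id + "/2", pred.reverse.bases, pred.reverse.quals),
            tag=pairs[slot].tag,
        )
        new_truth.iloc[slot, new_truth.columns.get_loc("species")] = predator_species
    return out, new_truth


def simulate_diet_otu_table(
    n_per_group=(20, 20),
    n_otus: int = 30,
    concentration: float = 5.0,
    separation: float = 3.0,
    reads_per_sample: int = 5000,
    seed: int = 1,
):
    """Two predator groups with distinct Dirichlet-mean diets.

    Group mean compositions are two permuted geometric profiles
    (``separation`` controls how different they are); per-sample
    compositions are Dirichlet draws around the group mean and read counts
    are multinomial.  Returns (OtuTable, group_labels).
    """
    from .assign import OtuTable

    rng = np.random.default_rng(seed)
    ranks = np.arange(n_otus, dtype=float)
    mean_a = np.exp(-ranks / separation)
    mean_a /= mean_a.sum()
    mean_b = mean_a[rng.permutation(n_otus)]
    samples, labels, counts = [], {}, []
    for g, (n_g, mean) in enumerate(zip(n_per_group, (mean_a, mean_b))):
        for i in range(n_g):
            sid = "fish%s%02d" % ("AB"[g], i)
            p = rng.dirichlet(mean * concentration * n_otus)
            counts.append(rng.multinomial(reads_per_sample, p))
            samples.append(sid)
            labels[sid] = "group%s" % "AB"[g]
    otus = ["prey%03d" % j for j in range(n_otus)]
    return OtuTable(samples, otus, np.array(counts)), labels
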