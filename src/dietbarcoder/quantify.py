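"""Quantitative evaluation of metabarcoding against known compositions.

Mock communities of counted, measured individuals give ground-truth
profiles; read-based profiles are compared to them two ways:

* "within taxon": one taxon's relative abundance tracked across several
  sample compositions (Pearson r across samples),
* "among taxa": all taxa's relative abundances within a single sample
  (Pearson r across OTUs).

Also here: count-to-biomass conversion via length-weight power laws,
per-OTU Kruskal-Wallis tests of technical-replicate consistency, and the
analytic (hypergeometric) rarefaction expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "MockDesign",
    "CommunityProfile",
    "BiomassModel",
    "expected_profiles",
    "counts_to_biomass",
    "within_taxon_correlation",
    "among_taxa_correlation",
    "replicate_consistency",
    "rarefaction",
]


@dataclass
class MockDesign:
    """Species x sample individual counts plus lengths and synonymy collapse."""

    species: list[str]
    samples: list[str]
    counts: np.ndarray  # species x samples
    mean_length_mm: dict[str, float]
    sd_length_mm: dict[str, float]
    collapse: dict[str, str]  # species -> OTU label

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.species), len(self.samples)):
            raise ValueError("counts shape mismatch")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")
        for sp in self.species:
            self.collapse.setdefault(sp, sp)

    @property
    def otus(self) -> list[str]:
        seen = []
        for sp in self.species:
            otu = self.collapse[sp]
            if otu not in seen:
                seen.append(otu)
        return seen

    def collapsed_counts(self) -> pd.DataFrame:
        """OTU x sample counts after synonymy collapse (total preserving)."""
        df = pd.DataFrame(self.counts, index=self.species, columns=self.samples)
        grouped = df.groupby(self.collapse, sort=False).sum()
        return grouped.loc[self.otus]

    def total_individuals(self) -> int:
        return int(self.counts.sum())


@dataclass
class CommunityProfile:
    """Relative-abundance profile of one sample in one unit."""

    sample_id: str
    unit: str  # "counts" | "biomass" | "reads"
    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.fractions.values())
        if self.fractions and abs(total - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1 (got %.12f)" % total)
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("fractions must be >= 0")

    def vector(self, otus) -> np.ndarray:
        return np.array([self.fractions.get(o, 0.0) for o in otus])


@dataclass
class BiomassModel:
    """Dry weight = a * L^b (mg, L in mm) per taxon, times a carbon fraction."""

    coefficients: dict[str, tuple[float, float]]
    carbon_fraction: float = 0.40

    def __post_init__(self):
        if not 0 < self.carbon_fraction <= 1:
            raise ValueError("carbon_fraction must be in (0, 1]")
        for taxon, (a, _b) in self.coefficients.items():
            if a <= 0:
                raise ValueError("coefficient a must be > 0 for %r" % taxon)

    @classmethod
    def from_yaml(cls, path) -> "BiomassModel":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        coeffs = {t: (float(v["a"]), float(v["b"])) for t, v in doc["taxa"].items()}
        return cls(coeffs, carbon_fraction=float(doc.get("carbon_fraction", 0.40)))


def expected_profiles(design: MockDesign) -> dict[str, CommunityProfile]:
    """Ground-truth count profiles per sample, synonymy collapsed."""
    collapsed = design.collapsed_counts()
    profiles = {}
    for sample in design.samples:
        col = collapsed[sample]
        total = col.sum()
        if total == 0:
            raise ValueError("empty-sample: %r" % sample)
        profiles[sample] = CommunityProfile(
            sample, "counts", {o: col[o] / total for o in collapsed.index}
        )
    return profiles


def counts_to_biomass(
    counts: dict[str, float], lengths: dict[str, float], model: BiomassModel
) -> tuple[dict[str, float], CommunityProfile]:
    """Per-taxon biomass (carbon units) and the renormalized biomass profile."""
    missing = set(counts) - set(model.coefficients)
    if missing:
        raise KeyError("no-model-for-taxon: %s" % sorted(missing))
    biomass = {}
    for taxon, n in counts.items():
        a, b = model.coefficients[taxon]
        biomass[taxon] = n * a * lengths[taxon] ** b * model.carbon_fraction
    total = sum(biomass.values())
    profile = CommunityProfile(
        "biomass", "biomass", {t: v / total for t, v in biomass.items()} if total else {}
    )
    return biomass, profile


def _pearson(x, y) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate: zero-variance vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def within_taxon_correlation(reference, observed) -> tuple[float, float]:
    """Pearson r of one taxon's fractions across k >= 3 samples."""
    if len(reference) < 3 or len(reference) != len(observed):
        raise ValueError("need >= 3 paired samples")
    return _pearson(reference, observed)


def among_taxa_correlation(
    reference: CommunityProfile, observed: CommunityProfile, otus=None
) -> tuple[float, float]:
    """Pearson r across OTU fractions within one sample (>= 3 shared OTUs)."""
    if otus is None:
        otus = sorted(set(reference.fractions) | set(observed.fractions))
    if len(otus) < 3:
        raise ValueError("degenerate-small: need >= 3 shared OTUs")
    return _pearson(reference.vector(otus), observed.vector(otus))


def replicate_consistency(table, replicate_groups: dict[str, list[str]]) -> pd.DataFrame:
    """Per-OTU Kruskal-Wallis H across replicate groups on relative abundances.

    ``replicate_groups`` maps group label -> sample ids (>= 2 groups of >= 2).
    Returns a DataFrame (otu, H, p) plus a ``significant_fraction`` attr
    (fraction of OTUs with p < 0.05).
    """
    if len(replicate_groups) < 2 or any(len(v) < 2 for v in replicate_groups.values()):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    rel = pd.DataFrame(
        table.relative_abundance(), index=table.samples, columns=table.otus
    )
    rows = []
    for otu in table.otus:
        vectors = [rel.loc[samples, otu].to_numpy() for samples in replicate_groups.values()]
        flat = np.concatenate(vectors)
        if np.ptp(flat) == 0:
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*vectors)
        rows.append((otu, float(h), float(p)))
    df = pd.DataFrame(rows, columns=["otu", "H", "p"])
    df.attrs["significant_fraction"] = float((df["p"] < 0.05).mean())
    return df


def rarefaction(counts, depths) -> pd.DataFrame:
    """Analytic expected OTU richness at each subsampling depth.

    E[S_d] = sum_o 1 - C(N - n_o, d) / C(N, d): the expectation over all
    without-replacement subsamples of size d, computed exactly (no
    resampling) via log-gamma.
    """
    counts = np.asarray([c for c in counts if c > 0], dtype=np.int64)
    N = int(counts.sum())
    rows = []
    for d in np.atleast_1d(depths):
        d = int(d)
        if d > N:
            raise ValueError("depth-exceeds-sample: %d > %d" % (d, N))
        # log C(N-n, d) - log C(N, d); C(N-n, d)=0 when N-n < d
        expected = 0.0
        for n in counts:
            if N - n < d:
                expected += 1.0
            else:
                log_ratio = (
                    gammaln(N - n + 1)
                    - gammaln(N - n - d + 1)
                    - gammaln(N + 1)
                    + gammaln(N - d + 1)
                )
                expected += 1.0 - float(np.exp(log_ratio))
        rows.append((d, expected))
    return pd.DataFrame(rows, columns=["depth", "expected_otus"])
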