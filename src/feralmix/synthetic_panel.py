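"""Synthetic genotype panels with known ground truth.

Generates everything the downstream stages consume — divergent reference
clusters, admixed query individuals, related sample pairs, and genomes with
planted runs of homozygosity — so the whole pipeline is testable without any
external data.

Cluster allele frequencies follow the Balding–Nichols model: an ancestral
frequency ``p_l`` is drawn per locus, and each cluster's frequency is a Beta
draw ``f_kl ~ Beta(p_l (1-Fst)/Fst, (1-p_l)(1-Fst)/Fst)``, which has mean
``p_l`` and variance ``Fst p_l (1-p_l)``.  Genotypes are Hardy–Weinberg
binomial draws from individual-specific mixed frequencies, independently
across loci (no linkage disequilibrium — matching the locus-independence
assumption of the admixture likelihood and the validity condition of the
across-locus bootstrap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from feralmix.ancestry_engine import ReferencePanel
from feralmix.genotype_io import MISSING, GenotypeMatrix, MarkerInfo, SampleInfo

#: default chromosome layout: 3 autosomes, evenly spaced markers
DEFAULT_LAYOUT: list[tuple[str, int, int]] = [
    ("1", 400, 50_000),
    ("2", 350, 50_000),
    ("3", 250, 50_000),
]


@dataclass
class SimulationConfig:
    """Parameters of a synthetic reference-panel draw."""

    n_clusters: int = 5
    fst: float = 0.15
    n_markers: int = 1000
    n_per_cluster: int = 50
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0
    chromosome_layout: list[tuple[str, int, int]] | None = None

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.n_markers < 1 or self.n_per_cluster < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie in the open interval (0, 1)")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("ancestral_freq_range must be within (0, 1)")

    def layout(self) -> list[tuple[str, int, int]]:
        """Chromosome layout covering exactly n_markers."""
        if self.chromosome_layout is not None:
            if sum(n for _, n, _ in self.chromosome_layout) != self.n_markers:
                raise ValueError("chromosome_layout marker total != n_markers")
            return self.chromosome_layout
        # single synthetic autosome at 50 kb spacing by default
        return [("1", self.n_markers, 50_000)]


@dataclass
class TruthRecord:
    """Ground truth for one simulated individual."""

    sample_id: str
    true_q: np.ndarray
    planted_roh: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.true_q = np.asarray(self.true_q, dtype=np.float64)
        if abs(self.true_q.sum() - 1.0) > 1e-12:
            raise ValueError("true_q must sum to 1 within 1e-12")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in self.planted_roh:
            by_chrom.setdefault(chrom, []).append((s, e))
        for segs in by_chrom.values():
            segs.sort()
            for (s1, e1), (s2, _) in zip(segs, segs[1:]):
                if s2 <= e1:
                    raise ValueError("planted ROH segments overlap")


def _markers_from_layout(layout: list[tuple[str, int, int]]) -> list[MarkerInfo]:
    markers = []
    for chrom, n, spacing in layout:
        for i in range(n):
            markers.append(MarkerInfo(
                marker_id=f"snp_{chrom}_{i + 1}",
                chromosome=chrom,
                position_bp=1 + i * spacing,
                allele_a="A",
                allele_b="B",
            ))
    return markers


def simulate_reference_panel(
    cfg: SimulationConfig,
) -> tuple[ReferencePanel, np.ndarray]:
    """Draw a K-cluster reference panel under the Balding–Nichols model.

    Returns the panel plus the true K x L cluster frequency matrix (also
    stored on the panel's ``frequencies`` field).
    """
    rng = np.random.default_rng(cfg.seed)
    K, L, n = cfg.n_clusters, cfg.n_markers, cfg.n_per_cluster
    lo, hi = cfg.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=L)
    ratio = (1.0 - cfg.fst) / cfg.fst
    f = rng.beta(p_anc * ratio, (1.0 - p_anc) * ratio, size=(K, L))
    f = np.clip(f, 1e-9, 1.0 - 1e-9)

    markers = _markers_from_layout(cfg.layout())
    samples: list[SampleInfo] = []
    cluster_of: dict[str, str] = {}
    dosage = np.empty((K * n, L), dtype=np.int8)
    for k in range(K):
        cname = f"cluster_{k + 1}"
        for i in range(n):
            sid = f"ref_{cname}_{i + 1}"
            samples.append(SampleInfo(sid, group_label=cname, role="reference"))
            cluster_of[sid] = cname
        dosage[k * n:(k + 1) * n] = rng.binomial(2, f[k], size=(n, L))

    g = GenotypeMatrix(samples=samples, markers=markers, dosage=dosage)
    return ReferencePanel(genotypes=g, cluster_of=cluster_of, frequencies=f), f


def simulate_admixed_queries(
    frequencies: np.ndarray,
    q_list: list[np.ndarray],
    seed: int | None = None,
    layout: list[tuple[str, int, int]] | None = None,
    missing_rate: float = 0.0,
    prefix: str = "query",
) -> tuple[GenotypeMatrix, list[TruthRecord]]:
    """Draw admixed query genotypes with known ancestry vectors.

    Each query's per-locus frequency is ``pi_l = sum_k q_k f_kl``; genotypes
    are Binomial(2, pi_l) draws, with optional uniform missing-data
    contamination at ``missing_rate``.
    """
    F = np.asarray(frequencies, dtype=np.float64)
    K, L = F.shape
    rng = np.random.default_rng(seed)
    markers = _markers_from_layout(layout or [("1", L, 50_000)])

    samples, truths = [], []
    dosage = np.empty((len(q_list), L), dtype=np.int8)
    for i, q in enumerate(q_list):
        q = np.asarray(q, dtype=np.float64)
        if q.shape != (K,) or np.any(q < -1e-9) or abs(q.sum() - 1.0) > 1e-9:
            raise ValueError(f"q_list[{i}] is not on the {K}-simplex")
        q = np.clip(q, 0.0, None)
        q = q / q.sum()
        pi = q @ F
        dosage[i] = rng.binomial(2, pi)
        if missing_rate > 0:
            dosage[i, rng.random(L) < missing_rate] = MISSING
        sid = f"{prefix}_{i + 1}"
        samples.append(SampleInfo(sid, role="query"))
        truths.append(TruthRecord(sample_id=sid, true_q=q))
    return GenotypeMatrix(samples=samples, markers=markers, dosage=dosage), truths


def simulate_related_pair(
    frequencies: np.ndarray,
    relationship: str,
    seed: int | None = None,
    cluster: int = 0,
    layout: list[tuple[str, int, int]] | None = None,
) -> GenotypeMatrix:
    """Draw a pair of genotype rows with a known relationship.

    ``duplicate`` duplicates one draw; ``parent_offspring`` gives the child
    one allele transmitted from the parent (a Bernoulli(g/2) copy per locus)
    and one drawn from the population frequency; ``unrelated`` draws
    independently.  Both members come from cluster ``cluster`` of
    ``frequencies``.
    """
    if relationship not in ("duplicate", "parent_offspring", "unrelated"):
        raise ValueError(f"unknown relationship {relationship!r}")
    F = np.asarray(frequencies, dtype=np.float64)
    f = F[cluster]
    L = f.shape[0]
    rng = np.random.default_rng(seed)
    a = rng.binomial(2, f)
    if relationship == "duplicate":
        b = a.copy()
    elif relationship == "unrelated":
        b = rng.binomial(2, f)
    else:
        transmitted = rng.binomial(1, a / 2.0)
        b = transmitted + rng.binomial(1, f)
    markers = _markers_from_layout(layout or [("1", L, 50_000)])
    samples = [
        SampleInfo(f"{relationship}_1", role="query"),
        SampleInfo(f"{relationship}_2", role="query"),
    ]
    return GenotypeMatrix(
        samples=samples, markers=markers,
        dosage=np.vstack([a, b]).astype(np.int8),
    )


def simulate_roh_individual(
    layout: list[tuple[str, int, int]],
    planted: list[tuple[str, int, int]],
    background_het: float = 0.3,
    seed: int | None = None,
    het_errors_per_segment: int = 0,
    missing_rate: float = 0.0,
    sample_id: str = "roh_sample",
) -> tuple[GenotypeMatrix, TruthRecord]:
    """One genome with homozygous runs planted at known coordinates.

    Inside planted segments every marker is homozygous (0 or 2, with
    ``het_errors_per_segment`` optional heterozygote errors injected);
    outside, heterozygotes occur at rate ``background_het``.
    """
    if not 0.0 <= background_het <= 1.0:
        raise ValueError("background_het must be in [0, 1]")
    markers = _markers_from_layout(layout)
    truth = TruthRecord(sample_id=sample_id, true_q=np.array([1.0]),
                        planted_roh=list(planted))

    rng = np.random.default_rng(seed)
    chrom = np.array([m.chromosome for m in markers])
    pos = np.array([m.position_bp for m in markers])
    in_roh = np.zeros(len(markers), dtype=bool)
    for c, s, e in planted:
        mask = (chrom == c) & (pos >= s) & (pos <= e)
        if not mask.any():
            raise ValueError(f"planted segment {c}:{s}-{e} covers no markers")
        in_roh |= mask

    hom = rng.choice([0, 2], size=len(markers))
    het = rng.random(len(markers)) < background_het
    dosage = np.where(in_roh, hom, np.where(het, 1, hom)).astype(np.int8)
    if het_errors_per_segment > 0:
        for c, s, e in planted:
            idx = np.flatnonzero((chrom == c) & (pos >= s) & (pos <= e))
            err = rng.choice(idx, size=min(het_errors_per_segment, len(idx)),
                             replace=False)
            dosage[err] = 1
    if missing_rate > 0:
        dosage[rng.random(len(markers)) < missing_rate] = MISSING

    g = GenotypeMatrix(
        samples=[SampleInfo(sample_id, role="query")],
        markers=markers,
        dosage=dosage[None, :],
    )
    return g, truth


def write_truth_table(truths: list[TruthRecord], path: str | Path) -> None:
    """Tab-separated ground-truth table (sample, q vector, planted segments)."""
    with open(path, "w") as fh:
        fh.write("sample_id\ttrue_q\tplanted_roh\n")
        for t in truths:
            qs = ",".join(f"{v:.10g}" for v in t.true_q)
            segs = ";".join(f"{c}:{s}-{e}" for c, s, e in t.planted_roh)
            fh.write(f"{t.sample_id}\t{qs}\t{segs}\n")
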