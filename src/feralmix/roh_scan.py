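"""Runs-of-homozygosity detection and fROH summaries.

A run of homozygosity (ROH) is reported as a maximal interval of consecutive
autosomal markers on one chromosome satisfying, simultaneously:

* at most ``max_het`` heterozygous calls (default 1: regions with more than
  one heterozygote are excluded),
* at most ``max_missing`` missing calls (default 2),
* every adjacent-marker gap at most ``max_gap_bp`` (default 600 kb),
* whole-segment density of at least one SNP per ``max_kb_per_snp`` kb
  (default 80 kb/SNP, evaluated as span_kb / n_snps),
* at least ``min_snps`` markers (default 25) spanning at least ``min_kb`` kb
  (default 500).

"Maximal" means the interval cannot be extended by one marker on either side
without violating a constraint.  Overlapping maximal candidates are resolved
by keeping the longer segment (ties: leftmost) and iterating on the
remainder; the procedure is deterministic.  fROH is the summed segment
length divided by the autosomal genome size (2,265,775 kb for Sscrofa11.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from feralmix.genotype_io import MISSING, GenotypeMatrix, MarkerInfo

#: autosomal genome length of the Sscrofa11.1 assembly, in kb
SSCROFA11_AUTOSOME_KB = 2_265_775.0

#: segments strictly longer than this count as "long" (10 Mb)
LONG_SEGMENT_KB = 10_000.0


@dataclass
class ROHParams:
    """Constraints defining a reportable homozygous run."""

    max_het: int = 1
    max_missing: int = 2
    max_gap_bp: int = 600_000
    max_kb_per_snp: float = 80.0
    min_snps: int = 25
    min_kb: float = 500.0


@dataclass(frozen=True)
class ROHSegment:
    """One detected run of homozygosity."""

    sample_id: str
    chromosome: str
    start_bp: int  # position of the first SNP in the run (1-based)
    end_bp: int  # position of the last SNP (inclusive)
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0


@dataclass
class ROHProfile:
    """Per-sample ROH summary."""

    sample_id: str
    segments: list[ROHSegment] = field(default_factory=list)
    autosome_kb: float = SSCROFA11_AUTOSOME_KB

    @property
    def froh(self) -> float:
        return sum(s.length_kb for s in self.segments) / self.autosome_kb

    @property
    def n_long(self) -> int:
        return sum(1 for s in self.segments if s.length_kb > LONG_SEGMENT_KB)


def _scan_chromosome(
    dosage: np.ndarray, pos: np.ndarray, p: ROHParams
) -> list[tuple[int, int, int, int]]:
    """Maximal valid intervals on one sorted chromosome.

    Returns (start_idx, end_idx, n_het, n_missing) tuples, before overlap
    resolution.  Uses prefix sums so single-interval validity is O(1); the
    right-extension frontier for each start is bounded by the monotone
    constraints (heterozygote count, missing count, gap), which keeps the
    scan near-linear on heterozygote-rich data.
    """
    n = len(pos)
    het = np.concatenate([[0], np.cumsum(dosage == 1)])
    mis = np.concatenate([[0], np.cumsum(dosage == MISSING)])
    gaps = np.diff(pos)
    big_gap = np.concatenate([[0], np.cumsum(gaps > p.max_gap_bp)])

    def counts(i: int, j: int) -> tuple[int, int]:
        return int(het[j + 1] - het[i]), int(mis[j + 1] - mis[i])

    def valid(i: int, j: int) -> bool:
        if i < 0 or j >= n:
            return False
        h, m = counts(i, j)
        if h > p.max_het or m > p.max_missing:
            return False
        if big_gap[j] - big_gap[i] > 0:  # a super-threshold gap inside [i, j]
            return False
        n_snps = j - i + 1
        length_kb = (pos[j] - pos[i] + 1) / 1000.0
        if n_snps < p.min_snps or length_kb < p.min_kb:
            return False
        return length_kb / n_snps <= p.max_kb_per_snp

    out: list[tuple[int, int, int, int]] = []
    for i in range(n):
        # frontier: furthest j reachable under the monotone constraints
        j = i
        while j + 1 < n:
            h, m = counts(i, j + 1)
            if h > p.max_het or m > p.max_missing or gaps[j] > p.max_gap_bp:
                break
            j += 1
        frontier = j
        for j in range(i, frontier + 1):
            if not valid(i, j):
                continue
            if valid(i, j + 1) or valid(i - 1, j):
                continue  # extensible, hence not maximal
            h, m = counts(i, j)
            out.append((i, j, h, m))
    return out


def _resolve_overlaps(
    cands: list[tuple[int, int, int, int]], pos: np.ndarray
) -> list[tuple[int, int, int, int]]:
    """Keep the longest candidate (ties: leftmost), drop overlaps, iterate."""
    remaining = list(cands)
    kept: list[tuple[int, int, int, int]] = []
    while remaining:
        best = max(
            remaining,
            key=lambda c: (pos[c[1]] - pos[c[0]], -pos[c[0]]),
        )
        kept.append(best)
        remaining = [
            c for c in remaining
            if c is not best and (c[1] < best[0] or c[0] > best[1])
        ]
    kept.sort(key=lambda c: c[0])
    return kept


def detect_roh_segments(
    dosage: np.ndarray,
    markers: list[MarkerInfo],
    params: ROHParams | None = None,
    sample_id: str = "sample",
) -> list[ROHSegment]:
    """Detect all runs of homozygosity in one sample's genotype row.

    ``markers`` must be sorted by (chromosome, position); unsorted input is
    an error.  Output is deterministic for fixed input.
    """
    params = params or ROHParams()
    dosage = np.asarray(dosage)
    if dosage.shape != (len(markers),):
        raise ValueError("dosage length does not match marker list")
    chroms = [m.chromosome for m in markers]
    pos = np.array([m.position_bp for m in markers], dtype=np.int64)
    for a, b in zip(range(len(markers) - 1), range(1, len(markers))):
        if chroms[a] == chroms[b] and pos[a] >= pos[b]:
            raise ValueError("markers must be sorted by (chromosome, position)")

    segments: list[ROHSegment] = []
    start = 0
    for end in range(1, len(markers) + 1):
        if end == len(markers) or chroms[end] != chroms[start]:
            cpos = pos[start:end]
            cands = _scan_chromosome(dosage[start:end], cpos, params)
            for i, j, h, m in _resolve_overlaps(cands, cpos):
                segments.append(ROHSegment(
                    sample_id=sample_id,
                    chromosome=chroms[start],
                    start_bp=int(cpos[i]),
                    end_bp=int(cpos[j]),
                    n_snps=j - i + 1,
                    n_het=h,
                    n_missing=m,
                ))
            start = end
    return segments


def scan_panel(
    g: GenotypeMatrix,
    params: ROHParams | None = None,
    autosome_kb: float = SSCROFA11_AUTOSOME_KB,
) -> list[ROHProfile]:
    """ROH profiles for every sample of a genotype matrix."""
    return [
        summarize_froh(
            detect_roh_segments(g.dosage[i], g.markers, params, sample_id=sid),
            autosome_kb=autosome_kb,
            sample_id=sid,
        )
        for i, sid in enumerate(g.sample_ids)
    ]


def summarize_froh(
    segments: list[ROHSegment],
    autosome_kb: float = SSCROFA11_AUTOSOME_KB,
    sample_id: str | None = None,
) -> ROHProfile:
    """Fold detected segments into a per-sample fROH profile."""
    sid = sample_id if sample_id is not None else (
        segments[0].sample_id if segments else "sample"
    )
    return ROHProfile(sample_id=sid, segments=list(segments), autosome_kb=autosome_kb)


def compare_groups(profiles_by_group: dict[str, list[ROHProfile]]) -> pd.DataFrame:
    """Descriptive per-group fROH comparison (no inferential statistics).

    Returns one row per non-empty group with mean/median/quartile fROH and
    the mean count of long (> 10 Mb) segments.
    """
    if not profiles_by_group:
        raise ValueError("need at least one group")
    rows = []
    for name, profiles in profiles_by_group.items():
        if not profiles:
            import warnings

            warnings.warn(f"group {name!r} is empty; excluded", stacklevel=2)
            continue
        froh = np.array([p.froh for p in profiles])
        nlong = np.array([p.n_long for p in profiles])
        rows.append({
            "group": name,
            "n": len(profiles),
            "mean_froh": froh.mean(),
            "median_froh": float(np.median(froh)),
            "q25_froh": float(np.quantile(froh, 0.25)),
            "q75_froh": float(np.quantile(froh, 0.75)),
            "mean_n_long": nlong.mean(),
        })
    return pd.DataFrame(rows).set_index("group")


def segments_to_table(segments: list[ROHSegment]) -> pd.DataFrame:
    """Segment list as a tidy table (one row per segment)."""
    return pd.DataFrame([
        {
            "sample_id": s.sample_id,
            "chromosome": s.chromosome,
            "start_bp": s.start_bp,
            "end_bp": s.end_bp,
            "n_snps": s.n_snps,
            "n_het": s.n_het,
            "n_missing": s.n_missing,
            "length_kb": s.length_kb,
        }
        for s in segments
    ])
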