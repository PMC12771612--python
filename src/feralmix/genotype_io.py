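"""Reading, writing, merging and call-rate filtering of SNP-array genotypes.

Genotypes travel through the pipeline as a :class:`GenotypeMatrix`: a
samples x markers array of allele-B dosages in {0, 1, 2} with ``MISSING``
(-1) for no-calls, plus per-marker and per-sample metadata.  Supported disk
formats are PLINK text (.ped/.map) and PLINK 1 binary (.bed/.bim/.fam,
SNP-major).

Conventions
-----------
* Dosage counts copies of ``allele_b`` — the second allele column (A2 in a
  .bim file) — fixing one orientation so allele-frequency arithmetic is
  unambiguous.
* Coordinates are 1-based inclusive, per .bim/.map convention.
* The text pair .ped/.map does not record which allele the dosage counts, so
  :func:`write_genotypes` emits a sidecar ``<prefix>.alleles`` table
  (marker_id, allele_a, allele_b).  :func:`read_genotypes` uses it when
  present; without it, orientation falls back to a major/minor rule
  (allele_a = major allele, ties broken lexicographically).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

MISSING: int = -1

#: .bed magic bytes + SNP-major flag (PLINK v1.00)
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

#: 2-bit .bed codes, SNP-major: 00=hom A1 (dosage 0), 01=missing,
#: 10=het (dosage 1), 11=hom A2 (dosage 2)
_BED_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_DOSAGE_TO_BED_CODE = {0: 0b00, 1: 0b10, 2: 0b11, MISSING: 0b01}


class GenotypeFormatError(ValueError):
    """Malformed file contents (bad magic bytes, unparsable records)."""


class GenotypeConsistencyError(ValueError):
    """Companion files disagree on sample or marker counts."""


@dataclass(frozen=True)
class MarkerInfo:
    """One biallelic autosomal SNP on the array manifest."""

    marker_id: str
    chromosome: str
    position_bp: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"{self.marker_id}: position_bp must be >= 1")
        if self.allele_a == self.allele_b:
            raise ValueError(f"{self.marker_id}: allele_a == allele_b")


@dataclass(frozen=True)
class SampleInfo:
    """A genotyped individual: reference-panel member or query."""

    sample_id: str
    group_label: str | None = None
    role: str = "query"

    def __post_init__(self) -> None:
        if self.role not in ("reference", "query"):
            raise ValueError(f"role must be 'reference' or 'query', got {self.role!r}")


@dataclass
class GenotypeMatrix:
    """Samples x markers allele-B dosage matrix with metadata.

    ``dosage`` entries are in {0, 1, 2, MISSING}; rows follow ``samples``,
    columns follow ``markers``.
    """

    samples: list[SampleInfo]
    markers: list[MarkerInfo]
    dosage: np.ndarray  # int8, shape (n_samples, n_markers)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.markers)):
            raise GenotypeConsistencyError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"dosage contains values outside {{0,1,2,{MISSING}}}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id within panel")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def observed_mask(self) -> np.ndarray:
        """Boolean mask of called genotypes."""
        return self.dosage != MISSING

    def missing_fraction_per_sample(self) -> np.ndarray:
        return (self.dosage == MISSING).mean(axis=1)

    def callrate_per_marker(self) -> np.ndarray:
        return (self.dosage != MISSING).mean(axis=0)

    def allele_b_frequencies(self) -> np.ndarray:
        """Observed allele-B frequency per marker (NaN where fully missing)."""
        obs = self.observed_mask()
        n_obs = obs.sum(axis=0)
        counts = np.where(obs, self.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, counts / (2.0 * n_obs), np.nan)

    def subset(
        self,
        sample_idx: np.ndarray | list[int] | None = None,
        marker_idx: np.ndarray | list[int] | None = None,
    ) -> "GenotypeMatrix":
        s_idx = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        m_idx = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in s_idx],
            markers=[self.markers[j] for j in m_idx],
            dosage=self.dosage[np.ix_(s_idx, m_idx)].copy(),
        )


@dataclass
class FilterReport:
    """Record of what a call-rate filtering pass removed."""

    removed_samples: list[str] = field(default_factory=list)
    removed_markers: list[str] = field(default_factory=list)
    order: str = "markers_first"

    @property
    def n_samples_removed(self) -> int:
        return len(self.removed_samples)

    @property
    def n_markers_removed(self) -> int:
        return len(self.removed_markers)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tid\n")
            for m in self.removed_markers:
                fh.write(f"marker\t{m}\n")
            for s in self.removed_samples:
                fh.write(f"sample\t{s}\n")


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str) -> GenotypeMatrix:
    """Read a PLINK fileset rooted at ``path`` (prefix without extension).

    Parameters
    ----------
    path
        Fileset prefix: ``path.ped``/``path.map`` for ``plink_text``,
        ``path.bed``/``path.bim``/``path.fam`` for ``plink_binary``.
    format
        ``"plink_text"`` or ``"plink_binary"``.
    """
    prefix = Path(path)
    if format == "plink_text":
        return _read_plink_text(prefix)
    if format == "plink_binary":
        return _read_plink_binary(prefix)
    raise ValueError(f"unknown format {format!r}")


def _require(p: Path) -> Path:
    if not p.exists():
        raise FileNotFoundError(p)
    return p


def _read_map(path: Path) -> list[tuple[str, str, int]]:
    out = []
    for line in _require(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) not in (3, 4):
            raise GenotypeFormatError(f"{path}: bad .map record: {line!r}")
        chrom, mid = parts[0], parts[1]
        pos = int(parts[-1])
        out.append((chrom, mid, pos))
    return out


def _read_fam_like(fields: list[str], path: Path) -> SampleInfo:
    if len(fields) < 6:
        raise GenotypeFormatError(f"{path}: short sample record")
    fid, iid, _pat, _mat, _sex, pheno = fields[:6]
    group = None if fid in ("0", "-9", "NA") else fid
    role = "reference" if pheno == "1" else "query"
    return SampleInfo(sample_id=iid, group_label=group, role=role)


def _read_alleles_sidecar(path: Path) -> dict[str, tuple[str, str]]:
    table = {}
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("marker_id"):
            continue
        mid, a, b = line.split()
        table[mid] = (a, b)
    return table


def _read_plink_text(prefix: Path) -> GenotypeMatrix:
    ped_path = _require(prefix.with_suffix(".ped"))
    map_records = _read_map(prefix.with_suffix(".map"))
    n_markers = len(map_records)

    sidecar = prefix.with_suffix(".alleles")
    orientation = _read_alleles_sidecar(sidecar) if sidecar.exists() else {}

    samples: list[SampleInfo] = []
    allele_rows: list[list[tuple[str, str]]] = []
    for line in ped_path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_markers:
            raise GenotypeConsistencyError(
                f"{ped_path}: record has {len(parts)} fields, expected "
                f"{6 + 2 * n_markers} for {n_markers} markers"
            )
        samples.append(_read_fam_like(parts[:6], ped_path))
        calls = parts[6:]
        allele_rows.append([(calls[2 * j], calls[2 * j + 1]) for j in range(n_markers)])

    markers: list[MarkerInfo] = []
    dosage = np.full((len(samples), n_markers), MISSING, dtype=np.int8)
    for j, (chrom, mid, pos) in enumerate(map_records):
        observed: dict[str, int] = {}
        for row in allele_rows:
            for a in row[j]:
                if a != "0":
                    observed[a] = observed.get(a, 0) + 1
        if mid in orientation:
            a_a, a_b = orientation[mid]
        elif observed:
            # major allele -> allele_a; ties broken lexicographically
            ranked = sorted(observed, key=lambda a: (-observed[a], a))
            if len(ranked) == 1:
                a_a, a_b = ranked[0], "." if ranked[0] != "." else "N"
            else:
                a_a, a_b = ranked[0], ranked[1]
            if len(ranked) > 2:
                raise GenotypeFormatError(f"marker {mid}: more than 2 alleles observed")
        else:
            a_a, a_b = "A", "B"  # fully missing marker, placeholder alleles
        markers.append(MarkerInfo(mid, chrom, pos, a_a, a_b))
        for i, row in enumerate(allele_rows):
            c1, c2 = row[j]
            if c1 == "0" or c2 == "0":
                continue
            d = 0
            for c in (c1, c2):
                if c == a_b:
                    d += 1
                elif c != a_a:
                    raise GenotypeFormatError(
                        f"marker {mid}: allele {c!r} not in ({a_a!r}, {a_b!r})"
                    )
            dosage[i, j] = d
    logger.info("read %d samples x %d markers from %s (text)", len(samples), n_markers, prefix)
    return GenotypeMatrix(samples=samples, markers=markers, dosage=dosage)


def _read_plink_binary(prefix: Path) -> GenotypeMatrix:
    bed_path = _require(prefix.with_suffix(".bed"))
    bim_path = _require(prefix.with_suffix(".bim"))
    fam_path = _require(prefix.with_suffix(".fam"))

    markers: list[MarkerInfo] = []
    for line in bim_path.read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise GenotypeFormatError(f"{bim_path}: bad .bim record: {line!r}")
        chrom, mid, _cm, pos, a1, a2 = parts
        markers.append(MarkerInfo(mid, chrom, int(pos), allele_a=a1, allele_b=a2))

    samples = []
    for line in fam_path.read_text().splitlines():
        if not line.strip():
            continue
        samples.append(_read_fam_like(line.split(), fam_path))

    raw = bed_path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise GenotypeFormatError(
            f"{bed_path}: bad magic bytes {raw[:3].hex()} (expected SNP-major v1.00)"
        )
    n, L = len(samples), len(markers)
    bytes_per_marker = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_marker * L:
        raise GenotypeConsistencyError(
            f"{bed_path}: {body.size} data bytes, expected {bytes_per_marker * L} "
            f"for {n} samples x {L} markers"
        )
    blocks = body.reshape(L, bytes_per_marker)
    # unpack 2-bit codes, sample 0 in the lowest bits of each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(L, bytes_per_marker * 4)[:, :n]
    dosage = _BED_CODE_TO_DOSAGE[codes].T.copy()  # -> samples x markers
    logger.info("read %d samples x %d markers from %s (binary)", n, L, prefix)
    return GenotypeMatrix(samples=samples, markers=markers, dosage=dosage)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_genotypes(g: GenotypeMatrix, path: str | Path, format: str) -> None:
    """Write ``g`` as a PLINK fileset rooted at prefix ``path``."""
    prefix = Path(path)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if format == "plink_text":
        _write_plink_text(g, prefix)
    elif format == "plink_binary":
        _write_plink_binary(g, prefix)
    else:
        raise ValueError(f"unknown format {format!r}")


def _fam_fields(s: SampleInfo) -> list[str]:
    fid = s.group_label if s.group_label else "0"
    pheno = "1" if s.role == "reference" else "2"
    return [fid, s.sample_id, "0", "0", "0", pheno]


def _write_plink_text(g: GenotypeMatrix, prefix: Path) -> None:
    with open(prefix.with_suffix(".map"), "w") as fh:
        for m in g.markers:
            fh.write(f"{m.chromosome}\t{m.marker_id}\t0\t{m.position_bp}\n")
    with open(prefix.with_suffix(".alleles"), "w") as fh:
        fh.write("marker_id\tallele_a\tallele_b\n")
        for m in g.markers:
            fh.write(f"{m.marker_id}\t{m.allele_a}\t{m.allele_b}\n")
    call = {
        0: lambda m: (m.allele_a, m.allele_a),
        1: lambda m: (m.allele_a, m.allele_b),
        2: lambda m: (m.allele_b, m.allele_b),
        MISSING: lambda m: ("0", "0"),
    }
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, s in enumerate(g.samples):
            fields = _fam_fields(s)
            for j, m in enumerate(g.markers):
                fields.extend(call[int(g.dosage[i, j])](m))
            fh.write(" ".join(fields) + "\n")


def _write_plink_binary(g: GenotypeMatrix, prefix: Path) -> None:
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for m in g.markers:
            fh.write(
                f"{m.chromosome}\t{m.marker_id}\t0\t{m.position_bp}\t"
                f"{m.allele_a}\t{m.allele_b}\n"
            )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in g.samples:
            fh.write(" ".join(_fam_fields(s)) + "\n")
    n, L = g.n_samples, g.n_markers
    bytes_per_marker = (n + 3) // 4
    # index by dosage+1 so MISSING (-1) -> slot 0
    lut = np.array(
        [_DOSAGE_TO_BED_CODE[MISSING], _DOSAGE_TO_BED_CODE[0],
         _DOSAGE_TO_BED_CODE[1], _DOSAGE_TO_BED_CODE[2]],
        dtype=np.uint8,
    )
    codes = lut[g.dosage.T.astype(np.int16) + 1]  # markers x samples
    padded = np.zeros((L, bytes_per_marker * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded.reshape(L, bytes_per_marker, 4)
        << np.array([0, 2, 4, 6], dtype=np.uint8)[None, None, :]
    ).sum(axis=2, dtype=np.uint16).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# merging and filtering
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_strand_ambiguous(a: str, b: str) -> bool:
    return _COMPLEMENT.get(a.upper()) == b.upper()


def merge_on_shared_markers(panels: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Concatenate panels on the intersection of their marker sets.

    Markers are matched by ``marker_id`` with a chromosome/position collision
    check.  Where a panel stores a marker with swapped alleles relative to the
    first panel, its dosages are recoded ``d -> 2 - d``.  Markers whose allele
    pairs are irreconcilable (including strand-ambiguous A/T and C/G pairs in
    conflict) are dropped and logged.
    """
    if len(panels) < 2:
        raise ValueError("need at least 2 panels to merge")

    all_ids = [s.sample_id for p in panels for s in p.samples]
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("duplicate sample_id across panels")

    shared = set(panels[0].marker_ids)
    for p in panels[1:]:
        shared &= set(p.marker_ids)
    if not shared:
        raise ValueError("no shared markers across panels")

    ref_markers = {m.marker_id: m for m in panels[0].markers}
    # preserve first panel's marker order
    order = [m.marker_id for m in panels[0].markers if m.marker_id in shared]

    lookups = [{m.marker_id: m for m in p.markers} for p in panels]
    keep: list[str] = []
    dropped: list[str] = []
    for mid in order:
        ref = ref_markers[mid]
        ok = True
        for lookup in lookups:
            m = lookup[mid]
            if (m.chromosome, m.position_bp) != (ref.chromosome, ref.position_bp):
                raise ValueError(
                    f"marker {mid}: chromosome/position collision between panels"
                )
            if (m.allele_a, m.allele_b) == (ref.allele_a, ref.allele_b):
                continue
            # swapped alleles are recodable, unless the pair is strand-
            # ambiguous (A/T, C/G), where a swap is indistinguishable from a
            # strand flip: drop those rather than guess
            if (m.allele_a, m.allele_b) == (ref.allele_b, ref.allele_a) and not (
                _is_strand_ambiguous(ref.allele_a, ref.allele_b)
            ):
                continue
            ok = False
            break
        if ok:
            keep.append(mid)
        else:
            dropped.append(mid)
    if dropped:
        logger.warning("dropped %d markers with irreconcilable alleles: %s",
                       len(dropped), ", ".join(dropped[:10]))

    markers = [ref_markers[mid] for mid in keep]
    pos_of = {mid: j for j, mid in enumerate(keep)}
    samples: list[SampleInfo] = []
    blocks: list[np.ndarray] = []
    for p in panels:
        col_idx = np.empty(len(keep), dtype=np.intp)
        flip = np.zeros(len(keep), dtype=bool)
        marker_lookup = {m.marker_id: (j, m) for j, m in enumerate(p.markers)}
        for mid in keep:
            j, m = marker_lookup[mid]
            col_idx[pos_of[mid]] = j
            flip[pos_of[mid]] = (m.allele_a, m.allele_b) != (
                ref_markers[mid].allele_a, ref_markers[mid].allele_b
            )
        d = p.dosage[:, col_idx].copy()
        obs = d != MISSING
        d[:, flip] = np.where(obs[:, flip], 2 - d[:, flip], MISSING)
        blocks.append(d)
        samples.extend(p.samples)
    return GenotypeMatrix(samples=samples, markers=markers, dosage=np.vstack(blocks))


def apply_callrate_filters(
    g: GenotypeMatrix,
    max_individual_missing: float = 0.05,
    min_marker_callrate: float = 0.95,
    markers_first: bool = True,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop low-call-rate markers and high-missingness individuals.

    Markers with call rate < ``min_marker_callrate`` and individuals with
    missing fraction > ``max_individual_missing`` are removed; by default the
    marker filter is applied first (order configurable and recorded in the
    report).
    """
    for t in (max_individual_missing, min_marker_callrate):
        if not 0.0 <= t <= 1.0:
            raise ValueError("thresholds must be in [0, 1]")

    report = FilterReport(order="markers_first" if markers_first else "samples_first")

    def filter_markers(gm: GenotypeMatrix) -> GenotypeMatrix:
        keep = gm.callrate_per_marker() >= min_marker_callrate
        report.removed_markers.extend(
            m.marker_id for m, k in zip(gm.markers, keep) if not k
        )
        return gm.subset(marker_idx=np.flatnonzero(keep))

    def filter_samples(gm: GenotypeMatrix) -> GenotypeMatrix:
        keep = gm.missing_fraction_per_sample() <= max_individual_missing
        report.removed_samples.extend(
            s.sample_id for s, k in zip(gm.samples, keep) if not k
        )
        return gm.subset(sample_idx=np.flatnonzero(keep))

    out = filter_samples(filter_markers(g)) if markers_first else filter_markers(filter_samples(g))
    if out.n_samples == 0:
        raise ValueError("call-rate filtering removed all samples")
    logger.info(
        "call-rate filters removed %d markers, %d samples (%s)",
        report.n_markers_removed, report.n_samples_removed, report.order,
    )
    return out, report
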