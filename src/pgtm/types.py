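"""Core domain types shared by every stage of the PGT-M pipeline.

Genotypes are carried as small integer codes throughout (``HOM_REF``,
``HET``, ``HOM_ALT``, ``MISSING``); allele identity within a site uses
``0`` (ref) / ``1`` (alt), with ``DELETED`` marking a haplotype segment
that is physically absent because it lies inside a large deletion.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

# Genotype-class codes (unordered diploid calls).
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

# Allele codes within a biallelic site.
REF = 0
ALT = 1
DELETED = -9  # haplotype allele inside a deleted segment: no DNA present

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}

DOMINANT_PATERNAL = "dominant_paternal"
DOMINANT_MATERNAL = "dominant_maternal"
RECESSIVE_BIALLELIC = "recessive_biallelic"
INHERITANCE_MODES = (DOMINANT_PATERNAL, DOMINANT_MATERNAL, RECESSIVE_BIALLELIC)


@dataclass(frozen=True)
class VariantLocus:
    """A pathogenic variant: either a point change or a deletion interval.

    Coordinates are 1-based; deletion intervals are inclusive on both ends,
    so the deleted length is ``del_end - del_start + 1``.
    """

    chrom: str
    kind: str  # "point" | "deletion"
    gene: str
    inheritance: str
    pos: int | None = None
    ref: str | None = None
    alt: str | None = None
    del_start: int | None = None
    del_end: int | None = None
    build: str = "unspecified"  # reference-build label; never mixed, never converted

    def __post_init__(self) -> None:
        if self.kind not in ("point", "deletion"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.inheritance not in INHERITANCE_MODES:
            raise ValueError(f"unknown inheritance mode {self.inheritance!r}")
        if self.kind == "point":
            if self.pos is None or not self.ref or not self.alt:
                raise ValueError("point variant needs pos, ref and alt")
        else:
            if self.del_start is None or self.del_end is None:
                raise ValueError("deletion variant needs del_start/del_end")
            if self.del_end < self.del_start:
                raise ValueError("deletion has del_end < del_start")

    @property
    def length(self) -> int:
        """Inclusive length of a deletion; 1 for a point variant."""
        if self.kind == "deletion":
            return self.del_end - self.del_start + 1
        return 1

    @property
    def anchor_pos(self) -> int:
        """Representative position used to centre the SNP search window."""
        if self.kind == "point":
            return self.pos
        return (self.del_start + self.del_end) // 2

    def contains(self, pos: int) -> bool:
        """True when ``pos`` falls inside the deletion interval."""
        if self.kind != "deletion":
            return False
        return self.del_start <= pos <= self.del_end

    @property
    def carrier_parents(self) -> tuple[str, ...]:
        if self.inheritance == DOMINANT_PATERNAL:
            return ("father",)
        if self.inheritance == DOMINANT_MATERNAL:
            return ("mother",)
        return ("father", "mother")


#: The Southeast-Asian alpha-globin cluster deletion (HBA1/HBA2 region),
#: with its published GRCh38 interval.  Inclusive length: 19,304 bp.
SEA_DELETION = VariantLocus(
    chrom="chr16",
    kind="deletion",
    gene="HBA",
    inheritance=RECESSIVE_BIALLELIC,
    del_start=165_397,
    del_end=184_700,
    build="GRCh38",
)


class GenotypeCall(NamedTuple):
    """One unphased diploid call: the allele pair is an unordered set."""

    site_id: str
    alleles: tuple[str, str] | None  # None == missing
    origin_sample: str


@dataclass
class GenotypeTable:
    """Unphased genotype matrix over biallelic SNP sites.

    ``sites`` has columns chrom/pos/ref/alt; ``gt`` is an (n_sites, n_samples)
    int8 matrix of genotype-class codes aligned to ``samples``.
    """

    sites: pd.DataFrame
    gt: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.gt = np.asarray(self.gt, dtype=np.int8)
        if self.gt.shape != (len(self.sites), len(self.samples)):
            raise ValueError("genotype matrix shape does not match sites/samples")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not present (have {self.samples})")

    def sample_gt(self, sample: str) -> np.ndarray:
        return self.gt[:, self.sample_index(sample)]

    def subset_window(self, chrom: str, lo: int, hi: int) -> "GenotypeTable":
        mask = (
            (self.sites["chrom"] == chrom)
            & (self.sites["pos"] >= lo)
            & (self.sites["pos"] <= hi)
        ).to_numpy()
        return GenotypeTable(
            sites=self.sites.loc[mask].reset_index(drop=True),
            gt=self.gt[mask],
            samples=list(self.samples),
        )

    def calls(self, sample: str) -> Iterator[GenotypeCall]:
        """Yield unordered per-site calls for one sample."""
        col = self.sample_gt(sample)
        for i, row in enumerate(self.sites.itertuples(index=False)):
            sid = f"{row.chrom}:{row.pos}"
            g = int(col[i])
            if g == MISSING:
                alleles = None
            elif g == HOM_REF:
                alleles = (row.ref, row.ref)
            elif g == HET:
                alleles = (row.ref, row.alt)
            else:
                alleles = (row.alt, row.alt)
            yield GenotypeCall(sid, alleles, sample)


@dataclass
class GeneticMap:
    """Cumulative genetic-map positions for a single chromosome.

    Linear interpolation between tabulated points; cumulative cM is held
    constant beyond the tabulated range so that off-map gaps contribute
    zero genetic distance.
    """

    chrom: str
    positions: np.ndarray  # 1-based bp, strictly increasing
    rate_cM_per_Mb: np.ndarray
    cumulative_cM: np.ndarray  # nondecreasing

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.rate_cM_per_Mb = np.asarray(self.rate_cM_per_Mb, dtype=float)
        self.cumulative_cM = np.asarray(self.cumulative_cM, dtype=float)
        if len(self.positions) < 1:
            raise ValueError("genetic map is empty")
        d = np.diff(self.positions)
        if np.any(d <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(self.cumulative_cM) < 0):
            raise ValueError("cumulative cM must be nondecreasing")
        if np.any(self.rate_cM_per_Mb < 0):
            raise ValueError("rates must be nonnegative")

    def interpolate_cM(self, pos) -> np.ndarray | float:
        """Cumulative cM at ``pos`` (scalar or array), constant beyond range."""
        return np.interp(pos, self.positions, self.cumulative_cM)


DIRECT_CALLS = ("carrier", "affected", "wild_type", "failed")


@dataclass(frozen=True)
class DirectTestResult:
    """Outcome of direct mutation detection (Sanger / Gap-PCR) for one embryo."""

    embryo_id: str
    call: str
    method: str = "sanger"

    def __post_init__(self) -> None:
        if self.call not in DIRECT_CALLS:
            raise ValueError(f"unknown direct-test call {self.call!r}")


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their defaults.

    Phasing: ``window_bp`` is the half-width of the SNP search window around
    the pathogenic variant; ``ado_rate``/``genotype_error`` parameterise the
    genotype-observation (emission) model.  CNV: bin geometry, reporting
    thresholds and CBS settings.
    """

    window_bp: int = 5_000_000
    ado_rate: float = 0.05
    genotype_error: float = 0.01
    # CNV bin geometry
    cnv_window_bp: int = 400_000
    cnv_step_bp: int = 200_000
    # CNV reporting thresholds
    log2_threshold: float = 0.25
    min_segment_bp: int = 4_000_000
    min_segment_bins: int = 20
    mosaic_min_bp: int = 10_000_000
    mosaic_min_level: float = 0.30
    neutral_band: float = 0.10
    full_event_level: float = 0.70
    whole_scope_fraction: float = 0.90
    # CBS
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 1000
    cbs_merge_delta: float = 0.10
    # LOESS GC fit
    loess_frac: float = 0.30
    loess_iter: int = 3
    # Ploidy gate
    mendel_violation_threshold: float = 0.10
    het_excess_threshold: float = 0.75
    nocall_excess_threshold: float = 0.10
    # Diagnosis
    low_margin_nats: float = 2.0
    # Sample naming and randomness
    father_id: str = "father"
    mother_id: str = "mother"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.ado_rate < 1 and 0 <= self.genotype_error < 1):
            raise ValueError("rates must lie in [0, 1)")
        if self.ado_rate + self.genotype_error >= 1:
            raise ValueError("ado_rate + genotype_error must be < 1")
        if self.cnv_step_bp > self.cnv_window_bp:
            raise ValueError("CNV step must not exceed window")
        for name in ("window_bp", "cnv_window_bp", "cnv_step_bp",
                     "min_segment_bp", "mosaic_min_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class RunManifest:
    """Reproducibility record: config hash, input digests, version, seed."""

    config_hash: str
    input_digests: dict[str, str]
    tool_version: str
    seed: int
    timestamp: str = ""

    @staticmethod
    def hash_config(config: RunConfig) -> str:
        blob = json.dumps(config.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def identity(self) -> str:
        """Manifest hash excluding timestamps."""
        blob = json.dumps(
            {"config": self.config_hash, "inputs": self.input_digests,
             "version": self.tool_version, "seed": self.seed},
            sort_keys=True,
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def bed_to_1based(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open BED interval to 1-based inclusive."""
    if end0 <= start0:
        raise ValueError(f"empty/invalid BED interval [{start0}, {end0})")
    return start0 + 1, end0


def one_based_to_bed(start1: int, end1: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open BED."""
    if end1 < start1:
        raise ValueError(f"invalid 1-based interval [{start1}, {end1}]")
    return start1 - 1, end1
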