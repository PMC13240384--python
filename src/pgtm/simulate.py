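"""Family, genotype and read-depth simulators.

The generators reproduce the statistical structure the method assumes:
Mendelian transmission with map-distributed (Poisson) crossovers, the
exact allele-dropout/genotype-error observation model of the phasing
engine, and GC-biased negative-binomial read depth with copy-number
multipliers.  Everything is driven by a single ``numpy`` Generator so
seeded runs are fully reproducible.

The triploid observation model deserves a note: with three alleles at a
biallelic SNP, array callers face 1:2 allelic ratios that fall between the
diploid genotype clusters, so sites with a mixed-allele triple are called
heterozygous, homozygous-for-the-major-allele, or not at all, with the
no-call channel dominating.  This is what makes triploids detectable (and
haplotype construction infeasible) from hard genotype calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cnv as cnv_mod
from .types import (
    ALT,
    DELETED,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    RECESSIVE_BIALLELIC,
    REF,
    SEA_DELETION,
    DirectTestResult,
    GeneticMap,
    GenotypeTable,
    VariantLocus,
)

# triploid caller-confusion channel for mixed-allele (2:1) sites
TRIPLOID_P_MISSING = 0.40
TRIPLOID_P_HET = 0.45
TRIPLOID_P_HOM_MAJOR = 0.15


@dataclass
class SimScenario:
    """Everything needed to simulate one family.

    Ploidy events are keyed by embryo index: ``("trisomy", chrom)`` adds a
    depth-only extra copy of a whole chromosome, ``("monosomy", parent)``
    drops that parent's contribution on the variant chromosome,
    ``("triploid", "MI"|"MII")`` adds a full extra maternal genome (MI:
    both maternal haplotypes; MII: a duplicated single meiotic product).
    ``forced_transmission`` pins (paternal, maternal) haplotype indices at
    the variant locus, with the crossover process left intact.
    """

    variant: VariantLocus
    n_markers: int = 200
    n_inside_markers: int = 0
    window_bp: int = 5_000_000
    freq_range: tuple[float, float] = (0.2, 0.8)
    n_embryos: int = 4
    ado_rate: float = 0.05
    genotype_error: float = 0.01
    cm_per_mb: float = 1.0
    ploidy: dict[int, tuple] = field(default_factory=dict)
    forced_transmission: dict[int, tuple[int, int]] = field(default_factory=dict)
    embryo_prefix: str = "E"


@dataclass
class EmbryoTruth:
    embryo_id: str
    pat_indicator: np.ndarray   # haplotype index transmitted per marker
    mat_indicator: np.ndarray
    pat_var_hap: int            # index transmitted at the variant locus
    mat_var_hap: int
    crossovers: dict[str, list[int]]
    ploidy: tuple | None = None

    def true_status(self, variant: VariantLocus) -> str:
        carriers = variant.carrier_parents
        n_m = 0
        if "father" in carriers and self.pat_var_hap == 0:
            n_m += 1
        if "mother" in carriers and self.mat_var_hap == 0:
            n_m += 1
        if variant.inheritance == RECESSIVE_BIALLELIC:
            return {2: "affected", 1: "carrier", 0: "wild_type"}[n_m]
        return "carrier" if n_m else "wild_type"


@dataclass
class FamilyTruth:
    scenario: SimScenario
    markers: pd.DataFrame        # chrom,pos,ref,alt,freq,inside
    father_haps: np.ndarray      # (2, n_markers) allele codes
    mother_haps: np.ndarray
    gmap: GeneticMap
    embryos: list[EmbryoTruth]

    @property
    def positions(self) -> np.ndarray:
        return self.markers["pos"].to_numpy()


def uniform_genetic_map(chrom: str, lo: int, hi: int,
                        cm_per_mb: float = 1.0) -> GeneticMap:
    """Piecewise-linear map at a constant rate over [lo, hi]."""
    lo, hi = int(lo), int(hi)
    return GeneticMap(
        chrom=chrom,
        positions=np.array([lo, hi]),
        rate_cM_per_Mb=np.array([cm_per_mb, cm_per_mb]),
        cumulative_cM=np.array([0.0, (hi - lo) / 1e6 * cm_per_mb]),
    )


def _meiosis(gmap: GeneticMap, positions: np.ndarray, variant_pos: int,
             rng: np.random.Generator,
             forced_var_hap: int | None = None) -> tuple[np.ndarray, int, list[int]]:
    """One meiosis: Poisson crossovers on the cM scale, uniform start phase.

    Returns the transmitted-haplotype indicator at each marker, the
    indicator at the variant position, and crossover bp positions.  Forcing
    the indicator at the variant only fixes the (uniform) start phase, so
    the crossover process is untouched.
    """
    cm = np.asarray(gmap.interpolate_cM(positions), dtype=float)
    cm_var = float(gmap.interpolate_cM(variant_pos))
    cm_lo = min(cm.min(), cm_var)
    cm_hi = max(cm.max(), cm_var)
    total_m = (cm_hi - cm_lo) / 100.0
    n_x = rng.poisson(total_m)
    x_cm = np.sort(rng.uniform(cm_lo, cm_hi, size=n_x))
    parity = np.searchsorted(x_cm, cm, side="right") % 2
    parity_var = int(np.searchsorted(x_cm, cm_var, side="right") % 2)
    start = int(rng.integers(2))
    if forced_var_hap is not None:
        start = forced_var_hap ^ parity_var
    indicator = (start ^ parity).astype(np.int8)
    var_hap = start ^ parity_var
    x_bp = [int(np.interp(c, gmap.cumulative_cM, gmap.positions)) for c in x_cm]
    return indicator, var_hap, x_bp


def simulate_family(scenario: SimScenario, rng: np.random.Generator) -> FamilyTruth:
    """Draw founder haplotypes and per-embryo transmissions with truth kept.

    The variant rides haplotype 0 of each carrier parent; for deletion
    variants that haplotype carries no alleles inside the interval.
    """
    v = scenario.variant
    lo = max(1, v.anchor_pos - scenario.window_bp)
    hi = v.anchor_pos + scenario.window_bp
    pos: set[int] = set()
    while len(pos) < scenario.n_markers:
        pos.update(rng.integers(lo, hi + 1, size=scenario.n_markers).tolist())
    pos = set(rng.choice(sorted(pos), size=scenario.n_markers, replace=False).tolist())
    if scenario.n_inside_markers and v.kind == "deletion":
        extra = rng.integers(v.del_start, v.del_end + 1,
                             size=scenario.n_inside_markers)
        pos = sorted(set(pos) | set(int(x) for x in extra))
    positions = np.array(sorted(pos), dtype=np.int64)
    n = len(positions)

    f_lo, f_hi = scenario.freq_range
    freqs = rng.uniform(f_lo, f_hi, size=n)
    markers = pd.DataFrame({
        "chrom": v.chrom, "pos": positions,
        "ref": "A", "alt": "G", "freq": freqs,
        "inside": [v.contains(int(p)) for p in positions],
    })

    def founder(carrier: bool) -> np.ndarray:
        haps = (rng.random((2, n)) < freqs).astype(np.int8)
        if carrier and v.kind == "deletion":
            haps[0, markers["inside"].to_numpy()] = DELETED
        return haps

    carriers = set(v.carrier_parents)
    father_haps = founder("father" in carriers)
    mother_haps = founder("mother" in carriers)

    gmap = uniform_genetic_map(v.chrom, lo, hi, scenario.cm_per_mb)

    embryos = []
    for i in range(scenario.n_embryos):
        forced = scenario.forced_transmission.get(i, (None, None))
        pat, pv, fx = _meiosis(gmap, positions, v.anchor_pos, rng, forced[0])
        mat, mv, mx = _meiosis(gmap, positions, v.anchor_pos, rng, forced[1])
        embryos.append(EmbryoTruth(
            embryo_id=f"{scenario.embryo_prefix}{i + 1}",
            pat_indicator=pat, mat_indicator=mat,
            pat_var_hap=int(pv), mat_var_hap=int(mv),
            crossovers={"father": fx, "mother": mx},
            ploidy=scenario.ploidy.get(i),
        ))
    return FamilyTruth(scenario=scenario, markers=markers,
                       father_haps=father_haps, mother_haps=mother_haps,
                       gmap=gmap, embryos=embryos)


# ---------------------------------------------------------------------------
# Genotype observation
# ---------------------------------------------------------------------------

def _sample_observed(alleles: list[int], a: float, e: float,
                     rng: np.random.Generator) -> int:
    """Observe one genotype call from the allele multiset actually present.

    Diploid sites follow the phasing engine's emission model exactly
    (shared likelihood); hemizygous sites are read as the matching
    homozygote with error ``e``; triple-allele (triploid) mixed sites go
    through the caller-confusion channel; empty sites are no-calls.
    """
    alleles = [x for x in alleles if x != DELETED]
    if not alleles:
        return MISSING
    u = rng.random()
    if len(alleles) >= 3:
        if len(set(alleles)) == 1:
            true = 2 * alleles[0]
            return true if u < 1 - e else (HET if u < 1 - e / 2 else 2 - true)
        counts = np.bincount(alleles, minlength=2)
        major = int(np.argmax(counts))
        if u < TRIPLOID_P_MISSING:
            return MISSING
        if u < TRIPLOID_P_MISSING + TRIPLOID_P_HET:
            return HET
        return 2 * major
    if len(alleles) == 1:
        true = 2 * alleles[0]
        if u < 1 - e:
            return true
        return HET if u < 1 - e / 2 else 2 - true
    true = alleles[0] + alleles[1]
    if true == HET:
        if u < 1 - a - e:
            return HET
        return HOM_REF if u < 1 - (a + e) / 2 else HOM_ALT
    if u < 1 - e:
        return true
    return HET if u < 1 - e / 2 else 2 - true


def _embryo_alleles(truth: FamilyTruth, emb: EmbryoTruth, k: int) -> list[int]:
    """Allele multiset of one embryo at marker k, honouring ploidy events."""
    pat = [int(truth.father_haps[emb.pat_indicator[k], k])]
    mat = [int(truth.mother_haps[emb.mat_indicator[k], k])]
    if emb.ploidy:
        kind = emb.ploidy[0]
        if kind == "monosomy":
            if emb.ploidy[1] == "father":
                pat = []
            else:
                mat = []
        elif kind == "triploid":
            if emb.ploidy[1] == "MI":
                mat = [int(truth.mother_haps[0, k]), int(truth.mother_haps[1, k])]
            else:  # MII: duplicated single product
                mat = mat * 2
        # trisomy of a non-variant chromosome leaves window genotypes alone
    return pat + mat


def observe_genotypes(truth: FamilyTruth, a: float, e: float,
                      rng: np.random.Generator,
                      father_id: str = "father",
                      mother_id: str = "mother") -> GenotypeTable:
    """VCF-ready unphased calls for parents and all embryos."""
    n = len(truth.markers)
    samples = [father_id, mother_id] + [emb.embryo_id for emb in truth.embryos]
    gt = np.full((n, len(samples)), MISSING, dtype=np.int8)
    for k in range(n):
        f_all = [int(x) for x in truth.father_haps[:, k]]
        m_all = [int(x) for x in truth.mother_haps[:, k]]
        gt[k, 0] = _sample_observed(f_all, a, e, rng)
        gt[k, 1] = _sample_observed(m_all, a, e, rng)
        for j, emb in enumerate(truth.embryos):
            gt[k, 2 + j] = _sample_observed(_embryo_alleles(truth, emb, k), a, e, rng)
    sites = truth.markers[["chrom", "pos", "ref", "alt"]].copy().reset_index(drop=True)
    return GenotypeTable(sites=sites, gt=gt, samples=samples)


def observe_direct_test(truth: FamilyTruth, emb: EmbryoTruth,
                        rng: np.random.Generator,
                        failure_rate: float = 0.0,
                        ado_miss_rate: float = 0.0,
                        method: str = "sanger") -> DirectTestResult:
    """Direct mutation test from the embryo's true transmitted haplotypes.

    ``failure_rate`` models assay failure, ``ado_miss_rate`` the chance
    that dropout at the variant site makes a carrier read as wild type.
    """
    status = emb.true_status(truth.scenario.variant)
    # ploidy overrides for the variant chromosome
    if emb.ploidy:
        kind = emb.ploidy[0]
        if kind == "monosomy":
            lost = emb.ploidy[1]
            carriers = truth.scenario.variant.carrier_parents
            has = []
            if "father" in carriers and lost != "father" and emb.pat_var_hap == 0:
                has.append("father")
            if "mother" in carriers and lost != "mother" and emb.mat_var_hap == 0:
                has.append("mother")
            status = "carrier" if has else "wild_type"
        elif kind == "triploid" and emb.ploidy[1] == "MI":
            if "mother" in truth.scenario.variant.carrier_parents:
                status = "carrier" if status == "wild_type" else status
    if rng.random() < failure_rate:
        return DirectTestResult(emb.embryo_id, "failed", method)
    if status in ("carrier", "affected") and rng.random() < ado_miss_rate:
        status = "wild_type" if status == "carrier" else "carrier"
    return DirectTestResult(emb.embryo_id, status, method)


# ---------------------------------------------------------------------------
# Read-depth simulation
# ---------------------------------------------------------------------------

def gc_track(bins: pd.DataFrame) -> np.ndarray:
    """Deterministic smooth GC fraction per bin (a genome property, shared
    by sample and panel)."""
    mid = (bins["start"].to_numpy() + bins["end"].to_numpy()) / 2.0
    chrom_shift = np.array([sum(ord(ch) for ch in c) % 7 for c in bins["chrom"]],
                           dtype=float)
    return 0.45 + 0.07 * np.sin(mid / 1.3e6 + chrom_shift)


def _gc_bias(gc: np.ndarray) -> np.ndarray:
    """Smooth unimodal amplification-efficiency curve peaking near 0.47 GC."""
    return 0.55 + 0.45 * np.exp(-((gc - 0.47) ** 2) / (2 * 0.08 ** 2))


def _nb_counts(mu: np.ndarray, dispersion: float,
               rng: np.random.Generator) -> np.ndarray:
    """Negative binomial where ``dispersion`` is the extra multiplicative
    coefficient of variation beyond Poisson: var = mu + (dispersion*mu)^2,
    i.e. size = dispersion^-2."""
    if dispersion <= 0:
        return rng.poisson(mu)
    size = dispersion ** -2
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_depth_profile(bins: pd.DataFrame, rng: np.random.Generator,
                           events: list[tuple[str, int, int, float]] | None = None,
                           base_depth: float = 500.0,
                           dispersion: float = 0.1) -> pd.DataFrame:
    """Per-bin fragment counts for one sample.

    ``events`` are (chrom, start, end, effective_copy_number) — e.g. 3 for
    a trisomy, 1 for a loss, 2 + level for a mosaic gain.
    """
    df = bins.copy()
    if df["gc"].isna().any():
        df["gc"] = gc_track(df)
    cn = np.full(len(df), 2.0)
    for chrom, s, e, c in events or []:
        m = (df["chrom"] == chrom) & (df["start"] >= s) & (df["end"] <= e)
        cn[m.to_numpy()] = c
    mu = base_depth * _gc_bias(df["gc"].to_numpy()) * cn / 2.0
    df["count"] = _nb_counts(mu, dispersion, rng)
    return df


def simulate_panel(bins: pd.DataFrame, rng: np.random.Generator, n_ref: int = 8,
                   base_depth: float = 500.0, dispersion: float = 0.1,
                   loess_frac: float = 0.3) -> pd.DataFrame:
    """Reference panel: GC-normalised diploid control samples."""
    profs = []
    for _ in range(n_ref):
        p = simulate_depth_profile(bins, rng, base_depth=base_depth,
                                   dispersion=dispersion)
        profs.append(cnv_mod.gc_normalize(p, frac=loess_frac))
    return cnv_mod.build_reference_panel(profs)


# ---------------------------------------------------------------------------
# Packaged regression fixture (three families, ten embryos)
# ---------------------------------------------------------------------------

#: Synthetic genomic placements for the two frameshift variants: only cDNA
#: coordinates are published for these alleles, so the fixture places them
#: on small synthetic chromosomes (documented in docs/methods.md).
EXT1_VARIANT = VariantLocus(chrom="chr8", kind="point", gene="EXT1",
                            inheritance="dominant_maternal",
                            pos=8_000_000, ref="CT", alt="C",
                            build="synthetic")
CUL3_VARIANT = VariantLocus(chrom="chr2", kind="point", gene="CUL3",
                            inheritance="dominant_paternal",
                            pos=8_000_000, ref="TTG", alt="T",
                            build="synthetic")

COHORT_FIXTURE_SEED = 20230


@dataclass
class FamilyBundle:
    family_id: str
    variant: VariantLocus
    truth: FamilyTruth
    genotypes: GenotypeTable
    gmap: GeneticMap
    direct_tests: dict[str, DirectTestResult]
    proband_id: str
    embryo_ids: list[str]
    chrom_sizes: dict[str, int]
    arms: dict[str, int]
    depth_profiles: dict[str, pd.DataFrame]
    panel: pd.DataFrame


def _family_bundle(family_id: str, variant: VariantLocus, seed: int,
                   statuses: list[str], ploidy: dict[int, tuple],
                   depth_trisomy: set[int], aneu_chrom: str = "chr21",
                   n_markers: int = 140, n_inside: int = 0) -> FamilyBundle:
    """Deterministic family with prescribed per-embryo carrier statuses."""
    rng = np.random.default_rng(seed)
    carriers = set(variant.carrier_parents)

    forced: dict[int, tuple[int, int]] = {}
    for i, st in enumerate(statuses):
        if variant.inheritance == RECESSIVE_BIALLELIC:
            if st == "carrier_father":
                forced[i] = (0, 1)
            elif st == "carrier_mother":
                forced[i] = (1, 0)
            elif st == "affected":
                forced[i] = (0, 0)
            else:
                forced[i] = (1, 1)
        else:
            m = 0 if st == "carrier" else 1
            if "father" in carriers:
                forced[i] = (m, None)
            else:
                forced[i] = (None, m)

    scn = SimScenario(
        variant=variant, n_markers=n_markers, n_inside_markers=n_inside,
        n_embryos=len(statuses), ado_rate=0.0, genotype_error=0.0,
        ploidy=ploidy, forced_transmission=forced,
        embryo_prefix=f"{family_id}-",
    )
    truth = simulate_family(scn, rng)
    genotypes = observe_genotypes(truth, 0.0, 0.0, rng)
    direct = {e.embryo_id: observe_direct_test(truth, e, rng)
              for e in truth.embryos}

    # proband: the (first) embryo that demonstrably carries the variant
    proband_id = next(e.embryo_id for e in truth.embryos
                      if direct[e.embryo_id].call in ("affected", "carrier")
                      and e.ploidy is None)

    var_size = ((variant.anchor_pos + scn.window_bp) // 1_000_000 + 2) * 1_000_000
    # a diploid filler chromosome keeps the aneuploid fraction of the genome
    # realistic, so the median-ratio baseline stays copy-neutral
    chrom_sizes = {variant.chrom: max(var_size, 30_000_000),
                   "chr5": 40_000_000, aneu_chrom: 12_000_000}
    arms = {c: int(0.4 * s) for c, s in chrom_sizes.items()}
    bins = cnv_mod.make_bins(chrom_sizes)
    bins["gc"] = gc_track(bins)

    depth = {}
    for i, e in enumerate(truth.embryos):
        events = []
        if i in depth_trisomy:
            events.append((aneu_chrom, 1, chrom_sizes[aneu_chrom], 3.0))
        depth[e.embryo_id] = simulate_depth_profile(bins, rng, events=events)
    panel = simulate_panel(bins, rng, n_ref=6)

    return FamilyBundle(
        family_id=family_id, variant=variant, truth=truth,
        genotypes=genotypes, gmap=truth.gmap, direct_tests=direct,
        proband_id=proband_id,
        embryo_ids=[e.embryo_id for e in truth.embryos],
        chrom_sizes=chrom_sizes, arms=arms,
        depth_profiles=depth, panel=panel,
    )


def make_cohort_fixture(seed: int = COHORT_FIXTURE_SEED) -> list[FamilyBundle]:
    """The packaged three-family, ten-embryo regression dataset.

    Family 1: both parents carry a ~19.3-kb alpha-globin cluster deletion
    (recessive); the proband embryo is a paternal-origin carrier, two
    siblings are deletion-free, and one embryo is a digynic MII-type
    triploid whose haplotype construction fails on genotyping QC.
    Family 2: a de novo maternal dominant frameshift; one carrier embryo
    (the proband), three wild-type.  Family 3: a de novo paternal dominant
    frameshift; one carrier (the proband), one wild-type.  CNV-abnormal
    embryos carry a whole-chromosome trisomy of a second chromosome.
    """
    f1 = _family_bundle(
        "E1", SEA_DELETION, seed,
        statuses=["wild_type", "carrier_father", "wild_type", "wild_type"],
        ploidy={3: ("triploid", "MII")},
        depth_trisomy={0, 1},
        n_markers=140, n_inside=4,
    )
    f2 = _family_bundle(
        "E2", EXT1_VARIANT, seed + 1,
        statuses=["wild_type", "wild_type", "wild_type", "carrier"],
        ploidy={},
        depth_trisomy={0, 1},
        n_markers=140,
    )
    f3 = _family_bundle(
        "E3", CUL3_VARIANT, seed + 2,
        statuses=["wild_type", "carrier"],
        ploidy={},
        depth_trisomy={0, 1},
        n_markers=140,
    )
    return [f1, f2, f3]
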