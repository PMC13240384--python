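"""Embryo-as-proband parental haplotype phasing and inheritance decoding.

The method phases the two parental haplotypes around a pathogenic variant
using an embryo with a confirmed direct mutation test as the proband, then
decodes, for every embryo, which parental haplotype was transmitted at each
informative SNP.  Decoding is exact Viterbi over a 4-state HMM — the hidden
state at each marker is the pair (paternal haplotype, maternal haplotype)
transmitted to the embryo — with transition probabilities derived from
genetic-map recombination fractions (Haldane map function) and emissions
from an allele-dropout + genotype-error observation model.

Haplotype labels: for a carrier parent, index 0 is M (the mutant-linked
haplotype) and index 1 is N (the normal homolog); for a non-carrier parent
the labels are H1 (the haplotype the proband inherited) and H2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    ALT,
    DELETED,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    REF,
    RECESSIVE_BIALLELIC,
    DirectTestResult,
    GeneticMap,
    GenotypeTable,
    VariantLocus,
)

log = logging.getLogger(__name__)

PARENTS = ("father", "mother")

#: Marker classes.  ``deletion_hemi`` covers inside-deletion sites in a
#: both-carrier family where each parent is hemizygous and the parents'
#: apparent homozygous alleles differ — the sites that reveal which parent's
#: deletion the proband inherited.
PATERNAL_ONLY = "paternal_only"
MATERNAL_ONLY = "maternal_only"
DOUBLE_HET = "double_het"
DELETION_HEMI = "deletion_hemi"

_TIE_TOL = 1e-9


# ---------------------------------------------------------------------------
# Emission model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmissionModel:
    """Symmetric allele-dropout (ADO) + genotype-error observation model.

    A true heterozygote is observed het with probability ``1 - a - e`` and
    as either homozygote with probability ``(a + e) / 2`` each (dropout of
    either allele, or an outright call error).  A true homozygote is read
    correctly with probability ``1 - e``, the two wrong classes sharing
    ``e``.  A missing observation carries no information (probability 1).
    """

    ado_rate: float = 0.05
    genotype_error: float = 0.01

    def __post_init__(self) -> None:
        a, e = self.ado_rate, self.genotype_error
        if not (0 <= a < 1 and 0 <= e < 1 and a + e < 1):
            raise ValueError("require 0 <= ado_rate, genotype_error and a + e < 1")

    def prob(self, true_genotype: int, observed: int) -> float:
        """P(observed genotype class | true diploid genotype class)."""
        if observed == MISSING:
            return 1.0
        a, e = self.ado_rate, self.genotype_error
        if true_genotype == HET:
            return 1.0 - a - e if observed == HET else (a + e) / 2.0
        if observed == true_genotype:
            return 1.0 - e
        return e / 2.0

    def prob_hemizygous(self, present_allele_class: int, observed: int) -> float:
        """Observation probability for a hemizygous locus (one allele present).

        The single allele is read as the matching homozygote; dropout of the
        lone allele surfaces as a no-call, which is uninformative here, so
        only the genotype-error channel applies to non-missing calls.
        """
        if observed == MISSING:
            return 1.0
        e = self.genotype_error
        return 1.0 - e if observed == present_allele_class else e / 2.0

    def prob_null(self, observed: int) -> float:
        """Observation probability when no DNA is present (both haplotypes
        deleted): any concrete call can only arise from error."""
        if observed == MISSING:
            return 1.0
        return self.genotype_error


def emission_prob(model: EmissionModel, true_genotype: int, observed: int) -> float:
    """Functional wrapper around :meth:`EmissionModel.prob`."""
    return model.prob(true_genotype, observed)


def _emission_from_alleles(present: list[int], observed: int, model: EmissionModel) -> float:
    """Observation probability given the transmitted alleles actually present
    (0/1 allele codes; deleted haplotypes contribute nothing)."""
    if observed == MISSING:
        return 1.0
    if len(present) == 2:
        true_gt = present[0] + present[1]  # 0,1,2 == hom_ref, het, hom_alt
        return model.prob(true_gt, observed)
    if len(present) == 1:
        return model.prob_hemizygous(2 * present[0], observed)
    return model.prob_null(observed)


# ---------------------------------------------------------------------------
# Recombination fractions
# ---------------------------------------------------------------------------

def recombination_fraction(gmap: GeneticMap, pos_i: int, pos_j: int) -> float:
    """Recombination fraction between two positions on one chromosome.

    Haldane map function (no interference): r = (1 - exp(-2 d)) / 2 with d
    the genetic distance in Morgans, consistent with a Poisson crossover
    process.  r = 0 at zero map distance and r < 0.5 always.
    """
    if pos_i >= pos_j:
        raise ValueError("require pos_i < pos_j")
    d_cm = abs(float(gmap.interpolate_cM(pos_j)) - float(gmap.interpolate_cM(pos_i)))
    d = d_cm / 100.0
    return 0.5 * (1.0 - math.exp(-2.0 * d))


# ---------------------------------------------------------------------------
# Informative-marker selection
# ---------------------------------------------------------------------------

@dataclass
class InformativeSnp:
    """A phase-anchorable marker around the pathogenic variant.

    ``father_haps``/``mother_haps`` give the allele carried by haplotype 0
    (M or H1) and haplotype 1 (N or H2); ``None`` until the phase at this
    marker is resolved.  ``DELETED`` marks an allele that is physically
    absent (carrier parent inside a deletion).
    """

    site_index: int
    chrom: str
    pos: int
    ref: str
    alt: str
    klass: str
    father_gt: int
    mother_gt: int
    inside_deletion: bool = False
    father_haps: tuple[int, int] | None = None
    mother_haps: tuple[int, int] | None = None
    father_provenance: str = "unresolved"
    mother_provenance: str = "unresolved"

    def haps(self, parent: str) -> tuple[int, int] | None:
        return self.father_haps if parent == "father" else self.mother_haps

    def set_haps(self, parent: str, haps: tuple[int, int], provenance: str) -> None:
        if parent == "father":
            self.father_haps, self.father_provenance = haps, provenance
        else:
            self.mother_haps, self.mother_provenance = haps, provenance

    def provenance(self, parent: str) -> str:
        return self.father_provenance if parent == "father" else self.mother_provenance

    def set_haps_raw(self, parent: str, haps: tuple[int, int] | None) -> None:
        if parent == "father":
            self.father_haps = haps
        else:
            self.mother_haps = haps

    def set_provenance(self, parent: str, provenance: str) -> None:
        if parent == "father":
            self.father_provenance = provenance
        else:
            self.mother_provenance = provenance

    def parent_gt(self, parent: str) -> int:
        return self.father_gt if parent == "father" else self.mother_gt


def _gt_alleles(gt: int) -> tuple[int, int] | None:
    if gt == HOM_REF:
        return (REF, REF)
    if gt == HET:
        return (REF, ALT)
    if gt == HOM_ALT:
        return (ALT, ALT)
    return None


def select_informative_snps(
    table: GenotypeTable,
    variant: VariantLocus,
    window_bp: int,
    father_id: str = "father",
    mother_id: str = "mother",
) -> list[InformativeSnp]:
    """Select heterozygous SNPs within ``window_bp`` of the variant.

    Retained classes: one parent het / other hom (paternal_only or
    maternal_only), both het (double_het — kept for likelihood but never
    used as an anchor), and, for deletion variants in both-carrier
    families, inside-deletion sites where both parents appear homozygous
    for different alleles (deletion_hemi).  Sites with a missing parent,
    both parents homozygous (outside the deletion case) or non-SNP alleles
    are excluded.
    """
    lo = variant.anchor_pos - window_bp
    hi = variant.anchor_pos + window_bp
    fgt = table.sample_gt(father_id)
    mgt = table.sample_gt(mother_id)
    carriers = set(variant.carrier_parents)
    out: list[InformativeSnp] = []
    for i, row in enumerate(table.sites.itertuples(index=False)):
        if row.chrom != variant.chrom or not (lo <= row.pos <= hi):
            continue
        if len(row.ref) != 1 or len(row.alt) != 1:
            continue  # biallelic SNP markers only
        f, m = int(fgt[i]), int(mgt[i])
        if f == MISSING or m == MISSING:
            continue
        inside = variant.contains(row.pos)
        if inside:
            # a deletion-carrier parent is hemizygous here: an apparent het
            # from such a parent is incoherent — drop the site
            if ("father" in carriers and f == HET) or ("mother" in carriers and m == HET):
                continue
        if f == HET and m == HET:
            klass = DOUBLE_HET
        elif f == HET:
            klass = PATERNAL_ONLY
        elif m == HET:
            klass = MATERNAL_ONLY
        elif inside and carriers == {"father", "mother"} and f != m:
            klass = DELETION_HEMI
        else:
            continue  # both homozygous (or identical hemizygous): uninformative
        snp = InformativeSnp(
            site_index=i, chrom=row.chrom, pos=int(row.pos),
            ref=row.ref, alt=row.alt, klass=klass,
            father_gt=f, mother_gt=m, inside_deletion=inside,
        )
        # trivially known phases
        for parent, gt in (("father", f), ("mother", m)):
            if inside and parent in carriers:
                # hemizygous: haplotype 0 (M) is deleted, N carries the
                # apparent homozygous allele
                snp.set_haps(parent, (DELETED, REF if gt == HOM_REF else ALT), "deletion")
            elif gt in (HOM_REF, HOM_ALT):
                a = REF if gt == HOM_REF else ALT
                snp.set_haps(parent, (a, a), "hom")
        out.append(snp)
    out.sort(key=lambda s: s.pos)
    if not out:
        raise ValueError("no informative markers in window")
    return out


# ---------------------------------------------------------------------------
# Proband anchoring
# ---------------------------------------------------------------------------

@dataclass
class PhasedParents:
    """Phased parental haplotypes over the informative markers.

    ``proband_expected`` records, per parent, the haplotype index the
    proband inherited (0 = M/H1): the anchoring convention that makes the
    proband's own decoded path the all-zeros path in the noise-free,
    crossover-free case.
    """

    markers: list[InformativeSnp]
    variant: VariantLocus
    proband_id: str
    proband_expected: dict[str, int]
    deletion_origin: str | None = None

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.pos for m in self.markers], dtype=np.int64)

    def hap_label(self, parent: str, index: int) -> str:
        if parent in self.variant.carrier_parents:
            return "M" if index == 0 else "N"
        return "H1" if index == 0 else "H2"

    def to_frame(self) -> pd.DataFrame:
        """Phase table: marker, parent, hap-0 allele, hap-1 allele, provenance."""
        rows = []
        for mk in self.markers:
            for parent in PARENTS:
                haps = mk.haps(parent)

                def _a(code: int) -> str:
                    if code == DELETED:
                        return "<DEL>"
                    return mk.ref if code == REF else mk.alt

                rows.append({
                    "chrom": mk.chrom, "pos": mk.pos, "parent": parent,
                    "class": mk.klass,
                    self.hap_label(parent, 0): _a(haps[0]) if haps else ".",
                    self.hap_label(parent, 1): _a(haps[1]) if haps else ".",
                    "provenance": mk.provenance(parent),
                })
        return pd.DataFrame(rows)


def _transmitted_allele(het_gt_alleles: tuple[int, int],
                        other_allele: int | None,
                        obs: int) -> int | None:
    """Infer which allele the het parent transmitted to the proband.

    ``other_allele`` is the allele contributed by the other parent (None when
    the proband is hemizygous there).  Returns None when the observation is
    missing or inconsistent (possible dropout) — no anchor is taken.
    """
    pair = _gt_alleles(obs)
    if pair is None:
        return None
    if other_allele is None:
        # hemizygous proband: a het observation is incoherent
        if pair[0] != pair[1]:
            return None
        t = pair[0]
    else:
        rest = list(pair)
        if other_allele not in rest:
            return None
        rest.remove(other_allele)
        t = rest[0]
    return t if t in het_gt_alleles else None


def resolve_deletion_origin(markers: list[InformativeSnp],
                            proband_obs: np.ndarray,
                            model: EmissionModel) -> str | None:
    """Decide which parent's deletion a carrier proband inherited.

    Inside the deletion the proband is hemizygous: the lone observed allele
    is the transmitted *normal* haplotype of the other parent.  Each origin
    hypothesis is scored by the emission likelihood of the proband's calls
    at inside-deletion markers; ties (or no usable markers) return None.
    """
    scores = {"father": 0.0, "mother": 0.0}
    used = 0
    for k, mk in enumerate(markers):
        if not mk.inside_deletion:
            continue
        obs = int(proband_obs[k])
        if obs == MISSING:
            continue
        usable = False
        for hyp in PARENTS:
            other = "mother" if hyp == "father" else "father"
            haps = mk.haps(other)
            if haps is None or haps[1] == DELETED:
                continue
            # under `hyp`, the proband's DNA here is the other parent's
            # transmitted N haplotype allele
            # floor keeps a zero-probability hypothesis finite (and losing)
            scores[hyp] += math.log(max(model.prob_hemizygous(2 * haps[1], obs), 1e-12))
            usable = True
        if usable:
            used += 1
    if used == 0:
        return None
    if abs(scores["father"] - scores["mother"]) <= _TIE_TOL:
        return None
    return max(scores, key=scores.get)


def anchor_parental_phase(
    markers: list[InformativeSnp],
    proband_obs: np.ndarray,
    proband_direct: DirectTestResult,
    variant: VariantLocus,
    model: EmissionModel | None = None,
) -> PhasedParents:
    """Anchor each parent's M/N (or H1/H2) haplotypes using the proband.

    The proband must demonstrably carry the variant (direct test carrier or
    affected).  At every single-parent-het marker where the proband's
    genotype determines the transmitted allele, that allele is labelled M
    for a carrier parent that passed the variant to the proband, N for a
    carrier parent that did not (recessive carrier proband), and H1 for a
    non-carrier parent.  Anchoring assumes the proband has no crossover in
    the window; ``decode_paths`` later flags markers conflicting with the
    proband's own decoded path.
    """
    if proband_direct.call not in ("carrier", "affected"):
        raise ValueError(
            f"proband {proband_direct.embryo_id} does not carry the variant "
            f"(direct test: {proband_direct.call})"
        )
    model = model or EmissionModel()
    carriers = set(variant.carrier_parents)

    # which parents transmitted the variant to the proband
    transmitted_m: set[str]
    deletion_origin = None
    if variant.inheritance == RECESSIVE_BIALLELIC:
        if proband_direct.call == "affected":
            transmitted_m = {"father", "mother"}
        else:
            deletion_origin = resolve_deletion_origin(markers, proband_obs, model)
            if deletion_origin is None:
                raise ValueError(
                    "cannot resolve parental origin of the variant for a "
                    "recessive carrier proband: need inside-deletion markers "
                    "with discriminating parental alleles, or an affected "
                    "embryo to use as proband"
                )
            transmitted_m = {deletion_origin}
    else:
        transmitted_m = carriers  # single carrier parent passed M

    # expected proband haplotype index per parent under the labelling
    expected = {}
    for parent in PARENTS:
        if parent in carriers:
            expected[parent] = 0 if parent in transmitted_m else 1
        else:
            expected[parent] = 0  # H1 := proband-transmitted by convention

    for k, mk in enumerate(markers):
        if mk.klass == DOUBLE_HET:
            continue  # no unambiguous anchor (down-weighted at decode time)
        obs = int(proband_obs[k])
        for parent in PARENTS:
            if mk.parent_gt(parent) != HET or mk.haps(parent) is not None:
                continue
            other = "mother" if parent == "father" else "father"
            ohaps = mk.haps(other)
            if ohaps is None:
                continue
            # allele the other parent contributed to the proband
            oidx = expected[other]
            other_allele = ohaps[oidx] if ohaps[oidx] != DELETED else None
            t = _transmitted_allele((REF, ALT), other_allele, obs)
            if t is None:
                continue  # missing or dropout-inconsistent: unresolved
            o = ALT if t == REF else REF
            haps = (t, o) if expected[parent] == 0 else (o, t)
            mk.set_haps(parent, haps, "proband")

    return PhasedParents(
        markers=markers, variant=variant,
        proband_id=proband_direct.embryo_id,
        proband_expected=expected,
        deletion_origin=deletion_origin,
    )


# ---------------------------------------------------------------------------
# Viterbi decoding
# ---------------------------------------------------------------------------

@dataclass
class InheritancePath:
    """Per-embryo Viterbi decoding of transmitted parental haplotypes.

    ``paternal``/``maternal`` hold the haplotype index (0 = M/H1, 1 = N/H2)
    at every marker; ``skipped`` marks markers with a missing embryo call
    (decoded by interpolation only).  ``margin`` is the log-probability gap
    to the second-best path.
    """

    embryo_id: str
    paternal: np.ndarray
    maternal: np.ndarray
    skipped: np.ndarray
    log_prob: float
    margin: float
    breakpoints: dict[str, list[tuple[int, int]]]
    failed: bool = False
    failure_reason: str = ""

    @property
    def n_switches(self) -> int:
        return int(np.sum(np.diff(self.paternal) != 0) + np.sum(np.diff(self.maternal) != 0))

    def to_frame(self, positions: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame({
            "pos": positions,
            "paternal": self.paternal,
            "maternal": self.maternal,
            "skipped": self.skipped.astype(int),
        })


def _parent_hap_options(mk: InformativeSnp, parent: str) -> list[tuple[tuple[int, int], float]]:
    """Phase hypotheses for one parent at one marker, with weights.

    A resolved marker contributes its single assignment; an unresolved het
    marker is marginalised over both orders (weight 1/2 each).
    """
    haps = mk.haps(parent)
    if haps is not None:
        return [(haps, 1.0)]
    return [((REF, ALT), 0.5), ((ALT, REF), 0.5)]


def emission_matrix(markers: list[InformativeSnp], obs: np.ndarray,
                    model: EmissionModel) -> np.ndarray:
    """(n_markers, 4) emission probabilities for one embryo.

    State s encodes (paternal index, maternal index) as s = 2*pi + mi.
    Unresolved parental phases are marginalised.
    """
    n = len(markers)
    E = np.ones((n, 4))
    for k, mk in enumerate(markers):
        o = int(obs[k])
        if o == MISSING:
            continue
        fopts = _parent_hap_options(mk, "father")
        mopts = _parent_hap_options(mk, "mother")
        for s in range(4):
            fi, mi = s >> 1, s & 1
            p = 0.0
            for fh, fw in fopts:
                for mh, mw in mopts:
                    present = [a for a in (fh[fi], mh[mi]) if a != DELETED]
                    p += fw * mw * _emission_from_alleles(present, o, model)
            E[k, s] = p
    return E


_N_SWITCH = np.zeros((4, 4), dtype=int)
for _s in range(4):
    for _t in range(4):
        _N_SWITCH[_s, _t] = ((_s >> 1) != (_t >> 1)) + ((_s & 1) != (_t & 1))


def _transition_logs(r: float) -> np.ndarray:
    """(4, 4) log transition matrix for one marker gap: independent
    per-parent switch (probability r) / stay (1 - r)."""
    with np.errstate(divide="ignore"):
        ls, lw = np.log(1.0 - r), np.log(r) if r > 0 else -np.inf
    T = np.empty((4, 4))
    for s in range(4):
        for t in range(4):
            nsw = _N_SWITCH[s, t]
            T[s, t] = nsw * lw + (2 - nsw) * ls
    return T


def _tuple_better(a: tuple[float, int], b: tuple[float, int], tol: float = _TIE_TOL) -> bool:
    """Is score-tuple ``a`` (log-prob, -switches) strictly better than ``b``?"""
    if a[0] > b[0] + tol:
        return True
    if b[0] > a[0] + tol:
        return False
    return a[1] > b[1]


def _tuple_equal(a: tuple[float, int], b: tuple[float, int], tol: float) -> bool:
    return abs(a[0] - b[0]) <= tol and a[1] == b[1]


def viterbi_decode(log_emis: np.ndarray, trans_logs: list[np.ndarray]
                   ) -> tuple[np.ndarray, float, float]:
    """Exact max-log-probability decoding over the 4-state trellis.

    Ties are broken toward the path with fewer haplotype switches, then
    lexicographically (haplotype 0, i.e. M, preferred) — a deterministic
    rule implemented via a suffix DP over (log-prob, -switches) tuples and
    a greedy left-to-right reconstruction.  Also returns the Viterbi
    log-probability and the margin to the second-best path.
    """
    n = log_emis.shape[0]
    log_init = -math.log(4.0)
    tol = _TIE_TOL * max(n, 1)

    # suffix DP: best (logp, -switches) of a path from marker k given state s
    suf = np.empty((n, 4), dtype=object)
    for s in range(4):
        suf[n - 1, s] = (log_emis[n - 1, s], 0)
    for k in range(n - 2, -1, -1):
        T = trans_logs[k]
        for s in range(4):
            best = None
            for t in range(4):
                nxt = suf[k + 1, t]
                cand = (T[s, t] + nxt[0], -_N_SWITCH[s, t] + nxt[1])
                if best is None or _tuple_better(cand, best):
                    best = cand
            suf[k, s] = (log_emis[k, s] + best[0], best[1])

    # global optimum and greedy reconstruction (lexicographically smallest)
    best = None
    for s in range(4):
        cand = (log_init + suf[0, s][0], suf[0, s][1])
        if best is None or _tuple_better(cand, best):
            best = cand
    path = np.zeros(n, dtype=np.int8)
    prefix = (log_init, 0)
    prev = None
    for k in range(n):
        for s in range(4):
            if prev is None:
                step_lp, step_sw = 0.0, 0
            else:
                step_lp = trans_logs[k - 1][prev, s]
                step_sw = -_N_SWITCH[prev, s]
            total = (prefix[0] + step_lp + suf[k, s][0],
                     prefix[1] + step_sw + suf[k, s][1])
            if _tuple_equal(total, best, tol):
                path[k] = s
                prefix = (prefix[0] + step_lp + log_emis[k, s],
                          prefix[1] + step_sw)
                prev = s
                break
        else:  # pragma: no cover - defensive; DP guarantees a match
            raise RuntimeError("Viterbi reconstruction failed")

    log_prob = best[0]

    # second-best path score via top-2 Viterbi (scores only)
    tops = [[(log_init + log_emis[0, s], )] for s in range(4)]
    for k in range(1, n):
        T = trans_logs[k - 1]
        new = []
        for t in range(4):
            cands = [x[0] + T[s, t] for s in range(4) for x in tops[s]]
            cands.sort(reverse=True)
            new.append([(c + log_emis[k, t],) for c in cands[:2]])
        tops = new
    finals = sorted((x[0] for s in range(4) for x in tops[s]), reverse=True)
    margin = finals[0] - finals[1] if len(finals) > 1 else math.inf

    return path, log_prob, margin


def _breakpoints(path_parent: np.ndarray, positions: np.ndarray) -> list[tuple[int, int]]:
    out = []
    for k in np.flatnonzero(np.diff(path_parent) != 0):
        out.append((int(positions[k]), int(positions[k + 1])))
    return out


def decode_paths(
    phased: PhasedParents,
    embryo_obs: dict[str, np.ndarray],
    model: EmissionModel,
    gmap: GeneticMap,
    refine_rounds: int = 2,
) -> tuple[dict[str, InheritancePath], PhasedParents]:
    """Decode every embryo's inheritance path; refine unresolved phases.

    Runs ``refine_rounds`` rounds of coordinate ascent between (a) Viterbi
    decoding of all embryos given the current parental phase and (b)
    assignment of still-unresolved marker phases by maximising the joint
    emission likelihood across the decoded embryo states.  Afterwards,
    proband-anchored markers whose anchor conflicts with the proband's own
    decoded path (a possible proband crossover) are flagged ``conflicted``
    and excluded from other embryos' diagnoses.
    """
    markers = phased.markers
    positions = phased.positions
    n = len(markers)
    trans_logs = [
        _transition_logs(recombination_fraction(gmap, int(positions[k]), int(positions[k + 1]))
                         if positions[k + 1] > positions[k] else 0.0)
        for k in range(n - 1)
    ]

    paths: dict[str, InheritancePath] = {}

    def decode_all() -> None:
        for eid, obs in embryo_obs.items():
            skipped = np.asarray(obs) == MISSING
            if skipped.all():
                paths[eid] = InheritancePath(
                    embryo_id=eid,
                    paternal=np.zeros(n, dtype=np.int8),
                    maternal=np.zeros(n, dtype=np.int8),
                    skipped=skipped, log_prob=-math.inf, margin=0.0,
                    breakpoints={"father": [], "mother": []},
                    failed=True, failure_reason="all markers missing",
                )
                continue
            with np.errstate(divide="ignore"):
                logE = np.log(emission_matrix(markers, obs, model))
            path, lp, margin = viterbi_decode(logE, trans_logs)
            pat = (path >> 1).astype(np.int8)
            mat = (path & 1).astype(np.int8)
            paths[eid] = InheritancePath(
                embryo_id=eid, paternal=pat, maternal=mat, skipped=skipped,
                log_prob=lp, margin=margin,
                breakpoints={"father": _breakpoints(pat, positions),
                             "mother": _breakpoints(mat, positions)},
            )

    def refine_phases() -> int:
        changed = 0
        for k, mk in enumerate(markers):
            for parent in PARENTS:
                if mk.haps(parent) is not None or mk.parent_gt(parent) != HET \
                        or mk.provenance(parent) == "conflicted":
                    continue
                scores = {}
                for order in ((REF, ALT), (ALT, REF)):
                    total = 0.0
                    for eid, obs in embryo_obs.items():
                        pth = paths[eid]
                        if pth.failed or int(obs[k]) == MISSING:
                            continue
                        fi = int(pth.paternal[k]); mi = int(pth.maternal[k])
                        other = "mother" if parent == "father" else "father"
                        oi = mi if parent == "father" else fi
                        si = fi if parent == "father" else mi
                        p = 0.0
                        for oh, ow in _parent_hap_options(mk, other):
                            pres = [a for a in (order[si], oh[oi]) if a != DELETED]
                            p += ow * _emission_from_alleles(pres, int(obs[k]), model)
                        total += math.log(max(p, 1e-300))
                    scores[order] = total
                a, b = scores[(REF, ALT)], scores[(ALT, REF)]
                if abs(a - b) > _TIE_TOL:
                    mk.set_haps(parent, (REF, ALT) if a > b else (ALT, REF), "inferred")
                    changed += 1
        return changed

    def flag_conflicts() -> int:
        """Mark proband-anchored markers whose anchor disagrees with the
        proband's own decoded path: a proband crossover or a proband
        dropout at anchoring time."""
        if phased.proband_id not in paths or paths[phased.proband_id].failed:
            return 0
        ppath = paths[phased.proband_id]
        n = 0
        for k, mk in enumerate(markers):
            for parent in PARENTS:
                if mk.provenance(parent) != "proband":
                    continue
                decoded = int(ppath.paternal[k] if parent == "father" else ppath.maternal[k])
                if decoded != phased.proband_expected[parent]:
                    mk.set_haps(parent, mk.haps(parent), "conflicted")
                    n += 1
        return n

    decode_all()
    for _ in range(refine_rounds):
        if refine_phases() == 0:
            break
        decode_all()

    if flag_conflicts():
        # a conflicted anchor may have poisoned every phase inferred from
        # it: drop conflicted anchors and inferred phases, then re-infer
        # from the surviving anchors via path continuity
        for mk in markers:
            for parent in PARENTS:
                prov = mk.provenance(parent)
                if prov == "conflicted":
                    mk.set_haps_raw(parent, None)
                elif prov == "inferred":
                    mk.set_haps_raw(parent, None)
                    mk.set_provenance(parent, "unresolved")
        decode_all()
        for _ in range(refine_rounds):
            if refine_phases() == 0:
                break
            decode_all()

    return paths, phased


# ---------------------------------------------------------------------------
# Ploidy gate
# ---------------------------------------------------------------------------

# offspring genotype classes possible under diploid biparental inheritance,
# keyed by (father class, mother class)
_MENDEL: dict[tuple[int, int], set[int]] = {}
for _f in (HOM_REF, HET, HOM_ALT):
    for _m in (HOM_REF, HET, HOM_ALT):
        fa = _gt_alleles(_f)
        ma = _gt_alleles(_m)
        _MENDEL[(_f, _m)] = {x + y for x in set(fa) for y in set(ma)}


@dataclass(frozen=True)
class PloidyStatus:
    ok: bool
    reason: str = ""


def detect_ploidy_failure(
    window_table: GenotypeTable,
    embryo_id: str,
    cnv_segments: pd.DataFrame | None = None,
    variant_chrom: str | None = None,
    father_id: str = "father",
    mother_id: str = "mother",
    mendel_threshold: float = 0.10,
    het_excess_threshold: float = 0.75,
    nocall_threshold: float = 0.10,
    exclude_positions: set[int] | None = None,
) -> PloidyStatus:
    """Gate an embryo on evidence of non-disomic copy number in the window.

    Three SNP-based signals plus the read-depth CNV result:

    * reported CNV segment on the variant chromosome (from the depth module);
    * Mendelian-inconsistency fraction over *constrained* sites (sites where
      at least one offspring class is impossible) above ``mendel_threshold``
      — catches monosomy / uniparental DNA;
    * heterozygosity excess at one-parent-het sites (either parent) above
      ``het_excess_threshold`` — catches extra-genome (triploid) events that
      duplicate both of one parent's haplotypes and are Mendel-consistent at
      every site;
    * no-call excess above ``nocall_threshold`` — array callers fail on the
      intermediate allelic ratios of triploids, so haplotype construction
      has too few usable markers.
    """
    if cnv_segments is not None and variant_chrom is not None and len(cnv_segments):
        bad = cnv_segments[
            (cnv_segments["chrom"] == variant_chrom)
            & (cnv_segments["class"] != "neutral")
        ]
        if len(bad):
            return PloidyStatus(False, "cnv_aneuploid")

    fgt = window_table.sample_gt(father_id)
    mgt = window_table.sample_gt(mother_id)
    egt = window_table.sample_gt(embryo_id)
    pos = window_table.sites["pos"].to_numpy()
    keep = np.ones(len(pos), dtype=bool)
    if exclude_positions:
        keep = ~np.isin(pos, list(exclude_positions))

    parents_known = (fgt != MISSING) & (mgt != MISSING) & keep
    observed = parents_known & (egt != MISSING)

    # no-call excess (among sites where both parents genotyped)
    n_known = int(parents_known.sum())
    if n_known >= 20:
        nocall_frac = 1.0 - observed.sum() / n_known
        if nocall_frac > nocall_threshold:
            return PloidyStatus(False, "excess_nocalls")

    # Mendelian violations over constrained sites
    n_con = n_vio = 0
    n_single_het = n_single_het_het = 0
    for i in np.flatnonzero(observed):
        f, m, e = int(fgt[i]), int(mgt[i]), int(egt[i])
        allowed = _MENDEL[(f, m)]
        if len(allowed) < 3:
            n_con += 1
            if e not in allowed:
                n_vio += 1
        if (f == HET) != (m == HET):
            n_single_het += 1
            if e == HET:
                n_single_het_het += 1
    if n_con >= 10 and n_vio / n_con > mendel_threshold:
        return PloidyStatus(False, "mendelian_inconsistent")

    # per-parent heterozygosity excess
    for parent, pgt in (("father", fgt), ("mother", mgt)):
        other = mgt if parent == "father" else fgt
        sel = observed & (pgt == HET) & (other != HET)
        nsel = int(sel.sum())
        if nsel >= 20:
            frac = float((egt[sel] == HET).sum()) / nsel
            if frac > het_excess_threshold:
                return PloidyStatus(False, f"triploid_consistent_{parent}")

    return PloidyStatus(True)
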