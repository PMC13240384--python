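"""Reconcile haplotype-derived calls with direct mutation detection.

The final per-embryo status combines three evidence streams: the decoded
inheritance path read off at the variant locus, the direct mutation test
(Sanger / Gap-PCR), and the ploidy/CNV gate.  Disagreements are never
silently resolved toward the milder call: the more severe status wins and
an explanatory flag (allele-dropout suspicion or in-window recombination)
is always attached.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .types import (
    MISSING,
    RECESSIVE_BIALLELIC,
    DirectTestResult,
    VariantLocus,
)
from .phasing import InheritancePath, PhasedParents, PloidyStatus

WILD_TYPE = "wild_type"
CARRIER = "carrier"
AFFECTED = "affected"
FAILURE = "failure"

SEVERITY = {WILD_TYPE: 0, CARRIER: 1, AFFECTED: 2}

FLAG_ADO = "ado_suspect"
FLAG_RECOMB = "recombination_in_window"
FLAG_PLOIDY = "ploidy_failure"
FLAG_LOW_MARGIN = "low_margin"


@dataclass
class EmbryoDiagnosis:
    """Final reconciled status for one embryo."""

    embryo_id: str
    haplotype_call: str
    direct_call: DirectTestResult
    final_status: str
    flags: set[str] = field(default_factory=set)
    cnv_flag: str = "normal"  # normal | abnormal
    proband_id: str = ""

    def to_dict(self) -> dict:
        return {
            "embryo_id": self.embryo_id,
            "haplotype_call": self.haplotype_call,
            "direct_call": self.direct_call.call,
            "direct_method": self.direct_call.method,
            "final_status": self.final_status,
            "flags": sorted(self.flags),
            "cnv_flag": self.cnv_flag,
            "proband_id": self.proband_id,
        }


def _indicator_at_variant(path: InheritancePath, phased: PhasedParents,
                          parent: str) -> tuple[int | None, bool]:
    """Consensus transmitted-haplotype index for one parent at the variant.

    Reads the decoded indicator at the nearest informative marker at or
    below and at or above the variant position, skipping markers whose
    anchor was flagged conflicted and markers the embryo missed.  Returns
    (index, disagreement): a flanking disagreement means a recombination
    event cannot be placed relative to the variant.
    """
    variant = phased.variant
    vpos = variant.anchor_pos
    seq = path.paternal if parent == "father" else path.maternal
    usable = []
    for k, mk in enumerate(phased.markers):
        if path.skipped[k]:
            continue
        if mk.provenance(parent) in ("conflicted", "unresolved"):
            continue
        if mk.parent_gt(parent) not in (0, 1, 2):
            continue
        usable.append(k)
    if not usable:
        return None, False
    below = [k for k in usable if phased.markers[k].pos <= vpos]
    above = [k for k in usable if phased.markers[k].pos >= vpos]
    if not below and not above:
        raise ValueError("variant not bracketed by informative markers")
    if below and above:
        pair = (below[-1], above[0])
    elif above:
        # telomeric variant (e.g. a deletion near the p-terminus): no usable
        # marker below — require agreement of the two nearest markers above
        pair = (above[0], above[1]) if len(above) > 1 else (above[0], above[0])
    else:
        pair = (below[-1], below[-2]) if len(below) > 1 else (below[-1], below[-1])
    i_lo, i_hi = int(seq[pair[0]]), int(seq[pair[1]])
    if i_lo != i_hi:
        return None, True
    return i_lo, False


def haplotype_to_genotype(path: InheritancePath, variant: VariantLocus,
                          phased: PhasedParents) -> tuple[str, set[str]]:
    """Translate a decoded inheritance path into a variant-locus call.

    The call at the variant is the consensus of the two flanking informative
    markers (disagreement means an in-window recombination and yields
    failure).  Dominant: M from the carrier parent means carrier, otherwise
    wild type.  Recessive biallelic: M from both parents means affected,
    from one carrier, from neither wild type.
    """
    if path.failed:
        return FAILURE, set()
    flags: set[str] = set()
    indicators: dict[str, int] = {}
    for parent in variant.carrier_parents:
        idx, disagree = _indicator_at_variant(path, phased, parent)
        if disagree:
            return FAILURE, {FLAG_RECOMB}
        if idx is None:
            return FAILURE, flags
        indicators[parent] = idx

    n_mutant = sum(1 for v in indicators.values() if v == 0)
    if variant.inheritance == RECESSIVE_BIALLELIC:
        call = {2: AFFECTED, 1: CARRIER, 0: WILD_TYPE}[n_mutant]
    else:
        call = CARRIER if n_mutant else WILD_TYPE
    return call, flags


def reconcile(haplotype_call: str, direct: DirectTestResult,
              ploidy: PloidyStatus, cnv_flag: str = "normal",
              extra_flags: set[str] | None = None,
              proband_id: str = "") -> EmbryoDiagnosis:
    """Combine haplotype and direct evidence into a final status.

    Agreement yields the shared call.  A failed direct test defers to the
    haplotype call (flagged ado_suspect); a failed haplotype (including
    ploidy failure) defers to the direct call (flagged).  A genuine
    disagreement reports the more severe status with an explanatory flag —
    clinical conservatism, logged loudly rather than silently softened.
    """
    flags = set(extra_flags or ())
    if not ploidy.ok:
        flags.add(FLAG_PLOIDY)
        haplotype_call = FAILURE

    hap_ok = haplotype_call in SEVERITY
    dir_ok = direct.call in SEVERITY

    if hap_ok and dir_ok:
        if haplotype_call == direct.call:
            final = haplotype_call
        else:
            final = max((haplotype_call, direct.call), key=SEVERITY.get)
            if SEVERITY[direct.call] < SEVERITY[haplotype_call]:
                flags.add(FLAG_ADO)  # direct test likely dropped the variant allele
            else:
                flags.add(FLAG_RECOMB)  # haplotype likely broken by recombination
    elif hap_ok:
        final = haplotype_call
        flags.add(FLAG_ADO)  # direct test failed: haplotype is the evidence
    elif dir_ok:
        final = direct.call  # haplotype failed: direct detection stands, flagged above
    else:
        final = FAILURE

    return EmbryoDiagnosis(
        embryo_id=direct.embryo_id,
        haplotype_call=haplotype_call,
        direct_call=direct,
        final_status=final,
        flags=flags,
        cnv_flag=cnv_flag,
        proband_id=proband_id,
    )


def diagnose_embryo(path: InheritancePath, variant: VariantLocus,
                    phased: PhasedParents, direct: DirectTestResult,
                    ploidy: PloidyStatus, cnv_flag: str = "normal",
                    low_margin_nats: float = 2.0) -> EmbryoDiagnosis:
    """End-to-end single-embryo diagnosis: path -> call -> reconciliation."""
    if ploidy.ok:
        hap_call, flags = haplotype_to_genotype(path, variant, phased)
    else:
        hap_call, flags = FAILURE, set()
    if ploidy.ok and not path.failed and math.isfinite(path.margin) \
            and path.margin < low_margin_nats:
        flags.add(FLAG_LOW_MARGIN)
    return reconcile(hap_call, direct, ploidy, cnv_flag=cnv_flag,
                     extra_flags=flags, proband_id=phased.proband_id)
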