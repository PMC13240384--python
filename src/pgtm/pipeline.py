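"""End-to-end orchestration: CNV -> ploidy gate -> phasing -> diagnosis.

The stage order mirrors clinical practice: read-depth CNV calls and the
SNP-based ploidy gate run first so that non-disomic embryos never receive
a haplotype diagnosis; a proband is then chosen among the embryos that
demonstrably carry the variant, parental haplotypes are anchored and all
embryos decoded, and finally each haplotype call is reconciled with the
direct mutation test.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import cnv as cnv_mod
from . import io_formats as io
from .diagnosis import EmbryoDiagnosis, diagnose_embryo
from .phasing import (
    EmissionModel,
    InheritancePath,
    PhasedParents,
    PloidyStatus,
    anchor_parental_phase,
    decode_paths,
    detect_ploidy_failure,
    select_informative_snps,
)
from .types import (
    DirectTestResult,
    GeneticMap,
    GenotypeTable,
    RunConfig,
    RunManifest,
    VariantLocus,
)

log = logging.getLogger(__name__)


@dataclass
class FamilyInputs:
    """Everything the pipeline needs for one family."""

    family_id: str
    variant: VariantLocus
    genotypes: GenotypeTable          # parents + embryos, variant chromosome
    gmap: GeneticMap
    direct_tests: dict[str, DirectTestResult]
    embryo_ids: list[str]
    proband_id: str | None = None     # auto-selected when None
    depth_profiles: dict[str, pd.DataFrame] = field(default_factory=dict)
    panel: pd.DataFrame | None = None
    arms: dict[str, int] = field(default_factory=dict)
    embryo_sex: dict[str, str] = field(default_factory=dict)  # default XX/no adjust


@dataclass
class FamilyResult:
    family_id: str
    diagnoses: list[EmbryoDiagnosis]
    segments: dict[str, pd.DataFrame]
    bin_profiles: dict[str, pd.DataFrame]
    phased: PhasedParents
    paths: dict[str, InheritancePath]
    ploidy: dict[str, PloidyStatus]


def _choose_proband(inputs: FamilyInputs, ploidy: dict[str, PloidyStatus]) -> str:
    """Pick the proband: an affected embryo if any, else a carrier, skipping
    embryos that failed the ploidy gate."""
    if inputs.proband_id is not None:
        return inputs.proband_id
    for wanted in ("affected", "carrier"):
        for eid in inputs.embryo_ids:
            t = inputs.direct_tests.get(eid)
            if t and t.call == wanted and ploidy[eid].ok:
                return eid
    raise ValueError(
        f"family {inputs.family_id}: no embryo with a positive direct test "
        "passes the ploidy gate; cannot anchor parental haplotypes"
    )


def run_family(inputs: FamilyInputs, config: RunConfig) -> FamilyResult:
    """Run the full diagnostic pipeline on one family."""
    v = inputs.variant
    model = EmissionModel(config.ado_rate, config.genotype_error)

    # 1. read-depth CNV per embryo
    segments: dict[str, pd.DataFrame] = {}
    profiles: dict[str, pd.DataFrame] = {}
    for j, eid in enumerate(sorted(inputs.embryo_ids)):
        if eid in inputs.depth_profiles and inputs.panel is not None:
            prof, segs = cnv_mod.call_cnvs(
                inputs.depth_profiles[eid], inputs.panel, config=config,
                sex=inputs.embryo_sex.get(eid, "XX"),
                arms=inputs.arms, seed=config.seed + 1000 + j,
            )
            profiles[eid], segments[eid] = prof, segs
        else:
            segments[eid] = pd.DataFrame(
                columns=["chrom", "start", "end", "n_bins", "mean_log2", "z",
                         "class", "scope", "level"])

    # 2. ploidy gate on the variant-chromosome window
    lo = max(1, v.anchor_pos - config.window_bp)
    hi = v.anchor_pos + config.window_bp
    window = inputs.genotypes.subset_window(v.chrom, lo, hi)
    inside = {int(p) for p in window.sites["pos"] if v.contains(int(p))}
    ploidy = {
        eid: detect_ploidy_failure(
            window, eid, cnv_segments=segments.get(eid), variant_chrom=v.chrom,
            father_id=config.father_id, mother_id=config.mother_id,
            mendel_threshold=config.mendel_violation_threshold,
            het_excess_threshold=config.het_excess_threshold,
            nocall_threshold=config.nocall_excess_threshold,
            exclude_positions=inside,
        )
        for eid in inputs.embryo_ids
    }

    # 3. anchoring on the proband, 4. decoding of all gated embryos
    proband_id = _choose_proband(inputs, ploidy)
    markers = select_informative_snps(
        window, v, config.window_bp,
        father_id=config.father_id, mother_id=config.mother_id)
    marker_idx = np.array([m.site_index for m in markers])
    proband_obs = window.sample_gt(proband_id)[marker_idx]
    phased = anchor_parental_phase(
        markers, proband_obs, inputs.direct_tests[proband_id], v, model)
    embryo_obs = {
        eid: window.sample_gt(eid)[marker_idx]
        for eid in inputs.embryo_ids if ploidy[eid].ok
    }
    paths, phased = decode_paths(phased, embryo_obs, model, inputs.gmap)

    # 5. reconciliation
    diagnoses = []
    for eid in inputs.embryo_ids:
        cnv_flag = "normal"
        segs = segments.get(eid)
        if segs is not None and len(segs) and (segs["class"] != "neutral").any():
            cnv_flag = "abnormal"
        if not ploidy[eid].ok:
            cnv_flag = "abnormal"  # SNP-based ploidy call counts as abnormal
        path = paths.get(eid) or InheritancePath(
            embryo_id=eid, paternal=np.zeros(0, dtype=np.int8),
            maternal=np.zeros(0, dtype=np.int8),
            skipped=np.zeros(0, dtype=bool), log_prob=float("-inf"),
            margin=0.0, breakpoints={"father": [], "mother": []},
            failed=True, failure_reason=ploidy[eid].reason,
        )
        direct = inputs.direct_tests.get(eid) or DirectTestResult(eid, "failed")
        diagnoses.append(diagnose_embryo(
            path, v, phased, direct, ploidy[eid], cnv_flag=cnv_flag,
            low_margin_nats=config.low_margin_nats))

    return FamilyResult(
        family_id=inputs.family_id, diagnoses=diagnoses, segments=segments,
        bin_profiles=profiles, phased=phased, paths=paths, ploidy=ploidy,
    )


def run_end_to_end(families: list[FamilyInputs], config: RunConfig,
                   out_dir: str | Path | None = None,
                   input_digests: dict[str, str] | None = None
                   ) -> tuple[list[FamilyResult], RunManifest]:
    """Run every family and (optionally) write the report bundle.

    Reports: a combined per-embryo summary TSV + JSON, per-family phase and
    path tables, per-embryo segment TSVs, and a run manifest.
    """
    results = [run_family(f, config) for f in families]
    manifest = RunManifest(
        config_hash=RunManifest.hash_config(config),
        input_digests=dict(input_digests or {}),
        tool_version=__version__,
        seed=config.seed,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        all_diag = [d for r in results for d in r.diagnoses]
        all_segs = {d.embryo_id: r.segments[d.embryo_id]
                    for r in results for d in r.diagnoses}
        io.write_report(all_diag, all_segs, out / "summary")
        for r in results:
            r.phased.to_frame().to_csv(out / f"{r.family_id}.phase.tsv",
                                       sep="\t", index=False)
            pos = r.phased.positions
            for eid, path in sorted(r.paths.items()):
                path.to_frame(pos).to_csv(out / f"{eid}.path.tsv",
                                          sep="\t", index=False)
            for eid, segs in sorted(r.segments.items()):
                io.write_segments_tsv(segs, out / f"{eid}.segments.tsv")
        with open(out / "manifest.json", "w") as fh:
            import json
            json.dump({"identity": manifest.identity(),
                       "config_hash": manifest.config_hash,
                       "inputs": manifest.input_digests,
                       "version": manifest.tool_version,
                       "seed": manifest.seed,
                       "timestamp": manifest.timestamp}, fh, indent=1)
            fh.write("\n")
    return results, manifest
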