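"""Readers and writers for every external format the pipeline touches.

Coordinate conventions: VCF, variant loci, genetic maps and bin tables are
1-based inclusive; BED is 0-based half-open.  All TSV output uses a fixed
column order and 4-decimal float formatting so reports are byte-stable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .types import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    DirectTestResult,
    GeneticMap,
    GenotypeTable,
    RunConfig,
    bed_to_1based,
)

log = logging.getLogger(__name__)

FLOAT_FMT = "%.4f"


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | os.PathLike, sample_ids: list[str] | None = None) -> GenotypeTable:
    """Read unphased diploid genotype calls for ``sample_ids`` from a VCF.

    Phase separators (``|``) in the input are deliberately ignored — the
    method must not trust upstream phasing.  Multi-allelic sites are dropped
    with a logged warning; non-diploid or malformed GT fields become missing.
    """
    vcf = VCF(str(path))
    have = list(vcf.samples)
    if sample_ids is None:
        sample_ids = have
    for s in sample_ids:
        if s not in have:
            raise ValueError(f"sample {s!r} not in VCF {path} (has {have})")
    idx = [have.index(s) for s in sample_ids]

    rows, gts = [], []
    for rec_no, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            log.warning("dropping multi-allelic site %s:%d (line-record %d)",
                        rec.CHROM, rec.POS, rec_no)
            continue
        try:
            # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt (cyvcf2 convention)
            raw = rec.gt_types
        except Exception as exc:  # pragma: no cover - malformed records are rare
            raise ValueError(f"malformed VCF record #{rec_no} in {path}: {exc}")
        code = np.full(len(idx), MISSING, dtype=np.int8)
        for k, j in enumerate(idx):
            v = int(raw[j])
            if v == 0:
                code[k] = HOM_REF
            elif v == 1:
                code[k] = HET
            elif v == 3:
                code[k] = HOM_ALT
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        gts.append(code)

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    gt = np.vstack(gts) if gts else np.zeros((0, len(sample_ids)), dtype=np.int8)
    return GenotypeTable(sites=sites, gt=gt, samples=list(sample_ids))


_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(table: GenotypeTable, path: str | os.PathLike,
              contigs: dict[str, int] | None = None) -> None:
    """Write a minimal VCF 4.2 with unphased GT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pgtm\n")
        if contigs:
            for c, ln in contigs.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for i, row in enumerate(table.sites.itertuples(index=False)):
            gts = "\t".join(_GT_STR[int(g)] for g in table.gt[i])
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

def read_genetic_map(path: str | os.PathLike, chrom: str | None = None) -> GeneticMap:
    """Read a 3-column genetic-map text file (position, rate cM/Mb, cumulative cM).

    An optional leading chromosome column (4-column layout) is accepted; a
    header line is skipped when the first field is non-numeric.  Duplicate
    positions and non-monotone cumulative cM are rejected.
    """
    pos, rate, cm = [], [], []
    map_chrom = chrom
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 4:
                c, parts = parts[0], parts[1:]
                if map_chrom is None:
                    map_chrom = c
                elif c != map_chrom:
                    continue  # chrom-tagged file: keep requested chromosome only
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 (or 4) columns, got {len(parts)}")
            try:
                p, r, m = float(parts[0]), float(parts[1]), float(parts[2])
            except ValueError:
                if ln == 1:
                    continue  # header
                raise ValueError(f"{path}:{ln}: non-numeric map row")
            pos.append(int(p)); rate.append(r); cm.append(m)
    if len(pos) != len(set(pos)):
        raise ValueError(f"{path}: duplicate map positions")
    order = np.argsort(pos)
    arr_pos = np.asarray(pos, dtype=np.int64)[order]
    arr_cm = np.asarray(cm, dtype=float)[order]
    if np.any(np.diff(arr_cm) < 0):
        raise ValueError(f"{path}: cumulative cM is not nondecreasing")
    return GeneticMap(
        chrom=map_chrom or "unknown",
        positions=arr_pos,
        rate_cM_per_Mb=np.asarray(rate, dtype=float)[order],
        cumulative_cM=arr_cm,
    )


def write_genetic_map(gmap: GeneticMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("position\trate_cM_per_Mb\tcM\n")
        for p, r, m in zip(gmap.positions, gmap.rate_cM_per_Mb, gmap.cumulative_cM):
            fh.write(f"{int(p)}\t{FLOAT_FMT % r}\t{'%.6f' % m}\n")


def interpolate_cM(gmap: GeneticMap, pos) -> float | np.ndarray:
    """Cumulative cM at ``pos``: linear between tabulated points, constant outside."""
    return gmap.interpolate_cM(pos)


# ---------------------------------------------------------------------------
# BED blacklist / fragments / bin counts
# ---------------------------------------------------------------------------

def read_bed_blacklist(path: str | os.PathLike) -> pd.DataFrame:
    """Read a BED blacklist as a frame of 1-based inclusive intervals."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith(("#", "track", "browser")):
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED row needs >= 3 columns")
            try:
                s0, e0 = int(parts[1]), int(parts[2])
                s1, e1 = bed_to_1based(s0, e0)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}")
            rows.append((parts[0], s1, e1))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def read_chrom_sizes(path: str | os.PathLike) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected 'chrom<TAB>size'")
            sizes[parts[0]] = int(parts[1])
    return sizes


def fragment_bin_counts(frag_chroms: np.ndarray, frag_starts: np.ndarray,
                        bins: pd.DataFrame) -> np.ndarray:
    """Count 1-based fragment starts into every (possibly overlapping) bin
    whose inclusive span contains the start."""
    counts = np.zeros(len(bins), dtype=np.int64)
    for chrom in np.unique(frag_chroms):
        bmask = (bins["chrom"] == chrom).to_numpy()
        if not bmask.any():
            continue
        bidx = np.flatnonzero(bmask)
        starts = bins["start"].to_numpy()[bmask]
        ends = bins["end"].to_numpy()[bmask]
        frs = np.sort(frag_starts[frag_chroms == chrom])
        # bins are sorted by start within a chromosome; ends are nondecreasing
        lo = np.searchsorted(frs, starts, side="left")
        hi = np.searchsorted(frs, ends, side="right")
        counts[bidx] = hi - lo
    return counts


def read_fragments_or_counts(path: str | os.PathLike, bins: pd.DataFrame) -> np.ndarray:
    """Per-bin integer counts, from either a precomputed count TSV or a
    fragment-start BED/TSV.

    A header containing a ``count`` column selects the precomputed route
    (keyed by chrom+start of the bin grid).  Otherwise rows are fragments:
    BED files (``.bed``) give 0-based starts, TSVs give 1-based positions.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    header = first.lower().split()
    if "count" in header:
        df = pd.read_csv(path, sep="\t")
        key = bins[["chrom", "start"]].merge(
            df, on=["chrom", "start"], how="left"
        )
        counts = key["count"].fillna(0).to_numpy()
        return counts.astype(np.int64)
    is_bed = path.suffix.lower() == ".bed"
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if not parts[1].lstrip("-").isdigit():
                if ln == 1:
                    continue  # header without 'count'
                raise ValueError(f"{path}:{ln}: non-numeric fragment start")
            s = int(parts[1]) + 1 if is_bed else int(parts[1])
            rows.append((parts[0], s))
    if not rows:
        return np.zeros(len(bins), dtype=np.int64)
    ch = np.array([r[0] for r in rows])
    st = np.array([r[1] for r in rows], dtype=np.int64)
    return fragment_bin_counts(ch, st, bins)


# ---------------------------------------------------------------------------
# Direct mutation tests, config, reports
# ---------------------------------------------------------------------------

def read_direct_tests(path: str | os.PathLike) -> dict[str, DirectTestResult]:
    df = pd.read_csv(path, sep="\t")
    for col in ("embryo_id", "call"):
        if col not in df.columns:
            raise ValueError(f"{path}: direct-test TSV needs column {col!r}")
    out: dict[str, DirectTestResult] = {}
    for row in df.itertuples(index=False):
        if row.embryo_id in out:
            raise ValueError(f"{path}: duplicate direct test for {row.embryo_id}")
        out[row.embryo_id] = DirectTestResult(
            embryo_id=row.embryo_id, call=row.call,
            method=getattr(row, "method", "sanger"),
        )
    return out


def write_direct_tests(tests: dict[str, DirectTestResult], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("embryo_id\tcall\tmethod\n")
        for eid in sorted(tests):
            t = tests[eid]
            fh.write(f"{t.embryo_id}\t{t.call}\t{t.method}\n")


def read_config(path: str | os.PathLike) -> RunConfig:
    """Load a YAML (or JSON) run configuration."""
    with open(path) as fh:
        text = fh.read()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def write_config(config: RunConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def file_digest(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_report(diagnoses, segments_by_embryo: dict[str, pd.DataFrame],
                 out_prefix: str | os.PathLike) -> tuple[Path, Path]:
    """Write the per-embryo summary TSV and a machine-readable JSON report.

    ``diagnoses`` is a sequence of ``EmbryoDiagnosis``.  Output is
    deterministic: fixed column order, sorted flags, 4-decimal floats.
    """
    out_prefix = Path(out_prefix)
    tsv_path = out_prefix.with_suffix(".tsv")
    json_path = out_prefix.with_suffix(".json")

    lines = ["embryo_id\tcnv_flag\tdirect_call\tproband_id\thaplotype_call\t"
             "final_status\tflags"]
    payload = {"embryos": [], "segments": {}}
    for d in diagnoses:
        flags = ";".join(sorted(d.flags)) if d.flags else "-"
        lines.append(
            f"{d.embryo_id}\t{d.cnv_flag}\t{d.direct_call.call}\t{d.proband_id}\t"
            f"{d.haplotype_call}\t{d.final_status}\t{flags}"
        )
        payload["embryos"].append(d.to_dict())
    for eid, segs in sorted(segments_by_embryo.items()):
        payload["segments"][eid] = json.loads(
            segs.to_json(orient="records", double_precision=4)
        )
    with open(tsv_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return tsv_path, json_path


def write_counts_tsv(bins: pd.DataFrame, counts: np.ndarray,
                     path: str | os.PathLike) -> None:
    out = bins[["chrom", "start", "end"]].copy()
    out["count"] = np.asarray(counts, dtype=np.int64)
    out.to_csv(path, sep="\t", index=False)


def read_panel_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"chrom", "start", "end", "median", "sd", "n"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: panel TSV missing columns {sorted(missing)}")
    return df


def write_panel_tsv(panel: pd.DataFrame, path: str | os.PathLike) -> None:
    panel[["chrom", "start", "end", "median", "sd", "n"]].to_csv(
        path, sep="\t", index=False, float_format="%.6f")


def write_gc_tsv(bins: pd.DataFrame, path: str | os.PathLike) -> None:
    bins[["chrom", "start", "end", "gc"]].to_csv(
        path, sep="\t", index=False, float_format="%.6f")


def write_segments_tsv(segs: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = ["chrom", "start", "end", "n_bins", "mean_log2", "z", "class", "scope", "level"]
    out = segs.copy()
    for c in cols:
        if c not in out.columns:
            out[c] = np.nan
    out = out[cols]
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
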