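"""Read-depth CNV calling for low-pass WGA sequencing.

Pipeline: half-overlapping 400-kb/200-kb windows -> LOESS GC-bias
normalisation -> log2 copy-number ratios and Z-scores against a reference
panel (with sex adjustment) -> circular binary segmentation (CBS) with a
permutation acceptance test -> classification under the reporting rules:
segments with |log2| > 0.25 are CNVs, reported when whole-chromosome,
whole-arm, or segmental of at least 4 Mb (>= 20 consecutive bins);
intermediate copy states ("mosaics") need >= 10 Mb and an estimated
aberrant-cell level above 30%.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .types import SEX_CHROMS, RunConfig

log = logging.getLogger(__name__)

BIN_COLUMNS = ["chrom", "start", "end", "gc", "excluded", "count",
               "gc_norm", "log2_ratio", "z"]


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

def make_bins(chrom_sizes: dict[str, int], window: int = 400_000,
              step: int = 200_000, blacklist: pd.DataFrame | None = None,
              excluded_overlap: float = 0.5) -> pd.DataFrame:
    """Half-overlapping bin grid (1-based inclusive coordinates).

    Full windows start at ``1 + k*step`` while they fit on the chromosome;
    a trailing partial bin is added only when the full windows leave an
    uncovered tail and the partial is at least ``step`` wide.  A chromosome
    shorter than one window becomes a single full-chromosome bin.  A bin is
    excluded when more than ``excluded_overlap`` of its width intersects
    the blacklist.
    """
    if step > window:
        raise ValueError("step must not exceed window")
    rows = []
    for chrom, size in chrom_sizes.items():
        if size < window:
            log.warning("chromosome %s (%d bp) shorter than one window", chrom, size)
            rows.append((chrom, 1, size))
            continue
        n_full = (size - window) // step + 1
        starts = [1 + k * step for k in range(n_full)]
        for s in starts:
            rows.append((chrom, s, s + window - 1))
        last_end = starts[-1] + window - 1
        if last_end < size:
            s = starts[-1] + step
            if size - s + 1 >= step:
                rows.append((chrom, s, size))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["gc"] = np.nan
    df["excluded"] = False
    df["count"] = 0
    df["gc_norm"] = np.nan
    df["log2_ratio"] = np.nan
    df["z"] = np.nan

    if blacklist is not None and len(blacklist):
        for i, row in enumerate(df.itertuples(index=False)):
            bl = blacklist[blacklist["chrom"] == row.chrom]
            if not len(bl):
                continue
            ov = np.minimum(bl["end"].to_numpy(), row.end) \
                - np.maximum(bl["start"].to_numpy(), row.start) + 1
            ov = ov[ov > 0].sum()
            width = row.end - row.start + 1
            if ov > excluded_overlap * width:
                df.iat[i, df.columns.get_loc("excluded")] = True
    return df


def expected_bin_count(chrom_sizes: dict[str, int], window: int = 400_000,
                       step: int = 200_000) -> int:
    """Closed-form count of full windows: sum of floor((L-window)/step)+1."""
    total = 0
    for size in chrom_sizes.values():
        if size >= window:
            total += (size - window) // step + 1
        else:
            total += 1
    return total


# ---------------------------------------------------------------------------
# GC normalisation
# ---------------------------------------------------------------------------

def gc_normalize(profile: pd.DataFrame, frac: float = 0.3, it: int = 3,
                 min_bins: int = 200) -> pd.DataFrame:
    """LOESS GC-bias correction on retained autosomal bins.

    Fits depth ~ gc by locally weighted regression (span ``frac``, degree 1,
    ``it`` robustness iterations) and rescales each bin by the ratio of the
    global mean fitted depth to the fitted depth at its GC; GC values
    outside the fitted range use the boundary fit.  Skipped with a warning
    when the GC spread is degenerate (< 0.05).
    """
    df = profile.copy()
    mask = (~df["excluded"]) & (~df["chrom"].isin(SEX_CHROMS)) & df["gc"].notna()
    gc = df.loc[mask, "gc"].to_numpy(dtype=float)
    depth = df.loc[mask, "count"].to_numpy(dtype=float)
    if mask.sum() < min_bins:
        raise ValueError(f"need >= {min_bins} retained autosomal bins, have {int(mask.sum())}")
    if gc.max() - gc.min() < 0.05:
        log.warning("degenerate GC spread (%.3f); skipping GC normalisation",
                    gc.max() - gc.min())
        df.loc[~df["excluded"], "gc_norm"] = df.loc[~df["excluded"], "count"].astype(float)
        return df
    curve = lowess(depth, gc, frac=frac, it=it, return_sorted=True)
    xs, ys = curve[:, 0], curve[:, 1]
    all_keep = ~df["excluded"]
    fitted = np.interp(df.loc[all_keep, "gc"].to_numpy(dtype=float), xs, ys)
    fitted = np.clip(fitted, 1e-9, None)
    scale = float(np.mean(np.interp(gc, xs, ys)))
    df.loc[all_keep, "gc_norm"] = df.loc[all_keep, "count"].to_numpy(dtype=float) \
        * scale / fitted
    return df


# ---------------------------------------------------------------------------
# Panel comparison
# ---------------------------------------------------------------------------

def build_reference_panel(profiles: list[pd.DataFrame],
                          sex_composition: str = "mixed") -> pd.DataFrame:
    """Per-bin median and standard deviation of GC-normalised depth across
    control samples (all sharing one bin grid)."""
    base = profiles[0][["chrom", "start", "end"]].copy()
    stack = np.vstack([p["gc_norm"].to_numpy(dtype=float) for p in profiles])
    base["median"] = np.nanmedian(stack, axis=0)
    sd = np.nanstd(stack, axis=0, ddof=1)
    # guard: retained bins must carry a positive spread
    floor = 0.02 * np.nanmedian(base["median"])
    base["sd"] = np.maximum(sd, floor)
    base["n"] = stack.shape[0]
    base.attrs["sex_composition"] = sex_composition
    return base


def log2_and_z(profile: pd.DataFrame, panel: pd.DataFrame, sex: str = "XX",
               panel_sex: str = "mixed") -> pd.DataFrame:
    """log2 copy-number ratios and Z-scores against the reference panel.

    Sample and panel are first scaled to equal autosomal mean depth; for a
    46,XY sample against a non-male panel, the expected depth on X and Y is
    halved before the ratio is taken.  Bins with a non-positive panel
    median are excluded and logged.
    """
    df = profile.merge(panel, on=["chrom", "start", "end"], how="left",
                       suffixes=("", "_panel"))
    if df["median"].isna().any() and len(df) != len(profile):
        raise ValueError("bin grids of sample and panel do not match")
    keep = (~df["excluded"]) & df["gc_norm"].notna() & df["median"].notna()
    auto = keep & (~df["chrom"].isin(SEX_CHROMS)) & (df["median"] > 0)
    # robust per-bin ratio scaling: the median bin is copy-neutral as long as
    # less than half of the autosome is aberrant, so aneuploid chromosomes do
    # not drag the baseline the way mean scaling would; a second pass over
    # bins near the initial median removes the residual shift a sizeable
    # aneuploid fraction induces
    ratios = df.loc[auto, "gc_norm"].to_numpy(dtype=float) \
        / df.loc[auto, "median"].to_numpy(dtype=float)
    m0 = float(np.median(ratios))
    near = ratios[(ratios > m0 / 1.25) & (ratios < m0 * 1.25)]
    scale = float(np.median(near)) if len(near) else m0
    expected = df["median"].to_numpy(dtype=float) * scale
    sd = df["sd"].to_numpy(dtype=float) * scale
    if sex == "XY" and panel_sex != "XY":
        on_sex = df["chrom"].isin(SEX_CHROMS).to_numpy()
        expected = np.where(on_sex, expected / 2.0, expected)
        sd = np.where(on_sex, sd / 2.0, sd)
    bad = keep & (expected <= 0)
    if bad.any():
        log.warning("excluding %d bins with zero panel median", int(bad.sum()))
        df.loc[bad, "excluded"] = True
        keep &= ~bad
    vals = df["gc_norm"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        df.loc[keep, "log2_ratio"] = np.log2(vals[keep.to_numpy()] / expected[keep.to_numpy()])
        df.loc[keep, "z"] = (vals[keep.to_numpy()] - expected[keep.to_numpy()]) \
            / sd[keep.to_numpy()]
    return df[BIN_COLUMNS]


# ---------------------------------------------------------------------------
# Circular binary segmentation
# ---------------------------------------------------------------------------

def _max_arc_t(x: np.ndarray) -> tuple[float, int, int]:
    """Maximum |t| of the circular two-sample statistic over all arcs
    x[i:j] vs complement; returns (|t|, i, j)."""
    n = len(x)
    S = np.concatenate(([0.0], np.cumsum(x)))
    SS = np.concatenate(([0.0], np.cumsum(x * x)))
    T, TS = S[n], SS[n]
    best_t, best_i, best_j = 0.0, 0, n
    for m in range(1, n):  # arc length
        sums = S[m:] - S[:-m]          # arc sums for i = 0..n-m
        mean1 = sums / m
        mean2 = (T - sums) / (n - m)
        ss = TS - m * mean1 ** 2 - (n - m) * mean2 ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            sp2 = np.maximum(ss, 0.0) / max(n - 2, 1)
            denom = np.sqrt(sp2 * (1.0 / m + 1.0 / (n - m)))
            t = np.abs(mean1 - mean2) / denom
        t = np.where(np.isfinite(t), t, np.where(np.abs(mean1 - mean2) > 1e-12, 1e12, 0.0))
        k = int(np.argmax(t))
        if t[k] > best_t:
            best_t, best_i, best_j = float(t[k]), k, k + m
    return best_t, best_i, best_j


def _split_significant(x: np.ndarray, alpha: float, n_perm: int,
                       rng: np.random.Generator) -> tuple[int, int] | None:
    """Permutation test for the best arc split; early-stops once the
    rejection bound alpha*n_perm is reached."""
    n = len(x)
    if n < 4:
        return None
    obs, i, j = _max_arc_t(x)
    if obs <= 0:
        return None
    bound = math.ceil(alpha * n_perm)
    exceed = 0
    for p in range(n_perm):
        t, _, _ = _max_arc_t(rng.permutation(x))
        if t >= obs:
            exceed += 1
            if exceed >= bound:
                return None  # p-value cannot drop below alpha
    if exceed / n_perm < alpha:
        return i, j
    return None


def cbs_segment(profile: pd.DataFrame, alpha: float = 0.01,
                n_perm: int = 1000, seed: int = 0,
                merge_delta: float = 0.10) -> pd.DataFrame:
    """Recursive CBS over per-chromosome log2-ratio profiles.

    Each segment's best arc (maximising the circular two-sample t-statistic
    against its complement) is accepted when its permutation p-value falls
    below ``alpha``; recursion continues until no split is accepted, then
    adjacent segments whose means differ by less than ``merge_delta`` are
    re-merged.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    segs = []
    for chrom in profile["chrom"].unique():
        sub = profile[(profile["chrom"] == chrom) & (~profile["excluded"])
                      & profile["log2_ratio"].notna()]
        if not len(sub):
            continue
        vals = sub["log2_ratio"].to_numpy(dtype=float)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        zs = sub["z"].to_numpy(dtype=float)

        pieces: list[tuple[int, int]] = []

        def recurse(lo: int, hi: int) -> None:
            x = vals[lo:hi]
            split = _split_significant(x, alpha, n_perm, rng)
            if split is None:
                pieces.append((lo, hi))
                return
            i, j = split
            for a, b in ((lo, lo + i), (lo + i, lo + j), (lo + j, hi)):
                if b > a:
                    recurse(a, b)

        recurse(0, len(vals))
        pieces.sort()
        # merge adjacent near-equal segments
        merged = [pieces[0]]
        for lo, hi in pieces[1:]:
            plo, phi = merged[-1]
            if abs(vals[plo:phi].mean() - vals[lo:hi].mean()) < merge_delta:
                merged[-1] = (plo, hi)
            else:
                merged.append((lo, hi))
        for lo, hi in merged:
            segs.append({
                "chrom": chrom,
                "start": int(starts[lo]),
                "end": int(ends[hi - 1]),
                "n_bins": hi - lo,
                "mean_log2": float(vals[lo:hi].mean()),
                "z": float(np.nanmean(zs[lo:hi])),
            })
    return pd.DataFrame(segs, columns=["chrom", "start", "end", "n_bins",
                                       "mean_log2", "z"])


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def mosaic_level(mean_log2: float) -> float:
    """Estimated aberrant-cell fraction from a segment's mean log2 ratio.

    A fraction f of cells with a single-copy gain gives ratio (2 + f)/2,
    so f = 2*(2^L - 1); a single-copy loss gives f = 2*(1 - 2^L).  Values
    are clipped to [0, 1] (a full trisomy/monosomy corresponds to f = 1).
    """
    if mean_log2 >= 0:
        level = 2.0 * (2.0 ** mean_log2 - 1.0)
    else:
        level = 2.0 * (1.0 - 2.0 ** mean_log2)
    return float(np.clip(level, 0.0, 1.0))


def classify_segments(segments: pd.DataFrame, bins: pd.DataFrame,
                      arms: dict[str, int] | None = None,
                      config: RunConfig | None = None) -> pd.DataFrame:
    """Apply the reporting rules to raw CBS segments.

    Full-magnitude events (estimated level >= ``full_event_level``) with
    |log2| above the reporting threshold are gains/losses, reported when
    whole-chromosome, whole-arm (>= 90% of the relevant retained bins) or
    segmental of >= 4 Mb and >= 20 bins.  Intermediate states become
    mosaic_gain/mosaic_loss when >= 10 Mb with level > 30%.  Everything
    else is neutral.  ``arms`` maps chromosome -> centromere position.
    """
    cfg = config or RunConfig()
    arms = arms or {}
    out = segments.copy()
    classes, scopes, levels = [], [], []
    retained = bins[~bins["excluded"]]
    for seg in out.itertuples(index=False):
        L = seg.mean_log2
        length = seg.end - seg.start + 1
        level = mosaic_level(L)
        chrom_bins = retained[retained["chrom"] == seg.chrom]
        n_chrom = len(chrom_bins)
        scope = "segmental"
        if n_chrom and seg.n_bins >= cfg.whole_scope_fraction * n_chrom:
            scope = "whole_chromosome"
        elif seg.chrom in arms and n_chrom:
            cen = arms[seg.chrom]
            p_arm = chrom_bins[chrom_bins["end"] <= cen]
            q_arm = chrom_bins[chrom_bins["start"] > cen]
            for arm in (p_arm, q_arm):
                if not len(arm):
                    continue
                inside = arm[(arm["start"] >= seg.start) & (arm["end"] <= seg.end)]
                if len(inside) >= cfg.whole_scope_fraction * len(arm):
                    scope = "whole_arm"
                    break

        if abs(L) <= cfg.neutral_band:
            klass = "neutral"
        elif level >= cfg.full_event_level and abs(L) > cfg.log2_threshold:
            klass = "gain" if L > 0 else "loss"
            if scope == "segmental" and not (
                length >= cfg.min_segment_bp and seg.n_bins >= cfg.min_segment_bins
            ):
                klass = "neutral"  # below the segmental reporting floor
        elif length >= cfg.mosaic_min_bp and level > cfg.mosaic_min_level:
            klass = "mosaic_gain" if L > 0 else "mosaic_loss"
        else:
            klass = "neutral"
        classes.append(klass)
        scopes.append(scope if klass != "neutral" else "segmental")
        levels.append(level if klass != "neutral" else 0.0)
    out["class"] = classes
    out["scope"] = scopes
    out["level"] = levels
    return out


def call_cnvs(profile: pd.DataFrame, panel: pd.DataFrame,
              config: RunConfig | None = None, sex: str = "XX",
              panel_sex: str = "mixed", arms: dict[str, int] | None = None,
              seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-sample CNV pipeline: normalise, compare, segment, classify.

    Returns (completed bin profile, classified segment table).
    """
    cfg = config or RunConfig()
    prof = gc_normalize(profile, frac=cfg.loess_frac, it=cfg.loess_iter)
    prof = log2_and_z(prof, panel, sex=sex, panel_sex=panel_sex)
    segs = cbs_segment(prof, alpha=cfg.cbs_alpha, n_perm=cfg.cbs_n_perm,
                       seed=seed, merge_delta=cfg.cbs_merge_delta)
    segs = classify_segments(segs, prof, arms=arms, config=cfg)
    return prof, segs
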