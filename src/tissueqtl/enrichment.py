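"""Functional enrichment of eVariants against interval annotations.

eVariants are compared with background variants matched on chromosome,
distance to nearest TSS and MAF; overlap with annotation tracks is
summarized by Fisher's exact test (odds ratio with a Woolf-Haldane
correction at zero cells), and cluster-style annotations (e.g. piRNA
clusters) get a location-permutation test that uniformly re-places every
cluster within its chromosome outside excluded regions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_MAF_BINS = np.linspace(0.0, 0.5, 21)
#: log-spaced TSS-distance bin edges (bp), decade-ish resolution.
DEFAULT_TSS_BINS = np.array(
    [0, 1e3, 1e4, 1e5, 1e6, 1e7, np.inf]
)


def distance_to_nearest_tss(
    variants: pd.DataFrame, genes: pd.DataFrame
) -> np.ndarray:
    """|pos - nearest TSS| per variant (same chromosome; inf if none)."""
    out = np.full(len(variants), np.inf)
    by_chrom = {c: np.sort(g["tss"].to_numpy()) for c, g in genes.groupby("chrom")}
    for i, (_, row) in enumerate(variants.iterrows()):
        tss = by_chrom.get(row["chrom"])
        if tss is None or tss.size == 0:
            continue
        j = np.searchsorted(tss, row["pos"])
        cands = tss[max(0, j - 1) : j + 1]
        out[i] = np.abs(cands - row["pos"]).min()
    return out


def match_background(
    focal: pd.DataFrame,
    pool: pd.DataFrame,
    genes: pd.DataFrame,
    n_controls: int = 10,
    seed: int = 0,
    maf_bins: np.ndarray = DEFAULT_MAF_BINS,
    tss_bins: np.ndarray = DEFAULT_TSS_BINS,
) -> dict:
    """Matched control variants per focal variant.

    Controls are drawn uniformly without replacement (with replacement
    only when the stratum is too small) from the focal variant's
    (chromosome, TSS-distance bin, MAF bin) stratum, excluding all focal
    variants.  Focal variants whose stratum is empty are reported
    unmatched and excluded from downstream tests.
    """
    rng = np.random.default_rng(seed)
    pool = pool.reset_index(drop=True)
    focal = focal.reset_index(drop=True)
    focal_ids = set(focal["variant"])

    def strata(df: pd.DataFrame) -> pd.Series:
        dist = distance_to_nearest_tss(df, genes)
        d_bin = np.digitize(dist, tss_bins)
        m_bin = np.digitize(df["maf"].to_numpy(float), maf_bins)
        return pd.Series(
            list(zip(df["chrom"], d_bin, m_bin)), index=df.index
        )

    pool_strata = strata(pool)
    focal_strata = strata(focal)
    eligible = ~pool["variant"].isin(focal_ids)
    groups: dict = {}
    for key, idx in pool_strata[eligible].groupby(pool_strata[eligible]).groups.items():
        groups[key] = np.array(idx)

    controls: dict[str, list[str]] = {}
    unmatched: list[str] = []
    for i, key in focal_strata.items():
        vid = focal["variant"].iloc[i]
        stratum = groups.get(key)
        if stratum is None or stratum.size == 0:
            unmatched.append(vid)
            continue
        replace = stratum.size < n_controls
        pick = rng.choice(stratum, size=n_controls, replace=replace)
        controls[vid] = pool["variant"].iloc[pick].tolist()
    return {
        "controls": controls,
        "unmatched": unmatched,
        "n_focal": len(focal),
        "n_matched": len(controls),
    }


def interval_overlap(
    variants: pd.DataFrame, track: pd.DataFrame
) -> np.ndarray:
    """Membership of 1-based variant positions in BED intervals.

    A variant at 1-based position p overlaps [start, end) iff
    start <= p - 1 < end.
    """
    out = np.zeros(len(variants), dtype=bool)
    for chrom, sub in track.groupby("chrom"):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        mask = (variants["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        pos0 = variants.loc[mask, "pos"].to_numpy() - 1
        # running max of ends handles overlapping intervals (e.g. states
        # from several cell types): pos is covered iff some interval with
        # start <= pos extends past it
        end_cummax = np.maximum.accumulate(ends)
        j = np.searchsorted(starts, pos0, side="right") - 1
        hit = (j >= 0) & (pos0 < end_cummax[np.clip(j, 0, len(ends) - 1)])
        out[np.flatnonzero(mask)] |= hit
    return out


def fisher_enrichment(
    focal_in: np.ndarray, background_in: np.ndarray, label: str = ""
) -> dict:
    """2x2 Fisher's exact test of annotation overlap.

    Returns the odds ratio (Woolf-Haldane 0.5 correction when any cell is
    zero), two-sided exact p, and a normal-approximation 95% CI on the
    log odds ratio.
    """
    focal_in = np.asarray(focal_in, dtype=bool)
    background_in = np.asarray(background_in, dtype=bool)
    if focal_in.size == 0 or background_in.size == 0:
        raise ValueError("both groups must be nonempty")
    a = int(focal_in.sum())
    b = int(focal_in.size - a)
    c = int(background_in.sum())
    d = int(background_in.size - c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a_, b_, c_, d_ = a, b, c, d
    orr = (a_ * d_) / (b_ * c_)
    se = np.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    ci = (orr * np.exp(-1.96 * se), orr * np.exp(1.96 * se))
    return {
        "annotation": label,
        "odds_ratio": float(orr),
        "ci95": (float(ci[0]), float(ci[1])),
        "p": float(p),
        "counts": (a, b, c, d),
    }


def _allowed_gaps(length: int, excluded: pd.DataFrame, chrom: str,
                  cluster_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Start-position gaps where a cluster of cluster_len fits."""
    sub = excluded[excluded["chrom"] == chrom].sort_values("start")
    gaps = []
    prev = 0
    for _, row in sub.iterrows():
        gaps.append((prev, int(row["start"])))
        prev = int(row["end"])
    gaps.append((prev, length))
    starts, widths = [], []
    for lo, hi in gaps:
        room = hi - lo - cluster_len
        if room >= 0:
            starts.append(lo)
            widths.append(room + 1)
    return np.array(starts), np.array(widths)


def permutation_cluster_test(
    focal: pd.DataFrame,
    clusters: pd.DataFrame,
    excluded: pd.DataFrame,
    genome: dict[str, int],
    n_perm: int = 10_000,
    seed: int = 0,
    proximity: int | None = 10_000,
) -> dict:
    """Cluster-location permutation test of variant overlap.

    The observed statistic is the fraction of focal variants inside a
    cluster.  Each permutation re-places every cluster uniformly within
    its chromosome (length-preserving, outside excluded regions) and
    recomputes the statistic; ``p = (1 + #{null >= obs}) / (1 + n_perm)``.
    A within-``proximity``-bp variant of the statistic is also reported.
    """
    rng = np.random.default_rng(seed)
    obs = float(interval_overlap(focal, clusters).mean())
    if proximity is not None:
        prox_track = clusters.assign(
            start=np.maximum(clusters["start"] - proximity, 0),
            end=clusters["end"] + proximity,
        )
        obs_prox = float(interval_overlap(focal, prox_track).mean())

    # Pre-resolve, per cluster: its chromosome's sorted focal positions and
    # the gaps (outside excluded regions) where it can land.
    gap_cache: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}
    by_chrom_pos = {
        chrom: np.sort(sub["pos"].to_numpy() - 1)
        for chrom, sub in focal.groupby("chrom")
    }
    cluster_info = []
    for row in clusters.itertuples(index=False):
        clen = int(row.end - row.start)
        key = (row.chrom, clen)
        if key not in gap_cache:
            starts, widths = _allowed_gaps(
                genome[row.chrom], excluded, row.chrom, clen
            )
            if widths.size == 0:
                raise ValueError(
                    f"cluster of length {clen} does not fit on {row.chrom}"
                )
            gap_cache[key] = (starts, widths.cumsum())
        cluster_info.append((row.chrom, clen, *gap_cache[key]))

    n_focal = len(focal)

    def _count(intervals_by_chrom: dict[str, list[tuple[int, int]]]) -> int:
        hits = 0
        for chrom, ivs in intervals_by_chrom.items():
            pos = by_chrom_pos.get(chrom)
            if pos is None or pos.size == 0:
                continue
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:  # merge overlaps so variants count once
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            for s, e in merged:
                hits += int(
                    np.searchsorted(pos, e, side="left")
                    - np.searchsorted(pos, s, side="left")
                )
        return hits

    null = np.empty(n_perm)
    null_prox = np.empty(n_perm)
    pad = proximity or 0
    for b in range(n_perm):
        placed: dict[str, list[tuple[int, int]]] = {}
        padded: dict[str, list[tuple[int, int]]] = {}
        for chrom, clen, starts, cum in cluster_info:
            u = int(rng.integers(0, cum[-1]))
            gi = int(np.searchsorted(cum, u, side="right"))
            offset = u - (int(cum[gi - 1]) if gi else 0)
            s = int(starts[gi] + offset)
            placed.setdefault(chrom, []).append((s, s + clen))
            if proximity is not None:
                padded.setdefault(chrom, []).append(
                    (max(s - pad, 0), s + clen + pad)
                )
        null[b] = _count(placed) / n_focal
        if proximity is not None:
            null_prox[b] = _count(padded) / n_focal
    p = (1.0 + (null >= obs).sum()) / (1.0 + n_perm)
    out = {"observed": obs, "null": null, "p": float(p)}
    if proximity is not None:
        p_prox = (1.0 + (null_prox >= obs_prox).sum()) / (1.0 + n_perm)
        out["observed_proximity"] = obs_prox
        out["p_proximity"] = float(p_prox)
    return out
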