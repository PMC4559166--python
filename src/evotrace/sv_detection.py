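"""Structural-variant detection from mapped mate pairs.

Large (>= 500 bp) indels are detected from the deviation of regional
mate-pair distance medians from the library-wide mean: windows tiling the
reference collect pairs by their leftmost mapped coordinate, and a window is
flagged when its distance median lies more than ``z_threshold`` library
standard deviations from the library mean (two-sided; deletions stretch the
mapped distance, insertions shrink it).  Flagged windows are merged into
maximal regions; the event size estimate is |regional median - library mean|.
An insertion whose region contains reads whose mates map into an IS element
is classified as an IS-element insertion.

Duplications are detected independently from the read-depth profile: maximal
runs of windows whose fold-coverage exceeds a ratio threshold relative to
the genome-wide median.

When an insertion's length approaches the library fragment length, pairs
spanning both flanks are lost (insert-size censoring) and the raw size
estimate is biased low; calls in that regime carry ``censored=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (DegenerateDataError, InsufficientDataError,
                     InvalidArgumentError)
from .synthetic_data import MappedPairSet


@dataclass(frozen=True)
class DistanceStats:
    """Library-wide outer-distance statistics over all mapped pairs."""

    mean_distance: float
    sd_distance: float
    n_pairs: int


@dataclass(frozen=True)
class RegionScan:
    """One window of the distance-deviation scan."""

    start: int
    end: int
    median_distance: float
    n_pairs: int
    z: float


@dataclass
class LargeIndelCall:
    kind: str                      # "insertion" | "deletion"
    position: int                  # breakpoint estimate, 0-based
    size_estimate: float           # |regional median - library mean|
    support: int
    z: float
    is_element: Optional[str] = None
    censored: bool = False
    ambiguous_is: bool = False
    region: tuple = (0, 0)

    @property
    def key(self) -> tuple:
        return ("large_indel", self.kind, self.region)


@dataclass
class CoverageProfile:
    """Per-window fold-coverage estimated from read starts."""

    window_size: int
    starts: np.ndarray             # window start coordinates
    depth: np.ndarray              # fold coverage per window


@dataclass
class DuplicationCall:
    start: int
    end: int
    length: int
    mean_ratio: float


# --------------------------------------------------------------------------- #
# Quality filtering and library statistics
# --------------------------------------------------------------------------- #


def filter_pairs(pairs: MappedPairSet, min_mapq: int = 10,
                 min_baseq: int = 30) -> MappedPairSet:
    """Remove low-quality pairs (mapq < 10 or any base quality < 30)."""
    f = pairs.frame
    keep = (f["mapq"] >= min_mapq) & (f["min_baseq"] >= min_baseq)
    return MappedPairSet(f[keep], pairs.read_length, pairs.ref_length)


def global_distance_stats(pairs: MappedPairSet) -> DistanceStats:
    """Mean and sample SD (n-1) of outer distances over all mapped pairs."""
    d = pairs.distances.dropna().to_numpy()
    if len(d) < 2:
        raise InsufficientDataError("need >= 2 both-mapped pairs")
    return DistanceStats(mean_distance=float(np.mean(d)),
                         sd_distance=float(np.std(d, ddof=1)),
                         n_pairs=len(d))


# --------------------------------------------------------------------------- #
# Distance-deviation scan
# --------------------------------------------------------------------------- #


def scan_distance_deviation(pairs: MappedPairSet, stats: DistanceStats,
                            window_size: Optional[int] = None,
                            step: Optional[int] = None,
                            min_pairs: int = 20,
                            z_threshold: float = 3.0,
                            ref_length: Optional[int] = None
                            ) -> list[RegionScan]:
    """Flag windows whose distance median deviates > z_threshold SD.

    Windows of ``window_size`` (default: the library mean distance) tile the
    reference with the given step (default window_size/4); a pair belongs to
    the window containing its leftmost mapped coordinate.  Windows with
    fewer than ``min_pairs`` distance observations are not scored.
    """
    if stats.sd_distance <= 0:
        raise DegenerateDataError("library distance SD is zero")
    window_size = int(window_size or round(stats.mean_distance))
    step = int(step or max(window_size // 4, 1))
    f = pairs.frame
    mapped = f[f["right_pos"].notna()]
    left = mapped["left_pos"].to_numpy()
    dist = (mapped["right_pos"] - mapped["left_pos"]).to_numpy()
    L = ref_length or pairs.ref_length or int(f["left_pos"].max()) + window_size

    order = np.argsort(left)
    left = left[order]
    dist = dist[order]
    flagged = []
    for w0 in range(0, max(L - window_size + 1, 1), step):
        lo = np.searchsorted(left, w0, side="left")
        hi = np.searchsorted(left, w0 + window_size, side="left")
        n = hi - lo
        if n < min_pairs:
            continue
        med = float(np.median(dist[lo:hi]))
        z = (med - stats.mean_distance) / stats.sd_distance
        if abs(z) > z_threshold:
            flagged.append(RegionScan(w0, w0 + window_size, med, int(n),
                                      float(z)))
    return flagged


def merge_flagged_windows(windows: Sequence[RegionScan]
                          ) -> list[list[RegionScan]]:
    """Group overlapping/adjacent flagged windows into maximal regions."""
    groups: list[list[RegionScan]] = []
    for w in sorted(windows, key=lambda w: w.start):
        if groups and w.start <= groups[-1][-1].end:
            groups[-1].append(w)
        else:
            groups.append([w])
    return groups


def classify_large_indel(region: Sequence[RegionScan], pairs: MappedPairSet,
                         stats: DistanceStats,
                         min_is_support: int = 3,
                         insert_sd: Optional[float] = None
                         ) -> LargeIndelCall:
    """Turn one merged flagged region into a large-indel call.

    Kind follows the sign of (regional median - library mean): a deletion
    stretches mapped distances, an insertion shrinks them.  The regional
    median is taken from the most deviant window of the region (the window
    whose pairs most consistently span the event; windows further out mix
    in event-free pairs and dilute the estimate), and the size estimate is
    |regional median - library mean|.  If enough pairs in the region carry
    a counterpart-read hit into one IS element, the insertion is classified
    as that IS element.  The breakpoint estimate is the median midpoint of
    the deviant pairs' spans.
    """
    if not region:
        raise InvalidArgumentError("empty region")
    a = min(w.start for w in region)
    b = max(w.end for w in region)
    peak = max(region, key=lambda w: abs(w.z))
    f = pairs.frame
    in_region = (f["left_pos"] >= a) & (f["left_pos"] < b)
    sub = f[in_region]
    mapped = sub[sub["right_pos"].notna()]
    d = (mapped["right_pos"] - mapped["left_pos"]).to_numpy()
    if len(d) == 0:
        raise InsufficientDataError("no mapped pairs in region")
    # refine the regional median to the event-spanning population: pairs
    # within 3 library SD of the peak-window median.  Event-free pairs sit
    # > 3 SD away by construction (the window only flags beyond 3 SD), so
    # this strips their dilution without biasing the spanning median.
    sel = np.abs(d - peak.median_distance) < 3 * stats.sd_distance
    m_w = float(np.median(d[sel])) if sel.any() else peak.median_distance
    delta = m_w - stats.mean_distance
    kind = "deletion" if delta > 0 else "insertion"
    size = abs(delta)

    # breakpoint: midpoint of the most deviant pairs' spans
    deviant = mapped[np.abs(d - stats.mean_distance)
                     > 0.5 * abs(delta)] if len(mapped) else mapped
    src = deviant if len(deviant) else mapped
    bp = int(np.median((src["left_pos"].to_numpy()
                        + src["right_pos"].to_numpy()) / 2))

    is_element = None
    ambiguous = False
    cp = sub["counterpart"].astype(str)
    hits = cp[(cp != "") & (cp != "nan")]
    if kind == "insertion" and len(hits):
        counts = hits.value_counts()
        top = counts.index[0]
        if counts.iloc[0] >= min_is_support:
            is_element = str(top)
            others = counts[counts >= min_is_support]
            if len(others) > 1:
                ambiguous = True

    censored = False
    if kind == "insertion" and insert_sd is not None:
        # censoring: both-flank pairs require fragments >= L + 2*read_length
        needed = size + 2 * pairs.read_length + 3 * insert_sd
        censored = stats.mean_distance < needed

    return LargeIndelCall(kind=kind, position=bp, size_estimate=size,
                          support=int(len(d)),
                          z=float(delta / stats.sd_distance),
                          is_element=is_element, censored=censored,
                          ambiguous_is=ambiguous, region=(a, b))


def counterpart_clusters(pairs: MappedPairSet, min_is_support: int = 3,
                         gap: float = 2000.0) -> list[dict]:
    """Cluster counterpart-read evidence into candidate IS insertion sites.

    Pairs whose mate was absorbed by an IS element carry the element name
    and the mapped flank read's coordinate; flank coordinates of the same
    element within ``gap`` bp of each other form one cluster.  Clusters
    with at least ``min_is_support`` pairs are returned.
    """
    f = pairs.frame
    cp = f["counterpart"].astype(str)
    hits = f[(cp != "") & (cp != "nan")]
    clusters = []
    for name, grp in hits.groupby(hits["counterpart"].astype(str)):
        pos = np.sort(grp["left_pos"].to_numpy())
        start = 0
        for i in range(1, len(pos) + 1):
            if i == len(pos) or pos[i] - pos[i - 1] > gap:
                chunk = pos[start:i]
                if len(chunk) >= min_is_support:
                    clusters.append({
                        "is_element": str(name),
                        "start": float(chunk[0]),
                        "end": float(chunk[-1]) + pairs.read_length,
                        "position": int(np.median(chunk))
                                    + pairs.read_length,
                        "support": int(len(chunk)),
                    })
                start = i
    return clusters


def detect_large_indels(pairs: MappedPairSet,
                        window_size: Optional[int] = None,
                        step: Optional[int] = None,
                        min_pairs: int = 20, z_threshold: float = 3.0,
                        min_is_support: int = 3,
                        insert_sd: Optional[float] = None,
                        ref_length: Optional[int] = None
                        ) -> list[LargeIndelCall]:
    """Full large-indel scan.

    1. library distance statistics over all mapped pairs;
    2. window flagging by median deviation, merging, classification;
    3. counterpart-read clusters: an IS insertion whose length approaches
       the library fragment size loses its both-flank pairs to censoring
       and may never deviate the window median, but its flanks accumulate
       reads whose mates were absorbed by the element.  Clusters not
       already explained by a scan call become censored insertion calls;
       their size estimate uses the deviant (short-distance) spanning pairs
       when at least ``min_is_support`` exist, and is NaN otherwise.
    """
    stats = global_distance_stats(pairs)
    flagged = scan_distance_deviation(pairs, stats, window_size, step,
                                      min_pairs, z_threshold, ref_length)
    sd = insert_sd if insert_sd is not None else stats.sd_distance
    regions = merge_flagged_windows(flagged)

    # refine library statistics on event-free pairs only: on a short
    # reference the flagged regions' own (distance-shifted) pairs make up a
    # non-negligible share of the library and bias the global mean toward
    # the event, which in turn biases |median - mean| size estimates low.
    w = window_size or int(round(stats.mean_distance))
    f = pairs.frame
    keep = np.ones(len(f), dtype=bool)
    left_all = f["left_pos"].to_numpy()
    for region in regions:
        a = min(x.start for x in region) - w
        b = max(x.end for x in region)
        keep &= ~((left_all >= a) & (left_all < b))
    bg = MappedPairSet(f[keep], pairs.read_length, pairs.ref_length)
    try:
        cls_stats = global_distance_stats(bg)
    except InsufficientDataError:
        cls_stats = stats

    calls = []
    for region in regions:
        calls.append(classify_large_indel(region, pairs, cls_stats,
                                          min_is_support, sd))
    stats = cls_stats  # counterpart-cluster sizing below uses the same base

    f = pairs.frame
    mapped = f[f["right_pos"].notna()]
    dist = (mapped["right_pos"] - mapped["left_pos"]).to_numpy()
    left = mapped["left_pos"].to_numpy()
    reach = stats.mean_distance + 3 * sd
    for cl in counterpart_clusters(pairs, min_is_support):
        explained = any(
            c.kind == "insertion"
            and abs(c.position - cl["position"]) <= reach
            for c in calls)
        if explained:
            for c in calls:
                if (c.kind == "insertion" and c.is_element is None
                        and abs(c.position - cl["position"]) <= reach):
                    c.is_element = cl["is_element"]
            continue
        near = ((left >= cl["position"] - reach)
                & (left < cl["position"])
                & (dist < stats.mean_distance - 3 * sd))
        if near.sum() >= min_is_support:
            size = float(stats.mean_distance - np.median(dist[near]))
        else:
            size = float("nan")
        calls.append(LargeIndelCall(
            kind="insertion", position=cl["position"], size_estimate=size,
            support=cl["support"],
            z=float(-size / stats.sd_distance) if np.isfinite(size) else 0.0,
            is_element=cl["is_element"], censored=True,
            region=(int(cl["start"]), int(cl["end"]))))
    return sorted(calls, key=lambda c: c.position)


# --------------------------------------------------------------------------- #
# Read-depth duplication detection
# --------------------------------------------------------------------------- #


def coverage_profile(pairs: MappedPairSet, window_size: int = 5000,
                     ref_length: Optional[int] = None) -> CoverageProfile:
    """Per-window fold coverage from read starts.

    Each mapped pair contributes two read starts (leftmost coordinate of
    each read); counterpart pairs contribute their one mapped read.  Fold
    coverage per window = read_starts * read_length / window_size.
    """
    f = pairs.frame
    rl = pairs.read_length
    left_starts = f["left_pos"].to_numpy(dtype=float)
    mapped = f["right_pos"].notna().to_numpy()
    right_starts = f.loc[mapped, "right_pos"].to_numpy(dtype=float) - rl
    starts = np.concatenate([left_starts, right_starts])
    L = ref_length or pairs.ref_length
    if L is None:
        L = int(starts.max()) + 1 if len(starts) else window_size
    edges = np.arange(0, L + window_size, window_size)
    counts, _ = np.histogram(starts, bins=edges)
    depth = counts * rl / window_size
    return CoverageProfile(window_size=window_size, starts=edges[:-1],
                           depth=depth)


def detect_duplication(profile: CoverageProfile, ratio_threshold: float = 1.5,
                       min_consecutive_windows: int = 10
                       ) -> list[DuplicationCall]:
    """Maximal runs of elevated-coverage windows.

    A window is elevated when depth / genome-median depth >= ratio_threshold;
    runs of at least ``min_consecutive_windows`` are reported with their
    length and mean depth ratio.
    """
    if len(profile.depth) == 0:
        raise InvalidArgumentError("empty coverage profile")
    med = float(np.median(profile.depth))
    if med <= 0:
        raise InsufficientDataError("genome median coverage is zero")
    ratio = profile.depth / med
    high = ratio >= ratio_threshold
    calls = []
    i = 0
    n = len(high)
    while i < n:
        if high[i]:
            j = i
            while j < n and high[j]:
                j += 1
            if j - i >= min_consecutive_windows:
                start = int(profile.starts[i])
                end = int(profile.starts[j - 1]) + profile.window_size
                calls.append(DuplicationCall(
                    start=start, end=end, length=end - start,
                    mean_ratio=float(ratio[i:j].mean())))
            i = j
        else:
            i += 1
    return calls


# --------------------------------------------------------------------------- #
# Plain-text IO
# --------------------------------------------------------------------------- #


def sv_calls_to_frame(calls: Sequence[LargeIndelCall]) -> pd.DataFrame:
    rows = [(c.kind, c.position + 1, c.size_estimate,
             c.is_element or ".", c.support, c.z, c.censored)
            for c in calls]
    return pd.DataFrame(rows, columns=["kind", "pos_1based", "size", "IS",
                                       "support", "z", "censored"])


def duplications_to_frame(calls: Sequence[DuplicationCall]) -> pd.DataFrame:
    rows = [(c.start, c.end, c.length, c.mean_ratio) for c in calls]
    return pd.DataFrame(rows, columns=["start", "end", "length_bp",
                                       "mean_ratio"])
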