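"""Point-mutation and small-indel calling from per-site pileup evidence.

Calls are made per platform with three gates — minimum depth, minimum
variant-read fraction, and a one-sided binomial tail test of the
variant-supporting count against the per-base error rate — then reconciled
across the two platforms, with discrepancies resolved against a confirmation
oracle (the programmatic stand-in for Sanger re-sequencing).  Low-coverage
regions are masked and parent-strain variants subtracted.

The variant-read "ratio" is variant_count / depth (fraction of total), and
the depth/ratio thresholds are inclusive at their configured values; the
binomial p-value threshold is strict.  The binomial tail replaces the
proprietary caller the quality scores originally came from: it plays the
same role (error-aware call confidence) with an auditable formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataIntegrityError, InvalidArgumentError
from .synthetic_data import PileupTable


@dataclass
class CallerConfig:
    """Thresholds for point-mutation and small-indel calling.

    min_depth and min_ratio are inclusive bounds; p_threshold is strict
    (call iff binomial tail < p_threshold).  error_rate is the per-base
    sequencing error probability the tail test assumes.
    """

    min_depth: int = 10
    min_ratio: float = 0.6
    p_threshold: float = 1e-7
    error_rate: float = 0.005

    def __post_init__(self):
        if self.min_depth < 0 or not (0.0 <= self.min_ratio <= 1.0):
            raise InvalidArgumentError("invalid depth/ratio thresholds")
        if not (0.0 < self.p_threshold <= 1.0):
            raise InvalidArgumentError("p_threshold must be in (0, 1]")
        if not (0.0 <= self.error_rate < 1.0):
            raise InvalidArgumentError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class PointMutationCall:
    position: int          # 0-based reference coordinate
    ref_base: str
    alt_base: str
    ratio: float
    depth: int
    p_value: float
    platform: str = ""

    @property
    def key(self) -> tuple:
        return ("snv", self.position, self.alt_base)


@dataclass(frozen=True)
class SmallIndelCall:
    position: int
    signed_length: int     # +L insertion, -L deletion
    ratio: float
    depth: int
    platform: str = ""

    @property
    def key(self) -> tuple:
        return ("indel", self.position, self.signed_length)


@dataclass
class ConsensusReport:
    """Outcome of reconciling two platforms' call sets."""

    agreed: list
    only_a: list
    only_b: list
    oracle_resolutions: list = field(default_factory=list)  # (call, bool|None)
    final: list = field(default_factory=list)
    unresolved: list = field(default_factory=list)


def binomial_tail(k: int, n: int, p: float) -> float:
    """One-sided upper binomial tail P(X >= k | n, p)."""
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def call_point_mutations(pileup: PileupTable,
                         config: Optional[CallerConfig] = None
                         ) -> list[PointMutationCall]:
    """Call point mutations from a single-platform pileup.

    A site is called iff depth >= min_depth AND variant_count/depth >=
    min_ratio AND P(X >= variant_count | depth, error_rate) < p_threshold.
    Returns calls sorted by position.
    """
    config = config or CallerConfig()
    depth = np.asarray(pileup.depth)
    vc = np.asarray(pileup.variant_count)
    if (vc > depth).any():
        raise DataIntegrityError("variant_count exceeds depth")

    nz = depth > 0
    ratio = np.zeros_like(depth, dtype=float)
    ratio[nz] = vc[nz] / depth[nz]
    candidate = (depth >= config.min_depth) & (ratio >= config.min_ratio)
    idx = np.nonzero(candidate)[0]
    if len(idx):
        pvals = stats.binom.sf(vc[idx] - 1, depth[idx], config.error_rate)
        idx = idx[pvals < config.p_threshold]
        pvals = stats.binom.sf(vc[idx] - 1, depth[idx], config.error_rate)
    else:
        pvals = np.array([])

    ref = pileup.ref_sequence
    calls = []
    for pos, p in zip(idx, pvals):
        pos = int(pos)
        calls.append(PointMutationCall(
            position=pos,
            ref_base=ref[pos] if ref else "N",
            alt_base=pileup.alt.get(pos, "N"),
            ratio=float(ratio[pos]),
            depth=int(depth[pos]),
            p_value=float(p),
            platform=pileup.platform,
        ))
    return sorted(calls, key=lambda c: c.position)


def call_small_indels(pileup: PileupTable,
                      config: Optional[CallerConfig] = None
                      ) -> list[SmallIndelCall]:
    """Call small (< 500 bp) indels from per-site indel-evidence counts.

    The same depth/ratio gates as point calling apply to the supporting
    counts.  Events of 500 bp or more are out of range here and raise; they
    belong to the mate-pair distance scan.
    """
    from .synthetic_data import SMALL_EVENT_MAX

    config = config or CallerConfig()
    calls = []
    for pos, (slen, count) in sorted(pileup.indel_evidence.items()):
        if abs(slen) >= SMALL_EVENT_MAX:
            raise InvalidArgumentError(
                f"indel of {slen} bp at {pos} must go to the SV scan")
        depth = int(pileup.depth[pos])
        if depth < config.min_depth or depth == 0:
            continue
        ratio = count / depth
        if ratio >= config.min_ratio:
            calls.append(SmallIndelCall(position=int(pos),
                                        signed_length=int(slen),
                                        ratio=float(ratio), depth=depth,
                                        platform=pileup.platform))
    return calls


def consensus_calls(calls_a: Sequence, calls_b: Sequence,
                    oracle: Optional[Callable[[tuple], Optional[bool]]] = None
                    ) -> ConsensusReport:
    """Reconcile two platforms' call sets.

    Calls agreeing by (kind, position, alt) are accepted outright; each
    discrepant call is queried against the confirmation oracle (truth lookup
    standing in for Sanger re-sequencing) and accepted iff confirmed.  With
    no oracle, or when the oracle returns None for a query, the call is
    flagged unresolved rather than silently accepted or dropped.
    """
    by_key_a = {c.key: c for c in calls_a}
    by_key_b = {c.key: c for c in calls_b}
    agreed_keys = set(by_key_a) & set(by_key_b)
    agreed = [by_key_a[k] for k in sorted(agreed_keys, key=str)]
    only_a = [c for c in calls_a if c.key not in agreed_keys]
    only_b = [c for c in calls_b if c.key not in agreed_keys]

    resolutions = []
    confirmed = []
    unresolved = []
    for call in only_a + only_b:
        verdict = oracle(call.key) if oracle is not None else None
        resolutions.append((call, verdict))
        if verdict is True:
            confirmed.append(call)
        elif verdict is None:
            unresolved.append(call)
    final = agreed + confirmed
    return ConsensusReport(agreed=agreed, only_a=only_a, only_b=only_b,
                           oracle_resolutions=resolutions, final=final,
                           unresolved=unresolved)


def truth_oracle(events) -> Callable[[tuple], Optional[bool]]:
    """Build a confirmation oracle from a planted-event truth table."""
    keys = set()
    for ev in events:
        if ev.kind == "snv":
            keys.add(("snv", ev.position, ev.alt))
        elif ev.kind in ("small_insertion", "small_deletion"):
            keys.add(("indel", ev.position, ev.signed_length))

    def query(key: tuple) -> Optional[bool]:
        return key in keys

    return query


def mask_low_coverage(depth_track: np.ndarray, min_reads: int = 10
                      ) -> tuple[list[tuple[int, int]], int]:
    """Maximal half-open intervals with depth strictly below min_reads.

    Returns (intervals, total_masked_bp).
    """
    depth = np.asarray(depth_track)
    low = depth < min_reads
    if not low.any():
        return [], 0
    edges = np.diff(low.astype(np.int8))
    starts = np.nonzero(edges == 1)[0] + 1
    ends = np.nonzero(edges == -1)[0] + 1
    if low[0]:
        starts = np.concatenate([[0], starts])
    if low[-1]:
        ends = np.concatenate([ends, [len(depth)]])
    intervals = list(zip(starts.tolist(), ends.tolist()))
    total = int(sum(b - a for a, b in intervals))
    return intervals, total


def apply_mask(calls: Sequence, mask: Sequence[tuple[int, int]]
               ) -> tuple[list, list]:
    """Split calls into (kept, suppressed-inside-mask)."""
    kept, suppressed = [], []
    for c in calls:
        inside = any(a <= c.position < b for a, b in mask)
        (suppressed if inside else kept).append(c)
    return kept, suppressed


def subtract_parent(calls: Sequence, parent_calls: Sequence) -> list:
    """Drop calls also present in the parent, matched by (kind, pos, alt)."""
    parent_keys = {c.key for c in parent_calls}
    return [c for c in calls if c.key not in parent_keys]


# --------------------------------------------------------------------------- #
# Plain-text IO
# --------------------------------------------------------------------------- #


def read_pileup_tsv(path, platform: str = "", ref_length: Optional[int] = None
                    ) -> PileupTable:
    """Read a pileup TSV (pos_1based, ref, depth, variant_count, alt,
    indel_len, indel_count) into a dense PileupTable."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    L = ref_length or int(df["pos_1based"].max())
    depth = np.zeros(L, dtype=np.int64)
    vc = np.zeros(L, dtype=np.int64)
    alt = {}
    indel = {}
    for r in df.itertuples():
        pos = int(r.pos_1based) - 1
        depth[pos] = int(r.depth)
        vc[pos] = int(r.variant_count)
        if str(r.alt) not in ("", "N"):
            alt[pos] = str(r.alt)
        if int(r.indel_len) != 0:
            indel[pos] = (int(r.indel_len), int(r.indel_count))
    return PileupTable(platform=platform, depth=depth, variant_count=vc,
                       alt=alt, indel_evidence=indel)


def calls_to_frame(calls: Iterable) -> pd.DataFrame:
    """VCF-like table (1-based POS) of point/indel calls."""
    rows = []
    for c in calls:
        if isinstance(c, PointMutationCall):
            rows.append(("snv", c.position + 1, c.ref_base, c.alt_base,
                         c.ratio, c.depth, c.p_value, c.platform))
        else:
            alt = f"{c.signed_length:+d}bp"
            rows.append(("indel", c.position + 1, ".", alt, c.ratio,
                         c.depth, np.nan, c.platform))
    return pd.DataFrame(rows, columns=["kind", "pos_1based", "ref", "alt",
                                       "ratio", "depth", "p_value",
                                       "platform"])


def mask_to_bed(mask: Sequence[tuple[int, int]], path,
                chrom: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for a, b in mask:
            fh.write(f"{chrom}\t{a}\t{b}\n")
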