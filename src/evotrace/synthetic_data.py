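"""Synthetic data generation for the laboratory-evolution resequencing pipeline.

Every input the downstream analyses consume — reference genome, mutated sample
genomes with a ground-truth event table, mapped mate-pair coordinates, per-site
pileup counts from two sequencing platforms, expression/metabolite matrices,
population allele-frequency time courses and OD600 growth series — can be
generated here with the statistical structure the analyses assume, so the whole
pipeline is testable without any external download.

Coordinate convention: 0-based half-open everywhere inside the package;
1-based only in human-facing output files (VCF-like convention).

Mapped-pair "distance" is the *outer* distance: leftmost mapped coordinate of
one read to the rightmost mapped coordinate (exclusive) of its mate, both in
reference coordinates.  For an event-free fragment this equals the fragment
length; a deletion of L bp between the two reads adds +L, an insertion of L bp
subtracts L.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConflictError, InvalidArgumentError

# --------------------------------------------------------------------------- #
# Constants: event vocabulary, IS catalog, study time grids
# --------------------------------------------------------------------------- #

EVENT_KINDS = (
    "snv",
    "small_insertion",
    "small_deletion",
    "large_insertion",
    "large_deletion",
    "duplication",
)

#: small/large split for indels, in bp
SMALL_EVENT_MAX = 500

#: IS-element catalog lengths (bp).  The per-locus length variants observed in
#: the evolved strains are carried as separate entries so planted events can
#: reproduce each printed length exactly.
DEFAULT_IS_LENGTHS: dict[str, int] = {
    "IS5": 1199,
    "IS5_hns": 1195,
    "IS186": 1343,
    "IS186_yeaR": 1342,
}

#: expression sampling grid (hours after starting the evolution culture)
EXPRESSION_TIMEPOINTS_H = (0, 384, 744, 1224, 1824, 2496)

#: population-genotyping sampling grid (hours)
POPULATION_TIMEPOINTS_H = (
    216, 384, 576, 744, 888, 1056, 1224, 1392, 1584, 1824, 1968, 2232,
)

_BASES = np.array(["A", "C", "G", "T"])


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# --------------------------------------------------------------------------- #
# Domain types
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SyntheticGenome:
    """A reference genome with gene annotations and an IS-element catalog."""

    sequence: str
    gene_annotations: list  # (name, start, end, strand), 0-based half-open
    is_catalog: dict  # name -> nucleotide sequence

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PlantedEvent:
    """One ground-truth mutation planted into a sample genome.

    ``length`` is the unsigned event size in bp (0 for a SNV).  ``alt`` holds
    the replacement base(s) for SNVs/small insertions, or the IS-catalog name
    for large insertions.  ``allele_fraction`` is the fraction of the
    population carrying the event.
    """

    kind: str
    position: int
    length: int = 0
    alt: str = ""
    allele_fraction: float = 1.0

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise InvalidArgumentError(f"unknown event kind {self.kind!r}")
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise InvalidArgumentError("allele_fraction must be in [0, 1]")
        if self.kind == "snv":
            if self.length != 0:
                raise InvalidArgumentError("snv events have length 0")
        elif self.length <= 0:
            raise InvalidArgumentError(f"{self.kind} requires length > 0")
        if self.kind in ("small_insertion", "small_deletion"):
            if self.length >= SMALL_EVENT_MAX:
                raise InvalidArgumentError(
                    f"small events must be < {SMALL_EVENT_MAX} bp"
                )
        if self.kind in ("large_insertion", "large_deletion"):
            if self.length < SMALL_EVENT_MAX:
                raise InvalidArgumentError(
                    f"large events must be >= {SMALL_EVENT_MAX} bp"
                )

    @property
    def signed_length(self) -> int:
        """Net change in genome length caused by this event."""
        if self.kind in ("small_insertion", "large_insertion", "duplication"):
            return self.length
        if self.kind in ("small_deletion", "large_deletion"):
            return -self.length
        return 0

    def footprint(self) -> tuple[int, int]:
        """Reference interval occupied by the event (half-open)."""
        if self.kind in ("small_deletion", "large_deletion", "duplication"):
            return (self.position, self.position + self.length)
        return (self.position, self.position + 1)


@dataclass(frozen=True)
class _Segment:
    """One liftover segment: a sample interval and its reference image.

    kind 'match'  -- 1:1 linear mapping sample<->reference
    kind 'ins'    -- inserted novel sequence; ref_start is the anchor point
    kind 'dup'    -- second tandem copy; maps onto the same reference interval
                     as its primary 'match' copy
    """

    samp_start: int
    samp_end: int
    ref_start: int
    ref_end: int
    kind: str
    name: str = ""


class Liftover:
    """Monotone piecewise mapping between reference and sample coordinates."""

    def __init__(self, segments: Sequence[_Segment], ref_length: int,
                 sample_length: int):
        self.segments = list(segments)
        self.ref_length = ref_length
        self.sample_length = sample_length
        self._samp_starts = np.array([s.samp_start for s in self.segments])
        # primary (forward-mappable) segments for ref -> sample
        self._primary = [s for s in self.segments if s.kind == "match"]
        self._prim_ref_starts = np.array([s.ref_start for s in self._primary])

    def segment_index_of_sample(self, pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos)
        idx = np.searchsorted(self._samp_starts, pos, side="right") - 1
        return idx

    def sample_to_ref(self, pos):
        """Map sample coordinates to reference coordinates.

        Returns an int array with -1 where the position has no reference
        image (inside inserted novel sequence).
        """
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        idx = self.segment_index_of_sample(pos)
        out = np.full(pos.shape, -1, dtype=np.int64)
        for i, seg in enumerate(self.segments):
            m = idx == i
            if not m.any():
                continue
            if seg.kind in ("match", "dup"):
                out[m] = seg.ref_start + (pos[m] - seg.samp_start)
        return out

    def ref_to_sample(self, pos):
        """Map reference coordinates to the primary sample copy.

        Returns -1 for positions inside deleted reference sequence.
        """
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        idx = np.searchsorted(self._prim_ref_starts, pos, side="right") - 1
        out = np.full(pos.shape, -1, dtype=np.int64)
        for i, seg in enumerate(self._primary):
            m = idx == i
            if not m.any():
                continue
            inside = m & (pos < seg.ref_end)
            out[inside] = seg.samp_start + (pos[inside] - seg.ref_start)
        return out


@dataclass
class SampleGenome:
    """A mutated genome plus its ground truth and coordinate liftover."""

    sequence: str
    truth_table: list  # of PlantedEvent
    liftover: Liftover
    reference: SyntheticGenome

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadSimConfig:
    """Mate-pair / paired-end read simulation parameters.

    insert_mean/insert_sd parameterise the Normal fragment-length
    distribution; pair_coverage is fold read coverage (reads x read_length /
    genome length).  low_mapq_fraction and low_baseq_fraction control the
    fraction of pairs drawn below the mapq-10 / baseq-30 quality gates.
    """

    insert_mean: float = 1200.0
    insert_sd: float = 100.0
    read_length: int = 50
    pair_coverage: float = 200.0
    base_error_rate: float = 0.005
    low_mapq_fraction: float = 0.0
    low_baseq_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.insert_mean <= 2 * self.read_length:
            raise InvalidArgumentError("insert_mean must exceed 2 x read_length")
        if self.pair_coverage <= 0:
            raise InvalidArgumentError("pair_coverage must be > 0")
        if not 0.0 <= self.base_error_rate < 1.0:
            raise InvalidArgumentError("base_error_rate must be in [0, 1)")


class MappedPairSet:
    """Reference-mapped mate pairs with quality annotations.

    Backed by a DataFrame with columns ``pair_id, left_pos, right_pos, mapq,
    min_baseq, counterpart``.  ``right_pos`` is the exclusive rightmost mapped
    coordinate, so ``right_pos - left_pos`` is the outer distance.  Pairs with
    one read absorbed by inserted IS sequence carry the IS name in
    ``counterpart`` and NaN in ``right_pos``.
    """

    COLUMNS = ("pair_id", "left_pos", "right_pos", "mapq", "min_baseq",
               "counterpart")

    def __init__(self, frame: pd.DataFrame, read_length: int = 50,
                 ref_length: Optional[int] = None):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise InvalidArgumentError(f"pair table missing columns {missing}")
        self.frame = frame.reset_index(drop=True)
        self.read_length = int(read_length)
        self.ref_length = ref_length

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def distances(self) -> pd.Series:
        """Outer distances; NaN for counterpart/half-mapped pairs."""
        return self.frame["right_pos"] - self.frame["left_pos"]

    def both_mapped(self) -> "MappedPairSet":
        m = self.frame["right_pos"].notna()
        return MappedPairSet(self.frame[m], self.read_length, self.ref_length)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, read_length: int = 50) -> "MappedPairSet":
        frame = pd.read_csv(path, sep="\t")
        return cls(frame, read_length=read_length)

    @classmethod
    def from_sam(cls, path) -> "MappedPairSet":
        """Read mapped pairs from a (headered) SAM file.

        Uses the leftmost position and TLEN of the first-in-pair record; the
        minimum base quality is taken over both reads of the template.
        """
        import pysam

        rows = []
        minq: dict[str, int] = {}
        firsts = {}
        read_len = 50
        with pysam.AlignmentFile(str(path), "r") as sam:
            for rec in sam:
                if rec.is_unmapped or rec.mate_is_unmapped:
                    continue
                q = min(rec.query_qualities) if rec.query_qualities else 0
                minq[rec.query_name] = min(minq.get(rec.query_name, 255), q)
                if rec.is_read1:
                    firsts[rec.query_name] = rec
                if rec.query_length:
                    read_len = rec.query_length
        for name, rec in firsts.items():
            left = min(rec.reference_start, rec.next_reference_start)
            tlen = abs(rec.template_length)
            rows.append((name, left, left + tlen, rec.mapping_quality,
                         minq.get(name, 0), ""))
        frame = pd.DataFrame(rows, columns=list(cls.COLUMNS))
        return cls(frame, read_length=read_len)


@dataclass
class PileupTable:
    """Per-reference-site read-count evidence from one sequencing platform.

    ``depth`` and ``variant_count`` are dense int arrays over the reference;
    ``alt`` maps positions with simulated variant alleles to their alt base;
    ``indel_evidence`` maps positions to ``(signed_length, supporting_count)``.
    """

    platform: str
    depth: np.ndarray
    variant_count: np.ndarray
    alt: dict = field(default_factory=dict)
    indel_evidence: dict = field(default_factory=dict)
    ref_sequence: Optional[str] = None

    def __post_init__(self):
        from .errors import DataIntegrityError

        if (self.variant_count > self.depth).any():
            raise DataIntegrityError("variant_count exceeds depth")

    def __len__(self) -> int:
        return len(self.depth)

    def to_tsv(self, path) -> None:
        """Write sites with any variant/indel evidence plus depth track."""
        pos = sorted(set(self.alt) | set(self.indel_evidence)
                     | set(np.nonzero(self.variant_count)[0].tolist()))
        rows = []
        for p in pos:
            il, ic = self.indel_evidence.get(p, (0, 0))
            ref = self.ref_sequence[p] if self.ref_sequence else "N"
            rows.append((p + 1, ref, int(self.depth[p]),
                         int(self.variant_count[p]),
                         self.alt.get(p, "N"), il, ic))
        pd.DataFrame(rows, columns=["pos_1based", "ref", "depth",
                                    "variant_count", "alt", "indel_len",
                                    "indel_count"]).to_csv(
            path, sep="\t", index=False)


@dataclass(frozen=True)
class ODSeries:
    """An optical-density growth curve (OD600 vs time in hours)."""

    times: np.ndarray
    od600: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise InvalidArgumentError("times must be strictly increasing")
        if np.any(self.od600 <= 0):
            raise InvalidArgumentError("od600 values must be positive")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample metadata."""

    values: pd.DataFrame
    metadata: pd.DataFrame  # index = sample id, columns strain, time_h

    def __post_init__(self):
        if not set(self.values.columns) <= set(self.metadata.index):
            raise InvalidArgumentError("metadata must cover every column")


# --------------------------------------------------------------------------- #
# Reference and sample genome generation
# --------------------------------------------------------------------------- #


def _random_sequence(rng: np.random.Generator, length: int,
                     gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def generate_reference(length: int, gc_fraction: float = 0.508,
                       n_genes: int = 20, seed: int = 0,
                       is_lengths: Optional[Mapping[str, int]] = None
                       ) -> SyntheticGenome:
    """Generate a random bacterial-style reference genome.

    Gene annotations are non-overlapping intervals of ~1 kb laid out on an
    even grid; the IS catalog is attached with freshly drawn element
    sequences at the configured lengths.  Deterministic for a fixed seed.
    """
    if length <= 0:
        raise InvalidArgumentError("length must be positive")
    if not 0.0 < gc_fraction < 1.0:
        raise InvalidArgumentError("gc_fraction must be in (0, 1)")
    rng = _rng(seed)
    seq = _random_sequence(rng, length, gc_fraction)

    genes = []
    if n_genes > 0:
        slot = length // n_genes
        gene_len = max(min(1000, slot // 2), 1)
        for i in range(n_genes):
            start = i * slot
            genes.append((f"gene{i + 1:04d}", start, start + gene_len,
                          "+" if rng.random() < 0.5 else "-"))

    catalog = {}
    for name, is_len in (is_lengths or DEFAULT_IS_LENGTHS).items():
        if is_len <= 0:
            raise InvalidArgumentError("IS catalog lengths must be > 0")
        catalog[name] = _random_sequence(rng, is_len, gc_fraction)
    return SyntheticGenome(seq, genes, catalog)


def plant_events(genome: SyntheticGenome,
                 events: Iterable[PlantedEvent]) -> SampleGenome:
    """Apply planted events to a reference genome.

    Events must be non-overlapping on the reference.  The mutated sequence is
    assembled in one left-to-right walk over the sorted events; the same walk
    yields the liftover segment map relating sample and reference
    coordinates.  Duplications are tandem (the second copy immediately
    follows the first and lifts onto the same reference interval).
    """
    events = sorted(events, key=lambda e: e.position)
    ref_len = len(genome)
    prev_end = -1
    for ev in events:
        a, b = ev.footprint()
        if a < 0 or b > ref_len:
            raise InvalidArgumentError(
                f"event at {ev.position} outside reference [0, {ref_len})")
        if a < prev_end:
            raise ConflictError(f"events overlap at reference position {a}")
        prev_end = b
        if ev.kind == "large_insertion":
            if ev.alt not in genome.is_catalog:
                raise InvalidArgumentError(f"unknown IS element {ev.alt!r}")
            if ev.length != len(genome.is_catalog[ev.alt]):
                raise InvalidArgumentError(
                    f"length {ev.length} != catalog length of {ev.alt!r}")

    chunks: list[str] = []
    segments: list[_Segment] = []
    snv_edits: list[tuple[int, str]] = []  # sample-coordinate base edits
    cur_ref = 0
    cur_samp = 0

    def emit_match(ref_a: int, ref_b: int):
        nonlocal cur_samp
        if ref_b <= ref_a:
            return
        chunks.append(genome.sequence[ref_a:ref_b])
        segments.append(_Segment(cur_samp, cur_samp + (ref_b - ref_a),
                                 ref_a, ref_b, "match"))
        cur_samp += ref_b - ref_a

    for ev in events:
        p = ev.position
        emit_match(cur_ref, p)
        cur_ref = p
        if ev.kind == "snv":
            snv_edits.append((cur_samp, ev.alt))
            # the SNV base itself stays part of a match segment
            continue
        if ev.kind in ("small_insertion", "large_insertion"):
            ins_seq = (genome.is_catalog[ev.alt]
                       if ev.kind == "large_insertion" else ev.alt)
            if len(ins_seq) != ev.length:
                raise InvalidArgumentError(
                    "insertion alt sequence length mismatch")
            chunks.append(ins_seq)
            segments.append(_Segment(cur_samp, cur_samp + ev.length, p, p,
                                     "ins", ev.alt))
            cur_samp += ev.length
        elif ev.kind in ("small_deletion", "large_deletion"):
            cur_ref = p + ev.length
        elif ev.kind == "duplication":
            emit_match(p, p + ev.length)          # primary copy
            chunks.append(genome.sequence[p:p + ev.length])  # tandem copy
            segments.append(_Segment(cur_samp, cur_samp + ev.length,
                                     p, p + ev.length, "dup"))
            cur_samp += ev.length
            cur_ref = p + ev.length
    emit_match(cur_ref, ref_len)

    seq = list("".join(chunks))
    for samp_pos, alt in snv_edits:
        seq[samp_pos] = alt
    sequence = "".join(seq)

    expected = ref_len + sum(e.signed_length for e in events)
    assert len(sequence) == expected, "length conservation violated"
    lift = Liftover(segments, ref_len, len(sequence))
    return SampleGenome(sequence, list(events), lift, genome)


# --------------------------------------------------------------------------- #
# Mate-pair simulation
# --------------------------------------------------------------------------- #


def simulate_mate_pairs(sample: SampleGenome, config: ReadSimConfig,
                        n_pairs: Optional[int] = None) -> MappedPairSet:
    """Simulate reference-mapped mate pairs from a sample genome.

    Fragments of Normal(insert_mean, insert_sd) length are placed uniformly
    on the *sample* genome; each end read is then mapped back to *reference*
    coordinates through the liftover.  A read lying >= 50 % inside inserted
    novel sequence is mapped to its IS source locus (recorded as a
    counterpart hit) when the insertion is a named IS element, otherwise the
    pair is dropped as unmapped.  Deterministic per config.seed.
    """
    rng = _rng(config.seed)
    samp_len = len(sample)
    rl = config.read_length
    if n_pairs is None:
        n_pairs = int(round(config.pair_coverage * samp_len / (2 * rl)))
    frag = np.rint(rng.normal(config.insert_mean, config.insert_sd,
                              n_pairs)).astype(np.int64)
    frag = np.clip(frag, 2 * rl, None)
    if (frag >= samp_len).any():
        raise InvalidArgumentError("fragment longer than the sample genome")
    start = rng.integers(0, samp_len - frag + 1)
    end = start + frag

    lift = sample.liftover
    segs = lift.segments
    # segment index of each read's outer coordinate and of its other end
    li_a = lift.segment_index_of_sample(start)
    li_b = lift.segment_index_of_sample(start + rl - 1)
    ri_a = lift.segment_index_of_sample(end - rl)
    ri_b = lift.segment_index_of_sample(end - 1)

    kinds = np.array([s.kind for s in segs])
    names = np.array([s.name for s in segs])
    ref_starts = np.array([s.ref_start for s in segs])
    samp_starts = np.array([s.samp_start for s in segs])
    samp_ends = np.array([s.samp_end for s in segs])

    def read_status(ia, ib, a, b):
        """Per-read: mapped flag, counterpart name ('' if none).

        A read within one segment is trivially classified; reads straddling
        segment boundaries are resolved by the fraction of their length
        overlapping inserted sequence (>= 50 % -> absorbed by the insertion).
        """
        n = len(ia)
        mapped = np.zeros(n, dtype=bool)
        cpart = np.full(n, "", dtype=object)
        same = ia == ib
        ins_seg = kinds[ia] == "ins"
        mapped[same & ~ins_seg] = True
        inside_ins = same & ins_seg
        cpart[inside_ins] = names[ia[inside_ins]]
        cross = np.nonzero(~same)[0]
        for k in cross:
            ov = 0
            for j in range(ia[k], ib[k] + 1):
                if kinds[j] == "ins":
                    ov += (min(b[k], samp_ends[j])
                           - max(a[k], samp_starts[j]))
            if ov >= 0.5 * (b[k] - a[k]):
                # absorbed: credit the (single) insertion it overlaps
                nm = ""
                for j in range(ia[k], ib[k] + 1):
                    if kinds[j] == "ins" and names[j]:
                        nm = names[j]
                        break
                cpart[k] = nm
            else:
                mapped[k] = True
        return mapped, cpart

    lmap, lcp = read_status(li_a, li_b, start, start + rl)
    rmap, rcp = read_status(ri_a, ri_b, end - rl, end)

    def point_ref(pos, idx):
        """Reference image of a sample coordinate, -1 inside insertions."""
        out = np.full(len(pos), -1, dtype=np.int64)
        ok = kinds[idx] != "ins"
        out[ok] = ref_starts[idx[ok]] + (pos[ok] - samp_starts[idx[ok]])
        return out

    left_ref = point_ref(start, li_a)
    right_ref_excl = point_ref(end - 1, ri_b) + 1

    mapq = np.full(n_pairs, 60, dtype=np.int64)
    if config.low_mapq_fraction > 0:
        low = rng.random(n_pairs) < config.low_mapq_fraction
        mapq[low] = rng.integers(0, 10, low.sum())
    baseq = np.full(n_pairs, 38, dtype=np.int64)
    if config.low_baseq_fraction > 0:
        low = rng.random(n_pairs) < config.low_baseq_fraction
        baseq[low] = rng.integers(2, 30, low.sum())

    both = lmap & rmap & (left_ref >= 0) & (right_ref_excl > 0)
    # one mapped read + one IS-absorbed read = counterpart evidence
    lc = lmap & (left_ref >= 0) & (rcp != "")
    rc = rmap & (right_ref_excl > 0) & (lcp != "")

    n_keep = int(both.sum() + lc.sum() + rc.sum())
    pair_id = np.arange(n_keep)
    left_out = np.concatenate([left_ref[both],
                               left_ref[lc],
                               right_ref_excl[rc] - rl])
    right_out = np.concatenate([right_ref_excl[both].astype(float),
                                np.full(int(lc.sum()), np.nan),
                                np.full(int(rc.sum()), np.nan)])
    cpart_out = np.concatenate([np.full(int(both.sum()), "", dtype=object),
                                rcp[lc], lcp[rc]])
    mq = np.concatenate([mapq[both], mapq[lc], mapq[rc]])
    bq = np.concatenate([baseq[both], baseq[lc], baseq[rc]])

    frame = pd.DataFrame({
        "pair_id": pair_id,
        "left_pos": left_out,
        "right_pos": right_out,
        "mapq": mq,
        "min_baseq": bq,
        "counterpart": cpart_out,
    })
    order = np.argsort(frame["left_pos"].to_numpy(), kind="stable")
    frame = frame.iloc[order].reset_index(drop=True)
    frame["pair_id"] = np.arange(len(frame))
    return MappedPairSet(frame, read_length=rl,
                         ref_length=lift.ref_length)


# --------------------------------------------------------------------------- #
# Pileup simulation (two-platform point/indel evidence)
# --------------------------------------------------------------------------- #


def simulate_pileups(population: Sequence[tuple[SampleGenome, float]],
                     config: ReadSimConfig,
                     platform: str = "SOLiD") -> PileupTable:
    """Simulate per-site pileup counts over the reference for one platform.

    Site depth ~ Poisson(pair_coverage); at planted SNV sites the
    variant-supporting count ~ Binomial(depth, f(1-e) + (1-f)e) where f is
    the population frequency of the allele and e the per-base error rate;
    elsewhere variant counts are pure error draws.  Small indels emit
    indel-evidence counts ~ Binomial(depth, f) at their positions.
    """
    population = list(population)
    if not population:
        raise InvalidArgumentError("population must be non-empty")
    freqs = np.array([f for _, f in population], dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise InvalidArgumentError("population frequencies must sum to 1")

    ref = population[0][0].reference
    L = len(ref)
    rng = _rng(config.seed)
    e = config.base_error_rate
    depth = rng.poisson(config.pair_coverage, L)
    variant = rng.binomial(depth, e) if e > 0 else np.zeros(L, dtype=np.int64)

    # population frequency per planted point/indel event
    snv_f: dict[int, tuple[str, float]] = {}
    indel_f: dict[int, tuple[int, float]] = {}
    for sample, w in population:
        for ev in sample.truth_table:
            f = w * ev.allele_fraction
            if ev.kind == "snv":
                alt, f0 = snv_f.get(ev.position, (ev.alt, 0.0))
                snv_f[ev.position] = (ev.alt, f0 + f)
            elif ev.kind in ("small_insertion", "small_deletion"):
                sl = ev.signed_length
                _, f0 = indel_f.get(ev.position, (sl, 0.0))
                indel_f[ev.position] = (sl, f0 + f)

    alt_map = {}
    for pos, (alt, f) in snv_f.items():
        p = f * (1 - e) + (1 - f) * e
        variant[pos] = rng.binomial(depth[pos], min(p, 1.0))
        alt_map[pos] = alt
    indel_map = {}
    for pos, (sl, f) in indel_f.items():
        indel_map[pos] = (sl, int(rng.binomial(depth[pos], min(f, 1.0))))

    return PileupTable(platform=platform, depth=depth, variant_count=variant,
                       alt=alt_map, indel_evidence=indel_map,
                       ref_sequence=ref.sequence)


# --------------------------------------------------------------------------- #
# Expression / metabolome / growth / population time-course simulation
# --------------------------------------------------------------------------- #


def _strain_labels(n: int) -> list[str]:
    return [chr(ord("A") + i) for i in range(n)]


def simulate_expression_timecourse(
        n_genes: int = 2420,
        strains: int = 6,
        timepoints: Sequence[float] = EXPRESSION_TIMEPOINTS_H,
        shared_amplitude: float = 0.4,
        noise_sd: float = 0.05,
        divergent_strain: Optional[int] = None,
        divergent_fraction: float = 0.10,
        divergent_shift: float = np.log10(2.0),
        detection_floor: float = 1.0,
        seed: int = 0) -> ExpressionMatrix:
    """Simulate a strains x timepoints expression matrix with shared dynamics.

    Each gene follows ``log10 x = b_g + a_g f_g(t) + eps`` where f_g is a
    smooth non-monotone cubic trajectory shared across strains (f_g(0)=0,
    normalised to unit max amplitude), a_g ~ Normal(0, shared_amplitude) and
    eps ~ Normal(0, noise_sd) independently per strain/timepoint.  If
    ``divergent_strain`` is given, a contiguous block of genes in that strain
    receives an additive up-shift at all t > 0, emulating the expression
    footprint of a large genomic duplication.  Values are floored at
    ``detection_floor``.
    """
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    timepoints = list(timepoints)
    if 0 not in timepoints:
        raise InvalidArgumentError("timepoints must include 0 (parent)")
    rng = _rng(seed)
    labels = _strain_labels(strains)
    t = np.array(timepoints, dtype=float)
    ts = t / t.max() if t.max() > 0 else t

    baseline = rng.uniform(2.0, 4.0, n_genes)
    amp = rng.normal(0.0, shared_amplitude, n_genes)
    coef = rng.normal(0.0, 1.0, (n_genes, 3))  # cubic through the origin
    traj = (coef[:, [0]] * ts + coef[:, [1]] * ts ** 2
            + coef[:, [2]] * ts ** 3)
    peak = np.abs(traj).max(axis=1)
    peak[peak == 0] = 1.0
    traj = traj / peak[:, None]  # genes x timepoints, f(0) = 0

    cols = {}
    meta_rows = []
    cols["parent"] = baseline + rng.normal(0, noise_sd, n_genes)
    meta_rows.append(("parent", "parent", 0.0))
    block = slice(0, max(1, int(round(divergent_fraction * n_genes))))
    for si, s in enumerate(labels):
        for ti, tp in enumerate(timepoints):
            logv = (baseline + amp * traj[:, ti]
                    + rng.normal(0, noise_sd, n_genes))
            if divergent_strain is not None and si == divergent_strain and tp > 0:
                logv = logv.copy()
                logv[block] += divergent_shift
            name = f"{s}_t{int(tp)}"
            cols[name] = logv
            meta_rows.append((name, s, float(tp)))

    values = pd.DataFrame(
        {k: np.maximum(10.0 ** v, detection_floor) for k, v in cols.items()},
        index=[f"gene{i + 1:05d}" for i in range(n_genes)])
    metadata = pd.DataFrame(meta_rows, columns=["sample", "strain", "time_h"]
                            ).set_index("sample")
    return ExpressionMatrix(values, metadata)


def simulate_metabolome(n_metabolites: int = 83, strains: int = 6,
                        shared_logshift_sd: float = 0.5,
                        noise_sd: float = 0.1,
                        seed: int = 0) -> pd.DataFrame:
    """Simulate a metabolite x strain concentration table (uM).

    Each metabolite has a parent concentration and a log10 shift shared
    across evolved strains (~Normal(0, shared_logshift_sd)) plus independent
    per-strain noise; all concentrations are positive.
    """
    if n_metabolites <= 0 or strains <= 0:
        raise InvalidArgumentError("counts must be positive")
    if noise_sd < 0 or shared_logshift_sd < 0:
        raise InvalidArgumentError("dispersions must be >= 0")
    rng = _rng(seed)
    parent = 10.0 ** rng.uniform(0.0, 3.0, n_metabolites)
    shift = rng.normal(0.0, shared_logshift_sd, n_metabolites)
    data = {"parent": parent}
    for s in _strain_labels(strains):
        eps = rng.normal(0.0, noise_sd, n_metabolites)
        data[s] = parent * 10.0 ** (shift + eps)
    return pd.DataFrame(
        data, index=[f"met{i + 1:03d}" for i in range(n_metabolites)])


def simulate_od_series(mu: float, od0: float = 0.05, duration: float = 10.0,
                       interval: float = 0.5, noise_sd: float = 0.0,
                       seed: int = 0) -> ODSeries:
    """Simulate exponential growth OD600 readings with multiplicative noise."""
    if od0 <= 0:
        raise InvalidArgumentError("od0 must be positive")
    rng = _rng(seed)
    times = np.arange(0.0, duration + interval / 2, interval)
    eps = rng.normal(0.0, noise_sd, len(times)) if noise_sd > 0 else 0.0
    od = od0 * np.exp(mu * times) * (1.0 + eps)
    return ODSeries(times=times, od600=od)


def simulate_population_timecourse(
        mutations: Sequence[str],
        frequency_trajectories: Mapping[str, Sequence[float]],
        timepoints: Sequence[float] = POPULATION_TIMEPOINTS_H) -> pd.DataFrame:
    """Build a (mutation x timepoint) population allele-frequency table.

    Trajectories are stored verbatim; non-monotone trajectories (clonal
    interference) are permitted.
    """
    timepoints = list(timepoints)
    rows = {}
    for m in mutations:
        traj = np.asarray(frequency_trajectories[m], dtype=float)
        if len(traj) != len(timepoints):
            raise InvalidArgumentError(
                f"trajectory for {m!r} has {len(traj)} values, "
                f"expected {len(timepoints)}")
        if np.any((traj < 0) | (traj > 1)):
            raise InvalidArgumentError("frequencies must lie in [0, 1]")
        rows[m] = traj
    return pd.DataFrame(rows, index=timepoints).T


# --------------------------------------------------------------------------- #
# Plain-text writers (FASTA / TSV)
# --------------------------------------------------------------------------- #


def write_fasta(genome: SyntheticGenome | SampleGenome, path,
                name: str = "synthetic") -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write([SeqRecord(Seq(genome.sequence), id=name, description="")],
                str(path), "fasta")


def read_fasta(path) -> str:
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq).upper()


def write_truth_tsv(events: Sequence[PlantedEvent], path) -> None:
    rows = [(e.kind, e.position + 1, e.length, e.alt, e.allele_fraction)
            for e in events]
    pd.DataFrame(rows, columns=["kind", "ref_pos_1based", "length", "alt",
                                "allele_fraction"]).to_csv(
        path, sep="\t", index=False)


def read_truth_tsv(path) -> list[PlantedEvent]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [PlantedEvent(kind=r.kind, position=int(r.ref_pos_1based) - 1,
                         length=int(r.length), alt=str(r.alt),
                         allele_fraction=float(r.allele_fraction))
            for r in df.itertuples()]
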