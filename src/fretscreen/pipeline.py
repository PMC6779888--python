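"""Amplicon read processing: merge, quality filter, trim, cluster, translate.

The stages mirror a standard pooled-amplicon workflow: paired 2x250 reads are
assembled into minigene contigs (overlap merging with "outie" support, since
the amplicon is shorter than the read length), quality filtered (>= 90% of
bases above Q20), trimmed to the insert by matching the constant transgene
flanks, collapsed by Levenshtein-distance clustering to absorb PCR/sequencing
error, translated in frame 0, and stripped of stop-codon clusters and known
artifacts.  Every stage reports a drop ledger and the module is fully
deterministic.

Merging rule
------------
Candidate overlaps are end-anchored: *innie* geometry aligns the tail of R1
with the head of the reverse-complemented R2 (merged length L1+L2-o) and
*outie* geometry the converse, keeping only the overlap (merged length o, the
3' overhangs being adapter read-through).  Among all candidates with overlap in
[min_overlap, max_overlap] the one minimizing the overlap mismatch ratio wins;
ties prefer the larger overlap, and at equal overlap the innie arrangement.
The compiled kernel prunes candidates with exact integer bounds (a candidate is
abandoned as soon as its mismatch count can no longer strictly beat the best
qualifying candidate, nor pass ``max_mismatch_ratio``), which is
output-equivalent to the exhaustive scan.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np
from numba import njit

from .design import STOP, translate_nt
from .io import FastqBlock

__all__ = [
    "ReadPair", "MergedRead", "MergedBlock", "SeqCluster", "PipelineParams",
    "merge_read_pairs", "quality_filter", "trim_to_insert",
    "cluster_by_edit_distance", "translate_and_filter", "apply_blacklist",
    "process_gate",
]

logger = logging.getLogger(__name__)

_COMP_LUT = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTacgt", b"TGCAtgca"):
    _COMP_LUT[_a] = _b


@dataclass(frozen=True)
class ReadPair:
    """One paired-end record; qualities are Phred scores, not ASCII."""

    r1_seq: str
    r2_seq: str
    r1_qual: Sequence[int]
    r2_qual: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(self.r2_qual):
            raise ValueError("sequence and quality lengths differ")


@dataclass(frozen=True)
class MergedRead:
    seq: str
    qual: tuple[int, ...]
    overlap_len: int
    mismatches_in_overlap: int


@dataclass
class MergedBlock:
    """Columnar batch of merged contigs."""

    seqs: np.ndarray       # (n, width) uint8 ASCII
    quals: np.ndarray      # (n, width) uint8 Phred
    lengths: np.ndarray
    overlap_len: np.ndarray
    mismatches: np.ndarray

    def __len__(self) -> int:
        return self.seqs.shape[0]

    def record(self, i: int) -> MergedRead:
        L = self.lengths[i]
        return MergedRead(seq=self.seqs[i, :L].tobytes().decode("ascii"),
                          qual=tuple(int(q) for q in self.quals[i, :L]),
                          overlap_len=int(self.overlap_len[i]),
                          mismatches_in_overlap=int(self.mismatches[i]))

    def to_records(self) -> list[MergedRead]:
        return [self.record(i) for i in range(len(self))]

    def select(self, mask: np.ndarray) -> "MergedBlock":
        return MergedBlock(self.seqs[mask], self.quals[mask], self.lengths[mask],
                           self.overlap_len[mask], self.mismatches[mask])


@njit(cache=True)
def _merge_kernel(r1, l1, q1, r2, l2, q2, comp,
                  min_o, max_o, max_ratio, allow_outies,
                  out_seq, out_q, out_len, out_overlap, out_mm, out_status):
    n = r1.shape[0]
    for i in range(n):
        L1 = l1[i]
        L2 = l2[i]
        ohi = max_o
        if L1 < ohi:
            ohi = L1
        if L2 < ohi:
            ohi = L2
        best_m = -1
        best_o = 0
        best_geom = 0
        for o in range(ohi, min_o - 1, -1):
            for geom in range(2):
                if geom == 1:
                    if not allow_outies:
                        continue
                    if o == L1 and o == L2:
                        continue  # identical to the innie full-overlap candidate
                m_allow = int(max_ratio * o + 1e-9)
                if best_m >= 0:
                    ma2 = (best_m * o - 1) // best_o
                    if ma2 < m_allow:
                        m_allow = ma2
                if m_allow < 0:
                    continue
                m = 0
                ok = True
                if geom == 0:
                    s = L1 - o
                    for j in range(o):
                        if r1[i, s + j] != comp[r2[i, L2 - 1 - j]]:
                            m += 1
                            if m > m_allow:
                                ok = False
                                break
                else:
                    for j in range(o):
                        if r1[i, j] != comp[r2[i, o - 1 - j]]:
                            m += 1
                            if m > m_allow:
                                ok = False
                                break
                if ok:
                    best_m = m
                    best_o = o
                    best_geom = geom
            if best_m == 0:
                break  # nothing at a smaller overlap can strictly beat ratio 0
        if best_m < 0:
            out_status[i] = 1
            out_len[i] = 0
            out_overlap[i] = 0
            out_mm[i] = 0
            continue
        o = best_o
        if best_geom == 0:
            s = L1 - o
            for j in range(s):
                out_seq[i, j] = r1[i, j]
                out_q[i, j] = q1[i, j]
            for j in range(o):
                a = r1[i, s + j]
                b = comp[r2[i, L2 - 1 - j]]
                qa = q1[i, s + j]
                qb = q2[i, L2 - 1 - j]
                if a == b:
                    out_seq[i, s + j] = a
                    out_q[i, s + j] = qa if qa >= qb else qb
                else:
                    if qa >= qb:
                        out_seq[i, s + j] = a
                    else:
                        out_seq[i, s + j] = b
                    d = qa - qb if qa >= qb else qb - qa
                    out_q[i, s + j] = d if d >= 2 else 2
            for t in range(o, L2):
                out_seq[i, s + t] = comp[r2[i, L2 - 1 - t]]
                out_q[i, s + t] = q2[i, L2 - 1 - t]
            out_len[i] = L1 + L2 - o
        else:
            for j in range(o):
                a = r1[i, j]
                b = comp[r2[i, o - 1 - j]]
                qa = q1[i, j]
                qb = q2[i, o - 1 - j]
                if a == b:
                    out_seq[i, j] = a
                    out_q[i, j] = qa if qa >= qb else qb
                else:
                    if qa >= qb:
                        out_seq[i, j] = a
                    else:
                        out_seq[i, j] = b
                    d = qa - qb if qa >= qb else qb - qa
                    out_q[i, j] = d if d >= 2 else 2
            out_len[i] = o
        out_status[i] = 0
        out_overlap[i] = o
        out_mm[i] = best_m


def _as_blocks(pairs) -> tuple[FastqBlock, FastqBlock, list[int], list[tuple[int, str]]]:
    """Normalize input to a pair of FastqBlocks, pre-failing malformed records."""
    if isinstance(pairs, tuple) and len(pairs) == 2 and isinstance(pairs[0], FastqBlock):
        b1, b2 = pairs
        if len(b1) != len(b2):
            raise ValueError("R1 and R2 blocks have different sizes")
        return b1, b2, list(range(len(b1))), []
    recs1, recs2, keep_idx, failures = [], [], [], []
    for i, p in enumerate(pairs):
        if isinstance(p, ReadPair):
            r1s, r1q, r2s, r2q = p.r1_seq, p.r1_qual, p.r2_seq, p.r2_qual
        else:
            r1s, r1q, r2s, r2q = p
            if len(r1s) != len(r1q) or len(r2s) != len(r2q):
                failures.append((i, "length_mismatch"))
                continue
        recs1.append((r1s, r1q))
        recs2.append((r2s, r2q))
        keep_idx.append(i)
    return (FastqBlock.from_records(recs1), FastqBlock.from_records(recs2),
            keep_idx, failures)


def merge_read_pairs(pairs, min_overlap: int = 10, max_overlap: int = 304,
                     max_mismatch_ratio: float = 0.25, allow_outies: bool = True):
    """Assemble read pairs into contigs.

    ``pairs`` is either ``(r1_block, r2_block)`` of :class:`FastqBlock` or an
    iterable of :class:`ReadPair` / ``(r1_seq, r1_qual, r2_seq, r2_qual)``
    tuples.  Returns ``(MergedBlock, failures)`` where failures is a list of
    ``(input_index, reason)``; malformed records fail individually rather than
    aborting the batch.  Consensus in the overlap takes the higher-quality base
    (R1 on quality ties); consensus quality is ``max(q1,q2)`` on agreement and
    ``max(2, |q1-q2|)`` on disagreement.
    """
    if min_overlap < 1 or max_overlap < min_overlap:
        raise ValueError("need 1 <= min_overlap <= max_overlap")
    b1, b2, keep_idx, failures = _as_blocks(pairs)
    n = len(b1)
    wout = (b1.seqs.shape[1] if n else 0) + (b2.seqs.shape[1] if n else 0)
    # rows are only defined up to their merged length; everything downstream
    # masks by length, so uninitialized padding is fine
    out_seq = np.empty((n, wout), dtype=np.uint8)
    out_q = np.empty((n, wout), dtype=np.uint8)
    out_len = np.zeros(n, dtype=np.int32)
    out_overlap = np.zeros(n, dtype=np.int32)
    out_mm = np.zeros(n, dtype=np.int32)
    out_status = np.zeros(n, dtype=np.int8)
    if n:
        _merge_kernel(b1.seqs, b1.lengths.astype(np.int64), b1.quals,
                      b2.seqs, b2.lengths.astype(np.int64), b2.quals,
                      _COMP_LUT, min_overlap, max_overlap,
                      float(max_mismatch_ratio), allow_outies,
                      out_seq, out_q, out_len, out_overlap, out_mm, out_status)
    ok = out_status == 0
    for j in np.flatnonzero(~ok):
        failures.append((keep_idx[j], "no_overlap"))
    failures.sort()
    wmax = int(out_len.max()) if n else 0
    if ok.all():
        merged = MergedBlock(out_seq[:, :wmax], out_q[:, :wmax], out_len,
                             out_overlap, out_mm)
    else:
        merged = MergedBlock(out_seq[ok, :wmax], out_q[ok, :wmax], out_len[ok],
                             out_overlap[ok], out_mm[ok])
    return merged, failures


def quality_filter(merged, min_q: int = 20, min_fraction: float = 0.9):
    """Keep contigs whose fraction of bases with quality strictly above
    ``min_q`` is at least ``min_fraction``.

    Accepts a :class:`MergedBlock` (returns a filtered block) or a sequence of
    :class:`MergedRead` (returns a filtered list).  Second return value is the
    stage ledger.
    """
    if isinstance(merged, MergedBlock):
        width = merged.quals.shape[1]
        valid = np.arange(width)[None, :] < merged.lengths[:, None]
        good = ((merged.quals > min_q) & valid).sum(axis=1)
        keep = good >= min_fraction * merged.lengths - 1e-9
        ledger = {"input": len(merged), "kept": int(keep.sum()),
                  "dropped_quality": int((~keep).sum())}
        return merged.select(keep), ledger
    kept = []
    for r in merged:
        qual = np.asarray(r.qual)
        if len(qual) and (qual > min_q).sum() >= min_fraction * len(qual) - 1e-9:
            kept.append(r)
    return kept, {"input": len(merged), "kept": len(kept),
                  "dropped_quality": len(merged) - len(kept)}


def trim_to_insert(merged, flank5: str, flank3: str, max_flank_mismatches: int = 3):
    """Strip the constant transgene flanks, returning insert sequences.

    Flank matching is positional Hamming at fixed offsets (no indel tolerance):
    ``flank5`` must match the contig prefix and ``flank3`` the suffix, each with
    at most ``max_flank_mismatches`` mismatches.  Contigs failing either match,
    or shorter than the two flanks combined, are dropped and tallied.
    """
    if not flank5 or not flank3:
        raise ValueError("flanks must be non-empty")
    f5 = np.frombuffer(flank5.encode(), dtype=np.uint8)
    f3 = np.frombuffer(flank3.encode(), dtype=np.uint8)
    if isinstance(merged, MergedBlock):
        seqs, lengths = merged.seqs, merged.lengths
    else:
        block = FastqBlock.from_records([(r.seq, r.qual) for r in merged])
        seqs, lengths = block.seqs, block.lengths
    n = len(lengths)
    inserts: list[str] = []
    ledger = {"input": n, "kept": 0, "dropped_short": 0, "dropped_flank5": 0,
              "dropped_flank3": 0}
    min_len = len(f5) + len(f3)
    for L in np.unique(lengths):
        idx = np.flatnonzero(lengths == L)
        if L < min_len:
            ledger["dropped_short"] += idx.size
            continue
        sub = seqs[idx]
        mm5 = (sub[:, : len(f5)] != f5[None, :]).sum(axis=1)
        mm3 = (sub[:, L - len(f3): L] != f3[None, :]).sum(axis=1)
        ok5 = mm5 <= max_flank_mismatches
        ok3 = mm3 <= max_flank_mismatches
        ledger["dropped_flank5"] += int((~ok5).sum())
        ledger["dropped_flank3"] += int((ok5 & ~ok3).sum())
        good = idx[ok5 & ok3]
        ins = seqs[good, len(f5): L - len(f3)]
        inserts.extend(row.tobytes().decode("ascii") for row in ins)
        ledger["kept"] += good.size
    return inserts, ledger


# ---------------------------------------------------------------------------
# Clustering


@dataclass(frozen=True)
class SeqCluster:
    """An error-collapsed sequence cluster.

    ``canonical`` is the highest-count member (count ties broken
    lexicographically); every member is within the clustering distance of it.
    ``productive``/``peptide`` are filled by :func:`translate_and_filter`.
    """

    canonical: str
    member_count: int
    members: tuple[tuple[str, int], ...]
    productive: Optional[bool] = None
    peptide: Optional[str] = None


def _edit_distance_at_most(a: str, b: str, k: int) -> int:
    """Levenshtein distance if <= k else -1 (edlib, global alignment)."""
    if a == b:
        return 0
    res = edlib.align(a, b, task="distance", k=k)
    return res["editDistance"]


class _BandedIndex:
    """Exact candidate generation for Levenshtein <= d joins.

    Same-length sequences use the (d+1)-segment pigeonhole: if dist(q, c) <= d
    at least one of q's d+1 segments appears verbatim in c shifted by at most d,
    so each canonical is registered under every segment substring at offsets
    -d..d.  Sequences of different (but compatible) lengths are compared
    exhaustively; short sequences (< d+1 long) fall back to brute force within
    their length class.
    """

    def __init__(self, max_dist: int):
        self.d = max_dist
        self.by_len: dict[int, list[int]] = defaultdict(list)
        self.band: dict[tuple[int, int, str], list[int]] = defaultdict(list)
        self.canonicals: list[str] = []

    @staticmethod
    def _starts(L: int, nseg: int) -> list[int]:
        return [i * L // nseg for i in range(nseg + 1)]

    def add(self, seq: str) -> int:
        idx = len(self.canonicals)
        self.canonicals.append(seq)
        L = len(seq)
        self.by_len[L].append(idx)
        d = self.d
        if L >= d + 1:
            starts = self._starts(L, d + 1)
            for slot in range(d + 1):
                s, e = starts[slot], starts[slot + 1]
                for off in range(-d, d + 1):
                    if 0 <= s + off and e + off <= L:
                        self.band[(L, slot, seq[s + off: e + off])].append(idx)
        return idx

    def candidates(self, seq: str) -> set[int]:
        L = len(seq)
        d = self.d
        out: set[int] = set()
        if L >= d + 1:
            starts = self._starts(L, d + 1)
            for slot in range(d + 1):
                s, e = starts[slot], starts[slot + 1]
                out.update(self.band.get((L, slot, seq[s:e]), ()))
        else:
            out.update(self.by_len.get(L, ()))
        for L2 in range(L - d, L + d + 1):
            if L2 != L:
                out.update(self.by_len.get(L2, ()))
        return out


def cluster_by_edit_distance(insert_counts: Mapping[str, int],
                             max_dist: int = 3) -> list[SeqCluster]:
    """Greedy centroid clustering of insert sequences.

    Sequences are visited by descending count (ties lexicographic); each joins
    the earliest-founded cluster whose canonical is within Levenshtein distance
    ``max_dist``, else founds a new cluster.  The canonical of a cluster is its
    founder, which is by construction its highest-count member.
    """
    if any(c < 1 for c in insert_counts.values()):
        raise ValueError("insert counts must be >= 1")
    ordered = sorted(insert_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    index = _BandedIndex(max_dist)
    members: list[list[tuple[str, int]]] = []
    totals: list[int] = []
    for seq, cnt in ordered:
        cand = index.candidates(seq)
        target = None
        for idx in sorted(cand):
            if _edit_distance_at_most(seq, index.canonicals[idx], max_dist) >= 0:
                target = idx
                break
        if target is None:
            target = index.add(seq)
            members.append([])
            totals.append(0)
        members[target].append((seq, cnt))
        totals[target] += cnt
    return [SeqCluster(canonical=index.canonicals[i], member_count=totals[i],
                       members=tuple(members[i]))
            for i in range(len(totals))]


def translate_and_filter(clusters: Sequence[SeqCluster]):
    """Translate canonicals in frame 0; drop length artifacts and stop clusters.

    Inserts are cloned in frame with the reporter cassette, so no frame search
    is performed: clusters whose canonical length is not divisible by 3 are
    length artifacts, and clusters whose translation contains a stop codon are
    residual non-productive inserts that escaped purity sorting.
    """
    kept: list[SeqCluster] = []
    ledger = {"input": len(clusters), "kept": 0, "dropped_length": 0,
              "dropped_stop": 0, "reads_dropped": 0}
    for c in clusters:
        if len(c.canonical) % 3 != 0:
            ledger["dropped_length"] += 1
            ledger["reads_dropped"] += c.member_count
            continue
        pep = translate_nt(c.canonical)
        if STOP in pep:
            ledger["dropped_stop"] += 1
            ledger["reads_dropped"] += c.member_count
            continue
        kept.append(SeqCluster(canonical=c.canonical, member_count=c.member_count,
                               members=c.members, productive=True, peptide=pep))
    ledger["kept"] = len(kept)
    return kept, ledger


def apply_blacklist(clusters: Sequence[SeqCluster], blacklist: Iterable[str]):
    """Remove clusters whose canonical is a known PCR / in-silico artifact."""
    bl = set(blacklist)
    kept = [c for c in clusters if c.canonical not in bl]
    removed = [c for c in clusters if c.canonical in bl]
    present = {c.canonical for c in clusters}
    for seq in bl - present:
        logger.warning("blacklisted sequence absent from input: %s", seq)
    ledger = {"input": len(clusters), "kept": len(kept),
              "dropped_blacklist": len(removed),
              "reads_dropped": sum(c.member_count for c in removed)}
    return kept, ledger


@dataclass(frozen=True)
class PipelineParams:
    """Bundled stage parameters for one analysis run."""

    min_overlap: int = 10
    max_overlap: int = 304
    max_mismatch_ratio: float = 0.25
    allow_outies: bool = True
    min_q: int = 20
    min_fraction: float = 0.9
    max_flank_mismatches: int = 3
    cluster_max_dist: int = 3


def process_gate(r1_block: FastqBlock, r2_block: FastqBlock,
                 flank5: str, flank3: str,
                 params: PipelineParams = PipelineParams(),
                 blacklist: Iterable[str] = ()):
    """Run the full per-gate pipeline; returns ``(clusters, ledger)``.

    The ledger reconciles read counts across stages: input pairs equal merged
    plus merge failures, merged equals QC-kept plus QC-dropped, and so on.
    """
    merged, failures = merge_read_pairs(
        (r1_block, r2_block), min_overlap=params.min_overlap,
        max_overlap=params.max_overlap,
        max_mismatch_ratio=params.max_mismatch_ratio,
        allow_outies=params.allow_outies)
    ledger: dict = {"input_pairs": len(r1_block), "merged": len(merged),
                    "merge_failures": len(failures)}
    kept, ql = quality_filter(merged, min_q=params.min_q,
                              min_fraction=params.min_fraction)
    ledger["qc"] = ql
    inserts, tl = trim_to_insert(kept, flank5, flank3,
                                 max_flank_mismatches=params.max_flank_mismatches)
    ledger["trim"] = tl
    counts = Counter(inserts)
    clusters = cluster_by_edit_distance(counts, max_dist=params.cluster_max_dist) if counts else []
    ledger["clusters_raw"] = len(clusters)
    clusters, fl = translate_and_filter(clusters)
    ledger["translate"] = fl
    clusters, bl_ledger = apply_blacklist(clusters, blacklist)
    ledger["blacklist"] = bl_ledger
    ledger["clusters_final"] = len(clusters)
    ledger["reads_final"] = sum(c.member_count for c in clusters)
    return clusters, ledger
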