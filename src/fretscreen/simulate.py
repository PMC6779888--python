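"""Generative model of the FRET-shift FACS screen.

The wet-lab process being emulated: a minigene library is delivered to target
cells by lentivirus at low MOI (so most cells carry a single integration),
purity-sorted to cells with a productive reporter-minigene transgene, optionally
spiked with a cognate clone at a defined abundance, co-cultured with effector
T cells, and sorted into Shifted (reporter cleaved by granzyme B) and Unshifted
gates.  Integrated minigenes in each gate are PCR-amplified from the constant
transgene context and sequenced as 2x250 paired-end amplicons.

Granzyme delivery is collapsed to a single Bernoulli gate probability per cell:
a cell carrying a cognate minigene enters the Shifted gate with probability
``min(1, p_hit * f_reactive * et_ratio)`` and every other cell with the
false-positive probability ``p_fp`` (bystander uptake plus gate spillover).
FRET kinetics are not modelled; the defaults describe a 4-h co-culture inside
the safe-sorting window, before apoptotic loss of shifted cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import stats

from .design import LibrarySpec

__all__ = [
    "TransductionModel", "CocultureParams", "SequencingModel",
    "CellPopulation", "SortResult",
    "build_cell_library", "simulate_coculture_sort", "simulate_amplicon_reads",
    "DEFAULT_FLANK5", "DEFAULT_FLANK3",
]

# Constant transgene context amplified around the minigene insert (arbitrary
# fixed sequences standing in for the vector's cloning-site flanks).
DEFAULT_FLANK5 = ("AATGCAGCGTCAACTAGGTGGTTGATCGAACCAACTCGTAGAACAAAGGG"
                  "AACAGGGGTGTTCTGTCCGCTCGCTATAGTCTCCATTTGTCGTACAAAAC")
DEFAULT_FLANK3 = ("TCTATCAGGGGAATACTATGGGTTACGTAACTAAAAATATGTCACCTTAG"
                  "GGCTACCTCCGACTGTATAATCCTTAGTAAATTAGACTGGCGGCCCCGCT")

# Adapter context sequenced through when the read is longer than the amplicon
# (Illumina TruSeq adapter starts); constants, not tunables.
_ADAPTER_R1 = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
_ADAPTER_R2 = "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGTA"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _CODE[_c] = _i
_COMP_LUT = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMP_LUT[_a] = _b


def _revcomp(seq: str) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _COMP_LUT[arr][::-1].tobytes().decode("ascii")


@dataclass(frozen=True)
class TransductionModel:
    """Poisson model of lentiviral integrations per cell.

    ``moi_lambda`` is the Poisson rate; with the default 0.1 and conditioning on
    transduced cells (the purity sort keeps only cells with >= 1 integration),
    ~95% of kept cells carry exactly one minigene.
    """

    moi_lambda: float = 0.1
    condition_on_transduced: bool = True

    def __post_init__(self) -> None:
        if self.moi_lambda <= 0:
            raise ValueError("moi_lambda must be > 0")

    def single_integrant_fraction(self) -> float:
        """Closed form P(k=1 | k>=1) = lambda*exp(-lambda)/(1-exp(-lambda))."""
        lam = self.moi_lambda
        return lam * np.exp(-lam) / (1.0 - np.exp(-lam))


@dataclass(frozen=True)
class CocultureParams:
    """Per-cell gate probabilities for the co-culture sort.

    ``p_hit`` applies at reactive-effector fraction 1 and E:T 1:1; the effective
    hit probability scales linearly with ``f_reactive`` and ``et_ratio`` and is
    capped at 1.  ``p_fp`` is the probability that a non-cognate cell lands in
    the Shifted gate anyway.
    """

    p_hit: float = 0.6
    f_reactive: float = 1.0
    et_ratio: float = 1.0
    p_fp: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("p_hit", "f_reactive", "p_fp"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.et_ratio <= 0:
            raise ValueError("et_ratio must be > 0")

    @property
    def p_effective(self) -> float:
        return min(1.0, self.p_hit * self.f_reactive * self.et_ratio)


@dataclass(frozen=True)
class SequencingModel:
    """Amplicon sequencing of gate-sorted cells.

    Per-template weights are cell counts times a log-normal PCR amplification
    factor (sigma ``amp_lognorm_sigma``); reads are drawn multinomially over
    templates.  Substitution errors are i.i.d. per base; qualities are drawn
    from a clipped normal (Phred+33 encoding downstream) and are independent of
    the error process.
    """

    reads_per_gate: int = 500_000
    read_len: int = 250
    sub_error_rate: float = 0.002
    amp_lognorm_sigma: float = 0.5
    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3
    qual_mean: float = 32.0
    qual_sd: float = 3.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sub_error_rate < 1.0):
            raise ValueError("sub_error_rate outside [0,1)")
        if self.reads_per_gate < 0 or self.read_len < 1:
            raise ValueError("invalid reads_per_gate / read_len")


@dataclass
class CellPopulation:
    """Per-clone composition of a transduced target-cell population.

    Single-integrant cells are stored as per-clone counts; multi-integrant cells
    are kept individually (``multi_clones`` rows, padded with -1) because a cell
    carrying a cognate plus a passenger minigene contributes *both* inserts to
    the Shifted gate when it shifts.
    """

    ids: tuple[str, ...]
    single_counts: np.ndarray              # (n_clones,) int64
    multi_clones: np.ndarray               # (n_multi, kmax) int32, -1 padded
    untransduced: int = 0

    def __post_init__(self) -> None:
        if (self.single_counts < 0).any():
            raise ValueError("negative cell counts")

    @property
    def n_cells(self) -> int:
        return int(self.single_counts.sum()) + self.multi_clones.shape[0] + self.untransduced

    @property
    def multi_integrant_fraction(self) -> float:
        trans = self.n_cells - self.untransduced
        return self.multi_clones.shape[0] / trans if trans else 0.0

    def counts_by_clone(self) -> np.ndarray:
        """Cells carrying each clone (multi-integrant cells count once per clone carried)."""
        out = self.single_counts.copy()
        if self.multi_clones.size:
            flat = self.multi_clones[self.multi_clones >= 0]
            np.add.at(out, flat, 1)
        return out

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "CellPopulation":
        ids = tuple(counts)
        return cls(ids=ids,
                   single_counts=np.array([counts[i] for i in ids], dtype=np.int64),
                   multi_clones=np.empty((0, 1), dtype=np.int32))


@dataclass
class SortResult:
    """Per-clone carrier-cell counts in each FACS gate for one co-culture."""

    ids: tuple[str, ...]
    shifted: np.ndarray         # (n_clones,) int64 carrier counts
    unshifted: np.ndarray
    n_cells_shifted: int
    n_cells_unshifted: int
    gate_capacity: Optional[int] = None

    def counts(self, gate: str) -> np.ndarray:
        if gate not in ("shifted", "unshifted"):
            raise ValueError(f"unknown gate {gate!r}")
        return self.shifted if gate == "shifted" else self.unshifted


def _draw_truncated_poisson(rng: np.random.Generator, lam: float, n: int) -> np.ndarray:
    """k ~ Poisson(lam) conditioned on k >= 1, via inverse CDF."""
    kmax = 1
    while stats.poisson.sf(kmax, lam) > 1e-12 / max(n, 1):
        kmax += 1
    ks = np.arange(1, kmax + 1)
    pmf = stats.poisson.pmf(ks, lam)
    cdf = np.cumsum(pmf / pmf.sum())
    u = rng.random(n)
    return ks[np.searchsorted(cdf, u, side="right").clip(max=len(ks) - 1)]


def build_cell_library(spec: LibrarySpec, total_cells: int,
                       tm: TransductionModel = TransductionModel(),
                       seed=None, purity_sorted: bool = True) -> CellPopulation:
    """Transduce ``total_cells`` target cells with the library and apply spikes.

    Each cell draws an integration count from the MOI model (conditioned on >= 1
    when ``condition_on_transduced``); each integration draws a clone from the
    effective abundance vector (DNA-mode spikes are folded into that vector
    before transduction).  Cell-mode spikes replace a binomially drawn fraction
    of cells with pure single-integrant spike cells.  With ``purity_sorted``,
    cells are additionally conditioned on carrying at least one productive
    minigene, emulating the reporter purity sort.
    """
    if total_cells < 1:
        raise ValueError("total_cells must be >= 1")
    rng = np.random.default_rng(seed)

    ab = spec.effective_abundances()
    minigenes = spec.minigenes
    cell_spikes = [(mg, f) for mg, f, mode in spec.spikes if mode == "cell"]
    # cell-mode spike fractions act at the cell level, not through transduction
    for mg, f in cell_spikes:
        ab[mg.id] -= f
    ids = tuple(ab)
    probs = np.array([max(ab[i], 0.0) for i in ids], dtype=float)
    probs /= probs.sum()
    index = {i: j for j, i in enumerate(ids)}
    productive = np.array([minigenes[i].peptide is not None for i in ids])
    if purity_sorted and not productive.any():
        raise ValueError("purity sort requested but no productive clones in the library")

    n_spike_cells = {}
    remaining = total_cells
    for mg, f in cell_spikes:
        k = int(rng.binomial(total_cells, f))
        n_spike_cells[mg.id] = k
        remaining -= k
    if remaining < 0:
        raise ValueError("spike fractions exceed the population")

    untransduced = 0
    if tm.condition_on_transduced:
        k_int = _draw_truncated_poisson(rng, tm.moi_lambda, remaining)
    else:
        k_int = rng.poisson(tm.moi_lambda, remaining)
        untransduced = int((k_int == 0).sum())
        k_int = k_int[k_int > 0]

    n_single = int((k_int == 1).sum())
    multi_ks = k_int[k_int >= 2]

    # Single-integrant cells: purity sort conditions the clone draw on productivity.
    p_single = probs.copy()
    if purity_sorted:
        p_single[~productive] = 0.0
        p_single /= p_single.sum()
    single_counts = rng.multinomial(n_single, p_single).astype(np.int64)

    # Multi-integrant cells: draw k clones i.i.d.; purity sort keeps cells with
    # >= 1 productive integration (rejection resampling).
    kmax = int(multi_ks.max()) if multi_ks.size else 1
    multi = np.full((multi_ks.size, kmax), -1, dtype=np.int32)
    if multi_ks.size:
        # vectorized fill: draw kmax clones per cell, mask beyond each cell's k
        draws = rng.choice(len(ids), size=(multi_ks.size, kmax), p=probs).astype(np.int32)
        mask = np.arange(kmax)[None, :] < multi_ks[:, None]
        multi = np.where(mask, draws, -1)
        if purity_sorted:
            bad = ~(productive[np.clip(multi, 0, None)] & (multi >= 0)).any(axis=1)
            while bad.any():
                nbad = int(bad.sum())
                redraw = rng.choice(len(ids), size=(nbad, kmax), p=probs).astype(np.int32)
                multi[bad] = np.where(mask[bad], redraw, -1)
                bad2 = ~(productive[np.clip(multi, 0, None)] & (multi >= 0)).any(axis=1)
                bad = bad2
    for mg_id, k in n_spike_cells.items():
        single_counts[index[mg_id]] += k

    return CellPopulation(ids=ids, single_counts=single_counts,
                          multi_clones=multi, untransduced=untransduced)


def simulate_coculture_sort(pop: CellPopulation, cp: CocultureParams,
                            cognate_ids: Iterable[str],
                            gate_capacity: Optional[int] = None,
                            seed=None) -> SortResult:
    """Two-gate FACS sort of the co-culture.

    Every cell carrying >= 1 cognate minigene enters the Shifted gate with
    probability ``min(1, cp.p_effective + cp.p_fp)``; every other cell with
    ``cp.p_fp``; the rest are Unshifted.  The false-positive pathway (bystander
    granzyme uptake plus gate spillover) applies to every cell, so with no
    reactive effectors the whole population shifts at exactly ``p_fp``.  With
    ``gate_capacity``, each gate is subsampled without replacement to at most
    that many cells (finite sort yield).  Untransduced cells carry no template
    and are ignored.
    """
    cognate_ids = set(cognate_ids)
    unknown = cognate_ids - set(pop.ids)
    if unknown:
        raise ValueError(f"cognate ids not in population: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n_clones = len(pop.ids)
    is_cognate = np.array([i in cognate_ids for i in pop.ids])
    p_eff = min(1.0, cp.p_effective + cp.p_fp)

    p_vec = np.where(is_cognate, p_eff, cp.p_fp)
    single_shifted = rng.binomial(pop.single_counts, p_vec)
    single_unshifted = pop.single_counts - single_shifted

    multi = pop.multi_clones
    if multi.size:
        carries_cognate = (is_cognate[np.clip(multi, 0, None)] & (multi >= 0)).any(axis=1)
        p_multi = np.where(carries_cognate, p_eff, cp.p_fp)
        multi_shift = rng.random(multi.shape[0]) < p_multi
    else:
        multi_shift = np.zeros(0, dtype=bool)

    def _subsample(single_vec: np.ndarray, multi_idx: np.ndarray, cap: int):
        total = int(single_vec.sum()) + multi_idx.size
        if total <= cap:
            return single_vec, multi_idx
        keep_single = rng.hypergeometric(int(single_vec.sum()), multi_idx.size, cap)
        single_kept = rng.multivariate_hypergeometric(single_vec, keep_single).astype(np.int64)
        multi_kept = rng.choice(multi_idx, size=cap - keep_single, replace=False)
        return single_kept, multi_kept

    multi_idx_shift = np.flatnonzero(multi_shift)
    multi_idx_unshift = np.flatnonzero(~multi_shift)
    if gate_capacity is not None:
        single_shifted, multi_idx_shift = _subsample(single_shifted, multi_idx_shift, gate_capacity)
        single_unshifted, multi_idx_unshift = _subsample(single_unshifted, multi_idx_unshift, gate_capacity)

    def _carrier_counts(single_vec: np.ndarray, multi_idx: np.ndarray) -> np.ndarray:
        out = single_vec.astype(np.int64).copy()
        if multi_idx.size:
            flat = multi[multi_idx]
            flat = flat[flat >= 0]
            np.add.at(out, flat, 1)
        return out

    shifted = _carrier_counts(single_shifted, multi_idx_shift)
    unshifted = _carrier_counts(single_unshifted, multi_idx_unshift)
    return SortResult(
        ids=pop.ids, shifted=shifted, unshifted=unshifted,
        n_cells_shifted=int(single_shifted.sum()) + multi_idx_shift.size,
        n_cells_unshifted=int(single_unshifted.sum()) + multi_idx_unshift.size,
        gate_capacity=gate_capacity)


def _amplicon_rows(sr: SortResult, sm: SequencingModel,
                   clone_seqs: Mapping[str, str]):
    """Per-clone R1/R2 template rows (uint8), reading into adapter if needed."""
    n = len(sr.ids)
    r1_rows = np.zeros((n, sm.read_len), dtype=np.uint8)
    r2_rows = np.zeros((n, sm.read_len), dtype=np.uint8)
    read_lens = np.zeros(n, dtype=np.int32)
    for j, cid in enumerate(sr.ids):
        insert = clone_seqs.get(cid)
        if insert is None:
            raise ValueError(f"no sequence for clone {cid!r}")
        amp = sm.flank5 + insert + sm.flank3
        t1 = (amp + _ADAPTER_R1)[: sm.read_len]
        t2 = (_revcomp(amp) + _ADAPTER_R2)[: sm.read_len]
        L = len(t1)
        read_lens[j] = L
        r1_rows[j, :L] = np.frombuffer(t1.encode(), dtype=np.uint8)
        r2_rows[j, :L] = np.frombuffer(t2.encode(), dtype=np.uint8)
    return r1_rows, r2_rows, read_lens


def _uniform_subset(rng: np.random.Generator, n_total: int, k: int) -> np.ndarray:
    """Uniform k-subset of range(n_total) without materializing the range."""
    pool = np.unique(rng.integers(0, n_total, size=int(k * 1.05) + 16))
    while pool.size < k:
        extra = rng.integers(0, n_total, size=2 * (k - pool.size) + 16)
        pool = np.unique(np.concatenate([pool, extra]))
    if pool.size > k:
        pool = rng.permutation(pool)[:k]
    return pool


def _apply_errors(mat: np.ndarray, lengths: np.ndarray, rate: float,
                  rng: np.random.Generator) -> None:
    """I.i.d. substitutions in place.

    The per-base Bernoulli process is drawn as its exact equivalent: a binomial
    total error count and a uniform without-replacement choice of positions.
    """
    if rate <= 0 or mat.size == 0:
        return
    n, width = mat.shape
    if not (lengths == width).all():
        # ragged reads: per-row Bernoulli fallback
        col = np.arange(width)
        m = rng.random(mat.shape, dtype=np.float32) < rate
        m &= col[None, :] < lengths[:, None]
        idx = np.nonzero(m)
        if idx[0].size:
            shift = rng.integers(1, 4, size=idx[0].size)
            mat[idx] = _BASES[(_CODE[mat[idx]] + shift) % 4]
        return
    total = n * width
    n_err = int(rng.binomial(total, rate))
    if n_err == 0:
        return
    pos = _uniform_subset(rng, total, n_err)
    rows, cols = pos // width, pos % width
    shift = rng.integers(1, 4, size=n_err)
    mat[rows, cols] = _BASES[(_CODE[mat[rows, cols]] + shift) % 4]


_QUAL_LUT_CACHE: dict[tuple[float, float], np.ndarray] = {}


def _qual_lut(mean: float, sd: float) -> np.ndarray:
    """8-bit inverse-CDF table of the discretized clipped normal quality model."""
    key = (mean, sd)
    lut = _QUAL_LUT_CACHE.get(key)
    if lut is None:
        u = (np.arange(256) + 0.5) / 256.0
        q = stats.norm.ppf(u, loc=mean, scale=sd) if sd > 0 else np.full(256, mean)
        lut = np.clip(np.rint(q), 2, 41).astype(np.uint8)
        _QUAL_LUT_CACHE[key] = lut
    return lut


def _draw_quals(shape, lengths, sm: SequencingModel, rng) -> np.ndarray:
    lut = _qual_lut(sm.qual_mean, sm.qual_sd)
    out = lut[rng.integers(0, 256, size=shape, dtype=np.uint8)]
    out[np.arange(shape[1])[None, :] >= lengths[:, None]] = 0
    return out


def simulate_amplicon_reads(sr: SortResult, gate: str, sm: SequencingModel,
                            clone_seqs: Mapping[str, str], seed=None,
                            annotate: bool = True):
    """Emit paired reads for one gate.

    Returns ``(r1_block, r2_block, read_clone_ids)`` where the blocks are
    :class:`~fretscreen.io.FastqBlock` and ``read_clone_ids`` gives the truth
    clone of each pair.  Templates are the gate's per-clone carrier counts;
    each template receives a log-normal amplification factor and
    ``sm.reads_per_gate`` pairs are drawn multinomially over templates.
    """
    from .io import FastqBlock

    counts = sr.counts(gate)
    total_templates = int(counts.sum())
    if total_templates == 0:
        if sm.reads_per_gate > 0:
            raise ValueError(f"gate {gate!r} is empty but reads were requested")
        empty = FastqBlock(seqs=np.zeros((0, 0), np.uint8), quals=np.zeros((0, 0), np.uint8),
                           lengths=np.zeros(0, np.int32), ids=[])
        return empty, empty, np.zeros(0, dtype=np.int64)
    rng = np.random.default_rng(seed)

    template_clone = np.repeat(np.arange(len(sr.ids)), counts)
    if sm.amp_lognorm_sigma > 0:
        w = rng.lognormal(mean=0.0, sigma=sm.amp_lognorm_sigma, size=total_templates)
    else:
        w = np.ones(total_templates)
    p = w / w.sum()
    per_template = rng.multinomial(sm.reads_per_gate, p)
    read_clone = np.repeat(template_clone, per_template)
    rng.shuffle(read_clone)

    r1_rows, r2_rows, row_lens = _amplicon_rows(sr, sm, clone_seqs)
    r1 = r1_rows[read_clone]
    r2 = r2_rows[read_clone]
    lengths = row_lens[read_clone]
    _apply_errors(r1, lengths, sm.sub_error_rate, rng)
    _apply_errors(r2, lengths, sm.sub_error_rate, rng)
    q1 = _draw_quals(r1.shape, lengths, sm, rng)
    q2 = _draw_quals(r2.shape, lengths, sm, rng)

    if annotate:
        # Illumina-style names with the truth clone id in the comment field
        ids = [f"sim:{gate}:{i}" for i in range(len(read_clone))]
        comments = [f"clone={sr.ids[c]}" for c in read_clone]
    else:
        ids = comments = None
    b1 = FastqBlock(seqs=r1, quals=q1, lengths=lengths, ids=ids, comments=comments)
    b2 = FastqBlock(seqs=r2, quals=q2, lengths=lengths.copy(),
                    ids=list(ids) if ids else None,
                    comments=list(comments) if comments else None)
    return b1, b2, read_clone
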