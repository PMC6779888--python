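"""Minigene library construction for pooled T-cell epitope screens.

A *minigene* is a short peptide-coding DNA insert expressed in antigen-presenting
cells, where its translation product is proteolytically processed and candidate
peptides are presented on MHC class I for CD8+ T-cell recognition.  Screens are
built from four kinds of minigene:

``random``
    Fully degenerate inserts (a stretch of randomized bases, 48 nt by default,
    encoding 16-mers).  Roughly half of such clones carry an in-frame stop codon
    and produce no peptide; they are generated with ``peptide=None`` because the
    real degenerate library contains them and downstream purity-sort / stop-filter
    stages have to handle them.
``canonical``
    A known epitope (e.g. SIINFEKL or KVPRNQDWL) embedded at a chosen position in
    a longer peptide, reverse-translated to DNA.
``scrambled``
    A canonical construct whose epitope residues have been permuted; the classic
    negative control.
``panning``
    A second-round library assembled from the top-enriched sequences of a primary
    screen.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "Minigene",
    "LibrarySpec",
    "EpitopePlacement",
    "translate_nt",
    "generate_random_minigenes",
    "encode_minigene",
    "scramble_epitope",
    "design_panning_library",
    "required_screen_scale",
    "SIINFEKL",
    "LKNFISEI",
    "KVPRNQDWL",
    "OVA_SCRAMBLE_PERMUTATION",
]

CATEGORIES = ("random", "canonical", "scrambled", "panning")

STOP = "*"
_DNA_RE = re.compile(r"^[ACGT]+$")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: OT-I minimal epitope (chicken ovalbumin 257-264).
SIINFEKL = "SIINFEKL"
#: Scrambled OT-I epitope used as the negative control.
LKNFISEI = "LKNFISEI"
#: pmel-1 TCR minimal epitope, human gp100(25-33).
KVPRNQDWL = "KVPRNQDWL"

#: Index permutation carrying SIINFEKL onto LKNFISEI.
OVA_SCRAMBLE_PERMUTATION = (7, 6, 3, 4, 1, 0, 5, 2)

# Most-used human codon per amino acid; fixed table so reverse translation is
# deterministic under the default policy.
_MOST_FREQUENT_CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "AGA",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_SYNONYMOUS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _STANDARD_TABLE.forward_table.items():
    _SYNONYMOUS.setdefault(_aa, [])  # type: ignore[arg-type]
    _SYNONYMOUS[_aa] = tuple(sorted((*_SYNONYMOUS[_aa], _codon)))

AMINO_ACIDS = "".join(sorted(_MOST_FREQUENT_CODON))


def translate_nt(nt_seq: str) -> str:
    """Translate a DNA sequence in frame 0 with the standard genetic code.

    Stop codons appear as ``*``; the length must be divisible by 3.
    """
    if len(nt_seq) % 3 != 0:
        raise ValueError(f"sequence length {len(nt_seq)} not divisible by 3")
    return str(Seq(nt_seq).translate())


@dataclass(frozen=True)
class Minigene:
    """A peptide-coding insert plus its translation and provenance.

    ``peptide`` is ``None`` for non-productive inserts (in-frame stop); when set
    it must equal the frame-0 translation of ``nt_seq`` and contain no stop.
    ``epitope_span`` is a 0-based half-open interval on the peptide.
    """

    id: str
    nt_seq: str
    peptide: Optional[str] = None
    category: str = "random"
    epitope_span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if not _DNA_RE.match(self.nt_seq):
            raise ValueError(f"minigene {self.id!r}: nt_seq is not plain ACGT DNA")
        if self.category not in CATEGORIES:
            raise ValueError(f"minigene {self.id!r}: unknown category {self.category!r}")
        if self.peptide is not None:
            if translate_nt(self.nt_seq) != self.peptide:
                raise ValueError(f"minigene {self.id!r}: peptide does not match translation")
            if STOP in self.peptide:
                raise ValueError(f"minigene {self.id!r}: productive peptide contains a stop")
        if self.epitope_span is not None:
            if self.peptide is None:
                raise ValueError(f"minigene {self.id!r}: epitope_span on non-productive insert")
            start, end = self.epitope_span
            if not (0 <= start < end <= len(self.peptide)):
                raise ValueError(f"minigene {self.id!r}: epitope_span {self.epitope_span} out of bounds")

    @property
    def productive(self) -> bool:
        return self.peptide is not None

    @classmethod
    def from_nt(cls, id: str, nt_seq: str, category: str = "random",
                epitope_span: Optional[tuple[int, int]] = None) -> "Minigene":
        """Build a minigene from DNA alone, deriving peptide / productivity."""
        pep: Optional[str] = None
        if len(nt_seq) % 3 == 0:
            aa = translate_nt(nt_seq)
            if STOP not in aa:
                pep = aa
        return cls(id=id, nt_seq=nt_seq, peptide=pep, category=category,
                   epitope_span=epitope_span if pep is not None else None)


@dataclass(frozen=True)
class EpitopePlacement:
    """Where a minimal epitope sits inside a short minigene peptide."""

    minigene_len_aa: int
    position: int

    def validate(self, epitope: str) -> None:
        if self.position < 0 or self.position + len(epitope) > self.minigene_len_aa:
            raise ValueError(
                f"epitope of length {len(epitope)} at position {self.position} "
                f"does not fit in {self.minigene_len_aa} aa")


@dataclass(frozen=True)
class LibrarySpec:
    """The clone universe of a screen.

    ``clones`` carry base relative abundances summing to 1.  ``spikes`` are
    cognate clones added at a defined fraction, either at the cell level
    (replacing that fraction of cells after transduction) or at the DNA level
    (added to the abundance vector before transduction).  Effective abundances
    after spiking sum to 1 by construction.
    """

    clones: tuple[tuple[Minigene, float], ...]
    spikes: tuple[tuple[Minigene, float, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.clones:
            raise ValueError("library has no clones")
        fracs = np.array([f for _, f in self.clones], dtype=float)
        if (fracs < 0).any():
            raise ValueError("negative clone abundance")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError(f"clone abundances sum to {fracs.sum()!r}, not 1")
        spike_total = 0.0
        for mg, f, mode in self.spikes:
            if not (0.0 < f < 1.0):
                raise ValueError(f"spike {mg.id!r}: fraction {f} outside (0,1)")
            if mode not in ("cell", "dna"):
                raise ValueError(f"spike {mg.id!r}: mode must be 'cell' or 'dna'")
            spike_total += f
        if spike_total >= 1.0:
            raise ValueError("spike fractions sum to >= 1")
        ids = [mg.id for mg, _ in self.clones] + [mg.id for mg, _, _ in self.spikes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate minigene ids in library")

    @classmethod
    def uniform(cls, minigenes: Sequence[Minigene],
                spikes: Sequence[tuple[Minigene, float, str]] = ()) -> "LibrarySpec":
        n = len(minigenes)
        return cls(clones=tuple((m, 1.0 / n) for m in minigenes), spikes=tuple(spikes))

    @property
    def minigenes(self) -> dict[str, Minigene]:
        out = {mg.id: mg for mg, _ in self.clones}
        out.update({mg.id: mg for mg, _, _ in self.spikes})
        return out

    @property
    def spike_ids(self) -> tuple[str, ...]:
        return tuple(mg.id for mg, _, _ in self.spikes)

    def effective_abundances(self) -> dict[str, float]:
        """Per-clone fractions with all spikes applied; sums to 1 (±1e-9)."""
        spike_total = sum(f for _, f, _ in self.spikes)
        out = {mg.id: frac * (1.0 - spike_total) for mg, frac in self.clones}
        for mg, f, _ in self.spikes:
            out[mg.id] = out.get(mg.id, 0.0) + f
        return out


def generate_random_minigenes(n: int, length_nt: int = 48, seed: int | None = None,
                              id_prefix: str = "rand") -> list[Minigene]:
    """Draw ``n`` fully random minigenes of ``length_nt`` bases.

    Bases are i.i.d. uniform over {A,C,G,T}; clones with an in-frame stop are
    kept with ``peptide=None`` (non-productive).  Deterministic for a fixed
    ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if length_nt % 3 != 0:
        raise ValueError(f"length_nt={length_nt} is not divisible by 3")
    rng = np.random.default_rng(seed)
    mat = _BASES[rng.integers(0, 4, size=(n, length_nt))]
    width = max(6, len(str(n - 1)))
    out = []
    for i in range(n):
        nt = mat[i].tobytes().decode("ascii")
        out.append(Minigene.from_nt(f"{id_prefix}{i:0{width}d}", nt, category="random"))
    return out


def _reverse_translate(peptide: str, codon_policy: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in peptide:
        if aa not in _MOST_FREQUENT_CODON:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        if codon_policy == "most-frequent":
            codons.append(_MOST_FREQUENT_CODON[aa])
        elif codon_policy == "seeded-random":
            syn = _SYNONYMOUS[aa]
            codons.append(syn[rng.integers(0, len(syn))])
        else:
            raise ValueError(f"unknown codon_policy {codon_policy!r}")
    return "".join(codons)


def encode_minigene(epitope_peptide: str, total_len_aa: int, position: int,
                    flanking_source: str = "random",
                    codon_policy: str = "most-frequent",
                    seed: int | None = 0,
                    id: str | None = None,
                    category: str = "canonical") -> Minigene:
    """Embed an epitope in a peptide of ``total_len_aa`` residues and reverse-translate.

    ``flanking_source`` is either the literal string ``"random"`` (seeded random
    residues around the epitope) or a protein context of at least ``total_len_aa``
    residues into which the epitope is overwritten at ``position``.  The round
    trip ``translate(nt_seq) == peptide`` always holds.
    """
    if not epitope_peptide:
        raise ValueError("empty epitope")
    if position < 0 or position + len(epitope_peptide) > total_len_aa:
        raise ValueError(
            f"epitope of length {len(epitope_peptide)} does not fit at position "
            f"{position} in {total_len_aa} aa")
    rng = np.random.default_rng(seed)
    if flanking_source == "random":
        residues = [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), total_len_aa)]
    else:
        if len(flanking_source) < total_len_aa:
            raise ValueError("flanking_source shorter than total_len_aa")
        residues = list(flanking_source[:total_len_aa])
    residues[position:position + len(epitope_peptide)] = list(epitope_peptide)
    peptide = "".join(residues)
    nt = _reverse_translate(peptide, codon_policy, rng)
    mg_id = id if id is not None else f"{epitope_peptide}@{position}/{total_len_aa}"
    return Minigene(id=mg_id, nt_seq=nt, peptide=peptide, category=category,
                    epitope_span=(position, position + len(epitope_peptide)))


def scramble_epitope(epitope: str, permutation: Sequence[int]) -> str:
    """Permute epitope residues; the residue multiset is preserved.

    ``scramble_epitope("SIINFEKL", OVA_SCRAMBLE_PERMUTATION) == "LKNFISEI"``.
    """
    if sorted(permutation) != list(range(len(epitope))):
        raise ValueError("permutation is not a permutation of 0..len(epitope)-1")
    return "".join(epitope[i] for i in permutation)


def required_screen_scale(diversity: int, min_copies: int) -> int:
    """Target cells needed so every distinct clone reaches ``min_copies`` cells.

    At the detection limit of roughly 300 cells per clone, a library of 1e6
    distinct minigenes implies 3e8 target cells per screen.
    """
    if diversity < 1 or min_copies < 1:
        raise ValueError("diversity and min_copies must be >= 1")
    return int(diversity) * int(min_copies)


def design_panning_library(enrichment, top_n: int = 480,
                           epitope_variants: Sequence[EpitopePlacement] = (),
                           epitope: str | None = None,
                           flanking_source: str = "random",
                           codon_policy: str = "most-frequent",
                           seed: int | None = 0) -> LibrarySpec:
    """Second-round (panning) library: the ``top_n`` most enriched sequences.

    ``enrichment`` is an :class:`~fretscreen.enrichment.EnrichmentResult` whose
    ids are minigene DNA sequences.  Ranking is by Δ relative abundance
    descending, ties broken by higher Shifted-gate count, then lexicographic
    sequence, so output is deterministic.  If ``epitope`` is given, every
    selected minigene whose peptide contains it is replaced by the requested
    short positional variants (the re-encoded minimal-epitope formats).
    Abundances are uniform.
    """
    ranked = enrichment.ranking
    if top_n > len(ranked):
        raise ValueError(f"top_n={top_n} exceeds the {len(ranked)} ranked minigenes")
    if epitope is not None:
        for pl in epitope_variants:
            pl.validate(epitope)
    selected = ranked[:top_n]
    minigenes: list[Minigene] = []
    variants_added = False
    for i, seq in enumerate(selected):
        mg = Minigene.from_nt(f"pan{i:05d}", seq, category="panning")
        if epitope is not None and mg.peptide is not None and epitope in mg.peptide:
            if not variants_added:
                for j, pl in enumerate(epitope_variants):
                    vmg = encode_minigene(
                        epitope, pl.minigene_len_aa, pl.position,
                        flanking_source=flanking_source, codon_policy=codon_policy,
                        seed=seed, id=f"pan_{epitope}@{pl.position}/{pl.minigene_len_aa}",
                        category="panning")
                    minigenes.append(vmg)
                variants_added = True
            continue
        minigenes.append(mg)
    return LibrarySpec.uniform(minigenes)
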