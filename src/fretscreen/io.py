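"""File formats: FASTQ read blocks, library FASTA/TSV, cluster tables.

Reads are carried in columnar :class:`FastqBlock` containers (one padded uint8
matrix per mate for bases, one for Phred qualities) because per-gate files run
to ~5e5 pairs and the pipeline is vectorized end to end.  FASTQ parsing and
writing are deliberately minimal: plain or gzip, Phred+33 only.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .design import LibrarySpec, Minigene

__all__ = [
    "FastqBlock", "read_fastq", "write_fastq",
    "library_to_fasta", "library_from_fasta",
    "library_to_tsv", "library_from_tsv",
    "oligo_pool_lines", "clusters_to_tsv", "clusters_from_tsv",
]

PHRED_OFFSET = 33


@dataclass
class FastqBlock:
    """Columnar batch of reads: padded base and quality matrices plus lengths."""

    seqs: np.ndarray          # (n, width) uint8 ASCII, zero-padded
    quals: np.ndarray         # (n, width) uint8 Phred scores, zero-padded
    lengths: np.ndarray       # (n,) int32
    ids: Optional[list[str]] = None
    comments: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if self.seqs.shape != self.quals.shape:
            raise ValueError("seqs and quals shapes differ")
        if len(self.lengths) != self.seqs.shape[0]:
            raise ValueError("lengths do not match number of reads")

    def __len__(self) -> int:
        return self.seqs.shape[0]

    def seq_str(self, i: int) -> str:
        return self.seqs[i, : self.lengths[i]].tobytes().decode("ascii")

    def qual_array(self, i: int) -> np.ndarray:
        return self.quals[i, : self.lengths[i]]

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, Sequence[int]]],
                     ids: Optional[list[str]] = None) -> "FastqBlock":
        seqs_b = []
        quals_l = []
        for seq, qual in records:
            if len(seq) != len(qual):
                raise ValueError("sequence and quality lengths differ")
            seqs_b.append(seq.encode("ascii"))
            quals_l.append(np.asarray(qual, dtype=np.uint8))
        n = len(seqs_b)
        width = max((len(s) for s in seqs_b), default=0)
        seqs = np.zeros((n, width), dtype=np.uint8)
        quals = np.zeros((n, width), dtype=np.uint8)
        lengths = np.zeros(n, dtype=np.int32)
        for i, (s, q) in enumerate(zip(seqs_b, quals_l)):
            seqs[i, : len(s)] = np.frombuffer(s, dtype=np.uint8)
            quals[i, : len(q)] = q
            lengths[i] = len(s)
        return cls(seqs=seqs, quals=quals, lengths=lengths, ids=ids)


def _open(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_fastq(path, block: FastqBlock) -> None:
    """Write a block as Phred+33 FASTQ (gzip if the path ends in .gz)."""
    qchars = block.quals + PHRED_OFFSET
    lines: list[bytes] = []
    n = len(block)
    for i in range(n):
        L = block.lengths[i]
        name = block.ids[i] if block.ids is not None else f"read{i}"
        comment = f" {block.comments[i]}" if block.comments is not None else ""
        lines.append(f"@{name}{comment}".encode("ascii"))
        lines.append(block.seqs[i, :L].tobytes())
        lines.append(b"+")
        lines.append(qchars[i, :L].astype(np.uint8).tobytes())
    data = b"\n".join(lines) + b"\n" if lines else b""
    with _open(path, "wb") as fh:
        fh.write(data)


def read_fastq(path) -> FastqBlock:
    """Read FASTQ (plain or gzip) into a :class:`FastqBlock`."""
    with _open(path, "rb") as fh:
        data = fh.read()
    lines = data.splitlines()
    if len(lines) % 4 != 0:
        raise ValueError(f"{path}: truncated FASTQ ({len(lines)} lines)")
    n = len(lines) // 4
    ids: list[str] = []
    comments: list[str] = []
    seq_lines = lines[1::4]
    qual_lines = lines[3::4]
    for header in lines[0::4]:
        h = header.decode("ascii")
        if not h.startswith("@"):
            raise ValueError(f"{path}: malformed FASTQ header {h!r}")
        name, _, comment = h[1:].partition(" ")
        ids.append(name)
        comments.append(comment)
    lengths = np.fromiter((len(s) for s in seq_lines), dtype=np.int32, count=n)
    width = int(lengths.max()) if n else 0
    seqs = np.zeros((n, width), dtype=np.uint8)
    quals = np.zeros((n, width), dtype=np.uint8)
    if n and (lengths == width).all():
        seqs[:] = np.frombuffer(b"".join(seq_lines), dtype=np.uint8).reshape(n, width)
        quals[:] = np.frombuffer(b"".join(qual_lines), dtype=np.uint8).reshape(n, width)
    else:
        for i, (s, q) in enumerate(zip(seq_lines, qual_lines)):
            seqs[i, : len(s)] = np.frombuffer(s, dtype=np.uint8)
            quals[i, : len(q)] = np.frombuffer(q, dtype=np.uint8)
    if n:
        np.subtract(quals, PHRED_OFFSET, out=quals, where=quals > 0)
    return FastqBlock(seqs=seqs, quals=quals, lengths=lengths, ids=ids, comments=comments)


# ---------------------------------------------------------------------------
# Library import/export


def library_to_fasta(spec: LibrarySpec, path) -> None:
    """FASTA of insert DNA; headers carry category/abundance/span as key=value."""
    ab = spec.effective_abundances()
    with _open(path, "wt") as fh:
        for mg_id, mg in spec.minigenes.items():
            attrs = [f"category={mg.category}", f"abundance={ab.get(mg_id, 0.0):.6g}"]
            if mg.epitope_span is not None:
                attrs.append(f"epitope_span={mg.epitope_span[0]}-{mg.epitope_span[1]}")
            if mg_id in spec.spike_ids:
                mode = next(m for s, _, m in spec.spikes if s.id == mg_id)
                attrs.append(f"spike_mode={mode}")
            fh.write(f">{mg_id} {' '.join(attrs)}\n{mg.nt_seq}\n")


def library_from_fasta(path) -> LibrarySpec:
    clones: list[tuple[Minigene, float]] = []
    spikes: list[tuple[Minigene, float, str]] = []
    with _open(path, "rt") as fh:
        header = None
        seq_parts: list[str] = []
        entries = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    entries.append((header, "".join(seq_parts)))
                header, seq_parts = line[1:], []
            else:
                seq_parts.append(line)
        if header is not None:
            entries.append((header, "".join(seq_parts)))
    for header, seq in entries:
        name, *attr_parts = header.split()
        attrs = dict(p.split("=", 1) for p in attr_parts if "=" in p)
        span = None
        if "epitope_span" in attrs:
            a, b = attrs["epitope_span"].split("-")
            span = (int(a), int(b))
        mg = Minigene.from_nt(name, seq, category=attrs.get("category", "random"),
                              epitope_span=span)
        frac = float(attrs.get("abundance", 0.0))
        if "spike_mode" in attrs:
            spikes.append((mg, frac, attrs["spike_mode"]))
        else:
            clones.append((mg, frac))
    total = sum(f for _, f in clones)
    spike_total = sum(f for _, f, _ in spikes)
    if total <= 0:
        raise ValueError(f"{path}: no clone abundances")
    # undo the spiking scale so base clone abundances sum to 1 again
    clones = [(mg, f / total) for mg, f in clones]
    return LibrarySpec(clones=tuple(clones), spikes=tuple(spikes))


def library_to_tsv(spec: LibrarySpec, path) -> None:
    ab = spec.effective_abundances()
    modes = {mg.id: mode for mg, _, mode in spec.spikes}
    rows = []
    for mg_id, mg in spec.minigenes.items():
        rows.append({
            "id": mg_id, "nt_seq": mg.nt_seq,
            "peptide": mg.peptide if mg.peptide is not None else "",
            "category": mg.category, "abundance": ab.get(mg_id, 0.0),
            "spike_mode": modes.get(mg_id, ""),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def library_from_tsv(path) -> LibrarySpec:
    df = pd.read_csv(path, sep="\t", dtype={"spike_mode": "string"})
    clones: list[tuple[Minigene, float]] = []
    spikes: list[tuple[Minigene, float, str]] = []
    for row in df.itertuples(index=False):
        mg = Minigene.from_nt(str(row.id), str(row.nt_seq), category=str(row.category))
        mode = "" if pd.isna(row.spike_mode) else str(row.spike_mode)
        if mode:
            spikes.append((mg, float(row.abundance), mode))
        else:
            clones.append((mg, float(row.abundance)))
    total = sum(f for _, f in clones)
    clones = [(mg, f / total) for mg, f in clones]
    return LibrarySpec(clones=tuple(clones), spikes=tuple(spikes))


def oligo_pool_lines(spec: LibrarySpec, flank5: str, flank3: str) -> list[str]:
    """Array-synthesis input: one 5'flank+insert+3'flank sequence per line."""
    return [f"{flank5}{mg.nt_seq}{flank3}" for mg in spec.minigenes.values()]


# ---------------------------------------------------------------------------
# Cluster tables


def clusters_to_tsv(clusters, path) -> None:
    rows = [{
        "canonical": c.canonical,
        "peptide": c.peptide if c.peptide is not None else "",
        "count": c.member_count,
        "n_members": len(c.members),
        "productive": bool(c.productive) if c.productive is not None else "",
    } for c in clusters]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def clusters_from_tsv(path):
    from .pipeline import SeqCluster
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        pep = str(row["peptide"]) or None
        prod = row["productive"]
        prod = None if prod == "" else bool(prod)
        out.append(SeqCluster(canonical=str(row["canonical"]),
                              member_count=int(row["count"]),
                              members=((str(row["canonical"]), int(row["count"])),),
                              productive=prod, peptide=pep))
    return out
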