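"""End-to-end orchestration: design -> simulate -> process -> enrich.

:func:`run_screen` executes one whole in-silico screen from a validated
:class:`~fretscreen.config.ScreenConfig`; the ``simulate`` and ``analyze`` CLI
commands are thin wrappers that add FASTQ/TSV/JSON serialization around the
same stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import DataError, ScreenConfig
from .design import LibrarySpec, Minigene, encode_minigene, generate_random_minigenes
from .enrichment import CountTable, EnrichmentResult, build_count_table, call_hits
from .io import read_fastq, write_fastq
from .pipeline import PipelineParams, process_gate
from .simulate import (CellPopulation, CocultureParams, SequencingModel, SortResult,
                       TransductionModel, build_cell_library, simulate_amplicon_reads,
                       simulate_coculture_sort)

__all__ = ["build_library", "run_screen", "ScreenOutcome",
           "cmd_simulate", "cmd_analyze"]

GATES = ("shifted", "unshifted")


def _child_seeds(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def build_library(cfg: ScreenConfig) -> LibrarySpec:
    """Materialize the library block: random clones plus encoded spikes."""
    seeds = _child_seeds(cfg.seed, 6)
    lib_seed = seeds[0]
    clones = generate_random_minigenes(cfg.library.n_clones, cfg.library.length_nt,
                                       seed=lib_seed)
    spikes = []
    for i, sp in enumerate(cfg.library.spikes):
        if sp.nt_seq is not None:
            mg = Minigene.from_nt(sp.id, sp.nt_seq, category="canonical")
        else:
            # fixed encode seed: the cognate construct is the same physical
            # clone whatever the screen replicate seed
            mg = encode_minigene(sp.epitope, sp.total_len_aa, sp.position,
                                 flanking_source="random", codon_policy="most-frequent",
                                 seed=1000 + i, id=sp.id, category="canonical")
        if mg.peptide is None:
            raise DataError(f"spike {sp.id!r} is non-productive")
        spikes.append((mg, sp.fraction, sp.mode))
    return LibrarySpec.uniform(clones, spikes=spikes)


@dataclass
class ScreenOutcome:
    """Everything one simulated screen produced."""

    library: LibrarySpec
    population: CellPopulation
    sort: SortResult
    counts: CountTable
    enrichment: EnrichmentResult
    truth: pd.DataFrame
    ledgers: dict
    spike_ids: tuple[str, ...]

    def spike_row(self, spike_id: str) -> Optional[pd.Series]:
        """Enrichment row of a spike clone, addressed by its insert sequence."""
        seq = self.library.minigenes[spike_id].nt_seq
        if seq in self.enrichment.table.index:
            return self.enrichment.table.loc[seq]
        return None

    def spike_z(self, spike_id: str) -> float:
        row = self.spike_row(spike_id)
        return float(row["z"]) if row is not None else float("-inf")

    def spike_rank(self, spike_id: str) -> int:
        seq = self.library.minigenes[spike_id].nt_seq
        if seq not in self.enrichment.table.index:
            return len(self.enrichment.table) + 1
        return self.enrichment.rank_of(seq)


def _simulate_reads(cfg: ScreenConfig, library: LibrarySpec, seed_pop, seed_sort,
                    seed_gates, annotate: bool = True):
    sim = cfg.simulation
    tm = TransductionModel(moi_lambda=sim.moi_lambda,
                           condition_on_transduced=sim.condition_on_transduced)
    cp = CocultureParams(p_hit=sim.p_hit, f_reactive=sim.f_reactive,
                         et_ratio=sim.et_ratio, p_fp=sim.p_fp)
    sm = SequencingModel(reads_per_gate=sim.reads_per_gate, read_len=sim.read_len,
                         sub_error_rate=sim.sub_error_rate,
                         amp_lognorm_sigma=sim.amp_lognorm_sigma,
                         flank5=sim.flank5, flank3=sim.flank3,
                         qual_mean=sim.qual_mean, qual_sd=sim.qual_sd)
    pop = build_cell_library(library, sim.total_cells, tm, seed=seed_pop,
                             purity_sorted=sim.purity_sorted)
    sort = simulate_coculture_sort(pop, cp, library.spike_ids,
                                   gate_capacity=sim.gate_capacity, seed=seed_sort)
    clone_seqs = {mid: mg.nt_seq for mid, mg in library.minigenes.items()}
    gate_blocks = {}
    gate_read_clone = {}
    for gate, sg in zip(GATES, seed_gates):
        b1, b2, read_clone = simulate_amplicon_reads(sort, gate, sm, clone_seqs,
                                                     seed=sg, annotate=annotate)
        gate_blocks[gate] = (b1, b2)
        gate_read_clone[gate] = read_clone
    return pop, sort, gate_blocks, gate_read_clone


def _truth_table(library: LibrarySpec, sort: SortResult, gate_read_clone) -> pd.DataFrame:
    minigenes = library.minigenes
    reads = {gate: np.bincount(gate_read_clone[gate], minlength=len(sort.ids))
             for gate in GATES}
    return pd.DataFrame({
        "id": list(sort.ids),
        "nt_seq": [minigenes[i].nt_seq for i in sort.ids],
        "productive": [minigenes[i].peptide is not None for i in sort.ids],
        "cells_shifted": sort.shifted,
        "cells_unshifted": sort.unshifted,
        "reads_shifted": reads["shifted"],
        "reads_unshifted": reads["unshifted"],
    })


def _pipeline_params(cfg: ScreenConfig) -> PipelineParams:
    p = cfg.pipeline
    return PipelineParams(min_overlap=p.min_overlap, max_overlap=p.max_overlap,
                          max_mismatch_ratio=p.max_mismatch_ratio,
                          allow_outies=p.allow_outies, min_q=p.min_q,
                          min_fraction=p.min_fraction,
                          max_flank_mismatches=p.max_flank_mismatches,
                          cluster_max_dist=p.cluster_max_dist)


def _analyze_blocks(cfg: ScreenConfig, gate_blocks) -> tuple[CountTable, EnrichmentResult, dict]:
    params = _pipeline_params(cfg)
    sim = cfg.simulation
    clusters = {}
    ledgers = {}
    for gate in GATES:
        b1, b2 = gate_blocks[gate]
        cl, ledger = process_gate(b1, b2, sim.flank5, sim.flank3, params,
                                  blacklist=cfg.pipeline.blacklist)
        if not cl:
            raise DataError(f"no clusters survive the pipeline in the {gate} gate "
                            f"(last non-empty stage: see ledger)")
        clusters[gate] = cl
        ledgers[gate] = ledger
    counts = build_count_table(clusters["shifted"], clusters["unshifted"])
    enr = call_hits(counts, k=cfg.enrichment.k, background=cfg.enrichment.background)
    return counts, enr, ledgers


def run_screen(cfg: ScreenConfig, seed: Optional[int] = None) -> ScreenOutcome:
    """Simulate one screen and analyze it, entirely in memory.

    ``seed`` overrides ``cfg.seed``.  The same sub-seeds drive the identical
    stages executed by the ``simulate``/``analyze`` CLI commands, so in-memory
    and file-based runs agree read for read.
    """
    if seed is not None:
        cfg = cfg.model_copy(update={"seed": int(seed)})
    seeds = _child_seeds(cfg.seed, 6)
    library = build_library(cfg)
    pop, sort, gate_blocks, gate_read_clone = _simulate_reads(
        cfg, library, seeds[1], seeds[2], (seeds[3], seeds[4]), annotate=False)
    truth = _truth_table(library, sort, gate_read_clone)
    counts, enr, ledgers = _analyze_blocks(cfg, gate_blocks)
    return ScreenOutcome(library=library, population=pop, sort=sort, counts=counts,
                         enrichment=enr, truth=truth, ledgers=ledgers,
                         spike_ids=library.spike_ids)


# ---------------------------------------------------------------------------
# CLI-facing commands


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, kind: str, params: dict, inputs: dict, outputs: list):
    manifest = {
        "tool": "fretscreen", "version": __version__, "command": kind,
        "parameters": params,
        "parameter_hash": hashlib.sha256(
            json.dumps(params, sort_keys=True).encode()).hexdigest(),
        "inputs": inputs, "outputs": outputs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def cmd_simulate(cfg: ScreenConfig, outdir, gzip_fastq: bool = False) -> dict:
    """Run design + simulation; write per-gate FASTQ pairs and a truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(cfg.seed, 6)
    library = build_library(cfg)
    pop, sort, gate_blocks, gate_read_clone = _simulate_reads(
        cfg, library, seeds[1], seeds[2], (seeds[3], seeds[4]))
    truth = _truth_table(library, sort, gate_read_clone)
    suffix = ".fastq.gz" if gzip_fastq else ".fastq"
    outputs = []
    for gate in GATES:
        b1, b2 = gate_blocks[gate]
        for mate, block in (("R1", b1), ("R2", b2)):
            path = outdir / f"sim_{gate}_{mate}{suffix}"
            write_fastq(path, block)
            outputs.append(path.name)
    truth_path = outdir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    outputs.append(truth_path.name)
    from .io import library_to_tsv
    library_to_tsv(library, outdir / "library.tsv")
    outputs.append("library.tsv")
    _write_manifest(outdir, "simulate", cfg.model_dump(), {}, outputs)
    return {"outdir": str(outdir), "outputs": outputs,
            "n_cells_shifted": sort.n_cells_shifted,
            "n_cells_unshifted": sort.n_cells_unshifted}


def cmd_analyze(shifted_r1, shifted_r2, unshifted_r1, unshifted_r2,
                flank5: str, flank3: str, outdir,
                params: PipelineParams = PipelineParams(),
                blacklist=(), k: float = 10.0, background="all") -> dict:
    """Full pipeline from per-gate FASTQ to ranked enrichment calls.

    Writes ``enrichment.tsv``, ``summary.json`` (with every stage ledger) and
    ``hits.fasta`` (hit peptides, ready for MHC-binding prediction or protein
    database search).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"shifted": (Path(shifted_r1), Path(shifted_r2)),
             "unshifted": (Path(unshifted_r1), Path(unshifted_r2))}
    clusters = {}
    ledgers = {}
    for gate, (p1, p2) in paths.items():
        b1 = read_fastq(p1)
        b2 = read_fastq(p2)
        if len(b1) == 0 or len(b2) == 0:
            raise DataError(f"{gate} gate: empty FASTQ input")
        if len(b1) != len(b2):
            raise DataError(f"{gate} gate: R1/R2 record counts differ")
        cl, ledger = process_gate(b1, b2, flank5, flank3, params, blacklist=blacklist)
        if not cl:
            raise DataError(f"{gate} gate: no clusters survive the pipeline")
        clusters[gate] = cl
        ledgers[gate] = ledger
    counts = build_count_table(clusters["shifted"], clusters["unshifted"])
    enr = call_hits(counts, k=k, background=background)

    table = enr.table.copy()
    table.insert(0, "id", table.index)
    ranked = enr.ranking
    table = table.loc[ranked]
    table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    with open(outdir / "hits.fasta", "w") as fh:
        for mg_id in enr.hits:
            pep = table.loc[mg_id, "peptide"] if "peptide" in table.columns else None
            if isinstance(pep, str) and pep:
                fh.write(f">{mg_id}\n{pep}\n")
    summary = {"enrichment": enr.summary(), "ledgers": ledgers,
               "hits": [str(h) for h in enr.hits]}
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=int) + "\n")
    inputs = {str(p): _sha256(p) for pair in paths.values() for p in pair}
    _write_manifest(outdir, "analyze",
                    {"flank5": flank5, "flank3": flank3, "k": k,
                     "background": background, **params.__dict__},
                    inputs, ["enrichment.tsv", "summary.json", "hits.fasta"])
    return summary
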