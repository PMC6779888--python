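"""Δ relative abundance enrichment statistics and hit calling.

The screen read-out is, per minigene, the difference between its read frequency
in the Shifted gate and in the Unshifted gate:

    Δ(m) = shifted(m)/shifted_total - unshifted(m)/unshifted_total

Δ sums to zero over the library.  Hits are minigenes whose Δ exceeds
``mean + k·σ`` over the background Δ distribution, with k = 10 by default (the
dashed-line rule of the screen figures).  σ is the population standard
deviation over all minigenes' Δ values, hits included, matching a single global
cutoff line; a robust variant excluding the top-j Δ values from the background
is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["CountTable", "EnrichmentResult", "build_count_table",
           "delta_relative_abundance", "call_hits", "compare_screens",
           "DegenerateBackgroundError"]


class DegenerateBackgroundError(ValueError):
    """Raised when sigma is zero but some minigene sits above the mean."""


@dataclass
class CountTable:
    """Per-minigene read counts in the Shifted and Unshifted gates."""

    df: pd.DataFrame  # index: minigene id; columns: shifted, unshifted [, peptide]

    def __post_init__(self) -> None:
        for col in ("shifted", "unshifted"):
            if col not in self.df.columns:
                raise ValueError(f"count table missing column {col!r}")
            if (self.df[col] < 0).any():
                raise ValueError("negative counts")
        if self.total("shifted") == 0 and self.total("unshifted") == 0:
            raise ValueError("both gates are empty")

    def total(self, gate: str) -> int:
        return int(self.df[gate].sum())

    def __len__(self) -> int:
        return len(self.df)


def build_count_table(shifted_clusters, unshifted_clusters) -> CountTable:
    """Union the per-gate cluster sets into one count table (absent gate = 0)."""
    def as_series(clusters):
        counts, peps = {}, {}
        for c in clusters:
            counts[c.canonical] = counts.get(c.canonical, 0) + c.member_count
            if getattr(c, "peptide", None) is not None:
                peps[c.canonical] = c.peptide
        return counts, peps

    sc, sp = as_series(shifted_clusters)
    uc, up = as_series(unshifted_clusters)
    ids = sorted(set(sc) | set(uc))
    if not ids:
        raise ValueError("no clusters in either gate")
    df = pd.DataFrame({
        "shifted": [sc.get(i, 0) for i in ids],
        "unshifted": [uc.get(i, 0) for i in ids],
    }, index=pd.Index(ids, name="id"))
    peps = {**up, **sp}
    if peps:
        df["peptide"] = [peps.get(i) for i in ids]
    return CountTable(df)


def delta_relative_abundance(table: CountTable) -> pd.Series:
    """Δ(m) = shifted frequency minus unshifted frequency; sums to zero."""
    for gate in ("shifted", "unshifted"):
        if table.total(gate) == 0:
            raise ValueError(f"{gate} gate has zero total reads")
    s = table.df["shifted"] / table.total("shifted")
    u = table.df["unshifted"] / table.total("unshifted")
    return (s - u).rename("delta")


@dataclass
class EnrichmentResult:
    """Ranked Δ relative abundance results with the mean + k·σ hit threshold."""

    table: pd.DataFrame  # index id; columns shifted, unshifted, delta, z, hit [, peptide]
    mean_delta: float
    sigma_delta: float
    k: float

    @property
    def threshold(self) -> float:
        return self.mean_delta + self.k * self.sigma_delta

    @property
    def ranking(self) -> list:
        """All ids ordered by (Δ desc, shifted count desc, id asc)."""
        # stable sorts applied minor-to-major key: id asc, shifted desc, delta desc
        tmp = self.table.copy()
        tmp["_id"] = tmp.index
        tmp = tmp.sort_values("_id", ascending=True, kind="mergesort")
        tmp = tmp.sort_values("shifted", ascending=False, kind="mergesort")
        tmp = tmp.sort_values("delta", ascending=False, kind="mergesort")
        return list(tmp.index)

    @property
    def hits(self) -> list:
        """Hit ids (Δ strictly above threshold), ranked."""
        hit_set = set(self.table.index[self.table["hit"]])
        return [i for i in self.ranking if i in hit_set]

    def rank_of(self, mg_id) -> int:
        """1-based Δ rank of a minigene."""
        return self.ranking.index(mg_id) + 1

    def summary(self) -> dict:
        return {"n": int(len(self.table)), "mean_delta": float(self.mean_delta),
                "sigma_delta": float(self.sigma_delta), "k": float(self.k),
                "threshold": float(self.threshold), "n_hits": int(self.table["hit"].sum())}


def call_hits(delta: Union[CountTable, pd.Series], counts: Optional[CountTable] = None,
              k: float = 10.0, background: Union[str, int] = "all") -> EnrichmentResult:
    """Call hits at the mean + k·σ rule.

    ``delta`` may be a :class:`CountTable` (Δ is computed from it) or a Δ
    series with ``counts`` supplying the table.  ``background`` is ``"all"``
    (default: σ over every minigene, hits included) or an integer j to exclude
    the top-j Δ values from the background estimate.  z-scores use the
    population (ddof=0) standard deviation.
    """
    if isinstance(delta, CountTable):
        counts = delta
        delta = delta_relative_abundance(counts)
    if counts is None:
        raise ValueError("counts table required when delta is a series")
    if len(delta) < 2:
        raise ValueError("need at least 2 minigenes to estimate a background")
    dvals = delta.to_numpy(dtype=float)
    if background == "all":
        bg = dvals
    else:
        j = int(background)
        if j < 0 or j >= len(dvals):
            raise ValueError("background exclusion out of range")
        bg = np.sort(dvals)[: len(dvals) - j] if j else dvals
    mean = float(bg.mean())
    sigma = float(bg.std(ddof=0))
    if sigma == 0.0 and (dvals > mean).any():
        raise DegenerateBackgroundError("sigma is zero but deltas exceed the mean")
    z = (dvals - mean) / sigma if sigma > 0 else np.zeros_like(dvals)
    threshold = mean + k * sigma
    df = counts.df.copy()
    df["delta"] = dvals
    df["z"] = z
    df["hit"] = dvals > threshold
    return EnrichmentResult(table=df, mean_delta=mean, sigma_delta=sigma, k=float(k))


def compare_screens(primary: EnrichmentResult, secondary: EnrichmentResult,
                    epitope: Optional[str] = None) -> pd.DataFrame:
    """Outer join of primary and secondary (panning) screens on minigene id.

    Columns: delta/z/hit for each screen; members below either threshold keep
    their rows.  With ``epitope`` given, a ``contains_epitope_*`` flag is added
    per screen from the peptide column where available, linking long-format
    primary minigenes to short positional variants that carry the same minimal
    epitope.
    """
    p = primary.table[[c for c in ("delta", "z", "hit", "shifted", "peptide")
                       if c in primary.table.columns]].add_suffix("_primary")
    s = secondary.table[[c for c in ("delta", "z", "hit", "shifted", "peptide")
                         if c in secondary.table.columns]].add_suffix("_secondary")
    joint = p.join(s, how="outer")
    if "hit_primary" in joint and "hit_secondary" in joint:
        joint["concordant"] = joint["hit_primary"].eq(True) & joint["hit_secondary"].eq(True)
    if epitope is not None:
        for side in ("primary", "secondary"):
            col = f"peptide_{side}"
            if col in joint:
                joint[f"contains_epitope_{side}"] = joint[col].map(
                    lambda pep: isinstance(pep, str) and epitope in pep)
    return joint
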