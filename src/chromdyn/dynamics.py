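"""Temporal accessibility-class assignment across a culture-transition time course.

Stage 1 of the pipeline. Per-time-point peak calls are unified into consensus
loci; each locus's open/closed vector over the T time points is matched
against three monotone archetypes — permanently open (PO), closed-to-open
switching at time k (CO_k), open-to-closed at time k (OC_k) — and anything
else (all-closed or flickering) is EXCLUDED. The class sets of the two
transition directions define Regions 1-4: serum-specific chromatin (OC of the
serum-to-ground-state direction = Region 1; CO of the reverse = Region 4) and
ground-state-specific chromatin (CO forward = Region 2; OC reverse = Region 3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .intervals import (
    GenomicInterval,
    PeakSet,
    merge_intervals,
    overlap_pairs,
    overlapping_indices,
)

PO, CO, OC, EXCLUDED = "PO", "CO", "OC", "EXCLUDED"


@dataclass(frozen=True)
class DynamicsLabel:
    """Accessibility class with the switch time index for CO/OC."""

    cls: str
    k: Optional[int] = None

    def __post_init__(self) -> None:
        if self.cls not in (PO, CO, OC, EXCLUDED):
            raise ValueError(f"unknown class {self.cls!r}")
        if (self.k is not None) != (self.cls in (CO, OC)):
            raise ValueError("switch index k present iff class is CO or OC")

    def __str__(self) -> str:
        return self.cls if self.k is None else f"{self.cls}{self.k}"


@dataclass
class ConsensusPeak:
    """A merged locus with its boolean open-state vector over T time points."""

    interval: GenomicInterval
    open_state: np.ndarray  # bool, length T


@dataclass
class RegionAssignment:
    """One of Regions 1-4 with its member peaks and labels."""

    region: int
    peaks: list[ConsensusPeak]
    labels: list[DynamicsLabel]

    def __len__(self) -> int:
        return len(self.peaks)

    def peak_set(self, name: Optional[str] = None) -> PeakSet:
        return PeakSet(
            name if name is not None else f"region{self.region}",
            [p.interval for p in self.peaks],
        )

    def subgroup_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for lab in self.labels:
            counts[lab.k] = counts.get(lab.k, 0) + 1
        return dict(sorted(counts.items()))


def build_consensus(peak_sets: Sequence[PeakSet]) -> list[ConsensusPeak]:
    """Merge all time points' peaks into consensus loci with open vectors.

    Consensus loci are the gap-0 merged union of every time point; the open
    bit at time t is set iff at least one peak of set t overlaps the locus by
    >= 1 bp. Every input peak maps to exactly one locus by construction.
    """
    T = len(peak_sets)
    if T < 3:
        raise ValueError(f"need >= 3 time points, got {T}")
    pooled = PeakSet(
        "consensus", [iv for ps in peak_sets for iv in ps.intervals]
    )
    merged = merge_intervals(pooled, gap=0)
    open_state = np.zeros((len(merged), T), dtype=bool)
    for t, ps in enumerate(peak_sets):
        for locus_idx in overlapping_indices(merged, ps):
            open_state[locus_idx, t] = True
    return [
        ConsensusPeak(iv, open_state[i]) for i, iv in enumerate(merged.intervals)
    ]


def classify_vector(v: np.ndarray) -> DynamicsLabel:
    """Match one open-state vector against the PO / CO_k / OC_k archetypes."""
    v = np.asarray(v, dtype=bool)
    T = v.size
    if v.all():
        return DynamicsLabel(PO)
    n_open = int(v.sum())
    if n_open == 0:
        return DynamicsLabel(EXCLUDED)
    if v[T - n_open :].all() and not v[: T - n_open].any():
        return DynamicsLabel(CO, k=T - n_open)  # 0^k 1^(T-k)
    if v[:n_open].all() and not v[n_open:].any():
        return DynamicsLabel(OC, k=n_open)  # 1^k 0^(T-k)
    return DynamicsLabel(EXCLUDED)


def classify_dynamics(
    consensus: Sequence[ConsensusPeak],
) -> tuple[list[DynamicsLabel], dict[str, int]]:
    """Label every consensus peak; returns labels plus per-class counts."""
    labels = [classify_vector(p.open_state) for p in consensus]
    counts: dict[str, int] = {}
    for lab in labels:
        counts[str(lab)] = counts.get(str(lab), 0) + 1
    return labels, counts


def define_regions(
    consensus_fwd: Sequence[ConsensusPeak],
    labels_fwd: Sequence[DynamicsLabel],
    consensus_rev: Sequence[ConsensusPeak],
    labels_rev: Sequence[DynamicsLabel],
) -> dict[int, RegionAssignment]:
    """Regions 1-4 from the two classified transition directions.

    Region 1 = OC of the forward (serum-to-ground) direction, Region 2 = CO
    forward, Region 3 = OC reverse, Region 4 = CO reverse. PO and EXCLUDED
    peaks belong to no region.
    """

    def pick(consensus, labels, cls):
        peaks, labs = [], []
        for p, lab in zip(consensus, labels):
            if lab.cls == cls:
                peaks.append(p)
                labs.append(lab)
        return peaks, labs

    spec = {1: (consensus_fwd, labels_fwd, OC), 2: (consensus_fwd, labels_fwd, CO),
            3: (consensus_rev, labels_rev, OC), 4: (consensus_rev, labels_rev, CO)}
    out = {}
    for region, (cons, labs, cls) in spec.items():
        peaks, labels = pick(cons, labs, cls)
        out[region] = RegionAssignment(region, peaks, labels)
    return out


def region_overlap_stats(
    a: RegionAssignment | PeakSet,
    b: RegionAssignment | PeakSet,
    min_bp: int = 1,
) -> dict[str, float]:
    """Sharing of region ``a`` with region ``b`` (Venn-style, from a's side).

    Returns n_a, n_b, the count of a-peaks overlapping >= 1 b-peak, and the
    percentage (half-up rounded to 1 decimal for reporting; the unrounded
    value is retained under ``percent_raw``).
    """
    pa = a.peak_set() if isinstance(a, RegionAssignment) else a
    pb = b.peak_set() if isinstance(b, RegionAssignment) else b
    if len(pa) == 0:
        raise ZeroDivisionError("region a is empty; percent undefined")
    n_overlap = len(overlapping_indices(pa, pb, min_bp=min_bp))
    raw = 100.0 * n_overlap / len(pa)
    return {
        "n_a": len(pa),
        "n_b": len(pb),
        "n_a_overlapping_b": n_overlap,
        "percent": round_half_up(raw, 1),
        "percent_raw": raw,
    }


def switch_timing_table(
    labels: Sequence[DynamicsLabel],
    peak_to_genes: Mapping[int, Sequence[str]],
    bins: Sequence[Sequence[int]],
    rule: str = "earliest",
) -> pd.DataFrame:
    """Per-bin gene counts by switch timing.

    Each gene is tallied once, at its earliest (default), latest, or modal
    switch index among the CO/OC peaks mapped to it; bins group switch
    indices (e.g. [(1, 2), (3, 4, 5)]). Fractions are over the total number
    of timed genes. Genes mapped only to PO/EXCLUDED peaks are dropped.
    """
    if rule not in ("earliest", "latest", "modal"):
        raise ValueError(f"unknown timing rule {rule!r}")
    gene_ks: dict[str, list[int]] = {}
    for peak_idx, genes in peak_to_genes.items():
        lab = labels[peak_idx]
        if lab.k is None:
            continue
        for g in genes:
            gene_ks.setdefault(g, []).append(lab.k)
    gene_k: dict[str, int] = {}
    for g, ks in gene_ks.items():
        if rule == "earliest":
            gene_k[g] = min(ks)
        elif rule == "latest":
            gene_k[g] = max(ks)
        else:
            vals, counts = np.unique(ks, return_counts=True)
            gene_k[g] = int(vals[counts.argmax()])
    total = len(gene_k)
    rows = []
    for b in bins:
        members = sorted(g for g, k in gene_k.items() if k in set(b))
        pct = round_half_up(100.0 * len(members) / total, 1) if total else float("nan")
        rows.append(
            {
                "bin": "+".join(str(k) for k in b),
                "n_genes": len(members),
                "total_genes": total,
                "percent": pct,
            }
        )
    return pd.DataFrame(rows)
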