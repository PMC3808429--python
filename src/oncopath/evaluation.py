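"""Evaluation of extracted subnetworks against reference linear pathways.

A reference pathway (an ordered linear cascade of genes, e.g. a curated
cancer-signaling chain) is scored against an extracted subnetwork by its
success rate: the fraction of the cascade's consecutive directed edges that
the subnetwork contains.  Edges match as directed (source, target) pairs,
ignoring interaction type.  Aggregate statistics mirror the method's
benchmark: fractions of subnetworks at full and at ≥50% coverage, and
Kendall rank correlations (tau-b, tie-corrected) of success against pathway
size and against the subnetwork:pathway size ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path as FilePath

import numpy as np
from scipy import stats

from .subnetwork import SubnetworkCandidate
from .training import Edge


@dataclass(frozen=True)
class LinearPathway:
    """An ordered gene chain g0 → g1 → … → gm; m = number of interactions."""

    genes: tuple[int, ...]
    tag: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("a linear pathway needs at least one interaction")

    @property
    def edges(self) -> tuple[Edge, ...]:
        return tuple(zip(self.genes[:-1], self.genes[1:]))

    @property
    def n_edges(self) -> int:
        return len(self.genes) - 1


def read_linear_pathways(path: str | FilePath) -> list[LinearPathway]:
    """One pathway per line, tab-separated ordered gene ids; optional
    leading ``name:`` token tags the pathway."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            tag = ""
            if parts and parts[0].endswith(":"):
                tag = parts[0][:-1]
                parts = parts[1:]
            out.append(LinearPathway(tuple(int(p) for p in parts), tag))
    return out


def olp_success_rate(sub: SubnetworkCandidate, olp: LinearPathway) -> float:
    """Fraction of the pathway's directed edges present in the subnetwork."""
    present = sum(1 for e in olp.edges if e in sub.edges)
    return present / olp.n_edges


def kendall_tau(x: list[float], y: list[float]) -> tuple[float, float]:
    """Kendall tau-b with two-sided p-value; errors on constant input."""
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length lists of at least 3 values")
    if len(set(x)) < 2 or len(set(y)) < 2:
        raise ValueError("Kendall tau undefined for a constant list")
    res = stats.kendalltau(x, y, variant="b")
    return float(res.statistic), float(res.pvalue)


@dataclass
class EvaluationReport:
    success_rates: list[float]
    olp_sizes: list[int]
    subnet_sizes: list[int]
    frac_full: float  # success == 1.0
    frac_half: float  # success >= 0.5
    tau_size: tuple[float, float] | None  # success vs pathway size
    tau_ratio: tuple[float, float] | None  # success vs subnet:pathway ratio

    def as_dict(self) -> dict:
        return {
            "success_rates": self.success_rates,
            "olp_sizes": self.olp_sizes,
            "subnet_sizes": self.subnet_sizes,
            "frac_full": self.frac_full,
            "frac_half": self.frac_half,
            "tau_size": self.tau_size,
            "tau_ratio": self.tau_ratio,
        }


def evaluate_subnetworks(
    subs: list[SubnetworkCandidate], olps: list[LinearPathway]
) -> EvaluationReport:
    """Per-pair success rates plus the aggregate benchmark statistics.

    ``subs[i]`` is the subnetwork extracted for the endpoint pair of
    ``olps[i]``.  Kendall correlations are reported as None when either
    variable is constant (correlation undefined).
    """
    if len(subs) != len(olps):
        raise ValueError("subnetwork and pathway lists differ in length")
    if not subs:
        raise ValueError("nothing to evaluate")
    rates = [olp_success_rate(s, o) for s, o in zip(subs, olps)]
    sizes = [o.n_edges for o in olps]
    sub_sizes = [len(s.edges) for s in subs]
    ratios = [ss / os for ss, os in zip(sub_sizes, sizes)]

    def _tau(a, b):
        try:
            return kendall_tau(a, b)
        except ValueError:
            return None

    return EvaluationReport(
        success_rates=rates,
        olp_sizes=sizes,
        subnet_sizes=sub_sizes,
        frac_full=float(np.mean([r == 1.0 for r in rates])),
        frac_half=float(np.mean([r >= 0.5 for r in rates])),
        tau_size=_tau(rates, [float(s) for s in sizes]) if len(rates) >= 3 else None,
        tau_ratio=_tau(rates, ratios) if len(rates) >= 3 else None,
    )
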