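"""Gene-level background filtering against a healthy control cohort.

Genes in which a CH (or HA) variant is common among seemingly healthy
controls are unlikely to be disease-causing; disease-cohort calls in genes
whose control prevalence reaches the cutoff (default 1%) are excluded.  The
prevalence denominator defaults to the number of control samples carrying at
least one call of that kind anywhere in the genome, with the full control
cohort size available as an alternative.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .model import ChCall, HaCall, sample_gene_pairs


@dataclass
class GeneBackgroundTable:
    """Per-gene count of distinct control samples with >= 1 call."""

    call_kind: str  # "CH" or "HA"
    denominator: int
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.call_kind not in ("CH", "HA"):
            raise ValueError(f"call_kind must be CH or HA, got {self.call_kind!r}")
        for gene, count in self.counts.items():
            if not (0 <= count <= max(self.denominator, 0)):
                raise ValueError(
                    f"count {count} for gene {gene!r} outside [0, {self.denominator}]"
                )

    def prevalence(self, gene: str) -> Optional[float]:
        if gene not in self.counts or self.denominator == 0:
            return None
        return self.counts[gene] / self.denominator

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (gene, count, self.denominator, count / self.denominator)
            for gene, count in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "count", "denominator", "prevalence"])

    def write(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | os.PathLike, call_kind: str) -> "GeneBackgroundTable":
        frame = pd.read_csv(path, sep="\t")
        denominator = int(frame["denominator"].iloc[0]) if len(frame) else 0
        counts = dict(zip(frame["gene"].astype(str), frame["count"].astype(int)))
        return cls(call_kind=call_kind, denominator=denominator, counts=counts)


def _kind_of(calls: Iterable) -> Optional[str]:
    for call in calls:
        if isinstance(call, ChCall):
            return "CH"
        if isinstance(call, HaCall):
            return "HA"
        return None
    return None


def build_background(
    control_calls: Iterable,
    call_kind: Optional[str] = None,
    denominator_mode: str = "calling_samples",
    n_control_samples: Optional[int] = None,
) -> GeneBackgroundTable:
    """Tabulate control-cohort call prevalence per gene.

    ``denominator_mode="calling_samples"`` (default) divides by the number
    of distinct control samples with >= 1 call of this kind anywhere;
    ``"all_samples"`` divides by ``n_control_samples``.
    """
    calls = list(control_calls)
    inferred = _kind_of(calls)
    if call_kind is None:
        call_kind = inferred or "CH"
    elif inferred is not None and inferred != call_kind:
        raise ValueError(f"calls are {inferred} but call_kind={call_kind!r}")
    pairs = sample_gene_pairs(calls)
    calling_samples = {sample for sample, _ in pairs}
    if denominator_mode == "calling_samples":
        denominator = len(calling_samples)
    elif denominator_mode == "all_samples":
        if n_control_samples is None:
            raise ValueError("denominator_mode='all_samples' needs n_control_samples")
        denominator = n_control_samples
    else:
        raise ValueError("denominator_mode must be 'calling_samples' or 'all_samples'")
    counts: dict[str, int] = {}
    for _, gene in pairs:
        counts[gene] = counts.get(gene, 0) + 1
    return GeneBackgroundTable(call_kind=call_kind, denominator=denominator, counts=counts)


def filter_by_background(
    disease_calls: Iterable,
    table: GeneBackgroundTable,
    prevalence_max: float = 0.01,
) -> list:
    """Retain calls in genes below the background-prevalence cutoff.

    A call in gene g survives iff g is absent from the control table or its
    prevalence is strictly below ``prevalence_max`` (a gene exactly at the
    cutoff is excluded).  Filtering is a pure per-gene predicate: calls in
    the same gene are always retained or removed together.
    """
    calls = list(disease_calls)
    kind = _kind_of(calls)
    if kind is not None and kind != table.call_kind:
        raise ValueError(
            f"cannot filter {kind} calls with a {table.call_kind} background table"
        )
    retained = []
    for call in calls:
        gene = call.gene if isinstance(call, (ChCall, HaCall)) else call[1]
        prevalence = table.prevalence(gene)
        if prevalence is None or prevalence < prevalence_max:
            retained.append(call)
    return retained
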