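"""Haplotype frequency tables, allele-frequency profiles, thresholding and
position-drop compression.

Frequencies are maintained as exact copy counts wherever the table originates
from a cohort; division happens at access time, so compression (which sums
counts of haplotypes that project to the same core string) conserves per-unit
frequency mass exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .panel import MISSING, PhasedCohort

logger = logging.getLogger(__name__)


@dataclass
class HaplotypeFrequencyTable:
    """Distinct haplotype strings x units (populations or supergroups).

    ``freq`` rows are haplotype strings over the panel subset ``positions``
    (1-based panel_index values, in panel order); columns are unit labels.
    ``counts``/``totals`` are present when the table was built from copies.
    """

    freq: pd.DataFrame
    positions: tuple[int, ...]
    counts: Optional[pd.DataFrame] = None
    totals: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        lengths = {len(h) for h in self.freq.index}
        if lengths and lengths != {len(self.positions)}:
            raise ValueError("haplotype string length != |position subset|")
        if (self.freq.to_numpy() < 0).any():
            raise ValueError("negative frequency")

    @property
    def units(self) -> list[str]:
        return list(self.freq.columns)

    @property
    def haplotypes(self) -> list[str]:
        return list(self.freq.index)

    @property
    def sum_column(self) -> pd.Series:
        """Unweighted row sum of unit frequencies (the published SUM column)."""
        return self.freq.sum(axis=1).rename("SUM")

    def pooled_frequency(self) -> Optional[pd.Series]:
        """Copy-weighted pooled frequency across units (needs counts)."""
        if self.counts is None or self.totals is None:
            return None
        return (self.counts.sum(axis=1) / float(self.totals.sum())).rename("pooled")

    def sorted_by_sum(self) -> "HaplotypeFrequencyTable":
        order = self.sum_column.sort_values(ascending=False, kind="stable").index
        return replace(
            self,
            freq=self.freq.loc[order],
            counts=None if self.counts is None else self.counts.loc[order],
        )

    def to_frame(self, sigfigs: int = 3) -> pd.DataFrame:
        """Report frame with SUM column and per-unit retained-mass row."""
        out = self.freq.copy()
        out["SUM"] = self.sum_column
        mass = out.sum(axis=0).rename("SUM")
        out = pd.concat([out, mass.to_frame().T])
        return out.map(lambda v: _round_sig(v, sigfigs))

    def write_tsv(self, path: str | Path, sigfigs: int = 3) -> None:
        self.to_frame(sigfigs).to_csv(path, sep="\t", index_label="haplotype")


def _round_sig(v: float, sig: int) -> float:
    if v == 0 or not np.isfinite(v):
        return v
    return float(np.format_float_positional(v, precision=sig, fractional=False, unique=False))


@dataclass
class AlleleFrequencyProfile:
    """Per panel position x unit frequency of the low-risk (non-risk) allele."""

    low_risk_freq: pd.DataFrame  # index: panel_index; columns: units
    monomorphic: pd.DataFrame    # bool, same shape: minor-allele freq < epsilon
    epsilon: float

    @property
    def risk_freq(self) -> pd.DataFrame:
        return 1.0 - self.low_risk_freq


def count_haplotypes(cohort: PhasedCohort, level: str = "population") -> HaplotypeFrequencyTable:
    """Count complete haplotype copies per unit and convert to frequencies.

    Copies with any missing entry are excluded from counting (the excluded
    count is logged).  Raises if any unit is left without complete copies.
    """
    mask = cohort.complete_mask()
    n_excl = int((~mask).sum())
    if n_excl:
        logger.warning("excluding %d haplotype copies with missing entries", n_excl)
    labels = cohort.unit_labels(level)
    positions = tuple(range(1, len(cohort.panel) + 1))
    strings = np.array(cohort.strings(), dtype=object)

    all_units = sorted(set(labels.tolist()))
    kept_labels = labels[mask]
    kept_strings = strings[mask]
    counts = (
        pd.crosstab(pd.Series(kept_strings, name="haplotype"), pd.Series(kept_labels, name="unit"))
        .reindex(columns=all_units, fill_value=0)
    )
    totals = counts.sum(axis=0)
    empty = totals[totals == 0].index.tolist()
    if empty or counts.empty:
        raise ValueError(f"unit(s) with zero complete haplotype copies: {empty or all_units}")
    freq = counts / totals
    table = HaplotypeFrequencyTable(
        freq=freq.astype(float), positions=positions,
        counts=counts.astype(int), totals=totals.astype(int),
    )
    return table.sorted_by_sum()


def filter_by_total_frequency(
    table: HaplotypeFrequencyTable, threshold: float
) -> HaplotypeFrequencyTable:
    """Keep haplotypes whose SUM across units strictly exceeds ``threshold``.

    Unit columns are deliberately not renormalized, so the per-unit retained
    mass (column sum) may be below 1.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = table.sum_column > threshold
    idx = table.freq.index[keep]
    return replace(
        table,
        freq=table.freq.loc[idx],
        counts=None if table.counts is None else table.counts.loc[idx],
    )


def allele_frequency_profile(
    cohort: PhasedCohort, level: str = "population", epsilon: float = 0.01
) -> AlleleFrequencyProfile:
    """Low-risk allele frequency per panel position per unit.

    Frequencies use all non-missing entries per site.  A position is flagged
    monomorphic in a unit when its minor-allele frequency is below ``epsilon``.
    """
    labels = cohort.unit_labels(level)
    units = sorted(set(labels.tolist()))
    L = len(cohort.panel)
    low = np.zeros((L, len(units)))
    for u_i, u in enumerate(units):
        sub = cohort.matrix[labels == u]
        if sub.size == 0:
            raise ValueError(f"unit {u!r} has no haplotype copies")
        observed = sub != MISSING
        n_obs = observed.sum(axis=0)
        if (n_obs == 0).any():
            raise ValueError(f"unit {u!r} has positions with no observed alleles")
        low[:, u_i] = ((sub == 0) & observed).sum(axis=0) / n_obs
    idx = pd.Index(range(1, L + 1), name="panel_index")
    low_df = pd.DataFrame(low, index=idx, columns=units)
    maf = np.minimum(low_df, 1.0 - low_df)
    return AlleleFrequencyProfile(low_risk_freq=low_df, monomorphic=maf < epsilon, epsilon=epsilon)


def project_haplotype(haplotype: str, positions: Sequence[int], drop_positions: set[int]) -> str:
    """Project a haplotype string onto the positions not in ``drop_positions``.

    ``positions`` are the panel_index values the string currently spans.
    """
    return "".join(c for c, p in zip(haplotype, positions) if p not in drop_positions)


def compress_haplotypes(
    table: HaplotypeFrequencyTable, drop_positions: Sequence[int]
) -> HaplotypeFrequencyTable:
    """Project haplotypes onto the kept positions, merging identical cores.

    Frequencies (and counts, when present) of haplotypes mapping to the same
    core string are summed exactly per unit; per-unit total mass is conserved.
    """
    drop = set(drop_positions)
    bad = drop - set(table.positions)
    if bad:
        raise ValueError(f"drop positions not in table position subset: {sorted(bad)}")
    kept = tuple(p for p in table.positions if p not in drop)
    if not kept:
        raise ValueError("cannot drop every position")
    if not drop:
        return replace(table)
    cores = [project_haplotype(h, table.positions, drop) for h in table.haplotypes]
    freq = table.freq.groupby(pd.Index(cores, name="haplotype"), sort=False).sum()
    counts = None
    if table.counts is not None:
        counts = table.counts.groupby(pd.Index(cores, name="haplotype"), sort=False).sum()
    out = HaplotypeFrequencyTable(freq=freq, positions=kept, counts=counts, totals=table.totals)
    return out.sorted_by_sum()


def table_from_frequencies(
    freqs: dict[str, dict[str, float]], positions: Sequence[int]
) -> HaplotypeFrequencyTable:
    """Build a (count-free) table from a nested {haplotype: {unit: freq}} dict."""
    freq = pd.DataFrame(freqs).T.fillna(0.0)
    freq.index.name = "haplotype"
    freq.columns.name = "unit"
    return HaplotypeFrequencyTable(freq=freq, positions=tuple(positions))


def read_table_tsv(path: str | Path) -> HaplotypeFrequencyTable:
    """Read a table written by :meth:`HaplotypeFrequencyTable.write_tsv`.

    The SUM column and per-unit mass row are dropped; positions are assumed
    1..string length (the TSV format does not carry the panel subset).
    """
    df = pd.read_csv(path, sep="\t", index_col="haplotype")
    df = df.drop(columns=[c for c in df.columns if c == "SUM"])
    df = df.drop(index=[i for i in df.index if i == "SUM"])
    ell = len(df.index[0])
    return HaplotypeFrequencyTable(freq=df.astype(float), positions=tuple(range(1, ell + 1)))
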