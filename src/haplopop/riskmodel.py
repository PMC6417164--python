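"""Risk-allele load scoring, Yin-Yang haplotype detection, Hardy-Weinberg
diplotype inference and sex-stratified haplotype frequencies."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .hapfreq import HaplotypeFrequencyTable
from .panel import PhasedCohort, SnpPanel, SnpRecord


@dataclass
class RiskProfile:
    haplotype: str
    risk_load: int
    label: str  # lowest_risk | highest_risk | intermediate


@dataclass
class DiplotypeDistribution:
    """HWE genotype proportions from the two Yin-Yang haplotype frequencies.

    ``raw`` mode keeps the input frequencies as absolute haplotype
    frequencies (an ``other`` category absorbs 1 - (p_low + p_risk))^2 mass);
    ``renormalized`` mode rescales the two frequencies to sum to one first.
    """

    p_low: float
    p_risk: float
    n_individuals: int
    mode: str
    proportions: dict[str, float]  # HH, HR, RR, other
    counts: dict[str, int]

    def percentages(self) -> dict[str, int]:
        return {k: round(100.0 * v) for k, v in self.proportions.items()}


def _subset_records(
    orientation: Union[SnpPanel, Sequence[SnpRecord]],
    positions: Optional[Sequence[int]] = None,
) -> tuple[SnpRecord, ...]:
    if isinstance(orientation, SnpPanel):
        if positions is None:
            return orientation.records
        return orientation.subset(positions)
    return tuple(orientation)


def risk_load(
    haplotype: str,
    orientation: Union[SnpPanel, Sequence[SnpRecord]],
    positions: Optional[Sequence[int]] = None,
) -> RiskProfile:
    """Count risk alleles carried by a haplotype over the panel subset.

    Load 0 is classed lowest_risk, a full house highest_risk, anything else
    intermediate.  A letter matching neither allele at a position is an error.
    """
    recs = _subset_records(orientation, positions)
    if len(haplotype) != len(recs):
        raise ValueError(
            f"haplotype length {len(haplotype)} != panel subset length {len(recs)}"
        )
    load = 0
    for rec, letter in zip(recs, haplotype):
        code = rec.code(letter)  # raises on a foreign letter
        load += code
    ell = len(recs)
    label = "lowest_risk" if load == 0 else ("highest_risk" if load == ell else "intermediate")
    return RiskProfile(haplotype=haplotype, risk_load=load, label=label)


def complement_haplotype(
    haplotype: str,
    orientation: Union[SnpPanel, Sequence[SnpRecord]],
    positions: Optional[Sequence[int]] = None,
) -> str:
    """Swap risk and non-risk allele at every position."""
    recs = _subset_records(orientation, positions)
    return "".join(r.letter(1 - r.code(c)) for r, c in zip(recs, haplotype))


def yin_yang_pair(
    table: HaplotypeFrequencyTable,
) -> Optional[tuple[str, str, pd.Series]]:
    """The highest-frequency pair of haplotypes differing at every position.

    Pairs are ranked by summed SUM-column frequency; the winner is returned as
    (haplotype_a, haplotype_b, per-unit combined frequency) with the two
    strings in lexicographic order, or None when no fully complementary pair
    exists.
    """
    haps = table.haplotypes
    sums = table.sum_column
    best: Optional[tuple[str, str]] = None
    best_mass = -1.0
    for i in range(len(haps)):
        for j in range(i + 1, len(haps)):
            a, b = haps[i], haps[j]
            if any(x == y for x, y in zip(a, b)):
                continue
            mass = float(sums[a] + sums[b])
            pair = tuple(sorted((a, b)))
            if mass > best_mass or (mass == best_mass and best is not None and pair < best):
                best, best_mass = pair, mass
    if best is None:
        return None
    combined = table.freq.loc[best[0]] + table.freq.loc[best[1]]
    return best[0], best[1], combined


def _largest_remainder_counts(proportions: dict[str, float], n: int) -> dict[str, int]:
    raw = {k: n * v for k, v in proportions.items()}
    base = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(base.values())
    order = sorted(raw, key=lambda k: (raw[k] - base[k], k), reverse=True)
    for k in order[:short]:
        base[k] += 1
    return base


def hwe_diplotypes(
    p_low: float, p_risk: float, n_individuals: int, mode: str = "raw"
) -> DiplotypeDistribution:
    """Hardy-Weinberg genotype distribution from two haplotype frequencies.

    H denotes the low-risk and R the risk haplotype.  Counts use the
    largest-remainder method so they sum exactly to N.
    """
    if p_low < 0 or p_risk < 0:
        raise ValueError("frequencies must be non-negative")
    if mode == "raw":
        if p_low + p_risk > 1 + 1e-12:
            raise ValueError("p_low + p_risk must not exceed 1 in raw mode")
        props = {
            "HH": p_low ** 2,
            "HR": 2.0 * p_low * p_risk,
            "RR": p_risk ** 2,
            "other": max(0.0, 1.0 - (p_low + p_risk) ** 2),
        }
    elif mode == "renormalized":
        s = p_low + p_risk
        if s <= 0:
            raise ValueError("p_low + p_risk must be positive in renormalized mode")
        p = p_low / s
        q = 1.0 - p
        props = {"HH": p * p, "HR": 2.0 * p * q, "RR": q * q, "other": 0.0}
    else:
        raise ValueError(f"mode must be 'raw' or 'renormalized', got {mode!r}")
    counts = _largest_remainder_counts(props, n_individuals)
    return DiplotypeDistribution(
        p_low=p_low, p_risk=p_risk, n_individuals=n_individuals, mode=mode,
        proportions=props, counts=counts,
    )


@dataclass
class SexStratifiedFrequency:
    target: str
    unit: str
    male_freq: Optional[float]
    female_freq: Optional[float]
    n_male_copies: int
    n_female_copies: int
    n_unknown_copies: int


def sex_stratified_frequency(
    cohort: PhasedCohort,
    target: Union[str, Sequence[str]],
    unit: str,
    level: str = "supergroup",
    positions: Optional[Sequence[int]] = None,
) -> SexStratifiedFrequency:
    """Frequency of a haplotype (or set of haplotypes) among male vs female
    copies of one unit.

    ``target`` may be a single string or a collection (e.g. all haplotypes of
    a risk class) over the panel subset ``positions`` (default: full panel).
    A sex stratum with no copies reports ``None``, not 0; unknown-sex copies
    are excluded and counted.
    """
    labels = cohort.unit_labels(level)
    in_unit = labels == unit
    if not in_unit.any():
        raise ValueError(f"unit {unit!r} not present at level {level!r}")
    complete = cohort.complete_mask()
    sex = cohort.sex
    if not np.isin(sex[in_unit], ["male", "female"]).any():
        raise ValueError(f"no sexed samples in unit {unit!r}")
    strings = np.array(cohort.strings(positions), dtype=object)
    targets = {target} if isinstance(target, str) else set(target)
    hit = np.isin(strings, list(targets))

    out = {}
    for s in ("male", "female"):
        m = in_unit & complete & (sex == s)
        n = int(m.sum())
        out[s] = (float(hit[m].mean()) if n else None, n)
    n_unknown = int((in_unit & complete & (sex == "unknown")).sum())
    return SexStratifiedFrequency(
        target=",".join(sorted(targets)), unit=unit,
        male_freq=out["male"][0], female_freq=out["female"][0],
        n_male_copies=out["male"][1], n_female_copies=out["female"][1],
        n_unknown_copies=n_unknown,
    )
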