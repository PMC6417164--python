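"""Hierarchical analysis of molecular variance (AMOVA).

Three-level design: haplotype copies within populations within groups.  Sums
of squared deviations are computed from squared pairwise distances between
copies,

    SSD_total = (1 / 2N) * sum_ij d_ij^2           (all ordered pairs)
    SSD_WP    = sum_p (1 / 2N_p) * sum_{i,j in p} d_ij^2
    SSD_WG    = sum_g (1 / 2N_g) * sum_{i,j in g} d_ij^2
    SSD_APWG  = SSD_WG - SSD_WP
    SSD_AG    = SSD_total - SSD_WG

with variance components obtained by equating mean squares to their
expectations under the unbalanced three-level design.  The single-locus
distance is 0/1 identity; the haplotypic distance is the Hamming count
(squared inside the SSDs).  Negative variance components are reported as
computed and flagged; percent variation can optionally truncate them at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .panel import PhasedCohort

LEVELS = ("among_groups", "among_populations_within_groups", "within_populations")


@dataclass
class AmovaLevel:
    ssd: float
    df: int
    variance: float


@dataclass
class AmovaResult:
    locus: str
    levels: dict[str, AmovaLevel]
    coefficients: dict[str, float]  # n, n_prime, n_dprime
    percent: dict[str, float]
    degenerate: bool = False
    has_negative_components: bool = False

    @property
    def ssd_total(self) -> float:
        return sum(l.ssd for l in self.levels.values())

    @property
    def percent_among_groups(self) -> float:
        return self.percent["among_groups"]

    @property
    def va(self) -> float:
        return self.levels["among_groups"].variance


@dataclass
class PositionFilterResult:
    kept: list[int]
    dropped: list[int]
    threshold: float
    percent_among_groups: dict[int, float]


def _weighted_ssd(D2: np.ndarray, w: np.ndarray) -> float:
    """(1/2n) * sum over ordered copy pairs of d^2, from unique-row weights."""
    n = w.sum()
    if n == 0:
        return 0.0
    return float(w @ D2 @ w) / (2.0 * n)


def amova_from_arrays(
    data: np.ndarray,
    populations: Sequence[str],
    groups: Sequence[str],
    locus: str = "haplotypic",
    truncate_for_percent: bool = True,
) -> AmovaResult:
    """Three-level AMOVA on a (N, L) matrix of haplotype copies.

    ``populations``/``groups`` give the copy-level labels (every population
    must lie in exactly one group).  Distances are Hamming counts over the L
    columns, squared inside the SSDs; pass a single column for a 0/1
    single-locus distance.
    """
    data = np.atleast_2d(np.asarray(data))
    pops = np.asarray(populations)
    grps = np.asarray(groups)
    N = data.shape[0]
    if pops.shape[0] != N or grps.shape[0] != N:
        raise ValueError("label lengths must match the number of copies")
    pop_group = pd.Series(grps).groupby(pd.Series(pops)).nunique()
    if (pop_group > 1).any():
        raise ValueError("population assigned to more than one group")
    pop_names = sorted(set(pops.tolist()))
    grp_names = sorted(set(grps.tolist()))
    P, G = len(pop_names), len(grp_names)
    if G < 2:
        raise ValueError("need at least 2 groups")
    if P - G == 0:
        raise ValueError(
            "the three-level design needs within-group replication (P - G > 0)"
        )

    # collapse to unique haplotypes; squared Hamming distances between them
    uniq, inv = np.unique(data, axis=0, return_inverse=True)
    U = uniq.shape[0]
    D = (uniq[:, None, :] != uniq[None, :, :]).sum(axis=2).astype(np.float64)
    D2 = D * D

    def weights(mask: np.ndarray) -> np.ndarray:
        return np.bincount(inv[mask], minlength=U).astype(np.float64)

    all_mask = np.ones(N, dtype=bool)
    ssd_total = _weighted_ssd(D2, weights(all_mask))
    ssd_wp = sum(_weighted_ssd(D2, weights(pops == p)) for p in pop_names)
    ssd_wg = sum(_weighted_ssd(D2, weights(grps == g)) for g in grp_names)
    ssd_apwg = ssd_wg - ssd_wp
    ssd_ag = ssd_total - ssd_wg

    n_p = {p: int((pops == p).sum()) for p in pop_names}
    n_g = {g: int((grps == g).sum()) for g in grp_names}
    group_of = {p: grps[pops == p][0] for p in pop_names}
    if min(n_p.values()) < 1:
        raise ValueError("every population needs at least 1 copy")

    df_ag, df_apwg, df_wp = G - 1, P - G, N - P

    # expected-mean-square coefficients for the unbalanced nested design
    sum_np2_over_ng = sum(
        sum(n_p[p] ** 2 for p in pop_names if group_of[p] == g) / n_g[g] for g in grp_names
    )
    n_coef = (N - sum_np2_over_ng) / (P - G)
    n_prime = (sum_np2_over_ng - sum(v * v for v in n_p.values()) / N) / (G - 1)
    n_dprime = (N - sum(v * v for v in n_g.values()) / N) / (G - 1)

    ms_wp = ssd_wp / df_wp if df_wp > 0 else 0.0
    ms_apwg = ssd_apwg / df_apwg
    ms_ag = ssd_ag / df_ag
    vc = ms_wp
    vb = (ms_apwg - vc) / n_coef
    va = (ms_ag - vc - n_prime * vb) / n_dprime

    degenerate = ssd_total == 0.0
    comps = {"among_groups": va, "among_populations_within_groups": vb, "within_populations": vc}
    has_negative = any(v < 0 for v in comps.values())
    if degenerate:
        percent = {k: 0.0 for k in comps}
    else:
        basis = {k: (max(v, 0.0) if truncate_for_percent else v) for k, v in comps.items()}
        total = sum(basis.values())
        percent = {k: (100.0 * v / total if total > 0 else 0.0) for k, v in basis.items()}

    levels = {
        "among_groups": AmovaLevel(ssd_ag, df_ag, va),
        "among_populations_within_groups": AmovaLevel(ssd_apwg, df_apwg, vb),
        "within_populations": AmovaLevel(ssd_wp, df_wp, vc),
    }
    return AmovaResult(
        locus=locus,
        levels=levels,
        coefficients={"n": n_coef, "n_prime": n_prime, "n_dprime": n_dprime},
        percent=percent,
        degenerate=degenerate,
        has_negative_components=has_negative,
    )


def amova(
    cohort: PhasedCohort,
    distance: Union[str, int] = "hamming",
    truncate_for_percent: bool = True,
) -> AmovaResult:
    """AMOVA on a cohort: populations nested in supergroups.

    ``distance`` is ``"hamming"`` for full haplotypes or a 1-based
    panel_index for a single-locus 0/1 distance.
    """
    mask = cohort.complete_mask()
    if isinstance(distance, int):
        data = cohort.matrix[mask][:, [distance - 1]]
        locus = str(distance)
    elif distance == "hamming":
        data = cohort.matrix[mask]
        locus = "haplotypic"
    else:
        raise ValueError(f"unknown distance {distance!r}")
    return amova_from_arrays(
        data, cohort.populations[mask], cohort.supergroups[mask],
        locus=locus, truncate_for_percent=truncate_for_percent,
    )


def amova_per_locus(
    cohort: PhasedCohort, truncate_for_percent: bool = True
) -> list[AmovaResult]:
    """One single-locus AMOVA per panel position, in panel order."""
    return [
        amova(cohort, distance=i, truncate_for_percent=truncate_for_percent)
        for i in range(1, len(cohort.panel) + 1)
    ]


def select_informative_positions(
    per_locus: Sequence[Union[AmovaResult, float]], threshold_percent: float
) -> PositionFilterResult:
    """Drop positions whose among-group percent variation is strictly below
    the threshold; positions are the 1-based indices of the input order."""
    if not 0.0 <= threshold_percent <= 100.0:
        raise ValueError("threshold must lie in [0, 100]")
    percents: dict[int, float] = {}
    for i, item in enumerate(per_locus, start=1):
        percents[i] = item.percent_among_groups if isinstance(item, AmovaResult) else float(item)
    dropped = [p for p, v in percents.items() if v < threshold_percent]
    kept = [p for p in percents if p not in set(dropped)]
    return PositionFilterResult(
        kept=kept, dropped=dropped, threshold=threshold_percent, percent_among_groups=percents
    )


def per_locus_report(results: Sequence[AmovaResult]) -> pd.DataFrame:
    """Report frame mirroring the published per-locus table layout."""
    rows = []
    for i, r in enumerate(results, start=1):
        ag = r.levels["among_groups"]
        rows.append(
            {"Locus": i, "SSD": ag.ssd, "d.f.": ag.df, "Va": ag.variance,
             "%variation": r.percent_among_groups}
        )
    return pd.DataFrame(rows).set_index("Locus")
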