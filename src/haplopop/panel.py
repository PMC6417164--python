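"""SNP panel and sample panel I/O, and risk-oriented haplotype extraction from phased VCF.

The panel defines, for each SNP, which allele is the GWAS risk allele and which
is the low-risk (reference/major) alternative.  All downstream computation uses
the binary risk/non-risk encoding; nucleotide strings are a rendering of that
encoding through the panel letters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: matrix codes for haplotype entries
NONRISK, RISK, MISSING = 0, 1, -1


@dataclass(frozen=True)
class SnpRecord:
    """One panel SNP with its risk orientation.

    ``panel_index`` is the 1-based ordinal of the SNP within the panel and is
    the coordinate system used by position filtering and compression.
    """

    rsid: str
    chrom: str
    risk_allele: str
    other_allele: str
    pos: Optional[int] = None
    cpg_flag: bool = False
    panel_index: int = 0
    haploblock: Optional[int] = None
    gwas_pvalue: Optional[float] = None

    def __post_init__(self) -> None:
        if self.risk_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.rsid}: risk allele {self.risk_allele!r} not in A/C/G/T")
        if self.other_allele not in _VALID_ALLELES:
            raise ValueError(f"{self.rsid}: other allele {self.other_allele!r} not in A/C/G/T")
        if self.risk_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: risk and other allele are both {self.risk_allele!r}")

    def letter(self, code: int) -> str:
        """Render a risk/non-risk code as the panel nucleotide."""
        if code == RISK:
            return self.risk_allele
        if code == NONRISK:
            return self.other_allele
        return "N"

    def code(self, letter: str) -> int:
        if letter == self.risk_allele:
            return RISK
        if letter == self.other_allele:
            return NONRISK
        raise ValueError(
            f"{self.rsid}: letter {letter!r} matches neither risk ({self.risk_allele}) "
            f"nor other ({self.other_allele}) allele"
        )


class SnpPanel(Sequence[SnpRecord]):
    """Ordered risk-oriented SNP panel."""

    def __init__(self, records: Iterable[SnpRecord]):
        recs = list(records)
        if not recs:
            raise ValueError("empty SNP panel")
        seen: set[str] = set()
        for r in recs:
            if r.rsid in seen:
                raise ValueError(f"duplicate rsid in panel: {r.rsid}")
            seen.add(r.rsid)
        idx = [r.panel_index for r in recs]
        if idx != list(range(1, len(recs) + 1)):
            raise ValueError("panel_index values must form 1..L in file order")
        by_chrom: dict[str, int] = {}
        for r in recs:
            if r.pos is None:
                continue
            prev = by_chrom.get(r.chrom)
            if prev is not None and r.pos <= prev:
                raise ValueError(f"panel positions not strictly increasing at {r.rsid}")
            by_chrom[r.chrom] = r.pos
        self.records: tuple[SnpRecord, ...] = tuple(recs)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SnpRecord]:
        return iter(self.records)

    def __getitem__(self, i):  # type: ignore[override]
        return self.records[i]

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(r.rsid for r in self.records)

    def record(self, panel_index: int) -> SnpRecord:
        """Look up a record by its 1-based panel index."""
        return self.records[panel_index - 1]

    def subset(self, positions: Sequence[int]) -> tuple[SnpRecord, ...]:
        """Records for a panel_index subset, kept in panel order."""
        keep = sorted(set(positions))
        bad = [p for p in keep if not 1 <= p <= len(self)]
        if bad:
            raise ValueError(f"panel_index out of range: {bad}")
        return tuple(self.record(p) for p in keep)

    def encode(self, haplotype: str, positions: Optional[Sequence[int]] = None) -> np.ndarray:
        """Nucleotide string -> risk/non-risk codes over a panel_index subset."""
        recs = self.records if positions is None else self.subset(positions)
        if len(haplotype) != len(recs):
            raise ValueError(f"haplotype length {len(haplotype)} != subset length {len(recs)}")
        return np.array([r.code(c) for r, c in zip(recs, haplotype)], dtype=np.int8)

    def render(self, codes: Sequence[int], positions: Optional[Sequence[int]] = None) -> str:
        """Risk/non-risk codes -> nucleotide string."""
        recs = self.records if positions is None else self.subset(positions)
        if len(codes) != len(recs):
            raise ValueError("code vector length mismatch")
        return "".join(r.letter(int(c)) for r, c in zip(recs, codes))


@dataclass
class SamplePanel:
    """Sample metadata: population, continental supergroup and optional sex."""

    table: pd.DataFrame  # index: sample id; columns: pop, super_pop, sex

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        grouping = self.table.groupby("pop")["super_pop"].nunique()
        bad = grouping[grouping > 1].index.tolist()
        if bad:
            raise ValueError(f"population(s) assigned to more than one supergroup: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def populations(self) -> list[str]:
        return sorted(self.table["pop"].unique())

    @property
    def supergroups(self) -> list[str]:
        return sorted(self.table["super_pop"].unique())

    def supergroup_of(self) -> dict[str, str]:
        return dict(self.table.groupby("pop")["super_pop"].first())

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PhasedCohort:
    """Phased haplotype copies over the panel: 2 rows per individual.

    ``matrix`` holds risk(1)/non-risk(0)/missing(-1) codes, one row per
    haplotype copy, one column per panel SNP (in panel order).  Copies of a
    sample are adjacent (copy 1 then copy 2).
    """

    matrix: np.ndarray  # (2N, L) int8
    sample_ids: np.ndarray  # (2N,) str
    copy_index: np.ndarray  # (2N,) 1|2
    populations: np.ndarray  # (2N,) str
    supergroups: np.ndarray  # (2N,) str
    sex: np.ndarray  # (2N,) str in {male, female, unknown}
    panel: SnpPanel

    def __post_init__(self) -> None:
        n_rows, n_cols = self.matrix.shape
        if n_cols != len(self.panel):
            raise ValueError("matrix width != panel length")
        if n_rows % 2:
            raise ValueError("odd number of haplotype rows")
        counts = pd.Series(self.sample_ids).value_counts()
        if (counts != 2).any():
            raise ValueError("every sample must contribute exactly two haplotype rows")
        if bool(np.any((self.matrix == MISSING).all(axis=1))):
            raise ValueError("all-missing haplotype row present")

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0] // 2

    @property
    def n_copies(self) -> int:
        return self.matrix.shape[0]

    def unit_labels(self, level: str) -> np.ndarray:
        if level == "population":
            return self.populations
        if level == "supergroup":
            return self.supergroups
        raise ValueError(f"level must be 'population' or 'supergroup', got {level!r}")

    def complete_mask(self) -> np.ndarray:
        """True for copies without any missing entry."""
        return ~(self.matrix == MISSING).any(axis=1)

    def strings(self, positions: Optional[Sequence[int]] = None) -> list[str]:
        """Render every copy as a nucleotide string over a panel_index subset."""
        if positions is None:
            positions = range(1, len(self.panel) + 1)
        keep = sorted(set(positions))
        cols = [p - 1 for p in keep]
        sub = self.matrix[:, cols]
        return [self.panel.render(row, keep) for row in sub]

    def subset_units(self, level: str, units: Sequence[str]) -> "PhasedCohort":
        labels = self.unit_labels(level)
        mask = np.isin(labels, list(units))
        return PhasedCohort(
            matrix=self.matrix[mask],
            sample_ids=self.sample_ids[mask],
            copy_index=self.copy_index[mask],
            populations=self.populations[mask],
            supergroups=self.supergroups[mask],
            sex=self.sex[mask],
            panel=self.panel,
        )


def load_snp_panel(path: str | Path) -> SnpPanel:
    """Read a risk-oriented SNP panel from TSV.

    Required columns: rsid, chrom, risk, other.  Optional: pos, cpg,
    haploblock, gwas_p.  Records keep file order; panel_index is assigned 1..L.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"rsid", "chrom", "risk", "other"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"SNP panel missing columns: {sorted(missing_cols)}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = row._asdict()
        records.append(
            SnpRecord(
                rsid=d["rsid"],
                chrom=str(d["chrom"]),
                pos=int(str(d["pos"]).replace(",", "")) if _present(d.get("pos")) else None,
                risk_allele=str(d["risk"]).upper(),
                other_allele=str(d["other"]).upper(),
                cpg_flag=_truthy(d.get("cpg")),
                panel_index=i,
                haploblock=int(d["haploblock"]) if _present(d.get("haploblock")) else None,
                gwas_pvalue=float(d["gwas_p"]) if _present(d.get("gwas_p")) else None,
            )
        )
    return SnpPanel(records)


def load_sample_panel(path: str | Path) -> SamplePanel:
    """Read a sample panel TSV with columns sample, pop, super_pop[, sex]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "pop", "super_pop"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"sample panel missing columns: {sorted(missing_cols)}")
    if "sex" not in df.columns:
        df["sex"] = "unknown"
    df["sex"] = df["sex"].fillna("unknown").str.lower()
    bad_sex = set(df["sex"]) - {"male", "female", "unknown"}
    if bad_sex:
        raise ValueError(f"unrecognized sex values: {sorted(bad_sex)}")
    return SamplePanel(df.set_index("sample")[["pop", "super_pop", "sex"]])


def write_snp_panel(panel: SnpPanel, path: str | Path) -> None:
    """Write a panel back to the TSV layout accepted by :func:`load_snp_panel`."""
    rows = []
    for r in panel.records:
        rows.append({
            "rsid": r.rsid, "chrom": r.chrom, "pos": r.pos,
            "risk": r.risk_allele, "other": r.other_allele,
            "cpg": int(r.cpg_flag),
            "haploblock": r.haploblock if r.haploblock is not None else "",
            "gwas_p": r.gwas_pvalue if r.gwas_pvalue is not None else "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _present(v) -> bool:
    return v is not None and not (isinstance(v, float) and np.isnan(v)) and str(v) not in ("", "nan")


def _truthy(v) -> bool:
    return _present(v) and str(v).strip().lower() in ("1", "true", "yes", "y")


def _is_ambiguous(a: str, b: str) -> bool:
    """A/T and C/G SNPs cannot be disambiguated by reverse complement."""
    return _COMPLEMENT[a] == b


def extract_haplotypes(
    vcf_path: str | Path,
    panel: SnpPanel,
    samples: SamplePanel,
    *,
    allow_unphased: bool = False,
    try_reverse_complement: bool = False,
) -> PhasedCohort:
    """Extract risk-oriented phased haplotypes for the panel sites.

    Sites are matched by rsid (VCF ID column) first; when the panel carries a
    position it is used as a cross-check (mismatch logs a warning).  VCF
    REF/ALT order is immaterial: alleles are mapped onto the panel's
    risk/non-risk dichotomy.  Panel sites absent from the VCF yield missing
    entries.  Unphased genotypes at panel sites raise unless
    ``allow_unphased`` is set, in which case the sample is dropped with a
    warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    panel_samples = set(samples.sample_ids)
    extra = [s for s in vcf_samples if s not in panel_samples]
    if extra:
        logger.warning("excluding %d VCF sample(s) absent from the sample panel", len(extra))
    kept_samples = [s for s in samples.sample_ids if s in set(vcf_samples)]
    if not kept_samples:
        raise ValueError("no overlap between VCF samples and sample panel")
    col_of = {s: i for i, s in enumerate(vcf_samples)}

    by_rsid = {r.rsid: r for r in panel.records}
    L = len(panel)
    n = len(kept_samples)
    # allele codes per site per sample copy; start as missing
    geno = np.full((2 * n, L), MISSING, dtype=np.int8)
    seen_sites: set[str] = set()
    unphased_samples: set[str] = set()

    for variant in vcf:
        rec = by_rsid.get(variant.ID) if variant.ID else None
        if rec is None:
            continue
        if rec.rsid in seen_sites:
            raise ValueError(f"panel site {rec.rsid} occurs more than once in the VCF")
        seen_sites.add(rec.rsid)
        if len(variant.ALT) != 1:
            raise ValueError(f"panel site {rec.rsid} is not biallelic in the VCF")
        if rec.pos is not None and variant.POS != rec.pos:
            logger.warning(
                "position mismatch for %s: panel %d vs VCF %d (rsid match takes precedence)",
                rec.rsid, rec.pos, variant.POS,
            )
        mapping = _allele_mapping(rec, variant.REF.upper(), variant.ALT[0].upper(),
                                  try_reverse_complement)
        j = rec.panel_index - 1
        genotypes = variant.genotypes  # [a0, a1, phased]
        for i, s in enumerate(kept_samples):
            a0, a1, phased = genotypes[col_of[s]][:3]
            if a0 >= 0 and a1 >= 0 and not phased and a0 != a1:
                if not allow_unphased:
                    raise ValueError(
                        f"unphased heterozygous genotype for sample {s} at panel site "
                        f"{rec.rsid}; phasing is required (or pass allow_unphased)"
                    )
                unphased_samples.add(s)
                continue
            geno[2 * i, j] = mapping[a0] if a0 >= 0 else MISSING
            geno[2 * i + 1, j] = mapping[a1] if a1 >= 0 else MISSING

    absent = [r.rsid for r in panel.records if r.rsid not in seen_sites]
    if absent:
        logger.warning("panel site(s) absent from VCF, entries set missing: %s", absent)

    if unphased_samples:
        logger.warning("dropping %d sample(s) with unphased genotypes", len(unphased_samples))
        kept = [i for i, s in enumerate(kept_samples) if s not in unphased_samples]
        kept_samples = [kept_samples[i] for i in kept]
        rows = sorted([2 * i for i in kept] + [2 * i + 1 for i in kept])
        geno = geno[rows]
        n = len(kept_samples)

    if n == 0:
        raise ValueError("no samples left after filtering")

    meta = samples.table.loc[kept_samples]
    rep = np.repeat(np.arange(n), 2)
    return PhasedCohort(
        matrix=geno,
        sample_ids=np.array(kept_samples, dtype=object)[rep],
        copy_index=np.tile([1, 2], n),
        populations=meta["pop"].to_numpy()[rep],
        supergroups=meta["super_pop"].to_numpy()[rep],
        sex=meta["sex"].to_numpy()[rep],
        panel=panel,
    )


def _allele_mapping(rec: SnpRecord, ref: str, alt: str, try_rc: bool) -> dict[int, int]:
    """Map VCF allele indices {0: REF, 1: ALT} onto risk/non-risk codes."""
    pair = {ref, alt}
    if pair == {rec.risk_allele, rec.other_allele}:
        return {0: RISK if ref == rec.risk_allele else NONRISK,
                1: RISK if alt == rec.risk_allele else NONRISK}
    if try_rc and not _is_ambiguous(rec.risk_allele, rec.other_allele):
        rc = {_COMPLEMENT[rec.risk_allele], _COMPLEMENT[rec.other_allele]}
        if pair == rc:
            logger.warning("strand flip applied for %s", rec.rsid)
            return {0: RISK if ref == _COMPLEMENT[rec.risk_allele] else NONRISK,
                    1: RISK if alt == _COMPLEMENT[rec.risk_allele] else NONRISK}
    raise ValueError(
        f"panel alleles for {rec.rsid} ({rec.risk_allele}/{rec.other_allele}) "
        f"irreconcilable with VCF REF/ALT {ref}/{alt}"
    )
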