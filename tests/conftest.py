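"""Shared fixtures: panels, hand-built cohorts and a small simulated run."""

from __future__ import annotations

import numpy as np
import pytest

from haplopop import fto
from haplopop.panel import (
    PhasedCohort,
    SnpPanel,
    SnpRecord,
    extract_haplotypes,
    load_sample_panel,
)
from haplopop.simulate import default_fto_spec, simulate_cohort


@pytest.fixture(scope="session")
def fto_panel() -> SnpPanel:
    return fto.fto_panel()


def binary_panel(length: int) -> SnpPanel:
    """Generic biallelic panel: risk 'A', non-risk 'G' at every position."""
    return SnpPanel(
        SnpRecord(rsid=f"rs{i}", chrom="1", pos=100 * i, risk_allele="A",
                  other_allele="G", panel_index=i)
        for i in range(1, length + 1)
    )


def cohort_from_codes(codes, populations, supergroups, sex=None, panel=None) -> PhasedCohort:
    """Build a cohort from a (2N, L) risk/non-risk code matrix and labels."""
    codes = np.asarray(codes, dtype=np.int8)
    n_rows, L = codes.shape
    assert n_rows % 2 == 0
    n = n_rows // 2
    if panel is None:
        panel = binary_panel(L)
    if sex is None:
        sex = ["unknown"] * n_rows
    return PhasedCohort(
        matrix=codes,
        sample_ids=np.repeat([f"s{i}" for i in range(n)], 2).astype(object),
        copy_index=np.tile([1, 2], n),
        populations=np.asarray(populations, dtype=object),
        supergroups=np.asarray(supergroups, dtype=object),
        sex=np.asarray(sex, dtype=object),
        panel=panel,
    )


def cohort_from_unit_codes(unit_codes: dict, group_of: dict, panel=None) -> PhasedCohort:
    """Cohort from {population: list-of-code-rows} (rows paired into samples)."""
    rows, pops, grps = [], [], []
    for pop, mat in unit_codes.items():
        for row in mat:
            rows.append(row)
            pops.append(pop)
            grps.append(group_of[pop])
    return cohort_from_codes(np.array(rows), pops, grps, panel=panel)


@pytest.fixture(scope="session")
def core_ml_tree():
    """ML tree over the six published core haplotypes (exhaustive search)."""
    from haplopop.phylo import ml_tree

    return ml_tree(list(fto.CORE_HAPLOTYPE_FREQS))


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A reduced-size default-scenario simulation plus its extracted cohort."""
    out = tmp_path_factory.mktemp("small_sim")
    spec = default_fto_spec(size_factor=0.1, seed=2024)
    sim = simulate_cohort(spec, out)
    samples = load_sample_panel(sim.sample_panel_path)
    cohort = extract_haplotypes(sim.vcf_path, spec.panel, samples)
    return {"spec": spec, "sim": sim, "samples": samples, "cohort": cohort}
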