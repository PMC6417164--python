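"""End-to-end analysis pipeline.

Fixed stage order: extract -> frequency tables -> pairwise differentiation +
MDS -> per-locus AMOVA -> position filter -> compression -> phylogeny -> PCA
-> risk/HWE report.  Every stage writes its artifact into the output bundle;
a manifest records the seed, config hash and stage list.  Stage randomness
(only the permutation tests use any) draws from per-stage seeds derived by
stable hashing of the stage name, so adding stages never shifts streams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .amova import amova_per_locus, per_locus_report, select_informative_positions
from .diffstat import pairwise_distance_matrix, write_distance_matrix, write_phylip_matrix
from .hapfreq import compress_haplotypes, count_haplotypes, filter_by_total_frequency
from .ordination import classical_mds, pca_frequencies
from .panel import load_sample_panel, load_snp_panel, extract_haplotypes
from .phylo import annotate_ancestral, ml_tree, write_newick
from .riskmodel import hwe_diplotypes, risk_load, sex_stratified_frequency, yin_yang_pair

logger = logging.getLogger(__name__)

STAGES = (
    "extract", "frequencies", "diffstat", "amova", "position_filter",
    "compression", "phylogeny", "pca", "risk_report",
)


@dataclass
class PipelineConfig:
    vcf: str
    snp_panel: str
    sample_panel: str
    out_dir: str
    haplotype_threshold: float = 0.1
    amova_threshold_percent: float = 8.0
    n_permutations: int = 100_000
    seed: Optional[int] = None
    table_level: str = "supergroup"
    diffstat_level: str = "population"
    ancestral_unit: str = "AFR"
    hwe_unit: str = "EUR"
    truncate_negative_variance: bool = True
    mds_dimensions: int = 2
    pca_dimensions: int = 2
    allow_unphased: bool = False
    strand_flip: bool = False
    #: fixed core-position drop set; None means use the AMOVA filter's result
    drop_positions: Optional[list[int]] = None
    #: the tree stage keeps at most this many top-frequency core haplotypes
    max_tree_taxa: int = 12

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _py(obj):
    """JSON default: unwrap numpy scalars."""
    if isinstance(obj, np.generic):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _stage_seed(master: Optional[int], stage: str) -> Optional[int]:
    if master is None:
        return None
    ss = np.random.SeedSequence([int(master), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return a bundle summary dict.

    Any stage failure aborts with :class:`PipelineError` after writing a
    partial-bundle marker listing the stages that completed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    done: list[str] = []
    summary: dict = {"out_dir": str(out)}
    state: dict = {}

    try:
        for stage in STAGES:
            _run_stage(stage, config, out, state, summary)
            done.append(stage)
    except Exception as exc:  # noqa: BLE001 - stage name must reach the user
        (out / "PARTIAL").write_text("completed stages:\n" + "\n".join(done) + "\n")
        raise PipelineError(stage, exc) from exc

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "haplopop_version": __version__,
        "stages": list(STAGES),
        "config": asdict(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    summary["manifest"] = manifest
    return summary


def _run_stage(stage: str, config: PipelineConfig, out: Path, state: dict, summary: dict) -> None:
    if stage == "extract":
        panel = load_snp_panel(config.snp_panel)
        samples = load_sample_panel(config.sample_panel)
        state["panel"] = panel
        state["cohort"] = extract_haplotypes(
            config.vcf, panel, samples,
            allow_unphased=config.allow_unphased,
            try_reverse_complement=config.strand_flip,
        )
        summary["n_individuals"] = state["cohort"].n_individuals

    elif stage == "frequencies":
        table = count_haplotypes(state["cohort"], level=config.table_level)
        state["full_table"] = table
        filtered = filter_by_total_frequency(table, config.haplotype_threshold)
        state["full_filtered"] = filtered
        filtered.write_tsv(out / "haplotype_table_full.tsv")
        summary["n_major_full_haplotypes"] = len(filtered.haplotypes)

    elif stage == "diffstat":
        result = pairwise_distance_matrix(
            state["cohort"], level=config.diffstat_level,
            n_perm=config.n_permutations, seed=_stage_seed(config.seed, stage),
        )
        state["distmat"] = result
        write_distance_matrix(result, out / "pprime_matrix.tsv")
        result.p_values.to_csv(out / "pprime_pvalues.tsv", sep="\t", index_label="unit")
        write_phylip_matrix(result, out / "pprime_matrix.phy")
        mds = classical_mds(result.p_corrected, k=config.mds_dimensions)
        mds.write_tsv(out / "mds_coordinates.tsv")
        state["mds"] = mds

    elif stage == "amova":
        results = amova_per_locus(
            state["cohort"], truncate_for_percent=config.truncate_negative_variance
        )
        state["amova_per_locus"] = results
        rep = per_locus_report(results)
        rep.to_csv(out / "amova_per_locus.tsv", sep="\t", float_format="%.6g")
        full = json.dumps(
            [
                {
                    "locus": r.locus,
                    "levels": {k: vars(v) for k, v in r.levels.items()},
                    "coefficients": r.coefficients,
                    "percent": r.percent,
                    "degenerate": r.degenerate,
                    "has_negative_components": r.has_negative_components,
                }
                for r in results
            ],
            indent=1, default=_py,
        )
        (out / "amova_per_locus.json").write_text(full + "\n")

    elif stage == "position_filter":
        pf = select_informative_positions(
            state["amova_per_locus"], config.amova_threshold_percent
        )
        state["position_filter"] = pf
        (out / "position_filter.json").write_text(
            json.dumps(
                {"kept": pf.kept, "dropped": pf.dropped, "threshold": pf.threshold,
                 "percent_among_groups": pf.percent_among_groups},
                indent=1, sort_keys=True, default=_py,
            ) + "\n"
        )
        summary["dropped_positions"] = pf.dropped

    elif stage == "compression":
        dropped = (config.drop_positions if config.drop_positions is not None
                   else state["position_filter"].dropped)
        summary["compression_drop_positions"] = list(dropped)
        core = compress_haplotypes(state["full_table"], dropped)
        state["core_table"] = core
        core_filtered = filter_by_total_frequency(core, config.haplotype_threshold)
        state["core_filtered"] = core_filtered
        core_filtered.write_tsv(out / "haplotype_table_core.tsv")
        summary["n_major_core_haplotypes"] = len(core_filtered.haplotypes)

    elif stage == "phylogeny":
        table = state["core_filtered"]
        if len(table.haplotypes) > config.max_tree_taxa:
            order = table.sum_column.sort_values(ascending=False, kind="stable")
            keep = list(order.index[: config.max_tree_taxa])
            from dataclasses import replace as _replace

            table = _replace(table, freq=table.freq.loc[keep], counts=None)
        tree = ml_tree(table.haplotypes)
        annotated = annotate_ancestral(
            tree, table, ancestral_unit=config.ancestral_unit, panel=state["panel"]
        )
        state["tree"] = annotated
        write_newick(annotated, out / "tree.nwk")
        ann = {
            "leaves": annotated.leaf_annotations,
            "branch_changes": {
                "|".join(k): v for k, v in annotated.branch_changes.items()
            },
        }
        (out / "tree_annotations.json").write_text(json.dumps(ann, indent=1, sort_keys=True, default=_py) + "\n")

    elif stage == "pca":
        pca = pca_frequencies(state["core_filtered"], k=config.pca_dimensions)
        pca.write_tsv(out / "pca_coordinates.tsv")
        state["pca"] = pca

    elif stage == "risk_report":
        _risk_report(config, out, state, summary)

    else:  # pragma: no cover
        raise ValueError(f"unknown stage {stage!r}")


def _risk_report(config: PipelineConfig, out: Path, state: dict, summary: dict) -> None:
    table = state["core_filtered"]
    panel = state["panel"]
    positions = table.positions
    cohort = state["cohort"]

    rows = []
    for h in table.haplotypes:
        prof = risk_load(h, panel, positions)
        row = {"haplotype": h, "risk_load": prof.risk_load, "class": prof.label}
        row.update({u: table.freq.loc[h, u] for u in table.units})
        rows.append(row)
    report = pd.DataFrame(rows).set_index("haplotype")

    yy = yin_yang_pair(table)
    hwe_out: dict = {"yin_yang": None}
    if yy is not None:
        a, b, combined = yy
        load_a = risk_load(a, panel, positions).risk_load
        low, high = (a, b) if load_a <= risk_load(b, panel, positions).risk_load else (b, a)
        unit = config.hwe_unit
        if unit in table.units:
            p_low = float(table.freq.loc[low, unit])
            p_risk = float(table.freq.loc[high, unit])
            labels = cohort.unit_labels(config.table_level)
            n_unit = int((labels == unit).sum()) // 2
            raw = hwe_diplotypes(p_low, p_risk, n_unit, mode="raw")
            ren = hwe_diplotypes(p_low, p_risk, n_unit, mode="renormalized")
            hwe_out = {
                "yin_yang": {"low_risk": low, "risk": high,
                             "combined_frequency": {u: float(v) for u, v in combined.items()}},
                "unit": unit,
                "p_low": p_low,
                "p_risk": p_risk,
                "n_individuals": n_unit,
                "raw": {"proportions": raw.proportions, "counts": raw.counts},
                "renormalized": {"proportions": ren.proportions, "counts": ren.counts},
            }
            summary["hwe_renormalized_percent"] = ren.percentages()

        risky = [h for h in table.haplotypes
                 if risk_load(h, panel, positions).label == "highest_risk"]
        if risky and np.isin(cohort.sex, ["male", "female"]).any():
            strat = sex_stratified_frequency(
                cohort, risky, unit=config.hwe_unit, level=config.table_level,
                positions=positions,
            )
            hwe_out["sex_stratified_risk"] = {
                "unit": strat.unit, "male": strat.male_freq, "female": strat.female_freq,
                "n_male_copies": strat.n_male_copies,
                "n_female_copies": strat.n_female_copies,
            }
    (out / "hwe_report.json").write_text(
        json.dumps(hwe_out, indent=1, sort_keys=True, default=_py) + "\n"
    )
    report.to_csv(out / "risk_report.tsv", sep="\t", float_format="%.6g")
    state["risk_report"] = report
    state["hwe"] = hwe_out
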