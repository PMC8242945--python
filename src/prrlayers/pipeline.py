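"""End-to-end orchestration: simulate -> screen -> normalize -> layers ->
differential expression -> consistent/variable partition.

Every stage writes plain tab-separated/JSON artifacts into the run
directory and the run report records a digest of each, so a run is
reproducible (same config + seed -> identical digests, timings aside) and
each paper-style threshold actually applied is logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import de, domains, io, layers, normalization, partition, simulate

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulation`` (a SimulationConfig block) or ``inputs``
    (paths to counts/lengths/design/domain/flags tables) must be given.
    """

    outdir: str = "prrlayers_run"
    seed: int = 0
    simulation: simulate.SimulationConfig | None = None
    inputs: dict | None = None
    alpha: float = 0.005
    lfc_min: float = 2.0
    high_expr: float = 10.0
    cut_fraction: float = 0.40
    support_lfc: float = 1.0
    n_permutations: int = 999

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of a simulation block or input paths is required"
            )
        for name in ("alpha", "lfc_min", "high_expr", "cut_fraction",
                     "support_lfc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = io.read_yaml(path)
        sim = raw.pop("simulation", None)
        if sim is not None:
            if "dropout_samples" in sim:
                sim["dropout_samples"] = tuple(
                    tuple(d) for d in sim["dropout_samples"]
                )
            sim = simulate.SimulationConfig(**sim)
        return cls(simulation=sim, **raw)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_inputs(
    counts: pd.DataFrame,
    lengths: pd.Series,
    design: pd.DataFrame,
    domain_table: pd.DataFrame | None = None,
) -> dict:
    """Cross-consistency diagnostics; fatal problems raise."""
    warnings: list[str] = []
    design_samples = set(design["sample_id"])
    matrix_samples = set(map(str, counts.columns))
    orphans = matrix_samples - design_samples
    if orphans:
        raise ValueError(
            f"sample(s) in count matrix absent from design: {sorted(orphans)[:5]}"
        )
    unused = design_samples - matrix_samples
    if unused:
        warnings.append(
            f"{len(unused)} design sample(s) have no count column"
        )
    missing_len = set(counts.index) - set(lengths.index)
    if missing_len:
        raise ValueError(
            f"gene(s) without length: {sorted(missing_len)[:5]}"
        )
    dup = design.duplicated(["individual_id", "treatment", "timepoint"])
    if dup.any():
        raise ValueError("duplicate (individual, treatment, timepoint) rows")
    both = design.groupby("individual_id")["treatment"].nunique()
    if (both > 1).any():
        raise ValueError(
            f"individual(s) in both treatments: "
            f"{both.index[both > 1].tolist()[:5]}"
        )
    if domain_table is not None:
        unknown = set(domain_table["transcript_id"].astype(str)) - set(
            map(str, counts.index)
        )
        if unknown:
            warnings.append(
                f"domain table references {len(unknown)} unknown transcript(s)"
            )
    return {"fatal": [], "warnings": warnings}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full layered analysis; returns the run report dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "thresholds": {
        "alpha": config.alpha,
        "lfc_min": config.lfc_min,
        "high_expr": config.high_expr,
        "cut_fraction": config.cut_fraction,
        "support_lfc": config.support_lfc,
    }}
    timings: dict[str, float] = {}

    def stage(name: str):
        class _T:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return _T()

    truth = None
    family_truth = None
    if config.simulation is not None:
        sim_cfg = config.simulation
        with stage("simulate"):
            design = simulate.simulate_design(
                sim_cfg.n_individuals, sim_cfg.dropout_samples
            )
            exp = simulate.simulate_counts(sim_cfg, design)
            domain_table, flags, family_truth = simulate.simulate_annotations(
                sim_cfg
            )
            truth = exp.truth.copy()
            truth["receptor_family"] = family_truth.reindex(truth.index)
            counts, lengths = exp.counts, exp.lengths
            io.write_table(design, out / "design.tsv")
            io.write_matrix(counts, out / "counts.tsv")
            io.write_lengths(lengths, out / "lengths.tsv")
            truth.to_csv(out / "truth.tsv", sep="\t")
            io.write_table(domain_table, out / "domains.tsv")
            io.write_table(flags, out / "flags.tsv")
    else:
        with stage("load"):
            counts = io.read_matrix(config.inputs["counts"])
            lengths = io.read_lengths(config.inputs["lengths"])
            design = io.read_design(config.inputs["design"])
            domain_table = (
                domains.read_domain_table(config.inputs["domains"])
                if "domains" in config.inputs
                else None
            )
            flags = (
                domains.read_flags_table(config.inputs["flags"])
                if "flags" in config.inputs
                else None
            )
            diag = validate_inputs(counts, lengths, design, domain_table)
            report["stages"]["validate"] = diag

    with stage("screen"):
        if domain_table is not None:
            tally, calls = domains.screen_transcriptome(domain_table, flags)
            io.write_table(calls, out / "receptor_calls.tsv")
            report["stages"]["screen"] = {"tally": tally,
                                          "n_transcripts": len(calls)}
        else:
            calls = None

    with stage("normalize"):
        tpm = normalization.compute_tpm(counts, lengths)
        factors = normalization.compute_tmm_factors(counts)
        norm_expr = normalization.apply_tmm(tpm, factors)
        io.write_matrix(norm_expr, out / "tmm_tpm.tsv")
        factor_table = pd.DataFrame(
            {
                "sample_id": counts.columns,
                "library_size": counts.sum(axis=0).to_numpy(),
                "tmm_factor": factors.to_numpy(),
            }
        )
        io.write_table(factor_table, out / "tmm_factors.tsv")
        report["stages"]["normalize"] = {
            "n_samples": int(counts.shape[1]),
            "n_genes": int(counts.shape[0]),
        }

    with stage("layers"):
        assignment = layers.call_layers(
            counts, norm_expr, high_threshold=config.high_expr
        )
        assignment.to_csv(out / "layers.tsv", sep="\t")
        summary = layers.layer_summary(assignment)
        report["stages"]["layers"] = summary
        if truth is not None:
            immune = truth["is_immune"].reindex(counts.index)
            ratio = layers.immune_median_ratio(norm_expr, assignment, immune)
            report["stages"]["layers"]["immune_median"] = ratio
        if calls is not None:
            prr = calls.loc[calls.family != "none", "transcript_id"]
            prr = prr[prr.isin(assignment.index)]
            if len(prr):
                report["stages"]["layers"]["prr_summary"] = (
                    layers.layer_summary(assignment, prr)
                )
        presence = layers.presence_matrix(counts)
        ind_specific = assignment.index[
            assignment.layer == "individual_specific"
        ]
        lps_design = design[design.treatment == "LPS"]
        pairable = lps_design.groupby("individual_id").size()
        if len(ind_specific) >= 2 and (pairable == 2).sum() >= 2:
            res = layers.individuality_analysis(
                presence,
                lps_design[
                    lps_design.individual_id.isin(
                        pairable.index[pairable == 2]
                    )
                ],
                ind_specific,
                n_permutations=config.n_permutations,
                seed=config.seed,
            )
            (out / "individuality.nwk").write_text(
                layers.linkage_to_newick(res.linkage, res.sample_ids) + "\n"
            )
            report["stages"]["individuality"] = {
                "pairing_score": res.pairing_score,
                "p_value": res.p_value,
                "n_pairs": res.n_pairs,
                "tied": res.tied,
            }

    de_tables: dict[str, pd.DataFrame] = {}
    with stage("detest"):
        report["stages"]["de"] = {}
        for tp in sorted(design.timepoint.unique()):
            contrast = de.contrast_from_design(
                design, tp, alpha=config.alpha, lfc_min=config.lfc_min
            )
            table = de.test_contrast(counts, factors, contrast)
            table.to_csv(out / f"de_{tp}.tsv", sep="\t")
            de_tables[tp] = table
            report["stages"]["de"][tp] = {
                "n_significant": int(table.significant.sum()),
                "n_up": int((table.direction == "up").sum()),
                "n_down": int((table.direction == "down").sum()),
                "n_tested": int(table.tested.sum()),
            }
        tps = sorted(de_tables)
        if len(tps) == 2:
            overlap = de.timepoint_overlap(de_tables[tps[0]], de_tables[tps[1]])
            report["stages"]["overlap"] = overlap
            io.write_json(overlap, out / "overlap.json")

    with stage("partition"):
        report["stages"]["partition"] = {}
        for tp, table in de_tables.items():
            deg_ids = table.index[table.significant]
            if len(deg_ids) < 2:
                report["stages"]["partition"][tp] = {
                    "n_degs": int(len(deg_ids)),
                    "note": "too few DEGs to cluster",
                }
                continue
            contrast = de.contrast_from_design(
                design, tp, alpha=config.alpha, lfc_min=config.lfc_min
            )
            clusters = partition.cluster_degs(
                norm_expr,
                deg_ids,
                samples=contrast.group_a + contrast.group_b,
                cut_fraction=config.cut_fraction,
            )
            sup = partition.support_counts(
                norm_expr, table, contrast, deg_ids=clusters.index,
                support_lfc=config.support_lfc,
            )
            part = partition.label_partition(
                clusters, sup, n_reps=len(contrast.group_a)
            )
            part.to_csv(out / f"partition_{tp}.tsv", sep="\t",
                        index_label="gene_id")
            report["stages"]["partition"][tp] = partition.partition_summary(
                part
            )

    digests = {
        f.name: _digest(f)
        for f in sorted(out.iterdir())
        if f.suffix in {".tsv", ".json", ".nwk"}
    }
    report["digests"] = digests
    report["timings"] = timings
    io.write_json(
        {k: v for k, v in report.items() if k != "timings"},
        out / "run_report.json",
    )
    return report
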