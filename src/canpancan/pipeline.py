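"""End-to-end pipeline runner over a synthetic (or pre-generated) cohort.

Stages run in the analysis order QC -> pairing -> breed -> somatic filters ->
TMB -> recurrence -> CNA -> signatures, each consuming the previous stage's
in-memory outputs and writing its table under the run directory. A manifest
records the seed, per-stage record counts and exclusion reasons so case
accounting is auditable: a case excluded at QC or pairing never reappears
downstream.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import breed, burden, cna, filters, io, qc, signatures
from .simulate import SimConfig, simulate_annotation, simulate_cna, \
    simulate_germline, simulate_qc_metrics, simulate_somatic

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "run"
    seed: int = 0
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    filter_config: filters.FilterConfig = field(default_factory=filters.FilterConfig)
    segmenter: cna.SegmenterConfig = field(
        default_factory=lambda: cna.SegmenterConfig(permutations=2000))
    stages: tuple = ("qc", "pairing", "breed", "filters", "tmb", "cna", "signatures")
    allow_unfiltered: bool = False
    nmf_iterations: int = 10
    nmf_rank_range: tuple = (1, 4)


def _checksum(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.to_csv(index=False).encode()
    ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; returns the manifest (also written as JSON)."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "exclusions": {}}
    sim = config.sim

    cohort = simulate_germline(sim)
    candidates, somatic_truth = simulate_somatic(sim)
    metrics = simulate_qc_metrics(sim)
    alive = set(cohort.samples["case_id"])

    if "qc" in config.stages:
        report = qc.apply_qc_gates(metrics, config.qc_thresholds)
        io.write_tsv(report, os.path.join(config.out_dir, "qc_report.tsv"))
        failed = set(report.loc[report["status"] != "pass", "sample_id"])
        dropped = {c for c in alive if f"{c}_T" in failed or f"{c}_N" in failed}
        for c in sorted(dropped):
            manifest["exclusions"][c] = "qc_fail"
        alive -= dropped
        manifest["stages"]["qc"] = {
            "samples_in": len(report), "cases_dropped": len(dropped),
            "checksum": _checksum(report),
        }

    if "pairing" in config.stages:
        calls = cohort.calls[cohort.calls["case_id"].isin(alive)]
        pairing = qc.pairing_concordance(calls)
        io.write_tsv(pairing, os.path.join(config.out_dir, "pairing.tsv"))
        mispaired = set(pairing.loc[pairing["flag"] == "mispaired", "case_id"])
        for c in sorted(mispaired):
            manifest["exclusions"][c] = "mispaired"
        alive -= mispaired
        manifest["stages"]["pairing"] = {
            "cases_in": len(pairing), "cases_dropped": len(mispaired),
            "checksum": _checksum(pairing),
        }

    if "breed" in config.stages:
        labels = pd.Series(cohort.truth.breed_of_dog.set_index("dog_id")["breed"])
        panel = breed.discover_panel(cohort.vaf, cohort.depth, labels)
        io.write_tsv(panel, os.path.join(config.out_dir, "breed_panel.tsv"))
        assignments = []
        if not panel.empty:
            res, _, _ = breed.assign_breeds(cohort.vaf, cohort.depth, panel,
                                            labels, seed=config.seed)
            assignments = pd.DataFrame([vars(a) for a in res])
            io.write_tsv(assignments, os.path.join(config.out_dir,
                                                   "breed_assignments.tsv"))
        manifest["stages"]["breed"] = {
            "panel_sites": len(panel),
            "dogs_assigned": int(len(assignments)) if len(assignments) else 0,
            "checksum": _checksum(panel),
        }

    filtered = None
    if "filters" in config.stages:
        cand = candidates[candidates["case_id"].isin(alive)]
        filtered, log = filters.run_filters(cand, config=config.filter_config)
        io.write_tsv(filtered.drop(columns=["is_artifact", "artifact_class",
                                            "true_channel"], errors="ignore"),
                     os.path.join(config.out_dir, "somatic_filtered.tsv"))
        manifest["stages"]["filters"] = {
            "candidates_in": len(cand), "survivors": len(filtered),
            "rejected": len(log), "checksum": _checksum(filtered),
        }

    if "tmb" in config.stages:
        if filtered is None:
            if not config.allow_unfiltered:
                raise ValueError("TMB stage refuses unfiltered candidates "
                                 "(set allow_unfiltered to override)")
            filtered = candidates[candidates["case_id"].isin(alive)]
        callable_bases = pd.Series(sim.callable_mb * 1e6,
                                   index=sorted(alive))
        _, _, ann_truth = simulate_annotation(sim)
        problematic = set(ann_truth.genes.loc[ann_truth.genes["problematic"],
                                              "gene_id"])
        burdens = burden.compute_tmb(filtered, callable_bases, problematic)
        io.write_tsv(burdens, os.path.join(config.out_dir, "tmb.tsv"))
        manifest["stages"]["tmb"] = {
            "cases": len(burdens),
            "total_mutations": int(burdens["mutation_count"].sum()),
            "checksum": _checksum(burdens),
        }

    if "cna" in config.stages:
        bins, cna_truth = simulate_cna(sim, n_tumors=min(len(alive), 5))
        seg_rows = []
        for case, grp in bins.groupby("case_id"):
            segs = cna.segment_track(grp["log2_ratio"].to_numpy(),
                                     config.segmenter, seed=config.seed)
            segs.insert(0, "case_id", case)
            seg_rows.append(segs)
        segs_all = pd.concat(seg_rows, ignore_index=True)
        io.write_tsv(segs_all, os.path.join(config.out_dir, "cna_segments.tsv"))
        manifest["stages"]["cna"] = {
            "tumors": segs_all["case_id"].nunique(),
            "segments": len(segs_all), "checksum": _checksum(segs_all),
        }

    if "signatures" in config.stages and filtered is not None and len(filtered):
        catalog, n_uncls = signatures.build_catalog(filtered)
        sigset = signatures.extract_signatures(
            catalog, n_iterations=config.nmf_iterations,
            rank_range=config.nmf_rank_range, seed=config.seed)
        sig_df = pd.DataFrame(sigset.signatures,
                              columns=catalog.columns,
                              index=[f"S{i + 1}" for i in
                                     range(sigset.selected_rank)])
        io.write_tsv(sig_df.reset_index(names="signature"),
                     os.path.join(config.out_dir, "signatures.tsv"))
        manifest["stages"]["signatures"] = {
            "rank": sigset.selected_rank,
            "rank_votes": {str(k): v for k, v in sigset.rank_votes.items()},
            "unclassifiable": n_uncls, "checksum": _checksum(sig_df),
        }

    manifest["cases_final"] = sorted(alive)
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
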