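"""Generate the reference synthetic cohort used by the downstream analyses.

Two breeds x 30 dogs, two tumor types (0.4 and 1.0 mutations/Mb) with a 2x
TP53 burden effect, FFPE/oxoG artifact injection, annotation with problematic
genes, and per-tumor CNA tracks. Writes the cohort tables and truth tables
under results/cohort/.
"""

import pathlib

from canpancan import io
from canpancan.simulate import (
    BreedSpec,
    SimConfig,
    simulate_annotation,
    simulate_cna,
    simulate_germline,
    simulate_qc_metrics,
    simulate_somatic,
)

SEED = 1
OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "cohort"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED, breeds=[BreedSpec("Rottweiler"),
                                       BreedSpec("GoldenRetriever")],
                    n_dogs_per_breed=30, n_shared_sites=300,
                    n_specific_per_breed=25, n_swaps=3,
                    tumor_types={"OSA": 0.4, "OM": 1.0},
                    signature_mix={"OSA": [0.7, 0.2, 0.1],
                                   "OM": [0.1, 0.2, 0.7]},
                    artifact_rates={"frozen": 20.0, "FFPE": 50.0})
    cohort = simulate_germline(cfg)
    io.write_tsv(cohort.calls, OUT / "germline_calls.tsv")
    io.write_tsv(cohort.sites, OUT / "sites.tsv")
    io.write_tsv(cohort.truth.breed_of_dog, OUT / "truth_breeds.tsv")

    cand, somatic_truth = simulate_somatic(cfg)
    io.write_tsv(cand, OUT / "somatic_candidates.tsv")
    io.write_tsv(somatic_truth.tumors, OUT / "truth_tumors.tsv")

    genes, exons, ann_truth = simulate_annotation(cfg, n_genes=120,
                                                  n_problematic=12,
                                                  n_retrogenes=4)
    io.write_gtf(genes, exons, OUT / "annotation.gtf")
    io.write_bed(genes, OUT / "annotation.bed")
    io.write_tsv(ann_truth.genes, OUT / "truth_genes.tsv")

    bins, cna_truth = simulate_cna(cfg, n_tumors=10)
    io.write_tsv(bins, OUT / "cna_bins.tsv")
    io.write_tsv(cna_truth.cna_segments, OUT / "truth_cna_segments.tsv")
    io.write_tsv(simulate_qc_metrics(cfg, n_fail=3), OUT / "qc_metrics.tsv")

    print(f"cohort written to {OUT}")
    print(f"  {len(cohort.samples)} samples, {len(cand)} somatic candidates "
          f"({int(cand['is_artifact'].sum())} injected artifacts), "
          f"{len(genes)} genes, 10 CNA tracks, "
          f"{len(cohort.truth.swapped_case_ids)} injected tumor-normal swaps")


if __name__ == "__main__":
    main()
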