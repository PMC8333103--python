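"""Recurrence statistics and enrichment scores on the filtered cohort.

MAF-outlier screen within each tumor, per-scope recurrence of mutant genes,
signed enrichment scores by tumor type, and a worked cross-species comparison
on summary tables. Run 01 and 04 first.
"""

import pathlib

import pandas as pd

from canpancan import io, recurrence

ROOT = pathlib.Path(__file__).resolve().parent.parent / "results"


def main():
    mutations = io.read_tsv(ROOT / "somatic_filtered.tsv")
    tumors = io.read_tsv(ROOT / "cohort" / "truth_tumors.tsv")
    ttype = tumors.set_index("case_id")["tumor_type"]

    maf = recurrence.maf_outlier_test(mutations)
    io.write_tsv(maf[["sample_id", "chrom", "pos", "gene", "maf",
                      "maf_outlier_p", "maf_testable"]],
                 ROOT / "maf_outliers.tsv")
    sig_frac = (maf["maf_outlier_p"] < 0.05).mean()
    print(f"MAF-outlier screen: {sig_frac:.1%} of mutations significantly "
          f"above their tumor's remaining MAF")

    indicator = pd.crosstab(mutations["case_id"],
                            mutations["gene"]).astype(bool)
    indicator = indicator.drop(columns=[""], errors="ignore")
    # keep genes altered in >= 3 cases to keep the table readable
    indicator = indicator.loc[:, indicator.sum() >= 3]
    scores = recurrence.enrichment_scores(indicator,
                                          ttype.loc[indicator.index])
    io.write_tsv(scores, ROOT / "enrichment_scores.tsv")
    top = scores.sort_values("score", ascending=False).iloc[0]
    print(f"strongest enrichment: {top['entity']} in {top['scope']} "
          f"(score {top['score']:.2f}, q {top['q']:.3g})")

    dog = pd.DataFrame({"altered": [20, 5], "total": [60, 60]},
                       index=["TP53", "PIK3CA"])
    human = pd.DataFrame({"altered": [22, 40], "total": [70, 70]},
                         index=["TP53", "PIK3CA"])
    cross = recurrence.cross_species_compare(dog, human)
    io.write_tsv(cross, ROOT / "cross_species.tsv")
    print("cross-species example:")
    for r in cross.itertuples(index=False):
        print(f"  {r.entity}: dog {r.dog_freq:.2f} vs human {r.human_freq:.2f}"
              f" -> {r.call} (q {r.q:.3g}, fold {r.fold:.1f})")


if __name__ == "__main__":
    main()
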